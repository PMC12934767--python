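# Classical HLA class I and II loci plus common paralogs; one symbol per line.
HLA-A
HLA-B
HLA-C
HLA-E
HLA-F
HLA-G
HLA-DRA
HLA-DRB1
HLA-DRB3
HLA-DRB4
HLA-DRB5
HLA-DQA1
HLA-DQA2
HLA-DQB1
HLA-DQB2
HLA-DPA1
HLA-DPB1
HLA-DMA
HLA-DMB
HLA-DOA
HLA-DOB
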