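"""Transcript-model analyses of ASAS exons.

Classifies alternatively spliced exons into genomic regions (5' UTR, CDS,
3' UTR, non-coding exon) against a reference transcript, tests per-class
enrichment of ASAS exons against an annotated-exon background, and compares
start-codon positions between isoforms that include versus skip an ASAS exon
— 5' UTR cassette exons can move the start codon and hence alter the protein.

All internal coordinates are 0-based half-open; GTF input (1-based closed) is
converted on read.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

__all__ = [
    "TranscriptModel",
    "read_gtf_transcripts",
    "classify_exon_region",
    "region_enrichment",
    "compare_start_codons",
]

FIVE_UTR = "FIVE_UTR"
CDS = "CDS"
THREE_UTR = "THREE_UTR"
NC_EXON = "NC_EXON"
REGION_CLASSES = [FIVE_UTR, CDS, THREE_UTR, NC_EXON]


@dataclass
class TranscriptModel:
    transcript_id: str
    gene_id: str
    strand: str
    exons: list[tuple[int, int]]          # 0-based half-open, sorted
    cds: list[tuple[int, int]]
    start_codon: int | None = None        # genomic position of first start-codon base,
    # strand-normalized (5'-most in transcript orientation)
    is_canonical: bool = False

    def __post_init__(self):
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)
        for a, b in zip(self.exons, self.exons[1:]):
            if a[1] > b[0]:
                raise ValueError(f"{self.transcript_id}: overlapping exons {a} {b}")
        if self.start_codon is not None and self.cds:
            if not any(s <= self.start_codon < e for s, e in self.cds):
                raise ValueError(f"{self.transcript_id}: start codon outside CDS")

    @property
    def is_coding(self) -> bool:
        return bool(self.cds)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def cds_span(self) -> tuple[int, int] | None:
        return (self.cds[0][0], self.cds[-1][1]) if self.cds else None

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)


def read_gtf_transcripts(path: str) -> list[TranscriptModel]:
    """Read GENCODE-dialect GTF into transcript models (via gffutils)."""
    import gffutils

    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    models = []
    for tx in db.features_of_type("transcript"):
        exons = [(f.start - 1, f.end) for f in db.children(tx, featuretype="exon")]
        cds = [(f.start - 1, f.end) for f in db.children(tx, featuretype="CDS")]
        starts = [(f.start - 1, f.end) for f in db.children(tx, featuretype="start_codon")]
        start = None
        if starts:
            lo = min(s for s, _ in starts)
            hi = max(e for _, e in starts)
            start = lo if tx.strand == "+" else hi - 1
        tags = tx.attributes.get("tag", [])
        models.append(
            TranscriptModel(
                transcript_id=tx.id,
                gene_id=tx.attributes.get("gene_id", [""])[0],
                strand=tx.strand,
                exons=exons,
                cds=cds,
                start_codon=start,
                is_canonical="Ensembl_canonical" in tags or "canonical" in tags,
            )
        )
    return models


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def _reference_transcript(transcripts: list[TranscriptModel]) -> TranscriptModel | None:
    coding = [t for t in transcripts if t.is_coding]
    canonical = [t for t in transcripts if t.is_canonical]
    if canonical:
        # prefer a coding canonical transcript
        coding_canonical = [t for t in canonical if t.is_coding]
        return (coding_canonical or canonical)[0]
    if coding:
        return max(coding, key=lambda t: (t.cds_length, t.transcript_id))
    return None


def classify_exon_region(exon: tuple[int, int], transcripts: list[TranscriptModel]) -> str:
    """Assign one region class to an exon interval.

    Classified against the canonical transcript when flagged, otherwise the
    longest-CDS coding transcript; genes with no coding transcript give
    NC_EXON. The class is the transcript region (5' UTR span, CDS span,
    3' UTR span, strand-aware) with the largest base overlap; ties resolve
    FIVE_UTR > THREE_UTR > CDS.
    """
    hits = [t for t in transcripts if _overlap(exon, t.span) > 0]
    if not hits:
        raise ValueError(f"exon {exon} overlaps no supplied transcript")
    ref = _reference_transcript(hits)
    if ref is None or not ref.is_coding:
        return NC_EXON
    tx_start, tx_end = ref.span
    cds_start, cds_end = ref.cds_span
    if ref.strand == "+":
        five = (tx_start, cds_start)
        three = (cds_end, tx_end)
    else:
        five = (cds_end, tx_end)
        three = (tx_start, cds_start)
    overlaps = {
        FIVE_UTR: _overlap(exon, five),
        CDS: _overlap(exon, (cds_start, cds_end)),
        THREE_UTR: _overlap(exon, three),
    }
    if max(overlaps.values()) == 0:
        return NC_EXON
    priority = {FIVE_UTR: 0, THREE_UTR: 1, CDS: 2}
    return max(overlaps, key=lambda c: (overlaps[c], -priority[c]))


def region_enrichment(asas_classes: list[str], background_classes: list[str]) -> pd.DataFrame:
    """Per-class two-sided Fisher test of ASAS exons vs background exons."""
    rows = []
    if not asas_classes:
        return pd.DataFrame(columns=["region", "asas_in", "asas_out", "bg_in", "bg_out", "odds_ratio", "p"])
    a = pd.Series(asas_classes).value_counts()
    b = pd.Series(background_classes).value_counts()
    na, nb = len(asas_classes), len(background_classes)
    for cls in REGION_CLASSES:
        ai = int(a.get(cls, 0))
        bi = int(b.get(cls, 0))
        table = [[ai, na - ai], [bi, nb - bi]]
        orat, p = stats.fisher_exact(table, alternative="two-sided")
        rows.append(
            {
                "region": cls,
                "asas_in": ai,
                "asas_out": na - ai,
                "bg_in": bi,
                "bg_out": nb - bi,
                "odds_ratio": float(orat),
                "p": float(p),
            }
        )
    return pd.DataFrame(rows)


def _includes_exon(t: TranscriptModel, exon: tuple[int, int]) -> bool:
    return tuple(exon) in {tuple(e) for e in t.exons}


def _skips_exon(t: TranscriptModel, exon: tuple[int, int], up_flank: tuple[int, int], down_flank: tuple[int, int]) -> bool:
    """Exon chain joins the flanking exons while omitting the event exon."""
    if _includes_exon(t, exon):
        return False
    for u, v in zip(t.exons, t.exons[1:]):
        if u[1] == up_flank[1] and v[0] == down_flank[0]:
            return True
    return False


def compare_start_codons(event, transcripts: list[TranscriptModel]) -> dict:
    """Compare start codons between inclusion and skipping isoforms of an event.

    ``event`` needs exon_start/exon_end and upstream_flank/downstream_flank
    ("start-end" strings or (start, end) pairs). Per-inclusion-transcript
    verdicts are SAME when the (strand-normalized) start-codon position equals
    that of any skipping transcript, else ALTERNATIVE with a flag for whether
    the alternative start lies inside the ASAS exon. Transcripts lacking a
    start codon are untestable.
    """

    def interval(v):
        if isinstance(v, str):
            s, e = v.split("-")
            return int(s), int(e)
        return int(v[0]), int(v[1])

    exon = (int(event["exon_start"]), int(event["exon_end"]))
    up = interval(event["upstream_flank"])
    down = interval(event["downstream_flank"])

    inclusion = [t for t in transcripts if _includes_exon(t, exon)]
    skipping = [t for t in transcripts if _skips_exon(t, exon, up, down)]
    ignored = len(transcripts) - len(inclusion) - len(skipping)

    result = {
        "event_id": event.get("event_id", ""),
        "inclusion_transcripts": [t.transcript_id for t in inclusion],
        "skipping_transcripts": [t.transcript_id for t in skipping],
        "n_partial_ignored": ignored,
        "per_transcript": [],
        "verdict": None,
        "any_alternative": False,
        "alt_start_within_exon": None,
    }
    if not inclusion or not skipping:
        result["verdict"] = "UNTESTABLE"
        result["reason"] = "MISSING_ISOFORM_SIDE"
        return result
    skip_starts = {t.start_codon for t in skipping if t.start_codon is not None}
    testable = False
    for t in inclusion:
        if t.start_codon is None or not skip_starts:
            result["per_transcript"].append(
                {"transcript_id": t.transcript_id, "verdict": "UNTESTABLE"}
            )
            continue
        testable = True
        if t.start_codon in skip_starts:
            result["per_transcript"].append(
                {"transcript_id": t.transcript_id, "verdict": "SAME"}
            )
        else:
            within = exon[0] <= t.start_codon < exon[1]
            result["per_transcript"].append(
                {
                    "transcript_id": t.transcript_id,
                    "verdict": "ALTERNATIVE",
                    "alt_start_within_exon": within,
                }
            )
    if not testable:
        result["verdict"] = "UNTESTABLE"
        result["reason"] = "MISSING_START_CODON"
        return result
    alts = [r for r in result["per_transcript"] if r["verdict"] == "ALTERNATIVE"]
    result["any_alternative"] = bool(alts)
    result["verdict"] = "ALTERNATIVE" if alts else "SAME"
    if alts:
        result["alt_start_within_exon"] = any(r["alt_start_within_exon"] for r in alts)
    return result
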