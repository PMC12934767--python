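"""Synthetic ASAS cohort generation.

Emulates the statistical structure of a post-mortem brain cohort assayed for
allele-specific alternative splicing: phased heterozygous SNPs inside
alternatively spliced and constitutive exons, a planted functional SNP per gene
whose allele shifts exon inclusion by ``delta_psi``, and allelic read counts
drawn from an overdispersed beta-binomial. Disease-specific regulation is
modelled by adding ``ad_specific_effect`` to the inclusion shift in AD-labelled
individuals only.

The generative model, per gene:

* one cassette (SE) exon per event, flanked by constitutive exons;
* one functional SNP (minor-allele frequency ``functional_maf``), placed inside
  the cassette exon with probability 0.5 and otherwise intronic within 300 bp
  of it;
* per haplotype h, inclusion level ``psi_h = baseline_psi + delta * allele_h``
  (clamped to [0, 1]; clamping is counted);
* a tag SNP inside the cassette exon, in strong LD with the functional SNP
  (per-haplotype allele mismatch ``tag_ld_mismatch``), whose expected
  reference-allele read fraction is ``psi_ref_hap / (psi_h1 + psi_h2)`` for
  heterozygotes — LD keeps the imbalance direction consistent across
  individuals, as for a real cis-acting variant;
* constitutive SNPs with expected allelic ratio 0.5;
* read totals Poisson(``mean_coverage``), reference counts beta-binomial with
  intra-class correlation ``overdispersion`` around the expected fraction.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seeds import child_rng

__all__ = [
    "CohortSpec",
    "GenotypeMatrix",
    "SimulatedTruth",
    "Cohort",
    "simulate_cohort",
    "write_cohort",
    "read_cohort",
]

ALTERNATIVE = "ALTERNATIVE"
CONSTITUTIVE = "CONSTITUTIVE"

COUNT_COLUMNS = [
    "sample_id",
    "snp_id",
    "chrom",
    "pos",
    "ref_count",
    "alt_count",
    "gene_id",
    "region_class",
    "event_id",
]
EVENT_COLUMNS = [
    "event_id",
    "gene_id",
    "type",
    "chrom",
    "exon_start",
    "exon_end",
    "upstream_flank",
    "downstream_flank",
    "strand",
]
METADATA_COLUMNS = ["sample_id", "individual_id", "region", "group"]


def _check_interval(name, value, lo, hi, lo_open=False, hi_open=False):
    ok = (value > lo if lo_open else value >= lo) and (value < hi if hi_open else value <= hi)
    if not ok:
        lb = "(" if lo_open else "["
        rb = ")" if hi_open else "]"
        raise ValueError(f"{name}={value} outside {lb}{lo}, {hi}{rb}")


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a simulated cohort. Validated at construction."""

    n_individuals: int = 100
    n_genes: int = 10
    events_per_gene: int = 1
    functional_maf: float = 0.3
    delta_psi: float = 0.4
    baseline_psi: float = 0.5
    mean_coverage: float = 50.0
    overdispersion: float = 0.02
    constitutive_snps_per_gene: int = 3
    fraction_ad: float = 0.5
    ad_specific_effect: float = 0.0
    # per-haplotype probability that a tag-SNP allele disagrees with the
    # functional-SNP allele: 0 is perfect LD, 0.5 is linkage equilibrium.
    # 0.3 keeps a realistic cis correlation while leaving both genotype
    # classes represented among tag heterozygotes (the concordance score
    # needs that variation)
    tag_ld_mismatch: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be positive")
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.events_per_gene < 0:
            raise ValueError("events_per_gene must be non-negative")
        if self.constitutive_snps_per_gene < 1:
            raise ValueError("constitutive_snps_per_gene must be positive")
        if self.mean_coverage < 0:
            raise ValueError("mean_coverage must be non-negative")
        _check_interval("functional_maf", self.functional_maf, 0.0, 0.5, lo_open=True)
        _check_interval("delta_psi", self.delta_psi, 0.0, 1.0)
        _check_interval("baseline_psi", self.baseline_psi, 0.0, 1.0, lo_open=True, hi_open=True)
        _check_interval("overdispersion", self.overdispersion, 0.0, 0.9)
        _check_interval("fraction_ad", self.fraction_ad, 0.0, 1.0)
        _check_interval("ad_specific_effect", self.ad_specific_effect, -1.0, 1.0)
        _check_interval("tag_ld_mismatch", self.tag_ld_mismatch, 0.0, 0.5)


class GenotypeMatrix:
    """Phased genotypes, individuals x SNPs.

    Codes: 0 hom-ref (0|0), 1 het ref-on-h1 (0|1), 2 het alt-on-h1 (1|0),
    3 hom-alt (1|1), -1 missing.
    """

    HOM_REF, HET_01, HET_10, HOM_ALT, MISSING = 0, 1, 2, 3, -1

    def __init__(self, codes: pd.DataFrame, snps: pd.DataFrame):
        self.codes = codes.astype(np.int8)
        # snp table: snp_id, chrom, pos (0-based), gene_id, ref, alt
        self.snps = snps.reset_index(drop=True)

    @property
    def individuals(self) -> list[str]:
        return list(self.codes.index)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.codes.columns)

    def is_het(self, snp_id: str) -> pd.Series:
        c = self.codes[snp_id]
        return (c == self.HET_01) | (c == self.HET_10)

    def phase(self, individual: str, snp_id: str) -> str:
        c = int(self.codes.at[individual, snp_id])
        if c == self.HET_01:
            return "REF_ON_H1"
        if c == self.HET_10:
            return "ALT_ON_H1"
        return "UNPHASED"

    def equals(self, other: "GenotypeMatrix") -> bool:
        return self.codes.equals(other.codes) and self.snps.reset_index(drop=True).equals(
            other.snps.reset_index(drop=True)
        )


@dataclass
class SimulatedTruth:
    """Ground truth of the planted signal."""

    functional_snp_ids: list[str]
    table: pd.DataFrame  # individual_id, event_id, gene_id, functional_snp_id,
    # hap1_allele, hap2_allele, psi_h1, psi_h2
    n_clamped: int = 0


@dataclass
class Cohort:
    spec: CohortSpec
    genotypes: GenotypeMatrix
    events: pd.DataFrame
    counts: pd.DataFrame
    metadata: pd.DataFrame
    truth: SimulatedTruth
    untestable_genes: list[str] = field(default_factory=list)


def _betabinom_draws(rng, totals: np.ndarray, mu: np.ndarray, rho: float) -> np.ndarray:
    """Reference-count draws; rho = 0 degenerates to binomial."""
    mu = np.clip(mu, 0.0, 1.0)
    if rho == 0.0:
        return rng.binomial(totals, mu)
    a = mu * (1.0 - rho) / rho
    b = (1.0 - mu) * (1.0 - rho) / rho
    # deterministic edges: mu 0/1 give degenerate beta
    p = np.where(
        (mu <= 0.0) | (mu >= 1.0),
        mu,
        rng.beta(np.clip(a, 1e-12, None), np.clip(b, 1e-12, None)),
    )
    return rng.binomial(totals, p)


def simulate_cohort(spec: CohortSpec) -> Cohort:
    """Generate a phased, counted synthetic cohort. Deterministic given spec."""
    rng = child_rng(spec.seed, "cohort")
    n = spec.n_individuals
    individuals = [f"I{i:04d}" for i in range(n)]
    samples = [f"S{i:04d}" for i in range(n)]

    n_ad = int(round(spec.fraction_ad * n))
    group = np.array(["control"] * n, dtype=object)
    ad_idx = rng.permutation(n)[:n_ad]
    group[ad_idx] = "AD"
    metadata = pd.DataFrame(
        {
            "sample_id": samples,
            "individual_id": individuals,
            "region": "R1",
            "group": group,
        }
    )

    gene_span = 20_000
    gene_gap = 100_000
    snp_rows = []
    event_rows = []
    codes = {}
    truth_rows = []
    functional_ids = []
    n_clamped = 0
    count_frames = []
    untestable = []

    is_ad = group == "AD"

    for g in range(spec.n_genes):
        gene_id = f"G{g:03d}"
        gene_start = g * gene_gap
        chrom = "chr1"

        # functional SNP genotype: two haplotype alleles, HWE at functional_maf
        f_snp = f"{gene_id}_fsnp"
        f_h1 = rng.random(n) < spec.functional_maf
        f_h2 = rng.random(n) < spec.functional_maf
        functional_ids.append(f_snp)

        # per-individual inclusion shift (AD-specific modifier)
        delta = np.where(
            is_ad, spec.delta_psi + spec.ad_specific_effect, spec.delta_psi
        )
        psi_h1 = spec.baseline_psi + delta * f_h1
        psi_h2 = spec.baseline_psi + delta * f_h2
        clip1 = np.clip(psi_h1, 0.0, 1.0)
        clip2 = np.clip(psi_h2, 0.0, 1.0)
        n_clamped += int(np.sum(clip1 != psi_h1) + np.sum(clip2 != psi_h2))
        psi_h1, psi_h2 = clip1, clip2

        gene_events = []
        for e in range(spec.events_per_gene):
            event_id = f"{gene_id}_E{e}"
            exon_start = gene_start + 5_000 + e * 3_000
            exon_end = exon_start + 150
            event_rows.append(
                {
                    "event_id": event_id,
                    "gene_id": gene_id,
                    "type": "SE",
                    "chrom": chrom,
                    "exon_start": exon_start,
                    "exon_end": exon_end,
                    "upstream_flank": f"{exon_start - 1_000}-{exon_start - 850}",
                    "downstream_flank": f"{exon_end + 850}-{exon_end + 1_000}",
                    "strand": "+",
                }
            )
            gene_events.append((event_id, exon_start, exon_end))
            for i, ind in enumerate(individuals):
                truth_rows.append(
                    {
                        "individual_id": ind,
                        "event_id": event_id,
                        "gene_id": gene_id,
                        "functional_snp_id": f_snp,
                        "hap1_allele": int(f_h1[i]),
                        "hap2_allele": int(f_h2[i]),
                        "psi_h1": psi_h1[i],
                        "psi_h2": psi_h2[i],
                    }
                )

        # functional SNP position relative to the first event's exon
        if gene_events:
            _, ex_s, ex_e = gene_events[0]
            exonic = bool(rng.random() < 0.5)
            if exonic:
                f_pos = int(rng.integers(ex_s, ex_e))
            else:
                off = int(rng.integers(1, 301))
                f_pos = ex_s - off if rng.random() < 0.5 else ex_e - 1 + off
        else:
            exonic = False
            f_pos = gene_start + 1_000
        snp_rows.append(
            {"snp_id": f_snp, "chrom": chrom, "pos": f_pos, "gene_id": gene_id,
             "ref": "A", "alt": "G"}
        )
        # haplotype-allele pairs to codes: (0,0)->0, (0,1)->1, (1,0)->2, (1,1)->3
        codes[f_snp] = np.select(
            [~f_h1 & ~f_h2, ~f_h1 & f_h2, f_h1 & ~f_h2, f_h1 & f_h2],
            [0, 1, 2, 3],
        ).astype(np.int8)

        gene_counts = []

        def emit_counts(snp_id, pos, region_class, event_id, code, mu_het_h1ref):
            """Counts for one SNP across individuals.

            mu_het_h1ref: expected ref fraction when ref allele is on h1.
            """
            totals = rng.poisson(spec.mean_coverage, size=n)
            mu = np.empty(n)
            mu[code == 0] = 1.0
            mu[code == 3] = 0.0
            mu[code == 1] = mu_het_h1ref[code == 1]
            mu[code == 2] = 1.0 - mu_het_h1ref[code == 2]
            ref = _betabinom_draws(rng, totals, mu, spec.overdispersion)
            gene_counts.append(
                pd.DataFrame(
                    {
                        "sample_id": samples,
                        "snp_id": snp_id,
                        "chrom": chrom,
                        "pos": pos,
                        "ref_count": ref,
                        "alt_count": totals - ref,
                        "gene_id": gene_id,
                        "region_class": region_class,
                        "event_id": event_id,
                    }
                )
            )
            return totals

        psi_sum = psi_h1 + psi_h2
        with np.errstate(invalid="ignore", divide="ignore"):
            mu_alt_h1ref = np.where(psi_sum > 0, psi_h1 / np.where(psi_sum > 0, psi_sum, 1.0), 0.5)

        all_totals = []
        for event_id, ex_s, ex_e in gene_events:
            tag_snp = f"{event_id}_tag"
            # tag alleles track the functional haplotype up to rare mismatches,
            # so allelic-ratio direction is consistent across individuals
            t_h1 = f_h1 ^ (rng.random(n) < spec.tag_ld_mismatch)
            t_h2 = f_h2 ^ (rng.random(n) < spec.tag_ld_mismatch)
            t_code = np.select(
                [~t_h1 & ~t_h2, ~t_h1 & t_h2, t_h1 & ~t_h2, t_h1 & t_h2], [0, 1, 2, 3]
            ).astype(np.int8)
            t_pos = int(rng.integers(ex_s, ex_e))
            snp_rows.append(
                {"snp_id": tag_snp, "chrom": chrom, "pos": t_pos, "gene_id": gene_id,
                 "ref": "C", "alt": "T"}
            )
            codes[tag_snp] = t_code
            all_totals.append(emit_counts(tag_snp, t_pos, ALTERNATIVE, event_id, t_code, mu_alt_h1ref))
            # exonic functional SNP doubles as an expressed alt-region SNP
            if exonic and ex_s <= f_pos < ex_e and event_id == gene_events[0][0]:
                all_totals.append(
                    emit_counts(f_snp, f_pos, ALTERNATIVE, event_id, codes[f_snp], mu_alt_h1ref)
                )

        for c in range(spec.constitutive_snps_per_gene):
            c_snp = f"{gene_id}_const{c}"
            c_h1 = rng.random(n) < 0.5
            c_h2 = rng.random(n) < 0.5
            c_code = np.select(
                [~c_h1 & ~c_h2, ~c_h1 & c_h2, c_h1 & ~c_h2, c_h1 & c_h2], [0, 1, 2, 3]
            ).astype(np.int8)
            c_pos = gene_start + 2_000 + c * 200
            snp_rows.append(
                {"snp_id": c_snp, "chrom": chrom, "pos": c_pos, "gene_id": gene_id,
                 "ref": "G", "alt": "A"}
            )
            codes[c_snp] = c_code
            all_totals.append(
                emit_counts(c_snp, c_pos, CONSTITUTIVE, "", c_code, np.full(n, 0.5))
            )

        if all_totals and int(np.sum(np.concatenate(all_totals))) == 0:
            untestable.append(gene_id)
        count_frames.extend(gene_counts)

    snps = pd.DataFrame(snp_rows)
    geno = GenotypeMatrix(
        pd.DataFrame(codes, index=pd.Index(individuals, name="individual_id")), snps
    )
    events = pd.DataFrame(event_rows, columns=EVENT_COLUMNS)
    counts = (
        pd.concat(count_frames, ignore_index=True)
        if count_frames
        else pd.DataFrame(columns=COUNT_COLUMNS)
    )
    truth = SimulatedTruth(
        functional_snp_ids=functional_ids,
        table=pd.DataFrame(truth_rows),
        n_clamped=n_clamped,
    )
    return Cohort(
        spec=spec,
        genotypes=geno,
        events=events,
        counts=counts,
        metadata=metadata,
        truth=truth,
        untestable_genes=untestable,
    )


_CODE_TO_GT = {0: "0|0", 1: "0|1", 2: "1|0", 3: "1|1", -1: ".|."}
_GT_TO_CODE = {v: k for k, v in _CODE_TO_GT.items()}


def write_cohort(cohort: Cohort, out_dir: str) -> dict[str, str]:
    """Write VCF + TSV tables; returns a manifest of logical name -> path.

    VCF positions are written 1-based per VCF v4.2; internal coordinates are
    0-based half-open.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "vcf": os.path.join(out_dir, "genotypes.vcf"),
        "events": os.path.join(out_dir, "events.tsv"),
        "counts": os.path.join(out_dir, "counts.tsv"),
        "metadata": os.path.join(out_dir, "metadata.tsv"),
        "truth": os.path.join(out_dir, "truth.tsv"),
    }
    geno = cohort.genotypes
    snps = geno.snps.sort_values(["chrom", "pos", "snp_id"])
    with open(paths["vcf"], "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=chr1>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.individuals)
            + "\n"
        )
        for _, row in snps.iterrows():
            gts = "\t".join(
                _CODE_TO_GT[int(c)] for c in geno.codes[row["snp_id"]].to_numpy()
            )
            fh.write(
                f"{row['chrom']}\t{int(row['pos']) + 1}\t{row['snp_id']}\t"
                f"{row['ref']}\t{row['alt']}\t.\tPASS\t.\tGT\t{gts}\n"
            )
    cohort.events.to_csv(paths["events"], sep="\t", index=False)
    cohort.counts.to_csv(paths["counts"], sep="\t", index=False)
    cohort.metadata.to_csv(paths["metadata"], sep="\t", index=False)
    cohort.truth.table.to_csv(paths["truth"], sep="\t", index=False, float_format="%.10g")
    return paths


def read_genotypes_vcf(path: str) -> GenotypeMatrix:
    """Read a phased VCF into a GenotypeMatrix (positions converted to 0-based)."""
    from cyvcf2 import VCF

    vcf = VCF(path)
    individuals = list(vcf.samples)
    snp_rows = []
    code_cols = {}
    for var in vcf:
        gts = var.genotypes  # [a0, a1, phased] per sample
        col = np.full(len(individuals), -1, dtype=np.int8)
        for i, (a0, a1, *_) in enumerate(gts):
            if a0 < 0 or a1 < 0:
                continue
            col[i] = {(0, 0): 0, (0, 1): 1, (1, 0): 2, (1, 1): 3}[(a0, a1)]
        snp_rows.append(
            {
                "snp_id": var.ID,
                "chrom": var.CHROM,
                "pos": var.POS - 1,
                "gene_id": "",
                "ref": var.REF,
                "alt": var.ALT[0] if var.ALT else ".",
            }
        )
        code_cols[var.ID] = col
    snps = pd.DataFrame(snp_rows)
    codes = pd.DataFrame(code_cols, index=pd.Index(individuals, name="individual_id"))
    return GenotypeMatrix(codes, snps)


def read_cohort(out_dir: str, spec: CohortSpec | None = None) -> Cohort:
    """Read back a written cohort directory."""
    geno = read_genotypes_vcf(os.path.join(out_dir, "genotypes.vcf"))
    events = pd.read_csv(
        os.path.join(out_dir, "events.tsv"), sep="\t", keep_default_na=False
    )
    counts = pd.read_csv(
        os.path.join(out_dir, "counts.tsv"), sep="\t", keep_default_na=False
    )
    metadata = pd.read_csv(os.path.join(out_dir, "metadata.tsv"), sep="\t")
    truth_tbl = pd.read_csv(os.path.join(out_dir, "truth.tsv"), sep="\t")
    truth = SimulatedTruth(
        functional_snp_ids=sorted(truth_tbl["functional_snp_id"].unique()),
        table=truth_tbl,
    )
    # gene_id is not encoded in the VCF; restore from counts and the truth table
    gene_map = counts.drop_duplicates("snp_id").set_index("snp_id")["gene_id"].to_dict()
    gene_map.update(
        truth_tbl.drop_duplicates("functional_snp_id")
        .set_index("functional_snp_id")["gene_id"]
        .to_dict()
    )
    geno.snps["gene_id"] = geno.snps["snp_id"].map(gene_map).fillna("")
    return Cohort(
        spec=spec or CohortSpec(),
        genotypes=geno,
        events=events,
        counts=counts,
        metadata=metadata,
        truth=truth,
    )
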