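"""Run configuration and input validation."""

from __future__ import annotations

import os
from dataclasses import asdict, dataclass, field, fields

import pandas as pd
import yaml

from .cohort import COUNT_COLUMNS, EVENT_COLUMNS, METADATA_COLUMNS

__all__ = ["RunConfig", "validate_inputs"]


@dataclass
class RunConfig:
    """All pipeline thresholds and paths.

    Threshold defaults are the analysis defaults used throughout the package:
    FDR 0.05, het fraction 10%, usable-sample fraction 10%, >= 5 samples per
    group with a 0.1 minimum ratio difference at nominal alpha 0.05, 200 kb
    GWAS window, 10,000 matched background sets, 1,000 permutation /
    resampling iterations, 100 random distance sets.
    """

    out_dir: str = "asas_run"
    counts: str | None = None
    events: str | None = None
    vcf: str | None = None
    metadata: str | None = None

    # simulation (used when no input paths are given)
    simulate: bool = True
    n_individuals: int = 100
    n_genes: int = 10
    delta_psi: float = 0.4
    baseline_psi: float = 0.5
    mean_coverage: float = 50.0
    overdispersion: float = 0.02
    functional_maf: float = 0.3
    fraction_ad: float = 0.5
    ad_specific_effect: float = 0.0

    # stage toggles
    run_detect: bool = True
    run_concordance: bool = True
    run_differential: bool = True

    # statistical thresholds
    fdr_threshold: float = 0.05
    min_coverage: int = 20
    het_fraction: float = 0.10
    sample_fraction: float = 0.10
    min_stratum_size: int = 20
    min_per_group: int = 5
    delta_min: float = 0.1
    alpha: float = 0.05
    window: int = 200_000
    n_go_sets: int = 10_000
    n_permutations: int = 1000
    n_fold_iterations: int = 1000
    n_random_distance_sets: int = 100

    seed: int = 0
    hla_genes: list[str] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def asdict(self) -> dict:
        return asdict(self)


def _check_columns(path: str, required: list[str], report: list[str]) -> pd.DataFrame | None:
    if not os.path.exists(path):
        report.append(f"ERROR missing file: {path}")
        return None
    try:
        df = pd.read_csv(path, sep="\t", keep_default_na=False)
    except Exception as exc:  # noqa: BLE001 - report, don't raise
        report.append(f"ERROR unparsable {path}: {exc}")
        return None
    missing = [c for c in required if c not in df.columns]
    if missing:
        report.append(f"ERROR {path}: missing columns {missing}")
        return None
    return df


def validate_inputs(config: RunConfig) -> dict:
    """Schema checks for configured input tables; returns a report dict."""
    messages: list[str] = []
    summary: dict[str, int] = {}
    if config.counts:
        counts = _check_columns(config.counts, COUNT_COLUMNS, messages)
        if counts is not None:
            zero = (counts["ref_count"] + counts["alt_count"]) == 0
            if zero.any():
                messages.append(
                    f"WARN {int(zero.sum())} count rows with zero coverage (untestable)"
                )
            bad_event = (counts["region_class"] == "ALTERNATIVE") & (counts["event_id"] == "")
            if bad_event.any():
                messages.append(
                    f"ERROR {int(bad_event.sum())} ALTERNATIVE rows lack an event_id"
                )
            summary["count_rows"] = len(counts)
            summary["genes"] = counts["gene_id"].nunique()
            summary["snps"] = counts["snp_id"].nunique()
    if config.events:
        events = _check_columns(config.events, EVENT_COLUMNS, messages)
        if events is not None:
            bad = events[~events["type"].isin(["SE", "RI", "A5SS", "A3SS"])]
            if len(bad):
                messages.append(f"ERROR {len(bad)} events with unknown type")
            summary["events"] = len(events)
    if config.metadata:
        meta = _check_columns(config.metadata, METADATA_COLUMNS, messages)
        if meta is not None:
            bad = meta[~meta["group"].isin(["AD", "control"])]
            if len(bad):
                messages.append(f"ERROR {len(bad)} metadata rows with unknown group")
            summary["samples"] = len(meta)
    if config.vcf:
        if not os.path.exists(config.vcf):
            messages.append(f"ERROR missing file: {config.vcf}")
        else:
            with open(config.vcf) as fh:
                first = fh.readline()
            if not first.startswith("##fileformat=VCF"):
                messages.append(f"ERROR {config.vcf}: not a VCF (bad header)")
    ok = not any(m.startswith("ERROR") for m in messages)
    return {"ok": ok, "messages": messages, "summary": summary}
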