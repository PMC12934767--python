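"""Pipeline orchestration: simulate -> detect -> concordance -> differential.

Each run writes its outputs and a manifest (config echo, seed, input digests,
row counts) into the run directory; identical config + seed reproduces
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os

import pandas as pd

from .cohort import Cohort, CohortSpec, read_cohort, simulate_cohort, write_cohort
from .concordance import ConcordanceConfig, run_mode
from .config import RunConfig, validate_inputs
from .detect import call_asas, filter_hla
from .differential import differential_scan, disease_specific_functional

__all__ = ["run_pipeline"]

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write(df: pd.DataFrame, path: str) -> int:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    return len(df)


def _load_inputs(config: RunConfig) -> Cohort:
    if config.simulate:
        spec = CohortSpec(
            n_individuals=config.n_individuals,
            n_genes=config.n_genes,
            delta_psi=config.delta_psi,
            baseline_psi=config.baseline_psi,
            mean_coverage=config.mean_coverage,
            overdispersion=config.overdispersion,
            functional_maf=config.functional_maf,
            fraction_ad=config.fraction_ad,
            ad_specific_effect=config.ad_specific_effect,
            seed=config.seed,
        )
        return simulate_cohort(spec)
    for name in ("counts", "events", "vcf", "metadata"):
        path = getattr(config, name)
        if not path or not os.path.exists(path):
            raise FileNotFoundError(f"required input '{name}' missing: {path}")
    # inputs share a directory layout with write_cohort
    return read_cohort(os.path.dirname(config.counts))


def run_pipeline(config: RunConfig) -> dict:
    """Execute enabled stages in dependency order; returns the run manifest."""
    os.makedirs(config.out_dir, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "config": config.asdict(),
        "stages": [],
        "outputs": {},
        "input_digests": {},
        "status": "incomplete",
    }
    config.to_yaml(os.path.join(config.out_dir, "config.yaml"))

    report = validate_inputs(config)
    if not report["ok"]:
        manifest["validation"] = report
        _dump_manifest(manifest, config.out_dir)
        raise ValueError(f"input validation failed: {report['messages']}")
    manifest["validation"] = report

    try:
        cohort = _load_inputs(config)
        if config.simulate:
            cohort_dir = os.path.join(config.out_dir, "cohort")
            paths = write_cohort(cohort, cohort_dir)
            manifest["outputs"].update({k: v for k, v in paths.items()})
            manifest["stages"].append("simulate")
        for name in ("counts", "events", "vcf", "metadata"):
            path = getattr(config, name)
            if path and os.path.exists(path):
                manifest["input_digests"][name] = _sha256(path)

        tag_calls = None
        if config.run_detect:
            tag_calls = call_asas(
                cohort.counts,
                cohort.genotypes,
                cohort.metadata,
                min_coverage=config.min_coverage,
                fdr_threshold=config.fdr_threshold,
            )
            tag_calls = filter_hla(tag_calls, set(config.hla_genes) or None)
            path = os.path.join(config.out_dir, "tag_snp_calls.tsv")
            manifest["outputs"]["tag_snp_calls"] = path
            manifest["row_counts"] = {"tag_snp_calls": _write(tag_calls, path)}
            manifest["stages"].append("detect")

        conc = {}
        if config.run_concordance:
            if tag_calls is None:
                manifest["skipped"] = {"concordance": "detect stage disabled"}
            else:
                ccfg = ConcordanceConfig(
                    het_fraction=config.het_fraction,
                    sample_fraction=config.sample_fraction,
                    n_permutations=config.n_permutations,
                    fdr_threshold=config.fdr_threshold,
                    min_stratum_size=config.min_stratum_size,
                    min_tag_coverage=config.min_coverage,
                    seed=config.seed,
                )
                for mode in ("ALL", "AD", "CONTROL"):
                    conc[mode] = run_mode(
                        tag_calls,
                        cohort.counts,
                        cohort.genotypes,
                        cohort.events,
                        cohort.metadata,
                        mode=mode,
                        config=ccfg,
                    )
                    path = os.path.join(config.out_dir, f"functional_snps_{mode.lower()}.tsv")
                    manifest["outputs"][f"functional_snps_{mode.lower()}"] = path
                    manifest.setdefault("row_counts", {})[
                        f"functional_snps_{mode.lower()}"
                    ] = _write(conc[mode], path)
                manifest["stages"].append("concordance")

        if config.run_differential:
            if tag_calls is None:
                manifest.setdefault("skipped", {})["differential"] = "detect stage disabled"
            else:
                diff = differential_scan(
                    tag_calls,
                    cohort.counts,
                    cohort.metadata,
                    min_per_group=config.min_per_group,
                    delta_min=config.delta_min,
                    alpha=config.alpha,
                )
                path = os.path.join(config.out_dir, "differential_imbalance.tsv")
                manifest["outputs"]["differential_imbalance"] = path
                manifest.setdefault("row_counts", {})["differential_imbalance"] = _write(diff, path)
                manifest["stages"].append("differential")
                if config.run_concordance and conc.get("AD") is not None and conc.get("CONTROL") is not None:
                    parts = disease_specific_functional(conc["AD"], conc["CONTROL"])
                    rows = [
                        {"partition": part, "candidate_snp": snp, "event_id": ev}
                        for part in ("both", "AD_only", "control_only")
                        for snp, ev in sorted(parts[part])
                    ]
                    dsf = pd.DataFrame(rows, columns=["partition", "candidate_snp", "event_id"])
                    path = os.path.join(config.out_dir, "disease_specific_functional.tsv")
                    manifest["outputs"]["disease_specific_functional"] = path
                    manifest.setdefault("row_counts", {})["disease_specific_functional"] = _write(dsf, path)
                    manifest["stages"].append("disease_specific")
                else:
                    manifest.setdefault("skipped", {})[
                        "disease_specific"
                    ] = "concordance stage disabled or stratified modes unavailable"
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["error"] = str(exc)
        _dump_manifest(manifest, config.out_dir)
        raise

    manifest["status"] = "complete"
    _dump_manifest(manifest, config.out_dir)
    return manifest


def _dump_manifest(manifest: dict, out_dir: str) -> None:
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
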