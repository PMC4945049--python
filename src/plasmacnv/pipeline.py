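"""End-to-end pipeline wiring: simulate -> normalize -> fetal fraction ->
call -> evaluate, with a manifest of every artifact.

The calling stages never see the truth manifest — it is read only by the
evaluation step — mirroring the blinded design of a screening validation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import concord, coverage, fcaps, fetfrac, simulate
from .genome import GenomeModel, build_genome_model, hg19_genome, toy_genome

log = logging.getLogger("plasmacnv")


@dataclass
class PipelineConfig:
    """Everything one run needs: genome, cohort, caller and output paths."""

    out_dir: str = "plasmacnv_run"
    genome: str = "toy"                    # "toy", "hg19", or a chrom-table path
    bin_size: int = 100_000
    seed: int = 0
    cohort: simulate.CohortConfig = field(default_factory=simulate.CohortConfig)
    caller: dict = field(default_factory=dict)       # CnvCaller params
    fetfrac: dict = field(default_factory=dict)      # FetalFractionRegressor params
    size_cut_mb: float = 10.0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cohort = simulate.CohortConfig(**raw.pop("cohort", {}))
        return cls(cohort=cohort, **raw)


def _build_genome(cfg: PipelineConfig) -> GenomeModel:
    if cfg.genome == "toy":
        return toy_genome(cfg.bin_size, seed=cfg.seed)
    if cfg.genome == "hg19":
        return hg19_genome(cfg.bin_size, seed=cfg.seed)
    from .genome import read_chromosome_table
    return build_genome_model(read_chromosome_table(cfg.genome), cfg.bin_size,
                              seed=cfg.seed)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def analyze_sample(cov: coverage.BinnedCoverage,
                   ref: fetfrac.FetalFractionRegressor | None,
                   caller: fcaps.CnvCaller):
    """Blind per-sample analysis: normalize, estimate f, call CNVs."""
    norm = coverage.normalize(cov)
    est = None
    f = None
    sex = None
    if ref is not None:
        cr, gc = fetfrac.relative_chrY_coverage(cov)
        est = ref.estimate(cr, gc, sample_id=cov.sample_id)
        f, sex = est.epsilon, est.sex_call
    calls = caller.predict(norm, fetal_fraction=f, sex_call=sex)
    return norm, est, calls


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full synthetic experiment; returns the artifact manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model = _build_genome(cfg)
    log.info("genome: %d chromosomes, %d bins", len(model.chromosomes),
             model.n_bins)

    cohort_manifest = simulate.simulate_cohort(model, cfg.cohort, out,
                                               seed=cfg.seed)

    # reference curves from the dedicated panels
    male_covs = [coverage.BinnedCoverage.from_tsv(out / e["path"], model,
                                                  e["sample_id"])
                 for e in cohort_manifest["ref_male"]]
    fem_covs = [coverage.BinnedCoverage.from_tsv(out / e["path"], model,
                                                 e["sample_id"])
                for e in cohort_manifest["ref_female"]]
    ref = fetfrac.fit_reference_curves(
        fetfrac.panel_frame(male_covs, "male_adult"),
        fetfrac.panel_frame(fem_covs, "female_fetus"), **cfg.fetfrac)

    caller = fcaps.CnvCaller(**cfg.caller)
    all_calls = []
    estimates = []
    for entry in cohort_manifest["samples"]:
        sid = entry["sample_id"]
        cov = coverage.BinnedCoverage.from_tsv(out / entry["path"], model, sid)
        norm, est, calls = analyze_sample(cov, ref, caller)
        norm.to_tsv(out / "samples" / f"{sid}.norm.tsv")
        estimates.append({"sample_id": sid,
                          "sex_call": est.sex_call if est else None,
                          "epsilon": est.epsilon if est else None})
        all_calls.extend(calls)
        log.info("%s: %d calls, sex=%s", sid, len(calls),
                 est.sex_call if est else "NA")

    calls_df = fcaps.calls_to_frame(all_calls)
    calls_df.to_csv(out / "calls.tsv", sep="\t", index=False)
    pd.DataFrame(estimates).to_csv(out / "fetal_fractions.tsv", sep="\t",
                                   index=False)

    # evaluation — the only stage that reads the truth manifest
    truths = concord.read_truth_manifest(out / cohort_manifest["truth_manifest"])
    cnv_samples = {t.sample_id for t in truths}
    records = concord.classify(all_calls, truths)
    euploid_calls = {e["sample_id"]: [] for e in cohort_manifest["samples"]
                     if e["sample_id"] not in cnv_samples}
    for c in all_calls:
        if c.sample_id in euploid_calls:
            euploid_calls[c.sample_id].append(c)
    perf = concord.performance(records, euploid_calls, cfg.size_cut_mb)
    perf_payload = {"strata": [p.to_dict() for p in perf],
                    "records": [{
                        "sample_id": r.truth.sample_id,
                        "chrom": r.truth.chrom,
                        "truth_kb": [r.truth.start_kb, r.truth.end_kb],
                        "class": r.klass, "overlap_kb": r.overlap_kb}
                        for r in records]}
    with open(out / "perf.json", "w") as fh:
        json.dump(perf_payload, fh, indent=2)

    artifacts = sorted(str(p.relative_to(out)) for p in out.rglob("*")
                     if p.is_file())
    manifest = {"seed": cfg.seed, "n_samples": cfg.cohort.n_samples,
                "files": {p: _sha256(out / p) for p in artifacts
                          if not p.endswith("manifest.json")}}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


# -- reporting -----------------------------------------------------------

def _fmt_rate(x) -> str:
    return "NA" if x is None or (isinstance(x, float) and np.isnan(x)) \
        else f"{100 * x:.2f}%"


def _fmt_ci(ci) -> str:
    lo, hi = ci
    if any(isinstance(v, float) and np.isnan(v) for v in ci):
        return "NA"
    return f"{100 * lo:.2f}%-{100 * hi:.2f}%"


def report(perf_json_path, out_md_path) -> str:
    """Render the performance JSON as a markdown table; returns the text."""
    with open(perf_json_path) as fh:
        payload = json.load(fh)
    if "strata" not in payload:
        raise ValueError("performance JSON lacks a 'strata' section")
    lines = ["# CNV screening performance", "",
             "| Stratum | Consistent | Partly consistent | Inconsistent | "
             "Sensitivity | 95% CI | Specificity | 95% CI | PPV |",
             "|---|---|---|---|---|---|---|---|---|"]
    for s in payload["strata"]:
        lines.append(
            f"| {s['stratum']} | {s['consistent']} | {s['partly_consistent']} "
            f"| {s['inconsistent']} | {_fmt_rate(s['sensitivity'])} "
            f"| {_fmt_ci(s['sensitivity_ci'])} | {_fmt_rate(s['specificity'])} "
            f"| {_fmt_ci(s['specificity_ci'])} | {_fmt_rate(s['ppv'])} |")
    text = "\n".join(lines) + "\n"
    with open(out_md_path, "w") as fh:
        fh.write(text)
    return text
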