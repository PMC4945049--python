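"""Synthetic maternal-plasma sequencing: binned read counts with the
statistical structure the caller assumes.

Plasma cfDNA is modelled as a two-genome mixture: a maternal genome at
weight (1 - f) and a fetal genome at weight f, each contributing reads in
proportion to local copy number. Per-bin expected weights combine that copy
ratio with a smooth multiplicative GC bias and a mappability weight, and a
single multinomial draw of ``total_reads`` produces the counts — so read
totals are exact by construction. Defaults emulate the study conditions:
about 7 million uniquely aligned reads per sample, mean fetal fraction near
10%, and fetal or maternal CNVs between 1 and 129 Mb.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .coverage import BinnedCoverage
from .genome import AUTOSOMES, GenomeModel, normalize_chrom

# Smooth quadratic GC bias g(gc) = peak - curvature * (gc - mode)^2 :
# an Illumina-era unimodal bias peaking near gc = 0.42, spanning roughly
# 0.7-1.2 over [0, 1].
DEFAULT_GC_BIAS = (1.2, 0.42, 1.5)


@dataclass(frozen=True)
class CnvSpec:
    """One simulated copy-number event.

    ``copy_delta`` is the signed change in copies carried by the affected
    genome(s): -1 is a heterozygous loss, +1 a heterozygous gain, -2 a
    homozygous loss. ``origin`` selects which genome carries it — a
    maternal event shifts read depth at full dose regardless of fetal
    fraction (the mechanism behind maternal-background false positives).
    """

    chrom: str
    start: int
    end: int
    direction: str = "loss"
    origin: str = "fetal"
    copy_delta: int | None = None

    def __post_init__(self):
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.copy_delta is None:
            object.__setattr__(self, "copy_delta",
                               1 if self.direction == "gain" else -1)
        if self.copy_delta == 0:
            raise ValueError("copy_delta must be non-zero")
        expected = "gain" if self.copy_delta > 0 else "loss"
        if self.direction != expected:
            raise ValueError(f"direction {self.direction!r} inconsistent with "
                             f"copy_delta {self.copy_delta}")
        if not self.start < self.end:
            raise ValueError("CnvSpec start must be < end")
        if self.origin not in ("fetal", "maternal", "both"):
            raise ValueError(f"unknown origin {self.origin!r}")

    @property
    def size_mb(self) -> float:
        return (self.end - self.start) / 1e6


@dataclass
class SimulationConfig:
    """Per-sample generative parameters (defaults are the study conditions)."""

    total_reads: int = 7_000_000
    fetal_fraction: float = 0.10
    fetus_sex: str = "male"
    cnv_specs: tuple = ()
    gc_bias: tuple = DEFAULT_GC_BIAS
    dispersion: float = 0.0            # gamma-multiplier variance; 0 = pure multinomial
    chry_female_background: float = 0.002   # relative chrY mis-mapping coverage
    seed: int | None = None

    def __post_init__(self):
        if self.total_reads <= 0:
            raise ValueError("total_reads must be positive")
        if not 0 <= self.fetal_fraction <= 1:
            raise ValueError("fetal_fraction outside [0, 1]")
        if self.fetus_sex not in ("male", "female"):
            raise ValueError(f"unknown fetus_sex {self.fetus_sex!r}")
        if self.chry_female_background < 0:
            raise ValueError("chrY background must be >= 0")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        peak, mode, curv = self.gc_bias
        gc = np.linspace(0, 1, 101)
        if np.any(peak - curv * (gc - mode) ** 2 <= 0):
            raise ValueError("gc_bias curve must be positive on [0, 1]")
        self.cnv_specs = tuple(self.cnv_specs)

    def gc_bias_at(self, gc) -> np.ndarray:
        peak, mode, curv = self.gc_bias
        return peak - curv * (np.asarray(gc, float) - mode) ** 2


def _copy_numbers(model: GenomeModel, config: SimulationConfig):
    """Per-bin maternal and fetal copy numbers implied by sex + CNV specs."""
    n = model.n_bins
    chroms = model.bins["chrom"].to_numpy()
    c_m = np.full(n, 2.0)
    c_f = np.full(n, 2.0)
    c_m[chroms == "chrY"] = 0.0
    if config.fetus_sex == "male":
        c_f[chroms == "chrX"] = 1.0
        c_f[chroms == "chrY"] = 1.0
    else:
        c_f[chroms == "chrY"] = 0.0

    starts = model.bins["start"].to_numpy()
    ends = model.bins["end"].to_numpy()
    for spec in config.cnv_specs:
        if spec.chrom not in model.chrom_names:
            raise ValueError(f"CNV on unknown chromosome {spec.chrom}")
        if spec.end > model.length_of(spec.chrom):
            raise ValueError(f"CNV extends past the end of {spec.chrom}")
        # a bin belongs to the event if its midpoint falls inside
        mid = (starts + ends) / 2
        hit = (chroms == spec.chrom) & (mid >= spec.start) & (mid < spec.end)
        if spec.origin in ("maternal", "both"):
            c_m[hit] += spec.copy_delta
        if spec.origin in ("fetal", "both"):
            c_f[hit] += spec.copy_delta
    if np.any(c_m < 0) or np.any(c_f < 0):
        raise ValueError("CNV specs drive a copy number below zero")
    return c_m, c_f


def expected_copy_ratio(model: GenomeModel, config: SimulationConfig) -> np.ndarray:
    """Mixture copy ratio r_i = (1-f) c_m/2 + f c_f/2 (chrY: background + f c_fY/2)."""
    f = config.fetal_fraction
    c_m, c_f = _copy_numbers(model, config)
    r = (1 - f) * c_m / 2 + f * c_f / 2
    y = model.chrom_index("chrY")
    r[y] = config.chry_female_background + f * c_f[y] / 2
    return r


def expected_bin_weights(model: GenomeModel, config: SimulationConfig) -> np.ndarray:
    """Per-bin multinomial probabilities: w_i ∝ m_i g(gc_i) r_i, normalized."""
    r = expected_copy_ratio(model, config)
    g = config.gc_bias_at(model.bins["gc"].to_numpy())
    m = model.bins["mappability"].to_numpy()
    lengths = model.bin_lengths() / model.bin_size   # short terminal bins
    w = m * g * r * lengths
    total = w.sum()
    if total <= 0:
        raise ValueError("all-zero expected bin weights")
    return w / total


def simulate_sample(model: GenomeModel, config: SimulationConfig,
                    rng: np.random.Generator | None = None,
                    sample_id: str = "sim"):
    """Draw one sample's counts; returns (BinnedCoverage, truth, true_f).

    One multinomial of size ``total_reads`` over the expected weights keeps
    the read total exact. Optional extra-Poisson noise multiplies the
    weights by unit-mean gamma variates (variance = ``dispersion``) before
    the draw.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    w = expected_bin_weights(model, config)
    if config.dispersion > 0:
        shape = 1.0 / config.dispersion
        w = w * rng.gamma(shape, 1.0 / shape, size=len(w))
        w = w / w.sum()
    counts = rng.multinomial(config.total_reads, w)
    cov = BinnedCoverage(sample_id=sample_id, model=model, counts=counts)
    return cov, list(config.cnv_specs), config.fetal_fraction


def positions_from_counts(cov: BinnedCoverage,
                          rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Scatter each bin's reads to uniform start positions inside the bin.

    BED-like output (chrom, start) for exercising the read-position entry
    point; re-counting recovers the original BinnedCoverage exactly.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    bins = cov.model.bins
    reps = np.asarray(cov.counts, np.int64)
    chrom = np.repeat(bins["chrom"].to_numpy(), reps)
    lo = np.repeat(bins["start"].to_numpy(), reps)
    hi = np.repeat(bins["end"].to_numpy(), reps)
    pos = rng.integers(lo, hi)
    return pd.DataFrame({"chrom": chrom, "start": pos})


# -- cohorts -------------------------------------------------------------

@dataclass
class CohortConfig:
    """Study-design-level parameters for a synthetic cohort.

    Fetal fractions are drawn from a truncated normal centred near the
    cohort mean reported for male pregnancies (9.7%); CNV sizes are uniform
    over the clinical range 1-129 Mb and placed uniformly on a random
    autosome; fetal sex is a fair coin. Separate adult-male and
    female-fetus panels are emitted for training the chrY fetal-fraction
    reference curves.
    """

    n_samples: int = 10
    n_cnv_samples: int = 3
    total_reads: int = 7_000_000
    mean_fetal_fraction: float = 0.10
    sd_fetal_fraction: float = 0.035
    min_fetal_fraction: float = 0.03
    max_fetal_fraction: float = 0.25
    cnv_size_range_mb: tuple = (1.0, 129.0)
    maternal_cnv_rate: float = 0.0
    n_male_reference: int = 20
    n_female_fetus_reference: int = 20
    gc_bias: tuple = DEFAULT_GC_BIAS
    dispersion: float = 0.0
    chry_female_background: float = 0.002

    def __post_init__(self):
        if not 0 <= self.n_cnv_samples <= self.n_samples:
            raise ValueError("n_cnv_samples outside [0, n_samples]")
        lo, hi = self.cnv_size_range_mb
        if not 0 < lo <= hi:
            raise ValueError("bad CNV size range")


def _draw_fetal_fraction(rng, cc: CohortConfig) -> float:
    while True:
        f = rng.normal(cc.mean_fetal_fraction, cc.sd_fetal_fraction)
        if cc.min_fetal_fraction <= f <= cc.max_fetal_fraction:
            return float(f)


def random_cnv_spec(model: GenomeModel, rng: np.random.Generator,
                    size_range_mb=(1.0, 129.0), origin: str = "fetal",
                    chroms=None) -> CnvSpec:
    """Uniform-size CNV placed uniformly on an autosome large enough to hold it."""
    lo, hi = size_range_mb
    candidates = [c for c in (chroms or model.chrom_names)
                  if c in AUTOSOMES and model.length_of(c) > lo * 1e6]
    if not candidates:
        raise ValueError("no autosome can hold a CNV of the requested size")
    for _ in range(1000):
        chrom = candidates[rng.integers(len(candidates))]
        size = rng.uniform(lo, hi) * 1e6
        if size >= model.length_of(chrom):
            continue
        start = int(rng.uniform(0, model.length_of(chrom) - size))
        direction = "gain" if rng.random() < 0.5 else "loss"
        return CnvSpec(chrom=chrom, start=start, end=int(start + size),
                       direction=direction, origin=origin)
    raise RuntimeError("failed to place CNV")


def draw_cohort_configs(model: GenomeModel, cc: CohortConfig, seed: int = 0):
    """Per-sample (sample_id, SimulationConfig) pairs plus reference panels.

    Returns (samples, male_refs, female_refs); the first ``n_cnv_samples``
    study samples carry one CNV each. Adult-male reference individuals are
    represented as the f = 1, male limit of the mixture (one chrX, one chrY,
    diploid autosomes).
    """
    rng = np.random.default_rng(seed)
    common = dict(total_reads=cc.total_reads, gc_bias=cc.gc_bias,
                  dispersion=cc.dispersion,
                  chry_female_background=cc.chry_female_background)
    samples = []
    for i in range(cc.n_samples):
        sid = f"S{i:04d}"
        sex = "male" if rng.random() < 0.5 else "female"
        f = _draw_fetal_fraction(rng, cc)
        specs = []
        if i < cc.n_cnv_samples:
            origin = ("maternal" if rng.random() < cc.maternal_cnv_rate
                      else "fetal")
            specs.append(random_cnv_spec(model, rng, cc.cnv_size_range_mb,
                                         origin=origin))
        samples.append((sid, SimulationConfig(
            fetal_fraction=f, fetus_sex=sex, cnv_specs=tuple(specs), **common)))
    male_refs = [(f"REFM{i:03d}", SimulationConfig(
        fetal_fraction=1.0, fetus_sex="male", **common))
        for i in range(cc.n_male_reference)]
    female_refs = [(f"REFF{i:03d}", SimulationConfig(
        fetal_fraction=_draw_fetal_fraction(rng, cc), fetus_sex="female",
        **common)) for i in range(cc.n_female_fetus_reference)]
    return samples, male_refs, female_refs


def truth_manifest(samples_with_truth) -> pd.DataFrame:
    """Tabulate CNV truth as the kb-coordinate manifest the evaluator reads."""
    rows = []
    for sid, specs in samples_with_truth:
        for s in specs:
            rows.append({"sample_id": sid, "chrom": s.chrom,
                         "start_kb": int(round(s.start / 1000)),
                         "end_kb": int(round(s.end / 1000)),
                         "direction": s.direction, "origin": s.origin,
                         "source_string": ""})
    return pd.DataFrame(rows, columns=["sample_id", "chrom", "start_kb",
                                       "end_kb", "direction", "origin",
                                       "source_string"])


def simulate_cohort(model: GenomeModel, cc: CohortConfig, out_dir,
                    seed: int = 0) -> dict:
    """Simulate and write a cohort: one bin-count TSV per sample, a truth
    manifest, and adult-male / female-fetus reference panels.

    Per-sample seeds are spawned from the cohort seed, so reruns are
    byte-identical.
    """
    out = Path(out_dir)
    (out / "samples").mkdir(parents=True, exist_ok=True)
    (out / "ref_male").mkdir(exist_ok=True)
    (out / "ref_female").mkdir(exist_ok=True)
    samples, male_refs, female_refs = draw_cohort_configs(model, cc, seed)
    ids = [sid for sid, _ in samples + male_refs + female_refs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample IDs in cohort")

    seeds = np.random.SeedSequence(seed).spawn(len(ids))
    manifest = {"seed": seed, "samples": [], "ref_male": [], "ref_female": []}
    truths = []
    k = 0
    for group, key in ((samples, "samples"), (male_refs, "ref_male"),
                       (female_refs, "ref_female")):
        for sid, config in group:
            rng = np.random.default_rng(seeds[k]); k += 1
            cov, truth, f = simulate_sample(model, config, rng, sample_id=sid)
            rel = f"{key}/{sid}.tsv"
            cov.to_tsv(out / rel)
            # paths relative to the cohort dir keep reruns byte-identical
            manifest[key].append(
                {"sample_id": sid, "path": rel, "fetal_fraction": f,
                 "fetus_sex": config.fetus_sex})
            if key == "samples":
                truths.append((sid, truth))
    tm = truth_manifest(truths)
    tm.to_csv(out / "truth_manifest.tsv", sep="\t", index=False)
    manifest["truth_manifest"] = "truth_manifest.tsv"
    with open(out / "cohort.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
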