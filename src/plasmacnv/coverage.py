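"""Raw binned read counts and GC-bias-corrected copy-ratio estimates.

Low-coverage plasma sequencing shows a smooth dependence of per-bin read
count on bin GC content. :class:`GcNormalizer` removes it with a locally
weighted (tricube/LOWESS) regression of count on GC fitted over autosomal
bins, then rescales so that the autosomal median copy ratio is exactly 1.
The per-bin standard error uses a Poisson approximation and feeds the
caller's dynamic threshold downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.nonparametric.smoothers_lowess import lowess

from .genome import AUTOSOMES, GenomeModel, normalize_chrom

COVERAGE_COLUMNS = ["chrom", "start", "end", "gc", "count"]


@dataclass
class BinnedCoverage:
    """Per-bin raw read counts for one sample, aligned to a GenomeModel."""

    sample_id: str
    model: GenomeModel
    counts: np.ndarray = field(repr=False)
    dropped_reads: int = 0

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if len(self.counts) != self.model.n_bins:
            raise ValueError("counts not aligned to genome model bins")
        if np.any(self.counts < 0):
            raise ValueError("negative bin count")

    @property
    def total_reads(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        df = self.model.bins[["chrom", "start", "end", "gc"]].copy()
        df["count"] = self.counts
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, model: GenomeModel, sample_id: str | None = None):
        df = pd.read_csv(path, sep="\t")
        missing = set(COVERAGE_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"bin-count table missing columns: {sorted(missing)}")
        if len(df) != model.n_bins or not (
            (df["chrom"].to_numpy() == model.bins["chrom"].to_numpy()).all()
            and (df["start"].to_numpy() == model.bins["start"].to_numpy()).all()
        ):
            raise ValueError("bin-count table does not match the genome model tiling")
        sid = sample_id if sample_id is not None else str(path)
        return cls(sample_id=sid, model=model,
                   counts=df["count"].to_numpy(np.int64))


@dataclass
class NormalizedCoverage:
    """GC-corrected per-bin copy ratios (euploid expectation 1) + Poisson SEs."""

    sample_id: str
    model: GenomeModel
    counts: np.ndarray = field(repr=False)
    ratio: np.ndarray = field(repr=False)
    sigma: np.ndarray = field(repr=False)
    scale: float = 1.0

    def to_frame(self) -> pd.DataFrame:
        df = self.model.bins[["chrom", "start", "end", "gc"]].copy()
        df["count"] = self.counts
        df["ratio"] = self.ratio
        df["sigma"] = self.sigma
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def count_reads(read_positions: pd.DataFrame, model: GenomeModel,
                sample_id: str = "sample") -> BinnedCoverage:
    """Assign BED-like read start positions to bins (half-open convention).

    A read whose start equals a bin's end coordinate belongs to the next
    bin. Reads on chromosomes absent from the model are dropped and counted;
    more than 10% unresolvable reads is treated as a naming mismatch and
    rejected.
    """
    if len(read_positions) == 0:
        raise ValueError("no reads supplied")
    chroms = read_positions["chrom"].map(normalize_chrom)
    pos = read_positions["start"].to_numpy(np.int64)
    known = set(model.chrom_names)
    resolvable = chroms.isin(known).to_numpy()
    n_dropped = int((~resolvable).sum())
    if n_dropped > 0.10 * len(read_positions):
        raise ValueError(
            f"{n_dropped}/{len(read_positions)} reads on chromosomes absent "
            "from the genome model — chromosome naming mismatch?")

    counts = np.zeros(model.n_bins, dtype=np.int64)
    offset = 0
    for chrom, length in model.chromosomes:
        mask = model.chrom_index(chrom)
        n_bins_c = int(mask.sum())
        sel = (chroms == chrom).to_numpy() & resolvable
        p = pos[sel]
        if np.any((p < 0) | (p >= length)):
            raise ValueError(f"read position outside {chrom}")
        idx = p // model.bin_size
        counts[offset:offset + n_bins_c] += np.bincount(idx, minlength=n_bins_c)
        offset += n_bins_c
    return BinnedCoverage(sample_id=sample_id, model=model, counts=counts,
                          dropped_reads=n_dropped)


class GcNormalizer(BaseEstimator, TransformerMixin):
    """GC-bias correction by locally weighted regression of count on GC.

    fit() learns the expected-count curve c-hat(gc) on autosomal bins with GC
    inside [gc_min, gc_max] and positive mappability; transform() divides
    counts by the curve and rescales so the autosomal median ratio is 1.
    Sex chromosomes never enter the fit or the median but are corrected with
    the autosomal curve, since their dosage depends on fetal sex.

    Parameters
    ----------
    span : LOWESS span as a fraction of fitted points (tricube weights).
    gc_min, gc_max : GC window outside which bins are excluded from fitting
        (extreme-GC bins are noise-dominated); they are still corrected.
    min_bins : minimum masked-in bins required for a local fit.
    min_gc_span : minimum GC range the masked-in bins must cover.
    robust_iters : LOWESS robustifying iterations.
    """

    def __init__(self, span: float = 0.3, gc_min: float = 0.25,
                 gc_max: float = 0.75, min_bins: int = 200,
                 min_gc_span: float = 0.10, robust_iters: int = 2):
        self.span = span
        self.gc_min = gc_min
        self.gc_max = gc_max
        self.min_bins = min_bins
        self.min_gc_span = min_gc_span
        self.robust_iters = robust_iters

    # -- fitting ---------------------------------------------------------
    def _fit_mask(self, cov: BinnedCoverage, mask) -> np.ndarray:
        bins = cov.model.bins
        gc = bins["gc"].to_numpy()
        full = (bins["end"] - bins["start"]).to_numpy() == cov.model.bin_size
        m = (cov.model.autosome_mask & full
             & (gc >= self.gc_min) & (gc <= self.gc_max)
             & (bins["mappability"].to_numpy() > 0))
        if mask is not None:
            m &= np.asarray(mask, bool)
        return m

    def fit(self, X: BinnedCoverage, y=None, mask=None):
        """Fit the expected-count curve; ``mask`` marks bins presumed diploid."""
        m = self._fit_mask(X, mask)
        if m.sum() < self.min_bins:
            raise ValueError(f"only {int(m.sum())} usable bins "
                             f"(< {self.min_bins}) for the GC fit")
        gc = X.model.bins["gc"].to_numpy()[m]
        counts = X.counts[m].astype(float)
        gc_span = gc.max() - gc.min()
        self.n_bins_used_ = int(m.sum())
        self.gc_range_ = (float(gc.min()), float(gc.max()))
        if gc_span < max(self.min_gc_span * 0.01, 1e-9):
            warnings.warn("degenerate GC variance — falling back to a "
                          "global-median expected count", stacklevel=2)
            med = float(np.median(counts))
            self.curve_gc_ = np.array([gc.min(), gc.max() + 1e-9])
            self.curve_val_ = np.array([med, med])
            self.fallback_ = True
        else:
            if gc_span < self.min_gc_span:
                raise ValueError(
                    f"masked-in bins span only {gc_span:.3f} of GC "
                    f"(< {self.min_gc_span})")
            delta = 0.005 * gc_span
            fitted = lowess(counts, gc, frac=self.span, it=self.robust_iters,
                            delta=delta, return_sorted=True)
            self.curve_gc_ = fitted[:, 0]
            self.curve_val_ = fitted[:, 1]
            self.fallback_ = False
        if np.any(self.curve_val_ <= 0):
            raise ValueError("fitted expected count is non-positive over part "
                             "of the GC range")
        resid = counts - self.predict_expected(gc)
        self.residual_sd_ = float(resid.std())
        return self

    def predict_expected(self, gc) -> np.ndarray:
        """Evaluate c-hat(gc), clamped to the fitted GC range."""
        gc = np.clip(np.asarray(gc, float), self.curve_gc_[0], self.curve_gc_[-1])
        return np.interp(gc, self.curve_gc_, self.curve_val_)

    # -- correction ------------------------------------------------------
    def transform(self, X: BinnedCoverage) -> NormalizedCoverage:
        expected = self.predict_expected(X.model.bins["gc"].to_numpy())
        # short terminal bins expect proportionally fewer reads
        expected = expected * (X.model.bin_lengths() / X.model.bin_size)
        if np.any(expected <= 0):
            raise ValueError("expected count non-positive — cannot correct")
        ratio = X.counts / expected
        auto = X.model.autosome_mask
        scale = float(np.median(ratio[auto]))
        if scale <= 0:
            raise ValueError("autosomal median ratio non-positive")
        ratio = ratio / scale
        sigma = np.sqrt(np.maximum(X.counts, 1)) / expected / scale
        return NormalizedCoverage(sample_id=X.sample_id, model=X.model,
                                  counts=np.asarray(X.counts),
                                  ratio=ratio, sigma=sigma, scale=scale)


# -- spec-level functional surface --------------------------------------

def fit_gc_curve(cov: BinnedCoverage, mask=None, span: float = 0.3,
                 **params) -> GcNormalizer:
    """Fit the GC expected-count curve on bins presumed diploid."""
    return GcNormalizer(span=span, **params).fit(cov, mask=mask)


def gc_correct(cov: BinnedCoverage, curve: GcNormalizer) -> NormalizedCoverage:
    """Divide counts by the fitted curve and rescale to autosomal median 1."""
    return curve.transform(cov)


def normalize(cov: BinnedCoverage, mask=None, **params) -> NormalizedCoverage:
    """fit_gc_curve + gc_correct in one step (per-sample correction)."""
    return gc_correct(cov, fit_gc_curve(cov, mask=mask, **params))
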