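"""Fetal-fraction estimation from relative chromosome-Y coverage.

In a male pregnancy the only chrY reads beyond a small mis-mapping
background come from the fetus, so chrY relative coverage interpolates
linearly between a female-fetus reference (fetal fraction 0) and an adult
male (fraction 1). The estimator fits one GC regression per reference
panel and reads the fetal fraction off as

    epsilon = (cr_Y - f_female(GC_Y)) / (f_male(GC_Y) - f_female(GC_Y))

where cr_Y is the sample's observed relative chrY coverage and the f(.) are
the fitted panel curves evaluated at the sample's chrY GC. Samples whose
cr_Y sits within k standard deviations of the female reference are called
female and get no estimate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .coverage import BinnedCoverage, NormalizedCoverage


@dataclass
class FetalFractionEstimate:
    """Result of the chrY estimator for one sample."""

    sample_id: str
    cr_y: float
    gc_y: float
    sex_call: str                 # male | female | indeterminate
    epsilon: float | None = None  # in [0, 1]; None unless sex_call == male
    qc: dict | None = None

    def to_json(self) -> str:
        return json.dumps({
            "sample_id": self.sample_id, "cr_y": self.cr_y, "gc_y": self.gc_y,
            "sex_call": self.sex_call, "epsilon": self.epsilon,
            "qc": self.qc or {}})


def relative_chrY_coverage(cov) -> tuple[float, float]:
    """(cr_Y, GC_Y) for one sample.

    cr_Y is chrY read density relative to autosomal read density (reads per
    binned bp over reads per binned bp), i.e. 1.0 would mean diploid
    autosome-equivalent coverage and an adult male sits near 0.5. Relative
    to the autosomes — not to the whole genome — the expected value is
    linear in fetal fraction, background + f/2 for a male fetus. GC_Y is
    the coverage-weighted mean GC of chrY bins (length-weighted when chrY
    has no reads).
    """
    if not isinstance(cov, (BinnedCoverage, NormalizedCoverage)):
        raise TypeError("expected BinnedCoverage or NormalizedCoverage")
    model = cov.model
    if "chrY" not in model.chrom_names:
        raise ValueError("genome model has no chrY")
    y = model.chrom_index("chrY")
    auto = model.autosome_mask
    counts = np.asarray(cov.counts, float)
    if counts.sum() == 0:
        raise ValueError("sample has no reads")
    lengths = model.bin_lengths().astype(float)
    auto_density = counts[auto].sum() / lengths[auto].sum()
    cr_y = (counts[y].sum() / lengths[y].sum()) / auto_density
    gc = model.bins["gc"].to_numpy()[y]
    w = counts[y]
    if w.sum() == 0:
        w = lengths[y]
    gc_y = float(np.average(gc, weights=w))
    return float(cr_y), gc_y


class FetalFractionRegressor(BaseEstimator, RegressorMixin):
    """Reference-panel regressions of chrY relative coverage on chrY GC.

    fit() takes per-sample (cr_Y, GC_Y) rows labelled ``male_adult`` or
    ``female_fetus`` and fits one polynomial (default linear) per panel;
    predict() maps new (cr_Y, GC_Y) rows to the fetal-fraction estimate,
    clamped to [0, 1]. The male curve must lie strictly above the female
    curve over the observed GC range — otherwise the panels cannot separate
    fetal signal from background and fitting fails.

    Parameters
    ----------
    degree : polynomial degree of each GC regression (1 = linear).
    sex_call_k : a sample is called male only when its cr_Y exceeds the
        female curve by more than ``sex_call_k`` female-panel residual SDs.
    min_panel : minimum samples required per reference panel.
    min_gc_span : GC range a panel must cover before a slope is estimated;
        below it the GC values are dominated by counting noise and the fit
        collapses to the panel mean (a spurious slope would extrapolate
        badly at query GC values near the panel edge).
    """

    def __init__(self, degree: int = 1, sex_call_k: float = 3.0,
                 min_panel: int = 20, min_gc_span: float = 0.02):
        self.degree = degree
        self.sex_call_k = sex_call_k
        self.min_panel = min_panel
        self.min_gc_span = min_gc_span

    def fit(self, X, y):
        """X: array-like (n, 2) of [cr_Y, GC_Y]; y: panel labels."""
        X = np.asarray(X, float)
        y = np.asarray(y)
        coefs = {}
        for label in ("male_adult", "female_fetus"):
            sel = y == label
            if sel.sum() < self.min_panel:
                raise ValueError(f"panel {label!r} has {int(sel.sum())} "
                                 f"samples (< {self.min_panel})")
            cr, gc = X[sel, 0], X[sel, 1]
            if np.ptp(gc) < self.min_gc_span:   # GC carries no information
                coefs[label] = np.array([np.mean(cr)])
            else:
                coefs[label] = np.polyfit(gc, cr, self.degree)
        self.male_coef_ = coefs["male_adult"]
        self.female_coef_ = coefs["female_fetus"]
        fem = y == "female_fetus"
        resid = X[fem, 0] - np.polyval(self.female_coef_, X[fem, 1])
        self.female_resid_sd_ = float(resid.std())
        self.gc_range_ = (float(X[:, 1].min()), float(X[:, 1].max()))
        self.panel_sizes_ = {"male_adult": int((y == "male_adult").sum()),
                             "female_fetus": int(fem.sum())}

        grid = np.linspace(*self.gc_range_, 50)
        gap = np.polyval(self.male_coef_, grid) - np.polyval(self.female_coef_, grid)
        if np.any(gap <= 0):
            bad = grid[gap <= 0]
            raise ValueError(
                "male and female reference curves cross on GC in "
                f"[{bad.min():.3f}, {bad.max():.3f}]")
        return self

    # -- evaluation ------------------------------------------------------
    def male_curve(self, gc):
        return np.polyval(self.male_coef_, np.asarray(gc, float))

    def female_curve(self, gc):
        return np.polyval(self.female_coef_, np.asarray(gc, float))

    def predict(self, X) -> np.ndarray:
        """Fetal fraction for rows of [cr_Y, GC_Y], clamped to [0, 1]."""
        X = np.asarray(X, float).reshape(-1, 2)
        lo = self.female_curve(X[:, 1])
        hi = self.male_curve(X[:, 1])
        denom = hi - lo
        if np.any(denom <= 0):
            raise ValueError("reference curves cross at a queried GC")
        return np.clip((X[:, 0] - lo) / denom, 0.0, 1.0)

    def estimate(self, cr_y: float, gc_y: float,
                 sample_id: str = "sample") -> FetalFractionEstimate:
        """Full per-sample result: sex call plus epsilon when male."""
        bound = float(self.female_curve(gc_y)) + self.sex_call_k * self.female_resid_sd_
        if cr_y > bound:
            sex = "male"
            eps = float(self.predict([[cr_y, gc_y]])[0])
        elif cr_y < bound:
            sex, eps = "female", None
        else:
            sex, eps = "indeterminate", None
        qc = {"female_bound": bound, "sex_call_k": self.sex_call_k,
              "gc_in_training_range":
                  bool(self.gc_range_[0] <= gc_y <= self.gc_range_[1])}
        return FetalFractionEstimate(sample_id=sample_id, cr_y=float(cr_y),
                                     gc_y=float(gc_y), sex_call=sex,
                                     epsilon=eps, qc=qc)


# -- spec-level functional surface --------------------------------------

def panel_frame(covs, label: str) -> pd.DataFrame:
    """Summarize reference samples into the (sample_id, cr_Y, GC_Y, class) table."""
    rows = []
    for cov in covs:
        cr, gc = relative_chrY_coverage(cov)
        rows.append({"sample_id": cov.sample_id, "cr_y": cr, "gc_y": gc,
                     "class": label})
    return pd.DataFrame(rows)


def fit_reference_curves(male_panel: pd.DataFrame,
                         female_fetus_panel: pd.DataFrame,
                         **params) -> FetalFractionRegressor:
    """Fit the two reference regressions from panel tables (cr_y, gc_y)."""
    df = pd.concat([male_panel.assign(**{"class": "male_adult"}),
                    female_fetus_panel.assign(**{"class": "female_fetus"})])
    X = df[["cr_y", "gc_y"]].to_numpy()
    return FetalFractionRegressor(**params).fit(X, df["class"].to_numpy())


def estimate_fetal_fraction(cr_y: float, gc_y: float,
                            ref: FetalFractionRegressor,
                            sample_id: str = "sample") -> FetalFractionEstimate:
    return ref.estimate(cr_y, gc_y, sample_id=sample_id)
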