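"""Concordance evaluation against karyotype/microarray truth.

Clinical truth arrives as ISCN-like karyotype strings ("46,XX,del(5)
(p15.33p15.2)") or array findings ("arr 13q21.2(60,399-61,730)x3"). Bands
are resolved against a UCSC-format cytoband table, array coordinates are
taken verbatim in kb, and every truth event is classified against the
sample's calls:

* consistent — the call is contained in the truth interval, or the overlap
  reaches 50% of either interval's length;
* partly consistent — a same-chromosome, same-direction call exists but
  overlaps less than 50% of both (possibly not at all);
* inconsistent — no matching call (a false negative).

Sensitivity is per truth event, specificity per euploid sample, each with
an exact (Clopper-Pearson) binomial 95% CI; events and false-positive
calls are stratified by size around a 10 Mb cut.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import beta

from .genome import normalize_chrom

CONSISTENT = "consistent"
PARTLY = "partly_consistent"
INCONSISTENT = "inconsistent"


# -- cytobands -----------------------------------------------------------

class CytobandTable:
    """Banded chromosome coordinates with prefix lookup.

    ``band_interval("chr5", "p14")`` returns the union of p14.1-p14.3; an
    exact band name returns that band. Input is the UCSC cytoBand format
    (chrom, start, end, band, stain; 0-based half-open bp; no header).
    """

    def __init__(self, frame: pd.DataFrame):
        need = {"chrom", "start", "end", "band"}
        if not need <= set(frame.columns):
            raise ValueError(f"cytoband table needs columns {sorted(need)}")
        frame = frame.sort_values(["chrom", "start"]).reset_index(drop=True)
        for chrom, sub in frame.groupby("chrom"):
            s, e = sub["start"].to_numpy(), sub["end"].to_numpy()
            if np.any(s[1:] != e[:-1]) or s[0] != 0:
                raise ValueError(f"{chrom}: cytobands do not tile the chromosome")
        self.frame = frame

    @classmethod
    def from_ucsc(cls, path) -> "CytobandTable":
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["chrom", "start", "end", "band", "stain"])
        return cls(df)

    @classmethod
    def shipped(cls) -> "CytobandTable":
        """The reconstructed hg19-like cytoband subset shipped with the package.

        Synthetic: band boundaries rebuilt to round, hg19-like values (the
        genuine UCSC table is not redistributed here); chromosomes absent
        from the clinical truth dialects are omitted. Supply your own UCSC
        file via :meth:`from_ucsc` for real-data work.
        """
        from .genome import _data_path
        with _data_path("cytoband_hg19_synthetic.tsv").open() as fh:
            return cls.from_ucsc(fh)

    def band_interval(self, chrom: str, band: str) -> tuple[int, int]:
        """(start, end) bp of a band or of the union of a band prefix."""
        chrom = normalize_chrom(chrom)
        sub = self.frame[self.frame["chrom"] == chrom]
        if sub.empty:
            raise KeyError(f"no cytobands for {chrom}")
        exact = sub[sub["band"] == band]
        if len(exact):
            return int(exact["start"].iloc[0]), int(exact["end"].iloc[0])
        pref = sub[sub["band"].str.startswith(band + ".")
                   | sub["band"].str.startswith(band)]
        pref = pref[pref["band"].str.match(re.escape(band) + r"(\.|$|\d)")]
        if pref.empty:
            raise KeyError(f"band {band!r} not found on {chrom}")
        return int(pref["start"].min()), int(pref["end"].max())


# -- truth events --------------------------------------------------------

@dataclass(frozen=True)
class TruthEvent:
    """One confirmed CNV from karyotyping or microarray, in kb."""

    sample_id: str
    chrom: str
    start_kb: int
    end_kb: int
    direction: str          # gain | loss
    source: str = "karyotype"
    raw: str = ""

    def __post_init__(self):
        if not self.start_kb < self.end_kb:
            raise ValueError(f"empty truth interval in {self.raw!r}")

    @property
    def size_mb(self) -> float:
        return (self.end_kb - self.start_kb) / 1000


_ARR_RE = re.compile(
    r"(\d+|[XY])\s*[pq][\d.]+(?:\.?[pq][\d.]+)?\s*"
    r"\(\s*([\d,]+)\s*[–—-]\s*([\d,]+)\s*\)\s*[x×X](\d+)")
_SEG_RE = re.compile(r"\??(del|dup)\s*\(\s*(\w+)\s*\)\s*\(\s*([^)]+)\s*\)")
_BAND_RE = re.compile(r"[pq]\d+(?:\.\d+)?")
_KARYO_PREFIX_RE = re.compile(r"^\s*\d{2}\s*,\s*X[XY?]\s*,?")
_COMPLEX_RE = re.compile(r"(der|mos|i\s*\(|\+|\[|/)")


def parse_truth(raw: str, bands: CytobandTable | None = None,
                sample_id: str = "sample") -> list[TruthEvent]:
    """Parse one karyotype/array result string into truth events.

    Supported dialects: "46,XX,del(5)(p15.33p15.2)" (one or more del/dup
    segments, bands resolved against ``bands``), "arr 13q21.2(60,399-61,730)x3"
    (coordinates verbatim in kb), and plain "46,XX"/"46,XY" (no events).
    Derivative/mosaic/isochromosome and otherwise unparseable forms raise,
    pointing at the truth manifest's explicit-coordinate override.
    """
    text = raw.strip()
    if not text:
        return []

    if text.lower().startswith("arr"):
        events = []
        for m in _ARR_RE.finditer(text):
            chrom = normalize_chrom(m.group(1))
            start_kb = int(m.group(2).replace(",", ""))
            end_kb = int(m.group(3).replace(",", ""))
            n = int(m.group(4))
            if n == 2:
                continue
            events.append(TruthEvent(sample_id=sample_id, chrom=chrom,
                                     start_kb=start_kb, end_kb=end_kb,
                                     direction="gain" if n > 2 else "loss",
                                     source="array", raw=raw))
        if not events:
            raise ValueError(f"unparseable array result: {raw!r}")
        return events

    body = _KARYO_PREFIX_RE.sub("", text)
    events = []
    consumed = _KARYO_PREFIX_RE.match(text)
    remainder = body
    for m in _SEG_RE.finditer(body):
        kind, chrom, band_text = m.group(1), normalize_chrom(m.group(2)), m.group(3)
        tokens = _BAND_RE.findall(band_text)
        if not tokens or len(tokens) > 2:
            raise ValueError(f"cannot resolve bands in {raw!r}")
        if bands is None:
            raise ValueError("karyotype string requires a cytoband table")
        intervals = [bands.band_interval(chrom, t) for t in tokens]
        start = min(i[0] for i in intervals)
        end = max(i[1] for i in intervals)
        events.append(TruthEvent(
            sample_id=sample_id, chrom=chrom,
            start_kb=int(round(start / 1000)), end_kb=int(round(end / 1000)),
            direction="gain" if kind == "dup" else "loss",
            source="karyotype", raw=raw))
        remainder = remainder.replace(m.group(0), "", 1)
    leftover = remainder.strip(" ,")
    if leftover:
        # del/dup segments parsed cleanly leave nothing behind; derivative,
        # mosaic and other complex forms land here
        raise ValueError(
            f"unsupported karyotype form {raw!r} — supply explicit "
            "coordinates via the truth manifest override")
    if not events and not consumed:
        raise ValueError(f"unparseable karyotype: {raw!r}")
    return events


def read_truth_manifest(path, bands: CytobandTable | None = None) -> list[TruthEvent]:
    """Load a truth manifest TSV; explicit kb coordinates override parsing."""
    df = pd.read_csv(path, sep="\t")
    events = []
    for _, row in df.iterrows():
        if pd.notna(row.get("start_kb")) and pd.notna(row.get("end_kb")):
            events.append(TruthEvent(
                sample_id=row["sample_id"], chrom=normalize_chrom(row["chrom"]),
                start_kb=int(row["start_kb"]), end_kb=int(row["end_kb"]),
                direction=row["direction"],
                source=row.get("source", "manifest"),
                raw=str(row.get("source_string", ""))))
        else:
            events.extend(parse_truth(str(row["source_string"]), bands,
                                      sample_id=row["sample_id"]))
    return events


# -- interval arithmetic and classification ------------------------------

def overlap_kb(a, b) -> int:
    """Overlap length in kb of two same-chromosome (start_kb, end_kb) items.

    Accepts TruthEvent/CnvCall-like objects (with chrom + kb fields) or
    plain (start_kb, end_kb) tuples.
    """
    def unpack(x):
        if hasattr(x, "start_kb"):
            return getattr(x, "chrom", None), x.start_kb, x.end_kb
        if hasattr(x, "start"):       # CnvCall in bp
            return x.chrom, round(x.start / 1000), round(x.end / 1000)
        return None, x[0], x[1]

    ca, sa, ea = unpack(a)
    cb, sb, eb = unpack(b)
    if ca is not None and cb is not None and ca != cb:
        raise ValueError(f"overlap across chromosomes: {ca} vs {cb}")
    return max(0, min(ea, eb) - max(sa, sb))


@dataclass
class ConcordanceRecord:
    """Classification of one truth event against one sample's calls."""

    truth: TruthEvent
    call: object | None
    overlap_kb: int
    frac_truth: float
    frac_call: float
    klass: str


def _call_kb(call) -> tuple[int, int]:
    if hasattr(call, "start_kb"):
        return int(call.start_kb), int(call.end_kb)
    return int(round(call.start / 1000)), int(round(call.end / 1000))


def classify(calls, truths) -> list[ConcordanceRecord]:
    """Classify every truth event as consistent / partly consistent /
    inconsistent against same-sample calls.

    Candidates are same-chromosome, same-direction calls; each call matches
    at most one truth event, assigned greedily by overlap (ties to the
    larger truth). Consistent means the call is contained in the truth or
    the overlap reaches 50% of either interval's length.
    """
    by_sample_calls: dict = {}
    for c in calls:
        by_sample_calls.setdefault(c.sample_id, []).append(c)

    records = []
    for sid in sorted({t.sample_id for t in truths}):
        sample_truths = [t for t in truths if t.sample_id == sid]
        sample_calls = list(by_sample_calls.get(sid, []))
        pairs = []
        for t in sample_truths:
            for c in sample_calls:
                if c.chrom == t.chrom and c.direction == t.direction:
                    pairs.append((overlap_kb(t, c), t.size_mb, t, c))
        pairs.sort(key=lambda p: (-p[0], -p[1]))
        assigned: dict = {}
        used = set()
        for ov, _, t, c in pairs:
            if id(t) in assigned or id(c) in used:
                continue
            assigned[id(t)] = (c, ov)
            used.add(id(c))
        for t in sample_truths:
            if id(t) not in assigned:
                records.append(ConcordanceRecord(
                    truth=t, call=None, overlap_kb=0, frac_truth=0.0,
                    frac_call=0.0, klass=INCONSISTENT))
                continue
            c, ov = assigned[id(t)]
            cs, ce = _call_kb(c)
            lt = t.end_kb - t.start_kb
            lc = ce - cs
            frac_t = ov / lt if lt else 0.0
            frac_c = ov / lc if lc else 0.0
            contained = ov == lc and lc > 0
            klass = (CONSISTENT if contained or max(frac_t, frac_c) >= 0.5
                     else PARTLY)
            records.append(ConcordanceRecord(
                truth=t, call=c, overlap_kb=ov, frac_truth=frac_t,
                frac_call=frac_c, klass=klass))
    return records


# -- performance ---------------------------------------------------------

def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact binomial CI for a proportion k/n."""
    if n == 0:
        return (float("nan"), float("nan"))
    lo = beta.ppf(alpha / 2, k, n - k + 1) if k > 0 else 0.0
    hi = beta.ppf(1 - alpha / 2, k + 1, n - k) if k < n else 1.0
    return float(lo), float(hi)


@dataclass
class PerformanceSummary:
    """One stratum's screening metrics (per-event sensitivity, per-sample
    specificity, call-level PPV)."""

    stratum: str
    consistent: int
    partly: int
    inconsistent: int
    fp_calls: int
    fp_samples: int
    euploid_n: int
    sensitivity: float | None
    sensitivity_ci: tuple
    specificity: float | None
    specificity_ci: tuple
    ppv: float | None

    @property
    def tp(self) -> int:
        return self.consistent + self.partly

    @property
    def n_events(self) -> int:
        return self.tp + self.inconsistent

    def to_dict(self) -> dict:
        return {
            "stratum": self.stratum, "consistent": self.consistent,
            "partly_consistent": self.partly, "inconsistent": self.inconsistent,
            "events": self.n_events, "fp_calls": self.fp_calls,
            "fp_samples": self.fp_samples, "euploid_n": self.euploid_n,
            "sensitivity": self.sensitivity,
            "sensitivity_ci": list(self.sensitivity_ci),
            "specificity": self.specificity,
            "specificity_ci": list(self.specificity_ci),
            "ppv": self.ppv,
        }


def performance_from_counts(strata_counts: dict, euploid_n: int) -> list:
    """Screening metrics from already-tabulated counts.

    ``strata_counts`` maps stratum name -> dict with keys consistent,
    partly, inconsistent, fp_calls and (optionally) fp_samples; a "total"
    stratum is added as the sum when absent. Empty strata report rates as
    None rather than zero.
    """
    counts = {k: dict(v) for k, v in strata_counts.items()}
    if "total" not in counts:
        tot: dict = {}
        for v in counts.values():
            for key, val in v.items():
                tot[key] = tot.get(key, 0) + val
        counts["total"] = tot

    out = []
    for stratum, v in counts.items():
        cons = v.get("consistent", 0)
        part = v.get("partly", 0)
        inc = v.get("inconsistent", 0)
        fp_calls = v.get("fp_calls", 0)
        fp_samples = v.get("fp_samples", fp_calls if euploid_n else 0)
        fp_samples = min(fp_samples, euploid_n)
        tp = cons + part
        n_ev = tp + inc
        sens = tp / n_ev if n_ev else None
        sens_ci = clopper_pearson(tp, n_ev) if n_ev else (float("nan"),) * 2
        spec = (euploid_n - fp_samples) / euploid_n if euploid_n else None
        spec_ci = (clopper_pearson(euploid_n - fp_samples, euploid_n)
                   if euploid_n else (float("nan"),) * 2)
        ppv = tp / (tp + fp_calls) if (tp + fp_calls) else None
        out.append(PerformanceSummary(
            stratum=stratum, consistent=cons, partly=part, inconsistent=inc,
            fp_calls=fp_calls, fp_samples=fp_samples, euploid_n=euploid_n,
            sensitivity=sens, sensitivity_ci=sens_ci, specificity=spec,
            specificity_ci=spec_ci, ppv=ppv))
    return out


def performance(records, euploid_calls: dict, size_cut_mb: float = 10.0) -> list:
    """Stratified screening metrics from classification records.

    ``euploid_calls`` maps every euploid sample id to its (possibly empty)
    call list — euploid samples with zero calls must be present so the
    specificity denominator is the full euploid cohort. Truth events are
    stratified by truth size, false-positive calls by call size.
    """
    euploid_n = len(euploid_calls)
    strata = {">10Mb": {"consistent": 0, "partly": 0, "inconsistent": 0,
                        "fp_calls": 0, "fp_samples": 0},
              "<10Mb": {"consistent": 0, "partly": 0, "inconsistent": 0,
                        "fp_calls": 0, "fp_samples": 0}}

    def stratum_of(size_mb):
        return ">10Mb" if size_mb > size_cut_mb else "<10Mb"

    for r in records:
        key = {CONSISTENT: "consistent", PARTLY: "partly",
               INCONSISTENT: "inconsistent"}[r.klass]
        strata[stratum_of(r.truth.size_mb)][key] += 1

    fp_sample_sets = {">10Mb": set(), "<10Mb": set(), "total": set()}
    for sid, calls in euploid_calls.items():
        for c in calls:
            cs, ce = _call_kb(c)
            s = stratum_of((ce - cs) / 1000)
            strata[s]["fp_calls"] += 1
            fp_sample_sets[s].add(sid)
            fp_sample_sets["total"].add(sid)
    for s in (">10Mb", "<10Mb"):
        strata[s]["fp_samples"] = len(fp_sample_sets[s])
    total_fp_samples = len(fp_sample_sets["total"])

    out = performance_from_counts(strata, euploid_n)
    for summ in out:
        if summ.stratum == "total":
            # samples with FP calls in both strata are one FP sample, not two
            summ.fp_samples = total_fp_samples
            summ.specificity = ((euploid_n - total_fp_samples) / euploid_n
                                if euploid_n else None)
            summ.specificity_ci = (clopper_pearson(
                euploid_n - total_fp_samples, euploid_n)
                if euploid_n else (float("nan"),) * 2)
    return out
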