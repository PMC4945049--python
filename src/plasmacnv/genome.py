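"""Genome coordinate frame: chromosomes tiled into fixed-width bins.

Every downstream stage (simulation, GC correction, segmentation, calling)
works per bin of a :class:`GenomeModel` — an ordered, contiguous tiling of
each chromosome into ``bin_size`` windows, the last of which may be short.
Each bin carries a GC fraction and a mappability weight; coordinates are
0-based half-open base pairs internally and kilobases (closed intervals) at
the IO boundary.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

AUTOSOMES = tuple(f"chr{i}" for i in range(1, 23))
SEX_CHROMS = ("chrX", "chrY")

BIN_COLUMNS = ["chrom", "start", "end", "gc", "mappability"]


def normalize_chrom(name: str) -> str:
    """Map '5', 'X', 'chr5' ... onto the canonical 'chr5' form."""
    s = str(name).strip()
    return s if s.startswith("chr") else f"chr{s}"


@dataclass(frozen=True)
class GenomeModel:
    """Chromosome lengths plus the contiguous bin tiling used everywhere.

    Attributes
    ----------
    chromosomes : tuple of (name, length) pairs, in genome order.
    bins : DataFrame with columns chrom, start, end, gc, mappability,
        sorted by (chromosome order, start), tiling each chromosome.
    bin_size : nominal bin width in bp (last bin of a chromosome may be short).
    """

    chromosomes: tuple
    bins: pd.DataFrame = field(repr=False)
    bin_size: int

    def __post_init__(self):
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        lengths = dict(self.chromosomes)
        gc = self.bins["gc"].to_numpy()
        if np.any((gc < 0) | (gc > 1)):
            raise ValueError("gc fraction outside [0, 1]")
        if np.any(self.bins["mappability"].to_numpy() < 0):
            raise ValueError("negative mappability weight")
        for chrom, sub in self.bins.groupby("chrom", sort=False):
            if chrom not in lengths:
                raise ValueError(f"bins reference unknown chromosome {chrom}")
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            if starts[0] != 0 or ends[-1] != lengths[chrom]:
                raise ValueError(f"{chrom}: bins do not span the chromosome")
            if np.any(starts[1:] != ends[:-1]):
                raise ValueError(f"{chrom}: bins are not contiguous")
        if list(self.bins["chrom"].unique()) != names:
            raise ValueError("bin chromosome order does not match chromosome table")

    # -- lookups ---------------------------------------------------------
    @property
    def chrom_names(self) -> list:
        return [c for c, _ in self.chromosomes]

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def length_of(self, chrom: str) -> int:
        return dict(self.chromosomes)[chrom]

    def chrom_index(self, chrom: str) -> np.ndarray:
        """Boolean mask over bins belonging to ``chrom``."""
        return (self.bins["chrom"] == chrom).to_numpy()

    @property
    def autosome_mask(self) -> np.ndarray:
        return self.bins["chrom"].isin(AUTOSOMES).to_numpy()

    def bin_lengths(self) -> np.ndarray:
        return (self.bins["end"] - self.bins["start"]).to_numpy()


def _smooth_gc_field(n: int, rng: np.random.Generator,
                     center: float = 0.42, amplitude: float = 0.05,
                     window: int = 31) -> np.ndarray:
    """Spatially smooth per-bin GC fractions around a genome-typical center.

    White noise convolved with a boxcar of ``window`` bins, rescaled to the
    requested amplitude — mimics the Mb-scale autocorrelation of real GC
    content without modelling isochores explicitly.
    """
    noise = rng.normal(size=n + window)
    kernel = np.ones(window) / window
    smooth = np.convolve(noise, kernel, mode="valid")[:n]
    sd = smooth.std()
    if sd > 0:
        smooth = smooth / sd * amplitude
    return np.clip(center + smooth, 0.25, 0.65)


def build_genome_model(chromosome_table, bin_size: int,
                       gc_source="smooth-random", seed: int | None = 0,
                       mappability=None) -> GenomeModel:
    """Tile a chromosome table into bins and attach GC / mappability tracks.

    Parameters
    ----------
    chromosome_table : DataFrame with columns ``name``/``length`` (or a list
        of ``(name, length)`` pairs), unique names, positive lengths.
    bin_size : bin width in bp.
    gc_source : ``"smooth-random"`` for a seeded smooth random field, a float
        for a constant GC, or a DataFrame with columns chrom/start/gc giving
        per-bin values.
    mappability : optional per-bin array; defaults to 1 everywhere.
    """
    if isinstance(chromosome_table, pd.DataFrame):
        pairs = [(normalize_chrom(r["name"]), int(r["length"]))
                 for _, r in chromosome_table.iterrows()]
    else:
        pairs = [(normalize_chrom(n), int(l)) for n, l in chromosome_table]
    names = [n for n, _ in pairs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate chromosome names in table")
    if any(l <= 0 for _, l in pairs):
        raise ValueError("non-positive chromosome length")
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")

    rows = []
    for chrom, length in pairs:
        starts = np.arange(0, length, bin_size, dtype=np.int64)
        ends = np.minimum(starts + bin_size, length)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    bins = pd.concat(rows, ignore_index=True)

    n = len(bins)
    if isinstance(gc_source, pd.DataFrame):
        key = bins.merge(gc_source, on=["chrom", "start"], how="left")
        if key["gc"].isna().any():
            raise ValueError("gc table does not cover every bin")
        gc = key["gc"].to_numpy(float)
    elif np.isscalar(gc_source) and not isinstance(gc_source, str):
        gc = np.full(n, float(gc_source))
    elif gc_source == "smooth-random":
        rng = np.random.default_rng(seed)
        gc = np.concatenate([
            _smooth_gc_field(int((bins["chrom"] == c).sum()), rng)
            for c in names
        ])
    else:
        raise ValueError(f"unrecognized gc_source: {gc_source!r}")
    bins["gc"] = gc
    bins["mappability"] = 1.0 if mappability is None else np.asarray(mappability, float)
    return GenomeModel(chromosomes=tuple(pairs), bins=bins, bin_size=int(bin_size))


# -- shipped tables ------------------------------------------------------

def _data_path(name: str):
    return importlib.resources.files("plasmacnv.data").joinpath(name)


def hg19_chromosome_table() -> pd.DataFrame:
    """The 24 hg19 chromosome lengths (name, length) shipped with the package."""
    with _data_path("hg19_chrom_sizes.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def toy_chromosome_table() -> pd.DataFrame:
    """A small 3-autosome + X + Y genome for fast tests (30-150 Mb each)."""
    return pd.DataFrame({
        "name": ["chr1", "chr2", "chr3", "chrX", "chrY"],
        "length": [150_000_000, 100_000_000, 60_000_000, 90_000_000, 30_000_000],
    })


def hg19_genome(bin_size: int = 100_000, seed: int = 0) -> GenomeModel:
    return build_genome_model(hg19_chromosome_table(), bin_size, seed=seed)


def toy_genome(bin_size: int = 100_000, seed: int = 0) -> GenomeModel:
    return build_genome_model(toy_chromosome_table(), bin_size, seed=seed)


def read_chromosome_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"name", "length"} <= set(df.columns):
        raise ValueError("chromosome table needs 'name' and 'length' columns")
    return df
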