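"""Anchor-aligned occupancy profiles and differential-digestion analyses.

Rows of a :class:`ProfileMatrix` are strand-oriented: positive offsets run
downstream of the anchor (into the gene body for a TSS anchor), so genes on
the two strands aggregate coherently.  Offsets are half-open,
``[-flank, +flank)``, with offset 0 the anchor base itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats

from .annotation import Annotation
from .fragments import FragmentSet
from .tracks import TrackSet

__all__ = [
    "Anchor",
    "ProfileMatrix",
    "DigestionCorrelationProfile",
    "WindowTestResult",
    "extract_anchors",
    "profile_matrix",
    "aggregate_profile",
    "digestion_index",
    "digestion_correlation",
    "window_occupancy_test",
    "plus1_position",
    "moving_average",
    "stable_reference_scale",
]


@dataclass(frozen=True)
class Anchor:
    feature_id: str
    chrom: str
    pos: int
    strand: str
    kind: str  # 'TSS' | 'CSS' | 'exon_boundary'

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")


def extract_anchors(
    annotation: Annotation, kind: str, shared_only: bool = True
) -> list[Anchor]:
    """Strand-aware anchors at TSS, CSS or intron/exon junctions."""
    if kind not in ("TSS", "CSS", "exon_boundary"):
        raise ValueError(f"unknown anchor kind {kind!r}")
    anchors: list[Anchor] = []
    for g in annotation.genes:
        if shared_only and not g.shared_isoform:
            continue
        if kind == "TSS":
            anchors.append(Anchor(g.gene_id, g.chrom, g.tss, g.strand, kind))
        elif kind == "CSS":
            anchors.append(Anchor(g.gene_id, g.chrom, g.css, g.strand, kind))
        else:
            for i, (pos, side) in enumerate(g.exon_junctions()):
                anchors.append(
                    Anchor(f"{g.gene_id}:{side}{i}", g.chrom, pos, g.strand, kind)
                )
    return anchors


@dataclass
class ProfileMatrix:
    """anchors x signed offsets, NaN where the window leaves the chromosome."""

    anchors: list[Anchor]
    offsets: np.ndarray  # signed, strand-oriented, length = n columns
    values: np.ndarray  # (n_anchors, n_offsets), NaN = missing
    bin_size: int = 1

    def binned(self, bin_size: int) -> "ProfileMatrix":
        """Average columns into ``bin_size``-bp bins (NaN-aware)."""
        if bin_size <= 0:
            raise ValueError("bin size must be positive")
        n = (self.values.shape[1] // bin_size) * bin_size
        v = self.values[:, :n].reshape(self.values.shape[0], -1, bin_size)
        with np.errstate(invalid="ignore"):
            binned = np.nanmean(v, axis=2)
        offsets = self.offsets[:n:bin_size]
        return ProfileMatrix(self.anchors, offsets, binned, bin_size=bin_size * self.bin_size)


def profile_matrix(
    tracks: TrackSet,
    anchors: Sequence[Anchor],
    flank: int = 1000,
    bin_size: int = 1,
) -> ProfileMatrix:
    """Extract per-anchor rows over [pos - flank, pos + flank).

    Minus-strand rows are read right-to-left so that positive offsets point
    downstream; out-of-chromosome cells are NaN, never zero.
    """
    if len(anchors) == 0:
        raise ValueError("no anchors")
    if flank % bin_size:
        raise ValueError("flank must be a multiple of bin_size")
    offsets = np.arange(-flank, flank)
    rows = np.full((len(anchors), 2 * flank), np.nan)
    for i, a in enumerate(anchors):
        tr = tracks.get(a.chrom)
        if tr is None:
            continue
        if a.strand == "+":
            rows[i] = tr.slice(a.pos - flank, a.pos + flank)
        else:
            # offset o maps to genomic pos - o
            rows[i] = tr.slice(a.pos - flank + 1, a.pos + flank + 1)[::-1]
    pm = ProfileMatrix(list(anchors), offsets, rows)
    return pm if bin_size == 1 else pm.binned(bin_size)


def aggregate_profile(
    matrix: ProfileMatrix, stat: str = "mean"
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column-wise aggregate ignoring missing cells.

    Returns (offsets, values, n_contributing_rows).
    """
    if matrix.values.shape[0] < 1:
        raise ValueError("empty profile matrix")
    with np.errstate(invalid="ignore"):
        if stat == "mean":
            vals = np.nanmean(matrix.values, axis=0)
        elif stat == "median":
            vals = np.nanmedian(matrix.values, axis=0)
        else:
            raise ValueError(f"unknown stat {stat!r}")
    n = np.sum(~np.isnan(matrix.values), axis=0)
    return matrix.offsets, vals, n


# -------------------------------------------------------- digestion metrics


def digestion_index(
    frags: FragmentSet,
    estimator: str | Callable[[np.ndarray], float] = "mono_fraction",
    mono_band: tuple[int, int] = (120, 180),
    nuc_min: int = 120,
) -> float:
    """Per-sample digestion-completeness estimate in [0, 1].

    The default estimator is the mono-nucleosome fraction of all
    nucleosome-scale fragments: complete digestion cleaves oligo-nucleosome
    fragments to monomers, so the statistic rises monotonically with
    digestion.  Alternative estimators can be passed as a callable on the
    fragment-length vector.
    """
    lengths = frags.lengths
    if callable(estimator):
        return float(estimator(lengths))
    if estimator != "mono_fraction":
        raise ValueError(f"unknown estimator {estimator!r}")
    nuc = lengths[lengths >= nuc_min]
    if len(nuc) == 0:
        raise ValueError("no nucleosome-scale fragments; digestion index undefined")
    lo, hi = mono_band
    return float(((nuc >= lo) & (nuc <= hi)).sum() / len(nuc))


@dataclass
class DigestionCorrelationProfile:
    """Per-bin Pearson r between digestion index and occupancy across samples."""

    offsets: np.ndarray  # bin left edges, strand-oriented
    r: np.ndarray  # NaN where undefined
    defined: np.ndarray  # False where zero variance made r undefined
    n_samples: int
    bin_size: int


def digestion_correlation(
    profiles: Mapping[str, np.ndarray],
    indices: Mapping[str, float],
    offsets: np.ndarray,
    bin_size: int = 10,
) -> DigestionCorrelationProfile:
    """Correlate digestion level with aggregate occupancy per offset bin.

    ``profiles`` maps sample id to its depth-normalized aggregate profile
    on common ``offsets``; ``indices`` maps sample id to its digestion
    index.  Requires >= 3 samples.  Zero-variance bins are flagged
    undefined rather than assigned a fabricated r.
    """
    samples = sorted(profiles)
    if len(samples) < 3:
        raise ValueError("need >= 3 samples for a correlation profile")
    if sorted(indices) != samples:
        raise ValueError("profiles and indices must cover the same samples")
    mat = np.vstack([profiles[s] for s in samples])  # samples x offsets
    n = (mat.shape[1] // bin_size) * bin_size
    binned = np.nanmean(mat[:, :n].reshape(mat.shape[0], -1, bin_size), axis=2)
    bin_offsets = np.asarray(offsets)[:n:bin_size]
    x = np.array([indices[s] for s in samples], dtype=float)
    xd = x - x.mean()
    yd = binned - binned.mean(axis=0)
    sx = np.sqrt((xd**2).sum())
    sy = np.sqrt((yd**2).sum(axis=0))
    defined = (sx > 0) & (sy > 0) & ~np.isnan(sy)
    r = np.full(binned.shape[1], np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        r[defined] = (xd @ binned[:, defined]) / (sx * sy[defined])
    return DigestionCorrelationProfile(
        offsets=bin_offsets, r=r, defined=defined, n_samples=len(samples), bin_size=bin_size
    )


@dataclass
class WindowTestResult:
    window: str
    span: tuple[int, int]
    mean_low: float
    mean_high: float
    t: float
    p: float
    significant: bool
    degenerate: bool = False


DEFAULT_WINDOWS = {"minus1": (-125, -75), "plus1": (75, 125)}


def window_occupancy_test(
    profiles: Mapping[str, np.ndarray],
    offsets: np.ndarray,
    groups: Mapping[str, str],
    windows: Mapping[str, tuple[int, int]] | None = None,
    alpha: float = 0.05,
) -> list[WindowTestResult]:
    """Welch t-test of mean window occupancy between digestion groups.

    Each sample contributes its mean occupancy over the window; the two
    groups ('low' vs 'high' digestion) are compared per window.  Requires
    >= 2 samples per group.
    """
    windows = dict(windows or DEFAULT_WINDOWS)
    offsets = np.asarray(offsets)
    low = [s for s in sorted(profiles) if groups[s] == "low"]
    high = [s for s in sorted(profiles) if groups[s] == "high"]
    if len(low) < 2 or len(high) < 2:
        raise ValueError("need >= 2 samples per digestion group")
    out = []
    for name, (lo, hi) in windows.items():
        sel = (offsets >= lo) & (offsets < hi)
        a = np.array([np.nanmean(profiles[s][sel]) for s in low])
        b = np.array([np.nanmean(profiles[s][sel]) for s in high])
        degenerate = a.std() == 0 and b.std() == 0
        if degenerate and a.mean() == b.mean():
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(a, b, equal_var=False)
        out.append(
            WindowTestResult(
                window=name,
                span=(lo, hi),
                mean_low=float(a.mean()),
                mean_high=float(b.mean()),
                t=float(t),
                p=float(p),
                significant=bool(p < alpha),
                degenerate=bool(degenerate),
            )
        )
    return out


def stable_reference_scale(
    tracks: TrackSet, anchors: Sequence[Anchor], exclusion: int = 2000
) -> float:
    """Mean track value over bases farther than ``exclusion`` from anchors.

    Differential-digestion comparisons of coverage need a normalizer that
    is itself insensitive to digestion level: per-fragment scaling is
    confounded because cleavage multiplies fragment counts without
    changing which bases stay protected.  Distal chromatin (far from any
    TSS) is dominated by stable nucleosomes, so its mean coverage serves
    as an internal reference.
    """
    total = 0.0
    n = 0
    by_chrom: dict[str, list[int]] = {}
    for a in anchors:
        by_chrom.setdefault(a.chrom, []).append(a.pos)
    for chrom, tr in tracks.items():
        mask = np.ones(len(tr.values), dtype=bool)
        for pos in by_chrom.get(chrom, []):
            mask[max(0, pos - exclusion) : pos + exclusion] = False
        total += float(tr.values[mask].sum())
        n += int(mask.sum())
    if n == 0:
        raise ValueError("no bases outside the exclusion zones")
    scale = total / n
    if scale <= 0:
        raise ValueError("stable reference has zero coverage")
    return scale


def moving_average(values: np.ndarray, width: int) -> np.ndarray:
    """Centered moving average; NaNs propagate as missing, edges shrink."""
    if width <= 1:
        return np.asarray(values, dtype=float)
    v = np.asarray(values, dtype=float)
    mask = np.isfinite(v)
    num = np.convolve(np.where(mask, v, 0.0), np.ones(width), mode="same")
    den = np.convolve(mask.astype(float), np.ones(width), mode="same")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[den == 0] = np.nan
    return out


def plus1_position(
    values: np.ndarray,
    offsets: np.ndarray,
    span: tuple[int, int] = (0, 250),
    smooth: int = 31,
) -> float | None:
    """Offset of the smoothed maximum within the search span.

    Returns None when the span carries no signal (all zero or missing).
    """
    offsets = np.asarray(offsets)
    sm = moving_average(values, smooth)
    sel = (offsets >= span[0]) & (offsets <= span[1])
    window = sm[sel]
    if not np.isfinite(window).any() or np.nanmax(window) <= 0:
        return None
    # box smoothing turns sharp peaks into plateaus: report the plateau centre
    mx = np.nanmax(window)
    at_max = np.flatnonzero(window >= mx * (1 - 1e-12))
    return float(offsets[sel][at_max[len(at_max) // 2]])
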