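"""Discrete subNSP position calling, distance-to-CDS statistics, and
TF-binding-site (TFBS) aggregation.

Positions are called from a depth-normalized subNSP midpoint track by
moving-average smoothing, thresholding at a multiple of the genome-wide
nonzero median, and greedy highest-first selection of local maxima with a
minimum separation — a deliberately simple, fully deterministic caller.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import Annotation
from .profiles import Anchor, ProfileMatrix, aggregate_profile, moving_average, profile_matrix
from .tracks import TrackSet

__all__ = [
    "SubnspPosition",
    "TFBSSet",
    "call_subnsp_positions",
    "distance_to_nearest_cds",
    "fraction_beyond",
    "tfbs_aggregate",
    "TfbsAggregate",
    "gene_region_report",
    "GeneRegionReport",
]


@dataclass(frozen=True)
class SubnspPosition:
    chrom: str
    pos: int
    score: float
    label: str = ""


def call_subnsp_positions(
    tracks: TrackSet,
    smooth_bw: int = 15,
    threshold_k: float = 4.0,
    min_sep: int = 60,
    label: str = "",
) -> list[SubnspPosition]:
    """Call subNSP summits from a normalized midpoint track.

    Threshold = ``threshold_k`` x genome-wide nonzero median of the raw
    track.  For a sparse midpoint track the nonzero median is the weight
    of a single fragment, so the threshold reads as "at least k stacked
    midpoints" and does not collapse on quiet genomes.  Candidate local
    maxima of the smoothed signal (ties resolved leftmost) are accepted
    highest-first subject to ``min_sep``; iteration over chromosomes in
    sorted order makes the output independent of dict order.
    """
    smoothed = {c: moving_average(tracks[c].values, smooth_bw) for c in sorted(tracks)}
    raw = [tracks[c].values for c in sorted(tracks)]
    pooled = np.concatenate([v[v > 0] for v in raw]) if raw else np.array([])
    if pooled.size == 0:
        return []
    threshold = threshold_k * float(np.median(pooled))
    candidates: list[tuple[float, str, int]] = []
    for chrom, v in smoothed.items():
        if len(v) < 3:
            continue
        left = v[1:-1] >= v[:-2]
        right = v[1:-1] > v[2:]  # strict on the right => leftmost of a plateau
        peaks = np.flatnonzero(left & right & (v[1:-1] > threshold)) + 1
        for p in peaks:
            candidates.append((float(v[p]), chrom, int(p)))
    # greedy highest-first; deterministic tie-break by (chrom, pos)
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    taken: dict[str, list[int]] = {}
    out: list[SubnspPosition] = []
    for score, chrom, pos in candidates:
        near = taken.setdefault(chrom, [])
        if any(abs(pos - q) < min_sep for q in near):
            continue
        near.append(pos)
        out.append(SubnspPosition(chrom, pos, score, label))
    out.sort(key=lambda s: (s.chrom, s.pos))
    return out


def distance_to_nearest_cds(
    positions: Sequence[SubnspPosition], annotation: Annotation
) -> np.ndarray:
    """Edge-to-edge distance from each position to the nearest CDS.

    Zero inside a CDS; otherwise the gap to the closest CDS edge on either
    side, strand-ignored.  Distances are against CDS features specifically,
    not gene or transcript spans.
    """
    cds = annotation.cds_intervals()
    if not any(cds.values()):
        raise ValueError("annotation has no CDS features")
    dists = np.empty(len(positions), dtype=np.int64)
    per_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, ivs in cds.items():
        if ivs:
            arr = np.array(ivs)
            per_chrom[chrom] = (arr[:, 0], arr[:, 1])
    all_edges = {
        c: np.sort(np.concatenate([s, e - 1])) for c, (s, e) in per_chrom.items()
    }
    for i, p in enumerate(positions):
        if p.chrom not in per_chrom:
            # no CDS on this chromosome: use nearest on any chromosome? No —
            # report the distance as to the nearest CDS edge genome-wide is
            # ill-defined across chromosomes; treat as max over this chrom.
            raise ValueError(f"no CDS on chromosome {p.chrom}")
        s, e = per_chrom[p.chrom]
        inside = np.any((s <= p.pos) & (p.pos < e))
        if inside:
            dists[i] = 0
            continue
        edges = all_edges[p.chrom]
        j = np.searchsorted(edges, p.pos)
        best = np.inf
        if j < len(edges):
            best = min(best, edges[j] - p.pos)
        if j > 0:
            best = min(best, p.pos - edges[j - 1])
        dists[i] = int(best)
    return dists


def fraction_beyond(
    distances: np.ndarray, thresholds: Sequence[int] = (10_000, 100_000)
) -> dict[int, float]:
    """Percentage of positions strictly farther than each threshold.

    Order-independent in ``thresholds``; empty input is an error.
    """
    distances = np.asarray(distances)
    if distances.size == 0:
        raise ValueError("no distances")
    return {
        int(t): float((distances > t).sum() / distances.size * 100.0)
        for t in thresholds
    }


# ------------------------------------------------------------------- TFBS


@dataclass
class TFBSSet:
    """Named TF binding-site intervals (BED6; strand assumed '+' if absent)."""

    name: str
    sites: pd.DataFrame  # chrom, start, end, strand

    def __post_init__(self) -> None:
        self.sites = self.sites.sort_values(["chrom", "start"]).reset_index(drop=True)

    @classmethod
    def from_bed(cls, path: str | Path, name: str | None = None) -> "TFBSSet":
        rows = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t") if "\t" in line else line.split()
                if len(parts) < 3:
                    raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
                strand = parts[5] if len(parts) >= 6 and parts[5] in "+-" else "+"
                rows.append((parts[0], int(parts[1]), int(parts[2]), strand))
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])
        return cls(name or Path(path).stem, df)

    def anchors(self) -> list[Anchor]:
        return [
            Anchor(f"{self.name}_{i}", r.chrom, (r.start + r.end) // 2, r.strand, "TSS")
            for i, r in enumerate(self.sites.itertuples())
        ]


@dataclass
class TfbsAggregate:
    offsets: np.ndarray
    aggregates: dict[str, np.ndarray]  # condition -> mean profile
    difference: np.ndarray  # first condition minus second
    matrices: dict[str, ProfileMatrix]
    conditions: tuple[str, str]


def tfbs_aggregate(
    tracks_by_condition: Mapping[str, TrackSet],
    sites: TFBSSet,
    flank: int = 500,
    conditions: tuple[str, str] = ("light", "dark"),
) -> TfbsAggregate:
    """Site-centered, strand-oriented subNSP aggregation per condition.

    Both input track sets must be depth-normalized so the (first - second)
    difference profile is meaningful; swapping the two condition labels
    negates the difference exactly.
    """
    if len(sites.sites) == 0:
        raise ValueError("empty TFBS set")
    anchors = sites.anchors()
    mats = {}
    aggs = {}
    offsets = None
    for cond in conditions:
        mats[cond] = profile_matrix(tracks_by_condition[cond], anchors, flank=flank)
        offsets, agg, _ = aggregate_profile(mats[cond])
        aggs[cond] = agg
    diff = aggs[conditions[0]] - aggs[conditions[1]]
    return TfbsAggregate(
        offsets=offsets,
        aggregates=aggs,
        difference=diff,
        matrices=mats,
        conditions=conditions,
    )


# ------------------------------------------------------- gene region report


@dataclass
class GeneRegionReport:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    # sample -> class name -> values oriented 5'->3' of the gene
    tracks: dict[str, dict[str, np.ndarray]]


def gene_region_report(
    sample_tracks: Mapping[str, Mapping[str, TrackSet]],
    annotation: Annotation,
    gene_id: str,
    flank: int = 500,
    outdir: str | Path | None = None,
) -> GeneRegionReport:
    """Bundle subNSP / mono-midpoint / total-coverage tracks over one gene.

    ``sample_tracks`` maps sample id -> track-class name -> TrackSet.
    Arrays are oriented 5'->3' of the gene; with ``outdir`` given, each
    track is exported as bedGraph (genomic orientation) plus one overview
    plot per gene.
    """
    gene = annotation.get_gene(gene_id)  # raises with nearest ids if unknown
    size = annotation.chrom_sizes[gene.chrom]
    lo = max(0, gene.start - flank)
    hi = min(size, gene.end + flank)
    out: dict[str, dict[str, np.ndarray]] = {}
    for sample, classes in sample_tracks.items():
        out[sample] = {}
        for klass, tracks in classes.items():
            tr = tracks.get(gene.chrom)
            vals = tr.slice(lo, hi) if tr is not None else np.full(hi - lo, np.nan)
            out[sample][klass] = vals if gene.strand == "+" else vals[::-1]
    report = GeneRegionReport(gene_id, gene.chrom, lo, hi, gene.strand, out)
    if outdir is not None:
        _write_gene_report(report, sample_tracks, outdir)
    return report


def _write_gene_report(
    report: GeneRegionReport,
    sample_tracks: Mapping[str, Mapping[str, TrackSet]],
    outdir: str | Path,
) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for sample, classes in sample_tracks.items():
        for klass, tracks in classes.items():
            tr = tracks.get(report.chrom)
            if tr is None:
                continue
            vals = tr.slice(report.start, report.end)
            path = outdir / f"{report.gene_id}_{sample}_{klass}.bedGraph"
            with open(path, "w") as fh:
                for i, v in enumerate(vals):
                    if np.isfinite(v) and v != 0:
                        g = report.start + i
                        fh.write(f"{report.chrom}\t{g}\t{g + 1}\t{v:.6g}\n")
    n = len(report.tracks)
    fig, axes = plt.subplots(n, 1, figsize=(8, 1.6 * n), sharex=True, squeeze=False)
    x = np.arange(report.end - report.start)
    for ax, (sample, classes) in zip(axes[:, 0], report.tracks.items()):
        for klass, vals in classes.items():
            ax.plot(x, vals, label=klass, lw=0.8)
        ax.set_ylabel(sample, fontsize=7)
    axes[0, 0].legend(fontsize=6)
    axes[-1, 0].set_xlabel(f"{report.gene_id} 5'->3' (bp)")
    fig.tight_layout()
    fig.savefig(outdir / f"{report.gene_id}.png", dpi=100)
    plt.close(fig)
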