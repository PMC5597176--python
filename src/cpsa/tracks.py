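"""Occupancy tracks: midpoint, interpolated coverage, and size x position.

A midpoint track counts one event per fragment at the midpoint base and is
used for dyad mapping of mono-nucleosome-sized fragments and for subNSP
footprints.  A coverage track increments every base the fragment protects
("interpolating" between the sequenced pair ends), built by interval
difference-accumulation which is exactly equivalent to a per-base loop.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .fragments import FragmentSet, SizeClassScheme

__all__ = [
    "OccupancyTrack",
    "SizePositionMatrix",
    "midpoint_track",
    "coverage_track",
    "normalize_per_million",
    "normalize_tracks",
    "size_position_matrix",
    "write_tracks",
    "read_tracks",
]


@dataclass
class OccupancyTrack:
    """Per-base (or binned) non-negative signal on one chromosome."""

    chrom: str
    values: np.ndarray
    origin: int = 0
    bin_size: int = 1
    mode: str = "midpoint"  # or "coverage"
    normalization: str = "raw"  # or "per_million"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < 0).any():
            raise ValueError("negative track values")

    def slice(self, start: int, end: int) -> np.ndarray:
        """Values over [start, end); positions outside the track are NaN."""
        n = len(self.values)
        out = np.full(end - start, np.nan)
        lo = max(start, self.origin)
        hi = min(end, self.origin + n)
        if hi > lo:
            out[lo - start : hi - start] = self.values[lo - self.origin : hi - self.origin]
        return out


TrackSet = dict[str, OccupancyTrack]


def _empty_tracks(chrom_sizes: dict[str, int], mode: str) -> TrackSet:
    return {
        c: OccupancyTrack(c, np.zeros(n), mode=mode) for c, n in chrom_sizes.items()
    }


def midpoint_track(
    frags: FragmentSet,
    chrom_sizes: dict[str, int],
    size_window: tuple[int, int] | None = None,
    scheme: SizeClassScheme | None = None,
) -> TrackSet:
    """Per-base midpoint counts of fragments within a length window.

    Default window is the mono-nucleosome dyad window (150 +/- 15 bp).
    The raw track sum equals the number of contributing fragments.
    """
    if size_window is None:
        size_window = (scheme or SizeClassScheme()).mono_mid_window
    lo, hi = size_window
    tracks = _empty_tracks(chrom_sizes, "midpoint")
    lengths = frags.lengths
    mids = frags.midpoints
    keep = (lengths >= lo) & (lengths <= hi)
    chroms = frags.df["chrom"].to_numpy()
    for chrom, tr in tracks.items():
        m = mids[keep & (chroms == chrom)]
        m = m[(m >= 0) & (m < len(tr.values))]
        np.add.at(tr.values, m, 1.0)
    return tracks


def coverage_track(
    frags: FragmentSet,
    chrom_sizes: dict[str, int],
    min_length: int = 120,
    max_length: int | None = None,
) -> TrackSet:
    """Per-base protection depth of fragments with length in range.

    The default ``min_length`` keeps nucleosomal-and-larger fragments; use
    ``min_length=20, max_length=119`` for the subNSP coverage split.
    """
    tracks = _empty_tracks(chrom_sizes, "coverage")
    lengths = frags.lengths
    keep = lengths >= min_length
    if max_length is not None:
        keep &= lengths <= max_length
    chroms = frags.df["chrom"].to_numpy()
    starts = frags.df["start"].to_numpy()
    ends = frags.df["end"].to_numpy()
    for chrom, tr in tracks.items():
        n = len(tr.values)
        m = keep & (chroms == chrom)
        s = np.clip(starts[m], 0, n)
        e = np.clip(ends[m], 0, n)
        diff = np.zeros(n + 1)
        np.add.at(diff, s, 1.0)
        np.add.at(diff, e, -1.0)
        tr.values = np.cumsum(diff[:-1])
    return tracks


def normalize_per_million(track: OccupancyTrack, total_retained: int) -> OccupancyTrack:
    """Scale by 1e6 / total retained fragments of the sample.

    Raises on a zero total or on a track already normalized (the scale
    factor is not idempotent, so re-application is a contract error).
    """
    if track.normalization != "raw":
        raise ValueError("track already normalized")
    if total_retained <= 0:
        raise ValueError("total retained fragment count must be positive")
    return replace(
        track, values=track.values * (1e6 / total_retained), normalization="per_million"
    )


def normalize_tracks(tracks: TrackSet, total_retained: int) -> TrackSet:
    return {c: normalize_per_million(t, total_retained) for c, t in tracks.items()}


@dataclass
class SizePositionMatrix:
    """Fragment counts binned jointly by length and midpoint position."""

    chrom: str
    start: int
    end: int
    size_edges: np.ndarray  # length-bin edges
    pos_edges: np.ndarray  # midpoint-bin edges
    counts: np.ndarray  # (n_size_bins, n_pos_bins)
    normalization: str = "raw"

    def size_marginal(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def position_marginal(self) -> np.ndarray:
        return self.counts.sum(axis=0)


def size_position_matrix(
    frags: FragmentSet,
    region: tuple[str, int, int],
    size_bin: int = 10,
    pos_bin: int = 10,
    size_range: tuple[int, int] | None = None,
) -> SizePositionMatrix:
    """Joint (length, midpoint) histogram over one region.

    The matrix total equals the number of fragments whose midpoint falls in
    the region and whose length falls in ``size_range``.
    """
    if size_bin <= 0 or pos_bin <= 0:
        raise ValueError("bin sizes must be positive")
    chrom, start, end = region
    if size_range is None:
        size_range = SizeClassScheme().retention
    lo, hi = size_range
    size_edges = np.arange(lo, hi + size_bin + 1, size_bin)  # upper bound inclusive
    pos_edges = np.arange(start, end + pos_bin, pos_bin)
    m = (frags.df["chrom"].to_numpy() == chrom)
    lengths = frags.lengths[m]
    mids = frags.midpoints[m]
    sel = (mids >= start) & (mids < pos_edges[-1]) & (lengths >= lo) & (lengths < size_edges[-1])
    counts, _, _ = np.histogram2d(
        lengths[sel], mids[sel], bins=(size_edges, pos_edges)
    )
    return SizePositionMatrix(chrom, start, end, size_edges, pos_edges, counts)


# ----------------------------------------------------------------- track I/O


def write_tracks(
    tracks: TrackSet,
    path: str | Path,
    fmt: str = "bedGraph",
    chrom_sizes: dict[str, int] | None = None,
) -> None:
    """Export tracks as wiggle fixedStep (1-based) or bedGraph (0-based).

    Adjacent equal values are merged into one bedGraph interval; zero runs
    are omitted from bedGraph output per convention.
    """
    if fmt not in ("wiggle", "bedGraph"):
        raise ValueError(f"unknown format {fmt!r}")
    if chrom_sizes is not None:
        for chrom in tracks:
            if chrom not in chrom_sizes:
                raise ValueError(f"chromosome {chrom!r} absent from declared set")
    with open(path, "w") as fh:
        for chrom in sorted(tracks):
            tr = tracks[chrom]
            if fmt == "wiggle":
                fh.write(
                    f"fixedStep chrom={chrom} start={tr.origin + 1} "
                    f"step={tr.bin_size} span={tr.bin_size}\n"
                )
                for v in tr.values:
                    fh.write(f"{v:.6g}\n")
            else:
                v = tr.values
                if len(v) == 0:
                    continue
                # run-length encode
                change = np.flatnonzero(np.diff(v) != 0)
                starts = np.concatenate(([0], change + 1))
                ends = np.concatenate((change + 1, [len(v)]))
                for s, e in zip(starts, ends):
                    if v[s] == 0:
                        continue
                    gs = tr.origin + s * tr.bin_size
                    ge = tr.origin + e * tr.bin_size
                    fh.write(f"{chrom}\t{gs}\t{ge}\t{v[s]:.6g}\n")


def read_tracks(path: str | Path, chrom_sizes: dict[str, int] | None = None) -> TrackSet:
    """Read wiggle fixedStep or bedGraph written by :func:`write_tracks`."""
    text = Path(path).read_text().splitlines()
    tracks: TrackSet = {}
    if any(line.startswith("fixedStep") for line in text):
        chrom, start, step, vals = None, 0, 1, []

        def flush():
            if chrom is not None:
                tracks[chrom] = OccupancyTrack(
                    chrom, np.array(vals), origin=start, bin_size=step
                )

        for line in text:
            if line.startswith("fixedStep"):
                flush()
                kv = dict(p.split("=") for p in line.split()[1:])
                chrom, start, step = kv["chrom"], int(kv["start"]) - 1, int(kv["step"])
                vals = []
            elif line.strip():
                vals.append(float(line))
        flush()
        return tracks
    # bedGraph
    rows: dict[str, list[tuple[int, int, float]]] = {}
    for line in text:
        if not line.strip() or line.startswith(("track", "#")):
            continue
        chrom, s, e, v = line.split("\t")
        rows.setdefault(chrom, []).append((int(s), int(e), float(v)))
    for chrom, ivs in rows.items():
        size = (chrom_sizes or {}).get(chrom, max(e for _, e, _ in ivs))
        arr = np.zeros(size)
        for s, e, v in ivs:
            arr[s:e] = v
        tracks[chrom] = OccupancyTrack(chrom, arr)
    return tracks
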