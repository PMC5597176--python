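"""Paired-end protected-DNA fragments and size classification.

The protected fragment length (paired-end insert distance) reports the size
of the DNA-bound particle: sub-nucleosomal particles (subNSP) protect
< 120 bp, a mono-nucleosome ~150 bp, and partially digested arrays of N
nucleosomes protect ~N*150 + (N-1)*30 bp including linkers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

log = logging.getLogger(__name__)

__all__ = [
    "SizeClassScheme",
    "FragmentSet",
    "classify_fragment",
    "classify_lengths",
    "read_fragment_bed",
    "fragments_from_paired_bam",
]


@dataclass(frozen=True)
class SizeClassScheme:
    """Thresholds mapping protected-fragment length to particle class.

    ``sub_max`` is exclusive: a fragment is subNSP iff length < sub_max.
    Fragments >= sub_max are assigned a nucleosome order
    ``N = round((length + linker) / (nuc_unit + linker))`` (clamped to >= 1);
    order 1 is mono-nucleosomal, higher orders multi-nucleosomal.
    ``mono_mid_tol`` defines the tighter window (nuc_unit +/- tol) used for
    dyad-midpoint tracks; ``retention`` is the sequencer/gel size selection.
    """

    sub_max: int = 120
    nuc_unit: int = 150
    linker: int = 30
    mono_mid_tol: int = 15
    retention: tuple[int, int] = (20, 1000)

    def __post_init__(self) -> None:
        if not self.sub_max < self.nuc_unit:
            raise ValueError("sub_max must be below nuc_unit")
        if not self.mono_mid_tol < self.nuc_unit / 2:
            raise ValueError("mono_mid_tol too wide")
        lo, hi = self.retention
        if not (0 < lo < hi):
            raise ValueError("bad retention range")

    @property
    def mono_mid_window(self) -> tuple[int, int]:
        """Inclusive length window for mono-nucleosome midpoint mapping."""
        return (self.nuc_unit - self.mono_mid_tol, self.nuc_unit + self.mono_mid_tol)


def classify_lengths(lengths: np.ndarray, scheme: SizeClassScheme) -> np.ndarray:
    """Vectorised particle order: 0 = subNSP, 1 = mono, N >= 2 = multi(N)."""
    lengths = np.asarray(lengths)
    unit = scheme.nuc_unit + scheme.linker
    # floor(x + 0.5) rounding: deterministic at the halfway points
    order = np.floor((lengths + scheme.linker) / unit + 0.5).astype(int)
    order = np.maximum(order, 1)
    order[lengths < scheme.sub_max] = 0
    return order


def classify_fragment(length: int, scheme: SizeClassScheme | None = None) -> str:
    """Classify one fragment length: 'subNSP', 'mono' or 'multi(N)'."""
    scheme = scheme or SizeClassScheme()
    lo, hi = scheme.retention
    if not (lo <= length <= hi):
        raise ValueError(f"length {length} outside retention range {scheme.retention}")
    order = int(classify_lengths(np.array([length]), scheme)[0])
    if order == 0:
        return "subNSP"
    if order == 1:
        return "mono"
    return f"multi({order})"


@dataclass
class FragmentSet:
    """Sorted retained fragments for one sample plus drop accounting."""

    df: pd.DataFrame  # columns: chrom (str), start, end (int64)
    sample_id: str = ""
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if not (self.df["end"] > self.df["start"]).all():
            raise ValueError("fragment with end <= start")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def lengths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy()

    @property
    def midpoints(self) -> np.ndarray:
        # even lengths round down: fixed convention
        return ((self.df["start"] + self.df["end"]) // 2).to_numpy()

    def subset(self, mask: np.ndarray, sample_id: str | None = None) -> "FragmentSet":
        return FragmentSet(
            self.df.loc[np.asarray(mask)].reset_index(drop=True),
            sample_id if sample_id is not None else self.sample_id,
        )

    def by_class(self, scheme: SizeClassScheme, klass: str) -> "FragmentSet":
        """Subset to one particle class ('subNSP', 'mono', or 'multi')."""
        order = classify_lengths(self.lengths, scheme)
        if klass == "subNSP":
            mask = order == 0
        elif klass == "mono":
            mask = order == 1
        elif klass == "multi":
            mask = order >= 2
        else:
            raise ValueError(f"unknown class {klass!r}")
        return self.subset(mask)

    def class_counts(self, scheme: SizeClassScheme) -> dict[str, int]:
        order = classify_lengths(self.lengths, scheme)
        out: dict[str, int] = {"subNSP": int((order == 0).sum()), "mono": int((order == 1).sum())}
        for n in sorted(set(order[order >= 2])):
            out[f"multi({n})"] = int((order == n).sum())
        return out

    def to_bed(self, path: str | Path) -> None:
        """6-column BED: name = sample id, score = fragment length."""
        df = self.df
        with open(path, "w") as fh:
            for chrom, s, e in zip(df["chrom"], df["start"], df["end"]):
                fh.write(f"{chrom}\t{s}\t{e}\t{self.sample_id or '.'}\t{e - s}\t.\n")


def _finish(df: pd.DataFrame, scheme: SizeClassScheme, sample_id: str, n_dropped_pre: int = 0) -> FragmentSet:
    lo, hi = scheme.retention
    lengths = df["end"] - df["start"]
    keep = (lengths >= lo) & (lengths <= hi)
    n_drop = int((~keep).sum()) + n_dropped_pre
    if n_drop:
        log.info("%s: dropped %d fragments outside retention %s", sample_id or "fragments", n_drop, scheme.retention)
    df = df.loc[keep].sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
    return FragmentSet(df, sample_id=sample_id, n_dropped=n_drop)


def read_fragment_bed(
    path: str | Path, scheme: SizeClassScheme | None = None, sample_id: str = ""
) -> FragmentSet:
    """Read fragments from a >=3-column BED file.

    Fragments outside the retention range are dropped and tallied; malformed
    lines raise with their line number.
    """
    scheme = scheme or SizeClassScheme()
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                s, e = int(parts[1]), int(parts[2])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from None
            if e <= s:
                raise ValueError(f"{path}:{lineno}: end <= start")
            chroms.append(parts[0])
            starts.append(s)
            ends.append(e)
    if not chroms:
        log.warning("%s: empty fragment file", path)
    df = pd.DataFrame(
        {"chrom": pd.Series(chroms, dtype=str),
         "start": pd.Series(starts, dtype=np.int64),
         "end": pd.Series(ends, dtype=np.int64)}
    )
    return _finish(df, scheme, sample_id or Path(path).stem)


def fragments_from_paired_bam(
    path: str | Path,
    min_mapq: int = 10,
    scheme: SizeClassScheme | None = None,
    sample_id: str = "",
) -> FragmentSet:
    """Infer protected fragments from properly paired alignments.

    One fragment per template: span from the leftmost mate start over
    ``|template length|`` bases.  Only the first mate of each pair is
    counted to avoid doubling; mates below ``min_mapq`` or with zero
    template length are excluded and tallied.
    """
    scheme = scheme or SizeClassScheme()
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    n_excluded = 0
    n_reads = 0
    with pysam.AlignmentFile(str(path), check_sq=False) as bam:
        for read in bam.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            n_reads += 1
            if not (read.is_paired and read.is_proper_pair and read.is_read1):
                continue
            if read.mapping_quality < min_mapq or read.template_length == 0:
                n_excluded += 1
                continue
            start = min(read.reference_start, read.next_reference_start)
            chroms.append(read.reference_name)
            starts.append(start)
            ends.append(start + abs(read.template_length))
    if n_reads and not (chroms or n_excluded):
        raise ValueError(
            f"{path}: no properly paired templates found; "
            "supply fragment intervals as BED instead"
        )
    df = pd.DataFrame(
        {"chrom": pd.Series(chroms, dtype=str),
         "start": pd.Series(starts, dtype=np.int64),
         "end": pd.Series(ends, dtype=np.int64)}
    )
    return _finish(df, scheme, sample_id or Path(path).stem, n_dropped_pre=n_excluded)
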