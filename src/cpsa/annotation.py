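"""Gene annotation container and GFF3 round-trip.

Coordinates are 0-based half-open internally (BED convention); GFF3 is
converted to/from its native 1-based inclusive representation only at the
file boundary.  A :class:`GeneModel` records the transcription start site
(TSS), coding start site (CSS) and transcription end site (TES) as genomic
base positions: on the ``+`` strand the TSS is the smallest coordinate of
the transcript, on the ``-`` strand it is the largest (the 5' base).
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import gffutils

__all__ = ["GeneModel", "Annotation"]


@dataclass(frozen=True)
class GeneModel:
    """One gene with a single (primary) transcript model.

    ``start``/``end`` delimit the transcript span, half-open.  ``exons`` are
    genomic half-open intervals within the span; ``cds`` likewise.  The
    ``shared_isoform`` flag marks genes whose primary isoform is consistent
    across samples and therefore eligible for anchor-aligned aggregation.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    css: int
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...] = ()
    shared_isoform: bool = True

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if not self.start < self.end:
            raise ValueError(f"{self.gene_id}: empty span")
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise ValueError(f"{self.gene_id}: exon ({s},{e}) outside span")

    @property
    def tss(self) -> int:
        """Genomic base of transcription initiation (strand-aware)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    def exon_junctions(self) -> list[tuple[int, str]]:
        """Intron/exon junction positions: (first intron base, 'donor') and
        (first exon base, 'acceptor') in genomic order."""
        out = []
        exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            out.append((e1, "donor"))
            out.append((s2, "acceptor"))
        return out


class Annotation:
    """Chromosome table plus gene models, with GFF3 export/import."""

    def __init__(self, chrom_sizes: dict[str, int], genes: Iterable[GeneModel]):
        self.chrom_sizes = dict(chrom_sizes)
        self.genes = list(genes)
        for g in self.genes:
            if g.chrom not in self.chrom_sizes:
                raise ValueError(f"{g.gene_id}: unknown chromosome {g.chrom}")
            if g.end > self.chrom_sizes[g.chrom]:
                raise ValueError(f"{g.gene_id}: extends past end of {g.chrom}")
        self._by_id = {g.gene_id: g for g in self.genes}

    def __len__(self) -> int:
        return len(self.genes)

    def get_gene(self, gene_id: str) -> GeneModel:
        try:
            return self._by_id[gene_id]
        except KeyError:
            near = difflib.get_close_matches(gene_id, self._by_id, n=3, cutoff=0.4)
            raise KeyError(
                f"unknown gene {gene_id!r}; nearest ids: {', '.join(near) or 'none'}"
            ) from None

    def cds_intervals(self) -> dict[str, list[tuple[int, int]]]:
        """Merged, sorted CDS intervals per chromosome."""
        raw: dict[str, list[tuple[int, int]]] = {}
        for g in self.genes:
            raw.setdefault(g.chrom, []).extend(g.cds)
        merged: dict[str, list[tuple[int, int]]] = {}
        for chrom, ivs in raw.items():
            ivs.sort()
            out: list[list[int]] = []
            for s, e in ivs:
                if out and s <= out[-1][1]:
                    out[-1][1] = max(out[-1][1], e)
                else:
                    out.append([s, e])
            merged[chrom] = [(s, e) for s, e in out]
        return merged

    # ------------------------------------------------------------------ GFF3

    def to_gff3(self, path: str | Path) -> None:
        lines = ["##gff-version 3"]
        for chrom, size in self.chrom_sizes.items():
            lines.append(f"##sequence-region {chrom} 1 {size}")
        for g in self.genes:
            flag = "true" if g.shared_isoform else "false"

            def row(ftype: str, s: int, e: int, attrs: str) -> str:
                return "\t".join(
                    [g.chrom, "cpsa", ftype, str(s + 1), str(e), ".", g.strand, ".", attrs]
                )

            lines.append(
                row(
                    "gene",
                    g.start,
                    g.end,
                    f"ID={g.gene_id};shared_isoform={flag};css={g.css}",
                )
            )
            mrna = f"{g.gene_id}.1"
            lines.append(row("mRNA", g.start, g.end, f"ID={mrna};Parent={g.gene_id}"))
            for i, (s, e) in enumerate(sorted(g.exons), 1):
                lines.append(row("exon", s, e, f"ID={mrna}.exon{i};Parent={mrna}"))
            for i, (s, e) in enumerate(sorted(g.cds), 1):
                lines.append(row("CDS", s, e, f"ID={mrna}.cds{i};Parent={mrna}"))
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_gff3(cls, path: str | Path) -> "Annotation":
        chrom_sizes: dict[str, int] = {}
        for line in Path(path).read_text().splitlines():
            if line.startswith("##sequence-region"):
                _, chrom, _one, size = line.split()
                chrom_sizes[chrom] = int(size)
        db = gffutils.create_db(
            str(path), ":memory:", merge_strategy="create_unique", keep_order=True
        )
        genes = []
        for f in db.features_of_type("gene", order_by=("seqid", "start")):
            exons, cds = [], []
            for child in db.children(f, featuretype="exon"):
                exons.append((child.start - 1, child.end))
            for child in db.children(f, featuretype="CDS"):
                cds.append((child.start - 1, child.end))
            shared = f.attributes.get("shared_isoform", ["true"])[0] == "true"
            css_attr = f.attributes.get("css", [None])[0]
            if css_attr is not None:
                css = int(css_attr)
            elif cds:
                css = min(s for s, _ in cds) if f.strand == "+" else max(e for _, e in cds) - 1
            else:
                css = f.start - 1
            genes.append(
                GeneModel(
                    gene_id=f.id,
                    chrom=f.seqid,
                    strand=f.strand,
                    start=f.start - 1,
                    end=f.end,
                    css=css,
                    exons=tuple(sorted(exons)),
                    cds=tuple(sorted(cds)),
                    shared_isoform=shared,
                )
            )
        return cls(chrom_sizes, genes)
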