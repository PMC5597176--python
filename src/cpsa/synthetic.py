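"""Synthetic MNase-digestion landscapes with planted ground truth.

Generates toy genomes, plants a chromatin landscape per gene (a phased
nucleosome array downstream of the TSS, a digestion-labile -1 nucleosome
upstream, and a sub-nucleosomal TF footprint in the 5' region), draws
digestion-dependent paired-end fragment sets, and emits expression /
differential-expression tables whose condition fold change is coupled to
the planted subNSP occupancy change.  Every planted quantity is recorded
in a truth table so downstream analyses can be validated against it.

The default experiment mirrors a 2 conditions x 2 digestion levels x 2
replicates design (8 samples).

Model sketch
------------
Each particle template survives a digestion with probability equal to its
occupancy for the sample's (condition, digestion) pair.  The landscape is
digested in ``R`` independent rounds so that the expected fragment yield
matches the requested depth; per template the fragment count is therefore
Binomial(R, occupancy).  Within a gene's nucleosome array, runs of
adjacent survivors remain joined into one multi-nucleosomal fragment with
per-junction probability ``p_link`` (lower digestion keeps more junctions),
giving lengths ~ N*150 + (N-1)*30.  Fragment boundaries receive independent
rounded-Gaussian jitter; naked-DNA background fragments are added at a
uniform rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .annotation import Annotation, GeneModel
from .fragments import FragmentSet

__all__ = [
    "ToyGenomeSpec",
    "LandscapeParams",
    "ParticleTemplate",
    "DigestionSetting",
    "SampleSpec",
    "ExpressionCoupling",
    "SyntheticLandscape",
    "build_toy_genome",
    "plant_landscape",
    "sample_fragments",
    "simulate_expression",
    "default_samples",
    "write_experiment",
]

CONDITIONS = ("light", "dark")
DIGESTIONS = ("low", "high")


# ------------------------------------------------------------------- genome


@dataclass(frozen=True)
class ToyGenomeSpec:
    """Layout of a small annotated genome used for simulation."""

    chrom_lengths: tuple[tuple[str, int], ...] = (("chr1", 200_000),)
    n_genes: int = 30
    gene_length: int = 3_000
    intergenic_spacing: int = 2_500
    utr5: int = 300
    utr3: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.gene_length <= 0 or self.intergenic_spacing < 0:
            raise ValueError("invalid genome spec")
        for name, ln in self.chrom_lengths:
            if ln <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")


def build_toy_genome(spec: ToyGenomeSpec) -> Annotation:
    """Place non-overlapping genes with alternating strands.

    Deterministic for a given spec; raises a sizing error naming the first
    chromosome that cannot hold its share of genes.
    """
    genes: list[GeneModel] = []
    idx = 0
    chrom_iter = iter(spec.chrom_lengths)
    chrom, clen = next(chrom_iter)
    cursor = spec.intergenic_spacing
    while idx < spec.n_genes:
        if cursor + spec.gene_length + spec.intergenic_spacing > clen:
            nxt = next(chrom_iter, None)
            if nxt is None:
                raise ValueError(
                    f"genes do not fit: {spec.n_genes - idx} genes left over after "
                    f"filling chromosome {chrom}"
                )
            chrom, clen = nxt
            cursor = spec.intergenic_spacing
            continue
        start, end = cursor, cursor + spec.gene_length
        strand = "+" if idx % 2 == 0 else "-"
        # two-exon transcript with a short central intron
        e1 = int(spec.gene_length * 0.4)
        intron = min(300, max(50, int(spec.gene_length * 0.1)))
        exons = ((start, start + e1), (start + e1 + intron, end))
        if strand == "+":
            css = start + spec.utr5
            cds_end = end - spec.utr3
            cds = _clip_intervals(exons, css, cds_end)
        else:
            css = end - 1 - spec.utr5
            cds_start = start + spec.utr3
            cds = _clip_intervals(exons, cds_start, css + 1)
        genes.append(
            GeneModel(
                gene_id=f"g{idx + 1:04d}",
                chrom=chrom,
                strand=strand,
                start=start,
                end=end,
                css=css,
                exons=exons,
                cds=tuple(cds),
                shared_isoform=(idx % 7 != 3),
            )
        )
        cursor = end + spec.intergenic_spacing
        idx += 1
    return Annotation(dict(spec.chrom_lengths), genes)


def _clip_intervals(
    ivs: Sequence[tuple[int, int]], lo: int, hi: int
) -> list[tuple[int, int]]:
    out = []
    for s, e in ivs:
        s2, e2 = max(s, lo), min(e, hi)
        if e2 > s2:
            out.append((s2, e2))
    return out


# ---------------------------------------------------------------- landscape


@dataclass
class ParticleTemplate:
    """One plantable DNA-bound particle.

    ``occupancy`` maps (condition, digestion) to survival probability.  For
    subNSP templates, ``conc`` is the probability a bound footprint sits at
    the template center (vs. scattered uniformly within ``scatter`` bp),
    modelling how focal the recruitment is.
    """

    kind: str  # 'nucleosome' | 'subNSP'
    chrom: str
    center: int
    width: int
    occupancy: dict[tuple[str, str], float]
    labile: bool = False
    role: str = ""  # 'minus1' | 'array' | 'intergenic' | 'tss_footprint'
    gene_id: str = ""
    conc: float = 1.0
    scatter: int = 0

    def __post_init__(self) -> None:
        for key, p in self.occupancy.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"occupancy {p} for {key} outside [0,1]")
        if self.labile:
            for cond in CONDITIONS:
                if (cond, "low") in self.occupancy and (cond, "high") in self.occupancy:
                    lo = self.occupancy[(cond, "low")]
                    hi = self.occupancy[(cond, "high")]
                    if not (hi < lo or hi == lo == 0.0):
                        raise ValueError("labile template must lose occupancy at high digest")
        if self.kind == "subNSP":
            for cond in CONDITIONS:
                if (cond, "low") in self.occupancy and (cond, "high") in self.occupancy:
                    if self.occupancy[(cond, "high")] > self.occupancy[(cond, "low")]:
                        raise ValueError("subNSP occupancy may not rise with digestion")


@dataclass(frozen=True)
class DigestionSetting:
    """Digestion-level-dependent fragmentation parameters."""

    level: str  # 'low' | 'high'
    p_link: float
    boundary_jitter_sd: float = 8.0
    background_rate: float = 2.0  # expected naked-DNA fragments per kb per sample
    background_length_range: tuple[int, int] = (40, 400)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_link <= 1.0:
            raise ValueError("p_link outside [0,1]")
        if self.level not in DIGESTIONS:
            raise ValueError(f"unknown digestion level {self.level!r}")


DEFAULT_DIGESTIONS = {
    "low": DigestionSetting("low", p_link=0.55, background_rate=2.0),
    "high": DigestionSetting("high", p_link=0.10, background_rate=5.0),
}


@dataclass(frozen=True)
class SampleSpec:
    """One biological replicate.

    ``occupancy_noise_sd`` models replicate-to-replicate variability: each
    gene's template occupancies are raised to a per-(sample, gene) power
    ``f ~ lognormal(0, sd)``, which perturbs survival probabilities while
    keeping them in [0, 1].
    """

    sample_id: str
    condition: str
    digestion: DigestionSetting
    depth: int = 50_000
    seed: int = 0
    replicate: int = 1
    occupancy_noise_sd: float = 0.25
    size_selection: tuple[int, int] = (20, 1000)  # gel excision window

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if self.occupancy_noise_sd < 0:
            raise ValueError("occupancy_noise_sd must be >= 0")


def default_samples(
    depth: int = 50_000,
    digestions: dict[str, DigestionSetting] | None = None,
    base_seed: int = 100,
) -> list[SampleSpec]:
    """The 8-sample default design: 2 conditions x 2 digestions x 2 reps."""
    digestions = digestions or DEFAULT_DIGESTIONS
    out = []
    i = 0
    for cond in CONDITIONS:
        for dig in DIGESTIONS:
            for rep in (1, 2):
                out.append(
                    SampleSpec(
                        sample_id=f"{cond}_{dig}_{rep}",
                        condition=cond,
                        digestion=digestions[dig],
                        depth=depth,
                        seed=base_seed + i,
                        replicate=rep,
                    )
                )
                i += 1
    return out


@dataclass
class LandscapeParams:
    """Planted per-gene chromatin architecture.

    Distances are strand-oriented base pairs relative to the TSS (positive
    downstream).  ``minus1_occ`` encodes the digestion-labile upstream
    nucleosome; the stable genic array keeps the same occupancy at both
    digestion levels.  ``subnsp_high_factor`` scales footprint survival
    under heavy digestion (labile small particles).  A fraction of genes is
    light-responsive: their footprint occupancy in dark is divided by
    2**delta with per-gene delta ~ Normal(0, response_log2fc_sd).
    """

    nuc_width: int = 150
    period: int = 180
    plus1_offset: int = 100
    array_n: int = 6
    minus1_offset: int = -100
    stable_occ_range: tuple[float, float] = (0.55, 0.95)
    minus1_occ: dict[str, float] = field(default_factory=lambda: {"low": 0.8, "high": 0.3})
    subnsp_offset: int = -60
    subnsp_width_range: tuple[int, int] = (30, 110)
    subnsp_occ_low: float = 0.65
    subnsp_high_factor: float = 0.35
    conc_range: tuple[float, float] = (0.15, 0.9)
    subnsp_scatter: int = 120
    responsive_fraction: float = 0.5
    response_log2fc_sd: float = 1.5
    subnsp_dark_factor: float | None = None  # hard occlusion: occ(dark) = factor * occ(light)
    intergenic_spacing: int = 600
    intergenic_occ: float = 0.40
    couple_array_to_conc: bool = True


@dataclass
class SyntheticLandscape:
    """Planted particles plus per-gene truth for downstream validation."""

    annotation: Annotation
    params: LandscapeParams
    templates: list[ParticleTemplate]
    arrays: list[list[int]]  # template indices forming linkable runs
    truth: pd.DataFrame
    seed: int

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return self.annotation.chrom_sizes


def plant_landscape(
    annotation: Annotation, params: LandscapeParams | None = None, seed: int = 0
) -> SyntheticLandscape:
    """Plant nucleosome arrays, labile -1 nucleosomes and TSS footprints."""
    if len(annotation.genes) == 0:
        raise ValueError("annotation has no genes")
    params = params or LandscapeParams()
    rng = np.random.default_rng(seed)
    templates: list[ParticleTemplate] = []
    arrays: list[list[int]] = []
    truth_rows = []

    all_pairs = [(c, d) for c in CONDITIONS for d in DIGESTIONS]
    for gi, g in enumerate(annotation.genes):
        sgn = 1 if g.strand == "+" else -1
        tss = g.tss
        conc = float(rng.uniform(*params.conc_range))
        responsive = bool(rng.random() < params.responsive_fraction)
        delta = float(rng.normal(0.0, params.response_log2fc_sd)) if responsive else 0.0
        # footprint occupancy per condition/digestion (light is reference)
        occ_light_low = params.subnsp_occ_low
        if params.subnsp_dark_factor is not None:
            occ_dark_low = occ_light_low * params.subnsp_dark_factor
        else:
            occ_dark_low = float(np.clip(occ_light_low * 2.0 ** (-delta), 0.0, 1.0))
        sub_occ = {
            ("light", "low"): occ_light_low,
            ("light", "high"): occ_light_low * params.subnsp_high_factor,
            ("dark", "low"): occ_dark_low,
            ("dark", "high"): occ_dark_low * params.subnsp_high_factor,
        }
        # realized (clipped) planted footprint fold change, light vs dark
        planted_sub_log2fc = float(
            np.log2((sub_occ[("light", "low")] + 1e-12) / (sub_occ[("dark", "low")] + 1e-12))
        )
        stable = float(rng.uniform(*params.stable_occ_range))
        if params.couple_array_to_conc:
            stable = float(np.clip(0.45 + 0.5 * conc, 0.0, 1.0))
        sub_width = int(rng.integers(params.subnsp_width_range[0], params.subnsp_width_range[1] + 1))

        arr_idx: list[int] = []
        # labile -1 nucleosome
        m1_center = tss + sgn * params.minus1_offset
        templates.append(
            ParticleTemplate(
                kind="nucleosome",
                chrom=g.chrom,
                center=m1_center,
                width=params.nuc_width,
                occupancy={(c, d): params.minus1_occ[d] for c, d in all_pairs},
                labile=True,
                role="minus1",
                gene_id=g.gene_id,
            )
        )
        arr_idx.append(len(templates) - 1)
        # stable +1 .. +N array
        dyads = [tss + sgn * (params.plus1_offset + k * params.period) for k in range(params.array_n)]
        for k, dy in enumerate(dyads):
            templates.append(
                ParticleTemplate(
                    kind="nucleosome",
                    chrom=g.chrom,
                    center=dy,
                    width=params.nuc_width,
                    occupancy={(c, d): stable for c, d in all_pairs},
                    role="array",
                    gene_id=g.gene_id,
                )
            )
            arr_idx.append(len(templates) - 1)
        if sgn < 0:
            arr_idx = arr_idx[::-1]  # keep arrays in genomic order for linkage
        arrays.append(arr_idx)
        # TSS-proximal subNSP footprint
        sub_center = tss + sgn * params.subnsp_offset
        templates.append(
            ParticleTemplate(
                kind="subNSP",
                chrom=g.chrom,
                center=sub_center,
                width=sub_width,
                occupancy=sub_occ,
                role="tss_footprint",
                gene_id=g.gene_id,
                conc=conc,
                scatter=params.subnsp_scatter,
            )
        )
        truth_rows.append(
            {
                "gene_id": g.gene_id,
                "chrom": g.chrom,
                "strand": g.strand,
                "tss": tss,
                "subnsp_center": sub_center,
                "subnsp_width": sub_width,
                "conc": conc,
                "responsive": responsive,
                "subnsp_log2fc": planted_sub_log2fc,
                "stable_occ": stable,
                "plus1_dyad": dyads[0],
                "minus1_center": m1_center,
                "occ_light_low": sub_occ[("light", "low")],
                "occ_dark_low": sub_occ[("dark", "low")],
            }
        )

    # sparse background nucleosomes in intergenic space (non-linkable)
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in annotation.chrom_sizes}
    for g in annotation.genes:
        pad = params.plus1_offset + params.array_n * params.period + params.nuc_width
        occupied[g.chrom].append((g.start - pad, g.end + pad))
    for chrom, size in annotation.chrom_sizes.items():
        ivs = sorted(occupied[chrom])
        pos = params.nuc_width
        while pos < size - params.nuc_width:
            if not any(s <= pos < e for s, e in ivs):
                templates.append(
                    ParticleTemplate(
                        kind="nucleosome",
                        chrom=chrom,
                        center=pos,
                        width=params.nuc_width,
                        occupancy={(c, d): params.intergenic_occ for c, d in all_pairs},
                        role="intergenic",
                    )
                )
            pos += params.intergenic_spacing

    return SyntheticLandscape(
        annotation=annotation,
        params=params,
        templates=templates,
        arrays=arrays,
        truth=pd.DataFrame(truth_rows),
        seed=seed,
    )


# ---------------------------------------------------------------- fragments


def _expected_yield_per_round(
    landscape: SyntheticLandscape, key: tuple[str, str], p_link: float
) -> float:
    """Expected fragments per digestion round, net of junction merging.

    Each merged junction (both neighbours survive and stay linked) removes
    one fragment from the survivor count.
    """
    total = float(sum(t.occupancy.get(key, 0.0) for t in landscape.templates))
    for arr in landscape.arrays:
        occ = [landscape.templates[i].occupancy.get(key, 0.0) for i in arr]
        total -= p_link * sum(a * b for a, b in zip(occ, occ[1:]))
    return total


def sample_fragments(landscape: SyntheticLandscape, sample: SampleSpec) -> FragmentSet:
    """Draw one sample's paired-end fragment set from the landscape.

    Deterministic for a given (landscape seed, sample seed).  Zero depth
    yields an empty set.
    """
    key = (sample.condition, sample.digestion.level)
    rng = np.random.default_rng([landscape.seed, sample.seed])
    per_round = _expected_yield_per_round(landscape, key, sample.digestion.p_link)
    if sample.depth == 0 or per_round == 0:
        rounds = 0
    else:
        rounds = max(1, int(round(sample.depth / per_round)))
    jitter_sd = sample.digestion.boundary_jitter_sd
    p_link = sample.digestion.p_link

    occ_eff = np.array([t.occupancy.get(key, 0.0) for t in landscape.templates])
    if sample.occupancy_noise_sd > 0 and rounds > 0:
        # biological replicate noise: one factor per gene, one per solo template
        per_t = np.exp(rng.normal(0.0, sample.occupancy_noise_sd, len(occ_eff)))
        gene_ids = [g.gene_id for g in landscape.annotation.genes]
        gene_f = dict(
            zip(gene_ids, np.exp(rng.normal(0.0, sample.occupancy_noise_sd, len(gene_ids))))
        )
        for i, t in enumerate(landscape.templates):
            if t.gene_id:
                per_t[i] = gene_f[t.gene_id]
        occ_eff = occ_eff**per_t

    chroms: list[np.ndarray] = []
    starts: list[np.ndarray] = []
    ends: list[np.ndarray] = []
    chrom_names = list(landscape.chrom_sizes)
    chrom_code = {c: i for i, c in enumerate(chrom_names)}

    in_array = set()
    for arr in landscape.arrays:
        in_array.update(arr)

    def emit(chrom: str, s: np.ndarray, e: np.ndarray) -> None:
        if len(s) == 0:
            return
        if jitter_sd > 0:
            s = s + np.rint(rng.normal(0.0, jitter_sd, len(s))).astype(np.int64)
            e = e + np.rint(rng.normal(0.0, jitter_sd, len(e))).astype(np.int64)
        size = landscape.chrom_sizes[chrom]
        s = np.clip(s, 0, size - 1)
        e = np.clip(e, 1, size)
        e = np.maximum(e, s + 1)
        chroms.append(np.full(len(s), chrom_code[chrom], dtype=np.int32))
        starts.append(s.astype(np.int64))
        ends.append(e.astype(np.int64))

    if rounds > 0:
        # linkable nucleosome arrays: joint survival + junction linkage
        for arr in landscape.arrays:
            tmpl = [landscape.templates[i] for i in arr]
            K = len(tmpl)
            occ = occ_eff[arr]
            centers = np.array([t.center for t in tmpl])
            half = np.array([t.width // 2 for t in tmpl])
            S = rng.random((rounds, K)) < occ
            if K > 1:
                J = S[:, :-1] & S[:, 1:] & (rng.random((rounds, K - 1)) < p_link)
            else:
                J = np.zeros((rounds, 0), dtype=bool)
            startm = S & ~np.pad(J, ((0, 0), (1, 0)))
            endm = S & ~np.pad(J, ((0, 0), (0, 1)))
            rs, ks = np.nonzero(startm)
            re_, ke = np.nonzero(endm)
            # row-major order pairs i-th start with i-th end (runs do not nest)
            assert len(ks) == len(ke)
            emit(tmpl[0].chrom, centers[ks] - half[ks], centers[ke] + half[ke])
        # solo templates: subNSP footprints and intergenic nucleosomes
        for ti, t in enumerate(landscape.templates):
            if ti in in_array:
                continue
            n = int(rng.binomial(rounds, occ_eff[ti]))
            if n == 0:
                continue
            if t.kind == "subNSP" and t.scatter > 0:
                focal = rng.random(n) < t.conc
                cen = np.where(
                    focal,
                    t.center,
                    rng.integers(t.center - t.scatter, t.center + t.scatter + 1, n),
                )
            else:
                cen = np.full(n, t.center)
            emit(t.chrom, cen - t.width // 2, cen - t.width // 2 + t.width)

        # naked-DNA background: uniform positions, broad length range
        lo, hi = sample.digestion.background_length_range
        for chrom, size in landscape.chrom_sizes.items():
            n_bg = int(rng.poisson(sample.digestion.background_rate * size / 1000.0))
            if n_bg == 0:
                continue
            ln = rng.integers(lo, hi + 1, n_bg)
            s = rng.integers(0, np.maximum(size - ln, 1))
            chroms.append(np.full(n_bg, chrom_code[chrom], dtype=np.int32))
            starts.append(s.astype(np.int64))
            ends.append((s + ln).astype(np.int64))

    if chroms:
        cc = np.concatenate(chroms)
        ss = np.concatenate(starts)
        ee = np.concatenate(ends)
    else:
        cc = np.zeros(0, dtype=np.int32)
        ss = np.zeros(0, dtype=np.int64)
        ee = np.zeros(0, dtype=np.int64)
    lo, hi = sample.size_selection
    keep = (ee - ss >= lo) & (ee - ss <= hi)
    cc, ss, ee = cc[keep], ss[keep], ee[keep]
    order = np.lexsort((ee, ss, cc))
    df = pd.DataFrame(
        {
            "chrom": pd.Series([chrom_names[i] for i in cc[order]], dtype=str),
            "start": ss[order],
            "end": ee[order],
        }
    )
    return FragmentSet(df, sample_id=sample.sample_id)


# --------------------------------------------------------------- expression


@dataclass(frozen=True)
class ExpressionCoupling:
    """Couples planted chromatin features to simulated RNA counts.

    ``link_coefficient`` ties a gene's expression log2 fold change (light
    vs dark) to its planted footprint occupancy log2FC; ``level_coefficient``
    ties baseline abundance to footprint focality (``conc``), producing the
    within-sample recruitment/expression association.
    """

    baseline_mean: float = 200.0
    dispersion: float = 0.05
    link_coefficient: float = 1.0
    level_coefficient: float = 3.0
    n_replicates: int = 4
    fc_noise_sd: float = 0.25
    level_noise_sd: float = 0.30

    def __post_init__(self) -> None:
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates per condition")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    if dispersion < 1e-8:
        return rng.poisson(mean)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def simulate_expression(
    landscape: SyntheticLandscape,
    coupling: ExpressionCoupling | None = None,
    seed: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate per-replicate counts plus a differential-expression table.

    Returns ``(counts, de_table, truth)``.  The DE table is deliberately
    simple plumbing: a Welch t-test on log2(count+1) with Benjamini-
    Hochberg adjustment, standing in for an upstream count-model pipeline.
    """
    coupling = coupling or ExpressionCoupling()
    rng = np.random.default_rng([landscape.seed, seed, 77])
    truth = landscape.truth
    n_genes = len(truth)
    conc = truth["conc"].to_numpy()
    planted_sub_fc = truth["subnsp_log2fc"].to_numpy()

    level = coupling.level_coefficient * (conc - conc.mean()) + rng.normal(
        0.0, coupling.level_noise_sd, n_genes
    )
    base_mean = coupling.baseline_mean * 2.0 ** level
    expr_fc = coupling.link_coefficient * planted_sub_fc + rng.normal(
        0.0, coupling.fc_noise_sd, n_genes
    )
    mean_light = base_mean * 2.0 ** (expr_fc / 2.0)
    mean_dark = base_mean * 2.0 ** (-expr_fc / 2.0)

    r = coupling.n_replicates
    cols = {}
    for i in range(r):
        cols[f"light_{i + 1}"] = _nb_draw(rng, mean_light, coupling.dispersion)
    for i in range(r):
        cols[f"dark_{i + 1}"] = _nb_draw(rng, mean_dark, coupling.dispersion)
    counts = pd.DataFrame({"gene_id": truth["gene_id"], **cols})
    counts["shared_isoform"] = [
        landscape.annotation.get_gene(g).shared_isoform for g in counts["gene_id"]
    ]

    light = counts[[f"light_{i + 1}" for i in range(r)]].to_numpy(float)
    dark = counts[[f"dark_{i + 1}" for i in range(r)]].to_numpy(float)
    log2fc = np.log2((light.mean(axis=1) + 0.5) / (dark.mean(axis=1) + 0.5))
    t, p = stats.ttest_ind(
        np.log2(light + 1.0), np.log2(dark + 1.0), axis=1, equal_var=False
    )
    p = np.where(np.isnan(p), 1.0, p)
    from statsmodels.stats.multitest import multipletests

    fdr = multipletests(p, method="fdr_bh")[1]
    de = pd.DataFrame(
        {"gene_id": truth["gene_id"], "log2FC": log2fc, "p": p, "FDR": fdr}
    )
    truth_out = truth.assign(expr_log2fc_planted=expr_fc, base_mean=base_mean)
    return counts, de, truth_out


# ------------------------------------------------------------ orchestration


def write_experiment(
    outdir: str | Path,
    genome: ToyGenomeSpec | None = None,
    params: LandscapeParams | None = None,
    samples: Sequence[SampleSpec] | None = None,
    coupling: ExpressionCoupling | None = None,
    seed: int = 0,
) -> dict:
    """Generate and write the full default experiment to ``outdir``.

    Emits per-sample fragment BEDs, the GFF3 annotation, expression / DE /
    truth tables, and a run manifest echoing every parameter and seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = genome or ToyGenomeSpec(seed=seed)
    params = params or LandscapeParams()
    samples = list(samples) if samples is not None else default_samples(base_seed=seed + 100)
    coupling = coupling or ExpressionCoupling()

    ann = build_toy_genome(genome)
    ann.to_gff3(outdir / "annotation.gff3")
    landscape = plant_landscape(ann, params, seed=seed)
    sample_rows = []
    for sp in samples:
        frags = sample_fragments(landscape, sp)
        frags.to_bed(outdir / f"{sp.sample_id}.bed")
        sample_rows.append(
            {
                "sample_id": sp.sample_id,
                "condition": sp.condition,
                "digestion": sp.digestion.level,
                "replicate": sp.replicate,
                "depth": sp.depth,
                "seed": sp.seed,
                "n_fragments": len(frags),
                "path": f"{sp.sample_id}.bed",
            }
        )
    sheet = pd.DataFrame(sample_rows)
    sheet.to_csv(outdir / "samples.tsv", sep="\t", index=False)
    counts, de, truth = simulate_expression(landscape, coupling, seed=seed + 1)
    counts.to_csv(outdir / "expression.tsv", sep="\t", index=False)
    de.to_csv(outdir / "de.tsv", sep="\t", index=False)
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    manifest = {
        "seed": seed,
        "genome": {
            "chrom_lengths": [list(x) for x in genome.chrom_lengths],
            "n_genes": genome.n_genes,
            "gene_length": genome.gene_length,
            "intergenic_spacing": genome.intergenic_spacing,
            "seed": genome.seed,
        },
        "landscape": {k: v for k, v in vars(params).items()},
        "coupling": {k: v for k, v in vars(coupling).items()} if coupling else {},
        "samples": sample_rows,
    }
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(_plain(manifest), fh, sort_keys=True)
    return manifest


def _plain(obj):
    """Recursively convert numpy scalars/containers for YAML emission."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj
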