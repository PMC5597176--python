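"""Linking chromatin structure to expression.

Covers expression-quartile profiling, kurtosis-based quantification of the
TSS subNSP peak, the per-gene subNSP abundance log2 fold change between
conditions, and the fold-change/fold-change association with a loess trend
and bootstrap confidence band.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .fragments import FragmentSet
from .profiles import Anchor

__all__ = [
    "quartiles_by_expression",
    "tss_subnsp_stats",
    "quartiles_by_kurtosis",
    "subnsp_log2fc",
    "fc_correlation",
    "LoessTrend",
]

QUARTILE_LABELS = ("Q1", "Q2", "Q3", "Q4")


def _assign_quartiles(gene_ids: Sequence[str], values: np.ndarray) -> pd.DataFrame:
    """Rank-based quartiles, ties broken by input (gene id) order.

    Q1 holds the lowest-ranked quarter.  Sizes are balanced to within 1.
    """
    n = len(gene_ids)
    order = np.argsort(values, kind="stable")  # stable => ties by input order
    chunks = np.array_split(order, 4)
    quart = np.empty(n, dtype=object)
    for lab, idx in zip(QUARTILE_LABELS, chunks):
        quart[idx] = lab
    return pd.DataFrame({"gene_id": list(gene_ids), "quartile": quart, "value": values})


def quartiles_by_expression(
    expression: pd.DataFrame, sample: str
) -> pd.DataFrame:
    """Split genes into quartiles of one sample's expression level.

    ``expression`` must carry ``gene_id`` plus per-sample columns.
    Deterministic: ties are broken by gene order.
    """
    if len(expression) < 4:
        raise ValueError("need >= 4 genes for quartiles")
    if sample not in expression.columns:
        raise ValueError(f"sample {sample!r} not in expression table")
    return _assign_quartiles(
        expression["gene_id"].tolist(), expression[sample].to_numpy(float)
    )


def excess_kurtosis(x: np.ndarray) -> float:
    """Fisher (excess) kurtosis, biased moment form: m4/m2^2 - 3."""
    return float(stats.kurtosis(x, fisher=True, bias=True))


def tss_subnsp_stats(
    subnsp: FragmentSet,
    anchors: Sequence[Anchor],
    window: tuple[int, int] = (-250, 50),
    min_fragments: int = 20,
) -> pd.DataFrame:
    """Per-gene subNSP midpoint count and peak kurtosis in the TSS window.

    Offsets are strand-oriented (positive downstream).  Genes with fewer
    than ``min_fragments`` midpoints are flagged ineligible; the moment
    estimate is too unstable below that and is never imputed.
    """
    mids = subnsp.midpoints
    chroms = subnsp.df["chrom"].to_numpy()
    lo, hi = window
    rows = []
    for a in anchors:
        m = mids[chroms == a.chrom]
        off = (m - a.pos) if a.strand == "+" else (a.pos - m)
        off = off[(off >= lo) & (off <= hi)]
        n = len(off)
        # a zero-variance offset set has no defined peak shape
        kurt = excess_kurtosis(off) if n >= 2 and np.ptp(off) > 0 else np.nan
        rows.append(
            {
                "gene_id": a.feature_id,
                "n_fragments": n,
                "kurtosis": kurt,
                "eligible": n >= min_fragments,
            }
        )
    return pd.DataFrame(rows)


def quartiles_by_kurtosis(
    results: pd.DataFrame,
    expression: pd.DataFrame | None = None,
    sample: str | None = None,
    statistic: str = "kurtosis",
) -> pd.DataFrame:
    """Quartile eligible genes by subNSP peak shape (or abundance).

    ``statistic`` may be 'kurtosis' (peak sharpness) or 'n_fragments'
    (recruitment abundance).  When an expression table and sample are
    given, the per-gene expression value is attached for grouped
    distribution plots.
    """
    if statistic not in ("kurtosis", "n_fragments"):
        raise ValueError(f"unknown quartiling statistic {statistic!r}")
    elig = results.loc[results["eligible"]].reset_index(drop=True)
    if len(elig) < 4:
        raise ValueError("need >= 4 eligible genes")
    out = _assign_quartiles(elig["gene_id"].tolist(), elig[statistic].to_numpy(float))
    if expression is not None and sample is not None:
        expr = expression.set_index("gene_id")[sample]
        out["expression"] = out["gene_id"].map(expr).to_numpy(float)
    return out


def subnsp_log2fc(
    frags_by_condition: Mapping[str, Sequence[FragmentSet]],
    totals_by_condition: Mapping[str, Sequence[int]],
    anchors: Sequence[Anchor],
    window: tuple[int, int] = (-250, 50),
    pseudocount: float = 1.0,
    conditions: tuple[str, str] = ("light", "dark"),
) -> pd.DataFrame:
    """Per-gene log2 fold change of TSS subNSP abundance between conditions.

    Replicates are pooled within each condition; counts are scaled to
    fragments-per-million of retained sequencing depth before the ratio.
    Swapping the two condition labels negates every value exactly.
    """
    c1, c2 = conditions
    for c in conditions:
        if c not in frags_by_condition or len(frags_by_condition[c]) == 0:
            raise ValueError(f"missing fragments for condition {c!r}")
    lo, hi = window

    def windowed_counts(cond: str) -> np.ndarray:
        counts = np.zeros(len(anchors))
        for fs in frags_by_condition[cond]:
            mids = fs.midpoints
            chroms = fs.df["chrom"].to_numpy()
            for i, a in enumerate(anchors):
                m = mids[chroms == a.chrom]
                off = (m - a.pos) if a.strand == "+" else (a.pos - m)
                counts[i] += ((off >= lo) & (off <= hi)).sum()
        return counts

    n1 = windowed_counts(c1)
    n2 = windowed_counts(c2)
    tot1 = float(sum(totals_by_condition[c1]))
    tot2 = float(sum(totals_by_condition[c2]))
    if tot1 <= 0 or tot2 <= 0:
        raise ValueError("non-positive retained totals")
    cpm1 = n1 / tot1 * 1e6
    cpm2 = n2 / tot2 * 1e6
    # difference of logs (not log of ratio): label swap negates bit-exactly
    fc = np.log2(cpm1 + pseudocount) - np.log2(cpm2 + pseudocount)
    return pd.DataFrame(
        {
            "gene_id": [a.feature_id for a in anchors],
            f"n_{c1}": n1,
            f"n_{c2}": n2,
            "subnsp_log2fc": fc,
        }
    )


@dataclass
class LoessTrend:
    grid: np.ndarray
    fit: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    spearman_rho: float
    spearman_p: float
    spearman_rho_sig: float
    spearman_p_sig: float
    n_points: int
    n_sig: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"grid": self.grid, "fit": self.fit, "lo": self.lo, "hi": self.hi}
        )


def fc_correlation(
    points: pd.DataFrame,
    span: float = 0.5,
    n_boot: int = 500,
    grid_size: int = 50,
    ci: float = 0.95,
    seed: int = 0,
) -> LoessTrend:
    """Loess trend of expression log2FC against subNSP log2FC, with a
    bootstrap percentile confidence band and Spearman rank correlations.

    ``points`` needs columns ``subnsp_log2fc``, ``expression_log2fc`` and
    boolean ``significant`` (differential-expression FDR < 0.05).  The
    smoother is tricube-weighted local linear regression; the band is the
    percentile interval over ``n_boot`` case resamples.
    """
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    if len(points) < 20:
        raise ValueError("need >= 20 points")
    x = points["subnsp_log2fc"].to_numpy(float)
    y = points["expression_log2fc"].to_numpy(float)
    grid = np.linspace(x.min(), x.max(), grid_size)
    fit = lowess(y, x, frac=span, xvals=grid)
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, grid_size))
    for b in range(n_boot):
        idx = rng.integers(0, len(x), len(x))
        boots[b] = lowess(y[idx], x[idx], frac=span, xvals=grid)
    alpha = (1 - ci) / 2
    lo_band = np.nanquantile(boots, alpha, axis=0)
    hi_band = np.nanquantile(boots, 1 - alpha, axis=0)
    rho, p = stats.spearmanr(x, y)
    sig = points["significant"].to_numpy(bool)
    if sig.sum() >= 3:
        rho_s, p_s = stats.spearmanr(x[sig], y[sig])
    else:
        rho_s, p_s = np.nan, np.nan
    return LoessTrend(
        grid=grid,
        fit=fit,
        lo=lo_band,
        hi=hi_band,
        spearman_rho=float(rho),
        spearman_p=float(p),
        spearman_rho_sig=float(rho_s),
        spearman_p_sig=float(p_s),
        n_points=len(points),
        n_sig=int(sig.sum()),
    )
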