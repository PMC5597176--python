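"""Tests of the digestion simulator: geometry, determinism, fragment
statistics, and the expression coupling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cpsa.annotation import Annotation, GeneModel
from cpsa.synthetic import (
    DigestionSetting,
    ExpressionCoupling,
    LandscapeParams,
    SampleSpec,
    ToyGenomeSpec,
    build_toy_genome,
    default_samples,
    plant_landscape,
    sample_fragments,
    simulate_expression,
)


def one_gene_annotation(tss=10_000, strand="+", chrom_len=40_000):
    start, end = (tss, tss + 3000) if strand == "+" else (tss - 2999, tss + 1)
    g = GeneModel("gA", "chr1", strand, start, end,
                  css=start + 300 if strand == "+" else end - 301,
                  exons=((start, end),))
    return Annotation({"chr1": chrom_len}, [g])


# ------------------------------------------------------------------- genome


def test_toy_genome_layout():
    spec = ToyGenomeSpec((("chr1", 100_000),), n_genes=10, gene_length=3000,
                         intergenic_spacing=6000)
    ann = build_toy_genome(spec)
    assert len(ann) == 10
    strands = [g.strand for g in ann.genes]
    assert strands == ["+", "-"] * 5
    spans = sorted((g.start, g.end) for g in ann.genes)
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        assert e1 <= s2  # non-overlapping


def test_toy_genome_deterministic_gff3(tmp_path):
    spec = ToyGenomeSpec((("chr1", 100_000),), n_genes=10, seed=5)
    p1, p2 = tmp_path / "a.gff3", tmp_path / "b.gff3"
    build_toy_genome(spec).to_gff3(p1)
    build_toy_genome(spec).to_gff3(p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_toy_genome_sizing_error_names_chromosome():
    spec = ToyGenomeSpec((("chrZ", 10_000),), n_genes=10, gene_length=3000,
                         intergenic_spacing=6000)
    with pytest.raises(ValueError, match="chrZ"):
        build_toy_genome(spec)


# ---------------------------------------------------------------- landscape


def test_planted_array_dyads_plus_strand():
    ann = one_gene_annotation(tss=10_000, strand="+")
    ls = plant_landscape(ann, LandscapeParams(array_n=5), seed=0)
    dyads = [t.center for t in ls.templates if t.role == "array"]
    assert dyads == [10_100, 10_280, 10_460, 10_640, 10_820]


def test_planted_array_dyads_minus_strand_mirror():
    ann = one_gene_annotation(tss=10_000, strand="-")
    ls = plant_landscape(ann, LandscapeParams(array_n=3), seed=0)
    dyads = [t.center for t in ls.templates if t.role == "array"]
    assert dyads == [9_900, 9_720, 9_540]
    m1 = next(t for t in ls.templates if t.role == "minus1")
    assert m1.center == 10_100  # upstream of a - strand TSS is genomic-right


def test_labile_minus1_occupancy_drops_with_digestion(landscape):
    for t in landscape.templates:
        if t.role == "minus1":
            assert t.labile
            for cond in ("light", "dark"):
                assert t.occupancy[(cond, "high")] < t.occupancy[(cond, "low")]


def test_dark_occlusion_factor_zero(toy_annotation):
    ls = plant_landscape(
        toy_annotation, LandscapeParams(subnsp_dark_factor=0.0), seed=0
    )
    for t in ls.templates:
        if t.kind == "subNSP":
            assert t.occupancy[("dark", "low")] == 0.0
            assert t.occupancy[("light", "low")] > 0.0


# ---------------------------------------------------------------- fragments


def test_zero_occupancy_zero_background_yields_empty(toy_annotation):
    params = LandscapeParams(subnsp_occ_low=0.0, intergenic_occ=0.0,
                             stable_occ_range=(0.0, 0.0),
                             minus1_occ={"low": 0.0, "high": 0.0},
                             couple_array_to_conc=False)
    ls = plant_landscape(toy_annotation, params, seed=0)
    dig = DigestionSetting("low", p_link=0.5, background_rate=0.0)
    sp = SampleSpec("s", "light", dig, depth=10_000, seed=1)
    assert len(sample_fragments(ls, sp)) == 0


def test_zero_depth_yields_empty(landscape):
    sp = SampleSpec("s", "light", DigestionSetting("low", 0.5), depth=0, seed=1)
    assert len(sample_fragments(landscape, sp)) == 0


def test_single_nucleosome_deterministic_limit():
    ann = one_gene_annotation()
    params = LandscapeParams(array_n=1, subnsp_occ_low=0.0, intergenic_occ=0.0,
                             stable_occ_range=(1.0, 1.0),
                             minus1_occ={"low": 1.0, "high": 0.5},
                             couple_array_to_conc=False)
    ls = plant_landscape(ann, params, seed=0)
    dig = DigestionSetting("low", p_link=0.0, boundary_jitter_sd=0.0, background_rate=0.0)
    sp = SampleSpec("s", "light", dig, depth=500, seed=2, occupancy_noise_sd=0.0)
    fs = sample_fragments(ls, sp)
    assert len(fs) > 0
    lengths = fs.lengths
    assert (lengths == 150).all()
    mids = fs.midpoints
    assert set(mids) <= {10_100, 9_900}  # +1 dyad and -1 center


def test_full_linkage_gives_dinucleosomal_fragments():
    """Two adjacent nucleosomes, occupancy 1, p_link 1: every fragment
    spans both, length 2*150 + 30 = 330."""
    ann = one_gene_annotation()
    params = LandscapeParams(array_n=2, subnsp_occ_low=0.0, intergenic_occ=0.0,
                             stable_occ_range=(1.0, 1.0),
                             minus1_occ={"low": 1e-9, "high": 0.0},
                             couple_array_to_conc=False)
    ls = plant_landscape(ann, params, seed=0)
    dig = DigestionSetting("low", p_link=1.0, boundary_jitter_sd=0.0, background_rate=0.0)
    sp = SampleSpec("s", "light", dig, depth=300, seed=2, occupancy_noise_sd=0.0)
    lengths = sample_fragments(ls, sp).lengths
    assert len(lengths) > 100
    assert (lengths == 330).all()


@pytest.mark.parametrize("p_link", [0.0, 0.5, 1.0])
def test_linkage_counts_match_junction_enumeration(p_link):
    """Fragment-length counts for a 2-nucleosome array match the exact
    per-junction enumeration: P(merged) = p_link, else two monomers."""
    ann = one_gene_annotation()
    params = LandscapeParams(array_n=2, subnsp_occ_low=0.0, intergenic_occ=0.0,
                             stable_occ_range=(1.0, 1.0),
                             minus1_occ={"low": 1e-12, "high": 0.0},
                             couple_array_to_conc=False)
    ls = plant_landscape(ann, params, seed=0)
    dig = DigestionSetting("low", p_link=p_link, boundary_jitter_sd=0.0,
                           background_rate=0.0)
    sp = SampleSpec("s", "light", dig, depth=4000, seed=9, occupancy_noise_sd=0.0)
    fs = sample_fragments(ls, sp)
    lengths = fs.lengths
    n330 = int((lengths == 330).sum())
    n150 = int((lengths == 150).sum())
    rounds = n330 + n150 // 2  # each round yields one 330 or two 150s
    assert rounds > 500
    # enumeration oracle: merged ~ Binomial(rounds, p_link)
    exp = rounds * p_link
    sd = np.sqrt(rounds * p_link * (1 - p_link))
    assert abs(n330 - exp) <= 4 * sd + 1e-9


def test_per_template_counts_within_binomial_bounds():
    """With p_link 0 each template yields Binomial(R, occupancy) fragments."""
    ann = one_gene_annotation()
    params = LandscapeParams(array_n=4, subnsp_occ_low=0.4, intergenic_occ=0.0,
                             stable_occ_range=(0.7, 0.7), conc_range=(1.0, 1.0),
                             couple_array_to_conc=False)
    ls = plant_landscape(ann, params, seed=0)
    dig = DigestionSetting("low", p_link=0.0, boundary_jitter_sd=0.0, background_rate=0.0)
    per_round = sum(t.occupancy[("light", "low")] for t in ls.templates)
    depth = int(per_round * 1500)  # R ~ 1500 rounds
    sp = SampleSpec("s", "light", dig, depth=depth, seed=4, occupancy_noise_sd=0.0)
    fs = sample_fragments(ls, sp)
    rounds = round(depth / per_round)
    mids = fs.midpoints
    for t in ls.templates:
        occ = t.occupancy[("light", "low")]
        n = int((mids == t.center).sum())
        sd = np.sqrt(rounds * occ * (1 - occ))
        assert abs(n - rounds * occ) <= 4 * sd


def test_size_mixture_mononucleosomal_band(toy_annotation):
    """p_link 0, jitter sd 5: >= 99% of nucleosomal fragments in [120, 180]."""
    params = LandscapeParams(subnsp_occ_low=0.0)
    ls = plant_landscape(toy_annotation, params, seed=2)
    dig = DigestionSetting("low", p_link=0.0, boundary_jitter_sd=5.0, background_rate=0.0)
    sp = SampleSpec("s", "light", dig, depth=30_000, seed=8)
    lengths = sample_fragments(ls, sp).lengths
    assert len(lengths) > 10_000
    frac = ((lengths >= 120) & (lengths <= 180)).mean()
    assert frac >= 0.99


def test_fragment_sampling_deterministic(landscape):
    sp = SampleSpec("s", "dark", DigestionSetting("high", 0.1), depth=5_000, seed=11)
    a = sample_fragments(landscape, sp)
    b = sample_fragments(landscape, sp)
    pd.testing.assert_frame_equal(a.df, b.df)


def test_fragments_sorted_bed_convention(light_low_fragments):
    df = light_low_fragments.df
    assert (df["end"] > df["start"]).all()
    assert df.sort_values(["chrom", "start", "end"]).equals(df)


# --------------------------------------------------------------- expression


def test_expression_recovers_planted_eightfold_change(toy_annotation):
    """Planted 8x expression change at near-zero dispersion: estimated
    log2FC converges to 3."""
    ls = plant_landscape(toy_annotation, seed=0)
    ls.truth["subnsp_log2fc"] = 3.0  # planted contrast, light over dark
    coupling = ExpressionCoupling(dispersion=1e-6, link_coefficient=1.0,
                                  fc_noise_sd=0.0, level_coefficient=0.0,
                                  level_noise_sd=0.0, n_replicates=4,
                                  baseline_mean=5000.0)
    counts, de, truth = simulate_expression(ls, coupling, seed=1)
    assert truth["expr_log2fc_planted"].eq(3.0).all()
    assert np.allclose(de["log2FC"], 3.0, atol=0.05)
    assert (de["FDR"] < 0.05).all()


def test_null_coupling_controls_false_positives(toy_annotation):
    spec = ToyGenomeSpec((("chr1", 900_000),), n_genes=200, gene_length=2000,
                         intergenic_spacing=2000)
    ann = build_toy_genome(spec)
    ls = plant_landscape(ann, LandscapeParams(responsive_fraction=0.0), seed=3)
    coupling = ExpressionCoupling(link_coefficient=0.0, level_coefficient=0.0)
    counts, de, truth = simulate_expression(ls, coupling, seed=2)
    assert truth["subnsp_log2fc"].abs().max() == 0.0
    assert (de["FDR"] < 0.05).mean() <= 0.05


def test_de_fdr_matches_hand_computed_benjamini_hochberg(toy_annotation):
    ls = plant_landscape(toy_annotation, seed=0)
    _, de, _ = simulate_expression(ls, ExpressionCoupling(), seed=5)
    p = de["p"].to_numpy()
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    # step-up: running minimum from the largest rank
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    expected = np.empty(n)
    expected[order] = np.minimum(adj, 1.0)
    assert np.allclose(de["FDR"].to_numpy(), expected, atol=1e-12)


def test_expression_coupling_positive_association():
    """Planted footprint fold changes drive realized expression fold
    changes (Spearman > 0, p < 0.01, 200 genes)."""
    spec = ToyGenomeSpec((("chr1", 900_000),), n_genes=200, gene_length=2000,
                         intergenic_spacing=2000)
    ann = build_toy_genome(spec)
    ls = plant_landscape(ann, seed=4)
    _, de, truth = simulate_expression(ls, ExpressionCoupling(), seed=6)
    rho, p = stats.spearmanr(truth["subnsp_log2fc"], de["log2FC"])
    assert rho > 0 and p < 0.01


def test_too_few_replicates_rejected():
    with pytest.raises(ValueError, match="replicates"):
        ExpressionCoupling(n_replicates=1)


def test_default_experiment_is_two_by_two_by_two():
    samples = default_samples()
    assert len(samples) == 8
    key = {(s.condition, s.digestion.level, s.replicate) for s in samples}
    assert len(key) == 8
    assert {s.condition for s in samples} == {"light", "dark"}
    assert {s.digestion.level for s in samples} == {"low", "high"}
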