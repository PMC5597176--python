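import numpy as np
import pytest

from cpsa.annotation import Annotation, GeneModel
from cpsa.fragments import SizeClassScheme
from cpsa.synthetic import (
    DigestionSetting,
    LandscapeParams,
    SampleSpec,
    ToyGenomeSpec,
    build_toy_genome,
    plant_landscape,
    sample_fragments,
)


@pytest.fixture(scope="session")
def scheme():
    return SizeClassScheme()


@pytest.fixture(scope="session")
def toy_annotation():
    spec = ToyGenomeSpec(
        chrom_lengths=(("chr1", 100_000),),
        n_genes=10,
        gene_length=3_000,
        intergenic_spacing=3_000,
        seed=0,
    )
    return build_toy_genome(spec)


@pytest.fixture(scope="session")
def landscape(toy_annotation):
    return plant_landscape(toy_annotation, LandscapeParams(), seed=1)


@pytest.fixture(scope="session")
def light_low_fragments(landscape):
    sp = SampleSpec(
        "light_low_1", "light", DigestionSetting("low", p_link=0.55), depth=50_000, seed=3
    )
    return sample_fragments(landscape, sp)


@pytest.fixture
def single_gene_annotation():
    """One + strand gene with TSS at 10,000 on a 40 kb chromosome."""
    g = GeneModel(
        gene_id="gA",
        chrom="chr1",
        strand="+",
        start=10_000,
        end=13_000,
        css=10_300,
        exons=((10_000, 11_200), (11_500, 13_000)),
        cds=((10_300, 11_200), (11_500, 12_800)),
    )
    return Annotation({"chr1": 40_000}, [g])


def random_fragments(rng, n, chrom_sizes, lo=20, hi=1000):
    """Random retained fragments over the given chromosomes (helper)."""
    import pandas as pd

    from cpsa.fragments import FragmentSet

    chroms = rng.choice(list(chrom_sizes), n)
    lengths = rng.integers(lo, hi + 1, n)
    starts = np.array(
        [rng.integers(0, chrom_sizes[c] - L) for c, L in zip(chroms, lengths)]
    )
    df = pd.DataFrame(
        {"chrom": chroms.astype(str), "start": starts, "end": starts + lengths}
    ).sort_values(["chrom", "start", "end"]).reset_index(drop=True)
    return FragmentSet(df, sample_id="random")
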