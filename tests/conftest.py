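import pytest

from cilioprio.simulate import ScrnaSimConfig, gen_scrna_counts
from cilioprio.variants import (
    AnnotatedVariant,
    Consequence,
    Genotype,
    ToolCall,
)


def make_variant(**overrides):
    """Variant factory with sensible pass-everything defaults."""
    kwargs = dict(
        chrom="chr1",
        pos=1000,
        ref="A",
        alt="T",
        gene="GENE1",
        consequence=Consequence.missense,
        sample_id="P1",
        genotype=Genotype.het,
        af_1000g=0.001,
        af_exac=None,
        af_esp6500=0.002,
        af_gnomad=0.0005,
        af_cg46=None,
        gerp=5.0,
        mcap=0.8,
        tool_calls={
            "SIFT": ToolCall.deleterious,
            "PolyPhen2_HDIV": ToolCall.highly_pathogenic,
            "MutationTaster": ToolCall.tolerated,
        },
    )
    kwargs.update(overrides)
    return AnnotatedVariant(**kwargs)


@pytest.fixture(scope="session")
def small_scrna():
    """Clean 5-type dataset, no injected outliers, small enough for unit tests."""
    cfg = ScrnaSimConfig(
        cells_per_type=60,
        n_genes=400,
        n_markers_per_type=15,
        qc_outlier_fractions=(0.0, 0.0, 0.0, 0.0),
        seed=7,
    )
    return gen_scrna_counts(cfg)
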