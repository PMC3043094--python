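import numpy as np
import pytest

from pdpathways.models import CASE, CONTROL, ExpressionPanel, GeneModel, PipelineConfig
from pdpathways.simulate import SimulationSpec


@pytest.fixture
def config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture
def small_spec() -> SimulationSpec:
    """A scaled-down planted-signal dataset for fast structural tests."""
    return SimulationSpec(
        rng_seed=11,
        n_genes=300,
        n_chrom=3,
        n_pathways=40,
        pathway_size_range=(15, 15),
        planted_pathways=frozenset({"pw001"}),
        n_snps=3000,
        n_cases=3,
        n_controls=3,
    )


@pytest.fixture
def three_genes() -> list[GeneModel]:
    """The worked window-mapping annotation: three genes on chr1."""
    return [
        GeneModel("A", "chr1", 10_000, 15_000),
        GeneModel("B", "chr1", 50_000, 60_000),
        GeneModel("C", "chr1", 120_000, 130_000),
    ]


def make_panel(values: np.ndarray, n_cases: int, n_controls: int,
               regions=("R1", "R2", "R3")) -> ExpressionPanel:
    """Wrap a (genes, subjects, regions) array with generated labels."""
    n_genes = values.shape[0]
    cases = [f"case{i}" for i in range(n_cases)]
    controls = [f"ctrl{i}" for i in range(n_controls)]
    return ExpressionPanel(
        genes=[f"g{i}" for i in range(n_genes)],
        subjects=cases + controls,
        groups={s: CASE for s in cases} | {s: CONTROL for s in controls},
        regions=list(regions),
        values=values,
    )
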