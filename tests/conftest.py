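import numpy as np
import pandas as pd
import pytest

from adipoatlas.config import AnalysisConfig, OMENTAL, SUBCUTANEOUS
from adipoatlas.io_formats import ExpressionMatrix
from adipoatlas.synthetic_data import SimConfig, generate_atlas, generate_depot_counts


@pytest.fixture
def config() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture(scope="session")
def small_sim() -> SimConfig:
    # 12 tissues x 40 samples keeps every tissue above the 30-donor rule
    return SimConfig(
        seed=11, n_tissues=12, samples_per_tissue=40, n_genes=250,
        n_specific_sub=8, n_specific_om=8, n_specific_both=8,
        n_enhanced_except1=8, n_enhanced_except2=8,
    )


@pytest.fixture(scope="session")
def small_atlas(small_sim):
    return generate_atlas(small_sim)


@pytest.fixture(scope="session")
def small_counts(small_sim):
    return generate_depot_counts(small_sim)


def make_matrix(medoids: dict[str, list[float]], n_samples: int = 4) -> ExpressionMatrix:
    """Constant-valued matrix: tissue -> per-gene values, replicated per sample."""
    tissues = list(medoids)
    n_genes = len(next(iter(medoids.values())))
    cols, tissue_of = {}, {}
    for t_i, tissue in enumerate(tissues):
        for s in range(n_samples):
            sid = f"S{t_i}_{s}"
            cols[sid] = medoids[tissue]
            tissue_of[sid] = tissue
    values = pd.DataFrame(cols, index=[f"g{i}" for i in range(n_genes)], dtype=float)
    return ExpressionMatrix(values, tissue_of)


@pytest.fixture
def depot_labels():
    return SUBCUTANEOUS, OMENTAL
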