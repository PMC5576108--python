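import numpy as np
import pandas as pd
import pytest

from tebodymap import (CompartmentAnnotation, ExpressionMatrix, SampleDesign,
                       assign_compartments, default_config, enumerate_samples,
                       link_tes_to_genes, simulate_dataset)


@pytest.fixture(scope="session")
def design() -> SampleDesign:
    return SampleDesign()


@pytest.fixture(scope="session")
def default_ds():
    """The full study-emulation dataset (every planted effect), one seed."""
    return simulate_dataset(default_config(11))


@pytest.fixture(scope="session")
def assigned_tes(default_ds):
    ann = CompartmentAnnotation.from_genes(default_ds.annotation.genes)
    return assign_compartments(default_ds.annotation.tes, ann)


@pytest.fixture(scope="session")
def nearest_table(default_ds, assigned_tes):
    return link_tes_to_genes(assigned_tes, default_ds.annotation.genes)


def make_design(n_organs=2, stages=(2, 6, 21, 104), n_replicates=4,
                single_sex=()):
    organs = tuple(f"O{i}" for i in range(n_organs))
    sexes = {o: ("male", "female") for o in organs}
    for o in single_sex:
        sexes[o] = ("male",)
    return SampleDesign(organs, tuple(stages), sexes, n_replicates)


@pytest.fixture
def small_design():
    return make_design(n_organs=2)


def matrix_from_cells(design: SampleDesign, cell_values, features,
                      noise_sd=0.0, seed=0) -> ExpressionMatrix:
    """Build an ExpressionMatrix from per-(organ, stage, sex) cell RPKM means.

    ``cell_values``: feature -> {(organ, stage, sex): rpkm} with a '*'
    fallback key for unlisted cells.
    """
    rng = np.random.default_rng(seed)
    samples = enumerate_samples(design)
    data = {}
    for feat in features:
        spec = cell_values[feat]
        vals = []
        for s in samples:
            base = spec.get((s.organ, s.stage, s.sex), spec.get("*", 0.0))
            v = base * 2 ** rng.normal(0, noise_sd) if noise_sd else base
            vals.append(v)
        data[feat] = vals
    df = pd.DataFrame(data, index=[s.sample_id for s in samples]).T
    return ExpressionMatrix(df, design)
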