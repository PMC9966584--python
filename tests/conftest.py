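import numpy as np
import pytest

from probioscreen.data_model_io import fixture_path
from probioscreen.pipeline import reference_trait_panels
from probioscreen.selection_funnel import SelectionConfig, binarize_traits


@pytest.fixture(scope="session")
def fixtures_dir(tmp_path_factory):
    """Materialized copies of the packaged fixture tables."""
    from importlib import resources

    out = tmp_path_factory.mktemp("fixtures")
    for name in (
        "isolate_identification.tsv",
        "typing_biomass.tsv",
        "enzyme_panels.tsv",
        "selection_criteria.tsv",
        "adhesion_traits_synthetic.tsv",
        "survival_safety_synthetic.tsv",
        "survival_stress_synthetic.tsv",
    ):
        with resources.as_file(fixture_path(name)) as p:
            (out / name).write_bytes(p.read_bytes())
    return out


@pytest.fixture(scope="session")
def trait_panels():
    """Trait panels for the 16 reference strains, keyed by strain id."""
    return {p["strain_id"]: p for p in reference_trait_panels()}


@pytest.fixture(scope="session")
def selection_records(trait_panels):
    cfg = SelectionConfig()
    return [binarize_traits(p, cfg) for p in trait_panels.values()]


@pytest.fixture
def rng():
    return np.random.default_rng(20230218)
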