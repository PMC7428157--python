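import warnings

import pytest

from dietfba import (
    CompiledDiet,
    ProvenanceRecord,
    RunConfig,
    ToyModelSpec,
    make_toy_model,
    make_toy_recipe_bundle,
)
from dietfba.fixtures import write_toy_bundle


def diet_from(entries: dict[str, float]) -> CompiledDiet:
    """Build a compiled diet directly from concentrations (test shorthand)."""
    return CompiledDiet(
        entries,
        {c: [ProvenanceRecord(source="test", rule="direct")] for c in entries},
    )


@pytest.fixture
def toy_bundle():
    """(recipe, compositions, rules, registry) miniature rich-medium bundle."""
    return make_toy_recipe_bundle()


@pytest.fixture
def single_substrate_model():
    """One substrate, biomass stoichiometry 10: optimum = conc / 10."""
    return make_toy_model(ToyModelSpec(biomass_stoichiometry=(10.0,)))


@pytest.fixture
def two_substrate_model():
    """Two substrates, stoichiometries (1, 2)."""
    return make_toy_model(ToyModelSpec(biomass_stoichiometry=(1.0, 2.0)))


@pytest.fixture
def bundle_dir(tmp_path):
    """Toy bundle + matching model written to disk in public formats."""
    return write_toy_bundle(tmp_path / "bundle")


@pytest.fixture
def bundle_config(bundle_dir, tmp_path):
    return RunConfig(
        recipe=bundle_dir["recipe"],
        compositions=bundle_dir["compositions"],
        rules=bundle_dir["rules"],
        registry=bundle_dir["registry"],
        model=bundle_dir["model"],
        output_dir=tmp_path / "out",
    )


@pytest.fixture(autouse=True)
def _silence_drop_warnings():
    """Dropped-compound warnings are expected noise in many tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield
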