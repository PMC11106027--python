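import pytest

import polyxpop as px
from polyxpop import classify, simulate, variants


@pytest.fixture(scope="session")
def table1_fixture():
    return simulate.table1_fixture()


@pytest.fixture(scope="session")
def table1_pipeline_table(table1_fixture):
    """The variant-type table obtained by running the full classification
    path (scan -> map -> refine -> assign -> classify -> tabulate) on the
    deterministic fixture inputs."""
    fx = table1_fixture
    repeats = px.scan_proteome(fx.proteome, aa_filter="Q")
    vs, _ = variants.map_to_uniprot(fx.variants, fx.id_mapping, fx.proteome)
    vs = variants.refine_duplications(vs, fx.proteome)
    pairs = classify.assign_variants_to_repeats(repeats, vs, aa="Q")
    return classify.tabulate(pairs)


@pytest.fixture(scope="session")
def small_synthetic():
    """A small seeded synthetic data set shared by read-only tests."""
    spec = simulate.SyntheticSpec(seed=11, n_proteins=60)
    proteome, repeat_truth = simulate.gen_proteome(spec)
    vs, variant_truth = simulate.gen_variants(spec, proteome)
    return spec, proteome, repeat_truth, vs, variant_truth
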