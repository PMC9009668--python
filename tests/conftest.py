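import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fishaudit.identify import BarcodeIdentifier, ReferenceLibrary
from fishaudit.labeling import call_all
from fishaudit.simulate import (
    SpeciesPool,
    SurveyDesign,
    generate_catalogs,
    generate_reference_library,
    simulate_survey,
)

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_pool():
    """Ten species in four genera spanning all three origin categories."""
    return SpeciesPool(
        (
            ("Thunnus albacares", "marine_bony", 8.0),
            ("Thunnus obesus", "marine_bony", 2.0),
            ("Lutjanus peru", "marine_bony", 3.0),
            ("Lutjanus guttatus", "marine_bony", 1.5),
            ("Lutjanus argentiventris", "marine_bony", 1.0),
            ("Coryphaena hippurus", "marine_bony", 5.0),
            ("Sphyrna lewini", "elasmobranch", 1.0),
            ("Alopias pelagicus", "elasmobranch", 0.8),
            ("Oreochromis niloticus", "aquaculture_freshwater", 6.0),
            ("Pangasianodon hypophthalmus", "aquaculture_freshwater", 4.0),
        )
    )


@pytest.fixture(scope="session")
def small_libraries(small_pool):
    return generate_reference_library(
        small_pool, length=654, min_interspecies_divergence=0.05,
        n_libraries=2, seed=11,
    )


@pytest.fixture(scope="session")
def small_catalogs(small_pool):
    catalogs, master = generate_catalogs(
        small_pool, ["atun", "dorado", "tilapia", "cazon", "basa", "pargo"],
        n_catalogs=3, seed=7,
    )
    return catalogs


@pytest.fixture(scope="session")
def small_survey(small_pool, small_catalogs, small_libraries):
    design = SurveyDesign(
        samples_per_name={"atun": 12, "dorado": 8, "tilapia": 8, "cazon": 6,
                          "basa": 4, "pargo": 6, "pescado": 2},
        mislabel_probability={"atun": 0.1, "dorado": 0.5, "tilapia": 0.2,
                              "cazon": 0.4, "basa": 0.0, "pargo": 0.3,
                              "pescado": 0.0},
        seed=5,
    )
    return simulate_survey(small_pool, design, small_catalogs, small_libraries[0])


@pytest.fixture(scope="session")
def small_calls(small_survey, small_libraries, small_catalogs):
    samples, _truth = small_survey
    identifier = BarcodeIdentifier().fit(small_libraries)
    results = identifier.identify(dict(zip(samples["sample_id"], samples["sequence"])))
    return call_all(samples, results, small_catalogs)


@pytest.fixture(scope="session")
def oracle_corpus():
    """50-species library plus 20 mutated queries with known true species."""
    from fishaudit.simulate import mutate_sequence

    pool = SpeciesPool.zipf(50, seed=3)
    (library,) = generate_reference_library(pool, n_libraries=1, seed=3)
    rng = np.random.default_rng(3)
    anchors = {sp: seq for _, sp, seq in library.entries}
    names = pool.names
    queries = {}
    truth = {}
    for i in range(20):
        species = names[int(rng.integers(len(names)))]
        queries[f"q{i}"] = mutate_sequence(
            anchors[species], float(rng.uniform(0, 0.012)), rng=rng
        )
        truth[f"q{i}"] = species
    return library, queries, truth
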