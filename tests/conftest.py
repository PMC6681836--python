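import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tps_survey.profile_hmm import calibrate_for_database
from tps_survey.synthetic_data import (
    ProteomeConfig, default_profiles, generate_proteome, make_subfamily_panel,
)

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def profiles():
    """Uncalibrated NTD/CTD/IDS profiles built from the synthetic seeds."""
    return default_profiles()


@pytest.fixture(scope="session")
def bench_proteome():
    """500-protein benchmark proteome (planted domains at divergence 0.3)
    with NTD/CTD profiles calibrated against it."""
    profs = default_profiles(("NTD", "CTD"))
    config = ProteomeConfig(n_full=60, n_ntd_only=30, n_ctd_only=30,
                            n_decoy=380, divergence=0.3)
    records, truth = generate_proteome(config, seed=424242, profiles=profs)
    assert len(records) == 500
    for p in profs.values():
        calibrate_for_database(p, records, seed=99)
    return records, truth, profs


@pytest.fixture(scope="session")
def subfamily_panels():
    """NTD+CTD reference panels and held-out queries at a 2x
    between/within divergence ratio."""
    refs_ntd, queries_ntd = make_subfamily_panel("NTD", seed=5)
    refs_ctd, queries_ctd = make_subfamily_panel("CTD", seed=6)
    return {"NTD": (refs_ntd, queries_ntd), "CTD": (refs_ctd, queries_ctd)}


@pytest.fixture()
def rng():
    return np.random.default_rng(20190715)
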