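import datetime as dt
import logging

import numpy as np
import pytest

from gorillanet import (Demography, Individual, Tenure, AlphaTenure,
                        ScenarioConfig, Effects, simulate)

logging.getLogger("gorillanet").setLevel(logging.ERROR)


def D(s: str) -> dt.date:
    return dt.date.fromisoformat(s)


def make_female(iid, group="G1", entry="2014-01-01", entry_type="natal",
                exit=None, exit_type=None, birth="2000-01-01", births=()):
    return Individual(iid, "female", D(birth),
                      [Tenure(group, D(entry), entry_type,
                              D(exit) if exit else None, exit_type)],
                      [D(b) for b in births])


def make_male(iid, group="G1", entry="2014-01-01", birth="1998-01-01",
              alpha_from=None, alpha_to=None):
    alphas = []
    if alpha_from:
        alphas.append(AlphaTenure(group, D(alpha_from),
                                  D(alpha_to) if alpha_to else None))
    return Individual(iid, "male", D(birth),
                      [Tenure(group, D(entry), "natal")], [], alphas)


@pytest.fixture
def small_demography():
    """One group, four adult females and two males, static membership."""
    inds = [make_female(f"F{i}", birth=f"200{i}-03-01") for i in range(4)]
    inds += [make_male("M0", alpha_from="2014-01-01"), make_male("M1")]
    return Demography(inds)


@pytest.fixture(scope="session")
def default_sim():
    """One simulated dataset at the study scale, shared across tests."""
    return simulate(ScenarioConfig(seed=42))


@pytest.fixture(scope="session")
def quiet_effects():
    """No injected effects, no random heterogeneity beyond sampling noise."""
    return Effects(beta_rank_avg=0.0, beta_both_infant=0.0, beta_one_infant=0.0,
                   beta_immigrant=0.0, dyad_affinity_sd=0.0, female_re_sd=0.0,
                   year_re_sd=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
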