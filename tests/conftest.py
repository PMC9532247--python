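import datetime as dt
import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from pollinet import BipartiteNetwork, CommunitySpec, InteractionRecord
from pollinet.synth import generate_community, generate_surveys


def make_record(
    plant="Trifolium repens",
    insect="Bombus pascuorum",
    guild="bee",
    visits=1,
    week=25,
    site="s1",
    habitat="seminatural grassland",
    units=10,
    size=25.0,
    family="Fabaceae",
    native="native",
    n_habitats=1,
):
    return InteractionRecord(
        site_id=site,
        date=dt.date.fromisocalendar(2021, week, 3),
        habitat_l2=habitat,
        plant_taxon=plant,
        insect_taxon=insect,
        insect_guild=guild,
        visits=visits,
        floral_units=units,
        inflorescence_size=size,
        plant_family=family,
        plant_native=native,
        n_habitats=n_habitats,
    )


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture
def small_net():
    """A hand-checkable 3x3 web."""
    return BipartiteNetwork.from_weights(
        [[3, 1, 0], [1, 2, 1], [0, 1, 2]],
        ["p1", "p2", "p3"],
        ["v1", "v2", "v3"],
    )


@pytest.fixture(scope="session")
def synthetic_records():
    """A moderate synthetic survey dataset shared across tests."""
    spec = CommunitySpec(n_plants=40, n_insects=20)
    comm = generate_community(spec, seed=7)
    return generate_surveys(comm, n_sites=12, n_weeks=20, seed=8)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_web(rng, shape=(6, 6), lam=2.0):
    """A random pruned web guaranteed nonempty."""
    while True:
        w = rng.poisson(lam, shape)
        if w.sum() and (w.sum(axis=1) > 0).all() and (w.sum(axis=0) > 0).all():
            return BipartiteNetwork.from_weights(w)
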