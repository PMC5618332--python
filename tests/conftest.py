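import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ramtool.core import RAMModel, ReactionRecord, SpeciesRecord
from ramtool.fixtures import toy_model

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def toy() -> RAMModel:
    return toy_model()


def make_self_replicator(k: float = 1.0, p0: float = 1.0,
                         nutrient: float = 1e6) -> RAMModel:
    """One-enzyme self replicator: nutrient -> precursor -> enzyme.

    Uptake is spontaneous and the enzyme catalyzes its own synthesis with
    turnover number ``k``, so at the optimum dp/dt = v = k p and
    p(t) = p0 exp(k t).
    """
    return RAMModel(
        id="self_replicator",
        species=[
            SpeciesRecord(id="Nut", species_type="extracellular",
                          compartment="external", initial_amount=nutrient),
            SpeciesRecord(id="M", species_type="metabolite"),
            SpeciesRecord(id="E", species_type="enzyme",
                          molecular_weight=1.0, objective_weight=1.0,
                          initial_amount=p0),
        ],
        reactions=[
            ReactionRecord(id="uptake", stoichiometry={"Nut": -1.0, "M": 1.0}),
            ReactionRecord(id="synth_E", stoichiometry={"M": -1.0, "E": 1.0},
                           kcat_forward=k, gene_product="E"),
        ],
    )


def make_maintenance_replicator(psi: float = 0.0) -> RAMModel:
    """Self replicator with an ATP-hydrolysis maintenance sink.

    The enzyme imports nutrient into an energy pool (kcat 10) and converts
    the pool into itself (kcat 1); maintenance drains the pool at
    ``psi * B_t``.  Balanced growth satisfies
    mu/1 + (mu + psi)/10 <= 1, i.e. mu = (1 - psi/10) / 1.1.
    """
    return RAMModel(
        id="maintenance_replicator",
        species=[
            SpeciesRecord(id="Nut", species_type="extracellular",
                          compartment="external", initial_amount=1e8),
            SpeciesRecord(id="Energy", species_type="metabolite"),
            SpeciesRecord(id="E", species_type="enzyme",
                          molecular_weight=1.0, objective_weight=1.0,
                          initial_amount=1.0),
        ],
        reactions=[
            ReactionRecord(id="uptake", stoichiometry={"Nut": -1.0, "Energy": 1.0},
                           kcat_forward=10.0, gene_product="E"),
            ReactionRecord(id="growth", stoichiometry={"Energy": -1.0, "E": 1.0},
                           kcat_forward=1.0, gene_product="E"),
            ReactionRecord(id="maint", stoichiometry={"Energy": -1.0},
                           maintenance_scaling=psi),
        ],
    )


@pytest.fixture
def self_replicator():
    return make_self_replicator


@pytest.fixture
def maintenance_replicator():
    return make_maintenance_replicator


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)
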