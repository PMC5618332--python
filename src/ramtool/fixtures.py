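"""Validation utilities and programmatic fixtures.

Contains the reference 14-species/14-reaction toy resource-allocation
model (a self-replicating cell with two nutrient transport routes, three
metabolic conversions, a storage polymer, a structural quota compound and a
ribosome), growth-rate fitting from optical-density measurements,
maintenance tuning against an experimental growth rate, and reproducible
random generators so the builder and the SBML round trip can be exercised
without any external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from .builder import AMINO_ACIDS, QuotaSpec
from .core import GeneProduct, RAMModel, ReactionRecord, SpeciesRecord
from .errors import DomainError, GrowthRateError, InfeasibleProblemError
from .solver import DiscretizationConfig, Scenario, solve_defba

__all__ = [
    "GrowthSeries",
    "toy_model",
    "fit_growth_rate_from_od",
    "tune_maintenance",
    "random_builder_fixture",
    "random_ram_model",
    "yeast_protein_quota_spec",
    "YEAST_PROTEIN_MASS_FRACTION",
]


@dataclass
class GrowthSeries:
    """Optical-density measurements of a growing batch culture."""

    times: np.ndarray
    od: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.times.shape != self.od.shape or self.times.ndim != 1:
            raise DomainError("times and od must be 1-d arrays of equal length")
        if np.any(np.diff(self.times) <= 0):
            raise DomainError("times must be strictly increasing")
        if np.any(self.od <= 0):
            raise DomainError("optical densities must be positive")


def fit_growth_rate_from_od(series: GrowthSeries) -> float:
    """Experimental growth rate: least-squares slope of ln(OD) vs time.

    Uses ordinary least squares over all points; windowing to the
    exponential phase is the caller's responsibility.
    """
    if series.times.size < 2:
        raise DomainError("need at least two measurements to fit a slope")
    slope = np.polyfit(series.times, np.log(series.od), 1)[0]
    return float(slope)


# ---------------------------------------------------------------------------
# the toy model
# ---------------------------------------------------------------------------


def toy_model(
    psi_maintenance: float = 0.01,
    bp_s: float = 0.3,
    n2_amount: float = 10.0,
    enzyme_amount: float = 1e-3,
) -> RAMModel:
    """The reference 14-species / 14-reaction toy model.

    Two nitrogen sources N1/N2 are imported (with nonlimiting O2) by the
    transporters ETrans1/ETrans2 into a common precursor N, converted by
    EMetab1/EMetab2 into amino acids and ATP, which feed a spontaneous
    maintenance sink, a reversible storage polymer (EStor, forward kcat 25,
    backward 30), and the ribosome-catalyzed synthesis of all seven
    macromolecules including the structural quota compound S and the
    ribosome R itself.

    Reference quantities (stoichiometries, turnover numbers, initial amounts
    N1 = O2 = 10, N = Stor = 0, R = 0.03364, S = 0.7499) are fixed.
    Quantities the reference tables leave open are keyword parameters with
    documented fixture defaults: the maintenance coefficient
    ``psi_maintenance`` (0.01 mmol/(g*h)), the structural biomass fraction
    ``bp_s`` (0.3), the N2 amount (10), the initial amount of each
    non-ribosomal enzyme (0.001), and molecular/objective weights set to
    chain length / 1000 g/mmol (so 1000 amino acids weigh 1 g).
    """
    # molecular weight = synthesis chain length / 1000 (fixture convention)
    enz = [
        # id, weight, chain AA, chain ATP, kcat of synthesis
        ("ETrans1", 0.100, 100, 400, 10.0),
        ("ETrans2", 0.160, 160, 640, 6.25),
        ("EMetab1", 0.200, 200, 800, 5.0),
        ("EMetab2", 0.160, 160, 640, 6.25),
        ("EStor", 0.150, 150, 500, 5.0),
    ]
    species = [
        SpeciesRecord(id="N1", species_type="extracellular", name="Nutrient 1",
                      compartment="external", initial_amount=10.0),
        SpeciesRecord(id="N2", species_type="extracellular", name="Nutrient 2",
                      compartment="external", initial_amount=float(n2_amount)),
        SpeciesRecord(id="O2", species_type="extracellular", name="Oxygen",
                      compartment="external", is_boundary=True,
                      is_constant=True, initial_amount=10.0),
        SpeciesRecord(id="N", species_type="metabolite", name="Precursor",
                      initial_amount=0.0),
        SpeciesRecord(id="AA", species_type="metabolite", name="Amino acids"),
        SpeciesRecord(id="ATP", species_type="metabolite", name="Energy"),
        SpeciesRecord(id="Stor", species_type="storage", name="Storage",
                      molecular_weight=0.2, initial_amount=0.0),
    ]
    for sid, w, _aa, _atp, _k in enz:
        species.append(
            SpeciesRecord(id=sid, species_type="enzyme", name=sid,
                          molecular_weight=w, objective_weight=w,
                          initial_amount=float(enzyme_amount))
        )
    species.append(
        SpeciesRecord(id="S", species_type="quota",
                      name="Structural biomass component",
                      molecular_weight=1.5, objective_weight=1.5,
                      biomass_percentage=float(bp_s), initial_amount=0.7499)
    )
    species.append(
        SpeciesRecord(id="R", species_type="enzyme", name="Ribosome",
                      molecular_weight=1.0, objective_weight=1.0,
                      initial_amount=0.03364)
    )

    gene_products = [
        GeneProduct(id="gp_ETrans1", associated_species="ETrans1",
                    label="1*GTRANS1"),
        GeneProduct(id="gp_ETrans2", associated_species="ETrans2",
                    label="1*GTRANS2 AND 1*GTRANS3"),
        GeneProduct(id="gp_EMetab1", associated_species="EMetab1",
                    label="1*GMETAB1"),
        GeneProduct(id="gp_EMetab2", associated_species="EMetab2",
                    label="1*GMETAB2"),
        GeneProduct(id="gp_EStor", associated_species="EStor",
                    label="1*GSTOR"),
        GeneProduct(id="gp_R", associated_species="R", label="1*GRIB"),
    ]

    reactions = [
        ReactionRecord(id="Trans1", name="N1 uptake",
                       stoichiometry={"N1": -1, "O2": -1, "N": 1},
                       reversible=True, kcat_forward=1800.0,
                       kcat_backward=1800.0, gene_product="gp_ETrans1"),
        ReactionRecord(id="Trans2", name="N2 uptake",
                       stoichiometry={"N2": -1, "O2": -1, "N": 1},
                       reversible=True, kcat_forward=2400.0,
                       kcat_backward=2400.0, gene_product="gp_ETrans2"),
        ReactionRecord(id="Metab1", name="Precursor conversion 1",
                       stoichiometry={"N": -1, "AA": 1, "ATP": 1},
                       kcat_forward=2000.0, gene_product="gp_EMetab1"),
        ReactionRecord(id="Metab2", name="Precursor conversion 2",
                       stoichiometry={"N": -1, "AA": 1, "ATP": 1},
                       kcat_forward=2500.0, gene_product="gp_EMetab2"),
        ReactionRecord(id="Metab3", name="Precursor conversion 3",
                       stoichiometry={"N": -1, "AA": 1, "ATP": 2},
                       kcat_forward=2000.0, gene_product="gp_EMetab2"),
        ReactionRecord(id="Maintenance", name="ATP maintenance",
                       stoichiometry={"AA": -50, "ATP": -60},
                       maintenance_scaling=float(psi_maintenance)),
        ReactionRecord(id="Storage", name="Storage polymerization",
                       stoichiometry={"AA": -200, "ATP": -300, "Stor": 1},
                       reversible=True, kcat_forward=25.0, kcat_backward=30.0,
                       gene_product="gp_EStor"),
        ReactionRecord(id="synth_S", name="Quota synthesis",
                       stoichiometry={"AA": -1500, "ATP": -200, "S": 1},
                       kcat_forward=10.0, gene_product="gp_R"),
        ReactionRecord(id="synth_R", name="Ribosome synthesis",
                       stoichiometry={"AA": -1000, "ATP": -4000, "R": 1},
                       kcat_forward=1.0, gene_product="gp_R"),
    ]
    for sid, _w, aa, atp, kcat in enz:
        reactions.insert(
            -2,
            ReactionRecord(id=f"synth_{sid}", name=f"{sid} synthesis",
                           stoichiometry={"AA": -float(aa), "ATP": -float(atp),
                                          sid: 1},
                           kcat_forward=float(kcat), gene_product="gp_R"),
        )

    model = RAMModel(id="toy_ram", name="Toy resource allocation model",
                     species=species, reactions=reactions,
                     gene_products=gene_products)
    model.validate()
    return model


# ---------------------------------------------------------------------------
# maintenance tuning
# ---------------------------------------------------------------------------


def _mu_model(model: RAMModel, maintenance_reaction_id: str, psi: float,
              scenario: Scenario, config: DiscretizationConfig) -> Optional[float]:
    """Simulated growth rate at a given maintenance coefficient.

    Returns ``ln(B_t(T)/B_t(0)) / T`` or None if the problem is infeasible
    at this coefficient.
    """
    m = model.copy()
    rxn = m.reaction_by_id(maintenance_reaction_id)
    rxn.maintenance_scaling = float(psi)
    try:
        traj = solve_defba(m, scenario, config)
    except InfeasibleProblemError:
        return None
    bt = traj.total_biomass_series()
    if bt[0] <= 0 or bt[-1] <= 0:
        return None
    return float(np.log(bt[-1] / bt[0]) / config.t_end)


def tune_maintenance(
    model: RAMModel,
    maintenance_reaction_id: str,
    mu_exp: float,
    scenario: Scenario,
    config: DiscretizationConfig,
    tolerance: float = 1e-4,
    max_iter: int = 100,
) -> float:
    """Find the maintenance coefficient matching an experimental growth rate.

    The simulated growth rate decreases monotonically in the maintenance
    coefficient psi, so psi is found by bisection until
    ``|mu_model(psi) - mu_exp| <= tolerance``.  If the experimental rate
    exceeds the model optimum at psi = 0 the model is missing capacity and
    a :class:`GrowthRateError` tells the user to check the turnover
    numbers instead.
    """
    model.reaction_by_id(maintenance_reaction_id)
    mu0 = _mu_model(model, maintenance_reaction_id, 0.0, scenario, config)
    if mu0 is None:
        raise InfeasibleProblemError(
            "model infeasible even without maintenance"
        )
    if mu_exp > mu0 + tolerance:
        raise GrowthRateError(
            f"experimental growth rate {mu_exp:.4g}/h exceeds the model"
            f" optimum {mu0:.4g}/h; check the turnover numbers"
        )
    if abs(mu0 - mu_exp) <= tolerance:
        return 0.0

    lo, hi = 0.0, 1e-3
    for _ in range(60):
        mu_hi = _mu_model(model, maintenance_reaction_id, hi, scenario, config)
        if mu_hi is None or mu_hi < mu_exp:
            break
        lo, hi = hi, 2.0 * hi
    else:
        raise GrowthRateError(
            "could not bracket the maintenance coefficient; the growth rate"
            " does not fall below the target"
        )

    psi = hi
    for _ in range(max_iter):
        psi = 0.5 * (lo + hi)
        mu = _mu_model(model, maintenance_reaction_id, psi, scenario, config)
        if mu is not None and abs(mu - mu_exp) <= tolerance:
            return psi
        if mu is None or mu < mu_exp:
            hi = psi
        else:
            lo = psi
    raise GrowthRateError(
        f"maintenance tuning did not converge to |mu - mu_exp| <="
        f" {tolerance} within {max_iter} bisections"
    )


# ---------------------------------------------------------------------------
# random generators
# ---------------------------------------------------------------------------


def random_builder_fixture(
    seed: int,
    n_genes: int,
    length_range: Tuple[int, int] = (50, 300),
) -> Tuple[List[Tuple[str, str]], Dict[str, List[str]], Dict[str, List[Tuple[str, int]]]]:
    """Reproducible random builder inputs.

    Returns ``(fasta_records, gene_reaction_map, subunit_stoichiometries)``:
    ``fasta_records`` is a list of ``(gene_id, amino_acid_sequence)``;
    every reaction in the map is catalyzed by at least one gene; subunit
    stoichiometries assign each enzyme its genes with copy numbers 1-3.
    """
    rng = np.random.default_rng(seed)
    lo, hi = length_range
    if n_genes < 0 or lo < 1 or hi < lo:
        raise DomainError("invalid fixture parameters")
    genes = [f"g{i:03d}" for i in range(n_genes)]
    alphabet = np.array(list(AMINO_ACIDS))
    records = [
        (g, "".join(rng.choice(alphabet, size=int(rng.integers(lo, hi + 1)))))
        for g in genes
    ]
    gene_reaction_map: Dict[str, List[str]] = {}
    subunits: Dict[str, List[Tuple[str, int]]] = {}
    for j, gene in enumerate(genes):
        rid = f"r{j:03d}"
        n_sub = int(rng.integers(1, min(3, n_genes) + 1))
        chosen = list(rng.choice(genes, size=n_sub, replace=False))
        if gene not in chosen:
            chosen[0] = gene  # every gene catalyzes something
        gene_reaction_map[rid] = chosen
        subunits[f"E_{rid}"] = [
            (g, int(rng.integers(1, 4))) for g in chosen
        ]
    return records, gene_reaction_map, subunits


def random_ram_model(seed: int) -> RAMModel:
    """A random structurally valid resource-allocation model.

    Used to exercise the SBML round trip and matrix assembly on models with
    varying numbers of nutrients, metabolites, storage polymers, enzymes
    and quota compounds.  All numeric parameters are drawn on coarse
    decimal grids so serialization is bit-faithful.
    """
    rng = np.random.default_rng(seed)

    def val(lo: float, hi: float, digits: int = 4) -> float:
        return float(round(float(rng.uniform(lo, hi)), digits))

    n_ext = int(rng.integers(1, 4))
    n_met = int(rng.integers(1, 4))
    n_stor = int(rng.integers(0, 3))
    n_enz = int(rng.integers(2, 5))
    n_quota = int(rng.integers(0, 3))

    species: List[SpeciesRecord] = []
    for i in range(n_ext):
        species.append(SpeciesRecord(
            id=f"Ext{i}", species_type="extracellular", compartment="external",
            is_boundary=bool(i == 0 and rng.random() < 0.5),
            is_constant=bool(i == 0 and rng.random() < 0.5),
            initial_amount=val(1, 50),
        ))
        if species[-1].is_constant and not species[-1].is_boundary:
            species[-1].is_constant = False
    mets = [f"Met{i}" for i in range(n_met)]
    species += [
        SpeciesRecord(id=m, species_type="metabolite") for m in mets
    ]
    for i in range(n_stor):
        species.append(SpeciesRecord(
            id=f"Stor{i}", species_type="storage",
            molecular_weight=val(0.05, 0.5), initial_amount=val(0, 5),
        ))
    enzymes = [f"Enz{i}" for i in range(n_enz)]
    for e in enzymes:
        w = val(0.05, 2.0)
        species.append(SpeciesRecord(
            id=e, species_type="enzyme", molecular_weight=w,
            objective_weight=w if rng.random() < 0.7 else val(0.01, 2.0),
            initial_amount=val(0, 0.1),
        ))
    for i in range(n_quota):
        species.append(SpeciesRecord(
            id=f"Quota{i}", species_type="quota",
            molecular_weight=val(0.5, 2.0), objective_weight=val(0.5, 2.0),
            biomass_percentage=val(0.05, 0.4),
            initial_amount=val(0.1, 1.0),
        ))

    gene_products = [
        GeneProduct(id=f"gp_{e}", associated_species=e, label=f"1*{e.upper()}")
        for e in enzymes
    ]

    def catalyst() -> Optional[str]:
        if rng.random() < 0.8:
            return f"gp_{enzymes[int(rng.integers(0, n_enz))]}"
        return None

    reactions: List[ReactionRecord] = []
    for i in range(n_ext):
        reactions.append(ReactionRecord(
            id=f"uptake{i}",
            stoichiometry={f"Ext{i}": -1.0,
                           mets[int(rng.integers(0, n_met))]: 1.0},
            reversible=bool(rng.random() < 0.3),
            kcat_forward=val(10, 5000, 1),
            kcat_backward=0.0,
            gene_product=catalyst(),
        ))
        if reactions[-1].reversible:
            reactions[-1].kcat_backward = val(10, 5000, 1)
    if n_met > 1:
        reactions.append(ReactionRecord(
            id="interconv",
            stoichiometry={mets[0]: -1.0, mets[1]: 1.0},
            kcat_forward=val(10, 5000, 1),
            gene_product=catalyst(),
        ))
    for i in range(n_stor):
        reactions.append(ReactionRecord(
            id=f"store{i}",
            stoichiometry={mets[int(rng.integers(0, n_met))]: -val(5, 50, 1),
                           f"Stor{i}": 1.0},
            reversible=True,
            kcat_forward=val(5, 100, 1), kcat_backward=val(5, 100, 1),
            gene_product=catalyst(),
        ))
    for e in enzymes:
        reactions.append(ReactionRecord(
            id=f"synth_{e}",
            stoichiometry={m: -val(10, 500, 1) for m in mets} | {e: 1.0},
            kcat_forward=val(1, 20),
            gene_product=f"gp_{enzymes[-1]}",
            ec_number="2.7.1.17" if rng.random() < 0.3 else None,
        ))
    for i in range(n_quota):
        reactions.append(ReactionRecord(
            id=f"synth_Quota{i}",
            stoichiometry={mets[0]: -val(100, 2000, 1), f"Quota{i}": 1.0},
            kcat_forward=val(1, 20),
            gene_product=f"gp_{enzymes[-1]}",
        ))
    if rng.random() < 0.5:
        reactions.append(ReactionRecord(
            id="maint",
            stoichiometry={mets[0]: -val(5, 50, 1)},
            maintenance_scaling=val(0.001, 0.1, 5),
        ))

    # ensure every catalyzed reaction has usable turnover numbers
    for rxn in reactions:
        if rxn.gene_product is not None and rxn.kcat_forward <= 0:
            rxn.kcat_forward = val(10, 1000, 1)

    model = RAMModel(id=f"random_{seed}", species=species,
                     reactions=reactions, gene_products=gene_products)
    model.validate()
    return model


# ---------------------------------------------------------------------------
# synthetic protein-quota coefficients
# ---------------------------------------------------------------------------

#: Protein mass fraction of yeast biomass used by the synthetic quota table
#: (g protein per g dry weight).
YEAST_PROTEIN_MASS_FRACTION = 0.466298

# approximate residue mole fractions of the S. cerevisiae proteome
_YEAST_AA_FRACTIONS = {
    "Ala": 0.0760, "Arg": 0.0450, "Asn": 0.0520, "Asp": 0.0590,
    "Cys": 0.0120, "Glu": 0.0650, "Gln": 0.0400, "Gly": 0.0740,
    "His": 0.0220, "Ile": 0.0560, "Leu": 0.0900, "Lys": 0.0700,
    "Met": 0.0190, "Phe": 0.0430, "Pro": 0.0440, "Ser": 0.0850,
    "Thr": 0.0560, "Trp": 0.0110, "Tyr": 0.0330, "Val": 0.0580,
}

# average residue masses in g/mmol (monomer mass minus water)
_RESIDUE_MASS = {
    "Ala": 0.0710788, "Arg": 0.1561875, "Asn": 0.1141038, "Asp": 0.1150886,
    "Cys": 0.1031388, "Glu": 0.1291155, "Gln": 0.1281307, "Gly": 0.0570519,
    "His": 0.1371411, "Ile": 0.1131594, "Leu": 0.1131594, "Lys": 0.1281741,
    "Met": 0.1311926, "Phe": 0.1471766, "Pro": 0.0971167, "Ser": 0.0870782,
    "Thr": 0.1011051, "Trp": 0.1862132, "Tyr": 0.1631760, "Val": 0.0991326,
}


def yeast_protein_quota_spec() -> QuotaSpec:
    """Synthetic charged-tRNA coefficient table for the protein quota.

    A stand-in for a genome-scale reconstruction's biomass reaction: the
    20 charged-tRNA consumption coefficients (mmol per g dry weight) are
    built from the canonical yeast proteome residue composition, scaled so
    that the residue-weighted total equals the yeast protein content of
    :data:`YEAST_PROTEIN_MASS_FRACTION` g/gDW.  Each charged tRNA releases
    its uncharged tRNA as a byproduct; weights are net residue masses, so
    the byproducts carry no mass.  This table is synthetic — it reproduces
    the documented composition statistics, not any database entry.
    """
    mass_per_mole = sum(
        f * _RESIDUE_MASS[a] for a, f in _YEAST_AA_FRACTIONS.items()
    )
    scale = YEAST_PROTEIN_MASS_FRACTION / mass_per_mole
    components = {
        f"{aa}_tRNA": f * scale for aa, f in _YEAST_AA_FRACTIONS.items()
    }
    byproducts = {
        f"tRNA_{aa}": f * scale for aa, f in _YEAST_AA_FRACTIONS.items()
    }
    weights = {
        f"{aa}_tRNA": _RESIDUE_MASS[aa] for aa in _YEAST_AA_FRACTIONS
    }
    return QuotaSpec(
        quota_id="protein_quota",
        components=components,
        byproducts=byproducts,
        weights=weights,
    )
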