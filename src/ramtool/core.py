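"""In-memory representation of metabolic resource-allocation models.

A resource-allocation model extends a stoichiometric network with the
macromolecules (enzymes, ribosome, noncatalytic quota compounds) that
produce and constrain it.  Species fall into four groups:

* ``Y`` — extracellular species (nutrients, gases, secreted products),
* ``X`` — internal metabolites kept in quasi-steady state,
* ``C`` — storage polymers (glycogen, starch, ...),
* ``P`` — macromolecules: catalytic enzymes plus quota compounds.

Reactions are partitioned accordingly into exchange (``R_y``), metabolic
(``R_x``), storage (``R_c``) and macromolecule-synthesis (``R_p``) groups.

This module owns the record types for species, reactions and gene products,
the :class:`RAMModel` container, and the assembly of every constraint matrix
the dynamic optimization needs:

* the stoichiometric matrix ``S`` (and its sign-split variant used once
  reversible fluxes are decomposed into nonnegative parts),
* the enzyme-capacity pair ``(HC, HE)`` encoding
  ``sum_{j in cat(P_i)} v_j / kcat_j <= p_i``,
* the biomass-composition matrix ``HB`` encoding the quota constraints
  ``w_s p_s >= phi_s B_t``,
* the maintenance matrix ``HM`` encoding biomass-proportional flux floors
  ``v_m >= psi_m B_t``.

Units: amounts mmol, molecular/objective weights g/mmol, time h, turnover
numbers 1/h, maintenance coefficients mmol/(g*h).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import (
    ClassificationError,
    DomainError,
    ModelStructureError,
    ParameterizationError,
)

__all__ = [
    "SPECIES_TYPES",
    "SpeciesRecord",
    "ReactionRecord",
    "GeneProduct",
    "RAMModel",
    "ModelPartition",
    "ConstraintMatrices",
    "partition_model",
    "build_capacity_matrices",
    "build_biomass_composition_matrix",
    "build_maintenance_matrix",
    "build_constraint_matrices",
    "objective_biomass",
    "total_biomass",
]

#: Recognized species types of the resource-allocation dialect.
SPECIES_TYPES = ("extracellular", "metabolite", "storage", "enzyme", "quota")

#: Species types whose mass contributes to biomass ("biomass species").
BIOMASS_TYPES = ("storage", "enzyme", "quota")


@dataclass
class SpeciesRecord:
    """One model species.

    Parameters
    ----------
    id : str
        Unique identifier.
    species_type : str
        One of :data:`SPECIES_TYPES`.
    compartment : str
        Compartment id; only used for bookkeeping and serialization.
    is_boundary : bool
        True for nonlimiting extracellular species whose amount is not
        changed by cellular uptake (SBML ``boundaryCondition``).
    is_constant : bool
        True if the amount is fixed during a simulation; only meaningful
        for boundary species.
    molecular_weight : float
        ``w_i`` in g/mmol.
    objective_weight : float
        ``b_i`` in g/mmol; weight in the biomass objective.  Zero is allowed
        (e.g. secreted enzymes excluded from the objective).
    biomass_percentage : float
        Quota fraction ``phi_i`` in [0, 1]; nonzero only for quota species.
    initial_amount : float
        Initial molar amount in mmol.
    """

    id: str
    species_type: str
    name: str = ""
    compartment: str = "cytosol"
    is_boundary: bool = False
    is_constant: bool = False
    molecular_weight: float = 0.0
    objective_weight: float = 0.0
    biomass_percentage: float = 0.0
    initial_amount: float = 0.0
    foreign_annotations: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.species_type not in SPECIES_TYPES:
            raise ModelStructureError(
                f"species {self.id!r}: unknown species type {self.species_type!r};"
                f" expected one of {SPECIES_TYPES}"
            )
        if not 0.0 <= self.biomass_percentage <= 1.0:
            raise ModelStructureError(
                f"species {self.id!r}: biomass percentage"
                f" {self.biomass_percentage} outside [0, 1]"
            )
        if self.biomass_percentage > 0.0 and self.species_type != "quota":
            raise ModelStructureError(
                f"species {self.id!r}: nonzero biomass percentage on"
                f" non-quota species ({self.species_type})"
            )
        if self.molecular_weight < 0.0 or self.objective_weight < 0.0:
            raise ModelStructureError(
                f"species {self.id!r}: negative molecular or objective weight"
            )
        if self.is_boundary and self.species_type != "extracellular":
            raise ModelStructureError(
                f"species {self.id!r}: boundary flag on non-extracellular species"
            )


@dataclass
class ReactionRecord:
    """One reaction with stoichiometry and resource-allocation parameters.

    ``stoichiometry`` maps species id to a signed coefficient (negative for
    reactants).  ``gene_product`` names the single catalyzing gene product
    (or, for convenience in hand-built micro-models, directly an enzyme
    species id); ``None`` marks a spontaneous reaction.  Reactions carrying a
    positive ``maintenance_scaling`` (psi_m) are maintenance reactions and
    must be spontaneous.
    """

    id: str
    stoichiometry: Dict[str, float]
    reversible: bool = False
    kcat_forward: float = 0.0
    kcat_backward: float = 0.0
    maintenance_scaling: float = 0.0
    lower_bound: Optional[float] = None
    upper_bound: Optional[float] = None
    gene_product: Optional[str] = None
    ec_number: Optional[str] = None
    name: str = ""
    foreign_annotations: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.reversible and self.kcat_backward != 0.0:
            raise ModelStructureError(
                f"reaction {self.id!r}: irreversible reactions must have a"
                " zero backward turnover number"
            )
        if self.maintenance_scaling < 0.0:
            raise ModelStructureError(
                f"reaction {self.id!r}: negative maintenance coefficient"
            )
        if self.maintenance_scaling > 0.0 and self.gene_product is not None:
            raise ModelStructureError(
                f"reaction {self.id!r}: maintenance reactions are spontaneous"
                " and cannot carry a gene product"
            )
        if self.lower_bound is None:
            self.lower_bound = -np.inf if self.reversible else 0.0
        if self.upper_bound is None:
            self.upper_bound = np.inf
        if self.lower_bound > self.upper_bound:
            raise ModelStructureError(
                f"reaction {self.id!r}: lower bound exceeds upper bound"
            )


@dataclass
class GeneProduct:
    """A gene product entry linking catalysis to an enzyme species.

    ``label`` carries the complex recipe (e.g. ``"1*GTRANS2 AND 1*GTRANS3"``)
    verbatim; it is never parsed for semantics.
    """

    id: str
    associated_species: str
    label: str = ""


@dataclass
class ModelPartition:
    """Index partition of species into Y/X/C/P and reactions into groups.

    All entries are positions into the model's species/reaction order, so
    ``[model.species[i].id for i in part.P]`` lists the macromolecules.
    """

    Y: List[int]
    X: List[int]
    C: List[int]
    P: List[int]
    R_y: List[int]
    R_x: List[int]
    R_c: List[int]
    R_p: List[int]


@dataclass
class RAMModel:
    """A full resource-allocation model.

    The species and reaction orders are significant: all matrices and
    trajectories index into them.
    """

    id: str = "ram_model"
    species: List[SpeciesRecord] = field(default_factory=list)
    reactions: List[ReactionRecord] = field(default_factory=list)
    gene_products: List[GeneProduct] = field(default_factory=list)
    name: str = ""

    # -- basic accessors ---------------------------------------------------

    @property
    def n(self) -> int:
        """Number of species."""
        return len(self.species)

    @property
    def r(self) -> int:
        """Number of reactions."""
        return len(self.reactions)

    def species_index(self) -> Dict[str, int]:
        return {s.id: i for i, s in enumerate(self.species)}

    def reaction_index(self) -> Dict[str, int]:
        return {r.id: i for i, r in enumerate(self.reactions)}

    def species_by_id(self, sid: str) -> SpeciesRecord:
        try:
            return self.species[self.species_index()[sid]]
        except KeyError:
            raise ModelStructureError(f"unknown species id {sid!r}") from None

    def reaction_by_id(self, rid: str) -> ReactionRecord:
        try:
            return self.reactions[self.reaction_index()[rid]]
        except KeyError:
            raise ModelStructureError(f"unknown reaction id {rid!r}") from None

    def gene_product_by_id(self, gid: str) -> Optional[GeneProduct]:
        for gp in self.gene_products:
            if gp.id == gid:
                return gp
        return None

    def copy(self) -> "RAMModel":
        """Deep-enough copy: records are replaced, stoichiometries copied."""
        return RAMModel(
            id=self.id,
            name=self.name,
            species=[replace(s) for s in self.species],
            reactions=[
                replace(r, stoichiometry=dict(r.stoichiometry))
                for r in self.reactions
            ],
            gene_products=[replace(g) for g in self.gene_products],
        )

    # -- catalysis ---------------------------------------------------------

    def catalyzing_enzyme(self, reaction: ReactionRecord) -> Optional[str]:
        """Resolve a reaction's catalyzing enzyme *species* id.

        The ``gene_product`` field may name a declared gene product (whose
        ``associated_species`` is the enzyme) or, as a convenience for small
        hand-built models, an enzyme species directly.
        """
        gid = reaction.gene_product
        if gid is None:
            return None
        gp = self.gene_product_by_id(gid)
        if gp is not None:
            return gp.associated_species
        idx = self.species_index()
        if gid in idx and self.species[idx[gid]].species_type == "enzyme":
            return gid
        raise ModelStructureError(
            f"reaction {reaction.id!r}: gene product {gid!r} resolves to"
            " neither a declared gene product nor an enzyme species"
        )

    def catalysis_map(self) -> Dict[str, List[str]]:
        """Map enzyme species id -> ids of the reactions it catalyzes."""
        cat: Dict[str, List[str]] = {}
        for rxn in self.reactions:
            enz = self.catalyzing_enzyme(rxn)
            if enz is not None:
                cat.setdefault(enz, []).append(rxn.id)
        return cat

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        """Raise :class:`ModelStructureError` on any structural defect."""
        idx = self.species_index()
        if len(idx) != len(self.species):
            raise ModelStructureError(f"model {self.id!r}: duplicate species ids")
        if len(self.reaction_index()) != len(self.reactions):
            raise ModelStructureError(f"model {self.id!r}: duplicate reaction ids")
        gids = [g.id for g in self.gene_products]
        if len(set(gids)) != len(gids):
            raise ModelStructureError(f"model {self.id!r}: duplicate gene product ids")
        for rxn in self.reactions:
            for sid in rxn.stoichiometry:
                if sid not in idx:
                    raise ModelStructureError(
                        f"reaction {rxn.id!r}: stoichiometry references"
                        f" unknown species {sid!r}"
                    )
            self.catalyzing_enzyme(rxn)  # raises on dangling reference
        for gp in self.gene_products:
            if gp.associated_species not in idx:
                raise ModelStructureError(
                    f"gene product {gp.id!r}: associated species"
                    f" {gp.associated_species!r} does not exist"
                )
            if self.species[idx[gp.associated_species]].species_type != "enzyme":
                raise ModelStructureError(
                    f"gene product {gp.id!r}: associated species"
                    f" {gp.associated_species!r} is not an enzyme"
                )

    # -- matrices ----------------------------------------------------------

    def stoichiometric_matrix(self) -> np.ndarray:
        """Dense n x r stoichiometric matrix in model order."""
        S = np.zeros((self.n, self.r))
        idx = self.species_index()
        for j, rxn in enumerate(self.reactions):
            for sid, coeff in rxn.stoichiometry.items():
                S[idx[sid], j] = coeff
        return S


# ---------------------------------------------------------------------------
# partitioning
# ---------------------------------------------------------------------------

_TYPE_TO_GROUP = {
    "extracellular": "Y",
    "metabolite": "X",
    "storage": "C",
    "enzyme": "P",
    "quota": "P",
}


def partition_model(model: RAMModel) -> ModelPartition:
    """Partition species into Y/X/C/P and reactions into R_y/R_x/R_c/R_p.

    Reactions are classified from the species types they touch: any contact
    with an extracellular species makes a reaction an exchange reaction
    (R_y); otherwise producing a macromolecule makes it a synthesis reaction
    (R_p); otherwise touching storage makes it a storage reaction (R_c); the
    remainder are metabolic (R_x).  A reaction that couples the environment
    directly to macromolecules or storage has no consistent class and raises
    :class:`ClassificationError`.
    """
    model.validate()
    groups: Dict[str, List[int]] = {"Y": [], "X": [], "C": [], "P": []}
    for i, sp in enumerate(model.species):
        groups[_TYPE_TO_GROUP[sp.species_type]].append(i)

    idx = model.species_index()
    rgroups: Dict[str, List[int]] = {"R_y": [], "R_x": [], "R_c": [], "R_p": []}
    for j, rxn in enumerate(model.reactions):
        touched = {
            model.species[idx[sid]].species_type: None for sid in rxn.stoichiometry
        }
        produces_macro = any(
            coeff > 0
            and model.species[idx[sid]].species_type in ("enzyme", "quota")
            for sid, coeff in rxn.stoichiometry.items()
        )
        if "extracellular" in touched:
            if {"enzyme", "quota", "storage"} & set(touched):
                raise ClassificationError(
                    f"reaction {rxn.id!r} couples extracellular species"
                    " directly to macromolecules or storage and cannot be"
                    " classified"
                )
            rgroups["R_y"].append(j)
        elif produces_macro:
            rgroups["R_p"].append(j)
        elif "storage" in touched:
            rgroups["R_c"].append(j)
        else:
            rgroups["R_x"].append(j)
    return ModelPartition(
        Y=groups["Y"], X=groups["X"], C=groups["C"], P=groups["P"], **rgroups
    )


# ---------------------------------------------------------------------------
# constraint matrices
# ---------------------------------------------------------------------------


@dataclass
class ConstraintMatrices:
    """All constraint matrices derived from one model.

    ``flux_columns`` lists the columns of the sign-split flux basis as
    ``(reaction_id, sign)`` pairs: each reversible reaction contributes a
    ``+1`` and a ``-1`` column (``v = v_plus - v_minus``, both nonnegative),
    irreversible reactions a single ``+1`` column.  ``S_split`` and ``HC``
    are expressed over this basis; ``S`` is over plain net fluxes.

    ``HB`` and ``HM`` act on the stacked amount vector ``[c; p]`` in
    partition order.
    """

    model: RAMModel
    partition: ModelPartition
    S: np.ndarray
    S_split: np.ndarray
    flux_columns: List[Tuple[str, int]]
    HC: np.ndarray
    HE: np.ndarray
    enzyme_rows: List[str]
    HB: np.ndarray
    quota_rows: List[str]
    HM: np.ndarray
    maintenance_rows: List[str]

    def split_to_net(self, v_split: np.ndarray) -> np.ndarray:
        """Collapse a sign-split flux vector back to net fluxes (model order)."""
        ridx = self.model.reaction_index()
        v = np.zeros(self.model.r)
        for col, (rid, sign) in enumerate(self.flux_columns):
            v[ridx[rid]] += sign * v_split[..., col]
        return v

    def net_to_split(self, v: np.ndarray) -> np.ndarray:
        """Decompose net fluxes into the nonnegative sign-split basis."""
        ridx = self.model.reaction_index()
        out = np.zeros(len(self.flux_columns))
        for col, (rid, sign) in enumerate(self.flux_columns):
            val = v[ridx[rid]]
            out[col] = max(sign * val, 0.0)
        return out


def _split_columns(model: RAMModel) -> List[Tuple[str, int]]:
    cols: List[Tuple[str, int]] = []
    for rxn in model.reactions:
        cols.append((rxn.id, +1))
        if rxn.reversible:
            cols.append((rxn.id, -1))
    return cols


def build_capacity_matrices(
    model: RAMModel, partition: Optional[ModelPartition] = None
) -> Tuple[np.ndarray, np.ndarray, List[str], List[Tuple[str, int]]]:
    """Build the enzyme-capacity pair ``(HC, HE)``.

    One row per catalytically active enzyme: the row of ``HC`` holds
    ``1/kcat`` for every sign-split flux column of the reactions the enzyme
    catalyzes (forward columns use the forward constant, backward columns the
    backward constant), so that ``HC v_split <= HE p`` bounds both directions
    of every catalyzed flux by the enzyme amount.  ``HE`` is a filter matrix
    with exactly one entry equal to 1 per row, selecting the enzyme.

    Returns ``(HC, HE, enzyme_row_ids, flux_columns)``.
    """
    if partition is None:
        partition = partition_model(model)
    cols = _split_columns(model)
    col_index: Dict[Tuple[str, int], int] = {c: i for i, c in enumerate(cols)}
    cat = model.catalysis_map()
    p_ids = [model.species[i].id for i in partition.P]
    p_pos = {sid: k for k, sid in enumerate(p_ids)}

    enzyme_rows = [sid for sid in p_ids if sid in cat]
    HC = np.zeros((len(enzyme_rows), len(cols)))
    HE = np.zeros((len(enzyme_rows), len(p_ids)))
    for row, enz in enumerate(enzyme_rows):
        HE[row, p_pos[enz]] = 1.0
        for rid in cat[enz]:
            rxn = model.reaction_by_id(rid)
            if rxn.kcat_forward <= 0.0:
                raise ParameterizationError(
                    f"reaction {rid!r} is catalyzed but has no forward"
                    " turnover number"
                )
            HC[row, col_index[(rid, +1)]] = 1.0 / rxn.kcat_forward
            if rxn.reversible:
                if rxn.kcat_backward <= 0.0:
                    raise ParameterizationError(
                        f"reaction {rid!r} is reversible and catalyzed but"
                        " has no backward turnover number"
                    )
                HC[row, col_index[(rid, -1)]] = 1.0 / rxn.kcat_backward
    return HC, HE, enzyme_rows, cols


def _biomass_weight_row(model: RAMModel, partition: ModelPartition) -> np.ndarray:
    """Row vector over ``[c; p]`` whose dot product is total biomass B_t.

    Storage contributes its molecular weight, macromolecules their objective
    weight, following the objective-biomass definition extended by storage.
    """
    w_c = np.array([model.species[i].molecular_weight for i in partition.C])
    b_p = np.array([model.species[i].objective_weight for i in partition.P])
    return np.concatenate([w_c, b_p])


def build_biomass_composition_matrix(
    model: RAMModel, partition: Optional[ModelPartition] = None
) -> Tuple[np.ndarray, List[str]]:
    """Build the biomass-composition (quota) matrix ``HB``.

    One row per quota species ``s`` encoding
    ``phi_s * B_t - w_s * p_s <= 0``  i.e.  ``w_s p_s >= phi_s B_t``
    over the stacked amount vector ``[c; p]``.
    """
    if partition is None:
        partition = partition_model(model)
    bt_row = _biomass_weight_row(model, partition)
    n_c = len(partition.C)
    p_ids = [model.species[i].id for i in partition.P]
    quota_rows = [
        model.species[i].id
        for i in partition.P
        if model.species[i].species_type == "quota"
    ]
    HB = np.zeros((len(quota_rows), n_c + len(p_ids)))
    for row, sid in enumerate(quota_rows):
        sp = model.species_by_id(sid)
        if sp.molecular_weight <= 0.0:
            raise ParameterizationError(
                f"quota species {sid!r} has no molecular weight"
            )
        HB[row, :] = sp.biomass_percentage * bt_row
        HB[row, n_c + p_ids.index(sid)] -= sp.molecular_weight
    return HB, quota_rows


def build_maintenance_matrix(
    model: RAMModel, partition: Optional[ModelPartition] = None
) -> Tuple[np.ndarray, List[str]]:
    """Build the maintenance matrix ``HM`` and the affected reactions.

    One row per reaction with ``psi_m > 0``:
    ``v_m >= psi_m * B_t = HM [c; p]`` (row = ``psi_m`` times the biomass
    weight row).  Returns ``(HM, maintenance_reaction_ids)``; both are empty
    when no maintenance coefficient is set.
    """
    if partition is None:
        partition = partition_model(model)
    bt_row = _biomass_weight_row(model, partition)
    maint = [r for r in model.reactions if r.maintenance_scaling > 0.0]
    HM = np.zeros((len(maint), bt_row.size))
    for row, rxn in enumerate(maint):
        HM[row, :] = rxn.maintenance_scaling * bt_row
    return HM, [r.id for r in maint]


def build_constraint_matrices(model: RAMModel) -> ConstraintMatrices:
    """Assemble every constraint matrix for a model in one pass."""
    partition = partition_model(model)
    S = model.stoichiometric_matrix()
    cols = _split_columns(model)
    ridx = model.reaction_index()
    S_split = np.column_stack(
        [sign * S[:, ridx[rid]] for rid, sign in cols]
    ) if cols else np.zeros((model.n, 0))
    HC, HE, enzyme_rows, _ = build_capacity_matrices(model, partition)
    HB, quota_rows = build_biomass_composition_matrix(model, partition)
    HM, maintenance_rows = build_maintenance_matrix(model, partition)
    return ConstraintMatrices(
        model=model,
        partition=partition,
        S=S,
        S_split=S_split,
        flux_columns=cols,
        HC=HC,
        HE=HE,
        enzyme_rows=enzyme_rows,
        HB=HB,
        quota_rows=quota_rows,
        HM=HM,
        maintenance_rows=maintenance_rows,
    )


# ---------------------------------------------------------------------------
# biomass functionals
# ---------------------------------------------------------------------------


def objective_biomass(
    model: RAMModel, p: Sequence[float], partition: Optional[ModelPartition] = None
) -> float:
    """Objective biomass ``B_o = b_P . p`` in grams.

    ``p`` is the macromolecule amount vector in partition order.
    """
    if partition is None:
        partition = partition_model(model)
    p = np.asarray(p, dtype=float)
    if p.shape != (len(partition.P),):
        raise DomainError(
            f"expected {len(partition.P)} macromolecule amounts, got {p.shape}"
        )
    if np.any(p < 0):
        raise DomainError("negative macromolecule amounts")
    b = np.array([model.species[i].objective_weight for i in partition.P])
    return float(b @ p)


def total_biomass(
    model: RAMModel,
    c: Sequence[float],
    p: Sequence[float],
    partition: Optional[ModelPartition] = None,
) -> float:
    """Total biomass ``B_t = B_o + w_C . c`` in grams (storage included)."""
    if partition is None:
        partition = partition_model(model)
    c = np.asarray(c, dtype=float)
    if c.shape != (len(partition.C),):
        raise DomainError(
            f"expected {len(partition.C)} storage amounts, got {c.shape}"
        )
    if np.any(c < 0):
        raise DomainError("negative storage amounts")
    w = np.array([model.species[i].molecular_weight for i in partition.C])
    return objective_biomass(model, p, partition) + float(w @ c)
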