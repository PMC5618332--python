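"""Construction of macromolecule synthesis reactions, quota compounds and
turnover-number assignments.

This module turns the raw ingredients of a resource-allocation model —
amino-acid sequences, subunit stoichiometries, biomass-reaction
coefficients, candidate turnover numbers — into the synthesis reactions and
parameters the core model needs:

* per-gene amino-acid counts and protein synthesis reactions, including
  homo-oligomers and multi-gene complexes with per-subunit copy numbers;
* translation energy in a detailed mode (per residue: 1 ATP -> AMP + PPi and
  2 GTP -> 2 GDP + 2 Pi) or a lumped mode (a single ATP charge proportional
  to chain length, for models that do not track GTP);
* ribosome turnover numbers ``kcat = a / l`` from the elongation rate ``a``
  (aa/s) and the protein length ``l``;
* isoenzyme splitting (one reaction copy per catalyzing enzyme) and
  per-compartment enzyme duplication with deterministic ids;
* lumped quota reactions normalized so one quota unit weighs exactly 1 g,
  with the protein-quota fraction adjusted for explicitly modeled enzymes;
* turnover-number aggregation (median/mean) over filtered database
  observations, with a same-organism-first fallback chain.
"""

from __future__ import annotations

import logging
import statistics
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, NamedTuple, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import GeneProduct, RAMModel, ReactionRecord
from .errors import DomainError, MissingKcatError, ModelStructureError, ParseError

logger = logging.getLogger(__name__)

__all__ = [
    "AMINO_ACIDS",
    "DEFAULT_RESIDUE_SPECIES",
    "ProteinSpec",
    "EnergyModel",
    "QuotaSpec",
    "KcatObservation",
    "QuotaKcat",
    "amino_acid_counts",
    "protein_synthesis_reaction",
    "ribosome_kcat",
    "split_isoenzyme_reactions",
    "duplicate_enzyme_per_compartment",
    "make_enzyme_id",
    "build_quota_reaction",
    "adjust_protein_quota",
    "quota_reaction_kcat",
    "aggregate_kcat",
    "select_kcat",
    "read_fasta",
    "read_subunit_table",
    "read_kcat_table",
    "explicit_protein_fraction",
]

#: The 20 standard amino-acid one-letter codes.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Default mapping from one-letter residue codes to metabolite species ids.
#: Builders targeting a specific reconstruction pass their own namespace map.
DEFAULT_RESIDUE_SPECIES: Dict[str, str] = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "E": "Glu", "Q": "Gln", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
}

#: Nearest-standard-residue replacements for ambiguity codes, applied only
#: when explicitly requested.
AMBIGUITY_MAP: Dict[str, str] = {"B": "D", "Z": "E", "U": "C", "X": "A"}


@dataclass
class ProteinSpec:
    """Recipe for one enzyme (or enzyme complex).

    ``subunits`` lists ``(gene_id, amino_acid_sequence, copy_number)``
    triples; a homotrimer is a single subunit with copy number 3, a complex
    of two dimers is two subunits with copy number 2 each.  ``compartments``
    holds one id for resident enzymes and two for transporters.
    """

    enzyme_id: str
    subunits: List[Tuple[str, str, int]]
    compartments: List[str] = field(default_factory=lambda: ["cytosol"])

    def __post_init__(self) -> None:
        for gene, _seq, copies in self.subunits:
            if not (isinstance(copies, int) and copies >= 1):
                raise ModelStructureError(
                    f"enzyme {self.enzyme_id!r}: subunit {gene!r} has invalid"
                    f" copy number {copies!r} (positive integer required)"
                )


@dataclass
class EnergyModel:
    """Translation energy accounting.

    ``detailed`` charges, per residue added, 1 ATP hydrolyzed to AMP + PPi
    (charging) and 2 GTP hydrolyzed to 2 GDP + 2 Pi (elongation).
    ``lumped`` charges ``atp_per_aa`` ATP -> ADP + Pi per residue, for
    small-scale models that do not resolve GTP; the default of 4 counts the
    three detailed hydrolysis events plus one for charging at the same cost.
    """

    mode: str = "detailed"
    atp_per_aa: float = 4.0

    def __post_init__(self) -> None:
        if self.mode not in ("detailed", "lumped"):
            raise DomainError(f"unknown energy mode {self.mode!r}")
        if self.atp_per_aa < 0:
            raise DomainError("negative ATP cost per amino acid")


@dataclass
class QuotaSpec:
    """A lumped quota compound assembled from biomass-reaction coefficients.

    ``components`` maps precursor species ids to their biomass-reaction
    coefficients ``S_i`` (mmol per gram dry weight); ``byproducts`` maps
    released species (e.g. uncharged tRNAs) to their coefficients.
    ``weights`` gives the mass each species contributes per mmol consumed
    (g/mmol); byproducts default to zero weight, i.e. the component weights
    are understood as net (residue) masses.
    """

    quota_id: str
    components: Dict[str, float]
    weights: Dict[str, float]
    byproducts: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sid, coeff in {**self.components, **self.byproducts}.items():
            if coeff <= 0:
                raise DomainError(
                    f"quota {self.quota_id!r}: nonpositive coefficient for {sid!r}"
                )
        for sid in self.components:
            if self.weights.get(sid, 0.0) < 0:
                raise DomainError(
                    f"quota {self.quota_id!r}: negative weight for {sid!r}"
                )


@dataclass
class KcatObservation:
    """One candidate turnover number from a database or the literature."""

    reaction_or_ec: str
    organism: str
    value: float
    wild_type: bool = True

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise DomainError(
                f"turnover observation for {self.reaction_or_ec!r}:"
                f" nonpositive value {self.value}"
            )


class QuotaKcat(NamedTuple):
    """Turnover number of a lumped quota synthesis reaction.

    Because the quota reaction consumes a whole gram-normalized bundle of
    residues per unit, the unit is 1/(mmol*h), not 1/h.
    """

    value: float
    unit: str = "1/(mmol*h)"


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------


def amino_acid_counts(
    sequence: str,
    *,
    strip_stop: bool = True,
    map_ambiguous: bool = False,
) -> Tuple[Counter, int]:
    """Count residues in an amino-acid sequence.

    Returns ``(counts, length)`` with ``sum(counts.values()) == length``.
    ``*`` stop characters are stripped when ``strip_stop`` is set; ambiguity
    codes (B, Z, X, U) raise :class:`ParseError` unless ``map_ambiguous``
    replaces them by their nearest standard residue.
    """
    seq = str(sequence).upper()
    if strip_stop:
        seq = seq.replace("*", "")
    counts: Counter = Counter()
    for pos, ch in enumerate(seq):
        if ch in AMBIGUITY_MAP and map_ambiguous:
            ch = AMBIGUITY_MAP[ch]
        if ch not in AMINO_ACIDS:
            raise ParseError(
                f"illegal residue {ch!r} at position {pos} in sequence"
            )
        counts[ch] += 1
    return counts, sum(counts.values())


# ---------------------------------------------------------------------------
# protein synthesis reactions
# ---------------------------------------------------------------------------

_DETAILED_COFACTORS = {
    "ATP": -1.0, "GTP": -2.0,        # consumed per residue
    "AMP": 1.0, "PPi": 1.0, "GDP": 2.0, "Pi": 2.0,  # released per residue
}


def protein_synthesis_reaction(
    spec: ProteinSpec,
    energy: Optional[EnergyModel] = None,
    *,
    residue_species: Optional[Mapping[str, str]] = None,
    cofactor_species: Optional[Mapping[str, Optional[str]]] = None,
    catalyzed_by: Optional[str] = None,
    kcat: float = 0.0,
    map_ambiguous: bool = False,
) -> ReactionRecord:
    """Build the synthesis reaction for one enzyme.

    Reactants are the per-gene residue counts multiplied by the subunit copy
    numbers and summed over subunits, mapped to metabolite ids through
    ``residue_species`` (default: three-letter residue names).  Energy
    cofactors scale with the copies-weighted total residue count.  The
    product is one unit of the enzyme species; the reaction id is
    ``synth_<enzyme_id>``.

    ``cofactor_species`` can rename cofactor ids (keys ATP/GTP/AMP/ADP/PPi/
    GDP/Pi); mapping a *byproduct* id to ``None`` drops it, for models that
    do not track it.  ``catalyzed_by`` sets the gene product reference
    (typically the ribosome) and ``kcat`` its forward turnover number.
    """
    if not spec.subunits:
        raise ModelStructureError(
            f"enzyme {spec.enzyme_id!r}: empty subunit list"
        )
    energy = energy or EnergyModel()
    residues = dict(DEFAULT_RESIDUE_SPECIES)
    if residue_species:
        residues.update(residue_species)
    cof: Dict[str, Optional[str]] = {
        k: k for k in ("ATP", "GTP", "AMP", "ADP", "PPi", "GDP", "Pi")
    }
    if cofactor_species:
        cof.update(cofactor_species)

    stoich: Dict[str, float] = {}
    total_residues = 0.0
    for gene, seq, copies in spec.subunits:
        counts, length = amino_acid_counts(seq, map_ambiguous=map_ambiguous)
        total_residues += copies * length
        for res, cnt in counts.items():
            sid = residues[res]
            stoich[sid] = stoich.get(sid, 0.0) - copies * cnt

    def _charge(key: str, coeff_per_aa: float) -> None:
        sid = cof.get(key)
        coeff = coeff_per_aa * total_residues
        if coeff == 0.0:
            return
        if sid is None:
            if coeff_per_aa < 0:
                raise ModelStructureError(
                    f"enzyme {spec.enzyme_id!r}: consumed cofactor {key!r}"
                    " cannot be dropped from the model"
                )
            return  # unmodeled byproduct
        stoich[sid] = stoich.get(sid, 0.0) + coeff

    if energy.mode == "detailed":
        for key, per_aa in _DETAILED_COFACTORS.items():
            _charge(key, per_aa)
    else:
        _charge("ATP", -energy.atp_per_aa)
        _charge("ADP", energy.atp_per_aa)
        _charge("Pi", energy.atp_per_aa)

    stoich[spec.enzyme_id] = stoich.get(spec.enzyme_id, 0.0) + 1.0
    return ReactionRecord(
        id=f"synth_{spec.enzyme_id}",
        stoichiometry=stoich,
        reversible=False,
        kcat_forward=kcat,
        gene_product=catalyzed_by,
    )


def ribosome_kcat(a: float, l: float) -> float:
    """Ribosome turnover number for translating one protein, in 1/h.

    ``a`` is the ribosome elongation rate in amino acids per *second*, ``l``
    the protein length in amino acids; ``kcat = a / l`` converted to hours:
    a 100-residue protein at 15 aa/s is produced at 540 enzyme units per
    hour and ribosome unit.
    """
    if a <= 0 or l <= 0:
        raise DomainError("elongation rate and protein length must be positive")
    return 3600.0 * a / l


# ---------------------------------------------------------------------------
# isoenzymes and compartments
# ---------------------------------------------------------------------------


def split_isoenzyme_reactions(
    model: RAMModel, mapping: Mapping[str, Sequence[str]]
) -> RAMModel:
    """Split reactions catalyzed by several isoenzymes into identical copies.

    ``mapping`` maps reaction ids to the list of catalyzing enzyme species;
    each listed reaction is replaced by one copy per enzyme (ids
    ``<rid>_iso1``, ``<rid>_iso2``, ...), each catalyzed by exactly one gene
    product.  Gene products are created for enzymes that lack one.
    Reactions not listed (or listed with a single enzyme) keep their id.
    """
    sidx = model.species_index()
    for rid, enzymes in mapping.items():
        model.reaction_by_id(rid)
        for enz in enzymes:
            if enz not in sidx or model.species[sidx[enz]].species_type != "enzyme":
                raise ModelStructureError(
                    f"isoenzyme split of {rid!r}: unknown enzyme {enz!r}"
                )

    out = model.copy()
    gp_for_species = {g.associated_species: g.id for g in out.gene_products}

    def _gene_product(enz: str) -> str:
        if enz not in gp_for_species:
            gid = f"gp_{enz}"
            out.gene_products.append(GeneProduct(id=gid, associated_species=enz))
            gp_for_species[enz] = gid
        return gp_for_species[enz]

    new_reactions: List[ReactionRecord] = []
    for rxn in out.reactions:
        enzymes = list(mapping.get(rxn.id, ()))
        if len(enzymes) <= 1:
            if enzymes:
                rxn = replace(rxn, gene_product=_gene_product(enzymes[0]))
            new_reactions.append(rxn)
            continue
        for k, enz in enumerate(enzymes, start=1):
            new_reactions.append(
                replace(
                    rxn,
                    id=f"{rxn.id}_iso{k}",
                    stoichiometry=dict(rxn.stoichiometry),
                    gene_product=_gene_product(enz),
                )
            )
    out.reactions = new_reactions
    out.validate()
    return out


def make_enzyme_id(main_id: str, compartments) -> str:
    """Deterministic enzyme id combining the main id and acting compartments.

    Resident enzymes get ``<main>_<compartment>``; transporters spanning two
    compartments get ``<main>_<comp1>_<comp2>``.
    """
    if isinstance(compartments, str):
        compartments = [compartments]
    if not compartments:
        raise DomainError(f"enzyme {main_id!r}: no compartments given")
    return "_".join([main_id, *compartments])


def duplicate_enzyme_per_compartment(
    spec: ProteinSpec, compartments: Optional[Sequence[str]] = None
) -> List[ProteinSpec]:
    """One ProteinSpec per compartment an enzyme acts in.

    Identical enzymes acting in several compartments (e.g. cytosolic and
    mitochondrial fumarase) cannot share one species, because an enzyme in
    one compartment cannot catalyze in another.  Each returned spec keeps
    the subunit recipe, acts in a single compartment, and carries a unique
    compartment-suffixed id.  With one compartment the spec is returned
    as-is (transporters, which span two compartments as one species, should
    not be passed through this helper).
    """
    comps = list(compartments) if compartments is not None else list(spec.compartments)
    if len(comps) <= 1:
        return [spec]
    return [
        ProteinSpec(
            enzyme_id=make_enzyme_id(spec.enzyme_id, comp),
            subunits=[tuple(s) for s in spec.subunits],
            compartments=[comp],
        )
        for comp in comps
    ]


# ---------------------------------------------------------------------------
# quota compounds
# ---------------------------------------------------------------------------


def build_quota_reaction(
    quota: QuotaSpec,
    polymerization_energy: Optional[Mapping[str, float]] = None,
) -> Tuple[ReactionRecord, float]:
    """Build the normalized lumped synthesis reaction for a quota compound.

    The biomass fraction is ``phi = sum_i S_i * w_i`` over the components;
    all component, byproduct and polymerization-energy coefficients are
    divided by ``phi`` so one unit of the quota compound weighs exactly
    1 g.  ``polymerization_energy`` is a signed stoichiometry map (negative
    consumed, positive released), likewise scaled by ``1/phi``.

    Returns ``(reaction, phi)``; the reaction is spontaneous as built, and
    callers producing a ribosome-catalyzed protein quota set its gene
    product and :func:`quota_reaction_kcat` afterwards.
    """
    phi = sum(
        coeff * quota.weights.get(sid, 0.0)
        for sid, coeff in quota.components.items()
    )
    phi -= sum(
        coeff * quota.weights.get(sid, 0.0)
        for sid, coeff in quota.byproducts.items()
    )
    if phi <= 0:
        raise DomainError(
            f"quota {quota.quota_id!r}: zero or negative total mass fraction"
        )
    stoich: Dict[str, float] = {}
    for sid, coeff in quota.components.items():
        stoich[sid] = stoich.get(sid, 0.0) - coeff / phi
    for sid, coeff in quota.byproducts.items():
        stoich[sid] = stoich.get(sid, 0.0) + coeff / phi
    for sid, coeff in (polymerization_energy or {}).items():
        stoich[sid] = stoich.get(sid, 0.0) + coeff / phi
    stoich[quota.quota_id] = stoich.get(quota.quota_id, 0.0) + 1.0
    rxn = ReactionRecord(
        id=f"synth_{quota.quota_id}",
        stoichiometry=stoich,
        reversible=False,
    )
    return rxn, phi


def adjust_protein_quota(phi_protein: float, explicit_fraction: float) -> float:
    """Reduce the protein-quota fraction by the explicitly modeled share.

    ``explicit_fraction`` (``fe``) is the mass fraction of the proteome that
    the model carries explicitly as enzymes/ribosome; the quota keeps the
    noncatalytic remainder ``phi_protein * (1 - fe)``.
    """
    if not 0.0 <= explicit_fraction <= 1.0:
        raise DomainError("explicit proteome fraction must lie in [0, 1]")
    return phi_protein * (1.0 - explicit_fraction)


def quota_reaction_kcat(a: float, total_aa_coefficient: float) -> QuotaKcat:
    """Ribosome turnover number for a lumped (normalized) quota reaction.

    The "protein length" of the lumped reaction is the sum of its amino-acid
    stoichiometric coefficients (mmol per quota unit), so the resulting rate
    carries the non-standard unit 1/(mmol*h).
    """
    if a <= 0 or total_aa_coefficient <= 0:
        raise DomainError(
            "elongation rate and total amino-acid coefficient must be positive"
        )
    return QuotaKcat(value=3600.0 * a / total_aa_coefficient)


# ---------------------------------------------------------------------------
# turnover-number aggregation
# ---------------------------------------------------------------------------


def aggregate_kcat(
    observations: Iterable[KcatObservation],
    strategy: str = "median",
    *,
    wild_type_only: bool = True,
) -> float:
    """Aggregate candidate turnover numbers into one value (1/h).

    Observations are filtered to wild-type entries by default; the median
    (recommended) or mean of the remaining values is returned.  An empty set
    after filtering raises :class:`MissingKcatError` so the caller can apply
    its own fallback.
    """
    if strategy not in ("median", "mean"):
        raise DomainError(f"unknown aggregation strategy {strategy!r}")
    values = [
        o.value for o in observations if (o.wild_type or not wild_type_only)
    ]
    if not values:
        raise MissingKcatError("no usable turnover-rate observations")
    return float(statistics.median(values) if strategy == "median" else
                 statistics.fmean(values))


def select_kcat(
    observations: Iterable[KcatObservation],
    organism: str,
    default: Optional[float] = None,
    strategy: str = "median",
) -> float:
    """Pick a turnover number with a same-organism-first fallback chain.

    1. aggregate over wild-type observations from ``organism``;
    2. else aggregate over wild-type observations from all other organisms
       (their enzyme-wise median approximates the native value best);
    3. else fall back to ``default``.

    Each fallback step is logged; with no observations and no default a
    :class:`MissingKcatError` propagates.
    """
    obs = list(observations)
    own = [o for o in obs if o.organism == organism]
    if any(o.wild_type for o in own):
        return aggregate_kcat(own, strategy)
    others = [o for o in obs if o.organism != organism]
    if any(o.wild_type for o in others):
        logger.info(
            "no wild-type turnover data for %s; falling back to the %s over"
            " %d other-organism observations",
            organism, strategy, len(others),
        )
        return aggregate_kcat(others, strategy)
    if default is not None:
        logger.warning(
            "no turnover data at all for %s; using default %g 1/h",
            organism, default,
        )
        return float(default)
    raise MissingKcatError(
        f"no turnover-rate observations for {organism!r} and no default given"
    )


# ---------------------------------------------------------------------------
# external table/sequence interfaces
# ---------------------------------------------------------------------------


def read_fasta(source) -> Dict[str, str]:
    """Read a multi-record amino-acid FASTA file into ``{id: sequence}``."""
    from Bio import SeqIO

    records = {}
    for rec in SeqIO.parse(source, "fasta"):
        records[rec.id] = str(rec.seq)
    return records


def read_subunit_table(source) -> Dict[str, List[Tuple[str, int]]]:
    """Read a subunit-stoichiometry table.

    Expected delimited columns: ``enzyme``, ``gene``, ``copies``.  Returns
    ``{enzyme_id: [(gene_id, copy_number), ...]}``.
    """
    df = pd.read_csv(source, sep=None, engine="python")
    required = {"enzyme", "gene", "copies"}
    if not required.issubset(df.columns):
        raise ParseError(
            f"subunit table must have columns {sorted(required)},"
            f" got {list(df.columns)}"
        )
    out: Dict[str, List[Tuple[str, int]]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["enzyme"]), []).append(
            (str(row["gene"]), int(row["copies"]))
        )
    return out


def read_kcat_table(source) -> List[KcatObservation]:
    """Read candidate turnover numbers from a delimited table.

    Expected columns: ``reaction_or_ec``, ``organism``, ``value`` (1/h) and
    optionally ``wild_type`` (boolean, default true).
    """
    df = pd.read_csv(source, sep=None, engine="python")
    required = {"reaction_or_ec", "organism", "value"}
    if not required.issubset(df.columns):
        raise ParseError(
            f"kcat table must have columns {sorted(required)},"
            f" got {list(df.columns)}"
        )
    obs = []
    for _, row in df.iterrows():
        wt = bool(row["wild_type"]) if "wild_type" in df.columns else True
        obs.append(
            KcatObservation(
                reaction_or_ec=str(row["reaction_or_ec"]),
                organism=str(row["organism"]),
                value=float(row["value"]),
                wild_type=wt,
            )
        )
    return obs


def explicit_protein_fraction(
    abundances: Mapping[str, float], modeled_genes: Iterable[str]
) -> float:
    """Mass fraction ``fe`` of the proteome modeled explicitly as enzymes.

    ``abundances`` maps gene/protein ids to quantitative-proteomics mass
    abundances (any common scale); they are normalized to sum to one and the
    share of ``modeled_genes`` is returned.  Use the result with
    :func:`adjust_protein_quota`.
    """
    total = float(sum(abundances.values()))
    if total <= 0:
        raise DomainError("proteomics abundances sum to zero")
    modeled = set(modeled_genes)
    fe = sum(v for k, v in abundances.items() if k in modeled) / total
    return float(fe)
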