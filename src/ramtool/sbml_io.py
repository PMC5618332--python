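"""Reader, writer and validator for the resource-allocation SBML dialect.

Models are exchanged as SBML Level 3 Version 1 documents using the Flux
Balance Constraints package (version 2) plus a small ``ram:*`` annotation
layer (namespace ``https://www.fairdomhub.org/sops/304``):

* every species carries ``ram:speciesType`` (extracellular | metabolite |
  storage | enzyme | quota); biomass species (storage, enzyme, quota)
  additionally carry ``ram:molecularWeight``, ``ram:objectiveWeight`` and
  ``ram:biomassPercentage``;
* every reaction carries ``ram:kcatForward``, ``ram:kcatBackward`` and
  ``ram:maintenanceScaling``; irreversible reactions resolve their backward
  turnover number to zero;
* all ram numeric attributes hold either a literal number or the id of a
  declared model parameter (``weight_R``, ``kcat2``, ``zero``, ...);
* catalysis is a single ``fbc:geneProductRef`` per reaction — complexes are
  pre-resolved into one gene product, isoenzymes pre-split into reaction
  copies — and reactions without a gene-product association are spontaneous;
* nonlimiting extracellular species have ``boundaryCondition="true"`` (and
  ``constant="true"`` unless driven by external processes); all other
  species have both flags false.

The writer emits numeric ram attributes as parameter references
(``weight_<species>``, ``bp_<species>``, ``kcat_fwd_<reaction>``,
``kcat_bwd_<reaction>``, ``psi_<reaction>``, plus a shared ``zero``); the
reader accepts literals and references interchangeably.  Unknown foreign
annotations are carried through round trips opaquely.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import libsbml

from .core import (
    BIOMASS_TYPES,
    GeneProduct,
    RAMModel,
    ReactionRecord,
    SPECIES_TYPES,
    SpeciesRecord,
)
from .errors import ParseError, SBMLValidationError

__all__ = [
    "RAM_NS",
    "Finding",
    "write_ram_sbml",
    "read_ram_sbml",
    "validate_ram_document",
]

#: Namespace of the resource-allocation annotation layer.
RAM_NS = "https://www.fairdomhub.org/sops/304"

_EC_PREFIXES = (
    "http://identifiers.org/ec-code/",
    "https://identifiers.org/ec-code/",
    "urn:miriam:ec-code:",
)


@dataclass
class Finding:
    """One located validation finding."""

    severity: str  # "error" | "warning"
    rule: str
    element: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.severity}] {self.rule} at {self.element}: {self.message}"


# ---------------------------------------------------------------------------
# writer
# ---------------------------------------------------------------------------


def _fmt(x: float) -> str:
    return repr(float(x))


class _ParameterPool:
    """Deduplicating registry of SBML parameters for ram attribute values."""

    def __init__(self, sbml_model: libsbml.Model) -> None:
        self._model = sbml_model
        self._declared: Dict[str, float] = {}
        self.declare("zero", 0.0)

    def declare(self, pid: str, value: float) -> str:
        if pid not in self._declared:
            par = self._model.createParameter()
            par.setId(pid)
            par.setValue(float(value))
            par.setConstant(True)
            self._declared[pid] = float(value)
        return pid

    def ref(self, pid: str, value: float) -> str:
        """Parameter reference for a value, collapsing zeros onto ``zero``."""
        if value == 0.0:
            return "zero"
        return self.declare(pid, value)


def _species_annotation(sp: SpeciesRecord, pool: _ParameterPool) -> str:
    attrs = [f'ram:speciesType="{sp.species_type}"']
    if sp.species_type in BIOMASS_TYPES:
        w = pool.ref(f"weight_{sp.id}", sp.molecular_weight)
        if sp.objective_weight == sp.molecular_weight:
            b = w
        else:
            b = pool.ref(f"ow_{sp.id}", sp.objective_weight)
        bp = pool.ref(f"bp_{sp.id}", sp.biomass_percentage)
        attrs = [
            f'ram:molecularWeight="{w}"',
            f'ram:objectiveWeight="{b}"',
            f'ram:biomassPercentage="{bp}"',
        ] + attrs
    return (
        f'<ram:RAM xmlns:ram="{RAM_NS}">'
        f'<ram:species {" ".join(attrs)}/>'
        "</ram:RAM>"
    )


def _reaction_annotation(rxn: ReactionRecord, pool: _ParameterPool) -> str:
    kf = pool.ref(f"kcat_fwd_{rxn.id}", rxn.kcat_forward)
    kb = pool.ref(f"kcat_bwd_{rxn.id}", rxn.kcat_backward)
    psi = pool.ref(f"psi_{rxn.id}", rxn.maintenance_scaling)
    return (
        f'<ram:RAM xmlns:ram="{RAM_NS}">'
        f'<ram:reaction ram:kcatForward="{kf}" ram:kcatBackward="{kb}"'
        f' ram:maintenanceScaling="{psi}"/>'
        "</ram:RAM>"
    )


def write_ram_sbml(model: RAMModel, destination: Optional[str] = None) -> str:
    """Serialize a model to the resource-allocation SBML dialect.

    Returns the XML string; when ``destination`` is given the document is
    also written to that path.
    """
    model.validate()
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    sm.setId(model.id)
    if model.name:
        sm.setName(model.name)
    mfbc = sm.getPlugin("fbc")
    mfbc.setStrict(False)

    for comp_id in dict.fromkeys(s.compartment for s in model.species):
        comp = sm.createCompartment()
        comp.setId(comp_id)
        comp.setConstant(True)
        comp.setSize(1.0)
        comp.setSpatialDimensions(3)

    pool = _ParameterPool(sm)

    for sp in model.species:
        el = sm.createSpecies()
        el.setId(sp.id)
        if sp.name:
            el.setName(sp.name)
        el.setCompartment(sp.compartment)
        # flag rules: only nonlimiting extracellular species sit on the
        # boundary, and only those may be constant
        el.setBoundaryCondition(bool(sp.is_boundary))
        el.setConstant(bool(sp.is_constant and sp.is_boundary))
        el.setHasOnlySubstanceUnits(True)
        el.setInitialAmount(float(sp.initial_amount))
        el.appendAnnotation(_species_annotation(sp, pool))
        for extra in sp.foreign_annotations:
            el.appendAnnotation(extra)

    for gp in model.gene_products:
        gel = mfbc.createGeneProduct()
        gel.setId(gp.id)
        # fbc requires a label; an empty recipe is normalized to the id
        gel.setLabel(gp.label or gp.id)
        gel.setAssociatedSpecies(gp.associated_species)

    for rxn in model.reactions:
        rel = sm.createReaction()
        rel.setId(rxn.id)
        if rxn.name:
            rel.setName(rxn.name)
        rel.setReversible(bool(rxn.reversible))
        rel.setFast(False)
        for sid, coeff in rxn.stoichiometry.items():
            if coeff < 0:
                ref = rel.createReactant()
                ref.setStoichiometry(-float(coeff))
            elif coeff > 0:
                ref = rel.createProduct()
                ref.setStoichiometry(float(coeff))
            else:
                continue
            ref.setSpecies(sid)
            ref.setConstant(True)
        rfbc = rel.getPlugin("fbc")
        lb = pool.declare(f"lb_{rxn.id}", rxn.lower_bound)
        ub = pool.declare(f"ub_{rxn.id}", rxn.upper_bound)
        rfbc.setLowerFluxBound(lb)
        rfbc.setUpperFluxBound(ub)
        if rxn.gene_product is not None:
            gpa = rfbc.createGeneProductAssociation()
            ref = gpa.createGeneProductRef()
            ref.setGeneProduct(rxn.gene_product)
        rel.appendAnnotation(_reaction_annotation(rxn, pool))
        for extra in rxn.foreign_annotations:
            rel.appendAnnotation(extra)
        if rxn.ec_number:
            rel.setMetaId(f"meta_{rxn.id}")
            cv = libsbml.CVTerm(libsbml.BIOLOGICAL_QUALIFIER)
            cv.setBiologicalQualifierType(libsbml.BQB_IS_VERSION_OF)
            cv.addResource(f"http://identifiers.org/ec-code/{rxn.ec_number}")
            rel.addCVTerm(cv)

    xml = libsbml.writeSBMLToString(doc)
    if destination is not None:
        with open(destination, "w") as fh:
            fh.write(xml)
    return xml


# ---------------------------------------------------------------------------
# parsing helpers shared by reader and validator
# ---------------------------------------------------------------------------


def _load_document(source) -> libsbml.SBMLDocument:
    if isinstance(source, libsbml.SBMLDocument):
        return source
    text = None
    if isinstance(source, (str, os.PathLike)):
        s = os.fspath(source)
        if s.lstrip().startswith("<"):
            text = s
        elif os.path.exists(s):
            with open(s) as fh:
                text = fh.read()
        else:
            raise ParseError(f"no such file: {s}")
    else:  # file-like
        text = source.read()
    doc = libsbml.readSBMLFromString(text)
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        msgs = [
            doc.getError(i).getMessage().strip()
            for i in range(doc.getNumErrors())
            if doc.getError(i).getSeverity() >= libsbml.LIBSBML_SEV_ERROR
        ]
        raise ParseError("malformed SBML document: " + "; ".join(msgs))
    if doc.getModel() is None:
        raise ParseError("SBML document contains no model")
    return doc


def _ram_element(node, kind: str):
    """Find the ``ram:<kind>`` element inside an annotation XMLNode."""
    if node is None:
        return None, []
    foreign: List[str] = []
    found = None
    for i in range(node.getNumChildren()):
        child = node.getChild(i)
        if child.getURI() == RAM_NS and child.getName() == "RAM":
            for j in range(child.getNumChildren()):
                sub = child.getChild(j)
                if sub.getName() == kind:
                    found = sub
        elif child.getName() == "RDF":
            continue  # handled through CV terms
        else:
            foreign.append(child.toXMLString())
    return found, foreign


def _ram_attr(node, name: str) -> Optional[str]:
    val = node.getAttrValue(name, RAM_NS)
    if val == "":
        # tolerate annotations written without attribute-level namespace
        val = node.getAttrValue(name)
    return val if val != "" else None


def _resolve(value: str, params: Dict[str, float]):
    """Resolve a ram numeric attribute: literal number or parameter id."""
    try:
        return float(value)
    except ValueError:
        pass
    if value in params:
        return params[value]
    return None


def _ec_number(rel) -> Optional[str]:
    for i in range(rel.getNumCVTerms()):
        cv = rel.getCVTerm(i)
        if (
            cv.getQualifierType() == libsbml.BIOLOGICAL_QUALIFIER
            and cv.getBiologicalQualifierType() == libsbml.BQB_IS_VERSION_OF
        ):
            for k in range(cv.getNumResources()):
                uri = cv.getResourceURI(k)
                for prefix in _EC_PREFIXES:
                    if uri.startswith(prefix):
                        return uri[len(prefix):]
    return None


def _parameters(sm) -> Dict[str, float]:
    return {
        sm.getParameter(i).getId(): sm.getParameter(i).getValue()
        for i in range(sm.getNumParameters())
    }


# ---------------------------------------------------------------------------
# reader
# ---------------------------------------------------------------------------


def read_ram_sbml(source) -> RAMModel:
    """Parse a resource-allocation SBML document into a :class:`RAMModel`.

    ``source`` may be a path, an XML string, a file-like object or a parsed
    ``libsbml.SBMLDocument``.  All parameter references are resolved to
    numbers; reactions without a gene-product association are spontaneous.
    Violations of the dialect raise :class:`SBMLValidationError` naming the
    offending element.
    """
    doc = _load_document(source)
    sm = doc.getModel()
    params = _parameters(sm)

    def fail(element: str, message: str):
        raise SBMLValidationError(f"{element}: {message}")

    def resolve(element: str, attr: str, value: Optional[str], default=None):
        if value is None:
            if default is not None:
                return default
            fail(element, f"missing mandatory attribute {attr}")
        out = _resolve(value, params)
        if out is None:
            fail(element, f"{attr}={value!r} is neither a number nor a"
                          " declared parameter id")
        return out

    species: List[SpeciesRecord] = []
    for i in range(sm.getNumSpecies()):
        el = sm.getSpecies(i)
        sid = el.getId()
        ram, foreign = _ram_element(el.getAnnotation(), "species")
        if ram is None:
            fail(sid, "missing ram:species annotation")
        stype = _ram_attr(ram, "speciesType")
        if stype not in SPECIES_TYPES:
            fail(sid, f"unknown ram:speciesType {stype!r}")
        if el.isSetInitialAmount():
            amount = el.getInitialAmount()
        elif el.isSetInitialConcentration():
            comp = sm.getCompartment(el.getCompartment())
            if comp is None or not comp.isSetSize():
                fail(sid, "initialConcentration given but compartment size"
                          " is not set")
            amount = el.getInitialConcentration() * comp.getSize()
        else:
            amount = 0.0
        if stype in BIOMASS_TYPES:
            w = resolve(sid, "ram:molecularWeight",
                        _ram_attr(ram, "molecularWeight"))
            b = resolve(sid, "ram:objectiveWeight",
                        _ram_attr(ram, "objectiveWeight"))
            bp_raw = _ram_attr(ram, "biomassPercentage")
            bp = resolve(sid, "ram:biomassPercentage", bp_raw) \
                if bp_raw is not None else 0.0
        else:
            w = b = bp = 0.0
        species.append(
            SpeciesRecord(
                id=sid,
                name=el.getName(),
                compartment=el.getCompartment(),
                species_type=stype,
                is_boundary=el.getBoundaryCondition(),
                is_constant=el.getConstant() and el.getBoundaryCondition(),
                molecular_weight=w,
                objective_weight=b,
                biomass_percentage=bp,
                initial_amount=amount,
                foreign_annotations=tuple(foreign),
            )
        )

    gene_products: List[GeneProduct] = []
    mfbc = sm.getPlugin("fbc")
    if mfbc is not None:
        for i in range(mfbc.getNumGeneProducts()):
            gel = mfbc.getGeneProduct(i)
            if not gel.isSetAssociatedSpecies():
                fail(gel.getId(), "gene product without fbc:associatedSpecies")
            gene_products.append(
                GeneProduct(
                    id=gel.getId(),
                    label=gel.getLabel(),
                    associated_species=gel.getAssociatedSpecies(),
                )
            )

    reactions: List[ReactionRecord] = []
    for i in range(sm.getNumReactions()):
        rel = sm.getReaction(i)
        rid = rel.getId()
        ram, foreign = _ram_element(rel.getAnnotation(), "reaction")
        if ram is None:
            fail(rid, "missing ram:reaction annotation")
        kf = resolve(rid, "ram:kcatForward", _ram_attr(ram, "kcatForward"))
        kb = resolve(rid, "ram:kcatBackward", _ram_attr(ram, "kcatBackward"))
        psi = resolve(rid, "ram:maintenanceScaling",
                      _ram_attr(ram, "maintenanceScaling"))
        if not rel.getReversible() and kb != 0.0:
            fail(rid, "irreversible reaction with nonzero backward turnover"
                      " number")
        stoich: Dict[str, float] = {}
        for k in range(rel.getNumReactants()):
            ref = rel.getReactant(k)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) \
                - ref.getStoichiometry()
        for k in range(rel.getNumProducts()):
            ref = rel.getProduct(k)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) \
                + ref.getStoichiometry()
        gene_product = None
        rfbc = rel.getPlugin("fbc")
        lb = ub = None
        if rfbc is not None:
            if rfbc.isSetLowerFluxBound():
                lb = params.get(rfbc.getLowerFluxBound())
            if rfbc.isSetUpperFluxBound():
                ub = params.get(rfbc.getUpperFluxBound())
            gpa = rfbc.getGeneProductAssociation()
            if gpa is not None:
                assoc = gpa.getAssociation()
                if not isinstance(assoc, libsbml.GeneProductRef):
                    fail(rid, "gene-product association must be a single"
                              " fbc:geneProductRef (complexes are"
                              " pre-resolved, isoenzymes pre-split)")
                gene_product = assoc.getGeneProduct()
                if all(g.id != gene_product for g in gene_products):
                    fail(rid, f"dangling gene product reference"
                              f" {gene_product!r}")
        reactions.append(
            ReactionRecord(
                id=rid,
                name=rel.getName(),
                stoichiometry=stoich,
                reversible=rel.getReversible(),
                kcat_forward=kf,
                kcat_backward=kb,
                maintenance_scaling=psi,
                lower_bound=lb,
                upper_bound=ub,
                gene_product=gene_product,
                ec_number=_ec_number(rel),
                foreign_annotations=tuple(foreign),
            )
        )

    model = RAMModel(
        id=sm.getId() or "ram_model",
        name=sm.getName(),
        species=species,
        reactions=reactions,
        gene_products=gene_products,
    )
    try:
        model.validate()
    except Exception as exc:
        raise SBMLValidationError(str(exc)) from exc
    return model


# ---------------------------------------------------------------------------
# validator
# ---------------------------------------------------------------------------


def validate_ram_document(source) -> List[Finding]:
    """Check a document against the dialect rules; return located findings.

    The report is empty iff the document satisfies every structural rule of
    the annotation layer.  Severity ``error`` marks violations of MUST
    rules; ``warning`` marks discouraged-but-legal constructs (an enzyme
    whose catalyzed reactions live in disjoint compartments should be
    duplicated into per-compartment species with distinct ids).
    """
    doc = _load_document(source)
    sm = doc.getModel()
    params = _parameters(sm)
    findings: List[Finding] = []

    def err(rule: str, element: str, message: str) -> None:
        findings.append(Finding("error", rule, element, message))

    def warn(rule: str, element: str, message: str) -> None:
        findings.append(Finding("warning", rule, element, message))

    def check_numeric(rule: str, element: str, attr: str,
                      value: Optional[str]) -> Optional[float]:
        if value is None:
            err(rule, element, f"missing mandatory attribute {attr}")
            return None
        out = _resolve(value, params)
        if out is None:
            err(rule, element,
                f"{attr}={value!r} is neither a literal number nor the id"
                " of a declared parameter")
        return out

    species_types: Dict[str, str] = {}
    species_comp: Dict[str, str] = {}
    for i in range(sm.getNumSpecies()):
        el = sm.getSpecies(i)
        sid = el.getId()
        species_comp[sid] = el.getCompartment()
        ram, _ = _ram_element(el.getAnnotation(), "species")
        if ram is None:
            err("ram-species-annotation", sid,
                "every species must carry a ram:species annotation")
            continue
        stype = _ram_attr(ram, "speciesType")
        if stype not in SPECIES_TYPES:
            err("ram-species-type", sid,
                f"ram:speciesType must be one of {SPECIES_TYPES},"
                f" got {stype!r}")
            continue
        species_types[sid] = stype
        if stype in BIOMASS_TYPES:
            check_numeric("ram-molecular-weight", sid, "ram:molecularWeight",
                          _ram_attr(ram, "molecularWeight"))
            check_numeric("ram-objective-weight", sid, "ram:objectiveWeight",
                          _ram_attr(ram, "objectiveWeight"))
            bp = _ram_attr(ram, "biomassPercentage")
            if bp is not None:  # absence tolerated as zero
                check_numeric("ram-biomass-percentage", sid,
                              "ram:biomassPercentage", bp)
        if el.getBoundaryCondition() and stype != "extracellular":
            err("ram-boundary-flags", sid,
                "only nonlimiting extracellular species may have"
                " boundaryCondition='true'")
        if el.getConstant() and not el.getBoundaryCondition():
            err("ram-boundary-flags", sid,
                "constant='true' is only allowed on boundary species")
        if stype != "metabolite" and not (
            el.isSetInitialAmount() or el.isSetInitialConcentration()
        ):
            err("ram-initial-value", sid,
                "external, storage and biomass species need an"
                " initialAmount or initialConcentration")
        if el.isSetInitialConcentration():
            comp = sm.getCompartment(el.getCompartment())
            if comp is None or not comp.isSetSize():
                err("ram-initial-value", sid,
                    "initialConcentration requires the compartment size")

    gp_species: Dict[str, str] = {}
    mfbc = sm.getPlugin("fbc")
    if mfbc is not None:
        for i in range(mfbc.getNumGeneProducts()):
            gel = mfbc.getGeneProduct(i)
            gid = gel.getId()
            if not gel.isSetAssociatedSpecies():
                err("ram-gene-product", gid,
                    "gene product without fbc:associatedSpecies")
                continue
            target = gel.getAssociatedSpecies()
            if target not in species_comp:
                err("ram-gene-product", gid,
                    f"fbc:associatedSpecies {target!r} does not exist")
            elif species_types.get(target) != "enzyme":
                err("ram-gene-product", gid,
                    f"fbc:associatedSpecies {target!r} is not an enzyme"
                    " species")
            else:
                gp_species[gid] = target

    enzyme_reaction_comps: Dict[str, List[Tuple[str, frozenset]]] = {}
    for i in range(sm.getNumReactions()):
        rel = sm.getReaction(i)
        rid = rel.getId()
        ram, _ = _ram_element(rel.getAnnotation(), "reaction")
        if ram is None:
            err("ram-reaction-annotation", rid,
                "every reaction must carry a ram:reaction annotation")
            continue
        check_numeric("ram-kcat", rid, "ram:kcatForward",
                      _ram_attr(ram, "kcatForward"))
        kb = check_numeric("ram-kcat", rid, "ram:kcatBackward",
                           _ram_attr(ram, "kcatBackward"))
        psi = check_numeric("ram-maintenance", rid, "ram:maintenanceScaling",
                            _ram_attr(ram, "maintenanceScaling"))
        if not rel.getReversible() and kb not in (None, 0.0):
            err("ram-irreversible-kcat", rid,
                "irreversible reactions must resolve ram:kcatBackward to"
                " zero")
        rfbc = rel.getPlugin("fbc")
        gpa = rfbc.getGeneProductAssociation() if rfbc is not None else None
        if psi not in (None, 0.0) and gpa is not None:
            err("ram-maintenance", rid,
                "maintenance reactions are spontaneous and must not carry a"
                " gene-product association")
        if gpa is not None:
            assoc = gpa.getAssociation()
            if not isinstance(assoc, libsbml.GeneProductRef):
                err("ram-single-catalyst", rid,
                    "each reaction must be catalyzed by exactly one"
                    " fbc:geneProductRef; and/or trees are not part of the"
                    " dialect")
            else:
                gid = assoc.getGeneProduct()
                if gid not in gp_species:
                    err("ram-single-catalyst", rid,
                        f"dangling gene product reference {gid!r}")
                else:
                    comps = frozenset(
                        species_comp[ref.getSpecies()]
                        for lst in (
                            [rel.getReactant(k)
                             for k in range(rel.getNumReactants())],
                            [rel.getProduct(k)
                             for k in range(rel.getNumProducts())],
                        )
                        for ref in lst
                        if ref.getSpecies() in species_comp
                    )
                    enzyme_reaction_comps.setdefault(
                        gp_species[gid], []
                    ).append((rid, comps))

    # one enzyme species catalyzing reactions in disjoint compartments is a
    # likely id-collapse of what should be two per-compartment enzymes
    for enz, pairs in enzyme_reaction_comps.items():
        for a in range(len(pairs)):
            for b in range(a + 1, len(pairs)):
                rid_a, comp_a = pairs[a]
                rid_b, comp_b = pairs[b]
                if comp_a and comp_b and not (comp_a & comp_b):
                    warn("ram-compartment-unique-id", enz,
                         f"enzyme catalyzes reactions {rid_a!r} and"
                         f" {rid_b!r} in disjoint compartments; use one"
                         " species per acting compartment with"
                         " compartment-suffixed ids")
                    break
            else:
                continue
            break

    return findings
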