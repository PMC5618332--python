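"""Protein synthesis, quota construction and turnover-number assignment."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import linprog

from ramtool.builder import (
    AMINO_ACIDS,
    DEFAULT_RESIDUE_SPECIES,
    EnergyModel,
    KcatObservation,
    ProteinSpec,
    QuotaSpec,
    adjust_protein_quota,
    aggregate_kcat,
    amino_acid_counts,
    build_quota_reaction,
    duplicate_enzyme_per_compartment,
    make_enzyme_id,
    protein_synthesis_reaction,
    quota_reaction_kcat,
    ribosome_kcat,
    select_kcat,
    split_isoenzyme_reactions,
)
from ramtool.core import (
    RAMModel,
    ReactionRecord,
    SpeciesRecord,
    build_constraint_matrices,
)
from ramtool.errors import (
    DomainError,
    MissingKcatError,
    ModelStructureError,
    ParseError,
)
from ramtool.fixtures import yeast_protein_quota_spec


class TestAminoAcidCounts:
    @pytest.mark.parametrize("seq,expected", [
        ("M", {"M": 1}),
        ("MKM", {"M": 2, "K": 1}),
        ("MKM*", {"M": 2, "K": 1}),  # stop stripped
        ("", {}),
    ])
    def test_counts(self, seq, expected):
        counts, length = amino_acid_counts(seq)
        assert dict(counts) == expected
        assert length == sum(expected.values())

    def test_illegal_residue_is_located(self):
        with pytest.raises(ParseError, match="position 2"):
            amino_acid_counts("MK1M")

    def test_ambiguity_codes_rejected_by_default(self):
        with pytest.raises(ParseError, match="'B'"):
            amino_acid_counts("MBM")

    def test_ambiguity_codes_mapped_on_request(self):
        counts, length = amino_acid_counts("MBZUX", map_ambiguous=True)
        assert dict(counts) == {"M": 1, "D": 1, "E": 1, "C": 1, "A": 1}
        assert length == 5

    @given(st.text(alphabet=AMINO_ACIDS, min_size=0, max_size=400))
    def test_counts_sum_to_length(self, seq):
        counts, length = amino_acid_counts(seq)
        assert sum(counts.values()) == length == len(seq)


class TestProteinSynthesis:
    def test_single_residue_monomer_detailed_energy(self):
        spec = ProteinSpec(enzyme_id="E1", subunits=[("g1", "M", 1)])
        rxn = protein_synthesis_reaction(spec)
        assert rxn.id == "synth_E1"
        assert rxn.stoichiometry == {
            "Met": -1.0, "ATP": -1.0, "GTP": -2.0,
            "AMP": 1.0, "PPi": 1.0, "GDP": 2.0, "Pi": 2.0, "E1": 1.0,
        }

    def test_homotrimer_scales_everything_by_three(self):
        seq = "MKVLAWY"
        mono = protein_synthesis_reaction(
            ProteinSpec(enzyme_id="E", subunits=[("g", seq, 1)]))
        tri = protein_synthesis_reaction(
            ProteinSpec(enzyme_id="E", subunits=[("g", seq, 3)]))
        for sid, coeff in mono.stoichiometry.items():
            if sid == "E":
                assert tri.stoichiometry[sid] == coeff == 1.0
            else:
                assert tri.stoichiometry[sid] == pytest.approx(3 * coeff)

    def test_two_gene_complex_of_dimers(self):
        """Both gene products participate twice; counts x2, then summed."""
        sA, sB = "MKV", "WYE"
        both = protein_synthesis_reaction(ProteinSpec(
            enzyme_id="IDH", subunits=[("gA", sA, 2), ("gB", sB, 2)]))
        partA = protein_synthesis_reaction(ProteinSpec(
            enzyme_id="IDH", subunits=[("gA", sA, 2)]))
        partB = protein_synthesis_reaction(ProteinSpec(
            enzyme_id="IDH", subunits=[("gB", sB, 2)]))
        for sid in set(partA.stoichiometry) | set(partB.stoichiometry):
            if sid == "IDH":
                continue
            assert both.stoichiometry.get(sid, 0) == pytest.approx(
                partA.stoichiometry.get(sid, 0)
                + partB.stoichiometry.get(sid, 0))
        # per-residue energy: 2x3 + 2x3 = 12 residues -> 12 ATP, 24 GTP
        assert both.stoichiometry["ATP"] == -12.0
        assert both.stoichiometry["GTP"] == -24.0

    def test_lumped_energy_mode(self):
        spec = ProteinSpec(enzyme_id="E", subunits=[("g", "MKVLA", 1)])
        rxn = protein_synthesis_reaction(
            spec, EnergyModel(mode="lumped", atp_per_aa=4.0))
        assert rxn.stoichiometry["ATP"] == -20.0
        assert rxn.stoichiometry["ADP"] == 20.0
        assert rxn.stoichiometry["Pi"] == 20.0
        assert "GTP" not in rxn.stoichiometry

    def test_unmodeled_byproducts_can_be_dropped(self):
        spec = ProteinSpec(enzyme_id="E", subunits=[("g", "MK", 1)])
        rxn = protein_synthesis_reaction(
            spec, EnergyModel(mode="lumped", atp_per_aa=4.0),
            cofactor_species={"ADP": None, "Pi": None})
        assert rxn.stoichiometry == {"Met": -1.0, "Lys": -1.0,
                                     "ATP": -8.0, "E": 1.0}

    def test_consumed_cofactor_cannot_be_dropped(self):
        spec = ProteinSpec(enzyme_id="E", subunits=[("g", "MK", 1)])
        with pytest.raises(ModelStructureError):
            protein_synthesis_reaction(spec,
                                       cofactor_species={"ATP": None})

    def test_empty_subunit_list_rejected(self):
        with pytest.raises(ModelStructureError):
            protein_synthesis_reaction(ProteinSpec(enzyme_id="E", subunits=[]))

    @pytest.mark.parametrize("copies", [1, 2, 4])
    def test_energy_matches_copies_weighted_residue_count(self, rng, copies):
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=37))
        rxn = protein_synthesis_reaction(
            ProteinSpec(enzyme_id="E", subunits=[("g", seq, copies)]))
        total = 37 * copies
        assert rxn.stoichiometry["ATP"] == -total
        assert rxn.stoichiometry["GTP"] == -2 * total
        assert rxn.stoichiometry["AMP"] == total
        assert rxn.stoichiometry["GDP"] == 2 * total
        # residue mass balance: reactant count equals total residues
        residue_ids = set(DEFAULT_RESIDUE_SPECIES.values())
        consumed = -sum(c for s, c in rxn.stoichiometry.items()
                        if s in residue_ids)
        assert consumed == total


class TestRibosomeKcat:
    @pytest.mark.parametrize("a,l,expected", [
        (15.0, 100.0, 540.0),            # standard bacterial elongation rate
        (1 / 3600, 1.0, 1.0),            # a*3600 == l
        (1000 / 3600, 100.0, 10.0),      # implied rate of the toy synthesis rows
    ])
    def test_values(self, a, l, expected):
        assert ribosome_kcat(a, l) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("a,l", [(0, 100), (15, 0), (-1, 100), (15, -5)])
    def test_nonpositive_inputs_rejected(self, a, l):
        with pytest.raises(DomainError):
            ribosome_kcat(a, l)


def _micro_isoenzyme_model():
    return RAMModel(
        id="iso",
        species=[
            SpeciesRecord(id="M", species_type="metabolite"),
            SpeciesRecord(id="Q", species_type="metabolite"),
            SpeciesRecord(id="e1", species_type="enzyme", molecular_weight=1.0),
            SpeciesRecord(id="e2", species_type="enzyme", molecular_weight=1.0),
        ],
        reactions=[
            ReactionRecord(id="r", stoichiometry={"M": -1.0, "Q": 1.0},
                           kcat_forward=5.0),
        ],
    )


class TestIsoenzymeSplit:
    def test_two_isoenzymes_give_two_copies(self):
        model = _micro_isoenzyme_model()
        out = split_isoenzyme_reactions(model, {"r": ["e1", "e2"]})
        rids = [r.id for r in out.reactions]
        assert rids == ["r_iso1", "r_iso2"]
        for rxn, enz in zip(out.reactions, ["e1", "e2"]):
            assert rxn.stoichiometry == {"M": -1.0, "Q": 1.0}
            assert out.catalyzing_enzyme(rxn) == enz

    def test_single_enzyme_reaction_unchanged(self):
        model = _micro_isoenzyme_model()
        out = split_isoenzyme_reactions(model, {"r": ["e1"]})
        assert [r.id for r in out.reactions] == ["r"]
        assert out.catalyzing_enzyme(out.reactions[0]) == "e1"

    def test_unknown_enzyme_rejected(self):
        model = _micro_isoenzyme_model()
        with pytest.raises(ModelStructureError, match="e9"):
            split_isoenzyme_reactions(model, {"r": ["e9"]})

    def test_split_preserves_combined_capacity(self):
        """Max total flux through the copies equals kcat*(p1+p2)."""
        model = _micro_isoenzyme_model()
        out = split_isoenzyme_reactions(model, {"r": ["e1", "e2"]})
        mats = build_constraint_matrices(out)
        p = np.array([0.7, 0.3, 0.0, 0.0])[: len(mats.partition.P)]
        p = np.array([0.7, 0.3])  # e1, e2 amounts
        res = linprog(
            c=-np.ones(len(mats.flux_columns)),
            A_ub=mats.HC, b_ub=mats.HE @ p,
            bounds=[(0, None)] * len(mats.flux_columns),
            method="highs",
        )
        assert res.status == 0
        assert -res.fun == pytest.approx(5.0 * (0.7 + 0.3), rel=1e-9)


class TestCompartments:
    @pytest.mark.parametrize("main,comps,expected", [
        ("FUM", "cytosol", "FUM_cytosol"),
        ("ETrans2", ["e", "c"], "ETrans2_e_c"),
    ])
    def test_make_enzyme_id(self, main, comps, expected):
        assert make_enzyme_id(main, comps) == expected
        assert make_enzyme_id(main, comps) == expected  # deterministic

    def test_duplicate_across_two_compartments(self):
        spec = ProteinSpec(enzyme_id="FUM", subunits=[("YPL262W", "MKV", 1)],
                           compartments=["cytosol", "mitochondrion"])
        out = duplicate_enzyme_per_compartment(spec)
        assert [s.enzyme_id for s in out] == ["FUM_cytosol",
                                              "FUM_mitochondrion"]
        assert all(s.subunits == spec.subunits for s in out)
        assert [s.compartments for s in out] == [["cytosol"],
                                                 ["mitochondrion"]]

    def test_single_compartment_is_identity(self):
        spec = ProteinSpec(enzyme_id="E", subunits=[("g", "M", 1)],
                           compartments=["cytosol"])
        assert duplicate_enzyme_per_compartment(spec) == [spec]

    def test_generated_ids_unique(self):
        spec = ProteinSpec(enzyme_id="E", subunits=[("g", "M", 1)],
                           compartments=["a", "b", "c", "d"])
        ids = [s.enzyme_id for s in duplicate_enzyme_per_compartment(spec)]
        assert len(set(ids)) == len(ids) == 4


class TestQuota:
    def test_yeast_protein_quota_fraction(self):
        spec = yeast_protein_quota_spec()
        rxn, phi = build_quota_reaction(spec)
        assert phi == pytest.approx(0.466298, abs=1e-6)
        assert rxn.stoichiometry[spec.quota_id] == 1.0

    def test_single_component_with_reciprocal_weight(self):
        spec = QuotaSpec(quota_id="Q", components={"X": 2.0},
                         weights={"X": 0.5})
        rxn, phi = build_quota_reaction(spec)
        assert phi == 1.0
        assert rxn.stoichiometry == {"X": -2.0, "Q": 1.0}

    def test_normalized_mass_is_one(self, rng):
        """After division by phi the weighted net mass is exactly 1 g."""
        for _ in range(200):
            n = int(rng.integers(1, 8))
            comps = {f"c{i}": float(rng.uniform(0.01, 5)) for i in range(n)}
            weights = {f"c{i}": float(rng.uniform(0.01, 2)) for i in range(n)}
            bps = {f"b{i}": float(rng.uniform(0.01, 5))
                   for i in range(int(rng.integers(0, 3)))}
            spec = QuotaSpec(quota_id="Q", components=comps,
                             byproducts=bps, weights=weights)
            rxn, phi = build_quota_reaction(spec)
            mass = -sum(rxn.stoichiometry[s] * weights[s] for s in comps)
            mass -= sum(rxn.stoichiometry[s] * 0.0 for s in bps)
            assert mass == pytest.approx(1.0, abs=1e-9)

    def test_energy_coefficients_scaled_by_phi(self):
        spec = QuotaSpec(quota_id="Q", components={"X": 4.0},
                         weights={"X": 0.5})  # phi = 2
        rxn, phi = build_quota_reaction(
            spec, polymerization_energy={"ATP": -6.0, "ADP": 6.0, "Pi": 6.0})
        assert phi == 2.0
        assert rxn.stoichiometry["ATP"] == -3.0
        assert rxn.stoichiometry["ADP"] == 3.0

    def test_zero_fraction_rejected(self):
        spec = QuotaSpec(quota_id="Q", components={"X": 1.0}, weights={})
        with pytest.raises(DomainError):
            build_quota_reaction(spec)

    @pytest.mark.parametrize("phi,fe,expected", [
        (0.466298, 1.0, 0.0),
        (0.466298, 0.0, 0.466298),
        (0.466298, 0.4, 0.2797788),
    ])
    def test_adjust_protein_quota(self, phi, fe, expected):
        assert adjust_protein_quota(phi, fe) == pytest.approx(expected,
                                                              rel=1e-12)

    def test_adjust_rejects_bad_fraction(self):
        with pytest.raises(DomainError):
            adjust_protein_quota(0.4, 1.5)

    def test_quota_kcat_unit_and_values(self):
        assert quota_reaction_kcat(2.0, 7200.0).value == 1.0
        assert quota_reaction_kcat(2.0, 7200.0).unit == "1/(mmol*h)"
        # the toy structural reaction consumes 1500 AA at rate 10:
        # the implied elongation rate is 10*1500/3600 aa/s
        a_implied = 10.0 * 1500.0 / 3600.0
        assert quota_reaction_kcat(a_implied, 1500.0).value == \
            pytest.approx(10.0, rel=1e-12)
        # doubling the bundle size halves the rate
        assert quota_reaction_kcat(a_implied, 3000.0).value == \
            pytest.approx(5.0, rel=1e-12)


class TestKcatAggregation:
    def _obs(self, values, organism="org", wild_type=True):
        return [KcatObservation(reaction_or_ec="1.1.1.1", organism=organism,
                                value=v, wild_type=wild_type) for v in values]

    def test_median_is_robust(self):
        assert aggregate_kcat(self._obs([1.0, 2.0, 100.0])) == 2.0

    def test_singleton(self):
        assert aggregate_kcat(self._obs([7.5])) == 7.5

    def test_mean_strategy(self):
        assert aggregate_kcat(self._obs([1.0, 2.0, 3.0]), "mean") == 2.0

    def test_against_sort_based_oracle(self, rng):
        for _ in range(300):
            n = int(rng.integers(1, 12))
            values = rng.uniform(0.1, 1e4, size=n)
            got = aggregate_kcat(self._obs(list(values)))
            s = np.sort(values)
            oracle = s[n // 2] if n % 2 else 0.5 * (s[n // 2 - 1] + s[n // 2])
            assert got == pytest.approx(oracle, rel=1e-12)

    @given(st.lists(st.floats(min_value=0.01, max_value=1e5), min_size=1,
                    max_size=20),
           st.floats(min_value=0.1, max_value=10.0))
    def test_permutation_invariant_and_scale_equivariant(self, values, scale):
        base = aggregate_kcat(self._obs(values))
        assert aggregate_kcat(self._obs(values[::-1])) == base
        assert aggregate_kcat(self._obs([scale * v for v in values])) == \
            pytest.approx(scale * base, rel=1e-9)

    def test_mutant_observations_filtered(self):
        obs = self._obs([1.0, 2.0]) + self._obs([1000.0], wild_type=False)
        assert aggregate_kcat(obs) == 1.5

    def test_empty_after_filtering_raises(self):
        with pytest.raises(MissingKcatError):
            aggregate_kcat(self._obs([5.0], wild_type=False))

    def test_fallback_chain(self):
        own = self._obs([3.0], organism="yeast")
        other = self._obs([10.0, 20.0, 30.0], organism="coli")
        assert select_kcat(own + other, "yeast") == 3.0
        assert select_kcat(other, "yeast") == 20.0
        assert select_kcat([], "yeast", default=12.0) == 12.0
        with pytest.raises(MissingKcatError):
            select_kcat([], "yeast")
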