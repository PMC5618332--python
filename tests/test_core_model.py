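"""Model containers, partitioning and constraint-matrix assembly."""

import numpy as np
import pytest

from ramtool.core import (
    RAMModel,
    ReactionRecord,
    SpeciesRecord,
    build_biomass_composition_matrix,
    build_capacity_matrices,
    build_constraint_matrices,
    build_maintenance_matrix,
    objective_biomass,
    partition_model,
    total_biomass,
)
from ramtool.errors import (
    ClassificationError,
    DomainError,
    ModelStructureError,
    ParameterizationError,
)
from ramtool.fixtures import random_ram_model, toy_model


class TestRecords:
    def test_boundary_flag_requires_extracellular(self):
        with pytest.raises(ModelStructureError):
            SpeciesRecord(id="x", species_type="metabolite", is_boundary=True)

    def test_biomass_percentage_only_on_quota(self):
        with pytest.raises(ModelStructureError):
            SpeciesRecord(id="e", species_type="enzyme", biomass_percentage=0.1)

    def test_irreversible_requires_zero_backward_kcat(self):
        with pytest.raises(ModelStructureError):
            ReactionRecord(id="r", stoichiometry={}, reversible=False,
                           kcat_forward=10.0, kcat_backward=5.0)

    def test_maintenance_reactions_are_spontaneous(self):
        with pytest.raises(ModelStructureError):
            ReactionRecord(id="m", stoichiometry={}, maintenance_scaling=0.1,
                           gene_product="gp")

    def test_unknown_species_type_rejected(self):
        with pytest.raises(ModelStructureError):
            SpeciesRecord(id="x", species_type="protein")


class TestPartition:
    def test_toy_species_groups(self, toy):
        part = partition_model(toy)
        ids = lambda idxs: {toy.species[i].id for i in idxs}
        assert ids(part.Y) == {"N1", "N2", "O2"}
        assert ids(part.X) == {"N", "AA", "ATP"}
        assert ids(part.C) == {"Stor"}
        assert ids(part.P) == {"ETrans1", "ETrans2", "EMetab1", "EMetab2",
                               "EStor", "S", "R"}

    def test_toy_reaction_groups(self, toy):
        part = partition_model(toy)
        rids = lambda idxs: {toy.reactions[j].id for j in idxs}
        assert rids(part.R_y) == {"Trans1", "Trans2"}
        assert rids(part.R_x) == {"Metab1", "Metab2", "Metab3", "Maintenance"}
        assert rids(part.R_c) == {"Storage"}
        # every macromolecule-producing reaction lands in the synthesis group
        expected_rp = {
            r.id for r in toy.reactions
            if any(coeff > 0 and toy.species_by_id(s).species_type
                   in ("enzyme", "quota")
                   for s, coeff in r.stoichiometry.items())
        }
        assert rids(part.R_p) == expected_rp == {
            f"synth_{e}" for e in
            ("ETrans1", "ETrans2", "EMetab1", "EMetab2", "EStor", "S", "R")
        }

    def test_empty_model(self):
        part = partition_model(RAMModel(id="empty"))
        for group in (part.Y, part.X, part.C, part.P,
                      part.R_y, part.R_x, part.R_c, part.R_p):
            assert group == []

    @pytest.mark.parametrize("seed", range(5))
    def test_partition_is_disjoint_and_exhaustive(self, seed):
        model = random_ram_model(seed)
        part = partition_model(model)
        species = sorted(part.Y + part.X + part.C + part.P)
        reactions = sorted(part.R_y + part.R_x + part.R_c + part.R_p)
        assert species == list(range(model.n))
        assert reactions == list(range(model.r))

    def test_external_to_macromolecule_coupling_rejected(self):
        model = RAMModel(
            id="bad",
            species=[
                SpeciesRecord(id="Ext", species_type="extracellular",
                              compartment="external"),
                SpeciesRecord(id="E", species_type="enzyme",
                              molecular_weight=1.0),
            ],
            reactions=[ReactionRecord(id="direct",
                                      stoichiometry={"Ext": -1.0, "E": 1.0})],
        )
        with pytest.raises(ClassificationError, match="direct"):
            partition_model(model)


class TestCapacityMatrices:
    def test_shared_enzyme_row(self, toy):
        """EMetab2 catalyzes two conversions: v/2500 + v/2000 <= p."""
        HC, HE, rows, cols = build_capacity_matrices(toy)
        r = rows.index("EMetab2")
        coeffs = {cols[c]: HC[r, c] for c in np.nonzero(HC[r])[0]}
        assert coeffs == {("Metab2", 1): pytest.approx(1 / 2500),
                          ("Metab3", 1): pytest.approx(1 / 2000)}
        part = partition_model(toy)
        p_ids = [toy.species[i].id for i in part.P]
        assert np.nonzero(HE[r])[0].tolist() == [p_ids.index("EMetab2")]

    def test_spontaneous_reaction_absent(self, toy):
        HC, _, _, cols = build_capacity_matrices(toy)
        maint_cols = [i for i, (rid, _) in enumerate(cols)
                      if rid == "Maintenance"]
        assert np.all(HC[:, maint_cols] == 0)

    def test_reversible_reaction_bounds_both_directions(self, toy):
        HC, _, rows, cols = build_capacity_matrices(toy)
        r = rows.index("EStor")
        coeffs = {cols[c]: HC[r, c] for c in np.nonzero(HC[r])[0]}
        assert coeffs == {("Storage", 1): pytest.approx(1 / 25),
                          ("Storage", -1): pytest.approx(1 / 30)}

    def test_he_is_a_filter_matrix(self, toy):
        for model in [toy] + [random_ram_model(s) for s in range(5)]:
            _, HE, _, _ = build_capacity_matrices(model)
            for row in HE:
                nz = row[row != 0]
                assert nz.shape == (1,) and nz[0] == 1.0

    def test_matrix_form_equals_per_enzyme_sums(self, toy, rng):
        """HC v against the explicit sum over cat(P_i), 100 random fluxes."""
        mats = build_constraint_matrices(toy)
        cat = toy.catalysis_map()
        for _ in range(100):
            v_split = rng.uniform(0, 10, size=len(mats.flux_columns))
            lhs = mats.HC @ v_split
            for r, enz in enumerate(mats.enzyme_rows):
                expected = 0.0
                for c, (rid, sign) in enumerate(mats.flux_columns):
                    if rid in cat[enz]:
                        rxn = toy.reaction_by_id(rid)
                        k = rxn.kcat_forward if sign > 0 else rxn.kcat_backward
                        expected += v_split[c] / k
                assert lhs[r] == pytest.approx(expected, rel=1e-12)

    def test_catalyzed_reaction_without_kcat_rejected(self):
        model = RAMModel(
            id="nokcat",
            species=[
                SpeciesRecord(id="M", species_type="metabolite"),
                SpeciesRecord(id="E", species_type="enzyme",
                              molecular_weight=1.0),
            ],
            reactions=[ReactionRecord(id="synth_E",
                                      stoichiometry={"M": -1.0, "E": 1.0},
                                      kcat_forward=0.0, gene_product="E")],
        )
        with pytest.raises(ParameterizationError, match="synth_E"):
            build_capacity_matrices(model)


class TestBiomassMatrices:
    def test_quota_row_encodes_mass_floor(self, toy, rng):
        """Row of HB gives phi_s * B_t - w_s * p_s for random amounts."""
        mats = build_constraint_matrices(toy)
        part = mats.partition
        s = toy.species_by_id("S")
        p_ids = [toy.species[i].id for i in part.P]
        for _ in range(20):
            c = rng.uniform(0, 5, size=len(part.C))
            p = rng.uniform(0, 5, size=len(part.P))
            bt = total_biomass(toy, c, p, part)
            val = (mats.HB @ np.concatenate([c, p]))[0]
            direct = s.biomass_percentage * bt \
                - s.molecular_weight * p[p_ids.index("S")]
            assert val == pytest.approx(direct, rel=1e-12, abs=1e-12)

    def test_zero_fraction_row_always_satisfied(self):
        model = toy_model(bp_s=0.0)
        HB, rows = build_biomass_composition_matrix(model)
        assert rows == ["S"]
        cp = np.abs(np.random.default_rng(0).normal(size=HB.shape[1]))
        assert np.all(HB @ cp <= 0)

    def test_quota_without_weight_rejected(self):
        model = RAMModel(
            id="badquota",
            species=[SpeciesRecord(id="Q", species_type="quota",
                                   biomass_percentage=0.2)],
        )
        with pytest.raises(ParameterizationError, match="Q"):
            build_biomass_composition_matrix(model)

    def test_maintenance_floor_formula(self, toy, rng):
        mats = build_constraint_matrices(toy)
        part = mats.partition
        psi = toy.reaction_by_id("Maintenance").maintenance_scaling
        for _ in range(20):
            c = rng.uniform(0, 5, size=len(part.C))
            p = rng.uniform(0, 5, size=len(part.P))
            floor = (mats.HM @ np.concatenate([c, p]))[0]
            assert floor == pytest.approx(
                psi * total_biomass(toy, c, p, part), rel=1e-12)

    def test_no_maintenance_no_rows(self):
        model = toy_model(psi_maintenance=0.0)
        HM, rows = build_maintenance_matrix(model)
        assert HM.shape[0] == 0 and rows == []


class TestBiomassFunctionals:
    def test_zero_amounts(self, toy):
        part = partition_model(toy)
        z_p = np.zeros(len(part.P))
        z_c = np.zeros(len(part.C))
        assert objective_biomass(toy, z_p, part) == 0.0
        assert total_biomass(toy, z_c, z_p, part) == 0.0

    def test_storage_counts_only_in_total_biomass(self, toy):
        part = partition_model(toy)
        c = np.array([2.0])
        p = np.zeros(len(part.P))
        assert objective_biomass(toy, p, part) == 0.0
        assert total_biomass(toy, c, p, part) == pytest.approx(
            2.0 * toy.species_by_id("Stor").molecular_weight)

    def test_total_at_least_objective(self, toy, rng):
        part = partition_model(toy)
        for _ in range(50):
            c = rng.uniform(0, 10, size=len(part.C))
            p = rng.uniform(0, 10, size=len(part.P))
            bo = objective_biomass(toy, p, part)
            bt = total_biomass(toy, c, p, part)
            assert bt >= bo
            if np.all(c == 0):
                assert bt == bo

    def test_negative_amounts_rejected(self, toy):
        part = partition_model(toy)
        with pytest.raises(DomainError):
            objective_biomass(toy, -np.ones(len(part.P)), part)
        with pytest.raises(DomainError):
            total_biomass(toy, -np.ones(len(part.C)),
                          np.zeros(len(part.P)), part)

    def test_unit_weight_hand_computation(self):
        """With unit weights the biomass functionals are plain sums."""
        model = RAMModel(
            id="unit",
            species=[
                SpeciesRecord(id="C1", species_type="storage",
                              molecular_weight=1.0),
                SpeciesRecord(id="P1", species_type="enzyme",
                              molecular_weight=1.0, objective_weight=1.0),
                SpeciesRecord(id="P2", species_type="enzyme",
                              molecular_weight=1.0, objective_weight=1.0),
            ],
        )
        part = partition_model(model)
        assert objective_biomass(model, [2.0, 3.0], part) == 5.0
        assert total_biomass(model, [4.0], [2.0, 3.0], part) == 9.0
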