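"""Reaction network structure: species registry, model systems, fluxes, scales."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from maillard_kinetics import (
    ACTIVE_SETS,
    MOLAR_MASS_G_PER_MOL,
    SPECIES,
    RateConstants,
    build_model_system,
    natural_to_printed,
    ode_rhs,
    printed_to_natural,
)
from maillard_kinetics.reaction_model import (
    AMINO_ACIDS,
    ELIMINATION_SPECIES,
    IDX,
    N_SPECIES,
    REACTIONS,
    reachable_species,
)


class TestSpeciesRegistry:
    def test_fourteen_unique_species(self):
        assert len(SPECIES) == 14
        assert len(set(SPECIES)) == 14

    def test_molar_masses_positive_except_melanoidins(self):
        for s in SPECIES:
            if s == "MEL":
                assert MOLAR_MASS_G_PER_MOL[s] is None
            else:
                assert MOLAR_MASS_G_PER_MOL[s] > 0


class TestBuildModelSystem:
    @pytest.mark.parametrize(
        "name, temp, initials, active",
        [
            ("Trp/Glu", 170, {"TRP": 5.0, "GLU": 100.0}, {1, 2, 6, 7, 9, 10, 11}),
            ("Lys/Glu", 200, {"LYS": 30.0, "GLU": 100.0}, {1, 2, 3, 4, 6, 7, 11}),
            ("Asn/Glu", 170, {"ASN": 200.0, "GLU": 100.0}, {1, 2, 5, 6, 7, 8, 11}),
            (
                "Com/Glu",
                170,
                {"LYS": 30.0, "ASN": 200.0, "TRP": 5.0, "GLU": 100.0},
                set(range(1, 12)),
            ),
        ],
    )
    def test_design_compositions_and_active_sets(self, name, temp, initials, active):
        spec = build_model_system(name, temp)
        assert spec.active_k == frozenset(active)
        for s in SPECIES:
            assert spec.initial_mmolL[s] == initials.get(s, 0.0)

    def test_com_lysine_variant(self):
        assert build_model_system("Com/Glu", 170, lys_variant=True).initial_mmolL["LYS"] == 100.0
        assert build_model_system("Com/Glu", 170).initial_mmolL["LYS"] == 30.0

    def test_unknown_system_and_temperature_rejected_with_valid_values(self):
        with pytest.raises(ValueError, match="Lys/Glu"):
            build_model_system("Gly/Glu", 170)
        with pytest.raises(ValueError, match="170"):
            build_model_system("Lys/Glu", 180)

    def test_lys_variant_outside_com_rejected(self):
        with pytest.raises(ValueError, match="Com/Glu"):
            build_model_system("Lys/Glu", 170, lys_variant=True)

    def test_nonzero_product_initial_rejected(self):
        with pytest.raises(ValueError, match="start at 0"):
            build_model_system("Lys/Glu", 170, initial_mmolL={"AA": 1.0})


class TestPrintedScales:
    @pytest.mark.parametrize(
        "printed, index, natural",
        [(0.721, 4, 0.00721), (0.006, 9, 6e-6), (2.198, 11, 2.198)],
    )
    def test_tabulated_scale_examples(self, printed, index, natural):
        assert printed_to_natural(printed, index) == pytest.approx(natural, rel=1e-12)

    @given(
        value=st.floats(1e-6, 10.0, allow_nan=False),
        index=st.integers(1, 18),
    )
    def test_round_trip_is_identity(self, value, index):
        assert natural_to_printed(printed_to_natural(value, index), index) == pytest.approx(
            value, rel=1e-14
        )

    @pytest.mark.parametrize("index", [0, 19, -1])
    def test_invalid_index_rejected(self, index):
        with pytest.raises(ValueError):
            printed_to_natural(1.0, index)


class TestRateConstants:
    def test_indexing_covers_reactions_and_eliminations(self):
        k = RateConstants.from_mapping({1: 0.1, 11: 2.0, 12: 0.05})
        assert k[1] == 0.1 and k[11] == 2.0 and k[12] == 0.05 and k[5] == 0.0

    def test_negative_constant_rejected(self):
        with pytest.raises(ValueError):
            RateConstants.from_mapping({3: -1.0})

    def test_from_printed_applies_scales(self):
        k = RateConstants.from_printed({4: 0.721, 9: 0.006, 11: 2.198})
        assert k[4] == pytest.approx(0.00721)
        assert k[9] == pytest.approx(6e-6)
        assert k[11] == pytest.approx(2.198)
        printed = k.to_printed()
        assert printed[4] == pytest.approx(0.721)
        assert printed[9] == pytest.approx(0.006)


def _rhs_oracle(state, k, spec):
    """Assemble the derivative directly from the declarative reaction list.

    Independent of ode_rhs: walks REACTIONS, computes each flux (first or
    normalised second order), adds it once negatively per reactant and once
    positively per product, then applies the melanoidin amino-acid
    co-consumption and the first-order eliminations.
    """
    ref = spec.dicarbonyl_ref_mmolL
    d = np.zeros(N_SPECIES)
    active = {i: (k[i] if i in spec.active_k else 0.0) for i in range(1, 12)}
    for idx, reactants, products in REACTIONS:
        flux = active[idx]
        for r in reactants:
            flux *= state[IDX[r]]
        if len(reactants) == 2 and ref is not None:
            flux /= ref
        for r in reactants:
            d[IDX[r]] -= flux
        for p in products:
            d[IDX[p]] += flux
        if idx == 11:
            total = sum(state[IDX[a]] for a in AMINO_ACIDS)
            for a in AMINO_ACIDS:
                d[IDX[a]] -= flux * state[IDX[a]] / (total + spec.aa_sat_mmolL)
    for j, s in enumerate(ELIMINATION_SPECIES):
        d[IDX[s]] -= k[12 + j] * state[IDX[s]]
    return d


class TestOdeRhs:
    def test_zero_state_zero_flux(self, com_scenario):
        d = ode_rhs(np.zeros(N_SPECIES), com_scenario.k, com_scenario.spec)
        assert np.all(d == 0.0)

    def test_single_channel_glucose_to_glyoxal(self):
        spec = build_model_system("Lys/Glu", 170)
        k = RateConstants.from_mapping({1: 0.1})
        state = np.zeros(N_SPECIES)
        state[IDX["GLU"]] = 100.0
        d = ode_rhs(state, k, spec)
        assert d[IDX["GLU"]] == pytest.approx(-10.0)
        assert d[IDX["GO"]] == pytest.approx(10.0)
        other = [i for i in range(N_SPECIES) if i not in (IDX["GLU"], IDX["GO"])]
        assert np.all(d[other] == 0.0)

    def test_negative_state_rejected(self, com_scenario):
        state = np.zeros(N_SPECIES)
        state[IDX["GLU"]] = -1.0
        with pytest.raises(ValueError, match="GLU"):
            ode_rhs(state, com_scenario.k, com_scenario.spec)

    def test_per_reaction_stoichiometry_matches_declarative_assembly(self, rng):
        # full network with eliminations, random positive states
        spec = build_model_system("Com/Glu", 170)
        k = RateConstants(
            k=tuple(rng.uniform(0.01, 2.0, 11)), e=tuple(rng.uniform(0.0, 0.1, 7))
        )
        for _ in range(10):
            state = rng.uniform(0.0, 50.0, N_SPECIES)
            np.testing.assert_allclose(
                ode_rhs(state, k, spec), _rhs_oracle(state, k, spec), rtol=1e-12, atol=1e-12
            )

    def test_inactive_constants_contribute_no_flux(self, rng):
        # Lys/Glu: k5, k8, k9, k10 must be inert even when nonzero
        spec = build_model_system("Lys/Glu", 170)
        state = rng.uniform(0.0, 50.0, N_SPECIES)
        k_base = RateConstants.from_mapping({i: 0.1 for i in spec.active_k})
        k_spiked = k_base.with_values({5: 9.9, 8: 9.9, 9: 9.9, 10: 9.9})
        np.testing.assert_array_equal(
            ode_rhs(state, k_base, spec), ode_rhs(state, k_spiked, spec)
        )

    @given(data=st.data())
    def test_species_at_zero_never_driven_negative(self, data):
        spec = build_model_system("Com/Glu", 170)
        rng_local = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
        k = RateConstants(
            k=tuple(rng_local.uniform(0.0, 2.0, 11)), e=tuple(rng_local.uniform(0.0, 0.2, 7))
        )
        state = rng_local.uniform(0.0, 100.0, N_SPECIES)
        zero_mask = rng_local.random(N_SPECIES) < 0.5
        state[zero_mask] = 0.0
        d = ode_rhs(state, k, spec)
        assert np.all(d[zero_mask] >= 0.0)


class TestReachability:
    def test_lys_system_cannot_form_acrylamide_or_carbolines(self, lys_spec):
        reach = reachable_species(lys_spec)
        assert {"AA", "HAR", "NOR", "ASN", "TRP"}.isdisjoint(reach)
        assert {"GLU", "LYS", "GO", "MGO", "ACH", "ACR", "CML", "CEL", "MEL"} <= reach

    def test_com_system_reaches_everything(self):
        assert reachable_species(build_model_system("Com/Glu", 170)) == frozenset(SPECIES)
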