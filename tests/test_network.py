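import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hifdyn as h
from hifdyn.errors import ConfigurationError, ValidationError
from hifdyn.network import O2, SPECIES, mass_action_flux, mm_hydroxylation_flux

from conftest import random_params, random_state


class TestBuildDefaultModel:
    def test_fifteen_species(self, full_model):
        assert len(full_model.species) == 15
        assert set(full_model.species) == set(SPECIES)

    def test_hre_totals(self, full_model):
        assert full_model.hre1_total == 12
        assert full_model.hre2_total == 18

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            h.build_default_model(-1, 0)
        with pytest.raises(ValidationError):
            h.build_default_model(0, -3)

    def test_expected_reactions_present(self, full_model):
        ids = {r.id for r in full_model.reactions}
        assert {
            "hif1a_mrna_to_protein",
            "hif2a_mrna_to_protein",
            "hif1a_protein_out",
            "hif2a_protein_out",
            "phd_to_hif1a_protein",
            "phd_to_hif2a_protein",
            "hif1a_dimerization",
            "hif2a_dimerization",
            "hif1b_in",
            "hif1b_out",
        } <= ids
        # four HRE bindings, four transcription reactions
        assert sum(1 for r in full_model.reactions if r.kind == "reversible_binding") == 6
        assert sum("transcription" in r.id for r in full_model.reactions) == 4

    def test_translation_uses_modifier_not_reactant(self, full_model):
        rxn = full_model.reaction("hif1a_mrna_to_protein")
        assert rxn.kind == "catalytic_production"
        assert rxn.modifiers == ("HIF1A_mrna",)
        assert rxn.reactants == ()

    def test_hydroxylation_consumes_alpha_only(self, full_model):
        rxn = full_model.reaction("phd_to_hif1a_protein")
        col = full_model.stoichiometry(rxn)
        assert col[full_model.index("HIF1A_protein")] == -1
        assert col[full_model.index("PHD_protein")] == 0
        nonzero = np.nonzero(col)[0]
        assert list(nonzero) == [full_model.index("HIF1A_protein")]

    def test_no_sites_means_basal_gene_only(self):
        """(0, 0): Gene_mRNA stays at its basal level under any protocol."""
        model = h.build_default_model(0, 0)
        params = model.default_parameters()
        init = h.default_initial_state(model)
        traj = h.simulate(model, params, init)
        assert np.allclose(traj.series("Gene_mRNA"), 1.0, atol=1e-6)

    def test_zero_hre2_class_carries_no_flux(self, rng):
        """(1, 0): HRE2-touching reactions exist but their flux is 0."""
        model = h.build_default_model(1, 0)
        params = model.default_parameters()
        state = random_state(model, rng)
        state["HRE2"] = 0.0
        state["HIF1AB_HRE2"] = 0.0
        state["HIF2AB_HRE2"] = 0.0
        hre2_reactions = [
            r
            for r in model.reactions
            if any(n in ("HRE2", "HIF1AB_HRE2", "HIF2AB_HRE2")
                   for n, _ in (*r.reactants, *r.products))
        ]
        assert len(hre2_reactions) == 2
        for rxn in hre2_reactions:
            fwd, rev = mass_action_flux(rxn, state, params)
            assert fwd == 0.0 and rev == 0.0

    def test_default_parameters(self, full_model):
        params = full_model.default_parameters()
        for name, value in params.items():
            assert value == (1e-4 if name.endswith(".kd") else 1.0)

    def test_serialization_round_trip(self, full_model):
        clone = h.ModelDefinition.from_dict(full_model.to_dict())
        assert clone.species == full_model.species
        assert clone.hre1_total == full_model.hre1_total
        assert [r.id for r in clone.reactions] == [r.id for r in full_model.reactions]
        assert clone.to_dict() == full_model.to_dict()


class TestMMHydroxylationFlux:
    def test_zero_oxygen_zero_flux(self):
        assert mm_hydroxylation_flux(1.0, 0.0, 1.0, 2.0, 0.5, 0.5) == 0.0

    def test_half_saturation(self):
        # hif = km_hif, o2 >> km_o2, phd = 1, kcat = 2 -> flux -> 1
        flux = mm_hydroxylation_flux(0.7, 1e9, 1.0, 2.0, 0.7, 1e-3)
        assert flux == pytest.approx(1.0, rel=1e-6)

    def test_matches_hand_evaluation(self, rng):
        for _ in range(50):
            hif, o2, phd, kcat, km_h, km_o = rng.random(6) * 3 + 1e-3
            expected = kcat * phd * (hif / (km_h + hif)) * (o2 / (km_o + o2))
            assert mm_hydroxylation_flux(hif, o2, phd, kcat, km_h, km_o) == pytest.approx(
                expected, rel=1e-12
            )

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValidationError):
            mm_hydroxylation_flux(-1.0, 1.0, 1.0, 1.0, 1.0, 1.0)
        with pytest.raises(ValidationError):
            mm_hydroxylation_flux(1.0, 1.0, 1.0, 1.0, 0.0, 1.0)

    def test_km_o2_limit_recovers_single_substrate_form(self):
        """km_o2 -> 0 with o2 > 0 fixed gives single-substrate MM."""
        single = 2.0 * 1.3 * (0.8 / (0.5 + 0.8))
        for km_o2 in (1e-3, 1e-6, 1e-9):
            flux = mm_hydroxylation_flux(0.8, 0.7, 1.3, 2.0, 0.5, km_o2)
            assert flux == pytest.approx(single, rel=2 * km_o2 / 0.7 + 1e-12)


class TestMassActionFlux:
    def test_first_order_zero_reactant(self, full_model):
        rxn = full_model.reaction("hif1a_mrna_out")
        state = {"HIF1A_mrna": 0.0}
        assert mass_action_flux(rxn, state, {"hif1a_mrna_out.k": 1.0}) == 0.0

    def test_reversible_detailed_balance_point(self, full_model):
        rxn = full_model.reaction("hif1a_dimerization")
        kd = 1e-4
        state = {"HIF1A_protein": kd, "HIF1B": 0.37, "HIF1AB": 0.37}
        params = {"hif1a_dimerization.k": 5.0, "hif1a_dimerization.kd": kd}
        fwd, rev = mass_action_flux(rxn, state, params)
        assert fwd == pytest.approx(rev, rel=1e-12)

    def test_reversible_arithmetic_oracle(self, full_model):
        rxn = full_model.reaction("hif1a_dimerization")
        state = {"HIF1A_protein": 0.2, "HIF1B": 0.5, "HIF1AB": 0.1}
        params = {"hif1a_dimerization.k": 3.0, "hif1a_dimerization.kd": 1e-4}
        fwd, rev = mass_action_flux(rxn, state, params)
        assert fwd == pytest.approx(0.3, rel=1e-12)
        assert rev == pytest.approx(3e-5, rel=1e-12)

    def test_missing_parameter_names_key(self, full_model):
        rxn = full_model.reaction("hif1a_mrna_out")
        with pytest.raises(ConfigurationError, match="hif1a_mrna_out.k"):
            mass_action_flux(rxn, {"HIF1A_mrna": 1.0}, {})


def _rhs_oracle(model, state, params, o2):
    """Independent per-reaction accumulation of stoichiometry * flux."""
    acc = {name: 0.0 for name in model.species}
    for rxn in model.reactions:
        if rxn.kind == "mm_hydroxylation":
            (sub, _), = rxn.reactants
            phd = next(m for m in rxn.modifiers if m != O2)
            keys = rxn.parameter_keys
            flux = mm_hydroxylation_flux(
                state[sub], o2, state[phd],
                params[keys["kcat"]], params[keys["km_hif"]], params[keys["km_o2"]],
            )
        else:
            flux = mass_action_flux(rxn, state, params)
            if isinstance(flux, tuple):
                flux = flux[0] - flux[1]
        for name, stoich in rxn.reactants:
            acc[name] -= stoich * flux
        for name, stoich in rxn.products:
            acc[name] += stoich * flux
    return acc


class TestRHS:
    def test_all_rates_zero(self, full_model, rng):
        params = h.ParameterSet({name: 0.0 for name in full_model.parameter_names()})
        state = random_state(full_model, rng)
        deriv = full_model.rhs(state, params, o2=1.0)
        assert all(v == 0.0 for v in deriv.values())

    def test_matches_accumulation_oracle(self, full_model, rng):
        for _ in range(100):
            state = random_state(full_model, rng)
            params = random_params(full_model, rng)
            o2 = float(rng.random() * 2)
            deriv = full_model.rhs(state, params, o2)
            oracle = _rhs_oracle(full_model, state, params, o2)
            for name in full_model.species:
                assert deriv[name] == pytest.approx(oracle[name], abs=1e-12, rel=1e-12)

    @given(data=st.data())
    @settings(max_examples=120, deadline=None)
    def test_rhs_oracle_property(self, full_model, data):
        draw = data.draw
        conc = st.floats(0.0, 50.0, allow_nan=False)
        rate = st.floats(1e-6, 100.0, allow_nan=False)
        state = h.SpeciesState(
            {name: draw(conc) for name in full_model.species}
        )
        params = h.ParameterSet(
            {name: draw(rate) for name in full_model.parameter_names()}
        )
        o2 = draw(st.floats(0.0, 3.0, allow_nan=False))
        deriv = full_model.rhs(state, params, o2)
        oracle = _rhs_oracle(full_model, state, params, o2)
        for name in full_model.species:
            assert deriv[name] == pytest.approx(oracle[name], abs=1e-12, rel=1e-12)

    def test_hre_derivative_sums_to_zero(self, full_model, rng):
        for _ in range(20):
            state = random_state(full_model, rng)
            params = random_params(full_model, rng)
            deriv = full_model.rhs(state, params, o2=1.0)
            d1 = deriv["HRE1"] + deriv["HIF1AB_HRE1"] + deriv["HIF2AB_HRE1"]
            d2 = deriv["HRE2"] + deriv["HIF1AB_HRE2"] + deriv["HIF2AB_HRE2"]
            assert d1 == pytest.approx(0.0, abs=1e-12)
            assert d2 == pytest.approx(0.0, abs=1e-12)

    def test_isolated_hre_pool_is_static(self, full_model):
        params = h.ParameterSet({name: 0.0 for name in full_model.parameter_names()})
        state = h.SpeciesState({name: 0.0 for name in full_model.species})
        state["HRE1"] = 12.0
        deriv = full_model.rhs(state, params, o2=1.0)
        assert deriv["HRE1"] == 0.0


class TestTotalAlpha:
    def test_free_only(self):
        assert h.total_alpha({"HIF1A_protein": 1.0}) == (1.0, 0.0)

    def test_initial_state(self):
        """Totals at the packaged initial state are derived, not read from
        the (internally inconsistent) printed total rows."""
        hif1a, hif2a = h.total_alpha(h.initial_state())
        assert hif1a == pytest.approx(1.0)
        assert hif2a == pytest.approx(5.26)

    def test_random_state_summation_oracle(self, rng):
        for _ in range(30):
            values = rng.random(8) * 10
            state = dict(
                zip(
                    (
                        "HIF1A_protein", "HIF1AB", "HIF1AB_HRE1", "HIF1AB_HRE2",
                        "HIF2A_protein", "HIF2AB", "HIF2AB_HRE1", "HIF2AB_HRE2",
                    ),
                    values,
                )
            )
            hif1a, hif2a = h.total_alpha(state)
            assert hif1a == pytest.approx(values[:4].sum(), rel=1e-12)
            assert hif2a == pytest.approx(values[4:].sum(), rel=1e-12)
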