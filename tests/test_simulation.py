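import numpy as np
import pytest

import hifdyn as h
from hifdyn.errors import ValidationError
from hifdyn.simulate import OxygenProtocol


def equilibrium_bound(a_total, b_total, kd):
    """Closed-form equilibrium [AB] of A + B <-> AB from totals and kd
    (independent quadratic-formula oracle)."""
    s = a_total + b_total + kd
    return (s - np.sqrt(s * s - 4 * a_total * b_total)) / 2


class TestOxygenProtocol:
    def test_constant(self):
        protocol = OxygenProtocol.constant(0.5)
        assert protocol.level_at(-1) == 0.5
        assert protocol.level_at(100) == 0.5

    def test_step_lookup(self):
        protocol = OxygenProtocol(((0.0, 1.0), (24.0, 1 / 3)))
        assert protocol.level_at(23.9) == 1.0
        assert protocol.level_at(24.0) == pytest.approx(1 / 3)

    def test_non_increasing_times_rejected(self):
        with pytest.raises(ValidationError):
            OxygenProtocol(((0.0, 1.0), (0.0, 0.5)))

    def test_first_time_positive_rejected(self):
        with pytest.raises(ValidationError):
            OxygenProtocol(((5.0, 1.0),))

    def test_negative_level_rejected(self):
        with pytest.raises(ValidationError):
            OxygenProtocol(((0.0, -0.1),))


class TestSimulate:
    def test_all_rates_zero_constant_trajectory(self, full_model):
        params = h.ParameterSet({n: 0.0 for n in full_model.parameter_names()})
        init = h.default_initial_state(full_model)
        traj = h.simulate(full_model, params, init)
        for name in full_model.species:
            assert np.allclose(traj.series(name), init[name], atol=1e-12)

    def test_first_order_decay_closed_form(self, full_model):
        """Isolated decay: x(t) = e^(-k t) within 1e-6."""
        k = 0.31
        params = h.ParameterSet({n: 0.0 for n in full_model.parameter_names()})
        params["gene_mrna_out.k"] = k
        init = h.SpeciesState({n: 0.0 for n in full_model.species})
        init["Gene_mRNA"] = 1.0
        t = np.array([0, 1, 2, 5, 10, 20], float)
        traj = h.simulate(full_model, params, init, t_grid=t, rtol=1e-9, atol=1e-12)
        assert np.max(np.abs(traj.series("Gene_mRNA") - np.exp(-k * t))) < 1e-6

    def test_reversible_binding_reaches_closed_form_equilibrium(self, full_model):
        """Isolated dimerization approaches the quadratic-formula
        equilibrium to 4 significant digits."""
        kd = 0.05
        params = h.ParameterSet({n: 0.0 for n in full_model.parameter_names()})
        params["hif1a_dimerization.k"] = 2.0
        params["hif1a_dimerization.kd"] = kd
        init = h.SpeciesState({n: 0.0 for n in full_model.species})
        a_total, b_total = 1.3, 0.8
        init["HIF1A_protein"] = a_total
        init["HIF1B"] = b_total
        traj = h.simulate(
            full_model, params, init, t_grid=[0, 500], rtol=1e-10, atol=1e-12
        )
        ab = traj.series("HIF1AB")[-1]
        expected = equilibrium_bound(a_total, b_total, kd)
        assert ab == pytest.approx(expected, rel=1e-4)
        # and [A][B]/[AB] = kd at equilibrium
        a = traj.series("HIF1A_protein")[-1]
        b = traj.series("HIF1B")[-1]
        assert a * b / ab == pytest.approx(kd, rel=1e-4)

    def test_hre_conservation_along_trajectory(self, full_model, rng):
        from conftest import random_params

        params = random_params(full_model, rng)
        init = h.default_initial_state(full_model)
        traj = h.simulate(full_model, params, init)
        hre1 = traj.free_hre1 + traj.series("HIF1AB_HRE1") + traj.series("HIF2AB_HRE1")
        hre2 = traj.free_hre2 + traj.series("HIF1AB_HRE2") + traj.series("HIF2AB_HRE2")
        assert np.max(np.abs(hre1 - 12)) <= 1e-6 * 12
        assert np.max(np.abs(hre2 - 18)) <= 1e-6 * 18

    def test_non_negativity(self, full_model, rng):
        from conftest import random_params

        for _ in range(5):
            params = random_params(full_model, rng)
            traj = h.simulate(full_model, params, h.default_initial_state(full_model))
            assert traj.y.min() >= -1e-9

    def test_grid_insensitivity_to_tolerances(self, full_model):
        params = full_model.default_parameters()
        init = h.default_initial_state(full_model)
        loose = h.simulate(full_model, params, init, rtol=1e-7, atol=1e-9)
        tight = h.simulate(full_model, params, init, rtol=5e-8, atol=5e-10)
        rel = np.abs(tight.y - loose.y) / np.maximum(np.abs(tight.y), 1e-6)
        assert rel.max() < 1e-3

    def test_oxygen_step_changes_dynamics(self, full_model):
        params = full_model.default_parameters()
        init = h.default_initial_state(full_model)
        constant = h.simulate(full_model, params, init, t_grid=[0, 12, 24, 48])
        stepped = h.simulate(
            full_model,
            params,
            init,
            OxygenProtocol(((0.0, 1.0), (24.0, 1 / 3))),
            t_grid=[0, 12, 24, 48],
        )
        # identical up to the switch, different afterwards
        assert np.allclose(stepped.y[:3], constant.y[:3], rtol=1e-5)
        assert not np.allclose(stepped.y[3], constant.y[3], rtol=1e-3)

    def test_negative_initial_rejected(self, full_model):
        init = h.default_initial_state(full_model)
        init["HIF1B"] = -1.0
        with pytest.raises(ValidationError):
            h.simulate(full_model, full_model.default_parameters(), init)


class TestTitrateHif1b:
    def test_gene_fold_non_decreasing_in_level(self, full_model):
        params = full_model.default_parameters()
        init = h.default_initial_state(full_model)
        result = h.titrate_hif1b(
            full_model, params, init, [1, 30, 60], t_grid=[0, 2, 8, 16]
        )
        folds = [result[lv].value_at(result[lv].gene_fold, 16.0) for lv in (1, 30, 60)]
        assert folds[0] <= folds[1] <= folds[2]

    def test_huge_hif1b_fills_all_sites(self, full_model):
        params = full_model.default_parameters()
        init = h.default_initial_state(full_model)
        result = h.titrate_hif1b(full_model, params, init, [1e6], t_grid=[0, 48])
        traj = result[1e6]
        assert traj.free_hre1[-1] < 1e-3 * full_model.hre1_total
        assert traj.free_hre2[-1] < 1e-3 * full_model.hre2_total

    def test_zero_hif1b_inflow_keeps_gene_at_baseline(self, full_model):
        params = full_model.default_parameters()
        params["hif1b_in.k"] = 0.0
        init = h.default_initial_state(full_model, hif1b=1e-12)
        traj = h.simulate(full_model, params, init, t_grid=[0, 8, 16])
        assert np.allclose(traj.gene_fold, 1.0, atol=1e-5)

    def test_nonpositive_level_rejected(self, full_model):
        with pytest.raises(ValidationError):
            h.titrate_hif1b(
                full_model,
                full_model.default_parameters(),
                h.default_initial_state(full_model),
                [0.0],
            )


class TestPredictGene:
    def test_fold_is_one_at_time_zero(self):
        model = h.build_default_model(12, 18)
        folds = h.predict_gene(model.default_parameters(), 12, 18, 60.0)
        assert folds[0] == pytest.approx(1.0)

    def test_no_sites_no_induction(self):
        model = h.build_default_model(0, 0)
        folds = h.predict_gene(model.default_parameters(), 0, 0, 60.0)
        assert np.allclose(folds, 1.0, atol=1e-6)

    def test_negative_counts_rejected(self):
        model = h.build_default_model(1, 1)
        with pytest.raises(ValidationError):
            h.predict_gene(model.default_parameters(), -1, 2, 60.0)

    def test_monotone_in_hre_count(self):
        model = h.build_default_model(1, 1)
        params = model.default_parameters()
        fold_small = h.predict_gene(params, 2, 2, 60.0, t_obs=(0, 16))[-1]
        fold_large = h.predict_gene(params, 8, 8, 60.0, t_obs=(0, 16))[-1]
        assert fold_large >= fold_small

    def test_saturated_regime_linear_in_count(self):
        """With HIF1B >> sites and tight binding, occupancy ~ count, so the
        excess induction is linear in count (5 % over counts 1..30)."""
        model = h.build_default_model(1, 0)
        params = model.default_parameters()
        counts = [1, 3, 10, 30]
        slopes = []
        for c in counts:
            fold = h.predict_gene(params, c, 0, 1e6, t_obs=(0, 48))[-1]
            slopes.append((fold - 1.0) / c)
        slopes = np.array(slopes)
        assert slopes.max() / slopes.min() - 1 < 0.05
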