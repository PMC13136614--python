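"""Growth predictor: baseline, loss components, recurrence, training."""

import numpy as np
import pytest

from chotwin import growth as G
from chotwin.basis import sigmoid_sum
from chotwin.records import GROWTH_NN_EXCLUDED
from chotwin.synthetic import (
    SyntheticConfig,
    generate_cohort,
    growth_training_batch,
)


class TestFeatureAssembly:
    def test_feature_count_2k_plus_3(self):
        assert G.feature_dimension(21) == 45
        assert G.feature_dimension(5) == 13
        x = G.assemble_features(np.zeros(21), np.zeros(21), 0.0, 0.0, 1.0)
        assert x.shape == (45,)

    def test_excluded_metabolites(self):
        assert set(GROWTH_NN_EXCLUDED) == {"glucose", "lactate", "ammonium"}
        assert not set(GROWTH_NN_EXCLUDED) & set(G.FEATURE_ANALYTES)
        assert len(G.FEATURE_ANALYTES) == 21


class TestBaseline:
    def test_constant_mu_reproduced(self):
        t = np.linspace(0, 14, 15)
        model = G.fit_baseline([t, t], [np.full(15, 0.03), np.full(15, 0.03)])
        assert np.max(np.abs(model(t) - 0.03)) < 1e-3

    def test_four_sigmoid_sum_recovered(self):
        t = np.linspace(0, 14, 60)
        amps, mids, slopes = (-0.5, -0.1, 0.05, -0.02), (5, 9, 2, 12), \
            (1.0, 0.8, 0.6, 0.7)
        y = sigmoid_sum(t, amps, mids, slopes, 0.7)
        model = G.fit_baseline([t], [y])
        assert np.sqrt(np.mean((model(t) - y) ** 2)) < 1e-6

    def test_single_batch_accepted(self):
        t = np.linspace(0, 14, 15)
        model = G.fit_baseline([t], [0.5 - 0.03 * t])
        assert np.isfinite(model.rmse)


class TestWeights:
    def test_identical_trajectories_uniform(self):
        w = G.trajectory_weights(np.tile([0.1, 0.2], (5, 1)))
        assert np.allclose(w, 0.2)

    def test_outlier_downweighted(self):
        mu = np.array([[0.05] * 3, [0.05] * 3, [0.5] * 3])
        w = G.trajectory_weights(mu)
        assert w[2] == w.min()

    def test_three_trajectory_ordering(self):
        # batch mean 0.05: nearest 0.03, then 0.02, then 0.10
        w = G.trajectory_weights([[0.02] * 4, [0.03] * 4, [0.10] * 4])
        assert w[1] > w[0] > w[2]
        assert w.sum() == pytest.approx(1.0)

    def test_time_weights_linear(self):
        w = G.time_weights([0.0, 7.0, 14.0], 14.0)
        assert np.allclose(w, [1.0, 0.5, 0.0])
        with pytest.raises(ValueError):
            G.time_weights([15.0], 14.0)


class TestLoss:
    def test_perfect_prediction_zero_terms(self):
        y = np.array([[0.1, 0.2, 0.15]])
        lc = G.compute_loss(y, y, np.array([1.0]), np.array([1, 0.5, 0.0]))
        assert lc.weighted_mse == 0.0
        assert lc.mean_matching == 0.0

    def test_affine_prediction_zero_smoothness(self):
        y = np.array([[0.0, 1.0, 2.0, 3.0]])
        lc = G.compute_loss(y, y, np.array([1.0]), np.ones(4))
        assert lc.smoothness == 0.0

    def test_second_difference_hand_value(self):
        y = np.array([[0.0, 1.0, 0.0]])
        lc = G.compute_loss(y, np.zeros((1, 3)), np.array([1.0]), np.ones(3))
        assert lc.smoothness == pytest.approx(2.0)

    def test_total_is_sum(self):
        rng = np.random.default_rng(0)
        y, mu = rng.random((4, 6)), rng.random((4, 6))
        w = G.trajectory_weights(mu)
        tw = G.time_weights(np.arange(6.0), 6.0)
        lc = G.compute_loss(y, mu, w, tw)
        assert lc.total == pytest.approx(
            lc.weighted_mse + lc.mean_matching + lc.smoothness)

    def test_nan_rejected(self):
        y = np.array([[np.nan, 0.0, 0.0]])
        with pytest.raises(ValueError):
            G.compute_loss(y, np.zeros((1, 3)), np.array([1.0]), np.ones(3))

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(1)
        y, mu = rng.random((3, 5)), rng.random((3, 5))
        w = G.trajectory_weights(mu)
        tw = G.time_weights(np.arange(5.0), 5.0)
        g = G._loss_gradient(y, mu, w, tw, 0.01, 0.01)
        eps = 1e-7
        for idx in ((0, 0), (1, 2), (2, 4)):
            yp, ym = y.copy(), y.copy()
            yp[idx] += eps
            ym[idx] -= eps
            fd = (G.compute_loss(yp, mu, w, tw, 0.01, 0.01).total
                  - G.compute_loss(ym, mu, w, tw, 0.01, 0.01).total) / (2 * eps)
            assert g[idx] == pytest.approx(fd, rel=1e-4, abs=1e-8)


class TestRecurrence:
    def test_zero_growth(self):
        xv, g = G.recurrence_step(2.0, 0.0, 1.0, 1.0)
        assert xv == 2.0 and g == 3.0

    def test_hand_iteration(self):
        xv, g = 1.0, 0.0
        for _ in range(2):
            xv, g = G.recurrence_step(xv, 0.1, g, 1.0)
        assert xv == pytest.approx(1.21)
        assert g == pytest.approx(2.1)

    def test_zero_vcd_keeps_gamma(self):
        _, g = G.recurrence_step(0.0, 0.5, 0.0, 1.0)
        assert g == 0.0

    def test_vcd_integration_matches_exponential(self):
        t = np.linspace(0, 5, 2001)
        xv = G.integrate_vcd(np.full_like(t, 0.3), t, 1.0)
        # first-order update: relative error ~ t*mu^2*dt/2 ~ 6e-4 here
        assert np.allclose(xv, np.exp(0.3 * t), rtol=1e-3)
        fine = G.integrate_vcd(np.full(20001, 0.3), np.linspace(0, 5, 20001),
                               1.0)
        assert abs(fine[-1] - np.exp(1.5)) < abs(xv[-1] - np.exp(1.5))


class TestNetwork:
    def test_backprop_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        net = G.DeviationNetwork(6, hidden=(8, 4), dropout=0.0, seed=1)
        x = rng.standard_normal((5, 6))
        y0, cache = net.forward(x)
        dy = rng.standard_normal(y0.shape)
        grads = net.backward(cache, dy)
        for key in ("W0", "g0", "c0", "W1", "b2"):
            p = net.params[key]
            idx = tuple(rng.integers(0, s) for s in p.shape)
            eps = 1e-6
            p[idx] += eps
            up, _ = net.forward(x)
            p[idx] -= 2 * eps
            dn, _ = net.forward(x)
            p[idx] += eps
            fd = np.sum((up - dn) * dy) / (2 * eps)
            assert grads[key][idx] == pytest.approx(fd, rel=1e-4, abs=1e-8)

    def test_shape_error(self):
        net = G.DeviationNetwork(6, hidden=(8,), seed=0)
        with pytest.raises(ValueError, match="feature dimension"):
            net.predict(np.zeros((2, 5)))

    def test_serialization_round_trip(self):
        net = G.DeviationNetwork(6, hidden=(8, 4), seed=3)
        clone = G.DeviationNetwork.from_state(net.state_dict())
        x = np.random.default_rng(0).standard_normal((4, 6))
        assert np.allclose(net.predict(x), clone.predict(x))


@pytest.fixture(scope="module")
def growth_batches():
    cfg = SyntheticConfig(n_batches=8, n_media_groups=4, noise_cv=0.02)
    cohort = generate_cohort(cfg)
    return [growth_training_batch(r, t, n_traj=30, jitter=0.05, seed=i)
            for i, (r, t) in enumerate(cohort)]


class TestTraining:
    def test_zero_learning_rate_one_epoch(self, growth_batches):
        cfg = G.TrainingConfig(epochs=1, n_traj=30, learning_rate=0.0,
                               validation_fraction=0.25, seed=0)
        model, _ = G.train(growth_batches, cfg)
        fresh = G.DeviationNetwork(
            G.feature_dimension(30 and len(model.feature_analytes)),
            dropout=cfg.dropout, seed=cfg.seed)
        for k, v in fresh.params.items():
            assert np.array_equal(model.network.params[k], v)
        assert len(model.loss_history) == 1

    def test_fixed_seed_reproducible(self, growth_batches):
        cfg = G.TrainingConfig(epochs=3, n_traj=30, validation_fraction=0.25,
                               seed=7)
        m1, _ = G.train(growth_batches, cfg)
        m2, _ = G.train(growth_batches, cfg)
        assert m1.loss_history == m2.loss_history

    def test_loss_decreases(self, growth_batches):
        cfg = G.TrainingConfig(epochs=40, n_traj=30, validation_fraction=0.25,
                               seed=0)
        model, _ = G.train(growth_batches, cfg)
        assert model.loss_history[-1] < 0.5 * model.loss_history[0]

    def test_zero_deviation_equals_baseline(self, growth_batches):
        cfg = G.TrainingConfig(epochs=1, n_traj=30, learning_rate=0.0,
                               validation_fraction=0.25, seed=0)
        model, _ = G.train(growth_batches, cfg)
        # zero the final layer: prediction must equal the baseline exactly
        last = model.network.n_layers - 1
        model.network.params[f"W{last}"][:] = 0.0
        model.network.params[f"b{last}"][:] = 0.0
        b = growth_batches[0]
        pred = model.predict_mu(b.times, b.rates.mean(axis=0),
                                b.concentrations, b.xv0)
        assert np.allclose(pred, model.baseline(b.times), atol=1e-12)

    def test_time_ordered_contract(self, growth_batches):
        cfg = G.TrainingConfig(epochs=1, n_traj=30, learning_rate=0.0,
                               validation_fraction=0.25, seed=0)
        model, _ = G.train(growth_batches, cfg)
        b = growth_batches[0]
        shuffled = b.times[::-1].copy()
        with pytest.raises(ValueError, match="increasing"):
            model.predict_mu(shuffled, b.rates.mean(axis=0),
                             b.concentrations, b.xv0)

    def test_held_out_improves_on_baseline(self, growth_batches):
        """The deviation network reduces held-out error below the pooled
        baseline (pooled over the validation batches)."""
        cfg = G.TrainingConfig(epochs=100, n_traj=30,
                               validation_fraction=0.25, seed=0)
        model, val = G.train(growth_batches, cfg)
        assert val
        tot_nn = tot_base = 0.0
        for b in val:
            mu = b.mu_trajectories.mean(axis=0)
            pred = model.predict_mu(b.times, b.rates.mean(axis=0),
                                    b.concentrations, b.xv0)
            base = model.baseline(b.times)
            tot_nn += np.mean((pred - mu) ** 2)
            tot_base += np.mean((base - mu) ** 2)
        assert np.sqrt(tot_nn / tot_base) < 0.8

    def test_sampling_frequency_invariance(self, growth_batches):
        """Resampling the same trajectory to a finer grid leaves the
        predicted growth curve within tolerance."""
        cfg = G.TrainingConfig(epochs=40, n_traj=30, validation_fraction=0.25,
                               seed=0)
        model, _ = G.train(growth_batches, cfg)
        b = growth_batches[0]
        daily = model.predict_mu(b.times, b.rates.mean(axis=0),
                                 b.concentrations, b.xv0)
        fine_t = np.arange(b.times[0], b.times[-1] + 1e-9, 0.25)
        rates_f = np.stack([np.interp(fine_t, b.times, b.rates.mean(axis=0)[:, j])
                            for j in range(b.rates.shape[2])], axis=1)
        conc_f = np.stack([np.interp(fine_t, b.times, b.concentrations[:, j])
                           for j in range(b.concentrations.shape[1])], axis=1)
        fine = model.predict_mu(fine_t, rates_f, conc_f, b.xv0)
        shared = np.searchsorted(fine_t, b.times)
        assert np.sqrt(np.mean((fine[shared] - daily) ** 2)) < 0.05
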