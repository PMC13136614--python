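"""Integrated digital twin: mass balance, evaluation, closed-loop coupling."""

import numpy as np
import pandas as pd
import pytest

from chotwin import growth as G
from chotwin import pcdfba as P
from chotwin import twin as T
from chotwin.kinetics import KineticParameters
from chotwin.records import (
    FLEX_ANALYTES,
    GROWTH_NN_EXCLUDED,
    GROWTH_RATE_NAME,
    feed_schedule_from_record,
)
from chotwin.synthetic import growth_training_batch


class TestMassBalanceStep:
    def test_conservation(self):
        assert T.mass_balance_step(2.0, 0.0, 5.0, 0.0, 10.0, 0.0, 0.1) == 2.0

    def test_equal_concentration_feed(self):
        out = T.mass_balance_step(2.0, 0.0, 5.0, 1.0, 10.0, 2.0, 0.1)
        assert out == pytest.approx(2.0)

    def test_dilution_matches_exponential(self):
        e, f_over_v = 4.0, 0.3
        dt = 0.001
        for _ in range(10000):
            e = T.mass_balance_step(e, 0.0, 0.0, f_over_v * 10.0, 10.0,
                                    0.0, dt)
        assert e == pytest.approx(4.0 * np.exp(-f_over_v * 10.0), rel=1e-3)

    def test_production_term(self):
        out = T.mass_balance_step(1.0, 0.5, 2.0, 0.0, 10.0, 0.0, 0.1)
        assert out == pytest.approx(1.0 + 0.5 * 2.0 * 0.1)


class TestEvaluate:
    def _result(self, times, values):
        conc = pd.DataFrame({"glucose": values}, index=times)
        n = len(times)
        return T.TwinResult(
            times=np.asarray(times, dtype=float), concentrations=conc,
            vcd=np.asarray(values, dtype=float), dead=np.zeros(n),
            lysed=np.zeros(n), biomaterial=np.zeros(n), mu=np.zeros(n),
            mu_eff=np.zeros(n), volume=np.full(n, 10.0),
            fluxes=pd.DataFrame(index=times), scores=np.zeros((n, 1)))

    def _record(self, times, values):
        from chotwin.records import ProcessRecord

        conc = pd.DataFrame({"glucose": values}, index=times)
        t = np.asarray(times, dtype=float)
        return ProcessRecord("X", 0, t, conc, np.asarray(values, float),
                             np.ones_like(t), np.full_like(t, 10.0))

    def test_perfect_prediction(self):
        res = self._result([0.0, 1.0, 2.0], [1.0, 2.0, 3.0])
        ev = T.evaluate(res, self._record([0.0, 1.0, 2.0], [1.0, 2.0, 3.0]))
        assert ev.loc["glucose", "r2"] == pytest.approx(1.0)
        assert ev.loc["glucose", "sse"] == 0.0

    def test_mean_prediction_r2_zero(self):
        res = self._result([0.0, 1.0, 2.0], [2.0, 2.0, 2.0])
        ev = T.evaluate(res, self._record([0.0, 1.0, 2.0], [1.0, 2.0, 3.0]))
        assert ev.loc["glucose", "r2"] == pytest.approx(0.0)

    def test_hand_computed_example(self):
        # obs (1,2,3) vs pred (1,2,4): SSE = 1, SStot = 2, R^2 = 0.5
        res = self._result([0.0, 1.0, 2.0], [1.0, 2.0, 4.0])
        ev = T.evaluate(res, self._record([0.0, 1.0, 2.0], [1.0, 2.0, 3.0]))
        assert ev.loc["glucose", "sse"] == pytest.approx(1.0)
        assert ev.loc["glucose", "r2"] == pytest.approx(0.5)
        assert ev.loc["glucose", "log_sse"] == pytest.approx(0.0)

    def test_zero_variance_r2_missing(self):
        res = self._result([0.0, 1.0, 2.0], [1.0, 2.0, 3.0])
        ev = T.evaluate(res, self._record([0.0, 1.0, 2.0], [2.0, 2.0, 2.0]))
        assert np.isnan(ev.loc["glucose", "r2"])

    def test_observations_beyond_horizon_rejected(self):
        res = self._result([0.0, 1.0], [1.0, 2.0])
        with pytest.raises(ValueError, match="horizon"):
            T.evaluate(res, self._record([0.0, 1.0, 5.0], [1.0, 2.0, 3.0]))


HELD_OUT = 3   # LOBO-style held-out batch for the end-to-end sanity check


@pytest.fixture(scope="module")
def twin_setup(clean_cohort, toy_network, toy_rate_tables, toy_panel):
    """Artifacts trained on the cohort minus the held-out batch."""
    growth_feats = tuple(a for a in toy_panel
                         if a not in GROWTH_NN_EXCLUDED + (GROWTH_RATE_NAME,))
    train = [c for i, c in enumerate(clean_cohort) if i != HELD_OUT]
    tables = {rec.batch_id: toy_rate_tables[rec.batch_id]
              for rec, _ in train}
    targets = P.window_pca(tables, analytes=toy_panel)
    loading = P.train_loading_model(
        tables, targets, feature_set=toy_panel,
        hp_config=P.LoadingHPConfig(budget=1, max_iter=600))
    stats = P.compute_band_stats(tables, analytes=toy_panel)
    gb = [growth_training_batch(r, t, n_traj=30, jitter=0.05, seed=i,
                                analytes=growth_feats)
          for i, (r, t) in enumerate(train)]
    gm, _ = G.train(gb, G.TrainingConfig(epochs=150, n_traj=30,
                                         validation_fraction=0.0, seed=0))
    npc = targets.max_pcs()
    bounds = (np.full(npc, -50.0), np.full(npc, 50.0))
    return gm, loading, stats, bounds


def run_twin_on(record, truth, twin_setup, toy_network, toy_panel, **kw):
    gm, loading, stats, bounds = twin_setup
    analytes = [a for a in toy_panel if a != GROWTH_RATE_NAME]
    init = {a: float(truth.latent[a].iloc[0]) for a in analytes}
    init["vcd"] = float(truth.latent.Xv.iloc[0])
    init["volume_ml"] = 10.0
    return T.run_twin(init, feed_schedule_from_record(record), gm,
                      KineticParameters(), toy_network, loading, stats,
                      T.TwinConfig(**kw), score_bounds=bounds)


class TestRunTwin:
    def test_no_look_ahead_bit_identity(self, clean_cohort, twin_setup,
                                        toy_network, toy_panel):
        """Deleting every observation after t0 leaves the simulation
        bit-identical: the twin reads only the initial state and feeds."""
        rec, truth = clean_cohort[HELD_OUT]
        res1 = run_twin_on(rec, truth, twin_setup, toy_network, toy_panel,
                           dt=0.25, horizon=6.0)
        import copy

        rec2 = copy.deepcopy(rec)
        rec2.concentrations.iloc[1:] = np.nan
        rec2.vcd[1:] = np.nan
        res2 = run_twin_on(rec2, truth, twin_setup, toy_network, toy_panel,
                           dt=0.25, horizon=6.0)
        assert np.array_equal(res1.concentrations.values,
                              res2.concentrations.values)
        assert np.array_equal(res1.vcd, res2.vcd)
        assert np.array_equal(res1.mu, res2.mu)

    def test_volume_bookkeeping(self, clean_cohort, twin_setup, toy_network,
                                toy_panel):
        rec, truth = clean_cohort[HELD_OUT]
        res = run_twin_on(rec, truth, twin_setup, toy_network, toy_panel,
                          dt=0.25, horizon=14.0)
        t_end = res.times[-1]
        fed = sum(e.volume_ml for e in rec.feed_events
                  if e.time_d <= t_end + 1e-9)
        sampled = sum(s.volume_ml for s in rec.sample_events
                      if s.time_d <= t_end + 1e-9)
        assert res.volume[-1] == pytest.approx(10.0 + fed - sampled, abs=1e-9)

    def test_hard_bound_fluxes_match_kinetic_rates(self, clean_cohort,
                                                   twin_setup, toy_network,
                                                   toy_panel):
        """At unrelaxed steps the FLEX exchange fluxes equal the kinetic
        layer's rates (hard-bound consistency)."""
        rec, truth = clean_cohort[HELD_OUT]
        res = run_twin_on(rec, truth, twin_setup, toy_network, toy_panel,
                          dt=0.25, horizon=14.0)
        from chotwin.kinetics import (
            PopulationState, death_lysis_rates, effective_growth,
            flex_specific_rates)
        kp = KineticParameters()
        relaxed = set(res.relaxed_steps)
        checked = 0
        for k, t in enumerate(res.times):
            if k in relaxed:
                continue
            pop = PopulationState(res.vcd[k], res.dead[k], res.lysed[k],
                                  res.biomaterial[k])
            mu_d, mu_l = death_lysis_rates(pop, kp)
            mu_eff = float(effective_growth(res.mu[k], mu_d, mu_l))
            conc = res.concentrations.iloc[k][list(FLEX_ANALYTES)].to_numpy()
            rates = flex_specific_rates(conc, mu_eff, kp)
            for a, r in zip(FLEX_ANALYTES, rates):
                assert res.fluxes.iloc[k][a] == pytest.approx(r, abs=1e-7)
            checked += 1
        assert checked > 0

    def test_titer_nondecreasing_when_flux_nonnegative(self, clean_cohort,
                                                       twin_setup,
                                                       toy_network,
                                                       toy_panel):
        rec, truth = clean_cohort[HELD_OUT]
        res = run_twin_on(rec, truth, twin_setup, toy_network, toy_panel,
                          dt=0.25, horizon=14.0)
        if np.all(res.fluxes["titer"].values >= -1e-12):
            titer = res.concentrations["titer"].values
            feed_times = {e.time_d for e in rec.feed_events}
            for k in range(1, len(titer)):
                # dilution at feeds may lower titer; exclude those steps
                crossed = any(res.times[k - 1] < ft <= res.times[k]
                              for ft in feed_times)
                if not crossed:
                    assert titer[k] >= titer[k - 1] - 1e-12

    def test_closed_loop_feedback(self, clean_cohort, twin_setup,
                                  toy_network, toy_panel):
        """Perturbing a concentration changes subsequent growth-rate
        predictions: the concentration->growth coupling is active."""
        rec, truth = clean_cohort[HELD_OUT]
        gm, loading, stats, bounds = twin_setup
        analytes = [a for a in toy_panel if a != GROWTH_RATE_NAME]
        init = {a: float(truth.latent[a].iloc[0]) for a in analytes}
        init["vcd"] = float(truth.latent.Xv.iloc[0])
        init["volume_ml"] = 10.0
        base = T.run_twin(init, None, gm, KineticParameters(), toy_network,
                          loading, stats, T.TwinConfig(dt=0.25, horizon=4.0),
                          score_bounds=bounds)
        init2 = dict(init)
        init2["glutamine"] *= 1.1
        pert = T.run_twin(init2, None, gm, KineticParameters(), toy_network,
                          loading, stats, T.TwinConfig(dt=0.25, horizon=4.0),
                          score_bounds=bounds)
        assert np.max(np.abs(base.mu - pert.mu)) > 1e-6

    def test_held_out_terminal_vcd(self, clean_cohort, twin_setup,
                                   toy_network, toy_panel):
        """End-to-end sanity on a held-out batch: the twin's terminal VCD
        stays within 25% of the generator's latent truth."""
        rec, truth = clean_cohort[HELD_OUT]
        res = run_twin_on(rec, truth, twin_setup, toy_network, toy_panel,
                          dt=0.1, horizon=14.0)
        true_end = float(truth.latent.Xv.iloc[-1])
        assert abs(res.vcd[-1] - true_end) / true_end < 0.25
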