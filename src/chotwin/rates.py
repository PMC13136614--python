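"""Bayesian ensemble estimation of specific metabolic rates from concentrations.

The pipeline converts sampled extracellular concentrations into posterior
ensembles of specific rates in four steps:

1. **Volume correction** — feeding and sampling events cause instantaneous
   concentration jumps that have nothing to do with cellular exchange.  These
   jumps are removed additively, yielding a continuous "pseudo-concentration"
   series whose variation reflects cellular uptake/secretion only.  The
   transformation is exactly invertible given the event log.
2. **Logistic-basis fitting** — the pseudo-concentration series is fitted with
   a linear combination of logistic basis functions.  Posteriors are computed
   for 1..max_basis terms and the model is chosen by log evidence (a larger
   model needs > 1 nat of evidence to be preferred).
3. **Rate extraction** — each posterior draw has an analytic time derivative;
   dividing by the paired VCD trajectory gives specific-rate trajectories
   (g/1e9 cells/day; production positive) at arbitrary time points.
4. **Concentration back-propagation** — events can be re-applied to posterior
   pseudo-curves to reconstruct raw concentrations with uncertainty.

The default inference backend is an affine-invariant ensemble MCMC sampler
(emcee) seeded from a least-squares MAP fit, with model evidence from a
Laplace approximation; a fast pure-Laplace backend is available behind the
same interface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from . import basis
from .records import ProcessRecord

#: Concentration at an event time is post-event; queries at an event time
#: therefore return the post-event value.
POST_EVENT_CONVENTION = "post-event"


# --------------------------------------------------------------------------
# volume correction
# --------------------------------------------------------------------------

@dataclass
class EventJump:
    """One instantaneous mixing event: ``c_post = d * c_pre + (1-d) * c_feed``."""

    time_d: float
    dilution: float       # V_pre / (V_pre + V_feed)
    feed_conc: float      # g/l of the analyte in the added stream

    def forward(self, c_pre: float) -> float:
        return self.dilution * c_pre + (1.0 - self.dilution) * self.feed_conc

    def backward(self, c_post: float) -> float:
        return (c_post - (1.0 - self.dilution) * self.feed_conc) / self.dilution


@dataclass
class PseudoConcentrationSeries:
    times: np.ndarray
    values: np.ndarray
    analyte: str
    batch: str
    jumps: list[EventJump] = field(default_factory=list)
    noise_sd: np.ndarray | None = None   # per-point measurement sd, pseudo scale

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have the same length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.noise_sd is not None:
            self.noise_sd = np.asarray(self.noise_sd, dtype=float)


def event_jumps(record: ProcessRecord, analyte: str) -> list[EventJump]:
    """Derive the mixing-jump log for one analyte from the record's events.

    Within one sampling time the order is: sample withdrawal (volume only),
    then feed boluses in event-log order.  Volumes are reconstructed backwards
    from the recorded post-event volume trajectory.
    """
    jumps: list[EventJump] = []
    vcd_like = analyte == "vcd"
    for i, t in enumerate(record.times_d):
        feeds = [e for e in record.feed_events if np.isclose(e.time_d, t)]
        if not feeds:
            continue
        v_post = record.volume_ml[i]
        vols = [e.volume_ml for e in feeds]
        v_pre = v_post - sum(vols)
        if v_pre <= 0:
            raise ValueError(f"non-positive pre-feed volume at t={t}")
        v = v_pre
        for e in feeds:
            if vcd_like:
                conc = 0.0
            else:
                if e.stream not in record.feed_compositions:
                    raise KeyError(
                        f"missing composition for feed stream {e.stream!r}")
                conc = record.feed_concentration(e.stream, analyte)
            jumps.append(EventJump(t, v / (v + e.volume_ml), conc))
            v += e.volume_ml
    return jumps


def volume_correct(record: ProcessRecord, analyte: str,
                   noise_cv: float = 0.05) -> PseudoConcentrationSeries:
    """Remove feed/dilution jumps from a raw concentration series.

    Measured values at event times are post-event; the pre-event value is
    recovered by inverting the mixing jumps, and an additive correction makes
    the pseudo series continuous across each event.  The raw series is exactly
    recoverable (see :func:`invert_volume_correction`).

    ``noise_cv`` is the assumed multiplicative assay coefficient of variation;
    each event correction is an affine function of the measured value at the
    event time, so measurement noise accumulates along the correction chain.
    The propagated per-point standard deviation is attached to the series and
    used by :func:`fit_basis` as a known heteroscedastic noise model.
    """
    raw = record.vcd if analyte == "vcd" else record.series(analyte)
    jumps = event_jumps(record, analyte)
    pseudo = np.empty_like(raw, dtype=float)
    var = np.empty_like(raw, dtype=float)
    corr = 0.0
    corr_var = 0.0
    for i, t in enumerate(record.times_d):
        here = [j for j in jumps if np.isclose(j.time_d, t)]
        sd_i = noise_cv * abs(raw[i])
        if here:
            c = raw[i]
            for j in reversed(here):
                c = j.backward(c)       # pre-event concentration
            pseudo[i] = c + corr
            # correction slope wrt the measured value: 1/D - 1
            D = float(np.prod([j.dilution for j in here]))
            kappa = 1.0 / D - 1.0
            var[i] = corr_var + (sd_i / D) ** 2
            corr += c - raw[i]
            corr_var += (kappa * sd_i) ** 2
        else:
            pseudo[i] = raw[i] + corr
            var[i] = corr_var + sd_i ** 2
    return PseudoConcentrationSeries(record.times_d.copy(), pseudo,
                                     analyte, record.batch_id, jumps,
                                     np.sqrt(var))


def invert_volume_correction(series: PseudoConcentrationSeries) -> np.ndarray:
    """Exact inverse of :func:`volume_correct` on the same time grid."""
    raw = np.empty_like(series.values)
    corr = 0.0
    for i, t in enumerate(series.times):
        here = [j for j in series.jumps if np.isclose(j.time_d, t)]
        c = series.values[i] - corr
        if here:
            pre = c
            for j in here:
                c = j.forward(c)
            corr += pre - c
        raw[i] = c
    return raw


# --------------------------------------------------------------------------
# Bayesian logistic-basis fitting
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SamplerConfig:
    backend: str = "emcee"       # "emcee" (full posterior) | "laplace" (fast approx.)
    n_draws: int = 100
    n_starts: int = 4
    evidence_margin: float = 1.0  # nats required to prefer a larger model
    ensemble: str = "rich"        # "rich": draws from the largest basis model;
                                  # "selected": draws from the evidence winner
    emcee_steps: int = 3000
    emcee_burn: int = 1500
    seed: int = 0


@dataclass
class BasisFitPosterior:
    """Posterior of the logistic-basis fit for one analyte/batch.

    ``n_basis``/``theta_map`` describe the evidence-selected model;
    ``parameter_draws`` are posterior samples used for uncertainty ensembles
    and may come from the largest fitted model (``ensemble="rich"``), whose
    posterior includes every simpler fit compatible with the noise and hence
    honestly represents between-sample interpolation ambiguity.
    """

    n_basis: int
    parameter_draws: np.ndarray   # (n_draws, 3*draw_n_basis + 1)
    log_evidence: float
    analyte: str
    batch: str
    theta_map: np.ndarray
    sigma: float
    t_range: tuple[float, float]
    jumps: list[EventJump] = field(default_factory=list)

    @staticmethod
    def _nb(theta: np.ndarray) -> int:
        return (len(theta) - 1) // 3

    def curve(self, theta: np.ndarray, t) -> np.ndarray:
        return basis.evaluate(theta, t, self._nb(theta))

    def curve_derivative(self, theta: np.ndarray, t) -> np.ndarray:
        return basis.evaluate_derivative(theta, t, self._nb(theta))

    def mean_curve(self, t) -> np.ndarray:
        return self.curve(self.theta_map, t)


class EstimationError(RuntimeError):
    pass


def _initial_guesses(t, y, n_basis, n_starts, rng):
    t0, t1 = t[0], t[-1]
    span = max(y.max() - y.min(), 1e-6)
    guesses = []
    for s in range(n_starts):
        mids = np.linspace(t0 + 0.15 * (t1 - t0), t1 - 0.15 * (t1 - t0), n_basis)
        if s > 0:
            mids = mids + rng.uniform(-0.1, 0.1, n_basis) * (t1 - t0)
        amps = np.full(n_basis, (y[-1] - y[0]) / n_basis)
        if s > 0:
            amps = amps * rng.uniform(0.3, 2.0, n_basis) * rng.choice([-1, 1], n_basis)
        slopes = np.full(n_basis, (t1 - t0) / (4.0 * n_basis)) * \
            (rng.uniform(0.5, 2.0, n_basis) if s > 0 else 1.0)
        offset = y[0]
        guesses.append(basis.pack_params(
            amps if s > 0 else np.where(amps == 0, 0.1 * span, amps),
            mids, slopes, offset))
    return guesses


def _canonicalize(theta, n_basis):
    """Fold negative-slope logistics into the equivalent positive-slope form.

    ``A/(1+exp(-(t-m)/s))`` with ``s < 0`` equals ``A - A/(1+exp(-(t-m)/|s|))``,
    so the sign flip is absorbed into the amplitude and offset.
    """
    a, m, s, c = basis.unpack_params(np.array(theta, dtype=float), n_basis)
    for k in range(n_basis):
        if s[k] < 0:
            c += a[k]
            a[k] = -a[k]
            s[k] = -s[k]
    return basis.pack_params(a, m, s, c)


def _log_prior(theta, n_basis, span, t0, t1):
    """Weakly informative priors scaled to the data range (all soft)."""
    a, m, s, c = basis.unpack_params(theta, n_basis)
    scale = 3.0 * max(span, 1e-6)
    lp = -0.5 * np.sum((a / scale) ** 2) - n_basis * np.log(scale * np.sqrt(2 * np.pi))
    lp += -0.5 * (c / scale) ** 2 - np.log(scale * np.sqrt(2 * np.pi))
    center, width = 0.5 * (t0 + t1), 0.75 * (t1 - t0) + 1.0
    lp += -0.5 * np.sum(((m - center) / width) ** 2) \
        - n_basis * np.log(width * np.sqrt(2 * np.pi))
    if np.any(s <= 0):
        return -np.inf
    ls = np.log(s)
    mu_s, sd_s = np.log((t1 - t0) / 4.0), 1.5
    lp += np.sum(-0.5 * ((ls - mu_s) / sd_s) ** 2 - ls
                 - np.log(sd_s * np.sqrt(2 * np.pi)))
    return lp


def fit_basis(series: PseudoConcentrationSeries, max_basis: int = 3,
              sampler_config: SamplerConfig | None = None) -> BasisFitPosterior:
    """Fit logistic-basis models of increasing size and select by evidence.

    The measurement noise is treated as *known* (heteroscedastic, propagated
    by :func:`volume_correct`); evidence-based model comparison and posterior
    width are therefore referenced to the assay noise rather than to the
    in-sample residual, which would be over-confident for a flexible basis on
    a short series.
    """
    cfg = sampler_config or SamplerConfig()
    t, y = series.times, series.values
    if len(t) < 4:
        raise ValueError("need at least 4 time points to fit a basis model")
    if max_basis < 1:
        raise ValueError("max_basis must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    span = max(y.max() - y.min(), 1e-6)
    if series.noise_sd is not None:
        sd = np.maximum(series.noise_sd, 1e-7 * span)
    else:
        sd = np.full(len(t), 1e-7 * span)  # refined below from residuals
    candidates = []
    for n_basis in range(1, max_basis + 1):
        best = None
        for x0 in _initial_guesses(t, y, n_basis, cfg.n_starts, rng):
            res = least_squares(
                lambda th: (basis.evaluate(th, t, n_basis) - y) / sd, x0,
                method="lm", max_nfev=4000, ftol=1e-14, xtol=1e-14,
                gtol=1e-14)
            if best is None or res.cost < best.cost:
                best = res
        if best is None or not np.all(np.isfinite(best.x)):
            raise EstimationError(
                f"basis fit failed for {series.analyte}/{series.batch} "
                f"at n_basis={n_basis}")
        theta = _canonicalize(best.x, n_basis)
        n = len(t)
        sd_fit = sd
        if series.noise_sd is None:
            # no noise model supplied: fall back to the residual scale
            scale = max(np.sqrt(2 * best.cost / n), 1.0)
            sd_fit = sd * scale
        sse_w = float(np.sum(((basis.evaluate(theta, t, n_basis) - y)
                              / sd_fit) ** 2))
        d = len(theta)
        J = best.jac * (sd / sd_fit)[:, None]
        prior_prec = np.eye(d) / (3.0 * span) ** 2
        A = J.T @ J + prior_prec
        sign, logdet = np.linalg.slogdet(A)
        if sign <= 0:
            A = A + 1e-8 * np.eye(d)
            sign, logdet = np.linalg.slogdet(A)
        loglik = -0.5 * np.sum(np.log(2 * np.pi * sd_fit ** 2)) - 0.5 * sse_w
        lp = _log_prior(theta, n_basis, span, t[0], t[-1])
        log_ev = loglik + lp + 0.5 * d * np.log(2 * np.pi) - 0.5 * logdet
        candidates.append((n_basis, theta, sd_fit, log_ev, A))

    chosen = candidates[0]
    for cand in candidates[1:]:
        if cand[3] > chosen[3] + cfg.evidence_margin:
            chosen = cand
    n_basis, theta, sd_fit, log_ev, A = chosen
    sigma = float(np.median(sd_fit))

    # the uncertainty ensemble is drawn from the richest model by default:
    # its posterior contains every simpler curve compatible with the noise,
    # so between-sample derivative ambiguity is represented honestly
    draw_model = candidates[-1] if cfg.ensemble == "rich" else chosen
    nb_d, theta_d, sd_d, _, A_d = draw_model

    if cfg.backend == "laplace":
        draws = _band_constrained_draws(theta_d, A_d, t, y, sd_d, nb_d,
                                        cfg.n_draws, rng)
    elif cfg.backend == "emcee":
        import emcee

        def log_post(th):
            lp = _log_prior(th, nb_d, span, t[0], t[-1])
            if not np.isfinite(lp):
                return -np.inf
            r = (basis.evaluate(th, t, nb_d) - y) / sd_d
            return lp - 0.5 * np.sum(r ** 2)
        d = len(theta_d)
        nwalkers = max(2 * d + 2, 24)
        p0 = theta_d + 1e-2 * (np.abs(theta_d) + 0.02 * span) \
            * rng.standard_normal((nwalkers, d))
        sampler = emcee.EnsembleSampler(nwalkers, d, log_post)
        sampler._random = np.random.RandomState(cfg.seed)   # determinism
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sampler.run_mcmc(p0, cfg.emcee_steps, progress=False)
        chain = sampler.get_chain(discard=cfg.emcee_burn, flat=True)
        if not len(chain):
            raise EstimationError("emcee produced no post-burn-in samples")
        idx = rng.choice(len(chain), size=cfg.n_draws)
        draws = chain[idx]
    else:
        raise ValueError(f"unknown sampler backend {cfg.backend!r}")

    return BasisFitPosterior(n_basis, draws, log_ev, series.analyte,
                             series.batch, theta, sigma,
                             (float(t[0]), float(t[-1])), series.jumps)


def _band_constrained_draws(theta, A, t, y, sd, n_basis, n_draws, rng):
    """Gaussian proposals projected into the chi-square likelihood band.

    Proposals come from the Laplace covariance; a proposal whose whitened SSE
    leaves the 99.5% chi-square band around the MAP fit is shrunk back toward
    the MAP by bisection, so every draw stays in the region where the fit is
    statistically indistinguishable from the optimum at the known noise level.
    """
    from scipy.stats import chi2

    d = len(theta)
    cov = np.linalg.inv(A)
    cov = 0.5 * (cov + cov.T)
    sse_map = float(np.sum(((basis.evaluate(theta, t, n_basis) - y) / sd) ** 2))
    band = chi2.ppf(0.995, d)
    ns = slice(2 * n_basis, 3 * n_basis)

    def sse_at(th):
        return float(np.sum(((basis.evaluate(th, t, n_basis) - y) / sd) ** 2))

    draws = np.empty((n_draws, d))
    deltas = rng.multivariate_normal(np.zeros(d), cov, size=n_draws,
                                     method="svd")
    for k in range(n_draws):
        th = theta + deltas[k]
        th[ns] = np.maximum(np.abs(th[ns]), 1e-3)
        if sse_at(th) > sse_map + band:
            lo, hi = 0.0, 1.0
            for _ in range(14):
                mid = 0.5 * (lo + hi)
                thm = theta + mid * deltas[k]
                thm[ns] = np.maximum(np.abs(thm[ns]), 1e-3)
                if sse_at(thm) <= sse_map + band:
                    lo = mid
                else:
                    hi = mid
            th = theta + lo * deltas[k]
            th[ns] = np.maximum(np.abs(th[ns]), 1e-3)
        draws[k] = th
    return draws


# --------------------------------------------------------------------------
# rate ensembles
# --------------------------------------------------------------------------

@dataclass
class RateEnsemble:
    times: np.ndarray
    trajectories: np.ndarray      # (n_traj, n_times)
    analyte: str
    batch: str

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.trajectories = np.atleast_2d(np.asarray(self.trajectories, float))

    @property
    def mean(self) -> np.ndarray:
        return self.trajectories.mean(axis=0)

    @property
    def p5(self) -> np.ndarray:
        return np.percentile(self.trajectories, 5, axis=0)

    @property
    def p95(self) -> np.ndarray:
        return np.percentile(self.trajectories, 95, axis=0)

    def percentile(self, q: float) -> np.ndarray:
        return np.percentile(self.trajectories, q, axis=0)


def sample_rates(posterior: BasisFitPosterior, vcd, times,
                 n_traj: int = 100, seed: int = 0) -> RateEnsemble:
    """Specific-rate ensemble: analytic pseudo-curve derivatives over VCD.

    ``vcd`` may be a callable ``t -> VCD``, a ``(times, values)`` tuple
    (linearly interpolated), or a :class:`RateEnsemble`-like object carrying
    VCD trajectories, in which case rate draws are index-matched to VCD draws
    by a seeded random pairing.
    """
    times = np.asarray(times, dtype=float)
    t0, t1 = posterior.t_range
    if times.min() < t0 - 1e-9 or times.max() > t1 + 1e-9:
        raise ValueError("requested times outside the fitted horizon")
    rng = np.random.default_rng(seed)
    n_draws = len(posterior.parameter_draws)
    idx = rng.integers(0, n_draws, size=n_traj) if n_traj != n_draws \
        else np.arange(n_draws)
    derivs = np.stack([
        posterior.curve_derivative(posterior.parameter_draws[i], times)
        for i in idx
    ])
    if callable(vcd):
        denom = np.asarray(vcd(times), dtype=float)[None, :]
    elif isinstance(vcd, tuple):
        denom = np.interp(times, vcd[0], vcd[1])[None, :]
    else:  # ensemble of VCD trajectories: seeded index-matched pairing
        vidx = rng.integers(0, vcd.trajectories.shape[0], size=n_traj)
        denom = np.stack([
            np.interp(times, vcd.times, vcd.trajectories[i]) for i in vidx])
    if np.any(denom <= 0):
        raise ValueError("VCD must be positive at all requested times")
    return RateEnsemble(times, derivs / denom, posterior.analyte, posterior.batch)


def estimate_growth(record: ProcessRecord, max_basis: int = 3,
                    sampler_config: SamplerConfig | None = None,
                    times=None, n_traj: int = 100,
                    noise_cv: float = 0.05) -> RateEnsemble:
    """Net specific growth rate from VCD: derivative of log pseudo-VCD.

    The VCD series is volume-corrected like any analyte (feed concentration
    zero), the log series is fitted with the logistic-basis machinery, and
    each posterior draw's derivative is a net growth-rate trajectory (1/d).
    """
    pseudo = volume_correct(record, "vcd", noise_cv=noise_cv)
    if np.any(pseudo.values <= 0):
        raise ValueError("pseudo-VCD must be positive to take logs")
    log_series = PseudoConcentrationSeries(
        pseudo.times, np.log(pseudo.values), "log_vcd", record.batch_id,
        pseudo.jumps, pseudo.noise_sd / np.abs(pseudo.values))
    post = fit_basis(log_series, max_basis, sampler_config)
    t = np.asarray(times if times is not None else record.times_d, dtype=float)
    cfg = sampler_config or SamplerConfig()
    rng = np.random.default_rng(cfg.seed + 1)
    n_draws = len(post.parameter_draws)
    idx = rng.integers(0, n_draws, size=n_traj) if n_traj != n_draws \
        else np.arange(n_draws)
    derivs = np.stack([
        post.curve_derivative(post.parameter_draws[i], t) for i in idx
    ])
    return RateEnsemble(t, derivs, "growth", record.batch_id)


def reconstruct_concentrations(posterior: BasisFitPosterior,
                               record: ProcessRecord, times) -> np.ndarray:
    """Re-apply dilution/feed events to posterior pseudo-curves.

    Returns an ensemble array (n_draws, n_times) of raw-concentration
    reconstructions.  At a query time equal to an event time the post-event
    value is returned.
    """
    times = np.asarray(times, dtype=float)
    t0, t1 = posterior.t_range
    if times.min() < t0 - 1e-9 or times.max() > t1 + 1e-9:
        raise ValueError("requested times outside the fitted horizon")
    jumps = sorted(posterior.jumps, key=lambda j: j.time_d)
    out = np.empty((len(posterior.parameter_draws), len(times)))
    for k, theta in enumerate(posterior.parameter_draws):
        pseudo = posterior.curve(theta, times)
        # corrections accumulated forward over events
        corr = 0.0
        ji = 0
        for i, t in enumerate(times):
            while ji < len(jumps) and jumps[ji].time_d <= t + 1e-12:
                j = jumps[ji]
                c_pre = float(posterior.curve(theta, np.array([j.time_d]))[0]) - corr
                c_post = j.forward(c_pre)
                corr += c_pre - c_post
                ji += 1
            out[k, i] = pseudo[i] - corr
    return out
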