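"""Recurrent growth-rate predictor: sigmoid baseline plus deviation network.

The viable-cell-density (VCD) predictor models the specific growth rate
``mu(t)`` as a shared 4-sigmoid baseline (the pooled mean growth behaviour of
the training cohort) plus a per-condition deviation predicted by a dense
network from metabolic features.  Temporal context enters through a
recurrence on the cumulative "biomaterial" variable ``gamma = int Xv dt``
(a proxy for accumulated inhibitory by-products) and on the previously
predicted growth rate.

Feature vector per time step (``2k + 3`` entries for ``k`` metabolites;
45 with the standard 21-metabolite panel, which excludes glucose, lactate
and ammonium):

* ``k`` specific exchange rates, ``k`` extracellular concentrations,
* previous growth rate, previous biomaterial, and the time step.

The biomaterial recurrence serves as the temporal coordinate, which is what
lets the model generalize across sampling frequencies.

The deviation network is a dense stack with layer widths 64, 64, 64, 16, 8
and 1, GeLU activations, layer normalization, and dropout between hidden
layers; it is trained with a composite loss (trajectory- and time-weighted
MSE, a mean-matching term, and an integrated |second difference| smoothness
penalty) by Adam with manual backpropagation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.special import erf

from .basis import sigmoid_sum
from .records import ALL_ANALYTES, GROWTH_NN_EXCLUDED

#: Analytes whose rates/concentrations feed the network (k = 21 by default).
FEATURE_ANALYTES = tuple(a for a in ALL_ANALYTES if a not in GROWTH_NN_EXCLUDED)

HIDDEN_WIDTHS = (64, 64, 64, 16, 8)


def feature_dimension(n_metabolites: int = len(FEATURE_ANALYTES)) -> int:
    """Feature count: rates + concentrations + (prev growth, biomaterial, dt)."""
    return 2 * n_metabolites + 3


# --------------------------------------------------------------------------
# baseline
# --------------------------------------------------------------------------

@dataclass
class BaselineModel:
    """Sum of four logistic terms plus offset, fitted to the pooled mean mu."""

    amplitudes: np.ndarray
    midpoints: np.ndarray
    slopes: np.ndarray
    offset: float
    rmse: float = np.nan

    def __call__(self, t) -> np.ndarray:
        return sigmoid_sum(t, self.amplitudes, self.midpoints, self.slopes,
                           self.offset)

    def to_dict(self) -> dict:
        return {"amplitudes": list(map(float, self.amplitudes)),
                "midpoints": list(map(float, self.midpoints)),
                "slopes": list(map(float, self.slopes)),
                "offset": float(self.offset), "rmse": float(self.rmse)}

    @classmethod
    def from_dict(cls, d: dict) -> "BaselineModel":
        return cls(np.asarray(d["amplitudes"]), np.asarray(d["midpoints"]),
                   np.asarray(d["slopes"]), d["offset"], d.get("rmse", np.nan))


def fit_baseline(times, mu_mean_per_batch, n_sigmoids: int = 4,
                 n_starts: int = 6, seed: int = 0) -> BaselineModel:
    """Least-squares 4-sigmoid fit of the pooled mean growth rate.

    ``times`` may be one shared grid or a list of per-batch grids;
    ``mu_mean_per_batch`` is the matching list of mean-growth trajectories.
    A single batch is accepted (the baseline then interpolates one curve).
    """
    if isinstance(times, np.ndarray) and np.ndim(times) == 1 \
            and np.ndim(mu_mean_per_batch[0]) == 0:
        times, mu_mean_per_batch = [times], [np.asarray(mu_mean_per_batch)]
    t = np.concatenate([np.asarray(ti, dtype=float) for ti in times])
    y = np.concatenate([np.asarray(mi, dtype=float) for mi in mu_mean_per_batch])
    order = np.argsort(t)
    t, y = t[order], y[order]
    t0, t1 = t.min(), t.max()
    rng = np.random.default_rng(seed)

    def pack(a, m, s, c):
        return np.concatenate([a, m, s, [c]])

    def evaluate(theta, tt):
        return sigmoid_sum(tt, theta[:n_sigmoids],
                           theta[n_sigmoids:2 * n_sigmoids],
                           np.abs(theta[2 * n_sigmoids:3 * n_sigmoids]) + 1e-3,
                           theta[-1])

    best = None
    span = max(y.max() - y.min(), 1e-6)
    for s in range(n_starts):
        mids = np.linspace(t0 + 0.1 * (t1 - t0), t1 - 0.1 * (t1 - t0), n_sigmoids)
        amps = np.full(n_sigmoids, -span / n_sigmoids)
        slopes = np.full(n_sigmoids, (t1 - t0) / 10)
        if s > 0:
            mids = mids + rng.uniform(-1, 1, n_sigmoids)
            amps = amps * rng.uniform(0.3, 2.0, n_sigmoids) \
                * rng.choice([-1, 1], n_sigmoids)
            slopes = slopes * rng.uniform(0.5, 2.0, n_sigmoids)
        x0 = pack(amps, mids, slopes, y[0])
        res = least_squares(lambda th: evaluate(th, t) - y, x0,
                            method="lm", max_nfev=6000)
        if best is None or res.cost < best.cost:
            best = res
    theta = best.x
    if not np.all(np.isfinite(theta)):
        raise RuntimeError("baseline fit produced non-finite parameters")
    rmse = float(np.sqrt(2 * best.cost / len(t)))
    return BaselineModel(theta[:n_sigmoids], theta[n_sigmoids:2 * n_sigmoids],
                         np.abs(theta[2 * n_sigmoids:3 * n_sigmoids]) + 1e-3,
                         float(theta[-1]), rmse)


# --------------------------------------------------------------------------
# loss weights and components
# --------------------------------------------------------------------------

def trajectory_weights(mu_trajectories, eps: float | None = None) -> np.ndarray:
    """Inverse-distance weights: trajectories near the batch-mean growth get
    more weight, outliers less.  Normalized to sum to one.

    ``eps`` regularizes the inverse distance.  By default it scales with the
    spread of the trajectory means (half their standard deviation): a fixed
    tiny epsilon would hand essentially all weight to whichever trajectory
    happens to sit closest to the ensemble mean, collapsing the fit onto a
    single noisy draw.
    """
    mu = np.atleast_2d(np.asarray(mu_trajectories, dtype=float))
    traj_means = mu.mean(axis=1)
    grand = traj_means.mean()
    dist = np.abs(traj_means - grand)
    if eps is None:
        eps = max(1e-6, 0.5 * float(np.std(traj_means)))
    w = 1.0 / (dist + eps)
    return w / w.sum()


def time_weights(times, t_end: float) -> np.ndarray:
    """Linearly decreasing time weights ``(T - t)/T`` (early points count more)."""
    times = np.asarray(times, dtype=float)
    if np.any(times > t_end):
        raise ValueError("times must not exceed t_end")
    return (t_end - times) / t_end


@dataclass
class LossComponents:
    weighted_mse: float
    mean_matching: float
    smoothness: float

    @property
    def total(self) -> float:
        return self.weighted_mse + self.mean_matching + self.smoothness


def compute_loss(predictions, targets, traj_w, time_w,
                 smoothness_weight: float = 1.0,
                 mean_matching_weight: float = 1.0) -> LossComponents:
    """Composite training loss on one batch of trajectories.

    * weighted MSE: per-trajectory weights ``traj_w`` and per-time weights
      ``time_w`` on squared errors against the target trajectories;
    * mean matching: absolute difference of the time-summed weighted-mean
      predicted and target growth rates;
    * smoothness: mean over trajectories of the summed absolute second
      difference of the prediction (a discrete integral of ``|f''|``).

    The term weights default to one (the nominal composite); during training
    much smaller weights are used for the two regularizing terms, because at
    equal weights their scale-free gradients dominate the data-fit term and
    the optimum degenerates to a flat trajectory (see the methods note).
    """
    y = np.atleast_2d(np.asarray(predictions, dtype=float))
    mu = np.atleast_2d(np.asarray(targets, dtype=float))
    if y.shape != mu.shape:
        raise ValueError("predictions and targets must have the same shape")
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(mu))):
        raise ValueError("non-finite values in loss inputs")
    traj_w = np.asarray(traj_w, dtype=float)
    time_w = np.asarray(time_w, dtype=float)
    n_t = y.shape[1]
    term1 = float(np.sum(traj_w[:, None] * time_w[None, :] * (y - mu) ** 2) / n_t)
    ybar = traj_w @ y
    mubar = traj_w @ mu
    term2 = float(mean_matching_weight * np.abs(np.sum(ybar) - np.sum(mubar)))
    if n_t >= 3:
        d2 = np.diff(y, n=2, axis=1)
        term3 = float(smoothness_weight * np.mean(np.sum(np.abs(d2), axis=1)))
    else:
        term3 = 0.0
    return LossComponents(term1, term2, term3)


def _loss_gradient(y, mu, traj_w, time_w, smoothness_weight=1.0,
                   mean_matching_weight=1.0):
    """d(total loss)/d(predictions); mirrors :func:`compute_loss`."""
    n_traj, n_t = y.shape
    g = 2.0 * traj_w[:, None] * time_w[None, :] * (y - mu) / n_t
    s = np.sum(traj_w @ y) - np.sum(traj_w @ mu)
    g = g + mean_matching_weight * np.sign(s) * traj_w[:, None] * np.ones_like(y)
    if n_t >= 3:
        d2 = np.diff(y, n=2, axis=1)
        sg = np.sign(d2) * (smoothness_weight / n_traj)
        # adjoint of the second-difference operator
        g[:, :-2] += sg
        g[:, 1:-1] += -2.0 * sg
        g[:, 2:] += sg
    return g


# --------------------------------------------------------------------------
# recurrence
# --------------------------------------------------------------------------

def recurrence_step(xv_prev: float, mu_prev: float, gamma_prev: float,
                    dt: float) -> tuple[float, float]:
    """Discrete biomass/biomaterial update.

    First-order update of ``dX/dt = mu X`` (multiplicative form) and the
    biomaterial integral: ``Xv <- Xv (1 + mu dt)``, ``gamma <- gamma + Xv dt``
    (the increment uses the pre-step viable density).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    gamma = gamma_prev + xv_prev * dt
    xv = xv_prev * (1.0 + mu_prev * dt)
    return xv, gamma


def integrate_vcd(mu, times, xv0: float) -> np.ndarray:
    """VCD trajectory from a growth-rate trajectory via the recurrence."""
    mu = np.asarray(mu, dtype=float)
    times = np.asarray(times, dtype=float)
    xv = np.empty_like(times)
    xv[0] = xv0
    g = 0.0
    for i in range(1, len(times)):
        xv[i], g = recurrence_step(xv[i - 1], mu[i - 1], g, times[i] - times[i - 1])
    return xv


# --------------------------------------------------------------------------
# deviation network (numpy, manual backprop)
# --------------------------------------------------------------------------

def _gelu(x):
    return 0.5 * x * (1.0 + erf(x / np.sqrt(2.0)))


def _gelu_grad(x):
    phi = np.exp(-0.5 * x ** 2) / np.sqrt(2.0 * np.pi)
    return 0.5 * (1.0 + erf(x / np.sqrt(2.0))) + x * phi


class DeviationNetwork:
    """Dense deviation predictor with GeLU, layer norm, and dropout.

    Hidden layer order: linear -> layer norm -> GeLU -> dropout; the output
    layer is purely linear.  All parameters live in numpy arrays; gradients
    are computed by explicit backpropagation.
    """

    LN_EPS = 1e-5

    def __init__(self, n_features: int, hidden=HIDDEN_WIDTHS,
                 dropout: float = 0.1, seed: int = 0):
        self.n_features = int(n_features)
        self.hidden = tuple(hidden)
        self.dropout = float(dropout)
        rng = np.random.default_rng(seed)
        widths = [self.n_features, *self.hidden, 1]
        self.params: dict[str, np.ndarray] = {}
        for i, (a, b) in enumerate(zip(widths[:-1], widths[1:])):
            scale = np.sqrt(2.0 / a)
            self.params[f"W{i}"] = scale * rng.standard_normal((a, b))
            self.params[f"b{i}"] = np.zeros(b)
            if i < len(widths) - 2:    # hidden layers carry layer-norm params
                self.params[f"g{i}"] = np.ones(b)
                self.params[f"c{i}"] = np.zeros(b)
        self.n_layers = len(widths) - 1

    # -- forward / backward ------------------------------------------------

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None):
        """Returns (output (n, 1), cache for backward)."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.n_features:
            raise ValueError(
                f"feature dimension {x.shape[1]} != network input width "
                f"{self.n_features}")
        cache = {"x0": x}
        h = x
        for i in range(self.n_layers - 1):
            z = h @ self.params[f"W{i}"] + self.params[f"b{i}"]
            mu = z.mean(axis=1, keepdims=True)
            var = z.var(axis=1, keepdims=True)
            inv = 1.0 / np.sqrt(var + self.LN_EPS)
            zhat = (z - mu) * inv
            ln = zhat * self.params[f"g{i}"] + self.params[f"c{i}"]
            a = _gelu(ln)
            if training and self.dropout > 0:
                if rng is None:
                    raise ValueError("training-mode forward needs an rng")
                mask = (rng.random(a.shape) >= self.dropout) / (1 - self.dropout)
            else:
                mask = None
            out = a if mask is None else a * mask
            cache[f"h{i}"] = h
            cache[f"zhat{i}"] = zhat
            cache[f"inv{i}"] = inv
            cache[f"ln{i}"] = ln
            cache[f"mask{i}"] = mask
            h = out
        i = self.n_layers - 1
        y = h @ self.params[f"W{i}"] + self.params[f"b{i}"]
        cache[f"h{i}"] = h
        return y, cache

    def backward(self, cache, dy: np.ndarray) -> dict[str, np.ndarray]:
        grads: dict[str, np.ndarray] = {}
        i = self.n_layers - 1
        h = cache[f"h{i}"]
        grads[f"W{i}"] = h.T @ dy
        grads[f"b{i}"] = dy.sum(axis=0)
        dh = dy @ self.params[f"W{i}"].T
        for i in range(self.n_layers - 2, -1, -1):
            mask = cache[f"mask{i}"]
            da = dh if mask is None else dh * mask
            dln = da * _gelu_grad(cache[f"ln{i}"])
            zhat, inv = cache[f"zhat{i}"], cache[f"inv{i}"]
            grads[f"g{i}"] = (dln * zhat).sum(axis=0)
            grads[f"c{i}"] = dln.sum(axis=0)
            dzhat = dln * self.params[f"g{i}"]
            m = dzhat.mean(axis=1, keepdims=True)
            mz = (dzhat * zhat).mean(axis=1, keepdims=True)
            dz = inv * (dzhat - m - zhat * mz)
            h = cache[f"h{i}"]
            grads[f"W{i}"] = h.T @ dz
            grads[f"b{i}"] = dz.sum(axis=0)
            dh = dz @ self.params[f"W{i}"].T
        return grads

    def predict(self, x: np.ndarray) -> np.ndarray:
        y, _ = self.forward(x, training=False)
        return y[:, 0]

    # -- (de)serialization -------------------------------------------------

    def state_dict(self) -> dict:
        return {"n_features": self.n_features, "hidden": list(self.hidden),
                "dropout": self.dropout,
                "params": {k: v.tolist() for k, v in self.params.items()}}

    @classmethod
    def from_state(cls, state: dict) -> "DeviationNetwork":
        net = cls(state["n_features"], state["hidden"], state["dropout"])
        net.params = {k: np.asarray(v, dtype=float)
                      for k, v in state["params"].items()}
        return net


class _Adam:
    def __init__(self, params, lr=1e-3, b1=0.9, b2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# --------------------------------------------------------------------------
# training data container and feature assembly
# --------------------------------------------------------------------------

@dataclass
class GrowthBatchData:
    """Training material for one bioreactor batch.

    ``rates``: (n_traj, n_times, k) specific-rate trajectories;
    ``concentrations``: (n_times, k) measured values, shared by trajectories;
    ``mu_trajectories``: (n_traj, n_times) growth-rate targets (1/d);
    ``xv0``: initial VCD (1e6 cells/ml).
    """

    batch_id: str
    media_group: int
    times: np.ndarray
    rates: np.ndarray
    concentrations: np.ndarray
    mu_trajectories: np.ndarray
    xv0: float
    analytes: tuple[str, ...] = FEATURE_ANALYTES

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        n_traj, n_times, k = np.shape(self.rates)
        if np.shape(self.mu_trajectories) != (n_traj, n_times):
            raise ValueError("mu_trajectories shape mismatch with rates")
        if np.shape(self.concentrations) != (n_times, k):
            raise ValueError("concentrations shape mismatch")


def assemble_features(rates, concentrations, prev_growth, prev_biomaterial, dt):
    """One feature matrix row per (trajectory, time): ``2k + 3`` columns."""
    r = np.asarray(rates, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    cols = [r, c,
            np.asarray(prev_growth, dtype=float)[..., None],
            np.asarray(prev_biomaterial, dtype=float)[..., None],
            np.asarray(dt, dtype=float)[..., None]]
    return np.concatenate(cols, axis=-1)


def _teacher_forced_features(batch: GrowthBatchData, baseline: BaselineModel):
    """Features with recurrence driven by the *target* growth trajectories."""
    n_traj, n_times, k = batch.rates.shape
    t = batch.times
    dts = np.diff(t, prepend=t[0] - (t[1] - t[0]))
    feats = np.empty((n_traj, n_times, 2 * k + 3))
    for n in range(n_traj):
        xv, gamma = batch.xv0, 0.0
        prev_mu = float(baseline(t[:1])[0])
        for i in range(n_times):
            feats[n, i] = assemble_features(
                batch.rates[n, i], batch.concentrations[i],
                prev_mu, gamma, dts[i])
            xv, gamma = recurrence_step(xv, batch.mu_trajectories[n, i],
                                        gamma, dts[i])
            prev_mu = batch.mu_trajectories[n, i]
    return feats


# --------------------------------------------------------------------------
# training and prediction
# --------------------------------------------------------------------------

@dataclass
class TrainingConfig:
    epochs: int = 250
    n_traj: int = 200
    max_time_points: int = 32
    learning_rate: float = 1e-3
    dropout: float = 0.1
    smoothness_weight: float = 0.01       # see compute_loss docstring
    mean_matching_weight: float = 0.01
    #: probability of replacing the teacher-forced previous-growth feature by
    #: the baseline value during training.  The lagged target is such a strong
    #: shortcut that without this the network ignores the metabolic features
    #: and its deviations collapse at (self-fed) inference time.
    lag_feature_dropout: float = 0.5
    validation_fraction: float = 2.0 / 23.0   # batch-level split
    seed: int = 0


#: Standardized network inputs are clamped to this many SDs: closed-loop
#: simulation can drift outside the training envelope, where an unclamped
#: dense net extrapolates arbitrarily.
FEATURE_CLAMP_SD = 4.0


@dataclass
class GrowthModel:
    baseline: BaselineModel
    network: DeviationNetwork
    feature_scale: np.ndarray     # per-feature standardization (mean, sd)
    feature_analytes: tuple[str, ...] = FEATURE_ANALYTES
    loss_history: list[float] = field(default_factory=list)

    def standardize(self, x: np.ndarray) -> np.ndarray:
        mean, sd = self.feature_scale
        return np.clip((x - mean) / sd, -FEATURE_CLAMP_SD, FEATURE_CLAMP_SD)

    def predict_mu(self, times, rates, concentrations, xv0: float) -> np.ndarray:
        """Sequential growth-rate prediction (self-fed recurrence).

        ``rates``/``concentrations``: (n_times, k) mean trajectories.
        Times must be strictly increasing (time-ordered contract).
        """
        t = np.asarray(times, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        rates = np.asarray(rates, dtype=float)
        conc = np.asarray(concentrations, dtype=float)
        dts = np.diff(t, prepend=t[0] - (t[1] - t[0]))
        out = np.empty(len(t))
        xv, gamma = xv0, 0.0
        prev_mu = float(self.baseline(t[:1])[0])
        for i in range(len(t)):
            x = assemble_features(rates[i], conc[i], prev_mu, gamma, dts[i])
            dev = self.network.predict(self.standardize(x))[0]
            out[i] = float(self.baseline(t[i:i + 1])[0]) + dev
            xv, gamma = recurrence_step(xv, out[i], gamma, dts[i])
            prev_mu = out[i]
        return out


def train(batches: list[GrowthBatchData], config: TrainingConfig | None = None,
          baseline: BaselineModel | None = None
          ) -> tuple[GrowthModel, list[GrowthBatchData]]:
    """Train baseline + deviation network; returns (model, validation batches).

    The train/validation split is at batch level; per epoch, batches are
    presented in random order and a full forward/backward/Adam step is taken
    per batch (batch-wise sequential strategy).  Recurrence features are
    teacher-forced with the target growth trajectories during training.
    """
    cfg = config or TrainingConfig()
    rng = np.random.default_rng(cfg.seed)
    n_val = int(round(cfg.validation_fraction * len(batches)))
    order = rng.permutation(len(batches))
    val_idx = set(order[:n_val].tolist())
    train_b = [b for i, b in enumerate(batches) if i not in val_idx]
    val_b = [b for i, b in enumerate(batches) if i in val_idx]
    if not train_b:
        raise ValueError("empty training split")

    # cap trajectories and time points
    def clip(b: GrowthBatchData) -> GrowthBatchData:
        nt = min(cfg.n_traj, b.rates.shape[0])
        ntime = min(cfg.max_time_points, len(b.times))
        step = max(1, len(b.times) // ntime)
        sl = slice(0, step * ntime, step)
        return GrowthBatchData(b.batch_id, b.media_group, b.times[sl],
                               b.rates[:nt, sl], b.concentrations[sl],
                               b.mu_trajectories[:nt, sl], b.xv0, b.analytes)

    train_b = [clip(b) for b in train_b]

    if baseline is None:
        baseline = fit_baseline(
            [b.times for b in train_b],
            [b.mu_trajectories.mean(axis=0) for b in train_b], seed=cfg.seed)

    k = train_b[0].rates.shape[2]
    net = DeviationNetwork(feature_dimension(k), dropout=cfg.dropout,
                           seed=cfg.seed)
    opt = _Adam(net.params, lr=cfg.learning_rate)

    # precompute teacher-forced features, weights and standardization
    feats = {b.batch_id: _teacher_forced_features(b, baseline) for b in train_b}
    allf = np.concatenate([f.reshape(-1, f.shape[-1])
                           for f in feats.values()])
    mean = allf.mean(axis=0)
    sd = allf.std(axis=0)
    # a feature constant in training (e.g. a fixed sampling step) passes
    # through unscaled instead of exploding under a degenerate 1/sd
    sd = np.where(sd < 1e-8, 1.0, sd)
    scale = np.stack([mean, sd])
    weights = {b.batch_id: trajectory_weights(b.mu_trajectories)
               for b in train_b}
    twts = {b.batch_id: time_weights(b.times, b.times[-1]) for b in train_b}

    # baseline value of the previous-growth feature, for lag dropout
    base_prev = {}
    for b in train_b:
        t = b.times
        tprev = np.concatenate([[t[0] - (t[1] - t[0])], t[:-1]])
        base_prev[b.batch_id] = baseline(tprev)
    k_col = 2 * k   # previous-growth column in the feature layout

    history = []
    for _ in range(cfg.epochs):
        epoch_loss = 0.0
        for bi in rng.permutation(len(train_b)):
            b = train_b[bi]
            f = feats[b.batch_id]
            n_traj, n_times, nf = f.shape
            if cfg.lag_feature_dropout > 0:
                f = f.copy()
                mask = rng.random((n_traj, n_times)) < cfg.lag_feature_dropout
                f[..., k_col] = np.where(mask, base_prev[b.batch_id][None, :],
                                         f[..., k_col])
            x = (f.reshape(-1, nf) - mean) / sd
            yhat, cache = net.forward(x, training=cfg.dropout > 0, rng=rng)
            base = baseline(b.times)[None, :]
            pred = yhat[:, 0].reshape(n_traj, n_times) + base
            loss = compute_loss(pred, b.mu_trajectories, weights[b.batch_id],
                                twts[b.batch_id], cfg.smoothness_weight,
                                cfg.mean_matching_weight)
            if not np.isfinite(loss.total):
                raise RuntimeError(
                    f"training diverged (non-finite loss) in epoch {len(history)}")
            g = _loss_gradient(pred, b.mu_trajectories, weights[b.batch_id],
                               twts[b.batch_id], cfg.smoothness_weight,
                               cfg.mean_matching_weight)
            grads = net.backward(cache, g.reshape(-1, 1))
            if cfg.learning_rate > 0:
                opt.step(net.params, grads)
            epoch_loss += loss.total
        history.append(epoch_loss / len(train_b))

    model = GrowthModel(baseline, net, scale, train_b[0].analytes, history)
    return model, val_b
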