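"""Synthetic fed-batch cohort generator with known ground truth.

Emulates the structure of the experimental campaign the framework targets:
a cohort of fed-batch Ambr-scale CHO cultures sampled daily, partitioned into
media groups that share feed compositions, with two nutrient feed streams
(FMA + FMB) bolused daily from day 3 and a concentrated glucose stock (FMG)
added from day 5 whenever glucose would otherwise fall below a floor.

The latent dynamics are the package's own kinetic equations
(:mod:`chotwin.kinetics`) driven by a 4-sigmoid effective-growth profile, so
parameter-recovery tests are exact by construction.  Amino acids outside the
FLEX panel are consumed with group-specific loading vectors linear in the
effective growth rate, giving the exchange-rate matrix a known low-rank
structure (what the window-PCA / loading-network layers are designed to
recover).  A smooth depletion guard (``tanh`` of the squared reduced
concentration) keeps every latent concentration non-negative.

Measurement noise is multiplicative lognormal with unit mean and configurable
coefficient of variation; the noise-free latent states are returned alongside
each record.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .basis import sigmoid_sum
from .kinetics import (
    FLEX_STATE_NAMES,
    KineticParameters,
    PopulationState,
    death_lysis_rates,
    flex_specific_rates,
    integrate_events,
    population_rhs,
)
from .records import (
    ALL_ANALYTES,
    AMINO_ACID_ANALYTES,
    FLEX_ANALYTES,
    GROWTH_RATE_NAME,
    PRODUCT_ANALYTE,
    FeedEvent,
    ProcessRecord,
    SampleEvent,
)
from .toynet import generate_toy_network  # noqa: F401  (re-export: module surface)

#: Baseline 4-sigmoid effective-growth profile (1/d): exponential phase near
#: 0.75/d, main decline around day 5, late decline around day 9.5.
MU_EFF_BASELINE = {
    "amplitudes": (-0.62, -0.10, 0.04, -0.015),
    "midpoints": (5.2, 9.5, 2.0, 12.5),
    "slopes": (0.9, 0.8, 0.6, 0.6),
    "offset": 0.75,
}

#: Depletion-guard half-saturation for non-FLEX analytes, g/l.
K_DEPLETION = 0.1


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-condition defaults: 23 batches, 8 media groups, daily sampling."""

    n_batches: int = 23
    n_media_groups: int = 8
    horizon: float = 14.0                 # days
    sampling_interval: float = 1.0        # days
    inoculation_vcd: float = 0.3          # 1e6 cells/ml
    feed_start_day: float = 3.0
    glucose_floor: float = 5.0            # g/l
    glucose_feed_start_day: float = 5.0
    glucose_headroom: float = 8.0         # FMG restores floor + headroom, g/l
    noise_cv: float = 0.05
    seed: int = 0
    initial_volume_ml: float = 10.0
    sample_volume_ml: float = 0.45
    fma_volume_ml: float = 0.30           # daily base bolus, scaled per batch
    fmb_volume_ml: float = 0.25
    kinetic_params: KineticParameters = field(default_factory=KineticParameters)

    def __post_init__(self) -> None:
        if self.n_media_groups > self.n_batches:
            raise ValueError("n_media_groups must be <= n_batches")
        if self.horizon <= self.feed_start_day:
            raise ValueError("horizon must exceed feed_start_day")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")

    @property
    def sampling_times(self) -> np.ndarray:
        n = int(round(self.horizon / self.sampling_interval))
        return np.linspace(0.0, n * self.sampling_interval, n + 1)


#: Within-group relative spread of the two latent rate factors (growth-linked
#: loading and maintenance); batches in a group share loading directions but
#: differ along them, which is exactly the low-rank structure the
#: group-matched window PCA is meant to recover.
AA_FACTOR_SD = (0.15, 0.3)


@dataclass
class GroupDefinition:
    """Deterministic per-media-group parameters (shared within the group)."""

    index: int
    mu_offset_scale: float            # multiplies the baseline offset
    mu_midpoint_shift: float          # days, shifts the main decline sigmoid
    aa_loadings: dict[str, float]     # growth-linked consumption loading
    aa_maintenance: dict[str, float]  # growth-independent consumption
    qp_titer: float                   # specific productivity, g/1e9 cells/d
    feed_compositions: dict[str, dict[str, float]]

    def mu_eff(self, t):
        amp = list(MU_EFF_BASELINE["amplitudes"])
        mid = list(MU_EFF_BASELINE["midpoints"])
        mid[0] = mid[0] + self.mu_midpoint_shift
        return np.maximum(
            sigmoid_sum(t, amp, mid, MU_EFF_BASELINE["slopes"],
                        MU_EFF_BASELINE["offset"] * self.mu_offset_scale),
            1e-4,
        )


@dataclass
class GroundTruth:
    """Noise-free generating quantities for one batch."""

    kinetic_params: KineticParameters
    group: GroupDefinition
    mu_profile: dict[float, float]            # sampling day -> net growth, 1/d
    feed_compositions: dict[str, dict[str, float]]
    latent: pd.DataFrame                       # dense noise-free states
    specific_rates: pd.DataFrame               # dense signed rates, g/1e9 cells/d
    feed_scale: dict[str, float]               # per-stream bolus scale factor
    factors: tuple[float, float] = (0.0, 0.0)  # latent within-group factor scores
    qp_titer: float = np.nan                   # realized specific productivity


def _aa_base_initial(analyte: str, rng: np.random.Generator) -> float:
    return float(rng.uniform(1.2, 3.0))


def define_group(config: SyntheticConfig, group_index: int) -> GroupDefinition:
    """Deterministic media-group definition derived from the cohort seed."""
    if group_index >= config.n_media_groups:
        raise ValueError(
            f"group_index {group_index} >= n_media_groups {config.n_media_groups}")
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 7919, group_index]))
    loadings = {a: float(rng.uniform(0.03, 0.12)) for a in AMINO_ACID_ANALYTES}
    maintenance = {a: float(rng.uniform(0.001, 0.008)) for a in AMINO_ACID_ANALYTES}
    fma = {"glucose": 60.0 * (1 + 0.1 * rng.uniform(-1, 1)),
           "glutamine": 6.0 * (1 + 0.2 * rng.uniform(-1, 1)),
           "glutamate": 3.5 * (1 + 0.2 * rng.uniform(-1, 1))}
    fmb = {"glucose": 40.0 * (1 + 0.1 * rng.uniform(-1, 1)),
           "glutamate": 1.5 * (1 + 0.2 * rng.uniform(-1, 1))}
    for a in AMINO_ACID_ANALYTES:
        fma[a] = float(rng.uniform(2.0, 6.0))
        fmb[a] = float(rng.uniform(1.0, 4.0))
    return GroupDefinition(
        index=group_index,
        mu_offset_scale=float(1.0 + 0.08 * rng.uniform(-1, 1)),
        mu_midpoint_shift=float(rng.uniform(-0.8, 0.8)),
        aa_loadings=loadings,
        aa_maintenance=maintenance,
        qp_titer=float(rng.uniform(0.015, 0.03)),
        feed_compositions={"FMA": fma, "FMB": fmb, "FMG": {"glucose": 400.0}},
    )


def _initial_concentrations(config: SyntheticConfig, group: GroupDefinition) -> np.ndarray:
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 104729, group.index]))
    # glutamine starts above its half-saturation scale so that the uptake
    # kinetics traverse both the saturated and sub-saturated regimes
    # (otherwise only the ratio vGln_max/KGln^2 would be identifiable)
    # basal glucose must carry the culture (maintenance-dominated uptake)
    # through day 5, when the FMG maintenance feed becomes available
    c0 = {"glucose": 15.0, "lactate": 0.1, "glutamine": 3.0,
          "glutamate": 0.7, "ammonium": 0.02, PRODUCT_ANALYTE: 0.0}
    for a in AMINO_ACID_ANALYTES:
        c0[a] = _aa_base_initial(a, rng)
    return np.array([c0[a] for a in ALL_ANALYTES])


def _aa_specific_rates(conc_aa: np.ndarray, mu_eff: float,
                       group: GroupDefinition,
                       factors: tuple[float, float] = (0.0, 0.0)) -> np.ndarray:
    """Signed rates (consumption negative) with smooth depletion guard.

    ``factors`` are the batch's latent coordinates along the group's two
    loading directions (growth-linked and maintenance consumption).
    """
    w = np.array([group.aa_loadings[a] for a in AMINO_ACID_ANALYTES])
    m = np.array([group.aa_maintenance[a] for a in AMINO_ACID_ANALYTES])
    z1, z2 = factors
    w = w * (1.0 + AA_FACTOR_SD[0] * z1)
    m = m * (1.0 + AA_FACTOR_SD[1] * z2)
    guard = np.tanh((np.maximum(conc_aa, 0.0) / K_DEPLETION) ** 2)
    return -(w * mu_eff + m) * guard


def _latent_rhs(config: SyntheticConfig, group: GroupDefinition,
                factors=(0.0, 0.0), qp: float | None = None):
    params = config.kinetic_params
    n_aa = len(AMINO_ACID_ANALYTES)
    qp = group.qp_titer if qp is None else qp

    def rhs(t, y):
        pop = PopulationState(*y[:4])
        conc = y[4:]
        mu_eff = float(group.mu_eff(t))
        dpop = population_rhs(pop, params, mu_eff)
        flex = flex_specific_rates(conc[:5], mu_eff, params) * pop.Xv
        aa = _aa_specific_rates(conc[5:5 + n_aa], mu_eff, group,
                                factors) * pop.Xv
        titer = np.array([qp * pop.Xv])
        return np.concatenate([dpop, flex, aa, titer])

    return rhs


def generate_batch(config: SyntheticConfig, group_index: int,
                   seed: int) -> tuple[ProcessRecord, GroundTruth]:
    """Generate one fed-batch record plus its noise-free ground truth.

    Group-level structure (compositions, growth profile, loadings) depends
    only on ``config.seed`` and ``group_index``; ``seed`` controls the
    batch-level realization (feed volume scaling and measurement noise).
    """
    group = define_group(config, group_index)
    params = config.kinetic_params
    rng = np.random.default_rng(np.random.SeedSequence([seed, 15485863]))
    feed_scale = {"FMA": float(rng.uniform(0.7, 1.3)),
                  "FMB": float(rng.uniform(0.7, 1.3))}
    factors = tuple(np.clip(rng.standard_normal(2), -2.0, 2.0))
    qp = group.qp_titer * (1.0 + AA_FACTOR_SD[0] * factors[0])

    sample_times = config.sampling_times
    rhs = _latent_rhs(config, group, factors, qp)
    n_aa = len(AMINO_ACID_ANALYTES)

    y = np.concatenate([[config.inoculation_vcd, 0.0, 0.0, 0.0],
                        _initial_concentrations(config, group)])
    volume = config.initial_volume_ml
    feed_events: list[FeedEvent] = []
    sample_events: list[SampleEvent] = []
    dense_t: list[np.ndarray] = []
    dense_y: list[np.ndarray] = []
    dense_v: list[np.ndarray] = []
    sampled_states = [y.copy()]
    sampled_volumes = [volume]

    def mix(state, feed_vol, comp):
        d = volume / (volume + feed_vol)
        conc = state[4:].copy()
        feed_conc = np.array([comp.get(a, 0.0) for a in ALL_ANALYTES])
        out = state.copy()
        out[:4] *= d                      # cells and biomaterial are diluted
        out[4:] = conc * d + feed_conc * (1.0 - d)
        return out

    for k in range(len(sample_times) - 1):
        t0, t1 = sample_times[k], sample_times[k + 1]
        seg = np.linspace(t0, t1, 51)
        try:
            traj = integrate_events(rhs, y, seg, dt_max=0.02)
        except FloatingPointError as err:
            names = ["Xv", "Xd", "Xl", "gammaX", *ALL_ANALYTES]
            idx = int(str(err).split("component ")[1].split(" ")[0])
            raise RuntimeError(
                f"synthetic generation diverged in state {names[idx]!r}: {err}"
            ) from err
        dense_t.append(seg[:-1] if k < len(sample_times) - 2 else seg)
        dense_y.append(traj[:-1] if k < len(sample_times) - 2 else traj)
        dense_v.append(np.full(len(dense_t[-1]), volume))
        y = traj[-1]
        # sampling withdrawal (concentrations unchanged)
        volume = max(volume - config.sample_volume_ml, 1e-3)
        sample_events.append(SampleEvent(t1, config.sample_volume_ml))
        glc_idx = 4 + ALL_ANALYTES.index("glucose")
        glc_pre_feed = y[glc_idx]
        # nutrient feeds from feed_start_day
        if t1 >= config.feed_start_day:
            for stream, base in (("FMA", config.fma_volume_ml),
                                 ("FMB", config.fmb_volume_ml)):
                vol = base * feed_scale[stream]
                y = mix(y, vol, group.feed_compositions[stream])
                volume += vol
                feed_events.append(FeedEvent(t1, stream, vol))
        # glucose maintenance feed: predictive trigger — feed whenever the
        # projected glucose at the next daily check would fall below the
        # floor.  The projection scales the last interval's consumption by
        # the culture's growth over the coming interval, because demand is
        # proportional to the (exponentially growing) viable-cell density.
        glc_consumed = max(sampled_states[-1][glc_idx] - glc_pre_feed, 0.0)
        growth_factor = float(np.exp(group.mu_eff(t1) * config.sampling_interval))
        projected_demand = glc_consumed * growth_factor
        if t1 >= config.glucose_feed_start_day and \
                y[glc_idx] - projected_demand < config.glucose_floor:
            target = config.glucose_floor + max(config.glucose_headroom,
                                                1.2 * projected_demand)
            if y[glc_idx] < target:
                stock = group.feed_compositions["FMG"]["glucose"]
                vol = volume * (target - y[glc_idx]) / (stock - target)
                y = mix(y, vol, group.feed_compositions["FMG"])
                volume += vol
                feed_events.append(FeedEvent(t1, "FMG", vol))
        sampled_states.append(y.copy())
        sampled_volumes.append(volume)
        if k == len(sample_times) - 2:
            dense_y[-1][-1] = y
            dense_v[-1][-1] = volume

    dense_t = np.concatenate(dense_t)
    dense_y = np.vstack(dense_y)
    dense_v = np.concatenate(dense_v)
    state_cols = ["Xv", "Xd", "Xl", "gammaX", *ALL_ANALYTES]
    latent = pd.DataFrame(dense_y, index=pd.Index(dense_t, name="time_d"),
                          columns=state_cols)
    latent["volume_ml"] = dense_v

    # ground-truth signed specific rates along the latent trajectory
    mu_eff_dense = group.mu_eff(dense_t)
    mu_net = np.empty_like(mu_eff_dense)
    rate_rows = np.empty((len(dense_t), len(ALL_ANALYTES)))
    for i, (t, row) in enumerate(zip(dense_t, dense_y)):
        pop = PopulationState(*row[:4])
        mu_d, mu_l = death_lysis_rates(pop, params)
        mu_net[i] = mu_eff_dense[i] - mu_d - mu_l
        rate_rows[i, :5] = flex_specific_rates(row[4:9], mu_eff_dense[i], params)
        rate_rows[i, 5:5 + n_aa] = _aa_specific_rates(
            row[9:9 + n_aa], mu_eff_dense[i], group, factors)
        rate_rows[i, -1] = qp
    rates = pd.DataFrame(
        np.column_stack([mu_net, rate_rows]),
        index=pd.Index(dense_t, name="time_d"),
        columns=[GROWTH_RATE_NAME, *ALL_ANALYTES],
    )

    sampled = np.vstack(sampled_states)
    noisy = sampled.copy()
    if config.noise_cv > 0:
        sigma = np.sqrt(np.log(1.0 + config.noise_cv ** 2))
        z = rng.standard_normal(sampled.shape)
        noisy = sampled * np.exp(sigma * z - sigma ** 2 / 2.0)

    vcd = noisy[:, 0]
    xd = noisy[:, 1]
    viability = vcd / np.maximum(vcd + xd, 1e-12)
    conc = pd.DataFrame(noisy[:, 4:], index=pd.Index(sample_times, name="time_d"),
                        columns=list(ALL_ANALYTES))
    record = ProcessRecord(
        batch_id=f"B{seed}",
        media_group=group_index,
        times_d=sample_times,
        concentrations=conc,
        vcd=vcd,
        viability=viability,
        volume_ml=np.asarray(sampled_volumes),
        feed_events=feed_events,
        sample_events=sample_events,
        feed_compositions=group.feed_compositions,
    )
    sample_mu = {float(t): float(np.interp(t, dense_t, mu_net)) for t in sample_times}
    truth = GroundTruth(
        kinetic_params=params,
        group=group,
        mu_profile=sample_mu,
        feed_compositions=group.feed_compositions,
        latent=latent,
        specific_rates=rates,
        feed_scale=feed_scale,
        factors=factors,
        qp_titer=qp,
    )
    return record, truth


def growth_training_batch(record: ProcessRecord, truth: GroundTruth,
                          n_traj: int = 200, jitter: float = 0.05,
                          seed: int = 0, analytes=None):
    """Build growth-network training material emulating posterior ensembles.

    Rate and growth trajectories are the ground-truth profiles perturbed by
    trajectory-level multiplicative (rates) and additive (growth) jitter,
    standing in for posterior rate ensembles at a comparable spread.
    """
    from .growth import FEATURE_ANALYTES, GrowthBatchData

    analytes = tuple(analytes if analytes is not None else FEATURE_ANALYTES)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2 ** 20 + 7]))
    t = record.times_d
    tr = truth.specific_rates
    base_rates = np.column_stack([
        np.interp(t, tr.index.values, tr[a].values) for a in analytes])
    mu = np.array([truth.mu_profile[ti] for ti in t])
    scale_r = 1.0 + jitter * rng.standard_normal((n_traj, 1, 1))
    rates = base_rates[None, :, :] * scale_r \
        + 0.2 * jitter * np.abs(base_rates).mean() \
        * rng.standard_normal((n_traj, len(t), base_rates.shape[1]))
    mu_sd = jitter * max(np.max(np.abs(mu)), 1e-3)
    mus = mu[None, :] + mu_sd * rng.standard_normal((n_traj, len(t)))
    conc = record.concentrations[list(analytes)].to_numpy(dtype=float)
    return GrowthBatchData(record.batch_id, record.media_group, t,
                           rates, conc, mus, float(record.vcd[0]), analytes)


def _event_jumps_5(record: ProcessRecord):
    """FLEX-vector bolus jump maps (time, apply) from a record's event log."""
    from .kinetics import bolus_jump

    events = []
    for i, t in enumerate(record.times_d):
        feeds = [e for e in record.feed_events if np.isclose(e.time_d, t)]
        if not feeds:
            continue
        v_post = record.volume_ml[i]
        v_pre = v_post - sum(e.volume_ml for e in feeds)
        v = v_pre
        for e in feeds:
            comp = record.feed_compositions[e.stream]
            conc5 = np.array([comp.get("glucose", 0.0), 0.0,
                              comp.get("glutamine", 0.0),
                              comp.get("glutamate", 0.0), 0.0])
            events.append((float(t), bolus_jump(e.volume_ml, v, conc5)))
            v += e.volume_ml
    return events


def flex_fit_batch(record: ProcessRecord, truth: GroundTruth) -> dict:
    """Identification input for the FLEX model: observed concentrations with
    imposed (ground-truth) effective growth and viable-cell dynamics."""
    lat = truth.latent
    conc = record.concentrations[list(FLEX_ANALYTES)].to_numpy(dtype=float)
    xv_t, xv_v = lat.index.values, lat.Xv.values
    return {
        "times": record.times_d,
        "conc_obs": conc,
        "mu_eff": truth.group.mu_eff,
        "xv": lambda t: np.interp(t, xv_t, xv_v),
        "c0": conc[0].copy(),
        "events": _event_jumps_5(record),
    }


def population_fit_batch(record: ProcessRecord, truth: GroundTruth) -> dict:
    """Identification input for the population model: viable/dead biomass
    with the (ground-truth) net growth-rate trajectory imposed."""
    from .kinetics import PopulationState

    sr = truth.specific_rates
    mu_t, mu_v = sr.index.values, sr[GROWTH_RATE_NAME].values
    lat = truth.latent
    xd = lat.Xd.loc[record.times_d].to_numpy(dtype=float)
    # feed boluses dilute every cell pool and the biomaterial
    events = []
    for i, t in enumerate(record.times_d):
        feeds = [e for e in record.feed_events if np.isclose(e.time_d, t)]
        if not feeds:
            continue
        v_post = record.volume_ml[i]
        v_pre = v_post - sum(e.volume_ml for e in feeds)
        d_total = v_pre / v_post
        events.append((float(t), lambda y, d=d_total: y * d))
    return {
        "times": record.times_d,
        "xv_obs": lat.Xv.loc[record.times_d].to_numpy(dtype=float),
        "xd_obs": xd,
        "mu": lambda t: np.interp(t, mu_t, mu_v),
        "x0": PopulationState(float(lat.Xv.iloc[0]), float(lat.Xd.iloc[0]),
                              float(lat.Xl.iloc[0]), float(lat.gammaX.iloc[0])),
        "events": events,
    }


def generate_cohort(config: SyntheticConfig) -> list[tuple[ProcessRecord, GroundTruth]]:
    """Generate the full cohort, batches balanced over media groups.

    Batch ``b`` is assigned to group ``b % n_media_groups`` (group sizes
    differ by at most one); feed volumes vary within a group while the
    compositions are shared.
    """
    children = np.random.SeedSequence(config.seed).spawn(config.n_batches)
    out = []
    for b in range(config.n_batches):
        seed = int(children[b].generate_state(1)[0] % (2 ** 31))
        rec, truth = generate_batch(config, b % config.n_media_groups, seed)
        rec.batch_id = f"B{b:02d}"
        out.append((rec, truth))
    return out
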