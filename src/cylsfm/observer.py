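"""Synthetic observers for the rotating-cylinder tasks.

No raw behavioral data ship with this package; instead this module
generates keypress streams whose statistical structure matches what the
downstream analysis assumes about real observers:

* **Bi-stable blocks** — percept dominance durations follow a gamma renewal
  process (the standard phenomenological model for bi-stable alternation),
  with the first report delayed by an initial-percept latency.
* **Real-switch blocks** — each physical direction reversal elicits, with
  some miss probability, a response at a lognormal reaction time after the
  reversal, occasionally reporting the wrong direction; spontaneous extra
  reversal reports arrive as a Poisson stream.
* **Cohorts** — per-subject log10 switch rates are drawn from group-shifted
  normals (a medium control-vs-psychosis effect by default), decomposed
  into a stable trait plus session noise to give a target test–retest
  reliability, and clinical/metabolite covariates are coupled to the trait
  by a Gaussian copula to hit target Spearman correlations.

Everything is deterministic given the master seed: per-subject and
per-block generators are derived with ``numpy`` seed-sequence spawn keys,
so any subset of the cohort can be regenerated independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .records import BlockRecord, Cohort, GROUPS, KeypressEvent, SessionRecord
from .stimulus import CylinderParams, SwitchSchedule, make_real_switch_schedule

__all__ = [
    "ObserverParams",
    "CohortSpec",
    "simulate_bistable_block",
    "simulate_real_switch_block",
    "generate_cohort",
    "generate_cohort_rates",
    "child_rng",
]

#: Latency distribution shape for the initial-percept report (gamma).
_LATENCY_SHAPE = 4.0


def child_rng(master_seed: int, *key: int) -> np.random.Generator:
    """Independent generator for one (subject, session, block, ...) cell.

    Uses seed-sequence spawn keys so streams are reproducible regardless of
    generation order.
    """
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=tuple(int(k) for k in key))
    return np.random.default_rng(ss)


@dataclass(frozen=True)
class ObserverParams:
    """Generative parameters of one synthetic observer.

    Dominance durations are Gamma(``gamma_shape``, ``gamma_scale``) with
    mean ``shape * scale`` seconds. Real-switch responses have lognormal
    reaction times (``rt_mu``, ``rt_sigma`` on the log-seconds scale),
    a per-switch ``miss_prob``, a per-response ``error_prob`` of reporting
    the wrong direction, and extra reversal reports at ``spontaneous_rate``
    Hz.
    """

    gamma_shape: float = 3.5
    gamma_scale: float = 1.9
    initial_latency_mean: float = 1.5
    rt_mu: float = math.log(0.9)
    rt_sigma: float = 0.35
    miss_prob: float = 0.05
    error_prob: float = 0.02
    spontaneous_rate: float = 0.01

    def __post_init__(self) -> None:
        if self.gamma_shape <= 0 or self.gamma_scale <= 0 or self.rt_sigma <= 0:
            raise ValueError("gamma_shape, gamma_scale and rt_sigma must be positive")
        for name in ("miss_prob", "error_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.spontaneous_rate < 0:
            raise ValueError("spontaneous_rate must be non-negative")

    @property
    def mean_duration(self) -> float:
        """Mean dominance duration in seconds."""
        return self.gamma_shape * self.gamma_scale


def _draw_latency(obs: ObserverParams, rng: np.random.Generator) -> float:
    return float(rng.gamma(_LATENCY_SHAPE, obs.initial_latency_mean / _LATENCY_SHAPE))


def _flip(key: str) -> str:
    return "right" if key == "left" else "left"


def simulate_bistable_block(
    obs: ObserverParams,
    duration: float,
    seed: int | np.random.Generator,
    block_index: int = 0,
) -> BlockRecord:
    """Simulate the keypress stream of one bi-stable block.

    The observer reports the initial percept after a latency, then presses
    the opposite key at each gamma-renewal epoch until the block ends. A
    latency exceeding the block duration yields an empty stream.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    events: list[KeypressEvent] = []
    latency = _draw_latency(obs, rng)
    if latency < duration:
        key = "left" if rng.random() < 0.5 else "right"
        events.append(KeypressEvent(t=latency, key=key))
        t = latency
        while True:
            t += float(rng.gamma(obs.gamma_shape, obs.gamma_scale))
            if t >= duration:
                break
            key = _flip(key)
            events.append(KeypressEvent(t=t, key=key))
    return BlockRecord(
        block_index=block_index, block_type="bistable", duration=duration, events=events
    )


def simulate_real_switch_block(
    obs: ObserverParams,
    schedule: SwitchSchedule,
    seed: int | np.random.Generator,
    block_index: int = 0,
) -> BlockRecord:
    """Simulate responses to the cued (unambiguous) real-switch block.

    The initial percept is reported near onset; each physical switch is
    answered with probability ``1 - miss_prob`` at a lognormal reaction
    time, with the reported direction flipped with probability
    ``error_prob``. Spontaneous reversal reports (Poisson at
    ``spontaneous_rate``) are superimposed, each flipping the previously
    reported direction.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    duration = schedule.block_duration

    timed: list[tuple[float, Optional[str]]] = []  # (time, key or None for spontaneous)
    latency = _draw_latency(obs, rng)
    if latency < duration:
        key = schedule.directions[0]
        if rng.random() < obs.error_prob:
            key = _flip(key)
        timed.append((latency, key))

    for t_switch, new_dir in zip(schedule.switch_times, schedule.directions[1:]):
        if rng.random() < obs.miss_prob:
            continue
        rt = float(rng.lognormal(obs.rt_mu, obs.rt_sigma))
        t = t_switch + rt
        if t >= duration:
            continue
        key = new_dir if rng.random() >= obs.error_prob else _flip(new_dir)
        timed.append((t, key))

    n_spont = rng.poisson(obs.spontaneous_rate * duration)
    for t in np.sort(rng.uniform(0.0, duration, size=n_spont)):
        timed.append((float(t), None))

    timed.sort(key=lambda pair: pair[0])
    events: list[KeypressEvent] = []
    for t, key in timed:
        if key is None:  # spontaneous reversal of whatever was last reported
            prev = events[-1].key if events else ("left" if rng.random() < 0.5 else "right")
            key = _flip(prev)
        events.append(KeypressEvent(t=t, key=key))
    return BlockRecord(
        block_index=block_index,
        block_type="real_switch",
        duration=duration,
        events=events,
        schedule=schedule,
    )


# --------------------------------------------------------------------------
# Cohort generation


@dataclass(frozen=True)
class CohortSpec:
    """Design of a synthetic cohort.

    Group structure lives on the log10 switch-rate scale (the analysis
    scale): people with psychotic psychopathology (``pwpp``) sit
    ``target_d`` pooled-SD units above controls, first-degree relatives at
    ``relative_position`` of the way in between. The within-group SD is
    split into a stable subject trait and session noise so that the
    two-session average-measures consistency ICC of latent rates equals
    ``retest_icc``. Clinical covariates and occipital metabolites are
    rank-coupled to the subject trait at the target Spearman correlations
    (``symptom_rho`` is the disorganization score BPRS_D; other scales
    in ``covariate_rhos``; ``gaba_rho`` for GABA).
    """

    n_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"control": 40, "relative": 43, "pwpp": 65}
    )
    control_log10_rate_mean: float = -0.82
    group_log10_rate_sd: float = 0.35
    target_d: float = 0.58
    relative_position: float = 0.5
    retest_icc: float = 0.88
    symptom_rho: float = 0.264
    gaba_rho: float = -0.16
    covariate_rhos: Mapping[str, float] = field(
        default_factory=lambda: {
            "BPRS": 0.207,
            "SPQ": 0.188,
            "BACS": -0.139,
            "SGI": 0.161,
            "SPQ_CP": 0.209,
        }
    )
    metabolite_rhos: Mapping[str, float] = field(
        default_factory=lambda: {"glutamate": -0.058, "glutamine": 0.06}
    )
    n_sessions: int = 2
    n_bistable_blocks: int = 5
    block_slope_log10: float = -0.02
    gamma_shape: float = 3.5
    initial_latency_mean: float = 1.5
    rt_mu: float = math.log(0.9)
    rt_sigma: float = 0.35
    group_miss_prob: Mapping[str, float] = field(
        default_factory=lambda: {"control": 0.18, "relative": 0.21, "pwpp": 0.25}
    )
    error_prob: float = 0.02
    spontaneous_rate: float = 0.01
    benzodiazepine_rate: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.retest_icc < 1.0:
            raise ValueError("retest_icc must lie in [0, 1)")
        for name, rho in self.all_covariate_rhos().items():
            if not abs(rho) < 1.0:
                raise ValueError(f"target rank correlation for {name} must satisfy |rho| < 1")
        for g, n in self.n_per_group.items():
            if n < 0:
                raise ValueError(f"negative group size for {g}")
        if self.n_sessions < 1 or self.n_bistable_blocks < 1:
            raise ValueError("need at least one session and one bi-stable block")

    def group_means(self) -> dict[str, float]:
        """Per-group mean of log10 switch rate implied by the effect size."""
        shift = self.target_d * self.group_log10_rate_sd
        return {
            "control": self.control_log10_rate_mean,
            "relative": self.control_log10_rate_mean + self.relative_position * shift,
            "pwpp": self.control_log10_rate_mean + shift,
        }

    def all_covariate_rhos(self) -> dict[str, float]:
        out = dict(self.covariate_rhos)
        out["BPRS_D"] = self.symptom_rho
        out["GABA"] = self.gaba_rho
        out.update(self.metabolite_rhos)
        return out

    def variance_split(self) -> tuple[float, float]:
        """(trait SD, session-noise SD) implied by the ICC target.

        For k = 2 sessions the average-measures consistency ICC equals
        ``2 r / (1 + r)`` with ``r`` the trait share of within-group
        variance, so ``r = ICC / (2 - ICC)``.
        """
        r = self.retest_icc / (2.0 - self.retest_icc)
        sd = self.group_log10_rate_sd
        return sd * math.sqrt(r), sd * math.sqrt(1.0 - r)


#: Marginal (mean, SD) used for covariate scores; ranks are what matter
#: downstream, the marginals only set plausible numbers.
COVARIATE_MARGINALS: dict[str, tuple[float, float]] = {
    "BPRS": (35.0, 12.0),
    "SPQ": (22.0, 14.0),
    "BACS": (0.0, 1.0),
    "SGI": (30.0, 18.0),
    "BPRS_D": (4.5, 1.8),
    "SPQ_CP": (7.0, 4.5),
}

#: Metabolite concentration marginals (mM-scale, occipital voxel).
METABOLITE_MARGINALS: dict[str, tuple[float, float]] = {
    "GABA": (1.1, 0.15),
    "glutamate": (8.0, 0.9),
    "glutamine": (2.4, 0.45),
}

_DIAGNOSES = ("schizophrenia", "schizoaffective", "bipolar")
_DIAGNOSIS_P = (36 / 65, 9 / 65, 20 / 65)


def _latent_tables(spec: CohortSpec) -> dict[str, np.ndarray]:
    """Draw per-subject latent structure: group, trait, session noise, covariates."""
    groups = [g for g in GROUPS for _ in range(spec.n_per_group.get(g, 0))]
    n = len(groups)
    means = spec.group_means()
    mu = np.array([means[g] for g in groups])
    sd_b, sd_e = spec.variance_split()

    rng = child_rng(spec.seed, 0)
    trait = mu + rng.normal(0.0, sd_b, size=n)
    session_noise = rng.normal(0.0, sd_e, size=(n, spec.n_sessions))

    # Copula: standardize the latent (group + trait) component, then couple
    # each covariate to it. Session noise dilutes the observable
    # correlation with measured rates, so the latent coupling is inflated
    # by the analytic attenuation factor.
    w = np.array([spec.n_per_group.get(g, 0) for g in GROUPS], dtype=float)
    w = w / w.sum() if w.sum() else w
    gm = np.array([means[g] for g in GROUPS])
    grand = float(np.dot(w, gm))
    var_g = float(np.dot(w, (gm - grand) ** 2))
    var_latent = var_g + sd_b**2
    atten = math.sqrt(var_latent / (var_latent + sd_e**2))
    z = (trait - grand) / math.sqrt(var_latent)  # trait already includes the group mean

    cov_rng = child_rng(spec.seed, 1)
    covariates: dict[str, np.ndarray] = {}
    for name, rho in spec.all_covariate_rhos().items():
        r_latent = 2.0 * math.sin(math.pi * rho / 6.0) / atten
        if not abs(r_latent) < 1.0:
            raise ValueError(
                f"rank-correlation target {rho} for {name} is infeasible "
                f"after attenuation correction (needs latent r = {r_latent:.3f})"
            )
        zc = r_latent * z + math.sqrt(1.0 - r_latent**2) * cov_rng.normal(size=n)
        m, s = COVARIATE_MARGINALS.get(name) or METABOLITE_MARGINALS[name]
        covariates[name] = m + s * zc

    return {
        "groups": np.array(groups, dtype=object),
        "mu": mu,
        "trait": trait,
        "session_noise": session_noise,
        **covariates,
    }


def _block_log10_rates(spec: CohortSpec, lat: dict[str, np.ndarray]) -> np.ndarray:
    """Latent log10 rate per (subject, session, block), centered block drift."""
    k = spec.n_bistable_blocks
    base = lat["trait"][:, None] + lat["session_noise"]  # (n, n_sessions); trait includes mu
    drift = spec.block_slope_log10 * (np.arange(k) - (k - 1) / 2.0)
    return base[:, :, None] + drift[None, None, :]


def _vectorized_counts(
    rates: np.ndarray,
    duration: float,
    latency_mean: float,
    gamma_shape: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Renewal switch counts for a flat array of rates, exact in distribution.

    Equivalent to counting the gamma-renewal epochs of the event-level
    simulator that land inside the block after the initial-percept latency.
    """
    r = np.asarray(rates, dtype=float).ravel()
    n = r.size
    latency = rng.gamma(_LATENCY_SHAPE, latency_mean / _LATENCY_SHAPE, size=n)
    horizon = np.clip(duration - latency, 0.0, None)
    scale = 1.0 / (gamma_shape * r)

    mean_counts = duration * r
    k_max = int(np.ceil(mean_counts.max() + 10.0 * math.sqrt(mean_counts.max() / gamma_shape) + 25))
    counts = np.zeros(n, dtype=int)
    todo = np.arange(n)
    while todo.size:
        draws = rng.standard_gamma(gamma_shape, size=(todo.size, k_max)) * scale[todo, None]
        csum = np.cumsum(draws, axis=1)
        counts[todo] += (csum < horizon[todo, None]).sum(axis=1)
        unfinished = csum[:, -1] < horizon[todo]
        horizon[todo] -= np.minimum(csum[:, -1], horizon[todo])
        todo = todo[unfinished]
    return counts


def generate_cohort_rates(spec: CohortSpec, duration: float = 120.0):
    """Fast cohort draw: per-block switch counts without event streams.

    Returns a tidy :class:`pandas.DataFrame` with one row per
    subject x session x bi-stable block (columns ``subject_id``, ``group``,
    ``session``, ``block``, ``n_switches``) plus per-subject covariate
    columns. The count distribution is identical to scoring the
    event-level streams from :func:`generate_cohort`; use this for
    Monte Carlo work where only rates matter.
    """
    import pandas as pd

    lat = _latent_tables(spec)
    log10_rates = _block_log10_rates(spec, lat)  # (n, sessions, blocks)
    n, n_sess, n_blk = log10_rates.shape
    rng = child_rng(spec.seed, 2)
    counts = _vectorized_counts(
        10.0**log10_rates, duration, spec.initial_latency_mean, spec.gamma_shape, rng
    ).reshape(n, n_sess, n_blk)

    idx = np.repeat(np.arange(n), n_sess * n_blk)
    frame = pd.DataFrame(
        {
            "subject_id": [f"S{i:04d}" for i in idx],
            "group": lat["groups"][idx],
            "session": np.tile(np.repeat(np.arange(1, n_sess + 1), n_blk), n),
            "block": np.tile(np.arange(1, n_blk + 1), n * n_sess),
            "n_switches": counts.ravel(),
        }
    )
    for name in spec.all_covariate_rhos():
        frame[name] = lat[name][idx]
    return frame


def generate_cohort(
    spec: CohortSpec,
    cyl: CylinderParams | None = None,
    schedule: SwitchSchedule | None = None,
) -> Cohort:
    """Generate a full event-level cohort.

    Every subject-session holds one real-switch block (responses to the
    canonical physical schedule) followed by ``n_bistable_blocks``
    bi-stable blocks driven by the subject's latent switch rate for that
    session and block. Deterministic given ``spec.seed``.
    """
    cyl = cyl or CylinderParams()
    schedule = schedule or make_real_switch_schedule(cyl, "paper")
    duration = cyl.block_duration

    lat = _latent_tables(spec)
    log10_rates = _block_log10_rates(spec, lat)
    n = lat["mu"].size
    diag_rng = child_rng(spec.seed, 3)

    sessions: list[SessionRecord] = []
    for i in range(n):
        group = str(lat["groups"][i])
        if group == "pwpp":
            diagnosis = str(diag_rng.choice(_DIAGNOSES, p=_DIAGNOSIS_P))
            benzo = bool(diag_rng.random() < spec.benzodiazepine_rate)
        else:
            diagnosis = "none"
            benzo = False
        covariates = {
            name: float(lat[name][i]) for name in COVARIATE_MARGINALS
        }
        metabolites = {name: float(lat[name][i]) for name in METABOLITE_MARGINALS}

        for s in range(spec.n_sessions):
            blocks: list[BlockRecord] = []
            rs_obs = ObserverParams(
                gamma_shape=spec.gamma_shape,
                gamma_scale=1.0,
                initial_latency_mean=spec.initial_latency_mean,
                rt_mu=spec.rt_mu,
                rt_sigma=spec.rt_sigma,
                miss_prob=float(spec.group_miss_prob.get(group, 0.2)),
                error_prob=spec.error_prob,
                spontaneous_rate=spec.spontaneous_rate,
            )
            blocks.append(
                simulate_real_switch_block(
                    rs_obs, schedule, child_rng(spec.seed, 10, i, s, 0), block_index=0
                )
            )
            for k in range(spec.n_bistable_blocks):
                rate = 10.0 ** log10_rates[i, s, k]
                obs = ObserverParams(
                    gamma_shape=spec.gamma_shape,
                    gamma_scale=1.0 / (spec.gamma_shape * rate),
                    initial_latency_mean=spec.initial_latency_mean,
                    rt_mu=spec.rt_mu,
                    rt_sigma=spec.rt_sigma,
                )
                blocks.append(
                    simulate_bistable_block(
                        obs, duration, child_rng(spec.seed, 10, i, s, k + 1), block_index=k + 1
                    )
                )
            sessions.append(
                SessionRecord(
                    subject_id=f"S{i:04d}",
                    group=group,
                    session_index=s + 1,
                    blocks=blocks,
                    covariates=covariates,
                    metabolites=metabolites,
                    benzodiazepine_flag=benzo,
                    diagnosis=diagnosis,
                )
            )
    return Cohort(sessions=sessions)
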