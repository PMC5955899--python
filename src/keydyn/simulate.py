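"""Synthetic keystroke-stream generator for simulated PD and control cohorts.

No public keystroke dataset accompanies the method, so this module emulates
cohorts of short typing sessions whose windowed statistics match the reported
group-level values: PD typists hold keys longer and more variably
(window-level HT mean 0.15 s / std 0.03 vs. 0.09 s / 0.02 for controls),
press more softly (NP mean 0.51 vs. 0.60) and show flight-time distributions
whose mass shifts to longer latencies (lower windowed NFT skewness, 0.90 vs.
1.51, after the conditional filter).

Model per keystroke (all draws independent given the subject/session
parameters):

* hold time  ~ log-normal with the profile's mean and standard deviation;
* flight time ~ log-normal with the profile's mean and a shape parameter
  moment-matched so the windowed post-filter skewness statistics hit the
  group targets; with a small stall probability the flight time is instead
  drawn uniformly above 3 s (a reading pause the filter must remove);
* pressure   ~ normal truncated to [0, 1].

Timestamps are built by accumulation (press_{n+1} = release_n + FT_n,
release_n = press_n + HT_n) and rounded to integer milliseconds, so applying
the sequence extractors to a generated session recovers the drawn values
exactly.

A cohort draws, per subject, a latent severity u ~ U(0, 1) that (for PD
subjects) produces unit-mean multiplicative jitter of the timing/pressure
parameters and monotone noisy UPDRS Part III item scores, planting a
recoverable feature-clinical-score association while keeping the group means
exactly on the profile targets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
from scipy import stats

from .errors import ConfigError
from .session_io import KeystrokeEvent, SubjectRecord, TypingSession

__all__ = [
    "GeneratorProfile",
    "CohortJitter",
    "SyntheticCohort",
    "make_profile",
    "generate_session",
    "generate_cohort",
    "UPDRS_ITEMS",
]

# Group anchor parameters. Timing/pressure levels come from the reported
# group statistics; the flight-time shapes were moment-matched by simulation
# (see docs/methods.md) so the cohort-level mean of the windowed post-filter
# NFT skewness equals the group targets (control 1.51, PD 0.90) under the
# default between-subject shape jitter.
_CONTROL = dict(
    ht_mean=0.09, ht_std=0.02,
    ft_mean=0.30, ft_sigma=0.89,
    stall_prob=0.02, stall_min=3.5, stall_max=10.0,
    np_mean=0.60, np_std=0.05,
)
_PD = dict(
    ht_mean=0.15, ht_std=0.03,
    ft_mean=0.40, ft_sigma=0.477,
    stall_prob=0.02, stall_min=3.5, stall_max=10.0,
    np_mean=0.51, np_std=0.05,
)

#: UPDRS Part III items of interest, with the strength of their link to the
#: latent severity (right-hand items strongest: the cohort types right-handed).
UPDRS_ITEMS = {
    "finger_tapping_rh": 1.0,
    "finger_tapping_lh": 0.7,
    "rigidity_ue_rh": 1.0,
    "rigidity_ue_lh": 0.7,
    "action_tremor_rh": 0.5,
    "action_tremor_lh": 0.3,
    "bk_hk": 0.9,
}


@dataclass
class GeneratorProfile:
    """Distribution parameters driving the keystroke-stream generator."""

    group: str  # "PD" or "control"
    severity: float  # interpolation coordinate: 0 = control, 1 = PD defaults
    ht_mean: float  # s, per-draw (window-level) hold-time mean
    ht_std: float  # s, per-draw hold-time std
    ft_mean: float  # s, flight-time mean (stalls excluded)
    ft_sigma: float  # log-normal shape of the flight-time distribution
    stall_prob: float  # per-keystroke probability of a >3 s reading pause
    stall_min: float  # s
    stall_max: float  # s
    np_mean: float  # normalised-pressure mean
    np_std: float  # normalised-pressure std (before truncation to [0,1])

    def __post_init__(self) -> None:
        if not 0.0 <= self.severity <= 1.0:
            raise ConfigError("severity must lie in [0, 1]")
        for name in ("ht_mean", "ht_std", "ft_mean", "ft_sigma", "np_std"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if not 0.0 <= self.stall_prob < 1.0:
            raise ConfigError("stall_prob must lie in [0, 1)")
        if not 0.0 < self.np_mean < 1.0:
            raise ConfigError("np_mean must lie in (0, 1)")


@dataclass
class CohortJitter:
    """Spread of the unit-mean between-subject and between-session jitter.

    Defaults are chosen so the across-session standard deviations of the
    headline session features match the reported group spreads (HT window-
    mean feature std ~0.06 s for PD / ~0.03 s for controls, NP window-mean
    std ~0.06-0.08): a modest between-subject component plus a dominant
    right-skewed (log-normal, unit-mean) session-to-session multiplier.
    """

    subject_ht: float = 0.55  # peak-to-centre relative range of HT scaling
    subject_ft: float = 0.25
    subject_np: float = 0.075  # absolute shift range of the pressure mean
    subject_shape: float = 0.4  # log-sd of the flight-time shape multiplier
    severity_weight: float = 0.55  # per-channel share of the common severity
    session_scale: float = 0.24  # log-sd of the per-session timing multiplier
    session_np: float = 0.035  # sd of the per-session pressure-mean shift


@dataclass
class SyntheticCohort:
    subjects: list[SubjectRecord]
    profiles: dict[str, GeneratorProfile]
    severities: dict[str, float]  # latent u per subject
    seed: int | None = None


def make_profile(
    group: str, severity: float | None = None, **overrides: float
) -> GeneratorProfile:
    """Profile for a group, optionally interpolated along a severity axis.

    ``severity`` defaults to 0 for controls and 1 for PD; intermediate values
    interpolate every parameter linearly between the two anchor sets, so
    severity 0 reproduces the control defaults and severity 1 the PD
    defaults. Keyword overrides replace individual parameters afterwards.
    """
    if group not in ("PD", "control"):
        raise ConfigError(f"group must be 'PD' or 'control', got {group!r}")
    s = (1.0 if group == "PD" else 0.0) if severity is None else float(severity)
    if not 0.0 <= s <= 1.0:
        raise ConfigError("severity must lie in [0, 1]")
    params = {k: (1 - s) * _CONTROL[k] + s * _PD[k] for k in _CONTROL}
    params.update(overrides)
    return GeneratorProfile(group=group, severity=s, **params)


def _lognormal(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    var_log = math.log1p((sd / mean) ** 2)
    mu_log = math.log(mean) - var_log / 2.0
    return rng.lognormal(mu_log, math.sqrt(var_log), size)


def _lognormal_shape(rng: np.random.Generator, mean: float, sigma: float, size: int) -> np.ndarray:
    mu_log = math.log(mean) - sigma**2 / 2.0
    return rng.lognormal(mu_log, sigma, size)


def generate_session(
    profile: GeneratorProfile,
    n_chars: int,
    seed: int | np.random.Generator | None = None,
    subject_id: str = "SYN",
    session_index: int = 1,
) -> TypingSession:
    """Generate one typing session of ``n_chars`` keystrokes.

    Hold/flight times are drawn from the profile, timestamps accumulate from
    t = 0 and are rounded to integer milliseconds (so the extractors recover
    the stored values exactly); pressures are rounded to three decimals as the
    capture layer reports them.
    """
    if n_chars < 2:
        raise ConfigError("a session needs at least two keystrokes")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    ht_ms = np.maximum(1, np.rint(_lognormal(rng, profile.ht_mean, profile.ht_std, n_chars) * 1000).astype(int))
    ft = _lognormal_shape(rng, profile.ft_mean, profile.ft_sigma, n_chars - 1)
    stall = rng.random(n_chars - 1) < profile.stall_prob
    ft[stall] = rng.uniform(profile.stall_min, profile.stall_max, int(stall.sum()))
    ft_ms = np.maximum(1, np.rint(ft * 1000).astype(int))

    a, b = (0.0 - profile.np_mean) / profile.np_std, (1.0 - profile.np_mean) / profile.np_std
    np_vals = stats.truncnorm.rvs(
        a, b, loc=profile.np_mean, scale=profile.np_std, size=n_chars, random_state=rng
    )
    np_vals = np.clip(np.round(np_vals, 3), 0.0, 1.0)

    events, t = [], 0
    for n in range(n_chars):
        press = t
        release = press + int(ht_ms[n])
        events.append(KeystrokeEvent(press, release, float(np_vals[n])))
        if n < n_chars - 1:
            t = release + int(ft_ms[n])
    return TypingSession(subject_id, session_index, events)


def _subject_profile(
    base: GeneratorProfile, u: float, jitter: CohortJitter, rng: np.random.Generator
) -> GeneratorProfile:
    """Unit-mean multiplicative jitter of a subject's parameters.

    ``u`` is the subject's latent severity draw; u > 0.5 means slower, more
    variable, softer typing than the group centre. The HT/FT multipliers
    scale the whole distribution (mean and std alike) so window-level
    statistics stay on target in expectation. The flight-time shape gets a
    median-one log-normal multiplier, partly anti-correlated with severity
    (more severe typists have less right-skewed flight times); its size is
    set so the across-session spread of the windowed NFT skewness matches
    the reported group values.
    """
    w = jitter.severity_weight
    s = (2.0 * u - 1.0)  # shared severity deviation, var 1/3

    def expression() -> float:
        # channel-specific expression: partly the shared severity, partly
        # idiosyncratic, same variance as s; typists differ in *which*
        # keystroke variable carries their deficit
        e = w * s + math.sqrt(1.0 - w**2) * rng.normal(0.0, 1.0 / math.sqrt(3.0))
        return float(np.clip(e, -1.2, 1.2))

    m_ht = 1.0 + jitter.subject_ht * expression()
    m_ft = 1.0 + jitter.subject_ft * expression()
    d_np = -jitter.subject_np * expression()
    z = -math.sqrt(3.0) * expression()
    m_shape = math.exp(jitter.subject_shape * z)
    return replace(
        base,
        ht_mean=base.ht_mean * m_ht,
        ht_std=base.ht_std * m_ht,
        ft_mean=base.ft_mean * m_ft,
        ft_sigma=base.ft_sigma * m_shape,
        np_mean=float(np.clip(base.np_mean + d_np, 0.05, 0.95)),
    )


def _updrs_scores(u: float, rng: np.random.Generator) -> tuple[dict[str, int], int]:
    items = {}
    for name, strength in UPDRS_ITEMS.items():
        level = np.clip(u * strength + rng.normal(0.0, 0.12), 0.0, 1.0)
        items[name] = int(np.clip(round(4.0 * level), 0, 4))
    total = int(np.clip(round(6.0 + 22.0 * u + rng.normal(0.0, 3.0)), 1, 60))
    return items, total


def generate_cohort(
    n_pd: int = 18,
    n_control: int = 15,
    sessions_per_subject: int = 10,
    seed: int | None = None,
    jitter: CohortJitter | None = None,
    excerpt_chars: tuple[int, int] = (46, 115),
    pd_profile: GeneratorProfile | None = None,
    control_profile: GeneratorProfile | None = None,
) -> SyntheticCohort:
    """Generate a labelled cohort of synthetic subjects.

    Defaults mirror the study cohort shape: 18 PD / 15 control subjects, 10
    sessions each, excerpt lengths uniform on 46-115 characters. PD subjects
    receive severity-linked UPDRS Part III item scores; controls score zero
    on every item. Fully reproducible under ``seed``.
    """
    jitter = jitter or CohortJitter()
    ss = np.random.SeedSequence(seed)
    subjects: list[SubjectRecord] = []
    profiles: dict[str, GeneratorProfile] = {}
    severities: dict[str, float] = {}

    groups = [("PD", i + 1) for i in range(n_pd)] + [("control", i + 1) for i in range(n_control)]
    children = ss.spawn(len(groups))
    for (group, k), child in zip(groups, children):
        rng = np.random.default_rng(child)
        sid = f"{'PD' if group == 'PD' else 'HC'}{k:02d}"
        base = (pd_profile if group == "PD" else control_profile) or make_profile(group)
        u = float(rng.uniform())
        prof = _subject_profile(base, u, jitter, rng)
        sessions = []
        for s_idx in range(1, sessions_per_subject + 1):
            # unit-mean log-normal: occasional much slower sessions, never
            # negative, expectation stays on the subject's parameters
            m = float(rng.lognormal(-jitter.session_scale**2 / 2.0, jitter.session_scale))
            sess_prof = replace(
                prof,
                ht_mean=prof.ht_mean * m,
                ht_std=prof.ht_std * m,
                ft_mean=prof.ft_mean * m,
                np_mean=float(np.clip(prof.np_mean + rng.normal(0.0, jitter.session_np), 0.05, 0.95)),
            )
            n_chars = int(rng.integers(excerpt_chars[0], excerpt_chars[1] + 1))
            sessions.append(generate_session(sess_prof, n_chars, rng, sid, s_idx))
        if group == "PD":
            items, total = _updrs_scores(u, rng)
        else:
            items, total = {name: 0 for name in UPDRS_ITEMS}, 0
        subjects.append(SubjectRecord(sid, group, sessions, updrs_items=items, updrs_total=total))
        profiles[sid] = prof
        severities[sid] = u if group == "PD" else 0.0
    return SyntheticCohort(subjects, profiles, severities, seed)
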