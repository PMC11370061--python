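"""Synthetic study generator: motor profiles, phenotypes and kinematics.

Emulates the statistical structure the downstream analysis assumes, so the
whole pipeline is testable without clinical data:

* a two-subtype Gaussian mixture on the MABC2 subscales (Manual Dexterity,
  Aiming & Catching, Balance) within the autism group — large separation on
  MD and BL, small on AC — plus TD and DCD comparison groups, additive batch
  offsets by originating study / test module / sex, and module assignment
  by age band (module 1: 3-6 y, module 2: 7-10 y, module 3: 11-16 y);
* reach-to-drop trials built from two concatenated minimum-jerk
  sub-movements (start -> ball, ball -> castle) for a wrist reference point,
  rigid marker offsets for the four recorded markers, smooth (8 Hz low-pass
  filtered) Gaussian trajectory noise whose amplitude is the per-subject
  "motor noise" ground truth, and small per-trial duration jitter;
* phenotype tables in which IQ and age at independent walking differ
  between the hidden subtypes while autism-symptom measures (ADOS-2 CSS,
  SRS) do not.

All scores use the MABC2 standard-score convention (TD reference mean 10,
SD 3 per subscale); the Total is kept on the same scale as the mean of the
three subscales, since only relative structure matters downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

from ._seeding import substream
from .kinematics import MARKERS, TrialTrajectory

SUBSCALES = ("md", "ac", "bl")

#: Fraction of the minimum-jerk reach at which its deceleration peaks
#: (root of the jerk polynomial after peak velocity); used to place the
#: nominal feedforward/feedback boundary of the noise envelope.
MINJERK_DP_TAU = 0.5 + np.sqrt(1.0 / 12.0)


def minimum_jerk(p0: np.ndarray, p1: np.ndarray, n_frames: int) -> np.ndarray:
    """Minimum-jerk point-to-point path sampled at n_frames (inclusive ends).

    Position follows p0 + (p1-p0) * s(tau) with s = 10 tau^3 - 15 tau^4 +
    6 tau^5, giving the classic bell-shaped speed profile 30 tau^2 (1-tau)^2.
    """
    tau = np.linspace(0.0, 1.0, n_frames)
    s = 10 * tau**3 - 15 * tau**4 + 6 * tau**5
    return p0[None, :] + s[:, None] * (p1 - p0)[None, :]


# ---------------------------------------------------------------------------
# motor-profile tables


@dataclass
class ProfileSimConfig:
    """Study conditions for the subject-level motor-profile table."""

    n_per_group: dict = field(
        default_factory=lambda: {"autism": 156, "td": 149, "dcd": 23}
    )
    subtype_fraction: float = 0.44  # share of autism in the "Low" subtype
    subtype_effect_d: tuple = (2.0, 0.45, 2.0)  # (md, ac, bl), pooled-SD units
    high_offset_d: float = 0.67  # autism "High" below TD, SD units
    score_mean: float = 10.0  # TD reference mean per subscale
    score_sd: float = 3.0
    study_offsets: dict = field(
        default_factory=lambda: {"MEDEA": 0.0, "NDA1": 1.0, "NDA2": -1.0}
    )
    study_probs: dict = field(
        default_factory=lambda: {"MEDEA": 0.5, "NDA1": 0.3, "NDA2": 0.2}
    )
    module_offsets: dict = field(default_factory=lambda: {1: 0.0, 2: 0.5, 3: -0.5})
    sex_offsets: dict = field(default_factory=lambda: {"F": 0.0, "M": 0.3})
    female_fraction: float = 0.2
    age_range: tuple = (3.0, 16.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.n_per_group.values()):
            raise ValueError("group counts must be positive")
        if not 0.0 <= self.subtype_fraction <= 1.0:
            raise ValueError("subtype_fraction must be in [0, 1]")
        if self.score_sd <= 0:
            raise ValueError("score SD must be positive")


def module_from_age(age: float) -> int:
    """MABC2 age-band module: 3-6 -> 1, 7-10 -> 2, 11-16 -> 3."""
    if age < 6.5:
        return 1
    if age < 10.5:
        return 2
    return 3


def simulate_profiles(cfg: ProfileSimConfig) -> pd.DataFrame:
    """One row per subject with MABC2 scores, covariates and, for autism
    rows, the hidden ground-truth subtype label (``true_subtype``)."""
    rng = substream(cfg.seed, "profiles")
    sd = cfg.score_sd
    high_mean = cfg.score_mean - cfg.high_offset_d * sd
    d = dict(zip(SUBSCALES, cfg.subtype_effect_d))
    # DCD matches the autism marginal mean (no case-control difference)
    autism_marginal = {
        s: high_mean - cfg.subtype_fraction * d[s] * sd for s in SUBSCALES
    }

    rows = []
    idx = 0
    for group, n in cfg.n_per_group.items():
        for _ in range(n):
            idx += 1
            age = float(rng.uniform(*cfg.age_range))
            sex = "F" if rng.random() < cfg.female_fraction else "M"
            study = str(
                rng.choice(list(cfg.study_probs), p=list(cfg.study_probs.values()))
            )
            module = module_from_age(age)
            subtype = None
            if group == "autism":
                subtype = "Low" if rng.random() < cfg.subtype_fraction else "High"
            means = {}
            for s in SUBSCALES:
                if group == "td":
                    mu = cfg.score_mean
                elif group == "dcd":
                    mu = autism_marginal[s]
                elif subtype == "High":
                    mu = high_mean
                else:
                    mu = high_mean - d[s] * sd
                means[s] = mu
            batch = (
                cfg.study_offsets[study]
                + cfg.module_offsets[module]
                + cfg.sex_offsets[sex]
            )
            scores = {s: rng.normal(means[s], sd) + batch for s in SUBSCALES}
            rows.append(
                {
                    "subject_id": f"S{idx:04d}",
                    "diagnosis": group,
                    "study_id": study,
                    "module": module,
                    "sex": sex,
                    "age": age,
                    **scores,
                    "total": float(np.mean(list(scores.values()))),
                    "true_subtype": subtype,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# phenotype tables


def simulate_phenotypes(
    table: pd.DataFrame,
    iq_gap_d: float = 0.7,
    walk_delay_d: float = 0.67,
    seed: int = 0,
) -> pd.DataFrame:
    """Phenotypes for the autism rows of a simulated profile table.

    IQ (mean 100, SD 15) and age at independent walking (mean 13 mo, SD 3)
    differ between the hidden subtypes by the configured effect sizes; age
    at first words, ADOS-2 calibrated severity scores and SRS are drawn
    identically for both subtypes (null effects by construction).
    """
    autism = table[table["diagnosis"] == "autism"]
    if autism["true_subtype"].isna().any():
        raise ValueError("profile table lacks hidden subtype labels")
    rng = substream(seed, "phenotypes")
    low = (autism["true_subtype"] == "Low").to_numpy()
    n = len(autism)
    out = pd.DataFrame(
        {
            "subject_id": autism["subject_id"].to_numpy(),
            "iq": rng.normal(100.0, 15.0, n) - iq_gap_d * 15.0 * low,
            "age_walk_months": rng.normal(13.0, 3.0, n) + walk_delay_d * 3.0 * low,
            "age_words_months": rng.normal(18.0, 6.0, n),
            "ados_css_total": np.clip(np.round(rng.normal(7.0, 2.0, n)), 1, 10),
            "ados_css_sa": np.clip(np.round(rng.normal(7.0, 2.0, n)), 1, 10),
            "ados_css_rrb": np.clip(np.round(rng.normal(7.0, 2.0, n)), 1, 10),
            "srs": rng.normal(70.0, 10.0, n),
        }
    )
    return out


# ---------------------------------------------------------------------------
# reach-to-drop kinematics


@dataclass
class KinematicSimConfig:
    """Study conditions for the reach-to-drop kinematic task (60 Hz)."""

    n_subjects_per_group: dict = field(
        default_factory=lambda: {"td": 35, "autism_high": 35, "autism_low": 35}
    )
    n_trials: int = 10
    sample_rate: float = 60.0
    #: per-group noise amplitude (mm RMS) before and after the nominal
    #: deceleration peak: (sigma_feedforward, sigma_feedback_and_drop)
    noise_sigma_by_group: dict = field(
        default_factory=lambda: {
            "td": (1.0, 1.0),
            "autism_high": (1.0, 1.0),
            "autism_low": (1.45, 1.15),
        }
    )
    subject_sigma_cv: float = 0.30  # lognormal between-subject spread of amplitude
    reach_duration: float = 1.0  # s, start -> ball
    drop_duration: float = 0.8  # s, ball -> castle
    dwell_frames: int = 2  # short hold at the grasp so its speed minimum is sharp
    duration_jitter: float = 0.03  # lognormal sigma on per-trial durations
    noise_cutoff_hz: float = 8.0  # noise smoothed by the pipeline's own filter band
    start_pos: tuple = (0.0, 0.0, 0.0)
    ball_pos: tuple = (250.0, 0.0, 50.0)  # mm; ~80% forearm length, raised support
    castle_pos: tuple = (400.0, 150.0, 150.0)
    marker_offsets: dict = field(
        default_factory=lambda: {
            "elbow": (-250.0, 0.0, 40.0),
            "wrist_ulnar": (0.0, -25.0, 0.0),
            "wrist_radial": (0.0, 25.0, 0.0),
            "hand_dorsum": (60.0, 0.0, 10.0),
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 2:
            raise ValueError("need at least 2 trials")
        if self.sample_rate <= 0 or self.reach_duration <= 0 or self.drop_duration <= 0:
            raise ValueError("sample rate and durations must be positive")


def _smooth_noise(rng: np.random.Generator, n: int, cutoff: float, fs: float) -> np.ndarray:
    """Unit-RMS smooth 12-channel noise field (low-pass-filtered Gaussian)."""
    white = rng.normal(size=(n, 12))
    b, a = butter(5, cutoff, btype="low", fs=fs)
    padlen = 3 * max(len(a), len(b))
    smooth = filtfilt(b, a, white, axis=0, padlen=min(padlen, n - 1))
    rms = np.sqrt(np.mean(smooth**2))
    return smooth / rms


def simulate_reach_to_drop(
    cfg: KinematicSimConfig,
    subject_noise: float | tuple,
    subject_id: str = "SIM",
    rng: np.random.Generator | None = None,
) -> list[TrialTrajectory]:
    """All trials for one subject.

    ``subject_noise`` is the trajectory-noise RMS amplitude in mm — a scalar,
    or a ``(sigma_feedforward, sigma_feedback)`` pair applied before/after
    the reach's nominal deceleration peak (boundary ramped over ~100 ms).
    Zero amplitude and zero duration jitter reproduce the identical
    noiseless trial ``n_trials`` times.
    """
    if np.any(np.asarray(subject_noise) < 0):
        raise ValueError("subject_noise must be non-negative")
    sigma_ff, sigma_fb = (
        (float(subject_noise),) * 2
        if np.isscalar(subject_noise)
        else tuple(float(s) for s in subject_noise)
    )
    if rng is None:
        rng = substream(cfg.seed, f"kinematics:{subject_id}")
    p0, p1, p2 = (np.asarray(p, dtype=float) for p in (cfg.start_pos, cfg.ball_pos, cfg.castle_pos))
    offsets = np.concatenate([np.asarray(cfg.marker_offsets[m], dtype=float) for m in MARKERS])

    trials = []
    for t in range(cfg.n_trials):
        jitter = float(np.exp(rng.normal(0.0, cfg.duration_jitter))) if cfg.duration_jitter > 0 else 1.0
        n_reach = max(10, int(round(cfg.reach_duration * jitter * cfg.sample_rate)))
        n_drop = max(10, int(round(cfg.drop_duration * jitter * cfg.sample_rate)))
        reach = minimum_jerk(p0, p1, n_reach + 1)
        dwell = np.repeat(p1[None, :], cfg.dwell_frames, axis=0)
        drop = minimum_jerk(p1, p2, n_drop + 1)
        ref = np.vstack([reach, dwell, drop[1:]])
        n = ref.shape[0]

        data = np.tile(ref, (1, 4)) + offsets[None, :]
        if sigma_ff > 0 or sigma_fb > 0:
            envelope = np.full(n, sigma_fb)
            dp_frame = int(round(MINJERK_DP_TAU * n_reach))
            envelope[: dp_frame + 1] = sigma_ff
            ramp = max(1, int(round(0.1 * cfg.sample_rate)))
            kernel = np.ones(ramp) / ramp
            envelope = np.convolve(envelope, kernel, mode="same")
            data = data + _smooth_noise(rng, n, cfg.noise_cutoff_hz, cfg.sample_rate) * envelope[:, None]
        trials.append(TrialTrajectory(subject_id, t + 1, data, cfg.sample_rate))
    return trials


def simulate_kinematic_cohort(
    cfg: KinematicSimConfig,
    subject_ids: dict | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Trials for a whole cohort.

    Returns (subject table with columns subject_id, group, noise_sigma_ff,
    noise_sigma_fb; dict subject_id -> list of TrialTrajectory). Per-subject
    amplitudes are the group amplitudes scaled by a lognormal multiplier
    exp(N(0, cv)), the same multiplier for both phases.

    ``subject_ids`` optionally maps group -> explicit id list (e.g. ids from
    a simulated profile table), overriding ``n_subjects_per_group``.
    """
    rng = substream(cfg.seed, "kinematic-cohort")
    rows, trials = [], {}
    for group, sigmas in cfg.noise_sigma_by_group.items():
        sigma_ff, sigma_fb = (sigmas, sigmas) if np.isscalar(sigmas) else sigmas
        if subject_ids is not None:
            ids = list(subject_ids.get(group, []))
        else:
            n = cfg.n_subjects_per_group.get(group, 0)
            ids = [f"{group.upper()}{i:03d}" for i in range(1, n + 1)]
        for sid in ids:
            mult = float(np.exp(rng.normal(0.0, cfg.subject_sigma_cv))) if cfg.subject_sigma_cv > 0 else 1.0
            s_ff, s_fb = sigma_ff * mult, sigma_fb * mult
            trials[sid] = simulate_reach_to_drop(cfg, (s_ff, s_fb), sid, rng=rng)
            rows.append(
                {"subject_id": sid, "group": group, "noise_sigma_ff": s_ff, "noise_sigma_fb": s_fb}
            )
    return pd.DataFrame(rows), trials
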