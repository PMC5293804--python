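"""Synthetic reach-to-grasp trial generator with controllable ground truth.

The generator emulates the two studies' structure: a 2 (verb type) x 3
(pronoun) within-subject design, 60 or 200 Hz sampling, a ~33-35 cm reach, and
per-cell calibration values for reach time, normalized velocity-peak latency,
grasp time and maximal aperture, plus between-subject, trial-level and sensor
noise, and catch trials.

Wrist transport follows a beta-family speed profile v(tau) ~ tau^a (1-tau)^b
with a/(a+b) equal to the peak fraction and a+b = 4, so the symmetric case is
exactly the minimum-jerk profile (peak speed 1.875 D/T). The index and thumb
markers sit at +/- half the aperture from the wrist along a fixed grip axis
orthogonal to the transport axis, so the inter-marker distance equals the
aperture profile by construction. The aperture opens and closes at constant
speed (triangular profile) and finishes closing at the end of the transport.

Extracted movement windows are integer frame counts, so a single trial cannot
realize an arbitrary reach time / peak-latency pair exactly. Two mechanisms
make the *extracted* parameters land on the configured values:

1. Each trial's targets are snapped to the frame grid, and the quantization
   residual is error-diffused across the trials of the same (subject, cell),
   so cell means converge to the configured values well below one frame.
2. For each realized (window frames, peak frame) pair, the continuous support
   length and profile peak position are calibrated against the actual
   filtering + segmentation pipeline (cached per integer key), compensating
   the inward bias of the threshold rules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import betainc

from .errors import ConfigurationError, InvalidArgumentError
from .kinematics import (
    SegmentationConfig,
    aperture as _aperture_series,
    filter_trajectory,
    lowpass,
    segment_grasp,
    segment_reach_displacement,
    segment_reach_velocity,
    speed as _speed_series,
)
from .stimuli import CELLS, Condition, StimulusTimeline, verbs_of_type
from .trajio import Trajectory, TrialRecord

#: Exponent sum of the beta-family speed profile; 4 makes the symmetric case
#: the minimum-jerk profile.
PROFILE_EXPONENT_SUM = 4.0

#: Transport direction: dominant forward axis with lift/curve components on
#: the other two, so the all-axis onset rule is exercised on every axis. The
#: smaller components are kept large enough that their threshold crossings are
#: steep, which keeps onset detection well-conditioned under sensor noise.
TRANSPORT_AXIS = np.array([2.0, 1.2, 1.0]) / math.sqrt(2.0**2 + 1.2**2 + 1.0**2)

#: Grip axis (index-thumb opening direction), orthogonal to the transport axis.
_g = np.cross(TRANSPORT_AXIS, np.array([0.0, 0.0, 1.0]))
GRIP_AXIS = _g / np.linalg.norm(_g)

PARAM_NAMES = ("reach_time_ms", "pct_t_vpeak", "grasp_time_ms", "max_aperture_mm")


# ---------------------------------------------------------------------------
# Profile primitives
# ---------------------------------------------------------------------------

def _profile_exponents(peak_fraction: float) -> tuple[float, float]:
    a = PROFILE_EXPONENT_SUM * peak_fraction
    return a, PROFILE_EXPONENT_SUM - a


def _n_samples(duration_ms: float, rate_hz: float) -> int:
    return int(round(duration_ms * rate_hz / 1000.0)) + 1


def speed_profile(
    peak_fraction: float, duration_ms: float, amplitude_mm: float, rate_hz: float
) -> np.ndarray:
    """Unimodal speed series (mm/s), zero at both ends.

    The peak sits at ``peak_fraction * duration_ms`` within one sample period
    and the time-integral of the series equals ``amplitude_mm`` (the discrete
    trapezoid integral is normalized exactly). With ``peak_fraction = 0.5``
    this is the minimum-jerk profile v(tau) = (30 D / T) tau^2 (1 - tau)^2.
    """
    args = (peak_fraction, duration_ms, amplitude_mm, rate_hz)
    if not all(np.isfinite(args)):
        raise InvalidArgumentError("speed_profile arguments must be finite")
    if not (0.0 < peak_fraction < 1.0):
        raise InvalidArgumentError("peak_fraction must be in (0, 1)")
    if duration_ms <= 0 or amplitude_mm <= 0 or rate_hz <= 0:
        raise InvalidArgumentError("duration, amplitude and rate must be positive")
    n = _n_samples(duration_ms, rate_hz)
    if n < 10:
        raise InvalidArgumentError("duration_ms must yield at least 10 samples")
    a, b = _profile_exponents(peak_fraction)
    tau = np.linspace(0.0, 1.0, n)
    v = tau**a * (1.0 - tau) ** b
    dt_s = duration_ms / 1000.0 / (n - 1)
    v *= amplitude_mm / np.trapezoid(v, dx=dt_s)
    return v


def _triangle(tau: np.ndarray, peak_fraction: float) -> np.ndarray:
    up = np.clip(tau / peak_fraction, 0.0, 1.0)
    down = np.clip((1.0 - tau) / (1.0 - peak_fraction), 0.0, 1.0)
    return np.minimum(up, down)


def aperture_profile(
    baseline_mm: float,
    max_aperture_mm: float,
    peak_fraction: float,
    duration_ms: float,
    rate_hz: float,
) -> np.ndarray:
    """Triangular index-thumb aperture series (mm).

    Starts and ends at baseline, with a unique maximum equal to
    ``max_aperture_mm`` at ``peak_fraction * duration_ms`` within one sample
    period. Constant-speed opening and closing keeps the frame-to-frame
    aperture change above the 0.3 mm grasp thresholds away from the endpoints,
    which a smooth bell at 60 Hz would not.
    """
    if not all(np.isfinite((baseline_mm, max_aperture_mm, peak_fraction,
                            duration_ms, rate_hz))):
        raise InvalidArgumentError("aperture_profile arguments must be finite")
    if max_aperture_mm <= baseline_mm:
        raise InvalidArgumentError("max_aperture_mm must exceed baseline_mm")
    if not (0.0 < peak_fraction < 1.0):
        raise InvalidArgumentError("peak_fraction must be in (0, 1)")
    if baseline_mm <= 0 or duration_ms <= 0 or rate_hz <= 0:
        raise InvalidArgumentError("baseline, duration and rate must be positive")
    n = _n_samples(duration_ms, rate_hz)
    tau = np.linspace(0.0, 1.0, n)
    ap = baseline_mm + (max_aperture_mm - baseline_mm) * _triangle(tau, peak_fraction)
    apex = int(np.argmin(np.abs(tau - peak_fraction)))
    apex = min(max(apex, 1), n - 2)
    ap[apex] = max_aperture_mm  # place the apex on the grid
    return ap


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CellMeans:
    """Calibration values for one (pronoun, verb type) cell."""

    reach_time_ms: float
    pct_t_vpeak: float
    grasp_time_ms: float
    max_aperture_mm: float

    def __post_init__(self) -> None:
        if not (0.0 < self.pct_t_vpeak < 100.0):
            raise ConfigurationError("pct_t_vpeak mean must be strictly in (0, 100)")
        if self.reach_time_ms <= 0 or self.grasp_time_ms <= 0:
            raise ConfigurationError("cell durations must be positive")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-level configuration of the synthetic generator.

    ``between_subject_sd`` holds per-parameter SDs of subject offsets (drawn
    once per subject); ``trial_param_sd`` holds per-parameter trial-to-trial
    SDs; ``trial_noise_sd_mm`` is isotropic Gaussian sensor noise added to
    every marker sample. ``catch_fraction`` is the fraction of *total* trials
    that are catch trials.
    """

    sampling_rate_hz: float
    condition_means: dict[tuple[str, str], CellMeans]
    n_subjects: int = 12
    n_trials_per_condition: int = 5
    catch_fraction: float = 0.25
    reach_amplitude_mm: float = 330.0
    between_subject_sd: dict[str, float] = field(default_factory=dict)
    trial_param_sd: dict[str, float] = field(default_factory=dict)
    trial_noise_sd_mm: float = 0.1
    aperture_baseline_mm: float = 5.0
    aperture_peak_fraction: float = 0.66
    reaction_time_ms: float = 300.0
    reaction_time_sd_ms: float = 50.0
    linguistic_error_rate: float = 0.0
    anticipation_rate: float = 0.0
    language: str = "italian"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0:
            raise ConfigurationError("sampling_rate_hz must be positive")
        if self.reach_amplitude_mm <= 0:
            raise ConfigurationError("reach_amplitude_mm must be positive")
        if self.n_subjects < 1 or self.n_trials_per_condition < 1:
            raise ConfigurationError("n_subjects and n_trials_per_condition must be >= 1")
        if not (0.0 <= self.catch_fraction < 1.0):
            raise ConfigurationError("catch_fraction must be in [0, 1)")
        if self.trial_noise_sd_mm < 0:
            raise ConfigurationError("trial_noise_sd_mm must be non-negative")
        missing = [cell for cell in CELLS if cell not in self.condition_means]
        if missing:
            raise ConfigurationError(f"condition_means missing cell(s) {missing!r}")
        for sd_map in (self.between_subject_sd, self.trial_param_sd):
            for key, value in sd_map.items():
                if value < 0:
                    raise ConfigurationError(f"negative SD for {key!r}")

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sampling_rate_hz

    def segmentation_variant(self) -> str:
        return "velocity_exp2" if self.sampling_rate_hz >= 100 else "displacement_exp1"

    def n_catch_per_subject(self) -> int:
        n_critical = 6 * self.n_trials_per_condition
        if self.catch_fraction == 0.0:
            return 0
        return int(round(n_critical * self.catch_fraction / (1.0 - self.catch_fraction)))


def _table(reach: list[float], pct: list[float], maxap: float) -> dict:
    cells = {}
    for (cell, rt, p) in zip(CELLS, reach, pct):
        cells[cell] = CellMeans(
            reach_time_ms=rt, pct_t_vpeak=p, grasp_time_ms=rt, max_aperture_mm=maxap
        )
    return cells

# Cell order: (I,AV), (YOU,AV), (HE,AV), (I,IV), (YOU,IV), (HE,IV)
_EXP1_REACH = [742.6, 685.6, 744.8, 705.1, 729.8, 720.7]
_EXP1_PCT = [49.4, 52.2, 48.5, 51.8, 47.4, 49.3]
_EXP2_REACH = [883.4, 869.3, 868.5, 861.2, 879.8, 894.5]
_EXP2_PCT = [31.6, 31.7, 32.3, 31.6, 31.0, 31.2]

_DEFAULT_BETWEEN_SD = {
    "reach_time_ms": 20.0,
    "pct_t_vpeak": 1.5,
    "grasp_time_ms": 20.0,
    "max_aperture_mm": 3.0,
}
_DEFAULT_TRIAL_SD = {
    "reach_time_ms": 30.0,
    "pct_t_vpeak": 2.0,
    "grasp_time_ms": 30.0,
    "max_aperture_mm": 2.0,
    "pct_t_max_aperture": 2.0,
}

PRESETS = {
    "exp1_italian": GeneratorConfig(
        sampling_rate_hz=60.0,
        condition_means=_table(_EXP1_REACH, _EXP1_PCT, 85.0),
        n_subjects=12,
        n_trials_per_condition=5,
        catch_fraction=0.25,
        reach_amplitude_mm=330.0,
        between_subject_sd=dict(_DEFAULT_BETWEEN_SD),
        trial_param_sd=dict(_DEFAULT_TRIAL_SD),
        trial_noise_sd_mm=0.1,
        linguistic_error_rate=0.01,
        anticipation_rate=0.005,
        language="italian",
    ),
    "exp2_german": GeneratorConfig(
        sampling_rate_hz=200.0,
        condition_means=_table(_EXP2_REACH, _EXP2_PCT, 85.0),
        n_subjects=16,
        n_trials_per_condition=14,
        catch_fraction=0.16,
        reach_amplitude_mm=350.0,
        between_subject_sd=dict(_DEFAULT_BETWEEN_SD),
        # The >1 mm/s onset/offset rule only functions when the post-filter
        # velocity noise floor sits well below the threshold (at 200 Hz even
        # 0.02 mm jitter yields ~1 mm/s velocity noise); the preset noise is
        # set accordingly, so rejections come from the planted error rates.
        trial_param_sd=dict(_DEFAULT_TRIAL_SD),
        trial_noise_sd_mm=0.005,
        linguistic_error_rate=0.06,
        anticipation_rate=0.02,
        language="german",
    ),
}


def preset(name: str, noiseless: bool = False) -> GeneratorConfig:
    """A shipped preset; ``noiseless=True`` zeroes every noise source."""
    try:
        config = PRESETS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
    if noiseless:
        config = replace(
            config,
            between_subject_sd={},
            trial_param_sd={},
            trial_noise_sd_mm=0.0,
            reaction_time_sd_ms=0.0,
            linguistic_error_rate=0.0,
            anticipation_rate=0.0,
        )
    return config


# ---------------------------------------------------------------------------
# Frame-grid realization (quantization + error diffusion)
# ---------------------------------------------------------------------------

class ResidualLedger:
    """Carries quantization residuals across the trials of one (subject, cell).

    ``update`` adds the residual keyed by parameter; ``peek`` returns the carry
    to add to the next trial's target before snapping to the frame grid.
    """

    def __init__(self) -> None:
        self._carry: dict[str, float] = {}

    def peek(self, key: str) -> float:
        return self._carry.get(key, 0.0)

    def update(self, key: str, target: float, realized: float, cap: float) -> None:
        carry = self._carry.get(key, 0.0) + (target - realized)
        self._carry[key] = float(np.clip(carry, -cap, cap))


def realize_window(
    duration_ms: float,
    pct: float,
    dt_ms: float,
    res_duration: float = 0.0,
    res_pct: float = 0.0,
) -> tuple[int, int]:
    """Snap a (duration, percent-latency) target to integer (frames, peak frame).

    Candidates are the floor/ceil frame counts and floor/ceil peak frames; the
    combination minimizing the percent-latency error (with a small weight on
    the duration error) wins. Guarantees 1 <= k <= n - 1.
    """
    t_target = duration_ms + res_duration
    p_target = pct + res_pct
    n_lo = max(int(math.floor(t_target / dt_ms)), 10)
    candidates = []
    for n in {n_lo, n_lo + 1}:
        k_raw = n * p_target / 100.0
        for k in {int(math.floor(k_raw)), int(math.ceil(k_raw))}:
            k = min(max(k, 1), n - 1)
            pct_err = abs(100.0 * k / n - p_target)
            dur_err = abs(n * dt_ms - t_target) / dt_ms
            candidates.append((pct_err + 0.3 * dur_err, n, k))
    _, n, k = min(candidates)
    return n, k


# ---------------------------------------------------------------------------
# Pipeline calibration (cached per integer frame key)
# ---------------------------------------------------------------------------

_REACH_CALIBRATION: dict[tuple, tuple[float, float, float, int, int]] = {}
_GRASP_CALIBRATION: dict[tuple, tuple[float, float, float, float, int, int]] = {}


def _build_wrist_positions(
    t_ms: np.ndarray, t0_ms: float, support_ms: float, peak_fraction: float,
    amplitude_mm: float,
) -> np.ndarray:
    a, b = _profile_exponents(peak_fraction)
    tau = np.clip((t_ms - t0_ms) / support_ms, 0.0, 1.0)
    arc = amplitude_mm * betainc(a + 1.0, b + 1.0, tau)
    return arc[:, None] * TRANSPORT_AXIS[None, :]


def _build_aperture(
    t_ms: np.ndarray, end_ms: float, support_ms: float, peak_fraction: float,
    baseline_mm: float, amplitude_mm: float,
) -> np.ndarray:
    tau = np.clip((t_ms - (end_ms - support_ms)) / support_ms, 0.0, 1.0)
    return baseline_mm + amplitude_mm * _triangle(tau, peak_fraction)


def _measure_reach(
    t_ms: np.ndarray, positions: np.ndarray, grasp_end_ms: float,
    seg_cfg: SegmentationConfig, dt_ms: float,
) -> tuple[int, int, float, float] | None:
    """Detected (window frames, peak frame, onset, crossing margin).

    The margin is the smallest distance of any onset/offset threshold crossing
    from its threshold; larger margins make frame-exact detection robust to
    sensor noise, and the calibration maximizes it among exact solutions.
    """
    traj = Trajectory(t_ms, positions[:, 0], positions[:, 1], positions[:, 2])
    filtered = filter_trajectory(traj, seg_cfg)
    v = _speed_series(filtered)
    if seg_cfg.variant == "velocity_exp2":
        window = segment_reach_velocity(v, t_ms, seg_cfg)
    else:
        window = segment_reach_displacement(filtered, grasp_end_ms, seg_cfg,
                                            speed_series=v)
    if window is None:
        return None
    i_on = int(np.argmin(np.abs(t_ms - window.onset_ms)))
    i_off = int(np.argmin(np.abs(t_ms - window.offset_ms)))
    if i_off - i_on < 2:
        return None
    i_pk = i_on + int(np.argmax(v[i_on : i_off + 1]))

    margins = []
    if seg_cfg.variant == "velocity_exp2":
        thr = seg_cfg.velocity_threshold_mm_s
        margins.append(v[i_on] - thr)
        if i_on > 0:
            margins.append(thr - v[i_on - 1])
        margins.append(v[i_off] - thr)
        if i_off + 1 < v.size:
            margins.append(thr - v[i_off + 1])
    else:
        thr = seg_cfg.displacement_threshold_mm
        disp = np.zeros_like(positions)
        pos_f = filtered.positions()
        disp[1:] = np.abs(np.diff(pos_f, axis=0))
        margins.append(float(disp[i_on].min()) - thr)
        if i_on > 0:
            margins.append(thr - float(disp[i_on - 1].min()))
        # Offset margins belong to the axis whose first sub-threshold frame was
        # selected by the grasp-end tie-break.
        sel_axis = None
        for axis in range(3):
            below = np.nonzero(disp[i_pk + 1:, axis] < thr)[0]
            if below.size and i_pk + 1 + int(below[0]) == i_off:
                sel_axis = axis
                break
        if sel_axis is not None:
            margins.append(thr - float(disp[i_off, sel_axis]))
            if i_off - 1 > i_pk:
                margins.append(float(disp[i_off - 1, sel_axis]) - thr)
    return i_off - i_on, i_pk - i_on, window.onset_ms, float(min(margins))


def calibrate_reach(
    rate_hz: float, n_frames: int, k_peak: int, amplitude_mm: float,
    seg_cfg: SegmentationConfig,
) -> tuple[float, float, float, int, int]:
    """Support length, peak position and grid phase realizing (n_frames, k_peak).

    Iterates the actual filter + segmentation pipeline on a noiseless trial
    until the detected window spans ``n_frames`` frames with the velocity peak
    ``k_peak`` frames after onset, then searches the exact-solution basin for
    the (support, phase) pair whose threshold crossings sit farthest from the
    thresholds, so sensor noise rarely shifts detection by a frame. Returns
    ``(support_ms, peak_fraction, phase, achieved_n, achieved_k)`` where
    ``phase`` is the sub-frame offset of the motion start; cached per integer
    key.
    """
    key = (round(rate_hz, 6), seg_cfg.variant, n_frames, k_peak,
           round(amplitude_mm, 3), seg_cfg.filter_cutoff_hz, seg_cfg.filter_order,
           seg_cfg.displacement_threshold_mm, seg_cfg.velocity_threshold_mm_s)
    if key in _REACH_CALIBRATION:
        return _REACH_CALIBRATION[key]

    dt = 1000.0 / rate_hz
    t_ms = np.arange(-20, n_frames + 40) * dt
    t0 = 0.5 * dt  # support starts mid-frame, matching trial construction
    support = (n_frames + 4) * dt
    fp = k_peak / n_frames
    best: tuple[int, float, float, int, int] | None = None
    seen: set[tuple[float, float]] = set()

    exact: tuple[float, float, float] | None = None  # (margin, support, fp)
    for _ in range(60):
        state = (round(support, 4), round(fp, 6))
        if state in seen:
            support += 0.37 * dt  # break limit cycles deterministically
        seen.add(state)
        positions = _build_wrist_positions(t_ms, t0, support, fp, amplitude_mm)
        # The real grasp end lands a few frames after the transport support end
        # (closure-detection delay), i.e. beyond every per-axis stop candidate;
        # calibrate in that regime so the tie-break picks the same candidate.
        measured = _measure_reach(t_ms, positions, t0 + support + 3.0 * dt,
                                  seg_cfg, dt)
        if measured is None:
            support += 2.0 * dt
            continue
        n_hat, k_hat, onset_ms, margin = measured
        score = 2 * abs(n_hat - n_frames) + abs(k_hat - k_peak)
        if best is None or score < best[0]:
            best = (score, support, fp, n_hat, k_hat)
        if n_hat == n_frames and k_hat == k_peak:
            exact = (margin, support, fp)
            break
        support = float(
            np.clip(support + (n_frames - n_hat) * dt,
                    max(n_frames - 6, 8) * dt, (n_frames + 25) * dt)
        )
        fp = float(np.clip((onset_ms + k_peak * dt - t0) / support, 0.10, 0.90))

    if exact is not None:
        # Search the exact-solution basin over support stretch and sub-frame
        # grid phase for maximal crossing margins; the profile mode is held
        # fixed in absolute time while the support stretches.
        margin0, support0, fp0 = exact
        t_mode0 = t0 + fp0 * support0
        best_exact = (margin0, support0, fp0, 0.5)
        for phase in (0.5, 0.25, 0.75, 0.0):
            t0_try = phase * dt
            for delta in np.linspace(-0.7, 0.7, 15) * dt:
                support_try = support0 + delta
                if support_try <= 0:
                    continue
                fp_try = float(np.clip((t_mode0 - t0_try) / support_try,
                                       0.10, 0.90))
                positions = _build_wrist_positions(t_ms, t0_try, support_try,
                                                   fp_try, amplitude_mm)
                measured = _measure_reach(
                    t_ms, positions, t0_try + support_try + 3.0 * dt, seg_cfg, dt)
                if measured is None:
                    continue
                n_hat, k_hat, _, margin = measured
                if (n_hat, k_hat) == (n_frames, k_peak) and margin > best_exact[0]:
                    best_exact = (margin, support_try, fp_try, phase)
        result = (best_exact[1], best_exact[2], best_exact[3], n_frames, k_peak)
    else:
        assert best is not None
        result = (best[1], best[2], 0.5, best[3], best[4])
    _REACH_CALIBRATION[key] = result
    return result


def calibrate_grasp(
    rate_hz: float, n_frames: int, k_peak: int, baseline_mm: float,
    nominal_amplitude_mm: float, seg_cfg: SegmentationConfig,
    phase: float = 0.5,
) -> tuple[float, float, float, int, int]:
    """Aperture support length/peak position realizing (n_frames, k_peak).

    ``phase`` is the sub-frame offset of the aperture-closure end (which is
    anchored to the reach support end). Also returns the amplitude scale that
    makes the *filtered* aperture maximum hit the target exactly (the
    zero-phase filter rounds the triangular apex) and a small non-negative
    ``end_shift_ms`` that delays the closure so its final step does not sit on
    the threshold. Returns ``(support_ms, peak_fraction, amp_scale,
    end_shift_ms, achieved_n, achieved_k)``.
    """
    key = (round(rate_hz, 6), n_frames, k_peak, round(baseline_mm, 3),
           round(phase, 6), seg_cfg.filter_cutoff_hz, seg_cfg.filter_order,
           seg_cfg.displacement_threshold_mm)
    if key in _GRASP_CALIBRATION:
        return _GRASP_CALIBRATION[key]

    dt = 1000.0 / rate_hz
    t_ms = np.arange(-15, n_frames + 30) * dt
    end_ms = (n_frames + 8) * dt + phase * dt
    support = n_frames * dt
    gp = k_peak / n_frames
    best: tuple[int, float, float, int, int, float] | None = None
    exact: tuple[float, float, float, float] | None = None

    for _ in range(40):
        measured = _measure_grasp(t_ms, end_ms, support, gp, baseline_mm,
                                  nominal_amplitude_mm, rate_hz, seg_cfg)
        if measured is None:
            support += 2.0 * dt
            continue
        n_hat, k_hat, onset_ms, margin, peak_deficit = measured
        score = 2 * abs(n_hat - n_frames) + abs(k_hat - k_peak)
        if best is None or score < best[0]:
            best = (score, support, gp, n_hat, k_hat, peak_deficit)
        if n_hat == n_frames and k_hat == k_peak:
            exact = (margin, support, gp, peak_deficit)
            break
        support = float(
            np.clip(support + (n_frames - n_hat) * dt,
                    max(n_frames - 6, 6) * dt, (n_frames + 20) * dt)
        )
        gp = float(np.clip((onset_ms + k_peak * dt - (end_ms - support))
                           / support, 0.10, 0.90))

    if exact is not None:
        # Search support stretch (apex held fixed in absolute time) and a small
        # closure delay for the exact solution whose threshold crossings
        # (including the first post-apex step, which guards against a premature
        # grasp end) sit farthest from the thresholds.
        margin0, support0, gp0, deficit0 = exact
        apex_t = end_ms - support0 + gp0 * support0
        chosen = (margin0, support0, gp0, 0.0, deficit0)
        for shift in (0.0, 0.25 * dt, 0.5 * dt, 0.75 * dt):
            end_try = end_ms + shift
            for delta in np.linspace(-0.7, 0.7, 15) * dt:
                support_try = support0 + delta
                if support_try <= 0:
                    continue
                gp_try = float(np.clip(
                    (apex_t - (end_try - support_try)) / support_try, 0.10, 0.90))
                measured = _measure_grasp(t_ms, end_try, support_try, gp_try,
                                          baseline_mm, nominal_amplitude_mm,
                                          rate_hz, seg_cfg)
                if measured is None:
                    continue
                n_hat, k_hat, _, margin, peak_deficit = measured
                if (n_hat, k_hat) == (n_frames, k_peak) and margin > chosen[0]:
                    chosen = (margin, support_try, gp_try, shift, peak_deficit)
        deficit = chosen[4]
        amp_scale = nominal_amplitude_mm / deficit if deficit > 0 else 1.0
        result = (chosen[1], chosen[2], amp_scale, chosen[3], n_frames, k_peak)
    else:
        assert best is not None
        amp_scale = nominal_amplitude_mm / best[5] if best[5] > 0 else 1.0
        result = (best[1], best[2], amp_scale, 0.0, best[3], best[4])
    _GRASP_CALIBRATION[key] = result
    return result


def _measure_grasp(
    t_ms: np.ndarray, end_ms: float, support: float, gp: float,
    baseline_mm: float, amplitude_mm: float, rate_hz: float,
    seg_cfg: SegmentationConfig,
) -> tuple[int, int, float, float, float] | None:
    """Detected (frames, apex frame, onset, crossing margin, filtered peak rise).

    The margin includes every frame-to-frame step between the apex and the
    detected grasp end: if any of them sits close to the threshold, noise (or a
    sub-frame apex shift) would end the grasp prematurely right after the
    maximum.
    """
    ap = _build_aperture(t_ms, end_ms, support, gp, baseline_mm, amplitude_mm)
    ap_f = lowpass(ap, rate_hz, seg_cfg.filter_cutoff_hz, seg_cfg.filter_order)
    window = segment_grasp(ap_f, t_ms, seg_cfg)
    if window is None:
        return None
    thr = seg_cfg.displacement_threshold_mm
    i_on = int(np.argmin(np.abs(t_ms - window.onset_ms)))
    i_off = int(np.argmin(np.abs(t_ms - window.offset_ms)))
    if i_off - i_on < 2:
        return None
    i_max = i_on + int(np.argmax(ap_f[i_on : i_off + 1]))
    change = np.abs(ap_f - ap_f[0])
    dap = np.abs(np.diff(ap_f))  # dap[j] = |ap[j+1] - ap[j]|

    margins = [float(change[i_on]) - thr]
    if i_on > 0:
        margins.append(thr - float(change[i_on - 1]))
    closing = dap[i_max : i_off - 1]  # steps that must stay above threshold
    if closing.size:
        margins.append(float(closing.min()) - thr)
    else:
        margins.append(-thr)  # offset immediately after apex: premature
    margins.append(thr - float(dap[i_off - 1]))
    return (i_off - i_on, i_max - i_on, window.onset_ms, float(min(margins)),
            float(np.max(ap_f)) - baseline_mm)


# ---------------------------------------------------------------------------
# Trial and experiment simulation
# ---------------------------------------------------------------------------

_NOMINAL_GRASP_AMPLITUDE = 80.0


def _segmentation_for(config: GeneratorConfig) -> SegmentationConfig:
    return SegmentationConfig(variant=config.segmentation_variant())


def simulate_trial(
    condition: Condition,
    subject_offsets: dict[str, float],
    config: GeneratorConfig,
    seed,
    ledger: ResidualLedger | None = None,
    force_anticipation: bool = False,
    linguistic_error: bool = False,
    subject_id: str = "s01",
    trial_id: str = "t001",
) -> TrialRecord:
    """One synthetic trial whose extracted parameters realize the cell targets.

    The noiseless wrist trajectory realizes the reach time and percent latency
    of (cell mean + subject offset) on the frame grid; index/thumb equal the
    wrist plus half-aperture offsets of opposite sign along the grip axis;
    isotropic Gaussian position noise is added per marker sample. Fully
    reproducible for a fixed seed.
    """
    cell = condition.cell
    if cell not in config.condition_means:
        raise ConfigurationError(f"condition cell {cell!r} not in condition_means")
    means = config.condition_means[cell]
    rng = np.random.default_rng(seed)
    dt = config.dt_ms
    trial_sd = config.trial_param_sd
    ledger = ledger if ledger is not None else ResidualLedger()

    def draw(name: str, mean: float) -> float:
        sd = trial_sd.get(name, 0.0)
        noise = rng.normal(0.0, sd) if sd > 0 else 0.0
        return mean + subject_offsets.get(name, 0.0) + noise

    reach_t = max(draw("reach_time_ms", means.reach_time_ms), 25 * dt)
    reach_pct = float(np.clip(draw("pct_t_vpeak", means.pct_t_vpeak), 10.0, 90.0))
    grasp_t = float(np.clip(draw("grasp_time_ms", means.grasp_time_ms),
                            0.4 * reach_t, reach_t))
    max_ap = max(draw("max_aperture_mm", means.max_aperture_mm),
                 config.aperture_baseline_mm + 20.0)
    grasp_pct = float(np.clip(
        draw("pct_t_max_aperture", 100.0 * config.aperture_peak_fraction),
        15.0, 90.0))

    seg_cfg = _segmentation_for(config)

    # Snap targets to the frame grid, carrying quantization residuals.
    n_r, k_r = realize_window(reach_t, reach_pct, dt,
                              ledger.peek("reach_time_ms"), ledger.peek("pct_t_vpeak"))
    support, fp, phase, n_ra, k_ra = calibrate_reach(
        config.sampling_rate_hz, n_r, k_r, config.reach_amplitude_mm, seg_cfg)
    ledger.update("reach_time_ms", reach_t, n_ra * dt, cap=2.0 * dt)
    ledger.update("pct_t_vpeak", reach_pct, 100.0 * k_ra / n_ra, cap=3.0)

    n_g, k_g = realize_window(grasp_t, grasp_pct, dt,
                              ledger.peek("grasp_time_ms"),
                              ledger.peek("pct_t_max_aperture"))
    g_support, gp, amp_scale, g_end_shift, n_ga, k_ga = calibrate_grasp(
        config.sampling_rate_hz, n_g, k_g, config.aperture_baseline_mm,
        _NOMINAL_GRASP_AMPLITUDE, seg_cfg, phase=phase)
    ledger.update("grasp_time_ms", grasp_t, n_ga * dt, cap=2.0 * dt)
    ledger.update("pct_t_max_aperture", grasp_pct, 100.0 * k_ga / n_ga, cap=3.0)

    # Movement start: reaction time after verb-stem onset, snapped to the frame
    # grid at a fixed half-frame phase so calibration transfers exactly.
    if force_anticipation:
        rt = min(-150.0 + (rng.normal(0.0, 30.0) if config.reaction_time_sd_ms > 0
                           else 0.0), -3 * dt)
    else:
        rt = config.reaction_time_ms + (
            rng.normal(0.0, config.reaction_time_sd_ms)
            if config.reaction_time_sd_ms > 0 else 0.0)
        rt = max(rt, 2 * dt)
    t0 = round(rt / dt) * dt + phase * dt

    timeline = StimulusTimeline()
    i_start = int(round(-timeline.pronoun_ms / dt))
    i_end = int(math.ceil((t0 + support + 250.0) / dt))
    t_ms = np.arange(i_start, i_end + 1) * dt

    wrist_pos = _build_wrist_positions(t_ms, t0, support, fp,
                                       config.reach_amplitude_mm)
    # Closure ends at the grid-phase point nearest the reach support end, so
    # the grasp channel keeps the sub-frame alignment it was calibrated at.
    g_end = (round((t0 + support) / dt - phase) + phase) * dt + g_end_shift
    ap = _build_aperture(t_ms, g_end, g_support, gp,
                         config.aperture_baseline_mm,
                         (max_ap - config.aperture_baseline_mm) * amp_scale)
    half = (ap / 2.0)[:, None] * GRIP_AXIS[None, :]
    index_pos = wrist_pos + half
    thumb_pos = wrist_pos - half

    if config.trial_noise_sd_mm > 0:
        sd = config.trial_noise_sd_mm
        wrist_pos = wrist_pos + rng.normal(0.0, sd, wrist_pos.shape)
        index_pos = index_pos + rng.normal(0.0, sd, index_pos.shape)
        thumb_pos = thumb_pos + rng.normal(0.0, sd, thumb_pos.shape)

    markers = {
        "wrist": Trajectory(t_ms, *wrist_pos.T),
        "index": Trajectory(t_ms, *index_pos.T),
        "thumb": Trajectory(t_ms, *thumb_pos.T),
    }
    return TrialRecord(
        subject_id=subject_id,
        trial_id=trial_id,
        condition=condition,
        markers=markers,
        timeline=timeline,
        linguistic_error=linguistic_error,
        ground_truth={
            "reach_time_ms": n_ra * dt,
            "pct_t_vpeak": 100.0 * k_ra / n_ra,
            "t_vpeak_ms": k_ra * dt,
            "grasp_time_ms": n_ga * dt,
            "pct_t_max_aperture": 100.0 * k_ga / n_ga,
            "max_aperture_mm": max_ap,
            "reach_frames": n_ra,
            "peak_frame": k_ra,
            "onset_ms": t0,
        },
    )


def _catch_condition(rng: np.random.Generator, language: str) -> Condition:
    """A pronoun paired with a verb form inflected for a different person."""
    pronouns = ("I", "YOU", "HE")
    pronoun = pronouns[int(rng.integers(3))]
    verb_type = ("AV", "IV")[int(rng.integers(2))]
    verbs = verbs_of_type(language, verb_type)
    verb = verbs[int(rng.integers(len(verbs)))]
    wrong = pronouns[(pronouns.index(pronoun) + 1 + int(rng.integers(2))) % 3]
    return Condition(pronoun=pronoun, verb_type=verb_type,
                     verb_label=verb.form(wrong), is_catch=True)


def simulate_experiment(config: GeneratorConfig, seed: int | None = None
                        ) -> list[TrialRecord]:
    """A full multi-subject experiment.

    Per subject: ``n_trials_per_condition`` critical trials in each of the six
    cells (verbs cycled through the stimulus table) plus the configured catch
    fraction, in randomized order; subject offsets drawn once per subject from
    ``between_subject_sd``. All randomness flows from one seed through a
    ``SeedSequence`` hierarchy, so identical (config, seed) gives a
    byte-identical dataset after serialization.
    """
    entropy = config.seed if seed is None else seed
    root = (entropy if isinstance(entropy, np.random.SeedSequence)
            else np.random.SeedSequence(entropy))
    subject_sequences = root.spawn(config.n_subjects)
    dataset: list[TrialRecord] = []

    for s_idx, subj_seq in enumerate(subject_sequences):
        subject_id = f"s{s_idx + 1:02d}"
        rng = np.random.default_rng(subj_seq)
        offsets = {
            name: (rng.normal(0.0, sd) if sd > 0 else 0.0)
            for name, sd in config.between_subject_sd.items()
        }

        plan: list[Condition] = []
        for pronoun, verb_type in CELLS:
            verbs = verbs_of_type(config.language, verb_type)
            for j in range(config.n_trials_per_condition):
                verb = verbs[j % len(verbs)]
                plan.append(Condition(pronoun=pronoun, verb_type=verb_type,
                                      verb_label=verb.form(pronoun)))
        for _ in range(config.n_catch_per_subject()):
            plan.append(_catch_condition(rng, config.language))

        order = rng.permutation(len(plan))
        trial_seeds = subj_seq.spawn(len(plan))
        # Catch trials are excluded from analysis, so they carry their own
        # residual ledgers and never consume critical-trial diffusion state.
        ledgers: dict[tuple, ResidualLedger] = {}
        for position, plan_idx in enumerate(order):
            condition = plan[int(plan_idx)]
            ledger = ledgers.setdefault((condition.cell, condition.is_catch),
                                        ResidualLedger())
            anticipate = (config.anticipation_rate > 0
                          and rng.random() < config.anticipation_rate)
            ling_err = (config.linguistic_error_rate > 0
                        and rng.random() < config.linguistic_error_rate)
            dataset.append(
                simulate_trial(
                    condition,
                    offsets,
                    config,
                    trial_seeds[position],
                    ledger=ledger,
                    force_anticipation=anticipate,
                    linguistic_error=ling_err,
                    subject_id=subject_id,
                    trial_id=f"{subject_id}_t{position + 1:03d}",
                )
            )
    return dataset
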