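"""Threshold procedures for the simulated listener.

Two procedures are modelled, matching the behavioural methods they emulate:

* a one-up/one-down adaptive staircase for single-channel monopolar
  triphasic stimuli (one track per polarity), with a 0.5 dB initial step
  shrinking to 0.2 dB after the first reversal, termination after eight
  reversals, and the threshold taken as the mean of the last six;
* a Bekesy-style continuous threshold sweep for steered-quadrupolar (sQP)
  stimuli, stepping current by 1 dB per presentation while the steering
  coefficient alpha advances 0 -> 1 in steps of 0.1 (two presentations per
  alpha), two forward plus two reverse runs, with integer-channel thresholds
  reconstructed by a triangular-weighted average of the press/release
  transition levels.

The listener is a yes/no observer: detection probability is
``gamma + (1 - gamma - lambda) * Phi((level - T) / s)`` where T is the ear's
true threshold for the presented stimulus.  With slope ``s = 0`` the observer
is a deterministic step (detects iff level >= T), which makes the procedure
oracles unambiguous.  Most-comfortable levels (threshold + dynamic range)
cap every presented level.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.stats import norm

from .synthetic_cochlea import VirtualEar

__all__ = [
    "TRIPHASIC_CENTER_RATIO",
    "StimulusSpec",
    "monopolar_stimulus",
    "sqp_stimulus",
    "ListenerModel",
    "StaircaseResult",
    "ThresholdEstimate",
    "SweepResult",
    "db_from_microamps",
    "microamps_from_db",
    "detect",
    "run_staircase",
    "estimate_threshold_staircase",
    "sqp_current_weights",
    "run_sweep",
]

#: central high-amplitude phase of the triphasic pulse is twice the flankers
TRIPHASIC_CENTER_RATIO = 2.0

ALPHA_GRID = np.round(np.arange(0.0, 1.05, 0.1), 10)


@dataclasses.dataclass
class StimulusSpec:
    """Electrical stimulus description.

    ``mode`` is ``"monopolar-triphasic"`` (polarity ACA or CAC) or
    ``"sQP-biphasic"`` (steering alpha, focusing sigma).  Monopolar stimuli
    ignore alpha/sigma.  Channels are 1-based with electrode 1 apical.
    """

    mode: str
    channel: int
    polarity: str = "n/a"
    alpha: float = 0.0
    sigma: float = 0.9
    phase_us: float = 43.0
    rate_pps: float = 99.0
    duration_ms: float = 400.0

    def __post_init__(self) -> None:
        if self.mode not in ("monopolar-triphasic", "sQP-biphasic"):
            raise ValueError(f"unknown stimulus mode {self.mode!r}")
        if self.mode == "monopolar-triphasic" and self.polarity not in ("ACA", "CAC"):
            raise ValueError("monopolar triphasic stimuli need polarity ACA or CAC")
        if self.mode == "sQP-biphasic":
            if not 0.0 <= self.alpha <= 1.0:
                raise ValueError("alpha must lie in [0, 1]")
            if not 0.0 <= self.sigma <= 1.0:
                raise ValueError("sigma must lie in [0, 1]")


def monopolar_stimulus(polarity: str, channel: int) -> StimulusSpec:
    """99-pps monopolar triphasic train, 43 us/phase, 400 ms."""
    return StimulusSpec(mode="monopolar-triphasic", channel=channel, polarity=polarity)


def sqp_stimulus(channel: int, alpha: float = 0.0, sigma: float = 0.9) -> StimulusSpec:
    """Steered-quadrupolar biphasic train, 102 us/phase, ~998 pps, 200.4 ms."""
    return StimulusSpec(
        mode="sQP-biphasic",
        channel=channel,
        alpha=alpha,
        sigma=sigma,
        phase_us=102.0,
        rate_pps=997.9,
        duration_ms=200.4,
    )


def db_from_microamps(i_ua) -> np.ndarray | float:
    """Current in uA -> level in dB re 1 uA."""
    i = np.asarray(i_ua, dtype=float)
    if np.any(i <= 0):
        raise ValueError("current must be positive")
    out = 20.0 * np.log10(i)
    return float(out) if out.ndim == 0 else out


def microamps_from_db(level_db) -> np.ndarray | float:
    """Level in dB re 1 uA -> current in uA."""
    out = np.power(10.0, np.asarray(level_db, dtype=float) / 20.0)
    return float(out) if out.ndim == 0 else out


def sqp_current_weights(
    channel: int, alpha: float, sigma: float, n_electrodes: int = 16
) -> dict:
    """Signed per-electrode current fractions of a steered quadrupole.

    Channel c uses active electrodes (c-1, c) carrying fractions
    (1-alpha, alpha) of the main current and flanking returns (c-2, c+1)
    carrying -sigma/2 each; the remaining (1 - sigma) returns through the
    extracochlear ground.  Channel numbers follow the convention that the
    channel equals the basal active electrode at alpha = 1.  Channel 2 cannot
    steer (it would need an electrode 0), so it reuses the channel-3 set with
    alpha forced to 0, centring the current on electrode 2.
    """
    if not 2 <= channel <= n_electrodes - 1:
        raise ValueError(
            "sQP thresholds cannot be measured on channels 1 and "
            f"{n_electrodes} (two intracochlear returns are required); "
            f"got channel {channel}"
        )
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    if not 0.0 <= sigma <= 1.0:
        raise ValueError("sigma must lie in [0, 1]")
    c = channel
    if channel == 2:
        c, alpha = 3, 0.0
    weights = {
        c - 2: -sigma / 2.0,
        c - 1: 1.0 - alpha,
        c: alpha,
        c + 1: -sigma / 2.0,
    }
    return weights


@dataclasses.dataclass
class ListenerModel:
    """Simulated observer bound to a virtual ear.

    ``slope_db`` is the psychometric spread s (s = 0 -> step observer);
    ``false_alarm`` and ``lapse`` are the guess/lapse rates.  MCLs are
    threshold + per-channel dynamic range, floor applied at generation.
    """

    ear: VirtualEar
    slope_db: float | None = None
    false_alarm: float | None = None
    lapse: float | None = None

    def __post_init__(self) -> None:
        lp = self.ear.listener
        if self.slope_db is None:
            self.slope_db = lp.psychometric_slope_db
        if self.false_alarm is None:
            self.false_alarm = lp.false_alarm_rate
        if self.lapse is None:
            self.lapse = lp.lapse_rate
        if self.slope_db < 0:
            raise ValueError("psychometric slope must be >= 0")
        if not (0 <= self.false_alarm < 0.5 and 0 <= self.lapse < 0.5):
            raise ValueError("false-alarm and lapse rates must lie in [0, 0.5)")

    # -- true thresholds ---------------------------------------------------
    def _sqp_threshold_at(self, channel: int, alpha: float) -> float:
        """Linear interpolation of the latent sQP profile at the fractional
        channel position (c-1) + alpha; channel 2 is pinned at position 2."""
        pos = 2.0 if channel == 2 else (channel - 1) + alpha
        t = self.ear.t_sqp_db
        chans = np.arange(1, self.ear.n_electrodes + 1, dtype=float)
        ok = np.isfinite(t)
        if not ok.any():
            return np.nan
        lo, hi = chans[ok].min(), chans[ok].max()
        if pos < lo or pos > hi:
            return np.nan
        return float(np.interp(pos, chans[ok], t[ok]))

    def true_threshold(self, stimulus: StimulusSpec) -> float:
        if stimulus.mode == "monopolar-triphasic":
            idx = stimulus.channel - 1
            arr = self.ear.t_aca_db if stimulus.polarity == "ACA" else self.ear.t_cac_db
            return float(arr[idx])
        return self._sqp_threshold_at(stimulus.channel, stimulus.alpha)

    def mcl_db(self, stimulus: StimulusSpec) -> float:
        t = self.true_threshold(stimulus)
        if stimulus.mode == "monopolar-triphasic":
            dr = float(self.ear.listener.dynamic_range_mono_db[stimulus.channel - 1])
            return t + dr
        pos = 2.0 if stimulus.channel == 2 else (stimulus.channel - 1) + stimulus.alpha
        chans = np.arange(1, self.ear.n_electrodes + 1, dtype=float)
        mcl = self.ear.t_sqp_db + self.ear.listener.dynamic_range_sqp_db
        ok = np.isfinite(mcl)
        if not ok.any():
            return np.nan
        return float(np.interp(pos, chans[ok], mcl[ok]))


def detect(
    listener: ListenerModel,
    stimulus: StimulusSpec,
    level_db: float,
    rng: np.random.Generator,
) -> bool:
    """One yes/no trial.  NaN true threshold (no percept) -> guesses only."""
    if not np.isfinite(level_db):
        raise ValueError("presented level must be finite")
    t = listener.true_threshold(stimulus)
    gamma, lam, s = listener.false_alarm, listener.lapse, listener.slope_db
    if not np.isfinite(t):
        p = gamma
    elif s == 0:
        p = gamma + (1.0 - gamma - lam) * (1.0 if level_db >= t else 0.0)
    else:
        p = gamma + (1.0 - gamma - lam) * norm.cdf((level_db - t) / s)
    return bool(rng.uniform() < p)


@dataclasses.dataclass
class StaircaseResult:
    levels_db: list
    responses: list
    reversal_levels: list
    threshold_db: float
    converged: bool
    n_trials: int


def run_staircase(
    listener: ListenerModel,
    stimulus: StimulusSpec,
    rng: np.random.Generator,
    start_fraction_of_mcl: float = 0.90,
    initial_step_db: float = 0.5,
    small_step_db: float = 0.2,
    n_reversals: int = 8,
    n_mean_reversals: int = 6,
    max_trials: int = 200,
    max_consecutive_at_mcl: int = 12,
    floor_db: float = 0.0,
) -> StaircaseResult:
    """One adaptive one-up/one-down track.

    Starts at ``start_fraction_of_mcl`` x MCL on the dB scale (0.90 default;
    0.50-0.98 allowed), decreases after a detection and increases otherwise.
    A reversal is logged at the level where the response flips; the step
    shrinks from 0.5 to 0.2 dB after the first reversal, and the track
    terminates after eight reversals with threshold = mean of the last six.
    Presented levels never exceed MCL; a listener who never detects near MCL
    (no percept) yields a non-converged result.
    """
    if not 0.50 <= start_fraction_of_mcl <= 0.98:
        raise ValueError("start_fraction_of_mcl must lie in [0.50, 0.98]")
    mcl = listener.mcl_db(stimulus)
    if not np.isfinite(mcl):
        return StaircaseResult([], [], [], np.nan, False, 0)
    level = start_fraction_of_mcl * mcl
    step = initial_step_db
    levels: list = []
    responses: list = []
    reversals: list = []
    prev = None
    at_mcl_misses = 0
    for _ in range(max_trials):
        level = min(max(level, floor_db), mcl)
        r = detect(listener, stimulus, level, rng)
        levels.append(level)
        responses.append(r)
        if prev is not None and r != prev:
            reversals.append(level)
            if len(reversals) == 1:
                step = small_step_db
            if len(reversals) >= n_reversals:
                thr = float(np.mean(reversals[-n_mean_reversals:]))
                return StaircaseResult(levels, responses, reversals, thr, True, len(levels))
        if level >= mcl and not r:
            at_mcl_misses += 1
            if at_mcl_misses > max_consecutive_at_mcl:
                return StaircaseResult(levels, responses, reversals, np.nan, False, len(levels))
        else:
            at_mcl_misses = 0
        level += -step if r else step
        prev = r
    return StaircaseResult(levels, responses, reversals, np.nan, False, len(levels))


@dataclasses.dataclass
class ThresholdEstimate:
    threshold_db: float
    run_values: list
    n_runs: int
    missing_reason: str | None = None

    @property
    def is_missing(self) -> bool:
        return not np.isfinite(self.threshold_db)


def estimate_threshold_staircase(
    listener: ListenerModel,
    stimulus: StimulusSpec,
    rng: np.random.Generator,
    rerun_criterion_db: float = 1.0,
    staircase_fn=run_staircase,
    **staircase_kwargs,
) -> ThresholdEstimate:
    """Two-run threshold with the four-run fallback.

    Runs two tracks and averages them; if the first two estimates differ by
    ``rerun_criterion_db`` (1 dB) or more, two further tracks are run and all
    four are averaged.  Any non-converged track yields a missing estimate.
    ``staircase_fn`` is injectable so alternative track procedures (or test
    doubles) can reuse the run-combination rule.
    """
    runs = [staircase_fn(listener, stimulus, rng, **staircase_kwargs) for _ in range(2)]
    if any(not r.converged for r in runs):
        return ThresholdEstimate(np.nan, [r.threshold_db for r in runs], len(runs),
                                 missing_reason="non-converged track (no percept)")
    values = [r.threshold_db for r in runs]
    if abs(values[0] - values[1]) >= rerun_criterion_db:
        more = [staircase_fn(listener, stimulus, rng, **staircase_kwargs) for _ in range(2)]
        if any(not r.converged for r in more):
            return ThresholdEstimate(np.nan, values + [r.threshold_db for r in more], 4,
                                     missing_reason="non-converged track (no percept)")
        values += [r.threshold_db for r in more]
    return ThresholdEstimate(float(np.mean(values)), values, len(values))


@dataclasses.dataclass
class SweepResult:
    """Bekesy-sweep outcome: raw per-run trajectories, per-run channel
    estimates, and final integer-channel thresholds for channels 2..n-1."""

    trajectories: list  # one list of (channel, alpha, position, level, response) per run
    run_thresholds: np.ndarray  # (n_runs, n_channels) aligned with `channels`
    channels: np.ndarray
    thresholds_db: np.ndarray
    missing: np.ndarray  # bool per channel
    alpha_grid: np.ndarray = dataclasses.field(default_factory=lambda: ALPHA_GRID.copy())


def _run_positions(n_electrodes: int, forward: bool) -> list:
    """(channel-set, alpha) visit order for one run; two presentations each."""
    sets = range(3, n_electrodes)  # channel sets 3..n-1
    if forward:
        seq = [(c, a) for c in sets for a in ALPHA_GRID]
    else:
        seq = [(c, a) for c in reversed(sets) for a in ALPHA_GRID[::-1]]
    return seq


def run_sweep(
    listener: ListenerModel,
    rng: np.random.Generator,
    sigma: float = 0.9,
    n_forward: int = 2,
    n_reverse: int = 2,
    step_db: float = 1.0,
    start_below_mcl_db: float = 6.0,
    presentations_per_alpha: int = 2,
    floor_db: float = 0.0,
) -> SweepResult:
    """Sweep thresholds across the array.

    Forward runs traverse channels 2->n-1 (alpha 0->1 within each electrode
    set), reverse runs the mirror image.  The level starts 6 dB below the MCL
    of the first position, moves 1 dB down after a press (detection) and 1 dB
    up after a release, and is capped at the local MCL.  Per run, every
    press/release transition contributes a local threshold sample (mean of
    the two straddling levels at their mean array position); integer-channel
    thresholds are triangular-weighted averages (weight 1 - |position - c|)
    of those samples, then averaged across runs.  Channels with no transition
    sample in any run are flagged missing.
    """
    n = listener.ear.n_electrodes
    channels = np.arange(2, n)  # integer channels 2..n-1
    plans = [True] * n_forward + [False] * n_reverse
    trajectories = []
    run_estimates = np.full((len(plans), len(channels)), np.nan)

    for r_idx, forward in enumerate(plans):
        seq = _run_positions(n, forward)
        first_stim = sqp_stimulus(seq[0][0], seq[0][1], sigma)
        start_mcl = listener.mcl_db(first_stim)
        if not np.isfinite(start_mcl):
            finite = listener.ear.t_sqp_db + listener.ear.listener.dynamic_range_sqp_db
            finite = finite[np.isfinite(finite)]
            if finite.size == 0:
                trajectories.append([])
                continue
            start_mcl = float(np.median(finite))
        level = start_mcl - start_below_mcl_db
        track = []
        for c, a in seq:
            # set 3 at alpha 0 realizes "channel 2" (current centred on e2)
            stim = sqp_stimulus(c, a, sigma)
            pos = (c - 1) + a
            mcl_here = listener.mcl_db(stim)
            cap = mcl_here if np.isfinite(mcl_here) else start_mcl
            for _ in range(presentations_per_alpha):
                level = min(max(level, floor_db), cap)
                resp = detect(listener, stim, level, rng)
                track.append((c, float(a), pos, level, resp))
                level += -step_db if resp else step_db
        trajectories.append(track)

        # press/release transitions -> local threshold samples
        sample_pos, sample_val = [], []
        for i in range(len(track) - 1):
            if track[i][4] != track[i + 1][4]:
                sample_pos.append(0.5 * (track[i][2] + track[i + 1][2]))
                sample_val.append(0.5 * (track[i][3] + track[i + 1][3]))
        sample_pos = np.asarray(sample_pos)
        sample_val = np.asarray(sample_val)
        for k_idx, k in enumerate(channels):
            if sample_pos.size == 0:
                continue
            w = np.clip(1.0 - np.abs(sample_pos - k), 0.0, None)
            if w.sum() > 1e-12:
                run_estimates[r_idx, k_idx] = float(np.average(sample_val, weights=w))

    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        finals = np.nanmean(run_estimates, axis=0)
    missing = ~np.isfinite(finals)
    return SweepResult(
        trajectories=trajectories,
        run_thresholds=run_estimates,
        channels=channels,
        thresholds_db=finals,
        missing=missing,
    )
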