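"""Seeded synthetic rat atrial-electrophysiology generator.

Emulates the recordings the analysis pipeline expects: ambulatory rat sinus
rhythm (RR around 168–182 ms) on one atrial bipolar channel plus three
surface-ECG leads at 2 kHz, 1-s 100-Hz induction bursts with their possible
post-burst outcomes (sinus resumption, regular SVT with stable cycle length
above 60 ms, AF with irregular intervals below 55 ms), ventricular far-field
mixing into the atrial channel, a rule-based sinoatrial/atrioventricular
node responding to programmed stimulation, and whole repeated-measures
cohorts with the study's group structure.

Morphologies are analytic bumps: Gaussian humps for P and T waves, Gaussian
first derivatives (biphasic wavelets) for the QRS, the atrial bipolar
deflection and the ventricular far-field.  AF activation times follow a
Gamma renewal process (configurable mean interval and coefficient of
variation, intervals below 15 ms rejected as physiologically impossible),
which yields irregular, band-limited activity with a dominant frequency of
about 1000/mean_interval Hz.  All randomness flows from a single seed
through :class:`numpy.random.Generator` spawning.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .recording import ATRIAL, ECG1, ECG2, ECG3, Recording

__all__ = [
    "SignalModelParams",
    "OutcomeSpec",
    "NodeModelParams",
    "CohortDesign",
    "BurstTrial",
    "StimulationSchedule",
    "ResponseLog",
    "generate_sinus_recording",
    "generate_burst_trial",
    "simulate_programmed_stimulation",
    "render_response",
    "generate_cohort",
    "s1s2_schedule",
    "decremental_schedule",
    "snrt_schedule",
]


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Wave:
    """Analytic bump descriptor: peak amplitude (mV) and full width (ms)."""
    amplitude: float
    width: float


@dataclass(frozen=True)
class SignalModelParams:
    """Morphology and timing parameters of the signal generator.

    Defaults emulate an adult male rat: sinus cycle length 182.2 ms,
    PR interval near 50 ms, sharp ~1 mV atrial bipolar deflections, and a
    ventricular far-field leaking into the atrial channel at 35% of the
    deflection amplitude with ±10% per-beat gain jitter (so template
    cancellation is exercised beyond the trivial exact case).  Additive
    noise is band-limited to 200 Hz; a small 1.5-Hz respiratory baseline
    wander rides on the atrial channel.  During AF episodes the electrogram
    is fractionated: per-activation amplitude/width variability, occasional
    double potentials and continuous low-amplitude fibrillatory (f-wave)
    activity between activations.
    """

    sinus_cl: float = 182.2            # ms
    sinus_cl_jitter_sd: float = 1.0    # ms, beat-to-beat
    pr_interval: float = 50.0          # ms, P onset to R peak
    p_wave: Wave = Wave(0.15, 14.0)
    qrs: Wave = Wave(1.0, 12.0)
    t_wave: Wave = Wave(0.22, 30.0)
    atrial_amplitude: float = 1.0      # mV
    atrial_deflection_width: float = 4.0  # ms
    ventricular_farfield_gain: float = 0.35  # fraction of atrial amplitude
    farfield_width: float = 22.0       # ms
    farfield_jitter: float = 0.10      # per-beat uniform gain jitter
    noise_sd: float = 0.03             # mV
    noise_bandwidth: float = 200.0     # Hz low-pass on the additive noise
    # fractionated AF electrogram morphology (AF episodes only)
    af_amp_cv: float = 0.30            # lognormal amplitude CV per activation
    af_width_jitter: tuple = (0.7, 1.6)  # uniform width scale per activation
    af_fractionation_p: float = 0.35   # probability of a double potential
    af_fraction_offset_ms: tuple = (3.0, 6.0)  # secondary-spike delay range
    af_fibrillatory_amp: float = 0.12  # mV continuous f-wave activity in AF
    af_fibrillatory_band: tuple = (40.0, 250.0)  # Hz
    wander_amplitude: float = 0.05     # mV respiratory baseline wander
    wander_hz: float = 1.5
    stim_amplitude: float = 3.0        # mV burst-artifact peak
    sample_rate: float = 2000.0        # Hz
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.sinus_cl <= 0:
            raise ValueError("sinus_cl must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass(frozen=True)
class OutcomeSpec:
    """Ground-truth post-burst outcome of one induction burst.

    ``kind`` is one of ``sinus`` (immediate resumption), ``regular_svt``
    (stable cycle length > 60 ms), ``af`` (irregular intervals, mean < 55 ms)
    or ``indeterminate`` (stable rhythm inside the 55–60 ms definitional
    gap).
    """

    kind: str
    episode_duration: float = 0.0      # s
    svt_cl: float = 70.0               # ms, regular_svt / indeterminate
    svt_cv: float = 0.01               # fractional interval CV for svt
    af_mean_interval: float = 45.0     # ms
    af_interval_cv: float = 0.25       # fraction

    def __post_init__(self) -> None:
        if self.kind not in {"sinus", "regular_svt", "af", "indeterminate"}:
            raise ValueError(f"unknown outcome kind {self.kind!r}")
        if self.episode_duration < 0:
            raise ValueError("episode_duration must be >= 0")
        if self.kind == "regular_svt" and not self.svt_cl > 60:
            raise ValueError("regular_svt requires svt_cl > 60 ms")
        if self.kind == "af" and not self.af_mean_interval < 55:
            raise ValueError("af requires af_mean_interval < 55 ms")
        if self.kind == "sinus" and self.episode_duration != 0:
            raise ValueError("sinus outcome carries no episode")


@dataclass(frozen=True)
class NodeModelParams:
    """Rule-based SA/AV node response model.

    The atrial effective refractory period is flat across basic cycle
    lengths (the rat atrium shows essentially no ERP rate adaptation);
    premature (S2) AV conduction blocks below ``av_erp_base``.  Sustained
    pacing engages a decremental conduction-delay recurrence whose
    parameters are derived so that a descending constant-CL sweep produces
    Wenckebach periodicity at and below ``wenckebach_cl`` and strict 2:1
    conduction at and below ``two_to_one_cl`` (thresholds exact for sweep
    steps of 2 ms or more).  After at least 10 s of overdrive pacing the
    first spontaneous cycle is prolonged by ``snrt_suppression``.
    """

    atrial_erp: float = 28.0           # ms
    av_erp_base: float = 73.0          # ms, premature (S2) AV block threshold
    av_decrement_gain: float = 1.0     # ms delay per ms of recovery deficit
    snrt_suppression: float = 22.0     # ms added to first post-overdrive cycle
    wenckebach_cl: float = 90.0        # ms
    two_to_one_cl: float = 75.0        # ms
    sinus_cl: float = 182.2            # ms spontaneous cycle
    spontaneous_jitter_sd: float = 0.5  # ms on spontaneous cycles
    av_delay: float = 20.0             # ms baseline AV conduction time

    def __post_init__(self) -> None:
        if not self.two_to_one_cl < self.wenckebach_cl:
            raise ValueError("two_to_one_cl must be below wenckebach_cl")
        for name in ("atrial_erp", "av_erp_base", "wenckebach_cl",
                     "two_to_one_cl", "sinus_cl"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class BurstTrial:
    """One induction burst with its surrounding signal and ground truth."""

    recording: Recording
    burst_start_s: float
    burst_end_s: float
    outcome: OutcomeSpec
    truth_atrial_times: np.ndarray     # s, atrial activations (all segments)
    truth_qrs_times: np.ndarray        # s, ventricular beats
    episode_end_s: float               # = burst_end_s when no episode

    @property
    def truth_duration_s(self) -> float:
        return self.episode_end_s - self.burst_end_s


#: T-wave peak delay after the R peak (s): the rat T wave rides directly
#: on the QRS downstroke (rats have no isoelectric ST segment).
T_OFFSET_S = 0.030


# ---------------------------------------------------------------------------
# waveform primitives
# ---------------------------------------------------------------------------

def _add_bump(x: np.ndarray, fs: float, t_center: float, amp: float,
              width_ms: float, biphasic: bool = False) -> None:
    """Add a Gaussian (or Gaussian-derivative) bump in place."""
    sigma = width_ms / 4.0 / 1000.0          # width spans ~4 sigma
    half = int(round(3 * sigma * fs)) + 1
    c = int(round(t_center * fs))
    lo, hi = max(0, c - half), min(len(x), c + half + 1)
    if lo >= hi:
        return
    t = (np.arange(lo, hi) / fs) - t_center
    if biphasic:
        # first derivative of a Gaussian, normalized to peak amplitude
        w = -t / sigma * np.exp(0.5 - 0.5 * (t / sigma) ** 2)
    else:
        w = np.exp(-0.5 * (t / sigma) ** 2)
    x[lo:hi] += amp * w


def _add_square_biphasic(x: np.ndarray, fs: float, t_start: float,
                         amp: float, total_ms: float = 4.0) -> None:
    """Biphasic square stimulus artifact: half period each polarity."""
    n_half = max(1, int(round(total_ms / 2.0 / 1000.0 * fs)))
    i0 = int(round(t_start * fs))
    a, b = i0, min(len(x), i0 + n_half)
    c, d = b, min(len(x), i0 + 2 * n_half)
    if a < b:
        x[a:b] += amp
    if c < d:
        x[c:d] -= amp
    return


def _bandlimited_noise(rng: np.random.Generator, n: int, fs: float,
                       sd: float, bandwidth: float) -> np.ndarray:
    """Gaussian noise low-passed to ``bandwidth`` and rescaled to ``sd``."""
    if sd == 0 or n == 0:
        return np.zeros(n)
    w = rng.standard_normal(n)
    if bandwidth < fs / 2:
        b, a = sps.butter(4, bandwidth / (fs / 2), btype="low")
        w = sps.filtfilt(b, a, w)
    s = w.std()
    return w * (sd / s) if s > 0 else w


# ---------------------------------------------------------------------------
# event-time synthesis
# ---------------------------------------------------------------------------

def _sinus_beat_times(rng: np.random.Generator, params: SignalModelParams,
                      t_start: float, t_stop: float) -> np.ndarray:
    """Ventricular (R-peak) times of a jittered sinus train in [start, stop)."""
    times = []
    t = t_start
    while t < t_stop:
        times.append(t)
        t += (params.sinus_cl
              + rng.normal(0.0, params.sinus_cl_jitter_sd)) / 1000.0
    return np.asarray(times)


def _af_intervals(rng: np.random.Generator, mean_ms: float, cv: float,
                  total_ms: float, floor_ms: float = 15.0) -> np.ndarray:
    """Gamma-renewal AF intervals covering at least ``total_ms``."""
    shape = 1.0 / cv**2 if cv > 0 else np.inf
    out = []
    acc = 0.0
    while acc < total_ms:
        if np.isfinite(shape):
            iv = rng.gamma(shape, mean_ms / shape)
        else:
            iv = mean_ms
        if iv < floor_ms:
            continue   # reject physiologically impossible intervals
        out.append(iv)
        acc += iv
    return np.asarray(out)


# ---------------------------------------------------------------------------
# recording-level generators
# ---------------------------------------------------------------------------

def _render(params: SignalModelParams, n: int,
            atrial_times: np.ndarray, v_times: np.ndarray,
            stim_times: np.ndarray, rng: np.random.Generator,
            atrial_amps: np.ndarray | None = None,
            atrial_widths: np.ndarray | None = None,
            ) -> tuple[np.ndarray, list[str]]:
    """Render the four channels from event times.  Returns (signals, roles).

    ``atrial_amps`` / ``atrial_widths`` optionally give per-activation
    deflection morphology (fractionated AF); defaults are the nominal
    amplitude and width for every activation.
    """
    fs = params.sample_rate
    atrial = np.zeros(n)
    ecg = np.zeros(n)
    if atrial_amps is None:
        atrial_amps = np.full(len(atrial_times), params.atrial_amplitude)
    if atrial_widths is None:
        atrial_widths = np.full(len(atrial_times),
                                params.atrial_deflection_width)

    # ECG: P (tied to atrial activations), QRS and T (tied to ventricular)
    for ta in atrial_times:
        _add_bump(ecg, fs, ta + params.p_wave.width / 2 / 1000.0,
                  params.p_wave.amplitude, params.p_wave.width)
    ff_gains = 1.0 + params.farfield_jitter * rng.uniform(-1, 1, len(v_times))
    for tv, g in zip(v_times, ff_gains):
        _add_bump(ecg, fs, tv, params.qrs.amplitude, params.qrs.width,
                  biphasic=True)
        _add_bump(ecg, fs, tv + T_OFFSET_S, params.t_wave.amplitude,
                  params.t_wave.width)
        # ventricular far-field on the atrial channel: broader biphasic + T
        amp = params.atrial_amplitude * params.ventricular_farfield_gain * g
        _add_bump(atrial, fs, tv, amp, params.farfield_width, biphasic=True)
        _add_bump(atrial, fs, tv + T_OFFSET_S, 0.35 * amp,
                  params.t_wave.width)

    for ta, amp, wd in zip(atrial_times, atrial_amps, atrial_widths):
        _add_bump(atrial, fs, ta, amp, wd, biphasic=True)

    for ts in stim_times:
        _add_square_biphasic(atrial, fs, ts, params.stim_amplitude)
        _add_square_biphasic(ecg, fs, ts, 0.15 * params.stim_amplitude)

    t = np.arange(n) / fs
    wander_phase = rng.uniform(0, 2 * np.pi)
    wander = params.wander_amplitude * np.sin(
        2 * np.pi * params.wander_hz * t + wander_phase)
    atrial = atrial + wander + _bandlimited_noise(
        rng, n, fs, params.noise_sd, params.noise_bandwidth)
    ecg1 = ecg + 0.3 * wander + _bandlimited_noise(
        rng, n, fs, params.noise_sd, params.noise_bandwidth)
    ecg2 = 0.8 * ecg + _bandlimited_noise(
        rng, n, fs, params.noise_sd, params.noise_bandwidth)
    ecg3 = 0.6 * ecg + _bandlimited_noise(
        rng, n, fs, params.noise_sd, params.noise_bandwidth)
    return np.vstack([atrial, ecg1, ecg2, ecg3]), [ATRIAL, ECG1, ECG2, ECG3]


def _annotation_table(atrial_times, v_times, stim_times) -> pd.DataFrame:
    rows = ([(t, "atrial", "") for t in atrial_times]
            + [(t, "qrs", "") for t in v_times]
            + [(t, "stim", "") for t in stim_times])
    df = pd.DataFrame(rows, columns=["time_s", "kind", "label"])
    return df.sort_values("time_s", ignore_index=True)


def generate_sinus_recording(params: SignalModelParams,
                             duration: float) -> Recording:
    """Baseline sinus-rhythm recording with ground-truth beat annotations.

    The atrial channel carries the sharp atrial deflections plus the
    ventricular far-field scaled by ``ventricular_farfield_gain``; the three
    ECG leads carry P-QRS-T complexes.  Identical parameters (including the
    seed) give bit-identical sample arrays.

    Parameters
    ----------
    params : SignalModelParams
    duration : float
        Seconds; must be at least two sinus cycles.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if duration < 2 * params.sinus_cl / 1000.0:
        raise ValueError("duration must cover at least two sinus cycles")
    rng = np.random.default_rng(params.seed)
    fs = params.sample_rate
    n = int(round(duration * fs))
    v_times = _sinus_beat_times(rng, params, 0.060, duration - 0.02)
    atrial_times = v_times - params.pr_interval / 1000.0
    atrial_times = atrial_times[atrial_times > 0]
    sig, roles = _render(params, n, atrial_times, v_times,
                         np.array([]), rng)
    ann = _annotation_table(atrial_times, v_times, [])
    return Recording(sig, fs, roles, 0.0, ann)


def generate_burst_trial(params: SignalModelParams, outcome: OutcomeSpec,
                         pre_burst_s: float = 5.0, burst_s: float = 1.0,
                         burst_cl_ms: float = 10.0,
                         tail_s: float = 2.5) -> BurstTrial:
    """One induction-burst trial realizing a specified post-burst outcome.

    Layout: ``pre_burst_s`` of sinus rhythm, a 1-s burst of biphasic square
    stimulus artifacts at 10-ms cycle length, the post-burst episode
    required by ``outcome`` and a sinus tail.  Ventricular beats continue
    through burst and episode at an irregular conducted rate so that the
    far-field cancellation stage is exercised inside the analysis windows.
    """
    rng = np.random.default_rng(params.seed)
    fs = params.sample_rate
    burst_start = pre_burst_s
    burst_end = burst_start + burst_s
    episode_end = burst_end + outcome.episode_duration
    total = episode_end + tail_s
    n = int(round(total * fs))

    # ventricular beats: sinus pre-burst, irregular during burst + episode,
    # sinus again after episode end
    v_pre = _sinus_beat_times(rng, params, 0.060, burst_start)
    v_times = list(v_pre)
    t = v_pre[-1] if len(v_pre) else 0.06
    while t < episode_end:
        t += params.sinus_cl / 1000.0 * rng.uniform(0.8, 1.25)
        if t < episode_end:
            v_times.append(t)
    t_first_sinus = episode_end + params.sinus_cl / 1000.0 * rng.uniform(0.4, 0.7)
    v_post = _sinus_beat_times(rng, params, t_first_sinus, total - 0.02)
    v_times = np.asarray(v_times + list(v_post))

    # atrial activations
    a_pre = v_pre - params.pr_interval / 1000.0
    a_pre = a_pre[a_pre > 0]
    if outcome.kind == "af":
        ivs = _af_intervals(rng, outcome.af_mean_interval,
                            outcome.af_interval_cv,
                            outcome.episode_duration * 1000.0)
        a_ep = burst_end + np.cumsum(ivs) / 1000.0
        a_ep = a_ep[a_ep < episode_end]
    elif outcome.kind in ("regular_svt", "indeterminate"):
        ivs = []
        acc = 0.0
        while acc < outcome.episode_duration * 1000.0:
            iv = outcome.svt_cl * (1.0 + outcome.svt_cv * rng.standard_normal())
            ivs.append(iv)
            acc += iv
        a_ep = burst_end + np.cumsum(ivs) / 1000.0
        a_ep = a_ep[a_ep < episode_end]
    else:
        a_ep = np.array([])
    a_post = v_post - params.pr_interval / 1000.0
    atrial_times = np.concatenate([a_pre, a_ep, a_post])

    # per-activation morphology: nominal everywhere; fractionated (variable
    # amplitude/width, occasional double potentials) during AF episodes
    render_times = list(atrial_times)
    amps = [params.atrial_amplitude] * len(atrial_times)
    widths = [params.atrial_deflection_width] * len(atrial_times)
    if outcome.kind == "af" and len(a_ep):
        off = len(a_pre)
        for k in range(len(a_ep)):
            sd = np.sqrt(np.log(1 + params.af_amp_cv**2))
            amps[off + k] = params.atrial_amplitude * rng.lognormal(
                -0.5 * sd**2, sd)
            widths[off + k] = params.atrial_deflection_width * rng.uniform(
                *params.af_width_jitter)
            if rng.random() < params.af_fractionation_p:
                lo, hi = params.af_fraction_offset_ms
                render_times.append(a_ep[k] + rng.uniform(lo, hi) / 1000.0)
                amps.append(0.5 * amps[off + k])
                widths.append(widths[off + k])
    order = np.argsort(render_times)
    render_times = np.asarray(render_times)[order]
    amps = np.asarray(amps)[order]
    widths = np.asarray(widths)[order]

    stim_times = burst_start + np.arange(
        int(round(burst_s * 1000.0 / burst_cl_ms))) * burst_cl_ms / 1000.0

    sig, roles = _render(params, n, render_times, v_times, stim_times, rng,
                         atrial_amps=amps, atrial_widths=widths)

    # continuous fibrillatory (f-wave) activity on the atrial channel during
    # the AF episode: band-limited stochastic activity between the discrete
    # activation spikes, tapered at the episode edges
    if outcome.kind == "af" and params.af_fibrillatory_amp > 0 \
            and outcome.episode_duration > 0:
        i_ep0, i_ep1 = int(round(burst_end * fs)), int(round(episode_end * fs))
        m = i_ep1 - i_ep0
        if m > 50:
            w = rng.standard_normal(m)
            lo, hi = params.af_fibrillatory_band
            b, a = sps.butter(2, [lo / (fs / 2), min(hi, 0.49 * fs) / (fs / 2)],
                              btype="band")
            w = sps.filtfilt(b, a, w)
            w *= params.af_fibrillatory_amp / max(w.std(), 1e-12)
            ramp = min(int(0.05 * fs), m // 4)
            env = np.ones(m)
            env[:ramp] = np.linspace(0, 1, ramp)
            env[-ramp:] = np.linspace(1, 0, ramp)
            sig[0, i_ep0:i_ep1] += w * env
    ann = _annotation_table(atrial_times, v_times, stim_times)
    rec = Recording(sig, fs, roles, 0.0, ann)
    return BurstTrial(rec, burst_start, burst_end, outcome,
                      atrial_times, v_times, episode_end)


# ---------------------------------------------------------------------------
# programmed stimulation
# ---------------------------------------------------------------------------

@dataclass
class StimulationSchedule:
    """Stimulus pulse table: ``time_s``, ``type`` (S1/S2/burst), ``basic_cl_ms``.

    Pulse times must be strictly increasing with at least a pulse width
    (4 ms) between consecutive pulses.
    """

    pulses: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.pulses["time_s"].to_numpy(float)
        if len(t) and np.any(np.diff(t) < 0.004):
            raise ValueError("overlapping or non-increasing stimulus pulses")


def s1s2_schedule(basic_cl_ms: float, s2_coupling_ms: float,
                  n_s1: int = 10, t_start: float = 0.5) -> StimulationSchedule:
    """S1 drive train (``n_s1`` pulses) followed by one premature S2."""
    t_s1 = t_start + np.arange(n_s1) * basic_cl_ms / 1000.0
    t_s2 = t_s1[-1] + s2_coupling_ms / 1000.0
    df = pd.DataFrame({
        "time_s": np.append(t_s1, t_s2),
        "type": ["S1"] * n_s1 + ["S2"],
        "basic_cl_ms": basic_cl_ms,
        "coupling_ms": [basic_cl_ms] * n_s1 + [s2_coupling_ms],
    })
    return StimulationSchedule(df)


def decremental_schedule(cls_ms, dwell_s: float = 5.0,
                         t_start: float = 0.5,
                         gap_s: float = 1.0) -> StimulationSchedule:
    """Constant-CL trains at each cycle length in ``cls_ms`` (descending)."""
    rows = []
    t = t_start
    for cl in cls_ms:
        n_p = int(round(dwell_s * 1000.0 / cl))
        for _ in range(n_p):
            rows.append((t, "burst", cl, cl))
            t += cl / 1000.0
        t += gap_s
    df = pd.DataFrame(rows, columns=["time_s", "type", "basic_cl_ms",
                                     "coupling_ms"])
    return StimulationSchedule(df)


def snrt_schedule(n_bursts: int = 3, burst_s: float = 30.0,
                  cl_ms: float = 120.0, pause_s: float = 30.0,
                  t_start: float = 0.5) -> StimulationSchedule:
    """Overdrive bursts for sinus-node recovery time (30 s at 120 ms CL)."""
    rows = []
    t = t_start
    for _ in range(n_bursts):
        n_p = int(round(burst_s * 1000.0 / cl_ms))
        for _ in range(n_p):
            rows.append((t, "burst", cl_ms, cl_ms))
            t += cl_ms / 1000.0
        t += pause_s
    df = pd.DataFrame(rows, columns=["time_s", "type", "basic_cl_ms",
                                     "coupling_ms"])
    return StimulationSchedule(df)


@dataclass
class ResponseLog:
    """Per-event response log of the node simulator.

    ``events`` columns: ``time_s``, ``type`` (S1/S2/burst/spontaneous),
    ``basic_cl_ms``, ``coupling_ms``, ``atrial_captured``,
    ``ventricular_conducted``, ``v_time_s`` (NaN when not conducted).
    """

    events: pd.DataFrame
    node: NodeModelParams


_EPS_MS = 1e-6   # float tolerance on millisecond comparisons


def simulate_programmed_stimulation(node: NodeModelParams,
                                    protocol: StimulationSchedule,
                                    seed: int | None = 0,
                                    tail_beats: int = 8) -> ResponseLog:
    """Rule-based SA/AV node response to a programmed stimulation schedule.

    Atrial capture requires the interval from the previous atrial activation
    to reach ``atrial_erp`` (flat across basic CLs).  Premature S2 pulses
    conduct to the ventricle when their coupling reaches ``av_erp_base``.
    Sustained trains engage a decremental delay recurrence which produces
    Wenckebach periodicity at and below ``wenckebach_cl`` and strict 2:1
    conduction at and below ``two_to_one_cl``.  Gaps longer than two sinus
    cycles are filled with spontaneous beats; the first spontaneous cycle
    after at least 10 s of uninterrupted pacing is prolonged by
    ``snrt_suppression``.
    """
    rng = np.random.default_rng(seed)
    # decremental-model constants derived from the configured block CLs
    # (thresholds exact for descending sweeps with step >= 2 ms)
    d0 = node.av_delay
    theta = node.wenckebach_cl + 1.0 - d0      # recovery below which delay grows
    erp_rec = node.two_to_one_cl + 1.0 - d0    # recovery below which V blocks
    g = node.av_decrement_gain

    pulses = protocol.pulses.reset_index(drop=True)
    rows = []
    last_a: float | None = None       # last atrial activation (s)
    last_v: float | None = None       # last ventricular activation (s)
    paced_run_start: float | None = None
    last_pulse_t: float | None = None

    def spontaneous_cycle() -> float:
        return (node.sinus_cl
                + rng.normal(0.0, node.spontaneous_jitter_sd)) / 1000.0

    def emit_spontaneous(until: float, after_overdrive_s: float) -> None:
        """Fill [last_a, until) with spontaneous sinus beats."""
        nonlocal last_a, last_v
        if last_a is None:
            t = 0.0
        else:
            first = spontaneous_cycle()
            if after_overdrive_s >= 10.0:
                first += node.snrt_suppression / 1000.0
            t = last_a + first
        while t < until:
            v_t = t + d0 / 1000.0
            rows.append((t, "spontaneous", np.nan, np.nan, True, True, v_t))
            last_a, last_v = t, v_t
            t = t + spontaneous_cycle()

    for _, p in pulses.iterrows():
        t = float(p["time_s"])
        # spontaneous activity in long gaps before this pulse
        run_s = 0.0
        if last_pulse_t is not None and paced_run_start is not None:
            run_s = last_pulse_t - paced_run_start
        if last_pulse_t is None or t - last_pulse_t > 2.5 * node.sinus_cl / 1000.0:
            emit_spontaneous(t - node.atrial_erp / 1000.0, run_s)
            paced_run_start = t
        elif paced_run_start is None:
            paced_run_start = t

        coupling = np.inf if last_a is None else (t - last_a) * 1000.0
        captured = coupling > node.atrial_erp + _EPS_MS  # ERP interval itself fails
        conducted = False
        v_t = np.nan
        if captured:
            if p["type"] == "S2":
                conducted = coupling > node.av_erp_base + _EPS_MS
                if conducted:
                    v_t = t + d0 / 1000.0
            else:
                recovery = np.inf if last_v is None else (t - last_v) * 1000.0
                if recovery >= theta:
                    conducted, v_t = True, t + d0 / 1000.0
                elif recovery >= erp_rec:
                    delay = d0 + g * (theta - recovery)
                    conducted, v_t = True, t + delay / 1000.0
            last_a = t
            if conducted:
                last_v = v_t
        rows.append((t, p["type"], float(p["basic_cl_ms"]),
                     float(p["coupling_ms"]) if captured or True else np.nan,
                     captured, conducted, v_t))
        last_pulse_t = t

    run_s = 0.0
    if last_pulse_t is not None and paced_run_start is not None:
        run_s = last_pulse_t - paced_run_start
    tail_until = (last_a or 0.0) + (tail_beats + 1) * node.sinus_cl / 1000.0
    emit_spontaneous(tail_until, run_s)

    df = pd.DataFrame(rows, columns=[
        "time_s", "type", "basic_cl_ms", "coupling_ms",
        "atrial_captured", "ventricular_conducted", "v_time_s"])
    df = df.sort_values("time_s", ignore_index=True)
    return ResponseLog(df, node)


def render_response(log: ResponseLog, params: SignalModelParams,
                    capture_latency_ms: float = 6.0,
                    pad_s: float = 0.3) -> Recording:
    """Render a :class:`ResponseLog` as a signal-level :class:`Recording`.

    Stimulus artifacts appear at every pulse time; captured pulses add an
    atrial deflection ``capture_latency_ms`` later; conducted beats add
    QRS-T complexes and ventricular far-field at their conduction times.
    """
    rng = np.random.default_rng(params.seed)
    ev = log.events
    t_end = float(ev["time_s"].max()) + pad_s
    n = int(round(t_end * params.sample_rate))
    stim = ev.loc[ev["type"] != "spontaneous", "time_s"].to_numpy(float)
    cap = ev["atrial_captured"].to_numpy(bool)
    a_times = ev.loc[cap, "time_s"].to_numpy(float)
    is_stim = (ev["type"] != "spontaneous").to_numpy()
    a_times = a_times + np.where(is_stim[cap], capture_latency_ms / 1000.0, 0.0)
    v_times = ev.loc[ev["ventricular_conducted"].astype(bool),
                     "v_time_s"].to_numpy(float)
    sig, roles = _render(params, n, a_times, v_times, stim, rng)
    ann = _annotation_table(a_times, v_times, stim)
    return Recording(sig, params.sample_rate, roles, 0.0, ann)


# ---------------------------------------------------------------------------
# cohort generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParameterModel:
    """Distribution of one EP parameter across the cohort.

    ``mean``/``between_sd`` per sex; ``within_sd`` is the residual spread of
    repeated measurements within an animal; ``shifts[condition][sex]`` are
    additive condition effects relative to the unanesthetized state.
    """

    mean: dict
    between_sd: dict
    within_sd: float
    shifts: dict = field(default_factory=dict)

    def shift(self, condition: str, sex: str) -> float:
        return self.shifts.get(condition, {}).get(sex, 0.0)


def _table1_defaults() -> dict:
    """Cohort parameter models anchored to the study's UAS group statistics.

    Between-animal SDs are SEM-matched (sd = sem * sqrt(n), n = 13 males /
    16 females).  Condition shifts follow the reported directions: PEN slows
    the sinus rate in both sexes, ISO prolongs CSNRT in males only, both
    anesthetics prolong AERP in both sexes and reduce the AF dominant
    frequency.
    """
    def sem(m, f):
        return {"male": m * np.sqrt(13), "female": f * np.sqrt(16)}

    return {
        "rr": ParameterModel({"male": 182.2, "female": 168.6},
                             sem(4.21, 3.48), 4.0,
                             {"PEN": {"male": 14.0, "female": 14.0}}),
        "pr": ParameterModel({"male": 49.96, "female": 46.99},
                             sem(1.15, 0.90), 1.0,
                             {"ISO": {"female": 2.0},
                              "PEN": {"female": 2.5}}),
        "csnrt": ParameterModel({"male": 20.29, "female": 23.15},
                                sem(1.87, 1.69), 2.0,
                                {"ISO": {"male": 8.0}}),
        "aerp_120": ParameterModel({"male": 26.11, "female": 30.40},
                                   sem(1.26, 1.59), 1.5,
                                   {"ISO": {"male": 6.0, "female": 4.0},
                                    "PEN": {"male": 4.0, "female": 4.0}}),
        "averp_120": ParameterModel({"male": 73.38, "female": 72.25},
                                    sem(1.06, 1.73), 1.5,
                                    {"ISO": {"male": 5.0},
                                     "PEN": {"male": 7.0, "female": 6.0}}),
        "wenckebach": ParameterModel({"male": 90.83, "female": 82.5},
                                     sem(2.03, 1.34), 2.0,
                                     {"ISO": {"male": 8.0, "female": 4.0},
                                      "PEN": {"male": 6.0, "female": 5.0}}),
        "mean_cr": ParameterModel({"male": 1.22, "female": 1.10},
                                  sem(0.03, 0.02), 0.02,
                                  {"ISO": {"male": -0.08},
                                   "PEN": {"male": -0.07}}),
    }


@dataclass(frozen=True)
class CohortDesign:
    """Repeated-measures cohort layout: per-sex n, three within-animal
    conditions, per-parameter distributions and AF-substrate models."""

    n_male: int = 13
    n_female: int = 16
    conditions: tuple = ("UAS", "ISO", "PEN")
    parameters: dict = field(default_factory=_table1_defaults)
    n_bursts: int = 20
    af_induction_p: dict = field(default_factory=lambda: {
        "UAS": {"male": 0.3077, "female": 0.0969},
        "ISO": {"male": 0.10, "female": 0.08},
        "PEN": {"male": 0.20, "female": 0.09},
    })
    # right-skewed episode durations: lognormal(mu, sigma) in seconds
    af_duration_lognorm: dict = field(default_factory=lambda: {
        "male": (2.2, 1.4), "female": (1.2, 0.9)})

    def __post_init__(self) -> None:
        if self.n_male < 2 or self.n_female < 2:
            raise ValueError("cohort design requires n >= 2 per group")


def generate_cohort(design: CohortDesign, seed: int = 0) -> pd.DataFrame:
    """Per-animal, per-condition study results with repeated-measures
    structure (animal-level random effects shared across conditions).

    Returns a tidy DataFrame with columns ``animal_id, sex, condition,
    parameter, value``; AF substrate appears as the parameters
    ``af_induction_pct`` (binomial over ``n_bursts``) and
    ``af_duration`` (mean of lognormal episode durations, 0 if none).
    """
    rng = np.random.default_rng(seed)
    rows = []
    animal = 0
    for sex, n_sex in (("male", design.n_male), ("female", design.n_female)):
        for _ in range(n_sex):
            animal += 1
            aid = f"{sex[0]}{animal:03d}"
            effects = {name: rng.normal(0.0, pm.between_sd[sex])
                       for name, pm in design.parameters.items()}
            for cond in design.conditions:
                for name, pm in design.parameters.items():
                    val = (pm.mean[sex] + effects[name]
                           + pm.shift(cond, sex)
                           + rng.normal(0.0, pm.within_sd))
                    rows.append((aid, sex, cond, name, val))
                p_ind = design.af_induction_p[cond][sex]
                k = rng.binomial(design.n_bursts, p_ind)
                rows.append((aid, sex, cond, "af_induction_pct",
                             100.0 * k / design.n_bursts))
                mu, sg = design.af_duration_lognorm[sex]
                dur = float(np.mean(rng.lognormal(mu, sg, k))) if k else 0.0
                rows.append((aid, sex, cond, "af_duration", dur))
    return pd.DataFrame(rows, columns=["animal_id", "sex", "condition",
                                       "parameter", "value"])
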