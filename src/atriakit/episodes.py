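"""Post-burst arrhythmia detection, AF/SVT classification and session metrics.

Episode rules: a positive arrhythmic event lasts more than 1 s after the
pacing burst.  AF is an irregular rhythm whose main repeating interval
(operationalized as the median activation interval) is below 55 ms; a
regular SVT has a stable cycle length (interval CV at or below 5% by
default) above 60 ms.  Stable rhythms inside the 55–60 ms definitional gap
are reported as indeterminate rather than silently merged into either
class.  Sessions comprise 20 induction bursts; AF and regular SVT are
tallied separately.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = ["Episode", "SubstrateSummary", "detect_activations",
           "detect_episode", "classify_episode", "summarize_session",
           "schedule_next_burst", "STABILITY_CV"]

#: Fractional interval CV at or below which a rhythm counts as "stable".
STABILITY_CV = 0.05

AF_INTERVAL_MS = 55.0
SVT_INTERVAL_MS = 60.0
MIN_EPISODE_S = 1.0


@dataclass
class Episode:
    """One detected post-burst event (times relative to burst offset)."""

    start: float
    end: float
    klass: str                      # af / regular_svt / indeterminate / none
    activation_intervals: np.ndarray = field(
        default_factory=lambda: np.array([]))

    @property
    def duration(self) -> float:
        return self.end - self.start

    @property
    def median_interval_ms(self) -> float:
        iv = self.activation_intervals
        return float(np.median(iv)) if len(iv) else np.nan

    @property
    def interval_cv(self) -> float:
        iv = self.activation_intervals
        if len(iv) < 2 or np.mean(iv) == 0:
            return np.nan
        return float(np.std(iv) / np.mean(iv))


@dataclass
class SubstrateSummary:
    """Per-session substrate metrics over the 20-burst induction protocol."""

    af_induction_pct: float
    af_mean_duration: float
    svt_induction_pct: float
    svt_mean_duration: float
    n_bursts: int
    no_af_flag: bool = False
    no_svt_flag: bool = False


def detect_activations(clean_atrial: np.ndarray, sample_rate: float,
                       refractory_ms: float = 15.0,
                       threshold_frac: float = 0.35) -> np.ndarray:
    """Atrial activation times from adaptive-threshold peak detection.

    Peaks of the absolute cleaned signal above ``threshold_frac`` of a
    robust amplitude reference (median of the strongest peaks), separated
    by at least the 15-ms atrial refractory floor.  Returns times in
    seconds from the start of the segment; a quiescent signal yields an
    empty array.
    """
    x = np.abs(np.asarray(clean_atrial, float))
    if x.size == 0 or np.ptp(x) == 0:
        return np.array([])
    dist = max(1, int(round(refractory_ms / 1000.0 * sample_rate)))
    cand, _ = sps.find_peaks(x, distance=dist)
    if len(cand) == 0:
        return np.array([])
    n_top = max(3, int(x.size / sample_rate * 5))
    top = np.sort(x[cand])[-n_top:]
    thr = threshold_frac * np.median(top)
    noise_floor = 5.0 * np.median(x) / 0.6745
    thr = max(thr, 0.5 * noise_floor)
    keep = cand[x[cand] >= thr]
    return keep / sample_rate


def detect_episode(activations: np.ndarray, sinus_cl_ms: float,
                   sinus_tol: float = 0.2,
                   n_sinus_beats: int = 3) -> Episode:
    """Delimit the post-burst episode from activation times.

    The episode runs from the burst offset (t = 0 of ``activations``) until
    the rhythm reverts to sinus: the first activation opening a run of
    ``n_sinus_beats`` consecutive intervals within ±``sinus_tol`` of the
    pre-burst sinus cycle length.  Events of 1 s or less classify as
    ``none`` (no positive arrhythmic event).
    """
    act = np.sort(np.asarray(activations, float))
    if len(act) < 2:
        return Episode(0.0, 0.0, "none")
    iv = np.diff(act) * 1000.0
    sinus_like = np.abs(iv - sinus_cl_ms) <= sinus_tol * sinus_cl_ms
    end_idx = len(act) - 1
    run = 0
    for i, s in enumerate(sinus_like):
        run = run + 1 if s else 0
        if run >= n_sinus_beats:
            end_idx = i - n_sinus_beats + 1  # first activation of the run
            break
    end_t = act[end_idx]
    # drop the terminal transition interval (last tachy beat -> first sinus
    # beat): it belongs to neither rhythm and would inflate the interval CV
    ep_iv = iv[: max(0, end_idx - 1)]
    if end_t <= MIN_EPISODE_S:
        return Episode(0.0, end_t, "none", ep_iv)
    ep = Episode(0.0, end_t, "unclassified", ep_iv)
    ep.klass = classify_episode(ep)
    return ep


def classify_episode(ep: Episode) -> str:
    """AF / regular-SVT / indeterminate call by the interval rules.

    AF: median interval < 55 ms, or an unstable rhythm (CV above the
    stability tolerance) with median < 60 ms.  Regular SVT: stable rhythm
    with median > 60 ms.  Anything else (including stable rhythms in the
    55–60 ms gap, or fewer than 10 measurable intervals) is indeterminate.
    """
    if ep.duration <= MIN_EPISODE_S:
        return "none"
    iv = ep.activation_intervals
    if len(iv) < 10:
        warnings.warn("fewer than 10 activation intervals: indeterminate",
                      stacklevel=2)
        return "indeterminate"
    med = float(np.median(iv))
    # robust CV: detection dropouts (merged intervals) and double counts
    # (split intervals) land far from the median and are excluded before
    # the stability measure is taken
    core = iv[(iv > 0.5 * med) & (iv < 1.5 * med)]
    cv = float(np.std(core) / np.mean(core)) if len(core) >= 5 \
        else float(np.std(iv) / np.mean(iv))
    if med < AF_INTERVAL_MS or (cv > STABILITY_CV and med < SVT_INTERVAL_MS):
        return "af"
    if cv <= STABILITY_CV and med > SVT_INTERVAL_MS:
        return "regular_svt"
    return "indeterminate"


def summarize_session(episodes: list[Episode], n_bursts: int = 20,
                      allow_partial: bool = False) -> SubstrateSummary:
    """Session-level induction percentages and mean durations.

    AF and regular SVT are tallied separately; a class with zero induced
    bursts reports duration 0 with an explicit flag.
    """
    if len(episodes) != n_bursts and not allow_partial:
        raise ValueError(
            f"expected one episode per burst ({n_bursts}), got {len(episodes)}")
    n = len(episodes)
    af = [e for e in episodes if e.klass == "af"]
    svt = [e for e in episodes if e.klass == "regular_svt"]
    return SubstrateSummary(
        af_induction_pct=100.0 * len(af) / n,
        af_mean_duration=float(np.mean([e.duration for e in af])) if af else 0.0,
        svt_induction_pct=100.0 * len(svt) / n,
        svt_mean_duration=float(np.mean([e.duration for e in svt])) if svt else 0.0,
        n_bursts=n,
        no_af_flag=not af,
        no_svt_flag=not svt,
    )


def schedule_next_burst(prev: Episode,
                        elapsed_s: float | None = None) -> dict:
    """Inter-burst scheduling rule of the induction protocol.

    The next burst waits at least 60 s from the end of the previous event;
    after an episode longer than 60 s the wait equals that episode's
    duration.  An ongoing episode exceeding 240 s is aborted (by pacing
    bursts of increasing intensity, outside this package's scope).
    """
    ongoing = elapsed_s if elapsed_s is not None else prev.duration
    return {
        "wait_s": max(60.0, prev.duration if prev.duration > 60.0 else 0.0),
        "abort_action": bool(ongoing > 240.0),
    }
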