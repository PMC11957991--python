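"""End-to-end burst-trial analysis chain.

Glues the stages together the way a study session is processed: condition
the raw recording, detect QRS on the reference ECG lead, sample and
subtract the ventricular far-field template from the atrial channel, then
compute the complexity-ratio series, the rule-based episode classification
and (for AF windows) the envelope dominant frequency.  No ground truth is
consumed anywhere: the sinus cycle length is estimated from the pre-burst
beats and the burst boundaries come from the stimulation log.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cancellation import sample_template, subtract_template
from .complexity import (ARRHYTHMIC_CR_THRESHOLD, CRWindowSeries,
                         compute_cr_series)
from .episodes import Episode, detect_activations, detect_episode
from .preprocess import condition_signal, detect_qrs
from .recording import ATRIAL, BeatAnnotations
from .spectral import power_spectrum
from .synth import BurstTrial

__all__ = ["TrialAnalysis", "analyze_burst_trial"]


@dataclass
class TrialAnalysis:
    """Everything the analysis derives from one burst trial."""

    cr: CRWindowSeries
    episode: Episode
    beats: BeatAnnotations
    clean_atrial: np.ndarray
    sinus_cl_ms: float
    dominant_freqs: list          # per within-episode 1-s window (envelope)

    @property
    def cr_af_call(self) -> bool:
        """CR-flag-based AF call: any window above the arrhythmic cutoff."""
        return bool(np.any(self.cr.arrhythmic_flags))


def analyze_burst_trial(trial: BurstTrial,
                        threshold: float = ARRHYTHMIC_CR_THRESHOLD,
                        qrs_channel: str = "ecg_1",
                        compute_df: bool = False) -> TrialAnalysis:
    """Run the full analysis chain on one induction-burst trial."""
    rec = condition_signal(trial.recording)
    ann = detect_qrs(rec, qrs_channel)
    fs = rec.sample_rate
    atr = rec.channel(ATRIAL)

    pre_qrs = ann.qrs_times[ann.qrs_times < trial.burst_start_s - 0.06]
    tpl = sample_template(atr, pre_qrs, fs)
    clean = subtract_template(atr, ann.qrs_times, tpl)

    i_b0 = rec.index_at(trial.burst_start_s)
    i_b1 = rec.index_at(trial.burst_end_s)
    cr = compute_cr_series(clean[i_b1:], clean[:i_b0], fs,
                           threshold=threshold)

    sinus_cl_ms = float(np.mean(np.diff(pre_qrs)) * 1000.0)
    activations = detect_activations(clean[i_b1:], fs)
    episode = detect_episode(activations, sinus_cl_ms)

    dfs: list[float] = []
    if compute_df and episode.klass == "af":
        n_win = int(episode.duration)
        for w in range(n_win):
            seg = clean[i_b1 + int(w * fs): i_b1 + int((w + 1) * fs)]
            if len(seg) >= 0.5 * fs:
                dfs.append(power_spectrum(seg, fs, envelope=True)
                           .dominant_freq)
    return TrialAnalysis(cr, episode, ann, clean, sinus_cl_ms, dfs)
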