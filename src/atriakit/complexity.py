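"""Windowed Lempel–Ziv complexity-ratio (CR) quantification of atrial signals.

The CR statistic quantifies the irregularity of a post-burst atrial
electrogram relative to the pre-burst sinus rhythm of the same trace.  Each
cleaned 1-s post-burst window is symbolized to a binary string, its LZ76
production count is computed, and the ratio to the pre-burst reference
window's count is taken.  Values near 1 indicate sinus-like regularity;
values above the arrhythmic cutoff (1.236 by default, a calibration constant
of the recording system this statistic was developed on) flag irregular,
fibrillation-like activity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CRWindowSeries",
    "ARRHYTHMIC_CR_THRESHOLD",
    "binarize",
    "lz_complexity",
    "compute_cr_series",
    "summarize_cr",
]

#: Default cutoff above which a window's CR is called arrhythmic (AF-like).
ARRHYTHMIC_CR_THRESHOLD = 1.236


@dataclass
class CRWindowSeries:
    """Per-window complexity ratios for one post-burst trace.

    Attributes
    ----------
    window_s : float
        Window length in seconds (1.0 by convention).
    cr_values : np.ndarray
        One CR per consecutive, non-overlapping post-burst window.
    pre_burst_lz : float
        LZ76 production count of the pre-burst reference (mean over the
        reference windows when more than one is used).
    threshold : float
        Arrhythmic cutoff applied to ``cr_values``.
    arrhythmic_flags : np.ndarray
        Boolean per window, ``cr > threshold``.
    low_variance_windows : np.ndarray
        Indices of windows whose amplitude range was degenerate (flat).
    """

    window_s: float
    cr_values: np.ndarray
    pre_burst_lz: float
    threshold: float = ARRHYTHMIC_CR_THRESHOLD
    arrhythmic_flags: np.ndarray = field(default=None)  # type: ignore[assignment]
    low_variance_windows: np.ndarray = field(default_factory=lambda: np.array([], int))

    def __post_init__(self) -> None:
        self.cr_values = np.asarray(self.cr_values, float)
        if self.arrhythmic_flags is None:
            self.arrhythmic_flags = self.cr_values > self.threshold

    @property
    def n_windows(self) -> int:
        return len(self.cr_values)


def binarize(window: np.ndarray) -> str:
    """Symbolize one window by a per-window median split.

    Sample *i* maps to ``'1'`` iff it is strictly greater than the window
    median, which makes the symbolization invariant to amplitude scaling and
    offset.  A constant window maps to all zeros.

    Parameters
    ----------
    window : array-like
        Non-empty amplitude vector.

    Returns
    -------
    str
        Binary string of the same length as ``window``.
    """
    x = np.asarray(window, float)
    if x.size == 0:
        raise ValueError("binarize: window is empty")
    med = np.median(x)
    bits = x > med
    return "".join("1" if b else "0" for b in bits)


def is_low_variance(window: np.ndarray, rel_tol: float = 1e-12) -> bool:
    """True when the window is (numerically) constant."""
    x = np.asarray(window, float)
    span = np.ptp(x)
    scale = max(np.max(np.abs(x)), 1.0)
    return bool(span <= rel_tol * scale)


def lz_complexity(s: str) -> int:
    """LZ76 production count of a binary string (Kaspar–Schuster counting).

    The string is scanned left to right; a new production is counted each
    time the upcoming symbols cannot be reproduced by copying from the
    already-seen prefix.  ``lz_complexity("0001101001000101") == 6``.

    Parameters
    ----------
    s : str
        Non-empty string over the alphabet {'0', '1'}.

    Returns
    -------
    int
        Number of LZ76 components (>= 1).
    """
    if not s:
        raise ValueError("lz_complexity: empty string")
    if set(s) - {"0", "1"}:
        raise ValueError("lz_complexity: string must be binary")
    n = len(s)
    if n == 1:
        return 1
    c = 1
    l = 1  # noqa: E741 - standard symbol in the counting scheme
    i = 0
    k = 1
    k_max = 1
    while True:
        if s[i + k - 1] == s[l + k - 1]:
            k += 1
            if l + k > n:
                c += 1
                break
        else:
            k_max = max(k, k_max)
            i += 1
            if i == l:
                c += 1
                l += k_max
                if l + 1 > n:
                    break
                i = 0
                k = 1
                k_max = 1
            else:
                k = 1
    return c


def compute_cr_series(
    post_burst: np.ndarray,
    pre_burst: np.ndarray,
    sample_rate: float,
    window_s: float = 1.0,
    threshold: float = ARRHYTHMIC_CR_THRESHOLD,
    reference_windows: int = 1,
) -> CRWindowSeries:
    """Windowed complexity ratios of a cleaned post-burst atrial trace.

    The post-burst signal is divided into consecutive, non-overlapping
    ``window_s`` windows starting at the burst offset (a final partial window
    is dropped).  Each window's LZ76 count is normalized to the pre-burst
    reference of the same cleaned trace: by default the single ``window_s``
    window ending at burst onset; with ``reference_windows = k`` the mean
    LZ76 count of the last k pre-burst windows.

    Parameters
    ----------
    post_burst, pre_burst : array-like
        Cleaned (ventricular-far-field-subtracted) atrial signal segments.
    sample_rate : float
        Hz.
    window_s : float
        Analysis window, seconds.
    threshold : float
        Arrhythmic cutoff on the ratio.
    reference_windows : int
        Number of trailing pre-burst windows averaged into the reference.

    Returns
    -------
    CRWindowSeries
    """
    post = np.asarray(post_burst, float)
    pre = np.asarray(pre_burst, float)
    nwin = int(round(window_s * sample_rate))
    if reference_windows < 1:
        raise ValueError("reference_windows must be >= 1")
    if pre.size < nwin * reference_windows:
        raise ValueError(
            f"compute_cr_series: pre-burst segment shorter than "
            f"{reference_windows} window(s) "
            f"({pre.size} < {nwin * reference_windows} samples)"
        )
    ref_counts = [
        lz_complexity(binarize(pre[-(k + 1) * nwin: pre.size - k * nwin]))
        for k in range(reference_windows)
    ]
    ref_lz = float(np.mean(ref_counts))
    n_windows = post.size // nwin
    crs = np.empty(n_windows)
    low_var = []
    for i in range(n_windows):
        w = post[i * nwin : (i + 1) * nwin]
        if is_low_variance(w):
            low_var.append(i)
        crs[i] = lz_complexity(binarize(w)) / ref_lz
    return CRWindowSeries(
        window_s=window_s,
        cr_values=crs,
        pre_burst_lz=ref_lz,
        threshold=threshold,
        low_variance_windows=np.asarray(low_var, int),
    )


def summarize_cr(series_per_trial: list[CRWindowSeries]) -> dict:
    """Session-level CR summary over a set of burst trials.

    ``mean_cr`` averages, over trials, the mean CR of each trial's first five
    windows (fewer if the trial is shorter); ``arrhythmic_pct`` is the
    percentage of all post-burst windows in the session whose CR exceeds the
    arrhythmic threshold.

    Returns
    -------
    dict with keys ``mean_cr``, ``arrhythmic_pct``, ``n_windows``.
    """
    usable = [s for s in series_per_trial if s.n_windows >= 1]
    if not usable:
        raise ValueError("summarize_cr: no trial contributes any window")
    first5_means = [float(np.mean(s.cr_values[:5])) for s in usable]
    total = sum(s.n_windows for s in usable)
    flagged = sum(int(np.sum(s.arrhythmic_flags)) for s in usable)
    return {
        "mean_cr": float(np.mean(first5_means)),
        "arrhythmic_pct": 100.0 * flagged / total,
        "n_windows": total,
    }
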