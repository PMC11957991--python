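"""Power spectra and dominant-frequency extraction from cleaned AF windows.

Each window is Hann-tapered, zero-padded fourfold (for peak localization)
and Fourier transformed; power is scaled as a one-sided PSD so that its
integral matches the time-domain variance (Hann-corrected).  The dominant
frequency (DF) is the argmax of power over a physiological search band
(3–45 Hz by default, covering rat AF activation rates) minus a notch
exclusion band around 50 Hz, where the recording chain suppresses power.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft as spfft
from scipy import signal as sps

__all__ = ["Spectrum", "power_spectrum", "dominant_frequency",
           "average_spectra", "activation_envelope",
           "DEFAULT_DF_BAND", "DEFAULT_EXCLUDE_BAND"]

DEFAULT_DF_BAND = (3.0, 45.0)
DEFAULT_EXCLUDE_BAND = (48.0, 52.0)


@dataclass
class Spectrum:
    """One-sided power spectrum of a signal window."""

    freqs: np.ndarray          # Hz
    power: np.ndarray          # PSD units (mV^2/Hz), >= 0
    window_s: float
    sample_rate: float
    dominant_freq: float | None = None
    excluded_band: tuple = DEFAULT_EXCLUDE_BAND

    def __post_init__(self) -> None:
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")


#: Rat-scaled activation-envelope corners (Hz): band-pass edges and the
#: post-rectification low-pass.  The classic human settings (40-250 band,
#: 20 Hz low-pass) are scaled up for rat activation rates; the low-pass
#: corner equals the top of the dominant-frequency search band.
ENVELOPE_BAND = (40.0, 350.0)
ENVELOPE_LOWPASS = 45.0


def activation_envelope(window: np.ndarray, sample_rate: float) -> np.ndarray:
    """Botteron–Smith-style activation envelope of an atrial electrogram.

    Band-pass to the deflection energy band, rectify, low-pass: the result
    oscillates at the atrial activation rate, so its spectral peak sits at
    the activation frequency rather than at waveform harmonics.  This is
    the standard preprocessing for electrogram dominant-frequency analysis.
    """
    x = np.asarray(window, float)
    nyq = sample_rate / 2.0
    b, a = sps.butter(2, [ENVELOPE_BAND[0] / nyq,
                          min(ENVELOPE_BAND[1], 0.98 * nyq) / nyq], "band")
    y = np.abs(sps.filtfilt(b, a, x))
    b, a = sps.butter(2, ENVELOPE_LOWPASS / nyq, "low")
    return sps.filtfilt(b, a, y)


def power_spectrum(window: np.ndarray, sample_rate: float,
                   detrend: bool = True, pad_factor: int = 4,
                   envelope: bool = False) -> Spectrum:
    """Hann-tapered, zero-padded power spectrum of one cleaned window.

    Requires at least 0.5 s of signal.  The frequency grid spacing is
    ``1 / (pad_factor * window_s)`` Hz; total power integrates to the
    (Hann-corrected) time-domain variance.  With ``envelope=True`` the
    spectrum is taken on the activation envelope (the convention for
    electrogram dominant-frequency analysis); leave it off for raw
    waveform spectra.
    """
    x = np.asarray(window, float)
    fs = sample_rate
    if x.size < 0.5 * fs:
        raise ValueError("window shorter than 0.5 s")
    if envelope:
        x = activation_envelope(x, fs)
    if detrend:
        x = sps.detrend(x, type="linear")
    w = np.hanning(x.size)
    n_fft = pad_factor * x.size
    spec = spfft.rfft(x * w, n=n_fft)
    # one-sided PSD normalization with window power correction
    scale = 2.0 / (fs * np.sum(w**2))
    p = scale * np.abs(spec) ** 2
    p[0] /= 2.0
    if n_fft % 2 == 0:
        p[-1] /= 2.0
    freqs = spfft.rfftfreq(n_fft, d=1.0 / fs)
    sp = Spectrum(freqs, p, x.size / fs, fs)
    sp.dominant_freq = dominant_frequency(sp)
    return sp


def dominant_frequency(spec: Spectrum,
                       band: tuple[float, float] = DEFAULT_DF_BAND,
                       exclude: tuple[float, float] | None = None) -> float:
    """Argmax of power over ``band`` minus the notch exclusion sub-band.

    Ties break toward the lower frequency (argmax returns the first hit on
    an ascending grid).
    """
    if exclude is None:
        exclude = spec.excluded_band
    f = spec.freqs
    mask = (f >= band[0]) & (f <= band[1])
    if exclude is not None:
        mask &= ~((f >= exclude[0]) & (f <= exclude[1]))
    if not np.any(mask):
        raise ValueError("empty dominant-frequency search set")
    idx = np.nonzero(mask)[0]
    return float(f[idx[np.argmax(spec.power[idx])]])


def average_spectra(spectra: list[Spectrum]) -> Spectrum:
    """Pointwise mean power over same-grid spectra; DF recomputed on the mean."""
    if not spectra:
        raise ValueError("no spectra to average")
    f0 = spectra[0].freqs
    for s in spectra[1:]:
        if s.window_s != spectra[0].window_s or len(s.freqs) != len(f0) \
                or not np.allclose(s.freqs, f0):
            raise ValueError("spectra grids do not match")
    mean_p = np.mean([s.power for s in spectra], axis=0)
    out = Spectrum(f0.copy(), mean_p, spectra[0].window_s,
                   spectra[0].sample_rate,
                   excluded_band=spectra[0].excluded_band)
    out.dominant_freq = dominant_frequency(out)
    return out
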