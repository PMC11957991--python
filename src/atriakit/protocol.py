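"""Programmed-stimulation interpretation: ERPs, SNRT/CSNRT and AV block CLs.

Effective refractory periods are reported as the longest failing coupling
interval (standard EP convention, recorded in the result metadata): atrial
capture failure for the atrial ERP, atrial capture with ventricular
non-conduction for the AV-node ERP.  Values are confirmed over three
repeated sweeps.  The sinus-node recovery time follows 30-s overdrive
bursts at 120 ms basic CL applied three times; the corrected value
subtracts the spontaneous cycle length (mean of three consecutive
spontaneous cycles).  Dynamic AV properties come from a decremental
constant-CL sweep: the Wenckebach CL is the longest pacing CL showing at
least one dropped ventricular beat in an otherwise conducting train, the
2:1 CL the longest with strict conduct/drop alternation over at least six
stimuli.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .episodes import SubstrateSummary
from .synth import ResponseLog

__all__ = ["S1S2Sweep", "EPStudyResult", "detect_capture", "determine_erp",
           "confirm_erp", "compute_csnrt", "find_block_cls",
           "sweep_from_log"]

ERP_CONVENTION = "longest-failing-coupling"


@dataclass
class S1S2Sweep:
    """Outcome of one descending S1–S2 coupling sweep at a fixed basic CL."""

    basic_cl: float
    couplings: np.ndarray          # ms, strictly decreasing
    atrial_captured: np.ndarray    # bool per trial
    ventricular_conducted: np.ndarray
    step: float = 2.0

    def __post_init__(self) -> None:
        self.couplings = np.asarray(self.couplings, float)
        if np.any(np.diff(self.couplings) >= 0):
            raise ValueError("couplings must be strictly decreasing")
        if self.step <= 0:
            raise ValueError("step must be positive")
        self.atrial_captured = np.asarray(self.atrial_captured, bool)
        self.ventricular_conducted = np.asarray(self.ventricular_conducted, bool)


@dataclass
class EPStudyResult:
    """Per-animal, per-condition EP parameter set (one study-table row)."""

    rr: float | None = None
    pr: float | None = None
    csnrt: float | None = None
    aerp: dict = field(default_factory=dict)    # basic_cl -> ms
    averp: dict = field(default_factory=dict)   # basic_cl -> ms
    wenckebach_cl: float | None = None
    two_to_one_cl: float | None = None
    substrate: SubstrateSummary | None = None
    cr_summary: dict | None = None
    erp_convention: str = ERP_CONVENTION


def detect_capture(clean_atrial: np.ndarray, stimulus_times: np.ndarray,
                   sample_rate: float,
                   window_ms: tuple[float, float] = (2.0, 20.0),
                   threshold_frac: float = 0.4,
                   artifact_ms: float = 4.0) -> np.ndarray:
    """Per-stimulus atrial-capture flags from the cleaned atrial signal.

    A stimulus captured when an atrial deflection exceeding a robust
    amplitude threshold appears in the post-stimulus window.  The leading
    blanking interval covers the full biphasic pulse duration
    (``artifact_ms``, 4 ms by the stimulator's pulse shape) plus 1 ms of
    filter ringing, so the effective search starts at
    ``max(window_ms[0], artifact_ms + 1)``.  The threshold is
    ``threshold_frac`` of the largest response over all stimuli, floored
    above the noise level.
    """
    x = np.abs(np.asarray(clean_atrial, float))
    st = np.asarray(stimulus_times, float)
    n = len(x)
    start_ms = max(window_ms[0], artifact_ms + 1.0)
    lo_off = int(round(start_ms / 1000.0 * sample_rate))
    hi_off = int(round(window_ms[1] / 1000.0 * sample_rate))
    peaks = np.empty(len(st))
    for i, t in enumerate(st):
        c = int(round(t * sample_rate))
        if c < 0 or c >= n:
            raise ValueError(f"stimulus at {t:.4f}s outside signal span")
        a, b = min(n, c + lo_off), min(n, c + hi_off + 1)
        peaks[i] = x[a:b].max() if b > a else 0.0
    noise = np.median(x) / 0.6745
    thr = max(threshold_frac * peaks.max(), 5.0 * noise)
    return peaks >= thr


def determine_erp(sweep: S1S2Sweep, which: str = "atrial") -> float:
    """ERP from a descending S1–S2 sweep (longest failing coupling, ms).

    For ``which="atrial"`` a failure is loss of atrial capture; for
    ``which="av"`` it is atrial capture without ventricular conduction.
    The response pattern must be monotone (all successes at long couplings,
    all failures below); a non-monotone sweep raises, and a sweep with no
    failure reports the ERP as below the tested range.
    """
    if which == "atrial":
        success = sweep.atrial_captured
    elif which == "av":
        success = sweep.ventricular_conducted
        if np.any(~sweep.atrial_captured & success):
            raise ValueError("inconsistent sweep: conduction without capture")
        # only consider couplings where the atrium was captured
        keep = sweep.atrial_captured
        success = success[keep]
        couplings = sweep.couplings[keep]
        return _erp_from_pattern(couplings, success)
    else:
        raise ValueError(f"unknown ERP kind {which!r}")
    return _erp_from_pattern(sweep.couplings, success)


def _erp_from_pattern(couplings: np.ndarray, success: np.ndarray) -> float:
    fails = np.nonzero(~success)[0]
    if len(fails) == 0:
        raise ValueError("erp-below-range: no failure observed in the sweep")
    first_fail = fails[0]
    if np.any(success[first_fail:]):
        raise ValueError("inconsistent sweep: non-monotone response pattern")
    return float(couplings[first_fail])


def confirm_erp(values: list[float]) -> dict:
    """Three-fold ERP confirmation: common value, else flagged median."""
    if len(values) < 3:
        raise ValueError(f"need 3 ERP repeats, got {len(values)}")
    vals = np.asarray(values[:3], float)
    if np.all(vals == vals[0]):
        return {"erp": float(vals[0]), "confirmed": True}
    warnings.warn(f"ERP repeats not reproducible: {vals.tolist()}",
                  stacklevel=2)
    return {"erp": float(np.median(vals)), "confirmed": False}


def compute_csnrt(log: ResponseLog, min_overdrive_s: float = 10.0,
                  n_spont_cycles: int = 3) -> dict:
    """SNRT, spontaneous CL and corrected SNRT from an overdrive-burst log.

    For each overdrive run (a paced stretch of at least ``min_overdrive_s``),
    the SNRT is the interval from the last captured paced atrial beat to the
    first spontaneous atrial activation; the spontaneous CL is the mean of
    the following ``n_spont_cycles`` consecutive spontaneous cycles
    (excluding the suppressed recovery cycle itself).  Values are averaged
    over runs; CSNRT = SNRT - spontaneous CL.  Raises a sinus-arrest flag if
    no spontaneous beat follows within 2 s.
    """
    ev = log.events
    paced = ev[ev["type"] != "spontaneous"].reset_index()
    if paced.empty:
        raise ValueError("no paced events in log")
    # split paced stimuli into runs separated by > 1 s
    t = paced["time_s"].to_numpy(float)
    breaks = np.nonzero(np.diff(t) > 1.0)[0]
    run_bounds = np.split(np.arange(len(t)), breaks + 1)
    snrts, sponts = [], []
    spont = ev[ev["type"] == "spontaneous"]["time_s"].to_numpy(float)
    for idx in run_bounds:
        run = paced.iloc[idx]
        if run["time_s"].iloc[-1] - run["time_s"].iloc[0] < min_overdrive_s:
            continue
        cap = run[run["atrial_captured"].astype(bool)]
        if cap.empty:
            continue
        t_last = float(cap["time_s"].iloc[-1])
        after = spont[spont > t_last]
        if len(after) == 0 or after[0] - t_last > 2.0:
            raise ValueError("sinus-arrest: no spontaneous beat within 2 s")
        snrts.append((after[0] - t_last) * 1000.0)
        if len(after) >= n_spont_cycles + 2:
            cycles = np.diff(after[1 : n_spont_cycles + 2]) * 1000.0
            sponts.append(float(np.mean(cycles)))
    if not snrts:
        raise ValueError("no overdrive run of sufficient length found")
    snrt = float(np.mean(snrts))
    spont_cl = float(np.mean(sponts)) if sponts else np.nan
    return {"snrt": snrt, "spontaneous_cl": spont_cl,
            "csnrt": snrt - spont_cl, "n_runs": len(snrts)}


def _strict_alternation(conducted: np.ndarray, min_len: int = 6) -> bool:
    """True when some run of >= min_len stimuli alternates conduct/drop."""
    c = np.asarray(conducted, bool)
    run = 1
    for i in range(1, len(c)):
        run = run + 1 if c[i] != c[i - 1] else 1
        if run >= min_len:
            return True
    return False


def find_block_cls(log: ResponseLog) -> dict:
    """Wenckebach and 2:1 block CLs from a decremental constant-CL log.

    Considers captured stimuli of each constant-CL train.  The Wenckebach
    CL is the longest basic CL whose train contains at least one dropped
    ventricular beat while still conducting most stimuli; the 2:1 CL is the
    longest basic CL whose train shows strict conduct/drop alternation over
    at least six stimuli.  Raises when no block occurs in the tested range.
    """
    ev = log.events
    paced = ev[(ev["type"] != "spontaneous")
               & ev["atrial_captured"].astype(bool)]
    if paced.empty:
        raise ValueError("no captured paced stimuli in log")
    wenck, two_one = [], []
    for cl, grp in paced.groupby("basic_cl_ms"):
        cond = grp["ventricular_conducted"].to_numpy(bool)
        if len(cond) < 6:
            continue
        n_drop = int(np.sum(~cond))
        if n_drop >= 1 and np.mean(cond) > 0.3:
            wenck.append(float(cl))
        if _strict_alternation(cond):
            two_one.append(float(cl))
    if not wenck:
        raise ValueError("block-below-range: no dropped beats in any train")
    return {
        "wenckebach_cl": max(wenck),
        "two_to_one_cl": max(two_one) if two_one else None,
    }


def sweep_from_log(log: ResponseLog, basic_cl: float,
                   step: float = 2.0) -> S1S2Sweep:
    """Collect the S2 outcomes of repeated S1–S2 trains into one sweep."""
    ev = log.events
    s2 = ev[ev["type"] == "S2"]
    s2 = s2[s2["basic_cl_ms"] == basic_cl]
    if s2.empty:
        raise ValueError(f"no S2 events at basic CL {basic_cl}")
    order = np.argsort(-s2["coupling_ms"].to_numpy(float))
    return S1S2Sweep(
        basic_cl=basic_cl,
        couplings=s2["coupling_ms"].to_numpy(float)[order],
        atrial_captured=s2["atrial_captured"].to_numpy(bool)[order],
        ventricular_conducted=s2["ventricular_conducted"].to_numpy(bool)[order],
        step=step,
    )
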