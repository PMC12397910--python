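"""FRAP trace correction and double-exponential recovery fitting.

Raw fluorescence-recovery traces carry three channels: the bleached region
of interest (ROI), a reference region in an unbleached condensate (tracking
acquisition photofading), and a background region.  Correction is the
standard double normalization

    corrected(t) = (roi - bg) / (ref - bg)
                   * mean_pre(ref - bg) / mean_pre(roi - bg)

which removes background, divides out photofading, and scales the pre-bleach
plateau to 1.  The corrected recovery is fitted with

    F(t) = F0 + A1*(1 - exp(-t/tau1)) + A2*(1 - exp(-t/tau2))

with t measured from the bleach.  Because a single "recovery tau" from a
two-component fit is ambiguous, the fit reports the dominant-component tau
(larger amplitude), the amplitude-weighted mean tau, and both components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .errors import (
    CorrectionError,
    FitFailureError,
    InvalidInputError,
)


@dataclass
class FrapTrace:
    """Raw three-channel FRAP trace; ``bleach_index`` is the first
    post-bleach sample."""

    time: np.ndarray
    roi: np.ndarray
    reference: np.ndarray
    background: np.ndarray
    bleach_index: int

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        for name in ("roi", "reference", "background"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != self.time.shape:
                raise InvalidInputError(f"{name} length mismatch")
        if np.any(np.diff(self.time) <= 0):
            raise InvalidInputError("time must be strictly increasing")
        if not (0 < self.bleach_index < self.time.size):
            raise InvalidInputError("bleach_index must leave pre-bleach samples")


@dataclass
class FrapFit:
    """Double-exponential recovery parameters (components ordered A1 >= A2)."""

    A1: float
    tau1: float
    A2: float
    tau2: float
    F0: float                       # corrected intensity right after bleach
    plateau: float                  # F0 + A1 + A2
    tau_dominant: float
    tau_weighted: float
    residual_norm: float = np.nan
    converged: bool = False
    single_exponential: bool = False   # degenerate (tau1 ~ tau2 or A2 ~ 0)


def correct_trace(trace: FrapTrace) -> np.ndarray:
    """Background-subtract, reference-correct, and pre-bleach-normalize.

    The pre-bleach mean of the corrected series is 1 by construction.
    Raises :class:`CorrectionError` if the reference ever falls to or below
    the background, or if the pre-bleach ROI signal is non-positive.
    """
    pre = slice(0, trace.bleach_index)
    ref_net = trace.reference - trace.background
    roi_net = trace.roi - trace.background
    if np.any(ref_net <= 0):
        raise CorrectionError("reference <= background at some time point")
    pre_roi = roi_net[pre].mean()
    pre_ref = ref_net[pre].mean()
    if pre_roi <= 0:
        raise CorrectionError("non-positive pre-bleach ROI signal")
    return (roi_net / ref_net) * (pre_ref / pre_roi)


def _recovery_model(t, f0, a1, tau1, a2, tau2):
    return (f0 + a1 * (1.0 - np.exp(-t / tau1))
            + a2 * (1.0 - np.exp(-t / tau2)))


def fit_double_exponential(corrected: np.ndarray, bleach_index: int,
                           time: np.ndarray | None = None,
                           tau_ratio_collapse: float = 1.5,
                           amp_floor: float = 1e-3) -> FrapFit:
    """Fit the post-bleach recovery with two exponential components.

    ``time`` defaults to sample index (1-s frames).  ``t`` is re-zeroed at
    the bleach.  Multi-start over tau pairs; components are ordered so the
    dominant (larger-amplitude) one comes first.  When the two taus are
    within ``tau_ratio_collapse`` of each other, or one amplitude is below
    ``amp_floor``, the fit is flagged as effectively single-exponential and
    the dominant tau is taken from the surviving component.
    """
    corrected = np.asarray(corrected, dtype=float)
    if time is None:
        time = np.arange(corrected.size, dtype=float)
    t = time[bleach_index:] - time[bleach_index]
    y = corrected[bleach_index:]
    if t.size < 20:
        raise InvalidInputError("need >= 20 post-bleach points")

    f0_guess = y[0]
    amp_guess = max(y[-1] - y[0], 1e-3)
    t_span = t[-1]
    starts = []
    for frac1, frac2 in ((0.3, 0.03), (0.6, 0.1), (0.15, 0.015), (1.0, 0.05)):
        starts.append((f0_guess, 0.8 * amp_guess, frac1 * t_span,
                       0.2 * amp_guess, frac2 * t_span))
    lb = [-np.inf, 0.0, 1e-6, 0.0, 1e-6]
    ub = [np.inf, np.inf, np.inf, np.inf, np.inf]
    best = None
    for p0 in starts:
        try:
            popt, _ = optimize.curve_fit(_recovery_model, t, y, p0=p0,
                                         bounds=(lb, ub), maxfev=40000)
        except (RuntimeError, ValueError):
            continue
        rss = float(np.linalg.norm(y - _recovery_model(t, *popt)))
        if best is None or rss < best[1]:
            best = (popt, rss)
    if best is None:
        raise FitFailureError("double-exponential fit failed from all starts")
    f0, a1, tau1, a2, tau2 = best[0]
    rss = best[1]

    # order by amplitude, dominant first
    if a2 > a1:
        a1, tau1, a2, tau2 = a2, tau2, a1, tau1

    total_amp = a1 + a2
    degenerate = False
    if total_amp <= 0:
        raise FitFailureError("no recovery amplitude; trace may be immobile")
    if a2 < amp_floor * max(total_amp, 1.0):
        degenerate = True          # second component vanishes
    elif max(tau1, tau2) / max(min(tau1, tau2), 1e-12) < tau_ratio_collapse:
        # indistinguishable timescales: refit a single exponential
        degenerate = True
        popt, _ = optimize.curve_fit(
            lambda tt, f0s, a, tau: f0s + a * (1 - np.exp(-tt / tau)),
            t, y, p0=(f0, total_amp, tau1), maxfev=20000)
        f0, a1, tau1 = popt
        a2, tau2 = 0.0, tau1
        rss = float(np.linalg.norm(
            y - (f0 + a1 * (1 - np.exp(-t / tau1)))))

    tau_weighted = ((a1 * tau1 + a2 * tau2) / (a1 + a2)) if (a1 + a2) > 0 \
        else tau1
    return FrapFit(A1=float(a1), tau1=float(tau1), A2=float(a2),
                   tau2=float(tau2), F0=float(f0),
                   plateau=float(f0 + a1 + a2),
                   tau_dominant=float(tau1), tau_weighted=float(tau_weighted),
                   residual_norm=rss, converged=True,
                   single_exponential=degenerate)


def analyze_frap(trace: FrapTrace) -> tuple[np.ndarray, FrapFit]:
    """Correct a raw trace and fit its recovery in one call."""
    corrected = correct_trace(trace)
    fit = fit_double_exponential(corrected, trace.bleach_index,
                                 time=trace.time)
    return corrected, fit


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def read_frap_csv(path) -> FrapTrace:
    """Read a trace from CSV with columns time_s, roi, reference,
    background, post_bleach (0/1)."""
    import pandas as pd

    df = pd.read_csv(path)
    post = np.asarray(df["post_bleach"], dtype=int)
    bleach_index = int(np.flatnonzero(post)[0])
    return FrapTrace(time=df["time_s"].to_numpy(),
                     roi=df["roi"].to_numpy(),
                     reference=df["reference"].to_numpy(),
                     background=df["background"].to_numpy(),
                     bleach_index=bleach_index)


def write_frap_csv(trace: FrapTrace, path):
    import pandas as pd

    post = np.zeros(trace.time.size, dtype=int)
    post[trace.bleach_index:] = 1
    pd.DataFrame({"time_s": trace.time, "roi": trace.roi,
                  "reference": trace.reference,
                  "background": trace.background,
                  "post_bleach": post}).to_csv(path, index=False)
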