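"""Stiffness extraction from force-probe indentation traces.

A flat probe advances at constant speed (nominally 0.1 mm/s) into a membrane
sample while force is logged at high frequency.  Because the push speed is
constant, the rate of force increase (mN/s) over the linear part of the
force curve is a stiffness readout that can be compared across samples.

Processing pipeline, in order:

1. ``baseline_correct`` — subtract the mean force recorded before probe
   movement starts, so each trace carries its own zero.
2. ``downsample_1hz`` — average the high-frequency samples to one value per
   second (bin centers as timestamps).
3. ``qc_trace`` — flag traces with early membrane rupture (mid-push force
   drop), probe/holder collision (force cap or slope discontinuity) or no
   contact at all.
4. ``linear_phase_slope`` — among all contiguous 20-s windows after contact,
   fit a line in each and keep the window maximizing R^2 (earliest wins
   ties); the fitted slope is the stiffness metric.

Contact is detected on the 1-Hz trace as the first sample where force
exceeds 3x the pre-movement residual SD for 3 consecutive samples.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import InsufficientDataError, TraceQCError

__all__ = [
    "ProbeTrace",
    "StiffnessResult",
    "baseline_correct",
    "downsample_1hz",
    "qc_trace",
    "contact_time",
    "linear_phase_slope",
    "DEFAULT_WINDOW_S",
]

DEFAULT_WINDOW_S = 20.0
PUSH_SPEED_MM_S = 0.1


@dataclass(frozen=True)
class ProbeTrace:
    """Force-probe record: time (s), probe position (mm), force (mN).

    ``baseline_mN`` is the offset removed by :func:`baseline_correct` (0 for
    a raw trace); ``noise_sd_mN`` the residual SD of the pre-movement force,
    used for contact detection.
    """

    time_s: np.ndarray
    position_mm: np.ndarray
    force_mN: np.ndarray
    baseline_mN: float = 0.0
    noise_sd_mN: float = float("nan")

    def __post_init__(self):
        t = np.asarray(self.time_s, dtype=float)
        x = np.asarray(self.position_mm, dtype=float)
        f = np.asarray(self.force_mN, dtype=float)
        if not (t.shape == x.shape == f.shape) or t.ndim != 1:
            raise ValueError("time, position and force must be 1-D, equal length")
        if not np.all(np.diff(t) > 0):
            raise ValueError("time_s must be strictly increasing")
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "position_mm", x)
        object.__setattr__(self, "force_mN", f)

    @property
    def sampling_rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.time_s)))

    def movement_onset(self, tol_mm: float = 1e-4) -> float:
        """Time at which the probe position first leaves its initial value."""
        moved = np.nonzero(self.position_mm > self.position_mm[0] + tol_mm)[0]
        if moved.size == 0:
            raise InsufficientDataError("probe never moves in this trace")
        return float(self.time_s[moved[0]])


@dataclass(frozen=True)
class StiffnessResult:
    """Linear-phase slope and its provenance.

    ``slope_mN_per_s`` is only meaningful when ``qc == "ok"``.
    """

    slope_mN_per_s: float
    window_start_s: float
    window_end_s: float
    contact_time_s: float
    baseline_mN: float
    qc: str
    r_squared: float = float("nan")


def baseline_correct(trace: ProbeTrace, pre_window: float = 2.0) -> ProbeTrace:
    """Zero each trace on its own pre-movement force.

    Requires at least ``pre_window`` seconds of data before movement onset;
    the mean force over the whole pre-movement stretch is subtracted and its
    residual SD stored for contact detection.
    """
    onset = trace.movement_onset()
    pre = trace.time_s < onset
    if trace.time_s[pre].size == 0 or onset - trace.time_s[0] < pre_window:
        raise TraceQCError(
            f"only {onset - trace.time_s[0]:.2f} s of pre-movement baseline, "
            f"need >= {pre_window:.2f} s"
        )
    baseline = float(trace.force_mN[pre].mean())
    noise_sd = float(trace.force_mN[pre].std(ddof=1))
    return replace(
        trace,
        force_mN=trace.force_mN - baseline,
        baseline_mN=baseline,
        noise_sd_mN=noise_sd,
    )


def downsample_1hz(trace: ProbeTrace) -> ProbeTrace:
    """Average to one sample per second; empty bins are dropped."""
    if trace.sampling_rate < 1.0:
        raise ValueError("sampling rate below 1 Hz; nothing to downsample")
    bins = np.floor(trace.time_s - trace.time_s[0]).astype(int)
    counts = np.bincount(bins)
    keep = counts > 0
    centers = trace.time_s[0] + np.nonzero(keep)[0] + 0.5
    x = np.bincount(bins, weights=trace.position_mm)[keep] / counts[keep]
    f = np.bincount(bins, weights=trace.force_mN)[keep] / counts[keep]
    return replace(trace, time_s=centers, position_mm=x, force_mN=f)


def contact_time(
    trace_1hz: ProbeTrace, n_sd: float = 3.0, consecutive: int = 3
) -> float:
    """First 1-Hz time where force exceeds ``n_sd`` x baseline noise SD
    for ``consecutive`` samples."""
    sd = trace_1hz.noise_sd_mN
    if not np.isfinite(sd):
        raise TraceQCError("trace not baseline-corrected (no noise estimate)")
    thr = max(n_sd * sd, 1e-12)
    above = trace_1hz.force_mN > thr
    run = np.convolve(above.astype(int), np.ones(consecutive, dtype=int), "valid")
    hits = np.nonzero(run == consecutive)[0]
    if hits.size == 0:
        raise InsufficientDataError("no contact detected")
    return float(trace_1hz.time_s[hits[0]])


def qc_trace(
    trace_1hz: ProbeTrace,
    drop_tol: float = 0.05,
    force_cap: float = 50.0,
    slope_jump_factor: float = 5.0,
) -> str:
    """Quality flag for a baseline-corrected 1-Hz trace.

    Returns one of ``"ok"``, ``"early_rupture"``, ``"holder_hit"``,
    ``"no_contact"``:

    - ``early_rupture`` — force falls by more than ``drop_tol`` (mN) between
      consecutive seconds during the push phase;
    - ``holder_hit`` — force exceeds ``force_cap`` (mN), or the per-second
      slope jumps by more than ``slope_jump_factor`` times the established
      push-phase slope;
    - ``no_contact`` — force never clears the contact threshold.
    """
    try:
        t_c = contact_time(trace_1hz)
    except InsufficientDataError:
        return "no_contact"

    push = trace_1hz.position_mm > trace_1hz.position_mm[0] + 1e-4
    in_push = push & (trace_1hz.time_s >= t_c)
    f = trace_1hz.force_mN[in_push]
    if f.size >= 2:
        df = np.diff(f)
        if np.any(df < -drop_tol):
            return "early_rupture"
        if np.any(trace_1hz.force_mN > force_cap):
            return "holder_hit"
        median_slope = np.median(df[df > 0]) if np.any(df > 0) else 0.0
        if median_slope > 0 and np.any(df > slope_jump_factor * median_slope):
            return "holder_hit"
    return "ok"


def linear_phase_slope(
    trace_1hz: ProbeTrace, window: float = DEFAULT_WINDOW_S
) -> StiffnessResult:
    """Slope of the best-fitting straight line over a ``window``-second span.

    All contiguous windows starting at successive 1-Hz samples after contact
    are fit by least squares; the window with maximal R^2 is selected, the
    earliest winning near-ties (within 1e-9).  This keeps soft-contact
    curvature at the start of the push out of the fitted span without fixing
    an offset from contact.
    """
    t_c = contact_time(trace_1hz)
    t, f = trace_1hz.time_s, trace_1hz.force_mN
    sel = t >= t_c
    t, f = t[sel], f[sel]
    n_win = int(round(window))
    if t.size < n_win:
        raise InsufficientDataError(
            f"push phase has {t.size} s after contact, need >= {n_win} s"
        )

    best = None
    for start in range(t.size - n_win + 1):
        tw = t[start : start + n_win]
        fw = f[start : start + n_win]
        slope, intercept = np.polyfit(tw, fw, 1)
        resid = fw - (slope * tw + intercept)
        ss_tot = float(np.sum((fw - fw.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
        if best is None or r2 > best[0] + 1e-9:
            best = (r2, start, slope)

    r2, start, slope = best
    return StiffnessResult(
        slope_mN_per_s=float(slope),
        window_start_s=float(t[start]),
        window_end_s=float(t[start + n_win - 1]),
        contact_time_s=t_c,
        baseline_mN=trace_1hz.baseline_mN,
        qc="ok",
        r_squared=r2,
    )
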