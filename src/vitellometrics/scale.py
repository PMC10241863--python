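"""Native and maximum VM tension from balance-scale weight traces.

The protocol: a membrane strip mounted between filter papers hangs a small
clip weight inside a digital balance.  The reading starts at the full weight
(pre-cut plateau).  Cutting the supporting paper transfers part of the load
to the membrane, dropping the reading by ``dm = gamma_native * L / g``.
Raising the holder then ramps the reading further down until the membrane
ruptures, at which point the reading jumps back to the full weight (terminal
plateau).  Tensions follow from weight differences::

    gamma_native = |m_after_cut - m_detached| * g / L
    gamma_max    = |m_breaking  - m_detached| * g / L

with masses in kg, ``L`` the strip width (m).  The detached weight is read
from the post-rupture plateau (and from the pre-cut plateau when the trace
ends before rupture — the two coincide because the full weight rests on the
balance in both states).  Differences are taken in absolute value so the
reported tension is non-negative regardless of the sign convention of the
reading change.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import IncompleteTraceError, TraceQCError
from .shape import STANDARD_GRAVITY

__all__ = [
    "ScaleTrace",
    "ScaleEvents",
    "detect_events",
    "native_tension",
    "max_tension",
]

DEFAULT_STRIP_WIDTH_M = 0.02


@dataclass(frozen=True)
class ScaleTrace:
    """Weight-reading time series from the balance.

    ``time_s`` strictly increasing (s); ``reading_g`` non-negative (grams);
    ``width_m`` the membrane strip width carrying the load.
    """

    time_s: np.ndarray
    reading_g: np.ndarray
    width_m: float = DEFAULT_STRIP_WIDTH_M
    annotations: dict = field(default_factory=dict)

    def __post_init__(self):
        t = np.asarray(self.time_s, dtype=float)
        m = np.asarray(self.reading_g, dtype=float)
        if t.ndim != 1 or t.shape != m.shape:
            raise ValueError("time_s and reading_g must be 1-D and equal length")
        if not np.all(np.diff(t) > 0):
            raise ValueError("time_s must be strictly increasing")
        if np.any(m < 0):
            raise ValueError("reading_g must be non-negative")
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "reading_g", m)

    @property
    def sampling_interval(self) -> float:
        return float(np.median(np.diff(self.time_s)))


@dataclass(frozen=True)
class ScaleEvents:
    """Event weights extracted from one trace (grams).

    ``m_breaking_g`` is ``None`` when the trace ends before rupture; the
    native tension is still defined in that case, the maximum tension is not.
    """

    m_detached_g: float
    m_after_cut_g: float
    m_breaking_g: float | None
    t_cut_s: float
    t_rupture_s: float | None

    @property
    def complete(self) -> bool:
        return self.m_breaking_g is not None


def _rolling_median(x, w):
    if w <= 1:
        return x.copy()
    pad = w // 2
    xp = np.pad(x, pad, mode="edge")
    windows = np.lib.stride_tricks.sliding_window_view(xp, w)[: x.size]
    return np.median(windows, axis=1)


def _plateau_mean(reading, lo, hi, plateau_tol, min_samples):
    """Mean of reading[lo:hi] provided it is stable; None otherwise."""
    seg = reading[lo:hi]
    if seg.size < min_samples:
        return None
    if np.ptp(seg) > 4.0 * plateau_tol:  # allow plateau_tol of noise each side
        return None
    return float(seg.mean())


def detect_events(
    trace: ScaleTrace,
    plateau_tol: float = 0.05,
    jump_tol: float = 0.3,
    settle_s: float = 1.0,
    plateau_min_s: float = 2.0,
) -> ScaleEvents:
    """Locate the cut and rupture events and read the three event weights.

    Steps (``jump_tol`` grams within ~0.5 s) are detected on a median-smoothed
    trace: the first downward step is the cut, the last upward step the
    rupture.  The default ``jump_tol`` of 0.3 g resolves the sub-gram cut
    steps that weak (late-stage) membranes produce on a 2-cm strip while
    staying far above gram-scale sensor noise.  Plateau weights are means over stable segments (spread within a
    few ``plateau_tol``) of at least ``plateau_min_s`` seconds, skipping
    ``settle_s`` of transient after each step.  ``m_breaking_g`` is the
    extremal (minimum) reading in the ramp immediately before the rupture
    step.

    Raises
    ------
    IncompleteTraceError
        If no cut step exists (e.g. a flat trace).
    TraceQCError
        If the post-cut plateau is absent or unstable (e.g. the ramp starts
        immediately after the cut).
    """
    t, m = trace.time_s, trace.reading_g
    dt = trace.sampling_interval
    smooth = _rolling_median(m, max(3, int(round(0.5 / dt)) | 1))

    span = max(1, int(round(0.5 / dt)))
    step = smooth[span:] - smooth[:-span]
    down = np.nonzero(step < -jump_tol)[0]
    up = np.nonzero(step > jump_tol)[0]
    if down.size == 0:
        raise IncompleteTraceError("no cut step found in trace")
    i_cut = int(down[0])
    up = up[up > i_cut]
    i_rupture = int(up[-1] + span) if up.size else None

    n_settle = int(round(settle_s / dt))
    n_min = max(2, int(round(plateau_min_s / dt)))

    # post-cut plateau: stable stretch right after the cut transient
    lo = i_cut + span + n_settle
    hi = lo + n_min
    m_after_cut = _plateau_mean(m, lo, hi, plateau_tol, n_min)
    if m_after_cut is None:
        raise TraceQCError("no stable plateau after the cut")

    if i_rupture is not None:
        # refine the rupture index on the raw trace (largest single-sample
        # rise inside the step region found on the smoothed trace)
        lo_j = max(i_cut + 1, i_rupture - 2 * span)
        hi_j = min(m.size - 1, i_rupture + span)
        j = lo_j + int(np.argmax(np.diff(m[lo_j : hi_j + 1]))) + 1
        i_rupture = j
        # terminal plateau after rupture gives the detached weight
        lo_d = i_rupture + n_settle
        m_detached = _plateau_mean(m, lo_d, m.size, plateau_tol, n_min)
        if m_detached is None:
            raise TraceQCError("no stable post-rupture plateau")
        # extremal reading immediately before the rupture: fit the last ~2 s
        # of the ramp and evaluate at the final pre-rupture sample, which is
        # unbiased under both the descending ramp and the sensor noise
        n_fit = max(3, int(round(2.0 / dt)))
        lo_f = max(i_cut, i_rupture - n_fit)
        seg_t = t[lo_f:i_rupture]
        seg_m = m[lo_f:i_rupture]
        if seg_t.size >= 3:
            coef = np.polyfit(seg_t, seg_m, 1)
            m_breaking = float(np.polyval(coef, t[i_rupture - 1]))
        elif seg_m.size:
            m_breaking = float(seg_m.min())
        else:
            m_breaking = None
        t_rupture = float(t[i_rupture])
    else:
        # incomplete trace: fall back to the pre-cut plateau for m_detached
        m_detached = _plateau_mean(m, 0, i_cut, plateau_tol, n_min)
        if m_detached is None:
            raise TraceQCError("no stable pre-cut plateau")
        m_breaking = None
        t_rupture = None

    return ScaleEvents(
        m_detached_g=m_detached,
        m_after_cut_g=m_after_cut,
        m_breaking_g=m_breaking,
        t_cut_s=float(t[min(i_cut + span, t.size - 1)]),
        t_rupture_s=t_rupture,
    )


def _tension_from_dm(dm_g, width_m, gravity):
    if width_m <= 0:
        raise ValueError(f"strip width must be positive, got {width_m!r}")
    return abs(dm_g) * 1e-3 * gravity / width_m


def native_tension(
    events: ScaleEvents,
    width_m: float = DEFAULT_STRIP_WIDTH_M,
    gravity: float = STANDARD_GRAVITY,
) -> float:
    """|m_after_cut - m_detached| * g / L, N/m."""
    return _tension_from_dm(
        events.m_after_cut_g - events.m_detached_g, width_m, gravity
    )


def max_tension(
    events: ScaleEvents,
    width_m: float = DEFAULT_STRIP_WIDTH_M,
    gravity: float = STANDARD_GRAVITY,
) -> float:
    """|m_breaking - m_detached| * g / L, N/m (requires a complete trace)."""
    if events.m_breaking_g is None:
        raise IncompleteTraceError("no rupture in trace: maximum tension undefined")
    return _tension_from_dm(
        events.m_breaking_g - events.m_detached_g, width_m, gravity
    )
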