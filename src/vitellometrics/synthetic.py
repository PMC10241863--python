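"""Synthetic measurement data with known ground truth.

Every input type consumed by the analysis modules can be generated here with
the statistical structure the pipeline assumes, so each estimator can be
tested for parameter recovery without any external data.  Generators are
deterministic functions of their seed (identical arguments + seed give
byte-identical tables) and each returns, alongside the measurement-style
table or trace, a *truth* record of the hidden parameters that produced it.

Default settings mirror the study conditions the package targets: a ~17 mL
yolk of density 1.035 g/cm^3, tensions of order 0.1–1 N/m with day-2 tension
about 40% of day 0, 2-cm scale strips read in grams, a 0.1 mm/s probe with a
40-s push sampled at 100 Hz, landmark series spanning several hours at tens
of um/h, and fibre coverages of a few tens of percent.  Measurement noise is
Gaussian throughout: 0.3 mm on puddle height/diameter, 0.02 g on scale
readings, 0.01 mN on probe force, 5 um on landmarks.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import line as draw_line
from skimage.morphology import dilation, disk

from .morphometry import AxisLandmarkSeries, FibreImage
from .probe import ProbeTrace
from .scale import ScaleTrace
from .shape import STANDARD_GRAVITY, MembraneDropParams, solve_drop_shape

__all__ = [
    "SimConfig",
    "gen_puddle_observations",
    "gen_scale_trace",
    "gen_probe_trace",
    "gen_landmark_series",
    "gen_fibre_image",
]


@dataclass(frozen=True)
class SimConfig:
    """Parameter block for a full synthetic study (see ``simulate_all``)."""

    seed: int = 0
    # puddle-shape block: tensions per day-group, N/m (day-2 ~ 40% of day 0)
    gamma_by_group: dict = field(
        default_factory=lambda: {"D0": 0.8, "D2": 0.32}
    )
    volume_m3: float = 17e-6
    density_kg_m3: float = 1035.0
    geom_noise_sd_mm: float = 0.3
    n_per_group: int = 20
    # scale block: native/max tension per group (Fig-style cohort sizes)
    scale_gamma_native: dict = field(
        default_factory=lambda: {"D0": 0.6, "D2": 0.25}
    )
    scale_gamma_max: dict = field(
        default_factory=lambda: {"D0": 2.2, "D2": 1.0}
    )
    scale_n: dict = field(default_factory=lambda: {"D0": 15, "D2": 19})
    scale_noise_sd_g: float = 0.02
    # probe block: linear-phase slope per group, mN/s
    probe_slope: dict = field(default_factory=lambda: {"D0": 0.08, "D2": 0.03})
    probe_noise_sd_mN: float = 0.01
    probe_n: dict = field(default_factory=lambda: {"D0": 15, "D2": 16})
    # morphometry block: (elongation um/h, convergence um/h, pairs/h)
    landmark_groups: dict = field(
        default_factory=lambda: {"CTRL": (80.0, 30.0, 0.667), "SW": (30.0, 5.0, 0.4)}
    )
    landmark_n: int = 10
    landmark_noise_sd_um: float = 5.0
    fibre_coverages: tuple = (0.05, 0.1, 0.15, 0.2, 0.25, 0.3, 0.35, 0.4)

    def to_dict(self):
        return asdict(self)


# ---------------------------------------------------------------------------
# puddle geometry
# ---------------------------------------------------------------------------


def gen_puddle_observations(
    gamma_by_group: dict,
    volume: float = 17e-6,
    density: float = 1035.0,
    geom_noise_sd_mm: float = 0.3,
    n_per_group: int = 20,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Puddle-geometry table from the forward drop-shape model plus noise.

    For each group the forward model is solved once at the group's true
    tension; every sample then observes that height and diameter with
    additive Gaussian measurement noise (SD ``geom_noise_sd_mm``).

    Returns
    -------
    (table, truth)
        ``table`` with columns ``sample_id, day, height_mm, diameter_mm,
        volume_ml, density_g_per_cm3``; ``truth`` with the generating
        tension and noiseless geometry per group.
    """
    rng = np.random.default_rng(seed)
    rows, truth_rows = [], []
    for group, gamma in gamma_by_group.items():
        profile = solve_drop_shape(MembraneDropParams(gamma, density, volume))
        h_mm = profile.height * 1e3
        d_mm = profile.diameter * 1e3
        truth_rows.append(
            {
                "day": group,
                "gamma_true_N_per_m": gamma,
                "height_true_mm": h_mm,
                "diameter_true_mm": d_mm,
                "yolk_index_true": profile.yolk_index,
            }
        )
        noise = rng.normal(0.0, geom_noise_sd_mm, size=(n_per_group, 2))
        for i in range(n_per_group):
            rows.append(
                {
                    "sample_id": f"{group}_{i:03d}",
                    "day": group,
                    "height_mm": h_mm + noise[i, 0],
                    "diameter_mm": d_mm + noise[i, 1],
                    "volume_ml": volume * 1e6,
                    "density_g_per_cm3": density / 1e3,
                }
            )
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# scale traces
# ---------------------------------------------------------------------------


def gen_scale_trace(
    gamma_native: float,
    gamma_max: float | None,
    width_m: float = 0.02,
    clip_weight_g: float = 10.0,
    noise_sd_g: float = 0.02,
    seed: int = 0,
    rate_hz: float = 10.0,
    plateau_s: float = 10.0,
    ramp_s: float = 15.0,
    gravity: float = STANDARD_GRAVITY,
) -> tuple[ScaleTrace, dict]:
    """Piecewise scale trace: plateau, cut, plateau, ramp, rupture, plateau.

    The after-cut plateau sits ``gamma_native * L / g`` (in grams) below the
    full clip weight and the ramp descends to ``gamma_max * L / g`` below it,
    then jumps back at rupture.  ``gamma_max=None`` produces an incomplete
    trace that ends mid-ramp with no rupture.
    """
    rng = np.random.default_rng(seed)
    dm_native = gamma_native * width_m / gravity * 1e3  # grams
    dm_max = gamma_max * width_m / gravity * 1e3 if gamma_max is not None else None
    if dm_max is not None and dm_max < dm_native:
        raise ValueError("gamma_max must be >= gamma_native")

    dt = 1.0 / rate_hz
    segs = []

    def plateau(level, dur):
        n = int(round(dur * rate_hz))
        segs.append(np.full(n, level))

    plateau(clip_weight_g, plateau_s)  # pre-cut
    # cut transient: fast exponential settle onto the after-cut plateau
    n_tr = int(round(0.5 * rate_hz))
    tt = np.arange(n_tr) * dt
    segs.append(clip_weight_g - dm_native * (1.0 - np.exp(-tt / 0.1)))
    plateau(clip_weight_g - dm_native, plateau_s)  # after-cut
    if dm_max is not None:
        n_ramp = int(round(ramp_s * rate_hz))
        segs.append(
            np.linspace(clip_weight_g - dm_native, clip_weight_g - dm_max, n_ramp)
        )
        plateau(clip_weight_g, plateau_s)  # rupture jump + terminal plateau
    else:
        n_ramp = int(round(ramp_s * rate_hz / 2))
        segs.append(
            clip_weight_g
            - dm_native
            - np.arange(n_ramp) * dt * (dm_native * 0.05)
        )

    reading = np.concatenate(segs) + rng.normal(0.0, noise_sd_g, sum(s.size for s in segs))
    reading = np.clip(reading, 0.0, None)
    time = np.arange(reading.size) * dt
    truth = {
        "gamma_native_N_per_m": gamma_native,
        "gamma_max_N_per_m": gamma_max,
        "m_detached_g": clip_weight_g,
        "m_after_cut_g": clip_weight_g - dm_native,
        "m_breaking_g": clip_weight_g - dm_max if dm_max is not None else None,
        "width_m": width_m,
        "noise_sd_g": noise_sd_g,
        "seed": seed,
    }
    return ScaleTrace(time, reading, width_m=width_m), truth


# ---------------------------------------------------------------------------
# probe traces
# ---------------------------------------------------------------------------


def gen_probe_trace(
    true_slope: float,
    baseline_mN: float = 0.3,
    contact_time_s: float = 10.0,
    onset_dur_s: float = 0.0,
    noise_sd_mN: float = 0.01,
    rupture: tuple | None = None,
    seed: int = 0,
    rate_hz: float = 100.0,
    pre_s: float = 5.0,
    push_s: float = 40.0,
    speed_mm_s: float = 0.1,
) -> tuple[ProbeTrace, dict]:
    """Indentation force trace with a known linear-phase slope.

    Force is flat at ``baseline_mN`` until ``contact_time_s``, blends through
    a quadratic soft-contact onset of duration ``onset_dur_s`` and then rises
    linearly at ``true_slope`` mN/s.  ``rupture=(t, drop)`` inserts a sudden
    force drop of ``drop`` mN at time ``t``.  The probe is stationary for
    ``pre_s`` seconds, then advances at ``speed_mm_s``.
    """
    rng = np.random.default_rng(seed)
    dt = 1.0 / rate_hz
    total = pre_s + push_s
    t = np.arange(0.0, total, dt)
    pos = np.where(t < pre_s, 0.0, (t - pre_s) * speed_mm_s)

    force = np.full_like(t, baseline_mN)
    after = t >= contact_time_s
    tau = t[after] - contact_time_s
    if onset_dur_s > 0:
        # quadratic ramp-in matching slope continuity at the end of onset
        rise = np.where(
            tau < onset_dur_s,
            true_slope * tau**2 / (2.0 * onset_dur_s),
            true_slope * (tau - onset_dur_s / 2.0),
        )
    else:
        rise = true_slope * tau
    force[after] += rise
    if rupture is not None:
        t_rup, drop = rupture
        force[t >= t_rup] -= drop
    force = force + rng.normal(0.0, noise_sd_mN, t.size)

    truth = {
        "slope_mN_per_s": true_slope,
        "baseline_mN": baseline_mN,
        "contact_time_s": contact_time_s,
        "onset_dur_s": onset_dur_s,
        "noise_sd_mN": noise_sd_mN,
        "rupture": rupture,
        "seed": seed,
    }
    return ProbeTrace(t, pos, force), truth


# ---------------------------------------------------------------------------
# landmark series
# ---------------------------------------------------------------------------


def gen_landmark_series(
    elongation_um_h: float = 80.0,
    convergence_um_h: float = 30.0,
    seg_rate_per_h: float = 0.667,
    duration_h: float = 8.0,
    frame_interval_h: float = 0.5,
    noise_sd_um: float = 5.0,
    initial_length_um: float = 2000.0,
    initial_width_um: float = 400.0,
    initial_somites: int = 4,
    seed: int = 0,
) -> tuple[AxisLandmarkSeries, dict]:
    """Landmark time series with known elongation/convergence/segmentation.

    The reference somite sits at the origin; the posterior end recedes along
    +y at the elongation speed; the pNT walls close symmetrically at the
    convergence speed; somite pairs accrue at ``seg_rate_per_h`` (counts are
    kept fractional so the generating slope is exact).  Gaussian noise of SD
    ``noise_sd_um`` is added to every landmark coordinate.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_h + frame_interval_h / 2, frame_interval_h)
    n = t.size
    ref = rng.normal(0.0, noise_sd_um, (n, 2))
    post = np.column_stack(
        [
            rng.normal(0.0, noise_sd_um, n),
            initial_length_um + elongation_um_h * t + rng.normal(0, noise_sd_um, n),
        ]
    )
    width = initial_width_um - convergence_um_h * t
    if np.any(width <= 0):
        raise ValueError("convergence closes the pNT within the duration")
    half = width / 2.0
    left = -half + rng.normal(0.0, noise_sd_um, n)
    right = half + rng.normal(0.0, noise_sd_um, n)
    somites = initial_somites + seg_rate_per_h * t

    series = AxisLandmarkSeries(
        time_h=t,
        somite_ref=ref,
        post_end=post,
        pnt_left_x=left,
        pnt_right_x=right,
        somite_pairs=somites,
    )
    truth = {
        "elongation_um_h": elongation_um_h,
        "convergence_um_h": convergence_um_h,
        "seg_rate_per_h": seg_rate_per_h,
        "noise_sd_um": noise_sd_um,
        "seed": seed,
    }
    return series, truth


# ---------------------------------------------------------------------------
# fibre images
# ---------------------------------------------------------------------------


def gen_fibre_image(
    coverage: float = 0.2,
    fibre_width_px: int = 3,
    size_px: int = 512,
    noise_sd: float = 0.05,
    seed: int = 0,
    max_fibres: int = 20000,
) -> tuple[FibreImage, dict]:
    """Random oriented line fibres rasterized to a target area coverage.

    Straight segments with uniform random endpoints are drawn and dilated to
    ``fibre_width_px`` until the white fraction reaches ``coverage``; the
    image is foreground 1.0 / background 0.0 plus Gaussian intensity noise
    clipped to [0, 1].  ``coverage=0`` yields a pure-noise background image.
    """
    if not (0.0 <= coverage < 1.0):
        raise ValueError("coverage must be in [0, 1)")
    rng = np.random.default_rng(seed)
    mask = np.zeros((size_px, size_px), dtype=bool)
    n_fibres = 0
    selem = disk(max(fibre_width_px // 2, 1))
    while coverage > 0 and mask.mean() < coverage and n_fibres < max_fibres:
        r0, c0, r1, c1 = rng.integers(0, size_px, 4)
        rr, cc = draw_line(r0, c0, r1, c1)
        stroke = np.zeros_like(mask)
        stroke[rr, cc] = True
        mask |= dilation(stroke, footprint=selem)
        n_fibres += 1
    img = mask.astype(float) + rng.normal(0.0, noise_sd, mask.shape)
    img = np.clip(img, 0.0, 1.0)
    truth = {
        "coverage_target": coverage,
        "coverage_true": float(mask.mean()),
        "n_fibres": n_fibres,
        "fibre_width_px": fibre_width_px,
        "noise_sd": noise_sd,
        "seed": seed,
    }
    return FibreImage(img), truth


# ---------------------------------------------------------------------------
# full fixture set
# ---------------------------------------------------------------------------


def simulate_all(config: SimConfig, out_dir) -> dict:
    """Write the complete synthetic study to ``out_dir``.

    Produces the puddle-geometry table, per-sample scale and probe trace
    CSVs, per-embryo landmark CSVs and fibre-stain PNGs, each with a
    ``*_truth.csv`` sidecar recording the generating parameters.  Item seeds
    are derived deterministically from ``config.seed``, so the same config
    yields byte-identical files.
    """
    import imageio.v3 as iio
    from pathlib import Path

    from .io import write_landmark_series, write_probe_trace, write_scale_trace

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    base = int(config.seed)

    def item_seed(k):
        return (base * 1_000_003 + k) % (2**31)

    manifest = {}

    table, truth = gen_puddle_observations(
        config.gamma_by_group,
        volume=config.volume_m3,
        density=config.density_kg_m3,
        geom_noise_sd_mm=config.geom_noise_sd_mm,
        n_per_group=config.n_per_group,
        seed=item_seed(0),
    )
    table.to_csv(out / "puddle_geometry.csv", index=False)
    truth.to_csv(out / "puddle_truth.csv", index=False)
    manifest["puddle_geometry"] = len(table)

    k = 1
    (out / "scale_traces").mkdir(exist_ok=True)
    scale_truths = []
    for day, n in config.scale_n.items():
        for i in range(n):
            trace, t = gen_scale_trace(
                config.scale_gamma_native[day],
                config.scale_gamma_max[day],
                noise_sd_g=config.scale_noise_sd_g,
                seed=item_seed(k),
            )
            k += 1
            sid = f"{day}_{i:03d}"
            write_scale_trace(trace, out / "scale_traces" / f"{sid}.csv")
            scale_truths.append({"sample_id": sid, "day": day, **t})
    pd.DataFrame(scale_truths).to_csv(out / "scale_truth.csv", index=False)
    manifest["scale_traces"] = len(scale_truths)

    (out / "probe_traces").mkdir(exist_ok=True)
    probe_truths = []
    for day, n in config.probe_n.items():
        for i in range(n):
            trace, t = gen_probe_trace(
                config.probe_slope[day],
                noise_sd_mN=config.probe_noise_sd_mN,
                seed=item_seed(k),
            )
            k += 1
            sid = f"{day}_{i:03d}"
            write_probe_trace(trace, out / "probe_traces" / f"{sid}.csv")
            t = {key: v for key, v in t.items() if key != "rupture"}
            probe_truths.append({"sample_id": sid, "day": day, **t})
    pd.DataFrame(probe_truths).to_csv(out / "probe_truth.csv", index=False)
    manifest["probe_traces"] = len(probe_truths)

    (out / "landmarks").mkdir(exist_ok=True)
    landmark_truths = []
    for grp, (elong, conv, seg) in config.landmark_groups.items():
        for i in range(config.landmark_n):
            series, t = gen_landmark_series(
                elong, conv, seg,
                noise_sd_um=config.landmark_noise_sd_um,
                seed=item_seed(k),
            )
            k += 1
            sid = f"{grp}_{i:03d}"
            write_landmark_series(series, out / "landmarks" / f"{sid}.csv")
            landmark_truths.append({"sample_id": sid, "day": grp, **t})
    pd.DataFrame(landmark_truths).to_csv(out / "landmark_truth.csv", index=False)
    manifest["landmarks"] = len(landmark_truths)

    (out / "fibre_images").mkdir(exist_ok=True)
    fibre_truths = []
    for j, cov in enumerate(config.fibre_coverages):
        image, t = gen_fibre_image(coverage=cov, seed=item_seed(k))
        k += 1
        name = f"cov{int(round(cov * 100)):02d}.png"
        iio.imwrite(
            out / "fibre_images" / name,
            (image.intensity * 255).astype(np.uint8),
        )
        fibre_truths.append({"image": name, **t})
    pd.DataFrame(fibre_truths).to_csv(out / "fibre_truth.csv", index=False)
    manifest["fibre_images"] = len(fibre_truths)
    return manifest
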