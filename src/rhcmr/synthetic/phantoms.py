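"""Geometric phantoms with closed-form ground truth.

Ventricle phantoms are stacks of polygonized circles: each ventricle is a
pair of concentric rings (endocardium, epicardium) on every slice, with the
cavity cross-section scaled through the cardiac cycle so that end-systole
lands on a declared phase. All ground-truth volumes and masses are computed
from the analytic circle areas; the polygonization error a measurement
module sees is the usual regular-n-gon deficit, (n/2π)·sin(2π/n) of the
disc area (≈0.16% at 64 vertices).

Velocity phantoms lay a parabolic antegrade jet over systolic frames and a
uniform retrograde patch over diastolic frames, then rescale both so the
discrete per-beat volumes match the requested values exactly.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

from ..flow import VelocityFrameSeries
from ..geometry import ContourStack, SliceContour, Structure
from ..units import MM3_PER_ML, MYOCARDIAL_DENSITY_G_PER_CM3


class PhantomShape(str, enum.Enum):
    CYLINDER = "CYLINDER"
    HALF_ELLIPSOID = "HALF_ELLIPSOID"
    SHELL = "SHELL"


@dataclass
class PhantomSpec:
    """Recipe for a two-ventricle contour phantom.

    ``rv_radius``/``lv_radius`` are end-diastolic cavity radii in mm
    (equatorial radii for the half-ellipsoid); ``*_wall`` are wall
    thicknesses in mm (the SHELL/CYLINDER wall ring; for HALF_ELLIPSOID the
    wall ring shrinks with the cavity). ``systolic_scale`` is the ES/ED
    cavity *area* ratio, so EF = 100·(1 − systolic_scale).
    """

    shape: PhantomShape = PhantomShape.CYLINDER
    rv_radius: float = 20.0
    rv_wall: float = 4.0
    lv_radius: float = 22.0
    lv_wall: float = 9.0
    slice_spacing: float = 10.0
    n_slices: int = 10
    n_phases: int = 20
    es_phase: int = 8
    systolic_scale: float = 0.5
    vertex_count: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.systolic_scale <= 1:
            raise ValueError("systolic_scale must be in (0, 1]")
        if self.n_phases >= 2 and not 0 < self.es_phase < self.n_phases:
            raise ValueError("es_phase must lie strictly inside the cycle")
        if self.vertex_count < 3:
            raise ValueError("vertex_count must be >= 3")


def sinusoidal_phase_scales(n_phases: int, es_phase: int, systolic_scale: float) -> np.ndarray:
    """Per-phase cavity area scale: 1 at phase 0, minimum at ``es_phase``.

    Piecewise sin² ramp down to end-systole and back up, the standard smooth
    single-minimum volume curve of a cine acquisition.
    """
    if n_phases < 2:
        return np.ones(max(1, n_phases))
    p = np.arange(n_phases, dtype=float)
    w = np.empty(n_phases)
    w[: es_phase + 1] = np.sin(0.5 * math.pi * p[: es_phase + 1] / es_phase) ** 2
    if es_phase < n_phases - 1:
        tail = (n_phases - 1 - p[es_phase + 1 :]) / (n_phases - 1 - es_phase)
        w[es_phase + 1 :] = np.sin(0.5 * math.pi * tail) ** 2 * (1 - 1e-9)
    return 1.0 - (1.0 - systolic_scale) * w


def _circle(cx: float, cy: float, r: float, n: int, phase_offset: float) -> tuple[tuple[float, float], ...]:
    theta = phase_offset + 2.0 * math.pi * np.arange(n) / n
    return tuple((cx + r * math.cos(t), cy + r * math.sin(t)) for t in theta)


def _ngon_area_factor(n: int) -> float:
    """Regular n-gon area / circumscribing disc area."""
    return n / (2.0 * math.pi) * math.sin(2.0 * math.pi / n)


def _slice_radii(spec: PhantomSpec) -> np.ndarray:
    """End-diastolic cavity radius multiplier per slice (1.0 for cylinders)."""
    if spec.shape is PhantomShape.HALF_ELLIPSOID:
        # slice midpoints of a half-ellipsoid of height n_slices·spacing
        c = spec.n_slices * spec.slice_spacing
        z = (np.arange(spec.n_slices) + 0.5) * spec.slice_spacing
        return np.sqrt(np.clip(1.0 - (z / c) ** 2, 0.0, None))
    return np.ones(spec.n_slices)


def make_ventricle_phantom(spec: PhantomSpec) -> tuple[ContourStack, dict[str, float]]:
    """Build a contour stack plus its closed-form volumetric ground truth.

    RV and LV are concentric ring pairs at separated centres; the RV
    epicardial ring plays the free wall (the septum is, by convention, part
    of the LV). Endocardial contours exist at every phase with the cavity
    area scaled by :func:`sinusoidal_phase_scales`; epicardial contours are
    drawn at end-diastole, where mass is measured.

    Ground-truth keys: rv_edv/rv_esv/rv_sv (mL), rv_ef (%), rv_mass/lv_mass
    (g), vmi, ed_phase, es_phase, and the same volumes for the polygonized
    contours (``*_poly``) so extraction can be checked exactly.
    """
    rng = np.random.default_rng(spec.seed)
    scales = sinusoidal_phase_scales(spec.n_phases, spec.es_phase, spec.systolic_scale)
    radii_mult = _slice_radii(spec)
    factor = _ngon_area_factor(spec.vertex_count)

    contours: list[SliceContour] = []
    rv_c, lv_c = (-2.5 * spec.rv_radius, 0.0), (2.5 * spec.lv_radius, 0.0)

    def add(structure: Structure, s: int, p: int, centre: tuple[float, float], r: float) -> None:
        contours.append(
            SliceContour(
                structure=structure,
                slice_index=s,
                phase_index=p,
                vertices=_circle(centre[0], centre[1], r, spec.vertex_count,
                                 rng.uniform(0, 2 * math.pi)),
            )
        )

    for s in range(spec.n_slices):
        rv_r_ed = spec.rv_radius * radii_mult[s]
        lv_r_ed = spec.lv_radius * radii_mult[s]
        if rv_r_ed <= 0 or lv_r_ed <= 0:
            continue
        for p in range(spec.n_phases):
            k = math.sqrt(scales[p])
            add(Structure.RV_ENDO, s, p, rv_c, rv_r_ed * k)
            add(Structure.LV_ENDO, s, p, lv_c, lv_r_ed * k)
        add(Structure.RV_EPI, s, 0, rv_c, rv_r_ed + spec.rv_wall)
        add(Structure.LV_EPI, s, 0, lv_c, lv_r_ed + spec.lv_wall)

    stack = ContourStack(
        patient_id=f"phantom-{spec.shape.value.lower()}-{spec.seed}",
        slice_spacing=spec.slice_spacing,
        n_slices=spec.n_slices,
        n_phases=spec.n_phases,
        contours=contours,
    )

    h = spec.slice_spacing
    rv_areas = math.pi * (spec.rv_radius * radii_mult) ** 2
    lv_areas = math.pi * (spec.lv_radius * radii_mult) ** 2
    rv_epi_areas = math.pi * (spec.rv_radius * radii_mult + spec.rv_wall) ** 2
    lv_epi_areas = math.pi * (spec.lv_radius * radii_mult + spec.lv_wall) ** 2
    keep = radii_mult > 0
    rv_edv = float(rv_areas[keep].sum() * h) / MM3_PER_ML
    rv_esv = rv_edv * spec.systolic_scale
    rv_mass = float((rv_epi_areas - rv_areas)[keep].sum() * h) / MM3_PER_ML * MYOCARDIAL_DENSITY_G_PER_CM3
    lv_mass = float((lv_epi_areas - lv_areas)[keep].sum() * h) / MM3_PER_ML * MYOCARDIAL_DENSITY_G_PER_CM3

    truth = {
        "rv_edv": rv_edv,
        "rv_esv": rv_esv,
        "rv_sv": rv_edv - rv_esv,
        "rv_ef": 100.0 * (1.0 - spec.systolic_scale),
        "rv_mass": rv_mass,
        "lv_mass": lv_mass,
        "vmi": rv_mass / lv_mass,
        "ed_phase": 0,
        "es_phase": spec.es_phase,
        # what the polygonized contours actually enclose (n-gon deficit)
        "rv_edv_poly": rv_edv * factor,
        "rv_esv_poly": rv_esv * factor,
        "polygon_area_factor": factor,
    }
    return stack, truth


@dataclass
class VelocityPhantomTruth:
    antegrade_ml_per_beat: float
    retrograde_ml_per_beat: float
    retrograde_flow_index: float  # L/min/m²
    retrograde_percent: float
    average_velocity: float  # cm/s
    systolic_area: float  # cm²
    diastolic_area: float  # cm²
    pa_rac: float  # percent


def make_velocity_phantom(
    antegrade_ml_per_beat: float = 80.0,
    retrograde_fraction: float = 0.1,
    rr_interval: float = 1.0,
    bsa: float = 2.0,
    n_frames: int = 20,
    grid: tuple[int, int] = (48, 48),
    pixel_area: float = 0.1,
    mean_velocity: float | None = None,
    area_pulsatility_pct: float = 0.0,
    seed: int = 0,
) -> tuple[VelocityFrameSeries, VelocityPhantomTruth]:
    """Velocity-map series whose per-beat volumes match the request exactly.

    A parabolic antegrade profile fills the first (systolic) half of the
    cycle with a sinusoidal temporal envelope; a uniform retrograde patch
    occupies half of the jet region during diastole. Both are rescaled so
    that the discrete antegrade volume equals ``antegrade_ml_per_beat`` and
    the retrograde volume equals ``retrograde_fraction`` times it.

    ``mean_velocity`` (cm/s), if given, sets the PA mask size so the
    cycle-averaged masked mean velocity comes out at that value (net volume
    / (RR × mask area)). ``area_pulsatility_pct`` modulates the mask area
    sinusoidally around its diastolic minimum by (max−min)/min percent;
    velocities stay inside the minimal mask so flows are unaffected.
    """
    if not 0 <= retrograde_fraction:
        raise ValueError("retrograde_fraction must be >= 0")
    ny, nx = grid
    yy, xx = np.mgrid[0:ny, 0:nx]
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    dist = np.hypot(yy - cy, xx - cx)
    order = np.argsort(dist, axis=None, kind="stable")

    n_sys = max(1, n_frames // 2)
    dt = rr_interval / n_frames
    env = np.zeros(n_frames)
    env[:n_sys] = np.sin(math.pi * (np.arange(n_sys) + 0.5) / n_sys)
    retro_env = np.zeros(n_frames)
    if retrograde_fraction > 0 and n_frames > n_sys:
        retro_env[n_sys:] = np.sin(math.pi * (np.arange(n_frames - n_sys) + 0.5) / (n_frames - n_sys))

    # per-frame flow (mL/s) is fixed by the volumes and temporal envelopes,
    # independent of the spatial discretization
    retro_target = antegrade_ml_per_beat * retrograde_fraction
    flows = antegrade_ml_per_beat * env / (env.sum() * dt)
    if retro_env.sum() > 0:
        flows = flows - retro_target * retro_env / (retro_env.sum() * dt)

    # mask-area modulation multipliers (diastolic minimum at frame 0)
    mod = 1.0 + (area_pulsatility_pct / 100.0) * 0.5 * (
        1.0 - np.cos(2 * math.pi * np.arange(n_frames) / n_frames)
    )
    if mean_velocity is not None:
        # cycle-mean masked velocity = mean_t flow_t / (n_min * mod_t * pixel_area)
        n_min = max(4, round(float(np.mean(flows / mod)) / (mean_velocity * pixel_area)))
    else:
        n_min = max(4, int(0.15 * nx * ny))
    areas_px = np.round(n_min * mod).astype(int)
    if areas_px.max() > nx * ny:
        raise ValueError("grid too small for requested mask area")

    # jet region: innermost 60% of the minimal mask, parabolic profile
    n_jet = max(3, int(0.6 * n_min))
    jet_idx = order[:n_jet]
    r_jet = dist.ravel()[jet_idx]
    profile = np.zeros(nx * ny)
    r_edge = r_jet.max() * 1.001
    profile[jet_idx] = 1.0 - (r_jet / r_edge) ** 2
    profile = profile.reshape(ny, nx)

    retro_region = np.zeros(nx * ny, dtype=bool)
    retro_region[jet_idx[: max(1, n_jet // 2)]] = True
    retro_region = retro_region.reshape(ny, nx)

    raw_ante = float(profile.sum() * env.sum() * pixel_area * dt)
    alpha = antegrade_ml_per_beat / raw_ante
    raw_retro = float(retro_region.sum() * retro_env.sum() * pixel_area * dt)
    beta = retro_target / raw_retro if raw_retro > 0 else 0.0

    frames = []
    flows = np.zeros(n_frames)
    for t in range(n_frames):
        vel = alpha * env[t] * profile - beta * retro_env[t] * retro_region
        mask = np.zeros((ny, nx), dtype=bool)
        mask.ravel()[order[: areas_px[t]]] = True
        frames.append((vel, mask))
        flows[t] = float(vel.sum()) * pixel_area  # mL/s (all velocity inside min mask)

    series = VelocityFrameSeries(
        frames=frames, pixel_area=pixel_area, rr_interval=rr_interval, bsa=bsa
    )
    areas_cm2 = areas_px * pixel_area
    truth = VelocityPhantomTruth(
        antegrade_ml_per_beat=antegrade_ml_per_beat,
        retrograde_ml_per_beat=retro_target,
        retrograde_flow_index=retro_target / 1000.0 * (60.0 / rr_interval) / bsa,
        retrograde_percent=100.0 * retrograde_fraction,
        average_velocity=float(np.mean(flows / areas_cm2)),
        systolic_area=float(areas_cm2.max()),
        diastolic_area=float(areas_cm2.min()),
        pa_rac=100.0 * (areas_cm2.max() - areas_cm2.min()) / areas_cm2.min(),
    )
    return series, truth
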