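"""Phase-contrast pulmonary artery flow quantification.

Inputs are time-resolved through-plane velocity maps (cm/s) with a
pulmonary-artery region mask per cardiac frame, a pixel area (cm²), the RR
interval (s) and the patient's BSA (m²). Antegrade flow is positive by
convention. Frames are treated as uniform bins of the cardiac cycle
(retrospective gating), so each frame lasts rr_interval / n_frames and
per-beat volumes are plain sums over frames — no trapezoidal weighting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import EmptyRoiError
from .units import ML_PER_L, S_PER_MIN


@dataclass
class VelocityFrameSeries:
    """One cardiac cycle of velocity maps with PA masks.

    ``frames`` is an ordered list of (velocity_map, pa_mask) pairs; all maps
    share dimensions and every mask must be non-empty.
    """

    frames: list[tuple[np.ndarray, np.ndarray]]
    pixel_area: float  # cm²
    rr_interval: float  # s
    bsa: float  # m²

    def __post_init__(self) -> None:
        if not self.frames:
            raise EmptyRoiError("a velocity series needs at least one frame")
        if self.rr_interval <= 0:
            raise ValueError("rr_interval must be > 0 s")
        if self.pixel_area <= 0:
            raise ValueError("pixel_area must be > 0 cm²")
        shape = np.asarray(self.frames[0][0]).shape
        norm = []
        for i, (vel, mask) in enumerate(self.frames):
            vel = np.asarray(vel, dtype=float)
            mask = np.asarray(mask, dtype=bool)
            if vel.shape != shape or mask.shape != shape:
                raise ValueError(f"frame {i}: velocity/mask shape mismatch")
            if not mask.any():
                raise EmptyRoiError(f"frame {i}: PA mask is empty")
            norm.append((vel, mask))
        self.frames = norm

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def frame_duration(self) -> float:
        """Seconds per frame under uniform retrospective gating."""
        return self.rr_interval / self.n_frames


@dataclass
class FlowResult:
    flow_per_phase: list[float]  # mL/s per frame
    average_velocity: float  # cm/s
    retrograde_flow_index: float  # L/min/m²
    retrograde_percent: float  # percent (NaN if antegrade volume is zero)
    systolic_area: float  # cm² (cycle maximum of mask area)
    diastolic_area: float  # cm² (cycle minimum)
    pa_rac: float  # percent, (max-min)/min


def frame_flow(velocity_map: np.ndarray, pa_mask: np.ndarray, pixel_area: float) -> float:
    """Instantaneous flow through the masked ROI, mL/s.

    Sum of velocity (cm/s) × pixel area (cm²) over masked pixels; cm³/s ≡
    mL/s. Antegrade velocities are positive, so retrograde pixels subtract.
    """
    mask = np.asarray(pa_mask, dtype=bool)
    if not mask.any():
        raise EmptyRoiError("PA mask is empty")
    vel = np.asarray(velocity_map, dtype=float)
    return float(vel[mask].sum() * pixel_area)


def average_velocity(series: VelocityFrameSeries) -> float:
    """Mean over frames of the mean masked velocity per frame, cm/s."""
    per_frame = [float(vel[mask].mean()) for vel, mask in series.frames]
    return float(np.mean(per_frame))


def _beat_volumes(series: VelocityFrameSeries) -> tuple[float, float]:
    """(antegrade, retrograde) volume per beat in mL; both non-negative."""
    dt = series.frame_duration
    ante = 0.0
    retro = 0.0
    for vel, mask in series.frames:
        v = vel[mask]
        ante += float(v[v > 0].sum()) * series.pixel_area * dt
        retro += float(-v[v < 0].sum()) * series.pixel_area * dt
    return ante, retro


def retrograde_metrics(series: VelocityFrameSeries) -> tuple[float, float]:
    """(retrograde flow index L/min/m², retrograde percent of antegrade volume).

    Retrograde volume per beat is the summed magnitude of negative-velocity
    pixel flow times the frame duration; the index converts it to L/min
    (60/rr beats per minute) and divides by BSA. The percent uses the
    antegrade volume per beat as denominator; if no antegrade flow exists the
    percent is NaN (undefined marker) while the index is still returned.
    """
    ante, retro = _beat_volumes(series)
    index = retro / ML_PER_L * (S_PER_MIN / series.rr_interval) / series.bsa
    percent = 100.0 * retro / ante if ante > 0 else math.nan
    return index, percent


def pa_area_pulsatility(series: VelocityFrameSeries) -> tuple[float, float, float]:
    """(systolic area, diastolic area, PA relative area change percent).

    Areas are mask pixel counts × pixel area; systolic is the cycle maximum,
    diastolic the minimum. The relative area change uses the *minimum* area
    as denominator, 100·(max − min)/min — unlike RVRAC which divides by the
    diastolic (larger) area.
    """
    if series.n_frames < 2:
        raise ValueError("area pulsatility needs >= 2 frames")
    areas = [float(mask.sum()) * series.pixel_area for _, mask in series.frames]
    a_max, a_min = max(areas), min(areas)
    return a_max, a_min, 100.0 * (a_max - a_min) / a_min


def flow_analysis(series: VelocityFrameSeries) -> FlowResult:
    """All phase-contrast indices for one series."""
    sys_area, dia_area, rac = pa_area_pulsatility(series)
    index, percent = retrograde_metrics(series)
    return FlowResult(
        flow_per_phase=[frame_flow(v, m, series.pixel_area) for v, m in series.frames],
        average_velocity=average_velocity(series),
        retrograde_flow_index=index,
        retrograde_percent=percent,
        systolic_area=sys_area,
        diastolic_area=dia_area,
        pa_rac=rac,
    )
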