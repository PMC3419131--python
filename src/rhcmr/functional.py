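"""Longitudinal, transverse, area and eccentricity indices of RV function.

All inputs are manual annotations: 4-chamber landmarks (tricuspid annulus,
RV apex, septal and free-wall mid-points, RV cavity area) at end-diastole and
end-systole, and the two perpendicular LV minor-axis diameters on the
mid-chamber short-axis slice. Landmark coordinates are in mm; excursions are
reported in cm, fractional measures in percent.

Sign convention: excursions are ED minus ES, so normal systolic shortening is
positive and paradoxical motion comes out negative. Values are returned
as-is, never clamped — threshold rules operate on the signed values.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

from .errors import InvalidLandmarksError
from .units import CM_PER_MM


class CinePhase(str, enum.Enum):
    ED = "ED"
    ES = "ES"


@dataclass(frozen=True)
class FourChamberFrame:
    """Landmarks on one 4-chamber cine frame (coordinates in mm, area in mm²)."""

    phase: CinePhase
    tricuspid_annulus: tuple[float, float]
    rv_apex: tuple[float, float]
    septal_mid: tuple[float, float]
    freewall_mid: tuple[float, float]
    rv_area: float

    def __post_init__(self) -> None:
        if self.rv_area <= 0:
            raise InvalidLandmarksError("rv_area must be > 0 mm²")
        if _dist(self.tricuspid_annulus, self.rv_apex) == 0.0:
            raise InvalidLandmarksError("tricuspid annulus coincides with RV apex")


@dataclass(frozen=True)
class MidSliceDiameters:
    """LV minor-axis diameters (mm) on the mid-chamber short-axis slice.

    ``d1`` is perpendicular to the inter-ventricular septum, ``d2`` parallel
    to it.
    """

    phase: CinePhase
    d1: float
    d2: float

    def __post_init__(self) -> None:
        if self.d1 <= 0 or self.d2 <= 0:
            raise InvalidLandmarksError("diameters must be > 0 mm")


@dataclass
class FunctionalMetrics:
    """The full set of 4-chamber / mid-slice functional indices."""

    tapse: float  # cm
    f_taad: float  # percent
    sfd_excursion: float  # cm
    f_sfd: float  # percent
    rvrac: float  # percent
    sei: float  # systolic eccentricity, ratio
    dei: float  # diastolic eccentricity, ratio


def _dist(a: tuple[float, float], b: tuple[float, float]) -> float:
    return float(np.hypot(a[0] - b[0], a[1] - b[1]))


def _taad_mm(frame: FourChamberFrame) -> float:
    """Tricuspid annulus–apex distance, mm."""
    return _dist(frame.tricuspid_annulus, frame.rv_apex)


def _sfd_mm(frame: FourChamberFrame) -> float:
    """Septum–free-wall distance at mid-ventricle, mm."""
    d = _dist(frame.septal_mid, frame.freewall_mid)
    if d == 0.0:
        raise InvalidLandmarksError("septal and free-wall mid-points coincide")
    return d


def tapse(ed: FourChamberFrame, es: FourChamberFrame) -> float:
    """Tricuspid annular plane systolic excursion, cm.

    The change of the annulus–apex distance between end-diastole and
    end-systole; negative for paradoxical motion.
    """
    return (_taad_mm(ed) - _taad_mm(es)) * CM_PER_MM


def fractional_taad(ed: FourChamberFrame, es: FourChamberFrame) -> float:
    """TAPSE as a percentage of the end-diastolic annulus–apex distance."""
    taad_ed_cm = _taad_mm(ed) * CM_PER_MM
    return 100.0 * tapse(ed, es) / taad_ed_cm


def septum_freewall_excursion(
    ed: FourChamberFrame, es: FourChamberFrame
) -> tuple[float, float]:
    """Transverse function: (SFD excursion cm, fractional SFD percent).

    SFD is the perpendicular septum–free-wall distance at the mid-point
    between apex and base; the excursion is ED minus ES, the fractional form
    is the excursion as a percentage of the ED distance.
    """
    sfd_ed = _sfd_mm(ed) * CM_PER_MM
    sfd_es = _sfd_mm(es) * CM_PER_MM
    excursion = sfd_ed - sfd_es
    return excursion, 100.0 * excursion / sfd_ed


def rv_relative_area_change(ed: FourChamberFrame, es: FourChamberFrame) -> float:
    """RVRAC, percent: 100·(diastolic area − systolic area)/diastolic area."""
    return 100.0 * (ed.rv_area - es.rv_area) / ed.rv_area


def eccentricity_index(d: MidSliceDiameters) -> float:
    """LV eccentricity index D2/D1 (parallel over perpendicular to the septum).

    The same formula serves the systolic (sEI) and diastolic (dEI) frames;
    values above 1.2 indicate septal flattening.
    """
    return d.d2 / d.d1


def functional_metrics(
    ed: FourChamberFrame,
    es: FourChamberFrame,
    diameters_ed: MidSliceDiameters,
    diameters_es: MidSliceDiameters,
) -> FunctionalMetrics:
    """Bundle every functional index for one patient."""
    sfd_cm, f_sfd = septum_freewall_excursion(ed, es)
    return FunctionalMetrics(
        tapse=tapse(ed, es),
        f_taad=fractional_taad(ed, es),
        sfd_excursion=sfd_cm,
        f_sfd=f_sfd,
        rvrac=rv_relative_area_change(ed, es),
        sei=eccentricity_index(diameters_es),
        dei=eccentricity_index(diameters_ed),
    )
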