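"""Short-axis contour volumetry, myocardial mass and ventricular mass index.

Cavity volumes follow Simpson slice summation: the area enclosed by each
short-axis endocardial contour is multiplied by the effective inter-slice
distance and summed from base to apex. Myocardial volume per slice is the
epicardial minus the endocardial area times the slice distance; mass is that
volume times the density of myocardium (1.05 g/cm³). The inter-ventricular
septum is counted with the left ventricle: the RV epicardial contour is
expected to trace only the RV free wall, so the RV wall ring it bounds
excludes the septum by construction.

End-diastole is the first cine phase of the R-wave-triggered acquisition
(phase 0); end-systole is the phase with the smallest summed endocardial
cavity volume, ties broken by the earliest phase.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from shapely.geometry import Polygon

from .errors import (
    InconsistentContourError,
    InsufficientPhasesError,
    InvalidAnthropometryError,
    InvalidBsaError,
    InvalidContourError,
    MissingStructureError,
)
from .units import MM3_PER_ML, MYOCARDIAL_DENSITY_G_PER_CM3


class Structure(str, enum.Enum):
    """Traced cardiac boundary."""

    RV_ENDO = "RV_ENDO"
    RV_EPI = "RV_EPI"
    LV_ENDO = "LV_ENDO"
    LV_EPI = "LV_EPI"


def polygon_area(vertices: Sequence[Sequence[float]]) -> float:
    """Absolute (orientation-independent) area of a simple polygon, mm².

    Parameters
    ----------
    vertices
        Ordered (x, y) points in mm, at least three. The polygon must be
        simple (non-self-intersecting).

    Returns
    -------
    float
        Enclosed area in mm² (shoelace magnitude).

    Raises
    ------
    InvalidContourError
        Fewer than 3 vertices, a self-intersecting outline, or zero area.
    """
    pts = np.asarray(vertices, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise InvalidContourError(
            f"a contour needs >= 3 (x, y) vertices, got shape {pts.shape}"
        )
    poly = Polygon(pts)
    if not poly.is_valid or not poly.is_simple:
        raise InvalidContourError("contour polygon is self-intersecting or degenerate")
    area = float(poly.area)
    if area <= 0.0:
        raise InvalidContourError("contour encloses zero area")
    return area


@dataclass(frozen=True)
class SliceContour:
    """One traced boundary on one short-axis slice at one cine phase."""

    structure: Structure
    slice_index: int
    phase_index: int
    vertices: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if self.slice_index < 0 or self.phase_index < 0:
            raise InvalidContourError("slice_index and phase_index must be >= 0")
        object.__setattr__(
            self, "vertices", tuple((float(x), float(y)) for x, y in self.vertices)
        )
        polygon_area(self.vertices)  # validates simplicity / area > 0

    @property
    def area(self) -> float:
        """Enclosed area, mm²."""
        return polygon_area(self.vertices)


@dataclass
class ContourStack:
    """All segmented contours for one patient across slices, phases, structures.

    ``slice_spacing`` is the effective inter-slice distance in mm (slice
    thickness plus gap; 10 mm for an 8 mm slice with a 2 mm gap).
    """

    patient_id: str
    slice_spacing: float
    n_slices: int
    n_phases: int
    contours: list[SliceContour] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.slice_spacing <= 0:
            raise InvalidContourError("slice_spacing must be > 0 mm")
        seen: set[tuple[Structure, int, int]] = set()
        for c in self.contours:
            key = (c.structure, c.slice_index, c.phase_index)
            if key in seen:
                raise InvalidContourError(
                    f"duplicate contour for {c.structure.value} "
                    f"slice {c.slice_index} phase {c.phase_index}"
                )
            seen.add(key)

    def get(self, structure: Structure, slice_index: int, phase_index: int) -> SliceContour | None:
        for c in self.contours:
            if (
                c.structure == structure
                and c.slice_index == slice_index
                and c.phase_index == phase_index
            ):
                return c
        return None

    def select(self, structure: Structure, phase_index: int) -> list[SliceContour]:
        return [
            c
            for c in self.contours
            if c.structure == structure and c.phase_index == phase_index
        ]

    def phases_with(self, structure: Structure) -> list[int]:
        return sorted({c.phase_index for c in self.contours if c.structure == structure})


@dataclass
class VolumetricsResult:
    """Cavity volumes, function and mass derived from one contour stack."""

    rv_edv: float  # mL
    rv_esv: float  # mL
    rv_sv: float  # mL
    rv_ef: float  # percent
    lv_mass: float  # g
    rv_mass: float  # g
    rv_edvi: float  # mL/m²
    rv_svi: float  # mL/m²
    rv_mass_index: float  # g/m²
    vmi: float  # RV mass / LV mass, dimensionless
    ed_phase: int
    es_phase: int


def stack_volume(stack: ContourStack, structure: Structure, phase_index: int) -> float:
    """Simpson slice-summation volume for one structure at one phase, mL.

    volume = Σ over slices of contour area × slice spacing. Slices without a
    contour contribute zero (no extrapolation at base or apex).
    """
    contours = stack.select(structure, phase_index)
    if not contours:
        raise MissingStructureError(
            f"no {structure.value} contours at phase {phase_index} "
            f"for patient {stack.patient_id!r}"
        )
    total_mm3 = sum(c.area for c in contours) * stack.slice_spacing
    return total_mm3 / MM3_PER_ML


def select_ed_es_phases(stack: ContourStack, structure: Structure) -> tuple[int, int]:
    """(end-diastolic, end-systolic) phase indices for one endocardial structure.

    ED is phase 0 (first cine phase after the R-wave trigger). ES is the phase
    whose summed cavity volume is smallest; ties go to the earliest phase.
    """
    phases = stack.phases_with(structure)
    if len(phases) < 2:
        raise InsufficientPhasesError(
            f"need endocardial contours in >= 2 phases for {structure.value}, "
            f"found {len(phases)}"
        )
    volumes = {p: stack_volume(stack, structure, p) for p in phases}
    es_phase = min(phases, key=lambda p: (volumes[p], p))
    return 0, es_phase


def _myocardial_mass(stack: ContourStack, endo: Structure, epi: Structure, phase: int) -> float:
    """Wall mass in g at one phase: Σ(epi − endo area)·spacing × 1.05 g/cm³."""
    epi_contours = {c.slice_index: c for c in stack.select(epi, phase)}
    endo_contours = {c.slice_index: c for c in stack.select(endo, phase)}
    if not epi_contours:
        raise MissingStructureError(
            f"no {epi.value} contours at phase {phase} for patient {stack.patient_id!r}"
        )
    wall_mm3 = 0.0
    for idx, epi_c in epi_contours.items():
        endo_area = endo_contours[idx].area if idx in endo_contours else 0.0
        if epi_c.area < endo_area:
            raise InconsistentContourError(
                f"{epi.value} area < {endo.value} area on slice {idx} phase {phase}"
            )
        wall_mm3 += (epi_c.area - endo_area) * stack.slice_spacing
    return wall_mm3 / MM3_PER_ML * MYOCARDIAL_DENSITY_G_PER_CM3


def ventricular_volumetrics(stack: ContourStack, bsa: float) -> VolumetricsResult:
    """Full volumetric work-up of one contour stack.

    RV end-diastolic and end-systolic volumes come from slice summation at the
    ED/ES phases picked on the RV endocardium; stroke volume and ejection
    fraction follow by definition (SV = EDV − ESV, EF = 100·SV/EDV). Masses
    are measured at end-diastole. BSA-indexed variants divide by ``bsa`` (m²);
    VMI is RV mass over LV mass.

    Raises
    ------
    InvalidBsaError
        ``bsa`` <= 0.
    InconsistentContourError
        Any slice where the epicardial area is below the endocardial area.
    """
    if bsa <= 0:
        raise InvalidBsaError(f"bsa must be > 0 m², got {bsa}")
    ed_phase, es_phase = select_ed_es_phases(stack, Structure.RV_ENDO)
    rv_edv = stack_volume(stack, Structure.RV_ENDO, ed_phase)
    rv_esv = stack_volume(stack, Structure.RV_ENDO, es_phase)
    rv_sv = rv_edv - rv_esv
    rv_ef = 100.0 * rv_sv / rv_edv if rv_edv > 0 else math.nan

    rv_mass = _myocardial_mass(stack, Structure.RV_ENDO, Structure.RV_EPI, ed_phase)
    lv_mass = _myocardial_mass(stack, Structure.LV_ENDO, Structure.LV_EPI, ed_phase)

    return VolumetricsResult(
        rv_edv=rv_edv,
        rv_esv=rv_esv,
        rv_sv=rv_sv,
        rv_ef=rv_ef,
        lv_mass=lv_mass,
        rv_mass=rv_mass,
        rv_edvi=rv_edv / bsa,
        rv_svi=rv_sv / bsa,
        rv_mass_index=rv_mass / bsa,
        vmi=rv_mass / lv_mass if lv_mass > 0 else math.nan,
        ed_phase=ed_phase,
        es_phase=es_phase,
    )


def bsa_from_height_weight(height_cm: float, weight_kg: float) -> float:
    """Body surface area (m²) by the Du Bois formula.

    BSA = 0.007184 · height^0.725 · weight^0.425 with height in cm and weight
    in kg.
    """
    if height_cm <= 0 or weight_kg <= 0:
        raise InvalidAnthropometryError(
            f"height and weight must be > 0, got {height_cm} cm / {weight_kg} kg"
        )
    return 0.007184 * height_cm**0.725 * weight_kg**0.425
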