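"""Contour volumetry: shoelace areas, Simpson slice summation, masses, BSA."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rhcmr.errors import (
    InconsistentContourError,
    InsufficientPhasesError,
    InvalidAnthropometryError,
    InvalidBsaError,
    InvalidContourError,
    MissingStructureError,
)
from rhcmr.geometry import (
    ContourStack,
    SliceContour,
    Structure,
    bsa_from_height_weight,
    polygon_area,
    select_ed_es_phases,
    stack_volume,
    ventricular_volumetrics,
)
from rhcmr.synthetic import PhantomShape, PhantomSpec, make_ventricle_phantom


def circle(r, n=64, cx=0.0, cy=0.0):
    t = 2 * math.pi * np.arange(n) / n
    return tuple((cx + r * math.cos(a), cy + r * math.sin(a)) for a in t)


SQUARE = ((0.0, 0.0), (10.0, 0.0), (10.0, 10.0), (0.0, 10.0))


class TestPolygonArea:
    def test_unit_square(self):
        assert polygon_area(SQUARE) == pytest.approx(100.0)

    def test_orientation_independent(self):
        assert polygon_area(SQUARE[::-1]) == pytest.approx(100.0)

    def test_regular_64gon_close_to_disc(self):
        # closed-form n-gon area (n/2)·r²·sin(2π/n)
        expected = 64 / 2 * 100 * math.sin(2 * math.pi / 64)
        assert polygon_area(circle(10.0)) == pytest.approx(expected, rel=1e-9)
        assert polygon_area(circle(10.0)) == pytest.approx(math.pi * 100, rel=2e-3)

    @pytest.mark.parametrize(
        "bad",
        [
            ((0, 0), (1, 1)),  # too few vertices
            ((0, 0), (1, 1), (1, 0), (0, 1)),  # bow-tie self-intersection
        ],
    )
    def test_invalid_polygons_rejected(self, bad):
        with pytest.raises(InvalidContourError):
            polygon_area(bad)


def single_structure_stack(areas_by_phase, structure=Structure.RV_ENDO, spacing=10.0):
    """Stack with one slice per entry; each phase's circles have given total area."""
    contours = []
    n_phases = len(areas_by_phase)
    for p, area in enumerate(areas_by_phase):
        r = math.sqrt(area / math.pi)
        contours.append(
            SliceContour(structure=structure, slice_index=0, phase_index=p, vertices=circle(r, 256))
        )
    return ContourStack(
        patient_id="t", slice_spacing=spacing, n_slices=1, n_phases=n_phases, contours=contours
    )


class TestStackVolume:
    def test_cylinder_matches_analytic(self):
        contours = [
            SliceContour(Structure.RV_ENDO, s, 0, circle(20.0)) for s in range(10)
        ]
        stack = ContourStack("cyl", 10.0, 10, 1, contours)
        v = stack_volume(stack, Structure.RV_ENDO, 0)
        assert v == pytest.approx(math.pi * 400 * 100 / 1000, rel=3e-3)  # 125.66 mL

    def test_single_slice_is_area_times_spacing(self):
        stack = ContourStack(
            "one", 7.5, 1, 1, [SliceContour(Structure.LV_ENDO, 0, 0, SQUARE)]
        )
        assert stack_volume(stack, Structure.LV_ENDO, 0) == pytest.approx(100 * 7.5 / 1000)

    def test_half_ellipsoid_converges_to_closed_form(self):
        spec = PhantomSpec(
            shape=PhantomShape.HALF_ELLIPSOID,
            rv_radius=30.0,
            n_slices=80,
            slice_spacing=1.0,
            n_phases=2,
            es_phase=1,
            vertex_count=64,
        )
        stack, _ = make_ventricle_phantom(spec)
        analytic = 2 / 3 * math.pi * 30 * 30 * 80 / 1000
        assert stack_volume(stack, Structure.RV_ENDO, 0) == pytest.approx(analytic, rel=0.01)

    def test_missing_structure_raises(self):
        stack = ContourStack(
            "m", 10.0, 1, 1, [SliceContour(Structure.RV_ENDO, 0, 0, SQUARE)]
        )
        with pytest.raises(MissingStructureError):
            stack_volume(stack, Structure.LV_ENDO, 0)


class TestPhaseSelection:
    def test_argmin_picks_smallest_cavity(self):
        stack = single_structure_stack([100.0, 80.0, 50.0, 70.0])
        assert select_ed_es_phases(stack, Structure.RV_ENDO) == (0, 2)

    def test_tie_breaks_to_earliest_phase(self):
        stack = single_structure_stack([90.0, 90.0, 90.0])
        assert select_ed_es_phases(stack, Structure.RV_ENDO) == (0, 0)

    def test_sinusoidal_phantom_minimum_recovered(self):
        spec = PhantomSpec(n_phases=20, es_phase=7)
        stack, truth = make_ventricle_phantom(spec)
        assert select_ed_es_phases(stack, Structure.RV_ENDO) == (0, 7)
        assert truth["es_phase"] == 7

    def test_single_phase_raises(self):
        stack = single_structure_stack([100.0])
        with pytest.raises(InsufficientPhasesError):
            select_ed_es_phases(stack, Structure.RV_ENDO)


class TestVentricularVolumetrics:
    def test_phantom_recovery_within_polygonization_error(self, cylinder_phantom):
        stack, truth = cylinder_phantom
        res = ventricular_volumetrics(stack, bsa=2.0)
        assert res.rv_edv == pytest.approx(truth["rv_edv"], rel=0.005)
        assert res.rv_ef == pytest.approx(truth["rv_ef"], abs=0.1)
        assert res.rv_mass == pytest.approx(truth["rv_mass"], rel=0.005)
        assert res.vmi == pytest.approx(truth["vmi"], rel=0.005)
        assert (res.ed_phase, res.es_phase) == (0, truth["es_phase"])

    def test_definitional_identities(self, cylinder_phantom):
        stack, _ = cylinder_phantom
        res = ventricular_volumetrics(stack, bsa=1.8)
        assert res.rv_sv == pytest.approx(res.rv_edv - res.rv_esv, abs=1e-12)
        assert res.rv_ef == pytest.approx(100 * res.rv_sv / res.rv_edv, abs=1e-9)
        assert res.rv_edvi == pytest.approx(res.rv_edv / 1.8)
        assert res.rv_svi == pytest.approx(res.rv_sv / 1.8)
        assert res.rv_mass_index == pytest.approx(res.rv_mass / 1.8)
        assert res.vmi == pytest.approx(res.rv_mass / res.lv_mass)

    def test_mass_equals_wall_volume_times_density_exactly(self, cylinder_phantom):
        stack, _ = cylinder_phantom
        res = ventricular_volumetrics(stack, bsa=2.0)
        wall = stack_volume(stack, Structure.RV_EPI, 0) - stack_volume(stack, Structure.RV_ENDO, 0)
        assert res.rv_mass == pytest.approx(wall * 1.05, rel=1e-12)

    def test_annular_shell_mass(self):
        # wall cross-section 300 mm² × 10 slices × 10 mm = 30 cm³ -> 31.5 g
        r_in = 10.0
        r_out = math.sqrt(300 / math.pi + r_in**2)
        contours = []
        for s in range(10):
            contours.append(SliceContour(Structure.RV_ENDO, s, 0, circle(r_in, 4096)))
            contours.append(SliceContour(Structure.RV_EPI, s, 0, circle(r_out, 4096)))
            contours.append(SliceContour(Structure.RV_ENDO, s, 1, circle(r_in * 0.8, 4096)))
            contours.append(SliceContour(Structure.LV_ENDO, s, 0, circle(5.0, 64, cx=50)))
            contours.append(SliceContour(Structure.LV_EPI, s, 0, circle(8.0, 64, cx=50)))
        stack = ContourStack("shell", 10.0, 10, 2, contours)
        res = ventricular_volumetrics(stack, bsa=2.0)
        assert res.rv_mass == pytest.approx(31.5, rel=2e-3)

    def test_epicardium_smaller_than_endocardium_rejected(self):
        contours = [
            SliceContour(Structure.RV_ENDO, 0, 0, circle(20.0)),
            SliceContour(Structure.RV_ENDO, 0, 1, circle(15.0)),
            SliceContour(Structure.RV_EPI, 0, 0, circle(10.0)),
            SliceContour(Structure.LV_ENDO, 0, 0, circle(5.0, cx=60)),
            SliceContour(Structure.LV_EPI, 0, 0, circle(8.0, cx=60)),
        ]
        stack = ContourStack("bad", 10.0, 1, 2, contours)
        with pytest.raises(InconsistentContourError):
            ventricular_volumetrics(stack, bsa=2.0)

    def test_invalid_bsa(self, cylinder_phantom):
        with pytest.raises(InvalidBsaError):
            ventricular_volumetrics(cylinder_phantom[0], bsa=0.0)


class TestRigidInvariance:
    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        dx=st.floats(-100, 100),
        dy=st.floats(-100, 100),
        theta=st.floats(0, 2 * math.pi),
    )
    def test_volume_and_mass_invariant_under_rigid_motion(self, dx, dy, theta):
        stack, _ = make_ventricle_phantom(PhantomSpec(n_slices=3, n_phases=2, es_phase=1, seed=5))
        c, s = math.cos(theta), math.sin(theta)
        moved = ContourStack(
            stack.patient_id,
            stack.slice_spacing,
            stack.n_slices,
            stack.n_phases,
            [
                SliceContour(
                    k.structure,
                    k.slice_index,
                    k.phase_index,
                    tuple((c * x - s * y + dx, s * x + c * y + dy) for x, y in k.vertices),
                )
                for k in stack.contours
            ],
        )
        r0 = ventricular_volumetrics(stack, bsa=2.0)
        r1 = ventricular_volumetrics(moved, bsa=2.0)
        assert r1.rv_edv == pytest.approx(r0.rv_edv, rel=1e-9)
        assert r1.rv_mass == pytest.approx(r0.rv_mass, rel=1e-9)


class TestBsa:
    def test_du_bois_reference_value(self):
        assert bsa_from_height_weight(180, 75) == pytest.approx(1.9424, abs=5e-4)

    def test_weight_power_law(self):
        assert bsa_from_height_weight(170, 140) / bsa_from_height_weight(170, 70) == pytest.approx(
            2**0.425, rel=1e-12
        )

    @pytest.mark.parametrize("h,w", [(0, 70), (170, 0), (-1, 70)])
    def test_nonpositive_inputs_rejected(self, h, w):
        with pytest.raises(InvalidAnthropometryError):
            bsa_from_height_weight(h, w)
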