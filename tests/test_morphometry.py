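import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from myoquant.cohort import DixonROI, SliceStack
from myoquant.morphometry import (
    dixon_imat,
    frustum_volume,
    l3_smi,
    mid_acsa,
    pcsa_eff,
    restrict_roi,
    volume_index,
)


def stack_from_areas(areas, t=4.0, muscle="quadriceps", start=0.0):
    positions = tuple(start + i * t for i in range(len(areas)))
    return SliceStack(muscle=muscle, positions=positions, thickness=t, areas=tuple(areas))


def cone_stack(r_prox, r_dist, n_slices, length):
    """Slices through a truncated cone with linearly tapering radius."""
    t = length / (n_slices - 1)
    radii = np.linspace(r_prox, r_dist, n_slices)
    return stack_from_areas(np.pi * radii**2, t=t)


def cone_volume(r_prox, r_dist, length):
    """Analytic truncated-cone volume: pi*h/3 * (R^2 + R*r + r^2)."""
    return math.pi * length / 3.0 * (r_prox**2 + r_prox * r_dist + r_dist**2)


class TestFrustumVolume:
    def test_constant_area_equals_cylinder(self):
        # 7 slices of 50 cm^2 at 4 cm spacing span 24 cm: V = 50 * 24
        stack = stack_from_areas([50.0] * 7, t=4.0)
        assert frustum_volume(stack) == pytest.approx(1200.0, rel=1e-14)

    def test_two_slice_closed_form(self):
        # (t/3) * (9 + sqrt(9*16) + 16) = (3/3) * 37
        stack = stack_from_areas([9.0, 16.0], t=3.0)
        assert frustum_volume(stack) == pytest.approx(37.0, rel=1e-14)

    @pytest.mark.parametrize("n_slices", [2, 5, 20, 200])
    def test_exact_for_linear_taper(self, n_slices):
        """Each inter-slice segment of a linear-radius taper is itself a
        frustum, so the estimator matches the analytic cone volume at any
        slice count."""
        v = frustum_volume(cone_stack(4.0, 1.0, n_slices, length=30.0))
        assert v == pytest.approx(cone_volume(4.0, 1.0, 30.0), rel=1e-9)

    def test_refinement_converges_from_above_for_convex_profiles(self):
        """For a quadratic (non-linear) area profile the frustum sum
        approaches the true integral monotonically as slices are added."""
        length = 30.0

        def volume_at(n):
            x = np.linspace(0.0, length, n)
            areas = 10.0 + 0.05 * (x - 15.0) ** 2
            return frustum_volume(stack_from_areas(areas, t=length / (n - 1)))

        estimates = [volume_at(n) for n in (4, 8, 16, 64, 256)]
        exact = 10.0 * length + 0.05 * (15.0**3 * 2) / 3.0
        errors = [abs(v - exact) for v in estimates]
        assert all(e1 > e2 for e1, e2 in zip(errors, errors[1:]))
        assert errors[-1] < 1e-3 * exact

    def test_invariant_under_slice_order_reversal(self):
        areas = [30.0, 45.0, 52.0, 48.0, 33.0]
        assert frustum_volume(stack_from_areas(areas)) == pytest.approx(
            frustum_volume(stack_from_areas(areas[::-1])), rel=1e-14
        )

    @given(
        areas=st.lists(st.floats(1.0, 120.0), min_size=2, max_size=10),
        t=st.floats(0.5, 6.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_segment_bracketing(self, areas, t):
        """Every frustum segment lies between t*min(A) and t*max(A)."""
        a = np.asarray(areas)
        seg = (t / 3.0) * (a[:-1] + np.sqrt(a[:-1] * a[1:]) + a[1:])
        lo = t * np.minimum(a[:-1], a[1:])
        hi = t * np.maximum(a[:-1], a[1:])
        assert np.all(seg >= lo * (1 - 1e-12))
        assert np.all(seg <= hi * (1 + 1e-12))
        total = frustum_volume(stack_from_areas(areas, t=t))
        assert lo.sum() * (1 - 1e-12) <= total <= hi.sum() * (1 + 1e-12)

    def test_trapezoid_option_differs_and_exceeds_frustum(self):
        stack = stack_from_areas([9.0, 16.0], t=3.0)
        trap = frustum_volume(stack, method="trapezoid")
        assert trap == pytest.approx(37.5)
        assert trap > frustum_volume(stack)  # AM-GM: trapezoid >= frustum

    def test_single_slice_rejected(self):
        with pytest.raises(ValueError, match="at least 2 slices"):
            frustum_volume(stack_from_areas([50.0]))

    def test_non_uniform_spacing_rejected_at_construction(self):
        with pytest.raises(ValueError, match="uniform"):
            SliceStack(
                muscle="quadriceps",
                positions=(0.0, 4.0, 9.0),
                thickness=4.0,
                areas=(10.0, 11.0, 12.0),
            )


class TestRestrictRoi:
    def test_distal_band_removed(self):
        # 10 slices spanning the landmarks exactly: the distal 20% band
        # holds 2 slices, so 8 survive
        stack = stack_from_areas([40.0] * 10, t=4.0, start=0.0)
        out = restrict_roi(stack, proximal_landmark=0.0, patella_proximal=36.0)
        # distal limit = 36 - 0.2*36 = 28.8 -> slices at 0..28
        assert out.n_slices == 8
        assert out.positions[-1] == 28.0
        assert out.roi_limits == (0.0, 28.8)

    def test_all_inside_is_identity(self):
        stack = stack_from_areas([40.0, 42.0, 41.0], t=4.0, start=10.0)
        out = restrict_roi(stack, proximal_landmark=0.0, patella_proximal=100.0)
        assert out.positions == stack.positions
        assert out.areas == stack.areas

    def test_landmarks_outside_stack_rejected(self):
        stack = stack_from_areas([40.0] * 5, t=4.0, start=20.0)
        with pytest.raises(ValueError, match="outside"):
            restrict_roi(stack, proximal_landmark=100.0, patella_proximal=200.0)

    def test_too_few_survivors_rejected(self):
        stack = stack_from_areas([40.0] * 5, t=4.0, start=0.0)
        with pytest.raises(ValueError, match="fewer than 2"):
            restrict_roi(stack, proximal_landmark=15.9, patella_proximal=20.5)


class TestIndices:
    def test_volume_index(self):
        assert volume_index(1200.0, 2.0) == pytest.approx(300.0)
        assert volume_index(1012.0, 1.71) == pytest.approx(346.09, abs=0.005)

    def test_l3_smi(self):
        assert l3_smi(120.0, 1.71) == pytest.approx(41.04, abs=0.005)
        assert l3_smi(100.0, 2.0) == pytest.approx(25.0)

    @pytest.mark.parametrize(
        "fn, args",
        [
            (volume_index, (0.0, 1.7)),
            (volume_index, (1000.0, 0.0)),
            (l3_smi, (-1.0, 1.7)),
            (l3_smi, (100.0, -2.0)),
        ],
    )
    def test_invalid_inputs(self, fn, args):
        with pytest.raises(ValueError):
            fn(*args)

    def test_mid_acsa_picks_nearest_slice(self):
        stack = stack_from_areas([30.0, 50.0, 45.0], t=4.0, start=16.0)
        assert mid_acsa(stack, mid_position=21.0) == 50.0  # slice at 20 cm
        assert mid_acsa(stack, mid_position=23.0) == 45.0  # slice at 24 cm


class TestDixon:
    @pytest.mark.parametrize(
        "fat, water, expected",
        [(50.0, 50.0, 50.0), (0.0, 80.0, 0.0), (10.5, 89.5, 10.5), (80.0, 0.0, 100.0)],
    )
    def test_fat_fraction(self, fat, water, expected):
        assert dixon_imat(DixonROI(fat, water)) == pytest.approx(expected, rel=1e-12)

    @given(
        fat=st.floats(0.01, 1e4),
        water=st.floats(0.01, 1e4),
        k=st.floats(1e-6, 1e6),
    )
    @settings(max_examples=200, deadline=None)
    def test_scale_invariance(self, fat, water, k):
        assert dixon_imat(DixonROI(k * fat, k * water)) == pytest.approx(
            dixon_imat(DixonROI(fat, water)), rel=1e-12
        )

    def test_from_maps_reduces_over_mask(self):
        fat = np.array([[10.0, 99.0], [10.0, 99.0]])
        water = np.array([[90.0, 0.0], [90.0, 0.0]])
        mask = np.array([[True, False], [True, False]])
        roi = DixonROI.from_maps(fat, water, mask)
        assert dixon_imat(roi) == pytest.approx(10.0)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="mask is empty"):
            DixonROI.from_maps(np.ones((2, 2)), np.ones((2, 2)), np.zeros((2, 2), dtype=bool))

    def test_zero_total_signal_rejected(self):
        with pytest.raises(ValueError):
            DixonROI(0.0, 0.0)


class TestPcsa:
    @pytest.mark.parametrize(
        "vol, lf, penn, exp_pcsa, exp_eff",
        [
            (100.0, 10.0, 0.0, 10.0, 10.0),
            (100.0, 10.0, 60.0, 10.0, 5.0),
            (450.0, 9.0, 14.0, 50.0, 48.51),
        ],
    )
    def test_values(self, vol, lf, penn, exp_pcsa, exp_eff):
        pcsa, eff = pcsa_eff(vol, lf, penn)
        assert pcsa == pytest.approx(exp_pcsa)
        assert eff == pytest.approx(exp_eff, abs=0.005)

    @given(
        vol=st.floats(50.0, 1000.0),
        lf=st.floats(4.0, 15.0),
        penn=st.floats(0.0, 45.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_effective_over_total_is_cosine(self, vol, lf, penn):
        pcsa, eff = pcsa_eff(vol, lf, penn)
        assert eff / pcsa == pytest.approx(math.cos(math.radians(penn)), rel=1e-12)

    def test_out_of_range_pennation_rejected(self):
        with pytest.raises(ValueError):
            pcsa_eff(100.0, 10.0, 90.0)
        with pytest.raises(ValueError):
            pcsa_eff(100.0, 10.0, -5.0)
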