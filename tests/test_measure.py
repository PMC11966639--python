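"""Angle measurement, axial circular statistics and fiber-field comparison."""

import numpy as np
import pytest
from scipy.special import i0, i1

import atriafiber as af
from atriafiber.fibers import local_axis
from atriafiber.measure import (
    MeasureError,
    agreement_fraction,
    axial_stats,
    dominant_angle,
    embed_measured,
    fiber_angle,
    fiber_diff,
)

E_L, E_N, E_T = local_axis((0, 0, 1), (1, 0, 0))


def _rows(*vs):
    return np.array(vs, dtype=float)


def _frames(n):
    return (
        np.tile(E_L, (n, 1)),
        np.tile(E_N, (n, 1)),
        np.tile(E_T, (n, 1)),
    )


class TestEmbedding:
    def test_in_plane_vector_is_unchanged(self):
        f_m = _rows(0.6 * E_L + 0.8 * E_N)
        f_D, n_D, s_D, mask = embed_measured(f_m, *_frames(1))
        assert not mask[0]
        assert np.allclose(f_D[0], 0.6 * E_L + 0.8 * E_N)
        assert np.allclose(s_D[0], E_T)

    def test_transmural_vector_is_masked(self):
        f_D, _, _, mask = embed_measured(_rows(E_T), *_frames(1))
        assert mask[0]

    def test_oblique_vector_projects_to_longitudinal(self):
        f_m = _rows((E_L + E_T) / np.sqrt(2))
        f_D, _, _, mask = embed_measured(f_m, *_frames(1))
        assert not mask[0]
        assert np.allclose(f_D[0], E_L)


class TestAngle:
    @pytest.mark.parametrize("vec,expect_deg", [
        (E_L, 0.0), (E_N, 90.0), (-E_L, 0.0), (-E_N, 90.0),
        ((E_L + E_N) / np.sqrt(2), 45.0),
        ((E_L - E_N) / np.sqrt(2), -45.0),
    ])
    def test_signed_axial_angle(self, vec, expect_deg):
        a = fiber_angle(_rows(vec), *_frames(1)[:2])
        assert np.degrees(a) == pytest.approx(expect_deg)

    def test_range_is_half_open(self, rng):
        v = rng.normal(size=(5000, 3))
        f_D, _, _, mask = embed_measured(v, *_frames(5000))
        a = fiber_angle(f_D, *_frames(5000)[:2])
        a = a[~mask]
        assert (a > -np.pi / 2).all() and (a <= np.pi / 2).all()


class TestDominantAngle:
    def test_constant_sample(self):
        d, _, _ = dominant_angle(np.radians([30.0] * 100))
        assert d == 30.0

    def test_modal_bin_wins(self):
        d, _, _ = dominant_angle(np.radians([-45.0] * 70 + [40.0] * 30))
        assert abs(d - (-45.0)) <= 5.0  # the bin containing the 70% mass

    def test_too_few_samples_flagged(self):
        d, _, _ = dominant_angle(np.radians([10.0] * 5), n_min=50)
        assert d is None

    def test_axial_von_mises_mode_recovered(self, rng):
        mu = np.radians(20.0)
        a = 0.5 * rng.vonmises(2 * mu, 8.0, size=5000)
        d, _, _ = dominant_angle(a)
        assert abs(d - 20.0) <= 10.0  # within one bin

    def test_matches_bruteforce_argmax(self, rng):
        for _ in range(20):
            a = rng.uniform(-np.pi / 2 + 1e-9, np.pi / 2, size=300)
            d, counts, centers = dominant_angle(a)
            # brute force: count samples per bin (c - 5, c + 5]
            deg = np.degrees(a)
            brute = []
            for c in centers:
                lo, hi = c - 5.0, c + 5.0
                x = deg if c < 90 else np.where(deg <= -85.0, deg + 180.0, deg)
                brute.append(((x > lo) & (x <= hi)).sum())
            assert counts.max() == max(brute)
            assert counts[list(centers).index(d)] == max(brute)

    def test_ties_break_toward_zero_then_negative(self):
        d, _, _ = dominant_angle(np.radians([-40.0] * 50 + [40.0] * 50))
        assert d == -40.0


class TestAxialStats:
    def test_constant_sample(self):
        m, sd, r = axial_stats(np.radians([25.0] * 10))
        assert np.degrees(m) == pytest.approx(25.0)
        assert sd == pytest.approx(0.0, abs=1e-7)
        assert r == pytest.approx(1.0)

    def test_wrap_through_the_axis(self):
        m, _, _ = axial_stats(np.radians([85.0, -85.0]))
        assert np.degrees(m) == pytest.approx(90.0)

    def test_uniform_sample_flagged(self, rng):
        m, sd, r = axial_stats(rng.uniform(-np.pi / 2, np.pi / 2, 10000))
        assert r < 0.05
        assert m is None

    def test_needs_two_samples(self):
        with pytest.raises(MeasureError):
            axial_stats([0.1])

    def test_sd_matches_von_mises_closed_form(self, rng):
        kappa = 20.0
        a = 0.5 * rng.vonmises(0.0, kappa, size=20000)
        _, sd, _ = axial_stats(a)
        sd_theory = np.sqrt(2 * (1 - i1(kappa) / i0(kappa))) / 2
        assert sd == pytest.approx(sd_theory, rel=0.05)


class TestDiffAndAgreement:
    def test_parallel_orthogonal_and_oblique(self, rng):
        f = rng.normal(size=(100, 3))
        f /= np.linalg.norm(f, axis=1, keepdims=True)
        assert np.allclose(fiber_diff(f, f), 0.0)
        assert np.allclose(fiber_diff(f, -f), 0.0)  # axial invariance
        # orthogonal pair
        g = np.cross(f, np.roll(f, 1, axis=0))
        g /= np.linalg.norm(g, axis=1, keepdims=True)
        assert np.allclose(fiber_diff(f, g), 1.0)

    def test_forty_five_degree_value(self):
        f = _rows(E_L)
        g = _rows((E_L + E_N) / np.sqrt(2))
        assert fiber_diff(f, g)[0] == pytest.approx(1 - np.cos(np.radians(45)))

    def test_signed_literal_form_available(self):
        f = _rows(E_L)
        assert fiber_diff(f, -f, axial=False)[0] == pytest.approx(2.0)

    def test_agreement_examples(self):
        d_same = np.zeros(100)
        assert agreement_fraction(d_same) == 100.0
        d_orth = np.ones(100)
        assert agreement_fraction(d_orth, threshold=0.99) == 0.0

    def test_half_offset_fixture(self):
        # half the nodes offset by exactly 30 degrees, threshold at 30 deg
        n = 200
        f = np.tile(E_L, (n, 1))
        g = f.copy()
        off = np.cos(np.radians(30)) * E_L + np.sin(np.radians(30)) * E_N
        g[: n // 2] = 1.001 * off  # just beyond the threshold
        g /= np.linalg.norm(g, axis=1, keepdims=True)
        d = fiber_diff(f, g)
        thr = 1 - np.cos(np.radians(30))
        pct = agreement_fraction(d, threshold=thr * 0.999)
        assert pct == pytest.approx(50.0, abs=1.0)

    def test_empty_mask_raises(self):
        with pytest.raises(MeasureError):
            agreement_fraction(np.zeros(5), np.zeros(5, dtype=bool))


def test_axial_invariance_end_to_end(la_run, rng):
    """Negating any subset of measured vectors changes nothing downstream."""
    _, bmap, frames, _ = la_run
    fm = af.make_ground_truth_fibers(
        frames, bmap, af.GroundTruthFiberSpec(kappa=20.0, seed=3, sign_flips=False)
    )
    flip = rng.random(fm.shape[0]) < 0.5
    fm2 = np.where(flip[:, None], -fm, fm)

    a1, m1, s1 = af.measure_fiber_field(fm, frames, bmap.label)
    a2, m2, s2 = af.measure_fiber_field(fm2, frames, bmap.label)
    assert np.allclose(a1[~m1], a2[~m2])
    for key in s1:
        assert s1[key].dominant_deg == s2[key].dominant_deg
        assert s1[key].sd_deg == pytest.approx(s2[key].sd_deg)

    f1 = fm / np.linalg.norm(fm, axis=1, keepdims=True)
    f2 = fm2 / np.linalg.norm(fm2, axis=1, keepdims=True)
    assert np.allclose(fiber_diff(f1, frames.f), fiber_diff(f2, frames.f))
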