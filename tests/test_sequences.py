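"""Waveform construction, discretisation and b-value computation."""

import numpy as np
import pytest

from myowalk.sequences import (GAMMA_UM, B_TO_S_MM2,
                               SequenceError, SequenceSpec, TABLE1,
                               build_waveform, bvalue, direction_set,
                               discretize, moments, table1_spec)


def lobe_scale(wave):
    """Per-order magnitude scale for residual-moment comparisons."""
    g = np.max(np.abs(wave.g))
    T = wave.total_time
    return g * T ** np.arange(1, 4)


class TestEchoCondition:
    @pytest.mark.parametrize("kind,gmax", list(TABLE1))
    def test_zeroth_moment_vanishes(self, kind, gmax):
        wave = build_waveform(table1_spec(kind, gmax), allow_residual=True)
        m = moments(wave)
        assert np.linalg.norm(m[0]) < 1e-9 * lobe_scale(wave)[0]

    def test_zero_gradient_waveform(self):
        spec = SequenceSpec("PGSE", 0.0, te=40.0, eps=0.5, Delta=20.0,
                            delta=10.0)
        wave = build_waveform(spec)
        assert np.all(wave.g == 0.0)
        b, _ = bvalue(wave)
        assert b == 0.0


class TestBValues:
    @pytest.mark.parametrize("kind", ["PGSE", "STEAM"])
    @pytest.mark.parametrize("gmax", [40, 80])
    def test_two_axis_b_is_450(self, kind, gmax):
        """Catalogued timings reproduce the protocol b-value within 1 %."""
        b, bmat = bvalue(build_waveform(table1_spec(kind, gmax)))
        assert b == pytest.approx(450.0, rel=0.01)
        assert np.allclose(bmat, bmat.T)

    def test_m2se_40_b_is_450(self):
        b, _ = bvalue(build_waveform(table1_spec("M2SE", 40)))
        assert b == pytest.approx(450.0, rel=0.01)

    def test_rectangular_closed_form(self):
        """eps -> 0 limit matches gamma^2 G^2 d^2 (Delta - d/3)."""
        spec = SequenceSpec("PGSE", 40.0, te=40.0, eps=0.0, Delta=20.0,
                            delta=10.0, direction=(1, 0, 0))
        b, _ = bvalue(build_waveform(spec))
        closed = (GAMMA_UM * 40.0 * 10.0) ** 2 * (20.0 - 10.0 / 3.0)
        assert b == pytest.approx(closed * B_TO_S_MM2, rel=1e-3)

    def test_b_scales_as_g_squared(self):
        spec = table1_spec("PGSE", 40)
        b1, _ = bvalue(build_waveform(spec))
        import dataclasses
        b2, _ = bvalue(build_waveform(
            dataclasses.replace(spec, g_max=2 * spec.g_max)))
        assert b2 / b1 == pytest.approx(4.0, rel=1e-9)

    def test_bmatrix_trace_and_cross_terms(self):
        """Two-axis encoding has equal on-axis terms and a cross term."""
        d = direction_set()[0]  # (1, 1, 0)/sqrt(2)
        _, bm = bvalue(build_waveform(table1_spec("PGSE", 40, direction=d)))
        assert bm[0, 0] == pytest.approx(bm[1, 1], rel=1e-12)
        assert bm[0, 1] == pytest.approx(bm[0, 0], rel=1e-9)
        assert bm[2, 2] == pytest.approx(0.0, abs=1e-9)


class TestM2SEMomentNulling:
    def test_first_and_second_moments_null(self):
        """Motion compensation: m1 and m2 vanish to < 1e-6 of lobe scale."""
        wave = build_waveform(table1_spec("M2SE", 40))
        m = moments(wave)
        scale = lobe_scale(wave)
        assert np.linalg.norm(m[1]) < 1e-6 * scale[1]
        assert np.linalg.norm(m[2]) < 1e-6 * scale[2]

    def test_infeasible_nulling_raises_with_residuals(self):
        with pytest.raises(SequenceError, match="residual"):
            build_waveform(table1_spec("M2SE", 80))

    def test_min_residual_fallback_still_refocused(self):
        wave = build_waveform(table1_spec("M2SE", 80), allow_residual=True)
        m = moments(wave)
        assert np.linalg.norm(m[0]) < 1e-9 * lobe_scale(wave)[0]


class TestDiscretisation:
    def test_timestep_rules(self):
        """0.1 ms cap on gradient, 1 ms cap off-gradient (STEAM)."""
        disc = discretize(build_waveform(table1_spec("STEAM", 40)))
        on = np.linalg.norm(disc.g_mid, axis=1) > 0
        assert disc.dt[on].max() <= 0.1 + 1e-12
        assert disc.dt[~on].max() <= 1.0 + 1e-12
        assert disc.dt[~on].max() > 0.5  # mixing-time steps stay coarse

    def test_minimum_step_count(self):
        disc = discretize(build_waveform(table1_spec("PGSE", 40)), n_min=1000)
        assert disc.n_steps >= 1000

    def test_idempotence(self):
        disc = discretize(build_waveform(table1_spec("PGSE", 40)))
        again = discretize(disc)
        assert np.array_equal(again.edges, disc.edges)

    def test_breakpoints_are_grid_points(self):
        wave = build_waveform(table1_spec("PGSE", 40))
        disc = discretize(wave)
        for t in wave.times:
            assert np.min(np.abs(disc.edges - t)) < 1e-9

    def test_refinement_does_not_change_b(self):
        wave = build_waveform(table1_spec("PGSE", 40))
        b1, _ = bvalue(wave, quad_dt=0.05)
        b2, _ = bvalue(wave, quad_dt=0.005)
        assert b1 == pytest.approx(b2, rel=1e-4)


class TestDirectionSet:
    def test_six_two_axis_unit_vectors(self):
        d = direction_set()
        assert d.shape == (6, 3)
        assert np.allclose(np.linalg.norm(d, axis=1), 1.0)
        assert np.all(np.sum(d != 0, axis=1) == 2)
        assert np.allclose(np.abs(d[d != 0]), 1 / np.sqrt(2))

    def test_pairwise_distinct_up_to_sign(self):
        d = direction_set()
        for i in range(6):
            for j in range(i + 1, 6):
                assert not np.allclose(d[i], d[j])
                assert not np.allclose(d[i], -d[j])

    def test_isotropic_scheme(self):
        d = direction_set()
        outer = np.einsum("ki,kj->ij", d, d)
        assert np.allclose(outer, 2.0 * np.eye(3))
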