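"""Attenuation, tensor fitting, scalar metrics and realisation stats."""

import numpy as np
import pytest

from myowalk.sequences import build_waveform, bvalue, direction_set, table1_spec
from myowalk.tensor import (AnalysisError, DiffusionTensor, SignalSet,
                            attenuation, cone_of_uncertainty, fit_tensor,
                            median_ci, realisation_stats, volume_weighted_D0)


def study_bmatrices():
    spec = table1_spec("PGSE", 40)
    return np.array([bvalue(build_waveform(spec.with_direction(d)))[1]
                     for d in direction_set()])


def tensor_of(diag, rotation=None):
    d = np.diag(diag).astype(float)
    if rotation is not None:
        d = rotation @ d @ rotation.T
    lam, vec = np.linalg.eigh(d)
    order = np.argsort(lam)[::-1]
    return DiffusionTensor(tensor=d, eigenvalues=lam[order],
                           eigenvectors=vec[:, order])


class TestAttenuation:
    def test_zero_phases(self):
        a, ai = attenuation(np.zeros(100))
        assert a == 1.0 and ai == 0.0

    def test_gaussian_phase_closed_form(self):
        """phi ~ N(0, s^2) gives A -> exp(-s^2/2)."""
        rng = np.random.default_rng(0)
        s = 1.3
        a, _ = attenuation(rng.normal(0.0, s, 400_000))
        assert a == pytest.approx(np.exp(-s * s / 2.0), abs=3e-3)

    def test_empty_voxel_raises(self):
        with pytest.raises(AnalysisError):
            attenuation(np.array([1.0]), np.array([False]))


class TestFitTensor:
    def test_forward_inverse_identity(self):
        """Noiseless signals from a known tensor are inverted exactly."""
        d0 = np.diag([1.5, 1.0, 0.5])
        bmats = study_bmatrices()
        atts = np.exp(-np.einsum("kij,ij->k", bmats * 1e-3, d0))
        fit = fit_tensor(SignalSet(atts, bmats, 1))
        assert np.allclose(fit.tensor, d0, atol=1e-10)
        assert fit.eigenvalues == pytest.approx([1.5, 1.0, 0.5], abs=1e-10)

    def test_rotated_tensor_recovered(self):
        th = np.deg2rad(30.0)
        rot = np.array([[np.cos(th), 0, np.sin(th)],
                        [0, 1, 0],
                        [-np.sin(th), 0, np.cos(th)]])
        d0 = rot @ np.diag([2.0, 0.8, 0.3]) @ rot.T
        bmats = study_bmatrices()
        atts = np.exp(-np.einsum("kij,ij->k", bmats * 1e-3, d0))
        fit = fit_tensor(SignalSet(atts, bmats, 1))
        assert np.allclose(fit.tensor, d0, atol=1e-10)
        # principal eigenvector along the rotated x axis (sign-free)
        e1 = fit.eigenvectors[:, 0]
        assert abs(e1 @ rot[:, 0]) == pytest.approx(1.0, abs=1e-9)

    def test_md_rotation_invariant(self):
        bmats = study_bmatrices()
        d0 = np.diag([1.5, 1.0, 0.5])
        for th in (0.2, 0.9):
            rot = np.array([[np.cos(th), -np.sin(th), 0],
                            [np.sin(th), np.cos(th), 0], [0, 0, 1]])
            d = rot @ d0 @ rot.T
            atts = np.exp(-np.einsum("kij,ij->k", bmats * 1e-3, d))
            fit = fit_tensor(SignalSet(atts, bmats, 1))
            assert fit.md == pytest.approx(1.0, abs=1e-10)

    def test_non_positive_attenuation_rejected(self):
        bmats = study_bmatrices()
        with pytest.raises(AnalysisError):
            fit_tensor(SignalSet(np.array([0.5, 0.4, -0.1, 0.3, 0.2, 0.6]),
                                 bmats, 1))


class TestScalarMetrics:
    def test_isotropic(self):
        t = tensor_of([1.0, 1.0, 1.0])
        assert t.fa == 0.0
        assert t.mode == 0.0
        assert t.md == 1.0

    def test_prolate(self):
        """lambda = (2, 1, 1): FA = sqrt(1/6), mode = +1 (linear)."""
        t = tensor_of([2.0, 1.0, 1.0])
        assert t.fa == pytest.approx(np.sqrt(1.0 / 6.0), abs=1e-12)
        assert t.mode == pytest.approx(1.0, abs=1e-9)

    def test_oblate(self):
        t = tensor_of([1.0, 1.0, 0.2])
        assert t.mode == pytest.approx(-1.0, abs=1e-9)

    def test_bounds(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            lam = np.sort(rng.uniform(0.05, 3.0, 3))[::-1]
            t = tensor_of(lam)
            assert 0.0 <= t.fa <= 1.0
            assert -1.0 <= t.mode <= 1.0


class TestVolumeWeightedD0:
    def test_convex_combination(self):
        assert volume_weighted_D0(0.25, 1.5, 3.0) == pytest.approx(1.875)
        assert volume_weighted_D0(1.0, 1.5, 3.0) == 3.0
        assert volume_weighted_D0(0.0, 1.5, 3.0) == 1.5

    def test_slope_per_percent(self):
        """d<D0>/dECV% = (D_EC - D_IC)/100 = 0.015 for 1.5/3.0."""
        d1 = volume_weighted_D0(0.20, 1.5, 3.0)
        d2 = volume_weighted_D0(0.30, 1.5, 3.0)
        assert (d2 - d1) / 10.0 == pytest.approx(0.015)


class TestMedianCI:
    def test_rank_2_9_for_ten(self):
        x = np.arange(1.0, 11.0)
        med, lo, hi = median_ci(x)
        assert med == 5.5
        assert lo == 2.0 and hi == 9.0  # coverage 97.9 %, nearest to 95 %

    def test_identical_values_collapse(self):
        med, lo, hi = median_ci(np.full(10, 3.3))
        assert med == lo == hi == 3.3

    def test_too_few_realisations(self):
        with pytest.raises(AnalysisError):
            median_ci(np.array([1.0, 2.0]))


class TestConeOfUncertainty:
    def test_identical_vectors(self):
        v = np.tile([0.0, 0.0, 1.0], (10, 1))
        assert cone_of_uncertainty(v) == 0.0

    def test_sign_flips_ignored(self):
        v = np.tile([0.0, 0.0, 1.0], (10, 1))
        v[::2] *= -1.0
        assert cone_of_uncertainty(v) == pytest.approx(0.0, abs=1e-6)

    def test_known_ten_degree_spread(self):
        """Vectors on a 10-degree ring around z reproduce a 10-degree
        cone."""
        phi = np.linspace(0.0, 2 * np.pi, 24, endpoint=False)
        th = np.deg2rad(10.0)
        v = np.column_stack([np.sin(th) * np.cos(phi),
                             np.sin(th) * np.sin(phi),
                             np.full_like(phi, np.cos(th))])
        assert cone_of_uncertainty(v) == pytest.approx(10.0, abs=0.2)

    def test_degenerate_plane_near_cap(self):
        """Vectors spread uniformly in a plane (degenerate eigenvalue
        pair): the cone approaches the 90-degree cap."""
        phi = np.linspace(0.0, np.pi, 36, endpoint=False)
        v = np.column_stack([np.cos(phi), np.sin(phi), np.zeros_like(phi)])
        assert cone_of_uncertainty(v) > 60.0


class TestRealisationStats:
    def test_collapsed_for_identical_tensors(self):
        tensors = [tensor_of([1.5, 1.0, 0.5]) for _ in range(10)]
        st = realisation_stats(tensors)
        s = st.scalars["md"]
        assert s["median"] == s["ci_low"] == s["ci_high"] == 1.0
        assert st.cones["dE1"] == 0.0

    def test_ci_brackets_median(self):
        rng = np.random.default_rng(1)
        tensors = [tensor_of(np.sort(rng.uniform(0.5, 2.0, 3))[::-1])
                   for _ in range(10)]
        st = realisation_stats(tensors)
        for s in st.scalars.values():
            assert s["ci_low"] <= s["median"] <= s["ci_high"]
        for cone in st.cones.values():
            assert 0.0 <= cone <= 90.0
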