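"""Forward model, dipole fitting and component-rejection heuristics."""

import numpy as np
import pytest

from gaitdecode.headmodel import (Dipole, DipoleFit, DomainError, HeadModel,
                                  Montage, detect_eye_components, dipole_gain,
                                  fit_single_dipole, forward_potentials,
                                  homogeneous_sphere_potentials,
                                  reject_components_by_dipole)


class TestMontage:
    def test_left_right_pairs_mirror_in_y(self, montage):
        pos = {lbl: p for lbl, p in zip(montage.labels, montage.positions)}
        for left, right in [("C3", "C4"), ("Fp1", "Fp2"), ("P7", "P8"),
                            ("AF7", "AF8"), ("O1", "O2")]:
            a, b = pos[left], pos[right]
            assert np.allclose(a * [1, -1, 1], b, atol=1e-9)

    def test_on_scalp_sphere(self, montage, headmodel):
        radii = np.linalg.norm(montage.positions, axis=1)
        assert np.allclose(radii, headmodel.scalp_radius, rtol=1e-9)

    def test_canonical_channel_order(self, montage):
        assert montage.labels[0] == "Fp1"
        assert montage.labels[12] == "C3"
        assert montage.labels[-1] == "O2"
        assert len(set(montage.labels)) == 64


class TestModelValidation:
    def test_radii_must_increase(self):
        with pytest.raises(ValueError):
            HeadModel(shell_radii=(71.0, 70.0, 79.0, 85.0))

    def test_conductivities_positive(self):
        with pytest.raises(ValueError):
            HeadModel(shell_conductivities=(0.33, -1.0, 0.0042, 0.33))

    def test_minimum_series_terms(self):
        with pytest.raises(ValueError):
            HeadModel(series_terms=10)


class TestForward:
    def test_linearity_and_superposition(self, montage, headmodel, rng):
        loc = np.array([10.0, -20.0, 30.0])
        m1, m2 = rng.normal(size=3) * 20, rng.normal(size=3) * 20
        v1 = forward_potentials(Dipole(loc, m1), montage, headmodel)
        v2 = forward_potentials(Dipole(loc, m2), montage, headmodel)
        v12 = forward_potentials(Dipole(loc, m1 + 2 * m2), montage, headmodel)
        scale = np.abs(v12).max()
        assert np.allclose(v12, v1 + 2 * v2, atol=1e-9 * scale)

    def test_average_reference(self, montage, headmodel, rng):
        for _ in range(5):
            loc = rng.normal(size=3)
            loc = loc / np.linalg.norm(loc) * rng.uniform(5, 60)
            v = forward_potentials(Dipole(loc, rng.normal(size=3) * 30),
                                   montage, headmodel)
            assert abs(v.sum()) < 1e-9 * np.linalg.norm(v)

    def test_origin_radial_moment_symmetric(self, montage, headmodel):
        v = forward_potentials(Dipole([0., 0., 0.], [0., 0., 10.]),
                               montage, headmodel)
        cosang = montage.positions[:, 2] / montage.radius
        # electrodes at equal polar angle must see equal potentials
        for c in np.unique(np.round(cosang, 9)):
            sel = np.isclose(cosang, c, atol=1e-9)
            if sel.sum() > 1:
                assert np.ptp(v[sel]) < 1e-9 * np.abs(v).max()

    def test_homogeneous_reduction_matches_closed_form(
            self, montage, homogeneous_model, rng):
        for _ in range(10):
            loc = rng.normal(size=3)
            loc = loc / np.linalg.norm(loc) * rng.uniform(5, 60)
            d = Dipole(loc, rng.normal(size=3) * 20)
            v = forward_potentials(d, montage, homogeneous_model)
            ref = homogeneous_sphere_potentials(d, montage, 0.33,
                                                homogeneous_model.scalp_radius)
            assert np.linalg.norm(v - ref) < 1e-6 * np.linalg.norm(ref)

    def test_dipole_outside_brain_rejected(self, montage, headmodel):
        with pytest.raises(DomainError):
            forward_potentials(Dipole([0., 0., 72.], [0., 0., 10.]),
                               montage, headmodel)

    def test_gain_matches_forward(self, montage, headmodel, rng):
        loc = np.array([-30.0, 10.0, 25.0])
        G = dipole_gain(loc, montage, headmodel)
        m = rng.normal(size=3) * 15
        v = forward_potentials(Dipole(loc, m), montage, headmodel)
        assert np.allclose(G @ m, v, rtol=1e-12)


class TestFit:
    def test_recovers_known_dipole(self, montage, headmodel, rng):
        for i in range(4):
            loc = rng.normal(size=3)
            loc = loc / np.linalg.norm(loc) * rng.uniform(15, 55)
            vmap = forward_potentials(Dipole(loc, rng.normal(size=3) * 30),
                                      montage, headmodel)
            fit = fit_single_dipole(vmap, montage, headmodel,
                                    n_restarts=4, seed=i)
            assert np.linalg.norm(fit.dipole.location - loc) < 2.0
            assert fit.residual_variance < 1e-4

    def test_zero_map_is_an_error(self, montage, headmodel):
        with pytest.raises(ValueError):
            fit_single_dipole(np.zeros(64), montage, headmodel)

    def test_two_source_map_fits_worse(self, montage, headmodel):
        m1 = forward_potentials(Dipole([-35., 10., 40.], [0., 20., 10.]),
                                montage, headmodel)
        m2 = forward_potentials(Dipole([40., -15., 20.], [15., 0., -10.]),
                                montage, headmodel)
        rv_single = fit_single_dipole(m1, montage, headmodel, n_restarts=4,
                                      seed=0).residual_variance
        rv_double = fit_single_dipole(m1 + m2, montage, headmodel,
                                      n_restarts=6, seed=0).residual_variance
        assert rv_double > rv_single


def _fit(rv, radial, z):
    return DipoleFit(dipole=Dipole([0., 0., z], [0., 0., 1.]),
                     residual_variance=rv, radial_fraction=radial,
                     converged=True)


class TestDipoleRejection:
    @pytest.mark.parametrize("rv,radial,z,kept,why", [
        (0.05, 0.50, 30.0, True, []),                       # clean parietal-like
        (0.05, 0.50, -1.0, False, ["low_z"]),               # cerebellum/neck
        (0.10, 0.70, 0.0, True, []),                        # exact thresholds kept
        (0.11, 0.50, 30.0, False, ["residual_variance"]),
        (0.05, 0.71, 30.0, False, ["radial_fraction"]),
    ])
    def test_threshold_rules(self, rv, radial, z, kept, why):
        keep, reasons = reject_components_by_dipole([_fit(rv, radial, z)])
        assert keep[0] == kept
        assert reasons[0] == why

    def test_pure_function(self):
        fits = [_fit(0.05, 0.5, 10.0), _fit(0.2, 0.5, 10.0)]
        a = reject_components_by_dipole(fits)
        b = reject_components_by_dipole(fits)
        assert np.array_equal(a[0], b[0]) and a[1] == b[1]


class TestEyeDetector:
    def _session(self, montage, headmodel, kind, rng, fs=128.0, dur=90.0):
        from gaitdecode.synth import SourceSpec, Carrier, render_source_waveform
        n = int(dur * fs)
        t = np.arange(n) / fs
        if kind == "blink":
            src = SourceSpec("blink", Dipole((60., 0., -10.), (30., 0., 20.)), 50.0)
        else:
            src = SourceSpec("cortical", Dipole((-34.5, 7.7, 42.1), (0., 1., 0.)),
                             20.0, carriers=(Carrier((9.0, 11.0), 1.0, 0.0),))
        w = render_source_waveform(src, t, fs, np.zeros(n), np.array([]), rng)
        gain = forward_potentials(Dipole(src.dipole.location,
                                         src.dipole.moment * src.amplitude),
                                  montage, headmodel)
        return gain, w

    def test_blink_flagged_oscillator_not(self, montage, headmodel, rng):
        g_blink, w_blink = self._session(montage, headmodel, "blink", rng)
        g_osc, w_osc = self._session(montage, headmodel, "cortical", rng)
        maps = np.stack([g_blink, g_osc])
        acts = np.stack([w_blink, w_osc])
        flagged = detect_eye_components(maps, acts, montage, fs=128.0)
        assert flagged[0] and not flagged[1]

    def test_zero_variance_activation_not_flagged(self, montage, headmodel, rng):
        g_blink, _ = self._session(montage, headmodel, "blink", rng)
        flagged = detect_eye_components(g_blink[None], np.zeros((1, 1000)),
                                        montage, fs=128.0)
        assert not flagged[0]

    def test_missing_frontal_channels_is_config_error(self, montage):
        labels = tuple(l + "x" for l in montage.labels)
        bad = Montage(labels, montage.positions)
        with pytest.raises(ValueError, match="frontal"):
            detect_eye_components(np.ones((1, 64)), np.random.randn(1, 500),
                                  bad, fs=128.0)
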