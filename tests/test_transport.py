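"""Transport kernels: free paths, channel selection, Compton/Thomson
sampling, direction rotation, and full-history bookkeeping."""

import numpy as np
import pytest
from scipy import stats
from scipy.integrate import cumulative_trapezoid, quad

from mammoshield import materials as M
from mammoshield import transport as T
from mammoshield.errors import InvalidMediumError
from mammoshield.geometry import BoxRegion, Scene
from mammoshield.source import Rectangle, SourceSpec
from mammoshield.tally import PlanarCountTally
from mammoshield.xsdata import MEC2_KEV


class TestFreePath:
    def test_closed_form_for_known_deviate(self):
        class FixedRng:
            def random(self, size=None):
                # 1 - U = e^-1  ->  distance = 1/mu
                return np.full(size, 1.0 - np.exp(-1.0)) if size else 1.0 - np.exp(-1.0)

        d = T.sample_free_path(np.array([2.0]), FixedRng())
        assert d[0] == pytest.approx(0.5, rel=1e-12)

    def test_sample_mean_matches_exponential(self, rng):
        mu = 2.0
        d = T.sample_free_path(np.full(100_000, mu), rng)
        se = 1.0 / mu / np.sqrt(d.size)
        assert abs(d.mean() - 1.0 / mu) < 3 * se

    def test_large_mu_gives_short_paths(self, rng):
        d = T.sample_free_path(np.full(1000, 1e8), rng)
        assert d.max() < 1e-6

    def test_vacuum_rejected(self, rng):
        with pytest.raises(InvalidMediumError):
            T.sample_free_path(0.0, rng)


class TestChannelSelection:
    def test_degenerate_single_channel(self, rng):
        # only the photoelectric partial is nonzero -> chosen with certainty
        pp = np.array([[1.0], [0.0], [0.0]])
        is_pe, is_inc, is_coh = T._select_channels(pp, rng)
        assert is_pe.all() and not is_inc.any() and not is_coh.any()

    def test_coherent_disabled_renormalizes(self, library, rng):
        channels = T.sample_interaction_batch(
            library.get("water"), 30.0, rng, 5000, coherent_enabled=False)
        assert set(np.unique(channels)) <= {"photoelectric", "incoherent"}

    def test_scalar_api_returns_valid_channel(self, library, rng):
        ch = T.sample_interaction(library.get("water"), 30.0, rng)
        assert ch in ("photoelectric", "incoherent", "coherent")

    def test_vacuum_partials_rejected(self, library, rng):
        with pytest.raises(InvalidMediumError):
            T.sample_interaction(library.get("vacuum"), 30.0, rng)

    def test_frequencies_match_partial_ratios(self, library, rng):
        """Chi-square on 1e5 draws against the tabulated partial fractions."""
        m = library.get("GF50")
        n = 100_000
        channels = T.sample_interaction_batch(m, 30.0, rng, n)
        parts = np.array([M.mu_rho(m, 30.0, c)
                          for c in ("photoelectric", "incoherent", "coherent")])
        expected = n * parts / parts.sum()
        observed = np.array([(channels == c).sum()
                             for c in ("photoelectric", "incoherent", "coherent")])
        chi2 = ((observed - expected) ** 2 / expected).sum()
        assert chi2 < stats.chi2.ppf(0.999, df=2)


class TestCompton:
    def test_forward_scatter_keeps_energy(self):
        assert T.compton_scattered_energy(30.0, 1.0) == pytest.approx(30.0)

    def test_backscatter_at_mec2(self):
        # E = mec^2, theta = pi  ->  E' = E/3
        e = MEC2_KEV
        assert T.compton_scattered_energy(e, -1.0) == pytest.approx(e / 3.0, rel=1e-12)

    def test_energy_bounds(self, rng):
        e = 35.0
        e_out, ct = T.sample_compton(np.full(50_000, e), rng)
        assert np.all(e_out <= e + 1e-12)
        assert np.all(e_out >= e / (1.0 + 2.0 * e / MEC2_KEV) - 1e-12)
        assert np.all((ct >= -1) & (ct <= 1))

    def test_angle_distribution_matches_klein_nishina_cdf(self, rng):
        """KS test of sampled cos(theta) at 30 keV against the numerically
        integrated Klein-Nishina CDF, 1e5 draws, 0.001 level."""
        e = 30.0
        n = 100_000
        _, ct = T.sample_compton(np.full(n, e), rng)
        grid = np.linspace(-1, 1, 4001)
        pdf = T.klein_nishina_pdf(e, grid)
        cdf = cumulative_trapezoid(pdf, grid, initial=0.0)
        cdf /= cdf[-1]
        res = stats.kstest(ct, lambda x: np.interp(x, grid, cdf))
        d_crit = 1.949 / np.sqrt(n)  # alpha = 0.001
        assert res.statistic < d_crit

    def test_scattered_energy_consistent_with_angle(self, rng):
        e = 50.0
        e_out, ct = T.sample_compton(np.full(1000, e), rng)
        np.testing.assert_allclose(e_out, T.compton_scattered_energy(e, ct), rtol=1e-10)


class TestCoherent:
    def test_second_moment_matches_thomson_density(self, rng):
        """Sampled cos^2 mean equals the numeric moment of (1+cos^2)."""
        num = quad(lambda x: x * x * (1 + x * x), -1, 1)[0]
        den = quad(lambda x: (1 + x * x), -1, 1)[0]
        oracle = num / den
        ct = T.sample_coherent(rng, 200_000)
        se = ct.var() ** 0.5 / np.sqrt(ct.size)
        assert abs((ct**2).mean() - oracle) < 5 * se

    def test_azimuth_uniformity_preserves_transverse_symmetry(self, rng):
        dirs = np.tile([0.0, 0.0, 1.0], (100_000, 1))
        ct = T.sample_coherent(rng, dirs.shape[0])
        phi = 2 * np.pi * rng.random(dirs.shape[0])
        out = T.rotate_direction(dirs, ct, phi)
        assert abs(out[:, 0].mean()) < 0.01 and abs(out[:, 1].mean()) < 0.01


class TestRotation:
    def test_preserves_unit_norm(self, rng):
        dirs = rng.normal(size=(5000, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        ct = 2 * rng.random(5000) - 1
        phi = 2 * np.pi * rng.random(5000)
        out = T.rotate_direction(dirs, ct, phi)
        np.testing.assert_allclose(np.linalg.norm(out, axis=1), 1.0, atol=1e-12)

    def test_polar_angle_realized(self, rng):
        dirs = rng.normal(size=(2000, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        ct = 2 * rng.random(2000) - 1
        phi = 2 * np.pi * rng.random(2000)
        out = T.rotate_direction(dirs, ct, phi)
        np.testing.assert_allclose(np.sum(out * dirs, axis=1), ct, atol=1e-9)

    def test_pole_convention(self):
        out = T.rotate_direction(np.array([[0.0, 0.0, -1.0]]),
                                 np.array([0.5]), np.array([0.3]))
        assert out[0, 2] == pytest.approx(-0.5, abs=1e-12)


def _slab_scene(material="water", thickness=1.0, world_material="vacuum"):
    world = BoxRegion(0, "world", (-30, 30, -30, 30, -30, 30), world_material)
    slab = BoxRegion(1, "slab", (-10, 10, -10, 10, -thickness, 0.0), material, priority=1)
    return Scene([slab], world)


def _pencil(energy, n):
    fp = Rectangle("z", 0.0, -1e-4, 1e-4, -1e-4, 1e-4)
    return SourceSpec("collimated_pyramid", (0, 0, 10.0), energy, n, fp)


class TestHistories:
    def test_vacuum_scene_escapes_with_zero_deposit(self, library):
        world = BoxRegion(0, "world", (-5, 5, -5, 5, -5, 5), "vacuum")
        scene = Scene([], world)
        spec = SourceSpec("isotropic_point", (0, 0, 0), 30.0, 1)
        dep, escaped = T.run_history(scene, library, spec, T.TransportConfig(seed=3))
        assert dep == {}
        assert escaped == pytest.approx(30_000.0)

    def test_per_history_energy_conservation(self, library):
        scene = _slab_scene()
        spec = _pencil(30.0, 2000)
        res = T.run_simulation(scene, library, spec, T.TransportConfig(seed=9),
                               per_history=True)
        emitted = 30_000.0
        balance = res.per_history_eV.sum(axis=1) + res.escaped_per_history_eV
        np.testing.assert_allclose(balance, emitted, rtol=1e-12)

    def test_uncollided_fraction_matches_attenuation_law(self, library):
        scene = _slab_scene(thickness=1.0)
        n = 100_000
        spec = _pencil(30.0, n)
        back = PlanarCountTally(Rectangle("z", -1.0001, -10, 10, -10, 10),
                                direction_sign=-1, primary_only=True)
        T.run_simulation(scene, library, spec, T.TransportConfig(seed=12), planes=[back])
        p = np.exp(-M.linear_mu(library.get("water"), 30.0) * 1.0)
        se = np.sqrt(p * (1 - p) / n)
        assert abs(back.count / n - p) < 3 * se

    def test_bit_identical_reproducibility(self, library):
        scene = _slab_scene()
        spec = _pencil(25.0, 5000)
        cfg = T.TransportConfig(seed=77, batch_size=2000)
        r1 = T.run_simulation(scene, library, spec, cfg)
        r2 = T.run_simulation(scene, library, spec, cfg)
        assert np.array_equal(r1.dep_sum_eV, r2.dep_sum_eV)
        assert r1.escaped_eV == r2.escaped_eV

    def test_absorbing_medium_coherent_off_transmission(self, library):
        """With coherent scattering disabled the uninteracted fraction is
        exp(-(mu_pe + mu_incoh) t)."""
        scene = _slab_scene(material="lead", thickness=0.005)
        n = 50_000
        spec = _pencil(30.0, n)
        cfg = T.TransportConfig(seed=5, coherent_enabled=False)
        back = PlanarCountTally(Rectangle("z", -0.0051, -10, 10, -10, 10),
                                direction_sign=-1, primary_only=True)
        T.run_simulation(scene, library, spec, cfg, planes=[back])
        pb = library.get("lead")
        mu = (M.linear_mu(pb, 30.0, "photoelectric") + M.linear_mu(pb, 30.0, "incoherent"))
        p = np.exp(-mu * 0.005)
        se = np.sqrt(p * (1 - p) / n)
        assert abs(back.count / n - p) < 3 * se

    def test_interaction_cap_truncates_and_conserves(self, library):
        scene = _slab_scene(thickness=5.0)
        spec = _pencil(40.0, 2000)
        cfg = T.TransportConfig(seed=4, max_interactions=1)
        res = T.run_simulation(scene, library, spec, cfg)
        assert res.truncated_histories > 0
        total = res.dep_sum_eV.sum() + res.escaped_eV
        assert total == pytest.approx(res.emitted_eV, rel=1e-12)
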