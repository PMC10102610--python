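"""Phantom construction, screen characterization and the scenario driver."""

import numpy as np
import pandas as pd
import pytest

from mammoshield import materials as M
from mammoshield import study as S
from mammoshield.errors import InvalidPhantomError, NotConfiguredError, UnknownMaterialError
from mammoshield.geometry import locate


class TestPhantomConstruction:
    def test_region_count_and_stable_ids(self, library):
        spec = S.PhantomSpec()
        bare = S.build_breast_phantom(spec, None, library)
        with_screen = S.build_breast_phantom(spec, S.ScreenSpec("C40"), library)
        # 2 x (3 layers + 5 skin faces) + body (+ screen)
        assert bare.n_regions == 17
        assert with_screen.n_regions == 18
        assert [r.region_id for r in bare.regions] == [r.region_id for r in bare.regions]
        again = S.build_breast_phantom(spec, None, library)
        assert [(r.region_id, r.label, r.bounds) for r in bare.regions] == \
               [(r.region_id, r.label, r.bounds) for r in again.regions]

    def test_left_breast_skin_ids_are_9_10_11(self, library):
        scene = S.build_breast_phantom(S.PhantomSpec(), None, library)
        labels = {r.region_id: r.label for r in scene.regions}
        assert labels[9] == "left_skin_top"
        assert labels[10] == "left_skin_front"
        assert labels[11] == "left_skin_bottom"

    def test_screen_is_only_difference(self, library):
        spec = S.PhantomSpec()
        bare = S.build_breast_phantom(spec, None, library)
        shielded = S.build_breast_phantom(spec, S.ScreenSpec("lead_acrylic"), library)
        bare_set = {(r.region_id, r.bounds, r.material) for r in bare.regions}
        scr_set = {(r.region_id, r.bounds, r.material) for r in shielded.regions}
        extra = scr_set - bare_set
        assert bare_set <= scr_set
        assert len(extra) == 1 and next(iter(extra))[2] == "lead_acrylic"

    def test_screen_centered_between_breasts(self, library):
        spec = S.PhantomSpec()
        scene = S.build_breast_phantom(spec, S.ScreenSpec("C40"), library)
        sb = scene.region(S.SCREEN_ID).bounds
        assert sb[0] == pytest.approx(-sb[1])  # x-symmetric about the midplane
        ex, ey, ez = spec.envelope
        assert (sb[4] + sb[5]) / 2 == pytest.approx(ez / 2)
        # the midpoint between the breasts resolves to the screen
        assert locate(scene, (0.0, ey / 2, ez / 2)) == S.SCREEN_ID

    def test_layer_materials_top_to_bottom(self, library):
        spec = S.PhantomSpec()
        scene = S.build_breast_phantom(spec, None, library)
        mats = {r.label: r.material for r in scene.regions}
        assert mats["right_layer1"] == "GF25"
        assert mats["right_layer2"] == "GF50"
        assert mats["right_layer3"] == "GF75"
        z_tops = {r.label: r.bounds[5] for r in scene.regions}
        assert z_tops["right_layer1"] > z_tops["right_layer2"] > z_tops["right_layer3"]

    def test_thick_screen_rejected(self, library):
        with pytest.raises(InvalidPhantomError):
            S.build_breast_phantom(S.PhantomSpec(gap=1.0),
                                   S.ScreenSpec("C40", thickness=1.2), library)

    def test_unknown_screen_material_rejected(self, library):
        with pytest.raises(UnknownMaterialError):
            S.build_breast_phantom(S.PhantomSpec(), S.ScreenSpec("kryptonite"), library)

    def test_two_layer_phantom_rejected(self):
        with pytest.raises(InvalidPhantomError):
            S.PhantomSpec(layer_materials=("GF25", "GF50"))


class TestLeadEquivalence:
    def test_pure_lead_self_equivalence(self, library):
        assert S.lead_equivalence(library, "lead", 1.2, 30.0) == pytest.approx(12.0, rel=1e-12)

    def test_linearity_in_thickness(self, library):
        full = S.lead_equivalence(library, "lead_acrylic", 1.2, 30.0)
        half = S.lead_equivalence(library, "lead_acrylic", 0.6, 30.0)
        assert half == pytest.approx(full / 2, rel=1e-12)

    def test_default_screen_near_half_mm(self, library):
        assert S.lead_equivalence(library, "lead_acrylic", 1.2, 30.0) == \
            pytest.approx(0.5, rel=0.10)

    def test_calibration_hits_target_exactly(self):
        w = S.calibrate_lead_acrylic_pb_fraction(target_pb_mm=0.5)
        lib = M.default_library()
        lib.register(M.lead_acrylic_material(w))
        assert S.lead_equivalence(lib, "lead_acrylic", 1.2, 30.0) == \
            pytest.approx(0.5, abs=1e-6)


class TestDoseReduction:
    def test_equal_doses_zero(self):
        assert S.dose_reduction(5.0, 5.0)[0] == 0.0

    def test_total_absorption_hundred_percent(self):
        assert S.dose_reduction(5.0, 0.0)[0] == 100.0

    def test_error_propagation(self):
        pct, err = S.dose_reduction(10.0, 5.0, reference_err=0.0, candidate_err=1.0)
        assert pct == pytest.approx(50.0)
        assert err == pytest.approx(10.0)

    def test_normalization_invariance(self):
        """Reduction is unchanged when both doses share a normalization."""
        a, b = 7.3, 4.1
        assert S.dose_reduction(a, b)[0] == pytest.approx(S.dose_reduction(a / 3, b / 3)[0])

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            S.dose_reduction(0.0, 1.0)


class TestScenario:
    def test_identical_seed_identical_table(self, library):
        kw = dict(energies=(30.0,), n_histories=5_000, seed=99, library=library)
        r1 = S.run_scenario(screen_option=None, **kw)
        r2 = S.run_scenario(screen_option=None, **kw)
        pd.testing.assert_frame_equal(r1.summary, r2.summary)
        pd.testing.assert_frame_equal(r1.doses, r2.doses)

    def test_energy_balance_in_summary(self, library):
        r = S.run_scenario(screen_option="C40", energies=(25.0,),
                           n_histories=5_000, seed=1, library=library)
        row = r.summary.iloc[0]
        assert row.deposited_eV + row.escaped_eV == pytest.approx(row.emitted_eV, rel=1e-12)

    def test_exposed_breast_transparency_rises_with_energy(self, library):
        """The fraction of emitted energy absorbed in the exposed breast
        falls as the beam hardens (the tissue becomes more transparent),
        while the per-photon deposit stays below the photon energy."""
        r = S.run_scenario(screen_option=None, energies=(20.0, 40.0),
                           n_histories=20_000, seed=17, library=library)
        lo = r.row("none", 20.0)
        hi = r.row("none", 40.0)
        assert lo.right_total_eV / 20e3 > hi.right_total_eV / 40e3
        assert 0 < hi.right_total_eV < 40e3

    def test_reduction_table_shape(self, library):
        kw = dict(energies=(30.0,), n_histories=4_000, seed=5, library=library)
        res = S.run_scenario(screen_option="lead_acrylic", **kw).merged(
            S.run_scenario(screen_option="C40", **kw))
        red = S.reduction_table(res)
        assert list(red.columns) == ["energy_keV", "reference", "candidate",
                                     "quantity", "reduction_pct", "reduction_err_pct"]
        assert len(red) == 1


class TestTfPilot:
    def test_equal_primary_counts_across_materials(self, library):
        df = S.tf_pilot(("lead_acrylic", "C40"), energies=(30.0,),
                        n_histories=20_000, seed=10, library=library)
        prim = df.groupby("material").primary_count.first()
        assert prim["lead_acrylic"] == prim["C40"] > 0

    def test_vacuum_screen_is_transparent(self, library):
        df = S.tf_pilot(("vacuum",), energies=(30.0,), n_histories=20_000,
                        seed=10, library=library)
        assert df.tf_mc.iloc[0] == pytest.approx(1.0, abs=0.02)
        assert df.tf_narrow_beam.iloc[0] == 1.0


class TestMixtures:
    def test_adipose_glandular_mixture_weight_fraction(self, library):
        """A 20% glandular admixture carries exactly 0.2 of its mass from
        the glandular component."""
        adipose = M.Material("adipose_tst", 0.95, (("C", 0.6), ("H", 0.1), ("O", 0.3)))
        glandular = M.Material("glandular_tst", 1.02, (("N", 1.0),))
        mix = S.mix_materials("mix", adipose, glandular, 0.20)
        comp = dict(mix.composition)
        assert comp["N"] == pytest.approx(0.20, abs=1e-12)
        assert sum(comp.values()) == pytest.approx(1.0, abs=1e-12)

    def test_validation_case_requires_external_parameters(self):
        with pytest.raises(NotConfiguredError):
            S.tg195_validation(None)
        with pytest.raises(NotConfiguredError):
            S.tg195_validation({"energy_keV": 30.0})

    def test_validation_case_runs_when_configured(self, library):
        """With (synthetic stand-in) parameters supplied, the validation
        block runs and doubling histories leaves the mean within 2 sigma."""
        cfg = dict(
            adipose=dict(density=0.95,
                         composition=[("H", 11.4), ("C", 59.8), ("N", 0.7), ("O", 27.8)]),
            glandular=dict(density=1.02,
                           composition=[("H", 10.6), ("C", 33.2), ("N", 3.0), ("O", 52.7)]),
            glandular_weight_fraction=0.20,
            phantom_size_cm=(8.0, 8.0, 4.0),
            energy_keV=30.0,
            source_distance_cm=30.0,
            n_histories=4_000,
        )
        m1, re1 = S.tg195_validation(cfg, seed=1)
        cfg2 = dict(cfg, n_histories=8_000)
        m2, re2 = S.tg195_validation(cfg2, seed=2)
        assert m1 > 0 and m2 > 0
        sigma = np.hypot(m1 * re1, m2 * re2)
        assert abs(m1 - m2) < 2 * sigma + 1e-9
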