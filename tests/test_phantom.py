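import dataclasses

import numpy as np
import pytest

from callusfe import biomech, materials, phantom
from callusfe.phantom import PhantomSpec


def intact_spec(**kw):
    defaults = dict(gap_width=0.0)
    defaults.update(kw)
    return dataclasses.replace(PhantomSpec(), **defaults)


class TestSpecValidation:
    def test_thickness_must_fit_radius(self):
        with pytest.raises(ValueError):
            PhantomSpec(outer_radius=3.0, cortical_thickness=3.5)

    def test_gap_must_fit_length(self):
        with pytest.raises(ValueError):
            PhantomSpec(bone_length=10.0, gap_width=12.0, callus_axial_extent=14.0)

    def test_gap_density_cannot_exceed_peak(self):
        with pytest.raises(ValueError):
            PhantomSpec(callus_gap_density=900.0, callus_peak_density=800.0)


class TestIntactPhantom:
    def test_zero_noise_cortex_is_exactly_mean(self):
        spec = intact_spec(cortical_density_sd=0.0)
        vol = phantom.generate_intact_phantom(spec)
        cortex = vol.data > spec.soft_background_density
        assert cortex.any()
        np.testing.assert_array_equal(vol.data[cortex], spec.cortical_density_mean)

    def test_deterministic_given_seed(self):
        spec = intact_spec(rng_seed=42)
        a = phantom.generate_intact_phantom(spec)
        b = phantom.generate_intact_phantom(spec)
        np.testing.assert_array_equal(a.data, b.data)

    def test_cortical_volume_matches_analytic_annulus(self):
        spec = intact_spec(
            outer_radius=10.0,
            cortical_thickness=3.0,
            callus_max_radius=10.5,
            bone_length=20.0,
            cortical_density_sd=0.0,
            voxel_spacing=500.0,
        )
        vol = phantom.generate_intact_phantom(spec)
        h = spec.voxel_spacing / 1000
        count = np.sum(vol.data > spec.soft_background_density)
        analytic = np.pi * (10.0**2 - 7.0**2) * 20.0
        assert count * h**3 == pytest.approx(analytic, rel=0.02)

    def test_gap_spec_rejected(self):
        with pytest.raises(ValueError, match="gap_width"):
            phantom.generate_intact_phantom(PhantomSpec())


class TestOsteotomyPhantom:
    def test_axial_profile_minimal_at_fracture_line(self, default_spec):
        dz = np.linspace(-default_spec.callus_axial_extent / 2, default_spec.callus_axial_extent / 2, 101)
        profile = phantom.callus_axial_profile(default_spec, dz)
        assert profile.argmin() == 50  # centre of the gap
        assert profile[0] == profile[-1] == default_spec.callus_peak_density

    def test_gap_width_zero_rejected(self):
        with pytest.raises(ValueError, match="gap_width"):
            phantom.generate_osteotomy_phantom(intact_spec())

    def test_callus_narrower_than_gap_rejected(self):
        with pytest.raises(ValueError, match="callus_axial_extent"):
            phantom.generate_osteotomy_phantom(
                dataclasses.replace(PhantomSpec(), gap_width=12.0, callus_axial_extent=8.0)
            )

    def test_mean_callus_density_matches_linear_grading(self):
        spec = dataclasses.replace(PhantomSpec(), cortical_density_sd=0.0, voxel_spacing=400.0)
        vol = phantom.generate_osteotomy_phantom(spec)
        h, shp = vol.spacing_mm, vol.data.shape
        x = (np.arange(shp[0]) + 0.5) * h - shp[0] * h / 2
        r = np.sqrt(x[:, None] ** 2 + x[None, :] ** 2)
        z = (np.arange(shp[2]) + 0.5) * h
        dz = z - spec.bone_length / 2
        callus = (
            (r[:, :, None] > spec.outer_radius)
            & (vol.data > spec.soft_background_density)
            & (np.abs(dz)[None, None, :] <= spec.callus_axial_extent / 2)
        )
        mean_density = vol.data[callus].mean()
        # analytic mean of the linear profile, volume-weighted by the
        # fusiform shell: integrate profile * shell area over the extent
        ro, rmax, ext = spec.outer_radius, spec.callus_max_radius, spec.callus_axial_extent
        zz = np.linspace(-ext / 2, ext / 2, 20001)
        area = np.pi * (phantom.callus_outer_radius(spec, zz) ** 2 - ro**2)
        prof = phantom.callus_axial_profile(spec, zz)
        expected = np.trapezoid(prof * area, zz) / np.trapezoid(area, zz)
        assert mean_density == pytest.approx(expected, rel=0.03)

    def test_tissue_volume_conservation(self):
        # osteotomy tissue = intact cortex (gap replaced by a soft plug)
        # + fusiform callus shell; each term vs its analytic volume
        # generous radii so the voxel staircase stays below the 2% band
        spec = dataclasses.replace(
            PhantomSpec(),
            outer_radius=10.0,
            cortical_thickness=3.0,
            callus_max_radius=13.0,
            callus_axial_extent=12.0,
            bone_length=30.0,
            cortical_density_sd=0.0,
            voxel_spacing=250.0,
        )
        vol = phantom.generate_osteotomy_phantom(spec)
        intact = phantom.generate_intact_phantom(dataclasses.replace(spec, gap_width=0.0))
        h3 = vol.voxel_volume_mm3
        v_tissue = np.sum(vol.data > spec.soft_background_density) * h3
        v_intact = np.sum(intact.data > spec.soft_background_density) * h3
        ro, rmax, ext = spec.outer_radius, spec.callus_max_radius, spec.callus_axial_extent
        delta = rmax - ro
        v_callus_analytic = 4 * ro * delta * ext + np.pi * delta**2 * ext / 2
        ri = ro - spec.cortical_thickness
        v_annulus = np.pi * (ro**2 - ri**2) * spec.bone_length
        assert v_intact == pytest.approx(v_annulus, rel=0.02)
        assert v_tissue - v_intact == pytest.approx(v_callus_analytic, rel=0.02)

    def test_deterministic_given_seed(self, default_spec):
        a = phantom.generate_osteotomy_phantom(default_spec)
        b = phantom.generate_osteotomy_phantom(default_spec)
        np.testing.assert_array_equal(a.data, b.data)


class TestCohort:
    def test_zero_variation_identical_geometry(self, default_spec):
        cohort = phantom.generate_cohort((2, 2, 0), default_spec, variation=0.0, seed=5)
        specs = [sp.spec for sp in cohort]
        assert all(s.outer_radius == default_spec.outer_radius for s in specs)
        assert all(s.cortical_thickness == default_spec.cortical_thickness for s in specs)

    def test_study_sized_cohort(self, default_spec):
        cohort = phantom.generate_cohort((7, 18, 8), default_spec, variation=0.05, seed=1)
        assert len(cohort) == 33
        labels = [sp.dataset_label for sp in cohort]
        assert labels.count(1) == 7 and labels.count(2) == 18 and labels.count(3) == 8
        # dataset 3 is the critical-size (17 mm) defect model
        assert all(sp.spec.gap_width == 17.0 for sp in cohort if sp.dataset_label == 3)
        assert all(sp.spec.gap_width == 3.0 for sp in cohort if sp.dataset_label != 3)

    def test_deterministic_given_seed(self, default_spec):
        a = phantom.generate_cohort((2, 3, 2), default_spec, seed=9)
        b = phantom.generate_cohort((2, 3, 2), default_spec, seed=9)
        for sa, sb in zip(a, b):
            assert sa.id == sb.id
            np.testing.assert_array_equal(sa.volume.data, sb.volume.data)

    def test_negative_variation_rejected(self, default_spec):
        with pytest.raises(ValueError, match="variation"):
            phantom.generate_cohort((1, 1, 1), default_spec, variation=-0.1)


class TestSimulatedTorsion:
    def test_noise_free_closure(self, osteotomy_specimen):
        """Noise-free simulated curve returns the FE rigidity through the
        6-10 N*m regression to well under 0.1%."""
        model = materials.DualZoneModel(e_sc=50.0, rho_cut=600.0)
        curve = phantom.simulate_physical_torsion(osteotomy_specimen, model, noise_cv=0.0, seed=3)
        vtr = osteotomy_specimen.torsion_result(model).vtr
        gj = biomech.compute_gj(curve).gj
        assert abs(gj - vtr) / vtr < 1e-3

    def test_curve_spans_regression_window(self, osteotomy_specimen):
        model = materials.DualZoneModel(e_sc=50.0, rho_cut=600.0)
        curve = phantom.simulate_physical_torsion(osteotomy_specimen, model, noise_cv=0.0, seed=3)
        assert curve.torque.max() >= 10.0
        assert np.sum((curve.torque >= 6.0) & (curve.torque <= 10.0)) >= 3

    def test_monte_carlo_noise_calibration(self, osteotomy_specimen):
        """Recovered GJ over replicates has the requested ~2% CV."""
        model = materials.DualZoneModel(e_sc=50.0, rho_cut=600.0)
        gjs = []
        for s in range(100):
            curve = phantom.simulate_physical_torsion(
                osteotomy_specimen, model, noise_cv=0.02, seed=1000 + s
            )
            gjs.append(biomech.compute_gj(curve).gj)
        cv = np.std(gjs, ddof=1) / np.mean(gjs)
        assert cv == pytest.approx(0.02, abs=0.006)  # sampling error at n=100

    def test_negative_noise_rejected(self, osteotomy_specimen):
        with pytest.raises(ValueError, match="noise_cv"):
            phantom.simulate_physical_torsion(osteotomy_specimen, materials.DualZoneModel(), noise_cv=-0.01)


class TestCohortIO:
    def test_round_trip(self, tmp_path, default_spec):
        cohort = phantom.generate_cohort((2, 2, 0), default_spec, variation=0.0, seed=2)
        for sp in cohort:
            sp.measured_gj = 0.5
            sp.gauge_length = 23.0
        manifest = phantom.write_cohort(cohort, tmp_path)
        back = phantom.read_cohort(manifest)
        assert [sp.id for sp in back] == [sp.id for sp in cohort]
        np.testing.assert_allclose(back[0].volume.data, cohort[0].volume.data, rtol=1e-6)
        assert back[0].measured_gj == 0.5
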