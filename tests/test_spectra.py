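"""Orientational averaging, response assembly, 2D FFT, kinetics fits."""

import numpy as np
import pytest

import cg2des as cg
from cg2des.doorway_window import doorway, time_grid, window_gb, window_se
from cg2des.kinetics import TransferMap, build_dimer_rate_fixture, transfer_map
from cg2des.spectra import (
    anisotropy,
    assemble_response,
    cross_peak_kinetics,
    integrate_box,
    isotropic_contraction,
    orientational_weights,
    orientational_weights_quadrature,
    orientational_weights_sampled,
    spectrum_2d,
)

GRID = time_grid(64, 2.0)


def _dimer_tables(system, realizations=20, seed=3):
    seg_ids = [int(s) for s in system.segmentation.segment_ids]
    doorways = {
        p: {
            s: doorway(system, s, GRID, realizations, seed, pathway=p)
            for s in seg_ids
        }
        for p in ("nonrephasing", "rephasing")
    }
    windows = {"GB": {}, "SE": {}}
    for s in seg_ids:
        windows["GB"][s] = window_gb(system, s, GRID, realizations, seed + 1)
        d = system.segmentation.sites_of(s).size
        windows["SE"][s] = window_se(
            system, s, np.eye(d) / d, GRID, realizations, seed + 1
        )
    return doorways, windows


class TestOrientationalWeights:
    @pytest.mark.parametrize("scheme", ["parallel", "perpendicular"])
    def test_exactly_21_of_81_components_nonzero(self, scheme):
        assert orientational_weights(scheme).n_nonzero == 21

    @pytest.mark.parametrize("scheme", ["parallel", "perpendicular"])
    def test_matches_rotation_group_quadrature(self, scheme):
        A = orientational_weights(scheme).A
        Q = orientational_weights_quadrature(scheme).A
        assert np.abs(A - Q).max() < 1e-12

    def test_monte_carlo_sampling_converges_to_closed_form(self):
        A = orientational_weights("parallel").A
        M = orientational_weights_sampled("parallel", 200_000, seed=1).A
        assert np.abs(A - M).max() < 5e-3

    def test_parallel_dipoles_reproduce_cos4_average(self):
        u = np.array([0.3, -0.5, 0.81])
        u /= np.linalg.norm(u)
        val = isotropic_contraction(orientational_weights("parallel"), [u] * 4)
        assert val == pytest.approx(1.0 / 5.0)

    def test_contraction_invariant_under_global_rotation(self):
        rng = np.random.default_rng(2)
        mus = [rng.normal(size=3) for _ in range(4)]
        from scipy.spatial.transform import Rotation

        R = Rotation.random(random_state=rng).as_matrix()
        for scheme in ("parallel", "perpendicular"):
            W = orientational_weights(scheme)
            a = isotropic_contraction(W, mus)
            b = isotropic_contraction(W, [R @ m for m in mus])
            assert a == pytest.approx(b, abs=1e-12)

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError):
            orientational_weights("magic_angle")


class TestAssembleResponse:
    def test_single_segment_response_is_t2_independent(self, dimer_single):
        doorways, windows = _dimer_tables(dimer_single)
        W = orientational_weights("parallel")
        grids = []
        for t2 in (0.0, 7.5, 50.0):
            T = TransferMap(T=np.eye(1), t2=t2)
            grids.append(
                assemble_response(
                    doorways["nonrephasing"], windows, T, W, "nonrephasing"
                )
            )
        assert np.array_equal(grids[0].total(), grids[1].total())
        assert np.array_equal(grids[0].total(), grids[2].total())

    def test_identity_transfer_reduces_to_segment_products(self, dimer_double):
        doorways, windows = _dimer_tables(dimer_double)
        W = orientational_weights("parallel")
        T = TransferMap(T=np.eye(2), t2=0.0)
        R = assemble_response(
            doorways["nonrephasing"], windows, T, W, "nonrephasing"
        )
        manual = np.zeros_like(R.diagrams["GB"])
        for s in (0, 1):
            manual += np.einsum(
                "abgd,tab,ugd->tu",
                W.A,
                doorways["nonrephasing"][s].values,
                windows["GB"][s].values,
            )
        assert np.allclose(R.diagrams["GB"], manual)

    def test_long_time_weights_approach_stationary_distribution(self, dimer_double):
        doorways, windows = _dimer_tables(dimer_double)
        W = orientational_weights("parallel")
        K = build_dimer_rate_fixture("RT")
        p = cg.stationary_distribution(K)
        T_inf = transfer_map(K, 1e4)
        R = assemble_response(
            doorways["nonrephasing"], windows, T_inf, W, "nonrephasing"
        )
        manual = np.zeros_like(R.diagrams["SE"])
        for j in (0, 1):
            manual += p[j] * np.einsum(
                "abgd,tab,ugd->tu",
                W.A,
                (
                    doorways["nonrephasing"][0].values
                    + doorways["nonrephasing"][1].values
                ),
                windows["SE"][j].values,
            )
        assert np.allclose(R.diagrams["SE"], manual, atol=1e-10)

    def test_dimension_mismatch_rejected(self, dimer_double):
        doorways, windows = _dimer_tables(dimer_double)
        W = orientational_weights("parallel")
        T = TransferMap(T=np.eye(3), t2=0.0)
        with pytest.raises(ValueError):
            assemble_response(
                doorways["nonrephasing"], windows, T, W, "nonrephasing"
            )


class TestSpectrum2D:
    def _static_spectrum(self, system, rotating_frame, zero_pad=4):
        doorways, windows = _dimer_tables(system, realizations=1, seed=1)
        T = TransferMap(T=np.eye(system.segmentation.n_segments), t2=0.0)
        W = orientational_weights("parallel")
        nr = assemble_response(doorways["nonrephasing"], windows, T, W, "nonrephasing")
        r = assemble_response(doorways["rephasing"], windows, T, W, "rephasing")
        return spectrum_2d(nr, r, rotating_frame=rotating_frame, zero_pad=zero_pad)

    def test_static_site_peaks_at_its_energy(self, static_site_ht):
        spec = self._static_spectrum(static_site_ht, 12000.0)
        i, j = np.unravel_index(np.argmax(spec.absorptive), spec.absorptive.shape)
        dw = spec.w1[1] - spec.w1[0]
        assert abs(spec.w1[i] - 12000.0) <= dw
        assert abs(spec.w3[j] - 12000.0) <= dw

    def test_zero_response_gives_zero_spectrum(self, static_site_ht):
        doorways, windows = _dimer_tables(static_site_ht, realizations=1, seed=1)
        for tab in doorways["nonrephasing"].values():
            tab.values[:] = 0.0
        for tab in doorways["rephasing"].values():
            tab.values[:] = 0.0
        T = TransferMap(T=np.eye(1), t2=0.0)
        W = orientational_weights("parallel")
        nr = assemble_response(doorways["nonrephasing"], windows, T, W, "nonrephasing")
        r = assemble_response(doorways["rephasing"], windows, T, W, "rephasing")
        spec = spectrum_2d(nr, r)
        assert not spec.absorptive.any()

    def test_zero_padding_preserves_peak_position(self, static_site_ht):
        coarse = self._static_spectrum(static_site_ht, 12000.0, zero_pad=2)
        fine = self._static_spectrum(static_site_ht, 12000.0, zero_pad=4)
        dw_coarse = coarse.w1[1] - coarse.w1[0]
        for spec in (coarse, fine):
            i, j = np.unravel_index(
                np.argmax(spec.absorptive), spec.absorptive.shape
            )
            assert abs(spec.w1[i] - 12000.0) <= dw_coarse

    def test_normalized_copy_has_unit_peak(self, static_site_ht):
        spec = self._static_spectrum(static_site_ht, 12000.0)
        assert np.max(np.abs(spec.normalized().absorptive)) == pytest.approx(1.0)


class TestCrossPeakKinetics:
    def _series(self, k, t2):
        rng = np.random.default_rng(0)
        w = np.linspace(-100, 100, 32)
        base = np.exp(-0.5 * (w[:, None] ** 2 + w[None, :] ** 2) / 40.0**2)
        specs = []
        for t in t2:
            amp = 1.0 - np.exp(-k * t)
            specs.append(
                cg.Spectrum2D(absorptive=amp * base + 0.2, w1=w, w3=w)
            )
        return specs

    def test_recovers_known_rate_within_one_percent(self):
        t2 = np.array([0.0, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0])
        fit = cross_peak_kinetics(
            t2, self._series(0.31, t2), (-50, 50), (-50, 50)
        )
        assert fit.rate == pytest.approx(0.31, rel=0.01)

    def test_constant_series_reported_degenerate(self):
        t2 = np.array([0.0, 5.0, 10.0])
        fit = cross_peak_kinetics(
            t2, self._series(0.0, t2), (-50, 50), (-50, 50)
        )
        assert fit.degenerate
        assert fit.amplitude == 0.0
        assert fit.rate == 0.0

    def test_requires_three_waiting_times(self):
        t2 = np.array([0.0, 5.0])
        with pytest.raises(ValueError):
            cross_peak_kinetics(t2, self._series(0.1, t2), (-50, 50), (-50, 50))

    def test_box_outside_grid_rejected(self):
        t2 = np.array([0.0, 5.0, 10.0])
        with pytest.raises(ValueError):
            cross_peak_kinetics(
                t2, self._series(0.1, t2), (900, 1000), (-50, 50)
            )


class TestAnisotropy:
    def test_fixed_dipole_value(self):
        # I_par = 3 I_perp for an isotropic ensemble of one fixed dipole
        Ipar = np.full(5, 0.3)
        r = anisotropy(Ipar, Ipar / 3.0)
        assert np.allclose(r, 0.4)

    def test_equal_intensities_give_zero(self):
        r = anisotropy(np.ones(4), np.ones(4))
        assert np.allclose(r, 0.0)

    def test_randomized_dipole_memory_loss_gives_zero(self):
        """If the detection dipole is uncorrelated with the excitation
        dipole, the isotropic average makes both schemes equal."""
        rng = np.random.default_rng(8)
        Wpar = orientational_weights("parallel")
        Wperp = orientational_weights("perpendicular")
        vals = {"par": 0.0, "perp": 0.0}
        n = 4000
        for _ in range(n):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            vals["par"] += isotropic_contraction(Wpar, [u, u, v, v]) / n
            vals["perp"] += isotropic_contraction(Wperp, [u, u, v, v]) / n
        r = anisotropy(np.array([vals["par"]]), np.array([vals["perp"]]))
        assert abs(r[0]) < 0.02

    def test_zero_denominator_flagged(self):
        r = anisotropy(np.array([1.0, 2.0]), np.array([-0.5, 1.0]))
        assert np.isnan(r[0])
        assert np.isfinite(r[1])

    def test_misaligned_series_rejected(self):
        with pytest.raises(ValueError):
            anisotropy(np.ones(3), np.ones(4))
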