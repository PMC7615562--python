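import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import momnet as mn
from momnet.fitting import (
    COMMON_GRID,
    EmpiricalSpectrum,
    ParameterGrid,
    SweepResult,
    best_fit_per_subject,
    cell_seed,
    resample_to_common_grid,
    run_sweep,
    spectral_distance,
)
from momnet.observables import PowerSpectrum


class TestParameterGrid:
    def test_defaults_reproduce_paper_grid(self):
        grid = ParameterGrid()
        assert grid.shape == (28, 31)
        assert grid.k_values[0] == pytest.approx(0.1)
        assert grid.k_values[-1] == pytest.approx(10**1.7)
        assert np.allclose(np.diff(np.log10(grid.k_values)), 0.1)
        assert grid.delays_s[0] == 0.0
        assert grid.delays_s[-1] == pytest.approx(30e-3)
        assert np.allclose(np.diff(grid.delays_s), 1e-3)

    def test_non_monotone_axis_rejected(self):
        with pytest.raises(ValueError):
            ParameterGrid(k_values=np.array([1.0, 0.5]), delays_s=np.array([0.0]))


class TestSpectralDistance:
    def _delta_spectrum(self, f0):
        power = np.zeros_like(COMMON_GRID)
        power[np.argmin(np.abs(COMMON_GRID - f0))] = 1.0
        return PowerSpectrum(COMMON_GRID, power)

    def test_identical_spectra_zero(self):
        a = self._delta_spectrum(10.0)
        assert spectral_distance(a, a) == 0.0

    def test_disjoint_unit_deltas_distance_two(self):
        a, b = self._delta_spectrum(10.0), self._delta_spectrum(20.0)
        assert spectral_distance(a, b) == pytest.approx(2.0)

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=25, deadline=None)
    def test_axioms(self, seed):
        rng = np.random.default_rng(seed)
        a = PowerSpectrum(COMMON_GRID, rng.random(len(COMMON_GRID)))
        b = PowerSpectrum(COMMON_GRID, rng.random(len(COMMON_GRID)))
        dab, dba = spectral_distance(a, b), spectral_distance(b, a)
        assert dab >= 0
        assert dab == pytest.approx(dba)
        assert spectral_distance(a, a) == pytest.approx(0.0, abs=1e-15)

    def test_grid_refinement_stable(self):
        # smooth spectra sampled far finer than either evaluation grid, so
        # the per-bin distance scales exactly with the bin count
        freqs = np.linspace(0, 80, 3201)
        rng = np.random.default_rng(0)
        pa = np.convolve(rng.random(3201), np.ones(301) / 301, mode="same")
        pb = np.convolve(rng.random(3201), np.ones(301) / 301, mode="same")
        a, b = PowerSpectrum(freqs, pa), PowerSpectrum(freqs, pb)
        coarse = spectral_distance(a, b)
        fine_grid = np.linspace(0.0, 80.0, 4 * (len(COMMON_GRID) - 1) + 1)
        fine = spectral_distance(a, b, grid=fine_grid) * len(fine_grid) / len(COMMON_GRID)
        assert fine == pytest.approx(coarse, rel=0.02)

    def test_empty_mass_rejected(self):
        with pytest.raises(ValueError):
            resample_to_common_grid(np.array([100.0, 110.0]), np.array([1.0, 1.0]))


class TestCellSeeds:
    def test_deterministic_unique_and_bounded(self):
        seeds = {cell_seed(123, ik, it) for ik in range(29) for it in range(31)}
        assert len(seeds) == 29 * 31
        assert all(0 <= s < 2**31 for s in seeds)
        assert cell_seed(123, 3, 4) == cell_seed(123, 3, 4)
        assert cell_seed(123, 3, 4) != cell_seed(124, 3, 4)


@pytest.fixture(scope="module")
def small_sweep(connectome12):
    grid = ParameterGrid(
        k_values=np.array([1.0, 10.0]), delays_s=np.array([0.0, 1e-3])
    )
    base = mn.SimulationParams(K=1.0, mean_delay_s=1e-3, duration=6.0, seed=31)
    return grid, base, run_sweep(connectome12, grid, base)


class TestSweep:
    def test_all_cells_valid_with_consistent_shapes(self, small_sweep):
        grid, _, res = small_sweep
        assert res.valid.all()
        assert res.mean_R.shape == grid.shape
        assert res.spectra.shape == grid.shape + (len(COMMON_GRID),)
        assert np.allclose(res.spectra.sum(axis=-1), 1.0)

    def test_degenerate_single_cell_matches_direct_run(self, connectome12):
        grid = ParameterGrid(k_values=np.array([5.0]), delays_s=np.array([1e-3]))
        base = mn.SimulationParams(K=1.0, mean_delay_s=1e-3, duration=6.0, seed=31)
        res = run_sweep(connectome12, grid, base)
        params = base.replace(K=5.0, mean_delay_s=1e-3, seed=cell_seed(31, 0, 0))
        act = mn.integrate(connectome12, params)
        kop = mn.kuramoto_order_parameter(act.z, act.dt)
        mean_r, _ = mn.synchrony_metastability(kop, base.transient)
        assert res.mean_R[0, 0] == pytest.approx(mean_r)

    def test_checkpoint_resume_identical(self, tmp_path, connectome12, small_sweep):
        grid, base, res = small_sweep
        ckpt = tmp_path / "ck.npz"
        res1 = run_sweep(connectome12, grid, base, checkpoint=ckpt)
        assert ckpt.exists()
        res2 = run_sweep(connectome12, grid, base, checkpoint=ckpt)  # resumes, no recompute
        assert np.array_equal(res1.mean_R, res2.mean_R)
        assert np.array_equal(res1.mean_R, res.mean_R)

    def test_self_fitting_recovers_generating_cell(self, small_sweep):
        """A cell's own spectrum fed back as a subject wins with distance ~ 0."""
        grid, base, res = small_sweep
        refs = [
            EmpiricalSpectrum(f"cell{ik}{it}", COMMON_GRID, res.spectra[ik, it])
            for ik in range(2)
            for it in range(2)
        ]
        res.subjects = tuple(r.subject for r in refs)
        res.distances = np.stack(
            [
                np.sum((res.spectra - resample_to_common_grid(r.freqs, r.power)) ** 2, axis=-1)
                for r in refs
            ],
            axis=-1,
        )
        fits = best_fit_per_subject(res)
        for row, (ik, it) in zip(fits.itertuples(), [(0, 0), (0, 1), (1, 0), (1, 1)]):
            assert (row.ik, row.itau) == (ik, it)
            assert row.distance < 1e-20


class TestBestFit:
    def _result_with_distances(self, d):
        nK, nT, nS = d.shape
        grid = ParameterGrid(
            k_values=np.arange(1.0, nK + 1), delays_s=np.arange(nT) * 1e-3
        )
        return SweepResult(
            grid=grid,
            mean_R=np.zeros((nK, nT)),
            std_R=np.zeros((nK, nT)),
            peak_hz=np.zeros((nK, nT)),
            analytic_hz=np.zeros((nK, nT)),
            spectra=np.zeros((nK, nT, 1)),
            valid=np.ones((nK, nT), bool),
            distances=d,
            subjects=tuple(f"s{j}" for j in range(nS)),
        )

    def test_unique_minimum(self):
        d = np.ones((3, 3, 1))
        d[2, 1, 0] = 0.1
        fits = best_fit_per_subject(self._result_with_distances(d))
        assert (fits.iloc[0].ik, fits.iloc[0].itau) == (2, 1)

    def test_tie_breaks_toward_smaller_k_then_delay(self):
        d = np.ones((3, 3, 1))
        d[2, 2, 0] = d[1, 2, 0] = d[1, 0, 0] = 0.1
        fits = best_fit_per_subject(self._result_with_distances(d))
        assert (fits.iloc[0].ik, fits.iloc[0].itau) == (1, 0)

    def test_no_distances_rejected(self):
        res = self._result_with_distances(np.ones((2, 2, 1)))
        res.distances = None
        with pytest.raises(ValueError):
            best_fit_per_subject(res)


class TestEmpiricalSpectraIO:
    def test_directory_of_csv(self, tmp_path):
        for name in ("s01", "s02"):
            arr = np.column_stack([np.linspace(0, 80, 161), np.random.rand(161)])
            np.savetxt(tmp_path / f"{name}.csv", arr, delimiter=",")
        refs = mn.load_empirical_spectra(tmp_path)
        assert [r.subject for r in refs] == ["s01", "s02"]
        assert len(refs[0].freqs) == 161

    def test_mat_container(self, tmp_path):
        from scipy.io import savemat

        path = tmp_path / "spectra.mat"
        savemat(path, {"freqs": np.linspace(0, 80, 81), "spectra": np.random.rand(3, 81)})
        refs = mn.load_empirical_spectra(path)
        assert len(refs) == 3
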