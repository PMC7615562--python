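"""Parameter-plane sweeps and power-spectrum fitting.

Sweeps the (global coupling K, mean conduction delay <tau>) plane — by
default K = 10^-1 ... 10^1.7 in multiplicative steps of 10^0.1 (28 values)
and <tau> = 0 ... 30 ms in 1 ms steps (31 values) — computing per cell the
synchrony <R>, metastability STD(R), peak frequency, the analytic collective
frequency, and the across-unit mean power spectrum.  Simulated spectra are
compared to empirical per-subject spectra by squared Euclidean distance after
resampling to a common 0-80 Hz grid and unit-mass normalization.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .connectome import Connectome
from .observables import (
    PowerSpectrum,
    kuramoto_order_parameter,
    peak_frequency,
    power_spectrum,
    synchrony_metastability,
)
from .simulation import SimulationParams, integrate
from .theory import collective_frequency_closed_form

__all__ = [
    "ParameterGrid",
    "EmpiricalSpectrum",
    "SweepResult",
    "spectral_distance",
    "resample_to_common_grid",
    "run_sweep",
    "best_fit_per_subject",
    "load_empirical_spectra",
]

#: common frequency grid for spectral distances: 0-80 Hz at 0.5 Hz
COMMON_GRID = np.arange(0.0, 80.0 + 1e-9, 0.5)


def _default_k_values() -> np.ndarray:
    # 10^-1 ... 10^1.7 in multiplicative steps of 10^0.1: 28 values
    return 10.0 ** (-1.0 + 0.1 * np.arange(28))


def _default_delays() -> np.ndarray:
    return np.arange(0, 31) * 1e-3


@dataclasses.dataclass(frozen=True)
class ParameterGrid:
    """Axes of the (K, <tau>) exploration plane."""

    k_values: np.ndarray = dataclasses.field(default_factory=_default_k_values)
    delays_s: np.ndarray = dataclasses.field(default_factory=_default_delays)

    def __post_init__(self) -> None:
        for name, ax in (("k_values", self.k_values), ("delays_s", self.delays_s)):
            ax = np.asarray(ax, dtype=float)
            if ax.ndim != 1 or len(ax) == 0:
                raise ValueError(f"{name} must be a non-empty 1-D axis")
            if np.any(np.diff(ax) <= 0):
                raise ValueError(f"{name} must be strictly increasing")
            object.__setattr__(self, name, ax)

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.k_values), len(self.delays_s)


@dataclasses.dataclass(frozen=True)
class EmpiricalSpectrum:
    """A subject's sensor-averaged power spectrum."""

    subject: str
    freqs: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.power) < 0):
            raise ValueError("power must be non-negative")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequencies must be increasing")


@dataclasses.dataclass
class SweepResult:
    """Per-cell observables over the grid (K-major layout, shape (nK, ntau))."""

    grid: ParameterGrid
    mean_R: np.ndarray
    std_R: np.ndarray
    peak_hz: np.ndarray
    analytic_hz: np.ndarray
    spectra: np.ndarray          # (nK, ntau, len(COMMON_GRID)) unit-mass spectra
    valid: np.ndarray            # boolean; False where integration failed
    distances: np.ndarray | None = None   # (nK, ntau, n_subjects)
    subjects: tuple[str, ...] = ()
    base_seed: int = 0


def resample_to_common_grid(
    freqs: np.ndarray, power: np.ndarray, grid: np.ndarray = COMMON_GRID
) -> np.ndarray:
    """Linear interpolation onto the common grid followed by unit-mass
    renormalization.  Out-of-range frequencies get zero power."""
    p = np.interp(grid, freqs, power, left=0.0, right=0.0)
    total = p.sum()
    if total == 0:
        raise ValueError("no spectral mass on the common grid")
    return p / total


def spectral_distance(
    a: PowerSpectrum | EmpiricalSpectrum,
    b: PowerSpectrum | EmpiricalSpectrum,
    grid: np.ndarray = COMMON_GRID,
) -> float:
    """Squared Euclidean distance between unit-mass spectra on a common grid."""
    pa = resample_to_common_grid(a.freqs, a.power, grid)
    pb = resample_to_common_grid(b.freqs, b.power, grid)
    return float(np.sum((pa - pb) ** 2))


def cell_seed(base_seed: int, ik: int, it: int) -> int:
    """Deterministic per-cell seed below 2^31, unique per (base, K, tau) index."""
    return int((base_seed * 1_000_003 + ik * 8191 + it * 131 + 7) % (2**31 - 1))


def _analyze_run(activity, transient: float):
    kop = kuramoto_order_parameter(
        activity.z, activity.dt, band="auto-peak", peak_transient=transient
    )
    mean_r, std_r = synchrony_metastability(kop, transient)
    zpost = activity.post_transient()
    ps = power_spectrum(np.real(zpost), activity.dt, normalize=True)
    pk = peak_frequency(ps, f_min=0.25)
    spec = resample_to_common_grid(ps.freqs, ps.power)
    return mean_r, std_r, pk, spec


def run_sweep(
    c: Connectome,
    grid: ParameterGrid,
    base: SimulationParams,
    refs: list[EmpiricalSpectrum] | None = None,
    checkpoint: str | Path | None = None,
    progress: bool = False,
) -> SweepResult:
    """One simulation per grid cell; observables post-transient.

    Per-cell seeds derive deterministically from ``base.seed`` and the cell
    indices, so cells are order-independent: a resumed or parallelized sweep
    gives results identical to serial execution.  A failed integration marks
    its cell invalid and the sweep continues.  ``checkpoint`` names an .npz
    file updated after each cell and consulted on restart.
    """
    nK, nT = grid.shape
    nF = len(COMMON_GRID)
    res = SweepResult(
        grid=grid,
        mean_R=np.full((nK, nT), np.nan),
        std_R=np.full((nK, nT), np.nan),
        peak_hz=np.full((nK, nT), np.nan),
        analytic_hz=np.full((nK, nT), np.nan),
        spectra=np.zeros((nK, nT, nF)),
        valid=np.zeros((nK, nT), dtype=bool),
        base_seed=base.seed,
    )
    done = np.zeros((nK, nT), dtype=bool)
    ckpt = Path(checkpoint) if checkpoint else None
    if ckpt is not None and ckpt.exists():
        with np.load(ckpt) as f:
            if f["mean_R"].shape == res.mean_R.shape and int(f["base_seed"]) == base.seed:
                res.mean_R, res.std_R = f["mean_R"], f["std_R"]
                res.peak_hz, res.analytic_hz = f["peak_hz"], f["analytic_hz"]
                res.spectra, res.valid = f["spectra"], f["valid"]
                done = f["done"]
    iterator = [(ik, it) for ik in range(nK) for it in range(nT)]
    if progress:
        try:
            from tqdm import tqdm

            iterator = tqdm(iterator, desc="sweep")
        except ImportError:
            pass
    for ik, it in iterator:
        if done[ik, it]:
            continue
        K = float(grid.k_values[ik])
        tau = float(grid.delays_s[it])
        params = base.replace(
            K=K, mean_delay_s=tau, speed_mps=None, seed=cell_seed(base.seed, ik, it)
        )
        res.analytic_hz[ik, it] = collective_frequency_closed_form(
            base.omega0_hz, K, c.n, tau
        )
        try:
            activity = integrate(c, params)
            mean_r, std_r, pk, spec = _analyze_run(activity, base.transient)
        except (FloatingPointError, ValueError, MemoryError):
            done[ik, it] = True
            continue
        res.mean_R[ik, it], res.std_R[ik, it] = mean_r, std_r
        res.peak_hz[ik, it] = pk
        res.spectra[ik, it] = spec
        res.valid[ik, it] = True
        done[ik, it] = True
        if ckpt is not None:
            np.savez_compressed(
                ckpt,
                mean_R=res.mean_R, std_R=res.std_R, peak_hz=res.peak_hz,
                analytic_hz=res.analytic_hz, spectra=res.spectra,
                valid=res.valid, done=done, base_seed=base.seed,
            )
    if refs:
        res.subjects = tuple(r.subject for r in refs)
        res.distances = np.full((nK, nT, len(refs)), np.nan)
        for j, ref in enumerate(refs):
            target = resample_to_common_grid(ref.freqs, ref.power)
            d = np.sum((res.spectra - target) ** 2, axis=-1)
            d[~res.valid] = np.nan
            res.distances[:, :, j] = d
    return res


def best_fit_per_subject(sweep: SweepResult) -> pd.DataFrame:
    """Argmin cell per subject; ties break toward smaller K, then smaller delay.

    Returns one row per subject (subject, ik, itau, K, delay_s, distance).
    """
    if sweep.distances is None:
        raise ValueError("sweep carries no reference-spectrum distances")
    if not sweep.valid.any():
        raise ValueError("all cells invalid")
    rows = []
    nK, nT, _ = sweep.distances.shape
    for j, subject in enumerate(sweep.subjects):
        d = sweep.distances[:, :, j]
        if np.all(np.isnan(d)):
            raise ValueError(f"no valid distance for subject {subject}")
        best = (np.inf, None)
        # K-major, delay-minor ascending scan makes the first strict minimum
        # the tie-winner (smaller K, then smaller delay)
        for ik in range(nK):
            for it in range(nT):
                v = d[ik, it]
                if np.isfinite(v) and v < best[0]:
                    best = (v, (ik, it))
        ik, it = best[1]
        rows.append(
            {
                "subject": subject,
                "ik": ik,
                "itau": it,
                "K": sweep.grid.k_values[ik],
                "delay_s": sweep.grid.delays_s[it],
                "distance": best[0],
            }
        )
    return pd.DataFrame(rows)


def load_empirical_spectra(path: str | Path) -> list[EmpiricalSpectrum]:
    """Load subject spectra from delimited text files or a MAT container.

    A directory is scanned for ``*.csv``/``*.tsv`` files of (frequency, power)
    rows, one subject per file (subject id = file stem).  A ``.mat`` file is
    expected to hold ``freqs`` (F,) and ``spectra`` (subjects x F).
    """
    path = Path(path)
    out: list[EmpiricalSpectrum] = []
    if path.is_dir():
        for f in sorted(list(path.glob("*.csv")) + list(path.glob("*.tsv"))):
            sep = "\t" if f.suffix == ".tsv" else ","
            arr = np.loadtxt(f, delimiter=sep)
            out.append(EmpiricalSpectrum(f.stem, arr[:, 0], arr[:, 1]))
    elif path.suffix.lower() == ".mat":
        from scipy.io import loadmat

        data = loadmat(path)
        freqs = np.asarray(data["freqs"]).ravel()
        spectra = np.atleast_2d(np.asarray(data["spectra"]))
        for i, row in enumerate(spectra):
            out.append(EmpiricalSpectrum(f"subject{i:03d}", freqs, row))
    else:
        raise ValueError(f"unsupported spectra source: {path}")
    if not out:
        raise ValueError(f"no spectra found at {path}")
    return out
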