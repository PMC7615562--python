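"""Structural connectomes: loading, validation, normalization, delays, synthesis.

A connectome is a pair of square symmetric matrices over ``n`` brain areas:
coupling weights ``C`` (unitless, e.g. streamline counts) and tract lengths
``D`` (mm).  Lengths convert to conduction delays ``tau_np = D_np / v`` for a
homogeneous conduction speed ``v`` (m/s); on a fixed integration grid the
delays are discretized to integer step lags.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import numpy as np

__all__ = [
    "Connectome",
    "DelaySchedule",
    "load_connectome",
    "save_connectome",
    "normalize_to_unit_mean",
    "build_delay_schedule",
    "generate_synthetic_connectome",
]

#: tolerance below which asymmetric inputs are silently symmetrized by averaging
SYMMETRY_TOL = 1e-9


@dataclasses.dataclass(frozen=True)
class Connectome:
    """Weighted structural network with inter-area tract lengths.

    Attributes
    ----------
    weights : (n, n) ndarray
        Non-negative, symmetric, zero-diagonal relative coupling strengths.
    lengths : (n, n) ndarray
        Non-negative, symmetric, zero-diagonal tract lengths in millimetres.
        Positive wherever the corresponding weight is positive.
    labels : tuple of str
        Area names, length ``n``.
    """

    weights: np.ndarray
    lengths: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        d = np.asarray(self.lengths, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be a square matrix")
        if d.shape != w.shape:
            raise ValueError(
                f"size mismatch between weights {w.shape} and lengths {d.shape}"
            )
        for name, m in (("weights", w), ("lengths", d)):
            if not np.all(np.isfinite(m)):
                raise ValueError(f"{name} contains non-finite entries")
            if np.any(m < 0):
                raise ValueError(f"{name} contains negative entries")
            asym = np.abs(m - m.T).max(initial=0.0)
            if asym > SYMMETRY_TOL:
                raise ValueError(f"asymmetric {name} (max deviation {asym:g})")
        # symmetrize sub-tolerance numerical asymmetry, clear the diagonal
        w = 0.5 * (w + w.T)
        d = 0.5 * (d + d.T)
        np.fill_diagonal(w, 0.0)
        np.fill_diagonal(d, 0.0)
        if np.any((w > 0) & (d == 0)):
            raise ValueError("zero length on a connected pair (weights > 0)")
        labels = tuple(self.labels) if self.labels else tuple(
            f"area{i}" for i in range(w.shape[0])
        )
        if len(labels) != w.shape[0]:
            raise ValueError("label count does not match matrix size")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "lengths", d)
        object.__setattr__(self, "labels", labels)

    @property
    def n(self) -> int:
        return self.weights.shape[0]

    @property
    def mean_length(self) -> float:
        """Mean tract length <D> (mm) over connected pairs (weights > 0)."""
        mask = self.weights > 0
        if not mask.any():
            raise ValueError("connectome has no connections")
        return float(self.lengths[mask].mean())

    def offdiag_mean_weight(self, include_zeros: bool = True) -> float:
        off = ~np.eye(self.n, dtype=bool)
        w = self.weights[off]
        if not include_zeros:
            w = w[w > 0]
        return float(w.mean())


@dataclasses.dataclass(frozen=True)
class DelaySchedule:
    """Integer step lags implementing conduction delays on a fixed grid.

    ``lags[n, p] = round(D_np / v / dt)`` (half-up).  ``mean_delay`` is the
    continuous mean delay <D>/v over connected pairs; ``speed`` is m/s and may
    be ``inf`` to encode the zero-delay condition.
    """

    lags: np.ndarray
    dt: float
    speed: float
    mean_delay: float

    @property
    def max_lag(self) -> int:
        return int(self.lags.max(initial=0))


def normalize_to_unit_mean(c: Connectome, include_zeros: bool = True) -> Connectome:
    """Rescale weights so the off-diagonal mean equals 1 (<C> = 1).

    By default the mean runs over all n(n-1) off-diagonal entries including
    zeros, which makes row sums of the normalized matrix of order n — the
    scaling under which the collective-frequency prediction uses the product
    K*N.  Set ``include_zeros=False`` to average over connected pairs only.
    Lengths and zero entries are untouched.
    """
    mean = c.offdiag_mean_weight(include_zeros=include_zeros)
    if mean == 0:
        raise ValueError("all-zero weight matrix cannot be normalized")
    return Connectome(c.weights / mean, c.lengths, c.labels)


def build_delay_schedule(c: Connectome, speed: float, dt: float) -> DelaySchedule:
    """Discretize conduction delays D/v onto the integration grid.

    ``speed`` in m/s (``inf`` gives the zero-delay condition), ``dt`` in
    seconds; lengths are mm.  Lags round half-up to the nearest step, so the
    per-edge discretization error is at most dt/2.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if speed <= 0:
        raise ValueError("speed must be positive (inf encodes zero delay)")
    if math.isinf(speed):
        lags = np.zeros_like(c.lengths, dtype=np.int64)
        return DelaySchedule(lags=lags, dt=dt, speed=speed, mean_delay=0.0)
    tau = c.lengths * 1e-3 / speed  # mm -> m, then seconds
    lags = np.floor(tau / dt + 0.5).astype(np.int64)  # half-up, ties away from zero
    np.fill_diagonal(lags, 0)
    mask = c.weights > 0
    mean_delay = float(tau[mask].mean()) if mask.any() else 0.0
    return DelaySchedule(lags=lags, dt=dt, speed=speed, mean_delay=mean_delay)


def speed_for_mean_delay(c: Connectome, mean_delay_s: float) -> float:
    """Conduction speed (m/s) realizing a requested mean delay on this network.

    v = <D>/<tau> with <D> the mean length over connected pairs; a zero mean
    delay maps to infinite speed rather than a division.
    """
    if mean_delay_s < 0:
        raise ValueError("mean delay must be non-negative")
    if mean_delay_s == 0:
        return math.inf
    return c.mean_length * 1e-3 / mean_delay_s


# ---------------------------------------------------------------------------
# I/O: delimited text (one file per matrix) and MATLAB v7 container


def _read_delimited(path: Path) -> tuple[np.ndarray, list[str] | None]:
    text = path.read_text().strip().splitlines()
    if not text:
        raise ValueError(f"{path}: empty matrix file")
    sep = "\t" if "\t" in text[0] else ","
    first = text[0].split(sep)
    labels: list[str] | None = None
    try:
        [float(v) for v in first]
        rows = text
    except ValueError:
        labels = [v.strip() for v in first]
        rows = text[1:]
    mat = np.array([[float(v) for v in row.split(sep)] for row in rows])
    return mat, labels


def load_connectome(
    weights_path: str | Path,
    lengths_path: str | Path | None = None,
    fmt: str | None = None,
) -> Connectome:
    """Load a connectome from delimited text (two files) or a MAT container.

    Text format: one file per matrix, comma- or tab-separated, optional header
    row of area labels.  MAT format: a single file holding square variables
    named ``C`` (weights) and ``D`` (lengths).
    """
    weights_path = Path(weights_path)
    if fmt is None:
        fmt = "mat" if weights_path.suffix.lower() == ".mat" else "text"
    if fmt == "mat":
        from scipy.io import loadmat

        data = loadmat(weights_path)
        if "C" not in data or "D" not in data:
            raise ValueError(f"{weights_path}: MAT container must hold 'C' and 'D'")
        return Connectome(np.asarray(data["C"], float), np.asarray(data["D"], float), ())
    if lengths_path is None:
        raise ValueError("text format requires separate weights and lengths files")
    w, labels = _read_delimited(weights_path)
    d, _ = _read_delimited(Path(lengths_path))
    return Connectome(w, d, tuple(labels) if labels else ())


def save_connectome(
    c: Connectome, weights_path: str | Path, lengths_path: str | Path, sep: str = ","
) -> None:
    """Write weights and lengths as delimited text with a label header row."""
    for path, mat in ((weights_path, c.weights), (lengths_path, c.lengths)):
        lines = [sep.join(c.labels)]
        lines += [sep.join(repr(float(v)) for v in row) for row in mat]
        Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Synthetic connectomes


def generate_synthetic_connectome(
    n: int,
    n_modules: int = 3,
    density: float = 0.6,
    seed: int = 0,
    mean_length_mm: float = 70.0,
    within_module_boost: float = 5.0,
) -> Connectome:
    """Random modular connectome emulating tract-count networks.

    Weights are symmetric, non-negative, zero-diagonal and heavy-tailed
    (lognormal magnitudes), with within-module connections both denser and
    ``within_module_boost`` times stronger than between-module ones.  Lengths
    are Euclidean distances between random 3-D node positions, rescaled so
    their mean over connected pairs is ``mean_length_mm`` — the
    centimetre-scale geometry of a human brain parcellation.
    """
    if n < 2:
        raise ValueError("need at least 2 nodes")
    if n_modules > n:
        raise ValueError("more modules than nodes")
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")
    rng = np.random.default_rng(seed)
    module = rng.integers(0, n_modules, size=n)
    same = module[:, None] == module[None, :]

    # module centres pulled apart so within-module pairs are also nearer in space
    centres = rng.normal(scale=40.0, size=(n_modules, 3))
    pos = centres[module] + rng.normal(scale=15.0, size=(n, 3))
    dist = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)

    p_within = min(1.0, density * 1.5)
    p_between = density * 0.5
    conn_prob = np.where(same, p_within, p_between)
    upper = np.triu(rng.random((n, n)) < conn_prob, k=1)
    adj = upper | upper.T

    mag = rng.lognormal(mean=0.0, sigma=1.0, size=(n, n))
    mag = np.triu(mag, 1)
    mag = mag + mag.T
    w = np.where(adj, mag * np.where(same, within_module_boost, 1.0), 0.0)

    # guarantee connectivity: chain adjacent nodes so no isolated node exists
    for i in range(n - 1):
        if w[i, i + 1] == 0 and w[i].sum() == 0:
            w[i, i + 1] = w[i + 1, i] = float(rng.lognormal(0.0, 1.0))

    mask = w > 0
    d = dist * (mean_length_mm / dist[mask].mean())
    np.fill_diagonal(d, 0.0)
    labels = tuple(f"area{i:02d}" for i in range(n))
    return Connectome(w, d, labels)
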