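"""Analytic collective frequency of delay-coupled synchronization.

A fully synchronized one-cluster state of N oscillators with natural
frequency omega_0, homogeneous delay tau and (unit-mean normalized) coupling
K rotates at a frequency Omega satisfying the self-consistency relation

    Omega = omega_0 - K * N * sin(Omega * tau)

For small Omega*tau this linearizes to the closed form

    Omega_min = omega_0 / (1 + K * N * tau)

the lowest branch, which the coupled system settles on as synchrony is
approached.  For large K*N*tau the relation has multiple fixed points
(multistability).  All Omegas are angular internally; the public API speaks
Hz (the reduction ratio is identical in both units).
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "FrequencySolutionSet",
    "collective_frequency_closed_form",
    "collective_frequency_roots",
]


@dataclasses.dataclass(frozen=True)
class FrequencySolutionSet:
    """All fixed points of the delay self-consistency relation, in rad/s."""

    omega0: float           # rad/s
    K: float
    N: int
    tau: float              # s
    solutions: tuple[float, ...]   # rad/s, ascending
    stable_advisory: tuple[bool, ...]  # |K N tau cos(Omega tau)| < 1 per solution

    @property
    def lowest(self) -> float:
        return self.solutions[0]

    @property
    def solutions_hz(self) -> tuple[float, ...]:
        return tuple(s / (2 * math.pi) for s in self.solutions)

    @property
    def lowest_hz(self) -> float:
        return self.lowest / (2 * math.pi)


def _check_nonneg(omega0_hz: float, K: float, N: int, tau_s: float) -> None:
    if omega0_hz <= 0:
        raise ValueError("natural frequency must be positive")
    if K < 0 or tau_s < 0:
        raise ValueError("K and tau must be non-negative")
    if N < 1:
        raise ValueError("N must be >= 1")


def collective_frequency_closed_form(
    omega0_hz: float, K: float, N: int, mean_delay_s: float
) -> float:
    """Lowest collective frequency omega_0 / (1 + K*N*tau), in Hz."""
    _check_nonneg(omega0_hz, K, N, mean_delay_s)
    return omega0_hz / (1.0 + K * N * mean_delay_s)


def collective_frequency_roots(
    omega0_hz: float,
    K: float,
    N: int,
    tau_s: float,
    search_ceiling_hz: float | None = None,
    points_per_period: int = 40,
) -> FrequencySolutionSet:
    """Enumerate all synchronized-frequency fixed points by bracketing.

    Scans f(Omega) = Omega - omega_0 + K*N*sin(Omega*tau) for sign changes on
    a grid with at least ``points_per_period`` points per delay period
    2*pi/tau, then bisects each bracket to ~1e-12 relative tolerance.
    """
    _check_nonneg(omega0_hz, K, N, tau_s)
    omega0 = 2 * math.pi * omega0_hz
    KN = K * N
    if tau_s == 0 or KN == 0:
        return FrequencySolutionSet(omega0, K, N, tau_s, (omega0,), (True,))
    if search_ceiling_hz is None:
        search_ceiling_hz = omega0_hz + KN / (2 * math.pi) + 1.0
    elif search_ceiling_hz < omega0_hz:
        raise ValueError("search ceiling must be at least the natural frequency")
    ceiling = 2 * math.pi * search_ceiling_hz

    def f(om: float) -> float:
        return om - omega0 + KN * math.sin(om * tau_s)

    period = 2 * math.pi / tau_s
    n_grid = max(int(math.ceil(ceiling / period * points_per_period)), 200)
    grid = np.linspace(0.0, ceiling, n_grid + 1)
    vals = grid - omega0 + KN * np.sin(grid * tau_s)

    roots: list[float] = []
    for i in range(n_grid):
        a, b = grid[i], grid[i + 1]
        fa, fb = vals[i], vals[i + 1]
        if fa == 0.0 and a > 0:
            roots.append(a)
        elif fa * fb < 0:
            roots.append(brentq(f, a, b, xtol=1e-12 * max(omega0, 1.0), rtol=1e-14))
    if vals[-1] == 0.0:
        roots.append(grid[-1])
    # dedupe near-identical roots from grid-point hits
    roots = sorted(roots)
    merged: list[float] = []
    for r in roots:
        if not merged or r - merged[-1] > 1e-9 * max(omega0, 1.0):
            merged.append(r)
    if not merged:  # cannot happen for tau, K >= 0; guarded anyway
        raise RuntimeError("no synchronized solution found in search range")
    stable = tuple(abs(KN * tau_s * math.cos(r * tau_s)) < 1.0 for r in merged)
    return FrequencySolutionSet(omega0, K, N, tau_s, tuple(merged), stable)
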