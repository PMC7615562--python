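"""Metastable oscillatory mode (MOM) detection and statistics.

A node engages in a MOM when its band-limited amplitude envelope exceeds a
threshold calibrated from a matched zero-delay run: for each node and band,
5 standard deviations of the envelope that emerges from purely noisy
(delay-free) interactions.  Detected supra-threshold episodes are summarized
per band by duration (consecutive supra-threshold time), size (simultaneously
supra-threshold node count) and occupancy (fraction of node-time above
threshold).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .connectome import Connectome
from .observables import (
    CANONICAL_BANDS,
    BandSpec,
    bandpass,
    filter_margin_samples,
    hilbert_envelope,
)
from .simulation import SimulatedActivity, SimulationParams, integrate

__all__ = [
    "BaselineThresholds",
    "MOMStats",
    "calibrate_baseline",
    "thresholds_from_activity",
    "band_envelopes",
    "detect_moms",
    "mom_statistics",
]

DEFAULT_SD_MULTIPLIER = 5.0


@dataclasses.dataclass(frozen=True)
class BaselineThresholds:
    """Per-node, per-band envelope thresholds from a zero-delay baseline run."""

    values: np.ndarray          # (n_nodes, n_bands), envelope units, > 0
    bands: tuple[BandSpec, ...]
    multiplier: float
    calibration: dict           # K, seed, duration, mode of the baseline run

    def __post_init__(self) -> None:
        if np.any(self.values <= 0):
            raise ValueError("degenerate baseline: zero-variance envelope")
        if self.values.shape[1] != len(self.bands):
            raise ValueError("one threshold column per band required")


@dataclasses.dataclass(frozen=True)
class MOMStats:
    """Per-band duration / size / occupancy summary of detected MOMs."""

    bands: tuple[str, ...]
    duration_mean: np.ndarray   # s
    duration_sd: np.ndarray
    size_mean: np.ndarray       # simultaneously active node count
    size_sd: np.ndarray
    occupancy: np.ndarray       # fraction of node-time in [0, 1]
    n_events: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "band": self.bands,
                "duration_mean_s": self.duration_mean,
                "duration_sd_s": self.duration_sd,
                "size_mean": self.size_mean,
                "size_sd": self.size_sd,
                "occupancy": self.occupancy,
                "n_events": self.n_events,
            }
        )


def band_envelopes(
    z: np.ndarray, dt: float, bands: tuple[BandSpec, ...] = CANONICAL_BANDS
) -> np.ndarray:
    """Hilbert amplitude envelopes of the band-filtered real parts.

    Returns an (n_nodes, n_samples, n_bands) array.
    """
    x = np.real(z)
    out = np.empty(x.shape + (len(bands),))
    for b, band in enumerate(bands):
        out[..., b] = hilbert_envelope(bandpass(x, band, dt))
    return out


def thresholds_from_activity(
    baseline: SimulatedActivity,
    bands: tuple[BandSpec, ...] = CANONICAL_BANDS,
    multiplier: float = DEFAULT_SD_MULTIPLIER,
) -> BaselineThresholds:
    """Thresholds = multiplier x SD of each node's post-transient band envelope.

    The full series is filtered and the SD taken over an interior window
    (transient and filter edge margins excluded).
    """
    x = np.real(baseline.z)
    sd = np.empty((x.shape[0], len(bands)))
    for b, band in enumerate(bands):  # band-at-a-time keeps memory bounded
        margin = filter_margin_samples(band.f_lo, baseline.dt)
        i0 = max(round(baseline.params.transient / baseline.dt), margin)
        i1 = max(x.shape[1] - margin, i0 + 1)
        env = hilbert_envelope(bandpass(x, band, baseline.dt))
        sd[:, b] = env[:, i0:i1].std(axis=1)
    if np.any(sd == 0):
        raise ValueError("zero-variance envelope in baseline run")
    calib = {
        "K": baseline.params.K,
        "seed": baseline.params.seed,
        "duration": baseline.params.duration,
        "zero_delay": True,
    }
    return BaselineThresholds(multiplier * sd, tuple(bands), multiplier, calib)


def calibrate_baseline(
    c: Connectome,
    params: SimulationParams,
    bands: tuple[BandSpec, ...] = CANONICAL_BANDS,
    multiplier: float = DEFAULT_SD_MULTIPLIER,
    seed: int | None = None,
) -> BaselineThresholds:
    """Run the zero-delay baseline simulation and derive thresholds.

    ``params`` should match the target run except that delays are forced to
    zero here (infinite conduction speed).  The calibration uses an
    independent seed by default (``params.seed + 104729``), recorded in the
    returned provenance.
    """
    calib_seed = params.seed + 104729 if seed is None else seed
    base = params.replace(speed_mps=np.inf, mean_delay_s=None, seed=calib_seed)
    activity = integrate(c, base)
    return thresholds_from_activity(activity, bands, multiplier)


def detect_moms(
    activity: SimulatedActivity,
    thresholds: BaselineThresholds,
    bands: tuple[BandSpec, ...] | None = None,
    transient: float | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Supra-threshold mask and event table for a simulated run.

    Returns ``(mask, events)`` where ``mask`` is boolean
    (n_nodes, n_samples, n_bands) — true where the band envelope exceeds the
    node's calibrated threshold — and ``events`` lists maximal true runs as
    rows (node, band, start_s, end_s).  ``transient`` (defaults to the run's
    configured transient) is trimmed before detection.
    """
    bands = thresholds.bands if bands is None else tuple(bands)
    if bands != thresholds.bands:
        raise ValueError("requested bands do not match calibrated bands")
    if activity.n_nodes != thresholds.values.shape[0]:
        raise ValueError("node count mismatch between activity and thresholds")
    transient = activity.params.transient if transient is None else transient
    # one common interior window across bands (largest filter edge margin)
    margin = max(filter_margin_samples(b.f_lo, activity.dt) for b in bands)
    i0 = max(round(transient / activity.dt), margin)
    i1 = max(activity.n_samples - margin, i0 + 1)
    x = np.real(activity.z)
    mask = np.empty((x.shape[0], i1 - i0, len(bands)), dtype=bool)
    for b, band in enumerate(bands):  # band-at-a-time keeps memory bounded
        env = hilbert_envelope(bandpass(x, band, activity.dt))
        mask[..., b] = env[:, i0:i1] > thresholds.values[:, b : b + 1]
    events = events_from_mask(mask, activity.dt, bands, t_offset=i0 * activity.dt)
    return mask, events


def events_from_mask(
    mask: np.ndarray,
    dt: float,
    bands: tuple[BandSpec, ...],
    t_offset: float = 0.0,
) -> pd.DataFrame:
    """Maximal consecutive true runs per (node, band) as a tidy event table."""
    records = []
    n_nodes, _, n_bands = mask.shape
    for b in range(n_bands):
        for node in range(n_nodes):
            m = mask[node, :, b]
            if not m.any():
                continue
            edges = np.diff(m.astype(np.int8))
            starts = np.flatnonzero(edges == 1) + 1
            ends = np.flatnonzero(edges == -1) + 1
            if m[0]:
                starts = np.r_[0, starts]
            if m[-1]:
                ends = np.r_[ends, len(m)]
            for s, e in zip(starts, ends):
                records.append(
                    (node, bands[b].name, t_offset + s * dt, t_offset + e * dt)
                )
    return pd.DataFrame(records, columns=["node", "band", "start_s", "end_s"])


def mom_statistics(
    mask: np.ndarray,
    dt: float,
    bands: tuple[BandSpec, ...] = CANONICAL_BANDS,
    size_over_active_only: bool = True,
) -> MOMStats:
    """Summarize a supra-threshold mask into per-band duration/size/occupancy.

    Size averages the simultaneously-active node count over samples with at
    least one active node by default (set ``size_over_active_only=False`` to
    average over all samples).  An all-false band yields zeros throughout.
    """
    n_nodes, n_samples, n_bands = mask.shape
    if len(bands) != n_bands:
        raise ValueError("band list does not match mask depth")
    dur_mean = np.zeros(n_bands)
    dur_sd = np.zeros(n_bands)
    size_mean = np.zeros(n_bands)
    size_sd = np.zeros(n_bands)
    occupancy = np.zeros(n_bands)
    n_events = np.zeros(n_bands, dtype=int)
    events = events_from_mask(mask, dt, bands)
    for b, band in enumerate(bands):
        sub = events[events["band"] == band.name]
        if len(sub):
            lengths = (sub["end_s"] - sub["start_s"]).to_numpy()
            dur_mean[b] = lengths.mean()
            dur_sd[b] = lengths.std()
            n_events[b] = len(sub)
        counts = mask[:, :, b].sum(axis=0)
        active = counts[counts >= 1] if size_over_active_only else counts
        if active.size:
            size_mean[b] = active.mean()
            size_sd[b] = active.std()
        occupancy[b] = mask[:, :, b].sum() / (n_nodes * n_samples)
    return MOMStats(
        bands=tuple(b.name for b in bands),
        duration_mean=dur_mean,
        duration_sd=dur_sd,
        size_mean=size_mean,
        size_sd=size_sd,
        occupancy=occupancy,
        n_events=n_events,
    )
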