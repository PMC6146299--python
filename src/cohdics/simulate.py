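"""Synthetic multi-subject, two-condition oscillatory sensor data.

The generator emulates the statistical structure the downstream analysis
assumes: a small number of narrowband dipole sources with a *known*
inter-source coherence, projected to the sensors through the forward
model, plus white sensor noise.  Coupling between two sources is imposed
by construction,

    s2 = c * quadrature(s1) + sqrt(1 - c^2) * independent process,

where quadrature(.) is the Hilbert transform, a 90-degree phase shift
within the band.  All source signals are normalized to unit variance
per epoch, so the expected magnitude-squared coherence at the band
centre is c^2; because the quadrature component is instantaneously
uncorrelated with s1, the sources do not interfere at the sensors and
the sensor-level band power is the same for any value of c.  Conditions
that differ only in coupling are therefore power-matched by
construction, which is the regime the group contrast is designed for.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .geometry import ForwardModel, forward_to_tangential

__all__ = [
    "SimulationConfig",
    "EpochsData",
    "simulate_source_pair",
    "simulate_epochs",
    "simulate_group",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated recording session.

    active_sources: list of (vertex_id, in-plane orientation angle in
        radians); the angle selects the dipole orientation within the
        tangential plane.
    coupling: target coherence (amplitude mixing coefficient c, giving
        magnitude-squared coherence c^2) between consecutive active
        sources (source k+1 is coupled to source k's signal).  A scalar
        applies to the first pair; a sequence gives one value per pair.
    snr: RMS signal field over RMS sensor noise, averaged over sensors.
    noise_sigma: absolute sensor noise standard deviation in tesla, used
        when there are no active sources (otherwise noise is scaled from
        snr).
    """

    fs: float = 200.0
    tmin: float = -0.8
    tmax: float = 1.2
    n_epochs: int = 100
    carrier_band: tuple[float, float] = (8.0, 12.0)
    active_sources: tuple = ()
    coupling: float | tuple = 0.0
    snr: float = 2.0
    n_subjects: int = 16
    seed: int = 0
    noise_sigma: float = 1e-13

    def __post_init__(self):
        if self.fs <= 2.0 * self.carrier_band[1]:
            raise ValueError("fs must exceed twice the upper carrier frequency")
        if self.tmax <= self.tmin:
            raise ValueError("tmax must exceed tmin")
        for c in np.atleast_1d(self.coupling):
            if not 0.0 <= c <= 1.0:
                raise ValueError("coupling must lie in [0, 1]")

    @property
    def n_times(self) -> int:
        return int(round((self.tmax - self.tmin) * self.fs)) + 1

    @property
    def times(self) -> np.ndarray:
        return self.tmin + np.arange(self.n_times) / self.fs


@dataclass(frozen=True)
class EpochsData:
    """Epoch x sensor x time array (tesla) with its sampling metadata."""

    data: np.ndarray
    fs: float
    tmin: float

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 3:
            raise ValueError("data must be epoch x sensor x time")
        if not np.all(np.isfinite(data)):
            raise ValueError("epoch data must be finite")
        object.__setattr__(self, "data", data)

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_sensors(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.tmin + np.arange(self.data.shape[2]) / self.fs


def _narrowband_noise(rng, n_epochs, n_times, band, fs):
    """Unit-variance Gaussian processes band-limited to ``band`` (zero-phase)."""
    pad = n_times  # generous padding so filtfilt transients stay outside
    white = rng.standard_normal((n_epochs, n_times + 2 * pad))
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, white, axis=-1)[:, pad:pad + n_times]
    return x / x.std(axis=-1, keepdims=True)


def _source_time_courses(cfg: SimulationConfig, rng) -> np.ndarray:
    """(n_sources, n_epochs, n_times) unit-variance coupled narrowband signals."""
    n_src = len(cfg.active_sources)
    couplings = np.broadcast_to(
        np.atleast_1d(np.asarray(cfg.coupling, dtype=float)),
        (max(n_src - 1, 1),),
    )
    base = _narrowband_noise(
        rng, n_src * cfg.n_epochs, cfg.n_times, cfg.carrier_band, cfg.fs
    ).reshape(n_src, cfg.n_epochs, cfg.n_times)
    out = np.empty_like(base)
    for k in range(n_src):
        if k == 0:
            out[k] = base[k]
        else:
            c = couplings[k - 1]
            quad = signal.hilbert(out[k - 1], axis=-1).imag
            quad = quad / quad.std(axis=-1, keepdims=True)
            mixed = c * quad + np.sqrt(1.0 - c * c) * base[k]
            out[k] = mixed / mixed.std(axis=-1, keepdims=True)
    return out


def simulate_source_pair(cfg: SimulationConfig, rng=None) -> np.ndarray:
    """Two coupled narrowband source time courses, (2, n_epochs, n_times).

    The second series mixes the quadrature of the first (weight c) with
    an independent process (weight sqrt(1-c^2)), renormalized to unit
    variance per epoch; its expected band coherence with the first is
    c^2.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    cfg2 = replace(cfg, active_sources=((0, 0.0), (1, 0.0)))
    return _source_time_courses(cfg2, rng)


def simulate_epochs(
    fwd: ForwardModel, cfg: SimulationConfig, rng=None
) -> tuple[EpochsData, dict]:
    """Project the configured sources through ``fwd`` and add sensor noise.

    Returns the epochs and a ground-truth record (vertex ids, in-plane
    angles, coupling, source signals and noise level actually used).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if fwd.n_orient == 3:
        fwd = forward_to_tangential(fwd)
    n_sensors = fwd.sensor_array.n_sensors
    data = np.zeros((cfg.n_epochs, n_sensors, cfg.n_times))
    sources = _source_time_courses(cfg, rng) if cfg.active_sources else None
    vids = list(fwd.source_space.vertex_ids)
    gains = []
    for k, (vid, angle) in enumerate(cfg.active_sources):
        if vid not in vids:
            raise ValueError(f"vertex {vid} not in the forward model")
        rows = fwd.leadfields[vids.index(vid)]  # (2, n_sensors)
        gain = np.sin(angle) * rows[0] + np.cos(angle) * rows[1]
        gains.append(gain)
        data += sources[k][:, None, :] * gain[None, :, None]
    if cfg.active_sources:
        rms = np.sqrt((data**2).mean(axis=(0, 2)))  # per-sensor signal RMS
        noise_sigma = rms.mean() / cfg.snr
    else:
        noise_sigma = cfg.noise_sigma
    data += noise_sigma * rng.standard_normal(data.shape)
    truth = {
        "active_sources": tuple(cfg.active_sources),
        "coupling": cfg.coupling,
        "noise_sigma": noise_sigma,
        "gains": np.array(gains) if gains else np.empty((0, n_sensors)),
        "source_signals": sources,
    }
    return EpochsData(data=data, fs=cfg.fs, tmin=cfg.tmin), truth


def simulate_group(
    fwd: ForwardModel,
    cfg_by_condition: dict[str, SimulationConfig],
    n_subjects: int,
    angle_jitter: float = 0.0,
) -> list[dict[str, tuple[EpochsData, dict]]]:
    """Per-subject, per-condition epochs with deterministic seeding.

    Each subject gets an independent substream derived from the master
    seed of the first condition's config; conditions of one subject
    share the subject's source-orientation jitter but use independent
    noise and signal realizations.
    """
    if n_subjects < 2:
        raise ValueError("a group needs at least 2 subjects")
    master = next(iter(cfg_by_condition.values())).seed
    n_active = max(
        (len(c.active_sources) for c in cfg_by_condition.values()), default=0
    )
    out = []
    for subj in range(n_subjects):
        subj_entry = {}
        jitter_rng = np.random.default_rng((master, subj, 0xA5))
        jitters = angle_jitter * jitter_rng.standard_normal(max(n_active, 1))
        for ci, (cond, cfg) in enumerate(sorted(cfg_by_condition.items())):
            active = tuple(
                (vid, angle + dj)
                for (vid, angle), dj in zip(cfg.active_sources, jitters)
            )
            rng = np.random.default_rng((master, subj, ci))
            subj_entry[cond] = simulate_epochs(
                fwd, replace(cfg, active_sources=active), rng
            )
        out.append(subj_entry)
    return out
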