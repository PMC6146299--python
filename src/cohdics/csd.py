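"""Morlet-wavelet cross-spectral density estimation.

The sensor signals are transformed to the time-frequency domain by
linear convolution with complex Morlet wavelets and the cross-spectral
density (CSD) between every sensor pair is averaged over the analysis
window, per epoch, and then over epochs.  The wavelet's temporal width
is set by the number of oscillations it completes,

    sigma_t = n_o / (2 pi f),

so a fixed ``n_cycles`` trades frequency resolution for temporal
resolution as f grows.  Per-frequency CSD matrices are kept separate;
band averaging is an explicit second step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _sig

from .simulate import EpochsData

__all__ = [
    "MorletWavelet",
    "CSDMatrix",
    "make_morlet",
    "demean_epoch",
    "wavelet_transform",
    "csd_morlet",
    "csd_band_mean",
    "EdgeEffectWarning",
]


class EdgeEffectWarning(UserWarning):
    """Analysis window too close to an epoch edge for the wavelet length."""


@dataclass(frozen=True)
class MorletWavelet:
    f: float  # center frequency, Hz
    n_o: float  # number of oscillations (cycles)
    fs: float  # sampling rate, Hz
    sigma_t: float  # temporal standard deviation, s
    taper: np.ndarray  # complex samples, odd length, ~zero mean


@dataclass(frozen=True)
class CSDMatrix:
    """Hermitian sensor x sensor CSD with its frequency/window metadata."""

    matrix: np.ndarray
    frequencies: tuple
    tmin: float
    tmax: float
    n_epochs: int
    sensor_names: tuple = ()

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=complex)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("CSD matrix must be square")
        if not self.frequencies:
            raise ValueError("CSD must list at least one frequency")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "frequencies", tuple(self.frequencies))

    @property
    def n_sensors(self) -> int:
        return self.matrix.shape[0]


def make_morlet(f: float, n_o: float = 7.0, fs: float = 1000.0) -> MorletWavelet:
    """Complex Morlet wavelet sampled on [-5 sigma_t, 5 sigma_t] at 1/fs.

    The taper is a Gaussian envelope of width sigma_t = n_o / (2 pi f)
    times a complex exponential at f, with the (sigma_t pi)^(-1/2)
    amplitude prefactor.  An odd sample count keeps the peak centred.
    """
    if f <= 0 or n_o <= 0:
        raise ValueError("f and n_o must be positive")
    if fs <= 2.0 * f:
        raise ValueError(f"fs={fs} aliases a wavelet at f={f}")
    sigma_t = n_o / (2.0 * np.pi * f)
    n_half = int(np.floor(5.0 * sigma_t * fs))
    t = np.arange(-n_half, n_half + 1) / fs
    taper = (
        (sigma_t * np.pi) ** -0.5
        * np.exp(-(t**2) / (2.0 * sigma_t**2))
        * np.exp(2j * np.pi * f * t)
    )
    return MorletWavelet(f=f, n_o=n_o, fs=fs, sigma_t=sigma_t, taper=taper)


def demean_epoch(epoch: np.ndarray) -> np.ndarray:
    """Remove each sensor's temporal mean (the wavelet method assumes ~0 offset)."""
    epoch = np.asarray(epoch, dtype=float)
    if epoch.size == 0:
        raise ValueError("empty epoch")
    return epoch - epoch.mean(axis=-1, keepdims=True)


def wavelet_transform(epoch: np.ndarray, w: MorletWavelet) -> np.ndarray:
    """Linear convolution with the wavelet, centre-aligned to the input axis.

    Output sample t corresponds to the taper centred on input sample t
    ("same" extent), so window selection on the output uses the input's
    time axis directly.
    """
    epoch = np.atleast_2d(np.asarray(epoch))
    return _sig.fftconvolve(
        epoch, w.taper[None, :], mode="same", axes=-1
    )


def _window_indices(epochs: EpochsData, tmin: float, tmax: float, decim: int):
    i0 = int(round((tmin - epochs.tmin) * epochs.fs))
    i1 = int(round((tmax - epochs.tmin) * epochs.fs))
    n_times = epochs.data.shape[2]
    if i0 < 0 or i1 >= n_times or i1 < i0:
        raise ValueError("analysis window must lie inside the epoch extent")
    return np.arange(i0, i1 + 1, decim)


def csd_morlet(
    epochs: EpochsData,
    frequencies,
    tmin: float,
    tmax: float,
    n_cycles: float = 7.0,
    decim: int = 20,
) -> list[CSDMatrix]:
    """Per-frequency, epoch-averaged sensor CSD matrices over [tmin, tmax].

    For each epoch (demeaned per sensor) and frequency, the CSD entry is
    the mean over the selected time points of e_i(t) conj(e_j(t)), where
    e are the wavelet coefficients; matrices are then averaged over
    epochs.  Time points are tmin-aligned indices with stride ``decim``.
    Averaging per-frequency matrices afterwards (see
    :func:`csd_band_mean`) equals the one-pass 1/(N_f N_t) normalization
    because every frequency uses the same N_t.
    """
    frequencies = [float(f) for f in np.atleast_1d(frequencies)]
    if not frequencies:
        raise ValueError("need at least one frequency")
    if decim < 1:
        raise ValueError("decim must be >= 1")
    sel = _window_indices(epochs, tmin, tmax, decim)
    if sel.size == 0:
        raise ValueError("empty analysis window")
    data = demean_epoch(epochs.data)
    n_epochs, n_sensors, n_times = data.shape
    out = []
    for f in frequencies:
        w = make_morlet(f, n_cycles, epochs.fs)
        margin = 5.0 * w.sigma_t * epochs.fs
        if sel[0] < margin or sel[-1] > n_times - 1 - margin:
            warnings.warn(
                f"window within 5 sigma_t of the epoch edge at {f} Hz; "
                "wavelet coefficients there are contaminated by edge effects",
                EdgeEffectWarning,
                stacklevel=2,
            )
        coeffs = wavelet_transform(
            data.reshape(n_epochs * n_sensors, n_times), w
        ).reshape(n_epochs, n_sensors, n_times)[:, :, sel]
        c = np.einsum("est,eut->su", coeffs, coeffs.conj()) / (
            n_epochs * sel.size
        )
        out.append(
            CSDMatrix(
                matrix=c, frequencies=(f,), tmin=tmin, tmax=tmax,
                n_epochs=n_epochs,
            )
        )
    return out


def csd_band_mean(csds: list[CSDMatrix], fmin: float, fmax: float) -> CSDMatrix:
    """Unweighted mean of the CSDs whose frequency lies in [fmin, fmax]."""
    chosen = [
        c for c in csds
        if any(fmin <= f <= fmax for f in c.frequencies)
    ]
    if not chosen:
        raise ValueError(f"no CSD frequencies inside [{fmin}, {fmax}] Hz")
    mat = np.mean([c.matrix for c in chosen], axis=0)
    freqs = tuple(f for c in chosen for f in c.frequencies)
    first = chosen[0]
    return CSDMatrix(
        matrix=mat, frequencies=freqs, tmin=first.tmin, tmax=first.tmax,
        n_epochs=first.n_epochs, sensor_names=first.sensor_names,
    )
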