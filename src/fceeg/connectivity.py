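"""Functional connectivity: cross-spectra and the imaginary part of coherence.

The coherency between channels x and y at frequency f is
``C_xy(f) = S_xy(f) / sqrt(S_xx(f) S_yy(f))`` with S the Welch-averaged
cross-spectral density.  The connectivity statistic is the band average of
``|Im C_xy(f)|``: instantaneous (zero-lag) coupling, such as a single
source volume-conducted into several electrodes, is purely real and drops
out, so surviving imaginary coherence indicates genuinely lagged
interaction.  The magnitude is taken per bin before averaging so lags of
opposite sign at different frequencies do not cancel; set ``signed=True``
for the plain average of the imaginary part.

Cross-spectra reuse the exact Welch segmentation of the PSD estimator, so
the CSD diagonal and the PSD agree to rounding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .io import Recording
from .spectral import BandDefinition, _as_chunks, segment_ffts

__all__ = ["CrossSpectra", "ConnectivityMatrix", "cross_spectra", "imaginary_coherence"]


@dataclass
class CrossSpectra:
    """Hermitian cross-spectral density per frequency bin.

    ``S`` has shape ``(n_freqs, n_channels, n_channels)``; its diagonal is
    the one-sided Welch PSD of each channel.
    """

    frequencies: np.ndarray
    S: np.ndarray
    channel_names: list[str]
    n_segments: int


@dataclass
class ConnectivityMatrix:
    """Symmetric, zero-diagonal band connectivity in [0, 1]."""

    values: np.ndarray
    band: BandDefinition
    channel_names: list[str]
    subject_id: str = ""
    task: str = ""

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[0] != v.shape[1]:
            raise ParameterError("connectivity matrix must be square")
        if not np.allclose(v, v.T):
            raise ParameterError("connectivity matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ParameterError("connectivity diagonal must be zero")
        if v.min() < 0 or v.max() > 1 + 1e-9:
            raise ParameterError("connectivity entries must lie in [0, 1]")


def cross_spectra(
    rec: Recording | list,
    window_s: float = 2.0,
    overlap: float = 0.5,
    *,
    sampling_rate: float | None = None,
    channel_names: list[str] | None = None,
) -> CrossSpectra:
    """Welch cross-spectral matrix, pooled over continuous chunks."""
    chunks, names, fs = _as_chunks(rec)
    fs = sampling_rate if fs is None else fs
    if fs is None:
        raise ParameterError("sampling_rate required for raw-array input")
    if names is None:
        names = list(channel_names) if channel_names is not None else [
            f"ch{i}" for i in range(chunks[0].shape[0])
        ]
    freqs, X, scale = segment_ffts(chunks, fs, window_s, overlap)
    # S[f] = scale * mean_seg x(f) x(f)^H, one-sided doubling off DC/Nyquist
    S = scale * np.einsum("sif,sjf->fij", X, X.conj()) / X.shape[0]
    S[1:] *= 2.0
    if len(freqs) and freqs[-1] == fs / 2:
        S[-1] /= 2.0
    return CrossSpectra(
        frequencies=freqs, S=S, channel_names=names, n_segments=X.shape[0]
    )


def imaginary_coherence(
    cs: CrossSpectra,
    band: BandDefinition,
    *,
    signed: bool = False,
    subject_id: str = "",
    task: str = "",
) -> ConnectivityMatrix:
    """Band-averaged (absolute) imaginary coherence for all channel pairs.

    Per bin in the band, the coherency is formed from the cross-spectral
    matrix; the connectivity entry is the mean over bins of ``|Im C|``
    (or of ``Im C`` itself, then absolute, when ``signed=True``).  Channel
    pairs with a zero auto-spectrum anywhere in the band get 0 with a
    warning.
    """
    freqs = cs.frequencies
    mask = (freqs >= band.f_low - 1e-9) & (freqs <= band.f_high + 1e-9)
    if not mask.any():
        raise ParameterError(
            f"band {band.name} [{band.f_low}, {band.f_high}] Hz outside the "
            "estimated frequency range"
        )
    S = cs.S[mask]
    auto = np.real(np.einsum("fii->fi", S))
    bad = auto <= 0
    if bad.any():
        warnings.warn(
            "zero auto-spectrum in band for some channels; their coherence "
            "entries are set to 0"
        )
    denom = np.sqrt(
        np.maximum(auto, 1e-300)[:, :, None] * np.maximum(auto, 1e-300)[:, None, :]
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        imag = np.imag(S) / denom
    imag = np.nan_to_num(imag)
    if signed:
        values = np.abs(imag.mean(axis=0))
    else:
        values = np.abs(imag).mean(axis=0)
    if bad.any():
        idx = np.flatnonzero(bad.any(axis=0))
        values[idx, :] = 0.0
        values[:, idx] = 0.0
    values = 0.5 * (values + values.T)
    np.fill_diagonal(values, 0.0)
    values = np.clip(values, 0.0, 1.0)
    return ConnectivityMatrix(
        values=values,
        band=band,
        channel_names=list(cs.channel_names),
        subject_id=subject_id,
        task=task,
    )
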