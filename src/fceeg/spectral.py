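"""Power spectra and relative band power.

The quantity of interest is the relative power of the five canonical EEG
bands (delta 0.5-4, theta 4-8, alpha 8-13, beta 13-30, gamma 30-45 Hz):
per channel, the integral of the PSD over a band divided by the integral
over the full 0.5-45 Hz range.  Being a ratio, it is invariant to global
amplitude scaling, which suppresses inter-individual differences in signal
attenuation.

Spectra are Welch estimates (Hann taper, 2 s windows, 50% overlap by
default, i.e. 0.5 Hz resolution).  A recording whose bad segments have
been excised contributes the Welch segments of each remaining continuous
chunk jointly; data are never concatenated across an excised gap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import EstimationError, MappingError, ParameterError
from .io import Recording
from .montage import ChannelMontage

__all__ = [
    "BandDefinition",
    "BANDS",
    "BAND_NAMES",
    "PowerSpectrum",
    "welch_psd",
    "relative_power",
    "band_power_table",
    "aggregate_regions",
    "topographic_grid",
]


@dataclass(frozen=True)
class BandDefinition:
    name: str
    f_low: float
    f_high: float

    def __post_init__(self) -> None:
        if not 0 <= self.f_low < self.f_high:
            raise ParameterError(f"band {self.name}: need 0 <= f_low < f_high")


#: The five canonical bands; they tile [0.5, 45] Hz without overlap.
BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 0.5, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
    BandDefinition("gamma", 30.0, 45.0),
)
BAND_NAMES: tuple[str, ...] = tuple(b.name for b in BANDS)
FULL_RANGE: tuple[float, float] = (0.5, 45.0)


@dataclass
class PowerSpectrum:
    """One-sided Welch PSD per channel (power in microvolt^2 / Hz)."""

    frequencies: np.ndarray
    power: np.ndarray  # (n_channels, n_freqs)
    channel_names: list[str]
    window_s: float
    overlap: float
    taper: str
    n_segments: int

    def __post_init__(self) -> None:
        if np.any(np.diff(self.frequencies) <= 0):
            raise ParameterError("frequency grid must be strictly increasing")
        if np.any(self.power < -1e-12):
            raise ParameterError("PSD values must be non-negative")


# --------------------------------------------------------------------------
# Welch segmentation (shared with the cross-spectral estimator)

def good_sample_ranges(
    n_samples: int, fs: float, bad_segments: Sequence[tuple[float, float]]
) -> list[tuple[int, int]]:
    """Complement of the bad segments, as half-open sample-index ranges."""
    if not bad_segments:
        return [(0, n_samples)]
    marks = sorted(
        (max(0, int(np.floor(o * fs))), min(n_samples, int(np.ceil((o + d) * fs))))
        for o, d in bad_segments
    )
    ranges: list[tuple[int, int]] = []
    cursor = 0
    for lo, hi in marks:
        if lo > cursor:
            ranges.append((cursor, lo))
        cursor = max(cursor, hi)
    if cursor < n_samples:
        ranges.append((cursor, n_samples))
    return [r for r in ranges if r[1] > r[0]]


def _as_chunks(data) -> tuple[list[np.ndarray], list[str] | None, float | None]:
    """Normalize Recording / list-of-Recording / list-of-array input."""
    if isinstance(data, Recording):
        arrays = [
            data.data[:, lo:hi]
            for lo, hi in good_sample_ranges(
                data.n_samples, data.sampling_rate, data.bad_segments
            )
        ]
        return arrays, list(data.channel_names), data.sampling_rate
    data = list(data)
    if data and isinstance(data[0], Recording):
        names = list(data[0].channel_names)
        fs = data[0].sampling_rate
        return [r.data for r in data], names, fs
    return [np.asarray(c, dtype=float) for c in data], None, None


def segment_ffts(
    chunks: Iterable[np.ndarray], fs: float, window_s: float, overlap: float
) -> tuple[np.ndarray, np.ndarray, float]:
    """Tapered-segment rFFTs pooled across continuous chunks.

    Returns ``(frequencies, X, scale)`` with ``X`` of shape
    ``(n_segments, n_channels, n_freqs)``; ``scale * mean(|X|^2)`` (doubled
    off DC/Nyquist) is the one-sided PSD, so PSD and CSD estimates built
    from the same segments are mutually consistent by construction.
    """
    if not 0 <= overlap < 1:
        raise ParameterError("overlap must be in [0, 1)")
    nper = int(round(window_s * fs))
    if nper < 2:
        raise ParameterError("window too short for the sampling rate")
    step = max(1, int(round(nper * (1 - overlap))))
    win = sps.get_window("hann", nper, fftbins=True)

    segments = []
    for chunk in chunks:
        chunk = np.atleast_2d(chunk)
        if chunk.shape[1] < nper:
            warnings.warn(
                f"chunk of {chunk.shape[1]} samples shorter than the "
                f"{nper}-sample window; skipped",
                stacklevel=2,
            )
            continue
        for start in range(0, chunk.shape[1] - nper + 1, step):
            segments.append(chunk[:, start : start + nper] * win)
    if not segments:
        raise EstimationError("no data chunk is at least one window long")
    X = np.fft.rfft(np.stack(segments), axis=-1)
    freqs = np.fft.rfftfreq(nper, d=1.0 / fs)
    scale = 1.0 / (fs * np.sum(win**2))
    return freqs, X, scale


def welch_psd(
    rec,
    window_s: float = 2.0,
    overlap: float = 0.5,
    *,
    sampling_rate: float | None = None,
    channel_names: Sequence[str] | None = None,
) -> PowerSpectrum:
    """Welch PSD of a recording (or of pre-split continuous chunks)."""
    chunks, names, fs = _as_chunks(rec)
    fs = sampling_rate if fs is None else fs
    if fs is None:
        raise ParameterError("sampling_rate required for raw-array input")
    if names is None:
        n_ch = chunks[0].shape[0] if chunks else 0
        names = list(channel_names) if channel_names is not None else [
            f"ch{i}" for i in range(n_ch)
        ]
    freqs, X, scale = segment_ffts(chunks, fs, window_s, overlap)
    psd = scale * np.mean(np.abs(X) ** 2, axis=0)
    psd[:, 1:] *= 2.0
    if len(freqs) and freqs[-1] == fs / 2:
        psd[:, -1] /= 2.0
    return PowerSpectrum(
        frequencies=freqs,
        power=psd,
        channel_names=list(names),
        window_s=window_s,
        overlap=overlap,
        taper="hann",
        n_segments=X.shape[0],
    )


# --------------------------------------------------------------------------
# Relative power

def _band_integral(freqs: np.ndarray, power: np.ndarray, lo: float, hi: float) -> np.ndarray:
    mask = (freqs >= lo - 1e-9) & (freqs <= hi + 1e-9)
    if mask.sum() < 2:
        raise ParameterError(f"frequency grid does not resolve [{lo}, {hi}] Hz")
    return np.trapezoid(power[:, mask], freqs[mask], axis=1)


def relative_power(
    ps: PowerSpectrum, bands: Sequence[BandDefinition] = BANDS
) -> np.ndarray:
    """Per-channel band fractions, shape ``(n_channels, n_bands)``.

    Trapezoid integration on the PSD grid; a shared band edge contributes
    half an integration interval to each neighbour, so fractions over a
    tiling band set sum to exactly 1.  Channels with zero total power get
    NaN in every band (with a warning).
    """
    freqs = ps.frequencies
    lo = min(b.f_low for b in bands)
    hi = max(b.f_high for b in bands)
    if freqs[0] > lo + 1e-9 or freqs[-1] < hi - 1e-9:
        raise ParameterError(
            f"frequency grid [{freqs[0]}, {freqs[-1]}] does not cover [{lo}, {hi}] Hz"
        )
    band_int = np.column_stack(
        [_band_integral(freqs, ps.power, b.f_low, b.f_high) for b in bands]
    )
    total = _band_integral(freqs, ps.power, *FULL_RANGE)
    out = np.full_like(band_int, np.nan)
    ok = total > 0
    if not np.all(ok):
        warnings.warn("zero total power in some channels; relative power undefined")
    out[ok] = band_int[ok] / total[ok, None]
    return out


def band_power_table(
    rp: np.ndarray,
    channel_names: Sequence[str],
    *,
    subject_id: str | None = None,
    task: str | None = None,
    bands: Sequence[BandDefinition] = BANDS,
    **extra,
) -> pd.DataFrame:
    """Tidy long-format table of per-channel relative power."""
    rows = []
    for i, ch in enumerate(channel_names):
        for j, b in enumerate(bands):
            row = {"channel": ch, "band": b.name, "relative_power": rp[i, j]}
            if subject_id is not None:
                row["subject_id"] = subject_id
            if task is not None:
                row["task"] = task
            row.update(extra)
            rows.append(row)
    return pd.DataFrame(rows)


def aggregate_regions(
    table: pd.DataFrame,
    montage: ChannelMontage,
    *,
    exclude: set[str] | None = None,
) -> pd.DataFrame:
    """Average per-channel relative power into the five lobes.

    Every channel must map to exactly one lobe; interpolated channels are
    kept, channels listed in ``exclude`` are dropped before averaging.
    Grouping keys are every column other than ``channel``/``relative_power``.
    """
    exclude = exclude or set()
    table = table[~table["channel"].isin(exclude)].copy()
    unmapped = [
        ch for ch in table["channel"].unique() if ch not in montage.regions
        and _no_prefix(ch, montage)
    ]
    if unmapped:
        raise MappingError(f"channels not mapped to a region: {unmapped}")
    table["region"] = [montage.region_of(ch) for ch in table["channel"]]
    keys = [c for c in table.columns if c not in ("channel", "relative_power", "region")]
    out = (
        table.groupby(keys + ["region"], sort=False, as_index=False)["relative_power"]
        .mean()
    )
    return out


def _no_prefix(ch: str, montage: ChannelMontage) -> bool:
    try:
        montage.region_of(ch)
        return False
    except MappingError:
        return True


# --------------------------------------------------------------------------
# Scalp maps

def topographic_grid(
    values: Sequence[float],
    positions_2d: np.ndarray,
    grid_size: int = 67,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Interpolate per-channel values onto a regular grid inside the head disc.

    Thin-plate-spline radial-basis interpolation; cells outside the head
    circle (5% beyond the outermost electrode) are NaN.  Returns
    ``(x, y, grid)`` with ``grid[j, i]`` the value at ``(x[i], y[j])``.
    """
    values = np.asarray(values, dtype=float)
    positions_2d = np.asarray(positions_2d, dtype=float)
    if len(values) < 4:
        raise ParameterError("need at least 4 channels for a scalp map")
    from scipy.interpolate import RBFInterpolator

    radius = 1.05 * np.linalg.norm(positions_2d, axis=1).max()
    x = np.linspace(-radius, radius, grid_size)
    y = np.linspace(-radius, radius, grid_size)
    xx, yy = np.meshgrid(x, y)
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    interp = RBFInterpolator(positions_2d, values, kernel="thin_plate_spline")
    grid = interp(pts).reshape(grid_size, grid_size)
    grid[xx**2 + yy**2 > radius**2] = np.nan
    return x, y, grid
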