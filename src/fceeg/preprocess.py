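"""Preprocessing: band-pass filtering, flatline QC, interpolation, artifacts.

Stage order in :func:`preprocess_recording` is filter -> bad-channel
detection -> spherical-spline interpolation -> bad-segment detection ->
artifact-component removal.  Flatline detection always inspects the raw
amplitudes (a zero-phase IIR filter smears energy into a flat window, so
the near-zero criterion is only meaningful before filtering).

Artifact handling is a pluggable stand-in for classifier-based component
labelling: the recording is unmixed with ICA and components whose time
course correlates with a caller-supplied artifact reference beyond a
threshold are zeroed.  Any callable with the same signature can be plugged
into the pipeline in its place.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from numpy.polynomial import legendre
from scipy import signal as sps

from .errors import InputError, InterpolationError, ParameterError
from .io import Recording
from .montage import ChannelMontage
from .spectral import good_sample_ranges

__all__ = [
    "PreprocessReport",
    "bandpass_filter",
    "detect_bad_channels",
    "detect_bad_segments",
    "per_channel_flat_duration",
    "split_good_chunks",
    "interpolate_channels",
    "remove_artifact_components",
    "qc_summary",
    "crop_resting",
    "preprocess_recording",
]

FLATLINE_AMP = 1e-10  # uV; near-zero amplitude criterion
FLATLINE_FRACTION = 0.60
DEFAULT_FILTER_ORDER = 4  # Butterworth order; applied forward-backward


@dataclass
class PreprocessReport:
    """QC percentages for one recording plus a per-stage log."""

    subject_id: str = ""
    task: str = ""
    pct_bad_channels: float = 0.0
    pct_bad_segments: float = 0.0
    pct_artifacts_removed: float = 0.0
    #: Same bad-segment total under the per-interval (not per-channel-time)
    #: denominator convention.
    pct_bad_segments_interval: float = 0.0
    log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("pct_bad_channels", "pct_bad_segments", "pct_artifacts_removed"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise InputError(f"{name} must be a percentage in [0, 100]")


# --------------------------------------------------------------------------
# Filtering

def design_bandpass(
    low: float, high: float, fs: float, order: int = DEFAULT_FILTER_ORDER
) -> np.ndarray:
    if not 0 < low < high:
        raise ParameterError("need 0 < low < high")
    if high >= fs / 2:
        raise ParameterError(f"high={high} Hz is not below Nyquist ({fs / 2} Hz)")
    return sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")


def bandpass_filter(
    rec: Recording,
    low: float = 0.5,
    high: float = 45.0,
    order: int = DEFAULT_FILTER_ORDER,
) -> Recording:
    """Zero-phase Butterworth band-pass, applied per channel.

    Forward-backward application doubles the stop-band attenuation and
    leaves pass-band phase untouched, which matters for the coherence
    estimates downstream.
    """
    sos = design_bandpass(low, high, rec.sampling_rate, order)
    return rec.copy(data=sps.sosfiltfilt(sos, rec.data, axis=1))


# --------------------------------------------------------------------------
# Flatline detection

def detect_bad_channels(
    rec: Recording,
    fraction: float = FLATLINE_FRACTION,
    amp: float = FLATLINE_AMP,
) -> set[str]:
    """Channels with prolonged flatlining.

    A channel is flagged iff strictly more than ``fraction`` of its samples
    have absolute amplitude below ``amp``.
    """
    if rec.n_samples == 0:
        raise InputError("empty recording")
    if not 0 < fraction < 1:
        raise ParameterError("fraction must be in (0, 1)")
    near_zero = np.abs(rec.data) < amp
    frac = near_zero.mean(axis=1)
    return {name for name, f in zip(rec.channel_names, frac) if f > fraction}


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True, as half-open index ranges."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(mask))
    return list(zip(starts, ends))


def _channel_flat_runs(
    rec: Recording, amp: float, min_run: float, exclude: set[str]
) -> dict[str, list[tuple[int, int]]]:
    if rec.n_samples == 0:
        raise InputError("empty recording")
    if min_run <= 0:
        raise ParameterError("min_run must be > 0")
    min_samples = int(round(min_run * rec.sampling_rate))
    out: dict[str, list[tuple[int, int]]] = {}
    for i, name in enumerate(rec.channel_names):
        if name in exclude:
            continue
        runs = [
            (a, b)
            for a, b in _runs(np.abs(rec.data[i]) < amp)
            if b - a >= min_samples
        ]
        if runs:
            out[name] = runs
    return out


def detect_bad_segments(
    rec: Recording,
    amp: float = FLATLINE_AMP,
    min_run: float = 0.2,
    exclude_channels: set[str] | None = None,
) -> list[tuple[float, float]]:
    """Transient flatline intervals, merged across channels.

    Per channel, maximal near-zero runs of at least ``min_run`` seconds are
    found; overlapping runs from different channels are merged into one
    ``(onset_s, duration_s)`` interval.  Channels in ``exclude_channels``
    (typically already-flagged bad channels) are ignored.
    """
    per_channel = _channel_flat_runs(rec, amp, min_run, exclude_channels or set())
    fs = rec.sampling_rate
    intervals = sorted(
        (a / fs, b / fs) for runs in per_channel.values() for a, b in runs
    )
    merged: list[tuple[float, float]] = []
    for lo, hi in intervals:
        if merged and lo <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return [(lo, hi - lo) for lo, hi in merged]


def per_channel_flat_duration(
    rec: Recording,
    amp: float = FLATLINE_AMP,
    min_run: float = 0.2,
    exclude_channels: set[str] | None = None,
) -> float:
    """Total flatline duration summed over channels (seconds x channels).

    This is the numerator for the per-channel-time QC convention, where a
    segment in one channel counts only that channel's time.
    """
    per_channel = _channel_flat_runs(rec, amp, min_run, exclude_channels or set())
    fs = rec.sampling_rate
    return sum((b - a) / fs for runs in per_channel.values() for a, b in runs)


def split_good_chunks(rec: Recording) -> list[Recording]:
    """Split a recording at its bad segments into continuous good chunks.

    Chunks are never concatenated across an excised gap; each is returned
    as its own Recording so spectral estimation can pool their Welch
    segments without bridging the gap.
    """
    fs = rec.sampling_rate
    return [
        Recording(
            data=rec.data[:, lo:hi].copy(),
            sampling_rate=fs,
            channel_names=list(rec.channel_names),
            bad_channels=set(rec.bad_channels),
        )
        for lo, hi in good_sample_ranges(rec.n_samples, fs, rec.bad_segments)
    ]


# --------------------------------------------------------------------------
# Spherical-spline interpolation (Perrin-style)

def _g_matrix(cosang: np.ndarray, m: int, n_terms: int) -> np.ndarray:
    """Perrin g-function: (1/4pi) sum_l (2l+1)/(l(l+1))^m P_l(cos angle)."""
    ell = np.arange(1, n_terms + 1, dtype=float)
    coeffs = np.zeros(n_terms + 1)
    coeffs[1:] = (2 * ell + 1) / (ell * (ell + 1)) ** m
    return legendre.legval(np.clip(cosang, -1.0, 1.0), coeffs) / (4 * np.pi)


def interpolation_matrix(
    good_pos: np.ndarray,
    bad_pos: np.ndarray,
    m: int = 4,
    n_terms: int = 50,
    reg: float = 1e-5,
) -> np.ndarray:
    """Matrix M with ``V_bad = M @ V_good`` under the spherical spline.

    Solves the regularized spline system on the good-electrode potentials
    (Legendre series stiffness order ``m``, truncated at ``n_terms``,
    ridge ``reg`` on the g-matrix) and evaluates the spline at the bad
    positions.
    """
    n_good = len(good_pos)
    G = _g_matrix(good_pos @ good_pos.T, m, n_terms) + reg * np.eye(n_good)
    A = np.zeros((n_good + 1, n_good + 1))
    A[:n_good, :n_good] = G
    A[:n_good, n_good] = 1.0
    A[n_good, :n_good] = 1.0
    Gb = _g_matrix(bad_pos @ good_pos.T, m, n_terms)
    # [c; mu] = A^-1 [V; 0]  ->  V_bad = Gb c + mu = [Gb, 1] A^-1 [V; 0]
    B = np.column_stack([Gb, np.ones(len(bad_pos))])
    M = B @ np.linalg.solve(A, np.eye(n_good + 1))
    return M[:, :n_good]


def interpolate_channels(
    rec: Recording,
    bad: set[str],
    montage: ChannelMontage,
    m: int = 4,
    n_terms: int = 50,
    reg: float = 1e-5,
) -> Recording:
    """Replace bad channels with spherical-spline estimates from good ones.

    Good channels are passed through bit-exactly.
    """
    unknown = bad - set(rec.channel_names)
    if unknown:
        raise InputError(f"bad channels not in the recording: {sorted(unknown)}")
    if not bad:
        return rec.copy()
    pos = {name: montage.positions[list(montage.names).index(name)]
           for name in rec.channel_names}
    good_names = [n for n in rec.channel_names if n not in bad]
    if len(good_names) < 4:
        raise InterpolationError(
            f"only {len(good_names)} good channels; need at least 4"
        )
    bad_names = [n for n in rec.channel_names if n in bad]
    good_pos = np.array([pos[n] for n in good_names])
    bad_pos = np.array([pos[n] for n in bad_names])
    M = interpolation_matrix(good_pos, bad_pos, m=m, n_terms=n_terms, reg=reg)
    good_idx = [rec.index_of(n) for n in good_names]
    out = rec.copy()
    estimates = M @ rec.data[good_idx]
    for row, name in enumerate(bad_names):
        out.data[rec.index_of(name)] = estimates[row]
    out.bad_channels = set(rec.bad_channels) | bad
    return out


# --------------------------------------------------------------------------
# Artifact-component removal (classifier stand-in)

def remove_artifact_components(
    rec: Recording,
    reference: np.ndarray,
    threshold: float = 0.8,
    seed: int = 0,
    n_components: int | None = None,
) -> tuple[Recording, float]:
    """Zero ICA components correlated with an artifact reference signal.

    The recording is unmixed with FastICA (deterministic given ``seed``),
    components whose absolute Pearson correlation with ``reference``
    exceeds ``threshold`` are zeroed, and the data are re-mixed.  Returns
    the cleaned recording and the fraction of the recording's duration in
    which removed activity was present (samples where the removed signal's
    cross-channel RMS exceeds 10% of its peak).

    If the decomposition fails the input is returned unchanged with a
    warning and a removed fraction of 0.
    """
    if not 0 < threshold <= 1:
        raise ParameterError("threshold must be in (0, 1]")
    reference = np.asarray(reference, dtype=float)
    if reference.shape != (rec.n_samples,):
        raise InputError("reference must have the same duration as the recording")

    from sklearn.decomposition import FastICA

    if n_components is None:
        # Interpolated channels make the data rank-deficient; a full-rank
        # unmixing would then not be invertible, so fit only the numerical
        # rank of the data.
        sv = np.linalg.svd(rec.data, compute_uv=False)
        n_components = int(np.sum(sv > 1e-10 * sv[0]))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ica = FastICA(
                n_components=n_components, random_state=seed, max_iter=1000
            )
            sources = ica.fit_transform(rec.data.T)  # (n_samples, k)
    except Exception as exc:  # noqa: BLE001 - degrade gracefully
        warnings.warn(f"ICA decomposition failed ({exc}); no components removed")
        return rec.copy(), 0.0

    ref = reference - reference.mean()
    ref_sd = ref.std()
    if ref_sd == 0:
        return rec.copy(), 0.0
    src = sources - sources.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.abs(src.T @ ref) / (
            np.maximum(src.std(axis=0), 1e-30) * ref_sd * len(ref)
        )
    to_remove = np.flatnonzero(corr > threshold)
    if len(to_remove) == 0:
        return rec.copy(), 0.0

    kept = sources.copy()
    kept[:, to_remove] = 0.0
    cleaned = ica.inverse_transform(kept).T
    removed_signal = rec.data - cleaned
    rms = np.sqrt(np.mean(removed_signal**2, axis=0))
    active = rms > 0.1 * rms.max() if rms.max() > 0 else np.zeros_like(rms, bool)
    return rec.copy(data=cleaned), float(active.mean())


# --------------------------------------------------------------------------
# QC summary and resting crop

def qc_report(
    rec: Recording,
    *,
    n_bad_channels: int,
    flat_channel_seconds: float,
    artifact_fraction: float,
    subject_id: str = "",
    task: str = "",
    log: list[str] | None = None,
) -> PreprocessReport:
    """Assemble the three QC percentages for one recording.

    * bad channels: flagged / total channels;
    * bad segments: summed per-channel flatline duration divided by
      (number of channels x recording duration) -- per-channel-time
      convention -- with the per-interval convention reported alongside;
    * artifacts removed: removed duration / recording duration.
    """
    n_ch, dur = rec.n_channels, rec.duration
    interval_seconds = sum(d for _o, d in rec.bad_segments)
    return PreprocessReport(
        subject_id=subject_id,
        task=task,
        pct_bad_channels=100.0 * n_bad_channels / n_ch,
        pct_bad_segments=100.0 * flat_channel_seconds / (n_ch * dur),
        pct_bad_segments_interval=100.0 * interval_seconds / dur,
        pct_artifacts_removed=100.0 * artifact_fraction,
        log=log or [],
    )


def qc_summary(reports: Sequence[PreprocessReport]):
    """Per-recording QC table plus cohort mean +/- SD of each percentage.

    Returns ``(table, aggregate)`` where ``aggregate`` maps each percentage
    to ``(mean, sd)`` (SD over recordings, ddof=1; 0 for a single one).
    The summary is invariant to channel ordering by construction.
    """
    import pandas as pd

    cols = ["pct_bad_channels", "pct_bad_segments", "pct_artifacts_removed"]
    table = pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "task": r.task,
                **{c: getattr(r, c) for c in cols},
                "pct_bad_segments_interval": r.pct_bad_segments_interval,
            }
            for r in reports
        ]
    )
    agg = {
        c: (float(table[c].mean()), float(table[c].std(ddof=1)) if len(table) > 1 else 0.0)
        for c in cols
    }
    return table, agg


def crop_resting(rec: Recording, seconds: float = 120.0) -> Recording:
    """Keep the first two minutes of a resting recording.

    Shorter recordings are returned whole, with a warning.
    """
    n_keep = int(round(seconds * rec.sampling_rate))
    if rec.n_samples < n_keep:
        warnings.warn(
            f"recording is {rec.duration:.1f} s, shorter than {seconds:.0f} s; "
            "using the full length"
        )
        return rec.copy()
    out = rec.copy(data=rec.data[:, :n_keep].copy())
    end = n_keep / rec.sampling_rate
    out.annotations = [a for a in rec.annotations if a[0] < end]
    out.bad_segments = [
        (o, min(d, end - o)) for o, d in rec.bad_segments if o < end
    ]
    return out


# --------------------------------------------------------------------------
# Full per-recording pipeline

def preprocess_recording(
    rec: Recording,
    montage: ChannelMontage,
    *,
    low: float = 0.5,
    high: float = 45.0,
    order: int = DEFAULT_FILTER_ORDER,
    artifact_reference: np.ndarray | None = None,
    artifact_threshold: float = 0.8,
    artifact_remover: Callable | None = None,
    seed: int = 0,
    subject_id: str = "",
    task: str = "",
) -> tuple[Recording, PreprocessReport]:
    """Filter, flag and repair one recording; return it with its QC report.

    Flatline detection runs on the raw amplitudes; the data then pass
    through the band-pass filter, spherical-spline interpolation of bad
    channels, bad-segment marking, and (when a reference is given) the
    artifact-component remover.
    """
    log: list[str] = []
    bad_channels = detect_bad_channels(rec)
    log.append(f"bad channels: {sorted(bad_channels) or 'none'}")
    flat_seconds = per_channel_flat_duration(rec, exclude_channels=bad_channels)
    segments = detect_bad_segments(rec, exclude_channels=bad_channels)
    log.append(f"bad segments: {len(segments)}")

    out = bandpass_filter(rec, low=low, high=high, order=order)
    log.append(f"band-pass {low}-{high} Hz (order {order}, zero-phase)")
    if bad_channels:
        out = interpolate_channels(out, bad_channels, montage)
        log.append(f"interpolated {len(bad_channels)} channels")
    out.bad_segments = segments

    artifact_fraction = 0.0
    if artifact_reference is not None:
        remover = artifact_remover or remove_artifact_components
        out, artifact_fraction = remover(
            out, artifact_reference, threshold=artifact_threshold, seed=seed
        )
        log.append(f"artifact removal: {100 * artifact_fraction:.2f}% of duration")

    report = qc_report(
        out,
        n_bad_channels=len(bad_channels),
        flat_channel_seconds=flat_seconds,
        artifact_fraction=artifact_fraction,
        subject_id=subject_id,
        task=task,
        log=log,
    )
    return out, report
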