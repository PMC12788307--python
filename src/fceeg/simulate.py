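"""Synthetic EEG cohort generator.

Generates multi-subject, multi-task 64-channel recordings at 250 Hz with
the statistical structure the downstream analysis measures, so the whole
pipeline is testable without access to patient data:

* a 1/f background (power ~ f**-exponent over 0.5-45 Hz),
* five band-limited oscillators per lobe, built as mixtures of a
  region-shared latent source (each channel sees it through a random,
  channel-specific phase lag) and channel-private filtered noise -- the
  shared fraction controls imaginary coherence, and the nonzero lags make
  it nonzero,
* group/region/task/band amplitude gains plus per-subject log-normal
  amplitude variability, which together set the between-group effect size
  of relative power,
* injectable flatline artifacts (whole channels and transient segments)
  and stereotyped frontally-weighted blinks.

Cohort structure defaults mirror the study design being emulated: 21
patients (ages 23-80) vs 37 controls (ages 20-60), a 420 s eyes-open
resting block, a 160 s cognitive block (two counting tasks and a
word-formation task), and 30 s imagery / 250 s execution blocks for
defecation and anal contraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import signal as sps

from .errors import CalibrationError, ConfigurationError
from .io import Recording, save_recording
from .montage import REGIONS, ChannelMontage, default_montage
from .spectral import BANDS, BAND_NAMES, relative_power, welch_psd

__all__ = [
    "BandGains",
    "ArtifactRates",
    "SimulationConfig",
    "SubjectRecord",
    "DEFAULT_TASK_SCHEDULE",
    "generate_recording",
    "generate_cohort",
    "calibrate_effect",
    "blink_template",
    "blink_reference",
    "write_cohort",
]

GROUPS = ("patient", "control")

#: Task blocks and their durations in seconds: a 420 s resting baseline, a
#: 160 s cognitive block split into its three sub-tasks, then the
#: defecation-related imagery (30 s) and execution (250 s) blocks.
DEFAULT_TASK_SCHEDULE: tuple[tuple[str, float], ...] = (
    ("resting", 420.0),
    ("counting_1", 60.0),
    ("word_formation", 50.0),
    ("counting_2", 50.0),
    ("imaginary_defecation", 30.0),
    ("simulated_defecation", 250.0),
    ("imaginary_anal_contraction", 30.0),
    ("anal_contraction", 250.0),
)

#: Baseline oscillator amplitudes (uV RMS) per band, before any gain.
DEFAULT_BASE_AMPLITUDES: dict[str, float] = {
    "delta": 3.0,
    "theta": 2.0,
    "alpha": 4.0,
    "beta": 1.5,
    "gamma": 0.8,
}


@dataclass(frozen=True)
class BandGains:
    """Oscillator amplitude model.

    ``base`` holds the per-band baseline amplitude (uV RMS); ``overrides``
    maps ``(group, region, task, band)`` to a unitless multiplier.  The
    task slot accepts ``"*"`` as a wildcard.  Lookup tries the exact key
    first, then the task wildcard, and defaults to 1.
    """

    base: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASE_AMPLITUDES)
    )
    overrides: Mapping[tuple[str, str, str, str], float] = field(default_factory=dict)

    def scale(self, group: str, region: str, task: str, band: str) -> float:
        key = (group, region, task, band)
        if key in self.overrides:
            return self.overrides[key]
        return self.overrides.get((group, region, "*", band), 1.0)

    def amplitude(self, group: str, region: str, task: str, band: str) -> float:
        return self.base[band] * self.scale(group, region, task, band)

    def with_override(
        self, group: str, region: str, task: str, band: str, scale: float
    ) -> "BandGains":
        new = dict(self.overrides)
        new[(group, region, task, band)] = scale
        return replace(self, overrides=new)


@dataclass(frozen=True)
class ArtifactRates:
    """Artifact injection rates.

    Defaults are chosen so the QC summaries land in the range reported for
    real recordings: a few percent of channels flat, about one transient
    flatline every few minutes, and a handful of blinks per minute.
    """

    flatline_channel_prob: float = 0.05
    flatline_segment_per_min: float = 0.3
    blink_per_min: float = 4.0


@dataclass(frozen=True)
class SimulationConfig:
    n_patients: int = 21
    n_controls: int = 37
    seed: int = 0
    sampling_rate: float = 250.0
    montage: ChannelMontage | None = None
    task_schedule: tuple[tuple[str, float], ...] = DEFAULT_TASK_SCHEDULE
    background_exponent: float = 1.0
    background_rms: float = 5.0
    band_gains: BandGains = field(default_factory=BandGains)
    subject_sigma: float = 0.2
    shared_fraction: float = 0.5
    artifact_rates: ArtifactRates = field(default_factory=ArtifactRates)
    age_ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"patient": (23.0, 80.0), "control": (20.0, 60.0)}
    )
    sex_male_prob: Mapping[str, float] = field(
        default_factory=lambda: {"patient": 4 / 21, "control": 22 / 37}
    )
    #: When set, annotate execution blocks with (hold_s, relax_s) cycles.
    cycle_timing: tuple[float, float] | None = None
    #: Sample patient ages from the upper half of their range (and control
    #: ages from the lower half) to create a deliberate group-age confound.
    age_confound: bool = False

    def resolved_montage(self) -> ChannelMontage:
        return self.montage if self.montage is not None else default_montage()

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty when valid)."""
        problems: list[str] = []
        if self.n_patients < 2:
            problems.append("n_patients: need at least 2 subjects per group")
        if self.n_controls < 2:
            problems.append("n_controls: need at least 2 subjects per group")
        if self.sampling_rate <= 2 * max(b.f_high for b in BANDS):
            problems.append(
                "sampling_rate: must exceed twice the highest band edge (45 Hz)"
            )
        if not self.task_schedule:
            problems.append("task_schedule: empty")
        for name, dur in self.task_schedule:
            if dur <= 0:
                problems.append(f"task_schedule: task {name!r} has duration <= 0")
        if any(v < 0 for v in self.band_gains.base.values()):
            problems.append("band_gains.base: negative amplitude")
        if any(v < 0 for v in self.band_gains.overrides.values()):
            problems.append("band_gains.overrides: negative gain")
        if self.subject_sigma < 0:
            problems.append("subject_sigma: must be >= 0")
        if not 0 <= self.shared_fraction <= 1:
            problems.append("shared_fraction: must be in [0, 1]")
        if self.background_rms < 0:
            problems.append("background_rms: must be >= 0")
        ar = self.artifact_rates
        if not 0 <= ar.flatline_channel_prob <= 1:
            problems.append("artifact_rates.flatline_channel_prob: not a probability")
        if ar.flatline_segment_per_min < 0 or ar.blink_per_min < 0:
            problems.append("artifact_rates: negative rate")
        for g in GROUPS:
            lo, hi = self.age_ranges[g]
            if not lo < hi:
                problems.append(f"age_ranges[{g}]: min must be < max")
        return problems


@dataclass
class SubjectRecord:
    subject_id: str
    group: str
    age: float
    sex: str
    recordings: dict[str, Recording]


# --------------------------------------------------------------------------
# Signal building blocks

def _one_over_f_noise(
    n_ch: int, n: int, fs: float, exponent: float, rms: float, rng: np.random.Generator
) -> np.ndarray:
    """FFT-shaped noise with power ~ f**-exponent over the analysis range."""
    white = rng.standard_normal((n_ch, n))
    if exponent == 0 or rms == 0:
        return white * rms
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.ones_like(freqs)
    nz = freqs > 0
    # Flatten below 0.5 Hz so the slope applies to the analysed band only
    # and slow drifts stay bounded.
    shape[nz] = np.maximum(freqs[nz], 0.5) ** (-exponent / 2.0)
    shape[0] = 0.0
    x = np.fft.irfft(np.fft.rfft(white, axis=1) * shape, n=n, axis=1)
    x *= rms / max(x.std(), 1e-30)
    return x


def _band_sos(band, fs: float):
    return sps.butter(
        4, [band.f_low, band.f_high], btype="bandpass", fs=fs, output="sos"
    )


def _unit_rms(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=-1, keepdims=True)
    return x / np.maximum(sd, 1e-30)


def blink_template(fs: float, amplitude: float = 120.0) -> np.ndarray:
    """Stereotyped biphasic blink transient (about 0.4 s, uV)."""
    t = np.arange(int(round(0.4 * fs))) / fs
    wave = np.exp(-(((t - 0.12) / 0.05) ** 2)) - 0.45 * np.exp(
        -(((t - 0.24) / 0.08) ** 2)
    )
    return amplitude * wave


def _frontal_profile(montage: ChannelMontage) -> np.ndarray:
    y = montage.positions[:, 1]
    w = np.clip(y, 0.0, None) ** 2
    return w / max(w.max(), 1e-30)


def blink_reference(rec: Recording) -> np.ndarray:
    """Reconstruct the blink time course from a recording's annotations."""
    ref = np.zeros(rec.n_samples)
    tmpl = blink_template(rec.sampling_rate)
    for onset, _dur, label in rec.annotations:
        if label == "blink":
            i = int(round(onset * rec.sampling_rate))
            j = min(rec.n_samples, i + len(tmpl))
            ref[i:j] += tmpl[: j - i]
    return ref


# --------------------------------------------------------------------------
# Recording and cohort generation

def generate_recording(
    config: SimulationConfig,
    group: str,
    task: str,
    duration: float,
    rng: np.random.Generator,
    subject_scale: np.ndarray | None = None,
) -> Recording:
    """Simulate one task block for one subject.

    ``subject_scale`` is the subject's ``(n_regions, n_bands)`` log-normal
    amplitude multiplier; omit it for an average subject.
    """
    if duration <= 0:
        raise ConfigurationError("task_schedule: duration must be > 0")
    montage = config.resolved_montage()
    fs = config.sampling_rate
    n = int(round(duration * fs))
    n_ch = montage.n_channels
    if subject_scale is None:
        subject_scale = np.ones((len(REGIONS), len(BANDS)))

    data = _one_over_f_noise(
        n_ch, n, fs, config.background_exponent, config.background_rms, rng
    )

    region_idx = {
        r: [i for i, name in enumerate(montage.names) if montage.region_of(name) == r]
        for r in REGIONS
    }
    sf = config.shared_fraction
    for bi, band in enumerate(BANDS):
        sos = _band_sos(band, fs)
        for ri, region in enumerate(REGIONS):
            idx = region_idx[region]
            if not idx:
                continue
            amp = (
                config.band_gains.amplitude(group, region, task, band.name)
                * subject_scale[ri, bi]
            )
            if amp == 0:
                continue
            shared = _unit_rms(sps.sosfiltfilt(sos, rng.standard_normal(n)))
            analytic = sps.hilbert(shared)
            lags = rng.uniform(-np.pi / 2, np.pi / 2, size=len(idx))
            shifted = np.real(analytic[None, :] * np.exp(-1j * lags[:, None]))
            private = _unit_rms(
                sps.sosfiltfilt(sos, rng.standard_normal((len(idx), n)), axis=1)
            )
            osc = np.sqrt(sf) * shifted + np.sqrt(1 - sf) * private
            data[idx] += amp * osc

    annotations: list[tuple[float, float, str]] = []
    if config.cycle_timing is not None and task in (
        "simulated_defecation",
        "anal_contraction",
    ):
        hold, relax = config.cycle_timing
        t = 0.0
        while t + hold <= duration:
            annotations.append((t, hold, "hold"))
            t += hold
            if t + relax > duration:
                break
            annotations.append((t, relax, "relax"))
            t += relax

    ar = config.artifact_rates
    n_blinks = rng.poisson(ar.blink_per_min * duration / 60.0)
    if n_blinks and duration > 0.4:
        tmpl = blink_template(fs)
        profile = _frontal_profile(montage)
        for onset in np.sort(rng.uniform(0, duration - len(tmpl) / fs, size=n_blinks)):
            i = int(round(onset * fs))
            data[:, i : i + len(tmpl)] += profile[:, None] * tmpl[None, :]
            annotations.append((i / fs, len(tmpl) / fs, "blink"))

    n_flat_seg = rng.poisson(ar.flatline_segment_per_min * duration / 60.0)
    for _ in range(n_flat_seg):
        seg_dur = rng.uniform(0.5, 2.0)
        onset = rng.uniform(0, max(duration - seg_dur, 0.0))
        ch = rng.integers(n_ch)
        i, j = int(round(onset * fs)), int(round((onset + seg_dur) * fs))
        data[ch, i:j] = 0.0
        annotations.append(
            (i / fs, (j - i) / fs, f"sim_flat_segment:{montage.names[ch]}")
        )

    flat_mask = rng.random(n_ch) < ar.flatline_channel_prob
    for ch in np.flatnonzero(flat_mask):
        data[ch] = 0.0
        annotations.append((0.0, duration, f"sim_flat_channel:{montage.names[ch]}"))

    return Recording(
        data=data,
        sampling_rate=fs,
        channel_names=list(montage.names),
        annotations=annotations,
    )


def _subject_scale(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    return np.exp(
        config.subject_sigma * rng.standard_normal((len(REGIONS), len(BANDS)))
    )


def generate_cohort(config: SimulationConfig):
    """Simulate the full cohort.

    Returns ``(subjects, metadata)``: a list of :class:`SubjectRecord` and a
    pandas DataFrame with one row per subject.  Deterministic given the
    config (including the seed): per-subject and per-task random streams
    are spawned from a single seed sequence.
    """
    import pandas as pd

    problems = config.validate()
    if problems:
        raise ConfigurationError("; ".join(problems))

    root = np.random.SeedSequence(config.seed)
    groups = ["patient"] * config.n_patients + ["control"] * config.n_controls
    subjects: list[SubjectRecord] = []
    rows = []
    counters = {"patient": 0, "control": 0}
    subject_seeds = root.spawn(len(groups))
    for group, seq in zip(groups, subject_seeds):
        counters[group] += 1
        sid = ("P" if group == "patient" else "C") + f"{counters[group]:02d}"
        demo_rng = np.random.default_rng(seq.spawn(1)[0])
        lo, hi = config.age_ranges[group]
        if config.age_confound:
            mid = (lo + hi) / 2
            lo, hi = (mid, hi) if group == "patient" else (lo, mid)
        age = float(demo_rng.uniform(lo, hi))
        sex = "M" if demo_rng.random() < config.sex_male_prob[group] else "F"
        scale = _subject_scale(config, demo_rng)
        recordings: dict[str, Recording] = {}
        task_seeds = seq.spawn(len(config.task_schedule))
        for (task, dur), tseq in zip(config.task_schedule, task_seeds):
            rng = np.random.default_rng(tseq)
            recordings[task] = generate_recording(
                config, group, task, dur, rng, subject_scale=scale
            )
        subjects.append(
            SubjectRecord(
                subject_id=sid, group=group, age=age, sex=sex, recordings=recordings
            )
        )
        rows.append(
            {"subject_id": sid, "group": group, "age": age, "sex": sex,
             "seed": config.seed}
        )
    return subjects, pd.DataFrame(rows)


def write_cohort(subjects: Sequence[SubjectRecord], metadata, out_dir: str | Path) -> Path:
    """Write one EDF per subject and task plus ``metadata.csv``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for subj in subjects:
        for task, rec in subj.recordings.items():
            save_recording(rec, out_dir / f"{subj.subject_id}_{task}")
    metadata.to_csv(out_dir / "metadata.csv", index=False)
    return out_dir


# --------------------------------------------------------------------------
# Effect-size calibration

def _pilot_effect(
    config: SimulationConfig,
    band: str,
    region: str,
    task: str,
    ratio: float,
    pilot_n: int,
    duration: float,
    seed: int,
) -> float:
    """Cohen's d of region/band relative power at a given patient gain ratio.

    Uses a paired common-random-numbers design: pilot subject ``i`` is
    simulated twice from the same random stream, once with the patient
    gain and once with the control gain, so the group mean difference is
    nearly noise-free and the pilot d is a smooth function of the ratio.
    """
    from .stats import cohens_d

    gains = config.band_gains
    base_scale = gains.scale("patient", region, task, band)
    patient_gains = gains.with_override(
        "patient", region, task, band, base_scale * ratio
    )
    quiet = replace(
        config,
        task_schedule=((task, duration),),
        artifact_rates=ArtifactRates(0.0, 0.0, 0.0),
    )
    montage = quiet.resolved_montage()
    bi = BAND_NAMES.index(band)
    idx = [i for i, nm in enumerate(montage.names) if montage.region_of(nm) == region]
    vals = {"patient": [], "control": []}
    for i in range(pilot_n):
        ss = np.random.SeedSequence([seed, i])
        jitter_seed, rec_seed = ss.spawn(2)
        scale = _subject_scale(quiet, np.random.default_rng(jitter_seed))
        for group, g in (("patient", patient_gains), ("control", gains)):
            rec = generate_recording(
                replace(quiet, band_gains=g), group, task, duration,
                np.random.default_rng(rec_seed), subject_scale=scale,
            )
            rp = relative_power(welch_psd(rec))
            vals[group].append(float(np.mean(rp[idx, bi])))
    return cohens_d(np.array(vals["patient"]), np.array(vals["control"]))


def calibrate_effect(
    band: str,
    region: str,
    task: str,
    target_d: float,
    *,
    config: SimulationConfig | None = None,
    pilot_n: int = 20,
    seed: int = 1234,
    duration: float = 30.0,
    tol: float = 0.15,
    max_iter: int = 24,
) -> float:
    """Patient/control amplitude ratio producing a target Cohen's d.

    Bisection on the log gain ratio against pilot cohorts simulated with
    common random numbers (the same seed at every trial ratio), so the
    pilot effect size is a smooth monotone function of the ratio and the
    search converges to within ``tol`` of the target.
    """
    if not np.isfinite(target_d):
        raise CalibrationError("target_d must be finite")
    if pilot_n < 10:
        raise CalibrationError("pilot_n must be at least 10 per group")
    if target_d == 0:
        return 1.0
    config = config if config is not None else SimulationConfig()

    def d_of(ratio: float) -> float:
        return _pilot_effect(
            config, band, region, task, ratio, pilot_n, duration, seed
        )

    lo, hi = (1.0, 2.0) if target_d > 0 else (0.5, 1.0)
    d_lo, d_hi = d_of(lo), d_of(hi)
    expand = 0
    while d_hi < target_d and expand < 6:
        hi *= 2.0
        d_hi = d_of(hi)
        expand += 1
    while d_lo > target_d and expand < 6:
        lo /= 2.0
        d_lo = d_of(lo)
        expand += 1
    best_ratio, best_err = (lo, abs(d_lo - target_d))
    if abs(d_hi - target_d) < best_err:
        best_ratio, best_err = hi, abs(d_hi - target_d)
    if not d_lo <= target_d <= d_hi:
        raise CalibrationError(
            f"could not bracket target d={target_d}", best_ratio=best_ratio
        )
    # Converge well inside the contracted tolerance; the limiting error is
    # then the pilot's sampling noise, not the bisection stopping rule.
    tol_internal = min(tol, 0.05)
    for _ in range(max_iter):
        mid = float(np.sqrt(lo * hi))
        d_mid = d_of(mid)
        if abs(d_mid - target_d) < best_err:
            best_ratio, best_err = mid, abs(d_mid - target_d)
        if abs(d_mid - target_d) <= tol_internal:
            return mid
        if d_mid < target_d:
            lo = mid
        else:
            hi = mid
    raise CalibrationError(
        f"calibration did not reach |d - {target_d}| <= {tol}; "
        f"best ratio {best_ratio:.4f} (err {best_err:.3f})",
        best_ratio=best_ratio,
    )
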