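# fceeg

EEG band-power and coherence-network analysis for case–control cohorts,
with a synthetic-cohort simulator. The package implements the analysis
used to look for brain–gut-axis signatures of functional constipation
(FC) in scalp EEG: patients and healthy controls are recorded across
resting, cognitive and defecation-related task blocks, and compared on
regional oscillatory power and on the topology of whole-brain functional
networks. Because such clinical recordings are not publicly deposited,
`fceeg` ships a generative model of the whole study design, so every
stage of the analysis is testable end to end.

It is aimed at EEG methodologists and clinical-neurophysiology
researchers who want a reproducible, validated reference implementation
of this analysis stack — or a controllable test bed for power analysis
and method checks.

## The analysis

For each subject, task block and channel, the **relative power** of band
*b* is

    RP_b = ∫_{Ω_b} P(f) df / ∫_{0.5}^{45} P(f) df

with P(f) a Welch PSD (2 s Hann, 50% overlap) and Ω_b the canonical
bands δ 0.5–4, θ 4–8, α 8–13, β 13–30, γ 30–45 Hz; channel values are
averaged into five lobes (frontal, central, temporal, parietal,
occipital).

Functional connectivity is the band-averaged **imaginary part of
coherency**, |Im C_xy(f)| with C_xy = S_xy/√(S_xx S_yy), which is blind
to instantaneous (volume-conducted) coupling. Each connectivity matrix
is binarized at proportional sparsity thresholds s ∈ {0.10, …, 0.30},
and three graph metrics — global efficiency E_glob, average local
efficiency E_loc, and average clustering coefficient C — are integrated
over the threshold sweep (trapezoid AUC) into threshold-independent
features.

Group differences are tested per (task, band, region/metric) cell with an
ANCOVA (value ~ group + age), Benjamini–Hochberg FDR within each
(task, band) family of five lobes, and Cohen's d (pooled SD, signed
patient − control) with |d| > 0.5 flagged as a medium effect.

Preprocessing mirrors standard clinical practice: 0.5–45 Hz zero-phase
band-pass, flatline bad-channel (>60% of samples < 1e-10 µV) and
bad-segment detection, spherical-spline interpolation, and a pluggable
ICA-based artifact remover, with per-recording QC percentages.

## Worked example

Simulate a small cohort in which patients have a 40% parietal alpha
amplitude elevation, then run the whole pipeline:

```python
from fceeg import PipelineConfig, run_all
from fceeg.simulate import ArtifactRates, BandGains, SimulationConfig

gains = BandGains().with_override("patient", "parietal", "*", "alpha", 1.4)
config = PipelineConfig(
    simulation=SimulationConfig(
        n_patients=10, n_controls=10, seed=42,
        task_schedule=(("resting", 60.0),),
        band_gains=gains,
        artifact_rates=ArtifactRates(0.03, 0.3, 4.0),
    ),
    seed=42,
)
out = run_all(config, "demo_run")
print((out / "summary.txt").read_text())
```

which prints (`*`/`**` = FDR-significant at 0.05/0.01, `#` = medium
effect, |d| > 0.5; only flagged rows are listed):

```
task | band | feature | p_fdr | d | flags
resting | delta | parietal | 0.4056 | -0.79 | #
resting | theta | temporal | 0.5797 | +0.79 | #
resting | theta | parietal | 0.0026 | -2.26 | **#
resting | theta | occipital | 0.7506 | -0.59 | #
resting | alpha | parietal | 0.0872 | +1.44 | #
resting | beta | central | 0.2437 | +0.82 | #
resting | beta | parietal | 0.2351 | -1.05 | #
resting | gamma | frontal | 0.1828 | +0.80 | #
resting | gamma | central | 0.0558 | +0.83 | #
resting | gamma | parietal | 0.0312 | -1.82 | *#
resting | gamma | occipital | 0.2768 | -0.76 | #

task | band | feature | p_fdr | d | flags
resting | gamma | global_efficiency | 0.2890 | +0.75 | #
```

The injected parietal alpha elevation comes back with the right sign and
a large standardized effect (d = +1.44). Because relative power is a
closed composition, the boost necessarily depresses the other parietal
band fractions (the negative parietal delta/theta/beta/gamma rows), and
at n = 10 per group many cells clear the |d| > 0.5 bar by chance alone —
a useful reminder of why the statistics stage reports the FDR-adjusted
p-value and the effect-size flag as separate columns. The run directory
contains every intermediate product: `metadata.csv`, per-recording QC
(`qc_reports.csv`, `qc_summary.json` — here 3.4% ± 2.2% bad channels,
1.8% ± 1.1% artifacts removed), `band_power_channels.csv`,
`band_power_regions.csv`, `network_auc.csv`, `network_per_threshold.csv`,
scalp-map grids under `topomaps/`, the statistics tables, and a
`manifest.json` whose config hash and seeds make the run
bit-reproducible.

The same stages are available as a CLI:

```bash
fceeg simulate --config cfg.yaml --out raw --seed 7
fceeg preprocess --in raw --out clean --config cfg.yaml
fceeg features --in clean --out feats --config cfg.yaml
fceeg stats --in feats --out results --config cfg.yaml
fceeg run-all --config cfg.yaml --out run1 --seed 7
```

Recordings are exchanged as EDF plus a JSON sidecar; all feature and
statistics tables are plain CSV.

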