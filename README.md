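# synergyemg

Muscle-synergy and independent-component analysis of multi-channel
forearm EMG for decoding eight-direction index-finger movements.

High-density surface EMG mixes the activity of superficial muscles
(localized electrode footprints), deep muscles (activity spread over
the forearm cross-section), crosstalk and noise. This package
implements the two-stage decomposition pipeline used to separate and
compare those contributions, for researchers working on myoelectric
decoding and motor control:

1. **ICA** (X = AS): blind source separation of the 95 recording
   channels into independent components; components with white-noise
   characteristics are rejected.
2. **Non-negative matrix factorization** (E = TM, HALS updates) of
   pseudo-joint-torque envelopes — rectified, 5 Hz low-passed,
   mean-normalized signals — extracting muscle synergies from either
   raw channels (*EMG-synergy*) or retained ICs (*ICA-synergy*). The
   synergy count is the smallest rank with Variance Accounted For
   above 0.9 and a linear VAF plateau (regression MSE below 1e-4).
3. **Synergy modules**: synergies extracted from Elbow-0, Elbow-90 and
   Total datasets are clustered by their scalar product (UPGMA, merge
   while SP > 0.75), each synergy's direction tuning is fitted as
   m(θ) = a0 + a1 cos θ + a2 sin θ with preferred direction
   PD = atan2(a2, a1) and tuning weight W = √(a1² + a2²), and modules
   are typed *parallel* (along the forearm, superficial signature) or
   *local* (cross-sectional, deep signature).
4. **Classification**: a small CNN (3×3, 32 filters) decodes the eight
   movement directions from four input types (EMG-input, IC-input,
   EMG-synergy, ICA-synergy) in both extrinsic (screen) and intrinsic
   (forearm) coordinate frames under stratified fivefold
   cross-validation.

Because the original recordings are not public, the package ships a
first-class synthetic-data generator (`synergyemg.emg_synth`) that
plants direction-tuned superficial and deep sources with known lead
field, tuning and labels on a 96-electrode cylindrical forearm grid,
plus line noise, white sensor noise and baseline movement-artifact
noise — so every stage is testable against ground truth.

## Worked example

```python
from synergyemg.pipeline_cli import PipelineConfig, run_all

cfg = PipelineConfig.from_dict({"seed": 1, "out": "run.h5"})
manifest, state = run_all(cfg)
print(manifest.stage_info["ica"])
print(manifest.stage_info["synergy"])
print(state["classify_summary"])
```

On the default reduced-scale dataset (8 directions × 2 elbow postures
× 10 repetitions at 1024 Hz, 0 dB white + 0 dB artifact noise) this
prints, for seed 1:

```
{'n_components': 10, 'n_retained': 10}
{'rank_emg': 3, 'vaf_emg': 0.945, 'rank_ica': 3, 'vaf_ica': 0.969}
    input_type      frame  n_inputs  mean_accuracy  sd_accuracy
0    EMG-input  extrinsic        95        0.25000     0.038273
1    EMG-input  intrinsic        95        0.53125     0.091109
2     IC-input  extrinsic        10        0.29375     0.035630
3     IC-input  intrinsic        10        0.91875     0.100293
4  EMG-synergy  extrinsic         3        0.14375     0.047393
5  EMG-synergy  intrinsic         3        0.45625     0.047393
6  ICA-synergy  extrinsic         3        0.32500     0.092702
7  ICA-synergy  intrinsic         3        1.00000     0.000000
```

Reading the numbers: ICA found the 10-dimensional planted-source
subspace among 95 channels and retained all 10 components; intrinsic
decoding beats extrinsic for every input type (the planted sources are
muscle-fixed, so rotating Elbow-90 labels into the forearm frame makes
classes consistent — extrinsic decoding is capped near 50 % by the
posture ambiguity); and ICA-synergy decodes essentially perfectly
where EMG-synergy, contaminated by channel-level noise that NMF cannot
remove, reaches 46 %. The module tables in `state["modules_df"]` show
the matching tuning statistics: ICA-synergy modules have larger cosine
tuning weights and much smaller within-module preferred-direction
errors (about 22° vs 85° at this noise level) than EMG-synergy
modules.

The same pipeline is scriptable from the shell:

```bash
synergyemg all --seed 1 --out run.h5
synergyemg validate run.h5
```

`run.h5` holds every stage's outputs (see `synergyemg.container` for
the schema) next to CSV summaries and a JSON manifest with per-stage
seeds, wall times and content hashes; re-running with the same config
reproduces the hashes bit for bit, and `--resume` recomputes only the
stages downstream of whatever changed.

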