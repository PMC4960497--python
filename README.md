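# stresskit

Minute-block stress detection from wearable physiology. The pipeline goes
from raw photoplethysmography (PPG) and electrodermal activity (EDA)
traces to per-minute stress/non-stress decisions and signal-detection
evaluation:

1. **session_model** (`stresskit.session`) — trace/schedule types,
   plain-text CSV I/O, anti-aliased rational resampling to the analysis
   rates (PPG 64 Hz, EDA 4 Hz), half-open phase slicing.
2. **pulse_features** (`stresskit.pulse`) — derivative-based pulse
   upstroke detection, inter-beat intervals with 40–180 bpm validity
   filtering, non-overlapping 1-minute block features (mean HR = 60 /
   mean valid IBI, kept only with ≥ 40 valid IBIs; mean EDA over raw
   samples), and per-participant baseline normalization (subtract the
   5-min seated-baseline means).
3. **stress_classifier** (`stresskit.classifier`) — phase-derived
   labeling (baseline = non-stress, speech task = stress; arithmetic
   task optionally stress for held-out evaluation; anticipation always
   unlabeled), seeded stratified 75:25 split, SGD linear model (hinge
   loss, L2, standardized features), 5-fold cross-validation, and
   bias-term threshold adjustment.
4. **detection_eval** (`stresskit.detection`) — hits / misses / false
   alarms / correct rejections and the derived accuracy, hit-rate, and
   false-alarm-rate.
5. **synthetic_cohort** (`stresskit.simulate`) — seeded generator of
   TSST-structured sessions (5-min baseline + three 5-min task phases)
   with ground-truth beat times and programmed per-phase HR/EDA deltas;
   stands in for study recordings that were never deposited.
6. **cli** (`stresskit.cli`, `stresskit.config`, `stresskit.pipeline`) —
   configuration-driven orchestration.

## CLI

```bash
# synthetic cohort -> per-participant trace CSVs + schedule + ground truth
stresskit simulate --n 20 --seed 1 --out-dir data/

# feature table (one row per minute block, normalized features for valid blocks)
stresskit features --data-dir data/ --seed 1 --out-dir feat/

# train / cross-validate / evaluate / classify
stresskit train    --features feat/features.csv --seed 1 --out-dir model/
stresskit cv       --features feat/features.csv --seed 1 --out-dir cv/
stresskit evaluate --features feat/features.csv --model model/model.json --out-dir report/
stresskit classify --features feat/features.csv --model model/model.json --out-dir pred/
```

Common flags: `--config <yaml>` (file values; CLI flags override),
`--seed`, `--out-dir`, `--log-level`. Every command serializes the
effective configuration (`config_used.yaml`) next to its outputs, and
all randomness flows from the seed, so reruns are byte-identical.

File contracts: trace CSVs are `time_s,value` (or single-column
`value`), schedules are `phase,start_s,end_s`, feature tables are
`participant_id,phase,minute_index,mean_hr,mean_eda,dhr,deda,hr_valid,n_valid_ibi`,
models are versioned JSON.

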