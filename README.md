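# cranioflow

Surgical tool detection and workflow phase estimation for **open cranial
vault remodeling**, the operation that corrects craniosynostosis
(premature fusion of cranial sutures in infants).

The intervention follows eleven ordered phases (P1 skin incision … P11
suturing), and each phase is characterised by the set of instruments in
the surgical field — its *right-phase tools*.  `cranioflow` implements
the full recognition pipeline:

1. **Multilabel tool detection.**  A compact CNN (*CranioNet*: blocks of
   two 3×3 stride-1 convolutions with batch norm and ReLU, a 3×3
   stride-2 max pool and 0.25 dropout, then a dense ReLU/batch-norm/0.5
   dropout classifier) maps each 64×64 video frame to ten independent
   sigmoid probabilities — nine tools plus an `Environment` background
   label.  A transfer-learning variant puts a global-average-pooling +
   dropout + sigmoid head on any frozen backbone.  Training minimises
   binary cross-entropy with a weighted L1 penalty,
   `L = BCE + λ·Σ|w|`, using Adam (β₁ = 0.9, ε = 10⁻⁸), Xavier weights
   and zero biases.
2. **Detection logging.**  A tool counts as detected when its
   probability exceeds 0.5 (strictly); per-frame records go to a CSV log
   (`frame,time_s,p_Forceps,…,p_Environment,detected`), with `None` for
   empty frames.
3. **Phase estimation.**  For each phase, a binary signal marks frames
   whose detected tool set equals the right-phase set (Environment
   ignored).  The signal is smoothed by a centred moving average,
   re-binarised, and maximal runs of 1s are matched to phases in
   workflow order; the limit between consecutive phases is the rounded
   mean of the adjoining batch end and start.
4. **Evaluation.**  Per-tool precision `TP/(TP+FP)`, recall
   `TP/(TP+FN)`, F1 (harmonic mean), frame-level **exact-match
   accuracy** (the predicted label set must equal the truth exactly),
   and per-phase **coverage** (percent of the ground-truth interval
   overlapped by the estimate).
5. **Synthetic data.**  The original phantom recordings are not public,
   so a procedural generator renders green-sheet scenes with one
   distinct colored glyph per tool, a skin-toned phantom blob,
   blue-glove occluders and varying illumination, plus ground-truth
   timelines and noisy detection logs — everything needed to exercise
   and test the pipeline end to end.

## Worked example

Estimate phases from a noisy detection log (2% per-label flips, ±5-frame
boundary jitter) over a 3,300-frame simulated surgery:

```python
import numpy as np
from cranioflow import PHASES, phase_coverage, estimate_phases, PhaseEstimationConfig
from cranioflow.synthdata import NoiseModel, default_timeline, simulate_detection_log

tl = default_timeline(3300)                       # 11 phases, 15 fps
log = simulate_detection_log(tl, NoiseModel(flip_rate=0.02, jitter=5), seed=42)
ests = estimate_phases(log, PHASES, PhaseEstimationConfig(window=45, threshold=0.4))
for e in ests[:3]:
    gt = tl.interval(e.phase)
    print(f"{e.phase}: truth {gt}  estimate {e.final_interval}  "
          f"coverage {phase_coverage(gt, e.final_interval):.1f}%")
covs = [phase_coverage(tl.interval(e.phase), e.final_interval) for e in ests]
print(f"mean coverage over 11 phases: {np.mean(covs):.1f}%")
```

prints

```
P1: truth (0, 299)  estimate (0, 296)  coverage 99.0%
P2: truth (300, 599)  estimate (297, 604)  coverage 100.0%
P3: truth (600, 899)  estimate (605, 899)  coverage 98.3%
mean coverage over 11 phases: 98.8%
```

Each phase's estimated interval tracks its ground-truth segment to
within a few frames despite the injected detection noise.  Scoring the
same log frame by frame gives per-tool rows such as
`Motor: P 90.8  R 97.5  F1 94.1` and a frame exact-match accuracy of
80.9% — lower than any per-tool accuracy, as a frame only counts when
*all ten* label decisions are right.

The same pipeline is available from the shell:

```bash
cranioflow synth  --preset mini --seed 7 --out data/
cranioflow train  --data data/training --out data/model --seed 7
cranioflow detect --model data/model --frames data/video --fps 15 --out data/log.csv
cranioflow phases --log data/log.csv --truth data/timeline.json --out data/report.json
cranioflow eval   --log data/log.csv --truth data/timeline.json --out data/scores
```

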