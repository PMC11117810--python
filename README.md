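# fecgsep — fetal/maternal ECG separation and interval analysis

Non-invasive fetal monitoring records a composite signal: electrodes on a
pregnant woman's abdomen pick up the fetal electrocardiogram (fECG) buried
under the far larger maternal one (mECG) — the fetal trace typically carries
only ~25% of the composite energy — plus baseline wander, 50 Hz mains pickup
and muscle noise. `fecgsep` implements the full desk-top chain for this
problem, for researchers and students in biomedical signal processing:

1. **Synthesis** (`fecgsep.synth`) — ground-truth maternal and fetal beat
   trains (Gaussian-sum PQRST morphology), mixed onto thorax/abdomen
   channels through a known 2×2 matrix with the abdominal fetal energy
   fraction calibrated exactly, and optional noise.
2. **Blind source separation** (`fecgsep.bss`) — the linear instantaneous
   model *x(k) = H s(k)*: channels are centered, whitened (unit-variance,
   uncorrelated), and the remaining rotation is estimated by symmetric
   fixed-point ICA (tanh or kurtosis contrast, symmetric decorrelation
   *B ← (BBᵀ)^(-1/2)B*), giving *y(k) = W x(k) ≈ s(k)* up to permutation and
   scale, which a labelling step then resolves.
3. **Separation scoring** (`fecgsep.metrics`) — the Amari performance index
   of the global matrix *G = W·H*: 0 for perfect separation, 1 for the
   maximally mixed case.
4. **Clinical delineation** (`fecgsep.analysis`) — zero-phase band-pass
   filtering, R-peak detection against a horizontal reference line
   recomputed every 10 s, RR intervals, BPM = 60000/RR(ms), QT intervals by
   the tangent method, and inclusive healthy-range checks
   (mother: RR 600–1200 ms, QT 350–450 ms, BPM 60–100;
   fetus: RR 300–600 ms, QT 250–340 ms, BPM 105–150).
5. **Orchestration** (`fecgsep.pipeline` + the `fecg` CLI) — end-to-end
   runs, CSV/JSON I/O, and a per-minute monitoring loop writing
   `latest.json` / `history.jsonl`.

## Worked example

```python
import numpy as np
from fecgsep import make_fixture, separate, evaluate_separation

sources, record = make_fixture(seed=0)   # 4 s, 250 Hz, 6 + 11 beats
result = separate(record)                # center -> whiten -> ICA -> labels
print(result.labels)                     # ('fECG', 'mECG')
print(evaluate_separation(result, sources.H))
```

Running the bundled narrative scripts prints, among other things:

```
$ python examples/02_separate_and_score.py
converged      : True (4 iterations)
row labels     : ('fECG', 'mECG')
Amari performance index of W @ H_true : 0.0143
|correlation| of recovered mECG with ground truth: 0.9999
|correlation| of recovered fECG with ground truth: 0.9999

$ python examples/03_interval_analysis.py
--- mother (mECG)
  R peaks  : 6 at [0.1   0.768 1.432 2.1   2.768 3.432] s
  BPM      : 90.0  [in_range]
  mean RR  : 666.4 ms  [in_range]
  mean QT  : 406.5 ms  [in_range]
--- fetus (fECG)
  BPM      : 164.8  [above]
  mean RR  : 364.0 ms  [in_range]
  mean QT  : 311.1 ms  [in_range]
```

Both sources are recovered essentially exactly (correlation > 0.999 with
ground truth); all 6 maternal and 11 fetal beats are found; the fetal rate
of 165 BPM exceeds the healthy ceiling of 150 and is flagged accordingly.
The performance index of 0.014 reflects the small residual cross-leakage
left by ICA on a 4-second window — see `docs/methods.md` for why short
windows of overlapping periodic beat trains bound what any
whitening-plus-rotation separator can achieve.

The same chain is available from the shell:

```sh
fecg simulate --duration 4 --fs 250 --seed 0 --out fixture.csv --truth-out truth.csv
fecg separate --in fixture.csv --out sources.csv --contrast tanh --truth truth.csv
fecg analyze  --in sources.csv --out report.json
fecg run      --seed 0 --report-out report.json
fecg stream   --in fixture.csv --outdir monitor/
```

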