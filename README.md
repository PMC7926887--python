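# ecgmultirate

Multirate ECG processing for computationally efficient arrhythmia
classification.

Wearable ECG devices must classify heartbeats under tight power and
bandwidth budgets. This package implements a front-end chain that reduces
both the arithmetic cost of on-device processing and the volume of data
shipped to a classifier, while keeping four-class beat classification
(normal **N**, right/left bundle branch block **RBBB**/**LBBB**, atrial
premature complex **APC**) accurate. It is aimed at biomedical-signal
researchers who want a tested, reproducible reference implementation of the
chain and its evaluation protocols.

## The method

Starting from a single-channel ECG $y(n)$ sampled at $F_S = 360$ Hz
(11-bit ADC, 60 Hz anti-aliasing bandwidth):

1. **Windowing** — rectangular windows of 0.9 s (the average cardiac pulse
   duration), $N_r = 324$ samples each.
2. **First decimation** by $D_1 = 2$. Decimation without pre-filtering is
   alias-free when $D \le F_S / (2 f_{max})$; here the bound is
   $360/120 = 3$, so $D_1 = 2$ is valid and yields 180 Hz windows.
3. **QRS selection** — a threshold $\alpha$ equal to 50 % of the mean
   R-peak amplitude is applied; at the first upward crossing the R peak is
   located as the maximum on the pulse's leading edge and a 60-sample
   (333 ms) excerpt centred on R is kept. Windows that never cross
   $\alpha$ are ignored.
4. **Denoising** — a 45-tap equiripple (Parks–McClellan) linear-phase FIR
   low-pass, cut-off $F_C = 40$ Hz at 180 Hz, group delay compensated.
   Working at the reduced rate roughly halves the tap count relative to a
   360 Hz design with the same band edges.
5. **Second decimation** by $D_2 = 2$ (bound $180/80 = 2.25$), leaving
   $N = 30$ samples per segment at 90 Hz.
6. **Wavelet features** — a partial wavelet-packet tree (8-tap Daubechies-4
   analysis pair, symmetric extension) splits the segment into subbands
   $d_1$ (18), $d_2$ (12) and four level-4 blocks of 8 coefficients each:
   62 coefficients (feature set **P1**). Because the diagnostic content of
   the ECG lies below ~22 Hz, only the four level-4 subbands
   $[dd_4, da_4, ad_4, aa_4]$ are kept: 32 features (**P2**). The
   fixed-rate baseline — a full 4-level packet tree on the raw 324-sample
   window — produces 416 coefficients (**Pr**), so the selection compresses
   the transmitted volume by $R_{COMP} = 416/32 = 13$.
7. **Classification** — six configurations (MLP, k-NN with $k=5$, decision
   tree, degree-3 polynomial SVM with $C=10$, 100-tree random forest,
   bagging of 10 SVMs) after per-fold min–max scaling, evaluated under
   stratified 5-fold CV and a subject-wise **partial-blind** protocol: one
   fold per subject index, with ~29 % (50 of 170) of each held-out
   subject's beats injected into training as calibration and excluded from
   testing. Metrics: accuracy, micro-F1 (identically equal to accuracy for
   pooled multi-class counts), Cohen's kappa and macro one-vs-rest AUC.

A closed-form model counts the additions and multiplications of both
chains per window; with the canonical parameters ($K_r = 91$, $K = 45$,
$K_{wd} = 8$) the multirate chain is more than 12-fold cheaper in both
operation types, and cubic-spline reconstruction of each decimation stage
quantifies the (small) information loss.

Because the reference recordings require an external database download, the
package ships a first-class synthetic generator that emulates the study
conditions: 4 classes × 3 subjects × 170 beats = 2040 instances at 360 Hz
with class-distinct QRS morphology and powerline/baseline/white noise.

## Worked example

```bash
ecgmultirate simulate --seed 0 --out demo/records
ecgmultirate extract --records demo/records --mode P2 --out demo/p2.csv
ecgmultirate evaluate --features demo/p2.csv --classifier rf --protocol cv5 \
    --seed 0 --out demo/rf_cv5.json
ecgmultirate evaluate --features demo/p2.csv --classifier rf \
    --protocol partial-blind --inject 50 --seed 0 --out demo/rf_pb.json
ecgmultirate cost-report
```

prints

```
wrote 12 records (2040 beats) to demo/records
2040 windows -> 2040 QRS selected, 0 ignored (alpha = 0.643 mV)
wrote 2040 x 32 feature matrix (P2) to demo/p2.csv
RF / P2 / cv5: accuracy 99.61 (+-0.25)
RF / P2 / partial-blind: accuracy 99.51 (+-0.55)
```

Every one of the 2040 synthetic beats crosses the calibrated threshold
(α = 0.643 mV, half the mean R amplitude) and yields one 30-sample segment.
The random forest separates the four synthetic morphologies almost
perfectly under 5-fold CV (99.61 % ± 0.25 over folds); the subject-wise
partial-blind protocol is the harder test and shows the larger fold spread
(± 0.55). The synthetic classes are cleaner than real recordings, so these
accuracies sit above those achievable on clinical data; the structural
numbers below do not depend on the data at all. `cost-report` prints the
closed-form model:

```
"fixed_rate": { "additions": 48676, "multiplications": 51788 },
"proposed":   { "additions": 3899.5, "multiplications": 4048.0 },
"gain": { "additions_fold": 12.48, "multiplications_fold": 12.79 },
"compression_ratio": 13.0
```

i.e. the multirate chain needs 12.5× fewer additions and 12.8× fewer
multiplications per window than the fixed-rate chain, and transmits 13×
fewer coefficients per beat.

The same pipeline is available as a library:

```python
import ecgmultirate as em

records = em.synthesize_dataset(em.SynthConfig(seed=0))
windows, denoised, stats = em.process_dataset(records)
features = em.build_feature_matrix(denoised, "P2")
result = em.run_5cv(features, em.ClassifierSpec.for_mode("RF", "P2"), seed=0)
print(result.mean_std["accuracy"])   # (99.61, 0.25)
```

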