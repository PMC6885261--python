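# emgkit

Automated classification of clinical electromyography (EMG) signals into
**Normal**, **Myopathy** and **Neuropathy**, built from three stages:

1. **Wavelet-packet feature extraction.** Each recording is cut into
   non-overlapping rectangular frames of 2048 samples. A level-4 wavelet
   packet decomposition (default Daubechies-4, periodized) splits every
   frame into 16 uniform frequency subbands of 128 coefficients. Each
   subband *y₁…y_M* is summarised by six statistics:
   mean absolute value (1/M)Σ|yⱼ|, average power (1/M)Σyⱼ²,
   population standard deviation σ, skewness (1/M)Σ((yⱼ−ȳ)/σ)³,
   raw kurtosis (1/M)Σ((yⱼ−ȳ)/σ)⁴, and the ratio of summed absolute
   coefficients of frequency-adjacent subbands — 16·5 + 15 = **95
   features per frame**.
2. **Ensemble classification.** Native, instance-weighted base learners
   (C4.5-style gain-ratio tree, Gaussian naive Bayes, k-NN, random tree,
   random forest) combined by **bagging**, **AdaBoost.M1**
   (β_t = ε_t/(1−ε_t), member vote weight log(1/β_t)) or **MultiBoosting**
   (AdaBoost sub-committees restarted by wagging's random instance
   weights). External estimators (ANN/SVM-style) attach through a
   scikit-learn adapter.
3. **Evaluation.** Stratified 10-fold cross-validation with pooled
   out-of-fold predictions: accuracy, per-class and prevalence-weighted
   precision/recall/F, one-vs-rest rank-sum AUC, and Cohen's kappa
   K = (P₀−P_e)/(1−P_e).

Because clinical needle-EMG datasets are licensed, the package ships a
**synthetic motor-unit action potential (MUAP) train simulator**: per-unit
MUAP templates (alternating-sign Gaussian lobes with controlled amplitude,
duration and phase count) fire as jittered renewal processes, are summed,
noise-corrupted and band-limited (5 Hz–10 kHz at 20 kHz sampling), with
class profiles encoding the textbook contrasts — myopathic MUAPs short,
small and polyphasic; neuropathic MUAPs long and large from few units.
Everything is a pure function of one integer seed.

Intended users: biomedical-signal researchers and students who need a
transparent, fully reproducible reference pipeline for subband-statistics
EMG classification, not a clinical diagnostic device.

## Worked example

```python
import emgkit as ek

recordings = ek.simulate_dataset(
    ek.default_profiles(), n_recordings_per_class=4,
    config=ek.SimulationConfig(duration_s=0.6, seed=11))
frames = [f for r in recordings for f in ek.frame_signal(r, 1024)]
table = ek.extract_features(frames)

cv = ek.CvConfig(k_folds=10, seed=11)
knn = ek.make_learner("knn", k=5)
forest = ek.make_learner("random_forest", n_trees=15)
bagged = ek.cross_validate(lambda ds, s: ek.bagging_train(knn, ds, T=10, seed=s), table, cv)
single = ek.cross_validate(lambda ds, s: forest.train(ds, s), table, cv)
```

This (examples/04_cross_validated_pipeline.py) prints:

```
feature table: 132 frames x 95 features
 bagging + 5-NN: accuracy 77.27%  F 0.771  AUC 0.923  kappa 0.659
  random forest: accuracy 92.42%  F 0.925  AUC 0.990  kappa 0.886
```

Accuracy is the percentage of frames classified correctly when held out;
kappa corrects that agreement for chance (0 = chance, 1 = perfect); AUC is
the prevalence-weighted one-vs-rest ranking quality of the committee's
score vectors. On this deliberately tiny run (132 frames from 0.6 s
recordings) the forest separates the three classes well; the full-scale
benchmark below reaches ≈98 % accuracy.

The other scripts in `examples/` walk through the simulator's class
contrast, the wavelet-packet energy identity, and AdaBoost's weight
mechanics on a ten-point toy set.

A thin CLI wraps the same pipeline for shell use:

```sh
emgkit run --config run.yaml     # simulate -> extract -> evaluate
emgkit simulate --seed 42 --output-dir out
```

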