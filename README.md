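# sevodoa

EEG-based depth-of-anesthesia (DoA) index estimation for sevoflurane
anesthesia, built for anesthesia-monitoring researchers and biosignal
engineers.  The package extracts hybrid entropy/spectral features from
single-channel EEG, regresses the sevoflurane **effect-site concentration**
with a sparse denoising autoencoder + LSTM network (SDAE-LSTM), and
validates the resulting index with the **prediction probability (Pk)**
statistic under leave-one-subject-out cross-validation.  A synthetic
anesthesia-session simulator makes the whole pipeline runnable and testable
without clinical recordings.

## Method

Per 5 s window (500 samples at 100 Hz) of notch/band-pass-filtered EEG, 46
features are computed: 40 half-Hz spectral bins over 30–50 Hz, the average
powers in 30–47 and 47–50 Hz, permutation entropy
(−Σ Pⱼ ln Pⱼ / ln m!, m = 4, τ = 1), sample entropy
(−ln[A(m+1,r)/A(m,r)], m = 2, r = 0.2·SD), wavelet entropy
(−Σ pⱼ ln pⱼ over relative wavelet energies), and the alpha-ratio
log₁₀(E₃₀₋₄₂.₅/E₆₋₁₂).

Training labels come from the first-order effect-compartment model

    dC_eff/dt = k_eo (C_et − C_eff)

applied to the recorded end-tidal concentration; an inhibitory sigmoid
Emax curve (Effect = E_max − (E_max−E_min)·C_eff^γ/(EC50^γ + C_eff^γ)) is
available for index visualisation.  The regressor is a 46–92–12–18–1 stack:
two sparse denoising autoencoders (masking corruption, KL sparsity
penalty) pretrained layerwise, an LSTM on the encoded window sequence, a
linear output, then end-to-end fine-tuning — implemented in plain numpy
with hand-derived, finite-difference-verified gradients.

Validation uses Smith's prediction probability
Pk = (P_c + P_tx/2)/(P_c + P_d + P_tx) over all window pairs with distinct
true depth (Pk = 1: perfect ordering, 0.5: chance; anticorrelated indices
are reported as 1 − Pk).

## Worked example

```python
import sevodoa as sd

# simulate a 6-subject cohort of 600 s sessions
scale = 600.0 / 900.0
profile = tuple((t * scale, c) for t, c in sd.synthetic.DEFAULT_CET_PROFILE)
base = sd.SessionSpec(duration_s=600.0, cet_profile=profile)
sessions = sd.simulate_cohort(6, base, seed=42)

# preprocess, extract 46 features per 5 s window, align effect-site labels
feats, labels = sd.cohort_features(sessions)
print("windows per subject:", feats[0].n_windows, "features:", len(feats[0].names))

# train on five subjects, evaluate the held-out sixth
net = sd.train(feats[:5], labels[:5], sd.NetworkSpec(seed=0))
index = sd.predict(net, feats[5])
res = sd.pk_statistic(index, labels[5])
print(f"held-out Pk = {res.pk:.4f} (reflected: {res.reflected})")

for name in ("peen", "sampen", "alpha_ratio"):
    b = sd.baseline_pk(feats[5], labels[5], name)
    print(f"baseline Pk [{name}] = {b.pk:.4f}")
```

prints

```
windows per subject: 120 features: 46
held-out Pk = 0.8515 (reflected: False)
baseline Pk [peen] = 0.7298
baseline Pk [sampen] = 0.7171
baseline Pk [alpha_ratio] = 0.7784
```

The trained network orders the held-out subject's windows by effect-site
concentration better (Pk 0.85) than any single feature used directly as an
index (0.72–0.78); the entropies anticorrelate with depth, so their Pk
values are reported after reflection.

The same pipeline is scriptable from the shell:

```sh
doa simulate --subjects 20 --duration 600 --seed 7 --out cohort/
doa crossval --cohort cohort/ --repeats 1 --seed 7 --out report.json
doa extract  --in cohort/S00/eeg.csv --out features.csv
```

`sevodoa` also plays with scikit-learn directly: `SDAELSTMRegressor` is an
estimator with `fit(X, y, subjects=...)`/`predict`, and
`HybridFeatureExtractor` a transformer from raw EEG windows to the
46-column feature matrix.

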