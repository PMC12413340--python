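# phasesleep

EEG functional connectivity across sleep stages: six Hilbert-based
phase-coupling metrics per frequency band and 10 s epoch, nonparametric
stage-difference statistics, and subject-wise gradient-boosted sleep-stage
classification — plus a synthetic cohort generator so the whole pipeline is
testable without clinical data.

## Who this is for

Sleep and consciousness researchers asking how much stage information
(W / N1 / N2 / N3) is carried by *phase coupling* between scalp electrodes,
as opposed to the amplitude features that visual AASM scoring relies on —
and methodologists comparing volume-conduction-sensitive and -insensitive
coupling metrics on the same data.

## The model

For band-passed channels `x_i(t)` with analytic signals
`z_i(t) = A_i(t) e^{iφ_i(t)}`, define the per-sample cross spectrum

    S_ij(t) = A_i(t) A_j(t) exp(+i Δφ_ij(t)),   Δφ_ij = φ_i − φ_j

and, with ⟨·⟩ the time average over one 10 s epoch, the six metrics

    COH   = |⟨S_ij⟩| / √(⟨S_ii⟩⟨S_jj⟩)
    iCOH  = Im(⟨S_ij⟩ / √(⟨S_ii⟩⟨S_jj⟩))
    PLV   = |⟨e^{iΔφ}⟩|
    ciPLV = |⟨Im e^{iΔφ}⟩| / √(1 − ⟨Re e^{iΔφ}⟩²)
    PLI   = |⟨sign(Im S_ij)⟩|
    wPLI  = |⟨Im S_ij⟩| / ⟨|Im S_ij|⟩

computed in four gapped bands (delta 1–3.5, theta 4.5–7, alpha 8–12, beta
13–30 Hz) after average referencing and zero-phase 6th-order Butterworth
filtering. Per metric, each epoch becomes a feature vector of the 435
channel-pair values × 4 bands = 1740 coefficients (30-channel montage).
Friedman tests (Bonferroni α = 0.05/24) with Nemenyi post-hocs test stage
differences; gradient-boosted trees classify epochs under subject-wise
80/20 splits. See `docs/methods.md` for every convention and default.

## Worked example

```python
import phasesleep as ps

# a small synthetic cohort: 6 subjects x 4 stages, 100 s at 100 Hz, 8 channels
spec = ps.CohortSpec(n_subjects=6, segment_length_s=100, fs=100,
                     n_channels=8, seed=3)
model = ps.StageConnectivityModel.from_synthetic(spec=spec, metrics=("PLV", "COH"))
res = model.fit(classify=True, n_splits=4, test_n=1, seed=0)
print(res.stage_tables[("PLV", "alpha")].mean().round(3))
print(res.summary())
```

prints (abridged) the subject-averaged alpha-band phase locking per stage

```
stage
W     0.412
N1    0.276
N2    0.195
N3    0.165
```

— alpha coupling is highest in wakefulness and falls monotonically with
sleep depth, while (not shown) delta coupling rises from W to N3 and beta
coupling peaks in N2 where spindle bursts occur — followed by the summary
with the Friedman omnibus results and the mean held-out classification
accuracy per metric over the subject-wise splits. On high-contrast
synthetic cohorts the classifier recovers the stage of ~99% of epochs;
with permuted labels it drops to the 4-class chance level of 0.25.

The same pipeline runs from the shell:

```bash
phasesleep synth --out recs/ --seed 1
phasesleep connect --recordings recs/ --out feats/ --metrics PLV,COH
phasesleep stats --features feats/ --out stage_stats.csv
phasesleep classify --features feats/features_PLV.csv --metric PLV --out clf/
phasesleep run --out results/        # everything, one manifest
```

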