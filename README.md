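# eegdrift

Tools for quantifying — and mitigating — day-to-day variability in EEG-based
emotion classification. The package implements, as a tested and reusable
pipeline:

- **Band-power feature extraction**: Welch spectral estimation (500 ms
  Hamming segments, 50 % overlap) integrated over six canonical bands
  (delta 0.5–4, theta 4–8, alpha 8–13, beta 13–30, low gamma 30–44,
  high gamma 44–100 Hz), with mastoid re-referencing and anti-aliased
  decimation for raw epochs.
- **Calibration protocols** over a subject's 5-day study: within-day
  classification (WDC, stratified 80/20 splits), standard cross-day
  classification (SCDC, train one day / test the others with matched
  training size), learning-N-days information (LNDI: equal sample quotas
  from N training days, all C(5, N) day combinations, budget
  `M_min = floor(min day count / 12) × 12`), and a window-width analysis
  that alternates consecutive temporal blocks between train and test.
- **Consensus recursive feature elimination**: a wrapper RFE that ranks
  features by the accuracy lost when each is removed, run once per
  held-out day; features appearing in at least 3 of the 5 fold top-M lists
  form the salient subset, which is then validated on a held-back half of
  the data under every LNDI condition. Cross-subject contribution rates
  summarise which channel-band features are selected.
- **A synthetic multi-day EEG generator** (feature-level and signal-level)
  with controllable class effects, day-to-day drift, and within-day drift,
  so the whole pipeline is testable without any recordings.

## Test

```bash
python -m pytest tests/
```

`tests/test_acceptance.py` holds the property-based acceptance suite
(budget arithmetic, combinatorial exhaustiveness, chance-level soundness,
drift-degradation patterns, RFE recovery, spectral oracle, leakage audit);
the other files are per-module unit and property tests.

## CLI

```bash
# synthetic 5-day study -> feature table (CSV)
eegdrift simulate --subject S01 --n-channels 60 --epochs-per-day 20 \
    --day-effect-sd 0.3 --seed 1 --out study.csv

# raw signal epochs -> band-power features (with mastoid re-referencing)
eegdrift extract --epochs-dir epochs/ --reference M1 --reference M2 --out features.csv

# calibration protocols
eegdrift evaluate --features study.csv --protocol wdc  --out wdc.csv
eegdrift evaluate --features study.csv --protocol scdc --out scdc.csv
eegdrift evaluate --features study.csv --protocol lndi --n-days 3 --out l3di.csv
eegdrift evaluate --features study.csv --protocol window --window-width 1min --out ww.csv

# feature selection and validation
eegdrift select --features study.csv --top-m 100 --out votes.csv
eegdrift validate --features votes.validation.csv --subset votes.csv --out compare.csv

# summaries: confusion matrix, cross-subject contribution rates
eegdrift report --predictions preds.csv --votes votes.csv --out summary
```

Every result table is delimited text and carries a `.provenance.yaml`
sidecar embedding the full run configuration and its hash.

## Library example

```python
from eegdrift import synthetic, protocols, selection

model = synthetic.make_model(
    n_channels=60,
    informative=[(c, 4) for c in range(8)],   # low-gamma class effects
    class_effect_scale=0.5, day_effect_sd=0.3, noise_sd=0.3,
    epochs_per_day_per_class=(20,) * 5, seed=1,
)
study = synthetic.generate_feature_study(model, "S01")

l4 = protocols.lndi_evaluate(study, 4, repetitions=10, seed=1)
print(l4.mean_accuracy)

sel, val = selection.split_selection_validation(study, seed=1)
rankings, subset = selection.run_l4di_selection(sel, m=100, seed=1, step=10)
print(selection.validate_subset(val, subset.selected, seed=1))
```
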