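# breathauth

Biometric user confirmation and identification from the turbulence of
exhaled breath.

Exhaled airflow is turbulent, and its fine structure is shaped by the
anatomy of the speaker-independent extrathoracic airway — which makes a
short hot-wire anemometer recording of a single exhalation a candidate
biometric. `breathauth` is a library and CLI for researchers exploring this
idea: it takes raw breath velocity/voltage time series (nominally 1.5 s at
10 kHz), screens and summarizes them with multifractal analysis, and runs
the two standard biometric protocols against an enrolled cohort.

## Method in brief

- Each trial is cut into 19 half-overlapping segments (window = N/10,
  slide = window/2) and each segment is z-scored:
  z(i) = (x(i) − μ)/σ.
- Multifractal detrended fluctuation analysis (MFDFA) gives each segment a
  singularity spectrum f(α); segments with non-convex (folded) spectra or
  width ω = α_max − α_min < 0.05 are rejected as irregular.
- Valid segments become 10-dimensional feature vectors: β (α at the
  spectral maximum), ω, and eight time-domain statistics (absolute sum of
  changes, AR(10) coefficients 3 and 4, peak counts, Ricker-CWT peak counts
  at widths 1 and 5, partial autocorrelation at lag 3, excess kurtosis G2).
- Enrollment trains one random-forest classifier per user pair — C(n, 2)
  models, growing by exactly n models per added user.
- **Confirmation** of a claimed identity runs either pairwise Hotelling T²
  tests against the stored training features (HT) or the n−1 stored pair
  models (ML); the confidence is η = 100·v/(n−1), the share of favorable
  pairwise decisions, and the claim is accepted at η ≥ 50%.
- **Identification** runs confirmation for every enrolled identity, fuses
  the per-method vote vectors as V′ = w₁·V_HT + w₂·V_ML (weights sum to 1)
  and answers with the unique argmax of V′ above a threshold η_t.
- Performance: true confirmation rate TCR = c/n·100; identification
  precision P = t/(t+f)·100 and accuracy E = t/n·100 over (t, f, h) =
  (correct, incorrect, not identified), reported as μ ± 2σ across
  re-randomized train/test shuffles.

Since no public breath-turbulence corpus exists, the package includes a
seeded generator of exhalation-like signals whose fluctuations follow a
binomial multiplicative cascade — the canonical multifractal with a
closed-form spectrum — so every stage can be validated against analytic
ground truth. See `docs/methods.md` for the full model description and
design choices.

## Worked example

```python
import breathauth as ba
from breathauth.pipeline import extract_cohort_features
from breathauth.authentication import evaluate

# five synthetic users, ten trials each, well separated
profiles = ba.generate_profiles(5, separation=1.0, master_seed=42)
signals = [ba.generate_trial(p, k) for p in profiles for k in range(10)]

features, rejected = extract_cohort_features(signals)
print(f"{len(rejected)} of 950 segments rejected by the MFDFA filter")

report = evaluate(features, n_shuffles=10, seed=7)
for key in ("TCR_HT", "TCR_ML", "P", "E"):
    print(key, report.format_summary(key))
```

Output:

```
117 of 950 segments rejected by the MFDFA filter
TCR_HT 72.0±51.2%
TCR_ML 100.0±0.0%
P 100.0±0.0%
E 100.0±0.0%
```

Reading: ~12% of segments fail the spectrum-quality screen (mostly at the
envelope edges of a trial). Over ten train/test reshuffles, the machine
learning engine confirms every genuine claim (TCR 100%), while the
hypothesis-testing engine is noisier (mean 72%, ±2σ spanning 51 points) —
the ML > HT ordering expected from a learned versus an axis-aligned
statistical decision boundary. At this separation the fused identifier
names every user correctly (P = E = 100%); with statistically identical
users (separation 0) it falls to the 20% chance rate for five users.

The same protocol is available from the shell:

```bash
breathauth simulate --users 5 --trials 10 --separation 1.0 --seed 42 --out cohort/
breathauth enroll   --manifest cohort/manifest.csv --out library/
breathauth confirm  --lib library/ --claim user000 --input cohort/user000_trial00.txt
breathauth identify --lib library/ --input cohort/user003_trial09.txt
breathauth evaluate --manifest cohort/manifest.csv --shuffles 10 --seed 7 --report report.json
```

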