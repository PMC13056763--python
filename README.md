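# hydrascore

Hydration status matters for health and performance in occupational and
athletic populations — wildland firefighters, construction and
agricultural workers, endurance athletes — yet the reference method,
collecting and pooling every urine void for 24 hours, is impractical
outside a laboratory. `hydrascore` implements a 4-item hydration
**self-assessment** instrument and the complete statistical chain needed
to evaluate it against the 24-hour reference, for researchers who want
to apply the instrument, re-derive it, or stress-test it on simulated
cohorts.

## The model

Four self-observable markers are each scored 0 when they suggest a *low*
urine concentration (i.e. ample fluid intake), 1 otherwise:

| item | marker | scores 0 when |
|---|---|---|
| intake | self-reported 24-h fluid intake | ≥ 2697 mL (females) / ≥ 3697 mL (males) |
| frequency | self-reported 24-h void count | ≥ 7 |
| volume | spot-void volume before the assessment | ≥ 250 mL |
| colour | 7-level urine colour chart score | ≤ 2 |

A total score of 0–1 predicts a **low** 24-h urine concentration
(optimal fluid intake); 2–4 predicts a **high** concentration
(suboptimal intake). The reference standard is the volume-weighted 24-h
urine specific gravity,

USG₂₄ = Σᵢ (USGᵢ · Vᵢ) / Σᵢ Vᵢ,

over all voids in the 24-h window ending at the assessment,
dichotomised either at the *low* cut-off (low iff USG ≤ 1.012, the
"optimal fluid intake" threshold) or at the conventional underhydration
cut-off (high iff USG ≥ 1.020). Morning and afternoon assessments use
two intentionally overlapping 24-h windows of one 32-h void stream.

The package provides:

- `synthgen` — a synthetic-cohort generator (32-h void streams, fluid
  diaries, self-assessments) with configurable coupling between the
  latent 24-h USG and the four markers;
- `features` — windowing, weighted USG, void frequency/volume, thirst
  VAS percentage, body-mass change, void-duration flag;
- `scoring` — the 4-item rule and the USG reference labels;
- `diagnostics` — contingency tables, sensitivity/specificity/accuracy,
  rank (Mann–Whitney) AUC with tie handling, rank-biserial and Cramér's
  V effect sizes, Spearman correlation, Wilcoxon/Mann–Whitney/χ²/Fisher
  tests;
- `selection` — forward–backward stepwise logistic screening (entry
  p ≤ 0.10, retention p < 0.05) with covariate adjustment and
  separation handling;
- a thin CLI (`hydrascore simulate|features|score|evaluate|select|run-all`)
  and narrative scripts under `examples/`.

## Worked example

```python
from hydrascore import (GeneratorConfig, build_features, classify_cohort,
                        evaluate_model, generate_cohort)

cohort = generate_cohort(GeneratorConfig(n_participants=300, seed=8))
features = build_features(cohort.voids, cohort.assessments)
classified, _ = classify_cohort(features, usg_cutoff="low")
for session in ("morning", "afternoon"):
    m = evaluate_model(classified[classified["session"] == session])["model"]
    print(f"{session:9s}: AUC {m.auc:.2f} ({m.band}), sens {m.sensitivity}%, "
          f"spec {m.specificity}%, acc {m.accuracy}%")
```

prints

```
morning  : AUC 0.86 (good), sens 81.7%, spec 74.1%, acc 77.0%
afternoon: AUC 0.89 (good), sens 85.1%, spec 79.0%, acc 81.3%
```

The AUC is the probability that a randomly chosen high-USG participant
has a higher 4-item score than a randomly chosen low-USG participant
(ties counted half); sensitivity is the share of high-USG participants
the instrument flags, specificity the share of low-USG participants it
clears. The afternoon assessment is typically the more accurate one,
because the generator's morning spot sample accumulates overnight and
tracks the 24-h pool less faithfully — the same ordering reported for
the instrument's development cohort. See `examples/` for simulation,
windowing, selection and published-count walk-throughs, and
`docs/methods.md` for the model of the generator and all statistical
conventions.

The same chain is available from the shell:

```sh
hydrascore run-all --out run1 --seed 8 --cutoff low
```

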