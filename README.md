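# nhqi — risk-adjusted nursing-home quality indicators

Nursing-home quality indicators (QIs) are facility-level fractions: residents
triggering an outcome (pressure ulcers, worsening pain, ADL decline, ...)
over residents at risk. Raw QI rates are poor quality signals because
facilities admit very different residents: a home full of frail, cognitively
impaired residents will show high adverse-event rates however good its care.
`nhqi` implements a third-generation risk-adjustment algorithm for such
indicators, the second-generation comparator it improves on, and the
reliability/validity evaluation framework used to judge both — exercisable
end to end on synthetic assessment panels with known ground truth.

The package is aimed at health-services researchers and quality-measurement
methodologists working with MDS-style resident-assessment panels (one row
per resident-quarter).

## The adjustment algorithm

For one QI, a *standard population* (a large reference panel) fixes every
adjustment quantity:

1. **Restriction.** Residents whose outcomes do not reflect the facility's
   care (e.g. new admissions) are excluded before counting; each QI adds its
   own exclusion rules.
2. **Stratification.** Residents are sorted into low / middle / high risk
   strata at the 20th and 80th percentiles (p20, p80) of a continuous
   stratifier (e.g. an ADL summary scale), thresholds taken from the
   standard population.
3. **Indirect standardization within strata.** Per stratum *s*, a logistic
   regression of the outcome on case-mix covariates, fitted in the standard
   population, gives each facility an expected rate
   E_s = mean_i expit(α_s + β_s·x_i) over its stratum-s denominator. The
   observed rate O_s is compared with E_s as a difference of log odds,
   re-anchored at the standard population's stratum rate P_s:

       A_s = expit( logit(O_s) − logit(E_s) + logit(P_s) )

   (an observed rate of exactly 0 or 1 is first corrected to
   (n + ½)/(d + 1)).
4. **Direct standardization.** The stratum scores are combined with fixed
   standard-population denominator-share weights w_s into one composite:

       gen3 = Σ_s w̃_s · A_s

   with w̃ renormalized over the facility's non-empty strata. The
   second-generation comparator (`gen2`) is step 3 alone, unstratified.

Inference is relative: the quality signal is `gen3 − P_std`, the composite's
departure from the overall standard rate — not the absolute score.

**Evaluation.** Reliability is the quarter-to-quarter Pearson
autocorrelation of facility scores. Validity regresses a QI's adjusted
facility scores on orthogonal principal components of external care-process
measures — 10 from *preventive* elements (anticipatory care) and 10 from
*responsive* elements (reactions to identified problems), single-imputed by
chained regression with hot-deck replacement. The multiple correlations R1
(preventive model) and R3 (combined, 20 components) classify each QI:
Level I if R1 ≥ 0.45 or R3 > 0.55; else Level II if R1 ∈ [0.30, 0.45) or
R3 ∈ (0.40, 0.55]; else Level III.

## Worked example

```python
import nhqi

config = nhqi.SimulationConfig(n_facilities=60, residents_per_facility=80, seed=42)
panel, truth = nhqi.simulate_panel(config)

qi = next(q for q in nhqi.load_default_qi_set() if q.qi_id == "PRU01")
results = nhqi.RiskAdjustmentModel(panel, qi).fit()   # standard-population artifact
print(results.summary())
```

```
Risk adjustment artifact: QI PRU01
==============================================
Strata thresholds (stratifier p20/p80): -0.8355 / 0.8193
Standard-population rate P_std: 0.2504

     stratum   weight      P_s  intercept  status
         low   0.1843   0.1316    -1.1995  converged
      middle   0.6314   0.2387    -1.3526  converged
        high   0.1843   0.4089    -1.3188  converged
    unstrat.   1.0000   0.2504    -1.3183  converged
...
```

The artifact holds everything fixed from the reference panel: thresholds
(residents below −0.84 on the ADL scale are low risk), the 18/63/18%
denominator-share weights, the anchor rates P_s (13% of low-risk residents
have a pressure ulcer versus 41% of high-risk ones), and per-stratum
logistic coefficients. Scoring a panel then gives:

```python
scores = results.score(panel)
print(scores[["facility_id", "quarter", "denominator", "raw_rate",
              "gen2_score", "gen3_score", "relative_quality"]].head(4))
```

```
facility_id  quarter  denominator  raw_rate  gen2_score  gen3_score  relative_quality
      F0000        1           73    0.0685      0.1610      0.1903           -0.0601
      F0000        2           58    0.1552      0.2984      0.3622            0.1119
      F0000        3           73    0.0685      0.1523      0.2063           -0.0441
      F0001        1           70    0.0429      0.0970      0.1038           -0.1465
```

Facility F0000's raw ulcer rate in quarter 1 (6.9%) looks excellent, but its
residents are unusually robust: given its case mix the standard model
expected an even lower rate, so its adjusted score (19.0%) sits only
6 points better than the standard population — a much more modest signal
than the raw rate suggests.

The same pipeline is available from the shell:

```bash
nhqi simulate --seed 7 --out-dir run/
nhqi fit      --panel run/panel.csv --out-dir run/models
nhqi score    --panel run/panel.csv --models run/models --seed 7 --out-dir run/
nhqi evaluate --scores run/scores.csv --elements run/elements.csv --out-dir run/
```

producing `scores.csv`, `reliability.csv` (per-QI quarter-to-quarter
autocorrelations for raw/gen2/gen3) and `validity.csv` (R1/R2/R3 and the
Level I–III classification per QI), all with provenance comment headers.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the pipeline's main outputs from scratch: it generates the
default synthetic world from the given seed, fits the fixed
standard-population artifact for every QI in the shipped library, scores
the panel (raw, gen2, gen3), and writes the score, reliability and validity
reports next to the JSON manifest.

## Layout

- `src/nhqi/definitions.py` — QI schema and the declarative rule language
- `src/nhqi/rates.py` — restriction, membership, raw facility rates
- `src/nhqi/adjustment.py` — stratification, log-odds adjustment, the
  Model/Results fitting surface
- `src/nhqi/evaluation.py` — reliability, element imputation, PCA
  components, validity models and classification
- `src/nhqi/simulate.py` — the synthetic world (facility quality effects,
  confounded case mix, Markov change outcomes, validation elements)
- `src/nhqi/pipeline.py`, `src/nhqi/cli.py`, `src/nhqi/io.py` — orchestration,
  CLI, file formats

See `docs/methods.md` for the statistical model, the synthetic world's
assumptions, and known limitations.
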