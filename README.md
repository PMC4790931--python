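# lactbias

Does the gender of a calf change how much milk its dam gives — or does it
only *look* that way because of how seasonal dairy systems measure milk?

In pastoral Spring-calving herds (New Zealand being the canonical case),
dams of bull calves calve about 2 days later than dams of heifer calves,
because male gestations run longer.  The whole herd is dried off on one
date and herd-tested on common dates, so a 2-day-later calver (i) milks two
fewer days and (ii) is tested two days earlier in her lactation.  Both
effects flow into the *interval-centering* (test-interval) estimate of
whole-lactation yield, creating an apparent "female calves mean more milk"
signal with no biology behind it.  `lactbias` implements the full analysis
chain for quantifying that artefact and its consequences for genetic
evaluation:

* **Pedigree BLUP animal models** — Henderson's mixed-model equations with
  the sparse inverse of the numerator relationship matrix **A** (built
  directly by Henderson's rules with inbreeding), REML variance components,
  and contrast standard errors from the coefficient-matrix inverse.
  The models are, for cow-lactation yield *Y* and lactation length *LL*:

  | model | formula | use |
  |---|---|---|
  | 1 | `Y = CG + HY + A + e` | calf-gender-sequence effects on yield |
  | 2 | `LL = C + HY + A + PE + e` | gender effect on lactation length (repeatability model) |
  | 3 | `Y = LL.C + CG + HY + A + e` | yield with gender-specific length slopes |
  | 5 | `Y = LL + HY + A + e` | gender-free model for EBV comparison |

  where `CG` is the calf-gender sequence over a parity window (2³ = 8
  levels), `HY` the herd-year contemporary group, `A` the additive-genetic
  animal effect with Var(A) ∝ **A**σ²ₐ, and `PE` a permanent-environment
  effect.

* **Wood's lactation curves** `y(t) = a·t^b·exp(−c·t)` fitted per cow to
  herd-test records by nonlinear least squares, and the interval-centering
  estimator Σᵢ yᵢwᵢ whose integer weights wᵢ count the lactation days
  nearest each test.

* **The bias study** — every fitted curve is "calved" on each day of a
  44-day Spring window and again 2 days later; the weighted difference in
  interval-centred totals is the artefact, for fixed 305-day and
  herd-truncated lactations.

* **A synthetic herd generator** that reproduces the study conditions
  (multi-generation pedigree with additive + permanent-environment +
  residual variance, Wood's-curve lactations, common test dates and
  dry-off, the 2-day male gestation offset), so every stage runs — and
  parameter recovery can be verified — without any external data.

## Worked example

```bash
python analysis/01_simulate_herds.py     # writes results/data/...
python analysis/02_bias_study.py
python analysis/03_gender_models.py
python analysis/04_ebv_comparison.py
```

Output from a run (seed 20160314):

```
fixed_305: earlier calver yields +4.0 +/- 3.2 L (SD) more
truncated: earlier calver yields +26.4 +/- 5.3 L (SD) more
model 1 parity-1 contrast (F-M): +7.6 +/- 13.3 L (p=0.568) — artefact only, no true effect
model 3 slopes: F 12.63, M 12.03 L/day (difference +0.60 +/- 0.99)
model 2 lactation length: F 239.1 d, M 237.4 d, gap 1.72 +/- 0.20 d
dams:  Pearson 0.9998, Spearman 0.9997, top-100 overlap 97/100, largest rank drop 11
sires: Pearson 0.9999, Spearman 0.9991, top-30 overlap 30/30, largest rank drop 2
```

Reading it: with **no** true gender effect simulated, the 2-day gestation
offset alone makes an earlier-calving (female-calf) dam's interval-centred
total ~26 L higher once herd truncation is in play; the animal model sees a
positive female−male contrast (here +7.6 ± 13.3 L at 5 000 cows — the SE
shows why the original-scale cohorts of 10⁵ cows are needed to resolve a
~25 L artefact); the repeatability model recovers the ~2-day length gap;
the yield-on-length slope sits at the late-lactation daily yield
(~12–13 L/d); and swapping calf-gender terms in or out of the evaluation
model leaves EBV rankings essentially untouched — correlations of 1.00 at
two decimals for cows and sires alike.

## Layout

```
src/lactbias/        io_formats, pedigree, lactation_yield,
                     bias_simulation, mixed_models, synthetic_data,
                     gender_analysis
analysis/            numbered narrative drivers (simulate → bias study →
                     gender models → EBV comparison)
scripts/acceptance.py
docs/methods.md      model and generator documentation
tests/               pytest suite (unit, property, acceptance)
```
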