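# Methods

## The mechanism under study

In a seasonal-calving pastoral system all cows in a herd are dried off on a
single date and herd-tested on common dates.  Gestations carrying bull
calves run ~2 days longer than those carrying heifer calves, so dams of
males calve ~2 days later inside the Spring window.  Relative to a
female-calf dam, a male-calf dam therefore (a) milks ~2 fewer days and
(b) is ~2 days earlier in lactation on every test day.  Whole-lactation
yield is not observed; it is estimated from 4–10 test-day yields by the
test-interval ("interval-centering") method, so both (a) and (b) leak into
the recorded phenotype.  The package's pipeline quantifies this leak and
asks whether modelling calf gender changes breeding-value rankings.

## Models

All mixed models are solved through Henderson's mixed-model equations in
lambda form, `C(λ) = W'W + Σ_u λ_u K_u` with `λ_u = σ²ₑ/σ²_u`, where `K` is
the sparse A-inverse for the animal term and identity for the
permanent-environment (PE) term.  Fixed effects use a reference-level
constraint (first factor full, later factors drop their first level); only
estimable contrasts are reported, and these are invariant to that choice
(verified by test).  Contrast variances are `σ²ₑ·L'C⁻¹L` via one sparse
solve per contrast; t-tests use residual df `n − rank(X)`, comparison-wise
α = 0.05, with no multiplicity correction.  The compact letter display over
sequence levels uses the insert-and-absorb algorithm on the pairwise
significance matrix.

**A-inverse.**  Built directly by Henderson's rules with inbreeding:
Mendelian-sampling variance `d_i = 1 − 0.25(1+F_s)[s] − 0.25(1+F_d)[d]`,
contributions `1/d_i`, `−1/(2d_i)`, `1/(4d_i)`.  Inbreeding coefficients
come from memoised recursive kinship on the tabular definition (exact, and
fast at the pedigree depths used here); `log|A| = Σ log d_i` is kept for
the restricted likelihood.  Inbreeding is always on (switchable), since
the rules are only exact with it.

**REML.**  The restricted likelihood is evaluated through the MME:
`−2l_R = (n−p)ln σ²ₑ − Σ_u q_u ln λ_u + ln|A| + ln|C(λ)| + y'Py`, with
`ln|C|` from a sparse LU factorisation (symmetric minimum-degree ordering —
crucial: it keeps fill-in near the A-inverse pattern) and
`y'Py = (y'y − θ̂'W'y)/σ²ₑ`.  Two maximisers:

* **EM** — the classic update (`σ²_u ← (û'Kû + σ²ₑ·tr(K C^{uu}))/q_u`,
  `σ²ₑ ← (y'y − θ̂'W'y)/(n−p)`), needing the dense inverse of C each
  round; restricted to systems ≤ ~1500 equations.  Its likelihood is
  non-decreasing (tested) and its fixed point coincides with the direct
  optimum, but convergence is slow on ridge-shaped surfaces.
* **Direct** (default for large systems) — the residual variance is
  profiled out analytically and the likelihood is maximised over
  `log(σ²_u/σ²ₑ)` with bounded Brent (one ratio) or Nelder–Mead (two);
  each evaluation is one sparse factorisation.  On the balanced paternal
  half-sib design it reproduces the ANOVA closed form to 4 significant
  figures.

Tolerance 1e-6 on the relative parameter change (EM) or the log-ratio
(direct); boundary estimates (variance ratios < ~1e-5) are legitimate
outputs, not errors.  Per-fit likelihood evaluations are O(20) for one
random term, so 5 000-cow animal-model fits take ~1–2 s.

**Interval centering.**  Weights are day counts between successive test
midpoints; the boundary day `⌊(t_i+t_{i+1})/2⌋` goes to the earlier test
(any fixed tie rule preserves Σw = L); the first test's span extends back
to day 1 and the last forward to dry-off.  The estimator is exact for
constant daily yield and agrees with the day-by-day sum within 1 % at six
tests for realistic Wood's parameters when the first test falls near day
15; a first test at day 25–30 can push the error to ~1.2–1.6 % for steep
curves, which is why the test calendar is an explicit, reported choice.

**Wood's fitting.**  `scipy.optimize.curve_fit` on the natural scale with
starting values from the log-linearised regression
`ln y = ln a + b ln t − c t`; bounds keep `a > 0`, `c ≥ 0`.
Non-convergence sets a flag rather than discarding the cow.

**Bias study.**  Each fitted curve is evaluated at the common test dates
for calving day d (female proxy) and d + shift (male proxy), interval
centred, differenced, then averaged over calving days with the herd's
empirical calving-date proportions as weights — in both scenarios.  The
fixed-305 scenario gives both proxies 305-day lactations (pure
test-placement bias); the truncated scenario dries both off at
`earliest calving + 305` days, so the shifted proxy also loses tail days.
The "±" dispersion is reported as the SD over per-cow weighted differences
(SE is also computed).  With flat curves the truncated difference is
exactly `shift × a` per cow and the fixed difference exactly zero (tested).

## The synthetic generator

The generator emulates the study conditions rather than any one dataset:
a 44-day Spring calving spread (uniform by default; a front-loaded Beta
option exists), a 2-day male gestation offset, common herd-test dates, a
common dry-off 260 days after season start (giving ~215–260-day
lactations), 5–9 in-lactation tests per cow, and a 2–4-generation pedigree
bred with a small per-generation sire team as under AI.  Breeding values
follow the additive model (founders ~ N(0, σ²ₐ); offspring = parent mean +
Mendelian sampling shrunk by parental inbreeding).

Yield-scale parameters (chosen once, from what is typical of first-parity
pasture-fed Holstein Friesians): Wood's means a = 15 L/d, b = 0.15,
c = 0.004 /d (peak ≈ 22 L/d near day 40, ≈ 13 L/d at day 235, 305-day
total ≈ 4 800 L), between-cow SDs (2, 0.03, 0.0008); heritability 0.30 and
PE fraction 0.15 around a residual variance of 120 000 L², i.e. a
phenotypic SD near 470 L; herd-year SD 150 L.  Calving dates carry small
genetic (SD 2 d) and permanent (SD 3 d) cow components so the
lactation-length repeatability model has something to estimate.

Animal-level effects enter as a uniform level shift of daily yield
(`η/L` per day), so the exact lactation total is the curve total plus η.
By default each cow's curve is additionally **centred**: her exact total
equals the population-mean curve's total over her own lactation length
plus η.  Curve shapes still differ between cows — Wood's fitting and the
bias study see realistic dispersion — but total-yield variance stays
governed by the configured components.  Without centring, curve-parameter
dispersion adds ~500 L of permanent between-cow SD and the realised
heritability falls well below its configured value.  `curve_variation="raw"`
disables this.

The recorded whole-lactation yield is, by default, the interval-centred
total of the cow's own test-day series — that is what lets the gestation
artefact propagate into the phenotype file exactly as it does in national
recording.  `yield_method="exact"` records the daily sum instead; the
parameter-recovery experiments use it (with a zero gestation offset) so the
injected effect is the only gender signal.

**What the generator does not emulate:** culling and selection between
parities, twinning, abortion, dystocia, seasonal feed curves, heterogeneous
herd sizes or test schedules, and any true hormonal gender effect unless
injected.  Passing tests therefore demonstrate that the *methods* behave
correctly under the stated mechanism, not that real-herd effect sizes are
reproduced; quantities that depend on real curve shapes (notably the
fixed-length test-placement bias, which is small and calendar-sensitive
for our smooth synthetic curves) can differ from field estimates even when
the truncation-driven component (~2 days × late-lactation daily yield
≈ 25 L) matches well.

## Problem sizes and design choices

* Acceptance-level experiments use 5 000-cow herds (25 herds × 200) —
  enough to estimate h² to ±0.02 and a parity contrast to ±13 L — and a
  20 000-cow herd where the ~25 L artefact itself must clear significance
  (SE ≈ 7 L).  These sizes are the package's chosen compromise between
  Monte-Carlo error and fit time; all conclusions are scale-stable.
* Parity windows: sequences over parities 1–3 for lactation-1/2 analyses;
  the machinery accepts 4-length windows (2⁴ = 16 levels) and a window
  origin for parities-2–4 analyses.
* Sires are defined as pedigree animals with ≥1 phenotyped daughter; dams
  as cows with own records.  Top-k comparisons use the gender-free model's
  ranking as the base.
* Degenerate inputs: cows with <4 distinct test days cannot be interval
  centred or Wood-fitted (error); empty factor levels never arise because
  levels are indexed from the data; zero variance components are reported
  at the boundary and flagged by the convergence field.

## Known limitations

* EM-REML is quadratic-memory (dense C inverse) and deliberately capped at
  small systems; large fits use the direct maximiser, which does not
  expose a monotone iteration trace.
* Contrast SEs treat estimated variance components as known, as is
  standard for BLUP software; at the problem sizes used the REML
  uncertainty is negligible relative to the contrast SEs.
* The first/last interval convention (extend to day 1 and to dry-off) is
  one of several in field use; alternatives (e.g. capping the first
  interval) would shift totals by a few litres and are not implemented.
* The Model-3 sequence contrast is reported at the mean lactation length
  (sequence contrast plus `L̄ × (slope_F − slope_M)`); the raw sequence
  contrast alone is the effect extrapolated to zero days in milk and has a
  correspondingly inflated SE.
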