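# Methods

## The model

`hmgb1smc` implements a reaction-network model of proliferation signaling
initiated by extracellular HMGB1.  A single lumped receptor species (RAGE,
standing in for RAGE and the toll-like receptors) is activated by HMGB1 and
drives three coupled pathways:

* **p53–MDM2** — PI3K → PIP3 → AKT → MDM2 ⊣ p53 → MDM2, the delayed
  negative-feedback oscillator, with the positive loop p53 → PTEN ⊣ PIP3.
  MDM2 is synthesized through an explicit mRNA transcript (`mdm2`), and only
  the phosphorylated form MDM2_p degrades p53 (AKT_p performs the
  phosphorylation, so receptor input controls how strongly p53 is held
  down).
* **RAS–ERK** — RAS → RAF → MEK → ERK → CyclinD (and Myc), a
  three-stage push–pull kinase cascade.
* **Rb–E2F** — CyclinD/Myc/CyclinE phosphorylate Rb in the Rb–E2F complex
  (RE), releasing E2F, which transcribes CyclinE and itself; CyclinE closes
  the positive feedback.

Crosstalk: RAS also activates PI3K; E2F induces ARF, which degrades MDM2;
p53 induces P21 (lumping the P21 and FBXW7 contributions), which degrades
CyclinD/E; INK4A degrades CyclinD.

The network has **31 species and 59 reactions**.  The totals of active +
inactive forms of RAGE, PI3K, PIP, AKT, RAS, RAF, MEK and ERK are conserved
(8 relations), leaving 23 independent dynamical variables.  Protein
synthesis of PTEN, MDM2 (via its transcript), CyclinD, Myc, E2F and CyclinE
uses Hill rate laws `basal + vmax·R^n/(K^n + R^n)`; every other reaction is
elementary mass action.  Units are minutes and molecule counts throughout.

Reactions whose existence is structurally implied but not individually
documented anywhere are: basal (receptor-independent) AKT phosphorylation,
basal PIP3 dephosphorylation, slow HMGB1 clearance, explicit synthesis and
decay for ARF/P21/INK4A/Rb, ARF-driven degradation of both MDM2 forms,
INK4A-driven CyclinD loss, and CyclinD/E-driven removal of free Rb.

## Simulation engines

* **SSA** — Gillespie's direct method, exact: exponential waiting times with
  the total propensity as rate, next reaction proportional to propensity.
  The kernel (numba-compiled) updates propensities incrementally through the
  reaction dependency graph and stores traces as an event log (initial
  state, event times, reaction indices); species time series are
  reconstructed on demand by cumulative sums.  Bimolecular self-reactions
  use the combinatorial propensity `k·c(c−1)/2`.  A fixed seed reproduces
  the identical event sequence.
* **ODE** — the same rate functions in continuous form (`k·c²/2` for
  homodimers), integrated with LSODA at `rtol 1e-6`, `atol 1e-3` over all
  31 species; the conservation relations are verified post hoc (they hold to
  machine precision because every reaction conserves them structurally).
  Solutions are sampled on a 1-minute grid, matching the minute-valued
  bounds of the temporal properties.

Traces are timed state sequences with piecewise-constant semantics; SSA
traces are event-resolved so that temporal-logic checking is exact, never
interpolated.

## BLTL checking

Formulas follow the grammar `AP | φ∧φ | φ∨φ | ¬φ | φ U^t φ` with atomic
propositions comparing arithmetic expressions over species counts;
`F^t φ ≡ true U^t φ` and `G^t φ ≡ ¬F^t¬φ` are stored as their definitions.
The bounded until at step k requires an i with cumulative sojourn of states
k..k+i−1 **at most** t (inclusive bound), φ₂ at k+i and φ₁ before.  A trace
must be at least as long as the formula's required horizon (the nesting sum
of bounds); shorter traces raise an error rather than defaulting to false.
Evaluation is vectorized: every subformula is evaluated at all trace indices
using O(n) sliding-window scans, making 10⁷-event traces checkable in
seconds; a brute-force recursive evaluator in the test suite serves as the
independent oracle on small traces.  Equality atoms compare exactly, which
is sharp on continuous ODE values (none of the stock properties use `=`).

## Statistical model checking

Whether the stochastic model satisfies a formula with probability ≥ θ is
decided by Bayesian sequential hypothesis testing: each simulated trace is
one Bernoulli outcome, and after each sample the Bayes factor of
H0: p ≥ θ against H1: p < θ is computed in closed form through the
regularized incomplete Beta function (Beta(α, β) prior; default uniform
with equal hypothesis priors).  Sampling stops when the Bayes factor
exceeds T (accept) or falls below 1/T (reject); ties continue; the error
probability is bounded by 1/T.  With θ = 0.9 and T = 1000 under the uniform
prior, acceptance requires exactly 65 consecutive satisfying traces and
rejection exactly 3 consecutive violating ones.  A sample cap (default
10⁵) makes the tool total, returning an explicit "undecided".  Per-sample
seeds are `base_seed + index` and are logged, so any individual trace can
be replayed.

## Parameters

Most rate constants of this pathway have never been measured individually.
The shipped defaults (`hmgb1smc.hmgb1.DEFAULT_PARAMETERS`) are a
calibration: a self-consistent set chosen once so that the default network
reproduces, simultaneously,

* a p53 first peak near 5.4×10⁴ molecules within 100 min at the reference
  dose (HMGB1 = 10³), rising toward ~7×10⁴ as the dose falls to 10, each
  followed by a collapse below 4×10³ within the next 100 min;
* damped deterministic p53/MDM2_p oscillations settling near 2.4×10⁴
  (staying below 3.3×10⁴ from ~400 min onward) while the stochastic
  dynamics keep quasi-cycling past the G1-S point;
* half-maximal PI3K activation within 20 min only at high dose (≥10⁵);
* CyclinE peaking near the G1-S transition (~600 min) and crossing the
  9×10² threshold before 600 min only under HMGB1 overexpression, with the
  analogous CyclinD behavior under RAS-deactivation changes;
* the qualitative dose and mutation sweep directions (p53 repressed by
  HMGB1/AKT with a plateau above 10⁵ ligand molecules; CyclinD/E and E2F
  promoted by HMGB1; CyclinD/E lowered by d_RAS and d_P21, p53 raised and
  MDM2_p lowered by d_ARF).

The three mutation knobs keep their conventional names: `d_RAS` (RAS
deactivation; default 10⁻²), `d_ARF` (ARF-driven MDM2 degradation) and
`d_P21` (P21-driven Cyclin degradation).  Initial counts follow the
reference table (RAGE 10³; PI3K, PIP2, AKT, RE 10⁵; MDM2 10⁴; MDM2_p, p53
2×10⁴; RAS, RAF, MEK, ERK 10⁴; everything else 0; HMGB1 set per
experiment).

Mechanistically notable calibration choices: the p53 rise outruns its own
negative feedback because the mdm2 transcript (τ ≈ 34 min) and the AKT_p
activation ramp delay the MDM2_p surge past the first peak — the surge then
overshoots and produces the deep first trough; the dose dependence of the
first peak comes from how fast that AKT_p ramp arrives (PI3K/PIP3 kinetics
saturate between doses of 10² and 10³, and a saturating RAS → PI3K
crosstalk shapes the intermediate-dose response); Hill coefficients were
allowed to be large (n ≈ 8.7 on mdm2 transcription) to keep the transcription
switch sharp relative to the steady state.

## Known limitations

* One of the nineteen published verification rows is not reproduced by this
  calibration: the first-peak threshold test at HMGB1 = 10², a = 6.0 sits
  on the wrong side of its decision boundary (our peak distribution there
  is ~6.2×10⁴ ± 1×10³, so the "eventually ≥ 6×10⁴" clause holds with
  probability ≈ 0.98 rather than ≈ 0.27).  Every receptor/PI3K/AKT variant
  we explored that fixed this row instead broke the (always-quoted)
  first-peak property at the reference dose, so the calibration keeps the
  latter.  The suite reports the row honestly.
* Deterministic damping is a property of the default parameters, not of the
  engine; other parameter sets can sustain deterministic oscillations.
* The published per-row sample counts are not comparable: they depend on an
  unstated prior, and with the uniform prior the same verdicts simply take
  different sample numbers.
* Scaled-down verification: the full T = 1000 test needs 65 consecutive
  satisfying traces per accepted row (tens of CPU-minutes per row at
  10⁷-event traces), so the stock suite runs (`property_suite`,
  `scripts/acceptance.py`, the acceptance tests) use T = 10 with a sample
  cap of 50 and shared trace pools for same-condition rows.  The error
  bound per row is then 0.1, which is why the suite check asserts a
  near-complete, not perfect, verdict agreement.
* The model is a caricature of real signaling: one lumped receptor, no
  compartments, no NF-κB/TNF/autophagy arms, no explicit transcripts except
  mdm2, and molecule counts tuned for qualitative agreement only.  Passing
  tests demonstrate internal consistency with the published behavioral
  pattern, not quantitative agreement with cell biology.

## Numerical choices

SSA propensity totals are refreshed every 2¹⁴ events to bound float drift;
an apparent zero total propensity is confirmed by a full recomputation
before a trace is declared absorbed.  ODE trajectories are clipped at zero
(solver undershoot ~1e-8 of a molecule).  The oscillation-persistence
statistic counts p53 peaks after 600 min with prominence at least 10% of
the pre-600-min peak-to-trough amplitude on a 1-minute grid smoothed with
an 11-minute moving average (so SSA shot noise does not register).
Problem sizes in the stock experiments (replicate counts, sample caps,
sweep grids) follow the published study design where stated — ten
replicates per stochastic sweep value, θ = 0.9 — and otherwise were chosen
once as the package's own defaults.

Sweep statistics: p53 responses to HMGB1 dose and to AKT abundance are read
as the maximum during G1 ([0, 600] min, the same statistic for both knobs);
Cyclin/E2F dose responses and the d_RAS/d_P21 responses are read at the
G1-S point; the d_ARF readouts average over ±60 min around G1-S because the
damped p53/MDM2_p oscillation still rings there and a point readout
aliases its phase.  Oscillation persistence is a distributional property:
the stock checks require at least two qualifying post-600-min p53 peaks in
a majority of three replicate traces (across seeds the count typically
falls between 3 and 9, with occasional single-peak traces).
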