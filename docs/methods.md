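# Methods

## Generative observer

A trial presents one of two stimuli s ∈ {−1, +1} with equal probability.
Internal evidence is drawn as e ~ N(s·d′/2, 1) and the first-order decision
is a threshold at criterion c (default 0, the unbiased optimum), so accuracy
is Φ(d′/2). All evidence-scale quantities are expressed in units of the
evidence SD; d′ = 2·Φ⁻¹(0.71) ≈ 1.107 by default, the sensitivity a
1-up/2-down staircase enforces.

Two corruptions of e model two distinct imperfections:

- **Proxy noise.** e_proxy = e + N(0, σ_proxy), thresholded at 0, stands in
  for a covert decision inferred from motor tracking. Adding noise to the
  *evidence* (rather than flipping the binary response) preserves the data's
  structure: trials near the decision bound — the low-confidence trials —
  are the ones most likely to flip. The default σ_proxy = 1.6 evidence-SDs
  is calibrated so that proxy and actual decisions agree on ~70% of trials
  at d′ = 1.107 (closed form: E[Φ(|e|/σ_proxy)] = 0.699). Note the
  calibration anchor is the *correspondence*, not the noise value itself: a
  0.8-SD noise on a half-unit evidence scale and a 1.6-SD noise on the unit
  scale are the same observer; only the ratio of noise SD to evidence SD is
  identified, and 1.6 is the ratio that produces the ~70% agreement the
  design analysis assumes (with σ_noise/σ_e = 0.8 the minimum possible
  agreement is 78.5%, at d′ = 0).

- **Metacognitive noise.** e_degraded = e + N(0, mσ); confidence is
  |e_degraded|, the distance of the corrupted decision variable from the
  criterion. mσ = 0 makes confidence a sufficient statistic for the type-2
  task (fitted M-ratio ≈ 1); larger mσ drives M-ratio toward 0. M-ratios
  above 1 are produced by swapping the two copies: the first-order decision
  is then taken on e_degraded while confidence reads |e|, making the
  second-order distributions sharper than the first-order ones. At the
  boundary (target exactly 1) the no-swap branch is used; the two coincide
  there. Decisions *and* proxies are always derived from whichever copy the
  first-order stage actually used, so proxy correspondence is governed by
  σ_proxy alone in both regimes.

The mσ → M-ratio mapping has no useful closed form once confidence is
scaled, binned and fit, so `calibrate_meta_noise` measures it by simulation
(the full measurement stack at 10⁴–10⁵ trials per grid point) and
`meta_sigma_for_m_ratio` inverts the monotone empirical curve around an
analytic first guess (mσ ≈ √(1/m²−1) below 1, √(m²−1) above, from variance
inflation). The swap branch saturates near M-ratio ≈ 1.6 at this d′ and
4 confidence bins — very high targets map to the closest achievable noise
level. This is a property of the generative mechanism itself (the same
mechanism, calibrated empirically, yields only a bounded M-ratio range),
and the power grid's ordering in the *target* values is unaffected.

## Synthetic task generator

Emulates a 5-s duration-discrimination trial: four intervals alternate two
colors, each color's two intervals summing to 2.5 ± Δ/2 s (Δ = the
staircase level, so the color totals differ by Δ), each interval half its
color total, first color randomized. Four interleaved conditions cross
continuous report (CR±) with overt response (R±); confidence is rated in
all four. Defaults: 23 subjects, 60 trials/condition (240 total), two
25-trial pre-experiment staircases per subject whose final levels carry
into the main blocks, and two independent 1-up/2-down staircases (one per
CR condition) updated only on R+ trials.

One evidence draw e = s·d′/2 + η per trial drives everything, with
d′ = k_sensitivity·Δ (linear psychometric link; only behavior near
threshold matters). From it:

- **Decision/accuracy**: sign(e); the staircase holds accuracy near
  √0.5 ≈ 70.7%.
- **RT** (R+ only): rt_base − rt_slope·|e| + N(0, rt_sd), floored at
  0.2 s. Because both RT and confidence are monotone in |e|, the negative
  RT–confidence correlation emerges without an accumulator model.
- **Confidence**: conf_base + conf_scale·|e + N(0, conf_noise_sd)|, plus
  cr_conf_boost (default 4 points on the 0–100 scale) in CR+ conditions —
  continuous report raises mean confidence without changing accuracy —
  clipped to [0, 100]. Higher = more sure (the scale's orientation is a
  package convention).
- **Continuous-report trace** (CR+ only): the ideal trace presses the key
  of the currently shown color; each tracked switch is delayed by a motor
  lag N(0.3, 0.25²) s, whole segments lapse to the wrong key with
  probability 0.08, and each switch is additionally shifted by
  percept_coupling·η (default 0.08 s per unit evidence noise) in the
  direction that lengthens the key matching sign(η). The coupling is what
  makes the longest-pressed key informative about the *decision* over and
  above the stimulus — without it the proxy would be conditionally
  independent of the response given the stimulus, and the
  stimulus+proxy vs stimulus-only model comparison would be null.

Per-subject heterogeneity is a lognormal (σ = 0.2) multiplicative jitter
on k_sensitivity and conf_noise_sd, giving realistic between-subject
accuracy SDs (~3–4 pp).

Trace-noise defaults (lag SD 0.25 s, lapse 0.08, coupling 0.08) were
calibrated in a single design pass so the default session reproduces the
target behavioral statistics: ~65% group-mean proxy/response
correspondence with ~6 pp between-subject SD, alongside ~71% staircased
accuracy. What the generator does **not** emulate: serial dependencies
between trials, confidence leak, post-decisional evidence accumulation,
RT distributions' heavy right tails, or any perceptual learning — so
passing tests show the *pipeline* behaves correctly under the stated
generative assumptions, not that real data obey them.

## Measurement stack

- **Scaling**: per subject, ratings are min-max scaled to [0, 1]
  (subtract the individual minimum, divide by the range), preserving
  within-subject ordering and condition differences. All-equal ratings are
  degenerate: mapped to 0.5 and flagged (kept in mean-confidence analyses,
  excluded from binned type-2 fits).
- **Binning**: four equal-width half-open bins on [0, 1] (equal-width
  because the scaled range is fixed; quantile binning would re-introduce
  subject-specific bin edges).
- **meta-d′ MLE**: type-1 d′ and criterion come from the marginal counts
  under the equal-variance Gaussian model; meta-d′ and 2×(n_bins−1)
  type-2 criteria maximize the multinomial likelihood of the
  response-conditional confidence counts for a meta-observer whose type-1
  criterion is rescaled to keep c′ = c/d′ constant. Criteria are
  parametrized as positive increments outward from the meta-criterion
  (ordering enforced by construction) and optimized by Nelder–Mead from
  two starts (meta-d′ = d′ and d′/2). Every cell is padded with
  1/(2·n_bins) before fitting to avoid 0/1 rates at 60–80 trials. This is
  a per-subject maximum-likelihood estimator; hierarchical Bayesian
  variants estimate the same subject-level quantity but need an MCMC
  stack and can converge poorly at low trial counts, so group summaries
  here are plain statistics over subject fits.
- **Sensitivity regression**: per subject, logistic
  accuracy ~ confidence × condition with confidence standardized within
  subject (making the fit invariant to subject-wise affine confidence
  transforms) and conditions coded ±0.5; then one-sample t tests across
  subjects on each coefficient. Raw (unbinned) confidence enters the
  regressions while binned confidence feeds meta-d′ — the two routes are
  deliberately not harmonized. Subjects with degenerate inputs or
  (quasi-)separated fits (|coef| > 15) are dropped with a warning; fewer
  than 5 usable subjects is an error.

## Power grid

Each cell fixes a pair of target M-ratios; mσ values come from the
empirical calibration (cached per distinct target). Per experiment:
23 subjects × 80 trials × 2 conditions, fit twice — scoring accuracy
against actual decisions and against proxy decisions — and the interaction
term's group-level p value is compared to α = 0.05 (two-sided; a standard
frequentist operationalization of "significant effect"). Power is the
fraction of n_experiments (default 250) with p < α; experiments that
cannot be fit are excluded and counted, and cells with > 20% failures are
flagged. Each cell draws from an independent stream keyed by (seed, cell),
so any subset of cells is bit-reproducible regardless of evaluation order.
Diagonal cells (equal M-ratios) estimate the realized type-I error.

The default grid spans M-ratio 0.2–2.0 per axis (the empirically relevant
range; subject-level estimates in this kind of task rarely exceed ~1.1).
A full 10 × 10 grid at 250 reps costs roughly 100 × 20 s ≈ 35 min on one
CPU; the test suite and the CLI examples therefore exercise representative
cells (diagonal, near-diagonal, far off-diagonal) at full reps, which is
sufficient for the operating characteristics of interest: nominal type-I
error on the diagonal, power increasing in |ΔM-ratio|, proxy-based power
at or below response-based power near the diagonal, and the two analyses
coinciding far from it. Subject-level d′ is fixed across simulated
participants (jitter exists in the task generator, not the power
simulator, where it would only dilute the marginal effect under study).

## Numerical conventions

- Stimuli, responses, keys: −1/+1 (never 0/1); key 0 = no key pressed.
- Times in seconds; confidence raw in [0, 100]; evidence in SD units.
- All randomness flows through explicit `numpy.random.Generator` streams;
  no global state. Scalar boundary conventions: evidence exactly at the
  criterion maps to +1; scaled confidence exactly at a bin edge belongs to
  the upper bin; exact proxy ties break to the last-pressed key and are
  flagged.
- Exclusion rules (applied before analysis): subjects with no CR+ key
  presses, subjects with any R+ condition accuracy outside [60%, 80%],
  then R+ trials with RT < 200 ms or > 5 s.

## Known limitations

- The meta-d′ fit assumes the equal-variance Gaussian model and a
  response-balanced design; response-specific meta-d′ is out of scope.
- The swap mechanism cannot reach arbitrarily high M-ratios (saturation
  near 1.6 at default settings); targets beyond it are clamped to the
  closest achievable value.
- The two-stage sensitivity fit treats subjects as exchangeable and
  ignores within-subject coefficient uncertainty; with ≥ 20 subjects and
  ≥ 80 trials each this is close to a random-effects analysis, but at much
  smaller sizes a hierarchical model would differ.
- The generator's trace model is piecewise-constant tracking with lapses;
  it does not produce hesitations, partial presses, or drift.
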