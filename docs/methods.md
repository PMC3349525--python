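# Methods

## The estimation problem

A coupling-phase F2 population segregates for two dominant fluorescent
seed markers on the same chromosome: a green marker proximal to the
centromere and a red marker distal to it. Every seed falls in one of
four phenotype classes — yellow (both markers), green only, red only,
grey (neither) — with counts (n1, n2, n3, n4). The parameters of
interest are the recombination fraction r between the markers and, in
autotetraploids, the coefficient of double reduction α at the green
marker (the probability that a gamete carries two sister-derived copies
of a chromosomal segment, a hallmark of multivalent pairing).

The data are multinomial, so the proportional log-likelihood is

    L = Σᵢ nᵢ ln fᵢ(θ)

with the multinomial coefficient omitted throughout (it does not depend
on the parameters; all log-likelihood values reported by this package
follow this convention).

## Disomic model (diploids and allotetraploids)

Strict bivalent pairing gives the classical two-locus F2 phenotype
frequencies

    f1 = 3(1−r)²/4 + r(1−r) + r²/2,  f2 = f3 = r(2−r)/4,  f4 = (1−r)²/4

with r ∈ [0, 1/2]. Allotetraploids are treated disomically because
homoeologous pairing is excluded in the studied lines. Setting dL/dr = 0
and clearing denominators yields (1−r) times a quartic polynomial in r
with coefficients linear in the counts; `mle_disomic` extracts its real
roots in (0, 1/2) exactly (`numpy.roots`), compares the log-likelihood
at every root and at both endpoints, and returns the argmax. (The
quartic does not reduce further; in all data sets analysed here it has a
single root in the domain, which the `n_roots_in_domain` diagnostic
records.)

## Tetrasomic model (autotetraploids)

Gametes of the double-simplex autotetraploid parent fall in four
classes — carrying {green and red}, {green only}, {red only},
{neither} — with probabilities g₁..g₄ that are quadratic polynomials in
r with coefficients linear in α (r ∈ [0, 3/4], α ∈ [0, 1/4]; the wider
r range is the theoretical tetrasomic bound). Random union of gametes
gives the seed-phenotype probabilities

    f1 = g1(2−g1) + 2g2g3,  f2 = g2(g2+2g4),  f3 = g3(g3+2g4),  f4 = g4²

(a seed shows a marker iff at least one gamete carries it). Both Σgᵢ = 1
and Σfᵢ = 1 are algebraic identities, verified to 1e-12 on a dense
parameter grid.

Estimation is the two-step procedure:

1. **α from the green margin.** At r = 0 the probability that a seed
   carries the green marker is p_g(α) = (12−4α−α²)/16. Maximising the
   two-class marginal likelihood of n_g = n1+n2 vs n0 = n3+n4 gives the
   closed form α̂ = 4√(n0/n) − 2, the exact moment inversion of
   p₀(α) = (2+α)²/16 (so p₀(α̂) = n0/n to machine precision). Estimates
   outside [0, 1/4] are clamped with a boundary flag.
2. **r given α̂.** The four-class log-likelihood with α fixed at α̂ is
   maximised over r ∈ [0, 3/4]: sign changes of the analytic score
   dL/dr on a 1501-point grid are polished by Brent root-finding
   (xtol 1e-12) and compared with the endpoints.
3. **β prediction.** The double-reduction coefficient at the red marker
   is predicted as β̂ = [α̂(3−4r̂)² + 2r̂(3−2r̂)]/9; values above the
   theoretical maximum 1/4 would be flagged, not rejected (within the
   declared parameter box β never exceeds 1/4).

No joint (α, r) maximisation is offered: the two-step path is the
procedure whose published results this package reproduces, and a joint
fit would produce different numbers (see the caveat below).

## Standard errors

All SEs are Wald errors from the **observed** Fisher information,
se = √(−1/L''(θ̂)), with L'' computed by Richardson-extrapolated central
differences (base step 1e-5). Observed — not expected — information is
what reproduces the published diploid SE 0.0062 (expected information
gives ≈0.0063). For the tetrasomic r the curvature is of the
conditional likelihood with α held at α̂, matching the published 0.0051;
this understates the uncertainty that would flow from estimating α and
r jointly. SEs are reported as undefined at boundary estimates, never
extrapolated.

## Comparison (moment) estimator

The earlier analysis of these data equated the recombinant-phenotype
probability to the observed single-colour fraction. Two variants are
exposed: `"proportion"` returns (n2+n3)/n and reproduces the previously
published 0.154 / 0.241 / 0.205; `"printed_equation"` solves
2r − r² = 2(n2+n3)/n, the literal description of that method, and gives
0.168 / 0.280 / 0.205 instead. The proportion variant is the default
and the reproduction target; which formula the original authors
actually used cannot be determined from the published record.

Comparison log-likelihoods are evaluated at the proportion estimates
rounded to 3 decimals, the precision at which they were published; the
autotetraploid comparison row uses the tetrasomic likelihood at α = 0
(confirmed numerically: it reproduces the published −21010.0 at
r = 0.205 to 0.02).

## Numerical reproduction notes

Two published figures do not reproduce at face value:

* **Likelihood ratio 4.096.** The full-precision ratio
  exp[L(r̂) − L(0.154)] on the diploid counts is 4.1103. The published
  4.096 equals exp(1.41), the difference of the two log-likelihoods
  *after* rounding to the 2 decimals at which they are printed. The CLI
  prints both figures; `table1 --check` verifies the printed-precision
  derivation.
* **Allotetraploid comparison log-likelihood −2,559.21.** The disomic
  log-likelihood at r = 0.241 is −2559.196 (and −2559.176 at the
  unrounded proportion estimate); no candidate evaluation point yields
  −2559.21, which corresponds to r ≈ 0.24096. This looks like a
  misprint of the final digit. `table1 --check` reports it as a known
  discrepancy and exits nonzero.

## A caveat on the tetrasomic model: the margin drifts with r

The printed gamete-class polynomials have the property that the
single-locus green margin g1+g2 (hence the seed margin f1+f2) depends
on r. Genetically this should not happen — segregation at one locus
cannot depend on its linkage to another — and it contradicts the r = 0
margin p_g(α) that step 1 inverts. The effect is not small at the
fitted values: at (α, r) = (0.0676, 0.3048) the model's green-seed
margin is 0.6924 versus p_g(α̂) = 0.7328, and the model's class
probabilities (0.606, 0.087, 0.125, 0.183) sit far from the observed
proportions (0.639, 0.094, 0.111, 0.156) relative to multinomial noise
at n = 19889.

The practical consequence, exposed by the simulator: drawing data from
the full tetrasomic model at the fitted values and re-running the
two-step procedure recovers α̂ ≈ 0.22 (bias +0.155, the r-dependent
margin being mis-read as double reduction) and r̂ with bias ≈ +0.006 and
95% Wald coverage ≈ 0.75. The two-step estimates are therefore **not**
self-consistent under the model they are computed from, and the
stochastic recovery check for the tetrasomic configuration fails by
design of the procedure, not of its implementation — the corresponding
acceptance test is left failing with this analysis. (At r = 0, where
the margin identity is exact, α is recovered without bias; the disomic
recovery checks pass: |bias| < 0.005, SE within 15% of the empirical
SD, coverage within [0.90, 0.99].) This package reproduces the
published procedure faithfully and reports the inconsistency rather
than substituting a joint estimator.

## Simulator

`simulate_counts` draws one multinomial count vector of size n per
replicate from the model's phenotype distribution; replicate i uses the
counter-based substream `default_rng([seed, i])`, so results are
bit-reproducible and independent of how many replicates are requested.
It emulates multinomial class sampling only — no meiosis-level
mechanism (pairing configurations, crossover interference, viability
selection), so passing recovery checks validate the estimators under
the model's own sampling assumptions, not against real-data artefacts
such as segregation distortion from selection. `run_recovery` refits
every replicate and reports bias, empirical SD, mean reported SE,
nominal-95% Wald coverage, boundary-hit rate and failed-fit count.
Default experiment sizes (200 replicates at the study sample sizes
n = 4251 and n = 19889) resolve a bias of 0.005 and SE calibration to
well under 15%.

## Degenerate inputs and tie-breaks

Classes with zero count drop out of the likelihood; a class with
positive count and zero model probability makes that parameter point
impossible (log-likelihood −∞) rather than raising. When the score has
several roots in the domain the argmax over {roots ∪ endpoints} is
returned and the root count is reported. Count vectors with no
single-colour seeds drive r̂ to 0 with the boundary flagged and the SE
undefined. Estimates are kept at full precision internally and rounded
to 4 decimals (estimates/SEs), 2 (log-likelihoods) only for display.
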