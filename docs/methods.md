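# Methods

## The model

`rsacodon` models the divergence of a pair of aligned coding sequences as a
continuous-time Markov chain on the 61 sense codons of the standard genetic
code, with the twist that every model parameter may depend on the relative
solvent accessibility (RSA) of the encoded residue. RSA — solvent-accessible
surface area divided by the residue's maximum accessibility in an extended
Gly-X-Gly peptide — runs from 0 (buried) to 1 (exposed), and buried residues
are empirically far more conserved than exposed ones.

For a site with RSA `r`, the GY94-family instantaneous rate from codon `i`
to codon `j` (`i ≠ j`) is

    Q_ij(r) = 0                    more than one nucleotide differs
            = Π_j                  synonymous transversion
            = κ(r) Π_j             synonymous transition
            = ω(r) Π_j             nonsynonymous transversion
            = κ(r) ω(r) Π_j        nonsynonymous transition

with diagonals set so rows sum to zero; the finite-time law is
`P(r) = exp[t(r) Q(r)]`. Here Π_j is the stationary frequency of the target
codon, κ the transition/transversion rate ratio, ω = dN/dS the
nonsynonymous/synonymous rate ratio, and t the divergence time (branch
length) in the rate units of the matrix. Q is deliberately **not** rescaled
to one expected substitution per unit time: t is itself a fitted function of
r, and rescaling each bin's generator separately would redefine the time
axis bin by bin and destroy the meaning of a linear t(r). The time unit is
therefore "rate of a synonymous transversion into a codon of unit
frequency".

The MG94 family replaces (t, ω) by a synonymous rate α(r) and a
nonsynonymous rate β(r). We define it through the exact correspondence
α = t, β = t·ω: the MG94 generator equals t times the GY94 generator and is
integrated over unit time, so both families share the target-codon-frequency
(Π_j) convention. An MG94 variant built on target *nucleotide* frequencies
would give slightly different likelihoods; we use the codon-frequency form
because it makes the two families exactly nested in the all-constant case
and makes the α↔t, β↔tω correspondence an identity rather than an
approximation.

### RSA dependence

RSA is discretized into `n` evenly spaced bins on [0, 1] (default n = 20),
each represented by its mid-point r_k; intervals are half-open [a, b) with
the last bin closed at 1.0. Each parameter can be

* **constant** — one value, no RSA dependence (1 df),
* **linear** — intercept + slope · r, evaluated at the bin mid-points (2 df),
* **per-bin** — one free value per bin (n df).

Crossing three forms with three parameters gives 27 GY94 variants. Codon
frequencies Π are estimated once by F3×4 (positional nucleotide frequencies
from both sequences, product restricted to sense codons and renormalized),
held fixed during optimization, and not counted in the degrees of freedom.

## Likelihood and fitting

Sites are independent given their bin. By reversibility the pairwise
likelihood can place a stationary root at one tip: a site in bin k with
codons (i, j) contributes Π_i · P_k[i, j], so the data reduce to per-bin
tables of ordered codon-pair counts and

    lnL = Σ_k Σ_{i,j} c_k(i, j) · log(Π_i P_k[i, j]).

Sites with a gap or non-ACGT character in either codon, and sites without an
RSA value, are excluded (and counted). P_k is computed through the symmetric
eigendecomposition of diag(√Π) Q diag(√Π)⁻¹, which is exact for a
reversible generator and several-fold faster than a general dense expm; the
general `scipy.linalg.expm` route is retained in `transition_matrix` and
used as the independent cross-check in the test suite.

Optimization is bounded L-BFGS-B with seeded multi-start (default 5 starts:
one from ω = 0.2, κ = 2, t = 0.3 with zero slopes, the rest jittered ±50%).
Positivity of every evaluated parameter is enforced through the coordinate
system rather than penalties: constants and per-bin values are box-bounded
at 10⁻⁶, and a linear form is optimized as its values at the lowest and
highest *occupied* bin mid-points — a line positive at both extremes is
positive at every mid-point between them. Per-bin values are only estimated
for occupied bins; unoccupied bins carry NaN. Positivity is demanded only at
occupied mid-points, so a fitted line may extrapolate negative outside the
observed RSA range.

## Model selection and grouped fits

Models are ranked by AIC = 2 df − 2 lnL (plain AIC, no small-sample
correction). Nested pairs — forms ordered constant ⊂ linear ⊂ per-bin
parameter-wise — are compared by likelihood-ratio test against the
asymptotic χ² with the df difference; no boundary corrections are applied
because slopes are interior parameters under our parameterization.

Grouped fits address questions like "do large-core and small-core proteins
share an ω–RSA line?": one κ form and one t form are shared across all
groups while each group gets a linear ω line, with optional ties on the
intercepts and/or slopes (any partition of groups per coefficient, which
covers shared-intercept tests and factorial designs such as expression ×
core size with the slope tied to one factor). Under a tie the endpoint
reparameterization is unavailable, so grouped fits use (intercept, slope)
coordinates and return a large finite penalty for iterates that push ω
non-positive at an occupied mid-point; with realistic positive-ω data the
optimum is interior and the penalty region is never visited at convergence.
When an LRT compares two grouped designs, all parameters are refit under
the constraint (not just the tied coefficient held at the free fit's
value).

## Derived dN and dS

dN and dS are derived per bin from a fitted model, not fitted directly.
Expected substitution numbers come from the stationary flux:
E_syn = t Σ_{syn pairs} Π_i Q_ij, and likewise for nonsynonymous pairs.
Site counts come in two flavors:

* **physical sites** — each of a codon's nine single-nucleotide mutations
  contributes ⅓ of a site to the synonymous or nonsynonymous tally;
  mutations that would create a stop codon are excluded, consistent with a
  state space of sense codons, so the per-codon total is 3 minus ⅓ per stop
  neighbor (≈ 2.96 averaged over uniform codon usage).
* **mutational opportunity** — the synonymous/nonsynonymous split of the
  stationary flux under the fitted process with selection switched off
  (ω = 1, fitted κ), normalized to the same stop-adjusted total as the
  physical counts. This normalization makes the two definitions coincide
  exactly when κ = 1 and Π is uniform, and makes the counts invariant to
  the overall scale of Q.

Two identities pin the bookkeeping down: dN·N + dS·S equals the expected
substitutions regardless of definition, and dN/dS under the
mutational-opportunity definition reproduces ω(r_k) exactly (for MG94,
β/α at r_k).

## The simulator

The generator draws, per site: RSA from a configurable distribution on
[0, 1] (uniform; Beta(a, b); or an "empirical-like" mixture
0.4·Beta(0.8, 8) + 0.6·Beta(1.6, 2.2) whose buried spike and exposed
shoulder caricature real RSA histograms), the bin, an ancestral codon from
Π, and a descendant codon from the ancestral row of the bin's transition
matrix. RSA is i.i.d. along the sequence — no autocorrelation — and there
are no indels, no multi-taxon trees, and no structural drift of RSA over
time. Because the likelihood treats sites as independent given the bin,
these simplifications are exactly the model's own assumptions: passing
recovery tests shows the estimator is correct *under the model*, not that
real alignments satisfy the model. Unless a frequency vector is supplied,
simulations use uniform Π = 1/61. All draws derive from one seeded
generator; output is byte-reproducible given the seed.

## Numerical choices and defaults

| quantity | default | note |
|---|---|---|
| bins n | 20 | evenly spaced on [0, 1]; sensitivity sweep via `fit --bin-range` |
| parameter lower bound | 10⁻⁶ | at occupied mid-points, via coordinates |
| upper bounds | ω, κ ≤ 100; t, α, β ≤ 50 | generous box bounds |
| starts | 5 | first un-jittered, rest ±50% multiplicative jitter |
| start values | ω 0.2, κ 2, t 0.3, α 0.3, β 0.06 | slopes 0 |
| expm | eigendecomposition of the symmetrized generator | `expm` fallback when Π has zeros |
| transition-matrix hygiene | clip at 0, renormalize rows | roundoff-level only |
| AIC rounding in reports | nearest integer | matches the field's table conventions |

Degenerate inputs: alignments with zero ungapped codons, site-RSA tables
without usable columns, empty occupied-bin sets, n < 2 bins, and linear
forms with fewer than two occupied bins are rejected with specific errors.
RSA values above 1 (possible for distorted residues under any max-ASA
table) are clamped to 1.0 rather than rejected. The bundled max-ASA table
is the theoretical Gly-X-Gly set of Tien et al. (2013); any 20-entry
positive table can be substituted.

## Study sizes used in tests and the acceptance script

Parameter-recovery and model-discrimination studies run at 5×10⁴ codon
sites under (ω = 0.2, t = 0.5, κ = 2) or (ω = 0.1 + 0.3 r, t = 0.5,
κ = 2) with uniform RSA and uniform Π. At this size the single-replicate
relative standard deviation of the MLE is ≈ 5% for ω (4% for t, 3.5% for
κ), so point-recovery claims are made about the mean over 12 replicates
rather than a single draw. The type-I calibration of the ω-slope LRT uses
200 replicates of 2,000 sites with n = 4 bins — small enough to run
routinely, large enough that the χ²(1) asymptotics hold — and checks the
rejection rate at α = 0.05 against the exact binomial 95% interval. The
alternative fit in each LRT is warm-started from the null optimum so the
statistic is non-negative by construction.

## Known limitations

* Pairwise alignments only; no trees, no rate variation within an RSA bin.
* Codon frequencies are global (one F3×4 vector), not per bin or per gene.
* The MG94 variant is the codon-frequency form defined by the α↔t, β↔tω
  correspondence; nucleotide-frequency MG94 is not implemented.
* Mapping structures to alignment sites is the caller's job: the DSSP
  reader assumes residue numbers correspond to codon sites up to a constant
  offset.
* A fitted linear form may be extrapolated negative outside the occupied
  RSA range; consumers evaluating parameters outside that range must guard
  for it.
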