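# Methods

## The model

`repeatscape` works with alignments of **pairs of consecutive repeats**: each
row is a sequence σ = (σ_1, …, σ_2L) over q = 21 states (20 amino acids plus
the gap, treated as an ordinary 21st symbol throughout — energies, overlap
counting, and entropies all live on the 21-letter alphabet, so the
unconstrained entropy is 2L·log2(21) bits). Columns i and i+L are homologous
positions in the two repeat halves.

The family is modelled by the maximum-entropy distribution P(σ) ∝ exp(−E(σ))
consistent with three sets of observables: per-site amino-acid frequencies
f_i(σ), joint pair frequencies f_ij(σ, τ), and the distribution P(ID) of the
repeat overlap ID(σ) = #{i ≤ L : σ_i = σ_{i+L}} (which absorbs phylogenic
similarity of consecutive repeats). The resulting energy is a disordered
Potts model with an overlap term:

    E(σ) = − Σ_i h_i(σ_i) − Σ_{i<j ∈ mask} J_ij(σ_i, σ_j) + λ_{ID(σ)}

Each unordered pair is summed once (the symmetric-sum convention differs only
by a factor-2 reparameterization of J). The interaction mask restricts which
pairs may carry couplings: the full model, intra-repeat pairs only, a linear
band |i − j| ≤ W, or a 3D distance cutoff on a supplied residue–residue
distance matrix. λ_ID is stored as L+1 free values; no gauge is fixed on h
and J — the L1 penalty used in fitting selects a representative.

The **model hierarchy** removes constraints one at a time: E_rand (everything
zero), E_1 (fields only, closed form h = log f), E_ir and E_ir,λ
(single-repeat models with parameters tied across the two halves, fitted to
repeat-averaged targets, without/with the overlap constraint), E_2 (all
couplings, no overlap constraint, seeded from E_full), and E_full. Entropy
differences across the hierarchy decompose the diversity reduction into
within-repeat interactions (S_1 − S_ir), phylogenic overlap bias
(S_ir − S_ir,λ), repeat-repeat interactions (S_ir,λ − S_full), and the
redundancy S_ir − S_ir,λ − S_2 + S_full between the overlap constraint and
the homologous-pair couplings. The pipeline computes these directly from the
variant entropies, so the decomposition identities hold exactly.

## Curation and observables

FASTA input is integer-encoded ('.' ≡ '-', ambiguity codes X/B/Z/U/O map to
the gap — this keeps q = 21 without inventing frequencies for rare codes).
Columns whose gap fraction strictly exceeds `max_gap_frac` (default 0.8) are
removed; because the input is already paired, columns are dropped
symmetrically (i and i+L together) to keep halves homologous. Redundancy is
corrected by greedy identity clustering at 90%: the first sequence (input
order; rows have equal length) seeds a cluster, later sequences join the
first representative matching ≥ 90% of the 2L columns (gaps compared like
any symbol), and each sequence gets weight 1/(cluster size), so weights sum
to the number of clusters. Exact tie-breaking of the reference greedy
clustering tool is unspecified, so input order is fixed and documented; no
installed package clusters pre-aligned integer sequences with these exact
semantics, so the ~30-line loop is written here. Whether two aligned gaps
count toward ID is an open choice; we count them as a match (δ on the full
21-letter alphabet), consistent with treating the gap as a state everywhere.

## Sampling

Sequences are drawn by single-site Metropolis: a uniform site and a uniform
new symbol among the q − 1 alternatives are proposed (symmetric proposal, so
exp(−ΔE) is the exact acceptance ratio), downhill moves always accepted. ΔE
is computed incrementally from the changed site's field, its incident
couplings, and the overlap term via the change in ID — O(degree) per
proposal. One sequence is recorded every `thinning` proposals (default 1000,
counted over proposals, not acceptances) after a burn-in of 10 × thinning;
the burn-in multiplier is a cheap insurance choice, exposed in the
configuration. Chains are reproducible from an integer seed. Desk-scale runs
use thinning ≈ 10 proposals per site, which at 2L = 8–16 decorrelates
samples to well below the statistical errors the tests budget for.

## Fitting

Boltzmann-machine learning: each iteration samples an ensemble at the current
parameters, measures model observables, and steps along the likelihood
gradient, which equals the data − model difference of each observable:
h += ε_m (f_data − f_model); λ −= ε_ID (P_data − P_model) (the sign follows
from λ entering E with +). Couplings take an L1-proximal step of strength γ
with four cases: a zero coupling stays zero while |Δf_2| < γ (the γ tube
absorbs sampling noise — no pseudocounts are used on pair targets); it is
released along the soft-thresholded gradient when |Δf_2| > γ; an active
coupling moves along the soft-thresholded gradient and is clamped to zero if
the step crosses sign. Case precedence follows the order just given.
Learning stops at the first iteration where
max(|Δf_1|, |Δf_2| over masked pairs, 5·|ΔP(ID)|) < 0.02; the factor 5 and
the threshold are the published criterion, and the error terms included are
restricted to the constraints actually fitted for each variant.
Non-convergence at `max_iters` (default 500) is reported, not raised.

Defaults ε_m = 0.1, ε_j = 0.05, γ = 0.001 follow the published protocol.
ε_ID defaults to 10 to match that protocol, which targets L ≈ 33 where
P(ID) spreads over 34 bins and per-bin discrepancies are small. At desk
scale (L = 4–8) P(ID) is concentrated and a step of 10 × ΔP makes λ
oscillate without converging, so all desk-scale runs in the tests and
analyses use ε_ID = 1; this is a step-size rescaling of the same update, not
a change of the fitted constraint.

Tied-repeat variants symmetrize both the data targets
(f'_i = f'_{i+L} = ½(f_i + f_{i+L}), same for intra-repeat pairs) and the
per-iteration model observables; with a repeat-symmetric initialization the
parameter ties hold at every iteration by induction, so no explicit
re-tying is needed. Inter-repeat target blocks are replaced by products of
the tied marginals purely to keep the observable container self-consistent;
they are never fitted under the intra-repeat mask.

**Seeded range sweeps and de novo bias.** Range-restricted models
(|i − j| ≤ W) are fitted progressively: the model at one range initializes
the next, with newly unmasked couplings at zero. This matters beyond
convenience: fitting the full model de novo from the independent-sites
initialization satisfies the stopping criterion while couplings are still
underdeveloped, which systematically overestimates the entropy (see
"Known limitations"); progressive seeding reaches lower-entropy, better
converged parameters. E_ir,λ is seeded from the fitted E_ir and E_2 from
E_full for the same reason.

## Entropy by thermodynamic integration

S = ⟨E⟩ − F(1). F(0) = −Σ_i log Σ_σ e^{h_i(σ)} is closed-form (log-sum-exp
guarded); F(1) = F(0) + ∫_0^1 dα ⟨−ΣJ + λ_ID⟩_α, where the average at each α
is over an ensemble sampled from the interpolated energy
E_α = −Σh + α(−ΣJ + λ_ID). The integral uses composite Simpson on a uniform
odd-count grid; the default is 51 points at spacing 0.02 (an odd count is
required for Simpson to apply cleanly). ⟨E⟩ comes from a fresh α = 1
ensemble of the same size. Internal units are nats; results are reported in
bits (divide by ln 2).

Error model, three components:
- **MC error**: per-α standard errors of the integrand propagated through
  the Simpson weights, plus the ⟨E⟩ standard error, in quadrature.
- **Finite-sample error**: multinomial error propagation of the
  independent-sites entropy, per site: Var = (1/N)Σ_i[Σ_σ p log²p − S_i²],
  with variances of independent sites adding. (The per-site form is the
  correct first-order propagation; subtracting the square of the *total*
  entropy instead would give a negative variance for any multi-site system.)
- **Learning bias**: |S_indep(model-sampled f_1) − S_indep(data f_1)| —
  the independent-sites surrogate for systematic inference bias. This
  surrogate assumes coupling terms do not change the order of magnitude of
  the bias, which holds for weakly coupled families but fails for strongly
  coupled planted models (see below).

An exact-enumeration entropy (full sum over q^{2L} states, capped at 10^7
states) is the brute-force oracle; TI agrees with it within its reported MC
error on planted models small enough to enumerate.

## Energy landscape

A quench repeatedly collects all strictly energy-decreasing moves — every
single-site substitution plus, when σ_i = σ_{i+L}, the synchronized double
substitution of both homologous positions to one common new symbol (included
so residual phylogenic symmetry in the parameters does not manufacture
spurious minima) — and applies one uniformly at random until none remains.
Singles and allowed doubles compete in one uniform pool. λ_ID is set to zero
in the quench energy so minima reflect functional couplings rather than
phylogenic bias. Quenches are stochastic near ridges; the partition is
defined as the run at the recorded seed, matching a single-realization
procedure. Starts may be natural (curated weights) or model-generated
(uniform weights); basin weights are normalized weighted start counts, the
empirical estimate of P(b) = Σ_{σ∈b} P(σ), and S_conf = −Σ_b P(b) log2 P(b).
Minima are deduplicated by exact sequence identity; the largest basins
covering 90% of the weight are organised by average-linkage clustering of
pairwise Hamming distances (scipy), giving the merge tree and leaf order for
block-structure display. The consensus sequence is the per-column argmax of
f_1 (ties to the lowest symbol index); on the independent-sites model it is
the unique minimum, the contrast case to the multi-basin interacting
landscape.

## Family divergence

D(A‖B) = ⟨E_B − E_A⟩_A + F_A − F_B, with the average over samples from A
(B's energy evaluated through an explicit bijective column map; partial maps
are refused rather than guessed) and both free energies from thermodynamic
integration. Reported in bits, both directions, with the sampling error of
the energy difference and both TI quadrature errors combined in quadrature.
Against the unconstrained model, D(model‖rand) = n_sites·log2(q) − S_bits,
using the model's full site count (2L for pair models).

## Synthetic ground truth

Planted models draw fields ~ N(0, field_scale²) and q×q coupling blocks
~ N(0, coupling_scale²) on a random subset of pairs split between intra- and
inter-repeat pairs, with an optional λ_ID profile to mimic phylogenic
overlap bias. Defaults (field_scale 0.5, coupling_scale 1.0 at q = 4) put
desk-scale models in the frustrated, multi-minimum regime without freezing
them. Alignments are Metropolis samples from the planted model. What the
generator does **not** emulate: actual phylogenetic descent (the λ_ID bias
stands in for it), alignment insertions, ambiguous residues, and the weak,
spatially structured couplings of real families — passing tests demonstrate
correctness of the machinery under known ground truth, not performance on
PFAM-scale data.

Desk problem sizes used throughout tests and analyses: 2L = 8–16, q = 3–4,
alignments of 2 000–20 000 sequences, 10 000–80 000 MC samples per fitting
iteration, TI grids of 11–51 points. These sizes keep every stage
enumeration-checkable or minutes-fast while preserving all qualitative
regimes (frustration, overlap bias, range structure).

## Known limitations

- **De novo fits overestimate entropy.** With the published stopping rule
  (max error < 0.02) and constant learning rates, a full-coupling fit
  started from the independent model satisfies the criterion while strong
  planted couplings are still only partially developed. On the standard
  recovery benchmark (2L = 12, q = 4, 10 Gaussian coupling blocks of scale
  1.0, 20 000 training sequences) the de novo relearned entropy exceeds the
  planted model's by ≈ 0.9 bits (≈ 4.5%), far beyond the MC error
  (≈ 0.02 bits) and the independent-sites bias estimate (≈ 0.02 bits),
  and insensitive to raising the per-iteration sample size from 20 000 to
  80 000. Progressive seeded learning reduces but does not eliminate this
  bias at these coupling strengths. The bias is a property of the inference
  protocol at strong coupling, not of the entropy estimator: TI agrees with
  exact enumeration whenever the state space can be enumerated.
- The independent-sites bias surrogate only sees single-site marginals and
  therefore underestimates bias carried by couplings.
- Quench basins near ridges depend on the seed; only the recorded-seed
  partition is reproducible.
- Greedy identity clustering depends on input order (documented, fixed).
- The Metropolis sampler is a single chain; very strongly coupled models at
  large 2L would need longer thinning than the defaults used here.
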