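# repeatscape

Size and structure of the sequence space of repeat-protein families, from
maximum-entropy models of two-repeat alignments.

Repeat proteins (ankyrin, leucine-rich, tetratricopeptide repeats, …) are
tandem arrays of ~30-residue units. Given a multiple sequence alignment of
pairs of consecutive repeats (2L columns, 20 amino acids + gap), this package
fits the maximum-entropy (Potts) distribution

P(σ) ∝ exp(−E(σ)),  E(σ) = −Σᵢ hᵢ(σᵢ) − Σ_{i<j} J_ij(σᵢ, σⱼ) + λ_{ID(σ)}

constrained to reproduce the per-site frequencies fᵢ(σ), the pair frequencies
f_ij(σ, τ), and the distribution of the inter-repeat overlap
ID(σ) = #{i ≤ L : σᵢ = σ_{i+L}} (which absorbs the phylogenic similarity of
consecutive repeats). On top of the fitted models it computes:

- **Family entropy** S = −Σ P log P by thermodynamic integration over an
  interpolation parameter α (closed-form independent-sites reference,
  Simpson quadrature, full error model), i.e. the effective size 2^S of the
  family's sequence space — and its decomposition across a hierarchy of
  models with fewer constraints (E_rand, E_1, E_ir, E_ir,λ, E_2, E_full),
  separating within-repeat interactions, repeat-repeat interactions, and
  phylogenic overlap bias.
- **Interaction range**: seeded re-fits with couplings restricted to
  |i − j| ≤ W or to a 3D distance cutoff, tracing how entropy falls with
  interaction range.
- **Energy landscape**: zero-temperature quenches from natural sequences,
  basins of attraction, configurational entropy S_conf = −Σ_b P(b) log₂ P(b),
  and hierarchical clustering of the dominant minima.
- **Family divergence**: Kullback–Leibler divergence between two fitted
  family models (via thermodynamic integration of both free energies) and
  against the random-polypeptide model.

Everything is testable without downloads: a synthetic-data module plants
ground-truth models (Gaussian fields and sparse couplings, optional overlap
bias) and samples alignments from them, so each stage can be validated
against exact enumeration or the planted truth.

Who it is for: anyone doing inverse statistical mechanics on protein
families — fitting Potts/DCA-style models, measuring sequence-space
entropies, or dissecting multi-basin statistical energy landscapes — who
wants a compact, fully synthetic-testable reference implementation for
repeat-protein (two-repeat) alignments.

## Worked example

```python
import numpy as np
import repeatscape as rs

# a small planted family: two consecutive repeats of length L=4, q=3 states
spec = rs.PlantedSpec(L=4, q=3, coupling_density=0.3, seed=42,
                      lambda_profile=np.array([0.0, -0.1, -0.2, -0.3, -0.4]))
truth = rs.make_planted_model(spec)
aln = rs.make_planted_alignment(truth, 5000, seed=7)
aln.weights = rs.cluster_weights(aln, identity_threshold=0.9)
obs = rs.compute_observables(aln)
print(f"alignment: {aln.n_sequences} sequences, n_eff = {obs.n_eff:.0f}")
print(f"mean repeat overlap ID = {np.dot(np.arange(5), obs.p_id):.2f} of L = 4")

S_rand = rs.random_model_entropy_bits(truth.n_sites, truth.q)
res = rs.entropy_thermodynamic(truth, n=5000, alpha_grid=np.linspace(0, 1, 21),
                               thinning=80, seed=1)
exact = rs.entropy_exact_enumeration(truth) / np.log(2)
print(f"S_rand = {S_rand:.2f} bits")
print(f"S (thermodynamic integration) = {res.S_bits:.2f} +- {res.mc_error_bits:.2f} bits")
print(f"S (exact enumeration)         = {exact:.2f} bits")

part = rs.basin_decomposition(truth, aln.sequences[:1000], aln.weights[:1000], seed=0)
print(f"local minima: {len(part.minima)}, S_conf = {part.S_conf_bits:.2f} bits")
print(f"largest basin weight P(b) = {part.P_b[0]:.2f}")
```

Output:

```
alignment: 5000 sequences, n_eff = 1020
mean repeat overlap ID = 1.41 of L = 4
S_rand = 12.68 bits
S (thermodynamic integration) = 8.78 +- 0.04 bits
S (exact enumeration)         = 8.77 bits
local minima: 2, S_conf = 0.96 bits
largest basin weight P(b) = 0.62
```

Reading it: redundancy weighting (90% identity clustering) reduces 5000
sequences to ~1020 effective ones; the overlap bias planted through λ keeps
the two repeat halves similar (mean ID 1.4 of 4). The family occupies
2^8.78 ≈ 440 of the 2^12.68 ≈ 6561 possible sequences; the thermodynamic-
integration estimate agrees with brute-force enumeration to 0.01 bits. The
frustrated couplings split the landscape into two basins of attraction whose
62/38 occupation gives a configurational entropy of 0.96 bits.

## The analysis pipeline

The `analysis/` scripts run the full study on a synthetic family
(2L = 12, q = 4, 20 000 sequences) with the planted model as ground truth,
writing tables to `results/`:

```
python analysis/01_simulate_family.py     # planted model + alignment
python analysis/02_fit_variants.py        # model hierarchy E_rand .. E_full
python analysis/03_entropy_decomposition.py
python analysis/04_interaction_range.py   # W-sweeps + controls
python analysis/05_landscape.py           # basins, S_conf, clustering
python analysis/06_family_divergence.py   # KL between two families
```

Equivalently, the `repeatscape` command-line tool exposes each stage
(`curate`, `simulate`, `fit`, `sample`, `entropy`, `landscape`, `kl`) and a
config-driven `run` that orchestrates them idempotently; see
`repeatscape --help`.

Real alignments are supported through `read_alignment` / `repeatscape curate`
(FASTA of pre-paired two-repeat sequences; gap-column removal, identity
reweighting); 3D-restricted models take a plain-text residue distance matrix.

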