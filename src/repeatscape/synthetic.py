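"""Planted ground-truth models and synthetic alignments.

The generator emulates the statistical structure the analysis assumes in real
repeat-protein alignments: per-column symbol biases (Gaussian fields), sparse
pairwise couplings split between intra- and inter-repeat pairs (Gaussian q x q
blocks on a random subset of pairs), and an optional explicit bias on the
number of identical residues between the two repeat halves (a lambda_ID
profile mimicking phylogenic similarity of consecutive repeats). Alignments
are drawn from the planted model by Metropolis sampling, so every stage of the
pipeline can be tested against a known ground truth without any downloads.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment import Alignment
from .potts import InteractionMask, PottsModel
from .sampling import metropolis_sample


@dataclass
class PlantedSpec:
    """Ground-truth model specification.

    Scales default to values that put planted models in the interesting
    regime at desk sizes (q=4): neither near-uniform nor frozen, with enough
    frustration to produce several local minima.
    """

    L: int
    q: int = 4
    field_scale: float = 0.5
    coupling_density: float = 0.15  # fraction of site pairs carrying a coupling block
    coupling_scale: float = 1.0
    intra_frac: float = 0.5        # fraction of coupled pairs drawn from intra-repeat pairs
    n_couplings: int | None = None  # overrides coupling_density when set
    lambda_profile: np.ndarray | None = None  # (L+1,) overlap bias, e.g. favoring high ID
    max_range: int | None = None   # restrict couplings to |i-j| <= max_range
    seed: int = 0

    def __post_init__(self):
        if self.q < 2:
            raise ValueError("q must be >= 2")
        if not 0 <= self.coupling_density <= 1:
            raise ValueError("coupling_density must lie in [0, 1]")
        if not 0 <= self.intra_frac <= 1:
            raise ValueError("intra_frac must lie in [0, 1]")


def make_planted_model(spec: PlantedSpec) -> PottsModel:
    """Draw a reproducible random Potts model from the spec.

    Fields and coupling blocks are zero-mean Gaussian; coupled pairs are a
    random subset split between intra- and inter-repeat pairs according to
    intra_frac. The mask is the support of the planted couplings.
    """
    rng = np.random.default_rng(spec.seed)
    L, q = spec.L, spec.q
    n = 2 * L
    h = rng.normal(0.0, spec.field_scale, size=(n, q))
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    if spec.max_range is not None:
        pairs = [(i, j) for i, j in pairs if j - i <= spec.max_range]
    intra = [(i, j) for i, j in pairs if (i < L) == (j < L)]
    inter = [(i, j) for i, j in pairs if (i < L) != (j < L)]
    n_c = (
        spec.n_couplings
        if spec.n_couplings is not None
        else int(round(spec.coupling_density * len(pairs)))
    )
    n_c = min(n_c, len(pairs))
    n_intra = min(int(round(spec.intra_frac * n_c)), len(intra))
    n_inter = min(n_c - n_intra, len(inter))
    n_intra = n_c - n_inter  # rebalance if one pool ran short
    chosen = []
    if n_intra > 0:
        chosen += [intra[k] for k in rng.choice(len(intra), n_intra, replace=False)]
    if n_inter > 0:
        chosen += [inter[k] for k in rng.choice(len(inter), n_inter, replace=False)]
    A = np.zeros((n, n), dtype=bool)
    J = np.zeros((n, n, q, q))
    for i, j in chosen:
        A[i, j] = A[j, i] = True
        blk = rng.normal(0.0, spec.coupling_scale, size=(q, q))
        J[i, j] = blk
        J[j, i] = blk.T
    lam = (
        np.zeros(L + 1)
        if spec.lambda_profile is None
        else np.asarray(spec.lambda_profile, dtype=float)
    )
    if lam.shape != (L + 1,):
        raise ValueError(f"lambda_profile must have shape ({L + 1},)")
    return PottsModel(h=h, J=J, lam=lam, mask=InteractionMask(A))


def make_planted_alignment(
    model: PottsModel,
    n: int,
    seed: int = 0,
    thinning: int | None = None,
    burn_in: int | None = None,
) -> Alignment:
    """Sample n sequences from the planted model into an unweighted Alignment.

    Default thinning is 10 proposals per site, ample decorrelation at the
    desk scales the generator targets.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if thinning is None:
        thinning = 10 * model.n_sites
    ens = metropolis_sample(model, n, alpha=1.0, thinning=thinning,
                            burn_in=burn_in, seed=seed)
    ids = [f"synth_{k}" for k in range(n)]
    return Alignment(ens.sequences, ids, model.L, q=model.q)


def make_toy_distance_matrix(
    n_sites: int, repeat_len: int, near_range: int = 1, seed: int = 0
) -> np.ndarray:
    """Toy 3D distance matrix mimicking a regular repeat fold.

    Near-diagonal pairs (|i-j| <= near_range) and homologous pairs (i, i+L)
    sit at short distances (~5 A), everything else far (~20 A), with small
    jitter; symmetric with zero diagonal. A cutoff sweep on this matrix grows
    the mask in two stages: local contacts first, then inter-repeat contacts.
    """
    rng = np.random.default_rng(seed)
    d = np.full((n_sites, n_sites), 20.0)
    idx = np.arange(n_sites)
    near = np.abs(idx[:, None] - idx[None, :]) <= near_range
    d[near] = 5.0
    for i in range(n_sites - repeat_len):
        d[i, i + repeat_len] = d[i + repeat_len, i] = 8.0
    jitter = rng.uniform(0.0, 1.0, size=(n_sites, n_sites))
    jitter = 0.5 * (jitter + jitter.T)
    d = d + jitter
    np.fill_diagonal(d, 0.0)
    return d
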