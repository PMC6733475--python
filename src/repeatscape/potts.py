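"""The Potts energy model over two-repeat sequences and its restricted variants.

E(sigma) = - sum_i h_i(sigma_i) - sum_{i<j in mask} J_ij(sigma_i, sigma_j)
           + lambda_{ID(sigma)}

with ID(sigma) the number of homologous positions carried identically by the
two repeat halves. The interaction mask restricts which site pairs may carry
couplings (full model, intra-repeat only, linear range |i-j| <= W, or a 3D
distance cutoff). The interpolated energy E_alpha scales the coupling and
overlap terms by alpha in [0, 1] and is the backbone of thermodynamic
integration: E_0 is the independent-sites part, E_1 the full energy.

Couplings are stored dense and symmetric (J[j, i] = J[i, j].T) with each
unordered pair counted once in the energy; storing both orientations keeps the
incremental Metropolis updates branch-free.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from ._kernels import batch_energy, seq_energy
from .alignment import ObservableSet


@dataclass
class InteractionMask:
    """Symmetric boolean matrix of allowed site pairs (diagonal excluded)."""

    allowed: np.ndarray  # (n, n) bool

    def __post_init__(self):
        A = np.asarray(self.allowed, dtype=bool)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("mask must be square")
        if not np.array_equal(A, A.T):
            raise ValueError("mask must be symmetric")
        if A.diagonal().any():
            raise ValueError("mask diagonal must be empty")
        self.allowed = A

    @property
    def n_sites(self) -> int:
        return self.allowed.shape[0]

    @property
    def n_pairs(self) -> int:
        return int(np.triu(self.allowed, 1).sum())

    def pairs(self) -> np.ndarray:
        """(P, 2) array of allowed pairs i < j."""
        return np.argwhere(np.triu(self.allowed, 1))


def make_mask_linear(n_sites: int, W: int) -> InteractionMask:
    """Allow pairs within linear sequence range: |i - j| <= W (inclusive)."""
    if W < 0:
        raise ValueError("W must be >= 0")
    idx = np.arange(n_sites)
    A = np.abs(idx[:, None] - idx[None, :]) <= W
    np.fill_diagonal(A, False)
    return InteractionMask(A)


def make_mask_full(n_sites: int) -> InteractionMask:
    return make_mask_linear(n_sites, n_sites - 1)


def make_mask_empty(n_sites: int) -> InteractionMask:
    return InteractionMask(np.zeros((n_sites, n_sites), dtype=bool))


def make_mask_intra_repeat(n_sites: int) -> InteractionMask:
    """Allow only pairs within the same repeat half (no inter-repeat couplings)."""
    L = n_sites // 2
    A = np.zeros((n_sites, n_sites), dtype=bool)
    A[:L, :L] = True
    A[L:, L:] = True
    np.fill_diagonal(A, False)
    return InteractionMask(A)


def make_mask_3d(d3: np.ndarray, cutoff: float) -> InteractionMask:
    """Allow pairs whose minimum heavy-atom distance is <= cutoff (Angstrom)."""
    d3 = np.asarray(d3, dtype=float)
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if d3.ndim != 2 or d3.shape[0] != d3.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d3, d3.T):
        raise ValueError("distance matrix must be symmetric")
    A = d3 <= cutoff
    np.fill_diagonal(A, False)
    return InteractionMask(A)


def read_distance_matrix(path) -> np.ndarray:
    """Whitespace-delimited square distance matrix (Angstrom)."""
    d3 = np.loadtxt(path)
    if d3.ndim != 2 or d3.shape[0] != d3.shape[1]:
        raise ValueError("distance matrix must be square")
    return d3


@dataclass
class PottsModel:
    h: np.ndarray  # (2L, q)
    J: np.ndarray  # (2L, 2L, q, q), symmetric, zero outside mask
    lam: np.ndarray  # (L+1,) overlap multipliers lambda_ID
    mask: InteractionMask

    def __post_init__(self):
        self.h = np.ascontiguousarray(self.h, dtype=float)
        self.J = np.ascontiguousarray(self.J, dtype=float)
        self.lam = np.ascontiguousarray(self.lam, dtype=float)
        n, q = self.h.shape
        if n % 2:
            raise ValueError("models cover a pair of repeats: 2L sites, even")
        if self.J.shape != (n, n, q, q):
            raise ValueError(f"J must have shape {(n, n, q, q)}")
        if self.lam.shape != (n // 2 + 1,):
            raise ValueError(f"lam must have shape ({n // 2 + 1},)")
        if not isinstance(self.mask, InteractionMask):
            self.mask = InteractionMask(self.mask)
        if self.mask.n_sites != n:
            raise ValueError("mask size must match the number of sites")
        off = ~self.mask.allowed
        if np.abs(self.J[off]).max(initial=0.0) > 0:
            raise ValueError("J must be exactly zero outside the mask")

    # -- basic geometry ----------------------------------------------------
    @property
    def n_sites(self) -> int:
        return self.h.shape[0]

    @property
    def L(self) -> int:
        return self.n_sites // 2

    @property
    def q(self) -> int:
        return self.h.shape[1]

    @classmethod
    def zero(cls, L: int, q: int, mask: InteractionMask | None = None) -> "PottsModel":
        """The unconstrained (E_rand) model: every sequence equally likely."""
        n = 2 * L
        if mask is None:
            mask = make_mask_empty(n)
        return cls(
            h=np.zeros((n, q)),
            J=np.zeros((n, n, q, q)),
            lam=np.zeros(L + 1),
            mask=mask,
        )

    # -- energies ----------------------------------------------------------
    def _check_seq(self, seq: np.ndarray) -> np.ndarray:
        seq = np.ascontiguousarray(seq, dtype=np.int8)
        if seq.shape != (self.n_sites,):
            raise ValueError(f"sequence must have length {self.n_sites}")
        return seq

    def energy(self, seq: np.ndarray) -> float:
        return float(
            seq_energy(self._check_seq(seq), self.h, self.J, self.lam, self.mask.allowed, 1.0)
        )

    def energy_alpha(self, seq: np.ndarray, alpha: float) -> float:
        if not 0.0 <= alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        return float(
            seq_energy(self._check_seq(seq), self.h, self.J, self.lam, self.mask.allowed, alpha)
        )

    def energies(self, seqs: np.ndarray, alpha: float = 1.0) -> np.ndarray:
        seqs = np.ascontiguousarray(seqs, dtype=np.int8)
        return batch_energy(seqs, self.h, self.J, self.lam, self.mask.allowed, alpha)

    # -- utilities ---------------------------------------------------------
    def with_lambda_zero(self) -> "PottsModel":
        return PottsModel(self.h.copy(), self.J.copy(), np.zeros_like(self.lam), self.mask)

    def set_coupling(self, i: int, j: int, block: np.ndarray) -> None:
        """Set the (q, q) coupling block for pair i < j, keeping J symmetric."""
        if not self.mask.allowed[i, j]:
            raise ValueError(f"pair ({i},{j}) is outside the interaction mask")
        self.J[i, j] = block
        self.J[j, i] = np.asarray(block).T

    def content_hash(self) -> str:
        md = hashlib.sha256()
        for arr in (self.h, self.J, self.lam, self.mask.allowed):
            md.update(np.ascontiguousarray(arr).tobytes())
        return md.hexdigest()[:16]


def independent_model(obs: ObservableSet, pseudocount: float = 1e-6) -> PottsModel:
    """Independent-sites model h_i = log f_i (pseudocount-regularized), J = lambda = 0.

    With fields h = log f the per-site Boltzmann factors are normalized, so
    F(0) = 0 and the model reproduces the data marginals exactly as
    pseudocount -> 0.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    f = (obs.f1 + pseudocount) / (1.0 + obs.q * pseudocount)
    if (f <= 0).any():
        raise ValueError("zero frequencies require a positive pseudocount")
    n = 2 * obs.L
    return PottsModel(
        h=np.log(f),
        J=np.zeros((n, n, obs.q, obs.q)),
        lam=np.zeros(obs.L + 1),
        mask=make_mask_empty(n),
    )


def symmetrize_single_repeat(obs: ObservableSet) -> ObservableSet:
    """Tie the two repeat halves: average the single-site and intra-repeat pair
    frequencies over the repeats (f'_i = f'_{i+L} = (f_i + f_{i+L})/2, same for
    intra-repeat f'_ij). These are the targets for the non-interacting-repeat
    variants fitted with parameters shared across repeats.

    Inter-repeat blocks are replaced by products of the tied marginals so the
    marginal-consistency invariant holds; they are never fitted under the
    intra-repeat mask.
    """
    L, q = obs.L, obs.q
    n = 2 * L
    f1 = obs.f1.copy()
    f1[:L] = f1[L:] = 0.5 * (obs.f1[:L] + obs.f1[L:])
    f2 = np.empty_like(obs.f2)
    for i in range(n):
        for j in range(n):
            if i == j:
                f2[i, j] = obs.f2[i, j]
            elif (i < L) == (j < L):
                a, b = i % L, j % L
                f2[i, j] = 0.5 * (obs.f2[a, b] + obs.f2[a + L, b + L])
            else:
                f2[i, j] = np.outer(f1[i], f1[j])
    return ObservableSet(f1=f1, f2=f2, p_id=obs.p_id.copy(), n_eff=obs.n_eff, L=L, q=q)
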