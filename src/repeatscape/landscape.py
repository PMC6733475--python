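"""Zero-temperature quenches, basins of attraction, configurational entropy,
and the hierarchical organisation of local minima.

A quench repeatedly picks uniformly among all strictly energy-decreasing moves
(single-site substitutions plus, optionally, synchronized substitutions of a
matching homologous pair to one new symbol) until none remains; the endpoint
is a local minimum. The overlap multipliers lambda_ID are excluded from the
quench energy so that minima reflect the functional coupling terms rather than
phylogenic similarity. Starting quenches from every sequence of an alignment
partitions it into basins; basin weights P(b) (weighted start counts) define
the configurational entropy S_conf = -sum_b P(b) log2 P(b).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

from ._kernels import quench_chain
from .alignment import ObservableSet
from .potts import PottsModel


@dataclass
class QuenchOutcome:
    start_id: int
    minimum: np.ndarray
    E_min: float
    n_steps: int


@dataclass
class BasinPartition:
    """Quench endpoints and basin statistics, rank-ordered by basin weight."""

    minima: np.ndarray        # (M, 2L) distinct local minima, largest basin first
    energies: np.ndarray      # (M,) energy of each minimum (lambda = 0)
    assignment: np.ndarray    # start index -> minimum index
    sizes: np.ndarray         # (M,) weighted start counts
    P_b: np.ndarray           # (M,) normalized basin weights
    S_conf_bits: float


def quench(
    model: PottsModel,
    start: np.ndarray,
    seed: int = 0,
    allow_paired_double: bool = True,
    start_id: int = 0,
) -> QuenchOutcome:
    """Quench one start to a local minimum of the lambda-free energy."""
    m0 = model.with_lambda_zero()
    start = np.ascontiguousarray(start, dtype=np.int8)
    if start.shape != (model.n_sites,):
        raise ValueError(f"start must have length {model.n_sites}")
    seq, steps = quench_chain(
        m0.h, m0.J, m0.mask.allowed, start, allow_paired_double, int(seed) % 2**31
    )
    return QuenchOutcome(
        start_id=start_id, minimum=seq, E_min=m0.energy(seq), n_steps=int(steps)
    )


def basin_decomposition(
    model: PottsModel,
    starts: np.ndarray,
    start_weights: np.ndarray | None = None,
    seed: int = 0,
    allow_paired_double: bool = True,
) -> BasinPartition:
    """One quench per start; minima deduplicated by exact sequence identity.

    Basin weights are the (normalized) weighted counts of starts reaching each
    minimum — the empirical estimate of P(b) = sum_{sigma in b} P(sigma) when
    starts are natural sequences with curation weights. Output is ordered
    largest basin first (rank-energy plots read off directly).
    """
    starts = np.ascontiguousarray(starts, dtype=np.int8)
    if starts.ndim != 2 or len(starts) < 1:
        raise ValueError("need at least one start sequence")
    if start_weights is None:
        start_weights = np.ones(len(starts))
    start_weights = np.asarray(start_weights, dtype=float)
    seeds = np.random.default_rng(seed).integers(0, 2**31, size=len(starts))
    key_to_idx: dict[bytes, int] = {}
    minima: list[np.ndarray] = []
    assignment = np.empty(len(starts), dtype=int)
    for s in range(len(starts)):
        out = quench(model, starts[s], seed=int(seeds[s]),
                     allow_paired_double=allow_paired_double, start_id=s)
        key = out.minimum.tobytes()
        if key not in key_to_idx:
            key_to_idx[key] = len(minima)
            minima.append(out.minimum)
        assignment[s] = key_to_idx[key]
    minima_arr = np.array(minima, dtype=np.int8)
    sizes = np.bincount(assignment, weights=start_weights, minlength=len(minima))
    order = np.argsort(-sizes, kind="stable")
    rank_of = np.empty_like(order)
    rank_of[order] = np.arange(len(order))
    minima_arr = minima_arr[order]
    sizes = sizes[order]
    assignment = rank_of[assignment]
    P_b = sizes / sizes.sum()
    S_conf = float(-(P_b * np.log2(P_b, where=P_b > 0, out=np.zeros_like(P_b))).sum() + 0.0)
    m0 = model.with_lambda_zero()
    energies = m0.energies(minima_arr)
    return BasinPartition(
        minima=minima_arr,
        energies=energies,
        assignment=assignment,
        sizes=sizes,
        P_b=P_b,
        S_conf_bits=S_conf,
    )


def minima_clustering(partition: BasinPartition, coverage: float = 0.9):
    """Hierarchical organisation of the minima with the largest basins.

    Selects the top-ranked basins whose cumulative weight first reaches
    `coverage`, computes pairwise Hamming distances (site counts) between
    their minima, and builds an average-linkage merge tree. Returns
    (distance_matrix, linkage_matrix, selected_indices); with fewer than two
    selected minima the matrix is trivial and the linkage is None.
    """
    if not 0 < coverage <= 1:
        raise ValueError("coverage must lie in (0, 1]")
    cum = np.cumsum(partition.P_b)
    k = int(np.searchsorted(cum, coverage - 1e-12) + 1)
    sel = np.arange(min(k, len(partition.P_b)))
    M = partition.minima[sel]
    D = (M[:, None, :] != M[None, :, :]).sum(axis=2).astype(float)
    if len(sel) < 2:
        return D, None, sel
    Z = linkage(squareform(D, checks=False), method="average")
    return D, Z, sel


def clustering_leaf_order(Z: np.ndarray) -> np.ndarray:
    """Leaf order of a linkage tree, for block-structure display of the matrix."""
    return leaves_list(Z)


def consensus_sequence(obs: ObservableSet) -> np.ndarray:
    """Per-column most frequent symbol (ties broken by lowest symbol index)."""
    return np.argmax(obs.f1, axis=1).astype(np.int8)


def consensus_energy(model: PottsModel, obs: ObservableSet) -> float:
    """Energy (lambda = 0) of the consensus sequence of the alignment."""
    return model.with_lambda_zero().energy(consensus_sequence(obs))


def exhaustive_local_minima(model: PottsModel, allow_paired_double: bool = True) -> np.ndarray:
    """All true local minima of a small model by checking every neighbor.

    Brute-force oracle: a state is a local minimum iff every move in the
    quench move set strictly increases the lambda-free energy. Requires
    q**(2L) small enough to enumerate.
    """
    from .entropy import enumerate_states

    m0 = model.with_lambda_zero()
    states = enumerate_states(model.n_sites, model.q)
    E = m0.energies(states)
    n, q, L = model.n_sites, model.q, model.L
    # index of a state in the lexicographic enumeration
    place = q ** np.arange(n - 1, -1, -1)
    is_min = np.ones(len(states), dtype=bool)
    for s in range(len(states)):
        seq = states[s]
        e0 = E[s]
        for i in range(n):
            a = seq[i]
            for b in range(q):
                if b == a:
                    continue
                idx = s + (b - a) * place[i]
                if E[idx] < e0:
                    is_min[s] = False
                    break
            if not is_min[s]:
                break
        if is_min[s] and allow_paired_double:
            for i in range(L):
                if seq[i] == seq[i + L]:
                    a = seq[i]
                    for b in range(q):
                        if b == a:
                            continue
                        idx = s + (b - a) * (place[i] + place[i + L])
                        if E[idx] < e0:
                            is_min[s] = False
                            break
                if not is_min[s]:
                    break
    return states[is_min]
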