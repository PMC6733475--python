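"""Metropolis-Hastings sampling of sequence ensembles from a Potts model at any alpha."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernels import count_observables, mh_chain
from .alignment import ObservableSet
from .potts import PottsModel

#: Paper-scale defaults: one sequence kept every 1000 proposals, burn-in 10x that.
DEFAULT_THINNING = 1000


@dataclass
class SampleEnsemble:
    sequences: np.ndarray  # (N, 2L) int8
    alpha: float
    model_hash: str
    seed: int
    thinning: int
    burn_in: int
    q: int = 21

    @property
    def n(self) -> int:
        return len(self.sequences)


def metropolis_sample(
    model: PottsModel,
    n: int,
    alpha: float = 1.0,
    thinning: int = DEFAULT_THINNING,
    burn_in: int | None = None,
    seed: int = 0,
) -> SampleEnsemble:
    """Sample n sequences from P_alpha ∝ exp(-E_alpha) by single-site Metropolis.

    The chain starts from a uniformly random sequence; each proposal draws a
    uniform site and a uniform new symbol among the q-1 alternatives (symmetric
    proposal, so exp(-dE) is the exact acceptance ratio), accepting downhill
    moves always. One sequence is recorded every `thinning` proposals after
    `burn_in` proposals (default 10 x thinning).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if thinning < 1:
        raise ValueError("thinning must be >= 1")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    if burn_in is None:
        burn_in = 10 * thinning
    seqs = mh_chain(
        model.h,
        model.J,
        model.lam,
        model.mask.allowed,
        float(alpha),
        int(n),
        int(thinning),
        int(burn_in),
        int(seed) % 2**31,
    )
    return SampleEnsemble(
        sequences=seqs,
        alpha=float(alpha),
        model_hash=model.content_hash(),
        seed=int(seed),
        thinning=int(thinning),
        burn_in=int(burn_in),
        q=model.q,
    )


def ensemble_observables(ens: SampleEnsemble | np.ndarray, q: int | None = None) -> ObservableSet:
    """Unweighted empirical f1, f2, P(ID) of a sampled ensemble.

    Accepts either a SampleEnsemble or a raw (N, 2L) integer matrix (then q
    must be given).
    """
    if isinstance(ens, SampleEnsemble):
        seqs = ens.sequences
        q = ens.q if q is None else q
    else:
        seqs = np.asarray(ens)
        if q is None:
            raise ValueError("q is required for a raw sequence matrix")
    seqs = np.ascontiguousarray(seqs, dtype=np.int8)
    w = np.ones(len(seqs))
    f1, f2, p_id = count_observables(seqs, w, q)
    f2 = f2 + np.transpose(f2, (1, 0, 3, 2))
    L = seqs.shape[1] // 2
    return ObservableSet(f1=f1, f2=f2, p_id=p_id, n_eff=float(len(seqs)), L=L, q=q)
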