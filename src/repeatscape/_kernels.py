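"""Numba inner loops: energy evaluation, Metropolis chains, observable counting, quenches.

All kernels take the raw model arrays (h, J, lam, mask) rather than the
PottsModel object. J is stored dense and symmetric, J[i, j, a, b] == J[j, i, b, a],
with the energy summing each unordered pair once (i < j). lam is indexed by the
repeat overlap ID(sigma) = #{i < L : sigma_i == sigma_{i+L}}.

Randomness uses numba's internal RNG, seeded explicitly at the top of every
stochastic kernel, so identical seeds give identical output.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def seq_overlap(seq):
    """ID statistic: number of positions carried identically by the two halves."""
    n = seq.shape[0]
    L = n // 2
    ident = 0
    for i in range(L):
        if seq[i] == seq[i + L]:
            ident += 1
    return ident


@njit(cache=True)
def seq_energy(seq, h, J, lam, mask, alpha):
    """E_alpha(sigma) = -sum_i h_i(sigma_i) + alpha * (-sum_{i<j in mask} J_ij + lam_ID)."""
    n = seq.shape[0]
    e_field = 0.0
    for i in range(n):
        e_field += h[i, seq[i]]
    e_int = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            if mask[i, j]:
                e_int += J[i, j, seq[i], seq[j]]
    return -e_field + alpha * (-e_int + lam[seq_overlap(seq)])


@njit(cache=True)
def batch_energy(seqs, h, J, lam, mask, alpha):
    N = seqs.shape[0]
    out = np.empty(N)
    for s in range(N):
        out[s] = seq_energy(seqs[s], h, J, lam, mask, alpha)
    return out


@njit(cache=True)
def batch_interaction(seqs, J, lam, mask):
    """Per-sequence interaction part (-sum_{i<j in mask} J_ij + lam_ID); the TI integrand."""
    N, n = seqs.shape
    out = np.empty(N)
    for s in range(N):
        e_int = 0.0
        for i in range(n):
            for j in range(i + 1, n):
                if mask[i, j]:
                    e_int += J[i, j, seqs[s, i], seqs[s, j]]
        out[s] = -e_int + lam[seq_overlap(seqs[s])]
    return out


@njit(cache=True)
def mh_chain(h, J, lam, mask, alpha, n_keep, thinning, burn_in, seed):
    """Metropolis-Hastings chain over sequences under E_alpha.

    Starts from a uniformly random sequence. Each proposal picks a uniform site
    and a uniform new symbol (excluding the current one; symmetric proposal),
    accepts if dE <= 0, else with probability exp(-dE). One sequence is kept
    every `thinning` proposals after `burn_in` proposals.
    """
    np.random.seed(seed)
    n = h.shape[0]
    q = h.shape[1]
    L = n // 2
    seq = np.empty(n, np.int8)
    for i in range(n):
        seq[i] = np.random.randint(0, q)
    ident = seq_overlap(seq)
    out = np.empty((n_keep, n), np.int8)
    kept = 0
    total = burn_in + n_keep * thinning
    for step in range(total):
        i = np.random.randint(0, n)
        a = seq[i]
        b = np.random.randint(0, q - 1)
        if b >= a:
            b += 1
        dh = h[i, b] - h[i, a]
        dj = 0.0
        for j in range(n):
            if j != i and mask[i, j]:
                dj += J[i, j, b, seq[j]] - J[i, j, a, seq[j]]
        p = i + L if i < L else i - L
        new_ident = ident
        if seq[p] == a:
            new_ident -= 1
        if seq[p] == b:
            new_ident += 1
        de = -dh + alpha * (-dj + (lam[new_ident] - lam[ident]))
        if de <= 0.0 or np.random.random() < np.exp(-de):
            seq[i] = b
            ident = new_ident
        if step >= burn_in and (step - burn_in + 1) % thinning == 0:
            out[kept] = seq
            kept += 1
    return out


@njit(cache=True)
def count_observables(seqs, weights, q):
    """Weighted empirical f1 (n, q), f2 (n, n, q, q; upper triangle filled), P(ID)."""
    N, n = seqs.shape
    L = n // 2
    f1 = np.zeros((n, q))
    f2 = np.zeros((n, n, q, q))
    pid = np.zeros(L + 1)
    wsum = 0.0
    for s in range(N):
        w = weights[s]
        wsum += w
        for i in range(n):
            f1[i, seqs[s, i]] += w
            for j in range(i + 1, n):
                f2[i, j, seqs[s, i], seqs[s, j]] += w
        pid[seq_overlap(seqs[s])] += w
    f1 /= wsum
    f2 /= wsum
    pid /= wsum
    return f1, f2, pid


@njit(cache=True)
def _delta_single(seq, h, J, mask, i, b):
    """Energy change of sigma_i -> b with lam = 0."""
    a = seq[i]
    dh = h[i, b] - h[i, a]
    dj = 0.0
    for j in range(seq.shape[0]):
        if j != i and mask[i, j]:
            dj += J[i, j, b, seq[j]] - J[i, j, a, seq[j]]
    return -dh - dj


@njit(cache=True)
def _delta_double(seq, h, J, mask, i, p, b):
    """Energy change of the synchronized double mutation (sigma_i, sigma_p) -> (b, b), lam = 0."""
    a = seq[i]
    dh = h[i, b] - h[i, a] + h[p, b] - h[p, a]
    dj = 0.0
    for j in range(seq.shape[0]):
        if j != i and j != p:
            if mask[i, j]:
                dj += J[i, j, b, seq[j]] - J[i, j, a, seq[j]]
            if mask[p, j]:
                dj += J[p, j, b, seq[j]] - J[p, j, a, seq[j]]
    if mask[i, p]:
        dj += J[i, p, b, b] - J[i, p, a, a]
    return -dh - dj


@njit(cache=True)
def quench_chain(h, J, mask, start, allow_double, seed):
    """Zero-temperature quench: repeatedly pick uniformly among strictly
    energy-decreasing moves until none remains. Moves are all single-site
    substitutions plus, when allow_double and sigma_i == sigma_{i+L},
    synchronized double substitutions of both homologous positions to the same
    new symbol. The overlap multipliers are excluded (lam = 0 by construction).

    Returns (local minimum, number of accepted moves).
    """
    np.random.seed(seed)
    n = start.shape[0]
    q = h.shape[1]
    L = n // 2
    seq = start.copy()
    max_moves = (n + L) * (q - 1)
    msite = np.empty(max_moves, np.int64)
    msym = np.empty(max_moves, np.int64)
    mdouble = np.empty(max_moves, np.uint8)
    steps = 0
    while True:
        cnt = 0
        for i in range(n):
            a = seq[i]
            for b in range(q):
                if b == a:
                    continue
                if _delta_single(seq, h, J, mask, i, b) < 0.0:
                    msite[cnt] = i
                    msym[cnt] = b
                    mdouble[cnt] = 0
                    cnt += 1
        if allow_double:
            for i in range(L):
                if seq[i] == seq[i + L]:
                    a = seq[i]
                    for b in range(q):
                        if b == a:
                            continue
                        if _delta_double(seq, h, J, mask, i, i + L, b) < 0.0:
                            msite[cnt] = i
                            msym[cnt] = b
                            mdouble[cnt] = 1
                            cnt += 1
        if cnt == 0:
            break
        k = np.random.randint(0, cnt)
        i = msite[k]
        b = msym[k]
        seq[i] = b
        if mdouble[k] == 1:
            seq[i + L] = b
        steps += 1
    return seq, steps
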