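"""Reading, curation, and reweighting of two-repeat alignments, and the
empirical observables (site marginals, pair frequencies, repeat-overlap
distribution) that the maximum-entropy models are fit to.

Sequences are stored as integer arrays over the alphabet {0..q-1} with the gap
as the last state (q = 21 for proteins: 20 amino acids + gap). Each row covers
two consecutive repeats of length L, i.e. 2L columns; columns i and i+L are
homologous positions in the two repeats.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import SeqIO

from ._kernels import count_observables, seq_overlap

#: 20 amino acids in alphabetical one-letter order, then the gap.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY-"
GAP = 20


def _symbol_alphabet(q: int) -> str:
    """Display alphabet for a q-state model: amino acids for q=21, generic letters otherwise."""
    if q == 21:
        return AA_ALPHABET
    if q > 27:
        raise ValueError(f"no display alphabet for q={q}")
    return "ABCDEFGHIJKLMNOPQRSTUVWXYZ"[: q - 1] + "-"


@dataclass
class Alignment:
    """A weighted alignment of N two-repeat sequences (N x 2L integer matrix)."""

    sequences: np.ndarray  # (N, 2L) int8
    ids: list
    L: int
    q: int = 21
    weights: np.ndarray = None

    def __post_init__(self):
        self.sequences = np.ascontiguousarray(self.sequences, dtype=np.int8)
        if self.sequences.ndim != 2 or self.sequences.shape[1] != 2 * self.L:
            raise ValueError(
                f"sequence matrix has {self.sequences.shape[1]} columns, expected 2L={2 * self.L}"
            )
        if self.sequences.size and (
            self.sequences.min() < 0 or self.sequences.max() >= self.q
        ):
            raise ValueError(f"symbol indices must lie in [0, {self.q})")
        if self.weights is None:
            self.weights = np.ones(len(self.sequences))
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.sequences),):
            raise ValueError("one weight per sequence required")
        if (self.weights < 0).any():
            raise ValueError("weights must be non-negative")

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    @property
    def n_sites(self) -> int:
        return 2 * self.L


@dataclass
class ObservableSet:
    """Empirical observables of a weighted alignment.

    f1[i, s] is the weighted frequency of symbol s at site i; f2[i, j] the
    (q, q) joint for the ordered pair i < j (stored symmetrically,
    f2[j, i] = f2[i, j].T); p_id[k] the weighted probability that the two
    repeat halves agree at exactly k positions. n_eff is the sum of weights
    (the number of identity clusters under the default weighting).
    """

    f1: np.ndarray  # (2L, q)
    f2: np.ndarray  # (2L, 2L, q, q)
    p_id: np.ndarray  # (L+1,)
    n_eff: float
    L: int
    q: int

    def validate(self, atol: float = 1e-9) -> None:
        n = 2 * self.L
        if not np.allclose(self.f1.sum(axis=1), 1.0, atol=atol):
            raise ValueError("f1 rows must sum to 1")
        if abs(self.p_id.sum() - 1.0) > atol:
            raise ValueError("P(ID) must sum to 1")
        for i in range(n):
            for j in range(i + 1, n):
                blk = self.f2[i, j]
                if abs(blk.sum() - 1.0) > atol:
                    raise ValueError(f"f2({i},{j}) must sum to 1")
                if not np.allclose(blk.sum(axis=1), self.f1[i], atol=atol):
                    raise ValueError(f"f2({i},{j}) row marginal != f1({i})")
                if not np.allclose(blk.sum(axis=0), self.f1[j], atol=atol):
                    raise ValueError(f"f2({i},{j}) column marginal != f1({j})")
                if not np.allclose(self.f2[j, i], blk.T, atol=atol):
                    raise ValueError("f2 must be stored symmetrically")


def read_alignment(path, L: int, alphabet: str = AA_ALPHABET) -> Alignment:
    """Read a FASTA alignment of two-repeat sequences into integer form.

    All records must have exactly 2L columns. '.' is treated as '-'; characters
    outside the alphabet (ambiguity codes X/B/Z/U/O etc.) map to the gap state,
    keeping q fixed without inventing frequencies for rare codes.
    """
    q = len(alphabet)
    lut = np.full(256, q - 1, dtype=np.int8)
    for idx, ch in enumerate(alphabet):
        lut[ord(ch)] = idx
        lut[ord(ch.lower())] = idx
    lut[ord(".")] = q - 1
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    n = 2 * L
    rows, ids = [], []
    for rec in records:
        s = str(rec.seq)
        if len(s) != n:
            raise ValueError(
                f"record '{rec.id}' has length {len(s)}, expected 2L={n}"
            )
        rows.append(lut[np.frombuffer(s.encode("ascii"), dtype=np.uint8)])
        ids.append(rec.id)
    return Alignment(np.array(rows, dtype=np.int8), ids, L, q=q)


def write_alignment(aln: Alignment, path, alphabet: str | None = None) -> None:
    """Write an integer alignment back to FASTA (gap as '-')."""
    alpha = alphabet if alphabet is not None else _symbol_alphabet(aln.q)
    chars = np.frombuffer(alpha.encode("ascii"), dtype=np.uint8)
    with open(path, "w") as fh:
        for sid, row in zip(aln.ids, aln.sequences):
            fh.write(f">{sid}\n")
            fh.write(chars[row].tobytes().decode("ascii") + "\n")


def remove_gappy_columns(aln: Alignment, max_gap_frac: float = 0.8):
    """Drop columns whose gap fraction strictly exceeds max_gap_frac.

    To keep positions i and i+L homologous across the two repeat halves,
    columns are dropped in pairs: if either member of a homologous pair exceeds
    the threshold, both are removed. Returns the curated alignment and the
    indices (into the original 2L columns) that were kept.
    """
    if not (0 < max_gap_frac < 1):
        raise ValueError("max_gap_frac must lie in (0, 1)")
    gap = aln.q - 1
    gap_frac = (aln.sequences == gap).mean(axis=0)
    L = aln.L
    keep_repeat = ~((gap_frac[:L] > max_gap_frac) | (gap_frac[L:] > max_gap_frac))
    if not keep_repeat.any():
        raise ValueError("all columns exceed the gap threshold")
    kept = np.concatenate([np.flatnonzero(keep_repeat), np.flatnonzero(keep_repeat) + L])
    new_L = int(keep_repeat.sum())
    return (
        Alignment(
            aln.sequences[:, kept], list(aln.ids), new_L, q=aln.q, weights=aln.weights.copy()
        ),
        kept,
    )


def cluster_weights(aln: Alignment, identity_threshold: float = 0.9) -> np.ndarray:
    """Greedy incremental identity clustering; weight = 1 / cluster size.

    The first sequence (input order; all rows have equal length) seeds the
    first cluster; each subsequent sequence joins the first cluster whose
    representative matches it at >= identity_threshold of the 2L columns
    (gap counted as an ordinary symbol), else seeds a new cluster. Weights sum
    to the number of clusters, so frequencies computed with them average
    cluster representatives rather than raw database entries.
    """
    if not (0 < identity_threshold < 1):
        raise ValueError("identity_threshold must lie in (0, 1)")
    X = aln.sequences
    N, n_cols = X.shape
    need = identity_threshold * n_cols
    rep_rows = np.empty_like(X)  # representatives, in creation order
    n_reps = 0
    members = np.empty(N, dtype=int)
    for s in range(N):
        if n_reps:
            matches = (rep_rows[:n_reps] == X[s]).sum(axis=1)
            hit = np.flatnonzero(matches >= need)
            if hit.size:
                members[s] = hit[0]  # first matching cluster, greedy order
                continue
        rep_rows[n_reps] = X[s]
        members[s] = n_reps
        n_reps += 1
    sizes = np.bincount(members, minlength=n_reps)
    return 1.0 / sizes[members]


def compute_observables(aln: Alignment) -> ObservableSet:
    """Weighted empirical f1, f2, and P(ID) of the alignment.

    ID(sigma) counts positions i in {1..L} with sigma_i == sigma_{i+L}; the gap
    is a symbol like any other, so two aligned gaps count as a match.
    """
    if aln.L < 1:
        raise ValueError("need at least one column per repeat")
    f1, f2, p_id = count_observables(aln.sequences, aln.weights, aln.q)
    f2 = f2 + np.transpose(f2, (1, 0, 3, 2))  # mirror the upper triangle
    return ObservableSet(
        f1=f1, f2=f2, p_id=p_id, n_eff=float(aln.weights.sum()), L=aln.L, q=aln.q
    )


def overlap_statistic(seq: np.ndarray) -> int:
    """ID(sigma) for a single 2L sequence."""
    return int(seq_overlap(np.ascontiguousarray(seq, dtype=np.int8)))
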