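"""Independent reference implementations used only to check the package.

These are deliberately naive: the Viterbi oracle enumerates every legal
local alignment path, and the alignment oracle is a plain Gotoh affine-gap
DP.  They share no code with the implementations they validate.
"""

from __future__ import annotations

import math

import numpy as np


def brute_force_local_score(model, sequence: str) -> float:
    """Best local alignment score by exhaustive path enumeration.

    Paths start and end in a match state; M and I states consume one
    residue, D consumes none; emissions score log2(p/background), X scores
    0 bits, transitions score log2(p); flanking residues are free.  Only
    feasible for tiny models and sequences.
    """
    from cuprome.phmm import AA_INDEX

    L = model.length
    n = len(sequence)
    bg = model.background

    def esc(table_row, residue) -> float:
        if residue == "X":
            return 0.0
        p = table_row[AA_INDEX[residue]]
        if p <= 0:
            return -math.inf
        return math.log2(p) - math.log2(bg[AA_INDEX[residue]])

    def tsc(k: int, idx: int) -> float:
        p = model.transitions[k, idx]
        return math.log2(p) if p > 0 else -math.inf

    # transition indices (HMMER order)
    TMM, TMI, TMD, TIM, TII, TDM, TDD = range(7)

    best = -math.inf

    def extend(state: str, k: int, i: int, score: float) -> None:
        """state at node k (1-based) having consumed residues up to i."""
        nonlocal best
        if state == "M":
            best = max(best, score)  # may end at any match state
        if state == "M":
            if k < L and i < n:
                extend("M", k + 1, i + 1, score + tsc(k - 1, TMM) + esc(model.match_emissions[k], sequence[i]))
            if i < n:
                extend("I", k, i + 1, score + tsc(k - 1, TMI) + esc(model.insert_emissions[k - 1], sequence[i]))
            if k < L:
                extend("D", k + 1, i, score + tsc(k - 1, TMD))
        elif state == "I":
            if k < L and i < n:
                extend("M", k + 1, i + 1, score + tsc(k - 1, TIM) + esc(model.match_emissions[k], sequence[i]))
            if i < n:
                extend("I", k, i + 1, score + tsc(k - 1, TII) + esc(model.insert_emissions[k - 1], sequence[i]))
        elif state == "D":
            if k < L and i < n:
                extend("M", k + 1, i + 1, score + tsc(k - 1, TDM) + esc(model.match_emissions[k], sequence[i]))
            if k < L:
                extend("D", k + 1, score=score + tsc(k - 1, TDD), i=i)

    for k0 in range(1, L + 1):
        for i0 in range(n):
            entry = esc(model.match_emissions[k0 - 1], sequence[i0])
            extend("M", k0, i0 + 1, entry)
    return best


def gotoh_global_score(a: str, b: str, matrix, gap_open: float = 11.0, gap_extend: float = 1.0) -> float:
    """Optimal global affine-gap alignment score; gap of length k costs
    open + k*extend."""
    n, m = len(a), len(b)
    NEG = -math.inf
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in b (consume a)
    Y = np.full((n + 1, m + 1), NEG)  # gap in a (consume b)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -(gap_open + i * gap_extend)
    for j in range(1, m + 1):
        Y[0, j] = -(gap_open + j * gap_extend)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = matrix[a[i - 1], b[j - 1]]
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(
                M[i - 1, j] - gap_open - gap_extend,
                X[i - 1, j] - gap_extend,
                Y[i - 1, j] - gap_open - gap_extend,
            )
            Y[i, j] = max(
                M[i, j - 1] - gap_open - gap_extend,
                Y[i, j - 1] - gap_extend,
                X[i, j - 1] - gap_open - gap_extend,
            )
    return float(max(M[n, m], X[n, m], Y[n, m]))


def random_profile(rng: np.random.Generator, max_states: int = 4):
    """A random small ProfileHMM for oracle comparisons."""
    from cuprome.phmm import ProfileHMM

    L = int(rng.integers(1, max_states + 1))
    match = rng.dirichlet(np.full(20, 0.5), size=L)
    insert = rng.dirichlet(np.full(20, 5.0), size=L)
    transitions = np.empty((L, 7))
    transitions[:, 0:3] = rng.dirichlet(np.full(3, 2.0), size=L)
    transitions[:, 3:5] = rng.dirichlet(np.full(2, 2.0), size=L)
    transitions[:, 5:7] = rng.dirichlet(np.full(2, 2.0), size=L)
    background = rng.dirichlet(np.full(20, 10.0))
    return ProfileHMM(
        name="rand", accession="RAND",
        match_emissions=match, insert_emissions=insert,
        transitions=transitions, background=background,
    )


def random_sequence(rng: np.random.Generator, max_len: int = 5, allow_x: bool = True) -> str:
    from cuprome.phmm import AMINO_ACIDS

    n = int(rng.integers(1, max_len + 1))
    alphabet = AMINO_ACIDS + ("X" if allow_x else "")
    return "".join(alphabet[int(rng.integers(len(alphabet)))] for _ in range(n))
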