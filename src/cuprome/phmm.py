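"""Profile hidden Markov models for protein homolog search.

This module is the computational core of the copper-resistome pipeline: it
represents profile HMMs (the position-specific models used to find remote
homologs of Cue/Cus/Cop/Pco proteins), reads and writes the HMMER3 ASCII
format they are distributed in, builds small profiles from alignments so the
engine is testable without external model downloads, scores proteins with a
local Viterbi algorithm in log2-odds (bits), and converts bit scores to
E-values under Gumbel statistics.

Scoring semantics
-----------------
The aligner is plan-7-style local: an alignment may begin at any match state
and end at any match state, and unaligned flanking residues cost nothing.
Emission scores are ``log2(p_state(a) / background(a))``; transition scores
are ``log2`` of the transition probabilities.  The ambiguity residue ``X``
scores 0 bits at any state.  One best local alignment is reported per
(model, sequence) pair.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from Bio import SeqIO

#: Amino acids in HMMER column order.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

#: Transition column order within a node (HMMER convention).
TMM, TMI, TMD, TIM, TII, TDM, TDD = range(7)
TRANSITION_NAMES = ("m->m", "m->i", "m->d", "i->m", "i->i", "d->m", "d->d")

#: Log-probability floor standing in for log2(0); keeps DP arithmetic NaN-free.
_NEG = -1.0e30

_EULER_GAMMA = 0.5772156649015329  # for the Gumbel method-of-moments fit


class HmmParseError(ValueError):
    """Raised when a HMMER3 ASCII file cannot be parsed; names the line."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


@dataclass
class ProfileHMM:
    """A profile HMM over the 20 amino acids.

    Parameters
    ----------
    name, accession : str
        Model identifiers (e.g. accession ``"TIGR02044"``).
    match_emissions, insert_emissions : (L, 20) arrays
        Per-node emission distributions, node k on row k-1.
    transitions : (L, 7) array
        Per-node transition probabilities in the order
        ``m->m, m->i, m->d, i->m, i->i, d->m, d->d``.
    background : (20,) array
        Null-model residue distribution.
    viterbi_calibration : (mu, lam) or None
        Gumbel location (bits) and slope (per bit) for E-values.
    insert0_emissions, transitions0 : arrays or None
        Begin-node parameters kept for faithful file round-trips; they do
        not enter local scoring (flanks are free).
    """

    name: str
    accession: str
    match_emissions: np.ndarray
    insert_emissions: np.ndarray
    transitions: np.ndarray
    background: np.ndarray
    viterbi_calibration: tuple[float, float] | None = None
    insert0_emissions: np.ndarray | None = None
    transitions0: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.match_emissions = np.asarray(self.match_emissions, dtype=float)
        self.insert_emissions = np.asarray(self.insert_emissions, dtype=float)
        self.transitions = np.asarray(self.transitions, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        self.validate()

    @property
    def length(self) -> int:
        """Number of match states L."""
        return self.match_emissions.shape[0]

    def validate(self, tol: float = 1e-6) -> None:
        L = self.match_emissions.shape[0]
        if L < 1:
            raise ValueError("profile must have at least one match state")
        if self.match_emissions.shape != (L, 20) or self.insert_emissions.shape != (L, 20):
            raise ValueError("emission arrays must have shape (L, 20)")
        if self.transitions.shape != (L, 7):
            raise ValueError("transition array must have shape (L, 7)")
        for label, arr in (
            ("match emission", self.match_emissions),
            ("insert emission", self.insert_emissions),
        ):
            sums = arr.sum(axis=1)
            if np.any(np.abs(sums - 1.0) > tol):
                raise ValueError(f"{label} rows must sum to 1 (max dev {np.abs(sums-1).max():.2e})")
        if abs(self.background.sum() - 1.0) > tol:
            raise ValueError("background distribution must sum to 1")
        # outgoing groups: from M (MM+MI+MD), from I (IM+II), from D (DM+DD)
        t = self.transitions
        for label, cols in (("M", [TMM, TMI, TMD]), ("I", [TIM, TII]), ("D", [TDM, TDD])):
            sums = t[:, cols].sum(axis=1)
            if np.any(np.abs(sums - 1.0) > tol):
                raise ValueError(f"outgoing transitions from {label} must sum to 1")
        if self.viterbi_calibration is not None:
            mu, lam = self.viterbi_calibration
            if not (lam > 0):
                raise ValueError("calibration lambda must be positive")


def _log2_floor(p: np.ndarray) -> np.ndarray:
    """log2 with zeros mapped to a large negative finite constant."""
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, _NEG)
    pos = p > 0
    out[pos] = np.log2(p[pos])
    return out


def _encode_sequence(sequence: str) -> np.ndarray:
    """Map a protein string to column indices; X becomes -1 (scores 0 bits)."""
    if not sequence:
        raise ValueError("sequence must be non-empty")
    idx = np.empty(len(sequence), dtype=int)
    for i, a in enumerate(sequence.upper()):
        if a == "X":
            idx[i] = -1
        elif a in AA_INDEX:
            idx[i] = AA_INDEX[a]
        else:
            raise ValueError(f"residue {a!r} at position {i + 1} is not an amino acid or X")
    return idx


def viterbi_bitscore(model: ProfileHMM, sequence: str) -> tuple[float, int, int]:
    """Best local alignment score of ``sequence`` under ``model``.

    Returns
    -------
    (bit_score, ali_start, ali_end)
        The optimal log2-odds score and its 1-based inclusive residue
        envelope on the sequence.  Flanking residues outside the envelope
        cost 0 bits; the alignment starts and ends in a match state, so a
        single-residue alignment is legal and the score is never forced
        negative by the flanks.
    """
    seq = _encode_sequence(sequence)
    n = len(seq)
    L = model.length

    bg = model.background
    msc_tab = _emission_bits(model.match_emissions, bg)  # (L, 20)
    isc_tab = _emission_bits(model.insert_emissions, bg)
    t = np.where(model.transitions > 0, np.log2(np.where(model.transitions > 0, model.transitions, 1.0)), _NEG)

    # Per-position emission scores; X (index -1) scores 0 everywhere.
    def col_scores(tab: np.ndarray, a: int) -> np.ndarray:
        return tab[:, a] if a >= 0 else np.zeros(L)

    # cumulative delete-chain costs: S[k] = sum of d->d over nodes 1..k
    S = np.concatenate([[0.0], np.cumsum(t[:, TDD])])  # length L+1

    neg = np.full(L, _NEG)
    Mprev, Iprev, Dprev = neg.copy(), neg.copy(), neg.copy()
    Mstart = np.zeros(L, dtype=int)
    Istart = np.zeros(L, dtype=int)
    Dstart = np.zeros(L, dtype=int)

    best_score = -math.inf
    best_start = best_end = 1

    for i in range(1, n + 1):
        a = seq[i - 1]
        msc = col_scores(msc_tab, a)
        isc = col_scores(isc_tab, a)

        # --- match states: entry (0 bits) vs continuation from node k-1 ---
        contM = np.concatenate([[_NEG], Mprev[:-1] + t[:-1, TMM]])
        contI = np.concatenate([[_NEG], Iprev[:-1] + t[:-1, TIM]])
        contD = np.concatenate([[_NEG], Dprev[:-1] + t[:-1, TDM]])
        prevM = np.concatenate([[0], Mstart[:-1]])
        prevI = np.concatenate([[0], Istart[:-1]])
        prevD = np.concatenate([[0], Dstart[:-1]])
        cand = np.stack([np.zeros(L), contM, contI, contD])  # entry first: wins ties
        which = np.argmax(cand, axis=0)
        Mcur = msc + cand[which, np.arange(L)]
        starts = np.stack([np.full(L, i), prevM, prevI, prevD])
        Mstart_cur = starts[which, np.arange(L)]

        # --- insert states (consume residue, stay at node k) ---
        candI = np.stack([Mprev + t[:, TMI], Iprev + t[:, TII]])
        whichI = np.argmax(candI, axis=0)
        Icur = isc + candI[whichI, np.arange(L)]
        Istart_cur = np.stack([Mstart, Istart])[whichI, np.arange(L)]

        # --- delete states (consume no residue): chain within this column ---
        # D[k] = max_{j<k} M[j] + m->d(j) + sum_{j<l<k} d->d(l), via running max
        vals = Mcur + t[:, TMD] - S[1:]
        runmax = np.maximum.accumulate(vals)
        jnew = np.where(vals >= runmax, np.arange(L), 0)
        jbest = np.maximum.accumulate(jnew)
        Dcur = np.empty(L)
        Dcur[0] = _NEG
        if L > 1:
            Dcur[1:] = S[1:L] + runmax[:-1]
        Dstart_cur = np.empty(L, dtype=int)
        Dstart_cur[0] = i
        if L > 1:
            Dstart_cur[1:] = Mstart_cur[jbest[:-1]]

        # exit from any match state costs 0
        k_end = int(np.argmax(Mcur))
        if Mcur[k_end] > best_score:
            best_score = float(Mcur[k_end])
            best_start = int(Mstart_cur[k_end])
            best_end = i

        Mprev, Iprev, Dprev = Mcur, Icur, Dcur
        Mstart, Istart, Dstart = Mstart_cur, Istart_cur, Dstart_cur

    return best_score, best_start, best_end


def _emission_bits(emissions: np.ndarray, background: np.ndarray) -> np.ndarray:
    bg = np.log2(np.maximum(background, 1e-300))
    return np.where(emissions > 0, np.log2(np.where(emissions > 0, emissions, 1.0)) - bg, _NEG)


def evalue(bit_score: float, model: ProfileHMM, database_size: int) -> float:
    """E-value of a bit score under the model's Gumbel calibration.

    ``E = N * P(S >= s)`` with ``P`` the Gumbel survival function
    ``1 - exp(-exp(-lambda * (s - mu)))``.
    """
    if model.viterbi_calibration is None:
        raise ValueError(
            f"model {model.accession} has no Viterbi calibration; run "
            "calibrate_model() or set viterbi_calibration=(mu, lambda) explicitly"
        )
    if database_size < 1:
        raise ValueError("database_size must be >= 1")
    mu, lam = model.viterbi_calibration
    return float(database_size) * float(stats.gumbel_r.sf(bit_score, loc=mu, scale=1.0 / lam))


def calibrate_model(
    model: ProfileHMM,
    n_decoys: int = 200,
    decoy_length: int | None = None,
    lam: float = math.log(2.0),
    seed: int = 42,
) -> ProfileHMM:
    """Fit the Gumbel location by scoring background-sampled decoys.

    With the slope fixed at ``lam`` (default ln 2, i.e. one bit halves the
    tail probability), ``mu`` is the method-of-moments fit
    ``mean(decoy scores) - EulerGamma / lam``.  The calibration is stored on
    the model in place and the model returned for chaining.
    """
    rng = np.random.default_rng(seed)
    length = decoy_length if decoy_length is not None else max(100, model.length)
    scores = np.empty(n_decoys)
    for d in range(n_decoys):
        residues = rng.choice(list(AMINO_ACIDS), size=length, p=model.background)
        scores[d], _, _ = viterbi_bitscore(model, "".join(residues))
    mu = float(scores.mean()) - _EULER_GAMMA / lam
    model.viterbi_calibration = (mu, lam)
    return model


def search(
    models: Sequence[ProfileHMM],
    proteome: Mapping[str, str] | str | Path,
    max_evalue: float = 1e-30,
):
    """Score every (model, protein) pair and keep hits at ``evalue <= max_evalue``.

    ``proteome`` is a mapping of protein id to sequence, or a path to an
    amino-acid FASTA file.  The effective database size N is the number of
    proteins searched.  Returns a hit table (pandas DataFrame with columns
    protein_id, model_accession, bit_score, evalue, ali_start, ali_end)
    sorted by protein id then ascending e-value.
    """
    import pandas as pd

    if len(models) == 0:
        raise ValueError("at least one profile HMM is required")
    for m in models:
        if m.viterbi_calibration is None:
            raise ValueError(f"model {m.accession} is not calibrated")

    if isinstance(proteome, (str, Path)):
        records = {}
        for rec in SeqIO.parse(str(proteome), "fasta"):
            if rec.id in records:
                raise ValueError(f"duplicate protein id {rec.id!r} in proteome")
            records[rec.id] = str(rec.seq)
        proteome = records
    else:
        ids = list(proteome)
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate protein ids in proteome")

    columns = ["protein_id", "model_accession", "bit_score", "evalue", "ali_start", "ali_end"]
    if len(proteome) == 0:
        warnings.warn("empty proteome: returning empty hit table")
        return pd.DataFrame(columns=columns)

    N = len(proteome)
    rows = []
    for pid, seq in proteome.items():
        for m in models:
            score, a_start, a_end = viterbi_bitscore(m, seq)
            E = evalue(score, m, N)
            if E <= max_evalue:
                rows.append((pid, m.accession, score, E, a_start, a_end))
    table = pd.DataFrame(rows, columns=columns)
    return table.sort_values(["protein_id", "evalue"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# profile construction from alignments
# ---------------------------------------------------------------------------

def build_profile_from_alignment(
    aligned_sequences: Sequence[str],
    name: str = "profile",
    accession: str = "CUSTOM",
    alpha: float = 0.5,
    match_column_max_gap_fraction: float = 0.5,
) -> ProfileHMM:
    """Estimate a profile HMM from an aligned set of protein sequences.

    Columns whose gap fraction is at most ``match_column_max_gap_fraction``
    become match states.  Match emissions use Laplace-style pseudocounts:
    ``m_k(a) = (count_k(a) + alpha) / (n_k + 20 * alpha)``.  The background
    is the overall residue frequency with the same pseudocount, and
    transitions are estimated from the observed per-sequence state paths,
    again with pseudocount ``alpha``.
    """
    if len(aligned_sequences) == 0:
        raise ValueError("at least one aligned sequence is required")
    width = len(aligned_sequences[0])
    if any(len(s) != width for s in aligned_sequences):
        raise ValueError("aligned sequences must all have the same length")
    if alpha < 0:
        raise ValueError("pseudocount alpha must be >= 0")

    seqs = [s.upper() for s in aligned_sequences]
    nseq = len(seqs)
    gap_chars = {"-", "."}

    gap_fraction = [sum(s[c] in gap_chars for s in seqs) / nseq for c in range(width)]
    match_cols = [c for c in range(width) if gap_fraction[c] <= match_column_max_gap_fraction]
    L = len(match_cols)
    if L == 0:
        raise ValueError("no match columns survive the gap-fraction threshold")
    is_match = [False] * width
    for c in match_cols:
        is_match[c] = True

    # emissions
    def _residue_index(a: str, col: int) -> int:
        if a in gap_chars:
            return -1
        if a == "X":
            return -2
        if a not in AA_INDEX:
            raise ValueError(f"residue {a!r} in alignment column {col + 1} is not an amino acid")
        return AA_INDEX[a]

    match_counts = np.zeros((L, 20))
    insert_counts = np.zeros(20)
    total_counts = np.zeros(20)
    for s in seqs:
        for c in range(width):
            r = _residue_index(s[c], c)
            if r < 0:
                continue
            total_counts[r] += 1
            if is_match[c]:
                match_counts[_match_rank(match_cols, c), r] += 1
            else:
                insert_counts[r] += 1

    match_emissions = (match_counts + alpha) / (match_counts.sum(axis=1, keepdims=True) + 20 * alpha)
    if alpha == 0:  # guard divide-by-zero on empty rows (cannot happen: gap fraction <= 0.5 < 1)
        match_emissions = np.nan_to_num(match_emissions, nan=1.0 / 20)
    background = (total_counts + alpha) / (total_counts.sum() + 20 * alpha)
    if background.sum() == 0:
        background = np.full(20, 1.0 / 20)
    if insert_counts.sum() + 20 * alpha > 0:
        insert_row = (insert_counts + alpha) / (insert_counts.sum() + 20 * alpha)
    else:
        insert_row = background.copy()
    insert_emissions = np.tile(insert_row, (L, 1))

    # transitions from observed state paths
    tcounts = np.zeros((L, 7))
    for s in seqs:
        path = []  # (state, node) with state in {M, D, I}
        node = 0
        for c in range(width):
            r = _residue_index(s[c], c)
            if is_match[c]:
                node += 1
                path.append(("M" if r != -1 else "D", node))
            elif r != -1:
                path.append(("I", node))
        for (s1, k1), (s2, _k2) in zip(path, path[1:]):
            if k1 < 1 or k1 > L:
                continue
            key = {
                ("M", "M"): TMM, ("M", "I"): TMI, ("M", "D"): TMD,
                ("I", "M"): TIM, ("I", "I"): TII,
                ("D", "M"): TDM, ("D", "D"): TDD,
            }.get((s1, s2))
            if key is not None:  # plan-7 forbids I<->D; such pairs are dropped
                tcounts[k1 - 1, key] += 1

    transitions = np.empty((L, 7))
    for cols in ([TMM, TMI, TMD], [TIM, TII], [TDM, TDD]):
        grp = tcounts[:, cols] + alpha
        totals = grp.sum(axis=1, keepdims=True)
        uniform = np.full_like(grp, 1.0 / len(cols))
        transitions[:, cols] = np.where(totals > 0, grp / np.where(totals > 0, totals, 1.0), uniform)
    # last node exits to END deterministically
    transitions[L - 1] = [1.0, 0.0, 0.0, 1.0, 0.0, 1.0, 0.0]

    trans0 = np.array([1.0, 0.0, 0.0, 1.0, 0.0, 1.0, 0.0])
    return ProfileHMM(
        name=name,
        accession=accession,
        match_emissions=match_emissions,
        insert_emissions=insert_emissions,
        transitions=transitions,
        background=background,
        insert0_emissions=insert_row.copy(),
        transitions0=trans0,
    )


def _match_rank(match_cols: list[int], c: int) -> int:
    # match_cols is sorted; binary search for the rank of column c
    import bisect

    return bisect.bisect_left(match_cols, c)


# ---------------------------------------------------------------------------
# HMMER3 ASCII input/output
# ---------------------------------------------------------------------------

def _fmt(p: float) -> str:
    """Probability -> negative natural log field; '*' encodes zero."""
    if p <= 0:
        return "*"
    return f"{-math.log(p):.9f}"


def _parse_prob(tok: str, line_no: int) -> float:
    if tok == "*":
        return 0.0
    try:
        return math.exp(-float(tok))
    except ValueError:
        raise HmmParseError(f"non-numeric probability field {tok!r}", line_no) from None


def write_hmm_file(models: Iterable[ProfileHMM], path: str | Path) -> None:
    """Write models in the HMMER3/f ASCII dialect (probabilities as -ln p)."""
    with open(path, "w") as fh:
        for m in models:
            L = m.length
            fh.write("HMMER3/f [cuprome | profile HMM ASCII]\n")
            fh.write(f"NAME  {m.name}\n")
            fh.write(f"ACC   {m.accession}\n")
            fh.write(f"LENG  {L}\n")
            fh.write("ALPH  amino\n")
            if m.viterbi_calibration is not None:
                mu, lam = m.viterbi_calibration
                fh.write(f"STATS LOCAL VITERBI {mu:.5f} {lam:.5f}\n")
            fh.write("HMM          " + "        ".join(AMINO_ACIDS) + "\n")
            fh.write("            " + "     ".join(TRANSITION_NAMES) + "\n")
            fh.write("  COMPO   " + "  ".join(_fmt(p) for p in m.background) + "\n")
            ins0 = m.insert0_emissions if m.insert0_emissions is not None else m.background
            tr0 = m.transitions0 if m.transitions0 is not None else np.array([1, 0, 0, 1, 0, 1, 0], dtype=float)
            fh.write("          " + "  ".join(_fmt(p) for p in ins0) + "\n")
            fh.write("          " + "  ".join(_fmt(p) for p in tr0) + "\n")
            for k in range(L):
                fh.write(f"{k + 1:7d}   " + "  ".join(_fmt(p) for p in m.match_emissions[k]) + f"  {k + 1}  -  -  -  -\n")
                fh.write("          " + "  ".join(_fmt(p) for p in m.insert_emissions[k]) + "\n")
                fh.write("          " + "  ".join(_fmt(p) for p in m.transitions[k]) + "\n")
            fh.write("//\n")


def read_hmm_file(path: str | Path) -> list[ProfileHMM]:
    """Parse a HMMER3 ASCII file ("HMMER3/..." header family) into models.

    Probabilities are recovered from the file's negative-natural-log
    encoding ('*' meaning probability zero).  The Gumbel calibration is
    taken from the ``STATS LOCAL VITERBI`` line when present and left absent
    otherwise.  Malformed headers, a node count disagreeing with ``LENG``,
    or non-numeric emission fields raise :class:`HmmParseError` naming the
    offending line.
    """
    models: list[ProfileHMM] = []
    with open(path) as fh:
        lines = fh.readlines()

    i = 0
    n_lines = len(lines)
    while i < n_lines:
        # skip blank separation
        while i < n_lines and not lines[i].strip():
            i += 1
        if i >= n_lines:
            break
        header = lines[i].strip()
        if not header.startswith("HMMER3/"):
            raise HmmParseError(f"expected HMMER3 header, found {header[:40]!r}", i + 1)
        i += 1
        name = accession = ""
        leng = None
        calibration = None
        while i < n_lines and not lines[i].lstrip().startswith("HMM "):
            fields = lines[i].split()
            if not fields:
                raise HmmParseError("unexpected blank line inside model header", i + 1)
            key = fields[0]
            if key == "NAME":
                name = fields[1] if len(fields) > 1 else ""
            elif key == "ACC":
                accession = fields[1] if len(fields) > 1 else ""
            elif key == "LENG":
                try:
                    leng = int(fields[1])
                except (IndexError, ValueError):
                    raise HmmParseError("LENG must carry an integer", i + 1) from None
            elif key == "STATS" and len(fields) >= 5 and fields[1] == "LOCAL" and fields[2] == "VITERBI":
                try:
                    calibration = (float(fields[3]), float(fields[4]))
                except ValueError:
                    raise HmmParseError("non-numeric STATS LOCAL VITERBI parameters", i + 1) from None
            i += 1
        if leng is None:
            raise HmmParseError("model header lacks a LENG line", i + 1)
        if i >= n_lines:
            raise HmmParseError("file ends before the HMM matrix section", n_lines)
        i += 1  # HMM column-label line
        if i < n_lines and lines[i].split()[:1] == ["m->m"]:
            i += 1  # transition-label line
        background = None
        if i < n_lines and lines[i].split()[:1] == ["COMPO"]:
            toks = lines[i].split()[1:]
            if len(toks) != 20:
                raise HmmParseError("COMPO line must carry 20 fields", i + 1)
            background = np.array([_parse_prob(t, i + 1) for t in toks])
            i += 1
        # begin-node insert emissions and transitions
        ins0 = np.array([_parse_prob(t, i + 1) for t in lines[i].split()])
        if ins0.size != 20:
            raise HmmParseError("node-0 insert line must carry 20 fields", i + 1)
        i += 1
        tr0 = np.array([_parse_prob(t, i + 1) for t in lines[i].split()])
        if tr0.size != 7:
            raise HmmParseError("node-0 transition line must carry 7 fields", i + 1)
        i += 1

        match_rows, insert_rows, trans_rows = [], [], []
        while i < n_lines and lines[i].strip() != "//":
            fields = lines[i].split()
            try:
                node = int(fields[0])
            except ValueError:
                raise HmmParseError(f"expected node index, found {fields[0]!r}", i + 1) from None
            if node != len(match_rows) + 1:
                raise HmmParseError(f"node index {node} out of order", i + 1)
            if len(fields) < 21:
                raise HmmParseError("match emission line carries fewer than 20 fields", i + 1)
            match_rows.append([_parse_prob(t, i + 1) for t in fields[1:21]])
            i += 1
            ins = lines[i].split()
            if len(ins) != 20:
                raise HmmParseError("insert emission line must carry 20 fields", i + 1)
            insert_rows.append([_parse_prob(t, i + 1) for t in ins])
            i += 1
            tr = lines[i].split()
            if len(tr) != 7:
                raise HmmParseError("transition line must carry 7 fields", i + 1)
            trans_rows.append([_parse_prob(t, i + 1) for t in tr])
            i += 1
        if i >= n_lines:
            raise HmmParseError("model not terminated by '//'", n_lines)
        i += 1  # consume '//'
        if len(match_rows) != leng:
            raise HmmParseError(f"node count {len(match_rows)} does not match LENG {leng}", i)

        match_emissions = np.array(match_rows)
        insert_emissions = np.array(insert_rows)
        transitions = np.array(trans_rows)
        # renormalise the file's rounded probabilities and repair the final
        # node's exit group, which HMMER encodes against END
        match_emissions /= match_emissions.sum(axis=1, keepdims=True)
        insert_emissions /= insert_emissions.sum(axis=1, keepdims=True)
        for cols in ([TMM, TMI, TMD], [TIM, TII], [TDM, TDD]):
            grp = transitions[:, cols]
            sums = grp.sum(axis=1, keepdims=True)
            fallback = np.zeros((1, len(cols)))
            fallback[0, 0] = 1.0
            transitions[:, cols] = np.where(sums > 0, grp / np.where(sums > 0, sums, 1.0), fallback)
        if background is None:
            background = np.full(20, 1.0 / 20)
        else:
            background = background / background.sum()
        models.append(
            ProfileHMM(
                name=name or accession,
                accession=accession or name,
                match_emissions=match_emissions,
                insert_emissions=insert_emissions,
                transitions=transitions,
                background=background,
                viterbi_calibration=calibration,
                insert0_emissions=ins0 / ins0.sum() if ins0.sum() > 0 else None,
                transitions0=tr0,
            )
        )
    if not models:
        raise HmmParseError("no models found in file", 1)
    return models
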