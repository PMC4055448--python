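"""Independent brute-force oracles used by the test suite.

Each oracle re-derives a quantity by exhaustive enumeration (feasible
only at toy sizes) and never calls the code path it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from oligomod.sequences import AA_ALPHABET, AA_INDEX, BACKGROUND


# --- random test-instance generators ----------------------------------

def random_profile(rng, length, seq_id="p"):
    """A random but valid SequenceProfile for oracle tests."""
    from oligomod.sequences import SequenceProfile

    freq = rng.dirichlet(np.ones(20), size=length)
    log_odds = rng.normal(0.0, 2.0, size=(length, 20))
    return SequenceProfile(seq_id=seq_id, log_odds=log_odds,
                           frequencies=freq)


def random_hmm(rng, m):
    """A random valid profile HMM with M match states."""
    from oligomod.domains import ProfileHMM

    mat = rng.dirichlet(np.ones(20), size=m)
    ins = rng.dirichlet(np.ones(20), size=m)
    tr = np.zeros((m + 1, 7))
    mmd = rng.dirichlet(np.ones(3), size=m + 1)
    tr[:, 0], tr[:, 1], tr[:, 2] = mmd[:, 0], mmd[:, 1], mmd[:, 2]
    tr[0, 0] = tr[0, 0] + tr[0, 1]
    tr[0, 1] = 0.0  # no I0 state
    imi = rng.dirichlet(np.ones(2), size=m + 1)
    tr[:, 3], tr[:, 4] = imi[:, 0], imi[:, 1]
    dmd = rng.dirichlet(np.ones(2), size=m + 1)
    tr[:, 5], tr[:, 6] = dmd[:, 0], dmd[:, 1]
    return ProfileHMM(name="rand", match_emissions=mat, insert_emissions=ins,
                      transitions=tr)


def random_sequence(rng, length):
    return "".join(AA_ALPHABET[i] for i in rng.integers(0, 20, size=length))


# --- exhaustive alignment enumeration ---------------------------------

def _monotone_match_sets(la: int, lb: int):
    """All non-empty ordered monotone pairings of positions 1..la, 1..lb."""
    for k in range(1, min(la, lb) + 1):
        for rows in itertools.combinations(range(1, la + 1), k):
            for cols in itertools.combinations(range(1, lb + 1), k):
                yield list(zip(rows, cols))


def _gap_charge(length: int, gap_open: float, gap_extend: float) -> float:
    return 0.0 if length == 0 else gap_open + length * gap_extend


def best_alignment_score_bruteforce(
    S: np.ndarray, mode: str, gap_open: float, gap_extend: float
) -> float:
    """Optimal gapped-alignment score by enumerating all match sets.

    Internal gap runs always cost open + len*extend.  In
    ``global-free-ends`` the terminal run of one sequence is free at
    each end (the cheaper side is skipped); in ``local`` flanks cost
    nothing and the empty alignment (score 0) is allowed.
    """
    la, lb = S.shape
    best = 0.0 if mode == "local" else -math.inf
    for pairs in _monotone_match_sets(la, lb):
        score = sum(S[i - 1, j - 1] for i, j in pairs)
        for (i, j), (i2, j2) in zip(pairs, pairs[1:]):
            score -= _gap_charge(i2 - i - 1, gap_open, gap_extend)
            score -= _gap_charge(j2 - j - 1, gap_open, gap_extend)
        if mode == "global-free-ends":
            i0, j0 = pairs[0]
            i1, j1 = pairs[-1]
            score -= min(_gap_charge(i0 - 1, gap_open, gap_extend),
                         _gap_charge(j0 - 1, gap_open, gap_extend))
            score -= min(_gap_charge(la - i1, gap_open, gap_extend),
                         _gap_charge(lb - j1, gap_open, gap_extend))
        best = max(best, score)
    return best


# --- exhaustive plan7 Viterbi path enumeration -------------------------

def best_viterbi_score_bruteforce(hmm, residues: str) -> float:
    """Best local alignment score over all legal state paths.

    Mirrors the scanner's scoring model: entry into any match state at
    any sequence position costs log2(1/M); exit from any match state is
    free; match and insert emissions are scored as log-odds against the
    background; transitions in log2.  Returns -inf if no path exists.
    """
    m = hmm.M
    seq = [AA_INDEX.get(ch, -1) for ch in residues]
    n = len(seq)
    with np.errstate(divide="ignore"):
        lmat = np.log2(hmm.match_emissions / BACKGROUND[None, :])
        lins = np.log2(hmm.insert_emissions / BACKGROUND[None, :])
        ltr = np.log2(hmm.transitions)
    T = {name: col for col, name in
         enumerate(("MM", "MI", "MD", "IM", "II", "DM", "DD"))}
    entry = -math.log2(m)
    best = [-math.inf]

    def emit(kind, k, i):
        a = seq[i - 1]
        if a < 0:
            return 0.0
        return lmat[k - 1, a] if kind == "M" else lins[k - 1, a]

    def walk(state, k, i, score):
        # state in {M, I, D} at node k having consumed i residues
        if state == "M":
            best[0] = max(best[0], score)  # free exit after any match
        if k < m:
            if state == "M" and i < n:
                walk("M", k + 1, i + 1,
                     score + ltr[k, T["MM"]] + emit("M", k + 1, i + 1))
            if state == "I" and i < n:
                walk("M", k + 1, i + 1,
                     score + ltr[k, T["IM"]] + emit("M", k + 1, i + 1))
            if state == "D" and i < n:
                walk("M", k + 1, i + 1,
                     score + ltr[k, T["DM"]] + emit("M", k + 1, i + 1))
            if state == "M":
                walk("D", k + 1, i, score + ltr[k, T["MD"]])
            if state == "D":
                walk("D", k + 1, i, score + ltr[k, T["DD"]])
        if i < n:
            if state == "M":
                walk("I", k, i + 1,
                     score + ltr[k, T["MI"]] + emit("I", k, i + 1))
            if state == "I":
                walk("I", k, i + 1,
                     score + ltr[k, T["II"]] + emit("I", k, i + 1))

    for i0 in range(1, n + 1):
        for k0 in range(1, m + 1):
            walk("M", k0, i0, entry + emit("M", k0, i0))
    return best[0]


# --- exhaustive non-overlapping-subset selection -----------------------

def greedy_architecture_bruteforce(hits):
    """The greedy survivor set, found by exhaustive subset search.

    Enumerates every non-overlapping subset and returns the one whose
    members, listed in priority order (score desc, length desc, name),
    form the lexicographically best-priority sequence — which is the
    subset the greedy rule commits to.
    """
    def key(h):
        return (-h.score, -(h.end - h.start + 1), h.pfam)

    def compatible(subset):
        spans = sorted((h.start, h.end) for h in subset)
        return all(s2 > e1 for (_, e1), (s2, _) in zip(spans, spans[1:]))

    best_subset = None
    best_rank = None
    order = {id(h): i for i, h in enumerate(sorted(hits, key=key))}
    for r in range(len(hits), 0, -1):
        for subset in itertools.combinations(hits, r):
            if not compatible(subset):
                continue
            # maximal only: greedy never leaves an addable hit out
            rest = [h for h in hits if h not in subset]
            if any(compatible(list(subset) + [h]) for h in rest):
                continue
            rank = tuple(sorted(order[id(h)] for h in subset))
            if best_rank is None or rank < best_rank:
                best_rank = rank
                best_subset = subset
    return sorted(best_subset or [], key=lambda h: h.start)


def best_rotamer_bruteforce(entries, build, env, cutoff):
    """Pick the rotamer by exhaustively counting clashes for every entry.

    ``build`` maps a rotamer entry to its candidate atom coordinates.
    Zero-clash entries win by prior; otherwise the minimum clash count,
    ties by prior.
    """
    scored = []
    for entry in entries:
        coords = build(entry)
        if len(env):
            d2 = ((coords[:, None, :] - env[None, :, :]) ** 2).sum(axis=2)
            clashes = int((d2 < cutoff * cutoff).sum())
        else:
            clashes = 0
        scored.append((clashes, -entry.prior, entry))
    scored.sort(key=lambda t: (t[0], t[1]))
    return scored[0][2]
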