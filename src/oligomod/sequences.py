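"""Target sequences and position-specific scoring profiles.

A target is a plain amino-acid sequence over the 20 standard one-letter
codes ('X' tolerated as an unknown residue, scored as background).  A
:class:`SequenceProfile` is the familiar PSSM: for each position a row of
20 estimated residue frequencies and the matching log-odds scores in
half-bit units (the PSI-BLAST ASCII convention), so profiles built here
and profiles read from PSI-BLAST ``-out_ascii_pssm`` files are
interchangeable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Align import substitution_matrices

logger = logging.getLogger(__name__)

#: The 20 standard residues, in the alphabetical one-letter order used by
#: every matrix in this package (also pyhmmer's amino alphabet order).
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}

# BLOSUM62 marginal (background) amino-acid frequencies, renormalized.
_BG = {
    "A": 0.074, "R": 0.052, "N": 0.045, "D": 0.054, "C": 0.025,
    "Q": 0.034, "E": 0.054, "G": 0.074, "H": 0.026, "I": 0.068,
    "L": 0.099, "K": 0.058, "M": 0.025, "F": 0.047, "P": 0.039,
    "S": 0.057, "T": 0.051, "W": 0.013, "Y": 0.032, "V": 0.073,
}
BACKGROUND = np.array([_BG[a] for a in AA_ALPHABET])
BACKGROUND /= BACKGROUND.sum()

# Frequency floor used only inside log2; keeps log-odds finite for
# degenerate (pseudocount-free) profiles.
_FREQ_FLOOR = 1e-6

REJECTED_CODES = set("BZUO")


def _blosum62_half_bits() -> np.ndarray:
    """BLOSUM62 scores as a 20x20 array in AA_ALPHABET order (half-bits)."""
    mat = substitution_matrices.load("BLOSUM62")
    out = np.zeros((20, 20))
    for i, a in enumerate(AA_ALPHABET):
        for j, b in enumerate(AA_ALPHABET):
            out[i, j] = mat[a, b]
    return out


BLOSUM62 = _blosum62_half_bits()

# Conditional substitution mixture P(k | a) ∝ p_k * 2^(S(a,k)/2), derived
# from the half-bit BLOSUM62 scores; rows sum to 1.  Used as the
# pseudocount target so that a single-sequence profile's log-odds reduce
# exactly to the BLOSUM62 rows.
_COND = BACKGROUND[None, :] * np.exp2(BLOSUM62 / 2.0)
SUBSTITUTION_CONDITIONAL = _COND / _COND.sum(axis=1, keepdims=True)


@dataclass
class TargetSequence:
    """A validated amino-acid sequence, optionally with secondary structure.

    Parameters
    ----------
    id : str
        Label taken from the FASTA header.
    residues : str
        Sequence over the 20 standard codes; 'X' permitted (unknown).
    ss : str, optional
        Per-residue secondary structure, one of H/E/C per position.
    ss_conf : sequence of float, optional
        Winning-class confidence in [0, 1] per position.
    """

    id: str
    residues: str
    ss: str | None = None
    ss_conf: np.ndarray | None = None

    def __post_init__(self):
        if not self.residues:
            raise ValueError(f"sequence {self.id!r}: empty sequence")
        for pos, ch in enumerate(self.residues, start=1):
            if ch in REJECTED_CODES:
                raise ValueError(
                    f"sequence {self.id!r}: ambiguous/non-standard residue "
                    f"{ch!r} at position {pos} is not supported"
                )
            if ch != "X" and ch not in AA_INDEX:
                raise ValueError(
                    f"sequence {self.id!r}: illegal character {ch!r} at "
                    f"position {pos}"
                )
        if self.ss is not None:
            if len(self.ss) != len(self.residues):
                raise ValueError(
                    f"sequence {self.id!r}: secondary structure length "
                    f"{len(self.ss)} != sequence length {len(self.residues)}"
                )
            bad = set(self.ss) - set("HEC")
            if bad:
                raise ValueError(f"sequence {self.id!r}: bad ss labels {bad}")
        if self.ss_conf is not None:
            self.ss_conf = np.asarray(self.ss_conf, dtype=float)
            if self.ss_conf.shape != (len(self.residues),):
                raise ValueError(f"sequence {self.id!r}: ss confidence shape")
            if np.any(self.ss_conf < 0) or np.any(self.ss_conf > 1):
                raise ValueError(
                    f"sequence {self.id!r}: ss confidence outside [0,1]"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class SequenceProfile:
    """L x 20 log-odds (half-bits) and frequency matrices for one sequence."""

    seq_id: str
    log_odds: np.ndarray
    frequencies: np.ndarray
    residues: str | None = field(default=None)

    def __post_init__(self):
        self.log_odds = np.asarray(self.log_odds, dtype=float)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.log_odds.ndim != 2 or self.log_odds.shape[1] != 20:
            raise ValueError("log_odds must be L x 20")
        if self.log_odds.shape != self.frequencies.shape:
            raise ValueError("log_odds and frequencies must have equal shape")
        if self.log_odds.shape[0] < 1:
            raise ValueError("empty profile")
        rowsums = self.frequencies.sum(axis=1)
        if np.any(np.abs(rowsums - 1.0) > 1e-9):
            raise ValueError("frequency rows must sum to 1 within 1e-9")

    @property
    def length(self) -> int:
        return self.log_odds.shape[0]


def read_fasta(path, max_sequences: int = 6) -> list[TargetSequence]:
    """Read and validate target sequences from a FASTA file.

    Duplicate sequences are collapsed to the first occurrence (a warning
    is logged); more than ``max_sequences`` distinct sequences is an
    error, reported with the id of the first excess record.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    out: list[TargetSequence] = []
    seen: dict[str, str] = {}
    for rec in records:
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"{path}: record {rec.id!r} has an empty sequence")
        if seq in seen:
            logger.warning(
                "duplicate sequence %r identical to %r collapsed", rec.id,
                seen[seq],
            )
            continue
        if len(out) >= max_sequences:
            raise ValueError(
                f"{path}: more than {max_sequences} distinct sequences "
                f"(first excess record: {rec.id!r})"
            )
        target = TargetSequence(id=rec.id, residues=seq)
        seen[seq] = rec.id
        out.append(target)
    return out


def _henikoff_weights(rows: list[str]) -> np.ndarray:
    """Henikoff position-based sequence weights, normalized to sum 1."""
    n = len(rows)
    length = len(rows[0])
    w = np.zeros(n)
    ncols = 0
    for c in range(length):
        col = [r[c] for r in rows]
        residents = [(i, ch) for i, ch in enumerate(col)
                     if ch in AA_INDEX]
        if not residents:
            continue
        ncols += 1
        counts: dict[str, int] = {}
        for _, ch in residents:
            counts[ch] = counts.get(ch, 0) + 1
        r = len(counts)
        for i, ch in residents:
            w[i] += 1.0 / (r * counts[ch])
    if ncols == 0 or w.sum() == 0:
        return np.full(n, 1.0 / n)
    return w / w.sum()


def build_pssm(
    msa: list[str],
    query_index: int = 0,
    pseudocount_weight: float = 10.0,
) -> SequenceProfile:
    """Build a sequence profile from a gapped multiple sequence alignment.

    Columns gapped in the query row are dropped, so the profile length is
    the ungapped query length.  Rows are deduplicated exactly before
    Henikoff position-based weighting (this makes the profile invariant
    under duplication of any alignment row).  Observed weighted
    frequencies are blended with a BLOSUM62 conditional-substitution
    mixture::

        freq = (alpha * observed + beta * mixture) / (alpha + beta)

    with ``alpha`` = effective sequence count - 1 (mean number of distinct
    residue types per column, gaps excluded) and ``beta`` the
    ``pseudocount_weight``.  When ``alpha + beta == 0`` the raw observed
    frequencies are used.  Log-odds are ``2*log2(freq/background)``
    (half-bits); for a single-sequence alignment with the default
    pseudocounts this reduces to the query's BLOSUM62 rows up to a small
    per-row normalization constant.
    """
    if not msa:
        raise ValueError("empty alignment")
    if not 0 <= query_index < len(msa):
        raise ValueError(f"query_index {query_index} out of range")
    length = len(msa[0])
    for i, row in enumerate(msa):
        if len(row) != length:
            raise ValueError(f"ragged alignment: row {i} has length "
                             f"{len(row)} != {length}")
    msa = [row.upper() for row in msa]
    query_row = msa[query_index]
    keep = [c for c, ch in enumerate(query_row) if ch not in "-."]
    if not keep:
        raise ValueError("query row is entirely gaps")
    query = "".join(query_row[c] for c in keep)
    TargetSequence(id=f"query[{query_index}]", residues=query)

    # Exact deduplication (keeps the query row's copy).
    uniq: list[str] = []
    seen: set[str] = set()
    for row in msa:
        if row not in seen:
            seen.add(row)
            uniq.append(row)
    weights = _henikoff_weights(uniq)

    ncols = len(keep)
    observed = np.zeros((ncols, 20))
    distinct = np.zeros(ncols)
    for out_c, c in enumerate(keep):
        col = [row[c] for row in uniq]
        wsum = 0.0
        types = set()
        for w, ch in zip(weights, col):
            if ch in AA_INDEX:
                observed[out_c, AA_INDEX[ch]] += w
                wsum += w
                types.add(ch)
        if wsum > 0:
            observed[out_c] /= wsum
        distinct[out_c] = len(types)
    neff = distinct.mean() if ncols else 1.0
    alpha = max(neff - 1.0, 0.0)
    beta = float(pseudocount_weight)
    if beta < 0:
        raise ValueError("pseudocount_weight must be nonnegative")

    mixture = observed @ SUBSTITUTION_CONDITIONAL
    if alpha + beta > 0:
        freq = (alpha * observed + beta * mixture) / (alpha + beta)
    else:
        freq = observed.copy()
    # Guard degenerate all-gap columns.
    zero = freq.sum(axis=1) <= 0
    freq[zero] = BACKGROUND
    freq /= freq.sum(axis=1, keepdims=True)

    log_odds = 2.0 * np.log2(np.maximum(freq, _FREQ_FLOOR) / BACKGROUND)
    # Unknown query residues are scored as background.
    for out_c, ch in enumerate(query):
        if ch == "X":
            freq[out_c] = BACKGROUND
            log_odds[out_c] = 0.0
    return SequenceProfile(
        seq_id=f"msa_query_{query_index}", log_odds=log_odds,
        frequencies=freq, residues=query,
    )


def profile_from_sequence(
    target: TargetSequence, pseudocount_weight: float = 10.0
) -> SequenceProfile:
    """Single-sequence fallback profile (BLOSUM62 log-odds rows)."""
    prof = build_pssm([target.residues], 0, pseudocount_weight)
    prof.seq_id = target.id
    return prof


# --- PSI-BLAST ASCII PSSM dialect -------------------------------------

def read_pssm(path) -> SequenceProfile:
    """Read a PSI-BLAST ``-out_ascii_pssm`` file.

    Both the 20 log-odds columns and the 20 percentage columns are
    captured; percentages are renormalized to frequencies (rows that are
    all zero fall back to the background distribution).
    """
    with open(path) as fh:
        lines = fh.readlines()
    header_cols = None
    rows = []
    residues = []
    for lineno, line in enumerate(lines, start=1):
        tokens = line.split()
        if header_cols is None:
            if len(tokens) >= 40 and all(t in AA_INDEX for t in tokens[:40]):
                header_cols = tokens[:40]
            continue
        if not tokens:
            continue
        if not tokens[0].isdigit():
            break  # footer (statistics lines)
        if len(tokens) < 42:
            raise ValueError(
                f"{path}: truncated PSSM row at line {lineno} "
                f"({len(tokens)} fields, expected >= 42)"
            )
        idx = int(tokens[0])
        if idx != len(rows) + 1:
            raise ValueError(
                f"{path}: row index {idx} at line {lineno} out of order"
            )
        residues.append(tokens[1])
        try:
            rows.append([float(t) for t in tokens[2:42]])
        except ValueError as exc:
            raise ValueError(f"{path}: bad number at line {lineno}: {exc}")
    if header_cols is None:
        raise ValueError(f"{path}: malformed header (no 40-letter column line)")
    if not rows:
        raise ValueError(f"{path}: no PSSM rows found")
    arr = np.array(rows)
    log_odds = np.zeros((len(rows), 20))
    freq = np.zeros((len(rows), 20))
    for col, aa in enumerate(header_cols[:20]):
        log_odds[:, AA_INDEX[aa]] = arr[:, col]
    for col, aa in enumerate(header_cols[20:40]):
        freq[:, AA_INDEX[aa]] = arr[:, 20 + col]
    sums = freq.sum(axis=1, keepdims=True)
    empty = sums[:, 0] <= 0
    freq[empty] = BACKGROUND
    sums = freq.sum(axis=1, keepdims=True)
    freq = freq / sums
    return SequenceProfile(
        seq_id=str(path), log_odds=log_odds, frequencies=freq,
        residues="".join(residues),
    )


def write_pssm(profile: SequenceProfile, path) -> None:
    """Write a profile in the PSI-BLAST ASCII dialect read by read_pssm.

    Log-odds and percentages are printed as integers, matching
    PSI-BLAST; one read/write cycle is therefore quantizing, after which
    read -> write -> read is the identity.
    """
    residues = profile.residues or "A" * profile.length
    with open(path, "w") as fh:
        fh.write("\nLast position-specific scoring matrix computed\n")
        fh.write(" " * 11 + "  ".join(AA_ALPHABET) + "   "
                 + "  ".join(AA_ALPHABET) + "\n")
        for i in range(profile.length):
            lo = " ".join(f"{int(round(v)):3d}" for v in profile.log_odds[i])
            # largest-remainder quantization: percents sum to exactly 100,
            # so write -> read -> write is the identity
            raw = profile.frequencies[i] * 100.0
            ints = np.floor(raw).astype(int)
            short = 100 - ints.sum()
            order = np.argsort(-(raw - ints), kind="stable")
            ints[order[:short]] += 1
            pc = " ".join(f"{v:3d}" for v in ints)
            fh.write(f"{i + 1:5d} {residues[i]}  {lo}  {pc}\n")


def read_ss2(path, target: TargetSequence) -> TargetSequence:
    """Attach a PSIPRED ``.ss2`` prediction to a target sequence.

    The ss2 residue column must match ``target.residues`` exactly; the
    winning-class probability is stored as the per-residue confidence.
    """
    labels = []
    confs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens or tokens[0].startswith("#"):
                continue
            if len(tokens) < 6:
                raise ValueError(f"{path}: malformed ss2 row at line {lineno}")
            idx, aa, label = int(tokens[0]), tokens[1], tokens[2]
            pc, ph, pe = (float(tokens[3]), float(tokens[4]), float(tokens[5]))
            pos = len(labels) + 1
            if idx != pos:
                raise ValueError(f"{path}: row index {idx} at line {lineno}, "
                                 f"expected {pos}")
            if pos > len(target.residues):
                raise ValueError(
                    f"{path}: more rows than residues in {target.id!r}"
                )
            if aa != target.residues[pos - 1]:
                raise ValueError(
                    f"{path}: residue mismatch at position {pos}: ss2 has "
                    f"{aa!r}, sequence {target.id!r} has "
                    f"{target.residues[pos - 1]!r}"
                )
            if label not in "CHE":
                raise ValueError(f"{path}: bad ss label {label!r} at line "
                                 f"{lineno}")
            conf = {"C": pc, "H": ph, "E": pe}[label]
            if not 0.0 <= conf <= 1.0:
                raise ValueError(
                    f"{path}: confidence {conf} outside [0,1] at line {lineno}"
                )
            labels.append(label)
            confs.append(conf)
    if len(labels) != len(target.residues):
        raise ValueError(
            f"{path}: {len(labels)} ss2 rows for sequence of length "
            f"{len(target.residues)}"
        )
    return TargetSequence(
        id=target.id, residues=target.residues,
        ss="".join(labels), ss_conf=np.array(confs),
    )
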