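"""Profile-profile and transitive alignment, identity metrics, analyses.

Two alignment routes coexist here.  The direct route aligns two sequence
profiles by affine-gap dynamic programming under a symmetric
cross-product column score.  The transitive route never aligns the two
sequences at all: each is aligned to the same profile HMM and residues
mapped to the same match state are paired, which is how family-wide
identity statistics are computed without any pairwise search.

Also included: minimum within-family identity, a Gaussian kernel density
estimate over identity percentages, and the interface-cluster filter and
overlap classifier used to reason about recurring crystal interfaces.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .domains import DomainHit
from .sequences import SequenceProfile

logger = logging.getLogger(__name__)

GAP_OPEN_DEFAULT = 7.0
GAP_EXTEND_DEFAULT = 0.7


@dataclass
class PairAlignment:
    """A gapped alignment of two sequences.

    ``columns`` is an ordered list of ``(pos_a, pos_b)`` with 1-based
    positions or ``None`` for a gap; no column is gapped in both rows and
    each row's positions are strictly increasing.
    """

    id_a: str
    id_b: str
    columns: list[tuple[int | None, int | None]]
    score: float = 0.0

    def __post_init__(self):
        prev_a = prev_b = 0
        for col_no, (pa, pb) in enumerate(self.columns, start=1):
            if pa is None and pb is None:
                raise ValueError(f"column {col_no}: gap in both rows")
            if pa is not None:
                if pa <= prev_a:
                    raise ValueError(
                        f"column {col_no}: positions of {self.id_a!r} not "
                        f"strictly increasing"
                    )
                prev_a = pa
            if pb is not None:
                if pb <= prev_b:
                    raise ValueError(
                        f"column {col_no}: positions of {self.id_b!r} not "
                        f"strictly increasing"
                    )
                prev_b = pb

    @property
    def match_columns(self) -> list[tuple[int, int]]:
        return [(a, b) for a, b in self.columns
                if a is not None and b is not None]

    def swapped(self) -> "PairAlignment":
        return PairAlignment(
            id_a=self.id_b, id_b=self.id_a,
            columns=[(b, a) for a, b in self.columns], score=self.score,
        )


@dataclass
class ClusterRecord:
    """One interface cluster: recurring contact across crystal forms."""

    cluster_id: str
    pfams: tuple[str, ...]
    entries: frozenset[str]
    crystal_forms: int
    min_identity: float

    def __post_init__(self):
        self.pfams = tuple(self.pfams)
        self.entries = frozenset(self.entries)
        if not 1 <= len(self.pfams) <= 2:
            raise ValueError(f"cluster {self.cluster_id}: need 1 or 2 pfams")
        if self.crystal_forms < 1:
            raise ValueError(f"cluster {self.cluster_id}: crystal_forms >= 1")
        if not 0.0 <= self.min_identity <= 100.0:
            raise ValueError(
                f"cluster {self.cluster_id}: min_identity outside [0, 100]"
            )


def column_score(a: SequenceProfile, b: SequenceProfile) -> np.ndarray:
    """Symmetric cross-product score matrix, S[i, j] in half-bits.

    S(i, j) = 1/2 * sum_k( lo_a(i,k) f_b(j,k) + lo_b(j,k) f_a(i,k) ).
    """
    return 0.5 * (a.log_odds @ b.frequencies.T
                  + (b.log_odds @ a.frequencies.T).T)


def profile_profile_align(
    a: SequenceProfile,
    b: SequenceProfile,
    mode: str = "global-free-ends",
    gap_open: float = GAP_OPEN_DEFAULT,
    gap_extend: float = GAP_EXTEND_DEFAULT,
) -> PairAlignment:
    """Optimal affine-gap alignment of two profiles.

    A gap of length g costs ``gap_open + g * gap_extend`` (half-bits).
    ``global-free-ends`` is a semiglobal alignment: every maximal gap
    run is charged except that at each end of the alignment the
    terminal run of one sequence is free (the alignment may skip a
    prefix of one sequence and a suffix of one sequence without cost;
    skipped flanks appear as explicit gap columns).  ``local`` is
    Smith-Waterman-style: the best-scoring block alone, empty if
    nothing scores above zero.  Gap-in-a immediately following gap-in-b
    (and vice versa) is allowed and charged as two runs.  Traceback
    ties prefer a match column over consuming ``a`` over consuming
    ``b``, making the output reproducible bit for bit.
    """
    if mode not in ("global-free-ends", "local"):
        raise ValueError(f"unknown mode {mode!r}")
    if not (np.all(np.isfinite(a.log_odds)) and np.all(np.isfinite(b.log_odds))
            and np.all(np.isfinite(a.frequencies))
            and np.all(np.isfinite(b.frequencies))):
        raise ValueError("non-finite profile values")
    S = column_score(a, b)
    la, lb = a.length, b.length
    NEG = float("-inf")
    local = mode == "local"
    # M: column i aligned to j; X: consumes a against a gap; Y: consumes b.
    M = np.full((la + 1, lb + 1), NEG)
    X = np.full((la + 1, lb + 1), NEG)
    Y = np.full((la + 1, lb + 1), NEG)
    # pointer codes: 0 start/boundary, 1 from M, 2 from X, 3 from Y
    ptrM = np.zeros((la + 1, lb + 1), dtype=np.int8)
    ptrX = np.zeros((la + 1, lb + 1), dtype=np.int8)
    ptrY = np.zeros((la + 1, lb + 1), dtype=np.int8)
    open_cost = gap_open + gap_extend
    if not local:
        M[0, 0] = 0.0
        X[1:, 0] = 0.0   # free leading gap run in b (skip a prefix of a)
        Y[0, 1:] = 0.0   # free leading gap run in a

    def _pick(cands):
        # candidates ordered worst-to-best tie preference; >= keeps later
        best, src = cands[0]
        for val, tag in cands[1:]:
            if val >= best:
                best, src = val, tag
        return best, src

    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            s = S[i - 1, j - 1]
            diag = [(Y[i - 1, j - 1], 3), (X[i - 1, j - 1], 2),
                    (M[i - 1, j - 1], 1)]
            if local:
                diag.insert(0, (0.0, 0))
            best, src = _pick(diag)
            M[i, j] = s + best
            ptrM[i, j] = src
            bx, sx = _pick([(Y[i - 1, j] - open_cost, 3),
                            (X[i - 1, j] - gap_extend, 2),
                            (M[i - 1, j] - open_cost, 1)])
            X[i, j], ptrX[i, j] = bx, sx
            by, sy = _pick([(Y[i, j - 1] - gap_extend, 3),
                            (X[i, j - 1] - open_cost, 2),
                            (M[i, j - 1] - open_cost, 1)])
            Y[i, j], ptrY[i, j] = by, sy

    if local:
        best_score, bi, bj, bstate = NEG, 0, 0, 1
        for i in range(1, la + 1):
            for j in range(1, lb + 1):
                if M[i, j] > best_score:
                    best_score, bi, bj = M[i, j], i, j
        if best_score <= 0:
            return PairAlignment(id_a=a.seq_id, id_b=b.seq_id, columns=[],
                                 score=0.0)
    else:
        # free trailing run: end anywhere on the bottom row or right column
        best_score, bi, bj, bstate = NEG, la, lb, 1
        ends = [(la, j) for j in range(1, lb + 1)] + \
               [(i, lb) for i in range(1, la + 1)]
        for i, j in ends:
            for state, mat in ((3, Y), (2, X), (1, M)):
                if mat[i, j] >= best_score:
                    best_score, bi, bj, bstate = mat[i, j], i, j, state
        if not np.isfinite(best_score):
            raise ValueError("no finite alignment found")

    cols: list[tuple[int | None, int | None]] = []
    i, j, state = bi, bj, bstate
    while True:
        if state == 1:
            if i == 0 and j == 0:
                break
            cols.append((i, j))
            src = ptrM[i, j]
            i, j = i - 1, j - 1
            if src == 0:
                break
            state = src
        elif state == 2:
            if j == 0:
                break  # free leading run boundary
            cols.append((i, None))
            src = ptrX[i, j]
            i = i - 1
            state = src
        else:
            if i == 0:
                break
            cols.append((None, j))
            src = ptrY[i, j]
            j = j - 1
            state = src
    cols.reverse()

    if not local and cols:
        # materialize the free terminal runs as explicit gap columns
        first_a = min((ca for ca, _ in cols if ca is not None),
                      default=la + 1)
        first_b = min((cb for _, cb in cols if cb is not None),
                      default=lb + 1)
        last_a = max((ca for ca, _ in cols if ca is not None), default=la)
        last_b = max((cb for _, cb in cols if cb is not None), default=lb)
        lead = [(p, None) for p in range(1, first_a)] + \
               [(None, p) for p in range(1, first_b)]
        trail = [(p, None) for p in range(last_a + 1, la + 1)] + \
                [(None, p) for p in range(last_b + 1, lb + 1)]
        cols = lead + cols + trail
    return PairAlignment(id_a=a.seq_id, id_b=b.seq_id, columns=cols,
                         score=float(best_score))


def transitive_align(hit_a: DomainHit, hit_b: DomainHit) -> PairAlignment:
    """Pair residues of two sequences mapped to the same HMM match state.

    Both hits must carry a non-empty ``match_map`` against the same
    profile; the result's columns are ordered by match state and contain
    no gaps.
    """
    if hit_a.pfam != hit_b.pfam:
        raise ValueError(
            f"hits against different HMMs: {hit_a.pfam!r} vs {hit_b.pfam!r}"
        )
    if not hit_a.match_map or not hit_b.match_map:
        raise ValueError("transitive alignment requires non-empty match maps")
    map_a = dict((m, p) for p, m in hit_a.match_map)
    map_b = dict((m, p) for p, m in hit_b.match_map)
    shared = sorted(set(map_a) & set(map_b))
    if not shared:
        raise ValueError(
            f"no shared match states between hits on {hit_a.seq_id!r} "
            f"and {hit_b.seq_id!r}"
        )
    cols = [(map_a[m], map_b[m]) for m in shared]
    return PairAlignment(id_a=hit_a.seq_id, id_b=hit_b.seq_id, columns=cols)


def identity(aln: PairAlignment, seq_a: str, seq_b: str) -> float:
    """Percent identity over gap-free columns.

    The denominator is the number of columns aligned in both rows (not
    the alignment length and not the shorter sequence length).  Returns
    0 with a warning when there is no gap-free column.
    """
    pairs = aln.match_columns
    if not pairs:
        logger.warning("alignment %s/%s has no gap-free columns",
                       aln.id_a, aln.id_b)
        return 0.0
    same = 0
    for pa, pb in pairs:
        if pa > len(seq_a) or pb > len(seq_b):
            raise ValueError(
                f"alignment position ({pa}, {pb}) outside sequence bounds"
            )
        if seq_a[pa - 1] == seq_b[pb - 1]:
            same += 1
    return 100.0 * same / len(pairs)


def gap_percentage(aln: PairAlignment) -> float:
    """Percent of alignment columns containing a gap in either row."""
    if not aln.columns:
        return 0.0
    gapped = sum(1 for a, b in aln.columns if a is None or b is None)
    return 100.0 * gapped / len(aln.columns)


def min_family_identity(
    hits_by_pfam: dict[str, list[DomainHit]],
    sequences: dict[str, str],
) -> dict[str, float]:
    """Minimum pairwise transitive identity within each family.

    Families with fewer than two members are skipped (with a log
    notice); pairs whose hits share no match state are skipped likewise.
    """
    out: dict[str, float] = {}
    for pfam, hits in hits_by_pfam.items():
        if len(hits) < 2:
            logger.info("family %s has < 2 members; skipped", pfam)
            continue
        lowest = None
        for i in range(len(hits)):
            for j in range(i + 1, len(hits)):
                try:
                    aln = transitive_align(hits[i], hits[j])
                except ValueError:
                    continue
                ident = identity(aln, sequences[hits[i].seq_id],
                                 sequences[hits[j].seq_id])
                lowest = ident if lowest is None else min(lowest, ident)
        if lowest is not None:
            out[pfam] = lowest
    return out


def silverman_bandwidth(values: np.ndarray) -> float:
    """Silverman's rule of thumb, h = 0.9 min(sd, IQR/1.34) n^(-1/5)."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    sd = values.std(ddof=1)
    q75, q25 = np.percentile(values, [75, 25])
    iqr = q75 - q25
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread <= 0:
        spread = max(abs(values).max(), 1.0) * 1e-3
    return 0.9 * spread * n ** (-0.2)


def kde(
    values,
    bandwidth="auto",
    grid: np.ndarray | None = None,
    npoints: int = 512,
):
    """Gaussian kernel density estimate over identity percentages.

    ``bandwidth`` is the kernel standard deviation in percent units, or
    "auto" for Silverman's rule.  Returns ``(grid, density)``; the default
    grid spans [0, 100].  Over a grid wide enough to contain essentially
    all kernel mass the trapezoidal integral of the density is 1 within
    1e-3.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("kde needs at least 2 values")
    if bandwidth == "auto":
        h = silverman_bandwidth(values)
    else:
        h = float(bandwidth)
        if h <= 0:
            raise ValueError("bandwidth must be positive")
    if grid is None:
        grid = np.linspace(0.0, 100.0, npoints)
    grid = np.asarray(grid, dtype=float)
    z = (grid[:, None] - values[None, :]) / h
    dens = np.exp(-0.5 * z * z).sum(axis=1) / (
        len(values) * h * math.sqrt(2.0 * math.pi)
    )
    return grid, dens


def filter_clusters(
    clusters: list[ClusterRecord],
    min_crystal_forms: int = 5,
    max_min_identity: float = 90.0,
) -> list[ClusterRecord]:
    """Keep clusters with >= ``min_crystal_forms`` crystal forms and
    minimum identity strictly below ``max_min_identity`` percent."""
    return [c for c in clusters
            if c.crystal_forms >= min_crystal_forms
            and c.min_identity < max_min_identity]


def classify_cluster_overlap(a: ClusterRecord, b: ClusterRecord) -> str:
    """'disjoint' iff the two clusters share no PDB entry.

    The catalogue rows carry entry sets only, so crystal-form overlap is
    assessed at entry granularity.
    """
    return "disjoint" if not (a.entries & b.entries) else "overlapping"


# --- Serialization -----------------------------------------------------

def write_alignment_fasta(
    aln: PairAlignment, seq_a: str, seq_b: str, path
) -> None:
    """Serialize an alignment as two-record gapped FASTA (A2M dialect).

    Users may hand-edit the gap placement and feed the file back to
    model building; validity is re-checked on read.
    """
    row_a = []
    row_b = []
    for pa, pb in aln.columns:
        row_a.append(seq_a[pa - 1] if pa is not None else "-")
        row_b.append(seq_b[pb - 1] if pb is not None else "-")
    with open(path, "w") as fh:
        fh.write(f">{aln.id_a}\n{''.join(row_a)}\n")
        fh.write(f">{aln.id_b}\n{''.join(row_b)}\n")


def read_alignment_fasta(path, start_a: int = 1, start_b: int = 1
                         ) -> tuple[PairAlignment, str, str]:
    """Read a two-record gapped FASTA alignment written (or edited) by
    :func:`write_alignment_fasta`.  Returns the alignment plus the two
    ungapped sequences it encodes; positions are numbered from
    ``start_a``/``start_b``."""
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 2:
        raise ValueError(f"{path}: expected exactly 2 records, "
                         f"found {len(records)}")
    row_a, row_b = (str(r.seq) for r in records)
    if len(row_a) != len(row_b):
        raise ValueError(f"{path}: rows differ in length")
    cols = []
    pa, pb = start_a - 1, start_b - 1
    seq_a = []
    seq_b = []
    for ca, cb in zip(row_a, row_b):
        ga, gb = ca in "-.", cb in "-."
        if ga and gb:
            continue
        if not ga:
            pa += 1
            seq_a.append(ca.upper())
        if not gb:
            pb += 1
            seq_b.append(cb.upper())
        cols.append((None if ga else pa, None if gb else pb))
    aln = PairAlignment(id_a=records[0].id, id_b=records[1].id, columns=cols)
    return aln, "".join(seq_a), "".join(seq_b)


CLUSTER_COLUMNS = ["cluster_id", "pfams", "entries", "crystal_forms",
                   "min_identity"]


def read_cluster_table(path) -> list[ClusterRecord]:
    """Read an interface-cluster TSV (pfams and entries comma-joined)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(CLUSTER_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing cluster columns {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        out.append(ClusterRecord(
            cluster_id=row["cluster_id"],
            pfams=tuple(row["pfams"].split(",")),
            entries=frozenset(row["entries"].split(",")),
            crystal_forms=int(row["crystal_forms"]),
            min_identity=float(row["min_identity"]),
        ))
    return out


def write_cluster_table(clusters: list[ClusterRecord], path) -> None:
    rows = [[c.cluster_id, ",".join(c.pfams), ",".join(sorted(c.entries)),
             c.crystal_forms, c.min_identity] for c in clusters]
    pd.DataFrame(rows, columns=CLUSTER_COLUMNS).to_csv(
        path, sep="\t", index=False
    )
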