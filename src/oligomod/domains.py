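"""Domain assignment and template-architecture search.

Sequences are annotated with Pfam-style domains either by the built-in
profile-HMM scanner (:func:`viterbi_scan`, a local plan7 Viterbi in log
space) or by ingesting HMMER3 ``domtblout`` files.  The ordered list of
surviving domains is the sequence's *domain architecture*; template
biological assemblies are ranked by the similarity of their entities'
architectures to the targets'.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sequences import AA_ALPHABET, AA_INDEX, BACKGROUND, TargetSequence

logger = logging.getLogger(__name__)

NEG_INF = float("-inf")

# Plan7 core transition columns, per node k:
#   M_k->M_{k+1}, M_k->I_k, M_k->D_{k+1}, I_k->M_{k+1}, I_k->I_k,
#   D_k->M_{k+1}, D_k->D_{k+1}
TRANS_COLS = ("MM", "MI", "MD", "IM", "II", "DM", "DD")
_T = {name: i for i, name in enumerate(TRANS_COLS)}

DEFAULT_BITSCORE_CUTOFF = 10.0
DEFAULT_MAX_HITS = 5


@dataclass
class ProfileHMM:
    """A plan7-style profile HMM over the 20-letter amino alphabet.

    ``transitions`` has shape (M+1, 7); row 0 holds the begin-node
    transitions (B->M1 in the MM slot, B->D1 in MD, MI unused and 0) and
    row k the transitions out of node k.  Emission rows and each state's
    outgoing transition triples sum to 1.
    """

    name: str
    match_emissions: np.ndarray   # (M, 20), row k-1 emits at match state k
    insert_emissions: np.ndarray  # (M, 20)
    transitions: np.ndarray       # (M+1, 7)

    def __post_init__(self):
        self.match_emissions = np.asarray(self.match_emissions, dtype=float)
        self.insert_emissions = np.asarray(self.insert_emissions, dtype=float)
        self.transitions = np.asarray(self.transitions, dtype=float)
        m = self.M
        if m < 1:
            raise ValueError("HMM must have at least one match state")
        if self.insert_emissions.shape != (m, 20):
            raise ValueError("insert_emissions must be M x 20")
        if self.transitions.shape != (m + 1, 7):
            raise ValueError("transitions must be (M+1) x 7")
        for arr, what in ((self.match_emissions, "match"),
                          (self.insert_emissions, "insert")):
            if np.any(np.abs(arr.sum(axis=1) - 1.0) > 1e-9):
                raise ValueError(f"{what} emission rows must sum to 1")
        tr = self.transitions
        for cols in (("MM", "MI", "MD"), ("IM", "II"), ("DM", "DD")):
            s = sum(tr[:, _T[c]] for c in cols)
            bad = np.abs(s - 1.0) > 1e-9
            if cols != ("MM", "MI", "MD"):
                bad[0] = False  # the begin node has no insert/delete state
            if np.any(bad):
                raise ValueError(
                    f"outgoing transitions {cols} must sum to 1 per state"
                )

    @property
    def M(self) -> int:
        return self.match_emissions.shape[0]


@dataclass
class DomainHit:
    """One domain located on a sequence.

    ``match_map`` lists (sequence position, match state) pairs, 1-based
    and strictly increasing in both coordinates; it is the anchor for
    transitive alignment through shared match states.
    """

    pfam: str
    seq_id: str
    start: int
    end: int
    score: float
    match_map: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        if not 1 <= self.start <= self.end:
            raise ValueError(
                f"hit {self.pfam} on {self.seq_id}: bad interval "
                f"[{self.start}, {self.end}]"
            )
        prev = (0, 0)
        for pos, state in self.match_map:
            if not self.start <= pos <= self.end:
                raise ValueError(
                    f"hit {self.pfam} on {self.seq_id}: match_map position "
                    f"{pos} outside [{self.start}, {self.end}]"
                )
            if pos <= prev[0] or state <= prev[1]:
                raise ValueError(
                    f"hit {self.pfam} on {self.seq_id}: match_map not "
                    f"strictly increasing at ({pos}, {state})"
                )
            prev = (pos, state)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class DomainArchitecture:
    """Ordered, non-overlapping domain annotations along one sequence."""

    seq_id: str
    domains: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self):
        prev_end = 0
        prev_start = 0
        for pfam, start, end in self.domains:
            if start < prev_start:
                raise ValueError(f"{self.seq_id}: domains not sorted by start")
            if start <= prev_end:
                raise ValueError(f"{self.seq_id}: overlapping domains")
            prev_start, prev_end = start, end

    @property
    def names(self) -> list[str]:
        return [p for p, _, _ in self.domains]

    def __str__(self) -> str:
        return "".join(f"({p})" for p in self.names) or "(none)"


@dataclass
class TemplateRecord:
    """A catalogue row set: one PDB entry with entities and assemblies."""

    pdb_id: str
    resolution: float | None
    entities: list[tuple[str, str, DomainArchitecture]]
    assemblies: list[tuple[str, dict[str, int]]]

    def __post_init__(self):
        known = {eid for eid, _, _ in self.entities}
        for aid, comp in self.assemblies:
            for eid, count in comp.items():
                if eid not in known:
                    raise ValueError(
                        f"{self.pdb_id} assembly {aid}: unknown entity {eid}"
                    )
                if not (isinstance(count, (int, np.integer)) and count > 0):
                    raise ValueError(
                        f"{self.pdb_id} assembly {aid}: copy count for "
                        f"entity {eid} must be a positive integer"
                    )

    def entity_architecture(self, entity_id: str) -> DomainArchitecture:
        for eid, _, arch in self.entities:
            if eid == entity_id:
                return arch
        raise KeyError(entity_id)

    def entity_sequence(self, entity_id: str) -> str:
        for eid, seq, _ in self.entities:
            if eid == entity_id:
                return seq
        raise KeyError(entity_id)


# --- HMM construction and ingestion -----------------------------------

def hmm_from_msa(
    name: str,
    msa: list[str],
    match_gap_threshold: float = 0.5,
    pseudocount: float = 1.0,
    transition_pseudocount: float = 0.1,
) -> ProfileHMM:
    """Build a profile HMM from an aligned family by smoothed ML counts.

    Columns with a gap fraction below ``match_gap_threshold`` become
    match states; emission probabilities are maximum-likelihood counts
    with Laplace (add-``pseudocount``) smoothing.  Transitions use the
    lighter ``transition_pseudocount`` (an add-one prior over the 3-way
    match split would overwhelm small families and flatten the model's
    match-to-match backbone).
    """
    if not msa:
        raise ValueError("empty alignment")
    length = len(msa[0])
    if any(len(r) != length for r in msa):
        raise ValueError("ragged alignment")
    msa = [r.upper() for r in msa]
    n = len(msa)
    is_match = []
    for c in range(length):
        gaps = sum(1 for r in msa if r[c] in "-.")
        is_match.append(gaps / n < match_gap_threshold)
    m = sum(is_match)
    if m == 0:
        raise ValueError("no match columns under the gap threshold")

    mat = np.full((m, 20), pseudocount)
    ins = np.full((m, 20), pseudocount)
    # transition counts per node 0..M
    tcounts = np.full((m + 1, 7), transition_pseudocount)
    tcounts[0, _T["MI"]] = 0.0  # no I0 in this simplified architecture

    match_index = np.cumsum(is_match)  # 1-based match state per column
    for row in msa:
        state = "M"  # pseudo begin treated as a match at node 0
        node = 0
        for c in range(length):
            ch = row[c]
            gapped = ch in "-."
            if is_match[c]:
                k = match_index[c]
                if gapped:
                    tcounts[node, _T[state + "D"]] += 1
                    state, node = "D", k
                else:
                    if ch in AA_INDEX:
                        mat[k - 1, AA_INDEX[ch]] += 1
                    tcounts[node, _T[state + "M"]] += 1
                    state, node = "M", k
            else:
                if not gapped:
                    if ch in AA_INDEX:
                        ins[node - 1 if node > 0 else 0, AA_INDEX[ch]] += 1
                    if state == "D":
                        # D->I is not a plan7 core transition; treat the
                        # emitted residue as extending via M.
                        continue
                    tcounts[node, _T[state + "I"]] += 1
                    state = "I"
        # exit transition from final state to node M+1 is implicit

    mat /= mat.sum(axis=1, keepdims=True)
    ins /= ins.sum(axis=1, keepdims=True)
    tr = np.zeros((m + 1, 7))
    for cols in (("MM", "MI", "MD"), ("IM", "II"), ("DM", "DD")):
        idx = [_T[c] for c in cols]
        total = tcounts[:, idx].sum(axis=1)
        total[total == 0] = 1.0
        tr[:, idx] = tcounts[:, idx] / total[:, None]
    return ProfileHMM(name=name, match_emissions=mat, insert_emissions=ins,
                      transitions=tr)


def read_hmm(path) -> list[ProfileHMM]:
    """Read profile HMMs from a HMMER3 ASCII ``.hmm`` file (via pyhmmer)."""
    import pyhmmer

    out = []
    with pyhmmer.plan7.HMMFile(str(path)) as fh:
        for hmm in fh:
            m = hmm.M
            mat = np.asarray(hmm.match_emissions, dtype=float)[1:m + 1, :20]
            ins = np.asarray(hmm.insert_emissions, dtype=float)[1:m + 1, :20]
            # pyhmmer transition rows 0..M: MM MI MD IM II DM DD
            tp = np.asarray(hmm.transition_probabilities, dtype=float)
            tr = np.zeros((m + 1, 7))
            tr[:, :] = tp[:m + 1, :7]
            tr[0, _T["MI"]] = 0.0
            mat = mat / mat.sum(axis=1, keepdims=True)
            ins = ins / ins.sum(axis=1, keepdims=True)
            # renormalize in float64 (the file stores float32 precision)
            for cols in (("MM", "MI", "MD"), ("IM", "II"), ("DM", "DD")):
                idx = [_T[c] for c in cols]
                tot = tr[:, idx].sum(axis=1)
                tot[tot == 0] = 1.0
                tr[:, idx] = tr[:, idx] / tot[:, None]
            # last node: fold exit mass into MM
            name = hmm.name
            if isinstance(name, bytes):
                name = name.decode()
            out.append(ProfileHMM(
                name=name, match_emissions=mat,
                insert_emissions=ins, transitions=tr,
            ))
    return out


# --- Viterbi scanning --------------------------------------------------

def _log_arrays(hmm: ProfileHMM):
    with np.errstate(divide="ignore"):
        lmat = np.log2(hmm.match_emissions / BACKGROUND[None, :])
        lins = np.log2(hmm.insert_emissions / BACKGROUND[None, :])
        ltr = np.log2(hmm.transitions)
    return lmat, lins, ltr


def _viterbi_once(hmm, seq_idx, masked, lmat, lins, ltr):
    """One pass of local Viterbi; returns (score, match_map) or None.

    Local in both sequence and model: entry into any match state costs
    log2(1/M); exit from any match state is free.  Masked sequence
    positions cannot be emitted by match or insert states.
    """
    m = hmm.M
    n = len(seq_idx)
    entry = -math.log2(m)
    VM = np.full((n + 1, m + 1), NEG_INF)
    VI = np.full((n + 1, m + 1), NEG_INF)
    VD = np.full((n + 1, m + 1), NEG_INF)
    ptrM = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0 entry,1 M,2 I,3 D
    ptrI = np.zeros((n + 1, m + 1), dtype=np.int8)  # 1 from M, 2 from I
    ptrD = np.zeros((n + 1, m + 1), dtype=np.int8)  # 1 from M, 3 from D
    best = (NEG_INF, 0, 0)
    for i in range(1, n + 1):
        if masked[i - 1]:
            continue
        a = seq_idx[i - 1]
        for k in range(1, m + 1):
            em = lmat[k - 1, a] if a >= 0 else 0.0
            cands = [
                (entry, 0),
                (VM[i - 1, k - 1] + ltr[k - 1, _T["MM"]], 1),
                (VI[i - 1, k - 1] + ltr[k - 1, _T["IM"]], 2),
                (VD[i - 1, k - 1] + ltr[k - 1, _T["DM"]], 3),
            ]
            sc, src = max(cands, key=lambda t: t[0])
            VM[i, k] = em + sc
            ptrM[i, k] = src
            if VM[i, k] > best[0]:
                best = (VM[i, k], i, k)
            # insert at node k (emits residue, stays at node k)
            iem = lins[k - 1, a] if a >= 0 else 0.0
            ci = [
                (VM[i - 1, k] + ltr[k, _T["MI"]], 1),
                (VI[i - 1, k] + ltr[k, _T["II"]], 2),
            ]
            sci, srci = max(ci, key=lambda t: t[0])
            VI[i, k] = iem + sci
            ptrI[i, k] = srci
        for k in range(2, m + 1):
            cd = [
                (VM[i, k - 1] + ltr[k - 1, _T["MD"]], 1),
                (VD[i, k - 1] + ltr[k - 1, _T["DD"]], 3),
            ]
            scd, srcd = max(cd, key=lambda t: t[0])
            VD[i, k] = scd
            ptrD[i, k] = srcd
    if not np.isfinite(best[0]):
        return None
    score, i, k = best
    match_map = []
    state = 1
    while True:
        if state == 1:
            match_map.append((i, k))
            src = ptrM[i, k]
            if src == 0:
                break
            if src == 1:
                i, k, state = i - 1, k - 1, 1
            elif src == 2:
                i, k, state = i - 1, k - 1, 2
            else:
                # delete at node k-1 with i-1 residues consumed
                i, k, state = i - 1, k - 1, 3
        elif state == 2:
            src = ptrI[i, k]
            state = 1 if src == 1 else 2
            i = i - 1
        else:
            src = ptrD[i, k]
            state = 1 if src == 1 else 3
            k = k - 1
    match_map.reverse()
    return score, match_map


def viterbi_scan(
    hmm: ProfileHMM,
    seq: TargetSequence,
    bitscore_cutoff: float = DEFAULT_BITSCORE_CUTOFF,
    max_hits: int = DEFAULT_MAX_HITS,
) -> list[DomainHit]:
    """Find non-overlapping local hits of ``hmm`` on ``seq``.

    The best local Viterbi hit is reported, its sequence positions are
    masked, and the scan repeats until the score drops below
    ``bitscore_cutoff`` bits or ``max_hits`` hits are found.  Hits are
    returned sorted by start position.
    """
    seq_idx = [AA_INDEX.get(ch, -1) for ch in seq.residues]
    masked = [False] * len(seq_idx)
    lmat, lins, ltr = _log_arrays(hmm)
    hits: list[DomainHit] = []
    while len(hits) < max_hits:
        res = _viterbi_once(hmm, seq_idx, masked, lmat, lins, ltr)
        if res is None:
            break
        score, match_map = res
        if score < bitscore_cutoff:
            break
        start = match_map[0][0]
        end = match_map[-1][0]
        hits.append(DomainHit(
            pfam=hmm.name, seq_id=seq.id, start=start, end=end,
            score=score, match_map=match_map,
        ))
        for p in range(start, end + 1):
            masked[p - 1] = True
    hits.sort(key=lambda h: h.start)
    return hits


def read_domtblout(path) -> list[DomainHit]:
    """Read domain hits from a HMMER3 ``domtblout`` file.

    One hit per domain row, using envelope coordinates; ``match_map`` is
    left empty (transitive alignment then requires the built-in scanner).
    Follows the hmmscan convention: the target column is the profile and
    the query column the sequence.
    """
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) < 22:
                raise ValueError(
                    f"{path}: malformed domtblout row at line {lineno}"
                )
            try:
                pfam = tokens[0]
                seq_id = tokens[3]
                score = float(tokens[13])
                env_from = int(tokens[19])
                env_to = int(tokens[20])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: bad field at line {lineno}: {exc}"
                )
            if env_from > env_to:
                raise ValueError(
                    f"{path}: env_from {env_from} > env_to {env_to} at "
                    f"line {lineno}"
                )
            hits.append(DomainHit(pfam=pfam, seq_id=seq_id, start=env_from,
                                  end=env_to, score=score))
    return hits


# --- Architectures and ranking ----------------------------------------

def assign_architecture(
    seq: TargetSequence, hits: list[DomainHit]
) -> DomainArchitecture:
    """Resolve overlapping hits greedily into a domain architecture.

    Hits are taken in descending score order (ties: longer hit first,
    then lexicographic family name); a hit survives if it overlaps no
    previously accepted hit.  Survivors are reported sorted by start.
    """
    for h in hits:
        if h.seq_id != seq.id:
            raise ValueError(f"hit {h.pfam} refers to {h.seq_id!r}, "
                             f"not {seq.id!r}")
        if h.end > len(seq.residues):
            raise ValueError(f"hit {h.pfam} extends past sequence end")
    order = sorted(hits, key=lambda h: (-h.score, -h.length, h.pfam))
    chosen: list[DomainHit] = []
    for h in order:
        if all(h.end < c.start or h.start > c.end for c in chosen):
            chosen.append(h)
    chosen.sort(key=lambda h: h.start)
    return DomainArchitecture(
        seq_id=seq.id, domains=[(h.pfam, h.start, h.end) for h in chosen]
    )


def architecture_similarity(
    target: DomainArchitecture, template: DomainArchitecture
) -> float:
    """Multiset Jaccard index of the two architectures' family names.

    1.0 iff the name multisets are identical, 0.0 iff disjoint (or both
    empty).
    """
    from collections import Counter

    a = Counter(target.names)
    b = Counter(template.names)
    if not a and not b:
        return 0.0
    inter = sum((a & b).values())
    union = sum((a | b).values())
    return inter / union if union else 0.0


def rank_templates(
    targets: list[DomainArchitecture],
    catalogue: list[TemplateRecord],
) -> list[tuple[TemplateRecord, str, float]]:
    """Rank template assemblies by architecture similarity to the targets.

    The score of an assembly is the sum over targets of the best
    similarity between the target architecture and any entity
    architecture present in the assembly.  Assemblies sharing no family
    with any target are excluded.  Ties break by resolution ascending
    (unknown last), then pdb_id, then assembly id.
    """
    if not catalogue:
        raise ValueError("empty template catalogue")
    if not any(t.domains for t in targets):
        raise ValueError("no target has any assigned domain")
    rows = []
    for rec in catalogue:
        for aid, comp in rec.assemblies:
            archs = [rec.entity_architecture(eid) for eid in comp]
            score = 0.0
            shared = False
            for tgt in targets:
                sims = [architecture_similarity(tgt, a) for a in archs]
                best = max(sims) if sims else 0.0
                if best > 0:
                    shared = True
                score += best
            if shared:
                rows.append((rec, aid, score))
    if not rows:
        raise ValueError("no catalogue assembly shares a domain family "
                         "with any target")
    rows.sort(key=lambda r: (
        -r[2],
        r[0].resolution if r[0].resolution is not None else float("inf"),
        r[0].pdb_id,
        r[1],
    ))
    return rows


# --- Catalogue I/O -----------------------------------------------------

CATALOGUE_COLUMNS = ["pdb_id", "resolution", "entity_id", "entity_seq",
                     "domains", "assembly_id", "composition"]


def _parse_domains(text: str, seq_id: str) -> DomainArchitecture:
    domains = []
    if text and text != "-":
        for item in text.split(";"):
            name, _, span = item.partition(":")
            start, _, end = span.partition("-")
            domains.append((name, int(start), int(end)))
    domains.sort(key=lambda d: d[1])
    return DomainArchitecture(seq_id=seq_id, domains=domains)


def _parse_composition(text: str) -> dict[str, int]:
    comp = {}
    for item in text.split(","):
        eid, _, count = item.partition(":")
        comp[eid.strip()] = int(count)
    return comp


def read_catalogue(path) -> list[TemplateRecord]:
    """Read a template catalogue TSV.

    Columns: pdb_id, resolution, entity_id, entity_seq, domains
    (``Fam:start-end`` joined by ';', or '-'), assembly_id, composition
    (``entity:copies`` joined by ',').  One row per (entity, assembly)
    pair; entity and assembly descriptions repeated across rows must
    agree.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(CATALOGUE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing catalogue columns {sorted(missing)}")
    records = []
    for pdb_id, group in df.groupby("pdb_id", sort=False):
        res_text = group["resolution"].iloc[0]
        resolution = None if res_text in ("", "-", None) or pd.isna(res_text) \
            else float(res_text)
        entities = {}
        assemblies = {}
        for _, row in group.iterrows():
            eid = row["entity_id"]
            if eid not in entities:
                label = f"{pdb_id}_{eid}"
                entities[eid] = (
                    eid, row["entity_seq"],
                    _parse_domains(row["domains"], label),
                )
            aid = row["assembly_id"]
            if aid not in assemblies:
                assemblies[aid] = _parse_composition(row["composition"])
        records.append(TemplateRecord(
            pdb_id=pdb_id, resolution=resolution,
            entities=list(entities.values()),
            assemblies=list(assemblies.items()),
        ))
    return records


def write_catalogue(records: list[TemplateRecord], path) -> None:
    rows = []
    for rec in records:
        res = "-" if rec.resolution is None else f"{rec.resolution:g}"
        for aid, comp in rec.assemblies:
            comp_text = ",".join(f"{e}:{c}" for e, c in comp.items())
            for eid, seq, arch in rec.entities:
                dom = ";".join(f"{p}:{s}-{e}" for p, s, e in arch.domains) \
                    or "-"
                rows.append([rec.pdb_id, res, eid, seq, dom, aid, comp_text])
    pd.DataFrame(rows, columns=CATALOGUE_COLUMNS).to_csv(
        path, sep="\t", index=False
    )
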