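"""Threading targets onto template assemblies and grafting side chains.

The modeling step is deliberately conservative: backbone atoms of
aligned residues are copied verbatim from the template (no loop modeling
and no refinement), target insertions are left unmodeled as numbering
gaps, side chains of residues identical between target and template keep
the template's atoms — and hence its rotamers — exactly, and only
mutated side chains are rebuilt, greedily picking the highest-prior
rotamer without steric clashes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .alignment import (PairAlignment, gap_percentage, identity,
                        profile_profile_align)
from .assembly import Atom, AssemblyModel, Chain, GeneratedChain, Residue, \
    ONE_TO_THREE
from .domains import DomainArchitecture, TemplateRecord, \
    architecture_similarity
from .sequences import SequenceProfile, TargetSequence, profile_from_sequence
from .sidechains import (BACKBONE_SET, RotamerEntry, build_side_chain,
                         default_rotamer_library)

logger = logging.getLogger(__name__)

COPIED_IDENTICAL = "copied-identical"
MUTATED_REBUILT = "mutated-rebuilt"
UNMODELED_INSERTION = "unmodeled-insertion"

DEFAULT_CLASH_CUTOFF = 2.5


@dataclass
class EntityAssignment:
    """Greedy identity-based mapping of targets to template entities."""

    pairs: dict[str, tuple[str, PairAlignment, float]]
    unassigned: list[str] = field(default_factory=list)

    def __post_init__(self):
        entities = [e for e, _, _ in self.pairs.values()]
        if len(entities) != len(set(entities)):
            raise ValueError("an entity is assigned to multiple targets")
        for tid, (eid, _, ident) in self.pairs.items():
            if not 0.0 <= ident <= 100.0:
                raise ValueError(f"identity {ident} for target {tid!r} "
                                 f"outside [0, 100]")

    def target_for_entity(self, entity_id: str) -> str | None:
        for tid, (eid, _, _) in self.pairs.items():
            if eid == entity_id:
                return tid
        return None


@dataclass
class ThreadedChain:
    """One model chain: threaded backbone plus grafted side chains."""

    chain_id: str
    target_id: str
    entity_id: str
    residues: list[Residue]
    provenance: dict[int, str]
    identity_pct: float = 0.0
    gap_pct: float = 0.0

    @property
    def unmodeled(self) -> list[int]:
        return sorted(p for p, tag in self.provenance.items()
                      if tag == UNMODELED_INSERTION)

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)


@dataclass
class ComplexModel:
    """A threaded multi-chain homology model with per-chain report."""

    template_pdb_id: str
    assembly_id: str
    chains: list[ThreadedChain]

    @property
    def report(self) -> list[dict]:
        return [
            {
                "chain_id": ch.chain_id,
                "target_id": ch.target_id,
                "entity_id": ch.entity_id,
                "identity_pct": ch.identity_pct,
                "gap_pct": ch.gap_pct,
                "n_unmodeled": len(ch.unmodeled),
            }
            for ch in self.chains
        ]

    def remarks(self) -> list[str]:
        out = [f"TEMPLATE {self.template_pdb_id} ASSEMBLY {self.assembly_id}"]
        for row in self.report:
            out.append(
                f"CHAIN {row['chain_id']} TARGET {row['target_id']} "
                f"ENTITY {row['entity_id']} IDENTITY "
                f"{row['identity_pct']:.1f}% GAPS {row['gap_pct']:.1f}% "
                f"UNMODELED {row['n_unmodeled']}"
            )
        for ch in self.chains:
            if ch.unmodeled:
                spans = ",".join(str(p) for p in ch.unmodeled)
                out.append(f"CHAIN {ch.chain_id} UNMODELED INSERTIONS {spans}")
        return out


def assign_targets_to_entities(
    targets: list[TargetSequence],
    architectures: dict[str, DomainArchitecture],
    template: TemplateRecord,
    profiles: dict[str, SequenceProfile] | None = None,
    mode: str = "global-free-ends",
    gap_open: float = 7.0,
    gap_extend: float = 0.7,
) -> EntityAssignment:
    """Assign each target to at most one template entity.

    Every target x entity pair sharing a domain family is aligned
    (profile-profile); pairs are then taken greedily by descending
    alignment identity, ties broken by target input order then entity
    order, with each target and each entity used at most once.  All
    assembly copies of an entity are later threaded with its one
    assigned target.
    """
    profiles = dict(profiles or {})
    candidates = []
    for t_order, target in enumerate(targets):
        arch = architectures.get(target.id)
        t_names = set(arch.names) if arch is not None else set()
        for e_order, (eid, eseq, earch) in enumerate(template.entities):
            if not t_names & set(earch.names):
                continue
            prof_t = profiles.get(target.id)
            if prof_t is None:
                prof_t = profile_from_sequence(target)
                profiles[target.id] = prof_t
            prof_e = profile_from_sequence(
                TargetSequence(id=f"{template.pdb_id}_{eid}", residues=eseq)
            )
            aln = profile_profile_align(prof_t, prof_e, mode=mode,
                                        gap_open=gap_open,
                                        gap_extend=gap_extend)
            ident = identity(aln, target.residues, eseq)
            candidates.append((ident, t_order, e_order, target.id, eid, aln))
    if not candidates:
        raise ValueError(
            f"no target shares a domain family with any entity of "
            f"{template.pdb_id}"
        )
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    pairs: dict[str, tuple[str, PairAlignment, float]] = {}
    used_entities: set[str] = set()
    for ident, _, _, tid, eid, aln in candidates:
        if tid in pairs or eid in used_entities:
            continue
        pairs[tid] = (eid, aln, ident)
        used_entities.add(eid)
    unassigned = [t.id for t in targets if t.id not in pairs]
    return EntityAssignment(pairs=pairs, unassigned=unassigned)


def _copy_atom(atom: Atom) -> Atom:
    return Atom(atom.name, atom.element, atom.pos.copy(), atom.occupancy,
                atom.b_factor)


def thread_backbone(
    target: TargetSequence,
    template_chain: Chain | GeneratedChain,
    aln: PairAlignment,
    chain_id: str | None = None,
) -> ThreadedChain:
    """Copy template backbone onto the target numbering.

    For each gap-free alignment column the template residue's N, CA, C,
    O (and CB unless the target residue is glycine) are copied
    bit-exactly and renumbered to the target position.  Target residues
    aligned to gaps become unmodeled insertions (numbering gaps, no
    atoms); template residues aligned to gaps are skipped (deletions).
    Sequence position k of the template corresponds to the k-th residue
    of ``template_chain``.
    """
    t_res = template_chain.residues
    residues: list[Residue] = []
    provenance: dict[int, str] = {}
    for pa, pb in aln.columns:
        if pa is None:
            continue  # deletion relative to the target
        if pa > len(target.residues):
            raise ValueError(f"alignment position {pa} outside target "
                             f"{target.id!r}")
        aa = target.residues[pa - 1]
        if pb is None:
            provenance[pa] = UNMODELED_INSERTION
            continue
        if pb > len(t_res):
            raise ValueError(
                f"alignment position {pb} outside template chain "
                f"{template_chain.chain_id!r}"
            )
        tres = t_res[pb - 1]
        if tres.atom("CA") is None:
            raise ValueError(
                f"template residue {tres.seq_num} in chain "
                f"{template_chain.chain_id!r} lacks a CA atom"
            )
        wanted = ["N", "CA", "C", "O"]
        if aa != "G":
            wanted.append("CB")
        atoms = [_copy_atom(a) for name in wanted
                 if (a := tres.atom(name)) is not None]
        name3 = ONE_TO_THREE.get(aa, "UNK")
        residues.append(Residue(seq_num=pa, name=name3, atoms=atoms))
        provenance[pa] = (COPIED_IDENTICAL if aa == tres.one_letter
                          else MUTATED_REBUILT)
    return ThreadedChain(
        chain_id=chain_id or template_chain.chain_id,
        target_id=target.id,
        entity_id=getattr(template_chain, "entity_id", ""),
        residues=residues,
        provenance=provenance,
    )


def _count_clashes(candidate: np.ndarray, env: np.ndarray,
                   cutoff: float) -> int:
    if env.size == 0 or candidate.size == 0:
        return 0
    d2 = ((candidate[:, None, :] - env[None, :, :]) ** 2).sum(axis=2)
    return int((d2 < cutoff * cutoff).sum())


def graft_side_chains(
    threaded: ThreadedChain,
    template_chain: Chain | GeneratedChain,
    aln: PairAlignment,
    library: list[RotamerEntry] | None = None,
    clash_cutoff: float = DEFAULT_CLASH_CUTOFF,
    environment: np.ndarray | None = None,
) -> ThreadedChain:
    """Complete the threaded chain's side chains in place.

    Residues identical between target and template receive every
    template side-chain heavy atom verbatim (rotamer preservation).
    Mutated residues are rebuilt from ideal internal coordinates, trying
    the library's rotamers for the target type in descending prior and
    taking the first with zero heavy-atom contacts closer than
    ``clash_cutoff`` to already-placed atoms (own-residue atoms
    excluded); if every rotamer clashes, the minimum-clash-count rotamer
    wins, ties going to the higher prior.  ``environment`` may add
    external coordinates (e.g. other chains already built).
    """
    if library is None:
        library = list(default_rotamer_library())
    by_type: dict[str, list[RotamerEntry]] = {}
    for entry in library:
        by_type.setdefault(entry.residue_type, []).append(entry)
    for entries in by_type.values():
        entries.sort(key=lambda e: -e.prior)

    tpl_by_pos = {pb: template_chain.residues[pb - 1]
                  for _, pb in aln.match_columns}
    pos_to_tpl = {pa: pb for pa, pb in aln.match_columns}

    # every backbone atom of the chain is already placed
    env_parts = [environment] if environment is not None and \
        len(environment) else []
    chain_bb = []
    res_spans: dict[int, tuple[int, int]] = {}
    cursor = 0
    for res in threaded.residues:
        start = cursor
        for a in res.atoms:
            chain_bb.append(a.pos)
            cursor += 1
        res_spans[res.seq_num] = (start, cursor)
    placed = np.array(chain_bb) if chain_bb else np.zeros((0, 3))
    extra: list[np.ndarray] = []

    def env_for(res_num: int) -> np.ndarray:
        lo, hi = res_spans[res_num]
        own_mask = np.ones(len(placed), dtype=bool)
        own_mask[lo:hi] = False
        parts = [placed[own_mask]]
        parts.extend(env_parts)
        if extra:
            parts.append(np.array(extra))
        return np.concatenate([p for p in parts if len(p)]) \
            if parts else np.zeros((0, 3))

    for res in threaded.residues:
        tag = threaded.provenance[res.seq_num]
        aa = res.one_letter
        if tag == COPIED_IDENTICAL:
            tpl = tpl_by_pos[pos_to_tpl[res.seq_num]]
            have = {a.name for a in res.atoms}
            for atom in tpl.atoms:
                if atom.name in BACKBONE_SET or atom.name in have:
                    continue
                res.atoms.append(_copy_atom(atom))
                extra.append(atom.pos)
            continue
        if tag != MUTATED_REBUILT or aa == "G":
            continue
        backbone = {a.name: a.pos for a in res.atoms}
        if "CB" not in backbone and aa != "G":
            cb = build_side_chain(
                {k: backbone[k] for k in ("N", "CA", "C")},
                ONE_TO_THREE[aa],
            )
            # first built atom is CB
            name, element, pos = cb[0]
            res.atoms.append(Atom(name, element, pos))
            backbone[name] = pos
            extra.append(pos)
        if aa == "A":
            continue
        entries = by_type.get(aa)
        if not entries:
            raise ValueError(
                f"residue type {aa!r} absent from the rotamer library"
            )
        env = env_for(res.seq_num)
        best = None  # (clashes, -prior marker via order, atoms)
        chosen = None
        for entry in entries:
            atoms = build_side_chain(backbone, ONE_TO_THREE[aa], entry.chi)
            coords = np.array([p for _, _, p in atoms])
            clashes = _count_clashes(coords, env, clash_cutoff)
            if clashes == 0:
                chosen = atoms
                break
            if best is None or clashes < best[0]:
                best = (clashes, atoms)
        if chosen is None:
            chosen = best[1]
        for name, element, pos in chosen:
            res.atoms.append(Atom(name, element, pos))
            extra.append(pos)
    return threaded


def build_complex(
    template_assembly: AssemblyModel,
    assignment: EntityAssignment,
    targets: list[TargetSequence],
    include_chains: list[str] | None = None,
    library: list[RotamerEntry] | None = None,
    clash_cutoff: float = DEFAULT_CLASH_CUTOFF,
) -> ComplexModel:
    """Thread and graft every assembly chain whose entity has a target.

    All copies of an entity are threaded with that entity's one assigned
    target; chains of unassigned entities are excluded with a logged
    notice.  ``include_chains`` filters by assembly chain id.
    """
    target_by_id = {t.id: t for t in targets}
    chains: list[ThreadedChain] = []
    env: np.ndarray | None = None
    for gchain in template_assembly.chains:
        if include_chains is not None and \
                gchain.new_chain_id not in include_chains:
            continue
        tid = assignment.target_for_entity(gchain.entity_id)
        if tid is None:
            logger.info("chain %s (entity %s) has no assigned target; "
                        "excluded", gchain.new_chain_id, gchain.entity_id)
            continue
        eid, aln, ident = assignment.pairs[tid]
        target = target_by_id[tid]
        threaded = thread_backbone(target, gchain, aln,
                                   chain_id=gchain.new_chain_id)
        graft_side_chains(threaded, gchain, aln, library=library,
                          clash_cutoff=clash_cutoff, environment=env)
        threaded.identity_pct = ident
        threaded.gap_pct = gap_percentage(aln)
        chains.append(threaded)
        coords = np.array([a.pos for r in threaded.residues
                           for a in r.atoms])
        env = coords if env is None else np.vstack([env, coords])
    if not chains:
        raise ValueError("no assembly chain maps to an assigned entity")
    return ComplexModel(
        template_pdb_id=template_assembly.source.pdb_id,
        assembly_id=template_assembly.assembly_id,
        chains=chains,
    )
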