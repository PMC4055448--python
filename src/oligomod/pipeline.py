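"""End-to-end modeling pipeline: sequences to a complex model PDB.

Stages (each usable on its own through the library API): read and
validate targets; build profiles; optionally attach secondary
structure; scan targets against the family HMMs; resolve domain
architectures; rank catalogue template assemblies by architecture
similarity; align targets to the chosen template's entities; expand the
biological assembly from its operators; assign targets to entities by
alignment identity; thread backbones and graft side chains; write the
model and a hit-table report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import alignment as almod
from . import assembly as asmod
from . import domains as dmod
from . import modelbuild as mbmod
from . import sequences as sqmod
from .sidechains import load_rotamer_table

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and tunables for a modeling run.

    ``hmm_dir`` may hold family alignments (``*.fasta``, converted to
    HMMs by smoothed maximum likelihood) and/or HMMER3 ``*.hmm`` files.
    """

    catalogue: str
    structures_dir: str
    hmm_dir: str
    rotamer_table: str | None = None
    ss2_dir: str | None = None
    alignment_dir: str | None = None  # hand-edited <target>.a2m overrides
    gap_open: float = 7.0
    gap_extend: float = 0.7
    mode: str = "global-free-ends"
    bitscore_cutoff: float = 10.0
    max_hits: int = 5
    template: str | None = None       # pdb_id; default best-ranked
    assembly_id: str | None = None    # default the ranked assembly
    include_chains: list[str] | None = None
    clash_cutoff: float = 2.5
    max_sequences: int = 6
    seed: int = 0

    def validate(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be nonnegative")
        if self.mode not in ("global-free-ends", "local"):
            raise ValueError(f"unknown alignment mode {self.mode!r}")
        if self.max_hits < 1:
            raise ValueError("max_hits must be >= 1")
        if self.clash_cutoff <= 0:
            raise ValueError("clash_cutoff must be positive")
        for path, what in ((self.catalogue, "catalogue"),
                           (self.structures_dir, "structures_dir"),
                           (self.hmm_dir, "hmm_dir")):
            if not Path(path).exists():
                raise ValueError(f"{what} path does not exist: {path}")


@dataclass
class HitRow:
    pdb_id: str
    assembly_id: str
    resolution: float | None
    architecture: str
    arch_score: float
    target_id: str
    entity_id: str
    identity_pct: float
    gap_pct: float
    aln_length: int
    aln_start: tuple[int, int]
    aln_end: tuple[int, int]


@dataclass
class PipelineResult:
    targets: list
    architectures: dict
    ranked: list
    hit_table: list[HitRow]
    assembly_model: object
    assignment: object
    model: object


def load_hmms(hmm_dir) -> list[dmod.ProfileHMM]:
    """Load family HMMs from a directory of MSA FASTAs and/or .hmm files."""
    from Bio import SeqIO

    hmm_dir = Path(hmm_dir)
    hmms = []
    for path in sorted(hmm_dir.glob("*.fasta")):
        rows = [str(r.seq) for r in SeqIO.parse(str(path), "fasta")]
        hmms.append(dmod.hmm_from_msa(path.stem, rows))
    for path in sorted(hmm_dir.glob("*.hmm")):
        hmms.extend(dmod.read_hmm(path))
    if not hmms:
        raise ValueError(f"no family alignments or HMMs found in {hmm_dir}")
    return hmms


def _find_structure(structures_dir, pdb_id: str) -> Path:
    for ext in (".cif", ".mmcif", ".pdb", ".ent"):
        path = Path(structures_dir) / f"{pdb_id}{ext}"
        if path.exists():
            return path
    raise FileNotFoundError(
        f"no coordinate file for {pdb_id} under {structures_dir}"
    )


def _alignment_span(aln: almod.PairAlignment):
    pairs = aln.match_columns
    if not pairs:
        return (0, 0), (0, 0)
    return pairs[0], pairs[-1]


def run_pipeline(
    fasta_path,
    config: PipelineConfig,
    out_pdb=None,
    report_path=None,
) -> PipelineResult:
    """Run the full modeling pipeline on a target FASTA file."""
    config.validate()

    targets = sqmod.read_fasta(fasta_path, config.max_sequences)
    logger.info("stage sequences: %d target(s) read", len(targets))

    if config.ss2_dir:
        for i, t in enumerate(targets):
            ss2 = Path(config.ss2_dir) / f"{t.id}.ss2"
            if ss2.exists():
                targets[i] = sqmod.read_ss2(ss2, t)

    profiles = {t.id: sqmod.profile_from_sequence(t) for t in targets}

    hmms = load_hmms(config.hmm_dir)
    architectures = {}
    for t in targets:
        hits = []
        for hmm in hmms:
            hits.extend(dmod.viterbi_scan(
                hmm, t, bitscore_cutoff=config.bitscore_cutoff,
                max_hits=config.max_hits,
            ))
        architectures[t.id] = dmod.assign_architecture(t, hits)
        logger.info("stage domains: %s -> %s", t.id, architectures[t.id])

    catalogue = dmod.read_catalogue(config.catalogue)
    ranked = dmod.rank_templates(list(architectures.values()), catalogue)
    logger.info("stage ranking: %d eligible assembly(ies)", len(ranked))

    # hit table, sorted by architecture similarity then identity
    hit_table: list[HitRow] = []
    for rec, aid, score in ranked:
        try:
            assignment = mbmod.assign_targets_to_entities(
                targets, architectures, rec, profiles,
                mode=config.mode, gap_open=config.gap_open,
                gap_extend=config.gap_extend,
            )
        except ValueError:
            continue
        arch_text = " + ".join(
            str(rec.entity_architecture(eid)) for eid in
            dict(rec.assemblies)[aid]
        )
        for tid, (eid, aln, ident) in assignment.pairs.items():
            start, end = _alignment_span(aln)
            hit_table.append(HitRow(
                pdb_id=rec.pdb_id, assembly_id=aid,
                resolution=rec.resolution, architecture=arch_text,
                arch_score=score, target_id=tid, entity_id=eid,
                identity_pct=ident, gap_pct=almod.gap_percentage(aln),
                aln_length=len(aln.columns), aln_start=start, aln_end=end,
            ))
    hit_table.sort(key=lambda r: (-r.arch_score, -r.identity_pct,
                                  r.pdb_id, r.assembly_id, r.target_id))

    # choose the template
    if config.template is not None:
        chosen = [(rec, aid, s) for rec, aid, s in ranked
                  if rec.pdb_id == config.template
                  and (config.assembly_id is None
                       or aid == config.assembly_id)]
        if not chosen:
            raise ValueError(
                f"template {config.template!r} (assembly "
                f"{config.assembly_id!r}) is not in the eligible ranking"
            )
        rec, aid, _ = chosen[0]
    else:
        rec, aid, _ = ranked[0]
    logger.info("stage template: %s assembly %s", rec.pdb_id, aid)

    structure, definitions, operators = asmod.read_structure(
        _find_structure(config.structures_dir, rec.pdb_id)
    )
    wanted_aid = config.assembly_id or aid
    defs = {d.assembly_id: d for d in definitions}
    if wanted_aid not in defs:
        raise ValueError(
            f"{rec.pdb_id}: assembly {wanted_aid!r} not present "
            f"(available: {sorted(defs)})"
        )
    assembly_model = asmod.build_assembly(structure, defs[wanted_aid],
                                          operators)
    logger.info("stage assembly: %d chain(s), composition %s",
                len(assembly_model.chains),
                asmod.assembly_composition(assembly_model))

    assignment = mbmod.assign_targets_to_entities(
        targets, architectures, rec, profiles, mode=config.mode,
        gap_open=config.gap_open, gap_extend=config.gap_extend,
    )
    if config.alignment_dir:
        target_by_id = {t.id: t for t in targets}
        for tid, (eid, _, _) in list(assignment.pairs.items()):
            path = Path(config.alignment_dir) / f"{tid}.a2m"
            if not path.exists():
                continue
            edited, sa, sb = almod.read_alignment_fasta(path)
            eseq = rec.entity_sequence(eid)
            if sa != target_by_id[tid].residues or sb != eseq:
                raise ValueError(
                    f"{path}: edited alignment sequences do not match "
                    f"target {tid!r} / entity {eid!r}"
                )
            ident = almod.identity(edited, sa, sb)
            assignment.pairs[tid] = (eid, edited, ident)
            logger.info("stage alignment: %s uses edited alignment %s",
                        tid, path)
    library = None
    if config.rotamer_table:
        library = load_rotamer_table(config.rotamer_table)
    model = mbmod.build_complex(
        assembly_model, assignment, targets,
        include_chains=config.include_chains, library=library,
        clash_cutoff=config.clash_cutoff,
    )
    logger.info("stage model: %d chain(s) built", len(model.chains))

    if out_pdb is not None:
        asmod.write_pdb(model, out_pdb, remarks=model.remarks())
    if report_path is not None:
        write_report(hit_table, model, report_path)
    return PipelineResult(
        targets=targets, architectures=architectures, ranked=ranked,
        hit_table=hit_table, assembly_model=assembly_model,
        assignment=assignment, model=model,
    )


def write_report(hit_table, model, path) -> None:
    """Plain-text report mirroring the hit-table columns."""
    lines = ["pdb_id\tassembly\tresolution\tarchitecture\ttarget\tentity"
             "\tidentity%\tgap%\taln_len\tstart\tend"]
    for r in hit_table:
        res = "-" if r.resolution is None else f"{r.resolution:.2f}"
        lines.append(
            f"{r.pdb_id}\t{r.assembly_id}\t{res}\t{r.architecture}\t"
            f"{r.target_id}\t{r.entity_id}\t{r.identity_pct:.1f}\t"
            f"{r.gap_pct:.1f}\t{r.aln_length}\t"
            f"{r.aln_start[0]}/{r.aln_start[1]}\t"
            f"{r.aln_end[0]}/{r.aln_end[1]}"
        )
    lines.append("")
    lines.append("model chains:")
    for row in model.report:
        lines.append(
            f"  {row['chain_id']}: target {row['target_id']} -> entity "
            f"{row['entity_id']}, identity {row['identity_pct']:.1f}%, "
            f"gaps {row['gap_pct']:.1f}%, unmodeled {row['n_unmodeled']}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
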