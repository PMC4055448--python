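"""Deterministic synthetic fixtures for every pipeline stage.

The generator emulates the external inputs a modeling session needs —
family alignments for the domain scanner, a template catalogue, template
coordinates in both mmCIF and legacy PDB encodings with assembly
operators, target FASTA files, a PSSM and a secondary-structure file,
an interface-cluster table and the rotamer table — from a single RNG
seed, and records the quantities it realized (e.g. pairwise transitive
identities within each family) in a JSON manifest so tests can verify
the analysis modules against the generator's own bookkeeping.

The flagship structure is a 2H64-style heterohexamer: a ligand-family
dimer bound by two copies of each of two homologous receptor entities
(three entities, six chains, identity operators), mirroring the shape of
a deposited TGF-beta/receptor assembly.  A second template is a monomer
whose biological dimer is generated by a C2 rotation, written once as
mmCIF and once as a REMARK 350 PDB so the two dialect readers can be
checked against each other.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np

from . import alignment as almod
from . import domains as dmod
from .assembly import ONE_TO_THREE
from .sequences import AA_ALPHABET, BACKGROUND
from .sidechains import build_side_chain, default_rotamer_library, \
    place_atom, write_rotamer_table

# family design: name -> (ancestor length, members, mutation rate)
FAMILY_DESIGN = {
    "FamP": (24, 6, 0.20),
    "FamL": (36, 6, 0.25),
    "FamX": (20, 4, 0.25),
    "FamDiv": (40, 6, 0.45),
}
# FamR is generated as two subclades so the two receptor entities are
# homologous but clearly distinct (~35-60% identity between clades).
FAMR_LENGTH = 33
FAMR_PER_CLADE = 4

HELIX_PHI = -57.0
HELIX_PSI = -47.0


def _random_sequence(rng, length: int) -> str:
    idx = rng.choice(20, size=length, p=BACKGROUND)
    return "".join(AA_ALPHABET[i] for i in idx)


def _mutate(rng, seq: str, rate: float) -> str:
    out = []
    for ch in seq:
        if rng.random() < rate:
            choices = [a for a in AA_ALPHABET if a != ch]
            out.append(choices[rng.integers(len(choices))])
        else:
            out.append(ch)
    return "".join(out)


def _seq_identity(a: str, b: str) -> float:
    same = sum(1 for x, y in zip(a, b) if x == y)
    return 100.0 * same / len(a)


def _write_fasta(path: Path, records: list[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


def _generate_families(rng):
    families: dict[str, list[tuple[str, str]]] = {}
    for fam, (length, members, rate) in FAMILY_DESIGN.items():
        ancestor = _random_sequence(rng, length)
        families[fam] = [
            (f"{fam}_m{i}", _mutate(rng, ancestor, rate))
            for i in range(members)
        ]
    root = _random_sequence(rng, FAMR_LENGTH)
    clade1 = _mutate(rng, root, 0.18)
    clade2 = _mutate(rng, root, 0.18)
    members = []
    for i in range(FAMR_PER_CLADE):
        members.append((f"FamR_m{i}", _mutate(rng, clade1, 0.12)))
    for i in range(FAMR_PER_CLADE):
        members.append((f"FamR_m{FAMR_PER_CLADE + i}",
                        _mutate(rng, clade2, 0.12)))
    families["FamR"] = members
    return families


def _transitive_family_identities(fam: str, members: list[tuple[str, str]]):
    """Scan every member against the family HMM and record pairwise
    transitive identities (the manifest's self-consistency anchor)."""
    hmm = dmod.hmm_from_msa(fam, [seq for _, seq in members])
    hits = {}
    for name, seq in members:
        found = dmod.viterbi_scan(
            hmm, dmod.TargetSequence(id=name, residues=seq),
            bitscore_cutoff=0.0, max_hits=1,
        )
        if found:
            hits[name] = found[0]
    pairwise = {}
    names = [n for n, _ in members if n in hits]
    seqs = dict(members)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            try:
                aln = almod.transitive_align(hits[names[i]], hits[names[j]])
            except ValueError:
                continue
            ident = almod.identity(aln, seqs[names[i]], seqs[names[j]])
            pairwise[f"{names[i]}|{names[j]}"] = ident
    return pairwise


# --- coordinate construction ------------------------------------------

def _helix_backbone(sequence: str):
    """Ideal alpha-helical backbone plus side chains for a sequence.

    Returns a list of residues: (name3, [(atom, element, coord), ...]).
    Side chains take each type's highest-prior rotamer; fixture
    geometry, not an energy-minimized structure.
    """
    top_rotamer: dict[str, tuple[float, ...]] = {}
    for entry in default_rotamer_library():
        if entry.residue_type not in top_rotamer:
            top_rotamer[entry.residue_type] = entry.chi
        # library is not sorted; keep the max-prior entry
    best_prior: dict[str, float] = {}
    for entry in default_rotamer_library():
        if entry.prior > best_prior.get(entry.residue_type, -1.0):
            best_prior[entry.residue_type] = entry.prior
            top_rotamer[entry.residue_type] = entry.chi

    residues = []
    prev = None
    for i, aa in enumerate(sequence):
        if prev is None:
            n = np.array([0.0, 0.0, 0.0])
            ca = np.array([1.458, 0.0, 0.0])
            c = place_atom(n + np.array([0.0, 1.0, 0.0]), n, ca,
                           1.525, 111.2, -150.0)
        else:
            pn, pca, pc = prev
            n = place_atom(pn, pca, pc, 1.329, 114.2, HELIX_PSI)
            ca = place_atom(pca, pc, n, 1.458, 121.7, 180.0)
            c = place_atom(pc, n, ca, 1.525, 111.2, HELIX_PHI)
        o = place_atom(n, ca, c, 1.231, 120.1, HELIX_PSI + 180.0)
        atoms = [("N", "N", n), ("CA", "C", ca), ("C", "C", c),
                 ("O", "O", o)]
        if aa != "G":
            built = build_side_chain({"N": n, "CA": ca, "C": c},
                                     ONE_TO_THREE[aa],
                                     top_rotamer.get(aa, ()))
            atoms.extend(built)
        residues.append((ONE_TO_THREE[aa], atoms))
        prev = (n, ca, c)
    return residues


def _place_chain(residues, angle_deg: float, radius: float):
    """Rotate a built chain about z and push it out radially."""
    th = math.radians(angle_deg)
    rot = np.array([[math.cos(th), -math.sin(th), 0.0],
                    [math.sin(th), math.cos(th), 0.0],
                    [0.0, 0.0, 1.0]])
    shift = rot @ np.array([radius, 0.0, 0.0])
    out = []
    for name3, atoms in residues:
        out.append((name3, [(an, el, rot @ pos + shift)
                            for an, el, pos in atoms]))
    return out


def _write_mmcif(path: Path, pdb_id: str, chains, assemblies, operators):
    """Write a minimal but standard-conformant mmCIF coordinate file.

    ``chains``: list of (chain_id, entity_id, residues); ``assemblies``:
    list of (assembly_id, oper_expression, [chain ids]); ``operators``:
    list of (op id, 3x3 R, 3-vector t).
    """
    lines = [f"data_{pdb_id}", f"_entry.id {pdb_id.upper()}", "#"]
    entity_seqs: dict[str, str] = {}
    for cid, eid, residues in chains:
        if eid not in entity_seqs:
            entity_seqs[eid] = "".join(
                {v: k for k, v in ONE_TO_THREE.items()}.get(n3, "X")
                for n3, _ in residues
            )
    lines += ["loop_", "_entity.id", "_entity.type"]
    for eid in entity_seqs:
        lines.append(f"{eid} polymer")
    lines.append("#")
    lines += ["loop_", "_entity_poly.entity_id",
              "_entity_poly.type",
              "_entity_poly.pdbx_seq_one_letter_code"]
    for eid, seq in entity_seqs.items():
        lines.append(f"{eid} 'polypeptide(L)' {seq}")
    lines.append("#")
    lines += ["loop_", "_pdbx_struct_assembly.id",
              "_pdbx_struct_assembly.details"]
    for aid, _, _ in assemblies:
        lines.append(f"{aid} author_defined_assembly")
    lines.append("#")
    lines += ["loop_", "_pdbx_struct_assembly_gen.assembly_id",
              "_pdbx_struct_assembly_gen.oper_expression",
              "_pdbx_struct_assembly_gen.asym_id_list"]
    for aid, expr, cids in assemblies:
        lines.append(f"{aid} '{expr}' {','.join(cids)}")
    lines.append("#")
    lines += ["loop_", "_pdbx_struct_oper_list.id",
              "_pdbx_struct_oper_list.type"]
    for head in ("matrix[1][1]", "matrix[1][2]", "matrix[1][3]", "vector[1]",
                 "matrix[2][1]", "matrix[2][2]", "matrix[2][3]", "vector[2]",
                 "matrix[3][1]", "matrix[3][2]", "matrix[3][3]", "vector[3]"):
        lines.append(f"_pdbx_struct_oper_list.{head}")
    for oid, rot, tr in operators:
        kind = "'identity operation'" if np.allclose(rot, np.eye(3)) \
            and np.allclose(tr, 0) else "'point symmetry operation'"
        nums = []
        for r in range(3):
            nums.extend([f"{rot[r][c]:.10f}" for c in range(3)])
            nums.append(f"{tr[r]:.10f}")
        lines.append(f"{oid} {kind} " + " ".join(nums))
    lines.append("#")
    lines += ["loop_", "_atom_site.group_PDB", "_atom_site.id",
              "_atom_site.type_symbol", "_atom_site.label_atom_id",
              "_atom_site.label_alt_id", "_atom_site.label_comp_id",
              "_atom_site.label_asym_id", "_atom_site.label_entity_id",
              "_atom_site.label_seq_id", "_atom_site.pdbx_PDB_ins_code",
              "_atom_site.Cartn_x", "_atom_site.Cartn_y", "_atom_site.Cartn_z",
              "_atom_site.occupancy", "_atom_site.B_iso_or_equiv",
              "_atom_site.auth_seq_id", "_atom_site.auth_asym_id",
              "_atom_site.pdbx_PDB_model_num"]
    serial = 0
    for cid, eid, residues in chains:
        for rnum, (name3, atoms) in enumerate(residues, start=1):
            for an, el, pos in atoms:
                serial += 1
                lines.append(
                    f"ATOM {serial} {el} {an} . {name3} {cid} {eid} {rnum} ? "
                    f"{pos[0]:.3f} {pos[1]:.3f} {pos[2]:.3f} 1.00 0.00 "
                    f"{rnum} {cid} 1"
                )
    lines.append("#")
    path.write_text("\n".join(lines) + "\n")


def _write_remark350_pdb(path: Path, chains, biomolecules, operators):
    """Write a legacy PDB with a REMARK 350 assembly block."""
    lines = []
    for bid, cids, op_ids in biomolecules:
        lines.append(f"REMARK 350 BIOMOLECULE: {bid}")
        lines.append("REMARK 350 APPLY THE FOLLOWING TO CHAINS: "
                     + ", ".join(cids))
        for oid in op_ids:
            rot, tr = operators[oid]
            for r in range(3):
                lines.append(
                    f"REMARK 350   BIOMT{r + 1} {int(oid):3d}"
                    f"{rot[r][0]:10.6f}{rot[r][1]:10.6f}{rot[r][2]:10.6f}"
                    f"{tr[r]:15.5f}"
                )
    serial = 0
    for cid, _, residues in chains:
        last = None
        for rnum, (name3, atoms) in enumerate(residues, start=1):
            for an, el, pos in atoms:
                serial += 1
                name = f" {an}" if len(an) < 4 and len(el) == 1 else an
                lines.append(
                    f"ATOM  {serial:5d} {name:<4s} {name3:>3s} {cid}"
                    f"{rnum:4d}    {pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}"
                    f"  1.00  0.00          {el:>2s}"
                )
            last = (name3, rnum)
        serial += 1
        lines.append(f"TER   {serial:5d}      {last[0]:>3s} {cid}"
                     f"{last[1]:4d}")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def _pick_variant(rng, base: str, rate: float, closer_to: str,
                  farther_from: str, max_tries: int = 50) -> str:
    """A mutant of ``base`` strictly closer to it than to the decoy."""
    for _ in range(max_tries):
        cand = _mutate(rng, base, rate)
        if _seq_identity(cand, closer_to) > _seq_identity(cand, farther_from):
            return cand
    raise RuntimeError("could not realize the requested identity ordering")


def generate_fixtures(seed: int, out_dir) -> dict:
    """Generate the full fixture tree; returns (and writes) the manifest.

    Byte-identical output for identical seeds.
    """
    out = Path(out_dir)
    rng = np.random.default_rng(seed)
    for sub in ("pfams", "structures", "targets"):
        (out / sub).mkdir(parents=True, exist_ok=True)

    families = _generate_families(rng)
    for fam, members in sorted(families.items()):
        _write_fasta(out / "pfams" / f"{fam}.fasta", members)

    identities = {}
    for fam, members in sorted(families.items()):
        pairwise = _transitive_family_identities(fam, members)
        identities[fam] = {
            "pairwise": pairwise,
            "min": min(pairwise.values()) if pairwise else None,
        }

    seqs = {name: seq for members in families.values()
            for name, seq in members}
    e1 = seqs["FamL_m0"]
    e2 = seqs["FamR_m0"]
    e3 = seqs["FamR_m4"]

    t_lig = _mutate(rng, e1, 0.15)
    t_r1 = _pick_variant(rng, e2, 0.12, closer_to=e2, farther_from=e3)
    t_r2 = _pick_variant(rng, e3, 0.12, closer_to=e3, farther_from=e2)
    _write_fasta(out / "targets" / "hetero_targets.fasta",
                 [("t_lig", t_lig), ("t_r1", t_r1), ("t_r2", t_r2)])
    _write_fasta(out / "targets" / "self_targets.fasta",
                 [("s_e1", e1), ("s_e2", e2), ("s_e3", e3)])

    # secondary-structure and PSSM companions for the ligand target
    with open(out / "targets" / "t_lig.ss2", "w") as fh:
        fh.write("# PSIPRED VFORMAT (synthetic fixture)\n\n")
        for i, aa in enumerate(t_lig, start=1):
            label = "C" if i <= 2 or i > len(t_lig) - 2 else "H"
            probs = {"C": (0.8, 0.1, 0.1), "H": (0.05, 0.9, 0.05)}[label]
            fh.write(f"{i:4d} {aa} {label}   {probs[0]:.3f}  {probs[1]:.3f}"
                     f"  {probs[2]:.3f}\n")
    from .sequences import TargetSequence, profile_from_sequence, write_pssm
    write_pssm(profile_from_sequence(TargetSequence("t_lig", t_lig)),
               out / "targets" / "t_lig.pssm")

    # --- structures ----------------------------------------------------
    identity_op = (np.eye(3), np.zeros(3))
    hex_chains = []
    entity_seq = {"1": e1, "2": e2, "3": e3}
    layout = [("A", "1"), ("B", "1"), ("C", "2"), ("D", "2"),
              ("E", "3"), ("F", "3")]
    for k, (cid, eid) in enumerate(layout):
        built = _helix_backbone(entity_seq[eid])
        hex_chains.append((cid, eid, _place_chain(built, 60.0 * k, 26.0)))
    _write_mmcif(
        out / "structures" / "9hex.cif", "9hex", hex_chains,
        assemblies=[("1", "1", [c for c, _ in layout])],
        operators=[("1", *identity_op)],
    )

    c2_rot = np.array([[-1.0, 0.0, 0.0], [0.0, -1.0, 0.0], [0.0, 0.0, 1.0]])
    cee_built = _place_chain(_helix_backbone(e1), 0.0, 16.0)
    cee_chains = [("A", "1", cee_built)]
    _write_mmcif(
        out / "structures" / "9cee.cif", "9cee", cee_chains,
        assemblies=[("1", "1,2", ["A"])],
        operators=[("1", *identity_op), ("2", c2_rot, np.zeros(3))],
    )
    _write_remark350_pdb(
        out / "structures" / "9cee.pdb", cee_chains,
        biomolecules=[("1", ["A"], ["1", "2"])],
        operators={"1": identity_op, "2": (c2_rot, np.zeros(3))},
    )

    # --- catalogue ------------------------------------------------------
    def _arch(seq_id, fam, length):
        return dmod.DomainArchitecture(seq_id=seq_id,
                                       domains=[(fam, 1, length)])

    catalogue = [
        dmod.TemplateRecord(
            pdb_id="9hex", resolution=2.0,
            entities=[("1", e1, _arch("9hex_1", "FamL", len(e1))),
                      ("2", e2, _arch("9hex_2", "FamR", len(e2))),
                      ("3", e3, _arch("9hex_3", "FamR", len(e3)))],
            assemblies=[("1", {"1": 2, "2": 2, "3": 2})],
        ),
        dmod.TemplateRecord(
            pdb_id="9cee", resolution=1.8,
            entities=[("1", e1, _arch("9cee_1", "FamL", len(e1)))],
            assemblies=[("1", {"1": 2})],
        ),
        dmod.TemplateRecord(
            pdb_id="9par", resolution=2.5,
            entities=[("1", seqs["FamX_m0"],
                       _arch("9par_1", "FamX", len(seqs["FamX_m0"])))],
            assemblies=[("1", {"1": 2})],
        ),
    ]
    dmod.write_catalogue(catalogue, out / "catalogue.tsv")

    # --- interface clusters --------------------------------------------
    clusters = [
        almod.ClusterRecord("c1", ("FamL",), {"9hex", "9aaa", "9bbb"},
                            5, 89.99),
        almod.ClusterRecord("c2", ("FamL",), {"9ccc"}, 4, 50.0),
        almod.ClusterRecord("c3", ("FamR",), {"9ddd", "9eee"}, 5, 90.0),
        almod.ClusterRecord("c4", ("FamR",), {"9fff", "9ggg"}, 7, 45.0),
        almod.ClusterRecord("c5", ("FamL", "FamR"), {"9bbb", "9hhh"},
                            6, 30.0),
        almod.ClusterRecord("c6", ("FamX",), {"9iii", "9jjj", "9kkk"},
                            12, 88.0),
    ]
    almod.write_cluster_table(clusters, out / "clusters.tsv")

    write_rotamer_table(default_rotamer_library(), out / "rotamers.tsv")

    manifest = {
        "seed": int(seed),
        "families": {
            fam: {
                "members": {n: s for n, s in members},
                "identities": identities[fam],
            }
            for fam, members in sorted(families.items())
        },
        "entities": entity_seq,
        "targets": {
            "t_lig": {"sequence": t_lig,
                      "identity_to_e1": _seq_identity(t_lig, e1)},
            "t_r1": {"sequence": t_r1,
                     "identity_to_e2": _seq_identity(t_r1, e2),
                     "identity_to_e3": _seq_identity(t_r1, e3)},
            "t_r2": {"sequence": t_r2,
                     "identity_to_e2": _seq_identity(t_r2, e2),
                     "identity_to_e3": _seq_identity(t_r2, e3)},
        },
        "structures": {
            "9hex": {"chains": 6, "composition": {"1": 2, "2": 2, "3": 2}},
            "9cee": {"chains": 1, "assembly_chains": 2,
                     "composition": {"1": 2}},
        },
        "clusters": {
            "kept": ["c1", "c4", "c5", "c6"],
            "dropped": ["c2", "c3"],
            "overlap": {"c1|c4": "disjoint", "c1|c5": "overlapping"},
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest
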