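"""Template coordinates, symmetry operators, and biological assemblies.

A deposited crystal structure carries the asymmetric unit plus a recipe
for the biologically relevant oligomer: a set of rigid-body operators
(rotation + translation) and instructions stating which operators apply
to which chains.  This module reads both encodings of that recipe — the
mmCIF ``pdbx_struct_assembly_gen`` / ``pdbx_struct_oper_list`` categories
and the legacy PDB ``REMARK 350`` block — expands operator product
expressions such as ``"(1-60)(61-88)"``, and generates the assembly
coordinates.  Atom and entity parsing is delegated to gemmi; the
operator grammar and the expansion itself live here.
"""

from __future__ import annotations

import itertools
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

BACKBONE_ATOMS = ("N", "CA", "C", "O")

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}


def three_to_one(name: str) -> str:
    return _THREE_TO_ONE.get(name.upper(), "X")


@dataclass
class Atom:
    name: str
    element: str
    pos: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0

    def __post_init__(self):
        self.pos = np.asarray(self.pos, dtype=float)


@dataclass
class Residue:
    seq_num: int
    name: str
    atoms: list[Atom]
    icode: str = ""

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def one_letter(self) -> str:
        return three_to_one(self.name)


@dataclass
class Chain:
    chain_id: str
    entity_id: str
    residues: list[Residue]

    def __post_init__(self):
        prev = None
        for r in self.residues:
            key = (r.seq_num, r.icode)
            if prev is not None and key <= prev:
                raise ValueError(
                    f"chain {self.chain_id}: residue numbering not strictly "
                    f"increasing at {r.seq_num}{r.icode}"
                )
            prev = key

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    def coords(self) -> np.ndarray:
        return np.array([a.pos for r in self.residues for a in r.atoms])


@dataclass
class Structure:
    pdb_id: str
    entities: dict[str, tuple[str, str]]  # entity_id -> (sequence, descr)
    chains: list[Chain]
    resolution: float | None = None

    def __post_init__(self):
        for ch in self.chains:
            if ch.entity_id not in self.entities:
                raise ValueError(
                    f"chain {ch.chain_id} references unknown entity "
                    f"{ch.entity_id}"
                )

    def chain(self, chain_id: str) -> Chain:
        for ch in self.chains:
            if ch.chain_id == chain_id:
                return ch
        raise KeyError(chain_id)


@dataclass
class AssemblyOperator:
    operator_id: str
    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise ValueError(f"operator {self.operator_id}: bad shapes")
        det = np.linalg.det(self.rotation)
        if abs(det - 1.0) > 1e-6:
            raise ValueError(
                f"operator {self.operator_id}: determinant {det} is not 1"
            )
        if not np.allclose(self.rotation.T @ self.rotation, np.eye(3),
                           atol=1e-6):
            raise ValueError(f"operator {self.operator_id}: not orthogonal")

    @property
    def is_identity(self) -> bool:
        return (np.array_equal(self.rotation, np.eye(3))
                and np.array_equal(self.translation, np.zeros(3)))


@dataclass
class AssemblyDefinition:
    assembly_id: str
    instructions: list[tuple[str, list[str]]]  # (oper expression, chain ids)


@dataclass
class GeneratedChain:
    new_chain_id: str
    source_chain_id: str
    operator_id: str
    entity_id: str
    residues: list[Residue]

    @property
    def chain_id(self) -> str:
        return self.new_chain_id

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)


@dataclass
class AssemblyModel:
    source: Structure
    assembly_id: str
    chains: list[GeneratedChain]

    def __post_init__(self):
        ids = [c.new_chain_id for c in self.chains]
        if len(ids) != len(set(ids)):
            raise ValueError("generated chain ids are not unique")


# --- Reading -----------------------------------------------------------

def _dedup_altlocs(res: gemmi.Residue) -> list[Atom]:
    """Highest-occupancy altloc per atom name (ties: first), heavy only."""
    best: dict[str, gemmi.Atom] = {}
    order: list[str] = []
    for at in res:
        if at.is_hydrogen():
            continue
        prev = best.get(at.name)
        if prev is None:
            best[at.name] = at
            order.append(at.name)
        elif at.occ > prev.occ:
            best[at.name] = at
    out = []
    for name in order:
        at = best[name]
        out.append(Atom(
            name=name, element=at.element.name,
            pos=np.array([at.pos.x, at.pos.y, at.pos.z]),
            occupancy=at.occ, b_factor=at.b_iso,
        ))
    return out


def _is_amino(res: gemmi.Residue) -> bool:
    info = gemmi.find_tabulated_residue(res.name)
    if info is not None:
        return info.is_amino_acid()
    return res.name.upper() in _THREE_TO_ONE


def _mmcif_assembly_info(doc_block, label_to_auth):
    operators = []
    table = doc_block.find("_pdbx_struct_oper_list.",
                           ["id",
                            "matrix[1][1]", "matrix[1][2]", "matrix[1][3]",
                            "vector[1]",
                            "matrix[2][1]", "matrix[2][2]", "matrix[2][3]",
                            "vector[2]",
                            "matrix[3][1]", "matrix[3][2]", "matrix[3][3]",
                            "vector[3]"])
    for row in table:
        vals = [row[i] for i in range(13)]
        rot = np.array([[float(vals[1]), float(vals[2]), float(vals[3])],
                        [float(vals[5]), float(vals[6]), float(vals[7])],
                        [float(vals[9]), float(vals[10]), float(vals[11])]])
        tr = np.array([float(vals[4]), float(vals[8]), float(vals[12])])
        operators.append(AssemblyOperator(operator_id=vals[0], rotation=rot,
                                          translation=tr))
    definitions: dict[str, AssemblyDefinition] = {}
    gen = doc_block.find("_pdbx_struct_assembly_gen.",
                         ["assembly_id", "oper_expression", "asym_id_list"])
    for row in gen:
        aid, expr, asyms = row[0], row[1], row[2]
        chain_ids = []
        for asym in asyms.replace(" ", "").split(","):
            auth = label_to_auth.get(asym, asym)
            if auth not in chain_ids:
                chain_ids.append(auth)
        definitions.setdefault(
            aid, AssemblyDefinition(assembly_id=aid, instructions=[])
        ).instructions.append((expr.strip().strip("'\""), chain_ids))
    return list(definitions.values()), operators


_REMARK350_BIOMOL = re.compile(r"REMARK 350 BIOMOLECULE:\s*(\d+)")
_REMARK350_CHAINS = re.compile(
    r"REMARK 350 (?:APPLY THE FOLLOWING TO CHAINS:|\s*AND CHAINS:)\s*(.*)"
)
_REMARK350_BIOMT = re.compile(
    r"REMARK 350\s+BIOMT([123])\s+(\d+)\s+"
    r"(-?[\d.]+)\s+(-?[\d.]+)\s+(-?[\d.]+)\s+(-?[\d.]+)"
)


def _remark350_assembly_info(text: str):
    operators: dict[str, list[list[float]]] = {}
    definitions: list[AssemblyDefinition] = []
    current: AssemblyDefinition | None = None
    chains: list[str] = []
    opers_in_section: list[str] = []

    def flush_section():
        nonlocal chains, opers_in_section
        if current is not None and chains and opers_in_section:
            expr = ",".join(opers_in_section)
            current.instructions.append((expr, list(chains)))
        chains, opers_in_section = [], []

    for line in text.splitlines():
        if not line.startswith("REMARK 350"):
            continue
        m = _REMARK350_BIOMOL.search(line)
        if m:
            flush_section()
            current = AssemblyDefinition(assembly_id=m.group(1),
                                         instructions=[])
            definitions.append(current)
            continue
        m = _REMARK350_CHAINS.search(line)
        if m:
            if "APPLY" in line:
                flush_section()
            chains.extend(
                c.strip() for c in m.group(1).split(",") if c.strip()
            )
            continue
        m = _REMARK350_BIOMT.search(line)
        if m:
            rownum = int(m.group(1))
            serial = m.group(2)
            vals = [float(m.group(k)) for k in (3, 4, 5, 6)]
            operators.setdefault(serial, [[0.0] * 4] * 0)
            rows = operators[serial]
            if rownum == 1 and len(rows) == 3:
                pass  # defensive: duplicate serial rows
            rows.append(vals)
            if serial not in opers_in_section:
                opers_in_section.append(serial)
    flush_section()
    ops = []
    for serial, rows in operators.items():
        if len(rows) != 3:
            raise ValueError(f"REMARK 350 operator {serial}: "
                             f"{len(rows)} BIOMT rows, expected 3")
        arr = np.array(rows)
        ops.append(AssemblyOperator(
            operator_id=serial, rotation=arr[:, :3], translation=arr[:, 3]
        ))
    definitions = [d for d in definitions if d.instructions]
    return definitions, ops


def read_structure(path):
    """Read coordinates plus assembly recipe from mmCIF or PDB.

    Returns ``(Structure, [AssemblyDefinition], [AssemblyOperator])``.
    Only polymer amino-acid residues are kept (waters and non-polymer
    HETATM dropped); altlocs resolve to the highest-occupancy conformer.
    Entity sequences are derived from the observed residues of the first
    chain of each entity, so sequence position k is residue k in chain
    order throughout the package.
    """
    path = Path(path)
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    is_cif = path.suffix.lower() in (".cif", ".mmcif") or \
        path.read_text().lstrip().startswith("data_")
    if len(st) == 0:
        raise ValueError(f"{path}: no models")
    model = st[0]

    # label_asym -> auth chain id map (needed for mmCIF asym_id_list)
    label_to_auth: dict[str, str] = {}
    sub_to_entity: dict[str, str] = {}
    for ent in st.entities:
        for sub in ent.subchains:
            sub_to_entity[sub] = ent.name or ""

    chains: list[Chain] = []
    chain_entity: dict[str, str] = {}
    for ch in model:
        residues = []
        ent_id = ""
        for res in ch:
            if not _is_amino(res):
                continue
            sub = res.subchain
            if sub:
                label_to_auth.setdefault(sub, ch.name)
                ent_id = sub_to_entity.get(sub, ent_id)
            atoms = _dedup_altlocs(res)
            if not atoms:
                continue
            residues.append(Residue(
                seq_num=res.seqid.num, name=res.name.upper(),
                icode=(res.seqid.icode or "").strip(), atoms=atoms,
            ))
        if residues:
            chains.append(Chain(chain_id=ch.name, entity_id="",
                                residues=residues))
            chain_entity[ch.name] = ent_id
    if not chains:
        raise ValueError(f"{path}: no polymer protein chains found")

    # Assign entity ids: honor parsed entity names where available,
    # otherwise group chains by identical derived sequence.
    seq_to_eid: dict[str, str] = {}
    next_eid = 1
    entities: dict[str, tuple[str, str]] = {}
    for ch in chains:
        # legacy PDB carries no entity ids; group chains by sequence there
        eid = (chain_entity.get(ch.chain_id) or "") if is_cif else ""
        if not eid:
            seq = ch.sequence
            if seq not in seq_to_eid:
                seq_to_eid[seq] = str(next_eid)
                next_eid += 1
            eid = seq_to_eid[seq]
        ch.entity_id = eid
        if eid not in entities:
            entities[eid] = (ch.sequence, "")

    structure = Structure(
        pdb_id=(st.name or path.stem).lower(), entities=entities,
        chains=chains,
        resolution=st.resolution if st.resolution > 0 else None,
    )

    if is_cif:
        doc = gemmi.cif.read(str(path))
        block = doc.sole_block()
        definitions, operators = _mmcif_assembly_info(block, label_to_auth)
    else:
        definitions, operators = _remark350_assembly_info(path.read_text())

    known_chains = {c.chain_id for c in structure.chains}
    known_ops = {o.operator_id for o in operators}
    for d in definitions:
        for expr, chain_ids in d.instructions:
            for cid in chain_ids:
                if cid not in known_chains:
                    raise ValueError(
                        f"{path}: assembly {d.assembly_id} references "
                        f"unknown chain {cid!r}"
                    )
            for oid in _expression_ids(expr):
                if oid not in known_ops:
                    raise ValueError(
                        f"{path}: assembly {d.assembly_id} references "
                        f"unknown operator {oid!r}"
                    )
    return structure, definitions, operators


# --- Operator expression grammar ---------------------------------------

def _parse_id_list(text: str) -> list[str]:
    ids = []
    for item in text.split(","):
        item = item.strip()
        if not item:
            raise ValueError(f"empty item in operator list {text!r}")
        if "-" in item and not item.startswith("-"):
            lo, _, hi = item.partition("-")
            if not (lo.strip().isdigit() and hi.strip().isdigit()):
                raise ValueError(f"malformed range {item!r}")
            lo_i, hi_i = int(lo), int(hi)
            if hi_i < lo_i:
                raise ValueError(f"descending range {item!r}")
            ids.extend(str(k) for k in range(lo_i, hi_i + 1))
        else:
            ids.append(item)
    return ids


def _parse_expression(expr: str) -> list[list[str]]:
    """Parse an oper_expression into factors (lists of operator ids)."""
    expr = expr.strip().strip("'\"")
    if not expr:
        raise ValueError("empty operator expression")
    if "(" in expr:
        factors = re.findall(r"\(([^()]*)\)", expr)
        rebuilt = "".join(f"({f})" for f in factors)
        if rebuilt != expr.replace(" ", ""):
            raise ValueError(f"malformed operator expression {expr!r}")
        return [_parse_id_list(f) for f in factors]
    return [_parse_id_list(expr)]


def _expression_ids(expr: str) -> set[str]:
    return {oid for factor in _parse_expression(expr) for oid in factor}


def compose_operators(first_applied: AssemblyOperator,
                      then: AssemblyOperator) -> AssemblyOperator:
    """The operator equivalent to applying ``first_applied`` then ``then``."""
    rot = then.rotation @ first_applied.rotation
    tr = then.rotation @ first_applied.translation + then.translation
    return AssemblyOperator(
        operator_id=f"{then.operator_id}*{first_applied.operator_id}",
        rotation=rot, translation=tr,
    )


def expand_operator_expression(
    expr: str, operators: list[AssemblyOperator]
) -> list[AssemblyOperator]:
    """Expand an mmCIF ``oper_expression`` into composed operators.

    Grammar: a comma list (``"1,2,3"``), ranges (``"1-60"``), and
    parenthesized products (``"(1-60)(61-88)"``).  In a product
    ``(P)(Q)`` the Q operator is applied first, then P (wwPDB
    convention); the result count is the product of the factor counts.
    """
    by_id = {op.operator_id: op for op in operators}
    factors = _parse_expression(expr)
    for factor in factors:
        for oid in factor:
            if oid not in by_id:
                raise ValueError(f"unknown operator id {oid!r} in {expr!r}")
    out = []
    for combo in itertools.product(*factors):
        ops = [by_id[oid] for oid in combo]
        acc = ops[-1]
        for op in reversed(ops[:-1]):
            acc = compose_operators(acc, op)
        if len(ops) == 1:
            acc = AssemblyOperator(operator_id=ops[0].operator_id,
                                   rotation=ops[0].rotation.copy(),
                                   translation=ops[0].translation.copy())
        out.append(acc)
    return out


def apply_operator(coords: np.ndarray, op: AssemblyOperator) -> np.ndarray:
    """Apply x' = R x + t to an N x 3 coordinate array."""
    coords = np.asarray(coords, dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite coordinates")
    return coords @ op.rotation.T + op.translation


# --- Assembly construction ---------------------------------------------

def _chain_id_generator():
    singles = ("ABCDEFGHIJKLMNOPQRSTUVWXYZ"
               "abcdefghijklmnopqrstuvwxyz")
    for c in singles:
        yield c
    count = 0
    for a in singles:
        for b in singles:
            if count >= 9999:
                raise ValueError("chain-id namespace exhausted")
            count += 1
            yield a + b
    raise ValueError("chain-id namespace exhausted")


def _transform_residues(residues: list[Residue],
                        op: AssemblyOperator) -> list[Residue]:
    if op.is_identity:
        return [Residue(seq_num=r.seq_num, name=r.name, icode=r.icode,
                        atoms=[Atom(a.name, a.element, a.pos.copy(),
                                    a.occupancy, a.b_factor)
                               for a in r.atoms])
                for r in residues]
    out = []
    for r in residues:
        atoms = [Atom(a.name, a.element,
                      op.rotation @ a.pos + op.translation,
                      a.occupancy, a.b_factor) for a in r.atoms]
        out.append(Residue(seq_num=r.seq_num, name=r.name, icode=r.icode,
                           atoms=atoms))
    return out


def build_assembly(
    structure: Structure,
    definition: AssemblyDefinition,
    operators: list[AssemblyOperator],
    include_chains: list[str] | None = None,
) -> AssemblyModel:
    """Generate biological-assembly chains from a definition.

    One generated chain per (composed operator x source chain), chains
    varying fastest within an operator; new chain ids run A..Z, a..z,
    then two-letter pairs.  Identity-operator copies keep the source
    coordinates bit-exactly.  ``include_chains`` filters by source chain
    id.
    """
    ids = _chain_id_generator()
    generated: list[GeneratedChain] = []
    for expr, chain_ids in definition.instructions:
        composed = expand_operator_expression(expr, operators)
        for op in composed:
            for cid in chain_ids:
                if include_chains is not None and cid not in include_chains:
                    continue
                src = structure.chain(cid)
                generated.append(GeneratedChain(
                    new_chain_id=next(ids),
                    source_chain_id=cid,
                    operator_id=op.operator_id,
                    entity_id=src.entity_id,
                    residues=_transform_residues(src.residues, op),
                ))
    return AssemblyModel(source=structure, assembly_id=definition.assembly_id,
                         chains=generated)


def assembly_composition(model: AssemblyModel) -> dict[str, int]:
    """Copy count per entity over the generated chains."""
    out: dict[str, int] = {}
    for ch in model.chains:
        out[ch.entity_id] = out.get(ch.entity_id, 0) + 1
    return out


# --- PDB output --------------------------------------------------------

def write_pdb(model, path, remarks: list[str] | None = None) -> None:
    """Write an assembly or complex model as fixed-column legacy PDB.

    At most 62 chains (single-character ids); TER between chains;
    occupancy and B-factor carried from the source atoms.
    """
    chains = model.chains
    if len(chains) > 62:
        raise ValueError(
            f"{len(chains)} chains exceed the 62 single-character chain ids "
            f"of the PDB format; write mmCIF instead"
        )
    serial = 0
    lines = []
    for text in remarks or []:
        lines.append(f"REMARK   3 {text}"[:80])
    for ch in chains:
        cid = ch.chain_id
        if len(cid) != 1:
            raise ValueError(f"chain id {cid!r} does not fit PDB format")
        for res in ch.residues:
            for atom in res.atoms:
                serial += 1
                name = atom.name
                if len(name) < 4 and len(atom.element) == 1:
                    name = f" {name}"
                lines.append(
                    f"ATOM  {serial:5d} {name:<4s}{'':1s}{res.name:>3s} "
                    f"{cid}{res.seq_num:4d}{res.icode or ' ':1s}   "
                    f"{atom.pos[0]:8.3f}{atom.pos[1]:8.3f}{atom.pos[2]:8.3f}"
                    f"{atom.occupancy:6.2f}{atom.b_factor:6.2f}"
                    f"          {atom.element:>2s}"
                )
        serial += 1
        last = ch.residues[-1]
        lines.append(
            f"TER   {serial:5d}      {last.name:>3s} {cid}"
            f"{last.seq_num:4d}{last.icode or ' ':1s}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
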