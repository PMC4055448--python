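"""Side-chain geometry: ideal internal coordinates and a rotamer table.

Rebuilt side chains are grown atom by atom with the standard NeRF
construction (bond length, bond angle, torsion against three placed
reference atoms).  The ideal bond lengths, angles and non-rotatable
torsions are measured at import time from the chemical-component
reference coordinates bundled with biotite, so the geometry table is the
CCD's, not a hand-maintained one; only the chi torsions about rotatable
bonds are free, and those come from a compact backbone-independent
rotamer table with per-residue-type priors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

BACKBONE_SET = {"N", "CA", "C", "O", "OXT"}

#: chi dihedrals per residue, standard atom quadruples.
CHI_DEFS: dict[str, list[tuple[str, str, str, str]]] = {
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "CYS": [("N", "CA", "CB", "SG")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "PRO": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD")],
    "SER": [("N", "CA", "CB", "OG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "VAL": [("N", "CA", "CB", "CG1")],
}

N_CHI = {res: len(defs) for res, defs in CHI_DEFS.items()}
N_CHI.update({"GLY": 0, "ALA": 0})


@dataclass
class RotamerEntry:
    """One discrete side-chain conformation with its prior probability."""

    residue_type: str  # 1-letter code
    chi: tuple[float, ...]
    prior: float

    def __post_init__(self):
        self.chi = tuple(float(c) for c in self.chi)
        for c in self.chi:
            if not -180.0 < c <= 180.0:
                raise ValueError(f"chi angle {c} outside (-180, 180]")
        if not 0.0 < self.prior <= 1.0:
            raise ValueError(f"prior {self.prior} outside (0, 1]")


# --- basic vector geometry --------------------------------------------

def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    ang = math.degrees(math.atan2(y, x))
    return 180.0 if ang <= -180.0 else ang


def bond_angle(a, b, c) -> float:
    """Angle a-b-c in degrees."""
    v1 = np.asarray(a) - np.asarray(b)
    v2 = np.asarray(c) - np.asarray(b)
    cosv = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return math.degrees(math.acos(np.clip(cosv, -1.0, 1.0)))


def place_atom(a, b, c, bond: float, angle_deg: float,
               torsion_deg: float) -> np.ndarray:
    """Place atom d given references a-b-c (NeRF construction).

    d is bonded to c at distance ``bond``, with angle b-c-d and dihedral
    a-b-c-d as specified.
    """
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    theta = math.radians(angle_deg)
    phi = math.radians(torsion_deg)
    d_local = np.array([
        -bond * math.cos(theta),
        -bond * math.sin(theta) * math.cos(phi),
        -bond * math.sin(theta) * math.sin(phi),
    ])
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    norm = np.linalg.norm(n)
    if norm < 1e-10:
        raise ValueError("collinear reference atoms")
    n /= norm
    m = np.cross(n, bc)
    frame = np.column_stack([bc, m, n])
    return c + frame @ d_local


# --- ideal geometry from the bundled chemical-component templates ------

@dataclass
class AtomRecipe:
    name: str
    element: str
    refs: tuple[str, str, str]  # (a, b, c); bonded to c
    bond: float
    angle: float
    torsion: float          # ideal torsion; replaced when on a chi axis
    chi_index: int | None   # 0-based chi this torsion rides on
    chi_offset: float       # torsion = chi + offset when chi_index set


def _element_of(name: str) -> str:
    return name[0]


@lru_cache(maxsize=None)
def ideal_recipe(res3: str) -> list[AtomRecipe]:
    """Side-chain build recipe (CB outward) for one residue type.

    Atom order is a breadth-first walk of the CCD bond graph from CB;
    each atom's internal coordinates are measured from the ideal
    template coordinates, so rebuilding with unchanged torsions
    reproduces the template geometry exactly.
    """
    import biotite.structure.info as info

    res3 = res3.upper()
    if res3 in ("GLY",):
        return []
    template = info.residue(res3)
    heavy = [i for i, (el, nm) in
             enumerate(zip(template.element, template.atom_name))
             if el != "H" and nm != "OXT"]
    names = {i: template.atom_name[i] for i in heavy}
    index_of = {template.atom_name[i]: i for i in heavy}
    coords = {template.atom_name[i]: template.coord[i] for i in heavy}
    bonds = template.bonds.as_array()
    adj: dict[str, list[str]] = {names[i]: [] for i in heavy}
    for i, j, _ in bonds:
        if i in names and j in names:
            adj[names[i]].append(names[j])
            adj[names[j]].append(names[i])

    # tree parents; the backbone stub N<-C gives CB its torsion reference
    parent = {"CA": "N", "N": "C"}
    order: list[str] = []
    queue = ["CB"]
    seen = {"N", "CA", "C", "O", "CB"}
    parent["CB"] = "CA"
    order.append("CB")
    while queue:
        cur = queue.pop(0)
        for nb in sorted(adj.get(cur, [])):
            if nb in seen or nb in BACKBONE_SET:
                continue
            seen.add(nb)
            parent[nb] = cur
            order.append(nb)
            queue.append(nb)

    chi_defs = CHI_DEFS.get(res3, [])
    axis_of = {}
    for k, (qa, qb, qc, qd) in enumerate(chi_defs):
        axis_of[(qb, qc)] = (k, qd)

    recipes = []
    for name in order:
        c = parent[name]
        b = parent[c]
        a = parent[b]
        bond = float(np.linalg.norm(coords[name] - coords[c]))
        angle = bond_angle(coords[b], coords[c], coords[name])
        torsion = dihedral(coords[a], coords[b], coords[c], coords[name])
        chi_index = None
        chi_offset = 0.0
        if (b, c) in axis_of:
            chi_index, primary = axis_of[(b, c)]
            ideal_primary = dihedral(coords[a], coords[b], coords[c],
                                     coords[primary])
            chi_offset = torsion - ideal_primary
        recipes.append(AtomRecipe(
            name=name, element=_element_of(name), refs=(a, b, c),
            bond=bond, angle=angle, torsion=torsion,
            chi_index=chi_index, chi_offset=chi_offset,
        ))
    return recipes


def build_side_chain(
    backbone: dict[str, np.ndarray],
    res3: str,
    chis: tuple[float, ...] = (),
) -> list[tuple[str, str, np.ndarray]]:
    """Build side-chain heavy atoms onto a placed backbone.

    ``backbone`` must contain N, CA, C (and may contain CB, which is
    then kept rather than rebuilt).  Returns ``(name, element, coord)``
    tuples for every atom built, in build order.  ``chis`` supplies the
    rotatable torsions; missing chis fall back to the ideal-template
    torsion.
    """
    res3 = res3.upper()
    coords = {k: np.asarray(v, dtype=float) for k, v in backbone.items()}
    for need in ("N", "CA", "C"):
        if need not in coords:
            raise ValueError(f"backbone atom {need} required to build "
                             f"{res3} side chain")
    placed = []
    for rec in ideal_recipe(res3):
        if rec.name in coords:
            continue  # e.g. CB copied from the template
        torsion = rec.torsion
        if rec.chi_index is not None and rec.chi_index < len(chis):
            torsion = chis[rec.chi_index] + rec.chi_offset
        a, b, c = (coords[r] for r in rec.refs)
        pos = place_atom(a, b, c, rec.bond, rec.angle, torsion)
        coords[rec.name] = pos
        placed.append((rec.name, rec.element, pos))
    return placed


# --- compact backbone-independent rotamer table ------------------------

_CHI1 = [(-65.0, 0.50), (180.0, 0.30), (62.0, 0.20)]
_CHI2 = [(180.0, 0.50), (-65.0, 0.30), (65.0, 0.20)]


def _product(res: str, chi1, chi2, tail=()):
    out = []
    for c1, p1 in chi1:
        for c2, p2 in chi2:
            out.append((res, (c1, c2) + tail, p1 * p2))
    return out


def _raw_rotamers() -> list[tuple[str, tuple[float, ...], float]]:
    rows: list[tuple[str, tuple[float, ...], float]] = []
    for res in "SCTV":
        rows.extend((res, (c,), p) for c, p in _CHI1)
    rows += [
        ("L", (-65.0, 175.0), 0.55), ("L", (177.0, 65.0), 0.30),
        ("L", (-85.0, 65.0), 0.08), ("L", (177.0, 180.0), 0.07),
        ("I", (-65.0, 170.0), 0.55), ("I", (-57.0, -60.0), 0.15),
        ("I", (62.0, 170.0), 0.15), ("I", (177.0, 165.0), 0.15),
        ("P", (25.0, -35.0), 0.50), ("P", (-25.0, 35.0), 0.50),
    ]
    for res in "FYHW":
        for c1, p1 in _CHI1:
            for c2, p2 in ((90.0, 0.5), (-90.0, 0.5)):
                rows.append((res, (c1, c2), p1 * p2))
    for res in "DN":
        for c1, p1 in _CHI1:
            for c2, p2 in ((-20.0, 0.4), (60.0, 0.35), (150.0, 0.25)):
                rows.append((res, (c1, c2), p1 * p2))
    for res in "EQM":
        rows.extend(_product(res, _CHI1, _CHI2, tail=(180.0,)))
    rows.extend(_product("K", _CHI1, _CHI2, tail=(180.0, 180.0)))
    rows.extend(_product("R", _CHI1, _CHI2, tail=(180.0, 180.0)))
    return rows


@lru_cache(maxsize=1)
def default_rotamer_library() -> tuple[RotamerEntry, ...]:
    """The built-in rotamer table (~110 entries, priors normalized)."""
    rows = _raw_rotamers()
    totals: dict[str, float] = {}
    for res, _, p in rows:
        totals[res] = totals.get(res, 0.0) + p
    return tuple(
        RotamerEntry(residue_type=res, chi=chi, prior=p / totals[res])
        for res, chi, p in rows
    )


def write_rotamer_table(library, path) -> None:
    """Serialize a rotamer library as TSV (residue, prior, chi1..chi4)."""
    with open(path, "w") as fh:
        fh.write("residue_type\tprior\tchi1\tchi2\tchi3\tchi4\n")
        for e in library:
            chis = list(e.chi) + [""] * (4 - len(e.chi))
            chis = [f"{c:.1f}" if c != "" else "" for c in chis]
            fh.write(f"{e.residue_type}\t{e.prior:.6f}\t"
                     + "\t".join(chis) + "\n")


def load_rotamer_table(path) -> list[RotamerEntry]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("residue_type"):
            raise ValueError(f"{path}: missing rotamer table header")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: malformed row at line {lineno}")
            chis = tuple(float(f) for f in fields[2:6] if f != "")
            out.append(RotamerEntry(residue_type=fields[0], chi=chis,
                                    prior=float(fields[1])))
    return out
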