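"""Macromolecular structure parsing and Ramachandran validation.

Binding-site residues that sit in sterically disallowed (phi, psi) regions
are a red flag for docking studies: a pose built on strained backbone
geometry is a likely false positive.  This module parses PDB files, computes
backbone dihedrals, classifies each residue against a shipped coarse
polygonal Ramachandran contour (general case), and reports the percentage
of binding-site residues in favored-or-allowed regions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import gemmi
import numpy as np
from matplotlib.path import Path as MplPath

__all__ = [
    "Atom",
    "Structure",
    "ResidueGeometry",
    "RamachandranClass",
    "read_structure",
    "dihedral",
    "compute_phi_psi",
    "classify_ramachandran",
    "site_flexibility_report",
    "write_rama_report",
]


@dataclass(frozen=True)
class Atom:
    chain_id: str
    res_seq: int
    icode: str
    res_name: str
    atom_name: str
    element: str
    coord: tuple[float, float, float]
    occupancy: float = 1.0
    het: bool = False

    @property
    def residue_id(self) -> tuple[str, int, str]:
        return (self.chain_id, self.res_seq, self.icode)


class Structure:
    """Flat atom list with chain/residue grouping helpers.

    Residue identity is (chain id, author residue number, insertion code);
    residues keep file order within each chain.
    """

    def __init__(self, atoms: Sequence[Atom]):
        if not atoms:
            raise ValueError("empty structure: no ATOM/HETATM records")
        for a in atoms:
            if not all(np.isfinite(a.coord)):
                raise ValueError(f"non-finite coordinate on atom {a}")
        self.atoms: list[Atom] = list(atoms)
        # chain -> ordered residue ids -> {atom_name: Atom}
        self._chains: dict[str, dict[tuple[str, int, str], dict[str, Atom]]] = {}
        for a in self.atoms:
            res = self._chains.setdefault(a.chain_id, {}).setdefault(a.residue_id, {})
            if a.atom_name in res:
                raise ValueError(f"duplicate atom {a.atom_name} in residue {a.residue_id}")
            res[a.atom_name] = a

    @property
    def chain_ids(self) -> list[str]:
        return list(self._chains)

    def residues(self, chain_id: str) -> list[tuple[str, int, str]]:
        return list(self._chains[chain_id])

    def n_residues(self) -> int:
        return sum(len(c) for c in self._chains.values())

    def atom(self, residue_id: tuple[str, int, str], atom_name: str) -> Atom | None:
        return self._chains.get(residue_id[0], {}).get(residue_id, {}).get(atom_name)

    def residue_name(self, residue_id: tuple[str, int, str]) -> str:
        res = self._chains[residue_id[0]][residue_id]
        return next(iter(res.values())).res_name


def read_structure(path: str) -> Structure:
    """Read a PDB file keeping one atom per (chain, residue, atom name).

    Alternate locations are resolved to the highest-occupancy conformer
    (ties: first occurrence).  HETATM records are retained and flagged.
    """
    try:
        st = gemmi.read_pdb(str(path))
    except Exception as exc:  # unreadable / not PDB
        raise IOError(f"cannot read PDB file {path!r}: {exc}") from exc
    best: dict[tuple, Atom] = {}
    order: list[tuple] = []
    for model in st:
        for chain in model:
            for res in chain:
                for at in res:
                    key = (chain.name, res.seqid.num, res.seqid.icode.strip(), at.name)
                    rec = Atom(
                        chain_id=chain.name,
                        res_seq=res.seqid.num,
                        icode=res.seqid.icode.strip(),
                        res_name=res.name,
                        atom_name=at.name,
                        element=at.element.name,
                        coord=(at.pos.x, at.pos.y, at.pos.z),
                        occupancy=at.occ,
                        het=res.het_flag == "H",
                    )
                    if key not in best:
                        best[key] = rec
                        order.append(key)
                    elif rec.occupancy > best[key].occupancy:
                        best[key] = rec
        break  # first model only
    if not best:
        raise ValueError(f"no ATOM/HETATM records in {path!r}")
    return Structure([best[k] for k in order])


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle (IUPAC convention) in degrees, in (-180, 180]."""
    b0 = np.asarray(p0, float) - np.asarray(p1, float)
    b1 = np.asarray(p2, float) - np.asarray(p1, float)
    b2 = np.asarray(p3, float) - np.asarray(p2, float)
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - (b0 @ b1) * b1
    w = b2 - (b2 @ b1) * b1
    x = float(v @ w)
    y = float(np.cross(b1, v) @ w)
    ang = np.degrees(np.arctan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


@dataclass(frozen=True)
class ResidueGeometry:
    chain_id: str
    res_seq: int
    icode: str
    res_name: str
    phi: float | None
    psi: float | None


def compute_phi_psi(s: Structure) -> list[ResidueGeometry]:
    """Backbone dihedrals per residue.

    phi(i) = C(i-1)-N(i)-CA(i)-C(i); psi(i) = N(i)-CA(i)-C(i)-N(i+1).
    An angle is None when the residue is terminal or a required backbone
    atom is missing (never an exception).  HETATM-only residues (waters,
    ligands) are skipped.
    """
    out: list[ResidueGeometry] = []
    for chain_id in s.chain_ids:
        rids = [r for r in s.residues(chain_id) if s.atom(r, "CA") is not None]
        for k, rid in enumerate(rids):
            n, ca, c = (s.atom(rid, nm) for nm in ("N", "CA", "C"))
            prev_c = s.atom(rids[k - 1], "C") if k > 0 else None
            next_n = s.atom(rids[k + 1], "N") if k + 1 < len(rids) else None
            phi = psi = None
            if prev_c is not None and None not in (n, ca, c):
                phi = dihedral(prev_c.coord, n.coord, ca.coord, c.coord)
            if next_n is not None and None not in (n, ca, c):
                psi = dihedral(n.coord, ca.coord, c.coord, next_n.coord)
            out.append(
                ResidueGeometry(chain_id, rid[1], rid[2], s.residue_name(rid), phi, psi)
            )
    return out


@dataclass(frozen=True)
class RamachandranClass:
    label: str  # favored | allowed | disallowed | not-classifiable
    region: str | None = None


def _load_contours() -> dict[str, list[tuple[str, MplPath]]]:
    raw = json.loads(
        resources.files("fibriddi.data").joinpath("rama_contour.json").read_text()
    )
    table: dict[str, list[tuple[str, MplPath]]] = {}
    for tier in ("favored", "allowed"):
        table[tier] = [
            (name.removesuffix("-wrap"), MplPath(np.asarray(poly)))
            for name, poly in raw[tier].items()
        ]
    return table


_CONTOURS = _load_contours()


def classify_ramachandran(phi: float | None, psi: float | None) -> RamachandranClass:
    """Classify (phi, psi) against the shipped contour table.

    Pure function of its arguments; the favored tier is a strict subset of
    the allowed tier, so every favored residue is also allowed.
    """
    if phi is None or psi is None:
        return RamachandranClass("not-classifiable")
    pt = (float(phi), float(psi))
    for name, path in _CONTOURS["favored"]:
        if path.contains_point(pt, radius=1e-9):
            return RamachandranClass("favored", name)
    for name, path in _CONTOURS["allowed"]:
        if path.contains_point(pt, radius=1e-9):
            return RamachandranClass("allowed", name)
    return RamachandranClass("disallowed")


def site_flexibility_report(
    s: Structure, residues: Iterable[tuple[str, int]]
) -> float:
    """Percent of the listed binding-site residues in favored-or-allowed regions.

    ``residues`` is a list of (chain id, author residue number) pairs.  Only
    residues with both dihedrals defined count toward the denominator, so
    chain termini do not dilute the statistic.
    """
    wanted = {(c, int(n)) for c, n in residues}
    if not wanted:
        raise ValueError("empty binding-site residue list")
    geoms = {
        (g.chain_id, g.res_seq): g for g in compute_phi_psi(s)
    }
    n_class = n_ok = 0
    for key in wanted:
        g = geoms.get(key)
        if g is None:
            continue
        cls = classify_ramachandran(g.phi, g.psi)
        if cls.label == "not-classifiable":
            continue
        n_class += 1
        if cls.label in ("favored", "allowed"):
            n_ok += 1
    if n_class == 0:
        raise ValueError("no classifiable residue in the requested site")
    return 100.0 * n_ok / n_class


def write_rama_report(s: Structure, path: str) -> None:
    """TSV report: chain, resnum, icode, resname, phi, psi, class, region."""
    with open(path, "w") as fh:
        fh.write("chain\tresnum\ticode\tresname\tphi\tpsi\tclass\tregion\n")
        for g in compute_phi_psi(s):
            cls = classify_ramachandran(g.phi, g.psi)
            fmt = lambda v: "" if v is None else f"{v:.2f}"  # noqa: E731
            fh.write(
                f"{g.chain_id}\t{g.res_seq}\t{g.icode}\t{g.res_name}\t"
                f"{fmt(g.phi)}\t{fmt(g.psi)}\t{cls.label}\t{cls.region or ''}\n"
            )
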