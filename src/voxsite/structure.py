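"""Protein structure I/O and active-site queries.

Structures are ordered atom lists read from PDB (fixed-column) or PQR
(whitespace-delimited, with per-atom charge and radius) text.  Backbone
atoms are flagged by name — ``N, CA, C, O, OXT`` plus the hydrogens bonded
to them — so that downstream featurization can restrict itself to side
chains.  Coordinates are Cartesian angstroms throughout; no unit conversion
happens at I/O time.
"""

from __future__ import annotations

import io
import math
import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .errors import ParseError, VoxsiteError

#: Atom names treated as backbone.  CB is deliberately side chain so that
#: alanine retains one informative atom.
BACKBONE_NAMES = frozenset({"N", "CA", "C", "O", "OXT"})

#: Hydrogen names attached to backbone atoms in common naming schemes.
BACKBONE_H_NAMES = frozenset({"H", "H1", "H2", "H3", "HA", "HA2", "HA3", "HN"})


def is_backbone_name(name: str) -> bool:
    return name in BACKBONE_NAMES or name in BACKBONE_H_NAMES


@dataclass(frozen=True)
class Atom:
    """A single atom record.

    ``charge`` is in units of the elementary charge *e* and is ``None``
    unless a charge-bearing format (PQR) was read or the caller set it.
    """

    serial: int
    name: str
    element: str
    res_name: str
    res_seq: int
    chain: str
    xyz: tuple[float, float, float]
    charge: float | None = None
    icode: str = ""

    def __post_init__(self):
        if not self.element:
            raise VoxsiteError(f"atom {self.serial} {self.name!r}: empty element")
        if not all(math.isfinite(c) for c in self.xyz):
            raise VoxsiteError(f"atom {self.serial} {self.name!r}: non-finite coordinates")

    @property
    def is_backbone(self) -> bool:
        return is_backbone_name(self.name)

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Identity triplet (chain, res_seq+icode, name) used for uniqueness."""
        return (self.chain, self.res_seq, self.icode, self.name)


@dataclass
class Structure:
    """An ordered list of atoms with an optional class label (e.g. an EC string)."""

    id: str
    atoms: list[Atom] = field(default_factory=list)
    label: str | None = None

    def __post_init__(self):
        seen: set[tuple] = set()
        for a in self.atoms:
            if a.key in seen:
                raise VoxsiteError(
                    f"structure {self.id!r}: duplicate atom "
                    f"(chain {a.chain!r}, residue {a.res_seq}{a.icode}, name {a.name!r})"
                )
            seen.add(a.key)

    def __len__(self) -> int:
        return len(self.atoms)

    def residues(self) -> list[tuple[str, int, str]]:
        """Unique (chain, res_seq, res_name) in order of first appearance."""
        out, seen = [], set()
        for a in self.atoms:
            k = (a.chain, a.res_seq, a.icode)
            if k not in seen:
                seen.add(k)
                out.append((a.chain, a.res_seq, a.res_name))
        return out

    def atoms_of(self, chain: str, res_seq: int) -> list[Atom]:
        return [a for a in self.atoms if a.chain == chain and a.res_seq == res_seq]

    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms], dtype=float).reshape(-1, 3)

    def charges(self) -> np.ndarray:
        q = [a.charge for a in self.atoms]
        if any(c is None for c in q):
            raise VoxsiteError(f"structure {self.id!r}: atoms without charges")
        return np.asarray(q, dtype=float)

    def net_charge(self) -> float:
        return float(self.charges().sum())

    def translated(self, t) -> "Structure":
        t = np.asarray(t, dtype=float)
        atoms = [replace(a, xyz=tuple(np.asarray(a.xyz) + t)) for a in self.atoms]
        return Structure(id=self.id, atoms=atoms, label=self.label)


@dataclass
class SiteSpec:
    """Catalytic-residue specification plus the sampling box geometry.

    ``box_edge`` (default 20 Å) is the cube edge placed at the geometric
    center of the named residues; ``voxel_edge`` (default 1 Å) divides it.
    """

    residues: list[tuple[str, int]]
    box_edge: float = 20.0
    voxel_edge: float = 1.0

    def __post_init__(self):
        if self.box_edge <= 0 or self.voxel_edge <= 0:
            raise VoxsiteError("box_edge and voxel_edge must be positive")
        n = self.box_edge / self.voxel_edge
        if abs(n - round(n)) > 1e-9:
            raise VoxsiteError("box_edge must be an integer multiple of voxel_edge")
        if not self.residues:
            raise VoxsiteError("SiteSpec needs at least one residue")

    @property
    def n_voxels(self) -> int:
        return int(round(self.box_edge / self.voxel_edge))


# ---------------------------------------------------------------------------
# Parsing

def _as_lines(source) -> list[str]:
    if isinstance(source, (str, os.PathLike)):
        s = os.fspath(source) if isinstance(source, os.PathLike) else source
        if "\n" not in s and os.path.exists(s):
            with open(s) as fh:
                return fh.readlines()
        return io.StringIO(s).readlines()
    if hasattr(source, "read"):
        return source.read().splitlines(keepends=True)
    return list(source)


def _guess_element(name: str) -> str:
    # PDB v2-style names: a leading digit means hydrogen (e.g. 1HB);
    # otherwise the first alphabetic character is the element for organics.
    stripped = name.strip()
    if not stripped:
        return ""
    if stripped[0].isdigit():
        return "H"
    # "CA" is deliberately absent: a bare CA name is a backbone carbon,
    # not calcium, in the structures this package handles.
    for two in ("CL", "BR", "NA", "MG", "ZN", "FE", "MN"):
        # only trust two-letter metals when the name is exactly the symbol
        if stripped.upper() == two:
            return two.capitalize()
    return stripped[0].upper()


def read_structure(source, structure_id: str = "structure") -> Structure:
    """Parse PDB-format text (path, string, or stream) into a :class:`Structure`.

    One :class:`Atom` per ATOM/HETATM record; the first altloc of each atom is
    kept and later ones are dropped.  Raises :class:`ParseError` with the line
    number on malformed records, and :class:`VoxsiteError` on empty input or
    duplicated (chain, res_seq, name) triplets.
    """
    lines = _as_lines(source)
    atoms: list[Atom] = []
    seen_altloc: set[tuple] = set()
    for ln, line in enumerate(lines, start=1):
        rec = line[:6].strip()
        if rec not in ("ATOM", "HETATM"):
            continue
        try:
            serial = int(line[6:11])
            name = line[12:16].strip()
            altloc = line[16:17].strip()
            res_name = line[17:20].strip()
            chain = line[21:22].strip()
            res_seq = int(line[22:26])
            icode = line[26:27].strip()
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
            element = line[76:78].strip() if len(line) >= 78 else ""
        except (ValueError, IndexError) as exc:
            raise ParseError(f"malformed {rec} record: {exc}", ln) from None
        if altloc:
            ak = (chain, res_seq, icode, name)
            if ak in seen_altloc:
                continue
            seen_altloc.add(ak)
        if not element:
            element = _guess_element(name)
        atoms.append(
            Atom(serial=serial, name=name, element=element.capitalize(),
                 res_name=res_name, res_seq=res_seq, chain=chain,
                 xyz=(x, y, z), icode=icode)
        )
    if not atoms:
        raise VoxsiteError("no ATOM/HETATM records found in input")
    return Structure(id=structure_id, atoms=atoms)


def read_charged_structure(source, structure_id: str = "structure") -> Structure:
    """Parse PQR-dialect text: ``ATOM serial name res [chain] resseq x y z q r``.

    The per-atom charge (e) is kept on :attr:`Atom.charge`; the radius column
    is read for validation and discarded.  A PDB file (no charge/radius
    columns) is rejected.
    """
    lines = _as_lines(source)
    atoms: list[Atom] = []
    for ln, line in enumerate(lines, start=1):
        if not line[:6].strip() in ("ATOM", "HETATM"):
            continue
        tok = line.split()
        if len(tok) == 11:
            _, serial, name, res_name, chain, res_seq, x, y, z, q, r = tok
        elif len(tok) == 10:
            _, serial, name, res_name, res_seq, x, y, z, q, r = tok
            chain = ""
        else:
            raise ParseError(
                f"expected 10 or 11 whitespace-separated PQR fields, got {len(tok)} "
                "(missing charge/radius columns?)", ln)
        try:
            atoms.append(
                Atom(serial=int(serial), name=name, element=_guess_element(name),
                     res_name=res_name, res_seq=int(res_seq), chain=chain,
                     xyz=(float(x), float(y), float(z)), charge=float(q))
            )
            float(r)
        except ValueError as exc:
            raise ParseError(f"malformed PQR record: {exc}", ln) from None
    if not atoms:
        raise VoxsiteError("no ATOM/HETATM records found in input")
    return Structure(id=structure_id, atoms=atoms)


# ---------------------------------------------------------------------------
# Writing

_PDB_FMT = ("{rec:<6s}{serial:>5d} {name:<4s}{altloc:1s}{res:<3s} {chain:1s}"
            "{res_seq:>4d}{icode:1s}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}"
            "          {element:>2s}")


def _pdb_atom_name(name: str) -> str:
    # Columns 13-16: names of 1-3 chars start in column 14 unless the first
    # character is part of a two-letter element symbol.
    return name if len(name) >= 4 else f" {name:<3s}"


def write_structure(s: Structure, fmt: str = "PDB") -> str:
    """Serialize to PDB fixed-column or PQR text; ``read ∘ write`` is identity
    on the modelled fields.  PQR output requires every atom to carry a charge.
    """
    fmt = fmt.upper()
    if fmt not in ("PDB", "PQR"):
        raise VoxsiteError(f"unknown format {fmt!r}; expected PDB or PQR")
    lines = [f"REMARK   voxsite structure {s.id}"]
    if fmt == "PQR":
        if any(a.charge is None for a in s.atoms):
            raise VoxsiteError("PQR output requires a charge on every atom")
        for a in s.atoms:
            lines.append(
                f"ATOM  {a.serial:>5d} {a.name:<4s} {a.res_name:<3s} "
                f"{a.chain or 'A':1s} {a.res_seq:>4d}    "
                f"{a.xyz[0]:10.4f} {a.xyz[1]:10.4f} {a.xyz[2]:10.4f} "
                f"{a.charge:8.4f} {1.5:7.4f}"
            )
    else:
        for a in s.atoms:
            lines.append(_PDB_FMT.format(
                rec="ATOM", serial=a.serial, name=_pdb_atom_name(a.name),
                altloc="", res=a.res_name, chain=a.chain or "A",
                res_seq=a.res_seq, icode=a.icode or "",
                x=a.xyz[0], y=a.xyz[1], z=a.xyz[2], occ=1.0, b=0.0,
                element=a.element.upper()))
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Site queries

def sidechain_heavy_atoms(s: Structure, chain: str, res_seq: int) -> list[Atom]:
    return [a for a in s.atoms_of(chain, res_seq)
            if not a.is_backbone and not a.is_hydrogen]


def site_center(s: Structure, spec: SiteSpec) -> np.ndarray:
    """Unweighted mean of the side-chain heavy atoms of the named residues (Å).

    This is the geometric center on which the sampling box is placed.
    """
    coords = []
    for chain, res_seq in spec.residues:
        atoms = sidechain_heavy_atoms(s, chain, res_seq)
        if not atoms:
            raise VoxsiteError(
                f"site residue (chain {chain!r}, {res_seq}) has no side-chain "
                f"heavy atoms in structure {s.id!r}")
        coords.extend(a.xyz for a in atoms)
    return np.mean(np.asarray(coords, dtype=float), axis=0)
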