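"""Synthetic structure families, charged test systems and kinetic datasets.

The structure generator emulates, at desk scale, small labelled families of
enzymes whose class identity is carried by side-chain composition near a
catalytic triad: a fixed ring scaffold of 16 residues (radius 9 Å, side
chains pointing inward) carries a Ser–His–Asp triad at fixed positions, and
each family template overrides designated *motif* positions with its own
residue types.  Per-structure i.i.d. Gaussian coordinate jitter stands in
for conformational diversity.  The geometry is idealized pseudo-atom
placement, not rotamer-accurate chemistry: the featurizer consumes only atom
identities and positions, so this is sufficient to make family membership
learnable and the planted motif residues recoverable by an alanine scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import VoxsiteError
from .features import SIDECHAIN_ATOMS
from .structure import Atom, SiteSpec, Structure

N_POSITIONS = 16
RING_RADIUS = 9.0      # Å
TRIAD_POSITIONS = (0, 5, 11)          # SER, HIS, ASP
DEFAULT_MOTIF_POSITION = 8

#: Background residue sequence; triad positions hold the catalytic residues.
DEFAULT_SCAFFOLD = (
    "SER", "LEU", "THR", "VAL", "PHE", "HIS", "PRO", "ILE",
    "ALA", "ASN", "LEU", "ASP", "GLN", "MET", "VAL", "THR",
)

#: Assay substrate concentrations (M): 10, 50, 100, 250, 500, 1000, 2000, 3000 µM.
DEFAULT_CONCENTRATIONS_M = (10e-6, 50e-6, 100e-6, 250e-6, 500e-6,
                            1000e-6, 2000e-6, 3000e-6)


@dataclass
class FamilyTemplate:
    """One synthetic enzyme family: scaffold + class-defining motif residues."""

    class_name: str
    motif_residues: tuple[tuple[int, str], ...] = ((DEFAULT_MOTIF_POSITION, "TRP"),)
    scaffold: tuple[str, ...] = DEFAULT_SCAFFOLD
    jitter_sigma: float = 0.25     # Å
    n_structures: int = 30
    seed: int | None = None

    def __post_init__(self):
        if self.jitter_sigma < 0:
            raise VoxsiteError("jitter_sigma must be >= 0")
        if self.n_structures < 1:
            raise VoxsiteError("n_structures must be >= 1")
        if len(self.scaffold) != N_POSITIONS:
            raise VoxsiteError(f"scaffold must list {N_POSITIONS} residues")
        for pos, res in self.motif_residues:
            if not 0 <= pos < N_POSITIONS or pos in TRIAD_POSITIONS:
                raise VoxsiteError(f"invalid motif position {pos}")
            if res not in SIDECHAIN_ATOMS:
                raise VoxsiteError(f"unknown motif residue {res!r}")

    def sequence(self) -> list[str]:
        seq = list(self.scaffold)
        for pos, res in self.motif_residues:
            seq[pos] = res
        return seq


def triad_site_spec(box_edge: float = 20.0, voxel_edge: float = 1.0) -> SiteSpec:
    """SiteSpec naming the scaffold's Ser–His–Asp triad."""
    return SiteSpec(residues=[("A", p + 1) for p in TRIAD_POSITIONS],
                    box_edge=box_edge, voxel_edge=voxel_edge)


def default_templates(jitter_sigma: float = 0.25, n_structures: int = 30
                      ) -> list[FamilyTemplate]:
    """Three-class benchmark: one planted discriminative residue per family.

    The classes mirror a three-family serine-hydrolase setup (carboxylesterase
    / lipase / phospholipase EC labels); the motif residues TRP / LYS / GLU
    occupy disjoint feature channels, which guarantees linear separability of
    the voxelized sites.
    """
    return [
        FamilyTemplate("EC 3.1.1.1", ((DEFAULT_MOTIF_POSITION, "TRP"),),
                       jitter_sigma=jitter_sigma, n_structures=n_structures),
        FamilyTemplate("EC 3.1.1.3", ((DEFAULT_MOTIF_POSITION, "LYS"),),
                       jitter_sigma=jitter_sigma, n_structures=n_structures),
        FamilyTemplate("EC 3.1.1.4", ((DEFAULT_MOTIF_POSITION, "GLU"),),
                       jitter_sigma=jitter_sigma, n_structures=n_structures),
    ]


def _scaffold_atoms(sequence: list[str]) -> list[Atom]:
    """Idealized coordinates for one structure (no jitter)."""
    atoms: list[Atom] = []
    serial = 1
    for i, res in enumerate(sequence):
        theta = 2.0 * np.pi * i / N_POSITIONS
        outward = np.array([np.cos(theta), np.sin(theta), 0.0])
        inward = -outward
        tangent = np.array([-np.sin(theta), np.cos(theta), 0.0])
        z = np.array([0.0, 0.0, 1.5 * ((i % 4) - 1.5)])
        ca = RING_RADIUS * outward + z

        def add(name, element, xyz):
            nonlocal serial
            atoms.append(Atom(serial=serial, name=name, element=element,
                              res_name=res, res_seq=i + 1, chain="A",
                              xyz=tuple(xyz)))
            serial += 1

        add("N", "N", ca - 1.46 * tangent)
        add("CA", "C", ca)
        add("C", "C", ca + 1.53 * tangent)
        add("O", "O", ca + 1.53 * tangent + 1.23 * outward)
        for k, (name, (element, _)) in enumerate(SIDECHAIN_ATOMS[res].items()):
            depth = 1.5 + 1.25 * ((k + 1) // 2)
            lateral = 0.0 if k == 0 else (0.9 if k % 2 == 1 else -0.9)
            zoff = 0.3 * (k % 3 - 1)
            xyz = ca + depth * inward + lateral * tangent + np.array([0, 0, zoff])
            add(name, element, xyz)
    return atoms


def generate_family_dataset(templates: list[FamilyTemplate],
                            seed: int = 0) -> list[Structure]:
    """Labelled structures for every template, deterministic per seed.

    Each structure is the shared scaffold with the template's motif residues
    and i.i.d. Gaussian jitter on every atom coordinate.
    """
    if len(templates) < 2:
        raise VoxsiteError("need at least 2 templates")
    names = [t.class_name for t in templates]
    if len(set(names)) != len(names):
        raise VoxsiteError("duplicate class names among templates")
    motifs = [tuple(t.motif_residues) for t in templates]
    if len(set(motifs)) != len(motifs):
        raise VoxsiteError("motif residues must differ between templates")

    out: list[Structure] = []
    for ti, tpl in enumerate(templates):
        rng = np.random.default_rng(tpl.seed if tpl.seed is not None
                                    else [seed, ti])
        base = _scaffold_atoms(tpl.sequence())
        for j in range(tpl.n_structures):
            jitter = (rng.normal(0.0, tpl.jitter_sigma, size=(len(base), 3))
                      if tpl.jitter_sigma > 0 else np.zeros((len(base), 3)))
            atoms = [Atom(serial=a.serial, name=a.name, element=a.element,
                          res_name=a.res_name, res_seq=a.res_seq, chain=a.chain,
                          xyz=tuple(np.asarray(a.xyz) + jitter[k]))
                     for k, a in enumerate(base)]
            out.append(Structure(id=f"{tpl.class_name.replace(' ', '_')}-{j:03d}",
                                 atoms=atoms, label=tpl.class_name))
    return out


def generate_charged_system(layout: str = "random-cloud", n: int = 8,
                            seed: int = 0) -> tuple[Structure, float]:
    """Small point-charge systems for electrostatics tests.

    Layouts: ``point`` (a single -1 e charge), ``dipole`` (+1/-1 e separated
    by 1 Å, net zero) and ``random-cloud`` (n charges uniform in a 10 Å cube
    with uniform charges in [-1, 1] e).  Returns the structure and its
    declared net charge.
    """
    rng = np.random.default_rng(seed)
    if layout == "point":
        spec = [((0.0, 0.0, 0.0), -1.0)]
    elif layout == "dipole":
        spec = [((0.5, 0.0, 0.0), 1.0), ((-0.5, 0.0, 0.0), -1.0)]
    elif layout == "random-cloud":
        if n < 1:
            raise VoxsiteError("n must be >= 1")
        pos = rng.uniform(-5.0, 5.0, size=(n, 3))
        q = rng.uniform(-1.0, 1.0, size=n)
        spec = [(tuple(p), float(c)) for p, c in zip(pos, q)]
    else:
        raise VoxsiteError(f"unknown layout {layout!r}")
    atoms = [Atom(serial=i + 1, name="C", element="C", res_name="CHG",
                  res_seq=i + 1, chain="A", xyz=xyz, charge=q)
             for i, (xyz, q) in enumerate(spec)]
    s = Structure(id=f"charged-{layout}", atoms=atoms)
    return s, s.net_charge()


def generate_kinetics_data(kcat: float = 18.54e-3, KM: float = 0.182e-3,
                           enzyme_conc: float = 3.6e-7,
                           concentrations=DEFAULT_CONCENTRATIONS_M,
                           noise_sd: float = 0.05,
                           seed: int = 0) -> np.ndarray:
    """(S, v) table from the Michaelis–Menten law with fractional Gaussian noise.

    ``noise_sd`` is the relative standard deviation: each rate is multiplied
    by ``1 + N(0, noise_sd)``.  Defaults follow the Bs2 esterase assay:
    kcat = 18.54e-3 s⁻¹, K_M = 0.182 mM, eight substrate concentrations from
    10 µM to 3 mM.
    """
    if min(kcat, KM, enzyme_conc) <= 0:
        raise VoxsiteError("kcat, KM and enzyme_conc must be positive")
    if noise_sd < 0:
        raise VoxsiteError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    S = np.asarray(concentrations, dtype=float)
    v = kcat * enzyme_conc * S / (KM + S)
    if noise_sd > 0:
        v = v * (1.0 + rng.normal(0.0, noise_sd, size=len(S)))
    return np.column_stack([S, np.maximum(v, 0.0)])
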