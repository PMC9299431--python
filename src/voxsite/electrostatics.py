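"""Bare point-charge Coulomb electrostatics, bond-axis projections, and
grid-based counterion placement.

Potentials and fields are vacuum Coulomb sums — no dielectric, no cutoff,
no periodicity.  Two unit systems are supported for the outputs:

* ``"kJ/mol"``: potential in kJ·mol⁻¹·e⁻¹, field in kJ·mol⁻¹·e⁻¹·Å⁻¹.
* ``"au"``: potential in hartree·e⁻¹, field in hartree·e⁻¹·bohr⁻¹.

Positions are always given in Å and charges in units of *e*.  Counterions
are placed greedily on a regular grid at the most negative potential,
subject to minimum distances from the solute and from already-placed ions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .errors import VoxsiteError
from .structure import Structure

# CODATA 2018 constants
_E_CHARGE = 1.602176634e-19        # C
_EPS0 = 8.8541878128e-12           # F m^-1
_AVOGADRO = 6.02214076e23          # mol^-1
BOHR_ANGSTROM = 0.529177210903     # Å per bohr
HARTREE_KJ_MOL = 2625.4996394799   # kJ mol^-1 per hartree

#: Coulomb constant in kJ·mol⁻¹·Å·e⁻²: V(r) = K * q / r for r in Å.
COULOMB_KJ_MOL_ANG = (_E_CHARGE ** 2 / (4.0 * math.pi * _EPS0)
                      * _AVOGADRO / 1000.0 * 1e10)   # ~1389.35

UNIT_SYSTEMS = ("kJ/mol", "au")

_MIN_SEPARATION = 1e-9  # Å; probe coincident with a charge is an error


def potential_to_au(v_kj: float) -> float:
    return v_kj / HARTREE_KJ_MOL


def potential_from_au(v_au: float) -> float:
    return v_au * HARTREE_KJ_MOL


def field_to_au(e_kj_ang) -> np.ndarray | float:
    """kJ·mol⁻¹·e⁻¹·Å⁻¹ -> hartree·e⁻¹·bohr⁻¹."""
    return np.asarray(e_kj_ang) / HARTREE_KJ_MOL * BOHR_ANGSTROM


def field_from_au(e_au) -> np.ndarray | float:
    return np.asarray(e_au) * HARTREE_KJ_MOL / BOHR_ANGSTROM


@dataclass
class ChargeSet:
    """Point charges: positions (N, 3) in Å, charges (N,) in e."""

    positions: np.ndarray
    charges: np.ndarray

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.charges = np.atleast_1d(np.asarray(self.charges, dtype=float))
        if self.positions.shape != (len(self.charges), 3):
            raise VoxsiteError("positions must be (N, 3) matching N charges")
        if not (np.all(np.isfinite(self.positions)) and np.all(np.isfinite(self.charges))):
            raise VoxsiteError("positions and charges must be finite")

    @classmethod
    def from_structure(cls, s: Structure) -> "ChargeSet":
        return cls(positions=s.coords(), charges=s.charges())

    @property
    def net_charge(self) -> float:
        return float(self.charges.sum())

    def __len__(self) -> int:
        return len(self.charges)

    def __add__(self, other: "ChargeSet") -> "ChargeSet":
        return ChargeSet(positions=np.vstack([self.positions, other.positions]),
                         charges=np.concatenate([self.charges, other.charges]))


@dataclass
class FieldVector:
    """An electric-field vector with an explicit unit tag."""

    E: np.ndarray
    units: str = "kJ/mol"

    def __post_init__(self):
        self.E = np.asarray(self.E, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.E)):
            raise VoxsiteError("field components must be finite")
        if self.units not in UNIT_SYSTEMS:
            raise VoxsiteError(f"unknown unit system {self.units!r}")


@dataclass
class BondAxis:
    """Directed axis between two atoms, e.g. the scissile C1 -> N4 amide bond."""

    from_atom: np.ndarray
    to_atom: np.ndarray
    u: np.ndarray = field(init=False)

    def __post_init__(self):
        self.from_atom = np.asarray(self.from_atom, dtype=float).reshape(3)
        self.to_atom = np.asarray(self.to_atom, dtype=float).reshape(3)
        d = self.to_atom - self.from_atom
        norm = np.linalg.norm(d)
        if norm < _MIN_SEPARATION:
            raise VoxsiteError("bond axis endpoints coincide")
        self.u = d / norm


def _check_units(units: str):
    if units not in UNIT_SYSTEMS:
        raise VoxsiteError(f"unknown unit system {units!r}; expected one of {UNIT_SYSTEMS}")


def _displacements(q: ChargeSet, r) -> tuple[np.ndarray, np.ndarray]:
    r = np.asarray(r, dtype=float).reshape(3)
    d = r - q.positions
    dist = np.linalg.norm(d, axis=1)
    if np.any(dist < _MIN_SEPARATION):
        raise VoxsiteError("evaluation point coincides with a charge")
    return d, dist


def potential_at(q: ChargeSet, r, units: str = "kJ/mol") -> float:
    """Coulomb potential V(r) = K Σ q_i / |r - r_i|."""
    _check_units(units)
    _, dist = _displacements(q, r)
    v = COULOMB_KJ_MOL_ANG * float(np.sum(q.charges / dist))
    return potential_to_au(v) if units == "au" else v


def field_at(q: ChargeSet, r, units: str = "kJ/mol") -> FieldVector:
    """Electric field E(r) = K Σ q_i (r - r_i)/|r - r_i|³."""
    _check_units(units)
    d, dist = _displacements(q, r)
    e = COULOMB_KJ_MOL_ANG * (q.charges / dist ** 3) @ d
    if units == "au":
        e = field_to_au(e)
    return FieldVector(E=e, units=units)


@dataclass
class BondProjection:
    """Field and force components along a bond axis.

    ``net_attraction`` A = F_C·u - F_N·u; with u pointing from C to N,
    A > 0 means the projected force pair compresses the bond (our sign
    convention — documented, not a literature standard).
    """

    e_from: float
    e_to: float
    f_from: float
    f_to: float
    net_attraction: float
    units: str


def bond_projection(E_at_from: FieldVector, E_at_to: FieldVector,
                    axis: BondAxis, q_from: float, q_to: float) -> BondProjection:
    """Project fields at the two bond atoms onto the axis; derive forces.

    Forces are F = qE projected on u; units follow the input fields, which
    must agree.
    """
    if E_at_from.units != E_at_to.units:
        raise VoxsiteError(
            f"unit mismatch: {E_at_from.units!r} vs {E_at_to.units!r}")
    e_f = float(E_at_from.E @ axis.u)
    e_t = float(E_at_to.E @ axis.u)
    f_f = q_from * e_f
    f_t = q_to * e_t
    return BondProjection(e_from=e_f, e_to=e_t, f_from=f_f, f_to=f_t,
                          net_attraction=f_f - f_t, units=E_at_from.units)


# ---------------------------------------------------------------------------
# Counterion placement

@dataclass
class IonPlacementConfig:
    """Grid and exclusion-distance parameters for greedy ion placement.

    Defaults follow common solvation-setup practice: ions at least 10.5 Å
    from any solute atom and 5 Å from each other, searched on a regular
    0.5 Å grid.  ``n_ions`` may be an integer or ``"neutralize"``.
    """

    grid_spacing: float = 0.5
    min_solute_dist: float = 10.5
    min_ion_dist: float = 5.0
    ion_charge: float = 1.0
    n_ions: int | str = "neutralize"
    include_placed_ions: bool = True  # placed ions repel subsequent ones
    padding_extra: float = 5.0        # box padding beyond min_solute_dist

    def __post_init__(self):
        if min(self.grid_spacing, self.min_solute_dist, self.min_ion_dist) <= 0:
            raise VoxsiteError("distances and grid spacing must be positive")
        if self.grid_spacing >= self.min_ion_dist:
            raise VoxsiteError("grid_spacing must be smaller than min_ion_dist")
        if isinstance(self.n_ions, str) and self.n_ions != "neutralize":
            raise VoxsiteError("n_ions must be an integer or 'neutralize'")


@dataclass
class IonPlacementResult:
    positions: np.ndarray        # (n, 3) in placement order
    potentials: list[float]      # potential at each site when chosen (kJ/mol/e)
    final_net_charge: float


def _candidate_grid(solute: ChargeSet, cfg: IonPlacementConfig) -> np.ndarray:
    lo = solute.positions.min(axis=0) - (cfg.min_solute_dist + cfg.padding_extra)
    hi = solute.positions.max(axis=0) + (cfg.min_solute_dist + cfg.padding_extra)
    axes = [np.arange(lo[k], hi[k] + cfg.grid_spacing / 2, cfg.grid_spacing)
            for k in range(3)]
    g = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    # keep points far enough from every solute atom
    keep = np.ones(len(g), dtype=bool)
    for start in range(0, len(g), 65536):
        d = cdist(g[start:start + 65536], solute.positions)
        keep[start:start + 65536] = d.min(axis=1) >= cfg.min_solute_dist
    return g[keep]


def _potential_many(q: ChargeSet, points: np.ndarray) -> np.ndarray:
    v = np.zeros(len(points))
    for start in range(0, len(points), 65536):
        d = cdist(points[start:start + 65536], q.positions)
        v[start:start + 65536] = COULOMB_KJ_MOL_ANG * (1.0 / d) @ q.charges
    return v


def place_counterions(solute: ChargeSet | Structure,
                      cfg: IonPlacementConfig | None = None) -> IonPlacementResult:
    """Greedily place counterions at the most negative grid potential.

    At each step the potential of the solute (plus, by default, the already
    placed ions) is evaluated on the admissible grid — points at least
    ``min_solute_dist`` from every solute atom and ``min_ion_dist`` from every
    placed ion — and the next ion goes to the minimum (first occurrence on
    ties, which makes placement deterministic).  Raises if the admissible set
    empties before the requested count is reached.
    """
    cfg = cfg or IonPlacementConfig()
    if isinstance(solute, Structure):
        solute = ChargeSet.from_structure(solute)
    if cfg.n_ions == "neutralize":
        n_ions = int(round(-solute.net_charge / cfg.ion_charge))
        if n_ions < 0:
            raise VoxsiteError(
                "ion charge has the same sign as the solute net charge; "
                "cannot neutralize")
    else:
        n_ions = int(cfg.n_ions)

    grid = _candidate_grid(solute, cfg)
    v_solute = _potential_many(solute, grid)
    admissible = np.ones(len(grid), dtype=bool)
    placed: list[np.ndarray] = []
    potentials: list[float] = []
    v_ions = np.zeros(len(grid))
    for i in range(n_ions):
        if not admissible.any():
            raise VoxsiteError(
                f"admissible grid exhausted after placing {i} of {n_ions} ions")
        v = v_solute + (v_ions if cfg.include_placed_ions else 0.0)
        masked = np.where(admissible, v, np.inf)
        j = int(np.argmin(masked))
        placed.append(grid[j])
        potentials.append(float(v[j]))
        d_new = np.linalg.norm(grid - grid[j], axis=1)
        admissible &= d_new >= cfg.min_ion_dist
        if cfg.include_placed_ions:
            with np.errstate(divide="ignore"):
                contrib = COULOMB_KJ_MOL_ANG * cfg.ion_charge / d_new
            contrib[~np.isfinite(contrib)] = 0.0
            v_ions += contrib

    final_net = solute.net_charge + n_ions * cfg.ion_charge
    return IonPlacementResult(
        positions=np.array(placed).reshape(-1, 3),
        potentials=potentials,
        final_net_charge=float(final_net))


def ions_to_pdb(result: IonPlacementResult, element: str = "NA") -> str:
    """Serialize placed ions as PDB HETATM records."""
    lines = []
    for i, p in enumerate(result.positions, start=1):
        lines.append(
            f"HETATM{i:>5d} {element:<4s}{element:<3s}  {i:>4d}    "
            f"{p[0]:8.3f}{p[1]:8.3f}{p[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {element:>2s}")
    lines.append("END")
    return "\n".join(lines) + "\n"
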