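"""Side-chain atom encoding and voxel-grid featurization of active sites.

Each side-chain heavy atom is encoded as a 13-feature vector in [0, 1]:

====  =======================================
 ch    meaning
====  =======================================
 1-4   element one-hot (C, N, O, S)
 5     aromatic-ring atom
 6     aliphatic hydrophobic atom
 7     hydrogen-bond donor heavy atom
 8     hydrogen-bond acceptor heavy atom
 9     positively ionizable group member
 10    negatively ionizable group member
 11    amide side-chain atom
 12    hydroxyl / thiol atom
 13    residue-type ordinal / 20
====  =======================================

Channel 13 makes the per-residue multiset of vectors injective over the 20
standard residues, so chemically analogous residues (Asp vs Glu) are encoded
differently.  Atoms are binned into 1 Å voxels of a 20 Å cube centred on the
catalytic-residue centroid, optionally after a rotation about that centre,
and each channel is then smeared with a truncated, mass-preserving Gaussian.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation as _ScipyRotation

from .errors import VoxsiteError
from .structure import Atom, SiteSpec, Structure, site_center

logger = logging.getLogger(__name__)

N_FEATURES = 13

CHANNEL_NAMES = (
    "element_C", "element_N", "element_O", "element_S",
    "aromatic", "aliphatic", "hbond_donor", "hbond_acceptor",
    "pos_ionizable", "neg_ionizable", "amide", "hydroxyl_thiol",
    "residue_ordinal",
)

#: The 20 standard residues in alphabetical three-letter order; the index + 1,
#: divided by 20, is channel 13.
STANDARD_RESIDUES = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

_ARO = "aromatic"
_ALI = "aliphatic"
_DON = "donor"
_ACC = "acceptor"
_POS = "pos"
_NEG = "neg"
_AMD = "amide"
_OH = "hydroxyl"

#: Side-chain heavy atoms per residue: name -> (element, property flags).
SIDECHAIN_ATOMS: dict[str, dict[str, tuple[str, frozenset]]] = {
    "ALA": {"CB": ("C", frozenset({_ALI}))},
    "ARG": {"CB": ("C", frozenset({_ALI})), "CG": ("C", frozenset({_ALI})),
            "CD": ("C", frozenset({_ALI})), "NE": ("N", frozenset({_DON, _POS})),
            "CZ": ("C", frozenset({_POS})), "NH1": ("N", frozenset({_DON, _POS})),
            "NH2": ("N", frozenset({_DON, _POS}))},
    "ASN": {"CB": ("C", frozenset({_ALI})), "CG": ("C", frozenset({_AMD})),
            "OD1": ("O", frozenset({_ACC, _AMD})), "ND2": ("N", frozenset({_DON, _AMD}))},
    "ASP": {"CB": ("C", frozenset({_ALI})), "CG": ("C", frozenset({_NEG})),
            "OD1": ("O", frozenset({_ACC, _NEG})), "OD2": ("O", frozenset({_ACC, _NEG}))},
    "CYS": {"CB": ("C", frozenset({_ALI})), "SG": ("S", frozenset({_DON, _OH}))},
    "GLN": {"CB": ("C", frozenset({_ALI})), "CG": ("C", frozenset({_ALI})),
            "CD": ("C", frozenset({_AMD})), "OE1": ("O", frozenset({_ACC, _AMD})),
            "NE2": ("N", frozenset({_DON, _AMD}))},
    "GLU": {"CB": ("C", frozenset({_ALI})), "CG": ("C", frozenset({_ALI})),
            "CD": ("C", frozenset({_NEG})), "OE1": ("O", frozenset({_ACC, _NEG})),
            "OE2": ("O", frozenset({_ACC, _NEG}))},
    "GLY": {},
    "HIS": {"CB": ("C", frozenset({_ALI})), "CG": ("C", frozenset({_ARO})),
            "ND1": ("N", frozenset({_ARO, _DON, _ACC, _POS})),
            "CD2": ("C", frozenset({_ARO})), "CE1": ("C", frozenset({_ARO})),
            "NE2": ("N", frozenset({_ARO, _DON, _ACC, _POS}))},
    "ILE": {"CB": ("C", frozenset({_ALI})), "CG1": ("C", frozenset({_ALI})),
            "CG2": ("C", frozenset({_ALI})), "CD1": ("C", frozenset({_ALI}))},
    "LEU": {"CB": ("C", frozenset({_ALI})), "CG": ("C", frozenset({_ALI})),
            "CD1": ("C", frozenset({_ALI})), "CD2": ("C", frozenset({_ALI}))},
    "LYS": {"CB": ("C", frozenset({_ALI})), "CG": ("C", frozenset({_ALI})),
            "CD": ("C", frozenset({_ALI})), "CE": ("C", frozenset({_ALI})),
            "NZ": ("N", frozenset({_DON, _POS}))},
    "MET": {"CB": ("C", frozenset({_ALI})), "CG": ("C", frozenset({_ALI})),
            "SD": ("S", frozenset()), "CE": ("C", frozenset({_ALI}))},
    "PHE": {"CB": ("C", frozenset({_ALI})), "CG": ("C", frozenset({_ARO})),
            "CD1": ("C", frozenset({_ARO})), "CD2": ("C", frozenset({_ARO})),
            "CE1": ("C", frozenset({_ARO})), "CE2": ("C", frozenset({_ARO})),
            "CZ": ("C", frozenset({_ARO}))},
    "PRO": {"CB": ("C", frozenset({_ALI})), "CG": ("C", frozenset({_ALI})),
            "CD": ("C", frozenset({_ALI}))},
    "SER": {"CB": ("C", frozenset({_ALI})), "OG": ("O", frozenset({_DON, _ACC, _OH}))},
    "THR": {"CB": ("C", frozenset({_ALI})), "OG1": ("O", frozenset({_DON, _ACC, _OH})),
            "CG2": ("C", frozenset({_ALI}))},
    "TRP": {"CB": ("C", frozenset({_ALI})), "CG": ("C", frozenset({_ARO})),
            "CD1": ("C", frozenset({_ARO})), "CD2": ("C", frozenset({_ARO})),
            "NE1": ("N", frozenset({_ARO, _DON})), "CE2": ("C", frozenset({_ARO})),
            "CE3": ("C", frozenset({_ARO})), "CZ2": ("C", frozenset({_ARO})),
            "CZ3": ("C", frozenset({_ARO})), "CH2": ("C", frozenset({_ARO}))},
    "TYR": {"CB": ("C", frozenset({_ALI})), "CG": ("C", frozenset({_ARO})),
            "CD1": ("C", frozenset({_ARO})), "CD2": ("C", frozenset({_ARO})),
            "CE1": ("C", frozenset({_ARO})), "CE2": ("C", frozenset({_ARO})),
            "CZ": ("C", frozenset({_ARO})),
            "OH": ("O", frozenset({_DON, _ACC, _OH}))},
    "VAL": {"CB": ("C", frozenset({_ALI})), "CG1": ("C", frozenset({_ALI})),
            "CG2": ("C", frozenset({_ALI}))},
}

_ELEMENT_CHANNEL = {"C": 0, "N": 1, "O": 2, "S": 3}
_FLAG_CHANNEL = {_ARO: 4, _ALI: 5, _DON: 6, _ACC: 7, _POS: 8, _NEG: 9,
                 _AMD: 10, _OH: 11}


def encode_atom(a: Atom) -> np.ndarray:
    """13-feature vector for a side-chain heavy atom of a standard residue.

    Raises :class:`VoxsiteError` for non-standard residues, backbone atoms,
    hydrogens, or unknown side-chain atom names.
    """
    if a.res_name not in SIDECHAIN_ATOMS:
        raise VoxsiteError(f"non-standard residue {a.res_name!r}")
    if a.is_backbone or a.is_hydrogen:
        raise VoxsiteError(f"atom {a.name!r} of {a.res_name} is not a side-chain heavy atom")
    table = SIDECHAIN_ATOMS[a.res_name]
    if a.name not in table:
        raise VoxsiteError(f"unknown side-chain atom {a.name!r} for {a.res_name}")
    element, flags = table[a.name]
    v = np.zeros(N_FEATURES)
    v[_ELEMENT_CHANNEL[element]] = 1.0
    for f in flags:
        v[_FLAG_CHANNEL[f]] = 1.0
    v[12] = (STANDARD_RESIDUES.index(a.res_name) + 1) / 20.0
    return v


def residue_feature_multiset(res_name: str) -> frozenset:
    """Multiset (as counted tuples) of side-chain feature vectors for a residue."""
    vecs = []
    for name, (element, flags) in SIDECHAIN_ATOMS[res_name].items():
        a = Atom(serial=1, name=name, element=element, res_name=res_name,
                 res_seq=1, chain="A", xyz=(0.0, 0.0, 0.0))
        vecs.append(tuple(encode_atom(a)))
    return frozenset((v, vecs.count(v)) for v in vecs)


# ---------------------------------------------------------------------------
# Rotations

@dataclass(frozen=True)
class Rotation:
    """A proper rotation (3x3 orthonormal matrix, det +1)."""

    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.shape != (3, 3):
            raise VoxsiteError("rotation matrix must be 3x3")
        if not np.allclose(m.T @ m, np.eye(3), atol=1e-10):
            raise VoxsiteError("rotation matrix is not orthonormal")
        if abs(np.linalg.det(m) - 1.0) > 1e-8:
            raise VoxsiteError("rotation matrix must have determinant +1")

    @classmethod
    def identity(cls) -> "Rotation":
        return cls(np.eye(3))

    def apply(self, xyz: np.ndarray, about: np.ndarray) -> np.ndarray:
        """Rotate points about a pivot: ``R (x - c) + c``."""
        about = np.asarray(about, dtype=float)
        return (np.asarray(xyz, dtype=float) - about) @ self.matrix.T + about


def sample_rotation(rng: np.random.Generator | int | None = None) -> Rotation:
    """Draw a rotation uniformly from SO(3) (quaternion method).

    Reproducible given a seeded :class:`numpy.random.Generator`.
    """
    rng = np.random.default_rng(rng)
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    return Rotation(_ScipyRotation.from_quat(q).as_matrix())


# ---------------------------------------------------------------------------
# Grids

@dataclass
class SmearingConfig:
    """Truncated-Gaussian smearing applied per channel after deposition.

    ``sigma`` (Å) is the kernel width, ``truncation_radius`` (Å) the cutoff;
    the discrete kernel is normalized to unit mass, so channel totals are
    preserved away from the box faces.  ``sigma = 0`` disables smearing.
    """

    sigma: float = 1.0
    truncation_radius: float | None = None

    def __post_init__(self):
        if self.sigma < 0:
            raise VoxsiteError("sigma must be >= 0")
        if self.truncation_radius is None:
            self.truncation_radius = 3.0 * self.sigma
        if self.sigma > 0 and self.truncation_radius < self.sigma:
            raise VoxsiteError("truncation_radius must be >= sigma")


@dataclass
class FeatureGrid:
    """A (n, n, n, 13) cube of non-negative channel densities."""

    values: np.ndarray
    origin: np.ndarray
    voxel_edge: float

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.ndim != 4 or v.shape[3] != N_FEATURES or len(set(v.shape[:3])) != 1:
            raise VoxsiteError(f"grid must have shape (n, n, n, {N_FEATURES}); got {v.shape}")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def channel_totals(self) -> np.ndarray:
        return self.values.sum(axis=(0, 1, 2))


def featurize_site(s: Structure, spec: SiteSpec,
                   smear: SmearingConfig | None = None,
                   rotation: Rotation | None = None,
                   dtype=np.float32) -> FeatureGrid:
    """Voxelize the active-site box of a structure into a feature grid.

    Atoms are rotated about the site centre, backbone atoms / hydrogens /
    non-standard residues are discarded, atoms outside the box are dropped,
    and each survivor deposits its feature vector into the voxel containing
    it (half-open intervals).  If two atoms fall into one voxel the one
    nearest the voxel centre wins and a warning is logged.  Finally every
    channel is convolved with the truncated Gaussian.
    """
    smear = smear if smear is not None else SmearingConfig()
    rotation = rotation if rotation is not None else Rotation.identity()
    center = site_center(s, spec)
    n = spec.n_voxels
    origin = center - spec.box_edge / 2.0

    keep_atoms = []
    for a in s.atoms:
        if a.is_backbone or a.is_hydrogen:
            continue
        if a.res_name not in SIDECHAIN_ATOMS:
            logger.debug("skipping non-standard residue atom %s/%s", a.res_name, a.name)
            continue
        if a.name not in SIDECHAIN_ATOMS[a.res_name]:
            continue
        keep_atoms.append(a)

    grid = np.zeros((n, n, n, N_FEATURES), dtype=dtype)
    if keep_atoms:
        xyz = rotation.apply(np.array([a.xyz for a in keep_atoms]), about=center)
        idx = np.floor((xyz - origin) / spec.voxel_edge).astype(int)
        inside = np.all((idx >= 0) & (idx < n), axis=1)
        occupant: dict[tuple, tuple[float, int]] = {}
        n_collisions = 0
        for k in np.flatnonzero(inside):
            vox = tuple(idx[k])
            vox_center = origin + (np.asarray(vox) + 0.5) * spec.voxel_edge
            d = float(np.linalg.norm(xyz[k] - vox_center))
            if vox in occupant:
                n_collisions += 1
                if d >= occupant[vox][0]:
                    continue
            occupant[vox] = (d, k)
        if n_collisions:
            logger.warning("%s: %d voxel collisions; kept the atom nearest "
                           "each voxel centre", s.id, n_collisions)
        for vox, (_, k) in occupant.items():
            grid[vox] = encode_atom(keep_atoms[k])

    if smear.sigma > 0:
        sig = smear.sigma / spec.voxel_edge
        truncate = smear.truncation_radius / smear.sigma
        grid = ndimage.gaussian_filter(
            grid.astype(np.float64), sigma=(sig, sig, sig, 0.0),
            mode="constant", truncate=truncate).astype(dtype)

    return FeatureGrid(values=grid, origin=origin, voxel_edge=spec.voxel_edge)


# ---------------------------------------------------------------------------
# Datasets

@dataclass
class GridDataset:
    """Labelled feature grids with a structure-level train/test/validation split.

    Augmented (rotated) copies of a structure always inherit its split, so no
    structure leaks across partitions.
    """

    grids: np.ndarray                       # (N, n, n, n, 13) float32
    labels: np.ndarray                      # (N,) int class indices
    source_ids: list[str]
    class_names: list[str]
    split_of_structure: dict[str, str]      # structure id -> split name
    split_ratios: tuple[float, float, float] = (0.7, 0.15, 0.15)

    def split_of(self, i: int) -> str:
        return self.split_of_structure[self.source_ids[i]]

    def partition_indices(self, split: str) -> np.ndarray:
        sel = np.array([i for i in range(len(self.labels))
                        if self.split_of(i) == split], dtype=np.int64)
        if len(sel) == 0:
            raise VoxsiteError(f"partition {split!r} is empty")
        return sel

    def partition(self, split: str) -> tuple[np.ndarray, np.ndarray]:
        sel = self.partition_indices(split)
        return self.grids[sel], self.labels[sel]

    def __len__(self) -> int:
        return int(len(self.labels))


def assign_splits(structure_ids: Sequence[str],
                  ratios: tuple[float, float, float] = (0.7, 0.15, 0.15),
                  seed: int | None = 0) -> dict[str, str]:
    """Largest-remainder assignment of structures to train/test/validation.

    Sizes are the floors of ``ratio * n`` with leftovers going to the largest
    fractional remainders (ties broken in train, test, validation order);
    membership is a seeded shuffle.
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise VoxsiteError("split ratios must sum to 1")
    names = ("train", "test", "validation")
    n = len(structure_ids)
    exact = [r * n for r in ratios]
    counts = [int(np.floor(e)) for e in exact]
    rem = [e - c for e, c in zip(exact, counts)]
    for _ in range(n - sum(counts)):
        j = int(np.argmax(rem))
        counts[j] += 1
        rem[j] = -1.0
    order = list(structure_ids)
    np.random.default_rng(seed).shuffle(order)
    out: dict[str, str] = {}
    pos = 0
    for name, c in zip(names, counts):
        for sid in order[pos:pos + c]:
            out[sid] = name
        pos += c
    return out


def build_dataset(structures: Sequence[Structure], spec: SiteSpec,
                  smear: SmearingConfig | None = None,
                  augment_per_structure: int = 1,
                  ratios: tuple[float, float, float] = (0.7, 0.15, 0.15),
                  seed: int = 0) -> GridDataset:
    """Featurize labelled structures into a split, rotation-augmented dataset.

    Splits are assigned at the structure level *before* augmentation; each
    structure then contributes one identity-rotation grid plus
    ``augment_per_structure - 1`` uniformly rotated grids, all inheriting the
    structure's split.
    """
    if augment_per_structure < 1:
        raise VoxsiteError("augment_per_structure must be >= 1")
    labels = [s.label for s in structures]
    if any(l is None for l in labels):
        raise VoxsiteError("every structure must carry a class label")
    class_names = sorted(set(labels))
    for c in class_names:
        if labels.count(c) == 0:  # pragma: no cover - sorted(set) excludes this
            raise VoxsiteError(f"class {c!r} has no structures")
    if len(class_names) < 2:
        raise VoxsiteError("need at least two classes")

    rng = np.random.default_rng(seed)
    split_of_structure = assign_splits([s.id for s in structures], ratios,
                                       seed=int(rng.integers(2**31)))
    n = spec.n_voxels
    total = len(structures) * augment_per_structure
    grids = np.empty((total, n, n, n, N_FEATURES), dtype=np.float32)
    y = np.empty(total, dtype=np.int64)
    source_ids: list[str] = []
    k = 0
    for s in structures:
        ci = class_names.index(s.label)
        for j in range(augment_per_structure):
            rot = Rotation.identity() if j == 0 else sample_rotation(rng)
            grids[k] = featurize_site(s, spec, smear, rot).values
            y[k] = ci
            source_ids.append(s.id)
            k += 1
    return GridDataset(grids=grids, labels=y, source_ids=source_ids,
                       class_names=class_names,
                       split_of_structure=split_of_structure,
                       split_ratios=ratios)
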