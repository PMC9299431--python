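"""In-silico alanine scanning against a trained site classifier.

Each residue with a side-chain heavy atom inside the sampling box is mutated
to alanine by truncating its side chain to CB (backbone atoms are excluded
from featurization, so truncation is feature-equivalent to a full rebuild).
A mutant is scored by repeated classification under independent uniform
rotations: with p_c the fraction of argmax outcomes landing on class c,

    S = p_true - max_{c != true} p_c,   S in [-1, 1].

S = 1 is a perfectly classified protein, S = -1 a perfectly misclassified
one.  Iterating the scan and accumulating mutations whose score drop (wild
type minus mutant, on the current mutated background) exceeds a threshold
identifies the residues the network relies on for the family assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import VoxsiteError
from .features import (FeatureGrid, Rotation, SmearingConfig, featurize_site,
                       sample_rotation, N_FEATURES)
from .structure import Atom, SiteSpec, Structure, site_center

SCAN_SKIP_RESIDUES = ("GLY", "ALA")


@dataclass
class ScanConfig:
    """Monte-Carlo scoring and accumulation parameters.

    ``n_predictions`` rotated classifications per score (default 1000);
    ``relevance_threshold`` is the score drop, relative to the wild type on
    the current background, above which a mutation is accumulated.
    """

    n_predictions: int = 1000
    relevance_threshold: float = 0.5
    max_iterations: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.n_predictions < 1:
            raise VoxsiteError("n_predictions must be >= 1")
        if not (0.0 < self.relevance_threshold <= 2.0):
            raise VoxsiteError("relevance_threshold must be in (0, 2]")
        if self.max_iterations < 1:
            raise VoxsiteError("max_iterations must be >= 1")


@dataclass(frozen=True)
class ScanScore:
    chain: str
    res_seq: int
    res_name: str
    score: float
    iteration: int

    def __post_init__(self):
        if not -1.0 <= self.score <= 1.0:
            raise VoxsiteError("scan score must lie in [-1, 1]")


@dataclass
class MutationResult:
    structure: Structure
    skipped: bool   # True when the target was Gly/Ala (nothing to truncate)


def mutate_to_ala(s: Structure, residue: tuple[str, int]) -> MutationResult:
    """Truncate one residue's side chain to CB and relabel it as alanine.

    Gly/Ala targets return the structure unchanged with ``skipped=True``;
    a missing residue raises.
    """
    chain, res_seq = residue
    res_atoms = s.atoms_of(chain, res_seq)
    if not res_atoms:
        raise VoxsiteError(f"residue (chain {chain!r}, {res_seq}) not found in {s.id!r}")
    res_name = res_atoms[0].res_name
    if res_name in SCAN_SKIP_RESIDUES:
        return MutationResult(structure=s, skipped=True)
    atoms: list[Atom] = []
    for a in s.atoms:
        if a.chain == chain and a.res_seq == res_seq:
            if a.is_backbone or a.name == "CB":
                atoms.append(replace(a, res_name="ALA"))
            # all other side-chain atoms (and their hydrogens) are dropped
        else:
            atoms.append(a)
    return MutationResult(
        structure=Structure(id=f"{s.id}:{chain}{res_seq}{res_name}->ALA",
                            atoms=atoms, label=s.label),
        skipped=False)


def _featurize_rotations(s: Structure, spec: SiteSpec, smear: SmearingConfig | None,
                         n: int, rng: np.random.Generator) -> np.ndarray:
    nv = spec.n_voxels
    grids = np.empty((n, nv, nv, nv, N_FEATURES), dtype=np.float32)
    for i in range(n):
        grids[i] = featurize_site(s, spec, smear, sample_rotation(rng)).values
    return grids


def classification_score(model, s: Structure, spec: SiteSpec,
                         smear: SmearingConfig | None, true_class: str,
                         cfg: ScanConfig,
                         rng: np.random.Generator | None = None) -> float:
    """Rotation-averaged classification score S = p_true - best wrong ratio."""
    if true_class not in model.class_names:
        raise VoxsiteError(f"true class {true_class!r} not among model classes")
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    grids = _featurize_rotations(s, spec, smear, cfg.n_predictions, rng)
    probs = model.predict_proba(grids)
    picks = probs.argmax(axis=1)
    counts = np.bincount(picks, minlength=len(model.class_names))
    ratios = counts / cfg.n_predictions
    t = model.class_names.index(true_class)
    wrong = np.delete(ratios, t)
    return float(ratios[t] - wrong.max())


def scannable_residues(s: Structure, spec: SiteSpec) -> list[tuple[str, int, str]]:
    """Residues with >= 1 side-chain heavy atom inside the sampling box."""
    center = site_center(s, spec)
    lo = center - spec.box_edge / 2.0
    hi = center + spec.box_edge / 2.0
    out, seen = [], set()
    for a in s.atoms:
        if a.is_backbone or a.is_hydrogen:
            continue
        k = (a.chain, a.res_seq)
        if k in seen:
            continue
        if np.all(np.asarray(a.xyz) >= lo) and np.all(np.asarray(a.xyz) < hi):
            seen.add(k)
            out.append((a.chain, a.res_seq, a.res_name))
    return out


def scan_iteration(model, s: Structure, spec: SiteSpec,
                   smear: SmearingConfig | None, true_class: str,
                   cfg: ScanConfig, frozen_mutations: set[tuple[str, int]],
                   iteration: int = 1,
                   rng: np.random.Generator | None = None) -> list[ScanScore]:
    """Score the single-point Ala mutant of every scannable, non-frozen residue.

    ``s`` must already carry the frozen mutations; each candidate is mutated
    on top of that background.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    scores: list[ScanScore] = []
    for chain, res_seq, res_name in scannable_residues(s, spec):
        if (chain, res_seq) in frozen_mutations or res_name in SCAN_SKIP_RESIDUES:
            continue
        mut = mutate_to_ala(s, (chain, res_seq))
        if mut.skipped:
            continue
        sc = classification_score(model, mut.structure, spec, smear, true_class,
                                  cfg, rng=rng)
        scores.append(ScanScore(chain=chain, res_seq=res_seq, res_name=res_name,
                                score=sc, iteration=iteration))
    return scores


@dataclass
class ScanResult:
    scores: list[ScanScore]          # all iterations, scan order
    wild_type_scores: list[float]    # background score at the start of each iteration
    frozen: set[tuple[str, int]]     # accumulated relevant mutations


def iterative_scan(model, s: Structure, spec: SiteSpec,
                   smear: SmearingConfig | None, true_class: str,
                   cfg: ScanConfig) -> ScanResult:
    """Consecutive scan iterations, accumulating relevant mutations.

    After each iteration every residue whose score drop (background wild-type
    score minus mutant score) is >= the relevance threshold joins the frozen
    set and is applied to the background; the loop stops when no residue
    passes or ``max_iterations`` is reached.
    """
    rng = np.random.default_rng(cfg.seed)
    frozen: set[tuple[str, int]] = set()
    background = s
    all_scores: list[ScanScore] = []
    wt_scores: list[float] = []
    for it in range(1, cfg.max_iterations + 1):
        wt = classification_score(model, background, spec, smear, true_class,
                                  cfg, rng=rng)
        wt_scores.append(wt)
        scores = scan_iteration(model, background, spec, smear, true_class,
                                cfg, frozen, iteration=it, rng=rng)
        all_scores.extend(scores)
        newly = [(sc.chain, sc.res_seq) for sc in scores
                 if wt - sc.score >= cfg.relevance_threshold]
        if not newly:
            break
        for key in newly:
            frozen.add(key)
            background = mutate_to_ala(background, key).structure
    return ScanResult(scores=all_scores, wild_type_scores=wt_scores, frozen=frozen)
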