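import logging

import numpy as np
import pytest

import voxsite as vx

logging.disable(logging.WARNING)


def make_atom(serial=1, name="CB", element="C", res_name="ALA", res_seq=1,
              chain="A", xyz=(0.0, 0.0, 0.0), charge=None):
    return vx.Atom(serial=serial, name=name, element=element, res_name=res_name,
                   res_seq=res_seq, chain=chain, xyz=xyz, charge=charge)


def make_residue(res_name, res_seq, offset, start_serial=1, chain="A", spread=0.9):
    """A residue with backbone placeholders and its full side chain, compactly
    laid out around ``offset``."""
    from voxsite.features import SIDECHAIN_ATOMS
    offset = np.asarray(offset, dtype=float)
    atoms = [make_atom(start_serial + i, n, e, res_name, res_seq, chain,
                       tuple(offset + d))
             for i, (n, e, d) in enumerate([
                 ("N", "N", (-1.2, 0.0, 0.9)), ("CA", "C", (0.0, 0.0, 0.9)),
                 ("C", "C", (1.2, 0.0, 0.9)), ("O", "O", (1.2, 1.1, 0.9))])]
    serial = start_serial + 4
    for k, (name, (element, _)) in enumerate(SIDECHAIN_ATOMS[res_name].items()):
        d = np.array([spread * (k % 3 - 1), spread * (k // 3), -0.7 * (k % 2)])
        atoms.append(make_atom(serial, name, element, res_name, res_seq, chain,
                               tuple(offset + d)))
        serial += 1
    return atoms


@pytest.fixture
def compact_structure():
    """Three residues whose side chains all lie within ~5 Å of the site
    centre — safely inside radius box/2 - truncation for the default box."""
    atoms = (make_residue("SER", 1, (0.0, 0.0, 0.0), 1)
             + make_residue("PHE", 2, (3.0, 2.0, 1.0), 20)
             + make_residue("ASP", 3, (-3.0, 1.0, 2.0), 40))
    return vx.Structure(id="compact", atoms=atoms, label="toy")


@pytest.fixture
def toy_spec():
    return vx.SiteSpec(residues=[("A", 1)], box_edge=20.0, voxel_edge=1.0)


class StubModel:
    """Classifier stand-in returning scripted argmax outcomes in order."""

    def __init__(self, class_names, outcomes):
        self.class_names = list(class_names)
        self.outcomes = list(outcomes)
        self._cursor = 0

    def predict_proba(self, grids):
        n = len(grids)
        out = np.full((n, len(self.class_names)), 0.0)
        for i in range(n):
            out[i, self.outcomes[self._cursor % len(self.outcomes)]] = 1.0
            self._cursor += 1
        return out


@pytest.fixture
def stub_model_factory():
    return StubModel


@pytest.fixture(scope="session")
def small_benchmark():
    """A small trained model + its dataset, shared across classifier and
    alanine-scan tests (3 classes x 10 structures, x8 rotations)."""
    structures = vx.generate_family_dataset(
        vx.default_templates(jitter_sigma=0.25, n_structures=10), seed=11)
    spec = vx.triad_site_spec()
    smear = vx.SmearingConfig()
    ds = vx.build_dataset(structures, spec, smear, augment_per_structure=8, seed=11)
    cfg = vx.ModelConfig(architecture="tiny3d", n_classes=3, epochs=60,
                         patience=30, seed=0)
    model, log = vx.train(ds, cfg)
    return {"structures": structures, "spec": spec, "smear": smear,
            "ds": ds, "model": model, "log": log}
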