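"""Shared fixtures: idealized structures and the synthetic survey corpus."""

import numpy as np
import pytest

from pipistack.structure_io import AtomRecord, build_model
from pipistack.synthetic import make_annotation_corpus


def _atom(name, xyz, ridx, resname, chain="A", element=None):
    return AtomRecord(element=element or name[0], name=name,
                      coords=np.asarray(xyz, dtype=float), residue_index=ridx,
                      author_seq=str(ridx + 1), residue_name=resname,
                      chain_id=chain)


def _ring(center, ridx, resname="PHE", chain="A"):
    """Idealized aromatic six-ring (CG,CD1,CE1,CZ,CE2,CD2) in the z-plane."""
    names = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
    out = []
    for k, nm in enumerate(names):
        ang = k * np.pi / 3
        xyz = np.asarray(center) + [1.39 * np.cos(ang), 1.39 * np.sin(ang), 0.0]
        out.append(_atom(nm, xyz, ridx, resname, chain))
    return out


def make_tripeptide(resnames=("GLY", "PHE", "GLY"), with_oxt=True,
                    break_after=None):
    """Gly-Phe-Gly style tripeptide with planar backbone and an OXT terminus.

    ``break_after``: index i after which the next residue is translated far
    away (chain break).
    """
    atoms = []
    for i, rn in enumerate(resnames):
        d = i * 3.8
        shift = np.zeros(3)
        if break_after is not None and i > break_after:
            shift = np.array([50.0, 0.0, 0.0])
        atoms.append(_atom("N", [d, 0, 0] + shift, i, rn))
        atoms.append(_atom("CA", [d + 1.46, 0, 0] + shift, i, rn))
        atoms.append(_atom("C", [d + 2.52, 1.0, 0] + shift, i, rn))
        atoms.append(_atom("O", [d + 2.52, 2.23, 0] + shift, i, rn))
        if rn == "PHE":
            atoms.append(_atom("CB", [d + 1.46, -1.5, 0] + shift, i, rn))
            atoms.extend(a for a in _ring([d + 1.46, -4.0, 1.0], i, rn))
            # re-apply shift to ring atoms
            if break_after is not None and i > break_after:
                for a in atoms[-6:]:
                    a.coords = a.coords + shift
    if with_oxt:
        last = len(resnames) - 1
        d = last * 3.8
        shift = np.zeros(3)
        if break_after is not None and last > break_after:
            shift = np.array([50.0, 0.0, 0.0])
        atoms.append(_atom("OXT", [d + 3.75, 1.0, 0] + shift, last,
                           resnames[last]))
    return build_model(atoms, unit_cell=(80., 80., 80., 90., 90., 90.),
                       name="tripeptide")


@pytest.fixture(scope="session")
def tripeptide_model():
    return make_tripeptide()


@pytest.fixture(scope="session")
def survey_corpus():
    """240-chain synthetic annotation corpus with known rate structure."""
    return make_annotation_corpus(n_chains=240, seed=1)


@pytest.fixture(scope="session")
def fitted_predictor(survey_corpus):
    from pipistack.frequency_predictor import fit_predictor, split_chains
    annotations, truth = survey_corpus
    train, test = split_chains(annotations, seed=0)
    table, cal = fit_predictor(train, seed=7)
    return table, cal, train, test
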