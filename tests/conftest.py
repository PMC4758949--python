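"""Shared fixtures: synthetic structures and small residue builders."""

from __future__ import annotations

import numpy as np
import pytest

from satsup import geometry, synthdata
from satsup.structio import Atom, Residue, StructureModel


def make_residue(
    aa: str = "A",
    atoms: dict[str, tuple[float, float, float]] | None = None,
    chain: str = "A",
    seq: int = 1,
) -> Residue:
    """Build a residue from {atom_name: coords}; elements inferred."""
    atoms = atoms or {"CA": (0.0, 0.0, 0.0)}
    return Residue(
        chain_id=chain,
        seq_num=seq,
        icode="",
        aa=aa,
        atoms=[Atom(name, "", np.array(xyz, float)) for name, xyz in atoms.items()],
    )


def make_model(residues, index: int = 1) -> StructureModel:
    return StructureModel(model_index=index, residues=list(residues))


@pytest.fixture(scope="session")
def globule() -> StructureModel:
    return synthdata.compact_globule(60, seed=0)


@pytest.fixture(scope="session")
def globule_depths(globule):
    return geometry.residue_depth(globule)


@pytest.fixture(scope="session")
def native_bundle() -> StructureModel:
    return synthdata.synthetic_native(seed=0)
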