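"""Shared fixtures: synthetic structures and small helpers."""

from __future__ import annotations

import numpy as np
import pytest

from azidyn.structure_io import Atom, Structure


def make_chain_structure(n_residues: int, with_backbone: bool = True) -> Structure:
    """Synthetic poly-alanine Cα trace on a helix (non-collinear).

    With ``with_backbone`` each residue gets N, CA, C atoms so selector
    logic is exercised; otherwise one CA per residue.
    """
    atoms: list[Atom] = []
    coords: list[np.ndarray] = []
    phase = np.deg2rad(100.0)
    for i in range(n_residues):
        base = np.array(
            [2.3 * np.cos(phase * i), 2.3 * np.sin(phase * i), 1.5 * i]
        )
        names = ["N", "CA", "C"] if with_backbone else ["CA"]
        offsets = [
            np.array([0.5, 0.0, -0.4]),
            np.zeros(3),
            np.array([-0.5, 0.3, 0.4]),
        ]
        for name, off in zip(names, offsets):
            atoms.append(
                Atom(
                    name=name,
                    residue_name="ALA",
                    residue_number=i + 1,
                    chain_id="A",
                    element="N" if name == "N" else "C",
                    mass=14.007 if name == "N" else 12.011,
                )
            )
            coords.append(base + off)
    return Structure(atoms=atoms, coordinates=np.array(coords))


def write_pdb(structure: Structure, path) -> None:
    """Write a minimal fixed-column PDB for round-trip tests."""
    with open(path, "w") as fh:
        for serial, (atom, xyz) in enumerate(
            zip(structure.atoms, structure.coordinates), start=1
        ):
            name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
            fh.write(
                f"ATOM  {serial:5d} {name}{'':1s}{atom.residue_name:<3s} "
                f"{atom.chain_id or 'A':1s}{atom.residue_number:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {atom.element:>2s}\n"
            )
        fh.write("END\n")


@pytest.fixture
def chain_structure() -> Structure:
    return make_chain_structure(10)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
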