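"""Shared fixtures: synthetic structures, trajectories and models.

Everything is generated programmatically at test time; session scope
keeps the expensive fixtures (water boxes, calibrated-model runs) to
one construction each.
"""

import numpy as np
import pytest

from erbbscale import synthetic
from erbbscale.io_formats import Atom, StructureModel, TrajectoryEnsemble


@pytest.fixture(scope="session")
def toy():
    return synthetic.make_toy_kinase(40, seed=1)


@pytest.fixture(scope="session")
def toy_structure(toy):
    return toy.structure


@pytest.fixture(scope="session")
def ca_selection(toy_structure):
    return toy_structure.select(atom_name="CA")


@pytest.fixture(scope="session")
def poisson_box():
    """Pure-water box with independent Poisson frame statistics."""
    recipe = synthetic.WaterBoxRecipe(n_frames=1000, seed=42)
    return synthetic.make_water_box(recipe)


@pytest.fixture(scope="session")
def planted_network_traj(toy):
    recipe = synthetic.PlantedNetworkRecipe(
        pairs=((4, 37, 0.95), (7, 34, 0.40)), n_frames=200, seed=5
    )
    traj, truth = synthetic.make_planted_interaction_traj(toy, recipe)
    return traj, truth


@pytest.fixture(scope="session")
def egf_wt_result():
    from erbbscale.signaling import build_model, simulate

    model = build_model({"ligands": {"EGF": 8.0}, "receptors": {"ErbB3": 0.0}})
    return model, simulate(model)


def make_structure(positions, names=None, resnames=None, resids=None, elements=None, box=None):
    """Small helper for hand-built structures in tests."""
    positions = np.asarray(positions, dtype=float)
    n = positions.shape[0]
    names = names or ["CA"] * n
    resnames = resnames or ["ALA"] * n
    resids = resids or list(range(1, n + 1))
    elements = elements or [nm.strip()[0] for nm in names]
    atoms = [
        Atom(
            serial=i + 1,
            name=names[i],
            element=elements[i],
            residue_name=resnames[i],
            residue_id=resids[i],
            chain="A",
            position=positions[i],
        )
        for i in range(n)
    ]
    return StructureModel(atoms=atoms, box=box)


def static_trajectory(structure, n_frames=5):
    frames = np.repeat(structure.coords[None, :, :], n_frames, axis=0)
    return TrajectoryEnsemble(topology=structure, frames=frames)
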