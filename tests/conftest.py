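"""Shared fixtures: packaged toy-channel trajectories and small builders."""

from __future__ import annotations

import numpy as np
import pytest

from kvgate.io import Trajectory
from kvgate.pipeline import measure_variant
from kvgate.synthetic import build_toy_channel, mutant_channel_spec, wt_channel_spec

#: fixed fixture seeds so every statistical assertion is deterministic
WT_SEED, MUTANT_SEED = 101, 202


@pytest.fixture(scope="session")
def wt_traj():
    """Packaged WT fixture at the standard 2000 frames."""
    return build_toy_channel(wt_channel_spec(n_frames=2000, seed=WT_SEED))


@pytest.fixture(scope="session")
def mutant_traj():
    """Packaged S269-deletion fixture at the standard 2000 frames."""
    return build_toy_channel(mutant_channel_spec(n_frames=2000, seed=MUTANT_SEED))


@pytest.fixture(scope="session")
def wt_measured(wt_traj):
    return measure_variant(wt_traj)


@pytest.fixture(scope="session")
def mutant_measured(mutant_traj):
    return measure_variant(mutant_traj)


@pytest.fixture(scope="session")
def wt_small():
    """A cheaper WT fixture for structural (non-statistical) checks."""
    return build_toy_channel(wt_channel_spec(n_frames=120, seed=7))


@pytest.fixture(scope="session")
def mutant_small():
    return build_toy_channel(mutant_channel_spec(n_frames=120, seed=8))


def make_traj(records, variant="WT", pad_monomers=True):
    """Build a single-frame Trajectory from (monomer, res_name, res_seq,
    atom_name, xyz) tuples; pads the remaining monomers with far-away dummy
    atoms so the all-four-monomers invariant holds."""
    records = list(records)
    if pad_monomers:
        present = {r[0] for r in records if r[0] in "ABCD"}
        for i, m in enumerate(sorted(set("ABCD") - present)):
            records.append((m, "GLY", 999, "CA", (200.0 + i, 200.0, 200.0)))
    coords = np.asarray([r[4] for r in records], dtype=float)[None, :, :]
    return Trajectory(
        monomers=[r[0] for r in records],
        res_names=[r[1] for r in records],
        res_seqs=[r[2] for r in records],
        atom_names=[r[3] for r in records],
        coords=coords,
        variant=variant,
    )
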