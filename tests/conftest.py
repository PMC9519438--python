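"""Shared fixtures: Monte Carlo topoisomer ensembles and planted complexes.

The MC ensembles are expensive, so one session-scoped set is shared by the
topology, conformation and acceptance tests.  Problem sizes (84 beads for a
336-bp circle, ~100 production frames per topoisomer) keep the suite at
desk scale while leaving clear plectonemic signal.
"""

from __future__ import annotations

import numpy as np
import pytest

from supertwist.synthetic import (
    MCParams,
    MCTrajectory,
    PlantedComplexSpec,
    mc_ensemble,
    planted_complex,
)

#: integer linking-number offsets of the six emulated topoisomers
TOPOISOMER_OFFSETS = (-2, -1, 0, 1, 2, 3)

#: frames discarded as burn-in from each MC run
MC_BURN_FRAMES = 40


@pytest.fixture(scope="session")
def mc_topoisomers() -> dict[int, MCTrajectory]:
    """One equilibrated MC ensemble per topoisomer, ~100 production frames.

    Excluded volume (20 A) is enabled for |delta-Lk| = 3 so the tight
    plectoneme cannot pass through itself.
    """
    out = {}
    for dlk in TOPOISOMER_OFFSETS:
        params = MCParams(
            n_beads=84,
            delta_lk=float(dlk),
            n_steps=21_000,
            save_stride=150,
            seed=100 + dlk,
            excluded_diameter=20.0 if abs(dlk) >= 3 else 0.0,
        )
        out[dlk] = mc_ensemble(params)
    return out


def production_writhes(traj: MCTrajectory) -> np.ndarray:
    """Writhe series with burn-in discarded."""
    return traj.writhes[MC_BURN_FRAMES:]


@pytest.fixture(scope="session")
def planted_five_state():
    """Default 5-state planted protein-DNA trajectory (20 frames per state)."""
    return planted_complex(PlantedComplexSpec(seed=7))
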