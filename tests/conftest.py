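"""Shared fixtures: ideal-geometry loops at several sizes."""

import numpy as np
import pytest

from loopmodes.structure import LoopSpec, build_synthetic_loop, select_loop

# a mixed helix/turn/extended conformation so the loop is not degenerate
MIXED_PHI_PSI = {
    8: [(-65, -40)] * 3 + [(60, 45)] + [(-110, 130)] * 4,
    11: [(-65, -40)] * 5 + [(60, 45)] + [(-110, 130)] * 5,
}


def make_loop(n_res, phi_psi=None, scaffold=((6.0, 10),), env_cutoff=10.0,
              include_omega=False, sequence=None):
    """Build a synthetic loop structure and its LoopModel."""
    if phi_psi is None:
        phi_psi = MIXED_PHI_PSI.get(
            n_res, [(-65, -40), (60, 45), (-110, 130)] * ((n_res + 2) // 3)
        )[:n_res]
    structure = build_synthetic_loop(
        n_res, phi_psi, scaffold_shells=scaffold, sequence=sequence
    )
    spec = LoopSpec("A", 2, n_res + 1, include_omega=include_omega)
    return structure, select_loop(structure, spec, env_cutoff=env_cutoff)


def random_phi_psi(n_res, rng):
    """Random but sterically plausible backbone angles."""
    basins = [(-65.0, -40.0), (-110.0, 130.0), (60.0, 45.0), (-135.0, 155.0)]
    out = []
    for _ in range(n_res):
        phi, psi = basins[rng.integers(len(basins))]
        out.append(
            (phi + rng.uniform(-15, 15), psi + rng.uniform(-15, 15))
        )
    return out


@pytest.fixture(scope="session")
def loop8():
    return make_loop(8)


@pytest.fixture(scope="session")
def loop11():
    return make_loop(11)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
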