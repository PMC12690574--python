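import numpy as np
import pytest

import fdgamd as fg


@pytest.fixture(scope="session")
def energy_system():
    """Random 10x15-atom receptor/ligand system for oracle tests."""
    return fg.make_energy_test_system(10, 15, seed=42)


@pytest.fixture(scope="session")
def dominant_study():
    """One programmed dominant-site study, analyzed end to end."""
    spec = fg.dominant_site_spec(7)
    receptor, replicates, truth = fg.make_study(spec)
    result = fg.analyze_multicopy(replicates)
    return spec, receptor, replicates, truth, result


def brute_force_nonbonded(frame, topology, idx_a, idx_b):
    """Independent explicit double-loop nonbonded energy (oracle)."""
    from fdgamd.model_io import COULOMB_CONSTANT

    e_vdw = e_elec = 0.0
    for i in idx_a:
        ai = topology.atoms[i]
        for j in idx_b:
            aj = topology.atoms[j]
            r = float(np.linalg.norm(frame.coordinates[i]
                                     - frame.coordinates[j]))
            eps = np.sqrt(ai.lj_epsilon * aj.lj_epsilon)
            rmin = ai.lj_rmin_half + aj.lj_rmin_half
            rep_only = ai.is_repulsive_center and aj.is_repulsive_center
            b = 0.0 if rep_only else 2.0 * eps * rmin ** 6
            e_vdw += eps * rmin ** 12 / r ** 12 - b / r ** 6
            e_elec += COULOMB_CONSTANT * ai.charge * aj.charge / r
    return e_vdw, e_elec
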