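import numpy as np
import pytest

from photophys import ephys as ep
from photophys import synthetic as syn


@pytest.fixture(scope="session")
def photocycle_spec():
    return syn.default_photocycle_spec()


@pytest.fixture(scope="session")
def noisy_transient(photocycle_spec):
    """Default 3-intermediate fixture with 1% noise, fixed seed."""
    return syn.gen_transient_dataset(
        photocycle_spec, noise=syn.NoiseSpec(sd_relative=0.01, seed=7)
    )


def na_bath_conditions():
    """Symmetric 110 mM Na with impermeant Mg (standard composition)."""
    return syn.standard_na_conditions()


def k_bath_conditions(r_k: float = 0.0):
    """Bath Na replaced by K; pipette keeps 110 mM Na."""
    return ep.RecordingConditions(
        ions=[
            ep.IonSpecies("Na", 1, 110.0, 0.0, rel_permeability=1.0),
            ep.IonSpecies("K", 1, 0.0, 110.0, rel_permeability=r_k),
            ep.IonSpecies("Mg", 2, 2.0, 2.0, rel_permeability=0.0),
        ]
    )


def acidic_pipette_conditions():
    """Pipette pH 5.0 with impermeant arginine replacing Na; standard bath."""
    return ep.RecordingConditions(
        ions=[
            ep.IonSpecies("Na", 1, 0.0, 110.0, rel_permeability=1.0),
            ep.IonSpecies("H", 1, 1e-2, 10 ** (-7.4) * 1e3, rel_permeability=0.0),
            ep.IonSpecies("Arg", 1, 110.0, 0.0, rel_permeability=0.0),
            ep.IonSpecies("Mg", 2, 2.0, 2.0, rel_permeability=0.0),
        ]
    )


def spawn_seeds(base: int, n: int) -> list[int]:
    """n reproducible child seeds below 2**31 derived from one base seed."""
    ss = np.random.SeedSequence(base)
    return [int(child.generate_state(1)[0] % 2**31) for child in ss.spawn(n)]
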