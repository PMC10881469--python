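import numpy as np
import pytest

from depsort.core import DielectricMedium, ShelledParticle
from depsort.fitting import FitConfig
from depsort.synthetic import (
    default_frequency_grid,
    differentiated_like_population,
    msc_like_population,
)


@pytest.fixture
def buffer_004():
    return DielectricMedium(rel_permittivity=80.0, conductivity=0.04)


@pytest.fixture
def buffer_0128():
    return DielectricMedium(rel_permittivity=80.0, conductivity=0.128)


@pytest.fixture
def msc_cell():
    return msc_like_population().mean_particle()


@pytest.fixture
def diff_cell():
    return differentiated_like_population().mean_particle()


@pytest.fixture
def grid20():
    return default_frequency_grid()


@pytest.fixture
def fit_cfg(buffer_004, msc_cell):
    return FitConfig(radius=msc_cell.radius, medium=buffer_004)


def random_physical_particles(rng: np.random.Generator, n: int) -> list[ShelledParticle]:
    """Broad but physical single-shell parameter draws for property sweeps."""
    out = []
    for _ in range(n):
        r = rng.uniform(2e-6, 20e-6)
        out.append(
            ShelledParticle(
                radius=r,
                membrane_thickness=rng.uniform(3e-9, 10e-9),
                mem_rel_permittivity=rng.uniform(2.0, 20.0),
                mem_conductivity=10 ** rng.uniform(-8, -5),
                int_rel_permittivity=rng.uniform(40.0, 120.0),
                int_conductivity=10 ** rng.uniform(-2, 0.3),
            )
        )
    return out


def random_physical_media(rng: np.random.Generator, n: int) -> list[DielectricMedium]:
    return [
        DielectricMedium(
            rel_permittivity=rng.uniform(20.0, 80.0),
            conductivity=10 ** rng.uniform(-3, 0),
        )
        for _ in range(n)
    ]
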