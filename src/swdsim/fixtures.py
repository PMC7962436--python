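"""Small pinned fixtures for unit tests and quick experiments.

Each fixture is regenerated from its pinned seed on demand (nothing is
stored on disk) and is deliberately tiny so that every model fits in well
under five seconds.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .design import StudyDesign, build_design
from .simulate import ScenarioParams, SimulatedDataset, generate_dataset

__all__ = ["Fixture", "make_fixture", "FIXTURE_NAMES"]

FIXTURE_NAMES = ("glm_limit", "aghq", "smoke_s4")


@dataclasses.dataclass(frozen=True)
class Fixture:
    name: str
    design: StudyDesign
    params: ScenarioParams
    dataset: SimulatedDataset
    seed: int


def make_fixture(name: str) -> Fixture:
    """Return a pinned fixture by name.

    ``glm_limit``
        6 clusters x 5 periods, ``sigma_b0 = 0`` data: the random-intercept
        fit must reproduce the plain Poisson GLM.
    ``aghq``
        4 clusters x 3 periods with large offsets, for comparing the Laplace
        objective against adaptive Gauss-Hermite quadrature.
    ``smoke_s4``
        6 clusters x 5 periods under the combined confounding + early
        adoption scenario, exercising both latent exposure processes.
    """
    if name == "glm_limit":
        # pinned draw whose variance-component ML solution is the zero
        # boundary, so the mixed fit must collapse onto the plain GLM
        seed = 1004
        design = build_design(6, 5, 1, 2, 3.0, offsets=np.full(6, 2.0e5))
        params = ScenarioParams("1", alpha=-10.0, sigma_b0=0.0)
    elif name == "aghq":
        seed = 1002
        design = build_design(4, 3, 1, 2, 3.0, offsets=np.full(4, 5.0e6))
        params = ScenarioParams("1", alpha=-10.0, sigma_b0=0.4)
    elif name == "smoke_s4":
        seed = 1003
        design = build_design(6, 5, 1, 2, 3.0)
        params = ScenarioParams("4.1")
    else:
        raise ValueError(f"unknown fixture {name!r}; known: {', '.join(FIXTURE_NAMES)}")
    dataset = generate_dataset(design, params, np.random.default_rng(seed))
    return Fixture(name=name, design=design, params=params, dataset=dataset, seed=seed)
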