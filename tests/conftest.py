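"""Shared fixtures: default parameter sets and memoized scenario runs.

Full scenario solutions are expensive (seconds to ~half a minute), so a
session-scoped memoizing runner shares each converged case between the
behaviour tests and the acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from myofem.geometry import GeometryParams, LinkParams
from myofem.materials import MaterialParams
from myofem.scenarios import ScenarioSpec, build_variant_mesh, run_case, stiffness_sweep


@pytest.fixture(scope="session")
def geometry():
    return GeometryParams()


@pytest.fixture(scope="session")
def links():
    return LinkParams()


@pytest.fixture(scope="session")
def materials():
    return MaterialParams()


@pytest.fixture(scope="session")
def scenario(geometry, links):
    """Memoized scenario runner: ``scenario(variant, case)`` -> CaseResult."""
    cache: dict = {}
    meshes: dict = {}

    def get(variant: str, case: str):
        key = (variant, case)
        if key not in cache:
            if variant not in meshes:
                meshes[variant] = build_variant_mesh(variant, geometry, links)
            cache[key] = run_case(
                ScenarioSpec(model_variant=variant, case=case),
                geometry,
                links,
                mesh=meshes[variant],
            )
        return cache[key]

    return get


@pytest.fixture(scope="session")
def sweep(geometry, links):
    """Memoized stiffness sweep: ``sweep(case, factor)`` -> CaseResult
    (extramuscular variant)."""
    cache: dict = {}

    def get(case: str, factor: float):
        key = (case, factor)
        if key not in cache:
            spec = ScenarioSpec(model_variant="extramuscular", case=case)
            cache[key] = stiffness_sweep(spec, [factor], geometry, links)[0]
        return cache[key]

    return get


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260921)
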