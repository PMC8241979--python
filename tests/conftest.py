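"""Shared fixtures.

Expensive micro-FE artefacts (the desk-scale overloaded-strut phantom and
the cohort comparison) are session-scoped so each is computed once per run.
"""

from __future__ import annotations

import numpy as np
import pytest

import rtfe
from rtfe.cohort import demo_cohort, donor_target, simulate_cohort


@pytest.fixture(scope="session")
def overload_result():
    """Desk-scale overloaded-strut phantom with its generation-time FE solve."""
    return rtfe.make_overloaded_strut_phantom()


@pytest.fixture(scope="session")
def overload_distribution(overload_result):
    """Bone-masked strain distribution of the overloaded-strut phantom."""
    filtered = rtfe.gaussian_filter(overload_result.volume)
    matvol = rtfe.build_material_volume(filtered)
    return rtfe.effective_strain_field(
        overload_result.solution, rtfe.bone_mask(matvol)
    )


@pytest.fixture(scope="session")
def cohort_comparison():
    """Six-animal heterogeneous cohort over five weeks, both scenarios.

    Grid 32×32×40 (physical extent of the desk-scale femoral segment at a
    coarser voxel) keeps the 35 micro-FE solves tractable on one CPU.
    """
    target = donor_target()
    result = simulate_cohort(demo_cohort(seed=1), target=target)
    return result


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
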