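"""Shared fixtures: one small reduced-pacing population reused suite-wide."""

from __future__ import annotations

import warnings

import pytest

import atriavar as av


@pytest.fixture(scope="session")
def small_pop():
    """30-member reduced-pacing population (seeded, ~10 s to build)."""
    return av.build_population(30, 7, fast=True)


@pytest.fixture(scope="session")
def small_pops(small_pop):
    """Regional clustering of the small population (some regions empty)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return av.cluster_population(small_pop, warn_empty=False)


@pytest.fixture(scope="session")
def materials():
    return av.load_materials()


@pytest.fixture(scope="session")
def cv_targets():
    return av.load_cv_targets()
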