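"""Shared fixtures: toy segment maps, the default chromosome, and one
full default pipeline run reused by the slower end-to-end checks."""

from __future__ import annotations

import numpy as np
import pytest

from synscramble import ChromosomeStructure, Segment, SegmentMap, synthetic_map
from synscramble.pipeline import RunConfig, run_pipeline


@pytest.fixture(scope="session")
def smap6() -> SegmentMap:
    """Six-segment toy chromosome: centromere at C, marker on D."""
    return SegmentMap(
        [
            Segment("A", 10_000, genes=("gA1",), arm="left"),
            Segment("B", 15_000, genes=("gB1",), arm="left"),
            Segment("C", 5_000, is_centromere=True, arm="centromeric"),
            Segment("D", 8_000, marker="LEU2", arm="right"),
            Segment("E", 20_000, genes=("gE1", "gE2"), arm="right"),
            Segment("F", 12_000, genes=("gF1",), arm="right"),
        ]
    )


@pytest.fixture(scope="session")
def default_map() -> SegmentMap:
    return synthetic_map()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


def linear(*elems) -> ChromosomeStructure:
    return ChromosomeStructure("linear", tuple(_elem(e) for e in elems))


def circular(*elems) -> ChromosomeStructure:
    return ChromosomeStructure("circular", tuple(_elem(e) for e in elems))


def _elem(e):
    if isinstance(e, tuple):
        return e
    if e.startswith("-"):
        return (e[1:], -1)
    return (e, 1)


@pytest.fixture(scope="session")
def default_run():
    """One full default pipeline run (219 strains, seed 1), shared across
    the end-to-end and acceptance tests."""
    return run_pipeline(RunConfig(seed=1))
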