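"""Shared fixtures: small layouts, synthetic cohorts, z-score tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from epitile.signal import ZScoreTable
from epitile.simulate import SyntheticCohortConfig, simulate_cohort
from epitile.tiling import (
    ArrayLayout,
    MatureSequence,
    PeptideProbe,
    build_layout,
    tile_sequence,
)


def make_probes(
    starts, peptide_length: int = 15, antigen_id: str = "GAL1"
) -> list[PeptideProbe]:
    """Hand-built probes at explicit starts (grid need not begin at 1)."""
    return [
        PeptideProbe(
            probe_id=f"{antigen_id}_{s:03d}",
            antigen_id=antigen_id,
            start=s,
            end=s + peptide_length - 1,
            sequence="A" * peptide_length,
        )
        for s in starts
    ]


def make_ztable(
    layout: ArrayLayout,
    zmap: dict[str, float],
    patient_id: str = "P1",
    channel: str = "IgE",
    default: float = 0.0,
) -> ZScoreTable:
    """A one-array z-score table; probes absent from zmap get ``default``
    (NaN default marks them missing)."""
    row = {
        pid: zmap.get(pid, default)
        for pid in layout.probe_ids
    }
    z = pd.DataFrame(
        [row], index=pd.MultiIndex.from_tuples([(patient_id, channel)])
    )
    return ZScoreTable(z=z, normalization_stats={(patient_id, channel): (0.0, 1.0)})


@pytest.fixture
def seq30() -> MatureSequence:
    return MatureSequence("TEST30", "X00001", "ACDEFGHIKLMNPQRSTVWY" + "ACDEFGHIKL")


@pytest.fixture
def paper_grid_layout() -> ArrayLayout:
    """A 15/3 tiling on the grid of the printed epitope names (starts
    divisible by 3, spanning aa 24-98)."""
    return build_layout(make_probes(range(24, 85, 3)), blank_count=4)


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (13 allergic / 15 tolerant), seed 1."""
    return simulate_cohort(SyntheticCohortConfig(seed=1))


@pytest.fixture(scope="session")
def tiled_layout() -> ArrayLayout:
    seq = MatureSequence(
        "SYN_1", "SYNTH", "".join(np.random.default_rng(0).choice(list("ACDEFGHIKLMNPQRSTVWY"), 60))
    )
    return build_layout(tile_sequence(seq), blank_count=6)
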