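"""Shared fixtures: toy panels and hand-built count matrices."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cfmethdx.panel import AmpliconTarget
from cfmethdx.calling import build_site_matrix


def make_amplicon(
    gene: str,
    length: int = 100,
    cpgs: tuple[int, ...] = (20, 50),
    extra_c: tuple[int, ...] = (10, 70),
) -> AmpliconTarget:
    """Low-complexity amplicon with CpGs and non-CpG Cs at known offsets."""
    seq = ["A"] * length
    for p in extra_c:
        seq[p] = "C"  # followed by A: non-CpG context
    for p in cpgs:
        seq[p], seq[p + 1] = "C", "G"
    return AmpliconTarget(gene, "".join(seq), tuple(sorted(cpgs)))


@pytest.fixture
def toy_panel():
    return [
        make_amplicon("G1", 100, cpgs=(20, 50)),
        make_amplicon("G2", 120, cpgs=(30, 60, 90)),
    ]


def counts_row(sample, gene, pos, c, t, other=0):
    return {
        "sample_id": sample, "gene": gene, "pos": pos,
        "c_count": c, "t_count": t, "other_count": other,
    }


@pytest.fixture
def toy_matrix(toy_panel):
    """Two samples x full toy grid with mixed, well-covered sites."""
    rows = []
    for s, shift in (("S1", 0), ("S2", 2)):
        for gene, positions in (("G1", (20, 50)), ("G2", (30, 60, 90))):
            for p in positions:
                rows.append(counts_row(s, gene, p, 10 + shift, 10 - shift))
    return build_site_matrix(pd.DataFrame(rows), toy_panel)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
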