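"""Shared fixtures: small synthetic datasets and pair-table helpers."""

from __future__ import annotations

import pandas as pd
import pytest

from allodiverge.synthetic_hybrid import (
    HYBRID,
    SimulationConfig,
    SyntheticDataset,
    generate_dataset,
)


def pairs_from(genes, groups) -> pd.DataFrame:
    """Two-copy pair table (group_id, gene_a, gene_b, gene_ref) with gene_a
    the true subgenome-A copy."""
    label = {g.gene_id: g.subgenome for g in genes}
    rows = []
    for grp in groups:
        if grp.hybrid_status.get(HYBRID) != "two_copy":
            continue
        members = grp.members[HYBRID]
        a = next(g for g in members if label[g] == "A")
        b = next(g for g in members if label[g] == "B")
        rows.append(
            {
                "group_id": grp.group_id,
                "gene_a": a,
                "gene_b": b,
                "gene_ref": grp.members["ref"][0],
            }
        )
    return pd.DataFrame(rows, columns=["group_id", "gene_a", "gene_b", "gene_ref"])


@pytest.fixture(scope="session")
def small_dataset() -> SyntheticDataset:
    """One moderately sized synthetic hybrid shared across read-only tests."""
    return generate_dataset(SimulationConfig(seed=42, n_groups=600))


@pytest.fixture(scope="session")
def small_pairs(small_dataset) -> pd.DataFrame:
    return small_dataset.two_copy_pairs
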