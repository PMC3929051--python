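"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from bovscan.genotype import GenotypeMatrix
from bovscan.simulate import SelectedBlock, SimulationConfig, simulate_panel


def make_gm(dosage, breeds=None, chromosome=None, positions=None) -> GenotypeMatrix:
    """Build a GenotypeMatrix around a raw dosage array with sane defaults."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    if breeds is None:
        breeds = ["B1"] * (n // 2) + ["B2"] * (n - n // 2)
    if chromosome is None:
        chromosome = ["1"] * m
    if positions is None:
        pos, counts = [], {}
        for c in chromosome:
            counts[c] = counts.get(c, 0) + 1
            pos.append(counts[c] * 1000)
        positions = pos
    mm = pd.DataFrame(
        {
            "marker_id": [f"m{j}" for j in range(m)],
            "chromosome": [str(c) for c in chromosome],
            "position_bp": np.asarray(positions, dtype=np.int64),
            "allele_a": ["A"] * m,
            "allele_b": ["C"] * m,
        }
    )
    return GenotypeMatrix(
        sample_ids=[f"s{i}" for i in range(n)],
        breeds=np.array(breeds, dtype=object),
        marker_map=mm,
        dosage=dosage,
    )


@pytest.fixture(scope="session")
def five_breed_panel():
    """Clean 5-breed panel, no missingness or violations."""
    cfg = SimulationConfig(
        n_breeds=5,
        n_per_breed=(30,) * 5,
        n_chromosomes=3,
        n_markers_per_chromosome=200,
        f_background=0.1,
        seed=42,
    )
    return simulate_panel(cfg)


@pytest.fixture(scope="session")
def messy_panel():
    """Panel with missingness, HWE violations and a selected block."""
    cfg = SimulationConfig(
        n_breeds=3,
        n_per_breed=(40, 30, 30),
        n_chromosomes=3,
        n_markers_per_chromosome=150,
        f_background=0.05,
        selected_blocks=(
            SelectedBlock(chromosome=2, start_index=48, n_snps=16, f_selected=0.5),
        ),
        missing_rate=0.01,
        n_hwe_violating_markers=8,
        seed=99,
    )
    return simulate_panel(cfg)
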