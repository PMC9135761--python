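import numpy as np
import pandas as pd
import pytest

from gutdynamics.simulate import (
    SimConfig, generate_reference, plant_truth, simulate_bulk_counts,
    simulate_expression_tables, simulate_scatac_fragments,
)


@pytest.fixture(scope="session")
def toy_cfg():
    return SimConfig(
        seed=3, n_contigs=2, contig_length_bp=1_000_000, n_genes=60,
        organs=("intestine", "stomach", "lung"), n_cells_per_organ=100,
        n_peaks_total=600, n_temporal_gained_peaks=30, n_temporal_up_genes=8,
        n_ko_gained=30, n_ko_lost=30, fragment_rate=1500.0,
    )


@pytest.fixture(scope="session")
def toy_sim(toy_cfg):
    genome, genes = generate_reference(toy_cfg)
    peaks, truth = plant_truth(toy_cfg, genes)
    frags, cells = simulate_scatac_fragments(toy_cfg, genes, peaks, truth)
    bulk = simulate_bulk_counts(toy_cfg, peaks, truth)
    expr, de_lists = simulate_expression_tables(toy_cfg, genes, truth)
    return {
        "cfg": toy_cfg, "genome": genome, "genes": genes, "peaks": peaks,
        "truth": truth, "frags": frags, "cells": cells, "bulk": bulk,
        "expr": expr, "de_lists": de_lists,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_peak_frame(rng, n, contigs=("chr1", "chr2"), span=100_000, max_len=500):
    starts = rng.integers(0, span, size=n)
    lengths = rng.integers(1, max_len, size=n)
    return pd.DataFrame(
        {
            "contig": rng.choice(contigs, size=n),
            "start": starts,
            "end": starts + lengths,
            "name": [f"r{i}" for i in range(n)],
            "score": rng.uniform(0, 10, size=n),
            "strand": ".",
        }
    )
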