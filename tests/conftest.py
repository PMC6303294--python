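"""Shared fixtures: small simulated datasets, QC'd and normalized once."""

from __future__ import annotations

import numpy as np
import pytest

from il10het import hvg as hvg_mod
from il10het import normalize as nz
from il10het import qc as qc_mod
from il10het import synthdata as sd


@pytest.fixture(scope="session")
def full_thresholds():
    return qc_mod.QCThresholds.for_protocol("full_length")


@pytest.fixture(scope="session")
def sim3(full_thresholds):
    """3-cluster simulated dataset, QC'd: the workhorse for downstream stages."""
    spec = sd.SCSimSpec(
        n_genes=1500,
        n_cells=400,
        n_clusters=3,
        frac_de_genes_per_cluster=0.05,
        de_log2fc=3.0,
        seed=11,
    )
    m = sd.simulate_sc(spec)
    m, _ = qc_mod.filter_cells(m, full_thresholds)
    m, _ = qc_mod.filter_genes(m, full_thresholds)
    return m


@pytest.fixture(scope="session")
def sim3_norm(sim3):
    """Pooled-normalized log-expression of the 3-cluster dataset."""
    f = nz.pooled_factors(sim3)
    spike_f = nz.spike_factors(sim3)
    return nz.log_normalize(sim3, f, spike_f=spike_f)


@pytest.fixture(scope="session")
def sim3_hvg_table(sim3_norm):
    trend = hvg_mod.fit_technical_trend(sim3_norm, use_spikes=True)
    return hvg_mod.decompose_variance(sim3_norm, trend)


@pytest.fixture(scope="session")
def marker_panel():
    return sd.simulate_markers(sd.MarkerSimSpec(n_cells=3000, seed=2))


def planted_gene_ids(m):
    """Gene ids of all planted DE programs of a simulated matrix.

    Uses the id lists recorded at simulation time, which stay valid after
    gene filtering (positional indices would not).
    """
    ids = set()
    for prog in m.meta["de_program_gene_ids"]:
        ids.update(prog)
    return ids
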