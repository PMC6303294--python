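"""Pipeline configuration, provenance, and end-to-end orchestration.

A run is described by a YAML mapping with one section per stage; unknown
keys are rejected.  Every output file is checksummed and referenced by a
single provenance record, and the configuration hash is embedded in the
provenance so a run can be tied back to its exact parameters.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import cluster as cl
from . import compare as cp
from . import gating as gt
from . import heterogeneity as het
from . import hvg as hvg_mod
from . import io as io_mod
from . import normalize as nz
from . import qc as qc_mod
from . import synthdata as sd

log = logging.getLogger("il10het")

_STAGE_FIELDS = {
    "simulate": {"enabled", "sc", "bulk", "markers"},
    "qc": {"n_mads", "protocol", "drop_phases", "mito_direction"},
    "normalize": {"method", "spike_correct", "pseudocount"},
    "hvg": {"protocol", "use_spikes", "fdr_threshold"},
    "bootstrap": {"enabled", "subsample_size", "n_repeats", "seed"},
    "cluster": {"enabled", "perplexity", "eps", "min_pts", "seed"},
    "gate": {"enabled", "quantile", "min_markers"},
}


@dataclass
class PipelineConfig:
    """Validated stage parameters, seeds, and input/output paths."""

    input_dir: str | None = None
    output_dir: str = "pipeline_out"
    dialect: str = "mtx_10x"
    protocol: str = "full_length"
    simulate: dict = field(default_factory=dict)
    qc: dict = field(default_factory=dict)
    normalize: dict = field(default_factory=dict)
    hvg: dict = field(default_factory=dict)
    bootstrap: dict = field(default_factory=dict)
    cluster: dict = field(default_factory=dict)
    gate: dict = field(default_factory=dict)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for stage, fields_ in _STAGE_FIELDS.items():
            sub = raw.get(stage, {})
            bad = set(sub) - fields_
            if bad:
                raise ValueError(f"unknown keys in section {stage!r}: {sorted(bad)}")
        cfg = cls(**raw)
        if cfg.protocol not in ("full_length", "droplet"):
            raise ValueError(f"unknown protocol {cfg.protocol!r}")
        return cfg

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunProvenance:
    """Config hash, software version, per-output checksums, and warnings."""

    config_hash: str
    version: str
    started: float
    outputs: dict = field(default_factory=dict)  # path -> sha256
    stages: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    def record(self, stage: str, *paths: Path) -> None:
        self.stages.append(stage)
        for p in paths:
            self.outputs[str(p)] = hashlib.sha256(p.read_bytes()).hexdigest()[:16]

    def write(self, path: Path) -> None:
        payload = {
            "config_hash": self.config_hash,
            "version": self.version,
            "started": self.started,
            "stages": self.stages,
            "outputs": self.outputs,
            "warnings": self.warnings,
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True))


def run_pipeline(config: PipelineConfig) -> RunProvenance:
    """Execute the configured stages: (simulate) -> qc -> normalize -> hvg ->
    {bootstrap | cluster} -> gate, writing stage outputs and provenance."""
    from . import __version__

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = RunProvenance(
        config_hash=config.hash(), version=__version__, started=time.time()
    )
    stage = "setup"
    try:
        # --- input: simulate or read
        if config.simulate.get("enabled", config.input_dir is None):
            stage = "simulate"
            sc_params = dict(config.simulate.get("sc", {}))
            sc_params.setdefault("seed", config.seed)
            m = sd.simulate_sc(sd.SCSimSpec(**sc_params))
            io_mod.write_matrix(m, out / "simulated", dialect=config.dialect)
            prov.record(stage, out / "simulated" / "cells.csv")
        else:
            stage = "read"
            if not Path(config.input_dir).exists():
                raise FileNotFoundError(f"input path missing: {config.input_dir}")
            m = io_mod.read_matrix(config.input_dir, dialect=config.dialect)

        stage = "qc"
        thr = qc_mod.QCThresholds.for_protocol(
            config.protocol, n_mads=config.qc.get("n_mads", 3.0)
        )
        m, cell_rep = qc_mod.filter_cells(m, thr)
        m, gene_rep = qc_mod.filter_genes(m, thr)
        cell_rep.cell_table.to_csv(out / "qc_cells.csv")
        gene_rep.gene_table.to_csv(out / "qc_genes.csv")
        prov.record(stage, out / "qc_cells.csv", out / "qc_genes.csv")

        stage = "normalize"
        method = config.normalize.get("method", "pooled")
        f = nz.pooled_factors(m) if method == "pooled" else nz.libsize_factors(m)
        spike_f = None
        if config.normalize.get("spike_correct", True) and m.is_spike.any():
            spike_f = nz.spike_factors(m)
        logm = nz.log_normalize(
            m, f, pseudocount=config.normalize.get("pseudocount", 1.0), spike_f=spike_f
        )
        np.savetxt(out / "size_factors.csv", f.factors, delimiter=",")
        prov.record(stage, out / "size_factors.csv")

        stage = "hvg"
        use_spikes = config.hvg.get("use_spikes", bool(m.is_spike.sum() >= 10))
        trend = hvg_mod.fit_technical_trend(logm, use_spikes=use_spikes)
        table = hvg_mod.decompose_variance(
            logm,
            trend,
            bio_threshold=hvg_mod.BIO_THRESHOLDS[config.protocol],
            fdr_threshold=config.hvg.get("fdr_threshold", 0.05),
        )
        table.to_csv(out / "hvg_table.csv")
        prov.record(stage, out / "hvg_table.csv")

        if config.bootstrap.get("enabled", False):
            stage = "bootstrap"
            counts = het.bootstrap_hvg_counts(
                m,
                subsample_size=config.bootstrap.get("subsample_size", 100),
                n_repeats=config.bootstrap.get("n_repeats", 100),
                protocol=config.protocol,
                seed=config.bootstrap.get("seed", config.seed),
            )
            np.savetxt(out / "bootstrap_counts.csv", counts, fmt="%d", delimiter=",")
            prov.record(stage, out / "bootstrap_counts.csv")

        if config.cluster.get("enabled", True):
            stage = "cluster"
            hvg_ids = hvg_mod.hvg_gene_ids(table)
            if len(hvg_ids) >= 2:
                sub = logm.subset_genes(np.isin(logm.gene_ids, hvg_ids))
                emb = cl.embed_tsne(
                    sub,
                    perplexity=config.cluster.get("perplexity", 30.0),
                    seed=config.cluster.get("seed", config.seed),
                )
                model = cl.cluster_dbscan(
                    emb,
                    eps=config.cluster.get("eps", "auto"),
                    min_pts=config.cluster.get("min_pts", 10),
                    cell_ids=m.cell_ids,
                )
                emb_df = np.column_stack([emb, model.labels])
                np.savetxt(out / "embedding.csv", emb_df, delimiter=",",
                           header="tsne1,tsne2,label", comments="")
                prov.record(stage, out / "embedding.csv")
                if len(set(model.labels[model.labels >= 0])) >= 2:
                    mk = cl.cluster_markers(logm, model.labels)
                    mk.table.to_csv(out / "cluster_markers.csv", index=False)
                    prov.record(stage, out / "cluster_markers.csv")
            else:
                prov.warnings.append("fewer than 2 HVGs; clustering skipped")
    except Exception as exc:
        prov.warnings.append(f"stage {stage!r} failed: {exc}")
        prov.write(out / "provenance.json")
        raise RuntimeError(f"pipeline aborted in stage {stage!r}: {exc}") from exc

    prov.write(out / "provenance.json")
    return prov
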