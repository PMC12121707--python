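"""End-to-end orchestration of the pipeline stages from one config.

A run executes, in dependency order: simulate (optional) -> prep -> pls ->
network -> deg -> tfbm -> ddct, writing outputs and a manifest into the
output directory. The exact config (including the master seed) is
serialized next to the outputs for provenance, and per-stage seeds are
derived deterministically from the master seed via named streams so a
stage's draws do not depend on which other stages ran.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from helpnet import brain_network, cfos_prep, expression, synthetic_data, task_pls
from helpnet.data_model import (
    ValidationError,
    read_ct_table,
    read_expression,
    read_region_activity,
    read_tfbm,
    write_edge_list,
)

__all__ = ["RunConfig", "run_pipeline", "stage_seed"]

_STAGES = ("simulate", "prep", "pls", "network", "deg", "tfbm", "ddct")
_DEPS = {
    "prep": (),
    "pls": ("prep",),
    "network": ("prep",),
    "deg": (),
    "tfbm": ("deg",),
    "ddct": (),
}


@dataclass
class RunConfig:
    """Parameter registry for a pipeline run."""

    outdir: str = "run_out"
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(_STAGES))
    # inputs (ignored for stages fed by the simulate stage)
    counts_path: Optional[str] = None
    conditions_path: Optional[str] = None
    tpm_path: Optional[str] = None
    meta_path: Optional[str] = None
    motifs_path: Optional[str] = None
    ct_path: Optional[str] = None
    # thresholds and resampling counts
    min_per_condition: int = 3
    n_perm: int = 500
    n_boot: int = 500
    br_threshold: float = 2.57
    top_fraction: float = 0.10
    n_clusters: int = 4
    fc_threshold: float = 1.5
    tfbm_cycles: int = 200
    log_offset: float = 1.0
    network_condition: Optional[str] = "opener"

    def __post_init__(self) -> None:
        for name in ("min_per_condition", "n_perm", "n_boot", "tfbm_cycles"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        if self.br_threshold <= 0 or self.fc_threshold <= 1:
            raise ValidationError("thresholds out of range")
        if not 0 < self.top_fraction < 1:
            raise ValidationError("top_fraction must be in (0, 1)")
        unknown = [s for s in self.stages if s not in _STAGES]
        if unknown:
            raise ValidationError(f"unknown stage(s): {unknown}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(payload) - known
        if bad:
            raise ValidationError(f"unknown config key(s): {sorted(bad)}")
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns (and writes) the manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    manifest: dict = {"stages": {}, "seed": config.seed}
    state: dict = {}
    failed: set[str] = set()

    def record(stage: str, status: str, t0: float, outputs: list[Path]) -> None:
        manifest["stages"][stage] = {
            "status": status,
            "wall_clock_s": round(time.perf_counter() - t0, 4),
            "outputs": {p.name: _sha256(p) for p in outputs if p.exists()},
        }

    for stage in [s for s in _STAGES if s in config.stages]:
        t0 = time.perf_counter()
        blocked = [d for d in _DEPS.get(stage, ()) if d in failed]
        if blocked:
            manifest["stages"][stage] = {
                "status": f"blocked: upstream failure in {blocked[0]}",
                "wall_clock_s": 0.0,
                "outputs": {},
            }
            failed.add(stage)
            continue
        try:
            outputs = _run_stage(stage, config, state, outdir)
            record(stage, "ok", t0, outputs)
        except (ValidationError, FileNotFoundError) as exc:
            msg = str(exc)
            record(stage, msg if msg.startswith("blocked:") else f"failed: {msg}", t0, [])
            failed.add(stage)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _require_input(path: Optional[str], what: str) -> Path:
    if path is None:
        raise ValidationError(f"blocked: missing input ({what} not configured)")
    p = Path(path)
    if not p.exists():
        raise ValidationError(f"blocked: missing input ({p})")
    return p


def _run_stage(
    stage: str, config: RunConfig, state: dict, outdir: Path
) -> list[Path]:
    seed = stage_seed(config.seed, stage)
    if stage == "simulate":
        records, conditions, cfos_truth = synthetic_data.gen_cfos(seed=seed)
        e, t, expr_truth = synthetic_data.gen_expression(seed=seed)
        ct, ct_truth = synthetic_data.gen_ct(seed=seed)
        state.update(records=records, conditions=conditions, expr=e, tfbm=t, ct=ct)
        cfos_truth.to_json(outdir / "cfos_truth.json")
        expr_truth.to_json(outdir / "expression_truth.json")
        ct_truth.to_json(outdir / "ct_truth.json")
        return [outdir / n for n in ("cfos_truth.json", "expression_truth.json", "ct_truth.json")]

    if stage == "prep":
        if "records" not in state:
            counts = _require_input(config.counts_path, "counts table")
            cond_path = _require_input(config.conditions_path, "conditions table")
            records = read_region_activity(counts)
            cond_df = pd.read_csv(cond_path)
            conditions = dict(
                zip(cond_df["subject_id"].astype(str), cond_df["condition"].astype(str))
            )
        else:
            records, conditions = state["records"], state["conditions"]
        matrix, report = cfos_prep.prepare(
            records, conditions, min_per_condition=config.min_per_condition
        )
        state["matrix"] = matrix
        matrix.to_frame().to_csv(outdir / "activity_matrix.csv")
        (outdir / "prep_report.json").write_text(
            json.dumps(dataclasses.asdict(report), indent=2)
        )
        return [outdir / "activity_matrix.csv", outdir / "prep_report.json"]

    if stage == "pls":
        result = task_pls.run(
            state["matrix"],
            n_perm=config.n_perm,
            n_boot=config.n_boot,
            seed=seed,
            threshold=config.br_threshold,
        )
        state["pls"] = result
        out = outdir / "pls_regions.csv"
        pd.DataFrame(
            {
                "region_id": result.region_ids,
                "salience_lv1": result.saliences[:, 0],
                "bootstrap_ratio_lv1": result.bootstrap_ratio[:, 0],
                "reliable_lv1": result.reliable_mask[:, 0],
            }
        ).to_csv(out, index=False)
        (outdir / "pls_summary.json").write_text(
            json.dumps(
                {
                    "singular_values": result.singular_values.tolist(),
                    "perm_p": result.perm_p.tolist(),
                    "conditions": result.conditions,
                    "n_perm": config.n_perm,
                    "n_boot": config.n_boot,
                    "seed": seed,
                },
                indent=2,
            )
        )
        return [out, outdir / "pls_summary.json"]

    if stage == "network":
        r, region_ids = brain_network.correlation_matrix(
            state["matrix"], condition=config.network_condition
        )
        net = brain_network.threshold_top_decile(
            r, region_ids, fraction=config.top_fraction
        )
        brain_network.cluster_network(net, k=config.n_clusters)
        edges = outdir / "network_edges.csv"
        write_edge_list(net.adjacency, net.r_matrix, net.region_ids, edges)
        import networkx as nx

        graphml = outdir / "network.graphml"
        nx.write_graphml(brain_network.to_graph(net), graphml)
        state["network"] = net
        return [edges, graphml]

    if stage == "deg":
        if "expr" not in state:
            tpm = _require_input(config.tpm_path, "TPM matrix")
            meta = _require_input(config.meta_path, "sample metadata")
            state["expr"] = read_expression(tpm, meta, log_offset=config.log_offset)
        deg = expression.fit_deg_model(state["expr"], threshold=config.fc_threshold)
        state["deg"] = deg
        out = outdir / "deg.csv"
        deg.to_frame().to_csv(out, index=False)
        return [out]

    if stage == "tfbm":
        if "tfbm" not in state:
            motifs = _require_input(config.motifs_path, "TFBM count matrix")
            state["tfbm"] = read_tfbm(motifs)
        res = expression.tfbm_bootstrap(
            state["expr"],
            state["deg"],
            state["tfbm"],
            n_cycles=config.tfbm_cycles,
            seed=seed,
        )
        out = outdir / "tfbm.csv"
        res.to_frame().to_csv(out, index=False)
        return [out]

    if stage == "ddct":
        if "ct" not in state:
            ct_path = _require_input(config.ct_path, "Ct table")
            state["ct"] = read_ct_table(ct_path)
        res = expression.ddct_fold_change(state["ct"])
        out = outdir / "ddct.csv"
        res.samples.to_csv(out, index=False)
        summary = outdir / "ddct_summary.csv"
        res.group_summary.to_csv(summary, index=False)
        return [out, summary]

    raise ValidationError(f"unknown stage {stage!r}")
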