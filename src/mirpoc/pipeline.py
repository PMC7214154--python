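"""End-to-end pipeline orchestration, manifest and summary reporting.

Stage order: stratify the post-conditioned arm -> differential expression
per contrast -> regulation calls -> protective-pattern miR selection ->
signed miR-target network and node strength -> mitochondrial subnetwork.
A manifest records the seed, a hash of the configuration and per-stage
row counts so a re-run with the same configuration reproduces outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import expression, mito, network as netmod, patterns, stratify
from .patterns import CONTRASTS

GROUPS = ("Sham", "IR", "IPC", "IPoC_R", "IPoC_NR")
_CONTRAST_PAIRS = {
    "IR_vs_Sham": ("IR", "Sham"),
    "IPC_vs_IR": ("IPC", "IR"),
    "IPoCR_vs_IR": ("IPoC_R", "IR"),
    "IPoCNR_vs_IR": ("IPoC_NR", "IR"),
}


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """One source of truth for a pipeline run."""

    counts: str
    samples: str
    interactions: list = field(default_factory=list)  # [(path, dialect), ...]
    annotation: str = ""
    outdir: str = "run"
    alpha: float = 0.05
    lfc_min: float = 0.0
    shrinkage: float = 0.3
    pseudo_count: float = 0.5
    stratification_method: str = "mixture"
    convention: str = "repression"
    require_ipc_opposite: bool = True
    annotation_columns: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_table(df: pd.DataFrame, path: Path, config_hash: str, index: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, sep="\t", index=index)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns the manifest (also written to disk)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    manifest: dict = {
        "config_hash": chash,
        "seed": config.seed,
        "config": asdict(config),
        "stages": {},
    }

    # ---- stratification ----------------------------------------------------
    try:
        samples = pd.read_csv(config.samples)
        ipoc = samples[samples["arm"] == "IPoC"]
        strat = stratify.split_responders(
            ipoc["tni"],
            reference_ir=samples.loc[samples["arm"] == "IR", "tni"],
            reference_ipc=samples.loc[samples["arm"] == "IPC", "tni"],
            method=config.stratification_method,
        )
        group = samples["arm"].astype(str).copy()
        group.loc[ipoc.index] = np.where(
            strat.labels.to_numpy() == stratify.RESPONDER, "IPoC_R", "IPoC_NR"
        )
        samples = samples.assign(group=group)
        labels_out = pd.DataFrame(
            {
                "animal_id": ipoc["animal_id"].to_numpy(),
                "label": strat.labels.to_numpy(),
                "posterior": strat.posterior.to_numpy(),
                "method": strat.method,
            }
        )
        _write_table(labels_out, outdir / "labels.tsv", chash, index=False)
        summary = stratify.summarize_groups(samples.drop(columns=["group"]), strat)
        summary.columns = [f"{a}_{b}" for a, b in summary.columns]
        _write_table(summary, outdir / "group_summary.tsv", chash)
        manifest["stages"]["stratify"] = {
            "n_ipoc": int(len(ipoc)),
            "n_responders": strat.n_responders,
            "n_non_responders": strat.n_non_responders,
            "method": strat.method,
            "threshold": strat.threshold,
            "degenerate": strat.degenerate,
        }
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001 - abort names the stage
        raise StageError("stratify", e) from e

    # ---- differential expression -------------------------------------------
    try:
        counts = pd.read_csv(config.counts, sep="\t", index_col=0)
        groups = samples.set_index("animal_id")["group"].reindex(counts.columns)
        if groups.isna().any():
            raise ValueError("count matrix has samples absent from the annotation")
        model = expression.DifferentialExpression(
            counts, groups, shrinkage=config.shrinkage, pseudo_count=config.pseudo_count
        )
        de = model.fit(_CONTRAST_PAIRS)
        for name, tab in de.contrasts.items():
            _write_table(tab, outdir / f"de_{name}.tsv", chash)
        manifest["stages"]["de"] = {
            "n_features": int(len(counts)),
            "contrasts": list(de.contrasts),
            "n_significant": {
                name: int((tab["p"] <= config.alpha).sum()) for name, tab in de.contrasts.items()
            },
        }
    except Exception as e:
        raise StageError("de", e) from e

    # ---- calls + protective filter -----------------------------------------
    try:
        calls = {
            name: patterns.call_regulation(tab, alpha=config.alpha, lfc_min=config.lfc_min)
            for name, tab in de.contrasts.items()
        }
        selected = patterns.protective_mir_filter(
            calls, require_ipc_opposite=config.require_ipc_opposite
        )
        _write_table(selected, outdir / "protective_mirs.tsv", chash)
        manifest["stages"]["patterns"] = {
            "alpha": config.alpha,
            "n_input": int(len(selected)),
            "n_selected": int(selected["selected"].sum()),
        }
    except Exception as e:
        raise StageError("patterns", e) from e

    # ---- network -----------------------------------------------------------
    try:
        frames = []
        for path, dialect in config.interactions:
            df = pd.read_csv(path, sep="\t")
            df["source"] = dialect
            frames.append(df)
        raw = (
            pd.concat(frames, ignore_index=True)
            if frames
            else pd.DataFrame(columns=["mir_id", "target_id", "source", "score"])
        )
        kept = netmod.filter_interactions(raw)
        sel = selected[selected["selected"]]
        direction = sel["ir_direction"].rename("direction")
        g = netmod.build_network(direction, kept, convention=config.convention)
        strengths = netmod.node_strength(g)
        _write_table(strengths, outdir / "node_strength.tsv", chash)
        netmod.export_network(g, "tsv", outdir / "network_edges.tsv")
        netmod.export_network(g, "sif", outdir / "network.sif")
        manifest["stages"]["network"] = {
            "n_interactions_in": int(len(raw)),
            "n_interactions_kept": int(len(kept)),
            "thresholds": {"score_min": netmod.SCORE_MIN, "mirsvr_max": netmod.MIRSVR_MAX},
            "n_mirs": len(netmod.mir_nodes(g)),
            "n_targets": len(netmod.target_nodes(g)),
            "n_edges": g.number_of_edges(),
        }
    except Exception as e:
        raise StageError("network", e) from e

    # ---- mitochondrial subnetwork ------------------------------------------
    try:
        if not config.annotation:
            raise ValueError("no annotation file configured")
        annot = mito.load_annotation(config.annotation, column_map=config.annotation_columns)
        targets = netmod.target_nodes(g)
        matches = mito.reconcile_ids(targets, annot)
        kept_targets = mito.mito_select(matches, annot)
        sub = mito.extract_subnetwork(g, kept_targets)
        sub_strength = netmod.node_strength(sub)
        _write_table(mito.match_report(matches, annot), outdir / "mito_matches.tsv", chash, index=False)
        _write_table(sub_strength, outdir / "mito_node_strength.tsv", chash)
        netmod.export_network(sub, "tsv", outdir / "mito_edges.tsv")
        manifest["stages"]["mito"] = {
            "n_annotation_rows": int(len(annot)),
            "n_targets_in": len(targets),
            "n_targets_kept": len(kept_targets),
            "impi_min": mito.IMPI_MIN,
            "n_sub_mirs": len(netmod.mir_nodes(sub)),
            "n_sub_edges": sub.number_of_edges(),
        }
    except Exception as e:
        raise StageError("mito", e) from e

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return manifest


def percent(n: int, total: int, decimals: int = 1) -> float:
    """Share of a count as a percentage, rounded for reporting."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * n / total, decimals)


def report_summary(run_dir: str | Path, top_k: int = 10) -> str:
    """Human-readable report of a completed run directory."""
    run_dir = Path(run_dir)
    manifest_path = run_dir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"incomplete run directory: {manifest_path} missing")
    manifest = json.loads(manifest_path.read_text())
    st = manifest["stages"]

    lines = ["Post-conditioning responder pipeline — run summary", ""]
    s = st["stratify"]
    lines.append(
        f"Stratification ({s['method']}): {s['n_responders']} responders, "
        f"{s['n_non_responders']} non-responders of {s['n_ipoc']} post-conditioned animals"
    )

    de = st["de"]
    calls = de["n_significant"]
    n_feat = de["n_features"]
    up = down = None
    de_path = run_dir / "de_IR_vs_Sham.tsv"
    any_sig = None
    if de_path.exists():
        tabs = {
            name: pd.read_csv(run_dir / f"de_{name}.tsv", sep="\t", comment="#", index_col=0)
            for name in de["contrasts"]
        }
        alpha = manifest["config"]["alpha"]
        ir = tabs["IR_vs_Sham"]
        sig_ir = ir["p"] <= alpha
        up = int((sig_ir & (ir["log2fc"] > 0)).sum())
        down = int((sig_ir & (ir["log2fc"] < 0)).sum())
        any_sig = int(
            np.logical_or.reduce([tabs[n]["p"].to_numpy() <= alpha for n in tabs]).sum()
        )
    lines.append(f"Differential expression: {n_feat} miRs read; per-contrast hits: {calls}")
    if any_sig:
        lines.append(
            f"  {any_sig} miRs differentially expressed in any contrast; "
            f"{up} up after I/R ({percent(up, any_sig)}%), "
            f"{down} down after I/R ({percent(down, any_sig)}%)"
        )

    pat = st["patterns"]
    lines.append(
        f"Protective-pattern filter: {pat['n_selected']} of {pat['n_input']} miRs selected "
        f"(alpha={pat['alpha']})"
    )

    net = st["network"]
    lines.append(
        f"Network: kept {net['n_interactions_kept']}/{net['n_interactions_in']} interactions "
        f"(score > {net['thresholds']['score_min']}, mirSVR < {net['thresholds']['mirsvr_max']}); "
        f"{net['n_mirs']} miRs, {net['n_targets']} targets, {net['n_edges']} edges"
    )

    m = st["mito"]
    lines.append(
        f"Mitochondrial filter: {m['n_targets_kept']}/{m['n_targets_in']} targets kept "
        f"(GO flag or IMPI > {m['impi_min']}); subnetwork: {m['n_sub_mirs']} miRs, "
        f"{m['n_sub_edges']} edges"
    )

    strengths = run_dir / "mito_node_strength.tsv"
    lines.append("")
    lines.append(f"Top mitochondrial targets by |strength| (top {top_k}):")
    if strengths.exists():
        tab = pd.read_csv(strengths, sep="\t", comment="#", index_col=0)
        if tab.empty:
            lines.append("  none (empty subnetwork)")
        else:
            for t, row in tab.head(top_k).iterrows():
                lines.append(f"  {t}: strength {int(row['strength'])} (degree {int(row['degree'])})")
    else:
        lines.append("  none (empty subnetwork)")
    return "\n".join(lines)
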