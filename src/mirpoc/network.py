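"""Signed bipartite miR-target network construction and node strength.

Interaction records from three source dialects are merged under fixed
thresholds — validated interactions kept unconditionally, score-based
predictions kept for score > 80.0 (strict), mirSVR-style predictions kept
for score < -1.2 (strict) — and duplicated (miR, target) pairs collapse to
a single edge with the union of sources.

Edges are signed by the regulation direction of the miR. Under the default
``repression`` convention an edge from an up-regulated miR carries weight
-1 (its targets are expected to drop under miR-mediated repression) and an
edge from a down-regulated miR carries +1; the ``literal`` convention
inverts this. Per-target *node strength* is the sum of incident edge
weights and predicts the direction of the target's expression change;
targets are ranked by absolute strength.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

SOURCES = ("validated", "predicted_score", "predicted_mirsvr")
SCORE_MIN = 80.0  # strict: kept iff score > 80.0
MIRSVR_MAX = -1.2  # strict: kept iff score < -1.2


def validate_interactions(records: pd.DataFrame) -> pd.DataFrame:
    """Check source/score consistency of an interaction table."""
    needed = {"mir_id", "target_id", "source"}
    if not needed.issubset(records.columns):
        raise ValueError(f"interaction table needs columns {sorted(needed)}")
    df = records.copy()
    if "score" not in df.columns:
        df["score"] = np.nan
    bad = ~df["source"].isin(SOURCES)
    if bad.any():
        raise ValueError(f"unknown interaction sources: {sorted(df.loc[bad, 'source'].unique())}")
    score = df["score"].to_numpy(dtype=float)
    is_val = df["source"].to_numpy() == "validated"
    is_mirsvr = df["source"].to_numpy() == "predicted_mirsvr"
    is_score = df["source"].to_numpy() == "predicted_score"
    if np.any(is_val & ~np.isnan(score)):
        raise ValueError("validated records must not carry a score")
    if np.any((is_score | is_mirsvr) & np.isnan(score)):
        raise ValueError("predicted records must carry a score")
    if np.any(is_mirsvr & (score > 0)):
        raise ValueError("mirSVR scores must be <= 0")
    return df


def filter_interactions(records: pd.DataFrame) -> pd.DataFrame:
    """Apply the source thresholds and collapse duplicate pairs.

    Validated records always pass; scored predictions need score > 80.0;
    mirSVR predictions need score < -1.2 (both strict). Each surviving
    (miR, target) pair yields exactly one record whose ``source`` is the
    '+'-joined, sorted union of contributing sources.
    """
    df = validate_interactions(records)
    if df.empty:
        return df.head(0)[["mir_id", "target_id", "source"]].copy()
    src = df["source"].to_numpy()
    score = df["score"].to_numpy(dtype=float)
    keep = (
        (src == "validated")
        | ((src == "predicted_score") & (score > SCORE_MIN))
        | ((src == "predicted_mirsvr") & (score < MIRSVR_MAX))
    )
    kept = df.loc[keep, ["mir_id", "target_id", "source"]]
    merged = (
        kept.groupby(["mir_id", "target_id"], sort=True)["source"]
        .apply(lambda s: "+".join(sorted(set(s))))
        .reset_index()
    )
    return merged


def build_network(
    selected_mirs: pd.DataFrame | pd.Series,
    interactions: pd.DataFrame,
    convention: str = "repression",
) -> nx.Graph:
    """Signed bipartite graph over selected miRs and their targets.

    ``selected_mirs`` maps miR id to regulation direction ('up'/'down'),
    either a Series or a DataFrame with a ``direction`` column indexed by
    miR. Edges are the filtered interactions restricted to selected miRs;
    targets without edges do not enter the graph.
    """
    if convention not in ("repression", "literal"):
        raise ValueError("convention must be 'repression' or 'literal'")
    if isinstance(selected_mirs, pd.DataFrame):
        direction = selected_mirs["direction"]
    else:
        direction = selected_mirs
    bad = ~direction.isin(["up", "down"])
    if bad.any():
        raise ValueError(f"selected miRs without a valid direction: {list(direction.index[bad])}")

    sign = -1 if convention == "repression" else 1
    g = nx.Graph()
    sub = interactions[interactions["mir_id"].isin(direction.index)]
    for mir, target, source in sub[["mir_id", "target_id", "source"]].itertuples(index=False):
        d = direction[mir]
        weight = sign if d == "up" else -sign
        if not g.has_node(mir):
            g.add_node(mir, bipartite="mir", direction=d)
        if not g.has_node(target):
            g.add_node(target, bipartite="target")
        g.add_edge(mir, target, weight=int(weight), source=source)
    return g


def mir_nodes(g: nx.Graph) -> list[str]:
    return [n for n, d in g.nodes(data=True) if d.get("bipartite") == "mir"]


def target_nodes(g: nx.Graph) -> list[str]:
    return [n for n, d in g.nodes(data=True) if d.get("bipartite") == "target"]


def node_strength(g: nx.Graph) -> pd.DataFrame:
    """Per-target signed strength with degree and rank.

    strength(t) = sum of incident edge weights; ranking by |strength|
    descending, then strength descending, then target id ascending.
    """
    rows = []
    for t in target_nodes(g):
        weights = [d["weight"] for _, _, d in g.edges(t, data=True)]
        s = int(sum(weights))
        rows.append({"target_id": t, "strength": s, "degree": len(weights)})
    df = pd.DataFrame(rows, columns=["target_id", "strength", "degree"])
    if df.empty:
        df["rank"] = pd.Series(dtype=int)
        return df.set_index("target_id")
    df["abs_strength"] = df["strength"].abs()
    df = df.sort_values(
        by=["abs_strength", "strength", "target_id"], ascending=[False, False, True]
    ).drop(columns="abs_strength")
    df["rank"] = np.arange(1, len(df) + 1)
    return df.set_index("target_id")


# ---------------------------------------------------------------------------
# export / import
# ---------------------------------------------------------------------------

def export_network(g: nx.Graph, fmt: str, path: str | Path) -> Path:
    """Write the network as edge-list TSV, SIF or GraphML.

    The edge-list TSV is round-trip safe via :func:`read_edge_list`; the
    SIF relation encodes the weight sign (``pos`` / ``neg``).
    """
    path = Path(path)
    if fmt == "tsv":
        rows = [
            {
                "mir_id": u if g.nodes[u].get("bipartite") == "mir" else v,
                "target_id": v if g.nodes[u].get("bipartite") == "mir" else u,
                "weight": d["weight"],
                "source": d.get("source", ""),
                "mir_direction": g.nodes[u if g.nodes[u].get("bipartite") == "mir" else v]["direction"],
            }
            for u, v, d in g.edges(data=True)
        ]
        df = pd.DataFrame(rows, columns=["mir_id", "target_id", "weight", "source", "mir_direction"])
        df = df.sort_values(["mir_id", "target_id"]) if len(df) else df
        df.to_csv(path, sep="\t", index=False)
    elif fmt == "sif":
        with open(path, "w") as fh:
            for u, v, d in sorted(g.edges(data=True)):
                mir, tgt = (u, v) if g.nodes[u].get("bipartite") == "mir" else (v, u)
                rel = "pos" if d["weight"] > 0 else "neg"
                fh.write(f"{mir}\t{rel}\t{tgt}\n")
    elif fmt == "graphml":
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown export format {fmt!r}")
    return path


def read_edge_list(path: str | Path) -> nx.Graph:
    """Rebuild a network from the edge-list TSV written by export_network."""
    df = pd.read_csv(path, sep="\t")
    g = nx.Graph()
    for row in df.itertuples(index=False):
        if not g.has_node(row.mir_id):
            g.add_node(row.mir_id, bipartite="mir", direction=row.mir_direction)
        if not g.has_node(row.target_id):
            g.add_node(row.target_id, bipartite="target")
        g.add_edge(row.mir_id, row.target_id, weight=int(row.weight), source=row.source)
    return g
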