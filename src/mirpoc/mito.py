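"""Mitochondrial annotation reconciliation and subnetwork extraction.

Targets predicted by the network stage carry heterogeneous identifiers;
they are reconciled against a mitochondrial annotation table (IMPI-style
score plus a GO mitochondrial flag) through a fixed cascade of identifier
columns — Ensembl id, RGD id, NCBI id, symbol (case-insensitive), then
exact description — where the first hit wins and ambiguous symbol hits
are excluded rather than guessed. A target is retained as mitochondrial
when it matched and its annotation row has the GO flag or an IMPI score
strictly above 0.7. The mitochondria-related subnetwork is the subgraph
induced by the retained targets together with every miR interacting with
at least one of them, with node strengths recomputed on the subgraph.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import network as netmod

IMPI_MIN = 0.7  # strict: kept iff impi_score > 0.7 (or GO flag)
CASCADE = ("ensembl_id", "rgd_id", "ncbi_id", "symbol", "description")
MATCH_LEVELS = ("ensembl", "rgd", "ncbi_id", "symbol", "description")
_LEVEL_OF = dict(zip(CASCADE, MATCH_LEVELS))

DEFAULT_CLASSES = frozenset({"known", "predicted"})

_COLUMNS = [
    "ensembl_id",
    "rgd_id",
    "ncbi_id",
    "symbol",
    "description",
    "impi_score",
    "go_mito",
    "impi_class",
]


def load_annotation(
    table: pd.DataFrame | str | Path,
    restrict_classes: frozenset | set = DEFAULT_CLASSES,
    column_map: dict | None = None,
) -> pd.DataFrame:
    """Load and class-restrict the mitochondrial annotation table.

    ``column_map`` renames input columns onto the canonical schema. Rows
    whose IMPI class falls outside ``restrict_classes`` (default: known or
    predicted mitochondrial) are dropped; scores are validated to [0, 1].
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table, sep="\t", dtype=str, keep_default_na=False)
    df = table.copy()
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation lacks columns: {missing}")
    df = df[_COLUMNS].copy()
    df["impi_score"] = pd.to_numeric(df["impi_score"], errors="coerce")
    if df["impi_score"].isna().any() or (df["impi_score"] < 0).any() or (df["impi_score"] > 1).any():
        raise ValueError("malformed IMPI scores (must be numeric in [0, 1])")
    if df["go_mito"].dtype != bool:
        df["go_mito"] = (
            df["go_mito"].astype(str).str.strip().str.lower().isin(["true", "1", "yes", "t"])
        )
    keep = df["impi_class"].astype(str).str.lower().isin({c.lower() for c in restrict_classes})
    return df.loc[keep].reset_index(drop=True)


def reconcile_ids(targets: list[str], annotation: pd.DataFrame) -> pd.DataFrame:
    """Map each target id to an annotation row through the id cascade.

    For every target the cascade tries Ensembl -> RGD -> NCBI id ->
    case-insensitive symbol -> exact description; the first level with a
    unique hit wins. A symbol shared by two or more annotation rows is
    flagged ``unmatched_ambiguous``. Unmatched is a value, not an error.
    Results do not depend on annotation row order for unambiguous matches.
    """
    lookups: dict[str, dict] = {}
    ambiguous: dict[str, set] = {}
    for col in CASCADE:
        vals = annotation[col].astype(str)
        if col == "symbol":
            vals = vals.str.casefold()
        counts = vals[vals != ""].value_counts()
        dup = set(counts[counts > 1].index)
        table = {}
        for row_i, v in enumerate(vals):
            if v and v not in dup and v not in table:
                table[v] = row_i
        lookups[col] = table
        ambiguous[col] = dup

    rows = []
    for t in targets:
        t_str = str(t)
        level, row_i = "unmatched", None
        for col in CASCADE:
            key = t_str.casefold() if col == "symbol" else t_str
            if key in lookups[col]:
                level, row_i = _LEVEL_OF[col], lookups[col][key]
                break
            if key in ambiguous[col]:
                level, row_i = "unmatched_ambiguous", None
                break
        rows.append({"target_id": t, "match_level": level, "row": row_i})
    return pd.DataFrame(rows, columns=["target_id", "match_level", "row"])


def mito_select(matches: pd.DataFrame, annotation: pd.DataFrame) -> list[str]:
    """Targets retained as mitochondrial.

    Kept iff matched and the matched row has the GO mitochondrial flag or
    an IMPI score strictly above 0.7. Pure predicate: idempotent.
    """
    kept = []
    for t, level, row in matches[["target_id", "match_level", "row"]].itertuples(index=False):
        if level in ("unmatched", "unmatched_ambiguous") or row is None or pd.isna(row):
            continue
        rec = annotation.iloc[int(row)]
        if bool(rec["go_mito"]) or float(rec["impi_score"]) > IMPI_MIN:
            kept.append(t)
    return kept


def extract_subnetwork(g: nx.Graph, kept_targets) -> nx.Graph:
    """Induced mitochondria-related subnetwork.

    Target nodes are the kept targets present in the network; miR nodes are
    those with at least one edge to a kept target; edges are induced.
    Strengths must be recomputed on the subgraph (``node_strength``).
    """
    kept = set(kept_targets) & set(netmod.target_nodes(g))
    mirs = {m for t in kept for m in g.neighbors(t)}
    sub = g.subgraph(kept | mirs).copy()
    return sub


def match_report(matches: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Per-target report: match level, matched symbol, score and GO flag."""
    rows = []
    for t, level, row in matches[["target_id", "match_level", "row"]].itertuples(index=False):
        rec = annotation.iloc[int(row)] if row is not None and not pd.isna(row) else None
        rows.append(
            {
                "target_id": t,
                "match_level": level,
                "matched_symbol": "" if rec is None else rec["symbol"],
                "impi_score": np.nan if rec is None else float(rec["impi_score"]),
                "go_mito": False if rec is None else bool(rec["go_mito"]),
            }
        )
    return pd.DataFrame(rows)
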