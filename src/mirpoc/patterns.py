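"""Regulation calls, the protective-pattern miR filter and mRNA
group-partition categories.

A miR shows a *protective pattern* when its change after
ischaemia/reperfusion is reversed by the conditioning interventions that
actually protected (pre-conditioning and post-conditioning responders)
while the non-responders show no such reversal — the non-responder change
may be absent or even further enhanced in the injury direction; both count
as "not protective" there.

mRNAs measured by qPCR are partitioned by which conditioning groups
significantly changed them relative to I/R (all three / R and NR only /
R and IPC only / single groups / none).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

CONTRASTS = ("IR_vs_Sham", "IPC_vs_IR", "IPoCR_vs_IR", "IPoCNR_vs_IR")
DIRECTIONS = ("up", "down", "unchanged")

CATEGORIES = (
    "ALL3",
    "R_AND_NR",
    "R_AND_IPC",
    "R_ONLY",
    "NR_ONLY",
    "IPC_ONLY",
    "NONE",
    "OTHER",
)


def call_regulation(
    results: pd.DataFrame, alpha: float = 0.05, lfc_min: float = 0.0
) -> pd.DataFrame:
    """Discretize a contrast table into up / down / unchanged calls.

    ``up`` iff p <= alpha and log2fc > lfc_min; ``down`` iff p <= alpha
    and log2fc < -lfc_min; otherwise ``unchanged``. A boundary p exactly
    at alpha is called (<= semantics); a significant feature with log2fc
    exactly 0 is ``unchanged`` (directionless significance carries no
    information for a direction-based rule).
    """
    if not {"log2fc", "p"}.issubset(results.columns):
        raise ValueError("results need 'log2fc' and 'p' columns")
    sig = results["p"].to_numpy() <= alpha
    lfc = results["log2fc"].to_numpy()
    direction = np.where(
        sig & (lfc > lfc_min), "up", np.where(sig & (lfc < -lfc_min), "down", "unchanged")
    )
    out = results[["log2fc", "p"]].copy()
    out["direction"] = direction
    return out


def _opposite(a: str, b: str) -> bool:
    return (a == "up" and b == "down") or (a == "down" and b == "up")


def protective_mir_filter(
    calls: dict[str, pd.DataFrame], require_ipc_opposite: bool = True
) -> pd.DataFrame:
    """Select miRs with the protective expression pattern.

    ``calls`` maps each of the four contrast names to a call table (from
    :func:`call_regulation`, indexed by feature). A miR is selected iff

    1. it is regulated by I/R versus Sham (not ``unchanged``);
    2. the responder change versus I/R is opposite to the I/R change;
    3. (default) the IPC change versus I/R is also opposite — set
       ``require_ipc_opposite=False`` for the looser reading that lets the
       responder reversal alone satisfy the conditioned arms;
    4. the non-responder change versus I/R is NOT opposite (unchanged or
       same-direction both count as "no protective change").

    Returns a per-feature table with the I/R direction, the selected flag
    and a rationale string recording which clauses held.
    """
    missing = [c for c in CONTRASTS if c not in calls]
    if missing:
        raise ValueError(f"missing contrasts: {missing}")
    idx = calls["IR_vs_Sham"].index
    for c in CONTRASTS:
        if calls[c].index.duplicated().any():
            raise ValueError(f"duplicate feature calls in {c}")
        if not calls[c].index.equals(idx):
            calls = {k: v.reindex(idx) for k, v in calls.items()}
            break

    ir = calls["IR_vs_Sham"]["direction"]
    ipc = calls["IPC_vs_IR"]["direction"]
    r = calls["IPoCR_vs_IR"]["direction"]
    nr = calls["IPoCNR_vs_IR"]["direction"]

    rows = []
    for feat in idx:
        d_ir, d_ipc, d_r, d_nr = ir[feat], ipc[feat], r[feat], nr[feat]
        c1 = d_ir != "unchanged"
        c2 = _opposite(d_r, d_ir)
        c3 = _opposite(d_ipc, d_ir) if require_ipc_opposite else True
        c4 = not _opposite(d_nr, d_ir)
        selected = bool(c1 and c2 and c3 and c4)
        rationale = (
            f"ir_regulated={c1};responder_reversal={c2};"
            f"ipc_clause={c3};nr_not_protective={c4}"
        )
        rows.append(
            {
                "feature_id": feat,
                "ir_direction": d_ir,
                "selected": selected,
                "rationale": rationale,
            }
        )
    return pd.DataFrame(rows).set_index("feature_id")


def classify_mrna_pattern(sig_flags: pd.DataFrame) -> pd.Series:
    """Partition mRNAs by which conditioning groups regulated them vs I/R.

    ``sig_flags`` carries boolean columns ``IPC``, ``IPoCR``, ``IPoCNR``
    (significant change versus I/R). Categories are mutually exclusive and
    exhaustive: ALL3; R_AND_NR (R and NR but not IPC); R_AND_IPC; the three
    singletons; NONE; OTHER (IPC and NR without R).
    """
    needed = {"IPC", "IPoCR", "IPoCNR"}
    if not needed.issubset(sig_flags.columns):
        raise ValueError(f"sig_flags needs boolean columns {sorted(needed)}")
    ipc = sig_flags["IPC"].astype(bool)
    r = sig_flags["IPoCR"].astype(bool)
    nr = sig_flags["IPoCNR"].astype(bool)

    cat = pd.Series("OTHER", index=sig_flags.index, name="category")
    cat[ipc & r & nr] = "ALL3"
    cat[r & nr & ~ipc] = "R_AND_NR"
    cat[r & ipc & ~nr] = "R_AND_IPC"
    cat[r & ~ipc & ~nr] = "R_ONLY"
    cat[nr & ~r & ~ipc] = "NR_ONLY"
    cat[ipc & ~r & ~nr] = "IPC_ONLY"
    cat[~ipc & ~r & ~nr] = "NONE"
    return cat


def category_counts(categories: pd.Series) -> dict[str, int]:
    """Tally of partition categories, all categories present (zeros kept)."""
    vc = categories.value_counts()
    return {c: int(vc.get(c, 0)) for c in CATEGORIES}
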