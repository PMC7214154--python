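"""Synthetic study generator for the post-conditioning responder pipeline.

Emulates the structure of an in-vivo rat ischaemia/reperfusion (I/R) study
with four arms — Sham, I/R, ischaemic pre-conditioning (IPC) and ischaemic
post-conditioning (IPoC) — in which the IPoC arm splits into responders
(low plasma troponin I, infarct-protected) and non-responders (I/R-like
troponin). Every input the downstream pipeline consumes is generated here
with planted ground truth:

* plasma TnI and echo/morphology records per animal,
* a miR count matrix with negative-binomial noise, library-size factors
  and planted per-contrast log2 fold changes including conditioning-
  dependent reversal patterns,
* qPCR Ct tables with planted group fold changes,
* three miR-target interaction tables in the three dialects the network
  stage accepts (validated / scored 0-100 / mirSVR-style negative scores),
* a mitochondrial annotation table with multi-identifier aliasing.

All generators draw from counter-keyed substreams of one global seed, so
adding a generator never perturbs the output of an existing one, and the
same ``SimulationConfig`` always reproduces byte-identical tables.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

ARMS = ("Sham", "IR", "IPC", "IPoC")
GROUPS = ("Sham", "IR", "IPC", "IPoC_R", "IPoC_NR")
CONTRASTS = ("IR_vs_Sham", "IPC_vs_IR", "IPoCR_vs_IR", "IPoCNR_vs_IR")
#: group whose planted fold change feeds each "X vs I/R" contrast
_CONTRAST_GROUP = {
    "IR_vs_Sham": ("IR", "Sham"),
    "IPC_vs_IR": ("IPC", "IR"),
    "IPoCR_vs_IR": ("IPoC_R", "IR"),
    "IPoCNR_vs_IR": ("IPoC_NR", "IR"),
}

# fixed substream keys: appending new generators must not renumber these
_STREAMS = {
    "labels": 0,
    "troponin": 1,
    "counts": 2,
    "qpcr": 3,
    "interactions": 4,
    "mito": 5,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Counter-keyed substream of the global seed."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAMS[stream],))
    return np.random.default_rng(ss)


class ParameterError(ValueError):
    """Invalid simulation parameters."""


def _default_tni_params() -> dict:
    # natural-log location/spread of plasma TnI (ng/mL); injury markers are
    # right-skewed so components are log-normal. The spread (0.25 on the ln
    # scale) keeps the two IPoC components cleanly separable so planted
    # labels are recoverable by any inter-component threshold — a design
    # property of the generator, tighter than a real assay's spread.
    return {
        "Sham": (math.log(0.2), 0.25),
        "IR": (math.log(50.0), 0.25),
        "IPC": (math.log(5.0), 0.25),
        "IPoC_R": (math.log(5.0), 0.25),
        "IPoC_NR": (math.log(50.0), 0.25),
    }


def _default_reversal_fractions() -> dict:
    return {"IPC": 0.5, "IPoC_R": 0.28, "IPoC_NR": 0.05}


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study.

    Defaults emulate the study conditions: 4 arms of 20 rats, a 40%
    responder fraction in the IPoC arm (8 R / 12 NR), 627 expressed miRs
    of which 286 are differentially expressed (82 up and 77 down after
    I/R, the remainder regulated by conditioning only).
    """

    seed: int = 0
    n_per_arm: int = 20
    responder_fraction: float = 0.4
    tni_params: dict = field(default_factory=_default_tni_params)
    n_mirs: int = 627
    n_de: int = 286
    n_up: int = 82
    n_down: int = 77
    reversal_fractions: dict = field(default_factory=_default_reversal_fractions)
    nr_enhanced_fraction: float = 0.05
    dispersion: float | np.ndarray = 0.1
    lib_size_range: tuple = (0.5, 2.0)
    effect_size_range: tuple = (1.0, 3.0)
    base_mean_range: tuple = (10.0, 1000.0)
    db_sizes: tuple = (1500, 3000, 3000)
    n_targets: int = 300
    mito_fraction: float = 0.3
    alias_rate: float = 0.2
    qpcr_n_per_group: int = 5
    qpcr_noise_sd: float = 0.15

    def __post_init__(self) -> None:
        if not (0.0 < self.responder_fraction < 1.0):
            raise ParameterError("responder_fraction must be in (0, 1)")
        for name in ("n_per_arm", "n_mirs", "n_targets"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.n_up + self.n_down > self.n_de:
            raise ParameterError("n_up + n_down must not exceed n_de")
        if self.n_de > self.n_mirs:
            raise ParameterError("n_de must not exceed n_mirs")
        if np.any(np.asarray(self.dispersion) <= 0):
            raise ParameterError("dispersion must be positive")
        for grp, (_, sd) in self.tni_params.items():
            if sd <= 0:
                raise ParameterError(f"non-positive TnI spread for {grp}")
        lo, hi = self.lib_size_range
        if not (0 < lo <= hi):
            raise ParameterError("invalid lib_size_range")
        for frac in list(self.reversal_fractions.values()) + [
            self.nr_enhanced_fraction,
            self.alias_rate,
            self.mito_fraction,
        ]:
            if not (0.0 <= frac <= 1.0):
                raise ParameterError("fractions must lie in [0, 1]")

    @property
    def n_responders(self) -> int:
        return int(round(self.responder_fraction * self.n_per_arm))


def responder_labels(config: SimulationConfig) -> np.ndarray:
    """Planted responder flags for the IPoC arm (assigned, not sampled).

    Exactly ``round(responder_fraction * n_per_arm)`` animals are
    responders; only their placement within the arm is randomized.
    """
    rng = _rng(config.seed, "labels")
    n = config.n_per_arm
    labels = np.zeros(n, dtype=bool)
    labels[: config.n_responders] = True
    rng.shuffle(labels)
    return labels


def sample_groups(config: SimulationConfig) -> pd.DataFrame:
    """Animal ids with arm and (truth) five-group assignment."""
    labels = responder_labels(config)
    rows = []
    for arm in ARMS:
        for i in range(config.n_per_arm):
            if arm == "IPoC":
                group = "IPoC_R" if labels[i] else "IPoC_NR"
            else:
                group = arm
            rows.append({"animal_id": f"{arm}-{i + 1:02d}", "arm": arm, "group": group})
    return pd.DataFrame(rows)


# per-group echo/morphology generator means and SDs (mm, bpm, %, mg/g)
_ECHO_PARAMS = {
    #            HR        AWTd        PWTd        LVEDD       FS           hw_bw
    "Sham":    ((353, 44), (1.65, 0.36), (1.72, 0.35), (4.91, 0.73), (61.8, 12.5), (2.9, 0.20)),
    "IR":      ((394, 30), (1.75, 0.62), (1.78, 0.36), (5.67, 1.04), (45.8, 13.6), (3.6, 0.30)),
    "IPC":     ((421, 37), (2.02, 0.23), (1.75, 0.37), (5.01, 0.58), (53.9, 16.4), (3.3, 0.25)),
    "IPoC_R":  ((405, 28), (1.80, 0.47), (1.96, 0.35), (5.54, 0.63), (50.2, 6.4),  (3.0, 0.20)),
    "IPoC_NR": ((399, 48), (1.87, 0.40), (1.90, 0.53), (5.44, 0.85), (42.1, 15.1), (3.6, 0.30)),
}


def simulate_troponin(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-animal records: TnI, heart/body weight, echo summaries.

    TnI is drawn log-normally per group; the IPoC arm is the two-component
    mixture (responder component centred at the IPC location, non-responder
    at the I/R location). Returns ``(animals, truth)`` where truth carries
    the planted responder labels.
    """
    rng = _rng(config.seed, "troponin")
    frame = sample_groups(config)
    n = len(frame)

    mu = np.array([config.tni_params[g][0] for g in frame["group"]])
    sd = np.array([config.tni_params[g][1] for g in frame["group"]])
    tni = np.exp(rng.normal(mu, sd))

    hr = np.empty(n)
    awtd = np.empty(n)
    pwtd = np.empty(n)
    lvedd = np.empty(n)
    fs = np.empty(n)
    hw_bw = np.empty(n)
    for i, g in enumerate(frame["group"]):
        (hr_p, awtd_p, pwtd_p, lvedd_p, fs_p, hw_p) = _ECHO_PARAMS[g]
        hr[i] = rng.normal(*hr_p)
        awtd[i] = max(rng.normal(*awtd_p), 0.5)
        pwtd[i] = max(rng.normal(*pwtd_p), 0.5)
        lvedd[i] = max(rng.normal(*lvedd_p), 2.0)
        fs[i] = np.clip(rng.normal(*fs_p), 5.0, 95.0)
        hw_bw[i] = max(rng.normal(*hw_p), 1.0)
    lvesd = lvedd * (1.0 - fs / 100.0)  # keeps LVESD <= LVEDD by construction
    ef = np.clip(fs * 1.45, 0.0, 100.0)  # crude FS->EF mapping, % scale

    animals = frame[["animal_id", "arm"]].copy()
    animals["tni"] = tni
    animals["hw_bw"] = hw_bw
    animals["HR"] = hr
    animals["AWTd"] = awtd
    animals["PWTd"] = pwtd
    animals["LVEDD"] = lvedd
    animals["LVESD"] = lvesd
    animals["FS"] = fs
    animals["EF"] = ef

    truth = frame.copy()
    truth["responder"] = frame["group"].eq("IPoC_R")
    return animals, truth


def mir_names(n: int) -> list[str]:
    """miRBase-style synthetic mature names."""
    return [f"rno-miR-{i + 1:04d}-{'3p' if i % 2 else '5p'}" for i in range(n)]


def _planted_lfc(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Per-feature planted log2 fold change of each group relative to Sham.

    Counts of up-, down- and conditioning-only regulated features are
    assigned exactly from the config (never sampled); only which features
    carry them is randomized.
    """
    names = mir_names(config.n_mirs)
    de_idx = rng.choice(config.n_mirs, size=config.n_de, replace=False)
    up_idx = de_idx[: config.n_up]
    down_idx = de_idx[config.n_up : config.n_up + config.n_down]
    cond_idx = de_idx[config.n_up + config.n_down :]

    lo, hi = config.effect_size_range
    lfc = pd.DataFrame(0.0, index=names, columns=list(GROUPS))
    mag = rng.uniform(lo, hi, size=config.n_de)

    ir_effect = np.zeros(config.n_mirs)
    ir_effect[up_idx] = mag[: config.n_up]
    ir_effect[down_idx] = -mag[config.n_up : config.n_up + config.n_down]
    for g in ("IR", "IPC", "IPoC_R", "IPoC_NR"):
        lfc[g] = ir_effect  # start at the I/R level; reversal pulls back to Sham

    reg_idx = np.concatenate([up_idx, down_idx])
    reversed_in = {}
    for g in ("IPC", "IPoC_R", "IPoC_NR"):
        frac = config.reversal_fractions.get(g, 0.0)
        k = int(round(frac * len(reg_idx)))
        chosen = rng.choice(reg_idx, size=k, replace=False) if k else np.array([], int)
        lfc.iloc[chosen, lfc.columns.get_loc(g)] = 0.0  # back to the Sham level
        reversed_in[g] = set(chosen.tolist())

    # a minority of regulated miRs is pushed even further in non-responders
    k_enh = int(round(config.nr_enhanced_fraction * len(reg_idx)))
    not_reversed_nr = np.array(sorted(set(reg_idx.tolist()) - reversed_in["IPoC_NR"]), int)
    if k_enh and len(not_reversed_nr):
        enh = rng.choice(not_reversed_nr, size=min(k_enh, len(not_reversed_nr)), replace=False)
        col = lfc.columns.get_loc("IPoC_NR")
        lfc.iloc[enh, col] = lfc.iloc[enh, col] + np.sign(lfc.iloc[enh, col])
        enhanced_nr = set(enh.tolist())
    else:
        enhanced_nr = set()

    # conditioning-only features: unchanged after I/R, regulated in IPoC-R
    half = len(cond_idx) // 2
    cond_mag = rng.uniform(lo, hi, size=len(cond_idx))
    col_r = lfc.columns.get_loc("IPoC_R")
    for j, idx in enumerate(cond_idx):
        for g in ("IR", "IPC", "IPoC_NR"):
            lfc.iloc[idx, lfc.columns.get_loc(g)] = 0.0
        lfc.iloc[idx, col_r] = cond_mag[j] if j < half else -cond_mag[j]

    truth = pd.DataFrame(index=names)
    truth.index.name = "feature_id"
    for c, (num, den) in _CONTRAST_GROUP.items():
        truth[f"lfc_{c}"] = (lfc[num] - lfc[den]).to_numpy()
    truth["regulated_ir"] = False
    truth.iloc[reg_idx, truth.columns.get_loc("regulated_ir")] = True
    truth["de_any"] = False
    truth.iloc[de_idx, truth.columns.get_loc("de_any")] = True
    for g in ("IPC", "IPoC_R", "IPoC_NR"):
        flag = np.zeros(config.n_mirs, bool)
        flag[list(reversed_in[g])] = True
        truth[f"reversed_{g}"] = flag
    enh_flag = np.zeros(config.n_mirs, bool)
    enh_flag[list(enhanced_nr)] = True
    truth["enhanced_NR"] = enh_flag
    # the planted "protective pattern": regulated by I/R, reversed in
    # IPoC-R (strict mode additionally requires IPC reversal), and not
    # reversed in the non-responders
    truth["protective_loose"] = (
        truth["regulated_ir"] & truth["reversed_IPoC_R"] & ~truth["reversed_IPoC_NR"]
    )
    truth["protective_strict"] = truth["protective_loose"] & truth["reversed_IPC"]
    for g in GROUPS:
        truth[f"group_lfc_{g}"] = lfc[g].to_numpy()
    return truth


def simulate_mir_counts(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """NB count matrix (miRs x samples) with planted effects.

    Returns ``(counts, truth)``; truth carries planted per-contrast log2
    fold changes, reversal/enhancement flags, the protective-pattern flag
    in both clause modes, per-sample library-size factors and the
    dispersion used.
    """
    rng = _rng(config.seed, "counts")
    groups = sample_groups(config)
    truth = _planted_lfc(config, rng)

    base = np.exp(
        rng.uniform(
            math.log(config.base_mean_range[0]),
            math.log(config.base_mean_range[1]),
            size=config.n_mirs,
        )
    )
    lib = np.exp(
        rng.uniform(
            math.log(config.lib_size_range[0]),
            math.log(config.lib_size_range[1]),
            size=len(groups),
        )
    )
    alpha = np.broadcast_to(np.asarray(config.dispersion, float), (config.n_mirs,)).copy()

    group_lfc = truth[[f"group_lfc_{g}" for g in GROUPS]].to_numpy()
    gidx = np.array([GROUPS.index(g) for g in groups["group"]])
    mean = base[:, None] * np.power(2.0, group_lfc[:, gidx]) * lib[None, :]

    if np.all(alpha < 1e-8):
        counts = rng.poisson(mean)
    else:
        r = 1.0 / alpha[:, None]
        p = r / (r + mean)
        counts = rng.negative_binomial(np.broadcast_to(r, mean.shape), p)

    counts_df = pd.DataFrame(counts, index=truth.index, columns=groups["animal_id"].tolist())
    truth = truth.copy()
    truth["base_mean"] = base
    truth["dispersion"] = alpha
    truth.attrs["lib_sizes"] = dict(zip(groups["animal_id"], lib))
    truth.attrs["sample_groups"] = dict(zip(groups["animal_id"], groups["group"]))
    return counts_df, truth


HOUSEKEEPING = "Gapdh"


def _default_qpcr_folds() -> pd.DataFrame:
    """Planted group fold changes (vs Sham) for the qPCR generator.

    Magnitudes emulate calcium-handling/remodelling genes in the four
    injured groups, including one strongly induced gene (fold ~9.7 in
    responders).
    """
    data = {
        #            IR     IPC   IPoC_R  IPoC_NR
        "Serca2a": (0.70, 2.99, 9.74, 5.02),
        "Vegfa":   (0.69, 0.90, 1.60, 1.65),
        "Zbtb20":  (0.77, 0.45, 0.35, 0.37),
        "Efhd2":   (2.49, 1.03, 0.33, 1.03),
        "Arg2":    (1.05, 0.80, 0.21, 0.61),
        "Ucp2":    (1.00, 1.80, 2.10, 1.00),
    }
    df = pd.DataFrame(data, index=["IR", "IPC", "IPoC_R", "IPoC_NR"]).T
    df.insert(0, "Sham", 1.0)
    return df


def simulate_qpcr(
    config: SimulationConfig, folds: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Ct table (features x samples, housekeeping row included).

    Ct noise is additive Gaussian so that delta-delta-Ct recovery of the
    planted folds is unbiased. Returns ``(ct, truth_folds, sample_groups)``.
    """
    if folds is None:
        folds = _default_qpcr_folds()
    missing = [g for g in GROUPS if g not in folds.columns]
    if missing:
        raise ParameterError(f"fold table lacks groups: {missing}")
    rng = _rng(config.seed, "qpcr")
    n = config.qpcr_n_per_group
    sd = config.qpcr_noise_sd

    sample_ids, group_of = [], []
    for g in GROUPS:
        for i in range(n):
            sample_ids.append(f"q{g}-{i + 1}")
            group_of.append(g)
    group_of = pd.Series(group_of, index=sample_ids, name="group")

    base_dct = rng.uniform(2.0, 8.0, size=len(folds))  # gene-specific offset vs housekeeping
    hk_ct = 18.0 + rng.normal(0.0, sd, size=len(sample_ids))
    rows = {HOUSEKEEPING: hk_ct}
    for gi, gene in enumerate(folds.index):
        fold_per_sample = np.array([folds.loc[gene, g] for g in group_of])
        ct = hk_ct + base_dct[gi] - np.log2(fold_per_sample) + rng.normal(0.0, sd, len(sample_ids))
        rows[gene] = ct
    ct_df = pd.DataFrame(rows, index=sample_ids).T
    ct_df.index.name = "feature_id"
    return ct_df, folds.copy(), group_of


def gene_symbols(n: int) -> list[str]:
    return [f"Gene{i + 1:04d}" for i in range(n)]


def simulate_interaction_dbs(
    config: SimulationConfig, mirs: list[str] | None = None, targets: list[str] | None = None
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Three interaction tables in the three source dialects.

    Dialect ``validated`` has no score; ``predicted_score`` scores are
    uniform on [0, 100]; ``predicted_mirsvr`` scores uniform on [-2.5, 0],
    both straddling the filtering thresholds (80.0 and -1.2). Vocabularies
    overlap the supplied miR/target lists but include novel names too.
    Returns ``({dialect: table}, truth)`` where truth flags which records
    are planted to survive threshold filtering.
    """
    rng = _rng(config.seed, "interactions")
    if mirs is None:
        mirs = mir_names(config.n_mirs)
    if targets is None:
        targets = gene_symbols(config.n_targets)
    mir_vocab = list(mirs) + [f"rno-miR-nov-{i + 1:03d}" for i in range(max(3, len(mirs) // 20))]
    tgt_vocab = list(targets) + [f"Novel{i + 1:03d}" for i in range(max(3, len(targets) // 20))]

    # mild rank-skew on target choice: real interaction databases have hub
    # targets, which gives the node-strength ranking non-trivial structure
    tgt_w = 1.0 / np.power(np.arange(1, len(tgt_vocab) + 1), 0.7)
    tgt_w /= tgt_w.sum()

    sizes = dict(zip(("validated", "predicted_score", "predicted_mirsvr"), config.db_sizes))
    tables, truth_rows = {}, []
    for source, size in sizes.items():
        mi = rng.choice(len(mir_vocab), size=size) if size else np.array([], int)
        ti = rng.choice(len(tgt_vocab), size=size, p=tgt_w) if size else np.array([], int)
        df = pd.DataFrame(
            {
                "mir_id": [mir_vocab[i] for i in mi],
                "target_id": [tgt_vocab[i] for i in ti],
                "source": source,
            }
        )
        if source == "validated":
            df["score"] = np.nan
            kept = np.ones(size, bool)
        elif source == "predicted_score":
            df["score"] = rng.uniform(0.0, 100.0, size=size)
            kept = df["score"].to_numpy() > 80.0
        else:
            df["score"] = rng.uniform(-2.5, 0.0, size=size)
            kept = df["score"].to_numpy() < -1.2
        tables[source] = df
        t = df.copy()
        t["planted_kept"] = kept
        truth_rows.append(t)
    truth = pd.concat(truth_rows, ignore_index=True) if truth_rows else pd.DataFrame()
    return tables, truth


_ALIAS_MODES = ("drop_ensembl", "drop_to_ncbi", "symbol_case", "description_only")


def simulate_mito_annotation(
    config: SimulationConfig, targets: list[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mitochondrial annotation table with identifier aliasing.

    Each gene row carries Ensembl/RGD/NCBI ids, symbol and description, an
    IMPI-style score in [0, 1], a GO-mitochondrial flag and an IMPI class.
    Planted mitochondrial genes satisfy (GO flag or score > 0.7); planted
    non-mitochondrial genes satisfy neither. ``alias_rate`` of rows have
    identifier columns blanked or case-mutated to exercise the downstream
    reconciliation cascade. Returns ``(annotation, truth)``.
    """
    rng = _rng(config.seed, "mito")
    if targets is None:
        targets = gene_symbols(config.n_targets)
    n = len(targets)
    mito = np.zeros(n, bool)
    mito[: int(round(config.mito_fraction * n))] = True
    rng.shuffle(mito)

    rows = []
    for i, sym in enumerate(targets):
        if mito[i]:
            go = bool(rng.random() < 0.7)
            impi = rng.uniform(0.3, 1.0) if go else rng.uniform(0.75, 1.0)
            klass = "known" if (impi > 0.85 or go) else "predicted"
        else:
            go = False
            impi = rng.uniform(0.0, 0.65)
            klass = "predicted" if rng.random() < 0.5 else "other"
        rows.append(
            {
                "ensembl_id": f"ENSRNOG{i + 1:011d}",
                "rgd_id": f"RGD:{1000000 + i + 1}",
                "ncbi_id": str(100000 + i + 1),
                "symbol": sym,
                "description": f"{sym.lower()} mitochondrion-study protein {i + 1}",
                "impi_score": round(float(impi), 4),
                "go_mito": go,
                "impi_class": klass,
            }
        )
    annot = pd.DataFrame(rows)

    n_alias = int(round(config.alias_rate * n))
    alias_idx = rng.choice(n, size=n_alias, replace=False) if n_alias else np.array([], int)
    alias_mode = np.array(["none"] * n, object)
    # expected cascade level when the row is queried by gene symbol, the
    # identifier form the interaction tables carry
    symbol_query_level = np.array(["symbol"] * n, object)
    for j, i in enumerate(alias_idx):
        mode = _ALIAS_MODES[j % len(_ALIAS_MODES)]  # deterministic mutation cycle
        alias_mode[i] = mode
        if mode == "drop_ensembl":
            annot.loc[i, "ensembl_id"] = ""
        elif mode == "drop_to_ncbi":
            annot.loc[i, ["ensembl_id", "rgd_id"]] = ""
        elif mode == "symbol_case":
            annot.loc[i, ["ensembl_id", "rgd_id", "ncbi_id"]] = ""
            annot.loc[i, "symbol"] = str(annot.loc[i, "symbol"]).upper()
        else:
            annot.loc[i, ["ensembl_id", "rgd_id", "ncbi_id", "symbol"]] = ""
            symbol_query_level[i] = "unmatched"

    truth = pd.DataFrame(
        {
            "target_id": targets,
            "mito": mito,
            "alias_mode": alias_mode,
            "symbol_query_level": symbol_query_level,
            "ensembl_id": [f"ENSRNOG{i + 1:011d}" for i in range(n)],
            "description": annot["description"].tolist(),
        }
    )
    return annot, truth


def write_study(config: SimulationConfig, outdir: str | Path) -> dict[str, str]:
    """Generate every pipeline input and write it under ``outdir``.

    Writes counts TSV, sample-annotation CSV, qPCR Ct TSV, the three
    interaction TSVs, the annotation TSV and a JSON truth bundle. Returns
    a manifest of written paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    animals, animal_truth = simulate_troponin(config)
    counts, count_truth = simulate_mir_counts(config)
    ct, fold_truth, qpcr_groups = simulate_qpcr(config)
    dbs, db_truth = simulate_interaction_dbs(config)
    annot, mito_truth = simulate_mito_annotation(config)

    def _write(df: pd.DataFrame, name: str, sep: str = "\t", index: bool = False) -> None:
        p = outdir / name
        df.to_csv(p, sep=sep, index=index)
        paths[name] = str(p)

    _write(animals, "samples.csv", sep=",")
    _write(counts.reset_index().rename(columns={"index": "feature_id"}), "counts.tsv")
    _write(ct.reset_index(), "qpcr_ct.tsv")
    _write(qpcr_groups.rename_axis("sample_id").reset_index(), "qpcr_samples.csv", sep=",")
    _write(dbs["validated"], "interactions_validated.tsv")
    _write(dbs["predicted_score"], "interactions_score.tsv")
    _write(dbs["predicted_mirsvr"], "interactions_mirsvr.tsv")
    _write(annot, "mito_annotation.tsv")

    truth = {
        "config": {k: v for k, v in asdict(config).items() if k != "tni_params"},
        "tni_params": {k: list(v) for k, v in config.tni_params.items()},
        "animals": animal_truth.to_dict(orient="list"),
        "mir_truth": count_truth.reset_index().to_dict(orient="list"),
        "lib_sizes": count_truth.attrs.get("lib_sizes", {}),
        "qpcr_folds": fold_truth.to_dict(orient="index"),
        "mito_truth": mito_truth.to_dict(orient="list"),
        "interactions_planted_kept": db_truth["planted_kept"].astype(bool).tolist()
        if len(db_truth)
        else [],
    }
    truth_path = outdir / "truth.json"
    truth_path.write_text(json.dumps(truth, default=float))
    paths["truth.json"] = str(truth_path)
    return paths
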