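"""Responder / non-responder stratification from plasma troponin I.

Post-conditioned animals split into two phenotypes: responders with very
low plasma TnI (infarct protected, TnI near the pre-conditioned arm) and
non-responders whose TnI is indistinguishable from untreated
ischaemia/reperfusion. The study defines no numeric cut, only the observed
bimodality, so two declared conventions are provided:

``mixture``
    a two-component Gaussian mixture on log TnI, assignment by posterior,
    with a degeneracy guard that falls back to the threshold rule;
``threshold``
    responder iff log TnI is below the midpoint of the median log TnI of
    the IPC and I/R reference arms (the geometric midpoint of the two
    reference medians on the original scale).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

RESPONDER = "responder"
NON_RESPONDER = "non_responder"


def _as_positive_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError(f"{name} is empty")
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
        raise ValueError(f"{name} must contain finite positive concentrations")
    return arr


@dataclass
class StratificationResults:
    """Labels and diagnostics from a responder split.

    Attributes
    ----------
    labels : per-animal label, ``responder`` or ``non_responder``
    posterior : responder-component posterior probability (mixture method;
        degenerate/threshold fits report 0/1 indicators)
    method : method actually used (``mixture`` or ``threshold``)
    threshold : TnI concentration (ng/mL) separating the classes; for the
        mixture method this is the posterior-0.5 crossing when it exists,
        otherwise the geometric midpoint of the component means
    degenerate : True when the mixture collapsed and the fallback fired
    params : fitted mixture parameters (log-scale means, sds, weights)
    """

    labels: pd.Series
    posterior: pd.Series
    method: str
    threshold: float
    degenerate: bool = False
    params: dict = field(default_factory=dict)

    @property
    def n_responders(self) -> int:
        return int((self.labels == RESPONDER).sum())

    @property
    def n_non_responders(self) -> int:
        return int((self.labels == NON_RESPONDER).sum())

    def summary(self) -> str:
        lines = [
            "Responder stratification",
            f"  method      : {self.method}" + ("  [degenerate fallback]" if self.degenerate else ""),
            f"  threshold   : {self.threshold:.4g} ng/mL",
            f"  responders  : {self.n_responders}",
            f"  non-resp.   : {self.n_non_responders}",
        ]
        if self.params:
            mus = self.params.get("log_means")
            sds = self.params.get("log_sds")
            if mus is not None:
                lines.append(
                    "  components  : "
                    + ", ".join(f"exp(mu)={np.exp(m):.3g} (sd_log={s:.2f})" for m, s in zip(mus, sds))
                )
        return "\n".join(lines)


class TroponinMixture:
    """Two-component Gaussian mixture model on log TnI.

    Parameters
    ----------
    ipoc_tni : TnI concentrations (ng/mL) of the post-conditioned arm.
    reference_ir, reference_ipc : TnI of the I/R and IPC reference arms;
        required for the threshold method and the degenerate fallback.
    min_separation : degeneracy guard — if the fitted component means are
        closer than ``min_separation`` pooled component SDs, the mixture is
        declared degenerate and the threshold fallback fires.
    """

    def __init__(self, ipoc_tni, reference_ir=None, reference_ipc=None, min_separation: float = 0.5):
        self.ipoc_tni = _as_positive_array(ipoc_tni, "ipoc_tni")
        self.reference_ir = None if reference_ir is None else _as_positive_array(reference_ir, "reference_ir")
        self.reference_ipc = None if reference_ipc is None else _as_positive_array(reference_ipc, "reference_ipc")
        self.min_separation = float(min_separation)

    # -- threshold convention -------------------------------------------------
    def _threshold_fit(self, degenerate: bool = False) -> StratificationResults:
        if self.reference_ir is None or self.reference_ipc is None:
            raise ValueError("threshold method needs both I/R and IPC reference arms")
        log_t = np.log(self.ipoc_tni)
        cut = 0.5 * (np.median(np.log(self.reference_ipc)) + np.median(np.log(self.reference_ir)))
        is_resp = log_t < cut
        labels = pd.Series(np.where(is_resp, RESPONDER, NON_RESPONDER))
        return StratificationResults(
            labels=labels,
            posterior=pd.Series(is_resp.astype(float)),
            method="threshold",
            threshold=float(np.exp(cut)),
            degenerate=degenerate,
        )

    # -- mixture convention ---------------------------------------------------
    def fit(self, method: str = "mixture") -> StratificationResults:
        if method == "threshold":
            return self._threshold_fit()
        if method != "mixture":
            raise ValueError(f"unknown method {method!r}")
        x = np.log(self.ipoc_tni)
        if x.size < 4:
            raise ValueError("mixture method needs at least 4 IPoC animals")
        if np.ptp(x) == 0.0:  # all identical: nothing to split
            return self._threshold_fit(degenerate=True)

        # deterministic initialization at the 25th/75th percentiles
        q25, q75 = np.percentile(x, [25.0, 75.0])
        var0 = max(np.var(x), 1e-6)
        gm = GaussianMixture(
            n_components=2,
            covariance_type="full",
            means_init=np.array([[q25], [q75]]),
            weights_init=np.array([0.5, 0.5]),
            precisions_init=np.array([[[1.0 / var0]], [[1.0 / var0]]]),
            max_iter=500,
            n_init=1,
            random_state=0,
        )
        gm.fit(x[:, None])
        mus = gm.means_.ravel()
        sds = np.sqrt(gm.covariances_.ravel())
        pooled_sd = float(np.sqrt(np.mean(sds**2)))

        degenerate = (not gm.converged_) or abs(mus[1] - mus[0]) < self.min_separation * pooled_sd
        if degenerate:
            return self._threshold_fit(degenerate=True)

        resp_comp = int(np.argmin(mus))  # lower-mean component = responder
        post = gm.predict_proba(x[:, None])[:, resp_comp]
        is_resp = post >= 0.5  # tie assigned responder
        labels = pd.Series(np.where(is_resp, RESPONDER, NON_RESPONDER))

        threshold = _posterior_crossing(gm, resp_comp, x)
        return StratificationResults(
            labels=labels,
            posterior=pd.Series(post),
            method="mixture",
            threshold=threshold,
            degenerate=False,
            params={
                "log_means": mus.tolist(),
                "log_sds": sds.tolist(),
                "weights": gm.weights_.ravel().tolist(),
            },
        )


def _posterior_crossing(gm: GaussianMixture, resp_comp: int, x: np.ndarray) -> float:
    """TnI value where the responder posterior crosses 0.5 (bisection
    between the component means; falls back to the mean midpoint)."""
    mus = gm.means_.ravel()
    lo, hi = sorted(mus)
    f = lambda v: gm.predict_proba(np.array([[v]]))[0, resp_comp] - 0.5
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        return float(np.exp(0.5 * (lo + hi)))
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if f(lo) * f(mid) <= 0:
            hi = mid
        else:
            lo = mid
    return float(np.exp(0.5 * (lo + hi)))


def split_responders(
    ipoc_tni,
    reference_ir=None,
    reference_ipc=None,
    method: str = "mixture",
    min_separation: float = 0.5,
) -> StratificationResults:
    """Split the post-conditioned arm into responders and non-responders.

    Functional facade over :class:`TroponinMixture`; see that class for the
    conventions. Labels are exhaustive and exclusive over the IPoC arm.
    """
    model = TroponinMixture(ipoc_tni, reference_ir, reference_ipc, min_separation=min_separation)
    return model.fit(method=method)


def summarize_groups(records: pd.DataFrame, labels: StratificationResults | None = None) -> pd.DataFrame:
    """Per-group mean / sample-SD / n table over every numeric field.

    ``records`` needs ``arm`` (Sham/IR/IPC/IPoC); when ``labels`` is given
    the IPoC arm is reported as IPoC_R / IPoC_NR. Groups with n = 1 report
    SD as NaN (undefined), never zero; all-missing fields are omitted.
    """
    if records.empty:
        raise ValueError("no animal records")
    df = records.copy()
    group = df["arm"].astype(str).copy()
    if labels is not None:
        ipoc_mask = group == "IPoC"
        lab = labels.labels.to_numpy()
        if ipoc_mask.sum() != len(lab):
            raise ValueError("label count does not match IPoC arm size")
        group.loc[ipoc_mask] = np.where(lab == RESPONDER, "IPoC_R", "IPoC_NR")
    df["_group"] = group.to_numpy()

    numeric = df.select_dtypes(include=[np.number]).columns
    numeric = [c for c in numeric if df[c].notna().any()]
    agg = df.groupby("_group")[list(numeric)].agg(["mean", lambda s: s.std(ddof=1), "count"])
    agg.columns = [
        (f, {"mean": "mean", "count": "n"}.get(stat, "sd")) for f, stat in agg.columns
    ]
    agg.columns = pd.MultiIndex.from_tuples(agg.columns)
    agg.index.name = "group"
    order = [g for g in ("Sham", "IR", "IPC", "IPoC_R", "IPoC_NR", "IPoC") if g in agg.index]
    return agg.loc[order]


def relative_change(baseline_mean: float, treated_mean: float) -> float:
    """Percent change of a treated mean relative to baseline, one decimal.

    ``100 * (treated - baseline) / baseline``; e.g. cell shortening rising
    from 10.30 to 11.16 percent of diastolic length is an 8.3% increase.
    """
    if not np.isfinite(baseline_mean) or baseline_mean <= 0:
        raise ValueError("baseline mean must be positive")
    return round(100.0 * (float(treated_mean) - float(baseline_mean)) / float(baseline_mean), 1)
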