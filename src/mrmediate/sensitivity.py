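"""Heterogeneity, pleiotropy, outlier and influence diagnostics.

Covers Cochran's Q, the MR-Egger intercept test, an MR-PRESSO-style
global/outlier/distortion analysis, leave-one-out IVW, and deterministic
data tables backing scatter, funnel, forest and leave-one-out plots
(rendering to image files is a thin optional layer over the tables).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import MRResult, MRBattery, _arrays, egger, ivw, \
    wald_ratio_arrays
from .sumstats import HarmonizedSet

logger = logging.getLogger(__name__)


def cochran_q(h, theta: float | None = None) -> tuple[float, int, float]:
    """Cochran's Q about ``theta`` (default: fixed-effects IVW estimate).

    Q = Σ_j w_j (r_j − θ)² over Wald ratios r_j with w_j = 1/se_ratio_j²;
    df = k − 1; upper-tail chi-square p.  Q is minimized exactly at the
    fixed-effects IVW estimate.
    """
    bx, sx, by, sy = _arrays(h)
    if len(bx) < 2:
        raise ValueError("Cochran's Q requires >=2 SNPs")
    ratios, rse = wald_ratio_arrays(bx, sx, by, sy)
    w = 1.0 / rse**2
    if theta is None:
        theta = float(np.sum(w * ratios) / np.sum(w))
    q = float(np.sum(w * (ratios - theta) ** 2))
    df = len(bx) - 1
    return q, df, float(stats.chi2.sf(q, df))


def _loo_ivw_slopes(bx, by, w) -> np.ndarray:
    """Leave-one-out fixed-effect IVW slope for every SNP, O(k)."""
    s1 = np.sum(w * bx * by)
    s2 = np.sum(w * bx**2)
    return (s1 - w * bx * by) / (s2 - w * bx**2)


@dataclass
class PressoResult:
    """MR-PRESSO-style global, outlier and distortion diagnostics."""

    global_rss_obs: float
    global_pval: float
    outlier_indices: list[int]
    outlier_rsids: list[str]
    outlier_pvals: list[float]
    distortion_pval: float | None
    corrected_estimate: MRResult | None
    n_sim: int

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.corrected_estimate is not None:
            d["corrected_estimate"] = self.corrected_estimate.to_dict()
        return d


def mr_presso(h, n_sim: int = 1000, sig: float = 0.05,
              seed: int | None = None) -> PressoResult:
    """Residual-sum-of-squares outlier analysis.

    Global test: RSS_obs = Σ_j w_j (βY_j − θ_{−j} βX_j)² with θ_{−j} the
    leave-one-out fixed-effect IVW slope and w_j = 1/sy_j²; the null
    distribution comes from ``n_sim`` parametric draws βX*_j ~ N(βX_j, sx_j),
    βY*_j ~ N(θ_{−j} βX_j, sy_j), recomputing the leave-one-out slopes within
    each draw.  Outlier test: each observed weighted residual against its
    simulated distribution, Bonferroni-corrected.  Distortion test: the
    outlier-free IVW estimate against estimates from removing equally many
    random SNPs.  Empirical p-values use the add-one rule (1+#)/(n_sim+1).
    """
    bx, sx, by, sy = _arrays(h)
    k = len(bx)
    if k < 4:
        raise ValueError("MR-PRESSO requires >=4 SNPs")
    if n_sim < 100:
        warnings.warn("mr_presso: n_sim < 100 gives coarse empirical p-values")
    rng = np.random.default_rng(seed)
    w = 1.0 / sy**2

    theta_loo = _loo_ivw_slopes(bx, by, w)
    resid_obs = w * (by - theta_loo * bx) ** 2
    rss_obs = float(resid_obs.sum())

    # parametric null draws (vectorized over simulations)
    bx_sim = rng.normal(bx, sx, size=(n_sim, k))
    by_sim = rng.normal(theta_loo * bx, sy, size=(n_sim, k))
    s1 = np.sum(w * bx_sim * by_sim, axis=1, keepdims=True)
    s2 = np.sum(w * bx_sim**2, axis=1, keepdims=True)
    theta_loo_sim = (s1 - w * bx_sim * by_sim) / (s2 - w * bx_sim**2)
    resid_sim = w * (by_sim - theta_loo_sim * bx_sim) ** 2
    rss_sim = resid_sim.sum(axis=1)

    global_pval = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))

    per_snp_p = (1 + np.sum(resid_sim >= resid_obs[None, :], axis=0)) / (n_sim + 1)
    corrected = np.minimum(per_snp_p * k, 1.0)
    outliers = np.flatnonzero(corrected < sig)

    rsids = (list(h.kept_table["rsid"]) if isinstance(h, HarmonizedSet)
             else list(h["rsid"]) if "rsid" in getattr(h, "columns", [])
             else [str(i) for i in range(k)])

    distortion_pval = None
    corrected_estimate = None
    if outliers.size and outliers.size < k - 1:
        mask = np.ones(k, bool)
        mask[outliers] = False
        sub = pd.DataFrame({"beta_exposure": bx[mask], "se_exposure": sx[mask],
                            "beta_outcome": by[mask], "se_outcome": sy[mask]})
        corrected_estimate = ivw(sub)
        # distortion: same-size random removals
        theta_rand = np.empty(n_sim)
        n_out = outliers.size
        for s in range(n_sim):
            drop = rng.choice(k, size=n_out, replace=False)
            m = np.ones(k, bool)
            m[drop] = False
            theta_rand[s] = (np.sum(w[m] * bx[m] * by[m])
                             / np.sum(w[m] * bx[m] ** 2))
        r = (1 + np.sum(theta_rand <= corrected_estimate.beta)) / (n_sim + 1)
        distortion_pval = float(2 * min(r, 1 - r))

    return PressoResult(
        global_rss_obs=rss_obs, global_pval=global_pval,
        outlier_indices=[int(i) for i in outliers],
        outlier_rsids=[rsids[i] for i in outliers],
        outlier_pvals=[float(corrected[i]) for i in outliers],
        distortion_pval=distortion_pval,
        corrected_estimate=corrected_estimate, n_sim=n_sim)


def leave_one_out(h, model: str = "random") -> pd.DataFrame:
    """IVW re-estimated with each SNP excluded in turn (one row per SNP)."""
    bx, sx, by, sy = _arrays(h)
    k = len(bx)
    if k < 3:
        raise ValueError("leave-one-out requires >=3 SNPs")
    rsids = (list(h.kept_table["rsid"]) if isinstance(h, HarmonizedSet)
             else list(h["rsid"]) if "rsid" in getattr(h, "columns", [])
             else [str(i) for i in range(k)])
    rows = []
    for j in range(k):
        m = np.ones(k, bool)
        m[j] = False
        sub = pd.DataFrame({"beta_exposure": bx[m], "se_exposure": sx[m],
                            "beta_outcome": by[m], "se_outcome": sy[m]})
        res = ivw(sub, model=model)
        rows.append({"excluded_rsid": rsids[j], "beta": res.beta,
                     "se": res.se, "pval": res.pval})
    return pd.DataFrame(rows)


@dataclass
class SensitivityReport:
    """Bundle of all instrument diagnostics for one exposure/outcome pair."""

    q_ivw: float
    q_df: int
    q_pval: float
    egger_intercept: float
    egger_intercept_se: float
    egger_intercept_pval: float
    presso: PressoResult | None
    loo: pd.DataFrame
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "q_ivw": self.q_ivw, "q_df": self.q_df, "q_pval": self.q_pval,
            "egger_intercept": self.egger_intercept,
            "egger_intercept_se": self.egger_intercept_se,
            "egger_intercept_pval": self.egger_intercept_pval,
            "presso": None if self.presso is None else self.presso.to_dict(),
            "loo": self.loo.to_dict(orient="records"),
            "seed": self.seed,
        }

    def write_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


def sensitivity_report(h, n_sim: int = 1000, sig: float = 0.05,
                       seed: int | None = None) -> SensitivityReport:
    """Run the full diagnostic suite on a harmonized set."""
    q, df, qp = cochran_q(h)
    eg = egger(h)
    presso = None
    bx, *_ = _arrays(h)
    if len(bx) >= 4:
        presso = mr_presso(h, n_sim=n_sim, sig=sig, seed=seed)
    else:
        logger.info("sensitivity_report: <4 SNPs, MR-PRESSO skipped")
    loo = leave_one_out(h)
    return SensitivityReport(
        q_ivw=q, q_df=df, q_pval=qp,
        egger_intercept=eg.extra["intercept"],
        egger_intercept_se=eg.extra["intercept_se"],
        egger_intercept_pval=eg.extra["intercept_p"],
        presso=presso, loo=loo, seed=seed)


def plot_exports(h, battery: MRBattery,
                 report: SensitivityReport | None = None
                 ) -> dict[str, pd.DataFrame]:
    """Deterministic data tables behind the standard MR plots.

    Returns ``scatter`` (per-SNP effect pairs + per-method fit lines),
    ``funnel`` (Wald ratio vs precision + method verticals), ``forest``
    (per-SNP ratios with CIs plus combined method rows) and ``loo``.
    """
    bx, sx, by, sy = _arrays(h)
    ratios, rse = wald_ratio_arrays(bx, sx, by, sy)
    rsids = (list(h.kept_table["rsid"]) if isinstance(h, HarmonizedSet)
             else [str(i) for i in range(len(bx))])

    scatter_points = pd.DataFrame({
        "kind": "point", "rsid": rsids, "beta_exposure": bx,
        "se_exposure": sx, "beta_outcome": by, "se_outcome": sy,
        "slope": np.nan, "intercept": np.nan, "method": ""})
    lines = []
    for name, res in battery.results.items():
        inter = res.extra.get("intercept", 0.0)
        lines.append({"kind": "line", "rsid": "", "beta_exposure": np.nan,
                      "se_exposure": np.nan, "beta_outcome": np.nan,
                      "se_outcome": np.nan, "slope": res.beta,
                      "intercept": inter, "method": name})
    scatter = pd.concat([scatter_points, pd.DataFrame(lines)],
                        ignore_index=True)

    funnel_points = pd.DataFrame({
        "kind": "point", "rsid": rsids, "ratio": ratios,
        "precision": 1.0 / rse, "method": ""})
    funnel_lines = pd.DataFrame(
        [{"kind": "line", "rsid": "", "ratio": res.beta, "precision": np.nan,
          "method": name} for name, res in battery.results.items()])
    funnel = pd.concat([funnel_points, funnel_lines], ignore_index=True)

    forest_rows = pd.DataFrame({
        "label": rsids, "kind": "snp", "beta": ratios,
        "ci_low": ratios - 1.96 * rse, "ci_high": ratios + 1.96 * rse})
    combined = pd.DataFrame(
        [{"label": name, "kind": "combined", "beta": res.beta,
          "ci_low": res.beta - 1.96 * res.se,
          "ci_high": res.beta + 1.96 * res.se}
         for name, res in battery.results.items()])
    forest = pd.concat([forest_rows, combined], ignore_index=True)

    loo = report.loo.copy() if report is not None else leave_one_out(h)
    return {"scatter": scatter, "funnel": funnel, "forest": forest, "loo": loo}


def render_plots(tables: dict[str, pd.DataFrame], outdir: str | Path,
                 prefix: str = "mr", fmt: str = "png") -> list[Path]:
    """Render the exported plot tables to image files (optional layer)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []

    sc = tables["scatter"]
    pts = sc[sc["kind"] == "point"]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.errorbar(pts["beta_exposure"], pts["beta_outcome"],
                xerr=1.96 * pts["se_exposure"], yerr=1.96 * pts["se_outcome"],
                fmt="o", ms=3, lw=0.7, alpha=0.7)
    xs = np.linspace(0, pts["beta_exposure"].max() * 1.05, 10)
    for _, ln in sc[sc["kind"] == "line"].iterrows():
        ax.plot(xs, ln["intercept"] + ln["slope"] * xs, label=ln["method"])
    ax.set_xlabel("SNP effect on exposure")
    ax.set_ylabel("SNP effect on outcome")
    ax.legend(fontsize=7)
    p = outdir / f"{prefix}_scatter.{fmt}"
    fig.savefig(p, dpi=150, bbox_inches="tight")
    plt.close(fig)
    paths.append(p)

    fn = tables["funnel"]
    pts = fn[fn["kind"] == "point"]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(pts["ratio"], pts["precision"], "o", ms=3)
    for _, ln in fn[fn["kind"] == "line"].iterrows():
        ax.axvline(ln["ratio"], lw=0.8, label=ln["method"])
    ax.set_xlabel("Wald ratio")
    ax.set_ylabel("1 / SE of ratio")
    ax.legend(fontsize=7)
    p = outdir / f"{prefix}_funnel.{fmt}"
    fig.savefig(p, dpi=150, bbox_inches="tight")
    plt.close(fig)
    paths.append(p)

    fo = tables["forest"]
    fig, ax = plt.subplots(figsize=(5, 0.25 * len(fo) + 1))
    ys = np.arange(len(fo))[::-1]
    ax.hlines(ys, fo["ci_low"], fo["ci_high"], lw=1)
    ax.plot(fo["beta"], ys, "s", ms=3)
    ax.axvline(0, color="grey", lw=0.8)
    ax.set_yticks(ys)
    ax.set_yticklabels(fo["label"], fontsize=6)
    ax.set_xlabel("causal estimate")
    p = outdir / f"{prefix}_forest.{fmt}"
    fig.savefig(p, dpi=150, bbox_inches="tight")
    plt.close(fig)
    paths.append(p)

    lo = tables["loo"]
    fig, ax = plt.subplots(figsize=(5, 0.25 * len(lo) + 1))
    ys = np.arange(len(lo))[::-1]
    ax.hlines(ys, lo["beta"] - 1.96 * lo["se"], lo["beta"] + 1.96 * lo["se"],
              lw=1)
    ax.plot(lo["beta"], ys, "s", ms=3)
    ax.axvline(0, color="grey", lw=0.8)
    ax.set_yticks(ys)
    ax.set_yticklabels(lo["excluded_rsid"], fontsize=6)
    ax.set_xlabel("IVW estimate excluding SNP")
    p = outdir / f"{prefix}_loo.{fmt}"
    fig.savefig(p, dpi=150, bbox_inches="tight")
    plt.close(fig)
    paths.append(p)
    return paths
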