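"""Two-sample MR estimators operating on a harmonized SNP set.

Implements the standard summary-data battery — inverse-variance weighted
(IVW, the primary estimator), MR-Egger regression, the weighted median, and
the simple/weighted mode estimators — plus the per-SNP Wald ratio they all
build on.  The Bayesian weighted estimator lives in :mod:`mrmediate.bwmr`.

All estimators consume per-SNP effect pairs (β_exposure, β_outcome) with
their standard errors.  Under the instrumental-variable assumptions each
Wald ratio β_outcome/β_exposure estimates the same causal effect; the
estimators differ in how they pool the ratios and which violations they
tolerate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .sumstats import HarmonizedSet

logger = logging.getLogger(__name__)

METHODS_FIVE = ("IVW", "Egger", "WeightedMedian", "WeightedMode", "SimpleMode")


@dataclass
class MRResult:
    """One estimator's causal estimate on the log-odds (or SD) scale."""

    method: str
    beta: float
    se: float
    pval: float
    n_snp: int
    extra: dict[str, Any] = field(default_factory=dict)

    @property
    def or_point(self) -> float:
        return float(np.exp(self.beta))

    @property
    def ci_low(self) -> float:
        return float(np.exp(self.beta - 1.96 * self.se))

    @property
    def ci_high(self) -> float:
        return float(np.exp(self.beta + 1.96 * self.se))

    def to_dict(self) -> dict[str, Any]:
        d = {"method": self.method, "nsnp": self.n_snp, "beta": self.beta,
             "se": self.se, "pval": self.pval, "or": self.or_point,
             "ci_low": self.ci_low, "ci_high": self.ci_high}
        for k, v in self.extra.items():
            d[f"extra_{k}"] = v
        return d


def _arrays(h: HarmonizedSet | pd.DataFrame
            ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(h, HarmonizedSet):
        return h.arrays()
    return (h["beta_exposure"].to_numpy(float),
            h["se_exposure"].to_numpy(float),
            h["beta_outcome"].to_numpy(float),
            h["se_outcome"].to_numpy(float))


def _norm_p(z: float) -> float:
    return float(2 * stats.norm.sf(abs(z)))


def wald_ratio_arrays(bx, sx, by, sy, second_order: bool = False
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP Wald ratios and their SEs.

    First order: se = se_outcome/|β_exposure|.  The second-order form adds
    the exposure-uncertainty term β_outcome²·se_exposure²/β_exposure⁴.
    """
    bx = np.asarray(bx, float)
    if np.any(bx == 0):
        raise ValueError("Wald ratio undefined for beta_exposure = 0")
    ratio = np.asarray(by, float) / bx
    var = np.asarray(sy, float) ** 2 / bx**2
    if second_order:
        var = var + np.asarray(by, float) ** 2 * np.asarray(sx, float) ** 2 / bx**4
    return ratio, np.sqrt(var)


def wald_ratio(entry: pd.Series | dict, second_order: bool = False) -> MRResult:
    """Single-SNP causal estimate β_outcome/β_exposure."""
    bx, sx = float(entry["beta_exposure"]), float(entry["se_exposure"])
    by, sy = float(entry["beta_outcome"]), float(entry["se_outcome"])
    r, s = wald_ratio_arrays([bx], [sx], [by], [sy], second_order)
    beta, se = float(r[0]), float(s[0])
    return MRResult("WaldRatio", beta, se, _norm_p(beta / se), 1)


def _ivw_fit(bx, by, w) -> tuple[float, float, float]:
    """Weighted regression of by on bx through the origin.

    Returns (slope, fixed-effect se, Cochran's Q about the slope).
    """
    s2 = np.sum(w * bx**2)
    beta = np.sum(w * bx * by) / s2
    se_fixed = np.sqrt(1.0 / s2)
    q = float(np.sum(w * (by - beta * bx) ** 2))
    return float(beta), float(se_fixed), q


def ivw(h: HarmonizedSet | pd.DataFrame, model: str = "random") -> MRResult:
    """Inverse-variance weighted estimate (weights 1/se_outcome²).

    ``model='random'`` (default) uses multiplicative random effects: the
    fixed-effect SE is scaled by max(1, sqrt(Q/(k−1))) so excess
    heterogeneity widens the interval but never narrows it.  With fewer than
    two SNPs the estimate downgrades to the single-SNP Wald ratio.
    """
    if model not in ("fixed", "random"):
        raise ValueError("model must be 'fixed' or 'random'")
    bx, sx, by, sy = _arrays(h)
    k = len(bx)
    if k == 0:
        raise ValueError("IVW requires at least one SNP")
    if k < 2:
        logger.info("ivw: single SNP, downgrading to Wald ratio")
        r, s = wald_ratio_arrays(bx, sx, by, sy)
        res = MRResult("IVW", float(r[0]), float(s[0]),
                       _norm_p(r[0] / s[0]), 1)
        res.extra["downgraded_to"] = "WaldRatio"
        return res
    w = 1.0 / sy**2
    beta, se, q = _ivw_fit(bx, by, w)
    scale = 1.0
    if model == "random":
        scale = max(1.0, np.sqrt(q / (k - 1)))
    se *= scale
    return MRResult("IVW", beta, se, _norm_p(beta / se), k,
                    extra={"model": model, "q": q, "se_scale": scale})


def egger(h: HarmonizedSet | pd.DataFrame) -> MRResult:
    """MR-Egger regression: weighted fit of β_outcome on β_exposure with
    an intercept capturing average directional pleiotropy.

    SNPs are re-oriented so every β_exposure is non-negative before fitting
    (the intercept is only interpretable on that frame).  Slope and intercept
    p-values use a t reference with k−2 degrees of freedom.
    """
    bx, sx, by, sy = _arrays(h)
    k = len(bx)
    if k < 3:
        raise ValueError("Egger requires >=3 instruments")
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    bx, by = bx * flip, by * flip
    if np.ptp(bx) < 1e-12:
        raise ValueError("degenerate design: all beta_exposure equal, "
                         "slope collinear with intercept")
    w = 1.0 / sy**2
    X = sm.add_constant(bx)
    fit = sm.WLS(by, X, weights=w).fit()
    # classical Egger inference: multiplicative over-dispersion bounded below at 1
    sigma = max(1.0, np.sqrt(fit.scale))
    bse = fit.bse / np.sqrt(fit.scale) * sigma
    slope, slope_se = float(fit.params[1]), float(bse[1])
    inter, inter_se = float(fit.params[0]), float(bse[0])
    tdist = stats.t(df=k - 2)
    slope_p = float(2 * tdist.sf(abs(slope / slope_se)))
    inter_p = float(2 * tdist.sf(abs(inter / inter_se)))
    return MRResult("Egger", slope, slope_se, slope_p, k, extra={
        "intercept": inter, "intercept_se": inter_se, "intercept_p": inter_p})


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios)
    r, w = ratios[order], weights[order]
    w = w / w.sum()
    cum = np.cumsum(w) - 0.5 * w          # midpoint cumulative weight
    below = cum < 0.5
    if not below.any():
        return float(r[0])
    if below.all():
        return float(r[-1])
    j = int(np.argmax(~below))            # first index with cum >= 0.5
    # linear interpolation between the bracketing ratios
    return float(r[j - 1] + (r[j] - r[j - 1])
                 * (0.5 - cum[j - 1]) / (cum[j] - cum[j - 1]))


def _bootstrap_se(point_fn, bx, sx, by, sy, n_boot: int, seed) -> float:
    rng = np.random.default_rng(seed)
    ests = np.empty(n_boot)
    for b in range(n_boot):
        bxb = rng.normal(bx, sx)
        byb = rng.normal(by, sy)
        bxb[bxb == 0] = 1e-300
        ests[b] = point_fn(byb / bxb, bxb, byb)
    return float(np.std(ests, ddof=1))


def weighted_median(h: HarmonizedSet | pd.DataFrame, n_boot: int = 1000,
                    seed: int | None = None) -> MRResult:
    """Weighted-median estimator: consistent when valid instruments carry
    more than half the total weight.  SE via parametric bootstrap.
    """
    bx, sx, by, sy = _arrays(h)
    if len(bx) < 3:
        raise ValueError("weighted median requires >=3 SNPs")
    ratios, rse = wald_ratio_arrays(bx, sx, by, sy)
    weights = 1.0 / rse**2

    def point(r, bxb, byb):
        return _weighted_median_point(r, 1.0 / (sy / np.abs(bxb)) ** 2)

    beta = _weighted_median_point(ratios, weights)
    se = _bootstrap_se(point, bx, sx, by, sy, n_boot, seed)
    se = max(se, 1e-300)
    return MRResult("WeightedMedian", beta, se, _norm_p(beta / se), len(bx))


def _mode_bandwidth(ratios: np.ndarray, phi: float) -> float:
    """Modified Silverman rule on the ratio scale: 0.9·min(sd, 1.4826·MAD)·n^{-1/5}."""
    sd = np.std(ratios, ddof=1)
    mad = 1.4826 * np.median(np.abs(ratios - np.median(ratios)))
    s = min(sd, mad) if mad > 0 else sd
    if s <= 0:
        s = max(abs(np.mean(ratios)) * 1e-6, 1e-12)
    return float(phi * 0.9 * s * len(ratios) ** (-1 / 5))


def _mode_point(ratios: np.ndarray, weights: np.ndarray, bandwidth: float) -> float:
    grid = np.linspace(ratios.min() - 3 * bandwidth,
                       ratios.max() + 3 * bandwidth, 2048)
    wn = weights / weights.sum()
    z = (grid[None, :] - ratios[:, None]) / bandwidth
    dens = wn @ np.exp(-0.5 * z**2)
    return float(grid[int(np.argmax(dens))])


def mode_estimate(h: HarmonizedSet | pd.DataFrame, weighted: bool = True,
                  bandwidth_factor: float = 1.0, n_boot: int = 1000,
                  seed: int | None = None) -> MRResult:
    """Mode-based estimator: argmax of a normal-kernel density of the Wald
    ratios (inverse-variance weights when ``weighted``), consistent when the
    largest group of instruments shares the true ratio.  SE via parametric
    bootstrap.
    """
    bx, sx, by, sy = _arrays(h)
    if len(bx) < 3:
        raise ValueError("mode estimator requires >=3 SNPs")
    ratios, rse = wald_ratio_arrays(bx, sx, by, sy)
    bandwidth = _mode_bandwidth(ratios, bandwidth_factor)

    def wts(rse_b):
        return 1.0 / rse_b**2 if weighted else np.ones_like(rse_b)

    def point(r, bxb, byb):
        return _mode_point(r, wts(sy / np.abs(bxb)),
                           _mode_bandwidth(r, bandwidth_factor))

    beta = _mode_point(ratios, wts(rse), bandwidth)
    se = _bootstrap_se(point, bx, sx, by, sy, n_boot, seed)
    se = max(se, 1e-300)
    method = "WeightedMode" if weighted else "SimpleMode"
    return MRResult(method, beta, se, _norm_p(beta / se), len(bx),
                    extra={"bandwidth": bandwidth})


@dataclass
class MRBattery:
    """Results of the full estimator battery on one exposure/outcome pair."""

    results: dict[str, MRResult]
    errors: dict[str, str]
    direction_concordant: bool
    concordance_reason: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.to_dict() for r in self.results.values()])


def run_all_methods(h: HarmonizedSet | pd.DataFrame,
                    n_boot: int = 1000, seed: int | None = None,
                    ivw_model: str = "random",
                    include_bwmr: bool = False,
                    bwmr_kwargs: dict | None = None) -> MRBattery:
    """Run the five-method battery (optionally plus BWMR).

    ``direction_concordant`` is true iff all five point estimates share one
    sign; if any of the five methods cannot run the flag is false with
    reason "incomplete battery".  Near a true null the flag carries no
    validity claim (signs of noise-level estimates are arbitrary).
    """
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)]
    results: dict[str, MRResult] = {}
    errors: dict[str, str] = {}

    runners = {
        "IVW": lambda: ivw(h, model=ivw_model),
        "Egger": lambda: egger(h),
        "WeightedMedian": lambda: weighted_median(h, n_boot, seeds[0]),
        "WeightedMode": lambda: mode_estimate(h, True, 1.0, n_boot, seeds[1]),
        "SimpleMode": lambda: mode_estimate(h, False, 1.0, n_boot, seeds[2]),
    }
    for name, fn in runners.items():
        try:
            results[name] = fn()
        except ValueError as exc:
            errors[name] = str(exc)
    if include_bwmr:
        from .bwmr import bwmr
        try:
            results["BWMR"] = bwmr(h, seed=seeds[3], **(bwmr_kwargs or {}))
        except ValueError as exc:
            errors["BWMR"] = str(exc)

    five = [results.get(m) for m in METHODS_FIVE]
    if any(r is None for r in five):
        concordant, reason = False, "incomplete battery"
    else:
        signs = {np.sign(r.beta) for r in five}
        concordant = len(signs) == 1 and 0.0 not in signs
        reason = "" if concordant else "discordant signs"
    return MRBattery(results, errors, concordant, reason)
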