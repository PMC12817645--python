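"""Synthetic two-sample GWAS summary statistics with known causal structure.

Emulates the statistical shape of the real data sources behind a
lipidome → immune-phenotype → PCOS two-step MR study — a lipidomic exposure
GWAS of ~7,000 individuals, a flow-cytometry immune-trait GWAS of ~3,800,
and a large case/control outcome GWAS of ~255,000 — without requiring any
download.  Summary statistics are simulated directly (no individual-level
genotypes): for a standardized trait measured in N individuals the sampling
SE of a per-allele effect at minor allele frequency p is 1/sqrt(2·N·p(1−p)).

Causal structure, for exposure-instrument SNP j with true effect γ_j:

    exposure:  βX_j ~ N(γ_j, seX_j²)
    mediator:  true effect α_xm·γ_j (+ mediator-path pleiotropy if invalid)
    outcome:   true effect θ_direct·γ_j + β_my·(mediator true) + α_j

with horizontal pleiotropy α_j ~ N(μ, sd²) on an invalid fraction (μ = 0
balanced, μ > 0 directional; α independent of γ, so InSIDE holds).  The
mediator additionally carries its own instruments δ_j that do not touch the
exposure — without them the mediator→outcome leg cannot be estimated, since
exposure-driven SNPs proxy the direct path as correlated pleiotropy.  The
implied total effect is exactly θ_total = θ_direct + α_xm·β_my.

Realism knobs: palindromic allele pairs, allele-swapped rows (which
harmonization must undo), gross outcome outliers displaced in SE units,
block-diagonal LD, and a binary-outcome SE inflation factor approximating
the case/control design (default 2.8 ≈ 1/sqrt(φ(1−φ)) at case fraction
0.15).  Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .instruments import LDMatrix
from .sumstats import COLUMNS, write_sumstats

_NONPALINDROMIC = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                   ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]
_PALINDROMIC = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass(frozen=True)
class PleiotropyConfig:
    """Horizontal pleiotropy on the outcome (and mediator) path.

    ``mode``: none | balanced (mean 0) | directional (mean > 0).
    ``fraction_invalid`` of exposure instruments receive a pleiotropic
    effect drawn from N(mean, sd²).
    """

    mode: str = "none"
    sd: float = 0.0
    fraction_invalid: float = 0.0
    mean: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("none", "balanced", "directional"):
            raise ValueError(f"unknown pleiotropy mode {self.mode!r}")
        if self.sd < 0 or not (0 <= self.fraction_invalid <= 1):
            raise ValueError("invalid pleiotropy parameters")
        if self.mode == "directional" and self.mean <= 0:
            raise ValueError("directional pleiotropy requires mean > 0")
        if self.mode == "balanced" and self.mean != 0:
            raise ValueError("balanced pleiotropy requires mean = 0")


@dataclass(frozen=True)
class LDBlockConfig:
    """Block-diagonal LD among exposure instruments."""

    block_size: int = 1
    r2: float = 0.0

    def __post_init__(self) -> None:
        if self.block_size < 1 or not (0 <= self.r2 <= 1):
            raise ValueError("invalid LD block configuration")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated two-sample MR mediation dataset.

    Sample sizes default to the motivating cohorts (lipidomic exposure GWAS
    N=7,174; immune-trait mediator GWAS N=3,757; case/control outcome GWAS
    N=254,618 with SEs inflated by 2.8 for the binary design).  True
    instrument effects are N(0, gamma_sd²) on the exposure and
    N(0, mediator_gamma_sd²) for the mediator's own instruments; both traits
    carry large-effect loci, so the spreads are set high enough that most
    variants clear the relaxed p < 1e-5 threshold at those sample sizes.
    """

    n_snps: int = 50
    n_mediator_snps: int = 0
    n_exposure: int = 7174
    n_mediator: int = 3757
    n_outcome: int = 254618
    maf_range: tuple[float, float] = (0.05, 0.5)
    gamma_sd: float = 0.35
    mediator_gamma_sd: float = 0.5
    theta_direct: float = 0.0
    alpha_xm: float = 0.0
    beta_my: float = 0.0
    pleiotropy: PleiotropyConfig = field(default_factory=PleiotropyConfig)
    n_outliers: int = 0
    outlier_shift: float = 10.0
    palindrome_fraction: float = 0.1
    flip_fraction: float = 0.2
    ld_blocks: LDBlockConfig = field(default_factory=LDBlockConfig)
    outcome_se_inflation: float = 2.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 2 or self.n_mediator_snps < 0:
            raise ValueError("n_snps must be >= 2, n_mediator_snps >= 0")
        for n in (self.n_exposure, self.n_mediator, self.n_outcome):
            if n < 2:
                raise ValueError("sample sizes must be >= 2")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        for frac in (self.palindrome_fraction, self.flip_fraction):
            if not (0 <= frac <= 1):
                raise ValueError("fractions must lie in [0, 1]")
        for sd in (self.gamma_sd, self.mediator_gamma_sd):
            if sd < 0:
                raise ValueError("effect spreads must be >= 0")
        if self.n_outliers < 0 or self.n_outliers > self.n_snps:
            raise ValueError("n_outliers must lie in [0, n_snps]")
        if self.outcome_se_inflation < 1:
            raise ValueError("outcome_se_inflation must be >= 1")

    @property
    def theta_total(self) -> float:
        return self.theta_direct + self.alpha_xm * self.beta_my

    def to_dict(self) -> dict:
        d = asdict(self)
        d["maf_range"] = list(self.maf_range)
        return d


@dataclass
class SimulatedStudy:
    """Three summary-stat tables plus the generating truth."""

    exposure: pd.DataFrame
    mediator: pd.DataFrame
    outcome: pd.DataFrame
    ld: LDMatrix
    truth: dict
    config: SimulationConfig

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_sumstats(self.exposure, outdir / "exposure.tsv")
        write_sumstats(self.mediator, outdir / "mediator.tsv")
        write_sumstats(self.outcome, outdir / "outcome.tsv")
        self.ld.write(outdir / "ld.tsv")
        with open(outdir / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=2, sort_keys=True)


def _sampling_se(n: float, maf: np.ndarray) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * n * maf * (1.0 - maf))


def _layout_positions(m: int, block_size: int) -> tuple[list[str], np.ndarray]:
    """Chromosome/position layout: 50 kb spacing inside an LD block, blocks
    20,000 kb apart (outside any clumping window), cycling chromosomes 1-22."""
    chroms, positions = [], []
    block, chrom, pos = 0, 1, 1_000_000
    for j in range(m):
        if j and j % block_size == 0:
            block += 1
            pos += 20_000_000
            if block % 5 == 0:
                chrom = chrom % 22 + 1
                pos = 1_000_000
        else:
            pos += 50_000 if j % block_size else 0
        chroms.append(str(chrom))
        positions.append(pos)
    return chroms, np.asarray(positions, dtype=np.int64)


def _emit_table(rsid, chrom, pos, ea, oa, maf, true_beta, n, se,
                flip_mask, rng) -> pd.DataFrame:
    beta = rng.normal(true_beta, se)
    pval = 2 * stats.norm.sf(np.abs(beta) / se)
    pval = np.clip(pval, np.finfo(float).tiny, 1.0)
    df = pd.DataFrame({
        "rsid": rsid, "chrom": chrom, "pos": pos,
        "effect_allele": ea.copy(), "other_allele": oa.copy(),
        "eaf": maf.astype(float).copy(), "beta": beta, "se": se,
        "pval": pval, "n": float(n)})
    if flip_mask.any():
        f = flip_mask
        df.loc[f, ["effect_allele", "other_allele"]] = \
            df.loc[f, ["other_allele", "effect_allele"]].to_numpy()
        df.loc[f, "beta"] = -df.loc[f, "beta"]
        df.loc[f, "eaf"] = 1.0 - df.loc[f, "eaf"]
    return df[COLUMNS]


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Generate one study: exposure, mediator and outcome tables plus LD.

    Deterministic given ``config.seed``; independent random streams are used
    for the genetic architecture, the allele bookkeeping and each trait's
    sampling noise, so changing e.g. ``flip_fraction`` leaves the simulated
    effect sizes untouched.
    """
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    (s_maf, s_gamma, s_delta, s_alleles, s_pal, s_flip_m, s_flip_y,
     s_noise_x, s_noise_m, s_noise_y, s_pleio) = [
        np.random.default_rng(c) for c in ss.spawn(11)]

    m = cfg.n_snps + cfg.n_mediator_snps
    is_exposure_snp = np.zeros(m, bool)
    is_exposure_snp[:cfg.n_snps] = True

    maf = s_maf.uniform(*cfg.maf_range, size=m)
    # True instrument effects are leptokurtic (many small, few large), the
    # standard sparse-architecture assumption for complex traits: Laplace
    # with the configured sd.  Magnitudes are capped so no single variant
    # explains more than ~half the trait variance (2·beta²·p(1−p) < 0.5),
    # keeping the emitted summary statistics internally consistent.
    cap = 0.7 / np.sqrt(2.0 * maf * (1.0 - maf))
    gamma = np.where(is_exposure_snp,
                     s_gamma.laplace(0.0, cfg.gamma_sd / np.sqrt(2), size=m),
                     0.0)
    delta = np.where(~is_exposure_snp,
                     s_delta.laplace(0.0, cfg.mediator_gamma_sd / np.sqrt(2),
                                     size=m), 0.0)
    gamma = np.sign(gamma) * np.minimum(np.abs(gamma), cap)
    delta = np.sign(delta) * np.minimum(np.abs(delta), cap)

    # allele pairs
    pal_mask = s_pal.uniform(size=m) < cfg.palindrome_fraction
    ea = np.empty(m, dtype=object)
    oa = np.empty(m, dtype=object)
    idx_np = s_alleles.integers(0, len(_NONPALINDROMIC), size=m)
    idx_p = s_alleles.integers(0, len(_PALINDROMIC), size=m)
    for j in range(m):
        ea[j], oa[j] = (_PALINDROMIC[idx_p[j]] if pal_mask[j]
                        else _NONPALINDROMIC[idx_np[j]])

    # horizontal pleiotropy on invalid exposure instruments
    pl = cfg.pleiotropy
    alpha_y = np.zeros(m)
    alpha_m = np.zeros(m)
    invalid_ids: list[int] = []
    if pl.mode != "none" and pl.fraction_invalid > 0:
        n_invalid = int(round(pl.fraction_invalid * cfg.n_snps))
        invalid_ids = list(s_pleio.choice(cfg.n_snps, size=n_invalid,
                                          replace=False))
        mu = pl.mean if pl.mode == "directional" else 0.0
        # "directional" means consistently signed relative to the
        # exposure-raising allele: orienting a SNP to its exposure-increasing
        # direction flips both betas, so pleiotropy drawn on the raw allele
        # frame would cancel; aligning with sign(gamma) keeps its mean mu on
        # the oriented frame that MR-Egger analyzes.
        orient = np.sign(gamma[invalid_ids])
        orient[orient == 0] = 1.0
        alpha_y[invalid_ids] = orient * s_pleio.normal(mu, pl.sd,
                                                       size=n_invalid)
        if cfg.alpha_xm != 0 or cfg.beta_my != 0:
            alpha_m[invalid_ids] = orient * s_pleio.normal(mu, pl.sd,
                                                           size=n_invalid)

    beta_x_true = gamma
    beta_m_true = cfg.alpha_xm * gamma + delta + alpha_m
    beta_y_true = (cfg.theta_direct * gamma + cfg.beta_my * beta_m_true
                   + alpha_y)

    se_x = _sampling_se(cfg.n_exposure, maf)
    se_m = _sampling_se(cfg.n_mediator, maf)
    se_y = _sampling_se(cfg.n_outcome, maf) * cfg.outcome_se_inflation

    # gross outliers: displace the outcome effect of the strongest exposure
    # instruments (ones certain to survive selection) by outlier_shift SEs
    outlier_ids: list[int] = []
    if cfg.n_outliers:
        order = np.argsort(-np.abs(gamma[:cfg.n_snps]))
        outlier_ids = [int(i) for i in order[:cfg.n_outliers]]
        beta_y_true = beta_y_true.copy()
        beta_y_true[outlier_ids] += cfg.outlier_shift * se_y[outlier_ids]

    chrom, pos = _layout_positions(m, cfg.ld_blocks.block_size)
    rsid = np.array([f"rs{j + 1:06d}" for j in range(m)])

    flip_m = s_flip_m.uniform(size=m) < cfg.flip_fraction
    flip_y = s_flip_y.uniform(size=m) < cfg.flip_fraction
    no_flip = np.zeros(m, bool)

    exposure = _emit_table(rsid, chrom, pos, ea, oa, maf, beta_x_true,
                           cfg.n_exposure, se_x, no_flip, s_noise_x)
    mediator = _emit_table(rsid, chrom, pos, ea, oa, maf, beta_m_true,
                           cfg.n_mediator, se_m, flip_m, s_noise_m)
    outcome = _emit_table(rsid, chrom, pos, ea, oa, maf, beta_y_true,
                          cfg.n_outcome, se_y, flip_y, s_noise_y)

    # block-diagonal LD among exposure instruments
    r2 = np.eye(m)
    bs = cfg.ld_blocks.block_size
    if bs > 1 and cfg.ld_blocks.r2 > 0:
        for start in range(0, cfg.n_snps, bs):
            stop = min(start + bs, cfg.n_snps)
            r2[start:stop, start:stop] = cfg.ld_blocks.r2
            np.fill_diagonal(r2[start:stop, start:stop], 1.0)
    ld = LDMatrix(list(rsid), r2)

    truth = {
        "theta_total": cfg.theta_total,
        "theta_direct": cfg.theta_direct,
        "alpha_xm": cfg.alpha_xm,
        "beta_my": cfg.beta_my,
        "invalid_snp_ids": sorted(str(rsid[i]) for i in invalid_ids),
        "outlier_snp_ids": sorted(str(rsid[i]) for i in outlier_ids),
        "mediator_instrument_ids": [str(r) for r in rsid[~is_exposure_snp]],
        "seed": cfg.seed,
    }
    return SimulatedStudy(exposure, mediator, outcome, ld, truth, cfg)


def scenario_presets() -> dict[str, SimulationConfig]:
    """Named study conditions exercising each pipeline property.

    ``clean``: a genuine causal effect with fully valid instruments.
    ``null``: no effect anywhere (type-I error calibration).
    ``balanced_pleiotropy`` / ``directional_pleiotropy``: invalid instruments
    with zero-mean or consistently signed pleiotropy (InSIDE holds).
    ``outliers``: one gross outcome outlier displaced 10 SEs.
    ``mediation`` / ``null_mediation``: the three-trait mediation structure
    with and without the exposure→mediator path.
    """
    base = SimulationConfig()
    return {
        "clean": replace(base, theta_direct=0.3, seed=11),
        "null": replace(base, theta_direct=0.0, seed=12),
        "balanced_pleiotropy": replace(
            base, theta_direct=0.3, seed=13,
            pleiotropy=PleiotropyConfig("balanced", sd=0.05,
                                        fraction_invalid=0.3)),
        "directional_pleiotropy": replace(
            base, theta_direct=0.3, seed=14,
            pleiotropy=PleiotropyConfig("directional", sd=0.05,
                                        fraction_invalid=0.5, mean=0.2)),
        "outliers": replace(base, theta_direct=0.3, seed=15,
                            n_outliers=1, outlier_shift=10.0),
        "mediation": replace(base, theta_direct=0.1, alpha_xm=0.4,
                             beta_my=0.5, n_mediator_snps=50, seed=16),
        "null_mediation": replace(base, theta_direct=0.1, alpha_xm=0.0,
                                  beta_my=0.5, n_mediator_snps=50, seed=17),
    }
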