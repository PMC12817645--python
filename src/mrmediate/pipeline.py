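"""Workflow orchestration: forward/reverse screening and the mediation table.

The screening rule for an exposure→outcome pair mirrors the discovery
procedure of the motivating study design: IVW p < 0.05, the same effect
direction across all five MR methods, no Egger-intercept evidence of
directional pleiotropy (p > 0.05), and no MR-PRESSO global outlier signal
(p > 0.05).  A reverse-direction IVW p-value is recorded alongside but only
qualifies the causal-direction claim; it does not gate the screen.
Cochran's Q is reported, not gated on.

``run_mediation_pipeline`` chains the screens: exposures→outcome,
mediators→outcome, then exposure→mediator for the survivors, and computes
the product-of-coefficients mediation row for every triple passing all legs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import instruments as ins
from .estimators import MRBattery, run_all_methods
from .mediation import MediationResult, mediation_effect, mediation_table
from .sensitivity import SensitivityReport, sensitivity_report
from .sumstats import HarmonizedSet, harmonize

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Every tunable threshold of the workflow, serializable to YAML/JSON."""

    p_instrument: float = 1e-5
    clump_r2: float = 0.001
    clump_kb: float = 10_000
    f_min: float = 10.0
    palindrome_eaf_window: float = 0.08
    eaf_discrepancy: float = 0.2
    ivw_model: str = "random"
    n_boot: int = 1000
    n_sim: int = 1000
    include_bwmr: bool = False
    ivw_alpha: float = 0.05
    pleiotropy_alpha: float = 0.05
    presso_alpha: float = 0.05
    reverse_p_instrument: float | None = None  # None -> same as forward
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml
            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls(**data)

    def write(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            import yaml
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2,
                                       sort_keys=True))


@dataclass
class ScreeningDecision:
    """Outcome of the screening rule for one exposure/outcome pair."""

    exposure: str
    outcome: str
    ivw_pval: float
    direction_concordant: bool
    egger_intercept_pval: float
    presso_global_pval: float | None
    q_pval: float
    reverse_ivw_pval: float | None
    passed: bool
    reasons: list[str] = field(default_factory=list)
    error: str | None = None

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PairReport:
    """Full artifact bundle for one screened pair."""

    decision: ScreeningDecision
    instruments: ins.InstrumentSet | None = None
    harmonized: HarmonizedSet | None = None
    battery: MRBattery | None = None
    sensitivity: SensitivityReport | None = None
    reverse_battery: MRBattery | None = None


def _leg(exposure: pd.DataFrame, outcome: pd.DataFrame,
         ld: ins.LDMatrix | None, config: PipelineConfig,
         p_threshold: float | None = None
         ) -> tuple[ins.InstrumentSet, HarmonizedSet]:
    inst = ins.select_instruments(
        exposure, ld=ld,
        p_threshold=p_threshold or config.p_instrument,
        r2_threshold=config.clump_r2, window_kb=config.clump_kb,
        f_min=config.f_min)
    if len(inst) == 0:
        raise ValueError("no instruments survived selection")
    h = harmonize(inst.table, outcome,
                  palindrome_eaf_window=config.palindrome_eaf_window,
                  eaf_discrepancy=config.eaf_discrepancy)
    if h.n_kept == 0:
        raise ValueError("no SNPs survived harmonization")
    return inst, h


def screen_pair(exposure: pd.DataFrame, outcome: pd.DataFrame,
                config: PipelineConfig | None = None,
                ld: ins.LDMatrix | None = None,
                ld_outcome: ins.LDMatrix | None = None,
                exposure_name: str = "exposure",
                outcome_name: str = "outcome",
                run_reverse: bool = True) -> PairReport:
    """Run the full forward (and reverse) screen for one pair.

    Any hard downstream error yields a decision with ``passed=False`` and
    the diagnostic recorded, so multi-pair loops can continue.
    """
    config = config or PipelineConfig()
    try:
        inst, h = _leg(exposure, outcome, ld, config)
        battery = run_all_methods(h, n_boot=config.n_boot, seed=config.seed,
                                  ivw_model=config.ivw_model,
                                  include_bwmr=config.include_bwmr)
        report = sensitivity_report(h, n_sim=config.n_sim,
                                    sig=config.presso_alpha,
                                    seed=config.seed)
    except ValueError as exc:
        logger.warning("screen_pair(%s -> %s) failed: %s",
                       exposure_name, outcome_name, exc)
        decision = ScreeningDecision(
            exposure=exposure_name, outcome=outcome_name,
            ivw_pval=np.nan, direction_concordant=False,
            egger_intercept_pval=np.nan, presso_global_pval=None,
            q_pval=np.nan, reverse_ivw_pval=None, passed=False,
            reasons=["error"], error=str(exc))
        return PairReport(decision)

    reverse_battery = None
    reverse_p: float | None = None
    if run_reverse:
        try:
            _, h_rev = _leg(outcome, exposure, ld_outcome, config,
                            p_threshold=config.reverse_p_instrument)
            reverse_battery = run_all_methods(
                h_rev, n_boot=config.n_boot, seed=config.seed,
                ivw_model=config.ivw_model)
            reverse_p = reverse_battery.results["IVW"].pval
        except ValueError as exc:
            logger.info("reverse MR %s -> %s not estimable: %s",
                        outcome_name, exposure_name, exc)

    ivw_p = battery.results["IVW"].pval
    presso_p = report.presso.global_pval if report.presso else None
    reasons = []
    if not ivw_p < config.ivw_alpha:
        reasons.append("ivw_pval")
    if not battery.direction_concordant:
        reasons.append("direction")
    if not report.egger_intercept_pval > config.pleiotropy_alpha:
        reasons.append("egger_intercept")
    if presso_p is not None and not presso_p > config.presso_alpha:
        reasons.append("presso_global")
    decision = ScreeningDecision(
        exposure=exposure_name, outcome=outcome_name, ivw_pval=ivw_p,
        direction_concordant=battery.direction_concordant,
        egger_intercept_pval=report.egger_intercept_pval,
        presso_global_pval=presso_p, q_pval=report.q_pval,
        reverse_ivw_pval=reverse_p, passed=not reasons, reasons=reasons)
    logger.info("screen_pair(%s -> %s): passed=%s reasons=%s",
                exposure_name, outcome_name, decision.passed, reasons)
    return PairReport(decision, inst, h, battery, report, reverse_battery)


def run_mediation_pipeline(exposures: dict[str, pd.DataFrame],
                           mediators: dict[str, pd.DataFrame],
                           outcome: pd.DataFrame,
                           config: PipelineConfig | None = None,
                           lds: dict[str, ins.LDMatrix] | None = None,
                           outcome_name: str = "outcome",
                           ) -> tuple[pd.DataFrame, dict]:
    """Screen exposures and mediators against the outcome, then the
    exposure→mediator legs for the survivors, and emit the mediation table.

    Returns ``(table, artifacts)`` where ``artifacts`` maps each screened
    pair to its :class:`PairReport` and each surviving triple to its
    :class:`MediationResult`.  Per-triple failures are logged, never fatal.

    Mediator→outcome legs drop variants associated with any screened
    exposure (exposure p < ``config.p_instrument``): such variants reach the
    outcome through the direct exposure path too, contaminating β2 with
    correlated pleiotropy, so only the mediator's own instruments are used.
    """
    config = config or PipelineConfig()
    lds = lds or {}
    artifacts: dict[str, object] = {"pairs": {}, "triples": {}}

    exposure_hits: set[str] = set()
    for df in exposures.values():
        exposure_hits |= set(df.loc[df["pval"] < config.p_instrument,
                                    "rsid"])

    surviving_exp: dict[str, PairReport] = {}
    for name, df in exposures.items():
        rep = screen_pair(df, outcome, config, ld=lds.get(name),
                          exposure_name=name, outcome_name=outcome_name)
        artifacts["pairs"][f"{name}->{outcome_name}"] = rep
        if rep.decision.passed:
            surviving_exp[name] = rep

    surviving_med: dict[str, PairReport] = {}
    for name, df in mediators.items():
        own = df[~df["rsid"].isin(exposure_hits)]
        if len(own) < len(df):
            logger.info("pipeline: %s->%s leg drops %d exposure-associated "
                        "variant(s)", name, outcome_name, len(df) - len(own))
        rep = screen_pair(own, outcome, config, ld=lds.get(name),
                          exposure_name=name, outcome_name=outcome_name)
        artifacts["pairs"][f"{name}->{outcome_name}"] = rep
        if rep.decision.passed:
            surviving_med[name] = rep

    results: list[MediationResult] = []
    for ename, erep in surviving_exp.items():
        for mname, mrep in surviving_med.items():
            rep_xm = screen_pair(exposures[ename], mediators[mname], config,
                                 ld=lds.get(ename), exposure_name=ename,
                                 outcome_name=mname, run_reverse=False)
            artifacts["pairs"][f"{ename}->{mname}"] = rep_xm
            if not rep_xm.decision.passed:
                continue
            b1 = rep_xm.battery.results["IVW"]
            b2 = mrep.battery.results["IVW"]
            total = erep.battery.results["IVW"]
            med = mediation_effect(b1.beta, b1.se, b2.beta, b2.se, total.beta,
                                   ename, mname, outcome_name)
            artifacts["triples"][f"{ename}->{mname}->{outcome_name}"] = med
            results.append(med)

    table = mediation_table(results)
    if "indirect_pval" in table.columns and len(table):
        # optional FDR column for users screening many pathways
        from statsmodels.stats.multitest import multipletests
        table["indirect_qval_fdr"] = multipletests(
            table["indirect_pval"], method="fdr_bh")[1]
    return table, artifacts


def write_pipeline_outputs(table: pd.DataFrame, artifacts: dict,
                           outdir: str | Path,
                           config: PipelineConfig) -> None:
    """Persist the mediation table, per-pair decisions/harmonized sets, and a
    run manifest; byte-stable given identical inputs, config and seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table.to_csv(outdir / "mediation_table.tsv", sep="\t", index=False,
                 float_format="%.10g")
    decisions = [rep.decision.to_dict()
                 for rep in artifacts["pairs"].values()]
    with open(outdir / "screening_decisions.json", "w") as fh:
        json.dump(decisions, fh, indent=2, sort_keys=True, default=str)
    for key, rep in artifacts["pairs"].items():
        if rep.harmonized is not None:
            safe = key.replace(">", "").replace("/", "_").replace(" ", "_")
            rep.harmonized.write(outdir / f"harmonized_{safe}.tsv")
            rep.battery.to_frame().to_csv(
                outdir / f"mr_{safe}.tsv", sep="\t", index=False,
                float_format="%.10g")
    from . import __version__
    manifest = {"config": config.to_dict(), "version": __version__,
                "n_mediation_rows": int(len(table))}
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def hash_directory(path: str | Path) -> str:
    """SHA-256 over the sorted relative paths and file contents of a tree."""
    path = Path(path)
    digest = hashlib.sha256()
    for p in sorted(path.rglob("*")):
        if p.is_file():
            digest.update(str(p.relative_to(path)).encode())
            digest.update(p.read_bytes())
    return digest.hexdigest()
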