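"""Two-step MR mediation: product of coefficients with delta-method inference.

The indirect (mediated) effect of an exposure X on an outcome Y through a
mediator M is the product β1·β2 of two MR estimates obtained on
non-overlapping summary datasets: β1 = effect of X on M and β2 = effect of
M on Y.  Its standard error is the first-order delta-method form

    se(β1·β2) = sqrt(β1²·se2² + β2²·se1²)

with zero cross-covariance (the two legs come from separate two-sample
estimations).  The proportion mediated is indirect/total; it is reported
signed and unconstrained, with a flag recording whether the indirect and
total effects agree in sign (published mediation tables contain
sign-inconsistent pathways, so clipping would misrepresent them).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy import stats

from . import instruments as ins
from .estimators import MRResult, ivw
from .sumstats import harmonize

logger = logging.getLogger(__name__)


@dataclass
class MediationResult:
    """Decomposition of a total effect into direct and mediated components.

    Invariants: ``indirect == beta1*beta2`` and
    ``direct + indirect == beta_all`` exactly.
    """

    exposure_name: str
    mediator_name: str
    outcome_name: str
    beta_all: float
    beta1: float
    se1: float
    beta2: float
    se2: float
    indirect: float
    indirect_se: float
    indirect_pval: float
    proportion: float | None
    direct: float
    sign_consistent: bool
    notes: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return {
            "Exposure": self.exposure_name, "Mediator": self.mediator_name,
            "Outcome": self.outcome_name, "beta_all": self.beta_all,
            "indirect": self.indirect, "Beta1": self.beta1,
            "Beta2": self.beta2, "se1": self.se1, "se2": self.se2,
            "indirect_se": self.indirect_se,
            "indirect_pval": self.indirect_pval,
            "proportion": self.proportion, "direct": self.direct,
            "sign_consistent": self.sign_consistent,
        }


def mediation_effect(beta1: float, se1: float, beta2: float, se2: float,
                     beta_all: float,
                     exposure_name: str = "exposure",
                     mediator_name: str = "mediator",
                     outcome_name: str = "outcome") -> MediationResult:
    """Product-of-coefficients mediation arithmetic.

    ``proportion`` is absent (None) when the total effect is exactly zero.
    """
    if se1 <= 0 or se2 <= 0:
        raise ValueError("se1 and se2 must be > 0")
    indirect = beta1 * beta2
    indirect_se = float(np.sqrt(beta1**2 * se2**2 + beta2**2 * se1**2))
    if indirect_se > 0:
        pval = float(2 * stats.norm.sf(abs(indirect / indirect_se)))
    else:
        pval = 1.0 if indirect == 0 else 0.0
    proportion = None if beta_all == 0 else indirect / beta_all
    if beta_all == 0:
        logger.info("mediation_effect: total effect is zero, "
                    "proportion mediated undefined")
    return MediationResult(
        exposure_name=exposure_name, mediator_name=mediator_name,
        outcome_name=outcome_name, beta_all=beta_all,
        beta1=beta1, se1=se1, beta2=beta2, se2=se2,
        indirect=indirect, indirect_se=indirect_se, indirect_pval=pval,
        proportion=proportion, direct=beta_all - indirect,
        sign_consistent=bool(indirect * beta_all > 0))


def _leg_estimate(exp_df: pd.DataFrame, out_df: pd.DataFrame,
                  ld: ins.LDMatrix | None, config) -> tuple[MRResult, dict]:
    """One instrument-selection + harmonization + IVW chain."""
    inst = ins.select_instruments(
        exp_df, ld=ld, p_threshold=config.p_instrument,
        r2_threshold=config.clump_r2, window_kb=config.clump_kb,
        f_min=config.f_min)
    if len(inst) == 0:
        raise ValueError("no instruments survived selection")
    h = harmonize(inst.table, out_df,
                  palindrome_eaf_window=config.palindrome_eaf_window,
                  eaf_discrepancy=config.eaf_discrepancy)
    if h.n_kept == 0:
        raise ValueError("no SNPs survived harmonization")
    res = ivw(h, model=config.ivw_model)
    return res, {"instruments": inst, "harmonized": h}


def two_step_mediation(exposure: pd.DataFrame, mediator: pd.DataFrame,
                       outcome: pd.DataFrame, config=None,
                       ld_exposure: ins.LDMatrix | None = None,
                       ld_mediator: ins.LDMatrix | None = None,
                       exposure_name: str = "exposure",
                       mediator_name: str = "mediator",
                       outcome_name: str = "outcome") -> MediationResult:
    """Run the three MR legs and assemble the mediation decomposition.

    Legs: exposure→outcome (total effect), exposure→mediator (β1),
    mediator→outcome (β2), each through the full instrument-selection,
    harmonization and IVW chain; the per-leg artifacts are attached under
    ``notes``.  A leg failing its preconditions raises with the leg named.

    For the β2 leg, variants associated with the exposure (exposure
    p < ``config.p_instrument``) are removed from the mediator's candidate
    instruments: exposure-driven variants reach the outcome through the
    direct exposure→outcome path as well, which enters the mediator→outcome
    leg as correlated pleiotropy and biases β2 toward
    β2 + direct/β1.  Only the mediator's own instruments identify β2.
    """
    if config is None:
        from .pipeline import PipelineConfig
        config = PipelineConfig()
    if exposure is mediator or (
            len(exposure) == len(mediator)
            and list(exposure["rsid"]) == list(mediator["rsid"])
            and np.allclose(exposure["beta"], mediator["beta"])
            and np.allclose(exposure["se"], mediator["se"])):
        raise ValueError("exposure and mediator tables are identical "
                         "(self-mediation)")

    exposure_hits = set(
        exposure.loc[exposure["pval"] < config.p_instrument, "rsid"])
    mediator_own = mediator[~mediator["rsid"].isin(exposure_hits)]
    n_removed = len(mediator) - len(mediator_own)
    if n_removed:
        logger.info("two_step_mediation: removed %d exposure-associated "
                    "variant(s) from the mediator->outcome leg", n_removed)

    artifacts: dict[str, dict] = {}
    legs = {
        "total (exposure->outcome)": (exposure, outcome, ld_exposure),
        "beta1 (exposure->mediator)": (exposure, mediator, ld_exposure),
        "beta2 (mediator->outcome)": (mediator_own, outcome, ld_mediator),
    }
    results: dict[str, MRResult] = {}
    for leg, (e, o, ld) in legs.items():
        try:
            results[leg], artifacts[leg] = _leg_estimate(e, o, ld, config)
        except ValueError as exc:
            raise ValueError(f"mediation leg failed [{leg}]: {exc}") from exc

    total = results["total (exposure->outcome)"]
    b1 = results["beta1 (exposure->mediator)"]
    b2 = results["beta2 (mediator->outcome)"]
    med = mediation_effect(b1.beta, b1.se, b2.beta, b2.se, total.beta,
                           exposure_name, mediator_name, outcome_name)
    med.notes["legs"] = results
    med.notes["artifacts"] = artifacts
    med.notes["beta_all_se"] = total.se
    return med


def mediation_table(results: list[MediationResult]) -> pd.DataFrame:
    """Published-table-shaped frame, sorted by exposure then mediator."""
    cols = ["Exposure", "Mediator", "Outcome", "beta_all", "indirect",
            "Beta1", "Beta2", "se1", "se2", "indirect_se", "indirect_pval",
            "proportion", "sign_consistent"]
    if not results:
        return pd.DataFrame(columns=cols)
    df = pd.DataFrame([r.to_dict() for r in results])[cols]
    return df.sort_values(["Exposure", "Mediator"]).reset_index(drop=True)
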