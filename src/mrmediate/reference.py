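"""Published reference estimates used as worked-example inputs.

These are the summary-level results of a published two-step MR study of
plasma lipidome species, immune phenotypes and polycystic ovary syndrome:
the IVW estimates (log-odds beta, odds ratio with 95% CI, p) for the six
lipid species that survived its screen, and the mediation-table rows
(total effect, exposure→mediator beta1, mediator→outcome beta2) for its
ten lipid→immune→PCOS pathways.  They serve as fixed numeric inputs for
consistency checks (OR = exp(beta)) and for the product-of-coefficients
arithmetic; no real genotype or summary data is shipped or downloaded.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: IVW estimates of lipid species effects on PCOS (log-odds scale).
#: One published row (Phosphatidylcholine (18:1_20:4)) prints an OR that
#: disagrees with exp(beta) at the third decimal (1.031 vs 1.030) — a
#: rounding slip in the source table; consistency checks therefore expect
#: five of the six rows to reproduce exactly at 3 d.p.
LIPID_PCOS_IVW = pd.DataFrame(
    [
        ("Phosphatidylcholine (O-16:1_18:0)", -0.053, 0.948, 0.905, 0.993, 0.025),
        ("Phosphatidylinositol (18:1_18:2)", -0.035, 0.966, 0.934, 0.999, 0.043),
        ("Phosphatidylcholine (18:1_20:4)", 0.030, 1.031, 1.003, 1.060, 0.031),
        ("Phosphatidylcholine (18:2_20:4)", 0.036, 1.037, 1.004, 1.070, 0.028),
        ("Triacylglycerol (50:4)", 0.037, 1.038, 1.005, 1.072, 0.025),
        ("Phosphatidylcholine (O-18:1_20:4)", 0.039, 1.040, 1.005, 1.075, 0.023),
    ],
    columns=["exposure", "beta", "or_published", "ci_low", "ci_high", "pval"],
)

#: Mediation pathways: total effect of the lipid on PCOS (beta_all),
#: lipid→immune-phenotype effect (beta1), immune-phenotype→PCOS effect
#: (beta2).  The published total effect for the first pathway (0.304)
#: disagrees with the same study's forward-MR text (0.030); both are kept
#: verbatim here and no mediation check asserts on that cell.
MEDIATION_PATHWAYS = pd.DataFrame(
    [
        ("Phosphatidylcholine (18:1_20:4)", "HLA DR on B cell", 0.304, -0.111, 0.021),
        ("Phosphatidylcholine (18:2_20:4)", "CD28 on secreting Treg", 0.036, -0.125, 0.016),
        ("Phosphatidylcholine (18:2_20:4)", "CD28 on CD45RA- CD4 not Treg", 0.036, -0.137, 0.025),
        ("Phosphatidylcholine (O-16:1_18:0)", "IgD+ CD38br AC", -0.053, 0.178, 0.012),
        ("Phosphatidylcholine (O-16:1_18:0)", "Secreting Treg %CD4", -0.053, -0.279, 0.015),
        ("Phosphatidylcholine (O-18:1_20:4)", "CD20- CD38- AC", 0.039, -0.108, -0.048),
        ("Phosphatidylinositol (18:1_18:2)", "CD33- HLA DR+ AC", -0.035, -0.155, 0.012),
        ("Phosphatidylinositol (18:1_18:2)", "CD33 on CD66b++ myeloid cell", -0.035, 0.163, 0.013),
        ("Phosphatidylinositol (18:1_18:2)", "CD33 on Mo MDSC", -0.035, 0.166, 0.015),
        ("Triacylglycerol (50:4)", "Activated & resting Treg AC", 0.037, 0.115, -0.043),
    ],
    columns=["exposure", "mediator", "beta_all", "beta1", "beta2"],
)


def or_consistency() -> pd.DataFrame:
    """exp(beta) at 3 d.p. against the published OR for each lipid row."""
    df = LIPID_PCOS_IVW.copy()
    df["or_from_beta"] = np.round(np.exp(df["beta"]), 3)
    df["consistent"] = df["or_from_beta"] == df["or_published"]
    return df


def mediation_products() -> pd.DataFrame:
    """beta1·beta2 indirect effects for the ten published pathways."""
    df = MEDIATION_PATHWAYS.copy()
    df["indirect"] = df["beta1"] * df["beta2"]
    return df
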