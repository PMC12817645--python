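"""GWAS summary-statistic tables: reading, validation, and allele harmonization.

Summary statistics are carried as pandas DataFrames with the canonical
internal columns ``rsid, chrom, pos, effect_allele, other_allele, eaf, beta,
se, pval, n``.  On disk the canonical header is ``SNP, CHR, POS, EA, OA, EAF,
BETA, SE, P, N`` (tab- or comma-delimited, auto-detected); a ``column_map``
can redirect any canonical name to an arbitrary file column.

Harmonization places an exposure table and an outcome table on a shared
effect-allele frame.  Strand is resolved purely from the allele pair:
palindromic variants (A/T, C/G) are kept only when the allele frequency on
both sides identifies the orientation unambiguously.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: internal column name -> canonical file header
CANONICAL_HEADER: dict[str, str] = {
    "rsid": "SNP",
    "chrom": "CHR",
    "pos": "POS",
    "effect_allele": "EA",
    "other_allele": "OA",
    "eaf": "EAF",
    "beta": "BETA",
    "se": "SE",
    "pval": "P",
    "n": "N",
}

COLUMNS = list(CANONICAL_HEADER)

_BASES = {"A", "C", "G", "T"}
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: harmonization outcomes, in the order they are decided
ACTIONS = ("kept", "flipped", "excluded_palindromic", "excluded_mismatch",
           "excluded_eaf")


@dataclass(frozen=True)
class SummaryStatRecord:
    """A single SNP-trait association.

    ``beta`` is the additive per-effect-allele effect (log-odds for binary
    traits, SD units for continuous traits); ``eaf`` may be ``None`` when the
    source does not report frequencies.
    """

    rsid: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    pval: float
    n: float

    def __post_init__(self) -> None:
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.rsid}: effect and other allele identical")
        if self.se <= 0:
            raise ValueError(f"{self.rsid}: se must be > 0")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            raise ValueError(f"{self.rsid}: eaf outside [0, 1]")
        if self.pos < 1:
            raise ValueError(f"{self.rsid}: pos must be >= 1")


def records_to_frame(records: Sequence[SummaryStatRecord]) -> pd.DataFrame:
    df = pd.DataFrame([vars(r) for r in records], columns=COLUMNS)
    df["eaf"] = df["eaf"].astype(float)
    return df


def frame_to_records(df: pd.DataFrame) -> list[SummaryStatRecord]:
    out = []
    for row in df.itertuples(index=False):
        eaf = None if pd.isna(row.eaf) else float(row.eaf)
        out.append(SummaryStatRecord(
            rsid=str(row.rsid), chrom=str(row.chrom), pos=int(row.pos),
            effect_allele=str(row.effect_allele),
            other_allele=str(row.other_allele),
            eaf=eaf, beta=float(row.beta), se=float(row.se),
            pval=float(row.pval), n=float(row.n)))
    return out


def _detect_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    if not header.strip():
        raise ValueError(f"{path}: empty file")
    return "\t" if "\t" in header else ","


def read_sumstats(path: str | Path,
                  column_map: Mapping[str, str] | None = None,
                  ) -> tuple[pd.DataFrame, int]:
    """Read a summary-statistic table, returning ``(frame, n_dropped)``.

    Rows violating the record invariants (non-ACGT or identical alleles,
    se <= 0, eaf outside [0,1], p outside (0,1], n < 2, pos < 1) are dropped
    and counted; multi-allelic rows (allele strings longer than one base)
    count as dropped too.  A missing mandatory column is a hard error.
    ``eaf`` is the only field allowed to be missing per-row.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _detect_sep(path)
    raw = pd.read_csv(path, sep=sep, dtype=str)
    if raw.empty and raw.columns.size == 0:
        raise ValueError(f"{path}: empty file")

    header = dict(CANONICAL_HEADER)
    if column_map:
        header.update(column_map)
    missing = [col for col in header.values() if col not in raw.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s): "
                         + ", ".join(missing))

    df = pd.DataFrame({internal: raw[col] for internal, col in header.items()})
    n_in = len(df)
    for col in ("pos", "eaf", "beta", "se", "pval", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["rsid"] = df["rsid"].astype(str)
    df["chrom"] = df["chrom"].astype(str)
    df["effect_allele"] = df["effect_allele"].astype(str).str.upper()
    df["other_allele"] = df["other_allele"].astype(str).str.upper()

    ok = (
        df["effect_allele"].isin(_BASES)
        & df["other_allele"].isin(_BASES)
        & (df["effect_allele"] != df["other_allele"])
        & (df["se"] > 0)
        & (df["eaf"].isna() | ((df["eaf"] >= 0) & (df["eaf"] <= 1)))
        & (df["pval"] > 0) & (df["pval"] <= 1)
        & (df["n"] >= 2)
        & (df["pos"] >= 1)
        & df[["pos", "beta", "se", "pval", "n"]].notna().all(axis=1)
    )
    dropped = int((~ok).sum())
    if dropped:
        logger.info("read_sumstats(%s): dropped %d invalid row(s)",
                    path.name, dropped)
    df = df.loc[ok].reset_index(drop=True)
    df["pos"] = df["pos"].astype(np.int64)
    if df.empty:
        raise ValueError(f"{path}: no valid rows")
    return df, dropped


def write_sumstats(df: pd.DataFrame, path: str | Path) -> None:
    out = df[COLUMNS].rename(columns=CANONICAL_HEADER)
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def is_palindromic(a1: str, a2: str) -> bool:
    return {a1, a2} in ({"A", "T"}, {"C", "G"})


@dataclass
class HarmonizedSet:
    """Exposure/outcome effect pairs on a common effect-allele frame.

    ``table`` has one row per shared rsid with columns ``rsid, chrom, pos,
    effect_allele, other_allele, beta_exposure, se_exposure, beta_outcome,
    se_outcome, eaf_exposure, eaf_outcome, action_taken``.  Only rows with
    action ``kept``/``flipped`` feed downstream estimators (``kept_table``).
    """

    table: pd.DataFrame
    exposure_name: str = "exposure"
    outcome_name: str = "outcome"

    def __post_init__(self) -> None:
        if self.table["rsid"].duplicated().any():
            raise ValueError("duplicate rsid in harmonized table")

    @property
    def kept_table(self) -> pd.DataFrame:
        return self.table[self.table["action_taken"].isin(("kept", "flipped"))]

    @property
    def n_kept(self) -> int:
        return len(self.kept_table)

    def counts(self) -> dict[str, int]:
        c = self.table["action_taken"].value_counts().to_dict()
        return {a: int(c.get(a, 0)) for a in ACTIONS}

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(beta_exposure, se_exposure, beta_outcome, se_outcome) of kept rows."""
        k = self.kept_table
        return (k["beta_exposure"].to_numpy(float),
                k["se_exposure"].to_numpy(float),
                k["beta_outcome"].to_numpy(float),
                k["se_outcome"].to_numpy(float))

    def write(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False, na_rep="NA")

    @classmethod
    def read(cls, path: str | Path, exposure_name: str = "exposure",
             outcome_name: str = "outcome") -> "HarmonizedSet":
        tab = pd.read_csv(path, sep="\t", na_values=["NA"])
        tab["rsid"] = tab["rsid"].astype(str)
        return cls(tab, exposure_name, outcome_name)


def _orient_one(ea_x: str, oa_x: str, ea_y: str, oa_y: str,
                eaf_x: float, eaf_y: float, w: float
                ) -> tuple[str, bool]:
    """Resolve one SNP's outcome orientation against the exposure frame.

    Returns ``(action, flip)`` where ``flip`` signals that the outcome beta
    must be negated and its frequency complemented.  ``action`` is one of
    kept / flipped / excluded_palindromic / excluded_mismatch (the frequency
    discrepancy check happens afterwards, on aligned frequencies).
    """
    if is_palindromic(ea_x, oa_x):
        if {ea_y, oa_y} != {ea_x, oa_x}:
            return "excluded_mismatch", False
        flip = ea_y != ea_x
        if w >= 0.5:
            return "excluded_palindromic", flip
        if np.isnan(eaf_x) or np.isnan(eaf_y):
            return "excluded_palindromic", flip
        f_y = 1.0 - eaf_y if flip else eaf_y
        lo, hi = 0.5 - w, 0.5 + w
        informative = (eaf_x < lo or eaf_x > hi) and (f_y < lo or f_y > hi)
        same_side = (eaf_x - 0.5) * (f_y - 0.5) > 0
        if informative and same_side:
            return ("flipped" if flip else "kept"), flip
        return "excluded_palindromic", flip

    pairs = {
        (ea_y, oa_y): False,
        (oa_y, ea_y): True,
        (_COMPLEMENT[ea_y], _COMPLEMENT[oa_y]): False,
        (_COMPLEMENT[oa_y], _COMPLEMENT[ea_y]): True,
    }
    flip = pairs.get((ea_x, oa_x))
    if flip is None:
        return "excluded_mismatch", False
    return ("flipped" if flip else "kept"), flip


def harmonize(exposure: pd.DataFrame, outcome: pd.DataFrame,
              palindrome_eaf_window: float = 0.08,
              eaf_discrepancy: float = 0.2,
              exposure_name: str = "exposure",
              outcome_name: str = "outcome") -> HarmonizedSet:
    """Harmonize exposure and outcome tables onto the exposure allele frame.

    For every rsid present in both tables: identical alleles are kept;
    swapped alleles (directly or via strand complement) flip the outcome beta
    sign and complement its frequency; palindromic variants are retained only
    when both frequencies fall outside ``0.5 ± palindrome_eaf_window`` on the
    same side of 0.5 after alignment (``window >= 0.5`` excludes every
    palindrome); irreconcilable alleles are excluded; finally, aligned
    frequencies differing by more than ``eaf_discrepancy`` are excluded.
    """
    merged = exposure.merge(outcome, on="rsid", suffixes=("_x", "_y"),
                            how="inner")
    if merged.empty:
        raise ValueError("no overlapping SNPs between exposure and outcome")
    if merged["rsid"].duplicated().any():
        raise ValueError("duplicate rsid within an input table")

    actions: list[str] = []
    beta_y = merged["beta_y"].to_numpy(float).copy()
    eaf_y = merged["eaf_y"].to_numpy(float).copy()
    eaf_x = merged["eaf_x"].to_numpy(float)

    for i, row in enumerate(merged.itertuples(index=False)):
        action, flip = _orient_one(
            row.effect_allele_x, row.other_allele_x,
            row.effect_allele_y, row.other_allele_y,
            eaf_x[i], eaf_y[i], palindrome_eaf_window)
        if flip:
            beta_y[i] = -beta_y[i]
            eaf_y[i] = 1.0 - eaf_y[i]
        if action in ("kept", "flipped"):
            if (not np.isnan(eaf_x[i]) and not np.isnan(eaf_y[i])
                    and abs(eaf_x[i] - eaf_y[i]) > eaf_discrepancy):
                action = "excluded_eaf"
        actions.append(action)

    table = pd.DataFrame({
        "rsid": merged["rsid"],
        "chrom": merged["chrom_x"],
        "pos": merged["pos_x"],
        "effect_allele": merged["effect_allele_x"],
        "other_allele": merged["other_allele_x"],
        "beta_exposure": merged["beta_x"].astype(float),
        "se_exposure": merged["se_x"].astype(float),
        "beta_outcome": beta_y,
        "se_outcome": merged["se_y"].astype(float),
        "eaf_exposure": eaf_x,
        "eaf_outcome": eaf_y,
        "n_exposure": merged["n_x"].astype(float),
        "n_outcome": merged["n_y"].astype(float),
        "pval_exposure": merged["pval_x"].astype(float),
        "action_taken": actions,
    })
    counts = pd.Series(actions).value_counts().to_dict()
    logger.info("harmonize(%s -> %s): %s", exposure_name, outcome_name, counts)
    return HarmonizedSet(table, exposure_name, outcome_name)


def harmonized_to_sumstats(h: HarmonizedSet) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rebuild exposure/outcome summary tables from the kept rows.

    Both tables come back on the shared effect-allele frame, so harmonizing
    them again is the identity (idempotence of harmonization).
    """
    k = h.kept_table
    base = {
        "rsid": k["rsid"], "chrom": k["chrom"], "pos": k["pos"],
        "effect_allele": k["effect_allele"], "other_allele": k["other_allele"],
    }
    exp = pd.DataFrame({**base, "eaf": k["eaf_exposure"],
                        "beta": k["beta_exposure"], "se": k["se_exposure"],
                        "pval": k["pval_exposure"], "n": k["n_exposure"]})
    out = pd.DataFrame({**base, "eaf": k["eaf_outcome"],
                        "beta": k["beta_outcome"], "se": k["se_outcome"],
                        "pval": 1.0, "n": k["n_outcome"]})
    return exp.reset_index(drop=True), out.reset_index(drop=True)
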