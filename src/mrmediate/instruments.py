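"""Instrument selection: p-value thresholding, LD clumping, strength filters.

Instruments are variants strongly associated with the exposure
(``pval < p_threshold``, default the relaxed 1e-5 used when genome-wide
significant hits are scarce), pruned to approximate linkage equilibrium by
greedy clumping (``r² < 0.001`` within a 10,000 kb window by default), and
screened for weak-instrument bias with the per-SNP F-statistic.

Per-SNP variance explained and instrument strength::

    R² = (2 β² EAF (1−EAF)) / (2 N EAF (1−EAF) SE²)
    F  = R² (N − 2) / (1 − R²)

The EAF factors of R² cancel algebraically, so R² reduces to β²/(N·SE²);
the frequency-free form is used as the fallback when EAF is unreported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class LDMatrix:
    """Pairwise r² among candidate instruments.

    Symmetric with unit diagonal; pairs absent from the matrix are treated
    as unlinked (r² = 0) by :func:`clump`.
    """

    rsids: list[str]
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.rsids = [str(r) for r in self.rsids]
        self.r2 = np.asarray(self.r2, dtype=float)
        m = self.r2
        if m.ndim != 2 or m.shape[0] != m.shape[1] or m.shape[0] != len(self.rsids):
            raise ValueError("LD matrix must be square and match the rsid list")
        if not np.allclose(m, m.T, atol=1e-8):
            raise ValueError("LD matrix must be symmetric")
        if not np.allclose(np.diag(m), 1.0, atol=1e-8):
            raise ValueError("LD matrix diagonal must be 1")
        if (m < -1e-12).any() or (m > 1 + 1e-12).any():
            raise ValueError("LD r² entries must lie in [0, 1]")
        self._index = {r: i for i, r in enumerate(self.rsids)}

    @classmethod
    def identity(cls, rsids: list[str]) -> "LDMatrix":
        return cls(list(rsids), np.eye(len(rsids)))

    def pair_r2(self, a: str, b: str) -> float:
        ia, ib = self._index.get(a), self._index.get(b)
        if ia is None or ib is None:
            return 1.0 if a == b else 0.0
        return float(self.r2[ia, ib])

    # -- serialization -------------------------------------------------
    def write(self, path: str | Path) -> None:
        pd.DataFrame(self.r2, index=self.rsids, columns=self.rsids).to_csv(
            path, sep="\t", index_label="rsid")

    @classmethod
    def from_square_tsv(cls, path: str | Path) -> "LDMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.columns.astype(str)), df.to_numpy(float))

    @classmethod
    def from_long_tsv(cls, path: str | Path) -> "LDMatrix":
        """3-column long format: rsid_a, rsid_b, r2 (unlisted pairs are 0)."""
        df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
        df.columns = ["rsid_a", "rsid_b", "r2"]
        rsids = sorted(set(df["rsid_a"]) | set(df["rsid_b"]))
        idx = {r: i for i, r in enumerate(rsids)}
        m = np.eye(len(rsids))
        for a, b, v in df.itertuples(index=False):
            m[idx[a], idx[b]] = v
            m[idx[b], idx[a]] = v
        return cls(rsids, m)


@dataclass
class InstrumentSet:
    """Variants that passed all three selection stages.

    ``table`` carries the summary-stat columns plus ``r2_trait`` and
    ``f_stat``; ``counts`` records how many variants survived each stage.
    """

    table: pd.DataFrame
    counts: dict = field(default_factory=dict)

    @property
    def rsids(self) -> list[str]:
        return list(self.table["rsid"])

    def __len__(self) -> int:
        return len(self.table)


def select_by_pvalue(records: pd.DataFrame, p_threshold: float = 1e-5
                     ) -> pd.DataFrame:
    """Rows with ``pval`` strictly below the threshold, order preserved."""
    if not (0 < p_threshold <= 1):
        raise ValueError("p_threshold must be in (0, 1]")
    out = records[records["pval"] < p_threshold].reset_index(drop=True)
    if out.empty:
        logger.info("select_by_pvalue: no variant below p < %g", p_threshold)
    return out


def clump(records: pd.DataFrame, ld: LDMatrix,
          r2_threshold: float = 0.001, window_kb: float = 10_000
          ) -> pd.DataFrame:
    """Greedy LD clumping: keep the lowest-p SNP of each LD block.

    Repeatedly promote the lowest-p unclaimed SNP to index status and remove
    every unclaimed same-chromosome SNP within ``window_kb`` (center to
    center) whose r² with the index is >= ``r2_threshold``.  Ties on p are
    broken by rsid so the result does not depend on input row order.
    """
    df = records.sort_values(["pval", "rsid"], kind="mergesort")
    claimed: set[str] = set()
    kept: list[str] = []
    rows = list(df.itertuples(index=False))
    for idx_row in rows:
        if idx_row.rsid in claimed:
            continue
        kept.append(idx_row.rsid)
        claimed.add(idx_row.rsid)
        for other in rows:
            if other.rsid in claimed:
                continue
            if str(other.chrom) != str(idx_row.chrom):
                continue
            if abs(int(other.pos) - int(idx_row.pos)) > window_kb * 1000:
                continue
            if ld.pair_r2(idx_row.rsid, other.rsid) >= r2_threshold:
                claimed.add(other.rsid)
    out = records[records["rsid"].isin(kept)].reset_index(drop=True)
    return out


def instrument_strength(beta: float, se: float, n: float,
                        eaf: float | None = None) -> tuple[float, float]:
    """Per-SNP variance explained and F-statistic.

    Uses the frequency-bearing R² form when EAF is available (its EAF
    factors cancel, so the value equals β²/(N·SE²)), and the frequency-free
    form otherwise.
    """
    if se <= 0:
        raise ValueError("se must be > 0")
    if n <= 2:
        raise ValueError("n must exceed 2")
    if eaf is not None and not np.isnan(eaf) and 0 < eaf < 1:
        r2 = (2 * beta**2 * eaf * (1 - eaf)) / (2 * n * eaf * (1 - eaf) * se**2)
    else:
        r2 = beta**2 / (n * se**2)
    if r2 >= 1:
        raise ValueError("inconsistent summary statistics: R² >= 1")
    f = r2 * (n - 2) / (1 - r2)
    return float(r2), float(f)


def add_strength(records: pd.DataFrame) -> pd.DataFrame:
    out = records.copy()
    vals = [instrument_strength(b, s, n, e) for b, s, n, e in zip(
        out["beta"], out["se"], out["n"], out["eaf"])]
    out["r2_trait"] = [v[0] for v in vals]
    out["f_stat"] = [v[1] for v in vals]
    return out


def filter_weak(records: pd.DataFrame, f_min: float = 10.0) -> pd.DataFrame:
    """Drop weak instruments: retain rows with ``f_stat > f_min``."""
    if f_min < 0:
        raise ValueError("f_min must be >= 0")
    if "f_stat" not in records.columns:
        records = add_strength(records)
    out = records[records["f_stat"] > f_min].reset_index(drop=True)
    removed = len(records) - len(out)
    if removed:
        logger.info("filter_weak: removed %d weak instrument(s) (F <= %g)",
                    removed, f_min)
    return out


def select_instruments(records: pd.DataFrame, ld: LDMatrix | None = None,
                       p_threshold: float = 1e-5, r2_threshold: float = 0.001,
                       window_kb: float = 10_000, f_min: float = 10.0
                       ) -> InstrumentSet:
    """Full selection chain: p-threshold -> LD clump -> weak-instrument filter."""
    sig = select_by_pvalue(records, p_threshold)
    if ld is None:
        ld = LDMatrix.identity(list(sig["rsid"]))
    clumped = clump(sig, ld, r2_threshold, window_kb) if len(sig) else sig
    strong = filter_weak(add_strength(clumped), f_min) if len(clumped) else clumped
    counts = {"n_input": len(records), "n_pass_p": len(sig),
              "n_pass_clump": len(clumped), "n_pass_f": len(strong)}
    logger.info("select_instruments: %s", counts)
    return InstrumentSet(strong, counts)
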