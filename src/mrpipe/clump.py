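"""Greedy LD clumping of summary statistics.

Selects approximately independent index SNPs: after discarding variants
above the p-value threshold, the smallest-p remaining variant becomes an
index and prunes every remaining variant on the same chromosome within
the window that is in LD (r² at or above the threshold) with it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class LdMatrix:
    """Pairwise squared-correlation matrix with aligned positions."""

    snp_ids: list[str]
    r2: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        k = len(self.snp_ids)
        if self.r2.shape != (k, k):
            raise ValueError("r2 must be square and aligned to snp_ids")
        if not np.allclose(self.r2, self.r2.T):
            raise ValueError("r2 must be symmetric")
        if not np.allclose(np.diag(self.r2), 1.0):
            raise ValueError("r2 diagonal must be 1")
        if np.any(self.r2 < 0) or np.any(self.r2 > 1 + 1e-12):
            raise ValueError("r2 entries must lie in [0,1]")

    def lookup(self, a: str, b: str) -> float:
        i, j = self.snp_ids.index(a), self.snp_ids.index(b)
        return float(self.r2[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r2, index=self.snp_ids, columns=self.snp_ids)


def clump(
    records: pd.DataFrame,
    ld: LdMatrix,
    r2_threshold: float = 0.001,
    window_kb: int = 10_000,
    p_threshold: float = 5e-8,
) -> pd.DataFrame:
    """Greedy clumping; returns the retained index-SNP records.

    Ties in p-value are broken by (chrom, pos, snp_id) so the result is
    deterministic.  SNPs absent from the LD matrix are excluded with
    reason ``no_ld_info``; exclusions are stored in
    ``result.attrs["exclusions"]``.  The retained set is verified post
    hoc to contain no within-window pair with r² at or above the
    threshold.
    """
    if r2_threshold <= 0 or window_kb <= 0 or p_threshold <= 0:
        raise ValueError("thresholds must be positive")
    exclusions: list[tuple[str, str]] = []

    df = records.copy()
    df["snp_id"] = df["snp_id"].astype(str)
    in_ld = df["snp_id"].isin(ld.snp_ids)
    for sid in df.loc[~in_ld, "snp_id"]:
        exclusions.append((sid, "no_ld_info"))
        logger.info("clump excluded %s: no_ld_info", sid)
    df = df[in_ld]
    sig = df["pvalue"] <= p_threshold
    for sid in df.loc[~sig, "snp_id"]:
        exclusions.append((sid, "above_p_threshold"))
    df = df[sig]

    idx_of = {s: i for i, s in enumerate(ld.snp_ids)}
    window_bp = int(window_kb) * 1000
    order = df.sort_values(
        ["pvalue", "chrom", "pos", "snp_id"],
        key=lambda c: c.astype(str) if c.name in ("chrom", "snp_id") else c,
    )

    remaining = {r.snp_id: r for r in order.itertuples(index=False)}
    retained: list[str] = []
    for r in order.itertuples(index=False):
        if r.snp_id not in remaining:
            continue
        retained.append(r.snp_id)
        del remaining[r.snp_id]
        i = idx_of[r.snp_id]
        for other_id in list(remaining):
            o = remaining[other_id]
            if str(o.chrom) != str(r.chrom):
                continue
            if abs(int(o.pos) - int(r.pos)) > window_bp:
                continue
            if ld.r2[i, idx_of[other_id]] >= r2_threshold:
                exclusions.append((other_id, f"clumped_with:{r.snp_id}"))
                del remaining[other_id]

    out = records[records["snp_id"].astype(str).isin(retained)].reset_index(drop=True)
    _assert_independent(out, ld, r2_threshold, window_bp)
    out.attrs["exclusions"] = exclusions
    return out


def _assert_independent(out: pd.DataFrame, ld: LdMatrix, r2_threshold: float,
                        window_bp: int) -> None:
    """Post-hoc scan: no retained within-window pair may reach the r² threshold."""
    idx_of = {s: i for i, s in enumerate(ld.snp_ids)}
    rows = list(out.itertuples(index=False))
    for a in range(len(rows)):
        for b in range(a + 1, len(rows)):
            ra, rb = rows[a], rows[b]
            if str(ra.chrom) != str(rb.chrom) or abs(int(ra.pos) - int(rb.pos)) > window_bp:
                continue
            if ld.r2[idx_of[str(ra.snp_id)], idx_of[str(rb.snp_id)]] >= r2_threshold:
                raise AssertionError(
                    f"clumping postcondition violated for {ra.snp_id}/{rb.snp_id}")
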