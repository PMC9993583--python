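"""Inverse-variance meta-analysis across cohorts, with genomic control.

Fixed-effect pooling weights each cohort by 1/SE²; the random-effects
model adds a DerSimonian–Laird between-cohort variance τ² to every
weight.  Cochran's Q (computed under fixed weights) quantifies
between-cohort heterogeneity.  Genomic control rescales a cohort's
standard errors by √λ, λ = median(z²)/median(χ²₁), floored at 1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

_CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, 1))  # 0.4549...


@dataclass
class MetaResult:
    beta_meta: float
    se_meta: float
    pvalue: float
    q_stat: float
    q_pvalue: float
    tau2: float
    model: str
    snp_id: str = ""


@dataclass
class CohortCounts:
    cohort: str
    cases: int
    controls: int

    def __post_init__(self) -> None:
        if self.cases < 0 or self.controls < 0 or self.cases + self.controls == 0:
            raise ValueError("need nonnegative counts with cases+controls > 0")


def cochran_q(betas, ses, pooled: float | None = None):
    """Cochran's Q heterogeneity statistic.

    Q = Σ(βᵢ − β̂)²/seᵢ² with β̂ the fixed-effect pooled estimate (or the
    supplied one); df = k−1; p from the upper χ² tail.  Returns
    ``(nan, 0, nan)`` with a warning for k < 2.
    """
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    k = len(b)
    if k < 2:
        warnings.warn("Cochran's Q undefined for fewer than 2 effects")
        return float("nan"), 0, float("nan")
    w = 1.0 / s**2
    if pooled is None:
        pooled = float(np.sum(w * b) / np.sum(w))
    q = float(np.sum(w * (b - pooled) ** 2))
    df = k - 1
    return q, df, float(stats.chi2.sf(q, df))


def inverse_variance_meta(betas, ses, model: str = "random", snp_id: str = "") -> MetaResult:
    """Pool per-cohort effects by inverse-variance weighting.

    ``model='fixed'`` uses weights 1/seᵢ²; ``model='random'`` estimates
    the DerSimonian–Laird τ² = max(0, (Q−(k−1))/(Σw − Σw²/Σw)) and
    reweights by 1/(seᵢ²+τ²).  A single cohort passes through with a
    warning.
    """
    if model not in ("fixed", "random"):
        raise ValueError(f"unknown model {model!r}")
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    if np.any(~np.isfinite(b)) or np.any(s <= 0):
        raise ValueError("betas must be finite and ses positive")
    k = len(b)
    if k < 2:
        warnings.warn("single-cohort meta-analysis is an identity pass-through")
        beta, se = float(b[0]), float(s[0])
        p = 2 * float(stats.norm.sf(abs(beta / se)))
        return MetaResult(beta, se, p, float("nan"), float("nan"), 0.0, model, snp_id)

    w = 1.0 / s**2
    beta_f = float(np.sum(w * b) / np.sum(w))
    q, df, q_p = cochran_q(b, s, pooled=beta_f)
    tau2 = 0.0
    if model == "random":
        denom = np.sum(w) - np.sum(w**2) / np.sum(w)
        tau2 = max(0.0, (q - df) / denom) if denom > 0 else 0.0
    wr = 1.0 / (s**2 + tau2)
    beta = float(np.sum(wr * b) / np.sum(wr))
    se = float(1.0 / np.sqrt(np.sum(wr)))
    p = 2 * float(stats.norm.sf(abs(beta / se)))
    return MetaResult(beta, se, p, q, q_p, tau2, model, snp_id)


def genomic_control_lambda(z) -> float:
    """Genomic inflation factor λ = median(z²)/median(χ²₁)."""
    z = np.asarray(z, dtype=float)
    z = z[np.isfinite(z)]
    if z.size == 0:
        raise ValueError("need at least one finite z-score")
    if z.size < 100:
        logger.info("genomic_control_lambda on %d z-scores; >=100 recommended", z.size)
    return float(np.median(z**2) / _CHI2_1_MEDIAN)


def apply_genomic_control(se, lam: float):
    """Inflate standard errors by √λ, with λ floored at 1 (no deflation)."""
    return np.asarray(se, dtype=float) * np.sqrt(max(1.0, float(lam)))


def combine_counts(cohorts: list[CohortCounts], label: str = "meta") -> CohortCounts:
    """Sum cases and controls across cohorts (the meta-analysis row)."""
    if not cohorts:
        raise ValueError("need at least one cohort")
    return CohortCounts(label, sum(c.cases for c in cohorts),
                        sum(c.controls for c in cohorts))


def meta_analyze_cohorts(
    cohorts: list[pd.DataFrame],
    model: str = "random",
    genomic_control: bool = True,
) -> pd.DataFrame:
    """Per-SNP meta-analysis of two or more cohort summary-stat tables.

    Tables must be pre-harmonized to a common effect allele per SNP.
    With ``genomic_control`` each cohort's SEs are first inflated by its
    genome-wide √λ (λ estimated from all of that cohort's z-scores,
    floored at 1).  SNPs present in only one cohort pass through.
    Returns a canonical-style table with extra q_stat/q_pvalue/tau2
    columns.
    """
    adjusted = []
    for df in cohorts:
        df = df.copy()
        if genomic_control:
            lam = genomic_control_lambda(df["beta"] / df["se"])
            df["se"] = apply_genomic_control(df["se"], lam)
            df.attrs["lambda_gc"] = lam
        adjusted.append(df.set_index(df["snp_id"].astype(str)))

    all_ids = list(dict.fromkeys(sid for df in adjusted for sid in df.index))
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # single-cohort pass-through is intended here
        for sid in all_ids:
            present = [df.loc[sid] for df in adjusted if sid in df.index]
            res = inverse_variance_meta([r["beta"] for r in present],
                                        [r["se"] for r in present],
                                        model=model, snp_id=sid)
            first = present[0]
            n_total = float(np.nansum([r.get("n", np.nan) for r in present]))
            eafs = [r["eaf"] for r in present if pd.notna(r.get("eaf", np.nan))]
            rows.append({
                "snp_id": sid, "chrom": first.get("chrom", ""), "pos": first.get("pos", np.nan),
                "effect_allele": first["effect_allele"], "other_allele": first["other_allele"],
                "eaf": float(np.mean(eafs)) if eafs else np.nan,
                "beta": res.beta_meta, "se": res.se_meta, "pvalue": res.pvalue,
                "n": n_total if n_total > 0 else np.nan,
                "q_stat": res.q_stat, "q_pvalue": res.q_pvalue, "tau2": res.tau2,
                "n_cohorts": len(present),
            })
    return pd.DataFrame(rows)
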