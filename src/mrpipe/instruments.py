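"""Instrument-strength diagnostics and inclusion filters.

Per-SNP variance explained uses R² = 2·MAF(1−MAF)·β² for a standardized
continuous exposure; instrument strength is F = R²(N−2)/(1−R²).  Power
for a binary outcome follows the standard two-sided normal approximation
with non-centrality |log OR|·√(N·R²·K(1−K)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class InstrumentDiagnostics:
    snp_id: str
    r2: float
    f_stat: float
    retained: bool = True
    reason: str = ""


@dataclass
class EligibilityVerdict:
    """Exposure-level verdict of the instrument inclusion rules."""

    eligible: bool
    reason: str
    set_r2: float
    best_power: float
    retained: list[InstrumentDiagnostics]
    removed: list[InstrumentDiagnostics]


def snp_r2(maf: float, beta: float) -> float:
    """Proportion of exposure variance explained by one SNP.

    ``maf`` must be the minor-allele frequency (fold frequencies above
    0.5 to ``1 − eaf`` before calling); ``beta`` is the per-allele effect
    in SD units of the exposure.
    """
    maf = float(maf)
    if not 0 < maf <= 0.5:
        if 0.5 < maf < 1:
            raise ValueError(f"maf {maf} > 0.5: fold to 1-eaf before calling")
        raise ValueError(f"maf must lie in (0, 0.5], got {maf}")
    return 2.0 * maf * (1.0 - maf) * float(beta) ** 2


def f_statistic(r2: float, n: float) -> float:
    """Instrument F statistic, F = R²(N−2)/(1−R²)."""
    r2, n = float(r2), float(n)
    if not 0 <= r2 < 1:
        raise ValueError(f"r2 must lie in [0, 1), got {r2}")
    if n <= 2:
        raise ValueError(f"n must exceed 2, got {n}")
    return r2 * (n - 2.0) / (1.0 - r2)


def mr_power_binary(
    n: float,
    r2: float,
    odds_ratio: float,
    case_fraction: float,
    alpha: float = 0.05,
) -> float:
    """Two-sided power of an MR test on a binary (case-control) outcome.

    Normal approximation: the IVW z-statistic under the alternative is
    centred at λ = |log OR|·√(N·R²·K(1−K)), where K is the case
    fraction, so power = Φ(λ − z_{1−α/2}) + Φ(−λ − z_{1−α/2}).  At
    OR = 1 this equals α by construction.
    """
    if not 0 < case_fraction < 1:
        raise ValueError("case_fraction must lie in (0,1)")
    if odds_ratio <= 0:
        raise ValueError("odds_ratio must be positive")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0,1)")
    if not 0 <= r2 < 1 or n <= 0:
        raise ValueError("need 0 <= r2 < 1 and n > 0")
    lam = abs(np.log(odds_ratio)) * np.sqrt(n * r2 * case_fraction * (1 - case_fraction))
    z = stats.norm.ppf(1 - alpha / 2)
    return float(stats.norm.cdf(lam - z) + stats.norm.cdf(-lam - z))


def effective_sample_size(cases: int, controls: int) -> float:
    """Balanced-design equivalent size, 4/(1/cases + 1/controls)."""
    if cases <= 0 or controls <= 0:
        raise ValueError("cases and controls must be positive")
    return 4.0 / (1.0 / cases + 1.0 / controls)


def diagnose_instruments(
    maf: np.ndarray,
    beta: np.ndarray,
    n: float,
    snp_ids: list[str] | None = None,
) -> list[InstrumentDiagnostics]:
    """Per-SNP R² and F for a clumped (independent) instrument set."""
    maf = np.minimum(np.asarray(maf, dtype=float), 1 - np.asarray(maf, dtype=float))
    beta = np.asarray(beta, dtype=float)
    ids = snp_ids or [f"snp{i}" for i in range(len(beta))]
    out = []
    for sid, m, b in zip(ids, maf, beta):
        r2 = snp_r2(m, b)
        out.append(InstrumentDiagnostics(sid, r2, f_statistic(r2, n)))
    return out


def apply_inclusion_filters(
    diagnostics: list[InstrumentDiagnostics],
    powers: list[float] | None = None,
    f_min: float = 10.0,
    set_r2_min: float = 0.01,
    power_min: float = 0.5,
) -> EligibilityVerdict:
    """Apply the instrument inclusion rules to one exposure.

    SNPs with F below ``f_min`` are removed.  The exposure is eligible
    when the surviving set explains more than ``set_r2_min`` of the
    exposure variance and/or the best available power across outcomes
    exceeds ``power_min``; with no surviving instruments it is flagged
    ``no_instruments``.
    """
    retained, removed = [], []
    for d in diagnostics:
        if d.f_stat < f_min:
            removed.append(InstrumentDiagnostics(d.snp_id, d.r2, d.f_stat, False,
                                                 f"F<{f_min:g}"))
        else:
            retained.append(d)
    set_r2 = float(sum(d.r2 for d in retained))
    best_power = float(max(powers)) if powers else 0.0
    if not retained:
        return EligibilityVerdict(False, "no_instruments", set_r2, best_power,
                                  retained, removed)
    eligible = (set_r2 > set_r2_min) or (best_power > power_min)
    reason = "" if eligible else f"set_r2<={set_r2_min:g} and power<={power_min:g}"
    return EligibilityVerdict(eligible, reason, set_r2, best_power, retained, removed)
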