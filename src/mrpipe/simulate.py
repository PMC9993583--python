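"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator emulates the statistical structure of a two-sample MR
study of a continuous (SD-unit) exposure on a binary, case-control
outcome observed in two independent cohorts:

* per-SNP exposure effects γⱼ scaled so the instrument set explains a
  chosen fraction of exposure variance, Σ 2pⱼ(1−pⱼ)γⱼ² = h²;
* observed exposure betas  b̂xⱼ ~ N(γⱼ, 1/(2pⱼ(1−pⱼ)·Nx));
* observed outcome log-ORs b̂yⱼ ~ N(θγⱼ + αⱼ, 1/(2pⱼ(1−pⱼ)·N·K(1−K)))
  per cohort, the logistic-regression asymptotic variance with K the
  case fraction;
* invalid instruments carry direct (pleiotropic) effects αⱼ, optionally
  correlated with γⱼ (an InSIDE violation).

Summary statistics are generated directly — no individual-level
genotypes — which gives exact control over instrument strength at desk
scale.  All randomness flows from a single seed through per-purpose
child generators, so outputs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .clump import LdMatrix

_BASES = np.array(["A", "C", "G", "T"])


@dataclass
class CohortSpec:
    n_cases: int
    n_controls: int
    name: str = ""

    @property
    def n_total(self) -> int:
        return self.n_cases + self.n_controls

    @property
    def case_fraction(self) -> float:
        return self.n_cases / self.n_total

    @property
    def n_eff(self) -> float:
        return 4.0 / (1.0 / self.n_cases + 1.0 / self.n_controls)


@dataclass
class PleiotropySpec:
    """Direct-effect configuration for invalid instruments.

    ``proportion_invalid`` of SNPs receive αⱼ ~ N(mean_alpha, sd_alpha²);
    with ``inside_violated`` the draw becomes αⱼ = c·γⱼ + noise so
    instrument strength and direct effects correlate.
    """

    proportion_invalid: float = 0.0
    mean_alpha: float = 0.0
    sd_alpha: float = 0.0
    inside_violated: bool = False
    inside_slope: float = 1.0


@dataclass
class SimulationConfig:
    """Generative parameters of one synthetic two-sample study.

    Defaults mirror the study conditions: a micronutrient-like exposure
    instrumented by a handful of genome-wide-significant SNPs explaining
    a few percent of variance, and two case-control cohorts at the
    sample sizes of the gastrointestinal-infection outcome.
    """

    m_snps: int = 10
    maf_range: tuple[float, float] = (0.05, 0.5)
    exposure_h2: float = 0.05
    n_exposure: int = 2603
    cohorts: list[CohortSpec] = field(default_factory=lambda: [
        CohortSpec(8991, 399_970, "cohortA"),
        CohortSpec(25_968, 234_437, "cohortB"),
    ])
    theta: float = 0.0
    pleiotropy: PleiotropySpec = field(default_factory=PleiotropySpec)
    ld: tuple[int, float] | None = None  # (block_size, ar1_rho)
    strand_flip_rate: float = 0.0
    palindromic_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not 0 < self.exposure_h2 < 1:
            raise ValueError("exposure_h2 must lie in (0,1)")
        if self.m_snps <= 0 or self.n_exposure <= 0:
            raise ValueError("sizes must be positive")
        if not 0 <= self.pleiotropy.proportion_invalid <= 1:
            raise ValueError("proportion_invalid must lie in [0,1]")
        if not self.cohorts:
            raise ValueError("need at least one outcome cohort")


@dataclass
class SimulationTruth:
    """Ground truth against which parameter recovery is judged."""

    theta: float
    gamma: np.ndarray
    alpha: np.ndarray
    maf: np.ndarray
    invalid_ids: set[str]
    snp_ids: list[str]
    cohorts: list[CohortSpec]

    def to_text(self) -> str:
        lines = [f"theta\t{self.theta!r}"]
        for sid, g, a in zip(self.snp_ids, self.gamma, self.alpha):
            lines.append(f"{sid}\tgamma={g!r}\talpha={a!r}")
        return "\n".join(lines) + "\n"


def _alleles(rng: np.random.Generator, m: int, palindromic: np.ndarray):
    ea = np.empty(m, dtype="<U1")
    oa = np.empty(m, dtype="<U1")
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    for j in range(m):
        a1 = rng.choice(_BASES)
        if palindromic[j]:
            a2 = comp[a1]
        else:
            a2 = rng.choice([b for b in _BASES if b not in (a1, comp[a1])])
        ea[j], oa[j] = a1, a2
    return ea, oa


def _table(snp_ids, chrom, pos, ea, oa, eaf, beta, se, n) -> pd.DataFrame:
    z = beta / se
    return pd.DataFrame({
        "snp_id": snp_ids, "chrom": chrom, "pos": pos,
        "effect_allele": ea, "other_allele": oa, "eaf": eaf,
        "beta": beta, "se": se,
        "pvalue": np.clip(2 * stats.norm.sf(np.abs(z)), np.finfo(float).tiny, 1.0),
        "n": n,
    })


def simulate_two_sample(config: SimulationConfig):
    """Generate exposure and per-cohort outcome summary statistics.

    Returns ``(exposure, outcomes, truth)`` — the exposure table, a list
    of per-cohort outcome tables (same SNPs), and the
    :class:`SimulationTruth`.  Optional strand flips and palindromic
    variants are injected into the outcome tables for harmonization
    testing; flipped rows stay statistically identical (allele, beta and
    EAF all recoded together).
    """
    config.validate()
    root = np.random.default_rng(config.seed)
    # independent child streams per purpose keep outputs stable when one
    # configuration knob changes
    r_maf, r_gamma, r_alpha, r_noise, r_allele, r_flip = root.spawn(6)

    m = config.m_snps
    maf = r_maf.uniform(*config.maf_range, size=m)
    snp_ids = [f"rs{1000 + j}" for j in range(m)]
    chrom = np.array([str(1 + j % 22) for j in range(m)])
    pos = np.arange(1, m + 1) * 1_000_000

    # raw effects scaled to the target variance explained
    raw = r_gamma.normal(1.0, 0.25, size=m) * r_gamma.choice([-1.0, 1.0], size=m)
    scale = np.sqrt(config.exposure_h2 / np.sum(2 * maf * (1 - maf) * raw**2))
    gamma = raw * scale

    p = config.pleiotropy
    n_invalid = int(round(p.proportion_invalid * m))
    invalid = np.zeros(m, dtype=bool)
    invalid[r_alpha.choice(m, size=n_invalid, replace=False)] = True
    alpha = np.zeros(m)
    if n_invalid:
        noise = r_alpha.normal(p.mean_alpha, max(p.sd_alpha, 0.0), size=m)
        if p.inside_violated:
            alpha[invalid] = p.inside_slope * gamma[invalid] + noise[invalid]
        else:
            alpha[invalid] = noise[invalid]

    palindromic = r_allele.random(m) < config.palindromic_rate
    ea, oa = _alleles(r_allele, m, palindromic)

    sx = 1.0 / np.sqrt(2 * maf * (1 - maf) * config.n_exposure)
    bx = r_noise.normal(gamma, sx)
    exposure = _table(snp_ids, chrom, pos, ea, oa, maf, bx, sx,
                      np.full(m, config.n_exposure))

    outcomes = []
    for c in config.cohorts:
        k_frac = c.case_fraction
        sy = 1.0 / np.sqrt(2 * maf * (1 - maf) * c.n_total * k_frac * (1 - k_frac))
        by = r_noise.normal(config.theta * gamma + alpha, sy)
        tbl = _table(snp_ids, chrom, pos, ea.copy(), oa.copy(), maf.copy(),
                     by, sy, np.full(m, c.n_total))
        if config.strand_flip_rate > 0:
            flip = r_flip.random(m) < config.strand_flip_rate
            comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
            # report the complementary strand: statistically a no-op
            tbl.loc[flip, "effect_allele"] = [comp[a] for a in tbl.loc[flip, "effect_allele"]]
            tbl.loc[flip, "other_allele"] = [comp[a] for a in tbl.loc[flip, "other_allele"]]
        outcomes.append(tbl)

    truth = SimulationTruth(config.theta, gamma, alpha, maf,
                            {snp_ids[j] for j in range(m) if alpha[j] != 0},
                            snp_ids, list(config.cohorts))
    return exposure, outcomes, truth


def simulate_ld_block(m: int, rho: float, spacing: int = 10_000,
                      start: int = 1, chrom: str = "1",
                      snp_ids: list[str] | None = None) -> LdMatrix:
    """AR(1) LD block: r²ᵢⱼ = ρ^(2|i−j|), positions on an arithmetic grid."""
    if not 0 <= rho < 1:
        raise ValueError("rho must lie in [0, 1)")
    idx = np.arange(m)
    r2 = rho ** (2 * np.abs(idx[:, None] - idx[None, :]))
    positions = start + idx * spacing
    ids = snp_ids or [f"rs{1000 + j}" for j in range(m)]
    return LdMatrix(ids, r2, positions)
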