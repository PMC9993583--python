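"""Full-study orchestration: eligibility, per-cohort and meta MR,
sensitivity battery, secondary analyses, bidirectional MR and
Bonferroni-corrected reporting.

A study is a grid of exposures × outcomes; each outcome is observed in
two (or more) cohorts plus their per-SNP meta-analysis.  For every
combination the pipeline clumps the exposure instruments, harmonizes
them against the outcome, applies the instrument-strength filters, runs
every applicable estimator (Cochran's Q needs ≥ 2 instruments;
Egger/median/mode/leave-one-out need ≥ 3), and flags nominal and
multiplicity-corrected significance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import estimators as est
from .clump import LdMatrix, clump
from .harmonize import EmptyOverlapError, HarmonizedSet, harmonize
from .instruments import (apply_inclusion_filters, diagnose_instruments,
                          mr_power_binary)
from .meta import CohortCounts, combine_counts, inverse_variance_meta, meta_analyze_cohorts
from .model import MRModel

logger = logging.getLogger(__name__)


def bonferroni_threshold(n_exposures: int, n_outcomes: int, alpha: float = 0.05) -> float:
    """Multiplicity-corrected significance level alpha/(exposures × outcomes)."""
    if n_exposures < 1 or n_outcomes < 1:
        raise ValueError("counts must be positive integers")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0,1)")
    return alpha / (n_exposures * n_outcomes)


@dataclass
class ExposureSpec:
    name: str
    stats: pd.DataFrame
    n_sample: float
    ld: LdMatrix | None = None


@dataclass
class OutcomeSpec:
    name: str
    cohorts: dict[str, pd.DataFrame]
    counts: dict[str, CohortCounts]

    def meta_counts(self) -> CohortCounts:
        return combine_counts(list(self.counts.values()))


@dataclass
class StudyConfig:
    exposures: list[ExposureSpec]
    outcomes: list[OutcomeSpec]
    r2_threshold: float = 0.001
    window_kb: int = 10_000
    p_threshold: float = 5e-8
    alpha: float = 0.05
    methods: list[str] = field(default_factory=lambda: [
        "ivw", "egger", "weighted_median", "simple_mode", "weighted_mode"])
    ivw_model: str = "multiplicative_random"
    genomic_control: bool = True
    meta_model: str = "random"
    f_min: float = 10.0
    or_alt: float = 0.9
    n_boot: int = 1000
    seed: int = 0
    exclude_snps: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.exposures or not self.outcomes:
            raise ValueError("need at least one exposure and one outcome")
        if min(self.r2_threshold, self.window_kb, self.p_threshold) <= 0:
            raise ValueError("thresholds must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0,1)")


@dataclass
class StudyResults:
    table: pd.DataFrame
    corrected_alpha: float
    log: list[str]

    def significant(self, corrected: bool = True) -> pd.DataFrame:
        col = "significant_corrected" if corrected else "significant_nominal"
        return self.table[self.table[col] == True]  # noqa: E712


def _battery_rows(mset: HarmonizedSet, exposure: str, outcome: str, cohort: str,
                  config: StudyConfig, log: list[str]) -> list[dict]:
    model = MRModel(mset, exposure=exposure, outcome=outcome)
    battery = model.fit_battery(
        methods=config.methods, seed=config.seed, n_boot=config.n_boot,
        ivw={"model": config.ivw_model})
    q = battery.q
    rows = []
    for _, row in battery.to_frame().iterrows():
        d = row.to_dict()
        d["cohort"] = cohort
        d["q_stat"] = q.q_stat if q is not None else np.nan
        d["q_pvalue"] = q.pvalue if q is not None else np.nan
        rows.append(d)
    return rows


def run_mr_study(config: StudyConfig) -> StudyResults:
    """Run the full study grid and return the long results table.

    Per-pair failures (no overlap, no surviving instruments, estimator
    errors) are recorded as rows with ``computed = False`` and never
    abort the study.  Deterministic given the config seed.
    """
    corrected = bonferroni_threshold(len(config.exposures), len(config.outcomes),
                                     config.alpha)
    log: list[str] = []
    rows: list[dict] = []

    for outc in config.outcomes:
        cohort_tables = dict(outc.cohorts)
        meta_tbl = meta_analyze_cohorts(
            list(cohort_tables.values()), model=config.meta_model,
            genomic_control=config.genomic_control)
        analyses = {**cohort_tables, "meta": meta_tbl}
        meta_cc = outc.meta_counts()

        for exp in config.exposures:
            stats_tbl = exp.stats
            if config.exclude_snps:
                before = len(stats_tbl)
                stats_tbl = stats_tbl[~stats_tbl["snp_id"].astype(str)
                                      .isin(config.exclude_snps)]
                if len(stats_tbl) < before:
                    log.append(f"{exp.name}: excluded "
                               f"{before - len(stats_tbl)} listed SNP(s)")
            if exp.ld is not None:
                stats_tbl = clump(stats_tbl, exp.ld, config.r2_threshold,
                                  config.window_kb, config.p_threshold)
                log.append(f"{exp.name}: {len(stats_tbl)} instruments after clumping")
            else:
                stats_tbl = stats_tbl[stats_tbl["pvalue"] <= config.p_threshold]

            for cohort_name, out_tbl in analyses.items():
                key = {"exposure": exp.name, "outcome": outc.name,
                       "cohort": cohort_name}
                try:
                    mset = harmonize(stats_tbl, out_tbl)
                except EmptyOverlapError as e:
                    log.append(f"{exp.name}/{outc.name}/{cohort_name}: {e}")
                    rows.append({**key, "method": "ivw", "computed": False,
                                 "reason": "empty_overlap"})
                    continue
                for sid, why in mset.exclusions:
                    log.append(f"{exp.name}/{outc.name}/{cohort_name}: "
                               f"excluded {sid} ({why})")
                if mset.n_snps == 0:
                    rows.append({**key, "method": "ivw", "computed": False,
                                 "reason": "no_instruments"})
                    continue

                # instrument-strength filter and exposure eligibility
                maf = np.where(np.isfinite(mset.eaf),
                               np.minimum(mset.eaf, 1 - mset.eaf), 0.25)
                diag = diagnose_instruments(maf, mset.bx, exp.n_sample, mset.snp_ids)
                power = mr_power_binary(
                    meta_cc.cases + meta_cc.controls,
                    sum(d.r2 for d in diag), config.or_alt,
                    meta_cc.cases / (meta_cc.cases + meta_cc.controls),
                    config.alpha)
                verdict = apply_inclusion_filters(diag, [power], f_min=config.f_min)
                for d in verdict.removed:
                    log.append(f"{exp.name}: removed {d.snp_id} ({d.reason})")
                keep = {d.snp_id for d in verdict.retained}
                mset = mset.subset(np.array([s in keep for s in mset.snp_ids]))
                if not verdict.eligible or mset.n_snps == 0:
                    rows.append({**key, "method": "ivw", "computed": False,
                                 "reason": verdict.reason or "ineligible"})
                    continue

                try:
                    for d in _battery_rows(mset, exp.name, outc.name,
                                           cohort_name, config, log):
                        rows.append(d)
                except Exception as e:  # record, never abort the grid
                    log.append(f"{exp.name}/{outc.name}/{cohort_name}: "
                               f"estimator failure {e!r}")
                    rows.append({**key, "method": "ivw", "computed": False,
                                 "reason": f"error:{type(e).__name__}"})

    table = pd.DataFrame(rows)
    for col in ("beta", "se", "ci_low", "ci_high", "pvalue", "q_stat", "q_pvalue"):
        if col not in table:
            table[col] = np.nan
    if "computed" not in table:
        table["computed"] = True
    table["computed"] = table["computed"].fillna(True).astype(bool)
    table["significant_nominal"] = table["computed"] & (table["pvalue"] < config.alpha)
    table["significant_corrected"] = table["computed"] & (table["pvalue"] < corrected)
    cols = ["exposure", "outcome", "cohort", "method"]
    table = table[cols + [c for c in table.columns if c not in cols]]
    return StudyResults(table.reset_index(drop=True), corrected, log)


def secondary_analysis(config: StudyConfig,
                       r2_threshold: float = 0.01,
                       p_threshold: float = 5e-6,
                       exclude_snps: list[str] | None = None) -> StudyResults:
    """Re-run the study at the liberal instrument thresholds with MR-RAPS.

    Weakly associated instruments increase power but risk weak-instrument
    bias, hence the RAPS estimator joins the battery.  ``exclude_snps``
    supports explicit removal of identified outlier variants.
    """
    import copy

    cfg = copy.copy(config)
    cfg.r2_threshold = r2_threshold
    cfg.p_threshold = p_threshold
    cfg.methods = list(config.methods) + (
        [] if "raps" in config.methods else ["raps"])
    cfg.exclude_snps = list(config.exclude_snps) + list(exclude_snps or [])
    return run_mr_study(cfg)


def bidirectional_mr(outcome_as_exposure: pd.DataFrame,
                     exposure_as_outcome: pd.DataFrame,
                     n_sample: float,
                     ld: LdMatrix | None = None,
                     r2_threshold: float = 0.01,
                     window_kb: int = 10_000,
                     p_threshold: float = 5e-6,
                     ivw_model: str = "multiplicative_random",
                     seed: int = 0,
                     n_boot: int = 1000):
    """Reverse-direction MR with the roles swapped.

    The former outcome's instruments (selected at the liberal
    thresholds) are used to estimate its effect on the former exposure.
    The result is on the outcome-beta scale — for a continuous former
    exposure this is an SD difference, not an OR.
    """
    tbl = outcome_as_exposure
    if ld is not None:
        tbl = clump(tbl, ld, r2_threshold, window_kb, p_threshold)
    else:
        tbl = tbl[tbl["pvalue"] <= p_threshold]
    mset = harmonize(tbl, exposure_as_outcome)
    if mset.n_snps == 0:
        raise EmptyOverlapError("no harmonizable SNPs in the reverse direction")
    model = MRModel(mset, exposure="reverse_exposure", outcome="reverse_outcome")
    return model.fit_battery(seed=seed, n_boot=n_boot, ivw={"model": ivw_model})


def replication_meta(primary: est.MREstimate, replication: est.MREstimate):
    """Fixed-effect pool of a primary and a replication causal estimate."""
    for e in (primary, replication):
        if not e.computed:
            raise ValueError("cannot pool a not-computed estimate")
    return inverse_variance_meta([primary.beta, replication.beta],
                                 [primary.se, replication.se], model="fixed")


def simulate_study(
    theta: dict[tuple[str, str], float] | None = None,
    n_exposures: int = 8,
    outcome_counts: dict[str, list[CohortCounts]] | None = None,
    m_snps: int | list[int] = 10,
    exposure_h2: float = 0.08,
    n_exposure: int = 10_000,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
    **config_kw,
) -> StudyConfig:
    """Build a complete synthetic study grid with known causal structure.

    Each exposure gets its own independent instrument set (distinct SNP
    ids, per-SNP effects scaled to ``exposure_h2``); every outcome is
    observed in each of its cohorts, whose per-SNP effects are
    θ(exposure, outcome)·γ plus case-control-scale noise
    (Var = 1/(2p(1−p)·N·K(1−K))).  ``theta`` maps (exposure name,
    outcome name) to the causal log-OR; unmapped pairs are null.  The
    default outcome cohorts reproduce the case/control bookkeeping of a
    two-biobank infection study.  Deterministic given ``seed``.
    """
    from scipy import stats as _st

    if outcome_counts is None:
        outcome_counts = {
            "gi": [CohortCounts("biobankA", 8991, 399_970),
                   CohortCounts("biobankB", 25_968, 234_437)],
            "pneumonia": [CohortCounts("biobankA", 6710, 398_538),
                          CohortCounts("biobankB", 9878, 223_587)],
            "uti": [CohortCounts("biobankA", 12_491, 379_936),
                    CohortCounts("biobankB", 19_479, 231_480)],
        }
    theta = theta or {}
    m_list = [m_snps] * n_exposures if isinstance(m_snps, int) else list(m_snps)
    root = np.random.default_rng(seed)
    streams = root.spawn(n_exposures)
    bases = "ACGT"

    exposures: list[ExposureSpec] = []
    outcome_rows: dict[str, dict[str, list[pd.DataFrame]]] = {
        o: {cc.cohort: [] for cc in cohorts} for o, cohorts in outcome_counts.items()}

    for e_idx, (m, rng) in enumerate(zip(m_list, streams)):
        name = f"exposure{e_idx}"
        maf = rng.uniform(*maf_range, size=m)
        raw = rng.normal(1.0, 0.25, size=m) * rng.choice([-1.0, 1.0], size=m)
        gamma = raw * np.sqrt(exposure_h2 / np.sum(2 * maf * (1 - maf) * raw**2))
        sx = 1.0 / np.sqrt(2 * maf * (1 - maf) * n_exposure)
        bx = rng.normal(gamma, sx)
        ids = [f"rs{e_idx}_{j}" for j in range(m)]
        ea = [bases[int(b)] for b in rng.integers(0, 2, size=m)]        # A or C
        oa = ["G" if a in "AC" else "T" for a in ea]                    # never palindromic
        base = {
            "snp_id": ids, "chrom": [str(1 + e_idx % 22)] * m,
            "pos": (np.arange(m) + 1) * 1_000_000 + e_idx,
            "effect_allele": ea, "other_allele": oa, "eaf": maf,
        }
        zx = bx / sx
        exposures.append(ExposureSpec(name, pd.DataFrame({
            **base, "beta": bx, "se": sx,
            "pvalue": np.clip(2 * _st.norm.sf(np.abs(zx)), np.finfo(float).tiny, 1),
            "n": np.full(m, n_exposure),
        }), n_sample=n_exposure))

        for o_name, cohorts in outcome_counts.items():
            th = theta.get((name, o_name), 0.0)
            for cc in cohorts:
                n_tot = cc.cases + cc.controls
                kf = cc.cases / n_tot
                sy = 1.0 / np.sqrt(2 * maf * (1 - maf) * n_tot * kf * (1 - kf))
                by = rng.normal(th * gamma, sy)
                zy = by / sy
                outcome_rows[o_name][cc.cohort].append(pd.DataFrame({
                    **base, "beta": by, "se": sy,
                    "pvalue": np.clip(2 * _st.norm.sf(np.abs(zy)),
                                      np.finfo(float).tiny, 1),
                    "n": np.full(m, n_tot),
                }))

    outcomes = [
        OutcomeSpec(o_name,
                    cohorts={c: pd.concat(frames, ignore_index=True)
                             for c, frames in per_cohort.items()},
                    counts={cc.cohort: cc for cc in outcome_counts[o_name]})
        for o_name, per_cohort in outcome_rows.items()]
    return StudyConfig(exposures=exposures, outcomes=outcomes, seed=seed, **config_kw)
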