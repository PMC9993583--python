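"""Model/Results interface over the MR estimator battery.

:class:`MRModel` is built from a harmonized exposure–outcome instrument
set; ``fit(method=...)`` returns an :class:`MRResults` for one
estimator, and ``fit_battery()`` runs the full sensitivity battery.
:class:`MVMRModel` fits the multivariable extension with several
exposures jointly.  Both follow the statsmodels convention: the model
object holds the data and configuration, the results object holds the
estimates, their uncertainties and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.iolib.table import SimpleTable

from . import estimators as est
from .estimators import MREstimate, QResult
from .harmonize import HarmonizedSet

DEFAULT_METHODS = ["ivw", "egger", "weighted_median", "simple_mode", "weighted_mode"]


class MRModel:
    """Univariable two-sample MR model for one exposure–outcome pair.

    Parameters
    ----------
    data
        A :class:`~mrpipe.harmonize.HarmonizedSet`, or a DataFrame with
        columns ``snp_id, bx, sx, by, sy`` (``eaf`` optional).
    exposure, outcome
        Labels used in summaries.
    """

    def __init__(self, data: HarmonizedSet | pd.DataFrame,
                 exposure: str = "exposure", outcome: str = "outcome"):
        if isinstance(data, pd.DataFrame):
            data = HarmonizedSet.from_frame(data)
        self.data = data
        self.exposure = exposure
        self.outcome = outcome

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kw) -> "MRModel":
        return cls(df, **kw)

    @property
    def n_snps(self) -> int:
        return self.data.n_snps

    def fit(self, method: str = "ivw", level: float = 0.95, seed: int | None = None,
            n_boot: int = 1000, **kw) -> "MRResults":
        """Fit one estimator; see :mod:`mrpipe.estimators` for the math.

        ``method`` is one of ``ivw`` (kw ``model``), ``wald``, ``egger``
        (slope, with the intercept attached), ``weighted_median``,
        ``simple_mode``, ``weighted_mode`` (bootstrap methods require
        ``seed``), or ``raps`` (kw ``overdispersion``, ``loss``).
        """
        s = self.data
        intercept = None
        q = est.cochran_q_mr(s) if s.n_snps >= 2 else None
        if method == "ivw":
            e = est.ivw(s, level=level, **kw)
        elif method == "wald":
            if s.n_snps != 1:
                raise ValueError("wald requires exactly one SNP; use ivw")
            e = est.wald_ratio(s.bx[0], s.sx[0], s.by[0], s.sy[0], level=level, **kw)
        elif method == "egger":
            e, intercept = est.mr_egger(s, level=level)
        elif method == "weighted_median":
            e = est.weighted_median(s, n_boot=n_boot, seed=seed, level=level, **kw)
        elif method in ("simple_mode", "weighted_mode"):
            e = est.mode_estimate(s, weighted=(method == "weighted_mode"),
                                  n_boot=n_boot, seed=seed, level=level, **kw)
        elif method == "raps":
            e = est.mr_raps(s, seed=seed, level=level, **kw)
        else:
            raise ValueError(f"unknown method {method!r}")
        return MRResults(self, e, intercept=intercept, q=q)

    def fit_battery(self, methods: list[str] | None = None, seed: int | None = None,
                    n_boot: int = 1000, level: float = 0.95, **kw) -> "MRBatteryResults":
        """Run several estimators plus Q and leave-one-out in one call."""
        methods = methods or DEFAULT_METHODS
        fits = [self.fit(m, level=level, seed=seed, n_boot=n_boot, **kw.get(m, {}))
                for m in methods]
        loo = est.leave_one_out(self.data) if self.data.n_snps >= 3 else None
        q = est.cochran_q_mr(self.data) if self.data.n_snps >= 2 else None
        return MRBatteryResults(self, fits, q=q, loo=loo)


class MRResults:
    """Estimates and diagnostics from one :class:`MRModel` fit."""

    def __init__(self, model: MRModel, estimate: MREstimate,
                 intercept: MREstimate | None = None, q: QResult | None = None):
        self.model = model
        self.estimate = estimate
        self.intercept = intercept
        self.q = q

    # statsmodels-flavoured accessors
    @property
    def params(self) -> float:
        return self.estimate.beta

    @property
    def bse(self) -> float:
        return self.estimate.se

    @property
    def pvalue(self) -> float:
        return self.estimate.pvalue

    @property
    def conf_int(self) -> tuple[float, float]:
        return self.estimate.ci_low, self.estimate.ci_high

    @property
    def odds_ratio(self) -> tuple[float, float, float]:
        return self.estimate.or_scale()

    def summary(self) -> SimpleTable:
        rows = [_estimate_row(self.estimate)]
        if self.intercept is not None:
            rows.append(_estimate_row(self.intercept))
        tbl = SimpleTable(
            rows, headers=_HEADERS,
            title=(f"Two-sample MR: {self.model.exposure} -> {self.model.outcome}"
                   f" ({self.estimate.n_snps} SNPs)"))
        return tbl

    def __repr__(self) -> str:
        e = self.estimate
        return (f"<MRResults {e.method} beta={e.beta:.4g} se={e.se:.4g} "
                f"p={e.pvalue:.3g} n_snps={e.n_snps}>")


class MRBatteryResults:
    """The full sensitivity battery for one exposure–outcome pair."""

    def __init__(self, model: MRModel, fits: list[MRResults],
                 q: QResult | None = None, loo: list[MREstimate] | None = None):
        self.model = model
        self.fits = fits
        self.q = q
        self.loo = loo

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for f in self.fits:
            for e in ([f.estimate] + ([f.intercept] if f.intercept is not None else [])):
                orr = e.or_scale() if e.computed else (np.nan, np.nan, np.nan)
                rows.append({
                    "exposure": self.model.exposure, "outcome": self.model.outcome,
                    "method": e.method, "beta": e.beta, "se": e.se,
                    "ci_low": e.ci_low, "ci_high": e.ci_high, "pvalue": e.pvalue,
                    "n_snps": e.n_snps, "or": orr[0], "or_ci_low": orr[1],
                    "or_ci_high": orr[2], "computed": e.computed, "reason": e.reason,
                })
        return pd.DataFrame(rows)

    def summary(self) -> SimpleTable:
        rows = [_estimate_row(f.estimate) for f in self.fits]
        for f in self.fits:
            if f.intercept is not None:
                rows.append(_estimate_row(f.intercept))
        title = f"MR battery: {self.model.exposure} -> {self.model.outcome}"
        if self.q is not None and self.q.computed:
            title += f"  (Q={self.q.q_stat:.2f}, df={self.q.df}, p={self.q.pvalue:.3g})"
        return SimpleTable(rows, headers=_HEADERS, title=title)


_HEADERS = ["method", "beta", "se", "ci95", "p", "OR (95% CI)", "nSNP"]


def _estimate_row(e: MREstimate) -> list[str]:
    if not e.computed:
        return [e.method, "-", "-", "-", "-", f"not computed: {e.reason}", str(e.n_snps)]
    o, lo, hi = e.or_scale()
    return [e.method, f"{e.beta:.4f}", f"{e.se:.4f}",
            f"[{e.ci_low:.4f}, {e.ci_high:.4f}]", f"{e.pvalue:.2e}",
            f"{o:.2f} ({lo:.2f}-{hi:.2f})", str(e.n_snps)]


# ---------------------------------------------------------------------------
# Multivariable MR


@dataclass
class MvmrSet:
    """Per-SNP effects for E exposures jointly with one outcome."""

    snp_ids: list[str]
    bx_matrix: np.ndarray  # (k, E)
    sx_matrix: np.ndarray  # (k, E)
    by: np.ndarray
    sy: np.ndarray
    exposures: list[str] | None = None

    def __post_init__(self) -> None:
        self.bx_matrix = np.atleast_2d(np.asarray(self.bx_matrix, dtype=float))
        self.sx_matrix = np.atleast_2d(np.asarray(self.sx_matrix, dtype=float))
        self.by = np.asarray(self.by, dtype=float)
        self.sy = np.asarray(self.sy, dtype=float)
        k, e = self.bx_matrix.shape
        if e < 2:
            raise ValueError("multivariable MR needs at least 2 exposures")
        if k < e + 1:
            raise ValueError("need more SNPs than exposures")
        if self.sx_matrix.shape != (k, e) or self.by.shape != (k,) or self.sy.shape != (k,):
            raise ValueError("inconsistent MVMR dimensions")
        if np.any(self.sy <= 0):
            raise ValueError("outcome SEs must be positive")
        if self.exposures is None:
            self.exposures = [f"exposure{j}" for j in range(e)]

    @property
    def n_snps(self) -> int:
        return self.bx_matrix.shape[0]

    @property
    def n_exposures(self) -> int:
        return self.bx_matrix.shape[1]


class CollinearityError(np.linalg.LinAlgError):
    pass


class MVMRModel:
    """Multivariable two-sample MR: joint direct effects of E exposures.

    The instrument set is the union of the exposures' instruments,
    harmonized to one orientation; the fit is the through-origin
    regression of by on the columns of bx with weights 1/sy².
    """

    def __init__(self, data: MvmrSet, outcome: str = "outcome"):
        self.data = data
        self.outcome = outcome

    def fit(self, level: float = 0.95) -> "MVMRResults":
        d = self.data
        k, e = d.n_snps, d.n_exposures
        w = 1.0 / d.sy**2
        # an exposure whose effect column is identically zero carries no
        # signal; drop it from the regression (reported as not computed)
        # so the remaining exposures reduce to the nested model
        active = [j for j in range(e) if np.any(d.bx_matrix[:, j] != 0)]
        X, y = d.bx_matrix[:, active], d.by
        xtwx = X.T @ (w[:, None] * X)
        if np.linalg.cond(xtwx) > 1e10:
            corr = np.corrcoef(X.T)
            off = np.abs(corr - np.eye(len(active)))
            worst = np.unravel_index(np.argmax(off), off.shape)
            raise CollinearityError(
                "exposure effect columns are collinear (worst pair: "
                f"{d.exposures[active[worst[0]]]}, {d.exposures[active[worst[1]]]})")
        coef = np.linalg.solve(xtwx, X.T @ (w * y))
        resid = y - X @ coef
        scale = float(np.sum(w * resid**2) / (k - len(active)))
        cov = np.linalg.inv(xtwx) * max(1.0, scale)
        ses = np.sqrt(np.diag(cov))

        z = stats.norm.ppf(0.5 + level / 2)
        estimates = []
        for j, name in enumerate(d.exposures):
            if j not in active:
                nc = MREstimate.not_computed("mvmr_ivw", "all-zero effect column", k)
                nc.label = name
                estimates.append(nc)
                continue
            a = active.index(j)
            b, se = float(coef[a]), float(ses[a])
            p = 2 * float(stats.norm.sf(abs(b / se)))
            estimates.append(MREstimate("mvmr_ivw", b, se, b - z * se, b + z * se,
                                        p, k, level=level, label=name))
        cond_f = self._conditional_f()
        return MVMRResults(self, estimates, cond_f, scale)

    def _conditional_f(self) -> list[float]:
        """Sanderson–Windmeijer-style conditional instrument strength.

        For each exposure, regress its SNP effects on the other
        exposures' effects (weights 1/sx²) and measure the precision-
        scaled residual variation per spare instrument.  Reported as a
        diagnostic, not used as a filter.
        """
        d = self.data
        k, e = d.n_snps, d.n_exposures
        out = []
        for j in range(e):
            others = [c for c in range(e) if c != j]
            Xo = d.bx_matrix[:, others]
            yj = d.bx_matrix[:, j]
            wj = 1.0 / d.sx_matrix[:, j] ** 2
            coef, *_ = np.linalg.lstsq(np.sqrt(wj)[:, None] * Xo,
                                       np.sqrt(wj) * yj, rcond=None)
            resid = yj - Xo @ coef
            qx = float(np.sum(wj * resid**2))
            out.append(qx / (k - e + 1))
        return out


class MVMRResults:
    def __init__(self, model: MVMRModel, estimates: list[MREstimate],
                 conditional_f: list[float], scale: float):
        self.model = model
        self.estimates = estimates
        self.conditional_f = conditional_f
        self.scale = scale

    @property
    def params(self) -> np.ndarray:
        return np.array([e.beta for e in self.estimates])

    @property
    def bse(self) -> np.ndarray:
        return np.array([e.se for e in self.estimates])

    @property
    def pvalues(self) -> np.ndarray:
        return np.array([e.pvalue for e in self.estimates])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "exposure": e.label, "method": e.method, "beta": e.beta, "se": e.se,
            "ci_low": e.ci_low, "ci_high": e.ci_high, "pvalue": e.pvalue,
            "n_snps": e.n_snps, "conditional_F": f,
        } for e, f in zip(self.estimates, self.conditional_f)])

    def summary(self) -> SimpleTable:
        rows = []
        for e, f in zip(self.estimates, self.conditional_f):
            o, lo, hi = e.or_scale()
            rows.append([e.label, f"{e.beta:.4f}", f"{e.se:.4f}",
                         f"[{e.ci_low:.4f}, {e.ci_high:.4f}]", f"{e.pvalue:.2e}",
                         f"{o:.2f} ({lo:.2f}-{hi:.2f})", f"{f:.1f}"])
        return SimpleTable(
            rows,
            headers=["exposure", "beta", "se", "ci95", "p", "OR (95% CI)", "cond. F"],
            title=(f"Multivariable MR -> {self.model.outcome} "
                   f"({self.model.data.n_snps} SNPs)"))
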