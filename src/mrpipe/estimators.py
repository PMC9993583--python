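"""Two-sample MR causal estimators and per-analysis heterogeneity.

Every estimator consumes a :class:`~mrpipe.harmonize.HarmonizedSet` of
per-SNP exposure effects (bx, sx) and outcome effects (by, sy) expressed
for a common effect allele, and returns an :class:`MREstimate` on the
log-OR (or outcome-beta) scale per SD of exposure.

The battery follows the standard division of labour:

* Wald ratio / IVW assume all instruments valid;
* MR-Egger allows directional pleiotropy under InSIDE, its intercept
  testing for it;
* the weighted median tolerates up to half the weight on invalid
  instruments;
* the mode estimators assume only that the largest cluster of ratio
  estimates is valid;
* MR-RAPS models the exposure-side measurement error explicitly and is
  robust to weak instruments and idiosyncratic pleiotropy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize, stats

from .harmonize import HarmonizedSet

__all__ = [
    "MREstimate", "QResult", "ConvergenceError",
    "wald_ratio", "ivw", "mr_egger", "weighted_median", "mode_estimate",
    "mr_raps", "cochran_q_mr", "leave_one_out", "to_odds_ratio",
]


class ConvergenceError(RuntimeError):
    """An iterative estimator failed to locate a root."""


@dataclass
class MREstimate:
    """One causal-effect estimate with its uncertainty.

    ``beta`` is on the log-OR scale for binary outcomes (outcome-beta
    scale for continuous ones); ``or_scale()`` exponentiates.  A method
    that is inapplicable for the given instrument count is represented
    by a not-computed marker (``computed`` False), not an exception.
    """

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snps: int
    level: float = 0.95
    label: str = ""
    computed: bool = True
    reason: str = ""

    @classmethod
    def not_computed(cls, method: str, reason: str, n_snps: int) -> "MREstimate":
        nan = float("nan")
        return cls(method, nan, nan, nan, nan, nan, n_snps,
                   computed=False, reason=reason)

    def or_scale(self) -> tuple[float, float, float]:
        """(OR, CI low, CI high) — exp of the beta-scale fields."""
        return math.exp(self.beta), math.exp(self.ci_low), math.exp(self.ci_high)


@dataclass
class QResult:
    q_stat: float
    df: int
    pvalue: float
    computed: bool = True
    reason: str = ""

    @property
    def heterogeneous(self) -> bool:
        return self.computed and self.pvalue < 0.05


def _finish(method: str, beta: float, se: float, pvalue: float, n_snps: int,
            level: float = 0.95, label: str = "") -> MREstimate:
    z = stats.norm.ppf(0.5 + level / 2)
    return MREstimate(method, float(beta), float(se), float(beta - z * se),
                      float(beta + z * se), float(pvalue), int(n_snps),
                      level=level, label=label)


def to_odds_ratio(beta: float, se: float, level: float = 0.95) -> tuple[float, float, float]:
    """Convert a log-OR and its SE into an OR with a Wald CI."""
    if se <= 0:
        raise ValueError("se must be positive")
    z = stats.norm.ppf(0.5 + level / 2)
    return math.exp(beta), math.exp(beta - z * se), math.exp(beta + z * se)


# ---------------------------------------------------------------------------
# Wald ratio and IVW


def wald_ratio(bx: float, sx: float, by: float, sy: float,
               second_order: bool = False, level: float = 0.95) -> MREstimate:
    """Single-SNP causal estimate by/bx.

    The first-order delta-method SE is sy/|bx|; ``second_order`` adds the
    exposure-uncertainty term by²sx²/bx⁴ under the square root.
    """
    if bx == 0:
        raise ZeroDivisionError("undefined Wald ratio: exposure beta is zero")
    beta = by / bx
    var = (sy / bx) ** 2
    if second_order:
        var += by**2 * sx**2 / bx**4
    se = math.sqrt(var)
    p = 2 * float(stats.norm.sf(abs(beta / se)))
    return _finish("wald", beta, se, p, 1, level)


def _ratio_stats(s: HarmonizedSet, second_order: bool = False):
    """Per-SNP Wald ratios and their delta-method SEs."""
    if np.any(s.bx == 0):
        raise ZeroDivisionError("exposure beta of zero in the instrument set")
    r = s.by / s.bx
    var = (s.sy / s.bx) ** 2
    if second_order:
        var += s.by**2 * s.sx**2 / s.bx**4
    return r, np.sqrt(var)


def ivw(s: HarmonizedSet, model: str = "multiplicative_random",
        level: float = 0.95) -> MREstimate:
    """Inverse-variance-weighted estimate.

    Equivalent to the through-origin regression of by on bx with weights
    1/sy², and to the 1/se²-weighted mean of the per-SNP Wald ratios.
    ``fixed`` uses SE = 1/√(Σ bx²/sy²); ``multiplicative_random``
    multiplies it by the residual scale √(Q/(k−1)) floored at 1.  With a
    single SNP this reduces exactly to the Wald ratio.
    """
    if model not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown IVW model {model!r}")
    k = s.n_snps
    if k == 0:
        raise ValueError("empty instrument set")
    if np.any(s.bx == 0):
        raise ZeroDivisionError("exposure beta of zero in the instrument set")
    w = 1.0 / s.sy**2
    beta = float(np.sum(w * s.bx * s.by) / np.sum(w * s.bx**2))
    se = float(1.0 / np.sqrt(np.sum(w * s.bx**2)))
    method = "ivw_fixed"
    if model == "multiplicative_random" and k > 1:
        q = float(np.sum(w * (s.by - beta * s.bx) ** 2))
        se *= math.sqrt(max(1.0, q / (k - 1)))
        method = "ivw_mre"
    elif model == "multiplicative_random":
        method = "ivw_mre"
    p = 2 * float(stats.norm.sf(abs(beta / se)))
    return _finish(method, beta, se, p, k, level)


# ---------------------------------------------------------------------------
# MR-Egger


def mr_egger(s: HarmonizedSet, level: float = 0.95) -> tuple[MREstimate, MREstimate]:
    """Egger regression: by on bx with an intercept, weights 1/sy².

    Each SNP is first oriented so bx > 0 (flipping by with it).  A
    non-zero intercept indicates directional pleiotropy; the slope is
    the pleiotropy-adjusted causal effect under InSIDE.  SEs use the
    residual scale floored at 1; p-values use t with k−2 df.
    """
    k = s.n_snps
    if k < 3:
        nc = MREstimate.not_computed("egger_slope", "fewer than 3 instruments", k)
        return nc, replace(nc, method="egger_intercept")
    sign = np.where(s.bx < 0, -1.0, 1.0)
    bx, by, sy = s.bx * sign, s.by * sign, s.sy
    w = 1.0 / sy**2
    X = np.column_stack([np.ones(k), bx])
    xtwx = X.T @ (w[:, None] * X)
    xtwy = X.T @ (w * by)
    coef = np.linalg.solve(xtwx, xtwy)
    resid = by - X @ coef
    scale = float(np.sum(w * resid**2) / (k - 2))
    cov = np.linalg.inv(xtwx) * max(1.0, scale)
    ses = np.sqrt(np.diag(cov))
    tcrit = stats.t.ppf(0.5 + level / 2, k - 2)

    out = []
    for name, b, se in (("egger_intercept", coef[0], ses[0]),
                        ("egger_slope", coef[1], ses[1])):
        p = 2 * float(stats.t.sf(abs(b / se), k - 2))
        out.append(MREstimate(name, float(b), float(se), float(b - tcrit * se),
                              float(b + tcrit * se), p, k, level=level))
    return out[1], out[0]


# ---------------------------------------------------------------------------
# Weighted median


def _weighted_median_point(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    v = values[order]
    w = weights[order] / np.sum(weights)
    # midpoint convention: cumulative weight at the centre of each step
    cum = np.cumsum(w) - 0.5 * w
    return float(np.interp(0.5, cum, v))


def weighted_median(s: HarmonizedSet, n_boot: int = 1000, seed: int | None = None,
                    second_order: bool = False, level: float = 0.95) -> MREstimate:
    """Weighted median of the per-SNP Wald ratios.

    Variants are ordered by their ratio estimates; weights proportional
    to inverse ratio variance are cumulated and the estimate is the
    linear interpolation at cumulative weight one half.  Consistent when
    valid instruments carry more than half the weight.  The SE comes
    from a parametric bootstrap (resampling bx, by from their SEs) with
    a caller-supplied seed.
    """
    k = s.n_snps
    if k < 3:
        return MREstimate.not_computed("weighted_median", "fewer than 3 instruments", k)
    if seed is None:
        raise ValueError("seed is required for the bootstrap")
    r, sr = _ratio_stats(s, second_order)
    w = 1.0 / sr**2
    beta = _weighted_median_point(r, w)
    se = _bootstrap_se(s, lambda rr, ww: _wm_vec(rr, ww), n_boot, seed, second_order)
    p = 2 * float(stats.norm.sf(abs(beta / se)))
    return _finish("weighted_median", beta, se, p, k, level)


def _wm_vec(ratios: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Row-wise weighted median of a (B, k) ratio matrix."""
    order = np.argsort(ratios, axis=1)
    v = np.take_along_axis(ratios, order, axis=1)
    w = np.take_along_axis(weights, order, axis=1)
    w = w / w.sum(axis=1, keepdims=True)
    cum = np.cumsum(w, axis=1) - 0.5 * w
    out = np.empty(len(v))
    for i in range(len(v)):
        out[i] = np.interp(0.5, cum[i], v[i])
    return out


def _bootstrap_se(s: HarmonizedSet, estimator, n_boot: int, seed: int,
                  second_order: bool) -> float:
    rng = np.random.default_rng(seed)
    bx = rng.normal(s.bx, s.sx, size=(n_boot, s.n_snps))
    by = rng.normal(s.by, s.sy, size=(n_boot, s.n_snps))
    bx = np.where(bx == 0, np.finfo(float).tiny, bx)
    r = by / bx
    var = (s.sy / bx) ** 2
    if second_order:
        var += by**2 * s.sx**2 / bx**4
    est = estimator(r, 1.0 / var)
    return float(np.std(est, ddof=1))


# ---------------------------------------------------------------------------
# Mode-based estimators


def _silverman_bandwidth(r: np.ndarray, phi: float) -> float:
    """Modified Silverman rule on the ratio estimates (MAD-robust)."""
    n = len(r)
    sd = np.std(r, ddof=1)
    mad = stats.median_abs_deviation(r, scale="normal")
    spread = min(sd, mad) if mad > 0 else sd
    if spread == 0:
        spread = max(abs(np.mean(r)), 1.0) * 1e-8
    return float(phi * 0.9 * spread * n ** (-1 / 5))


def _mode_vec(ratios: np.ndarray, weights: np.ndarray, phi: float) -> np.ndarray:
    """Row-wise kernel-density mode of a (B, k) ratio matrix."""
    B = ratios.shape[0]
    out = np.empty(B)
    for i in range(B):
        r, w = ratios[i], weights[i]
        h = _silverman_bandwidth(r, phi)
        grid = np.linspace(r.min() - 3 * h, r.max() + 3 * h, 512)
        dens = np.sum(w[None, :] * np.exp(-0.5 * ((grid[:, None] - r[None, :]) / h) ** 2),
                      axis=1)
        out[i] = grid[np.argmax(dens)]
    return out


def mode_estimate(s: HarmonizedSet, weighted: bool = True, phi: float = 1.0,
                  n_boot: int = 1000, seed: int | None = None,
                  second_order: bool = False, level: float = 0.95) -> MREstimate:
    """Mode of the kernel-smoothed density of the Wald ratios.

    Assumes the largest cluster of ratio estimates reflects the true
    causal effect (zero modal pleiotropy).  The ``weighted`` variant
    weights each kernel by inverse ratio variance; the simple variant
    uses unit weights.  Bandwidth is ``phi`` times a MAD-robust
    Silverman rule.  SE via parametric bootstrap.
    """
    k = s.n_snps
    method = "weighted_mode" if weighted else "simple_mode"
    if k < 3:
        return MREstimate.not_computed(method, "fewer than 3 instruments", k)
    if seed is None:
        raise ValueError("seed is required for the bootstrap")
    r, sr = _ratio_stats(s, second_order)
    w = 1.0 / sr**2 if weighted else np.ones(k)
    beta = float(_mode_vec(r[None, :], w[None, :], phi)[0])
    if weighted:
        se = _bootstrap_se(s, lambda rr, ww: _mode_vec(rr, ww, phi), n_boot, seed,
                           second_order)
    else:
        se = _bootstrap_se(s, lambda rr, ww: _mode_vec(rr, np.ones_like(rr), phi),
                           n_boot, seed, second_order)
    p = 2 * float(stats.norm.sf(abs(beta / se)))
    return _finish(method, beta, se, p, k, level)


# ---------------------------------------------------------------------------
# MR-RAPS


def _huber_rho_prime(t: np.ndarray, k: float = 1.345) -> np.ndarray:
    return np.clip(t, -k, k)


def mr_raps(s: HarmonizedSet, overdispersion: bool = True, loss: str = "huber",
            seed: int | None = None, level: float = 0.95,
            huber_k: float = 1.345) -> MREstimate:
    """Robust adjusted profile score estimator.

    Solves the profile-score equation Σⱼ ρ′(tⱼ(β))·∂tⱼ/∂β = 0 with
    standardized residuals tⱼ(β) = (byⱼ − β·bxⱼ)/√(syⱼ² + β²sxⱼ² + τ²).
    Modelling the exposure-side error sxⱼ removes regression-dilution
    (weak-instrument) bias; the overdispersion parameter τ² absorbs
    idiosyncratic pleiotropy; the Huber loss bounds the influence of
    outlying instruments.  With ρ the squared-error loss, sx → 0 and
    τ² = 0 this reduces to fixed-effect IVW.  SE from the sandwich of
    the profile score.
    """
    k = s.n_snps
    if k < 3:
        return MREstimate.not_computed("raps", "fewer than 3 instruments", k)
    if loss not in ("l2", "huber"):
        raise ValueError(f"unknown loss {loss!r}")

    if loss == "l2":
        rho_prime = lambda t: t
        delta1 = 1.0                      # E[rho'(Z) Z]
        delta2 = 1.0                      # E[rho'(Z)^2]
    else:
        rho_prime = lambda t: _huber_rho_prime(t, huber_k)
        delta1 = 2 * stats.norm.cdf(huber_k) - 1
        delta2 = float(delta1 - 2 * huber_k * stats.norm.pdf(huber_k)
                       + 2 * huber_k**2 * stats.norm.sf(huber_k))

    bx, sx, by, sy = s.bx, s.sx, s.by, s.sy

    def score(beta: float, tau2: float) -> float:
        s2 = sy**2 + beta**2 * sx**2 + tau2
        sdev = np.sqrt(s2)
        t = (by - beta * bx) / sdev
        dt = -bx / sdev - t * beta * sx**2 / s2
        return float(np.sum(rho_prime(t) * dt))

    def tau_score(tau2: float, beta: float) -> float:
        s2 = sy**2 + beta**2 * sx**2 + tau2
        t = (by - beta * bx) / np.sqrt(s2)
        return float(np.sum((rho_prime(t) * t - delta1) / s2))

    if loss == "l2":
        rho = lambda t: 0.5 * t**2
    else:
        rho = lambda t: np.where(np.abs(t) <= huber_k, 0.5 * t**2,
                                 huber_k * np.abs(t) - 0.5 * huber_k**2)

    def objective(beta: float, tau2: float) -> float:
        t = (by - beta * bx) / np.sqrt(sy**2 + beta**2 * sx**2 + tau2)
        return float(np.sum(rho(t)))

    start = ivw(s, model="fixed").beta

    def solve_beta(tau2: float) -> float:
        # the profile score vanishes in both tails (spurious roots), so
        # minimize the integrated loss locally around the IVW start and
        # polish with a bracketed root of the score
        width = max(1.0, 4 * abs(start))
        for _ in range(6):
            res = optimize.minimize_scalar(
                objective, bounds=(start - width, start + width),
                method="bounded", args=(tau2,), options={"xatol": 1e-10})
            b = float(res.x)
            interior = (b - (start - width) > 1e-6 * width
                        and (start + width) - b > 1e-6 * width)
            if interior:
                delta = 1e-3 * (1 + abs(b))
                lo, hi = b - delta, b + delta
                if score(lo, tau2) * score(hi, tau2) < 0:
                    return float(optimize.brentq(score, lo, hi, args=(tau2,),
                                                 xtol=1e-13, rtol=1e-14))
                return b
            width *= 4
        raise ConvergenceError(
            f"profile loss has no interior minimum near IVW start {start:.4g} "
            f"(tau2={tau2:.4g})")

    tau2 = 0.0
    beta = solve_beta(tau2)
    if overdispersion:
        for _ in range(50):
            hi = 10.0 * float(np.max(sy**2 + beta**2 * sx**2)) + 1.0
            if tau_score(0.0, beta) <= 0:
                new_tau2 = 0.0          # residuals underdispersed; floor at 0
            else:
                new_tau2 = float(optimize.brentq(tau_score, 0.0, hi, args=(beta,),
                                                 xtol=1e-14))
            new_beta = solve_beta(new_tau2)
            if abs(new_beta - beta) < 1e-10 and abs(new_tau2 - tau2) < 1e-12:
                beta, tau2 = new_beta, new_tau2
                break
            beta, tau2 = new_beta, new_tau2

    # sandwich variance of the M-estimator
    eps = 1e-6 * max(1.0, abs(beta))
    a = (score(beta + eps, tau2) - score(beta - eps, tau2)) / (2 * eps)
    s2 = sy**2 + beta**2 * sx**2 + tau2
    sdev = np.sqrt(s2)
    t = (by - beta * bx) / sdev
    dt = -bx / sdev - t * beta * sx**2 / s2
    b_mat = delta2 * float(np.sum(dt**2))
    se = math.sqrt(b_mat / a**2) if a != 0 else float("inf")
    p = 2 * float(stats.norm.sf(abs(beta / se)))
    est = _finish("raps", beta, se, p, k, level)
    est.label = f"tau2={tau2:.3e}"
    return est


# ---------------------------------------------------------------------------
# Heterogeneity and leave-one-out


def cochran_q_mr(s: HarmonizedSet, second_order: bool = False) -> QResult:
    """Cochran's Q across the per-SNP Wald ratios.

    Q = Σ wⱼ(rⱼ − β̂)² with wⱼ the inverse ratio variances and β̂ the
    fixed-effect IVW estimate; df = k−1.  Excess Q signals that effect
    differences among instruments exceed chance — a pleiotropy symptom.
    """
    k = s.n_snps
    if k < 2:
        return QResult(float("nan"), 0, float("nan"), computed=False,
                       reason="fewer than 2 instruments")
    r, sr = _ratio_stats(s, second_order)
    w = 1.0 / sr**2
    pooled = float(np.sum(w * r) / np.sum(w))
    q = float(np.sum(w * (r - pooled) ** 2))
    return QResult(q, k - 1, float(stats.chi2.sf(q, k - 1)))


def leave_one_out(s: HarmonizedSet, model: str = "multiplicative_random",
                  level: float = 0.95) -> list[MREstimate]:
    """IVW re-estimated with each SNP omitted in turn, plus the full set.

    Each entry is labeled with the omitted snp_id (``"all"`` for the full
    set); an influential or pleiotropic variant shows up as the omission
    that moves the estimate most.
    """
    k = s.n_snps
    if k < 3:
        return [MREstimate.not_computed("ivw_loo", "fewer than 3 instruments", k)]
    out = []
    for i, sid in enumerate(s.snp_ids):
        mask = np.ones(k, dtype=bool)
        mask[i] = False
        est = ivw(s.subset(mask), model=model, level=level)
        est.method = "ivw_loo"
        est.label = sid
        out.append(est)
    full = ivw(s, model=model, level=level)
    full.method = "ivw_loo"
    full.label = "all"
    out.append(full)
    return out
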