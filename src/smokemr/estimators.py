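"""Two-sample MR estimators: Wald ratios, multiplicative random-effects IVW,
weighted median, MR-Egger, multivariable IVW, and heterogeneity statistics.

All estimators are implemented directly from their closed-form weighted
least-squares expressions on the harmonized (beta_exp, beta_out) pairs.

Notation, per instrument j: beta_Xj is the SNP-exposure effect (SD units of
exposure), beta_Yj the SNP-outcome effect (log-odds), sigma_Yj its standard
error. The IVW estimate is the weighted regression of beta_Y on beta_X
through the origin with weights 1/sigma_Yj^2,

    theta_hat = sum(beta_Xj * beta_Yj / sigma_Yj^2) / sum(beta_Xj^2 / sigma_Yj^2),

equivalently the inverse-variance-weighted mean of the per-SNP Wald ratios
beta_Yj / beta_Xj under first-order ratio SEs. Under the multiplicative
random-effects model the fixed-effect SE is inflated by sqrt(phi) where
phi = max(1, Q / (k - 1)) and Q is Cochran's heterogeneity statistic, so the
reported SE never shrinks below the fixed-effect SE.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import CollinearityError, DomainError, EstimatorError
from .harmonize import HarmonizedSet

Z_95 = stats.norm.ppf(0.975)


@dataclass
class MrEstimate:
    """One estimator's causal effect on the log-odds-per-SD scale.

    ``odds_ratio`` and its CI are the exponentiated transforms; the odds
    ratio corresponds to a 1 SD increase in exposure prevalence.
    """

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snps: int
    odds_ratio: float = field(init=False)
    or_ci_low: float = field(init=False)
    or_ci_high: float = field(init=False)
    outcome: str | None = None
    exposure: str | None = None

    def __post_init__(self) -> None:
        self.odds_ratio = math.exp(self.beta)
        self.or_ci_low = math.exp(self.ci_low)
        self.or_ci_high = math.exp(self.ci_high)

    @classmethod
    def from_beta_se(
        cls,
        method: str,
        beta: float,
        se: float,
        n_snps: int,
        df: int | None = None,
        outcome: str | None = None,
        exposure: str | None = None,
    ) -> "MrEstimate":
        """Build an estimate with CI and two-sided p.

        Uses the normal reference by default; a t reference with ``df``
        degrees of freedom when given (MR-Egger convention).
        """
        if df is None:
            crit = Z_95
            p = 2.0 * stats.norm.sf(abs(beta) / se) if se > 0 else (1.0 if beta == 0 else 0.0)
        else:
            crit = stats.t.ppf(0.975, df)
            p = 2.0 * stats.t.sf(abs(beta) / se, df) if se > 0 else (1.0 if beta == 0 else 0.0)
        p = min(max(p, np.nextafter(0.0, 1.0)), 1.0)
        return cls(
            method=method,
            beta=beta,
            se=se,
            ci_low=beta - crit * se,
            ci_high=beta + crit * se,
            pvalue=p,
            n_snps=n_snps,
            outcome=outcome,
            exposure=exposure,
        )


@dataclass
class EggerResult:
    slope: MrEstimate
    intercept: float
    intercept_se: float
    intercept_p: float


@dataclass
class HeterogeneityStats:
    """Cochran's Q over per-SNP estimates, with I2 and the overdispersion phi."""

    q: float
    df: int
    i_squared: float
    phi: float

    @classmethod
    def from_q(cls, q: float, df: int) -> "HeterogeneityStats":
        i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
        phi = max(1.0, q / df) if df > 0 else 1.0
        return cls(q=q, df=df, i_squared=i2, phi=phi)


def wald_ratio(
    beta_exp: float,
    se_exp: float,
    beta_out: float,
    se_out: float,
    second_order: bool = False,
) -> MrEstimate:
    """Per-SNP causal estimate beta_out / beta_exp with delta-method SE.

    First-order SE (default) ignores exposure-side uncertainty,
    se_out/|beta_exp| — the convention under which IVW-combined ratios equal
    the weighted regression through the origin. ``second_order=True`` adds
    the beta_out^2 * se_exp^2 / beta_exp^4 term.
    """
    if beta_exp == 0:
        raise DomainError("wald_ratio undefined for beta_exp = 0")
    beta = beta_out / beta_exp
    var = se_out**2 / beta_exp**2
    if second_order:
        var += beta_out**2 * se_exp**2 / beta_exp**4
    return MrEstimate.from_beta_se("wald_ratio", beta, math.sqrt(var), n_snps=1)


def ivw_mre(data: HarmonizedSet) -> tuple[MrEstimate, HeterogeneityStats]:
    """Multiplicative random-effects IVW estimate plus heterogeneity stats.

    With a single SNP, falls back to the Wald ratio with a warning and
    degenerate heterogeneity (Q = 0, df = 0, phi = 1).
    """
    bx, sx, by, sy = data.arrays()
    k = len(bx)
    if k < 2:
        warnings.warn("ivw_mre called with < 2 SNPs; falling back to wald_ratio")
        est = wald_ratio(bx[0], sx[0], by[0], sy[0])
        est.method = "ivw_mre"
        return est, HeterogeneityStats.from_q(0.0, 0)
    if np.all(bx == 0):
        raise DomainError("all exposure betas are zero; IVW estimate undefined")
    w = 1.0 / sy**2
    denom = float(np.sum(w * bx**2))
    theta = float(np.sum(w * bx * by)) / denom
    se_fixed = 1.0 / math.sqrt(denom)
    q = float(np.sum(w * (by - theta * bx) ** 2))
    het = HeterogeneityStats.from_q(q, k - 1)
    se = se_fixed * math.sqrt(het.phi)
    return MrEstimate.from_beta_se("ivw_mre", theta, se, n_snps=k), het


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median at cumulative weight 1/2.

    Uses midpoint positions p_j = S_j - w_j/2 on the sorted ratios, linear
    interpolation between adjacent midpoints; clamps to the extreme ratios
    when 1/2 falls outside the midpoint range.
    """
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order] / np.sum(weights)
    s = np.cumsum(w)
    p = s - w / 2.0
    return float(np.interp(0.5, p, r))


def weighted_median(data: HarmonizedSet, n_boot: int = 1000, seed: int | None = None) -> MrEstimate:
    """Weighted-median causal estimate with parametric-bootstrap SE.

    Consistent when at least half the weight comes from valid instruments.
    Weights are inverse first-order ratio variances beta_Xj^2 / sigma_Yj^2.
    The SE is the SD of the estimate over ``n_boot`` parametric resamples of
    (beta_Xj, beta_Yj) from their reported normal distributions; it is
    reproducible only per seed, which is therefore mandatory.
    """
    bx, sx, by, sy = data.arrays()
    k = len(bx)
    if k < 3:
        raise EstimatorError(f"weighted_median needs >= 3 SNPs, got {k}")
    if n_boot < 100:
        raise DomainError("n_boot must be >= 100")
    if seed is None:
        raise DomainError("weighted_median requires an explicit seed")
    if np.any(bx == 0):
        raise DomainError("weighted_median undefined when any exposure beta is zero")
    ratios = by / bx
    weights = bx**2 / sy**2
    point = _weighted_median(ratios, weights)
    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        bx_b = rng.normal(bx, sx)
        by_b = rng.normal(by, sy)
        bx_b[bx_b == 0] = np.finfo(float).tiny  # zero draws have measure zero
        boot[b] = _weighted_median(by_b / bx_b, bx_b**2 / sy**2)
    se = float(np.std(boot, ddof=1))
    return MrEstimate.from_beta_se("weighted_median", point, se, n_snps=k)


def weighted_median_point(data: HarmonizedSet) -> float:
    """Point estimate only (no bootstrap); used for bias studies."""
    bx, _, by, sy = data.arrays()
    if np.any(bx == 0):
        raise DomainError("weighted_median undefined when any exposure beta is zero")
    return _weighted_median(by / bx, bx**2 / sy**2)


def mr_egger(data: HarmonizedSet) -> EggerResult:
    """MR-Egger weighted regression with intercept.

    Each SNP is first oriented so beta_Xj >= 0 (negating both betas where
    needed) — required for the intercept to estimate average directional
    pleiotropy. SEs are inflated by max(1, sqrt(Q_egger/(k-2))); p-values use
    the t distribution with k-2 df.
    """
    bx, sx, by, sy = data.arrays()
    k = len(bx)
    if k < 3:
        raise EstimatorError(f"mr_egger needs >= 3 SNPs, got {k}")
    flip = np.where(bx < 0, -1.0, 1.0)
    x = bx * flip
    y = by * flip
    if np.ptp(x) == 0:
        raise CollinearityError(
            "all |beta_exp| identical; Egger slope and intercept are not separable"
        )
    w = 1.0 / sy**2
    # weighted normal equations for y = a + b x
    xtx = np.array(
        [[np.sum(w), np.sum(w * x)], [np.sum(w * x), np.sum(w * x**2)]]
    )
    xty = np.array([np.sum(w * y), np.sum(w * x * y)])
    a, b = np.linalg.solve(xtx, xty)
    resid = y - a - b * x
    q = float(np.sum(w * resid**2))
    df = k - 2
    scale = max(1.0, math.sqrt(q / df))
    cov = np.linalg.inv(xtx)
    se_a = math.sqrt(cov[0, 0]) * scale
    se_b = math.sqrt(cov[1, 1]) * scale
    slope = MrEstimate.from_beta_se("mr_egger_slope", float(b), se_b, n_snps=k, df=df)
    p_a = 2.0 * stats.t.sf(abs(a) / se_a, df) if se_a > 0 else 1.0
    return EggerResult(
        slope=slope, intercept=float(a), intercept_se=se_a, intercept_p=min(max(p_a, 1e-300), 1.0)
    )


def mvmr_ivw(
    exposure_betas: np.ndarray,
    outcome_betas: np.ndarray,
    outcome_ses: np.ndarray,
    exposure_names: Sequence[str] | None = None,
) -> list[MrEstimate]:
    """Multivariable IVW: direct effect of each exposure, adjusted for the rest.

    Weighted regression of beta_Y on the (k x K) exposure-beta matrix with no
    intercept, weights 1/sigma_Yj^2; SEs inflated by sqrt(max(1, Q/(k-K))).
    Raises :class:`CollinearityError` naming the offending exposures on rank
    deficiency.
    """
    X = np.atleast_2d(np.asarray(exposure_betas, dtype=float))
    if X.ndim == 2 and X.shape[0] < X.shape[1] and X.shape[0] == 1:
        X = X.T
    y = np.asarray(outcome_betas, dtype=float)
    sy = np.asarray(outcome_ses, dtype=float)
    k, n_exp = X.shape
    names = list(exposure_names) if exposure_names is not None else [
        f"exposure_{i}" for i in range(n_exp)
    ]
    if len(names) != n_exp:
        raise DomainError("exposure_names length must match the number of exposure columns")
    if k <= n_exp:
        raise EstimatorError(f"need more SNPs ({k}) than exposures ({n_exp})")
    w = 1.0 / sy**2
    Xw = X * np.sqrt(w)[:, None]
    # QR diagnostics: near-zero pivots identify non-separable columns
    _, R = np.linalg.qr(Xw)
    diag = np.abs(np.diag(R))
    bad = diag <= max(Xw.shape) * np.finfo(float).eps * (diag.max() if diag.max() > 0 else 1.0)
    if bad.any():
        offending = [names[i] for i in np.nonzero(bad)[0]]
        raise CollinearityError(f"exposure-beta matrix is rank deficient: {offending}")
    xtx = Xw.T @ Xw
    beta = np.linalg.solve(xtx, Xw.T @ (y * np.sqrt(w)))
    resid = y - X @ beta
    q = float(np.sum(w * resid**2))
    phi = max(1.0, q / (k - n_exp))
    cov = np.linalg.inv(xtx) * phi
    ses = np.sqrt(np.diag(cov))
    return [
        MrEstimate.from_beta_se("mvmr_ivw", float(b), float(s), n_snps=k, exposure=name)
        for b, s, name in zip(beta, ses, names)
    ]
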