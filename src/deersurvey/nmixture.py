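"""Binomial-Poisson N-mixture model for repeated point counts.

The model: latent abundance at site i is N_i ~ Poisson(lambda_i) with
log(lambda_i) = x_i' beta, and the count on occasion j is
C_ij | N_i ~ Binomial(N_i, p_i) with the detection probability linked to
site covariates (logit link by default; a log link is available but does
not constrain p to [0, 1]). The infinite sum over the latent abundance is
truncated at a bound K chosen well beyond the plausible abundance range.

This module provides the marginal likelihood, maximum-likelihood fitting
with Wald inference, AIC selection over a candidate covariate set, exact
empirical Bayes posteriors for site abundance, and aggregation of site
abundances into a density for the surveyed area.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from ._common import DensityEstimate
from .io_ingest import CountMatrix

logger = logging.getLogger("deersurvey")

__all__ = [
    "ModelSpec",
    "NMixFit",
    "SiteAbundancePosterior",
    "DensityEstimate",
    "site_marginal_loglik",
    "fit_nmix",
    "candidate_model_set",
    "select_by_aic",
    "site_abundance_posterior",
    "nmix_density_estimate",
]

_BIG = 1e10  # penalty returned where the likelihood is undefined


@dataclass(frozen=True)
class ModelSpec:
    """Covariate structure of one candidate model: up to two predictors in
    the abundance component and up to two in the detection component."""

    abundance: tuple[str, ...] = ()
    detection: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for part, names in (("abundance", self.abundance), ("detection", self.detection)):
            if len(names) > 2:
                raise ValueError(f"{part} component takes at most two predictors")
            if len(set(names)) != len(names):
                raise ValueError(f"duplicate predictor in {part} component")

    @property
    def n_coef(self) -> int:
        return 2 + len(self.abundance) + len(self.detection)

    @property
    def label(self) -> str:
        ab = "+".join(self.abundance) or "1"
        de = "+".join(self.detection) or "1"
        return f"lam~{ab} p~{de}"


def site_marginal_loglik(
    counts_i: Sequence[float],
    lambda_i: float,
    p_ij: float | Sequence[float],
    K: int,
) -> float:
    """Log marginal probability of one site's occasion counts.

    Sums Poisson(N; lambda_i) * prod_j Binomial(c_ij; N, p_ij) over the
    latent abundance N from max(counts) to the truncation bound K, entirely
    in log space.
    """
    c = np.asarray(counts_i, dtype=float)
    c = c[~np.isnan(c)]
    if c.size == 0:
        return 0.0
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    if not np.allclose(c, np.round(c)):
        raise ValueError("counts must be integers")
    c = c.astype(int)
    if lambda_i <= 0:
        raise ValueError("lambda must be positive")
    p = np.broadcast_to(np.asarray(p_ij, dtype=float), c.shape)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("detection probabilities must lie in [0, 1]")
    m = int(c.max())
    if K < m:
        raise ValueError(f"truncation bound K={K} is below the max count {m}")
    N = np.arange(m, K + 1)
    log_pois = special.xlogy(N, lambda_i) - lambda_i - special.gammaln(N + 1)
    # log C(N, c_j) + c_j log p_j + (N - c_j) log(1 - p_j), summed over j
    Ncol = N[:, None]
    log_binom = (
        special.gammaln(Ncol + 1)
        - special.gammaln(c + 1)
        - special.gammaln(Ncol - c + 1)
        + special.xlogy(c, p)
        + special.xlog1py(Ncol - c, -p)
    ).sum(axis=1)
    return float(special.logsumexp(log_pois + log_binom))


# ---------------------------------------------------------------------------
# Fast likelihood machinery
# ---------------------------------------------------------------------------


class _SiteData:
    """Per-site sufficient quantities for the marginal likelihood with a
    site-constant detection probability.

    For N >= max(c) the binomial product collapses to
        J*lgamma(N+1) - sum_j lgamma(c_j+1) - S(N) + T log p + (NJ - T) log(1-p)
    with S(N) = sum_j lgamma(N - c_j + 1) and T = sum_j c_j, so one
    likelihood evaluation is O(K) per site.
    """

    __slots__ = ("J", "T", "m", "N", "base", "lgN")

    def __init__(self, counts_row: np.ndarray, K: int):
        c = counts_row[~np.isnan(counts_row)].astype(int)
        self.J = c.size
        self.T = int(c.sum())
        self.m = int(c.max()) if c.size else 0
        self.N = np.arange(self.m, K + 1)
        self.lgN = special.gammaln(self.N + 1)
        S = special.gammaln(self.N[:, None] - c[None, :] + 1).sum(axis=1)
        self.base = self.J * self.lgN - special.gammaln(c + 1).sum() - S

    def loglik(self, lam: float, logp: float, log1mp: float) -> float:
        log_pois = special.xlogy(self.N, lam) - lam - self.lgN
        log_bin = self.base + self.T * logp + (self.N * self.J - self.T) * log1mp
        return float(special.logsumexp(log_pois + log_bin))


@dataclass
class NMixFit:
    """A fitted N-mixture model.

    Coefficients are on the link scales (log for abundance, the chosen link
    for detection) and refer to the covariate scaling recorded in
    ``scaling``. ``lambda_hat`` and ``p_hat`` are the per-site fitted rate
    and detection probability.
    """

    spec: ModelSpec
    link: str
    coef_names: list[str]
    beta: np.ndarray
    alpha: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p_values: np.ndarray
    loglik: float
    K: int
    converged: bool
    site_ids: list[str]
    lambda_hat: np.ndarray
    p_hat: np.ndarray
    max_count: int
    scaling: dict = field(default_factory=dict)
    ses_ok: bool = True

    @property
    def n_coef(self) -> int:
        return len(self.beta) + len(self.alpha)

    @property
    def aic(self) -> float:
        return 2 * self.n_coef - 2 * self.loglik

    def coef_table(self) -> pd.DataFrame:
        """Coefficient summary in the conventional report layout."""
        return pd.DataFrame(
            {
                "parameter": self.coef_names,
                "estimate": np.concatenate([self.beta, self.alpha]),
                "se": self.se,
                "z": self.z,
                "p_value": self.p_values,
            }
        )


def _design_matrices(
    covariates: pd.DataFrame, spec: ModelSpec, site_ids: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    cov = covariates.set_index(covariates["site_id"].astype(str))
    missing = [s for s in site_ids if s not in cov.index]
    if missing:
        raise ValueError(f"covariate table lacks site(s) {missing}")
    cov = cov.loc[[str(s) for s in site_ids]]
    for name in (*spec.abundance, *spec.detection):
        if name not in cov.columns:
            raise ValueError(f"unknown predictor {name!r}")
    n = len(site_ids)
    X_ab = np.column_stack(
        [np.ones(n)] + [cov[c].to_numpy(float) for c in spec.abundance]
    )
    X_det = np.column_stack(
        [np.ones(n)] + [cov[c].to_numpy(float) for c in spec.detection]
    )
    return X_ab, X_det


def fit_nmix(
    counts: CountMatrix,
    covariates: pd.DataFrame,
    spec: ModelSpec = ModelSpec(),
    K: int | None = None,
    link: str = "logit",
    start: np.ndarray | None = None,
) -> NMixFit:
    """Maximum-likelihood fit of the N-mixture model.

    Parameters
    ----------
    counts : CountMatrix
        Daily maximum counts; NaN cells are treated as unsurveyed occasions.
    covariates : DataFrame
        Site covariates (standardized); must contain ``site_id`` plus every
        predictor named in ``spec``.
    K : int, optional
        Truncation bound for the latent abundance sum. Defaults to the
        maximum observed count plus 100.
    link : {"logit", "log"}
        Detection link. The log link is offered for fidelity with the
        model's printed form but is not recommended: it does not keep p
        below 1, and parameter regions implying p > 1 are penalised.
    start : array, optional
        Initial coefficient vector (beta then alpha). The default start is
        deterministic: log(mean site maximum + 0.5) for the abundance
        intercept, zeros elsewhere (detection intercept 0 on the logit
        scale, or log 0.5 for the log link).

    Standard errors come from the inverse of the finite-difference observed
    information; z and two-sided normal p-values follow. A singular
    information matrix yields NaN standard errors and ``ses_ok=False``.
    """
    if counts.n_sites < 2 or counts.n_occasions < 2:
        raise ValueError("need at least 2 sites and 2 occasions")
    if link not in {"logit", "log"}:
        raise ValueError("link must be 'logit' or 'log'")
    max_count = counts.max_count()
    if K is None:
        K = max_count + 100
    if K < max_count:
        raise ValueError(f"K={K} is below the maximum observed count {max_count}")

    X_ab, X_det = _design_matrices(covariates, spec, counts.site_ids)
    sites = [_SiteData(row, K) for row in counts.counts]
    k_ab, k_det = X_ab.shape[1], X_det.shape[1]

    def unpack(theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return theta[:k_ab], theta[k_ab:]

    def negloglik(theta: np.ndarray) -> float:
        beta, alpha = unpack(theta)
        eta_ab = X_ab @ beta
        if np.any(eta_ab > 30):  # lambda overflow guard
            return _BIG
        lam = np.exp(eta_ab)
        eta_det = X_det @ alpha
        if link == "logit":
            logp = -np.logaddexp(0.0, -eta_det)
            log1mp = -np.logaddexp(0.0, eta_det)
        else:
            if np.any(eta_det >= 0):  # p >= 1 is outside the model
                return _BIG
            logp = eta_det
            log1mp = np.log1p(-np.exp(eta_det))
        total = 0.0
        for s, la, lp, l1p in zip(sites, lam, logp, log1mp):
            total += s.loglik(la, lp, l1p)
        if not np.isfinite(total):
            return _BIG
        return -total

    if start is None:
        site_max = np.nanmax(counts.counts, axis=1)
        theta0 = np.zeros(k_ab + k_det)
        theta0[0] = np.log(np.mean(site_max) + 0.5)
        if link == "log":
            theta0[k_ab] = np.log(0.5)
    else:
        theta0 = np.asarray(start, dtype=float)
        if theta0.size != k_ab + k_det:
            raise ValueError(f"start must have {k_ab + k_det} entries")

    if negloglik(theta0) >= _BIG:
        raise ValueError(
            "likelihood is not finite at the starting values; "
            "increase K or rescale covariates"
        )

    res = optimize.minimize(
        negloglik, theta0, method="L-BFGS-B",
        options={"ftol": 1e-10, "gtol": 1e-7, "maxiter": 500},
    )
    theta = res.x
    loglik = -float(res.fun)
    beta, alpha = unpack(theta)

    # degenerate data (e.g. all-zero counts) push the abundance intercept
    # toward -inf; flag rather than fail
    degenerate = max_count == 0 or np.any(np.abs(theta) > 25)
    converged = bool(res.success) and np.isfinite(loglik) and not degenerate

    hessian = _numdiff_hessian(negloglik, theta)
    se = np.full(theta.size, np.nan)
    ses_ok = False
    try:
        cov_theta = np.linalg.inv(hessian)
        diag = np.diag(cov_theta)
        if np.all(diag > 0):
            se = np.sqrt(diag)
            ses_ok = True
    except np.linalg.LinAlgError:
        pass
    if not ses_ok:
        logger.warning("singular information matrix; SEs reported as missing")
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.concatenate([beta, alpha]) / se
        p_values = 2 * stats.norm.sf(np.abs(z))

    lam_hat = np.exp(X_ab @ beta)
    eta_det = X_det @ alpha
    p_hat = special.expit(eta_det) if link == "logit" else np.exp(eta_det)
    names = (
        ["B_abundance"] + list(spec.abundance)
        + ["B_detection"] + [f"{c}(det)" for c in spec.detection]
    )
    return NMixFit(
        spec=spec,
        link=link,
        coef_names=names,
        beta=beta,
        alpha=alpha,
        se=se,
        z=z,
        p_values=p_values,
        loglik=loglik,
        K=K,
        converged=converged,
        site_ids=list(counts.site_ids),
        lambda_hat=lam_hat,
        p_hat=p_hat,
        max_count=max_count,
        scaling=dict(covariates.attrs.get("scaling", {})),
        ses_ok=ses_ok,
    )


def _numdiff_hessian(f, x: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian with steps scaled to parameter magnitude."""
    n = x.size
    h = eps * np.maximum(1.0, np.abs(x))
    H = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            if i == j:
                H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
                ) / (4 * h[i] * h[j])
    return H


# ---------------------------------------------------------------------------
# Candidate set and AIC selection
# ---------------------------------------------------------------------------


def candidate_model_set(
    predictors: Sequence[str], include_null: bool = True
) -> list[ModelSpec]:
    """All models with one or two predictors in each component.

    The candidate set is the Cartesian product of the size-1 and size-2
    subsets of ``predictors`` for the abundance component with the same
    subsets for the detection component, optionally preceded by the null
    (intercept-only) model. Ordering is deterministic (lexicographic).
    """
    names = list(predictors)
    if len(set(names)) != len(names):
        raise ValueError("duplicate predictor names")
    if not names:
        raise ValueError("need at least one predictor")
    subsets = [
        tuple(combo)
        for size in (1, 2)
        for combo in itertools.combinations(sorted(names), size)
    ]
    subsets.sort()
    specs = [ModelSpec(ab, de) for ab in subsets for de in subsets]
    specs.sort(key=lambda s: (s.abundance, s.detection))
    if include_null:
        specs.insert(0, ModelSpec((), ()))
    return specs


def select_by_aic(fits: Sequence[NMixFit]) -> tuple[NMixFit, pd.DataFrame]:
    """Pick the converged fit with minimal AIC and build the ranking table.

    Ties are broken by fewer coefficients (parsimony), then by the
    lexicographic order of the model label.
    """
    converged = [f for f in fits if f.converged]
    if not converged:
        raise ValueError("no converged fits to select from")
    ranked = sorted(converged, key=lambda f: (f.aic, f.n_coef, f.spec.label))
    best = ranked[0]
    table = pd.DataFrame(
        {
            "model": [f.spec.label for f in ranked],
            "aic": [f.aic for f in ranked],
            "delta_aic": [f.aic - best.aic for f in ranked],
            "loglik": [f.loglik for f in ranked],
            "n_coef": [f.n_coef for f in ranked],
        }
    )
    return best, table


# ---------------------------------------------------------------------------
# Empirical Bayes posteriors and density
# ---------------------------------------------------------------------------


@dataclass
class SiteAbundancePosterior:
    """Exact posterior of one site's latent abundance given its counts and
    the fitted parameters, on the integer support 0..K."""

    site_id: str
    support: np.ndarray
    pmf: np.ndarray
    bup: float
    ci_low: int
    ci_high: int


def site_abundance_posterior(
    fit: NMixFit, counts: CountMatrix
) -> list[SiteAbundancePosterior]:
    """Empirical Bayes posterior of N_i per site, by direct enumeration.

    The posterior pmf over N is proportional to
    Poisson(N; lambda_hat_i) * prod_j Binomial(c_ij; N, p_hat_i) on the
    finite support 0..K, so it is normalised exactly rather than sampled.
    The best unbiased predictor (BUP) is the posterior mean; the interval
    is the central [2.5%, 97.5%] quantile interval on the integer support.
    """
    if not fit.converged:
        raise ValueError("fit did not converge; posteriors are not meaningful")
    if list(counts.site_ids) != fit.site_ids:
        raise ValueError("count matrix sites do not match the fitted sites")
    out = []
    K = fit.K
    for i, site in enumerate(counts.site_ids):
        c = counts.counts[i]
        c = c[~np.isnan(c)].astype(int)
        m = int(c.max()) if c.size else 0
        N = np.arange(0, K + 1)
        logw = np.full(N.size, -np.inf)
        Nv = np.arange(m, K + 1)
        lam, p = fit.lambda_hat[i], fit.p_hat[i]
        log_pois = special.xlogy(Nv, lam) - lam - special.gammaln(Nv + 1)
        Ncol = Nv[:, None]
        log_bin = (
            special.gammaln(Ncol + 1)
            - special.gammaln(c + 1)
            - special.gammaln(Ncol - c + 1)
            + special.xlogy(c, p)
            + special.xlog1py(Ncol - c, -p)
        ).sum(axis=1)
        logw[m:] = log_pois + log_bin
        norm = special.logsumexp(logw)
        if not np.isfinite(norm):
            raise ValueError(
                f"posterior mass underflows at site {site!r}; increase K"
            )
        pmf = np.exp(logw - norm)
        bup = float(np.dot(N, pmf))
        cdf = np.cumsum(pmf)
        ci_low = int(N[np.searchsorted(cdf, 0.025)])
        ci_high = int(N[np.searchsorted(cdf, 0.975)])
        out.append(
            SiteAbundancePosterior(
                site_id=str(site), support=N, pmf=pmf,
                bup=bup, ci_low=ci_low, ci_high=ci_high,
            )
        )
    return out


def nmix_density_estimate(
    posteriors: Sequence[SiteAbundancePosterior],
    area_km2: float,
    n_draws: int = 10_000,
    seed: int | None = None,
    period: str = "",
) -> DensityEstimate:
    """Aggregate site posteriors into a density for the surveyed area.

    The point estimate divides the sum of site BUPs by the area. The 95%
    interval is Monte Carlo: latent abundances are drawn independently from
    each site's posterior pmf ``n_draws`` times, summed, divided by the
    area, and the 2.5/97.5 percentiles taken.
    """
    if not posteriors:
        raise ValueError("no posteriors supplied")
    if area_km2 <= 0:
        raise ValueError("area must be positive")
    rng = np.random.default_rng(seed)
    density = sum(p.bup for p in posteriors) / area_km2
    totals = np.zeros(n_draws)
    for p in posteriors:
        totals += rng.choice(p.support, size=n_draws, p=p.pmf)
    lo, hi = np.percentile(totals / area_km2, [2.5, 97.5])
    return DensityEstimate(
        method="nmixture",
        period=period,
        density=float(density),
        ci_low=float(min(lo, density)),
        ci_high=float(max(hi, density)),
        area_km2=float(area_km2),
    )
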