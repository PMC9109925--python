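"""Negative binomial estimation for read-type groups.

The model per read-type group h of gene g: counts X_ghj ~ NB(N*_j θ_gh,
φ_gh), where N*_j is the TMM-effective library size of sample j, θ_gh a
relative expression level, and φ_gh an overdispersion shared across the
two conditions (variance = mean + φ·mean²; φ → 0 recovers Poisson).

Estimation follows the quantile-adjusted conditional maximum likelihood
(CML) scheme: counts are mapped to a common library size N* by matching
NB mid-quantiles ("pseudo counts"), the dispersion is estimated by
maximizing the conditional likelihood given each condition's pseudo-count
sum (which eliminates θ), and θ is estimated for fixed φ by an EM on the
latent Gamma rates of the Gamma–Poisson mixture. The two steps alternate
until the dispersion stabilizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.special import gammaln

from .read_typing import CountTable, DesignInfo

PHI_BOUNDS = (1e-6, 10.0)


@dataclass
class NormalizationResult:
    """TMM factors and effective library sizes."""

    samples: list[str]
    reference: str
    factors: np.ndarray          # f_j, geometric mean 1
    lib_sizes: np.ndarray        # N_j
    effective_sizes: np.ndarray  # N*_j = N_j * f_j

    @property
    def common_size(self) -> float:
        """Common pseudo library size N*: geometric mean of the N*_j."""
        return float(np.exp(np.mean(np.log(self.effective_sizes))))

    def effective(self, sample: str) -> float:
        return float(self.effective_sizes[self.samples.index(sample)])


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
              logratio_trim: float = 0.3, sum_trim: float = 0.05) -> float:
    """Weighted trimmed mean of M values of one sample against the reference."""
    keep = (obs > 0) & (ref > 0)
    obs, ref = obs[keep].astype(float), ref[keep].astype(float)
    if obs.size == 0:
        return 1.0
    m = np.log2((obs / n_obs) / (ref / n_ref))
    a = 0.5 * np.log2((obs / n_obs) * (ref / n_ref))
    # precision weights: delta-method variance of M
    w = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    n = m.size
    lo_m, hi_m = np.floor(n * logratio_trim) + 1, n - np.floor(n * logratio_trim)
    lo_a, hi_a = np.floor(n * sum_trim) + 1, n - np.floor(n * sum_trim)
    rank_m = stats.rankdata(m)
    rank_a = stats.rankdata(a)
    keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep2.any() or not np.any(w[keep2] > 0):
        return 1.0
    f = np.sum(m[keep2] / w[keep2]) / np.sum(1.0 / w[keep2])
    if not np.isfinite(f):
        return 1.0
    return float(2.0 ** f)


def tmm_normalize(table: CountTable, logratio_trim: float = 0.3, sum_trim: float = 0.05) -> NormalizationResult:
    """Trimmed-mean-of-M-values normalization across samples.

    The reference sample is the one whose upper-quartile count fraction
    is closest to the across-sample mean. Factors are renormalized to
    geometric mean 1.
    """
    samples = table.samples
    if len(samples) < 2:
        raise ValueError("TMM normalization needs >= 2 samples")
    counts = table.counts.to_numpy(dtype=float)
    lib = table.lib_sizes.loc[samples].to_numpy(dtype=float)
    if np.any(counts.sum(axis=0) <= 0):
        raise ValueError("every sample needs at least one positive count")
    f75 = np.array([np.quantile(counts[:, j] / lib[j], 0.75) for j in range(len(samples))])
    ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.array([
        1.0 if j == ref_idx else _tmm_pair(counts[:, j], counts[:, ref_idx], lib[j], lib[ref_idx],
                                           logratio_trim, sum_trim)
        for j in range(len(samples))
    ])
    factors = factors / np.exp(np.mean(np.log(factors)))
    return NormalizationResult(
        samples=list(samples),
        reference=samples[ref_idx],
        factors=factors,
        lib_sizes=lib,
        effective_sizes=lib * factors,
    )


def cml_loglik(counts, phi: float) -> float:
    """Conditional log-likelihood of the dispersion given the count sum.

    For J counts x_j at a common library size with sum z:

        l(φ) = Σ_j logΓ(x_j + 1/φ) + logΓ(J/φ) − logΓ(z + J/φ) − J·logΓ(1/φ)

    Terms that do not involve φ are dropped. As φ → 0 the expression
    tends to the Poisson/multinomial limit −z·log(J), which is returned
    at φ == 0 exactly.
    """
    x = np.asarray(counts, dtype=float)
    if np.any(x < 0):
        raise ValueError("negative counts")
    if phi < 0:
        raise ValueError("phi must be >= 0")
    j = x.size
    z = x.sum()
    if phi == 0.0:
        return float(-z * np.log(j))
    r = 1.0 / phi
    return float(gammaln(x + r).sum() + gammaln(j * r) - gammaln(z + j * r) - j * gammaln(r))


def _nb_params(mean: float, phi: float) -> tuple[float, float]:
    """scipy (n, p) parameterization for NB(mean, dispersion phi)."""
    r = 1.0 / phi
    return r, r / (r + mean)


def quantile_adjust(counts, sizes, target_size: float, theta: float, phi: float) -> np.ndarray:
    """Map counts to a common library size by NB mid-quantile matching.

    Each count x_j with library size N*_j is sent through the
    mid-quantile u = F(x_j) − p(x_j)/2 of NB(N*_j θ, φ) and inverted on
    the NB(N* θ, φ) scale, interpolating linearly between integer
    support points, which makes equal input and target sizes an exact
    identity. Zero counts map to zero. φ == 0 uses the Poisson law.
    """
    x = np.asarray(counts, dtype=float)
    sizes = np.broadcast_to(np.asarray(sizes, dtype=float), x.shape)
    if np.any(x < 0):
        raise ValueError("negative counts")
    if theta < 0 or phi < 0:
        raise ValueError("theta and phi must be >= 0")
    if theta == 0:
        if np.any(x > 0):
            raise ValueError("theta == 0 is inconsistent with positive counts")
        return np.zeros_like(x)

    def cdf_pmf(k, mean):
        if phi == 0:
            return stats.poisson.cdf(k, mean), stats.poisson.pmf(k, mean)
        n, p = _nb_params(mean, phi)
        return stats.nbinom.cdf(k, n, p), stats.nbinom.pmf(k, n, p)

    src_cdf, src_pmf = cdf_pmf(x, sizes * theta)
    u = src_cdf - 0.5 * src_pmf

    # target grid of mid-quantiles g(k) = F(k) - p(k)/2, k = 0..kmax
    tmean = target_size * theta
    u_max = float(u.max())
    if phi == 0:
        kmax = int(stats.poisson.ppf(min(u_max, 1 - 1e-15), tmean))
    else:
        n, p = _nb_params(tmean, phi)
        kmax = int(stats.nbinom.ppf(min(u_max, 1 - 1e-15), n, p))
    kmax = max(kmax + 3, 3)
    grid = np.arange(kmax + 1)
    gcdf, gpmf = cdf_pmf(grid, tmean)
    gmid = gcdf - 0.5 * gpmf
    while gmid[-1] < u_max and gmid[-1] < 1 - 1e-14:
        kmax = 2 * kmax
        grid = np.arange(kmax + 1)
        gcdf, gpmf = cdf_pmf(grid, tmean)
        gmid = gcdf - 0.5 * gpmf

    idx = np.searchsorted(gmid, u, side="right") - 1
    idx = np.clip(idx, 0, len(gmid) - 2)
    denom = gmid[idx + 1] - gmid[idx]
    frac = np.where(denom > 0, (u - gmid[idx]) / np.where(denom > 0, denom, 1.0), 0.0)
    pseudo = idx + np.clip(frac, 0.0, None)
    pseudo = np.where(u <= gmid[0], np.where(x == 0, 0.0, np.maximum(pseudo, 0.0)), pseudo)
    pseudo = np.where(x == 0, 0.0, pseudo)
    return np.maximum(pseudo, 0.0)


@dataclass
class EMState:
    """Trace of the θ EM: iterates and convergence information."""

    theta: float
    converged: bool
    n_iter: int
    theta_trace: list[float] = field(default_factory=list)

    def posterior_means(self, counts, offsets, phi: float) -> np.ndarray:
        """E[Θ_j | x_j] at the final θ (Gamma–Poisson conjugacy)."""
        x = np.asarray(counts, dtype=float)
        n = np.asarray(offsets, dtype=float)
        if phi == 0 or self.theta == 0:
            return np.full_like(x, self.theta)
        r = 1.0 / phi
        return (x + r) / (n + r / self.theta)


def estimate_theta_em(counts, offsets, phi: float, *, tol: float = 1e-8,
                      max_iter: int = 200, return_state: bool = False):
    """Estimate θ for fixed φ by EM on the latent Gamma rates.

    Model: X_j | Θ_j ~ Poisson(N*_j Θ_j), Θ_j ~ Gamma(shape 1/φ, mean θ).
    E-step: E[Θ_j | x_j] = (x_j + 1/φ) / (N*_j + 1/(φθ)); M-step: θ ←
    mean of the posterior means. This ascends the marginal NB likelihood.
    At φ == 0 (or all-zero counts) the closed form Σx_j / ΣN*_j is
    returned directly.
    """
    x = np.asarray(counts, dtype=float)
    n = np.asarray(offsets, dtype=float)
    if np.any(x < 0):
        raise ValueError("negative counts")
    if x.sum() == 0 or phi == 0:
        theta = float(x.sum() / n.sum())
        state = EMState(theta, True, 0, [theta])
        return (theta, state) if return_state else theta
    r = 1.0 / phi
    theta = float(x.sum() / n.sum())
    trace = [theta]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        post = (x + r) / (n + r / theta)
        new = float(post.mean())
        trace.append(new)
        if abs(new - theta) <= tol * max(theta, 1e-12):
            theta = new
            converged = True
            break
        theta = new
    state = EMState(theta, converged, it, trace)
    return (theta, state) if return_state else theta


@dataclass
class DispersionFit:
    """Fitted NB parameters for one read-type group."""

    group: str
    phi: float
    pseudo: np.ndarray            # per-sample pseudo counts at common size N*
    z0: int                       # rounded condition-0 pseudo sum
    z1: int
    theta_pooled: float
    theta0: float
    theta1: float
    common_size: float
    n_iter: int
    converged: bool
    at_bound: bool = False


def _round_half_up(v: np.ndarray) -> np.ndarray:
    return np.floor(v + 0.5)


def fit_dispersion(
    counts,
    design: DesignInfo,
    norm: NormalizationResult,
    *,
    group: str = "",
    phi_init: float = 0.1,
    phi_bounds: tuple[float, float] = PHI_BOUNDS,
    outer_tol: float = 1e-4,
    max_outer: int = 20,
) -> DispersionFit | None:
    """Quantile-adjusted CML fit of (φ, θ) for one group of counts.

    Alternates: pooled θ by EM on the raw counts with offsets N*_j;
    pseudo counts by quantile adjustment to the common size N* (pooled θ,
    current φ); then φ maximizing the sum over the two conditions of the
    conditional log-likelihood of the pseudo counts. Stops when
    |Δφ|/max(φ, 1e-4) < ``outer_tol``. Returns ``None`` for an all-zero
    group (nothing to estimate).
    """
    design.require_replicates()
    samples = norm.samples
    x = np.asarray(counts, dtype=float)
    if x.shape != (len(samples),):
        raise ValueError("counts must align with normalization samples")
    if x.sum() == 0:
        return None
    cond = np.array([design.conditions[s] for s in samples])
    nstar_j = norm.effective_sizes
    nstar = norm.common_size

    phi = phi_init
    pseudo = x.copy()
    converged = False
    it = 0
    for it in range(1, max_outer + 1):
        theta_pooled = estimate_theta_em(x, nstar_j, phi)
        pseudo = quantile_adjust(x, nstar_j, nstar, theta_pooled, phi)

        def neg_obj(p):
            return -(cml_loglik(pseudo[cond == 0], p) + cml_loglik(pseudo[cond == 1], p))

        res = optimize.minimize_scalar(neg_obj, bounds=phi_bounds, method="bounded",
                                       options={"xatol": 1e-6})
        phi_new = float(res.x)
        if abs(phi_new - phi) / max(phi_new, 1e-4) < outer_tol:
            phi = phi_new
            converged = True
            break
        phi = phi_new

    theta_pooled = estimate_theta_em(x, nstar_j, phi)
    pseudo = quantile_adjust(x, nstar_j, nstar, theta_pooled, phi)
    z0 = int(_round_half_up(pseudo[cond == 0].sum()))
    z1 = int(_round_half_up(pseudo[cond == 1].sum()))
    theta0 = estimate_theta_em(x[cond == 0], nstar_j[cond == 0], phi)
    theta1 = estimate_theta_em(x[cond == 1], nstar_j[cond == 1], phi)
    at_bound = phi <= phi_bounds[0] * (1 + 1e-3) or phi >= phi_bounds[1] * (1 - 1e-3)
    return DispersionFit(
        group=group,
        phi=phi,
        pseudo=pseudo,
        z0=z0,
        z1=z1,
        theta_pooled=float((z0 + z1) / (len(samples) * nstar)),
        theta0=theta0,
        theta1=theta1,
        common_size=nstar,
        n_iter=it,
        converged=converged,
        at_bound=at_bound,
    )
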