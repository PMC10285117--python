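"""Bayesian hierarchical model of allele-frequency dispersal within a region.

For SNP i with ancestral (center) frequency ``fA_i``, each sampling site j
carries a log-balance ``x_ji = log((1 - f_ji) / f_ji)`` whose vector over the
M sites drifts from the ancestral balance ``xA_i`` with tree-structured
covariance::

    x_i ~ MvN(xA_i * 1,  s_i * V * g(fA_i))
    y_ji ~ Binomial(n_ji, f_ji)

``V`` is the dispersal covariance of the region (shared path lengths under a
scenario, diagonal scaled to average one) and ``s_i ~ Exp(1)`` a per-SNP
drift scale. ``g`` converts Wright-Fisher drift variance to the balance
scale: the delta-method form ``g(fA) = 1 / (fA (1 - fA))`` is the default; a
literal multiplicative form ``g(fA) = fA (1 - fA)`` is available via
``variance_mode="literal"`` for comparison. The ancestral frequency carries a
Beta(a, b) hyper-prior with mean ``a/(a+b) ~ Unif(0, 1)`` and size
``a + b ~ Exp(1)``.

Posteriors are explored with Hamiltonian Monte Carlo using analytic
gradients; candidate centers and scenarios are compared by a BIC-type score
(higher is better) that, for a fixed parameter count, reduces to comparing
maximum log-likelihood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import digamma, gammaln

from . import hmc
from .diagnostics import ess as _ess
from .diagnostics import gelman_rubin as _gelman_rubin
from .geo_covariance import (
    DispersalCovariance,
    candidate_centers,
    heuristic_covariance,
    least_cost_distances,
    linear_distances,
)
from .io_geno import SiteSet, VariantCounts

__all__ = [
    "balance",
    "inverse_balance",
    "HmcConfig",
    "PopdispFit",
    "log_posterior",
    "run_hmc",
    "gelman_rubin",
    "ess",
    "model_score",
    "select_center_and_scenario",
    "representative_frequencies",
    "representative_balances",
    "LinearScenario",
    "RasterScenario",
    "FixedCovarianceScenario",
]

_FREQ_CLIP = 1e-12


def balance(f):
    """Log-balance (logit) of an allele frequency: ``x = log((1-f)/f)``."""
    f = np.asarray(f, dtype=float)
    if (f < 0).any() or (f > 1).any():
        raise ValueError("frequency outside [0, 1]")
    f = np.clip(f, _FREQ_CLIP, 1 - _FREQ_CLIP)
    return np.log((1 - f) / f)


def inverse_balance(x):
    """Frequency from a log-balance: ``f = 1 / (1 + exp(x))``."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = np.exp(-x[pos]) / (1 + np.exp(-x[pos]))
    out[~pos] = 1 / (1 + np.exp(x[~pos]))
    return out


def _softplus(x):
    return np.logaddexp(0.0, x)


def _sigmoid(x):
    return inverse_balance(-np.asarray(x, dtype=float))


@dataclass
class HmcConfig:
    """Sampling protocol. Defaults follow the model's standard protocol of
    3 chains of 50,000 iterations with the first half discarded."""

    chains: int = 3
    length: int = 50_000
    burnin: float = 0.5
    step_size: float = 0.01
    n_leapfrog: int = 10
    adapt: bool = True
    target_accept: float = 0.8
    seed: int = 0
    variance_mode: str = "delta"  # "delta" | "literal"
    parametrization: str = "noncentered"  # "noncentered" | "centered"
    compute_diagnostics: bool = True
    store_dtype: type = np.float32


class _Posterior:
    """Log posterior and gradient, vectorized over (chains, SNPs).

    Per-SNP parameter vector of length K = M + 4:
    ``[x_1 .. x_M, xA, log s, logit m, log k]`` with ``a = m k, b = (1-m) k``.
    """

    def __init__(self, counts: VariantCounts, V: np.ndarray, variance_mode: str = "delta",
                 jitter: float = 1e-8):
        self.M = counts.n_sites
        self.N = counts.n_snps
        self.K = self.M + 4
        self.variance_mode = variance_mode
        V = np.asarray(V, dtype=float)
        if V.shape != (self.M, self.M):
            raise ValueError("V dimension does not match the number of sites")
        Vj = V + jitter * np.eye(self.M)
        w = np.linalg.eigvalsh(Vj)
        if w.min() <= 0:
            raise ValueError("V is not positive definite after jitter")
        self.A = np.linalg.inv(Vj)
        self.logdetV = float(np.linalg.slogdet(Vj)[1])
        # (N, M) layouts so SNP blocks broadcast against (C, N, M) states
        self.Y = counts.y.T.astype(float)
        self.Nn = counts.n.T.astype(float)
        self._binom_const_per = (
            gammaln(self.Nn + 1) - gammaln(self.Y + 1) - gammaln(self.Nn - self.Y + 1)
        ).sum(axis=1)

    def logp_grad(self, theta: np.ndarray):
        M = self.M
        x = theta[..., :M]
        xA = theta[..., M]
        u = np.clip(theta[..., M + 1], -60, 60)
        mr = theta[..., M + 2]
        v = np.clip(theta[..., M + 3], -60, 60)

        s = np.exp(u)
        k = np.exp(v)
        m = _sigmoid(mr)
        m = np.clip(m, 1e-12, 1 - 1e-12)
        a = m * k
        b = (1 - m) * k
        fA = _sigmoid(-xA)

        grad = np.zeros_like(theta)

        # binomial layer: sum_j (n-y) x - n softplus(x)  (+ lgamma constants)
        sp = _softplus(x)
        B = ((self.Nn - self.Y) * x - self.Nn * sp).sum(axis=-1) + self._binom_const_per
        fx = _sigmoid(-x)
        grad[..., :M] = self.Nn * fx - self.Y

        # Gaussian drift layer with covariance c V, c = s * g(fA)
        log_g = _softplus(xA) + _softplus(-xA)  # -log fA - log(1-fA)
        if self.variance_mode == "literal":
            log_g = -log_g
            dlogc_dxA = 2 * fA - 1
        else:
            dlogc_dxA = 1 - 2 * fA
        log_c = u + log_g
        c = np.exp(np.clip(log_c, -300, 300))
        r = x - xA[..., None]
        Ar = r @ self.A
        q = np.sum(r * Ar, axis=-1)
        G = -0.5 * (M * np.log(2 * np.pi) + M * log_c + self.logdetV) - q / (2 * c)
        dG_dlogc = -0.5 * M + q / (2 * c)
        grad[..., :M] += -Ar / c[..., None]
        grad[..., M] = Ar.sum(axis=-1) / c + dG_dlogc * dlogc_dxA
        grad[..., M + 1] = dG_dlogc + (1.0 - s)  # + d/du of Exp(1) prior & Jacobian

        # Beta(a, b) hyper-prior on fA, expressed in xA space: the logit
        # change of variables contributes |dfA/dxA| = fA (1 - fA), raising the
        # exponents to (a, b) and giving the prior exponential tails in xA
        lfA = -_softplus(xA)
        l1fA = -_softplus(-xA)
        Pbeta = a * lfA + b * l1fA - (gammaln(a) + gammaln(b) - gammaln(a + b))
        grad[..., M] += -a * (1 - fA) + b * fA
        dPb_da = lfA - digamma(a) + digamma(a + b)
        dPb_db = l1fA - digamma(b) + digamma(a + b)

        # priors s ~ Exp(1), k ~ Exp(1), m ~ Unif(0,1), with log/logit Jacobians
        Pr = -s + u - k + v + np.log(m) + np.log(1 - m)
        grad[..., M + 2] = (dPb_da - dPb_db) * k * m * (1 - m) + (1 - 2 * m)
        grad[..., M + 3] = dPb_da * a + dPb_db * b + (1.0 - k)

        lp = B + G + Pbeta + Pr
        ll = B + G
        bad = ~np.isfinite(lp)
        if bad.any():
            lp = np.where(bad, -np.inf, lp)
            ll = np.where(bad, -np.inf, ll)
            grad[bad] = 0.0
        return lp, grad, ll

    def initial_state(self, chains: int, seed: int) -> tuple[np.ndarray, list[np.random.Generator]]:
        """Data-informed start, jittered per chain; chain c uses seed + c."""
        pooled = (self.Y.sum(axis=1) + 1.0) / (self.Nn.sum(axis=1) + 2.0)
        x_emp = np.where(
            self.Nn > 0,
            balance(np.clip((self.Y + 0.5) / np.maximum(self.Nn + 1.0, 1.0), 1e-3, 1 - 1e-3)),
            balance(np.clip(pooled, 1e-3, 1 - 1e-3))[:, None],
        )
        base = np.zeros((self.N, self.K))
        base[:, : self.M] = x_emp
        base[:, self.M] = balance(np.clip(pooled, 1e-3, 1 - 1e-3))
        base[:, self.M + 1] = np.log(0.2)
        base[:, self.M + 2] = 0.0
        base[:, self.M + 3] = 0.0
        rngs = [np.random.default_rng(seed + c) for c in range(chains)]
        x0 = np.stack([base + 0.1 * rng.standard_normal(base.shape) for rng in rngs])
        return x0, rngs


class _NcpPosterior(_Posterior):
    """Non-centered sampling parametrization of the same posterior.

    Site balances are driven by whitened innovations z: ``x = xA + sqrt(c) L
    z`` with ``L`` the Cholesky factor of V and ``c = s g(fA)``. This removes
    the funnel between the drift scale and the site balances (when s is
    small, z keeps unit scale while x collapses onto xA), which plain HMC
    with a fixed step size cannot traverse in the centered form.

    The ancestral balance is additionally bounded to |xA| <= logit(1 - 1e-4)
    through a smooth tanh map (the ancestral frequency is constrained to
    [1e-4, 1 - 1e-4]), which keeps balances finite and removes the heavy
    tails that otherwise stall mixing for weakly informed SNPs. Stored draws
    are converted back to natural parameters, so downstream summaries are
    unchanged.
    """

    XA_MAX = float(np.log((1 - 1e-4) / 1e-4))  # ~9.21

    def __init__(self, counts: VariantCounts, V: np.ndarray, variance_mode: str = "delta",
                 jitter: float = 1e-8):
        super().__init__(counts, V, variance_mode, jitter)
        Vj = np.asarray(V, dtype=float) + jitter * np.eye(self.M)
        self.Lchol = np.linalg.cholesky(Vj)

    def _common(self, theta):
        M = self.M
        z = theta[..., :M]
        wA = theta[..., M]
        th = np.tanh(wA / self.XA_MAX)
        xA = self.XA_MAX * th
        u = np.clip(theta[..., M + 1], -60, 60)
        fA = _sigmoid(-xA)
        log_g = _softplus(xA) + _softplus(-xA)
        if self.variance_mode == "literal":
            log_g = -log_g
            dlogc_dxA = 2 * fA - 1
        else:
            dlogc_dxA = 1 - 2 * fA
        log_c = u + log_g
        t = np.exp(np.clip(0.5 * log_c, -150, 150))
        lz = z @ self.Lchol.T
        x = xA[..., None] + t[..., None] * lz
        dxA_dw = 1.0 - th * th
        return z, xA, u, fA, log_c, t, lz, x, dlogc_dxA, th, dxA_dw

    def to_natural(self, theta):
        """Map sampled (z, wA, log s, hyper) draws to natural parameters
        (x, xA, log s, hyper)."""
        out = np.array(theta, dtype=float)
        parts = self._common(theta)
        out[..., : self.M] = parts[7]  # x
        out[..., self.M] = parts[1]  # xA
        return out

    def logp_grad(self, theta: np.ndarray):
        M = self.M
        z, xA, u, fA, log_c, t, lz, x, dlogc_dxA, th, dxA_dw = self._common(theta)
        mr = theta[..., M + 2]
        v = np.clip(theta[..., M + 3], -60, 60)
        s = np.exp(u)
        k = np.exp(v)
        m = np.clip(_sigmoid(mr), 1e-12, 1 - 1e-12)
        a = m * k
        b = (1 - m) * k

        grad = np.zeros_like(theta)

        sp = _softplus(x)
        B = ((self.Nn - self.Y) * x - self.Nn * sp).sum(axis=-1) + self._binom_const_per
        dBdx = self.Nn * _sigmoid(-x) - self.Y
        grad[..., :M] = t[..., None] * (dBdx @ self.Lchol)
        sum_dBdx = dBdx.sum(axis=-1)
        dB_dlogc = 0.5 * t * np.sum(dBdx * lz, axis=-1)
        g_xA = sum_dBdx + dB_dlogc * dlogc_dxA  # accumulates d/dxA terms
        grad[..., M + 1] = dB_dlogc

        # whitened innovations prior
        zz = np.sum(z * z, axis=-1)
        G = -0.5 * (M * np.log(2 * np.pi) + zz)
        grad[..., :M] += -z

        # data log-likelihood on the natural scale (binomial + Gaussian drift)
        ll = B - 0.5 * (M * np.log(2 * np.pi) + M * log_c + self.logdetV + zz)

        lfA = -_softplus(xA)
        l1fA = -_softplus(-xA)
        Pbeta = a * lfA + b * l1fA - (gammaln(a) + gammaln(b) - gammaln(a + b))
        g_xA += -a * (1 - fA) + b * fA
        dPb_da = lfA - digamma(a) + digamma(a + b)
        dPb_db = l1fA - digamma(b) + digamma(a + b)

        Pr = -s + u - k + v + np.log(m) + np.log(1 - m)
        # tanh bounding of xA: change-of-variables Jacobian
        Pr = Pr + np.log(np.clip(dxA_dw, 1e-300, None))
        grad[..., M] = g_xA * dxA_dw - 2.0 * th / self.XA_MAX
        grad[..., M + 1] += 1.0 - s
        grad[..., M + 2] = (dPb_da - dPb_db) * k * m * (1 - m) + (1 - 2 * m)
        grad[..., M + 3] = dPb_da * a + dPb_db * b + (1.0 - k)

        lp = B + G + Pbeta + Pr
        bad = ~np.isfinite(lp)
        if bad.any():
            lp = np.where(bad, -np.inf, lp)
            ll = np.where(bad, -np.inf, ll)
            grad[bad] = 0.0
        return lp, grad, ll

    def initial_state(self, chains: int, seed: int):
        x0_nat, rngs = super().initial_state(chains, seed)
        x0 = np.array(x0_nat)
        # map the natural ancestral balance through the inverse tanh bound
        xA_nat = np.clip(x0_nat[..., self.M] / self.XA_MAX, -1 + 1e-9, 1 - 1e-9)
        x0[..., self.M] = self.XA_MAX * np.arctanh(xA_nat)
        # whiten the data-informed balances relative to each chain's start
        parts = self._common(x0)
        xA, t = parts[1], parts[5]
        r = x0_nat[..., : self.M] - xA[..., None]
        flat = r.reshape(-1, self.M).T
        w = np.linalg.solve(self.Lchol, flat).T.reshape(r.shape)
        x0[..., : self.M] = w / np.maximum(t[..., None], 1e-12)
        return x0, rngs


@dataclass
class PopdispFit:
    """Posterior draws and diagnostics for one (center, scenario) fit.

    ``draws`` has shape (chains, kept, N, K) with per-SNP parameter order
    ``[x_1..x_M, xA, log s, logit m, log k]``.
    """

    draws: np.ndarray
    ll_trace: np.ndarray  # (chains, kept) data log-likelihood
    site_ids: list[str]
    snp_ids: list[str]
    n_obs: int  # site x SNP cells with n > 0
    accept_rate: float
    divergent_frac: float
    variance_mode: str
    rhat: np.ndarray | None = None
    ess: np.ndarray | None = None
    scenario_label: str = ""
    center: tuple[float, float] | None = None
    center_index: int = -1
    score: float | None = None

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def n_params(self) -> int:
        """Free-parameter count for the BIC-type score: per SNP the M site
        balances plus ancestral frequency, drift scale and hyper-prior."""
        return self.n_snps * (self.n_sites + 3)


def log_posterior(theta: np.ndarray, counts: VariantCounts, V, variance_mode: str = "delta"):
    """Log posterior density and its gradient.

    ``theta`` has shape (..., N, M + 4) (see :class:`PopdispFit` for the
    layout); returns ``(lp, grad)`` where ``lp`` sums over SNPs and the
    gradient matches ``theta``'s shape.
    """
    Vm = V.V if isinstance(V, DispersalCovariance) else np.asarray(V, dtype=float)
    post = _Posterior(counts, Vm, variance_mode)
    single = theta.ndim == 2
    th = theta[None] if single else theta
    lp, grad, _ = post.logp_grad(th)
    lp = lp.sum(axis=-1)
    if single:
        return float(lp[0]), grad[0]
    return lp, grad


def run_hmc(counts: VariantCounts, V, config: HmcConfig | None = None) -> PopdispFit:
    """Sample the posterior with HMC under covariance ``V``.

    Deterministic given ``config.seed``; chain c draws from an independent
    stream seeded ``seed + c``. The first ``burnin`` fraction of each chain is
    discarded (and used for step-size adaptation when ``adapt``).
    """
    config = config or HmcConfig()
    Vm = V.V if isinstance(V, DispersalCovariance) else np.asarray(V, dtype=float)
    label = V.scenario_label if isinstance(V, DispersalCovariance) else ""
    if config.parametrization == "noncentered":
        post = _NcpPosterior(counts, Vm, config.variance_mode)
        transform = post.to_natural
    else:
        post = _Posterior(counts, Vm, config.variance_mode)
        transform = None
    x0, rngs = post.initial_state(config.chains, config.seed)
    n_warmup = int(config.length * config.burnin)
    run = hmc.sample(
        post.logp_grad,
        x0,
        n_iter=config.length,
        n_warmup=n_warmup,
        rngs=rngs,
        step_size=config.step_size,
        n_leapfrog=config.n_leapfrog,
        adapt=config.adapt,
        target_accept=config.target_accept,
        store_dtype=config.store_dtype,
        store_transform=transform,
    )
    fit = PopdispFit(
        draws=run.draws,
        ll_trace=run.ll,
        site_ids=list(counts.site_ids),
        snp_ids=list(counts.snp_ids),
        n_obs=int((counts.n > 0).sum()),
        accept_rate=float(run.accept_rate.mean()),
        divergent_frac=run.divergent_frac,
        variance_mode=config.variance_mode,
        scenario_label=label,
    )
    if config.compute_diagnostics:
        fit.rhat = gelman_rubin(fit)
        fit.ess = ess(fit)
    fit.score = model_score(fit)
    return fit


def _chains_matrix(fit_or_chains) -> np.ndarray:
    if isinstance(fit_or_chains, PopdispFit):
        c, t, n, k = fit_or_chains.draws.shape
        return fit_or_chains.draws.reshape(c, t, n * k)
    return np.asarray(fit_or_chains)


def gelman_rubin(fit_or_chains) -> np.ndarray:
    """Split Gelman-Rubin R-hat per sampled parameter (flattened SNP x K for
    a :class:`PopdispFit`)."""
    return _gelman_rubin(_chains_matrix(fit_or_chains))


def ess(fit_or_chains) -> np.ndarray:
    """Effective sample size per sampled parameter."""
    return _ess(_chains_matrix(fit_or_chains))


def model_score(fit: PopdispFit) -> float:
    """BIC-type score ``2 max(logL) - k log(n_obs)``; higher is better.

    ``k`` counts the free parameters and ``n_obs`` the observed site x SNP
    cells. Because candidate centers and scenarios only change ``V`` and not
    the parameter count, ranking by this score equals ranking by maximum
    log-likelihood.
    """
    if fit.ll_trace.size == 0:
        raise ValueError("empty log-likelihood trace")
    k = fit.n_params
    penalty = k * np.log(fit.n_obs) if k > 0 else 0.0
    return float(2 * fit.ll_trace.max() - penalty)


class LinearScenario:
    """Geodesic-distance scenario backend."""

    label = "linear"

    def covariance(self, sites: SiteSet, center, center_index: int) -> DispersalCovariance:
        return heuristic_covariance(linear_distances(sites, center))


class RasterScenario:
    """Least-cost-route scenario backend over a cost raster."""

    label = "routes"

    def __init__(self, raster):
        self.raster = raster

    def covariance(self, sites: SiteSet, center, center_index: int) -> DispersalCovariance:
        return heuristic_covariance(least_cost_distances(self.raster, sites, center))


class FixedCovarianceScenario:
    """Scenario with precomputed covariance(s): a single matrix, or one per
    candidate center (keyed by center index)."""

    def __init__(self, label: str, V_by_center):
        self.label = label
        self._v = V_by_center

    def covariance(self, sites, center, center_index: int) -> DispersalCovariance:
        v = self._v
        if isinstance(v, (list, tuple, dict)):
            v = v[center_index]
        if isinstance(v, DispersalCovariance):
            return DispersalCovariance(v.V, v.scale_applied, self.label)
        return DispersalCovariance(np.asarray(v, dtype=float), True, self.label)


def select_center_and_scenario(
    counts: VariantCounts,
    sites: SiteSet,
    scenarios,
    centers: np.ndarray | None = None,
    config: HmcConfig | None = None,
    grid: int = 4,
    margin: float = 0.1,
) -> tuple[PopdispFit, pd.DataFrame]:
    """Fit every (candidate center, scenario) pair and keep the best score.

    ``scenarios`` is an iterable of backends exposing ``label`` and
    ``covariance(sites, center, center_index)``. Centers default to the even
    grid over the shrunk bounding rectangle of the sites. Returns the winning
    fit and the full score table (one row per pair). Ties go to the first
    pair in iteration order, with a warning.
    """
    config = config or HmcConfig()
    if centers is None:
        centers = candidate_centers(sites, grid=grid, margin=margin)
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    rows = []
    best: PopdispFit | None = None
    for scen in scenarios:
        for ci, center in enumerate(centers):
            V = scen.covariance(sites, center, ci)
            fit = run_hmc(counts, V, config)
            fit.center = (float(center[0]), float(center[1]))
            fit.center_index = ci
            fit.scenario_label = scen.label
            rows.append(
                {
                    "scenario": scen.label,
                    "center_index": ci,
                    "lon": center[0],
                    "lat": center[1],
                    "score": fit.score,
                    "max_loglik": float(fit.ll_trace.max()),
                    "max_rhat": float(np.max(fit.rhat)) if fit.rhat is not None else np.nan,
                }
            )
            if best is None or fit.score > best.score:
                best = fit
            elif fit.score == best.score:
                warnings.warn("score tie between candidate fits; keeping the first", stacklevel=2)
    table = pd.DataFrame(rows).sort_values("score", ascending=False).reset_index(drop=True)
    return best, table


def representative_frequencies(fit: PopdispFit, pop_id: str = "region") -> pd.DataFrame:
    """Representative ancestral allele frequency per SNP, as a 1 x N
    population table ready for admixture analysis.

    Following the compositional-data convention the posterior is averaged on
    the balance (logit) scale and back-transformed, so the frequency table
    and the balance table (:func:`representative_balances`) are consistent.
    """
    xA = fit.draws[:, :, :, fit.n_sites].astype(float).mean(axis=(0, 1))
    return pd.DataFrame(
        [inverse_balance(xA)], index=pd.Index([pop_id], name="pop"), columns=fit.snp_ids
    )


def site_frequencies(fit: PopdispFit) -> pd.DataFrame:
    """Posterior-mean site-level allele frequencies (M x N table), averaged
    on the balance scale and back-transformed."""
    x = fit.draws[:, :, :, : fit.n_sites].astype(float).mean(axis=(0, 1))
    return pd.DataFrame(
        inverse_balance(x).T, index=pd.Index(fit.site_ids, name="pop"), columns=fit.snp_ids
    )


def representative_balances(fit: PopdispFit, pop_id: str = "region") -> pd.DataFrame:
    """Posterior-mean ancestral log-balance per SNP (1 x N table)."""
    xA = fit.draws[:, :, :, fit.n_sites].astype(float).mean(axis=(0, 1))
    return pd.DataFrame([xA], index=pd.Index([pop_id], name="pop"), columns=fit.snp_ids)
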