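"""Hierarchical Bernoulli–beta model of group choice preference.

Per-subject free-trial decisions are Bernoulli(theta_s); the subject-level
rates share a mode-parameterized beta group prior

    theta_s ~ Beta(mu*(kappa-2)+1, (1-mu)*(kappa-2)+1),   kappa >= 2,

so ``mu`` is the group-level preference (the beta mode) and ``kappa`` the
concentration of subjects around it.  Hyperpriors: mu ~ Beta(1,1) (flat) and
(kappa - 2) ~ Gamma(shape 0.01, rate 0.01), i.e. the diffuse concentration
prior placed on the part of kappa above its floor of 2 — at kappa = 2 the
group prior is uniform, so both beta shape parameters stay >= 1 for every
draw.

Sampling is an adaptive Metropolis-within-Gibbs random walk on the
unconstrained scales (logit mu, log(kappa-2), logit theta_s).  Given mu and
kappa the subject rates are conditionally independent, so the theta block is
updated element-wise in one vectorized step.  Proposal scales adapt toward a
0.44 acceptance rate during warmup only, leaving the post-warmup kernel
fixed and valid.

Diagnostics follow the classic (rank-free) definitions: split-half
Gelman–Rubin R-hat and autocorrelation ESS with Geyer's initial monotone
positive-sequence truncation.  The HDI is the narrowest window containing
the requested mass of sorted draws.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import betaln, expit, logit

logger = logging.getLogger(__name__)

KAPPA_FLOOR = 2.0


@dataclass(frozen=True)
class PriorConfig:
    """Hyperprior shapes: Beta(mu_prior) on mu, Gamma(shape, rate) on kappa-2."""

    mu_prior: tuple[float, float] = (1.0, 1.0)
    kappa_shape: float = 0.01
    kappa_rate: float = 0.01
    kappa_floor: float = KAPPA_FLOOR

    def __post_init__(self) -> None:
        if min(self.mu_prior) <= 0 or self.kappa_shape <= 0 or self.kappa_rate <= 0:
            raise ValueError("prior shapes must be positive")
        if self.kappa_floor != KAPPA_FLOOR:
            raise ValueError("kappa floor is fixed at 2 by the beta mode parameterization")


@dataclass(frozen=True)
class McmcConfig:
    """Chains, lengths and proposal-scale seeds for the random-walk sampler."""

    n_chains: int = 12
    n_iter: int = 15_000
    n_warmup: int = 5_000
    seed: int = 0
    init_scale_mu: float = 0.1
    init_scale_kappa: float = 0.5
    init_scale_theta: float = 0.3

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ValueError("need at least one chain")
        if not 0 < self.n_warmup < self.n_iter:
            raise ValueError("need 0 < n_warmup < n_iter")


@dataclass
class PosteriorDraws:
    """Raw MCMC output: (chain, iteration) arrays, warmup included and flagged."""

    mu: np.ndarray  # (n_chains, n_iter)
    kappa: np.ndarray  # (n_chains, n_iter)
    theta: np.ndarray  # (n_chains, n_iter, n_subjects)
    n_warmup: int
    subject_ids: list[str] = field(default_factory=list)

    @property
    def post(self) -> "PosteriorDraws":
        """View restricted to post-warmup draws (n_warmup = 0)."""
        w = self.n_warmup
        return PosteriorDraws(
            self.mu[:, w:], self.kappa[:, w:], self.theta[:, w:, :], 0, self.subject_ids
        )

    def flat_mu(self) -> np.ndarray:
        return self.mu[:, self.n_warmup:].ravel()


@dataclass(frozen=True)
class ParamSummary:
    mean: float
    hdi: tuple[float, float]
    rhat: float
    ess: float


@dataclass(frozen=True)
class PosteriorSummary:
    mu: ParamSummary
    kappa: ParamSummary
    theta: list[ParamSummary]
    subject_ids: list[str]
    converged: bool

    def to_dict(self) -> dict:
        def d(p: ParamSummary) -> dict:
            return {"mean": p.mean, "hdi": list(p.hdi), "rhat": p.rhat, "ess": p.ess}

        return {
            "mu": d(self.mu),
            "kappa": d(self.kappa),
            "theta": {sid: d(p) for sid, p in zip(self.subject_ids, self.theta)},
            "converged": self.converged,
        }


def beta_shape_params(mu: float, kappa: float) -> tuple[float, float]:
    """Shape pair (a, b) of the mode-parameterized beta: a,b >= 1 always."""
    if not 0.0 < mu < 1.0:
        raise ValueError("mu must be in (0, 1)")
    if kappa < KAPPA_FLOOR:
        raise ValueError("kappa must be >= 2")
    return mu * (kappa - 2.0) + 1.0, (1.0 - mu) * (kappa - 2.0) + 1.0


def log_posterior(
    mu: float,
    kappa: float,
    thetas: Sequence[float],
    data: Sequence[tuple[int, int]],
    priors: PriorConfig = PriorConfig(),
) -> float:
    """Unnormalized log posterior density in the natural parameterization.

    ``data`` is one (successes, trials) pair per subject.  Returns -inf
    outside the support.
    """
    thetas = np.asarray(thetas, dtype=float)
    if len(thetas) != len(data):
        raise ValueError("one theta per subject required")
    if not (0.0 < mu < 1.0) or kappa < KAPPA_FLOOR:
        return -math.inf
    if np.any((thetas <= 0.0) | (thetas >= 1.0)):
        return -math.inf

    a, b = beta_shape_params(mu, kappa)
    lp = 0.0
    ks = np.array([k for k, _ in data], dtype=float)
    ns = np.array([n for _, n in data], dtype=float)
    if np.any(ks < 0) or np.any(ks > ns):
        raise ValueError("need 0 <= successes <= trials")
    lp += float(np.sum(ks * np.log(thetas) + (ns - ks) * np.log1p(-thetas)))
    lp += float(
        np.sum((a - 1.0) * np.log(thetas) + (b - 1.0) * np.log1p(-thetas)) - len(data) * betaln(a, b)
    )
    am, bm = priors.mu_prior
    lp += (am - 1.0) * math.log(mu) + (bm - 1.0) * math.log1p(-mu)
    g = kappa - priors.kappa_floor
    if g <= 0.0:
        # kappa exactly at the floor: the Gamma(0.01, 0.01) density diverges;
        # treat as outside support for a point evaluation
        return -math.inf
    lp += (priors.kappa_shape - 1.0) * math.log(g) - priors.kappa_rate * g
    return lp


# ---------------------------------------------------------------------------
# sampler internals (unconstrained scale)

def _log1p_exp(x: np.ndarray) -> np.ndarray:
    """log(1 + exp(x)), overflow-safe."""
    return np.logaddexp(0.0, x)


def _theta_logtarget(z: np.ndarray, ks: np.ndarray, ns: np.ndarray, a: float, b: float) -> np.ndarray:
    """Per-subject log target of logit(theta), Jacobian included.

    Exponents collapse to (k + a) log theta + (n - k + b) log(1 - theta).
    """
    log_t = -_log1p_exp(-z)
    log_1mt = -_log1p_exp(z)
    return (ks + a) * log_t + (ns - ks + b) * log_1mt


def _hyper_logtarget(
    z_mu: float, z_k: float, sum_log_t: float, sum_log_1mt: float, n_sub: int, priors: PriorConfig
) -> float:
    """Log target of (logit mu, log(kappa-2)) given theta sufficient stats."""
    mu = expit(z_mu)
    g = math.exp(z_k)
    kappa = priors.kappa_floor + g
    a, b = mu * (kappa - 2.0) + 1.0, (1.0 - mu) * (kappa - 2.0) + 1.0
    lp = (a - 1.0) * sum_log_t + (b - 1.0) * sum_log_1mt - n_sub * betaln(a, b)
    am, bm = priors.mu_prior
    # Beta(am, bm) prior on mu with the logit Jacobian mu(1-mu) folded in
    lp += am * math.log(mu) + bm * math.log1p(-mu)
    # Gamma(shape, rate) prior on g = kappa - 2 with the log Jacobian folded in
    lp += priors.kappa_shape * math.log(g) - priors.kappa_rate * g
    return lp


class _Adapt:
    """Robbins–Monro proposal-scale adaptation toward 0.44 acceptance."""

    def __init__(self, scale, batch: int = 50, target: float = 0.44):
        self.log_scale = np.log(np.asarray(scale, dtype=float))
        self.batch = batch
        self.target = target
        self.acc = np.zeros_like(self.log_scale)
        self.count = 0
        self.n_batches = 0

    @property
    def scale(self):
        return np.exp(self.log_scale)

    def update(self, accepted) -> None:
        self.acc = self.acc + accepted
        self.count += 1
        if self.count >= self.batch:
            self.n_batches += 1
            delta = min(0.1, self.n_batches ** -0.5)
            rate = self.acc / self.count
            self.log_scale = self.log_scale + np.where(rate > self.target, delta, -delta)
            self.acc = np.zeros_like(self.log_scale)
            self.count = 0


def _run_chain(
    ks: np.ndarray,
    ns: np.ndarray,
    priors: PriorConfig,
    mcmc: McmcConfig,
    seed: int,
    fix_mu: Optional[float],
    fix_kappa: Optional[float],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    rng = np.random.default_rng(seed)
    n_sub = len(ks)
    n_iter, n_warm = mcmc.n_iter, mcmc.n_warmup

    # init at smoothed empirical rates, jittered per chain
    theta0 = (ks + 1.0) / (ns + 2.0)
    z_theta = logit(np.clip(theta0 + rng.normal(0, 0.05, n_sub), 1e-3, 1 - 1e-3))
    mu0 = float(np.clip(np.mean(theta0) + rng.normal(0, 0.05), 1e-3, 1 - 1e-3))
    z_mu = float(logit(fix_mu)) if fix_mu is not None else float(logit(mu0))
    g0 = max(rng.lognormal(math.log(10.0), 0.5), 1e-3)
    z_k = math.log(max(fix_kappa - priors.kappa_floor, 1e-12)) if fix_kappa is not None else math.log(g0)

    ad_theta = _Adapt(np.full(n_sub, mcmc.init_scale_theta))
    ad_mu = _Adapt(mcmc.init_scale_mu)
    ad_kappa = _Adapt(mcmc.init_scale_kappa)

    mu_out = np.empty(n_iter)
    kappa_out = np.empty(n_iter)
    theta_out = np.empty((n_iter, n_sub))

    mu = expit(z_mu) if fix_mu is None else fix_mu
    kappa = priors.kappa_floor + math.exp(z_k)
    if fix_kappa is not None:
        kappa = fix_kappa
    a, b = beta_shape_params(min(max(mu, 1e-12), 1 - 1e-12), max(kappa, KAPPA_FLOOR))
    lt_theta = _theta_logtarget(z_theta, ks, ns, a, b)

    sample_hyper = fix_mu is None or fix_kappa is None
    for it in range(n_iter):
        warm = it < n_warm

        # --- theta block: element-wise Gaussian RW on logit theta ---
        z_prop = z_theta + ad_theta.scale * rng.standard_normal(n_sub)
        lt_prop = _theta_logtarget(z_prop, ks, ns, a, b)
        accept = np.log(rng.random(n_sub)) < (lt_prop - lt_theta)
        z_theta = np.where(accept, z_prop, z_theta)
        lt_theta = np.where(accept, lt_prop, lt_theta)
        if warm:
            ad_theta.update(accept.astype(float))

        if sample_hyper:
            log_t = -_log1p_exp(-z_theta)
            log_1mt = -_log1p_exp(z_theta)
            s_lt, s_l1mt = float(log_t.sum()), float(log_1mt.sum())

            # --- mu: scalar RW on logit mu ---
            if fix_mu is None:
                cur = _hyper_logtarget(z_mu, z_k, s_lt, s_l1mt, n_sub, priors)
                z_mu_p = z_mu + float(ad_mu.scale) * rng.standard_normal()
                prop = _hyper_logtarget(z_mu_p, z_k, s_lt, s_l1mt, n_sub, priors)
                acc = math.log(rng.random()) < prop - cur
                if acc:
                    z_mu = z_mu_p
                if warm:
                    ad_mu.update(float(acc))

            # --- kappa: scalar RW on log(kappa - 2) ---
            if fix_kappa is None:
                cur = _hyper_logtarget(z_mu, z_k, s_lt, s_l1mt, n_sub, priors)
                z_k_p = z_k + float(ad_kappa.scale) * rng.standard_normal()
                prop = _hyper_logtarget(z_mu, z_k_p, s_lt, s_l1mt, n_sub, priors)
                acc = math.log(rng.random()) < prop - cur
                if acc:
                    z_k = z_k_p
                if warm:
                    ad_kappa.update(float(acc))

            mu = expit(z_mu) if fix_mu is None else fix_mu
            kappa = (priors.kappa_floor + math.exp(z_k)) if fix_kappa is None else fix_kappa
            a = mu * (kappa - 2.0) + 1.0
            b = (1.0 - mu) * (kappa - 2.0) + 1.0
            lt_theta = _theta_logtarget(z_theta, ks, ns, a, b)

        mu_out[it] = mu
        kappa_out[it] = kappa
        theta_out[it] = expit(z_theta)

    return mu_out, kappa_out, theta_out


def sample_posterior(
    data: Sequence[tuple[int, int]],
    priors: PriorConfig = PriorConfig(),
    mcmc: McmcConfig = McmcConfig(),
    subject_ids: Optional[list[str]] = None,
    fix_mu: Optional[float] = None,
    fix_kappa: Optional[float] = None,
) -> PosteriorDraws:
    """Draw from the posterior by adaptive Metropolis-within-Gibbs.

    ``data`` is one (successes, trials) pair per subject.  ``fix_mu`` /
    ``fix_kappa`` clamp a hyperparameter at a point (delta prior), which
    reduces each subject's theta posterior to the conjugate
    Beta(a + k, b + n - k) — the analytic oracle used in validation.

    Reproducible: identical data + configs + seed give identical draws.
    """
    data = list(data)
    if len(data) == 0:
        raise ValueError("need at least one subject")
    ks = np.array([k for k, _ in data], dtype=float)
    ns = np.array([n for _, n in data], dtype=float)
    if np.any(ns < 0) or np.any((ks < 0) | (ks > ns)):
        raise ValueError("need 0 <= successes <= trials per subject")
    if np.all(ns == 0):
        raise ValueError("all subjects have zero trials")
    if fix_kappa is not None and fix_kappa < KAPPA_FLOOR:
        raise ValueError("fixed kappa must be >= 2")

    seeds = np.random.SeedSequence(mcmc.seed).spawn(mcmc.n_chains)
    mus, kappas, thetas = [], [], []
    for c in range(mcmc.n_chains):
        m, k, t = _run_chain(ks, ns, priors, mcmc, seeds[c], fix_mu, fix_kappa)
        mus.append(m)
        kappas.append(k)
        thetas.append(t)
    ids = subject_ids if subject_ids is not None else [f"s{i+1}" for i in range(len(data))]
    return PosteriorDraws(
        mu=np.stack(mus), kappa=np.stack(kappas), theta=np.stack(thetas),
        n_warmup=mcmc.n_warmup, subject_ids=ids,
    )


# ---------------------------------------------------------------------------
# posterior summaries and diagnostics

def hdi(draws: Sequence[float], mass: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``mass`` of the draws (narrowest-window scan)."""
    x = np.sort(np.asarray(draws, dtype=float).ravel())
    n = len(x)
    if n < 100:
        raise ValueError("need at least 100 draws for an HDI")
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must be in (0, 1)")
    m = int(math.ceil(mass * n))
    widths = x[m - 1:] - x[: n - m + 1]
    j = int(np.argmin(widths))
    lo, hi = float(x[j]), float(x[j + m - 1])
    _warn_if_multimodal(x)
    return lo, hi


def _warn_if_multimodal(sorted_draws: np.ndarray) -> None:
    """Warn when the draw histogram shows two well-separated substantial modes."""
    counts, _ = np.histogram(sorted_draws, bins=32)
    sm = np.convolve(counts, np.ones(5) / 5.0, mode="same")
    peaks = [
        i
        for i in range(1, len(sm) - 1)
        if sm[i] >= sm[i - 1] and sm[i] >= sm[i + 1] and sm[i] > 0.5 * sm.max()
    ]
    for i, j in zip(peaks, peaks[1:]):
        trough = sm[i : j + 1].min()
        if trough < 0.5 * min(sm[i], sm[j]):
            logger.warning("draw set looks multimodal; HDI is the single shortest window")
            return


def rhat(chains: np.ndarray) -> float:
    """Classic split-half Gelman–Rubin potential scale reduction factor.

    ``chains`` is (n_chains, n_draws) or a single 1-D chain; each chain is
    split in half, and the between/within variance ratio of the 2m
    half-chains is returned (so a single trending chain still registers).
    NaN (flagged undefined) for constant chains.
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    if x.ndim != 2 or x.shape[1] < 100:
        raise ValueError("need chains of equal length >= 100")
    half = x.shape[1] // 2
    splits = np.concatenate([x[:, :half], x[:, half: 2 * half]], axis=0)
    w = splits.var(axis=1, ddof=1).mean()
    if w == 0.0:
        logger.warning("constant chains: R-hat undefined")
        return math.nan
    n = half
    b = n * splits.mean(axis=1).var(ddof=1)
    var_hat = (n - 1) / n * w + b / n
    return float(math.sqrt(var_hat / w))


def _chain_autocorr(x: np.ndarray, max_lag: int) -> np.ndarray:
    n = len(x)
    xc = x - x.mean()
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(xc, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[: max_lag + 1].real / n
    if acov[0] == 0:
        return np.zeros(max_lag + 1)
    return acov / acov[0]


def ess(chains: np.ndarray) -> float:
    """Autocorrelation ESS with Geyer initial-monotone positive-sequence truncation.

    Chain-averaged autocorrelations are summed over lag pairs until the
    paired sum turns negative (then forced monotone non-increasing);
    ESS = total draws / integrated autocorrelation time.  0 for constant
    chains.
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    if x.shape[1] < 100:
        raise ValueError("need chains of length >= 100")
    m, n = x.shape
    if np.all(x.var(axis=1) == 0):
        logger.warning("constant chains: ESS = 0")
        return 0.0
    max_lag = n - 2
    rho = np.mean([_chain_autocorr(x[c], max_lag) for c in range(m)], axis=0)
    # Geyer pairs Gamma_t = rho_{2t} + rho_{2t+1}
    n_pairs = (max_lag + 1) // 2
    gammas = rho[0 : 2 * n_pairs : 2] + rho[1 : 2 * n_pairs : 2]
    pos = []
    for gdx in gammas:
        if gdx <= 0.0:
            break
        pos.append(gdx)
    # enforce monotone non-increasing
    for i in range(1, len(pos)):
        pos[i] = min(pos[i], pos[i - 1])
    tau = max(-1.0 + 2.0 * sum(pos), 1e-12)
    return float(min(m * n, m * n / tau))


def posterior_summary(
    draws: PosteriorDraws, mass: float = 0.95, rhat_limit: float = 1.05, force: bool = False
) -> PosteriorSummary:
    """Means, HDIs and convergence diagnostics for mu, kappa and each theta.

    Refuses (unless ``force``) when the group-level R-hat exceeds
    ``rhat_limit``; with force, the summary carries ``converged=False``.
    """
    post = draws.post

    def summarize(x2d: np.ndarray) -> ParamSummary:
        r = rhat(x2d)
        return ParamSummary(
            mean=float(x2d.mean()), hdi=hdi(x2d.ravel(), mass), rhat=r, ess=ess(x2d)
        )

    mu_s = summarize(post.mu)
    converged = not (math.isfinite(mu_s.rhat) and mu_s.rhat >= rhat_limit)
    if not converged:
        msg = f"group-level R-hat {mu_s.rhat:.3f} >= {rhat_limit}"
        if not force:
            raise RuntimeError(msg + " (pass force=True to summarize anyway)")
        logger.warning(msg)
    kappa_s = summarize(post.kappa)
    theta_s = [summarize(post.theta[:, :, j]) for j in range(post.theta.shape[2])]
    return PosteriorSummary(
        mu=mu_s, kappa=kappa_s, theta=theta_s, subject_ids=draws.subject_ids, converged=converged
    )
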