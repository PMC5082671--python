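"""Multilevel Bayesian Poisson model of between-year density change.

Strip-transect counts of the j-th taxon on the i-th transect are
modelled as

    y_ij ~ Poisson(mu_ij),
    log(mu_ij) = log(A_ij) + alpha_j + beta_j * Year_i + eps_ij,

where A_ij is the surveyed area (m^2, entering as an offset), Year_i is
0 for the first study year (2014) and 1 for the second, alpha_j is the
taxon log density (per m^2) in the first year, beta_j the taxon log
density change in the second, and eps_ij ~ N(0, sigma_eps) is an
observation-level normal random effect absorbing overdispersion.  The
taxon effects are exchangeable draws from a bivariate normal,

    (alpha_j, beta_j) ~ N((mu_alpha, mu_beta), Sigma),

with Sigma parameterised by standard deviations sigma_alpha,
sigma_beta and correlation rho.  Priors are vague: N(0, 10000)
(variance) for the two means, Uniform(0, 100) for the three standard
deviations and Uniform(-1, 1) for rho.

Sampling is by adaptive Metropolis-within-Gibbs: per-taxon joint
random-walk updates of (alpha_j, beta_j), vectorised element-wise
updates of the eps_ij, a conjugate Gibbs draw of (mu_alpha, mu_beta),
and scalar random-walk updates of sigma_alpha, sigma_beta, sigma_eps
and rho.  Proposal scales adapt toward a 20-40% acceptance rate during
burn-in only, so the retained chain is a valid time-homogeneous Markov
chain.  A taxon's density change is called credible when the
equal-tailed 95% posterior interval of beta_j excludes zero; the
posterior probability of a decline, P(beta_j < 0), is reported
alongside so borderline cases are visible without inventing a second
threshold.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

_LOG2PI = math.log(2.0 * math.pi)


# ---------------------------------------------------------------------------
# data preparation

def transect_counts(
    transects: pd.DataFrame,
    stars: pd.DataFrame,
    taxa: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per transect x taxon counts with area offset and year indicator.

    Zero counts are explicit rows (every surveyed transect contributes
    a row for every taxon).  ``year01`` is 0 for 2014 and 1 otherwise.
    """
    if taxa is None:
        if "taxon" not in stars.columns:
            raise ValueError("stars table has no taxon column; pass taxa=")
        taxa = sorted(stars["taxon"].unique())
    base = transects[["transect_id", "area_m2", "year"]].copy()
    grid = base.merge(pd.DataFrame({"taxon": list(taxa)}), how="cross")
    if len(stars):
        counts = (
            stars.groupby(["transect_id", "taxon"], observed=True)
            .size().rename("count").reset_index()
        )
    else:
        counts = pd.DataFrame(columns=["transect_id", "taxon", "count"])
    out = grid.merge(counts, on=["transect_id", "taxon"], how="left")
    out["count"] = out["count"].fillna(0).astype(int)
    out["year01"] = (out["year"] != 2014).astype(int)
    return out[["transect_id", "taxon", "count", "area_m2", "year", "year01"]]


def density_table(transects: pd.DataFrame, stars: pd.DataFrame,
                  taxa: Sequence[str] | None = None) -> pd.DataFrame:
    """Observed taxon density per 100 m^2, by year.

    density = 100 * total count / total surveyed area.  Years with no
    transects are absent from the table ("not surveyed"), which is
    distinct from a surveyed year with zero counts (density 0).
    """
    tc = transect_counts(transects, stars, taxa)
    g = tc.groupby(["taxon", "year"], observed=True).agg(
        total_count=("count", "sum"), total_area_m2=("area_m2", "sum"))
    g["density_per_100m2"] = 100.0 * g["total_count"] / g["total_area_m2"]
    return g.reset_index()


# ---------------------------------------------------------------------------
# model configuration

@dataclass(frozen=True)
class PriorConfig:
    """Vague priors: N(0, mu_variance) means, U(0, sigma_upper) SDs,
    U(-1, 1) correlation."""

    mu_variance: float = 10_000.0
    sigma_upper: float = 100.0

    @property
    def mu_sd(self) -> float:
        return math.sqrt(self.mu_variance)


@dataclass(frozen=True)
class ChainConfig:
    """MCMC run lengths.  ``retained_per_chain`` applies thinning after
    the burn-in, so the default study-scale configuration
    (3 x 60,000 after 10,000 burn-in, thin 5) retains 30,000 draws."""

    n_chains: int = 3
    iterations: int = 6_000
    burn_in: int = 1_000
    thin: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.iterations <= 0 or self.burn_in < 0:
            raise ValueError("need a positive post-burn-in iteration count")
        if self.thin < 1 or self.n_chains < 1:
            raise ValueError("thin and n_chains must be >= 1")

    @property
    def retained_per_chain(self) -> int:
        return self.iterations // self.thin

    @classmethod
    def study_scale(cls, seed: int = 0) -> "ChainConfig":
        return cls(n_chains=3, iterations=60_000, burn_in=10_000, thin=5, seed=seed)


@dataclass
class ModelParams:
    """One point in parameter space (used by :func:`log_posterior`)."""

    alpha: np.ndarray
    beta: np.ndarray
    eps: np.ndarray
    mu_alpha: float
    mu_beta: float
    sigma_alpha: float
    sigma_beta: float
    sigma_eps: float
    rho: float


# ---------------------------------------------------------------------------
# densities

def _bvn_logpdf_sum(a, b, mu_a, mu_b, sa, sb, rho) -> float:
    """Sum of bivariate-normal log densities of the pairs (a_j, b_j)."""
    da = (np.asarray(a) - mu_a) / sa
    db = (np.asarray(b) - mu_b) / sb
    omr2 = 1.0 - rho * rho
    quad = (da * da - 2.0 * rho * da * db + db * db) / omr2
    const = _LOG2PI + math.log(sa) + math.log(sb) + 0.5 * math.log(omr2)
    return float(-len(da) * const - 0.5 * np.sum(quad))


def log_posterior(
    params: ModelParams,
    data: pd.DataFrame,
    priors: PriorConfig | None = None,
) -> float:
    """Unnormalised log posterior density of the full parameter vector.

    Sums the Poisson log-likelihood with the log-area offset, the
    bivariate-normal density of the taxon effects, the normal density
    of the overdispersion effects, and the log priors.  Returns -inf
    outside the support (including non-finite inputs) rather than
    raising, so samplers can evaluate freely.
    """
    priors = priors or PriorConfig()
    p = params
    scalars = np.asarray([p.mu_alpha, p.mu_beta, p.sigma_alpha, p.sigma_beta,
                          p.sigma_eps, p.rho], dtype=float)
    arrays = np.concatenate([np.ravel(p.alpha), np.ravel(p.beta),
                             np.ravel(p.eps), scalars])
    if not np.all(np.isfinite(arrays)):
        return -math.inf
    if not (0.0 < p.sigma_alpha < priors.sigma_upper
            and 0.0 < p.sigma_beta < priors.sigma_upper
            and 0.0 < p.sigma_eps < priors.sigma_upper
            and -1.0 < p.rho < 1.0):
        return -math.inf

    y = data["count"].to_numpy(dtype=float)
    logA = np.log(data["area_m2"].to_numpy(dtype=float))
    year = data["year01"].to_numpy(dtype=float)
    taxa = sorted(data["taxon"].unique())
    tj = data["taxon"].map({t: i for i, t in enumerate(taxa)}).to_numpy()

    loglam = logA + np.asarray(p.alpha)[tj] + np.asarray(p.beta)[tj] * year + np.asarray(p.eps)
    lp = float(np.sum(y * loglam - np.exp(loglam) - gammaln(y + 1.0)))
    lp += _bvn_logpdf_sum(p.alpha, p.beta, p.mu_alpha, p.mu_beta,
                          p.sigma_alpha, p.sigma_beta, p.rho)
    eps = np.asarray(p.eps, dtype=float)
    lp += float(-0.5 * len(eps) * (_LOG2PI + 2.0 * math.log(p.sigma_eps))
                - 0.5 * np.sum(eps**2) / p.sigma_eps**2)
    # priors
    v = priors.mu_variance
    lp += -0.5 * (_LOG2PI + math.log(v)) - 0.5 * p.mu_alpha**2 / v
    lp += -0.5 * (_LOG2PI + math.log(v)) - 0.5 * p.mu_beta**2 / v
    lp += 3.0 * -math.log(priors.sigma_upper)  # three uniform SD priors
    lp += -math.log(2.0)  # uniform correlation prior
    return lp


# ---------------------------------------------------------------------------
# the sampler

@dataclass
class PosteriorDraws:
    """Retained draws, one array of shape (n_chains, n_retained) per
    parameter; taxon effects are named ``alpha[taxon]`` / ``beta[taxon]``."""

    draws: dict[str, np.ndarray]
    taxa: tuple[str, ...]
    chain_config: ChainConfig
    acceptance: dict[str, float] = field(default_factory=dict)

    def combined(self, name: str) -> np.ndarray:
        return self.draws[name].reshape(-1)

    @property
    def parameters(self) -> list[str]:
        return list(self.draws)

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({k: v.reshape(-1) for k, v in self.draws.items()})
        n = self.draws[next(iter(self.draws))].shape[1]
        out.insert(0, "chain", np.repeat(np.arange(self.chain_config.n_chains), n))
        return out


class _Adapt:
    """Robbins-Monro-style proposal scaling, active during burn-in only."""

    def __init__(self, scale, lo=0.20, hi=0.40, every=50):
        self.scale = np.asarray(scale, dtype=float)
        self.accepts = np.zeros_like(self.scale)
        self.count = 0
        self.lo, self.hi, self.every = lo, hi, every

    def record(self, accepted) -> None:
        self.accepts = self.accepts + accepted
        self.count += 1
        if self.count >= self.every:
            rate = self.accepts / self.count
            self.scale = np.clip(
                self.scale * np.where(
                    rate > self.hi, 1.25, np.where(rate < self.lo, 0.8, 1.0)),
                1e-3, 10.0)
            self.accepts = np.zeros_like(self.scale)
            self.count = 0


def _run_one_chain(y, logA, year, tj, J, priors, cfg, rng,
                   fix_sigma_eps, store_eps=False):
    N = len(y)
    counts_by_taxon = np.bincount(tj, minlength=J) if N else np.zeros(J, dtype=int)

    # random starts mirroring the study's dialect
    mu_a, mu_b = rng.normal(), rng.normal()
    sa, sb, se_, rho = rng.uniform(0, 1, size=4)
    sa, sb, se_ = max(sa, 1e-3), max(sb, 1e-3), max(se_, 1e-3)
    alpha = rng.normal(size=J)
    beta = rng.normal(size=J)
    if fix_sigma_eps is not None:
        se_ = float(fix_sigma_eps)
    eps = rng.normal(size=N) if (N and se_ > 0) else np.zeros(N)

    loglam = (logA + alpha[tj] + beta[tj] * year + eps) if N else np.zeros(0)

    ad_a = _Adapt(np.full(J, 0.3))
    ad_b = _Adapt(np.full(J, 0.3))
    ad_eps = _Adapt(np.array(0.5))
    ad_hyper = _Adapt(np.full(4, 0.3))  # sigma_alpha, sigma_beta, sigma_eps, rho
    ad_rescale = _Adapt(np.array(0.3))

    n_keep = cfg.iterations // cfg.thin
    out = {
        "mu_alpha": np.empty(n_keep), "mu_beta": np.empty(n_keep),
        "sigma_alpha": np.empty(n_keep), "sigma_beta": np.empty(n_keep),
        "sigma_eps": np.empty(n_keep), "rho": np.empty(n_keep),
        "alpha": np.empty((n_keep, J)), "beta": np.empty((n_keep, J)),
    }
    accept_totals = {"taxon_effects": 0.0, "eps": 0.0, "hyper": 0.0}
    post_n = 0

    prior_prec = 1.0 / priors.mu_variance

    def bvn_term(a, b, sa_, sb_, rho_):
        return _bvn_logpdf_sum(a, b, mu_a, mu_b, sa_, sb_, rho_) if J else 0.0

    # extreme proposals can overflow exp(); they get -inf likelihood and
    # are rejected, so the overflow itself is benign
    _err = np.errstate(over="ignore")
    _err.__enter__()
    for it in range(cfg.burn_in + cfg.iterations):
        burn = it < cfg.burn_in

        # --- per-taxon random-walk updates of alpha then beta, each with
        # its own adaptive scale (slopes of taxa unseen in one year are
        # weakly identified and need wider proposals than intercepts)
        if J:
            omr2 = 1.0 - rho * rho

            def quad(a, b):
                da, db = (a - mu_a) / sa, (b - mu_b) / sb
                return (da * da - 2.0 * rho * da * db + db * db) / omr2

            for comp, adapt in (("alpha", ad_a), ("beta", ad_b)):
                if comp == "alpha":
                    prop_a = alpha + adapt.scale * rng.normal(size=J)
                    prop_b = beta
                else:
                    prop_a = alpha
                    prop_b = beta + adapt.scale * rng.normal(size=J)
                if N:
                    loglam_new = logA + prop_a[tj] + prop_b[tj] * year + eps
                    dlik_obs = (y * (loglam_new - loglam)
                                - (np.exp(loglam_new) - np.exp(loglam)))
                    dlik = np.bincount(tj, weights=dlik_obs, minlength=J)
                else:
                    dlik = np.zeros(J)
                dprior = -0.5 * (quad(prop_a, prop_b) - quad(alpha, beta))
                acc = np.log(rng.random(J)) < dlik + dprior
                alpha = np.where(acc, prop_a, alpha)
                beta = np.where(acc, prop_b, beta)
                if N and acc.any():
                    loglam = logA + alpha[tj] + beta[tj] * year + eps
                if burn:
                    adapt.record(acc.astype(float))
                else:
                    accept_totals["taxon_effects"] += 0.5 * float(acc.mean())

        # --- element-wise eps update
        if N and (fix_sigma_eps is None or fix_sigma_eps > 0):
            prop_e = eps + float(ad_eps.scale) * rng.normal(size=N)
            loglam_new = loglam + (prop_e - eps)
            dlp = (y * (loglam_new - loglam) - (np.exp(loglam_new) - np.exp(loglam))
                   - 0.5 * (prop_e**2 - eps**2) / se_**2)
            acc = np.log(rng.random(N)) < dlp
            eps = np.where(acc, prop_e, eps)
            loglam = np.where(acc, loglam_new, loglam)
            if burn:
                ad_eps.record(float(acc.mean()))
            else:
                accept_totals["eps"] += float(acc.mean())

        # --- conjugate Gibbs draw of (mu_alpha, mu_beta)
        if J:
            cov_ab = np.array([[sa * sa, rho * sa * sb], [rho * sa * sb, sb * sb]])
            sinv = np.linalg.inv(cov_ab)
            post_prec = J * sinv + prior_prec * np.eye(2)
            post_cov = np.linalg.inv(post_prec)
            mean = post_cov @ (sinv @ np.array([alpha.sum(), beta.sum()]))
            draw = mean + np.linalg.cholesky(post_cov) @ rng.normal(size=2)
            mu_a, mu_b = float(draw[0]), float(draw[1])
        else:
            mu_a = rng.normal(0.0, priors.mu_sd)
            mu_b = rng.normal(0.0, priors.mu_sd)

        # --- scalar random-walk updates of the scale hyperparameters
        hyper_acc = np.zeros(4)
        cur_bvn = bvn_term(alpha, beta, sa, sb, rho)
        for hi_, name in enumerate(("sigma_alpha", "sigma_beta", "sigma_eps", "rho")):
            if name == "sigma_eps" and fix_sigma_eps is not None:
                continue
            step = float(ad_hyper.scale[hi_]) * rng.normal()
            if name == "sigma_alpha":
                prop = sa + step
                if not 0.0 < prop < priors.sigma_upper:
                    continue
                new_bvn = bvn_term(alpha, beta, prop, sb, rho)
                if math.log(rng.random()) < new_bvn - cur_bvn:
                    sa, cur_bvn, hyper_acc[hi_] = prop, new_bvn, 1.0
            elif name == "sigma_beta":
                prop = sb + step
                if not 0.0 < prop < priors.sigma_upper:
                    continue
                new_bvn = bvn_term(alpha, beta, sa, prop, rho)
                if math.log(rng.random()) < new_bvn - cur_bvn:
                    sb, cur_bvn, hyper_acc[hi_] = prop, new_bvn, 1.0
            elif name == "rho":
                prop = rho + step
                if not -1.0 < prop < 1.0:
                    continue
                new_bvn = bvn_term(alpha, beta, sa, sb, prop)
                if math.log(rng.random()) < new_bvn - cur_bvn:
                    rho, cur_bvn, hyper_acc[hi_] = prop, new_bvn, 1.0
            else:  # sigma_eps: exact Gibbs when the eps likelihood exists
                if N >= 2:
                    # sigma^2 | eps ~ InvGamma((N-1)/2, sum(eps^2)/2) under
                    # the uniform prior on sigma (change of variables)
                    s_sq = float(np.sum(eps**2))
                    if s_sq > 0:
                        v = (s_sq / 2.0) / rng.gamma((N - 1) / 2.0)
                        cand = math.sqrt(v)
                        if cand < priors.sigma_upper:
                            se_, hyper_acc[hi_] = cand, 1.0
                else:
                    prop = se_ + step
                    if 0.0 < prop < priors.sigma_upper:
                        se_, hyper_acc[hi_] = prop, 1.0
        if burn:
            ad_hyper.record(hyper_acc)
        else:
            accept_totals["hyper"] += float(hyper_acc.mean())

        # --- non-centered rescale of (sigma_eps, eps): holds eps/sigma_eps
        # fixed, so the eps-prior ratio cancels the Jacobian exactly and
        # only the Poisson likelihood decides; breaks the funnel at
        # sigma_eps -> 0
        if N and fix_sigma_eps is None:
            factor = math.exp(float(ad_rescale.scale) * rng.normal())
            prop_sigma = se_ * factor
            acc_r = 0.0
            if 1e-8 < prop_sigma < priors.sigma_upper:
                prop_eps = eps * factor
                loglam_new = loglam + (prop_eps - eps)
                # + log(factor): change-of-variables term for the
                # log-scale walk on (sigma_eps, eps/sigma_eps)
                dlp = float(np.sum(y * (loglam_new - loglam)
                                   - (np.exp(loglam_new) - np.exp(loglam)))
                            ) + math.log(factor)
                if math.log(rng.random()) < dlp:
                    se_, eps, loglam = prop_sigma, prop_eps, loglam_new
                    acc_r = 1.0
            if burn:
                ad_rescale.record(acc_r)
            else:
                accept_totals["hyper"] += 0.0  # reported via sigma draws

        if not burn:
            post_it = it - cfg.burn_in
            if post_it % cfg.thin == 0:
                k = post_it // cfg.thin
                out["mu_alpha"][k], out["mu_beta"][k] = mu_a, mu_b
                out["sigma_alpha"][k], out["sigma_beta"][k] = sa, sb
                out["sigma_eps"][k], out["rho"][k] = se_, rho
                out["alpha"][k], out["beta"][k] = alpha, beta
            post_n += 1

    _err.__exit__(None, None, None)
    rates = {k: v / max(post_n, 1) for k, v in accept_totals.items()}
    return out, rates


def run_mcmc(
    data: pd.DataFrame,
    priors: PriorConfig | None = None,
    chains: ChainConfig | None = None,
    fix_sigma_eps: float | None = None,
) -> PosteriorDraws:
    """Sample the posterior of the density-change model.

    ``data`` is the frame produced by :func:`transect_counts` (columns
    taxon, count, area_m2, year01).  An empty frame is allowed and
    recovers the priors.  ``fix_sigma_eps`` pins the overdispersion SD
    (0 disables the eps effects entirely), useful for oracle checks.

    With a single taxon the hyperparameters are not identifiable and
    act only as a vague hierarchical prior; a warning is emitted.
    """
    priors = priors or PriorConfig()
    cfg = chains or ChainConfig()

    if len(data):
        taxa = tuple(sorted(data["taxon"].unique()))
        y = data["count"].to_numpy(dtype=float)
        logA = np.log(data["area_m2"].to_numpy(dtype=float))
        year = data["year01"].to_numpy(dtype=float)
        tj = data["taxon"].map({t: i for i, t in enumerate(taxa)}).to_numpy()
    else:
        taxa = ()
        y = logA = year = np.zeros(0)
        tj = np.zeros(0, dtype=int)
    J = len(taxa)
    if J == 1:
        warnings.warn("single taxon: hyperparameters are not identifiable",
                      stacklevel=2)

    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_chains)
    per_chain = []
    rates_all: dict[str, float] = {}
    for c, s in enumerate(seeds):
        rng = np.random.Generator(np.random.PCG64(s))
        out, rates = _run_one_chain(y, logA, year, tj, J, priors, cfg, rng,
                                    fix_sigma_eps)
        per_chain.append(out)
        for k, v in rates.items():
            rates_all[f"chain{c}/{k}"] = v

    draws: dict[str, np.ndarray] = {}
    for name in ("mu_alpha", "mu_beta", "sigma_alpha", "sigma_beta",
                 "sigma_eps", "rho"):
        draws[name] = np.stack([c[name] for c in per_chain])
    for j, t in enumerate(taxa):
        draws[f"alpha[{t}]"] = np.stack([c["alpha"][:, j] for c in per_chain])
        draws[f"beta[{t}]"] = np.stack([c["beta"][:, j] for c in per_chain])
    return PosteriorDraws(draws=draws, taxa=taxa, chain_config=cfg,
                          acceptance=rates_all)


# ---------------------------------------------------------------------------
# diagnostics and summaries

def gelman_rubin(chains: np.ndarray) -> float:
    """Potential scale reduction factor from m chains of length n.

    Classic between/within-chain variance ratio:
    sqrt(((n-1)/n * W + (m+1)/(m n) * B) / W) with B the between-chain
    variance estimate n * var(chain means).
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need at least 2 chains of length >= 2")
    m, n = x.shape
    W = float(np.mean(np.var(x, axis=1, ddof=1)))
    B = n * float(np.var(np.mean(x, axis=1), ddof=1))
    if W == 0:
        return 1.0 if B == 0 else math.inf
    v_hat = (n - 1) / n * W + (m + 1) / (m * n) * B
    return math.sqrt(v_hat / W)


def _autocorrelation(x: np.ndarray) -> np.ndarray:
    n = len(x)
    x = x - x.mean()
    nfft = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conjugate(f))[:n].real / n
    if acov[0] == 0:
        return np.zeros(n)
    return acov / acov[0]


def effective_sample_size(draws: np.ndarray) -> float:
    """Autocorrelation-based ESS with Geyer initial-positive-sequence
    truncation.  2-D input (chains x draws) sums the per-chain ESS."""
    x = np.asarray(draws, dtype=float)
    if x.ndim == 2:
        return float(sum(effective_sample_size(row) for row in x))
    n = len(x)
    if n < 4 or np.ptp(x) == 0:
        return 1.0
    rho = _autocorrelation(x)
    gamma = rho[0:-1:2][: (n // 2)] + rho[1::2][: (n // 2)]
    pos = np.nonzero(gamma <= 0)[0]
    cut = pos[0] if len(pos) else len(gamma)
    tau = -1.0 + 2.0 * float(np.sum(gamma[:cut]))
    tau = max(tau, 1.0 / n)
    return float(max(min(n / tau, float(n)), 1.0))


@dataclass
class PosteriorSummary:
    """Posterior table plus per-taxon density-change calls."""

    table: pd.DataFrame
    change_flags: dict[str, str]
    decline_probability: dict[str, float]


def summarize(draws: PosteriorDraws, level: float = 0.95) -> PosteriorSummary:
    """Equal-tailed credible intervals, convergence diagnostics and the
    credible-change rule (interval excluding zero) per taxon."""
    lo_q, hi_q = 50 * (1 - level), 100 - 50 * (1 - level)
    rows = []
    for name, arr in draws.draws.items():
        flat = arr.reshape(-1)
        lo, med, hi = np.percentile(flat, [lo_q, 50, hi_q])
        rhat = gelman_rubin(arr) if arr.shape[0] >= 2 else math.nan
        rows.append({
            "parameter": name, "mean": float(flat.mean()),
            "sd": float(flat.std(ddof=1)),
            f"{lo_q:g}%": float(lo), "50%": float(med), f"{hi_q:g}%": float(hi),
            "rhat": rhat, "ess": effective_sample_size(arr),
        })
    table = pd.DataFrame(rows).set_index("parameter")
    flags: dict[str, str] = {}
    p_decline: dict[str, float] = {}
    for taxon in draws.taxa:
        flat = draws.combined(f"beta[{taxon}]")
        lo, hi = np.percentile(flat, [lo_q, hi_q])
        if hi < 0:
            flags[taxon] = "credible decline"
        elif lo > 0:
            flags[taxon] = "credible increase"
        else:
            flags[taxon] = "not credible"
        p_decline[taxon] = float(np.mean(flat < 0))
    return PosteriorSummary(table=table, change_flags=flags,
                            decline_probability=p_decline)
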