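"""Hierarchical Bayesian movement model and its MCMC sampler.

The probability that a bird banded in region i is recovered (shot and
reported) in region j is

    pi_ij = Psi_ij * lambda * h

where Psi is a row-stochastic movement matrix, lambda the band-type
reporting probability and h the continental harvest rate.  Recovery counts
are modelled as independent binomials D_ij ~ Bin(N_i, pi_ij) with N_i the
number of birds banded in region i.  Priors: a symmetric Dirichlet on each
row of Psi, Beta priors on lambda (moment-matched to the band type's known
reporting probability) and on h (Beta(2, 19) by default).

lambda and h enter the likelihood only through their product, so they are
confounded: the data inform lambda*h but cannot separate the factors, and
Psi remains identifiable because its rows live on the simplex.  Holding h's
prior fixed across regions is what buys that identifiability.

Sampling is Metropolis-within-Gibbs.  Each Psi row is a block updated with
a Dirichlet proposal centred at the current row (concentration =
proposal scale, adapted during burn-in); lambda and h get logit-scale
Gaussian random walks.  Blocks with no likelihood contribution (rows with
N_i = 0; lambda/h when the matrix is empty) are drawn exactly from their
priors, so a data-free run samples the prior without Monte-Carlo bias from
the proposal mechanism.  Chains are independent given a master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.special import gammaln, logit, expit

from .records import BetaPrior, PriorConfig, RecoveryMatrix

__all__ = [
    "ModelState",
    "MCMCConfig",
    "PosteriorDraws",
    "beta_from_mean",
    "log_posterior",
    "sample_posterior",
    "gelman_rubin",
]

_PEPS = 1e-300  # probability floor inside log-likelihoods


@dataclass
class ModelState:
    """A single point in parameter space: (Psi, lambda, h)."""

    Psi: np.ndarray
    lam: float
    h: float

    def __post_init__(self) -> None:
        self.Psi = np.asarray(self.Psi, dtype=float)
        if not np.allclose(self.Psi.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("every row of Psi must sum to 1")
        if np.any(self.Psi <= 0.0) or np.any(self.Psi >= 1.0):
            raise ValueError("Psi entries must lie strictly inside (0, 1)")
        if not (0.0 < self.lam < 1.0 and 0.0 < self.h < 1.0):
            raise ValueError("lam and h must lie in (0, 1)")


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler settings.

    ``n_iter`` counts total iterations per chain; the first ``n_burn`` are
    discarded (default half), the rest retained every ``thin`` steps.
    ``proposal_scale`` seeds the Dirichlet row-proposal concentration and is
    adapted per row during burn-in toward a 25% acceptance rate.
    """

    n_chains: int = 2
    n_iter: int = 3000
    n_burn: int | None = None
    thin: int = 1
    seed: int = 0
    proposal_scale: float = 200.0
    rhat_threshold: float = 1.1

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("need at least 2 chains for convergence diagnostics")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.burn >= self.n_iter:
            raise ValueError("n_burn must be smaller than n_iter")

    @property
    def burn(self) -> int:
        return self.n_iter // 2 if self.n_burn is None else self.n_burn


@dataclass
class PosteriorDraws:
    """Retained MCMC samples for one band type.

    Arrays are indexed (chain, draw[, region, region]).  ``acceptance``
    maps block name -> mean acceptance fraction across chains; ``rhat``
    holds the Gelman-Rubin statistic per scalar parameter.
    """

    band_type: str
    regions: tuple[str, ...]
    psi: np.ndarray  # (chains, draws, R, R)
    lam: np.ndarray  # (chains, draws)
    h: np.ndarray  # (chains, draws)
    acceptance: dict[str, float] = field(default_factory=dict)
    rhat: dict[str, float] = field(default_factory=dict)
    rhat_threshold: float = 1.1

    @property
    def n_chains(self) -> int:
        return self.psi.shape[0]

    @property
    def n_draws(self) -> int:
        return self.psi.shape[1]

    @property
    def converged(self) -> bool:
        return bool(self.rhat) and max(self.rhat.values()) < self.rhat_threshold

    def pooled_psi(self) -> np.ndarray:
        """All chains concatenated: (chains*draws, R, R)."""
        return self.psi.reshape(-1, *self.psi.shape[2:])

    def mean_psi(self) -> np.ndarray:
        return self.pooled_psi().mean(axis=0)


def beta_from_mean(mean: float, strength: float) -> tuple[float, float]:
    """Beta(alpha, beta) with the requested mean and alpha+beta = strength.

    alpha = mean * strength, beta = (1 - mean) * strength, so the prior mean
    alpha / (alpha + beta) equals ``mean`` exactly.  Used to centre the
    reporting-probability prior on a band type's known reporting rate.
    """
    if not 0.0 < mean < 1.0:
        raise ValueError(f"mean must lie in (0, 1), got {mean}")
    if strength <= 0.0:
        raise ValueError(f"strength must be positive, got {strength}")
    return mean * strength, (1.0 - mean) * strength


# ---------------------------------------------------------------------------
# densities


def _log_binom_pmf(D: np.ndarray, N: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Full binomial log-pmf, elementwise (constants included)."""
    p = np.clip(p, _PEPS, 1.0 - 1e-15)
    return (
        gammaln(N + 1)
        - gammaln(D + 1)
        - gammaln(N - D + 1)
        + D * np.log(p)
        + (N - D) * np.log1p(-p)
    )


def _log_beta_pdf(x: float, prior: BetaPrior) -> float:
    lognorm = gammaln(prior.alpha + prior.beta) - gammaln(prior.alpha) - gammaln(prior.beta)
    return float(lognorm + (prior.alpha - 1) * np.log(x) + (prior.beta - 1) * np.log1p(-x))


def _log_dirichlet_pdf(x: np.ndarray, alpha: np.ndarray) -> float:
    lognorm = gammaln(alpha.sum()) - gammaln(alpha).sum()
    return float(lognorm + ((alpha - 1.0) * np.log(x)).sum())


def log_posterior(
    state: ModelState,
    mat: RecoveryMatrix,
    priors: PriorConfig,
    likelihood: str = "binomial",
    n_mode: str = "per_region",
) -> float:
    """Unnormalised log posterior density at ``state`` (all constants kept).

    ``likelihood`` selects the independent-binomials model (``"binomial"``,
    the default, matching D_ij ~ Bin(N_i, Psi_ij*lambda*h)) or a
    multinomial with an explicit never-recovered cell (``"multinomial"``).
    ``n_mode`` selects per-region banded totals N_i (default) or a single
    global N shared by every cell (``"global"``) for sensitivity checks.
    Boundary states return ``-inf`` rather than raising, so a sampler can
    treat them as rejected proposals.
    """
    Psi, lam, h = state.Psi, state.lam, state.h
    D = mat.D.astype(float)
    Nvec = _effective_n(mat, n_mode)
    ll = _loglik(D, Nvec, Psi, lam, h, likelihood)

    alpha = np.full(Psi.shape[1], priors.dirichlet_alpha)
    lp = sum(_log_dirichlet_pdf(Psi[i], alpha) for i in range(Psi.shape[0]))
    lp += _log_beta_pdf(lam, priors.lambda_prior(mat.band_type))
    lp += _log_beta_pdf(h, priors.effective_h_prior())
    total = ll + lp
    return float(total) if np.isfinite(total) else -np.inf


def _effective_n(mat: RecoveryMatrix, n_mode: str) -> np.ndarray:
    if n_mode == "per_region":
        return mat.N.astype(float)
    if n_mode == "global":
        return np.full(len(mat.N), float(mat.N.sum()))
    raise ValueError(f"unknown n_mode: {n_mode!r}")


def _loglik(
    D: np.ndarray, Nvec: np.ndarray, Psi: np.ndarray, lam: float, h: float, likelihood: str
) -> float:
    """Full-data log likelihood (constants included), rows with N=0 contribute 0."""
    active = Nvec > 0
    if not active.any():
        return 0.0
    if likelihood == "binomial":
        terms = _log_binom_pmf(D[active], Nvec[active, None], Psi[active] * lam * h)
        return float(terms.sum())
    if likelihood == "multinomial":
        p = np.clip(Psi[active] * lam * h, _PEPS, 1.0 - 1e-15)
        Da = D[active]
        Na = Nvec[active]
        rest = Na - Da.sum(axis=1)
        if (rest < 0).any():
            return -np.inf
        lognorm = gammaln(Na + 1) - gammaln(Da + 1).sum(axis=1) - gammaln(rest + 1)
        core = (Da * np.log(p)).sum(axis=1) + rest * np.log1p(-np.clip(lam * h, 0, 1 - 1e-15))
        return float((lognorm + core).sum())
    raise ValueError(f"unknown likelihood: {likelihood!r}")


# ---------------------------------------------------------------------------
# sampler

_ROW_TARGET = 0.25  # target acceptance for simplex blocks
_SCALAR_TARGET = 0.44  # target acceptance for 1-d random walks
_ADAPT_BATCH = 50


def _row_loglik(
    d_row: np.ndarray, n_i: float, psi_row: np.ndarray, lam: float, h: float, likelihood: str
) -> float:
    """Log-likelihood terms involving one Psi row; constants dropped."""
    p = np.clip(psi_row * lam * h, _PEPS, 1.0 - 1e-15)
    if likelihood == "binomial":
        return float((d_row * np.log(p) + (n_i - d_row) * np.log1p(-p)).sum())
    # multinomial: the never-recovered cell depends only on lam*h, handled
    # in the scalar blocks; for a row update only the D*log(psi) term moves.
    return float((d_row * np.log(p)).sum())


def _full_loglik_fast(
    D: np.ndarray, Nvec: np.ndarray, Psi: np.ndarray, lam: float, h: float, likelihood: str
) -> float:
    """Likelihood up to state-independent constants, for MH ratios."""
    active = Nvec > 0
    if not active.any():
        return 0.0
    p = np.clip(Psi[active] * lam * h, _PEPS, 1.0 - 1e-15)
    Da = D[active]
    if likelihood == "binomial":
        return float((Da * np.log(p) + (Nvec[active, None] - Da) * np.log1p(-p)).sum())
    rest = Nvec[active] - Da.sum(axis=1)
    return float(
        (Da * np.log(p)).sum() + (rest * np.log1p(-min(lam * h, 1 - 1e-15))).sum()
    )


def _propose_row(rng: np.random.Generator, row: np.ndarray, scale: float):
    """Dirichlet proposal centred at ``row``; returns (proposal, log q ratio).

    Concentration = scale*row + 0.1; the +0.1 floor keeps near-zero
    components proposable.  The Hastings ratio accounts for the asymmetry.
    """
    a_fwd = scale * row + 0.1
    prop = rng.dirichlet(a_fwd)
    if np.any(prop < 1e-12):
        return None, 0.0
    a_rev = scale * prop + 0.1
    log_q_fwd = _log_dirichlet_pdf(prop, a_fwd)
    log_q_rev = _log_dirichlet_pdf(row, a_rev)
    return prop, log_q_rev - log_q_fwd


def _run_chain(
    rng: np.random.Generator,
    mat: RecoveryMatrix,
    priors: PriorConfig,
    cfg: MCMCConfig,
    fixed_lambda: float | None,
    fixed_h: float | None,
    likelihood: str,
    n_mode: str,
):
    R = len(mat.regions)
    D = mat.D.astype(float)
    Nvec = _effective_n(mat, n_mode)
    active = Nvec > 0
    any_data = bool(active.any())
    alpha = np.full(R, priors.dirichlet_alpha)
    lam_prior = priors.lambda_prior(mat.band_type)
    h_prior = priors.effective_h_prior()

    # dispersed initial state
    Psi = rng.dirichlet(alpha, size=R)
    lam = fixed_lambda if fixed_lambda is not None else float(rng.beta(lam_prior.alpha, lam_prior.beta))
    h = fixed_h if fixed_h is not None else float(rng.beta(h_prior.alpha, h_prior.beta))

    row_scale = np.full(R, cfg.proposal_scale)
    step = {"lam": 0.5, "h": 0.5, "ridge": 0.5}
    acc = {f"psi_row_{i}": [0, 0] for i in range(R)}
    acc["lam"] = [0, 0]
    acc["h"] = [0, 0]
    acc["ridge"] = [0, 0]
    batch_acc = {k: [0, 0] for k in acc}

    n_keep = (cfg.n_iter - cfg.burn + cfg.thin - 1) // cfg.thin
    psi_out = np.empty((n_keep, R, R))
    lam_out = np.empty(n_keep)
    h_out = np.empty(n_keep)
    k = 0

    def scalar_update(name: str, value: float, prior: BetaPrior) -> float:
        """Logit-space Gaussian random walk on lam or h."""
        z = logit(value)
        zp = z + step[name] * rng.normal()
        prop = float(expit(zp))
        if not 0.0 < prop < 1.0:
            batch_acc[name][1] += 1
            acc[name][1] += 1
            return value
        cur_ll = _full_loglik_fast(D, Nvec, Psi, lam, h, likelihood)
        lamp, hp = (prop, h) if name == "lam" else (lam, prop)
        prop_ll = _full_loglik_fast(D, Nvec, Psi, lamp, hp, likelihood)
        # Beta prior + logit-transform Jacobian x(1-x)
        logr = (
            prop_ll
            - cur_ll
            + _log_beta_pdf(prop, prior)
            - _log_beta_pdf(value, prior)
            + np.log(prop * (1 - prop))
            - np.log(value * (1 - value))
        )
        batch_acc[name][1] += 1
        acc[name][1] += 1
        if np.log(rng.random()) < logr:
            batch_acc[name][0] += 1
            acc[name][0] += 1
            return prop
        return value

    for t in range(cfg.n_iter):
        for i in range(R):
            key = f"psi_row_{i}"
            if not active[i]:
                # no likelihood contribution: exact Gibbs draw from the prior
                Psi[i] = rng.dirichlet(alpha)
                continue
            prop, log_q = _propose_row(rng, Psi[i], row_scale[i])
            batch_acc[key][1] += 1
            acc[key][1] += 1
            if prop is None:
                continue
            logr = (
                _row_loglik(D[i], Nvec[i], prop, lam, h, likelihood)
                - _row_loglik(D[i], Nvec[i], Psi[i], lam, h, likelihood)
                + _log_dirichlet_pdf(prop, alpha)
                - _log_dirichlet_pdf(Psi[i], alpha)
                + log_q
            )
            if np.log(rng.random()) < logr:
                Psi[i] = prop
                batch_acc[key][0] += 1
                acc[key][0] += 1

        if fixed_lambda is None:
            if any_data:
                lam = scalar_update("lam", lam, lam_prior)
            else:
                lam = float(rng.beta(lam_prior.alpha, lam_prior.beta))
        if fixed_h is None:
            if any_data:
                h = scalar_update("h", h, h_prior)
            else:
                h = float(rng.beta(h_prior.alpha, h_prior.beta))
        if fixed_lambda is None and fixed_h is None and any_data:
            # joint move along the lam*h ridge: the likelihood depends on
            # the product only, so individual walks mix slowly along it
            eps = step["ridge"] * rng.normal()
            lamp = lam * np.exp(eps)
            hp = h * np.exp(-eps)
            batch_acc["ridge"][1] += 1
            acc["ridge"][1] += 1
            if lamp < 1.0 and hp < 1.0:
                logr = (
                    _full_loglik_fast(D, Nvec, Psi, lamp, hp, likelihood)
                    - _full_loglik_fast(D, Nvec, Psi, lam, h, likelihood)
                    + _log_beta_pdf(lamp, lam_prior)
                    - _log_beta_pdf(lam, lam_prior)
                    + _log_beta_pdf(hp, h_prior)
                    - _log_beta_pdf(h, h_prior)
                    # log-scale random walk: Jacobian lam'*h'/(lam*h)
                    + np.log(lamp * hp) - np.log(lam * h)
                )
                if np.log(rng.random()) < logr:
                    lam, h = float(lamp), float(hp)
                    batch_acc["ridge"][0] += 1
                    acc["ridge"][0] += 1

        # burn-in adaptation toward target acceptance rates
        if t < cfg.burn and (t + 1) % _ADAPT_BATCH == 0:
            for i in range(R):
                key = f"psi_row_{i}"
                a, n = batch_acc[key]
                if n:
                    rate = a / n
                    # low acceptance => proposals too wide => raise concentration;
                    # high acceptance => too narrow => lower it
                    row_scale[i] *= np.exp(np.clip(_ROW_TARGET - rate, -0.5, 0.5) * 2.0)
                    row_scale[i] = float(np.clip(row_scale[i], 1.0, 1e8))
            for name in ("lam", "h", "ridge"):
                a, n = batch_acc[name]
                if n:
                    rate = a / n
                    step[name] *= np.exp(np.clip(rate - _SCALAR_TARGET, -0.5, 0.5) * 2.0)
                    step[name] = float(np.clip(step[name], 1e-4, 5.0))
            batch_acc = {kk: [0, 0] for kk in batch_acc}

        if t >= cfg.burn and (t - cfg.burn) % cfg.thin == 0:
            psi_out[k] = Psi
            lam_out[k] = lam
            h_out[k] = h
            k += 1

    rates = {kk: (a / n if n else np.nan) for kk, (a, n) in acc.items()}
    return psi_out[:k], lam_out[:k], h_out[:k], rates


def sample_posterior(
    mat: RecoveryMatrix,
    priors: PriorConfig,
    cfg: MCMCConfig = MCMCConfig(),
    fixed_lambda: float | None = None,
    fixed_h: float | None = None,
    likelihood: str = "binomial",
    n_mode: str = "per_region",
) -> PosteriorDraws:
    """Run Metropolis-within-Gibbs on one band type's recovery matrix.

    Runs ``cfg.n_chains`` independent chains from dispersed starts; the
    master seed deterministically spawns one stream per chain, so the same
    (seed, config) pair reproduces the retained draws bit for bit.
    Convergence is summarised with the Gelman-Rubin statistic; a run with
    any R-hat above ``cfg.rhat_threshold`` is flagged (``converged`` is
    False), never silently accepted.

    ``fixed_lambda`` / ``fixed_h`` pin a parameter instead of sampling it —
    used for oracle comparisons and sensitivity analyses.
    """
    # A data-free matrix (all N_i = 0) is legal: the posterior is the prior.
    priors.lambda_prior(mat.band_type)  # fail fast if the prior is missing

    streams = np.random.SeedSequence(cfg.seed).spawn(cfg.n_chains)
    chains = [
        _run_chain(
            np.random.Generator(np.random.PCG64(s)),
            mat,
            priors,
            cfg,
            fixed_lambda,
            fixed_h,
            likelihood,
            n_mode,
        )
        for s in streams
    ]
    psi = np.stack([c[0] for c in chains])
    lam = np.stack([c[1] for c in chains])
    h = np.stack([c[2] for c in chains])
    acceptance = {}
    for key in chains[0][3]:
        vals = [c[3][key] for c in chains if not np.isnan(c[3][key])]
        acceptance[key] = float(np.mean(vals)) if vals else float("nan")
    draws = PosteriorDraws(
        band_type=mat.band_type,
        regions=tuple(mat.regions),
        psi=psi,
        lam=lam,
        h=h,
        acceptance=acceptance,
        rhat_threshold=cfg.rhat_threshold,
    )
    draws.rhat = gelman_rubin(draws, include_fixed=False)
    return draws


# ---------------------------------------------------------------------------
# diagnostics


def _psrf(x: np.ndarray) -> float:
    """Potential scale reduction factor for one scalar, chains in rows.

    Classic between/within variance ratio; clamped at 1.0 from below so
    identical chains report exactly 1.0.
    """
    m, n = x.shape
    chain_means = x.mean(axis=1)
    W = float(x.var(axis=1, ddof=1).mean())
    B_over_n = float(chain_means.var(ddof=1))
    if W == 0.0:
        return 1.0 if B_over_n == 0.0 else np.inf
    var_plus = (n - 1) / n * W + B_over_n
    return max(1.0, float(np.sqrt(var_plus / W)))


def gelman_rubin(draws: PosteriorDraws, include_fixed: bool = True) -> dict[str, float]:
    """Gelman-Rubin R-hat per scalar parameter (49 Psi cells + lambda + h).

    Requires at least two chains of at least 10 retained draws each.
    Parameters held constant across all draws (e.g. a pinned lambda) are
    skipped unless ``include_fixed``, in which case they report 1.0.
    """
    if draws.n_chains < 2:
        raise ValueError("Gelman-Rubin diagnostic requires at least 2 chains")
    if draws.n_draws < 10:
        raise ValueError("need at least 10 retained draws per chain")
    out: dict[str, float] = {}
    R = len(draws.regions)
    for i in range(R):
        for j in range(R):
            out[f"psi[{i},{j}]"] = _psrf(draws.psi[:, :, i, j])
    for name, x in (("lam", draws.lam), ("h", draws.h)):
        if np.ptp(x) == 0.0 and not include_fixed:
            continue
        out[name] = _psrf(x)
    return out
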