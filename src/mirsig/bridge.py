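"""Bayesian latent-variable bridge between cohorts.

The signature components are measured on one cohort (D1/D7 animals) and the
clinical endpoints on another (D14 animals); no animal carries both.  The two
are linked through the dose group: the D1/D7 fit supplies, per dose group, the
mean and SD of a signature component's sample scores, which act as a prior on
an unobserved coordinate for each D14 animal.  The outcome then regresses on
that latent coordinate:

    x_j ~ Normal(mu_g(j), s_g(j))          latent signature coordinate
    y_j ~ Normal(alpha + beta * x_j, sigma_y)
    alpha, beta ~ Normal(0, 10^2)          (y standardized internally)
    sigma_y ~ Half-Normal(5)

Each posterior draw implies a correlation
    r = beta * sd_x / sqrt(beta^2 * var_x + sigma_y^2),
with var_x the variance of the prior mixture over the D14 dose composition,
so r is bounded in (-1, 1) draw by draw and invariant to affine changes of y.

Sampling is Metropolis-within-Gibbs: the latent coordinates and the
regression coefficients have conjugate normal updates; sigma_y moves by a
random walk on its log.  Group summaries are plug-in constants by default; an
optional hyperprior mode adds Normal(mu_g, s_g/sqrt(n_g)) uncertainty on the
group means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_PRIOR_SD_COEF = 10.0     # alpha, beta ~ Normal(0, 10^2)
_PRIOR_SCALE_SIGMA = 5.0  # sigma_y ~ Half-Normal(5)


@dataclass
class CoordinatePrior:
    """Per-dose-group mean/SD of a signature component's scores (cohort A)."""

    mu: dict[float, float]
    sd: dict[float, float]
    n: dict[float, int]
    component: int = 1

    def __post_init__(self) -> None:
        for g, s in self.sd.items():
            if not s > 0:
                raise ValueError(f"group {g}: coordinate SD must be positive")


def summarize_coordinates(model, component: int = 1, block: str = "miR",
                          use_average: bool = False) -> CoordinatePrior:
    """Group-wise mean/SD of a fitted model's component scores.

    ``use_average`` switches from the named block's scores to the
    block-averaged scores.  Groups with fewer than two samples have no SD and
    raise.
    """
    if component < 1 or component > model.ncomp:
        raise ValueError(f"component {component} not in fitted model (ncomp={model.ncomp})")
    if use_average:
        t = sum(model.scores[b][:, component - 1] for b in model.block_names)
        t = t / len(model.block_names)
    else:
        t = model.scores[block][:, component - 1]
    labels = np.asarray(model_labels(model))
    mu, sd, n = {}, {}, {}
    for g in model.groups:
        vals = t[labels == g]
        if len(vals) < 2:
            raise ValueError(f"group {g} has {len(vals)} sample(s); SD undefined")
        mu[float(g)] = float(vals.mean())
        sd[float(g)] = float(vals.std(ddof=1))
        n[float(g)] = int(len(vals))
    return CoordinatePrior(mu=mu, sd=sd, n=n, component=component)


def model_labels(model) -> np.ndarray:
    """Recover per-sample group labels from the training centroid assignment."""
    if not hasattr(model, "_train_labels"):
        raise AttributeError(
            "model lacks training labels; fit via fit_block_splsda and call "
            "attach_labels(model, outcome) or pass labels explicitly")
    return model._train_labels


def attach_labels(model, outcome: pd.Series) -> None:
    model._train_labels = outcome.to_numpy()


@dataclass
class BridgeResult:
    draws: pd.DataFrame            # columns alpha, beta, sigma_y, r; MultiIndex (chain, draw)
    summaries: dict
    tail_probability: float
    rhat: dict
    ess: dict
    converged: bool
    outcome: str = ""
    component: int = 1

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "component": self.component,
            "summaries": self.summaries,
            "tail_probability": self.tail_probability,
            "rhat": self.rhat,
            "ess": self.ess,
            "converged": self.converged,
        }


def fit_bridge(
    prior: CoordinatePrior,
    d14: pd.DataFrame,
    outcome: str = "injury_score",
    chains: int = 2,
    burn_in: int = 2000,
    draws: int = 5000,
    seed: int = 0,
    rw_scale: float = 0.3,
    hyperprior_means: bool = False,
) -> BridgeResult:
    """Posterior of the latent-variable correlation r between a signature
    component (summarized by ``prior``) and a D14 outcome.

    ``draws`` is the total number of kept draws across ``chains`` chains,
    after ``burn_in`` discarded iterations per chain.  The tail probability is
    p = 2 * min(P(r > 0), P(r < 0)).
    """
    import arviz as az

    if outcome not in d14.columns:
        raise KeyError(f"outcome column {outcome!r} absent from D14 table")
    tab = d14[["dose_gy", outcome]].dropna()
    uncovered = sorted(set(tab["dose_gy"]) - set(prior.mu))
    if uncovered:
        raise ValueError(f"dose groups without a coordinate prior: {uncovered}")
    y_raw = tab[outcome].to_numpy(float)
    if np.std(y_raw) == 0:
        raise ValueError("outcome is constant; correlation undefined")
    y = (y_raw - y_raw.mean()) / y_raw.std(ddof=1)
    g = tab["dose_gy"].to_numpy(float)
    mu0 = np.array([prior.mu[d] for d in g])
    s0 = np.array([prior.sd[d] for d in g])
    m = len(y)

    # variance of the latent coordinate under the prior mixture, weighted by
    # the D14 cohort's dose composition
    levels, counts = np.unique(g, return_counts=True)
    w = counts / counts.sum()
    mus = np.array([prior.mu[d] for d in levels])
    sds = np.array([prior.sd[d] for d in levels])
    var_x = float(np.sum(w * (sds**2 + mus**2)) - np.sum(w * mus) ** 2)
    sd_x = np.sqrt(var_x)

    kept_per_chain = max(1, draws // chains)
    all_draws = {k: np.empty((chains, kept_per_chain)) for k in ("alpha", "beta", "sigma_y", "r")}
    root = np.random.SeedSequence(int(seed) % (2**31))
    for c, ss in enumerate(root.spawn(chains)):
        rng = np.random.default_rng(ss)
        x = mu0 + rng.normal(size=m) * s0
        alpha, beta, sigma = 0.0, 0.0, 1.0
        mu_g = mu0.copy()
        for it in range(burn_in + kept_per_chain):
            inv_s2 = 1.0 / s0**2
            if hyperprior_means:
                # refresh group means around their cohort-A estimates
                for gi, d in enumerate(levels):
                    sel = g == d
                    se = prior.sd[d] / np.sqrt(prior.n[d])
                    prec = 1.0 / se**2 + sel.sum() / prior.sd[d] ** 2
                    mean = (prior.mu[d] / se**2 + x[sel].sum() / prior.sd[d] ** 2) / prec
                    mu_g[sel] = rng.normal(mean, 1.0 / np.sqrt(prec))
            # latent coordinates: conjugate normal
            prec = inv_s2 + beta**2 / sigma**2
            mean = (mu_g * inv_s2 + beta * (y - alpha) / sigma**2) / prec
            x = mean + rng.normal(size=m) / np.sqrt(prec)
            # regression coefficients: conjugate bivariate normal
            Z = np.column_stack([np.ones(m), x])
            P = Z.T @ Z / sigma**2 + np.eye(2) / _PRIOR_SD_COEF**2
            b = Z.T @ y / sigma**2
            L = np.linalg.cholesky(P)
            mean_ab = np.linalg.solve(P, b)
            alpha, beta = mean_ab + np.linalg.solve(L.T, rng.normal(size=2))
            # residual SD: random walk on log sigma, Half-Normal(5) prior
            prop = sigma * np.exp(rng.normal(0.0, rw_scale))
            resid = y - alpha - beta * x
            def logpost(s):
                return (-m * np.log(s) - 0.5 * np.sum(resid**2) / s**2
                        - 0.5 * s**2 / _PRIOR_SCALE_SIGMA**2 + np.log(s))
            if np.log(rng.random()) < logpost(prop) - logpost(sigma):
                sigma = prop
            if it >= burn_in:
                j = it - burn_in
                r = beta * sd_x / np.sqrt(beta**2 * var_x + sigma**2)
                all_draws["alpha"][c, j] = alpha
                all_draws["beta"][c, j] = beta
                all_draws["sigma_y"][c, j] = sigma
                all_draws["r"][c, j] = r

    for k, arr in all_draws.items():
        if np.isnan(arr).any():
            raise RuntimeError(f"NaN draws in parameter {k}")

    rhat = {k: float(az.rhat(arr)) for k, arr in all_draws.items()}
    ess = {k: float(az.ess(arr)) for k, arr in all_draws.items()}
    converged = all(v <= 1.05 for v in rhat.values())
    if not converged:
        logger.warning("bridge MCMC not converged: rhat=%s", rhat)

    flat = {k: arr.reshape(-1) for k, arr in all_draws.items()}
    index = pd.MultiIndex.from_product(
        [range(chains), range(kept_per_chain)], names=["chain", "draw"])
    draws_df = pd.DataFrame(flat, index=index)
    r = flat["r"]
    summaries = {
        k: {
            "mean": float(v.mean()),
            "median": float(np.median(v)),
            "ci95": [float(np.quantile(v, 0.025)), float(np.quantile(v, 0.975))],
        }
        for k, v in flat.items()
    }
    p_tail = 2.0 * min(float(np.mean(r > 0)), float(np.mean(r < 0)))
    return BridgeResult(
        draws=draws_df, summaries=summaries, tail_probability=p_tail,
        rhat=rhat, ess=ess, converged=converged, outcome=outcome,
        component=prior.component,
    )
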