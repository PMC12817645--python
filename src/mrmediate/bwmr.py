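"""Bayesian weighted MR: a hierarchical model with per-SNP robustness weights.

Model, for SNP j with observed effects (βX_j, βY_j) and known SEs (sx_j, sy_j):

    βX_j ~ Normal(γ_j, sx_j²)
    βY_j ~ Normal(θ γ_j + α_j, sy_j²),   α_j ~ Normal(0, τ²)

with priors θ ~ Normal(0, 10²), γ_j ~ Normal(0, 1²) and a half-normal prior
on τ.  The pleiotropy effects α_j are marginalized analytically, so the
outcome likelihood is βY_j ~ Normal(θ γ_j, sy_j² + τ²).

Robustness: each SNP carries a weight w_j ∈ (0, 1] that tempers its outcome
likelihood.  During burn-in the weights are refreshed from the standardized
residuals r_j = (βY_j − θγ_j)/sqrt(sy_j² + τ²) with a Huber-style rule
(w_j = 1 for |r_j| <= 2.5, (2.5/|r_j|)² beyond), then frozen so the chain
targets a fixed posterior.  This is a Metropolis-within-Gibbs approximation
to the published variational BWMR scheme: γ and θ have conjugate Gaussian
full conditionals, τ is updated by random-walk Metropolis on log τ.

Inference: posterior mean/sd of θ as beta/se, two-sided normal p.  Two
chains are run; a split-chain R-hat above 1.1 flags (but does not suppress)
the result.
"""

from __future__ import annotations

import numpy as np

from .estimators import MRResult, _arrays, _norm_p

_HUBER_C = 2.5
_THETA_PRIOR_SD = 10.0
_GAMMA_PRIOR_SD = 1.0
_TAU_PRIOR_SCALE = 0.25


def _split_rhat(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction factor for a scalar parameter.

    ``chains`` has shape (n_chains, n_draws); each chain is split in half.
    """
    n = chains.shape[1] // 2
    halves = np.concatenate([chains[:, :n], chains[:, n:2 * n]], axis=0)
    m, n = halves.shape
    means = halves.mean(axis=1)
    w = halves.var(axis=1, ddof=1).mean()
    b = n * means.var(ddof=1)
    var_plus = (n - 1) / n * w + b / n
    if w <= 0:
        return 1.0
    return float(np.sqrt(var_plus / w))


def _run_chain(bx, sx, by, sy, n_iter: int, burn: int, rng: np.random.Generator
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    k = len(bx)
    theta = 0.0
    log_tau = np.log(0.05)
    gamma = bx.copy()
    weights = np.ones(k)
    sx2 = sx**2

    theta_draws = np.empty(n_iter - burn)
    tau_draws = np.empty(n_iter - burn)
    step = 0.5  # random-walk sd on log tau

    for it in range(n_iter):
        tau2 = np.exp(2 * log_tau)
        v = sy**2 + tau2

        # gamma_j | theta, tau, w  (conjugate normal)
        prec = 1.0 / sx2 + weights * theta**2 / v + 1.0 / _GAMMA_PRIOR_SD**2
        mean = (bx / sx2 + weights * theta * by / v) / prec
        gamma = mean + rng.standard_normal(k) / np.sqrt(prec)

        # theta | gamma, tau, w  (conjugate normal)
        prec_t = np.sum(weights * gamma**2 / v) + 1.0 / _THETA_PRIOR_SD**2
        mean_t = np.sum(weights * gamma * by / v) / prec_t
        theta = mean_t + rng.standard_normal() / np.sqrt(prec_t)

        # log tau | theta, gamma, w  (random-walk Metropolis)
        def logpost(lt: float) -> float:
            t2 = np.exp(2 * lt)
            vv = sy**2 + t2
            ll = np.sum(weights * (-0.5 * np.log(vv)
                                   - 0.5 * (by - theta * gamma) ** 2 / vv))
            tau = np.exp(lt)
            # half-normal prior on tau, log-scale Jacobian tau
            return ll - 0.5 * (tau / _TAU_PRIOR_SCALE) ** 2 + lt

        prop = log_tau + step * rng.standard_normal()
        if np.log(rng.uniform()) < logpost(prop) - logpost(log_tau):
            log_tau = prop

        # robustness weights: refreshed during burn-in only, then frozen
        if it < burn and it % 50 == 49:
            tau2 = np.exp(2 * log_tau)
            resid = (by - theta * gamma) / np.sqrt(sy**2 + tau2)
            absr = np.abs(resid)
            weights = np.where(absr <= _HUBER_C, 1.0, (_HUBER_C / absr) ** 2)

        if it >= burn:
            theta_draws[it - burn] = theta
            tau_draws[it - burn] = np.exp(log_tau)

    return theta_draws, tau_draws, weights


def bwmr(h, n_iter: int = 3000, n_chains: int = 2,
         seed: int | None = None) -> MRResult:
    """Bayesian weighted MR estimate; deterministic given ``seed``.

    ``extra`` carries the posterior mean of τ, the per-SNP robustness
    weights, the split-chain R-hat of θ, and a convergence flag (R-hat
    <= 1.1); a non-converged run is flagged, never suppressed.
    """
    bx, sx, by, sy = _arrays(h)
    k = len(bx)
    if k < 3:
        raise ValueError("BWMR requires >=3 SNPs")
    burn = n_iter // 3
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    chains, taus, wts = [], [], []
    for child in ss.spawn(n_chains):
        t, tau, w = _run_chain(bx, sx, by, sy, n_iter, burn,
                               np.random.default_rng(child))
        chains.append(t)
        taus.append(tau)
        wts.append(w)
    draws = np.stack(chains)
    beta = float(draws.mean())
    se = float(draws.std(ddof=1))
    rhat = _split_rhat(draws)
    return MRResult("BWMR", beta, se, _norm_p(beta / se), k, extra={
        "tau": float(np.mean(taus)),
        "rhat": rhat,
        "converged": bool(rhat <= 1.1),
        "weights": np.mean(wts, axis=0).round(4).tolist(),
    })
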