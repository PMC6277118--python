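"""Bayesian unimodal/bimodal classification of expression and methylation.

Expression vectors are modelled as a normal (unimodal) or a two-component
normal mixture with shared precision tau (bimodal); methylation beta
values as a beta distribution parameterized by mean mu and concentration
kappa (alpha = mu*kappa, beta = (1-mu)*kappa) or a two-component beta
mixture with shared kappa. Priors:

* expression mean(s): Normal(0, sd=100) truncated to [0, inf)
* precision tau: Gamma(shape=0.01, rate=0.01)
* methylation mean(s): Beta(1, 1)
* concentration kappa: Gamma(shape=0.01, rate=0.01)
* mixture mass omega_1: uniform Beta(1, 1) restricted to [0.1, 0.9] for
  expression and [0.2, 0.8] for methylation; omega_1 + omega_2 = 1.

Posteriors are sampled by Gibbs with latent component indicators;
conjugate updates are used where available (normal means, tau, omega) and
adaptive random-walk Metropolis within Gibbs elsewhere (beta mu, kappa).
Model choice is by BIC computed at plug-in posterior means:
BIC = n_params * ln(n) - 2 * logLik, with 2 (unimodal) or 4 (bimodal)
parameters; ties are resolved in favour of the unimodal (simpler) model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special

__all__ = [
    "MCMCSettings",
    "ModalityFit",
    "EqtmClassification",
    "fit_expression_unimodal",
    "fit_expression_bimodal",
    "fit_methylation_unimodal",
    "fit_methylation_bimodal",
    "compute_bic",
    "classify_modality",
    "classify_eqtm",
]

_MIN_N = 20
_EXPR_MASS_BOUNDS = (0.1, 0.9)
_METH_MASS_BOUNDS = (0.2, 0.8)
_BETA_EPS = 1e-4

# prior hyperparameters
_MU_PRIOR_PREC = 1e-4        # Normal(0, sd=100) for expression means
_GAMMA_SHAPE = 0.01          # Gamma(0.01, rate 0.01) for tau and kappa
_GAMMA_RATE = 0.01


@dataclass
class MCMCSettings:
    """Sampler configuration. Defaults: 2 chains x 4000 iterations with a
    1000-iteration burn-in; convergence by split-chain potential scale
    reduction below 1.1."""

    n_chains: int = 2
    n_iter: int = 4000
    burn_in: int = 1000
    rhat_threshold: float = 1.1

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")


@dataclass
class ModalityFit:
    data_kind: str                # "expression" | "methylation"
    model: str                    # "unimodal" | "bimodal"
    params: dict                  # posterior means
    posterior_sd: dict
    log_likelihood: float
    bic: float
    n_params: int
    n: int
    rhat: float
    converged: bool
    shift: float = 0.0            # expression nonnegativity shift (already undone)
    settings: MCMCSettings = field(default_factory=MCMCSettings)


@dataclass
class EqtmClassification:
    gene_id: str
    cpg_id: str
    expression_class: str
    methylation_class: str
    call: str                     # "linear" | "bimodal" | "discordant"
    correlation_sign: str         # "+" | "-"
    expression_fits: tuple
    methylation_fits: tuple


# ---------------------------------------------------------------------------
# low-level draws
# ---------------------------------------------------------------------------

def _truncnorm_pos(mean: float, sd: float, rng: np.random.Generator) -> float:
    """Draw from Normal(mean, sd) truncated to [0, inf) by inverse CDF."""
    a = special.ndtr(-mean / sd)
    u = rng.uniform(a, 1.0)
    u = min(u, 1.0 - 1e-15)
    return mean + sd * special.ndtri(u)


def _truncbeta(a: float, b: float, lo: float, hi: float,
               rng: np.random.Generator) -> float:
    """Draw from Beta(a, b) restricted to [lo, hi] by inverse CDF."""
    flo = special.betainc(a, b, lo)
    fhi = special.betainc(a, b, hi)
    if fhi - flo < 1e-12:  # posterior mass concentrated outside the box
        return lo if special.betainc(a, b, (lo + hi) / 2) > 0.5 else hi
    u = rng.uniform(flo, fhi)
    return float(special.betaincinv(a, b, u))


class _AdaptiveStep:
    """Random-walk step size adapted toward ~30% acceptance during burn-in."""

    def __init__(self, step: float = 0.3):
        self.step = step
        self.frozen = False

    def update(self, accepted: bool) -> None:
        if self.frozen:
            return
        self.step *= np.exp(0.06) if accepted else np.exp(-0.026)
        self.step = float(np.clip(self.step, 1e-3, 10.0))


def _split_rhat(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction factor for one parameter.

    ``chains`` is (n_chains, n_draws); each chain is split in half.
    """
    n_chains, n_draws = chains.shape
    half = n_draws // 2
    if half < 2:
        return np.nan
    segments = chains[:, : 2 * half].reshape(2 * n_chains, half)
    w = segments.var(axis=1, ddof=1).mean()
    b = half * segments.mean(axis=1).var(ddof=1)
    if w <= 1e-300:
        return 1.0
    var_plus = (half - 1) / half * w + b / half
    return float(np.sqrt(var_plus / w))


def _chain_seeds(seed: int, n_chains: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in
            np.random.SeedSequence(seed).spawn(n_chains)]


def _prepare(values: np.ndarray, kind: str) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < _MIN_N:
        raise ValueError(f"need at least {_MIN_N} non-missing values, got {x.size}")
    if kind == "methylation":
        if (x < 0).any() or (x > 1).any():
            raise ValueError("methylation values must lie in [0, 1]")
        x = np.clip(x, _BETA_EPS, 1.0 - _BETA_EPS)
    return x


# ---------------------------------------------------------------------------
# expression (normal) models
# ---------------------------------------------------------------------------

def fit_expression_unimodal(
    values: np.ndarray,
    mcmc: MCMCSettings | None = None,
    seed: int = 0,
) -> ModalityFit:
    """Gibbs sampler for Normal(mu, 1/sqrt(tau)) with truncated-normal prior
    on mu >= 0 and Gamma prior on tau."""
    mcmc = mcmc or MCMCSettings()
    x = _prepare(values, "expression")
    shift = max(0.0, -float(x.min()))
    y = x + shift
    n = y.size
    sum_y = y.sum()
    ssy = float(y @ y)
    keep = mcmc.n_iter - mcmc.burn_in
    mu_draws = np.empty((mcmc.n_chains, keep))
    tau_draws = np.empty((mcmc.n_chains, keep))
    for ci, rng in enumerate(_chain_seeds(seed, mcmc.n_chains)):
        mu = max(float(y.mean()), 0.0)
        tau = 1.0 / max(float(y.var()), 1e-12)
        for it in range(mcmc.n_iter):
            prec = _MU_PRIOR_PREC + n * tau
            mu = _truncnorm_pos(tau * sum_y / prec, prec ** -0.5, rng)
            ss = ssy - 2.0 * mu * sum_y + n * mu * mu
            tau = rng.gamma(_GAMMA_SHAPE + 0.5 * n,
                            1.0 / (_GAMMA_RATE + 0.5 * max(ss, 0.0)))
            if it >= mcmc.burn_in:
                mu_draws[ci, it - mcmc.burn_in] = mu
                tau_draws[ci, it - mcmc.burn_in] = tau
    mu_hat = float(mu_draws.mean())
    tau_hat = float(tau_draws.mean())
    sigma_draws = tau_draws ** -0.5
    ll = float(
        -0.5 * n * np.log(2 * np.pi) + 0.5 * n * np.log(tau_hat)
        - 0.5 * tau_hat * (ssy - 2 * mu_hat * sum_y + n * mu_hat ** 2)
    )
    rhat = _split_rhat(mu_draws)
    fit = ModalityFit(
        data_kind="expression",
        model="unimodal",
        params={"mu": mu_hat - shift, "tau": tau_hat,
                "sigma": float(sigma_draws.mean())},
        posterior_sd={"mu": float(mu_draws.std(ddof=1)),
                      "sigma": float(sigma_draws.std(ddof=1))},
        log_likelihood=ll,
        bic=0.0,
        n_params=2,
        n=n,
        rhat=rhat,
        converged=bool(rhat < mcmc.rhat_threshold),
        shift=shift,
        settings=mcmc,
    )
    fit.bic = compute_bic(fit, n)
    return fit


def fit_expression_bimodal(
    values: np.ndarray,
    mcmc: MCMCSettings | None = None,
    seed: int = 0,
    mass_bounds: tuple[float, float] = _EXPR_MASS_BOUNDS,
) -> ModalityFit:
    """Gibbs sampler for the two-component normal mixture with shared tau.

    Latent indicators are sampled each iteration; component means use the
    truncated-normal conjugate update, tau the conjugate gamma update, and
    the mass a Beta posterior restricted to ``mass_bounds``. Component order
    mu1 < mu2 is enforced by relabelling the stored draws.
    """
    mcmc = mcmc or MCMCSettings()
    lo, hi = mass_bounds
    if not 0.0 < lo < hi < 1.0:
        raise ValueError("mass bounds must satisfy 0 < lo < hi < 1")
    x = _prepare(values, "expression")
    if np.ptp(x) == 0:
        raise ValueError("all values identical; mixture fit is degenerate")
    shift = max(0.0, -float(x.min()))
    y = x + shift
    n = y.size
    keep = mcmc.n_iter - mcmc.burn_in
    draws = np.empty((mcmc.n_chains, keep, 4))  # mu1, mu2, omega, tau
    med = np.median(y)
    for ci, rng in enumerate(_chain_seeds(seed, mcmc.n_chains)):
        mu1 = float(y[y <= med].mean())
        mu2 = float(y[y > med].mean()) if (y > med).any() else mu1 + y.std()
        tau = 1.0 / max(float(y.var()) / 2.0, 1e-12)
        omega = 0.5
        for it in range(mcmc.n_iter):
            d = (np.log(omega) - 0.5 * tau * (y - mu1) ** 2) - (
                np.log1p(-omega) - 0.5 * tau * (y - mu2) ** 2
            )
            p1 = 1.0 / (1.0 + np.exp(-d))
            z = rng.random(n) < p1          # True -> component 1
            n1 = int(z.sum())
            n2 = n - n1
            sum1 = float(y @ z)
            sum2 = float(y.sum() - sum1)
            prec1 = _MU_PRIOR_PREC + n1 * tau
            prec2 = _MU_PRIOR_PREC + n2 * tau
            mu1 = _truncnorm_pos(tau * sum1 / prec1, prec1 ** -0.5, rng)
            mu2 = _truncnorm_pos(tau * sum2 / prec2, prec2 ** -0.5, rng)
            ss = float(((y - np.where(z, mu1, mu2)) ** 2).sum())
            tau = rng.gamma(_GAMMA_SHAPE + 0.5 * n,
                            1.0 / (_GAMMA_RATE + 0.5 * max(ss, 1e-300)))
            omega = _truncbeta(1 + n1, 1 + n2, lo, hi, rng)
            if it >= mcmc.burn_in:
                draws[ci, it - mcmc.burn_in] = (mu1, mu2, omega, tau)
    flat = draws.reshape(-1, 4).copy()
    swap = flat[:, 0] > flat[:, 1]
    flat[swap, 0], flat[swap, 1] = draws.reshape(-1, 4)[swap, 1], draws.reshape(-1, 4)[swap, 0]
    flat[swap, 2] = 1.0 - flat[swap, 2]
    mu1_hat, mu2_hat, om_hat, tau_hat = flat.mean(axis=0)
    om_hat = float(np.clip(om_hat, lo, hi))
    sd = flat.std(axis=0, ddof=1)
    ll = float(
        np.logaddexp(
            np.log(om_hat) + _norm_logpdf(y, mu1_hat, tau_hat),
            np.log1p(-om_hat) + _norm_logpdf(y, mu2_hat, tau_hat),
        ).sum()
    )
    # relabel chains consistently before diagnosing convergence on mu1
    chains_mu1 = np.minimum(draws[:, :, 0], draws[:, :, 1])
    rhat = _split_rhat(chains_mu1)
    fit = ModalityFit(
        data_kind="expression",
        model="bimodal",
        params={"mu1": float(mu1_hat - shift), "mu2": float(mu2_hat - shift),
                "omega1": float(om_hat), "omega2": float(1 - om_hat),
                "tau": float(tau_hat), "sigma": float(tau_hat ** -0.5)},
        posterior_sd={"mu1": float(sd[0]), "mu2": float(sd[1]),
                      "omega1": float(sd[2])},
        log_likelihood=ll,
        bic=0.0,
        n_params=4,
        n=n,
        rhat=rhat,
        converged=bool(rhat < mcmc.rhat_threshold),
        shift=shift,
        settings=mcmc,
    )
    fit.bic = compute_bic(fit, n)
    return fit


def _norm_logpdf(y: np.ndarray, mu: float, tau: float) -> np.ndarray:
    return -0.5 * np.log(2 * np.pi) + 0.5 * np.log(tau) - 0.5 * tau * (y - mu) ** 2


# ---------------------------------------------------------------------------
# methylation (beta) models
# ---------------------------------------------------------------------------

def _beta_loglik_sums(mu: float, kappa: float, slx: float, sl1x: float,
                      n: int) -> float:
    a = mu * kappa
    b = (1.0 - mu) * kappa
    return (a - 1.0) * slx + (b - 1.0) * sl1x - n * special.betaln(a, b)


def _logit(p: float) -> float:
    return float(np.log(p) - np.log1p(-p))


def _expit(x: float) -> float:
    return float(1.0 / (1.0 + np.exp(-x)))


def fit_methylation_unimodal(
    values: np.ndarray,
    mcmc: MCMCSettings | None = None,
    seed: int = 0,
) -> ModalityFit:
    """Metropolis-within-Gibbs for Beta(mu*kappa, (1-mu)*kappa).

    mu moves on the logit scale under its uniform prior, kappa on the log
    scale under Gamma(0.01, 0.01); sufficient statistics (sum log x,
    sum log(1-x)) make each likelihood evaluation O(1).
    """
    mcmc = mcmc or MCMCSettings()
    x = _prepare(values, "methylation")
    n = x.size
    slx = float(np.log(x).sum())
    sl1x = float(np.log1p(-x).sum())
    keep = mcmc.n_iter - mcmc.burn_in
    mu_draws = np.empty((mcmc.n_chains, keep))
    k_draws = np.empty((mcmc.n_chains, keep))
    for ci, rng in enumerate(_chain_seeds(seed, mcmc.n_chains)):
        mu = float(np.clip(x.mean(), 0.02, 0.98))
        v = max(float(x.var()), 1e-6)
        kappa = float(np.clip(mu * (1 - mu) / v - 1.0, 0.5, 1e4))
        step_mu, step_k = _AdaptiveStep(0.2), _AdaptiveStep(0.3)
        lp = _beta_loglik_sums(mu, kappa, slx, sl1x, n)
        for it in range(mcmc.n_iter):
            if it == mcmc.burn_in:
                step_mu.frozen = step_k.frozen = True
            # mu update (logit walk; Jacobian mu(1-mu))
            lm = _logit(mu) + rng.normal(0.0, step_mu.step)
            mu_new = _expit(lm)
            lp_new = _beta_loglik_sums(mu_new, kappa, slx, sl1x, n)
            log_acc = (lp_new + np.log(mu_new * (1 - mu_new))) - (
                lp + np.log(mu * (1 - mu))
            )
            acc = np.log(rng.random()) < log_acc
            if acc:
                mu, lp = mu_new, lp_new
            step_mu.update(acc)
            # kappa update (log walk; Gamma prior + Jacobian kappa)
            k_new = kappa * np.exp(rng.normal(0.0, step_k.step))
            lp_new = _beta_loglik_sums(mu, k_new, slx, sl1x, n)
            log_acc = (
                lp_new - lp
                + _GAMMA_SHAPE * (np.log(k_new) - np.log(kappa))
                - _GAMMA_RATE * (k_new - kappa)
            )
            acc = np.log(rng.random()) < log_acc
            if acc:
                kappa, lp = k_new, lp_new
            step_k.update(acc)
            if it >= mcmc.burn_in:
                mu_draws[ci, it - mcmc.burn_in] = mu
                k_draws[ci, it - mcmc.burn_in] = kappa
    mu_hat = float(mu_draws.mean())
    k_hat = float(k_draws.mean())
    ll = _beta_loglik_sums(mu_hat, k_hat, slx, sl1x, n)
    rhat = _split_rhat(mu_draws)
    fit = ModalityFit(
        data_kind="methylation",
        model="unimodal",
        params={"mu": mu_hat, "kappa": k_hat,
                "alpha": mu_hat * k_hat, "beta": (1 - mu_hat) * k_hat},
        posterior_sd={"mu": float(mu_draws.std(ddof=1)),
                      "kappa": float(k_draws.std(ddof=1))},
        log_likelihood=float(ll),
        bic=0.0,
        n_params=2,
        n=n,
        rhat=rhat,
        converged=bool(rhat < mcmc.rhat_threshold),
        settings=mcmc,
    )
    fit.bic = compute_bic(fit, n)
    return fit


def fit_methylation_bimodal(
    values: np.ndarray,
    mcmc: MCMCSettings | None = None,
    seed: int = 0,
    mass_bounds: tuple[float, float] = _METH_MASS_BOUNDS,
) -> ModalityFit:
    """Gibbs with latent indicators for the two-component beta mixture with
    shared concentration kappa; component means and kappa move by adaptive
    Metropolis steps, the mass by a Beta posterior restricted to
    ``mass_bounds``."""
    mcmc = mcmc or MCMCSettings()
    lo, hi = mass_bounds
    if not 0.0 < lo < hi < 1.0:
        raise ValueError("mass bounds must satisfy 0 < lo < hi < 1")
    x = _prepare(values, "methylation")
    if np.ptp(x) == 0:
        raise ValueError("all values identical; mixture fit is degenerate")
    n = x.size
    lx = np.log(x)
    l1x = np.log1p(-x)
    keep = mcmc.n_iter - mcmc.burn_in
    draws = np.empty((mcmc.n_chains, keep, 4))  # mu1, mu2, omega, kappa
    med = float(np.median(x))
    for ci, rng in enumerate(_chain_seeds(seed, mcmc.n_chains)):
        mu1 = float(np.clip(x[x <= med].mean(), 0.02, 0.98))
        hi_mask = x > med
        mu2 = float(np.clip(x[hi_mask].mean() if hi_mask.any() else mu1 + 0.1,
                            0.02, 0.98))
        if mu2 <= mu1:
            mu2 = min(mu1 + 0.05, 0.98)
        v = max(float(x.var()) / 2.0, 1e-6)
        m = (mu1 + mu2) / 2
        kappa = float(np.clip(m * (1 - m) / v - 1.0, 0.5, 1e4))
        omega = 0.5
        steps = {"mu1": _AdaptiveStep(0.3), "mu2": _AdaptiveStep(0.3),
                 "kappa": _AdaptiveStep(0.3)}
        for it in range(mcmc.n_iter):
            if it == mcmc.burn_in:
                for s in steps.values():
                    s.frozen = True
            a1, b1 = mu1 * kappa, (1 - mu1) * kappa
            a2, b2 = mu2 * kappa, (1 - mu2) * kappa
            d = (
                np.log(omega) + (a1 - 1) * lx + (b1 - 1) * l1x
                - special.betaln(a1, b1)
            ) - (
                np.log1p(-omega) + (a2 - 1) * lx + (b2 - 1) * l1x
                - special.betaln(a2, b2)
            )
            z = rng.random(n) < 1.0 / (1.0 + np.exp(-d))  # True -> comp 1
            n1 = int(z.sum())
            n2 = n - n1
            s1x, s11x = float(lx @ z), float(l1x @ z)
            s2x, s21x = float(lx.sum() - s1x), float(l1x.sum() - s11x)

            def _comp_ll(mu_c, grp_sx, grp_s1x, grp_n, kap):
                return _beta_loglik_sums(mu_c, kap, grp_sx, grp_s1x, grp_n)

            # mu1 | z
            lm = _logit(mu1) + rng.normal(0.0, steps["mu1"].step)
            mu_new = _expit(lm)
            log_acc = (
                _comp_ll(mu_new, s1x, s11x, n1, kappa) + np.log(mu_new * (1 - mu_new))
                - _comp_ll(mu1, s1x, s11x, n1, kappa) - np.log(mu1 * (1 - mu1))
            )
            acc = np.log(rng.random()) < log_acc
            if acc:
                mu1 = mu_new
            steps["mu1"].update(acc)
            # mu2 | z
            lm = _logit(mu2) + rng.normal(0.0, steps["mu2"].step)
            mu_new = _expit(lm)
            log_acc = (
                _comp_ll(mu_new, s2x, s21x, n2, kappa) + np.log(mu_new * (1 - mu_new))
                - _comp_ll(mu2, s2x, s21x, n2, kappa) - np.log(mu2 * (1 - mu2))
            )
            acc = np.log(rng.random()) < log_acc
            if acc:
                mu2 = mu_new
            steps["mu2"].update(acc)
            # shared kappa | z
            k_new = kappa * np.exp(rng.normal(0.0, steps["kappa"].step))
            log_acc = (
                _comp_ll(mu1, s1x, s11x, n1, k_new)
                + _comp_ll(mu2, s2x, s21x, n2, k_new)
                - _comp_ll(mu1, s1x, s11x, n1, kappa)
                - _comp_ll(mu2, s2x, s21x, n2, kappa)
                + _GAMMA_SHAPE * (np.log(k_new) - np.log(kappa))
                - _GAMMA_RATE * (k_new - kappa)
            )
            acc = np.log(rng.random()) < log_acc
            if acc:
                kappa = k_new
            steps["kappa"].update(acc)
            omega = _truncbeta(1 + n1, 1 + n2, lo, hi, rng)
            if it >= mcmc.burn_in:
                draws[ci, it - mcmc.burn_in] = (mu1, mu2, omega, kappa)
    flat = draws.reshape(-1, 4).copy()
    orig = draws.reshape(-1, 4)
    swap = flat[:, 0] > flat[:, 1]
    flat[swap, 0], flat[swap, 1] = orig[swap, 1], orig[swap, 0]
    flat[swap, 2] = 1.0 - flat[swap, 2]
    mu1_hat, mu2_hat, om_hat, k_hat = flat.mean(axis=0)
    om_hat = float(np.clip(om_hat, lo, hi))
    sd = flat.std(axis=0, ddof=1)
    a1, b1 = mu1_hat * k_hat, (1 - mu1_hat) * k_hat
    a2, b2 = mu2_hat * k_hat, (1 - mu2_hat) * k_hat
    ll = float(
        np.logaddexp(
            np.log(om_hat) + (a1 - 1) * lx + (b1 - 1) * l1x - special.betaln(a1, b1),
            np.log1p(-om_hat) + (a2 - 1) * lx + (b2 - 1) * l1x - special.betaln(a2, b2),
        ).sum()
    )
    rhat = _split_rhat(np.minimum(draws[:, :, 0], draws[:, :, 1]))
    fit = ModalityFit(
        data_kind="methylation",
        model="bimodal",
        params={"mu1": float(mu1_hat), "mu2": float(mu2_hat),
                "omega1": float(om_hat), "omega2": float(1 - om_hat),
                "kappa": float(k_hat),
                "alpha1": float(a1), "beta1": float(b1),
                "alpha2": float(a2), "beta2": float(b2)},
        posterior_sd={"mu1": float(sd[0]), "mu2": float(sd[1]),
                      "omega1": float(sd[2]), "kappa": float(sd[3])},
        log_likelihood=ll,
        bic=0.0,
        n_params=4,
        n=n,
        rhat=rhat,
        converged=bool(rhat < mcmc.rhat_threshold),
        settings=mcmc,
    )
    fit.bic = compute_bic(fit, n)
    return fit


# ---------------------------------------------------------------------------
# model choice
# ---------------------------------------------------------------------------

def compute_bic(fit: ModalityFit, n: int) -> float:
    """BIC = n_params * ln(n) - 2 * logLik at plug-in posterior means."""
    return float(fit.n_params * np.log(n) - 2.0 * fit.log_likelihood)


def classify_modality(
    values: np.ndarray,
    data_kind: str,
    mcmc: MCMCSettings | None = None,
    seed: int = 0,
) -> tuple[str, ModalityFit, ModalityFit]:
    """Fit both models and pick the lower BIC; ties go to unimodal."""
    if data_kind == "expression":
        uni = fit_expression_unimodal(values, mcmc, seed)
        bi = fit_expression_bimodal(values, mcmc, seed + 1)
    elif data_kind == "methylation":
        uni = fit_methylation_unimodal(values, mcmc, seed)
        bi = fit_methylation_bimodal(values, mcmc, seed + 1)
    else:
        raise ValueError("data_kind must be 'expression' or 'methylation'")
    label = "bimodal" if bi.bic < uni.bic else "unimodal"
    return label, uni, bi


def classify_eqtm(
    gene_values: np.ndarray,
    cpg_values: np.ndarray,
    mcmc: MCMCSettings | None = None,
    seed: int = 0,
    gene_id: str = "gene",
    cpg_id: str = "cpg",
) -> EqtmClassification:
    """Classify one expression-methylation pair.

    linear  <- both sides unimodal (continuous cell-mixture signal)
    bimodal <- both sides bimodal (two-state switch)
    discordant otherwise.
    """
    g = np.asarray(gene_values, dtype=float)
    m = np.asarray(cpg_values, dtype=float)
    if g.shape != m.shape:
        raise ValueError("paired vectors must have equal length")
    mask = ~(np.isnan(g) | np.isnan(m))
    if mask.sum() < _MIN_N:
        raise ValueError(f"need at least {_MIN_N} complete pairs")
    g, m = g[mask], m[mask]
    expr_class, euni, ebi = classify_modality(g, "expression", mcmc, seed)
    meth_class, muni, mbi = classify_modality(m, "methylation", mcmc, seed + 1000)
    if expr_class == "unimodal" and meth_class == "unimodal":
        call = "linear"
    elif expr_class == "bimodal" and meth_class == "bimodal":
        call = "bimodal"
    else:
        call = "discordant"
    slope = float(np.polyfit(m, g, 1)[0]) if np.ptp(m) > 0 else 0.0
    return EqtmClassification(
        gene_id=gene_id,
        cpg_id=cpg_id,
        expression_class=expr_class,
        methylation_class=meth_class,
        call=call,
        correlation_sign="+" if slope >= 0 else "-",
        expression_fits=(euni, ebi),
        methylation_fits=(muni, mbi),
    )
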