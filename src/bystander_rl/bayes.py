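"""Bayesian response models for the adaptive bystander study.

Three models, all fit by MCMC — coordinate slice sampling within Gibbs over
hand-written log-posteriors, with multiple independent chains:

* **Model A** — Beta-Binomial logistic regression of each participant's
  response count (out of N action slots) on ``proprandom``, the realised
  fraction of randomly chosen agent actions:
  ``resp_i ~ BetaBinomial(N, p_i*phi, (1-p_i)*phi)`` with
  ``p_i = inv_logit(beta0 + beta1 * proprandom_i)``.  The Beta mixing
  absorbs the over-dispersion a plain Binomial cannot (response probability
  drifts over a session as the argument escalates).

* **Model B** — the same likelihood with the three-level factor ``RLLevel``
  (None / Medium / High) as dummy-coded predictor:
  ``p_i = inv_logit(gamma0 + gamma1*M_i + gamma2*H_i)``, with the derived
  per-level response probabilities
  ``p_none = inv_logit(gamma0)``, ``p_medium = inv_logit(gamma0+gamma1)``,
  ``p_high = inv_logit(gamma0+gamma2)`` computed draw-by-draw.

* **Model C** — per-trial Bernoulli logistic model of the binary response
  with subject effects and simplex-constrained action weights:
  ``eta_i = u_id(i) + b_vl*vl_i + b_pl*pl_i + b_bu*bu_i`` where
  ``(b_vl, b_pl, b_bu)`` are nonnegative and sum to 1 (the one-hot action
  indicators are collinear, so only the constrained combination is
  identified).  The simplex is parameterised by a stick-breaking transform,
  so every draw satisfies the constraint exactly; the uniform-simplex
  (Dirichlet(1,1,1)) prior enters through the transform's Jacobian.

Weakly informative priors follow the study defaults: Normal(0, 10) on
regression coefficients, Gamma(shape=2, rate=0.1) on the Beta-Binomial
scale ``phi``, and standard normal subject effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "inv_logit",
    "beta_binomial_logpmf",
    "PriorSpec",
    "prior_interval",
    "MCMCConfig",
    "PosteriorDraws",
    "fit_model_a",
    "fit_model_b",
    "fit_action_model",
    "derived_probabilities",
    "posterior_summary",
    "posterior_predictive_resp",
    "point_biserial",
    "rhat",
]


# --------------------------------------------------------------------------
# elementary pieces


def inv_logit(x):
    """Numerically stable logistic function 1 / (1 + exp(-x))."""
    arr = np.asarray(x, dtype=float)
    if np.any(np.isnan(arr)):
        raise ValueError("inv_logit: NaN input")
    out = special.expit(arr)
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


def beta_binomial_logpmf(k, N: int, p: float, phi: float):
    """Log pmf of the Beta-Binomial in mean/scale form.

    Shape parameters are alpha = p*phi and beta = (1-p)*phi, so the mean is
    N*p and phi controls over-dispersion (phi -> inf recovers Binomial(N, p)).
    """
    if phi <= 0:
        raise ValueError(f"phi must be > 0, got {phi}")
    if not (0.0 < p < 1.0):
        raise ValueError(f"p must be in (0, 1), got {p}")
    karr = np.asarray(k)
    if np.any((karr < 0) | (karr > N)):
        raise ValueError(f"k must be in 0..{N}")
    out = stats.betabinom.logpmf(karr, N, p * phi, (1.0 - p) * phi)
    return float(out) if karr.ndim == 0 else out


@dataclass(frozen=True)
class PriorSpec:
    """A named prior family with its parameters.

    Supported families: ``normal(mean, sd)``, ``gamma(shape, rate)`` and
    ``dirichlet(concentrations)``.
    """

    family: str
    mean: float = 0.0
    sd: float = 1.0
    shape: float = 1.0
    rate: float = 1.0
    concentrations: Sequence[float] = (1.0,)

    def __post_init__(self) -> None:
        if self.family == "normal":
            if self.sd <= 0:
                raise ValueError("normal prior needs sd > 0")
        elif self.family == "gamma":
            if self.shape <= 0 or self.rate <= 0:
                raise ValueError("gamma prior needs shape, rate > 0")
        elif self.family == "dirichlet":
            c = np.asarray(self.concentrations, dtype=float)
            if np.any(c <= 0):
                raise ValueError("dirichlet concentrations must be > 0")
        else:
            raise ValueError(f"unknown prior family {self.family!r}")


#: Weakly informative defaults: wide normal coefficients, diffuse scale.
DEFAULT_COEF_PRIOR = PriorSpec("normal", mean=0.0, sd=10.0)
DEFAULT_PHI_PRIOR = PriorSpec("gamma", shape=2.0, rate=0.1)


def prior_interval(prior: PriorSpec, mass: float = 0.95):
    """Equal-tail credible interval of a prior by CDF inversion.

    For the dirichlet family, returns one (lower, upper) pair per component
    from its Beta marginal.
    """
    if not (0.0 < mass < 1.0):
        raise ValueError(f"mass must be in (0, 1), got {mass}")
    lo, hi = (1.0 - mass) / 2.0, 1.0 - (1.0 - mass) / 2.0
    if prior.family == "normal":
        d = stats.norm(prior.mean, prior.sd)
        return (d.ppf(lo), d.ppf(hi))
    if prior.family == "gamma":
        d = stats.gamma(a=prior.shape, scale=1.0 / prior.rate)
        return (d.ppf(lo), d.ppf(hi))
    c = np.asarray(prior.concentrations, dtype=float)
    total = c.sum()
    return [
        (stats.beta(a, total - a).ppf(lo), stats.beta(a, total - a).ppf(hi))
        for a in c
    ]


# --------------------------------------------------------------------------
# MCMC plumbing


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler settings.

    ``iterations`` are Gibbs sweeps per chain; the first ``warmup``
    (default: half) are discarded, so the retained draw count is
    ``chains x (iterations - warmup)``.
    """

    iterations: int = 2000
    chains: int = 4
    warmup: Optional[int] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.iterations < 2:
            raise ValueError("iterations must be >= 2")
        if self.chains < 2:
            raise ValueError("need >= 2 chains for diagnostics")
        w = self.iterations // 2 if self.warmup is None else self.warmup
        if not (0 <= w < self.iterations):
            raise ValueError("warmup must be in [0, iterations)")

    @property
    def effective_warmup(self) -> int:
        return self.iterations // 2 if self.warmup is None else self.warmup


@dataclass
class PosteriorDraws:
    """MCMC output: named parameter arrays of shape (chains, draws).

    ``meta`` records the sampler configuration (iterations, chains, warmup,
    seed); ``diagnostics`` collects warnings such as large Rhat.
    """

    params: Dict[str, np.ndarray]
    meta: Dict[str, object] = field(default_factory=dict)
    diagnostics: List[str] = field(default_factory=list)

    @property
    def names(self) -> List[str]:
        return list(self.params)

    @property
    def n_chains(self) -> int:
        return next(iter(self.params.values())).shape[0]

    @property
    def n_draws(self) -> int:
        a = next(iter(self.params.values()))
        return a.shape[0] * a.shape[1]

    def flat(self, name: str) -> np.ndarray:
        return self.params[name].reshape(-1)

    def subset(self, names: Sequence[str]) -> "PosteriorDraws":
        return PosteriorDraws(
            {n: self.params[n] for n in names}, dict(self.meta), list(self.diagnostics)
        )

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format draws: chain and draw index columns plus one per parameter."""
        c, d = next(iter(self.params.values())).shape
        out = {
            "chain": np.repeat(np.arange(c), d),
            "draw": np.tile(np.arange(d), c),
        }
        for name, arr in self.params.items():
            out[name] = arr.reshape(-1)
        return pd.DataFrame(out)


def _slice_update(logf, x0, rng, w=1.0, max_step=32, max_shrink=100):
    """Vectorised univariate slice update (stepping out + shrinkage).

    ``x0`` is an array of current points and ``logf`` maps a same-shaped
    array to elementwise conditional log densities; every entry is updated
    independently with one slice-sampling transition.  The densities must
    be finite everywhere (all model parameterisations here are
    unconstrained).
    """
    z = logf(x0) - rng.exponential(size=x0.shape)  # log slice height
    u = rng.uniform(size=x0.shape)
    L = x0 - w * u
    R = L + w
    for _ in range(max_step):
        grow = logf(L) > z
        if not grow.any():
            break
        L = np.where(grow, L - w, L)
    for _ in range(max_step):
        grow = logf(R) > z
        if not grow.any():
            break
        R = np.where(grow, R + w, R)
    x1 = x0.copy()
    active = np.ones(x0.shape, dtype=bool)
    for _ in range(max_shrink):
        xp = rng.uniform(L, R)
        accept = active & (logf(xp) >= z)
        x1 = np.where(accept, xp, x1)
        active &= ~accept
        if not active.any():
            break
        below = active & (xp < x0)
        L = np.where(below, xp, L)
        R = np.where(active & ~below, xp, R)
    return x1


def _run_gibbs(
    sweep, x0: np.ndarray, config: MCMCConfig, transform, extra_meta=None
) -> PosteriorDraws:
    """Drive a Gibbs sweep function over ``chains`` parallel chains.

    ``sweep(x, rng)`` updates the (chains, ndim) state in place once;
    ``transform`` maps retained draws (n, ndim) to named parameter columns.
    The retained draw count is exactly chains x (iterations - warmup).
    """
    seed = 0 if config.seed is None else int(config.seed)
    rng = np.random.default_rng(seed)
    x = x0.copy()
    warm = config.effective_warmup
    kept = config.iterations - warm
    out = np.empty((kept, x.shape[0], x.shape[1]))
    for it in range(config.iterations):
        sweep(x, rng)
        if it >= warm:
            out[it - warm] = x
    flat = out.transpose(1, 0, 2).reshape(-1, x.shape[1])  # chain-major
    cols = transform(flat)
    params = {n: v.reshape(config.chains, kept) for n, v in cols.items()}
    meta = {
        "iterations": config.iterations,
        "warmup": warm,
        "chains": config.chains,
        "seed": seed,
        "sampler": "slice-within-gibbs",
    }
    meta.update(extra_meta or {})
    draws = PosteriorDraws(params, meta)
    _attach_convergence_warnings(draws)
    return draws


def _attach_convergence_warnings(draws: PosteriorDraws, threshold: float = 1.05):
    try:
        rh = rhat(draws)
    except Exception:  # pragma: no cover - diagnostics must never kill a fit
        return
    bad = {n: v for n, v in rh.items() if np.isfinite(v) and v > threshold}
    if bad:
        msg = "Rhat above %.2f for: %s" % (
            threshold,
            ", ".join(f"{n}={v:.3f}" for n, v in sorted(bad.items())),
        )
        draws.diagnostics.append(msg)
        warnings.warn(msg, RuntimeWarning, stacklevel=3)


def _map_center(neg_log_prob, x0: np.ndarray) -> np.ndarray:
    """Posterior mode in the unconstrained space, used to centre the chains."""
    res = optimize.minimize(neg_log_prob, x0, method="Nelder-Mead",
                            options={"maxiter": 4000, "fatol": 1e-8})
    return res.x if np.isfinite(res.fun) else x0


def _normal_logpdf(x, mean, sd):
    return -0.5 * ((x - mean) / sd) ** 2 - np.log(sd) - 0.5 * np.log(2 * np.pi)


def _gamma_logpdf(x, shape, rate):
    return shape * np.log(rate) + (shape - 1) * np.log(x) - rate * x - special.gammaln(shape)


# --------------------------------------------------------------------------
# Beta-Binomial regressions (models A and B)


def _betabinom_loglik(resp, N, eta, phi):
    """Vectorised Beta-Binomial log likelihood; eta (chains, n), phi (chains,)."""
    p = special.expit(eta)
    a = p * phi[:, None]
    b = (1.0 - p) * phi[:, None]
    k = resp[None, :]
    ll = (
        special.gammaln(N + 1)
        - special.gammaln(k + 1)
        - special.gammaln(N - k + 1)
        + special.betaln(k + a, N - k + b)
        - special.betaln(a, b)
    )
    return ll.sum(axis=1)


def _fit_betabinom_regression(
    X: np.ndarray,
    resp: np.ndarray,
    N: int,
    coef_names: Sequence[str],
    coef_prior: PriorSpec,
    phi_prior: PriorSpec,
    config: MCMCConfig,
) -> PosteriorDraws:
    """Shared machinery for models A and B.

    Parameterisation: coefficients unconstrained, phi sampled on the log
    scale with the Jacobian folded into the posterior.  An empty dataset
    yields prior-only draws.
    """
    n_coef = X.shape[1]
    ndim = n_coef + 1
    # sample with the intercept moved to the covariate mean: coordinate
    # updates mix poorly when intercept and slopes are strongly correlated
    xbar = X[:, 1:].mean(axis=0) if len(X) else np.zeros(n_coef - 1)
    Xc = X.copy()
    if len(Xc):
        Xc[:, 1:] -= xbar

    def to_original(theta):
        coefs = theta[:, :n_coef].copy()
        coefs[:, 0] -= coefs[:, 1:] @ xbar
        return coefs

    def log_post(theta):  # theta (chains, ndim) -> (chains,)
        coefs_c = theta[:, :n_coef]
        log_phi = theta[:, n_coef]
        phi = np.exp(log_phi)
        # the prior is on the original-scale coefficients
        lp = _normal_logpdf(to_original(theta), coef_prior.mean, coef_prior.sd).sum(axis=1)
        lp += _gamma_logpdf(phi, phi_prior.shape, phi_prior.rate) + log_phi
        if len(resp):
            lp += _betabinom_loglik(resp, N, coefs_c @ Xc.T, phi)
        return np.where(np.isfinite(lp), lp, -np.inf)

    x0 = np.zeros(ndim)
    x0[n_coef] = np.log(phi_prior.shape / phi_prior.rate)  # prior mean of phi
    center = _map_center(lambda x: -log_post(x[None, :])[0], x0)
    # slice widths of the order of the conditional scales; stepping out
    # corrects them adaptively, so only the order of magnitude matters
    widths = np.full(ndim, max(1.0, coef_prior.sd / 5.0))
    widths[n_coef] = 1.0

    def sweep(x, rng):
        for d in range(ndim):
            def logf(v, d=d):
                t = x.copy()
                t[:, d] = v
                return log_post(t)

            x[:, d] = _slice_update(logf, x[:, d], rng, w=widths[d])

    seed = 0 if config.seed is None else int(config.seed)
    init_rng = np.random.default_rng(seed + 1)
    x_init = center[None, :] + 0.5 * init_rng.standard_normal((config.chains, ndim))

    def transform(flat):
        orig = to_original(flat)
        cols = {n: orig[:, i] for i, n in enumerate(coef_names)}
        cols["phi"] = np.exp(flat[:, n_coef])
        return cols

    draws = _run_gibbs(sweep, x_init, config, transform, extra_meta={"N": N})
    return draws


def fit_model_a(
    dataset: pd.DataFrame,
    priors: Optional[Dict[str, PriorSpec]] = None,
    config: Optional[MCMCConfig] = None,
    N: int = 13,
) -> PosteriorDraws:
    """Beta-Binomial logistic regression of resp on proprandom.

    ``dataset`` needs columns ``resp`` (counts in 0..N) and ``proprandom``
    (in [0, 1]).  Returns draws over beta0, beta1 and phi.
    """
    config = config or MCMCConfig()
    priors = priors or {}
    resp = np.asarray(dataset["resp"], dtype=int) if len(dataset) else np.array([], int)
    x = (
        np.asarray(dataset["proprandom"], dtype=float)
        if len(dataset)
        else np.array([])
    )
    if len(resp) and (resp.min() < 0 or resp.max() > N):
        raise ValueError(f"resp must lie in 0..{N}")
    if len(x) and (x.min() < 0 or x.max() > 1):
        raise ValueError("proprandom must lie in [0, 1]")
    X = np.column_stack([np.ones_like(x), x]) if len(x) else np.empty((0, 2))
    return _fit_betabinom_regression(
        X,
        resp,
        N,
        ("beta0", "beta1"),
        priors.get("coef", DEFAULT_COEF_PRIOR),
        priors.get("phi", DEFAULT_PHI_PRIOR),
        config,
    )


def fit_model_b(
    dataset: pd.DataFrame,
    priors: Optional[Dict[str, PriorSpec]] = None,
    config: Optional[MCMCConfig] = None,
    N: int = 13,
) -> PosteriorDraws:
    """Beta-Binomial regression of resp on the RLLevel dummies M and H.

    ``dataset`` needs columns ``resp``, ``M`` and ``H`` (1 for Medium / High,
    0 otherwise; the None level is the intercept).  Returns draws over
    gamma0, gamma1, gamma2 and phi.
    """
    config = config or MCMCConfig()
    priors = priors or {}
    n = len(dataset)
    resp = np.asarray(dataset["resp"], dtype=int) if n else np.array([], int)
    M = np.asarray(dataset["M"], dtype=float) if n else np.array([])
    H = np.asarray(dataset["H"], dtype=float) if n else np.array([])
    if n and not (set(np.unique(M)) <= {0.0, 1.0} and set(np.unique(H)) <= {0.0, 1.0}):
        raise ValueError("M and H must be 0/1 dummies")
    if n and np.any((M == 1) & (H == 1)):
        raise ValueError("a participant cannot be both Medium and High")
    X = np.column_stack([np.ones(n), M, H]) if n else np.empty((0, 3))
    return _fit_betabinom_regression(
        X,
        resp,
        N,
        ("gamma0", "gamma1", "gamma2"),
        priors.get("coef", DEFAULT_COEF_PRIOR),
        priors.get("phi", DEFAULT_PHI_PRIOR),
        config,
    )


def derived_probabilities(draws: PosteriorDraws) -> PosteriorDraws:
    """Per-level response probabilities from model-B draws, draw by draw.

    Applies p_none = inv_logit(gamma0), p_medium = inv_logit(gamma0+gamma1),
    p_high = inv_logit(gamma0+gamma2) to every posterior draw (not to the
    posterior means, which would understate the uncertainty).
    """
    g0, g1, g2 = (draws.params[n] for n in ("gamma0", "gamma1", "gamma2"))
    return PosteriorDraws(
        {
            "p_none": special.expit(g0),
            "p_medium": special.expit(g0 + g1),
            "p_high": special.expit(g0 + g2),
        },
        dict(draws.meta),
        list(draws.diagnostics),
    )


# --------------------------------------------------------------------------
# simplex-constrained Bernoulli action model (model C)


def _stick_breaking(y: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Map unconstrained (n, K-1) to simplex (n, K); return (points, log|J|).

    The K-1 free coordinates are logit-transformed stick fractions with the
    centring offset log(1/(K-k)), so y = 0 maps to the simplex barycentre.
    A uniform density on the simplex corresponds to adding log|J| alone.
    """
    n, km1 = y.shape
    K = km1 + 1
    x = np.empty((n, K))
    remaining = np.ones(n)
    logj = np.zeros(n)
    for k in range(km1):
        z = special.expit(y[:, k] - np.log(K - k - 1.0))
        x[:, k] = remaining * z
        with np.errstate(divide="ignore"):
            logj += np.log(z) + np.log1p(-z) + np.log(remaining)
        remaining = remaining - x[:, k]
    x[:, K - 1] = remaining
    return x, logj


def fit_action_model(
    trials: pd.DataFrame,
    config: Optional[MCMCConfig] = None,
    subject_sd: float = 1.0,
) -> PosteriorDraws:
    """Bernoulli logistic model of per-trial responses with action weights.

    ``trials`` needs columns ``id`` (1..n in blocks), ``y`` (0/1) and the
    one-hot action indicators ``vl``, ``pl``, ``bu``.  The action weights
    (b_vl, b_pl, b_bu) live on the unit simplex — uniform (Dirichlet(1,1,1))
    prior via a stick-breaking parameterisation, so the constraint holds for
    every draw — and each subject gets an effect u_k ~ Normal(0, subject_sd).

    The Gibbs sweep alternates slice updates of the two stick-breaking
    coordinates of the simplex (conditioned on all subject effects) with
    parallel slice updates of the subject effects, which are conditionally
    independent given the weights.  The default runs 8000 iterations (the
    subject effects make this a much bigger parameter space than the count
    models).
    """
    config = config or MCMCConfig(iterations=8000)
    Xhot = trials[["vl", "pl", "bu"]].to_numpy(dtype=float)
    if not np.all(np.isin(Xhot, (0.0, 1.0))) or not np.all(Xhot.sum(axis=1) == 1.0):
        bad = int(np.flatnonzero(Xhot.sum(axis=1) != 1.0)[0]) if len(Xhot) else -1
        raise ValueError(f"rows must be one-hot in (vl, pl, bu); first bad row {bad}")
    y = trials["y"].to_numpy(dtype=float)
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("y must be 0/1")
    ids = trials["id"].to_numpy(dtype=int)
    uniq = np.unique(ids)
    if not np.array_equal(uniq, np.arange(1, len(uniq) + 1)):
        raise ValueError("id must take values 1..n_subjects")
    order = np.argsort(ids, kind="stable")  # group trials by subject
    y = y[order]
    Xhot = Xhot[order]
    id_idx = ids[order] - 1
    n_sub = len(uniq)
    starts = np.searchsorted(id_idx, np.arange(n_sub))
    ndim = 2 + n_sub
    C = config.chains

    def bern_ll(eta):
        return y[None, :] * eta - np.logaddexp(0.0, eta)

    def stick_logf(x, d, v):
        sticks = x[:, :2].copy()
        sticks[:, d] = v
        b, logj = _stick_breaking(sticks)
        eta = x[:, 2:][:, id_idx] + b @ Xhot.T
        return logj + bern_ll(eta).sum(axis=1)

    def sweep(x, rng):
        for d in range(2):
            x[:, d] = _slice_update(
                lambda v, d=d: stick_logf(x, d, v), x[:, d], rng, w=2.0
            )
        b, _ = _stick_breaking(x[:, :2])
        xb = b @ Xhot.T  # (chains, trials), fixed during the u block

        def u_logf(V):  # V (chains, n_sub) -> elementwise conditional density
            eta = V[:, id_idx] + xb
            per_subject = np.add.reduceat(bern_ll(eta), starts, axis=1)
            return per_subject + _normal_logpdf(V, 0.0, subject_sd)

        x[:, 2:] = _slice_update(u_logf, x[:, 2:], rng, w=2.0)

    # crude empirical start: logit of each subject's response rate, minus
    # the average action contribution (1/3); chains overdispersed around it
    rate = np.add.reduceat(y, starts) / np.diff(np.append(starts, len(y)))
    u_start = np.log((rate + 0.1) / (1.1 - rate)) - 1.0 / 3.0
    seed = 0 if config.seed is None else int(config.seed)
    init_rng = np.random.default_rng(seed + 1)
    x_init = np.concatenate([np.zeros(2), u_start])[None, :] + 0.5 * init_rng.standard_normal((C, ndim))

    def transform(flat):
        b, _ = _stick_breaking(flat[:, :2])
        cols = {"b_vl": b[:, 0], "b_pl": b[:, 1], "b_bu": b[:, 2]}
        for k in range(n_sub):
            cols[f"u_{k + 1}"] = flat[:, 2 + k]
        return cols

    draws = _run_gibbs(sweep, x_init, config, transform,
                       extra_meta={"n_subjects": n_sub})
    return draws


# --------------------------------------------------------------------------
# summaries and checks


def posterior_summary(
    draws: PosteriorDraws,
    thresholds: Optional[Dict[str, float]] = None,
    default_threshold: float = 0.0,
) -> pd.DataFrame:
    """Mean / SD / 2.5% / 97.5% / Prob>t table, one row per parameter.

    ``Prob>t`` is the fraction of draws strictly greater than the threshold
    (``thresholds`` maps parameter name to t; others use
    ``default_threshold``).
    """
    thresholds = thresholds or {}
    rows = []
    for name in draws.names:
        v = draws.flat(name)
        t = thresholds.get(name, default_threshold)
        rows.append(
            {
                "parameter": name,
                "mean": v.mean(),
                "sd": v.std(ddof=1) if len(v) > 1 else 0.0,
                "2.5%": np.percentile(v, 2.5),
                "97.5%": np.percentile(v, 97.5),
                "threshold": t,
                "prob_gt": float(np.mean(v > t)),
            }
        )
    return pd.DataFrame(rows)


def prob_greater(draws: PosteriorDraws, name: str, t: float) -> float:
    """Posterior probability that a parameter exceeds ``t`` (strict)."""
    return float(np.mean(draws.flat(name) > t))


def posterior_predictive_resp(
    draws: PosteriorDraws,
    model: str,
    dataset: pd.DataFrame,
    n_sims: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    N: int = 13,
    binomial_only: bool = False,
) -> np.ndarray:
    """Simulate new observations from a fitted model at the observed covariates.

    ``n_sims`` defaults to 4000 for the count models and 16000 for the
    per-trial model.

    For the count models ("a" / "b") each simulation picks a posterior draw
    at random, cycles through the observed covariate rows, draws the mixing
    probability from its Beta, and then the count from Binomial(N, p);
    ``binomial_only=True`` skips the Beta step (plug-in Binomial), which is
    how the over-dispersion failure of the plain Binomial is demonstrated.
    For the per-trial model ("c") the simulation returns 0/1 responses.
    """
    rng = np.random.default_rng() if rng is None else rng
    if n_sims is None:
        n_sims = 16000 if model == "c" else 4000
    if n_sims == 0:
        return np.array([], dtype=int)
    n_obs = len(dataset)
    if n_obs == 0:
        raise ValueError("need a dataset with covariate rows")
    obs_idx = np.arange(n_sims) % n_obs
    draw_idx = rng.integers(draws.n_draws, size=n_sims)

    if model in ("a", "b"):
        if model == "a":
            x = dataset["proprandom"].to_numpy(dtype=float)[obs_idx]
            eta = draws.flat("beta0")[draw_idx] + draws.flat("beta1")[draw_idx] * x
        else:
            M = dataset["M"].to_numpy(dtype=float)[obs_idx]
            H = dataset["H"].to_numpy(dtype=float)[obs_idx]
            eta = (
                draws.flat("gamma0")[draw_idx]
                + draws.flat("gamma1")[draw_idx] * M
                + draws.flat("gamma2")[draw_idx] * H
            )
        p = special.expit(eta)
        if binomial_only:
            return rng.binomial(N, p)
        phi = draws.flat("phi")[draw_idx]
        a, b = p * phi, (1.0 - p) * phi
        mix = p.copy()  # saturated p (0 or 1) has a degenerate mixing Beta
        ok = (a > 0) & (b > 0)
        mix[ok] = rng.beta(a[ok], b[ok])
        return rng.binomial(N, mix)

    if model == "c":
        b = np.column_stack(
            [draws.flat(n)[draw_idx] for n in ("b_vl", "b_pl", "b_bu")]
        )
        Xhot = dataset[["vl", "pl", "bu"]].to_numpy(dtype=float)[obs_idx]
        ids = dataset["id"].to_numpy(dtype=int)[obs_idx]
        u = np.array(
            [draws.flat(f"u_{i}")[j] for i, j in zip(ids, draw_idx)]
        )
        eta = u + (b * Xhot).sum(axis=1)
        return rng.binomial(1, special.expit(eta))

    raise ValueError(f"unknown model tag {model!r}")


def predictive_mean_response(draws: PosteriorDraws, dataset: pd.DataFrame) -> np.ndarray:
    """Posterior-predictive mean response probability per trial (model C)."""
    b = np.column_stack([draws.flat(n) for n in ("b_vl", "b_pl", "b_bu")])
    Xhot = dataset[["vl", "pl", "bu"]].to_numpy(dtype=float)
    ids = dataset["id"].to_numpy(dtype=int)
    u = np.column_stack([draws.flat(f"u_{i}") for i in ids])  # (draws, trials)
    eta = u + b @ Xhot.T
    return special.expit(eta).mean(axis=0)


def point_biserial(binary, continuous) -> Tuple[float, Tuple[float, float]]:
    """Point-biserial correlation with a Fisher-z 95% confidence interval.

    The point-biserial coefficient of a 0/1 variable against a continuous
    one is the ordinary Pearson correlation of the two vectors.
    """
    b = np.asarray(binary, dtype=float)
    c = np.asarray(continuous, dtype=float)
    if len(b) != len(c) or len(b) < 3:
        raise ValueError("need equal-length vectors with at least 3 entries")
    if np.ptp(b) == 0 or np.ptp(c) == 0:
        raise ValueError("correlation undefined for constant input")
    r = float(stats.pearsonr(b, c).statistic)
    n = len(b)
    z = np.arctanh(r)
    half = stats.norm.ppf(0.975) / np.sqrt(n - 3)
    return r, (float(np.tanh(z - half)), float(np.tanh(z + half)))


def rhat(draws: PosteriorDraws) -> Dict[str, float]:
    """Split-chain potential scale reduction factor per parameter.

    Values near 1 indicate the chains are comparable and mixed; constant
    (zero-variance) parameters yield NaN.
    """
    if draws.n_chains < 2:
        raise ValueError("rhat needs at least 2 chains")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        import arviz as az

        out = {}
        for name in draws.names:
            arr = draws.params[name]
            if arr.shape[1] < 4:
                raise ValueError("rhat needs at least 4 draws per chain")
            result = az.rhat(az.convert_to_dataset(arr))
            out[name] = float(result["x"].values)
        return out
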