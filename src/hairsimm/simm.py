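"""Bayesian stable-isotope mixing model (SIMM) with covariate structures.

The model expresses each hair section's (d13C, d15N) pair as a normal draw
around the concentration-weighted mixture mean of the TEF-corrected sources,
with variance equal to the propagated source+TEF ("process") variance plus a
residual term. Diet compositions are modelled in ILR coordinates:

    z_b = mu + beta_sex[sex(b)] + beta_status[status(b)] + u_b,
    p_b = ilr_inv(z_b),

with ``u_b ~ N(0, sigma_u^2 I)`` an individual (bear) random effect. Prior
dietary knowledge (EDEC%, digestible-energy diet shares from scat analysis)
enters as an informative Dirichlet prior on the baseline composition
``ilr_inv(mu)``; covariate coefficients get Normal(0, 10) priors in ILR
space, random-effect and residual SDs get half-normal priors.

Sampling is adaptive random-walk Metropolis-within-Gibbs: one block per
coefficient vector, one vectorised block updating all bear effects at once
(their likelihood contributions are conditionally independent), and log-scale
blocks for the SDs. Proposal scales adapt toward 20-40% acceptance during
burn-in only. Pointwise log-likelihoods are stored for every kept draw so
that PSIS-LOO model comparison needs no refitting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .compositions import ilr, ilr_inv
from .diagnostics import ConvergenceReport, convergence_report
from .mixing import ISOTOPES, MixingSpace, mixture_moments

__all__ = [
    "PriorSpec",
    "ModelSpec",
    "MODEL_STRUCTURES",
    "MCMCSettings",
    "PosteriorResult",
    "prior_from_edec",
    "log_likelihood",
    "fit_mcmc",
    "summarize_posterior",
]

#: Factor levels, first level is the reference absorbed into the intercept.
FACTOR_LEVELS = {
    "sex": ("F", "M"),
    "status": ("non-management", "management", "unknown"),
}

#: Placeholder seasonal prior-knowledge vectors (EDEC%, estimated digestible
#: energy content by diet category) over the alphabetical source order:
#: cultivated fleshy fruits, cultivated vegetables, Formicidae, hard masts,
#: herbs, ungulates, wild fleshy fruits. They encode generic brown-bear food
#: phenology (herbs in spring, ants in early summer, fleshy fruits in late
#: summer, hard mast in autumn); the study population's own scat-derived
#: vectors are not published, so these are a clearly-labelled stand-in and
#: should be replaced by real EDEC% values where available.
DEFAULT_EDEC: dict[str, tuple[float, ...]] = {
    "spring": (5.0, 5.0, 10.0, 20.0, 40.0, 10.0, 10.0),
    "early_summer": (5.0, 5.0, 35.0, 10.0, 25.0, 5.0, 15.0),
    "late_summer": (15.0, 5.0, 10.0, 15.0, 10.0, 5.0, 40.0),
    "autumn": (15.0, 3.0, 5.0, 50.0, 10.0, 2.0, 15.0),
}

#: The seven covariate structures compared per season.
MODEL_STRUCTURES: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "Null": ((), ()),
    "Sex": (("sex",), ()),
    "Status": (("status",), ()),
    "BearID": ((), ("bear",)),
    "Sex + Status": (("sex", "status"), ()),
    "Sex + BearID": (("sex",), ("bear",)),
    "Status + BearID": (("status",), ("bear",)),
}


@dataclass(frozen=True)
class PriorSpec:
    """Informative Dirichlet prior on the baseline diet composition."""

    edec: np.ndarray
    alpha: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "edec", np.asarray(self.edec, dtype=float))
        object.__setattr__(self, "alpha", np.asarray(self.alpha, dtype=float))
        if np.any(self.alpha <= 0):
            raise ValueError("Dirichlet concentrations must be positive")


def prior_from_edec(edec: Sequence[float], total: Optional[float] = None,
                    eps: float = 0.01) -> PriorSpec:
    """Turn an EDEC% vector into a Dirichlet prior with total weight K.

    ``alpha_k = max(eps, edec_k / sum(edec) * total)`` with ``total``
    defaulting to K, so a uniform EDEC vector reduces to the flat Dirichlet(1)
    prior and informative vectors carry the same overall weight.
    """
    edec = np.asarray(edec, dtype=float)
    if np.any(edec < 0):
        raise ValueError("EDEC entries must be non-negative")
    s = edec.sum()
    if s <= 0:
        raise ValueError("EDEC entries must not all be zero")
    if total is None:
        total = float(len(edec))
    alpha = np.maximum(eps, edec / s * total)
    return PriorSpec(edec=edec, alpha=alpha)


@dataclass(frozen=True)
class ModelSpec:
    """One covariate structure: fixed effects and random effects."""

    fixed: tuple[str, ...] = ()
    random: tuple[str, ...] = ()
    season: Optional[str] = None

    def __post_init__(self):
        if not set(self.fixed) <= {"sex", "status"}:
            raise ValueError(f"unknown fixed effect in {self.fixed}")
        if not set(self.random) <= {"bear"}:
            raise ValueError(f"unknown random effect in {self.random}")

    @property
    def label(self) -> str:
        for name, (fx, rd) in MODEL_STRUCTURES.items():
            if tuple(sorted(fx)) == tuple(sorted(self.fixed)) and rd == self.random:
                return name
        raise ValueError("not one of the seven supported structures")

    @classmethod
    def from_label(cls, label: str, season: Optional[str] = None) -> "ModelSpec":
        fx, rd = MODEL_STRUCTURES[label]
        return cls(fixed=fx, random=rd, season=season)


@dataclass
class MCMCSettings:
    chains: int = 3
    iterations: int = 300_000
    burn_in: int = 200_000
    thin: int = 100
    target_accept: float = 0.3
    adapt_window: int = 100
    beta_prior_sd: float = 3.1622776601683795  # Normal(0, variance 10) in ILR space
    sigma_u_prior_scale: float = 2.0
    sigma_res_prior_scale: float = 5.0
    sigma_res_fixed: Optional[tuple[float, ...]] = None
    rhat_threshold: float = 1.05
    geweke_threshold: float = 2.0

    def __post_init__(self):
        if self.chains < 1 or self.iterations < 1:
            raise ValueError("chains and iterations must be >= 1")
        if not 0 <= self.burn_in < self.iterations:
            raise ValueError("burn_in must be in [0, iterations)")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def kept_per_chain(self) -> int:
        return (self.iterations - self.burn_in) // self.thin


def log_likelihood(
    d13C: float,
    d15N: float,
    p: np.ndarray,
    space: MixingSpace,
    sigma_res: Sequence[float] = (0.0, 0.0),
    isotopes: Sequence[str] = ISOTOPES,
) -> float:
    """Log-density of one section's observed deltas under diet ``p``.

    Sum over the requested isotopes of the normal log-density at the
    concentration-weighted mixture mean, with variance = process variance
    (propagated source+TEF SDs) + residual variance.
    """
    p = np.asarray(p, dtype=float)
    if not np.all(np.isfinite(p)) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("p must be a finite simplex vector")
    obs = np.array([d13C, d15N], dtype=float)
    if not np.all(np.isfinite(obs)):
        raise ValueError("observed deltas must be finite")
    mean, pvar = mixture_moments(p, space)
    idx = [ISOTOPES.index(i) for i in isotopes]
    var = pvar[idx] + np.asarray(sigma_res, dtype=float)[: len(idx)] ** 2
    resid = obs[idx] - mean[idx]
    return float(np.sum(-0.5 * np.log(2 * np.pi * var) - resid**2 / (2 * var)))


# ---------------------------------------------------------------------------
# internal model state

try:  # compiled likelihood kernel; the numpy branch below is the reference
    from numba import njit

    @njit(cache=True)
    def _llb_kernel(z, H, conc, means, sds2, nb, sy, sy2, sig2):
        B, d = z.shape
        K = H.shape[1]
        n_iso = conc.shape[1]
        out = np.zeros(B)
        logp = np.empty(K)
        for b in range(B):
            m = -1e300
            for k in range(K):
                acc = 0.0
                for j in range(d):
                    acc += z[b, j] * H[j, k]
                logp[k] = acc
                if acc > m:
                    m = acc
            s = 0.0
            for k in range(K):
                logp[k] = np.exp(logp[k] - m)
                s += logp[k]
            ll = 0.0
            for i in range(n_iso):
                den = 0.0
                num = 0.0
                varnum = 0.0
                for k in range(K):
                    w = logp[k] / s * conc[k, i]
                    den += w
                    num += w * means[k, i]
                    varnum += w * w * sds2[k, i]
                mean = num / den
                var = varnum / (den * den) + sig2[i]
                ll += (
                    -0.5 * nb[b, i] * np.log(2 * np.pi * var)
                    - (sy2[b, i] - 2 * mean * sy[b, i] + nb[b, i] * mean * mean)
                    / (2 * var)
                )
            out[b] = ll
        return out

    _LLB_KERNEL = _llb_kernel
except Exception:  # pragma: no cover - numba is optional
    _LLB_KERNEL = None


class _ModelData:
    """Pre-computed design and sufficient statistics for one fit."""

    def __init__(self, sections: pd.DataFrame, space: MixingSpace,
                 model: ModelSpec, iso_idx: np.ndarray):
        df = sections.reset_index(drop=True)
        self.obs_y = df[["d13C", "d15N"]].to_numpy(dtype=float)[:, iso_idx]
        self.iso_idx = iso_idx
        self.bear_ids = sorted(df["bear_id"].astype(str).unique())
        self.bear_index = (
            df["bear_id"].astype(str).map({b: i for i, b in enumerate(self.bear_ids)})
            .to_numpy()
        )
        self.B = len(self.bear_ids)
        self.n_obs = len(df)
        # per-bear, per-isotope sufficient statistics
        n_iso = len(iso_idx)
        self.nb = np.zeros((self.B, n_iso))
        self.sy = np.zeros((self.B, n_iso))
        self.sy2 = np.zeros((self.B, n_iso))
        for j in range(n_iso):
            y = self.obs_y[:, j]
            self.nb[:, j] = np.bincount(self.bear_index, minlength=self.B)
            self.sy[:, j] = np.bincount(self.bear_index, weights=y, minlength=self.B)
            self.sy2[:, j] = np.bincount(
                self.bear_index, weights=y**2, minlength=self.B
            )
        # fixed-effect design: one indicator column per non-reference level
        self.coef_labels: list[tuple[str, str]] = []
        cols = []
        per_bear = df.groupby("bear_id", sort=False).first()
        per_bear = per_bear.loc[[b for b in self.bear_ids]]
        for factor in model.fixed:
            levels = FACTOR_LEVELS[factor]
            vals = per_bear[factor].astype(str).to_numpy()
            bad = set(vals) - set(levels)
            if bad:
                raise ValueError(f"unexpected {factor} level(s): {sorted(bad)}")
            for level in levels[1:]:
                if np.any(vals == level):
                    self.coef_labels.append((factor, level))
                    cols.append((vals == level).astype(float))
        self.X = (
            np.column_stack(cols) if cols else np.zeros((self.B, 0))
        )  # (B, L)
        self.L = self.X.shape[1]
        self.space = space
        self.K = space.n_sources
        # contiguous views for the compiled likelihood kernel
        from .compositions import ilr_basis

        self._H = np.ascontiguousarray(ilr_basis(self.K))
        self._conc = np.ascontiguousarray(space.conc[:, iso_idx])
        self._means = np.ascontiguousarray(space.means[:, iso_idx])
        self._sds2 = np.ascontiguousarray(space.sds[:, iso_idx] ** 2)

    def z_to_moments(self, z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        p = ilr_inv(z)
        mean, pvar = mixture_moments(p, self.space)
        return mean[:, self.iso_idx], pvar[:, self.iso_idx]

    def loglik_bear(self, z: np.ndarray, sigma_res: np.ndarray) -> np.ndarray:
        """Per-bear log-likelihood vector given bear ILR coordinates (B, K-1)."""
        if _LLB_KERNEL is not None:
            return _LLB_KERNEL(
                np.ascontiguousarray(z), self._H, self._conc, self._means,
                self._sds2, self.nb, self.sy, self.sy2,
                np.asarray(sigma_res, dtype=float) ** 2,
            )
        mean, pvar = self.z_to_moments(z)
        var = pvar + sigma_res**2
        return np.sum(
            -0.5 * self.nb * np.log(2 * np.pi * var)
            - (self.sy2 - 2 * mean * self.sy + self.nb * mean**2) / (2 * var),
            axis=1,
        )

    def loglik_pointwise(self, z: np.ndarray, sigma_res: np.ndarray) -> np.ndarray:
        """Per-observation log-likelihood (n_obs,)."""
        mean, pvar = self.z_to_moments(z)
        var = (pvar + sigma_res**2)[self.bear_index]
        resid = self.obs_y - mean[self.bear_index]
        return np.sum(-0.5 * np.log(2 * np.pi * var) - resid**2 / (2 * var), axis=1)


@dataclass
class PosteriorResult:
    """MCMC draws and metadata from one SIMM fit.

    Draw arrays keep the chain axis first: mu (C, S, K-1), beta (C, S, L, K-1),
    u (C, S, B, K-1) or None, sigma_res (C, S, n_iso), sigma_u (C, S) or None.
    ``pointwise_loglik`` is (C*S, n_obs), chains concatenated in order.
    """

    model: ModelSpec
    source_names: tuple[str, ...]
    coef_labels: list
    bear_ids: list
    bear_index: np.ndarray
    mu: np.ndarray
    beta: np.ndarray
    u: Optional[np.ndarray]
    sigma_res: np.ndarray
    sigma_u: Optional[np.ndarray]
    pointwise_loglik: np.ndarray
    convergence: ConvergenceReport
    settings: MCMCSettings
    seed: int
    isotopes: tuple[str, ...]
    bear_X: np.ndarray
    n_dropped: int = 0

    @property
    def n_draws(self) -> int:
        return self.mu.shape[0] * self.mu.shape[1]

    def _flat(self, a: np.ndarray) -> np.ndarray:
        return a.reshape((a.shape[0] * a.shape[1],) + a.shape[2:])

    def p_population(self) -> np.ndarray:
        """Baseline (reference-level) diet composition draws, (n_draws, K)."""
        if len(self.source_names) == 1:
            return np.ones((self.n_draws, 1))
        return ilr_inv(self._flat(self.mu))

    def p_level(self, factor: str, level: str) -> np.ndarray:
        """Diet composition draws for one covariate level, others at reference."""
        z = self._flat(self.mu).copy()
        if (factor, level) in self.coef_labels:
            j = self.coef_labels.index((factor, level))
            z = z + self._flat(self.beta)[:, j, :]
        elif level not in FACTOR_LEVELS[factor]:
            raise KeyError(f"unknown level {level!r} for factor {factor!r}")
        return ilr_inv(z)

    def p_bear(self, bear_id: str) -> np.ndarray:
        """Diet composition draws for one bear (its covariates + random effect)."""
        b = self.bear_ids.index(bear_id)
        beta = self._flat(self.beta)  # (S, L, K-1)
        z = self._flat(self.mu)
        if beta.shape[1]:
            z = z + np.einsum("l,slk->sk", self.bear_X[b], beta)
        if self.u is not None:
            z = z + self._flat(self.u)[:, b, :]
        return ilr_inv(z)


def _dirichlet_ilr_logprior(z: np.ndarray, alpha: np.ndarray) -> float:
    """log density (up to a constant) of the Dirichlet prior pushed to ILR
    coordinates; the change-of-variables Jacobian contributes sum(log p)."""
    p = ilr_inv(z)
    return float(np.sum(alpha * np.log(p)))


def fit_mcmc(
    sections: pd.DataFrame,
    space: MixingSpace,
    model: ModelSpec,
    prior: PriorSpec,
    settings: Optional[MCMCSettings] = None,
    seed: int = 0,
    isotopes: Sequence[str] = ISOTOPES,
) -> PosteriorResult:
    """Fit one covariate structure by adaptive Metropolis-within-Gibbs.

    ``sections`` needs columns bear_id, sex, status, d13C, d15N (already
    restricted to one season and polygon-screened). Bears of unknown sex are
    dropped from models with a Sex fixed effect. Non-convergence (R-hat or
    Geweke beyond thresholds) is reported in the result's convergence report,
    never raised.
    """
    settings = settings or MCMCSettings()
    if sections.empty:
        raise ValueError("empty section table")
    n_dropped = 0
    if "sex" in model.fixed:
        keep = sections["sex"].astype(str) != "unknown"
        n_dropped = int((~keep).sum())
        sections = sections.loc[keep]
        if sections.empty:
            raise ValueError("no sections left after dropping unknown-sex bears")

    iso_idx = np.array([ISOTOPES.index(i) for i in isotopes])
    if len(prior.alpha) != space.n_sources:
        raise ValueError("prior length != number of sources")
    if space.n_sources == 1:
        return _fit_single_source(sections, space, model, settings, seed, iso_idx)

    data = _ModelData(sections, space, model, iso_idx)
    if not np.all(np.isfinite(data.obs_y)):
        raise ValueError("non-finite isotope values in sections")
    has_re = "bear" in model.random
    K, B, L, n_iso = data.K, data.B, data.L, len(iso_idx)
    S = settings.kept_per_chain
    if S < 1:
        raise ValueError("settings keep no draws")

    fixed_sigma = None
    if settings.sigma_res_fixed is not None:
        fixed_sigma = np.asarray(settings.sigma_res_fixed, dtype=float)[:n_iso]

    chain_seeds = np.random.SeedSequence(seed).spawn(settings.chains)
    keep = {
        "mu": np.empty((settings.chains, S, K - 1)),
        "beta": np.empty((settings.chains, S, L, K - 1)),
        "u": np.empty((settings.chains, S, B, K - 1)) if has_re else None,
        "sigma_res": np.empty((settings.chains, S, n_iso)),
        "sigma_u": np.empty((settings.chains, S)) if has_re else None,
        "loglik": np.empty((settings.chains, S, data.n_obs)),
    }

    for c, ss in enumerate(chain_seeds):
        rng = np.random.default_rng(ss)
        _run_chain(rng, data, prior, settings, has_re, fixed_sigma, keep, c)

    # convergence on scalar summaries of every sampled parameter
    monitored = {}
    for j in range(K - 1):
        monitored[f"mu[{j}]"] = keep["mu"][:, :, j]
    for l, (factor, level) in enumerate(data.coef_labels):
        for j in range(K - 1):
            monitored[f"beta_{factor}[{level}][{j}]"] = keep["beta"][:, :, l, j]
    if fixed_sigma is None:
        for j, iso in enumerate(isotopes):
            monitored[f"sigma_res[{iso}]"] = keep["sigma_res"][:, :, j]
    if has_re:
        monitored["sigma_u"] = keep["sigma_u"]
    report = convergence_report(
        monitored,
        rhat_threshold=settings.rhat_threshold,
        geweke_threshold=settings.geweke_threshold,
    )

    return PosteriorResult(
        model=model,
        source_names=space.names,
        coef_labels=data.coef_labels,
        bear_ids=data.bear_ids,
        bear_index=data.bear_index,
        mu=keep["mu"],
        beta=keep["beta"],
        u=keep["u"],
        sigma_res=keep["sigma_res"],
        sigma_u=keep["sigma_u"],
        pointwise_loglik=keep["loglik"].reshape(-1, data.n_obs),
        convergence=report,
        settings=settings,
        seed=seed,
        isotopes=tuple(isotopes),
        bear_X=data.X,
        n_dropped=n_dropped,
    )


class _VectorBlock:
    """Random-walk proposal for one coefficient vector with adaptive scale and
    empirical-covariance shape (adapted during burn-in only)."""

    def __init__(self, d: int, scale: float = 0.15):
        self.d = d
        self.scale = scale
        self.chol = np.eye(d)
        self._n = 0
        self._mean = np.zeros(d)
        self._m2 = np.zeros((d, d))

    def propose(self, rng, x):
        return x + self.scale * (self.chol @ rng.standard_normal(self.d))

    def observe(self, x):
        self._n += 1
        delta = x - self._mean
        self._mean += delta / self._n
        self._m2 += np.outer(delta, x - self._mean)

    def refresh(self):
        if self._n > 10 * self.d:
            cov = self._m2 / (self._n - 1)
            try:
                self.chol = np.linalg.cholesky(
                    cov + 1e-6 * np.trace(cov) / self.d * np.eye(self.d)
                )
            except np.linalg.LinAlgError:
                pass


def _run_chain(rng, data: _ModelData, prior: PriorSpec, settings: MCMCSettings,
               has_re: bool, fixed_sigma, keep: dict, c: int) -> None:
    K, B, L = data.K, data.B, data.L
    n_iso = len(data.iso_idx)
    d = K - 1
    sd_beta = settings.beta_prior_sd

    # overdispersed start around the prior-mean composition
    mu = ilr(prior.alpha / prior.alpha.sum()) + rng.normal(0, 0.5, d)
    beta = np.zeros((L, d))
    u = np.zeros((B, d))
    log_su = np.log(0.3)
    sigma = fixed_sigma.copy() if fixed_sigma is not None else np.full(n_iso, 1.0)
    log_sig = np.log(sigma)

    def bear_z():
        z = mu + data.X @ beta
        return z + u if has_re else z

    llb = data.loglik_bear(bear_z(), sigma)

    vec_blocks = {"mu": _VectorBlock(d)}
    for l in range(L):
        vec_blocks[f"beta{l}"] = _VectorBlock(d)
    blocks = list(vec_blocks)
    if has_re:
        blocks += ["u", "log_su", "rescale_su"]
        # recentering moves shift a coefficient and counter-shift the random
        # effects it acts on; the likelihood is invariant, so these mix the
        # otherwise strongly anti-correlated (coefficient, u) pairs
        blocks += [f"rc_{b}" for b in vec_blocks]
    if fixed_sigma is None:
        blocks += ["log_sig"]
    scales = {b: (0.3 if b.startswith("log") else 0.15) for b in blocks}
    scales["u"] = 0.25
    acc = {b: 0 for b in blocks}
    tries = {b: 0 for b in blocks}

    S = settings.kept_per_chain
    kept = 0
    for it in range(settings.iterations):
        adapting = it < settings.burn_in
        # --- mu block
        prop = vec_blocks["mu"].propose(rng, mu)
        z_prop = prop + data.X @ beta + (u if has_re else 0.0)
        llb_prop = data.loglik_bear(z_prop, sigma)
        delta = (
            llb_prop.sum() - llb.sum()
            + _dirichlet_ilr_logprior(prop, prior.alpha)
            - _dirichlet_ilr_logprior(mu, prior.alpha)
        )
        tries["mu"] += 1
        if np.log(rng.random()) < delta:
            mu, llb = prop, llb_prop
            acc["mu"] += 1

        # --- fixed-effect coefficient blocks
        for l in range(L):
            prop_row = vec_blocks[f"beta{l}"].propose(rng, beta[l])
            beta_prop = beta.copy()
            beta_prop[l] = prop_row
            z_prop = mu + data.X @ beta_prop + (u if has_re else 0.0)
            llb_prop = data.loglik_bear(z_prop, sigma)
            delta = (
                llb_prop.sum() - llb.sum()
                + (beta[l] ** 2 - prop_row**2).sum() / (2 * sd_beta**2)
            )
            tries[f"beta{l}"] += 1
            if np.log(rng.random()) < delta:
                beta, llb = beta_prop, llb_prop
                acc[f"beta{l}"] += 1

        if has_re:
            # --- vectorised per-bear random-effect block
            su = np.exp(log_su)
            u_prop = u + rng.normal(0, scales["u"], (B, d))
            z_prop = mu + data.X @ beta + u_prop
            llb_prop = data.loglik_bear(z_prop, sigma)
            dprior = ((u**2).sum(axis=1) - (u_prop**2).sum(axis=1)) / (2 * su**2)
            accept = np.log(rng.random(B)) < (llb_prop - llb + dprior)
            u[accept] = u_prop[accept]
            llb = np.where(accept, llb_prop, llb)
            tries["u"] += 1
            acc["u"] += accept.mean()

            # --- random-effect SD (prior-only update)
            prop_ls = log_su + rng.normal(0, scales["log_su"])
            s0, s1 = np.exp(log_su), np.exp(prop_ls)
            ssq = (u**2).sum()
            lp0 = -ssq / (2 * s0**2) - B * d * np.log(s0) \
                - s0**2 / (2 * settings.sigma_u_prior_scale**2) + np.log(s0)
            lp1 = -ssq / (2 * s1**2) - B * d * np.log(s1) \
                - s1**2 / (2 * settings.sigma_u_prior_scale**2) + np.log(s1)
            tries["log_su"] += 1
            if np.log(rng.random()) < lp1 - lp0:
                log_su = prop_ls
                acc["log_su"] += 1

            # --- interweaving rescale: log_su' = log_su + eps, u' = u e^eps.
            # The u-prior ratio cancels against the transform Jacobian, so the
            # acceptance involves only the likelihood, the half-normal prior on
            # sigma_u and its log-scale Jacobian; this move crosses the
            # (sigma_u, u) funnel that plain conditional updates cannot.
            eps = rng.normal(0, scales["rescale_su"])
            s0, s1 = np.exp(log_su), np.exp(log_su + eps)
            u_prop = u * np.exp(eps)
            z_prop = mu + data.X @ beta + u_prop
            llb_prop = data.loglik_bear(z_prop, sigma)
            sc_u = settings.sigma_u_prior_scale
            delta = (
                llb_prop.sum() - llb.sum()
                + (s0**2 - s1**2) / (2 * sc_u**2)
                + eps
            )
            tries["rescale_su"] += 1
            if np.log(rng.random()) < delta:
                log_su, u, llb = log_su + eps, u_prop, llb_prop
                acc["rescale_su"] += 1

            # --- recentering: mu' = mu + step, u' = u - step (all bears)
            su2 = np.exp(2 * log_su)
            step = rng.normal(0, scales["rc_mu"], d)
            u_prop = u - step
            mu_prop = mu + step
            delta = (
                _dirichlet_ilr_logprior(mu_prop, prior.alpha)
                - _dirichlet_ilr_logprior(mu, prior.alpha)
                + ((u**2).sum() - (u_prop**2).sum()) / (2 * su2)
            )
            tries["rc_mu"] += 1
            if np.log(rng.random()) < delta:
                mu, u = mu_prop, u_prop
                acc["rc_mu"] += 1

            # --- recentering per coefficient: beta_l' = beta_l + step,
            #     u' = u - step for the bears that carry the coefficient
            for l in range(L):
                mask = data.X[:, l] == 1.0
                step = rng.normal(0, scales[f"rc_beta{l}"], d)
                prop_row = beta[l] + step
                u_sub = u[mask]
                u_sub_prop = u_sub - step
                delta = (
                    (beta[l] ** 2 - prop_row**2).sum() / (2 * sd_beta**2)
                    + ((u_sub**2).sum() - (u_sub_prop**2).sum()) / (2 * su2)
                )
                tries[f"rc_beta{l}"] += 1
                if np.log(rng.random()) < delta:
                    beta = beta.copy()
                    beta[l] = prop_row
                    u = u.copy()
                    u[mask] = u_sub_prop
                    acc[f"rc_beta{l}"] += 1

        if fixed_sigma is None:
            # --- residual SDs, joint log-scale block
            prop_ls = log_sig + rng.normal(0, scales["log_sig"], n_iso)
            sig_prop = np.exp(prop_ls)
            llb_prop = data.loglik_bear(bear_z(), sig_prop)
            sc = settings.sigma_res_prior_scale
            delta = (
                llb_prop.sum() - llb.sum()
                + np.sum(-sig_prop**2 / (2 * sc**2) + prop_ls)
                - np.sum(-sigma**2 / (2 * sc**2) + log_sig)
            )
            tries["log_sig"] += 1
            if np.log(rng.random()) < delta:
                log_sig, sigma, llb = prop_ls, sig_prop, llb_prop
                acc["log_sig"] += 1

        # --- proposal adaptation, burn-in only
        if adapting:
            vec_blocks["mu"].observe(mu)
            for l in range(L):
                vec_blocks[f"beta{l}"].observe(beta[l])
            if (it + 1) % settings.adapt_window == 0:
                for b in blocks:
                    if tries[b]:
                        rate = acc[b] / tries[b]
                        scales[b] = float(
                            np.clip(
                                scales[b]
                                * np.exp(1.2 * (rate - settings.target_accept)),
                                1e-3,
                                10.0,
                            )
                        )
                        if b in vec_blocks:
                            vec_blocks[b].scale = scales[b]
                    acc[b] = 0
                    tries[b] = 0
                for vb in vec_blocks.values():
                    vb.refresh()

        if it >= settings.burn_in and (it - settings.burn_in) % settings.thin == 0:
            if kept < S:
                keep["mu"][c, kept] = mu
                keep["beta"][c, kept] = beta
                if has_re:
                    keep["u"][c, kept] = u
                    keep["sigma_u"][c, kept] = np.exp(log_su)
                keep["sigma_res"][c, kept] = sigma
                keep["loglik"][c, kept] = data.loglik_pointwise(bear_z(), sigma)
                kept += 1


def _fit_single_source(sections, space, model, settings, seed, iso_idx):
    """Degenerate one-source model: the diet is the whole simplex point."""
    n_obs = len(sections)
    S = settings.kept_per_chain
    obs = sections[["d13C", "d15N"]].to_numpy(dtype=float)[:, iso_idx]
    mean, pvar = mixture_moments(np.ones(1), space)
    sigma = (
        np.asarray(settings.sigma_res_fixed, dtype=float)[: len(iso_idx)]
        if settings.sigma_res_fixed is not None
        else np.zeros(len(iso_idx))
    )
    var = pvar[iso_idx] + sigma**2
    ll = np.sum(
        -0.5 * np.log(2 * np.pi * var) - (obs - mean[iso_idx]) ** 2 / (2 * var),
        axis=1,
    )
    C = settings.chains
    bear_ids = sorted(sections["bear_id"].astype(str).unique())
    report = convergence_report({}, settings.rhat_threshold, settings.geweke_threshold)
    return PosteriorResult(
        model=model,
        source_names=space.names,
        coef_labels=[],
        bear_ids=bear_ids,
        bear_index=np.zeros(n_obs, dtype=int),
        mu=np.zeros((C, S, 0)),
        beta=np.zeros((C, S, 0, 0)),
        u=None,
        sigma_res=np.tile(sigma, (C, S, 1)),
        sigma_u=None,
        pointwise_loglik=np.tile(ll, (C * S, 1)),
        convergence=report,
        settings=settings,
        seed=seed,
        isotopes=tuple(np.array(ISOTOPES)[iso_idx]),
        bear_X=np.zeros((len(bear_ids), 0)),
    )


def summarize_posterior(
    result: PosteriorResult,
    level: str = "population",
    min_draws: int = 100,
) -> pd.DataFrame:
    """Posterior mean, SD and 95% credible interval per source.

    ``level`` is "population" (baseline composition), "bears" (one block per
    bear), or "factor:levelname" (e.g. "sex:M").
    """
    if result.n_draws < min_draws:
        raise ValueError(f"need >= {min_draws} draws, have {result.n_draws}")
    blocks: list[tuple[str, np.ndarray]] = []
    if level == "population":
        blocks.append(("population", result.p_population()))
    elif level == "bears":
        for b in result.bear_ids:
            blocks.append((b, result.p_bear(b)))
    elif ":" in level:
        factor, lev = level.split(":", 1)
        blocks.append((level, result.p_level(factor, lev)))
    else:
        raise ValueError(f"unknown summary level {level!r}")
    rows = []
    for name, draws in blocks:
        q = np.quantile(draws, [0.025, 0.975], axis=0)
        for k, source in enumerate(result.source_names):
            rows.append(
                {
                    "level": name,
                    "source": source,
                    "mean": float(draws[:, k].mean()),
                    "sd": float(draws[:, k].std(ddof=0)),
                    "q2.5": float(q[0, k]),
                    "q97.5": float(q[1, k]),
                }
            )
    return pd.DataFrame(rows)
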