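"""Model comparison: PSIS-LOO, pairwise differences and Akaike weights.

Each fitted covariate structure keeps its pointwise log-likelihood matrix, so
leave-one-out expected log predictive density (elpd) can be estimated by
Pareto-smoothed importance sampling (PSIS) without refitting. Models fitted
to the same observations are compared on the LOO information criterion
(LOOic = -2 * elpd); relative support is summarised by Akaike weights
w_i = exp(-Delta_i / 2) / sum_j exp(-Delta_j / 2), and the selected set is
every model with the lowest LOOic tier and weight > 0.2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

__all__ = ["LooResult", "psis_loo", "akaike_weights", "compare_models"]

PARETO_K_WARN = 0.7
SELECTION_WEIGHT = 0.2


@dataclass
class LooResult:
    """PSIS-LOO estimate for one model."""

    elpd_i: np.ndarray  # pointwise elpd, (n_obs,)
    looic: float
    se_looic: float
    pareto_k: np.ndarray
    n_fallback: int = 0  # observations where PSIS fell back to truncated IS

    @property
    def n_obs(self) -> int:
        return len(self.elpd_i)

    @property
    def n_high_k(self) -> int:
        return int(np.sum(self.pareto_k > PARETO_K_WARN))


def _truncated_is_logweights(neg_ll: np.ndarray) -> np.ndarray:
    """Truncated importance sampling fallback: raw log weights truncated at
    log(mean weight) + 0.5 log S, then normalised."""
    s = neg_ll.shape[0]
    lw = neg_ll - logsumexp(neg_ll, axis=0)
    cap = -np.log(s) + 0.5 * np.log(s)
    lw = np.minimum(lw, cap)
    return lw - logsumexp(lw, axis=0)


def psis_loo(pointwise_loglik: np.ndarray) -> LooResult:
    """PSIS-LOO from a (draws, observations) pointwise log-likelihood matrix.

    Importance ratios for leaving observation i out are 1/p(y_i | theta_s);
    their upper tail is stabilised by a generalized-Pareto fit (PSIS). The
    criterion is looic = -2 * sum_i elpd_i with
    se = 2 * sqrt(n * var(elpd_i)). Observations whose Pareto shape k
    exceeds 0.7 are counted in ``n_high_k``; non-finite smoothed weights fall
    back to truncated importance sampling with a warning.
    """
    ll = np.asarray(pointwise_loglik, dtype=float)
    if ll.ndim != 2:
        raise ValueError("pointwise log-likelihood must be (draws, observations)")
    s, n = ll.shape
    if s < 100:
        raise ValueError(f"need >= 100 draws, have {s}")
    if n < 2:
        raise ValueError(f"need >= 2 observations, have {n}")
    if not np.all(np.isfinite(ll)):
        raise ValueError("non-finite pointwise log-likelihoods")

    if np.allclose(ll, ll[0], atol=1e-12):
        # zero posterior uncertainty: importance weights are uniform and
        # elpd_i reduces to the log-likelihood itself
        elpd_i = ll[0]
        pareto_k = np.full(n, -np.inf)
        n_fallback = 0
    else:
        from arviz.stats import psislw

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            # psislw expects the sample dimension last: (n_obs, draws)
            lw, pareto_k = psislw(-ll.T)
        lw = np.asarray(lw)
        pareto_k = np.asarray(pareto_k)
        bad = ~np.all(np.isfinite(lw), axis=1)
        n_fallback = int(bad.sum())
        if n_fallback:
            warnings.warn(
                f"PSIS failed for {n_fallback} observation(s); "
                "falling back to truncated importance sampling"
            )
            lw[bad] = _truncated_is_logweights(-ll[:, bad]).T
        elpd_i = logsumexp(ll.T + lw, axis=1)

    looic = -2.0 * float(elpd_i.sum())
    se = 2.0 * float(np.sqrt(n * np.var(elpd_i, ddof=1)))
    return LooResult(
        elpd_i=elpd_i, looic=looic, se_looic=se,
        pareto_k=pareto_k, n_fallback=n_fallback,
    )


def akaike_weights(looic: Sequence[float]) -> np.ndarray:
    """Akaike weights over a model set from LOOic values (max-subtraction for
    numerical stability; invariant to adding a constant to every value)."""
    looic = np.asarray(looic, dtype=float)
    if looic.size < 1 or not np.all(np.isfinite(looic)):
        raise ValueError("need at least one finite LOOic value")
    half_delta = (looic - looic.min()) / 2.0
    w = np.exp(-half_delta)
    return w / w.sum()


def compare_models(
    models: Sequence[tuple[str, LooResult]],
) -> pd.DataFrame:
    """Comparison table across covariate structures fitted to identical data.

    Columns: model, looic, se_looic, delta_looic, se_delta, weight, selected.
    delta is taken against the lowest LOOic (ties broken by label order,
    reported deterministically); se_delta comes from the paired pointwise
    elpd differences, so it can be far smaller than either model's se_looic
    for near-identical models. Rows sort ascending by looic, then label.
    """
    if len(models) < 2:
        raise ValueError("need at least two models to compare")
    n_obs = {len(r.elpd_i) for _, r in models}
    if len(n_obs) != 1:
        raise ValueError("models were fitted to different observation sets")
    n = n_obs.pop()

    order = sorted(range(len(models)), key=lambda i: (models[i][1].looic, models[i][0]))
    best_label, best = models[order[0]]
    weights = akaike_weights([r.looic for _, r in models])
    rows = []
    for rank, i in enumerate(order):
        label, res = models[i]
        diff = res.elpd_i - best.elpd_i
        se_delta = 0.0 if i == order[0] else 2.0 * float(
            np.sqrt(n * np.var(diff, ddof=1))
        )
        rows.append(
            {
                "model": label,
                "looic": res.looic,
                "se_looic": res.se_looic,
                "delta_looic": res.looic - best.looic,
                "se_delta": se_delta,
                "weight": float(weights[i]),
            }
        )
    df = pd.DataFrame(rows)
    df["selected"] = df["weight"] > SELECTION_WEIGHT
    return df
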