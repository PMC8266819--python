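"""MCMC convergence diagnostics: Gelman-Rubin R-hat and Geweke z-scores."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["gelman_rubin", "geweke", "ConvergenceReport", "convergence_report"]


def gelman_rubin(chains: np.ndarray) -> float:
    """Classic potential scale reduction factor.

    ``chains`` is (m, n): m >= 2 chains of equal length n. Returns
    sqrt(((n-1)/n * W + B/n) / W) with W the mean within-chain variance and
    B/n the between-chain variance of chain means. Degenerate chains (W = 0)
    report 1 with a warning.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("need a (m>=2, n) array of chains")
    m, n = chains.shape
    w = chains.var(axis=1, ddof=1).mean()
    if w == 0:
        warnings.warn("degenerate chains (zero within-chain variance)")
        return 1.0
    b_over_n = chains.mean(axis=1).var(ddof=1)
    var_hat = (n - 1) / n * w + b_over_n
    return float(np.sqrt(var_hat / w))


def _spectral_density_zero(x: np.ndarray) -> float:
    """Spectral density of a (weakly stationary) series at frequency zero,
    via Bartlett-windowed autocovariances; equals the long-run variance."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    xc = x - x.mean()
    g0 = float(xc @ xc) / n
    if g0 == 0:
        return 0.0
    lmax = max(1, int(round(n ** (1 / 3))))  # bias/variance compromise
    s = g0
    for k in range(1, lmax + 1):
        gk = float(xc[:-k] @ xc[k:]) / n
        s += 2 * (1 - k / (lmax + 1)) * gk
    return max(s, 1e-12 * g0)


def geweke(chain: np.ndarray, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke convergence z-score for one chain.

    Compares the mean of the first ``first`` fraction against the last
    ``last`` fraction, with variances of the segment means estimated from the
    spectral density at zero (so autocorrelation is accounted for).
    """
    chain = np.asarray(chain, dtype=float)
    n = len(chain)
    if n < 20:
        raise ValueError("chain too short for the Geweke diagnostic")
    if not (0 < first < 1 and 0 < last < 1 and first + last <= 1):
        raise ValueError("invalid window fractions")
    a = chain[: int(first * n)]
    b = chain[n - int(last * n):]
    var = _spectral_density_zero(a) / len(a) + _spectral_density_zero(b) / len(b)
    if var == 0:
        return 0.0
    return float((a.mean() - b.mean()) / np.sqrt(var))


@dataclass
class ConvergenceReport:
    """Per-parameter R-hat and per-chain Geweke z, with pass flags."""

    rhat: dict = field(default_factory=dict)
    geweke_z: dict = field(default_factory=dict)  # name -> array over chains
    rhat_threshold: float = 1.05
    geweke_threshold: float = 2.0

    @property
    def passed(self) -> bool:
        ok_r = all(r < self.rhat_threshold for r in self.rhat.values())
        ok_g = all(
            np.all(np.abs(z) < self.geweke_threshold)
            for z in self.geweke_z.values()
        )
        return ok_r and ok_g

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, r in self.rhat.items():
            z = np.asarray(self.geweke_z.get(name, []))
            rows.append(
                {
                    "parameter": name,
                    "rhat": r,
                    "max_abs_geweke_z": float(np.abs(z).max()) if z.size else np.nan,
                    "pass": r < self.rhat_threshold
                    and (not z.size or np.all(np.abs(z) < self.geweke_threshold)),
                }
            )
        return pd.DataFrame(rows, columns=["parameter", "rhat", "max_abs_geweke_z", "pass"])


def convergence_report(
    monitored: dict,
    rhat_threshold: float = 1.05,
    geweke_threshold: float = 2.0,
) -> ConvergenceReport:
    """Build a report from {name: (chains, draws) array} of monitored scalars."""
    report = ConvergenceReport(
        rhat_threshold=rhat_threshold, geweke_threshold=geweke_threshold
    )
    for name, arr in monitored.items():
        arr = np.asarray(arr, dtype=float)
        if arr.shape[0] >= 2:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                report.rhat[name] = gelman_rubin(arr)
        else:
            report.rhat[name] = 1.0
        if arr.shape[1] >= 20:
            report.geweke_z[name] = np.array([geweke(c) for c in arr])
    return report
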