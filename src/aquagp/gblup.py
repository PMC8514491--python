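"""Single-kernel linear mixed model: REML, heritability, BLUP prediction.

The model is ``y = mu + Z a + e`` with ``a ~ N(0, K sigma_a^2)`` for a
genomic (GBLUP) or pedigree (PBLUP) kernel K and ``e ~ N(0, I
sigma_e^2)``; the only fixed effect is the intercept.  The restricted
likelihood is profiled over the variance ratio ``delta = sigma_e^2 /
sigma_a^2`` after one eigendecomposition of the kernel restricted to the
recorded individuals (the "spectral trick"), so each candidate delta
costs O(n): a 61-point grid on log delta in [-10, 10] is refined by
bounded scalar minimisation.  Narrow-sense heritability is
``h2 = sigma_a^2 / (sigma_a^2 + sigma_e^2)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .core import ConfigurationError
from .relatedness import RelationshipMatrix

logger = logging.getLogger(__name__)

__all__ = ["MixedModelFit", "reml_fit", "heritability", "predict_masked"]

_LOG_DELTA_BOUNDS = (-10.0, 10.0)
_GRID_POINTS = 61


@dataclass
class MixedModelFit:
    """REML solution and BLUP breeding values for one trait/kernel."""

    kernel_kind: str
    mu_hat: float
    sigma_a2: float
    sigma_e2: float
    delta: float
    h2: float
    loglik: float
    breeding_values: pd.Series  # (G)EBV for every individual in the kernel
    trained_ids: list[str]
    at_boundary: bool = False


def _restricted_loglik(
    log_delta: float, lam: np.ndarray, ys: np.ndarray, xs: np.ndarray
) -> tuple[float, float, float]:
    """Profiled restricted log-likelihood at one variance ratio.

    Returns (loglik, mu_hat, sigma_a2) for delta = exp(log_delta), with
    lam the kernel eigenvalues and ys/xs the rotated response/intercept.
    """
    n = lam.size
    v = lam + np.exp(log_delta)
    vinv = 1.0 / v
    xvx = float(np.sum(xs * xs * vinv))
    mu = float(np.sum(xs * ys * vinv) / xvx)
    r = ys - mu * xs
    rss = float(np.sum(r * r * vinv))
    sigma_a2 = rss / (n - 1)
    ll = -0.5 * (
        (n - 1) * np.log(sigma_a2)
        + float(np.sum(np.log(v)))
        + np.log(xvx)
        + (n - 1)
    )
    return ll, mu, sigma_a2


def _prepare_kernel(K: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecompose; repair tiny negative eigenvalues, reject larger ones."""
    lam, U = np.linalg.eigh((K + K.T) / 2.0)
    lmin = lam.min()
    if lmin < -1e-4:
        raise ValueError(
            f"kernel is not positive semi-definite (min eigenvalue {lmin:.3e})"
        )
    if lmin < 1e-8:
        eps = 1e-8 - lmin
        logger.info("repairing kernel: adding %.3e to the diagonal", eps)
        lam = lam + eps
    return lam, U


def reml_fit(
    y: Mapping[str, float] | pd.Series,
    kernel: RelationshipMatrix,
    min_records: int = 10,
) -> MixedModelFit:
    """Fit the intercept-only mixed model by restricted maximum likelihood.

    ``y`` maps recorded individual ids (a subset of the kernel ids) to
    phenotype values.  Breeding values are returned for *all* kernel
    individuals via ``a_hat = K[:, obs] (K_oo + delta I)^-1 (y - mu)``.
    """
    y = pd.Series(dict(y), dtype=float) if not isinstance(y, pd.Series) else y.dropna()
    y = y.dropna()
    obs_ids = [s for s in kernel.ids if s in y.index]
    if len(obs_ids) < min_records:
        raise ValueError(
            f"need at least {min_records} recorded individuals, got {len(obs_ids)}"
        )
    yv = y.loc[obs_ids].to_numpy()
    if yv.std() == 0.0:
        raise ValueError("zero phenotypic variance")

    pos = {s: i for i, s in enumerate(kernel.ids)}
    oidx = np.array([pos[s] for s in obs_ids])
    Koo = kernel.values[np.ix_(oidx, oidx)]
    lam, U = _prepare_kernel(Koo)
    ys = U.T @ yv
    xs = U.T @ np.ones(len(obs_ids))

    grid = np.linspace(*_LOG_DELTA_BOUNDS, _GRID_POINTS)
    lls = np.array([_restricted_loglik(g, lam, ys, xs)[0] for g in grid])
    if not np.all(np.isfinite(lls)):
        raise ValueError("non-finite restricted likelihood encountered")
    best = int(np.argmax(lls))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, _GRID_POINTS - 1)]
    res = minimize_scalar(
        lambda g: -_restricted_loglik(g, lam, ys, xs)[0],
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-8},
    )
    log_delta = float(res.x)
    ll, mu, sigma_a2 = _restricted_loglik(log_delta, lam, ys, xs)
    delta = float(np.exp(log_delta))
    sigma_e2 = delta * sigma_a2
    h2 = sigma_a2 / (sigma_a2 + sigma_e2)
    at_boundary = best in (0, _GRID_POINTS - 1)
    if at_boundary:
        logger.info("variance ratio at search boundary (log delta %.1f)", log_delta)

    # BLUP for all kernel individuals
    alpha = U @ ((ys - mu * xs) / (lam + delta))
    a_hat = kernel.values[:, oidx] @ alpha
    return MixedModelFit(
        kernel_kind=kernel.kind,
        mu_hat=mu,
        sigma_a2=sigma_a2,
        sigma_e2=sigma_e2,
        delta=delta,
        h2=float(h2),
        loglik=float(ll),
        breeding_values=pd.Series(a_hat, index=kernel.ids),
        trained_ids=obs_ids,
        at_boundary=at_boundary,
    )


def heritability(fit: MixedModelFit) -> float:
    """Narrow-sense heritability sigma_a^2 / (sigma_a^2 + sigma_e^2)."""
    total = fit.sigma_a2 + fit.sigma_e2
    if total == 0.0:
        raise ConfigurationError("both variance components are zero")
    return fit.sigma_a2 / total


def predict_masked(
    y: Mapping[str, float] | pd.Series,
    kernel: RelationshipMatrix,
    masked_ids: Iterable[str],
) -> pd.Series:
    """(G)EBV for masked individuals from a model trained without them.

    Variance components are re-estimated on the training records; the
    masked individuals' predictions come from the kernel cross-block.
    With an empty mask this returns the full-data breeding values.
    """
    y = pd.Series(dict(y), dtype=float) if not isinstance(y, pd.Series) else y.dropna()
    y = y.dropna()
    masked = set(masked_ids)
    unknown = masked - set(kernel.ids)
    if unknown:
        raise KeyError(f"masked ids not in kernel: {sorted(unknown)[:5]}")
    train = y.drop(index=[s for s in masked if s in y.index])
    if train.empty:
        raise ValueError("masking removed every recorded individual")
    fit = reml_fit(train, kernel)
    if not masked:
        return fit.breeding_values.loc[fit.trained_ids]
    return fit.breeding_values.loc[sorted(masked)]
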