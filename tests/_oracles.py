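"""Independent oracles used to validate the fast implementations.

The REML oracle maximises the restricted log-likelihood written in its
textbook matrix form (explicit inversion and determinants, no
eigendecomposition) over a heritability grid with bounded refinement;
it shares no code with the spectral path it checks.
"""

import numpy as np
from scipy.optimize import minimize_scalar


def brute_force_reml_h2(y: np.ndarray, K: np.ndarray) -> float:
    """REML heritability by direct matrix inversion on an h2 grid."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    X = np.ones((n, 1))
    I = np.eye(n)

    def neg2ll(h2: float) -> float:
        V = h2 * K + (1.0 - h2) * I
        Vi = np.linalg.inv(V)
        XVX = X.T @ Vi @ X
        beta = np.linalg.solve(XVX, X.T @ Vi @ y)
        r = y - X @ beta
        s2 = float(r.T @ Vi @ r) / (n - 1)
        _, logdet = np.linalg.slogdet(V)
        return (n - 1) * np.log(s2) + logdet + np.log(XVX[0, 0]) + (n - 1)

    grid = np.linspace(1e-4, 1 - 1e-4, 201)
    vals = [neg2ll(h) for h in grid]
    i = int(np.argmin(vals))
    res = minimize_scalar(
        neg2ll,
        bounds=(grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]),
        method="bounded",
        options={"xatol": 1e-9},
    )
    return float(res.x)


def modal_impute(dosages: np.ndarray, missing: int) -> np.ndarray:
    """Per-site most-frequent-dosage imputation (baseline)."""
    out = dosages.copy()
    for j in range(out.shape[1]):
        col = out[:, j]
        obs = col[col != missing]
        vals, counts = np.unique(obs, return_counts=True)
        col[col == missing] = vals[np.argmax(counts)]
    return out
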