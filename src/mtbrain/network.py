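"""Sparse partial-correlation networks: nonparanormal transform, graphical
LASSO with EBIC model selection, and bootstrap edge stability.

The network over p variables is the Gaussian graphical model whose precision
matrix Theta is estimated by the graphical lasso (L1-penalized Gaussian
log-likelihood) on the sample correlation matrix.  The penalty lambda is
chosen on a grid by the extended BIC,

    EBIC(lambda) = -2 l(Theta) + E log n + 4 gamma E log p,

with E the number of edges and gamma = 0.5 the conventional sparsity prior.
Edge weights are partial correlations -Theta_jk / sqrt(Theta_jj Theta_kk).
Count-valued or otherwise non-Gaussian variables are first passed through
the truncated-ECDF nonparanormal (Gaussian copula) transform.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.covariance import graphical_lasso as _sk_glasso

__all__ = [
    "NetworkResult",
    "nonparanormal",
    "glasso_ebic",
    "partial_correlations",
    "bootstrap_stability",
]

_EDGE_EPS = 1e-8  # |Theta_jk| above this counts as an edge


def nonparanormal(data: pd.DataFrame) -> pd.DataFrame:
    """Truncated-ECDF nonparanormal (Gaussian copula) transform, per column.

    Ranks (average ties) are mapped through the empirical CDF r/n, Winsorized
    into [delta_n, 1 - delta_n] with delta_n = 1 / (4 n^{1/4} sqrt(pi log n)),
    then through the standard normal quantile; each column is rescaled to
    unit SD.  Monotone in the input, hence invariant to any strictly
    increasing pre-transform of a column.
    """
    X = data.astype(float)
    n = len(X)
    if n < 2:
        raise ValueError("need at least 2 rows")
    delta = 1.0 / (4.0 * n**0.25 * np.sqrt(np.pi * np.log(n)))
    out = {}
    for c in X.columns:
        col = X[c].to_numpy()
        if np.unique(col).size < 2:
            raise ValueError(f"column {c!r} is constant; ranks undefined")
        u = stats.rankdata(col, method="average") / n
        z = stats.norm.ppf(np.clip(u, delta, 1.0 - delta))
        out[c] = z / z.std(ddof=1)
    return pd.DataFrame(out, index=X.index)


def partial_correlations(theta: np.ndarray) -> np.ndarray:
    """Partial-correlation matrix from a precision matrix (zero diagonal)."""
    d = np.sqrt(np.diag(theta))
    pc = -theta / np.outer(d, d)
    np.fill_diagonal(pc, 0.0)
    return pc


def restricted_mle(S: np.ndarray, adjacency: np.ndarray, maxiter: int = 200, tol: float = 1e-8) -> np.ndarray:
    """Gaussian MLE of the precision matrix under a fixed zero pattern.

    Classical covariance selection by cyclic modified regressions: for each
    variable, the implied covariance row is updated from a linear solve on the
    neighbor block only, iterated to a fixed point.  Used to score candidate
    supports with an unshrunken likelihood, which removes the lasso-shrinkage
    bias from EBIC comparisons across the penalty path.
    """
    p = S.shape[0]
    W = S.copy()
    eye = np.eye(p, dtype=bool)
    for _ in range(maxiter):
        W_old = W.copy()
        for j in range(p):
            nb = np.where(adjacency[j])[0]
            others = np.array([i for i in range(p) if i != j])
            if len(nb) == 0:
                W[others, j] = 0.0
                W[j, others] = 0.0
                continue
            beta_full = np.zeros(p)
            beta_full[nb] = np.linalg.solve(W[np.ix_(nb, nb)], S[nb, j])
            w = W[np.ix_(others, others)] @ beta_full[others]
            W[others, j] = w
            W[j, others] = w
        if np.abs(W - W_old).max() < tol:
            break
    theta = np.linalg.inv(W)
    theta[(~adjacency) & ~eye] = 0.0
    return (theta + theta.T) / 2.0


@dataclass
class NetworkResult:
    variables: tuple[str, ...]
    selected_lambda: float
    gamma: float
    precision: np.ndarray
    partial_corr: np.ndarray
    adjacency: np.ndarray          # boolean, zero diagonal
    ebic: float
    ebic_path: pd.DataFrame        # lambda, n_edges, loglik, ebic
    n: int

    def edges(self) -> list[tuple[str, str, float]]:
        out = []
        p = len(self.variables)
        for j in range(p):
            for k in range(j + 1, p):
                if self.adjacency[j, k]:
                    out.append((self.variables[j], self.variables[k], float(self.partial_corr[j, k])))
        return out


def _correlation(data: pd.DataFrame, ridge: float = 1e-4) -> np.ndarray:
    S = np.corrcoef(data.to_numpy(dtype=float), rowvar=False)
    S = (S + S.T) / 2.0
    if np.linalg.eigvalsh(S).min() < 1e-8:
        S = S + ridge * np.eye(S.shape[0])  # ridge jitter for a non-PD sample matrix
        d = np.sqrt(np.diag(S))
        S = S / np.outer(d, d)
    return S


def default_lambda_grid(S: np.ndarray, n_lambda: int = 30, min_ratio: float = 0.01) -> np.ndarray:
    lam_max = np.max(np.abs(S - np.diag(np.diag(S))))
    lam_max = max(lam_max, 1e-3)
    return np.logspace(np.log10(lam_max), np.log10(lam_max * min_ratio), n_lambda)


def glasso_ebic(
    data: pd.DataFrame,
    gamma: float = 0.5,
    lambdas: Sequence[float] | None = None,
    apply_nonparanormal: bool = False,
    refit: bool = True,
) -> NetworkResult:
    """Graphical lasso over a lambda grid with EBIC model selection.

    Works on the sample correlation matrix (variables are scale-free).  The
    Gaussian log-likelihood, up to constants, is
    l(Theta) = (n/2) (logdet Theta - tr(S Theta)).  With ``refit`` (default)
    each candidate support is scored by the likelihood of its unpenalized
    restricted MLE, so EBIC compares supports rather than shrinkage levels;
    the reported precision matrix is still the penalized glasso solution at
    the selected lambda.
    """
    n, p = data.shape
    if n <= p:
        import warnings

        warnings.warn(f"n = {n} <= p = {p}: network estimate will be unstable", stacklevel=2)
    X = nonparanormal(data) if apply_nonparanormal else data
    S = _correlation(X)
    grid = np.asarray(lambdas, dtype=float) if lambdas is not None else default_lambda_grid(S)

    rows = []
    best = None
    eye = np.eye(p, dtype=bool)
    for lam in grid:
        try:
            _, theta = _sk_glasso(S, alpha=float(lam), max_iter=1000)
        except FloatingPointError:
            continue
        adj = (np.abs(theta) > _EDGE_EPS) & ~eye
        n_edges = int(np.triu(adj, 1).sum())
        theta_score = restricted_mle(S, adj) if refit else theta
        sign, logdet = np.linalg.slogdet(theta_score)
        if sign <= 0:
            continue
        loglik = 0.5 * n * (logdet - np.trace(S @ theta_score))
        ebic = -2.0 * loglik + n_edges * np.log(n) + 4.0 * gamma * n_edges * np.log(p)
        rows.append({"lambda": float(lam), "n_edges": n_edges, "loglik": float(loglik), "ebic": float(ebic)})
        if best is None or ebic < best[0]:
            best = (ebic, float(lam), theta)
    if best is None:
        raise RuntimeError("graphical lasso failed on the entire lambda grid")
    ebic_val, lam_sel, theta = best
    pc = partial_correlations(theta)
    adj = (np.abs(theta) > _EDGE_EPS) & ~np.eye(p, dtype=bool)
    return NetworkResult(
        variables=tuple(map(str, data.columns)),
        selected_lambda=lam_sel,
        gamma=gamma,
        precision=theta,
        partial_corr=pc,
        adjacency=adj,
        ebic=float(ebic_val),
        ebic_path=pd.DataFrame(rows),
        n=n,
    )


def bootstrap_stability(
    data: pd.DataFrame,
    estimator: Callable[[pd.DataFrame], np.ndarray] | None = None,
    B: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Nonparametric case-resampling edge frequencies over ``B`` refits.

    ``estimator`` maps a data frame to a boolean adjacency matrix; the default
    is `glasso_ebic` with its defaults.  Returns a (p x p) frequency matrix in
    [0, 1] with the variables as row/column labels.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if estimator is None:
        estimator = lambda d: glasso_ebic(d).adjacency  # noqa: E731
    n, p = data.shape
    freq = np.zeros((p, p))
    n_ok = 0
    for _ in range(B):
        idx = rng.integers(0, n, n)
        boot = data.iloc[idx].reset_index(drop=True)
        try:
            adj = estimator(boot)
        except (ValueError, RuntimeError):
            continue  # degenerate resample (e.g. a constant column)
        freq += adj.astype(float)
        n_ok += 1
    if n_ok == 0:
        raise RuntimeError("every bootstrap refit failed")
    freq /= n_ok
    return pd.DataFrame(freq, index=data.columns, columns=data.columns)
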