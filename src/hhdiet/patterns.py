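"""Dietary-pattern derivation by principal component analysis.

PCA is run on the correlation matrix of the 18 food-group intakes, so the
loadings are the Pearson correlations between each food group and the
component score, and the per-household scores are standardized to unit
variance.  Component signs are fixed so the largest-|loading| entry of each
component is positive, which makes output deterministic across linear-algebra
backends.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .exceptions import ConfigError, DegenerateInputError

QUINTILE_LABELS = ("Q1", "Q2", "Q3", "Q4", "Q5")


@dataclass
class PatternModel:
    """Fitted dietary-pattern model."""

    loadings: pd.DataFrame          # p x K, variable-component correlations
    explained_variance: np.ndarray  # length K, fractions of total variance
    scores: pd.DataFrame            # n x K, standardized component scores
    eigenvalues: np.ndarray         # full length-p spectrum, descending
    retained_k: int

    @property
    def n_households(self) -> int:
        return len(self.scores)


def fit_patterns(group_intakes: pd.DataFrame, k: int | None = None) -> PatternModel:
    """Fit a correlation-matrix PCA of food-group intakes.

    Parameters
    ----------
    group_intakes : DataFrame
        n x p matrix (p = 18 in the standard configuration), one row per
        household, indexed by household id.
    k : int, optional
        Number of components to retain.  Defaults to the number of
        eigenvalues exceeding 1.

    Raises
    ------
    DegenerateInputError
        if a column is constant (its correlation is undefined).
    ConfigError
        if ``k`` exceeds the number of input variables.
    """
    X = group_intakes.to_numpy(dtype=float)
    n, p = X.shape
    if k is not None and k > p:
        raise ConfigError(f"requested {k} components from only {p} variables")
    sd = X.std(axis=0, ddof=1)
    constant = [str(c) for c, s in zip(group_intakes.columns, sd) if s == 0 or not np.isfinite(s)]
    if constant:
        raise DegenerateInputError(f"constant food-group column(s): {constant}")
    if n < 10 * p:
        warnings.warn(
            f"only {n} households for {p} variables; loadings may be unstable",
            stacklevel=2,
        )

    Z = (X - X.mean(axis=0)) / sd
    R = (Z.T @ Z) / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(R)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]

    if k is None:
        k = max(1, int((eigvals > 1.0).sum()))
    lam = eigvals[:k]
    V = eigvecs[:, :k]
    loadings = V * np.sqrt(lam)
    # deterministic sign: largest-|loading| entry of each component positive
    for j in range(k):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1.0
            V[:, j] *= -1.0
    scores = Z @ V / np.sqrt(lam)

    comp_names = [f"PC{j + 1}" for j in range(k)]
    return PatternModel(
        loadings=pd.DataFrame(loadings, index=group_intakes.columns, columns=comp_names),
        explained_variance=lam / p,
        scores=pd.DataFrame(scores, index=group_intakes.index, columns=comp_names),
        eigenvalues=eigvals,
        retained_k=k,
    )


def scree_report(model: PatternModel, retention_threshold: float = 1.0) -> pd.DataFrame:
    """Eigenvalue retention diagnostics.

    Returns one row per component with the eigenvalue, proportion of
    variance, cumulative proportion and first difference (elbow statistic).
    The suggested number of components (eigenvalue > ``retention_threshold``)
    is stored in ``.attrs['suggested_k']``; retention remains a user decision.
    """
    lam = model.eigenvalues
    p = len(lam)
    report = pd.DataFrame(
        {
            "component": np.arange(1, p + 1),
            "eigenvalue": lam,
            "proportion": lam / p,
            "cumulative": np.cumsum(lam) / p,
            "first_difference": np.concatenate([-np.diff(lam), [np.nan]]),
        }
    )
    report.attrs["suggested_k"] = int((lam > retention_threshold).sum())
    return report


def assign_quintiles(scores: pd.DataFrame) -> pd.DataFrame:
    """Assign adherence quintiles per pattern.

    Households are ranked by score (ascending); the ranking is cut at
    ``round(i*n/5)`` boundaries so every quintile holds between ``floor(n/5)``
    and ``ceil(n/5)`` households.  Q5 is highest adherence.  Ties are broken
    by stable input (household id) order.
    """
    n = len(scores)
    if n < 5:
        raise DegenerateInputError(f"need at least 5 households for quintiles, got {n}")
    bounds = [(i * n) // 5 for i in range(6)]
    out = pd.DataFrame(index=scores.index, columns=scores.columns, dtype=object)
    labels = np.empty(n, dtype=object)
    for col in scores.columns:
        order = np.argsort(scores[col].to_numpy(), kind="stable")
        for q, (lo, hi) in enumerate(zip(bounds[:-1], bounds[1:])):
            labels[order[lo:hi]] = QUINTILE_LABELS[q]
        out[col] = labels.copy()
    return out


def format_loading_table(model: PatternModel, display_threshold: float = 0.20) -> pd.DataFrame:
    """Render loadings as a publication-style table.

    Loadings are multiplied by 100 and rounded to integers; entries with
    absolute loading below ``display_threshold`` are rendered blank.
    """
    def fmt(x: float) -> str:
        return "" if abs(x) < display_threshold else str(int(round(x * 100)))

    return model.loadings.map(fmt)


# ---------------------------------------------------------------------------
# Recovery diagnostics
# ---------------------------------------------------------------------------

def tucker_congruence(a: np.ndarray, b: np.ndarray) -> float:
    """Tucker's congruence coefficient (cosine) between two loading vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        raise DegenerateInputError("zero-norm vector in congruence computation")
    return float(a @ b / denom)


def match_components(
    loadings: pd.DataFrame, targets: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Match fitted components to target loading vectors.

    Uses an optimal one-to-one assignment maximizing total |congruence|.
    Returns ``(component_indices, congruences)`` aligned with the columns of
    ``targets`` (p x K); congruences are reported after sign alignment, i.e.
    as absolute values.
    """
    targets = np.asarray(targets, dtype=float)
    L = loadings.to_numpy()
    K = targets.shape[1]
    phi = np.zeros((K, L.shape[1]))
    for i in range(K):
        for j in range(L.shape[1]):
            phi[i, j] = abs(tucker_congruence(targets[:, i], L[:, j]))
    rows, cols = linear_sum_assignment(-phi)
    return cols[np.argsort(rows)], phi[rows, cols][np.argsort(rows)]


def varimax(loadings: np.ndarray, max_iter: int = 500, tol: float = 1e-8) -> np.ndarray:
    """Varimax rotation of a loading matrix (optional, off by default)."""
    p, k = loadings.shape
    R = np.eye(k)
    var = 0.0
    for _ in range(max_iter):
        L = loadings @ R
        u, s, vt = np.linalg.svd(
            loadings.T @ (L**3 - (L * (L**2).sum(axis=0)) / p)
        )
        R = u @ vt
        new_var = s.sum()
        if new_var < var * (1 + tol):
            break
        var = new_var
    return loadings @ R
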