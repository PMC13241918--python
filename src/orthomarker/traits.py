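"""Diversity-ecology association layer.

Species-level mean diversity is modelled against ordinal ecological traits
(threat category, habitat specialisation, riparian / dry-meadow indicator
status, dispersal potential, thermophilic preference, elevation level) with
a Gaussian GLM on log-transformed diversity, after greedy pruning of
correlated predictors. Threatened (VU/EN/CR) vs non-threatened (LC/NT)
species are compared with a two-sided Wilcoxon rank-sum test, exact when
feasible. A standardised PCA summarises the trait space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import UndefinedValueError

IUCN_ORDER = ["LC", "NT", "VU", "EN", "CR"]
IUCN_RANK = {cat: i for i, cat in enumerate(IUCN_ORDER)}
THREATENED = {"VU", "EN", "CR"}

TRAIT_COLUMNS = [
    "iucn_rank",
    "habitat_specialisation",
    "riparian_indicator",
    "dry_meadow_indicator",
    "dispersal_potential",
    "thermophilic_preference",
    "elevation_level",
]


def prune_correlated(
    table: pd.DataFrame,
    threshold: float = 0.7,
    columns: Optional[Sequence[str]] = None,
) -> list[str]:
    """Greedy removal of correlated predictors.

    While any pair exceeds |Pearson r| > threshold, the member of the worst
    pair with the higher mean absolute correlation against the remaining
    variables is dropped; ties break to the later column, so the outcome is
    deterministic in column order. Constant columns are dropped up front with
    a warning.
    """
    if columns is None:
        columns = [c for c in table.columns
                   if pd.api.types.is_numeric_dtype(table[c])]
    cols = list(columns)
    for c in list(cols):
        if table[c].nunique(dropna=True) <= 1:
            warnings.warn(f"constant column {c!r} dropped", stacklevel=2)
            cols.remove(c)
    if len(cols) < 2:
        return cols
    while len(cols) > 1:
        corr = table[cols].corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(corr), corr.shape)
        if corr[i, j] <= threshold:
            break
        mean_i = corr[i].sum() / (len(cols) - 1)
        mean_j = corr[j].sum() / (len(cols) - 1)
        if mean_i > mean_j:
            drop = i
        elif mean_j > mean_i:
            drop = j
        else:
            drop = max(i, j)
        cols.pop(drop)
    return cols


@dataclass
class GLMResult:
    """Per-term Wald statistics of the diversity-on-traits model."""

    terms: pd.DataFrame  # index: term; columns: estimate, std_error, t_value, p_value
    response_transform: str
    family: str = "gaussian"
    n: int = 0

    def estimate(self, term: str) -> float:
        return float(self.terms.loc[term, "estimate"])


def fit_glm(
    table: pd.DataFrame,
    predictors: Optional[Sequence[str]] = None,
    response: str = "mean_pct_polymorphic",
    transform: str = "log",
    exclude_museum: bool = True,
) -> GLMResult:
    """Gaussian identity-link GLM of (transformed) species diversity on
    ordinal trait scores.

    transform='log' models the natural log of the polymorphic-site
    *proportion* (percent / 100); 'identity' models the percent as-is.
    Museum-only species are excluded when the table carries a ``museum``
    flag. Ordinal predictors enter as numeric scores. A rank-deficient
    design raises with the aliased terms named.
    """
    data = table.copy()
    if exclude_museum and "museum" in data.columns:
        data = data.loc[~data["museum"].astype(bool)]
    if "iucn_category" in data.columns and "iucn_rank" not in data.columns:
        data["iucn_rank"] = data["iucn_category"].map(IUCN_RANK)
    if predictors is None:
        predictors = [c for c in TRAIT_COLUMNS if c in data.columns]
    if transform == "log":
        y = np.log(data[response].astype(float) / 100.0)
    elif transform == "identity":
        y = data[response].astype(float)
    else:
        raise ValueError(f"unknown transform {transform!r}")
    X = sm.add_constant(data[list(predictors)].astype(float), has_constant="add")
    if len(data) < len(predictors) + 2:
        raise ValueError("too few species for the number of predictors")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        aliased = _aliased_terms(X)
        raise ValueError(f"singular design; aliased terms: {aliased}")
    model = sm.GLM(y.to_numpy(), X, family=sm.families.Gaussian())
    fit = model.fit()
    terms = pd.DataFrame(
        {
            "estimate": fit.params,
            "std_error": fit.bse,
            "t_value": fit.tvalues,
            "p_value": fit.pvalues,
        }
    )
    return GLMResult(terms=terms, response_transform=transform, n=len(data))


def _aliased_terms(X: pd.DataFrame) -> list[str]:
    kept: list[str] = []
    aliased: list[str] = []
    arr = X.to_numpy()
    for i, col in enumerate(X.columns):
        trial = arr[:, [X.columns.get_loc(c) for c in kept] + [i]]
        if np.linalg.matrix_rank(trial) == trial.shape[1]:
            kept.append(col)
        else:
            aliased.append(col)
    return aliased


def wilcoxon_threatened(
    table: pd.DataFrame,
    response: str = "mean_pct_polymorphic",
    category_column: str = "iucn_category",
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test of diversity between threatened
    (VU+EN+CR) and non-threatened (LC+NT) species.

    Exact enumeration when both groups are small (min n <= 10) and tie-free;
    normal approximation otherwise. Returns (U statistic, p-value).
    """
    threatened = table.loc[
        table[category_column].isin(THREATENED), response
    ].astype(float).to_numpy()
    non_threatened = table.loc[
        ~table[category_column].isin(THREATENED), response
    ].astype(float).to_numpy()
    return rank_sum_test(threatened, non_threatened)


def rank_sum_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney/Wilcoxon rank-sum test with exact small-sample
    enumeration when tie-free."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if np.ptp(pooled) == 0:
        # All observations identical: no evidence of any shift.
        return float(x.size * y.size / 2.0), 1.0
    method = "exact" if (min(x.size, y.size) <= 10 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class PCAResult:
    scores: pd.DataFrame       # species x components
    loadings: pd.DataFrame     # variables x components
    eigenvalues: np.ndarray
    explained_fraction: np.ndarray


def pca_traits(
    table: pd.DataFrame, columns: Optional[Sequence[str]] = None
) -> PCAResult:
    """Standardised PCA of the trait space.

    Columns are centred and scaled to unit variance (ddof=1), so eigenvalues
    sum to the number of retained variables. Constant columns are excluded
    with a warning. Loadings are the orthonormal principal axes.
    """
    if columns is None:
        columns = [c for c in table.columns
                   if pd.api.types.is_numeric_dtype(table[c])]
    cols = list(columns)
    for c in list(cols):
        if table[c].std(ddof=1) == 0 or table[c].isna().all():
            warnings.warn(f"constant column {c!r} excluded from PCA",
                          stacklevel=2)
            cols.remove(c)
    if len(cols) < 2:
        raise ValueError("PCA needs >= 2 non-constant variables")
    X = table[cols].astype(float).to_numpy()
    if X.shape[0] < 3:
        raise ValueError("PCA needs >= 3 rows")
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    eigenvalues = s**2 / (X.shape[0] - 1)
    scores = U * s
    comp_names = [f"PC{i + 1}" for i in range(len(s))]
    return PCAResult(
        scores=pd.DataFrame(scores, index=table.index, columns=comp_names),
        loadings=pd.DataFrame(Vt.T, index=cols, columns=comp_names),
        eigenvalues=eigenvalues,
        explained_fraction=eigenvalues / eigenvalues.sum(),
    )
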