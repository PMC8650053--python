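"""Climatic variable selection: ensemble importance, recurrence, collinearity.

A regression forest is fit repeatedly (distinct seeds per run) to the
per-site mean performance; two importance measures are recorded per run —
a permutation importance (mean decrease in accuracy, measured as the mean
increase in MSE when a column is permuted) and the impurity-based importance
— together with how often each variable lands in the top-k.  Collinear
variables are then grouped into blocks by thresholded |Pearson r| and one
representative per block is retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

DEFAULT_FOREST = dict(n_estimators=500, min_samples_leaf=2)


@dataclass
class ImportanceReport:
    table: pd.DataFrame  # variable, mda, mdi, recurrence
    n_runs: int
    top_k: int

    def ranked(self) -> pd.DataFrame:
        """Variables ordered by recurrence then permutation importance."""
        return self.table.sort_values(
            ["recurrence", "mda"], ascending=False, kind="stable"
        ).reset_index(drop=True)


def _fit_forest(
    X: np.ndarray, y: np.ndarray, seed: int, n_trees: int | None = None
) -> RandomForestRegressor:
    kwargs = dict(DEFAULT_FOREST)
    if n_trees is not None:
        kwargs["n_estimators"] = n_trees
    rf = RandomForestRegressor(random_state=seed, **kwargs)
    rf.fit(X, y)
    return rf


def permutation_importance_scores(
    rf: RandomForestRegressor,
    X: np.ndarray,
    y: np.ndarray,
    rng: np.random.Generator,
    n_repeats: int = 5,
) -> np.ndarray:
    """Mean increase in MSE when one column is permuted (per variable)."""
    base = float(np.mean((rf.predict(X) - y) ** 2))
    scores = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        drop = 0.0
        for _ in range(n_repeats):
            Xp = X.copy()
            Xp[:, j] = Xp[rng.permutation(len(y)), j]
            drop += float(np.mean((rf.predict(Xp) - y) ** 2)) - base
        scores[j] = drop / n_repeats
    return scores


def importance_ranking(
    climate: pd.DataFrame,
    response: pd.Series,
    n_runs: int = 20,
    top_k: int = 7,
    seed: int = 0,
    variables=None,
    n_trees: int | None = None,
    n_repeats: int = 5,
) -> ImportanceReport:
    """Rank climatic variables by repeated-forest importance.

    ``response`` is indexed by site and aligned against the climate table's
    ``site`` column.  Requires at least 8 sites and 2 candidate variables.
    """
    variables = (
        [c for c in climate.columns if c != "site"] if variables is None else list(variables)
    )
    if len(variables) < 2:
        raise ValueError("need at least 2 candidate variables")
    aligned = climate.set_index("site").loc[response.index, variables]
    X = aligned.to_numpy(dtype=float)
    y = response.to_numpy(dtype=float)
    if len(y) < 8:
        raise ValueError("need at least 8 sites for the forest ensemble")

    mda = np.zeros(len(variables))
    mdi = np.zeros(len(variables))
    recurrence = np.zeros(len(variables), dtype=int)
    k = min(top_k, len(variables))
    for run in range(n_runs):
        rf = _fit_forest(X, y, seed + run, n_trees)
        rng = np.random.default_rng(seed + run)
        scores = permutation_importance_scores(rf, X, y, rng, n_repeats)
        mda += scores
        mdi += rf.feature_importances_
        top = np.argsort(scores, kind="stable")[::-1][:k]
        recurrence[top] += 1
    table = pd.DataFrame(
        {
            "variable": variables,
            "mda": mda / n_runs,
            "mdi": mdi / n_runs,
            "recurrence": recurrence,
        }
    )
    return ImportanceReport(table, n_runs, k)


def collinearity_filter(
    climate: pd.DataFrame,
    variables,
    threshold: float = 0.85,
    recurrence: dict | None = None,
) -> tuple:
    """Group variables into connected blocks of |r| > threshold.

    Returns ``(blocks, representatives)``: the connected components of the
    collinearity graph (each sorted) and one representative per block (the
    highest-recurrence member, alphabetical tiebreak).  Constant columns are
    excluded with a warning since their correlation is undefined.
    """
    variables = list(variables)
    if len(variables) < 2:
        raise ValueError("need at least 2 variables")
    data = climate[variables]
    constant = [v for v in variables if data[v].nunique() <= 1]
    if constant:
        warnings.warn(f"excluding constant column(s) {constant}: correlation undefined")
        variables = [v for v in variables if v not in constant]
    corr = climate[variables].corr().abs()

    parent = {v: v for v in variables}

    def find(v):
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    for i, vi in enumerate(variables):
        for vj in variables[i + 1:]:
            if corr.loc[vi, vj] > threshold:
                parent[find(vi)] = find(vj)

    groups: dict = {}
    for v in variables:
        groups.setdefault(find(v), []).append(v)
    blocks = sorted((sorted(g) for g in groups.values()), key=lambda g: g[0])
    rec = recurrence or {}
    representatives = [
        max(block, key=lambda v: (rec.get(v, 0), [-ord(c) for c in v])) for block in blocks
    ]
    return blocks, representatives


def nominate_gradient_variable(
    climate: pd.DataFrame,
    response: pd.Series,
    n_runs: int = 20,
    top_k: int = 7,
    threshold: float = 0.85,
    seed: int = 0,
    n_trees: int | None = None,
    n_repeats: int = 5,
) -> tuple:
    """Full selection: ranking, collinearity blocks, and the nominated variable.

    The nominee is the representative of the block containing the overall
    top-ranked variable (recurrence count, then permutation importance).
    Also reports the forest R2 using the nominee alone as a rough measure of
    how much response variability the single gradient variable captures.
    """
    report = importance_ranking(
        climate, response, n_runs, top_k, seed, n_trees=n_trees, n_repeats=n_repeats
    )
    rec = dict(zip(report.table["variable"], report.table["recurrence"]))
    blocks, reps = collinearity_filter(
        climate, report.table["variable"], threshold, rec
    )
    best = report.ranked()["variable"].iloc[0]
    nominee = next(rep for block, rep in zip(blocks, reps) if best in block)
    r2 = representative_r2(climate, response, nominee, seed, n_trees)
    return nominee, report, blocks, r2


def representative_r2(
    climate: pd.DataFrame,
    response: pd.Series,
    variable: str,
    seed: int = 0,
    n_trees: int | None = None,
) -> float:
    """Forest R2 (training) of the response on a single variable."""
    x = climate.set_index("site").loc[response.index, [variable]].to_numpy(float)
    y = response.to_numpy(float)
    rf = _fit_forest(x, y, seed, n_trees)
    pred = rf.predict(x)
    tss = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - float(np.sum((y - pred) ** 2)) / tss if tss > 0 else 0.0
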