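"""Cellar-age biomarker discovery.

Two complementary routes, mirroring common microbiome practice:

* :func:`rf_select` -- random-forest regression of OTU relative
  abundances against the (ordinal) age group, with repeated k-fold
  cross-validation over nested feature subsets; the subset size with the
  least CV error defines the biomarker panel.
* :func:`lefse` -- linear discriminant analysis effect size: a
  Kruskal-Wallis screen keeps features that differ between groups, then a
  bootstrapped one-dimensional LDA yields a per-feature effect size
  reported on a log10 scale; scores above a threshold (4 by convention
  for strong markers) flag biomarkers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.model_selection import RepeatedKFold

from ._errors import DataError, ValidationError
from .table import AGE_GROUPS, CommunityTable

#: LEfSe rescales relative abundances by this factor (abundances per
#: million) before computing effect sizes, which is what places strong
#: enrichments above the conventional log10 threshold of 4.
LEFSE_SCALE = 1e6


@dataclass
class RfSelection:
    cv_error_curve: pd.Series        # n_features -> mean CV MSE
    selected_n: int
    selected_taxa: list[str]         # ordered by importance, length selected_n
    importances: pd.Series           # full importance ranking

    def to_dataframe(self) -> pd.DataFrame:
        df = self.importances.rename("importance").to_frame()
        df["selected"] = df.index.isin(self.selected_taxa)
        return df


def _feature_grid(n_features: int) -> list[int]:
    """Fibonacci-like ladder 1, 2, 3, 5, 8, ... capped at n_features."""
    grid, a, b = [], 1, 2
    while a < n_features:
        grid.append(a)
        a, b = b, a + b
    grid.append(n_features)
    return grid


def _age_response(frame: pd.DataFrame, sample_ids, response: str) -> np.ndarray:
    meta = frame.loc[list(sample_ids)]
    if response == "age_group_ordinal":
        y = meta["age_group"].astype(str).map(
            {g: i + 1 for i, g in enumerate(AGE_GROUPS)})
    elif response == "age_years":
        y = pd.to_numeric(meta["age_years"])
    else:
        raise ValidationError(f"unknown response {response!r}")
    y = y.to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValidationError("response contains missing values")
    if np.ptp(y) == 0:
        raise DataError("response is constant")
    return y


def rf_select(table: CommunityTable, frame: pd.DataFrame,
              response: str = "age_group_ordinal", n_trees: int = 100,
              folds: int = 10, repeats: int = 5, seed: int = 0) -> RfSelection:
    """Random-forest OTU selection against cellar age.

    A forest fit on all samples ranks taxa by permutation importance;
    nested top-n subsets (Fibonacci-like grid) are then re-fit under
    ``repeats`` x ``folds`` cross-validation and the subset with the
    smallest mean squared error wins (ties break toward fewer taxa).
    Fully deterministic under ``seed``.
    """
    y = _age_response(frame, table.sample_ids, response)
    if folds > len(y):
        raise ValidationError(f"folds ({folds}) exceed sample count ({len(y)})")
    # canonical taxon order so the result does not depend on how the
    # caller happened to sort the table
    data = table.data.sort_index()
    x = data.to_numpy(dtype=float).T  # samples x taxa
    taxa = np.array(data.index)

    # max_features = p/3, the usual regression-forest default
    base = RandomForestRegressor(n_estimators=n_trees, max_features=1.0 / 3.0,
                                 random_state=seed, n_jobs=1)
    base.fit(x, y)
    imp = permutation_importance(base, x, y, n_repeats=10,
                                 random_state=seed + 1, n_jobs=1)
    order = np.argsort(-imp.importances_mean, kind="stable")
    importances = pd.Series(imp.importances_mean[order], index=taxa[order])

    grid = _feature_grid(len(taxa))
    cv = RepeatedKFold(n_splits=folds, n_repeats=repeats, random_state=seed + 2)
    splits = list(cv.split(x))
    errors = {}
    for n_feat in grid:
        cols = order[:n_feat]
        xs = x[:, cols]
        fold_mse = []
        for tr, te in splits:
            model = RandomForestRegressor(n_estimators=n_trees, max_features=1.0 / 3.0,
                                          random_state=seed + 3, n_jobs=1)
            model.fit(xs[tr], y[tr])
            pred = model.predict(xs[te])
            fold_mse.append(float(np.mean((pred - y[te]) ** 2)))
        errors[n_feat] = float(np.mean(fold_mse))
    curve = pd.Series(errors).sort_index()
    selected_n = int(curve.index[np.argmin(curve.to_numpy())])  # ties -> smaller n
    return RfSelection(
        cv_error_curve=curve,
        selected_n=selected_n,
        selected_taxa=importances.index[:selected_n].tolist(),
        importances=importances,
    )


# ---------------------------------------------------------------------
# LEfSe
# ---------------------------------------------------------------------

def _lda_direction(x: np.ndarray, labels: np.ndarray, shrink: float = 1e-6) -> np.ndarray:
    """First discriminant direction (unit norm) of Fisher's LDA with
    identity shrinkage on the within-class scatter."""
    classes = np.unique(labels)
    overall = x.mean(axis=0)
    sw = np.zeros((x.shape[1], x.shape[1]))
    sb = np.zeros_like(sw)
    for c in classes:
        xc = x[labels == c]
        mc = xc.mean(axis=0)
        dev = xc - mc
        sw += dev.T @ dev
        diff = (mc - overall)[:, None]
        sb += len(xc) * (diff @ diff.T)
    sw += shrink * np.eye(sw.shape[0])
    # generalized eigenproblem Sb w = lambda Sw w
    vals, vecs = np.linalg.eig(np.linalg.solve(sw, sb))
    w = np.real(vecs[:, np.argmax(np.real(vals))])
    norm = np.linalg.norm(w)
    return w / norm if norm > 0 else w


def lefse(table: CommunityTable, frame: pd.DataFrame, group_col: str = "age_group",
          alpha: float = 0.05, lda_threshold: float = 4.0, n_boot: int = 30,
          seed: int = 0) -> pd.DataFrame:
    """LEfSe-style biomarker discovery.

    Stage 1: per-feature Kruskal-Wallis across groups on abundances
    scaled by 1e6; survivors (p < alpha) proceed.  Stage 2: ``n_boot``
    bootstrap rounds, each on two-thirds of every group's samples, fit a
    one-dimensional LDA over the surviving features; a feature's effect
    size is the absolute difference between the two most extreme group
    means of its LDA-projected values (coefficient x feature), averaged
    over bootstraps; lda_score = log10(1 + effect).  Biomarkers have
    lda_score > lda_threshold, attributed to the group with the highest
    mean abundance.  There is no subclass stage.
    """
    meta = frame.loc[table.sample_ids]
    groups = meta[group_col].astype(str).to_numpy()
    uniq, counts = np.unique(groups, return_counts=True)
    if len(uniq) < 2:
        raise DataError("lefse needs at least two groups")
    small = uniq[counts < 3]
    if small.size:
        raise DataError(f"group(s) below minimum size 3: {small.tolist()}")

    x = table.matrix().T * LEFSE_SCALE  # samples x features
    taxa = table.taxon_ids
    kw_p = np.ones(len(taxa))
    for f in range(len(taxa)):
        cols = [x[groups == g, f] for g in uniq]
        if all(np.ptp(c) == 0 for c in cols) and np.ptp(x[:, f]) == 0:
            kw_p[f] = 1.0
            continue
        try:
            kw_p[f] = stats.kruskal(*cols).pvalue
        except ValueError:  # all values identical
            kw_p[f] = 1.0

    group_means = pd.DataFrame(
        {g: x[groups == g].mean(axis=0) for g in uniq}, index=taxa)
    enriched = group_means.idxmax(axis=1)

    surviving = np.flatnonzero(kw_p < alpha)
    scores = np.full(len(taxa), np.nan)
    if surviving.size:
        rng = np.random.default_rng(seed)
        xs = x[:, surviving]
        effects = np.zeros(surviving.size)
        for _ in range(n_boot):
            take = []
            for g in uniq:
                gi = np.flatnonzero(groups == g)
                k = max(2, int(np.ceil(2 * gi.size / 3)))
                take.append(rng.choice(gi, k, replace=False))
            idx = np.concatenate(take)
            w = _lda_direction(xs[idx], groups[idx])
            proj = xs[idx] * w  # per-feature projected values
            gmeans = np.stack([proj[groups[idx] == g].mean(axis=0) for g in uniq])
            effects += gmeans.max(axis=0) - gmeans.min(axis=0)
        effects /= n_boot
        scores[surviving] = np.log10(1.0 + np.abs(effects))

    out = pd.DataFrame({
        "kw_p_value": kw_p,
        "enriched_group": enriched,
        "lda_score": scores,
    }, index=pd.Index(taxa, name="taxon_id"))
    out["is_biomarker"] = (out["kw_p_value"] < alpha) & (out["lda_score"] > lda_threshold)
    return out
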