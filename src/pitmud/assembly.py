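"""Phylogenetic null-model inference of community assembly.

Between-community mean nearest taxon distance (βMNTD) measures the
phylogenetic turnover between two samples: for each taxon present in one
sample, the patristic distance to its closest relative present in the
other sample, weighted by within-sample relative abundance and averaged
symmetrically,

    βMNTD = 0.5 [ Σ_i f_ik min_j Δ_ij  +  Σ_i f_im min_j Δ_ij ],

with f the per-sample relative abundances (renormalized over the taxa
present in that sample) and the minimum taken over taxa present in the
*other* sample (a shared taxon is its own nearest relative at distance
zero).

βNTI is the z-score of the observed βMNTD against a null distribution
obtained by shuffling taxon identities across the tips of the phylogeny
("taxa labels" randomization: every sample keeps its abundance vector and
richness, taxa get random phylogenetic positions).  |βNTI| > 2 signals
deterministic assembly, with βNTI > 2 read as heterogeneous selection
(more turnover than chance) and βNTI < -2 as homogeneous selection (less
turnover than chance); |βNTI| <= 2 is consistent with stochastic
assembly.  Per-group class fractions summarize the balance of these
processes along the cellar-age gradient.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._errors import DataError, ValidationError
from .phylo import cophenetic_matrix, prune_to_table
from .table import CommunityTable

logger = logging.getLogger(__name__)

STOCHASTIC = "stochastic"
HOMOGENEOUS = "homogeneous_selection"
HETEROGENEOUS = "heterogeneous_selection"


@dataclass
class AssemblyFractions:
    group: str
    frac_stochastic: float
    frac_homogeneous: float
    frac_heterogeneous: float
    n_pairs: int


# ---------------------------------------------------------------------
# Observed statistic
# ---------------------------------------------------------------------

def _sample_weights(values: np.ndarray, weighted: bool) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per sample: (indices of present taxa, renormalized weights)."""
    out = []
    for col in values.T:
        idx = np.flatnonzero(col > 0)
        if idx.size == 0:
            raise DataError("sample with no taxa present on the tree")
        if weighted:
            f = col[idx] / col[idx].sum()
        else:
            f = np.full(idx.size, 1.0 / idx.size)
        out.append((idx, f))
    return out


def _pair_beta_mntd(d: np.ndarray, kw, mw) -> float:
    (ik, fk), (im, fm) = kw, mw
    # min over taxa present in the other sample (self included if shared)
    to_m = d[np.ix_(ik, im)].min(axis=1)
    to_k = d[np.ix_(im, ik)].min(axis=1)
    return 0.5 * (float(fk @ to_m) + float(fm @ to_k))


def beta_mntd(table: CommunityTable, tree, pair: tuple[str, str],
              weighted: bool = True) -> float:
    """βMNTD between one pair of samples (tree branch-length units)."""
    sub = table.select_samples(list(pair))
    sub, tree = prune_to_table(sub, tree)
    d, order = cophenetic_matrix(tree, sub.taxon_ids)
    w = _sample_weights(sub.matrix(), weighted)
    return _pair_beta_mntd(d, w[0], w[1])


# ---------------------------------------------------------------------
# Null model and beta-NTI
# ---------------------------------------------------------------------

def _all_pair_beta_mntd(d: np.ndarray, weights, pairs) -> np.ndarray:
    """βMNTD for the listed pairs given a cophenetic matrix.

    Per sample s we first take the columnwise minimum of D over the taxa
    present in s, giving the distance from every taxon to its nearest
    relative in s; pair values are then two dot products.
    """
    n_taxa = d.shape[0]
    colmin = np.empty((len(weights), n_taxa))
    for s, (idx, _) in enumerate(weights):
        colmin[s] = d[:, idx].min(axis=1)
    out = np.empty(len(pairs))
    for p, (k, m) in enumerate(pairs):
        ik, fk = weights[k]
        im, fm = weights[m]
        out[p] = 0.5 * (fk @ colmin[m][ik] + fm @ colmin[k][im])
    return out


def beta_nti(table: CommunityTable, tree, n_null: int = 999, seed: int = 0,
             pairs: list[tuple[str, str]] | None = None,
             weighted: bool = True) -> pd.DataFrame:
    """βNTI for sample pairs (all unordered pairs by default).

    Null: ``n_null`` independent shuffles of taxon identities across the
    phylogeny's tips (equivalently, a joint row/column permutation of the
    cophenetic matrix); each sample keeps its abundance vector.  The same
    shuffles are shared by every pair, and the result is independent of
    pair evaluation order, so pairs may be computed in chunks and merged.

    Returns a tidy DataFrame with one row per pair: sample_k, sample_m,
    beta_mntd_obs, null_mean, null_sd, n_null, beta_nti, class.  Pairs
    with a degenerate null (sd == 0) get beta_nti = NaN and class
    ``degenerate`` (excluded from fractions downstream, with a warning).
    """
    if n_null < 99:
        raise ValidationError(f"n_null must be >= 99, got {n_null}")
    table, tree = prune_to_table(table, tree)
    d, _ = cophenetic_matrix(tree, table.taxon_ids)
    values = table.matrix()
    weights = _sample_weights(values, weighted)
    ids = table.sample_ids
    pos = {s: i for i, s in enumerate(ids)}
    if pairs is None:
        pair_idx = list(itertools.combinations(range(len(ids)), 2))
    else:
        pair_idx = [(pos[a], pos[b]) for a, b in pairs]

    obs = _all_pair_beta_mntd(d, weights, pair_idx)

    rng = np.random.default_rng(seed)
    run_sum = np.zeros(len(pair_idx))
    run_sq = np.zeros(len(pair_idx))
    n_taxa = d.shape[0]
    for _ in range(n_null):
        perm = rng.permutation(n_taxa)
        d_null = d[np.ix_(perm, perm)]
        vals = _all_pair_beta_mntd(d_null, weights, pair_idx)
        run_sum += vals
        run_sq += vals * vals
    null_mean = run_sum / n_null
    null_var = run_sq / n_null - null_mean ** 2
    null_sd = np.sqrt(np.maximum(null_var, 0.0) * n_null / (n_null - 1))

    with np.errstate(divide="ignore", invalid="ignore"):
        nti = np.where(null_sd > 0, (obs - null_mean) / null_sd, np.nan)
    n_degenerate = int(np.sum(null_sd == 0))
    if n_degenerate:
        logger.warning("beta_nti: %d pair(s) with degenerate null (sd = 0); "
                       "excluded from class fractions", n_degenerate)

    rows = []
    for p, (k, m) in enumerate(pair_idx):
        cls = "degenerate" if null_sd[p] == 0 else classify_pair(nti[p])
        rows.append({
            "sample_k": ids[k], "sample_m": ids[m],
            "beta_mntd_obs": obs[p], "null_mean": null_mean[p],
            "null_sd": null_sd[p], "n_null": n_null,
            "beta_nti": nti[p], "class": cls,
        })
    return pd.DataFrame(rows)


def ses_mntd(table: CommunityTable, tree, n_null: int = 999, seed: int = 0,
             weighted: bool = True) -> pd.DataFrame:
    """Within-sample standardized effect size of MNTD (NTI machinery).

    MNTD of a sample is the abundance-weighted mean distance from each of
    its taxa to the nearest *other* taxon in the same sample; the same
    tip-shuffling null standardizes it.  Secondary statistic to βNTI.
    """
    table, tree = prune_to_table(table, tree)
    d, _ = cophenetic_matrix(tree, table.taxon_ids)
    values = table.matrix()
    weights = _sample_weights(values, weighted)

    def mntd_all(dm: np.ndarray) -> np.ndarray:
        out = np.empty(len(weights))
        for s, (idx, f) in enumerate(weights):
            if idx.size < 2:
                out[s] = 0.0
                continue
            sub = dm[np.ix_(idx, idx)].copy()
            np.fill_diagonal(sub, np.inf)
            out[s] = float(f @ sub.min(axis=1))
        return out

    obs = mntd_all(d)
    rng = np.random.default_rng(seed)
    run_sum = np.zeros(len(weights))
    run_sq = np.zeros(len(weights))
    for _ in range(n_null):
        perm = rng.permutation(d.shape[0])
        vals = mntd_all(d[np.ix_(perm, perm)])
        run_sum += vals
        run_sq += vals * vals
    mean = run_sum / n_null
    var = run_sq / n_null - mean ** 2
    sd = np.sqrt(np.maximum(var, 0.0) * n_null / (n_null - 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        ses = np.where(sd > 0, (obs - mean) / sd, np.nan)
    return pd.DataFrame({
        "sample_id": table.sample_ids, "mntd_obs": obs,
        "null_mean": mean, "null_sd": sd, "ses_mntd": ses,
    }).set_index("sample_id")


# ---------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------

def classify_pair(beta_nti_value: float) -> str:
    """Assembly-process class of one βNTI value.

    > 2: heterogeneous selection; < -2: homogeneous selection; otherwise
    (including exactly +/-2) stochastic.
    """
    if np.isnan(beta_nti_value):
        raise DataError("cannot classify NaN beta-NTI value")
    if beta_nti_value > 2.0:
        return HETEROGENEOUS
    if beta_nti_value < -2.0:
        return HOMOGENEOUS
    return STOCHASTIC


def assembly_fractions(results: pd.DataFrame, frame: pd.DataFrame,
                       group_col: str = "age_group") -> pd.DataFrame:
    """Per-group fractions of stochastic / homogeneous / heterogeneous
    pairs, over within-group pairs only.

    Degenerate pairs are excluded; fractions sum to 1 per group.
    """
    gk = frame.loc[results["sample_k"], group_col].astype(str).to_numpy()
    gm = frame.loc[results["sample_m"], group_col].astype(str).to_numpy()
    within = results.loc[(gk == gm)].copy()
    within["group"] = gk[gk == gm]
    within = within[within["class"] != "degenerate"]
    rows = []
    for gname, sub in within.groupby("group"):
        n = len(sub)
        if n == 0:
            continue
        counts = sub["class"].value_counts()
        rows.append(AssemblyFractions(
            group=gname,
            frac_stochastic=counts.get(STOCHASTIC, 0) / n,
            frac_homogeneous=counts.get(HOMOGENEOUS, 0) / n,
            frac_heterogeneous=counts.get(HETEROGENEOUS, 0) / n,
            n_pairs=n,
        ).__dict__)
    if not rows:
        raise DataError("no group has >= 2 samples with valid pairs")
    return pd.DataFrame(rows).set_index("group")


def beta_nti_matrix(results: pd.DataFrame) -> pd.DataFrame:
    """Square symmetric βNTI matrix from the tidy pair table."""
    ids = sorted(set(results["sample_k"]) | set(results["sample_m"]))
    mat = pd.DataFrame(np.nan, index=ids, columns=ids)
    np.fill_diagonal(mat.values, 0.0)
    for _, r in results.iterrows():
        mat.loc[r["sample_k"], r["sample_m"]] = r["beta_nti"]
        mat.loc[r["sample_m"], r["sample_k"]] = r["beta_nti"]
    return mat
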