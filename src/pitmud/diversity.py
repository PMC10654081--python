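"""Alpha and beta diversity of pit-mud communities.

Alpha diversity uses the three indices reported along the cellar-age
gradient: bias-corrected Chao1 richness, Shannon diversity (natural log)
and Pielou evenness H / ln(S_obs).  Beta diversity offers Bray-Curtis and
normalized weighted UniFrac distances, NMDS ordination, multi-term
sequential PERMANOVA on the Gower-centred distance matrix, within-group
dissimilarity summaries, and group taxon-overlap (Venn) partitions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skbio.diversity import beta_diversity
from skbio.diversity.alpha import chao1, pielou_e, shannon
from sklearn.manifold import MDS
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from ._errors import DataError, ValidationError
from .table import AGE_GROUP_YEARS, CommunityTable, aggregate, numeric_age

__all__ = [
    "PairwiseMatrix", "TrendFit", "PermanovaResult", "NmdsResult",
    "alpha_indices", "trend_regression", "bray_curtis", "weighted_unifrac",
    "nmds", "permanova", "group_dissimilarity", "taxon_overlap",
    "group_alpha_test",
]


# ---------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------

@dataclass
class PairwiseMatrix:
    """Symmetric sample x sample distance matrix with labels."""

    sample_ids: list[str]
    values: np.ndarray
    metric_name: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValidationError("distance matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValidationError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValidationError("distance matrix diagonal is not zero")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index_label="sample_id")

    def submatrix(self, sample_ids) -> "PairwiseMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return PairwiseMatrix(list(sample_ids), self.values[np.ix_(idx, idx)],
                              self.metric_name)


@dataclass
class TrendFit:
    """Ordinary least-squares fit of y against a temporal axis."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


@dataclass
class NmdsResult:
    coordinates: pd.DataFrame  # sample_id x (axis1, axis2, ...)
    stress: float


@dataclass
class PermanovaResult:
    """Sequential (Type-I) PERMANOVA table.

    ``terms`` maps term name -> dict with sum_of_squares, df, pseudo_F,
    r2_fraction, p_value; ``residual`` holds sum_of_squares, df,
    r2_fraction; r2 fractions (terms + residual) sum to 1.
    """

    terms: dict[str, dict[str, float]]
    residual: dict[str, float]
    total_ss: float
    n_permutations: int

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for name, t in self.terms.items():
            rows.append({"term": name, **t})
        rows.append({"term": "Residual", **self.residual,
                     "pseudo_F": np.nan, "p_value": np.nan})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------
# Alpha diversity
# ---------------------------------------------------------------------

def alpha_indices(table: CommunityTable) -> pd.DataFrame:
    """Per-sample Chao1, Shannon (nats), Pielou and observed richness.

    Expects rarefied counts so indices are comparable across samples.
    """
    if table.is_relative:
        raise ValidationError("alpha_indices expects a count table")
    records = []
    for sample in table.sample_ids:
        counts = table.data[sample].to_numpy()
        counts = counts[counts > 0].astype(np.int64)
        if counts.size == 0:
            raise DataError(f"sample {sample!r} is empty")
        s_obs = int(counts.size)
        h = float(shannon(counts, base=np.e)) if s_obs > 1 else 0.0
        records.append({
            "sample_id": sample,
            "observed_richness": s_obs,
            "chao1": float(chao1(counts, bias_corrected=True)),
            "shannon": h,
            "pielou": float(pielou_e(counts)) if s_obs > 1 else np.nan,
        })
    return pd.DataFrame(records).set_index("sample_id")


def trend_regression(x, y) -> TrendFit:
    """OLS of y on x with a two-sided t-test on the slope."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise DataError(f"trend regression needs n >= 3, got {x.size}")
    if np.ptp(x) == 0:
        raise DataError("temporal axis has zero variance")
    fit = stats.linregress(x, y)
    return TrendFit(slope=float(fit.slope), intercept=float(fit.intercept),
                    r_squared=float(fit.rvalue) ** 2, p_value=float(fit.pvalue),
                    n=int(x.size))


def group_alpha_test(alpha: pd.DataFrame, frame: pd.DataFrame, group_col: str,
                     index: str = "shannon", alpha_level: float = 0.05):
    """One-way ANOVA plus Tukey-HSD-adjusted pairwise comparisons of an
    alpha-diversity index between groups.

    Returns ``(anova, pairwise)``: the F/p of the one-way ANOVA and a tidy
    DataFrame of Tukey-adjusted pairwise p-values.
    """
    merged = alpha.join(frame[group_col].astype(str), how="inner").dropna(
        subset=[index, group_col])
    groups = [g[index].to_numpy() for _, g in merged.groupby(group_col, observed=True)]
    if len(groups) < 2:
        raise DataError("group_alpha_test needs at least two groups")
    f_stat, p = stats.f_oneway(*groups)
    tk = pairwise_tukeyhsd(merged[index].to_numpy(),
                           merged[group_col].to_numpy(), alpha=alpha_level)
    pairwise = pd.DataFrame(
        tk.summary().data[1:],
        columns=[str(c) for c in tk.summary().data[0]],
    )
    pairwise["p-adj"] = pairwise["p-adj"].astype(float)
    return {"F": float(f_stat), "p_value": float(p)}, pairwise


# ---------------------------------------------------------------------
# Beta diversity
# ---------------------------------------------------------------------

def bray_curtis(table: CommunityTable) -> PairwiseMatrix:
    """Bray-Curtis dissimilarity between samples of a relative table."""
    values = table.matrix()
    if (values.sum(axis=0) <= 0).any():
        raise DataError("Bray-Curtis undefined for empty samples")
    from scipy.spatial.distance import pdist, squareform

    d = squareform(pdist(values.T, metric="braycurtis"))
    return PairwiseMatrix(table.sample_ids, d, "bray_curtis")


def weighted_unifrac(table: CommunityTable, tree) -> PairwiseMatrix:
    """Normalized weighted UniFrac: sum over branches b of
    l_b |A_b - B_b| / sum over branches of l_b (A_b + B_b), where A_b/B_b
    are the abundance fractions descending from b.  Values lie in [0, 1].

    All taxa in the table must be tips of the tree (reconcile upstream
    with :func:`pitmud.phylo.prune_to_table`).
    """
    from .phylo import tip_names

    tips = set(tip_names(tree))
    off = [t for t in table.taxon_ids if t not in tips]
    if off:
        raise ValidationError(f"taxa not on tree: {off[:10]}")
    values = table.matrix()
    if (values.sum(axis=0) <= 0).any():
        raise DataError("weighted UniFrac undefined for empty samples")
    if len(tree.children) > 2:
        # a multifurcating root (e.g. a star tree) is treated as rooted by
        # hanging it under a zero-length root; branch sums are unchanged
        from skbio import TreeNode

        inner = tree.copy()
        inner.length = 0.0
        root = TreeNode()
        root.append(inner)
        tree = root
    # the UniFrac driver truncates float abundances to integers; the
    # normalized metric is per-sample scale invariant, so close each
    # sample and rescale to integer "reads" at 1e12 resolution
    props = values / values.sum(axis=0, keepdims=True)
    scaled = np.rint(props * 1e12)
    dm = beta_diversity(
        "weighted_unifrac",
        scaled.T,
        ids=table.sample_ids,
        taxa=table.taxon_ids,
        tree=tree,
        normalized=True,
    )
    return PairwiseMatrix(list(dm.ids), dm.data, "weighted_unifrac")


def nmds(dist: PairwiseMatrix, k: int = 2, seed: int = 0,
         n_restarts: int = 20, max_iter: int = 500) -> NmdsResult:
    """Non-metric MDS of a distance matrix.

    Kruskal stress-1 minimization with ``n_restarts`` seeded random
    starts; the best embedding (lowest stress) is kept and centred at the
    origin.  Same seed, same coordinates.
    """
    n = len(dist.sample_ids)
    if n < 4:
        raise DataError(f"NMDS needs at least 4 samples, got {n}")
    model = MDS(
        n_components=k,
        metric_mds=False,
        metric="precomputed",
        n_init=n_restarts,
        init="random",
        max_iter=max_iter,
        random_state=int(seed) % (2**32),
        normalized_stress=True,
    )
    coords = model.fit_transform(dist.values)
    coords = coords - coords.mean(axis=0, keepdims=True)
    df = pd.DataFrame(coords, index=dist.sample_ids,
                      columns=[f"axis{i + 1}" for i in range(k)])
    return NmdsResult(coordinates=df, stress=float(model.stress_))


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d ** 2
    n = d.shape[0]
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    return j @ a @ j


def _hat(x: np.ndarray) -> np.ndarray:
    # projection onto the column space of x via pseudo-inverse
    return x @ np.linalg.pinv(x)


def permanova(dist: PairwiseMatrix, frame: pd.DataFrame, terms: list[str],
              n_perm: int = 999, seed: int = 0) -> PermanovaResult:
    """Sequential (Type-I) PERMANOVA.

    Distance matrix is Gower-centred; each term's sum of squares is the
    increase in tr(H G) as its dummy-coded factor enters the model in the
    stated order, so r2 fractions depend on term order (the classical
    sequential decomposition).  p-values come from free permutation of
    sample labels; each term's pseudo-F is recomputed per permutation.
    """
    if n_perm < 99:
        raise ValidationError(f"n_perm must be >= 99, got {n_perm}")
    meta = frame.loc[dist.sample_ids]
    n = len(dist.sample_ids)
    g = _gower_center(dist.values)
    ss_total = float(np.trace(g))

    # cumulative hat matrices: intercept, then + each term's dummies
    designs = [np.ones((n, 1))]
    dfs = []
    for term in terms:
        col = meta[term].astype(str)
        levels = sorted(col.unique())
        if len(levels) < 2:
            raise DataError(f"term {term!r} has a single level")
        dummies = pd.get_dummies(col, drop_first=True).to_numpy(dtype=float)
        designs.append(np.hstack([designs[-1], dummies]))
        dfs.append(len(levels) - 1)
    hats = [_hat(x) for x in designs]

    def seq_stats(gmat: np.ndarray):
        tr = np.array([float(np.sum(h * gmat)) for h in hats])  # tr(H G)
        ss_terms = np.diff(tr)
        ss_res = float(np.trace(gmat)) - tr[-1]
        df_res = n - designs[-1].shape[1]
        f = (ss_terms / np.array(dfs)) / (ss_res / df_res)
        return ss_terms, ss_res, df_res, f

    ss_terms, ss_res, df_res, f_obs = seq_stats(g)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(terms))
    for _ in range(n_perm):
        p = rng.permutation(n)
        _, _, _, f_perm = seq_stats(g[np.ix_(p, p)])
        exceed += f_perm >= f_obs
    p_values = (exceed + 1.0) / (n_perm + 1.0)

    term_table = {}
    for i, term in enumerate(terms):
        term_table[term] = {
            "sum_of_squares": float(ss_terms[i]),
            "df": int(dfs[i]),
            "pseudo_F": float(f_obs[i]),
            "r2_fraction": float(ss_terms[i] / ss_total),
            "p_value": float(p_values[i]),
        }
    residual = {
        "sum_of_squares": float(ss_res),
        "df": int(df_res),
        "r2_fraction": float(ss_res / ss_total),
    }
    return PermanovaResult(terms=term_table, residual=residual,
                           total_ss=ss_total, n_permutations=n_perm)


# ---------------------------------------------------------------------
# Group summaries
# ---------------------------------------------------------------------

def group_dissimilarity(dist: PairwiseMatrix, frame: pd.DataFrame,
                        group_col: str = "age_group",
                        age_encoding: dict | None = None) -> dict:
    """Within-group pairwise distance distributions plus trend/tests.

    Returns a dict with ``within`` (group -> 1-D array of all within-group
    pairwise distances), ``medians``, a Kruskal-Wallis test across groups,
    pairwise two-sided Mann-Whitney p-values, and (when the groups are
    age groups) an OLS trend of group medians against representative age.
    """
    meta = frame.loc[dist.sample_ids]
    groups = meta[group_col].astype(str)
    within: dict[str, np.ndarray] = {}
    pos = {s: i for i, s in enumerate(dist.sample_ids)}
    for gname, members in groups.groupby(groups):
        ids = members.index.tolist()
        if len(ids) < 2:
            raise DataError(f"group {gname!r} has fewer than 2 samples")
        idx = [pos[s] for s in ids]
        sub = dist.values[np.ix_(idx, idx)]
        within[gname] = sub[np.triu_indices(len(idx), k=1)]
    medians = {g: float(np.median(v)) for g, v in within.items()}
    kw = stats.kruskal(*within.values()) if len(within) > 1 else None
    pairwise = {}
    for a, b in itertools.combinations(sorted(within), 2):
        u = stats.mannwhitneyu(within[a], within[b], alternative="two-sided")
        pairwise[(a, b)] = float(u.pvalue)
    trend = None
    encoding = AGE_GROUP_YEARS if age_encoding is None else age_encoding
    if all(g in encoding for g in within) and len(within) >= 3:
        order = sorted(within, key=lambda g: encoding[g])
        trend = trend_regression([encoding[g] for g in order],
                                 [medians[g] for g in order])
    return {
        "within": within,
        "medians": medians,
        "kruskal_p": float(kw.pvalue) if kw is not None else np.nan,
        "pairwise_p": pairwise,
        "median_trend": trend,
    }


def taxon_overlap(table: CommunityTable, taxonomy: pd.DataFrame, rank: str,
                  frame: pd.DataFrame, group_col: str) -> dict:
    """Venn-style inclusion-exclusion partition of taxa between groups.

    A taxon (aggregated at ``rank``) is "present" in a group if it has
    nonzero abundance in at least one of the group's samples.  Returns the
    full partition keyed by frozenset of group names, plus per-group
    unique ("endemic") taxa.
    """
    agg = aggregate(table, taxonomy, rank)
    meta = frame.loc[agg.sample_ids]
    groups = meta[group_col].astype(str)
    present: dict[str, set] = {}
    for gname, members in groups.groupby(groups):
        sub = agg.data[members.index.tolist()]
        present[gname] = set(sub.index[(sub > 0).any(axis=1)])
    partition: dict[frozenset, set] = {}
    all_taxa = set().union(*present.values()) if present else set()
    for taxon in all_taxa:
        key = frozenset(g for g, s in present.items() if taxon in s)
        partition.setdefault(key, set()).add(taxon)
    unique = {g: partition.get(frozenset([g]), set()) for g in present}
    return {"present": present, "partition": partition, "unique": unique}


def alpha_age_trends(alpha: pd.DataFrame, frame: pd.DataFrame,
                     age_encoding: dict | None = None) -> pd.DataFrame:
    """Trend of each alpha index against numeric cellar age (Fig-1A style)."""
    ages = numeric_age(frame.loc[alpha.index], age_encoding)
    rows = []
    for index in ("chao1", "shannon", "pielou"):
        fit = trend_regression(ages.to_numpy(), alpha[index].to_numpy())
        rows.append({"index": index, "slope": fit.slope, "r_squared": fit.r_squared,
                     "p_value": fit.p_value, "n": fit.n})
    return pd.DataFrame(rows).set_index("index")
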