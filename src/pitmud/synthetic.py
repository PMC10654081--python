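"""Synthetic pit-mud-style data with exposed ground truth.

The generators emulate the statistical shape of a multi-study amplicon
meta-dataset over fermentation-cellar mud: a 4 cellar-age x 4
production-region sampling design, a few hundred OTUs on a birth-death
phylogeny, ~10,000 reads per sample, succession in which an early
dominant clade (the *Lactobacillus*-like niche) is replaced by a late
dominant clade (the *Caproiciproducens*-like niche) along the age
gradient, and community assembly under neutral drift, homogeneous
selection or heterogeneous selection acting on a phylogenetically
conserved (Brownian) trait.

Counts are Dirichlet-multinomial so that overdispersion resembles real
amplicon data (the default concentration gives roughly twice multinomial
variance).  Every generator is fully determined by its seed, and every
claim the ground truth makes is realized in expectation.
"""

from __future__ import annotations

import json
import random as _random
from dataclasses import dataclass

import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from ._errors import DataError, ValidationError
from .phylo import parse_newick
from .table import (AGE_GROUP_YEARS, AGE_GROUPS, LONGITUDE_GROUPS, RANKS,
                    CommunityTable)

NEUTRAL = "neutral_drift"
HOMOGENEOUS = "homogeneous_selection"
HETEROGENEOUS = "heterogeneous_selection"
_REGIMES = (NEUTRAL, HOMOGENEOUS, HETEROGENEOUS)


@dataclass
class ScenarioConfig:
    """Parameters of one simulated study.

    ``assembly_regime`` may be a single regime applied to every age group
    or a mapping age_group -> regime.  ``selection_strength`` likewise a
    scalar or a per-age-group mapping; it multiplies the squared
    trait-optimum mismatch in the Gaussian fitness kernel, so (in units
    of inverse squared trait) larger values concentrate fitness on taxa
    whose trait is close to the environmental optimum.

    The default scale echoes the study design at desk size: 300 taxa,
    4 age groups x 4 region groups x 6 samples = 96 samples, 10,000
    reads each.
    """

    n_taxa: int = 300
    n_samples_per_group: int = 6          # per age x region cell
    age_groups: tuple = AGE_GROUPS
    longitude_groups: tuple = LONGITUDE_GROUPS
    birth_rate: float = 1.0
    death_rate: float = 0.5
    brownian_sigma2: float = 1.0
    assembly_regime: object = NEUTRAL
    selection_strength: object = 3.0
    succession: dict | None = None        # see default_succession()
    depth: int = 10_000
    dispersion: float = 10_000.0          # Dirichlet concentration; ~2x multinomial var
    lognormal_sigma: float = 1.5          # metacommunity abundance spread
    occupancy: float = 0.4                # fraction of the pool present per sample
    drift_sigma: float = 2.0              # per-sample lognormal drift on weights
    planted_biomarkers: dict | None = None  # taxon -> {age_group: fold_change}
    correlation_blocks: list | None = None  # [(size, rho), ...]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.birth_rate <= self.death_rate or self.death_rate < 0:
            raise ValidationError("need birth_rate > death_rate >= 0")
        for v in ([self.selection_strength] if np.isscalar(self.selection_strength)
                  else list(dict(self.selection_strength).values())):
            if v < 0:
                raise ValidationError("selection_strength must be >= 0")
        regimes = ([self.assembly_regime] if isinstance(self.assembly_regime, str)
                   else list(dict(self.assembly_regime).values()))
        bad = set(regimes) - set(_REGIMES)
        if bad:
            raise ValidationError(f"unknown assembly regime(s): {sorted(bad)}")

    def regime_for(self, age_group: str) -> str:
        if isinstance(self.assembly_regime, str):
            return self.assembly_regime
        return dict(self.assembly_regime)[age_group]

    def strength_for(self, age_group: str) -> float:
        if np.isscalar(self.selection_strength):
            return float(self.selection_strength)
        return float(dict(self.selection_strength)[age_group])


def regime_scenario(regime: str, seed: int = 11,
                    n_samples_per_group: int = 3) -> ScenarioConfig:
    """Calibrated single-regime scenario preset.

    These presets are the study conditions under which the assembly stage
    is expected to recover the generating process: a sparse community
    (10% of the pool per sample) with mild ecological drift and a weak
    shared metacommunity profile, so that presence turnover between
    replicate samples carries the phylogenetic signal of selection.
    Homogeneous selection uses strength 1.0 (one shared extreme optimum
    per group); heterogeneous uses 2.0 with per-sample optima spread over
    the trait range.
    """
    strength = {NEUTRAL: 0.0, HOMOGENEOUS: 1.0, HETEROGENEOUS: 2.0}[regime]
    return ScenarioConfig(
        assembly_regime=regime,
        selection_strength=strength,
        occupancy=0.10,
        drift_sigma=0.7,
        lognormal_sigma=0.3,
        n_samples_per_group=n_samples_per_group,
        seed=seed,
    )


def succession_scenario(seed: int = 0, n_samples_per_group: int = 6) -> ScenarioConfig:
    """Default full-design scenario: dominant-clade replacement along the
    age gradient with assembly shifting from neutral drift in young
    cellars to increasingly strong homogeneous selection in old ones --
    the temporal pattern the pit-mud meta-analysis reports."""
    return ScenarioConfig(
        assembly_regime={"Aa": NEUTRAL, "Ab": NEUTRAL,
                         "Ac": HOMOGENEOUS, "Ad": HOMOGENEOUS},
        selection_strength={"Aa": 0.0, "Ab": 0.2, "Ac": 0.5, "Ad": 1.0},
        occupancy=0.10,
        drift_sigma=0.7,
        lognormal_sigma=0.3,
        succession=default_succession(),
        n_samples_per_group=n_samples_per_group,
        seed=seed,
    )


def default_succession(replacement_rate: float = 2.5,
                       amplitude: float = 6.0) -> dict:
    """Succession settings: the early clade's weight multiplier follows a
    falling logistic of log10(cellar age) and the late clade a rising one,
    crossing near ~50 years with steepness ``replacement_rate``."""
    return {
        "replacement_rate": float(replacement_rate),
        "amplitude": float(amplitude),
        "crossover_log10_years": np.log10(50.0),
        "clade_fraction": 0.08,   # fraction of tips in each dominant clade
    }


# ---------------------------------------------------------------------
# Tree and trait
# ---------------------------------------------------------------------

def simulate_tree(config: ScenarioConfig, seed: int | None = None):
    """Birth-death tree conditioned on ``n_taxa`` extant tips.

    Ultrametric over extant taxa, positive branch lengths, tips labelled
    ``O0000``...; the same seed yields the same Newick string.
    """
    seed = config.seed if seed is None else seed
    dtree = treesim.birth_death_tree(
        birth_rate=config.birth_rate,
        death_rate=config.death_rate,
        num_extant_tips=config.n_taxa,
        rng=_random.Random(int(seed)),
        repeat_until_success=True,
    )
    newick = dtree.as_string(schema="newick", suppress_rooting=True).strip()
    tree = parse_newick(newick)
    for node in tree.traverse(include_self=False):
        if node.length is None or node.length <= 0:
            node.length = 1e-8
    for i, tip in enumerate(tree.tips()):
        tip.name = f"O{i:04d}"
    return tree


def brownian_trait(tree, sigma2: float, seed: int) -> pd.Series:
    """Trait values at the tips from a root-to-tip Brownian walk."""
    rng = np.random.default_rng(seed)
    values: dict[int, float] = {id(tree): 0.0}
    for node in tree.preorder(include_self=False):
        step = rng.normal(0.0, np.sqrt(sigma2 * (node.length or 0.0)))
        values[id(node)] = values[id(node.parent)] + step
    return pd.Series({t.name: values[id(t)] for t in tree.tips()})


def _pick_clades(tree, fraction: float) -> tuple[list[str], list[str]]:
    """Two disjoint clades each holding roughly ``fraction`` of the tips,
    deterministic in tree shape (earliest qualifying clades in preorder)."""
    n = len(list(tree.tips()))
    lo, hi = max(2, int(0.5 * fraction * n)), max(3, int(2.0 * fraction * n))
    chosen: list[set[str]] = []
    for node in tree.preorder(include_self=False):
        if node.is_tip():
            continue
        tips = {t.name for t in node.tips()}
        if lo <= len(tips) <= hi and all(not tips & c for c in chosen):
            chosen.append(tips)
            if len(chosen) == 2:
                break
    if len(chosen) < 2:
        raise DataError("could not find two disjoint clades of the requested size")
    return sorted(chosen[0]), sorted(chosen[1])


# ---------------------------------------------------------------------
# Communities
# ---------------------------------------------------------------------

def _dirichlet_multinomial(rng, p: np.ndarray, depth: int, conc: float) -> np.ndarray:
    alpha = np.maximum(conc * p, 1e-12)
    probs = rng.dirichlet(alpha)
    return rng.multinomial(depth, probs)


def _weighted_subset(rng, weights: np.ndarray, k: int) -> np.ndarray:
    """k indices sampled without replacement with prob proportional to
    weights (Gumbel top-k trick)."""
    with np.errstate(divide="ignore"):
        keys = np.log(weights) + rng.gumbel(size=weights.size)
    return np.argpartition(-keys, k - 1)[:k]


def _logistic(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_communities(tree, config: ScenarioConfig, seed: int | None = None):
    """Simulate the full design: (counts table, sample frame, ground truth).

    Mechanism per sample: a log-normal metacommunity profile is bent by
    (i) a Gaussian fitness kernel exp(-s (trait - E)^2) around the
    sample's environmental optimum E -- one shared E per group under
    homogeneous selection, per-sample optima spread over the trait range
    under heterogeneous selection, no kernel under neutral drift; (ii)
    logistic succession multipliers on the early/late dominant clades;
    (iii) planted biomarker fold-changes.  Counts are then
    Dirichlet-multinomial at the configured depth and dispersion.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    taxa = [t.name for t in tree.tips()]
    if set(taxa) != set(f"O{i:04d}" for i in range(len(taxa))):
        pass  # arbitrary labels are fine; order follows the tree
    n_taxa = len(taxa)
    if config.depth < n_taxa:
        import logging
        logging.getLogger(__name__).warning(
            "depth %d below n_taxa %d; many taxa will be unobserved",
            config.depth, n_taxa)

    trait = brownian_trait(tree, config.brownian_sigma2, seed=seed + 1)
    trait = trait.reindex(taxa)
    meta_log = rng.normal(0.0, config.lognormal_sigma, n_taxa)
    metacommunity = np.exp(meta_log)

    succession = config.succession
    early, late = ([], [])
    if succession is not None:
        early, late = _pick_clades(tree, succession["clade_fraction"])
    early_mask = np.isin(taxa, early)
    late_mask = np.isin(taxa, late)

    # Trait-range anchors for optima.  The shared optimum of homogeneous
    # selection sits at an extreme trait quantile: Brownian traits near
    # the median occur all over the tree, so only an extreme optimum
    # selects a phylogenetically clustered set of taxa.
    t_lo, t_hi = np.quantile(trait.to_numpy(), [0.05, 0.95])

    planted = config.planted_biomarkers or {}
    taxon_pos = {t: i for i, t in enumerate(taxa)}

    columns = {}
    frame_rows = []
    group_optima: dict[str, float] = {}
    for age in config.age_groups:
        regime = config.regime_for(age)
        strength = config.strength_for(age)
        age_years = AGE_GROUP_YEARS[age]
        log_age = np.log10(age_years)
        weights = metacommunity.copy()
        if succession is not None:
            r = succession["replacement_rate"]
            x0 = succession["crossover_log10_years"]
            amp = succession["amplitude"]
            early_mult = 1.0 + amp * _logistic(-r * (log_age - x0))
            late_mult = 1.0 + amp * _logistic(+r * (log_age - x0))
            weights = weights * np.where(early_mask, early_mult, 1.0)
            weights = weights * np.where(late_mask, late_mult, 1.0)
        for taxon, folds in planted.items():
            fold = folds.get(age, 1.0) if isinstance(folds, dict) else 1.0
            weights[taxon_pos[taxon]] *= fold

        if regime == HOMOGENEOUS:
            # With succession configured, selection pulls toward the late
            # dominant clade's niche (the trait that wins with age);
            # otherwise an extreme trait quantile serves as the shared
            # optimum so the selected set is phylogenetically clustered.
            if succession is not None and late:
                group_optima[age] = float(trait.loc[late].mean())
            else:
                group_optima[age] = float(t_hi)
        for region in config.longitude_groups:
            for k in range(config.n_samples_per_group):
                sid = f"{age}_{region}_{k:02d}"
                if regime == NEUTRAL or strength == 0.0:
                    w = weights
                    optimum = None
                elif regime == HOMOGENEOUS:
                    optimum = group_optima[age]
                    w = weights * np.exp(-strength * (trait.to_numpy() - optimum) ** 2)
                elif regime == HETEROGENEOUS:
                    optimum = float(rng.uniform(t_lo, t_hi))
                    w = weights * np.exp(-strength * (trait.to_numpy() - optimum) ** 2)
                # ecological drift: per-sample lognormal noise on local
                # weights, then a fitness-biased occupancy subset -- so
                # presence turns over between replicate samples instead of
                # freezing at the top of the fitness ladder
                w_s = w * rng.lognormal(0.0, config.drift_sigma, n_taxa)
                k = max(2, int(round(config.occupancy * n_taxa)))
                present = _weighted_subset(rng, w_s, k)
                p = np.zeros(n_taxa)
                p[present] = w_s[present] / w_s[present].sum()
                columns[sid] = _dirichlet_multinomial(rng, p, config.depth,
                                                      config.dispersion)
                frame_rows.append({
                    "sample_id": sid, "age_group": age, "age_years": age_years,
                    "longitude_group": region,
                    "longitude_deg": 105.0 + 4.5 * LONGITUDE_GROUPS.index(region),
                })

    table = CommunityTable(pd.DataFrame(columns, index=taxa))
    frame = pd.DataFrame(frame_rows).set_index("sample_id")
    frame["age_group"] = pd.Categorical(frame["age_group"],
                                        categories=AGE_GROUPS, ordered=True)
    truth = {
        "regime_per_group": {g: config.regime_for(g) for g in config.age_groups},
        "selection_strength_per_group": {g: config.strength_for(g)
                                         for g in config.age_groups},
        "planted_biomarkers": planted,
        "trait": trait.to_dict(),
        "early_clade": early,
        "late_clade": late,
        "dominance_trajectory": _expected_dominance(config, early_mask, late_mask,
                                                    metacommunity),
        "seed": seed,
    }
    return table, frame, truth


def _expected_dominance(config, early_mask, late_mask, metacommunity) -> dict:
    """Expected mean relative abundance of the two dominant clades per age
    group, under the succession multipliers alone (no selection kernel)."""
    succ = config.succession
    out = {}
    for age in config.age_groups:
        if succ is None:
            w = metacommunity
        else:
            log_age = np.log10(AGE_GROUP_YEARS[age])
            r, x0, amp = succ["replacement_rate"], succ["crossover_log10_years"], succ["amplitude"]
            w = metacommunity * np.where(early_mask, 1 + amp * _logistic(-r * (log_age - x0)), 1.0)
            w = w * np.where(late_mask, 1 + amp * _logistic(+r * (log_age - x0)), 1.0)
        p = w / w.sum()
        out[age] = {"early": float(p[early_mask].sum()),
                    "late": float(p[late_mask].sum())}
    return out


def make_age_biomarkers(tree, n_markers: int = 12, effect: float = 3.0,
                        base_boost: float = 30.0, seed: int = 0) -> dict:
    """Plant ``n_markers`` age-informative taxa: monotone fold-changes
    across Aa..Ad, half increasing and half decreasing, with log-fold
    span ``effect`` (natural log) between the extreme groups.

    ``base_boost`` raises every marker's overall weight so markers are
    consistently present across samples -- informative taxa in real
    surveys are abundant ones, and an absent marker carries no signal.
    """
    rng = np.random.default_rng(seed)
    taxa = [t.name for t in tree.tips()]
    chosen = rng.choice(len(taxa), n_markers, replace=False)
    z = np.linspace(-0.5, 0.5, len(AGE_GROUPS))
    planted = {}
    for j, ti in enumerate(chosen):
        sign = 1.0 if j % 2 == 0 else -1.0
        planted[taxa[ti]] = {g: float(base_boost * np.exp(sign * effect * z[i]))
                             for i, g in enumerate(AGE_GROUPS)}
    return planted


# ---------------------------------------------------------------------
# Correlated table (network fixture)
# ---------------------------------------------------------------------

def simulate_correlated_table(config: ScenarioConfig, seed: int | None = None,
                              n_samples: int | None = None):
    """Latent Gaussian copula with block correlation structure.

    Taxa in the same block share pairwise latent correlation rho
    (cross-block correlation 0); latent normals map monotonically to
    log-normal abundances, so rank correlations survive the transform,
    then Dirichlet-multinomial counting noise is added.  Block members
    get a mean-abundance boost so that counting noise does not swamp the
    planted correlation at the configured depth.
    """
    seed = config.seed if seed is None else seed
    blocks = config.correlation_blocks or []
    sizes = [int(s) for s, _ in blocks]
    if sum(sizes) > config.n_taxa:
        raise ValidationError("block sizes exceed n_taxa")
    for _, rho in blocks:
        if not -1.0 < rho < 1.0:
            raise ValidationError(f"block rho must be in (-1, 1), got {rho}")
    rng = np.random.default_rng(seed)
    n_taxa = config.n_taxa
    if n_samples is None:
        n_samples = (config.n_samples_per_group * len(config.age_groups)
                     * len(config.longitude_groups))
    taxa = [f"O{i:04d}" for i in range(n_taxa)]

    corr = np.eye(n_taxa)
    start = 0
    membership = np.full(n_taxa, -1)
    for b, (size, rho) in enumerate(blocks):
        sl = slice(start, start + size)
        corr[sl, sl] = rho
        np.fill_diagonal(corr[sl, sl], 1.0)
        membership[sl] = b
        start += size
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise ValidationError("implied correlation matrix is not positive definite") from exc

    z = rng.standard_normal((n_samples, n_taxa)) @ chol.T
    mu = rng.normal(0.0, config.lognormal_sigma, n_taxa)
    # Block taxa sit at a uniform, comfortably-abundant baseline: every
    # member stays above the counting floor at the configured depth, so
    # rank correlations survive the (monotone) abundance transform and
    # the sequencing step instead of being squashed by zero-count ties.
    mu[membership >= 0] = 2.5
    x = np.exp(mu + z)
    counts = np.empty((n_samples, n_taxa), dtype=np.int64)
    for j in range(n_samples):
        p = x[j] / x[j].sum()
        counts[j] = _dirichlet_multinomial(rng, p, config.depth, config.dispersion)
    table = CommunityTable(pd.DataFrame(counts.T, index=taxa,
                                        columns=[f"s{j:03d}" for j in range(n_samples)]))
    truth = {
        "blocks": [{"taxa": taxa[sum(sizes[:b]):sum(sizes[:b + 1])], "rho": blocks[b][1]}
                   for b in range(len(blocks))],
        "membership": {t: int(m) for t, m in zip(taxa, membership)},
        "seed": seed,
    }
    return table, truth


# ---------------------------------------------------------------------
# Taxonomy
# ---------------------------------------------------------------------

def simulate_taxonomy(tree, seed: int = 0, n_phyla: int = 5,
                      unassigned_fraction: float = 0.02) -> pd.DataFrame:
    """Rank labels that respect the tree: cut the tree into clades at each
    rank so that related tips share labels, the way real lineages do."""
    rng = np.random.default_rng(seed)
    taxa = [t.name for t in tree.tips()]
    n_groups = {"phylum": n_phyla, "class": n_phyla + 3, "order": 2 * n_phyla + 2,
                "family": 4 * n_phyla, "genus": 7 * n_phyla}
    df = pd.DataFrame(index=pd.Index(taxa, name="taxon_id"), columns=list(RANKS),
                      dtype=object)
    for rank in RANKS:
        k = min(n_groups[rank], len(taxa))
        # contiguous tip blocks approximate clades on the ladderized tree
        bounds = np.linspace(0, len(taxa), k + 1).astype(int)
        labels = np.empty(len(taxa), dtype=object)
        for g in range(k):
            labels[bounds[g]:bounds[g + 1]] = f"{rank[0]}{g:02d}"
        df[rank] = labels
    mask = rng.random(len(taxa)) < unassigned_fraction
    df.loc[mask, "genus"] = None
    return df


def scenario_to_files(table, frame, truth, tree, outdir) -> dict:
    """Write the emitted artifacts in the formats the pipeline reads."""
    import os
    from .phylo import write_tree
    from .table import write_community, write_sample_frame

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "table": os.path.join(outdir, "otu_table.tsv"),
        "metadata": os.path.join(outdir, "metadata.tsv"),
        "tree": os.path.join(outdir, "tree.nwk"),
        "ground_truth": os.path.join(outdir, "ground_truth.json"),
    }
    write_community(table, paths["table"])
    write_sample_frame(frame, paths["metadata"])
    write_tree(tree, paths["tree"])
    with open(paths["ground_truth"], "w") as fh:
        json.dump(truth, fh, indent=1, default=str)
    return paths
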