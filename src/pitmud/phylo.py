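"""Rooted phylogenies over OTU tips.

Trees are scikit-bio :class:`~skbio.TreeNode` objects read from Newick;
this module adds the small amount of glue the pipeline needs: tip-label
checks, the cophenetic (tip-to-tip patristic) distance matrix that feeds
the between-community mean-nearest-taxon-distance machinery, and
reconciliation of a community table against the tips actually on the tree.
"""

from __future__ import annotations

import io
import logging

import numpy as np
from skbio import TreeNode

from ._errors import ValidationError
from .table import CommunityTable

logger = logging.getLogger(__name__)


def read_tree(path) -> TreeNode:
    tree = TreeNode.read(str(path), format="newick")
    return _validated(tree)


def parse_newick(newick: str) -> TreeNode:
    return _validated(TreeNode.read(io.StringIO(newick), format="newick"))


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def to_newick(tree: TreeNode) -> str:
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def _validated(tree: TreeNode) -> TreeNode:
    names = tip_names(tree)
    if len(names) != len(set(names)):
        dups = sorted({n for n in names if names.count(n) > 1})
        raise ValidationError(f"duplicate tip label(s) on tree: {dups}")
    for node in tree.traverse(include_self=False):
        if node.length is not None and node.length < 0:
            raise ValidationError("negative branch length on tree")
    return tree


def tip_names(tree: TreeNode) -> list[str]:
    return [t.name for t in tree.tips()]


def cophenetic_matrix(tree: TreeNode, taxa: list[str] | None = None):
    """Patristic distance matrix between tips, ordered as ``taxa``.

    Returns ``(D, order)`` with ``D`` a dense symmetric ndarray.
    """
    dm = tree.tip_tip_distances()
    order = list(dm.ids) if taxa is None else list(taxa)
    pos = {t: i for i, t in enumerate(dm.ids)}
    missing = [t for t in order if t not in pos]
    if missing:
        raise ValidationError(f"taxa not on tree: {missing[:10]}")
    idx = [pos[t] for t in order]
    return dm.data[np.ix_(idx, idx)].copy(), order


def prune_to_table(
    table: CommunityTable, tree: TreeNode, strict: bool = False
) -> tuple[CommunityTable, TreeNode]:
    """Reconcile a table with a tree for tree-based stages.

    Taxa absent from the tree are excluded (logged) unless ``strict``;
    the tree is sheared to the retained taxa.
    """
    tips = set(tip_names(tree))
    on_tree = [t for t in table.taxon_ids if t in tips]
    off_tree = [t for t in table.taxon_ids if t not in tips]
    if off_tree:
        if strict:
            raise ValidationError(f"taxa not on tree: {off_tree[:10]}")
        logger.warning("excluding %d taxa absent from the tree from this stage",
                       len(off_tree))
    if not on_tree:
        raise ValidationError("no taxa shared between table and tree")
    pruned = table.select_taxa(on_tree)
    sheared = tree.shear(on_tree) if len(on_tree) < len(tips) else tree
    return pruned, sheared
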