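"""Branch decomposition of a rooted phylogeny.

UniFrac and abundance-weighted phylogenetic diversity both reduce to sums
over branches of ``length(b) * f(descendant tips of b)``.  This module
turns a scikit-bio TreeNode into a (branch length vector, branch-by-tip
membership matrix) pair once, so every metric is a dense linear-algebra
expression afterwards.
"""

from __future__ import annotations

import numpy as np
from skbio import TreeNode

__all__ = ["branch_matrix", "check_tips_cover"]


def check_tips_cover(tree: TreeNode, asv_ids) -> None:
    """Raise if any of ``asv_ids`` is not a tip of ``tree``."""
    tips = {t.name for t in tree.tips()}
    missing = [a for a in asv_ids if a not in tips]
    if missing:
        raise ValueError(f"ASVs missing from tree: {missing}")


def branch_matrix(tree: TreeNode, tip_order) -> tuple[np.ndarray, np.ndarray]:
    """Decompose a rooted tree into branches over an ordered tip set.

    Parameters
    ----------
    tree
        Rooted tree; branch lengths default to 0 where absent (the root).
    tip_order
        ASV identifiers; every id must be a tip name.

    Returns
    -------
    lengths : (n_branches,) float array
    membership : (n_branches, n_tips) bool array
        ``membership[b, t]`` is True when tip ``t`` descends through
        branch ``b``.  The root itself contributes no branch.
    """
    tip_order = list(tip_order)
    check_tips_cover(tree, tip_order)
    tip_index = {name: i for i, name in enumerate(tip_order)}

    lengths: list[float] = []
    rows: list[np.ndarray] = []
    # postorder: children are visited before parents, so each node's tip
    # set is the union of its children's.
    node_tips: dict[int, np.ndarray] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            mask = np.zeros(len(tip_order), dtype=bool)
            idx = tip_index.get(node.name)
            if idx is not None:
                mask[idx] = True
        else:
            mask = np.zeros(len(tip_order), dtype=bool)
            for child in node.children:
                mask |= node_tips[id(child)]
        node_tips[id(node)] = mask
        if node.parent is not None:  # root carries no branch
            lengths.append(float(node.length or 0.0))
            rows.append(mask)
    return np.asarray(lengths), np.asarray(rows)
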