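"""Newick export for scipy hierarchical-clustering trees."""

from __future__ import annotations

from scipy.cluster.hierarchy import to_tree


def linkage_to_newick(Z, labels) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths.

    Branch lengths are the difference between a node's merge height and its
    parent's, so leaf-to-root distances reproduce the dendrogram heights.
    """
    tree = to_tree(Z)

    def render(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    if tree.is_leaf():
        return f"{labels[tree.id]};"
    left = render(tree.left, tree.dist)
    right = render(tree.right, tree.dist)
    return f"({left},{right});"
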