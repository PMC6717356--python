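"""Dated species trees, independent contrasts, and rank correlation of
gene-count contrasts against a binary lifestyle code.

Contrasts follow Felsenstein's pruning algorithm: at an internal node whose
children carry values x_i, x_j on (adjusted) branch lengths v_i, v_j,

    contrast   = (x_i - x_j) / sqrt(v_i + v_j)
    node value = (x_i/v_i + x_j/v_j) / (1/v_i + 1/v_j)

and the node's parent branch is lengthened by v_i*v_j/(v_i + v_j). The
binary lifestyle code is deliberately treated as a continuous trait.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from scipy import stats as _scipy_stats


@dataclass
class Contrast:
    node_id: str
    value: float


@dataclass
class CorrelationResult:
    rho: float
    p_two_tailed: float
    n: int


# ---------------------------------------------------------------------------
# Trees


def read_tree(path_or_string: str | Path) -> dendropy.Tree:
    """Read a Newick tree from a file path or a literal Newick string."""
    s = str(path_or_string)
    if s.lstrip().startswith("("):
        data, kind = s, "string"
    else:
        data, kind = Path(path_or_string).read_text(), "file"
    tree = dendropy.Tree.get(
        data=data,
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    return tree


def write_tree(tree: dendropy.Tree, path: str | Path) -> None:
    Path(path).write_text(
        tree.as_string(schema="newick", suppress_rooting=True)
    )


def tree_from_node_ages(
    topology: str | Path, node_ages: dict[str, float]
) -> dendropy.Tree:
    """Set branch lengths on a topology from internal-node ages (tips age 0).

    Every internal node must have a label present in ``node_ages``; a child
    older than its parent is an error. Branch length = parent age - own age,
    giving an ultrametric tree in the ages' units.
    """
    tree = read_tree(topology)
    ages: dict[int, float] = {}
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            ages[id(node)] = 0.0
        else:
            label = node.label or (node.taxon.label if node.taxon else None)
            if label is None or label not in node_ages:
                raise ValueError(f"internal node {label!r} has no age entry")
            ages[id(node)] = float(node_ages[label])
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        length = ages[id(node.parent_node)] - ages[id(node)]
        if length <= 0:
            raise ValueError(
                f"non-positive branch implied at node {node.label or node.taxon}: "
                f"parent age {ages[id(node.parent_node)]}, node age {ages[id(node)]}"
            )
        node.edge.length = length
    return tree


def read_node_age_table(path: str | Path) -> dict[str, float]:
    """Two-column TSV: node label, age (Myr)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    return dict(zip(df[0].astype(str), df[1].astype(float)))


# ---------------------------------------------------------------------------
# Trait tables


def read_trait_table(path: str | Path) -> pd.DataFrame:
    """TSV with columns species, lifestyle, intact, partial; adds functional."""
    df = pd.read_csv(path, sep="\t")
    required = {"species", "lifestyle", "intact", "partial"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trait table missing columns: {sorted(missing)}")
    if not set(df["lifestyle"].unique()) <= {0, 1}:
        raise ValueError("lifestyle codes must be 0 or 1")
    df = df.set_index("species")
    df["functional"] = df["intact"] + df["partial"]
    return df


def check_traits_match_tree(tree: dendropy.Tree, traits: pd.DataFrame) -> None:
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    if tips != set(traits.index):
        raise ValueError(
            f"species mismatch: tree-only {sorted(tips - set(traits.index))}, "
            f"table-only {sorted(set(traits.index) - tips)}"
        )


# ---------------------------------------------------------------------------
# Contrasts


def compute_pics(tree: dendropy.Tree, values: dict[str, float]) -> list[Contrast]:
    """Standardized independent contrasts, one per internal node, in
    post-order; contrast sign follows the Newick child order."""
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    missing = tips - set(values)
    if missing:
        raise ValueError(f"values missing for tips: {sorted(missing)}")

    contrasts: list[Contrast] = []
    node_x: dict[int, float] = {}
    node_v: dict[int, float] = {}

    for i, node in enumerate(tree.postorder_node_iter()):
        if node.is_leaf():
            node_x[id(node)] = float(values[node.taxon.label])
            node_v[id(node)] = node.edge.length or 0.0
            continue
        children = node.child_nodes()
        if len(children) != 2:
            raise ValueError(
                f"non-binary node with {len(children)} children; resolve the tree first"
            )
        ci, cj = children
        xi, xj = node_x[id(ci)], node_x[id(cj)]
        vi, vj = node_v[id(ci)], node_v[id(cj)]
        if vi + vj <= 0:
            raise ValueError("zero total branch length at an internal node")
        label = node.label or f"node{i}"
        contrasts.append(Contrast(label, (xi - xj) / math.sqrt(vi + vj)))
        node_x[id(node)] = (xi / vi + xj / vj) / (1.0 / vi + 1.0 / vj)
        node_v[id(node)] = (node.edge.length or 0.0) + vi * vj / (vi + vj)
    return contrasts


# ---------------------------------------------------------------------------
# Correlation


def spearman(
    x: list[float] | list[Contrast],
    y: list[float] | list[Contrast],
    exact: bool = False,
) -> CorrelationResult:
    """Spearman's rho on mid-ranks with a two-tailed t-approximation p-value.

    ``exact=True`` enumerates rank permutations (feasible for n <= 10 only).
    """
    xv = np.asarray([c.value if isinstance(c, Contrast) else c for c in x], float)
    yv = np.asarray([c.value if isinstance(c, Contrast) else c for c in y], float)
    if xv.shape != yv.shape or xv.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d collections")
    n = len(xv)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    rx = _scipy_stats.rankdata(xv, method="average")
    ry = _scipy_stats.rankdata(yv, method="average")
    if np.std(rx) == 0 or np.std(ry) == 0:
        raise ValueError("zero variance in ranks; rho undefined")
    rho = float(np.corrcoef(rx, ry)[0, 1])

    if exact:
        if n > 10:
            raise ValueError("exact permutation p limited to n <= 10")
        obs = abs(rho)
        count = total = 0
        for perm in itertools.permutations(ry):
            r = np.corrcoef(rx, np.asarray(perm))[0, 1]
            total += 1
            if abs(r) >= obs - 1e-12:
                count += 1
        return CorrelationResult(rho, count / total, n)

    if abs(rho) >= 1.0:
        return CorrelationResult(rho, 0.0, n)
    t = rho * math.sqrt((n - 2) / (1 - rho * rho))
    p = 2 * _scipy_stats.t.sf(abs(t), df=n - 2)
    return CorrelationResult(rho, float(min(1.0, p)), n)


def lifestyle_correlation(
    tree: dendropy.Tree,
    traits: pd.DataFrame,
    which: str = "intact",
) -> tuple[CorrelationResult, pd.DataFrame]:
    """Spearman correlation of gene-count PICs vs lifestyle-code PICs.

    ``which`` selects the count column ('intact' or 'functional'). Returns
    the correlation and a table of contrast pairs (scatter-plot data).
    """
    if which not in ("intact", "functional"):
        raise ValueError("which must be 'intact' or 'functional'")
    check_traits_match_tree(tree, traits)
    for col in (which, "lifestyle"):
        if traits[col].nunique() < 2:
            raise ValueError(f"{col} is constant across species; contrasts have zero variance")
    counts = compute_pics(tree, traits[which].to_dict())
    codes = compute_pics(tree, traits["lifestyle"].astype(float).to_dict())
    result = spearman(counts, codes)
    pairs = pd.DataFrame(
        {
            "node": [c.node_id for c in counts],
            f"pic_{which}": [c.value for c in counts],
            "pic_lifestyle": [c.value for c in codes],
        }
    )
    return result, pairs


def through_origin_slope(x: list[Contrast], y: list[Contrast]) -> float:
    """Secondary report: OLS slope of y on x through the origin (the
    conventional regression for standardized contrasts)."""
    xv = np.asarray([c.value for c in x])
    yv = np.asarray([c.value for c in y])
    return float(np.dot(xv, yv) / np.dot(xv, xv))
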