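"""Chemotype analysis: composition-matrix clustering and rule-based calls.

Samples (populations, literature reports) are rows of a composition matrix
of relative percentages.  Sample similarity is Euclidean distance over the
shared compound axis; hierarchical agglomeration uses complete linkage
(inter-cluster distance = maximum pairwise member distance), and the merge
tree can be exported to Newick for unrooted display in standard tree
viewers.

Chemotype assignment is rule-based: a chemotype is called when its marker
compound(s) fall inside published concentration ranges, e.g. an
E-caryophyllene chemotype when that compound contributes 15.6-45.8% of the
volatiles.  The default rule set is packaged as JSON and can be overridden.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "UNCLASSIFIED",
    "ChemotypeRule",
    "ClusterTree",
    "load_rules",
    "validate_composition",
    "euclidean_distances",
    "complete_linkage",
    "to_newick",
    "cut_tree",
    "canonical_name",
    "assign_chemotype",
]

UNCLASSIFIED = "diverse (unclassified)"

_GREEK = {"α": "alpha", "β": "beta", "γ": "gamma", "δ": "delta", "ε": "epsilon"}
_STEREO_PREFIX = re.compile(r"^(e|z|alpha|beta|gamma|delta|cis|trans)-")


def canonical_name(name: str, strip_stereo: bool = False) -> str:
    """Case-folded compound name with Greek letters spelled out; optionally
    strips leading stereo/positional prefixes (E-/Z-/alpha-/beta-/...)."""
    s = name.strip()
    for g, latin in _GREEK.items():
        s = s.replace(g, latin)
    s = s.casefold()
    if strip_stereo:
        while True:
            t = _STEREO_PREFIX.sub("", s)
            if t == s:
                break
            s = t
    return s


@dataclass(frozen=True)
class ChemotypeRule:
    """Marker-compound concentration ranges defining one chemotype."""

    name: str
    markers: tuple[tuple[str, float, float], ...]  # (compound, lo, hi)
    priority: int

    def __post_init__(self) -> None:
        for compound, lo, hi in self.markers:
            if lo > hi:
                raise ValueError(
                    f"rule {self.name!r}: empty range [{lo}, {hi}] for {compound}")

    def matches(self, sample: Mapping[str, float], strip_stereo: bool = False) -> bool:
        canon = {canonical_name(k, strip_stereo): v for k, v in sample.items()}
        for compound, lo, hi in self.markers:
            v = canon.get(canonical_name(compound, strip_stereo), 0.0)
            if not (lo <= v <= hi):
                return False
        return True


def load_rules(path: str | Path | None = None) -> tuple[ChemotypeRule, ...]:
    """Load chemotype rules from JSON; defaults to the packaged rule set."""
    path = Path(path) if path else Path(__file__).parent / "data" / "chemotype_rules.json"
    raw = json.loads(Path(path).read_text(encoding="utf-8"))
    rules = []
    for entry in raw:
        markers = tuple(
            (compound, float(lo), float(hi))
            for compound, (lo, hi) in entry["markers"].items())
        rules.append(ChemotypeRule(
            name=entry["name"], markers=markers, priority=int(entry["priority"])))
    return tuple(sorted(rules, key=lambda r: r.priority))


def assign_chemotype(
    sample: Mapping[str, float] | pd.Series,
    rules: Sequence[ChemotypeRule] | None = None,
    strip_stereo: bool = False,
) -> str:
    """Chemotype call for one composition row; the matching rule with the
    highest priority (lowest priority number) wins, otherwise
    ``diverse (unclassified)``."""
    if isinstance(sample, pd.Series):
        sample = sample.to_dict()
    rules = load_rules() if rules is None else sorted(rules, key=lambda r: r.priority)
    for rule in rules:
        if rule.matches(sample, strip_stereo=strip_stereo):
            return rule.name
    return UNCLASSIFIED


def validate_composition(matrix: pd.DataFrame, tol: float = 5.0) -> pd.DataFrame:
    """Check composition-matrix invariants: non-negative percentages and row
    sums not exceeding 100 by more than ``tol``; missing values become 0."""
    m = matrix.fillna(0.0).astype(float)
    if (m.to_numpy() < 0).any():
        raise ValueError("composition percentages must be non-negative")
    over = m.sum(axis=1) > 100.0 + tol
    if over.any():
        raise ValueError(
            f"row sums exceed 100+{tol}: {list(m.index[over])}")
    return m


def euclidean_distances(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Euclidean distances between samples over the compound axis
    (union of compounds; absences count as 0)."""
    m = validate_composition(matrix)
    if len(m) < 2:
        raise ValueError("need at least 2 samples")
    d = squareform(pdist(m.to_numpy(), metric="euclidean"))
    return pd.DataFrame(d, index=m.index, columns=m.index)


@dataclass(frozen=True)
class ClusterNode:
    """Node of the binary merge tree; leaves carry a sample label."""

    height: float
    label: str | None = None
    left: "ClusterNode | None" = None
    right: "ClusterNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.label is not None

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]
        return self.left.leaves() + self.right.leaves()


@dataclass(frozen=True)
class ClusterTree:
    """Complete-linkage merge tree with heights non-decreasing to the root."""

    root: ClusterNode
    merges: tuple[tuple[tuple[str, ...], tuple[str, ...], float], ...]

    def leaves(self) -> list[str]:
        return self.root.leaves()


def complete_linkage(distances: pd.DataFrame) -> ClusterTree:
    """Agglomerative clustering with complete (maximum) linkage.

    Tie-breaking is deterministic: among pairs at the minimal linkage
    distance the pair whose sorted member-label tuples compare smallest is
    merged first.
    """
    d = distances.to_numpy(dtype=float) if isinstance(distances, pd.DataFrame) \
        else np.asarray(distances, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    labels = [str(x) for x in distances.index] if isinstance(distances, pd.DataFrame) \
        else [str(i) for i in range(d.shape[0])]
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 samples to cluster")

    # active clusters: key -> (sorted member labels, node, member indices)
    clusters: dict[int, tuple[tuple[str, ...], ClusterNode, list[int]]] = {
        i: ((labels[i],), ClusterNode(height=0.0, label=labels[i]), [i])
        for i in range(n)
    }
    merges = []
    while len(clusters) > 1:
        best = None
        keys = sorted(clusters)
        for ai in range(len(keys)):
            for bi in range(ai + 1, len(keys)):
                a, b = keys[ai], keys[bi]
                la, _, ia = clusters[a]
                lb, _, ib = clusters[b]
                link = d[np.ix_(ia, ib)].max()
                pair_key = tuple(sorted((la, lb)))
                cand = (link, pair_key, a, b)
                if best is None or cand < best:
                    best = cand
        link, _, a, b = best
        la, na, ia = clusters.pop(a)
        lb, nb, ib = clusters.pop(b)
        first, second = ((la, na), (lb, nb)) if la <= lb else ((lb, nb), (la, na))
        node = ClusterNode(height=float(link), left=first[1], right=second[1])
        merges.append((first[0], second[0], float(link)))
        clusters[min(a, b)] = (tuple(sorted(la + lb)), node, ia + ib)
    root = next(iter(clusters.values()))[1]
    return ClusterTree(root=root, merges=tuple(merges))


def cut_tree(tree: ClusterTree, k: int) -> dict[str, int]:
    """Partition labels into ``k`` clusters by undoing the last k-1 merges."""
    leaves = tree.leaves()
    n = len(leaves)
    if not (1 <= k <= n):
        raise ValueError(f"k must lie in 1..{n}")
    groups = {lab: {lab} for lab in leaves}
    owner = {lab: lab for lab in leaves}
    for la, lb, _ in tree.merges[: n - k]:
        a, b = owner[la[0]], owner[lb[0]]
        groups[a] |= groups.pop(b)
        for lab in groups[a]:
            owner[lab] = a
    out = {}
    for gi, key in enumerate(sorted(groups)):
        for lab in groups[key]:
            out[lab] = gi
    return out


def _newick_label(label: str) -> str:
    if re.search(r"[\s()\[\]:;,']", label):
        return "'" + label.replace("'", "''") + "'"
    return label


def to_newick(tree: ClusterTree) -> str:
    """Newick export with branch lengths from the merge heights.

    Under the midpoint convention a node at merge height h sits at h/2 from
    its leaves, so a child's branch length is (parent height - child
    height) / 2; two leaves merging at h get h/2 each.
    """
    if len(tree.leaves()) < 2:
        raise ValueError("need at least 2 leaves for Newick export")

    def render(node: ClusterNode) -> str:
        if node.is_leaf:
            return _newick_label(node.label)
        parts = []
        for child in (node.left, node.right):
            blen = (node.height - child.height) / 2.0
            parts.append(f"{render(child)}:{blen:.10g}")
        return "(" + ",".join(parts) + ")"

    return render(tree.root) + ";"
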