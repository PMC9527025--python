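"""Node ages and pairwise divergence times from an ultrametric time tree.

A chronogram is a rooted tree whose branch lengths are in units of absolute
time (here millions of years, My).  On an ultrametric tree every tip is
equidistant from the root, so each internal node has a well-defined age
(tree height minus its root distance) and the divergence time of any two
tips is the age of their most recent common ancestor (MRCA).

Parsing is tolerant of the common Newick dialects: quoted labels, internal
node labels / support values, bracketed comments and exponent-format branch
lengths are accepted; internal labels are ignored.  Deviations from
ultrametricity beyond a relative tolerance are flagged with a warning rather
than an error, since published chronograms are often rounded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import dendropy
import pandas as pd

from .msa import SpeciesMap

__all__ = [
    "Chronogram",
    "PairTimes",
    "UltrametricityReport",
    "ChronogramError",
    "UltrametricityWarning",
    "parse_chronogram",
    "read_chronogram",
    "check_ultrametric",
    "pair_time",
    "pair_time_table",
]

DEFAULT_EPSILON = 1e-6


class ChronogramError(ValueError):
    """Raised for malformed or unusable time trees."""


class UltrametricityWarning(UserWarning):
    """Emitted when root-to-tip path lengths are unequal beyond tolerance."""


@dataclass
class Chronogram:
    """A rooted time tree with node ages in My.

    ``ages`` maps each node to ``height - root_distance``; tip ages within
    ``epsilon * height`` of zero are snapped to exactly zero (extant tips).
    """

    tree: dendropy.Tree
    height: float
    epsilon: float = DEFAULT_EPSILON
    _ages: dict[int, float] = field(repr=False, default_factory=dict)
    _leaves: dict[str, dendropy.Node] = field(repr=False, default_factory=dict)
    #: raw (unsnapped) root-to-tip path length per tip label
    _tip_paths: dict[str, float] = field(repr=False, default_factory=dict)

    @property
    def tip_labels(self) -> list[str]:
        return sorted(self._leaves)

    def __contains__(self, label: str) -> bool:
        return label in self._leaves

    def age(self, node: dendropy.Node) -> float:
        return self._ages[id(node)]

    def tip_age(self, label: str) -> float:
        return self.age(self._node(label))

    def _node(self, label: str) -> dendropy.Node:
        try:
            return self._leaves[label]
        except KeyError:
            raise ChronogramError(f"unknown tip label {label!r}") from None

    def mrca(self, labels: list[str]) -> dendropy.Node:
        """MRCA of a set of tips, by ancestor-path intersection."""
        nodes = [self._node(lb) for lb in labels]
        common: set[int] | None = None
        by_id: dict[int, dendropy.Node] = {}
        for nd in nodes:
            path = set()
            cur = nd
            while cur is not None:
                path.add(id(cur))
                by_id[id(cur)] = cur
                cur = cur.parent_node
            common = path if common is None else common & path
        assert common
        # the shared ancestor of minimal age is the MRCA
        return min((by_id[i] for i in common), key=lambda n: self._ages[id(n)])

    def as_newick(self) -> str:
        s = self.tree.as_string(
            schema="newick", unquoted_underscores=True, suppress_rooting=True
        )
        return s.strip() + "\n"

    def write_newick(self, path: str | Path) -> None:
        Path(path).write_text(self.as_newick())


@dataclass(frozen=True)
class UltrametricityReport:
    height: float
    max_path: float
    min_path: float
    epsilon: float
    #: (max_path - min_path) / height, 0 for a zero-height tree
    relative_spread: float
    passed: bool


def parse_chronogram(
    newick: str, *, epsilon: float = DEFAULT_EPSILON
) -> Chronogram:
    """Parse a Newick string into a :class:`Chronogram`.

    Requires branch lengths on all non-root edges (negative lengths are
    rejected).  A basal polytomy (root degree > 2, typical of trees stored
    unrooted) is accepted with a warning; non-ultrametric path lengths
    beyond ``epsilon`` (relative to tree height) raise an
    :class:`UltrametricityWarning`.
    """
    try:
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ChronogramError(f"malformed Newick: {exc}") from exc

    root = tree.seed_node
    leaves = {}
    dist = {id(root): 0.0}
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        bl = node.edge.length
        if bl is None:
            raise ChronogramError(
                "missing branch length on a non-root edge "
                f"(above {_describe(node)})"
            )
        if bl < 0:
            raise ChronogramError(
                f"negative branch length {bl} above {_describe(node)}"
            )
        dist[id(node)] = dist[id(node.parent_node)] + bl
        if node.is_leaf():
            label = node.taxon.label if node.taxon else node.label
            if label is None:
                raise ChronogramError("leaf without a label")
            if label in leaves:
                raise ChronogramError(f"duplicate tip label {label!r}")
            leaves[label] = node
    if not leaves:
        raise ChronogramError("tree has no labelled tips")

    paths = [dist[id(n)] for n in leaves.values()]
    height = max(paths)
    spread = (height - min(paths)) / height if height > 0 else 0.0
    if spread > epsilon:
        warnings.warn(
            f"tree is not ultrametric: root-to-tip paths span "
            f"{min(paths):.6g}–{height:.6g} "
            f"(relative spread {spread:.3g} > {epsilon:g})",
            UltrametricityWarning,
            stacklevel=2,
        )
    if len(root.child_nodes()) > 2:
        warnings.warn(
            f"basal polytomy of degree {len(root.child_nodes())} "
            "(tree may have been stored unrooted)",
            stacklevel=2,
        )

    ages = {}
    snap = epsilon * height
    for node in tree.preorder_node_iter():
        a = height - dist[id(node)]
        if node.is_leaf() and abs(a) <= snap:
            a = 0.0
        ages[id(node)] = a
    return Chronogram(
        tree=tree,
        height=height,
        epsilon=epsilon,
        _ages=ages,
        _leaves=leaves,
        _tip_paths={lb: dist[id(n)] for lb, n in leaves.items()},
    )


def read_chronogram(path: str | Path, *, epsilon: float = DEFAULT_EPSILON) -> Chronogram:
    return parse_chronogram(Path(path).read_text(), epsilon=epsilon)


def _describe(node: dendropy.Node) -> str:
    if node.is_leaf() and node.taxon is not None:
        return f"tip {node.taxon.label!r}"
    return "an internal node"


def check_ultrametric(
    chron: Chronogram, epsilon: float | None = None
) -> UltrametricityReport:
    """Report the relative spread of root-to-tip path lengths vs a tolerance."""
    eps = chron.epsilon if epsilon is None else epsilon
    paths = list(chron._tip_paths.values())
    hi, lo = max(paths), min(paths)
    spread = (hi - lo) / chron.height if chron.height > 0 else 0.0
    return UltrametricityReport(
        height=chron.height,
        max_path=hi,
        min_path=lo,
        epsilon=eps,
        relative_spread=spread,
        passed=spread <= eps,
    )


def pair_time(chron: Chronogram, a: str, b: str) -> float:
    """Divergence time (My) of two distinct tips = age of their MRCA."""
    if a == b:
        raise ChronogramError("pair_time requires two distinct tips")
    return chron.age(chron.mrca([a, b]))


@dataclass(frozen=True)
class PairTimes:
    """Unordered taxon pairs mapped to MRCA ages in My."""

    times: Mapping[tuple[str, str], float]

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def get(self, a: str, b: str) -> float:
        return self.times[self._key(a, b)]

    def __len__(self) -> int:
        return len(self.times)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return self._key(*pair) in self.times

    def to_dataframe(self) -> pd.DataFrame:
        recs = [
            {"species_a": a, "species_b": b, "time_my": t}
            for (a, b), t in sorted(self.times.items())
        ]
        return pd.DataFrame(recs, columns=["species_a", "species_b", "time_my"])

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def pair_time_table(
    chron: Chronogram,
    sm: SpeciesMap | None = None,
    *,
    cherries_only: bool = False,
) -> PairTimes:
    """Divergence times for all unordered taxon pairs.

    Without a species map, tips are the taxa.  With one, each species'
    time to another is the age of the MRCA of the union of their tips; a
    species whose tips are not monophyletic is used as-is with a warning
    (the MRCA age never underestimates the pair time).  ``cherries_only``
    keeps only pairs whose joint MRCA subtends no third taxon, the pairs a
    node-dating study would read directly off the tree.
    """
    if sm is None:
        groups = {lb: [lb] for lb in chron.tip_labels}
    else:
        groups = {}
        for lb in chron.tip_labels:
            groups.setdefault(sm.species_of(lb), []).append(lb)
        absent = [sp for sp in sm.species if sp not in groups]
        if absent:
            raise ChronogramError(
                f"species with no tips in the chronogram: {absent!r}"
            )
        for species, tips in groups.items():
            if len(tips) > 1 and not _is_monophyletic(chron, tips):
                warnings.warn(
                    f"species {species!r} is not monophyletic in the "
                    "chronogram; using the MRCA age of all its tips",
                    stacklevel=2,
                )
    names = sorted(groups)
    if len(names) < 2:
        raise ChronogramError("need at least two taxa for a pair-time table")
    label_species = {
        lb: sp for sp, tips in groups.items() for lb in tips
    }
    times: dict[tuple[str, str], float] = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            node = chron.mrca(groups[a] + groups[b])
            if cherries_only:
                under = {
                    label_species[lf.taxon.label]
                    for lf in node.leaf_iter()
                }
                if under != {a, b}:
                    continue
            times[(a, b)] = chron.age(node)
    if cherries_only and len(times) < 1:
        raise ChronogramError("no cherry pairs found")
    return PairTimes(times=times)


def _is_monophyletic(chron: Chronogram, tips: list[str]) -> bool:
    node = chron.mrca(tips)
    under = {lf.taxon.label for lf in node.leaf_iter()}
    return under == set(tips)
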