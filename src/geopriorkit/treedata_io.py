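"""Trees, tip-area tables and MCMC trace logs: parsing, validation, round-trips.

Newick and NEXUS parsing is delegated to dendropy; parsed trees are converted
into an index-based :class:`TimeTree` (flat parent/children/branch-length
arrays in postorder) that the pruning likelihood and the stochastic-mapping
samplers iterate over directly. Branch lengths are calendar times: the
sequential-inference workflow supplies time-calibrated trees, so no clock
rescaling is ever attempted here.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import dendropy

from .geomodel import GeoAlphabet


class ParseError(ValueError):
    """Malformed tree, table, or trace input."""


class ConsistencyError(ValueError):
    """Inputs that parse but are mutually inconsistent (tip sets, bindings)."""


class TimeTree:
    """Rooted binary time-calibrated tree over indexed nodes.

    Nodes are integers ``0..n_nodes-1``; tips come first (``0..n_tips-1``) in
    the order their labels were encountered. ``parent[root] == -1`` and
    ``blen[root] == 0``. Polytomies are resolved left-to-right with zero-length
    branches at construction; the CTMC likelihood is invariant to the
    resolution because P(0) is the identity.
    """

    __slots__ = ("parent", "blen", "children", "labels", "root", "postorder",
                 "preorder")

    def __init__(self, parent: np.ndarray, blen: np.ndarray,
                 children: Sequence[Sequence[int]],
                 labels: Sequence[Optional[str]]):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.blen = np.asarray(blen, dtype=float)
        self.children = tuple(tuple(c) for c in children)
        self.labels = tuple(labels)
        n = len(self.parent)
        if np.any(self.blen < 0):
            raise ParseError("negative branch length")
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise ParseError(f"tree must have exactly one root, found {len(roots)}")
        self.root = int(roots[0])
        for i, ch in enumerate(self.children):
            if len(ch) not in (0, 2):
                raise ParseError(f"node {i} has {len(ch)} children; tree not binary")
        tips = [self.labels[i] for i in range(n) if not self.children[i]]
        if any(lbl is None for lbl in tips):
            raise ParseError("unlabeled tip")
        if len(set(tips)) != len(tips):
            dup = sorted({t for t in tips if tips.count(t) > 1})
            raise ParseError(f"duplicate tip labels: {dup}")
        # postorder (children before parents) and preorder via explicit stack
        post, pre, stack = [], [], [(self.root, False)]
        while stack:
            node, done = stack.pop()
            if done:
                post.append(node)
                continue
            pre.append(node)
            stack.append((node, True))
            for c in reversed(self.children[node]):
                stack.append((c, False))
        self.postorder = np.asarray(post, dtype=np.int64)
        self.preorder = np.asarray(pre, dtype=np.int64)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def tip_indices(self) -> np.ndarray:
        return np.asarray([i for i in range(self.n_nodes) if not self.children[i]],
                          dtype=np.int64)

    @property
    def n_tips(self) -> int:
        return len(self.tip_indices)

    @property
    def tip_labels(self) -> tuple[str, ...]:
        return tuple(self.labels[i] for i in self.tip_indices)

    @property
    def tree_length(self) -> float:
        return float(self.blen.sum())

    def with_branch_lengths(self, blen: np.ndarray) -> "TimeTree":
        """Same topology and labels, new branch lengths."""
        return TimeTree(self.parent.copy(), blen, self.children, self.labels)

    def to_newick(self) -> str:
        parts: dict[int, str] = {}
        for node in self.postorder:
            node = int(node)
            if self.children[node]:
                inner = ",".join(parts[c] for c in self.children[node])
                s = f"({inner})"
            else:
                s = self.labels[node]
            if node != self.root:
                s += f":{self.blen[node]:.12g}"
            parts[node] = s
        return parts[self.root] + ";"

    def __repr__(self) -> str:
        return f"<TimeTree {self.n_tips} tips, length {self.tree_length:.4g}>"


def _from_dendropy(dtree: "dendropy.Tree") -> TimeTree:
    parent: list[int] = []
    blen: list[float] = []
    children: list[list[int]] = []
    labels: list[Optional[str]] = []

    def new_node(par: int, length: Optional[float], label: Optional[str]) -> int:
        idx = len(parent)
        parent.append(par)
        blen.append(0.0 if length is None else float(length))
        children.append([])
        labels.append(label)
        if par >= 0:
            children[par].append(idx)
        return idx

    seed = dtree.seed_node
    stack = [(seed, -1, True)]
    while stack:
        dnode, par, is_root = stack.pop()
        length = None if is_root else dnode.edge.length
        if not is_root and length is None:
            raise ParseError(
                f"missing branch length on edge above "
                f"{dnode.taxon.label if dnode.taxon else 'an internal node'!r}"
            )
        label = dnode.taxon.label if dnode.taxon is not None else None
        kids = list(dnode.child_nodes())
        if not kids:
            new_node(par, length, label)
            continue
        if len(kids) == 1:
            raise ParseError("unifurcation (node with a single child)")
        idx = new_node(par, length, None)
        # resolve polytomies left-to-right: (c1,(c2,(c3,...):0):0)
        holder = idx
        for pos, kid in enumerate(kids):
            if pos < len(kids) - 2:
                stack.append((kid, holder, False))
                holder = new_node(holder, 0.0, None)
            else:
                stack.append((kid, holder, False))
    return TimeTree(np.asarray(parent), np.asarray(blen), children, labels)


def parse_newick(text: str) -> TimeTree:
    """Parse a single Newick string into a :class:`TimeTree`."""
    try:
        dtree = dendropy.Tree.get(data=text, schema="newick",
                                  suppress_internal_node_taxa=True,
                                  rooting="default-rooted")
    except Exception as exc:  # dendropy raises several error classes
        raise ParseError(f"newick parse failure: {exc}") from exc
    return _from_dendropy(dtree)


@dataclass
class TreeSet:
    """Ordered collection of trees over one shared tip-label set."""

    trees: tuple[TimeTree, ...]
    burnin_discarded: bool = False

    def __post_init__(self) -> None:
        if not self.trees:
            raise ConsistencyError("TreeSet must be nonempty")
        self.trees = tuple(self.trees)
        ref = set(self.trees[0].tip_labels)
        for i, t in enumerate(self.trees[1:], start=1):
            if set(t.tip_labels) != ref:
                raise ConsistencyError(
                    f"tree {i} has a different tip set than tree 0"
                )

    def __len__(self) -> int:
        return len(self.trees)

    def __getitem__(self, i: int) -> TimeTree:
        return self.trees[i]

    def __iter__(self):
        return iter(self.trees)

    @property
    def mean_tree_length(self) -> float:
        return float(np.mean([t.tree_length for t in self.trees]))


def as_tree_set(trees: Union[TimeTree, TreeSet, Sequence[TimeTree]]) -> TreeSet:
    """Wrap a single tree (or sequence) as a TreeSet; pass TreeSets through."""
    if isinstance(trees, TreeSet):
        return trees
    if isinstance(trees, TimeTree):
        return TreeSet((trees,))
    return TreeSet(tuple(trees))


def parse_trees_file(path: str, format: str = "newick",
                     burnin_fraction: float = 0.0) -> TreeSet:
    """Read a tree file (``newick`` lines or ``nexus`` trees block).

    The first ``floor(burnin_fraction * N)`` trees are discarded. NEXUS
    Translate tables are honored (taxon numbers restored to names).
    """
    if not 0.0 <= burnin_fraction < 1.0:
        raise ValueError("burnin_fraction must be in [0, 1)")
    schema = {"newick": "newick", "newick-lines": "newick", "nexus": "nexus"}.get(
        format.lower())
    if schema is None:
        raise ValueError(f"unknown tree file format {format!r}")
    try:
        tlist = dendropy.TreeList.get(path=path, schema=schema,
                                      suppress_internal_node_taxa=True,
                                      rooting="default-rooted")
    except Exception as exc:
        raise ParseError(f"could not parse trees file {path!r}: {exc}") from exc
    if len(tlist) == 0:
        raise ParseError(f"no trees found in {path!r}")
    trees = [_from_dendropy(t) for t in tlist]
    drop = int(burnin_fraction * len(trees))
    kept = trees[drop:]
    return TreeSet(tuple(kept), burnin_discarded=drop > 0)


def write_trees_file(trees: Union[TimeTree, TreeSet], path: str) -> None:
    """Write one Newick string per line."""
    ts = as_tree_set(trees)
    with open(path, "w") as fh:
        for t in ts:
            fh.write(t.to_newick() + "\n")


def tree_length(tree: TimeTree) -> float:
    """Sum of all branch lengths (total evolutionary time on the tree)."""
    return tree.tree_length


# ---------------------------------------------------------------------------
# Tip-area tables


@dataclass
class TipAreas:
    """Mapping of taxon label -> sampled area, with its area alphabet."""

    mapping: dict[str, str]
    alphabet: GeoAlphabet

    def __post_init__(self) -> None:
        for taxon, area in self.mapping.items():
            if area not in self.alphabet.areas:
                raise ConsistencyError(
                    f"taxon {taxon!r} maps to area {area!r} not in alphabet"
                )

    def __len__(self) -> int:
        return len(self.mapping)

    @property
    def area_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for area in self.mapping.values():
            counts[area] = counts.get(area, 0) + 1
        return counts

    def bind(self, tree: TimeTree) -> np.ndarray:
        """Per-node array of area indices (-1 for internal nodes).

        Raises :class:`ConsistencyError` listing any tree tips absent from the
        table.
        """
        states = np.full(tree.n_nodes, -1, dtype=np.int64)
        missing = []
        for i in tree.tip_indices:
            label = tree.labels[i]
            if label not in self.mapping:
                missing.append(label)
            else:
                states[i] = self.alphabet.index(self.mapping[label])
        if missing:
            raise ConsistencyError(f"tips missing from the area table: {sorted(missing)}")
        return states


def read_tip_area_table(path: str,
                        alphabet: Optional[GeoAlphabet] = None) -> TipAreas:
    """Read a two-column TSV ``taxon<TAB>area`` (header required).

    The alphabet defaults to the sorted distinct observed areas; supply one
    explicitly when unobserved areas must be modelled (or when fewer than two
    areas are observed).
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment=None)
    except pd.errors.EmptyDataError:
        raise ParseError(f"empty tip-area table {path!r}") from None
    cols = [c.strip().lower() for c in df.columns]
    if len(df.columns) < 2 or cols[:2] != ["taxon", "area"]:
        raise ParseError(
            f"tip-area table must have header 'taxon<TAB>area', got {list(df.columns)}"
        )
    if len(df) == 0:
        raise ParseError(f"tip-area table {path!r} has a header but no rows")
    taxa = df.iloc[:, 0].astype(str)
    if taxa.duplicated().any():
        dup = sorted(taxa[taxa.duplicated()].unique())
        raise ParseError(f"duplicate taxon rows: {dup}")
    mapping = dict(zip(taxa, df.iloc[:, 1].astype(str)))
    if alphabet is None:
        observed = sorted(set(mapping.values()))
        if len(observed) < 2:
            raise ParseError(
                "only one distinct area observed; supply an explicit alphabet"
            )
        alphabet = GeoAlphabet(tuple(observed))
    return TipAreas(mapping=mapping, alphabet=alphabet)


def write_tip_area_table(tips: TipAreas, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("taxon\tarea\n")
        for taxon, area in tips.mapping.items():
            fh.write(f"{taxon}\t{area}\n")


# ---------------------------------------------------------------------------
# MCMC trace logs (BEAST-style tab-delimited)


@dataclass
class Trace:
    """Tab-delimited MCMC sample table with its likelihood power ``beta``.

    The first column is ``state`` (the iteration index, strictly increasing);
    the remaining columns are sampled parameters and derived quantities. beta
    is the power on the likelihood the chain targeted (0 = prior, 1 = plain
    posterior, integers > 1 = data-cloning powers).
    """

    table: pd.DataFrame
    beta: float = 1.0

    def __post_init__(self) -> None:
        if "state" not in self.table.columns:
            raise ParseError("trace must contain a 'state' column")
        states = self.table["state"].to_numpy()
        if len(states) > 1 and not np.all(np.diff(states) > 0):
            raise ParseError("'state' column must be strictly increasing")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def parameters(self) -> list[str]:
        return [c for c in self.table.columns if c != "state"]

    def __getitem__(self, col: str) -> np.ndarray:
        return self.table[col].to_numpy()

    def burned(self, burnin_fraction: float) -> "Trace":
        """Drop the first floor(burnin_fraction * N) rows."""
        if not 0.0 <= burnin_fraction < 1.0:
            raise ValueError("burnin_fraction must be in [0, 1)")
        drop = int(burnin_fraction * len(self.table))
        return Trace(self.table.iloc[drop:].reset_index(drop=True), beta=self.beta)


def read_trace(path: str) -> Trace:
    """Read a tab-delimited trace log ('#' comments; first column ``state``)."""
    beta = 1.0
    header: Optional[list[str]] = None
    rows: list[list[str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                stripped = line[1:].strip()
                if stripped.lower().startswith("beta"):
                    try:
                        beta = float(stripped.split("=", 1)[1])
                    except (IndexError, ValueError):
                        pass
                continue
            fields = line.split("\t")
            if header is None:
                header = [f.strip() for f in fields]
                continue
            if len(fields) != len(header):
                raise ParseError(
                    f"{path}:{lineno}: row has {len(fields)} fields, "
                    f"expected {len(header)}"
                )
            rows.append(fields)
    if header is None:
        raise ParseError(f"trace {path!r} has no header row")
    if header[0] != "state":
        raise ParseError(f"first trace column must be 'state', got {header[0]!r}")
    df = pd.DataFrame(rows, columns=header)
    for col in df.columns:
        df[col] = pd.to_numeric(df[col])
    return Trace(df, beta=beta)


def write_trace(trace: Trace, path: str) -> None:
    """Write a trace log; beta recorded in a '#' comment header line."""
    with open(path, "w") as fh:
        fh.write(f"# beta = {trace.beta:.12g}\n")
        trace.table.to_csv(fh, sep="\t", index=False, float_format="%.12g")
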