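"""Variant-annotated haplotype backbone trees for Y-chromosome lineage analysis.

The male-specific region of the Y chromosome (MSY) does not recombine, so the
haplotypes observed in a population are related by a single rooted tree.  Each
haplotype-determining "key" variant marks exactly one edge of that tree: every
sample below the edge carries the derived allele, every sample elsewhere the
ancestral one (infinite-sites assumption).  This module models that backbone:
parsing a variant panel, reading/writing the tree as Newick with labelled
internal nodes, reconstructing the tree from a binary sample x variant matrix
(rooted perfect phylogeny), condensing clades into sub-haplogroups (sHGs) and
validating structural counts.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "Variant",
    "BackboneNode",
    "BackboneTree",
    "SHGMap",
    "PerfectPhylogeny",
    "PanelError",
    "BackboneParseError",
    "VariantLinkError",
    "IncompatibleMatrixError",
    "SHGMappingError",
    "parse_variant_panel",
    "write_variant_panel",
    "parse_backbone",
    "build_tree_from_matrix",
    "condense_shg",
    "validate_backbone",
]

MARKER_CLASSES = ("SNP", "indel", "microsatellite")


class PanelError(ValueError):
    """Malformed variant panel (duplicate ids, bad states, bad columns)."""


class BackboneParseError(ValueError):
    """Newick backbone that violates the labelled-internal-node contract."""


class VariantLinkError(ValueError):
    """A placed variant references an edge (child-node name) not in the tree."""


class IncompatibleMatrixError(ValueError):
    """Binary matrix not compatible with a single rooted tree.

    Carries ``pairs``: the list of (variant_a, variant_b) tuples for which the
    gamete test fails (with known ancestral states, a pair is incompatible when
    the joint patterns 01, 10 and 11 all occur; the 00 gamete is implicit at
    the all-ancestral root).
    """

    def __init__(self, pairs: Sequence[tuple[str, str]]):
        self.pairs = list(pairs)
        shown = ", ".join(f"{a}/{b}" for a, b in self.pairs[:5])
        more = "" if len(self.pairs) <= 5 else f" (+{len(self.pairs) - 5} more)"
        super().__init__(f"matrix incompatible with a tree: {shown}{more}")


class SHGMappingError(ValueError):
    """sHG labels that are not valid, non-overlapping subtree roots."""


@dataclass(frozen=True)
class Variant:
    """One haplotype-determining marker.

    ``edge`` names the backbone node *below* the edge the derived allele
    defines; ``None`` for an unplaced marker.  ``derived_states`` may hold
    more than one token for a microsatellite used as a simple branch marker.
    """

    id: str
    marker_class: str = "SNP"
    ancestral_state: str = "0"
    derived_states: frozenset[str] = frozenset({"1"})
    edge: str | None = None

    def __post_init__(self) -> None:
        if self.marker_class not in MARKER_CLASSES:
            raise PanelError(
                f"variant {self.id!r}: unknown marker class {self.marker_class!r}"
            )
        if not self.derived_states:
            raise PanelError(f"variant {self.id!r}: empty derived-state set")
        if self.ancestral_state in self.derived_states:
            raise PanelError(
                f"variant {self.id!r}: ancestral state {self.ancestral_state!r} "
                "also listed as derived"
            )

    @property
    def placed(self) -> bool:
        return self.edge is not None


@dataclass
class BackboneNode:
    """A named haplotype/haplogroup node; ``variants`` sit on its parent edge."""

    name: str
    parent: str | None
    children: list[str] = field(default_factory=list)
    variants: list[str] = field(default_factory=list)

    @property
    def is_terminal(self) -> bool:
        return not self.children

    @property
    def is_junction(self) -> bool:
        """True for a non-root node whose parent edge carries no variant."""
        return self.parent is not None and not self.variants


class BackboneTree:
    """Rooted haplotype tree with variants attached to edges.

    Nodes are addressed by unique name.  ``crown_root`` optionally marks the
    root of the "Crown" clade (the recent expansion haplogroup to which most
    modern samples belong); it may equal the tree root, in which case the
    whole tree counts as Crown.
    """

    def __init__(
        self,
        root: str,
        nodes: Mapping[str, BackboneNode],
        panel: Sequence[Variant] = (),
        crown_root: str | None = None,
    ):
        self.root = root
        self.nodes: dict[str, BackboneNode] = dict(nodes)
        self.panel: list[Variant] = list(panel)
        self.crown_root = crown_root
        self.variant_index: dict[str, Variant] = {v.id: v for v in self.panel}
        self._validate()
        self._path_cache: dict[str, tuple[str, ...]] = {}

    # -- structure -----------------------------------------------------

    def _validate(self) -> None:
        if self.root not in self.nodes:
            raise BackboneParseError(f"root {self.root!r} not among nodes")
        if self.nodes[self.root].parent is not None:
            raise BackboneParseError("root must have no parent")
        if self.nodes[self.root].variants:
            raise BackboneParseError("root carries defining variants")
        seen: set[str] = set()
        stack = [self.root]
        while stack:
            name = stack.pop()
            if name in seen:
                raise BackboneParseError(f"cycle or duplicate at {name!r}")
            seen.add(name)
            node = self.nodes[name]
            for ch in node.children:
                if ch not in self.nodes:
                    raise BackboneParseError(f"child {ch!r} of {name!r} missing")
                if self.nodes[ch].parent != name:
                    raise BackboneParseError(f"parent link broken at {ch!r}")
                stack.append(ch)
        if seen != set(self.nodes):
            orphans = sorted(set(self.nodes) - seen)
            raise BackboneParseError(f"unreachable nodes: {orphans}")
        if len(self.variant_index) != len(self.panel):
            raise PanelError("duplicate variant ids in panel")
        for v in self.panel:
            if v.placed and v.edge not in self.nodes:
                raise VariantLinkError(
                    f"variant {v.id!r} placed on missing edge {v.edge!r}"
                )
        if self.crown_root is not None and self.crown_root not in self.nodes:
            raise BackboneParseError(f"crown root {self.crown_root!r} missing")

    def __contains__(self, name: str) -> bool:
        return name in self.nodes

    def preorder(self, start: str | None = None) -> Iterator[str]:
        stack = [start or self.root]
        while stack:
            name = stack.pop()
            yield name
            stack.extend(reversed(self.nodes[name].children))

    def path(self, name: str) -> tuple[str, ...]:
        """Node names from the root down to ``name`` (inclusive)."""
        cached = self._path_cache.get(name)
        if cached is not None:
            return cached
        chain = []
        cur: str | None = name
        while cur is not None:
            chain.append(cur)
            cur = self.nodes[cur].parent
        out = tuple(reversed(chain))
        self._path_cache[name] = out
        return out

    def path_variants(self, name: str) -> tuple[str, ...]:
        """Variant ids on the edges from the root down to ``name``, in order."""
        out: list[str] = []
        for n in self.path(name):
            out.extend(self.nodes[n].variants)
        return tuple(out)

    def is_ancestor_or_self(self, anc: str, desc: str) -> bool:
        return anc in self.path(desc)

    def tips(self, start: str | None = None) -> list[str]:
        return [n for n in self.preorder(start) if self.nodes[n].is_terminal]

    def depth(self, name: str) -> int:
        return len(self.path(name)) - 1

    def crown_nodes(self) -> set[str]:
        """Names of all nodes in the Crown clade (empty set if undefined)."""
        if self.crown_root is None:
            return set()
        return set(self.preorder(self.crown_root))

    @property
    def panel_order(self) -> list[str]:
        return [v.id for v in self.panel]

    def unplaced_variants(self) -> list[str]:
        return [v.id for v in self.panel if not v.placed]

    # -- serialization ---------------------------------------------------

    def to_newick(self) -> str:
        def q(label: str) -> str:
            safe = label.replace("_", "").replace("-", "").replace(".", "")
            if safe.isalnum() and " " not in label:
                return label
            return "'" + label.replace("'", "''") + "'"

        def rec(name: str) -> str:
            node = self.nodes[name]
            if node.is_terminal:
                return q(name)
            inner = ",".join(rec(c) for c in node.children)
            return f"({inner}){q(name)}"

        return rec(self.root) + ";"

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BackboneTree):
            return NotImplemented
        shape = lambda t: {
            n: (nd.parent, tuple(nd.children), tuple(nd.variants))
            for n, nd in t.nodes.items()
        }
        return (
            self.root == other.root
            and self.crown_root == other.crown_root
            and shape(self) == shape(other)
            and self.panel == other.panel
        )

    def __repr__(self) -> str:
        return (
            f"<BackboneTree root={self.root!r} nodes={len(self.nodes)} "
            f"variants={len(self.panel)}>"
        )


@dataclass
class SHGMap:
    """Condensation of haplotype nodes into sub-haplogroup (sHG) labels."""

    mapping: dict[str, str]
    shg_count: int

    def label(self, node: str) -> str | None:
        return self.mapping.get(node)


@dataclass
class PerfectPhylogeny:
    """Result of :func:`build_tree_from_matrix`.

    ``sample_to_node`` maps every input sample to the tree node whose
    root-to-node variant set equals the sample's derived set.
    """

    tree: BackboneTree
    sample_to_node: dict[str, str]
    dropped_variants: list[str] = field(default_factory=list)
    unplaced_variants: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Panel I/O
# ---------------------------------------------------------------------------

PANEL_COLUMNS = ["id", "marker_class", "ancestral", "derived", "edge"]


def parse_variant_panel(source) -> list[Variant]:
    """Read a variant panel from CSV (path, file handle, text, or DataFrame).

    Columns: ``id,marker_class,ancestral,derived,edge``; the ``derived`` field
    is a ``|``-separated allele set and an empty ``edge`` marks an unplaced
    variant.  An empty table yields an empty panel.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        if isinstance(source, str) and "\n" in source:
            source = io.StringIO(source)
        df = pd.read_csv(source, dtype=str, keep_default_na=False)
    if df.empty and not set(PANEL_COLUMNS) <= set(df.columns):
        return []
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise PanelError(f"panel missing columns: {missing}")
    dupes = df["id"][df["id"].duplicated()].unique().tolist()
    if dupes:
        raise PanelError(f"duplicate variant ids: {dupes}")
    out = []
    for row in df.itertuples(index=False):
        derived = frozenset(s for s in str(row.derived).split("|") if s)
        out.append(
            Variant(
                id=row.id,
                marker_class=row.marker_class or "SNP",
                ancestral_state=row.ancestral,
                derived_states=derived,
                edge=row.edge or None,
            )
        )
    return out


def write_variant_panel(panel: Sequence[Variant], path) -> None:
    rows = [
        {
            "id": v.id,
            "marker_class": v.marker_class,
            "ancestral": v.ancestral_state,
            "derived": "|".join(sorted(v.derived_states)),
            "edge": v.edge or "",
        }
        for v in panel
    ]
    pd.DataFrame(rows, columns=PANEL_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Newick parsing
# ---------------------------------------------------------------------------


def parse_backbone(
    newick: str,
    panel: Sequence[Variant] = (),
    crown_root: str | None = None,
) -> BackboneTree:
    """Build a :class:`BackboneTree` from Newick text plus a variant panel.

    Every internal node must carry a unique label; branch lengths are
    accepted and ignored.  Placed panel variants are attached to the edge
    above the node they name; a variant naming a missing node raises
    :class:`VariantLinkError`.
    """
    dtree = dendropy.Tree.get(
        data=newick,
        schema="newick",
        preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )
    nodes: dict[str, BackboneNode] = {}

    def name_of(nd: dendropy.Node) -> str | None:
        if nd.taxon is not None:
            return nd.taxon.label
        return nd.label

    def rec(nd: dendropy.Node, parent: str | None) -> str:
        name = name_of(nd)
        if not name:
            raise BackboneParseError("unlabeled node in backbone Newick")
        if name in nodes:
            raise BackboneParseError(f"duplicate node label {name!r}")
        nodes[name] = BackboneNode(name=name, parent=parent)
        for child in nd.child_nodes():
            nodes[name].children.append(rec(child, name))
        return name

    root = rec(dtree.seed_node, None)
    for v in panel:
        if v.placed:
            if v.edge not in nodes:
                raise VariantLinkError(
                    f"variant {v.id!r} references missing node {v.edge!r}"
                )
            nodes[v.edge].variants.append(v.id)
    return BackboneTree(root, nodes, panel=panel, crown_root=crown_root)


# ---------------------------------------------------------------------------
# Perfect phylogeny from a binary matrix
# ---------------------------------------------------------------------------


def incompatible_pairs(matrix: pd.DataFrame) -> list[tuple[str, str]]:
    """All variant pairs failing the rooted gamete test.

    With ancestral states known, two variants fit on one rooted tree iff
    their carrier sets are disjoint or nested — equivalently, iff the joint
    patterns 01, 10 and 11 do not all occur (00 sits at the root).  Exhaustive
    O(m^2) scan, vectorised.
    """
    a = matrix.to_numpy(dtype=np.int8)
    n11 = a.T @ a
    n10 = a.T @ (1 - a)
    bad = (n11 > 0) & (n10 > 0) & (n10.T > 0)
    cols = matrix.columns
    out = []
    for i, j in zip(*np.nonzero(np.triu(bad, k=1))):
        out.append((cols[i], cols[j]))
    return out


def build_tree_from_matrix(
    matrix: pd.DataFrame, drop_recurrent: bool = False
) -> PerfectPhylogeny:
    """Rooted perfect phylogeny from a 0/1 sample x variant matrix.

    Each variant labels exactly one edge; variants with identical carrier
    columns collapse onto the same edge.  Synthesized node names are "N<k>"
    in deterministic preorder (root "N0"); sibling edges are ordered by
    decreasing carrier count, then by smallest variant id.

    With ``drop_recurrent`` the column involved in the most gamete conflicts
    is removed greedily (ties broken lexicographically by variant id) until
    the matrix is compatible; dropped ids are reported in the result.
    Otherwise an incompatible matrix raises :class:`IncompatibleMatrixError`.
    """
    vals = matrix.to_numpy()
    if matrix.isna().any().any():
        raise PanelError("matrix contains missing values; mask upstream")
    if not np.isin(vals, (0, 1)).all():
        raise PanelError("matrix entries must be 0/1")
    work = matrix.astype(np.int8)
    dropped: list[str] = []
    while True:
        pairs = incompatible_pairs(work)
        if not pairs:
            break
        if not drop_recurrent:
            raise IncompatibleMatrixError(pairs)
        tally: dict[str, int] = {}
        for x, y in pairs:
            tally[x] = tally.get(x, 0) + 1
            tally[y] = tally.get(y, 0) + 1
        worst = sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
        dropped.append(worst)
        work = work.drop(columns=[worst])

    samples = list(work.index.astype(str))
    # group identical columns -> one edge each
    groups: dict[frozenset[str], list[str]] = {}
    unplaced: list[str] = []
    for vid in work.columns:
        carriers = frozenset(str(s) for s in work.index[work[vid] == 1])
        if not carriers:
            unplaced.append(str(vid))
            continue
        groups.setdefault(carriers, []).append(str(vid))
    # variant ids stay in matrix-column (panel) order within each group

    ordered = sorted(
        groups.items(), key=lambda kv: (-len(kv[0]), kv[1][0])
    )  # big clades first, then first variant id
    # parent of a group = smallest strict superset group, else root
    parent_of: dict[int, int | None] = {}
    for i, (si, _) in enumerate(ordered):
        best: int | None = None
        for j in range(i):  # supersets sort before i
            sj = ordered[j][0]
            if si < sj and (best is None or len(sj) < len(ordered[best][0])):
                best = j
        parent_of[i] = best

    children: dict[int | None, list[int]] = {None: []}
    for i in range(len(ordered)):
        children.setdefault(i, [])
        children.setdefault(parent_of[i], []).append(i)
    for sibs in children.values():
        sibs.sort(key=lambda i: (-len(ordered[i][0]), ordered[i][1][0]))

    # preorder naming
    names: dict[int | None, str] = {}
    counter = 0

    def assign(idx: int | None) -> None:
        nonlocal counter
        names[idx] = f"N{counter}"
        counter += 1
        for c in children.get(idx, []):
            assign(c)

    assign(None)

    nodes: dict[str, BackboneNode] = {}

    def build(idx: int | None, parent: str | None) -> None:
        name = names[idx]
        variants = [] if idx is None else list(ordered[idx][1])
        nodes[name] = BackboneNode(name=name, parent=parent, variants=variants)
        for c in children.get(idx, []):
            nodes[name].children.append(names[c])
            build(c, name)

    build(None, None)

    # panel: binary abstract states, placed on their edge
    edge_of = {
        vid: names[i] for i, (_, vids) in enumerate(ordered) for vid in vids
    }
    panel = [
        Variant(id=str(vid), edge=edge_of.get(str(vid)))
        for vid in work.columns
    ]
    tree = BackboneTree(names[None], nodes, panel=panel, crown_root=None)

    # sample -> node with matching path set: the smallest group containing it
    sample_to_node: dict[str, str] = {}
    by_sample: dict[str, int | None] = {s: None for s in samples}
    for i, (si, _) in enumerate(ordered):
        for s in si:
            cur = by_sample[s]
            if cur is None or si < ordered[cur][0]:
                by_sample[s] = i
    for s in samples:
        sample_to_node[s] = names[by_sample[s]]
    return PerfectPhylogeny(
        tree=tree,
        sample_to_node=sample_to_node,
        dropped_variants=dropped,
        unplaced_variants=unplaced,
    )


# ---------------------------------------------------------------------------
# sHG condensation and validation
# ---------------------------------------------------------------------------


def condense_shg(tree: BackboneTree, shg_table: Mapping[str, str]) -> SHGMap:
    """Condense whole subtrees into sHG labels.

    ``shg_table`` maps subtree-root node names to sHG labels.  Roots must be
    existing nodes and must not nest (an sHG is a union of whole, disjoint
    subtrees); every node under a root inherits its label.
    """
    roots = list(shg_table)
    for r in roots:
        if r not in tree:
            raise SHGMappingError(f"sHG root {r!r} is not a tree node")
    for a in roots:
        for b in roots:
            if a != b and tree.is_ancestor_or_self(a, b):
                raise SHGMappingError(f"sHG roots nest: {a!r} contains {b!r}")
    mapping: dict[str, str] = {}
    for r, label in shg_table.items():
        for n in tree.preorder(r):
            mapping[n] = label
    return SHGMap(mapping=mapping, shg_count=len(set(shg_table.values())))


def validate_backbone(tree: BackboneTree) -> dict:
    """Structural report: terminal/inner counts inside and outside the Crown,
    unplaced panel variants and variant-less junction nodes.  The root is not
    counted as an inner haplotype."""
    crown = tree.crown_nodes()
    report = {
        "n_nodes": len(tree.nodes),
        "crown_terminal": 0,
        "crown_inner": 0,
        "noncrown_terminal": 0,
        "noncrown_inner": 0,
        "junction_nodes": [],
        "unplaced_variants": tree.unplaced_variants(),
    }
    for name in tree.preorder():
        node = tree.nodes[name]
        if node.is_junction:
            report["junction_nodes"].append(name)
        if name == tree.root:
            continue
        key = (
            ("crown_" if name in crown else "noncrown_")
            + ("terminal" if node.is_terminal else "inner")
        )
        report[key] += 1
    return report
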