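"""Hierarchical haplotype calling on a variant-annotated backbone tree.

Samples are genotyped successively: a marker high in the tree is assayed
first and deeper markers only along the branch that turned out derived, so a
sample's genotype vector is usually sparse (mostly untested).  The caller
walks the backbone from the root and places each sample on the deepest node
whose incoming edge is tested-derived and whose path contains no
tested-ancestral edge.  Untested markers *between* two tested-derived markers
on one path are treated as derived ("bracketing"): this is what lets a
skip-ahead assay series like rAX -> rW -> rY resolve a terminal haplotype
without typing every intermediate marker.

Assignments to internal nodes are written with the field's asterisk
convention (e.g. ``daC_Ao*``): the sample is derived for the path but either
tested ancestral for every child branch (``inner_confirmed``) or has at least
one untested child branch (``inner_unresolved``).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .backbone import BackboneTree

__all__ = [
    "State",
    "Status",
    "SampleGenotypes",
    "Assignment",
    "TestPlan",
    "NoCallError",
    "AmbiguousCallError",
    "call_haplotype",
    "batch_call",
    "plan_tests",
    "impute_alleles",
    "encode_matrix",
    "genotypes_from_matrix",
    "assignments_to_frame",
]


class State(enum.Enum):
    ANCESTRAL = 0
    DERIVED = 1
    MISSING = 2


class Status(enum.Enum):
    TERMINAL = "terminal"
    INNER_CONFIRMED = "inner_confirmed"
    INNER_UNRESOLVED = "inner_unresolved"


class NoCallError(ValueError):
    """Sample with fewer than one tested variant cannot be placed."""


class AmbiguousCallError(ValueError):
    """Derived alleles support two mutually exclusive paths equally well."""

    def __init__(self, sample: str, candidate_paths: Sequence[Sequence[str]]):
        self.sample = sample
        self.candidate_paths = [list(p) for p in candidate_paths]
        super().__init__(
            f"sample {sample!r}: ambiguous call between paths "
            + " | ".join("->".join(p) for p in self.candidate_paths)
        )


@dataclass
class SampleGenotypes:
    """Hard three-state calls (ancestral / derived / missing) for one sample."""

    sample: str
    calls: dict[str, State]

    def tested(self) -> dict[str, State]:
        return {v: s for v, s in self.calls.items() if s is not State.MISSING}


@dataclass
class Assignment:
    sample: str
    node: str
    status: Status
    label: str
    conflicts: list[str] = field(default_factory=list)
    tested_path: list[str] = field(default_factory=list)
    n_tested: int = 0
    tested_calls: dict[str, State] = field(default_factory=dict)

    def __post_init__(self) -> None:
        starred = self.label.endswith("*")
        if starred != (self.status is not Status.TERMINAL):
            raise ValueError("label '*' must mark exactly the non-terminal calls")


@dataclass
class TestPlan:
    """Ordered assay plan; most promising (highest prior-mass subtree) first."""

    variants: list[str]
    prior: dict[str, float]


_DER, _ANC, _MIX, _UNT = "derived", "ancestral", "mixed", "untested"


def _edge_state(tree: BackboneTree, node: str, tested: Mapping[str, State]) -> str:
    d = a = 0
    for v in tree.nodes[node].variants:
        s = tested.get(v)
        if s is State.DERIVED:
            d += 1
        elif s is State.ANCESTRAL:
            a += 1
    if d and a:
        return _MIX
    if d:
        return _DER
    if a:
        return _ANC
    return _UNT


def call_haplotype(sample: SampleGenotypes, tree: BackboneTree) -> Assignment:
    """Place one sample on the backbone.

    Raises :class:`NoCallError` when nothing was tested and
    :class:`AmbiguousCallError` when two mutually exclusive paths carry equal
    derived support.  A single off-path derived variant is tolerated (recurrent
    mutation / assay error): the maximal-support path is kept and the variant
    reported in ``conflicts``.
    """
    tested = sample.tested()
    unknown = sorted(set(tested) - set(tree.variant_index))
    if unknown:
        raise NoCallError(
            f"sample {sample.sample!r}: variants not in panel: {unknown}"
        )
    if not tested:
        raise NoCallError(f"sample {sample.sample!r}: no tested variants")

    # candidates: nodes reachable without crossing a tested-ancestral (or
    # internally contradictory) edge, anchored by a tested-derived incoming
    # edge; untested edges in between are bracketed as derived.
    estate = {
        n: _edge_state(tree, n, tested) for n in tree.nodes if n != tree.root
    }
    candidates: list[tuple[str, int, int]] = [(tree.root, 0, 0)]  # name, support, depth
    stack: list[tuple[str, int, int]] = [(tree.root, 0, 0)]
    while stack:
        name, support, depth = stack.pop()
        for ch in tree.nodes[name].children:
            es = estate[ch]
            if es in (_ANC, _MIX):
                continue
            gain = sum(
                1
                for v in tree.nodes[ch].variants
                if tested.get(v) is State.DERIVED
            )
            if es == _DER:
                candidates.append((ch, support + gain, depth + 1))
            stack.append((ch, support + gain, depth + 1))

    best, best_support, _ = max(
        candidates, key=lambda c: (c[1], c[2], c[0])
    )
    derived_all = {v for v, s in tested.items() if s is State.DERIVED}
    on_path = set(tree.path_variants(best))
    conflicts = sorted(derived_all - on_path)

    best_path = set(tree.path(best))
    rivals = [
        c
        for c in candidates
        if c[0] not in best_path and best not in tree.path(c[0])
    ]
    tied = [c for c in rivals if c[1] >= best_support and c[1] > 0]
    if tied or len(conflicts) >= 2:
        paths = [list(tree.path(best))]
        if tied:
            alt = max(tied, key=lambda c: (c[1], c[2], c[0]))
            paths.append(list(tree.path(alt[0])))
        else:
            for v in conflicts:
                edge = tree.variant_index[v].edge
                if edge is not None:
                    paths.append(list(tree.path(edge)))
        raise AmbiguousCallError(sample.sample, paths)

    node = tree.nodes[best]
    if node.is_terminal:
        status = Status.TERMINAL
    else:
        child_states = [estate[c] for c in node.children]
        if all(s == _ANC for s in child_states):
            status = Status.INNER_CONFIRMED
        else:
            status = Status.INNER_UNRESOLVED
    label = best if status is Status.TERMINAL else best + "*"
    tested_path = [v for v in tree.path_variants(best) if v in derived_all]
    return Assignment(
        sample=sample.sample,
        node=best,
        status=status,
        label=label,
        conflicts=conflicts,
        tested_path=tested_path,
        n_tested=len(tested),
        tested_calls=dict(tested),
    )


def batch_call(
    samples: Iterable[SampleGenotypes], tree: BackboneTree
) -> tuple[list[Assignment], pd.DataFrame]:
    """Call every sample; failures never abort the batch.

    Returns the successful assignments plus a per-sample status frame with an
    ``error`` column ("" on success, else the failure class and message).
    """
    assignments: list[Assignment] = []
    rows = []
    for s in samples:
        try:
            a = call_haplotype(s, tree)
        except (NoCallError, AmbiguousCallError) as exc:
            rows.append(
                {
                    "sample": s.sample,
                    "node": "",
                    "label": "",
                    "status": "",
                    "error": f"{type(exc).__name__}: {exc}",
                }
            )
            continue
        assignments.append(a)
        rows.append(
            {
                "sample": a.sample,
                "node": a.node,
                "label": a.label,
                "status": a.status.value,
                "error": "",
            }
        )
    frame = pd.DataFrame(
        rows, columns=["sample", "node", "label", "status", "error"]
    )
    return assignments, frame


def plan_tests(
    tree: BackboneTree,
    current: SampleGenotypes,
    prior: Mapping[str, float],
) -> TestPlan:
    """Frequency-aware successive-assay plan from the current consistent node.

    Mirrors the field practice of testing the expected (most frequent in the
    breed) branch first: untested variants below the current node are ordered
    by descending prior mass of the subtree their edge leads into, ties by
    variant id.  A terminal placement yields an empty plan.
    """
    if any(m < 0 for m in prior.values()):
        raise ValueError("prior masses must be non-negative")
    if current.tested():
        node = call_haplotype(current, tree).node
    else:
        node = tree.root
    if tree.nodes[node].is_terminal:
        return TestPlan([], dict(prior))

    mass: dict[str, float] = {}

    def fill(name: str) -> float:
        m = float(prior.get(name, 0.0)) + sum(
            fill(c) for c in tree.nodes[name].children
        )
        mass[name] = m
        return m

    fill(node)
    tested = current.tested()
    entries: list[tuple[float, str]] = []
    stack = list(tree.nodes[node].children)
    while stack:
        desc = stack.pop()
        if _edge_state(tree, desc, tested) in (_ANC, _MIX):
            continue  # branch excluded by a tested-ancestral edge
        for v in tree.nodes[desc].variants:
            if current.calls.get(v, State.MISSING) is State.MISSING:
                entries.append((mass[desc], v))
        stack.extend(tree.nodes[desc].children)
    entries.sort(key=lambda e: (-e[0], e[1]))
    return TestPlan([v for _, v in entries], dict(prior))


def impute_alleles(a: Assignment, tree: BackboneTree) -> pd.Series:
    """Complete 0/1 vector over the panel implied by the assigned node.

    Path variants of the assigned node are set to 1, everything off-path to 0,
    but observed (tested) states are never overwritten — an off-path derived
    conflict stays 1 (it is flagged in ``a.conflicts``, never silently
    zeroed).  Idempotent by construction.
    """
    on_path = set(tree.path_variants(a.node))
    out = pd.Series(0, index=pd.Index(tree.panel_order, name="variant"), dtype=np.int8)
    out[out.index.isin(on_path)] = 1
    for v, s in a.tested_calls.items():
        out[v] = 1 if s is State.DERIVED else 0
    out.name = a.sample
    return out


def encode_matrix(
    assignments: Sequence[Assignment], tree: BackboneTree
) -> pd.DataFrame:
    """Imputed sample x variant 0/1 matrix, columns in panel order."""
    if not assignments:
        return pd.DataFrame(columns=tree.panel_order)
    rows = [impute_alleles(a, tree) for a in assignments]
    return pd.DataFrame(rows)


def genotypes_from_matrix(matrix: pd.DataFrame) -> list[SampleGenotypes]:
    """Convert a 0/1/NA matrix (rows samples) into SampleGenotypes records."""
    out = []
    for sample, row in matrix.iterrows():
        calls = {}
        for v, x in row.items():
            if pd.isna(x):
                calls[str(v)] = State.MISSING
            else:
                calls[str(v)] = State.DERIVED if int(x) == 1 else State.ANCESTRAL
        out.append(SampleGenotypes(sample=str(sample), calls=calls))
    return out


def assignments_to_frame(assignments: Sequence[Assignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample": a.sample,
                "node": a.node,
                "label": a.label,
                "status": a.status.value,
                "conflicts": "|".join(a.conflicts),
                "n_tested": a.n_tested,
            }
            for a in assignments
        ],
        columns=["sample", "node", "label", "status", "conflicts", "n_tested"],
    )
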