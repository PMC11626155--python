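"""Synthetic genealogies with known truth for every pipeline stage.

The generator emulates the statistical structure the analysis assumes for a
paternally inherited, non-recombining marker system: a rooted ultrametric
genealogy (optionally with a recent, Crown-like star expansion), Poisson
mutations on branches under the infinite-sites model, breed groups whose
haplotype spectra are skewed by line breeding (a small Dirichlet
concentration concentrates each breed on few patrilines), and a partial
genotyping panel with i.i.d. missingness and optional state-flip errors.

Everything is a pure function of :class:`SimParams` (seed included), so each
downstream stage can be scored against generator truth.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import dendropy
import msprime
import numpy as np
import pandas as pd
import yaml

from .backbone import (
    BackboneNode,
    BackboneTree,
    PerfectPhylogeny,
    Variant,
    build_tree_from_matrix,
    write_variant_panel,
)
from .htcaller import SampleGenotypes, genotypes_from_matrix

__all__ = [
    "SimParams",
    "TruthBundle",
    "simulate_genealogy",
    "drop_mutations",
    "assign_breeds",
    "mask_panel",
    "simulate_bundle",
    "write_bundle",
    "genealogy_to_backbone",
    "node_label",
    "tip_labels",
    "root_age",
]

TREE_MODELS = ("yule", "kingman", "star_burst")

# fraction of clade age within which all star_burst coalescences happen: the
# model's definition of "all coalescence near the root"
STAR_BURST_WINDOW = 0.02


@dataclass(frozen=True)
class SimParams:
    """Study conditions for one synthetic cohort.

    Defaults mirror the system the pipeline targets: a recent-expansion
    ("Crown"-like) clade with a ~1,500-year MRCA, the published horse MSY
    substitution rate of 1.69e-9 per site per year, an effective callable
    length of 5.0e6 sites (a synthetic placeholder on the order of the
    callable MSY), about 120 distinct sampled patrilines and seven breed
    groups with pronounced line-breeding skew.
    """

    n_tips: int = 120
    tree_model: str = "star_burst"
    tmrca_years: float = 1500.0
    mu: float = 1.69e-9
    L: float = 5.0e6
    n_breeds: int = 7
    line_breeding_alpha: float = 0.3
    missing_rate: float = 0.3
    genotyping_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tree_model not in TREE_MODELS:
            raise ValueError(f"unknown tree model {self.tree_model!r}")
        if self.n_tips < 2:
            raise ValueError("need n_tips >= 2")
        for r in (self.missing_rate, self.genotyping_error_rate):
            if not 0 <= r < 1:
                raise ValueError("rates must lie in [0, 1)")
        if self.seed is None:
            raise ValueError("a seed is mandatory")


@dataclass
class TruthBundle:
    params: SimParams
    genealogy: dendropy.Tree
    newick: str
    edge_counts: dict[str, int]
    panel: list[Variant]
    complete: pd.DataFrame
    masked: pd.DataFrame
    genotypes: list[SampleGenotypes]
    breeds: dict[str, str]
    spectra: pd.DataFrame
    phylogeny: PerfectPhylogeny
    true_node: dict[str, str]


# ---------------------------------------------------------------------------
# genealogy simulation
# ---------------------------------------------------------------------------


def node_label(nd: dendropy.Node) -> str:
    return nd.taxon.label if nd.taxon is not None else nd.label


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [node_label(nd) for nd in tree.leaf_node_iter()]


def root_age(tree: dendropy.Tree) -> float:
    """Maximum root-to-tip path length (the tree is ultrametric)."""
    return max(
        nd.distance_from_root() for nd in tree.leaf_node_iter()
    )


def _tree_from_ages(
    parent: dict[int, int | None],
    children: dict[int, list[int]],
    age: dict[int, float],
    root_id: int,
) -> dendropy.Tree:
    """Assemble a dendropy tree from node ages; names are assigned in
    deterministic preorder ('g<k>' internals, 's<k>' zero-padded tips)."""
    tree = dendropy.Tree()
    tns = tree.taxon_namespace
    g = s = 0
    pad = max(4, len(str(sum(1 for i in children if not children[i]))))

    def rec(nid: int, dnode: dendropy.Node) -> None:
        nonlocal g, s
        kids = children.get(nid, [])
        if kids:
            dnode.label = f"g{g}"
            g += 1
        else:
            dnode.taxon = tns.new_taxon(f"s{s:0{pad}d}")
            s += 1
        for k in kids:
            child = dendropy.Node()
            child.edge.length = age[nid] - age[k]
            dnode.add_child(child)
            rec(k, child)

    tree.seed_node.edge.length = None
    rec(root_id, tree.seed_node)
    return tree


def _simulate_yule(n: int, tmrca: float, rng: np.random.Generator) -> dendropy.Tree:
    # forward-time pure-birth splits; relative node ages rescaled so the
    # root sits exactly at tmrca
    split_times = [0.0]
    t = 0.0
    for k in range(2, n):
        t += rng.exponential(1.0 / k)
        split_times.append(t)
    present = t + rng.exponential(1.0 / n)
    parent: dict[int, int | None] = {0: None}
    children: dict[int, list[int]] = {0: []}
    age: dict[int, float] = {}
    open_ids = [0]
    next_id = 1
    for st in split_times:
        i = int(rng.integers(len(open_ids)))
        nid = open_ids.pop(i)
        age[nid] = present - st
        for _ in range(2):
            parent[next_id] = nid
            children[nid].append(next_id)
            children[next_id] = []
            open_ids.append(next_id)
            next_id += 1
    scale = tmrca / age[0]
    for nid in open_ids:
        age[nid] = 0.0
    for nid in age:
        age[nid] *= scale
    for nid in open_ids:
        age[nid] = 0.0
    return _tree_from_ages(parent, children, age, 0)


def _simulate_star_burst(
    n: int, tmrca: float, rng: np.random.Generator
) -> dendropy.Tree:
    # coalescent-style merging with every event inside the top
    # STAR_BURST_WINDOW fraction of the clade age
    ages = [0.0] * n
    if n > 2:
        internal = sorted(
            rng.uniform((1 - STAR_BURST_WINDOW) * tmrca, tmrca, size=n - 2)
        )
    else:
        internal = []
    event_ages = internal + [tmrca]
    parent: dict[int, int | None] = {}
    children: dict[int, list[int]] = {i: [] for i in range(n)}
    age: dict[int, float] = {i: 0.0 for i in range(n)}
    active = list(range(n))
    next_id = n
    for a in event_ages:
        i = int(rng.integers(len(active)))
        x = active.pop(i)
        j = int(rng.integers(len(active)))
        y = active.pop(j)
        age[next_id] = a
        children[next_id] = [x, y]
        parent[x] = parent[y] = next_id
        active.append(next_id)
        next_id += 1
    root = active[0]
    parent[root] = None
    return _tree_from_ages(parent, children, age, root)


def _simulate_kingman(
    n: int, tmrca: float, rng: np.random.Generator
) -> dendropy.Tree:
    seed = int(rng.integers(1, 2**31 - 1))
    ts = msprime.sim_ancestry(
        samples=n, ploidy=1, population_size=1.0, random_seed=seed
    )
    t = ts.first()
    scale = tmrca / t.time(t.root)
    parent: dict[int, int | None] = {}
    children: dict[int, list[int]] = {}
    age: dict[int, float] = {}
    for u in t.nodes():
        children[u] = list(t.children(u))
        p = t.parent(u)
        parent[u] = None if p == -1 else p
        age[u] = t.time(u) * scale
    return _tree_from_ages(parent, children, age, t.root)


def simulate_genealogy(p: SimParams) -> dendropy.Tree:
    """Rooted ultrametric binary genealogy with branch lengths in years.

    Models: "yule" (pure birth), "kingman" (constant-size coalescent via
    msprime), "star_burst" (all coalescence compressed near the root,
    mimicking a recent expansion clade).  The root age equals
    ``tmrca_years`` exactly; every node carries a unique label.
    """
    rng = np.random.default_rng(np.random.SeedSequence([p.seed, 1]))
    if p.tree_model == "yule":
        return _simulate_yule(p.n_tips, p.tmrca_years, rng)
    if p.tree_model == "kingman":
        return _simulate_kingman(p.n_tips, p.tmrca_years, rng)
    return _simulate_star_burst(p.n_tips, p.tmrca_years, rng)


# ---------------------------------------------------------------------------
# mutations, breeds, masking
# ---------------------------------------------------------------------------


def drop_mutations(
    tree: dendropy.Tree, mu: float, L: float, seed: int
) -> tuple[dict[str, int], list[Variant], pd.DataFrame]:
    """Poisson infinite-sites mutations on every branch.

    Each edge below node X receives Poisson(mu*L*t_edge) fresh variants with
    ids "v<X>_<k>" placed on that edge.  Returns (per-edge counts keyed by
    child-node label, variant panel, complete 0/1 sample x variant matrix).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    edge_counts: dict[str, int] = {}
    panel: list[Variant] = []
    derived: dict[str, list[str]] = {}

    def rec(nd: dendropy.Node, inherited: list[str]) -> None:
        name = node_label(nd)
        if nd.parent_node is None:
            k = 0
        else:
            k = int(rng.poisson(mu * L * (nd.edge.length or 0.0)))
        edge_counts[name] = k
        vids = [f"v{name}_{i}" for i in range(k)]
        for vid in vids:
            panel.append(Variant(id=vid, edge=name))
        carried = inherited + vids
        if nd.is_leaf():
            derived[name] = carried
        for ch in nd.child_nodes():
            rec(ch, carried)

    rec(tree.seed_node, [])
    samples = sorted(derived)
    cols = [v.id for v in panel]
    mat = pd.DataFrame(0, index=pd.Index(samples, name="sample"), columns=cols, dtype=np.int8)
    for s, vids in derived.items():
        if vids:
            mat.loc[s, vids] = 1
    return edge_counts, panel, mat


def assign_breeds(
    tip_haplotype: Mapping[str, str],
    n_breeds: int,
    alpha: float,
    seed: int,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Partition tips into breeds with line-breeding frequency skew.

    Every breed draws a Dirichlet(alpha) weight vector over the distinct
    haplotypes; a tip carrying haplotype h joins breed b with probability
    proportional to b's weight on h.  Small alpha concentrates each breed on
    a few patrilines (low haplotype diversity); large alpha approaches a
    uniform allocation whose per-breed spectra mirror the cohort spectrum.
    Returns (tip -> breed label, breed x haplotype count spectra).
    """
    if n_breeds < 1:
        raise ValueError("need n_breeds >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    haps = sorted(set(tip_haplotype.values()))
    labels = [f"B{i + 1:02d}" for i in range(n_breeds)]
    weights = rng.dirichlet([alpha] * len(haps), size=n_breeds)  # (b, h)
    hap_idx = {h: i for i, h in enumerate(haps)}
    grouping: dict[str, str] = {}
    for tip in sorted(tip_haplotype):
        w = weights[:, hap_idx[tip_haplotype[tip]]]
        probs = w / w.sum() if w.sum() > 0 else np.full(n_breeds, 1.0 / n_breeds)
        grouping[tip] = labels[int(rng.choice(n_breeds, p=probs))]
    spectra = pd.DataFrame(0, index=labels, columns=haps, dtype=int)
    for tip, b in grouping.items():
        spectra.loc[b, tip_haplotype[tip]] += 1
    return grouping, spectra


def mask_panel(
    complete: pd.DataFrame,
    missing_rate: float,
    error_rate: float,
    seed: int,
) -> tuple[pd.DataFrame, list[SampleGenotypes]]:
    """i.i.d. masking plus state-flip genotyping errors.

    Entries are masked to NA with ``missing_rate``; surviving entries flip
    0 <-> 1 with ``error_rate`` (the generator's stand-in for recurrent
    mutation and assay error).  Rates of zero return the input unchanged.
    """
    for r in (missing_rate, error_rate):
        if not 0 <= r < 1:
            raise ValueError("rates must lie in [0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    vals = complete.to_numpy(dtype=np.int8).astype(float)
    if complete.size:
        mask = rng.random(vals.shape) < missing_rate
        flip = (rng.random(vals.shape) < error_rate) & ~mask
        vals[flip] = 1.0 - vals[flip]
        vals[mask] = np.nan
    masked = pd.DataFrame(vals, index=complete.index, columns=complete.columns)
    masked = masked.astype("Int8")
    return masked, genotypes_from_matrix(masked)


# ---------------------------------------------------------------------------
# bundle assembly and serialization
# ---------------------------------------------------------------------------


def genealogy_to_backbone(
    tree: dendropy.Tree,
    panel: list[Variant],
    crown_root: str | None = None,
) -> BackboneTree:
    """Mirror a fully labelled genealogy as a BackboneTree (junction nodes —
    mutation-free edges — are retained)."""
    nodes: dict[str, BackboneNode] = {}

    def rec(nd: dendropy.Node, parent: str | None) -> str:
        name = node_label(nd)
        nodes[name] = BackboneNode(name=name, parent=parent)
        for ch in nd.child_nodes():
            nodes[name].children.append(rec(ch, name))
        return name

    root = rec(tree.seed_node, None)
    for v in panel:
        if v.placed:
            nodes[v.edge].variants.append(v.id)
    return BackboneTree(root, nodes, panel=panel, crown_root=crown_root)


def simulate_bundle(p: SimParams) -> TruthBundle:
    """Full synthetic cohort: genealogy, mutations, breeds, masked panel and
    the truth needed to score every downstream stage.

    The genotyping backbone is reconstructed from the complete matrix (a
    perfect phylogeny, guaranteed compatible under infinite sites) and the
    per-sample true node is the backbone node whose root path equals the
    sample's derived set.  The whole backbone is treated as the Crown clade.
    """
    genealogy = simulate_genealogy(p)
    edge_counts, panel, complete = drop_mutations(genealogy, p.mu, p.L, p.seed)
    pp = build_tree_from_matrix(complete)
    pp.tree.crown_root = pp.tree.root
    masked, genotypes = mask_panel(
        complete, p.missing_rate, p.genotyping_error_rate, p.seed
    )
    breeds, spectra = assign_breeds(pp.sample_to_node, p.n_breeds,
                                    p.line_breeding_alpha, p.seed)
    newick = genealogy.as_string(
        schema="newick", suppress_rooting=True, unquoted_underscores=True
    ).strip()
    return TruthBundle(
        params=p,
        genealogy=genealogy,
        newick=newick,
        edge_counts=edge_counts,
        panel=panel,
        complete=complete,
        masked=masked,
        genotypes=genotypes,
        breeds=breeds,
        spectra=spectra,
        phylogeny=pp,
        true_node=dict(pp.sample_to_node),
    )


def write_bundle(bundle: TruthBundle, outdir) -> None:
    """Write the bundle as deterministic plain-text files."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "tree.nwk").write_text(bundle.newick + "\n")
    write_variant_panel(bundle.panel, out / "panel.csv")
    # the collapsed genotyping backbone (variant-bearing edges only), with the
    # same variants re-placed on its synthesized node names
    (out / "backbone.nwk").write_text(bundle.phylogeny.tree.to_newick() + "\n")
    write_variant_panel(bundle.phylogeny.tree.panel, out / "backbone_panel.csv")
    bundle.complete.to_csv(out / "genotypes_complete.csv")
    bundle.masked.to_csv(out / "genotypes_masked.csv", na_rep="NA")
    pd.Series(bundle.breeds, name="breed").rename_axis("sample").sort_index().to_csv(
        out / "breeds.tsv", sep="\t"
    )
    truth = {
        "tmrca_years": bundle.params.tmrca_years,
        "edge_counts": dict(sorted(bundle.edge_counts.items())),
        "true_node": dict(sorted(bundle.true_node.items())),
        "backbone_newick": bundle.phylogeny.tree.to_newick(),
    }
    (out / "truth.json").write_text(json.dumps(truth, sort_keys=True, indent=1))
    (out / "params.yaml").write_text(
        yaml.safe_dump(asdict(bundle.params), sort_keys=True)
    )
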