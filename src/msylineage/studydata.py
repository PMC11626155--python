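"""Published marginal counts of the 1,517-horse MSY genotyping study.

The study's headline figures are simple functions of printed marginal counts:
how many of the 1,517 genotyped males fall into the Crown haplogroup, how
many Crown samples resolve to a predefined terminal haplotype versus an
inner-node "*HT", and the ancestry composition of the local-breed and Asian
panels.  This module records those printed counts as input data and rebuilds
sample-level cohorts from them, so that the frequency/ancestry summarizers
recompute the published percentages from scratch rather than quoting them.
"""

from __future__ import annotations

from . import ancestry as anc
from . import backbone as bb
from . import popstats as ps
from .htcaller import Assignment, Status

__all__ = [
    "CROWN_COUNTS",
    "ASIAN_PANEL_COUNTS",
    "LOCAL_PANEL_COUNTS",
    "headline_backbone",
    "crown_assignments",
    "reference_signature_map",
    "asian_panel_calls",
    "local_panel_calls",
]

# Overall genotyping panel: samples in the Crown haplogroup and, within the
# Crown, samples on predefined terminal haplotypes vs inner-node "*HTs".
CROWN_COUNTS = {
    "total": 1517,
    "crown": 1365,
    "crown_terminal": 965,
    "crown_inner": 400,
    "non_crown": 152,
}

# Local Asian riding/light-draft panel (Crown samples): males whose
# haplotypes indicate recent breeding with Thoroughbreds, Arabians or
# Coldbloods; the remainder sit in the two West Asian source haplogroups or
# on basal branching points.
ASIAN_PANEL_COUNTS = {
    "total": 194,
    "recent": 80,
    "west_asian_clades": 99,
    "basal_unexplained": 15,
}

# European/US local riding, light-draft and pony panel: per-signature counts.
LOCAL_PANEL_COUNTS = {
    "Thoroughbred": 48,
    "Arabian": 20,
    "Coldblood": 24,
    "Spanish": 97,
    "WestAsian": 55,
    "varied": 67,
    "unexplained": 12,
    "non_crown": 117,
}
LOCAL_PANEL_TOTAL = sum(LOCAL_PANEL_COUNTS.values())  # 440 genotyped males


def headline_backbone() -> bb.BackboneTree:
    """Minimal backbone shaped like the study design: a Crown clade with
    terminal haplotypes and an internal branching point, plus a non-Crown
    lineage."""
    newick = "((HT_term,(HT_deep)BRANCH)daC,(NC_term)NC)root;"
    panel = [
        bb.Variant(id="vC", edge="daC"),
        bb.Variant(id="vT", edge="HT_term"),
        bb.Variant(id="vB", edge="BRANCH"),
        bb.Variant(id="vD", edge="HT_deep"),
        bb.Variant(id="vN", edge="NC"),
        bb.Variant(id="vNT", edge="NC_term"),
    ]
    return bb.parse_backbone(newick, panel, crown_root="daC")


def _terminal(sample: str, node: str) -> Assignment:
    return Assignment(sample=sample, node=node, status=Status.TERMINAL, label=node)


def _inner(sample: str, node: str) -> Assignment:
    return Assignment(
        sample=sample, node=node, status=Status.INNER_UNRESOLVED, label=node + "*"
    )


def crown_assignments() -> list[Assignment]:
    """Sample-level cohort realizing the printed genotyping-panel marginals."""
    out = []
    i = 0
    for _ in range(CROWN_COUNTS["crown_terminal"]):
        out.append(_terminal(f"s{i}", "HT_term"))
        i += 1
    for _ in range(CROWN_COUNTS["crown_inner"]):
        out.append(_inner(f"s{i}", "BRANCH"))
        i += 1
    for _ in range(CROWN_COUNTS["non_crown"]):
        out.append(_terminal(f"s{i}", "NC_term"))
        i += 1
    assert len(out) == CROWN_COUNTS["total"]
    return out


# Haplotype labels standing for one predictor of each signature class, plus a
# shared (varied) haplotype and an unexplained one.
_PANEL_LABELS = {
    "Thoroughbred": "HT_tb",
    "Arabian": "HT_ar",
    "Coldblood": "HT_cb",
    "Spanish": "HT_sp",
    "WestAsian": "HT_wa",
}
_VARIED_LABEL = "HT_mix"
_UNEXPLAINED_LABEL = "HT_open"
_NON_CROWN_LABEL = "NC_term"


def reference_signature_map(min_count: int = 2) -> anc.SignatureMap:
    """Predictor map derived (by the frequency rule) from a reference-group
    table in which each signature haplotype is private to its group and the
    varied haplotype is shared between the Spanish and Coldblood groups."""
    ref_groups = {f"{sig}Grp": sig for sig in anc.BASE_SIGNATURES}
    counts = {}
    for sig, ht in _PANEL_LABELS.items():
        counts[ht] = {f"{sig}Grp": 10}
    counts[_VARIED_LABEL] = {"SpanishGrp": 5, "ColdbloodGrp": 5}
    counts[_UNEXPLAINED_LABEL] = {}
    import pandas as pd

    frame = (
        pd.DataFrame(counts).T.reindex(columns=list(ref_groups)).fillna(0).astype(int)
    )
    frame.index.name = "ht"
    freq = ps.FrequencyTable(counts=frame)
    crown_labels = set(counts)  # every reference haplotype is a Crown label
    return anc.derive_predictors(
        freq, ref_groups, min_count=min_count, crown_labels=crown_labels
    )


def _classified_cohort(
    label_counts: dict[str, int], smap: anc.SignatureMap, prefix: str
) -> list[anc.AncestryCall]:
    calls = []
    i = 0
    for label, n in label_counts.items():
        for _ in range(n):
            calls.append(anc.classify_sample(_terminal(f"{prefix}{i}", label), smap))
            i += 1
    return calls


def asian_panel_calls() -> list[anc.AncestryCall]:
    """Asian local-breed Crown panel rebuilt from its printed marginals.

    The recent-breeding males are split over the three recent signatures
    (the printed total is 80; the split does not affect the recent fraction);
    the West Asian source-clade males carry the West Asian signature and the
    basal branching-point males stay unexplained.
    """
    smap = reference_signature_map()
    recent = ASIAN_PANEL_COUNTS["recent"]
    label_counts = {
        _PANEL_LABELS["Thoroughbred"]: recent - 2 * (recent // 3),
        _PANEL_LABELS["Arabian"]: recent // 3,
        _PANEL_LABELS["Coldblood"]: recent // 3,
        _PANEL_LABELS["WestAsian"]: ASIAN_PANEL_COUNTS["west_asian_clades"],
        _UNEXPLAINED_LABEL: ASIAN_PANEL_COUNTS["basal_unexplained"],
    }
    calls = _classified_cohort(label_counts, smap, "as")
    assert len(calls) == ASIAN_PANEL_COUNTS["total"]
    return calls


def local_panel_calls() -> list[anc.AncestryCall]:
    """European/US local-breed panel rebuilt from its printed per-signature
    counts (440 genotyped males)."""
    smap = reference_signature_map()
    label_counts = {
        _PANEL_LABELS[sig]: n
        for sig, n in LOCAL_PANEL_COUNTS.items()
        if sig in _PANEL_LABELS
    }
    label_counts[_VARIED_LABEL] = LOCAL_PANEL_COUNTS["varied"]
    label_counts[_UNEXPLAINED_LABEL] = LOCAL_PANEL_COUNTS["unexplained"]
    label_counts[_NON_CROWN_LABEL] = LOCAL_PANEL_COUNTS["non_crown"]
    calls = _classified_cohort(label_counts, smap, "lo")
    assert len(calls) == LOCAL_PANEL_TOTAL
    return calls
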