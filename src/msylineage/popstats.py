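"""Haplotype frequency spectra and Nei haplotype diversity per breed group.

Haplotype diversity Hd is the probability that two samples drawn at random
from a group carry different haplotypes, estimated without bias as

    Hd = n (1 - sum p_i^2) / (n - 1)

with the sampling variance

    V = 2/(n(n-1)) * { 2(n-2) [sum p_i^3 - (sum p_i^2)^2]
                       + sum p_i^2 - (sum p_i^2)^2 }

(Nei 1987; the estimator used by pegas' ``hap.div``).  Asterisked internal
haplotype labels ("*HTs") count as distinct haplotypes throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .backbone import BackboneTree
from .htcaller import Assignment, Status

__all__ = [
    "FrequencyTable",
    "DiversityResult",
    "GroupingError",
    "UndefinedDiversityError",
    "ht_frequencies",
    "haplotype_diversity",
    "group_summary",
    "crown_fraction",
    "round_half_up",
    "label_in_crown",
]


class GroupingError(KeyError):
    """Samples missing from the sample -> group mapping."""


class UndefinedDiversityError(ValueError):
    """Hd is undefined for fewer than two samples."""


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal rounding with halves away from zero (printed-table convention)."""
    scale = 10.0**ndigits
    out = math.floor(abs(x) * scale + 0.5) / scale * (1 if x >= 0 else -1)
    return out if ndigits > 0 else int(out)


@dataclass
class FrequencyTable:
    """Haplotype x group count table with per-column frequencies.

    ``counts`` has haplotype labels as the index and group labels as columns.
    Columns with zero samples are kept but flagged in ``empty_groups`` and
    yield NaN frequencies.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        self.counts = self.counts.astype(int)

    @property
    def n(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def frequencies(self) -> pd.DataFrame:
        n = self.n.replace(0, np.nan)
        return self.counts / n

    @property
    def empty_groups(self) -> list[str]:
        return [str(g) for g, tot in self.n.items() if tot == 0]

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())


@dataclass
class DiversityResult:
    hd: float
    sd: float
    n: int
    k: int


def ht_frequencies(
    assignments: Sequence[Assignment],
    grouping: Mapping[str, str],
    groups: Iterable[str] | None = None,
) -> FrequencyTable:
    """Direct-count haplotype frequencies per group.

    Every assigned sample must appear in ``grouping``; extra group labels (for
    columns that should exist even when empty) can be forced via ``groups``.
    Terminal and asterisked labels are distinct rows.
    """
    missing = sorted(
        {a.sample for a in assignments} - set(grouping)
    )
    if missing:
        raise GroupingError(f"samples without a group: {missing}")
    labels = sorted({a.label for a in assignments})
    cols = sorted(set(grouping[a.sample] for a in assignments) | set(groups or ()))
    counts = pd.DataFrame(0, index=pd.Index(labels, name="ht"), columns=cols)
    for a in assignments:
        counts.loc[a.label, grouping[a.sample]] += 1
    return FrequencyTable(counts=counts)


def haplotype_diversity(counts) -> DiversityResult:
    """Unbiased Nei haplotype diversity with its standard deviation.

    ``counts`` is a vector of per-haplotype sample counts (a mapping is also
    accepted).  Requires n = sum(counts) >= 2.
    """
    if isinstance(counts, Mapping):
        counts = list(counts.values())
    c = np.asarray(list(counts), dtype=float)
    if (c < 0).any():
        raise ValueError("negative counts")
    n = c.sum()
    if n < 2:
        raise UndefinedDiversityError(f"need n >= 2 samples, got {int(n)}")
    p = c / n
    s2 = float((p**2).sum())
    s3 = float((p**3).sum())
    hd = n * (1.0 - s2) / (n - 1.0)
    var = (2.0 / (n * (n - 1.0))) * (
        2.0 * (n - 2.0) * (s3 - s2**2) + s2 - s2**2
    )
    sd = math.sqrt(max(var, 0.0))
    k = int((c > 0).sum())
    return DiversityResult(hd=hd, sd=sd, n=int(n), k=k)


def label_in_crown(label: str, crown: set[str]) -> bool:
    """Crown membership of a display label (asterisk stripped)."""
    return label.rstrip("*") in crown


def _div_cols(label_counts: Mapping[str, int]) -> tuple[float, float] | tuple[None, None]:
    vals = [v for v in label_counts.values() if v > 0]
    if sum(vals) < 2:
        return (None, None)
    r = haplotype_diversity(vals)
    return (r.hd, r.sd)


def group_summary(
    assignments: Sequence[Assignment],
    grouping: Mapping[str, str],
    tree: BackboneTree,
) -> pd.DataFrame:
    """Descriptive per-group summary in the style of a breed-group table.

    Per group (plus a Total row): sample counts and distinct-haplotype counts
    overall / within the Crown / outside it, and Hd with SD for the Crown
    subset and for all samples.  Hd cells are None when n < 2.
    """
    crown = tree.crown_nodes()
    ft = ht_frequencies(assignments, grouping)
    rows = []
    col_sets = list(ft.counts.columns) + ["Total"]
    for g in col_sets:
        if g == "Total":
            vec = ft.counts.sum(axis=1)
        else:
            vec = ft.counts[g]
        vec = vec[vec > 0]
        in_crown = {lab: int(c) for lab, c in vec.items() if label_in_crown(lab, crown)}
        out_crown = {lab: int(c) for lab, c in vec.items() if not label_in_crown(lab, crown)}
        hd_crown, sd_crown = _div_cols(in_crown)
        hd_all, sd_all = _div_cols(dict(vec))
        rows.append(
            {
                "group": g,
                "n_total": int(vec.sum()),
                "n_crown": sum(in_crown.values()),
                "n_noncrown": sum(out_crown.values()),
                "ht_total": int((vec > 0).sum()),
                "ht_crown": len(in_crown),
                "ht_noncrown": len(out_crown),
                "hd_crown": hd_crown,
                "sd_crown": sd_crown,
                "hd_all": hd_all,
                "sd_all": sd_all,
            }
        )
    return pd.DataFrame(rows).set_index("group")


def crown_fraction(
    assignments: Sequence[Assignment], tree: BackboneTree
) -> dict:
    """Headline Crown-clustering percentages (nearest-integer convention).

    Reports the percentage of samples falling in the Crown clade, the split of
    Crown samples between predefined terminal haplotypes and inner-node
    asterisk haplotypes, the number of distinct Crown haplotype labels and the
    number of inner nodes carrying at least one sample.
    """
    crown = tree.crown_nodes()
    n_total = len(assignments)
    in_crown = [a for a in assignments if a.node in crown]
    n_crown = len(in_crown)
    terminal = [a for a in in_crown if a.status is Status.TERMINAL]
    inner = [a for a in in_crown if a.status is not Status.TERMINAL]
    out = {
        "n_total": n_total,
        "n_crown": n_crown,
        "pct_crown": round_half_up(100.0 * n_crown / n_total) if n_total else 0,
        "n_terminal": len(terminal),
        "n_inner": len(inner),
        "pct_terminal": round_half_up(100.0 * len(terminal) / n_crown)
        if n_crown
        else 0,
        "pct_inner": round_half_up(100.0 * len(inner) / n_crown) if n_crown else 0,
        "n_distinct_hts": len({a.label for a in in_crown}),
        "n_terminal_hts": len({a.label for a in terminal}),
        "n_inner_nodes_occupied": len({a.node for a in inner}),
    }
    return out
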