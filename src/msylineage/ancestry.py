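"""Haplotype -> paternal-ancestry predictors and cohort composition.

Reference breed groups with documented histories (Arabian, Thoroughbred,
Coldblood line breeding; the earlier Spanish and West Asian disseminations)
anchor a signature for each Crown haplotype: a haplotype observed in exactly
one reference group becomes a unique predictor of that ancestry, one observed
in several groups gets a "varied" signature listing them (displayed joined
with "/", e.g. "Spanish/Coldblood"), and one observed in none stays
unexplained.  Curated overrides — the narrative-history layer that frequency
evidence alone cannot supply — are applied last and logged in the entry's
provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .htcaller import Assignment
from .popstats import FrequencyTable, round_half_up

__all__ = [
    "RECENT_SIGNATURES",
    "EARLY_SIGNATURES",
    "SignatureEntry",
    "SignatureMap",
    "AncestryCall",
    "ConfigurationError",
    "derive_predictors",
    "classify_sample",
    "summarize_composition",
]

RECENT_SIGNATURES = ("Arabian", "Thoroughbred", "Coldblood")
EARLY_SIGNATURES = ("Spanish", "WestAsian")
BASE_SIGNATURES = RECENT_SIGNATURES + EARLY_SIGNATURES

BASES = ("recent_breeding", "early_dissemination", "varied", "unexplained", "non_crown")


class ConfigurationError(ValueError):
    """Reference-group configuration inconsistent with the frequency table."""


@dataclass(frozen=True)
class SignatureEntry:
    """Signature of one haplotype label.

    ``signatures`` is empty for an unexplained haplotype, a single base
    signature for a unique predictor, and two or more for a varied signal.
    """

    ht: str
    signatures: tuple[str, ...]
    provenance: str = "frequency"

    @property
    def display(self) -> str:
        return "/".join(self.signatures) if self.signatures else "unexplained"

    @property
    def basis(self) -> str:
        if len(self.signatures) == 0:
            return "unexplained"
        if len(self.signatures) >= 2:
            return "varied"
        sig = self.signatures[0]
        if sig in RECENT_SIGNATURES:
            return "recent_breeding"
        if sig in EARLY_SIGNATURES:
            return "early_dissemination"
        raise ConfigurationError(f"unknown base signature {sig!r}")


@dataclass
class SignatureMap:
    """Complete haplotype -> signature lookup for a study.

    ``crown_labels`` (labels of Crown nodes, asterisked variants included)
    lets the classifier route non-Crown assignments to the ``non_crown``
    basis; when None every assignment is treated as Crown.
    """

    entries: dict[str, SignatureEntry]
    reference_groups: tuple[str, ...] = BASE_SIGNATURES
    crown_labels: set[str] | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"ht": e.ht, "signature": e.display, "provenance": e.provenance}
                for e in self.entries.values()
            ],
            columns=["ht", "signature", "provenance"],
        )


@dataclass(frozen=True)
class AncestryCall:
    sample: str
    ht: str
    signature: str
    basis: str

    def __post_init__(self) -> None:
        if self.basis not in BASES:
            raise ValueError(f"unknown basis {self.basis!r}")


def _parse_signature_spec(spec: str) -> tuple[str, ...]:
    if spec == "unexplained":
        return ()
    parts = tuple(s.strip() for s in spec.split("/"))
    for p in parts:
        if p not in BASE_SIGNATURES:
            raise ConfigurationError(f"unknown signature {p!r} in override")
    return parts


def derive_predictors(
    freq: FrequencyTable,
    reference_groups: Mapping[str, str],
    min_count: int = 2,
    curated: Mapping[str, str] | None = None,
    crown_labels: Iterable[str] | None = None,
) -> SignatureMap:
    """Frequency rule for ancestry predictors, plus curated overrides.

    ``reference_groups`` maps frequency-table column names to base signatures
    (e.g. ``{"ArabianGroup": "Arabian", ...}``).  A haplotype counted at least
    ``min_count`` times in exactly one reference group becomes that group's
    unique predictor; in two or more, a varied signature (in reference-group
    order); in none, unexplained.  ``curated`` maps haplotype labels to
    signature specs ("Spanish", "Spanish/Coldblood" or "unexplained") and is
    applied last with provenance "curated".
    """
    if min_count < 1:
        raise ConfigurationError("min_count must be >= 1")
    absent = [g for g in reference_groups if g not in freq.counts.columns]
    if absent:
        raise ConfigurationError(f"reference groups absent from table: {absent}")
    bad = [s for s in reference_groups.values() if s not in BASE_SIGNATURES]
    if bad:
        raise ConfigurationError(f"unknown signatures: {bad}")
    entries: dict[str, SignatureEntry] = {}
    for ht in freq.counts.index:
        sigs = tuple(
            sig
            for grp, sig in reference_groups.items()
            if int(freq.counts.loc[ht, grp]) >= min_count
        )
        entries[ht] = SignatureEntry(ht=ht, signatures=sigs)
    for ht, spec in (curated or {}).items():
        entries[ht] = SignatureEntry(
            ht=ht, signatures=_parse_signature_spec(spec), provenance="curated"
        )
    return SignatureMap(
        entries=entries,
        reference_groups=tuple(reference_groups.values()),
        crown_labels=set(crown_labels) if crown_labels is not None else None,
    )


def classify_sample(a: Assignment, smap: SignatureMap) -> AncestryCall:
    """Deterministic signature lookup for one assignment."""
    if smap.crown_labels is not None and a.label not in smap.crown_labels:
        return AncestryCall(a.sample, a.label, "non-Crown", "non_crown")
    entry = smap.entries.get(a.label)
    if entry is None:
        entry = SignatureEntry(ht=a.label, signatures=(), provenance="default")
    return AncestryCall(a.sample, a.label, entry.display, entry.basis)


def summarize_composition(
    calls: Sequence[AncestryCall], grouping: Mapping[str, str]
) -> pd.DataFrame:
    """Per-group ancestry composition: counts and one-decimal percentages.

    One row per group plus a Total row; count and percentage columns per
    basis (recent breeding / early dissemination / varied / unexplained /
    non-Crown) and per-signature counts in a trailing text column.
    """
    missing = sorted({c.sample for c in calls} - set(grouping))
    if missing:
        raise KeyError(f"samples without a group: {missing}")
    frame = pd.DataFrame(
        [
            {
                "group": grouping[c.sample],
                "basis": c.basis,
                "signature": c.signature,
            }
            for c in calls
        ]
    )
    rows = []
    groups = sorted(frame["group"].unique()) + ["Total"]
    for g in groups:
        sub = frame if g == "Total" else frame[frame["group"] == g]
        n = len(sub)
        row: dict = {"group": g, "n": n}
        for basis in BASES:
            cnt = int((sub["basis"] == basis).sum())
            row[f"n_{basis}"] = cnt
            row[f"pct_{basis}"] = round_half_up(100.0 * cnt / n, 1) if n else float("nan")
        sig_counts = sub["signature"].value_counts().sort_index()
        row["signatures"] = ";".join(f"{s}={c}" for s, c in sig_counts.items())
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")
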