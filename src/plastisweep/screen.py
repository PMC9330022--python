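"""Effective/ineffective comparison screen for environment-driven miRNAs.

In the 2x2 reciprocal-transplant design the six pairwise group
comparisons decompose additively into breed (BR), environment (EN) and
experimental-error (EE) factors. The four comparisons whose groups
differ in rearing environment carry the EN factor ("effective"
comparisons: TC-LC, TC-LTC, HLC-LC, HLC-LTC); the two whose groups share
an environment do not ("ineffective": TC-HLC, LTC-LC). A candidate
environment miRNA (ENM) is a feature that is differentially expressed in
every effective comparison and in neither ineffective one -- its signal
survives every contrast that contains the environment factor and
vanishes in every contrast that does not.

Comparisons are canonicalized as unordered pairs with direction signs
expressed relative to the high-altitude member (or the first-listed
member for same-environment pairs), so the screen is invariant to the
orientation the DE stage happened to use.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .design import DesignError, GROUP_BREED_ENV, GROUPS

FACTORS = ("BR", "EN", "EE")


@dataclass(frozen=True)
class Comparison:
    """Canonical unordered group pair; A is the reference orientation."""

    a: str
    b: str

    @property
    def label(self) -> str:
        return f"{self.a}-{self.b}"


@dataclass
class ScreenDesign:
    """The six comparisons with their factor incidence sets."""

    comparisons: list[Comparison]
    incidence: dict[str, frozenset]  # label -> subset of FACTORS

    @property
    def effective(self) -> list[str]:
        return [c.label for c in self.comparisons if "EN" in self.incidence[c.label]]

    @property
    def ineffective(self) -> list[str]:
        return [c.label for c in self.comparisons if "EN" not in self.incidence[c.label]]


@dataclass
class ENMCandidate:
    """A feature surviving the intersection/exclusion screen.

    ``altitude_preference`` is HIGH when the feature is up-regulated in
    the high-altitude group of every effective comparison, LOW when
    down-regulated in all of them, INCONSISTENT otherwise (kept but
    flagged; the screen itself never drops on direction).
    """

    feature: str
    tissue: str | None
    altitude_preference: str
    support: dict[str, int] = field(default_factory=dict)  # label -> +1/-1


def _canonical_pair(g1: str, g2: str) -> Comparison:
    (b1, e1), (b2, e2) = GROUP_BREED_ENV[g1], GROUP_BREED_ENV[g2]
    if e1 != e2:
        return Comparison(g1, g2) if e1 == "HIGH" else Comparison(g2, g1)
    # same environment: first-listed = canonical group order
    first, second = sorted((g1, g2), key=GROUPS.index)
    return Comparison(first, second)


def build_screen_design(design: pd.DataFrame | Iterable[str] | None = None) -> ScreenDesign:
    """Derive the comparison structure from the groups actually present.

    Incidence is computed from (breed, env) differences -- EN belongs to
    a comparison iff its groups differ in environment, BR iff they
    differ in breed, EE always -- never hard-coded per label.
    """
    if design is None:
        groups = list(GROUPS)
    elif isinstance(design, pd.DataFrame):
        groups = [g for g in GROUPS if g in set(design["group"])]
    else:
        groups = [g for g in GROUPS if g in set(design)]
    missing = [g for g in GROUPS if g not in groups]
    if missing:
        raise DesignError(f"screen requires all four groups; missing {missing}")

    comparisons = []
    incidence = {}
    for i, g1 in enumerate(GROUPS):
        for g2 in GROUPS[i + 1 :]:
            comp = _canonical_pair(g1, g2)
            (ba, ea), (bb, eb) = GROUP_BREED_ENV[comp.a], GROUP_BREED_ENV[comp.b]
            fac = {"EE"}
            if ba != bb:
                fac.add("BR")
            if ea != eb:
                fac.add("EN")
            comparisons.append(comp)
            incidence[comp.label] = frozenset(fac)
    return ScreenDesign(comparisons, incidence)


def normalize_de_sets(
    de_sets: Mapping[str, Mapping[str, int] | set],
    sdesign: ScreenDesign,
) -> dict[str, dict[str, int] | set]:
    """Map arbitrarily oriented 'X-Y' keys onto canonical labels.

    Direction signs are flipped when the input orientation is reversed
    relative to the canonical one.
    """
    canonical = {c.label: c for c in sdesign.comparisons}
    out: dict = {}
    for key, members in de_sets.items():
        a, b = key.split("-")
        if a not in GROUPS or b not in GROUPS:
            raise DesignError(f"unknown comparison {key!r}")
        comp = _canonical_pair(a, b)
        if comp.label not in canonical:
            raise DesignError(f"comparison {key!r} not part of the screen design")
        flip = (a, b) != (comp.a, comp.b)
        if isinstance(members, Mapping):
            out[comp.label] = {f: (-d if flip else d) for f, d in members.items()}
        else:
            out[comp.label] = set(members)
    return out


def _require_all_comparisons(de_sets: Mapping, sdesign: ScreenDesign) -> None:
    missing = [c.label for c in sdesign.comparisons if c.label not in de_sets]
    if missing:
        raise DesignError(f"missing comparisons: {missing}")


def intersect_effective(
    de_sets: Mapping[str, Mapping[str, int] | set], sdesign: ScreenDesign
) -> set[str]:
    """Features present in every effective (environment-carrying) DE set."""
    de_sets = normalize_de_sets(de_sets, sdesign)
    _require_all_comparisons(de_sets, sdesign)
    sets = [set(de_sets[label]) for label in sdesign.effective]
    out = sets[0]
    for s in sets[1:]:
        out = out & s
    return out


def screen_enm(
    de_sets: Mapping[str, Mapping[str, int] | set],
    sdesign: ScreenDesign,
    tissue: str | None = None,
) -> list[ENMCandidate]:
    """Intersection/exclusion screen for candidate ENMs.

    A feature is a candidate iff it is in every effective DE set and in
    neither ineffective DE set. Directions (+1 = up in the high-altitude
    member) must be available for every candidate in every effective
    comparison; a bare set for an effective comparison raises once a
    candidate is found in it.
    """
    de_sets = normalize_de_sets(de_sets, sdesign)
    _require_all_comparisons(de_sets, sdesign)
    inter = intersect_effective(de_sets, sdesign)
    excluded = set()
    for label in sdesign.ineffective:
        excluded |= set(de_sets[label])

    candidates = []
    for feature in sorted(inter - excluded):
        support = {}
        for label in sdesign.effective:
            members = de_sets[label]
            if not isinstance(members, Mapping):
                raise DesignError(
                    f"comparison {label!r} lacks directions for candidate {feature!r}"
                )
            support[label] = int(members[feature])
        signs = set(support.values())
        if signs == {1}:
            pref = "HIGH"
        elif signs == {-1}:
            pref = "LOW"
        else:
            pref = "INCONSISTENT"
        candidates.append(ENMCandidate(feature, tissue, pref, support))
    return candidates


def membership_table(
    de_sets: Mapping[str, Mapping[str, int] | set], sdesign: ScreenDesign
) -> pd.DataFrame:
    """Feature x comparison signed membership table (UpSet-style).

    Entries are +1/-1 for DE features with direction, 1 for membership
    without direction, 0 otherwise.
    """
    de_sets = normalize_de_sets(de_sets, sdesign)
    features = sorted(set().union(*[set(v) for v in de_sets.values()])) if de_sets else []
    labels = [c.label for c in sdesign.comparisons]
    data = {}
    for label in labels:
        members = de_sets.get(label, {})
        if isinstance(members, Mapping):
            data[label] = [members.get(f, 0) for f in features]
        else:
            data[label] = [1 if f in members else 0 for f in features]
    return pd.DataFrame(data, index=pd.Index(features, name="feature"), columns=labels)


def de_sets_from_membership(table: pd.DataFrame) -> dict[str, dict[str, int]]:
    """Inverse of :func:`membership_table` (signed entries only)."""
    out: dict[str, dict[str, int]] = {}
    for label in table.columns:
        col = table[label]
        out[label] = {f: int(v) for f, v in col.items() if v != 0}
    return out
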