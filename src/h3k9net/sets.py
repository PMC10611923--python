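"""Set algebra over phase- and bait-resolved interactomes.

Every True hit belongs to one or more (bait, phase) interactomes; the
questions asked of them are set-theoretic: Venn partitions by membership
signature, cross-phase overlap per bait, proteins shared by at least k
regulators, and "phase switchers" that change regulator between G1/S and
G2/M.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd


@dataclass
class InteractomeCollection:
    """Named protein sets keyed by (bait, phase), with derived unions."""

    sets: dict[tuple[str, str], frozenset]

    def __post_init__(self) -> None:
        self.sets = {k: frozenset(v) for k, v in self.sets.items()}

    @property
    def baits(self) -> tuple[str, ...]:
        seen: list[str] = []
        for bait, _ in self.sets:
            if bait not in seen:
                seen.append(bait)
        return tuple(seen)

    @property
    def phases(self) -> tuple[str, ...]:
        seen: list[str] = []
        for _, phase in self.sets:
            if phase not in seen:
                seen.append(phase)
        return tuple(seen)

    def get(self, bait: str, phase: str) -> frozenset:
        try:
            return self.sets[(bait, phase)]
        except KeyError:
            raise KeyError(f"no interactome for bait={bait!r} phase={phase!r}") from None

    def bait_union(self, bait: str) -> frozenset:
        parts = [s for (b, _), s in self.sets.items() if b == bait]
        return frozenset().union(*parts) if parts else frozenset()

    def phase_union(self, phase: str) -> frozenset:
        parts = [s for (_, p), s in self.sets.items() if p == phase]
        return frozenset().union(*parts) if parts else frozenset()

    def union(self) -> frozenset:
        return frozenset().union(*self.sets.values()) if self.sets else frozenset()

    def bait_membership(self, protein: str, phase: str | None = None) -> frozenset:
        """Baits whose interactome (optionally restricted to one phase) has the protein."""
        return frozenset(
            b
            for (b, p), s in self.sets.items()
            if protein in s and (phase is None or p == phase)
        )

    def restrict(self, keep: Iterable[str]) -> "InteractomeCollection":
        keep = frozenset(keep)
        return InteractomeCollection({k: v & keep for k, v in self.sets.items()})

    def membership_matrix(self) -> pd.DataFrame:
        """Binary protein x (bait, phase) matrix (heatmap input)."""
        proteins = sorted(self.union())
        cols = {f"{b}_{p}": [pr in s for pr in proteins] for (b, p), s in self.sets.items()}
        return pd.DataFrame(cols, index=proteins).astype(int)


@dataclass
class VennPartition:
    """Disjoint regions of a union of named sets, keyed by membership signature."""

    regions: dict[frozenset, frozenset]

    def sizes(self) -> dict[frozenset, int]:
        return {sig: len(members) for sig, members in self.regions.items()}

    def union_size(self) -> int:
        return sum(len(m) for m in self.regions.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("&".join(sorted(sig)), len(members), ",".join(sorted(members)))
            for sig, members in sorted(self.regions.items(), key=lambda kv: sorted(kv[0]))
        ]
        return pd.DataFrame(rows, columns=["signature", "size", "members"])


@dataclass
class PhaseOverlap:
    """Cross-phase overlap of one bait's two phase interactomes."""

    bait: str
    both: frozenset
    only_g1s: frozenset
    only_g2m: frozenset

    @property
    def total(self) -> int:
        return len(self.both) + len(self.only_g1s) + len(self.only_g2m)

    @property
    def fractions(self) -> tuple[float, float, float]:
        t = self.total
        if t == 0:
            return (0.0, 0.0, 0.0)
        return (len(self.both) / t, len(self.only_g1s) / t, len(self.only_g2m) / t)

    def percentages(self, ndigits: int = 1) -> tuple[float, float, float]:
        return tuple(round(100 * f, ndigits) for f in self.fractions)


def hits_to_sets(hits: pd.DataFrame) -> InteractomeCollection:
    """Collate True hits into per-(bait, phase) interactome sets."""
    sets: dict[tuple[str, str], frozenset] = {}
    if hits.empty:
        return InteractomeCollection(sets)
    for (bait, phase), group in hits.groupby(["bait", "phase"], sort=False):
        sets[(bait, phase)] = frozenset(group.loc[group["status"], "protein"])
    return InteractomeCollection(sets)


def venn_partition(named_sets: Mapping[str, Iterable[str]]) -> VennPartition:
    """Partition the union of 1-8 named sets by exact membership signature."""
    if isinstance(named_sets, Mapping):
        items = list(named_sets.items())
    else:
        items = list(named_sets)
        names = [n for n, _ in items]
        if len(names) != len(set(names)):
            raise ValueError("duplicate set names")
    if not 1 <= len(items) <= 8:
        raise ValueError("venn_partition supports 1-8 named sets")
    sets = {name: frozenset(s) for name, s in items}
    regions: dict[frozenset, set] = {}
    for element in frozenset().union(*sets.values()):
        sig = frozenset(name for name, s in sets.items() if element in s)
        regions.setdefault(sig, set()).add(element)
    return VennPartition({sig: frozenset(m) for sig, m in regions.items()})


def phase_overlap(
    collection: InteractomeCollection, bait: str, phases: tuple[str, str] = ("G1S", "G2M")
) -> PhaseOverlap:
    """Intersection/differences of one bait's interactomes across two phases."""
    first = collection.get(bait, phases[0])
    second = collection.get(bait, phases[1])
    return PhaseOverlap(
        bait=bait,
        both=first & second,
        only_g1s=first - second,
        only_g2m=second - first,
    )


def shared_by_at_least(
    collection: InteractomeCollection, k: int, scope: str | None = None
) -> frozenset:
    """Proteins in >= k distinct baits' interactomes.

    ``scope`` restricts membership to one phase; the default counts a bait if
    the protein appears with it in any phase (a protein seen with one bait in
    both phases still counts once).
    """
    n_baits = len(collection.baits)
    if not 1 <= k <= max(n_baits, 1):
        raise ValueError(f"k={k} out of range 1..{n_baits}")
    pool = collection.union() if scope is None else collection.phase_union(scope)
    return frozenset(
        p for p in pool if len(collection.bait_membership(p, phase=scope)) >= k
    )


def phase_switchers(
    collection: InteractomeCollection, phases: tuple[str, str] = ("G1S", "G2M")
) -> frozenset:
    """Proteins present in both phases whose bait memberships are disjoint.

    The strict reading of "interacted with a different regulator": the sets
    of baits seen with the protein in the two phases share no member.
    """
    first_union = collection.phase_union(phases[0])
    second_union = collection.phase_union(phases[1])
    out = set()
    for p in first_union & second_union:
        b1 = collection.bait_membership(p, phases[0])
        b2 = collection.bait_membership(p, phases[1])
        if b1 and b2 and not (b1 & b2):
            out.add(p)
    return frozenset(out)
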