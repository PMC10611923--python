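"""Histone-mimicry SLiM construction, proteome scanning and tiered screening.

EHMT1/EHMT2 methylate lysines inside a short linear motif (SLiM) resembling
the histone H3K9 context (the ARKS sequence of H3 tails). The motif is
modeled as an ordered list of per-position residue classes with the target
lysine fixed at one position — e.g. ``[ACEGKLNS][R][K][AEGKLMNQRSTV]`` with
the K at position 3. A protein carrying the motif is a mimicry candidate if
it is also found in the nuclear writer interactome (so the mark could be
written) and, at a second tier, in a reader (CBX3/CBX5) interactome (so the
mark could be read). Known lysine-methylation sites provide orthogonal
evidence when they coincide with a predicted K position.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .config import READERS, WRITERS
from .sets import InteractomeCollection

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

MIMICRY_COLUMNS = ("protein", "k_position", "tier1", "tier2", "phases", "evidence")


@dataclass(frozen=True)
class SlimMotif:
    """Ordered per-position residue classes with a fixed target-lysine slot."""

    positions: tuple[frozenset, ...]
    k_index: int = 3  # 1-based position of the target lysine within the motif
    name: str = ""

    def __post_init__(self) -> None:
        positions = tuple(frozenset(p) for p in self.positions)
        object.__setattr__(self, "positions", positions)
        if len(positions) < 2:
            raise ValueError("motif must have length >= 2")
        if not 1 <= self.k_index <= len(positions):
            raise ValueError("k_index out of range")
        for i, pos in enumerate(positions, start=1):
            if not pos:
                raise ValueError(f"position {i} class is empty")
            bad = set(pos) - AMINO_ACIDS
            if bad:
                raise ValueError(f"position {i} contains non-standard residues {sorted(bad)}")
        if positions[self.k_index - 1] != frozenset("K"):
            raise ValueError("the k_index position class must be exactly {K}")

    def __len__(self) -> int:
        return len(self.positions)

    def matches(self, window: str) -> bool:
        if len(window) != len(self.positions):
            return False
        return all(res in cls for res, cls in zip(window, self.positions))


def _motif(classes: Sequence[str], name: str) -> SlimMotif:
    return SlimMotif(tuple(frozenset(c) for c in classes), k_index=3, name=name)


#: Published motif presets. ``results_final`` is the final SLiM used for the
#: candidate screen; ``methods_scansite`` is the earlier 4-residue variant
#: submitted to the Scansite scan. Both place the target K at position 3 and
#: both accept the canonical histone ARKS context.
PRESETS: dict[str, SlimMotif] = {
    "results_final": _motif(["ASGNLKEC", "R", "K", "SVTRQNMLKEAGR"], "results_final"),
    "methods_scansite": _motif(["GCSAKLN", "R", "K", "TGQSVMALNKER"], "methods_scansite"),
}

DEFAULT_PRESET = "results_final"


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence; coordinates are 1-based residue indices."""

    protein: str | None
    start: int
    k_position: int


def build_motif(
    peptides: Sequence[str],
    window_start: int = 1,
    window_len: int | None = None,
    k_offset: int = 3,
    name: str = "",
) -> SlimMotif:
    """Union of observed residues per aligned position, K forced at k_offset.

    ``peptides`` must be >= 2 equal-length aligned sequences, each carrying K
    at the target position (window_start + k_offset - 1, 1-based).
    """
    if len(peptides) < 2:
        raise ValueError("need at least two peptides")
    lengths = {len(p) for p in peptides}
    if len(lengths) != 1:
        raise ValueError("peptides must have equal length")
    (length,) = lengths
    if window_len is None:
        window_len = length - window_start + 1
    if not (1 <= window_start and window_start + window_len - 1 <= length):
        raise ValueError("window out of bounds")
    if not 1 <= k_offset <= window_len:
        raise ValueError("k_offset outside window")
    k_col = window_start + k_offset - 2  # 0-based column of the target lysine
    for p in peptides:
        if p[k_col] != "K":
            raise ValueError(f"peptide {p!r} lacks K at the target position")
    classes = []
    for j in range(window_start - 1, window_start - 1 + window_len):
        classes.append(frozenset(p[j] for p in peptides))
    classes[k_offset - 1] = frozenset("K")
    return SlimMotif(tuple(classes), k_index=k_offset, name=name)


def motif_to_pattern(motif: SlimMotif) -> str:
    """Canonical bracket-class string, residues alphabetized within classes."""
    return "".join("[" + "".join(sorted(cls)) + "]" for cls in motif.positions)


def parse_pattern(pattern: str, k_index: int = 3, name: str = "") -> SlimMotif:
    """Parse a bracket-class pattern back into a :class:`SlimMotif`."""
    tokens = re.findall(r"\[([A-Z]+)\]", pattern)
    if "".join(f"[{t}]" for t in tokens) != pattern:
        raise ValueError(f"malformed bracket-class pattern: {pattern!r}")
    return SlimMotif(tuple(frozenset(t) for t in tokens), k_index=k_index, name=name)


def scan_sequence(sequence: str, motif: SlimMotif, protein: str | None = None) -> list[MotifHit]:
    """All (possibly overlapping) motif occurrences, ascending 1-based start.

    Non-standard letters (X, U, B, Z, ...) never satisfy a position class.
    """
    width = len(motif)
    hits: list[MotifHit] = []
    seq = sequence.upper()
    for i in range(len(seq) - width + 1):
        if motif.matches(seq[i : i + width]):
            hits.append(MotifHit(protein, i + 1, i + motif.k_index))
    return hits


def scan_proteome(
    sequences: Mapping[str, str], motif: SlimMotif
) -> tuple[pd.DataFrame, set[str]]:
    """Scan every protein; return the hit table and the set of hit proteins."""
    if not sequences:
        return pd.DataFrame(columns=["protein", "start", "k_position"]), set()
    records = []
    for protein in sequences:
        for hit in scan_sequence(sequences[protein], motif, protein):
            records.append((protein, hit.start, hit.k_position))
    table = pd.DataFrame(records, columns=["protein", "start", "k_position"])
    return table, set(table["protein"])


def tier_screen(
    motif_hits: pd.DataFrame,
    writer_nuclear: InteractomeCollection,
    readers: InteractomeCollection,
    writer_mode: str = "union",
) -> pd.DataFrame:
    """Two-tier mimicry screen over motif-bearing proteins.

    Tier 1: the protein carries the motif and is in the nuclear writer
    (EHMT1/EHMT2) interactome, so the methyl mark could be established.
    Tier 2: additionally present in a reader (CBX3/CBX5) interactome, so the
    mark could be read. ``writer_mode`` selects union (default) or
    intersection of the two writers' interactomes for tier 1. The ``phases``
    column lists the phases in which the protein appears in any of the four
    interactomes, comma-joined; rows keep one entry per motif occurrence.
    """
    if writer_mode not in ("union", "intersection"):
        raise ValueError("writer_mode must be 'union' or 'intersection'")
    writer_sets = [writer_nuclear.bait_union(b) for b in writer_nuclear.baits]
    if writer_mode == "union":
        tier1_pool = set().union(*writer_sets) if writer_sets else set()
    else:
        tier1_pool = frozenset.intersection(*writer_sets) if writer_sets else set()
    reader_pool = set().union(*(readers.bait_union(b) for b in readers.baits)) if readers.baits else set()

    phases = sorted(set(writer_nuclear.phases) | set(readers.phases))

    def protein_phases(p: str) -> str:
        present = []
        for phase in phases:
            in_writers = p in writer_nuclear.phase_union(phase)
            in_readers = p in readers.phase_union(phase)
            if in_writers or in_readers:
                present.append(phase)
        return ",".join(present)

    rows = []
    for rec in motif_hits.itertuples(index=False):
        tier1 = rec.protein in tier1_pool
        tier2 = tier1 and rec.protein in reader_pool
        rows.append(
            (
                rec.protein,
                int(rec.k_position),
                tier1,
                tier2,
                protein_phases(rec.protein) if tier1 else "",
                False,
            )
        )
    return pd.DataFrame(rows, columns=list(MIMICRY_COLUMNS))


def evidence_crosscheck(table: pd.DataFrame, known_sites: pd.DataFrame) -> pd.DataFrame:
    """Flag rows whose predicted K position has a known methyl-lysine site.

    ``known_sites`` needs columns (protein, position, modification) with
    1-based residue positions; the match is exact-position per protein.
    """
    out = table.copy()
    if known_sites.empty:
        out["evidence"] = False
        return out
    site_keys = set(zip(known_sites["protein"], known_sites["position"].astype(int)))
    out["evidence"] = [
        (p, k) in site_keys for p, k in zip(out["protein"], out["k_position"].astype(int))
    ]
    return out


def phase_split(table: pd.DataFrame, phases: Sequence[str] = ("G1S", "G2M")) -> dict[str, int]:
    """Both / first-only / second-only split of tier-2 candidate proteins."""
    tier2 = table[table["tier2"]]
    per_protein: dict[str, set] = {}
    for rec in tier2.itertuples(index=False):
        per_protein.setdefault(rec.protein, set()).update(
            ph for ph in rec.phases.split(",") if ph
        )
    first, second = phases
    counts = {"both": 0, f"only_{first}": 0, f"only_{second}": 0}
    for p, phs in per_protein.items():
        if first in phs and second in phs:
            counts["both"] += 1
        elif first in phs:
            counts[f"only_{first}"] += 1
        elif second in phs:
            counts[f"only_{second}"] += 1
    counts["total"] = len(per_protein)
    return counts
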