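"""IP-MS spectral-count filtering: from raw peptide counts to True/False hits.

Three filters are applied in sequence to every protein observed in a bait
pulldown, and the first failure determines the recorded reason:

1. ``low_enrichment`` — fewer than ``min_peptides`` total peptides in the
   bait sample (default: fewer than four).
2. ``low_fold_change`` — log2((bait + pc) / (IgG + pc)) below the configured
   threshold against the phase-matched IgG mock pulldown.
3. ``contaminant`` — identifier belongs to a common AP-MS contaminant family
   (actins, keratins, tubulins, histones), per CRAPome practice.

Proteins passing all three are True hits; everything else is a False hit
with a single reason code, so reason tallies partition each pulldown.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .config import IGG, ConfigurationError, FilterConfig

HIT_REASONS = ("hit", "low_enrichment", "low_fold_change", "contaminant")

HIT_COLUMNS = (
    "protein",
    "bait",
    "phase",
    "status",
    "reason",
    "bait_count",
    "igg_count",
    "log2fc",
)


@dataclass(frozen=True)
class SampleInfo:
    """Metadata for one MS sample: which bait was pulled down, in which phase."""

    bait: str
    phase: str

    @property
    def is_control(self) -> bool:
        return self.bait == IGG


@dataclass
class SpectralCountTable:
    """Total peptide counts per protein per sample (wide form).

    ``counts`` is a proteins x samples integer DataFrame; ``samples`` maps
    every column to its :class:`SampleInfo`. Exactly one IgG sample is
    required per phase that carries any bait sample.
    """

    counts: pd.DataFrame
    samples: dict[str, SampleInfo] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in self.counts.columns if c not in self.samples]
        if missing:
            raise ConfigurationError(f"samples missing metadata: {missing}")
        if (self.counts.values < 0).any():
            raise ValueError("peptide counts must be non-negative")
        if not all(np.issubdtype(dt, np.integer) for dt in self.counts.dtypes):
            raise ValueError("peptide counts must be integers")

    # -- lookups ----------------------------------------------------------
    @property
    def baits(self) -> tuple[str, ...]:
        seen: list[str] = []
        for info in self.samples.values():
            if not info.is_control and info.bait not in seen:
                seen.append(info.bait)
        return tuple(seen)

    @property
    def phases(self) -> tuple[str, ...]:
        seen: list[str] = []
        for info in self.samples.values():
            if info.phase not in seen:
                seen.append(info.phase)
        return tuple(seen)

    def sample_id(self, bait: str, phase: str) -> str:
        ids = [
            s
            for s, info in self.samples.items()
            if info.bait == bait and info.phase == phase and s in self.counts.columns
        ]
        if not ids:
            raise KeyError(f"no sample for bait={bait!r} phase={phase!r}")
        if bait == IGG and len(ids) > 1:
            raise ConfigurationError(f"multiple IgG samples for phase {phase!r}: {ids}")
        return ids[0]

    def bait_counts(self, bait: str, phase: str) -> pd.Series:
        return self.counts[self.sample_id(bait, phase)]

    def igg_counts(self, phase: str) -> pd.Series:
        return self.counts[self.sample_id(IGG, phase)]


def flag_low_enrichment(
    counts: SpectralCountTable, bait: str, phase: str, min_peptides: int = 4
) -> set[str]:
    """Proteins whose bait-sample count is strictly below ``min_peptides``.

    The boundary follows the protocol wording "less than four peptides":
    a count equal to ``min_peptides`` passes.
    """
    col = counts.bait_counts(bait, phase)
    return set(col.index[col < min_peptides])


def log2_enrichment(bait_count: float, igg_count: float, pseudocount: float = 1.0) -> float:
    """log2 fold change of bait over IgG counts with an additive pseudocount."""
    if bait_count < 0 or igg_count < 0:
        raise ValueError("counts must be non-negative")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    return math.log2((bait_count + pseudocount) / (igg_count + pseudocount))


def flag_contaminants(
    proteins: Iterable[str], contaminant_families: Iterable[str]
) -> set[str]:
    """Proteins whose identifier starts with a contaminant-family prefix.

    Matching is case-insensitive; families are gene-symbol prefixes such as
    ACT (actins), KRT (keratins), TUB (tubulins), HIST (histone clusters).
    """
    prefixes = tuple(f.upper() for f in contaminant_families)
    if not prefixes:
        return set()
    return {p for p in proteins if str(p).upper().startswith(prefixes)}


def classify_hits(counts: SpectralCountTable, config: FilterConfig | None = None) -> pd.DataFrame:
    """Apply the three filters to every pulldown and return the hit table.

    One row per (protein, bait, phase) for proteins with a nonzero count in
    that bait sample. ``status`` is True iff ``reason == "hit"``; the reason
    is the first failing filter in the fixed order low_enrichment ->
    low_fold_change -> contaminant.
    """
    config = config or FilterConfig()
    rows: list[pd.DataFrame] = []
    for phase in counts.phases:
        baits_here = [
            info.bait
            for s, info in counts.samples.items()
            if info.phase == phase and not info.is_control and s in counts.counts.columns
        ]
        if not baits_here:
            continue
        try:
            igg = counts.igg_counts(phase)
        except KeyError as exc:
            raise ConfigurationError(f"missing IgG sample for phase {phase!r}") from exc
        for bait in baits_here:
            bc = counts.bait_counts(bait, phase)
            observed = bc[bc > 0]
            if observed.empty:
                continue
            b = observed.to_numpy(dtype=float)
            g = igg.loc[observed.index].to_numpy(dtype=float)
            l2fc = np.log2((b + config.pseudocount) / (g + config.pseudocount))
            contam = np.array(
                [p in flag_contaminants(observed.index, config.contaminant_families)
                 for p in observed.index]
            )
            reason = np.select(
                [
                    b < config.min_peptides,
                    l2fc < config.log2fc_threshold,
                    contam,
                ],
                ["low_enrichment", "low_fold_change", "contaminant"],
                default="hit",
            )
            rows.append(
                pd.DataFrame(
                    {
                        "protein": observed.index,
                        "bait": bait,
                        "phase": phase,
                        "status": reason == "hit",
                        "reason": reason,
                        "bait_count": observed.to_numpy(),
                        "igg_count": igg.loc[observed.index].to_numpy(),
                        "log2fc": l2fc,
                    }
                )
            )
    if not rows:
        return pd.DataFrame(columns=list(HIT_COLUMNS))
    out = pd.concat(rows, ignore_index=True)
    return out[list(HIT_COLUMNS)]


def qc_enrichment_ratio(
    counts: SpectralCountTable,
    hits: pd.DataFrame,
    bait: str,
    phase: str,
    pseudocount: float = 1.0,
) -> tuple[float, float]:
    """Summed bait/IgG count ratio before and after filtering.

    ``before`` sums every protein in the pulldown; ``after`` restricts both
    sums to True hits. A pseudocount protects against a zero denominator.
    This is the summed-count reading of the published post-filtration
    enrichment check; a per-bait-protein reading is also defensible.
    """
    bc = counts.bait_counts(bait, phase)
    gc = counts.igg_counts(phase)
    denom = float(gc.sum())
    before = float(bc.sum()) / (denom if denom > 0 else pseudocount)
    sel = hits[(hits["bait"] == bait) & (hits["phase"] == phase) & hits["status"]]
    true_proteins = sel["protein"].tolist()
    denom_after = float(gc.loc[true_proteins].sum())
    after = float(bc.loc[true_proteins].sum()) / (
        denom_after if denom_after > 0 else pseudocount
    )
    return before, after


def reason_tallies(hits: pd.DataFrame) -> dict[str, int]:
    """Record counts per reason code; values sum to ``len(hits)``."""
    tallies = {r: 0 for r in HIT_REASONS}
    tallies.update(hits["reason"].value_counts().to_dict())
    return tallies
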