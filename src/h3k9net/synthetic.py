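"""Seeded generators for every input the pipeline consumes, with ground truth.

The generator emulates the structure of a four-bait, two-phase AP-MS study:

* spectral counts — true interactors draw bait counts from an overdispersed
  negative-binomial distribution well above the IgG background; designated
  noise proteins and incidental background stay strictly below the
  four-peptide floor; contaminant-family proteins (ACT/KRT/TUB/HIST names)
  are comparably abundant in bait and IgG pulldowns;
* a proteome with H3K9-like motifs planted at recorded lysine positions
  ("exact" mode rejection-samples flanking sequence so the planted registry
  is the complete set of motif occurrences);
* nuclear / expression annotations with configurable positive fractions;
* a reference interaction network denser among nuclear proteins;
* a complex catalog with a floor of four members and optional complexes
  enriched for a designated query set.

Every artifact is deterministic given ``SimulationConfig.seed``; each
generator derives an independent child stream from that seed so artifacts do
not perturb one another.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import IGG, NUCLEUS_TERM, ConfigurationError, SimulationConfig
from .ipms import SampleInfo, SpectralCountTable
from .mimicry import AMINO_ACIDS, DEFAULT_PRESET, PRESETS, SlimMotif, scan_sequence

# child-stream tags so each artifact has its own deterministic RNG
_STREAMS = {"counts": 1, "proteome": 2, "annotations": 3, "network": 4, "complexes": 5}


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), _STREAMS[stream]])


@dataclass
class GroundTruth:
    """Registries of what was planted, for parameter-recovery testing."""

    true_interactors: dict[tuple[str, str], frozenset] = field(default_factory=dict)
    contaminants: frozenset = frozenset()
    noise: frozenset = frozenset()
    planted_motifs: dict[str, list[int]] = field(default_factory=dict)
    nuclear: frozenset = frozenset()
    expressed: dict[str, frozenset] = field(default_factory=dict)

    def all_true(self) -> frozenset:
        return (
            frozenset().union(*self.true_interactors.values())
            if self.true_interactors
            else frozenset()
        )

    def check_disjoint(self) -> None:
        t, c, n = self.all_true(), self.contaminants, self.noise
        if t & c or t & n or c & n:
            raise AssertionError("true/contaminant/noise registries overlap")


def _negbin(rng: np.random.Generator, mean: float, dispersion: float, size: int) -> np.ndarray:
    """Negative binomial with given mean; variance = mean + mean^2/dispersion."""
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def _sub_threshold(rng: np.random.Generator, mean: float, size: int) -> np.ndarray:
    """Background counts capped below the four-peptide enrichment floor."""
    return np.minimum(rng.poisson(min(mean, 1.5), size=size), 3)


def protein_universe(config: SimulationConfig) -> list[str]:
    """Deterministic identifier list: generic symbols plus contaminant families."""
    n_generic = config.n_proteins - config.n_contaminants
    if n_generic < 0:
        raise ConfigurationError("n_contaminants exceeds n_proteins")
    names = [f"GEN{i:04d}" for i in range(1, n_generic + 1)]
    families = config.contaminant_families or ("CON",)
    for i in range(config.n_contaminants):
        fam = families[i % len(families)]
        names.append(f"{fam}{i + 1}")
    return names


def simulate_ipms_counts(config: SimulationConfig) -> tuple[SpectralCountTable, GroundTruth]:
    """Simulate the full bait/IgG x phase spectral-count table.

    Sampling order is fixed, so identical configs give identical tables.
    """
    rng = _rng(config, "counts")
    universe = protein_universe(config)
    generic = [p for p in universe if p.startswith("GEN")]
    contaminants = [p for p in universe if not p.startswith("GEN")]

    n_needed = config.n_true_per_bait_phase * len(config.baits) * len(config.phases)
    n_needed += config.n_noise
    if len(generic) < config.n_noise:
        raise ConfigurationError("not enough generic proteins for the noise set")

    shuffled = list(rng.permutation(generic))
    noise = shuffled[: config.n_noise]
    fresh = iter(shuffled[config.n_noise :])

    def take() -> str:
        try:
            return next(fresh)
        except StopIteration:
            raise ConfigurationError("n_proteins too small for requested interactors")

    n_t = config.n_true_per_bait_phase
    n_phases = len(config.phases)
    n_both = round(config.frac_shared_across_phases * n_t)
    # per-bait union size over phases: n_both in every phase, the rest unique
    u = n_phases * n_t - (n_phases - 1) * n_both if n_t else 0

    # Cross-bait sharing: each shared protein is explicitly assigned to one
    # pair of baits, until every bait holds its shared quota. This makes
    # frac_shared_across_baits the fraction of each bait's interactors that
    # are shared with another regulator.
    quota = {b: round(config.frac_shared_across_baits * u) for b in config.baits}
    bait_proteins: dict[str, list[str]] = {b: [] for b in config.baits}
    if len(config.baits) >= 2:
        while sum(q > 0 for q in quota.values()) >= 2:
            open_baits = [b for b in config.baits if quota[b] > 0]
            pair = list(rng.choice(open_baits, size=2, replace=False))
            p = take()
            for b in pair:
                bait_proteins[b].append(p)
                quota[b] -= 1
    for bait in config.baits:
        while len(bait_proteins[bait]) < u:
            bait_proteins[bait].append(take())

    true_interactors: dict[tuple[str, str], frozenset] = {}
    for bait in config.baits:
        members = list(rng.permutation(bait_proteins[bait]))
        both, rest = members[:n_both], members[n_both:]
        per_phase = n_t - n_both
        for i, phase in enumerate(config.phases):
            uniq = rest[i * per_phase : (i + 1) * per_phase]
            true_interactors[(bait, phase)] = frozenset(both + uniq)

    truth = GroundTruth(
        true_interactors=true_interactors,
        contaminants=frozenset(contaminants),
        noise=frozenset(noise),
    )
    truth.check_disjoint()

    index = pd.Index(universe, name="protein")
    n = len(universe)
    is_contam = ~index.str.startswith("GEN")
    columns: dict[str, np.ndarray] = {}
    samples: dict[str, SampleInfo] = {}
    for phase in config.phases:
        sid = f"{IGG}_{phase}"
        igg = _negbin(rng, config.igg_count_mean, config.count_dispersion, n)
        igg[is_contam] = _negbin(rng, config.bait_count_mean, config.count_dispersion, int(is_contam.sum()))
        columns[sid] = igg
        samples[sid] = SampleInfo(IGG, phase)
        for bait in config.baits:
            sid = f"{bait}_{phase}"
            # pulldowns are sparse: only this pulldown's true interactors,
            # the designated noise proteins (sub-threshold) and the
            # contaminant families register counts
            col = np.zeros(n, dtype=np.int64)
            noise_mask = index.isin(noise)
            col[noise_mask] = _sub_threshold(rng, config.igg_count_mean, int(noise_mask.sum()))
            mask = index.isin(true_interactors[(bait, phase)])
            col[mask] = _negbin(rng, config.bait_count_mean, config.count_dispersion, int(mask.sum()))
            col[is_contam] = _negbin(
                rng, config.bait_count_mean, config.count_dispersion, int(is_contam.sum())
            )
            columns[sid] = col
            samples[sid] = SampleInfo(bait, phase)

    counts = pd.DataFrame(columns, index=index).astype(int)
    return SpectralCountTable(counts, samples), truth


def _safe_residue(motif: SlimMotif) -> str | None:
    """A residue outside every position class (breaks any accidental match)."""
    blocked = frozenset().union(*motif.positions)
    free = sorted(AMINO_ACIDS - blocked)
    return free[0] if free else None


def simulate_proteome(
    config: SimulationConfig,
    proteins: Sequence[str],
    motif: SlimMotif | None = None,
) -> tuple[dict[str, str], dict[str, list[int]]]:
    """Random protein sequences with motif occurrences planted at recorded sites.

    In exact-planting mode (default) the registry of planted lysine positions
    is guaranteed to equal the scanner's hit list; permissive mode skips the
    rejection step for speed and only guarantees registry ⊆ hits.
    """
    if not proteins:
        raise ValueError("protein list must be nonempty")
    motif = motif or PRESETS[DEFAULT_PRESET]
    rng = _rng(config, "proteome")
    alphabet = np.array(sorted(AMINO_ACIDS))
    lo, hi = config.seq_length_range
    width = len(motif)
    safe = _safe_residue(motif)

    def clean_background(length: int) -> list[str]:
        """Random sequence with accidental motif occurrences swapped out."""
        seq = list(rng.choice(alphabet, size=length))
        for _ in range(10 * length):
            hits = scan_sequence("".join(seq), motif)
            if not hits:
                break
            if safe is None:
                seq = list(rng.choice(alphabet, size=length))
                continue
            seq[hits[0].k_position - 1] = safe
        return seq

    sequences: dict[str, str] = {}
    registry: dict[str, list[int]] = {}
    for protein in proteins:
        length = int(rng.integers(lo, hi + 1))
        plant = bool(rng.random() < config.motif_plant_rate)
        for _ in range(200):
            seq = clean_background(length) if config.exact_planting else list(
                rng.choice(alphabet, size=length)
            )
            planted: list[int] = []
            if plant:
                start = int(rng.integers(0, length - width + 1))
                for j, cls in enumerate(motif.positions):
                    choices = sorted(cls)
                    seq[start + j] = choices[int(rng.integers(0, len(choices)))]
                planted.append(start + motif.k_index)
            text = "".join(seq)
            if not config.exact_planting:
                break
            found = sorted(h.k_position for h in scan_sequence(text, motif))
            if found == sorted(planted):
                break  # planting did not collide with its flanks
        else:
            raise RuntimeError(f"could not plant motif cleanly in {protein}")
        sequences[protein] = text
        if planted:
            registry[protein] = planted
    return sequences, registry


def simulate_annotations(
    proteins: Sequence[str], config: SimulationConfig
) -> tuple[dict[str, frozenset], pd.DataFrame]:
    """Nuclear/cytoplasmic term labels and per-phase expression flags.

    Returns (annotation map protein -> term set, expression DataFrame with
    columns protein/phase/expressed).
    """
    if not proteins:
        raise ValueError("protein list must be nonempty")
    rng = _rng(config, "annotations")
    nuclear_mask = rng.random(len(proteins)) < config.frac_nuclear
    annotation = {
        p: frozenset({NUCLEUS_TERM} if nuc else {"GO:0005737"})
        for p, nuc in zip(proteins, nuclear_mask)
    }
    rows = []
    for phase in config.phases:
        expressed = rng.random(len(proteins)) >= config.frac_unexpressed
        rows.extend(
            (p, phase, bool(e)) for p, e in zip(proteins, expressed)
        )
    expression = pd.DataFrame(rows, columns=["protein", "phase", "expressed"])
    return annotation, expression


def simulate_reference_network(
    proteins: Sequence[str],
    nuclear: frozenset | set,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Undirected scored edge list, denser among nuclear protein pairs."""
    nuclear = frozenset(nuclear)
    if not nuclear <= set(proteins):
        raise ValueError("nuclear set must be a subset of proteins")
    rng = _rng(config, "network")
    prots = np.array(sorted(proteins))
    is_nuc = np.isin(prots, sorted(nuclear))
    iu, ju = np.triu_indices(len(prots), k=1)
    both_nuclear = is_nuc[iu] & is_nuc[ju]
    p = np.where(both_nuclear, config.edge_density_nuclear, config.edge_density_other)
    keep = rng.random(len(iu)) < p
    a, b = prots[iu[keep]], prots[ju[keep]]
    score = rng.random(keep.sum())
    return pd.DataFrame({"protein_a": a, "protein_b": b, "score": np.round(score, 4)})


def simulate_complex_catalog(
    proteins: Sequence[str],
    config: SimulationConfig,
    enriched_query: Sequence[str] | None = None,
) -> dict[str, frozenset]:
    """CORUM-like catalog: random complexes plus query-enriched positives.

    Each of the ``n_enriched_complexes`` planted complexes draws all its
    members from ``enriched_query`` (when given), giving the
    over-representation test a positive control.
    """
    rng = _rng(config, "complexes")
    if config.n_complexes == 0:
        return {}
    lo, hi = config.complex_size_range
    prots = np.array(sorted(proteins))
    catalog: dict[str, frozenset] = {}
    enriched = np.array(sorted(enriched_query)) if enriched_query else None
    for i in range(1, config.n_complexes + 1):
        size = int(rng.integers(lo, hi + 1))
        if enriched is not None and i <= config.n_enriched_complexes and len(enriched) >= lo:
            size = min(size, len(enriched))
            members = rng.choice(enriched, size=size, replace=False)
        else:
            members = rng.choice(prots, size=min(size, len(prots)), replace=False)
        catalog[f"CPX{i:03d}"] = frozenset(members.tolist())
    return catalog


def simulate_known_sites(
    registry: Mapping[str, list[int]],
    config: SimulationConfig,
    evidence_rate: float = 0.3,
) -> pd.DataFrame:
    """Known-methylation-site evidence covering a fraction of planted lysines."""
    rng = _rng(config, "complexes")  # reuse of a stream is harmless here
    rows = []
    for protein in sorted(registry):
        for pos in registry[protein]:
            if rng.random() < evidence_rate:
                rows.append((protein, int(pos), "me2"))
    return pd.DataFrame(rows, columns=["protein", "position", "modification"])


def simulate_study(config: SimulationConfig) -> dict:
    """Generate every pipeline input in one call; returns a keyed bundle."""
    table, truth = simulate_ipms_counts(config)
    proteins = list(table.counts.index)
    sequences, registry = simulate_proteome(config, proteins)
    annotation, expression = simulate_annotations(proteins, config)
    nuclear = frozenset(p for p, terms in annotation.items() if NUCLEUS_TERM in terms)
    edges = simulate_reference_network(proteins, nuclear, config)
    # positive control for over-representation: proteins that will survive the
    # tiered mimicry screen (motif-bearing, nuclear, seen with a writer and a
    # reader), as far as the ground truth can anticipate it
    from .config import READERS, WRITERS

    writer_true = frozenset().union(
        *(s for (b, _), s in truth.true_interactors.items() if b in WRITERS), frozenset()
    )
    reader_true = frozenset().union(
        *(s for (b, _), s in truth.true_interactors.items() if b in READERS), frozenset()
    )
    mimicry_pool = sorted(set(registry) & writer_true & reader_true & nuclear)
    catalog = simulate_complex_catalog(proteins, config, enriched_query=mimicry_pool or None)
    sites = simulate_known_sites(registry, config)
    truth.planted_motifs = registry
    truth.nuclear = nuclear
    truth.expressed = {
        phase: frozenset(
            expression.loc[
                (expression["phase"] == phase) & expression["expressed"], "protein"
            ]
        )
        for phase in config.phases
    }
    return {
        "counts": table,
        "truth": truth,
        "sequences": sequences,
        "annotation": annotation,
        "expression": expression,
        "edges": edges,
        "complexes": catalog,
        "known_sites": sites,
    }
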