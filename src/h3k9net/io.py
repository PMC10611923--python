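"""Readers and writers for the pipeline's plain-text interchange formats.

Everything is TSV except protein sequences (FASTA, via Biopython). Count
tables exist in long form (protein, sample, count) and wide form (protein x
sample matrix); sample metadata travels in a sidecar TSV (sample, bait,
phase) or is parsed from ``BAIT_PHASE`` column names.
"""
from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .ipms import SampleInfo, SpectralCountTable


# -- spectral counts ---------------------------------------------------------

def write_counts(table: SpectralCountTable, path: str | Path, long_form: bool = False) -> None:
    path = Path(path)
    if long_form:
        long_df = (
            table.counts.rename_axis("protein")
            .reset_index()
            .melt(id_vars="protein", var_name="sample", value_name="count")
        )
        long_df.to_csv(path, sep="\t", index=False)
    else:
        table.counts.rename_axis("protein").to_csv(path, sep="\t")
    meta = pd.DataFrame(
        [(s, info.bait, info.phase) for s, info in table.samples.items()],
        columns=["sample", "bait", "phase"],
    )
    meta.to_csv(path.with_suffix(".samples.tsv"), sep="\t", index=False)


def read_counts(path: str | Path) -> SpectralCountTable:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if set(df.columns) == {"protein", "sample", "count"}:
        wide = df.pivot(index="protein", columns="sample", values="count").fillna(0)
    else:
        wide = df.set_index("protein")
    wide = wide.astype(int)
    meta_path = path.with_suffix(".samples.tsv")
    samples: dict[str, SampleInfo] = {}
    if meta_path.exists():
        meta = pd.read_csv(meta_path, sep="\t")
        samples = {
            row.sample: SampleInfo(row.bait, row.phase) for row in meta.itertuples(index=False)
        }
    else:  # fall back to BAIT_PHASE column names
        for col in wide.columns:
            bait, _, phase = str(col).rpartition("_")
            if not bait:
                raise ValueError(f"cannot parse sample metadata from column {col!r}")
            samples[col] = SampleInfo(bait, phase)
    return SpectralCountTable(wide, samples)


# -- generic tables ----------------------------------------------------------

def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_annotation(annotation: Mapping[str, frozenset], path: str | Path) -> None:
    rows = [(p, t) for p in sorted(annotation) for t in sorted(annotation[p])]
    write_table(pd.DataFrame(rows, columns=["protein", "term"]), path)


def read_annotation(path: str | Path) -> dict[str, frozenset]:
    df = read_table(path)
    out: dict[str, set] = {}
    for p, t in zip(df["protein"], df["term"]):
        out.setdefault(p, set()).add(t)
    return {p: frozenset(t) for p, t in out.items()}


def write_complexes(catalog: Mapping[str, frozenset], path: str | Path) -> None:
    rows = [(c, m) for c in sorted(catalog) for m in sorted(catalog[c])]
    write_table(pd.DataFrame(rows, columns=["complex_id", "member"]), path)


def read_complexes(path: str | Path) -> dict[str, frozenset]:
    df = read_table(path)
    out: dict[str, set] = {}
    for c, m in zip(df["complex_id"], df["member"]):
        out.setdefault(c, set()).add(m)
    return {c: frozenset(m) for c, m in out.items()}


def write_protein_sets(sets: Mapping[tuple[str, str], frozenset], path: str | Path) -> None:
    rows = [
        (b, p, m) for (b, p) in sorted(sets) for m in sorted(sets[(b, p)])
    ]
    write_table(pd.DataFrame(rows, columns=["bait", "phase", "protein"]), path)


def read_protein_sets(path: str | Path) -> dict[tuple[str, str], frozenset]:
    df = read_table(path)
    out: dict[tuple[str, str], set] = {}
    for b, p, m in zip(df["bait"], df["phase"], df["protein"]):
        out.setdefault((b, p), set()).add(m)
    return {k: frozenset(v) for k, v in out.items()}


# -- FASTA -------------------------------------------------------------------

def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise ValueError(f"duplicate protein id in FASTA: {record.id}")
        sequences[record.id] = str(record.seq)
    return sequences


# -- graphs ------------------------------------------------------------------

def write_graphml(graph, path: str | Path) -> None:
    import networkx as nx

    nx.write_graphml(graph, str(path))


def graph_to_edge_frame(graph) -> pd.DataFrame:
    rows = [
        (min(u, v), max(u, v), data.get("score"))
        for u, v, data in graph.edges(data=True)
    ]
    rows.sort()
    return pd.DataFrame(rows, columns=["protein_a", "protein_b", "score"])
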