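"""Nuclear-annotation and transcriptome-expression validation of interactomes.

Cellular interactomes are restricted to proteins positively annotated with
the GO cellular-component term nucleus (GO:0005634), then further to proteins
called expressed in the phase-matched transcriptome. Both steps are
partitions of their input and are implemented as plain intersections, so
applying them in either order gives the same validated set.
"""
from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd

from .config import NUCLEUS_TERM


def filter_by_term(
    proteins: Iterable[str],
    annotation: Mapping[str, frozenset],
    term: str = NUCLEUS_TERM,
    keep_unknown: bool = False,
) -> tuple[frozenset, frozenset]:
    """Partition proteins by presence of an annotation term.

    Proteins absent from the annotation table count as lacking the term
    (inclusion requires positive annotation) unless ``keep_unknown``.
    """
    if not term:
        raise ValueError("term must be nonempty")
    proteins = frozenset(proteins)
    retained = set()
    for p in proteins:
        terms = annotation.get(p)
        if terms is None:
            if keep_unknown:
                retained.add(p)
        elif term in terms:
            retained.add(p)
    return frozenset(retained), proteins - retained


def expression_table_to_map(expression: pd.DataFrame) -> dict[tuple[str, str], bool]:
    """Long-form (protein, phase, expressed) frame -> lookup map."""
    return {
        (p, ph): bool(e)
        for p, ph, e in zip(
            expression["protein"], expression["phase"], expression["expressed"]
        )
    }


def expression_validate(
    proteins: Iterable[str],
    expression: Mapping[tuple[str, str], bool] | pd.DataFrame,
    phase: str,
) -> tuple[frozenset, frozenset]:
    """Partition proteins by expressed-in-phase flags.

    Proteins missing from the expression table are treated as not expressed
    and removed, mirroring the exclusion of interactors absent from the
    transcriptome dataset.
    """
    if isinstance(expression, pd.DataFrame):
        expression = expression_table_to_map(expression)
    proteins = frozenset(proteins)
    validated = frozenset(p for p in proteins if expression.get((p, phase), False))
    return validated, proteins - validated
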