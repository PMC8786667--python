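"""Study-specific aggregation ("misclassification") matrices.

Verbal-autopsy studies report heterogeneous cause lists: a study may lump
several true causes into one reported category or fold them into a residual
"other" group.  The matrix G (reported categories x true causes) is binary
and *not estimated* — it is fully determined by which causes a study
reports — and translates the common true-cause probability vector p into
the study's reported-category probabilities q = G p.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .taxonomy import CauseTaxonomy


@dataclass(frozen=True)
class MisclassMatrix:
    """Binary map from true causes (columns) to reported categories (rows).

    Invariants: each column sums to exactly 1 (every true cause lands in
    exactly one reported category), each row sums to >= 1 (no empty
    reported category), hence J <= C.
    """

    study_id: str
    reported_causes: tuple[str, ...]
    true_causes: tuple[str, ...]
    G: np.ndarray

    def __post_init__(self) -> None:
        G = np.asarray(self.G, dtype=float)
        object.__setattr__(self, "G", G)
        J, C = G.shape
        if J != len(self.reported_causes) or C != len(self.true_causes):
            raise ValueError("G shape inconsistent with cause lists")
        if not np.isin(G, (0.0, 1.0)).all():
            raise ValueError("G must be binary")
        if not (G.sum(axis=0) == 1).all():
            raise ValueError("every true cause must map to exactly one reported category")
        if not (G.sum(axis=1) >= 1).all():
            raise ValueError("every reported category must receive at least one true cause")

    @property
    def n_reported(self) -> int:
        return self.G.shape[0]

    @property
    def is_identity(self) -> bool:
        return self.G.shape[0] == self.G.shape[1] and (self.G == np.eye(self.G.shape[0])).all()


def build_matrix(
    taxonomy: CauseTaxonomy,
    reported_causes: list[str] | tuple[str, ...],
    mapping: Mapping[str, str],
    study_id: str = "",
) -> MisclassMatrix:
    """Construct G from an explicit true-cause -> reported-category mapping.

    Every true cause in the taxonomy must be assigned to exactly one
    reported category and every reported category must be used; otherwise
    construction fails loudly rather than guessing.
    """
    reported = tuple(reported_causes)
    missing = [c for c in taxonomy.causes if c not in mapping]
    if missing:
        raise ValueError(f"{study_id or 'study'}: true causes unmapped: {missing}")
    bad = {c: j for c, j in mapping.items() if j not in reported}
    if bad:
        raise ValueError(f"{study_id or 'study'}: mapping targets unknown categories: {bad}")
    G = np.zeros((len(reported), taxonomy.n_causes))
    for ci, cause in enumerate(taxonomy.causes):
        G[reported.index(mapping[cause]), ci] = 1.0
    unused = [reported[j] for j in range(len(reported)) if G[j].sum() == 0]
    if unused:
        raise ValueError(f"{study_id or 'study'}: reported categories with no mapped cause: {unused}")
    return MisclassMatrix(study_id, reported, taxonomy.causes, G)


def default_matrix(
    taxonomy: CauseTaxonomy,
    reported_causes: list[str] | tuple[str, ...],
    study_id: str = "",
    residual: str = "other",
) -> MisclassMatrix:
    """G under the default convention: any true cause the study does not
    report maps to the study's residual category.

    Raises if an unreported cause exists but the study has no residual
    category to absorb it.
    """
    reported = tuple(reported_causes)
    mapping: dict[str, str] = {}
    for cause in taxonomy.causes:
        if cause in reported:
            mapping[cause] = cause
        elif residual in reported:
            mapping[cause] = residual
        else:
            raise ValueError(
                f"{study_id or 'study'}: cause {cause!r} unreported and no "
                f"{residual!r} category to absorb it"
            )
    return build_matrix(taxonomy, reported, mapping, study_id)


def aggregate_probs(matrix: MisclassMatrix, p: np.ndarray) -> np.ndarray:
    """Reported-category probabilities q = G p.

    Conservation: because each G column sums to 1, sum(q) = sum(p).
    """
    p = np.asarray(p, dtype=float)
    if p.shape[-1] != matrix.G.shape[1]:
        raise ValueError(
            f"p has {p.shape[-1]} causes, matrix expects {matrix.G.shape[1]}"
        )
    return p @ matrix.G.T
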