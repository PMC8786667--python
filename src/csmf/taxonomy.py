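"""Cause taxonomies for the two under-5 age groups.

A taxonomy is the ordered list of *true* causes modelled for an age group,
with one designated reference ("base") cause whose multinomial-logit
contrast is fixed at zero.  The reference cause differs between the fitted
models: preterm birth complications for the low-mortality neonatal model,
intrapartum-related events for the high-mortality neonatal model, and lower
respiratory infections for both child models, reflecting which cause
carries the largest burden in each stratum.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum


class AgeGroup(str, Enum):
    NEONATAL = "neonatal"
    CHILD_1TO59M = "child_1to59m"


#: Canonical true-cause lists.  Neonatal sepsis and meningitis are modelled
#: as one combined cause and split afterwards using an external ratio.
NEONATAL_CAUSES = (
    "tetanus",
    "lower_respiratory_infections",
    "preterm",
    "intrapartum",
    "sepsis_meningitis",
    "congenital",
    "diarrhoea",
    "other",
)

CHILD_CAUSES = (
    "lower_respiratory_infections",
    "diarrhoea",
    "meningitis",
    "injury",
    "malaria",
    "congenital",
    "perinatal",
    "other",
)


@dataclass(frozen=True)
class CauseTaxonomy:
    """Ordered true-cause list for one age group with a reference cause."""

    age_group: AgeGroup
    causes: tuple[str, ...]
    base_cause: str

    def __post_init__(self) -> None:
        if len(set(self.causes)) != len(self.causes):
            raise ValueError("causes must be unique")
        if self.base_cause not in self.causes:
            raise ValueError(
                f"base cause {self.base_cause!r} not in cause list {self.causes}"
            )
        required = (
            set(NEONATAL_CAUSES)
            if self.age_group == AgeGroup.NEONATAL
            else set(CHILD_CAUSES)
        )
        missing = required - set(self.causes)
        if missing:
            raise ValueError(
                f"{self.age_group.value} taxonomy missing required causes: {sorted(missing)}"
            )

    @property
    def n_causes(self) -> int:
        return len(self.causes)

    @property
    def base_index(self) -> int:
        return self.causes.index(self.base_cause)

    @property
    def contrast_causes(self) -> tuple[str, ...]:
        """Causes with a free logit contrast (everything except the base)."""
        return tuple(c for c in self.causes if c != self.base_cause)

    def index(self, cause: str) -> int:
        return self.causes.index(cause)

    def with_base(self, base_cause: str) -> "CauseTaxonomy":
        return replace(self, base_cause=base_cause)

    @classmethod
    def custom(
        cls, age_group: AgeGroup, causes: tuple[str, ...] | list[str], base_cause: str
    ) -> "CauseTaxonomy":
        """Free-form taxonomy that bypasses the required-cause check.

        For reduced or simulated cause lists; the canonical constructors
        enforce the full neonatal/child cause sets.
        """
        causes = tuple(causes)
        if len(set(causes)) != len(causes):
            raise ValueError("causes must be unique")
        if base_cause not in causes:
            raise ValueError(f"base cause {base_cause!r} not in cause list")
        obj = object.__new__(cls)
        object.__setattr__(obj, "age_group", age_group)
        object.__setattr__(obj, "causes", causes)
        object.__setattr__(obj, "base_cause", base_cause)
        return obj

    def without(self, *drop: str) -> "CauseTaxonomy":
        """Taxonomy with causes removed (bypasses the required-cause check).

        Used for the low-mortality neonatal model, where diarrhoea deaths
        are assumed to be zero and the cause is dropped before fitting.
        """
        causes = tuple(c for c in self.causes if c not in drop)
        if self.base_cause in drop:
            raise ValueError("cannot drop the base cause")
        obj = object.__new__(CauseTaxonomy)
        object.__setattr__(obj, "age_group", self.age_group)
        object.__setattr__(obj, "causes", causes)
        object.__setattr__(obj, "base_cause", self.base_cause)
        return obj


def neonatal_taxonomy(base_cause: str = "intrapartum") -> CauseTaxonomy:
    """Neonatal (0-27 days) taxonomy.

    Default reference is intrapartum-related events (the high-mortality
    model's choice); pass ``base_cause="preterm"`` for the low-mortality
    model.
    """
    return CauseTaxonomy(AgeGroup.NEONATAL, NEONATAL_CAUSES, base_cause)


def child_taxonomy(base_cause: str = "lower_respiratory_infections") -> CauseTaxonomy:
    """1-59 month taxonomy; lower respiratory infections is the reference in
    both mortality strata."""
    return CauseTaxonomy(AgeGroup.CHILD_1TO59M, CHILD_CAUSES, base_cause)
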