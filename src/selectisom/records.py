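"""Core record types shared across the pipeline.

A compound library is a list of :class:`CompoundRecord` (structures) plus,
when dual-target potencies are known, a parallel list of
:class:`ActivityRecord`. Atom indices are 0-based everywhere inside the
package; the SDF boundary converts to the conventional 1-based indices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum


class Source(str, Enum):
    """Provenance of a compound: curated selectivity library or decoy pool."""

    SELECTIVITY_DB = "selectivity_db"
    DECOY = "decoy"


@dataclass(frozen=True)
class CompoundRecord:
    """One molecule: identifier, SMILES, provenance and optional name."""

    compound_id: str
    smiles: str
    source: Source = Source.SELECTIVITY_DB
    name: str | None = None


@dataclass(frozen=True)
class ActivityRecord:
    """Dual-target potencies for one compound, IC50 in nM against targets K and S."""

    compound_id: str
    ic50_K: float
    ic50_S: float

    def __post_init__(self) -> None:
        for label, value in (("ic50_K", self.ic50_K), ("ic50_S", self.ic50_S)):
            if not (math.isfinite(value) and value > 0):
                raise ValueError(
                    f"{label} must be strictly positive and finite, got {value!r}"
                )

    @property
    def pic50_K(self) -> float:
        """pIC50 against K: 9 - log10(IC50 / nM)."""
        return 9.0 - math.log10(self.ic50_K)

    @property
    def pic50_S(self) -> float:
        """pIC50 against S: 9 - log10(IC50 / nM)."""
        return 9.0 - math.log10(self.ic50_S)


@dataclass
class ParseFailure:
    """A rejected input row, kept so no data is lost silently."""

    line_number: int
    content: str
    reason: str


@dataclass
class LibraryReadResult:
    """Outcome of reading a library file: parsed records plus rejections."""

    records: list[CompoundRecord]
    activities: list[ActivityRecord] = field(default_factory=list)
    failures: list[ParseFailure] = field(default_factory=list)
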