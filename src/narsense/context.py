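"""Categorical experimental contexts for the biosensor factor space.

A biosensor experiment is identified by four categorical factors: the growth
medium (M0-M3), the carbon-source supplement (S0-S3), the promoter driving
the transcription factor (P1-P4), and the ribosome binding site tuning its
translation (R1-R5). The full factorial space therefore contains
4 x 4 x 4 x 5 = 320 contexts.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

MEDIA = ("M0", "M1", "M2", "M3")
SUPPLEMENTS = ("S0", "S1", "S2", "S3")
PROMOTERS = ("P1", "P2", "P3", "P4")
RBS_SITES = ("R1", "R2", "R3", "R4", "R5")


@dataclass(frozen=True, order=True)
class ContextKey:
    """One experimental condition: (medium, supplement, promoter, RBS)."""

    medium: str
    supplement: str
    promoter: str
    rbs: str

    def __post_init__(self) -> None:
        for value, levels, name in (
            (self.medium, MEDIA, "medium"),
            (self.supplement, SUPPLEMENTS, "supplement"),
            (self.promoter, PROMOTERS, "promoter"),
            (self.rbs, RBS_SITES, "rbs"),
        ):
            if value not in levels:
                raise ValueError(f"unknown {name} level {value!r}; expected one of {levels}")

    @property
    def context_id(self) -> str:
        return f"{self.medium}-{self.supplement}-{self.promoter}-{self.rbs}"

    @classmethod
    def from_id(cls, context_id: str) -> "ContextKey":
        medium, supplement, promoter, rbs = context_id.split("-")
        return cls(medium=medium, supplement=supplement, promoter=promoter, rbs=rbs)


@dataclass(frozen=True)
class FactorSpace:
    """Ordered categorical factors defining the candidate design space."""

    factors: tuple[tuple[str, tuple[str, ...]], ...] = (
        ("promoter", PROMOTERS),
        ("rbs", RBS_SITES),
        ("medium", MEDIA),
        ("supplement", SUPPLEMENTS),
    )

    def __post_init__(self) -> None:
        for name, levels in self.factors:
            if not levels:
                raise ValueError(f"factor {name!r} has no levels")
            if len(set(levels)) != len(levels):
                raise ValueError(f"factor {name!r} has duplicate levels")

    def levels(self, name: str) -> tuple[str, ...]:
        for fname, flevels in self.factors:
            if fname == name:
                return flevels
        raise KeyError(name)

    @property
    def size(self) -> int:
        n = 1
        for _, levels in self.factors:
            n *= len(levels)
        return n

    def all_contexts(self) -> list[ContextKey]:
        """Full factorial enumeration, in factor order."""
        by_name = dict(self.factors)
        return [
            ContextKey(medium=m, supplement=s, promoter=p, rbs=r)
            for p, r, m, s in itertools.product(
                by_name["promoter"], by_name["rbs"], by_name["medium"], by_name["supplement"]
            )
        ]


def default_factor_space() -> FactorSpace:
    return FactorSpace()
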