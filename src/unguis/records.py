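"""Typed specimen records for the two morphometric datasets.

A :class:`PhalanxRecord` holds the nine raw measurements taken on one distal
phalanx (eight linear distances in millimetres plus the facet–shaft angle in
degrees).  A :class:`FootRecord` holds the thirteen pedal element lengths
(five metatarsals, five proximal phalanges, three intermediate phalanges) of
one individual.  Both carry the categorical labels the downstream analyses
group on.  Any measurement may be ``None`` (missing); validation only checks
values that are present.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import InvalidMeasurementError

#: Names of the eight linear distal-phalanx measurements (mm).
PHALANX_LINEAR_FIELDS = ("BH", "BW", "TPL", "SH14", "SW14", "SH34", "SW34", "VFL")

#: The recognised unguis form groups.  "fossil" and "unassigned" specimens are
#: carried through but never used as statistical baselines.
UNGUIS_GROUPS = ("falcular", "grooming", "ungular", "tegular", "unassigned", "fossil")

#: Names of the thirteen pedal element lengths (mm).
FOOT_ELEMENTS = (
    "mt1", "mt2", "mt3", "mt4", "mt5",
    "pp1", "pp2", "pp3", "pp4", "pp5",
    "ip2", "ip3", "ip5",
)

#: The nine family-level groups used by the discriminant analyses.
DFA_GROUPS = (
    "Galagidae", "Lorisidae", "Daubentoniidae", "Cheirogaleiidae",
    "Lepilemuridae", "Lemuridae", "Indriidae", "Tarsiidae", "Anthropoidea",
)

#: The five clades used by the proximal-phalanx ratio comparisons.
RATIO_GROUPS = ("tarsioids", "lorises", "galagos", "lemuroids", "anthropoids")

#: The two gradistic groups used by the metatarsal ratio comparisons.
GRADISTIC_GROUPS = ("prosimian", "anthropoid")


@dataclass
class PhalanxRecord:
    """One distal phalanx: eight linear measurements (mm) plus FSA (degrees)."""

    specimen_id: str
    taxon: str = ""
    digit: int | None = None
    unguis_group: str = "unassigned"
    BH: float | None = None
    BW: float | None = None
    TPL: float | None = None
    SH14: float | None = None
    SW14: float | None = None
    SH34: float | None = None
    SW34: float | None = None
    VFL: float | None = None
    FSA: float | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.unguis_group not in UNGUIS_GROUPS:
            raise InvalidMeasurementError(
                "unguis_group", f"unknown group {self.unguis_group!r}"
            )
        if self.digit is not None and not 1 <= int(self.digit) <= 5:
            raise InvalidMeasurementError("digit", f"digit must be 1-5, got {self.digit}")
        for name in PHALANX_LINEAR_FIELDS:
            v = getattr(self, name)
            if v is not None and not (v > 0 and math.isfinite(v)):
                raise InvalidMeasurementError(name, f"must be a positive length, got {v}")
        if self.FSA is not None and not 0 < self.FSA < 180:
            raise InvalidMeasurementError("FSA", f"angle must lie in (0, 180), got {self.FSA}")
        if self.VFL is not None and self.TPL is not None and self.VFL > self.TPL + 1e-12:
            raise InvalidMeasurementError("VFL", f"volar feature ({self.VFL}) exceeds TPL ({self.TPL})")
        for name in ("SH14", "SH34"):
            v = getattr(self, name)
            if v is not None and self.TPL is not None and v > self.TPL + 1e-12:
                raise InvalidMeasurementError(name, f"shaft height ({v}) must not exceed TPL ({self.TPL})")

    @property
    def linears(self) -> dict[str, float | None]:
        return {name: getattr(self, name) for name in PHALANX_LINEAR_FIELDS}

    def has_all_linears(self) -> bool:
        return all(getattr(self, name) is not None for name in PHALANX_LINEAR_FIELDS)


@dataclass
class FootRecord:
    """Thirteen pedal element lengths (mm) for one individual."""

    individual_id: str
    taxon: str = ""
    dfa_group: str | None = None
    ratio_group: str | None = None
    gradistic_group: str | None = None
    mt1: float | None = None
    mt2: float | None = None
    mt3: float | None = None
    mt4: float | None = None
    mt5: float | None = None
    pp1: float | None = None
    pp2: float | None = None
    pp3: float | None = None
    pp4: float | None = None
    pp5: float | None = None
    ip2: float | None = None
    ip3: float | None = None
    ip5: float | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.dfa_group is not None and self.dfa_group not in DFA_GROUPS:
            raise InvalidMeasurementError("dfa_group", f"unknown group {self.dfa_group!r}")
        if self.ratio_group is not None and self.ratio_group not in RATIO_GROUPS:
            raise InvalidMeasurementError("ratio_group", f"unknown group {self.ratio_group!r}")
        if self.gradistic_group is not None and self.gradistic_group not in GRADISTIC_GROUPS:
            raise InvalidMeasurementError(
                "gradistic_group", f"unknown group {self.gradistic_group!r}"
            )
        for name in FOOT_ELEMENTS:
            v = getattr(self, name)
            if v is not None and not (v > 0 and math.isfinite(v)):
                raise InvalidMeasurementError(name, f"must be a positive length, got {v}")

    @property
    def elements(self) -> dict[str, float | None]:
        return {name: getattr(self, name) for name in FOOT_ELEMENTS}


@dataclass(frozen=True)
class GroupSummary:
    """Summary statistics (mean, variance, n) for one variable in one group.

    This is the baseline against which single specimens are tested; published
    comparative summaries can be loaded directly without the raw data.
    """

    group: str
    variable: str
    mean: float
    variance: float
    n: int

    def __post_init__(self) -> None:
        if self.variance < 0:
            raise InvalidMeasurementError("variance", f"negative variance {self.variance}")
        if self.n < 1:
            raise InvalidMeasurementError("n", f"n must be >= 1, got {self.n}")
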