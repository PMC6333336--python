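"""Domain types for marker quality evaluation.

The vocabulary mirrors how breeding programs talk about markers: a marker
assay (with a version, because two primer sets for the same polymorphism can
behave very differently), a panel of varieties whose QTL status is known
(donors carry the favourable allele, recipients do not), and a genotype
matrix of allele calls that may be missing, ambiguous or heterozygous.

All types are plain frozen/slotted dataclasses with validation; computation
lives in :mod:`markerqc.metrics` and friends.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional


class CallState(enum.Enum):
    """Outcome of one genotyping attempt on one sample."""

    CALLED = "called"
    MISSING = "missing"
    AMBIGUOUS = "ambiguous"


class MarkerClass(enum.Enum):
    ANONYMOUS = "anonymous"
    QTL_SPECIFIC_SNP = "qtl_specific_snp"
    QTL_SPECIFIC_INDEL = "qtl_specific_indel"
    SSR = "ssr"


class Polarity(enum.Enum):
    """Which QTL allele a marker (or the QTL itself) points at."""

    FAVOURABLE = "favourable"
    UNFAVOURABLE = "unfavourable"
    UNPOLARISED = "unpolarised"
    UNKNOWN = "unknown"


class PanelStatus(enum.Enum):
    DONOR = "donor"
    RECIPIENT = "recipient"
    UNKNOWN = "unknown"


class PolarisationSource(enum.Enum):
    DECLARED = "declared"
    FNR_CORRECTED = "fnr_corrected"


@dataclass(frozen=True)
class AlleleCall:
    """One allele call: a state plus the set of allele labels observed.

    Allele labels are opaque strings so SSR band sizes ("143bp", "Large"),
    SNP bases ("A") and indel states ("Small") share one representation.
    Two labels means heterozygous; ploidy beyond 2 is unsupported.
    """

    state: CallState
    alleles: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.state is CallState.CALLED:
            if not 1 <= len(self.alleles) <= 2:
                raise ValueError(
                    f"CALLED requires 1 or 2 allele labels, got {sorted(self.alleles)}"
                )
        elif self.alleles:
            raise ValueError(f"{self.state.name} call must carry no alleles")

    @classmethod
    def called(cls, *alleles: str) -> "AlleleCall":
        return cls(CallState.CALLED, frozenset(alleles))

    @classmethod
    def missing(cls) -> "AlleleCall":
        return cls(CallState.MISSING)

    @classmethod
    def ambiguous(cls) -> "AlleleCall":
        return cls(CallState.AMBIGUOUS)

    @property
    def is_scored(self) -> bool:
        return self.state is CallState.CALLED

    @property
    def is_het(self) -> bool:
        return self.state is CallState.CALLED and len(self.alleles) == 2


@dataclass(frozen=True)
class MarkerDefinition:
    """Identity, position, polarity and allele assignments of one marker assay.

    ``(marker_id, version)`` is the unique key: alternate primer pairs or
    platforms interrogating the same polymorphism are distinct versions with
    potentially very different technical performance.
    """

    marker_id: str
    version: str = "1"
    platform: str = "unknown"
    chromosome: str = ""
    position_bp: int = 1
    linkage_cM: Optional[float] = None
    marker_class: MarkerClass = MarkerClass.ANONYMOUS
    marker_target: Polarity = Polarity.UNPOLARISED
    favourable_allele: Optional[str] = None
    unfavourable_allele: Optional[str] = None
    derived_qtl_state: Polarity = Polarity.UNKNOWN
    diagnostic: bool = False

    def __post_init__(self) -> None:
        if self.position_bp < 1:
            raise ValueError(f"position_bp must be >= 1, got {self.position_bp}")
        if self.linkage_cM is not None and self.linkage_cM < 0:
            raise ValueError("linkage_cM must be non-negative")
        if self.marker_target is not Polarity.UNPOLARISED:
            if self.favourable_allele is None or self.unfavourable_allele is None:
                raise ValueError(
                    f"{self.marker_id}: a polarised marker needs both "
                    "favourable and unfavourable alleles"
                )
            if self.favourable_allele == self.unfavourable_allele:
                raise ValueError(
                    f"{self.marker_id}: favourable and unfavourable alleles "
                    "must differ"
                )
        if self.diagnostic and self.linkage_cM not in (0, 0.0):
            raise ValueError(
                f"{self.marker_id}: a diagnostic marker assays the causal "
                "polymorphism and must have linkage_cM == 0"
            )

    @property
    def key(self) -> tuple[str, str]:
        return (self.marker_id, self.version)

    @property
    def is_polarised(self) -> bool:
        return self.marker_target is not Polarity.UNPOLARISED


@dataclass(frozen=True)
class QTLDefinition:
    """A QTL interval in 1-based inclusive coordinates.

    ``derived_state`` records which QTL allele is evolutionarily derived;
    it is a property of the QTL, not of any marker that tracks it.
    """

    qtl_id: str
    chromosome: str
    start_bp: int
    end_bp: int
    trait: str = ""
    derived_state: Polarity = Polarity.UNKNOWN

    def __post_init__(self) -> None:
        if self.start_bp < 1 or self.end_bp < self.start_bp:
            raise ValueError(
                f"{self.qtl_id}: invalid interval [{self.start_bp}, {self.end_bp}]"
            )

    def contains(self, chromosome: str, position_bp: int) -> bool:
        return (
            chromosome == self.chromosome
            and self.start_bp <= position_bp <= self.end_bp
        )

    @property
    def midpoint(self) -> float:
        return (self.start_bp + self.end_bp) / 2.0


@dataclass(frozen=True)
class PanelAssignment:
    """Known QTL status of one variety for one QTL.

    DONOR = known QTL[+], RECIPIENT = known QTL[-]; UNKNOWN varieties still
    count toward the breeding pool (and hence utility) but never enter the
    accuracy-rate denominators.
    """

    variety_id: str
    qtl_id: str
    status: PanelStatus
    in_breeding_pool: bool = True


class Panel:
    """All assignments for one QTL, indexed by variety."""

    def __init__(self, assignments: Iterable[PanelAssignment]):
        self._by_variety: dict[str, PanelAssignment] = {}
        for a in assignments:
            if a.variety_id in self._by_variety:
                raise ValueError(
                    f"duplicate panel assignment for variety {a.variety_id!r} "
                    f"/ QTL {a.qtl_id!r}"
                )
            self._by_variety[a.variety_id] = a

    def __len__(self) -> int:
        return len(self._by_variety)

    def __iter__(self):
        return iter(self._by_variety.values())

    def status_of(self, variety_id: str) -> PanelStatus:
        a = self._by_variety.get(variety_id)
        return a.status if a is not None else PanelStatus.UNKNOWN

    @property
    def donors(self) -> set[str]:
        return {
            v for v, a in self._by_variety.items() if a.status is PanelStatus.DONOR
        }

    @property
    def recipients(self) -> set[str]:
        return {
            v
            for v, a in self._by_variety.items()
            if a.status is PanelStatus.RECIPIENT
        }

    @property
    def pool(self) -> set[str]:
        return {v for v, a in self._by_variety.items() if a.in_breeding_pool}


class GenotypeMatrix:
    """Allele calls for an ordered set of markers x varieties.

    Every (marker, variety) pair has exactly one call, possibly MISSING.
    Markers are keyed by ``(marker_id, version)``.
    """

    def __init__(
        self,
        markers: Iterable[MarkerDefinition],
        varieties: Iterable[str],
        calls: Mapping[tuple[str, str, str], AlleleCall] | None = None,
    ):
        self.markers: list[MarkerDefinition] = list(markers)
        self.varieties: list[str] = list(varieties)
        seen: set[tuple[str, str]] = set()
        for m in self.markers:
            if m.key in seen:
                raise ValueError(f"duplicate marker key {m.key}")
            seen.add(m.key)
        if len(set(self.varieties)) != len(self.varieties):
            raise ValueError("duplicate variety ids")
        # calls keyed by (marker_id, version, variety_id)
        self._calls: dict[tuple[str, str, str], AlleleCall] = (
            dict(calls) if calls else {}
        )

    def set_call(
        self, marker: MarkerDefinition | tuple[str, str], variety_id: str,
        call: AlleleCall,
    ) -> None:
        key = marker.key if isinstance(marker, MarkerDefinition) else tuple(marker)
        self._calls[(key[0], key[1], variety_id)] = call

    def get_call(
        self, marker: MarkerDefinition | tuple[str, str], variety_id: str
    ) -> AlleleCall:
        key = marker.key if isinstance(marker, MarkerDefinition) else tuple(marker)
        return self._calls[(key[0], key[1], variety_id)]

    def column(
        self, marker: MarkerDefinition | tuple[str, str]
    ) -> dict[str, AlleleCall]:
        """All calls for one marker, keyed by variety, in variety order."""
        key = marker.key if isinstance(marker, MarkerDefinition) else tuple(marker)
        return {
            v: self._calls[(key[0], key[1], v)] for v in self.varieties
        }

    def find_marker(self, marker_id: str, version: str | None = None
                    ) -> MarkerDefinition:
        for m in self.markers:
            if m.marker_id == marker_id and (version is None or m.version == version):
                return m
        raise KeyError(f"marker {marker_id!r} (version {version!r}) not in matrix")

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def n_varieties(self) -> int:
        return len(self.varieties)

    def items(self):
        return self._calls.items()


@dataclass(frozen=True)
class Diagnostic:
    """One validation finding: where and why a matrix violates an invariant."""

    marker_id: str
    variety_id: str
    reason: str


def validate_matrix(matrix: GenotypeMatrix) -> list[Diagnostic]:
    """Check every type invariant of a genotype matrix.

    Returns one diagnostic per violation; an empty list means the matrix is
    structurally sound. Never raises: callers decide whether findings are
    fatal.
    """
    out: list[Diagnostic] = []
    expected = {
        (m.marker_id, m.version, v)
        for m in matrix.markers
        for v in matrix.varieties
    }
    present = set(k for k, _ in matrix.items())
    for mid, ver, v in sorted(expected - present):
        out.append(Diagnostic(mid, v, f"no call for marker version {ver!r}"))
    for mid, ver, v in sorted(present - expected):
        out.append(
            Diagnostic(mid, v, "call for unknown marker/variety combination")
        )
    for (mid, ver, v), call in matrix.items():
        if call.state is CallState.CALLED and not 1 <= len(call.alleles) <= 2:
            out.append(Diagnostic(mid, v, "CALLED with invalid allele count"))
        elif call.state is not CallState.CALLED and call.alleles:
            out.append(Diagnostic(mid, v, f"{call.state.name} call carries alleles"))
    return out


@dataclass
class MetricsRecord:
    """Computed quality metrics for one marker against one QTL panel.

    Proportions are in [0, 1]; ``None`` means undefined (zero denominator)
    and is never conflated with 0. Panel sizes are reported alongside the
    rates because the rates are only as trustworthy as the number of
    characterised donors and recipients behind them.
    """

    marker_id: str
    version: str
    qtl_id: str
    marker_class: MarkerClass = MarkerClass.ANONYMOUS
    chromosome: str = ""
    position_bp: int = 1
    call_rate: Optional[float] = None
    clarity: Optional[float] = None
    fpr: Optional[float] = None
    fnr: Optional[float] = None
    bp_fpr: Optional[float] = None
    bp_fnr: Optional[float] = None
    utility: Optional[float] = None
    n_donors_scored: int = 0
    n_recipients_scored: int = 0
    n_pool_scored: int = 0
    favourable_allele: Optional[str] = None
    unfavourable_allele: Optional[str] = None
    polarisation_source: PolarisationSource = PolarisationSource.DECLARED
    target_matches_derived: Optional[bool] = None
    ideal_flags: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("call_rate", "clarity", "fpr", "fnr", "bp_fpr", "bp_fnr",
                     "utility"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} out of [0,1]: {v}")
        if (
            self.clarity is not None
            and self.call_rate is not None
            and self.clarity > self.call_rate + 1e-12
        ):
            raise ValueError("clarity cannot exceed call rate")
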