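"""Core marker-quality metrics.

Five core metrics describe a marker's reliability:

* **call rate** — fraction of samples giving any visible result;
* **clarity** — fraction giving an unambiguous, scorable result;
* **FPR** — fraction of known recipients (QTL[-]) mis-classified as QTL[+],
  i.e. lacking the unfavourable allele;
* **FNR** — fraction of known donors (QTL[+]) mis-classified as QTL[-],
  i.e. lacking the favourable allele;
* **utility** — fraction of a breeding pool lacking the favourable allele,
  hence the share of material the marker can be used to improve.

Breeding-program variants (BpFPR, BpFNR) apply the same formulas with donors
and recipients restricted to one program's germplasm.

Conventions adopted here (the definitions leave them open):

* Denominators count *scored* samples only; missingness is reported
  separately through the call rate, so a low call rate cannot masquerade as
  a low error rate.
* Classification is by allele presence: a heterozygote "has" both of its
  alleles, so a het donor is not a false negative and a het recipient is
  not a false positive.
* The rate formulas are applied literally: a recipient carrying a third
  allele — neither favourable nor unfavourable — lacks the unfavourable
  allele and therefore counts as a false positive (and symmetrically for
  donors and the FNR). Unpolymorphic third alleles genuinely mislead
  classification and the metric should say so.
* AMBIGUOUS results are visible (count toward call rate) but not clearly
  scorable (count against clarity).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

from .core import (
    AlleleCall,
    CallState,
    GenotypeMatrix,
    MarkerDefinition,
    MetricsRecord,
    Panel,
    Polarity,
    PolarisationSource,
    QTLDefinition,
)


class MetricsError(ValueError):
    """Raised when a metric is requested under unmet preconditions."""


class PolarisationError(MetricsError):
    """Raised when favourable/unfavourable alleles cannot be assigned."""


class Classification(enum.Enum):
    """How one call classifies a sample for the marker's target QTL."""

    QTL_POS = "qtl_pos"          # carries favourable allele only
    QTL_NEG = "qtl_neg"          # carries unfavourable allele only
    CONFLICT = "conflict"        # het carrying both
    UNINFORMATIVE = "uninformative"  # carries neither (third allele)
    UNSCORED = "unscored"        # missing or ambiguous


def call_rate(calls: Iterable[AlleleCall]) -> Optional[float]:
    """Proportion of samples giving a visible result.

    AMBIGUOUS is visible (a band or signal was seen, just not scorable), so
    only MISSING drops out of the numerator. Returns None on an empty column.
    """
    calls = list(calls)
    if not calls:
        return None
    visible = sum(1 for c in calls if c.state is not CallState.MISSING)
    return visible / len(calls)


def clarity(calls: Iterable[AlleleCall]) -> Optional[float]:
    """Proportion of samples giving a clearly scorable result.

    Both MISSING and AMBIGUOUS fail clarity, so clarity <= call rate always.
    Returns None on an empty column.
    """
    calls = list(calls)
    if not calls:
        return None
    scored = sum(1 for c in calls if c.state is CallState.CALLED)
    return scored / len(calls)


def classify(call: AlleleCall, marker: MarkerDefinition) -> Classification:
    """Classify one call against a polarised marker by allele presence."""
    if not marker.is_polarised:
        raise PolarisationError(
            f"marker {marker.marker_id!r} is unpolarised; run polarise_by_fnr "
            "(or declare favourable/unfavourable alleles) first"
        )
    if call.state is not CallState.CALLED:
        return Classification.UNSCORED
    has_fav = marker.favourable_allele in call.alleles
    has_unfav = marker.unfavourable_allele in call.alleles
    if has_fav and has_unfav:
        return Classification.CONFLICT
    if has_fav:
        return Classification.QTL_POS
    if has_unfav:
        return Classification.QTL_NEG
    return Classification.UNINFORMATIVE


def false_positive_rate(
    column: Mapping[str, AlleleCall],
    marker: MarkerDefinition,
    recipients: set[str],
) -> tuple[Optional[float], int]:
    """(FPR, n recipients scored).

    FPR = fraction of scored known recipients whose call lacks the
    unfavourable allele (and are therefore read as QTL[+]). None if no
    recipient gave a scorable call.
    """
    scored = [
        column[v] for v in recipients
        if v in column and column[v].state is CallState.CALLED
    ]
    if not scored:
        return None, 0
    fp = sum(1 for c in scored if marker.unfavourable_allele not in c.alleles)
    return fp / len(scored), len(scored)


def false_negative_rate(
    column: Mapping[str, AlleleCall],
    marker: MarkerDefinition,
    donors: set[str],
) -> tuple[Optional[float], int]:
    """(FNR, n donors scored).

    FNR = fraction of scored known donors whose call lacks the favourable
    allele (and are therefore read as QTL[-]). None if no donor gave a
    scorable call.
    """
    scored = [
        column[v] for v in donors
        if v in column and column[v].state is CallState.CALLED
    ]
    if not scored:
        return None, 0
    fn = sum(1 for c in scored if marker.favourable_allele not in c.alleles)
    return fn / len(scored), len(scored)


def breeding_rates(
    column: Mapping[str, AlleleCall],
    marker: MarkerDefinition,
    panel: Panel,
) -> tuple[Optional[float], Optional[float]]:
    """(BpFPR, BpFNR): the accuracy rates restricted to the breeding pool.

    Identical formulas on donors/recipients intersected with the pool; the
    resulting association is specific to that program. Components are None
    when the restricted set has no scored member.
    """
    pool = panel.pool
    bp_fpr, _ = false_positive_rate(column, marker, panel.recipients & pool)
    bp_fnr, _ = false_negative_rate(column, marker, panel.donors & pool)
    return bp_fpr, bp_fnr


def utility(
    column: Mapping[str, AlleleCall],
    marker: MarkerDefinition,
    pool: set[str],
) -> tuple[Optional[float], int]:
    """(utility, n pool members scored).

    Fraction of the scored breeding pool lacking the favourable allele —
    the share of material into which the QTL could usefully be introgressed.
    A favourable allele fixed in the pool gives 0; one absent gives 1.
    """
    scored = [
        column[v] for v in pool
        if v in column and column[v].state is CallState.CALLED
    ]
    if not scored:
        return None, 0
    without = sum(1 for c in scored if marker.favourable_allele not in c.alleles)
    return without / len(scored), len(scored)


@dataclass(frozen=True)
class PolarisationResult:
    """Outcome of FNR-correcting an anonymous marker.

    favourable is the allele most frequent among scored donor calls (hence
    minimising the FNR); unfavourable is the most frequent remaining allele
    over all scored calls.
    """

    favourable_allele: str
    unfavourable_allele: str
    source: PolarisationSource
    donor_allele_frequencies: dict[str, float]
    tie_broken: bool = False

    def __post_init__(self) -> None:
        if self.favourable_allele == self.unfavourable_allele:
            raise PolarisationError("favourable == unfavourable")


def polarise_by_fnr(
    column: Mapping[str, AlleleCall],
    donors: set[str],
    recipients: set[str] | None = None,
    tie_policy: str = "fpr_then_lex",
) -> PolarisationResult:
    """Assign favourable/unfavourable alleles to minimise the FNR.

    The favourable allele is the one present in the largest fraction of
    scored donor calls; because FNR = 1 - that fraction, this choice is
    guaranteed FNR-minimal over all single-allele polarisations. Ties are
    broken by (1) the lower resulting FPR over ``recipients`` (when given),
    then (2) lexicographic allele label; ``tie_broken`` records that a tie
    occurred. The unfavourable allele is the most frequent remaining allele
    among all scored calls (ties again lexicographic).

    Raises :class:`PolarisationError` when no donor call is scored or the
    column shows fewer than two alleles.
    """
    if tie_policy not in ("fpr_then_lex", "lex"):
        raise ValueError(f"unknown tie_policy {tie_policy!r}")
    donor_calls = [
        column[v] for v in donors
        if v in column and column[v].state is CallState.CALLED
    ]
    if not donor_calls:
        raise PolarisationError("no scored donor calls; cannot polarise")
    all_scored = [c for c in column.values() if c.state is CallState.CALLED]
    observed: set[str] = set()
    for c in all_scored:
        observed |= c.alleles
    if len(observed) < 2:
        raise PolarisationError(
            f"column is monomorphic (alleles {sorted(observed)}); "
            "cannot assign distinct favourable/unfavourable alleles"
        )

    donor_freq = {
        a: sum(1 for c in donor_calls if a in c.alleles) / len(donor_calls)
        for a in observed
    }
    best = max(donor_freq.values())
    candidates = sorted(a for a, f in donor_freq.items() if f == best)
    tie_broken = len(candidates) > 1

    def unfav_for(fav: str) -> str:
        rest = observed - {fav}
        counts = {a: sum(1 for c in all_scored if a in c.alleles) for a in rest}
        top = max(counts.values())
        return min(a for a, n in counts.items() if n == top)

    if tie_broken and tie_policy == "fpr_then_lex" and recipients:
        def fpr_of(fav: str) -> float:
            marker = MarkerDefinition(
                marker_id="_polarise_probe",
                marker_target=Polarity.FAVOURABLE,
                favourable_allele=fav,
                unfavourable_allele=unfav_for(fav),
            )
            fpr, _ = false_positive_rate(column, marker, recipients)
            return fpr if fpr is not None else 1.0

        candidates.sort(key=lambda a: (fpr_of(a), a))
    favourable = candidates[0]
    return PolarisationResult(
        favourable_allele=favourable,
        unfavourable_allele=unfav_for(favourable),
        source=PolarisationSource.FNR_CORRECTED,
        donor_allele_frequencies=donor_freq,
        tie_broken=tie_broken,
    )


def _polarised(marker: MarkerDefinition, pol: PolarisationResult,
               qtl: QTLDefinition | None) -> MarkerDefinition:
    """A polarised copy of ``marker`` carrying FNR-corrected alleles."""
    target = Polarity.FAVOURABLE
    if qtl is not None and qtl.derived_state is Polarity.UNFAVOURABLE:
        target = Polarity.UNFAVOURABLE
    return MarkerDefinition(
        marker_id=marker.marker_id,
        version=marker.version,
        platform=marker.platform,
        chromosome=marker.chromosome,
        position_bp=marker.position_bp,
        linkage_cM=marker.linkage_cM,
        marker_class=marker.marker_class,
        marker_target=target,
        favourable_allele=pol.favourable_allele,
        unfavourable_allele=pol.unfavourable_allele,
        derived_qtl_state=marker.derived_qtl_state,
        diagnostic=marker.diagnostic,
    )


def evaluate_marker(
    marker: MarkerDefinition,
    matrix: GenotypeMatrix,
    panel: Panel,
    qtl: QTLDefinition,
) -> MetricsRecord:
    """Compute the full metrics record for one marker against one QTL panel.

    Unpolarised markers are FNR-corrected first (``polarisation_source``
    records this). Ideal-target flags use exact comparisons: 0 for the error
    rates, 1 for call rate, clarity and utility — the targets are absolutes,
    not bands.
    """
    if marker.key not in {m.key for m in matrix.markers}:
        raise MetricsError(f"marker {marker.key} absent from matrix")
    column = matrix.column(marker)

    if marker.is_polarised:
        eff = marker
        source = PolarisationSource.DECLARED
    else:
        pol = polarise_by_fnr(column, panel.donors, panel.recipients)
        eff = _polarised(marker, pol, qtl)
        source = PolarisationSource.FNR_CORRECTED

    cr = call_rate(column.values())
    cl = clarity(column.values())
    fpr, n_rec = false_positive_rate(column, eff, panel.recipients)
    fnr, n_don = false_negative_rate(column, eff, panel.donors)
    bp_fpr, bp_fnr = breeding_rates(column, eff, panel)
    util, n_pool = utility(column, eff, panel.pool)

    matches = None
    if (
        eff.marker_target is not Polarity.UNPOLARISED
        and qtl.derived_state in (Polarity.FAVOURABLE, Polarity.UNFAVOURABLE)
    ):
        matches = eff.marker_target is qtl.derived_state

    flags = {
        "call_rate": cr == 1.0,
        "clarity": cl == 1.0,
        "fpr": fpr == 0.0,
        "fnr": fnr == 0.0,
        "utility": util == 1.0,
    }
    return MetricsRecord(
        marker_id=marker.marker_id,
        version=marker.version,
        qtl_id=qtl.qtl_id,
        marker_class=marker.marker_class,
        chromosome=marker.chromosome,
        position_bp=marker.position_bp,
        call_rate=cr,
        clarity=cl,
        fpr=fpr,
        fnr=fnr,
        bp_fpr=bp_fpr,
        bp_fnr=bp_fnr,
        utility=util,
        n_donors_scored=n_don,
        n_recipients_scored=n_rec,
        n_pool_scored=n_pool,
        favourable_allele=eff.favourable_allele,
        unfavourable_allele=eff.unfavourable_allele,
        polarisation_source=source,
        target_matches_derived=matches,
        ideal_flags=flags,
    )
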