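"""Programmatic marker selection over QTL intervals.

Given a genotype matrix over a QTL window and a donor/recipient panel, the
scanner evaluates every candidate marker, ranks them (perfect accuracy
first, then combined error, then utility, call rate and centrality), and
aggregates metrics by marker class — first within each QTL, then as an
unweighted grand mean across QTLs, so marker-rich QTLs do not dominate.
Class differences are assessed with a paired sign-flip permutation test on
the per-QTL means: distribution-free, and exactly reproducible for a fixed
seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .core import (
    GenotypeMatrix,
    MarkerClass,
    MetricsRecord,
    Panel,
    QTLDefinition,
)
from .metrics import MetricsError, PolarisationError, evaluate_marker

_RATE_METRICS = ("call_rate", "clarity", "fpr", "fnr", "bp_fpr", "bp_fnr",
                 "utility")


class ScanError(ValueError):
    pass


@dataclass
class QTLScanResult:
    """Ranked candidate markers for one QTL."""

    qtl_id: str
    records: list[MetricsRecord]
    rank_keys: list[tuple]
    n_candidates_examined: int
    n_skipped: int


def _rank_key(record: MetricsRecord, qtl: QTLDefinition) -> tuple:
    """Total order over candidates; smaller ranks first.

    Tiers: perfect accuracy (FPR == FNR == 0) first; then ascending
    FPR + FNR; then descending utility; then descending call rate; then
    distance from the window midpoint; finally marker id/version so the
    order is deterministic under input shuffling. Undefined rates sort
    last within their tier.
    """
    perfect = record.fpr == 0.0 and record.fnr == 0.0
    err = (
        math.inf if record.fpr is None or record.fnr is None
        else record.fpr + record.fnr
    )
    util = -math.inf if record.utility is None else record.utility
    cr = -math.inf if record.call_rate is None else record.call_rate
    return (
        0 if perfect else 1,
        err,
        -util,
        -cr,
        abs(record.position_bp - qtl.midpoint),
        record.marker_id,
        record.version,
    )


def scan_qtl(
    qtl: QTLDefinition,
    matrix: GenotypeMatrix,
    panel: Panel,
) -> QTLScanResult:
    """Evaluate and rank every candidate marker in a QTL window.

    Candidates are the matrix markers lying inside the window (markers with
    no recorded position are taken as pre-windowed). Unpolarised candidates
    are FNR-corrected; monomorphic columns that cannot be polarised are
    skipped and counted. Output order is deterministic for a fixed input
    set, regardless of row order.
    """
    panel_obj = panel if isinstance(panel, Panel) else Panel(panel)
    if not panel_obj.donors:
        raise ScanError(f"panel for {qtl.qtl_id} defines no donors")
    if not panel_obj.recipients:
        raise ScanError(f"panel for {qtl.qtl_id} defines no recipients")
    records: list[MetricsRecord] = []
    n_examined = 0
    n_skipped = 0
    for marker in matrix.markers:
        if marker.chromosome and not qtl.contains(
            marker.chromosome, marker.position_bp
        ):
            continue
        n_examined += 1
        try:
            records.append(evaluate_marker(marker, matrix, panel_obj, qtl))
        except PolarisationError:
            n_skipped += 1
    ordered = sorted(records, key=lambda r: _rank_key(r, qtl))
    return QTLScanResult(
        qtl_id=qtl.qtl_id,
        records=ordered,
        rank_keys=[_rank_key(r, qtl) for r in ordered],
        n_candidates_examined=n_examined,
        n_skipped=n_skipped,
    )


# ---------------------------------------------------------------------------
# class summaries


@dataclass
class ClassSummary:
    """Two-stage metric means for one marker class.

    ``within_qtl_means[qtl_id][metric]`` is the mean over that QTL's markers
    of the class (defined values only); ``grand_means[metric]`` is the
    unweighted mean of the within-QTL means over the QTLs where the metric
    was defined — not a pooled mean over markers.
    """

    marker_class: MarkerClass
    within_qtl_means: dict[str, dict[str, Optional[float]]]
    grand_means: dict[str, Optional[float]] = field(default_factory=dict)
    n_markers: int = 0
    n_qtls: int = 0

    def __post_init__(self) -> None:
        if not self.grand_means:
            self.grand_means = {
                metric: _mean_or_none(
                    [
                        per_qtl[metric]
                        for per_qtl in self.within_qtl_means.values()
                        if per_qtl.get(metric) is not None
                    ]
                )
                for metric in _RATE_METRICS
            }


def _mean_or_none(values: Sequence[float]) -> Optional[float]:
    return float(np.mean(values)) if values else None


def summarise_by_class(records: Iterable[MetricsRecord]) -> list[ClassSummary]:
    """Two-stage averaging: within each QTL first, then across QTLs.

    Undefined metrics are excluded from the within-QTL means; a QTL where a
    class has no defined value for a metric drops out of that metric's grand
    mean. Classes absent from every record are simply not returned.
    """
    grouped: dict[MarkerClass, dict[str, list[MetricsRecord]]] = {}
    for r in records:
        grouped.setdefault(r.marker_class, {}).setdefault(r.qtl_id, []).append(r)
    out: list[ClassSummary] = []
    for cls in sorted(grouped, key=lambda c: c.value):
        per_qtl: dict[str, dict[str, Optional[float]]] = {}
        n_markers = 0
        for qtl_id, recs in sorted(grouped[cls].items()):
            n_markers += len(recs)
            per_qtl[qtl_id] = {
                metric: _mean_or_none(
                    [getattr(r, metric) for r in recs
                     if getattr(r, metric) is not None]
                )
                for metric in _RATE_METRICS
            }
        out.append(
            ClassSummary(
                marker_class=cls,
                within_qtl_means=per_qtl,
                n_markers=n_markers,
                n_qtls=len(per_qtl),
            )
        )
    return out


def compare_classes(
    means_a: Mapping[str, float],
    means_b: Mapping[str, float],
    n_permutations: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Paired sign-flip permutation test on per-QTL class means.

    Pairs are the QTLs present in both mappings. Returns (observed mean of
    a - b, two-sided p-value) with p = (#{|permuted| >= |observed|} + 1) /
    (n + 1). Needs >= 3 paired QTLs; fewer makes the test meaningless.
    """
    if n_permutations < 1:
        raise ScanError("n_permutations must be >= 1")
    shared = sorted(set(means_a) & set(means_b))
    if len(shared) < 3:
        raise ScanError(
            f"need >= 3 paired QTLs for a class comparison, got {len(shared)}"
        )
    diffs = np.array([means_a[q] - means_b[q] for q in shared], dtype=float)
    observed = float(diffs.mean())
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    signs = rng.choice([-1.0, 1.0], size=(n_permutations, len(diffs)))
    permuted = (signs * diffs).mean(axis=1)
    n_extreme = int(np.sum(np.abs(permuted) >= abs(observed) - 1e-15))
    return observed, (n_extreme + 1) / (n_permutations + 1)


# ---------------------------------------------------------------------------
# utility spectrum


@dataclass
class UtilitySpectrum:
    """Per-QTL utility of the top-ranked perfectly accurate marker."""

    utilities: dict[str, float]
    excluded: dict[str, str]


def utility_spectrum(scans: Iterable[QTLScanResult]) -> UtilitySpectrum:
    """One utility per QTL, from its best marker with FPR = FNR = 0.

    QTLs with no accurate marker (or whose best accurate marker has no
    defined utility) are excluded with a recorded reason: only markers that
    classify all characterised material correctly give a trustworthy read
    of how much of the pool the QTL could improve.
    """
    utilities: dict[str, float] = {}
    excluded: dict[str, str] = {}
    for scan in scans:
        accurate = [
            r for r in scan.records if r.fpr == 0.0 and r.fnr == 0.0
        ]
        if not accurate:
            excluded[scan.qtl_id] = "no marker with FPR = FNR = 0"
            continue
        top = accurate[0]  # records are already rank-ordered
        if top.utility is None:
            excluded[scan.qtl_id] = "accurate marker has undefined utility"
            continue
        utilities[scan.qtl_id] = top.utility
    return UtilitySpectrum(utilities=utilities, excluded=excluded)
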