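"""Independent brute-force oracle for the marker metrics.

Deliberately naive: plain per-sample loops over (state, alleles) tuples
with explicit set membership, no shared code with the package. Calls are
``("called", {labels})``, ``("missing", set())`` or ``("ambiguous", set())``.
"""

from __future__ import annotations

from typing import Mapping, Optional

Call = tuple[str, set[str]]


def oracle_call_rate(column: Mapping[str, Call]) -> Optional[float]:
    calls = list(column.values())
    if not calls:
        return None
    n_visible = 0
    for state, _ in calls:
        if state != "missing":
            n_visible += 1
    return n_visible / len(calls)


def oracle_clarity(column: Mapping[str, Call]) -> Optional[float]:
    calls = list(column.values())
    if not calls:
        return None
    n_clear = 0
    for state, _ in calls:
        if state == "called":
            n_clear += 1
    return n_clear / len(calls)


def oracle_fpr(
    column: Mapping[str, Call], unfavourable: str, recipients: set[str]
) -> tuple[Optional[float], int]:
    n_scored = 0
    n_fp = 0
    for variety in recipients:
        state, alleles = column[variety]
        if state != "called":
            continue
        n_scored += 1
        if unfavourable not in alleles:
            n_fp += 1
    if n_scored == 0:
        return None, 0
    return n_fp / n_scored, n_scored


def oracle_fnr(
    column: Mapping[str, Call], favourable: str, donors: set[str]
) -> tuple[Optional[float], int]:
    n_scored = 0
    n_fn = 0
    for variety in donors:
        state, alleles = column[variety]
        if state != "called":
            continue
        n_scored += 1
        if favourable not in alleles:
            n_fn += 1
    if n_scored == 0:
        return None, 0
    return n_fn / n_scored, n_scored


def oracle_utility(
    column: Mapping[str, Call], favourable: str, pool: set[str]
) -> tuple[Optional[float], int]:
    n_scored = 0
    n_without = 0
    for variety in pool:
        state, alleles = column[variety]
        if state != "called":
            continue
        n_scored += 1
        if favourable not in alleles:
            n_without += 1
    if n_scored == 0:
        return None, 0
    return n_without / n_scored, n_scored


def all_polarisations(column: Mapping[str, Call]) -> list[tuple[str, str]]:
    """Every (favourable, unfavourable) pair over the observed alleles."""
    observed: set[str] = set()
    for state, alleles in column.values():
        if state == "called":
            observed |= alleles
    return [
        (fav, unfav)
        for fav in sorted(observed)
        for unfav in sorted(observed)
        if fav != unfav
    ]


def oracle_min_fnr(
    column: Mapping[str, Call], donors: set[str]
) -> Optional[float]:
    """Minimum FNR over all single-allele polarisations, by exhaustion."""
    best = None
    for fav, _ in all_polarisations(column):
        fnr, n = oracle_fnr(column, fav, donors)
        if fnr is None:
            continue
        if best is None or fnr < best:
            best = fnr
    return best
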