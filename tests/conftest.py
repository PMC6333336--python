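from __future__ import annotations

import numpy as np
import pytest

from markerqc import (
    AlleleCall,
    GenotypeMatrix,
    MarkerClass,
    MarkerDefinition,
    Panel,
    PanelAssignment,
    PanelStatus,
    Polarity,
    QTLDefinition,
)

ALLELE_POOL = ["A", "C", "G", "T", "Large", "Small"]


def make_marker(
    marker_id="MK1",
    favourable="G",
    unfavourable="A",
    target=Polarity.FAVOURABLE,
    **kwargs,
):
    if target is Polarity.UNPOLARISED:
        return MarkerDefinition(marker_id=marker_id, **kwargs)
    return MarkerDefinition(
        marker_id=marker_id,
        marker_target=target,
        favourable_allele=favourable,
        unfavourable_allele=unfavourable,
        **kwargs,
    )


def make_matrix(marker, calls_by_variety):
    """Single-marker matrix from {variety: AlleleCall}."""
    varieties = list(calls_by_variety)
    calls = {
        (marker.marker_id, marker.version, v): c
        for v, c in calls_by_variety.items()
    }
    return GenotypeMatrix([marker], varieties, calls)


def make_panel(qtl_id="qX", donors=(), recipients=(), unknown=(), pool=None):
    assignments = []
    for v in donors:
        assignments.append(PanelAssignment(v, qtl_id, PanelStatus.DONOR,
                                           pool is None or v in pool))
    for v in recipients:
        assignments.append(PanelAssignment(v, qtl_id, PanelStatus.RECIPIENT,
                                           pool is None or v in pool))
    for v in unknown:
        assignments.append(PanelAssignment(v, qtl_id, PanelStatus.UNKNOWN,
                                           pool is None or v in pool))
    return Panel(assignments)


def random_panel_case(rng: np.random.Generator, max_markers=20,
                      max_varieties=30):
    """A random genotype matrix + panel with messy cells.

    Cells mix missing, ambiguous, heterozygous and multiallelic calls; the
    variety panel mixes donors, recipients and unknowns with a random
    breeding-pool subset.
    """
    n_markers = int(rng.integers(1, max_markers + 1))
    n_varieties = int(rng.integers(4, max_varieties + 1))
    varieties = [f"V{i:02d}" for i in range(n_varieties)]
    alleles = list(rng.choice(ALLELE_POOL, size=3, replace=False))
    markers = []
    calls = {}
    for i in range(n_markers):
        fav, unfav = rng.choice(alleles, size=2, replace=False)
        polarised = rng.random() < 0.5
        m = make_marker(
            marker_id=f"M{i:02d}",
            favourable=str(fav),
            unfavourable=str(unfav),
            target=Polarity.FAVOURABLE if polarised else Polarity.UNPOLARISED,
        )
        markers.append(m)
        for v in varieties:
            u = rng.random()
            if u < 0.08:
                call = AlleleCall.missing()
            elif u < 0.14:
                call = AlleleCall.ambiguous()
            elif u < 0.28:
                pair = rng.choice(alleles, size=2, replace=False)
                call = AlleleCall.called(str(pair[0]), str(pair[1]))
            else:
                call = AlleleCall.called(str(rng.choice(alleles)))
            calls[(m.marker_id, m.version, v)] = call
    matrix = GenotypeMatrix(markers, varieties, calls)
    status = rng.choice(["donor", "recipient", "unknown"], size=n_varieties,
                        p=[0.3, 0.4, 0.3])
    in_pool = rng.random(n_varieties) < 0.8
    panel = Panel(
        PanelAssignment(v, "qX", PanelStatus(s), bool(p))
        for v, s, p in zip(varieties, status, in_pool)
    )
    qtl = QTLDefinition(qtl_id="qX", chromosome="", start_bp=1, end_bp=10**9)
    return matrix, panel, qtl


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
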