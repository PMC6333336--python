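"""Genealogy-based panel simulator with analytically known marker metrics.

The model is the simplest one in which the derived-allele reasoning behind
marker-QTL association is exactly true: varieties are the leaves of a random
rooted binary genealogy; mutations accumulate on branches under an
infinite-sites model (each mutation is unique, so its carriers are exactly
the leaves of one subtree); one or more mutations are designated *causal*,
which induces donor (QTL[+]) and recipient (QTL[-]) sets; every mutation is
then a candidate marker whose false positive rate, false negative rate and
utility are pure set arithmetic on the tree — no sampling, no estimation.

Three evolutionary scenarios are supported:

* ``A`` — a single favourable origin: the derived allele of one mutation is
  the favourable QTL allele; donors are exactly its carriers.
* ``B`` — several independent favourable origins on disjoint branches;
  donors are the union of their carrier sets.
* ``C`` — the favourable allele is ancestral and the derived origins are
  unfavourable; donors are the non-carriers.

Technical noise (missing calls, ambiguous calls, spurious heterozygotes) is
injected per cell after the ground truth is recorded, so technical-metric
recovery can be tested against the injected rates.

Lineages are haploid: each variety carries one allele per marker
("A" ancestral, "G" derived). Heterozygosity and ambiguity enter only as
injected corruption, not as genetics.

All randomness flows from one explicit seed through
``numpy.random.SeedSequence`` spawning — one child stream per stage
(topology, mutations, causal designation, panel emission) — so every
artefact is reproducible from ``(config, seed)`` alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

from .core import (
    AlleleCall,
    CallState,
    GenotypeMatrix,
    MarkerClass,
    MarkerDefinition,
    PanelAssignment,
    PanelStatus,
    Polarity,
    QTLDefinition,
)

ANCESTRAL = "A"
DERIVED = "G"


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# genealogy


@dataclass(frozen=True)
class TreeNode:
    """One node; ``branch_length`` is the branch above it (0 for the root)."""

    node_id: int
    children: tuple["TreeNode", ...] = ()
    branch_length: float = 0.0
    leaves: frozenset[str] = frozenset()
    name: str = ""

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass(frozen=True)
class Genealogy:
    """Rooted binary genealogy of varieties."""

    root: TreeNode
    leaf_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.leaf_names) < 4:
            raise SimulationError("a genealogy needs at least 4 leaves")

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_names)

    def nodes(self) -> list[TreeNode]:
        out: list[TreeNode] = []
        stack = [self.root]
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(n.children)
        return out

    def branches(self) -> list[TreeNode]:
        """All non-root nodes, i.e. one per branch, in stable order."""
        return sorted(
            (n for n in self.nodes() if n is not self.root),
            key=lambda n: n.node_id,
        )

    @property
    def total_length(self) -> float:
        return sum(n.branch_length for n in self.branches())

    def newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.branch_length:.6f}"
            inner = ",".join(fmt(c) for c in node.children)
            return f"({inner}):{node.branch_length:.6f}"

        return fmt(self.root).rsplit(":", 1)[0] + ";"


def simulate_genealogy(n_leaves: int, seed: int) -> Genealogy:
    """Random coalescent-style genealogy with exponential waiting times.

    Standard Kingman construction: ``n_leaves`` lineages merge pairwise at
    rate k(k-1)/2 until one remains. Branch lengths are in coalescent units
    and act as expected mutation counts once scaled by the mutation rate.
    Deterministic for fixed ``(n_leaves, seed)``.
    """
    if n_leaves < 4:
        raise SimulationError(f"n_leaves must be >= 4, got {n_leaves}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    names = tuple(f"V{i:03d}" for i in range(1, n_leaves + 1))
    next_id = 0
    lineages: list[tuple[TreeNode, float]] = []  # (node, node time)
    for name in names:
        lineages.append(
            (TreeNode(node_id=next_id, leaves=frozenset([name]), name=name), 0.0)
        )
        next_id += 1
    t = 0.0
    while len(lineages) > 1:
        k = len(lineages)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        (a, ta), (b, tb) = lineages[i], lineages[j]
        a = replace(a, branch_length=t - ta)
        b = replace(b, branch_length=t - tb)
        parent = TreeNode(
            node_id=next_id, children=(a, b), leaves=a.leaves | b.leaves
        )
        next_id += 1
        lineages = [x for idx, x in enumerate(lineages) if idx not in (i, j)]
        lineages.append((parent, t))
    return Genealogy(root=lineages[0][0], leaf_names=names)


# ---------------------------------------------------------------------------
# mutations


@dataclass(frozen=True)
class PlacedMutation:
    """One infinite-sites mutation; carriers = leaves under its branch."""

    mutation_id: str
    branch_node_id: int
    carriers: frozenset[str]


def drop_mutations(tree: Genealogy, mu: float, seed: int
                   ) -> list[PlacedMutation]:
    """Drop Poisson(mu x branch_length) mutations on every branch."""
    if mu <= 0:
        raise SimulationError(f"mu must be > 0, got {mu}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    out: list[PlacedMutation] = []
    counter = 0
    for branch in tree.branches():
        for _ in range(int(rng.poisson(mu * branch.branch_length))):
            counter += 1
            out.append(
                PlacedMutation(
                    mutation_id=f"M{counter:03d}",
                    branch_node_id=branch.node_id,
                    carriers=branch.leaves,
                )
            )
    return out


# ---------------------------------------------------------------------------
# causal designation


@dataclass(frozen=True)
class CausalDesignation:
    """Causal mutation(s) and the donor/recipient structure they induce."""

    causal_mutations: tuple[PlacedMutation, ...]
    scenario: str
    derived_state: Polarity
    donors: frozenset[str]
    recipients: frozenset[str]
    unknown: frozenset[str]
    all_leaves: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.donors & self.recipients:
            raise SimulationError("donor and recipient sets overlap")


def designate_causal(
    tree: Genealogy,
    mutations: list[PlacedMutation],
    scenario: str = "A",
    mask_fraction: float = 0.0,
    seed: int = 0,
) -> CausalDesignation:
    """Pick causal mutation(s) and label leaves DONOR / RECIPIENT / UNKNOWN.

    Scenario A picks one internal-branch mutation as the favourable origin;
    B picks 2-3 origins on branches with disjoint carrier sets; C uses the
    complement construction — the derived origins are unfavourable, and
    donors are the leaves carrying none of them. A ``mask_fraction`` of
    leaves is relabelled UNKNOWN (dropped from rate denominators but kept in
    the breeding pool).
    """
    scenario = scenario.upper()
    if scenario not in ("A", "B", "C"):
        raise SimulationError(f"unknown scenario {scenario!r}")
    if not 0.0 <= mask_fraction < 1.0:
        raise SimulationError("mask_fraction must be in [0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = tree.n_leaves
    eligible = [m for m in mutations if 2 <= len(m.carriers) <= n - 2]
    if not eligible:
        raise SimulationError(
            f"no internal-branch mutation eligible for scenario {scenario}"
        )

    def pick_disjoint(n_origins: int) -> list[PlacedMutation]:
        order = list(rng.permutation(len(eligible)))
        chosen: list[PlacedMutation] = []
        covered: frozenset[str] = frozenset()
        for idx in order:
            m = eligible[idx]
            if m.carriers & covered:
                continue
            if len(covered | m.carriers) > n - 2:
                continue
            chosen.append(m)
            covered |= m.carriers
            if len(chosen) == n_origins:
                break
        return chosen

    if scenario == "A":
        causal = [eligible[int(rng.integers(len(eligible)))]]
    elif scenario == "B":
        want = int(rng.integers(2, 4))  # 2 or 3 origins
        causal = pick_disjoint(want)
        if len(causal) < 2:
            raise SimulationError(
                "scenario B needs >= 2 disjoint internal-branch mutations"
            )
    else:  # C: derived origins are unfavourable
        want = int(rng.integers(1, 3))  # 1 or 2 origins
        causal = pick_disjoint(want)
        if not causal:
            raise SimulationError(
                "scenario C needs >= 1 eligible internal-branch mutation"
            )

    carriers: frozenset[str] = frozenset()
    for m in causal:
        carriers |= m.carriers
    if scenario in ("A", "B"):
        derived_state = Polarity.FAVOURABLE
        donors_all, recipients_all = carriers, frozenset(tree.leaf_names) - carriers
    else:
        derived_state = Polarity.UNFAVOURABLE
        recipients_all, donors_all = carriers, frozenset(tree.leaf_names) - carriers

    n_mask = int(round(mask_fraction * n))
    masked = frozenset(
        str(x) for x in rng.choice(tree.leaf_names, size=n_mask, replace=False)
    )
    donors = donors_all - masked
    recipients = recipients_all - masked
    if not donors or not recipients:
        raise SimulationError(
            "masking removed every donor or every recipient; "
            "lower mask_fraction or redraw"
        )
    return CausalDesignation(
        causal_mutations=tuple(causal),
        scenario=scenario,
        derived_state=derived_state,
        donors=donors,
        recipients=recipients,
        unknown=masked,
        all_leaves=tree.leaf_names,
    )


# ---------------------------------------------------------------------------
# ground truth


@dataclass(frozen=True)
class GroundTruth:
    expected_fpr: Optional[float]
    expected_fnr: Optional[float]
    expected_utility: Optional[float]
    favourable_allele: str = ""
    unfavourable_allele: str = ""


def ground_truth_metrics(
    designation: CausalDesignation, mutation: PlacedMutation
) -> tuple[Optional[float], Optional[float]]:
    """Exact (FPR, FNR) for a mutation-marker polarised toward the QTL.

    With the marker target matching the derived QTL state: when the derived
    allele is favourable, FNR = |donors \\ carriers| / |donors| and
    FPR = |recipients ∩ carriers| / |recipients|; when the derived allele is
    unfavourable the complements apply. Pure set arithmetic; components are
    None when the corresponding panel side is empty.
    """
    D, R, C = designation.donors, designation.recipients, mutation.carriers
    if designation.derived_state is Polarity.FAVOURABLE:
        fnr = len(D - C) / len(D) if D else None
        fpr = len(R & C) / len(R) if R else None
    else:
        fnr = len(D & C) / len(D) if D else None
        fpr = len(R - C) / len(R) if R else None
    return fpr, fnr


def ground_truth_utility(
    designation: CausalDesignation, mutation: PlacedMutation
) -> Optional[float]:
    """Exact utility over the full pool (all leaves, UNKNOWN included)."""
    pool = set(designation.all_leaves)
    if not pool:
        return None
    C = mutation.carriers
    if designation.derived_state is Polarity.FAVOURABLE:
        return len(pool - C) / len(pool)
    return len(pool & C) / len(pool)


def _anonymous_ground_truth(
    designation: CausalDesignation, carriers: frozenset[str]
) -> GroundTruth:
    """Exact metrics for a tree-independent marker under FNR correction.

    Replicates, in set arithmetic, the polarisation rule the metrics engine
    applies to unpolarised markers: favourable = allele most frequent among
    donors, ties broken by lower FPR then lexicographic label.
    """
    D, R = designation.donors, designation.recipients
    pool = set(designation.all_leaves)
    f_derived = len(D & carriers) / len(D)
    f_ancestral = len(D - carriers) / len(D)
    fpr_if_derived_fav = len(R & carriers) / len(R) if R else 1.0
    fpr_if_ancestral_fav = len(R - carriers) / len(R) if R else 1.0
    if f_derived > f_ancestral:
        fav = DERIVED
    elif f_ancestral > f_derived:
        fav = ANCESTRAL
    elif fpr_if_derived_fav < fpr_if_ancestral_fav:
        fav = DERIVED
    else:
        fav = ANCESTRAL  # lexicographic: "A" < "G"
    if fav == DERIVED:
        fnr = len(D - carriers) / len(D)
        fpr = fpr_if_derived_fav if R else None
        util = len(pool - carriers) / len(pool)
        unfav = ANCESTRAL
    else:
        fnr = len(D & carriers) / len(D)
        fpr = fpr_if_ancestral_fav if R else None
        util = len(pool & carriers) / len(pool)
        unfav = DERIVED
    return GroundTruth(fpr, fnr, util, fav, unfav)


# ---------------------------------------------------------------------------
# panel emission


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated QTL panel.

    Defaults are desk-scale stand-ins for a diverse characterised panel:
    40 varieties, a mutation rate giving on the order of a dozen candidate
    polymorphisms in the QTL window, a quarter of varieties of unknown QTL
    status, 8 tree-independent anonymous markers (the per-QTL density of a
    fixed genotyping chip), and low technical noise.
    """

    n_leaves: int = 40
    mu: float = 1.5
    scenario: str = "A"
    mask_fraction: float = 0.25
    missing_rate: float = 0.05
    ambiguous_rate: float = 0.02
    het_rate: float = 0.02
    n_anonymous: int = 8
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "n_leaves": self.n_leaves, "mu": self.mu,
            "scenario": self.scenario, "mask_fraction": self.mask_fraction,
            "missing_rate": self.missing_rate,
            "ambiguous_rate": self.ambiguous_rate, "het_rate": self.het_rate,
            "n_anonymous": self.n_anonymous, "seed": self.seed,
        }


@dataclass
class SimulatedPanel:
    """A simulated genotype panel with exact ground-truth metrics.

    ``ground_truth`` maps marker_id to the exact metrics implied by the
    genealogy *before* corruption was injected. ``designed_marker_ids``
    identifies the tree markers a developer could have designed from a
    biparental donor/recipient sequence comparison (see
    :func:`emit_panel`).
    """

    matrix: GenotypeMatrix
    assignments: list[PanelAssignment]
    qtl: QTLDefinition
    designation: CausalDesignation
    ground_truth: dict[str, GroundTruth]
    designed_marker_ids: frozenset[str]
    tree: Optional[Genealogy] = None
    seed: int = 0
    config: dict = field(default_factory=dict)


_QTL_START = 37_000_000
_QTL_END = 41_000_000


def emit_panel(
    designation: CausalDesignation,
    mutations: list[PlacedMutation],
    missing_rate: float = 0.0,
    ambiguous_rate: float = 0.0,
    het_rate: float = 0.0,
    n_anonymous: int = 0,
    seed: int = 0,
    qtl_id: str = "qSIM",
) -> SimulatedPanel:
    """Emit a genotype matrix + panel with exact pre-corruption ground truth.

    Tree mutations become QTL-specific SNP markers with declared polarity
    matching the derived QTL state (causal mutations are flagged
    diagnostic). ``n_anonymous`` extra markers have carrier sets drawn
    panmictically, independent of the genealogy, and are left unpolarised —
    they emulate fixed-chip SNPs chosen for polymorphism rather than for the
    QTL. Per-cell corruption (missing / ambiguous / spurious het) is applied
    independently at the stated rates after ground truth is recorded.

    The designed-marker subset emulates marker development from a biparental
    comparison: one donor and one recipient are drawn as the "sequenced
    parents", and a tree marker is designable iff the QTL-indicating derived
    allele separates them.
    """
    for name, rate in (("missing_rate", missing_rate),
                       ("ambiguous_rate", ambiguous_rate),
                       ("het_rate", het_rate)):
        if not 0.0 <= rate < 1.0:
            raise SimulationError(f"{name} must be in [0, 1), got {rate}")
    if missing_rate + ambiguous_rate + het_rate >= 1.0:
        raise SimulationError("corruption rates must sum to < 1")
    ss = np.random.SeedSequence(seed)
    rng_anon, rng_corrupt, rng_design = (
        np.random.default_rng(s) for s in ss.spawn(3)
    )
    leaves = list(designation.all_leaves)
    derived_fav = designation.derived_state is Polarity.FAVOURABLE
    fav, unfav = (DERIVED, ANCESTRAL) if derived_fav else (ANCESTRAL, DERIVED)
    causal_ids = {m.mutation_id for m in designation.causal_mutations}

    qtl = QTLDefinition(
        qtl_id=qtl_id, chromosome="chr1",
        start_bp=_QTL_START, end_bp=_QTL_END,
        trait="simulated", derived_state=designation.derived_state,
    )

    # carrier sets for anonymous markers: panmictic, tree-independent
    anon: list[tuple[str, frozenset[str]]] = []
    for i in range(1, n_anonymous + 1):
        carriers: frozenset[str] = frozenset()
        for _ in range(100):
            p = rng_anon.uniform(0.1, 0.9)
            mask = rng_anon.random(len(leaves)) < p
            carriers = frozenset(v for v, hit in zip(leaves, mask) if hit)
            if 0 < len(carriers) < len(leaves):
                break
        else:  # pragma: no cover - vanishingly unlikely
            raise SimulationError("could not draw a polymorphic anonymous marker")
        anon.append((f"ANON{i:03d}", carriers))

    n_sites = len(mutations) + len(anon)
    spacing = max((_QTL_END - _QTL_START) // (n_sites + 1), 1)

    markers: list[MarkerDefinition] = []
    carrier_of: dict[str, frozenset[str]] = {}
    ground_truth: dict[str, GroundTruth] = {}
    pos = _QTL_START
    for m in mutations:
        pos += spacing
        diagnostic = m.mutation_id in causal_ids
        markers.append(
            MarkerDefinition(
                marker_id=m.mutation_id, version="1", platform="simulated",
                chromosome="chr1", position_bp=pos,
                linkage_cM=0.0 if diagnostic else None,
                marker_class=MarkerClass.QTL_SPECIFIC_SNP,
                marker_target=designation.derived_state,
                favourable_allele=fav, unfavourable_allele=unfav,
                derived_qtl_state=designation.derived_state,
                diagnostic=diagnostic,
            )
        )
        carrier_of[m.mutation_id] = m.carriers
        fpr, fnr = ground_truth_metrics(designation, m)
        ground_truth[m.mutation_id] = GroundTruth(
            fpr, fnr, ground_truth_utility(designation, m), fav, unfav
        )
    for anon_id, carriers in anon:
        pos += spacing
        markers.append(
            MarkerDefinition(
                marker_id=anon_id, version="1", platform="chip",
                chromosome="chr1", position_bp=pos,
                marker_class=MarkerClass.ANONYMOUS,
                marker_target=Polarity.UNPOLARISED,
                derived_qtl_state=designation.derived_state,
            )
        )
        carrier_of[anon_id] = carriers
        ground_truth[anon_id] = _anonymous_ground_truth(designation, carriers)

    # designed subset: biparental comparison between one donor and one
    # recipient "sequenced parent"
    design_donor = str(rng_design.choice(sorted(designation.donors)))
    design_recipient = str(rng_design.choice(sorted(designation.recipients)))
    derived_parent = design_donor if derived_fav else design_recipient
    other_parent = design_recipient if derived_fav else design_donor
    designed = frozenset(
        m.mutation_id for m in mutations
        if derived_parent in m.carriers and other_parent not in m.carriers
    )

    calls: dict[tuple[str, str, str], AlleleCall] = {}
    for marker in markers:
        carriers = carrier_of[marker.marker_id]
        for v in leaves:
            u = rng_corrupt.random()
            if u < missing_rate:
                call = AlleleCall.missing()
            elif u < missing_rate + ambiguous_rate:
                call = AlleleCall.ambiguous()
            elif u < missing_rate + ambiguous_rate + het_rate:
                call = AlleleCall.called(ANCESTRAL, DERIVED)
            else:
                call = AlleleCall.called(DERIVED if v in carriers else ANCESTRAL)
            calls[(marker.marker_id, "1", v)] = call

    assignments = []
    for v in leaves:
        if v in designation.donors:
            status = PanelStatus.DONOR
        elif v in designation.recipients:
            status = PanelStatus.RECIPIENT
        else:
            status = PanelStatus.UNKNOWN
        assignments.append(
            PanelAssignment(variety_id=v, qtl_id=qtl_id, status=status,
                            in_breeding_pool=True)
        )

    return SimulatedPanel(
        matrix=GenotypeMatrix(markers, leaves, calls),
        assignments=assignments,
        qtl=qtl,
        designation=designation,
        ground_truth=ground_truth,
        designed_marker_ids=designed,
        seed=seed,
        config={
            "missing_rate": missing_rate, "ambiguous_rate": ambiguous_rate,
            "het_rate": het_rate, "n_anonymous": n_anonymous, "seed": seed,
        },
    )


def simulate_panel(config: SimulationConfig) -> SimulatedPanel:
    """Run the full pipeline: genealogy -> mutations -> causal -> panel.

    One seed drives everything; stages get independent child streams. A
    drawn genealogy that admits no eligible causal mutation raises
    :class:`SimulationError` — see :func:`simulate_panels` for deterministic
    rejection-resampling over many panels.
    """
    ss = np.random.SeedSequence(config.seed)
    s_tree, s_mut, s_causal, s_emit = (int(c.generate_state(1)[0] % (2**31))
                                       for c in ss.spawn(4))
    tree = simulate_genealogy(config.n_leaves, s_tree)
    mutations = drop_mutations(tree, config.mu, s_mut)
    designation = designate_causal(
        tree, mutations, config.scenario, config.mask_fraction, s_causal
    )
    panel = emit_panel(
        designation, mutations,
        missing_rate=config.missing_rate,
        ambiguous_rate=config.ambiguous_rate,
        het_rate=config.het_rate,
        n_anonymous=config.n_anonymous,
        seed=s_emit,
    )
    panel.tree = tree
    panel.seed = config.seed
    panel.config = config.to_dict()
    return panel


def simulate_panels(
    base_config: SimulationConfig, n_panels: int, max_rejections: int = 100
) -> list[SimulatedPanel]:
    """Simulate ``n_panels`` independent panels (one QTL each).

    Panel k uses a child seed derived from the base seed. A draw whose
    genealogy admits no eligible causal designation is rejected and redrawn
    from the next derived seed — standard rejection sampling, fully
    deterministic for a fixed base seed.

    With ``scenario="mixed"`` the panels cycle through scenarios A, B, C:
    real QTL catalogues contain single-origin favourable alleles, multiple
    independent favourable origins, and ancestral-favourable cases alike,
    and a marker set designed from one mapping pair behaves very
    differently across them.
    """
    out: list[SimulatedPanel] = []
    ss = np.random.SeedSequence(base_config.seed)
    children = ss.spawn(n_panels + max_rejections)
    mixed = base_config.scenario.lower() == "mixed"
    idx = 0
    while len(out) < n_panels:
        if idx >= len(children):
            raise SimulationError(
                f"exceeded {max_rejections} rejected genealogies"
            )
        seed = int(children[idx].generate_state(1)[0] % (2**31))
        idx += 1
        scenario = "ABC"[len(out) % 3] if mixed else base_config.scenario
        cfg = replace(base_config, seed=seed, scenario=scenario)
        try:
            panel = simulate_panel(cfg)
        except SimulationError:
            continue
        panel.qtl = replace(panel.qtl, qtl_id=f"qSIM{len(out) + 1:02d}")
        panel.assignments = [
            replace(a, qtl_id=panel.qtl.qtl_id) for a in panel.assignments
        ]
        out.append(panel)
    return out


@dataclass(frozen=True)
class ClassContrast:
    """Anonymous vs designed-marker class comparison over simulated QTLs."""

    fnr_anonymous: dict[str, float]
    fnr_linked: dict[str, float]
    fpr_anonymous: dict[str, float]
    fpr_linked: dict[str, float]
    fnr_difference: float
    fnr_p_value: float
    fpr_difference: float
    fpr_p_value: float
    n_qtls: int


def simulated_class_contrast(
    n_qtls: int = 20,
    seed: int = 0,
    base_config: Optional[SimulationConfig] = None,
    n_permutations: int = 10_000,
) -> ClassContrast:
    """Compare anonymous and QTL-specific designed markers over many QTLs.

    Simulates ``n_qtls`` panels (scenarios cycling A/B/C unless overridden),
    evaluates every marker, forms per-QTL class means of FNR and FPR for the
    tree-independent anonymous markers (FNR-corrected) versus the designed
    causal-linked markers, and runs a paired sign-flip permutation test on
    each. FNR correction pulls the anonymous class's false negative rate
    down to the designed markers' level, but their false positive rate stays
    far higher: being polymorphic is not the same as tagging the causal
    lineage.
    """
    from .core import MarkerClass, Panel
    from .metrics import PolarisationError, evaluate_marker
    from .scanner import compare_classes

    cfg = base_config or SimulationConfig(seed=seed, scenario="mixed")
    cfg = replace(cfg, seed=seed)
    panels = simulate_panels(cfg, n_qtls)
    fnr_a: dict[str, float] = {}
    fnr_l: dict[str, float] = {}
    fpr_a: dict[str, float] = {}
    fpr_l: dict[str, float] = {}
    for p in panels:
        panel = Panel(p.assignments)
        records = []
        for m in p.matrix.markers:
            try:
                records.append(evaluate_marker(m, p.matrix, panel, p.qtl))
            except PolarisationError:
                continue
        linked = [r for r in records if r.marker_id in p.designed_marker_ids]
        anon = [
            r for r in records if r.marker_class is MarkerClass.ANONYMOUS
        ]

        def class_mean(recs, attr):
            vals = [getattr(r, attr) for r in recs
                    if getattr(r, attr) is not None]
            return float(np.mean(vals)) if vals else None

        q = p.qtl.qtl_id
        means = [
            (fnr_a, "fnr", anon), (fnr_l, "fnr", linked),
            (fpr_a, "fpr", anon), (fpr_l, "fpr", linked),
        ]
        if all(class_mean(recs, attr) is not None for _, attr, recs in means):
            for target, attr, recs in means:
                target[q] = class_mean(recs, attr)
    ss = np.random.SeedSequence(seed)
    s_fnr, s_fpr = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(2))
    fnr_diff, fnr_p = compare_classes(fnr_a, fnr_l, n_permutations, s_fnr)
    fpr_diff, fpr_p = compare_classes(fpr_a, fpr_l, n_permutations, s_fpr)
    return ClassContrast(
        fnr_anonymous=fnr_a, fnr_linked=fnr_l,
        fpr_anonymous=fpr_a, fpr_linked=fpr_l,
        fnr_difference=fnr_diff, fnr_p_value=fnr_p,
        fpr_difference=fpr_diff, fpr_p_value=fpr_p,
        n_qtls=len(fnr_a),
    )


# ---------------------------------------------------------------------------
# on-disk emission


def write_vcf(panel: SimulatedPanel, path: str | Path) -> None:
    """Write the panel's SNP calls as a plain-text VCF 4.2 file.

    REF is the ancestral allele, ALT the derived one; AMBIGUOUS calls have
    no VCF representation and are written as missing genotypes.
    """
    path = Path(path)
    varieties = panel.matrix.varieties
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={panel.qtl.chromosome},length=50000000>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(varieties),
    ]
    for marker in sorted(panel.matrix.markers, key=lambda m: m.position_bp):
        col = panel.matrix.column(marker)
        gts = []
        for v in varieties:
            call = col[v]
            if call.state is not CallState.CALLED:
                gts.append("./.")
            elif call.alleles == {ANCESTRAL}:
                gts.append("0/0")
            elif call.alleles == {DERIVED}:
                gts.append("1/1")
            else:
                gts.append("0/1")
        lines.append(
            f"{marker.chromosome}\t{marker.position_bp}\t{marker.marker_id}\t"
            f"{ANCESTRAL}\t{DERIVED}\t.\tPASS\t.\tGT\t" + "\t".join(gts)
        )
    path.write_text("\n".join(lines) + "\n")


def write_simulated_panel(panel: SimulatedPanel, out_dir: str | Path) -> dict:
    """Write genotype CSV, panel CSV, QTL BED, ground-truth JSON and Newick.

    Returns the mapping of artefact name to path.
    """
    from . import io as mio  # local import to avoid a cycle at import time

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes": out_dir / "genotypes.csv",
        "markers": out_dir / "markers.csv",
        "panel": out_dir / "panel.csv",
        "qtl_bed": out_dir / "qtl.bed",
        "ground_truth": out_dir / "ground_truth.json",
        "newick": out_dir / "tree.nwk",
        "vcf": out_dir / "genotypes.vcf",
    }
    mio.write_genotype_csv(panel.matrix, paths["genotypes"])
    mio.write_marker_table(panel.matrix.markers, paths["markers"])
    mio.write_panel_csv(panel.assignments, paths["panel"])
    mio.write_qtl_bed([panel.qtl], paths["qtl_bed"])
    truth = {
        "qtl_id": panel.qtl.qtl_id,
        "scenario": panel.designation.scenario,
        "derived_state": panel.designation.derived_state.value,
        "causal_markers": [
            m.mutation_id for m in panel.designation.causal_mutations
        ],
        "designed_markers": sorted(panel.designed_marker_ids),
        "seed": panel.seed,
        "config": panel.config,
        "markers": {
            mid: {
                "expected_fpr": gt.expected_fpr,
                "expected_fnr": gt.expected_fnr,
                "expected_utility": gt.expected_utility,
                "favourable_allele": gt.favourable_allele,
                "unfavourable_allele": gt.unfavourable_allele,
            }
            for mid, gt in sorted(panel.ground_truth.items())
        },
    }
    paths["ground_truth"].write_text(json.dumps(truth, indent=2) + "\n")
    if panel.tree is not None:
        paths["newick"].write_text(panel.tree.newick() + "\n")
    else:
        paths.pop("newick")
    write_vcf(panel, paths["vcf"])
    return paths
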