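# Methods

## Metric definitions and conventions

The five core metrics split into technical (call rate, clarity), biological
(FPR, FNR) and breeding (BpFPR, BpFNR, utility) groups. Several points are
left open by the verbal definitions and are fixed here as package
conventions:

* **Denominators exclude unscored samples.** "Known recipients" is read as
  *scored* known recipients: a missing call carries no classification and
  must not dilute an error rate. Without this, a marker with a 50% call
  rate would look twice as accurate as an identical marker with full calls.
  Missingness is never lost — it is reported via the call rate, and every
  record carries `n_donors_scored` / `n_recipients_scored` /
  `n_pool_scored` so a reader can judge how much evidence sits behind each
  rate (small panels *inflate* accuracy; see the degenerate case below).
* **Allele-presence semantics for heterozygotes.** A het call "has" both of
  its alleles, so a het donor is not a false negative and a het recipient
  is not a false positive. The alternative — a dominant-marker reading in
  which a het recipient carrying the favourable allele counts as a false
  positive — is noted but not implemented; with presence semantics the
  conflict is still visible through the `CONFLICT` classification.
* **Literal error-rate formulas.** A recipient carrying a third allele
  (neither favourable nor unfavourable) lacks the unfavourable allele and
  counts as a false positive, symmetrically for donors and FNR. Third
  alleles genuinely mislead binary classification and the metric should
  show it rather than excuse it.
* **Ambiguity.** An `AMBIGUOUS` result is visible (counts toward call rate)
  but not scorable (counts against clarity), hence clarity ≤ call rate
  always. Repeatability as a metric distinct from clarity is out of scope.
* **Undefined ≠ zero.** A metric with an empty denominator is `None` in
  memory and empty/null on disk, never 0.
* **Ideal-target flags are exact** (FPR = 0, FNR = 0, call rate = clarity
  = utility = 1), not toleranced: the targets are absolutes.
* **Marker identity is `(marker_id, version)`**: alternate assays for the
  same polymorphism can have very different technical performance.
* Allele labels are opaque strings so SSR band-size categories, SNP bases
  and indel states share one representation; diploid calls only.

## FNR-correcting polarisation

An anonymous marker has no declared favourable allele. The correction
assigns favourable = the allele present in the largest fraction of scored
donor calls. Because FNR = 1 − (that fraction), the choice is exactly
FNR-minimal over all single-allele polarisations; the unit tests verify
this against exhaustive search. Ties are broken by (1) the lower resulting
FPR over the recipients, then (2) lexicographic allele label, and the
result records that a tie occurred. The unfavourable allele is the most
frequent remaining allele among all scored calls. A monomorphic column
cannot be polarised and raises an error; the scanner counts such candidates
as skipped.

Declared markers keep their declared polarity everywhere, including in the
scanner: re-correcting a designed marker whose target allele is absent from
the current donor set would silently flip its meaning and make its FPR
meaningless. In a VCF scan every candidate is anonymous, so all candidates
are FNR-corrected there.

## Scanner ranking and aggregation

The rank key is a total order invented for determinism; only its first
tiers are scientifically motivated (perfect accuracy first, then combined
error, then utility): remaining tiers (call rate, distance from the window
midpoint, marker id) are tie-breakers so that scan output is invariant
under input-row shuffling.

Class summaries use two-stage averaging: metric means are taken within each
QTL over defined values, then averaged *unweighted* across QTLs. This
deliberately down-weights marker-rich QTLs; a pooled mean over markers
would let one densely genotyped QTL dominate a 42-QTL summary. Class
differences are tested with a paired sign-flip permutation test on the
per-QTL means: p = (#{|permuted mean| ≥ |observed mean|} + 1) / (n + 1),
two-sided, requiring ≥ 3 paired QTLs, seeded and therefore exactly
reproducible. It assumes only exchangeability of the paired differences
under the null — appropriate for per-QTL means whose distribution is
unknown and strongly non-normal (many exact zeros).

The utility spectrum reports, per QTL, the utility of the top-ranked marker
with FPR = FNR = 0; QTLs without such a marker are excluded with a recorded
reason, because utility read from an inaccurate marker conflates allele
frequency with misclassification.

## The genealogy simulator

The simulator exists to make the package's claims *theorems* on a known
object rather than plausible behaviours on opaque data. Varieties are
leaves of a Kingman coalescent tree (pairwise merges at rate k(k−1)/2,
branch lengths in coalescent units). Mutations fall on branches as
Poisson(μ × branch length) under an infinite-sites model, so each
mutation's carriers are exactly one subtree's leaf set; lineages are
haploid with ancestral allele `A` and derived allele `G`.

A causal designation induces the panel:

* **Scenario A** — one internal-branch mutation is the favourable origin;
  donors are its carriers.
* **Scenario B** — 2–3 origins on disjoint branches; donors are the union.
  No single polymorphism can then tag every donor lineage, so even the
  causal-branch markers score FNR > 0 — this is a property of the
  scenario, not an error.
* **Scenario C** — the favourable allele is ancestral; 1–2 derived origins
  are unfavourable and donors are the non-carriers.

A configurable fraction of leaves is masked to UNKNOWN status (excluded
from rate denominators, retained in the breeding pool). Ground-truth
FPR/FNR/utility are pure set arithmetic on (donors, recipients, carriers)
with the marker polarised to match the derived QTL state — for a
favourable derived allele, FNR = |D∖C|/|D| and FPR = |R∩C|/|R|, with the
complements when the derived allele is unfavourable. Ground truth is
recorded before per-cell corruption (missing / ambiguous / spurious het)
is injected, so technical-metric recovery can be tested against the
injected rates.

Two marker classes are emitted. Tree mutations become QTL-specific SNP
markers with declared polarity (the causal ones flagged diagnostic,
linkage 0 cM). `n_anonymous` extra markers get carrier sets drawn
panmictically — each leaf carries the derived allele independently with a
per-marker probability uniform on (0.1, 0.9) — emulating fixed-chip SNPs
ascertained for polymorphism rather than for the QTL, and deliberately
independent of the genealogy so that their poor FPR after FNR correction
is guaranteed in expectation rather than assumed. The panel additionally
records a *designed* subset of the tree markers: one donor and one
recipient are drawn as the "sequenced parents" of a biparental comparison,
and a marker is designable iff its QTL-indicating derived allele separates
them. This is the standard origin of MAS markers, and it reproduces their
standard failure: markers designed from one pair track that pair's lineage
and miss alternative donor origins.

### Default study conditions

| parameter | default | rationale |
|---|---|---|
| `n_leaves` | 40 | desk-scale stand-in for a diverse characterised panel; large enough for non-trivial donor/recipient splits |
| `mu` | 1.5 | ≈ a dozen candidate polymorphisms per QTL window, the density of QTL-specific marker sets per QTL |
| `mask_fraction` | 0.25 | the status of many varieties is typically unknown |
| `missing_rate` / `ambiguous_rate` / `het_rate` | 0.05 / 0.02 / 0.02 | low technical noise, below gel-based assays, above chip claims |
| `n_anonymous` | 8 | per-QTL density of a fixed genotyping chip (a few hundred usable SNPs spread over ~40 QTLs) |
| multi-QTL scenario | cycle A, B, C | real QTL catalogues mix single-origin, multiple-origin and ancestral-favourable cases; the anonymous-vs-designed contrast is only meaningful over that mix, since under pure scenario A designed markers are nearly perfect on FNR |

All randomness flows from one explicit seed through
`numpy.random.SeedSequence` spawning, one child stream per stage; no global
state. Multi-panel simulation rejects and redraws (deterministically)
genealogies that admit no eligible causal designation.

### What the simulator does not model

Recombination between marker and QTL (FPR/FNR variation arises solely from
lineage placement, so linkage in cM is annotation only), realistic rice
demography or selection, genuine heterozygosity (injected as corruption,
not inherited), and LD between the anonymous markers and the QTL region —
real chip SNPs inside a QTL interval are partially correlated with its
genealogy, so real anonymous markers should do somewhat better on FNR than
the simulated ones. Passing tests therefore demonstrate correctness of the
metric arithmetic and the qualitative class contrast, not quantitative
error rates expected on any real panel.

## Numerical and I/O choices

Coordinates are 1-based inclusive internally (matching VCF POS); BED is
converted on ingest (`start_bp = bed_start + 1`). VCF alleles are used as
reported on the forward strand, never flipped. Multiallelic and indel VCF
records are skipped with counts — automated indel calls are unreliable for
longer events, so indel markers enter through genotype CSV with scored
`Large`/`Small`-style labels. Proportions serialise with 6 significant
digits; report round-trips are exact for identity fields and flags and
accurate to 1e-6 for proportions. Unknown genotype tokens parse as
`AMBIGUOUS` with a warning rather than failing a whole file. CLI
provenance (version, configuration, input SHA-256 checksums) is written to
a `<out>.run.json` sidecar so reports remain strict CSV/JSON.

## Known limitations

Confidence intervals on the error rates are not computed; panel sizes are
reported instead, leaving precision judgements to the reader. The breeding
pool is treated as a closed gene pool: BpFPR/BpFNR are only meaningful
under that assumption. The permutation test compares exactly two classes
at a time with no multiplicity correction across metrics.
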