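# markerqc

Quality metrics for molecular markers in marker-assisted selection (MAS).

Breeding programs select for a quantitative trait locus (QTL) indirectly,
through a marker assumed to track it. When the marker's association with the
QTL is weak — a common situation for SSRs chosen from a single mapping
population, or for fixed-chip SNPs designed for maximal polymorphism rather
than for the QTL — selection silently discards valuable germplasm or
advances lines that never carried the favourable allele. `markerqc`
quantifies that risk. It evaluates markers against panels of characterised
*donor* (QTL[+]) and *recipient* (QTL[−]) varieties, assigns favourable /
unfavourable alleles to anonymous markers, ranks candidate markers inside
QTL intervals scanned from variant data, and ships a genealogy-based
simulator that produces panels whose true marker metrics are known exactly.

## The metrics

For one marker scored on a panel of varieties:

* **Call rate** — proportion of samples giving a visible result
  (only `MISSING` fails). Ideal: 100%.
* **Clarity** — proportion giving a clearly scorable result (`MISSING` and
  `AMBIGUOUS` both fail, so clarity ≤ call rate). Ideal: 100%.
* **False positive rate (FPR)** — among scored known recipients, the
  fraction *without* the unfavourable allele, and therefore misread as
  QTL[+]:  FPR = #{recipients without unfavourable allele} / #{scored known
  recipients}. Ideal: 0%.
* **False negative rate (FNR)** — among scored known donors, the fraction
  *without* the favourable allele, misread as QTL[−]:
  FNR = #{donors without favourable allele} / #{scored known donors}.
  Ideal: 0%.
* **Utility** — fraction of a breeding pool lacking the favourable allele,
  i.e. the share of material the marker can be used to improve; a
  favourable allele fixed in the pool gives utility 0. Ideal: 100%.
* **BpFPR / BpFNR** — the same error rates restricted to one breeding
  program's germplasm.

Classification is by allele presence (a heterozygote "has" both alleles),
and the error-rate formulas are applied literally: a recipient carrying a
*third* allele — neither favourable nor unfavourable — lacks the
unfavourable allele and counts as a false positive. Denominators count
scored samples only; missingness is reported separately via the call rate.
An anonymous marker with no declared alleles is **FNR-corrected**: the
allele most frequent among scored donors becomes favourable, which provably
minimises the FNR over all single-allele polarisations (ties broken by
lower FPR, then lexicographically).

## Worked example

Simulate a panel (40 varieties on a random coalescent genealogy, one causal
mutation defining donor/recipient status, every mutation a candidate
marker, 8 tree-independent "chip" SNPs, no technical noise) and scan its
QTL window:

```python
import markerqc as mq

sim = mq.simulate_panel(mq.SimulationConfig(
    seed=11, missing_rate=0.0, ambiguous_rate=0.0, het_rate=0.0))
panel = mq.Panel(sim.assignments)
res = mq.scan_qtl(sim.qtl, sim.matrix, panel)
for r in res.records[:6]:
    print(f"{r.marker_id:8} {r.marker_class.value:18} "
          f"{r.fpr:6.3f} {r.fnr:6.3f} {r.utility:7.3f}")
```

```
M014     qtl_specific_snp    0.000  0.000   0.775
ANON004  anonymous           0.333  0.167   0.575
ANON007  anonymous           0.333  0.500   0.650
ANON003  anonymous           0.500  0.333   0.425
ANON006  anonymous           0.625  0.333   0.350
M005     qtl_specific_snp    0.000  1.000   0.975
```

The top-ranked marker `M014` is the causal mutation itself
(`sim.designation.causal_mutations`): it classifies every characterised
variety correctly (FPR = FNR = 0) and its favourable allele is absent from
77.5% of the pool, so it can drive introgression across most of the
program. The FNR-corrected anonymous chip SNPs misclassify 33–63% of known
recipients — polymorphic, but not tracking the causal lineage. `M005`
arose in a different lineage entirely: perfect FPR, useless FNR.

Ranking is deterministic: perfect accuracy first, then ascending
FPR + FNR, descending utility, descending call rate, distance from the
window midpoint, and finally marker id.

The same workflows are available from the shell:

```sh
markerqc simulate --out-dir sim/ --seed 11
markerqc scan --vcf sim/genotypes.vcf --qtl-bed sim/qtl.bed \
              --panel sim/panel.csv --out scan.csv
markerqc evaluate --genotypes sim/genotypes.csv --markers sim/markers.csv \
                  --panel sim/panel.csv --qtl-bed sim/qtl.bed --out report.csv
markerqc summarise report.csv --out summary.json \
                   --compare anonymous qtl_specific_snp --seed 1
```

Reports are CSV/JSON with a stable column order; undefined metrics (zero
denominators) serialise as empty/null, never 0. Every command writes a
`<out>.run.json` sidecar with the tool version, full configuration and
input checksums.

## File formats

* **Genotype CSV** — header `marker_id,version,<variety ids…>`; cells are
  allele labels (`A`, `Large`, `143bp`), heterozygotes `X/Y`, missing `NA`,
  ambiguous `?` (tokens configurable).
* **Panel CSV** — `variety_id,qtl_id,status,in_breeding_pool` with status
  `donor`/`recipient`/`unknown`.
* **QTL BED** — BED3+ (0-based half-open on disk; converted to 1-based
  inclusive internally); optional columns 4–5: QTL id, derived state.
* **VCF 4.x** — biallelic SNP records with GT; multiallelic and indel
  records are skipped with logged counts (indel markers enter via genotype
  CSV instead).

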