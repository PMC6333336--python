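"""Readers and writers for the on-disk formats.

* genotype CSV — markers x varieties allele-call tables (``marker_id,
  version, <variety>, ...``) with configurable missing/ambiguous tokens and
  ``X/Y`` heterozygotes;
* panel CSV — per-variety donor/recipient/unknown status for one QTL;
* QTL BED — BED3+ intervals (0-based half-open on disk, converted to the
  package's 1-based inclusive coordinates on ingest);
* report CSV/JSON — flat serialisations of metrics records that round-trip
  losslessly; undefined metrics serialise as empty/null, never 0;
* VCF — candidate-marker extraction over a QTL window via pysam.

Coordinates are 1-based inclusive internally, matching VCF POS. VCF alleles
are taken as reported (forward strand); no strand flipping is ever
performed, so marker tables must use forward-strand labels.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pysam

from .core import (
    AlleleCall,
    GenotypeMatrix,
    MarkerClass,
    MarkerDefinition,
    MetricsRecord,
    Panel,
    PanelAssignment,
    PanelStatus,
    Polarity,
    PolarisationSource,
    QTLDefinition,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CsvDialect:
    """Token configuration for genotype CSV files."""

    delimiter: str = ","
    missing_token: str = "NA"
    ambiguous_token: str = "?"
    het_separator: str = "/"


# ---------------------------------------------------------------------------
# genotype CSV


def _format_call(call: AlleleCall, dialect: CsvDialect) -> str:
    if call.state.name == "MISSING":
        return dialect.missing_token
    if call.state.name == "AMBIGUOUS":
        return dialect.ambiguous_token
    return dialect.het_separator.join(sorted(call.alleles))


def _parse_call(token: str, dialect: CsvDialect) -> AlleleCall:
    token = token.strip()
    if token == dialect.missing_token:
        return AlleleCall.missing()
    if token == dialect.ambiguous_token or not token:
        if token != dialect.ambiguous_token:
            logger.warning("unrecognised genotype token %r -> AMBIGUOUS", token)
        return AlleleCall.ambiguous()
    parts = [p for p in token.split(dialect.het_separator) if p]
    if len(parts) in (1, 2) and len(set(parts)) == len(parts):
        return AlleleCall.called(*parts)
    logger.warning("unrecognised genotype token %r -> AMBIGUOUS", token)
    return AlleleCall.ambiguous()


def read_genotype_csv(
    path: str | Path,
    dialect: CsvDialect = CsvDialect(),
    markers: Mapping[tuple[str, str], MarkerDefinition] | None = None,
) -> GenotypeMatrix:
    """Read a genotype matrix from CSV.

    The header row is ``marker_id, version, <variety ids...>``. When a
    ``markers`` lookup is supplied, rows adopt the matching full marker
    definition; otherwise minimal unpolarised definitions are created.
    Duplicate ``(marker_id, version)`` rows are an error.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter=dialect.delimiter)
        header = next(reader, None)
        if header is None or len(header) < 3 or header[:2] != ["marker_id", "version"]:
            raise ValueError(
                f"{path}: expected header 'marker_id,version,<varieties...>'"
            )
        varieties = [h.strip() for h in header[2:]]
        marker_defs: list[MarkerDefinition] = []
        calls: dict[tuple[str, str, str], AlleleCall] = {}
        seen: set[tuple[str, str]] = set()
        for row in reader:
            if not row or not any(cell.strip() for cell in row):
                continue
            mid, ver = row[0].strip(), row[1].strip()
            if (mid, ver) in seen:
                raise ValueError(f"{path}: duplicate marker row ({mid!r}, {ver!r})")
            seen.add((mid, ver))
            if markers and (mid, ver) in markers:
                mdef = markers[(mid, ver)]
            else:
                mdef = MarkerDefinition(marker_id=mid, version=ver)
            marker_defs.append(mdef)
            if len(row) - 2 != len(varieties):
                raise ValueError(
                    f"{path}: row {mid!r} has {len(row) - 2} cells, "
                    f"expected {len(varieties)}"
                )
            for v, cell in zip(varieties, row[2:]):
                calls[(mid, ver, v)] = _parse_call(cell, dialect)
    return GenotypeMatrix(marker_defs, varieties, calls)


def write_genotype_csv(
    matrix: GenotypeMatrix,
    path: str | Path,
    dialect: CsvDialect = CsvDialect(),
) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter=dialect.delimiter, lineterminator="\n")
        writer.writerow(["marker_id", "version", *matrix.varieties])
        for m in matrix.markers:
            col = matrix.column(m)
            writer.writerow(
                [m.marker_id, m.version]
                + [_format_call(col[v], dialect) for v in matrix.varieties]
            )


# ---------------------------------------------------------------------------
# panel CSV


def read_panel_csv(path: str | Path) -> list[PanelAssignment]:
    """Read per-variety panel assignments.

    Columns: variety_id, qtl_id, status (donor/recipient/unknown,
    case-insensitive), in_breeding_pool (0/1). Duplicate (variety, qtl)
    pairs are an error.
    """
    path = Path(path)
    out: list[PanelAssignment] = []
    seen: set[tuple[str, str]] = set()
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"variety_id", "qtl_id", "status", "in_breeding_pool"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(f"{path}: expected columns {sorted(required)}")
        for row in reader:
            key = (row["variety_id"], row["qtl_id"])
            if key in seen:
                raise ValueError(f"{path}: duplicate panel pair {key}")
            seen.add(key)
            status_token = row["status"].strip().lower()
            try:
                status = PanelStatus(status_token)
            except ValueError:
                raise ValueError(
                    f"{path}: unrecognised status {row['status']!r} for {key}"
                ) from None
            pool_token = row["in_breeding_pool"].strip()
            if pool_token not in ("0", "1"):
                raise ValueError(
                    f"{path}: in_breeding_pool must be 0 or 1, got {pool_token!r}"
                )
            out.append(
                PanelAssignment(
                    variety_id=row["variety_id"].strip(),
                    qtl_id=row["qtl_id"].strip(),
                    status=status,
                    in_breeding_pool=pool_token == "1",
                )
            )
    return out


def write_panel_csv(assignments: Iterable[PanelAssignment], path: str | Path
                    ) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["variety_id", "qtl_id", "status", "in_breeding_pool"])
        for a in assignments:
            writer.writerow(
                [a.variety_id, a.qtl_id, a.status.value,
                 int(a.in_breeding_pool)]
            )


# ---------------------------------------------------------------------------
# QTL BED


def read_qtl_bed(path: str | Path) -> list[QTLDefinition]:
    """Read QTL intervals from BED3+.

    BED is 0-based half-open; internally 1-based inclusive, so
    start_bp = bed_start + 1 and end_bp = bed_end. Optional column 4 is the
    QTL id (default ``chrom:start-end`` in internal coordinates) and column
    5 the derived QTL state.
    """
    path = Path(path)
    out: list[QTLDefinition] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: need at least 3 BED columns")
            chrom, bed_start, bed_end = fields[0], int(fields[1]), int(fields[2])
            if bed_start >= bed_end:
                raise ValueError(
                    f"{path}:{lineno}: empty interval [{bed_start}, {bed_end})"
                )
            start_bp, end_bp = bed_start + 1, bed_end
            qtl_id = (
                fields[3] if len(fields) >= 4
                else f"{chrom}:{start_bp}-{end_bp}"
            )
            derived = Polarity.UNKNOWN
            if len(fields) >= 5:
                derived = Polarity(fields[4].strip().lower())
            out.append(
                QTLDefinition(
                    qtl_id=qtl_id, chromosome=chrom,
                    start_bp=start_bp, end_bp=end_bp, derived_state=derived,
                )
            )
    return out


def write_qtl_bed(qtls: Iterable[QTLDefinition], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for q in qtls:
            fh.write(
                f"{q.chromosome}\t{q.start_bp - 1}\t{q.end_bp}\t{q.qtl_id}\t"
                f"{q.derived_state.value}\n"
            )


# ---------------------------------------------------------------------------
# VCF ingest


@dataclass
class VcfReadResult:
    matrix: GenotypeMatrix
    n_records: int = 0
    n_multiallelic_skipped: int = 0
    n_indel_skipped: int = 0


def read_vcf_region(
    path: str | Path,
    qtl: QTLDefinition,
    variety_map: Mapping[str, str] | None = None,
) -> VcfReadResult:
    """Extract candidate anonymous SNP markers from a VCF over a QTL window.

    One unpolarised marker per biallelic SNP record with POS inside the
    QTL's 1-based inclusive interval. GT fields map to allele calls
    (0/0 -> {REF}, 1/1 -> {ALT}, 0/1 -> {REF, ALT}, ./. -> MISSING).
    Multiallelic and indel records are skipped and counted. ``variety_map``
    renames VCF samples to variety ids; every mapped sample must exist in
    the header.
    """
    path = Path(path)
    vcf = pysam.VariantFile(str(path))
    samples = list(vcf.header.samples)
    if variety_map is not None:
        missing = sorted(set(variety_map) - set(samples))
        if missing:
            raise ValueError(
                f"{path}: samples in variety_map absent from VCF header: "
                f"{missing}"
            )
        keep = [s for s in samples if s in variety_map]
        varieties = [variety_map[s] for s in keep]
    else:
        keep = samples
        varieties = samples

    markers: list[MarkerDefinition] = []
    calls: dict[tuple[str, str, str], AlleleCall] = {}
    result = VcfReadResult(matrix=GenotypeMatrix([], varieties))
    for rec in vcf.fetch() if _has_index(vcf) else vcf:
        if rec.chrom != qtl.chromosome or not (
            qtl.start_bp <= rec.pos <= qtl.end_bp
        ):
            continue
        result.n_records += 1
        alts = rec.alts or ()
        if len(alts) != 1:
            result.n_multiallelic_skipped += 1
            continue
        ref, alt = rec.ref, alts[0]
        if len(ref) != 1 or len(alt) != 1 or not alt.isalpha():
            result.n_indel_skipped += 1
            continue
        mid = f"{rec.chrom}:{rec.pos}"
        marker = MarkerDefinition(
            marker_id=mid,
            version="vcf",
            platform="resequencing",
            chromosome=rec.chrom,
            position_bp=rec.pos,
            marker_class=MarkerClass.ANONYMOUS,
            marker_target=Polarity.UNPOLARISED,
        )
        markers.append(marker)
        alleles = (ref, alt)
        for sample, variety in zip(keep, varieties):
            gt = rec.samples[sample].get("GT")
            if gt is None or any(g is None for g in gt):
                call = AlleleCall.missing()
            else:
                call = AlleleCall.called(*{alleles[g] for g in gt})
            calls[(mid, "vcf", variety)] = call
    vcf.close()
    result.matrix = GenotypeMatrix(markers, varieties, calls)
    if result.matrix.n_varieties != len(varieties):
        raise AssertionError("sample count changed during VCF ingest")
    return result


def _has_index(vcf: pysam.VariantFile) -> bool:
    try:
        return vcf.index is not None
    except (AttributeError, ValueError):
        return False


# ---------------------------------------------------------------------------
# marker definition tables


_MARKER_COLUMNS = [
    "marker_id", "version", "platform", "chromosome", "position_bp",
    "linkage_cM", "marker_class", "marker_target", "favourable_allele",
    "unfavourable_allele", "derived_qtl_state", "diagnostic",
]


def read_marker_table(path: str | Path
                      ) -> dict[tuple[str, str], MarkerDefinition]:
    """Read full marker definitions keyed by (marker_id, version).

    Required columns: marker_id, version. Optional: platform, chromosome,
    position_bp, linkage_cM, marker_class, marker_target,
    favourable_allele, unfavourable_allele, derived_qtl_state, diagnostic.
    """
    path = Path(path)
    out: dict[tuple[str, str], MarkerDefinition] = {}
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"marker_id", "version"} <= set(
            reader.fieldnames
        ):
            raise ValueError(f"{path}: needs at least marker_id and version")
        for row in reader:
            def get(name: str, default: str = "") -> str:
                return (row.get(name) or default).strip()

            key = (get("marker_id"), get("version", "1"))
            if key in out:
                raise ValueError(f"{path}: duplicate marker {key}")
            linkage = get("linkage_cM")
            out[key] = MarkerDefinition(
                marker_id=key[0],
                version=key[1],
                platform=get("platform", "unknown") or "unknown",
                chromosome=get("chromosome"),
                position_bp=int(get("position_bp", "1") or 1),
                linkage_cM=float(linkage) if linkage else None,
                marker_class=MarkerClass(
                    get("marker_class", "anonymous") or "anonymous"
                ),
                marker_target=Polarity(
                    get("marker_target", "unpolarised") or "unpolarised"
                ),
                favourable_allele=get("favourable_allele") or None,
                unfavourable_allele=get("unfavourable_allele") or None,
                derived_qtl_state=Polarity(
                    get("derived_qtl_state", "unknown") or "unknown"
                ),
                diagnostic=get("diagnostic", "0") in ("1", "true", "True"),
            )
    return out


def write_marker_table(
    markers: Iterable[MarkerDefinition], path: str | Path
) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=_MARKER_COLUMNS,
                                lineterminator="\n")
        writer.writeheader()
        for m in markers:
            writer.writerow({
                "marker_id": m.marker_id,
                "version": m.version,
                "platform": m.platform,
                "chromosome": m.chromosome,
                "position_bp": m.position_bp,
                "linkage_cM": "" if m.linkage_cM is None else m.linkage_cM,
                "marker_class": m.marker_class.value,
                "marker_target": m.marker_target.value,
                "favourable_allele": m.favourable_allele or "",
                "unfavourable_allele": m.unfavourable_allele or "",
                "derived_qtl_state": m.derived_qtl_state.value,
                "diagnostic": int(m.diagnostic),
            })


# ---------------------------------------------------------------------------
# metrics reports

REPORT_COLUMNS = [
    "marker_id", "version", "qtl_id", "marker_class", "chromosome",
    "position_bp", "call_rate", "clarity", "fpr", "fnr", "bp_fpr", "bp_fnr",
    "utility", "n_donors_scored", "n_recipients_scored", "n_pool_scored",
    "favourable_allele", "unfavourable_allele", "polarisation_source",
    "target_matches_derived", "ideal_call_rate", "ideal_clarity",
    "ideal_fpr", "ideal_fnr", "ideal_utility",
]

_PROPORTIONS = ("call_rate", "clarity", "fpr", "fnr", "bp_fpr", "bp_fnr",
                "utility")


def _sig6(x: float) -> str:
    if x == 0:
        return "0"
    return f"{x:.6g}"


def record_to_row(record: MetricsRecord) -> dict[str, object]:
    row: dict[str, object] = {
        "marker_id": record.marker_id,
        "version": record.version,
        "qtl_id": record.qtl_id,
        "marker_class": record.marker_class.value,
        "chromosome": record.chromosome,
        "position_bp": record.position_bp,
        "n_donors_scored": record.n_donors_scored,
        "n_recipients_scored": record.n_recipients_scored,
        "n_pool_scored": record.n_pool_scored,
        "favourable_allele": record.favourable_allele or "",
        "unfavourable_allele": record.unfavourable_allele or "",
        "polarisation_source": record.polarisation_source.value,
        "target_matches_derived": (
            "" if record.target_matches_derived is None
            else int(record.target_matches_derived)
        ),
    }
    for name in _PROPORTIONS:
        v = getattr(record, name)
        row[name] = "" if v is None else _sig6(v)
    for name in ("call_rate", "clarity", "fpr", "fnr", "utility"):
        row[f"ideal_{name}"] = int(record.ideal_flags.get(name, False))
    return row


def row_to_record(row: Mapping[str, object]) -> MetricsRecord:
    def prop(name: str) -> Optional[float]:
        v = row.get(name)
        if v is None or v == "":
            return None
        return float(v)

    tmd = row.get("target_matches_derived")
    return MetricsRecord(
        marker_id=str(row["marker_id"]),
        version=str(row["version"]),
        qtl_id=str(row["qtl_id"]),
        marker_class=MarkerClass(str(row["marker_class"])),
        chromosome=str(row.get("chromosome", "")),
        position_bp=int(row.get("position_bp", 1) or 1),
        call_rate=prop("call_rate"),
        clarity=prop("clarity"),
        fpr=prop("fpr"),
        fnr=prop("fnr"),
        bp_fpr=prop("bp_fpr"),
        bp_fnr=prop("bp_fnr"),
        utility=prop("utility"),
        n_donors_scored=int(row.get("n_donors_scored", 0) or 0),
        n_recipients_scored=int(row.get("n_recipients_scored", 0) or 0),
        n_pool_scored=int(row.get("n_pool_scored", 0) or 0),
        favourable_allele=str(row.get("favourable_allele") or "") or None,
        unfavourable_allele=str(row.get("unfavourable_allele") or "") or None,
        polarisation_source=PolarisationSource(
            str(row.get("polarisation_source", "declared"))
        ),
        target_matches_derived=None if tmd in (None, "") else bool(int(tmd)),
        ideal_flags={
            name: bool(int(row.get(f"ideal_{name}", 0) or 0))
            for name in ("call_rate", "clarity", "fpr", "fnr", "utility")
        },
    )


def write_report(
    records: Iterable[MetricsRecord],
    path: str | Path,
    format: str = "csv",
) -> None:
    """Write metrics records as CSV or JSON.

    Column order is stable; proportions carry 6 significant digits;
    undefined metrics appear as empty cells (CSV) or null (JSON), never 0.
    """
    records = list(records)
    path = Path(path)
    if format == "csv":
        with path.open("w", newline="") as fh:
            writer = csv.DictWriter(
                fh, fieldnames=REPORT_COLUMNS, lineterminator="\n"
            )
            writer.writeheader()
            for r in records:
                writer.writerow(record_to_row(r))
    elif format == "json":
        rows = []
        for r in records:
            row = record_to_row(r)
            rows.append({k: (None if v == "" else v) for k, v in row.items()})
        path.write_text(json.dumps(rows, indent=2) + "\n")
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_report(path: str | Path) -> list[MetricsRecord]:
    path = Path(path)
    if path.suffix == ".json":
        rows = json.loads(path.read_text())
        return [
            row_to_record({k: ("" if v is None else v) for k, v in row.items()})
            for row in rows
        ]
    with path.open(newline="") as fh:
        return [row_to_record(row) for row in csv.DictReader(fh)]
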