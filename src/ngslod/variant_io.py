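"""Readers and writers for the tabular artifacts of the pipeline.

All allele frequencies are carried in **percent** throughout the package;
inputs on the fraction scale are converted at this boundary and never
downstream.  Tabular files are tab-separated UTF-8 with ``#`` comment
lines; target lists may alternatively be sites-only VCF.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

_BASES = ("A", "C", "G", "T")

#: columns of the on-disk AF-table format
AF_TABLE_COLUMNS = ["locus", "depth", "alt_count", "af_percent"]

#: maximum tolerated disagreement between the af_percent column and
#: 100*alt_count/depth, in percentage points
AF_CONSISTENCY_TOL = 0.05


class ParseError(ValueError):
    """Malformed input file; message carries file and line context."""


@dataclasses.dataclass(frozen=True)
class TargetVariant:
    """One pre-validated single-nucleotide mutation locus.

    ``validated_af`` is the orthogonally determined allele frequency in
    percent (e.g. by droplet digital PCR); ``None`` when no validation
    value is available, in which case accuracy analysis is skipped.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    validated_af: float | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref not in _BASES:
            raise ValueError(f"ref must be one of {_BASES}, got {self.ref!r}")
        if self.alt not in _BASES:
            raise ValueError(f"alt must be one of {_BASES}, got {self.alt!r}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt are both {self.ref!r}")
        if self.validated_af is not None and not (0.0 < self.validated_af <= 100.0):
            raise ValueError(
                f"validated_af must lie in (0, 100], got {self.validated_af}"
            )

    @property
    def locus(self) -> str:
        """Canonical locus key, ``chrom:pos:ref>alt``."""
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclasses.dataclass
class AFTable:
    """Per-replicate allele-frequency table for one data-size tier.

    ``data`` has columns ``locus, depth, alt_count, af_percent``; one row
    per target locus.  An undefined AF (zero depth) is stored as NaN.
    """

    replicate_id: str
    data_size_label: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in AF_TABLE_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"AFTable missing columns {missing}")
        self.data = self.data.loc[:, AF_TABLE_COLUMNS].reset_index(drop=True)
        bad = self.data[self.data["alt_count"] > self.data["depth"]]
        if len(bad):
            raise ValueError(
                f"alt_count exceeds depth at loci {bad['locus'].tolist()}"
            )
        defined = self.data["depth"] > 0
        expected = (
            100.0 * self.data.loc[defined, "alt_count"] / self.data.loc[defined, "depth"]
        )
        off = (self.data.loc[defined, "af_percent"] - expected).abs() > AF_CONSISTENCY_TOL
        if off.any():
            raise ValueError(
                "af_percent inconsistent with alt_count/depth at loci "
                f"{self.data.loc[defined].loc[off, 'locus'].tolist()}"
            )

    def __len__(self) -> int:
        return len(self.data)


def _parse_float(text: str, *, where: str) -> float:
    try:
        return float(text)
    except ValueError as exc:
        raise ParseError(f"{where}: not a number: {text!r}") from exc


def read_targets(
    path: str | Path,
    format: str = "tsv",
    *,
    vcf_af_key: str = "VAF",
    vcf_af_is_percent: bool = True,
) -> list[TargetVariant]:
    """Read a target-variant list from TSV or sites-only VCF.

    The TSV must have header columns ``chrom, pos, ref, alt, validated_af``
    (``validated_af`` may be empty).  VCF input accepts biallelic SNV
    records only; the validated AF is taken from INFO key ``vcf_af_key``
    and multiplied by 100 unless ``vcf_af_is_percent``.

    Returns targets in file order.  Duplicate (chrom, pos, ref, alt)
    entries are rejected.
    """
    path = Path(path)
    if format == "tsv":
        targets = _read_targets_tsv(path)
    elif format == "vcf":
        targets = _read_targets_vcf(path, vcf_af_key, vcf_af_is_percent)
    else:
        raise ValueError(f"unknown target-list format {format!r}")

    seen: set[tuple[str, int, str, str]] = set()
    for t in targets:
        key = (t.chrom, t.pos, t.ref, t.alt)
        if key in seen:
            raise ParseError(f"{path}: duplicate target {t.locus}")
        seen.add(key)
    return targets


def _read_targets_tsv(path: Path) -> list[TargetVariant]:
    targets: list[TargetVariant] = []
    header: list[str] | None = None
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                required = ["chrom", "pos", "ref", "alt", "validated_af"]
                if header[: len(required)] != required:
                    raise ParseError(
                        f"{path}:{lineno}: expected header columns {required}, "
                        f"got {header}"
                    )
                continue
            where = f"{path}:{lineno}"
            if len(fields) < 4:
                raise ParseError(f"{where}: expected >= 4 fields, got {len(fields)}")
            chrom, pos_s, ref, alt = fields[:4]
            af_s = fields[4] if len(fields) > 4 else ""
            try:
                pos = int(pos_s)
            except ValueError as exc:
                raise ParseError(f"{where}: malformed position {pos_s!r}") from exc
            af = _parse_float(af_s, where=where) if af_s.strip() else None
            try:
                targets.append(TargetVariant(chrom, pos, ref, alt, af))
            except ValueError as exc:
                raise ParseError(f"{where}: {exc}") from exc
    if header is None:
        raise ParseError(f"{path}: empty file, no header")
    return targets


def _read_targets_vcf(path: Path, af_key: str, af_is_percent: bool) -> list[TargetVariant]:
    import pysam

    targets: list[TargetVariant] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                raise ParseError(
                    f"{path}: record {rec.chrom}:{rec.pos} is not biallelic; "
                    "multi-allelic records must be split upstream"
                )
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) != 1 or len(alt) != 1:
                raise ParseError(
                    f"{path}: record {rec.chrom}:{rec.pos} is not an SNV "
                    f"({ref}>{alt}); only point mutations are supported"
                )
            af: float | None = None
            if af_key in rec.info:
                val = rec.info[af_key]
                if isinstance(val, tuple):
                    val = val[0]
                af = float(val)
                if not af_is_percent:
                    af *= 100.0
            try:
                targets.append(TargetVariant(rec.chrom, rec.pos, ref, alt, af))
            except ValueError as exc:
                raise ParseError(f"{path}: record {rec.chrom}:{rec.pos}: {exc}") from exc
    return targets


def write_targets(targets: Sequence[TargetVariant], path: str | Path) -> None:
    """Write a target list in the TSV dialect ``read_targets`` accepts."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("chrom\tpos\tref\talt\tvalidated_af\n")
        for t in targets:
            af = "" if t.validated_af is None else f"{t.validated_af:.4f}"
            fh.write(f"{t.chrom}\t{t.pos}\t{t.ref}\t{t.alt}\t{af}\n")


def write_af_table(table: AFTable, path: str | Path) -> None:
    """Serialize an AFTable: metadata as ``#key=value`` lines, then TSV."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"#replicate_id={table.replicate_id}\n")
        fh.write(f"#data_size_label={table.data_size_label}\n")
        fh.write("\t".join(AF_TABLE_COLUMNS) + "\n")
        for row in table.data.itertuples(index=False):
            af = "NA" if math.isnan(row.af_percent) else f"{row.af_percent:.4f}"
            fh.write(f"{row.locus}\t{int(row.depth)}\t{int(row.alt_count)}\t{af}\n")


def read_af_table(path: str | Path) -> AFTable:
    """Read an AFTable written by :func:`write_af_table`.

    Validates the AFTable invariants: ``alt_count <= depth`` and
    ``af_percent`` consistent with ``100*alt_count/depth`` to within
    0.05 percentage points.  An empty (header-only) table is accepted
    with a warning.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    rows: list[tuple[str, int, int, float]] = []
    header_seen = False
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if "=" in line:
                    key, _, val = line[1:].partition("=")
                    meta[key.strip()] = val.strip()
                continue
            fields = line.split("\t")
            if not header_seen:
                if fields[: len(AF_TABLE_COLUMNS)] != AF_TABLE_COLUMNS:
                    raise ParseError(
                        f"{path}:{lineno}: expected header {AF_TABLE_COLUMNS}, got {fields}"
                    )
                header_seen = True
                continue
            where = f"{path}:{lineno}"
            if len(fields) < 4:
                raise ParseError(f"{where}: expected 4 fields, got {len(fields)}")
            locus = fields[0]
            try:
                depth = int(fields[1])
                alt_count = int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{where}: malformed count") from exc
            af = math.nan if fields[3] == "NA" else _parse_float(fields[3], where=where)
            rows.append((locus, depth, alt_count, af))
    if not header_seen:
        raise ParseError(f"{path}: missing header line")
    if not rows:
        logger.warning("%s: AF table is empty (header only)", path)
    df = pd.DataFrame(rows, columns=AF_TABLE_COLUMNS)
    return AFTable(
        replicate_id=meta.get("replicate_id", "unknown"),
        data_size_label=meta.get("data_size_label", "unknown"),
        data=df,
    )


def _result_record(result) -> dict:
    if dataclasses.is_dataclass(result):
        return dataclasses.asdict(result)
    return dict(result)


def write_report(
    results: Iterable, path: str | Path, format: str = "tsv"
) -> None:
    """Write LOD and/or accuracy result records to TSV or JSON.

    Records (dataclasses or mappings) are flattened to one row each with
    a deterministic column order (union of fields in first-seen order).
    Floats are serialized with 4 decimals; ``None`` as ``none`` in TSV
    and ``null`` in JSON.  JSON output round-trips losslessly at that
    precision.
    """
    records = [_result_record(r) for r in results]
    if not records:
        raise ValueError("write_report: no results to write")
    columns: list[str] = []
    for rec in records:
        for key in rec:
            if key not in columns:
                columns.append(key)

    def _fmt(value):
        if isinstance(value, float):
            return round(value, 4)
        return value

    if format == "json":
        payload = [{c: _fmt(rec.get(c)) for c in columns} for rec in records]
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")
    elif format == "tsv":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\t".join(columns) + "\n")
            for rec in records:
                cells = []
                for c in columns:
                    v = rec.get(c)
                    if v is None:
                        cells.append("none")
                    elif isinstance(v, float):
                        cells.append(f"{v:.4f}")
                    else:
                        cells.append(str(v))
                fh.write("\t".join(cells) + "\n")
    else:
        raise ValueError(f"unknown report format {format!r}")
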