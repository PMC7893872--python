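"""Base counting at target loci and probabilistic downsampling.

Counting walks read alignments (SAM/BAM via pysam) and tallies the four
base types observed at each target position after quality filtering —
the allele frequency is computed from these tallies, with the total of
all four base types as denominator.  Downsampling emulates per-read
Bernoulli thinning (Picard ``DownsampleSam``) at the tally level: each
tally is independently binomially thinned with the keep-probability,
which is distributionally equivalent for independent reads at a single
locus.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import zlib
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .variant_io import AFTable, TargetVariant

logger = logging.getLogger(__name__)

_BASES = ("A", "C", "G", "T")

#: default quality filters; the upstream base-quality recalibration used
#: by full variant-calling workflows is out of scope, so mild fixed
#: filters stand in (both configurable at every call site)
DEFAULT_MIN_BASE_QUALITY = 13
DEFAULT_MIN_MAPPING_QUALITY = 20

COUNT_TABLE_COLUMNS = ["locus", "count_A", "count_C", "count_G", "count_T", "depth"]


@dataclasses.dataclass
class LocusCounts:
    """Base-type tallies at one target locus in one replicate."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    count_A: int = 0
    count_C: int = 0
    count_G: int = 0
    count_T: int = 0

    def __post_init__(self) -> None:
        for b in _BASES:
            if getattr(self, f"count_{b}") < 0:
                raise ValueError(f"negative tally for base {b}")

    @property
    def depth(self) -> int:
        return self.count_A + self.count_C + self.count_G + self.count_T

    @property
    def locus(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"

    def count(self, base: str) -> int:
        return getattr(self, f"count_{base}")

    @property
    def alt_count(self) -> int:
        return self.count(self.alt)


@dataclasses.dataclass(frozen=True)
class DownsampleSpec:
    """Keep-probability, tier label and RNG seed for one thinning pass."""

    fraction: float
    target_label: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.fraction <= 1.0):
            raise ValueError(f"fraction must lie in (0, 1], got {self.fraction}")


def count_bases_at_loci(
    alignments: str | Path,
    targets: Sequence[TargetVariant],
    min_base_quality: int = DEFAULT_MIN_BASE_QUALITY,
    min_mapping_quality: int = DEFAULT_MIN_MAPPING_QUALITY,
) -> list[LocusCounts]:
    """Tally base calls at each target position from a SAM/BAM file.

    Reads flagged unmapped, secondary, supplementary or duplicate are
    excluded, as are base calls below ``min_base_quality`` or on reads
    below ``min_mapping_quality``; deletions and reference skips at the
    position contribute nothing.  Coordinate-sorted indexed input is
    used via random access; otherwise the whole stream is scanned (with
    a warning).  Loci on chromosomes absent from the alignment header
    get depth 0 with a warning.
    """
    import pysam

    path = Path(alignments)
    mode = "rb" if path.suffix.lower() == ".bam" else "r"
    results = [
        LocusCounts(chrom=t.chrom, pos=t.pos, ref=t.ref, alt=t.alt) for t in targets
    ]
    with pysam.AlignmentFile(str(path), mode) as af:
        has_index = False
        try:
            has_index = af.has_index()
        except (AttributeError, ValueError):
            has_index = False
        known = set(af.references or ())
        if has_index:
            for t, counts in zip(targets, results):
                if t.chrom not in known:
                    logger.warning("chromosome %s absent from alignment header", t.chrom)
                    continue
                for read in af.fetch(t.chrom, t.pos - 1, t.pos):
                    _tally_read(read, t, counts, min_base_quality, min_mapping_quality)
        else:
            logger.warning(
                "%s has no index; scanning the full stream", path
            )
            by_chrom: dict[str, list[tuple[TargetVariant, LocusCounts]]] = {}
            for t, counts in zip(targets, results):
                if t.chrom not in known:
                    logger.warning("chromosome %s absent from alignment header", t.chrom)
                    continue
                by_chrom.setdefault(t.chrom, []).append((t, counts))
            for read in af.fetch(until_eof=True):
                if read.reference_name not in by_chrom:
                    continue
                for t, counts in by_chrom[read.reference_name]:
                    _tally_read(read, t, counts, min_base_quality, min_mapping_quality)
    return results


def _tally_read(read, target, counts, min_base_quality, min_mapping_quality) -> None:
    if (
        read.is_unmapped
        or read.is_secondary
        or read.is_supplementary
        or read.is_duplicate
    ):
        return
    if read.mapping_quality < min_mapping_quality:
        return
    ref_pos0 = target.pos - 1
    if not (read.reference_start <= ref_pos0 < (read.reference_end or -1)):
        return
    for qpos, rpos in read.get_aligned_pairs(matches_only=True):
        if rpos == ref_pos0:
            base = read.query_sequence[qpos].upper()
            qual = read.query_qualities[qpos]
            if base in _BASES and qual >= min_base_quality:
                setattr(counts, f"count_{base}", counts.count(base) + 1)
            return


def compute_af(counts: LocusCounts) -> dict:
    """Allele frequency of the alt base in percent.

    The denominator is the total of all four base tallies, so error
    bases at third alleles slightly depress the AF (conservative).
    Depth 0 yields ``af_percent`` NaN, excluded by downstream stages.
    """
    depth = counts.depth
    if depth == 0:
        logger.warning("locus %s has depth 0; AF undefined", counts.locus)
        af = math.nan
    else:
        af = 100.0 * counts.alt_count / depth
    return {
        "locus": counts.locus,
        "depth": depth,
        "alt_count": counts.alt_count,
        "af_percent": af,
    }


def af_table_from_counts(
    counts: Sequence[LocusCounts], replicate_id: str, data_size_label: str
) -> AFTable:
    """Assemble per-locus AF records into an :class:`AFTable`."""
    df = pd.DataFrame([compute_af(c) for c in counts])
    return AFTable(replicate_id=replicate_id, data_size_label=data_size_label, data=df)


def reads_for_data_size(total_bases: float, read_length: int = 100) -> float:
    """Number of reads a data size corresponds to at a given read length.

    e.g. 5 Gbp of 100-bp reads is 50 million reads.
    """
    if read_length <= 0:
        raise ValueError("read_length must be positive")
    return total_bases / read_length


def fraction_for_target_size(total_bases: float, target_size: float) -> float:
    """Keep-probability taking ``total_bases`` of data down to ``target_size``."""
    if target_size <= 0:
        raise ValueError("target_size must be positive")
    if target_size > total_bases:
        raise ValueError(
            f"cannot upsample: target {target_size} exceeds total {total_bases}"
        )
    return target_size / total_bases


def downsample_counts(counts: LocusCounts, spec: DownsampleSpec) -> LocusCounts:
    """Thin each base tally by an independent Binomial(tally, fraction) draw.

    Deterministic given (counts, fraction, seed): the RNG is seeded per
    invocation from ``spec.seed`` and the locus coordinates, so the same
    spec applied to the same locus reproduces the same thinned tallies
    and different loci get independent draws.
    """
    if spec.fraction == 1.0:
        return dataclasses.replace(counts)
    chrom_tag = zlib.crc32(counts.chrom.encode("utf-8"))
    rng = np.random.default_rng([spec.seed, counts.pos, chrom_tag])
    thinned = {
        f"count_{b}": int(rng.binomial(counts.count(b), spec.fraction)) for b in _BASES
    }
    return LocusCounts(
        chrom=counts.chrom, pos=counts.pos, ref=counts.ref, alt=counts.alt, **thinned
    )


def write_count_table(counts: Sequence[LocusCounts], path: str | Path) -> None:
    """TSV count table: locus, count_A, count_C, count_G, count_T, depth."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(COUNT_TABLE_COLUMNS) + "\n")
        for c in counts:
            fh.write(
                f"{c.locus}\t{c.count_A}\t{c.count_C}\t{c.count_G}\t{c.count_T}\t{c.depth}\n"
            )


def read_count_table(path: str | Path) -> list[LocusCounts]:
    """Read a TSV count table written by :func:`write_count_table`."""
    out: list[LocusCounts] = []
    with open(path, encoding="utf-8") as fh:
        header: list[str] | None = None
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                if fields != COUNT_TABLE_COLUMNS:
                    raise ValueError(
                        f"{path}:{lineno}: expected header {COUNT_TABLE_COLUMNS}"
                    )
                header = fields
                continue
            locus = fields[0]
            coord, _, allele = locus.rpartition(":")
            chrom, _, pos_s = coord.partition(":")
            ref, _, alt = allele.partition(">")
            counts = LocusCounts(
                chrom=chrom,
                pos=int(pos_s),
                ref=ref,
                alt=alt,
                count_A=int(fields[1]),
                count_C=int(fields[2]),
                count_G=int(fields[3]),
                count_T=int(fields[4]),
            )
            if counts.depth != int(fields[5]):
                raise ValueError(
                    f"{path}:{lineno}: depth column {fields[5]} does not equal "
                    f"the tally total {counts.depth}"
                )
            out.append(counts)
    if header is None:
        raise ValueError(f"{path}: missing header")
    return out
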