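"""Synthetic replicate experiments for the reference-standard design.

Emulates a reference DNA with a panel of low-frequency point mutations
measured by repeated independent sequencing: a truth set of loci with
known allele frequencies, per-replicate base-count tables generated
under binomial (or beta-binomial overdispersed) allele sampling at
configurable depth tiers, and small SAM fixtures for exercising the
alignment-counting path.

Defaults follow the quadruplicate reference-standard experiment: 20 loci
with true AFs evenly spanning 1.0-33.5%, four technical replicates, and
four data-size tiers whose mean depths are 63x (5 Gbp), 189x (15 Gbp),
377x (30 Gbp) and 503x (40 Gbp).
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .pileup_counts import LocusCounts, af_table_from_counts, write_count_table
from .variant_io import AFTable, TargetVariant, write_targets

#: tier label -> mean per-locus depth (x); depth scales with total data size
DEFAULT_DEPTH_TIERS: dict[str, float] = {
    "5Gbp": 63.0,
    "15Gbp": 189.0,
    "30Gbp": 377.0,
    "40Gbp": 503.0,
}

_SYNTH_CHROM = "chrS"
_LOCUS_SPACING = 1000
_FIRST_POS = 10_000
# ref/alt pairs cycled across loci so the panel exercises all base pairs
_ALLELE_CYCLE = [("G", "T"), ("C", "A"), ("A", "G"), ("T", "C")]


@dataclasses.dataclass
class SimulationConfig:
    """Parameters of one synthetic replicate experiment.

    ``overdispersion_rho`` is the intraclass correlation of a
    beta-binomial allele-sampling model; 0 (the default) is pure
    binomial sampling, for which the closed-form precision oracles hold
    exactly.  ``error_rate`` sends a small binomial spill of non-alt
    bases to a third base, exercising the all-bases AF denominator.
    """

    n_loci: int = 20
    af_range: tuple[float, float] = (1.0, 33.5)
    af_list: Sequence[float] | None = None
    n_replicates: int = 4
    depth_tiers: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_DEPTH_TIERS)
    )
    depth_model: str = "poisson"  # fixed | poisson
    overdispersion_rho: float = 0.0
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        lo, hi = self.af_range
        if not (0.0 < lo <= 100.0 and 0.0 < hi <= 100.0):
            raise ValueError(f"af_range endpoints must lie in (0, 100], got {self.af_range}")
        if lo > hi:
            raise ValueError("af_range must be (low, high)")
        if self.af_list is not None and len(self.af_list) != self.n_loci:
            raise ValueError(
                f"explicit AF list has {len(self.af_list)} entries for {self.n_loci} loci"
            )
        if any(d <= 0 for d in self.depth_tiers.values()):
            raise ValueError("depth_tiers means must be positive")
        if self.depth_model not in ("fixed", "poisson"):
            raise ValueError(f"unknown depth_model {self.depth_model!r}")
        if not (0.0 <= self.overdispersion_rho < 1.0):
            raise ValueError("overdispersion_rho must lie in [0, 1)")
        if not (0.0 <= self.error_rate < 0.25):
            raise ValueError("error_rate must lie in [0, 0.25)")


def make_truth(config: SimulationConfig) -> list[TargetVariant]:
    """Truth set: n_loci loci on a synthetic chromosome with known AFs.

    AFs are the explicit list if given, otherwise evenly spaced across
    ``af_range`` including both endpoints.  Positions are distinct and
    deterministic; ref/alt pairs cycle through all four bases.
    """
    if config.af_list is not None:
        afs = [float(a) for a in config.af_list]
        if any(not (0.0 < a <= 100.0) for a in afs):
            raise ValueError("explicit AFs must lie in (0, 100]")
    elif config.n_loci == 1:
        afs = [config.af_range[0]]
    else:
        afs = list(np.linspace(config.af_range[0], config.af_range[1], config.n_loci))
    targets = []
    for i, af in enumerate(afs):
        ref, alt = _ALLELE_CYCLE[i % len(_ALLELE_CYCLE)]
        targets.append(
            TargetVariant(
                chrom=_SYNTH_CHROM,
                pos=_FIRST_POS + i * _LOCUS_SPACING,
                ref=ref,
                alt=alt,
                validated_af=float(af),
            )
        )
    return targets


def _replicate_rng(config: SimulationConfig, tier_label: str, replicate_index: int):
    tag = zlib.crc32(tier_label.encode("utf-8"))
    return np.random.default_rng(
        [int(config.seed) % (2**31), tag, int(replicate_index)]
    )


def simulate_replicate(
    truth: Sequence[TargetVariant],
    tier_label: str,
    config: SimulationConfig,
    replicate_index: int,
) -> list[LocusCounts]:
    """Draw per-locus base tallies for one technical replicate.

    Per locus: depth d is fixed at the tier mean or Poisson with that
    mean (minimum 1); the replicate's alt fraction equals the true AF,
    perturbed by a Beta draw with mean p and intraclass correlation rho
    when overdispersion is on; alt count ~ Binomial(d, p_rep); of the
    remaining bases a Binomial(d - alt, error_rate) spill goes to a
    fixed third base and the rest to ref.  Deterministic given
    (config.seed, tier_label, replicate_index).
    """
    depth_mean = float(config.depth_tiers[tier_label])
    rng = _replicate_rng(config, tier_label, replicate_index)
    rho = config.overdispersion_rho
    out: list[LocusCounts] = []
    for t in truth:
        if config.depth_model == "fixed":
            d = int(round(depth_mean))
        else:
            d = max(1, int(rng.poisson(depth_mean)))
        p = (t.validated_af or 0.0) / 100.0
        if rho > 0.0 and 0.0 < p < 1.0:
            s = 1.0 / rho - 1.0  # Beta concentration: ICC = 1/(a+b+1)
            p_rep = float(rng.beta(p * s, (1.0 - p) * s))
        else:
            p_rep = p
        alt = int(rng.binomial(d, p_rep))
        err = int(rng.binomial(d - alt, config.error_rate)) if config.error_rate else 0
        ref = d - alt - err
        third = next(b for b in "ACGT" if b not in (t.ref, t.alt))
        tallies = {f"count_{b}": 0 for b in "ACGT"}
        tallies[f"count_{t.alt}"] = alt
        tallies[f"count_{t.ref}"] = ref
        tallies[f"count_{third}"] += err
        out.append(
            LocusCounts(chrom=t.chrom, pos=t.pos, ref=t.ref, alt=t.alt, **tallies)
        )
    return out


def simulate_experiment(
    config: SimulationConfig,
) -> tuple[list[TargetVariant], dict[str, list[AFTable]], dict]:
    """Full synthetic experiment: truth, per-tier replicate AF tables, manifest.

    For each depth tier, ``n_replicates`` AF tables are generated.  The
    manifest records every parameter and the per-replicate seeds so a
    rerun with the same config is bit-identical.
    """
    truth = make_truth(config)
    tables: dict[str, list[AFTable]] = {}
    manifest: dict = {
        "config": {
            "n_loci": config.n_loci,
            "af_range": list(config.af_range),
            "af_list": list(config.af_list) if config.af_list is not None else None,
            "n_replicates": config.n_replicates,
            "depth_tiers": dict(config.depth_tiers),
            "depth_model": config.depth_model,
            "overdispersion_rho": config.overdispersion_rho,
            "error_rate": config.error_rate,
            "seed": config.seed,
        },
        "replicates": [],
    }
    for tier_label in config.depth_tiers:
        tier_tables = []
        for r in range(config.n_replicates):
            counts = simulate_replicate(truth, tier_label, config, r)
            rep_id = f"rep{r + 1}"
            tier_tables.append(af_table_from_counts(counts, rep_id, tier_label))
            manifest["replicates"].append(
                {"tier": tier_label, "replicate_id": rep_id, "replicate_index": r}
            )
        tables[tier_label] = tier_tables
    return truth, tables, manifest


def write_experiment(
    config: SimulationConfig, out_dir: str | Path
) -> tuple[list[TargetVariant], dict[str, list[Path]]]:
    """Simulate and write truth, per-replicate count tables and manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truth = make_truth(config)
    write_targets(truth, out_dir / "targets.tsv")
    paths: dict[str, list[Path]] = {}
    manifest_entries = []
    for tier_label in config.depth_tiers:
        tier_paths = []
        for r in range(config.n_replicates):
            counts = simulate_replicate(truth, tier_label, config, r)
            path = out_dir / f"counts_{tier_label}_rep{r + 1}.tsv"
            write_count_table(counts, path)
            tier_paths.append(path)
            manifest_entries.append(
                {"tier": tier_label, "replicate_id": f"rep{r + 1}",
                 "replicate_index": r, "path": path.name}
            )
        paths[tier_label] = tier_paths
    _, _, manifest = simulate_experiment(config)
    manifest["replicates"] = manifest_entries
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return truth, paths


def emit_sam_fixture(
    truth: Sequence[TargetVariant],
    depth: int,
    seed: int = 0,
    *,
    alt_reads: Mapping[str, int] | None = None,
    n_low_baseq: int = 0,
    n_low_mapq: int = 0,
    read_length: int = 100,
) -> tuple[str, list[LocusCounts]]:
    """Small SAM fixture plus the tallies a correct counter must report.

    Each locus gets ``depth`` reads passing filters (``alt_reads[locus]``
    of them carrying the alt base, the rest ref), plus ``n_low_baseq``
    reads whose base at the locus is below quality 13 and ``n_low_mapq``
    reads with mapping quality 0 — both of which must be excluded from
    the tallies.  Reads are placed at staggered offsets so the locus
    falls at varying query positions.
    """
    if depth > 1000:
        raise ValueError("fixture depth is capped at 1000")
    rng = np.random.default_rng(seed)
    max_pos = max((t.pos for t in truth), default=0) + read_length + 10
    lines = [
        "@HD\tVN:1.6\tSO:coordinate",
        f"@SQ\tSN:{_SYNTH_CHROM}\tLN:{max_pos}",
    ]
    expected: list[LocusCounts] = []
    records: list[tuple[int, str]] = []
    read_no = 0
    for t in truth:
        n_alt = (alt_reads or {}).get(t.locus, 0)
        if n_alt > depth:
            raise ValueError(f"alt_reads for {t.locus} exceeds depth")
        tallies = {f"count_{b}": 0 for b in "ACGT"}
        tallies[f"count_{t.ref}"] = depth - n_alt
        tallies[f"count_{t.alt}"] = n_alt
        expected.append(
            LocusCounts(chrom=t.chrom, pos=t.pos, ref=t.ref, alt=t.alt, **tallies)
        )
        kinds = (["alt"] * n_alt + ["ref"] * (depth - n_alt)
                 + ["low_baseq"] * n_low_baseq + ["low_mapq"] * n_low_mapq)
        for kind in kinds:
            read_no += 1
            offset = int(rng.integers(0, read_length))
            start = t.pos - offset  # 1-based
            if start < 1:
                offset += start - 1
                start = 1
            base = t.alt if kind == "alt" else t.ref
            seq = ["A"] * read_length
            seq[offset] = base
            qual = [30] * read_length
            if kind == "low_baseq":
                qual[offset] = 5
            mapq = 0 if kind == "low_mapq" else 60
            seq_s = "".join(seq)
            qual_s = "".join(chr(q + 33) for q in qual)
            records.append(
                (
                    start,
                    f"read{read_no}\t0\t{_SYNTH_CHROM}\t{start}\t{mapq}\t"
                    f"{read_length}M\t*\t0\t0\t{seq_s}\t{qual_s}",
                )
            )
    records.sort(key=lambda r: r[0])
    lines.extend(r[1] for r in records)
    return "\n".join(lines) + "\n", expected
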