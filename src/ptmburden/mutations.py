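"""Cohort mutation ingestion, consequence filtering, and position counting.

Mutations arrive already mapped to protein coordinates, either as a TSV or
as a VCF whose records carry a pre-computed protein annotation in an INFO
field.  Only missense changes (non-synonymous substitutions that neither
create nor remove a stop codon) enter the counting step; counts are summed
over samples so recurrent hits accumulate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd
import pysam

from ptmburden.catalog import RegionPartition

logger = logging.getLogger(__name__)

DEFAULT_ANN_KEY = "PTM_ANN"

CONSEQUENCES = ("missense", "synonymous", "stopgain", "stoploss", "other")

TSV_COLUMNS = ("sample_id", "accession", "position", "ref_aa", "alt_aa", "consequence")


@dataclass(frozen=True)
class MutationRecord:
    """One protein-level substitution observed in one cohort sample."""

    sample_id: str
    accession: str
    position: int
    ref_aa: str
    alt_aa: str
    consequence: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"mutation position must be >= 1, got {self.position}")
        if self.consequence not in CONSEQUENCES:
            raise ValueError(
                f"unknown consequence {self.consequence!r}; expected one of {CONSEQUENCES}"
            )
        if self.consequence == "missense" and self.ref_aa == self.alt_aa:
            raise ValueError("missense record with ref_aa == alt_aa")


@dataclass(frozen=True)
class CountVector:
    """Per-position cohort mutation counts aligned to a region partition.

    ``mod_counts[i]`` counts retained mutations at ``partition.mod_positions[i]``
    (the Y_1..Y_k of the Poisson model); ``bg_counts`` covers the background
    positions Y_{k+1}..Y_n analogously.
    """

    partition: RegionPartition
    mod_counts: tuple[int, ...]
    bg_counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.mod_counts) != len(self.partition.mod_positions):
            raise ValueError("mod_counts misaligned with partition")
        if len(self.bg_counts) != len(self.partition.bg_positions):
            raise ValueError("bg_counts misaligned with partition")
        if any(c < 0 for c in self.mod_counts) or any(c < 0 for c in self.bg_counts):
            raise ValueError("counts must be non-negative")

    @property
    def mod_total(self) -> int:
        return int(sum(self.mod_counts))

    @property
    def bg_total(self) -> int:
        return int(sum(self.bg_counts))


def load_mutations(
    path: str | Path,
    format: str = "tsv",
    ann_key: str = DEFAULT_ANN_KEY,
) -> list[MutationRecord]:
    """Load cohort mutations from TSV or a pre-annotated VCF.

    TSV needs columns sample_id, accession, position, ref_aa, alt_aa,
    consequence.  VCF records must carry, in INFO key ``ann_key``, one
    pipe-delimited annotation ``accession|position|ref_aa|alt_aa|consequence``
    per ALT allele (comma-separated); the sample id is taken from the VCF
    sample column when present, else the record ID.  Genomic-to-protein
    mapping itself is upstream of this tool.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        return _load_mutations_tsv(path)
    if format == "vcf":
        return _load_mutations_vcf(path, ann_key)
    raise ValueError(f"unknown mutation format {format!r}; use 'tsv' or 'vcf'")


def _load_mutations_tsv(path: Path) -> list[MutationRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in TSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"mutation TSV {path} missing columns: {missing}")
    records: list[MutationRecord] = []
    n_skipped = 0
    for row in df.itertuples(index=False):
        try:
            records.append(
                MutationRecord(
                    sample_id=row.sample_id,
                    accession=row.accession,
                    position=int(row.position),
                    ref_aa=row.ref_aa,
                    alt_aa=row.alt_aa,
                    consequence=row.consequence,
                )
            )
        except (ValueError, TypeError):
            n_skipped += 1
    if n_skipped:
        warnings.warn(f"{n_skipped} malformed mutation row(s) skipped", stacklevel=3)
    return records


def _load_mutations_vcf(path: Path, ann_key: str) -> list[MutationRecord]:
    records: list[MutationRecord] = []
    n_skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        if ann_key not in vcf.header.info:
            raise ValueError(
                f"VCF lacks INFO key {ann_key!r}; pre-annotate protein consequences "
                f"(accession|position|ref_aa|alt_aa|consequence, one per ALT)"
            )
        sample_names = list(vcf.header.samples)
        for rec in vcf:
            ann = rec.info.get(ann_key)
            if ann is None:
                n_skipped += 1
                continue
            entries = ann if isinstance(ann, tuple) else (ann,)
            sample_id = sample_names[0] if sample_names else (rec.id or "unknown")
            for entry in entries:
                fields = str(entry).split("|")
                if len(fields) != 5:
                    n_skipped += 1
                    continue
                acc, pos, ref_aa, alt_aa, csq = fields
                try:
                    records.append(
                        MutationRecord(sample_id, acc, int(pos), ref_aa, alt_aa, csq)
                    )
                except (ValueError, TypeError):
                    n_skipped += 1
    if n_skipped:
        warnings.warn(f"{n_skipped} unparsable VCF annotation(s) skipped", stacklevel=3)
    return records


def filter_nonsynonymous(
    records: Iterable[MutationRecord],
) -> tuple[list[MutationRecord], dict[str, int]]:
    """Keep missense substitutions only.

    Synonymous changes carry no amino-acid consequence; stop-gain and
    stop-loss truncate or extend the protein rather than perturbing a motif,
    so all three classes are dropped.  Returns the retained records and a
    per-class tally of dropped ones.
    """
    kept: list[MutationRecord] = []
    dropped: dict[str, int] = {}
    for rec in records:
        if rec.consequence == "missense":
            kept.append(rec)
        else:
            dropped[rec.consequence] = dropped.get(rec.consequence, 0) + 1
    return kept, dropped


def count_by_position(
    partition: RegionPartition,
    records: Iterable[MutationRecord],
) -> CountVector:
    """Tally retained mutations per residue position into a CountVector.

    Counts are cohort totals: every record increments its position once, so
    a residue mutated in m samples contributes m.  Records on other
    accessions or beyond the protein length are dropped with a warning.
    """
    counts: dict[int, int] = {}
    n_dropped = 0
    for rec in records:
        if rec.accession != partition.accession or rec.position > partition.n:
            n_dropped += 1
            continue
        counts[rec.position] = counts.get(rec.position, 0) + 1
    if n_dropped:
        warnings.warn(
            f"{n_dropped} mutation(s) off-protein for {partition.accession}; dropped",
            stacklevel=2,
        )
    mod = tuple(counts.get(p, 0) for p in partition.mod_positions)
    bg = tuple(counts.get(p, 0) for p in partition.bg_positions)
    return CountVector(partition=partition, mod_counts=mod, bg_counts=bg)


def group_by_accession(
    records: Iterable[MutationRecord],
) -> dict[str, list[MutationRecord]]:
    """Bucket mutation records by protein accession."""
    grouped: dict[str, list[MutationRecord]] = {}
    for rec in records:
        grouped.setdefault(rec.accession, []).append(rec)
    return grouped
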