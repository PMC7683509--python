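"""PTM-site catalogs, protein lengths, and region partitioning.

A modification region is the union, per protein and PTM type, of closed
windows of ``window`` residues on either side of each known site (so an
interior site contributes ``2 * window + 1`` residues); everything else is
background.  Positions are 1-based protein coordinates throughout.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 7

REQUIRED_SITE_COLUMNS = ("accession", "position", "ptm_type")


@dataclass(frozen=True)
class PTMSite:
    """One experimentally known modification site on a protein."""

    accession: str
    position: int  # 1-based residue index
    ptm_type: str
    residue: str | None = None
    evidence: str | None = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"site position must be >= 1, got {self.position}")
        if not self.ptm_type:
            raise ValueError("ptm_type must be non-empty")


@dataclass(frozen=True)
class ProteinInfo:
    """Protein identifier with its residue count and optional sequence."""

    accession: str
    length: int
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"protein length must be >= 1, got {self.length}")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"sequence length {len(self.sequence)} != declared length {self.length}"
            )


@dataclass(frozen=True)
class RegionPartition:
    """Split of a protein's positions into modification region and background.

    ``mod_positions`` (size k) and ``bg_positions`` (size n - k) are disjoint,
    sorted tuples covering 1..n exactly.
    """

    accession: str
    ptm_type: str
    mod_positions: tuple[int, ...]
    bg_positions: tuple[int, ...]
    window: int = DEFAULT_WINDOW
    length: int = field(default=0)

    def __post_init__(self) -> None:
        n = self.length or (len(self.mod_positions) + len(self.bg_positions))
        object.__setattr__(self, "length", n)
        mod, bg = set(self.mod_positions), set(self.bg_positions)
        if mod & bg:
            raise ValueError("modification and background regions overlap")
        if len(mod) + len(bg) != n:
            raise ValueError("regions do not cover the protein exactly")
        all_pos = mod | bg
        if all_pos and (min(all_pos) < 1 or max(all_pos) > n):
            raise ValueError("positions outside [1, n]")

    @property
    def k(self) -> int:
        return len(self.mod_positions)

    @property
    def n(self) -> int:
        return self.length

    @property
    def has_background(self) -> bool:
        return len(self.bg_positions) > 0

    def contains(self, position: int) -> bool:
        """True if ``position`` lies in the modification region."""
        return position in self._mod_set

    @property
    def _mod_set(self) -> frozenset[int]:
        cached = getattr(self, "_mod_set_cache", None)
        if cached is None:
            cached = frozenset(self.mod_positions)
            object.__setattr__(self, "_mod_set_cache", cached)
        return cached


def load_ptm_sites(
    path: str | Path,
    ptm_type_filter: str | None = None,
) -> list[PTMSite]:
    """Read a PTM-site catalog TSV into deduplicated :class:`PTMSite` records.

    The file must be UTF-8 TSV with a header carrying at least the columns
    ``accession``, ``position`` and ``ptm_type``; ``residue`` and ``evidence``
    are optional.  Rows are deduplicated on (accession, position, ptm_type);
    rows with a non-integer or sub-1 position are rejected with a warning.

    Parameters
    ----------
    path
        Catalog TSV path.
    ptm_type_filter
        If given, only sites of this PTM type are returned (exact match).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in REQUIRED_SITE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"PTM catalog {path} missing required columns: {missing}")

    pos = pd.to_numeric(df["position"], errors="coerce")
    bad = pos.isna() | (pos < 1) | (pos != pos.round())
    n_bad = int(bad.sum())
    if n_bad:
        warnings.warn(
            f"{n_bad} catalog row(s) rejected for malformed position in {path.name}",
            stacklevel=2,
        )
    df = df.loc[~bad].copy()
    df["position"] = pos.loc[~bad].astype(int)

    if ptm_type_filter is not None:
        df = df[df["ptm_type"] == ptm_type_filter]

    df = df.drop_duplicates(subset=["accession", "position", "ptm_type"])

    sites = [
        PTMSite(
            accession=row.accession,
            position=int(row.position),
            ptm_type=row.ptm_type,
            residue=getattr(row, "residue", None),
            evidence=getattr(row, "evidence", None),
        )
        for row in df.itertuples(index=False)
    ]
    logger.info("loaded %d PTM sites from %s (%d rejected)", len(sites), path, n_bad)
    return sites


def load_protein_lengths(
    path: str | Path,
    format: str = "fasta",
) -> dict[str, ProteinInfo]:
    """Build an accession -> :class:`ProteinInfo` map from FASTA or TSV.

    For FASTA the accession is the first whitespace-delimited token of the
    header and length is the residue count; for TSV the file has two columns
    ``accession`` and ``length`` (header optional column names enforced).
    Duplicate accessions keep the first occurrence with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    proteins: dict[str, ProteinInfo] = {}
    n_dup = 0

    if format == "fasta":
        for rec in SeqIO.parse(str(path), "fasta"):
            seq = str(rec.seq)
            if not seq:
                warnings.warn(f"empty FASTA record {rec.id} rejected", stacklevel=2)
                continue
            if rec.id in proteins:
                n_dup += 1
                continue
            proteins[rec.id] = ProteinInfo(rec.id, len(seq), sequence=seq)
    elif format == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if not {"accession", "length"}.issubset(df.columns):
            raise ValueError(f"lengths TSV {path} needs columns accession, length")
        for row in df.itertuples(index=False):
            acc = row.accession
            if acc in proteins:
                n_dup += 1
                continue
            proteins[acc] = ProteinInfo(acc, int(row.length))
    else:
        raise ValueError(f"unknown proteome format {format!r}; use 'fasta' or 'tsv'")

    if not proteins:
        raise ValueError(f"no usable protein records in {path}")
    if n_dup:
        warnings.warn(
            f"{n_dup} duplicate accession(s) in {path.name}; first occurrence kept",
            stacklevel=2,
        )
    return proteins


def check_site_residues(
    proteins: Mapping[str, ProteinInfo], sites: Iterable[PTMSite]
) -> int:
    """Warn for sites whose annotated residue disagrees with the sequence.

    Sites are kept regardless; returns the number of mismatches found.
    Catalog curation against the exact proteome build is the caller's job.
    """
    n_mismatch = 0
    for site in sites:
        info = proteins.get(site.accession)
        if info is None or info.sequence is None or not site.residue:
            continue
        if site.position <= info.length:
            actual = info.sequence[site.position - 1]
            if actual.upper() != site.residue.upper():
                n_mismatch += 1
    if n_mismatch:
        warnings.warn(
            f"{n_mismatch} site(s) disagree with the FASTA residue; kept",
            stacklevel=2,
        )
    return n_mismatch


def build_partition(
    protein: ProteinInfo,
    sites: Iterable[PTMSite],
    window: int = DEFAULT_WINDOW,
) -> RegionPartition:
    """Partition a protein into a merged modification region and background.

    Each site at position p contributes the closed residue interval
    [max(1, p - window), min(n, p + window)]; same-type intervals are merged
    by union.  Sites must all share one accession and one PTM type.

    Raises
    ------
    ValueError
        If the site collection is empty, mixes accessions or PTM types, or
        contains a position beyond the protein length.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    sites = list(sites)
    if not sites:
        raise ValueError(f"no PTM sites for {protein.accession}: protein not testable")
    accessions = {s.accession for s in sites}
    ptm_types = {s.ptm_type for s in sites}
    if accessions != {protein.accession}:
        raise ValueError(f"sites span accessions {accessions}, expected {protein.accession}")
    if len(ptm_types) != 1:
        raise ValueError(f"sites mix PTM types {ptm_types}; partition one type at a time")

    n = protein.length
    mod: set[int] = set()
    for site in sites:
        if site.position > n:
            raise ValueError(
                f"site {protein.accession}:{site.position} exceeds protein length {n}"
            )
        mod.update(range(max(1, site.position - window), min(n, site.position + window) + 1))

    bg = [p for p in range(1, n + 1) if p not in mod]
    return RegionPartition(
        accession=protein.accession,
        ptm_type=ptm_types.pop(),
        mod_positions=tuple(sorted(mod)),
        bg_positions=tuple(bg),
        window=window,
        length=n,
    )


def build_partitions(
    proteins: Mapping[str, ProteinInfo],
    sites: Iterable[PTMSite],
    ptm_type: str,
    window: int = DEFAULT_WINDOW,
) -> tuple[dict[str, RegionPartition], dict[str, str]]:
    """Partition every protein that has sites of ``ptm_type``.

    Returns (partitions keyed by accession, skipped accessions -> reason).
    Proteins whose modification region swallows the whole sequence are kept
    here but flagged untestable downstream; proteins with a site beyond the
    declared length are skipped with a reason.
    """
    by_acc: dict[str, list[PTMSite]] = {}
    for s in sites:
        if s.ptm_type == ptm_type:
            by_acc.setdefault(s.accession, []).append(s)

    partitions: dict[str, RegionPartition] = {}
    skipped: dict[str, str] = {}
    for acc, acc_sites in sorted(by_acc.items()):
        info = proteins.get(acc)
        if info is None:
            skipped[acc] = "accession absent from proteome"
            continue
        try:
            partitions[acc] = build_partition(info, acc_sites, window=window)
        except ValueError as exc:
            skipped[acc] = str(exc)
    return partitions, skipped
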