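"""Per-mutation annotation: region membership, nearest site, pathogenicity tally.

The pathogenicity score of a mutation is the number of deleterious calls it
receives from seven functional predictors (SIFT, LRT, MutationTaster,
MutationAssessor, FATHMM, MetaSVM, MetaLR), read from a pre-computed table;
missing calls count as non-deleterious, so the score runs 0-7.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from ptmburden.catalog import PTMSite, RegionPartition
from ptmburden.mutations import MutationRecord

PREDICTORS = (
    "SIFT",
    "LRT",
    "MutationTaster",
    "MutationAssessor",
    "FATHMM",
    "MetaSVM",
    "MetaLR",
)

CALL_VALUES = ("deleterious", "tolerated", "missing")


@dataclass(frozen=True)
class PredictorCallRow:
    """Predictor verdicts for one amino-acid change.

    ``calls`` maps predictor name -> deleterious | tolerated | missing, with
    names restricted to the seven-predictor panel.
    """

    accession: str
    position: int
    ref_aa: str
    alt_aa: str
    calls: Mapping[str, str]

    def __post_init__(self) -> None:
        unknown = set(self.calls) - set(PREDICTORS)
        if unknown:
            raise ValueError(
                f"unknown predictor(s) {sorted(unknown)}; allowed: {list(PREDICTORS)}"
            )
        bad = {v for v in self.calls.values() if v not in CALL_VALUES}
        if bad:
            raise ValueError(f"unknown call value(s) {sorted(bad)}; allowed: {CALL_VALUES}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.accession, self.position, self.ref_aa, self.alt_aa)


@dataclass(frozen=True)
class AnnotatedMutation:
    """A retained mutation tagged with motif-region context and score."""

    record: MutationRecord
    in_mod_region: bool
    nearest_site_position: int | None
    nearest_site_ptm_type: str | None
    distance_to_site: int | None
    pathogenicity_score: int | None = None


def pathogenicity_score(row: PredictorCallRow) -> int:
    """Count deleterious predictor calls (0-7); missing calls contribute 0."""
    return sum(1 for v in row.calls.values() if v == "deleterious")


def load_predictor_table(path: str | Path) -> dict[tuple[str, int, str, str], PredictorCallRow]:
    """Read a predictor-call TSV keyed by (accession, position, ref_aa, alt_aa).

    Columns: the four key columns plus any subset of the seven predictor
    names; cell values are deleterious/tolerated/missing (empty = missing).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    key_cols = ["accession", "position", "ref_aa", "alt_aa"]
    missing_cols = [c for c in key_cols if c not in df.columns]
    if missing_cols:
        raise ValueError(f"predictor table missing key columns: {missing_cols}")
    pred_cols = [c for c in df.columns if c in PREDICTORS]
    table: dict[tuple[str, int, str, str], PredictorCallRow] = {}
    for rec in df.itertuples(index=False):
        d = rec._asdict()
        calls = {
            c: (d[c] if isinstance(d[c], str) and d[c] else "missing") for c in pred_cols
        }
        row = PredictorCallRow(
            accession=d["accession"],
            position=int(d["position"]),
            ref_aa=d["ref_aa"],
            alt_aa=d["alt_aa"],
            calls=calls,
        )
        table[row.key] = row
    return table


def _nearest_site(position: int, sites: list[PTMSite]) -> tuple[int, str, int] | None:
    """Closest same-type site; equidistant ties go to the lower position."""
    best: tuple[int, int] | None = None  # (distance, site index)
    for i, site in enumerate(sorted(sites, key=lambda s: s.position)):
        d = abs(site.position - position)
        if best is None or d < best[0]:
            best = (d, i)
    if best is None:
        return None
    site = sorted(sites, key=lambda s: s.position)[best[1]]
    return site.position, site.ptm_type, best[0]


def annotate_mutations(
    records: Iterable[MutationRecord],
    partitions: Mapping[str, RegionPartition],
    sites: Iterable[PTMSite],
    predictor_table: Mapping[tuple[str, int, str, str], PredictorCallRow] | None = None,
) -> list[AnnotatedMutation]:
    """Tag consequence-filtered mutations with motif context and scores.

    Every record gets region membership against its protein's partition, the
    nearest same-type site with residue distance, and — when a predictor
    table is supplied — the 0-7 deleteriousness tally.  Records without a
    partition (protein not in this run) are annotated with no region context.
    """
    sites_by_acc: dict[str, list[PTMSite]] = {}
    for s in sites:
        sites_by_acc.setdefault(s.accession, []).append(s)

    n_unmatched = 0
    out: list[AnnotatedMutation] = []
    for rec in records:
        partition = partitions.get(rec.accession)
        in_region = partition.contains(rec.position) if partition else False
        ptm_type = partition.ptm_type if partition else None
        acc_sites = [
            s
            for s in sites_by_acc.get(rec.accession, [])
            if ptm_type is None or s.ptm_type == ptm_type
        ]
        nearest = _nearest_site(rec.position, acc_sites)
        score: int | None = None
        if predictor_table is not None:
            key = (rec.accession, rec.position, rec.ref_aa, rec.alt_aa)
            row = predictor_table.get(key)
            if row is None:
                n_unmatched += 1
            else:
                score = pathogenicity_score(row)
        out.append(
            AnnotatedMutation(
                record=rec,
                in_mod_region=in_region,
                nearest_site_position=nearest[0] if nearest else None,
                nearest_site_ptm_type=nearest[1] if nearest else None,
                distance_to_site=nearest[2] if nearest else None,
                pathogenicity_score=score,
            )
        )
    if predictor_table is not None and n_unmatched:
        warnings.warn(
            f"{n_unmatched} mutation(s) had no predictor-table row", stacklevel=2
        )
    return out


def annotations_to_frame(annotated: Iterable[AnnotatedMutation]) -> pd.DataFrame:
    """Flatten annotated mutations into a report DataFrame."""
    rows = []
    for a in annotated:
        rows.append(
            {
                "sample_id": a.record.sample_id,
                "accession": a.record.accession,
                "position": a.record.position,
                "ref_aa": a.record.ref_aa,
                "alt_aa": a.record.alt_aa,
                "consequence": a.record.consequence,
                "in_mod_region": a.in_mod_region,
                "nearest_site_position": a.nearest_site_position,
                "nearest_site_ptm_type": a.nearest_site_ptm_type,
                "distance_to_site": a.distance_to_site,
                "pathogenicity_score": a.pathogenicity_score,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "accession",
            "position",
            "ref_aa",
            "alt_aa",
            "consequence",
            "in_mod_region",
            "nearest_site_position",
            "nearest_site_ptm_type",
            "distance_to_site",
            "pathogenicity_score",
        ],
    )
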