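"""Truth-labelled synthetic cohorts drawn from the Poisson-Gamma model itself.

Each simulated protein carries a few PTM sites; per-position cohort-summed
mutation counts are drawn Poisson(lambda_2) in the background and
Poisson(R_true * lambda_2) in the modification region, then expanded into
per-sample mutation rows.  Files are emitted in exactly the TSV dialects the
loaders consume, so end-to-end runs need no glue.  The generator is
sequence-agnostic: amino-acid letters are uniform draws and there is no
mutational-signature, codon or covariate structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ptmburden.catalog import DEFAULT_WINDOW, ProteinInfo, build_partition
from ptmburden.model import ProteinTestResult

AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class SimConfig:
    """Generative settings for one synthetic cohort.

    ``bg_rate`` is the expected cohort-summed count per background position
    (lambda_2); driver proteins multiply it by ``enrichment_ratio`` inside
    their modification regions.
    """

    n_proteins: int = 200
    protein_length: int | tuple[int, int] = 400
    sites_per_protein: int = 3
    window: int = DEFAULT_WINDOW
    cohort_size: int = 100
    bg_rate: float = 0.1
    enrichment_ratio: float = 5.0
    fraction_drivers: float = 0.1
    ptm_type: str = "Phosphorylation"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bg_rate <= 0:
            raise ValueError("bg_rate must be positive")
        if not 0 <= self.fraction_drivers <= 1:
            raise ValueError("fraction_drivers must lie in [0, 1]")
        if self.fraction_drivers > 0 and self.enrichment_ratio < 1:
            raise ValueError("enrichment_ratio must be >= 1 for designated drivers")
        if self.n_proteins < 1 or self.sites_per_protein < 1 or self.cohort_size < 1:
            raise ValueError("n_proteins, sites_per_protein, cohort_size must be >= 1")


@dataclass(frozen=True)
class SimTruth:
    """Ground truth for one simulated cohort."""

    accessions: tuple[str, ...]
    r_true: Mapping[str, float]
    is_driver: Mapping[str, bool]
    mod_counts: Mapping[str, int]  # realized region totals
    bg_counts: Mapping[str, int]
    k: Mapping[str, int] | None = None  # modification-region sizes
    n: Mapping[str, int] | None = None  # protein lengths

    @property
    def drivers(self) -> list[str]:
        return [a for a in self.accessions if self.is_driver[a]]

    @property
    def nulls(self) -> list[str]:
        return [a for a in self.accessions if not self.is_driver[a]]


def _protein_length(config: SimConfig, rng: np.random.Generator) -> int:
    if isinstance(config.protein_length, tuple):
        lo, hi = config.protein_length
        return int(rng.integers(lo, hi + 1))
    return int(config.protein_length)


def simulate_cohort(
    config: SimConfig,
    out_dir: str | Path,
) -> tuple[Path, Path, Path, SimTruth]:
    """Generate a cohort and write catalog/proteome/mutation TSVs.

    Returns (ptm_sites.tsv, proteome.tsv, mutations.tsv, truth).  Outputs are
    byte-identical across runs with the same config and seed.
    """
    rng = np.random.default_rng(config.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    n_drivers = int(round(config.fraction_drivers * config.n_proteins))
    driver_idx = set(rng.permutation(config.n_proteins)[:n_drivers].tolist())

    site_rows: list[dict] = []
    mut_rows: list[dict] = []
    prot_rows: list[dict] = []
    r_true: dict[str, float] = {}
    is_driver: dict[str, bool] = {}
    mod_totals: dict[str, int] = {}
    bg_totals: dict[str, int] = {}
    ks: dict[str, int] = {}
    ns: dict[str, int] = {}
    accessions: list[str] = []

    for i in range(config.n_proteins):
        acc = f"SIM{i:05d}"
        accessions.append(acc)
        length = _protein_length(config, rng)
        n_sites = min(config.sites_per_protein, length)
        positions = np.sort(rng.choice(length, size=n_sites, replace=False) + 1)
        prot_rows.append({"accession": acc, "length": length})
        for p in positions:
            site_rows.append(
                {
                    "accession": acc,
                    "position": int(p),
                    "residue": "S",
                    "ptm_type": config.ptm_type,
                    "evidence": "simulated",
                }
            )

        driver = i in driver_idx
        ratio = config.enrichment_ratio if driver else 1.0
        r_true[acc] = ratio
        is_driver[acc] = driver

        info = ProteinInfo(acc, length)
        from ptmburden.catalog import PTMSite  # local import avoids cycle at module load

        sites = [PTMSite(acc, int(p), config.ptm_type) for p in positions]
        partition = build_partition(info, sites, window=config.window)

        mod_counts = rng.poisson(ratio * config.bg_rate, size=partition.k)
        bg_counts = rng.poisson(config.bg_rate, size=partition.n - partition.k)
        mod_totals[acc] = int(mod_counts.sum())
        bg_totals[acc] = int(bg_counts.sum())
        ks[acc] = partition.k
        ns[acc] = partition.n

        for pos, count in zip(partition.mod_positions, mod_counts):
            _expand_rows(mut_rows, acc, pos, int(count), config, rng)
        for pos, count in zip(partition.bg_positions, bg_counts):
            _expand_rows(mut_rows, acc, pos, int(count), config, rng)

    sites_path = out_dir / "ptm_sites.tsv"
    proteome_path = out_dir / "proteome.tsv"
    mutations_path = out_dir / "mutations.tsv"
    pd.DataFrame(site_rows).to_csv(sites_path, sep="\t", index=False)
    pd.DataFrame(prot_rows).to_csv(proteome_path, sep="\t", index=False)
    pd.DataFrame(
        mut_rows,
        columns=["sample_id", "accession", "position", "ref_aa", "alt_aa", "consequence"],
    ).to_csv(mutations_path, sep="\t", index=False)

    truth = SimTruth(
        accessions=tuple(accessions),
        r_true=r_true,
        is_driver=is_driver,
        mod_counts=mod_totals,
        bg_counts=bg_totals,
        k=ks,
        n=ns,
    )
    truth_df = pd.DataFrame(
        {
            "accession": accessions,
            "r_true": [r_true[a] for a in accessions],
            "is_driver": [is_driver[a] for a in accessions],
            "mod_count": [mod_totals[a] for a in accessions],
            "bg_count": [bg_totals[a] for a in accessions],
            "k": [ks[a] for a in accessions],
            "n": [ns[a] for a in accessions],
        }
    )
    truth_df.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    return sites_path, proteome_path, mutations_path, truth


def _expand_rows(
    rows: list[dict],
    accession: str,
    position: int,
    count: int,
    config: SimConfig,
    rng: np.random.Generator,
) -> None:
    """Turn a per-position count into that many per-sample missense rows."""
    for _ in range(count):
        sample = int(rng.integers(config.cohort_size))
        ref, alt = rng.choice(len(AMINO_ACIDS), size=2, replace=False)
        rows.append(
            {
                "sample_id": f"S{sample:04d}",
                "accession": accession,
                "position": position,
                "ref_aa": AMINO_ACIDS[ref],
                "alt_aa": AMINO_ACIDS[alt],
                "consequence": "missense",
            }
        )


@dataclass(frozen=True)
class RunMetrics:
    """Error/power summary of one inference run against simulation truth."""

    n_null: int
    n_driver: int
    type_i_error: float  # fraction of null proteins with p < alpha
    power: float  # fraction of true drivers with q < q_threshold; nan if none
    realized_fdr: float  # nulls among q < q_threshold calls; 0 if no calls
    n_called: int
    alpha: float = 0.05
    q_threshold: float = 0.05


def evaluate_run(
    truth: SimTruth,
    results: Sequence[ProteinTestResult],
    alpha: float = 0.05,
    q_threshold: float = 0.05,
) -> RunMetrics:
    """Score inference results against simulation ground truth.

    Raises on empty results or on accessions unknown to the truth record;
    proteins the pipeline skipped (e.g. no background) simply do not
    contribute.
    """
    if not results:
        raise ValueError("no results to evaluate")
    unknown = {r.accession for r in results} - set(truth.accessions)
    if unknown:
        raise ValueError(f"results contain accessions absent from truth: {sorted(unknown)[:5]}")

    nulls = [r for r in results if not truth.is_driver[r.accession]]
    drivers = [r for r in results if truth.is_driver[r.accession]]

    type_i = (
        float(np.mean([r.p_value < alpha for r in nulls])) if nulls else float("nan")
    )
    power = (
        float(np.mean([(r.q_value is not None and r.q_value < q_threshold) for r in drivers]))
        if drivers
        else float("nan")
    )
    called = [r for r in results if r.q_value is not None and r.q_value < q_threshold]
    fdr = (
        float(np.mean([not truth.is_driver[r.accession] for r in called]))
        if called
        else 0.0
    )
    return RunMetrics(
        n_null=len(nulls),
        n_driver=len(drivers),
        type_i_error=type_i,
        power=power,
        realized_fdr=fdr,
        n_called=len(called),
        alpha=alpha,
        q_threshold=q_threshold,
    )
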