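"""End-to-end orchestration: catalog + mutations -> tests -> BH -> reports.

One run covers one cohort and one PTM type.  Outputs written to the run
directory: ``results.tsv`` (one row per testable protein), ``annotated_
mutations.tsv``, ``skipped_proteins.tsv`` (untestable proteins with reasons)
and ``manifest.json`` (config echo plus record counts at every filter
stage).  Reruns with identical config and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ptmburden import annotation, catalog, model, mutations

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "accession",
    "ptm_type",
    "k",
    "n",
    "mod_mutations",
    "bg_mutations",
    "R_mean",
    "p_value",
    "q_value",
    "is_driver",
]


@dataclass(frozen=True)
class RunConfig:
    """Settings for one pipeline run (one cohort x one PTM type)."""

    mutations_path: str
    ptm_sites_path: str
    proteome_path: str
    ptm_type: str
    out_dir: str
    mutation_format: str = "tsv"
    proteome_format: str = "tsv"
    predictor_table_path: str | None = None
    window: int = catalog.DEFAULT_WINDOW
    iterations: int = model.DEFAULT_ITERATIONS
    burn_in: int = model.DEFAULT_BURN_IN
    q_threshold: float = 0.05
    prior_shape: float = model.DEFAULT_PRIOR_SHAPE
    prior_rate: float = model.DEFAULT_PRIOR_RATE
    seed: int = 0
    ann_key: str = mutations.DEFAULT_ANN_KEY
    genome_assembly: str | None = None  # recorded only; no coordinate work here

    def __post_init__(self) -> None:
        if not self.iterations > self.burn_in >= 0:
            raise ValueError("need iterations > burn_in >= 0")
        if not 0 < self.q_threshold <= 1:
            raise ValueError("q_threshold must lie in (0, 1]")


@dataclass
class RunSummary:
    """What a pipeline run produced, with per-stage record counts."""

    results_path: Path
    annotated_path: Path
    skipped_path: Path
    manifest_path: Path
    n_tested: int
    n_drivers: int
    counts: dict[str, int] = field(default_factory=dict)


def run_pipeline(config: RunConfig) -> RunSummary:
    """Execute the full enrichment analysis for one run configuration.

    On any stage failure the partially written outputs are removed and the
    error re-raised with the stage name.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs = {
        "results": out_dir / "results.tsv",
        "annotated": out_dir / "annotated_mutations.tsv",
        "skipped": out_dir / "skipped_proteins.tsv",
        "manifest": out_dir / "manifest.json",
    }
    try:
        return _run(config, outputs)
    except Exception as exc:
        for p in outputs.values():
            p.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline failed: {exc}") from exc


def _run(config: RunConfig, outputs: dict[str, Path]) -> RunSummary:
    stage = "load proteome"
    proteins = catalog.load_protein_lengths(
        config.proteome_path, format=config.proteome_format
    )
    stage = "load PTM catalog"
    sites = catalog.load_ptm_sites(config.ptm_sites_path, ptm_type_filter=config.ptm_type)
    catalog.check_site_residues(proteins, sites)
    stage = "load mutations"
    all_records = mutations.load_mutations(
        config.mutations_path, format=config.mutation_format, ann_key=config.ann_key
    )
    logger.info("[%s] %d mutation records", stage, len(all_records))

    stage = "consequence filter"
    nonsyn, dropped_by_class = mutations.filter_nonsynonymous(all_records)

    stage = "proteome mapping"
    mapped = [r for r in nonsyn if r.accession in proteins]
    unmapped_tally: dict[str, int] = {}
    for r in nonsyn:
        if r.accession not in proteins:
            unmapped_tally[r.accession] = unmapped_tally.get(r.accession, 0) + 1

    stage = "region partitioning"
    partitions, skipped = catalog.build_partitions(
        proteins, sites, config.ptm_type, window=config.window
    )

    stage = "enrichment testing"
    prior_mod = model.GammaPrior(config.prior_shape, config.prior_rate)
    prior_bg = model.GammaPrior(config.prior_shape, config.prior_rate)
    grouped = mutations.group_by_accession(mapped)
    accessions = sorted(partitions)
    child_seeds = np.random.SeedSequence(config.seed).generate_state(
        max(len(accessions), 1)
    )
    results: list[model.ProteinTestResult] = []
    for acc, child_seed in zip(accessions, child_seeds):
        partition = partitions[acc]
        if not partition.has_background:
            skipped[acc] = "no background (motif regions cover whole protein)"
            continue
        counts = mutations.count_by_position(partition, grouped.get(acc, []))
        settings = model.MCSettings(
            iterations=config.iterations, burn_in=config.burn_in, seed=int(child_seed)
        )
        results.append(
            model.test_protein(partition, counts, prior_mod, prior_bg, settings)
        )

    stage = "multiple-testing correction"
    results = model.call_drivers(results, q_threshold=config.q_threshold)

    stage = "annotation"
    tested_accs = {r.accession for r in results}
    predictor_table = None
    if config.predictor_table_path:
        predictor_table = annotation.load_predictor_table(config.predictor_table_path)
    annotated = annotation.annotate_mutations(
        [r for r in mapped if r.accession in tested_accs],
        partitions,
        sites,
        predictor_table,
    )

    stage = "reporting"
    results_df = pd.DataFrame(
        [
            {
                "accession": r.accession,
                "ptm_type": r.ptm_type,
                "k": r.k,
                "n": r.n,
                "mod_mutations": r.mod_total,
                "bg_mutations": r.bg_total,
                "R_mean": r.posterior_R_mean,
                "p_value": r.p_value,
                "q_value": r.q_value,
                "is_driver": r.is_driver,
            }
            for r in results
        ],
        columns=RESULT_COLUMNS,
    )
    results_df.to_csv(outputs["results"], sep="\t", index=False, float_format="%.6g")

    annotation.annotations_to_frame(annotated).to_csv(
        outputs["annotated"], sep="\t", index=False
    )

    pd.DataFrame(
        sorted(skipped.items()), columns=["accession", "reason"]
    ).to_csv(outputs["skipped"], sep="\t", index=False)

    counts_summary = {
        "input_mutations": len(all_records),
        "dropped_by_consequence": int(sum(dropped_by_class.values())),
        "dropped_unmapped": len(nonsyn) - len(mapped),
        "retained_mutations": len(mapped),
        "proteins_with_sites": len(partitions),
        "proteins_tested": len(results),
        "proteins_skipped": len(skipped),
        "drivers_called": int(sum(bool(r.is_driver) for r in results)),
    }
    manifest = {
        "config": dataclasses.asdict(config),
        "counts": counts_summary,
        "dropped_by_consequence_class": dropped_by_class,
        "unmapped_accessions": dict(sorted(unmapped_tally.items())),
    }
    outputs["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    logger.info(
        "tested %d proteins, %d drivers at q < %g",
        len(results),
        counts_summary["drivers_called"],
        config.q_threshold,
    )
    return RunSummary(
        results_path=outputs["results"],
        annotated_path=outputs["annotated"],
        skipped_path=outputs["skipped"],
        manifest_path=outputs["manifest"],
        n_tested=len(results),
        n_drivers=counts_summary["drivers_called"],
        counts=counts_summary,
    )
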