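"""End-to-end orchestration: QC -> clustering -> discriminators.

Every stage communicates through files (filtered PLINK set, assignment TSV,
discriminator TSVs), so each stage can be re-run independently, and a rerun
with the same configuration reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import discriminators as disc
from . import qc as qc_mod
from .cluster import IPCAPSParams, ipcaps
from .io import (
    ClusterAssignmentTable,
    GenotypeDataset,
    read_plink,
    write_assignment,
    write_plink,
)

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "crosstab_report"]

logger = logging.getLogger("finestrat")


@dataclass
class PipelineConfig:
    """Inputs, outputs and per-stage parameters for one run."""

    bed_prefix: str
    out_dir: str
    qc: qc_mod.QCParams = field(default_factory=qc_mod.QCParams)
    clustering: IPCAPSParams = field(default_factory=IPCAPSParams)
    discriminators: disc.DiscriminatorParams = field(default_factory=disc.DiscriminatorParams)
    skip_qc: bool = False
    skip_clustering: bool = False
    skip_discriminators: bool = False
    permutation_p: bool = False

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        return cls(
            bed_prefix=raw["bed_prefix"],
            out_dir=raw["out_dir"],
            qc=qc_mod.QCParams(**raw.get("qc", {})),
            clustering=IPCAPSParams(**raw.get("clustering", {})),
            discriminators=disc.DiscriminatorParams(**raw.get("discriminators", {})),
            skip_qc=raw.get("skip_qc", False),
            skip_clustering=raw.get("skip_clustering", False),
            skip_discriminators=raw.get("skip_discriminators", False),
            permutation_p=raw.get("permutation_p", False),
        )


@dataclass
class RunReport:
    """Summary of one pipeline run (all counts recomputable from the logs)."""

    qc_report: pd.DataFrame | None
    group_sizes: dict[int, int]
    outlier_roster: list[str]
    discriminator_summary: pd.DataFrame | None
    crosstab: pd.DataFrame | None
    ari: float | None
    seeds: dict[str, int]

    def group_count(self) -> int:
        return len(self.group_sizes)


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute QC -> clustering -> discriminators, writing all artifacts.

    Any stage error aborts with the stage named in the exception; artifacts
    written by earlier stages are left in place.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    try:
        dataset = read_plink(config.bed_prefix)
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"stage 'input': {exc}") from exc
    logger.info("input: %d samples x %d SNPs", dataset.n_samples, dataset.n_variants)

    qc_frame = None
    if not config.skip_qc:
        try:
            dataset, report = qc_mod.run_qc(dataset, config.qc)
            qc_frame = report.to_frame()
            qc_frame.to_csv(out / "qc_report.tsv", sep="\t", index=False)
            write_plink(dataset, out / "filtered")
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"stage 'qc': {exc}") from exc
        logger.info("qc: %d samples x %d SNPs remain", dataset.n_samples, dataset.n_variants)
    else:
        dataset = qc_mod.impute_most_frequent(dataset)

    if config.skip_clustering:
        return RunReport(
            qc_report=qc_frame,
            group_sizes={},
            outlier_roster=[],
            discriminator_summary=None,
            crosstab=None,
            ari=None,
            seeds={"clustering": config.clustering.seed},
        )

    try:
        tree, assignment = ipcaps(dataset, config.clustering)
        write_assignment(assignment, out / "assignment.tsv")
        tree.to_json(out / "cluster_tree.json")
        _write_split_log(tree, out / "split_log.tsv")
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"stage 'clustering': {exc}") from exc
    sizes = {g.group_id: g.size for g in tree.groups}
    roster = [
        dataset.samples[i].individual_id for g in tree.outlier_groups for i in g.members
    ]
    logger.info("clustering: %d groups, %d outlier groups", len(tree.groups), len(tree.outlier_groups))

    summary = None
    if not config.skip_discriminators and len(tree.groups) >= 2:
        try:
            results = disc.all_pairs(
                dataset, assignment, config.discriminators, with_permutation_p=config.permutation_p
            )
            summary = pd.DataFrame(
                {
                    "group_i": [r.pair[0] for r in results],
                    "group_j": [r.pair[1] for r in results],
                    "set_size": [r.set_size for r in results],
                    "cutoff": [r.cutoff for r in results],
                    "max_permutation_p": [r.max_permutation_p for r in results],
                }
            )
            summary.to_csv(out / "discriminators_summary.tsv", sep="\t", index=False)
            for r in results:
                _write_snp_list(dataset, r, out / f"discriminators_{r.pair[0]}_{r.pair[1]}.tsv")
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"stage 'discriminators': {exc}") from exc

    crosstab = ari = None
    truth = dataset.population_labels()
    if any(t is not None for t in truth):
        crosstab, ari = crosstab_report(assignment, ["" if t is None else t for t in truth])
        crosstab.to_csv(out / "crosstab.tsv", sep="\t")

    report = RunReport(
        qc_report=qc_frame,
        group_sizes=sizes,
        outlier_roster=roster,
        discriminator_summary=summary,
        crosstab=crosstab,
        ari=ari,
        seeds={
            "clustering": config.clustering.seed,
            "discriminators": config.discriminators.seed,
        },
    )
    (out / "run_report.json").write_text(_report_json(report, config))
    return report


def _write_split_log(tree, path: Path) -> None:
    rows = []

    def walk(node):
        rows.append(
            {
                "path": node.path,
                "size": node.size,
                "status": node.status,
                "eigenfit": node.eigenfit_value,
                "split_method": node.split_method,
                "inter_child_fst": node.inter_child_fst,
                "group_id": node.group_id,
            }
        )
        for child in node.children:
            walk(child)

    walk(tree.root)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _write_snp_list(dataset: GenotypeDataset, result, path: Path) -> None:
    """Per-pair SNP list in a VEP-ready shape (chrom, pos, id, alleles)."""
    rows = [
        {
            "chromosome": dataset.variants[j].chromosome,
            "position": dataset.variants[j].position,
            "identifier": dataset.variants[j].identifier,
            "allele1": dataset.variants[j].allele1,
            "allele2": dataset.variants[j].allele2,
            "fst": float(v),
        }
        for j, v in zip(result.snp_indices, result.fst_values)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _report_json(report: RunReport, config: PipelineConfig) -> str:
    payload = {
        "config": {
            "bed_prefix": config.bed_prefix,
            "out_dir": config.out_dir,
            "qc": dataclasses.asdict(config.qc),
            "clustering": dataclasses.asdict(config.clustering),
            "discriminators": dataclasses.asdict(config.discriminators),
        },
        "group_sizes": {str(k): v for k, v in report.group_sizes.items()},
        "n_groups": report.group_count(),
        "outlier_roster": report.outlier_roster,
        "ari_vs_truth_labels": report.ari,
        "seeds": report.seeds,
    }
    return json.dumps(payload, indent=2)


def crosstab_report(
    assignment: ClusterAssignmentTable, truth_labels: list[str]
) -> tuple[pd.DataFrame, float]:
    """Contingency table of inferred groups vs. truth labels, plus ARI.

    The adjusted Rand index is computed over all samples (outliers
    included); the table adds a per-group majority label column.
    """
    groups = assignment.groups
    if len(truth_labels) != len(groups):
        raise ValueError("one truth label per sample required")
    table = pd.crosstab(
        pd.Series(groups, name="group"), pd.Series(truth_labels, name="truth")
    )
    ari = float(adjusted_rand_score(truth_labels, groups))
    table["majority_label"] = table.idxmax(axis=1)
    return table, ari
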