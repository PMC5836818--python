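"""End-to-end orchestration: ingest -> label -> search -> permutation -> report.

A run is driven by a single config (YAML/JSON file or :class:`RunConfig`),
writes every machine-readable output into one run directory, and finishes with
a manifest recording the resolved config, seed and package version, so a rerun
with the same config and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .cohorts import cohort_summary, label_cohort, read_clinical
from .evaluation import FILTER_AUC_THRESHOLD, TRAIN_AUC_THRESHOLD
from .io import (
    collapse_probes,
    concat_cohorts,
    check_cohort_medians,
    filter_low_expression,
    read_expression,
    read_probe_table,
)
from .metaset import MetaSet
from .permutation import permutation_test
from .subsets import SearchConfig, run_search, report_frame

__all__ = ["RunConfig", "run_pipeline", "load_run_config", "build_meta_from_files"]

logger = logging.getLogger("prognoset")


@dataclass
class RunConfig:
    # cohort -> {"expression": path, "clinical": path, optional "dialect"}
    cohorts: dict[str, dict[str, str]]
    training: str
    filtration: list[str]
    testing: str
    gene_family: list[str]
    probe_annotation: str | None = None  # enables probe -> gene collapse
    expression_percentile: float = 0.95
    expression_threshold: float = 7.0
    train_threshold: float = TRAIN_AUC_THRESHOLD
    filter_threshold: float = FILTER_AUC_THRESHOLD
    cost: float = 1.0
    subset_sizes: list[int] = field(default_factory=lambda: [1, 2, 3])
    include_full: bool = True
    n_permutations: int = 10_000
    permute_top: int = 1  # run the permutation test on this many top survivors
    seed: int = 0
    out_dir: str = "run"

    def validate(self) -> None:
        roles = [self.training, *self.filtration, self.testing]
        if len(set(roles)) != len(roles):
            raise ValueError("training/filtration/testing cohorts must be distinct")
        if not self.filtration:
            raise ValueError("at least one filtration cohort is required")
        missing = [c for c in roles if c not in self.cohorts]
        if missing:
            raise ValueError(f"role cohorts without data files: {missing}")
        for thr in (self.train_threshold, self.filter_threshold):
            if not 0.5 <= thr <= 1.0:
                raise ValueError(f"AUC threshold {thr} outside [0.5, 1]")
        if not self.gene_family:
            raise ValueError("gene_family must be non-empty")


def load_run_config(path: str | Path) -> RunConfig:
    doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    return RunConfig(**doc)


def build_meta_from_files(cfg: RunConfig) -> tuple[MetaSet, list[str]]:
    """Read, collapse, filter and label everything the run needs."""
    matrices = []
    labelings = {}
    for cohort, files in cfg.cohorts.items():
        m = read_expression(files["expression"], cohort,
                            dialect=files.get("dialect", "tsv"))
        matrices.append(m)
        labelings[cohort] = label_cohort(read_clinical(files["clinical"]))
    joint = concat_cohorts(matrices)
    if joint.level == "probe":
        if cfg.probe_annotation is None:
            raise ValueError("probe-level input requires probe_annotation")
        joint = collapse_probes(joint, read_probe_table(cfg.probe_annotation))
    check_cohort_medians(joint)
    joint, removed = filter_low_expression(
        joint, cfg.expression_percentile, cfg.expression_threshold
    )
    meta = MetaSet(expression=joint, labelings=labelings, training=cfg.training,
                   filtration=list(cfg.filtration), testing=cfg.testing)
    return meta, removed


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(dataclasses.asdict(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the full analysis; returns the run directory.

    Outputs: ``cohort_summary.tsv`` (patient counts per cohort),
    ``removed_genes.txt``, ``subset_report.tsv`` (every subset with its AUCs,
    verdict and weights), ``classifier_top.json``, ``permutation_*.json`` and
    ``manifest.json``.  Any stage failure aborts with the stage name; the
    manifest then lists the outputs written so far.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[str] = []
    stage = "ingest"
    try:
        meta, removed = build_meta_from_files(cfg)

        stage = "cohort_summary"
        summary = cohort_summary(meta.labelings)
        summary.to_csv(out / "cohort_summary.tsv", sep="\t")
        written.append("cohort_summary.tsv")
        (out / "removed_genes.txt").write_text(
            "\n".join(removed) + ("\n" if removed else ""), encoding="utf-8")
        written.append("removed_genes.txt")

        stage = "search"
        family = [g for g in cfg.gene_family if g in set(meta.gene_ids)]
        dropped = sorted(set(cfg.gene_family) - set(family))
        if dropped:
            logger.info("family genes removed by expression filter: %s", dropped)
        sc = SearchConfig(
            genes=tuple(family), sizes=tuple(cfg.subset_sizes),
            include_full=cfg.include_full, cost=cfg.cost,
            train_threshold=cfg.train_threshold,
            filter_threshold=cfg.filter_threshold,
        )
        evals = run_search(meta, sc)
        report_frame(evals).to_csv(out / "subset_report.tsv", sep="\t", index=False)
        written.append("subset_report.tsv")
        survivors = [e for e in evals if e.passed]

        stage = "permutation"
        perm_files = []
        for rank, ev in enumerate(survivors[: cfg.permute_top], start=1):
            res = permutation_test(ev.gene_set, meta, n=cfg.n_permutations,
                                   seed=cfg.seed, config=sc)
            name = f"permutation_{rank:02d}_{'-'.join(ev.gene_set)}.json"
            (out / name).write_text(json.dumps(res.to_dict(), indent=2) + "\n",
                                    encoding="utf-8")
            written.append(name)
            perm_files.append(name)
        if survivors:
            survivors[0].classifier.to_json(out / "classifier_top.json")
            written.append("classifier_top.json")

        stage = "manifest"
        manifest = {
            "package_version": __version__,
            "config": dataclasses.asdict(cfg),
            "config_hash": _config_hash(cfg),
            "seed": cfg.seed,
            "n_subsets": len(evals),
            "n_survivors": len(survivors),
            "removed_genes": removed,
            "outputs": written,
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8")
        return out
    except Exception:
        (out / "manifest.partial.json").write_text(
            json.dumps({"failed_stage": stage, "outputs": written}, indent=2)
            + "\n", encoding="utf-8")
        logger.exception("pipeline failed at stage %s", stage)
        raise
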