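#!/usr/bin/env python
"""Exhaustive subset search: singletons, pairs, triples and the full family.

Reads the meta-set written by 01_generate_cohorts.py through the same file
ingestion path the CLI uses (TSV -> labeling -> low-expression filter), trains
a linear soft-margin SVM per gene subset on the training cohort, applies the
AUC filtration cascade (>= 0.6 training, >= 0.55 on each filtration cohort),
and evaluates survivors on the independent testing cohort.  Writes the full
ranked report and prints the headline ranking.
"""

from pathlib import Path

from prognoset.pipeline import RunConfig, build_meta_from_files
from prognoset.subsets import SearchConfig, report_frame, run_search

ROOT = Path(__file__).resolve().parent.parent
FAMILY = [f"FAM{i:02d}" for i in range(1, 11)]

def main() -> None:
    data = ROOT / "scratch" / "meta"
    if not data.exists():
        raise SystemExit("run analysis/01_generate_cohorts.py first")
    cfg = RunConfig(
        cohorts={
            c: {"expression": str(data / f"expression_{c}.tsv"),
                "clinical": str(data / f"clinical_{c}.tsv")}
            for c in ["TRAIN", "FILT1", "FILT2", "TEST"]
        },
        training="TRAIN", filtration=["FILT1", "FILT2"], testing="TEST",
        gene_family=FAMILY,
    )
    meta, removed = build_meta_from_files(cfg)
    evs = run_search(meta, SearchConfig(genes=tuple(FAMILY), sizes=(1, 2, 3),
                                        include_full=True))
    frame = report_frame(evs)
    out = ROOT / "results" / "subset_report.tsv"
    frame.to_csv(out, sep="\t", index=False)

    survivors = frame[frame["passed"]]
    print(f"{len(frame)} subsets evaluated, {len(survivors)} passed filtration")
    print("\ntop 10 by testing AUC:")
    cols = ["gene_set", "n_genes", "auc_train", "auc_test", "km_p"]
    print(survivors.head(10)[cols].to_string(index=False))
    failed = frame[~frame["passed"]]
    print(f"\nfailed subsets: {len(failed)} "
          f"(report with failing stage in {out.relative_to(ROOT)})")

if __name__ == "__main__":
    main()
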