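"""Classify each catalog enhancer's temporal activity window.

Builds the week x enhancer binary activity matrix (active = supported by
>= 2 samples that week) and labels every enhancer constant, week-specific,
continuous or non-continuous, then summarizes week-to-week turnover.
"""

import importlib
import json

paths = importlib.import_module("00_paths")

from faceenh.catalog import build_catalog, read_manifest
from faceenh.intervals import read_tss_table
from faceenh.temporal import build_activity_matrix, classify_all, week_transition_summary


def main():
    tracks = [t for t in read_manifest(paths.STUDY_DIR / "manifest.tsv")
              if t.assay == "H3K27ac"]
    tss = read_tss_table(paths.STUDY_DIR / "tss.tsv")
    catalog = build_catalog(tracks, tss)

    matrix = build_activity_matrix(catalog)
    classes = classify_all(matrix)
    paths.TABLES_DIR.mkdir(parents=True, exist_ok=True)
    classes.to_csv(paths.TABLES_DIR / "03_temporal_classes.tsv", sep="\t", index=False)

    counts = classes["temporal_class"].value_counts()
    n = len(classes)
    print(f"temporal classes over {n} enhancers:")
    for cname in ("constant", "week_specific", "continuous", "non_continuous"):
        k = int(counts.get(cname, 0))
        print(f"  {cname:>15}: {k:5d} ({k / n:.1%})")

    transitions = week_transition_summary(matrix)
    transitions.to_csv(paths.RESULTS_DIR / "03_week_transitions.tsv", sep="\t", index=False)
    print(transitions.to_string(index=False))

    (paths.RESULTS_DIR / "03_temporal_summary.json").write_text(json.dumps(
        {c: int(counts.get(c, 0)) for c in counts.index}, indent=1, sort_keys=True
    ))


if __name__ == "__main__":
    main()
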