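"""Map catalog enhancers to the target genome and classify conservation.

Each enhancer is lifted through the chain alignments (>= 95% of bases must
map within a single chain), checked for preserved flanking-gene context via
the orthology table, and called conserved_active when its mapped location
overlaps a target-species H3K27ac peak.
"""

import importlib
import json

import pandas as pd

paths = importlib.import_module("00_paths")

from faceenh.catalog import build_catalog, read_manifest
from faceenh.conservation import (
    classify_conservation, conservation_to_rows, read_chain_file, read_orthology_table,
)
from faceenh.intervals import read_bed, read_tss_table


def main():
    tracks = [t for t in read_manifest(paths.STUDY_DIR / "manifest.tsv")
              if t.assay == "H3K27ac"]
    tss = read_tss_table(paths.STUDY_DIR / "tss.tsv")
    catalog = build_catalog(tracks, tss)

    chains = read_chain_file(paths.STUDY_DIR / "study.chain")
    target_ann = read_tss_table(paths.STUDY_DIR / "target_tss.tsv")
    orth = read_orthology_table(paths.STUDY_DIR / "orthology.tsv")
    target_peaks = read_bed(paths.STUDY_DIR / "target_peaks.bed").sort()

    calls = classify_conservation(
        catalog.regions, catalog.ids, chains, tss, target_ann, orth, target_peaks,
    )
    paths.TABLES_DIR.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(conservation_to_rows(calls)).to_csv(
        paths.TABLES_DIR / "04_conservation.tsv", sep="\t", index=False
    )

    n = len(calls)
    counts = {s: sum(1 for c in calls if c.status == s)
              for s in ("conserved_active", "conserved_inactive", "not_alignable")}
    alignable = counts["conserved_active"] + counts["conserved_inactive"]
    print(f"of {n} enhancers: {alignable} ({alignable / n:.0%}) sequence-conserved")
    print(f"  functionally conserved (target peak): {counts['conserved_active']} "
          f"({counts['conserved_active'] / n:.0%})")
    print(f"  conserved but inactive in target:     {counts['conserved_inactive']} "
          f"({counts['conserved_inactive'] / n:.0%})")
    (paths.RESULTS_DIR / "04_conservation_summary.json").write_text(
        json.dumps(counts, indent=1, sort_keys=True)
    )


if __name__ == "__main__":
    main()
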