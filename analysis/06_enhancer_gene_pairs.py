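"""Associate enhancers with target genes and test signal:expression coupling.

Assigns targets through promoter-interaction fragments, TMM-normalizes the
enhancer signal matrix, computes Spearman's rho per predicted pair across
matched samples, and compares predicted pairs against all other
enhancer x gene combinations with a one-sided Mann-Whitney U test.
"""

import importlib
import json

import numpy as np
import pandas as pd

paths = importlib.import_module("00_paths")

from faceenh.catalog import build_catalog, read_manifest
from faceenh.intervals import read_tss_table
from faceenh.pairs import assign_targets, correlate_pairs, read_interactions
from faceenh.report import _pairs_with_signal_ids


def main():
    tracks = [t for t in read_manifest(paths.STUDY_DIR / "manifest.tsv")
              if t.assay == "H3K27ac"]
    tss = read_tss_table(paths.STUDY_DIR / "tss.tsv")
    catalog = build_catalog(tracks, tss)

    imap = read_interactions(paths.STUDY_DIR / "interactions.tsv")
    predicted = assign_targets(catalog, imap)
    signal = pd.read_csv(paths.STUDY_DIR / "signal.tsv", sep="\t", index_col=0)
    expression = pd.read_csv(paths.STUDY_DIR / "expression.tsv", sep="\t", index_col=0)

    pairs = _pairs_with_signal_ids(predicted, catalog, signal)
    table, res = correlate_pairs(
        pairs, signal, expression, rng=np.random.default_rng(paths.SEED)
    )
    table.to_csv(paths.RESULTS_DIR / "06_pair_correlations.tsv", sep="\t", index=False)

    print(f"{len(predicted)} predicted enhancer:gene pairs "
          f"({res.n_pairs} testable, {res.n_background} background combinations)")
    print(f"median pair rho = {float(np.median(res.pair_rhos)):.3f}")
    print(f"Mann-Whitney U = {res.u_statistic:.0f}, one-sided p = {res.p_value:.3g}")

    (paths.RESULTS_DIR / "06_pairs_summary.json").write_text(json.dumps({
        "n_predicted": len(predicted), "n_tested": res.n_pairs,
        "n_background": res.n_background,
        "median_pair_rho": float(np.median(res.pair_rhos)),
        "u_statistic": res.u_statistic, "p_value": res.p_value,
    }, indent=1))


if __name__ == "__main__":
    main()
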