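"""Shared locations for the analysis scripts.

The synthetic study (bulky, regenerable) lives under scratch/; the small
result tables and summaries the scripts produce live under results/.
Run the scripts in order from the repository root:

    python analysis/01_simulate_study.py
    python analysis/02_build_catalog.py
    ...
"""

from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
STUDY_DIR = ROOT / "scratch" / "study"
RESULTS_DIR = ROOT / "results"
TABLES_DIR = ROOT / "scratch" / "tables"   # bulky per-row tables
PIPELINE_OUT = ROOT / "scratch" / "pipeline_out"
SEED = 1
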