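"""Shared paths and loaders for the numbered analysis scripts."""

from __future__ import annotations

import json
from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
STUDY_DIR = ROOT / "scratch" / "synthetic_study"
RESULTS = ROOT / "results"
SEED = 0


def require_study() -> Path:
    if not (STUDY_DIR / "metadata.tsv").exists():
        raise SystemExit("study not found; run analysis/01_simulate_study.py first")
    return STUDY_DIR


def load_truth() -> dict:
    return json.loads((STUDY_DIR / "truth.json").read_text())


def results_dir() -> Path:
    RESULTS.mkdir(exist_ok=True)
    return RESULTS
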