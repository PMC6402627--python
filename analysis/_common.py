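"""Shared paths and loaders for the numbered analysis scripts."""
from pathlib import Path

import pandas as pd

from oryzapop.variantio import FILTER_PRESETS, apply_filters, read_vcf

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "data"
RESULTS = ROOT / "results"


def load_matrix(filtered: bool = True):
    """Read the simulated call set, optionally applying the 'full' preset."""
    matrix, warnings = read_vcf(DATA / "variants.vcf")
    if filtered:
        matrix, _ = apply_filters(matrix, FILTER_PRESETS["full"])
    return matrix, warnings


def load_samples() -> pd.DataFrame:
    return pd.read_csv(DATA / "samples.tsv", sep="\t")


def save(table: pd.DataFrame, name: str) -> Path:
    RESULTS.mkdir(parents=True, exist_ok=True)
    path = RESULTS / name
    table.to_csv(path, index=False)
    print(f"wrote {path.relative_to(ROOT)} ({len(table)} rows)")
    return path
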