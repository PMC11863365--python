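"""CSV readers and writers shared by the command-line tools.

All files are comma-separated UTF-8 with a mandatory header row and "."
decimal separator, parsed locale-independently by pandas.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .calibration import ResponseTable
from .descriptors import LipidRecord


def panel_to_frame(panel: list[LipidRecord]) -> pd.DataFrame:
    n_levels = max((r.n_levels for r in panel), default=0)
    rows = []
    for r in panel:
        row = {
            "lipid_id": r.lipid_id,
            "name": r.name,
            "class": r.lipid_class,
            "smiles": r.smiles,
            "mode": r.ion_mode,
            "is_reference": r.is_reference_standard,
        }
        for lv in range(1, n_levels + 1):
            row[f"level_{lv}"] = r.spiked_conc.get(lv)
        rows.append(row)
    return pd.DataFrame(rows)


def write_panel(panel: list[LipidRecord], path: str | Path) -> None:
    panel_to_frame(panel).to_csv(path, index=False)


def write_responses(responses: ResponseTable, prefix: str | Path) -> tuple[Path, Path]:
    """Write a response table as <prefix>responses.csv (long) + <prefix>samples.csv."""
    prefix = Path(prefix)
    areas_path = prefix.parent / f"{prefix.name}responses.csv"
    samples_path = prefix.parent / f"{prefix.name}samples.csv"
    responses.to_long().to_csv(areas_path, index=False)
    responses.samples.reset_index(drop=True).to_csv(samples_path, index=False)
    return areas_path, samples_path


def read_responses(areas_path: str | Path, samples_path: str | Path) -> ResponseTable:
    return ResponseTable.from_long(areas_path, samples_path)


def read_truth(path: str | Path) -> pd.Series:
    """Read a truth table (lipid_id, true_conc) into a Series."""
    df = pd.read_csv(path)
    if not {"lipid_id", "true_conc"} <= set(df.columns):
        raise ValueError("truth table needs columns lipid_id, true_conc")
    return df.set_index("lipid_id")["true_conc"]
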