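"""Lipid panel parsing and molecular-descriptor computation.

The sensitivity model regresses relative ionization efficiency on numeric 2D
molecular descriptors computed from each lipid's SMILES.  This module turns a
panel table (one row per lipid standard or analyte, with SMILES, class, ion
mode and spiked calibration concentrations) into validated ``LipidRecord``
objects and a cleaned ``DescriptorMatrix`` ready for regression.

Descriptors are 2D only — no conformer generation — so the matrix is a pure,
deterministic function of the (canonicalized) SMILES.  The descriptor set is
RDKit's full 2D collection plus the topological autocorrelation family
(ATS/MATS/GATS, see :mod:`lipidsens.autocorr`).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors as _RD
from rdkit import RDLogger

from .autocorr import autocorrelation_descriptors

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")  # SMILES errors are reported through exceptions

ION_MODES = ("positive", "negative")
_LEVEL_COL = re.compile(r"^level_(\d+)$")


@dataclass
class LipidRecord:
    """One lipid standard or analyte in a panel.

    ``spiked_conc`` maps calibration level (1..L) to the spiked concentration
    in a single arbitrary unit used consistently throughout a study.
    """

    lipid_id: str
    name: str
    lipid_class: str
    smiles: str
    ion_mode: str
    spiked_conc: dict[int, float] = field(default_factory=dict)
    is_reference_standard: bool = False
    monoisotopic_mass: float = float("nan")

    def __post_init__(self) -> None:
        if self.ion_mode not in ION_MODES:
            raise ValueError(
                f"lipid {self.lipid_id!r}: ion_mode must be one of {ION_MODES}, "
                f"got {self.ion_mode!r}"
            )
        mol = Chem.MolFromSmiles(self.smiles)
        if mol is None:
            raise ValueError(f"lipid {self.lipid_id!r}: unparsable SMILES {self.smiles!r}")
        # canonical form so equivalent encodings of the same lipid collide
        self.smiles = Chem.MolToSmiles(mol)
        self.monoisotopic_mass = _RD.ExactMolWt(mol)
        if self.spiked_conc:
            levels = sorted(self.spiked_conc)
            if levels != list(range(1, len(levels) + 1)):
                raise ValueError(
                    f"lipid {self.lipid_id!r}: calibration levels must be contiguous "
                    f"1..L, got {levels}"
                )
            concs = [self.spiked_conc[lv] for lv in levels]
            if any(c2 <= c1 for c1, c2 in zip(concs, concs[1:])) or concs[0] <= 0:
                raise ValueError(
                    f"lipid {self.lipid_id!r}: spiked concentrations must be positive "
                    "and strictly increasing across levels"
                )

    @property
    def n_levels(self) -> int:
        return len(self.spiked_conc)

    def mol(self) -> Chem.Mol:
        return Chem.MolFromSmiles(self.smiles)


def parse_panel(table: pd.DataFrame | str | Path) -> list[LipidRecord]:
    """Parse a panel table into validated ``LipidRecord`` objects.

    Expected columns: ``lipid_id``, ``class``, ``smiles``, ``mode``, optional
    ``name`` and ``is_reference``, and one ``level_i`` column per calibration
    level.  Raises ``ValueError`` naming the offending row for unparsable
    SMILES, duplicated ids within a mode, or a mode whose reference-standard
    count differs from one.
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table, sep=None, engine="python")
    required = {"lipid_id", "class", "smiles", "mode"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"panel table is missing required columns: {sorted(missing)}")
    level_cols = sorted(
        (c for c in table.columns if _LEVEL_COL.match(c)),
        key=lambda c: int(_LEVEL_COL.match(c).group(1)),
    )
    records: list[LipidRecord] = []
    for idx, row in table.iterrows():
        spiked = {}
        for col in level_cols:
            val = row[col]
            if pd.notna(val):
                spiked[int(_LEVEL_COL.match(col).group(1))] = float(val)
        try:
            rec = LipidRecord(
                lipid_id=str(row["lipid_id"]),
                name=str(row.get("name", row["lipid_id"])),
                lipid_class=str(row["class"]),
                smiles=str(row["smiles"]),
                ion_mode=str(row["mode"]).lower(),
                spiked_conc=spiked,
                is_reference_standard=bool(row.get("is_reference", False)),
            )
        except ValueError as exc:
            raise ValueError(f"panel row {idx}: {exc}") from exc
        records.append(rec)
    for mode in ION_MODES:
        sub = [r for r in records if r.ion_mode == mode]
        if not sub:
            continue
        ids = [r.lipid_id for r in sub]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate lipid_id within mode {mode!r}: {dupes}")
        n_ref = sum(r.is_reference_standard for r in sub)
        if n_ref != 1:
            raise ValueError(
                f"mode {mode!r} must designate exactly one reference standard, found {n_ref}"
            )
    return records


@dataclass
class DescriptorMatrix:
    """Dense numeric descriptor matrix with provenance and cleaning report."""

    data: pd.DataFrame  # rows = lipid_ids, columns = descriptor names
    provenance: dict[str, str] = field(default_factory=dict)
    cleaning_report: dict[str, list[str]] = field(default_factory=dict)
    failed_lipids: list[str] = field(default_factory=list)

    @property
    def lipid_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def descriptor_names(self) -> list[str]:
        return list(self.data.columns)

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index_label="lipid_id")


def descriptor_family(name: str) -> str:
    """Descriptor family tag used for interpretability aggregation."""
    m = re.match(r"^(GATS|MATS|ATS)\d", name)
    if m:
        return m.group(1)
    return "RDKit2D"


def compute_descriptors(lipids: list[LipidRecord]) -> DescriptorMatrix:
    """All 2D descriptors for a list of lipids, one row per lipid.

    A lipid on which the descriptor engine fails is excluded with a warning
    (recorded in ``failed_lipids``) rather than aborting the whole panel.
    """
    rows: dict[str, dict[str, float]] = {}
    failed: list[str] = []
    for rec in lipids:
        try:
            mol = rec.mol()
            vals = dict(_RD.CalcMolDescriptors(mol))
            vals.update(autocorrelation_descriptors(mol))
            rows[rec.lipid_id] = vals
        except Exception:  # noqa: BLE001 - engine failures must not crash the panel
            logger.warning("descriptor computation failed for lipid %s; excluded", rec.lipid_id)
            failed.append(rec.lipid_id)
    if not rows:
        raise ValueError("descriptor computation failed for every lipid")
    data = pd.DataFrame.from_dict(rows, orient="index")
    data = data.loc[[r.lipid_id for r in lipids if r.lipid_id in rows]]
    provenance = {c: descriptor_family(c) for c in data.columns}
    return DescriptorMatrix(data=data, provenance=provenance, failed_lipids=failed)


def clean_descriptors(mat: DescriptorMatrix) -> DescriptorMatrix:
    """Drop unusable descriptor columns; deterministic and idempotent.

    Removes non-numeric columns, columns containing any missing or non-finite
    value, and zero-variance columns, recording each dropped name by reason.
    """
    data = mat.data
    report: dict[str, list[str]] = {"non_numeric": [], "non_finite": [], "zero_variance": []}
    numeric = data.select_dtypes(include=[np.number])
    report["non_numeric"] = [c for c in data.columns if c not in numeric.columns]
    finite_mask = np.isfinite(numeric.to_numpy(dtype=float)).all(axis=0)
    report["non_finite"] = [c for c, ok in zip(numeric.columns, finite_mask) if not ok]
    numeric = numeric.loc[:, finite_mask]
    var = numeric.to_numpy(dtype=float).var(axis=0)
    report["zero_variance"] = [c for c, v in zip(numeric.columns, var) if v == 0.0]
    cleaned = numeric.loc[:, var > 0.0].astype(float)
    if cleaned.shape[1] == 0:
        raise ValueError("descriptor cleaning removed every column")
    for reason, names in report.items():
        if names:
            logger.info("cleaning dropped %d columns (%s)", len(names), reason)
    return DescriptorMatrix(
        data=cleaned,
        provenance={c: mat.provenance.get(c, descriptor_family(c)) for c in cleaned.columns},
        cleaning_report=report,
        failed_lipids=list(mat.failed_lipids),
    )
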