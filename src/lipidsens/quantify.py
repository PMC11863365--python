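"""Concentration estimation from peak areas.

Three routes are implemented:

* ``svr_model`` — blank-corrected response, relativized to the same-mode
  reference internal standard in the same sample, divided by the (predicted
  or known) relative sensitivity m_R:

      c = (y - b) * c_ref / ((A_ref - b_ref) * m_R)

  where y is the analyte's peak area, b its blank-level area, A_ref/b_ref the
  reference standard's areas in the sample and in blanks, and c_ref the known
  spiked concentration of the reference.  With the true m_R this inverts the
  linear response model exactly, and it is invariant to a common rescaling of
  every area in the sample.
* ``one_point`` — a single response factor taken from the most structurally
  similar standard of the same class (same headgroup, then closest total
  chain length, then closest double-bond count).
* ``class_curve`` — a pooled least-squares slope over all standards of the
  analyte's class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .descriptors import LipidRecord
from .lipid_names import parse_lipid_name

logger = logging.getLogger(__name__)


@dataclass
class QuantResult:
    sample_id: str
    lipid_id: str
    method: str  # svr_model | one_point | class_curve
    predicted_mR: float
    y: float
    b: float
    predicted_conc: float
    clipped: bool = False
    true_conc: float | None = None

    @property
    def percent_error(self) -> float | None:
        if self.true_conc is None:
            return None
        return 100.0 * abs(self.predicted_conc - self.true_conc) / self.true_conc


def predict_concentration(
    y: float,
    b: float,
    mR: float,
    reference_area: float,
    reference_blank: float = 0.0,
    reference_conc: float = 1.0,
) -> tuple[float, bool]:
    """Invert the relative-sensitivity response model for one measurement.

    Returns (concentration, clipped); a negative estimate (blank larger than
    the response) is floored at 0 and flagged rather than propagated.
    """
    if mR <= 0:
        raise ValueError(f"m_R must be positive, got {mR}")
    if reference_area <= 0:
        raise ValueError(f"reference area must be positive, got {reference_area}")
    if y < 0 or b < 0:
        raise ValueError("areas must be non-negative")
    ref_corrected = reference_area - reference_blank
    if ref_corrected <= 0:
        raise ValueError("blank-corrected reference area must be positive")
    conc = (y - b) * reference_conc / (ref_corrected * mR)
    if conc < 0:
        return 0.0, True
    return conc, False


def blank_levels(responses, ion_mode: str) -> pd.Series:
    """Mean area per lipid across the mode's blank samples (0 when absent)."""
    blank_ids = responses.sample_ids("blank", ion_mode)
    if not blank_ids:
        return pd.Series(0.0, index=responses.areas.columns)
    means = responses.areas.loc[blank_ids].mean(axis=0, skipna=True)
    return means.fillna(0.0)


def quantify_samples(
    responses,
    mR: pd.Series,
    reference_id: str,
    reference_conc: float,
    ion_mode: str,
    sample_ids: list[str] | None = None,
    true_conc: pd.DataFrame | pd.Series | None = None,
    method: str = "svr_model",
) -> pd.DataFrame:
    """Apply the concentration equation to study samples.

    ``mR`` maps lipid_id to (predicted or true) relative sensitivity;
    ``true_conc`` may be a Series (lipid -> conc, same in every sample) or a
    frame indexed like the area table.  Returns one row per (sample, lipid).
    """
    if sample_ids is None:
        sample_ids = responses.sample_ids("study_sample", ion_mode)
    blanks = blank_levels(responses, ion_mode)
    rows = []
    for sid in sample_ids:
        ref_area = responses.areas.loc[sid, reference_id]
        if pd.isna(ref_area):
            raise ValueError(f"reference standard {reference_id!r} missing in sample {sid!r}")
        ref_blank = float(blanks.get(reference_id, 0.0))
        for lid, m in mR.items():
            if lid == reference_id or lid not in responses.areas.columns:
                continue
            area = responses.areas.loc[sid, lid]
            if pd.isna(area):
                continue
            conc, clipped = predict_concentration(
                float(area), float(blanks.get(lid, 0.0)), float(m),
                float(ref_area), ref_blank, reference_conc,
            )
            truth = None
            if true_conc is not None:
                if isinstance(true_conc, pd.DataFrame):
                    truth = float(true_conc.loc[sid, lid]) if lid in true_conc.columns else None
                elif lid in true_conc.index:
                    truth = float(true_conc.loc[lid])
            rows.append(
                {
                    "sample_id": sid, "lipid_id": lid, "method": method,
                    "predicted_mR": float(m), "y": float(area),
                    "b": float(blanks.get(lid, 0.0)), "predicted_conc": conc,
                    "clipped": clipped, "true_conc": truth,
                    "percent_error": (
                        100.0 * abs(conc - truth) / truth if truth else np.nan
                    ),
                }
            )
    return pd.DataFrame(rows)


def match_surrogate(
    analyte_name: str, standards: list[LipidRecord]
) -> LipidRecord:
    """Most structurally similar same-class standard for one analyte.

    Rule: identical class/headgroup is mandatory; ties resolved by smallest
    |delta total carbons|, then smallest |delta double bonds|, then the
    lexicographically smallest lipid_id (logged).
    """
    comp = parse_lipid_name(analyte_name)
    candidates = []
    for std in standards:
        try:
            std_comp = parse_lipid_name(std.name)
        except ValueError:
            continue
        if std_comp.lipid_class != comp.lipid_class:
            continue
        candidates.append(
            (
                abs(std_comp.n_carbons - comp.n_carbons),
                abs(std_comp.n_double_bonds - comp.n_double_bonds),
                std.lipid_id,
                std,
            )
        )
    if not candidates:
        raise ValueError(f"no surrogate available: no standard of class {comp.lipid_class!r}")
    candidates.sort(key=lambda t: t[:3])
    if len(candidates) > 1 and candidates[0][:2] == candidates[1][:2]:
        logger.info(
            "surrogate tie for %s broken lexicographically: chose %s",
            analyte_name, candidates[0][2],
        )
    return candidates[0][3]


def one_point_calibration(
    analyte_name: str,
    analyte_area: float,
    standards: list[tuple[LipidRecord, float, float]],
    analyte_blank: float = 0.0,
    standard_blanks: dict[str, float] | None = None,
) -> tuple[float, str]:
    """Single-point surrogate calibration.

    ``standards`` holds (record, known concentration, measured area) triples.
    The matched standard's blank-corrected response factor RF = area/conc is
    applied to the analyte: conc = (area - blank) / RF.  Returns
    (concentration, surrogate lipid_id).
    """
    standard_blanks = standard_blanks or {}
    surrogate = match_surrogate(analyte_name, [s for s, _, _ in standards])
    conc_std, area_std = next(
        (c, a) for s, c, a in standards if s.lipid_id == surrogate.lipid_id
    )
    area_std = area_std - standard_blanks.get(surrogate.lipid_id, 0.0)
    if conc_std <= 0 or area_std <= 0:
        raise ValueError(f"standard {surrogate.lipid_id!r} has unusable response factor")
    rf = area_std / conc_std
    return max((analyte_area - analyte_blank), 0.0) / rf, surrogate.lipid_id


def class_curve_calibration(
    analyte_name: str,
    analyte_area: float,
    standards: list[tuple[LipidRecord, float, float]],
    analyte_blank: float = 0.0,
    standard_blanks: dict[str, float] | None = None,
) -> tuple[float, int]:
    """Multipoint class-curve surrogate calibration.

    Pools every same-class standard's (concentration, blank-corrected area)
    pair into one least-squares line and divides the analyte's blank-corrected
    area by its slope.  With fewer than 2 class members it falls back to
    one-point calibration (warning).  Returns (concentration, n members used).
    """
    standard_blanks = standard_blanks or {}
    cls = parse_lipid_name(analyte_name).lipid_class
    members = []
    for std, conc, area in standards:
        try:
            if parse_lipid_name(std.name).lipid_class == cls:
                members.append((conc, area - standard_blanks.get(std.lipid_id, 0.0)))
        except ValueError:
            continue
    if len(members) < 2:
        logger.warning(
            "class %s has %d usable member(s); falling back to one-point calibration",
            cls, len(members),
        )
        conc, _ = one_point_calibration(
            analyte_name, analyte_area, standards, analyte_blank, standard_blanks
        )
        return conc, len(members)
    concs = np.array([c for c, _ in members], float)
    areas = np.array([a for _, a in members], float)
    if np.ptp(concs) == 0.0:
        slope = float(np.mean(areas) / np.mean(concs))
    else:
        slope = float(stats.linregress(concs, areas).slope)
    if slope <= 0:
        raise ValueError(f"class {cls!r} pooled calibration slope is non-positive")
    return max(analyte_area - analyte_blank, 0.0) / slope, len(members)
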