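"""Experimental ESI sensitivity from spiked calibration series.

A lipid's ionization sensitivity m is the slope of its peak-area vs
spiked-concentration line over the calibrant samples.  Lipids whose series is
too short, non-linear (R² < 0.8) or has non-positive slope are excluded; the
surviving slopes are divided by the slope of the mode-specific reference
internal standard (cholesterol-d7 in positive mode, monoacylglycerol-d7 in
negative mode) to give the unitless relative sensitivity m_R that the model
regresses on.  By default the top calibration level is dropped for every
lipid before fitting, because the highest calibrant commonly sits outside the
linear response range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .descriptors import DescriptorMatrix, LipidRecord

logger = logging.getLogger(__name__)

R2_LINEARITY_THRESHOLD = 0.8
MIN_POINTS = 3

SAMPLE_ROLES = ("calibrant", "study_sample", "blank", "neat_spike")


@dataclass
class ResponseTable:
    """Peak areas per (sample, lipid) with sample metadata.

    ``samples`` columns: sample_id, role (one of ``SAMPLE_ROLES``),
    calibration_level (nullable int), donor, ion_mode.
    ``areas``: wide frame, rows = sample_id, columns = lipid_id; NaN marks a
    lipid not observed in that sample.
    """

    samples: pd.DataFrame
    areas: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "role", "calibration_level", "donor", "ion_mode"}
        missing = required - set(self.samples.columns)
        if missing:
            raise ValueError(f"sample metadata missing columns: {sorted(missing)}")
        bad = set(self.samples["role"]) - set(SAMPLE_ROLES)
        if bad:
            raise ValueError(f"unknown sample roles: {sorted(bad)}")
        self.samples = self.samples.set_index("sample_id", drop=False)
        if not self.areas.index.equals(self.samples.index):
            self.areas = self.areas.reindex(self.samples.index)

    @classmethod
    def from_long(
        cls, areas: pd.DataFrame | str | Path, samples: pd.DataFrame | str | Path
    ) -> "ResponseTable":
        """Build from a long table (sample_id, lipid_id, area) + metadata table."""
        if not isinstance(areas, pd.DataFrame):
            areas = pd.read_csv(areas)
        if not isinstance(samples, pd.DataFrame):
            samples = pd.read_csv(samples)
        wide = areas.pivot_table(index="sample_id", columns="lipid_id", values="area")
        return cls(samples=samples, areas=wide)

    def to_long(self) -> pd.DataFrame:
        long = self.areas.stack().rename("area").reset_index()
        long.columns = ["sample_id", "lipid_id", "area"]
        return long

    def sample_ids(self, role: str, ion_mode: str | None = None) -> list[str]:
        sel = self.samples["role"] == role
        if ion_mode is not None:
            sel &= self.samples["ion_mode"] == ion_mode
        return list(self.samples.index[sel])

    def scaled(self, factor: float) -> "ResponseTable":
        """All areas multiplied by a constant (instrument-gain change)."""
        return ResponseTable(
            samples=self.samples.reset_index(drop=True), areas=self.areas * factor
        )


@dataclass
class CalibrationResult:
    lipid_id: str
    slope_m: float = float("nan")
    intercept: float = float("nan")
    r_squared: float = float("nan")
    m_R: float = float("nan")
    levels_used: list[int] = field(default_factory=list)
    status: str = "included"  # or excluded_linearity / excluded_missing / excluded_nonpositive_slope

    @property
    def included(self) -> bool:
        return self.status == "included"


def fit_calibration_curve(
    concs: np.ndarray, areas: np.ndarray
) -> tuple[float, float, float]:
    """Ordinary least-squares line area = m*conc + b; returns (m, b, R²).

    A flat series (zero area variance) is reported as slope 0, R² 0 so the
    caller excludes it; fewer than ``MIN_POINTS`` pairs is an error.
    """
    concs = np.asarray(concs, float)
    areas = np.asarray(areas, float)
    if concs.size != areas.size:
        raise ValueError("concs and areas must have equal length")
    if concs.size < MIN_POINTS:
        raise ValueError(f"need at least {MIN_POINTS} calibration points, got {concs.size}")
    if np.any(np.diff(concs) <= 0):
        raise ValueError("concentrations must be strictly increasing")
    if np.ptp(areas) == 0.0:
        return 0.0, float(areas[0]), 0.0
    fit = stats.linregress(concs, areas)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue**2)


def apply_level_policy(
    n_levels: int, policy: str = "drop_top", k: int = 1
) -> list[int]:
    """Calibration levels retained for fitting under the global level policy.

    ``drop_top`` removes the top ``k`` levels for every lipid (default k=1:
    the highest calibrant is routinely outside the linear range);
    ``drop_none`` keeps all levels.
    """
    if policy == "drop_none":
        levels = list(range(1, n_levels + 1))
    elif policy == "drop_top":
        levels = list(range(1, n_levels - k + 1))
    else:
        raise ValueError(f"unknown level policy {policy!r}")
    if len(levels) < MIN_POINTS:
        raise ValueError(
            f"level policy {policy!r} leaves {len(levels)} levels; at least {MIN_POINTS} required"
        )
    return levels


def calibrate_lipid(
    rec: LipidRecord,
    responses: ResponseTable,
    levels: list[int],
    blank_subtract: bool = False,
    relativize_responses: bool = False,
    reference_id: str | None = None,
) -> CalibrationResult:
    """Fit one lipid's calibration curve over the calibrant samples."""
    cal_ids = responses.sample_ids("calibrant", rec.ion_mode)
    meta = responses.samples.loc[cal_ids]
    concs, ys = [], []
    blank = 0.0
    if blank_subtract:
        blank_ids = responses.sample_ids("blank", rec.ion_mode)
        if blank_ids and rec.lipid_id in responses.areas.columns:
            blank = float(np.nanmean(responses.areas.loc[blank_ids, rec.lipid_id]))
            if not np.isfinite(blank):
                blank = 0.0
    for sid in cal_ids:
        lvl = meta.loc[sid, "calibration_level"]
        if pd.isna(lvl) or int(lvl) not in levels or int(lvl) not in rec.spiked_conc:
            continue
        if rec.lipid_id not in responses.areas.columns:
            continue
        area = responses.areas.loc[sid, rec.lipid_id]
        if pd.isna(area):
            continue
        y = float(area) - blank
        if relativize_responses:
            if reference_id is None:
                raise ValueError("relativize_responses requires reference_id")
            ref_area = responses.areas.loc[sid, reference_id]
            if pd.isna(ref_area) or float(ref_area) <= 0:
                continue
            y /= float(ref_area)
        concs.append(rec.spiked_conc[int(lvl)])
        ys.append(y)
    order = np.argsort(concs)
    concs_a = np.asarray(concs, float)[order]
    ys_a = np.asarray(ys, float)[order]
    res = CalibrationResult(lipid_id=rec.lipid_id, levels_used=list(levels))
    if concs_a.size < MIN_POINTS:
        res.status = "excluded_missing"
        return res
    m, b, r2 = fit_calibration_curve(concs_a, ys_a)
    res.slope_m, res.intercept, res.r_squared = m, b, r2
    if m <= 0:
        res.status = "excluded_nonpositive_slope"
    elif r2 < R2_LINEARITY_THRESHOLD:
        res.status = "excluded_linearity"
    return res


def relativize_slopes(
    results: list[CalibrationResult], reference_lipid_id: str
) -> list[CalibrationResult]:
    """Divide every included slope by the reference standard's slope.

    The reference gets m_R = 1 exactly.  A missing, excluded or non-positive
    reference is fatal for the mode: every m_R depends on it.
    """
    ref = next((r for r in results if r.lipid_id == reference_lipid_id), None)
    if ref is None:
        raise ValueError(f"reference standard {reference_lipid_id!r} not in calibration results")
    if not ref.included or ref.slope_m <= 0:
        raise ValueError(
            f"reference standard {reference_lipid_id!r} is unusable "
            f"(status={ref.status}, slope={ref.slope_m}); cannot relativize this mode"
        )
    for r in results:
        if r.included:
            r.m_R = 1.0 if r.lipid_id == reference_lipid_id else r.slope_m / ref.slope_m
    return results


def calibrate_mode(
    panel: list[LipidRecord],
    responses: ResponseTable,
    ion_mode: str,
    level_policy: str = "drop_top",
    drop_k: int = 1,
    blank_subtract: bool = False,
    relativize_responses: bool = False,
) -> list[CalibrationResult]:
    """Full per-mode calibration: fit, filter, relativize."""
    mode_panel = [r for r in panel if r.ion_mode == ion_mode]
    if not mode_panel:
        raise ValueError(f"panel has no lipids in mode {ion_mode!r}")
    ref = next((r for r in mode_panel if r.is_reference_standard), None)
    if ref is None:
        raise ValueError(f"mode {ion_mode!r} has no reference standard")
    n_levels = max(r.n_levels for r in mode_panel)
    levels = apply_level_policy(n_levels, level_policy, drop_k)
    results = [
        calibrate_lipid(
            rec,
            responses,
            levels,
            blank_subtract=blank_subtract,
            # the reference channel itself is never divided by itself
            relativize_responses=relativize_responses and not rec.is_reference_standard,
            reference_id=ref.lipid_id,
        )
        for rec in mode_panel
    ]
    for r in results:
        if not r.included:
            logger.info("lipid %s excluded from calibration: %s", r.lipid_id, r.status)
    if relativize_responses:
        # responses were divided per-sample by the reference channel, so each
        # fitted slope is already a relative sensitivity; this mode assumes
        # the reference is spiked at a constant level across calibrants
        # (with a co-diluted reference the ratio is flat and fits degenerate)
        for r in results:
            if r.lipid_id == ref.lipid_id:
                r.m_R = 1.0
            elif r.included:
                r.m_R = r.slope_m
        return results
    return relativize_slopes(results, ref.lipid_id)


def calibration_report(results: list[CalibrationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "lipid_id": [r.lipid_id for r in results],
            "slope_m": [r.slope_m for r in results],
            "intercept": [r.intercept for r in results],
            "r_squared": [r.r_squared for r in results],
            "m_R": [r.m_R for r in results],
            "levels_used": [",".join(map(str, r.levels_used)) for r in results],
            "status": [r.status for r in results],
        }
    )


def build_training_table(
    results: list[CalibrationResult], descriptors: DescriptorMatrix
) -> tuple[pd.DataFrame, pd.Series]:
    """Align included lipids' descriptor rows with their m_R targets.

    Lipids present on only one side are dropped (logged); fewer than 5
    remaining is an error, fewer than 10 a warning.
    """
    included = {r.lipid_id: r.m_R for r in results if r.included}
    common = [lid for lid in descriptors.lipid_ids if lid in included]
    only_cal = sorted(set(included) - set(common))
    only_desc = sorted(set(descriptors.lipid_ids) - set(included))
    if only_cal or only_desc:
        logger.info(
            "training table uses %d lipids; %d calibration-only and %d descriptor-only dropped",
            len(common), len(only_cal), len(only_desc),
        )
    if len(common) < 5:
        raise ValueError(f"only {len(common)} included lipids; at least 5 required for training")
    if len(common) < 10:
        logger.warning("only %d included lipids; model quality will be poor", len(common))
    X = descriptors.data.loc[common]
    y = pd.Series({lid: included[lid] for lid in common}, name="m_R").loc[common]
    return X, y
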