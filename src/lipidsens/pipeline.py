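"""End-to-end study runs on simulated data.

These functions chain the full workflow — simulate, calibrate, train the SVR
ensemble, quantify, evaluate — in the three configurations the package's
validation battery exercises:

* internal validation: train on the study's own calibrated panel, quantify
  the selected model's held-out lipids in replicate study samples;
* method comparison: descriptor-model quantitation vs one-point and
  class-curve surrogate calibration on a high within-class-spread panel;
* hold-out suite: leave-class-out on an out-of-law class, and
  largest/smallest-by-mass extrapolation under a smooth law.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .calibration import build_training_table, calibrate_mode
from .evaluate import (
    ValidationReport,
    holdout_by_class,
    holdout_by_size,
    percent_error_summary,
    r_squared,
)
from .model import EnsembleResult, ModelConfig, run_ensemble
from .quantify import blank_levels, class_curve_calibration, one_point_calibration, quantify_samples
from .simulate import ClassSpec, SimulatedStudy, SimulationConfig, simulate_study


def recovery_config(seed: int = 0) -> SimulationConfig:
    """Parameter-recovery conditions: 60 positive-mode lipids (reference
    included), a purely descriptor-driven law over 5 informative descriptors,
    and 5 % multiplicative area noise."""
    return SimulationConfig(
        class_specs=[
            ClassSpec("PC", "positive", 15, 2),
            ClassSpec("TG", "positive", 15, 3, chain_carbons=(10, 22)),
            ClassSpec("DG", "positive", 15, 2),
            ClassSpec("LPC", "positive", 14, 1, chain_carbons=(12, 22)),
        ],
        n_informative=5,
        weight_scale=0.8,
        class_offset_sd=0.0,
        within_class_sd=0.0,
        noise_sd=0.05,
        seed=seed,
    )


def high_spread_config(seed: int = 0) -> SimulationConfig:
    """Method-comparison conditions: steep size-driven sensitivity law giving
    a large within-class ionization-efficiency range (as triacylglycerols and
    ceramides show), plus moderate unexplained spread."""
    return SimulationConfig(
        class_specs=[
            ClassSpec("PC", "positive", 14, 2, chain_carbons=(10, 24)),
            ClassSpec("TG", "positive", 14, 3, chain_carbons=(8, 24)),
            ClassSpec("DG", "positive", 14, 2, chain_carbons=(10, 24)),
            ClassSpec("LPC", "positive", 8, 1, chain_carbons=(10, 24)),
        ],
        informative_descriptors=["MolWt", "FractionCSP3"],
        informative_weights=[0.4, 1.0],
        weight_scale=0.9,
        class_offset_sd=0.5,
        within_class_sd=0.3,
        noise_sd=0.05,
        seed=seed,
    )


def smooth_size_config(seed: int = 0) -> SimulationConfig:
    """Size-extrapolation conditions: a gentle mass-driven law on a panel
    whose classes span tight, overlapping chain ranges, so per-class mass
    extremes lie near the global descriptor support — the regime in which
    chain-length extrapolation is expected to succeed."""
    return SimulationConfig(
        class_specs=[
            ClassSpec("PC", "positive", 15, 2, chain_carbons=(14, 22), chain_double_bonds=(0, 1)),
            ClassSpec("TG", "positive", 15, 3, chain_carbons=(10, 15), chain_double_bonds=(0, 1)),
            ClassSpec("DG", "positive", 15, 2, chain_carbons=(14, 22), chain_double_bonds=(0, 1)),
            ClassSpec("LPC", "positive", 14, 1, chain_carbons=(13, 24), chain_double_bonds=(0, 1)),
        ],
        informative_descriptors=["MolWt", "MolLogP"],
        informative_weights=[1.0, 0.4],
        weight_scale=0.5,
        class_offset_sd=0.6,
        within_class_sd=0.05,
        noise_sd=0.05,
        seed=seed,
    )


@dataclass
class InternalValidationRun:
    study: SimulatedStudy
    ensemble: EnsembleResult
    quant: pd.DataFrame
    report: ValidationReport
    r2_internal_mR: float  # predicted vs calibration-measured m_R, held-out lipids


def run_internal_validation(
    cfg: SimulationConfig | None = None,
    mode: str = "positive",
    n_iterations: int = 51,
    model_config: ModelConfig | None = None,
    model_seed: int = 0,
) -> InternalValidationRun:
    """Simulate, calibrate, train the ensemble, quantify the held-out lipids."""
    cfg = cfg or SimulationConfig()
    study = simulate_study(cfg)
    cal = calibrate_mode(study.panel, study.responses, mode)
    X, y = build_training_table(cal, study.descriptors)
    ensemble = run_ensemble(X, y, n_iterations, model_seed, model_config, mode)
    model = ensemble.selected
    pred_mR = model.predict_mR(X.loc[model.test_ids])
    r2 = r_squared(y.loc[model.test_ids].to_numpy(float), pred_mR.to_numpy(float))
    ref = study.reference(mode)
    quant = quantify_samples(
        study.responses,
        pred_mR,
        reference_id=ref.lipid_id,
        reference_conc=ref.spiked_conc[cfg.study_level],
        ion_mode=mode,
        true_conc=study.true_conc,
    )
    report = percent_error_summary(quant, mode=mode, set_name="internal_validation")
    return InternalValidationRun(study, ensemble, quant, report, r2)


def split_standards_analytes(study: SimulatedStudy, mode: str) -> tuple[list, list]:
    """Split each class into calibration standards and interior analytes.

    Class members extreme in total chain length or double-bond count stay in
    the standard set; every other interior member (mass-ordered) becomes an
    analyte.  This mirrors how external-validation species sit inside the
    composition range their class's standards span — surrogate calibration
    and descriptor-model prediction are both interpolation tasks here.
    """
    from .lipid_names import parse_lipid_name

    standards, analytes = [], []
    recs = [r for r in study.panel if r.ion_mode == mode]
    by_class: dict[str, list] = {}
    for r in recs:
        by_class.setdefault(r.lipid_class, []).append(r)
    for _, members in sorted(by_class.items()):
        comps = {}
        for rec in members:
            try:
                comps[rec.lipid_id] = parse_lipid_name(rec.name)
            except ValueError:
                pass
        if len(comps) < 3:
            standards.extend(sorted(members, key=lambda r: r.lipid_id))
            continue
        carbons = {lid: c.n_carbons for lid, c in comps.items()}
        doubles = {lid: c.n_double_bonds for lid, c in comps.items()}
        interior = [
            rec for rec in members
            if rec.lipid_id in comps
            and not rec.is_reference_standard
            and min(carbons.values()) < carbons[rec.lipid_id] < max(carbons.values())
            and min(doubles.values()) <= doubles[rec.lipid_id] <= max(doubles.values())
            and doubles[rec.lipid_id] not in (min(doubles.values()), max(doubles.values()))
        ]
        interior = sorted(interior, key=lambda r: (r.monoisotopic_mass, r.lipid_id))
        chosen = {rec.lipid_id for rec in interior[::2]}
        for rec in sorted(members, key=lambda r: (r.monoisotopic_mass, r.lipid_id)):
            (analytes if rec.lipid_id in chosen else standards).append(rec)
    return standards, analytes


def run_method_comparison(
    seed: int = 0,
    n_iterations: int = 11,
    model_config: ModelConfig | None = None,
) -> dict[str, float]:
    """Mean percent error of the three quantitation routes on one study.

    The descriptor model is trained on the standards' calibrated m_R only and
    predicts the interleaved analytes; both surrogate baselines calibrate each
    analyte from the standards' responses in the same study sample.
    """
    cfg = high_spread_config(seed)
    mode = "positive"
    study = simulate_study(cfg)
    standards, analytes = split_standards_analytes(study, mode)
    standard_ids = {r.lipid_id for r in standards}
    cal = calibrate_mode(study.panel, study.responses, mode)
    cal_std = [c for c in cal if c.lipid_id in standard_ids]
    X, y = build_training_table(cal_std, study.descriptors)
    ensemble = run_ensemble(X, y, n_iterations, seed, model_config, mode)
    analyte_ids = [r.lipid_id for r in analytes if r.lipid_id in study.descriptors.lipid_ids]
    pred_mR = ensemble.selected.predict_mR(study.descriptors.data.loc[analyte_ids])

    ref = study.reference(mode)
    quant_svr = quantify_samples(
        study.responses,
        pred_mR,
        reference_id=ref.lipid_id,
        reference_conc=ref.spiked_conc[cfg.study_level],
        ion_mode=mode,
        true_conc=study.true_conc,
    )
    blanks = blank_levels(study.responses, mode)
    blank_map = {lid: float(blanks.get(lid, 0.0)) for lid in study.responses.areas.columns}
    errors: dict[str, list[float]] = {"one_point": [], "class_curve": []}
    by_id = {r.lipid_id: r for r in study.panel}
    # the class curve pools (spiked conc, area) points across class members
    # and the calibrant ladder (top level dropped, as in calibration)
    cal_samples = {
        int(study.responses.samples.loc[sid, "calibration_level"]): sid
        for sid in study.responses.sample_ids("calibrant", mode)
    }
    curve_levels = [lv for lv in sorted(cal_samples) if lv < max(cal_samples)]
    curve_triples = [
        (rec, rec.spiked_conc[lv], float(study.responses.areas.loc[cal_samples[lv], rec.lipid_id]))
        for rec in standards
        for lv in curve_levels
        if rec.lipid_id in study.responses.areas.columns
        and pd.notna(study.responses.areas.loc[cal_samples[lv], rec.lipid_id])
    ]
    for sid in study.responses.sample_ids("study_sample", mode):
        std_triples = [
            (rec, float(study.true_conc.loc[rec.lipid_id]),
             float(study.responses.areas.loc[sid, rec.lipid_id]))
            for rec in standards
            if rec.lipid_id in study.responses.areas.columns
            and pd.notna(study.responses.areas.loc[sid, rec.lipid_id])
        ]
        for lid in analyte_ids:
            area = study.responses.areas.loc[sid, lid]
            if pd.isna(area):
                continue
            truth = float(study.true_conc.loc[lid])
            name = by_id[lid].name
            c1, _ = one_point_calibration(
                name, float(area), std_triples, blank_map.get(lid, 0.0), blank_map
            )
            c2, _ = class_curve_calibration(
                name, float(area), curve_triples, blank_map.get(lid, 0.0), blank_map
            )
            errors["one_point"].append(100.0 * abs(c1 - truth) / truth)
            errors["class_curve"].append(100.0 * abs(c2 - truth) / truth)
    return {
        "svr_model": float(quant_svr["percent_error"].mean()),
        "class_curve": float(np.mean(errors["class_curve"])),
        "one_point": float(np.mean(errors["one_point"])),
    }


def run_holdout_suite(
    seed: int = 0,
    out_of_law_class: str = "DG",
    model_config: ModelConfig | None = None,
) -> dict[str, float]:
    """Leave-class-out and size-extrapolation R² on matched simulations.

    The leave-class-out study gives the held class a log-sensitivity offset
    outside anything the training classes span (out-of-law); the size
    hold-outs run on a smooth within-class law, where chain-length
    extrapolation is expected to work.
    """
    mode = "positive"
    smooth = smooth_size_config(seed)
    study = simulate_study(smooth)
    cal = calibrate_mode(study.panel, study.responses, mode)
    X, y = build_training_table(cal, study.descriptors)
    labels = study.class_labels()
    masses = study.masses()
    largest = holdout_by_size(X, y, masses, labels, "largest", 2, seed, model_config, mode)
    smallest = holdout_by_size(X, y, masses, labels, "smallest", 2, seed, model_config, mode)

    out_cfg = replace(smooth, out_of_law_class=out_of_law_class)
    study_out = simulate_study(out_cfg)
    cal_out = calibrate_mode(study_out.panel, study_out.responses, mode)
    Xo, yo = build_training_table(cal_out, study_out.descriptors)
    class_out = holdout_by_class(
        Xo, yo, study_out.class_labels(), out_of_law_class, seed, model_config, mode
    )
    return {
        "r2_leave_class_out": class_out.r2_pred_vs_true_mR,
        "r2_largest_holdout": largest.r2_pred_vs_true_mR,
        "r2_smallest_holdout": smallest.r2_pred_vs_true_mR,
    }
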