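"""Validation battery: error summaries, precision, hold-out extrapolation.

Accuracy is reported as percent error of predicted vs spiked concentration,
averaged per lipid across samples and then globally, both with and without
rule-flagged outliers.  Precision is the mean over lipids of the coefficient
of variation of predicted concentrations across replicate samples.  Hold-out
experiments (leave-class-out; largest/smallest lipids by mass per class)
probe how far the descriptor model extrapolates: R² of predicted vs true m_R
on the held set is computed in original (back-transformed) space, where
out-of-sample values can be strongly negative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import ModelConfig, train_full_model

logger = logging.getLogger(__name__)


@dataclass
class ValidationReport:
    mode: str
    set_name: str
    per_lipid: pd.DataFrame  # lipid_id, mean_ape, optionally cv
    global_mean_error: float
    global_mdape: float
    global_mean_error_outliers_removed: float
    outlier_ids: list[str] = field(default_factory=list)
    precision: float = float("nan")
    r2_pred_vs_true_mR: float = float("nan")


def outlier_rule(per_lipid_errors: pd.Series) -> list[str]:
    """Lipids whose mean APE exceeds median + 3*MAD.

    MAD is the raw median absolute deviation (no normal-consistency scaling).
    The rule is deliberately fixed so with/without-outlier summaries never
    depend on an ad hoc choice.
    """
    if len(per_lipid_errors) < 5:
        return []
    med = float(per_lipid_errors.median())
    mad = float((per_lipid_errors - med).abs().median())
    cutoff = med + 3.0 * mad
    return sorted(per_lipid_errors.index[per_lipid_errors > cutoff])


def r_squared(truth: np.ndarray, pred: np.ndarray) -> float:
    """Coefficient of determination; NaN when truth has zero variance."""
    truth = np.asarray(truth, float)
    pred = np.asarray(pred, float)
    ss_tot = float(np.sum((truth - truth.mean()) ** 2))
    if ss_tot == 0.0 or truth.size < 2:
        return float("nan")
    return 1.0 - float(np.sum((truth - pred) ** 2)) / ss_tot


def percent_error_summary(
    quant: pd.DataFrame, mode: str = "", set_name: str = ""
) -> ValidationReport:
    """Summarise a quantitation table with known truths.

    Rows without truth are dropped with a warning.  Per-lipid mean APE across
    samples, global means with and without rule-flagged outliers, and the
    precision (mean per-lipid CV of predicted concentrations) are reported.
    """
    usable = quant.dropna(subset=["true_conc"])
    n_dropped = len(quant) - len(usable)
    if n_dropped:
        logger.warning("%d quantitation rows lack a true concentration; dropped", n_dropped)
    if usable.empty:
        raise ValueError("no quantitation rows with known truth")
    ape = 100.0 * (usable["predicted_conc"] - usable["true_conc"]).abs() / usable["true_conc"]
    usable = usable.assign(ape=ape)
    per_lipid = usable.groupby("lipid_id").agg(
        mean_ape=("ape", "mean"), n_samples=("ape", "size")
    )
    cv = usable.groupby("lipid_id")["predicted_conc"].agg(
        lambda s: 100.0 * s.std(ddof=1) / s.mean() if len(s) > 1 and s.mean() != 0 else np.nan
    )
    per_lipid["cv_pct"] = cv
    outliers = outlier_rule(per_lipid["mean_ape"])
    kept = per_lipid.drop(index=outliers)
    return ValidationReport(
        mode=mode,
        set_name=set_name,
        per_lipid=per_lipid.reset_index(),
        global_mean_error=float(per_lipid["mean_ape"].mean()),
        global_mdape=float(per_lipid["mean_ape"].median()),
        global_mean_error_outliers_removed=float(kept["mean_ape"].mean()),
        outlier_ids=outliers,
        precision=float(per_lipid["cv_pct"].mean(skipna=True)),
    )


def _holdout_report(
    X: pd.DataFrame,
    y: pd.Series,
    held_ids: list[str],
    set_name: str,
    mode: str,
    seed: int,
    config: ModelConfig | None,
) -> ValidationReport:
    """Train on everything except ``held_ids``; evaluate m_R prediction on them."""
    train_ids = [i for i in X.index if i not in set(held_ids)]
    # the held set is the validation set: train on the full remainder
    model = train_full_model(X.loc[train_ids], y.loc[train_ids], seed, config, mode)
    pred = model.predict_mR(X.loc[held_ids])
    truth = y.loc[held_ids]
    ape = 100.0 * (pred - truth).abs() / truth
    per_lipid = pd.DataFrame(
        {"lipid_id": held_ids, "mean_ape": ape.to_numpy(float)}
    )
    r2 = r_squared(truth.to_numpy(float), pred.to_numpy(float))
    if len(held_ids) < 2:
        logger.info("held set %s has one lipid; R² undefined, APE reported", set_name)
    return ValidationReport(
        mode=mode,
        set_name=set_name,
        per_lipid=per_lipid,
        global_mean_error=float(ape.mean()),
        global_mdape=float(ape.median()),
        global_mean_error_outliers_removed=float(ape.mean()),
        outlier_ids=[],
        r2_pred_vs_true_mR=r2,
    )


def holdout_by_class(
    X: pd.DataFrame,
    y: pd.Series,
    class_labels: pd.Series,
    held_class: str,
    seed: int = 0,
    config: ModelConfig | None = None,
    mode: str = "positive",
) -> ValidationReport:
    """Leave an entire lipid class out of training and predict its m_R."""
    held_ids = list(X.index[class_labels.loc[X.index] == held_class])
    if not held_ids:
        raise ValueError(f"held class {held_class!r} has no members")
    if len(X) - len(held_ids) < 10:
        raise ValueError("fewer than 10 lipids remain for training after removing the class")
    return _holdout_report(X, y, held_ids, f"class:{held_class}", mode, seed, config)


def holdout_by_size(
    X: pd.DataFrame,
    y: pd.Series,
    masses: pd.Series,
    class_labels: pd.Series,
    which: str = "largest",
    k_per_class: int = 1,
    seed: int = 0,
    config: ModelConfig | None = None,
    mode: str = "positive",
) -> ValidationReport:
    """Hold out the k largest (or smallest) lipids by mass from each class.

    Mass ties are broken toward the lexicographically smallest lipid_id
    (logged); classes with too few members are skipped with a warning.
    """
    if which not in ("largest", "smallest"):
        raise ValueError("which must be 'largest' or 'smallest'")
    held_ids: list[str] = []
    for cls, ids in X.index.to_series().groupby(class_labels.loc[X.index]):
        members = list(ids)
        if len(members) <= k_per_class:
            logger.warning("class %s has %d members; skipped by size hold-out", cls, len(members))
            continue
        ordered = sorted(
            members,
            key=lambda lid: (-masses.loc[lid] if which == "largest" else masses.loc[lid], lid),
        )
        chosen = ordered[:k_per_class]
        if len(ordered) > k_per_class and masses.loc[ordered[k_per_class]] == masses.loc[chosen[-1]]:
            logger.info("mass tie in class %s broken lexicographically", cls)
        held_ids.extend(chosen)
    if not held_ids:
        raise ValueError("size hold-out selected no lipids (classes too small)")
    return _holdout_report(X, y, sorted(held_ids), f"size:{which}", mode, seed, config)


def recovery(matrix_areas: pd.Series, neat_areas: pd.Series) -> pd.DataFrame:
    """Percent recovery per lipid: 100 * matrix area / neat (nonmatrix) area.

    Values above 100 % flag possible ionization enhancement; a zero neat area
    leaves recovery undefined (flagged).
    """
    matrix_areas = matrix_areas.dropna()
    neat_areas = neat_areas.dropna()
    common = matrix_areas.index.intersection(neat_areas.index)
    if common.empty:
        raise ValueError("no lipids present in both matrix and neat tables")
    rows = []
    for lid in common:
        neat = float(neat_areas.loc[lid])
        matrix = float(matrix_areas.loc[lid])
        if neat == 0.0:
            rows.append({"lipid_id": lid, "recovery_pct": np.nan, "flag": "undefined_neat_zero"})
            continue
        rec = 100.0 * matrix / neat
        flag = "possible_enhancement" if rec > 100.0 else ""
        rows.append({"lipid_id": lid, "recovery_pct": rec, "flag": flag})
    return pd.DataFrame(rows)
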