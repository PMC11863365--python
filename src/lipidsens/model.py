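"""Relative-sensitivity regression: Box-Cox + RFE + SVR ensemble.

The regression target m_R (relative ionization sensitivity) is strictly
positive and right-skewed, so it is Box-Cox transformed before fitting.
Descriptors are standardized (training rows only), ranked and pruned by
recursive feature elimination with a linear-kernel SVR surrogate, and the
final support vector regressor is tuned by 5-fold cross-validation on the
training portion.  Because the panels are small (tens of lipids), a single
random train/test split is unreliable; the ensemble therefore repeats the
whole procedure over many random splits (1,101 by default) and selects the
iteration with the median held-out absolute error in predicted m_R as the
final model.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import inv_boxcox
from sklearn.feature_selection import RFECV
from sklearn.model_selection import GridSearchCV, KFold, train_test_split
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

logger = logging.getLogger(__name__)

_BUNDLE_VERSION = 1

#: hyperparameter grid searched by 5-fold CV inside each iteration
DEFAULT_SVR_GRID: list[dict] = [
    {"kernel": ["rbf"], "C": [1.0, 10.0, 100.0], "epsilon": [0.01, 0.1],
     "gamma": ["scale"]},
    {"kernel": ["linear"], "C": [1.0, 10.0, 100.0], "epsilon": [0.01, 0.1]},
]


def boxcox_fit_transform(y: np.ndarray) -> tuple[float, np.ndarray]:
    """Maximum-likelihood Box-Cox of strictly positive targets.

    Returns (lambda, transformed).  A constant vector has a flat Box-Cox
    likelihood; lambda = 1 is used so the transform stays well defined.
    """
    y = np.asarray(y, float)
    if np.any(y <= 0):
        raise ValueError("Box-Cox requires strictly positive targets")
    if np.ptp(y) == 0.0:
        return 1.0, boxcox_transform(y, 1.0)
    transformed, lam = stats.boxcox(y)
    return float(lam), np.asarray(transformed, float)


def boxcox_transform(y: np.ndarray, lam: float) -> np.ndarray:
    y = np.asarray(y, float)
    if np.any(y <= 0):
        raise ValueError("Box-Cox requires strictly positive targets")
    if lam == 0.0:
        return np.log(y)
    return (np.power(y, lam) - 1.0) / lam


def boxcox_inverse(z: np.ndarray, lam: float) -> np.ndarray:
    """Exact inverse of :func:`boxcox_transform`."""
    return np.asarray(inv_boxcox(np.asarray(z, float), lam), float)


@dataclass
class ModelConfig:
    """Tunables of one training iteration; defaults follow the workflow."""

    split_fraction: float = 0.8
    use_rfe: bool = True
    use_boxcox: bool = True
    svr_grid: list = field(default_factory=lambda: [dict(g) for g in DEFAULT_SVR_GRID])
    cv_folds: int = 5
    rfe_step: float = 0.5          # fraction of features removed per RFE round
    rfe_min_features: int = 4
    selection_metric: str = "mae_mR"  # or "mdape"
    # predictions are clamped to the training m_R range widened by this
    # factor; reins in Box-Cox-inverse blow-ups under extrapolation
    prediction_clamp_factor: float = 10.0

    def hash(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class SensitivityModel:
    """One trained iteration: transform, scaler, selected features, SVR."""

    ion_mode: str
    boxcox_lambda: float | None
    scaler: StandardScaler
    selected_descriptors: list[str]
    regressor: SVR
    train_ids: list[str]
    test_ids: list[str]
    seed: int
    test_mae_mR: float
    test_mdape: float
    test_mean_ape: float
    cv_r2: float
    config: ModelConfig
    y_train_min: float = float("nan")
    y_train_max: float = float("nan")

    def predict_mR(self, descriptors: pd.DataFrame) -> pd.Series:
        """Predict strictly positive m_R for rows of descriptor values.

        Raises ``KeyError`` naming any selected descriptor missing from the
        input columns.
        """
        missing = [c for c in self.selected_descriptors if c not in descriptors.columns]
        if missing:
            raise KeyError(f"descriptor row is missing selected descriptors: {missing}")
        X = self.scaler.transform(descriptors[self.selected_descriptors].to_numpy(float))
        z = self.regressor.predict(X)
        if self.boxcox_lambda is not None:
            lam = self.boxcox_lambda
            # the inverse transform requires lam*z + 1 > 0; clip regressor
            # output into the open domain so extrapolated predictions stay
            # finite and positive instead of becoming NaN
            if lam < 0:
                z = np.minimum(z, -1.0 / lam - 1e-9)
            elif lam > 0:
                z = np.maximum(z, -1.0 / lam + 1e-9)
            y = np.maximum(boxcox_inverse(z, lam), 1e-12)
        else:
            y = np.maximum(z, 1e-12)
        # a relative sensitivity far outside everything seen in training is
        # an extrapolation artefact, not a prediction; clamp with margin
        f = self.config.prediction_clamp_factor
        if f and np.isfinite(self.y_train_min) and np.isfinite(self.y_train_max):
            y = np.clip(y, self.y_train_min / f, self.y_train_max * f)
        return pd.Series(y, index=descriptors.index, name="predicted_mR")


@dataclass
class EnsembleResult:
    models: list[SensitivityModel]
    n_iterations: int
    selection_metric: str
    selected_index: int
    n_failed: int = 0

    @property
    def selected(self) -> SensitivityModel:
        return self.models[self.selected_index]

    def errors(self) -> np.ndarray:
        if self.selection_metric == "mdape":
            return np.array([m.test_mdape for m in self.models])
        return np.array([m.test_mae_mR for m in self.models])


def _scale_train_only(X_train: pd.DataFrame) -> StandardScaler:
    scaler = StandardScaler()
    scaler.fit(X_train.to_numpy(float))
    return scaler


def train_single_iteration(
    X: pd.DataFrame,
    y: pd.Series,
    seed: int,
    config: ModelConfig | None = None,
    ion_mode: str = "positive",
) -> SensitivityModel:
    """Train one model on a random split governed entirely by ``seed``.

    Training rows alone determine the Box-Cox lambda, the feature scaling and
    the RFE selection, so no information leaks from the held-out portion.
    """
    config = config or ModelConfig()
    if not 0.0 < config.split_fraction < 1.0:
        raise ValueError("split_fraction must lie in (0, 1)")
    if np.any(y.to_numpy(float) <= 0):
        raise ValueError("targets must be strictly positive (calibration filters violated?)")
    train_idx, test_idx = train_test_split(
        np.arange(len(y)), train_size=config.split_fraction, random_state=seed, shuffle=True
    )
    X_tr, X_te = X.iloc[train_idx], X.iloc[test_idx]
    y_tr, y_te = y.iloc[train_idx], y.iloc[test_idx]

    if config.use_boxcox:
        lam, z_tr = boxcox_fit_transform(y_tr.to_numpy(float))
    else:
        lam, z_tr = None, y_tr.to_numpy(float)

    scaler = _scale_train_only(X_tr)
    Z_tr = scaler.transform(X_tr.to_numpy(float))

    feature_names = list(X.columns)
    if config.use_rfe:
        cv = KFold(config.cv_folds, shuffle=True, random_state=seed)
        rfe = RFECV(
            estimator=SVR(kernel="linear"),
            step=config.rfe_step,
            min_features_to_select=config.rfe_min_features,
            cv=cv,
            scoring="neg_mean_absolute_error",
        )
        rfe.fit(Z_tr, z_tr)
        mask = rfe.support_
        if not mask.any():
            logger.warning("RFE selected zero features; falling back to all features")
            mask = np.ones(len(feature_names), bool)
        selected = [n for n, keep in zip(feature_names, mask) if keep]
    else:
        selected = feature_names

    # refit the scaler on the selected columns so the stored model carries
    # exactly the parameters it applies at prediction time
    scaler = _scale_train_only(X_tr[selected])
    Z_sel = scaler.transform(X_tr[selected].to_numpy(float))

    cv = KFold(config.cv_folds, shuffle=True, random_state=seed)
    search = GridSearchCV(
        SVR(),
        config.svr_grid,
        cv=cv,
        scoring={"mae": "neg_mean_absolute_error", "r2": "r2"},
        refit="mae",
    )
    search.fit(Z_sel, z_tr)
    regressor = search.best_estimator_
    cv_r2 = float(search.cv_results_["mean_test_r2"][search.best_index_])

    model = SensitivityModel(
        ion_mode=ion_mode,
        boxcox_lambda=lam,
        scaler=scaler,
        selected_descriptors=selected,
        regressor=regressor,
        train_ids=list(X_tr.index),
        test_ids=list(X_te.index),
        seed=seed,
        test_mae_mR=float("nan"),
        test_mdape=float("nan"),
        test_mean_ape=float("nan"),
        cv_r2=cv_r2,
        config=config,
        y_train_min=float(y_tr.min()),
        y_train_max=float(y_tr.max()),
    )
    pred = model.predict_mR(X_te).to_numpy(float)
    truth = y_te.to_numpy(float)
    ape = 100.0 * np.abs(pred - truth) / truth
    model.test_mae_mR = float(np.mean(np.abs(pred - truth)))
    model.test_mdape = float(np.median(ape))
    model.test_mean_ape = float(np.mean(ape))
    return model


def train_full_model(
    X: pd.DataFrame,
    y: pd.Series,
    seed: int = 0,
    config: ModelConfig | None = None,
    ion_mode: str = "positive",
) -> SensitivityModel:
    """Train on every supplied lipid with no internal hold-out.

    Used when an external validation set exists (e.g. a held-out class); the
    stored test error fields are NaN because nothing was withheld.
    """
    config = config or ModelConfig()
    if np.any(y.to_numpy(float) <= 0):
        raise ValueError("targets must be strictly positive")
    if config.use_boxcox:
        lam, z_tr = boxcox_fit_transform(y.to_numpy(float))
    else:
        lam, z_tr = None, y.to_numpy(float)
    scaler = _scale_train_only(X)
    Z = scaler.transform(X.to_numpy(float))
    feature_names = list(X.columns)
    if config.use_rfe:
        rfe = RFECV(
            estimator=SVR(kernel="linear"),
            step=config.rfe_step,
            min_features_to_select=config.rfe_min_features,
            cv=KFold(config.cv_folds, shuffle=True, random_state=seed),
            scoring="neg_mean_absolute_error",
        )
        rfe.fit(Z, z_tr)
        mask = rfe.support_ if rfe.support_.any() else np.ones(len(feature_names), bool)
        selected = [n for n, keep in zip(feature_names, mask) if keep]
    else:
        selected = feature_names
    scaler = _scale_train_only(X[selected])
    Z_sel = scaler.transform(X[selected].to_numpy(float))
    search = GridSearchCV(
        SVR(),
        config.svr_grid,
        cv=KFold(config.cv_folds, shuffle=True, random_state=seed),
        scoring={"mae": "neg_mean_absolute_error", "r2": "r2"},
        refit="mae",
    )
    search.fit(Z_sel, z_tr)
    return SensitivityModel(
        ion_mode=ion_mode,
        boxcox_lambda=lam,
        scaler=scaler,
        selected_descriptors=selected,
        regressor=search.best_estimator_,
        train_ids=list(X.index),
        test_ids=[],
        seed=seed,
        test_mae_mR=float("nan"),
        test_mdape=float("nan"),
        test_mean_ape=float("nan"),
        cv_r2=float(search.cv_results_["mean_test_r2"][search.best_index_]),
        config=config,
        y_train_min=float(y.min()),
        y_train_max=float(y.max()),
    )


def run_ensemble(
    X: pd.DataFrame,
    y: pd.Series,
    n_iterations: int = 1101,
    base_seed: int = 0,
    config: ModelConfig | None = None,
    ion_mode: str = "positive",
) -> EnsembleResult:
    """Repeat training over random splits and select the median-error model.

    Iteration i uses seed ``base_seed + i`` so any single iteration can be
    reproduced in isolation.  With an even number of successful iterations the
    lower median is taken; error ties are broken by the lower seed.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    config = config or ModelConfig()
    models: list[SensitivityModel] = []
    n_failed = 0
    for i in range(n_iterations):
        try:
            models.append(train_single_iteration(X, y, base_seed + i, config, ion_mode))
        except Exception as exc:  # noqa: BLE001 - one bad split must not kill the ensemble
            n_failed += 1
            logger.warning("iteration %d (seed %d) failed: %s", i, base_seed + i, exc)
    if not models:
        raise RuntimeError("every ensemble iteration failed")
    if n_failed:
        logger.info("%d of %d iterations failed and were skipped", n_failed, n_iterations)
    errors = (
        np.array([m.test_mdape for m in models])
        if config.selection_metric == "mdape"
        else np.array([m.test_mae_mR for m in models])
    )
    order = sorted(range(len(models)), key=lambda i: (errors[i], models[i].seed))
    median_pos = (len(models) - 1) // 2  # lower median for even counts
    selected_index = order[median_pos]
    return EnsembleResult(
        models=models,
        n_iterations=n_iterations,
        selection_metric=config.selection_metric,
        selected_index=selected_index,
        n_failed=n_failed,
    )


def learning_curve(
    X: pd.DataFrame,
    y: pd.Series,
    split_fractions: list[float],
    n_iterations_per_point: int = 25,
    base_seed: int = 0,
    config: ModelConfig | None = None,
) -> pd.DataFrame:
    """Held-out error as a function of the training fraction.

    Returns one row per usable fraction with the ensemble's median MdAPE and
    mean APE; fractions leaving fewer than 2 test lipids are skipped.
    """
    config = config or ModelConfig()
    rows = []
    for frac in split_fractions:
        if not 0.1 < frac < 0.95:
            raise ValueError(f"split fraction {frac} outside (0.1, 0.95)")
        n_test = len(y) - int(round(len(y) * frac))
        if n_test < 2:
            logger.warning("fraction %.2f leaves %d test lipids; skipped", frac, n_test)
            continue
        cfg = ModelConfig(**{**config.__dict__, "split_fraction": frac})
        ens = run_ensemble(X, y, n_iterations_per_point, base_seed, cfg)
        rows.append(
            {
                "split_fraction": frac,
                "mdape": float(np.median([m.test_mdape for m in ens.models])),
                "mean_ape": float(np.mean([m.test_mean_ape for m in ens.models])),
                "n_iterations": len(ens.models),
            }
        )
    return pd.DataFrame(rows)


def descriptor_importance_report(ensemble: EnsembleResult) -> pd.DataFrame:
    """Selection frequency of each descriptor across ensemble iterations.

    Families (GATS/MATS/ATS/RDKit2D) are aggregated as the mean selection
    frequency of their members that were ever selected.
    """
    from .descriptors import descriptor_family

    counts: dict[str, int] = {}
    for m in ensemble.models:
        for name in m.selected_descriptors:
            counts[name] = counts.get(name, 0) + 1
    n = len(ensemble.models)
    report = pd.DataFrame(
        {
            "descriptor": list(counts),
            "frequency": [c / n for c in counts.values()],
        }
    )
    report["family"] = report["descriptor"].map(descriptor_family)
    return report.sort_values(
        ["frequency", "descriptor"], ascending=[False, True]
    ).reset_index(drop=True)


def save_model(model: SensitivityModel, path: str) -> None:
    """Serialize a model bundle; round-trips exactly via :func:`load_model`."""
    joblib.dump(
        {"version": _BUNDLE_VERSION, "config_hash": model.config.hash(), "model": model}, path
    )


def load_model(path: str) -> SensitivityModel:
    payload = joblib.load(path)
    if payload.get("version") != _BUNDLE_VERSION:
        raise ValueError(f"unsupported model bundle version {payload.get('version')!r}")
    return payload["model"]
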