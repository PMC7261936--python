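"""Scoring metrics, PCA reduction state, and subject-wise cross-validation.

The clinical reference is the Modified Ashworth Scale restricted to grades
{0, 1, 1+, 2} (grades 3-4 are excluded — such patients cannot tolerate the
passive-stretch protocol), digitised to {0, 1, 1.5, 2}.

Evaluation is leave-one-subject-out: for each fold the feature
standardisation, PCA, cluster structure and consequent fit see only the
training subjects' windows; every window of the held-out subject is
predicted, and the subject's score is the mean window prediction clipped to
[0, 2].  Metrics over subjects: coefficient of determination R^2, RMSE,
unweighted Cohen's kappa on scores rounded to the nearest digitised level
(ties toward the higher level), and Pearson r.

The k-trial robustness protocol re-runs the whole cross-validation on k
randomly chosen fast trials per subject (without replacement, seeded),
repeated several times, mirroring how few stretches a therapist can ask a
patient to tolerate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _stats
from sklearn.decomposition import PCA
from sklearn.metrics import cohen_kappa_score

from .anfis import AnfisModel, ClusteringConfig, init_structure, train_consequents
from .exceptions import DegenerateFitError, InputError, UnsupportedLabelError
from .features import FEATURE_NAMES

MAS_NUMERIC = {"0": 0.0, "1": 1.0, "1+": 1.5, "2": 2.0}
MAS_LEVELS = (0.0, 1.0, 1.5, 2.0)


def digitize_mas(label: str | int | float) -> float:
    """Map a MAS label in {0, 1, 1+, 2} to its numeric score {0, 1, 1.5, 2}."""
    key = str(label).strip()
    if key in ("0.0", "1.0", "2.0"):
        key = key[0]
    if key not in MAS_NUMERIC:
        raise UnsupportedLabelError(
            f"MAS label {label!r} is outside the supported set {{0, 1, 1+, 2}}"
        )
    return MAS_NUMERIC[key]


def round_to_levels(y: np.ndarray, levels: tuple[float, ...] = MAS_LEVELS) -> np.ndarray:
    """Round scores to the nearest digitised level, ties toward the higher level."""
    y = np.atleast_1d(np.asarray(y, dtype=float))
    lv = np.asarray(levels, dtype=float)
    dist = np.abs(y[:, None] - lv[None, :])
    # scanning from the highest level, argmin picks it on ties
    idx = dist.shape[1] - 1 - np.argmin(dist[:, ::-1], axis=1)
    return lv[idx]


# ---------------------------------------------------------------------------
# metrics


def r_squared(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape or y.size < 2:
        raise InputError("r_squared needs two equal-length vectors of length >= 2")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise DegenerateFitError("R^2 undefined for a constant reference vector")
    return 1.0 - float(np.sum((y - y_hat) ** 2)) / ss_tot


def rmse(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Root-mean-square error sqrt(mean((y - y_hat)^2))."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape or y.size < 1:
        raise InputError("rmse needs two equal-length non-empty vectors")
    return float(np.sqrt(np.mean((y - y_hat) ** 2)))


def cohen_kappa(a: np.ndarray, b: np.ndarray) -> float:
    """Unweighted Cohen's kappa between two label vectors."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.size < 1:
        raise InputError("cohen_kappa needs two equal-length non-empty vectors")
    if np.array_equal(a, b) and np.unique(a).size == 1:
        return 1.0  # chance agreement is 1; agreement is perfect
    # sklearn rejects continuous dtypes: compare as categorical codes over
    # the shared label set
    labels = np.unique(np.concatenate([a.ravel(), b.ravel()]))
    a_codes = np.searchsorted(labels, a)
    b_codes = np.searchsorted(labels, b)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        kappa = float(cohen_kappa_score(a_codes, b_codes))
    if np.isnan(kappa):
        raise DegenerateFitError("kappa undefined: chance agreement equals 1")
    return kappa


def pearson_r(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Pearson correlation coefficient."""
    return float(_stats.pearsonr(np.asarray(y, float), np.asarray(y_hat, float)).statistic)


# ---------------------------------------------------------------------------
# PCA reduction


@dataclass
class PcaState:
    """Standardisation + PCA projection fitted on training windows only."""

    mean: np.ndarray
    scale: np.ndarray
    components: np.ndarray          # (n_components, n_features) orthonormal rows
    explained_variance_ratio: np.ndarray
    n_components: int

    def transform(self, F: np.ndarray) -> np.ndarray:
        Z = (np.asarray(F, dtype=float) - self.mean) / self.scale
        return Z @ self.components.T

    def inverse_transform(self, Y: np.ndarray) -> np.ndarray:
        Z = np.asarray(Y, dtype=float) @ self.components
        return Z * self.scale + self.mean


def fit_pca(F: np.ndarray, var_target: float = 0.95) -> PcaState:
    """Standardise features and retain the fewest components reaching
    ``var_target`` cumulative explained variance."""
    F = np.asarray(F, dtype=float)
    if F.ndim != 2 or F.shape[0] < 2:
        raise InputError("fit_pca needs a 2-D matrix with at least 2 rows")
    mean = F.mean(axis=0)
    scale = F.std(axis=0, ddof=0)
    constant = scale == 0.0
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant feature column(s): scale fallback to 1")
        scale = np.where(constant, 1.0, scale)
    Z = (F - mean) / scale
    pca = PCA(n_components=None, svd_solver="full")
    pca.fit(Z)
    evr = pca.explained_variance_ratio_
    if var_target >= 1.0:
        k = int(np.sum(pca.explained_variance_ > 1e-12 * pca.explained_variance_[0]))
        k = max(k, 1)
    else:
        k = int(np.searchsorted(np.cumsum(evr), var_target) + 1)
        k = min(k, evr.size)
    return PcaState(
        mean=mean,
        scale=scale,
        components=pca.components_[:k].copy(),
        explained_variance_ratio=evr[:k].copy(),
        n_components=k,
    )


# ---------------------------------------------------------------------------
# cross-validated evaluation


@dataclass
class FoldModel:
    """Everything fitted on one fold's training subjects."""

    pca: PcaState
    model: AnfisModel

    def predict_windows(self, F: np.ndarray) -> np.ndarray:
        from .anfis import predict

        return np.atleast_1d(predict(self.model, self.pca.transform(F)))

    def to_json(self) -> str:
        import json

        return json.dumps(
            {
                "pca": {
                    "mean": self.pca.mean.tolist(),
                    "scale": self.pca.scale.tolist(),
                    "components": self.pca.components.tolist(),
                },
                "anfis": self.model.to_dict(),
            },
            sort_keys=True,
        )


@dataclass
class EvaluationReport:
    """Per-subject reference vs predicted scores and summary metrics."""

    subjects: pd.DataFrame  # columns: subject_id, y, y_hat
    r2: float
    rmse: float
    kappa: float
    pearson_r: float
    config: dict = field(default_factory=dict)
    fold_models: list[FoldModel] | None = None

    def to_dict(self) -> dict:
        return {
            "r2": self.r2,
            "rmse": self.rmse,
            "kappa": self.kappa,
            "pearson_r": self.pearson_r,
            "subjects": self.subjects.to_dict(orient="records"),
            "config": self.config,
        }


@dataclass(frozen=True)
class EvaluationConfig:
    """Fold-model hyperparameters."""

    pca_var_target: float = 0.95
    clustering: ClusteringConfig = ClusteringConfig()
    training_mode: str = "lse"
    epochs: int = 20
    clip: tuple[float, float] | None = (0.0, 2.0)
    global_pca: bool = False  # fidelity switch: fit PCA on all subjects at once


def fit_fold(
    F_train: np.ndarray, y_train: np.ndarray, cfg: EvaluationConfig | None = None,
    pca_state: PcaState | None = None,
) -> FoldModel:
    """Fit standardisation/PCA, cluster structure and consequents on training windows."""
    cfg = cfg or EvaluationConfig()
    state = pca_state or fit_pca(F_train, cfg.pca_var_target)
    X = state.transform(F_train)
    model = init_structure(X, cfg.clustering)
    train_consequents(model, X, np.asarray(y_train, dtype=float),
                      epochs=cfg.epochs, mode=cfg.training_mode)
    return FoldModel(pca=state, model=model)


def loso_evaluate(
    table: pd.DataFrame,
    cfg: EvaluationConfig | None = None,
    keep_models: bool = False,
) -> EvaluationReport:
    """Leave-one-subject-out evaluation of a window feature table.

    ``table`` holds one row per analysis window with the 20 feature columns
    (:data:`~spastiq.features.FEATURE_NAMES`) plus ``subject_id`` and
    ``mas_numeric``.  Nothing from the held-out subject enters the fold
    fit.
    """
    cfg = cfg or EvaluationConfig()
    subjects = sorted(table["subject_id"].unique())
    if len(subjects) < 2:
        raise InputError("leave-one-subject-out needs at least 2 subjects")

    global_state = None
    if cfg.global_pca:
        global_state = fit_pca(table[list(FEATURE_NAMES)].to_numpy(), cfg.pca_var_target)

    rows = []
    models: list[FoldModel] = []
    for subject in subjects:
        test = table[table["subject_id"] == subject]
        train = table[table["subject_id"] != subject]
        if len(test) == 0:
            warnings.warn(f"subject {subject} has no analysis windows; excluded")
            continue
        fold = fit_fold(
            train[list(FEATURE_NAMES)].to_numpy(),
            train["mas_numeric"].to_numpy(dtype=float),
            cfg,
            pca_state=global_state,
        )
        pred = fold.predict_windows(test[list(FEATURE_NAMES)].to_numpy())
        score = float(np.mean(pred))
        if cfg.clip is not None:
            score = float(np.clip(score, *cfg.clip))
        rows.append(
            {
                "subject_id": subject,
                "y": float(test["mas_numeric"].iloc[0]),
                "y_hat": score,
                "n_windows": int(len(test)),
            }
        )
        if keep_models:
            models.append(fold)

    scores = pd.DataFrame(rows)
    y = scores["y"].to_numpy()
    y_hat = scores["y_hat"].to_numpy()
    return EvaluationReport(
        subjects=scores,
        r2=r_squared(y, y_hat),
        rmse=rmse(y, y_hat),
        kappa=cohen_kappa(round_to_levels(y), round_to_levels(y_hat)),
        pearson_r=pearson_r(y, y_hat),
        config={"pca_var_target": cfg.pca_var_target, "training_mode": cfg.training_mode},
        fold_models=models if keep_models else None,
    )


def sample_k_trials(
    table: pd.DataFrame, k: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Keep k randomly chosen trials per subject (all trials, with a warning,
    for subjects that have fewer).

    Each subject's trials are permuted once and the first k kept, so with a
    common ``rng`` state the k-trial subsets are nested in k (a paired,
    common-random-numbers design for comparing protocol sizes).
    """
    if k < 1:
        raise InputError("k must be >= 1")
    parts = []
    for subject in sorted(table["subject_id"].unique()):
        sub = table[table["subject_id"] == subject]
        trial_ids = sorted(sub["trial_id"].unique())
        perm = rng.permutation(trial_ids)
        if len(trial_ids) < k:
            warnings.warn(
                f"subject {subject} has only {len(trial_ids)} trials (< k={k}); using all"
            )
        chosen = list(perm[:k])
        parts.append(sub[sub["trial_id"].isin(chosen)])
    return pd.concat(parts, ignore_index=True)


def k_trial_protocol(
    table: pd.DataFrame,
    k: int,
    repeats: int = 3,
    seed: int = 0,
    cfg: EvaluationConfig | None = None,
) -> list[EvaluationReport]:
    """Robustness protocol: repeat LOSO on k sampled fast trials per subject.

    ``table`` should contain fast-stretch windows only (one row per window,
    with a ``trial_id`` column).  Returns one report per repeat; the same
    seed reproduces identical reports.  The per-repeat RNG does not depend
    on k, so runs at different k share the same nested trial subsets
    (paired comparisons across protocol sizes).
    """
    if k < 1:
        raise InputError("k must be >= 1")
    reports = []
    root = np.random.SeedSequence([int(seed)])
    for child in root.spawn(repeats):
        rng = np.random.default_rng(child)
        subset = sample_k_trials(table, k, rng)
        reports.append(loso_evaluate(subset, cfg))
    return reports
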