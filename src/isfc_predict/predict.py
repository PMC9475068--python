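"""Covariate-controlled repeated cross-validation, permutation inference, and
feature-dimensionality controls for the FC / ISFC / joint prediction models.

Design of the experiment:

* For each repeat, one seeded fold partition is shared across feature sets
  and component counts, so comparisons between models are paired.
* Within each training fold, feature standardization and the covariate
  regression are fitted on the training subjects only and applied to the
  held-out fold — no statistic ever sees test-fold data.
* "Controlling for" covariates means residualizing the *response*: the model
  predicts the part of the score not explained by age (linear + quadratic),
  gender, and handedness, and is scored on that same residual scale.
* Per repeat, held-out predictions are pooled across folds and scored by MAE
  and Spearman rho; summaries average over repeats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

FEATURE_SETS = ("FC", "ISFC", "JOINT")


@dataclass
class ExperimentConfig:
    feature_sets: tuple[str, ...] = FEATURE_SETS
    components_grid: tuple[int, ...] = tuple(range(1, 11))
    n_folds: int = 10
    n_repeats: int = 100
    n_permutations: int = 50_000
    n_subsample_reps: int = 1_000
    subsample_fraction: float = 0.5
    covariates: tuple[str, ...] = ("age", "age2", "gender", "handedness")
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.components_grid:
            raise ValueError("components_grid must be non-empty")
        if self.n_folds < 2:
            raise ValueError("need at least 2 folds")
        for fs in self.feature_sets:
            if fs not in FEATURE_SETS:
                raise ValueError(f"unknown feature set {fs!r}")


@dataclass
class EvaluationResult:
    """Long-format CV metrics plus artifacts attached by follow-up analyses."""

    results: pd.DataFrame          # feature_set, k, repeat, mae, rho
    partitions: list[np.ndarray]   # per-repeat fold id per subject
    config: ExperimentConfig
    selected_k: dict[str, int] = field(default_factory=dict)
    permutation: dict | None = None
    subsample: dict | None = None
    partial_correlations: pd.DataFrame | None = None

    def mean_metrics(self) -> pd.DataFrame:
        return (self.results.groupby(["feature_set", "k"])[["mae", "rho"]]
                .mean().reset_index())


# ---------------------------------------------------------------------------
# helpers

def feature_set_columns(columns, feature_set: str) -> list[str]:
    """Column names belonging to a feature set (ISC counts as ISFC)."""
    if feature_set == "FC":
        return [c for c in columns if c.startswith("FC:")]
    if feature_set == "ISFC":
        return [c for c in columns if c.startswith(("ISFC:", "ISC:"))]
    if feature_set == "JOINT":
        return list(columns)
    raise ValueError(f"unknown feature set {feature_set!r}")


def covariate_design(participants: pd.DataFrame,
                     covariates=("age", "age2", "gender", "handedness")) -> np.ndarray:
    """Design matrix [1, age, age^2, gender, handedness] from a phenotype table."""
    cols = [np.ones(len(participants))]
    for name in covariates:
        if name == "age":
            cols.append(participants["age"].to_numpy(float))
        elif name == "age2":
            cols.append(participants["age"].to_numpy(float) ** 2)
        elif name in ("gender", "handedness"):
            v = participants[name]
            codes = v.astype("category").cat.codes.to_numpy(float) \
                if v.dtype == object else v.to_numpy(float)
            cols.append(codes)
        else:
            raise ValueError(f"unknown covariate {name!r}")
    return np.column_stack(cols)


def residualize_covariates(y: np.ndarray, design: np.ndarray, fit_rows) -> tuple[np.ndarray, np.ndarray]:
    """OLS of y on the covariate design over ``fit_rows``; residuals for all rows.

    The design must include its intercept column. Raises on rank deficiency,
    naming the offending columns.
    """
    y = np.asarray(y, float)
    design = np.asarray(design, float)
    fit_rows = np.asarray(fit_rows)
    if fit_rows.dtype == bool:
        fit_rows = np.flatnonzero(fit_rows)
    sub = design[fit_rows]
    rank = np.linalg.matrix_rank(sub)
    if rank < design.shape[1]:
        _, r = np.linalg.qr(sub)
        bad = [str(i) for i in np.flatnonzero(np.abs(np.diag(r)) < 1e-10)]
        raise ValueError(f"covariate design is rank-deficient (columns {', '.join(bad)})")
    coefs, *_ = np.linalg.lstsq(sub, y[fit_rows], rcond=None)
    return y - design @ coefs, coefs


def fold_partition(n: int, n_folds: int, seed: int, repeat: int) -> np.ndarray:
    """Seeded fold id per subject for one CV repeat."""
    if n_folds > n:
        raise ValueError(f"n_folds={n_folds} exceeds n={n}")
    rng = np.random.default_rng([seed, repeat])
    order = rng.permutation(n)
    folds = np.empty(n, dtype=int)
    for f, chunk in enumerate(np.array_split(order, n_folds)):
        if chunk.size == 0:
            raise ValueError("a fold received zero subjects")
        folds[chunk] = f
    return folds


def _spearman(a: np.ndarray, b: np.ndarray) -> float:
    ra = stats.rankdata(a)
    rb = stats.rankdata(b)
    ra = ra - ra.mean()
    rb = rb - rb.mean()
    denom = np.sqrt((ra @ ra) * (rb @ rb))
    return float(ra @ rb / denom) if denom > 0 else 0.0


def _prepare_folds(X: np.ndarray, folds: np.ndarray) -> list[tuple]:
    """Per-fold train/test split with training-fold standardization of X.

    Cached across response permutations: X standardization never depends on y.
    """
    prepared = []
    for f in np.unique(folds):
        te = folds == f
        tr = ~te
        if te.sum() == 0 or tr.sum() < 2:
            raise ValueError("fold with too few subjects")
        mu = X[tr].mean(axis=0)
        sd = X[tr].std(axis=0, ddof=1)
        sd = np.where(sd == 0, 1.0, sd)
        Xtr = (X[tr] - mu) / sd
        Xte = (X[te] - mu) / sd
        prepared.append((np.flatnonzero(tr), np.flatnonzero(te), Xtr, Xte))
    return prepared


def _cv_pooled(prepared, y: np.ndarray, C: np.ndarray | None, k: int):
    """Pooled held-out predictions and matching residualized truth."""
    from .pls import fit_beta

    n = y.shape[0]
    yhat = np.empty(n)
    ytrue = np.empty(n)
    for tr, te, Xtr, Xte in prepared:
        if C is not None:
            coefs, *_ = np.linalg.lstsq(C[tr], y[tr], rcond=None)
            ytr = y[tr] - C[tr] @ coefs
            yte = y[te] - C[te] @ coefs
        else:
            ytr = y[tr]
            yte = y[te]
        ym = ytr.mean()
        ytr_c = ytr - ym
        k_eff = min(k, len(tr) - 1, Xtr.shape[1])
        beta = fit_beta(Xtr, ytr_c, k_eff)
        yhat[te] = Xte @ beta + ym
        ytrue[te] = yte
    return ytrue, yhat


def _score(ytrue: np.ndarray, yhat: np.ndarray) -> tuple[float, float]:
    return float(np.mean(np.abs(ytrue - yhat))), _spearman(ytrue, yhat)


# ---------------------------------------------------------------------------
# the experiment

def run_repeated_cv(features: pd.DataFrame, y, covariates: np.ndarray | None,
                    config: ExperimentConfig) -> EvaluationResult:
    """Repeated k-fold CV over feature sets and component counts.

    ``features`` is the children x named-features table; ``covariates`` is a
    full design matrix (with intercept) or None. Fold partitions depend only
    on (config.seed, repeat index) and are shared across feature sets and k,
    so every comparison is paired.
    """
    y = np.asarray(y, float)
    n = len(y)
    if features.shape[0] != n:
        raise ValueError("features and y disagree on the number of children")
    sets = {fs: features[feature_set_columns(features.columns, fs)].to_numpy(float)
            for fs in config.feature_sets}
    partitions = [fold_partition(n, config.n_folds, config.seed, r)
                  for r in range(config.n_repeats)]
    rows = []
    for r, folds in enumerate(partitions):
        for fs, X in sets.items():
            prepared = _prepare_folds(X, folds)
            for k in config.components_grid:
                ytrue, yhat = _cv_pooled(prepared, y, covariates, k)
                mae, rho = _score(ytrue, yhat)
                rows.append((fs, k, r, mae, rho))
    results = pd.DataFrame(rows, columns=["feature_set", "k", "repeat", "mae", "rho"])
    out = EvaluationResult(results=results, partitions=partitions, config=config)
    for fs in config.feature_sets:
        out.selected_k[fs] = select_components(out, fs)
    return out


def select_components(result: EvaluationResult, feature_set: str) -> int:
    """k minimizing mean MAE across repeats; ties go to the smaller k."""
    sub = result.results[result.results.feature_set == feature_set]
    if sub.empty:
        raise ValueError(f"feature set {feature_set!r} was not evaluated")
    means = sub.groupby("k")["mae"].mean().sort_index()
    return int(means.idxmin())  # idxmin takes the first (smallest k) on ties


def permutation_test(features: pd.DataFrame, y, covariates: np.ndarray | None,
                     config: ExperimentConfig, k: int, feature_set: str = "JOINT",
                     n_repeats: int = 1, observed_rho: float | None = None) -> dict:
    """Empirical null for the mean CV rho by permuting the response.

    Each permutation shuffles y together with its covariate rows (the
    y-covariate binding stays intact) against the connectivity features, and
    reruns the identical CV pipeline at the chosen k on the same fold
    partitions. One-sided p with the add-one correction:
    p = (1 + #{null >= observed}) / (1 + n_permutations).
    """
    y = np.asarray(y, float)
    n = len(y)
    X = features[feature_set_columns(features.columns, feature_set)].to_numpy(float)
    partitions = [fold_partition(n, config.n_folds, config.seed, r)
                  for r in range(n_repeats)]
    prepared = [_prepare_folds(X, folds) for folds in partitions]

    def _mean_rho(y_use, c_use):
        rhos = [_score(*_cv_pooled(prep, y_use, c_use, k))[1] for prep in prepared]
        return float(np.mean(rhos))

    if observed_rho is None:
        observed_rho = _mean_rho(y, covariates)
    null = np.empty(config.n_permutations)
    for b in range(config.n_permutations):
        perm = np.random.default_rng([config.seed, 100_003, b]).permutation(n)
        c_perm = covariates[perm] if covariates is not None else None
        null[b] = _mean_rho(y[perm], c_perm)
    p = (1.0 + np.sum(null >= observed_rho)) / (1.0 + config.n_permutations)
    return {"observed_rho": observed_rho, "null_rho": null, "p": float(p),
            "feature_set": feature_set, "k": k}


def subsample_control(features: pd.DataFrame, y, covariates: np.ndarray | None,
                      config: ExperimentConfig, k: int) -> dict:
    """Half-edge dimensionality control for the joint model.

    Each repetition draws (without replacement) a fraction of the FC features
    and the same fraction of the ISFC features, reruns the CV on the reduced
    joint feature set, and pairs the result with the FC-only and ISFC-only
    models evaluated on the identical fold partition. Paired one-sided t-tests
    ask whether the reduced joint model still outperforms each single-measure
    model.
    """
    y = np.asarray(y, float)
    n = len(y)
    fc_cols = feature_set_columns(features.columns, "FC")
    isfc_cols = feature_set_columns(features.columns, "ISFC")
    n_fc = int(np.floor(len(fc_cols) * config.subsample_fraction))
    n_isfc = int(np.floor(len(isfc_cols) * config.subsample_fraction))
    if n_fc < 2 or n_isfc < 2:
        raise ValueError("subsample_fraction leaves fewer than 2 features per block")
    X_fc = features[fc_cols].to_numpy(float)
    X_isfc = features[isfc_cols].to_numpy(float)
    X_joint = features[fc_cols + isfc_cols].to_numpy(float)

    partitions = [fold_partition(n, config.n_folds, config.seed, r)
                  for r in range(config.n_repeats)]
    base = {}
    for name, X in (("fc", X_fc), ("isfc", X_isfc), ("joint", X_joint)):
        base[name] = np.array([
            _score(*_cv_pooled(_prepare_folds(X, folds), y, covariates, k))[1]
            for folds in partitions])

    rho_reduced = np.empty(config.n_subsample_reps)
    matched = np.empty((config.n_subsample_reps, 3))
    for j in range(config.n_subsample_reps):
        rng = np.random.default_rng([config.seed, 7_907, j])
        pick_fc = np.sort(rng.choice(len(fc_cols), size=n_fc, replace=False))
        pick_isfc = np.sort(rng.choice(len(isfc_cols), size=n_isfc, replace=False))
        X_red = np.hstack([X_fc[:, pick_fc], X_isfc[:, pick_isfc]])
        folds = partitions[j % len(partitions)]
        rho_reduced[j] = _score(*_cv_pooled(_prepare_folds(X_red, folds), y,
                                            covariates, k))[1]
        idx = j % len(partitions)
        matched[j] = (base["fc"][idx], base["isfc"][idx], base["joint"][idx])

    t_fc = stats.ttest_rel(rho_reduced, matched[:, 0], alternative="greater")
    t_isfc = stats.ttest_rel(rho_reduced, matched[:, 1], alternative="greater")
    return {
        "rho_reduced": rho_reduced,
        "rho_fc": matched[:, 0], "rho_isfc": matched[:, 1], "rho_joint": matched[:, 2],
        "p_vs_fc": float(t_fc.pvalue), "p_vs_isfc": float(t_isfc.pvalue),
        "t_vs_fc": float(t_fc.statistic), "t_vs_isfc": float(t_isfc.statistic),
    }


def partial_correlation(x, y, controls) -> tuple[float, float]:
    """Spearman partial correlation of x and y given control variables.

    All variables (x, y and each control) are rank-transformed, x and y are
    residualized on [1, ranked controls], and the Pearson correlation of the
    residuals is returned with its t-distribution p-value
    (df = n - 2 - #controls).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    controls = np.asarray(controls, float)
    if controls.ndim == 1:
        controls = controls[:, None]
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 observations")
    controls = np.column_stack([stats.rankdata(c) for c in controls.T])
    design = np.column_stack([np.ones(n), controls])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("control design is rank-deficient")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    ex = rx - design @ np.linalg.lstsq(design, rx, rcond=None)[0]
    ey = ry - design @ np.linalg.lstsq(design, ry, rcond=None)[0]
    vx = ex @ ex
    vy = ey @ ey
    if vx < 1e-12 or vy < 1e-12:
        raise ValueError("zero residual variance after removing controls")
    r = float(ex @ ey / np.sqrt(vx * vy))
    df = n - 2 - controls.shape[1]
    if df <= 0:
        raise ValueError("not enough observations for a p-value")
    r_clamped = min(max(r, -1.0 + 1e-15), 1.0 - 1e-15)
    t = r_clamped * np.sqrt(df / (1.0 - r_clamped ** 2))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return r, p
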