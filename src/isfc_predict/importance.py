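"""Leave-one-region-out (LOO) importance for the joint prediction model.

Removing every connectivity feature incident to one ROI and measuring the
drop in cross-validated performance (delta rho) asks how much that region
contributes to the prediction. Variants remove only the FC edges, only the
ISFC features (edges plus the region's ISC entry — ISC is the ISFC
diagonal), or both. Reduced models keep the full model's component count so
the drop isolates feature removal rather than model-order changes, and they
are evaluated on the identical fold partitions so a paired test over repeats
is well-defined.
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd
from scipy import stats

from .predict import (ExperimentConfig, _cv_pooled, _prepare_folds, _score,
                      fold_partition)

VARIANTS = ("both", "fc_only", "isfc_only")

_EDGE_RE = re.compile(r"^(FC|ISFC):(.+)-(.+)$")
_ISC_RE = re.compile(r"^ISC:(.+)$")


def rois_in_features(feature_names) -> list[str]:
    """ROI labels appearing in a feature-name list, in first-seen order."""
    seen: dict[str, None] = {}
    for name in feature_names:
        m = _EDGE_RE.match(name)
        if m:
            seen.setdefault(m.group(2))
            seen.setdefault(m.group(3))
            continue
        m = _ISC_RE.match(name)
        if m:
            seen.setdefault(m.group(1))
    return list(seen)


def features_incident_to(feature_names, roi: str, variant: str = "both") -> list[str]:
    """Feature names removed when ROI ``roi`` is left out under ``variant``."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    if roi not in rois_in_features(feature_names):
        raise ValueError(f"ROI label {roi!r} absent from feature names")
    removed = []
    for name in feature_names:
        m = _EDGE_RE.match(name)
        if m:
            kind = m.group(1)
            incident = roi in (m.group(2), m.group(3))
            if incident and ((kind == "FC" and variant in ("both", "fc_only")) or
                             (kind == "ISFC" and variant in ("both", "isfc_only"))):
                removed.append(name)
            continue
        m = _ISC_RE.match(name)
        if m and m.group(1) == roi and variant in ("both", "isfc_only"):
            removed.append(name)
    return removed


def loo_region_importance(features: pd.DataFrame, y, covariates: np.ndarray | None,
                          config: ExperimentConfig, k: int,
                          variant: str = "both") -> pd.DataFrame:
    """Per-ROI performance drop when the ROI's features are removed.

    Returns a table (roi, variant, delta_rho_mean, t, p_raw, p_bonf,
    significant): delta rho = full-model rho - reduced-model rho per repeat on
    matched partitions, tested with a one-sided paired t-test (removal is
    hypothesized to *lower* performance) and Bonferroni-corrected over ROIs.
    """
    y = np.asarray(y, float)
    n = len(y)
    rois = rois_in_features(features.columns)
    partitions = [fold_partition(n, config.n_folds, config.seed, r)
                  for r in range(config.n_repeats)]

    X_full = features.to_numpy(float)
    full_rho = np.array([
        _score(*_cv_pooled(_prepare_folds(X_full, folds), y, covariates, k))[1]
        for folds in partitions])

    rows = []
    for roi in rois:
        removed = set(features_incident_to(features.columns, roi, variant))
        keep = [c for c in features.columns if c not in removed]
        X_red = features[keep].to_numpy(float)
        red_rho = np.array([
            _score(*_cv_pooled(_prepare_folds(X_red, folds), y, covariates, k))[1]
            for folds in partitions])
        delta = full_rho - red_rho
        if len(delta) > 1 and np.ptp(delta) > 0:
            t, p = stats.ttest_rel(full_rho, red_rho, alternative="greater")
        else:  # constant differences: no variance for a t-test
            t, p = (np.nan, 1.0 if np.allclose(delta, 0) else 0.0)
        p_bonf = min(1.0, float(p) * len(rois))
        rows.append({"roi": roi, "variant": variant,
                     "delta_rho_mean": float(delta.mean()),
                     "t": float(t), "p_raw": float(p), "p_bonf": p_bonf,
                     "significant": p_bonf < config.alpha})
    return pd.DataFrame(rows)


def coefficient_degrees(betas, feature_names) -> pd.DataFrame:
    """Per-ROI degree of the (averaged) beta coefficients, split by block.

    ``betas`` is a list of beta vectors (or fitted models with a ``beta``
    attribute) over a shared feature space. Betas are averaged, reshaped into
    the symmetric FC and ISFC coefficient matrices (ISC on the ISFC
    diagonal), and each ROI's degree is the sum of absolute coefficients over
    its row.
    """
    vecs = []
    for b in betas:
        vec = np.asarray(getattr(b, "beta", b), float)
        vecs.append(vec)
    if len({v.shape for v in vecs}) != 1 or vecs[0].shape[0] != len(feature_names):
        raise ValueError("beta vectors and feature names are inconsistent")
    mean_beta = np.mean(vecs, axis=0)

    rois = rois_in_features(feature_names)
    index = {r: i for i, r in enumerate(rois)}
    n = len(rois)
    fc_mat = np.zeros((n, n))
    isfc_mat = np.zeros((n, n))
    for name, coef in zip(feature_names, mean_beta):
        m = _EDGE_RE.match(name)
        if m:
            i, j = index[m.group(2)], index[m.group(3)]
            target = fc_mat if m.group(1) == "FC" else isfc_mat
            target[i, j] = coef
            target[j, i] = coef
            continue
        m = _ISC_RE.match(name)
        if m:
            i = index[m.group(1)]
            isfc_mat[i, i] = coef
    return pd.DataFrame({
        "roi": rois,
        "fc_degree": np.abs(fc_mat).sum(axis=1),
        "isfc_degree": np.abs(isfc_mat).sum(axis=1),
    })
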