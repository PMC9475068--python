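"""Intra-subject FC, inter-subject ISC/ISFC against an adult reference, and the
feature machinery built on top of them.

FC is the Pearson correlation of two ROI time series within one subject. ISFC
correlates ROI *i* in a child with ROI *j* in the adult reference signal; its
diagonal is the ISC. Because intrinsic activity and noise are uncorrelated
across individuals, ISFC isolates the coupling driven by the shared,
time-locked stimulus, while FC mixes it with the subject's intrinsic
"fingerprint" — the complementarity the downstream prediction models exploit.

Vectorization order is row-major upper triangle and is written into feature
names (``FC:a-b``, ``ISFC:a-b``, ``ISC:a``) so fitted models are portable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import SubjectRecord

FISHER_CLIP = 1e-7


# ---------------------------------------------------------------------------
# feature-name grammar

def fc_edge_names(roi_labels: list[str]) -> list[str]:
    r = len(roi_labels)
    return [f"FC:{roi_labels[i]}-{roi_labels[j]}" for i in range(r) for j in range(i + 1, r)]


def isfc_edge_names(roi_labels: list[str]) -> list[str]:
    r = len(roi_labels)
    return [f"ISFC:{roi_labels[i]}-{roi_labels[j]}" for i in range(r) for j in range(i + 1, r)]


def isc_names(roi_labels: list[str]) -> list[str]:
    return [f"ISC:{lbl}" for lbl in roi_labels]


def feature_names(roi_labels: list[str]) -> list[str]:
    """All model features: FC edges, then ISFC edges, then the ISC diagonal."""
    return fc_edge_names(roi_labels) + isfc_edge_names(roi_labels) + isc_names(roi_labels)


def _upper(mat: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(mat.shape[0], k=1)
    return mat[iu]


@dataclass
class ConnectivityFeatures:
    """Per-subject connectivity summaries.

    ``fc`` and ``isfc`` are raw correlation matrices (unit diagonal for FC, ISC
    on the ISFC diagonal); ``fc_edges`` and ``isfc_features`` are the
    Fisher-transformed vectorizations used as model features (ISFC off-diagonal
    edges followed by the ISC diagonal).
    """

    subject_id: str
    fc: np.ndarray
    isfc: np.ndarray
    fc_edges: np.ndarray
    isfc_features: np.ndarray
    valid_tr_mask: np.ndarray


@dataclass
class ReferenceSignal:
    """Mean adult time series, with per-TR counts of contributing adults."""

    timeseries: np.ndarray  # TR x ROI
    n_adults: np.ndarray    # per-TR contributing-adult count

    @property
    def valid(self) -> np.ndarray:
        return self.n_adults > 0


# ---------------------------------------------------------------------------
# core correlations

def compute_fc(timeseries: np.ndarray, valid_tr_mask: np.ndarray | None = None) -> np.ndarray:
    """Pearson FC over admissible TRs; symmetric with unit diagonal."""
    ts = np.asarray(timeseries, dtype=float)
    if valid_tr_mask is not None:
        ts = ts[np.asarray(valid_tr_mask, dtype=bool)]
    if ts.shape[0] < 3:
        raise ValueError("need at least 3 valid TRs for FC")
    sd = ts.std(axis=0)
    if np.any(sd == 0):
        bad = int(np.flatnonzero(sd == 0)[0])
        raise ValueError(f"zero-variance ROI at index {bad}; FC undefined")
    fc = np.corrcoef(ts.T)
    fc = (fc + fc.T) / 2.0
    np.fill_diagonal(fc, 1.0)
    return fc


def build_reference(adult_subjects: list[SubjectRecord],
                    scrub_masks: list[np.ndarray] | None = None) -> ReferenceSignal:
    """Per-TR/ROI mean over adults whose scrub mask admits that TR."""
    if not adult_subjects:
        raise ValueError("reference requires at least one adult subject")
    if scrub_masks is None:
        scrub_masks = [s.tr_mask() for s in adult_subjects]
    t, r = adult_subjects[0].timeseries.shape
    total = np.zeros((t, r))
    count = np.zeros(t, dtype=int)
    for subj, mask in zip(adult_subjects, scrub_masks):
        mask = np.asarray(mask, dtype=bool)
        total[mask] += subj.timeseries[mask]
        count += mask.astype(int)
    mean = np.full((t, r), np.nan)
    ok = count > 0
    mean[ok] = total[ok] / count[ok, None]
    return ReferenceSignal(timeseries=mean, n_adults=count)


def compute_isfc(child_timeseries: np.ndarray, reference: ReferenceSignal,
                 valid_tr_mask: np.ndarray | None = None) -> np.ndarray:
    """Symmetrized child-vs-reference cross-correlation; diagonal = ISC.

    raw[i, j] = Pearson(child ROI i, reference ROI j) over jointly valid TRs;
    the returned matrix is (raw + raw.T)/2, which leaves the diagonal (ISC)
    untouched.
    """
    child = np.asarray(child_timeseries, dtype=float)
    mask = reference.valid.copy()
    if valid_tr_mask is not None:
        mask &= np.asarray(valid_tr_mask, dtype=bool)
    if mask.sum() < 3:
        raise ValueError("fewer than 3 jointly valid TRs for ISFC")
    c = child[mask]
    a = reference.timeseries[mask]
    m = c.shape[0]
    c = c - c.mean(axis=0)
    a = a - a.mean(axis=0)
    c_sd = c.std(axis=0)
    a_sd = a.std(axis=0)
    if np.any(c_sd == 0) or np.any(a_sd == 0):
        raise ValueError("zero-variance ROI among valid TRs; ISFC undefined")
    raw = (c / c_sd).T @ (a / a_sd) / m
    return (raw + raw.T) / 2.0


def fisher_transform(matrix: np.ndarray) -> np.ndarray:
    """Elementwise artanh; values within FISHER_CLIP of ±1 are clipped first."""
    m = np.asarray(matrix, dtype=float)
    if not np.all(np.isfinite(m)):
        raise ValueError("non-finite correlation values")
    return np.arctanh(np.clip(m, -1.0 + FISHER_CLIP, 1.0 - FISHER_CLIP))


# ---------------------------------------------------------------------------
# feature tables

def subject_features(child: SubjectRecord, reference: ReferenceSignal) -> ConnectivityFeatures:
    mask = child.tr_mask()
    fc = compute_fc(child.timeseries, mask)
    isfc = compute_isfc(child.timeseries, reference, mask)
    return ConnectivityFeatures(
        subject_id=child.subject_id,
        fc=fc,
        isfc=isfc,
        fc_edges=fisher_transform(_upper(fc)),
        isfc_features=np.concatenate(
            [fisher_transform(_upper(isfc)), fisher_transform(np.diag(isfc))]
        ),
        valid_tr_mask=mask,
    )


def cohort_feature_table(cohort, reference_mode: str = "mean"):
    """Feature table (children x named features) plus per-child matrices.

    ``reference_mode='mean'`` correlates each child with the adult mean series;
    ``'per-adult'`` averages the child-vs-single-adult ISFC matrices instead.
    Both reduce to the same value in the noise-free shared-signal limit.
    """
    children = cohort.children
    adults = cohort.adults
    if not children or not adults:
        raise ValueError("cohort must contain children and at least one adult")
    feats: list[ConnectivityFeatures] = []
    if reference_mode == "mean":
        reference = build_reference(adults)
        for ch in children:
            feats.append(subject_features(ch, reference))
    elif reference_mode == "per-adult":
        singles = [build_reference([a]) for a in adults]
        for ch in children:
            mask = ch.tr_mask()
            fc = compute_fc(ch.timeseries, mask)
            isfc = np.mean(
                [compute_isfc(ch.timeseries, ref, mask) for ref in singles], axis=0
            )
            feats.append(ConnectivityFeatures(
                subject_id=ch.subject_id,
                fc=fc,
                isfc=isfc,
                fc_edges=fisher_transform(_upper(fc)),
                isfc_features=np.concatenate(
                    [fisher_transform(_upper(isfc)), fisher_transform(np.diag(isfc))]
                ),
                valid_tr_mask=mask,
            ))
    else:
        raise ValueError(f"unknown reference_mode {reference_mode!r}")
    table = pd.DataFrame(
        np.vstack([np.concatenate([f.fc_edges, f.isfc_features]) for f in feats]),
        index=[f.subject_id for f in feats],
        columns=feature_names(cohort.roi_labels),
    )
    return table, feats


def standardize_features(feature_table, fit_rows):
    """Per-feature z-scoring with statistics from ``fit_rows`` only.

    Returns (standardized table, means, sds). A feature constant on the fit
    rows is mapped to zero everywhere, with a warning.
    """
    values = np.asarray(feature_table, dtype=float)
    fit_rows = np.asarray(fit_rows)
    if fit_rows.dtype == bool:
        fit_rows = np.flatnonzero(fit_rows)
    if len(fit_rows) < 2:
        raise ValueError("need at least 2 fit rows to standardize")
    sub = values[fit_rows]
    means = sub.mean(axis=0)
    sds = sub.std(axis=0, ddof=1)
    degenerate = sds == 0
    if np.any(degenerate):
        warnings.warn(f"{int(degenerate.sum())} constant feature(s) set to zero")
        sds = np.where(degenerate, 1.0, sds)
    out = (values - means) / sds
    out[:, degenerate] = 0.0
    if isinstance(feature_table, pd.DataFrame):
        out = pd.DataFrame(out, index=feature_table.index, columns=feature_table.columns)
    return out, means, sds


# ---------------------------------------------------------------------------
# FC–ISFC similarity

def isfc_fc_similarity(features: ConnectivityFeatures) -> float:
    """Spearman correlation between a subject's ISFC and FC edge patterns.

    Uses the Fisher-transformed upper-triangle edges; the ISC diagonal is
    excluded so the statistic compares *connectivity* patterns only.
    """
    isfc_edges = fisher_transform(_upper(features.isfc))
    fc_edges = fisher_transform(_upper(features.fc))
    if isfc_edges.size < 3:
        raise ValueError("need at least 3 edges for a similarity rank correlation")
    rho, _ = stats.spearmanr(isfc_edges, fc_edges)
    return float(rho)


def _exact_spearman_p(a: np.ndarray, b: np.ndarray, observed: float) -> float:
    """Two-sided exact permutation p for Spearman rho (small samples only)."""
    from itertools import permutations

    ra = stats.rankdata(a)
    rb = stats.rankdata(b)
    ra = ra - ra.mean()
    hits = total = 0
    for perm in permutations(rb):
        pb = np.asarray(perm) - np.mean(perm)
        denom = np.sqrt((ra @ ra) * (pb @ pb))
        rho = ra @ pb / denom
        hits += abs(rho) >= abs(observed) - 1e-12
        total += 1
    return hits / total


def similarity_vs_covariates(similarities, ages, scores) -> dict[str, tuple[float, float]]:
    """Spearman correlation of per-subject FC–ISFC similarity with age and score.

    The p-value is the exact (exhaustive-permutation) two-sided p for n <= 8
    and the asymptotic one otherwise.
    """
    sim = np.asarray(similarities, dtype=float)
    if sim.size < 5:
        raise ValueError("need at least 5 subjects")
    out = {}
    for name, other in (("age", ages), ("score", scores)):
        other = np.asarray(other, dtype=float)
        if np.ptp(sim) == 0 or np.ptp(other) == 0:
            raise ValueError(f"constant vector in similarity-vs-{name} correlation")
        rho, p = stats.spearmanr(sim, other)
        if sim.size <= 8:
            p = _exact_spearman_p(sim, other, rho)
        out[name] = (float(rho), float(p))
    return out
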