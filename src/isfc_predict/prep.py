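"""Temporal cleaning and quality control for ROI time series.

The pipeline mirrors a standard movie-fMRI denoising sequence: artifact
detection from framewise displacement (FD) and global-signal excursions,
temporal interpolation over flagged TRs, nuisance principal-component
regression, simultaneous band-pass filtering and polynomial detrending as a
single least-squares projection, removal of the initial (opening-credits)
TRs, motion scrubbing, and subject-level exclusion by mean FD.

Scrubbing is recorded as a TR mask rather than deletion so that child and
adult time series stay aligned for inter-subject correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd
from numpy.polynomial import legendre

from .core import Cohort, SubjectRecord


@dataclass
class PrepConfig:
    """Thresholds and filter settings.

    ``fd_artifact_mm`` flags artifact TRs (interpolated), ``scrub_fd_mm``
    marks scrubbed TRs (masked during correlation), ``exclude_mean_fd_mm``
    drops whole subjects. The band edges are in Hz; ``fd_rotation_radius_mm``
    converts rotations to arc-length displacement.
    """

    fd_artifact_mm: float = 2.0
    global_signal_sd: float = 3.0
    scrub_fd_mm: float = 1.0
    exclude_mean_fd_mm: float = 0.5
    drop_initial_trs: int = 10
    band_low_hz: float = 0.008
    band_high_hz: float = 0.15
    detrend_orders: tuple[int, ...] = (1, 2)
    n_nuisance_pcs: int = 5
    fd_rotation_radius_mm: float = 50.0

    def __post_init__(self) -> None:
        if not (0.0 < self.band_low_hz < self.band_high_hz):
            raise ValueError("require 0 < band_low_hz < band_high_hz")
        for name in ("fd_artifact_mm", "global_signal_sd", "scrub_fd_mm",
                     "exclude_mean_fd_mm", "fd_rotation_radius_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SubjectQC:
    subject_id: str
    fd_series: np.ndarray
    mean_fd: float
    artifact_tr_indices: np.ndarray
    scrubbed_tr_indices: np.ndarray
    excluded: bool
    reason: str = ""


@dataclass
class QCReport:
    subjects: dict[str, SubjectQC] = field(default_factory=dict)

    @property
    def n_retained(self) -> int:
        return sum(not q.excluded for q in self.subjects.values())

    @property
    def n_excluded(self) -> int:
        return sum(q.excluded for q in self.subjects.values())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"subject_id": q.subject_id, "mean_fd": q.mean_fd,
             "n_artifact_trs": len(q.artifact_tr_indices),
             "n_scrubbed_trs": len(q.scrubbed_tr_indices),
             "excluded": q.excluded, "reason": q.reason}
            for q in self.subjects.values()
        ])


def compute_fd(motion_params: np.ndarray, rotation_radius_mm: float = 50.0) -> np.ndarray:
    """Framewise displacement per TR, in mm.

    fd[t] = sum |Δtranslation| + radius * sum |Δrotation|, with fd[0] = 0;
    rotations (radians) become arc length on a sphere of the given radius.
    """
    m = np.asarray(motion_params, dtype=float)
    if m.ndim != 2 or m.shape[1] != 6:
        raise ValueError("motion parameters must be TR x 6")
    if m.shape[0] < 2:
        raise ValueError("need at least 2 TRs")
    d = np.abs(np.diff(m, axis=0))
    fd = d[:, :3].sum(axis=1) + rotation_radius_mm * d[:, 3:].sum(axis=1)
    return np.concatenate([[0.0], fd])


def detect_artifacts(timeseries: np.ndarray, fd_series: np.ndarray,
                     config: PrepConfig | None = None) -> np.ndarray:
    """TR indices with fd > threshold or |global-signal z| > threshold.

    The global signal is the ROI mean per TR, z-scored against the subject's
    own mean/SD; a constant global signal yields no z-flags.
    """
    config = config or PrepConfig()
    ts = np.asarray(timeseries, dtype=float)
    fd = np.asarray(fd_series, dtype=float)
    if fd.shape[0] != ts.shape[0]:
        raise ValueError("fd_series is not aligned with the timeseries")
    gs = ts.mean(axis=1)
    sd = gs.std()
    z = np.zeros_like(gs) if sd == 0 else (gs - gs.mean()) / sd
    flagged = (fd > config.fd_artifact_mm) | (np.abs(z) > config.global_signal_sd)
    return np.flatnonzero(flagged)


def interpolate_artifacts(timeseries: np.ndarray, artifact_tr_indices) -> np.ndarray:
    """Replace flagged TRs by linear interpolation between clean neighbors.

    Boundary flags take the nearest clean value; clean TRs pass through
    unchanged.
    """
    ts = np.asarray(timeseries, dtype=float)
    flagged = np.zeros(ts.shape[0], dtype=bool)
    flagged[np.asarray(artifact_tr_indices, dtype=int)] = True
    if not flagged.any():
        return ts.copy()
    clean = np.flatnonzero(~flagged)
    if clean.size == 0:
        raise ValueError("all TRs flagged as artifacts; nothing to interpolate from")
    out = ts.copy()
    bad = np.flatnonzero(flagged)
    for r in range(ts.shape[1]):
        out[bad, r] = np.interp(bad, clean, ts[clean, r])
    return out


def regress_nuisance_pcs(timeseries: np.ndarray, nuisance_matrix: np.ndarray,
                         n_pcs: int) -> np.ndarray:
    """Remove the first ``n_pcs`` principal components of the nuisance matrix.

    The nuisance matrix is column-centered before PCA; residuals are centered
    (intercept removed) and orthogonal to the retained components.
    """
    ts = np.asarray(timeseries, dtype=float)
    nuis = np.asarray(nuisance_matrix, dtype=float)
    if nuis.shape[0] != ts.shape[0]:
        raise ValueError("nuisance matrix must have the same number of TRs")
    nc = nuis - nuis.mean(axis=0)
    u, s, _ = np.linalg.svd(nc, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-10)) if s.size and s[0] > 0 else 0
    if n_pcs > rank:
        raise ValueError(f"n_pcs={n_pcs} exceeds nuisance rank {rank}")
    pcs = u[:, :n_pcs]
    tc = ts - ts.mean(axis=0)
    return tc - pcs @ (pcs.T @ tc)


def _filter_regressors(n_trs: int, tr_seconds: float, config: PrepConfig) -> np.ndarray:
    """Legendre trends plus out-of-band DFT sinusoids (3dTproject construction)."""
    t = np.linspace(-1.0, 1.0, n_trs)
    cols = [legendre.legval(t, np.eye(order + 1)[order])
            for order in (0, *config.detrend_orders)]
    freqs = np.arange(1, n_trs // 2 + 1) / (n_trs * tr_seconds)
    out_of_band = (freqs < config.band_low_hz) | (freqs > config.band_high_hz)
    if not np.any(~out_of_band):
        removable = ", ".join(f"{f:.5f}" for f in freqs)
        raise ValueError(
            "band admits no DFT frequency for this series length; "
            f"removable frequencies are: {removable} Hz")
    idx = np.arange(n_trs)
    for j in np.flatnonzero(out_of_band) + 1:
        phase = 2.0 * np.pi * j * idx / n_trs
        cols.append(np.cos(phase))
        if 2 * j != n_trs:  # the Nyquist sine is identically zero on the grid
            cols.append(np.sin(phase))
    return np.column_stack(cols)


def bandpass_detrend(timeseries: np.ndarray, tr_seconds: float,
                     config: PrepConfig | None = None) -> np.ndarray:
    """Simultaneous band-pass filter and polynomial detrend.

    Implemented as one least-squares projection removing Legendre polynomials
    (orders 0..2 by default) and sine/cosine regressors at every DFT frequency
    outside [band_low_hz, band_high_hz]. Being an orthogonal projection, the
    operation is idempotent.
    """
    config = config or PrepConfig()
    ts = np.asarray(timeseries, dtype=float)
    if ts.shape[0] < 8:
        raise ValueError("need at least 8 TRs to band-pass filter")
    reg = _filter_regressors(ts.shape[0], tr_seconds, config)
    q, _ = np.linalg.qr(reg)
    return ts - q @ (q.T @ ts)


def apply_qc(cohort: Cohort, config: PrepConfig | None = None,
             tr_seconds: float = 2.0) -> tuple[Cohort, QCReport]:
    """Run the full per-subject cleaning sequence and subject-level QC.

    Order: artifact detection -> interpolation -> nuisance-PC regression (on
    the motion parameters, when present) -> band-pass + detrend -> drop the
    first ``drop_initial_trs`` TRs -> mark the scrub mask (FD > scrub
    threshold) -> exclude subjects with mean FD above threshold or with fewer
    than 10 usable TRs. Scrubbed TRs stay in the stored series and are masked
    at correlation time.
    """
    config = config or PrepConfig()
    report = QCReport()
    kept: list[SubjectRecord] = []
    for subj in cohort.subjects:
        if subj.motion_params is not None:
            fd = compute_fd(subj.motion_params, config.fd_rotation_radius_mm)
        else:
            fd = np.zeros(subj.n_trs)
        mean_fd = float(fd.mean())
        artifacts = detect_artifacts(subj.timeseries, fd, config)

        if mean_fd > config.exclude_mean_fd_mm:
            report.subjects[subj.subject_id] = SubjectQC(
                subj.subject_id, fd, mean_fd, artifacts, np.array([], int),
                excluded=True, reason=f"mean FD {mean_fd:.3f} mm > {config.exclude_mean_fd_mm} mm")
            continue
        if len(artifacts) == subj.n_trs:
            report.subjects[subj.subject_id] = SubjectQC(
                subj.subject_id, fd, mean_fd, artifacts, np.array([], int),
                excluded=True, reason="every TR flagged as artifact")
            continue

        ts = interpolate_artifacts(subj.timeseries, artifacts)
        if subj.motion_params is not None and config.n_nuisance_pcs > 0:
            centered = subj.motion_params - subj.motion_params.mean(axis=0)
            n_pcs = min(config.n_nuisance_pcs, int(np.linalg.matrix_rank(centered)))
            if n_pcs > 0:
                ts = regress_nuisance_pcs(ts, subj.motion_params, n_pcs)
        ts = bandpass_detrend(ts, tr_seconds, config)

        drop = config.drop_initial_trs
        ts = ts[drop:]
        fd_kept = fd[drop:]
        motion = subj.motion_params[drop:] if subj.motion_params is not None else None
        scrub_mask = fd_kept > config.scrub_fd_mm
        usable = int((~scrub_mask).sum())
        scrub_idx = np.flatnonzero(scrub_mask)
        if usable < 10:
            report.subjects[subj.subject_id] = SubjectQC(
                subj.subject_id, fd, mean_fd, artifacts, scrub_idx,
                excluded=True, reason=f"only {usable} usable TRs after scrubbing")
            continue

        report.subjects[subj.subject_id] = SubjectQC(
            subj.subject_id, fd, mean_fd, artifacts, scrub_idx, excluded=False)
        kept.append(dc_replace(
            subj, timeseries=ts, motion_params=motion, mean_fd=mean_fd,
            valid_tr_mask=~scrub_mask))
    return Cohort(subjects=kept, roi_labels=list(cohort.roi_labels),
                  ground_truth=cohort.ground_truth), report


def extract_roi_timeseries(image_4d: np.ndarray, atlas_labels: np.ndarray,
                           group_mask: np.ndarray, min_voxels: int = 5):
    """Mean ROI time series from a 4-D image with a labeled atlas.

    Each ROI mask is dilated by one voxel along each axis (6-neighborhood),
    then intersected with the binary group mask. Voxels claimed by several
    dilated ROIs go to the ROI whose original mask is nearer (ties to the
    lower label id). ROIs left with fewer than ``min_voxels`` voxels are
    dropped and reported.

    Returns ``(timeseries TR x ROI, kept_labels, dropped_labels)``.
    """
    from scipy import ndimage

    img = np.asarray(image_4d, dtype=float)
    atlas = np.asarray(atlas_labels)
    mask = np.asarray(group_mask).astype(bool)
    if img.shape[:3] != atlas.shape or atlas.shape != mask.shape:
        raise ValueError("image, atlas and mask must share the same 3-D grid")

    structure = ndimage.generate_binary_structure(3, 1)
    labels = [int(v) for v in np.unique(atlas) if v != 0]
    best_dist = np.full(atlas.shape, np.inf)
    assign = np.zeros(atlas.shape, dtype=int)
    for lab in labels:  # ascending order: strict '<' gives ties to lower ids
        roi = atlas == lab
        dilated = ndimage.binary_dilation(roi, structure=structure)
        dist = ndimage.distance_transform_edt(~roi)
        closer = dilated & (dist < best_dist)
        best_dist[closer] = dist[closer]
        assign[closer] = lab

    kept, dropped, series = [], [], []
    for lab in labels:
        voxels = (assign == lab) & mask
        if voxels.sum() < min_voxels:
            dropped.append(lab)
            continue
        kept.append(lab)
        series.append(img[voxels].mean(axis=0))
    ts = np.column_stack(series) if series else np.empty((img.shape[3], 0))
    return ts, kept, dropped
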