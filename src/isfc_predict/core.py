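"""Shared domain containers: one subject's recording and a multi-subject cohort.

A cohort is partitioned into a *target* group (children, who carry a behavioral
score) and a *reference* group (adults, whose time-locked responses define the
inter-subject reference signal).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CHILD = "child"
ADULT = "adult"

MOTION_COLUMNS = ("trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z")


@dataclass
class SubjectRecord:
    """One subject's ROI time series plus phenotype and quality metadata.

    ``timeseries`` is a TR x ROI matrix in arbitrary BOLD-like units.
    ``motion_params`` (optional) is TR x 6: three translations in mm followed by
    three rotations in radians. ``score`` is a proportion in [0, 1] and is only
    present for children. ``valid_tr_mask`` marks TRs admissible for correlation
    (scrubbing is masking, not deletion, so child/adult TR alignment survives).
    """

    subject_id: str
    group: str
    timeseries: np.ndarray
    motion_params: np.ndarray | None = None
    age: float = float("nan")
    gender: str = "F"
    handedness: str = "R"
    score: float | None = None
    mean_fd: float | None = None
    valid_tr_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.timeseries = np.asarray(self.timeseries, dtype=float)
        if self.timeseries.ndim != 2:
            raise ValueError(f"{self.subject_id}: timeseries must be 2-D (TR x ROI)")
        if self.timeseries.shape[0] < 2 or self.timeseries.shape[1] < 2:
            raise ValueError(f"{self.subject_id}: need >=2 TRs and >=2 ROIs")
        if not np.all(np.isfinite(self.timeseries)):
            raise ValueError(f"{self.subject_id}: non-finite values in timeseries")
        if self.group not in (CHILD, ADULT):
            raise ValueError(f"{self.subject_id}: group must be 'child' or 'adult'")
        if self.motion_params is not None:
            self.motion_params = np.asarray(self.motion_params, dtype=float)
            if self.motion_params.shape != (self.timeseries.shape[0], 6):
                raise ValueError(
                    f"{self.subject_id}: motion_params must be TR x 6 aligned with the timeseries"
                )

    @property
    def n_trs(self) -> int:
        return self.timeseries.shape[0]

    @property
    def n_rois(self) -> int:
        return self.timeseries.shape[1]

    def tr_mask(self) -> np.ndarray:
        """Boolean mask of admissible TRs (all-true when nothing was scrubbed)."""
        if self.valid_tr_mask is None:
            return np.ones(self.n_trs, dtype=bool)
        return np.asarray(self.valid_tr_mask, dtype=bool)


@dataclass
class Cohort:
    """A set of subjects with shared ROI labels.

    ``ground_truth`` (synthetic cohorts only) records the generating
    configuration, the true feature weights behind the behavioral score, and
    the monotone squashing applied to map raw scores into [0, 1].
    """

    subjects: list[SubjectRecord]
    roi_labels: list[str]
    ground_truth: dict | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        r = len(self.roi_labels)
        for s in self.subjects:
            if s.n_rois != r:
                raise ValueError(
                    f"subject {s.subject_id} has {s.n_rois} ROIs, cohort declares {r}"
                )
        for s in self.children:
            if s.score is None:
                raise ValueError(f"child {s.subject_id} lacks a behavioral score")

    @property
    def children(self) -> list[SubjectRecord]:
        return [s for s in self.subjects if s.group == CHILD]

    @property
    def adults(self) -> list[SubjectRecord]:
        return [s for s in self.subjects if s.group == ADULT]

    @property
    def n_rois(self) -> int:
        return len(self.roi_labels)
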