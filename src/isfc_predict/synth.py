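"""Synthetic multi-subject cohort generator.

Each subject's ROI signal decomposes additively into three sources::

    x_{s,r}(t) = lambda_{s,r} * S_r(t) + I_{s,r}(t) + N_{s,r}(t)

where ``S`` is a stimulus-evoked signal drawn once per cohort and shared by
every subject (scaled by subject/ROI loadings ``lambda``), ``I`` is an
intrinsic signal drawn independently per subject with a subject-specific
"fingerprint" covariance, and ``N`` is white noise. Because ``I`` and ``N``
are independent across subjects, only the ``S``-driven coupling survives in
inter-subject correlations — the premise the downstream ISFC analysis rests
on — while intra-subject FC mixes stimulus coupling with the fingerprint.

``S`` and ``I`` are AR(1)-smoothed Gaussian processes so that band-pass
filtering has a realistic effect on them. Behavioral scores are a declared
linear function of the cohort's standardized connectivity features plus
covariate effects and noise, squashed monotonically into [0, 1] like a
proportion-correct test score.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ADULT, CHILD, MOTION_COLUMNS, Cohort, SubjectRecord

SPIKE_TRANSLATION_MM = 3.0


def exchangeable_cov(n: int, rho: float) -> np.ndarray:
    """Unit-diagonal covariance with constant off-diagonal correlation."""
    cov = np.full((n, n), rho)
    np.fill_diagonal(cov, 1.0)
    return cov


@dataclass
class SynthConfig:
    """Generator configuration; defaults mirror the study's scale.

    A movie-viewing cohort: 90 children and 32 adults, 32 usable social-brain
    ROIs, 168 retained TRs at TR = 2 s. ``stimulus_cov``/``intrinsic_base_cov``
    default to exchangeable correlation matrices; ``None`` selects those
    defaults. ``effect_spec`` maps feature names (``FC:a-b``, ``ISFC:a-b``,
    ``ISC:a``) to the weights with which the standardized feature enters the
    behavioral score.
    """

    n_children: int = 90
    n_adults: int = 32
    n_rois: int = 32
    n_trs: int = 168
    tr_seconds: float = 2.0
    stimulus_cov: np.ndarray | None = None
    loading_mean: float = 1.0
    loading_sd: float = 0.25
    intrinsic_base_cov: np.ndarray | None = None
    fingerprint_sd: float = 0.3
    fingerprint_structure: float = 0.5
    noise_sd: float = 1.0
    ar1_coef: float = 0.6
    spike_rate: float = 0.02
    effect_spec: dict = field(default_factory=dict)
    covariate_effects: dict = field(default_factory=dict)
    score_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_children", "n_adults", "n_rois", "n_trs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 <= self.ar1_coef < 1.0):
            raise ValueError("ar1_coef must be in [0, 1)")
        if not (0.0 <= self.spike_rate <= 1.0):
            raise ValueError("spike_rate must be a probability")
        if not (0.0 <= self.fingerprint_structure <= 1.0):
            raise ValueError("fingerprint_structure must be in [0, 1]")
        if self.stimulus_cov is None:
            self.stimulus_cov = exchangeable_cov(self.n_rois, 0.3)
        if self.intrinsic_base_cov is None:
            self.intrinsic_base_cov = exchangeable_cov(self.n_rois, 0.2)
        self.stimulus_cov = _validate_cov(np.asarray(self.stimulus_cov, float),
                                          "stimulus_cov", self.n_rois)
        self.intrinsic_base_cov = _validate_cov(np.asarray(self.intrinsic_base_cov, float),
                                                "intrinsic_base_cov", self.n_rois)

    def roi_labels(self) -> list[str]:
        return [f"ROI{i + 1:02d}" for i in range(self.n_rois)]

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["stimulus_cov"] = np.asarray(self.stimulus_cov).tolist()
        d["intrinsic_base_cov"] = np.asarray(self.intrinsic_base_cov).tolist()
        return d


def _validate_cov(cov: np.ndarray, name: str, n: int) -> np.ndarray:
    if cov.shape != (n, n):
        raise ValueError(f"{name} must be {n}x{n}")
    if not np.allclose(cov, cov.T, atol=1e-10):
        raise ValueError(f"{name} must be symmetric")
    w = np.linalg.eigvalsh(cov)
    if w.min() < -1e-8 * max(1.0, abs(w.max())):
        raise ValueError(f"{name} must be positive semi-definite")
    diag = np.diag(cov)
    if np.ptp(diag) > 1e-10:
        raise ValueError(f"{name} must have a constant diagonal")
    return cov


def _psd_sqrt(cov: np.ndarray) -> np.ndarray:
    """Symmetric square root with negative eigenvalues clipped to zero."""
    w, v = np.linalg.eigh(cov)
    return v @ np.diag(np.sqrt(np.clip(w, 0.0, None))) @ v.T


def _ar1_process(rng: np.random.Generator, n_trs: int, sqrt_cov: np.ndarray,
                 phi: float) -> np.ndarray:
    """AR(1)-in-time Gaussian process with stationary spatial covariance."""
    n = sqrt_cov.shape[0]
    innov = rng.standard_normal((n_trs, n)) @ sqrt_cov.T
    if phi == 0.0:
        return innov
    out = np.empty_like(innov)
    out[0] = innov[0]
    scale = np.sqrt(1.0 - phi * phi)
    for t in range(1, n_trs):
        out[t] = phi * out[t - 1] + scale * innov[t]
    return out


def _motion(rng: np.random.Generator, n_trs: int, spike_rate: float) -> np.ndarray:
    """Slow random-walk head motion with occasional large translation steps."""
    steps = np.hstack([
        rng.normal(0.0, 0.02, size=(n_trs, 3)),   # translations, mm
        rng.normal(0.0, 4e-4, size=(n_trs, 3)),   # rotations, radians
    ])
    steps[0] = 0.0
    if spike_rate > 0 and n_trs > 1:
        spikes = rng.random(n_trs - 1) < spike_rate
        axes = rng.integers(0, 3, size=int(spikes.sum()))
        signs = rng.choice([-1.0, 1.0], size=int(spikes.sum()))
        rows = np.flatnonzero(spikes) + 1
        steps[rows, axes] += signs * SPIKE_TRANSLATION_MM
    return np.cumsum(steps, axis=0)


def generate_cohort(config: SynthConfig) -> Cohort:
    """Draw a cohort under the shared-signal + intrinsic + noise model.

    ``S`` is drawn once; children and adults differ only in their loadings,
    fingerprints, phenotypes, and the presence of a behavioral score. The same
    config and seed always reproduce a bit-identical cohort.
    """
    rng = np.random.default_rng(config.seed)
    labels = config.roi_labels()
    sqrt_stim = _psd_sqrt(config.stimulus_cov)
    shared = _ar1_process(rng, config.n_trs, sqrt_stim, config.ar1_coef)

    subjects: list[SubjectRecord] = []
    groups = [CHILD] * config.n_children + [ADULT] * config.n_adults
    for idx, group in enumerate(groups):
        lam = rng.normal(config.loading_mean, config.loading_sd, size=config.n_rois)
        # Fingerprint = shared-axis + idiosyncratic perturbation. The shared
        # axis (uniform off-diagonal coupling, subject position u_s) emulates
        # the dominant integration-segregation dimension along which intrinsic
        # connectomes empirically vary; the idiosyncratic part is symmetric
        # white noise on the edges.
        pert = rng.standard_normal((config.n_rois, config.n_rois))
        u_s = rng.standard_normal()
        a = config.fingerprint_structure
        axis = np.ones((config.n_rois, config.n_rois)) - np.eye(config.n_rois)
        perturbation = (1.0 - a) * (pert + pert.T) / 2.0 + a * u_s * axis
        cov_i = config.intrinsic_base_cov + config.fingerprint_sd * perturbation
        intrinsic = _ar1_process(rng, config.n_trs, _psd_sqrt(cov_i), config.ar1_coef)
        noise = config.noise_sd * rng.standard_normal((config.n_trs, config.n_rois))
        ts = lam * shared + intrinsic + noise
        if group == CHILD:
            age = rng.uniform(4.0, 12.0)
        else:
            age = rng.uniform(18.0, 39.0)
        subjects.append(SubjectRecord(
            subject_id=f"sub-{idx + 1:03d}",
            group=group,
            timeseries=ts,
            motion_params=_motion(rng, config.n_trs, config.spike_rate),
            age=float(age),
            gender=str(rng.choice(["F", "M"])),
            handedness=str(rng.choice(["R", "L"], p=[0.9, 0.1])),
            score=0.0 if group == CHILD else None,  # placeholder, set below
        ))

    ground_truth = _assign_scores(rng, subjects, labels, config)
    return Cohort(subjects=subjects, roi_labels=labels, ground_truth=ground_truth)


def _assign_scores(rng: np.random.Generator, subjects: list[SubjectRecord],
                   labels: list[str], config: SynthConfig) -> dict:
    """Build child scores as a linear effect on standardized features.

    Raw score = sum_f w_f z_f + covariate effects + N(0, score_noise_sd), then
    an affine clamp (offset at the cohort mean, slope 1/(8 SD)) maps it into
    [0, 1]; the clamp is monotone so rank-based evaluation is unaffected, and
    its parameters are stored in ``ground_truth`` so the linear effects remain
    recoverable.
    """
    from .connectivity import cohort_feature_table, standardize_features

    children = [s for s in subjects if s.group == CHILD]
    names: list[str] = []
    z = None
    if config.effect_spec:
        cohort = Cohort(subjects=subjects, roi_labels=labels)
        table, _ = cohort_feature_table(cohort)
        missing = [f for f in config.effect_spec if f not in table.columns]
        if missing:
            raise ValueError(f"effect_spec names unknown features: {missing}")
        names = list(config.effect_spec)
        std, _, _ = standardize_features(table[names], np.arange(len(children)))
        z = np.asarray(std)

    raw = np.zeros(len(children))
    if z is not None:
        raw += z @ np.array([config.effect_spec[f] for f in names])

    cov_design = _covariate_design(children)
    for key, weight in config.covariate_effects.items():
        if key not in cov_design:
            raise ValueError(f"unknown covariate effect {key!r}")
        raw += weight * cov_design[key]
    raw += config.score_noise_sd * rng.standard_normal(len(children))

    mean = float(raw.mean())
    sd = float(raw.std())
    scale = 1.0 / (8.0 * sd) if sd > 0 else 1.0
    scores = np.clip(0.5 + scale * (raw - mean), 0.0, 1.0)
    for child, s in zip(children, scores):
        child.score = float(s)

    return {
        "config": config.to_jsonable(),
        "effect_spec": dict(config.effect_spec),
        "covariate_effects": dict(config.covariate_effects),
        "squash_offset": mean,
        "squash_scale": scale,
    }


def _covariate_design(children: list[SubjectRecord]) -> dict[str, np.ndarray]:
    """Standardized covariate columns used by the score construction."""
    age = np.array([s.age for s in children], float)
    age2 = age ** 2
    gender = np.array([1.0 if s.gender == "M" else 0.0 for s in children])
    hand = np.array([1.0 if s.handedness == "L" else 0.0 for s in children])

    def _z(v: np.ndarray) -> np.ndarray:
        sd = v.std()
        return (v - v.mean()) / sd if sd > 0 else v - v.mean()

    return {"age": _z(age), "age2": _z(age2),
            "gender": gender - gender.mean(), "handedness": hand - hand.mean()}


# ---------------------------------------------------------------------------
# cohort directory I/O

_PARTICIPANT_COLUMNS = ["subject_id", "group", "age", "gender", "handedness",
                        "score", "mean_fd"]


def write_cohort(cohort: Cohort, directory) -> list[Path]:
    """Write the cohort directory layout; returns the files written.

    Layout: ``participants.tsv``, one ``<id>_timeseries.tsv`` per subject
    (header = ROI labels), optional ``<id>_motion.tsv``, and
    ``ground_truth.json`` for synthetic cohorts. Floats are written with
    round-trip precision.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    rows = []
    for s in cohort.subjects:
        rows.append({
            "subject_id": s.subject_id, "group": s.group, "age": s.age,
            "gender": s.gender, "handedness": s.handedness,
            "score": s.score if s.score is not None else "",
            "mean_fd": s.mean_fd if s.mean_fd is not None else "",
        })
    ptable = directory / "participants.tsv"
    pd.DataFrame(rows, columns=_PARTICIPANT_COLUMNS).to_csv(ptable, sep="\t", index=False)
    written.append(ptable)

    for s in cohort.subjects:
        ts_path = directory / f"{s.subject_id}_timeseries.tsv"
        pd.DataFrame(s.timeseries, columns=cohort.roi_labels).to_csv(
            ts_path, sep="\t", index=False, float_format="%.17g")
        written.append(ts_path)
        if s.motion_params is not None:
            mo_path = directory / f"{s.subject_id}_motion.tsv"
            pd.DataFrame(s.motion_params, columns=list(MOTION_COLUMNS)).to_csv(
                mo_path, sep="\t", index=False, float_format="%.17g")
            written.append(mo_path)

    if cohort.ground_truth is not None:
        gt_path = directory / "ground_truth.json"
        gt_path.write_text(json.dumps(cohort.ground_truth, indent=1))
        written.append(gt_path)
    return written


def read_cohort(directory) -> Cohort:
    """Read a cohort directory written by :func:`write_cohort`."""
    directory = Path(directory)
    ptable = directory / "participants.tsv"
    if not ptable.exists():
        raise FileNotFoundError(f"missing participants table: {ptable}")
    part = pd.read_csv(ptable, sep="\t", dtype={"subject_id": str})
    for col in ("subject_id", "group"):
        if col not in part.columns:
            raise ValueError(f"participants.tsv lacks required column {col!r}")

    subjects: list[SubjectRecord] = []
    roi_labels: list[str] | None = None
    for i, row in part.iterrows():
        sid = row["subject_id"]
        ts_path = directory / f"{sid}_timeseries.tsv"
        if not ts_path.exists():
            raise FileNotFoundError(
                f"subject {sid!r} listed in participants.tsv but {ts_path.name} is absent")
        ts = pd.read_csv(ts_path, sep="\t", float_precision="round_trip")
        try:
            values = ts.to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"non-numeric cell in {ts_path.name}: {exc}") from exc
        if roi_labels is None:
            roi_labels = list(ts.columns)
        elif list(ts.columns) != roi_labels:
            raise ValueError(f"{ts_path.name}: ROI labels differ from the first subject's")

        motion = None
        mo_path = directory / f"{sid}_motion.tsv"
        if mo_path.exists():
            mo = pd.read_csv(mo_path, sep="\t", float_precision="round_trip")
            if list(mo.columns) != list(MOTION_COLUMNS):
                raise ValueError(f"{mo_path.name}: expected columns {MOTION_COLUMNS}")
            motion = mo.to_numpy(dtype=float)

        def _opt(key):
            v = row.get(key, "")
            return None if pd.isna(v) or v == "" else float(v)

        subjects.append(SubjectRecord(
            subject_id=sid, group=str(row["group"]), timeseries=values,
            motion_params=motion,
            age=float(row["age"]) if "age" in part.columns and not pd.isna(row["age"]) else float("nan"),
            gender=str(row.get("gender", "F")),
            handedness=str(row.get("handedness", "R")),
            score=_opt("score"), mean_fd=_opt("mean_fd"),
        ))

    gt_path = directory / "ground_truth.json"
    ground_truth = json.loads(gt_path.read_text()) if gt_path.exists() else None
    return Cohort(subjects=subjects, roi_labels=roi_labels or [], ground_truth=ground_truth)
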