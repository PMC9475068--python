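"""Shared builders for the test suite.

All cohorts are generated at runtime from seeds; nothing is read from disk.
The "two-source" regime plants behavioral signal in both measures with
within-measure redundancy (a stimulus hub drives correlated ISFC features; the
shared fingerprint axis drives correlated FC features), mirroring the
complementarity the joint model is meant to exploit. The "planted-ROI" regime
confines all signal to three regions for the leave-one-region-out analysis.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import isfc_predict as ip


def hub_stimulus_cov(n_rois: int, hub: int = -1, rho: float = 0.35) -> np.ndarray:
    """Identity plus hub-spoke stimulus correlations (spokes mutually silent)."""
    cov = np.eye(n_rois)
    hub = hub % n_rois
    for j in range(n_rois):
        if j != hub:
            cov[j, hub] = cov[hub, j] = rho
    return cov


def two_source_effects() -> dict[str, float]:
    """Score effects: FC edges among ROIs 1-4 plus the ISFC hub at ROI 8."""
    eff = {f"FC:ROI0{a}-ROI0{b}": 1.0 for a in range(1, 5) for b in range(a + 1, 5)}
    eff.update({f"ISFC:ROI0{j}-ROI08": 1.0 for j in range(1, 8)})
    eff["ISC:ROI08"] = 1.0
    return eff


def two_source_cohort(seed: int, n_children: int = 40) -> ip.Cohort:
    cfg = ip.SynthConfig(
        n_children=n_children, n_adults=8, n_rois=8, n_trs=120, seed=seed,
        stimulus_cov=hub_stimulus_cov(8), loading_sd=0.3, fingerprint_sd=0.8,
        noise_sd=0.8, spike_rate=0.0, score_noise_sd=0.4,
        effect_spec=two_source_effects())
    return ip.generate_cohort(cfg)


def planted_roi_effects() -> dict[str, float]:
    """All behavioral signal confined to ROIs 1-3 (FC + ISFC edges + ISC)."""
    eff = {}
    for a in range(1, 4):
        for b in range(a + 1, 4):
            eff[f"FC:ROI0{a}-ROI0{b}"] = 1.0
            eff[f"ISFC:ROI0{a}-ROI0{b}"] = 1.0
        eff[f"ISC:ROI0{a}"] = 1.0
    return eff


def planted_roi_cohort(seed: int, n_children: int = 40) -> ip.Cohort:
    cfg = ip.SynthConfig(
        n_children=n_children, n_adults=8, n_rois=8, n_trs=120, seed=seed,
        loading_sd=0.3, fingerprint_sd=0.8, fingerprint_structure=0.0,
        noise_sd=0.8, spike_rate=0.0, score_noise_sd=0.3,
        effect_spec=planted_roi_effects())
    return ip.generate_cohort(cfg)


def null_cohort(seed: int, n_children: int = 24, n_rois: int = 6,
                n_trs: int = 100, n_adults: int = 4) -> ip.Cohort:
    """Scores independent of all connectivity features."""
    cfg = ip.SynthConfig(
        n_children=n_children, n_adults=n_adults, n_rois=n_rois, n_trs=n_trs,
        seed=seed, loading_sd=0.3, spike_rate=0.0, score_noise_sd=0.3)
    return ip.generate_cohort(cfg)


def features_and_scores(cohort: ip.Cohort) -> tuple[pd.DataFrame, np.ndarray]:
    table, _ = ip.cohort_feature_table(cohort)
    y = np.array([s.score for s in cohort.children])
    return table, y


def noise_free_config(**overrides) -> ip.SynthConfig:
    """Shared-signal-only limit: every subject's series equals S exactly."""
    n_rois = overrides.pop("n_rois", 6)
    kw = dict(n_children=3, n_adults=2, n_rois=n_rois, n_trs=60,
              loading_mean=1.0, loading_sd=0.0,
              intrinsic_base_cov=np.zeros((n_rois, n_rois)), fingerprint_sd=0.0,
              noise_sd=0.0, spike_rate=0.0, score_noise_sd=0.0, seed=7)
    kw.update(overrides)
    return ip.SynthConfig(**kw)


@pytest.fixture
def small_cohort() -> ip.Cohort:
    cfg = ip.SynthConfig(n_children=8, n_adults=3, n_rois=5, n_trs=60,
                         loading_sd=0.3, spike_rate=0.0, seed=42)
    return ip.generate_cohort(cfg)
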