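"""Synthetic paired qPCR-array Ct data with planted structure.

Generates datasets that mimic a paired tumor/adjacent-normal miRNA qPCR
array study: ~19 cases, ~667 features, a handful of truly differential
miRNAs shifted by a couple of cycles, between-case random effects, additive
per-array technical offsets (the nuisance quantile normalization exists to
remove), randomly missing wells, a 40-cycle detection ceiling, and an
optional Gleason-score subgroup structure among the malignant samples.

The qPCR sign convention is fixed here once and relied on everywhere
downstream: *increased* expression in the malignant tissue is encoded as a
*decreased* Ct (fewer cycles to cross threshold).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "generate_paired_dataset",
    "generate_null_dataset",
    "generate_gleason_dataset",
]


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the paired-Ct generative model.

    All magnitudes are in qPCR cycles.

    Parameters
    ----------
    n_cases
        Number of (normal, malignant) tissue pairs.
    n_features
        Number of miRNA assays on the array.
    n_de
        Number of truly differentially expressed features.
    effect_ct
        Ct shift magnitude applied to DE features in malignant samples.
    effect_sign_fraction_up
        Fraction of DE features up-regulated in malignant tissue
        (up-regulation = Ct decrease).
    baseline_ct_range
        Interval from which per-feature baseline mean Ct is drawn.
    case_sd
        SD of the per-case random effect shared by both tissues of a pair
        (this is what makes the design paired).
    noise_sd
        Residual well-level Gaussian SD.
    array_offset_sd
        SD of the additive per-sample-array technical shift; quantile
        normalization should remove it exactly.
    missing_rate
        Probability that a well is missing completely at random.
    ct_max
        Detection ceiling; wells beyond it are recorded as missing
        ("Undetermined"), not clamped.
    gleason_profile
        Optional mapping Gleason score -> Ct shift applied to a dedicated
        block of ``n_gleason_features`` features in malignant samples of
        cases carrying that score.
    n_gleason_features
        Size of the subgroup-feature block (disjoint from the DE block).
    seed
        RNG seed; equal configs produce bit-identical datasets.
    """

    n_cases: int = 19
    n_features: int = 667
    n_de: int = 9
    effect_ct: float = 2.0
    effect_sign_fraction_up: float = 0.5
    baseline_ct_range: tuple[float, float] = (20.0, 35.0)
    case_sd: float = 1.0
    noise_sd: float = 0.5
    array_offset_sd: float = 0.5
    missing_rate: float = 0.02
    ct_max: float = 40.0
    gleason_profile: Mapping[int, float] | None = None
    n_gleason_features: int = 16
    seed: int = 0

    def validate(self) -> None:
        if self.n_cases < 1:
            raise ConfigError("n_cases must be >= 1")
        if self.n_de < 0 or self.n_de > self.n_features:
            raise ConfigError("n_de must satisfy 0 <= n_de <= n_features")
        if not 0 <= self.missing_rate < 1:
            raise ConfigError("missing_rate must be in [0, 1)")
        for name in ("case_sd", "noise_sd", "array_offset_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not 0 <= self.effect_sign_fraction_up <= 1:
            raise ConfigError("effect_sign_fraction_up must be in [0, 1]")
        lo, hi = self.baseline_ct_range
        if not (0 < lo <= hi):
            raise ConfigError("baseline_ct_range must be an interval with 0 < low <= high")
        if self.gleason_profile is not None:
            if len(self.gleason_profile) < 2:
                raise ConfigError("gleason_profile must assign at least 2 distinct scores")
            if self.n_de + self.n_gleason_features > self.n_features:
                raise ConfigError("n_de + n_gleason_features exceeds n_features")


@dataclass
class SyntheticDataset:
    """A generated dataset plus its ground truth.

    ``truth_de`` maps DE feature IDs to their signed Ct shift in malignant
    samples (negative shift = up-regulated expression).  ``truth_subgroups``
    maps malignant sample IDs to their planted Gleason score, when present.
    """

    ct: pd.DataFrame
    annotation: pd.DataFrame
    truth_de: dict[str, float] = field(default_factory=dict)
    truth_subgroups: dict[str, int] | None = None


def _feature_ids(n: int) -> list[str]:
    return [f"MIR{i:04d}" for i in range(1, n + 1)]


def generate_paired_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Draw one paired Ct dataset from the generative model.

    Per well: ``Ct = baseline + case effect + array offset + DE shift
    (malignant wells of DE features only) + Gleason shift (if configured)
    + noise``; wells above ``ct_max`` or hit by random dropout are missing.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_feat, n_cases = config.n_features, config.n_cases
    features = _feature_ids(n_feat)
    cases = [str(i) for i in range(1, n_cases + 1)]
    normal_ids = [f"{c}N" for c in cases]
    malig_ids = [f"{c}M" for c in cases]
    samples = [s for pair in zip(normal_ids, malig_ids) for s in pair]

    lo, hi = config.baseline_ct_range
    baseline = rng.uniform(lo, hi, size=n_feat)
    case_eff = rng.normal(0.0, config.case_sd, size=n_cases)
    offsets = rng.normal(0.0, config.array_offset_sd, size=2 * n_cases)

    # signed DE shifts on the first n_de features; negative = up in malignant
    n_up = int(round(config.n_de * config.effect_sign_fraction_up))
    signs = np.array([-1.0] * n_up + [1.0] * (config.n_de - n_up))
    de_shift = np.zeros(n_feat)
    de_shift[: config.n_de] = signs * config.effect_ct
    truth_de = {features[i]: de_shift[i] for i in range(config.n_de)}

    # optional per-score shifts on a second, disjoint feature block
    truth_subgroups: dict[str, int] | None = None
    gleason_shift = np.zeros((n_feat, n_cases))
    case_scores: list[int] | None = None
    if config.gleason_profile is not None:
        scores = sorted(config.gleason_profile)
        case_scores = [scores[i % len(scores)] for i in range(n_cases)]
        block = slice(config.n_de, config.n_de + config.n_gleason_features)
        for i, sc in enumerate(case_scores):
            gleason_shift[block, i] = config.gleason_profile[sc]
        truth_subgroups = {malig_ids[i]: case_scores[i] for i in range(n_cases)}

    ct = np.empty((n_feat, 2 * n_cases))
    for i in range(n_cases):
        base = baseline + case_eff[i]
        ct[:, 2 * i] = base + offsets[2 * i]  # normal
        ct[:, 2 * i + 1] = base + offsets[2 * i + 1] + de_shift + gleason_shift[:, i]
    ct += rng.normal(0.0, config.noise_sd, size=ct.shape)

    missing = rng.random(ct.shape) < config.missing_rate
    ct[missing] = np.nan
    ct[ct > config.ct_max] = np.nan  # Undetermined: censored, never clamped

    frame = pd.DataFrame(
        ct, index=pd.Index(features, name="feature_id"), columns=samples
    )
    annot = pd.DataFrame(
        {
            "case_id": [s[:-1] for s in samples],
            "tissue_class": ["normal" if s.endswith("N") else "malignant" for s in samples],
            "gleason_score": [
                case_scores[cases.index(s[:-1])]
                if case_scores is not None and s.endswith("M")
                else np.nan
                for s in samples
            ],
            "tumor_pct": np.nan,
            "who_grade": np.nan,
            "paired": True,
        },
        index=pd.Index(samples, name="sample_id"),
    )
    return SyntheticDataset(frame, annot, truth_de, truth_subgroups)


def generate_null_dataset(config: SimulationConfig) -> SyntheticDataset:
    """A dataset with no differential expression (``truth_de`` empty)."""
    return generate_paired_dataset(replace(config, n_de=0))


def generate_gleason_dataset(config: SimulationConfig) -> SyntheticDataset:
    """A dataset whose malignant samples carry Gleason-linked subgroup shifts."""
    if config.gleason_profile is None:
        raise ConfigError("gleason_profile is required for a Gleason-structured dataset")
    return generate_paired_dataset(config)
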