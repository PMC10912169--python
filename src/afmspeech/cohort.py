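"""Synthetic labeled, subject-structured phoneme cohorts.

Stands in for real dysarthric/healthy corpora: each class has its own
distribution over the 28 generating parameters (two components x 14), each
subject draws a persistent offset from the class mean, and each phoneme
draws its parameters around the subject mean.  The default class effects are
deliberately artificial but directionally motivated: the dysarthric class
gets deeper frequency modulation (pitch instability), lower amplitude
(reduced loudness), and wider between-subject spread.

All randomness flows through one seeded generator with a fixed draw order
(classes sorted, subjects in index order, per-subject offsets before
per-phoneme draws), so cohorts are bit-reproducible from the seed.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from afmspeech.audio import write_wav
from afmspeech.evaluation import NEGATIVE_LABEL, POSITIVE_LABEL, LabeledFeatureTable
from afmspeech.features import FEATURE_NAMES
from afmspeech.signal_model import (
    AFMComponentParams,
    SampledSignal,
    ToneParams,
    synthesize_phoneme,
)

__all__ = [
    "CohortConfig",
    "Cohort",
    "PRESET_NAMES",
    "default_class_params",
    "generate_cohort",
    "preset",
    "write_cohort",
]

PRESET_NAMES = (
    "balanced-table2",
    "imbalanced-table2",
    "loso-balanced",
    "loso-imbalanced",
    "desk-small",
)

_OMEGA_LO = 5e-3
_OMEGA_HI = float(np.pi) - 5e-3
_THETA_LO = -float(np.pi)
_THETA_HI = float(np.pi) - 1e-9
_MU_AM_SUM_CAP = 0.9
_CARRIER_MIN_GAP = 0.2

# Healthy-class parameter means (c1 = low band, c2 = high band).
_HEALTHY_MEANS = {
    "c1_A": 1.0, "c1_omega_c": 0.15 * np.pi,
    "c1_mu_a1": 0.20, "c1_omega_a1": 0.035, "c1_theta_a1": 0.5,
    "c1_mu_a2": 0.10, "c1_omega_a2": 0.075, "c1_theta_a2": -1.0,
    "c1_mu_f1": 0.10, "c1_omega_f1": 0.030, "c1_theta_f1": 0.8,
    "c1_mu_f2": 0.05, "c1_omega_f2": 0.065, "c1_theta_f2": -0.6,
    "c2_A": 0.8, "c2_omega_c": 0.55 * np.pi,
    "c2_mu_a1": 0.15, "c2_omega_a1": 0.040, "c2_theta_a1": -0.3,
    "c2_mu_a2": 0.08, "c2_omega_a2": 0.085, "c2_theta_a2": 1.2,
    "c2_mu_f1": 0.08, "c2_omega_f1": 0.033, "c2_theta_f1": -1.5,
    "c2_mu_f2": 0.04, "c2_omega_f2": 0.070, "c2_theta_f2": 0.9,
}

# Additive shifts defining the dysarthric class at full effect size:
# deeper FM (unstable pitch), reduced amplitude, slightly deeper AM.
_DYSARTHRIC_SHIFTS = {
    "c1_mu_f1": +0.30, "c1_mu_f2": +0.12,
    "c2_mu_f1": +0.25, "c2_mu_f2": +0.10,
    "c1_A": -0.30, "c2_A": -0.25,
    "c1_mu_a1": +0.10, "c2_mu_a1": +0.08,
}

_HEALTHY_REL_SD = 0.05      # phoneme-level spread, fraction of scale
_DYSARTHRIC_REL_SD = 0.10   # wider within-subject variability


def _scales(means: dict[str, float]) -> dict[str, float]:
    """Per-parameter scale used for spreads: |mean|, floored for near-zero params."""
    return {k: max(abs(v), 0.05) for k, v in means.items()}


def default_class_params(effect_scale: float = 1.0) -> dict[str, dict[str, tuple[float, float]]]:
    """Per-class {parameter: (mean, sd)} maps.

    ``effect_scale`` interpolates the dysarthric class between the healthy
    distribution (0.0, the null cohort) and the full default effect (1.0).
    """
    healthy = {
        k: (v, _HEALTHY_REL_SD * s)
        for (k, v), s in zip(_HEALTHY_MEANS.items(), _scales(_HEALTHY_MEANS).values())
    }
    dys_means = {
        k: v + effect_scale * _DYSARTHRIC_SHIFTS.get(k, 0.0)
        for k, v in _HEALTHY_MEANS.items()
    }
    rel_sd = _HEALTHY_REL_SD + effect_scale * (_DYSARTHRIC_REL_SD - _HEALTHY_REL_SD)
    dys = {
        k: (v, rel_sd * s)
        for (k, v), s in zip(dys_means.items(), _scales(dys_means).values())
    }
    return {POSITIVE_LABEL: dys, NEGATIVE_LABEL: healthy}


@dataclass(frozen=True)
class CohortConfig:
    """Generation recipe for one synthetic cohort."""

    n_subjects: dict[str, int]
    phonemes_per_subject: dict[str, int]
    class_params: dict[str, dict[str, tuple[float, float]]]
    subject_effect_sd: float = 1.0   # subject offset sd as multiple of param sd
    noise_sd: float = 0.0
    n_samples: int = 1024
    sample_rate: float = 16000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.n_subjects) != set(self.phonemes_per_subject) or not self.n_subjects:
            raise ValueError("n_subjects and phonemes_per_subject must share class labels")
        for label, n in self.n_subjects.items():
            if n < 1 or self.phonemes_per_subject[label] < 1:
                raise ValueError(f"counts for class {label!r} must be >= 1")
            if label not in self.class_params:
                raise ValueError(f"no parameter distribution for class {label!r}")
        for label, dists in self.class_params.items():
            missing = set(FEATURE_NAMES) - set(dists)
            if missing:
                raise ValueError(f"class {label!r} missing distributions for {sorted(missing)}")
        if self.subject_effect_sd < 0 or self.noise_sd < 0:
            raise ValueError("spreads must be >= 0")
        if self.n_samples < 256:
            raise ValueError("n_samples must be >= 256 for resolvable components")

    @property
    def total_phonemes(self) -> dict[str, int]:
        return {
            label: self.n_subjects[label] * self.phonemes_per_subject[label]
            for label in self.n_subjects
        }


@dataclass(frozen=True)
class Cohort:
    """Generated waveforms with labels, subjects, and generating parameters."""

    signals: list[SampledSignal]
    labels: np.ndarray
    subject_ids: np.ndarray
    params: pd.DataFrame  # generating parameters, FEATURE_NAMES columns
    config: CohortConfig

    def __len__(self) -> int:
        return len(self.signals)

    def param_table(self) -> LabeledFeatureTable:
        """The generating parameters as a labeled feature table."""
        return LabeledFeatureTable(
            features=self.params, labels=self.labels, subject_ids=self.subject_ids
        )


def _clip_params(raw: dict[str, float]) -> dict[str, float]:
    """Force a raw parameter draw into the model's validity region."""
    p = dict(raw)
    for prefix in ("c1", "c2"):
        p[f"{prefix}_A"] = max(p[f"{prefix}_A"], 1e-3)
        p[f"{prefix}_omega_c"] = float(np.clip(p[f"{prefix}_omega_c"], _OMEGA_LO, _OMEGA_HI))
        for part in ("a", "f"):
            tones = []
            for i in (1, 2):
                mu = max(p[f"{prefix}_mu_{part}{i}"], 0.0)
                om = float(np.clip(p[f"{prefix}_omega_{part}{i}"], _OMEGA_LO, _OMEGA_HI))
                th = float(np.clip(p[f"{prefix}_theta_{part}{i}"], _THETA_LO, _THETA_HI))
                tones.append((om, mu, th))
            tones.sort()  # ascending tone frequency
            if tones[1][0] - tones[0][0] < 1e-4:
                tones[1] = (tones[0][0] + 1e-3, tones[1][1], tones[1][2])
            for i, (om, mu, th) in enumerate(tones, start=1):
                p[f"{prefix}_mu_{part}{i}"] = mu
                p[f"{prefix}_omega_{part}{i}"] = om
                p[f"{prefix}_theta_{part}{i}"] = th
        mu_sum = p[f"{prefix}_mu_a1"] + p[f"{prefix}_mu_a2"]
        if mu_sum >= _MU_AM_SUM_CAP:
            scale = _MU_AM_SUM_CAP / mu_sum
            p[f"{prefix}_mu_a1"] *= scale
            p[f"{prefix}_mu_a2"] *= scale
    if p["c2_omega_c"] - p["c1_omega_c"] < _CARRIER_MIN_GAP:
        p["c2_omega_c"] = min(p["c1_omega_c"] + _CARRIER_MIN_GAP, _OMEGA_HI)
    return p


def _component_from_flat(p: dict[str, float], prefix: str) -> AFMComponentParams:
    return AFMComponentParams(
        amplitude=p[f"{prefix}_A"],
        carrier=p[f"{prefix}_omega_c"],
        am_tones=(
            ToneParams(p[f"{prefix}_mu_a1"], p[f"{prefix}_omega_a1"], p[f"{prefix}_theta_a1"]),
            ToneParams(p[f"{prefix}_mu_a2"], p[f"{prefix}_omega_a2"], p[f"{prefix}_theta_a2"]),
        ),
        fm_tones=(
            ToneParams(p[f"{prefix}_mu_f1"], p[f"{prefix}_omega_f1"], p[f"{prefix}_theta_f1"]),
            ToneParams(p[f"{prefix}_mu_f2"], p[f"{prefix}_omega_f2"], p[f"{prefix}_theta_f2"]),
        ),
    )


def generate_cohort(config: CohortConfig) -> Cohort:
    """Draw subjects, then phonemes, then synthesize; reproducible from seed."""
    rng = np.random.default_rng(config.seed)
    signals: list[SampledSignal] = []
    labels: list[str] = []
    subjects: list[str] = []
    rows: list[dict[str, float]] = []

    for label in sorted(config.n_subjects):
        dists = config.class_params[label]
        short = "dys" if label == POSITIVE_LABEL else "hc"
        for s in range(config.n_subjects[label]):
            subject_id = f"{short}{s + 1:03d}"
            offsets = {
                name: rng.normal(0.0, config.subject_effect_sd * sd)
                for name, (_, sd) in ((n, dists[n]) for n in FEATURE_NAMES)
            }
            for _ in range(config.phonemes_per_subject[label]):
                raw = {
                    name: dists[name][0] + offsets[name] + rng.normal(0.0, dists[name][1])
                    for name in FEATURE_NAMES
                }
                p = _clip_params(raw)
                noise_seed = int(rng.integers(0, 2**31 - 1))
                sig = synthesize_phoneme(
                    _component_from_flat(p, "c1"),
                    _component_from_flat(p, "c2"),
                    n_samples=config.n_samples,
                    noise_sd=config.noise_sd,
                    seed=noise_seed,
                    sample_rate=config.sample_rate,
                )
                signals.append(sig)
                labels.append(label)
                subjects.append(subject_id)
                rows.append(p)

    return Cohort(
        signals=signals,
        labels=np.array(labels, dtype=object),
        subject_ids=np.array(subjects, dtype=object),
        params=pd.DataFrame(rows, columns=list(FEATURE_NAMES)),
        config=config,
    )


def preset(name: str, seed: int = 0, effect_scale: float = 1.0) -> CohortConfig:
    """Named cohort recipes mirroring the study's dataset sizes.

    - ``balanced-table2``:   2,450 dysarthric / 2,450 healthy phonemes
    - ``imbalanced-table2``: 2,450 / 1,050 (7:3 ratio)
    - ``loso-balanced``:     42 + 42 subjects
    - ``loso-imbalanced``:   42 dysarthric + 21 healthy subjects
    - ``desk-small``:        10 + 10 subjects x 10 phonemes (CI scale)
    """
    params = default_class_params(effect_scale)
    common = dict(class_params=params, seed=seed, n_samples=1024)
    if name == "balanced-table2":
        return CohortConfig(
            n_subjects={POSITIVE_LABEL: 49, NEGATIVE_LABEL: 49},
            phonemes_per_subject={POSITIVE_LABEL: 50, NEGATIVE_LABEL: 50},
            **common,
        )
    if name == "imbalanced-table2":
        return CohortConfig(
            n_subjects={POSITIVE_LABEL: 49, NEGATIVE_LABEL: 21},
            phonemes_per_subject={POSITIVE_LABEL: 50, NEGATIVE_LABEL: 50},
            **common,
        )
    if name == "loso-balanced":
        return CohortConfig(
            n_subjects={POSITIVE_LABEL: 42, NEGATIVE_LABEL: 42},
            phonemes_per_subject={POSITIVE_LABEL: 10, NEGATIVE_LABEL: 10},
            **common,
        )
    if name == "loso-imbalanced":
        return CohortConfig(
            n_subjects={POSITIVE_LABEL: 42, NEGATIVE_LABEL: 21},
            phonemes_per_subject={POSITIVE_LABEL: 10, NEGATIVE_LABEL: 10},
            **common,
        )
    if name == "desk-small":
        return CohortConfig(
            n_subjects={POSITIVE_LABEL: 10, NEGATIVE_LABEL: 10},
            phonemes_per_subject={POSITIVE_LABEL: 10, NEGATIVE_LABEL: 10},
            **common,
        )
    raise ValueError(f"unknown preset {name!r}; valid: {', '.join(PRESET_NAMES)}")


def sample_recovery_params(
    rng: np.random.Generator,
    carriers: tuple[float, float] = (0.15 * np.pi, 0.55 * np.pi),
    mu_max: float = 0.3,
) -> tuple[AFMComponentParams, AFMComponentParams]:
    """Draw one random, well-conditioned two-component parameter set.

    Intended for parameter-recovery benchmarking: carriers are fixed and well
    separated, modulation depths stay at or below ``mu_max``, tone
    frequencies are slow relative to the carriers and mutually resolvable,
    and phases are bounded away from zero so relative phase errors are
    meaningful.
    """

    def tone(w: float) -> ToneParams:
        mu = rng.uniform(0.08, mu_max / 2)
        theta = rng.uniform(0.8, 2.5) * rng.choice([-1.0, 1.0])
        return ToneParams(mu, w, theta)

    comps = []
    for carrier in carriers:
        # four mutually separated tone frequencies per component; AM and FM
        # tones sharing a frequency are not identifiable from the tracks
        freqs = 0.015 + np.cumsum(rng.uniform(0.012, 0.018, size=4))
        order = rng.permutation(4)
        am_f = np.sort(freqs[order[:2]])
        fm_f = np.sort(freqs[order[2:]])
        comps.append(
            AFMComponentParams(
                amplitude=rng.uniform(0.5, 1.5),
                carrier=carrier,
                am_tones=(tone(am_f[0]), tone(am_f[1])),
                fm_tones=(tone(fm_f[0]), tone(fm_f[1])),
            )
        )
    return comps[0], comps[1]


def extract_feature_table(
    cohort: Cohort, fb_order: int | None = None, on_error: str = "raise"
) -> LabeledFeatureTable:
    """Run the full extraction pipeline over a cohort's waveforms.

    ``on_error="skip"`` drops phonemes whose extraction fails instead of
    propagating the exception.
    """
    from afmspeech.features import extract_features

    rows: list[np.ndarray] = []
    keep: list[int] = []
    for i, sig in enumerate(cohort.signals):
        try:
            rows.append(extract_features(sig, fb_order=fb_order).values)
        except Exception:
            if on_error != "skip":
                raise
            continue
        keep.append(i)
    return LabeledFeatureTable(
        features=pd.DataFrame(rows, columns=list(FEATURE_NAMES)),
        labels=cohort.labels[keep],
        subject_ids=cohort.subject_ids[keep],
    )


def write_cohort(cohort: Cohort, out_dir: str) -> str:
    """Write WAV files plus a manifest CSV; returns the manifest path."""
    os.makedirs(out_dir, exist_ok=True)
    manifest_path = os.path.join(out_dir, "manifest.csv")
    with open(manifest_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["filename", "label", "subject_id"])
        for i, (sig, label, subject) in enumerate(
            zip(cohort.signals, cohort.labels, cohort.subject_ids)
        ):
            fname = f"phoneme_{i:05d}.wav"
            write_wav(os.path.join(out_dir, fname), sig)
            w.writerow([fname, label, subject])
    cohort.params.assign(
        label=cohort.labels, subject_id=cohort.subject_ids
    ).to_csv(os.path.join(out_dir, "generating_params.csv"), index=False)
    return manifest_path
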