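"""Synthetic longitudinal cohorts with known ground truth.

Generates sample metadata, feature tables and distance matrices with
planted longitudinal structure so that every analysis in the package can
be exercised, and its answers checked, without any external download.

The per-sample metric follows the generative mixed model

    y_ij = b0 + b1*t + (group effects) + u_i0 + u_i1*t + eps_ij,

with subject random intercepts u_i0 ~ N(0, tau0^2), random slopes
u_i1 ~ N(0, tau1^2) and residual noise eps_ij ~ N(0, sigma^2).  Feature
abundances are Dirichlet-multinomial draws around state-dependent mean
compositions — planted features carry a monotone trend in the mean
composition, the rest are exchangeable noise — which mimics microbiome
compositionality without claiming a fit to any particular study.

An "ECAM-like" preset mirrors a published early-childhood design:
43 subjects sampled monthly from birth to 24 months, two delivery-mode
groups and two diet groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import DistanceMatrix, FeatureTable, SampleMetadata, jaccard_distances


@dataclass
class CohortDesign:
    """Who is sampled when.

    ``groups`` maps a metadata column name to {level: probability};
    ``dropout_probability`` is the independent per-(subject, state)
    chance a sample is missing.
    """

    n_subjects: int = 43
    states: tuple[float, ...] = tuple(float(t) for t in range(0, 25))
    groups: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "delivery": {"cesarean": 0.35, "vaginal": 0.65},
            "diet": {"bd": 0.6, "fd": 0.4},
        }
    )
    dropout_probability: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.states) < 2:
            raise ValueError("need at least 2 states")
        if not 0.0 <= self.dropout_probability <= 1.0:
            raise ValueError("dropout_probability must be in [0, 1]")
        for col, levels in self.groups.items():
            probs = np.array(list(levels.values()), dtype=float)
            if (probs < 0).any() or not np.isclose(probs.sum(), 1.0):
                raise ValueError(f"probabilities for {col!r} must be >=0 and sum to 1")


@dataclass
class EffectSpec:
    """Ground-truth parameters of the generative mixed model.

    ``group_effects`` maps (column, level) to an additive intercept
    shift; ``group_slope_effects`` maps (column, level) to an additive
    change in the time slope (an interaction with time).
    """

    fixed_intercept: float = 2.0
    fixed_slope: float = 0.1
    group_effects: dict[tuple[str, str], float] = field(default_factory=dict)
    group_slope_effects: dict[tuple[str, str], float] = field(default_factory=dict)
    random_intercept_sd: float = 1.0
    random_slope_sd: float = 0.0
    residual_sd: float = 0.5
    n_features: int = 50
    n_planted_features: int = 5
    planted_amplitude: float = 5.0
    dirichlet_concentration: float = 100.0
    sequencing_depth: int = 2000

    def __post_init__(self) -> None:
        for name in ("random_intercept_sd", "random_slope_sd", "residual_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def simulate_cohort(
    design: CohortDesign,
    effects: EffectSpec | None = None,
    metric_name: str = "metric",
    distance: str = "jaccard",
    include_features: bool = True,
) -> tuple[SampleMetadata, FeatureTable | None, DistanceMatrix | None]:
    """Draw one cohort: metadata + feature table + distance matrix.

    ``distance`` selects how the distance matrix is derived from the
    feature table: ``"jaccard"`` (presence/absence) or ``"euclidean"``
    on relative frequencies.  ``include_features=False`` skips the
    feature table and distance matrix (returned as None) when only the
    metric is needed, e.g. for mixed-model simulations.  Fully
    reproducible from ``design.seed``.
    """
    effects = effects or EffectSpec()
    rng = np.random.default_rng(design.seed)
    subjects = [f"S{k:03d}" for k in range(design.n_subjects)]

    assignments: dict[str, dict[str, str]] = {s: {} for s in subjects}
    for col, levels in design.groups.items():
        names = list(levels)
        draws = rng.choice(names, size=design.n_subjects, p=[levels[n] for n in names])
        for s, g in zip(subjects, draws):
            assignments[s][col] = str(g)
    sexes = rng.choice(["female", "male"], size=design.n_subjects)
    u0 = rng.normal(0.0, effects.random_intercept_sd, size=design.n_subjects)
    u1 = rng.normal(0.0, effects.random_slope_sd, size=design.n_subjects)

    rows = []
    for k, subject in enumerate(subjects):
        for t in design.states:
            if rng.random() < design.dropout_probability:
                continue
            slope = effects.fixed_slope + u1[k]
            value = effects.fixed_intercept + u0[k]
            for (col, level), eff in effects.group_effects.items():
                if assignments[subject].get(col) == level:
                    value += eff
            for (col, level), eff in effects.group_slope_effects.items():
                if assignments[subject].get(col) == level:
                    slope += eff
            value += slope * t + rng.normal(0.0, effects.residual_sd)
            rows.append(
                {
                    "sample-id": f"{subject}.{t:g}",
                    "subject": subject,
                    "state": float(t),
                    "sex": str(sexes[k]),
                    **assignments[subject],
                    metric_name: value,
                }
            )
    frame = pd.DataFrame(rows).set_index("sample-id")
    column_types = {
        c: ("numeric" if c in ("state", metric_name) else "categorical")
        for c in frame.columns
    }
    metadata = SampleMetadata(frame, "state", "subject", column_types)

    if not include_features:
        return metadata, None, None
    table = _simulate_feature_table(metadata, effects, rng)
    if distance == "jaccard":
        dm = jaccard_distances(table)
    elif distance == "euclidean":
        rel = table.to_relative().values
        diff = rel[:, None, :] - rel[None, :, :]
        dm = DistanceMatrix(table.sample_ids, np.sqrt((diff**2).sum(axis=2)))
    else:
        raise ValueError(f"unknown distance {distance!r}")
    return metadata, table, dm


def _simulate_feature_table(
    metadata: SampleMetadata, effects: EffectSpec, rng: np.random.Generator
) -> FeatureTable:
    n_feat = effects.n_features
    n_planted = min(effects.n_planted_features, n_feat)
    base = rng.dirichlet(np.full(n_feat, 2.0))
    states = metadata.frame["state"].astype(float).to_numpy()
    span = states.max() - states.min() or 1.0
    # planted features trend monotonically (half up, half down) across time
    directions = np.array([1.0 if i % 2 == 0 else -1.0 for i in range(n_planted)])
    counts = np.zeros((len(metadata), n_feat))
    for row, t in enumerate(states):
        frac = (t - states.min()) / span
        mean = base.copy()
        for i in range(n_planted):
            mean[i] *= np.exp(effects.planted_amplitude * directions[i] * (frac - 0.5))
        mean /= mean.sum()
        comp = rng.dirichlet(mean * effects.dirichlet_concentration)
        counts[row] = rng.multinomial(effects.sequencing_depth, comp)
    feature_ids = [
        f"planted{i:02d}" if i < n_planted else f"noise{i:03d}" for i in range(n_feat)
    ]
    return FeatureTable(
        pd.DataFrame(counts, index=metadata.sample_ids, columns=feature_ids)
    )


def planted_feature_table(
    n_subjects: int = 50,
    states: tuple[float, ...] = tuple(float(t) for t in range(8)),
    n_features: int = 100,
    n_planted: int = 5,
    effect_to_noise: float = 3.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[SampleMetadata, FeatureTable]:
    """Abundance table with a controlled signal-to-noise ratio.

    Planted features have monotone state-dependent means spanning
    ``effect_to_noise * noise_sd`` per state step over i.i.d. Gaussian
    noise (truncated at 0); the remaining features are pure noise.
    Designed for benchmarking regressors that predict time from
    composition, where the effect size must be exact rather than
    filtered through compositional closure.
    """
    rng = np.random.default_rng(seed)
    subjects = [f"S{k:03d}" for k in range(n_subjects)]
    rows = [
        {"sample-id": f"{s}.{t:g}", "subject": s, "state": float(t)}
        for s in subjects
        for t in states
    ]
    frame = pd.DataFrame(rows).set_index("sample-id")
    metadata = SampleMetadata(
        frame, "state", "subject", {"subject": "categorical", "state": "numeric"}
    )
    n = len(frame)
    t = frame["state"].to_numpy()
    step = effect_to_noise * noise_sd
    values = rng.normal(10.0, noise_sd, size=(n, n_features))
    for i in range(n_planted):
        direction = 1.0 if i % 2 == 0 else -1.0
        values[:, i] += direction * step * (t - t.mean())
    values = np.clip(values, 0.0, None)
    feature_ids = [
        f"planted{i:02d}" if i < n_planted else f"noise{i:03d}" for i in range(n_features)
    ]
    return metadata, FeatureTable(
        pd.DataFrame(values, index=frame.index, columns=feature_ids)
    )


def ecam_like(seed: int = 0) -> tuple[SampleMetadata, FeatureTable, DistanceMatrix]:
    """The documented preset: 43 subjects, monthly states 0-24, two
    delivery-mode and two diet groups, mild dropout, diet intercept and
    delivery slope effects planted on the metric."""
    design = CohortDesign(seed=seed, dropout_probability=0.1)
    effects = EffectSpec(
        fixed_intercept=2.0,
        fixed_slope=0.08,
        group_effects={("diet", "fd"): -0.3},
        group_slope_effects={("delivery", "vaginal"): 0.02},
        random_intercept_sd=0.5,
        random_slope_sd=0.02,
        residual_sd=0.4,
    )
    return simulate_cohort(design, effects, metric_name="shannon")
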