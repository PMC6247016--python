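"""Within-subject temporal transforms.

First differences (dY_t = Y_t - Y_{t-1} between successive time points of
a per-sample metric), first distances (the beta-diversity distance between
a subject's successive samples, read from a precomputed distance matrix),
baseline-referenced variants (dY_t = Y_t - Y_baseline), and comparisons
against a static reference sample such as a mother's sample.

Successive deltas follow a fixed-interval gap rule: the time grid is the
ordered set of unique states in the metadata, and a delta at state t is
emitted only when the subject was observed at both t and the grid
predecessor of t.  A subject missing a month therefore contributes no
delta at that month or the next one.

Each transform returns :class:`DifferenceSeries` objects keyed by the
later/moving sample's ID, so results can be merged back into sample
metadata and fed to the mixed-model and volatility modules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import DistanceMatrix, SampleMetadata

logger = logging.getLogger(__name__)

REPLICATE_POLICIES = ("error", "drop", "mean")


@dataclass
class DifferenceSeries:
    """Per-subject deltas of one metric, keyed by the later sample.

    ``reference`` is ``("successive", None)``, ``("baseline-state", t)``
    or ``("static-sample", sample_id)``.
    """

    subject_id: str
    states: np.ndarray
    deltas: np.ndarray
    sample_ids: list[str]
    reference: tuple[str, object]

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=float)
        self.deltas = np.asarray(self.deltas, dtype=float)
        if not (len(self.states) == len(self.deltas) == len(self.sample_ids)):
            raise ValueError("states/deltas/sample_ids lengths differ")
        if len(self.states) > 1 and not (np.diff(self.states) > 0).all():
            raise ValueError("states must be strictly ascending")

    def __len__(self) -> int:
        return len(self.states)


def to_series(series_list: Sequence[DifferenceSeries], name: str = "Difference") -> pd.Series:
    """Flatten difference series into a per-sample column (sample ID -> delta)."""
    ids: list[str] = []
    vals: list[float] = []
    for ds in series_list:
        ids.extend(ds.sample_ids)
        vals.extend(ds.deltas)
    return pd.Series(vals, index=pd.Index(ids, name="sample-id"), name=name, dtype=float)


# ---------------------------------------------------------------------------
# internal helpers
# ---------------------------------------------------------------------------


def _subject_observations(
    metadata: SampleMetadata,
    metric: str | None,
    replicate_policy: str,
) -> dict[str, pd.DataFrame]:
    """State-sorted observations per subject with replicates resolved.

    Returns, per subject, a frame with columns ``state``, ``sample`` and,
    when a metric is given, ``value``.  The "mean" policy averages the
    metric across replicates (metric mode only) and keeps the
    lexicographically smallest sample ID as the representative.
    """
    if replicate_policy not in REPLICATE_POLICIES:
        raise ValueError(f"unknown replicate policy {replicate_policy!r}")
    extra = (metric,) if metric is not None else ()
    df = metadata.longitudinal_frame(extra_required=extra)
    if metric is not None and not metadata.is_numeric(metric):
        raise ValueError(f"metric column {metric!r} is categorical, not numeric")
    out: dict[str, pd.DataFrame] = {}
    for subject, sub in df.groupby(metadata.subject_column, sort=True):
        rec = pd.DataFrame(
            {
                "state": sub[metadata.state_column].astype(float).to_numpy(),
                "sample": list(sub.index),
            }
        )
        if metric is not None:
            rec["value"] = sub[metric].astype(float).to_numpy()
        dup_states = rec["state"][rec["state"].duplicated()].unique()
        if len(dup_states):
            if replicate_policy == "error":
                raise ValueError(
                    f"subject {subject!r} has replicate samples at state(s) "
                    f"{sorted(dup_states)}; choose a replicate policy"
                )
            if replicate_policy == "drop":
                rec = rec[~rec["state"].isin(dup_states)]
            else:  # mean
                if metric is None:
                    raise ValueError(
                        "replicate policy 'mean' is undefined in distance mode"
                    )
                rec = (
                    rec.sort_values(["state", "sample"])
                    .groupby("state", as_index=False)
                    .agg(sample=("sample", "first"), value=("value", "mean"))
                )
        rec = rec.sort_values("state", kind="mergesort").reset_index(drop=True)
        out[str(subject)] = rec
    return out


def _state_grid(observations: dict[str, pd.DataFrame]) -> np.ndarray:
    states = np.concatenate([rec["state"].to_numpy() for rec in observations.values()])
    return np.unique(states)


def _successive(
    observations: dict[str, pd.DataFrame],
    lookup,
    reference: tuple[str, object],
) -> list[DifferenceSeries]:
    grid = _state_grid(observations)
    predecessor = {grid[k]: grid[k - 1] for k in range(1, len(grid))}
    result = []
    for subject, rec in observations.items():
        by_state = {row.state: row for row in rec.itertuples()}
        states, deltas, samples = [], [], []
        for t, prev in predecessor.items():
            if t in by_state and prev in by_state:
                d = lookup(by_state[prev], by_state[t])
                if d is None:
                    continue
                states.append(t)
                deltas.append(d)
                samples.append(by_state[t].sample)
        if not states:
            logger.warning("subject %r has no usable successive pair", subject)
        result.append(DifferenceSeries(subject, np.array(states), np.array(deltas), samples, reference))
    return result


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def first_differences(
    metadata: SampleMetadata,
    metric: str,
    replicate_policy: str = "error",
    baseline: float | None = None,
) -> list[DifferenceSeries]:
    """First differences of a numeric metadata metric.

    With ``baseline`` set, every delta is taken against the subject's
    sample at the baseline state instead of the previous time point;
    subjects lacking a baseline sample are excluded with a warning.
    """
    obs = _subject_observations(metadata, metric, replicate_policy)
    if baseline is not None:
        return _against_baseline_state(
            obs, float(baseline), lambda ref, row: row.value - ref.value
        )
    return _successive(obs, lambda a, b: b.value - a.value, ("successive", None))


def first_distances(
    dm: DistanceMatrix,
    metadata: SampleMetadata,
    replicate_policy: str = "error",
    baseline: float | None = None,
) -> list[DifferenceSeries]:
    """Distances between each subject's successive samples.

    Samples absent from the distance matrix are dropped with a warning;
    it is a hard error if no subject retains two usable samples.
    """
    if replicate_policy == "mean":
        raise ValueError("replicate policy 'mean' is undefined in distance mode")
    obs = _subject_observations(metadata, None, replicate_policy)
    obs = _restrict_to_dm(obs, dm)
    if baseline is not None:
        return _against_baseline_state(
            obs, float(baseline), lambda ref, row: dm[row.sample, ref.sample]
        )
    series = _successive(obs, lambda a, b: dm[b.sample, a.sample], ("successive", None))
    if not any(len(s) for s in series):
        raise ValueError("no subject has >=2 samples present in the distance matrix")
    return series


def _restrict_to_dm(
    observations: dict[str, pd.DataFrame], dm: DistanceMatrix
) -> dict[str, pd.DataFrame]:
    out = {}
    for subject, rec in observations.items():
        keep = rec["sample"].map(lambda s: s in dm)
        if not keep.all():
            logger.warning(
                "subject %r: dropping %d sample(s) absent from distance matrix",
                subject, int((~keep).sum()),
            )
        out[subject] = rec[keep].reset_index(drop=True)
    return out


def _against_baseline_state(
    observations: dict[str, pd.DataFrame],
    baseline: float,
    delta_fn,
) -> list[DifferenceSeries]:
    any_baseline = False
    result = []
    for subject, rec in observations.items():
        by_state = {row.state: row for row in rec.itertuples()}
        if baseline not in by_state:
            logger.warning("subject %r lacks a sample at baseline state %g", subject, baseline)
            continue
        any_baseline = True
        ref = by_state[baseline]
        states, deltas, samples = [], [], []
        for row in rec.itertuples():
            if row.state == baseline:
                continue
            states.append(row.state)
            deltas.append(delta_fn(ref, row))
            samples.append(row.sample)
        result.append(
            DifferenceSeries(
                subject, np.array(states), np.array(deltas), samples,
                ("baseline-state", baseline),
            )
        )
    if not any_baseline:
        raise ValueError(f"baseline state {baseline!r} observed for zero subjects")
    return result


def from_baseline(
    metadata: SampleMetadata,
    baseline_state: float,
    metric: str | None = None,
    dm: DistanceMatrix | None = None,
    replicate_policy: str = "error",
) -> list[DifferenceSeries]:
    """Differences (metric given) or distances (dm given) from a static state."""
    if (metric is None) == (dm is None):
        raise ValueError("provide exactly one of metric= or dm=")
    if metric is not None:
        return first_differences(metadata, metric, replicate_policy, baseline=baseline_state)
    return first_distances(dm, metadata, replicate_policy, baseline=baseline_state)


def from_static_reference(
    dm: DistanceMatrix,
    metadata: SampleMetadata,
    reference_column: str,
    replicate_policy: str = "error",
) -> list[DifferenceSeries]:
    """Distance of each longitudinal sample from a linked static sample.

    ``reference_column`` maps each sample to a reference sample ID present
    in the distance matrix (e.g. child samples -> the mother's sample).
    Subjects with a missing or unknown reference are excluded with a
    warning; it is a hard error if every subject is excluded.
    """
    if reference_column not in metadata.frame.columns:
        raise ValueError(f"reference column {reference_column!r} not in metadata")
    obs = _subject_observations(metadata, None, replicate_policy)
    obs = _restrict_to_dm(obs, dm)
    refs = metadata.frame[reference_column]
    result = []
    for subject, rec in obs.items():
        ref_values = {
            refs.get(s) for s in rec["sample"] if pd.notna(refs.get(s))
        }
        if not ref_values:
            logger.warning("subject %r has no reference sample; excluded", subject)
            continue
        if len(ref_values) > 1:
            logger.warning(
                "subject %r maps to multiple references %s; using first sorted",
                subject, sorted(ref_values),
            )
        reference = sorted(ref_values)[0]
        if reference not in dm:
            logger.warning(
                "subject %r: reference %r absent from distance matrix; excluded",
                subject, reference,
            )
            continue
        states, deltas, samples = [], [], []
        for row in rec.itertuples():
            states.append(row.state)
            deltas.append(dm[row.sample, reference])
            samples.append(row.sample)
        if states:
            result.append(
                DifferenceSeries(
                    subject, np.array(states), np.array(deltas), samples,
                    ("static-sample", reference),
                )
            )
    if not result:
        raise ValueError("all subjects excluded: no usable reference samples")
    return result
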