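"""Paired difference and distance testing between two states.

Pre/post-style analyses: for each subject observed at both states, the
paired difference of a metric (or the beta-diversity distance between the
subject's two samples) is computed; within-group location tests and
between-group comparisons follow.  Nonparametric tests are the default
(Wilcoxon signed-rank within groups; Kruskal-Wallis plus pairwise
Mann-Whitney U between groups) with parametric equivalents (one-sample
t-test; ANOVA plus pairwise t-tests) behind a flag.  Pairwise group
P values are Benjamini-Hochberg corrected; all tests are two-sided.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import DistanceMatrix, SampleMetadata

_DEFAULT_GROUP = "all"


@dataclass
class PairedResult:
    """Per-subject paired values plus within- and between-group tests.

    ``subjects`` has one row per subject (subject, group, value at each
    state, and the paired ``value`` under test).  ``within_group`` has one
    row per group (test name, statistic, P, or a not-applicable reason).
    ``between_group`` holds the overall test and a BH-corrected pairwise
    table; it is None when fewer than two groups are present.
    """

    subjects: pd.DataFrame
    within_group: pd.DataFrame | None
    between_group: dict | None
    metric: str
    states: tuple[float, float]


def _paired_samples(
    metadata: SampleMetadata,
    state1: float,
    state2: float,
    group_column: str | None,
) -> pd.DataFrame:
    if float(state1) == float(state2):
        raise ValueError("state1 and state2 must differ")
    df = metadata.longitudinal_frame()
    states = df[metadata.state_column].astype(float)
    rows = []
    for subject, sub in df.groupby(metadata.subject_column, sort=True):
        st = states.loc[sub.index]
        s1 = list(sub.index[st == float(state1)])
        s2 = list(sub.index[st == float(state2)])
        if len(s1) > 1 or len(s2) > 1:
            raise ValueError(
                f"subject {subject!r} has replicate samples at a tested state"
            )
        if not s1 or not s2:
            continue  # gap rule: both states required
        group = _DEFAULT_GROUP
        if group_column is not None:
            g1 = sub.loc[s1[0], group_column]
            group = g1 if pd.notna(g1) else sub.loc[s2[0], group_column]
            if pd.isna(group):
                continue
        rows.append(
            {"subject": str(subject), "group": str(group),
             "sample1": s1[0], "sample2": s2[0]}
        )
    if not rows:
        raise ValueError("no subject observed at both states")
    return pd.DataFrame(rows)


def _within_group_tests(subjects: pd.DataFrame, parametric: bool) -> pd.DataFrame:
    rows = []
    for group, sub in subjects.groupby("group", sort=True):
        vals = sub["value"].to_numpy(dtype=float)
        row = {"group": group, "n": len(vals), "statistic": np.nan,
               "p": np.nan, "note": ""}
        if len(vals) < 2:
            row["note"] = "not applicable: fewer than 2 paired subjects"
        elif np.ptp(vals) == 0 and (parametric or vals[0] == 0):
            row["note"] = "not applicable: zero variance"
        elif parametric:
            row["test"] = "one-sample t-test"
            stat, p = stats.ttest_1samp(vals, 0.0)
            row.update(statistic=float(stat), p=float(p))
        else:
            nonzero = vals[vals != 0]
            row["n_zero_dropped"] = int(len(vals) - len(nonzero))
            if len(nonzero) < 2:
                row["note"] = "not applicable: zero variance"
            else:
                row["test"] = "wilcoxon signed-rank"
                stat, p = stats.wilcoxon(nonzero, alternative="two-sided")
                row.update(statistic=float(stat), p=float(p))
        row.setdefault("test", "one-sample t-test" if parametric else "wilcoxon signed-rank")
        rows.append(row)
    return pd.DataFrame(rows)


def _between_group_tests(subjects: pd.DataFrame, parametric: bool) -> dict | None:
    groups = sorted(subjects["group"].unique())
    if len(groups) < 2:
        return None
    samples = {g: subjects.loc[subjects["group"] == g, "value"].to_numpy(float)
               for g in groups}
    arrays = [samples[g] for g in groups]
    if parametric:
        overall_name = "one-way ANOVA"
        stat, p = stats.f_oneway(*arrays)
    else:
        overall_name = "kruskal-wallis"
        if all(np.ptp(np.concatenate(arrays)) == 0 for _ in (0,)):
            stat, p = 0.0, 1.0
        else:
            stat, p = stats.kruskal(*arrays)
    pair_rows = []
    for a, b in itertools.combinations(groups, 2):
        if parametric:
            s, pp = stats.ttest_ind(samples[a], samples[b])
            test = "t-test"
        else:
            if np.ptp(np.concatenate([samples[a], samples[b]])) == 0:
                s, pp = len(samples[a]) * len(samples[b]) / 2.0, 1.0
            else:
                s, pp = stats.mannwhitneyu(samples[a], samples[b], alternative="two-sided")
            test = "mann-whitney U"
        pair_rows.append({"group1": a, "group2": b, "test": test,
                          "statistic": float(s), "p": float(pp)})
    pairwise = pd.DataFrame(pair_rows)
    pairwise["q"] = multipletests(pairwise["p"], method="fdr_bh")[1]
    return {"test": overall_name, "statistic": float(stat), "p": float(p),
            "pairwise": pairwise}


def pairwise_differences(
    metadata: SampleMetadata,
    metric: str,
    state1: float,
    state2: float,
    group_column: str | None = None,
    parametric: bool = False,
) -> PairedResult:
    """Paired differences Y_state2 - Y_state1 of a metric, with tests."""
    if not metadata.is_numeric(metric):
        raise ValueError(f"metric column {metric!r} is not numeric")
    pairs = _paired_samples(metadata, state1, state2, group_column)
    vals = metadata.frame[metric]
    pairs["value1"] = pairs["sample1"].map(vals).astype(float)
    pairs["value2"] = pairs["sample2"].map(vals).astype(float)
    pairs = pairs[pairs["value1"].notna() & pairs["value2"].notna()].reset_index(drop=True)
    if pairs.empty:
        raise ValueError(f"no paired subject has {metric!r} at both states")
    pairs["value"] = pairs["value2"] - pairs["value1"]
    within = _within_group_tests(pairs, parametric)
    between = _between_group_tests(pairs, parametric) if group_column else None
    return PairedResult(pairs, within, between, metric, (float(state1), float(state2)))


def pairwise_distances(
    dm: DistanceMatrix,
    metadata: SampleMetadata,
    state1: float,
    state2: float,
    group_column: str,
    parametric: bool = False,
) -> PairedResult:
    """Within-pair distances dm[sample_state1, sample_state2], compared by group.

    The test variable is the distance between each subject's two samples;
    only between-group tests are meaningful (distances are nonnegative, so
    no within-group location test against 0 is run).
    """
    pairs = _paired_samples(metadata, state1, state2, group_column)
    present = pairs["sample1"].map(lambda s: s in dm) & pairs["sample2"].map(lambda s: s in dm)
    pairs = pairs[present].reset_index(drop=True)
    if pairs.empty:
        raise ValueError("no paired subject has both samples in the distance matrix")
    pairs["value"] = [dm[a, b] for a, b in zip(pairs["sample1"], pairs["sample2"])]
    summary = (
        pairs.groupby("group", sort=True)["value"]
        .agg(n="count", median="median", mean="mean")
        .reset_index()
    )
    between = _between_group_tests(pairs, parametric)
    return PairedResult(pairs, summary, between, "distance", (float(state1), float(state2)))
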