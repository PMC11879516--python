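"""Experience-sampling data handling.

Beep-level item responses (1–7 scales) are turned into analysis indices
(means of item sets), within-day time-lagged (t, t+1) pairs, person-level
descriptives and two-level Cronbach reliabilities.

The canonical long format has one row per *issued* signal:
``subject_id, day, beep, time_min, observed`` plus ``item_*`` response
columns (NaN when the beep was not completed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "IndexDefinition",
    "DEFAULT_INDICES",
    "ITEM_COLUMNS",
    "build_indices",
    "make_lagged_pairs",
    "person_descriptives",
    "reliability",
    "cronbach_alpha",
]

REQUIRED_COLUMNS = ("subject_id", "day", "beep", "time_min", "observed")


@dataclass(frozen=True)
class IndexDefinition:
    """A named analysis index computed as the mean of one or more items."""

    name: str
    items: tuple[str, ...]

    def columns(self) -> list[str]:
        return [f"item_{i}" for i in self.items]


# Momentary indices: two paranoia items, eight psychotic-like-experience
# items, a single negative-symptom proxy, four negative-affect and two
# positive-affect items, plus single-item appraisals of the current context.
DEFAULT_INDICES: tuple[IndexDefinition, ...] = (
    IndexDefinition("paranoia", ("suspicious", "mistreated")),
    IndexDefinition(
        "ple",
        (
            "fear_losing_control",
            "feel_weird",
            "difficulty_controlling_thoughts",
            "thoughts_strange",
            "perception_strange",
            "heard_seen_things",
            "thought_control",
            "familiar_strange",
        ),
    ),
    IndexDefinition("negative_like", ("no_thoughts_emotions",)),
    IndexDefinition("na", ("sad", "anxious", "angry", "guilty")),
    IndexDefinition("pa", ("happy", "relaxed")),
    IndexDefinition("stressful", ("situation_stressful",)),
    IndexDefinition("positive", ("situation_positive",)),
)

ITEM_COLUMNS: tuple[str, ...] = tuple(
    col for d in DEFAULT_INDICES for col in d.columns()
)


def validate_esm(data: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in data.columns]
    if missing:
        raise ValueError(f"ESM table missing columns: {missing}")
    if data.duplicated(["subject_id", "day", "beep"]).any():
        raise ValueError("duplicate (subject, day, beep) rows")


def build_indices(
    data: pd.DataFrame, defs: tuple[IndexDefinition, ...] = DEFAULT_INDICES
) -> pd.DataFrame:
    """Append index columns: arithmetic mean of the constituent items.

    An index is missing at a beep whenever any constituent item is missing
    (the strict policy; there is no mean-of-available fallback).
    """
    validate_esm(data)
    out = data.copy()
    for d in defs:
        cols = d.columns()
        unknown = [c for c in cols if c not in data.columns]
        if unknown:
            raise ValueError(f"index {d.name!r} references unknown items: {unknown}")
        block = out[cols].to_numpy(dtype=float)
        vals = block.mean(axis=1)
        vals[np.isnan(block).any(axis=1)] = np.nan
        out[d.name] = vals
    return out


def make_lagged_pairs(
    data: pd.DataFrame,
    predictor: str,
    outcome: str,
    covariates: tuple[str, ...] = (),
    g: pd.Series | None = None,
) -> pd.DataFrame:
    """Within-day (t, t+1) pairs over consecutive issued signals.

    A pair couples beep k and beep k+1 of the same subject-day and is
    emitted only when the predictor and all covariates are observed at t and
    the outcome is observed at t+1.  Pairs never cross a day boundary.

    Returns a table with columns ``subject_id, day, E`` (predictor at t),
    ``y`` (outcome at t+1), the covariates (values at t) and, when ``g``
    (a per-subject series) is given, ``G``.
    """
    validate_esm(data)
    for c in (predictor, outcome, *covariates):
        if c not in data.columns:
            raise ValueError(f"column {c!r} not in ESM table")
    d = data.sort_values(["subject_id", "day", "beep"], kind="mergesort")
    same_pair = (
        d["subject_id"].eq(d["subject_id"].shift(-1))
        & d["day"].eq(d["day"].shift(-1))
        & d["beep"].add(1).eq(d["beep"].shift(-1))
    )
    ok_t = d[predictor].notna()
    for c in covariates:
        ok_t &= d[c].notna()
    ok_t1 = d[outcome].notna().shift(-1, fill_value=False)
    keep = same_pair & ok_t & ok_t1
    out = pd.DataFrame(
        {
            "subject_id": d.loc[keep, "subject_id"].to_numpy(),
            "day": d.loc[keep, "day"].to_numpy(),
            "E": d.loc[keep, predictor].to_numpy(dtype=float),
            "y": d[outcome].shift(-1).loc[keep].to_numpy(dtype=float),
        }
    )
    for c in covariates:
        out[c] = d.loc[keep, c].to_numpy(dtype=float)
    if g is not None:
        out["G"] = out["subject_id"].map(g).to_numpy(dtype=float)
    return out.reset_index(drop=True)


def person_descriptives(
    data: pd.DataFrame,
    variables: tuple[str, ...],
    subject_vars: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Descriptives of person means plus their Pearson correlation matrix.

    ``subject_vars`` (e.g. PRS columns indexed by subject) are appended to
    the person-mean table before correlating.  Subjects with no observed
    beeps are excluded with a warning; constant variables are flagged.
    """
    validate_esm(data)
    obs = data[data["observed"].astype(bool)]
    n_dropped = data["subject_id"].nunique() - obs["subject_id"].nunique()
    if n_dropped:
        warnings.warn(
            f"{n_dropped} subjects with zero observed beeps excluded", stacklevel=2
        )
    pm = obs.groupby("subject_id")[list(variables)].mean()
    if subject_vars is not None:
        pm = pm.join(subject_vars, how="left")
    desc = pd.DataFrame(
        {
            "mean": pm.mean(),
            "sd": pm.std(ddof=1),
            "min": pm.min(),
            "max": pm.max(),
        }
    )
    constant = desc.index[desc["sd"] == 0].tolist()
    if constant:
        warnings.warn(
            f"constant person-mean variables (correlations undefined): {constant}",
            stacklevel=2,
        )
    corr = pm.corr()
    return desc, corr


def cronbach_alpha(items: np.ndarray) -> float:
    """Cronbach's alpha of an observations × items matrix (rows with NaN dropped)."""
    x = np.asarray(items, dtype=float)
    x = x[~np.isnan(x).any(axis=1)]
    k = x.shape[1]
    if k < 2 or x.shape[0] < 3:
        return float("nan")
    item_var = x.var(axis=0, ddof=1).sum()
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var == 0:
        return float("nan")
    return float(k / (k - 1) * (1.0 - item_var / total_var))


def reliability(
    data: pd.DataFrame, definition: IndexDefinition
) -> tuple[float, float]:
    """(between, within) Cronbach alphas of a multi-item index.

    Between: alpha over the subjects × items matrix of person-mean item
    scores.  Within: alpha over beep-level person-mean-centered item scores.
    Single-item indices have no internal consistency; both values are NaN.
    """
    cols = definition.columns()
    if len(cols) < 2:
        return float("nan"), float("nan")
    validate_esm(data)
    obs = data[data["observed"].astype(bool)]
    person_means = obs.groupby("subject_id")[cols].mean()
    between = cronbach_alpha(person_means.to_numpy())
    centered = obs[cols].to_numpy(dtype=float) - person_means.loc[
        obs["subject_id"]
    ].to_numpy(dtype=float)
    within = cronbach_alpha(centered)
    return between, within
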