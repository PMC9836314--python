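"""Dependent variables: intelligibility (RAU), localization error (MAE), promptness.

Intelligibility is the proportion of color/number items correctly repeated,
variance-stabilized with the rationalized arcsine transform:

    AU  = arcsin sqrt(X / (N+1)) + arcsin sqrt((X+1) / (N+1))
    RAU = (146 / pi) * AU - 23

where X is the number of items correct out of N scored.  RAU is finite at
X = 0 and X = N, strictly increasing in X, and numerically close to the
percent scale over most of its range.  Item bookkeeping: each trial
contributes two scored items (color, number), so N = 2 x trials.

Localization accuracy is the mean absolute error (MAE) between the response
and target azimuths, by default measured on the circle (an error can never
exceed 180 deg); a literal linear difference is available for audit.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import asin, pi, sqrt

import numpy as np
import pandas as pd

from .design import wrap_angle

__all__ = ["IntelligibilityScore", "score_trial", "rau", "angular_error",
           "mae", "summarize_cells"]


@dataclass(frozen=True)
class IntelligibilityScore:
    x_correct: int
    n_items: int
    percent: float
    au: float
    rau: float


def score_trial(reported_color, reported_number, target_color, target_number) -> int:
    """Items correct in {0, 1, 2}; an absent (None/NaN) report scores 0."""
    score = 0
    if reported_color is not None and not pd.isna(reported_color):
        score += int(str(reported_color).lower() == str(target_color).lower())
    if reported_number is not None and not pd.isna(reported_number):
        score += int(int(reported_number) == int(target_number))
    return score


def rau(x_correct: int, n_items: int, printed_variant: bool = False) -> IntelligibilityScore:
    """Rationalized arcsine units for ``x_correct`` of ``n_items`` items.

    ``printed_variant=True`` evaluates the transform without the square-root
    radicals (arcsin of the raw ratios), as some sources typeset it; that map
    is not the standard rationalized arcsine (and leaves the arcsine domain
    whenever the score is expressed as a percentage), so it exists only for
    auditing.
    """
    if n_items < 1:
        raise ValueError("n_items must be >= 1")
    if not 0 <= x_correct <= n_items:
        raise ValueError(f"x_correct must be in [0, {n_items}], got {x_correct}")
    x, n = float(x_correct), float(n_items)
    if printed_variant:
        au = asin(x / (n + 1)) + asin((x + 1) / (n + 1))
    else:
        au = asin(sqrt(x / (n + 1))) + asin(sqrt((x + 1) / (n + 1)))
    return IntelligibilityScore(
        x_correct=int(x_correct), n_items=int(n_items),
        percent=100.0 * x / n, au=au, rau=(146.0 / pi) * au - 23.0,
    )


def angular_error(response_deg, target_deg, convention: str = "circular"):
    """Absolute azimuth error in degrees.

    circular: shortest arc on the circle, in [0, 180].
    linear:   plain absolute difference of the numeric angles.
    """
    r = np.asarray(response_deg, dtype=float)
    t = np.asarray(target_deg, dtype=float)
    if convention == "circular":
        err = np.abs(wrap_angle(r - t))
    elif convention == "linear":
        err = np.abs(r - t)
    else:
        raise ValueError(f"unknown convention {convention!r}")
    if np.ndim(response_deg) == 0 and np.ndim(target_deg) == 0:
        return float(err)
    return err


def mae(errors) -> float:
    errors = np.asarray(errors, dtype=float)
    if errors.size == 0:
        raise ValueError("mae requires at least one error")
    return float(np.mean(np.abs(errors)))


def summarize_cells(trials: pd.DataFrame, responses: pd.DataFrame,
                    convention: str = "circular",
                    printed_rau: bool = False) -> pd.DataFrame:
    """Aggregate to subject x condition x SNR x hemifield cells.

    Per cell: RAU over pooled items (2 per trial; all trials count),
    MAE and mean promptness over trials with a detected movement (trials
    flagged ``no_movement`` or missing an endpoint are excluded from the
    movement metrics but still scored for intelligibility), front-back
    reversal rate as a diagnostic, and trial counts.  Empty cells are emitted
    with ``n_trials=0`` and missing metrics.
    """
    df = trials.merge(responses, on=["trial_id", "subject"], how="left",
                      validate="one_to_one")
    rep_color = df["reported_color"] if "reported_color" in df else pd.Series(np.nan, index=df.index)
    rep_number = df["reported_number"] if "reported_number" in df else pd.Series(np.nan, index=df.index)
    color_ok = rep_color.notna() & (rep_color.astype(str).str.lower()
                                    == df["target_color"].astype(str).str.lower())
    number_ok = rep_number.notna() & (
        pd.to_numeric(rep_number, errors="coerce") == df["target_number"].astype(int))
    df["items_correct"] = color_ok.astype(int) + number_ok.astype(int)

    if "endpoint_deg" not in df:
        df["endpoint_deg"] = np.nan
    for col in ("promptness_inv_s", "rt_s"):
        if col not in df:
            df[col] = np.nan
    flags = df.get("qc_flags", pd.Series("", index=df.index)).fillna("").astype(str)
    moved = (df["endpoint_deg"].notna() & ~flags.str.contains("no_movement")).to_numpy()
    abs_err = angular_error(df["endpoint_deg"].fillna(0.0).to_numpy(),
                            df["target_azimuth_deg"].to_numpy(), convention=convention)
    endpoint_front = np.abs(wrap_angle(df["endpoint_deg"].fillna(0.0).to_numpy())) < 90.0
    target_front = (df["target_hemifield"] == "front").to_numpy()
    df["_abs_err"] = np.where(moved, abs_err, np.nan)
    # reversal diagnostic: response hemifield differs from the target's
    df["_reversed"] = np.where(moved, (endpoint_front != target_front).astype(float), np.nan)
    df["_prompt"] = np.where(moved, df["promptness_inv_s"], np.nan)
    df["_rt"] = np.where(moved, df["rt_s"], np.nan)
    df["_moved"] = moved

    keys = ["subject", "condition", "snr_db", "target_hemifield"]
    grouped = df.groupby(keys, sort=False, observed=True).agg(
        n_trials=("trial_id", "size"),
        x_correct=("items_correct", "sum"),
        n_moved=("_moved", "sum"),
        mae_deg=("_abs_err", "mean"),
        mean_promptness_inv_s=("_prompt", "mean"),
        mean_rt_s=("_rt", "mean"),
        reversal_rate=("_reversed", "mean"),
    )
    full_index = pd.MultiIndex.from_product(
        [sorted(df["subject"].unique()), list(pd.unique(trials["condition"])),
         sorted(trials["snr_db"].unique()), ["front", "back"]],
        names=keys,
    )
    grouped = grouped.reindex(full_index)
    grouped["n_trials"] = grouped["n_trials"].fillna(0).astype(int)
    grouped["n_items"] = 2 * grouped["n_trials"]
    nonempty = grouped["n_trials"] > 0
    grouped["percent_correct"] = np.where(
        nonempty, 100.0 * grouped["x_correct"] / grouped["n_items"], np.nan)
    grouped["rau"] = [
        rau(int(x), int(n), printed_variant=printed_rau).rau if n > 0 else np.nan
        for x, n in zip(grouped["x_correct"].fillna(0), grouped["n_items"])
    ]
    out = grouped.reset_index().rename(columns={"target_hemifield": "hemifield"})
    return out
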