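"""Repeated-measures inferential layer.

Three fully-crossed within-subject factors (listening condition x SNR x
hemifield) with one observation per subject x cell.  The classical
univariate decomposition is used: for every factor subset E, the effect sum
of squares SS_E and its error term SS_{E x subject} come from the orthogonal
decomposition of the data array over subsets of {subject, factors}; then

    F_E = (SS_E / df_E) / (SS_{ExS} / df_err),   df_err = df_E * (n - 1)
    partial eta^2 = SS_E / (SS_E + SS_{ExS})

Uncorrected p-values are reported alongside Greenhouse-Geisser-corrected
ones (epsilon estimated from the covariance of the orthonormal-contrast
scores for the effect), since sphericity is never guaranteed with more than
two levels.

Follow-ups are paired t-tests on subject-level marginal means with Bonferroni
correction over all pairs within the factor; response-speed analyses operate
on promptness (reciprocal RT), which is approximately Gaussian, while RTs in
seconds are kept for the descriptive fast/slow responder split.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["AnovaEffect", "rm_anova", "bonferroni_pairwise", "correlate",
           "correlation_table", "classify_responders", "RESPONDER_CUTOFF_S"]

RESPONDER_CUTOFF_S = 1.5

FACTORS = ("condition", "snr_db", "hemifield")


@dataclass(frozen=True)
class AnovaEffect:
    effect: str
    df_num: int
    df_den: int
    ss_effect: float
    ss_error: float
    F: float
    p: float
    partial_eta_sq: float
    gg_epsilon: float
    p_gg: float


def _data_array(cells: pd.DataFrame, dv: str):
    """Pivot the cell table to an (n_subjects, l1, l2, l3) array; reject holes."""
    levels = {f: list(pd.unique(cells[f])) for f in FACTORS}
    subjects = list(pd.unique(cells["subject"]))
    idx = {f: {v: i for i, v in enumerate(levels[f])} for f in FACTORS}
    sidx = {s: i for i, s in enumerate(subjects)}
    shape = (len(subjects),) + tuple(len(levels[f]) for f in FACTORS)
    arr = np.full(shape, np.nan)
    for row in cells.itertuples(index=False):
        r = row._asdict()
        arr[sidx[r["subject"]], idx[FACTORS[0]][r[FACTORS[0]]],
            idx[FACTORS[1]][r[FACTORS[1]]], idx[FACTORS[2]][r[FACTORS[2]]]] = r[dv]
    if np.isnan(arr).any():
        holes = np.argwhere(np.isnan(arr))
        s, a, b, c = holes[0]
        raise ValueError(
            f"incomplete design for dv={dv!r}: missing/NaN cell for subject "
            f"{subjects[s]!r}, {FACTORS[0]}={levels[FACTORS[0]][a]!r}, "
            f"{FACTORS[1]}={levels[FACTORS[1]][b]!r}, "
            f"{FACTORS[2]}={levels[FACTORS[2]][c]!r} "
            f"({len(holes)} missing cells total); drop the subject or impute upstream"
        )
    return arr, subjects, levels


def _effect_arrays(arr: np.ndarray) -> dict[frozenset, np.ndarray]:
    """Orthogonal effect arrays for every subset of dimensions (Moebius over marginal means).

    Dimension 0 is the subject; the grand mean is the empty subset.  Each
    returned array is broadcast back to full shape, so summing squares over
    the full grid gives the term's SS and the arrays sum to the data minus
    nothing (complete decomposition).
    """
    ndim = arr.ndim
    dims = tuple(range(ndim))
    marg: dict[frozenset, np.ndarray] = {}
    for r in range(ndim + 1):
        for keep in itertools.combinations(dims, r):
            reduce_over = tuple(d for d in dims if d not in keep)
            marg[frozenset(keep)] = arr.mean(axis=reduce_over, keepdims=True)
    effects: dict[frozenset, np.ndarray] = {}
    for keep in marg:
        e = np.zeros_like(marg[keep])
        for sub in (frozenset(c) for r in range(len(keep) + 1)
                    for c in itertools.combinations(sorted(keep), r)):
            sign = (-1) ** (len(keep) - len(sub))
            e = e + sign * marg[sub]
        effects[keep] = np.broadcast_to(e, arr.shape)
    return effects


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal contrast matrix (orthonormalized Helmert)."""
    h = np.zeros((k - 1, k))
    for i in range(k - 1):
        h[i, : i + 1] = 1.0
        h[i, i + 1] = -(i + 1.0)
        h[i] /= np.linalg.norm(h[i])
    return h


def _gg_epsilon(arr: np.ndarray, factor_dims: tuple[int, ...],
                levels: tuple[int, ...]) -> float:
    """Greenhouse-Geisser epsilon for the effect spanned by ``factor_dims``.

    Subjects x cells scores are averaged over the uninvolved factors, the
    Kronecker product of per-factor orthonormal contrasts is applied, and
    epsilon = tr(S)^2 / (d * tr(S^2)) with S the covariance of the contrast
    scores and d the effect df.
    """
    n = arr.shape[0]
    other = tuple(d for d in range(1, arr.ndim) if d not in factor_dims)
    y = arr.mean(axis=other) if other else arr
    y = y.reshape(n, -1)
    contrast = np.array([[1.0]])
    for k in levels:
        contrast = np.kron(contrast, _orthonormal_contrasts(k))
    z = y @ contrast.T
    if z.shape[1] == 1:  # single-df effect: sphericity holds trivially
        return 1.0
    s = np.cov(z, rowvar=False)
    tr = np.trace(s)
    if tr <= 0:
        return 1.0
    eps = tr**2 / (z.shape[1] * np.sum(s * s))
    return float(min(1.0, max(eps, 1.0 / z.shape[1])))


def rm_anova(cells: pd.DataFrame, dv: str) -> pd.DataFrame:
    """Three-factor repeated-measures ANOVA table for one dependent variable.

    Requires the complete balanced cell table (every subject x condition x
    SNR x hemifield cell present and non-missing) and at least 3 subjects.
    Returns the seven effects with F, dfs, p, partial eta^2, and the
    Greenhouse-Geisser epsilon and corrected p.
    """
    arr, subjects, levels = _data_array(cells, dv)
    n = len(subjects)
    if n < 3:
        raise ValueError("rm_anova needs at least 3 subjects")
    effects = _effect_arrays(arr)

    dim_of = {f: i + 1 for i, f in enumerate(FACTORS)}
    rows = []
    for r in range(1, len(FACTORS) + 1):
        for combo in itertools.combinations(FACTORS, r):
            fdims = tuple(dim_of[f] for f in combo)
            lv = tuple(len(levels[f]) for f in combo)
            ss_eff = float(np.sum(effects[frozenset(fdims)] ** 2))
            ss_err = float(np.sum(effects[frozenset(fdims) | {0}] ** 2))
            df_num = int(np.prod([k - 1 for k in lv]))
            df_den = df_num * (n - 1)
            ms_eff = ss_eff / df_num
            ms_err = ss_err / df_den
            if ms_err > 0:
                F = ms_eff / ms_err
                p = float(sps.f.sf(F, df_num, df_den))
            else:  # degenerate: no error variance
                F, p = (np.inf if ms_eff > 0 else 0.0), (0.0 if ms_eff > 0 else 1.0)
            peta = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
            eps = _gg_epsilon(arr, fdims, lv)
            p_gg = float(sps.f.sf(F, eps * df_num, eps * df_den)) if np.isfinite(F) else p
            rows.append(AnovaEffect(
                effect=" x ".join(combo), df_num=df_num, df_den=df_den,
                ss_effect=ss_eff, ss_error=ss_err, F=float(F), p=p,
                partial_eta_sq=float(peta), gg_epsilon=eps, p_gg=p_gg,
            ))
    return pd.DataFrame([e.__dict__ for e in rows])


def decomposition_residual(cells: pd.DataFrame, dv: str) -> float:
    """Max |data - sum of all effect terms|: the decomposition identity check."""
    arr, _, _ = _data_array(cells, dv)
    effects = _effect_arrays(arr)
    recon = np.zeros_like(arr)
    for e in effects.values():
        recon = recon + e
    return float(np.max(np.abs(arr - recon)))


def bonferroni_pairwise(cells: pd.DataFrame, dv: str, factor: str,
                        family: int | None = None) -> pd.DataFrame:
    """Paired t-tests on subject-level marginal means for every level pair.

    p-values are multiplied by the family size (default: all C(k,2) pairs
    within the factor) and capped at 1.
    """
    if factor not in cells.columns:
        raise ValueError(f"unknown factor {factor!r}")
    marg = (cells.groupby(["subject", factor], sort=False, observed=True)[dv]
            .mean().unstack(factor))
    levels = list(marg.columns)
    if len(levels) < 2:
        raise ValueError("factor needs at least 2 levels")
    pairs = list(itertools.combinations(levels, 2))
    m = family if family is not None else len(pairs)
    rows = []
    for a, b in pairs:
        diff = marg[a] - marg[b]
        mean_diff = float(diff.mean())
        if np.allclose(diff, diff.iloc[0]):
            t, p = (0.0, 1.0) if np.isclose(mean_diff, 0.0) else (np.inf, 0.0)
        else:
            t, p = sps.ttest_rel(marg[a], marg[b])
        rows.append({"factor": factor, "level_a": a, "level_b": b,
                     "mean_difference": mean_diff, "t": float(t),
                     "p_raw": float(p), "p_bonferroni": min(1.0, m * float(p))})
    return pd.DataFrame(rows)


def correlate(dv_table: pd.DataFrame, x: str, y: str) -> tuple[float, float]:
    """Pearson r and p between two dependent variables on paired aggregates."""
    sub = dv_table[[x, y]].dropna()
    if len(sub) < 3:
        raise ValueError("need at least 3 paired observations")
    if sub[x].std() == 0 or sub[y].std() == 0:
        return float("nan"), float("nan")
    r, p = sps.pearsonr(sub[x], sub[y])
    return float(r), float(p)


def correlation_table(cells: pd.DataFrame,
                      pairs=(("mae_deg", "rau"),
                             ("mean_promptness_inv_s", "mae_deg"),
                             ("mean_promptness_inv_s", "rau"))) -> pd.DataFrame:
    """Pearson correlations among DVs on subject x condition aggregates."""
    agg = (cells.groupby(["subject", "condition"], sort=False, observed=True)
           [["rau", "mae_deg", "mean_promptness_inv_s"]].mean().reset_index())
    rows = []
    for x, y in pairs:
        r, p = correlate(agg, x, y)
        rows.append({"x": x, "y": y, "n": int(agg[[x, y]].dropna().shape[0]),
                     "pearson_r": r, "p": p})
    return pd.DataFrame(rows)


def classify_responders(responses: pd.DataFrame,
                        cutoff_s: float = RESPONDER_CUTOFF_S) -> pd.DataFrame:
    """Fast/slow split on per-subject mean RT across all conditions."""
    rt = responses.dropna(subset=["rt_s"])
    if rt.empty:
        raise ValueError("no reaction times present")
    out = rt.groupby("subject", sort=True)["rt_s"].mean().rename("mean_rt_s").reset_index()
    out["responder_class"] = np.where(out["mean_rt_s"] < cutoff_s, "fast", "slow")
    out["cutoff_s"] = cutoff_s
    return out
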