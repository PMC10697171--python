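"""Study-level statistics for the crossover angular-position analysis.

The modelling follows the study design: IPF observations (point-level, one
row per selected trace point) are modelled with a linear mixed-effects model
with fixed effects *condition × eyelid state* (no-device baseline and the
open state as reference levels) and random intercepts for participant and
for condition-within-participant-eye, fitted by REML.  Comfort ratings are
treated as interval data and modelled the same way with condition as the
only fixed effect.

Whether participants respond *differently* to the angular positions is a
question the random-effects model cannot answer, so a profile analysis is
provided: restricted to eyes with data at all five angles, it tests whether
the per-eye profiles of adjacent-angle differences are parallel.  The
implementation is the exact F test of the eye × angle interaction on
point-level data, which is equivalent to equality of the per-eye
segment-difference vectors.

Also here: the categorical expected rolling-direction lookup for the two
eyelid-magnet polarisations, observed/expected agreement arithmetic, and
participant-table demographics.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .detection import SegmentationResult
from .kinematics import (
    resting_open_points,
    spontaneous_min_points,
    volitional_min_points,
)
from .trace_io import ANGLE_CONDITIONS, IPFTrace, Recording, ValidationError

__all__ = [
    "FixedEffect",
    "ModelResult",
    "ProfileResult",
    "RollingCounts",
    "ParticipantRecord",
    "build_observation_table",
    "fit_ipf_mixed_model",
    "fit_comfort_model",
    "cell_mean",
    "condition_means_table",
    "estimate_contrast",
    "profile_parallelism_test",
    "expected_rolling_direction",
    "rolling_agreement",
    "demographics_summary",
]

Z95 = 1.96


@dataclass(frozen=True)
class FixedEffect:
    estimate: float
    se: float
    z: float
    p: float
    ci95_lo: float
    ci95_hi: float


@dataclass
class ModelResult:
    """Fitted mixed-model summary with Wald z tests and 95% CIs."""

    fixed_effects: dict
    random_variances: dict
    n_obs: int
    n_groups: int
    converged: bool
    degenerate: bool = False
    # machinery for contrasts / cell means (not serialised)
    _fe_params: Optional[np.ndarray] = None
    _fe_cov: Optional[np.ndarray] = None
    _fe_names: Optional[list] = None
    _design_info: object = None

    def to_dict(self) -> dict:
        return {
            "fixed_effects": {
                k: vars(v) for k, v in self.fixed_effects.items()
            },
            "random_variances": self.random_variances,
            "n_obs": self.n_obs,
            "n_groups": self.n_groups,
            "converged": self.converged,
            "degenerate": self.degenerate,
        }


@dataclass
class ProfileResult:
    """Parallelism (profile) test result for one eyelid state."""

    state: str
    statistic: float
    df: tuple
    p: float
    segments: pd.DataFrame  # per-eye adjacent-angle mean differences


@dataclass(frozen=True)
class RollingCounts:
    """Observed vs expected eyelid-magnet rolling counts for one cell."""

    magnet_type: str
    angle_deg: int
    observed: int
    expected: int
    observed_direction: str
    expected_direction: str

    def __post_init__(self) -> None:
        if not (0 <= self.observed <= self.expected):
            raise ValidationError("need 0 <= observed <= expected")


@dataclass(frozen=True)
class ParticipantRecord:
    """One row of the participant enrollment table."""

    id: str
    age_yr: float
    gender: str
    side: str  # left | right | both
    severity_mm: tuple = ()
    cause: str = ""
    duplicate_of: Optional[str] = None
    excluded: bool = False

    def __post_init__(self) -> None:
        if self.age_yr <= 0:
            raise ValidationError("age must be positive")
        if self.gender not in ("M", "F"):
            raise ValidationError(f"unknown gender {self.gender!r}")
        if self.side not in ("left", "right", "both"):
            raise ValidationError(f"unknown side {self.side!r}")


# ---------------------------------------------------------------------------
# observation table
# ---------------------------------------------------------------------------

def build_observation_table(items: Iterable[tuple]) -> pd.DataFrame:
    """Long-format point-level observation table.

    ``items`` yields ``(Recording, IPFTrace, SegmentationResult)`` triples
    with classified events.  One row per selected IPF point: open-band
    points, the three smallest points of each spontaneous blink, and the
    percentile-band points of each volitional blink, each labelled by
    condition and state, with the recording's comfort rating attached.
    """
    rows = []
    for recording, trace, seg in items:
        points = []
        for v in resting_open_points(trace, seg):
            points.append(("open", v))
        for ev in seg.events:
            if ev.type == "spontaneous":
                points.extend(("spont_blink", v) for v in spontaneous_min_points(ev))
            elif ev.type == "volitional":
                points.extend(("vol_blink", v) for v in volitional_min_points(ev))
        if not points:
            warnings.warn(
                f"recording {recording.recording_id}: no selected points, skipped"
            )
            continue
        for state, v in points:
            rows.append(
                {
                    "recording_id": recording.recording_id,
                    "participant_id": recording.participant_id,
                    "eye": recording.eye,
                    "condition": recording.condition,
                    "state": state,
                    "ipf_mm": float(v),
                    "comfort": recording.comfort,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["recording_id", "participant_id", "eye", "condition",
                 "state", "ipf_mm", "comfort"],
    )


# ---------------------------------------------------------------------------
# mixed models
# ---------------------------------------------------------------------------

_IPF_RHS = ("C(condition, Treatment('baseline'))"
            " * C(state, Treatment('open'))")
_COMFORT_RHS = "C(condition, Treatment('baseline'))"


def _clean_term(name: str) -> str:
    name = re.sub(r"C\(condition[^\[]*\)\[T\.([^\]]+)\]", r"condition[\1]", name)
    name = re.sub(r"C\(state[^\[]*\)\[T\.([^\]]+)\]", r"state[\1]", name)
    return name


# The REML fit is computed on sufficient statistics.  Every covariate is
# constant within a (recording, state) cell, so the Gaussian likelihood
# factorises exactly into (i) within-cell contrasts, which depend only on
# the residual variance, and (ii) the cell means, whose covariance per
# participant is
#
#     V_p = s2_participant * J + s2_cond_eye * S_p + s2_resid * diag(1/n_j)
#
# with J all-ones and S_p the same-eye-condition indicator.  Optimising the
# three log-variances on this collapsed problem is fast and far better
# conditioned than the raw 5e4-point problem, and gives the identical REML
# objective.

def _reml_neg_loglik(log_theta, groups, n_total, k_cells_total, k_fe,
                     within_ss, reml=True):
    s2_a, s2_c, s2_e = np.exp(np.clip(log_theta, -30.0, 30.0))
    xtvx = np.zeros((k_fe, k_fe))
    xtvy = np.zeros(k_fe)
    logdet_sum = 0.0
    quad_parts = []  # (m, X, Vinv) per group for the residual quad form
    for m, X, S, inv_n in groups:
        k = len(m)
        V = s2_a + s2_c * S + np.diag(s2_e * inv_n)
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return 1e12, None
        logdet_sum += 2.0 * np.sum(np.log(np.diag(L)))
        Vinv_X = np.linalg.solve(V, X)
        Vinv_m = np.linalg.solve(V, m)
        xtvx += X.T @ Vinv_X
        xtvy += X.T @ Vinv_m
        quad_parts.append((m, X, Vinv_m, Vinv_X))
    try:
        xtvx_inv = np.linalg.inv(xtvx)
    except np.linalg.LinAlgError:
        return 1e12, None
    beta = xtvx_inv @ xtvy
    quad = 0.0
    for m, X, Vinv_m, Vinv_X in quad_parts:
        r_v = Vinv_m - Vinv_X @ beta
        quad += float((m - X @ beta) @ r_v)
    # within-cell contrasts: iid residuals
    df_within = n_total - k_cells_total
    nll = 0.5 * (logdet_sum + quad + k_cells_total * np.log(2 * np.pi))
    if df_within > 0:
        nll += 0.5 * (df_within * np.log(2 * np.pi * s2_e) + within_ss / s2_e)
    if reml:
        sign, logdet_x = np.linalg.slogdet(xtvx)
        if sign <= 0:
            return 1e12, None
        nll += 0.5 * logdet_x
    return nll, (beta, xtvx_inv)


def _fit_mixed(df: pd.DataFrame, response: str, rhs: str) -> ModelResult:
    from patsy import dmatrix
    from scipy.optimize import minimize

    df = df.copy()
    df["eye_cond"] = df["eye"].astype(str) + ":" + df["condition"].astype(str)

    # sufficient statistics: one cell per (recording, state)
    cell_cols = ["participant_id", "recording_id", "eye_cond",
                 "condition", "state"]
    g = df.groupby(cell_cols, observed=True)[response]
    cells = g.agg(["mean", "count"]).reset_index()
    within_ss = float(((df[response] - g.transform("mean")) ** 2).sum())
    n_total = len(df)
    k_cells_total = len(cells)

    design = dmatrix(rhs, cells, return_type="dataframe")
    design_info = design.design_info
    X_all = design.to_numpy()
    k_fe = X_all.shape[1]

    groups = []
    for _, idx in cells.groupby("participant_id", observed=True).groups.items():
        sub = cells.loc[idx]
        m = sub["mean"].to_numpy(dtype=float)
        X = X_all[cells.index.get_indexer(idx)]
        ec = pd.Categorical(sub["eye_cond"]).codes
        S = (ec[:, None] == ec[None, :]).astype(float)
        inv_n = 1.0 / sub["count"].to_numpy(dtype=float)
        groups.append((m, X, S, inv_n))

    # method-of-moments starting values
    s2_e0 = max(within_ss / max(n_total - k_cells_total, 1), 1e-6)
    cond_mean = cells.groupby(["condition", "state"], observed=True)["mean"].transform("mean")
    cells_dev = cells["mean"] - cond_mean
    part_dev = cells_dev.groupby(cells["participant_id"], observed=True).mean()
    s2_a0 = max(float(part_dev.var()) if len(part_dev) > 1 else 0.01, 1e-4)
    x0 = np.log([s2_a0, 0.1 * s2_a0, s2_e0])

    def objective(lt):
        return _reml_neg_loglik(lt, groups, n_total, k_cells_total, k_fe,
                                within_ss)[0]

    best = None
    for start in (x0, x0 + np.log([0.3, 1.0, 1.0]), x0 + np.log([3.0, 1.0, 1.0])):
        r = minimize(objective, start, method="Nelder-Mead",
                     options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000})
        if best is None or r.fun < best.fun:
            best = r
    converged = bool(best.success and best.fun < 1e11)
    nll, (beta, cov_beta) = _reml_neg_loglik(
        best.x, groups, n_total, k_cells_total, k_fe, within_ss
    )
    s2_a, s2_c, s2_e = np.exp(np.clip(best.x, -30.0, 30.0))

    names = [_clean_term(n) for n in design_info.column_names]
    fixed = {}
    for j, name in enumerate(names):
        est = float(beta[j])
        se = float(np.sqrt(max(cov_beta[j, j], 0.0)))
        z = est / se if se > 0 else 0.0
        p = 2 * sps.norm.sf(abs(z)) if se > 0 else 1.0
        fixed[name] = FixedEffect(
            estimate=est, se=se, z=float(z), p=float(p),
            ci95_lo=float(est - Z95 * se), ci95_hi=float(est + Z95 * se),
        )
    return ModelResult(
        fixed_effects=fixed,
        random_variances={
            "participant": float(s2_a),
            "angle_within_eye": float(s2_c),
            "residual": float(s2_e),
        },
        n_obs=n_total,
        n_groups=int(df["participant_id"].nunique()),
        converged=converged,
        _fe_params=np.asarray(beta, dtype=float),
        _fe_cov=np.asarray(cov_beta, dtype=float),
        _fe_names=names,
        _design_info=design_info,
    )


def fit_ipf_mixed_model(table: pd.DataFrame,
                        include_unaffected: bool = False) -> ModelResult:
    """REML mixed model: IPF ~ condition × state, random intercepts for
    participant and condition-within-participant-eye.

    Unaffected-eye observations are excluded by default (they provide the
    reference band, not a device condition); pass ``include_unaffected=True``
    to keep them.  Unbalanced/missing cells are tolerated.
    """
    df = table.dropna(subset=["ipf_mm"]).copy()
    if not include_unaffected:
        df = df[df["condition"] != "unaffected"]
    if df["participant_id"].nunique() < 2 or df["condition"].nunique() < 2:
        raise ValidationError("need >= 2 participants and >= 2 conditions")
    return _fit_mixed(df, "ipf_mm", _IPF_RHS)


def fit_comfort_model(table: pd.DataFrame) -> ModelResult:
    """Mixed model for the Likert comfort ratings (treated as interval data).

    One observation per recording; all-constant comfort yields a degenerate,
    flagged result with zero condition effects.
    """
    df = (table.drop_duplicates("recording_id")
          .dropna(subset=["comfort"]).copy())
    df["comfort"] = df["comfort"].astype(float)
    if df["condition"].nunique() < 2:
        raise ValidationError("comfort present on fewer than 2 conditions")
    if df["comfort"].nunique() <= 1:
        value = float(df["comfort"].iloc[0])
        fixed = {"Intercept": FixedEffect(value, 0.0, 0.0, 1.0, value, value)}
        for cond in sorted(df["condition"].unique()):
            if cond == "baseline":
                continue
            fixed[f"condition[{cond}]"] = FixedEffect(0.0, 0.0, 0.0, 1.0, 0.0, 0.0)
        return ModelResult(
            fixed_effects=fixed, random_variances={}, n_obs=len(df),
            n_groups=int(df["participant_id"].nunique()),
            converged=True, degenerate=True,
        )
    return _fit_mixed(df, "comfort", _COMFORT_RHS)


# ---------------------------------------------------------------------------
# linear combinations of fixed effects
# ---------------------------------------------------------------------------

def _design_row(model: ModelResult, **factors) -> np.ndarray:
    from patsy import build_design_matrices

    data = {k: [v] for k, v in factors.items()}
    (mat,) = build_design_matrices([model._design_info], data)
    return np.asarray(mat)[0]


def cell_mean(model: ModelResult, condition: str, state: str = "open"):
    """Model-implied mean for a (condition, state) cell with Wald 95% CI.

    Returns ``(estimate, se, ci_lo, ci_hi)``.
    """
    L = _design_row(model, condition=condition, state=state)
    est = float(L @ model._fe_params)
    se = float(np.sqrt(max(L @ model._fe_cov @ L, 0.0)))
    return est, se, est - Z95 * se, est + Z95 * se


def comfort_cell_mean(model: ModelResult, condition: str):
    """Cell mean for the comfort model (condition-only fixed effects)."""
    if model.degenerate:
        est = model.fixed_effects["Intercept"].estimate
        term = f"condition[{condition}]"
        if term in model.fixed_effects:
            est += model.fixed_effects[term].estimate
        return est, 0.0, est, est
    from patsy import build_design_matrices

    (mat,) = build_design_matrices([model._design_info], {"condition": [condition]})
    L = np.asarray(mat)[0]
    est = float(L @ model._fe_params)
    se = float(np.sqrt(max(L @ model._fe_cov @ L, 0.0)))
    return est, se, est - Z95 * se, est + Z95 * se


def condition_means_table(model: ModelResult, conditions: Sequence[str],
                          states: Sequence[str] = ("open", "spont_blink", "vol_blink")
                          ) -> pd.DataFrame:
    """Per-(condition, state) model means with 95% CIs (Fig-style table)."""
    rows = []
    for cond in conditions:
        for state in states:
            est, se, lo, hi = cell_mean(model, cond, state)
            rows.append((cond, state, est, se, lo, hi))
    return pd.DataFrame(
        rows, columns=["condition", "state", "mean_mm", "se", "ci95_lo", "ci95_hi"]
    )


def estimate_contrast(model: ModelResult, term_a: str, term_b: str):
    """Covariance-aware contrast between two fixed-effect terms.

    Returns ``(difference, z, p)``; antisymmetric in its arguments.
    """
    names = model._fe_names
    if names is None:
        raise ValidationError("model carries no contrast machinery")
    for t in (term_a, term_b):
        if t not in names:
            raise ValidationError(f"unknown term {t!r}")
    if term_a == term_b:
        return 0.0, 0.0, 1.0
    L = np.zeros(len(names))
    L[names.index(term_a)] = 1.0
    L[names.index(term_b)] = -1.0
    diff = float(L @ model._fe_params)
    se = float(np.sqrt(max(L @ model._fe_cov @ L, 0.0)))
    z = diff / se if se > 0 else 0.0
    p = 2 * sps.norm.sf(abs(z)) if se > 0 else 1.0
    return diff, float(z), float(p)


# ---------------------------------------------------------------------------
# profile (parallelism) analysis
# ---------------------------------------------------------------------------

def profile_parallelism_test(table: pd.DataFrame, state: str) -> ProfileResult:
    """Exact F test that per-eye angle profiles are parallel.

    Restricted to eyes with observations at all five angular positions for
    the given state.  The full model fits one mean per (eye, angle) cell;
    the reduced model is additive (eye + angle).  Their F comparison tests
    the eye × angle interaction, i.e. that every eye shares the same vector
    of adjacent-angle differences.
    """
    df = table[(table["state"] == state)
               & (table["condition"].isin(ANGLE_CONDITIONS))].copy()
    df["eye_id"] = df["participant_id"].astype(str) + "_" + df["eye"].astype(str)
    counts = df.groupby("eye_id")["condition"].nunique()
    complete = counts[counts == len(ANGLE_CONDITIONS)].index
    df = df[df["eye_id"].isin(complete)]
    eyes = sorted(df["eye_id"].unique())
    if len(eyes) < 2:
        raise ValidationError("need >= 2 eyes with complete 5-angle data")

    means = df.groupby(["eye_id", "condition"])["ipf_mm"].mean()
    n_cells = len(means)
    fitted_full = df.groupby(["eye_id", "condition"])["ipf_mm"].transform("mean")
    rss_full = float(((df["ipf_mm"] - fitted_full) ** 2).sum())
    n = len(df)
    df2 = n - n_cells

    # reduced additive model via least squares on eye/angle indicators
    eye_idx = pd.Categorical(df["eye_id"], categories=eyes).codes
    ang_idx = pd.Categorical(df["condition"], categories=list(ANGLE_CONDITIONS)).codes
    E, A = len(eyes), len(ANGLE_CONDITIONS)
    X = np.zeros((n, 1 + (E - 1) + (A - 1)))
    X[:, 0] = 1.0
    for e in range(1, E):
        X[eye_idx == e, e] = 1.0
    for a in range(1, A):
        X[ang_idx == a, E - 1 + a] = 1.0
    beta, *_ = np.linalg.lstsq(X, df["ipf_mm"].to_numpy(), rcond=None)
    rss_reduced = float(((df["ipf_mm"].to_numpy() - X @ beta) ** 2).sum())

    q = n_cells - (E + A - 1)
    if q < 1 or df2 < 1:
        raise ValidationError("not enough data for the parallelism test")
    # guard against float fuzz when both models fit (near-)exactly
    tot_ss = float(((df["ipf_mm"] - df["ipf_mm"].mean()) ** 2).sum())
    eps = 1e-10 * (tot_ss + 1.0)
    num_ss = max(rss_reduced - rss_full, 0.0)
    if rss_full < eps:
        F = 0.0 if num_ss < eps else np.inf
    else:
        F = (num_ss / q) / (rss_full / df2)
    p = float(sps.f.sf(F, q, df2))

    seg_rows = []
    for eye in eyes:
        m = [means.loc[(eye, a)] for a in ANGLE_CONDITIONS]
        for j in range(len(ANGLE_CONDITIONS) - 1):
            seg_rows.append(
                (eye, f"{ANGLE_CONDITIONS[j]}->{ANGLE_CONDITIONS[j + 1]}",
                 m[j + 1] - m[j])
            )
    segments = pd.DataFrame(seg_rows, columns=["eye_id", "segment", "diff_mm"])
    return ProfileResult(state=state, statistic=float(F), df=(q, df2), p=p,
                         segments=segments)


# ---------------------------------------------------------------------------
# rolling-direction lookup and agreement
# ---------------------------------------------------------------------------

_EXPECTED_ROLLING = {
    ("type1", 0): "min", ("type1", 30): "min",
    ("type1", 60): "out", ("type1", 90): "out", ("type1", 180): "out",
    ("type2", 0): "out", ("type2", 30): "out",
    ("type2", 60): "min", ("type2", 90): "in", ("type2", 180): "in",
}


def expected_rolling_direction(magnet_type: str, angle_deg: int) -> str:
    """Predicted eyelid-magnet rolling direction under the rotated field.

    Type 1 (north pole up): minimal rolling at 0°/30°, outward from 60° on.
    Type 2 (north pole out): outward at 0°/30°, minimal at 60°, inward at
    90°/180°.  Assumes a positive back vertex distance.
    """
    key = (magnet_type, angle_deg)
    if key not in _EXPECTED_ROLLING:
        raise ValidationError(f"unknown magnet/angle combination {key}")
    return _EXPECTED_ROLLING[key]


def rolling_agreement(counts: RollingCounts) -> Optional[float]:
    """Observed/expected proportion, rounded half-up to 2 decimals.

    ``None`` when expected is zero (undefined).  Half-up (not banker's)
    rounding matches the printed-table convention (5/8 -> 0.63).
    """
    if counts.expected == 0:
        return None
    import math

    return math.floor(counts.observed / counts.expected * 100 + 0.5) / 100


# ---------------------------------------------------------------------------
# demographics
# ---------------------------------------------------------------------------

def demographics_summary(records: Sequence[ParticipantRecord]) -> dict:
    """Tabulate the participant table.

    The median age collapses duplicate enrollments (``duplicate_of``) to
    unique individuals; gender and laterality are counted over table rows;
    the contributing count is rows minus excluded rows.
    """
    if not records:
        raise ValidationError("no participant records")
    unique = [r for r in records if r.duplicate_of is None]
    ages = sorted(r.age_yr for r in unique)
    median_age = float(np.median(ages))
    gender_counts = {g: sum(r.gender == g for r in records) for g in ("M", "F")}
    side_counts = {s: sum(r.side == s for r in records)
                   for s in ("left", "right", "both")}
    return {
        "n_rows": len(records),
        "n_unique_individuals": len(unique),
        "median_age_yr": median_age,
        "gender_counts": gender_counts,
        "side_counts": side_counts,
        "n_contributing": sum(not r.excluded for r in records),
    }
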