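"""Cross-sectional association models between CSF analytes and network metrics.

The modelling ladder has three tiers, all ordinary least squares on
standardized variables:

* tier 1: ``outcome ~ predictor + sex``
* tier 2: ``outcome ~ predictor * mutation + sex``
* tier 3: ``outcome ~ predictor * mutation + sex + age``

Eight analytes (pTau, tTau, SNAP-25, Ng, NfL, VILIP-1, YKL-40, sTREM2) are
natural-log transformed to approach normality before Z-scoring; the
Abeta42/40 ratio is Z-scored but never logged.  Z-scoring always uses the
entire cohort so slope estimates are comparable across predictors.  With
nine analyte predictors tested against one outcome, Bonferroni-corrected
significance is reached at p < 0.05/9 ≈ 0.0056.

Carriers are additionally staged by amyloid status and clinical severity:
stage 1 is a normal pTau/Abeta42 ratio (< 0.019); stages 2-4 have abnormal
ratios with CDR 0, 0.5 and >= 1 respectively.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf

logger = logging.getLogger("gmnet")

from .simulate import ANALYTES, LOG_ANALYTES

__all__ = [
    "ModelResult",
    "StageAssignment",
    "PREDICTORS",
    "preprocess",
    "assign_stage",
    "fit_association",
    "group_slopes",
    "stage_interaction",
    "spearman_matrix",
    "BONFERRONI_FAMILY_SIZE",
]

#: The nine standard predictors of the main analysis.
PREDICTORS = (
    "ratio_ab4240", "ptau", "ttau", "snap25", "ng", "nfl",
    "vilip1", "ykl40", "strem2",
)

BONFERRONI_FAMILY_SIZE = 9

_Z = stats.norm.ppf(0.975)


@dataclass
class ModelResult:
    """One fitted association model with its derived quantities."""

    outcome: str
    predictor: str
    tier: int
    n: int
    coefficients: dict            # name -> {estimate, ci_low, ci_high, p}
    interaction_t: float | None = None
    interaction_p: float | None = None
    slopes: dict = field(default_factory=dict)  # group -> {estimate, ci_low, ci_high, p}
    bonferroni_alpha: float = 0.05 / BONFERRONI_FAMILY_SIZE
    params: np.ndarray | None = None
    cov: np.ndarray | None = None
    param_names: list | None = None
    resid_df: float | None = None

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "predictor": self.predictor,
            "tier": self.tier,
            "n": self.n,
            "coefficients": self.coefficients,
            "interaction_t": self.interaction_t,
            "interaction_p": self.interaction_p,
            "slopes": self.slopes,
            "bonferroni_alpha": self.bonferroni_alpha,
        }


@dataclass
class StageAssignment:
    """Disease stage of one carrier, derived from amyloid ratio and CDR."""

    stage: int | None
    ratio_ptau_ab42: float | None
    cdr: float | None


def preprocess(
    table: pd.DataFrame,
    outcome: str = "small_world",
    extra_zscore: tuple = ("age", "total_gm_volume"),
) -> pd.DataFrame:
    """Log-transform the eight skewed analytes and Z-score all model variables.

    The natural log is applied to pTau, tTau, SNAP-25, Ng, NfL, VILIP-1,
    YKL-40 and sTREM2 where present; the Abeta42/40 ratio (and the raw
    Abeta peptides) stay on their original scale.  Every predictor, the
    outcome, and the extra covariates are then Z-scored using mean and SD of
    all available values in the entire cohort.  Missing values propagate.
    """
    out = table.copy()
    for a in LOG_ANALYTES:
        if a not in out.columns:
            continue
        vals = out[a]
        bad = vals.notna() & (vals <= 0)
        if bad.any():
            sid = out.loc[bad, "subject_id"].iloc[0] if "subject_id" in out else "?"
            raise ValueError(
                f"non-positive {a} value for subject {sid}: cannot log-transform"
            )
        out[a] = np.log(vals)
    to_scale = [c for c in (*ANALYTES, "ratio_ab4240", outcome, *extra_zscore)
                if c in out.columns]
    for c in to_scale:
        v = out[c].astype(float)
        m, s = v.mean(), v.std(ddof=1)
        if not np.isfinite(s) or s == 0:
            raise ValueError(f"column {c!r} has zero variance; cannot Z-score")
        out[c] = (v - m) / s
    logger.info("preprocess: logged %d analytes, z-scored %d columns over n=%d",
                len(LOG_ANALYTES), len(to_scale), len(out))
    return out


def assign_stage(
    ratio_ptau_ab42: float | None,
    cdr: float,
    cutoff: float = 0.019,
) -> StageAssignment:
    """Stage a mutation carrier from the pTau/Abeta42 ratio and global CDR.

    Stage 1: ratio below the cutoff (amyloid-negative) regardless of CDR.
    Stages 2/3/4: ratio at or above the cutoff with CDR 0 / 0.5 / >= 1.
    The boundary value (ratio == cutoff) is classed abnormal, since the
    normal range is defined strictly below the cutoff.  A missing ratio
    leaves the subject unassigned.
    """
    if ratio_ptau_ab42 is None or (
        isinstance(ratio_ptau_ab42, float) and np.isnan(ratio_ptau_ab42)
    ):
        return StageAssignment(stage=None, ratio_ptau_ab42=None, cdr=cdr)
    if ratio_ptau_ab42 < 0:
        raise ValueError("ratio_ptau_ab42 must be >= 0")
    if cdr not in (0.0, 0.5, 1.0, 2.0, 3.0):
        raise ValueError(f"invalid CDR {cdr}")
    if ratio_ptau_ab42 < cutoff:
        stage = 1
    elif cdr == 0.0:
        stage = 2
    elif cdr == 0.5:
        stage = 3
    else:
        stage = 4
    return StageAssignment(stage=stage, ratio_ptau_ab42=float(ratio_ptau_ab42), cdr=cdr)


def assign_stages(table: pd.DataFrame, cutoff: float = 0.019) -> pd.Series:
    """Vectorized stage assignment over a cohort table (carriers and all)."""
    return pd.Series(
        [
            assign_stage(r, c, cutoff).stage
            for r, c in zip(table["ratio_ptau_ab42"], table["cdr"])
        ],
        index=table.index,
        dtype="object",
    ).astype("Int64")


def _check_rank(design: pd.DataFrame) -> None:
    x = design.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # identify columns involved in the collinearity
        bad = []
        base_cols: list[int] = []
        for j in range(x.shape[1]):
            cand = base_cols + [j]
            if np.linalg.matrix_rank(x[:, cand]) < len(cand):
                bad.append(design.columns[j])
            else:
                base_cols.append(j)
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")


def _wald(est: float, se: float, df: float) -> dict:
    p = 2 * stats.norm.sf(abs(est / se)) if se > 0 else float("nan")
    return {
        "estimate": float(est),
        "ci_low": float(est - _Z * se),
        "ci_high": float(est + _Z * se),
        "p": float(p),
    }


def fit_association(
    table: pd.DataFrame,
    predictor: str,
    outcome: str = "small_world",
    tier: int = 2,
) -> ModelResult:
    """Fit one tier of the association ladder by ordinary least squares.

    Expects a preprocessed (logged + Z-scored) table.  Complete cases are
    selected per model.  Wald 95% confidence intervals are reported on every
    coefficient; tiers 2 and 3 add the mutation-by-predictor interaction t
    and p, and the estimated within-group slopes.
    """
    if tier not in (1, 2, 3):
        raise ValueError("tier must be 1, 2 or 3")
    cols = [outcome, predictor, "sex"]
    if tier >= 2:
        cols.append("mutation_status")
    if tier == 3:
        cols.append("age")
    data = table[cols].dropna().copy()
    if len(data) < 10:
        raise ValueError(f"only {len(data)} complete cases; need at least 10")
    data["mutation"] = (
        (data["mutation_status"] == "carrier").astype(float) if tier >= 2 else 0.0
    )
    pred_term = f"Q('{predictor}')"
    if tier == 1:
        formula = f"Q('{outcome}') ~ {pred_term} + C(sex)"
    elif tier == 2:
        formula = f"Q('{outcome}') ~ {pred_term} * mutation + C(sex)"
    else:
        formula = f"Q('{outcome}') ~ {pred_term} * mutation + C(sex) + age"
    model = smf.ols(formula, data=data)
    _check_rank(pd.DataFrame(model.exog, columns=model.exog_names))
    fit = model.fit()
    names = list(fit.params.index)
    coefs = {
        nm: _wald(fit.params[nm], fit.bse[nm], fit.df_resid) for nm in names
    }
    inter_name = f"{pred_term}:mutation"
    result = ModelResult(
        outcome=outcome,
        predictor=predictor,
        tier=tier,
        n=len(data),
        coefficients=coefs,
        params=fit.params.to_numpy(),
        cov=fit.cov_params().to_numpy(),
        param_names=names,
        resid_df=float(fit.df_resid),
    )
    if tier >= 2:
        t = float(fit.tvalues[inter_name])
        result.interaction_t = t
        result.interaction_p = float(
            2 * stats.t.sf(abs(t), fit.df_resid)
        )
        for grp in ("non-carrier", "carrier"):
            result.slopes[grp] = group_slopes(result, grp)
    logger.info(
        "fit_association: %s ~ %s tier=%d n=%d beta=%.3f",
        outcome, predictor, tier, len(data),
        coefs[pred_term]["estimate"],
    )
    return result


def group_slopes(result: ModelResult, group: str) -> dict:
    """Estimated marginal slope of the predictor within one mutation group.

    Non-carrier slope is the predictor main effect; carrier slope adds the
    interaction coefficient.  The CI follows from the fitted covariance by
    the delta method (here: a fixed linear contrast of coefficients).
    """
    if result.tier < 2:
        raise ValueError("group slopes require a tier-2 or tier-3 model")
    if group not in ("carrier", "non-carrier"):
        raise ValueError(f"unknown group {group!r}")
    names = result.param_names
    pred_term = f"Q('{result.predictor}')"
    contrast = np.zeros(len(names))
    contrast[names.index(pred_term)] = 1.0
    if group == "carrier":
        contrast[names.index(f"{pred_term}:mutation")] = 1.0
    est = float(contrast @ result.params)
    se = float(np.sqrt(contrast @ result.cov @ contrast))
    return _wald(est, se, result.resid_df)


def stage_interaction(
    table: pd.DataFrame,
    predictor: str,
    outcome: str = "small_world",
    alpha: float = 0.05,
    min_stage_n: int = 3,
    cutoff: float = 0.019,
) -> dict:
    """Within carriers: does the predictor's slope depend on disease stage?

    Fits ``outcome ~ predictor * stage + sex`` on carriers, tests the joint
    predictor-by-stage interaction with a Wald F test, and — when that test
    is significant at ``alpha`` — compares every pair of stage slopes with
    studentized-range (Tukey HSD) adjusted p-values using the residual df of
    the single fitted model.  Stages with fewer than ``min_stage_n`` subjects
    are excluded with a warning.
    """
    mc = table[table["mutation_status"] == "carrier"].copy()
    mc["stage"] = assign_stages(mc, cutoff=cutoff)
    mc = mc.dropna(subset=[outcome, predictor, "sex", "stage"])
    counts = mc["stage"].value_counts()
    small = counts[counts < min_stage_n].index.tolist()
    if small:
        warnings.warn(
            f"stages {sorted(int(s) for s in small)} have fewer than "
            f"{min_stage_n} subjects and are excluded"
        )
        mc = mc[~mc["stage"].isin(small)]
    stages = sorted(int(s) for s in mc["stage"].unique())
    if len(stages) < 2:
        raise ValueError("need at least 2 stages represented")
    mc["stage"] = mc["stage"].astype(int).astype("category")
    formula = f"Q('{outcome}') ~ Q('{predictor}') * C(stage) + C(sex)"
    fit = smf.ols(formula, data=mc).fit()
    inter_terms = [
        nm for nm in fit.params.index
        if nm.startswith(f"Q('{predictor}'):C(stage)")
    ]
    ftest = fit.f_test([f"{t} = 0" for t in inter_terms])
    joint_p = float(ftest.pvalue)
    df_resid = float(fit.df_resid)

    # per-stage slopes via contrasts on the single fitted model
    names = list(fit.params.index)
    cov = fit.cov_params().to_numpy()
    params = fit.params.to_numpy()
    base = names.index(f"Q('{predictor}')")
    slope_info = {}
    contrasts = {}
    for s in stages:
        c = np.zeros(len(names))
        c[base] = 1.0
        term = f"Q('{predictor}'):C(stage)[T.{s}]"
        if term in names:
            c[names.index(term)] = 1.0
        contrasts[s] = c
        est = float(c @ params)
        se = float(np.sqrt(c @ cov @ c))
        slope_info[s] = _wald(est, se, df_resid)

    pairwise = []
    if joint_p < alpha:
        k = len(stages)
        for i, si in enumerate(stages):
            for sj in stages[i + 1:]:
                c = contrasts[si] - contrasts[sj]
                diff = float(c @ params)
                se = float(np.sqrt(c @ cov @ c))
                tstat = diff / se
                # Tukey HSD: refer |t|*sqrt(2) to the studentized range
                p_adj = float(
                    stats.studentized_range.sf(abs(tstat) * np.sqrt(2), k, df_resid)
                )
                pairwise.append(
                    {
                        "stage_a": si,
                        "stage_b": sj,
                        "slope_difference": diff,
                        "se": se,
                        "t": float(tstat),
                        "p_tukey": p_adj,
                    }
                )
    return {
        "outcome": outcome,
        "predictor": predictor,
        "stages": stages,
        "n": int(len(mc)),
        "joint_interaction_F": float(ftest.fvalue),
        "joint_interaction_p": joint_p,
        "stage_slopes": {str(s): v for s, v in slope_info.items()},
        "pairwise_tukey": pairwise,
    }


def spearman_matrix(
    table: pd.DataFrame, analytes: tuple | list = PREDICTORS, min_pairs: int = 3
) -> pd.DataFrame:
    """Pairwise-complete Spearman rank correlations among analytes.

    Cells with fewer than ``min_pairs`` complete observation pairs are NaN
    (flagged missing); the matrix is symmetric with unit diagonal.
    """
    cols = [a for a in analytes if a in table.columns]
    sub = table[cols].astype(float)
    corr = sub.corr(method="spearman", min_periods=min_pairs)
    notna = sub.notna().astype(float).to_numpy()
    pair_counts = notna.T @ notna
    corr = corr.mask(pair_counts < min_pairs)
    for c in cols:
        corr.loc[c, c] = 1.0
    return corr
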