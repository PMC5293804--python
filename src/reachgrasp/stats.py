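"""Within-subject inference on per-subject condition means.

The analysis chain is the classical one for a 2 (verb type) x 3 (pronoun)
fully within-subject design:

* per-subject cell means of each kinematic parameter;
* repeated-measures ANOVA with the subject-by-effect error strata, exact F
  p-values, and partial eta squared (eta_p^2 = SS_effect / (SS_effect +
  SS_error) = F df1 / (F df1 + df2));
* planned paired t comparisons of the two verb types within each pronoun,
  one-sided in the predicted direction by default, judged against a
  Bonferroni-style corrected alpha;
* a default-prior (Jeffreys-Zellner-Siow) Bayes-factor ANOVA comparing the
  full model (verb + pronoun + interaction + subject) against the subject-only
  null, with g-prior marginal likelihoods integrated by seeded Monte Carlo.

No sphericity correction is applied by default (uncorrected degrees of freedom
are reported); Greenhouse-Geisser is available behind a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.linalg import null_space
from scipy.special import logsumexp

from .errors import InsufficientDataError, NumericalFailureError, SchemaError
from .stimuli import CELLS, PRONOUNS, VERB_TYPES

#: Kinematic parameters carried through the means/report tables.
PARAMETERS = (
    "reach_time_ms",
    "t_vpeak_ms",
    "pct_t_vpeak",
    "vpeak_mm_s",
    "grasp_time_ms",
    "max_aperture_mm",
    "t_max_aperture_ms",
    "pct_t_max_aperture",
)

CELL_LABELS = {
    ("I", "AV"): "I_Action",
    ("YOU", "AV"): "You_Action",
    ("HE", "AV"): "He_Action",
    ("I", "IV"): "I_Interaction",
    ("YOU", "IV"): "You_Interaction",
    ("HE", "IV"): "He_Interaction",
}

#: JZS default prior scales: 1/2 on fixed effect blocks, 1 on the subject
#: (random) block — the conventional "medium"/"nuisance" defaults.
RSCALE_FIXED = 0.5
RSCALE_RANDOM = 1.0


@dataclass(frozen=True)
class AnovaResult:
    effect: str
    F: float
    df1: int
    df2: int
    MSE: float
    p: float
    eta_p2: float


@dataclass(frozen=True)
class TTestResult:
    comparison: str
    t: float
    df: int
    p: float
    sided: str
    alpha_corrected: float
    significant: bool
    degenerate: bool = False


@dataclass(frozen=True)
class BayesFactorResult:
    model: str
    BF10: float
    BF01: float
    mc_error: float


def eta_p2_from_f(F: float, df1: int, df2: int) -> float:
    """Partial eta squared recovered from an F statistic and its df."""
    return F * df1 / (F * df1 + df2)


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal half-up rounding (47.35 -> 47.4), as used in the report tables."""
    if not np.isfinite(x):
        return float("nan")
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Condition means
# ---------------------------------------------------------------------------

def condition_means(
    params: pd.DataFrame, parameters: tuple[str, ...] = PARAMETERS
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject cell means of each parameter over valid critical trials.

    Subjects missing any of the six cells are dropped (inference needs a
    complete 2x3 table per subject). Returns ``(means, dropped_report)``;
    ``means`` is long over (subject_id, pronoun, verb_type) with one column per
    parameter.
    """
    required = {"subject_id", "pronoun", "verb_type"}
    if not required.issubset(params.columns):
        raise SchemaError(f"params table needs columns {sorted(required)}")
    table = params
    if "is_catch" in table.columns:
        table = table[~table["is_catch"].astype(bool)]
    if "valid" in table.columns:
        table = table[table["valid"].astype(bool)]
    present = [p for p in parameters if p in table.columns]
    grouped = (
        table.groupby(["subject_id", "pronoun", "verb_type"], sort=True)[present]
        .mean()
        .reset_index()
    )
    dropped_rows = []
    complete = []
    for subject_id, g in grouped.groupby("subject_id", sort=True):
        cells = set(zip(g["pronoun"], g["verb_type"]))
        missing = [c for c in CELLS if c not in cells]
        if missing:
            dropped_rows.append({"subject_id": subject_id,
                                 "missing_cells": ";".join(map("_".join, missing))})
        else:
            complete.append(g)
    means = (pd.concat(complete, ignore_index=True) if complete
             else grouped.iloc[0:0].copy())
    report = pd.DataFrame(dropped_rows, columns=["subject_id", "missing_cells"])
    return means, report


def _cell_array(means: pd.DataFrame, parameter: str) -> tuple[np.ndarray, list[str]]:
    """(n_subjects, 3 pronouns, 2 verb types) array of one parameter."""
    if parameter not in means.columns:
        raise SchemaError(f"parameter {parameter!r} not in means table")
    pivot = means.pivot_table(index="subject_id", columns=["pronoun", "verb_type"],
                              values=parameter)
    subjects = list(pivot.index)
    data = np.empty((len(subjects), len(PRONOUNS), len(VERB_TYPES)))
    for i, p in enumerate(PRONOUNS):
        for j, v in enumerate(VERB_TYPES):
            data[:, i, j] = pivot[(p, v)].to_numpy()
    if np.isnan(data).any():
        raise InsufficientDataError(
            f"missing cell means for parameter {parameter!r}"
        )
    return data, subjects


# ---------------------------------------------------------------------------
# Repeated-measures ANOVA
# ---------------------------------------------------------------------------

def rm_anova(
    means: pd.DataFrame, parameter: str, sphericity_correction: bool = False
) -> list[AnovaResult]:
    """Two-way fully within-subject ANOVA (Verb, Pronoun, Verb x Pronoun).

    Each effect is tested against its own subject-by-effect interaction
    stratum. ``sphericity_correction=True`` applies Greenhouse-Geisser to the
    pronoun and interaction effects (Verb has 1 df and needs none).
    """
    y, subjects = _cell_array(means, parameter)
    n = len(subjects)
    if n < 2:
        raise InsufficientDataError("rm_anova needs at least 2 subjects")
    P, V = y.shape[1], y.shape[2]

    grand = y.mean()
    m_s = y.mean(axis=(1, 2))            # subject
    m_p = y.mean(axis=(0, 2))            # pronoun
    m_v = y.mean(axis=(0, 1))            # verb type
    m_sp = y.mean(axis=2)                # subject x pronoun
    m_sv = y.mean(axis=1)                # subject x verb
    m_pv = y.mean(axis=0)                # pronoun x verb

    ss_p = n * V * np.sum((m_p - grand) ** 2)
    ss_v = n * P * np.sum((m_v - grand) ** 2)
    ss_pv = n * np.sum((m_pv - m_p[:, None] - m_v[None, :] + grand) ** 2)
    ss_sp = V * np.sum((m_sp - m_s[:, None] - m_p[None, :] + grand) ** 2)
    ss_sv = P * np.sum((m_sv - m_s[:, None] - m_v[None, :] + grand) ** 2)
    resid = (
        y
        - m_sp[:, :, None]
        - m_sv[:, None, :]
        - m_pv[None, :, :]
        + m_s[:, None, None]
        + m_p[None, :, None]
        + m_v[None, None, :]
        - grand
    )
    ss_spv = np.sum(resid**2)

    def _result(effect: str, ss_eff: float, df1: int, ss_err: float,
                data_2d: np.ndarray | None) -> AnovaResult:
        df2 = (n - 1) * df1
        eps = 1.0
        if sphericity_correction and df1 > 1 and data_2d is not None:
            eps = _greenhouse_geisser(data_2d)
        F = (ss_eff / df1) / (ss_err / df2)
        p = float(sps.f.sf(F, df1 * eps, df2 * eps))
        return AnovaResult(
            effect=effect,
            F=float(F),
            df1=df1,
            df2=df2,
            MSE=float(ss_err / df2),
            p=p,
            eta_p2=float(ss_eff / (ss_eff + ss_err)),
        )

    pv_scores = (y[:, :, 0] - y[:, :, 1])  # verb difference per pronoun
    return [
        _result("verb_type", ss_v, V - 1, ss_sv, None),
        _result("pronoun", ss_p, P - 1, ss_sp, m_sp),
        _result("verb_type:pronoun", ss_pv, (P - 1) * (V - 1), ss_spv, pv_scores),
    ]


def _greenhouse_geisser(scores: np.ndarray) -> float:
    """GG epsilon from the covariance of the per-subject condition scores."""
    S = np.cov(scores.T, ddof=1)
    k = S.shape[0]
    mean_diag = np.trace(S) / k
    num = (k * mean_diag - S.mean()) ** 2 * k**2
    den = (k - 1) * (np.sum(S @ S) - 2 * k * np.sum(S.mean(axis=0) ** 2)
                     + k**2 * S.mean() ** 2) * k**2
    eps = num / den if den > 0 else 1.0
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


# ---------------------------------------------------------------------------
# Planned comparisons
# ---------------------------------------------------------------------------

#: Verb-type contrast within each pronoun, one-sided: interaction verbs are
#: predicted to reach the velocity peak earlier (AV > IV on percent latency).
DEFAULT_COMPARISONS = tuple(
    ((p, "AV"), (p, "IV"), "greater") for p in PRONOUNS
)


def planned_ttests(
    means: pd.DataFrame,
    parameter: str,
    comparisons=DEFAULT_COMPARISONS,
    alpha: float = 0.05,
    correction: str = "bonferroni",
) -> list[TTestResult]:
    """Paired t-tests on subject-wise cell differences.

    ``correction='bonferroni'`` judges each test at alpha/k; ``'paper'`` uses
    the fixed 0.01 convention; ``'none'`` leaves alpha unchanged. Zero-variance
    differences yield a flagged degenerate result (t = 0, one-sided p = 0.5
    when all differences vanish) instead of NaN.
    """
    y, _ = _cell_array(means, parameter)
    idx = {cell: (PRONOUNS.index(cell[0]), VERB_TYPES.index(cell[1]))
           for cell in CELLS}
    k = len(comparisons)
    if correction == "bonferroni":
        alpha_corr = alpha / k
    elif correction == "paper":
        alpha_corr = 0.01
    elif correction == "none":
        alpha_corr = alpha
    else:
        raise SchemaError(f"unknown correction {correction!r}")

    results = []
    for cell_a, cell_b, alternative in comparisons:
        (ia, ja), (ib, jb) = idx[tuple(cell_a)], idx[tuple(cell_b)]
        diffs = y[:, ia, ja] - y[:, ib, jb]
        n = diffs.size
        df = n - 1
        label = f"{CELL_LABELS[tuple(cell_a)]}-{CELL_LABELS[tuple(cell_b)]}"
        sd = diffs.std(ddof=1)
        if sd == 0.0:
            if np.allclose(diffs, 0.0):
                t_stat, degenerate = 0.0, True
            else:
                t_stat = math.copysign(math.inf, diffs.mean())
                degenerate = True
        else:
            t_stat = float(diffs.mean() / (sd / math.sqrt(n)))
            degenerate = False
        if alternative == "greater":
            p = float(sps.t.sf(t_stat, df))
        elif alternative == "less":
            p = float(sps.t.cdf(t_stat, df))
        elif alternative == "two-sided":
            p = float(2.0 * sps.t.sf(abs(t_stat), df))
        else:
            raise SchemaError(f"unknown alternative {alternative!r}")
        results.append(
            TTestResult(
                comparison=label,
                t=t_stat,
                df=df,
                p=p,
                sided="two" if alternative == "two-sided" else "one",
                alpha_corrected=alpha_corr,
                significant=bool(p < alpha_corr),
                degenerate=degenerate,
            )
        )
    return results


# ---------------------------------------------------------------------------
# JZS Bayes-factor ANOVA
# ---------------------------------------------------------------------------

def _orthonormal_contrasts(levels: int) -> np.ndarray:
    """(levels, levels-1) orthonormal basis of the sum-to-zero subspace."""
    return null_space(np.ones((1, levels)))


def _design_blocks(y_array: np.ndarray) -> tuple[np.ndarray, list[np.ndarray],
                                                 np.ndarray]:
    """Response vector and effect-block design matrices for the 2x3 design."""
    n, P, V = y_array.shape
    y = y_array.reshape(-1)
    rows = n * P * V
    z_subject = np.repeat(np.eye(n), P * V, axis=0)
    z_pron = np.tile(np.repeat(np.eye(P), V, axis=0), (n, 1))
    z_verb = np.tile(np.eye(V), (n * P, 1))
    x_verb = z_verb @ _orthonormal_contrasts(V)
    x_pron = z_pron @ _orthonormal_contrasts(P)
    x_int = np.empty((rows, x_verb.shape[1] * x_pron.shape[1]))
    c = 0
    for i in range(x_verb.shape[1]):
        for j in range(x_pron.shape[1]):
            x_int[:, c] = x_verb[:, i] * x_pron[:, j]
            c += 1
    x_subj = z_subject @ _orthonormal_contrasts(n)
    return y, [x_verb, x_pron, x_int], x_subj


def _log_marginal_ratios(
    y: np.ndarray, blocks: list[np.ndarray], rscales: list[float],
    rng: np.random.Generator, n_mc: int,
) -> np.ndarray:
    """log m(y|g)/m0(y) for Monte-Carlo draws of the block-wise g parameters.

    Conditional on g the marginal has the closed g-prior form; g for each block
    is drawn from its JZS prior, a scaled inverse-chi-squared(1) with scale
    rscale^2.
    """
    X = np.hstack(blocks)
    cols_per_block = [b.shape[1] for b in blocks]
    N = y.size
    y_c = y - y.mean()
    X_c = X - X.mean(axis=0)
    yty = float(y_c @ y_c)
    XtX = X_c.T @ X_c
    Xty = X_c.T @ y_c

    # g ~ rscale^2 / chi^2_1 per block, expanded to that block's columns.
    z = rng.standard_normal((n_mc, len(blocks)))
    g_blocks = np.array(rscales)[None, :] ** 2 / np.maximum(z**2, 1e-300)
    g_cols = np.repeat(g_blocks, cols_per_block, axis=1)

    A = XtX[None, :, :] + np.apply_along_axis(np.diag, 1, 1.0 / g_cols)
    try:
        chol = np.linalg.cholesky(A)
    except np.linalg.LinAlgError as exc:
        raise NumericalFailureError("g-prior normal matrix not PD") from exc
    logdet = 2.0 * np.sum(np.log(np.einsum("sii->si", chol)), axis=1)
    u = np.linalg.solve(A, np.broadcast_to(Xty, (n_mc, Xty.size))[..., None])
    quad = np.einsum("i,sij->s", Xty, u)
    R = yty - quad
    if np.any(R <= 0):
        raise NumericalFailureError("non-positive residual sum of squares")
    log_ratio = (
        -0.5 * (np.sum(np.log(g_cols), axis=1) + logdet)
        - 0.5 * (N - 1) * (np.log(R) - math.log(yty))
    )
    if not np.all(np.isfinite(log_ratio)):
        raise NumericalFailureError("non-finite marginal likelihood ratio")
    return log_ratio


def _log_mean_and_relse(log_ratio: np.ndarray) -> tuple[float, float]:
    n = log_ratio.size
    log_mean = float(logsumexp(log_ratio) - math.log(n))
    w = np.exp(log_ratio - log_ratio.max())
    rel_se = float(w.std(ddof=1) / (w.mean() * math.sqrt(n)))
    return log_mean, rel_se


def jzs_bf_anova(
    means: pd.DataFrame,
    parameter: str,
    n_mc_samples: int = 20000,
    seed: int = 0,
) -> BayesFactorResult:
    """Default-prior Bayes factor: full 2x3 model vs subject-only null.

    The full model carries verb, pronoun, their interaction and the subject
    block; the null carries the subject block alone. Each block has its own g
    with the JZS default scales (1/2 fixed, 1 random); the g integrals are
    seeded Monte Carlo, and ``mc_error`` is the propagated standard error on
    the BF10 scale.
    """
    y_array, subjects = _cell_array(means, parameter)
    if len(subjects) < 2:
        raise InsufficientDataError("jzs_bf_anova needs at least 2 subjects")
    y, fixed_blocks, x_subj = _design_blocks(y_array)

    rng = np.random.default_rng(seed)
    full_blocks = fixed_blocks + [x_subj]
    full_scales = [RSCALE_FIXED] * len(fixed_blocks) + [RSCALE_RANDOM]
    lr_full = _log_marginal_ratios(y, full_blocks, full_scales, rng, n_mc_samples)
    lr_null = _log_marginal_ratios(y, [x_subj], [RSCALE_RANDOM], rng, n_mc_samples)

    log_m1, rel1 = _log_mean_and_relse(lr_full)
    log_m0, rel0 = _log_mean_and_relse(lr_null)
    bf10 = math.exp(log_m1 - log_m0)
    mc_error = bf10 * math.sqrt(rel1**2 + rel0**2)
    return BayesFactorResult(
        model="verb_type + pronoun + verb_type:pronoun + subject vs subject",
        BF10=bf10,
        BF01=1.0 / bf10,
        mc_error=mc_error,
    )


# ---------------------------------------------------------------------------
# Report tables
# ---------------------------------------------------------------------------

def summarize_means(
    means: pd.DataFrame, parameters: tuple[str, ...] = PARAMETERS
) -> pd.DataFrame:
    """Grand-mean table: rows = parameters, columns = the six cells, 1 decimal."""
    columns = ["parameter"] + [CELL_LABELS[c] for c in CELLS]
    rows = []
    for param in parameters:
        if param not in means.columns:
            continue
        row: dict = {"parameter": param}
        for cell in CELLS:
            sel = means[(means["pronoun"] == cell[0])
                        & (means["verb_type"] == cell[1])][param]
            row[CELL_LABELS[cell]] = (round_half_up(float(sel.mean()), 1)
                                      if len(sel) else float("nan"))
        rows.append(row)
    return pd.DataFrame(rows, columns=columns)


def anova_table(results: list[AnovaResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"effect": r.effect, "F": r.F, "df1": r.df1, "df2": r.df2,
             "MSE": r.MSE, "p": r.p, "eta_p2": r.eta_p2}
            for r in results
        ],
        columns=["effect", "F", "df1", "df2", "MSE", "p", "eta_p2"],
    )


def ttest_table(results: list[TTestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"comparison": r.comparison, "t": r.t, "df": r.df, "p": r.p,
             "sided": r.sided, "alpha_corrected": r.alpha_corrected,
             "significant": r.significant, "degenerate": r.degenerate}
            for r in results
        ],
        columns=["comparison", "t", "df", "p", "sided", "alpha_corrected",
                 "significant", "degenerate"],
    )


def bayes_table(results: list[BayesFactorResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"model": r.model, "BF10": r.BF10, "BF01": r.BF01,
             "mc_error": r.mc_error}
            for r in results
        ],
        columns=["model", "BF10", "BF01", "mc_error"],
    )
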