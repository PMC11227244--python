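"""Diversity, dissimilarity and the statistical testing layer.

Alpha diversity is the Shannon index H = -sum p_i ln p_i (natural log,
the ecology-package convention) over relative vOTU abundances; beta
diversity is Bray-Curtis dissimilarity BC = sum|a-b| / sum(a+b). The
testing layer wraps Pearson chi-squared with standardized-residual post
hoc, Pearson correlation, Wilcoxon rank-sum, linear mixed models with a
treatment-by-timepoint interaction and a random intercept per subject,
and Benjamini-Hochberg FDR adjustment; p values are adjusted within the
family each analysis declares.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .catalog import AbundanceMatrix
from .model import (
    Lifestyle,
    Role,
    SampleRecord,
    Timepoint,
    Treatment,
    POST_TIMEPOINTS,
)

logger = logging.getLogger("phagefmt")


# ---------------------------------------------------------------------------
# metrics

def shannon(profile: Sequence[float] | np.ndarray) -> float:
    """Shannon diversity (natural log) of an abundance vector; NaN for
    an all-zero profile (undefined)."""
    x = np.asarray(profile, dtype=float)
    if (x < 0).any():
        raise ValueError("abundances must be non-negative")
    total = x.sum()
    if total == 0:
        return float("nan")
    p = x[x > 0] / total
    return float(-(p * np.log(p)).sum())


def bray_curtis(a: Sequence[float] | np.ndarray, b: Sequence[float] | np.ndarray) -> float:
    """Bray-Curtis dissimilarity; 0 = identical profiles, 1 = disjoint
    supports, NaN when both profiles are empty."""
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.shape != y.shape:
        raise ValueError("profiles must have equal length")
    denom = (x + y).sum()
    if denom == 0:
        return float("nan")
    return float(np.abs(x - y).sum() / denom)


def shannon_per_sample(abund: AbundanceMatrix) -> pd.Series:
    return abund.data.apply(lambda col: shannon(col.to_numpy()), axis=0)


# ---------------------------------------------------------------------------
# tests

def fdr_adjust(p: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up; NaNs pass through unadjusted."""
    p = np.asarray(p, dtype=float)
    q = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        q[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return q


@dataclass
class ChisqResult:
    statistic: float
    df: int
    p: float
    #: per-cell standardized Pearson residuals with two-sided normal p
    #: and BH-FDR q across cells
    residuals: pd.DataFrame


def chisq_with_posthoc(table: pd.DataFrame) -> ChisqResult:
    """Pearson chi-squared (no continuity correction) with a
    standardized-residual post hoc per cell."""
    obs = table.to_numpy(dtype=float)
    if obs.min() < 0:
        raise ValueError("counts must be non-negative")
    chi2, p, df, expected = sps.chi2_contingency(obs, correction=False)
    if (expected == 0).any():
        raise ValueError("degenerate margin: expected count of zero")
    n = obs.sum()
    row_p = obs.sum(axis=1, keepdims=True) / n
    col_p = obs.sum(axis=0, keepdims=True) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        resid = (obs - expected) / np.sqrt(expected * (1 - row_p) * (1 - col_p))
    cell_p = 2 * sps.norm.sf(np.abs(resid))
    cell_q = fdr_adjust(cell_p.ravel()).reshape(cell_p.shape)
    rows = []
    for i, ri in enumerate(table.index):
        for j, cj in enumerate(table.columns):
            rows.append(
                {"row": ri, "col": cj, "observed": obs[i, j], "expected": expected[i, j],
                 "residual": resid[i, j], "p": cell_p[i, j], "q": cell_q[i, j]}
            )
    return ChisqResult(float(chi2), int(df), float(p), pd.DataFrame(rows))


def pearson_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson r with two-sided p from the t distribution (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired observations")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U). Exact p for small
    tie-free samples, otherwise normal approximation with continuity
    correction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (max(len(x), len(y)) <= 25 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# linear mixed model

def lmm_timepoint_contrast(
    data: pd.DataFrame,
    timepoints: Sequence[Timepoint] = POST_TIMEPOINTS,
    reference_treatment: str = Treatment.placebo.value,
) -> pd.DataFrame:
    """Treatment contrast at each timepoint from a linear mixed model.

    ``data`` is long format with columns subject, treatment, timepoint,
    value. Fits value ~ treatment x timepoint (fixed) with a random
    intercept per subject (REML) and reports the treatment effect at
    every timepoint in ``timepoints``. Falls back to ordinary least
    squares with a logged warning when the mixed fit is singular. BH-FDR
    is applied across the returned contrasts (callers combining several
    models should re-adjust across their full family).
    """
    import statsmodels.formula.api as smf

    required = {"subject", "treatment", "timepoint", "value"}
    if not required.issubset(data.columns):
        raise ValueError(f"data must have columns {sorted(required)}")
    df = data.dropna(subset=["value"]).copy()
    present_tps = [tp for tp in timepoints if tp.value in set(df["timepoint"])]
    if df["timepoint"].nunique() < 2:
        raise ValueError("need >= 2 timepoints for a treatment-by-time model")
    for treat, arm in df.groupby("treatment"):
        if arm["subject"].nunique() < 2:
            raise ValueError(f"need >= 2 subjects in arm {treat!r}")
    tp_order = [t.value for t in Timepoint if t.value in set(df["timepoint"])]
    formula = (
        f"value ~ C(treatment, Treatment('{reference_treatment}'))"
        f" * C(timepoint, levels={tp_order!r})"
    )
    result = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = smf.mixedlm(formula, df, groups=df["subject"], re_formula="1")
            fit = model.fit(reml=True)
            if np.isfinite(fit.params).all() and np.isfinite(fit.bse.iloc[:-1]).all():
                result = fit
        except Exception:
            result = None
        if result is None:
            logger.warning("lmm_timepoint_contrast: singular mixed fit, "
                           "falling back to fixed-effects OLS")
            result = smf.ols(formula, df).fit()

    names = list(result.model.exog_names)   # fixed effects only
    treat_main = next(n for n in names if n.startswith("C(treatment") and ":" not in n)
    rows = []
    for tp in present_tps:
        vec = pd.Series(0.0, index=names)
        vec[treat_main] = 1.0
        inter = [n for n in names if ":" in n and f"[T.{tp.value}]" in n
                 and n.startswith("C(treatment")]
        for n in inter:
            vec[n] = 1.0
        tt = result.t_test(vec.to_numpy()[None, :])
        rows.append({"timepoint": tp.value, "estimate": float(np.ravel(tt.effect)[0]),
                     "p": float(np.ravel(tt.pvalue)[0])})
    out = pd.DataFrame(rows)
    out["q"] = fdr_adjust(out["p"].to_numpy())
    return out


def change_from_baseline(
    values: pd.DataFrame,
) -> pd.DataFrame:
    """Per-subject change of ``value`` from baseline at each later
    timepoint; input and output are long format (subject, treatment,
    timepoint, value). Subjects without a baseline value are dropped."""
    rows = []
    for subject, grp in values.groupby("subject"):
        base = grp.loc[grp["timepoint"] == Timepoint.baseline.value, "value"]
        if base.empty or base.isna().all():
            logger.warning("change_from_baseline: subject %s has no baseline value", subject)
            continue
        b = float(base.iloc[0])
        for _, r in grp[grp["timepoint"] != Timepoint.baseline.value].iterrows():
            rows.append({"subject": subject, "treatment": r["treatment"],
                         "timepoint": r["timepoint"], "value": r["value"] - b})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# longitudinal analyses

def _recipient_samples(metadata: Sequence[SampleRecord]) -> pd.DataFrame:
    rows = [
        {"sample_id": m.sample_id, "subject": m.subject_id,
         "treatment": m.treatment.value, "sex": m.sex.value,
         "timepoint": m.timepoint.value}
        for m in metadata if m.role is Role.recipient
    ]
    return pd.DataFrame(rows)


def variability_from_wk6(
    abund: AbundanceMatrix, metadata: Sequence[SampleRecord]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Within-subject phageome shift after week 6.

    Returns (per-subject Bray-Curtis at wk12 and wk26 vs the subject's
    wk6 profile; FMT-vs-placebo Wilcoxon rank-sum tests per sex and
    timepoint, BH-FDR across that family).
    """
    meta = _recipient_samples(metadata)
    mat = abund.data
    rows = []
    for subject, grp in meta.groupby("subject"):
        cols = dict(zip(grp["timepoint"], grp["sample_id"]))
        if Timepoint.wk6.value not in cols or cols[Timepoint.wk6.value] not in mat.columns:
            logger.warning("variability_from_wk6: subject %s lacks a wk6 sample; skipped", subject)
            continue
        ref = mat[cols[Timepoint.wk6.value]].to_numpy()
        for tp in (Timepoint.wk12, Timepoint.wk26):
            sid = cols.get(tp.value)
            if sid is None or sid not in mat.columns:
                continue
            rows.append({"subject": subject,
                         "treatment": grp["treatment"].iloc[0],
                         "sex": grp["sex"].iloc[0],
                         "timepoint": tp.value,
                         "bray_curtis": bray_curtis(ref, mat[sid].to_numpy())})
    bc = pd.DataFrame(rows)
    tests = []
    for (sex, tp), grp in bc.groupby(["sex", "timepoint"]):
        fmt = grp.loc[grp["treatment"] == Treatment.FMT.value, "bray_curtis"].dropna()
        plc = grp.loc[grp["treatment"] == Treatment.placebo.value, "bray_curtis"].dropna()
        if len(fmt) < 2 or len(plc) < 2:
            continue
        stat, p = wilcoxon_rank_sum(fmt.to_numpy(), plc.to_numpy())
        tests.append({"sex": sex, "timepoint": tp, "test": "wilcoxon",
                      "estimate": float(fmt.median() - plc.median()),
                      "statistic": stat, "p": p})
    tests = pd.DataFrame(tests)
    if not tests.empty:
        tests["q"] = fdr_adjust(tests["p"].to_numpy())
    return bc, tests


def votu_stability(
    abund: AbundanceMatrix, metadata: Sequence[SampleRecord]
) -> tuple[pd.DataFrame, dict[str, ChisqResult]]:
    """Distribution of each subject's vOTUs over the number of
    timepoints detected (1-4), tabulated treatment x category per sex,
    with a chi-squared test and standardized-residual post hoc per sex.
    """
    meta = _recipient_samples(metadata)
    mat = abund.data
    counts: dict[tuple[str, str], np.ndarray] = {}
    for (subject, treatment, sex), grp in meta.groupby(["subject", "treatment", "sex"]):
        cols = [s for s in grp["sample_id"] if s in mat.columns]
        present = (mat[cols] > 0).sum(axis=1)
        hist = np.array([(present == k).sum() for k in (1, 2, 3, 4)], dtype=float)
        key = (sex, treatment)
        counts[key] = counts.get(key, np.zeros(4)) + hist
    tables = []
    tests: dict[str, ChisqResult] = {}
    for sex in sorted({k[0] for k in counts}):
        tab = pd.DataFrame(
            {f"n_timepoints_{k}": [counts.get((sex, t), np.zeros(4))[k - 1]
                                   for t in (Treatment.FMT.value, Treatment.placebo.value)]
             for k in (1, 2, 3, 4)},
            index=[Treatment.FMT.value, Treatment.placebo.value],
        )
        tab.insert(0, "sex", sex)
        tables.append(tab)
        try:
            tests[sex] = chisq_with_posthoc(tab.drop(columns="sex"))
        except ValueError:
            logger.warning("votu_stability: degenerate table for sex %s", sex)
    return pd.concat(tables), tests


def lifestyle_totals(
    abund: AbundanceMatrix,
    lifestyle_of_votu: dict[str, Lifestyle],
    metadata: Sequence[SampleRecord],
    response: str = "change",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Total abundance of temperate and of virulent phages per sample,
    with per-timepoint FMT-vs-placebo mixed-model contrasts, BH-FDR
    within sex (family = lifestyles x timepoints).

    ``response`` is "change" (per-subject change from baseline, default)
    or "raw".
    """
    mat = abund.data
    temperate = [v for v in mat.index if lifestyle_of_votu.get(v) is Lifestyle.temperate]
    virulent = [v for v in mat.index if lifestyle_of_votu.get(v) is Lifestyle.virulent]
    totals = pd.DataFrame(
        {
            "temperate": mat.loc[temperate].sum(axis=0) if temperate else 0.0,
            "virulent": mat.loc[virulent].sum(axis=0) if virulent else 0.0,
        }
    )
    totals.index.name = "sample_id"
    meta = _recipient_samples(metadata).set_index("sample_id")
    long = totals.join(meta, how="inner").reset_index()
    contrasts = []
    for sex, sex_grp in long.groupby("sex"):
        for style in ("temperate", "virulent"):
            resp = sex_grp.rename(columns={style: "value"})[
                ["subject", "treatment", "timepoint", "value"]
            ]
            if response == "change":
                resp = change_from_baseline(resp)
            try:
                res = lmm_timepoint_contrast(resp)
            except ValueError as exc:
                logger.warning("lifestyle_totals: %s/%s skipped (%s)", sex, style, exc)
                continue
            res.insert(0, "lifestyle", style)
            res.insert(0, "sex", sex)
            contrasts.append(res)
    out = pd.concat(contrasts, ignore_index=True) if contrasts else pd.DataFrame()
    if not out.empty:
        # re-adjust within sex across the full lifestyle x timepoint family
        out["q"] = np.nan
        for sex, idx in out.groupby("sex").groups.items():
            out.loc[idx, "q"] = fdr_adjust(out.loc[idx, "p"].to_numpy())
    return long, out


def alpha_diversity_contrasts(
    abund: AbundanceMatrix,
    metadata: Sequence[SampleRecord],
    response: str = "change",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample Shannon diversity and per-sex FMT-vs-placebo
    mixed-model contrasts on its post-treatment variation (change from
    baseline by default), BH-FDR within sex."""
    h = shannon_per_sample(abund)
    meta = _recipient_samples(metadata).set_index("sample_id")
    long = meta.join(h.rename("value"), how="inner").reset_index()
    contrasts = []
    for sex, grp in long.groupby("sex"):
        resp = grp[["subject", "treatment", "timepoint", "value"]]
        if response == "change":
            resp = change_from_baseline(resp)
        try:
            res = lmm_timepoint_contrast(resp)
        except ValueError as exc:
            logger.warning("alpha_diversity_contrasts: %s skipped (%s)", sex, exc)
            continue
        res.insert(0, "sex", sex)
        contrasts.append(res)
    out = pd.concat(contrasts, ignore_index=True) if contrasts else pd.DataFrame()
    if not out.empty:
        out["q"] = np.nan
        for sex, idx in out.groupby("sex").groups.items():
            out.loc[idx, "q"] = fdr_adjust(out.loc[idx, "p"].to_numpy())
    return long, out


def convergence_to_donors(
    abund: AbundanceMatrix,
    metadata: Sequence[SampleRecord],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bray-Curtis distance of each recipient sample to each sex-matched
    donor profile, with one mixed model per donor on the change from
    baseline and a collective BH-FDR across donors x timepoints."""
    mat = abund.data
    meta = _recipient_samples(metadata)
    donors = [m for m in metadata if m.role is Role.donor and m.sample_id in mat.columns]
    rows = []
    for d in donors:
        dprof = mat[d.sample_id].to_numpy()
        for r in meta.itertuples(index=False):
            if r.sample_id not in mat.columns:
                continue
            if r.sex != d.sex.value:
                continue
            rows.append({"donor": d.subject_id, "subject": r.subject,
                         "treatment": r.treatment, "sex": r.sex,
                         "timepoint": r.timepoint,
                         "value": bray_curtis(dprof, mat[r.sample_id].to_numpy())})
    bc = pd.DataFrame(rows)
    contrasts = []
    for donor, grp in bc.groupby("donor"):
        resp = change_from_baseline(grp[["subject", "treatment", "timepoint", "value"]])
        try:
            res = lmm_timepoint_contrast(resp)
        except ValueError:
            continue
        res.insert(0, "donor", donor)
        contrasts.append(res)
    out = pd.concat(contrasts, ignore_index=True) if contrasts else pd.DataFrame()
    if not out.empty:
        out["q"] = fdr_adjust(out["p"].to_numpy())   # collective family
    return bc, out
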