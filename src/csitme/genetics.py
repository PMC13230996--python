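"""Associations between somatic mutations and cell states / interactions.

Mutation status is a binary gene x sample matrix (>= 1 nonsynonymous
mutation).  Component activity enters either as quantile-binned levels
(0/1/2) modeled by a binomial GLM with two trials per observation, or as
binary interaction activity tested by Fisher's exact test.  Grade-stratified
analyses split samples at WHO grade II (early) versus III/IV (late).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("csitme")


@dataclass
class GradeSplitCounts:
    """Counts of interaction-active samples split by grade and mutation status."""

    c1: int  # early-stage mutant
    c2: int  # late-stage mutant
    c3: int  # early-stage wild-type
    c4: int  # late-stage wild-type

    def __post_init__(self) -> None:
        for name in ("c1", "c2", "c3", "c4"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} must be a non-negative integer, got {v}")


def recurrent_genes(mut: pd.DataFrame, min_freq: float = 0.01) -> list[str]:
    """Genes mutated in strictly more than ``min_freq`` of samples."""
    if mut.shape[1] == 0:
        return []
    frac = mut.mean(axis=1)
    return list(mut.index[frac > min_freq])


def quantile_bin_levels(scores: pd.Series) -> pd.Series:
    """Quantile-bin continuous scores into activity levels 0/1/2 (low to high)."""
    if scores.nunique() <= 1:
        raise ValueError("constant scores cannot be binned")
    order = np.argsort(scores.to_numpy(), kind="stable")
    levels = np.empty(len(scores), dtype=int)
    for lvl, block in enumerate(np.array_split(order, 3)):
        levels[block] = lvl
    return pd.Series(levels, index=scores.index)


def ic_mutation_assoc(
    binned_ic: pd.Series, mutation: pd.Series, method: str = "binomial"
) -> tuple[float, float]:
    """Regress a 0/1/2 binned activity level on mutation status.

    ``method="binomial"`` (default) treats the level as successes out of two
    trials in a binomial GLM, yielding one coefficient per gene-component
    pair; ``method="ordinal"`` fits a proportional-odds model instead.
    Returns (coefficient, p) for the mutation term.
    """
    common = binned_ic.index.intersection(mutation.index)
    y = binned_ic[common].astype(int)
    m = mutation[common].astype(int)
    if m.nunique() <= 1:
        raise ValueError("mutation status is constant")
    if not set(y.unique()) <= {0, 1, 2}:
        raise ValueError("binned activity must take values in {0, 1, 2}")
    if method == "binomial":
        endog = np.column_stack([y.to_numpy(), 2 - y.to_numpy()])
        exog = sm.add_constant(m.to_numpy().astype(float))
        fit = sm.GLM(endog, exog, family=sm.families.Binomial()).fit()
        return float(fit.params[1]), float(fit.pvalues[1])
    if method == "ordinal":
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        fit = OrderedModel(y, m.to_frame("mut"), distr="logit").fit(
            method="bfgs", disp=False
        )
        return float(fit.params["mut"]), float(fit.pvalues["mut"])
    raise ValueError(f"unknown method: {method!r}")


def ic_mutation_assoc_all(
    binned_by_ic: pd.DataFrame,
    mut: pd.DataFrame,
    fdr: float = 0.20,
    method: str = "binomial",
) -> pd.DataFrame:
    """All gene x component binomial-regression associations with global BH.

    ``binned_by_ic`` is samples x components (levels 0/1/2); ``mut`` is the
    binary gene x sample matrix.  Degenerate tests (constant mutation) are
    skipped and logged.
    """
    rows = []
    for gene in mut.index:
        mvec = mut.loc[gene]
        for ic in binned_by_ic.columns:
            try:
                coef, p = ic_mutation_assoc(binned_by_ic[ic], mvec, method=method)
            except (ValueError, np.linalg.LinAlgError) as exc:
                logger.debug("skipping %s x %s: %s", gene, ic, exc)
                continue
            rows.append({"gene": gene, "target": ic, "estimate": coef, "p": p})
    res = pd.DataFrame(rows, columns=["gene", "target", "estimate", "p"])
    if len(res):
        res["fdr"] = multipletests(res["p"], method="fdr_bh")[1]
        res["significant"] = res["fdr"] < fdr
        res["test_kind"] = "binomial_regression"
    return res


def csi_mutation_assoc(
    activity_row: pd.Series, mutation: pd.Series, or_cap: float = 1e6
) -> tuple[float, float]:
    """Fisher exact association between interaction activity and mutation.

    Returns (odds ratio, two-sided p); infinite odds ratios are capped at
    ``or_cap`` with the exact p retained.
    """
    common = activity_row.index.intersection(mutation.index)
    a_vec = activity_row[common].astype(int)
    m_vec = mutation[common].astype(int)
    table = pd.crosstab(
        a_vec.reindex(common), m_vec.reindex(common)
    ).reindex(index=[1, 0], columns=[1, 0], fill_value=0)
    odds, p = stats.fisher_exact(table.to_numpy())
    if np.isinf(odds):
        odds = or_cap
    return float(odds), float(p)


def csi_mutation_assoc_all(
    activity: pd.DataFrame, mut: pd.DataFrame, fdr: float = 0.20
) -> pd.DataFrame:
    """All gene x interaction Fisher associations with global BH."""
    rows = []
    for gene in mut.index:
        for csi in activity.index:
            odds, p = csi_mutation_assoc(activity.loc[csi], mut.loc[gene])
            rows.append({"gene": gene, "target": csi, "estimate": odds, "p": p})
    res = pd.DataFrame(rows, columns=["gene", "target", "estimate", "p"])
    if len(res):
        res["fdr"] = multipletests(res["p"], method="fdr_bh")[1]
        res["significant"] = res["fdr"] < fdr
        res["test_kind"] = "fisher"
    return res


def mutation_burden_load_corr(
    mut: pd.DataFrame, load_vector: pd.Series
) -> tuple[float, float]:
    """Spearman correlation of per-sample mutated-gene count with CSI load."""
    common = mut.columns.intersection(load_vector.index)
    burden = mut[common].sum(axis=0)
    loads = load_vector[common]
    if burden.nunique() <= 1 or loads.nunique() <= 1:
        logger.warning("constant vector; correlation undefined")
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(burden, loads)
    if len(common) < 4:
        logger.warning("n=%d too small for a reliable p value", len(common))
    return float(rho), float(p)


def grade_split_counts(
    activity_row: pd.Series, mutation: pd.Series, early: pd.Series
) -> GradeSplitCounts:
    """Count interaction-active samples by (early/late grade) x (mutant/wt).

    ``early`` is a boolean per sample (WHO grade II = early; III/IV = late).
    Only samples where the interaction is active contribute.
    """
    common = activity_row.index.intersection(mutation.index).intersection(early.index)
    act = activity_row[common].astype(bool)
    m = mutation[common].astype(bool)
    e = early[common].astype(bool)
    return GradeSplitCounts(
        c1=int((act & m & e).sum()),
        c2=int((act & m & ~e).sum()),
        c3=int((act & ~m & e).sum()),
        c4=int((act & ~m & ~e).sum()),
    )


def early_late_odds(counts: GradeSplitCounts) -> float:
    """Early:late activity odds in mutants normalized by wild-type: (c1/c2)/(c3/c4)."""
    if counts.c2 == 0 or counts.c4 == 0 or counts.c3 == 0:
        raise ValueError(
            f"undefined odds for counts {counts}: zero denominator"
        )
    return (counts.c1 / counts.c2) / (counts.c3 / counts.c4)


def mic(m_vec: pd.Series, i_vec: pd.Series) -> pd.Series:
    """Mutation-interaction co-occurrence: elementwise AND of two 0/1 vectors."""
    common = m_vec.index.intersection(i_vec.index)
    m = m_vec[common]
    i = i_vec[common]
    for name, v in (("m", m), ("i", i)):
        if not v.isin([0, 1]).all():
            raise ValueError(f"{name} vector must be binary 0/1")
    return (m.astype(int) & i.astype(int)).astype(int)


def mic_grade_model(
    grade_late: pd.Series, mic_vec: pd.Series, m_vec: pd.Series, i_vec: pd.Series
) -> tuple[float, float]:
    """Logistic model late-grade ~ MIC + m + i; returns the MIC (coef, p).

    ``grade_late`` is 1 for WHO grade III/IV, 0 for grade II.  Perfect
    collinearity among MIC, m, i (or separation) is rejected.
    """
    df = pd.DataFrame(
        {"late": grade_late, "mic": mic_vec, "m": m_vec, "i": i_vec}
    ).dropna()
    X = sm.add_constant(df[["mic", "m", "i"]].astype(float))
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("MIC, m, i are collinear; model not identifiable")
    try:
        fit = sm.Logit(df["late"].astype(float), X).fit(disp=False, maxiter=200)
    except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError) as exc:
        raise ValueError(f"logistic fit failed (separation?): {exc}") from exc
    if not np.isfinite(fit.bse["mic"]) or fit.bse["mic"] > 1e4:
        raise ValueError("separation: MIC coefficient unstable")
    return float(fit.params["mic"]), float(fit.pvalues["mic"])
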