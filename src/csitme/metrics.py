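"""Network-level statistics over a cell-state interaction network.

All metrics derive from the binary CSI x sample activity matrix: *penetrance*
is a per-interaction row mean (fraction of patients in which the interaction
is active), *load* a per-sample column mean (fraction of interactions active
in a patient), computed separately for pro-tumor (positive log-hazard) and
anti-tumor subsets where relevant.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from statsmodels.stats.multitest import multipletests
import statsmodels.api as sm

from .screen import CSIN, CSIRecord, activity_matrix
from .states import SampleScores

logger = logging.getLogger("csitme")


def csi_activity(
    csin: CSIN, scores_by_celltype: dict[str, SampleScores]
) -> pd.DataFrame:
    """Binary CSI x sample activity on a (possibly new) cohort.

    Tertile bins are recomputed on the target cohort's own score
    distribution, so activity is cohort-relative.
    """
    for r in csin.records:
        for ct in (r.c1, r.c2):
            if ct not in scores_by_celltype:
                raise KeyError(f"no scores provided for cell type {ct!r}")
    return activity_matrix(csin.records, scores_by_celltype)


def penetrance(mat: pd.DataFrame, sample_subset: list | None = None) -> pd.Series:
    """Fraction of samples in which each interaction is active (row mean)."""
    if sample_subset is not None:
        mat = mat[list(sample_subset)]
    if mat.shape[1] == 0:
        raise ValueError("empty sample subset")
    return mat.mean(axis=1)


def _direction_subset(csin: CSIN, which: str) -> list[str]:
    if which == "all":
        return [r.csi_id for r in csin.records]
    want = 1 if which == "pro" else -1
    return [r.csi_id for r in csin.records if r.direction == want]


def load(mat: pd.DataFrame, csin: CSIN | None = None, csi_subset: str = "all") -> pd.Series:
    """Fraction of interactions active in each sample (column mean).

    ``csi_subset`` selects ``pro`` (positive log-hazard), ``anti`` or ``all``
    interactions; selection requires ``csin`` for direction lookup.
    """
    if csi_subset != "all":
        if csin is None:
            raise ValueError("pro/anti subsets require the CSIN for directions")
        ids = _direction_subset(csin, csi_subset)
        if not ids:
            raise ValueError(f"no {csi_subset}-tumor interactions in the network")
        mat = mat.loc[ids]
    if mat.shape[0] == 0:
        raise ValueError("empty interaction subset")
    return mat.mean(axis=0)


def assign_tme_subtype(pro_load: pd.Series, anti_load: pd.Series) -> pd.Series:
    """Label each sample by its dominant interaction class.

    ``pro-dominant`` when pro-tumor load exceeds anti-tumor load,
    ``anti-dominant`` for the converse, ``unassigned`` on ties (including
    both zero).
    """
    out = pd.Series("unassigned", index=pro_load.index, dtype=object)
    out[pro_load > anti_load] = "pro-dominant"
    out[anti_load > pro_load] = "anti-dominant"
    return out


def differential_penetrance(
    mat: pd.DataFrame, group_labels: pd.Series, fdr: float = 0.20
) -> pd.DataFrame:
    """Per-CSI Fisher exact test of activity between two sample groups.

    Builds the 2x2 table (active/inactive x group) per interaction, computes
    the two-sided exact p and odds ratio, applies BH across interactions, and
    reports which group each interaction is enriched in.
    """
    group_labels = group_labels.dropna()
    groups = sorted(group_labels.unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    g1, g2 = groups
    s1 = [s for s in mat.columns if s in group_labels.index and group_labels[s] == g1]
    s2 = [s for s in mat.columns if s in group_labels.index and group_labels[s] == g2]
    if not s1 or not s2:
        raise ValueError("each group must contain at least one sample")
    rows = []
    for csi in mat.index:
        a = int(mat.loc[csi, s1].sum())
        b = len(s1) - a
        c = int(mat.loc[csi, s2].sum())
        d = len(s2) - c
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        enriched = g1 if (a / len(s1)) > (c / len(s2)) else (g2 if (c / len(s2)) > (a / len(s1)) else "none")
        rows.append({"csi_id": csi, "odds_ratio": odds, "p": p, "enriched_group": enriched})
    res = pd.DataFrame(rows).set_index("csi_id")
    res["fdr"] = multipletests(res["p"], method="fdr_bh")[1]
    res["significant"] = res["fdr"] < fdr
    return res


def compare_group_penetrance(
    penetrance_a: pd.Series,
    penetrance_b: pd.Series,
    directions: pd.Series,
    paired: bool = False,
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """Rank-sum comparison of per-CSI penetrance between two sample groups.

    ``penetrance_a``/``penetrance_b`` are per-CSI penetrance vectors computed
    on the two groups (e.g., responders vs. non-responders, or primary vs.
    recurrent); ``directions`` maps csi_id to +1 (pro) / -1 (anti).  The
    comparison is run separately per direction class; the CSIs are matched
    across groups, so ``paired=True`` (Wilcoxon signed-rank) is available for
    patient-matched designs while the default is the unpaired rank-sum.
    Classes with fewer than 3 CSIs are flagged ``low_power``.
    """
    rows = []
    for name, want in (("pro", 1), ("anti", -1)):
        ids = directions.index[directions == want]
        ids = [i for i in ids if i in penetrance_a.index and i in penetrance_b.index]
        if len(ids) == 0:
            continue
        a, b = penetrance_a[ids], penetrance_b[ids]
        if np.allclose(a, b):
            p, stat = 1.0, 0.0
        elif paired:
            res = stats.wilcoxon(a, b, alternative=alternative)
            stat, p = float(res.statistic), float(res.pvalue)
        else:
            res = stats.mannwhitneyu(a, b, alternative=alternative)
            stat, p = float(res.statistic), float(res.pvalue)
        rows.append(
            {
                "direction": name, "n_csis": len(ids),
                "median_a": float(a.median()), "median_b": float(b.median()),
                "statistic": stat, "p": p, "low_power": len(ids) < 3,
            }
        )
    return pd.DataFrame(rows)


def survival_by_strata(
    clinical: pd.DataFrame, strata_labels: pd.Series
) -> tuple[dict[str, pd.DataFrame], float]:
    """Kaplan-Meier survival tables per stratum plus an overall log-rank p."""
    labels = strata_labels.dropna()
    common = clinical.index.intersection(labels.index)
    clin, labels = clinical.loc[common], labels[common]
    strata = sorted(labels.unique())
    if len(strata) < 2:
        raise ValueError("need at least two strata")
    curves = {}
    for s in strata:
        sub = clin[labels == s]
        if sub["os_event"].sum() == 0:
            logger.warning("stratum %r has no events", s)
        km = KaplanMeierFitter()
        km.fit(sub["os_time"], sub["os_event"], label=str(s))
        curves[str(s)] = km.survival_function_
    lr = multivariate_logrank_test(clin["os_time"], labels, clin["os_event"])
    return curves, float(lr.p_value)


def covariate_adjusted_enrichment(
    outcome: pd.Series, load_vector: pd.Series, covariates: pd.DataFrame
) -> tuple[float, float]:
    """Linear model outcome ~ load + covariates; returns (load beta, p).

    Used e.g. to test whether anti-tumor load differs by tumor subtype while
    controlling for age.  The outcome must be binary-coded 0/1; collinear or
    constant covariates are rejected.
    """
    df = pd.DataFrame({"outcome": outcome, "load": load_vector}).join(covariates).dropna()
    X = sm.add_constant(df.drop(columns="outcome"), has_constant="add")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("design matrix is rank-deficient (collinear or constant covariates)")
    fit = sm.OLS(df["outcome"].astype(float), X.astype(float)).fit()
    return float(fit.params["load"]), float(fit.pvalues["load"])
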