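"""The prognostic joint-activity screen.

Per cell type, sample-specific component scores are cut into tertiles
(Low / Med / High).  For every pair of components from two *different* cell
types and each joint-activity class — bin 1 (both Low), bin 9 (both High),
bin 3/7 (one Low, one High; the two symmetric configurations are merged) — a
binary indicator I marks the samples sitting in that class, and the
proportional-hazards model

    hazard ~ IC1 + IC2 + I + age + sex

is fit with the two component scores entering as continuous covariates.  The
interaction term's coefficient (log-hazard ratio) is the statistic of
interest; Benjamini-Hochberg correction is applied over all converged tests
in one family, and candidates are validated by refitting on bootstrap
resamples of the cohort.  A positive coefficient (worse survival) marks a
pro-tumor interaction, a negative one anti-tumor.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from statsmodels.stats.multitest import multipletests

from .core_io import ExpressionMatrix, working_cohort
from .states import SampleScores

logger = logging.getLogger("csitme")

BIN_CLASSES = ("bin1", "bin3or7", "bin9")
LOW, MED, HIGH = "Low", "Med", "High"


@dataclass
class ActivityBins:
    """Tertile labels (Low/Med/High) per sample per component, one cell type."""

    cell_type: str
    labels: pd.DataFrame  # samples x components, values in {Low, Med, High}
    scores: pd.DataFrame  # the underlying continuous samples x components


@dataclass
class CSIRecord:
    """One detected cell-state interaction: (C1, IC1, C2, IC2, B, D) + stats."""

    c1: str
    ic1: str
    c2: str
    ic2: str
    bin: str            # bin1 | bin3or7 | bin9
    beta: float
    hazard_ratio: float
    p: float
    fdr: float = math.nan
    cv_support: float = math.nan

    @property
    def direction(self) -> int:
        """+1 for a positive log-hazard ratio (pro-tumor), -1 otherwise."""
        return 1 if self.beta > 0 else -1

    @property
    def csi_id(self) -> str:
        return f"{self.c1}:{self.ic1}|{self.c2}:{self.ic2}|{self.bin}"


@dataclass
class CSIN:
    """A cell-state interaction network plus its binary activity matrix."""

    records: list[CSIRecord]
    activity: pd.DataFrame  # csi_id x samples, values in {0, 1}
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "csi_id": r.csi_id, "c1": r.c1, "ic1": r.ic1, "c2": r.c2,
                "ic2": r.ic2, "bin": r.bin, "direction": r.direction,
                "beta": r.beta, "hazard_ratio": r.hazard_ratio, "p": r.p,
                "fdr": r.fdr, "cv_support": r.cv_support,
            }
            for r in self.records
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "csi_id", "c1", "ic1", "c2", "ic2", "bin", "direction",
                "beta", "hazard_ratio", "p", "fdr", "cv_support",
            ],
        )


# ---------------------------------------------------------------------------
# binning


def _tertile_labels(values: np.ndarray) -> np.ndarray:
    """Stable-rank tertile labels; block sizes differ by at most one."""
    if np.ptp(values) == 0:
        raise ValueError("constant scores cannot be binned into tertiles")
    order = np.argsort(values, kind="stable")
    labels = np.empty(len(values), dtype=object)
    for name, block in zip((LOW, MED, HIGH), np.array_split(order, 3)):
        labels[block] = name
    return labels


def tertile_bins(scores: SampleScores) -> ActivityBins:
    """Cut each component's scores into three near-equal activity bins.

    Ties are broken by the stable order of samples as given, so bins are
    deterministic and their sizes differ by at most one.
    """
    if len(scores.scores) < 3:
        raise ValueError("need at least 3 samples to form tertiles")
    labels = pd.DataFrame(
        {ic: _tertile_labels(scores.scores[ic].to_numpy()) for ic in scores.scores.columns},
        index=scores.scores.index,
    )
    return ActivityBins(cell_type=scores.cell_type, labels=labels, scores=scores.scores.copy())


def joint_indicator(bins1: pd.Series, bins2: pd.Series, bin_class: str) -> pd.Series:
    """Per-sample 0/1 joint-activity indicator for one bin class.

    bin1: both Low; bin9: both High; bin3or7: one Low and the other High
    (symmetric).  Every other sample, including any involving Med, gets 0.
    """
    if not bins1.index.equals(bins2.index):
        common = bins1.index.intersection(bins2.index)
        bins1, bins2 = bins1[common], bins2[common]
    if bin_class == "bin1":
        ind = (bins1 == LOW) & (bins2 == LOW)
    elif bin_class == "bin9":
        ind = (bins1 == HIGH) & (bins2 == HIGH)
    elif bin_class == "bin3or7":
        ind = ((bins1 == LOW) & (bins2 == HIGH)) | ((bins1 == HIGH) & (bins2 == LOW))
    else:
        raise ValueError(f"unknown bin class: {bin_class!r}")
    return ind.astype(int)


# ---------------------------------------------------------------------------
# Cox interaction model


def _clinical_covariates(clinical: pd.DataFrame) -> pd.DataFrame:
    """Survival outcome plus age/sex covariates; rows missing either dropped."""
    cov = pd.DataFrame(index=clinical.index)
    cov["os_time"] = clinical["os_time"].astype(float)
    cov["os_event"] = clinical["os_event"].astype(int)
    if "age" in clinical.columns:
        cov["age"] = pd.to_numeric(clinical["age"], errors="coerce")
    if "sex" in clinical.columns:
        sex = clinical["sex"].astype("category")
        cov["sex"] = sex.cat.codes.astype(float).where(sex.notna())
    n0 = len(cov)
    cov = cov.dropna()
    if len(cov) < n0:
        logger.info("dropped %d samples with missing covariates", n0 - len(cov))
    return cov


def cox_interaction(
    ic1_scores: pd.Series,
    ic2_scores: pd.Series,
    indicator: pd.Series,
    clinical: pd.DataFrame,
    min_events: int = 10,
    min_active: int = 5,
) -> tuple[float, float, float]:
    """Fit hazard ~ IC1 + IC2 + I + age + sex; return (beta, HR, Wald p) of I."""
    cov = _clinical_covariates(clinical)
    df = cov.join(
        pd.DataFrame({"ic1": ic1_scores, "ic2": ic2_scores, "I": indicator})
    ).dropna()
    if df["os_event"].sum() < min_events:
        raise ValueError(f"fewer than {min_events} events")
    n_active = int(df["I"].sum())
    if n_active < min_active or n_active == len(df):
        raise ValueError(
            f"indicator active in {n_active}/{len(df)} samples "
            f"(need >= {min_active} and not all)"
        )
    # drop constant covariate columns (e.g., single-sex cohorts)
    keep = [c for c in df.columns if c in ("os_time", "os_event") or df[c].nunique() > 1]
    fitter = CoxPHFitter()
    fitter.fit(df[keep], duration_col="os_time", event_col="os_event")
    beta = float(fitter.params_["I"])
    p = float(fitter.summary.loc["I", "p"])
    return beta, math.exp(beta), p


# ---------------------------------------------------------------------------
# the screen


def _bh(pvals: pd.Series) -> pd.Series:
    return pd.Series(multipletests(pvals, method="fdr_bh")[1], index=pvals.index)


def screen_all(
    scores_by_celltype: dict[str, SampleScores],
    clinical: pd.DataFrame,
    fdr: float = 0.20,
    exclude_medium: bool = False,
    min_events: int = 10,
    min_active: int = 5,
    fdr_family: str = "global",
) -> tuple[list[CSIRecord], pd.DataFrame]:
    """Screen every component pair across distinct cell types, every bin class.

    Returns the candidate records passing BH FDR < ``fdr`` and the full table
    of converged tests.  ``fdr_family`` is ``global`` (one BH family over all
    tests, the default) or ``per_pair`` (BH within each cell-type pair).
    With ``exclude_medium`` samples falling in a Med bin of either component
    are dropped from that regression instead of contributing 0s.
    """
    if len(scores_by_celltype) < 2:
        raise ValueError("need at least 2 cell types")
    cohort = working_cohort(
        [clinical.index] + [s.scores.index for s in scores_by_celltype.values()]
    )
    bins = {
        ct: tertile_bins(
            SampleScores(ct, s.scores.loc[cohort], s.provenance)
        )
        for ct, s in scores_by_celltype.items()
    }
    clin = clinical.loc[cohort]
    rows = []
    for c1, c2 in itertools.combinations(sorted(scores_by_celltype), 2):
        for ic1 in bins[c1].labels.columns:
            for ic2 in bins[c2].labels.columns:
                b1, b2 = bins[c1].labels[ic1], bins[c2].labels[ic2]
                s1, s2 = bins[c1].scores[ic1], bins[c2].scores[ic2]
                for bc in BIN_CLASSES:
                    ind = joint_indicator(b1, b2, bc)
                    if exclude_medium:
                        keep = (b1 != MED) & (b2 != MED)
                        ind_f, s1_f, s2_f, clin_f = ind[keep], s1[keep], s2[keep], clin.loc[keep[keep].index]
                    else:
                        ind_f, s1_f, s2_f, clin_f = ind, s1, s2, clin
                    try:
                        beta, hr, p = cox_interaction(
                            s1_f, s2_f, ind_f, clin_f,
                            min_events=min_events, min_active=min_active,
                        )
                    except (ValueError, ConvergenceError, np.linalg.LinAlgError) as exc:
                        logger.debug("skipping %s:%s|%s:%s|%s: %s", c1, ic1, c2, ic2, bc, exc)
                        continue
                    rows.append(
                        {"c1": c1, "ic1": ic1, "c2": c2, "ic2": ic2, "bin": bc,
                         "beta": beta, "hazard_ratio": hr, "p": p}
                    )
    tested = pd.DataFrame(
        rows, columns=["c1", "ic1", "c2", "ic2", "bin", "beta", "hazard_ratio", "p"]
    )
    if len(tested) == 0:
        return [], tested
    if fdr_family == "global":
        tested["fdr"] = _bh(tested["p"])
    elif fdr_family == "per_pair":
        tested["fdr"] = tested.groupby(["c1", "c2"])["p"].transform(
            lambda p: multipletests(p, method="fdr_bh")[1]
        )
    else:
        raise ValueError(f"unknown fdr_family: {fdr_family!r}")
    candidates = [
        CSIRecord(
            c1=r.c1, ic1=r.ic1, c2=r.c2, ic2=r.ic2, bin=r.bin,
            beta=r.beta, hazard_ratio=r.hazard_ratio, p=r.p, fdr=r.fdr,
        )
        for r in tested.itertuples()
        if r.fdr < fdr
    ]
    return candidates, tested


def activity_matrix(
    records: list[CSIRecord],
    scores_by_celltype: dict[str, SampleScores],
    samples: list | None = None,
) -> pd.DataFrame:
    """Binary CSI x sample activity, bins recomputed on the given cohort."""
    if samples is None:
        samples = working_cohort([s.scores.index for s in scores_by_celltype.values()])
    bins = {
        ct: tertile_bins(SampleScores(ct, s.scores.loc[samples], s.provenance))
        for ct, s in scores_by_celltype.items()
    }
    rows = {}
    for r in records:
        for ct in (r.c1, r.c2):
            if ct not in bins:
                raise KeyError(f"no scores for cell type {ct!r}")
        ind = joint_indicator(bins[r.c1].labels[r.ic1], bins[r.c2].labels[r.ic2], r.bin)
        rows[r.csi_id] = ind
    mat = pd.DataFrame(rows, index=pd.Index(samples)).T
    if len(records) == 0:
        mat = pd.DataFrame(np.empty((0, len(samples)), dtype=int), columns=samples)
    return mat.astype(int)


def bootstrap_cv(
    candidates: list[CSIRecord],
    scores_by_celltype: dict[str, SampleScores],
    clinical: pd.DataFrame,
    n_boot: int = 10,
    support: float = 0.70,
    seed: int = 0,
    min_events: int = 10,
    min_active: int = 5,
) -> CSIN:
    """Bootstrap validation of screen candidates.

    Each bootstrap resamples the cohort with replacement, recomputes the
    tertile bins on the resample, and refits each candidate's Cox model.  A
    candidate is retained iff p < 0.05 with the full-data coefficient sign in
    at least ``ceil(support * n_boot)`` bootstraps; the qualifying fraction is
    recorded as ``cv_support``.
    """
    if not candidates:
        raise ValueError("no candidate interactions to validate")
    cohort = working_cohort(
        [clinical.index] + [s.scores.index for s in scores_by_celltype.values()]
    )
    rng = np.random.default_rng(seed)
    n = len(cohort)
    needed = math.ceil(support * n_boot)
    hits = {r.csi_id: 0 for r in candidates}
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        boot_ids = [cohort[i] for i in idx]
        pseudo = [f"b{j}" for j in range(n)]
        clin_b = clinical.loc[boot_ids].copy()
        clin_b.index = pseudo
        scores_b = {
            ct: SampleScores(
                ct,
                pd.DataFrame(
                    s.scores.loc[boot_ids].to_numpy(),
                    index=pseudo, columns=s.scores.columns,
                ),
                s.provenance,
            )
            for ct, s in scores_by_celltype.items()
        }
        bins_b = {ct: tertile_bins(s) for ct, s in scores_b.items()}
        for r in candidates:
            ind = joint_indicator(
                bins_b[r.c1].labels[r.ic1], bins_b[r.c2].labels[r.ic2], r.bin
            )
            try:
                beta, _, p = cox_interaction(
                    scores_b[r.c1].scores[r.ic1], scores_b[r.c2].scores[r.ic2],
                    ind, clin_b, min_events=min_events, min_active=min_active,
                )
            except (ValueError, ConvergenceError, np.linalg.LinAlgError):
                continue
            if p < 0.05 and np.sign(beta) == np.sign(r.beta):
                hits[r.csi_id] += 1
    retained = [
        replace(r, cv_support=hits[r.csi_id] / n_boot)
        for r in candidates
        if hits[r.csi_id] >= needed
    ]
    mat = activity_matrix(retained, scores_by_celltype, samples=cohort)
    return CSIN(
        records=retained,
        activity=mat,
        provenance={"n_boot": n_boot, "support": support, "seed": seed, "n_samples": n},
    )


def randomized_null_csins(
    scores_by_celltype: dict[str, SampleScores],
    clinical: pd.DataFrame,
    n_rand: int = 10,
    seed: int = 0,
    **screen_kwargs,
) -> list[CSIN]:
    """Rebuild the network after permuting clinical rows against sample ids.

    The clinical table's rows (time, event, age, sex, ...) are shuffled as
    whole rows, preserving every marginal distribution while severing the
    link to the expression-derived scores.  Returns one (possibly empty)
    null network per permutation.
    """
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_rand):
        perm = rng.permutation(len(clinical))
        clin_p = clinical.iloc[perm].copy()
        clin_p.index = clinical.index
        clin_p["sample_id"] = clinical.index
        cands, _ = screen_all(scores_by_celltype, clin_p, **screen_kwargs)
        if cands:
            csin = bootstrap_cv(
                cands, scores_by_celltype, clin_p,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        else:
            samples = working_cohort(
                [clin_p.index] + [s.scores.index for s in scores_by_celltype.values()]
            )
            csin = CSIN(records=[], activity=activity_matrix([], scores_by_celltype, samples))
        out.append(csin)
    return out


def gene_pair_screen(
    genes_a: set,
    genes_b: set,
    expr_a: ExpressionMatrix,
    expr_b: ExpressionMatrix,
    clinical: pd.DataFrame,
    bin_class: str,
    fdr: float = 0.20,
    min_events: int = 10,
    min_active: int = 5,
) -> pd.DataFrame:
    """Gene-level analogue of the screen for two signature gene sets.

    Each gene's deconvolved expression in its own cell type is tertile-binned
    and the joint indicator for ``bin_class`` replaces the component scores in
    the same Cox form.  For bin 1 a positive coefficient means simultaneous
    downregulation associates with worse survival (pro-tumor).  Pairs whose
    gene is absent or whose indicator is degenerate are skipped and logged.
    """
    cohort = working_cohort([clinical.index, expr_a.samples, expr_b.samples])
    clin = clinical.loc[cohort]

    def gene_data(expr: ExpressionMatrix, gene: str):
        logv = np.log2(expr.values.loc[gene, cohort].astype(float) + 1.0)
        sd = logv.std(ddof=1)
        z = (logv - logv.mean()) / sd if sd > 0 else logv * 0.0
        return z, pd.Series(_tertile_labels(logv.to_numpy()), index=cohort)

    rows = []
    for ga in sorted(genes_a):
        if ga not in expr_a.genes:
            logger.info("gene %s absent from %s matrix; pairs skipped", ga, expr_a.cell_type)
            continue
        za, la = gene_data(expr_a, ga)
        for gb in sorted(genes_b):
            if gb not in expr_b.genes:
                continue
            zb, lb = gene_data(expr_b, gb)
            ind = joint_indicator(la, lb, bin_class)
            try:
                beta, hr, p = cox_interaction(
                    za, zb, ind, clin, min_events=min_events, min_active=min_active
                )
            except (ValueError, ConvergenceError, np.linalg.LinAlgError):
                continue
            rows.append(
                {"gene_a": ga, "gene_b": gb, "bin": bin_class,
                 "beta": beta, "hazard_ratio": hr, "p": p}
            )
    res = pd.DataFrame(
        rows, columns=["gene_a", "gene_b", "bin", "beta", "hazard_ratio", "p"]
    )
    if len(res):
        res["fdr"] = _bh(res["p"])
        res["effect"] = np.where(res["beta"] > 0, "pro_tumor", "anti_tumor")
        res["significant"] = res["fdr"] < fdr
    return res


# ---------------------------------------------------------------------------
# serialization


def save_csin(csin: CSIN, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    csin.to_frame().to_csv(outdir / "csin.tsv", sep="\t", index=False)
    csin.activity.to_csv(outdir / "activity.tsv", sep="\t", index_label="csi_id")
    (outdir / "meta.json").write_text(
        json.dumps(csin.provenance, indent=2, sort_keys=True, default=str) + "\n"
    )


def load_csin(indir: str | Path) -> CSIN:
    indir = Path(indir)
    df = pd.read_csv(indir / "csin.tsv", sep="\t")
    records = [
        CSIRecord(
            c1=r.c1, ic1=r.ic1, c2=r.c2, ic2=r.ic2, bin=r.bin, beta=r.beta,
            hazard_ratio=r.hazard_ratio, p=r.p, fdr=r.fdr, cv_support=r.cv_support,
        )
        for r in df.itertuples()
    ]
    activity = pd.read_csv(indir / "activity.tsv", sep="\t", index_col=0)
    meta_path = indir / "meta.json"
    provenance = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return CSIN(records=records, activity=activity, provenance=provenance)
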