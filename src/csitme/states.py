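"""Per-cell-type latent transcriptional state inference.

Each cell type's deconvolved genes x samples matrix is log-transformed,
z-scored per gene, and decomposed as ``X = A S`` by independent component
analysis: ``A`` (genes x k) is the mixing/loading matrix whose column tails
define signature genes, and ``S`` (k x samples) holds sample-specific state
scores.  Heavy-tailed, mutually independent source rows are the
identifiability assumption; Gaussian sources are not recoverable and the
rank-selection elbow is the guard against over-extraction.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.spatial.distance import cdist, pdist
from sklearn.decomposition import FastICA
from statsmodels.stats.multitest import multipletests

from .core_io import ExpressionMatrix

logger = logging.getLogger("csitme")


# ---------------------------------------------------------------------------
# types


@dataclass
class ICADecomposition:
    """A fitted per-cell-type ICA model.

    ``A`` is genes x k (loading/mixing matrix), ``S`` is k x samples with
    unit-variance rows.  ``center``/``scale`` are the per-gene z-scoring
    parameters of the training cohort; projection of a new cohort uses that
    cohort's own center/scale but this model's ``A``.
    """

    cell_type: str
    k: int
    A: pd.DataFrame        # genes x components
    S: pd.DataFrame        # components x samples
    center: pd.Series      # per-gene mean of log expression
    scale: pd.Series       # per-gene SD of log expression
    seed: int
    algorithm: str = "fastica"

    @property
    def components(self) -> pd.Index:
        return self.A.columns


@dataclass
class ICSignature:
    """Signature gene sets of one independent component.

    Genes whose loading lies at least ``threshold_sd`` standard deviations
    above (positive set) or below (negative set) the column mean.  Either set
    may be empty.
    """

    cell_type: str
    ic: str
    positive_genes: frozenset
    negative_genes: frozenset
    threshold_sd: float = 2.5


@dataclass
class SampleScores:
    """Samples x ICs continuous score matrix for one cell type."""

    cell_type: str
    scores: pd.DataFrame  # samples x components
    provenance: str = "fitted"  # fitted | projected


# ---------------------------------------------------------------------------
# operations


def preprocess(expr: ExpressionMatrix) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """log2(x+1) then per-gene z-score across samples.

    Zero-variance genes are removed (logged).  Returns the z-scored
    genes x samples matrix plus the per-gene center and scale used.
    SDs use the n-1 (sample) convention.
    """
    vals = expr.values
    logged = vals if expr.is_log else np.log2(vals + 1.0)
    center = logged.mean(axis=1)
    scale = logged.std(axis=1, ddof=1)
    keep = scale > 0
    if not keep.any():
        raise ValueError("all genes have zero variance")
    n_drop = int((~keep).sum())
    if n_drop:
        logger.warning("removing %d zero-variance genes from %s", n_drop, expr.cell_type)
    logged, center, scale = logged[keep], center[keep], scale[keep]
    z = logged.sub(center, axis=0).div(scale, axis=0)
    return z, center, scale


def fit_ica(
    expr: ExpressionMatrix,
    k: int = 10,
    seed: int = 0,
    max_iter: int = 1000,
    tol: float = 1e-4,
) -> ICADecomposition:
    """Fit a k-component ICA of the preprocessed expression matrix.

    Deterministic given ``seed``.  Components are ordered by decreasing
    loading-column norm (explained variance), and each component's sign is
    fixed so that the skewness of its loading column is negative — the heavy
    tail of loadings becomes the negative signature, a reproducible
    resolution of ICA's inherent sign ambiguity.
    """
    z, center, scale = preprocess(expr)
    if k > min(z.shape):
        raise ValueError(f"k={k} exceeds min(genes, samples)={min(z.shape)}")
    # samples are observations, genes are mixed signals: sources are the
    # per-sample state scores, the mixing matrix the gene loadings.
    # Parallel (symmetric) extraction first; deflation as the fallback when
    # the symmetric fixed point fails to converge.
    sources = ica = None
    algorithm = None
    import warnings as _warnings

    for algo in ("parallel", "deflation"):
        ica = FastICA(
            n_components=k, random_state=seed, whiten="unit-variance",
            max_iter=max_iter, tol=tol, algorithm=algo,
        )
        with np.errstate(over="ignore"), _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            sources = ica.fit_transform(z.to_numpy().T)  # samples x k
        if np.max(ica.n_iter_) < max_iter:
            algorithm = f"fastica-{algo}"
            break
    if algorithm is None:
        raise RuntimeError(
            f"ICA did not converge in {max_iter} iterations with either "
            f"extraction mode (cell type {expr.cell_type}, k={k}, tol={tol})"
        )
    A = ica.mixing_  # genes x k
    S = sources.T    # k x samples

    # deterministic component order and sign
    order = np.argsort(-np.linalg.norm(A, axis=0), kind="stable")
    A, S = A[:, order], S[order]
    flip = np.where(stats.skew(A, axis=0) > 0, -1.0, 1.0)
    A, S = A * flip, S * flip[:, None]

    names = [f"IC{i + 1}" for i in range(k)]
    return ICADecomposition(
        cell_type=expr.cell_type,
        k=k,
        A=pd.DataFrame(A, index=z.index, columns=names),
        S=pd.DataFrame(S, index=names, columns=z.columns),
        center=center,
        scale=scale,
        seed=seed,
        algorithm=algorithm,
    )


def reconstruction_error(z: pd.DataFrame, k: int) -> float:
    """Frobenius error of the best rank-k reconstruction of ``z``.

    The ICA solution is a rotation of the top-k principal subspace, so its
    reconstruction of the input equals the rank-k PCA truncation; the error
    is computed from the singular spectrum directly.
    """
    sv = np.linalg.svd(z.to_numpy(), compute_uv=False)
    return float(np.sqrt(max(np.sum(sv[k:] ** 2), 0.0)))


def _two_segment_fit(x: np.ndarray, y: np.ndarray) -> tuple[int, float, float, float]:
    """Least-squares two-segment piecewise-linear fit.

    Returns (breakpoint index into x, total SSE, |slope left|, |slope right|).
    The breakpoint belongs to both segments.
    """
    best = (None, np.inf, 0.0, 0.0)
    for b in range(1, len(x) - 1):
        sse = 0.0
        slopes = []
        for xs, ys in ((x[: b + 1], y[: b + 1]), (x[b:], y[b:])):
            coef, res, *_ = np.polyfit(xs, ys, 1, full=True)
            slopes.append(coef[0])
            sse += float(res[0]) if len(res) else 0.0
        if sse < best[1]:
            best = (b, sse, abs(slopes[0]), abs(slopes[1]))
    return best


def select_rank(
    expr: ExpressionMatrix,
    k_max: int = 20,
    slope_ratio_min: float = 3.0,
) -> tuple[int, np.ndarray, bool]:
    """Choose the component count from the reconstruction-error elbow.

    Computes the Frobenius reconstruction error for k = 1..k_max and fits a
    two-segment piecewise-linear model over all candidate breakpoints,
    minimizing total squared residual; the breakpoint is the selected rank.
    Returns ``(k_star, error_curve, low_confidence)`` where
    ``low_confidence`` flags a near-linear curve (left/right slope ratio
    below ``slope_ratio_min``), as arises on structureless data.
    """
    z, _, _ = preprocess(expr)
    if k_max >= min(z.shape):
        raise ValueError(f"k_max={k_max} must be < min(genes, samples)={min(z.shape)}")
    ks = np.arange(1, k_max + 1)
    errors = np.array([reconstruction_error(z, k) for k in ks], dtype=float)
    if np.any(np.diff(errors) > 1e-6):
        logger.warning("reconstruction error curve is not monotone within tolerance")
    b, _, s_left, s_right = _two_segment_fit(ks.astype(float), errors)
    k_star = int(ks[b])
    low_confidence = s_right <= 0 or (s_left / max(s_right, 1e-12)) < slope_ratio_min
    return k_star, errors, low_confidence


def extract_signatures(dec: ICADecomposition, threshold_sd: float = 2.5) -> list[ICSignature]:
    """Per component: genes beyond +/- ``threshold_sd`` SD of the column mean.

    A column with zero loading SD yields empty sets (no signature genes).
    """
    out = []
    for ic in dec.components:
        col = dec.A[ic]
        mu, sd = col.mean(), col.std(ddof=1)
        if sd == 0:
            pos, neg = frozenset(), frozenset()
        else:
            pos = frozenset(col.index[col > mu + threshold_sd * sd])
            neg = frozenset(col.index[col < mu - threshold_sd * sd])
        out.append(
            ICSignature(
                cell_type=dec.cell_type, ic=ic,
                positive_genes=pos, negative_genes=neg,
                threshold_sd=threshold_sd,
            )
        )
    return out


def project_cohort(
    dec: ICADecomposition,
    new_expr: ExpressionMatrix,
    min_gene_overlap: float = 0.8,
    mode: str = "pinv",
) -> SampleScores:
    """Project a new cohort onto a fitted decomposition's component space.

    The new cohort is preprocessed with the same recipe (its own per-gene
    center/scale), aligned to the model's genes by identifier, and scored as
    ``pinv(A) @ X`` (least-squares source estimate; reproduces the fitted S
    exactly on the training data).  ``mode="transpose"`` uses ``A.T @ X``
    instead.
    """
    z, _, _ = preprocess(new_expr)
    common = dec.A.index.intersection(z.index)
    frac = len(common) / len(dec.A.index)
    if frac < min_gene_overlap:
        raise ValueError(
            f"gene overlap {frac:.2%} below required {min_gene_overlap:.0%} "
            f"({len(common)}/{len(dec.A.index)} model genes present)"
        )
    A = dec.A.loc[common].to_numpy()
    X = z.loc[common].to_numpy()
    if mode == "pinv":
        scores = np.linalg.pinv(A) @ X
    elif mode == "transpose":
        scores = A.T @ X
    else:
        raise ValueError(f"unknown projection mode: {mode!r}")
    return SampleScores(
        cell_type=dec.cell_type,
        scores=pd.DataFrame(scores.T, index=z.columns, columns=dec.components),
        provenance="projected",
    )


def fitted_scores(dec: ICADecomposition) -> SampleScores:
    return SampleScores(cell_type=dec.cell_type, scores=dec.S.T.copy(), provenance="fitted")


def match_components(
    S_ref: pd.DataFrame, S_other: pd.DataFrame
) -> pd.DataFrame:
    """One-to-one matching of components by absolute Pearson correlation.

    Both arguments are components x samples over the same samples.  Returns,
    per reference component, the matched component, |r| of the match, and the
    best |r| among the unmatched alternatives (``second_r``).  Matching
    maximizes total |r| (Hungarian assignment).
    """
    common = S_ref.columns.intersection(S_other.columns)
    a = S_ref[common].to_numpy()
    b = S_other[common].to_numpy()
    r = np.corrcoef(a, b)[: len(a), len(a):]
    absr = np.abs(r)
    ri, ci = optimize.linear_sum_assignment(-absr)
    rows = []
    for i, j in zip(ri, ci):
        others = np.delete(absr[i], j)
        rows.append(
            {
                "component": S_ref.index[i],
                "match": S_other.index[j],
                "r": float(r[i, j]),
                "abs_r": float(absr[i, j]),
                "second_r": float(others.max()) if len(others) else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("component")


def score_cells(
    signature_genes: frozenset | set,
    cell_expr: pd.DataFrame,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
    min_genes: int = 1,
) -> pd.Series:
    """Module score of a gene set in each cell (control-gene-bin method).

    ``cell_expr`` is cells x genes.  Genes are ranked by mean expression and
    cut into ``n_bins`` bins; for each signature gene, up to ``n_ctrl``
    control genes are drawn (without replacement) from its bin; the score is
    the mean signature expression minus the mean expression of the pooled
    (unique) control set, per cell.
    """
    present = [g for g in cell_expr.columns if g in signature_genes]
    if len(present) < min_genes:
        raise ValueError(
            f"only {len(present)} signature genes present (need >= {min_genes})"
        )
    rng = np.random.default_rng(seed)
    avg = cell_expr.mean(axis=0)
    bins = pd.qcut(avg.rank(method="first"), n_bins, labels=False)
    ctrl: set = set()
    for g in present:
        pool = bins.index[bins == bins[g]]
        take = min(n_ctrl, len(pool))
        ctrl.update(rng.choice(pool, size=take, replace=False))
    sig_mean = cell_expr[present].mean(axis=1)
    ctrl_mean = cell_expr[sorted(ctrl)].mean(axis=1)
    return sig_mean - ctrl_mean


def pc_clustering_test(
    cell_scores: pd.DataFrame,
    pc_embedding: pd.DataFrame,
    min_pct_diff: float = 10.0,
    fdr: float = 0.20,
) -> pd.DataFrame:
    """Test whether positively scoring cells cluster in PC space.

    For each score column, intra-group distances (pairs of positively scoring
    cells) are compared against inter-group distances (positive vs.
    non-positive cells) in the PC embedding.  ``pct_diff`` is the percent by
    which the mean intra distance falls short of the mean inter distance; p
    is a one-sided rank-sum test (intra < inter); a component is ``clustered``
    when BH-adjusted p < ``fdr`` and pct_diff > ``min_pct_diff``.
    """
    emb = pc_embedding.loc[cell_scores.index].to_numpy()
    rows = []
    for ic in cell_scores.columns:
        pos = (cell_scores[ic] > 0).to_numpy()
        if pos.sum() < 2 or (~pos).sum() < 1:
            rows.append({"ic": ic, "pct_diff": np.nan, "p": np.nan})
            continue
        intra = pdist(emb[pos])
        inter = cdist(emb[pos], emb[~pos]).ravel()
        pct_diff = 100.0 * (inter.mean() - intra.mean()) / inter.mean()
        p = stats.mannwhitneyu(intra, inter, alternative="less").pvalue
        rows.append({"ic": ic, "pct_diff": float(pct_diff), "p": float(p)})
    res = pd.DataFrame(rows).set_index("ic")
    ok = res["p"].notna()
    res["fdr"] = np.nan
    if ok.any():
        res.loc[ok, "fdr"] = multipletests(res.loc[ok, "p"], method="fdr_bh")[1]
    res["clustered"] = (res["fdr"] < fdr) & (res["pct_diff"] > min_pct_diff)
    return res


# ---------------------------------------------------------------------------
# serialization (directory of TSVs + JSON metadata)


def save_decomposition(dec: ICADecomposition, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dec.A.to_csv(outdir / "A.tsv", sep="\t", index_label="gene")
    dec.S.to_csv(outdir / "S.tsv", sep="\t", index_label="component")
    pd.DataFrame({"center": dec.center, "scale": dec.scale}).to_csv(
        outdir / "preprocessing.tsv", sep="\t", index_label="gene"
    )
    meta = {
        "cell_type": dec.cell_type, "k": dec.k,
        "seed": dec.seed, "algorithm": dec.algorithm,
    }
    (outdir / "meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")


def load_decomposition(indir: str | Path) -> ICADecomposition:
    indir = Path(indir)
    meta = json.loads((indir / "meta.json").read_text())
    A = pd.read_csv(indir / "A.tsv", sep="\t", index_col=0)
    S = pd.read_csv(indir / "S.tsv", sep="\t", index_col=0)
    prep = pd.read_csv(indir / "preprocessing.tsv", sep="\t", index_col=0)
    return ICADecomposition(
        cell_type=meta["cell_type"], k=meta["k"], A=A, S=S,
        center=prep["center"], scale=prep["scale"],
        seed=meta["seed"], algorithm=meta["algorithm"],
    )
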