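"""Synthetic-data generators with the statistical structure every pipeline
stage assumes, so the whole workflow is testable without downloads.

The cohort generator emulates deconvolved per-cell-type expression as a
low-rank non-Gaussian latent model: per cell type, heavy-tailed (Laplace)
source rows mixed through sparse gene loadings on a log scale plus Gaussian
noise, exponentiated to TPM-like values.  Survival times follow a
proportional-hazards model whose linear predictor contains the planted
joint-activity indicators at stated log-hazard ratios plus age and sex
effects, with independent exponential censoring.  Planted interactions can
couple the two source rows through a Gaussian copula so the joint tertile
bin is occupied well above the independence rate.

Slides are hexagonal lattices with contiguous patches of elevated signature
expression; mutation matrices are Bernoulli per gene with logit-linear
modulation by chosen component levels or interaction activity.

Every generator is a pure function of its configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

from .core_io import ExpressionMatrix, LRDatabase
from .crosstalk import SpatialSlide
from .screen import joint_indicator, _tertile_labels

SQRT3_2 = np.sqrt(3.0) / 2.0


@dataclass(frozen=True)
class PlantedCSI:
    """One planted prognostic interaction between two cell types' components."""

    c1: str
    ic1: int  # 0-based true source index within cell type c1
    c2: str
    ic2: int
    bin: str          # bin1 | bin3or7 | bin9
    log_hr: float
    # Gaussian-copula |rho| between the two sources; None selects the
    # occupancy-matched default giving ~25% joint-bin occupancy (0.84 for
    # bin1/bin9, 0.104 for the already-likelier merged bin3or7 class)
    coupling: float | None = None


@dataclass(frozen=True)
class SimulationConfig:
    n_cell_types: int = 2
    n_genes: int = 500
    n_samples: int = 400
    k_true: int = 5
    source_dist: str = "laplace"   # laplace | gaussian (negative control)
    loading_density: float = 0.2   # fraction of non-zero gene loadings
    noise_sd: float = 0.2
    baseline_hazard: float = 1e-3  # per day
    censoring_frac: float = 0.30
    age_log_hr: float = 0.01       # per year, centered
    sex_log_hr: float = 0.1
    planted_csis: tuple[PlantedCSI, ...] = ()
    min_bin_occupancy: int = 5
    seed: int = 0

    def cell_types(self) -> list[str]:
        return [f"ct{i + 1}" for i in range(self.n_cell_types)]


@dataclass(frozen=True)
class PlantedPatch:
    center: tuple[float, float]  # (row, col) lattice coordinates
    radius: float
    genes: tuple[str, ...]
    amplitude: float = 2.0


@dataclass(frozen=True)
class SlideConfig:
    rows: int = 30
    cols: int = 30
    n_genes: int = 200
    background_sd: float = 1.0
    patches: tuple[PlantedPatch, ...] = ()
    seed: int = 0


@dataclass(frozen=True)
class MutationLink:
    gene: str
    modulator: str  # key into the modulators mapping passed to gen_mutations
    effect: float   # logit-scale coefficient on the centered modulator


@dataclass(frozen=True)
class MutationConfig:
    n_genes: int = 50
    freq_low: float = 0.02
    freq_high: float = 0.10
    links: tuple[MutationLink, ...] = ()
    seed: int = 0


def _gene_names(n: int) -> list[str]:
    return [f"g{i + 1:04d}" for i in range(n)]


def _laplace_ppf(u: np.ndarray) -> np.ndarray:
    # unit-variance Laplace quantile function
    return stats.laplace(scale=1 / np.sqrt(2)).ppf(u)


def _coupled_sources(rho: float, n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Two unit-variance Laplace vectors with Gaussian-copula correlation rho."""
    cov = np.array([[1.0, rho], [rho, 1.0]])
    z = rng.multivariate_normal([0.0, 0.0], cov, size=n)
    u = stats.norm.cdf(z)
    return _laplace_ppf(u[:, 0]), _laplace_ppf(u[:, 1])


def gen_cohort(
    cfg: SimulationConfig,
) -> tuple[dict[str, ExpressionMatrix], pd.DataFrame, dict]:
    """Generate per-cell-type expression, a clinical table, and the truth record.

    Raises if any planted interaction's joint bin holds fewer than
    ``cfg.min_bin_occupancy`` samples (infeasible planting).
    """
    rng = np.random.default_rng(cfg.seed)
    cts = cfg.cell_types()
    samples = [f"s{i + 1:04d}" for i in range(cfg.n_samples)]
    genes = _gene_names(cfg.n_genes)

    # sources, with copula coupling for planted interactions
    S: dict[str, np.ndarray] = {}
    for ct in cts:
        if cfg.source_dist == "laplace":
            S[ct] = rng.laplace(0.0, 1 / np.sqrt(2), size=(cfg.k_true, cfg.n_samples))
        elif cfg.source_dist == "gaussian":
            S[ct] = rng.standard_normal((cfg.k_true, cfg.n_samples))
        else:
            raise ValueError(f"unknown source_dist: {cfg.source_dist!r}")
    used: set[tuple[str, int]] = set()
    for pc in cfg.planted_csis:
        for key in ((pc.c1, pc.ic1), (pc.c2, pc.ic2)):
            if key in used:
                raise ValueError(f"component {key} used by more than one planted interaction")
            used.add(key)
        coupling = pc.coupling
        if coupling is None:
            coupling = 0.104 if pc.bin == "bin3or7" else 0.84
        rho = abs(coupling) * (-1.0 if pc.bin == "bin3or7" else 1.0)
        s1, s2 = _coupled_sources(rho, cfg.n_samples, rng)
        S[pc.c1][pc.ic1] = s1
        S[pc.c2][pc.ic2] = s2

    # mixing and TPM-like expression
    A: dict[str, np.ndarray] = {}
    exprs: dict[str, ExpressionMatrix] = {}
    for ct in cts:
        mask = rng.random((cfg.n_genes, cfg.k_true)) < cfg.loading_density
        a = rng.standard_normal((cfg.n_genes, cfg.k_true)) * mask
        A[ct] = a
        baseline = rng.uniform(1.0, 8.0, size=cfg.n_genes)
        logx = baseline[:, None] + a @ S[ct] + rng.normal(0.0, cfg.noise_sd, (cfg.n_genes, cfg.n_samples))
        tpm = np.clip(2.0 ** logx - 1.0, 0.0, None)
        exprs[ct] = ExpressionMatrix(
            cell_type=ct, values=pd.DataFrame(tpm, index=genes, columns=samples)
        )

    # clinical covariates
    age = np.clip(rng.normal(55.0, 12.0, cfg.n_samples), 20.0, 90.0)
    sex = np.where(rng.random(cfg.n_samples) < 0.5, "F", "M")
    grade = rng.choice(["II", "III", "IV"], size=cfg.n_samples, p=[0.3, 0.4, 0.3])
    subtype = rng.choice(["IDH-A", "IDH-O"], size=cfg.n_samples, p=[0.6, 0.4])

    # planted joint-activity indicators from empirical tertiles of true sources
    lp = cfg.age_log_hr * (age - age.mean()) + cfg.sex_log_hr * (sex == "M")
    indicators: dict[str, np.ndarray] = {}
    for pc in cfg.planted_csis:
        b1 = pd.Series(_tertile_labels(S[pc.c1][pc.ic1]), index=samples)
        b2 = pd.Series(_tertile_labels(S[pc.c2][pc.ic2]), index=samples)
        ind = joint_indicator(b1, b2, pc.bin).to_numpy()
        occ = int(ind.sum())
        if occ < cfg.min_bin_occupancy:
            raise ValueError(
                f"planted bin {pc.bin} for {pc.c1}:{pc.ic1}x{pc.c2}:{pc.ic2} "
                f"holds only {occ} samples (need >= {cfg.min_bin_occupancy})"
            )
        key = f"{pc.c1}:IC{pc.ic1 + 1}|{pc.c2}:IC{pc.ic2 + 1}|{pc.bin}"
        indicators[key] = ind
        lp = lp + pc.log_hr * ind

    # survival with independent exponential censoring
    rate = cfg.baseline_hazard * np.exp(lp)
    t_event = rng.exponential(1.0 / rate)
    cf = cfg.censoring_frac
    if cf > 0:
        c_rate = cfg.baseline_hazard * cf / (1.0 - cf)
        t_cens = rng.exponential(1.0 / c_rate, cfg.n_samples)
    else:
        t_cens = np.full(cfg.n_samples, np.inf)
    os_time = np.minimum(t_event, t_cens)
    os_event = (t_event <= t_cens).astype(int)

    clinical = pd.DataFrame(
        {
            "sample_id": samples,
            "os_time": np.maximum(os_time, 1e-3),
            "os_event": os_event,
            "age": age,
            "sex": sex,
            "grade": pd.Series(grade).map({"II": 2, "III": 3, "IV": 4}).to_numpy(),
            "subtype": subtype,
        }
    ).set_index("sample_id", drop=False)

    truth = {
        "A": {ct: pd.DataFrame(A[ct], index=genes) for ct in cts},
        "S": {ct: pd.DataFrame(S[ct], columns=samples) for ct in cts},
        "planted": [
            {
                "c1": pc.c1, "ic1": pc.ic1, "c2": pc.c2, "ic2": pc.ic2,
                "bin": pc.bin, "log_hr": pc.log_hr,
                "csi_id": f"{pc.c1}:IC{pc.ic1 + 1}|{pc.c2}:IC{pc.ic2 + 1}|{pc.bin}",
                "occupancy": float(indicators[
                    f"{pc.c1}:IC{pc.ic1 + 1}|{pc.c2}:IC{pc.ic2 + 1}|{pc.bin}"
                ].mean()),
            }
            for pc in cfg.planted_csis
        ],
        "indicators": pd.DataFrame(indicators, index=samples),
        "age_log_hr": cfg.age_log_hr,
        "sex_log_hr": cfg.sex_log_hr,
    }
    return exprs, clinical, truth


def true_scores(truth: dict) -> dict:
    """Wrap the generator's true sources as per-cell-type sample scores."""
    from .states import SampleScores

    out = {}
    for ct, s in truth["S"].items():
        df = s.T.copy()
        df.columns = [f"IC{i + 1}" for i in range(df.shape[1])]
        out[ct] = SampleScores(cell_type=ct, scores=df, provenance="fitted")
    return out


def hex_lattice(rows: int, cols: int) -> pd.DataFrame:
    """Offset hexagonal lattice coordinates (unit pitch)."""
    recs = []
    for r in range(rows):
        for c in range(cols):
            recs.append(
                {"spot_id": f"r{r:02d}c{c:02d}", "row": r, "col": c,
                 "x": c + 0.5 * (r % 2), "y": r * SQRT3_2}
            )
    return pd.DataFrame(recs).set_index("spot_id")


def gen_slide(cfg: SlideConfig) -> tuple[SpatialSlide, dict]:
    """Hex-lattice slide with planted contiguous patches of elevated genes."""
    if cfg.rows < 5 or cfg.cols < 5:
        raise ValueError("grid must be at least 5x5")
    rng = np.random.default_rng(cfg.seed)
    coords = hex_lattice(cfg.rows, cfg.cols)
    genes = _gene_names(cfg.n_genes)
    expr = pd.DataFrame(
        rng.normal(0.0, cfg.background_sd, (len(coords), cfg.n_genes)),
        index=coords.index, columns=genes,
    )
    max_radius = max(cfg.rows * SQRT3_2, cfg.cols)
    patch_spots = {}
    for i, patch in enumerate(cfg.patches):
        if patch.radius > max_radius:
            raise ValueError(f"patch radius {patch.radius} exceeds the grid extent")
        cx = patch.center[1] + 0.5 * (int(patch.center[0]) % 2)
        cy = patch.center[0] * SQRT3_2
        d = np.hypot(coords["x"] - cx, coords["y"] - cy)
        inside = coords.index[d <= patch.radius]
        present = [g for g in patch.genes if g in expr.columns]
        expr.loc[inside, present] += patch.amplitude
        patch_spots[f"patch{i + 1}"] = list(inside)
    slide = SpatialSlide(coords=coords[["x", "y"]], expr=expr)
    return slide, {"patch_spots": patch_spots}


def gen_mutations(
    cfg: MutationConfig,
    samples: list[str],
    modulators: Mapping[str, pd.Series] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Binary gene x sample mutation matrix with planted modulated genes.

    Each gene mutates Bernoulli at its base frequency; linked genes'
    per-sample mutation probability is ``expit(logit(base) + effect * z)``
    with ``z`` the centered modulator (a binned component level, an
    interaction activity row, ...).
    """
    if not (0 < cfg.freq_low <= cfg.freq_high < 1):
        raise ValueError("mutation frequencies must lie in (0, 1)")
    rng = np.random.default_rng(cfg.seed)
    genes = [f"mut_g{i + 1}" for i in range(cfg.n_genes)]
    base = rng.uniform(cfg.freq_low, cfg.freq_high, cfg.n_genes)
    prob = np.tile(base[:, None], (1, len(samples)))
    links = {l.gene: l for l in cfg.links}
    for gi, g in enumerate(genes):
        if g in links:
            link = links[g]
            if modulators is None or link.modulator not in modulators:
                raise KeyError(f"modulator {link.modulator!r} not provided")
            z = modulators[link.modulator].reindex(samples).astype(float)
            z = (z - z.mean()).to_numpy()
            prob[gi] = expit(logit(base[gi]) + link.effect * z)
    mat = (rng.random((cfg.n_genes, len(samples))) < prob).astype(int)
    mut = pd.DataFrame(mat, index=genes, columns=samples)
    truth = {"base_freq": dict(zip(genes, base)), "links": list(cfg.links)}
    return mut, truth


def plant_grade_link(
    mic_vec: pd.Series, gamma: float, seed: int = 0, base_late: float = 0.6
) -> pd.Series:
    """Draw a binary late-grade label with a logit-linear MIC effect."""
    rng = np.random.default_rng(seed)
    p = expit(logit(base_late) + gamma * (mic_vec - mic_vec.mean()))
    return pd.Series(
        (rng.random(len(mic_vec)) < p).astype(int), index=mic_vec.index
    )


def gen_lr_database(
    n_ligands: int = 547,
    n_receptors: int = 466,
    n_pairs: int = 1986,
    ligand_pool: list[str] | None = None,
    receptor_pool: list[str] | None = None,
    seed: int = 0,
) -> LRDatabase:
    """Synthetic ligand-receptor database at a configurable scale.

    Pairs are sampled so that every ligand and every receptor participates in
    at least one pair, making the recomputed counts equal the requested ones.
    Defaults mirror the scale of a curated human cell-communication database
    (1986 pairs over 547 ligands and 466 receptors).
    """
    if n_pairs < max(n_ligands, n_receptors):
        raise ValueError("n_pairs must cover every ligand and receptor at least once")
    if n_pairs > n_ligands * n_receptors:
        raise ValueError("n_pairs exceeds the number of distinct pairs")
    rng = np.random.default_rng(seed)
    ligands = ligand_pool or [f"L{i + 1:04d}" for i in range(n_ligands)]
    receptors = receptor_pool or [f"R{i + 1:04d}" for i in range(n_receptors)]
    if len(ligands) != n_ligands or len(receptors) != n_receptors:
        raise ValueError("gene pools must match the requested counts")
    # cover every ligand and receptor with exactly max(n_ligands, n_receptors)
    # pairs, then fill with distinct random pairs
    pairs: set = {
        (ligands[i % n_ligands], receptors[i % n_receptors])
        for i in range(max(n_ligands, n_receptors))
    }
    while len(pairs) < n_pairs:
        l = ligands[int(rng.integers(0, n_ligands))]
        r = receptors[int(rng.integers(0, n_receptors))]
        pairs.add((l, r))
    return LRDatabase(pairs=frozenset(pairs))
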