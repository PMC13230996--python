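"""Ligand-receptor support of cell-state interactions and spatial
co-localization on hexagonal-lattice slides.

Ligand-receptor enrichment compares the observed count of complementary
pairs between two signature gene sets with the expectation under the
database's global pair density: for a database of ``P`` pairs over ``L``
ligands and ``R`` receptors, ``F = P / (L * R)``, ``E = m * n * F`` for set
sizes m and n, and the statistic is ``O/E = c / E``.

Spatial co-localization uses a neighborhood-overlap statistic on Visium-like
hex lattices: each spot's neighborhood is itself plus its (up to six)
lattice neighbors, and

    O(X, Y) = |union of nbhds where X and Y are both active|
              / |union of nbhds where X is active or Y is active|

with significance from a permutation null (activity shuffled over spots, a
normal fit to the null overlaps, one-sided p).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree
from statsmodels.stats.multitest import multipletests

from .core_io import LRDatabase
from .screen import CSIN
from .states import ICSignature

logger = logging.getLogger("csitme")

SIDES = ("pos", "neg")


@dataclass
class LRSupport:
    """Complementary ligand-receptor pairs backing one interaction."""

    csi_id: str
    pairs: pd.DataFrame  # ligand, receptor, side_ic1, side_ic2, ligand_on, activation
    n_unique_pairs: int


@dataclass
class SpatialSlide:
    """A spatial slide: spot coordinates, expression, and hex neighbor graph."""

    coords: pd.DataFrame               # spot_id index, columns x, y
    expr: pd.DataFrame                 # spots x genes (normalized)
    neighbors: dict = field(default_factory=dict)  # spot -> frozenset of spots

    def __post_init__(self) -> None:
        if not self.neighbors:
            self.neighbors = build_hex_neighbors(self.coords)


# ---------------------------------------------------------------------------
# ligand-receptor enrichment


def _signature_side(sig: ICSignature, side: str) -> frozenset:
    return sig.positive_genes if side == "pos" else sig.negative_genes


def count_complementary_lr(set_a: set, set_b: set, db: LRDatabase) -> int:
    """Unique database pairs with the ligand in one set and receptor in the other."""
    return sum(
        1
        for l, r in db.pairs
        if (l in set_a and r in set_b) or (l in set_b and r in set_a)
    )


def oe_ratio(c: int, m: int, n: int, db: LRDatabase) -> float:
    """Observed/expected complementary-pair count for set sizes m and n."""
    if m <= 0 or n <= 0:
        raise ValueError("both gene sets must be non-empty")
    f = db.n_pairs / (db.n_ligands * db.n_receptors)
    return c / (m * n * f)


def activation_state(bin_class: str, side_ic1: str, side_ic2: str) -> str:
    """Activation of a ligand-receptor pair given the CSI's bin and gene sides.

    A gene on the positive side of its component is upregulated when that
    component is High; a gene on the negative side is upregulated when it is
    Low.  The pair is ``activated`` iff both partners are up in the bin's
    active configuration (for bin 3/7 either of the two symmetric
    configurations), else ``inactivated``.
    """

    def up(side: str, level: str) -> bool:
        return level == ("High" if side == "pos" else "Low")

    if bin_class == "bin1":
        configs = [("Low", "Low")]
    elif bin_class == "bin9":
        configs = [("High", "High")]
    elif bin_class == "bin3or7":
        configs = [("High", "Low"), ("Low", "High")]
    else:
        raise ValueError(f"unknown bin class: {bin_class!r}")
    for l1, l2 in configs:
        if up(side_ic1, l1) and up(side_ic2, l2):
            return "activated"
    return "inactivated"


def map_lr_to_csis(
    csin: CSIN,
    signatures: dict[tuple[str, str], ICSignature],
    db: LRDatabase,
) -> list[LRSupport]:
    """Enumerate database pairs across all four signature-side combinations.

    A database pair found in several side combinations counts once toward
    support (``n_unique_pairs``) but is reported per combination with its
    activation state.
    """
    out = []
    for rec in csin.records:
        sig1 = signatures[(rec.c1, rec.ic1)]
        sig2 = signatures[(rec.c2, rec.ic2)]
        rows = []
        for s1, s2 in itertools.product(SIDES, SIDES):
            g1 = _signature_side(sig1, s1)
            g2 = _signature_side(sig2, s2)
            act = activation_state(rec.bin, s1, s2)
            for l, r in sorted(db.pairs):
                if l in g1 and r in g2:
                    rows.append(
                        {"ligand": l, "receptor": r, "side_ic1": s1,
                         "side_ic2": s2, "ligand_on": "ic1", "activation": act}
                    )
                if l in g2 and r in g1:
                    rows.append(
                        {"ligand": l, "receptor": r, "side_ic1": s1,
                         "side_ic2": s2, "ligand_on": "ic2", "activation": act}
                    )
        pairs = pd.DataFrame(
            rows,
            columns=["ligand", "receptor", "side_ic1", "side_ic2", "ligand_on", "activation"],
        )
        n_unique = pairs[["ligand", "receptor"]].drop_duplicates().shape[0] if len(pairs) else 0
        out.append(LRSupport(csi_id=rec.csi_id, pairs=pairs, n_unique_pairs=n_unique))
    return out


def celltype_lr_concordance(
    csin: CSIN,
    signatures: dict[tuple[str, str], ICSignature],
    db: LRDatabase,
    cell_types: list[str] | None = None,
    agg: str = "mean",
) -> tuple[float, float, pd.DataFrame]:
    """Correlate CSIN edge counts with ligand-receptor density per cell-type pair.

    For each unordered cell-type pair, the network degree (number of CSIs
    between the two types) is compared against the aggregated O/E ratio of
    complementary pairs over all component pairs and all four signature-side
    combinations.  Returns Spearman rho, its p, and the per-pair table
    (including per-side-combination aggregates).
    """
    if cell_types is None:
        cell_types = sorted({ct for ct, _ in signatures})
    pairs = list(itertools.combinations(sorted(cell_types), 2))
    if len(pairs) < 4:
        raise ValueError(f"need at least 4 cell-type pairs, got {len(pairs)}")
    edge_counts = {p: 0 for p in pairs}
    for rec in csin.records:
        key = tuple(sorted((rec.c1, rec.c2)))
        if key in edge_counts:
            edge_counts[key] += 1
    rows = []
    for ca, cb in pairs:
        oes: dict[str, list[float]] = {f"{s1}_{s2}": [] for s1 in SIDES for s2 in SIDES}
        for (ct1, ic1), sig1 in signatures.items():
            if ct1 != ca:
                continue
            for (ct2, ic2), sig2 in signatures.items():
                if ct2 != cb:
                    continue
                for s1, s2 in itertools.product(SIDES, SIDES):
                    g1, g2 = _signature_side(sig1, s1), _signature_side(sig2, s2)
                    if not g1 or not g2:
                        continue
                    c = count_complementary_lr(g1, g2, db)
                    oes[f"{s1}_{s2}"].append(oe_ratio(c, len(g1), len(g2), db))
        combine = np.mean if agg == "mean" else np.sum
        all_vals = [v for vals in oes.values() for v in vals]
        row = {
            "cell_type_a": ca, "cell_type_b": cb,
            "n_csis": edge_counts[(ca, cb)],
            "oe": float(combine(all_vals)) if all_vals else np.nan,
        }
        for key, vals in oes.items():
            row[f"oe_{key}"] = float(combine(vals)) if vals else np.nan
        rows.append(row)
    table = pd.DataFrame(rows)
    ok = table["oe"].notna()
    x, y = table.loc[ok, "n_csis"], table.loc[ok, "oe"]
    if x.nunique() <= 1 or y.nunique() <= 1:
        logger.warning("degenerate (constant) vectors; correlation undefined")
        return np.nan, np.nan, table
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p), table


# ---------------------------------------------------------------------------
# spatial co-localization


def build_hex_neighbors(coords: pd.DataFrame, pitch_tol: float = 1.3) -> dict:
    """Link each spot to its lattice neighbors (up to six nearest).

    The lattice pitch is the smallest inter-spot distance; spots within
    ``pitch * pitch_tol`` are neighbors, capped at the six nearest, and the
    relation is symmetrized.  Duplicate coordinates are rejected.
    """
    if len(coords) < 2:
        raise ValueError("need at least 2 spots")
    xy = coords[["x", "y"]].to_numpy(dtype=float)
    if len(np.unique(xy, axis=0)) < len(xy):
        raise ValueError("duplicate spot coordinates")
    tree = cKDTree(xy)
    dists, idxs = tree.query(xy, k=min(7, len(xy)))
    pitch = dists[:, 1].min()
    nbrs: dict = {s: set() for s in coords.index}
    spots = list(coords.index)
    for i, spot in enumerate(spots):
        for d, j in zip(dists[i, 1:], idxs[i, 1:]):
            if d <= pitch * pitch_tol:
                nbrs[spot].add(spots[j])
                nbrs[spots[j]].add(spot)  # symmetric closure
    return {s: frozenset(v) for s, v in nbrs.items()}


def threshold_spot_activity(
    state_scores: pd.DataFrame,
    reference_scores: pd.DataFrame | pd.Series,
    q: float = 0.90,
) -> tuple[pd.DataFrame, float]:
    """Binary spot activity from a slide-specific reference quantile.

    The threshold is the ``q`` quantile of the pooled reference-state scores
    (states expected to be absent from the tissue); a spot is active for a
    state iff its score strictly exceeds the threshold.
    """
    ref = np.asarray(reference_scores).ravel()
    ref = ref[~np.isnan(ref)]
    if ref.size == 0:
        raise ValueError("reference scores are empty")
    thr = float(np.quantile(ref, q))
    return state_scores.gt(thr), thr


class _NeighborIndex:
    """Positional neighborhood membership for fast repeated overlap calls."""

    def __init__(self, spots: pd.Index, neighbors: dict):
        self.spots = pd.Index(spots)
        pos = {s: i for i, s in enumerate(self.spots)}
        self.members = [
            np.array([i] + sorted(pos[n] for n in neighbors[s] if n in pos), dtype=int)
            for i, s in enumerate(self.spots)
        ]
        # incidence: spot -> centers whose neighborhood contains it (for rule=any)
        self.incidence = [np.array([], dtype=int)] * len(self.spots)
        inc: list[list[int]] = [[] for _ in self.spots]
        for c, mem in enumerate(self.members):
            for m in mem:
                inc[m].append(c)
        self.incidence = [np.array(v, dtype=int) for v in inc]


def _overlap_from_arrays(
    ax: np.ndarray, ay: np.ndarray, index: _NeighborIndex, rule: str
) -> float:
    if rule == "center":
        cx, cy = ax, ay
    elif rule == "any":
        cx = np.zeros_like(ax)
        cy = np.zeros_like(ay)
        for i in range(len(ax)):
            cx[i] = ax[index.members[i]].any()
            cy[i] = ay[index.members[i]].any()
    else:
        raise ValueError(f"unknown neighborhood rule: {rule!r}")
    either_c = np.flatnonzero(cx | cy)
    if len(either_c) == 0:
        return float("nan")
    both_c = np.flatnonzero(cx & cy)
    either = np.unique(np.concatenate([index.members[i] for i in either_c]))
    if len(both_c) == 0:
        return 0.0
    both = np.unique(np.concatenate([index.members[i] for i in both_c]))
    return len(both) / len(either)


def coloc_overlap(
    active_x: pd.Series,
    active_y: pd.Series,
    neighbors: dict,
    rule: str = "center",
) -> float:
    """Neighborhood-overlap co-localization statistic O(X, Y) in [0, 1].

    A neighborhood (a spot plus its neighbors) counts as X-active if its
    center spot is X-active (``rule="center"``, default) or if any member is
    (``rule="any"``).  O is the size of the union of member spots of
    neighborhoods active for both states over that of neighborhoods active
    for either; NaN when neither state is active anywhere.
    """
    index = _NeighborIndex(active_x.index, neighbors)
    o = _overlap_from_arrays(
        active_x.to_numpy(dtype=bool),
        active_y.reindex(active_x.index).to_numpy(dtype=bool),
        index, rule,
    )
    if np.isnan(o):
        logger.warning("neither state active anywhere; O(X, Y) undefined")
    return o


def coloc_significance(
    active_x: pd.Series,
    active_y: pd.Series,
    neighbors: dict,
    n_shuffle: int = 100,
    seed: int = 0,
    rule: str = "center",
) -> tuple[float, float]:
    """Permutation significance of O(X, Y).

    Activity assignments are shuffled over spots (independently for the two
    states) ``n_shuffle`` times, a normal distribution is fit to the null
    overlaps, and the one-sided p is the upper tail probability of the
    observed overlap.  Returns (O_obs, p); O_obs of NaN gives p = NaN.
    """
    index = _NeighborIndex(active_x.index, neighbors)
    xv = active_x.to_numpy(dtype=bool)
    yv = active_y.reindex(active_x.index).to_numpy(dtype=bool)
    o_obs = _overlap_from_arrays(xv, yv, index, rule)
    if np.isnan(o_obs):
        return o_obs, float("nan")
    rng = np.random.default_rng(seed)
    nulls = np.empty(n_shuffle)
    for i in range(n_shuffle):
        nulls[i] = _overlap_from_arrays(
            rng.permutation(xv), rng.permutation(yv), index, rule
        )
    nulls = nulls[~np.isnan(nulls)]
    mu = float(nulls.mean()) if len(nulls) else 0.0
    sd = float(nulls.std(ddof=1)) if len(nulls) > 1 else 0.0
    if sd == 0:
        logger.warning("degenerate permutation null (zero variance)")
        return o_obs, 1.0 if o_obs <= mu else 0.0
    p = float(stats.norm.sf((o_obs - mu) / sd))
    return o_obs, p


def coloc_all_pairs(
    activity: pd.DataFrame,
    neighbors: dict,
    n_shuffle: int = 100,
    seed: int = 0,
    rule: str = "center",
    state_pairs: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """O(X, Y) with permutation p and slide-level BH for state pairs.

    ``activity`` is spots x states (binary).  By default all unordered state
    pairs are tested; pass ``state_pairs`` to restrict the tested (and BH)
    universe to particular pairs.
    """
    if state_pairs is None:
        state_pairs = list(itertools.combinations(activity.columns, 2))
    rng = np.random.default_rng(seed)
    rows = []
    for x, y in state_pairs:
        o, p = coloc_significance(
            activity[x], activity[y], neighbors,
            n_shuffle=n_shuffle, seed=int(rng.integers(0, 2**31 - 1)), rule=rule,
        )
        rows.append({"state_x": x, "state_y": y, "O": o, "p": p})
    res = pd.DataFrame(rows, columns=["state_x", "state_y", "O", "p"])
    ok = res["p"].notna()
    res["fdr"] = np.nan
    if ok.any():
        res.loc[ok, "fdr"] = multipletests(res.loc[ok, "p"], method="fdr_bh")[1]
    return res


def lr_coloc_enrichment(
    lr_supported: set,
    proximal_by_slide: dict[str, set],
    all_tested: set,
) -> pd.DataFrame:
    """Per-slide Fisher enrichment of LR-supported CSIs among proximal pairs.

    For each slide the 2x2 table is (LR-supported yes/no) x (spatially
    proximal yes/no) over ``all_tested`` interactions, tested one-sided
    (enrichment).  A final row combines the per-slide p values with Fisher's
    method.
    """
    if not proximal_by_slide:
        raise ValueError("need at least one slide")
    rows = []
    pvals = []
    for slide, proximal in proximal_by_slide.items():
        a = len(lr_supported & proximal)
        b = len(lr_supported - proximal)
        c = len((all_tested - lr_supported) & proximal)
        d = len((all_tested - lr_supported) - proximal)
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        pvals.append(p)
        rows.append({"slide": slide, "odds_ratio": odds, "p": p})
    chi2, p_comb = stats.combine_pvalues(pvals, method="fisher")
    rows.append({"slide": "combined", "odds_ratio": np.nan, "p": p_comb})
    res = pd.DataFrame(rows)
    res.attrs["fisher_chi2"] = float(chi2)
    return res
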