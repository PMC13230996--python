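import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from csitme import crosstalk, screen, synthdata
from csitme.core_io import LRDatabase
from csitme.states import ICSignature
from csitme.synthdata import PlantedPatch, SlideConfig, gen_slide, hex_lattice


class TestComplementaryCount:
    def test_single_pair(self):
        db = LRDatabase(pairs=frozenset({("L1", "R1")}))
        assert crosstalk.count_complementary_lr({"L1"}, {"R1"}, db) == 1

    def test_no_db_genes_zero(self):
        db = LRDatabase(pairs=frozenset({("L1", "R1")}))
        assert crosstalk.count_complementary_lr({"x"}, {"y"}, db) == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_double_loop(self, seed):
        rng = np.random.default_rng(seed)
        genes = [f"G{i}" for i in range(40)]
        pairs = frozenset(
            (genes[rng.integers(40)], genes[rng.integers(40)]) for _ in range(30)
        )
        db = LRDatabase(pairs=pairs)
        a = set(rng.choice(genes, 12, replace=False))
        b = set(rng.choice(genes, 12, replace=False))
        brute = 0
        for l, r in pairs:
            if (l in a and r in b) or (l in b and r in a):
                brute += 1
        assert crosstalk.count_complementary_lr(a, b, db) == brute


class TestOERatio:
    def test_full_universe_identity(self):
        db = synthdata.gen_lr_database(seed=0)
        oe = crosstalk.oe_ratio(db.n_pairs, db.n_ligands, db.n_receptors, db)
        assert oe == 1.0

    def test_zero_observed(self):
        db = synthdata.gen_lr_database(n_ligands=5, n_receptors=5, n_pairs=10, seed=0)
        assert crosstalk.oe_ratio(0, 3, 3, db) == 0.0

    def test_doubling_sets_quarters_ratio(self):
        db = synthdata.gen_lr_database(n_ligands=5, n_receptors=5, n_pairs=10, seed=0)
        assert np.isclose(
            crosstalk.oe_ratio(4, 10, 10, db), crosstalk.oe_ratio(4, 5, 5, db) / 4
        )

    def test_empty_set_rejected(self):
        db = synthdata.gen_lr_database(n_ligands=5, n_receptors=5, n_pairs=10, seed=0)
        with pytest.raises(ValueError):
            crosstalk.oe_ratio(1, 0, 3, db)


class TestActivationState:
    def test_full_truth_table(self):
        # a positive-side gene is up in High; a negative-side gene is up in Low
        expected = {
            ("bin1", "neg", "neg"): "activated",
            ("bin1", "neg", "pos"): "inactivated",
            ("bin1", "pos", "neg"): "inactivated",
            ("bin1", "pos", "pos"): "inactivated",
            ("bin9", "pos", "pos"): "activated",
            ("bin9", "neg", "neg"): "inactivated",
            ("bin9", "pos", "neg"): "inactivated",
            ("bin9", "neg", "pos"): "inactivated",
            # one IC High and one Low: mixed sides give one configuration
            # with both partners up; same sides always leave one partner down
            ("bin3or7", "pos", "neg"): "activated",
            ("bin3or7", "neg", "pos"): "activated",
            ("bin3or7", "pos", "pos"): "inactivated",
            ("bin3or7", "neg", "neg"): "inactivated",
        }
        for (b, s1, s2), want in expected.items():
            assert crosstalk.activation_state(b, s1, s2) == want, (b, s1, s2)


class TestMapLR:
    def make_csin(self, bin_class):
        rec = screen.CSIRecord("ct1", "IC1", "ct2", "IC1", bin_class, 0.5, 1.6, 0.01)
        return screen.CSIN([rec], pd.DataFrame())

    def sigs(self):
        return {
            ("ct1", "IC1"): ICSignature("ct1", "IC1", frozenset({"Lpos"}), frozenset({"Lneg"})),
            ("ct2", "IC1"): ICSignature("ct2", "IC1", frozenset({"Rpos"}), frozenset({"Rneg"})),
        }

    def test_bin1_negative_sides_activated(self):
        db = LRDatabase(pairs=frozenset({("Lneg", "Rneg")}))
        sup = crosstalk.map_lr_to_csis(self.make_csin("bin1"), self.sigs(), db)[0]
        assert sup.n_unique_pairs == 1
        assert (sup.pairs["activation"] == "activated").all()

    def test_bin9_negative_sides_inactivated(self):
        db = LRDatabase(pairs=frozenset({("Lneg", "Rneg")}))
        sup = crosstalk.map_lr_to_csis(self.make_csin("bin9"), self.sigs(), db)[0]
        assert (sup.pairs["activation"] == "inactivated").all()

    def test_pair_in_multiple_side_combos_counted_once(self):
        sigs = {
            ("ct1", "IC1"): ICSignature(
                "ct1", "IC1", frozenset({"A"}), frozenset({"A"}) | frozenset()
            ),
            ("ct2", "IC1"): ICSignature("ct2", "IC1", frozenset({"B"}), frozenset({"B"})),
        }
        db = LRDatabase(pairs=frozenset({("A", "B")}))
        sup = crosstalk.map_lr_to_csis(self.make_csin("bin9"), sigs, db)[0]
        assert sup.n_unique_pairs == 1
        assert len(sup.pairs) == 4  # reported per side combination


class TestHexNeighbors:
    def test_interior_spot_has_six(self):
        coords = hex_lattice(7, 7)[["x", "y"]]
        nbrs = crosstalk.build_hex_neighbors(coords)
        assert len(nbrs["r03c03"]) == 6

    def test_corner_spot_has_at_most_three(self):
        coords = hex_lattice(5, 5)[["x", "y"]]
        nbrs = crosstalk.build_hex_neighbors(coords)
        assert len(nbrs["r00c00"]) <= 3

    def test_symmetric_graph(self):
        coords = hex_lattice(6, 6)[["x", "y"]]
        nbrs = crosstalk.build_hex_neighbors(coords)
        for s, ns in nbrs.items():
            for n in ns:
                assert s in nbrs[n]

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force_on_jittered_lattice(self, seed):
        rng = np.random.default_rng(seed)
        coords = hex_lattice(6, 6)[["x", "y"]] + rng.normal(0, 0.01, (36, 2))
        nbrs = crosstalk.build_hex_neighbors(coords)
        xy = coords.to_numpy()
        pitch = np.inf
        for i in range(len(xy)):
            d = np.hypot(*(xy - xy[i]).T)
            d[i] = np.inf
            pitch = min(pitch, d.min())
        brute = {s: set() for s in coords.index}
        for i, s in enumerate(coords.index):
            d = np.hypot(*(xy - xy[i]).T)
            d[i] = np.inf
            near = np.argsort(d)[:6]
            for j in near:
                if d[j] <= pitch * 1.3:
                    brute[s].add(coords.index[j])
                    brute[coords.index[j]].add(s)
        assert {s: set(v) for s, v in nbrs.items()} == brute

    def test_duplicate_coordinates_rejected(self):
        coords = pd.DataFrame(
            {"x": [0.0, 0.0, 1.0], "y": [0.0, 0.0, 0.0]}, index=["a", "b", "c"]
        )
        with pytest.raises(ValueError):
            crosstalk.build_hex_neighbors(coords)


class TestThreshold:
    def test_reference_exceedance_fraction_near_ten_percent(self):
        rng = np.random.default_rng(0)
        idx = [f"sp{i}" for i in range(1000)]
        ref = pd.DataFrame({"b": rng.normal(size=1000), "t": rng.normal(size=1000)}, index=idx)
        act, thr = crosstalk.threshold_spot_activity(ref, ref, q=0.90)
        frac = (ref.to_numpy() > thr).mean()
        assert abs(frac - 0.10) < 0.01

    def test_constant_reference_all_active_above(self):
        idx = ["a", "b"]
        ref = pd.Series([1.0, 1.0], index=idx)
        state = pd.DataFrame({"x": [2.0, 2.0]}, index=idx)
        act, thr = crosstalk.threshold_spot_activity(state, ref)
        assert act["x"].all() and thr == 1.0

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            crosstalk.threshold_spot_activity(
                pd.DataFrame({"x": [1.0]}, index=["a"]), pd.Series([], dtype=float)
            )


def brute_force_overlap(active_x, active_y, neighbors):
    """Independent neighborhood-union enumeration (center rule)."""
    def nbhd(s):
        return {s} | set(neighbors[s])

    cx = {s for s in active_x.index if active_x[s]}
    cy = {s for s in active_y.index if active_y[s]}
    both = set().union(*[nbhd(s) for s in (cx & cy)]) if (cx & cy) else set()
    either = set().union(*[nbhd(s) for s in (cx | cy)]) if (cx | cy) else set()
    if not either:
        return float("nan")
    return len(both) / len(either)


class TestColocOverlap:
    def setup_method(self):
        self.coords = hex_lattice(5, 5)[["x", "y"]]
        self.nbrs = crosstalk.build_hex_neighbors(self.coords)

    def active(self, spots):
        return pd.Series(
            [s in spots for s in self.coords.index], index=self.coords.index
        )

    def test_identical_sets_full_overlap(self):
        act = self.active({"r01c01", "r02c02"})
        assert crosstalk.coloc_overlap(act, act.copy(), self.nbrs) == 1.0

    def test_far_patches_zero(self):
        x = self.active({"r00c00"})
        y = self.active({"r04c04"})
        assert crosstalk.coloc_overlap(x, y, self.nbrs) == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        x = pd.Series(rng.random(25) < 0.3, index=self.coords.index)
        y = pd.Series(rng.random(25) < 0.3, index=self.coords.index)
        ours = crosstalk.coloc_overlap(x, y, self.nbrs)
        brute = brute_force_overlap(x, y, self.nbrs)
        if np.isnan(brute):
            assert np.isnan(ours)
        else:
            assert np.isclose(ours, brute)

    @pytest.mark.parametrize("seed", range(5))
    def test_symmetry(self, seed):
        rng = np.random.default_rng(100 + seed)
        x = pd.Series(rng.random(25) < 0.4, index=self.coords.index)
        y = pd.Series(rng.random(25) < 0.4, index=self.coords.index)
        assert np.isclose(
            crosstalk.coloc_overlap(x, y, self.nbrs),
            crosstalk.coloc_overlap(y, x, self.nbrs),
            equal_nan=True,
        )

    def test_any_rule_differs_and_bounded(self):
        rng = np.random.default_rng(1)
        x = pd.Series(rng.random(25) < 0.3, index=self.coords.index)
        y = pd.Series(rng.random(25) < 0.3, index=self.coords.index)
        o = crosstalk.coloc_overlap(x, y, self.nbrs, rule="any")
        assert 0.0 <= o <= 1.0


class TestColocSignificance:
    def test_same_seed_identical(self):
        coords = hex_lattice(8, 8)[["x", "y"]]
        nbrs = crosstalk.build_hex_neighbors(coords)
        rng = np.random.default_rng(0)
        x = pd.Series(rng.random(64) < 0.2, index=coords.index)
        y = pd.Series(rng.random(64) < 0.2, index=coords.index)
        r1 = crosstalk.coloc_significance(x, y, nbrs, n_shuffle=50, seed=5)
        r2 = crosstalk.coloc_significance(x, y, nbrs, n_shuffle=50, seed=5)
        assert r1 == r2

    def test_planted_overlapping_patches_significant(self):
        # reference signatures are smaller, hence noisier, so the 90th
        # percentile threshold sits above the tested states' background noise
        genes = [f"g{i + 1:04d}" for i in range(70)]
        sig_x, sig_y = tuple(genes[:15]), tuple(genes[15:30])
        cfg = SlideConfig(
            rows=15, cols=15, n_genes=70,
            patches=(
                PlantedPatch(center=(7, 7), radius=3.0, genes=sig_x, amplitude=3.0),
                PlantedPatch(center=(7, 8), radius=3.0, genes=sig_y, amplitude=3.0),
            ),
            seed=2,
        )
        slide, _ = gen_slide(cfg)
        sx = slide.expr[list(sig_x)].mean(axis=1)
        sy = slide.expr[list(sig_y)].mean(axis=1)
        ref = pd.DataFrame(
            {f"r{i}": slide.expr[genes[30 + 5 * i:35 + 5 * i]].mean(axis=1)
             for i in range(8)}
        )
        scores = pd.DataFrame({"X": sx, "Y": sy})
        act, _ = crosstalk.threshold_spot_activity(scores, ref, q=0.90)
        o, p = crosstalk.coloc_significance(
            act["X"], act["Y"], slide.neighbors, n_shuffle=100, seed=1
        )
        assert p < 0.01

    def test_degenerate_null_flagged(self):
        coords = hex_lattice(5, 5)[["x", "y"]]
        nbrs = crosstalk.build_hex_neighbors(coords)
        x = pd.Series(True, index=coords.index)  # every spot active: O always 1
        o, p = crosstalk.coloc_significance(x, x.copy(), nbrs, n_shuffle=20, seed=0)
        assert o == 1.0 and p in (0.0, 1.0)


class TestLRColocEnrichment:
    def test_table_matches_hypergeometric(self):
        lr = {f"c{i}" for i in range(12)}
        proximal = {f"c{i}" for i in range(10)} | {f"n{i}" for i in range(5)}
        universe = lr | {f"n{i}" for i in range(45)}
        res = crosstalk.lr_coloc_enrichment(lr, {"slide1": proximal}, universe)
        odds, p = stats.fisher_exact([[10, 2], [5, 40]], alternative="greater")
        row = res[res.slide == "slide1"].iloc[0]
        assert np.isclose(row["odds_ratio"], odds) and np.isclose(row["p"], p)

    def test_identical_proportions_or_one(self):
        lr = {"a", "b"}
        proximal = {"a", "c"}
        universe = {"a", "b", "c", "d"}
        res = crosstalk.lr_coloc_enrichment(lr, {"s": proximal}, universe)
        assert np.isclose(res.iloc[0]["odds_ratio"], 1.0)

    def test_fisher_combination_closed_form(self):
        p0 = 0.03
        k = 4
        lr = {"a"}
        universe = {"a", "b"}
        res = crosstalk.lr_coloc_enrichment(lr, {"s1": {"a"}}, universe)
        # closed form check of the combination statistic itself
        chi2 = -2 * k * np.log(p0)
        assert np.isclose(stats.chi2.sf(chi2, 2 * k),
                          stats.combine_pvalues([p0] * k, method="fisher")[1])


class TestConcordance:
    def test_requires_four_pairs(self):
        sigs = {
            ("ct1", "IC1"): ICSignature("ct1", "IC1", frozenset({"A"}), frozenset({"B"})),
            ("ct2", "IC1"): ICSignature("ct2", "IC1", frozenset({"C"}), frozenset({"D"})),
        }
        db = LRDatabase(pairs=frozenset({("A", "C")}))
        csin = screen.CSIN([], pd.DataFrame())
        with pytest.raises(ValueError):
            crosstalk.celltype_lr_concordance(csin, sigs, db)

    def test_planted_monotone_density_high_rho(self):
        rng = np.random.default_rng(0)
        cts = [f"ct{i}" for i in range(5)]
        gene_pool = {ct: [f"{ct}_g{j}" for j in range(30)] for ct in cts}
        sigs = {}
        for ct in cts:
            sigs[(ct, "IC1")] = ICSignature(
                ct, "IC1", frozenset(gene_pool[ct][:15]), frozenset(gene_pool[ct][15:])
            )
        # LR density and edge count both increase along the pair list
        pair_list = list(itertools.combinations(cts, 2))
        pairs = set()
        records = []
        for rank, (ca, cb) in enumerate(pair_list):
            for j in range(rank + 1):
                pairs.add((gene_pool[ca][j], gene_pool[cb][j]))
            for j in range(rank):
                records.append(
                    screen.CSIRecord(ca, "IC1", cb, "IC1", "bin9", 0.5, 1.6, 0.01)
                )
        db = LRDatabase(pairs=frozenset(pairs))
        csin = screen.CSIN(records, pd.DataFrame())
        rho, p, table = crosstalk.celltype_lr_concordance(
            csin, sigs, db, cell_types=cts
        )
        assert rho > 0.8
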