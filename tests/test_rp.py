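"""Regulatory-potential fitting and in-silico deletion oracles."""

import numpy as np
import pandas as pd
import pytest

import bifurcgrn as bg
from bifurcgrn import pipeline, rp
from bifurcgrn.types import RPModel


def _toy_peaks():
    return pd.DataFrame(
        {
            "chrom": ["chr1"] * 5,
            "start": [900, 5_000, 40_000, 149_000, 210_000],
            "end": [1_100, 5_400, 40_400, 149_400, 210_400],
            "name": [f"p{i}" for i in range(5)],
        }
    )


def _toy_tss():
    return pd.DataFrame(
        {
            "chrom": ["chr1", "chr1"],
            "tss": [1_000, 200_000],
            "strand": ["+", "-"],
            "name": ["gA", "gB"],
        }
    )


class TestPeakGeneLinking:
    def test_matches_brute_force_all_pairs(self):
        peaks, tss = _toy_peaks(), _toy_tss()
        window = 100_000
        index = rp.link_peaks_to_genes(peaks, tss, window=window)
        # brute force over every (gene, peak) pair
        expected = {}
        for _, g in tss.iterrows():
            entries = []
            for _, p in peaks.iterrows():
                if p["start"] <= g["tss"] < p["end"]:
                    d = 0
                elif g["tss"] < p["start"]:
                    d = p["start"] - g["tss"]
                else:
                    d = p["end"] - 1 - g["tss"]
                if abs(d) <= window:
                    ds = d if g["strand"] == "+" else -d
                    entries.append((p["name"], ds, "upstream" if ds < 0 else "downstream"))
            expected[g["name"]] = entries
        assert index.links == expected

    def test_spanning_peak_gets_distance_zero_weight_one(self):
        index = rp.link_peaks_to_genes(_toy_peaks(), _toy_tss(), window=100_000)
        entry = [e for e in index.peaks_for("gA") if e[0] == "p0"]
        assert entry == [("p0", 0, "downstream")]

    def test_beyond_window_excluded(self):
        index = rp.link_peaks_to_genes(_toy_peaks(), _toy_tss(), window=100_000)
        assert "p3" not in [e[0] for e in index.peaks_for("gA")]  # edge at 148 kb

    def test_minus_strand_side_orientation(self):
        index = rp.link_peaks_to_genes(_toy_peaks(), _toy_tss(), window=100_000)
        # gB is minus strand at 200 kb; p4 (210 kb, genomic right) is upstream
        d = dict((n, (dd, s)) for n, dd, s in index.peaks_for("gB"))
        assert d["p4"] == (-10_000, "upstream")
        assert d["p3"][1] == "downstream"

    def test_unknown_chromosome_warns_and_excludes(self, caplog):
        tss = pd.concat(
            [_toy_tss(), pd.DataFrame({"chrom": ["chrZ"], "tss": [5], "strand": ["+"], "name": ["gZ"]})],
            ignore_index=True,
        )
        with caplog.at_level("WARNING", logger="bifurcgrn.rp"):
            index = rp.link_peaks_to_genes(_toy_peaks(), tss, window=1_000)
        assert index.peaks_for("gZ") == []
        assert any("chrZ" in r.message for r in caplog.records)


class TestPoissonFit:
    def test_matches_statsmodels_glm(self, rng):
        import statsmodels.api as sm

        n = 400
        x = rng.gamma(2.0, 1.0, size=n)
        off = np.log(rng.uniform(0.5, 2.0, size=n))
        y = rng.poisson(np.exp(off + 0.3 + 0.5 * x))
        a, b, _ = rp.poisson_fit(y, x, off)
        X = sm.add_constant(x)
        fit = sm.GLM(y, X, family=sm.families.Poisson(), offset=off).fit()
        assert np.allclose([a, b], fit.params, atol=1e-6)

    def test_intercept_only_closed_form(self, rng):
        y = rng.poisson(3.0, size=200)
        off = np.zeros(200)
        a, b, _ = rp.poisson_fit(y, None, off)
        assert b == 0.0
        assert np.isclose(np.exp(a), y.mean())


class TestRPScores:
    def test_hand_computed_weighted_sum(self):
        model = RPModel(
            gene="g", l_up=1e4, l_down=1e4, peak_names=["a", "b", "c"],
            distances=np.array([0.0, 1.0, 2.0]), sides=["downstream"] * 3,
            weights=np.array([1.0, 0.5, 0.1]), alpha=0.0, beta=1.0,
            loglik=0.0, null_loglik=0.0,
        )
        acc = pd.DataFrame({"cell": [2.0, 4.0, 10.0]}, index=["a", "b", "c"])
        assert rp.rp_scores(model, acc) == pytest.approx([5.0])

    def test_zero_accessibility_and_linearity(self, rng):
        model = RPModel(
            gene="g", l_up=1e4, l_down=1e4, peak_names=["a", "b"],
            distances=np.array([10.0, 20.0]), sides=["upstream", "downstream"],
            weights=np.array([0.9, 0.8]), alpha=0.0, beta=1.0,
            loglik=0.0, null_loglik=0.0,
        )
        acc = pd.DataFrame(rng.poisson(2.0, size=(2, 30)).astype(float), index=["a", "b"])
        zero = acc * 0
        assert (rp.rp_scores(model, zero) == 0).all()
        assert np.allclose(rp.rp_scores(model, 2 * acc), 2 * rp.rp_scores(model, acc))

    def test_missing_peak_row_rejected(self):
        model = RPModel(
            gene="g", l_up=1e4, l_down=1e4, peak_names=["a", "zz"],
            distances=np.array([1.0, 2.0]), sides=["upstream", "upstream"],
            weights=np.array([1.0, 1.0]), alpha=0.0, beta=1.0,
            loglik=0.0, null_loglik=0.0,
        )
        acc = pd.DataFrame({0: [1.0]}, index=["a"])
        with pytest.raises(ValueError, match="zz"):
            rp.rp_scores(model, acc)


@pytest.fixture(scope="module")
def fitted_gene():
    """A simulated gene (no decoys) with its fitted RP model and context."""
    t = bg.generate_true_grn(8, 6, n_cre_per_gene=6, seed=22)
    # a gene with near-TSS elements on both sides, so both decay lengths
    # are informative
    def _informative(g):
        up = [abs(c.distance) for c in t.cre_table[g] if c.distance < 0]
        dn = [abs(c.distance) for c in t.cre_table[g] if c.distance > 0]
        return up and dn and min(up) < 15_000 and min(dn) < 15_000

    g = next(g for g in t.gene_names if t.cre_table[g] and _informative(g))
    t.gene_decay[g] = (10_000.0, 10_000.0)
    cfg = bg.SimulationConfig(n_decoy_peaks=0)
    ds = bg.simulate_multiome(t, n_cells=2_000, config=cfg, seed=22)
    expr, acc, lib = pipeline.frames(ds)
    index = rp.link_peaks_to_genes(
        ds.peaks, ds.genes[["chrom", "tss", "strand", "name"]], window=100_000
    )
    model = rp.fit_rp_model(g, index, acc, expr.loc[g].to_numpy(), lib)
    return t, ds, g, model, index, expr, acc, lib


class TestFitRPModel:
    def test_weight_invariants(self, fitted_gene):
        _, _, _, model, _, _, _, _ = fitted_gene
        assert model.loglik >= model.null_loglik
        for side in ("upstream", "downstream"):
            sel = np.array(model.sides) == side
            if sel.sum() > 1:
                order = np.argsort(np.abs(model.distances[sel]))
                assert (np.diff(model.weights[sel][order]) <= 1e-12).all()
        assert (model.weights > 0).all() and (model.weights <= 1.0).all()

    def test_planted_decay_recovered_within_one_grid_step(self, fitted_gene):
        _, _, _, model, _, _, _, _ = fitted_gene
        grid = rp.default_decay_grid()
        step = np.log(grid[1] / grid[0])
        assert abs(np.log(model.l_up / 1e4)) <= step + 1e-9
        assert abs(np.log(model.l_down / 1e4)) <= step + 1e-9

    def test_fit_equals_exhaustive_grid_oracle(self, fitted_gene):
        _, ds, g, model, index, expr, acc, lib = fitted_gene
        entries = index.peaks_for(g)
        names = [e[0] for e in entries]
        dist = np.array([e[1] for e in entries], dtype=float)
        sides = np.array([e[2] for e in entries])
        A = acc.loc[names].to_numpy(float)
        y = expr.loc[g].to_numpy()
        off = np.log(lib)
        best = None
        grid = rp.default_decay_grid()
        for lu in grid:
            for ld in grid:
                w = np.exp(-np.abs(dist) / np.where(sides == "upstream", lu, ld))
                _, _, ll = rp.poisson_fit(y, w @ A, off)
                if best is None or (ll, lu, ld) > best:
                    best = (ll, lu, ld)
        assert model.l_up == pytest.approx(best[1])
        assert model.l_down == pytest.approx(best[2])
        assert model.loglik == pytest.approx(best[0], abs=1e-6)

    def test_positive_planted_link(self, rng):
        # single peak; expression tracks accessibility five-fold
        acc = pd.DataFrame(rng.poisson(2.0, size=(1, 300)).astype(float), index=["p"])
        expr = np.round(5 * acc.loc["p"].to_numpy()) + rng.poisson(0.5, 300)
        index = rp.PeakGeneIndex(links={"g": [("p", 1_000, "downstream")]}, window=1e5)
        m = rp.fit_rp_model("g", index, acc, expr, np.ones(300))
        assert m.beta > 0
        assert m.loglik > m.null_loglik

    def test_independent_expression_gives_small_likelihood_ratio(self, rng):
        acc = pd.DataFrame(rng.poisson(2.0, size=(1, 500)).astype(float), index=["p"])
        expr = rng.poisson(3.0, size=500)
        index = rp.PeakGeneIndex(links={"g": [("p", 1_000, "downstream")]}, window=1e5)
        m = rp.fit_rp_model("g", index, acc, expr, np.ones(500))
        lr = m.loglik - m.null_loglik
        assert 0 <= lr < 5
        assert abs(m.beta * acc.loc["p"].std()) < 0.1

    def test_all_zero_accessibility_degenerate(self):
        acc = pd.DataFrame(np.zeros((2, 50)), index=["p", "q"])
        expr = np.ones(50)
        index = rp.PeakGeneIndex(
            links={"g": [("p", 1_000, "downstream"), ("q", -2_000, "upstream")]}, window=1e5
        )
        m = rp.fit_rp_model("g", index, acc, expr, np.ones(50))
        assert m.degenerate
        assert m.beta == 0.0


class TestISD:
    def _context(self, fitted_gene):
        t, ds, g, model, index, expr, acc, lib = fitted_gene
        y = expr.loc[g].to_numpy()
        return t, ds, g, model, y, acc, lib

    def test_disjoint_binding_scores_zero(self, fitted_gene):
        t, ds, g, model, y, acc, lib = self._context(fitted_gene)
        far = pd.DataFrame({"chrom": ["chr9"], "start": [0], "end": [100]})
        assert rp.isd_score(model, acc, y, lib, far, ds.peaks) == 0.0

    def test_full_deletion_equals_intercept_only_refit(self, fitted_gene):
        t, ds, g, model, y, acc, lib = self._context(fitted_gene)
        # binding set covering every model peak
        cover = ds.peaks[ds.peaks["name"].isin(model.peak_names)][["chrom", "start", "end"]]
        score = rp.isd_score(model, acc, y, lib, cover, ds.peaks)
        _, _, ll0 = rp.poisson_fit(y, None, np.log(lib))
        assert score == pytest.approx(model.loglik - ll0, abs=1e-8)

    def test_cell_permutation_invariance(self, fitted_gene):
        t, ds, g, model, y, acc, lib = self._context(fitted_gene)
        sets = pipeline.truth_binding_sets(t, ds)
        tf = next(iter(sets))
        s1 = rp.isd_score(model, acc, y, lib, sets[tf][0], ds.peaks)
        perm = np.random.default_rng(1).permutation(acc.shape[1])
        s2 = rp.isd_score(
            model, acc.iloc[:, perm], y[perm], lib[perm], sets[tf][0], ds.peaks
        )
        assert s1 == pytest.approx(s2, rel=1e-9)

    def test_driver_outscores_bystander(self):
        wins = 0
        n_seeds = 10
        for seed in range(n_seeds):
            t = bg.generate_true_grn(8, 8, seed=40 + seed)
            cfg = bg.SimulationConfig(n_decoy_peaks=0)
            ds = bg.simulate_multiome(t, n_cells=800, config=cfg, seed=140 + seed)
            expr, acc, lib = pipeline.frames(ds)
            g = next(
                g for g in t.gene_names
                if t.cre_table[g] and t.gene_role[g] == "PB_program"
            )
            # driver = strongest planted regulator under the true decay
            lu, ld = t.gene_decay[g]
            influence: dict[str, float] = {}
            for c in t.cre_table[g]:
                w = np.exp(-abs(c.distance) / (lu if c.distance < 0 else ld))
                for tf, s in c.bound_tfs.items():
                    influence[tf] = influence.get(tf, 0.0) + abs(s) * w
            bound = set(influence)
            driver = max(influence, key=influence.get)
            bystander = next(x for x in t.tf_names if x not in bound)
            index, models = pipeline.fit_rp_models(ds, genes=[g])
            sets = pipeline.truth_binding_sets(t, ds)
            y = expr.loc[g].to_numpy()
            s_driver = rp.isd_score(models[g], acc, y, lib, sets[driver][0], ds.peaks)
            s_by = (
                rp.isd_score(models[g], acc, y, lib, sets[bystander][0], ds.peaks)
                if bystander in sets else 0.0
            )
            wins += int(s_driver > s_by)
        assert wins >= int(0.9 * n_seeds)

    def test_matrix_matches_brute_force_and_max_rule(self, fitted_gene):
        t, ds, g, model, y, acc, lib = self._context(fitted_gene)
        expr_df = pd.DataFrame([y], index=[g])
        sets = pipeline.truth_binding_sets(t, ds)
        tfs = list(sets)[:3]
        far = pd.DataFrame({"chrom": ["chr9"], "start": [0], "end": [100]})
        binding = {tf: [far, sets[tf][0]] for tf in tfs}
        mat = rp.isd_matrix({g: model}, binding, acc, expr_df, lib, ds.peaks)
        for tf in tfs:
            expected = max(
                rp.isd_score(model, acc, y, lib, b, ds.peaks) for b in binding[tf]
            )
            assert mat.scores.at[tf, g] == pytest.approx(expected)
            if expected > 0:
                assert mat.provenance.at[tf, g] == "set1"

    def test_empty_binding_map_rejected(self, fitted_gene):
        t, ds, g, model, y, acc, lib = self._context(fitted_gene)
        with pytest.raises(ValueError):
            rp.isd_matrix({g: model}, {}, acc, pd.DataFrame([y], index=[g]), lib, ds.peaks)
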