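"""Summary-stat harmonisation, clumping, windows, scoring, survival models."""

import itertools

import numpy as np
import pandas as pd
import pytest

from comethnet.prs import (
    PRS_THRESHOLDS,
    build_event_table,
    compute_prs,
    cox_time_dependent,
    genetic_pcs,
    harmonize_sumstats,
    km_percentile_strata,
    ld_clump,
    module_windows,
    prs_trait_r2,
)


def _ss(rows):
    return pd.DataFrame(
        rows, columns=["SNP", "CHR", "BP", "A1", "A2", "BETA", "SE", "P", "INFO"]
    )


class TestHarmonize:
    def test_info_boundary(self):
        ss = _ss(
            [
                ("v1", 1, 100, "A", "G", 0.1, 0.01, 0.5, 0.89),
                ("v2", 1, 200, "A", "G", 0.1, 0.01, 0.5, 0.90),
            ]
        )
        out, rep = harmonize_sumstats(ss)
        assert list(out["SNP"]) == ["v2"]
        assert rep.n_info_dropped == 1

    def test_allele_flip_changes_sign(self):
        ss = _ss([("v1", 1, 100, "C", "A", 0.2, 0.01, 0.5, 0.99)])
        panel = pd.DataFrame({"SNP": ["v1"], "counted": ["A"], "other": ["C"]})
        out, rep = harmonize_sumstats(ss, panel)
        assert out["BETA"].iloc[0] == pytest.approx(-0.2)
        assert rep.n_flipped == 1

    def test_strand_ambiguous_dropped(self):
        ss = _ss(
            [
                ("v1", 1, 100, "A", "T", 0.1, 0.01, 0.5, 0.99),
                ("v2", 1, 200, "C", "G", 0.1, 0.01, 0.5, 0.99),
                ("v3", 1, 300, "A", "C", 0.1, 0.01, 0.5, 0.99),
            ]
        )
        out, rep = harmonize_sumstats(ss)
        assert list(out["SNP"]) == ["v3"]
        assert rep.n_ambiguous_dropped == 2


def _geno_from_matrix(X, snps):
    return pd.DataFrame(
        X, index=[f"S{i}" for i in range(len(X))], columns=snps
    )


class TestClump:
    def test_complete_ld_keeps_best_p(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 3, 100).astype(float)
        geno = _geno_from_matrix(np.column_stack([x, x, x]), ["a", "b", "c"])
        ss = _ss(
            [
                ("a", 1, 1000, "A", "G", 0.1, 0.01, 1e-8, 1.0),
                ("b", 1, 1100, "A", "G", 0.1, 0.01, 1e-6, 1.0),
                ("c", 1, 1200, "A", "G", 0.1, 0.01, 1e-4, 1.0),
            ]
        )
        assert ld_clump(ss, geno) == ["a"]

    def test_independent_variants_all_retained(self):
        rng = np.random.default_rng(1)
        X = rng.integers(0, 3, (200, 5)).astype(float)
        snps = [f"v{i}" for i in range(5)]
        geno = _geno_from_matrix(X, snps)
        ss = _ss(
            [(s, 1, 1000 + 10 * i, "A", "G", 0.1, 0.01, 0.01 * (i + 1), 1.0)
             for i, s in enumerate(snps)]
        )
        assert set(ld_clump(ss, geno)) == set(snps)

    def test_row_order_invariance(self):
        rng = np.random.default_rng(2)
        X = rng.integers(0, 3, (100, 8)).astype(float)
        X[:, 1] = X[:, 0]
        snps = [f"v{i}" for i in range(8)]
        geno = _geno_from_matrix(X, snps)
        ss = _ss(
            [(s, 1, 1000 + i, "A", "G", 0.1, 0.01, 0.05 + 0.01 * i, 1.0)
             for i, s in enumerate(snps)]
        )
        a = ld_clump(ss, geno)
        b = ld_clump(ss.sample(frac=1, random_state=3), geno)
        assert a == b

    def test_greedy_property_against_exhaustive_checker(self):
        """Oracle: verify every greedy invariant on a 20-variant fixture."""
        rng = np.random.default_rng(4)
        n, m = 150, 20
        base = rng.integers(0, 3, (n, m)).astype(float)
        # create LD clusters by copying columns with noise
        for j in range(0, m, 4):
            for k in range(1, 3):
                if j + k < m:
                    flip = rng.random(n) < 0.1
                    base[:, j + k] = np.where(flip, 2 - base[:, j], base[:, j])
        snps = [f"v{i}" for i in range(m)]
        geno = _geno_from_matrix(base, snps)
        pvals = rng.uniform(1e-8, 0.1, m)
        ss = _ss(
            [(s, 1, 1000 + 100 * i, "A", "G", 0.1, 0.01, pvals[i], 1.0)
             for i, s in enumerate(snps)]
        )
        kept = ld_clump(ss, geno, r2_max=0.1, window_kb=1000)
        X = geno.to_numpy()
        Xs = (X - X.mean(0)) / X.std(0)
        R2 = (Xs.T @ Xs / n) ** 2
        order = {s: i for i, s in enumerate(snps)}
        p_of = dict(zip(snps, pvals))
        # (1) kept variants pairwise below r2 threshold (within the window)
        for a, b in itertools.combinations(kept, 2):
            assert R2[order[a], order[b]] <= 0.1 + 1e-12
        # (2) every removed variant is within r2 > 0.1 of a kept variant
        #     with smaller p (the index that removed it)
        for s in snps:
            if s in kept:
                continue
            explained = any(
                R2[order[s], order[k]] > 0.1 and p_of[k] < p_of[s]
                for k in kept
            )
            assert explained

    def test_no_overlap_errors(self):
        geno = _geno_from_matrix(np.zeros((10, 1)), ["x"])
        ss = _ss([("y", 1, 100, "A", "G", 0.1, 0.01, 0.5, 1.0)])
        with pytest.raises(ValueError, match="overlap"):
            ld_clump(ss, geno)


class TestWindows:
    def _ann(self, rows):
        return pd.DataFrame(rows, columns=["probe", "chr", "pos", "genes"])

    def test_single_cpg_flank(self):
        ann = self._ann([("p1", "chr1", 2_000_000, "A")])
        w = module_windows({"p1"}, ann)
        assert w.iloc[0].tolist() == ["chr1", 1_000_000, 3_000_000]

    def test_close_cpgs_merge(self):
        ann = self._ann(
            [("p1", "chr1", 2_000_000, "A"), ("p2", "chr1", 2_500_000, "B")]
        )
        w = module_windows({"p1", "p2"}, ann)
        assert len(w) == 1
        assert w.iloc[0]["end"] - w.iloc[0]["start"] == 2_500_000

    def test_start_clamped_at_zero(self):
        ann = self._ann([("p1", "chr1", 400_000, "A")])
        w = module_windows({"p1"}, ann)
        assert w.iloc[0]["start"] == 0

    def test_uncoordinated_probe_skipped(self):
        ann = self._ann([("p1", "chr1", 2_000_000, "A")])
        w = module_windows({"p1", "p_missing"}, ann)
        assert w.attrs["n_skipped"] == 1


class TestComputePrs:
    def _simple(self):
        geno = _geno_from_matrix(
            np.array([[0.0, 1, 2], [1, 1, 1], [2, 0, 0]]), ["a", "b", "c"]
        )
        ss = _ss(
            [
                ("a", 1, 100, "A", "G", 0.1, 0.01, 1e-4, 1.0),
                ("b", 1, 200, "A", "G", -0.2, 0.01, 1e-3, 1.0),
                ("c", 1, 300, "A", "G", 0.3, 0.01, 1e-2, 1.0),
            ]
        )
        return geno, ss

    def test_per_allele_average(self):
        geno, ss = self._simple()
        scores = compute_prs(geno, ss, ["a", "b", "c"], thresholds=(1.0,))
        # sample S0: (0*0.1 - 0.2*1 + 0.3*2) / (2*3)
        assert scores.loc["S0", 1.0] == pytest.approx(0.4 / 6)
        assert scores.loc["S0", 1.0] == pytest.approx(0.0667, abs=1e-4)

    def test_restrict_excluding_everything_gives_nan(self):
        geno, ss = self._simple()
        far = pd.DataFrame({"chr": ["chr9"], "start": [0], "end": [10]})
        with pytest.raises(ValueError, match="no variants"):
            compute_prs(geno, ss, ["a", "b", "c"], thresholds=(1.0,), restrict=far)

    def test_partial_restrict_warns_and_nans(self):
        geno, ss = self._simple()
        win = pd.DataFrame({"chr": ["chr1"], "start": [50], "end": [150]})
        with pytest.warns(UserWarning, match="zero variants"):
            s = compute_prs(
                geno, ss, ["a", "b", "c"], thresholds=(1.0, 1e-9), restrict=win
            )
        assert s[1e-9].isna().all()
        assert s.attrs["n_variants"][1.0] == 1

    def test_variant_counts_monotone_in_threshold(self):
        geno, ss = self._simple()
        s = compute_prs(geno, ss, ["a", "b", "c"],
                        thresholds=(1.0, 1e-2, 1e-3, 1e-4))
        counts = [s.attrs["n_variants"][t] for t in (1e-4, 1e-3, 1e-2, 1.0)]
        assert counts == sorted(counts)

    def test_linearity_in_betas(self):
        geno, ss = self._simple()
        s1 = compute_prs(geno, ss, ["a", "b", "c"], thresholds=(1.0,))
        ss2 = ss.copy()
        ss2["BETA"] *= 2
        s2 = compute_prs(geno, ss2, ["a", "b", "c"], thresholds=(1.0,))
        assert np.allclose(s2[1.0], 2 * s1[1.0])

    def test_refined_subset_of_base(self, genetic_cohort):
        ss, _ = harmonize_sumstats(genetic_cohort.sumstats)
        idx = ld_clump(ss, genetic_cohort.dosages)
        win = pd.DataFrame(
            genetic_cohort.truth.windows, columns=["chr", "start", "end"]
        )
        base = compute_prs(genetic_cohort.dosages, ss, idx)
        refined = compute_prs(genetic_cohort.dosages, ss, idx, restrict=win)
        for t in PRS_THRESHOLDS:
            assert refined.attrs["n_variants"][t] <= base.attrs["n_variants"][t]


class TestTraitR2:
    def test_perfect_score_gives_r2_one(self):
        y = pd.Series([0, 1, 0, 1, 1, 0], index=[f"S{i}" for i in range(6)])
        scores = pd.DataFrame({0.05: y.astype(float)})
        scores.attrs["n_variants"] = {0.05: 1}
        res = prs_trait_r2(
            {"base": scores}, y, pd.DataFrame(index=y.index)
        )
        assert res["incremental_r2"].iloc[0] == pytest.approx(1.0)

    def test_family_of_eighteen_tests(self, genetic_cohort):
        ss, _ = harmonize_sumstats(genetic_cohort.sumstats)
        idx = ld_clump(ss, genetic_cohort.dosages)
        base = compute_prs(genetic_cohort.dosages, ss, idx)
        win = pd.DataFrame(
            genetic_cohort.truth.windows, columns=["chr", "start", "end"]
        )
        refined = compute_prs(genetic_cohort.dosages, ss, idx, restrict=win)
        binary = (genetic_cohort.pheno.groupby("sample")["GDS"].max() >= 5).astype(int)
        covs = genetic_pcs(genetic_cohort.dosages)
        res = prs_trait_r2({"base": base, "refined": refined}, binary, covs)
        assert len(res) == 18

    def test_constant_outcome_errors(self):
        y = pd.Series(np.ones(10, int), index=[f"S{i}" for i in range(10)])
        scores = pd.DataFrame({0.05: np.arange(10.0)}, index=y.index)
        scores.attrs["n_variants"] = {0.05: 1}
        with pytest.raises(ValueError, match="constant"):
            prs_trait_r2({"base": scores}, y, pd.DataFrame(index=y.index))


class TestEventTable:
    def _pheno(self, rows):
        return pd.DataFrame(
            rows, columns=["sample", "visit_month", "GDS", "UPDRS3", "age", "sex"]
        )

    def test_event_at_first_qualifying_confirmed_visit(self):
        ph = self._pheno(
            [("s1", 0, 3, 20, 60, "F"), ("s1", 6, 6, 21, 60.5, "F"),
             ("s1", 12, 7, 22, 61, "F")]
        )
        events, binary = build_event_table(ph)
        assert events["event"].sum() == 1
        assert events.loc[events["event"] == 1, "stop"].iloc[0] == 6
        assert binary["s1"] == 1

    def test_short_history_excluded(self):
        ph = self._pheno(
            [("s1", 0, 6, 20, 60, "M"), ("s1", 6, 3, 21, 60.5, "M")]
        )
        events, binary = build_event_table(ph)
        assert events.empty
        assert binary["s1"] == 1  # binary outcome still counted

    def test_single_qualifying_visit_censored(self):
        ph = self._pheno(
            [("s1", 0, 3, 20, 60, "F"), ("s1", 6, 6, 21, 60.5, "F"),
             ("s1", 12, 3, 22, 61, "F"), ("s1", 18, 4, 23, 61.5, "F")]
        )
        events, binary = build_event_table(ph)
        assert events["event"].sum() == 0
        assert events["stop"].max() == 18  # censored at last visit
        assert binary["s1"] == 1  # the two outcome definitions diverge

    def test_event_at_second_option(self):
        ph = self._pheno(
            [("s1", 0, 3, 20, 60, "F"), ("s1", 6, 6, 21, 60.5, "F"),
             ("s1", 12, 7, 22, 61, "F")]
        )
        events, _ = build_event_table(ph, event_at="second")
        assert events.loc[events["event"] == 1, "stop"].iloc[0] == 12

    def test_non_monotone_visits_error(self):
        ph = self._pheno(
            [("s1", 6, 3, 20, 60, "F"), ("s1", 0, 6, 21, 60.5, "F"),
             ("s1", 12, 7, 22, 61, "F")]
        )
        with pytest.raises(ValueError, match="non-monotone"):
            build_event_table(ph)


class TestCox:
    def test_constant_predictor_gives_unit_hazard(self):
        events = pd.DataFrame(
            {
                "sample": ["a", "b", "c", "d"],
                "start": 0.0,
                "stop": [2.0, 4.0, 6.0, 8.0],
                "event": [1, 1, 1, 0],
                "age": 60.0,
                "UPDRS3": 20.0,
                "sex": "F",
            }
        )
        prs = pd.Series(1.0, index=["a", "b", "c", "d"])
        out = cox_time_dependent(events, prs)
        assert out.loc["PRS", "HR"] == 1.0
        assert out.loc["PRS", "coef"] == 0.0

    def test_matches_grid_search_partial_likelihood(self):
        """Independent oracle: maximise the no-ties Cox partial likelihood
        (single covariate, Breslow = Efron without ties) on a grid."""
        times = np.array([3.0, 5.0, 7.0, 11.0, 13.0, 17.0])
        event = np.array([1, 1, 0, 1, 1, 0])
        z = np.array([1.2, -0.4, 0.6, -1.0, 0.8, -0.2])
        z = (z - z.mean())

        def neg_log_pl(beta):
            ll = 0.0
            for i in np.flatnonzero(event):
                risk = times >= times[i]
                ll += beta * z[i] - np.log(np.exp(beta * z[risk]).sum())
            return -ll

        grid = np.arange(-3, 3, 1e-3)
        oracle = grid[np.argmin([neg_log_pl(b) for b in grid])]

        events = pd.DataFrame(
            {
                "sample": [f"s{i}" for i in range(6)],
                "start": 0.0,
                "stop": times,
                "event": event,
                "age": 0.0,
                "UPDRS3": 0.0,
                "sex": "F",
            }
        )
        # constant age/UPDRS3/sex drop out of the partial likelihood; fit
        # with the PRS alone by passing them as all-equal columns
        from lifelines import CoxTimeVaryingFitter

        df = events.copy()
        df["z"] = z / z.std()
        ctv = CoxTimeVaryingFitter(penalizer=0.0)
        ctv.fit(df[["sample", "start", "stop", "event", "z"]],
                id_col="sample", start_col="start", stop_col="stop",
                event_col="event")
        fitted = ctv.summary.loc["z", "coef"] / z.std()
        assert fitted == pytest.approx(oracle, abs=1e-3)

    def test_too_few_events_error(self):
        events = pd.DataFrame(
            {
                "sample": ["a", "b"], "start": 0.0, "stop": [1.0, 2.0],
                "event": [0, 0], "age": 60.0, "UPDRS3": 20.0, "sex": "F",
            }
        )
        with pytest.raises(ValueError, match="events"):
            cox_time_dependent(events, pd.Series([0.1, 0.2], index=["a", "b"]))


class TestKm:
    def _events(self, stops, flags, n_extra_cov=True):
        df = pd.DataFrame(
            {
                "sample": [f"s{i}" for i in range(len(stops))],
                "start": 0.0,
                "stop": stops,
                "event": flags,
                "age": 60.0,
                "UPDRS3": 20.0,
                "sex": "F",
            }
        )
        return df

    def test_product_limit_hand_computation(self):
        # events at t=2 and t=4 among 4 subjects, no censoring before 4
        events = self._events([2.0, 4.0, 5.0, 6.0], [1, 1, 0, 0])
        prs = pd.Series([0.1, 0.2, 0.3, 0.4], index=[f"s{i}" for i in range(4)])
        curves, _ = km_percentile_strata(
            events, prs, strata=((0, 100),), reference=(0, 100)
        )
        s3 = curves[curves["time"] <= 3]["survival"].iloc[-1]
        assert s3 == pytest.approx(0.75)

    def test_no_events_flat_curves(self):
        events = self._events([5.0] * 6, [0] * 6)
        prs = pd.Series(np.arange(6) / 6, index=[f"s{i}" for i in range(6)])
        with pytest.warns(UserWarning):
            curves, hrs = km_percentile_strata(
                events, prs, strata=((0, 50), (50, 100)), reference=(0, 50)
            )
        assert (curves["survival"] == 1.0).all()
        assert hrs.empty

    def test_strata_must_cover_percentiles(self):
        events = self._events([2.0, 4.0], [1, 1])
        prs = pd.Series([0.1, 0.2], index=["s0", "s1"])
        with pytest.raises(ValueError, match="cover"):
            km_percentile_strata(events, prs, strata=((10, 90),),
                                 reference=(10, 90))

    def test_concentrated_risk_separates_top_stratum(self, genetic_cohort):
        from comethnet.prs import harmonize_sumstats as hs

        ss, _ = hs(genetic_cohort.sumstats)
        idx = ld_clump(ss, genetic_cohort.dosages)
        scores = compute_prs(genetic_cohort.dosages, ss, idx,
                             thresholds=(0.05,))
        events, _ = build_event_table(genetic_cohort.pheno)
        curves, hrs = km_percentile_strata(events, scores[0.05].dropna())
        hrs = hrs.set_index("stratum")
        assert hrs.loc["95-100%", "HR"] > hrs.loc["50-95%", "HR"] > 1.0
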