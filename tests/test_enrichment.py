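"""Gene mapping, bias-corrected ontology test, specificity and EWCE."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from comethnet.enrichment import (
    GeneSet,
    ewce_bootstrap,
    ewce_conditional,
    go_bias_corrected_test,
    map_probes_to_genes,
    specificity_from_expression,
)
from comethnet.simulate import SimConfig, simulate_cell_reference


class TestProbeGeneMapping:
    def test_multi_gene_annotation_split(self):
        ann = pd.DataFrame(
            {"probe": ["p1"], "chr": ["chr1"], "pos": [100],
             "genes": ["TP53;WRAP53"]}
        )
        target, bg, counts = map_probes_to_genes({"p1"}, ann, {"p1"})
        assert target.genes == frozenset({"TP53", "WRAP53"})

    def test_empty_probe_set(self):
        ann = pd.DataFrame(
            {"probe": ["p1"], "chr": ["chr1"], "pos": [100], "genes": ["A"]}
        )
        target, bg, _ = map_probes_to_genes(set(), ann, {"p1"})
        assert len(target) == 0 and bg.genes == frozenset({"A"})

    def test_probes_per_gene_counting(self):
        ann = pd.DataFrame(
            {"probe": [f"p{i}" for i in range(10)], "chr": "chr1",
             "pos": range(10), "genes": ["GENEA"] * 10}
        )
        _, _, counts = map_probes_to_genes(
            set(ann["probe"]), ann, set(ann["probe"])
        )
        assert counts["GENEA"] == 10

    def test_target_outside_background_errors(self):
        ann = pd.DataFrame(
            {"probe": ["p1"], "chr": ["chr1"], "pos": [1], "genes": ["A"]}
        )
        with pytest.raises(ValueError):
            map_probes_to_genes({"p2"}, ann, {"p1"})


def _one_gene_per_probe_annotation(n):
    return pd.DataFrame(
        {"probe": [f"p{i}" for i in range(n)], "chr": "chr1",
         "pos": range(n), "genes": [f"G{i}" for i in range(n)]}
    )


class TestGoBiasCorrection:
    def test_unbiased_limit_matches_hypergeometric(self):
        # one probe per gene: resampling probes = resampling genes uniformly
        n, term_size, target_size = 60, 15, 12
        ann = _one_gene_per_probe_annotation(n)
        term = pd.DataFrame(
            {"term": "T1", "gene": [f"G{i}" for i in range(term_size)]}
        )
        target = {f"p{i}" for i in range(0, 3 * target_size, 3)}
        res = go_bias_corrected_test(
            target, set(ann["probe"]), ann, term, reps=20_000, seed=0
        )
        obs = res.loc[res["term"] == "T1", "n_target_genes"].iloc[0]
        exact = sps.hypergeom.sf(obs - 1, n, term_size, target_size)
        assert abs(res["p"].iloc[0] - exact) < 0.02

    def test_term_covering_background_gives_p_one(self):
        ann = _one_gene_per_probe_annotation(30)
        term = pd.DataFrame(
            {"term": "ALL", "gene": [f"G{i}" for i in range(30)]}
        )
        res = go_bias_corrected_test(
            {f"p{i}" for i in range(5)}, set(ann["probe"]), ann, term,
            reps=500, seed=1,
        )
        assert res["p"].iloc[0] == pytest.approx(1.0)

    def test_probe_count_bias_is_corrected(self):
        # term genes carry 10 probes each; everything else 1 probe.
        # a probe-sampled target hits the term often, so the corrected p is
        # far larger than a naive gene-level hypergeometric claims.
        term_genes = [f"T{i}" for i in range(5)]
        other_genes = [f"O{i}" for i in range(50)]
        rows = []
        k = 0
        for g in term_genes:
            for _ in range(10):
                rows.append((f"p{k}", g))
                k += 1
        for g in other_genes:
            rows.append((f"p{k}", g))
            k += 1
        ann = pd.DataFrame(rows, columns=["probe", "genes"])
        ann["chr"], ann["pos"] = "chr1", range(len(ann))
        rng = np.random.default_rng(5)
        target = set(rng.choice(ann["probe"], 20, replace=False))
        term = pd.DataFrame({"term": "T", "gene": term_genes})
        res = go_bias_corrected_test(
            target, set(ann["probe"]), ann, term, reps=2000, seed=2
        )
        obs = res["n_target_genes"].iloc[0]
        n_genes = len(term_genes) + len(other_genes)
        target_genes = len(
            map_probes_to_genes(target, ann, set(ann["probe"]))[0]
        )
        naive = sps.hypergeom.sf(obs - 1, n_genes, len(term_genes), target_genes)
        assert res["p"].iloc[0] > 5 * naive


class TestSpecificity:
    def test_exclusive_gene_gets_specificity_one(self):
        counts = pd.DataFrame(
            {"c1": [5, 1], "c2": [7, 1], "c3": [0, 1], "c4": [0, 1]},
            index=["gA", "gB"],
        )
        cells = pd.DataFrame(
            {"cell": ["c1", "c2", "c3", "c4"],
             "subtype": ["A", "A", "B", "B"],
             "cell_class": ["A", "A", "B", "B"]}
        )
        spec = specificity_from_expression(counts, cells, fdr_cut=1.01)
        assert spec.loc["gA", "A"] == pytest.approx(1.0)

    def test_flat_gene_dropped_by_de_filter(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(
            rng.poisson(5, size=(20, 40)), index=[f"g{i}" for i in range(20)],
            columns=[f"c{i}" for i in range(40)],
        )
        counts.iloc[0] = 0  # zero-expression gene
        cells = pd.DataFrame(
            {"cell": counts.columns, "subtype": ["A"] * 20 + ["B"] * 20,
             "cell_class": ["A"] * 20 + ["B"] * 20}
        )
        spec = specificity_from_expression(counts, cells, fdr_cut=1e-5)
        assert "g0" not in spec.index  # zero-total dropped
        assert spec.shape[0] < 5  # flat genes not informative

    def test_rows_sum_to_one(self, cell_reference):
        spec = specificity_from_expression(
            cell_reference.counts, cell_reference.cells
        )
        assert np.allclose(spec.sum(axis=1), 1.0, atol=1e-9)
        assert (spec.to_numpy() >= 0).all()

    def test_planted_markers_survive_filter(self):
        cfg = SimConfig(cells_per_type=200, seed=6)
        ref = simulate_cell_reference(cfg)
        spec = specificity_from_expression(ref.counts, ref.cells)
        markers = ref.truth.celltype_markers[ref.truth.enriched_celltype]
        frac = np.mean([m in spec.index for m in markers])
        assert frac >= 0.95

    def test_no_signal_gives_uniform_rows(self):
        cfg = SimConfig(
            n_genes=300, n_celltypes=3, n_markers_per_type=30,
            n_overlap_markers=20, cells_per_type=500, marker_fold=1.0,
            marker_fold_sd=0.0, celltype_mod_sd=0.0,
            module_gene_pool_size=60, seed=4,
        )
        ref = simulate_cell_reference(cfg)
        spec = specificity_from_expression(ref.counts, ref.cells, fdr_cut=1.01)
        dev = np.abs(spec.to_numpy() - 1 / 3).max()
        assert dev < 0.1

    def test_tiny_cell_type_errors(self):
        counts = pd.DataFrame({"c1": [1], "c2": [2], "c3": [3]}, index=["g"])
        cells = pd.DataFrame(
            {"cell": ["c1", "c2", "c3"], "subtype": ["A", "A", "B"],
             "cell_class": ["A", "A", "B"]}
        )
        with pytest.raises(ValueError, match="fewer than 2"):
            specificity_from_expression(counts, cells)


@pytest.fixture(scope="module")
def spec_and_truth(cell_reference):
    spec = specificity_from_expression(
        cell_reference.counts, cell_reference.cells
    )
    return spec, cell_reference.truth


class TestEwce:
    def test_whole_universe_target_is_null(self, spec_and_truth):
        spec, _ = spec_and_truth
        res = ewce_bootstrap(
            GeneSet.from_symbols(spec.index), spec, reps=1000, seed=0
        )
        # null sets are permutations of the target itself
        assert res["sd_from_mean"].abs().max() < 1e-9
        assert (res["p"] > 0.9).all()

    def test_exclusive_markers_minimal_p(self):
        # 4 exclusive markers in a 60-gene universe: no null set can reach
        # the observed mean specificity of 1 in type A
        n = 60
        a = np.zeros(n)
        a[:4] = 1.0
        spec = pd.DataFrame(
            {"A": a, "B": (1 - a) / 1.0}, index=[f"g{i}" for i in range(n)]
        )
        spec = spec.div(spec.sum(axis=1), axis=0)
        reps = 400
        res = ewce_bootstrap(
            GeneSet.from_symbols(["g0", "g1", "g2", "g3"]), spec,
            reps=reps, seed=1,
        ).set_index("celltype")
        assert res.loc["A", "p"] == pytest.approx(1 / (reps + 1))

    def test_p_lower_bound_honoured(self, spec_and_truth):
        spec, truth = spec_and_truth
        reps = 500
        res = ewce_bootstrap(
            GeneSet.from_symbols(truth.module_gene_pool), spec,
            reps=reps, seed=2,
        )
        assert (res["p"] >= 1 / (reps + 1) - 1e-12).all()
        assert (res["q"] >= res["p"] - 1e-12).all()

    def test_empty_overlap_errors(self, spec_and_truth):
        spec, _ = spec_and_truth
        with pytest.raises(ValueError, match="overlap"):
            ewce_bootstrap(GeneSet.from_symbols(["NOPE"]), spec, reps=10)

    def test_planted_type_detected(self, spec_and_truth):
        spec, truth = spec_and_truth
        res = ewce_bootstrap(
            GeneSet.from_symbols(truth.module_gene_pool), spec,
            reps=2000, seed=3,
        ).set_index("celltype")
        assert res.loc[truth.enriched_celltype, "q"] < 0.05
        assert res.drop(truth.enriched_celltype)["q"].min() >= 0.05


class TestEwceConditional:
    def test_none_controlled_equals_unconditional(self, spec_and_truth):
        spec, truth = spec_and_truth
        target = GeneSet.from_symbols(truth.module_gene_pool)
        a = ewce_bootstrap(target, spec, reps=500, seed=4)
        b = ewce_conditional(target, spec, controlled=None, reps=500, seed=4)
        pd.testing.assert_frame_equal(a, b)

    def test_controlling_tested_type_collapses_signal(self, spec_and_truth):
        spec, truth = spec_and_truth
        res = ewce_conditional(
            GeneSet.from_symbols(truth.module_gene_pool), spec,
            controlled=truth.enriched_celltype, reps=2000, seed=5,
        ).set_index("celltype")
        assert abs(res.loc[truth.enriched_celltype, "sd_from_mean"]) < 0.5
        assert res.loc[truth.enriched_celltype, "p"] == pytest.approx(1.0)

    def test_orthogonal_control_preserves_signal(self, spec_and_truth):
        spec, truth = spec_and_truth
        other = [c for c in spec.columns if c != truth.enriched_celltype][0]
        res = ewce_conditional(
            GeneSet.from_symbols(truth.module_gene_pool), spec,
            controlled=other, reps=2000, seed=6,
        ).set_index("celltype")
        assert res.loc[truth.enriched_celltype, "q"] < 0.05

    def test_collinear_types_lose_significance_when_controlled(self):
        rng = np.random.default_rng(7)
        base = rng.dirichlet(np.ones(3), size=200)
        # types A and B fully collinear: identical specificity columns
        spec = pd.DataFrame(
            np.column_stack([base[:, 0], base[:, 0], base[:, 1], base[:, 2]]),
            index=[f"g{i}" for i in range(200)],
            columns=["A", "B", "C", "D"],
        )
        spec = spec.div(spec.sum(axis=1), axis=0)
        target = GeneSet.from_symbols(spec.nlargest(30, "A").index)
        uncond = ewce_bootstrap(target, spec, reps=2000, seed=8).set_index(
            "celltype"
        )
        assert uncond.loc["B", "q"] < 0.05  # collinear type looks enriched
        cond = ewce_conditional(
            target, spec, controlled="A", reps=2000, seed=8
        ).set_index("celltype")
        assert cond.loc["B", "q"] >= 0.05  # controlling A removes it
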