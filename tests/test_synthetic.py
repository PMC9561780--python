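"""Synthetic generators: determinism, planted structure, analytic means."""

import numpy as np
import pandas as pd
import pytest

from cscc_spatial import synthetic
from cscc_spatial.de import de_test
from cscc_spatial.synthetic import (
    CellProfileSpec,
    MetabolicPlant,
    RegionLayout,
    default_universe,
    make_layout,
    simulate_cells,
    simulate_chip,
    simulate_ihc_cohort,
)


class TestDeterminism:
    def test_cells_identical_across_runs(self, universe):
        a, la = simulate_cells(universe.cell_specs, universe.genes, 20, seed=42)
        b, lb = simulate_cells(universe.cell_specs, universe.genes, 20, seed=42)
        assert a.equals(b) and la.equals(lb)

    def test_chip_identical_across_runs(self, universe):
        layout = make_layout(width=48, height=48, n_tumors=1, ringed_tumors=(), seed=5)
        s1, t1 = simulate_chip(layout, universe.cell_specs, universe.genes, seed=7)
        s2, t2 = simulate_chip(layout, universe.cell_specs, universe.genes, seed=7)
        assert (s1.counts != s2.counts).nnz == 0
        assert t1.equals(t2)

    def test_cohort_identical_across_runs(self):
        a = simulate_ihc_cohort(71, effect=1.0, seed=9)
        b = simulate_ihc_cohort(71, effect=1.0, seed=9)
        assert a == b


class TestCellSimulation:
    def test_unknown_marker_gene_named_in_error(self):
        spec = CellProfileSpec("t", 0.5, 1.0, frozenset({"MISSING_GENE"}), 4.0)
        with pytest.raises(ValueError, match="MISSING_GENE"):
            simulate_cells([spec], ["A", "B"], 5, seed=0)

    def test_marker_fold_one_gives_no_systematic_marker_difference(self):
        """fold = 1 -> both types share one distribution; rank-sum p-values
        on the marker genes behave like a uniform null across seeds."""
        genes = [f"g{i}" for i in range(40)]
        specs = [
            CellProfileSpec(t, 1.0, 2.0, frozenset(genes[:10]), marker_fold=1.0)
            for t in ("A", "B")
        ]
        pvals = []
        for seed in range(5):
            counts, labels = simulate_cells(specs, genes, 100, seed=seed)
            expr = np.log1p(counts)
            res = de_test(expr, labels.index[labels == "A"].tolist(),
                          labels.index[labels == "B"].tolist())
            pvals.extend(res[res.gene.isin(genes[:10])].p)
        assert np.mean(np.array(pvals) < 0.05) <= 0.12  # 50 draws, null rate 5%
        assert np.mean(pvals) > 0.35  # uniform null has mean ~0.5

    def test_marker_elevation_raises_only_own_type(self, universe):
        counts, labels = simulate_cells(universe.cell_specs, universe.genes, 200, seed=1)
        postn = counts["POSTN"].groupby(labels).mean()
        assert postn["mycaf"] > 4 * postn.drop("mycaf").max()

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            CellProfileSpec("t", -1.0, 1.0, frozenset(), 2.0)
        with pytest.raises(ValueError):
            CellProfileSpec("t", 1.0, 0.0, frozenset(), 2.0)
        with pytest.raises(ValueError):
            CellProfileSpec("t", 1.0, 1.0, frozenset(), 0.5)


class TestLayout:
    def test_ring_spots_only_around_ringed_tumors(self):
        layout = make_layout(width=96, height=96, n_tumors=4, ringed_tumors=(1, 2), seed=3)
        ring = layout.region_map == "mycaf_ring"
        assert ring.any()
        assert set(np.unique(layout.area_id[ring])) == {1, 2}

    def test_ring_spots_adjacent_to_their_own_tumor(self):
        layout = make_layout(width=96, height=96, n_tumors=3, ringed_tumors=(0,), ring_width=1, seed=4)
        ys, xs = np.where(layout.region_map == "mycaf_ring")
        for y, x in zip(ys, xs):
            window = layout.region_map[max(0, y - 1): y + 2, max(0, x - 1): x + 2]
            area_w = layout.area_id[max(0, y - 1): y + 2, max(0, x - 1): x + 2]
            touching = set(area_w[(window == "tumor") | (window == "mycaf_ring")])
            assert touching == {0}

    def test_no_rings_when_none_requested(self):
        layout = make_layout(width=64, height=64, n_tumors=2, ringed_tumors=(), seed=0)
        assert not (layout.region_map == "mycaf_ring").any()

    def test_composition_validation(self):
        with pytest.raises(ValueError, match="sum to 1"):
            RegionLayout(
                width=2, height=2,
                region_map=np.full((2, 2), "stroma", dtype=object),
                area_id=np.full((2, 2), -1),
                composition={"stroma": {"fibroblast": 0.5}},
                abundance_factor={"stroma": 1.0},
            )

    def test_tumor_must_outweigh_stroma_abundance(self):
        with pytest.raises(ValueError, match="abundance"):
            RegionLayout(
                width=2, height=2,
                region_map=np.full((2, 2), "stroma", dtype=object),
                area_id=np.full((2, 2), -1),
                composition={},
                abundance_factor={"tumor": 1.0, "stroma": 2.0},
            )


class TestChipSimulation:
    def test_abundance_ratio_recovered_at_scale(self):
        """With identical compositions, mean UMI ratio tumor/stroma tracks
        the abundance factors (law of large numbers over >= 1e4 spots)."""
        genes = [f"g{i}" for i in range(50)]
        spec = CellProfileSpec("only", 0.5, 2.0, frozenset(), 2.0)
        half = np.full((200, 100), "stroma", dtype=object)
        half[:100] = "tumor"
        layout = RegionLayout(
            width=100, height=200, region_map=half,
            area_id=np.where(half == "tumor", 0, -1),
            composition={"tumor": {"only": 1.0}, "stroma": {"only": 1.0}},
            abundance_factor={"tumor": 3.0, "stroma": 1.0},
        )
        spots, truth = simulate_chip(layout, [spec], genes, seed=11, spot_depth=0.2)
        umi = np.asarray(spots.counts.sum(axis=1)).ravel()
        ratio = umi[truth.region == "tumor"].mean() / umi[truth.region == "stroma"].mean()
        assert 2.5 <= ratio <= 3.5

    def test_expected_counts_match_mixture_analytically(self):
        """1-gene toy: empirical mean ~= abundance * depth * sum_t comp * mu_t."""
        specs = [
            CellProfileSpec("a", 2.0, 5.0, frozenset(), 2.0),
            CellProfileSpec("b", 6.0, 5.0, frozenset(), 2.0),
        ]
        region = np.full((100, 100), "mix", dtype=object)
        layout = RegionLayout(
            width=100, height=100, region_map=region,
            area_id=np.full((100, 100), -1),
            composition={"mix": {"a": 0.25, "b": 0.75}},
            abundance_factor={"mix": 1.5},
        )
        spots, _ = simulate_chip(layout, specs, ["g"], seed=2, spot_depth=1.0)
        expected = 1.5 * 1.0 * (0.25 * 2.0 + 0.75 * 6.0)
        got = spots.counts.toarray().mean()
        assert got == pytest.approx(expected, rel=0.03)

    def test_empty_composition_rejected(self):
        region = np.full((4, 4), "void", dtype=object)
        layout = RegionLayout(
            width=4, height=4, region_map=region, area_id=np.full((4, 4), -1),
            composition={"void": {}}, abundance_factor={},
        )
        with pytest.raises(ValueError, match="empty composition"):
            simulate_chip(layout, [CellProfileSpec("a", 1.0, 1.0, frozenset(), 2.0)], ["g"], seed=0)

    def test_hyper_areas_have_elevated_pathway_counts(self, universe):
        layout = make_layout(width=96, height=96, n_tumors=4, ringed_tumors=(), seed=6)
        plant = MetabolicPlant(frozenset({0, 1}), frozenset({2, 3}), pathway_fold=4.0)
        spots, truth = simulate_chip(
            layout, universe.cell_specs, universe.genes, plant=plant,
            pathway_signatures=universe.pathway_signatures, seed=6,
        )
        pw_idx = [i for i, g in enumerate(universe.genes)
                  if g in universe.pathway_signatures[0].genes]
        counts = spots.counts.toarray()
        tumor = truth.region.to_numpy() == "tumor"
        hyper = tumor & truth.area_id.isin([0, 1]).to_numpy()
        hypo = tumor & truth.area_id.isin([2, 3]).to_numpy()
        ratio = counts[np.ix_(hyper, pw_idx)].mean() / counts[np.ix_(hypo, pw_idx)].mean()
        assert ratio > 2.5

    def test_plant_validation(self):
        with pytest.raises(ValueError, match="overlap"):
            MetabolicPlant(frozenset({1}), frozenset({1}), 2.0)
        with pytest.raises(ValueError):
            MetabolicPlant(frozenset({1}), frozenset({2}), 1.0)


class TestIhcCohort:
    def test_high_score_probability_increases_with_stage(self):
        from cscc_spatial.ihc import composite_score

        recs = simulate_ihc_cohort(3000, effect=1.5, seed=0)
        df = pd.DataFrame(
            {
                "stage": [r.covariates["stage"] for r in recs],
                "high": [composite_score(r).high for r in recs],
            }
        )
        rates = df.groupby("stage").high.mean()
        assert rates["I"] < rates["II"] < rates["III"]

    def test_na_injection(self):
        recs = simulate_ihc_cohort(300, effect=0.0, seed=1, na_rate=0.3)
        frac_na = np.mean([r.covariates["stage"] is None for r in recs])
        assert 0.15 < frac_na < 0.45

    def test_minimum_size_enforced(self):
        with pytest.raises(ValueError):
            simulate_ihc_cohort(5, effect=0.0)


def test_universe_structure(universe):
    assert len(universe.genes) == 340
    assert len(set(universe.genes)) == 340
    assert len(universe.pathway_signatures) == 6
    assert all(len(s.genes) == 30 for s in universe.pathway_signatures)
    for ct, markers in universe.marker_sets.items():
        assert markers <= set(universe.genes)
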