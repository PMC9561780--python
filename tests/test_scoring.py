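"""Module-score and rank-based single-sample enrichment engines."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cscc_spatial.scoring import GeneSignature, module_score, read_gmt, score_matrix, ssgsea_score, write_gmt


def brute_force_ssgsea(values: dict[str, float], sig_genes: set[str], alpha: float) -> float:
    """Independent term-by-term running-sum oracle (pure python)."""
    ordered = sorted(values, key=lambda g: (-values[g], list(values).index(g)))
    n = len(ordered)
    in_weights = {}
    for pos, g in enumerate(ordered):  # rank statistic: N down to 1
        if g in sig_genes:
            in_weights[g] = (n - pos) ** alpha
    total_in = sum(in_weights.values())
    n_out = n - len(in_weights)
    score, cum_in, cum_out = 0.0, 0.0, 0.0
    for g in ordered:
        if g in sig_genes:
            cum_in += in_weights[g] / total_in
        else:
            cum_out += 1.0 / n_out
        score += cum_in - cum_out
    return score / n


class TestSsgsea:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle_on_small_toys(self, seed):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(10)]
        vec = pd.Series(rng.normal(size=10), index=genes)
        sig_genes = set(rng.choice(genes, size=3, replace=False))
        sig = GeneSignature.of("toy", sig_genes)
        expected = brute_force_ssgsea(dict(vec), sig_genes, alpha=0.25)
        assert ssgsea_score(vec, sig) == pytest.approx(expected, abs=1e-12)

    def test_rank_invariance_under_monotone_transforms(self, rng):
        genes = [f"g{i}" for i in range(40)]
        vec = pd.Series(rng.normal(size=40), index=genes)
        sig = GeneSignature.of("s", genes[:6])
        base = ssgsea_score(vec, sig)
        for transform in (np.exp, lambda v: 3 * v + 10, lambda v: v**3):
            assert ssgsea_score(pd.Series(transform(vec.to_numpy()), index=genes), sig) == base

    def test_top_ranked_signature_is_maximal_among_same_size(self, rng):
        genes = list("abcdefgh")
        vec = pd.Series(rng.permutation(8).astype(float), index=genes)
        top3 = set(vec.sort_values(ascending=False).index[:3])
        scores = {
            frozenset(c): ssgsea_score(vec, GeneSignature.of("c", c))
            for c in combinations(genes, 3)
        }
        assert max(scores, key=scores.get) == frozenset(top3)

    def test_unweighted_random_signature_null_is_centered(self, rng):
        """At alpha=0 the running-sum statistic has exact zero null mean."""
        genes = [f"g{i}" for i in range(200)]
        vec = pd.Series(rng.normal(size=200), index=genes)
        draws = np.array(
            [
                ssgsea_score(vec, GeneSignature.of("r", rng.choice(genes, 15, replace=False)), alpha=0.0)
                for _ in range(1000)
            ]
        )
        assert abs(draws.mean()) < 2 * draws.std() / np.sqrt(len(draws))

    def test_weighted_null_matches_permutation_oracle(self, rng):
        """At alpha=0.25 the null is offset; implementation must track the
        oracle's permutation mean, not zero."""
        genes = [f"g{i}" for i in range(60)]
        vec = pd.Series(rng.normal(size=60), index=genes)
        impl, oracle = [], []
        for _ in range(200):
            members = set(rng.choice(genes, 8, replace=False))
            impl.append(ssgsea_score(vec, GeneSignature.of("r", members)))
            oracle.append(brute_force_ssgsea(dict(vec), members, alpha=0.25))
        np.testing.assert_allclose(impl, oracle, atol=1e-12)

    def test_whole_universe_signature_rejected(self):
        vec = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValueError, match="out-set"):
            ssgsea_score(vec, GeneSignature.of("all", ["a", "b"]))


class TestModuleScore:
    def test_shift_invariance(self, small_expr):
        sig = GeneSignature.of("s", list(small_expr.columns[:8]))
        a = module_score(small_expr, sig, seed=7)
        b = module_score(small_expr + 3.5, sig, seed=7)
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=1e-10)

    def test_null_signature_scores_are_zero_when_bins_share_values(self, rng):
        """Signature genes identical to every bin-mate -> zero score for any
        control draw (the control mean equals the signature mean exactly)."""
        genes = [f"g{i}" for i in range(120)]
        unit_effect = rng.normal(0, 1, size=40)
        level = np.repeat(np.arange(24), 5)  # 5 identical genes per expression bin
        expr = pd.DataFrame(
            unit_effect[:, None] + level[None, :].astype(float),
            columns=genes, index=[f"u{i}" for i in range(40)],
        )
        sig = GeneSignature.of("null", rng.choice(genes, 10, replace=False))
        for seed in range(20):
            assert module_score(expr, sig, n_bins=24, seed=seed).abs().max() < 1e-10

    def test_planted_elevation_separates_units(self, rng):
        genes = [f"g{i}" for i in range(150)]
        sig_genes = genes[:10]
        base = rng.lognormal(0, 0.3, size=(400, 150))
        base[:200, :10] *= 4.0
        expr = pd.DataFrame(np.log1p(base), columns=genes, index=[f"u{i}" for i in range(400)])
        scores = module_score(expr, GeneSignature.of("planted", sig_genes), seed=0)
        p = stats.mannwhitneyu(scores[:200], scores[200:], alternative="greater").pvalue
        assert p < 0.01

    def test_missing_signature_raises_listing_genes(self, small_expr):
        with pytest.raises(ValueError, match="ZZZ"):
            module_score(small_expr, GeneSignature.of("gone", ["ZZZ1", "ZZZ2"]))

    def test_reproducible_from_seed(self, small_expr):
        sig = GeneSignature.of("s", list(small_expr.columns[5:15]))
        assert module_score(small_expr, sig, seed=3).equals(module_score(small_expr, sig, seed=3))


class TestScoreMatrix:
    def test_single_signature_registry_matches_direct_call(self, small_expr):
        sig = GeneSignature.of("one", list(small_expr.columns[:5]))
        table = score_matrix(small_expr, [sig], engine="module", seed=11)
        direct = module_score(small_expr, sig, seed=11)
        np.testing.assert_allclose(table["one"].to_numpy(), direct.to_numpy())

    def test_duplicate_names_rejected(self, small_expr):
        sig = GeneSignature.of("dup", list(small_expr.columns[:5]))
        with pytest.raises(ValueError, match="duplicate"):
            score_matrix(small_expr, [sig, sig])

    def test_empty_expression_yields_empty_scores(self):
        empty = pd.DataFrame(columns=[f"g{i}" for i in range(30)])
        out = score_matrix(empty, [GeneSignature.of("s", ["g0"])], engine="module")
        assert out.empty and list(out.columns) == ["s"]

    def test_engines_agree_on_planted_elevation_ranking(self, rng):
        genes = [f"g{i}" for i in range(120)]
        base = rng.lognormal(0, 0.3, size=(120, 120))
        lift = np.linspace(1, 4, 120)  # graded elevation across units
        base[:, :12] *= lift[:, None]
        expr = pd.DataFrame(np.log1p(base), columns=genes, index=[f"u{i}" for i in range(120)])
        reg = [GeneSignature.of("planted", genes[:12])]
        m = score_matrix(expr, reg, engine="module", seed=0)["planted"]
        s = score_matrix(expr, reg, engine="ssgsea")["planted"]
        rho = stats.spearmanr(m, s).statistic
        assert rho > 0.5

    @pytest.mark.parametrize("engine", ["module", "ssgsea"])
    def test_planted_fold_monotonicity(self, engine, rng):
        genes = [f"g{i}" for i in range(100)]
        medians = []
        for fold in (1, 2, 4, 8):
            base = rng.lognormal(0, 0.2, size=(60, 100))
            base[:30, :10] *= fold
            expr = pd.DataFrame(np.log1p(base), columns=genes)
            sc = score_matrix(expr, [GeneSignature.of("s", genes[:10])], engine=engine, seed=1)
            medians.append(sc["s"][:30].median())
        assert np.all(np.diff(medians) > -1e-6)


def test_gmt_roundtrip(tmp_path):
    sigs = [GeneSignature.of("a", ["g1", "g2"]), GeneSignature.of("b", ["g3"])]
    p = tmp_path / "sigs.gmt"
    write_gmt(sigs, p)
    back = read_gmt(p)
    assert [(s.name, s.genes) for s in back] == [(s.name, s.genes) for s in sigs]
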