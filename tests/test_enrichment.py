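"""Host permutation, WMW enrichment and pair scoring."""

import itertools
import math

import numpy as np
import pytest
import scipy.stats

from mirhost import (
    PermutationError,
    SimulationConfig,
    draw_host_permutation,
    permute_hosts,
    simulate_compendium,
    wmw_two_sided,
)
from mirhost.enrichment import (
    FitResult,
    fit_compendium,
    null_pool_from_fits,
    score_all_pairs,
    score_pair,
)
from mirhost.errors import EmptyDatasetError
from mirhost.expression import filter_genes
from mirhost.annotation import build_all_designs
from mirhost.regression import fit_ulm


def wmw_exact_oracle(sample, pool):
    """Exhaustive enumeration over all rank assignments (tie-free data)."""
    combined = np.concatenate([sample, pool])
    n, total = len(sample), len(combined)
    ranks = scipy.stats.rankdata(combined)
    u_obs = ranks[:n].sum() - n * (n + 1) / 2
    us = []
    for idx in itertools.combinations(range(total), n):
        us.append(ranks[list(idx)].sum() - n * (n + 1) / 2)
    us = np.asarray(us)
    p = 2.0 * min((us <= u_obs).mean(), (us >= u_obs).mean())
    return min(1.0, p)


class TestPermutation:
    def test_same_seed_same_permutation(self):
        hosts = [f"H{i}" for i in range(6)]
        m1 = draw_host_permutation(hosts, np.random.default_rng(42))
        m2 = draw_host_permutation(hosts, np.random.default_rng(42))
        assert m1 == m2

    def test_two_host_universe_forces_swap(self, rng):
        mapping = draw_host_permutation(["A", "B"], rng)
        assert mapping == {"A": "B", "B": "A"}

    def test_two_column_matrix_forces_swap(self, rng):
        X = np.array([[1.0, 2.0], [3.0, 4.0]])
        np.testing.assert_array_equal(permute_hosts(X, rng), X[:, [1, 0]])

    def test_single_host_universe_impossible(self, rng):
        with pytest.raises(PermutationError):
            draw_host_permutation(["A"], rng)

    def test_identity_excluded_and_draws_near_uniform(self):
        # over many seeded draws on a 5-host universe the identity never
        # appears and the non-identity permutations are hit roughly uniformly
        rng = np.random.default_rng(7)
        hosts = list("ABCDE")
        counts: dict[tuple, int] = {}
        n_draws = 1000
        for _ in range(n_draws):
            mapping = draw_host_permutation(hosts, rng)
            key = tuple(mapping[h] for h in hosts)
            counts[key] = counts.get(key, 0) + 1
        assert tuple(hosts) not in counts  # identity excluded
        n_perms = math.factorial(5) - 1  # 119 admissible permutations
        assert len(counts) > 100
        expected = n_draws / n_perms
        assert max(counts.values()) < 4 * expected


class TestWmwTwoSided:
    def test_canonical_exact_case(self):
        # one extreme U among C(6,3)=20 equally likely assignments, doubled
        assert wmw_two_sided([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1, abs=1e-12)

    def test_identical_multiset_gives_one(self):
        assert wmw_two_sided([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(1.0)

    def test_two_sided_symmetry(self, rng):
        for _ in range(10):
            a = rng.normal(size=int(rng.integers(3, 9)))
            b = rng.normal(size=int(rng.integers(3, 30)))
            assert wmw_two_sided(a, b) == pytest.approx(wmw_two_sided(b, a), rel=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            wmw_two_sided([], [1.0])

    @pytest.mark.parametrize("n,m", [(2, 4), (3, 3), (3, 5), (4, 4), (5, 6)])
    def test_exact_branch_matches_enumeration(self, n, m, rng):
        for _ in range(3):
            vals = rng.permutation(np.arange(1.0, n + m + 1))
            sample, pool = vals[:n], vals[n:]
            assert wmw_two_sided(sample, pool) == pytest.approx(
                wmw_exact_oracle(sample, pool), abs=1e-12
            )

    def test_approximate_branch_uniform_under_null(self, rng):
        # samples drawn from the pool itself must give uniform p-values
        pool = rng.normal(size=3000)
        ps = [
            wmw_two_sided(rng.choice(pool, size=30, replace=False), pool)
            for _ in range(400)
        ]
        ks = scipy.stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01


def _null_fits(seed=1, n_datasets=8):
    cfg = SimulationConfig(
        rng_seed=seed,
        n_datasets=n_datasets,
        n_samples=12,
        n_hosts=4,
        n_targets=4,
        n_background=80,
        regulators_per_target=0,
        n_decoys=3,
    )
    comp = simulate_compendium(cfg)
    datasets = [filter_genes(ds) for ds in comp.datasets]
    designs = build_all_designs(comp.host_map, comp.target_map)
    rng = np.random.default_rng(seed)
    return fit_compendium(datasets, designs, ["ULM"], rng), designs, datasets


class TestNullPoolAndScoring:
    def test_pool_size_counts_coefficients(self, rng):
        # 1 target, 1 dataset, M=3 hosts, one permutation -> 3 pooled weights
        from mirhost.annotation import TargetDesign
        from mirhost.expression import ExpressionDataset

        values = rng.normal(size=(4, 10)) + 5.0
        ds = ExpressionDataset(
            "D1", ["H1", "H2", "H3", "G"], [f"s{j}" for j in range(10)], values
        )
        design = TargetDesign(
            target_gene_id="G",
            host_gene_ids=["H1", "H2", "H3"],
            mirna_edges={h: (f"mir-{h}",) for h in ["H1", "H2", "H3"]},
        )
        fits = fit_compendium([ds], [design], ["ULM"], np.random.default_rng(0))
        pool = null_pool_from_fits(fits["ULM"])
        assert pool.weights.size == 3

    def test_degenerate_vectors_excluded_from_pool(self):
        vec = fit_ulm(np.array([[0.0], [1.0]]), np.array([1.0, 0.0]),
                      host_gene_ids=["H"], target_gene_id="G", dataset_id="D")
        assert vec.degenerate
        result = FitResult(method="ULM", real_vectors=[], perm_vectors=[vec], pairs={})
        with pytest.raises(EmptyDatasetError):
            null_pool_from_fits(result)

    def test_null_pool_symmetric_on_no_signal_data(self):
        # hand-built no-signal compendium: independent host profiles and pure
        # noise targets, hosts a negligible fraction of the gene universe so
        # the universe-mean contribution of host rows cannot offset the pool
        from mirhost.annotation import TargetDesign
        from mirhost.expression import ExpressionDataset

        rng = np.random.default_rng(17)
        hosts = [f"H{i}" for i in range(6)]
        targets = [f"G{j}" for j in range(8)]
        designs = [
            TargetDesign(
                target_gene_id=t,
                host_gene_ids=sorted(hosts[(j + k) % 6] for k in range(3)),
                mirna_edges={hosts[(j + k) % 6]: (f"mir-{k}",) for k in range(3)},
            )
            for j, t in enumerate(targets)
        ]
        datasets = []
        for k in range(50):
            S = 12
            rows = np.vstack([
                rng.normal(size=(6, S)),                      # hosts
                10.0 + 0.5 * rng.normal(size=(8, S)),         # targets (noise only)
                10.0 + 0.5 * rng.normal(size=(200, S)),       # background
            ])
            datasets.append(ExpressionDataset(
                f"D{k}", hosts + targets + [f"B{i}" for i in range(200)],
                [f"s{j}" for j in range(S)], rows,
            ))
        fits = fit_compendium(datasets, designs, ["ULM"], np.random.default_rng(3))
        pool = null_pool_from_fits(fits["ULM"])
        se = pool.weights.std() / np.sqrt(pool.weights.size)
        assert abs(pool.mean) < 3 * se

    def test_separated_sample_scores_tiny_p_and_negative_sign(self, rng):
        fits, _, _ = _null_fits()
        pool = null_pool_from_fits(fits["ULM"])
        high = pool.weights.max() + 1.0 + rng.random(20)
        score = score_pair("H", "G", high, rng.choice(pool.weights, 20), pool)
        assert score.p_real < 1e-6
        assert score.sign == "negative"

    def test_scores_reproducible_with_same_seed(self):
        fits1, designs, datasets = _null_fits(seed=5)
        fits2 = fit_compendium(
            datasets, designs, ["ULM"], np.random.default_rng(5)
        )
        s1 = score_all_pairs(fits1["ULM"], null_pool_from_fits(fits1["ULM"]))
        s2 = score_all_pairs(fits2["ULM"], null_pool_from_fits(fits2["ULM"]))
        assert [(s.host_gene_id, s.target_gene_id, s.p_real, s.p_perm) for s in s1] == [
            (s.host_gene_id, s.target_gene_id, s.p_real, s.p_perm) for s in s2
        ]

    def test_missing_real_weights_rejected(self):
        fits, _, _ = _null_fits()
        pool = null_pool_from_fits(fits["ULM"])
        with pytest.raises(ValueError, match="no real weights"):
            score_pair("H", "G", np.array([]), np.array([0.1]), pool)
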