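"""Kruskal-Wallis, stepdown homogeneous subsets and the letters display."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from seedshape import (
    compare_traits,
    format_table,
    kruskal_wallis,
    stepdown_subsets,
    table_markdown,
)


class TestKruskalWallis:
    def test_hand_computable_H(self):
        # three groups whose pooled ranks are {1,2,3}, {4,5,6}, {7,8,9}:
        # H = 12/(N(N+1)) * sum n_i (Rbar_i - (N+1)/2)^2 = 7.2 exactly
        groups = [[1.0, 2.0, 3.0], [11.0, 12.0, 13.0], [21.0, 22.0, 23.0]]
        H, p = kruskal_wallis(groups)
        assert H == pytest.approx(7.2, abs=1e-9)
        assert p == pytest.approx(float(sps.chi2.sf(7.2, 2)), abs=1e-12)

    def test_identical_observations_degenerate(self):
        assert kruskal_wallis([[5.0, 5.0], [5.0, 5.0]]) == (0.0, 1.0)

    def test_label_invariance(self):
        g1, g2 = [1.0, 3.0, 5.0], [2.0, 4.0, 6.0]
        assert kruskal_wallis([g1, g2]) == pytest.approx(kruskal_wallis([g2, g1]))

    def test_input_validation(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0, 2.0]])
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0], []])
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0], [2.0]])

    def test_p_matches_permutation_oracle(self):
        # group size 15: large enough for the chi-square approximation to sit
        # within the oracle tolerance
        rng = np.random.default_rng(5)
        groups = [rng.normal(0.0, 1.0, 15), rng.normal(0.6, 1.0, 15), rng.normal(0.3, 1.0, 15)]
        H_obs, p_chi2 = kruskal_wallis(groups)
        pooled = np.concatenate(groups)
        sizes = [len(g) for g in groups]
        count = 0
        n_perm = 20_000
        for _ in range(n_perm):
            rng.shuffle(pooled)
            parts = np.split(pooled, np.cumsum(sizes)[:-1])
            H, _ = kruskal_wallis(parts)
            if H >= H_obs - 1e-12:
                count += 1
        p_perm = count / n_perm
        assert p_chi2 == pytest.approx(p_perm, abs=0.02)


def oracle_letters(samples, alpha):
    """Independent brute-force closed-testing oracle (small k only).

    Orders groups by pooled mean rank, then explores every chain of
    contiguous subsets starting from the full set, splitting a subset into
    its two trimmed children whenever its within-subset Kruskal-Wallis test
    is significant at alpha_p; the retained maximal homogeneous subsets are
    converted to letters.
    """
    labels = list(samples)
    pooled = np.concatenate([np.asarray(samples[g], float) for g in labels])
    ranks = sps.rankdata(pooled)
    mean_ranks, pos = {}, 0
    for g in labels:
        n = len(samples[g])
        mean_ranks[g] = ranks[pos : pos + n].mean()
        pos += n
    order = sorted(labels, key=lambda g: (mean_ranks[g], g))
    k = len(order)

    def alpha_p(p_size):
        return alpha if p_size >= k - 1 else 1 - (1 - alpha) ** (p_size / k)

    def is_significant(i, j):
        arrays = [np.asarray(samples[g], float) for g in order[i : j + 1]]
        flat = np.concatenate(arrays)
        if np.all(flat == flat[0]):
            return False
        _, p = sps.kruskal(*arrays)
        return p < alpha_p(j - i + 1)

    homogeneous = set()

    def explore(i, j):
        if i == j or not is_significant(i, j):
            homogeneous.add((i, j))
            return
        explore(i, j - 1)
        explore(i + 1, j)

    explore(0, k - 1)
    maximal = [
        (i, j)
        for (i, j) in homogeneous
        if not any(
            a <= i and j <= b and (a, b) != (i, j) for (a, b) in homogeneous
        )
    ]
    letters = {g: "" for g in order}
    for idx, (i, j) in enumerate(sorted(maximal)):
        for g in order[i : j + 1]:
            letters[g] += "abcdefghijklmnopqrstuvwxyz"[idx]
    return letters


class TestStepdownSubsets:
    def test_well_separated_groups_get_distinct_letters(self):
        samples = {
            "g1": [1.0, 2.0, 3.0, 4.0, 5.0],
            "g2": [11.0, 12.0, 13.0, 14.0, 15.0],
            "g3": [21.0, 22.0, 23.0, 24.0, 25.0],
        }
        comp = stepdown_subsets(samples)
        assert comp.letters == {"g1": "a", "g2": "b", "g3": "c"}
        assert comp.p < 0.05

    def test_homogeneous_groups_share_one_letter(self):
        rng = np.random.default_rng(1)
        samples = {f"g{i}": rng.normal(0.0, 1.0, 8) for i in range(3)}
        comp = stepdown_subsets(samples)
        assert set(comp.letters.values()) == {"a"}
        assert comp.subsets == [sorted(samples, key=lambda g: comp.mean_ranks[g])]

    def test_overlapping_middle_group(self):
        rng = np.random.default_rng(3)
        samples = {
            "low": rng.normal(0.0, 1.0, 12),
            "mid": rng.normal(1.2, 1.0, 12),
            "high": rng.normal(2.4, 1.0, 12),
        }
        comp = stepdown_subsets(samples)
        assert comp.letters == oracle_letters(samples, 0.05)

    def test_against_bruteforce_oracle(self):
        rng = np.random.default_rng(7)
        for trial in range(30):
            k = int(rng.integers(2, 5))
            shift = rng.uniform(0.0, 2.0)
            samples = {
                f"g{i}": rng.normal(i * shift / k, 1.0, int(rng.integers(4, 9)))
                for i in range(k)
            }
            got = stepdown_subsets(samples, alpha=0.05).letters
            want = oracle_letters(samples, 0.05)
            assert got == want, f"trial {trial}: {got} != {want}"

    def test_letter_display_consistency(self):
        rng = np.random.default_rng(12)
        samples = {f"g{i}": rng.normal(i * 0.8, 1.0, 10) for i in range(5)}
        comp = stepdown_subsets(samples)
        # every group carries at least one letter
        assert all(comp.letters[g] for g in samples)
        # groups inside one reported subset share that subset's letter
        for letter, subset in zip("abcdefghijklmnopqrstuvwxyz", comp.subsets):
            for g in subset:
                assert letter in comp.letters[g]
        # subsets are contiguous in mean-rank order
        order = sorted(samples, key=lambda g: (comp.mean_ranks[g], g))
        for subset in comp.subsets:
            idx = sorted(order.index(g) for g in subset)
            assert idx == list(range(idx[0], idx[-1] + 1))

    def test_two_groups_minimum(self):
        with pytest.raises(ValueError):
            stepdown_subsets({"only": [1.0, 2.0]})


class TestTables:
    @pytest.fixture()
    def long_df(self):
        rng = np.random.default_rng(2)
        rows = []
        for g, mu in (("sp1", 0.0), ("sp2", 4.0)):
            for v in rng.normal(mu + 10.0, 0.5, 10):
                rows.append({"group": g, "trait_x": v})
        return pd.DataFrame(rows)

    def test_compare_traits_and_format(self, long_df):
        comps = compare_traits(long_df, "group", ["trait_x"])
        assert comps["trait_x"].letters == {"sp1": "a", "sp2": "b"}
        table = format_table(long_df, comps, "group")
        assert list(table.columns) == ["group", "N", "trait_x"]
        assert all(table["N"] == 10)
        cell = table.loc[table["group"] == "sp1", "trait_x"].iloc[0]
        assert "^a^" in cell and "(" in cell

    def test_format_table_group_mismatch(self, long_df):
        comps = compare_traits(long_df, "group", ["trait_x"])
        bad = long_df.assign(group=long_df["group"].replace("sp2", "sp9"))
        with pytest.raises(ValueError, match="mismatch"):
            format_table(bad, comps, "group")

    def test_markdown_rendering(self, long_df):
        comps = compare_traits(long_df, "group", ["trait_x"])
        md = table_markdown(format_table(long_df, comps, "group"))
        lines = md.strip().splitlines()
        assert lines[0].startswith("| group |")
        assert len(lines) == 4  # header, rule, two groups
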