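import itertools
import math

import numpy as np
import pytest

from refstab import (
    CtTable,
    CtTableError,
    bestkeeper,
    delta_ct_stability,
    dense_ranks,
    genorm,
    normfinder,
    to_relative_quantities,
)
from tests.conftest import random_table


def brute_force_pairwise_sd(ct: np.ndarray) -> dict[int, float]:
    """Independent oracle: mean over partners of SD of per-sample differences."""
    K = ct.shape[0]
    out = {}
    for i in range(K):
        sds = []
        for k in range(K):
            if k == i:
                continue
            d = ct[i] - ct[k]
            m = d.mean()
            sds.append(math.sqrt(sum((x - m) ** 2 for x in d) / (len(d) - 1)))
        out[i] = sum(sds) / len(sds)
    return out


class TestDenseRanks:
    def test_plain(self):
        assert dense_ranks({"a": 0.3, "b": 0.1, "c": 0.2}) == {"a": 3, "b": 1, "c": 2}

    def test_ties_share_rank_no_gaps(self):
        assert dense_ranks({"a": 0.1, "b": 0.1, "c": 0.2}) == {"a": 1, "b": 1, "c": 2}


class TestDeltaCt:
    def test_identical_rows_zero(self):
        t = CtTable(genes=["A", "B"], samples=["s1", "s2", "s3"],
                    ct=np.array([[20.0, 21.0, 22.0]] * 2),
                    groups={f"s{i}": "g" for i in (1, 2, 3)})
        r = delta_ct_stability(t)
        assert r.values == {"A": 0.0, "B": 0.0}
        assert r.ranks == {"A": 1, "B": 1}

    def test_hand_worked_values(self, abc_table):
        r = delta_ct_stability(abc_table)
        assert r.values["A"] == pytest.approx(0.16330, abs=1e-4)
        assert r.values["B"] == pytest.approx(0.16330, abs=1e-4)
        assert r.values["C"] == pytest.approx(0.32660, abs=1e-4)
        assert r.ranks == {"A": 1, "B": 1, "C": 2}

    def test_global_shift_invariance(self, abc_table):
        shifted = abc_table.copy_with(ct=abc_table.ct + 3.0)
        r0, r1 = delta_ct_stability(abc_table), delta_ct_stability(shifted)
        for g in abc_table.genes:
            assert r1.values[g] == pytest.approx(r0.values[g], abs=1e-12)

    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            t = random_table(rng)
            r = delta_ct_stability(t)
            oracle = brute_force_pairwise_sd(t.ct)
            for i, g in enumerate(t.genes):
                assert r.values[g] == pytest.approx(oracle[i], rel=1e-10)

    def test_pair_with_too_few_samples_excluded(self):
        ct = np.array([
            [20.0, 21.0, 22.0],
            [22.0, 23.0, 24.0],
            [25.0, np.nan, np.nan],
        ])
        t = CtTable(genes=["A", "B", "C"], samples=["s1", "s2", "s3"], ct=ct,
                    groups={f"s{i}": "g" for i in (1, 2, 3)})
        with pytest.raises(CtTableError, match="no valid partner"):
            delta_ct_stability(t)


class TestGeNorm:
    def test_hand_worked_elimination(self, abc_table):
        r = genorm(to_relative_quantities(abc_table))
        d = r.details
        assert d.initial_m["A"] == pytest.approx(0.16330, abs=1e-4)
        assert d.initial_m["C"] == pytest.approx(0.32660, abs=1e-4)
        assert d.elimination_order[0] == "C"
        assert d.final_pair == ("A", "B")
        assert r.ranks["A"] == r.ranks["B"] == 1
        # final pair carries its mutual V (0 here: B is A + 2 cycles)
        assert r.values["A"] == pytest.approx(0.0, abs=1e-12)
        assert r.values["C"] == pytest.approx(0.32660, abs=1e-4)

    def test_v23_brute_force(self, abc_table):
        rq = to_relative_quantities(abc_table)
        r = genorm(rq)
        qa, qb, qc = rq.q
        nf2 = np.sqrt(qa * qb)
        nf3 = (qa * qb * qc) ** (1 / 3)
        ratio = np.log2(nf2 / nf3)
        v23 = float(np.std(ratio, ddof=1))
        assert r.details.v_series[2] == pytest.approx(v23, rel=1e-10)

    def test_duplicate_genes_form_final_pair(self):
        rng = np.random.default_rng(3)
        ct = rng.uniform(18, 28, size=(4, 6))
        ct[1] = ct[0]  # duplicate gene rows
        samples = [f"s{j}" for j in range(6)]
        t = CtTable(genes=["A", "B", "C", "D"], samples=samples, ct=ct,
                    groups={s: "g" for s in samples})
        r = genorm(to_relative_quantities(t))
        assert set(r.details.final_pair) == {"A", "B"}
        assert r.values["A"] == pytest.approx(0.0, abs=1e-12)

    def test_initial_m_equals_delta_ct(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            t = random_table(rng)
            m = genorm(to_relative_quantities(t)).details.initial_m
            dct = delta_ct_stability(t).values
            for g in t.genes:
                assert m[g] == pytest.approx(dct[g], abs=1e-11)

    def test_v_nonnegative_and_duplicate_panel_all_zero(self):
        samples = [f"s{j}" for j in range(5)]
        row = np.array([20.0, 21.0, 19.5, 22.0, 20.5])
        ct = np.stack([row + k for k in range(4)])  # exact duplicates up to shift
        t = CtTable(genes=list("ABCD"), samples=samples, ct=ct,
                    groups={s: "g" for s in samples})
        r = genorm(to_relative_quantities(t))
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in r.values.values())
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in r.details.v_series.values())

    def test_elimination_tiebreak_is_lexicographically_last(self):
        # two interchangeable noisy genes tied for worst M: 'Z' removed first
        samples = [f"s{j}" for j in range(4)]
        noise = np.array([0.0, 1.0, -1.0, 0.5])
        ct = np.stack([
            np.full(4, 20.0),
            np.full(4, 21.0),
            22.0 + noise,
            24.0 + noise[::-1],
        ])
        t = CtTable(genes=["A", "B", "M", "Z"], samples=samples, ct=ct,
                    groups={s: "g" for s in samples})
        t2 = t.copy_with(genes=["A", "B", "Z", "M"])
        r = genorm(to_relative_quantities(t))
        r2 = genorm(to_relative_quantities(t2))
        # values identical regardless of row order; tie broken by id
        assert r.values == r2.values

    def test_rejects_nonpositive_q(self, abc_table):
        rq = to_relative_quantities(abc_table)
        rq.q[0, 0] = 1.0  # keep valid, then check ctor guard separately
        with pytest.raises(CtTableError, match="strictly positive"):
            type(rq)(genes=rq.genes, samples=rq.samples, q=np.array([[1.0, -0.5], [1.0, 1.0]]),
                     groups={}, base={}, anchor={})


class TestNormFinder:
    def test_hand_worked_ungrouped(self, abc_table):
        r = normfinder(abc_table, use_groups=False)
        # z_A = (2.3333, 2.4667, 2.2, 2.3333); S_A = sd = 0.10887
        assert r.values["A"] == pytest.approx(0.10887, abs=1e-4)
        assert not r.details.grouped

    def test_constant_z_row_rank_one(self):
        samples = [f"s{j}" for j in range(4)]
        loading = np.array([0.0, 1.0, -0.5, 2.0])
        ct = np.stack([
            20.0 + loading,            # follows loading exactly
            22.0 + loading + np.array([0.0, 0.4, -0.4, 0.2]),
            25.0 + loading - np.array([0.0, 0.4, -0.4, 0.2]) / 2,
        ])
        # gene A's centered profile is constant only if the others cancel:
        # build B and C so their deviations sum to zero at every sample
        ct[2] = 25.0 + loading - (ct[1] - 22.0 - loading)
        t = CtTable(genes=["A", "B", "C"], samples=samples, ct=ct,
                    groups={s: "g" for s in samples})
        r = normfinder(t, use_groups=False)
        assert r.values["A"] == pytest.approx(0.0, abs=1e-12)
        assert r.ranks["A"] == 1

    def test_single_group_falls_back(self, abc_table):
        r = normfinder(abc_table, use_groups=True)
        assert not r.details.grouped
        assert any("falling back" in w for w in r.warnings)

    def test_singleton_group_errors(self):
        samples = [f"s{j}" for j in range(5)]
        rng = np.random.default_rng(0)
        t = CtTable(genes=["A", "B", "C"], samples=samples,
                    ct=rng.uniform(18, 25, (3, 5)),
                    groups={"s0": "g1", "s1": "g1", "s2": "g2", "s3": "g2", "s4": "g3"})
        with pytest.raises(CtTableError, match="'g3'"):
            normfinder(t, use_groups=True)

    def test_weighted_raw_deviations_sum_to_zero(self):
        rng = np.random.default_rng(21)
        t = random_table(rng, n_genes=4, n_samples=12, n_groups=3)
        r = normfinder(t, use_groups=True)
        d = r.details.raw_deviation
        sizes = {g: sum(1 for s in t.samples if t.groups[s] == g) for g in t.group_labels()}
        for gene in t.genes:
            total = sum(sizes[lab] * d[gene][lab] for lab in sizes)
            assert total == pytest.approx(0.0, abs=1e-9)

    def test_grouped_zero_effect_limit(self):
        # no true group differences at large n: tau2 ~ 0, shrunken d ~ 0 and
        # S ~ mean_g sqrt(s2/n) with s2 the centered variance sigma^2*(K-1)/K
        rng = np.random.default_rng(99)
        K, n_per, sigma = 4, 200, 0.5
        samples = [f"s{j}" for j in range(2 * n_per)]
        groups = {s: ("g1" if j < n_per else "g2") for j, s in enumerate(samples)}
        ct = 24.0 + rng.normal(0, sigma, size=(K, 2 * n_per))
        t = CtTable(genes=[f"G{i}" for i in range(K)], samples=samples, ct=ct, groups=groups)
        r = normfinder(t, use_groups=True)
        expected_se = math.sqrt(sigma ** 2 * (K - 1) / K / n_per)
        for gene in t.genes:
            assert r.details.tau2[gene] < 5 * sigma ** 2 / n_per
            for lab in ("g1", "g2"):
                assert abs(r.details.shrunken_deviation[gene][lab]) < 0.1
            assert r.values[gene] == pytest.approx(expected_se, rel=0.5)

    def test_needs_three_genes(self):
        t = CtTable(genes=["A", "B"], samples=["s1", "s2"],
                    ct=np.array([[20.0, 21.0], [22.0, 23.0]]),
                    groups={"s1": "g", "s2": "g"})
        with pytest.raises(CtTableError, match=">=3 genes"):
            normfinder(t)


class TestBestKeeper:
    def test_constant_row_rank_one(self):
        samples = [f"s{j}" for j in range(4)]
        rng = np.random.default_rng(1)
        ct = rng.uniform(18, 25, (3, 4))
        ct[1] = 23.0
        t = CtTable(genes=["A", "B", "C"], samples=samples, ct=ct,
                    groups={s: "g" for s in samples})
        r = bestkeeper(t)
        assert r.values["B"] == 0.0
        assert r.ranks["B"] == 1

    def test_hand_worked_dispersion(self, abc_table):
        sd = bestkeeper(abc_table, dispersion="sample_sd")
        mad = bestkeeper(abc_table, dispersion="mean_abs_dev")
        assert sd.values["A"] == pytest.approx(0.08165, abs=1e-4)
        assert mad.values["A"] == pytest.approx(0.05, abs=1e-12)

    def test_index_is_geometric_mean(self, abc_table):
        r = bestkeeper(abc_table)
        assert r.details.index["s1"] == pytest.approx((20.0 * 22.0 * 25.0) ** (1 / 3), rel=1e-10)
        assert r.details.index["s1"] == pytest.approx(22.2398, abs=1e-4)

    def test_descriptive_ordering_invariant(self):
        rng = np.random.default_rng(8)
        t = random_table(rng, n_genes=6, n_samples=10)
        r = bestkeeper(t)
        for g in t.genes:
            d = r.details.descriptives[g]
            assert d["min"] <= d["geo_mean"] <= d["mean"] <= d["max"]
            rho, _ = r.details.correlations[g]
            assert -1.0 <= rho <= 1.0

    def test_constant_index_correlation_undefined(self):
        samples = ["s1", "s2", "s3"]
        ct = np.array([[20.0, 20.0, 20.0], [25.0, 25.0, 25.0]])
        t = CtTable(genes=["A", "B"], samples=samples, ct=ct,
                    groups={s: "g" for s in samples})
        r = bestkeeper(t)
        assert math.isnan(r.details.correlations["A"][0])

    def test_loading_changes_bestkeeper_only(self):
        rng = np.random.default_rng(13)
        t = random_table(rng, n_genes=4, n_samples=10)
        loading = rng.normal(0, 2.0, size=t.n_samples)
        shifted = t.copy_with(ct=np.clip(t.ct + loading, 1, 44))
        bk0, bk1 = bestkeeper(t), bestkeeper(shifted)
        assert any(abs(bk0.values[g] - bk1.values[g]) > 0.2 for g in t.genes)


class TestCrossMethodProperties:
    def test_loading_invariance_delta_genorm_normfinder(self):
        rng = np.random.default_rng(17)
        t = random_table(rng, n_genes=5, n_samples=10)
        loading = rng.normal(0, 2.0, size=t.n_samples)
        shifted = t.copy_with(ct=np.clip(t.ct + loading, 1, 44))
        for fn in (
            lambda x: delta_ct_stability(x).values,
            lambda x: genorm(to_relative_quantities(x)).details.initial_m,
            lambda x: normfinder(x, use_groups=False).values,
        ):
            v0, v1 = fn(t), fn(shifted)
            for g in t.genes:
                assert v1[g] == pytest.approx(v0[g], abs=1e-9)

    def test_gene_permutation_stable(self):
        rng = np.random.default_rng(23)
        t = random_table(rng, n_genes=5, n_samples=8)
        perm = rng.permutation(t.n_genes)
        tp = t.copy_with(genes=[t.genes[i] for i in perm], ct=t.ct[perm])
        for fn in (delta_ct_stability, lambda x: genorm(to_relative_quantities(x)),
                   lambda x: normfinder(x, use_groups=False), bestkeeper):
            r0, r1 = fn(t), fn(tp)
            assert r1.values == pytest.approx(r0.values)
            assert r0.ranks == r1.ranks

    def test_iid_closed_form_limit(self):
        # K iid genes, Ct = 25 + N(0, sigma^2): initial M and delta-Ct tend
        # to sqrt(2)*sigma; ungrouped NormFinder S tends to sigma*sqrt((K-1)/K)
        rng = np.random.default_rng(2024)
        K, n, sigma = 6, 2000, 0.3
        samples = [f"s{j}" for j in range(n)]
        ct = 25.0 + rng.normal(0, sigma, size=(K, n))
        t = CtTable(genes=[f"G{i}" for i in range(K)], samples=samples, ct=ct,
                    groups={s: "g" for s in samples})
        m = genorm(to_relative_quantities(t)).details.initial_m
        dct = delta_ct_stability(t).values
        nf = normfinder(t, use_groups=False).values
        target_m = math.sqrt(2) * sigma
        target_s = sigma * math.sqrt((K - 1) / K)
        for g in t.genes:
            assert abs(m[g] - target_m) / target_m < 0.05
            assert abs(dct[g] - target_m) / target_m < 0.05
            assert abs(nf[g] - target_s) / target_s < 0.05
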