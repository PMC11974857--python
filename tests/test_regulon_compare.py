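import itertools

import numpy as np
import pandas as pd
import pytest

from rhodoflag.errors import DataError
from rhodoflag import regulon_compare as reg
from rhodoflag.io_formats import GeneRecord
from rhodoflag.synthetic_data import RegulonConfig, simulate_counts


def _counts(rng, n_genes=200, mu=100.0, phi=0.1, libs=(1, 1, 1, 1, 1, 1)):
    data = []
    for lib in libs:
        lam = rng.gamma(1 / phi, mu * phi * lib, size=n_genes) if phi > 0 else np.full(n_genes, mu * lib)
        data.append(rng.poisson(lam))
    return pd.DataFrame(
        np.column_stack(data),
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"s{i}" for i in range(len(libs))],
    )


class TestSizeFactors:
    def test_doubled_sample(self):
        df = pd.DataFrame({"s1": [10, 20, 30], "s2": [20, 40, 60]}, index=list("abc"))
        f = reg.size_factors(df)
        assert f["s2"] / f["s1"] == pytest.approx(2.0)
        assert np.prod(f) == pytest.approx(1.0)

    def test_identical_samples_unit_factors(self):
        df = pd.DataFrame({"s1": [5, 7], "s2": [5, 7]}, index=list("ab"))
        assert reg.size_factors(df).tolist() == pytest.approx([1.0, 1.0])

    def test_recovers_known_libsizes(self, rng):
        libs = [0.5, 0.8, 1.0, 1.3, 1.7, 2.0]
        df = _counts(rng, n_genes=3000, mu=200.0, phi=0.05, libs=libs)
        f = reg.size_factors(df)
        rel = f.to_numpy() / np.array(libs)
        rel /= np.exp(np.mean(np.log(rel)))
        assert np.all(np.abs(rel - 1) < 0.05)


class TestEstimateDispersion:
    def _groups(self, cols, n_per=6):
        labels = ["a"] * n_per + ["b"] * (len(cols) - n_per)
        return pd.Series(labels, index=cols)

    def test_poisson_data_near_floor(self, rng):
        df = _counts(rng, n_genes=2000, mu=100.0, phi=0.0)
        est = reg.estimate_dispersion(df, self._groups(df.columns))
        assert est.common < 0.01

    def test_recovers_true_dispersion(self):
        for seed in range(1, 11):
            r = np.random.default_rng(seed)
            df = _counts(r, n_genes=2000, mu=100.0, phi=0.1, libs=[1.0] * 12)
            est = reg.estimate_dispersion(
                df, pd.Series(["a"] * 6 + ["b"] * 6, index=df.columns)
            )
            assert 0.07 < est.common < 0.13

    def test_full_shrinkage_with_minimal_replication(self, rng):
        df = _counts(rng, n_genes=5, mu=50.0, phi=0.1, libs=[1.0, 1.0])
        est = reg.estimate_dispersion(df, pd.Series(["a", "a"], index=df.columns))
        # residual df = 1 -> weight 20/21 on the common value
        assert est.shrinkage_weight == pytest.approx(20 / 21)

    def test_no_replication_rejected(self, rng):
        df = _counts(rng, n_genes=5, libs=[1.0, 1.0])
        with pytest.raises(DataError):
            reg.estimate_dispersion(df, pd.Series(["a", "b"], index=df.columns))


def _two_group_fixture(rng, n_genes=50, effect=None):
    df = _counts(rng, n_genes=n_genes, libs=[1.0] * 12)
    if effect is not None:
        gene, fold = effect
        df.iloc[gene, 6:] = rng.poisson(100 * fold, size=6)
    groups = pd.Series(["wt"] * 6 + ["mut"] * 6, index=df.columns)
    return df, groups


class TestNbLrt:
    def test_identical_groups_null(self, rng):
        df = _counts(rng, n_genes=20, libs=[1.0] * 6)
        both = pd.concat([df, df], axis=1)
        both.columns = [f"s{i}" for i in range(12)]
        groups = pd.Series(["wt"] * 6 + ["mut"] * 6, index=both.columns)
        disp = pd.Series(0.1, index=both.index)
        res = reg.nb_lrt_test(both, groups, "wt", "mut", disp)
        assert np.allclose(res["log2fc"], 0)
        assert np.allclose(res["stat"], 0, atol=1e-8)
        assert np.allclose(res["pvalue"], 1)

    def test_statistic_matches_grid_oracle(self, rng):
        from scipy.special import gammaln

        df, groups = _two_group_fixture(rng, n_genes=5, effect=(0, 4.0))
        factors = pd.Series(1.0, index=df.columns)
        disp = pd.Series(0.1, index=df.index)
        res = reg.nb_lrt_test(df, groups, "wt", "mut", disp, factors)

        def loglik(y, m, phi):
            if m <= 0:
                m = 1e-12
            r = 1 / phi
            return float(
                np.sum(
                    gammaln(y + r) - gammaln(r) - gammaln(y + 1)
                    + r * np.log(r / (r + m)) + y * np.log(m / (r + m))
                )
            )

        for gi in range(5):
            y = df.iloc[gi].to_numpy(float)
            ywt, ymut = y[:6], y[6:]
            grid = np.linspace(0.5, max(y.max() * 1.5, 2), 40000)
            ll_null = max(loglik(y, m, 0.1) for m in grid)
            ll_alt = max(loglik(ywt, m, 0.1) for m in grid) + max(
                loglik(ymut, m, 0.1) for m in grid
            )
            expected = max(0.0, 2 * (ll_alt - ll_null))
            assert res["stat"].iloc[gi] == pytest.approx(expected, abs=1e-4)

    def test_direction_symmetry(self, rng):
        df, groups = _two_group_fixture(rng, effect=(3, 3.0))
        disp = pd.Series(0.1, index=df.index)
        fwd = reg.nb_lrt_test(df, groups, "wt", "mut", disp)
        rev = reg.nb_lrt_test(df, groups, "mut", "wt", disp)
        assert np.allclose(fwd["log2fc"], -rev["log2fc"])
        assert np.allclose(fwd["pvalue"], rev["pvalue"])

    def test_strong_effect_recovered(self, rng):
        cfg = RegulonConfig(
            n_genes=200, n_orthologs=50, n_shared=1, n_specific=0,
            contrasts=("ctrA",), n_replicates=6, dispersion=0.05,
            baseline_log_mean=np.log(5000), baseline_log_sd=0.0,
            libsize_range=(1.0, 1.0), effect_low=6.0, effect_high=6.0,
            down_fraction=1.0,
        )
        for seed in range(1, 11):
            b = simulate_counts(cfg, seed)
            de = reg.de_contrasts(b.counts_a, b.conditions_a)["ctrA"]
            row = de.loc["A_g0000"]
            assert abs(row["log2fc"] + 6) < 0.5
            assert row["pvalue"] < 1e-10


class TestBhAdjust:
    def _oracle(self, p):
        n = len(p)
        order = np.argsort(p, kind="stable")
        out = np.empty(n)
        running = 1.0
        for rank in range(n, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * n / rank)
            out[i] = running
        return out

    def test_spec_example(self):
        assert reg.bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_single_and_degenerate(self):
        assert reg.bh_adjust([0.3]) == pytest.approx([0.3])
        assert reg.bh_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0] * 3)

    def test_all_short_grid_vectors_match_oracle(self):
        grid = np.round(np.arange(0, 1.0001, 0.1), 3)
        for n in (1, 2, 3):
            for vec in itertools.product(grid, repeat=n):
                p = np.array(vec)
                assert np.allclose(reg.bh_adjust(p), self._oracle(p))

    def test_random_longer_vectors_match_oracle(self, rng):
        for n in (4, 5, 6):
            for _ in range(200):
                p = np.round(rng.random(n), 2)
                assert np.allclose(reg.bh_adjust(p), self._oracle(p))

    def test_out_of_range_rejected(self):
        with pytest.raises(DataError):
            reg.bh_adjust([0.5, 1.5])


class TestCallSignificant:
    def _df(self, lfc, fdr_target):
        # craft p-values so that BH fdr equals the requested value exactly
        return pd.DataFrame({"log2fc": [lfc], "stat": [0.0], "pvalue": [fdr_target]})

    def test_clear_downregulation(self):
        out = reg.call_significant(self._df(-6.0, 1e-12))
        assert bool(out["significant"].iloc[0])
        assert out["direction"].iloc[0] == "down"

    def test_fold_change_gate_is_strict(self):
        out = reg.call_significant(self._df(-0.9, 1e-12))
        assert not bool(out["significant"].iloc[0])
        assert out["direction"].iloc[0] == "none"

    def test_fdr_boundary_is_strict(self):
        out = reg.call_significant(self._df(-2.0, 0.05))
        assert out["fdr"].iloc[0] == pytest.approx(0.05)
        assert not bool(out["significant"].iloc[0])


class TestCrossSpeciesOrthologs:
    def _proteome(self, genome_id, seqs):
        return [
            GeneRecord(f"{genome_id}_{i}", genome_id, "c", i, "+", s)
            for i, s in enumerate(seqs)
        ]

    def test_identical_proteomes_fully_paired(self, rng):
        seqs = [
            "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=80))
            for _ in range(4)
        ]
        pairs = reg.cross_species_orthologs(
            self._proteome("A", seqs), self._proteome("B", seqs)
        )
        assert pairs == [(f"A_{i}", f"B_{i}") for i in range(4)]

    def test_non_reciprocal_excluded(self, rng):
        base = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=80))
        # B_0 is closer to A_1 than to A_0; A_0's best is B_0 but not back
        a0 = base
        a1 = base[:70] + "WWWWWWWWWW"
        b0 = base[:70] + "WWWWWWWWWW"
        pairs = reg.cross_species_orthologs(
            self._proteome("A", [a0, a1]), self._proteome("B", [b0])
        )
        assert pairs == [("A_1", "B_0")]


class TestCoreRegulon:
    def _de(self, rows):
        df = pd.DataFrame(rows).set_index("gene")
        df["stat"] = 1.0
        df["pvalue"] = df["fdr"]
        return df

    def _pair_tables(self, lfc_a, sig_a, lfc_b, sig_b):
        de_a = {
            "ctrA": self._de(
                [{"gene": "a1", "log2fc": lfc_a, "fdr": 0.01 if sig_a else 0.9,
                  "significant": sig_a,
                  "direction": ("down" if lfc_a < 0 else "up") if sig_a else "none"}]
            )
        }
        de_b = {
            "ctrA": self._de(
                [{"gene": "b1", "log2fc": lfc_b, "fdr": 0.01 if sig_b else 0.9,
                  "significant": sig_b,
                  "direction": ("down" if lfc_b < 0 else "up") if sig_b else "none"}]
            )
        }
        res = reg.core_regulon(de_a, de_b, [("a1", "b1")])
        ent = res["entries"]
        return ent["class"].iloc[0] if len(ent) else None

    def test_strict_both_significant_down(self):
        assert self._pair_tables(-3.0, True, -2.5, True) == "strict"

    def test_relaxed_near_miss(self):
        # 1.9-fold down (not significant) alongside significant down
        assert self._pair_tables(-0.93, False, -2.5, True) == "relaxed"

    def test_species_specific_noise_not_relaxed(self):
        assert self._pair_tables(-0.1, False, -2.5, True) == "species_specific"

    def test_discordant_opposite_directions(self):
        assert self._pair_tables(2.5, True, -2.5, True) == "discordant"

    def test_no_significance_no_entry(self):
        assert self._pair_tables(-0.5, False, 0.4, False) is None

    def test_missing_contrast_rejected(self):
        de = {"ctrA": self._de([{"gene": "a1", "log2fc": 0.0, "fdr": 1.0,
                                 "significant": False, "direction": "none"}])}
        with pytest.raises(DataError):
            reg.core_regulon(de, de, [("a1", "a1")], {"cckA": "cckA"})

    def test_classification_is_a_partition(self):
        cfg = RegulonConfig(
            n_genes=300, n_orthologs=200, n_shared=10, n_specific=10, n_replicates=4
        )
        b = simulate_counts(cfg, 3)
        de_a = reg.de_contrasts(b.counts_a, b.conditions_a)
        de_b = reg.de_contrasts(b.counts_b, b.conditions_b)
        res = reg.core_regulon(de_a, de_b, b.ortholog_pairs)
        ent = res["entries"]
        # one row (= one class) per pair per contrast
        assert not ent.duplicated(["contrast_a", "gene_a"]).any()
        assert set(ent["class"]) <= {"strict", "relaxed", "discordant", "species_specific"}
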