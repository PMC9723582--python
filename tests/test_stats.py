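import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from rocits import simulate as sim
from rocits.seqio import msa_from_rows
from rocits.stats import (
    chisq_uniform,
    estimate_error,
    informative_sites,
    load_community_stage_counts,
    pearson,
    r_squared,
    spearman,
    survival_table,
)


class TestEstimateError:
    def test_identical_sequence_is_100(self, template):
        est = estimate_error([("a", template[0])], [template[0]])
        assert est.mean_identity == 100.0

    def test_known_substitutions(self, template):
        base = template[0]
        mutated = "".join(
            ("A" if c != "A" else "C") if i % 100 == 0 else c
            for i, c in enumerate(base)
        )
        n_subs = len(base) // 100 + (1 if len(base) % 100 else 0)
        est = estimate_error([("m", mutated)], [base])
        row = est.per_sequence.iloc[0]
        assert row["alignment_length"] == len(base)
        assert row["identities"] == len(base) - n_subs
        assert row["percent_identity"] == pytest.approx(
            100 * (len(base) - n_subs) / len(base)
        )

    def test_best_reference_wins(self, template):
        base, its = template
        other = sim.make_rrn_set(base, 2, [[("snp", 100)]], 0)[1]
        est = estimate_error([("x", other)], [base, other])
        assert est.per_sequence.iloc[0]["best_ref"] == 1
        assert est.mean_identity == 100.0

    def test_duplication_invariance(self, template):
        base, _ = template
        noisy = sim.apply_errors(base, sim.ErrorModel(), np.random.default_rng(0))
        one = estimate_error([("a", noisy)], [base])
        two = estimate_error([("a", noisy), ("b", noisy)], [base])
        assert one.mean_identity == two.mean_identity

    def test_empty_refs_rejected(self):
        with pytest.raises(ValueError):
            estimate_error([("a", "ACGT")], [])


class TestChisqUniform:
    def test_uniform_counts(self):
        stat, df, p = chisq_uniform([50, 50])
        assert stat == 0 and p == 1

    def test_df1_closed_form(self):
        stat, df, p = chisq_uniform([10, 20])
        assert stat == pytest.approx(10 / 3, abs=1e-4)
        assert df == 1
        # closed form for df=1: p = erfc(sqrt(x/2))
        assert p == pytest.approx(math.erfc(math.sqrt(stat / 2)), rel=1e-10)
        assert p == pytest.approx(0.0679, abs=2e-4)

    def test_seven_uniform_rrns(self):
        stat, df, p = chisq_uniform([100] * 7)
        assert stat == 0 and df == 6 and p == 1

    @given(st.lists(st.integers(1, 500), min_size=2, max_size=2))
    def test_matches_closed_form_df1(self, counts):
        stat, df, p = chisq_uniform(counts)
        total = sum(counts)
        exp = total / 2
        stat_oracle = sum((c - exp) ** 2 / exp for c in counts)
        assert stat == pytest.approx(stat_oracle, rel=1e-12)
        assert p == pytest.approx(math.erfc(math.sqrt(stat / 2)), rel=1e-9)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            chisq_uniform([0, 0])


class TestCorrelations:
    def test_identity(self):
        x = [1.0, 2.0, 5.0, 9.0]
        assert pearson(x, x) == pytest.approx(1.0)
        assert spearman(x, x) == pytest.approx(1.0)
        assert r_squared(x, x) == pytest.approx(1.0)

    def test_antisorted_spearman(self):
        x = [1, 2, 3, 4, 5]
        y = [50, 40, 30, 20, 10]
        n = len(x)
        d2 = sum((i - (n - 1 - i)) ** 2 for i in range(n))
        rho_oracle = 1 - 6 * d2 / (n * (n**2 - 1))
        assert spearman(x, y) == pytest.approx(rho_oracle) == pytest.approx(-1.0)

    @given(
        st.lists(st.floats(0, 1000, allow_nan=False), min_size=4, max_size=30)
    )
    def test_pearson_matches_bruteforce(self, x):
        rng = np.random.default_rng(0)
        y = [v + float(rng.normal(0, 10)) for v in x]
        x = np.array(x)
        y = np.array(y)
        if x.std() == 0 or np.std(y) == 0:
            return
        cov = ((x - x.mean()) * (y - y.mean())).mean()
        r_oracle = cov / (x.std() * np.std(y))
        assert pearson(x, y) == pytest.approx(r_oracle, abs=1e-10)
        assert r_squared(x, y) == pytest.approx(r_oracle**2, abs=1e-8)

    def test_spearman_midranks_bruteforce(self):
        x = [1, 2, 2, 3, 10]
        y = [3, 1, 4, 4, 9]

        def midranks(v):
            v = np.asarray(v, float)
            order = np.argsort(v, kind="stable")
            ranks = np.empty(len(v))
            i = 0
            sv = v[order]
            while i < len(v):
                j = i
                while j < len(v) and sv[j] == sv[i]:
                    j += 1
                ranks[order[i:j]] = (i + j - 1) / 2 + 1
                i = j
            return ranks

        rx, ry = midranks(x), midranks(y)
        cov = ((rx - rx.mean()) * (ry - ry.mean())).mean()
        oracle = cov / (rx.std() * ry.std())
        assert spearman(x, y) == pytest.approx(oracle, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson([1, 1, 1], [1, 2, 3])


class TestInformativeSites:
    def test_identical_rows(self):
        msa = msa_from_rows(["a", "b"], ["ACGT", "ACGT"])
        assert informative_sites(msa, "variable") == 0
        assert informative_sites(msa, "parsimony") == 0

    def test_shared_variant_counts_in_both_modes(self):
        msa = msa_from_rows(list("abcd"), ["ACGT", "ACGA", "ACGA", "ACGT"])
        assert informative_sites(msa, "variable") == 1
        assert informative_sites(msa, "parsimony") == 1

    def test_singleton_variants_not_parsimony_informative(self):
        msa = msa_from_rows(list("abcd"), ["ACGT", "ACGA", "ACGC", "ACGT"])
        assert informative_sites(msa, "variable") == 1
        assert informative_sites(msa, "parsimony") == 0


class TestSurvivalTable:
    def test_published_rows(self):
        df = load_community_stage_counts()
        out = survival_table(df).set_index("genus")
        assert out.loc["Duganella", "largest_cluster_pct"] == 95.7
        assert out.loc["Pedobacter", "surviving_pct"] == 78.6
        assert out.loc["Total", "after_full_analysis"] == 2210

    def test_identity_run_is_100_everywhere(self):
        df = pd.DataFrame(
            {
                "genus": ["g"],
                "initial_clustering": [40],
                "largest_cluster": [40],
                "after_full_analysis": [40],
            }
        )
        out = survival_table(df)
        assert out.loc[0, "largest_cluster_pct"] == 100.0
        assert out.loc[0, "surviving_pct"] == 100.0

    def test_conservation_violation_rejected(self):
        df = pd.DataFrame(
            {
                "genus": ["g"],
                "initial_clustering": [10],
                "largest_cluster": [10],
                "after_full_analysis": [12],
            }
        )
        with pytest.raises(ValueError, match="conservation"):
            survival_table(df)
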