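import numpy as np
import pytest
from scipy import stats as sps

import edlib
from rocits import simulate as sim
from rocits.config import ConstructModel, PipelineConfig


def brute_edit_distance(a: str, b: str) -> int:
    """Full O(nm) DP, independent of the alignment library."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i] + [0] * len(b)
        for j, cb in enumerate(b, 1):
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb))
        prev = cur
    return prev[-1]


class TestMakeRrnSet:
    def test_single_copy_is_base(self):
        assert sim.make_rrn_set("ACGT" * 20, 1, None, 0) == ["ACGT" * 20]

    def test_snp_copies_distinct_by_brute_force(self):
        base = sim.make_template(np.random.default_rng(0))[0][:80]
        copies = sim.make_rrn_set(base, 7, [1, 2, 1, 2, 2, 1], 1)
        assert len(copies) == 7
        for i in range(7):
            for j in range(i + 1, 7):
                assert brute_edit_distance(copies[i], copies[j]) >= 1

    def test_duplicate_request_yields_exact_multiset(self):
        # two identical copies plus a third differing by a 2-base deletion
        base = sim.make_template(np.random.default_rng(1))[0]
        copies = sim.make_rrn_set(base, 3, [("dup", 0), [("del", 2)]], 2)
        assert copies[0] == copies[1] == base
        assert len(copies[2]) == len(base) - 2
        assert brute_edit_distance(copies[2][:200], base[:200]) <= 2

    def test_oversized_edit_rejected(self):
        with pytest.raises(ValueError):
            sim.make_rrn_set("ACGTACGT", 2, [[("del", 100)]], 0)


class TestConcatemerRead:
    def test_error_free_layout(self, cfg, template):
        base, _ = template
        rec, truth = sim.simulate_concatemer_read(
            base, cfg.construct, 5, ("ACGTT", "TTAGC"),
            sim.ErrorModel.error_free(), 0, orientation="+",
        )
        unit = cfg.construct.unit(base, "ACGTT", "TTAGC")
        expected = cfg.construct.splint + (unit + cfg.construct.splint) * 5
        assert rec.seq == expected
        assert truth["splint_starts"] == [
            i * (len(unit) + len(cfg.construct.splint)) for i in range(6)
        ]

    def test_k0_is_splint_only(self, cfg, template):
        rec, truth = sim.simulate_concatemer_read(
            template[0], cfg.construct, 0, ("AAAAA", "CCCCC"),
            sim.ErrorModel.error_free(), 0, orientation="+",
        )
        assert rec.seq == cfg.construct.splint
        assert truth["k"] == 0

    def test_subread_identity_98_pct(self, cfg, template):
        """Alignment of noisy sub-read spans to the template gives ~98%
        identity with ~1% spread under the default error model."""
        base, _ = template
        construct = cfg.construct
        unit = construct.unit(base, "ACGTT", "TTAGC")
        rng = np.random.default_rng(5)
        idents = []
        for i in range(200):
            noisy = sim.apply_errors(unit, sim.ErrorModel(), rng)
            ed = edlib.align(noisy, unit)["editDistance"]
            idents.append(1 - ed / len(unit))
        idents = np.array(idents)
        assert 0.97 <= idents.mean() <= 0.99
        assert 0.004 <= idents.std() <= 0.02

    def test_fixed_seed_is_deterministic(self, cfg, template):
        runs = []
        spec = sim.CommunitySpec(
            [sim.TaxonSpec("t", 1.0, [template[0]])]
        )
        for _ in range(2):
            recs, truth = sim.simulate_community_run(spec, 5, rng_seed=42)
            runs.append(([r.seq for r in recs], truth.to_csv()))
        assert runs[0] == runs[1]


class TestCommunityRun:
    def test_abundance_sampling_within_binomial_ci(self, template):
        base, its = template
        other = sim.make_rrn_set(base, 2, [4], 0, its_start=its)[1]
        spec = sim.CommunitySpec(
            [sim.TaxonSpec("major", 100.0, [base]),
             sim.TaxonSpec("minor", 1.0, [other])]
        )
        # sampling only: k=0 keeps the reads trivial
        recs, truth = sim.simulate_community_run(
            spec, 2000, error=sim.ErrorModel.error_free(), k_p=0.9, rng_seed=3
        )
        n_major = int((truth.taxon == "major").sum())
        lo, hi = sps.binom.interval(0.99, 2000, 100 / 101)
        assert lo <= n_major <= hi

    def test_chimera_rate_zero_and_ci(self, template):
        base, its = template
        other = sim.make_rrn_set(base, 2, [4], 0, its_start=its)[1]
        spec = sim.CommunitySpec([sim.TaxonSpec("a", 1.0, [base, other])])
        _, truth0 = sim.simulate_community_run(
            spec, 200, error=sim.ErrorModel.error_free(), chimera_rate=0.0,
            k_p=0.9, rng_seed=4,
        )
        assert truth0.is_chimera.sum() == 0
        _, truth1 = sim.simulate_community_run(
            spec, 1000, error=sim.ErrorModel.error_free(), chimera_rate=0.1,
            k_p=0.9, rng_seed=5,
        )
        lo, hi = sps.binom.interval(0.99, 1000, 0.1)
        assert lo <= truth1.is_chimera.sum() <= hi

    def test_empty_spec_rejected(self):
        with pytest.raises(ValueError):
            sim.CommunitySpec([])


class TestErrorModel:
    def test_realized_rates_match_model(self, template):
        base, _ = template
        em = sim.ErrorModel(0.01, 0.005, 0.005, 1.0, 0.0)
        rng = np.random.default_rng(6)
        eds = [
            edlib.align(sim.apply_errors(base, em, rng), base)["editDistance"]
            for _ in range(100)
        ]
        realized = np.mean(eds) / len(base)
        # alignment can reconcile some errors, so allow a one-sided slack
        assert 0.014 <= realized <= 0.021

    def test_homopolymer_multiplier_concentrates_indels(self):
        seq = ("ACGT" * 10 + "AAAAAAAA" + "CGTA" * 10) * 40
        em = sim.ErrorModel(0.0, 0.01, 0.01, 6.0, 0.0)
        rng = np.random.default_rng(7)
        noisy, coord = sim.apply_errors(seq, em, rng, return_map=True)
        lens = np.diff(coord)
        runs = sim._homopolymer_mask(np.array(list(seq)))
        rate_in = np.abs(lens[runs] - 1).mean()
        rate_out = np.abs(lens[~runs] - 1).mean()
        assert rate_in > 3 * rate_out

    def test_coordinate_map_monotone(self, template):
        base, _ = template
        noisy, coord = sim.apply_errors(
            base, sim.ErrorModel(), np.random.default_rng(8), return_map=True
        )
        assert coord[0] == 0 and coord[-1] == len(noisy)
        assert (np.diff(coord) >= 0).all()


def test_synthetic_genome_structures():
    ecoli = sim.ecoli_like_rrn_set(7)
    assert len(ecoli) == 7 and len(set(ecoli)) == 7
    bacillus = sim.bacillus_like_rrn_set(10)
    names = [n for n, _ in bacillus]
    seqs = {n: s for n, s in bacillus}
    assert names == list("ABCDEFGHIJ")
    assert len(set(seqs.values())) == 9
    assert seqs["F"] == seqs["G"]
    assert len(seqs["I"]) == len(seqs["F"]) - 2
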