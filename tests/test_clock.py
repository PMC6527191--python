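import numpy as np
import pytest

from helpers import greedy_families_from_table

from ltrpopgen.clock import (
    FamilyRule,
    greedy_families,
    mean_pairwise_pdistance,
    pairwise_identity,
    time_of_insertion,
    undatable,
)
from ltrpopgen.io import InputError
from ltrpopgen.simulate import simulate_family_set, simulate_ltr_pair


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        seq = "ACGT" * 25
        ident, overlap, cov = pairwise_identity(seq, seq)
        assert ident == 1.0
        assert overlap == 100
        assert cov == 1.0

    def test_single_mismatch(self):
        ident, overlap, cov = pairwise_identity("ACGT", "ACGA")
        assert ident == 0.75
        assert overlap == 4

    def test_prefix_coverage_against_longer(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), size=100))
        ident, overlap, cov = pairwise_identity(seq, seq[:50])
        assert ident == 1.0
        assert overlap == 50
        assert cov == 0.5  # denominator is the longer sequence

    def test_empty_sequence_rejected(self):
        with pytest.raises(InputError, match="empty"):
            pairwise_identity("", "ACGT")


class TestTimeOfInsertion:
    def test_identical_ltrs_age_zero(self):
        age = time_of_insertion(1.0)
        assert age.divergence == 0.0
        assert age.age_years == 0.0

    def test_one_million_years(self):
        age = time_of_insertion(1.0 - 0.026, rate=1.3e-8)
        assert age.age_years == pytest.approx(1_000_000.0)

    def test_reported_element_age(self):
        # k = 0.10998 at the grass intergenic rate dates to 4.23 my
        age = time_of_insertion(1.0 - 0.10998, rate=1.3e-8)
        assert round(age.age_my, 2) == 4.23

    def test_linear_in_rate(self):
        a1 = time_of_insertion(0.95, rate=1.3e-8)
        a2 = time_of_insertion(0.95, rate=0.65e-8)
        assert a2.age_years == pytest.approx(2 * a1.age_years)

    def test_validation(self):
        with pytest.raises(ValueError):
            time_of_insertion(1.5)
        with pytest.raises(ValueError):
            time_of_insertion(0.9, rate=0.0)

    def test_undatable_flag(self):
        age = undatable("e1")
        assert age.dating_unavailable
        assert age.age_years is None and age.age_my is None


class TestMeanPairwisePdistance:
    def test_identical(self):
        assert mean_pairwise_pdistance(["AAAA", "AAAA"]) == (0.0, 0.0)

    def test_half_diverged(self):
        mean, sd = mean_pairwise_pdistance(["AAAA", "AATT"])
        assert mean == 0.5

    def test_three_sequences(self):
        # pairwise distances {0.25, 0.5, 0.25} -> mean 1/3
        rows = ["AAAA", "AAAT", "AATT"]  # distances 1/4, 2/4, 1/4
        mean, sd = mean_pairwise_pdistance(rows)
        assert mean == pytest.approx(1.0 / 3.0)

    def test_pairwise_deletion(self):
        # gap columns are dropped per pair: compare only columns 3-4
        mean, _ = mean_pairwise_pdistance(["--AT", "GGAA"])
        assert mean == 0.5

    def test_zero_comparable_pair_warns(self):
        with pytest.warns(UserWarning, match="zero comparable"):
            mean, _ = mean_pairwise_pdistance(["A--A", "-GG-", "AGGA"])

    def test_order_invariance(self):
        rng = np.random.default_rng(8)
        rows = ["".join(rng.choice(list("ACDE-"), size=30)) for _ in range(6)]
        base = mean_pairwise_pdistance(rows)
        shuffled = list(rows)
        rng.shuffle(shuffled)
        assert mean_pairwise_pdistance(shuffled) == pytest.approx(base)


def _mutate_at(seq, positions, alphabet="ACGT"):
    out = list(seq)
    for p in positions:
        out[p] = alphabet[(alphabet.index(out[p]) + 1) % 4]
    return "".join(out)


class TestGreedyFamilies:
    def test_identical_pair_one_family(self):
        seq = "ACGT" * 25
        fa = greedy_families({"a": seq, "b": seq})
        assert fa.n_families == 1

    def test_short_identical_pair_two_families(self):
        # 70 bp < 80 bp overlap floor
        seq = "ACGT" * 17 + "AC"
        assert len(seq) == 70
        fa = greedy_families({"a": seq, "b": seq})
        assert fa.n_families == 2

    def test_chain_breaks_at_representative(self):
        # A~B 85%, B~C 85%, A~C 75%: B joins A's family, C fails vs the
        # representative A and founds its own
        rng = np.random.default_rng(17)
        a = "".join(rng.choice(list("ACGT"), size=100))
        b = _mutate_at(a, range(0, 15))        # 85% vs A
        c = _mutate_at(a, range(15, 40))       # 75% vs A, 60% vs B
        fa = greedy_families({"A": a, "B": b, "C": c})
        assert fa.family_of["A"] == fa.family_of["B"]
        assert fa.family_of["C"] != fa.family_of["A"]
        assert fa.representatives[fa.family_of["A"]] == "A"
        assert fa.representatives[fa.family_of["C"]] == "C"

    def test_input_order_stability(self):
        seqs, _ = simulate_family_set(3, 3, length=300, seed=5)
        base = greedy_families(seqs)
        reordered = dict(reversed(list(seqs.items())))
        again = greedy_families(reordered)
        assert base.family_of == again.family_of
        assert base.representatives == again.representatives

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_table_driven_oracle(self, seed):
        rng = np.random.default_rng(seed)
        seqs, _ = simulate_family_set(
            int(rng.integers(1, 4)), int(rng.integers(1, 4)),
            length=int(rng.integers(100, 300)), seed=seed + 100,
        )
        ids = list(seqs)
        rule = FamilyRule()
        match = {}
        for x in ids:
            for y in ids:
                ident, ov, cov = pairwise_identity(seqs[x], seqs[y])
                match[(x, y)] = rule.matches(ident, ov, cov)
        family_of, reps = greedy_families_from_table(
            ids, {s: len(seqs[s]) for s in ids}, match
        )
        fa = greedy_families(seqs)
        assert fa.family_of == family_of
        assert fa.representatives == reps

    def test_planned_families_recovered(self):
        seqs, plan = simulate_family_set(
            3, 4, within_identity=0.95, between_identity=0.5,
            length=500, seed=21,
        )
        fa = greedy_families(seqs)
        assert fa.n_families == 3
        # same plan <=> same inferred family
        for x in seqs:
            for y in seqs:
                assert (fa.family_of[x] == fa.family_of[y]) == \
                    (plan[x] == plan[y])

    def test_rule_validation(self):
        with pytest.raises(ValueError):
            FamilyRule(min_identity=0.0)
        with pytest.raises(ValueError):
            FamilyRule(min_overlap_bp=0)


class TestSimulatedPairsRoundTrip:
    def test_dating_simulated_pair(self):
        # d = 0.026 over long LTRs dates to ~1 my under the default rate
        ages = []
        for seed in range(20):
            l5, l3, _ = simulate_ltr_pair(10_000, 0.026, seed=seed)
            ident, _, _ = pairwise_identity(l5, l3)
            ages.append(time_of_insertion(ident).age_my)
        assert np.mean(ages) == pytest.approx(1.0, abs=0.05)
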