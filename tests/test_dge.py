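"""DGE: tag extraction/mapping oracles, TPM, strata, exact two-library test."""

import numpy as np
import pytest
from scipy.special import gammaln
from scipy.stats import binomtest

from epimark.dge import (
    DEFAULT_PICK,
    _binom_two_sided,
    build_tag_reference,
    differential_expression,
    extract_tags,
    map_tags_to_genes,
    pick_strata,
    stratify_by_expression,
    tpm_normalize,
)


def random_transcript(rng, length):
    return "".join(rng.choice(list("ACGT"), size=length))


def brute_force_sites(seq):
    """All CATG positions with >= 17 bp downstream, 3'-most first."""
    return [
        i for i in range(len(seq) - 21, -1, -1) if seq[i : i + 4] == "CATG"
    ]


def hamming(a, b):
    return sum(x != y for x, y in zip(a, b))


class TestExtraction:
    def test_single_site(self):
        tags = extract_tags("AACATGTTTTTTTTTTTTTTTTTAA")
        assert [t.sequence for t in tags] == ["CATGTTTTTTTTTTTTTTTTT"]

    def test_three_prime_site_without_room_falls_back(self):
        # last CATG has only 10 bp downstream; the earlier site is used
        seq = "CATG" + "A" * 17 + "CATG" + "G" * 10
        (tag,) = extract_tags(seq)
        assert tag.sequence == "CATG" + "A" * 17

    def test_no_qualifying_site_is_empty(self):
        assert extract_tags("A" * 30) == []
        assert extract_tags("TTTCATGAA") == []  # too short downstream

    def test_mode_all_ranks_from_three_prime(self):
        seq = ("CATG" + "A" * 17) + ("CATG" + "C" * 17) + ("CATG" + "G" * 17)
        tags = extract_tags(seq, mode="all")
        assert [t.site_rank for t in tags] == [1, 2, 3]
        assert tags[0].sequence == "CATG" + "G" * 17  # rank 1 = 3'-most

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_scan(self, seed):
        rng = np.random.default_rng(seed)
        seq = random_transcript(rng, int(rng.integers(21, 400)))
        sites = brute_force_sites(seq)
        tags = extract_tags(seq, mode="all")
        assert [t.sequence for t in tags] == [seq[i : i + 21] for i in sites]


class TestMapping:
    REF = {
        "g1": {"CATG" + "A" * 17},
        "g2": {"CATG" + "C" * 17},
        "g3": {"CATG" + "A" * 16 + "C"},  # 1 mismatch from g1's tag
    }

    def test_exact_unique(self):
        counts, amb, unm = map_tags_to_genes(["CATG" + "C" * 17], self.REF)
        assert (counts, amb, unm) == ({"g2": 1}, 0, 0)

    def test_exact_tie_is_ambiguous(self):
        ref = {"g1": {"CATG" + "A" * 17}, "g2": {"CATG" + "A" * 17}}
        counts, amb, unm = map_tags_to_genes(["CATG" + "A" * 17], ref)
        assert (counts, amb, unm) == ({}, 1, 0)

    def test_one_mismatch_tie_is_ambiguous(self):
        # observed tag is 1 mismatch from both g1 and g3, exact to neither
        tag = "CATG" + "A" * 16 + "G"
        counts, amb, unm = map_tags_to_genes([tag], self.REF)
        assert (counts, amb, unm) == ({}, 1, 0)

    def test_exact_beats_mismatch(self):
        # g1 exact; also 1 mismatch from g3 — the exact tier wins alone
        counts, amb, unm = map_tags_to_genes(["CATG" + "A" * 17], self.REF)
        assert (counts, amb, unm) == ({"g1": 1}, 0, 0)

    def test_non_acgt_unmapped(self):
        counts, amb, unm = map_tags_to_genes(["CATG" + "N" * 17], self.REF)
        assert (counts, amb, unm) == ({}, 0, 1)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_hamming_brute_force(self, seed):
        rng = np.random.default_rng(1000 + seed)
        transcripts = {
            f"g{i}": random_transcript(rng, 120) for i in range(40)
        }
        ref = build_tag_reference(transcripts, mode="all")
        ref_tags = [(g, t) for g, tags in ref.items() for t in tags]
        if not ref_tags:
            pytest.skip("no CATG sites in random draw")
        observed = []
        for _ in range(100):
            _, t = ref_tags[rng.integers(len(ref_tags))]
            t = list(t)
            if rng.random() < 0.6:  # mutate up to 2 positions
                for _ in range(rng.integers(1, 3)):
                    t[rng.integers(21)] = "ACGT"[rng.integers(4)]
            observed.append("".join(t))
        counts, amb, unm = map_tags_to_genes(observed, ref)
        expect, e_amb, e_unm = {}, 0, 0
        for t in observed:
            best = {0: set(), 1: set()}
            for g, rt in ref_tags:
                d = hamming(t, rt)
                if d <= 1:
                    best[d].add(g)
            genes = best[0] or best[1]
            if len(genes) == 1:
                g = next(iter(genes))
                expect[g] = expect.get(g, 0) + 1
            elif len(genes) > 1:
                e_amb += 1
            else:
                e_unm += 1
        assert (counts, amb, unm) == (expect, e_amb, e_unm)

    def test_conservation_and_permutation_invariance(self, rng):
        ref = self.REF
        obs = (["CATG" + "A" * 17] * 3 + ["CATG" + "C" * 17] * 2
               + ["CATG" + "T" * 17] + ["CATG" + "A" * 16 + "G"])
        counts, amb, unm = map_tags_to_genes(obs, ref)
        assert sum(counts.values()) + amb + unm == len(obs)
        perm = [obs[i] for i in rng.permutation(len(obs))]
        assert map_tags_to_genes(perm, ref) == (counts, amb, unm)


class TestTpmAndStrata:
    def test_tpm_examples(self):
        assert tpm_normalize({"a": 5}, 1_000_000)["a"] == 5.0
        got = tpm_normalize({"a": 10, "b": 30, "c": 60}, 100)
        assert got == {"a": 1e5, "b": 3e5, "c": 6e5}
        assert sum(got.values()) == pytest.approx(1e6)

    def test_tpm_zero_total_is_error(self):
        with pytest.raises(ValueError):
            tpm_normalize({"a": 1}, 0)

    def test_equal_sets_and_ordering(self):
        tpm = {f"g{i}": float(100 - i) for i in range(20)}
        sets = stratify_by_expression(tpm, n_sets=4)
        assert [len(s) for s in sets] == [5, 5, 5, 5]
        assert sets[0] == [f"g{i}" for i in range(5)]  # top TPM first

    def test_tie_break_is_deterministic_by_gene_id(self):
        tpm = {g: 1.0 for g in "edcba"}
        sets = stratify_by_expression(tpm, n_sets=5)
        assert [s[0] for s in sets] == ["a", "b", "c", "d", "e"]

    def test_seven_thousand_genes_ten_sets_of_700(self, rng):
        tpm = {f"g{i:04d}": float(v) for i, v in enumerate(rng.lognormal(4, 1.5, 7000))}
        sets = stratify_by_expression(tpm, n_sets=10)
        assert [len(s) for s in sets] == [700] * 10
        picked = pick_strata(sets)
        assert set(picked) == set(DEFAULT_PICK)
        assert picked["silent"] == sets[9]

    def test_silent_by_zero_tpm_flag(self):
        tpm = {"a": 5.0, "b": 0.0, "c": 1.0, "d": 0.0}
        sets = stratify_by_expression(tpm, n_sets=2)
        picked = pick_strata(sets, {"high": 0, "silent": 1}, silent_by_zero_tpm=tpm)
        assert picked["silent"] == ["b", "d"]


def audic_claverie_logpmf(y, x, n1, n2):
    """Direct log-space evaluation of the two-library posterior predictive."""
    t = n2 / n1
    return (
        y * np.log(t)
        + gammaln(x + y + 1)
        - gammaln(x + 1)
        - gammaln(y + 1)
        - (x + y + 1) * np.log1p(t)
    )


class TestDifferentialExpression:
    def test_double_zero_is_null(self):
        (r,) = differential_expression({"g": 0}, 100, {"g": 0}, 100)
        assert (r.p_value, r.significant) == (1.0, False)
        assert r.log2_ratio == 0.0

    def test_equal_counts_equal_totals(self):
        (r,) = differential_expression({"g": 100}, 10_000, {"g": 100}, 10_000)
        assert r.log2_ratio == 0.0
        assert not r.significant
        assert r.p_value > 0.5

    def test_tail_sum_matches_direct_formula(self):
        # equal totals, x=0 observed in A, y=5 in B: two-sided p from the
        # conditional test equals the direct tail sum of the Audic-Claverie
        # predictive (they coincide at equal library sizes)
        (r,) = differential_expression({"g": 0}, 1_000, {"g": 5}, 1_000)
        upper = np.exp([audic_claverie_logpmf(yy, 0, 1_000, 1_000) for yy in range(5, 200)]).sum()
        assert r.p_value == pytest.approx(2 * upper, rel=1e-6)
        assert r.p_value == pytest.approx(2 ** -5 * 2, rel=1e-6)

    def test_vectorized_two_sided_matches_scipy(self, rng):
        n = rng.integers(1, 400, size=60)
        x = np.array([rng.integers(0, nn + 1) for nn in n])
        for p in (0.5, 0.3, 0.72):
            got = _binom_two_sided(x, n, p)
            expect = [binomtest(int(xx), int(nn), p).pvalue for xx, nn in zip(x, n)]
            assert got == pytest.approx(expect, rel=1e-9)

    def test_swap_symmetry(self, rng):
        a = {f"g{i}": int(c) for i, c in enumerate(rng.poisson(40, 50))}
        b = {f"g{i}": int(c) for i, c in enumerate(rng.poisson(40, 50))}
        fwd = differential_expression(a, 3_000, b, 4_500)
        rev = differential_expression(b, 4_500, a, 3_000)
        for rf, rr in zip(fwd, rev):
            assert rf.log2_ratio == pytest.approx(-rr.log2_ratio, abs=1e-12)
            assert rf.p_value == pytest.approx(rr.p_value, abs=1e-10)

    def test_joint_rule_requires_both_thresholds(self):
        # large fold with tiny counts: ratio passes, p cannot
        res = differential_expression({"g": 2, "h": 4000}, 10_000, {"g": 0, "h": 4000}, 10_000)
        by = {r.gene_id: r for r in res}
        assert abs(by["g"].log2_ratio) >= 1 and not by["g"].significant

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            differential_expression({"g": -1}, 10, {"g": 1}, 10)
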