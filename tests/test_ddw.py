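"""Word-instance enumeration, conservation, KS testing, and PWM matching."""

import math
from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chipdiv.ddw import (
    PWM,
    ConservationChecker,
    canonical,
    ddw_scan,
    discover_ddws,
    enumerate_instances,
    ks_two_sample,
    pwm_ln_pvalue,
    read_pwm_file,
    revcomp,
)

from conftest import make_aln, make_block


class TestEnumerateInstances:
    def test_planted_forward_occurrence(self):
        seqs = {"chr2L": "T" * 40 + "AAACCCG" + "T" * 53}
        inst = enumerate_instances("AAACCCG", [("chr2L", 0, 100)], seqs)
        assert len(inst) == 1
        assert inst[0].position == 40 and inst[0].strand == "+"

    def test_reverse_complement_occurrence(self):
        word = "AACCGGT"
        seqs = {"chr2L": "T" * 40 + revcomp(word) + "T" * 53}
        inst = enumerate_instances(word, [("chr2L", 0, 100)], seqs)
        assert len(inst) == 1 and inst[0].strand == "-"

    def test_softmasked_instance_excluded(self):
        seqs = {"chr2L": "T" * 40 + "ACGtACG" + "T" * 53}
        assert enumerate_instances("ACGTACG", [("chr2L", 0, 100)], seqs) == []


class TestInstanceConservation:
    def checker(self, mel_row, yak_row):
        aln = make_aln(make_block(mel_row, yak_row))
        seqs = {"chr2L": mel_row.replace("-", "")}
        return ConservationChecker(aln, "mel", seqs)

    def word_arr(self, w):
        return np.frombuffer(w.encode(), dtype=np.uint8).reshape(1, -1)

    def test_identical_bases_conserved(self):
        ck = self.checker("TTACGTACGTT", "TTACGTACGTT")
        assert ck.conserved("chr2L", np.array([2]), self.word_arr("ACGTACG"))[0]

    def test_single_substitution_diverged(self):
        ck = self.checker("TTACGTACGTT", "TTACGAACGTT")
        assert not ck.conserved(
            "chr2L", np.array([2]), self.word_arr("ACGTACG")
        )[0]

    def test_gap_inside_word_diverged(self):
        ck = self.checker("TTACGTACGTT", "TTACG-ACGTT")
        assert not ck.conserved(
            "chr2L", np.array([2]), self.word_arr("ACGTACG")
        )[0]

    def test_unaligned_instance_diverged(self):
        mel = "TTACGTACGTT" + "A" * 20
        yak = "TTACGTACGTT" + "-" * 20
        ck = self.checker(mel, yak)
        assert not ck.conserved("chr2L", np.array([15]), self.word_arr("AAAAA"))[0]


class TestKsTwoSample:
    def brute_D(self, a, b):
        pts = np.concatenate([a, b])
        return max(
            abs((a <= t).mean() - (b <= t).mean()) for t in pts
        )

    def test_identical_samples(self):
        d, p = ks_two_sample([1.0, 2, 3], [1.0, 2, 3])
        assert d == 0.0 and p > 0.99

    def test_disjoint_supports(self):
        d, p = ks_two_sample([0.0, 1.0], [2.0, 3.0])
        assert d == 1.0

    @settings(max_examples=40, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_statistic_matches_brute_force_ecdf(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, rng.integers(5, 40))
        b = rng.normal(0.3, 1.2, rng.integers(5, 40))
        d, _ = ks_two_sample(a, b)
        assert d == pytest.approx(self.brute_D(a, b))

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])


def build_direction(seqs_by_genome, aln, genome):
    return ConservationChecker(aln, genome, seqs_by_genome[genome])


class TestDdwScan:
    def _paired_dataset(self, rng, n=300, effect=2.0, word="ACGTACG"):
        """Identical 100 bp windows in both genomes except that half the
        planted word instances are knocked out in yak; knockouts add
        `effect` to the peak's divergence value."""
        k = len(word)
        mel_parts, yak_parts, divs, wins = [], [], [], []
        pos = 0
        for i in range(n):
            core = "".join(rng.choice(list("ACGT"), 100))
            has = rng.random() < 0.7
            lost = has and rng.random() < 0.5
            if has:
                off = int(rng.integers(0, 100 - k))
                core = core[:off] + word + core[off + k :]
                ycore = (
                    core[:off] + "T" * k + core[off + k :] if lost else core
                )
            else:
                ycore = core
            mel_parts.append(core)
            yak_parts.append(ycore)
            wins.append(("chr2L", pos, pos + 100))
            divs.append(rng.normal(0, 1) + (effect if lost else 0.0))
            pos += 100
        mel = "".join(mel_parts)
        yak = "".join(yak_parts)
        aln = make_aln(make_block(mel, yak))
        seqs = {"mel": {"chr2L": mel}, "yak": {"chr2L": yak}}
        return seqs, aln, wins, np.array(divs)

    def test_planted_effect_word_detected(self):
        rng = np.random.default_rng(0)
        seqs, aln, wins, divs = self._paired_dataset(rng)
        ck = build_direction(seqs, aln, "mel")
        results, cands = ddw_scan(7, wins, divs, ck)
        assert canonical("ACGTACG") in cands

    def test_revcomp_symmetric_result(self):
        rng = np.random.default_rng(1)
        seqs, aln, wins, divs = self._paired_dataset(rng)
        ck = build_direction(seqs, aln, "mel")
        results, _ = ddw_scan(7, wins, divs, ck)
        # every result is indexed by the canonical form: scanning the word
        # or its reverse complement must address the same entry
        w = canonical("ACGTACG")
        assert w in results
        assert canonical(revcomp(w)) == w

    def test_null_candidate_rate_near_alpha(self):
        # sequence divergence but word-independent divergence values: the
        # candidate fraction stays near the KS type-I rate
        rng = np.random.default_rng(2)
        n = 2000
        mel = rng.choice(list("ACGT"), 100 * n)
        yak = mel.copy()
        hit = rng.random(yak.size) < 0.05
        yak[hit] = rng.choice(list("ACGT"), int(hit.sum()))
        mel_s, yak_s = "".join(mel), "".join(yak)
        aln = make_aln(make_block(mel_s, yak_s))
        seqs = {"mel": {"chr2L": mel_s}, "yak": {"chr2L": yak_s}}
        wins = [("chr2L", i * 100, (i + 1) * 100) for i in range(n)]
        divs = rng.normal(0, 1, n)
        ck = build_direction(seqs, aln, "mel")
        results, cands = ddw_scan(6, wins, divs, ck, min_count=10)
        assert len(results) > 1000
        rate = len(cands) / len(results)
        assert rate < 0.04  # ~alpha, generously bounded

    def test_absent_word_skipped(self):
        seqs = {"mel": {"chr2L": "A" * 200}, "yak": {"chr2L": "A" * 200}}
        aln = make_aln(make_block("A" * 200, "A" * 200))
        ck = build_direction(seqs, aln, "mel")
        results, cands = ddw_scan(
            7, [("chr2L", 0, 100)], np.array([0.0]), ck
        )
        assert canonical("ACGTACG") not in results

    def test_intersection_of_directions(self):
        assert discover_ddws({"A", "B"}, {"B", "C"}) == {"B"}


class TestPwm:
    def one_hot(self, word):
        probs = np.zeros((4, len(word)))
        for i, b in enumerate(word):
            probs["ACGT".index(b), i] = 1.0
        return PWM("m", probs, pseudocount=1e-9)

    def test_consensus_word_pvalue(self):
        m = pwm_ln_pvalue("TAATCCC", self.one_hot("TAATCCC"))
        assert m.ln_p == pytest.approx(7 * math.log(0.25))
        assert m.matched

    def test_minimum_score_word_has_p_one(self):
        # every column prefers A strongly; all-T scores lowest on both
        # strands is impossible (revcomp of T is A), so use an asymmetric
        # column set where one word attains the global minimum
        probs = np.array(
            [[0.7, 0.7, 0.7, 0.7], [0.1, 0.1, 0.1, 0.1],
             [0.1, 0.1, 0.1, 0.1], [0.1, 0.1, 0.1, 0.1]]
        )
        pwm = PWM("m", probs, pseudocount=0.0)
        # C/G/T all tie for the per-column minimum; CCCC and GGGG both spell
        # a minimal word on + and - strands
        m = pwm_ln_pvalue("CCCC", pwm)
        assert m.ln_p == pytest.approx(0.0)

    def test_dp_matches_enumeration_oracle(self):
        rng = np.random.default_rng(7)
        pwm = PWM("r", rng.dirichlet(np.ones(4), 4).T)
        sc = np.log(pwm.probs / 0.25)

        def score(w):
            return sum(sc["ACGT".index(c), i] for i, c in enumerate(w))

        for _ in range(10):
            word = "".join(rng.choice(list("ACGT"), 4))
            best = 0.0
            for w in (word, revcomp(word)):
                s0 = score(w)
                p = sum(
                    0.25**4
                    for cand in product("ACGT", repeat=4)
                    if score("".join(cand)) >= s0 - 1e-12
                )
                best = min(best, math.log(p))
            m = pwm_ln_pvalue(word, pwm)
            assert m.ln_p == pytest.approx(best, abs=1e-9)

    def test_monotone_in_column_probability(self):
        base = np.full((4, 7), 0.1)
        base[0] = 0.7
        weaker = PWM("w", base)
        stronger_probs = base.copy()
        stronger_probs[0] = 0.9
        stronger_probs[1:] = 1 / 30
        stronger = PWM("s", stronger_probs)
        w = "AAAAAAA"
        assert pwm_ln_pvalue(w, stronger).ln_p <= pwm_ln_pvalue(w, weaker).ln_p

    def test_word_longer_than_pwm_rejected(self):
        with pytest.raises(ValueError):
            pwm_ln_pvalue("AAAAA", self.one_hot("AAAA"))

    def test_pwm_file_round_trip(self, tmp_path):
        path = tmp_path / "pwm.txt"
        path.write_text(
            ">bcd\n"
            "A [ 10  0  1 ]\n"
            "C [  0 10  1 ]\n"
            "G [  0  0  8 ]\n"
            "T [  0  0  0 ]\n"
        )
        (pwm,) = read_pwm_file(path)
        assert pwm.name == "bcd" and pwm.width == 3
        np.testing.assert_allclose(pwm.probs.sum(axis=0), 1.0, atol=1e-9)
        assert (pwm.probs > 0).all()


class TestPwmKmerEnumeration:
    def test_one_hot_hexamer_enumerates_consensus_only(self):
        import numpy as np
        from chipdiv.ddw import enumerate_pwm_kmers

        probs = np.zeros((4, 6))
        for i, b in enumerate("TAATCC"):
            probs["ACGT".index(b), i] = 1.0
        pwm = PWM("m", probs, pseudocount=1e-9)
        # only the consensus reaches ln p = 6 ln(1/4) ~ -8.32 < -8
        hits = enumerate_pwm_kmers(pwm, 6, ln_threshold=-8.0)
        assert hits == [canonical("TAATCC")]


class TestEnrichmentConservationCurves:
    def test_fully_conserved_planted_windows(self):
        import numpy as np
        from chipdiv.ddw import enrichment_conservation_curves

        rng = np.random.default_rng(3)
        word = "AAACCCG"
        parts = []
        wins = []
        for i in range(30):
            core = "".join(rng.choice(list("ACGT"), 100))
            off = int(rng.integers(0, 93))
            core = core[:off] + word + core[off + 7:]
            parts.append(core)
            wins.append(("chr2L", i * 100, (i + 1) * 100))
        seq = "".join(parts) + "T" * 3000
        aln = make_aln(make_block(seq, seq))
        ck = ConservationChecker(aln, "mel", {"chr2L": seq})
        curves, bg = enrichment_conservation_curves(
            {canonical(word)}, wins, np.arange(30.0), ck,
            {"chr2L": len(seq)}, rng, cohort_size=10, stride=5,
            n_background=50,
        )
        assert (curves["frac_peaks_with_ddw"] == 1.0).all()
        assert (curves["frac_instances_conserved"] == 1.0).all()
        # background windows drawn from the wordless tail are rarely hit
        assert bg["n_windows"] == 50
        assert bg["frac_windows_with_ddw"] < 0.5

    def test_empty_ddw_set_rejected(self):
        import numpy as np
        import pytest as _pytest
        from chipdiv.ddw import enrichment_conservation_curves

        with _pytest.raises(ValueError):
            enrichment_conservation_curves(
                set(), [], [], None, {}, np.random.default_rng(0)
            )
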