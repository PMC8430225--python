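"""PWM p-values against enumeration, region definition, scanning, loops."""

import itertools

import numpy as np
import pandas as pd
import pytest

from lncnet import motif as mo
from lncnet.errors import ValidationError
from lncnet.simulate import simulate_sequences

from conftest import make_pair_table


def deterministic_pwm(bases, tf_id="DET", weight=1000.0):
    counts = np.zeros((len(bases), 4))
    for i, b in enumerate(bases):
        counts[i, "ACGT".index(b)] = weight
    return mo.PWMModel.from_counts(tf_id, counts)


def enumerate_scores(pwm):
    words = np.array(list(itertools.product(range(4), repeat=pwm.width)))
    return pwm.log_odds[np.arange(pwm.width)[None, :], words].sum(axis=1)


class TestRegions:
    def test_promoter_arithmetic(self):
        tss = pd.DataFrame({"gene_id": ["L1"], "chrom": ["chr1"], "tss": [5000]})
        (region,) = mo.define_promoters(tss, flank=2000)
        assert (region.start, region.end) == (3000, 7000)
        assert region.role == "promoter" and region.owner_gene == "L1"

    def test_promoter_clipped_at_zero(self):
        tss = pd.DataFrame({"gene_id": ["L1"], "chrom": ["chr1"], "tss": [1000]})
        (region,) = mo.define_promoters(tss, flank=2000)
        assert (region.start, region.end) == (0, 3000)

    def test_shared_tss_two_owners(self):
        tss = pd.DataFrame({"gene_id": ["L1", "L2"], "chrom": ["chr1"] * 2,
                            "tss": [5000, 5000]})
        regions = mo.define_promoters(tss)
        assert {r.owner_gene for r in regions} == {"L1", "L2"}

    def test_negative_tss_rejected(self):
        tss = pd.DataFrame({"gene_id": ["L1"], "chrom": ["chr1"], "tss": [-5]})
        with pytest.raises(ValidationError):
            mo.define_promoters(tss)

    def test_enhancer_assignment_rules(self):
        tss = pd.DataFrame({"gene_id": ["L1"], "chrom": ["chr1"], "tss": [50_000]})
        enh = pd.DataFrame({
            "chrom": ["chr1", "chr1", "chr2"],
            "start": [51_000, 60_000, 60_000],   # 1 kb (inside promoter), 10 kb, wrong chrom
            "end": [51_500, 60_500, 60_500],
        })
        regions = mo.assign_enhancers(enh, tss, min_dist=2000, max_dist=100_000)
        assert len(regions) == 1
        assert regions[0].start == 60_000 and regions[0].role == "enhancer"

    def test_enhancer_bad_distances(self):
        with pytest.raises(ValidationError):
            mo.assign_enhancers(pd.DataFrame(), pd.DataFrame(),
                                min_dist=2000, max_dist=2000)


class TestScorePvalue:
    def test_below_minimum_is_one(self):
        pwm = deterministic_pwm("ACGT")
        assert mo.score_pvalue(pwm, pwm.min_score() - 1) == 1.0

    def test_maximum_score_uniform_background(self):
        pwm = deterministic_pwm("ACGTA")
        assert mo.score_pvalue(pwm, pwm.max_score()) == pytest.approx(0.25 ** 5)

    def test_matches_enumeration_small_widths(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            width = int(rng.integers(3, 7))
            pwm = mo.PWMModel.from_counts(
                f"T{seed}", rng.integers(0, 60, (width, 4)))
            scores = enumerate_scores(pwm)
            for s in rng.choice(scores, 40):
                oracle = float(np.mean(scores >= s - 1e-9))
                assert mo.score_pvalue(pwm, s) == pytest.approx(oracle, abs=1e-6)

    def test_nonincreasing_in_score(self):
        rng = np.random.default_rng(5)
        pwm = mo.PWMModel.from_counts("T", rng.integers(0, 40, (6, 4)))
        grid = np.linspace(pwm.min_score() - 1, pwm.max_score() + 1, 200)
        ps = [mo.score_pvalue(pwm, s) for s in grid]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_lattice_mode_upper_bounds_exact(self):
        rng = np.random.default_rng(6)
        pwm = mo.PWMModel.from_counts("T", rng.integers(0, 40, (8, 4)))
        gran = (pwm.max_score() - pwm.min_score()) / 1000
        for s in np.linspace(pwm.min_score(), pwm.max_score(), 25):
            exact = mo.score_pvalue(pwm, s)
            lattice = mo.score_pvalue(pwm, s, granularity=gran)
            assert lattice >= exact - 1e-12


class TestScanRegions:
    def test_planted_word_hit_with_exact_p(self):
        pwm = deterministic_pwm("ACGTACGT")
        seq = "T" * 10 + "ACGTACGT" + "T" * 30
        region = mo.GenomicRegion("c1", 0, len(seq), owner_gene="L1")
        hits = mo.scan_regions(pwm, {"c1": seq}, [region], p_cutoff=1e-4)
        plus = [h for h in hits if h.strand == "+"]
        assert [h.offset for h in plus] == [10]
        assert plus[0].p == pytest.approx(0.25 ** 8, rel=1e-9)

    def test_uniform_pwm_has_no_hits(self):
        pwm = mo.PWMModel(tf_id="U", freq=np.full((6, 4), 0.25),
                          background=np.full(4, 0.25))
        seq = "ACGT" * 20
        region = mo.GenomicRegion("c1", 0, len(seq), owner_gene="L1")
        assert mo.scan_regions(pwm, {"c1": seq}, [region], p_cutoff=0.5) == []

    def test_minus_strand_hit(self):
        pwm = deterministic_pwm("AACGTTGC")
        rc = "AACGTTGC".translate(str.maketrans("ACGT", "TGCA"))[::-1]
        seq = "A" * 12 + rc + "A" * 20
        region = mo.GenomicRegion("c1", 0, len(seq), owner_gene="L1")
        hits = mo.scan_regions(pwm, {"c1": seq}, [region], p_cutoff=1e-4)
        assert [(h.offset, h.strand) for h in hits] == [(12, "-")]

    def test_reverse_complement_mirror(self):
        rng = np.random.default_rng(8)
        pwm = mo.PWMModel.from_counts("T", rng.integers(0, 30, (5, 4)))
        seq = "".join(rng.choice(list("ACGT"), 60))
        rc = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        reg_f = mo.GenomicRegion("f", 0, 60, owner_gene="L1")
        reg_r = mo.GenomicRegion("r", 0, 60, owner_gene="L1")
        fwd = mo.scan_regions(pwm, {"f": seq}, [reg_f], p_cutoff=0.05)
        rev = mo.scan_regions(pwm, {"r": rc}, [reg_r], p_cutoff=0.05)
        flip = {"+": "-", "-": "+"}
        mirrored = sorted((60 - pwm.width - h.offset, flip[h.strand],
                           round(h.score, 6)) for h in rev)
        assert mirrored == sorted((h.offset, h.strand, round(h.score, 6))
                                  for h in fwd)

    def test_missing_sequence_skipped(self):
        pwm = deterministic_pwm("ACGT")
        region = mo.GenomicRegion("nowhere", 0, 50, owner_gene="L1")
        assert mo.scan_regions(pwm, {}, [region]) == []

    def test_planted_site_recovery_and_background_calibration(self):
        # informative width-10 PWM planted in 50 of 200 synthetic promoters:
        # sensitivity >= 0.95; background hit count matches the DP-predicted
        # tail rate within 3 binomial SDs
        rng = np.random.default_rng(17)
        counts = np.zeros((10, 4))
        counts[np.arange(10), rng.integers(0, 4, 10)] = 100
        pwm = mo.PWMModel.from_counts("TF1", counts)
        seqs, regions, truth = simulate_sequences(
            pwm, n_seq=200, seq_len=500, planted_sites=0, seed=31)
        planted_seqs, planted_regions, planted_truth = simulate_sequences(
            pwm, n_seq=50, seq_len=500, planted_sites=1, seed=32)

        hits = mo.scan_regions(pwm, planted_seqs, planted_regions, p_cutoff=1e-4)
        found = {(h.region.chrom, h.offset) for h in hits}
        recovered = sum((chrom, off) in found
                        for chrom, off, _ in planted_truth.planted_motif_sites)
        assert recovered / len(planted_truth.planted_motif_sites) >= 0.95

        bg_hits = mo.scan_regions(pwm, seqs, regions, p_cutoff=1e-4)
        scores_axis, tail, _ = mo.score_distribution(pwm)
        # achieved per-window tail probability at the p < 1e-4 threshold
        passing = tail[tail < 1e-4]
        rate = float(passing.max()) if passing.size else 0.0
        n_windows = 2 * 200 * (500 - pwm.width + 1)
        expected = n_windows * rate
        sd = np.sqrt(n_windows * rate * (1 - rate))
        assert abs(len(bg_hits) - expected) <= 3 * sd + 1


class TestFeedbackLoops:
    def _hit(self, tf, owner, role):
        region = mo.GenomicRegion("c1", 0, 4000, role=role, owner_gene=owner)
        return mo.MotifHit(tf_id=tf, region=region, offset=5, strand="+",
                           score=12.0, p=1e-5)

    def test_significant_pair_with_promoter_hit(self):
        pairs = make_pair_table([("L1", "T1", True)])
        loops = mo.find_feedback_loops(pairs, [self._hit("T1", "L1", "promoter")])
        assert len(loops) == 1
        assert loops[0].region_roles == frozenset({"promoter"})

    def test_non_significant_pair_no_loop(self):
        pairs = make_pair_table([("L1", "T1", False)])
        assert mo.find_feedback_loops(pairs, [self._hit("T1", "L1", "promoter")]) == []

    def test_hit_without_pair_no_loop(self):
        pairs = make_pair_table([("L1", "T1", True)])
        assert mo.find_feedback_loops(pairs, [self._hit("T2", "L1", "promoter")]) == []

    def test_roles_aggregate(self):
        pairs = make_pair_table([("L1", "T1", True)])
        loops = mo.find_feedback_loops(
            pairs, [self._hit("T1", "L1", "promoter"),
                    self._hit("T1", "L1", "enhancer")])
        assert len(loops) == 1
        assert loops[0].region_roles == frozenset({"promoter", "enhancer"})

    def test_loops_subset_of_significant_pairs(self):
        pairs = make_pair_table([("L1", "T1", True), ("L2", "T2", False)])
        hits = [self._hit("T1", "L1", "promoter"), self._hit("T2", "L2", "promoter")]
        loops = mo.find_feedback_loops(pairs, hits)
        sig = set(zip(pairs[pairs.significant].tf_id, pairs[pairs.significant].lnc_id))
        assert {(lp.tf_id, lp.lnc_id) for lp in loops} <= sig
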