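"""PWM scanning, motif enrichment and positional profiles."""

import numpy as np
import pytest
from scipy.stats import hypergeom

from fitcage import motifs as mf
from fitcage.ctss import TagCluster

CONSENSUS = "TGACGTCA"


def rand_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def region_with_site(rng, site, offset, up=300, down=100):
    """Random -up/+down region with `site` planted at TSS offset `offset`."""
    seq = rand_seq(rng, up + down + 1)
    i = up + offset
    seq = seq[:i] + site + seq[i + len(site):]
    return mf.PromoterRegion("p", seq, up)


def brute_force_best(region, pwm):
    """Offset-by-offset rescore of both strands."""
    best = (-np.inf, None, None)
    lo = pwm.log_odds
    for strand in "+-":
        seq = region.sequence if strand == "+" else mf.reverse_complement(region.sequence)
        for i in range(len(seq) - pwm.width + 1):
            s = sum(lo[k, "ACGTN".index(seq[i + k])] for k in range(pwm.width))
            start = i if strand == "+" else len(seq) - pwm.width - i
            if s > best[0]:
                best = (s, start - region.upstream, strand)
    return best


class TestScanning:
    def test_consensus_scores_two_bits_per_base(self):
        pwm = mf.PWM.from_consensus("m", CONSENSUS)
        region = mf.PromoterRegion("p", CONSENSUS, 0)
        score, offset, strand = mf.best_hit(region, pwm)
        assert score == pytest.approx(2 * pwm.width)  # log2(1/0.25) per base
        assert offset == 0 and strand == "+"

    def test_all_n_region_scores_zero(self):
        pwm = mf.PWM.from_consensus("m", CONSENSUS)
        region = mf.PromoterRegion("p", "N" * 30, 10)
        score, _, _ = mf.best_hit(region, pwm)
        assert score == 0.0

    def test_too_short_region_is_none(self):
        pwm = mf.PWM.from_consensus("m", CONSENSUS)
        assert mf.best_hit(mf.PromoterRegion("p", "ACGT", 0), pwm) is None

    def test_matches_brute_force_oracle(self, rng):
        counts = rng.integers(1, 20, size=(6, 4))
        pwm = mf.PWM.from_counts("m", counts, pseudocount=0.5)
        for _ in range(5):
            region = mf.PromoterRegion("p", rand_seq(rng, 60), 30)
            score, offset, strand = mf.best_hit(region, pwm)
            b_score, b_offset, _ = brute_force_best(region, pwm)
            assert score == pytest.approx(b_score)
            assert score >= b_score - 1e-9

    def test_reverse_complement_invariance(self, rng):
        counts = rng.integers(1, 20, size=(7, 4))
        pwm = mf.PWM.from_counts("m", counts)
        seq = rand_seq(rng, 80)
        fwd = mf.best_hit(mf.PromoterRegion("p", seq, 40), pwm)
        rev = mf.best_hit(mf.PromoterRegion("p", mf.reverse_complement(seq), 40), pwm)
        assert fwd[0] == pytest.approx(rev[0])

    def test_width_validation(self):
        with pytest.raises(ValueError, match="width"):
            mf.PWM.from_consensus("m", "ACG")


class TestExtraction:
    def make_cluster(self, peak, strand):
        return TagCluster("c1", "chr1", peak, peak + 1, strand, peak,
                          np.array([peak]), np.array([10.0]))

    def test_plus_strand_arithmetic(self, small_genome):
        regions = mf.extract_regions([self.make_cluster(1000, "+")], small_genome)
        assert regions[0].sequence == small_genome["chr1"][700:1101]
        assert regions[0].upstream == 300

    def test_minus_strand_is_reverse_complement(self, small_genome):
        regions = mf.extract_regions([self.make_cluster(1000, "-")], small_genome)
        window = small_genome["chr1"][900:1301]
        assert regions[0].sequence == mf.reverse_complement(window)
        assert regions[0].upstream == 300

    def test_edge_truncation(self, small_genome):
        regions = mf.extract_regions([self.make_cluster(50, "+")], small_genome)
        assert len(regions[0].sequence) == 151
        assert regions[0].upstream == 50

    def test_off_chromosome_errors(self, small_genome):
        with pytest.raises(ValueError, match="off chromosome"):
            mf.extract_regions([self.make_cluster(99999, "+")], small_genome)


class TestEnrichment:
    def test_perfect_separation_closed_form(self, rng):
        """A 10/0 vs 0/10 table has Fisher p = 2 / C(20, 10)."""
        pwm = mf.PWM.from_consensus("m", CONSENSUS)
        fg = [region_with_site(rng, CONSENSUS, -50, up=100, down=20) for _ in range(10)]
        bg = [mf.PromoterRegion("p", "A" * 121, 100) for _ in range(10)]
        table = mf.motif_enrichment(fg, bg, [pwm], threshold_fraction=0.99)
        assert table.loc[0, "fg_hits"] == 10 and table.loc[0, "bg_hits"] == 0
        from scipy.special import comb
        assert table.loc[0, "pvalue"] == pytest.approx(2 / comb(20, 10), rel=1e-6)

    def test_null_foreground_not_enriched(self, rng):
        pwm = mf.PWM.from_consensus("m", CONSENSUS)
        pool = [mf.PromoterRegion("p", rand_seq(rng, 200), 150) for _ in range(60)]
        table = mf.motif_enrichment(pool[:20], pool, [pwm])
        assert table.loc[0, "p_bonferroni"] > 0.2

    def test_fisher_matches_hypergeometric_tail_sum(self, rng):
        """Two-sided Fisher p equals the sum of hypergeometric masses no
        larger than the observed one, over random 2x2 tables."""
        from scipy.stats import fisher_exact

        for _ in range(100):
            n_fg, n_bg = rng.integers(5, 40, 2)
            a = int(rng.integers(0, n_fg + 1))
            c = int(rng.integers(0, n_bg + 1))
            _, p = fisher_exact([[a, n_fg - a], [c, n_bg - c]])
            total, hits, draw = n_fg + n_bg, a + c, n_fg
            support = np.arange(max(0, draw - (total - hits)), min(draw, hits) + 1)
            pmf = hypergeom.pmf(support, total, hits, draw)
            obs = hypergeom.pmf(a, total, hits, draw)
            oracle = pmf[pmf <= obs * (1 + 1e-9)].sum()
            assert p == pytest.approx(oracle, rel=1e-6)

    def test_bonferroni_is_capped_and_monotone(self, rng):
        pwms = [mf.PWM.from_counts(f"m{i}", rng.integers(1, 20, size=(6, 4)))
                for i in range(5)]
        regions = [mf.PromoterRegion("p", rand_seq(rng, 100), 50) for _ in range(20)]
        table = mf.motif_enrichment(regions[:8], regions, pwms)
        assert (table["p_bonferroni"] <= 1.0).all()
        np.testing.assert_allclose(
            table["p_bonferroni"], np.minimum(1.0, table["pvalue"] * 5)
        )

    def test_planted_motif_recovered(self, rng):
        """Motif planted in 30% of foreground vs 5% of background reaches
        Bonferroni-adjusted significance."""
        pwm = mf.PWM.from_consensus("m", CONSENSUS)
        decoys = [mf.PWM.from_counts(f"d{i}", rng.integers(1, 20, (8, 4)))
                  for i in range(4)]
        hits = 0
        for seed in range(5):
            r = np.random.default_rng(seed)
            fg = [region_with_site(r, CONSENSUS, -60, 150, 50) if r.random() < 0.3
                  else mf.PromoterRegion("p", rand_seq(r, 201), 150) for _ in range(200)]
            bg = [region_with_site(r, CONSENSUS, -60, 150, 50) if r.random() < 0.05
                  else mf.PromoterRegion("p", rand_seq(r, 201), 150) for _ in range(2000)]
            table = mf.motif_enrichment(fg, bg, [pwm] + decoys, threshold_fraction=0.9)
            row = table[table["motif"] == "m"].iloc[0]
            hits += row["p_bonferroni"] < 0.05
        assert hits == 5

    def test_empty_foreground_errors(self):
        with pytest.raises(ValueError, match="foreground"):
            mf.motif_enrichment([], [], [mf.PWM.from_consensus("m", CONSENSUS)])


class TestPositionalProfile:
    def test_planted_site_peak(self, rng):
        pwm = mf.PWM.from_consensus("m", CONSENSUS)
        regions = [region_with_site(rng, CONSENSUS, -79) for _ in range(40)]
        prof = mf.positional_profile(regions, pwm, threshold_fraction=0.99)
        assert prof.peak_offset == -79
        assert prof.raw[prof.offsets == -79][0] == pytest.approx(1.0)

    def test_no_hits_gives_zero_curve(self):
        pwm = mf.PWM.from_consensus("m", CONSENSUS)
        regions = [mf.PromoterRegion("p", "A" * 401, 300) for _ in range(5)]
        prof = mf.positional_profile(regions, pwm)
        assert prof.raw.sum() == 0 and prof.smoothed.sum() == 0

    def test_coverage_counting_identity(self, rng):
        """With one non-overlapping hit per region, the unsmoothed curve
        integrates to hits-per-region x motif width."""
        pwm = mf.PWM.from_consensus("m", CONSENSUS)
        regions = [region_with_site(rng, CONSENSUS, int(off))
                   for off in rng.integers(-250, 50, size=30)]
        prof = mf.positional_profile(regions, pwm, threshold_fraction=0.99)
        assert prof.raw.sum() == pytest.approx(1.0 * pwm.width, rel=0.05)
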