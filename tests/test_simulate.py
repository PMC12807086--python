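"""Statistical and determinism properties of the signal simulator."""

import numpy as np
import pytest
from scipy.stats import ks_2samp

from methylformer.features import find_cpg_candidates
from methylformer.simulate import (
    LevelModel,
    SimConfig,
    SimResult,
    _taper_weights,
    simulate,
    truth_coverage_report,
)


@pytest.fixture(scope="module")
def small_run():
    return simulate(SimConfig(genome_length=6000, n_reads=12, read_length=800,
                              delta=2.0, noise_sd=0.3, seed=5))


def _center_mean_by_label(result):
    """Mean raw signal of the CpG-centre event, split by read-level label."""
    events = {
        rid: {e.ref_pos: e for e in evs} for rid, evs in result.events_by_read.items()
    }
    meth, unmeth = [], []
    for site in result.labels:
        e = events[site.read_id].get(site.ref_pos)
        if e is None:
            continue
        (meth if site.label == 1 else unmeth).append(float(np.mean(e.samples)))
    return np.array(meth), np.array(unmeth)


class TestDeterminism:
    def test_same_seed_byte_identical_outputs(self, tmp_path):
        cfg = SimConfig(genome_length=2000, n_reads=4, read_length=400, seed=9)
        paths1 = simulate(cfg).write(tmp_path / "a")
        paths2 = simulate(cfg).write(tmp_path / "b")
        for key in paths1:
            assert (tmp_path / "a").with_suffix("").parent  # paths exist
            b1 = open(paths1[key], "rb").read()
            b2 = open(paths2[key], "rb").read()
            assert b1 == b2, f"{key} differs between identically seeded runs"

    def test_level_map_pure_function_of_kmer(self, small_run):
        lm = small_run.level_model
        genome = small_run.genome
        # same k-mer at different genomic positions gets the same level
        levels = lm.sequence_levels(genome)
        seen = {}
        for p in range(3, len(genome) - 3):
            kmer = genome[p - 3 : p + 4]
            if kmer in seen:
                assert levels[p] == seen[kmer]
            seen[kmer] = levels[p]
        assert lm.level(genome[7:14]) == levels[10]

    def test_shared_pore_seed_shares_level_map(self):
        a = simulate(SimConfig(genome_length=1500, n_reads=2, read_length=300, seed=1,
                               pore_seed=42))
        b = simulate(SimConfig(genome_length=2500, n_reads=3, read_length=500, seed=2,
                               pore_seed=42))
        kmer = "ACGTACG"
        assert a.level_model.level(kmer) == b.level_model.level(kmer)


class TestSignalStructure:
    def test_event_sample_counts(self, small_run):
        counts = np.array(
            [len(e.samples) for evs in small_run.events_by_read.values() for e in evs]
        )
        assert counts.min() >= 1
        assert counts.size >= 9600
        assert abs(counts.mean() - 8.0) / 8.0 < 0.05

    def test_methylation_shift_recovered_at_centre_events(self):
        """With delta = 2 the methylated/unmethylated difference of centre-event
        means, recomputed from the emitted samples, is 2.0 +- 0.1."""
        result = simulate(SimConfig(genome_length=32_000, n_reads=40,
                                    read_length=1000, delta=2.0, noise_sd=0.3,
                                    seed=13))
        meth, unmeth = _center_mean_by_label(result)
        assert meth.size >= 1000 and unmeth.size >= 1000
        assert np.mean(meth) - np.mean(unmeth) == pytest.approx(2.0, abs=0.1)

    def test_null_delta_distributions_indistinguishable(self):
        result = simulate(SimConfig(genome_length=32_000, n_reads=32,
                                    read_length=1000, delta=0.0, noise_sd=0.3,
                                    seed=17))
        meth, unmeth = _center_mean_by_label(result)
        assert meth.size >= 500 and unmeth.size >= 500
        assert ks_2samp(meth[:1500], unmeth[:1500]).pvalue > 0.01

    def test_site_meth_fraction_close_to_probability(self, small_run):
        status = small_run.site_status["status"].to_numpy()
        n = status.size
        frac = status.mean()
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_taper_peaks_at_centre(self):
        w = _taper_weights(7)
        assert w[3] == 1.0
        np.testing.assert_allclose(w, [0.25, 0.5, 0.75, 1.0, 0.75, 0.5, 0.25])

    def test_marginal_level_distribution(self):
        rng = np.random.default_rng(0)
        lm = LevelModel(k=7, level_scale=1.0, additive_fraction=0.75, rng=rng)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 20_000))
        levels = lm.sequence_levels(seq)
        assert abs(levels.mean()) < 0.05
        assert abs(levels.std() - 1.0) < 0.05


class TestConsistency:
    def test_outputs_mutually_consistent(self, small_run):
        cfg = small_run.config
        cpgs = set(find_cpg_candidates(small_run.genome, "forward"))
        assert set(small_run.site_status["pos"]) == cpgs
        for site in small_run.labels[:200]:
            assert site.ref_pos in cpgs
            events = small_run.events_by_read[site.read_id]
            assert events[0].ref_pos <= site.ref_pos <= events[-1].ref_pos
        # truth coverage equals the number of reads labeled at each site
        from collections import Counter

        counted = Counter((s.ref_pos) for s in small_run.labels)
        for t in small_run.truth:
            assert t.coverage == counted[t.pos]

    def test_ref_bases_match_genome(self, small_run):
        events = next(iter(small_run.events_by_read.values()))
        for e in events[:50]:
            assert e.ref_base == small_run.genome[e.ref_pos]

    def test_genome_too_short_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(genome_length=100, read_length=400)


class TestCoverageReport:
    def test_no_reads(self):
        result = simulate(SimConfig(genome_length=2000, n_reads=0, read_length=300,
                                    seed=1))
        report = truth_coverage_report(result)
        assert (report["coverage"] == 0).all()

    def test_mean_coverage_matches_lander_waterman(self):
        cfg = SimConfig(genome_length=24_000, n_reads=60, read_length=600, seed=21)
        result = simulate(cfg)
        report = truth_coverage_report(result, window=21)
        # interior sites only (read starts cannot cover the genome tails evenly)
        interior = report[
            (report["pos"] > cfg.read_length) &
            (report["pos"] < cfg.genome_length - cfg.read_length)
        ]
        expected = cfg.n_reads * cfg.read_length / cfg.genome_length
        assert interior["coverage"].mean() == pytest.approx(expected, rel=0.10)

    def test_single_read_interior_site(self):
        result = simulate(SimConfig(genome_length=500, n_reads=1, read_length=500,
                                    seed=2))
        report = truth_coverage_report(result, window=21)
        interior = report[(report["pos"] >= 10) & (report["pos"] < 490)]
        assert (interior["coverage"] == 1).all()


class TestMinusStrand:
    def test_minus_strand_reads_and_sites(self):
        result = simulate(SimConfig(genome_length=4000, n_reads=20, read_length=500,
                                    emit_minus_strand=True, seed=8))
        strands = {evs[0].strand for evs in result.events_by_read.values()}
        assert strands == {"+", "-"}
        assert set(result.site_status["strand"]) == {"+", "-"}
        # minus-strand events carry the complement of the forward base
        comp = str.maketrans("ACGT", "TGCA")
        for evs in result.events_by_read.values():
            if evs[0].strand == "-":
                for e in evs[:20]:
                    assert e.ref_base == result.genome[e.ref_pos].translate(comp)
                break
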