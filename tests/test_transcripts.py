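import numpy as np
import pytest

from phagevo.io_utils import GeneFeature, GenomeRecord, Interval, revcomp
from phagevo.transcripts import (
    CoverageError,
    CoverageTrack,
    classify_temporal,
    detect_abundant_noncoding,
    find_hairpins,
    gene_expression,
    load_bedgraph_pair,
    orf_free_check,
    read_bedgraph,
    transcript_boundaries,
    write_bedgraph,
)
from helpers import random_genome


def track(depth, sample="s", strand="+", lib=1_000_000):
    return CoverageTrack("g", sample, strand, np.asarray(depth, float), lib)


class TestBedgraphIO:
    def test_empty_file_all_zero(self, tmp_path):
        p = tmp_path / "e.bedgraph"
        p.write_text("")
        assert (read_bedgraph(p, 50) == 0).all()

    def test_single_record_one_based_semantics(self, tmp_path):
        p = tmp_path / "one.bedgraph"
        p.write_text("chr\t0\t10\t5\n")
        d = read_bedgraph(p, 20)
        assert (d[:10] == 5).all() and (d[10:] == 0).all()

    def test_roundtrip(self, tmp_path):
        rng = np.random.default_rng(41)
        d = rng.poisson(3, size=500).astype(float)
        p = tmp_path / "rt.bedgraph"
        write_bedgraph(d, "chr", p)
        assert (read_bedgraph(p, 500) == d).all()

    def test_interval_beyond_genome_rejected(self, tmp_path):
        p = tmp_path / "bad.bedgraph"
        p.write_text("chr\t0\t100\t5\n")
        with pytest.raises(CoverageError, match="beyond"):
            read_bedgraph(p, 50)

    def test_pair_loader(self, tmp_path):
        (tmp_path / "p.bedgraph").write_text("g\t0\t5\t2\n")
        (tmp_path / "m.bedgraph").write_text("g\t5\t10\t7\n")
        g = GenomeRecord("g", "A" * 10)
        tracks = load_bedgraph_pair(tmp_path / "p.bedgraph",
                                    tmp_path / "m.bedgraph", g, "t0")
        assert tracks["+"].depth[0] == 2 and tracks["-"].depth[9] == 7


class TestGeneExpression:
    def _feats(self):
        return [GeneFeature("1", 1, 50, "+"), GeneFeature("2", 51, 100, "-")]

    def test_uniform_depth(self):
        tracks = [track(np.full(100, 10.0), strand="+"),
                  track(np.full(100, 10.0), strand="-")]
        expr = gene_expression(tracks, self._feats())
        assert (expr["mean_depth"] == 10).all()
        assert (expr["dpm"] == 10).all()

    def test_strand_matched(self):
        plus = np.zeros(100); plus[:50] = 8
        minus = np.zeros(100); minus[50:] = 4
        expr = gene_expression([track(plus, strand="+"), track(minus, strand="-")],
                               self._feats())
        assert expr.loc[("1", "s"), "mean_depth"] == 8
        assert expr.loc[("2", "s"), "mean_depth"] == 4

    def test_linear_in_depth(self):
        rng = np.random.default_rng(42)
        d = rng.poisson(5, 100).astype(float)
        t1 = [track(d, strand="+"), track(d, strand="-")]
        t2 = [track(2 * d, strand="+"), track(2 * d, strand="-")]
        e1 = gene_expression(t1, self._feats())
        e2 = gene_expression(t2, self._feats())
        assert np.allclose(2 * e1["mean_depth"], e2["mean_depth"])

    def test_missing_strand_rejected(self):
        with pytest.raises(CoverageError, match="strand"):
            gene_expression([track(np.ones(100), strand="+")], self._feats())


class TestClassifyTemporal:
    def _expr(self, values_by_gene, order):
        import pandas as pd
        rows = []
        for gene, vals in values_by_gene.items():
            for s, v in zip(order, vals):
                rows.append({"gene": gene, "sample": s, "strand": "+",
                             "kind": "CDS", "mean_depth": v, "dpm": v})
        return pd.DataFrame(rows).set_index(["gene", "sample"])

    def test_classes(self):
        order = ["15min", "30min", "60min", "150min"]
        expr = self._expr({
            "e": [50, 30, 5, 2],
            "l": [1, 2, 20, 60],
            "c": [10, 11, 12, 10],
            "s": [0.1, 0.2, 0.1, 0.3],
        }, order)
        cls = classify_temporal(expr, order)
        assert cls.to_dict() == {"e": "early", "l": "late",
                                 "c": "constitutive", "s": "silent"}

    def test_trna_excluded(self):
        import pandas as pd
        order = ["15min", "150min"]
        rows = [{"gene": "t", "sample": s, "strand": "+", "kind": "tRNA",
                 "mean_depth": 50, "dpm": 50} for s in order]
        expr = pd.DataFrame(rows).set_index(["gene", "sample"])
        assert classify_temporal(expr, order)["t"] == "excluded"

    def test_unknown_sample_rejected(self):
        order = ["15min", "150min"]
        expr = self._expr({"g": [1, 2]}, order)
        with pytest.raises(CoverageError, match="unknown sample"):
            classify_temporal(expr, ["15min", "bogus"])

    def test_simulated_program_recovered(self, sim, sim_coverage):
        """>=95% of genes get their planted early/late class back."""
        expr = gene_expression(sim_coverage.tracks, sim.layout.features)
        cls = classify_temporal(expr, ["15min", "30min", "60min", "150min"])
        agree = np.mean([cls[g] == c
                         for g, c in sim.layout.expected_classes.items()])
        assert agree >= 0.95

    def test_lysogen_repressor_unit_dominates(self, sim, sim_coverage):
        """In the lysogen sample the repressor unit tops the expression table."""
        expr = gene_expression(sim_coverage.tracks, sim.layout.features)
        lys = expr.xs("lysogen", level="sample")["dpm"].sort_values(
            ascending=False)
        rep = sim.layout.repressor.gene_id
        assert rep in set(lys.index[:3])


class TestAbundantNoncoding:
    def _setup(self, gap_depth, gene_depth=10.0):
        feats = [GeneFeature("1", 1, 300, "-"), GeneFeature("2", 501, 800, "-")]
        d = np.full(800, gene_depth)
        d[300:500] = gap_depth
        return [track(d, strand="-")], feats

    def test_quiet_intergenic_not_reported(self):
        tracks, feats = self._setup(gap_depth=10.0)
        assert detect_abundant_noncoding(tracks, feats) == []

    def test_abundant_intergenic_reported(self):
        tracks, feats = self._setup(gap_depth=100.0)
        regions = detect_abundant_noncoding(tracks, feats)
        assert len(regions) == 1
        r = regions[0]
        assert (r.interval.start, r.interval.end) == (301, 500)
        assert r.rank == 1 and r.peak_depth == 100

    def test_never_overlaps_a_gene(self, sim, sim_coverage):
        regions = detect_abundant_noncoding(sim_coverage.tracks,
                                            sim.layout.features)
        for r in regions:
            for f in sim.layout.features:
                assert not (r.interval.start <= f.end
                            and f.start <= r.interval.end)

    def test_srna_ranks_first_at_every_timepoint(self, sim, sim_coverage):
        srna = sim.layout.srna_interval
        for sample in sim_coverage.spec.samples:
            tracks = [t for t in sim_coverage.tracks if t.sample == sample]
            regions = detect_abundant_noncoding(tracks, sim.layout.features)
            top = regions[0]
            assert top.strand == "-"
            assert (top.interval.start <= srna.start
                    and top.interval.end >= srna.end), sample


class TestBoundaries:
    def test_rectangular_pulse_exact(self):
        d = np.zeros(1000)
        d[99:600] = 1000.0          # 1-based 100..600
        r = transcript_boundaries(track(d), Interval(1, 1000, "+"))
        assert r.rise == 100
        assert r.falloff == 601

    def test_minus_strand_mirrored(self):
        d = np.zeros(1000)
        d[399:900] = 1000.0         # 1-based 400..900
        r = transcript_boundaries(track(d, strand="-"), Interval(1, 1000, "-"))
        assert r.rise == 900
        assert r.falloff == 399

    def test_ramp_steep_rise_inside_ramp(self):
        d = np.zeros(1000)
        ramp = np.linspace(0, 1000, 31)
        d[99:130] = ramp            # 30-bp ramp then plateau
        d[130:600] = 1000.0
        r = transcript_boundaries(track(d), Interval(1, 1000, "+"))
        assert 100 <= r.rise < 130
        assert 100 < r.steep_rise <= 131
        assert r.rise <= r.steep_rise

    def test_all_zero_region_rejected(self):
        with pytest.raises(CoverageError, match="zero"):
            transcript_boundaries(track(np.zeros(100)), Interval(1, 100, "+"))

    def test_simulated_pleft_rise_near_tss_minus_ramp(self, sim):
        """On the noise-free program the 5' rise sits ~ramp below the TSS and
        the falloff at the sRNA 3' end."""
        from phagevo.simulate import CoverageSpec, expected_depth
        cspec = CoverageSpec.default_for(sim.layout)
        mu = expected_depth(len(sim.layout.genome), cspec, "15min", "-")
        t = track(mu, strand="-")
        iv = Interval(sim.layout.srna_interval.start - 200,
                      len(sim.layout.genome), "-")
        r = transcript_boundaries(t, iv)
        tss = sim.layout.promoters[0].tss
        assert r.rise == tss - sim.layout.srna_ramp
        assert r.falloff == sim.layout.srna_interval.start - 1


def brute_force_hairpins(seq, min_stem, min_loop, max_loop, max_mismatch):
    """Independent enumeration over all (stem, loop) placements, keeping the
    best-scoring stem per loop."""
    comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
    best_per_loop = {}
    n = len(seq)
    for loop_start in range(n):
        for loop_len in range(min_loop, max_loop + 1):
            loop_end = loop_start + loop_len
            if loop_end >= n:
                continue
            stem_best = None
            for stem in range(1, min(loop_start, n - loop_end) + 1):
                left = seq[loop_start - stem: loop_start]
                right = seq[loop_end: loop_end + stem]
                mism = sum(1 for a, b in zip(left[::-1], right)
                           if comp.get(a) != b)
                if mism > max_mismatch:
                    break   # growing the stem only adds mismatches at the base
                if stem >= min_stem and comp.get(left[0]) == right[-1]:
                    down = seq[loop_end + stem: loop_end + stem + 8]
                    score = stem - 2 * mism + 0.5 * down.count("T")
                    if stem_best is None or score > stem_best[0]:
                        stem_best = (score, stem, mism)
            if stem_best:
                best_per_loop[(loop_start, loop_len)] = stem_best[1:]
    return best_per_loop


class TestHairpins:
    def test_perfect_stem_found(self):
        stem = "GGGCCCGC"
        g = GenomeRecord("g", "AT" + stem + "TTT" + revcomp(stem) + "TTTTTTTT" + "AT")
        hits = find_hairpins(g, Interval(1, len(g.seq)), min_stem=8)
        assert hits
        top = hits[0]
        assert top.stem == 8 and top.mismatches == 0
        assert top.sequence.startswith(stem)

    def test_poly_a_has_no_hairpins(self):
        g = GenomeRecord("g", "A" * 60)
        assert find_hairpins(g, Interval(1, 60)) == []

    def test_equals_bruteforce_on_random_sequence(self):
        rng = np.random.default_rng(51)
        seq = random_genome(rng, 200, gc=0.6)
        g = GenomeRecord("g", seq)
        hits = find_hairpins(g, Interval(1, 200), min_stem=5, max_loop=6,
                             max_mismatch=1)
        oracle = brute_force_hairpins(seq, 5, 3, 6, 1)
        got = {}
        for h in hits:
            loop_start0 = h.interval.start - 1 + h.stem
            got[(loop_start0, h.loop)] = (h.stem, h.mismatches)
        assert got == oracle

    def test_mismatch_budget_respected(self):
        stem = "GGGCCCGC"
        broken = stem[:3] + "T" + stem[4:]
        g = GenomeRecord("g", "AT" + broken + "TTT" + revcomp(stem) + "AT")
        hits0 = find_hairpins(g, Interval(1, len(g.seq)), min_stem=8,
                              max_mismatch=0)
        hits1 = find_hairpins(g, Interval(1, len(g.seq)), min_stem=8,
                              max_mismatch=1)
        assert hits0 == [] and hits1 and hits1[0].mismatches == 1


class TestOrfFree:
    def test_tandem_stops(self):
        g = GenomeRecord("g", "TAATAGTGA" * 10)
        free, longest = orf_free_check(g, Interval(1, 90))
        assert free and longest == 0

    def test_planted_long_orf(self):
        rng = np.random.default_rng(52)
        orf = "ATG" + "".join(
            rng.choice(["GCT", "GCC", "GAA", "CTG"], size=59)) + "TAA"
        seq = "TTTTT" + orf + "TTTTT"
        g = GenomeRecord("g", seq)
        free, longest = orf_free_check(g, Interval(1, len(seq)))
        assert not free and longest == 60

    def test_matches_bruteforce_orf_scan(self):
        """Longest ORF equals a per-start-codon walk (independent of the
        frame-run bookkeeping the implementation uses)."""
        def oracle_longest(seq):
            starts, stops = ("ATG", "GTG"), ("TAA", "TAG", "TGA")
            best = 0
            for s in (seq, revcomp(seq)):
                for i in range(len(s) - 2):
                    if s[i: i + 3] not in starts:
                        continue
                    j = i + 3
                    while j + 3 <= len(s):
                        if s[j: j + 3] in stops:
                            best = max(best, (j - i) // 3)
                            break
                        j += 3
            return best

        rng = np.random.default_rng(53)
        for _ in range(10):
            seq = random_genome(rng, 500, gc=0.64)
            g = GenomeRecord("g", seq)
            _, longest = orf_free_check(g, Interval(1, 500))
            assert longest == oracle_longest(seq)
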