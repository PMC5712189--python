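import numpy as np
import pytest

from phagevo.align import build_alignment
from phagevo.io_utils import GeneFeature, GenomeRecord, Interval, revcomp
from phagevo.motifs import (
    MotifError,
    map_site_orthology,
    orientation_bias,
    parse_consensus,
    percent_identity,
    scan_genome,
)
from helpers import random_genome

STOPERATOR = "GGTGG[CA]TGTCAAG"


class TestParseConsensus:
    def test_bracket_alternatives(self):
        p = parse_consensus(STOPERATOR)
        assert len(p) == 13
        assert p.positions[5] == frozenset("AC")
        assert p.positions[0] == frozenset("G")

    def test_lowercase_slash_style(self):
        p = parse_consensus("GGTGGc/aTGTCAAG")
        assert len(p) == 13 and p.positions[5] == frozenset("AC")

    def test_plain_and_iupac(self):
        p = parse_consensus("ACGTN")
        assert p.positions[4] == frozenset("ACGT")
        assert all(len(s) == 1 for s in p.positions[:4])

    @pytest.mark.parametrize("bad", ["AC]X", "ACGT[", "AC[]GT", "ACX!T"])
    def test_illegal_input_rejected(self, bad):
        with pytest.raises(MotifError):
            parse_consensus(bad)

    def test_reverse_complement(self):
        p = parse_consensus("GGTGG[CA]TGTCAAG")
        rc = p.reverse_complement
        assert rc.positions[0] == frozenset("C")          # complement of G (last)
        assert rc.positions[7] == frozenset("GT")         # complement of {C,A}


def brute_force_scan(seq: str, pattern, max_mismatch: int, strand: str):
    """Per-window oracle, deliberately naive."""
    pat = pattern if strand == "+" else pattern.reverse_complement
    m = len(pat)
    out = []
    for i in range(len(seq) - m + 1):
        window = seq[i: i + m]
        mism = sum(1 for b, allowed in zip(window, pat.positions)
                   if b not in allowed)
        if mism <= max_mismatch:
            out.append((i + 1, strand, mism))
    return out


class TestScanGenome:
    def test_exact_hit(self):
        g = GenomeRecord("g", "GGTGGCTGTCAAG")
        hits = scan_genome(g, parse_consensus(STOPERATOR), max_mismatch=0,
                           strands="+")
        assert len(hits) == 1
        h = hits[0]
        assert (h.interval.start, h.interval.end, h.mismatches) == (1, 13, 0)

    def test_degenerate_position_not_a_mismatch(self):
        g = GenomeRecord("g", "TTGGTGGATGTCAAGTT")
        hits = scan_genome(g, parse_consensus(STOPERATOR), max_mismatch=0)
        assert [h.mismatches for h in hits if h.strand == "+"] == [0]

    def test_minus_strand_hit(self):
        site = "GGTGGCTGTCAAG"
        g = GenomeRecord("g", "AAAA" + revcomp(site) + "TTTT")
        hits = scan_genome(g, parse_consensus(STOPERATOR), max_mismatch=0)
        assert len(hits) == 1 and hits[0].strand == "-"
        assert (hits[0].interval.start, hits[0].interval.end) == (5, 17)

    @pytest.mark.parametrize("max_mismatch", [0, 1, 2])
    def test_equals_bruteforce_oracle(self, max_mismatch):
        rng = np.random.default_rng(31)
        seq = list(random_genome(rng, 10_000, gc=0.64))
        pattern = parse_consensus(STOPERATOR)
        # plant 20 sites, half of them with 1 planted mismatch
        site = "GGTGGCTGTCAAG"
        planted = []
        for i in range(20):
            pos = 200 + i * 480
            text = site
            if i % 2:
                text = site[:4] + ("T" if site[4] != "T" else "A") + site[5:]
            if i % 3 == 0:
                text = revcomp(text)
            seq[pos: pos + 13] = list(text)
            planted.append(pos + 1)
        g = GenomeRecord("g", "".join(seq))
        hits = scan_genome(g, pattern, max_mismatch=max_mismatch)
        got = sorted((h.interval.start, h.strand, h.mismatches) for h in hits)
        expected = sorted(brute_force_scan(g.seq, pattern, max_mismatch, "+")
                          + brute_force_scan(g.seq, pattern, max_mismatch, "-"))
        assert got == expected
        if max_mismatch == 0:
            exact = {p for i, p in enumerate(planted) if i % 2 == 0}
            assert exact <= {h.interval.start for h in hits}

    def test_n_counts_as_mismatch(self):
        g = GenomeRecord("g", "GGTGGNTGTCAAG")
        assert scan_genome(g, parse_consensus(STOPERATOR), max_mismatch=0,
                           strands="+") == []
        assert len(scan_genome(g, parse_consensus(STOPERATOR), max_mismatch=1,
                               strands="+")) == 1

    def test_strand_symmetry(self):
        rng = np.random.default_rng(32)
        seq = random_genome(rng, 3000, gc=0.64)
        pattern = parse_consensus(STOPERATOR)
        fwd = scan_genome(GenomeRecord("g", seq), pattern, max_mismatch=2)
        rev = scan_genome(GenomeRecord("g", revcomp(seq)), pattern,
                          max_mismatch=2)
        n = len(seq)
        mirrored = sorted((n - h.interval.end + 1,
                           "+" if h.strand == "-" else "-", h.mismatches)
                          for h in rev)
        assert mirrored == sorted((h.interval.start, h.strand, h.mismatches)
                                  for h in fwd)


class TestOrthology:
    def test_shared_site_one_id(self):
        rng = np.random.default_rng(33)
        seq = list(random_genome(rng, 600))
        seq[300:313] = list("GGTGGCTGTCAAG")
        s = "".join(seq)
        genomes = [GenomeRecord("a", s), GenomeRecord("b", s)]
        aln = build_alignment(genomes)
        pattern = parse_consensus(STOPERATOR)
        hits = {g.id: scan_genome(g, pattern, 0) for g in genomes}
        tagged, variants = map_site_orthology(aln, hits, pattern)
        assert {h.site_id for h in tagged} == {1}
        assert variants == []

    def test_variant_site_reported_with_edits(self):
        rng = np.random.default_rng(34)
        seq = list(random_genome(rng, 600))
        seq[300:313] = list("GGTGGCTGTCAAG")
        a = "".join(seq)
        b = a[:302] + "CA" + a[304:]        # two substitutions inside the site
        genomes = [GenomeRecord("a", a), GenomeRecord("b", b)]
        aln = build_alignment(genomes)
        pattern = parse_consensus(STOPERATOR)
        hits = {g.id: scan_genome(g, pattern, 0) for g in genomes}
        assert hits["b"] == []
        tagged, variants = map_site_orthology(aln, hits, pattern)
        assert len(variants) == 1
        v = variants[0]
        assert v.genome_id == "b" and "2 nt mutations" in v.description

    def test_deleted_base_reported(self):
        rng = np.random.default_rng(35)
        seq = list(random_genome(rng, 600))
        seq[300:313] = list("GGTGGCTGTCAAG")
        a = "".join(seq)
        b = a[:305] + a[306:]               # 1 nt deletion inside the site
        aln = build_alignment([GenomeRecord("a", a), GenomeRecord("b", b)])
        pattern = parse_consensus(STOPERATOR)
        hits = {"a": scan_genome(GenomeRecord("a", a), pattern, 0), "b": []}
        _, variants = map_site_orthology(aln, hits, pattern)
        assert any("1 nt deletion" in v.description for v in variants)

    def test_site_inside_deleted_region_is_parent_only(self, sim, sim_aln):
        """The site planted inside the deletion substrate keeps one orthology
        id shared by the parents, with D29 reported as lacking it."""
        from phagevo.motifs import scan_genome as scan
        pattern = parse_consensus(STOPERATOR)
        hits = {gid: scan(sim.leaves[gid], pattern, 1) for gid in sim_aln.ids}
        tagged, variants = map_site_orthology(sim_aln, hits, pattern)
        dele = sim.layout.deletion_interval
        inside = [s for s in sim.layout.motif_sites
                  if dele.contains(s.start) and dele.contains(s.end)]
        assert len(inside) == 1
        site_ids = {h.site_id for h in tagged
                    if h.genome_id == "StarStuff" and abs(
                        h.interval.start - inside[0].start) < 5000}
        missing_in_d29 = {v.site_id for v in variants if v.genome_id == "D29"}
        assert site_ids & missing_in_d29


class TestOrientationBias:
    def _feats(self):
        return [GeneFeature("1", 100, 400, "+"), GeneFeature("2", 600, 900, "-")]

    def test_all_co_oriented(self):
        from phagevo.motifs import MotifHit
        hits = [
            MotifHit("g", Interval(150, 162, "+"), "+", 0, "X"),
            MotifHit("g", Interval(950, 962, "-"), "-", 0, "X"),  # upstream of 2
        ]
        frac = orientation_bias(hits, self._feats())
        assert frac == 1.0
        assert hits[0].context == "genic" and hits[1].context == "intergenic"

    def test_half_co_oriented(self):
        from phagevo.motifs import MotifHit
        hits = [
            MotifHit("g", Interval(150, 162, "+"), "+", 0, "X"),
            MotifHit("g", Interval(150, 162, "-"), "-", 0, "X"),
        ]
        assert orientation_bias(hits, self._feats()) == 0.5

    def test_no_features_unknown(self):
        from phagevo.motifs import MotifHit
        hits = [MotifHit("g", Interval(1, 13, "+"), "+", 0, "X")]
        frac = orientation_bias(hits, [])
        assert np.isnan(frac) and hits[0].context == "unknown"

    def test_simulated_bias_matches_planting(self, sim):
        """Default planting is fully co-oriented with transcription."""
        from phagevo.motifs import MotifHit
        hits = [MotifHit("ancestor", s, s.strand or "+", 0, "X")
                for s in sim.layout.motif_sites]
        frac = orientation_bias(hits, sim.layout.features)
        assert frac == 1.0


class TestPercentIdentity:
    def test_identical(self):
        assert percent_identity("MKTAYIAK", "MKTAYIAK") == 100.0

    def test_single_difference(self):
        assert percent_identity("ACDE", "ACDF") == 75.0

    def test_gap_denominator_is_alignment_length(self):
        # one residue missing: 4 identical positions over length 5
        assert percent_identity("ACDEF", "ACDF") == pytest.approx(80.0)

    def test_empty_rejected(self):
        with pytest.raises(MotifError):
            percent_identity("", "ACD")
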