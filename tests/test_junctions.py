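"""Read filtering, split-read detection (vs brute force), junction calling
under the four criteria, origin classification, external record ingest."""

import numpy as np
import pytest

from capricirc._util import revcomp
from capricirc.genome import AnnotatedGenome
from capricirc.junctions import (
    BacksplicePolicy,
    ChimericAlignment,
    ReadFilterPolicy,
    build_anchor_index,
    call_backsplice_junctions,
    classify_origin,
    CircRNARecord,
    detect_split_reads,
    filter_reads,
    import_chimeric_records,
    write_chimeric_sam,
    _AMBIGUOUS,
)

Q30 = chr(30 + 33)
Q10 = chr(10 + 33)


def mkread(rid, seq, qual=None):
    return (rid, seq, qual if qual is not None else Q30 * len(seq))


# =========================================================================
# filtering
# =========================================================================
class TestFilterReads:
    def test_n_fraction_rule(self):
        good = mkread("ok", "A" * 95 + "N" * 5)      # exactly 5%: kept
        bad = mkread("bad", "A" * 94 + "N" * 6)      # above 5%: dropped
        kept, stats = filter_reads([good, bad])
        assert [r[0] for r in kept] == ["ok"]
        assert stats.n_high_n == 1

    def test_adapter_prefix_rule(self):
        policy = ReadFilterPolicy()
        adapter12 = policy.adapter_sequences[0][:12]
        contaminated = mkread("ad", "ACGT" * 10 + adapter12 + "ACGT" * 12)
        clean = mkread("ok", "ACGT" * 25)
        kept, stats = filter_reads([contaminated, clean], policy)
        assert [r[0] for r in kept] == ["ok"]
        assert stats.n_adapter == 1

    def test_low_quality_fraction_rule(self):
        # >20% of bases below Q20 -> dropped; exactly 20% kept
        seq = "A" * 100
        keep = mkread("keep", seq, Q10 * 20 + Q30 * 80)
        drop = mkread("drop", seq, Q10 * 21 + Q30 * 79)
        kept, stats = filter_reads([keep, drop])
        assert [r[0] for r in kept] == ["keep"]
        assert stats.n_low_quality == 1

    def test_all_clean_ratio_100(self):
        reads = [mkread(f"r{i}", "ACGT" * 25) for i in range(10)]
        kept, stats = filter_reads(reads)
        assert stats.valid_ratio_pct == 100.0

    def test_malformed_fastq_reports_line(self, tmp_path):
        path = tmp_path / "bad.fastq"
        path.write_text("@r1\nACGT\n+\nII\n")  # qual length mismatch
        with pytest.raises(ValueError, match="bad.fastq:4"):
            filter_reads(str(path))

    def test_fastq_file_roundtrip(self, tmp_path):
        src = tmp_path / "in.fastq"
        src.write_text("@r1\nACGTACGT\n+\n" + Q30 * 8 + "\n")
        out = tmp_path / "clean.fastq"
        kept, stats = filter_reads(str(src), fastq_out=str(out))
        assert stats.valid_reads == 1
        assert out.read_text() == src.read_text()


# =========================================================================
# split-read detection
# =========================================================================
class TestDetectSplitReads:
    def test_backsplice_read_yields_noncolinear_chimera(self, toy_genome):
        seq = toy_genome.fetch("chr1", 1000, 1050) + toy_genome.fetch("chr1", 500, 550)
        res = detect_split_reads([("r1", seq)], toy_genome)
        assert len(res.chimeras) == 1
        c = res.chimeras[0]
        assert not c.colinear
        assert c.seg_b[0] < c.seg_a[0]
        assert c.seg_a == (1000, 1050) and c.seg_b == (500, 550)

    def test_colinear_read_yields_no_chimera(self, toy_genome):
        seq = toy_genome.fetch("chr1", 500, 600)
        res = detect_split_reads([("r1", seq)], toy_genome)
        assert res.chimeras == [] and res.n_colinear == 1

    def test_minus_strand_read_recovers_same_junction(self, toy_genome):
        plus = toy_genome.fetch("chr1", 1000, 1050) + toy_genome.fetch("chr1", 500, 550)
        res = detect_split_reads([("r1", revcomp(plus))], toy_genome)
        assert len(res.chimeras) == 1
        c = res.chimeras[0]
        assert c.strand == "-"
        assert (c.seg_b[0], c.seg_a[1]) == (500, 1050)

    def test_extension_mismatch_counted(self, toy_genome):
        seq = toy_genome.fetch("chr1", 1000, 1050) + toy_genome.fetch("chr1", 500, 550)
        # substitute one base in the extension region (inside first segment,
        # past the 20-nt anchor)
        pos = 30
        sub = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[pos]]
        mutated = seq[:pos] + sub + seq[pos + 1:]
        res = detect_split_reads([("r1", mutated)], toy_genome)
        assert len(res.chimeras) == 1
        assert res.chimeras[0].mismatches == 1

    def test_ambiguous_anchor_discarded(self):
        # duplicate 40-mer at two loci -> terminal anchors ambiguous
        core = "ACGTTGCAGTACCGGATTCAGGCATTCGATCGGATCCGTA"
        filler = "TTTT" + "CAAC" * 60
        genome = AnnotatedGenome({"chr1": core + filler + core})
        read = core + core[:10] if len(core) >= 40 else None
        res = detect_split_reads([("r1", core[:40] + "A" * 10)], genome)
        assert res.n_ambiguous == 1 and res.chimeras == []

    def test_too_short_reads_raise(self, toy_genome):
        with pytest.raises(ValueError, match="shorter"):
            detect_split_reads([("r1", "ACGT" * 5)], toy_genome, anchor_len=20)

    def test_agrees_with_brute_force_search(self, scenario):
        """Detector output equals an exhaustive split-placement search."""
        genome = scenario.genome
        rng = np.random.default_rng(99)
        reads = scenario.sim.reads["PE1"]
        sample_idx = rng.choice(len(reads), size=60, replace=False)
        subset = [reads[i] for i in sample_idx]
        res = detect_split_reads(subset, genome, 20)
        got = {
            c.read_id: (c.chrom_a, c.seg_a, c.seg_b, c.mismatches, c.colinear)
            for c in res.chimeras
        }
        expected = {}
        for rid, seq in subset:
            bf = brute_force_place(seq.upper(), genome, 20)
            if bf is not None and bf[0] == "chimera":
                expected[rid] = bf[1]
        assert set(got) == set(expected)
        for rid in got:
            # segments and mismatch count must agree; brute force uses the
            # same minimal-mismatch criterion
            assert got[rid][3] == expected[rid][3], rid
            assert got[rid][:3] == expected[rid][:3], rid
            assert got[rid][4] == expected[rid][4], rid


def brute_force_place(seq, genome, k):
    """Exhaustive O(L*G) split placement: scan every genomic position for the
    exact terminal anchors, then try every split point, minimising Hamming
    mismatches.  Mirrors the detector's contract, independently."""
    from capricirc.junctions import _has_splice_signal

    def anchor_hits(a):
        hits = []
        for chrom, ref in genome.sequences.items():
            start = 0
            while True:
                i = ref.find(a, start)
                if i < 0:
                    break
                hits.append((chrom, i))
                start = i + 1
        return hits

    L = len(seq)
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        h1 = anchor_hits(s[:k])
        h2 = anchor_hits(s[-k:])
        if len(h1) > 1 or len(h2) > 1:
            return ("ambiguous", None)
        if h1:
            chrom, p1 = h1[0]
            ref = genome.sequences[chrom]
            if p1 + L <= len(ref) and ref[p1 : p1 + L] == s:
                return ("colinear", None)
        if not h1 or not h2:
            continue
        (c1, p1), (c2, p2) = h1[0], h2[0]
        if c1 != c2:
            continue
        ref = genome.sequences[c1]
        if p2 + k - L == p1:
            return ("colinear", None)
        best = None
        for split in range(k, L - k + 1):
            if p1 + split > len(ref) or p2 + k - (L - split) < 0:
                continue
            ga = ref[p1 : p1 + split]
            bstart = p2 + k - (L - split)
            gb = ref[bstart : p2 + k]
            m = sum(x != y for x, y in zip(s[:split], ga)) + sum(
                x != y for x, y in zip(s[split:], gb)
            )
            if best is None or m < best[0]:
                best = (m, [split])
            elif m == best[0]:
                best[1].append(split)
        if best is None:
            continue
        m, ties = best
        split = ties[0]
        for t in ties:
            donor, acceptor = p1 + t, p2 + k - (L - t)
            if acceptor < donor and _has_splice_signal(ref, acceptor, donor):
                split = t
                break
        seg_a = (p1, p1 + split)
        seg_b = (p2 + k - (L - split), p2 + k)
        return ("chimera", (c1, seg_a, seg_b, m, seg_b[0] > seg_a[0]))
    return None


# =========================================================================
# junction calling: the four criteria
# =========================================================================
def chim(chrom, acceptor, donor, mism=0, strand="+", colinear=False, sample="S1", rid="r"):
    return ChimericAlignment(
        rid, chrom, chrom, strand, (donor - 30, donor), (acceptor, acceptor + 30),
        mism, colinear, sample=sample,
    )


class TestCallBacksplice:
    def _signal_genome(self, span=5000):
        seq = list(np.random.default_rng(7).choice(list("ACGT"), size=200_000))
        genome = AnnotatedGenome({"c1": "".join(seq)})
        # plant + strand signal around [1000, 1000+span)
        genome.patch("c1", 998, "AG")
        genome.patch("c1", 1000 + span, "GT")
        return genome

    def test_all_criteria_met_accepted(self):
        genome = self._signal_genome()
        chims = [chim("c1", 1000, 6000, rid=f"r{i}") for i in range(3)]
        records, rejected = call_backsplice_junctions(chims, genome)
        assert len(records) == 1 and not rejected
        r = records[0]
        assert (r.start, r.end, r.strand) == (1000, 6000, "+")
        assert r.total_reads == 3

    def test_span_over_100kb_rejected(self):
        genome = self._signal_genome(span=150_000)
        chims = [chim("c1", 1000, 151_000, rid=f"r{i}") for i in range(3)]
        records, rejected = call_backsplice_junctions(chims, genome)
        assert not records
        assert rejected[0].failed == ("max_span",)

    def test_high_mismatch_read_excluded_not_fatal(self):
        genome = self._signal_genome()
        chims = [chim("c1", 1000, 6000, rid="r1"), chim("c1", 1000, 6000, mism=3, rid="r2")]
        records, rejected = call_backsplice_junctions(chims, genome)
        assert len(records) == 1
        assert records[0].total_reads == 1  # dirty read dropped

    def test_only_dirty_reads_rejected_with_both_criteria(self):
        genome = self._signal_genome()
        chims = [chim("c1", 1000, 6000, mism=5, rid="r1")]
        records, rejected = call_backsplice_junctions(chims, genome)
        assert not records
        assert set(rejected[0].failed) == {"mismatch", "min_reads"}

    def test_missing_splice_signal_rejected(self):
        genome = self._signal_genome()
        chims = [chim("c1", 2000, 7000)]  # no planted AG/GT there
        records, rejected = call_backsplice_junctions(chims, genome)
        assert not records
        assert "gt_ag" in rejected[0].failed

    def test_colinear_chimeras_are_not_candidates(self):
        genome = self._signal_genome()
        forward = ChimericAlignment(
            "r", "c1", "c1", "+", (1000, 1030), (5000, 5030), 0, colinear=True
        )
        records, rejected = call_backsplice_junctions([forward], genome)
        assert not records and not rejected

    def test_policy_relaxation_is_monotone(self, scenario, called):
        """Disabling criteria can only grow the call set."""
        strict_records, _, _ = called
        chims = {}
        for s, reads in scenario.sim.reads.items():
            chims[s] = detect_split_reads(reads, scenario.genome, 20, sample=s).chimeras
        lax = BacksplicePolicy(
            require_gt_ag=False, max_mismatches=10**9,
            min_junction_reads=1, max_span=10**12, same_chrom_only=False,
        )
        lax_records, _ = call_backsplice_junctions(chims, scenario.genome, lax)
        strict_keys = {(r.chrom, r.start, r.end) for r in strict_records}
        lax_keys = {(r.chrom, r.start, r.end) for r in lax_records}
        assert strict_keys <= lax_keys

    def test_gt_ag_symmetry_under_reverse_complement(self, toy_genome):
        """A junction accepted on + is accepted at mirrored coordinates when
        genome and reads are reverse-complemented."""
        # construct + junction with signal inside gA's introns: circ over exon 2
        gA = toy_genome.gene("gA")
        start, end = gA.exons[1].start, gA.exons[1].end  # [400,500)
        read = toy_genome.fetch("chr1", end - 50, end) + toy_genome.fetch("chr1", start, start + 50)
        res = detect_split_reads([("r1", read)], toy_genome)
        recs, rej = call_backsplice_junctions(res.chimeras, toy_genome)
        assert len(recs) == 1 and recs[0].strand == "+"

        mirrored = toy_genome.reverse_complemented()
        res2 = detect_split_reads([("r1", revcomp(read))], mirrored)
        recs2, _ = call_backsplice_junctions(res2.chimeras, mirrored)
        assert len(recs2) == 1
        L = len(toy_genome.sequences["chr1"])
        assert (recs2[0].start, recs2[0].end) == (L - end, L - start)
        assert recs2[0].strand == "-"


# =========================================================================
# origin classification
# =========================================================================
class TestClassifyOrigin:
    def circ(self, start, end, strand="+"):
        return CircRNARecord("c", "chr1", start, end, strand)

    def test_exonic_multi_exon_spliced_length(self, toy_genome):
        # exons 2-4 of gA: [400,500) [700,800) [1000,1100)
        r = classify_origin(self.circ(400, 1100), toy_genome)
        assert r.origin == "exonic" and r.host_gene == "gA"
        assert r.spliced_length == 100 + 100 + 100

    def test_intronic_ciRNA(self, toy_genome):
        r = classify_origin(self.circ(210, 380), toy_genome)  # inside intron 1 of gA
        assert r.origin == "intronic" and r.host_gene == "gA"
        assert r.spliced_length == 170

    def test_intergenic(self, toy_genome):
        r = classify_origin(self.circ(3500, 3800), toy_genome)
        assert r.origin == "intergenic" and r.host_gene is None

    def test_minus_strand_gene(self, toy_genome):
        r = classify_origin(self.circ(2400, 2950, strand="-"), toy_genome)
        assert r.origin == "exonic" and r.host_gene == "gB"
        assert r.spliced_length == 150 + 150

    def test_ambiguous_overlap_assigned_not_error(self, toy_genome):
        # spans gA partially without exact exon boundaries
        r = classify_origin(self.circ(150, 450), toy_genome)
        assert r.origin in ("exonic", "intronic")
        assert r.host_gene == "gA"


# =========================================================================
# external records
# =========================================================================
class TestImportChimeric:
    def test_fusion_tsv(self, tmp_path):
        path = tmp_path / "fusions.tsv"
        path.write_text("# chrom donor acceptor strand reads\nchr1\t6000\t1001\t+\t3\n")
        chims = import_chimeric_records(str(path), "fusion-tsv")
        assert len(chims) == 3
        for c in chims:
            assert c.donor == 6000 and c.acceptor == 1000
            assert not c.colinear

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        assert import_chimeric_records(str(path), "fusion-tsv") == []

    def test_unknown_dialect(self, tmp_path):
        path = tmp_path / "x.tsv"
        path.write_text("")
        with pytest.raises(ValueError, match="dialect"):
            import_chimeric_records(str(path), "bogus")

    def test_sam_roundtrip(self, tmp_path, toy_genome):
        orig = [
            ChimericAlignment("r1", "chr1", "chr1", "+", (1000, 1050), (500, 550), 1, False),
            ChimericAlignment("r2", "chr1", "chr1", "-", (2800, 2850), (2000, 2060), 0, False),
        ]
        path = tmp_path / "chim.sam"
        write_chimeric_sam(orig, str(path), toy_genome)
        back = import_chimeric_records(str(path), "sam-supplementary")
        assert len(back) == 2
        for a, b in zip(orig, back):
            assert (a.read_id, a.chrom_a, a.seg_a, a.seg_b, a.mismatches, a.colinear) == (
                b.read_id, b.chrom_a, b.seg_a, b.seg_b, b.mismatches, b.colinear
            )


# =========================================================================
# truth recovery on the default scenario
# =========================================================================
def test_truth_recovery_on_default_scenario(scenario, called):
    from capricirc.evaluate import evaluate_calls

    records, _, _ = called
    ev = evaluate_calls(records, scenario.truth)
    assert ev["precision"] >= 0.95
    assert ev["recall"] >= 0.95


def test_called_origins_match_truth(scenario, called):
    records, _, _ = called
    truth_by_key = {t.key: t for t in scenario.truth}
    checked = 0
    for r in records:
        t = truth_by_key.get(r.key)
        if t is None:
            continue
        assert r.origin == t.origin, r.circ_id
        assert r.host_gene == t.host_gene
        checked += 1
    assert checked >= 45
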