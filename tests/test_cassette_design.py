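import numpy as np
import pytest
from Bio.SeqUtils import MeltingTemp, gc_fraction

from delkit.cassette_design import (
    DesignFailure,
    DesignParams,
    MarkerCassette,
    attach_tails,
    design_domain_deletion,
    design_primer_set,
)
from delkit.genome_io import Contig, GeneModel, revcomp
from delkit import _thermo

import oracles
from conftest import random_dna


def make_locus(seed=5, orf=(5000, 5900), n=20000, strand="+", domain=None):
    rng = np.random.default_rng(seed)
    seq = random_dna(rng, n)
    genome = {"c1": Contig("c1", seq)}
    dom = domain or (None, None)
    gene = GeneModel("g", "c1", orf[0], orf[1], strand, dom[0], dom[1])
    return genome, gene


class TestVectorizedThermo:
    """The fast window Tm must agree with Biopython's scalar Tm_NN."""

    def test_agreement_with_biopython(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            L = int(rng.integers(18, 29))
            s = random_dna(rng, L)
            if s == revcomp(s):  # symmetric duplexes get a special term
                continue
            assert _thermo.primer_tm(s) == pytest.approx(
                MeltingTemp.Tm_NN(s), abs=1e-9
            )

    def test_windows_match_scalar(self):
        rng = np.random.default_rng(7)
        seq = random_dna(rng, 300)
        codes = _thermo.encode(seq)
        tms = _thermo.window_tm(codes, 20)
        for i in (0, 57, 143, 280):
            w = seq[i : i + 20]
            if w == revcomp(w):
                continue
            assert tms[i] == pytest.approx(MeltingTemp.Tm_NN(w), abs=1e-9)

    def test_n_bases_are_nan(self):
        codes = _thermo.encode("ACGTN" + "ACGT" * 10)
        tms = _thermo.window_tm(codes, 18)
        assert np.isnan(tms[0])
        assert not np.isnan(tms[5])

    def test_window_gc(self):
        codes = _thermo.encode("GGGGCCCCAAAATTTT")
        gcs = _thermo.window_gc(codes, 8)
        assert gcs[0] == 1.0
        assert gcs[4] == 0.5
        assert gcs[8] == 0.0


class TestDesignPrimerSet:
    def check_bounds(self, pset, params):
        for role, p in pset.primers.items():
            assert params.len_min <= p.length <= params.len_max
            assert params.tm_min <= MeltingTemp.Tm_NN(p.binding_seq) <= params.tm_max
            assert params.gc_min <= gc_fraction(p.binding_seq) <= params.gc_max

    def test_clean_gene_designs_window30(self, params):
        genome, gene = make_locus()
        pset = design_primer_set(gene, genome, params)
        assert not isinstance(pset, DesignFailure)
        assert pset.window_used == 30
        self.check_bounds(pset, params)
        assert oracles.classify_design_outcome(gene, genome, params) == "ok_window30"

    def test_binding_matches_template(self, params):
        genome, gene = make_locus()
        pset = design_primer_set(gene, genome, params)
        seq = genome["c1"].sequence
        for role in ("5f", "5r", "3f", "3r"):
            p = pset.primers[role]
            site = seq[p.anchor_start : p.anchor_end]
            assert p.binding_seq == (site if p.strand == "+" else revcomp(site))

    def test_anchor_windows_respected(self, params):
        genome, gene = make_locus()
        pset = design_primer_set(gene, genome, params)
        # 5r is antisense: 3' end at its leftmost genomic coordinate
        assert abs(pset.primers["5r"].anchor_start - gene.orf_start) <= 30
        assert abs(pset.primers["3f"].anchor_end - gene.orf_end) <= 30

    def test_flank_amplicon_lengths(self, params):
        genome, gene = make_locus()
        pset = design_primer_set(gene, genome, params)
        a5 = pset.flank5_amplicon(genome)
        a3 = pset.flank3_amplicon(genome)
        assert params.min_flank <= len(a5) <= params.max_flank
        assert params.min_flank <= len(a3) <= params.max_flank

    def test_contig_end_failure(self, params):
        genome, _ = make_locus()
        gene = GeneModel("g", "c1", 200, 1100, "+")
        res = design_primer_set(gene, genome, params)
        assert isinstance(res, DesignFailure)
        assert res.reason == "contig_end"

    def test_polyA_windows_fall_back_to_75(self, params):
        genome, gene = make_locus(seed=8)
        s, e = gene.orf_start, gene.orf_end
        seq = list(genome["c1"].sequence)
        # drown the 30 bp windows (plus max primer extent) in poly-A
        seq[s - 31 : s + 59] = "A" * 90
        seq[e - 59 : e + 31] = "A" * 90
        genome = {"c1": Contig("c1", "".join(seq))}
        res = design_primer_set(gene, genome, params)
        assert not isinstance(res, DesignFailure)
        assert res.window_used == 75
        assert oracles.classify_design_outcome(gene, genome, params) == "ok_window75"

    def test_determinism(self, params):
        genome, gene = make_locus(seed=13)
        a = design_primer_set(gene, genome, params)
        b = design_primer_set(gene, genome, params)
        assert a == b

    def test_minus_strand_orientation(self, params):
        genome, gene = make_locus(seed=21, strand="-")
        pset = design_primer_set(gene, genome, params)
        assert not isinstance(pset, DesignFailure)
        # 5f primes toward the gene from the genomic right side => '-' strand
        assert pset.primers["5f"].strand == "-"
        assert pset.primers["5f"].anchor_start > gene.orf_end

    def test_uniqueness_of_binding_seqs(self, full_bundle, full_designs, params):
        _, contigs, genes, _, _, _ = full_bundle
        by_id = {g.gene_id: g for g in genes}
        for gid, res in full_designs.items():
            if isinstance(res, DesignFailure):
                continue
            gene = by_id[gid]
            ctx = contigs[gene.contig].sequence
            if gene.strand == "-":
                ctx = revcomp(ctx)
            for p in res.primers.values():
                region_hits = ctx.count(p.binding_seq) + ctx.count(
                    revcomp(p.binding_seq)
                )
                assert region_hits >= 1


class TestAttachTails:
    def test_tails_attached_correctly(self, small_bundle, params):
        _, contigs, genes, _, marker, vector = small_bundle
        gene = next(g for g in genes if g.orf_start >= 1000)
        pset = design_primer_set(gene, contigs, params)
        vt = vector.exposed_tails(params.tail_len)
        tailed = attach_tails(pset, marker, vt)
        assert tailed.primers["5r"].tail_seq == marker.left_tail
        assert tailed.primers["3f"].tail_seq == marker.right_tail
        assert tailed.primers["5f"].tail_seq == vt[0]
        assert tailed.primers["3r"].tail_seq == vt[1]
        for role in ("5f", "5r", "3f", "3r"):
            assert tailed.primers[role].binding_seq == pset.primers[role].binding_seq
            assert tailed.primers[role].full_seq.startswith(
                tailed.primers[role].tail_seq
            )

    def test_retailing_rejected(self, small_bundle, params):
        _, contigs, genes, _, marker, vector = small_bundle
        gene = next(g for g in genes if g.orf_start >= 1000)
        pset = design_primer_set(gene, contigs, params)
        vt = vector.exposed_tails(params.tail_len)
        tailed = attach_tails(pset, marker, vt)
        with pytest.raises(ValueError, match="already"):
            attach_tails(tailed, marker, vt)

    def test_zero_length_tails_are_identity(self, small_bundle, params):
        _, contigs, genes, _, marker, vector = small_bundle
        gene = next(g for g in genes if g.orf_start >= 1000)
        pset = design_primer_set(gene, contigs, params)
        zero_marker = MarkerCassette(marker.name, marker.sequence, tail_len=0)
        tailed = attach_tails(pset, zero_marker, ("", ""))
        assert tailed == pset

    def test_amplicon_marker_homology_exactly_tail_len(self, small_bundle, params):
        _, contigs, genes, _, marker, vector = small_bundle
        gene = next(g for g in genes if g.orf_start >= 1000)
        pset = design_primer_set(gene, contigs, params)
        tailed = attach_tails(pset, marker, vector.exposed_tails(params.tail_len))
        a5 = tailed.flank5_amplicon(contigs)
        a3 = tailed.flank3_amplicon(contigs)
        # longest-common-affix oracle
        def affix(left, right):
            for L in range(min(len(left), len(right)), 0, -1):
                if left[-L:] == right[:L]:
                    return L
            return 0
        assert affix(a5, marker.sequence) == params.tail_len
        assert affix(marker.sequence, a3) == params.tail_len


class TestDomainDeletion:
    def test_domain_replaced_orf_preserved(self, params):
        genome, gene = make_locus(seed=30, orf=(5000, 12000), domain=(7000, 8500))
        pset = design_domain_deletion(gene, genome, params)
        assert not isinstance(pset, DesignFailure)
        assert pset.flanks.target_interval == (7000, 8500)
        # flanks carry ORF sequence outside the domain
        assert pset.flanks.five_prime_interval == (6000, 7000)
        assert pset.flanks.three_prime_interval == (8500, 9500)

    def test_missing_domain_raises(self, params):
        genome, gene = make_locus()
        with pytest.raises(ValueError):
            design_domain_deletion(gene, genome, params)


class TestMarkerCassette:
    def test_left_tail_is_revcomp_of_left_terminus(self, small_bundle):
        *_, marker, _ = small_bundle
        assert marker.left_tail == revcomp(marker.sequence[: marker.tail_len])
        assert marker.right_tail == marker.sequence[-marker.tail_len :]

    def test_too_short_marker_rejected(self):
        with pytest.raises(ValueError):
            MarkerCassette("m", "ACGT" * 10, tail_len=29)


class TestDesignParams:
    def test_yaml_roundtrip(self, tmp_path):
        p = DesignParams(tm_opt=62.0, tail_len=25)
        path = tmp_path / "params.yaml"
        p.to_yaml(path)
        assert DesignParams.from_yaml(path) == p
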