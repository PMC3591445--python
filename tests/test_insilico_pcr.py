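import numpy as np
import pytest

from delkit.cassette_design import (
    DesignFailure,
    MarkerCassette,
    attach_tails,
    design_primer_set,
)
from delkit.assembly_sim import simulate_fusion_pcr, simulate_recombination, amplify_final_construct
from delkit.genome_io import Contig, GeneModel, revcomp
from delkit.insilico_pcr import (
    ENZYME_TABLE,
    DiagnosticFailure,
    RestrictionEnzyme,
    build_null_locus,
    design_diagnostic,
    find_binding_sites,
    predict_genotype_bands,
    restriction_enzymes,
    simulate_pcr,
)

import oracles
from conftest import random_dna


class TestFindBindingSites:
    def test_identity_site(self):
        rng = np.random.default_rng(0)
        t = random_dna(rng, 500)
        primer = t[100:122]
        sites = find_binding_sites(t, primer)
        assert [(s.start, s.strand) for s in sites] == [(100, "+")]

    def test_palindromic_template_two_sites(self):
        stem = "ACGTGGCCTATAGCCAATGG"
        t = "TT" + stem + "AAAA" + revcomp(stem) + "TT"
        sites = find_binding_sites(t, stem)
        assert len(sites) == 2
        assert {s.strand for s in sites} == {"+", "-"}

    def test_mismatch_not_in_3prime(self):
        rng = np.random.default_rng(1)
        t = random_dna(rng, 300)
        primer = list(t[50:72])
        primer[-1] = "A" if primer[-1] != "A" else "C"  # 3'-terminal mismatch
        sites = find_binding_sites(t, "".join(primer), max_mismatch=1)
        assert (50, "+") not in {(s.start, s.strand) for s in sites}
        primer = list(t[50:72])
        primer[3] = "A" if primer[3] != "A" else "C"  # internal mismatch ok
        sites = find_binding_sites(t, "".join(primer), max_mismatch=1)
        assert (50, "+") in {(s.start, s.strand) for s in sites}

    def test_agrees_with_naive_scan(self):
        rng = np.random.default_rng(2)
        t = random_dna(rng, 5000)
        for _ in range(50):
            pos = int(rng.integers(0, 4978))
            primer = t[pos : pos + 22]
            got = {(s.start, s.strand) for s in find_binding_sites(t, primer, 1)}
            want = oracles.naive_binding_sites(t, primer, 1)
            assert got == want


class TestSimulatePcr:
    def test_unique_product_equals_slice(self):
        rng = np.random.default_rng(3)
        t = random_dna(rng, 2000)
        fwd = t[100:122]
        rev = revcomp(t[900:922])
        (prod,) = simulate_pcr(t, fwd, rev)
        assert prod.sequence == t[100:922]
        assert prod.length == 822

    def test_divergent_sites_no_product(self):
        rng = np.random.default_rng(4)
        t = random_dna(rng, 2000)
        fwd = revcomp(t[100:122])  # primes leftward at 100
        rev = t[900:922]  # primes rightward at 900
        assert simulate_pcr(t, fwd, rev) == []

    def test_multiple_sites_exhaustive_pairing(self):
        rng = np.random.default_rng(5)
        a = random_dna(rng, 22)
        b = random_dna(rng, 22)
        spacer = lambda: random_dna(rng, 200)
        t = spacer() + a + spacer() + a + spacer() + revcomp(b) + spacer() + revcomp(b) + spacer()
        prods = simulate_pcr(t, a, b, max_product=5000)
        assert len(prods) == 4
        spans = {(p.fwd_site.start, p.rev_site.end) for p in prods}
        assert spans == oracles.naive_products(t, a, b, 5000)

    def test_max_product_zero_rejected(self):
        with pytest.raises(ValueError):
            simulate_pcr("ACGT" * 10, "ACGTACGTACGTACGTAC", "ACGTACGTACGTACGTAC", 0)


def _marked_locus(seed=9, orf_len=900, marker_len=1732, strand="+"):
    rng = np.random.default_rng(seed)
    n = 20000
    seq = random_dna(rng, n)
    genome = {"c1": Contig("c1", seq)}
    gene = GeneModel("g", "c1", 5000, 5000 + orf_len, strand)
    marker = MarkerCassette("m", random_dna(rng, marker_len))
    return genome, gene, marker


class TestBuildNullLocus:
    def test_length_arithmetic(self):
        genome, gene, marker = _marked_locus()
        edited = build_null_locus(genome, gene, marker)
        assert edited.length == genome["c1"].length + marker.length - gene.length
        assert edited.length == genome["c1"].length + 832

    def test_differs_only_inside_replaced_interval(self):
        genome, gene, marker = _marked_locus()
        edited = build_null_locus(genome, gene, marker)
        wt = genome["c1"].sequence
        assert edited.sequence[: gene.orf_start] == wt[: gene.orf_start]
        assert edited.sequence[gene.orf_start + marker.length :] == wt[gene.orf_end :]
        assert (
            edited.sequence[gene.orf_start : gene.orf_start + marker.length]
            == marker.sequence
        )

    def test_minus_strand_inserts_revcomp(self):
        genome, gene, marker = _marked_locus(strand="-")
        edited = build_null_locus(genome, gene, marker)
        assert (
            edited.sequence[gene.orf_start : gene.orf_start + marker.length]
            == revcomp(marker.sequence)
        )

    def test_applying_twice_rejected(self):
        genome, gene, marker = _marked_locus()
        edited = build_null_locus(genome, gene, marker)
        with pytest.raises(ValueError, match="already"):
            build_null_locus({"c1": edited}, gene, marker)


class TestDesignDiagnostic:
    def _full_design(self, small_bundle, params, gene):
        _, contigs, genes, _, marker, vector = small_bundle
        pset = design_primer_set(gene, contigs, params)
        assert not isinstance(pset, DesignFailure)
        tailed = attach_tails(pset, marker, vector.exposed_tails(params.tail_len))
        a5 = tailed.flank5_amplicon(contigs)
        a3 = tailed.flank3_amplicon(contigs)
        construct = simulate_fusion_pcr(
            a5, a3, marker, (tailed.primers["5f"], tailed.primers["3r"]), 20,
            gene.gene_id,
        )
        return contigs, tailed, construct, marker

    def test_allele_size_identity(self, small_bundle, params):
        _, contigs, genes, *_ = small_bundle
        gene = next(g for g in genes if g.orf_start >= 1000)
        contigs, tailed, construct, marker = self._full_design(
            small_bundle, params, gene
        )
        plan = design_diagnostic(gene, contigs, construct, tailed, marker, params)
        assert plan.null_len - plan.wt_len == marker.length - gene.length

    def test_primers_external_to_targeting_sequence(self, small_bundle, params):
        _, contigs0, genes, *_ = small_bundle
        gene = next(g for g in genes if g.orf_start >= 1000)
        contigs, tailed, construct, marker = self._full_design(
            small_bundle, params, gene
        )
        plan = design_diagnostic(gene, contigs, construct, tailed, marker, params)
        lo = min(tailed.flanks.five_prime_interval[0], tailed.flanks.three_prime_interval[0])
        hi = max(tailed.flanks.five_prime_interval[1], tailed.flanks.three_prime_interval[1])
        for p in (plan.fwd, plan.rev):
            assert p.anchor_end <= lo or p.anchor_start >= hi

    def test_wt_and_null_templates_give_single_distinct_bands(
        self, small_bundle, params
    ):
        _, contigs0, genes, *_ = small_bundle
        gene = next(g for g in genes if g.orf_start >= 1000)
        contigs, tailed, construct, marker = self._full_design(
            small_bundle, params, gene
        )
        plan = design_diagnostic(gene, contigs, construct, tailed, marker, params)
        null_contig = build_null_locus(
            contigs, gene, construct, marker=marker, flanks=tailed.flanks
        )
        wt = simulate_pcr(contigs[gene.contig].sequence, plan.fwd, plan.rev)
        null = simulate_pcr(null_contig.sequence, plan.fwd, plan.rev)
        assert [p.length for p in wt] == [plan.wt_len]
        assert [p.length for p in null] == [plan.null_len]
        assert plan.wt_len != plan.null_len

    def test_enzyme_fallback_when_sizes_equal(self, params):
        # engineer marker length == ORF length: no size discrimination
        genome, gene, _ = _marked_locus(seed=23, orf_len=900, marker_len=900)
        rng = np.random.default_rng(77)
        marker_seq = random_dna(rng, 900)
        # guarantee a marker-only cutter exists
        site = ENZYME_TABLE["EcoRI"]
        marker_seq = marker_seq[:400] + site + marker_seq[406:]
        marker = MarkerCassette("m", marker_seq)
        pset = design_primer_set(gene, genome, params)
        assert not isinstance(pset, DesignFailure)
        tailed = attach_tails(pset, marker, ("A" * 29, "T" * 29))
        construct = simulate_fusion_pcr(
            tailed.flank5_amplicon(genome),
            tailed.flank3_amplicon(genome),
            marker,
            (tailed.primers["5f"], tailed.primers["3r"]),
        )
        plan = design_diagnostic(gene, genome, construct, tailed, marker, params)
        assert plan.null_len == plan.wt_len
        assert not plan.size_discriminable
        assert plan.enzymes
        # soundness by direct string counting
        null_contig = build_null_locus(genome, gene, marker)
        (null_prod,) = simulate_pcr(null_contig.sequence, plan.fwd, plan.rev)
        (wt_prod,) = simulate_pcr(genome[gene.contig].sequence, plan.fwd, plan.rev)
        for name, wt_frags, null_frags in plan.enzymes:
            s = ENZYME_TABLE[name]
            assert null_prod.sequence.count(s) >= 1
            assert wt_prod.sequence.count(s) == 0
            assert sum(null_frags) == plan.null_len
            assert sum(wt_frags) == plan.wt_len


class TestPredictGenotypeBands:
    @pytest.fixture()
    def plan(self, small_bundle, params):
        _, contigs, genes, _, marker, vector = small_bundle
        gene = next(g for g in genes if g.orf_start >= 1000)
        pset = design_primer_set(gene, contigs, params)
        tailed = attach_tails(pset, marker, vector.exposed_tails(params.tail_len))
        construct = simulate_fusion_pcr(
            tailed.flank5_amplicon(contigs),
            tailed.flank3_amplicon(contigs),
            marker,
            (tailed.primers["5f"], tailed.primers["3r"]),
        )
        return design_diagnostic(gene, contigs, construct, tailed, marker, params)

    def test_band_sets(self, plan):
        assert predict_genotype_bands(plan, "wt") == {plan.wt_len}
        assert predict_genotype_bands(plan, "null") == {plan.null_len}
        both = {plan.wt_len, plan.null_len}
        assert predict_genotype_bands(plan, "heterokaryon") == both
        assert predict_genotype_bands(plan, "diploid") == both

    def test_unknown_genotype_rejected(self, plan):
        with pytest.raises(ValueError):
            predict_genotype_bands(plan, "triploid")


class TestEnzymeTable:
    def test_table_size_and_validity(self):
        enzymes = restriction_enzymes()
        assert len(enzymes) >= 20
        for e in enzymes:
            assert len(e.recognition_site) >= 4
            assert set(e.recognition_site) <= set("ACGT")

    def test_sites_match_biopython(self):
        # packaged snapshot cross-checked against Bio.Restriction
        from Bio import Restriction

        for name, site in ENZYME_TABLE.items():
            assert str(getattr(Restriction, name).site) == site

    def test_digest_fragments(self):
        e = RestrictionEnzyme("EcoRI", "GAATTC")
        seq = "A" * 10 + "GAATTC" + "C" * 20 + "GAATTC" + "T" * 5
        frags = e.digest(seq)
        assert sum(frags) == len(seq)
        assert len(frags) == 3

    def test_ambiguous_site_rejected(self):
        with pytest.raises(ValueError):
            RestrictionEnzyme("BstXI", "CCANNNNNNTGG")
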