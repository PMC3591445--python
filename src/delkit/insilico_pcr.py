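"""In-silico PCR and diagnostic assay design.

Predicts PCR products on arbitrary templates, edits a wild-type contig into
its null (marker-replaced) counterpart, and designs the verification assay:
an external primer pair whose wild-type and null products are told apart by
size on a gel, or - when the size difference is too small - by restriction
enzymes cutting only within the marker of the null allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from delkit import _thermo
from delkit.assembly_sim import DeletionConstruct
from delkit.cassette_design import (
    DesignParams,
    MarkerCassette,
    Primer,
    PrimerSet,
)
from delkit.genome_io import Contig, GeneModel, revcomp

# Fixed, versioned snapshot of common restriction sites (no live REBASE
# dependency).  Mostly 6-cutters plus NotI.
ENZYME_TABLE: dict[str, str] = {
    "EcoRI": "GAATTC",
    "BamHI": "GGATCC",
    "HindIII": "AAGCTT",
    "XbaI": "TCTAGA",
    "SalI": "GTCGAC",
    "PstI": "CTGCAG",
    "SmaI": "CCCGGG",
    "KpnI": "GGTACC",
    "SacI": "GAGCTC",
    "SphI": "GCATGC",
    "NcoI": "CCATGG",
    "NdeI": "CATATG",
    "XhoI": "CTCGAG",
    "BglII": "AGATCT",
    "EcoRV": "GATATC",
    "ClaI": "ATCGAT",
    "MluI": "ACGCGT",
    "NheI": "GCTAGC",
    "SpeI": "ACTAGT",
    "ApaI": "GGGCCC",
    "ScaI": "AGTACT",
    "StuI": "AGGCCT",
    "DraI": "TTTAAA",
    "HpaI": "GTTAAC",
    "NotI": "GCGGCCGC",
}


@dataclass(frozen=True)
class RestrictionEnzyme:
    name: str
    recognition_site: str

    def __post_init__(self):
        if len(self.recognition_site) < 4:
            raise ValueError(f"{self.name}: site shorter than 4 bp")
        if set(self.recognition_site) - set("ACGT"):
            raise ValueError(f"{self.name}: ambiguous bases not supported")

    def cut_positions(self, seq: str) -> list[int]:
        """Start offsets of every recognition-site occurrence (both strands
        coincide for the palindromic sites in the packaged table)."""
        out = []
        start = 0
        while True:
            pos = seq.find(self.recognition_site, start)
            if pos < 0:
                return out
            out.append(pos)
            start = pos + 1

    def digest(self, seq: str) -> list[int]:
        """Fragment lengths after cutting a linear sequence at each site."""
        cuts = self.cut_positions(seq)
        if not cuts:
            return [len(seq)]
        bounds = [0] + cuts + [len(seq)]
        return [b - a for a, b in zip(bounds, bounds[1:]) if b > a]


def restriction_enzymes() -> list[RestrictionEnzyme]:
    """The packaged enzyme table as objects."""
    return [RestrictionEnzyme(n, s) for n, s in ENZYME_TABLE.items()]


@dataclass(frozen=True)
class BindingSite:
    """One primer annealing site on a template (plus-strand coords)."""

    start: int
    end: int
    strand: str
    mismatches: int


@dataclass(frozen=True)
class PcrProduct:
    template_id: str
    fwd_site: BindingSite
    rev_site: BindingSite
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


class DiagnosticFailure(Exception):
    """No external diagnostic primer could be designed."""


@dataclass(frozen=True)
class DiagnosticPlan:
    """External primer pair plus the size / enzyme discrimination logic."""

    gene_id: str
    fwd: Primer
    rev: Primer
    wt_len: int
    null_len: int
    size_discriminable: bool
    enzymes: tuple[tuple[str, tuple[int, ...], tuple[int, ...]], ...] = ()


def _pattern_sites(
    template: str, pattern: str, max_mismatch: int, exact_3prime: int, at_start: bool
) -> list[tuple[int, int]]:
    """(offset, mismatches) of every placement of ``pattern`` on ``template``.

    ``exact_3prime`` bases must match exactly; they sit at the pattern end
    (``at_start=False``) or start (``at_start=True``, for minus-strand
    patterns whose 3' terminus maps to the left edge).
    """
    n, m = len(template), len(pattern)
    if n < m:
        return []
    t = _thermo.encode(template)
    p = _thermo.encode(pattern)
    windows = np.lib.stride_tricks.sliding_window_view(t, m)
    mism = (windows != p).sum(axis=1)
    # count N/invalid as mismatch everywhere (encode maps them to -1, which
    # never equals a pattern code; pattern Ns mismatch every template base)
    cand = np.nonzero(mism <= max_mismatch)[0]
    if exact_3prime > 0 and cand.size:
        if at_start:
            crit = (windows[cand, :exact_3prime] != p[:exact_3prime]).any(axis=1)
        else:
            crit = (windows[cand, m - exact_3prime :] != p[m - exact_3prime :]).any(
                axis=1
            )
        cand = cand[~crit]
    return [(int(i), int(mism[i])) for i in cand]


def find_binding_sites(
    template: str,
    primer: Primer | str,
    max_mismatch: int = 0,
    circular: bool = False,
    exact_3prime: int = 3,
) -> list[BindingSite]:
    """All annealing sites of a primer's binding portion, both strands.

    Tails are ignored for matching.  Mismatches are never allowed in the
    ``exact_3prime`` terminal 3' bases.  Sites are returned sorted by
    (start, strand).
    """
    binding = primer.binding_seq if isinstance(primer, Primer) else primer
    n = len(template)
    search = template + template[: len(binding) - 1] if circular else template
    sites = []
    for off, mm in _pattern_sites(search, binding, max_mismatch, exact_3prime, False):
        if off < n:
            sites.append(BindingSite(off, off + len(binding), "+", mm))
    rc = revcomp(binding)
    for off, mm in _pattern_sites(search, rc, max_mismatch, exact_3prime, True):
        if off < n:
            sites.append(BindingSite(off, off + len(binding), "-", mm))
    sites.sort(key=lambda s: (s.start, s.strand))
    return sites


def simulate_pcr(
    template: str,
    fwd: Primer | str,
    rev: Primer | str,
    max_product: int = 10000,
    template_id: str = "",
    max_mismatch: int = 0,
) -> list[PcrProduct]:
    """All products from convergent site pairs within ``max_product`` bp.

    Either primer may prime either strand; a product arises whenever a
    plus-strand site of one primer lies upstream of a minus-strand site of
    the other.  Products are sorted by length.
    """
    if max_product <= 0:
        raise ValueError("max_product must be positive")
    sites_f = find_binding_sites(template, fwd, max_mismatch)
    sites_r = find_binding_sites(template, rev, max_mismatch)
    products = []
    for a_sites, b_sites in ((sites_f, sites_r), (sites_r, sites_f)):
        for sa in a_sites:
            if sa.strand != "+":
                continue
            for sb in b_sites:
                if sb.strand != "-":
                    continue
                if sb.end <= sa.start:
                    continue
                length = sb.end - sa.start
                if length > max_product:
                    continue
                products.append(
                    PcrProduct(
                        template_id=template_id,
                        fwd_site=sa,
                        rev_site=sb,
                        sequence=template[sa.start : sb.end],
                    )
                )
    # a fwd+ / rev- pairing is identical to the rev-/fwd+ view; dedupe
    seen = set()
    unique = []
    for p in products:
        key = (p.fwd_site.start, p.rev_site.end, p.fwd_site.strand, p.rev_site.strand)
        if key not in seen:
            seen.add(key)
            unique.append(p)
    unique.sort(key=lambda p: (p.length, p.fwd_site.start))
    return unique


def build_null_locus(
    genome: Mapping[str, Contig],
    gene: GeneModel,
    construct_or_marker: DeletionConstruct | MarkerCassette,
    marker: MarkerCassette | None = None,
    flanks=None,
) -> Contig:
    """Edit a contig to carry the null allele: replaced interval -> marker.

    The replacement boundary is fixed at the annotated codons (or the domain
    boundaries when ``flanks`` came from a domain-only design); homologous
    recombination happens within the flank homology, so residual vector
    tails on the construct are *not* integrated.  The marker is inserted in
    gene orientation.

    When a :class:`DeletionConstruct` is supplied, ``marker`` is required
    and the construct is validated: its flank sequences must match the
    current genome and it must contain the marker exactly once.  Applying
    the edit twice therefore fails (the locus already carries the marker).
    """
    contig = genome[gene.contig]
    if flanks is not None:
        t_start, t_end = flanks.target_interval
    else:
        t_start, t_end = gene.orf_start, gene.orf_end

    if isinstance(construct_or_marker, MarkerCassette):
        marker = construct_or_marker
        construct_seq = None
    else:
        construct_seq = construct_or_marker.sequence
        if marker is None:
            raise ValueError("marker cassette required to integrate a construct")

    marker_or = marker.sequence if gene.strand == "+" else revcomp(marker.sequence)
    locus = contig.sequence[
        max(0, t_start - marker.length) : t_end + marker.length
    ]
    if marker_or in locus:
        raise ValueError(f"{gene.gene_id}: locus already carries the marker")

    if construct_seq is not None:
        # probe the flank interiors: the amplicon edges may sit a few bases
        # off the codons (the inner primer anchors float in the window)
        n = contig.length
        if flanks is not None:
            five_iv, three_iv = flanks.five_prime_interval, flanks.three_prime_interval
        else:
            span = min(300, t_start, n - t_end)
            left_iv = (t_start - span, t_start)
            right_iv = (t_end, t_end + span)
            five_iv, three_iv = (
                (left_iv, right_iv) if gene.strand == "+" else (right_iv, left_iv)
            )

        def _probe(iv):
            mid = (iv[0] + iv[1]) // 2
            probe = contig.sequence[max(0, mid - 25) : mid + 25]
            return probe if gene.strand == "+" else revcomp(probe)

        i_up = construct_seq.find(_probe(five_iv))
        i_down = construct_seq.find(_probe(three_iv))
        i_marker = construct_seq.find(marker.sequence)
        if i_marker < 0 or construct_seq.find(marker.sequence, i_marker + 1) >= 0:
            raise ValueError(
                f"{gene.gene_id}: construct does not contain the marker exactly once"
            )
        if i_up < 0 or i_down < 0 or not (i_up < i_marker < i_down):
            raise ValueError(
                f"{gene.gene_id}: construct flanks do not match the genome at "
                "the target locus"
            )

    edited = contig.sequence[:t_start] + marker_or + contig.sequence[t_end:]
    return Contig(contig.name, edited)


def _design_external_primer(
    ctx: str,
    window: tuple[int, int],
    orient: str,
    params: DesignParams,
) -> tuple[int, int, float, float] | None:
    """Best primer entirely within ``window`` on the oriented context.

    ``orient`` 'fwd' primes rightward (sequence = ctx slice), 'rev' primes
    leftward (sequence = revcomp of slice).  Scored like cassette primers,
    preferring sites closest to the targeting sequence.
    """
    lo, hi = max(0, window[0]), min(len(ctx), window[1])
    if hi - lo < params.len_min:
        return None
    codes = _thermo.encode(ctx[lo:hi])
    ending, starting = _thermo.run_lengths(codes)
    best = None
    for length in range(params.len_min, params.len_max + 1):
        tm = _thermo.window_tm(codes, length)
        gc = _thermo.window_gc(codes, length)
        for start in range(codes.size - length + 1):
            t = tm[start]
            if np.isnan(t) or not (params.tm_min <= t <= params.tm_max):
                continue
            if not (params.gc_min <= gc[start] <= params.gc_max):
                continue
            run = ending[start + length - 1] if orient == "fwd" else starting[start]
            if min(int(run), length) > params.max_homopolymer:
                continue
            # prefer sites nearest the flank boundary: rightmost for fwd,
            # leftmost for rev
            prox = (hi - lo) - (start + length) if orient == "fwd" else start
            score = (abs(float(t) - params.tm_opt), prox, start, length)
            if best is None or score < best[0]:
                best = (score, lo + start, length, float(t), float(gc[start]))
    if best is None:
        return None
    return best[1], best[2], best[3], best[4]


def design_diagnostic(
    gene: GeneModel,
    genome: Mapping[str, Contig],
    construct: DeletionConstruct,
    pset: PrimerSet,
    marker: MarkerCassette,
    params: DesignParams | None = None,
) -> DiagnosticPlan:
    """Design the genotyping assay for one deletion.

    Primers are placed strictly outside the targeting sequence (the union of
    both flank intervals), within ``ext_offset`` bp beyond it.  Product
    sizes come from :func:`simulate_pcr` on the wild-type and null contigs;
    ``null_len - wt_len`` must equal ``marker_len - replaced_len``.  When
    the size difference is below ``min_gel_delta`` the plan lists every
    packaged enzyme that cuts the null product but not the wild-type one.
    """
    params = params or DesignParams()
    contig = genome[gene.contig]
    n = contig.length
    flanks = pset.flanks
    ivs = [flanks.five_prime_interval, flanks.three_prime_interval]
    region_lo = min(iv[0] for iv in ivs)
    region_hi = max(iv[1] for iv in ivs)

    ctx = contig.sequence if gene.strand == "+" else revcomp(contig.sequence)
    if gene.strand == "+":
        lo_or, hi_or = region_lo, region_hi
    else:
        lo_or, hi_or = n - region_hi, n - region_lo

    fwd_win = (lo_or - params.ext_offset, lo_or)
    rev_win = (hi_or, hi_or + params.ext_offset)
    fwd_hit = _design_external_primer(ctx, fwd_win, "fwd", params)
    rev_hit = _design_external_primer(ctx, rev_win, "rev", params)
    if fwd_hit is None or rev_hit is None:
        raise DiagnosticFailure(f"{gene.gene_id}: no external primer designable")

    def _mk(role_start, length, tm, gc, oriented_fwd):
        if gene.strand == "+":
            g_start, g_end = role_start, role_start + length
            strand = "+" if oriented_fwd else "-"
        else:
            g_start, g_end = n - (role_start + length), n - role_start
            strand = "-" if oriented_fwd else "+"
        seq = contig.sequence[g_start:g_end]
        if strand == "-":
            seq = revcomp(seq)
        role = "5f" if oriented_fwd else "3r"
        return Primer(
            role=role,
            binding_seq=seq,
            anchor_contig=gene.contig,
            anchor_start=g_start,
            anchor_end=g_end,
            strand=strand,
            tm=tm,
            gc_fraction=gc,
        )

    fwd_primer = _mk(*fwd_hit, True)
    rev_primer = _mk(*rev_hit, False)

    null_contig = build_null_locus(genome, gene, construct, marker=marker, flanks=flanks)
    wt_products = simulate_pcr(
        contig.sequence, fwd_primer, rev_primer, params.max_product, "wt"
    )
    null_products = simulate_pcr(
        null_contig.sequence, fwd_primer, rev_primer, params.max_product, "null"
    )
    if len(wt_products) != 1 or len(null_products) != 1:
        raise DiagnosticFailure(
            f"{gene.gene_id}: diagnostic primers do not yield a unique product"
        )
    wt_len = wt_products[0].length
    null_len = null_products[0].length
    replaced_len = flanks.target_interval[1] - flanks.target_interval[0]
    expected_delta = marker.length - replaced_len
    if null_len - wt_len != expected_delta:
        raise AssertionError(
            f"{gene.gene_id}: allele size identity violated "
            f"({null_len} - {wt_len} != {expected_delta})"
        )

    size_ok = abs(null_len - wt_len) >= params.min_gel_delta
    enzymes: list[tuple[str, tuple[int, ...], tuple[int, ...]]] = []
    if not size_ok:
        wt_seq = wt_products[0].sequence
        null_seq = null_products[0].sequence
        for enz in restriction_enzymes():
            if enz.cut_positions(null_seq) and not enz.cut_positions(wt_seq):
                enzymes.append(
                    (enz.name, tuple(enz.digest(wt_seq)), tuple(enz.digest(null_seq)))
                )
    return DiagnosticPlan(
        gene_id=gene.gene_id,
        fwd=fwd_primer,
        rev=rev_primer,
        wt_len=wt_len,
        null_len=null_len,
        size_discriminable=size_ok,
        enzymes=tuple(enzymes),
    )


GENOTYPES = ("wt", "null", "heterokaryon", "diploid")


def predict_genotype_bands(plan: DiagnosticPlan, genotype: str) -> set[int]:
    """Diagnostic band sizes expected for a genotype.

    Heterokaryons and diploids both show *both* alleles; PCR alone cannot
    tell them apart (streak stability does, see :mod:`delkit.rescue`).
    """
    if genotype == "wt":
        return {plan.wt_len}
    if genotype == "null":
        return {plan.null_len}
    if genotype in ("heterokaryon", "diploid"):
        return {plan.wt_len, plan.null_len}
    raise ValueError(f"unknown genotype {genotype!r}")
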