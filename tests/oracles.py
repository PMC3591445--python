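"""Independent brute-force oracles used to cross-check the package.

Everything here is deliberately written with plain loops, string methods
and direct Biopython calls so it shares no code path with delkit's
vectorized implementations.
"""

from __future__ import annotations

from Bio.Seq import Seq
from Bio.SeqUtils import MeltingTemp, gc_fraction


def rc(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def primer_ok(seq: str, params) -> bool:
    """Physico-chemical validity of one primer (Biopython Tm, plain checks)."""
    if "N" in seq:
        return False
    gc = gc_fraction(seq)
    if not (params.gc_min <= gc <= params.gc_max):
        return False
    run = 1
    for i in range(len(seq) - 1, 0, -1):
        if seq[i] == seq[i - 1]:
            run += 1
        else:
            break
    if run > params.max_homopolymer:
        return False
    tm = MeltingTemp.Tm_NN(seq)
    return params.tm_min <= tm <= params.tm_max


def _unique_in_context(ctx: str, t_start: int, t_end: int, binding: str, params) -> bool:
    lo = max(0, t_start - params.max_flank - params.uniqueness_context)
    hi = min(len(ctx), t_end + params.max_flank + params.uniqueness_context)
    region = ctx[lo:hi]
    total = 0
    for pat in (binding, rc(binding)):
        start = 0
        while True:
            p = region.find(pat, start)
            if p < 0:
                break
            total += 1
            start = p + 1
    return total == 1


def side_feasible(
    ctx: str, t_start: int, t_end: int, side: str, window: int, params
) -> bool:
    """Does any valid (inner, outer) primer pair exist on one side?

    Exhaustive enumeration over inner anchors in the window and outer
    positions in the flank-length range.
    """
    n = len(ctx)
    lengths = range(params.len_min, params.len_max + 1)
    anchor = t_start if side == "5" else t_end
    for a in range(anchor - window, anchor + window + 1):
        for L in lengths:
            if side == "5":
                lo, hi = a, a + L  # rev primer site
                if lo < 0 or hi > n:
                    continue
                inner = rc(ctx[lo:hi])
                amp_inner_edge = hi  # amplicon right edge
            else:
                lo, hi = a - L, a  # fwd primer, 3' end at a
                if lo < 0 or hi > n:
                    continue
                inner = ctx[lo:hi]
                amp_inner_edge = lo  # amplicon left edge
            if not primer_ok(inner, params):
                continue
            if not _unique_in_context(ctx, t_start, t_end, inner, params):
                continue
            # any compatible outer?
            for alen in range(params.min_flank, params.max_flank + 1):
                for OL in lengths:
                    if side == "5":
                        f = amp_inner_edge - alen
                        if f < 0:
                            continue
                        outer = ctx[f : f + OL]
                    else:
                        end = amp_inner_edge + alen
                        if end > n:
                            continue
                        outer = rc(ctx[end - OL : end])
                    if len(outer) != OL:
                        continue
                    if primer_ok(outer, params) and _unique_in_context(
                        ctx, t_start, t_end, outer, params
                    ):
                        return True
    return False


def classify_design_outcome(gene, genome, params) -> str:
    """Feasibility class: fail_contig_end / ok_window30 / ok_window75 / fail.

    Fully independent of delkit's search: orientation handling, candidate
    enumeration and scoring are all re-derived here.
    """
    contig = genome[gene.contig]
    left = gene.orf_start
    right = contig.length - gene.orf_end
    if min(left, right) < params.min_flank:
        return "fail_contig_end"
    ctx = contig.sequence if gene.strand == "+" else rc(contig.sequence)
    n = contig.length
    if gene.strand == "+":
        t_start, t_end = gene.orf_start, gene.orf_end
    else:
        t_start, t_end = n - gene.orf_end, n - gene.orf_start
    for w in params.window_sequence:
        if side_feasible(ctx, t_start, t_end, "5", w, params) and side_feasible(
            ctx, t_start, t_end, "3", w, params
        ):
            return f"ok_window{w}"
    return "fail"


def naive_binding_sites(
    template: str, binding: str, max_mismatch: int, exact_3prime: int = 3
) -> set[tuple[int, str]]:
    """All (start, strand) annealing sites by exhaustive mismatch-pattern
    enumeration + ``str.find`` — an approach disjoint from the vectorized
    window comparison it checks."""
    sites: set[tuple[int, str]] = set()

    def scan(pattern_base: str, strand: str, protect: str):
        m = len(pattern_base)
        patterns = {pattern_base}
        if max_mismatch >= 1:
            rng = (
                range(m - exact_3prime)
                if protect == "end"
                else range(exact_3prime, m)
            )
            for i in rng:
                for b in "ACGT":
                    if b != pattern_base[i]:
                        patterns.add(pattern_base[:i] + b + pattern_base[i + 1 :])
        if max_mismatch >= 2:
            raise NotImplementedError
        for pat in patterns:
            start = 0
            while True:
                p = template.find(pat, start)
                if p < 0:
                    break
                sites.add((p, strand))
                start = p + 1

    scan(binding, "+", "end")
    scan(rc(binding), "-", "start")
    return sites


def naive_products(template: str, fwd: str, rev: str, max_product: int) -> set[tuple[int, int]]:
    """(start, end) spans of all convergent products, brute force."""
    f_sites = naive_binding_sites(template, fwd, 0)
    r_sites = naive_binding_sites(template, rev, 0)
    spans = set()
    for a_sites, a_len, b_sites, b_len in (
        (f_sites, len(fwd), r_sites, len(rev)),
        (r_sites, len(rev), f_sites, len(fwd)),
    ):
        for sa, stra in a_sites:
            if stra != "+":
                continue
            for sb, strb in b_sites:
                if strb != "-":
                    continue
                end = sb + b_len
                if end > sa and end - sa <= max_product:
                    spans.add((sa, end))
    return spans
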