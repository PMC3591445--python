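"""Constrained four-primer design for marker-replacement deletion constructs.

Each gene gets a 5f/5r/3f/3r primer quartet.  The inner primers (5r, 3f)
are anchored so their 3' termini fall within a positional window (30 bp by
default, widened to 75 bp on failure) of the start/stop codon; the outer
primers (5f, 3r) are chosen so each homology-flank amplicon is
``min_flank``-``max_flank`` long.  Inner primers later receive 5' tails
complementary to the marker cassette ends, outer primers tails
complementary to the gapped vector ends.

Candidate scoring is deterministic: minimize ``|Tm - tm_opt|``, then the
anchor distance to the codon, then the leftmost coordinate, then length.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from delkit import _thermo
from delkit.genome_io import (
    Contig,
    DesignError,
    FlankPair,
    GeneModel,
    extract_flanks,
    revcomp,
)

ROLES = ("5f", "5r", "3f", "3r")


@dataclass
class DesignParams:
    """All tunables of the primer-design search.

    Physico-chemical defaults: 18-28 nt, Tm 55-65 deg C by nearest-neighbor
    thermodynamics at 50 mM monovalent salt, GC 30-70%, no homopolymer run
    longer than 4 at the 3' end.
    """

    window_sequence: tuple[int, ...] = (30, 75)
    min_flank: int = 600
    max_flank: int = 1000
    len_min: int = 18
    len_max: int = 28
    tm_min: float = 55.0
    tm_max: float = 65.0
    tm_opt: float = 60.0
    gc_min: float = 0.30
    gc_max: float = 0.70
    max_homopolymer: int = 4
    tail_len: int = 29
    uniqueness_context: int = 1000
    ext_offset: int = 300
    min_gel_delta: int = 150
    max_product: int = 10000
    min_homology: int = 20

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DesignParams":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "window_sequence" in data:
            data["window_sequence"] = tuple(data["window_sequence"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = dict(self.__dict__)
        data["window_sequence"] = list(self.window_sequence)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


@dataclass(frozen=True)
class Primer:
    """One design primer.

    ``binding_seq`` is the 3'-anchored genomic-binding portion written 5'->3'
    as synthesized; ``tail_seq`` is the optional 5' extension.  The genomic
    anchor is the plus-strand interval of the binding site; ``strand`` is the
    strand the primer sequence equals (the strand it primes synthesis of).
    """

    role: str
    binding_seq: str
    anchor_contig: str
    anchor_start: int
    anchor_end: int
    strand: str
    tm: float
    gc_fraction: float
    tail_seq: str = ""

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValueError(f"unknown primer role {self.role!r}")
        if self.anchor_end - self.anchor_start != len(self.binding_seq):
            raise ValueError(f"{self.role}: anchor does not match binding length")

    @property
    def full_seq(self) -> str:
        return self.tail_seq + self.binding_seq

    @property
    def length(self) -> int:
        return len(self.binding_seq)


@dataclass(frozen=True)
class PrimerSet:
    """A complete, validated 5f/5r/3f/3r quartet for one gene."""

    gene_id: str
    primers: Mapping[str, Primer]
    window_used: int
    flanks: FlankPair

    def __post_init__(self):
        if set(self.primers) != set(ROLES):
            raise ValueError("primer set must contain exactly the roles 5f,5r,3f,3r")

    @property
    def is_tailed(self) -> bool:
        return any(p.tail_seq for p in self.primers.values())

    def _oriented_contig(self, genome: Mapping[str, Contig]) -> str:
        seq = genome[self.flanks.contig].sequence
        return seq if self.flanks.strand == "+" else revcomp(seq)

    def _amplicon(self, genome: Mapping[str, Contig], outer: str, inner: str) -> str:
        """Tailed amplicon spanning the outer->inner primer pair."""
        ctx = self._oriented_contig(genome)
        n = len(ctx)
        po, pi = self.primers[outer], self.primers[inner]
        ivs = []
        for p in (po, pi):
            if self.flanks.strand == "+":
                ivs.append((p.anchor_start, p.anchor_end))
            else:
                ivs.append((n - p.anchor_end, n - p.anchor_start))
        start = min(iv[0] for iv in ivs)
        end = max(iv[1] for iv in ivs)
        return po.tail_seq + ctx[start:end] + revcomp(pi.tail_seq)

    def flank5_amplicon(self, genome: Mapping[str, Contig]) -> str:
        """5' flank PCR product (5f -> 5r), including any primer tails."""
        return self._amplicon(genome, "5f", "5r")

    def flank3_amplicon(self, genome: Mapping[str, Contig]) -> str:
        """3' flank PCR product (3f -> 3r).  Note 3f is the left/outer-tail
        carrier here only in the marker sense: its tail matches the marker."""
        ctx = self._oriented_contig(genome)
        n = len(ctx)
        p3f, p3r = self.primers["3f"], self.primers["3r"]
        ivs = []
        for p in (p3f, p3r):
            if self.flanks.strand == "+":
                ivs.append((p.anchor_start, p.anchor_end))
            else:
                ivs.append((n - p.anchor_end, n - p.anchor_start))
        start = min(iv[0] for iv in ivs)
        end = max(iv[1] for iv in ivs)
        return p3f.tail_seq + ctx[start:end] + revcomp(p3r.tail_seq)


@dataclass(frozen=True)
class MarkerCassette:
    """The selectable marker cassette and the tails primers need to fuse to it.

    ``left_tail`` goes on 5r (so the 5' flank amplicon ends with the
    cassette's left terminus) and ``right_tail`` on 3f (so the 3' flank
    amplicon begins with the cassette's right terminus).
    """

    name: str
    sequence: str
    tail_len: int = 29

    def __post_init__(self):
        if len(self.sequence) < 2 * self.tail_len:
            raise ValueError("marker shorter than twice the tail length")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def left_tail(self) -> str:
        return revcomp(self.sequence[: self.tail_len])

    @property
    def right_tail(self) -> str:
        return self.sequence[len(self.sequence) - self.tail_len :]


@dataclass(frozen=True)
class DesignFailure:
    """A typed per-gene design failure (returned, never raised)."""

    gene_id: str
    reason: str
    detail: str = ""


class _SideCandidates:
    """Validity/Tm/GC arrays for all primer windows on one oriented region."""

    def __init__(self, ctx: str, lo: int, hi: int, params: DesignParams):
        self.offset = max(0, lo)
        region = ctx[self.offset : min(len(ctx), hi)]
        self.codes = _thermo.encode(region)
        self.n = self.codes.size
        self.params = params
        self._ending, self._starting = _thermo.run_lengths(self.codes)
        self._by_len: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}

    def arrays(self, length: int):
        """(tm, gc, base_valid) arrays indexed by window start within region."""
        if length not in self._by_len:
            tm = _thermo.window_tm(self.codes, length)
            gc = _thermo.window_gc(self.codes, length)
            p = self.params
            with np.errstate(invalid="ignore"):
                valid = (
                    ~np.isnan(tm)
                    & (tm >= p.tm_min)
                    & (tm <= p.tm_max)
                    & (gc >= p.gc_min)
                    & (gc <= p.gc_max)
                )
            self._by_len[length] = (tm, gc, valid)
        return self._by_len[length]

    def homopolymer_ok(self, start: int, length: int, orient: str) -> np.ndarray | bool:
        """3'-end homopolymer constraint for window(s) at region-local start."""
        p = self.params
        if orient == "fwd":
            run = self._ending[start + length - 1]
        else:
            run = self._starting[start]
        return min(int(run), length) <= p.max_homopolymer


def _count_occurrences(haystack: str, needle: str) -> int:
    """Overlap-aware substring count."""
    count = start = 0
    while True:
        pos = haystack.find(needle, start)
        if pos < 0:
            return count
        count += 1
        start = pos + 1


def _candidate_list(
    side: _SideCandidates,
    pos_lo: int,
    pos_hi: int,
    orient: str,
    anchor: int | None,
    params: DesignParams,
) -> list[tuple[tuple, int, int, float, float]]:
    """Enumerate valid primer windows, sorted by the deterministic score.

    ``pos_lo``/``pos_hi`` bound the window *start* (region-local, inclusive).
    ``anchor``, when given, is the codon position the 3' terminus is scored
    against (region-local; fwd primers anchor at window end, rev at start).
    Returns tuples (score, start, length, tm, gc).
    """
    out = []
    for length in range(params.len_min, params.len_max + 1):
        tm, gc, valid = side.arrays(length)
        lo = max(0, pos_lo)
        hi = min(side.n - length, pos_hi)
        if hi < lo:
            continue
        idx = np.nonzero(valid[lo : hi + 1])[0] + lo
        for start in idx:
            if not side.homopolymer_ok(int(start), length, orient):
                continue
            if anchor is not None:
                end3 = int(start) + length if orient == "fwd" else int(start)
                dist = abs(end3 - anchor)
            else:
                dist = 0
            score = (abs(float(tm[start]) - params.tm_opt), dist, int(start), length)
            out.append((score, int(start), length, float(tm[start]), float(gc[start])))
    out.sort(key=lambda t: t[0])
    return out


def _is_unique(ctx: str, t_start: int, t_end: int, binding: str, params: DesignParams) -> bool:
    """Binding sequence occurs exactly once in the flanks + 1 kb context."""
    lo = max(0, t_start - params.max_flank - params.uniqueness_context)
    hi = min(len(ctx), t_end + params.max_flank + params.uniqueness_context)
    region = ctx[lo:hi]
    n = _count_occurrences(region, binding) + _count_occurrences(region, revcomp(binding))
    return n == 1


def _design_side(
    ctx: str,
    t_start: int,
    t_end: int,
    side_name: str,
    window: int,
    params: DesignParams,
) -> tuple[dict, dict] | str:
    """Design the (outer, inner) primer pair for one side, oriented coords.

    Returns two dicts with region-global window coords, or a failure reason
    string (``no_primer_in_window`` / ``constraint_unsatisfiable``).
    """
    n = len(ctx)
    w = window
    pad = params.len_max
    if side_name == "5":
        region_lo = t_start - params.max_flank - w - pad
        region_hi = t_start + w + pad
        anchor_global = t_start
    else:
        region_lo = t_end - w - pad
        region_hi = t_end + params.max_flank + w + pad
        anchor_global = t_end
    side = _SideCandidates(ctx, region_lo, region_hi, params)
    off = side.offset
    anchor_local = anchor_global - off

    if side_name == "5":
        # inner = 5r (rev primer): 3' terminus at window start
        inner = _candidate_list(
            side, anchor_local - w, anchor_local + w, "rev", anchor_local, params
        )
    else:
        # inner = 3f (fwd primer): 3' terminus at window end
        inner = _candidate_list(
            side,
            anchor_local - w - params.len_max,
            anchor_local + w,
            "fwd",
            anchor_local,
            params,
        )
        inner = [c for c in inner if c[0][1] <= w]
    if not inner:
        return "no_primer_in_window"

    for _, i_start, i_len, i_tm, i_gc in inner:
        if side_name == "5":
            amp_end = i_start + i_len  # amplicon right edge (local)
            binding_inner = revcomp(
                ctx[off + i_start : off + i_start + i_len]
            )
        else:
            amp_start = i_start
            binding_inner = ctx[off + i_start : off + i_start + i_len]
        if not _is_unique(ctx, t_start, t_end, binding_inner, params):
            continue

        if side_name == "5":
            out_lo = amp_end - params.max_flank
            out_hi_end = amp_end - params.min_flank  # outer window END bound
            outers = []
            for length in range(params.len_min, params.len_max + 1):
                lo = max(0, out_lo)
                hi = min(out_hi_end, side.n - length)
                tm, gc, valid = side.arrays(length)
                if hi < lo:
                    continue
                idx = np.nonzero(valid[lo : hi + 1])[0] + lo
                for start in idx:
                    # amplicon spans [start, amp_end); enforce flank bounds
                    alen = amp_end - int(start)
                    if not (params.min_flank <= alen <= params.max_flank):
                        continue
                    if off + start < 0 or not side.homopolymer_ok(int(start), length, "fwd"):
                        continue
                    score = (abs(float(tm[start]) - params.tm_opt), int(start), length)
                    outers.append((score, int(start), length, float(tm[start]), float(gc[start])))
        else:
            outers = []
            for length in range(params.len_min, params.len_max + 1):
                tm, gc, valid = side.arrays(length)
                lo = max(0, amp_start + params.min_flank - length)
                hi = min(amp_start + params.max_flank - length, side.n - length)
                if hi < lo:
                    continue
                idx = np.nonzero(valid[lo : hi + 1])[0] + lo
                for start in idx:
                    if off + start + length > n:
                        continue
                    if not side.homopolymer_ok(int(start), length, "rev"):
                        continue
                    score = (abs(float(tm[start]) - params.tm_opt), int(start), length)
                    outers.append((score, int(start), length, float(tm[start]), float(gc[start])))
        outers.sort(key=lambda t: t[0])
        for _, o_start, o_len, o_tm, o_gc in outers:
            if side_name == "5":
                binding_outer = ctx[off + o_start : off + o_start + o_len]
            else:
                binding_outer = revcomp(ctx[off + o_start : off + o_start + o_len])
            if not _is_unique(ctx, t_start, t_end, binding_outer, params):
                continue
            inner_d = {
                "start": off + i_start,
                "length": i_len,
                "tm": i_tm,
                "gc": i_gc,
                "binding": binding_inner,
            }
            outer_d = {
                "start": off + o_start,
                "length": o_len,
                "tm": o_tm,
                "gc": o_gc,
                "binding": binding_outer,
            }
            return outer_d, inner_d
    return "constraint_unsatisfiable"


def _to_genomic(
    gene: GeneModel, contig_len: int, start: int, length: int, oriented_fwd: bool
) -> tuple[int, int, str]:
    """Map an oriented window back to plus-strand genomic coords + strand."""
    if gene.strand == "+":
        g_start, g_end = start, start + length
        strand = "+" if oriented_fwd else "-"
    else:
        g_start = contig_len - (start + length)
        g_end = contig_len - start
        strand = "-" if oriented_fwd else "+"
    return g_start, g_end, strand


def design_primer_set(
    gene: GeneModel,
    genome: Mapping[str, Contig],
    params: DesignParams | None = None,
    domain_only: bool = False,
) -> PrimerSet | DesignFailure:
    """Design the untailed 5f/5r/3f/3r quartet for a gene.

    Returns a :class:`PrimerSet` on success or a :class:`DesignFailure`
    (reason ``contig_end``, ``no_primer_in_window`` or
    ``constraint_unsatisfiable``); never raises for design-level problems.
    """
    params = params or DesignParams()
    try:
        flanks = extract_flanks(
            gene,
            genome,
            min_flank=params.min_flank,
            max_flank=params.max_flank,
            domain_only=domain_only,
        )
    except DesignError as err:
        return DesignFailure(gene.gene_id, err.reason, err.detail)

    contig = genome[gene.contig]
    ctx = contig.sequence if gene.strand == "+" else revcomp(contig.sequence)
    n = contig.length
    t_start, t_end = flanks.target_interval
    if gene.strand == "-":
        t_start, t_end = n - flanks.target_interval[1], n - flanks.target_interval[0]

    saw_no_inner = False
    for w in params.window_sequence:
        res5 = _design_side(ctx, t_start, t_end, "5", w, params)
        res3 = _design_side(ctx, t_start, t_end, "3", w, params)
        if isinstance(res5, str) or isinstance(res3, str):
            for r in (res5, res3):
                if r == "no_primer_in_window":
                    saw_no_inner = True
            continue
        (o5, i5), (o3, i3) = res5, res3
        primers = {}
        for role, d, oriented_fwd in (
            ("5f", o5, True),
            ("5r", i5, False),
            ("3f", i3, True),
            ("3r", o3, False),
        ):
            g_start, g_end, strand = _to_genomic(
                gene, n, d["start"], d["length"], oriented_fwd
            )
            primers[role] = Primer(
                role=role,
                binding_seq=d["binding"],
                anchor_contig=gene.contig,
                anchor_start=g_start,
                anchor_end=g_end,
                strand=strand,
                tm=d["tm"],
                gc_fraction=d["gc"],
            )
        return PrimerSet(
            gene_id=gene.gene_id, primers=primers, window_used=w, flanks=flanks
        )
    reason = "no_primer_in_window" if saw_no_inner else "constraint_unsatisfiable"
    return DesignFailure(gene.gene_id, reason)


def design_domain_deletion(
    gene: GeneModel,
    genome: Mapping[str, Contig],
    params: DesignParams | None = None,
) -> PrimerSet | DesignFailure:
    """Like :func:`design_primer_set` but replacing only the kinase domain.

    Used for very large genes where whole-ORF replacement is inefficient.
    Raises ``ValueError`` if the gene carries no domain annotation.
    """
    if not gene.has_domain:
        raise ValueError(f"{gene.gene_id}: no kinase-domain interval annotated")
    return design_primer_set(gene, genome, params, domain_only=True)


def attach_tails(
    pset: PrimerSet,
    marker: MarkerCassette,
    vector_tails: tuple[str, str],
) -> PrimerSet:
    """Attach assembly tails: marker tails on 5r/3f, vector tails on 5f/3r.

    ``vector_tails`` is the (5f tail, 3r tail) pair.  Binding portions are
    untouched.  Re-tailing an already tailed set raises ``ValueError``.
    """
    if pset.is_tailed:
        raise ValueError(f"{pset.gene_id}: primer set already carries tails")
    tails = {
        "5f": vector_tails[0],
        "5r": marker.left_tail,
        "3f": marker.right_tail,
        "3r": vector_tails[1],
    }
    primers = {
        role: replace(p, tail_seq=tails[role]) for role, p in pset.primers.items()
    }
    return PrimerSet(
        gene_id=pset.gene_id,
        primers=primers,
        window_used=pset.window_used,
        flanks=pset.flanks,
    )


def write_primer_report(psets, path: str | Path) -> None:
    """Primer TSV: one row per primer with anchors, tails and metrics."""
    cols = [
        "gene_id", "role", "full_seq", "binding_seq", "tail_seq",
        "anchor_contig", "anchor_start", "anchor_end", "strand",
        "tm", "gc", "window_used",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for ps in psets:
            for role in ROLES:
                p = ps.primers[role]
                fh.write(
                    "\t".join(
                        str(v)
                        for v in (
                            ps.gene_id, role, p.full_seq, p.binding_seq,
                            p.tail_seq, p.anchor_contig, p.anchor_start,
                            p.anchor_end, p.strand, f"{p.tm:.2f}",
                            f"{p.gc_fraction:.3f}", ps.window_used,
                        )
                    )
                    + "\n"
                )
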