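"""Construct assembly: yeast gap-repair recombination and fusion PCR.

Fragments are joined by exact terminal homology (the primer tails).  Both
assembly routes produce the same 5'flank-marker-3'flank core; the final
linear construct retains the residual outer vector tails that are
physically present after amplification with the tailed 5f/3r primers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from delkit.cassette_design import MarkerCassette, Primer
from delkit.genome_io import revcomp


class AssemblyError(Exception):
    """A junction lacked the required homology or was ambiguous."""


class AmplificationError(Exception):
    """A primer bound the template zero times or more than once."""


@dataclass(frozen=True)
class VectorBackbone:
    """A circular shuttle vector with a pre-specified gap interval.

    ``gap_site`` (0-based half-open on the circular sequence, no wrap) is the
    stretch removed by digestion; the insert replaces it.  The sequence left
    of the gap provides the upstream homology end, the sequence right of the
    gap the downstream end.
    """

    name: str
    sequence: str
    gap_site: tuple[int, int]

    def __post_init__(self):
        g0, g1 = self.gap_site
        if not (0 <= g0 < g1 <= len(self.sequence)):
            raise ValueError("gap_site must lie within the vector sequence")

    @property
    def backbone(self) -> str:
        """The retained linear backbone, reading away from the gap.

        Starts at the downstream gap edge and ends at the upstream edge, so
        ``backbone[-k:]`` is the end the 5' flank joins and ``backbone[:k]``
        the end the 3' flank joins.
        """
        g0, g1 = self.gap_site
        return self.sequence[g1:] + self.sequence[:g0]

    def upstream_end(self, k: int) -> str:
        """Last ``k`` bases before the gap (5f tail source)."""
        return self.backbone[-k:]

    def downstream_start(self, k: int) -> str:
        """First ``k`` bases after the gap (3r tail source, as revcomp)."""
        return self.backbone[:k]

    def exposed_tails(self, tail_len: int) -> tuple[str, str]:
        """The (5f, 3r) tails required for recombination into this gap."""
        return self.upstream_end(tail_len), revcomp(self.downstream_start(tail_len))


@dataclass(frozen=True)
class DeletionConstruct:
    """An assembled linear deletion construct."""

    gene_id: str
    sequence: str
    route: str
    plasmid_seq: str | None = None

    @property
    def length(self) -> int:
        return len(self.sequence)


def _terminal_overlap(left: str, right: str) -> int:
    """Longest L with ``left[-L:] == right[:L]``."""
    max_l = min(len(left), len(right))
    for L in range(max_l, 0, -1):
        if left.endswith(right[:L]):
            return L
    return 0


def _orient_and_join(
    left: str, frag: str, min_homology: int, junction: str
) -> tuple[str, int, str]:
    """Join ``frag`` (either orientation) onto the end of ``left``.

    Returns (merged, overlap, oriented_frag).  Raises
    :class:`AssemblyError` if no orientation yields ``>= min_homology``
    terminal identity, or if both do (ambiguous).
    """
    fwd = _terminal_overlap(left, frag)
    rc = revcomp(frag)
    rev = _terminal_overlap(left, rc)
    ok_fwd = fwd >= min_homology
    ok_rev = rev >= min_homology
    if ok_fwd and ok_rev:
        raise AssemblyError(f"ambiguous homology at {junction} junction")
    if ok_fwd:
        return left + frag[fwd:], fwd, frag
    if ok_rev:
        return left + rc[rev:], rev, rc
    raise AssemblyError(
        f"{junction} junction homology {max(fwd, rev)} < {min_homology}"
    )


def simulate_recombination(
    flank5_amp: str,
    flank3_amp: str,
    marker: MarkerCassette,
    vector: VectorBackbone,
    min_homology: int = 20,
    gene_id: str = "",
    junctions: dict | None = None,
) -> str:
    """Assemble the circular plasmid by in-vivo gap repair.

    All four junctions (vector-flank5, flank5-marker, marker-flank3,
    flank3-vector) must share at least ``min_homology`` exact terminal
    identity; each shared region appears exactly once in the product.
    Returns the circular plasmid sequence, linearized to start at the
    downstream gap edge of the vector backbone.
    """
    assembly = vector.backbone
    log = {}
    for frag, junction in (
        (flank5_amp, "vector-flank5"),
        (marker.sequence, "flank5-marker"),
        (flank3_amp, "marker-flank3"),
    ):
        assembly, overlap, _ = _orient_and_join(assembly, frag, min_homology, junction)
        log[junction] = overlap
    # close the circle: end of flank3 overlaps the start of the backbone
    closing = _terminal_overlap(assembly, vector.backbone[: len(flank3_amp)])
    if closing < min_homology:
        raise AssemblyError(
            f"flank3-vector junction homology {closing} < {min_homology}"
        )
    log["flank3-vector"] = closing
    if junctions is not None:
        junctions.update(log)
    return assembly[: len(assembly) - closing]


def simulate_fusion_pcr(
    flank5_amp: str,
    flank3_amp: str,
    marker: MarkerCassette,
    outer_primers: tuple[Primer, Primer],
    min_homology: int = 20,
    gene_id: str = "",
) -> DeletionConstruct:
    """Join flanks and marker through their tail overlaps, then amplify.

    The alternative route used when recombinational cloning fails; produces
    a construct identical in its flank-marker-flank core.  ``outer_primers``
    is the (5f, 3r) pair; their binding portions must prime the fused
    template convergently at its ends.
    """
    core, _, _ = _orient_and_join(
        flank5_amp, marker.sequence, min_homology, "flank5-marker"
    )
    core, _, _ = _orient_and_join(core, flank3_amp, min_homology, "marker-flank3")

    p5f, p3r = outer_primers
    fwd_site = core.find(p5f.binding_seq)
    rev_site = core.find(revcomp(p3r.binding_seq))
    if fwd_site < 0 or rev_site < 0 or fwd_site >= rev_site:
        raise AssemblyError("outer primers do not prime the fused template convergently")
    product = (
        p5f.tail_seq
        + core[fwd_site : rev_site + len(p3r.binding_seq)]
        + revcomp(p3r.tail_seq)
    )
    return DeletionConstruct(gene_id=gene_id, sequence=product, route="fusion_pcr")


def amplify_final_construct(
    plasmid: str,
    p5f: Primer,
    p3r: Primer,
    gene_id: str = "",
) -> DeletionConstruct:
    """PCR the linear construct off the circular assembled plasmid.

    Both primers must bind exactly once, convergently; the product spans
    5f -> 3r (wrapping the origin if needed) and keeps the primer tails.
    """
    n = len(plasmid)
    doubled = plasmid + plasmid

    def _sites(pattern: str) -> list[int]:
        hits = []
        start = 0
        while True:
            pos = doubled.find(pattern, start)
            if pos < 0 or pos >= n:
                return hits
            hits.append(pos)
            start = pos + 1

    fwd = _sites(p5f.binding_seq)
    rev = _sites(revcomp(p3r.binding_seq))
    if len(fwd) != 1:
        raise AmplificationError(
            f"5f binds the plasmid {len(fwd)} times (need exactly 1)"
        )
    if len(rev) != 1:
        raise AmplificationError(
            f"3r binds the plasmid {len(rev)} times (need exactly 1)"
        )
    f, r = fwd[0], rev[0]
    end = r + len(p3r.binding_seq)
    if end <= f:
        end += n
    core = doubled[f:end]
    seq = p5f.tail_seq + core + revcomp(p3r.tail_seq)
    return DeletionConstruct(
        gene_id=gene_id, sequence=seq, route="recombination", plasmid_seq=plasmid
    )


def write_assembly_log(logs: dict[str, dict[str, int]], path) -> None:
    """JSON log of junction homology lengths, keyed by gene id."""
    import json

    with open(path, "w") as fh:
        json.dump(logs, fh, indent=2)


def write_construct_genbank(
    construct: DeletionConstruct,
    flank5_amp_len: int,
    marker_len: int,
    tail_len: int,
    path,
) -> None:
    """GenBank flat file with flank5 / marker / flank3 features annotated."""
    from Bio.Seq import Seq
    from Bio.SeqFeature import FeatureLocation, SeqFeature
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    m_start = flank5_amp_len - tail_len
    m_end = m_start + marker_len
    rec = SeqRecord(
        Seq(construct.sequence),
        id=(construct.gene_id or "construct")[:16],
        name=(construct.gene_id or "construct")[:16],
        description=f"deletion construct ({construct.route})",
        annotations={"molecule_type": "DNA"},
    )
    rec.features = [
        SeqFeature(FeatureLocation(0, m_start), type="misc_feature",
                   qualifiers={"label": ["flank5"]}),
        SeqFeature(FeatureLocation(m_start, m_end), type="misc_feature",
                   qualifiers={"label": ["marker"]}),
        SeqFeature(FeatureLocation(m_end, len(construct.sequence)),
                   type="misc_feature", qualifiers={"label": ["flank3"]}),
    ]
    seqio_write([rec], str(path), "genbank")


def write_constructs_fasta(constructs, path) -> None:
    """Write assembled constructs as multi-record FASTA (80-col wrap)."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(c.sequence), id=c.gene_id or "construct", description=c.route)
        for c in constructs
    ]
    seqio_write(records, str(path), "fasta")
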