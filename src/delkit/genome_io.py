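"""Genome and annotation I/O plus coordinate-safe flank extraction.

All intervals are internally 0-based half-open; GFF3 input (1-based
inclusive) is converted on load.  Flanks are always reported in *gene*
orientation: for a minus-strand gene the 5' flank is the
reverse complement of the genomic sequence downstream of the interval.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


class FormatError(ValueError):
    """Malformed input file (duplicate headers, bad characters, ...)."""


class CoordinateError(ValueError):
    """Feature coordinates fall outside their contig."""


class DesignError(Exception):
    """A per-gene design step failed for a classifiable reason.

    ``reason`` is one of ``contig_end``, ``no_primer_in_window`` or
    ``constraint_unsatisfiable``.
    """

    def __init__(self, gene_id: str, reason: str, detail: str = ""):
        self.gene_id = gene_id
        self.reason = reason
        self.detail = detail
        msg = f"{gene_id}: {reason}"
        if detail:
            msg += f" ({detail})"
        super().__init__(msg)


@dataclass(frozen=True)
class Contig:
    """A named chromosome/contig holding an uppercase DNA sequence."""

    name: str
    sequence: str

    def __post_init__(self):
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise FormatError(
                f"contig {self.name!r} contains invalid characters: {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneModel:
    """A strand-aware single-exon ORF interval on a named contig.

    ``orf_start``/``orf_end`` are 0-based half-open genomic coordinates with
    ``orf_start < orf_end`` regardless of strand.  The optional
    ``kinase_domain_start``/``kinase_domain_end`` sub-interval supports
    domain-only deletions of large genes.
    """

    gene_id: str
    contig: str
    orf_start: int
    orf_end: int
    strand: str
    kinase_domain_start: int | None = None
    kinase_domain_end: int | None = None

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if not (0 <= self.orf_start < self.orf_end):
            raise CoordinateError(
                f"{self.gene_id}: bad ORF interval [{self.orf_start}, {self.orf_end})"
            )
        has_ds = self.kinase_domain_start is not None
        has_de = self.kinase_domain_end is not None
        if has_ds != has_de:
            raise ValueError(f"{self.gene_id}: domain interval must be complete")
        if has_ds:
            if not (
                self.orf_start
                <= self.kinase_domain_start
                < self.kinase_domain_end
                <= self.orf_end
            ):
                raise CoordinateError(
                    f"{self.gene_id}: domain interval not inside ORF"
                )

    @property
    def has_domain(self) -> bool:
        return self.kinase_domain_start is not None

    @property
    def length(self) -> int:
        return self.orf_end - self.orf_start


@dataclass(frozen=True)
class FlankPair:
    """Homology flanks abutting a replaced interval, in gene orientation.

    ``five_prime_seq``/``three_prime_seq`` are already reverse-complemented
    for minus-strand genes.  The genomic intervals are plus-strand,
    0-based half-open.
    """

    gene_id: str
    contig: str
    strand: str
    five_prime_seq: str
    five_prime_interval: tuple[int, int]
    three_prime_seq: str
    three_prime_interval: tuple[int, int]
    target_interval: tuple[int, int]

    def __post_init__(self):
        f5, f3 = self.five_prime_interval, self.three_prime_interval
        t = self.target_interval
        # gene orientation: on '-' the genomic roles are swapped
        up, down = (f5, f3) if self.strand == "+" else (f3, f5)
        if up[1] != t[0] or down[0] != t[1]:
            raise ValueError(f"{self.gene_id}: flanks must abut the target")


def load_genome(path: str | Path) -> dict[str, Contig]:
    """Read a (multi-)FASTA into a mapping of contig name -> :class:`Contig`.

    Sequences are uppercased; characters outside {A,C,G,T,N} or duplicate
    headers raise :class:`FormatError`.
    """
    path = Path(path)
    contigs: dict[str, Contig] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in contigs:
            raise FormatError(f"duplicate contig name {rec.id!r} in {path}")
        contigs[rec.id] = Contig(rec.id, str(rec.seq).upper())
    if not contigs:
        raise FormatError(f"no FASTA records found in {path}")
    return contigs


def write_genome(contigs: Mapping[str, Contig] | Iterable[Contig], path: str | Path) -> None:
    """Write contigs as 80-column wrapped FASTA."""
    if isinstance(contigs, Mapping):
        contigs = contigs.values()
    records = [SeqRecord(Seq(c.sequence), id=c.name, description="") for c in contigs]
    SeqIO.write(records, str(path), "fasta")


def load_annotation(path: str | Path, genome: Mapping[str, Contig]) -> list[GeneModel]:
    """Parse ``gene`` features from a GFF3 file into :class:`GeneModel` s.

    GFF3 coordinates (1-based inclusive) are converted to 0-based half-open.
    Models are returned sorted by (contig, orf_start).  Features referencing
    unknown contigs raise :class:`FormatError`; out-of-bounds features raise
    :class:`CoordinateError`.
    """
    path = Path(path)
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="error",
    )
    models = []
    for feat in db.features_of_type("gene"):
        ids = feat.attributes.get("ID")
        if not ids:
            raise FormatError(f"gene feature at {feat.seqid}:{feat.start} lacks ID")
        gene_id = ids[0]
        if feat.seqid not in genome:
            raise FormatError(f"{gene_id}: unknown contig {feat.seqid!r}")
        start, end = feat.start - 1, feat.end
        contig = genome[feat.seqid]
        if start < 0 or end > contig.length:
            raise CoordinateError(
                f"{gene_id}: [{feat.start}, {feat.end}] outside contig "
                f"{feat.seqid} (length {contig.length})"
            )
        dom_s = feat.attributes.get("domain_start")
        dom_e = feat.attributes.get("domain_end")
        models.append(
            GeneModel(
                gene_id=gene_id,
                contig=feat.seqid,
                orf_start=start,
                orf_end=end,
                strand=feat.strand,
                kinase_domain_start=int(dom_s[0]) - 1 if dom_s else None,
                kinase_domain_end=int(dom_e[0]) if dom_e else None,
            )
        )
    models.sort(key=lambda m: (m.contig, m.orf_start))
    return models


def extract_flanks(
    gene: GeneModel,
    genome: Mapping[str, Contig],
    min_flank: int = 600,
    max_flank: int = 1000,
    domain_only: bool = False,
    neighbors: Iterable[GeneModel] = (),
) -> FlankPair:
    """Extract the 5' and 3' homology flanks around a gene's replaced interval.

    The replaced interval is the annotated ORF, or the kinase-domain interval
    when ``domain_only`` is set.  Flank length is
    ``min(max_flank, available sequence to the contig end)`` and must be at
    least ``min_flank``, otherwise :class:`DesignError` with reason
    ``contig_end`` is raised.  Flanks may extend into neighboring genes; if
    ``neighbors`` is provided a warning is logged when they do.
    """
    if min_flank > max_flank:
        raise ValueError("min_flank must be <= max_flank")
    contig = genome[gene.contig]
    if domain_only:
        if not gene.has_domain:
            raise ValueError(f"{gene.gene_id}: no kinase-domain interval annotated")
        t_start, t_end = gene.kinase_domain_start, gene.kinase_domain_end
    else:
        t_start, t_end = gene.orf_start, gene.orf_end

    left_avail = t_start
    right_avail = contig.length - t_end
    left_len = min(max_flank, left_avail)
    right_len = min(max_flank, right_avail)
    if left_len < min_flank or right_len < min_flank:
        raise DesignError(
            gene.gene_id,
            "contig_end",
            f"available flanks {left_avail}/{right_avail} < {min_flank}",
        )

    left_iv = (t_start - left_len, t_start)
    right_iv = (t_end, t_end + right_len)
    left_seq = contig.sequence[left_iv[0] : left_iv[1]]
    right_seq = contig.sequence[right_iv[0] : right_iv[1]]

    for nb in neighbors:
        if nb.gene_id == gene.gene_id or nb.contig != gene.contig:
            continue
        for iv in (left_iv, right_iv):
            if iv[0] < nb.orf_end and nb.orf_start < iv[1]:
                logger.warning(
                    "%s: flank [%d,%d) overlaps neighboring gene %s",
                    gene.gene_id,
                    iv[0],
                    iv[1],
                    nb.gene_id,
                )

    if gene.strand == "+":
        return FlankPair(
            gene_id=gene.gene_id,
            contig=gene.contig,
            strand="+",
            five_prime_seq=left_seq,
            five_prime_interval=left_iv,
            three_prime_seq=right_seq,
            three_prime_interval=right_iv,
            target_interval=(t_start, t_end),
        )
    return FlankPair(
        gene_id=gene.gene_id,
        contig=gene.contig,
        strand="-",
        five_prime_seq=revcomp(right_seq),
        five_prime_interval=right_iv,
        three_prime_seq=revcomp(left_seq),
        three_prime_interval=left_iv,
        target_interval=(t_start, t_end),
    )


def write_failure_report(failures: Iterable[DesignError], path: str | Path) -> None:
    """Serialize design failures to a two-column TSV (gene_id, reason)."""
    with open(path, "w") as fh:
        fh.write("gene_id\treason\n")
        for f in failures:
            fh.write(f"{f.gene_id}\t{f.reason}\n")
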