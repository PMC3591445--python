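"""Deterministic synthetic genomes, markers, vectors and assay observations.

Everything is generated from a seed with known ground truth, so the whole
design/assembly/diagnostic/classification pipeline is testable without any
external downloads.  Contigs carry non-overlapping single-exon ORFs with
configurable intergenic spacing; a configurable fraction of genes is placed
deliberately too close to a contig end to yield the minimum homology flank.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from delkit.assembly_sim import VectorBackbone
from delkit.cassette_design import MarkerCassette
from delkit.genome_io import Contig, GeneModel, revcomp
from delkit.rescue import TransformantObservation

OUTCOMES = ("ok_window30", "ok_window75", "fail_contig_end")


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic genome; the seed fully determines output."""

    seed: int = 1
    n_contigs: int = 8
    n_genes: int = 200
    orf_length_range: tuple[int, int] = (600, 2400)
    intergenic_range: tuple[int, int] = (1400, 2600)
    gc_content: float = 0.5
    fraction_edge_genes: float = 0.05
    fraction_essential: float = 0.2
    marker_length: int = 1732
    vector_length: int = 4500
    tail_length: int = 29
    min_flank: int = 600
    max_flank: int = 1000
    edge_margin: int = 300
    domain_min_orf: int = 2000

    def __post_init__(self):
        for frac in (self.fraction_edge_genes, self.fraction_essential):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must lie in (0, 1)")
        if self.edge_margin >= self.min_flank:
            raise ValueError("edge_margin must be below min_flank")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticSpec":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("orf_length_range", "intergenic_range"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one synthetic gene."""

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str
    essential: bool
    expected_outcome: str
    domain_start: int | None = None
    domain_end: int | None = None


def _random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    codes = rng.choice(4, size=length, p=p)
    return codes.astype(np.uint8).tobytes().translate(
        bytes.maketrans(b"\x00\x01\x02\x03", b"ACGT")
    ).decode("ascii")


def generate_genome(
    spec: SyntheticSpec,
) -> tuple[dict[str, Contig], list[GeneModel], list[TruthRecord]]:
    """Generate contigs, gene models and the per-gene truth table.

    Genes are packed left to right with intergenic gaps drawn from
    ``intergenic_range``; edge genes get a leading (or trailing) gap of only
    ``edge_margin`` bases and are expected to fail flank extraction.
    """
    rng = np.random.default_rng(spec.seed)
    n_edge = round(spec.fraction_edge_genes * spec.n_genes)
    if n_edge > 2 * spec.n_contigs:
        raise ValueError(
            f"cannot place {n_edge} edge genes on {spec.n_contigs} contigs "
            "(max 2 per contig)"
        )

    # distribute genes over contigs as evenly as possible
    per_contig = [spec.n_genes // spec.n_contigs] * spec.n_contigs
    for i in range(spec.n_genes % spec.n_contigs):
        per_contig[i] += 1

    # edge slots: leading slots first, then trailing
    lead_edge = [i < n_edge for i in range(spec.n_contigs)]
    tail_edge = [
        spec.n_contigs + i < n_edge for i in range(spec.n_contigs)
    ]

    essential_idx = set(
        rng.choice(
            spec.n_genes,
            size=round(spec.fraction_essential * spec.n_genes),
            replace=False,
        ).tolist()
    )

    contigs: dict[str, Contig] = {}
    genes: list[GeneModel] = []
    truth: list[TruthRecord] = []
    gene_no = 0
    for ci in range(spec.n_contigs):
        name = f"ctg{ci + 1:02d}"
        pieces: list[str] = []
        pos = 0
        k = per_contig[ci]
        for gi in range(k):
            first, last = gi == 0, gi == k - 1
            is_edge_lead = first and lead_edge[ci]
            gap = (
                spec.edge_margin
                if is_edge_lead
                else int(rng.integers(*spec.intergenic_range))
            )
            pieces.append(_random_dna(rng, gap, spec.gc_content))
            pos += gap
            orf_len = int(rng.integers(*spec.orf_length_range)) // 3 * 3
            orf = "ATG" + _random_dna(rng, orf_len - 6, spec.gc_content) + "TAA"
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                orf = revcomp(orf)
            start, end = pos, pos + orf_len
            pieces.append(orf)
            pos = end

            dom_s = dom_e = None
            if orf_len >= spec.domain_min_orf:
                dom_len = (orf_len // 2) // 3 * 3
                max_off = (orf_len - dom_len) // 3
                dom_s = start + 3 * int(rng.integers(1, max(2, max_off)))
                dom_e = dom_s + dom_len

            is_edge_tail = last and tail_edge[ci]
            if is_edge_lead:
                outcome = "fail_contig_end"
            elif is_edge_tail:
                outcome = "fail_contig_end"
            else:
                outcome = "ok_window30"

            gene_id = f"g{gene_no + 1:04d}"
            genes.append(
                GeneModel(
                    gene_id=gene_id,
                    contig=name,
                    orf_start=start,
                    orf_end=end,
                    strand=strand,
                    kinase_domain_start=dom_s,
                    kinase_domain_end=dom_e,
                )
            )
            truth.append(
                TruthRecord(
                    gene_id=gene_id,
                    contig=name,
                    start=start,
                    end=end,
                    strand=strand,
                    essential=gene_no in essential_idx,
                    expected_outcome=outcome,
                    domain_start=dom_s,
                    domain_end=dom_e,
                )
            )
            gene_no += 1

            if last:
                trailing = (
                    spec.edge_margin
                    if is_edge_tail
                    else int(rng.integers(*spec.intergenic_range))
                )
                pieces.append(_random_dna(rng, trailing, spec.gc_content))
                pos += trailing
        contigs[name] = Contig(name, "".join(pieces))
    return contigs, genes, truth


def _kmers(seq: str, k: int) -> set[str]:
    both = seq + " " + revcomp(seq)
    out = set()
    for part in both.split(" "):
        for i in range(len(part) - k + 1):
            out.add(part[i : i + k])
    return out


def generate_marker_and_vector(
    spec: SyntheticSpec, max_retries: int = 50
) -> tuple[MarkerCassette, VectorBackbone]:
    """Random marker cassette and gapped circular vector.

    The marker's terminal tail regions and the vector's exposed ends must
    not share any 12-mer (on either strand) so assembly junctions are
    unambiguous; the vector is re-drawn until the constraint holds.
    """
    if spec.marker_length < 2 * spec.tail_length:
        raise ValueError("marker_length must be at least twice tail_length")
    rng = np.random.default_rng([spec.seed, 7])
    marker_seq = _random_dna(rng, spec.marker_length, spec.gc_content)
    marker = MarkerCassette("synthetic_marker", marker_seq, tail_len=spec.tail_length)
    t = spec.tail_length
    marker_kmers = _kmers(marker_seq[:t], 12) | _kmers(marker_seq[-t:], 12)

    gap = (100, 100 + max(2 * t, 200))
    for _ in range(max_retries):
        vec_seq = _random_dna(rng, spec.vector_length, spec.gc_content)
        vector = VectorBackbone("synthetic_vector", vec_seq, gap)
        vec_kmers = _kmers(vector.upstream_end(t), 12) | _kmers(
            vector.downstream_start(t), 12
        )
        if not (marker_kmers & vec_kmers):
            return marker, vector
    raise ValueError("could not satisfy the marker/vector 12-mer disjointness")


def generate_observations(
    truth: list[TruthRecord],
    n_transformants: int = 6,
    targeting_rate: float = 0.7,
    seed: int = 0,
    ensure_informative: bool = False,
    max_redraws: int = 1000,
) -> list[TransformantObservation]:
    """Simulate the transformant assay for every gene in the truth table.

    Targeted integrations of essential genes produce heterokaryon patterns,
    of non-essential genes haploid-null patterns; untargeted events look
    ectopic.  With ``ensure_informative`` each gene's set is re-drawn
    (bounded) until it contains at least one targeted event.
    """
    if not 0.0 <= targeting_rate <= 1.0:
        raise ValueError("targeting_rate must lie in [0, 1]")
    out: list[TransformantObservation] = []
    for gi, rec in enumerate(truth):
        rng = np.random.default_rng([seed, gi])
        for _ in range(max_redraws):
            targeted = rng.random(n_transformants) < targeting_rate
            if not ensure_informative or targeting_rate == 0 or targeted.any():
                break
        for ti in range(n_transformants):
            if targeted[ti] and rec.essential:
                obs = TransformantObservation(
                    transformant_id=f"{rec.gene_id}_t{ti + 1}",
                    gene_id=rec.gene_id,
                    grows_selective=False,
                    grows_nonselective=True,
                    alleles_detected=frozenset({"wt", "null"}),
                    streak_stable_haploid=False,
                )
            elif targeted[ti]:
                obs = TransformantObservation(
                    transformant_id=f"{rec.gene_id}_t{ti + 1}",
                    gene_id=rec.gene_id,
                    grows_selective=True,
                    grows_nonselective=True,
                    alleles_detected=frozenset({"null"}),
                    streak_stable_haploid=True,
                )
            else:
                obs = TransformantObservation(
                    transformant_id=f"{rec.gene_id}_t{ti + 1}",
                    gene_id=rec.gene_id,
                    grows_selective=True,
                    grows_nonselective=True,
                    alleles_detected=frozenset({"wt"}),
                    streak_stable_haploid=True,
                )
            out.append(obs)
    return out


def write_gff3(
    genes: list[GeneModel], contigs: Mapping[str, Contig], path: str | Path
) -> None:
    """Emit gene models as GFF3 (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for c in contigs.values():
            fh.write(f"##sequence-region {c.name} 1 {c.length}\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            if g.has_domain:
                attrs += (
                    f";domain_start={g.kinase_domain_start + 1}"
                    f";domain_end={g.kinase_domain_end}"
                )
            fh.write(
                f"{g.contig}\tdelkit\tgene\t{g.orf_start + 1}\t{g.orf_end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )


def write_truth_table(truth: list[TruthRecord], path: str | Path) -> None:
    cols = [
        "gene_id", "contig", "start", "end", "strand",
        "essential", "expected_outcome", "domain_start", "domain_end",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for t in truth:
            fh.write(
                "\t".join(
                    str(v if v is not None else "")
                    for v in (
                        t.gene_id, t.contig, t.start, t.end, t.strand,
                        int(t.essential), t.expected_outcome,
                        t.domain_start, t.domain_end,
                    )
                )
                + "\n"
            )
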