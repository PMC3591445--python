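"""Heterokaryon-rescue classification of transformants and genes.

A deletion of an essential gene survives only as a heterokaryon: conidia
carrying the null allele cannot form colonies on selective medium, yet the
primary transformant shows both alleles by diagnostic PCR.  A non-essential
deletion yields streak-stable haploid nulls carrying only the null allele.
Diploids mimic heterokaryons by PCR but are streak-stable on selective
medium; they are discarded as evidence.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

CLASSIFICATIONS = (
    "haploid_null",
    "heterokaryon",
    "diploid",
    "ectopic_integrant",
    "inconclusive",
)

ESSENTIALITY = ("essential", "non_essential", "undetermined")


@dataclass(frozen=True)
class TransformantObservation:
    """Plate-growth and allele observations for one primary transformant."""

    transformant_id: str
    gene_id: str
    grows_selective: bool
    grows_nonselective: bool
    alleles_detected: frozenset[str]
    streak_stable_haploid: bool

    def __post_init__(self):
        object.__setattr__(self, "alleles_detected", frozenset(self.alleles_detected))
        if self.alleles_detected - {"wt", "null"}:
            raise ValueError(
                f"{self.transformant_id}: alleles must be a subset of {{wt, null}}"
            )
        if self.streak_stable_haploid and not self.grows_selective:
            raise ValueError(
                f"{self.transformant_id}: streak-stable without selective growth"
            )
        if (self.grows_selective or self.grows_nonselective) and not self.alleles_detected:
            raise ValueError(
                f"{self.transformant_id}: growth observed but no alleles detected"
            )


@dataclass(frozen=True)
class GeneCall:
    """Aggregated essentiality call for one gene."""

    gene_id: str
    essentiality: str
    evidence: tuple[str, ...]

    def __post_init__(self):
        if self.essentiality not in ESSENTIALITY:
            raise ValueError(f"bad essentiality {self.essentiality!r}")
        n_null = self.evidence.count("haploid_null")
        n_het = self.evidence.count("heterokaryon")
        if self.essentiality == "essential" and (n_het < 1 or n_null > 0):
            raise ValueError(
                f"{self.gene_id}: essential requires >=1 heterokaryon and "
                "0 stable haploid nulls"
            )
        if self.essentiality == "non_essential" and n_null < 1:
            raise ValueError(
                f"{self.gene_id}: non_essential requires >=1 confirmed haploid null"
            )


def classify_transformant(obs: TransformantObservation) -> str:
    """Classify one transformant from growth pattern + allele calls.

    Decision table:

    ========================  ==============  ==============  =================
    growth                    alleles         streak-stable   class
    ========================  ==============  ==============  =================
    selective + nonselective  {null}          yes             haploid_null
    nonselective only         {wt, null}      (no)            heterokaryon
    selective (stable)        {wt, null}      yes             diploid
    selective (stable)        {wt}            yes             ectopic_integrant
    anything else                                             inconclusive
    ========================  ==============  ==============  =================
    """
    alleles = obs.alleles_detected
    if (
        obs.grows_selective
        and obs.grows_nonselective
        and alleles == {"null"}
        and obs.streak_stable_haploid
    ):
        return "haploid_null"
    if not obs.grows_selective and obs.grows_nonselective and alleles == {"wt", "null"}:
        return "heterokaryon"
    if obs.streak_stable_haploid and obs.grows_selective and alleles == {"wt", "null"}:
        return "diploid"
    if obs.streak_stable_haploid and alleles == {"wt"}:
        return "ectopic_integrant"
    return "inconclusive"


def call_gene(
    observations: Sequence[TransformantObservation],
    min_transformants: int = 6,
) -> GeneCall:
    """Aggregate transformant classifications into one essentiality call.

    Any single verified haploid null forces ``non_essential``; otherwise at
    least one heterokaryon (with no haploid nulls) supports ``essential``.
    Diploids are excluded from the evidence.  Ectopic integrants and
    inconclusive transformants are neutral.
    """
    if not observations:
        raise ValueError("no observations supplied")
    gene_ids = {o.gene_id for o in observations}
    if len(gene_ids) != 1:
        raise ValueError(f"observations span multiple genes: {sorted(gene_ids)}")
    if len(observations) < min_transformants:
        raise ValueError(
            f"{observations[0].gene_id}: {len(observations)} observations "
            f"< required {min_transformants}"
        )
    classes = [classify_transformant(o) for o in observations]
    evidence = tuple(c for c in classes if c != "diploid")
    if "haploid_null" in evidence:
        ess = "non_essential"
    elif "heterokaryon" in evidence:
        ess = "essential"
    else:
        ess = "undetermined"
    return GeneCall(gene_id=gene_ids.pop(), essentiality=ess, evidence=evidence)


def read_observations(path: str | Path) -> list[TransformantObservation]:
    """Read transformant observations from TSV (one row per transformant)."""
    out = []
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            alleles = frozenset(
                a for a in row["alleles_detected"].split(",") if a
            )
            out.append(
                TransformantObservation(
                    transformant_id=row["transformant_id"],
                    gene_id=row["gene_id"],
                    grows_selective=row["grows_selective"] in ("1", "true", "True"),
                    grows_nonselective=row["grows_nonselective"]
                    in ("1", "true", "True"),
                    alleles_detected=alleles,
                    streak_stable_haploid=row["streak_stable_haploid"]
                    in ("1", "true", "True"),
                )
            )
    return out


def write_observations(
    observations: Iterable[TransformantObservation], path: str | Path
) -> None:
    cols = [
        "transformant_id",
        "gene_id",
        "grows_selective",
        "grows_nonselective",
        "alleles_detected",
        "streak_stable_haploid",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for o in observations:
            fh.write(
                "\t".join(
                    [
                        o.transformant_id,
                        o.gene_id,
                        str(int(o.grows_selective)),
                        str(int(o.grows_nonselective)),
                        ",".join(sorted(o.alleles_detected)),
                        str(int(o.streak_stable_haploid)),
                    ]
                )
                + "\n"
            )


def write_gene_calls(calls: Iterable[GeneCall], tsv_path=None, json_path=None) -> None:
    calls = list(calls)
    if tsv_path:
        with open(tsv_path, "w") as fh:
            fh.write("gene_id\tessentiality\tevidence\n")
            for c in calls:
                fh.write(f"{c.gene_id}\t{c.essentiality}\t{','.join(c.evidence)}\n")
    if json_path:
        with open(json_path, "w") as fh:
            json.dump(
                [
                    {
                        "gene_id": c.gene_id,
                        "essentiality": c.essentiality,
                        "evidence": list(c.evidence),
                    }
                    for c in calls
                ],
                fh,
                indent=2,
            )
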