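"""Packaged kinome deletion/phenotype dataset and its summary statistics.

The fixture ``data/kinome_table.tsv`` is a transcription of a published
131-kinase deletion survey: systematic id, kinase name, group/family path,
deletion outcome and a controlled-vocabulary phenotype list.  Free-text
phenotype notes were normalized to the tag vocabulary below at transcription
time; ``heterokaryons_recovered`` is a tag, not a status.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

DELETION_STATUSES = (
    "viable",
    "lethal",
    "viable_kinase_domain",
    "lethal_kinase_domain",
    "not_determined",
)

LETHAL_STATUSES = frozenset({"lethal", "lethal_kinase_domain"})
VIABLE_STATUSES = frozenset({"viable", "viable_kinase_domain"})

PHENOTYPE_VOCAB = frozenset(
    {
        "microcolony",
        "brown_pigment",
        "yellow_pigment",
        "polarity_defect",
        "NaCl_sensitive",
        "NaCl_remediated",
        "sucrose_sensitive",
        "sucrose_remediated",
        "strong_growth_defect",
        "moderate_growth_defect",
        "septation_conidiation_defect",
        "conidiation_defect",
        "increased_pigment",
        "HU_sensitive",
        "DEO_sensitive",
        "camptothecin_sensitive",
        "benomyl_sensitive",
        "early_sexual_development",
        "arrested_sexual_development",
        "incomplete_sexual_development",
        "cell_cycle",
        "swollen",
        "enlarged_vacuoles",
        "short_germling_arrest",
        "branched_germling_arrest",
        "colony_color",
        "heterokaryons_recovered",
        "variable_phenotype",
        "early_septation",
        "nulls_not_generated",
    }
)

TOP_GROUPS = ("AGC", "CAMK", "CK1", "CMGC", "STE", "Other", "Unclassified", "Atypical")


class KinomeFormatError(ValueError):
    """Malformed kinome table row."""


@dataclass(frozen=True)
class KinaseRecord:
    systematic_id: str
    name: str
    group_path: str
    deletion_status: str
    phenotype_annotations: tuple[str, ...]
    is_ffk: bool

    @property
    def group(self) -> str:
        return self.group_path.split("/")[0]


@dataclass(frozen=True)
class KinomeSummary:
    n_total: int
    n_deleted: int
    n_essential: int
    pct_essential: float
    n_nonessential: int
    n_nonessential_with_phenotype: int
    n_terminal_phenotype_defined: int
    group_counts: dict[str, int]

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)

    def pretty(self) -> str:
        lines = [
            f"kinases:                      {self.n_total}",
            f"deletion strains generated:   {self.n_deleted}",
            f"essential:                    {self.n_essential} ({self.pct_essential}%)",
            f"non-essential:                {self.n_nonessential}",
            f"  with >=1 phenotype:         {self.n_nonessential_with_phenotype}",
            f"terminal phenotype defined:   {self.n_terminal_phenotype_defined}",
            "groups:",
        ]
        for g, c in self.group_counts.items():
            lines.append(f"  {g:<22} {c}")
        return "\n".join(lines)


def packaged_kinome_table() -> Path:
    """Path to the packaged kinome fixture TSV."""
    return Path(str(resources.files("delkit").joinpath("data/kinome_table.tsv")))


def load_kinome_table(path: str | Path | None = None) -> list[KinaseRecord]:
    """Load a kinome table TSV, validating controlled vocabularies.

    With no argument, loads the packaged 131-record fixture.
    """
    path = Path(path) if path is not None else packaged_kinome_table()
    records = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"systematic_id", "name", "group_path", "deletion_status",
                    "phenotypes", "is_ffk"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise KinomeFormatError(f"{path}: missing required columns")
        seen = set()
        for i, row in enumerate(reader, start=2):
            sid = row["systematic_id"]
            if sid in seen:
                raise KinomeFormatError(f"row {i}: duplicate systematic_id {sid}")
            seen.add(sid)
            status = row["deletion_status"]
            if status not in DELETION_STATUSES:
                raise KinomeFormatError(
                    f"row {i}: unknown deletion_status {status!r}"
                )
            group = row["group_path"].split("/")[0]
            if group not in TOP_GROUPS:
                raise KinomeFormatError(
                    f"row {i}: malformed group_path {row['group_path']!r}"
                )
            tags = tuple(t for t in row["phenotypes"].split(",") if t)
            unknown = set(tags) - PHENOTYPE_VOCAB
            if unknown:
                raise KinomeFormatError(
                    f"row {i}: unknown phenotype tags {sorted(unknown)}"
                )
            if "nulls_not_generated" in tags and status not in LETHAL_STATUSES:
                raise KinomeFormatError(
                    f"row {i}: nulls_not_generated on non-lethal record"
                )
            records.append(
                KinaseRecord(
                    systematic_id=sid,
                    name=row["name"],
                    group_path=row["group_path"],
                    deletion_status=status,
                    phenotype_annotations=tags,
                    is_ffk=row["is_ffk"] in ("1", "true", "True"),
                )
            )
    if not records:
        raise KinomeFormatError(f"{path}: table contains no records")
    return records


def summarize(records: list[KinaseRecord]) -> KinomeSummary:
    """Headline counts over a kinase record list.

    ``n_deleted`` excludes not-determined records; essential means a lethal
    deletion outcome (whole-ORF or kinase-domain-only); the terminal
    phenotype of an essential kinase counts as defined unless nulls were
    never recovered from heterokaryons.
    """
    if not records:
        raise ValueError("no records to summarize")
    n_total = len(records)
    essential = [r for r in records if r.deletion_status in LETHAL_STATUSES]
    nonessential = [r for r in records if r.deletion_status in VIABLE_STATUSES]
    n_deleted = len(essential) + len(nonessential)
    n_essential = len(essential)
    pct = round(100.0 * n_essential / n_deleted, 1) if n_deleted else 0.0
    n_ne_pheno = sum(1 for r in nonessential if r.phenotype_annotations)
    n_terminal = sum(
        1 for r in essential if "nulls_not_generated" not in r.phenotype_annotations
    )
    group_counts: dict[str, int] = {g: 0 for g in TOP_GROUPS}
    for r in records:
        group_counts[r.group] = group_counts.get(r.group, 0) + 1
    group_counts["Atypical/HisK"] = sum(
        1 for r in records if r.group_path == "Atypical/HisK"
    )
    group_counts["CMGC/SRPK"] = sum(
        1 for r in records if r.group_path.startswith("CMGC/SRPK")
    )
    group_counts["Ffk"] = sum(1 for r in records if r.is_ffk)
    return KinomeSummary(
        n_total=n_total,
        n_deleted=n_deleted,
        n_essential=n_essential,
        pct_essential=pct,
        n_nonessential=len(nonessential),
        n_nonessential_with_phenotype=n_ne_pheno,
        n_terminal_phenotype_defined=n_terminal,
        group_counts=group_counts,
    )
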