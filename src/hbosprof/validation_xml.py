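"""wwPDB validation-report XML parsing and HBOS cross-tabulation.

Validation reports list, per modeled residue, the deposition-pipeline
criteria with outliers (Ramachandran, rotamer, omega, clashes, bond
lengths/angles, chirality, planarity).  A residue's color code depends only
on the number of distinct criteria with outliers: 0 green, 1 yellow,
2 orange, >= 3 red; any number of atomic clashes counts as one criterion.

The cross-tab of interest: HBOS outliers that the validation report still
marks green, per 1000 residues of the same type — conformations the
histogram score flags although the deposition pipeline found nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd
from lxml import etree

from .hbos_model import ScoreResult

#: Child-element tags mapped to criterion names.  Any number of clash
#: elements collapses to the single "clashes" criterion.
_TAG_CRITERIA = {
    "clash": "clashes",
    "symm-clash": "clashes",
    "bond-outlier": "bond_length",
    "angle-outlier": "bond_angle",
    "mog-bond-outlier": "bond_length",
    "mog-angle-outlier": "bond_angle",
    "chiral-outlier": "chirality",
    "plane-outlier": "planarity",
    "omega-outlier": "omega",
}

COLORS = ("green", "yellow", "orange", "red")


class ValidationParseError(ValueError):
    pass


@dataclass(frozen=True)
class ValidationRecord:
    chain_id: str
    seq_id: int
    icode: str
    res_type: str
    criteria: frozenset[str] = field(default_factory=frozenset)

    @property
    def criterion_count(self) -> int:
        return len(self.criteria)

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_id, self.icode)


def color_code(record: ValidationRecord) -> str:
    """green / yellow / orange / red from the distinct-criterion count."""
    count = record.criterion_count
    if count >= 3:
        return "red"
    return COLORS[count]


def parse_validation_xml(path) -> list[ValidationRecord]:
    """One ValidationRecord per ModelledSubgroup element of the report.

    Criteria come from the rama/rota attributes (value "OUTLIER") and from
    annotation child elements; unknown child tags are preserved verbatim as
    "other:<tag>" criteria.
    """
    try:
        tree = etree.parse(str(path))
    except (etree.XMLSyntaxError, OSError) as exc:
        raise ValidationParseError(f"cannot parse validation XML {path}: {exc}") from exc
    records: list[ValidationRecord] = []
    for el in tree.iter("ModelledSubgroup"):
        criteria: set[str] = set()
        if el.get("rama", "").upper() == "OUTLIER":
            criteria.add("ramachandran")
        if el.get("rota", "").upper() == "OUTLIER":
            criteria.add("rotamer")
        for child in el:
            tag = str(child.tag)
            criteria.add(_TAG_CRITERIA.get(tag, f"other:{tag}"))
        try:
            seq_id = int(el.get("resnum"))
        except (TypeError, ValueError):
            raise ValidationParseError(
                f"{path}: ModelledSubgroup without a numeric resnum"
            )
        records.append(
            ValidationRecord(
                chain_id=el.get("chain", ""),
                seq_id=seq_id,
                icode=(el.get("icode") or "").strip(),
                res_type=(el.get("resname") or "").upper(),
                criteria=frozenset(criteria),
            )
        )
    return records


@dataclass
class GreenRateResult:
    table: pd.DataFrame
    n_scored: int
    n_unmatched: int  # scored residues absent from the validation report


def green_outlier_rate(
    scores: Iterable[ScoreResult],
    validation: Iterable[ValidationRecord],
) -> GreenRateResult:
    """Per-type rate of HBOS outliers that the validation report marks green.

    Rate = 1000 * |HBOS outliers that are green| / |scored residues of the
    type present in the report|.  Scored residues missing from the report
    are excluded and tallied in the coverage count.
    """
    by_key = {rec.residue_key: rec for rec in validation}
    counts: dict[str, list[int]] = {}
    n_scored = 0
    n_unmatched = 0
    n_joined = 0
    for res in scores:
        if res.unscored:
            continue
        n_scored += 1
        vrec = by_key.get(res.record.residue_key)
        if vrec is None:
            n_unmatched += 1
            continue
        n_joined += 1
        entry = counts.setdefault(res.res_type, [0, 0, 0])
        entry[0] += 1
        if res.outlier:
            entry[1] += 1
            if color_code(vrec) == "green":
                entry[2] += 1
    if n_scored and n_joined == 0:
        raise ValueError(
            "no scored residue matched the validation report; "
            "check chain/residue numbering conventions"
        )
    rows = [
        {
            "res_type": rt,
            "n_residues": n,
            "n_hbos_outliers": k,
            "n_green_hbos_outliers": g,
            "outlier_rate_per_1000": 1000.0 * k / n,
            "green_rate_per_1000": 1000.0 * g / n,
        }
        for rt, (n, k, g) in sorted(counts.items())
    ]
    return GreenRateResult(
        table=pd.DataFrame(rows), n_scored=n_scored, n_unmatched=n_unmatched
    )


def write_green_rate_tsv(result: GreenRateResult, path) -> None:
    result.table.to_csv(path, sep="\t", index=False)
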