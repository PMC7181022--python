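"""The five per-residue geometric features.

For every residue that carries a chi1 torsion (all standard types except GLY
and ALA) five quantities are measured:

* ``phi``  — backbone torsion C(i-1)–N–CA–C, degrees in [0, 360)
* ``psi``  — backbone torsion N–CA–C–N(i+1), degrees in [0, 360)
* ``chi1`` — first sidechain torsion N–CA–CB–X, degrees in [0, 360)
* ``d_sidechain`` — distance (Å) from CA to the mass-weighted centroid of the
  heavy sidechain atoms
* ``d_block`` — distance (Å) from CA to the mass-weighted centroid of the
  residue's distal block (for LEU the CG–CD1–CD2 triangle)

Torsions use the 0°–360° convention throughout rather than the ±180°
Ramachandran convention, so that histogram bins never straddle a sign flip.
Features that cannot be measured (chain termini, missing atoms) are flagged
unavailable rather than raising.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .constants import (
    BACKBONE_ATOMS,
    CHI1_FOURTH_ATOM,
    NO_CHI1,
    element_mass,
)
from .structure_io import Chain, Residue, StructureModel

FEATURE_NAMES: tuple[str, ...] = ("phi", "psi", "chi1", "d_sidechain", "d_block")
ANGLE_FEATURES: frozenset[str] = frozenset({"phi", "psi", "chi1"})

#: C(i)-N(i+1) separation beyond which consecutive residues are a chain break.
CHAIN_BREAK_CN = 2.5


class GeometryError(ValueError):
    """Raised for degenerate atom configurations (collinear torsion atoms)."""


@dataclass(frozen=True)
class FeatureRecord:
    """Identity of one residue plus its five feature values.

    ``None`` marks an unavailable feature; a record with any unavailable
    feature is never fitted or scored.
    """

    entry_id: str
    chain_id: str
    seq_id: int
    icode: str
    res_type: str
    phi: float | None = None
    psi: float | None = None
    chi1: float | None = None
    d_sidechain: float | None = None
    d_block: float | None = None

    def values(self) -> tuple[float | None, ...]:
        return (self.phi, self.psi, self.chi1, self.d_sidechain, self.d_block)

    @property
    def complete(self) -> bool:
        return all(v is not None for v in self.values())

    @property
    def missing(self) -> tuple[str, ...]:
        return tuple(n for n, v in zip(FEATURE_NAMES, self.values()) if v is None)

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_id, self.icode)


def _wrap_360(deg: float) -> float:
    deg = deg % 360.0
    return 0.0 if deg == 360.0 else deg


def dihedral_angle(p1, p2, p3, p4) -> float:
    """Torsion angle of four points, degrees in [0, 360).

    The IUPAC signed dihedral is computed and negative values are mapped up
    by 360.  Collinear bond vectors make the torsion undefined and raise
    :class:`GeometryError`.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    norm_b2 = np.linalg.norm(b2)
    if norm_b2 < 1e-12:
        raise GeometryError("central atoms coincide")
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        raise GeometryError("collinear atom triple: torsion undefined")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2) / norm_b2)
    return _wrap_360(math.degrees(math.atan2(y, x)))


def _is_chain_break(prev: Residue, curr: Residue) -> bool:
    c = prev.pos("C")
    n = curr.pos("N")
    if c is None or n is None:
        return True
    return float(np.linalg.norm(c - n)) > CHAIN_BREAK_CN


def backbone_torsions(chain: Chain) -> list[tuple[float | None, float | None]]:
    """Per-residue (phi, psi); None where undefined.

    phi needs the previous residue's C, psi the next residue's N; both are
    unavailable at chain termini, across chain breaks (C–N > 2.5 Å) and where
    backbone atoms are missing.
    """
    out: list[tuple[float | None, float | None]] = []
    residues = chain.residues
    for i, res in enumerate(residues):
        phi = psi = None
        n, ca, c = res.pos("N"), res.pos("CA"), res.pos("C")
        if not any(p is None for p in (n, ca, c)):
            if i > 0 and not _is_chain_break(residues[i - 1], res):
                c_prev = residues[i - 1].pos("C")
                try:
                    phi = dihedral_angle(c_prev, n, ca, c)
                except GeometryError:
                    phi = None
            if i + 1 < len(residues) and not _is_chain_break(res, residues[i + 1]):
                n_next = residues[i + 1].pos("N")
                try:
                    psi = dihedral_angle(n, ca, c, n_next)
                except GeometryError:
                    psi = None
        out.append((phi, psi))
    return out


def chi1(residue: Residue) -> float | None:
    """First sidechain torsion N–CA–CB–X; None when an atom is missing.

    X is CG for most types, CG1 for ILE/VAL, OG for SER, OG1 for THR, SG for
    CYS.  GLY and ALA have no chi1 and are a caller error.
    """
    if residue.res_type in NO_CHI1:
        raise ValueError(f"{residue.res_type} has no chi1 torsion")
    fourth = CHI1_FOURTH_ATOM.get(residue.res_type)
    if fourth is None:
        return None
    points = [residue.pos(a) for a in ("N", "CA", "CB", fourth)]
    if any(p is None for p in points):
        return None
    try:
        return dihedral_angle(*points)
    except GeometryError:
        return None


def _mass_centroid(residue: Residue, atom_names: Iterable[str]) -> np.ndarray | None:
    total = 0.0
    acc = np.zeros(3)
    for name in atom_names:
        atom = residue.atoms.get(name)
        if atom is None:
            continue
        mass = element_mass(atom.element)
        if mass is None or atom.element.upper() in ("H", "D"):
            continue
        acc += mass * atom.pos
        total += mass
    if total == 0.0:
        return None
    return acc / total


def sidechain_atoms(residue: Residue) -> list[str]:
    return [
        name
        for name, atom in residue.atoms.items()
        if name not in BACKBONE_ATOMS and atom.element.upper() not in ("H", "D")
    ]


def sidechain_distance(residue: Residue) -> float | None:
    """CA to mass centroid of all heavy sidechain atoms (CB outward), Å."""
    ca = residue.pos("CA")
    if ca is None:
        return None
    centroid = _mass_centroid(residue, sidechain_atoms(residue))
    if centroid is None:
        return None
    return float(np.linalg.norm(ca - centroid))


class BlockTable(dict):
    """Map residue type -> distal-block atom-name set."""

    @classmethod
    def from_text(cls, text: str) -> "BlockTable":
        table = cls()
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            table[parts[0].upper()] = frozenset(parts[1:])
        return table

    @classmethod
    def from_file(cls, path) -> "BlockTable":
        return cls.from_text(Path(path).read_text())

    @classmethod
    def default(cls) -> "BlockTable":
        text = resources.files("hbosprof").joinpath("data/blocks.txt").read_text()
        return cls.from_text(text)


def block_distance(residue: Residue, blocks: Mapping[str, frozenset] | None = None) -> float | None:
    """CA to mass centroid of the residue's distal block, Å."""
    if blocks is None:
        blocks = BlockTable.default()
    ca = residue.pos("CA")
    names = blocks.get(residue.res_type)
    if ca is None or not names:
        return None
    centroid = _mass_centroid(residue, names)
    if centroid is None:
        return None
    return float(np.linalg.norm(ca - centroid))


def compute_features(
    chain: Chain,
    entry_id: str = "",
    blocks: Mapping[str, frozenset] | None = None,
) -> list[FeatureRecord]:
    """One FeatureRecord per non-GLY/ALA residue of the chain."""
    if blocks is None:
        blocks = BlockTable.default()
    torsions = backbone_torsions(chain)
    records = []
    for res, (phi, psi) in zip(chain.residues, torsions):
        if res.res_type in NO_CHI1:
            continue
        records.append(
            FeatureRecord(
                entry_id=entry_id,
                chain_id=chain.chain_id,
                seq_id=res.seq_id,
                icode=res.icode,
                res_type=res.res_type,
                phi=phi,
                psi=psi,
                chi1=chi1(res),
                d_sidechain=sidechain_distance(res),
                d_block=block_distance(res, blocks),
            )
        )
    return records


def compute_features_model(
    model: StructureModel,
    blocks: Mapping[str, frozenset] | None = None,
    deduplicate: bool = False,
    identity_threshold: float = 0.95,
) -> list[FeatureRecord]:
    """Feature records for every chain of a structure."""
    from .structure_io import dedup_chains

    chains = (
        dedup_chains(model, identity_threshold) if deduplicate else model.chains
    )
    records: list[FeatureRecord] = []
    for chain in chains:
        records.extend(compute_features(chain, model.entry_id, blocks))
    return records


_TSV_COLUMNS = (
    "entry", "chain", "seq_id", "icode", "res_type",
    "phi", "psi", "chi1", "d_sidechain", "d_block", "flags",
)


def write_feature_tsv(records: Iterable[FeatureRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_TSV_COLUMNS)
        for r in records:
            flags = ",".join(f"missing:{m}" for m in r.missing) or "ok"
            row = [r.entry_id, r.chain_id, r.seq_id, r.icode, r.res_type]
            row += [("NA" if v is None else repr(float(v))) for v in r.values()]
            row.append(flags)
            writer.writerow(row)


def read_feature_tsv(path) -> list[FeatureRecord]:
    records = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            def num(col):
                v = row[col]
                return None if v == "NA" else float(v)

            records.append(
                FeatureRecord(
                    entry_id=row["entry"],
                    chain_id=row["chain"],
                    seq_id=int(row["seq_id"]),
                    icode=row["icode"],
                    res_type=row["res_type"],
                    phi=num("phi"),
                    psi=num("psi"),
                    chi1=num("chi1"),
                    d_sidechain=num("d_sidechain"),
                    d_block=num("d_block"),
                )
            )
    return records


def displace(record: FeatureRecord, **updates) -> FeatureRecord:
    """Copy of *record* with some feature values replaced."""
    return replace(record, **updates)
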