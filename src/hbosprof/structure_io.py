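"""Reading protein structures and entry-level filtering.

PDB and mmCIF files are parsed with gemmi into a minimal in-memory model
(:class:`StructureModel` / :class:`Chain` / :class:`Residue`) that keeps only
polymer amino-acid residues and their heavy atoms.  Alternate locations are
resolved to the highest-occupancy conformer (altloc "A" wins ties).  Entries
can then be filtered by the resolution recorded in the file metadata, and
near-identical chains within an entry (non-crystallographic symmetry copies)
deduplicated by global sequence identity.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import gemmi
from Bio import Align

from .constants import NONSTANDARD_PARENT, STANDARD_AA, THREE_TO_ONE


class StructureParseError(ValueError):
    """Raised when a structure file cannot be parsed."""


class FormatError(ValueError):
    """Raised when the file format cannot be determined."""


class Atom(NamedTuple):
    x: float
    y: float
    z: float
    occupancy: float
    element: str
    altloc: str

    @property
    def pos(self):
        import numpy as np

        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass
class Residue:
    """One amino-acid residue: identity plus heavy-atom coordinates.

    ``atoms`` maps atom name to a single :class:`Atom`; alternate conformers
    have already been resolved at parse time.
    """

    res_type: str
    seq_id: int
    icode: str = ""
    atoms: dict[str, Atom] = field(default_factory=dict)

    @property
    def label(self) -> str:
        return f"{self.res_type}{self.seq_id}{self.icode}"

    def pos(self, name: str):
        atom = self.atoms.get(name)
        return None if atom is None else atom.pos


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def sequence(self) -> str:
        """One-letter sequence; unknown types become 'X'."""
        return "".join(THREE_TO_ONE.get(r.res_type, "X") for r in self.residues)


@dataclass
class StructureModel:
    entry_id: str
    chains: list[Chain] = field(default_factory=list)
    resolution: float | None = None
    experiment_method: str = ""

    def get_chain(self, chain_id: str) -> Chain:
        for chain in self.chains:
            if chain.chain_id == chain_id:
                return chain
        raise KeyError(chain_id)


_PDB_EXT = {".pdb", ".ent"}
_CIF_EXT = {".cif", ".mmcif"}


def _detect_format(path: Path, fmt: str) -> str:
    if fmt in ("pdb", "mmcif"):
        return fmt
    if fmt != "auto":
        raise FormatError(f"unknown format {fmt!r}; expected pdb, mmcif or auto")
    suffixes = [s.lower() for s in path.suffixes]
    ext = suffixes[-1] if suffixes else ""
    if ext == ".gz" and len(suffixes) > 1:
        ext = suffixes[-2]
    if ext in _PDB_EXT:
        return "pdb"
    if ext in _CIF_EXT:
        return "mmcif"
    raise FormatError(f"cannot infer format from extension of {path.name!r}")


def _pick_conformer(candidates: list[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy wins; altloc "A" (or blank) wins ties
    def key(a: gemmi.Atom):
        alt = a.altloc if a.altloc else "A"
        return (-a.occ, alt)

    return sorted(candidates, key=key)[0]


def read_structure(path, format: str = "auto") -> StructureModel:
    """Parse a PDB or mmCIF file into a :class:`StructureModel`.

    Only polymer amino-acid residues are kept; waters and ligands are
    dropped.  Non-standard residues with a known parent (e.g. MSE) are mapped
    to the parent type; other unknown residues are skipped with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _detect_format(path, format)
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        else:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"cannot parse {path.name}: {exc}") from exc

    st.setup_entities()
    if len(st) == 0:
        raise StructureParseError(f"{path.name}: no coordinate model found")

    entry_id = (st.name or path.stem).strip().upper() or path.stem.upper()
    resolution = float(st.resolution) if st.resolution and st.resolution > 0 else None
    method = st.info["_exptl.method"] if "_exptl.method" in st.info else ""

    model = StructureModel(
        entry_id=entry_id, resolution=resolution, experiment_method=method
    )
    first = st[0]
    for gchain in first:
        chain = Chain(chain_id=gchain.name)
        for gres in gchain:
            info = gemmi.find_tabulated_residue(gres.name)
            name = gres.name.upper()
            if name in STANDARD_AA:
                res_type = name
            elif name in NONSTANDARD_PARENT:
                res_type = NONSTANDARD_PARENT[name]
            elif info is not None and info.is_amino_acid():
                warnings.warn(
                    f"{entry_id} {gchain.name}/{name}{gres.seqid.num}: "
                    "no standard mapping, residue skipped"
                )
                continue
            else:
                continue  # water, ligand, nucleotide ...
            residue = Residue(
                res_type=res_type,
                seq_id=gres.seqid.num,
                icode=(gres.seqid.icode or "").strip(),
            )
            by_name: dict[str, list[gemmi.Atom]] = {}
            for atom in gres:
                if atom.element.is_hydrogen:
                    continue
                by_name.setdefault(atom.name, []).append(atom)
            for aname, cands in by_name.items():
                a = _pick_conformer(cands)
                if not all(map(math.isfinite, (a.pos.x, a.pos.y, a.pos.z))):
                    raise StructureParseError(
                        f"{path.name}: non-finite coordinate on atom {aname} "
                        f"of {residue.label}"
                    )
                residue.atoms[aname] = Atom(
                    a.pos.x, a.pos.y, a.pos.z, a.occ, a.element.name, a.altloc
                )
            if residue.atoms:
                chain.residues.append(residue)
        if chain.residues:
            model.chains.append(chain)
    if not model.chains:
        raise StructureParseError(f"{path.name}: no amino-acid residues parsed")
    return model


def filter_by_resolution(
    entries: Iterable[StructureModel],
    lo: float,
    hi: float,
    skipped: list | None = None,
) -> list[StructureModel]:
    """Keep entries with resolution in the half-open interval (lo, hi].

    Entries without resolution metadata are excluded; if a ``skipped`` list is
    given, (entry_id, reason) pairs are appended to it for reporting.
    """
    if not lo < hi:
        raise ValueError(f"need lo < hi, got ({lo}, {hi})")
    kept = []
    for entry in entries:
        if entry.resolution is None:
            if skipped is not None:
                skipped.append((entry.entry_id, "no resolution metadata"))
            continue
        if lo < entry.resolution <= hi:
            kept.append(entry)
        elif skipped is not None:
            skipped.append(
                (entry.entry_id, f"resolution {entry.resolution:g} outside ({lo:g}, {hi:g}]")
            )
    return kept


def write_skipped_report(skipped: list[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        fh.write("entry_id\treason\n")
        for entry_id, reason in skipped:
            fh.write(f"{entry_id}\t{reason}\n")


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -0.5
    aligner.extend_gap_score = -0.1
    return aligner


def sequence_identity(seq_a: str, seq_b: str) -> float:
    """Global-alignment identity: exact matches / alignment columns."""
    if not seq_a or not seq_b:
        return 0.0
    aligner = _make_aligner()
    alignment = aligner.align(seq_a, seq_b)[0]
    counts = alignment.counts()
    columns = alignment.shape[1]
    return counts.identities / columns if columns else 0.0


def dedup_chains(model: StructureModel, identity_threshold: float = 0.95) -> list[Chain]:
    """Drop within-entry duplicate chains (NCS copies).

    Chains are scanned in chain-ID order; a chain is dropped when its global
    sequence identity with any already-retained chain is >= the threshold.
    """
    if not model.chains:
        raise ValueError(f"{model.entry_id}: model has no chains")
    retained: list[Chain] = []
    for chain in sorted(model.chains, key=lambda c: c.chain_id):
        seq = chain.sequence()
        if not seq:
            warnings.warn(f"{model.entry_id}/{chain.chain_id}: no standard residues, skipped")
            continue
        duplicate = any(
            sequence_identity(seq, kept.sequence()) >= identity_threshold
            for kept in retained
        )
        if not duplicate:
            retained.append(chain)
    return retained
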