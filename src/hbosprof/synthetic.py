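"""Synthetic test inputs: ideal peptides, feature samples, injected outliers.

Everything the test suite consumes is generated here, with no downloads:

* :func:`build_peptide` constructs a peptide with ideal (Engh–Huber-style)
  bond lengths and angles at prescribed backbone/sidechain torsions, by
  internal-to-Cartesian (NeRF) placement.  Measuring the torsions back with
  the features module recovers the prescribed values, which makes
  build-then-measure round trips the natural oracle for the feature code.
* :func:`sample_features` draws per-residue-type feature vectors from a
  generative model — von Mises mixtures for the three angles (respecting the
  wrap at 0/360°) and truncated Gaussians for the two distances.
* :func:`inject_outliers` displaces a fraction of records into low-density
  regions and returns truth labels for recovery tests.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .features import ANGLE_FEATURES, FEATURE_NAMES, FeatureRecord
from .structure_io import Atom, Chain, Residue, StructureModel

# ---------------------------------------------------------------------------
# geometry table


def _load_geometry() -> dict:
    text = resources.files("hbosprof").joinpath("data/ideal_geometry.json").read_text()
    return json.loads(text)


_GEOMETRY = _load_geometry()
SUPPORTED_TYPES = frozenset(_GEOMETRY["sidechains"])


def place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Position atom d bonded to c with angle(b,c,d) and torsion(a,b,c,d)."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * math.cos(angle),
            bond * math.sin(angle) * math.cos(torsion),
            bond * math.sin(angle) * math.sin(torsion),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


@dataclass
class PeptideSpec:
    """Sequence plus per-residue torsion targets, degrees in [0, 360).

    ``phi``/``psi``/``chi1`` may be a single value (applied to every residue)
    or one value per residue.  phi of the first residue and psi of the last
    shape the construction but are not measurable afterwards.
    """

    sequence: list[str]
    phi: float | list[float] = 303.0  # -57 deg: alpha-helical default
    psi: float | list[float] = 313.0  # -47 deg
    chi1: float | list[float] = 300.0  # minus rotamer

    def per_residue(self, value) -> list[float]:
        n = len(self.sequence)
        if isinstance(value, (int, float)):
            return [float(value)] * n
        if len(value) != n:
            raise ValueError("torsion list length must match the sequence")
        return [float(v) for v in value]


def _element_of(atom_name: str) -> str:
    return atom_name[0]


def build_peptide(spec: PeptideSpec, chain_id: str = "A", entry_id: str = "SYNT") -> StructureModel:
    """Build a peptide with ideal geometry at the prescribed torsions."""
    geo = _GEOMETRY["backbone"]
    sequence = [s.upper() for s in spec.sequence]
    if len(sequence) < 2:
        raise ValueError("peptide needs at least 2 residues")
    for res_type in sequence:
        if res_type not in SUPPORTED_TYPES:
            raise ValueError(f"unsupported residue type {res_type!r}")
    phis = spec.per_residue(spec.phi)
    psis = spec.per_residue(spec.psi)
    chi1s = spec.per_residue(spec.chi1)

    chain = Chain(chain_id=chain_id)
    prev: dict[str, np.ndarray] | None = None
    for i, res_type in enumerate(sequence):
        atoms: dict[str, np.ndarray] = {}
        if prev is None:
            atoms["N"] = np.zeros(3)
            atoms["CA"] = np.array([geo["N_CA"], 0.0, 0.0])
            atoms["C"] = place_atom(
                np.array([0.0, 1.0, 0.0]), atoms["N"], atoms["CA"],
                geo["CA_C"], geo["angle_N_CA_C"], 0.0,
            )
        else:
            atoms["N"] = place_atom(
                prev["N"], prev["CA"], prev["C"],
                geo["C_N"], geo["angle_CA_C_N"], psis[i - 1],
            )
            atoms["CA"] = place_atom(
                prev["CA"], prev["C"], atoms["N"],
                geo["N_CA"], geo["angle_C_N_CA"], geo["omega"],
            )
            atoms["C"] = place_atom(
                prev["C"], atoms["N"], atoms["CA"],
                geo["CA_C"], geo["angle_N_CA_C"], phis[i],
            )
        atoms["O"] = place_atom(
            atoms["N"], atoms["CA"], atoms["C"],
            geo["C_O"], geo["angle_CA_C_O"], (psis[i] + 180.0) % 360.0,
        )
        if res_type != "GLY":
            atoms["CB"] = place_atom(
                atoms["C"], atoms["N"], atoms["CA"],
                geo["CA_CB"], geo["angle_N_CA_CB"], geo["torsion_C_N_CA_CB"],
            )
        for row in _GEOMETRY["sidechains"][res_type]:
            name, ref_a, ref_b, ref_c, bond, angle, torsion = row
            if isinstance(torsion, str):
                offset = 0.0
                if "+" in torsion:
                    base, off = torsion.split("+")
                    offset = float(off)
                    torsion = base
                assert torsion == "chi1"
                torsion_deg = (chi1s[i] + offset) % 360.0
            else:
                torsion_deg = float(torsion)
            atoms[name] = place_atom(
                atoms[ref_a], atoms[ref_b], atoms[ref_c], bond, angle, torsion_deg
            )
        residue = Residue(res_type=res_type, seq_id=i + 1, icode="")
        for name, pos in atoms.items():
            residue.atoms[name] = Atom(
                float(pos[0]), float(pos[1]), float(pos[2]),
                1.0, _element_of(name), "",
            )
        chain.residues.append(residue)
        prev = atoms
    return StructureModel(entry_id=entry_id, chains=[chain])


# ---------------------------------------------------------------------------
# structure writers (fixtures are plain-text PDB / mmCIF)


def _to_gemmi(model: StructureModel):
    import gemmi

    st = gemmi.Structure()
    st.name = model.entry_id
    if model.resolution is not None:
        st.resolution = model.resolution
    gmodel = gemmi.Model("1")
    for chain in model.chains:
        gchain = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.res_type
            gres.seqid = gemmi.SeqId(res.seq_id, res.icode or " ")
            for name, atom in res.atoms.items():
                ga = gemmi.Atom()
                ga.name = name
                ga.pos = gemmi.Position(atom.x, atom.y, atom.z)
                ga.occ = atom.occupancy
                ga.element = gemmi.Element(atom.element)
                gres.add_atom(ga)
            gchain.add_residue(gres)
        gmodel.add_chain(gchain)
    st.add_model(gmodel)
    st.setup_entities()
    return st


def write_pdb(model: StructureModel, path) -> None:
    _to_gemmi(model).write_pdb(str(path))


def write_mmcif(model: StructureModel, path) -> None:
    st = _to_gemmi(model)
    st.make_mmcif_document().write_file(str(path))


# ---------------------------------------------------------------------------
# generative feature model


@dataclass(frozen=True)
class AngleMixture:
    """Von Mises mixture on the circle; means in degrees, [0, 360)."""

    components: tuple[tuple[float, float, float], ...]  # (weight, mean, kappa)

    def __post_init__(self):
        total = sum(w for w, _, _ in self.components)
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError("mixture weights must sum to 1")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        weights = np.array([w for w, _, _ in self.components])
        idx = rng.choice(len(self.components), size=n, p=weights)
        out = np.empty(n)
        for k, (_, mean, kappa) in enumerate(self.components):
            mask = idx == k
            offsets = rng.vonmises(0.0, kappa, size=int(mask.sum()))
            out[mask] = (mean + np.degrees(offsets)) % 360.0
        return out

    def density(self, degrees: np.ndarray) -> np.ndarray:
        """Mixture density per degree (for locating low-density regions)."""
        theta = np.radians(np.asarray(degrees, dtype=float))
        dens = np.zeros_like(theta)
        for w, mean, kappa in self.components:
            mu = math.radians(mean)
            dens += w * np.exp(kappa * np.cos(theta - mu)) / (
                2 * np.pi * np.i0(kappa)
            )
        return dens


@dataclass(frozen=True)
class DistanceDist:
    """Gaussian truncated to positive values; mean/sd in Å."""

    mean: float
    sd: float

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return np.clip(rng.normal(self.mean, self.sd, size=n), 0.05, None)


@dataclass(frozen=True)
class TypeSpec:
    phi: AngleMixture
    psi: AngleMixture
    chi1: AngleMixture
    d_sidechain: DistanceDist
    d_block: DistanceDist

    def feature(self, name: str):
        return getattr(self, name)


@dataclass
class GenerativeSpec:
    """Per-residue-type generative model plus the outlier displacement rule."""

    types: dict[str, TypeSpec]
    outlier_fraction: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.outlier_fraction < 0.5:
            raise ValueError("outlier fraction must be in [0, 0.5)")


def _common_backbone() -> tuple[AngleMixture, AngleMixture]:
    phi = AngleMixture(((0.5, 297.0, 10.0), (0.4, 245.0, 5.0), (0.1, 60.0, 12.0)))
    psi = AngleMixture(((0.5, 319.0, 10.0), (0.4, 140.0, 5.0), (0.1, 10.0, 10.0)))
    return phi, psi


def _rotamer(p_minus=0.55, p_trans=0.3, p_plus=0.15, kappa=15.0) -> AngleMixture:
    return AngleMixture(
        ((p_minus, 300.0, kappa), (p_trans, 180.0, kappa), (p_plus, 60.0, kappa))
    )


def default_generative_spec() -> GenerativeSpec:
    """Six residue types with realistic torsion rotamers and centroid lengths."""
    phi, psi = _common_backbone()
    types = {
        "LEU": TypeSpec(phi, psi, _rotamer(), DistanceDist(2.58, 0.10), DistanceDist(3.10, 0.12)),
        "ILE": TypeSpec(phi, psi, _rotamer(), DistanceDist(2.42, 0.09), DistanceDist(2.85, 0.11)),
        "SER": TypeSpec(phi, psi, _rotamer(0.35, 0.25, 0.40), DistanceDist(2.02, 0.06), DistanceDist(2.42, 0.07)),
        "ASP": TypeSpec(phi, psi, _rotamer(), DistanceDist(2.46, 0.08), DistanceDist(2.94, 0.10)),
        "GLN": TypeSpec(phi, psi, _rotamer(), DistanceDist(3.09, 0.14), DistanceDist(4.10, 0.20)),
        "ARG": TypeSpec(phi, psi, _rotamer(), DistanceDist(4.10, 0.25), DistanceDist(5.60, 0.35)),
    }
    return GenerativeSpec(types=types)


def sample_features(
    spec: GenerativeSpec, n: int, seed: int, entry_id: str = "SYN"
) -> list[FeatureRecord]:
    """Draw *n* feature records, residue types assigned round-robin."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    res_types = sorted(spec.types)
    assignment = np.array([res_types[i % len(res_types)] for i in range(n)])
    columns: dict[str, np.ndarray] = {f: np.empty(n) for f in FEATURE_NAMES}
    for res_type in res_types:
        mask = assignment == res_type
        k = int(mask.sum())
        tspec = spec.types[res_type]
        for fname in FEATURE_NAMES:
            dist = tspec.feature(fname)
            columns[fname][mask] = dist.sample(rng, k)
    return [
        FeatureRecord(
            entry_id=entry_id,
            chain_id="A",
            seq_id=i + 1,
            icode="",
            res_type=assignment[i],
            **{f: float(columns[f][i]) for f in FEATURE_NAMES},
        )
        for i in range(n)
    ]


def _low_density_angle(mixture: AngleMixture, rng: np.random.Generator) -> float:
    grid = np.arange(0.0, 360.0, 1.0)
    dens = mixture.density(grid)
    cutoff = np.quantile(dens, 0.05)
    candidates = grid[dens <= cutoff]
    base = float(rng.choice(candidates))
    return (base + float(rng.uniform(-0.5, 0.5))) % 360.0


def inject_outliers(
    records: list[FeatureRecord],
    fraction: float,
    seed: int,
    spec: GenerativeSpec | None = None,
    n_features: int = 2,
) -> tuple[list[FeatureRecord], np.ndarray]:
    """Displace a fraction of records into near-zero-density regions.

    Exactly ``round(n * fraction)`` records are displaced in >= ``n_features``
    features each; returns (records, truth labels).
    """
    if not 0.0 < fraction < 0.5:
        raise ValueError("fraction must be in (0, 0.5)")
    spec = spec or default_generative_spec()
    rng = np.random.default_rng(seed)
    n = len(records)
    n_out = int(round(n * fraction))
    chosen = rng.choice(n, size=n_out, replace=False)
    labels = np.zeros(n, dtype=bool)
    labels[chosen] = True
    out = list(records)
    for idx in sorted(chosen):
        rec = records[idx]
        tspec = spec.types[rec.res_type]
        features = list(rng.choice(FEATURE_NAMES, size=n_features, replace=False))
        updates = {}
        for fname in features:
            if fname in ANGLE_FEATURES:
                updates[fname] = _low_density_angle(tspec.feature(fname), rng)
            else:
                dist = tspec.feature(fname)
                sign = 1.0 if rng.random() < 0.7 else -1.0
                updates[fname] = float(max(0.1, dist.mean + sign * 8.0 * dist.sd))
        out[idx] = FeatureRecord(
            entry_id=rec.entry_id,
            chain_id=rec.chain_id,
            seq_id=rec.seq_id,
            icode=rec.icode,
            res_type=rec.res_type,
            **{
                f: updates.get(f, getattr(rec, f))
                for f in FEATURE_NAMES
            },
        )
    return out, labels


# ---------------------------------------------------------------------------
# fixture sets

HELIX_SPEC = PeptideSpec(sequence=["LEU"] * 12, phi=303.0, psi=313.0, chi1=300.0)
#: Two extended strands joined by a type I' tight turn; these torsions pair
#: the strand NH/CO groups into an antiparallel hairpin.
HAIRPIN_PHI = [240.0] * 6 + [60.0, 90.0] + [240.0] * 6
HAIRPIN_PSI = [135.0] * 6 + [30.0, 0.0] + [135.0] * 6
HAIRPIN_SPEC = PeptideSpec(
    sequence=["VAL"] * 14, phi=HAIRPIN_PHI, psi=HAIRPIN_PSI, chi1=180.0
)
TRIPEPTIDE_SPEC = PeptideSpec(
    sequence=["GLY", "LEU", "SER"], phi=303.0, psi=313.0, chi1=300.0
)


def write_fixture_set(outdir) -> dict[str, Path]:
    """Write the standard structure fixtures; returns name -> path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, spec in (
        ("helix12", HELIX_SPEC),
        ("hairpin14", HAIRPIN_SPEC),
        ("tripeptide", TRIPEPTIDE_SPEC),
    ):
        model = build_peptide(spec, entry_id=name.upper()[:4])
        pdb = outdir / f"{name}.pdb"
        cif = outdir / f"{name}.cif"
        write_pdb(model, pdb)
        write_mmcif(model, cif)
        paths[name] = pdb
    return paths
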