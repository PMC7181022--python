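"""Secondary-structure assignment (Kabsch–Sander) and outlier breakdowns.

The 8-state assignment follows the classic dictionary-of-protein-secondary-
structure algorithm: backbone hydrogen bonds are identified with the
electrostatic energy model

    E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)   [kcal/mol]

with a bond where E < -0.5 kcal/mol; turns, helices, bridges, ladders and
bends are then derived with the published priority rules.  Amide hydrogens
are reconstructed geometrically from the preceding carbonyl (deposited
structures rarely contain hydrogens).  Labels: H/G/I (4-/3-/5-turn helix),
E (extended strand), B (isolated beta-bridge), T (hydrogen-bonded turn),
S (bend), "-" (coil).  Loops are the group {-, S, T}.

An optional cross-check mode parses the output of an external DSSP program
instead of computing labels internally.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .structure_io import Chain, StructureModel

SS_LABELS = ("-", "S", "T", "B", "E", "G", "H", "I")
LOOP_LABELS = frozenset({"-", "S", "T"})
HELIX_LABELS = frozenset({"G", "H", "I"})
SHEET_LABELS = frozenset({"E", "B"})

#: Kabsch–Sander electrostatic prefactor: q1*q2*332 kcal*Å/mol.
_COUPLING = 0.084 * 332.0
#: H-bond acceptance threshold, kcal/mol.
_HBOND_CUTOFF = -0.5
#: Donor/acceptor pairs farther apart than this (CA-CA, Å) are not tested.
_CA_CUTOFF = 9.0
#: Minimal heavy-atom separation; closer contacts get a clamp energy.
_MIN_DIST = 0.5
_CLAMP_ENERGY = -9.9
_CHAIN_BREAK_CN = 2.5


def _backbone_arrays(chain: Chain):
    n_res = len(chain.residues)
    coords = {name: np.full((n_res, 3), np.nan) for name in ("N", "CA", "C", "O")}
    has_bb = np.zeros(n_res, dtype=bool)
    for i, res in enumerate(chain.residues):
        ok = True
        for name in ("N", "CA", "C", "O"):
            p = res.pos(name)
            if p is None:
                ok = False
            else:
                coords[name][i] = p
        has_bb[i] = ok
    return coords, has_bb


def _segment_starts(chain: Chain, coords, has_bb) -> np.ndarray:
    """True where residue i starts a new covalently connected segment."""
    n_res = len(chain.residues)
    starts = np.zeros(n_res, dtype=bool)
    if n_res:
        starts[0] = True
    for i in range(1, n_res):
        c_prev, n_curr = coords["C"][i - 1], coords["N"][i]
        if np.isnan(c_prev).any() or np.isnan(n_curr).any():
            starts[i] = True
        elif float(np.linalg.norm(c_prev - n_curr)) > _CHAIN_BREAK_CN:
            starts[i] = True
    return starts


def _hydrogen_positions(chain: Chain, coords, has_bb, starts) -> np.ndarray:
    """Amide H along the preceding C=O direction, 1.0 Å from N."""
    n_res = len(chain.residues)
    h = np.full((n_res, 3), np.nan)
    for i in range(n_res):
        if starts[i] or chain.residues[i].res_type == "PRO":
            continue  # no donatable H
        if not (has_bb[i] and has_bb[i - 1]):
            continue
        co = coords["C"][i - 1] - coords["O"][i - 1]
        norm = float(np.linalg.norm(co))
        if norm < 1e-6:
            continue
        h[i] = coords["N"][i] + co / norm
    return h


def _hbond_map(chain: Chain) -> tuple[set[tuple[int, int]], np.ndarray, np.ndarray]:
    """Set of (acceptor, donor) pairs: C=O of *acceptor* binds N-H of *donor*.

    Each donor keeps only its two lowest-energy acceptors, as in the
    reference algorithm.
    """
    coords, has_bb = _backbone_arrays(chain)
    starts = _segment_starts(chain, coords, has_bb)
    h_pos = _hydrogen_positions(chain, coords, has_bb, starts)
    n_res = len(chain.residues)

    def energy(acc: int, don: int) -> float:
        o, c = coords["O"][acc], coords["C"][acc]
        n, h = coords["N"][don], h_pos[don]
        if np.isnan(h).any() or np.isnan(o).any():
            return 0.0
        r_on = float(np.linalg.norm(o - n))
        r_ch = float(np.linalg.norm(c - h))
        r_oh = float(np.linalg.norm(o - h))
        r_cn = float(np.linalg.norm(c - n))
        if min(r_on, r_ch, r_oh, r_cn) < _MIN_DIST:
            return _CLAMP_ENERGY
        return _COUPLING * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)

    best: list[list[tuple[float, int]]] = [[] for _ in range(n_res)]
    for don in range(n_res):
        if np.isnan(h_pos[don]).any():
            continue
        for acc in range(n_res):
            if acc == don or acc == don - 1:
                continue  # a residue cannot bind itself or its predecessor's NH
            if not has_bb[acc]:
                continue
            ca_d = float(np.linalg.norm(coords["CA"][acc] - coords["CA"][don]))
            if not np.isfinite(ca_d) or ca_d > _CA_CUTOFF:
                continue
            e = energy(acc, don)
            if e < _HBOND_CUTOFF:
                best[don].append((e, acc))
        best[don].sort()
        del best[don][2:]  # two best H-bonds per donor

    bonds = {(acc, don) for don in range(n_res) for _, acc in best[don]}
    return bonds, has_bb, starts


def assign_secondary_structure(chain: Chain) -> list[str]:
    """8-state label per residue of the chain."""
    n_res = len(chain.residues)
    labels = ["-"] * n_res
    if n_res < 3:
        return labels
    bonds, has_bb, starts = _hbond_map(chain)
    coords, _ = _backbone_arrays(chain)

    def hb(acc: int, don: int) -> bool:
        return (acc, don) in bonds

    # n-turns: C=O of i accepts N-H of i+n
    turn = {n: np.zeros(n_res, dtype=bool) for n in (3, 4, 5)}
    for n in (3, 4, 5):
        for i in range(n_res - n):
            if hb(i, i + n):
                turn[n][i] = True

    # helices: two consecutive n-turns start a minimal helix at i
    def helix_starts(n: int) -> list[int]:
        return [i for i in range(1, n_res - n) if turn[n][i] and turn[n][i - 1]]

    for i in helix_starts(4):
        for k in range(i, i + 4):
            labels[k] = "H"

    # bridges and ladders
    parallel: list[tuple[int, int]] = []
    antiparallel: list[tuple[int, int]] = []
    for i in range(1, n_res - 1):
        for j in range(i + 3, n_res - 1):
            if (hb(i - 1, j) and hb(j, i + 1)) or (hb(j - 1, i) and hb(i, j + 1)):
                parallel.append((i, j))
            if (hb(i, j) and hb(j, i)) or (hb(i - 1, j + 1) and hb(j - 1, i + 1)):
                antiparallel.append((i, j))

    def ladder_partition(bridges: list[tuple[int, int]], anti: bool):
        remaining = set(bridges)
        ladders = []
        for br in sorted(bridges):
            if br not in remaining:
                continue
            ladder = [br]
            remaining.discard(br)
            i, j = br
            while True:
                nxt = (i + 1, j - 1) if anti else (i + 1, j + 1)
                if nxt in remaining:
                    ladder.append(nxt)
                    remaining.discard(nxt)
                    i, j = nxt
                else:
                    break
            ladders.append(ladder)
        return ladders

    extended: set[int] = set()
    isolated: set[int] = set()
    for anti, bridges in ((False, parallel), (True, antiparallel)):
        for ladder in ladder_partition(bridges, anti):
            target = extended if len(ladder) >= 2 else isolated
            for i, j in ladder:
                target.add(i)
                target.add(j)
    for i in sorted(extended):
        if labels[i] == "-":
            labels[i] = "E"
    for i in sorted(isolated - extended):
        if labels[i] == "-":
            labels[i] = "B"

    # shorter/longer helices where nothing stronger claimed the residues
    for n, code in ((3, "G"), (5, "I")):
        for i in helix_starts(n):
            span = range(i, i + n)
            if all(labels[k] in ("-", code, "T", "S") for k in span):
                for k in span:
                    labels[k] = code

    # hydrogen-bonded turns
    for n in (3, 4, 5):
        for i in np.nonzero(turn[n])[0]:
            for k in range(i + 1, min(i + n, n_res)):
                if labels[k] == "-":
                    labels[k] = "T"

    # bends: CA direction changes by more than 70 degrees
    for i in range(2, n_res - 2):
        if labels[i] != "-":
            continue
        if starts[i - 1] or starts[i] or starts[i + 1] or starts[i + 2]:
            continue
        u = coords["CA"][i] - coords["CA"][i - 2]
        v = coords["CA"][i + 2] - coords["CA"][i]
        if np.isnan(u).any() or np.isnan(v).any():
            continue
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        if nu < 1e-6 or nv < 1e-6:
            continue
        cosang = float(np.dot(u, v) / (nu * nv))
        angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        if angle > 70.0:
            labels[i] = "S"

    for i in range(n_res):
        if not has_bb[i]:
            labels[i] = "-"
    return labels


def assign_model(model: StructureModel) -> dict[tuple[str, int, str], str]:
    """Labels for every residue of a structure, keyed (chain, seq_id, icode)."""
    out: dict[tuple[str, int, str], str] = {}
    for chain in model.chains:
        labels = assign_secondary_structure(chain)
        for res, label in zip(chain.residues, labels):
            out[(chain.chain_id, res.seq_id, res.icode)] = label
    return out


def read_dssp_output(path) -> dict[tuple[str, int, str], str]:
    """Parse a legacy DSSP output file (cross-check mode)."""
    out: dict[tuple[str, int, str], str] = {}
    with open(path) as fh:
        in_table = False
        for line in fh:
            if line.startswith("  #  RESIDUE"):
                in_table = True
                continue
            if not in_table or len(line) < 17:
                continue
            if line[13] == "!":
                continue  # chain break record
            try:
                seq_id = int(line[5:10])
            except ValueError:
                continue
            icode = line[10].strip()
            chain_id = line[11].strip()
            ss = line[16]
            out[(chain_id, seq_id, icode)] = "-" if ss == " " else ss
    return out


# ---------------------------------------------------------------------------
# Breakdown tables

_PCT_COLS = ("pct_coil", "pct_T", "pct_S", "pct_helix", "pct_sheet")


def _row_percentages(counts: dict[str, int]) -> dict[str, float]:
    total = sum(counts.values())
    if total == 0:
        return {c: 0.0 for c in _PCT_COLS} | {"pct_loop": 0.0}
    coil = counts["-"]
    helix = sum(counts[c] for c in ("G", "H", "I"))
    sheet = sum(counts[c] for c in ("B", "E"))
    loop = coil + counts["S"] + counts["T"]
    return {
        "pct_coil": round(100.0 * coil / total, 2),
        "pct_T": round(100.0 * counts["T"] / total, 2),
        "pct_S": round(100.0 * counts["S"] / total, 2),
        "pct_helix": round(100.0 * helix / total, 2),
        "pct_sheet": round(100.0 * sheet / total, 2),
        "pct_loop": round(100.0 * loop / total, 2),
    }


def ss_breakdown(outliers: Iterable[tuple[str, str]]) -> pd.DataFrame:
    """Count outliers per residue type and secondary-structure state.

    *outliers* is an iterable of (res_type, label) pairs.  Returns one row
    per residue type plus a Total row; count columns follow the label order
    (-, S, T, B, E, G, H, I), percentage columns are coil, T, S, helix
    (G+H+I), sheet (E+B), and a derived loop percentage (coil+T+S).  Rows
    with zero outliers carry an ``empty`` flag.
    """
    per_type: dict[str, dict[str, int]] = {}
    for res_type, label in outliers:
        if label not in SS_LABELS:
            raise ValueError(f"unknown secondary-structure label {label!r}")
        row = per_type.setdefault(res_type, {c: 0 for c in SS_LABELS})
        row[label] += 1

    rows = []
    total_counts = {c: 0 for c in SS_LABELS}
    for res_type in sorted(per_type):
        counts = per_type[res_type]
        for c in SS_LABELS:
            total_counts[c] += counts[c]
        rows.append(
            {"res_type": res_type}
            | counts
            | _row_percentages(counts)
            | {"empty": sum(counts.values()) == 0}
        )
    rows.append(
        {"res_type": "Total"}
        | total_counts
        | _row_percentages(total_counts)
        | {"empty": sum(total_counts.values()) == 0}
    )
    df = pd.DataFrame(rows).set_index("res_type")
    return df[list(SS_LABELS) + list(_PCT_COLS) + ["pct_loop", "empty"]]


def breakdown_from_counts(counts_by_type: dict[str, Sequence[int]]) -> pd.DataFrame:
    """Breakdown table from pre-tallied counts in (-, S, T, B, E, G, H, I) order."""
    pairs: list[tuple[str, str]] = []
    for res_type, counts in counts_by_type.items():
        if len(counts) != len(SS_LABELS):
            raise ValueError(f"{res_type}: expected {len(SS_LABELS)} counts")
        for label, k in zip(SS_LABELS, counts):
            pairs.extend([(res_type, label)] * int(k))
    return ss_breakdown(pairs)


def write_breakdown_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")
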