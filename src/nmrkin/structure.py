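"""Coordinate I/O, rigid superposition and loop deviation measurements.

Reads PDB/mmCIF coordinates (via gemmi), performs selection-based
least-squares superposition (Kabsch, reflection excluded), and measures the
quantities used to characterise loop rearrangements in lipocalin-type
proteins: per-residue C-alpha deviations, loop RMSDs after fitting on the
rigid beta-barrel core, single-atom displacements between states, and
intra-structure atom distances.

The default fitting frame is a 58-C-alpha selection spanning the eight
strands of the beta-barrel, shipped as a JSON selection file.  The strand
residue list is an approximation constructed from the loop boundaries
(strands lie between the variable loops) and is config-overridable.
"""

from __future__ import annotations

import json
import urllib.request
from dataclasses import dataclass, field as dc_field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
import pandas as pd

#: structurally variable loops at the open end of the beta-barrel
LOOPS: dict[str, tuple[int, int]] = {
    "L1": (38, 51),
    "L2": (70, 76),
    "L3": (95, 105),
    "L4": (125, 132),
}


@dataclass
class Structure:
    """Flat atom table of one model of a crystal structure."""

    chain: np.ndarray     # str
    res_id: np.ndarray    # int (author numbering)
    res_name: np.ndarray  # str
    atom_name: np.ndarray # str (PDB v3 names: CA, CD1, CG1, ...)
    element: np.ndarray   # str
    altloc: np.ndarray    # str ('' when absent)
    occupancy: np.ndarray # float
    xyz: np.ndarray       # (n, 3) Angstrom

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("coordinates must be finite")
        keys = list(zip(self.chain, self.res_id, self.atom_name, self.altloc))
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (chain, residue, atom, altloc) keys")

    @property
    def n_atoms(self) -> int:
        return len(self.res_id)

    def index_of(self, chain: str, res_id: int, atom_name: str) -> int:
        mask = (self.chain == chain) & (self.res_id == res_id) & (self.atom_name == atom_name)
        idx = np.where(mask)[0]
        if len(idx) != 1:
            raise KeyError(f"atom ({chain}, {res_id}, {atom_name}): {len(idx)} matches")
        return int(idx[0])


def read_structure(path: str | Path, dialect: str | None = None) -> Structure:
    """Read a PDB or mmCIF file into a flat atom table.

    The format is inferred from the extension unless ``dialect`` ("pdb" or
    "mmcif") is given.  Alternate locations are resolved by keeping, per
    (chain, residue, atom), the conformer with the highest occupancy,
    breaking ties alphabetically (so 'A' wins over 'B' and the blank altloc
    always stays).  Insertion codes are not supported.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "pdb":
        fmt = gemmi.CoorFormat.Pdb
    elif dialect == "mmcif":
        fmt = gemmi.CoorFormat.Mmcif
    else:
        fmt = gemmi.CoorFormat.Detect
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise ValueError(f"{path}: no models")
    st.setup_entities()
    model = st[0]
    rows: dict[tuple, tuple] = {}
    for chain in model:
        for res in chain:
            if res.seqid.icode not in (" ", ""):
                raise ValueError(
                    f"insertion code {res.seqid.icode!r} at {chain.name} "
                    f"{res.seqid.num} is not supported")
            for atom in res:
                key = (chain.name, res.seqid.num, atom.name)
                alt = atom.altloc if atom.altloc else ""
                cand = (atom.occ, alt, res.name, atom.element.name,
                        (atom.pos.x, atom.pos.y, atom.pos.z))
                if key in rows:
                    prev = rows[key]
                    if (cand[0], _alt_rank(alt)) <= (prev[0], _alt_rank(prev[1])):
                        continue  # keep previous conformer unless strictly better
                rows[key] = cand
    keys = list(rows)
    return Structure(
        chain=np.array([k[0] for k in keys]),
        res_id=np.array([k[1] for k in keys], dtype=int),
        res_name=np.array([rows[k][2] for k in keys]),
        atom_name=np.array([k[2] for k in keys]),
        element=np.array([rows[k][3] for k in keys]),
        altloc=np.array([rows[k][1] for k in keys]),
        occupancy=np.array([rows[k][0] for k in keys], dtype=float),
        xyz=np.array([rows[k][4] for k in keys], dtype=float),
    )


def _alt_rank(alt: str) -> float:
    # blank beats 'A' beats 'B' ... under equal occupancy
    return 0.0 if alt == "" else -ord(alt)


def write_pdb(structure: Structure, path: str | Path) -> None:
    st = gemmi.Structure()
    st.name = "nmrkin"
    model = gemmi.Model("1")
    for chain_name in dict.fromkeys(structure.chain.tolist()):
        chain = gemmi.Chain(str(chain_name))
        mask = structure.chain == chain_name
        order = np.argsort(structure.res_id[mask], kind="stable")
        idxs = np.where(mask)[0][order]
        current = None
        res = None
        for i in idxs:
            rid = int(structure.res_id[i])
            if rid != current:
                if res is not None:
                    chain.add_residue(res)
                res = gemmi.Residue()
                res.name = str(structure.res_name[i])
                res.seqid = gemmi.SeqId(rid, " ")
                current = rid
            atom = gemmi.Atom()
            atom.name = str(structure.atom_name[i])
            atom.element = gemmi.Element(str(structure.element[i]))
            atom.occ = float(structure.occupancy[i])
            atom.altloc = str(structure.altloc[i]) if structure.altloc[i] else "\0"
            atom.pos = gemmi.Position(*structure.xyz[i])
            res.add_atom(atom)
        if res is not None:
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


@dataclass(frozen=True)
class AtomSelection:
    """Chain / residue-range / atom-name selection."""

    chain: str | None = None
    residues: tuple[int, ...] | None = None
    atoms: tuple[str, ...] = ("CA",)

    @classmethod
    def from_ranges(cls, ranges: Iterable[tuple[int, int]], chain: str | None = None,
                    atoms: Sequence[str] = ("CA",)) -> "AtomSelection":
        residues: list[int] = []
        for lo, hi in ranges:
            residues.extend(range(lo, hi + 1))
        return cls(chain, tuple(residues), tuple(atoms))

    @classmethod
    def from_json(cls, path: str | Path) -> "AtomSelection":
        spec = json.loads(Path(path).read_text())
        return cls(spec.get("chain"),
                   tuple(spec["residues"]) if spec.get("residues") else None,
                   tuple(spec.get("atoms", ["CA"])))

    def keys(self, structure: Structure) -> list[tuple[str, int, str]]:
        """Ordered (chain, residue, atom) keys this selection resolves to."""
        mask = np.ones(structure.n_atoms, dtype=bool)
        if self.chain is not None:
            mask &= structure.chain == self.chain
        if self.residues is not None:
            mask &= np.isin(structure.res_id, np.asarray(self.residues))
        mask &= np.isin(structure.atom_name, np.asarray(self.atoms))
        idx = np.where(mask)[0]
        if len(idx) == 0:
            raise ValueError(f"selection {self} matches no atoms")
        order = np.lexsort((structure.atom_name[idx], structure.res_id[idx],
                            structure.chain[idx]))
        idx = idx[order]
        return [(str(structure.chain[i]), int(structure.res_id[i]),
                 str(structure.atom_name[i])) for i in idx]


def barrel_selection() -> AtomSelection:
    """The shipped 58-C-alpha beta-barrel fitting selection."""
    with resources.files("nmrkin.data").joinpath("barrel_selection.json").open() as fh:
        spec = json.load(fh)
    return AtomSelection(spec.get("chain"), tuple(spec["residues"]),
                         tuple(spec.get("atoms", ["CA"])))


@dataclass
class Superposition:
    """Rigid transform mapping mobile onto reference: x -> R x + t."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_atoms: int

    def __post_init__(self) -> None:
        r = self.rotation
        if np.abs(r.T @ r - np.eye(3)).max() > 1e-8:
            raise ValueError("rotation must be orthonormal")
        if np.linalg.det(r) < 0:
            raise ValueError("reflections are excluded")
        if self.rmsd < 0:
            raise ValueError("rmsd must be >= 0")

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        return np.asarray(xyz, float) @ self.rotation.T + self.translation


def _matched_coords(reference: Structure, mobile: Structure,
                    selection: AtomSelection) -> tuple[np.ndarray, np.ndarray]:
    keys = selection.keys(reference)
    missing = []
    p, q = [], []
    for chain, rid, aname in keys:
        try:
            j = mobile.index_of(chain, rid, aname)
        except KeyError:
            missing.append((chain, rid, aname))
            continue
        p.append(reference.xyz[reference.index_of(chain, rid, aname)])
        q.append(mobile.xyz[j])
    if missing:
        raise ValueError(f"atoms missing from mobile structure: {missing}")
    return np.array(p), np.array(q)


def superpose(reference: Structure, mobile: Structure,
              selection: AtomSelection) -> Superposition:
    """Least-squares rigid fit of mobile onto reference over a selection.

    Optimal rotation by the SVD (Kabsch) construction with the determinant
    correction that excludes reflections.
    """
    p, q = _matched_coords(reference, mobile, selection)
    pc, qc = p.mean(axis=0), q.mean(axis=0)
    h = (q - qc).T @ (p - pc)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = pc - rot @ qc
    moved = q @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - p) ** 2, axis=1))))
    return Superposition(rot, trans, rmsd, len(p))


def per_residue_ca_deviation(reference: Structure, mobile: Structure,
                             superposition: Superposition,
                             chain: str | None = None) -> pd.DataFrame:
    """|Delta| of C-alpha positions per residue after applying the fit."""
    sel = AtomSelection(chain=chain, atoms=("CA",))
    keys = [k for k in sel.keys(reference)]
    rows = []
    for ch, rid, aname in keys:
        try:
            j = mobile.index_of(ch, rid, aname)
        except KeyError:
            continue
        moved = superposition.apply(mobile.xyz[j])
        ref = reference.xyz[reference.index_of(ch, rid, aname)]
        rows.append({"chain": ch, "residue": rid,
                     "deviation": float(np.linalg.norm(moved - ref))})
    return pd.DataFrame(rows, columns=["chain", "residue", "deviation"])


def selection_rmsd(reference: Structure, mobile: Structure,
                   superposition: Superposition, selection: AtomSelection) -> float:
    """RMSD over a selection after applying an existing superposition."""
    p, q = _matched_coords(reference, mobile, selection)
    moved = superposition.apply(q)
    return float(np.sqrt(np.mean(np.sum((moved - p) ** 2, axis=1))))


def atom_distance(structure: Structure, atom_a: tuple[str, int, str],
                  atom_b: tuple[str, int, str]) -> float:
    """Distance (A) between two atoms of one structure."""
    xa = structure.xyz[structure.index_of(*atom_a)]
    xb = structure.xyz[structure.index_of(*atom_b)]
    return float(np.linalg.norm(xa - xb))


def atom_displacement_between_states(reference: Structure, mobile: Structure,
                                     superposition: Superposition,
                                     atom: tuple[str, int, str]) -> float:
    """How far one atom moves between two states, in the fitted frame."""
    xr = reference.xyz[reference.index_of(*atom)]
    xm = superposition.apply(mobile.xyz[mobile.index_of(*atom)])
    return float(np.linalg.norm(xm - xr))


def loop_report(reference: Structure, mobile: Structure,
                superposition: Superposition,
                loops: dict[str, tuple[int, int]] | None = None,
                chain: str | None = None) -> pd.DataFrame:
    """Per-loop C-alpha RMSD and maximum per-residue deviation."""
    loops = loops or LOOPS
    dev = per_residue_ca_deviation(reference, mobile, superposition, chain)
    rows = []
    for name, (lo, hi) in loops.items():
        sel = AtomSelection.from_ranges([(lo, hi)], chain=chain)
        sub = dev[(dev["residue"] >= lo) & (dev["residue"] <= hi)]
        if sub.empty:
            continue
        rmsd = selection_rmsd(reference, mobile, superposition, sel)
        imax = sub["deviation"].idxmax()
        rows.append({"loop": name, "rmsd": rmsd,
                     "max_deviation": float(sub.loc[imax, "deviation"]),
                     "max_residue": int(sub.loc[imax, "residue"])})
    return pd.DataFrame(rows, columns=["loop", "rmsd", "max_deviation", "max_residue"])


def fetch_rcsb(pdb_id: str, dest: str | Path, timeout: float = 30.0) -> Path:
    """Download a PDB entry from RCSB (requires network access)."""
    dest = Path(dest)
    dest.parent.mkdir(parents=True, exist_ok=True)
    url = f"https://files.rcsb.org/download/{pdb_id.upper()}.pdb"
    with urllib.request.urlopen(url, timeout=timeout) as resp:
        dest.write_bytes(resp.read())
    return dest
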