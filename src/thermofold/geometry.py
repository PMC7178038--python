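"""Coordinate-level structure measurements and sequence charge analysis.

Covers the geometry used to characterize a small helical-bundle protein:
rigid-body (Kabsch) superposition, ensemble precision as average RMSD to
iteratively refined mean coordinates, pocket-entrance C-alpha distances,
closest side-chain proton contacts, salt-bridge/ionic-cluster detection,
a sequence charge census with isoelectric point, and the RDC quality
factor Q = rms(measured - calculated) / rms(measured).

Structures are read from mmCIF or PDB format (via gemmi); author residue
numbering is used throughout.  Hydrogen atoms are used when present (NMR
models); distance routines fall back to heavy atoms with a warning.
"""

from __future__ import annotations

import itertools
import urllib.request
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "StructureModel",
    "Ensemble",
    "ChargeCensus",
    "read_structure",
    "fetch_pdb",
    "superpose",
    "ensemble_rmsd_to_mean",
    "entrance_distances",
    "closest_proton_contact",
    "detect_salt_bridges",
    "charge_census",
    "isoelectric_point",
    "rdc_q_factor",
]

BACKBONE_ATOMS = ("N", "CA", "C")
_BACKBONE_SET = set(BACKBONE_ATOMS) | {"O", "OXT", "H", "HA", "HA2", "HA3", "H1", "H2", "H3"}

_ATOM_COLUMNS = ["name", "element", "resnum", "resname", "chain", "x", "y", "z"]


@dataclass
class StructureModel:
    """Atoms of one structural model.

    ``atoms`` is a table with columns name, element, resnum (author
    numbering), resname, chain, x, y, z (angstrom).
    """

    atoms: pd.DataFrame
    model_id: str = "1"

    def __post_init__(self):
        missing = set(_ATOM_COLUMNS) - set(self.atoms.columns)
        if missing:
            raise ValueError(f"atom table missing columns {sorted(missing)}")
        xyz = self.atoms[["x", "y", "z"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(xyz)):
            raise ValueError("non-finite coordinates")

    def coords(self, mask=None) -> np.ndarray:
        df = self.atoms if mask is None else self.atoms[mask]
        return df[["x", "y", "z"]].to_numpy(dtype=float)

    def select(self, atom_names=None, resnums=None, chain=None) -> pd.DataFrame:
        df = self.atoms
        if atom_names is not None:
            df = df[df["name"].isin(atom_names)]
        if resnums is not None:
            df = df[df["resnum"].isin(resnums)]
        if chain is not None:
            df = df[df["chain"] == chain]
        return df

    def residue_atoms(self, resnum: int, chain=None) -> pd.DataFrame:
        df = self.atoms[self.atoms["resnum"] == resnum]
        if chain is not None:
            df = df[df["chain"] == chain]
        return df

    def atom_xyz(self, resnum: int, atom_name: str) -> np.ndarray:
        df = self.atoms[(self.atoms["resnum"] == resnum) & (self.atoms["name"] == atom_name)]
        if df.empty:
            raise ValueError(f"atom {atom_name} of residue {resnum} not found")
        return df[["x", "y", "z"]].to_numpy(dtype=float)[0]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        out = self.atoms.copy()
        xyz = self.coords() @ rotation.T + translation
        out[["x", "y", "z"]] = xyz
        return StructureModel(out, self.model_id)


@dataclass
class Ensemble:
    """Several models sharing the same atom identity (an NMR bundle)."""

    models: list[StructureModel]
    source: str = ""

    def __post_init__(self):
        if not self.models:
            raise ValueError("ensemble must contain at least one model")

    def __len__(self):
        return len(self.models)

    def __iter__(self):
        return iter(self.models)


# ---------------------------------------------------------------------------
# file IO

def _structure_to_ensemble(st: gemmi.Structure) -> Ensemble:
    models = []
    for model in st:
        rows = []
        for chain in model:
            for residue in chain:
                for atom in residue:
                    rows.append(
                        (
                            atom.name,
                            atom.element.name,
                            residue.seqid.num,
                            residue.name,
                            chain.name,
                            atom.pos.x,
                            atom.pos.y,
                            atom.pos.z,
                        )
                    )
        model_id = getattr(model, "num", None) or getattr(model, "name", "1")
        models.append(
            StructureModel(pd.DataFrame(rows, columns=_ATOM_COLUMNS), model_id=str(model_id))
        )
    return Ensemble(models, source=st.name)


def read_structure(path) -> Ensemble:
    """Read a PDB or mmCIF file into an :class:`Ensemble` (all models)."""
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    return _structure_to_ensemble(st)


def fetch_pdb(entry_id: str, directory=".", fmt: str = "pdb", timeout: float = 30.0) -> Path:
    """Download a PDB entry (pdb or cif format) from RCSB; returns the path.

    Requires network access; cached if the file already exists.
    """
    entry_id = entry_id.lower()
    suffix = "pdb" if fmt == "pdb" else "cif"
    out = Path(directory) / f"{entry_id}.{suffix}"
    if out.exists():
        return out
    url = f"https://files.rcsb.org/download/{entry_id.upper()}.{suffix}"
    with urllib.request.urlopen(url, timeout=timeout) as resp:
        out.write_bytes(resp.read())
    return out


# ---------------------------------------------------------------------------
# superposition

def _kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rotation/translation mapping mobile onto reference."""
    mc, rc = mobile.mean(axis=0), reference.mean(axis=0)
    H = (mobile - mc).T @ (reference - rc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = rc - R @ mc
    return R, t


def _matched_coords(model: StructureModel, atom_selection) -> np.ndarray:
    df = model.select(atom_names=atom_selection) if atom_selection is not None else model.atoms
    df = df.sort_values(["chain", "resnum", "name"], kind="stable")
    return df[["x", "y", "z"]].to_numpy(dtype=float)


def superpose(
    mobile: StructureModel, reference: StructureModel, atom_selection=BACKBONE_ATOMS
) -> tuple[StructureModel, float]:
    """Least-squares rigid-body superposition (Kabsch).

    Returns the transformed mobile model and the RMSD over the selection.
    Atom correspondence is by sorted (chain, residue, atom name); both
    models must contain the same selected atoms.
    """
    a = _matched_coords(mobile, atom_selection)
    b = _matched_coords(reference, atom_selection)
    if len(a) != len(b):
        raise ValueError("selections differ between mobile and reference")
    if len(a) < 3:
        raise ValueError("need at least 3 atoms for superposition")
    R, t = _kabsch(a, b)
    rmsd = float(np.sqrt(np.mean(np.sum((a @ R.T + t - b) ** 2, axis=1))))
    return mobile.transformed(R, t), rmsd


def ensemble_rmsd_to_mean(
    ensemble: Ensemble,
    atom_selection=BACKBONE_ATOMS,
    tol: float = 1e-6,
    max_iter: int = 100,
    return_per_model: bool = False,
):
    """Average RMSD of the models to their iteratively refined mean coordinates.

    All models are superposed onto the current mean, the mean is recomputed,
    and the cycle repeats until the mean moves less than ``tol`` angstrom.
    """
    if len(ensemble) < 2:
        raise ValueError("need at least 2 models")
    coords = [_matched_coords(m, atom_selection) for m in ensemble]
    n = {c.shape for c in coords}
    if len(n) != 1:
        raise ValueError("models have inconsistent atom sets for this selection")
    coords = [c.copy() for c in coords]
    mean = coords[0].copy()
    for _ in range(max_iter):
        for i, c in enumerate(coords):
            R, t = _kabsch(c, mean)
            coords[i] = c @ R.T + t
        new_mean = np.mean(coords, axis=0)
        shift = float(np.sqrt(np.mean(np.sum((new_mean - mean) ** 2, axis=1))))
        mean = new_mean
        if shift < tol:
            break
    per_model = np.array(
        [np.sqrt(np.mean(np.sum((c - mean) ** 2, axis=1))) for c in coords]
    )
    avg = float(per_model.mean())
    return (avg, per_model) if return_per_model else avg


# ---------------------------------------------------------------------------
# distances and contacts

def entrance_distances(model: StructureModel, residue_triplet, chain=None) -> dict:
    """Pairwise C-alpha distances among three pocket-entrance residues.

    Returns the three labelled pair distances plus min/max summaries (A).
    """
    triplet = tuple(residue_triplet)
    if len(triplet) != 3:
        raise ValueError("need exactly three residues")
    xyz = {}
    for resnum in triplet:
        df = model.select(atom_names=["CA"], resnums=[resnum], chain=chain)
        if df.empty:
            raise ValueError(f"residue {resnum} has no C-alpha atom")
        xyz[resnum] = df[["x", "y", "z"]].to_numpy(dtype=float)[0]
    pairs = {}
    for a, b in itertools.combinations(triplet, 2):
        pairs[(a, b)] = float(np.linalg.norm(xyz[a] - xyz[b]))
    values = list(pairs.values())
    return {
        "pairs": pairs,
        "min": min(values),
        "max": max(values),
        "mean": float(np.mean(values)),
    }


def _side_chain(df: pd.DataFrame) -> pd.DataFrame:
    return df[~df["name"].isin(_BACKBONE_SET)]


def closest_proton_contact(
    model: StructureModel, res_a: int, res_b: int, chain=None
) -> float:
    """Shortest distance between side-chain hydrogens of two residues (A).

    Falls back to side-chain heavy atoms (with a warning) when either
    residue carries no hydrogens, e.g. in a crystal structure.
    """
    if res_a == res_b:
        raise ValueError("need two distinct residues")
    sides = []
    for resnum in (res_a, res_b):
        df = _side_chain(model.residue_atoms(resnum, chain=chain))
        if df.empty:
            raise ValueError(f"residue {resnum} has no side-chain atoms")
        sides.append(df)
    h_sides = [df[df["element"] == "H"] for df in sides]
    if all(len(df) > 0 for df in h_sides):
        use = h_sides
    else:
        warnings.warn("no side-chain hydrogens; falling back to heavy atoms")
        use = [df[df["element"] != "H"] for df in sides]
    a = use[0][["x", "y", "z"]].to_numpy(dtype=float)
    b = use[1][["x", "y", "z"]].to_numpy(dtype=float)
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)
    return float(d.min())


_BASIC_ATOMS = {"ARG": ("NH1", "NH2", "NE"), "LYS": ("NZ",)}
_ACIDIC_ATOMS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}


def detect_salt_bridges(model: StructureModel, cutoff: float = 4.0) -> pd.DataFrame:
    """Arg/Lys to Asp/Glu charged-group contacts within ``cutoff`` angstrom.

    Returns one row per residue pair (minimum N-O distance <= cutoff) with
    a ``cluster`` column labelling connected components (ionic clusters).
    """

    def charged(groups):
        out = {}
        for (chain, resnum, resname), df in model.atoms.groupby(
            ["chain", "resnum", "resname"]
        ):
            if resname in groups:
                sel = df[df["name"].isin(groups[resname])]
                if not sel.empty:
                    out[(chain, resnum, resname)] = sel[["x", "y", "z"]].to_numpy(float)
        return out

    basics = charged(_BASIC_ATOMS)
    acidics = charged(_ACIDIC_ATOMS)
    rows = []
    for (bc, bnum, bname), bxyz in basics.items():
        for (ac, anum, aname), axyz in acidics.items():
            d = np.linalg.norm(bxyz[:, None, :] - axyz[None, :, :], axis=-1).min()
            if d <= cutoff:
                rows.append(
                    {
                        "basic_chain": bc, "basic_resnum": bnum, "basic_resname": bname,
                        "acidic_chain": ac, "acidic_resnum": anum, "acidic_resname": aname,
                        "distance_A": float(d),
                    }
                )
    df = pd.DataFrame(
        rows,
        columns=["basic_chain", "basic_resnum", "basic_resname",
                 "acidic_chain", "acidic_resnum", "acidic_resname", "distance_A"],
    )
    if df.empty:
        df["cluster"] = pd.Series(dtype=int)
        return df
    g = nx.Graph()
    for _, r in df.iterrows():
        g.add_edge(
            (r["basic_chain"], r["basic_resnum"]),
            (r["acidic_chain"], r["acidic_resnum"]),
        )
    membership = {}
    for i, comp in enumerate(sorted(nx.connected_components(g), key=sorted)):
        for node in comp:
            membership[node] = i
    df["cluster"] = [
        membership[(r["basic_chain"], r["basic_resnum"])] for _, r in df.iterrows()
    ]
    return df.sort_values(["cluster", "distance_A"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# sequence charge census and isoelectric point

# Bjellqvist pKa set (as used by the ProtParam tool): side chains and termini.
_PKA_SIDE_NEG = {"D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}
_PKA_SIDE_POS = {"H": 5.98, "K": 10.0, "R": 12.0}
_PKA_CTERM = 3.55
_PKA_NTERM = {
    "A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36, "T": 6.82, "V": 7.44, "E": 7.7, "G": 7.5,
}
_PKA_NTERM_DEFAULT = 7.5

_VALID_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class ChargeCensus:
    """Charged-residue counts and isoelectric point of a sequence.

    ``basic_total`` counts Arg/Lys only; His is reported in ``notes``.
    """

    n_glu: int
    n_asp: int
    n_arg: int
    n_lys: int
    n_his: int
    pI: float
    notes: dict = field(default_factory=dict)

    @property
    def acidic_total(self) -> int:
        return self.n_glu + self.n_asp

    @property
    def basic_total(self) -> int:
        return self.n_arg + self.n_lys


def net_charge(sequence: str, pH: float) -> float:
    """Henderson-Hasselbalch net charge of a sequence at the given pH."""
    seq = sequence.upper()
    pos = 1.0 / (1.0 + 10.0 ** (pH - _PKA_NTERM.get(seq[0], _PKA_NTERM_DEFAULT)))
    neg = 1.0 / (1.0 + 10.0 ** (_PKA_CTERM - pH))
    for aa in seq:
        if aa in _PKA_SIDE_POS:
            pos += 1.0 / (1.0 + 10.0 ** (pH - _PKA_SIDE_POS[aa]))
        elif aa in _PKA_SIDE_NEG:
            neg += 1.0 / (1.0 + 10.0 ** (_PKA_SIDE_NEG[aa] - pH))
    return pos - neg


def isoelectric_point(sequence: str, tol: float = 1e-6) -> float:
    """pH of zero net charge, found by bisection on :func:`net_charge`."""
    seq = sequence.upper()
    bad = set(seq) - _VALID_AA
    if bad:
        raise ValueError(f"invalid residue codes {sorted(bad)}")
    lo, hi = 0.0, 14.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if hi - lo < tol:
            break
        if net_charge(seq, mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def charge_census(sequence: str) -> ChargeCensus:
    """Charged-residue counts (Glu/Asp/Arg/Lys/His) and pI of a sequence."""
    seq = sequence.upper().strip()
    bad = set(seq) - _VALID_AA
    if bad:
        raise ValueError(f"invalid residue codes {sorted(bad)}")
    return ChargeCensus(
        n_glu=seq.count("E"),
        n_asp=seq.count("D"),
        n_arg=seq.count("R"),
        n_lys=seq.count("K"),
        n_his=seq.count("H"),
        pI=isoelectric_point(seq),
        notes={"his_can_be_basic_at_physiological_pH": seq.count("H") > 0},
    )


# ---------------------------------------------------------------------------
# RDC quality factor

def rdc_q_factor(measured, calculated) -> float:
    """Q = rms(measured - calculated) / rms(measured), dimensionless."""
    measured = np.asarray(measured, dtype=float)
    calculated = np.asarray(calculated, dtype=float)
    if measured.shape != calculated.shape or measured.ndim != 1 or len(measured) == 0:
        raise ValueError("measured and calculated must be equal-length 1-D vectors")
    rms_meas = np.sqrt(np.mean(measured**2))
    if rms_meas == 0:
        raise ZeroDivisionError("measured RDCs are all zero")
    return float(np.sqrt(np.mean((measured - calculated) ** 2)) / rms_meas)
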