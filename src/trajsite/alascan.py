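"""Alanine point-mutant construction and WT-vs-mutant contact-loss metrics.

Mutation is side-chain truncation: atoms beyond CB are removed, CB is kept
(or rebuilt at ideal tetrahedral geometry for glycine) and the residue is
renamed ALA.  Backbone coordinates are never touched, so WT and mutant
structures are directly comparable.

Contact loss is defined on occupancies / mean per-frame counts rather than
raw frame counts, so runs of different lengths are comparable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import contacts as _contacts
from .core import Atom, ResidueKey, Topology, Trajectory

__all__ = [
    "MutantSpec",
    "ScanReport",
    "SIDECHAIN_HEAVY_ATOMS",
    "mutate_to_alanine",
    "position_contact_loss",
    "site_contact_loss",
    "site_contact_counts",
    "ingest_energy_table",
    "build_scan_report",
]

#: Heavy side-chain atoms per residue type, CB included (PDB naming).
SIDECHAIN_HEAVY_ATOMS: dict[str, tuple[str, ...]] = {
    "GLY": (),
    "ALA": ("CB",),
    "SER": ("CB", "OG"),
    "CYS": ("CB", "SG"),
    "THR": ("CB", "OG1", "CG2"),
    "VAL": ("CB", "CG1", "CG2"),
    "LEU": ("CB", "CG", "CD1", "CD2"),
    "ILE": ("CB", "CG1", "CG2", "CD1"),
    "MET": ("CB", "CG", "SD", "CE"),
    "PRO": ("CB", "CG", "CD"),
    "PHE": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"),
    "TRP": ("CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "ASP": ("CB", "CG", "OD1", "OD2"),
    "GLU": ("CB", "CG", "CD", "OE1", "OE2"),
    "ASN": ("CB", "CG", "OD1", "ND2"),
    "GLN": ("CB", "CG", "CD", "OE1", "NE2"),
    "HIS": ("CB", "CG", "ND1", "CD2", "CE1", "NE2"),
    "LYS": ("CB", "CG", "CD", "CE", "NZ"),
    "ARG": ("CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"),
}

_CB_BOND_NM = 0.153
_TETRAHEDRAL_DEG = 109.5


@dataclass(frozen=True)
class MutantSpec:
    position: int
    wt_name: str
    chain: str = "A"
    mutant_name: str = "ALA"

    @property
    def label(self) -> str:
        return f"{self.wt_name}{self.position}{self.mutant_name}"

    @property
    def residue_key(self) -> ResidueKey:
        return (self.chain, self.position)


def _ideal_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """CB position at tetrahedral geometry from backbone N, CA, C."""
    nu = (n - ca) / np.linalg.norm(n - ca)
    cu = (c - ca) / np.linalg.norm(c - ca)
    cos_phi = float(np.dot(nu, cu))
    cos_theta = math.cos(math.radians(_TETRAHEDRAL_DEG))
    alpha = cos_theta / (1.0 + cos_phi)
    in_plane = alpha * (nu + cu)
    perp = np.cross(nu, cu)
    perp /= np.linalg.norm(perp)
    beta_sq = 1.0 - float(np.dot(in_plane, in_plane))
    beta = math.sqrt(max(beta_sq, 0.0))
    direction = in_plane + beta * perp
    return ca + _CB_BOND_NM * direction


def mutate_to_alanine(
    topology: Topology,
    coords: np.ndarray,
    spec: MutantSpec | int,
    chain: str = "A",
) -> tuple[Topology, np.ndarray]:
    """Truncate one residue's side chain to alanine.

    Keeps backbone atoms (N, CA, C, O, plus amide/alpha hydrogens when
    present) and CB, removing everything else of the residue; all other
    residues are untouched, bitwise.  Raises if the residue is absent, the
    wild-type name mismatches, or the backbone is incomplete.
    """
    if isinstance(spec, int):
        key = (chain, spec)
        try:
            wt_name = topology.residue_name(key)
        except KeyError:
            raise ValueError(f"position {spec} not in topology") from None
        spec = MutantSpec(position=spec, wt_name=wt_name, chain=chain)
    key = spec.residue_key
    try:
        res_atoms = topology.atom_indices(key)
    except KeyError:
        raise ValueError(f"position {spec.position} not in topology") from None
    wt_name = topology.residue_name(key)
    if wt_name.upper() != spec.wt_name.upper():
        raise ValueError(
            f"wild-type mismatch at {spec.position}: topology has {wt_name}, "
            f"spec says {spec.wt_name}"
        )
    names_here = {topology.atoms[i].name.upper(): i for i in res_atoms}
    missing = [n for n in ("N", "CA", "C", "O") if n not in names_here]
    if missing:
        raise ValueError(f"residue {spec.position} backbone incomplete: missing {missing}")

    keep_names = {"N", "CA", "C", "O", "CB", "H", "HN", "HA", "OXT"}
    coords = np.asarray(coords, dtype=float)
    new_atoms: list[Atom] = []
    new_coords: list[np.ndarray] = []
    cb_seen = "CB" in names_here
    for i, atom in enumerate(topology.atoms):
        if atom.residue_key != key:
            new_atoms.append(atom)
            new_coords.append(coords[i])
            continue
        if atom.name.upper() in keep_names:
            new_atoms.append(replace(atom, residue_name="ALA"))
            new_coords.append(coords[i])
    if not cb_seen:
        cb = _ideal_cb(coords[names_here["N"]], coords[names_here["CA"]],
                       coords[names_here["C"]])
        # insert CB right after the residue's O to keep residue atoms together
        insert_at = max(j for j, a in enumerate(new_atoms) if a.residue_key == key) + 1
        new_atoms.insert(insert_at, Atom(serial=0, name="CB", element="C",
                                         residue_seq=spec.position,
                                         residue_name="ALA", chain=spec.chain))
        new_coords.insert(insert_at, cb)
    out_top = Topology(new_atoms, region_of=dict(topology.region_of))
    return out_top, np.asarray(new_coords)


def position_contact_loss(wt_occupancy: float, mut_occupancy: float) -> float:
    """Percent reduction in contact occurrence at the mutated position:
    100 x (WT - mutant) / WT.  Undefined (raises) when WT is zero."""
    if wt_occupancy <= 0:
        raise ValueError("WT occupancy must be positive for a relative loss")
    # 1 - mut/wt rather than (wt - mut)/wt: keeps the mut = 0 -> exactly
    # 100% and mut = wt -> exactly 0% endpoints free of rounding
    return 100.0 * (1.0 - mut_occupancy / wt_occupancy)


def site_contact_counts(
    traj: Trajectory,
    site_residues,
    ligand_residue: ResidueKey,
    cutoff: float = _contacts.CONTACT_CUTOFF_NM,
    window=None,
) -> np.ndarray:
    """Per-frame number of site residues in contact with the ligand."""
    site = set(site_residues)
    frames = _contacts.resolve_window(traj.n_frames, window, equilibrium_fraction=0.0) \
        if window is not None else np.arange(traj.n_frames)
    sets = _contacts.contacts_per_frame(traj, ligand_residue, cutoff, frames=frames)
    return np.asarray([len(s & site) for s in sets], dtype=float)


def site_contact_loss(wt_counts: np.ndarray, mut_counts: np.ndarray) -> float:
    """Percent reduction in mean per-frame binding-site contacts:
    100 x (mean WT - mean mutant) / mean WT."""
    wt_mean = float(np.mean(wt_counts))
    if wt_mean <= 0:
        raise ValueError("WT mean contact count must be positive")
    return 100.0 * (wt_mean - float(np.mean(mut_counts))) / wt_mean


def ingest_energy_table(path: str | Path, column: str | None = None) -> pd.DataFrame:
    """Summarize an external per-frame interaction-energy table.

    Accepts whitespace- or comma-separated numeric tables (one run per
    column); non-numeric rows are skipped (counted in the ``n_skipped``
    attribute).  Returns one summary row per run: median, quartiles and
    1.5-IQR whiskers, for boxplot reporting.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else r"\s+"
    raw = pd.read_csv(path, sep=sep, comment="#", engine="python")
    if raw.empty:
        raise ValueError(f"empty energy table: {path}")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    n_skipped = int(numeric.isna().any(axis=1).sum())
    numeric = numeric.dropna(how="any")
    if numeric.empty:
        raise ValueError(f"no numeric rows in energy table: {path}")
    cols = [column] if column else list(numeric.columns)
    rows = []
    for col in cols:
        vals = numeric[col].to_numpy(float)
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        iqr = q3 - q1
        lo = vals[vals >= q1 - 1.5 * iqr].min()
        hi = vals[vals <= q3 + 1.5 * iqr].max()
        rows.append({"run": str(col), "n": vals.size, "mean": vals.mean(),
                     "median": med, "q1": q1, "q3": q3,
                     "whisker_low": lo, "whisker_high": hi})
    out = pd.DataFrame(rows)
    out.attrs["n_skipped"] = n_skipped
    return out


@dataclass
class ScanReport:
    """Per-mutant contact-loss table, optionally joined with external
    energy summaries."""

    table: pd.DataFrame  # columns: mutant, position, position_loss_pct, site_loss_pct

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")

    def to_json(self) -> str:
        return self.table.to_json(orient="records", double_precision=6)


def build_scan_report(
    wt_traj: Trajectory,
    mutant_trajs: "dict[MutantSpec, Trajectory]",
    site_residues,
    ligand_residue: ResidueKey,
    cutoff: float = _contacts.CONTACT_CUTOFF_NM,
    window=None,
    energy_tables: "dict[str, pd.DataFrame] | None" = None,
) -> ScanReport:
    """Full WT-vs-mutants scan: per-position occupancy loss and whole-site
    mean-contact loss for every mutant."""
    wt_occ = _contacts.interaction_probability(wt_traj, ligand_residue, cutoff, window)
    wt_counts = site_contact_counts(wt_traj, site_residues, ligand_residue, cutoff, window)
    rows = []
    for spec, mtraj in mutant_trajs.items():
        mut_occ = _contacts.interaction_probability(mtraj, ligand_residue, cutoff, window)
        key = spec.residue_key
        wt_val = wt_occ.get(key, 0.0)
        pos_loss = position_contact_loss(wt_val, mut_occ.get(key, 0.0)) if wt_val > 0 else float("nan")
        mut_counts = site_contact_counts(mtraj, site_residues, ligand_residue, cutoff, window)
        row = {
            "mutant": spec.label,
            "position": spec.position,
            "wt_occupancy_pct": wt_val,
            "mut_occupancy_pct": mut_occ.get(key, 0.0),
            "position_loss_pct": pos_loss,
            "site_loss_pct": site_contact_loss(wt_counts, mut_counts),
        }
        if energy_tables and spec.label in energy_tables:
            row["median_energy"] = float(energy_tables[spec.label]["median"].iloc[0])
        rows.append(row)
    return ScanReport(table=pd.DataFrame(rows))
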