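"""Protein-DNA contact classification and occupancy tracking.

Contacts are classified geometrically on each snapshot:

* hydrogen bond — protein/DNA N or O heavy atoms within 3.5 A; when
  hydrogens are present on either partner, a donor H must give a
  D-H...A angle >= 120 degrees (distance-only fallback otherwise);
* hydrophobic — protein/DNA carbon atoms within 4.5 A.

Each contact is tagged by the DNA moiety it touches: *base* (ring +
exocyclic atoms, a "specific" readout contact) versus *sugar* or
*phosphate* (backbone, "nonspecific").  Cutoffs are package conventions,
overridable through :class:`ContactCriteria`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import biotite.structure as struc

__all__ = [
    "ContactCriteria",
    "ContactRecord",
    "OccupancyTable",
    "classify_contacts",
    "occupancy",
    "MOIETY_OF_ATOM",
]

_DNA_RES = {"DA", "DC", "DG", "DT", "A", "C", "G", "T", "DA5", "DC5", "DG5", "DT5",
            "DA3", "DC3", "DG3", "DT3"}

_SUGAR_ATOMS = {"C1'", "C2'", "C3'", "C4'", "C5'", "O4'", "O2'"}
_PHOSPHATE_ATOMS = {"P", "OP1", "OP2", "O1P", "O2P", "O3'", "O5'"}


def MOIETY_OF_ATOM(atom_name: str) -> str:
    """Fixed atom-name partition: base / sugar / phosphate."""
    if atom_name in _PHOSPHATE_ATOMS:
        return "phosphate"
    if atom_name in _SUGAR_ATOMS:
        return "sugar"
    return "base"


@dataclass(frozen=True)
class ContactCriteria:
    """Geometric contact cutoffs (package defaults, overridable)."""

    hbond_distance: float = 3.5       # A, donor-acceptor heavy atoms
    hbond_angle: float = 120.0        # deg, D-H...A, when hydrogens exist
    hydrophobic_distance: float = 4.5  # A, carbon-carbon
    hydrogen_bond_length: float = 1.25  # A, H considered bonded to a heavy atom


@dataclass(frozen=True)
class ContactRecord:
    """One classified protein-DNA atomic contact."""

    protein_chain: str
    protein_res_id: int
    protein_res_name: str
    protein_atom: str
    dna_chain: str
    dna_res_id: int
    dna_base: str
    dna_atom: str
    moiety: str
    contact_type: str
    distance: float
    angle: float | None = None

    def __post_init__(self) -> None:
        if self.distance <= 0:
            raise ValueError("contact distance must be positive")
        if self.moiety not in ("base", "sugar", "phosphate"):
            raise ValueError(f"bad moiety {self.moiety!r}")

    @property
    def specific(self) -> bool:
        return self.moiety == "base"

    @property
    def key(self) -> tuple:
        """Residue-residue-moiety aggregation key."""
        return (
            self.protein_chain,
            self.protein_res_id,
            self.protein_res_name,
            self.dna_chain,
            self.dna_res_id,
            self.dna_base,
            self.moiety,
        )


@dataclass
class OccupancyTable:
    """Per-contact-key occupancy fractions over a trajectory."""

    table: pd.DataFrame
    n_frames: int

    def __post_init__(self) -> None:
        occ = self.table["occupancy"].to_numpy()
        if np.any((occ < 0) | (occ > 1)):
            raise ValueError("occupancies must lie in [0, 1]")


def _is_dna(res_name: str) -> bool:
    return res_name in _DNA_RES


def _split(model: struc.AtomArray):
    res_names = model.res_name
    dna_mask = np.isin(res_names, list(_DNA_RES))
    protein_mask = struc.filter_amino_acids(model)
    if not np.any(dna_mask):
        raise ValueError("no DNA chain detected in the structure")
    if not np.any(protein_mask):
        raise ValueError("no protein chain detected in the structure")
    return model[protein_mask], model[dna_mask]


def _angles_ok(donor_xyz, acceptor_xyz, hydrogens, min_angle) -> tuple[bool, float | None]:
    """Check D-H...A angles over candidate hydrogens bonded to the donor."""
    best = None
    for h in hydrogens:
        v1 = donor_xyz - h
        v2 = acceptor_xyz - h
        cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        ang = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
        if best is None or ang > best:
            best = ang
    if best is None:
        return True, None  # no hydrogens: distance-only fallback
    return best >= min_angle, best


def classify_contacts(
    model: struc.AtomArray, criteria: ContactCriteria = ContactCriteria()
) -> list[ContactRecord]:
    """Classify all protein-DNA contacts in one structure snapshot."""
    protein, dna = _split(model)
    records: list[ContactRecord] = []

    def heavy(sel, elements):
        mask = np.isin(sel.element, elements)
        return sel[mask]

    # hydrogen bonds: N/O vs N/O
    prot_no = heavy(protein, ["N", "O"])
    dna_no = heavy(dna, ["N", "O"])
    prot_h = protein[protein.element == "H"]
    dna_h = dna[dna.element == "H"]
    if len(prot_no) and len(dna_no):
        d = np.linalg.norm(
            prot_no.coord[:, None, :] - dna_no.coord[None, :, :], axis=2
        )
        for ip, id_ in zip(*np.where(d <= criteria.hbond_distance)):
            p_xyz, q_xyz = prot_no.coord[ip], dna_no.coord[id_]
            # hydrogens bonded to either partner may carry the bond
            hs = []
            for pool in (prot_h, dna_h):
                if len(pool):
                    hd = np.linalg.norm(pool.coord - p_xyz, axis=1)
                    hs.extend(pool.coord[hd <= criteria.hydrogen_bond_length])
                    hd = np.linalg.norm(pool.coord - q_xyz, axis=1)
                    hs.extend(pool.coord[hd <= criteria.hydrogen_bond_length])
            ok, ang = _angles_ok(p_xyz, q_xyz, hs, criteria.hbond_angle)
            if not ok:
                continue
            records.append(
                ContactRecord(
                    protein_chain=str(prot_no.chain_id[ip]),
                    protein_res_id=int(prot_no.res_id[ip]),
                    protein_res_name=str(prot_no.res_name[ip]),
                    protein_atom=str(prot_no.atom_name[ip]),
                    dna_chain=str(dna_no.chain_id[id_]),
                    dna_res_id=int(dna_no.res_id[id_]),
                    dna_base=str(dna_no.res_name[id_]),
                    dna_atom=str(dna_no.atom_name[id_]),
                    moiety=MOIETY_OF_ATOM(str(dna_no.atom_name[id_])),
                    contact_type="hbond",
                    distance=float(d[ip, id_]),
                    angle=ang,
                )
            )
    # hydrophobic: C vs C
    prot_c = heavy(protein, ["C"])
    dna_c = heavy(dna, ["C"])
    if len(prot_c) and len(dna_c):
        d = np.linalg.norm(
            prot_c.coord[:, None, :] - dna_c.coord[None, :, :], axis=2
        )
        for ip, id_ in zip(*np.where(d <= criteria.hydrophobic_distance)):
            records.append(
                ContactRecord(
                    protein_chain=str(prot_c.chain_id[ip]),
                    protein_res_id=int(prot_c.res_id[ip]),
                    protein_res_name=str(prot_c.res_name[ip]),
                    protein_atom=str(prot_c.atom_name[ip]),
                    dna_chain=str(dna_c.chain_id[id_]),
                    dna_res_id=int(dna_c.res_id[id_]),
                    dna_base=str(dna_c.res_name[id_]),
                    dna_atom=str(dna_c.atom_name[id_]),
                    moiety=MOIETY_OF_ATOM(str(dna_c.atom_name[id_])),
                    contact_type="hydrophobic",
                    distance=float(d[ip, id_]),
                )
            )
    records.sort(
        key=lambda r: (r.protein_chain, r.protein_res_id, r.protein_atom,
                       r.dna_chain, r.dna_res_id, r.dna_atom, r.contact_type)
    )
    return records


def contacts_to_dataframe(records: list[ContactRecord], frame: int = 1) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "frame": frame,
                "protein_chain": r.protein_chain,
                "protein_res": r.protein_res_id,
                "protein_res_name": r.protein_res_name,
                "protein_atom": r.protein_atom,
                "dna_chain": r.dna_chain,
                "dna_res": r.dna_res_id,
                "dna_base": r.dna_base,
                "dna_atom": r.dna_atom,
                "moiety": r.moiety,
                "type": r.contact_type,
                "distance": r.distance,
            }
            for r in records
        ]
    )


def occupancy(
    trajectory: struc.AtomArrayStack | list[struc.AtomArray],
    criteria: ContactCriteria = ContactCriteria(),
) -> OccupancyTable:
    """Residue-residue-moiety contact occupancies over a trajectory.

    A contact key is occupied in a frame when at least one atomic contact
    with that key is present; occupancy is the occupied-frame fraction.
    """
    if isinstance(trajectory, struc.AtomArrayStack):
        frames = [trajectory[i] for i in range(trajectory.stack_depth())]
    else:
        frames = list(trajectory)
    if not frames:
        raise ValueError("need at least one frame")
    counts: dict[tuple, int] = {}
    for model in frames:
        keys = {r.key for r in classify_contacts(model, criteria)}
        for k in keys:
            counts[k] = counts.get(k, 0) + 1
    rows = []
    for k, c in sorted(counts.items()):
        rows.append(
            {
                "protein_chain": k[0],
                "protein_res": k[1],
                "protein_res_name": k[2],
                "dna_chain": k[3],
                "dna_res": k[4],
                "dna_base": k[5],
                "moiety": k[6],
                "classification": "specific" if k[6] == "base" else "nonspecific",
                "n_frames_present": c,
                "occupancy": c / len(frames),
            }
        )
    return OccupancyTable(table=pd.DataFrame(rows), n_frames=len(frames))
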