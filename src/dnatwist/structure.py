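"""Idealized duplex coordinates from helical parameters, and PDB I/O.

``build_coordinates`` places standard-geometry base heavy atoms (plus C1'
and backbone P) for every frame of a parameter trajectory by chaining
``compose_step``; applying the helix-geometry analysis to the rebuilt
coordinates recovers the input parameters.  Structures are exchanged as
multi-model PDB via biotite (one MODEL per snapshot): Watson strand chain A
numbered 5'->3', Crick strand chain B.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import biotite.structure as struc
import biotite.structure.io.pdb as pdb

from .bases import COMPLEMENT, P_LOCAL_WATSON, RING_ATOMS, standard_base_atoms
from .geometry import (
    BaseFrame,
    IntraBpParams,
    bp_frame_and_params,
    compose_bp,
    fit_base_frame,
    flip_crick,
    frames_from_params,
    step_params,
)

__all__ = [
    "build_coordinates",
    "build_atom_dicts",
    "frames_from_atom_dicts",
    "write_pdb",
    "read_multimodel_pdb",
    "bp_frames_from_structure",
    "parameter_table",
]

_RES_NAME = {"A": "DA", "C": "DC", "G": "DG", "T": "DT"}
_BASE_OF_RES = {v: k for k, v in _RES_NAME.items()}
_BASE_OF_RES.update({k: k for k in "ACGT"})


def _bp_atoms(
    bp_frame: BaseFrame, base_w: str, intra: IntraBpParams | None
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Watson/Crick heavy-atom coordinates of one base pair."""
    if intra is None:
        frame_w = bp_frame
        frame_cf = bp_frame
    else:
        frame_w, frame_cf = compose_bp(bp_frame, intra)
    frame_c = flip_crick(frame_cf)  # undo the Watson-convention flip
    base_c = COMPLEMENT[base_w]
    atoms_w = {
        name: frame_w.transform_points(xyz)
        for name, xyz in standard_base_atoms(base_w).items()
    }
    atoms_c = {
        name: frame_c.transform_points(xyz)
        for name, xyz in standard_base_atoms(base_c).items()
    }
    p_local = np.asarray(P_LOCAL_WATSON)
    # non-bridging phosphate oxygens at ~1.48 A, idealized orientations
    op1_off = np.array([0.55, 1.25, 0.55])
    op2_off = np.array([-1.25, 0.55, -0.55])
    flip = np.array([1.0, -1.0, -1.0])
    atoms_w["P"] = bp_frame.transform_points(p_local)
    atoms_w["OP1"] = bp_frame.transform_points(p_local + op1_off)
    atoms_w["OP2"] = bp_frame.transform_points(p_local + op2_off)
    atoms_c["P"] = bp_frame.transform_points(p_local * flip)
    atoms_c["OP1"] = bp_frame.transform_points((p_local + op1_off) * flip)
    atoms_c["OP2"] = bp_frame.transform_points((p_local + op2_off) * flip)
    return atoms_w, atoms_c


def build_atom_dicts(
    sequence: str,
    step_params_model: np.ndarray,
    intra_params_model: np.ndarray | None = None,
) -> list[tuple[dict[str, np.ndarray], dict[str, np.ndarray]]]:
    """Full-precision heavy-atom coordinates for one model.

    Returns one ``(watson_atoms, crick_atoms)`` pair of name -> float64
    coordinate mappings per base pair.  This is the lossless counterpart of
    :func:`build_coordinates`, whose structure container quantizes
    coordinates to single precision.
    """
    sequence = sequence.upper()
    steps = np.asarray(step_params_model, dtype=float)
    if steps.shape != (max(len(sequence) - 1, 0), 6):
        raise ValueError("expected a (n_bp - 1, 6) step parameter array")
    frames = frames_from_params(steps)
    out = []
    for i, base in enumerate(sequence):
        ip = (
            IntraBpParams.from_array(intra_params_model[i])
            if intra_params_model is not None
            else None
        )
        out.append(_bp_atoms(frames[i], base, ip))
    return out


def frames_from_atom_dicts(
    sequence: str,
    bp_atoms: list[tuple[dict[str, np.ndarray], dict[str, np.ndarray]]],
):
    """Base-pair frames and intra parameters from per-bp atom mappings."""
    frames, intra_list = [], []
    for base, (aw, ac) in zip(sequence.upper(), bp_atoms):
        fw = fit_base_frame(aw, base)
        fc = flip_crick(fit_base_frame(ac, COMPLEMENT[base]))
        bp, intra = bp_frame_and_params(fw, fc)
        frames.append(bp)
        intra_list.append(intra)
    return frames, intra_list


def build_coordinates(
    sequence: str,
    step_params_traj: np.ndarray,
    intra_params_traj: np.ndarray | None = None,
) -> struc.AtomArrayStack:
    """Idealized duplex coordinates for a trajectory of helical parameters.

    Parameters
    ----------
    sequence : Watson-strand sequence over ACGT (n_bp bases).
    step_params_traj : (n_frames, n_bp - 1, 6) inter-bp parameters, or
        (n_bp - 1, 6) for a single model.  A single base pair is the
        degenerate case (0 steps).
    intra_params_traj : optional matching (n_frames, n_bp, 6) intra-bp
        parameters; bases are placed on the bp mid-frame when omitted.
    """
    sequence = sequence.upper()
    n_bp = len(sequence)
    steps = np.asarray(step_params_traj, dtype=float)
    if steps.ndim == 2:
        steps = steps[None]
    if steps.shape[1:] != (max(n_bp - 1, 0), 6):
        raise ValueError(
            f"step parameter array {steps.shape} does not match {n_bp} base pairs"
        )
    intra = None
    if intra_params_traj is not None:
        intra = np.asarray(intra_params_traj, dtype=float)
        if intra.ndim == 2:
            intra = intra[None]
        if intra.shape != (steps.shape[0], n_bp, 6):
            raise ValueError("intra parameter array shape mismatch")

    models = []
    for f in range(steps.shape[0]):
        frames = frames_from_params(steps[f])
        chain_w, chain_c = [], []
        for i, base in enumerate(sequence):
            ip = IntraBpParams.from_array(intra[f, i]) if intra is not None else None
            aw, ac = _bp_atoms(frames[i], base, ip)
            chain_w.append((i + 1, base, aw))
            chain_c.append((i + 1, COMPLEMENT[base], ac))
        atoms = []
        for chain_id, chain in (("A", chain_w), ("B", chain_c[::-1])):
            for res_id, (bp_index, base, coords) in enumerate(chain, start=1):
                for name, xyz in coords.items():
                    a = struc.Atom(
                        xyz,
                        chain_id=chain_id,
                        res_id=res_id,
                        res_name=_RES_NAME[base],
                        atom_name=name,
                        element=name[0],
                        hetero=False,
                    )
                    atoms.append(a)
        models.append(struc.array(atoms))
    return struc.stack(models)


def write_pdb(path, stack: struc.AtomArrayStack) -> None:
    """Write a structure (one MODEL per snapshot) as PDB."""
    f = pdb.PDBFile()
    pdb.set_structure(f, stack)
    f.write(str(path))


def read_multimodel_pdb(path) -> struc.AtomArrayStack:
    """Read a multi-model PDB into an AtomArrayStack."""
    f = pdb.PDBFile.read(str(path))
    structure = pdb.get_structure(f)
    if isinstance(structure, struc.AtomArray):
        structure = struc.stack([structure])
    return structure


def _dna_chains(atoms: struc.AtomArray) -> list[str]:
    chains = []
    for cid in np.unique(atoms.chain_id):
        res_names = set(atoms.res_name[atoms.chain_id == cid])
        if res_names and all(r in _BASE_OF_RES for r in res_names):
            chains.append(str(cid))
    return chains


def bp_frames_from_structure(
    model: struc.AtomArray,
    chain_w: str | None = None,
    chain_c: str | None = None,
):
    """Base-pair frames, intra-bp parameters and phosphate positions.

    Pairs residue i of the Watson chain with residue N+1-i of the Crick
    chain (both numbered 5'->3').  Returns ``(frames, intra_list,
    p_watson, p_crick, sequence)`` with phosphate arrays aligned to bp
    levels (NaN where absent).
    """
    dna = _dna_chains(model)
    if not dna:
        raise ValueError("no DNA chain detected in the structure")
    if chain_w is None or chain_c is None:
        if len(dna) < 2:
            raise ValueError("need two DNA chains to pair a duplex")
        chain_w, chain_c = dna[0], dna[1]

    def residues(cid):
        sel = model[model.chain_id == cid]
        out = []
        for rid in np.unique(sel.res_id):
            res = sel[sel.res_id == rid]
            base = _BASE_OF_RES[str(res.res_name[0])]
            coords = {str(n): c for n, c in zip(res.atom_name, res.coord)}
            out.append((int(rid), base, coords))
        out.sort(key=lambda r: r[0])
        return out

    res_w, res_c = residues(chain_w), residues(chain_c)
    if len(res_w) != len(res_c):
        raise ValueError("Watson and Crick chains have different lengths")
    n = len(res_w)
    frames, intra_list, seq = [], [], []
    p_w = np.full((n, 3), np.nan)
    p_c = np.full((n, 3), np.nan)
    for i in range(n):
        rid_w, base_w, coords_w = res_w[i]
        rid_c, base_c, coords_c = res_c[n - 1 - i]
        if COMPLEMENT[base_w] != base_c:
            raise ValueError(
                f"residues {rid_w}/{rid_c} ({base_w}.{base_c}) are not complementary"
            )
        fw = fit_base_frame(coords_w, base_w)
        fc = flip_crick(fit_base_frame(coords_c, base_c))
        bp, intra = bp_frame_and_params(fw, fc)
        frames.append(bp)
        intra_list.append(intra)
        seq.append(base_w)
        if "P" in coords_w:
            p_w[i] = coords_w["P"]
        if "P" in coords_c:
            p_c[i] = coords_c["P"]
    return frames, intra_list, p_w, p_c, "".join(seq)


def parameter_table(stack: struc.AtomArrayStack) -> pd.DataFrame:
    """Long-format per-frame helical parameter table from a structure.

    Columns: model (1-based), kind (step/bp), index (1-based), parameter,
    value.  Step i joins bp i and i+1.
    """
    rows = []
    for m in range(stack.stack_depth()):
        frames, intra_list, _, _, _ = bp_frames_from_structure(stack[m])
        for i, intra in enumerate(intra_list, start=1):
            for name, value in zip(
                ("shear", "stretch", "stagger", "buckle", "propeller", "opening"),
                intra.to_array(),
            ):
                rows.append((m + 1, "bp", i, name, float(value)))
        for i in range(len(frames) - 1):
            sp = step_params(frames[i], frames[i + 1])
            for name, value in zip(
                ("shift", "slide", "rise", "tilt", "roll", "twist"), sp.to_array()
            ):
                rows.append((m + 1, "step", i + 1, name, float(value)))
    return pd.DataFrame(rows, columns=["model", "kind", "index", "parameter", "value"])
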