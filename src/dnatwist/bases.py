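"""Idealized base geometries in the standard base-pair reference frame.

Each base is stored as planar heavy-atom coordinates (Angstrom) expressed in
the standard reference frame: the origin sits near the helix axis, +x points
toward the major groove, +y toward the Watson-strand backbone and +z along
the 5'->3' helix direction of the Watson strand.  A Watson.Crick pair is
formed by flipping the Crick base 180 degrees about the frame x-axis.

These coordinates are package data used both to fit observed bases (Kabsch
superposition) and to rebuild idealized coordinates from helical parameters.
"""

from __future__ import annotations

import numpy as np

# Planar heavy-atom coordinates (x, y, z) in the standard reference frame.
STANDARD_BASE_COORDS: dict[str, dict[str, tuple[float, float, float]]] = {
    "A": {
        "C1'": (-2.479, 5.346, 0.000),
        "N9": (-1.291, 4.498, 0.000),
        "C8": (0.024, 4.897, 0.000),
        "N7": (0.877, 3.902, 0.000),
        "C5": (0.071, 2.771, 0.000),
        "C6": (0.369, 1.398, 0.000),
        "N6": (1.611, 0.909, 0.000),
        "N1": (-0.668, 0.532, 0.000),
        "C2": (-1.912, 1.023, 0.000),
        "N3": (-2.320, 2.290, 0.000),
        "C4": (-1.267, 3.124, 0.000),
    },
    "G": {
        "C1'": (-2.477, 5.399, 0.000),
        "N9": (-1.289, 4.551, 0.000),
        "C8": (0.023, 4.962, 0.000),
        "N7": (0.870, 3.969, 0.000),
        "C5": (0.071, 2.833, 0.000),
        "C6": (0.424, 1.460, 0.000),
        "O6": (1.554, 0.955, 0.000),
        "N1": (-0.700, 0.641, 0.000),
        "C2": (-1.999, 1.087, 0.000),
        "N2": (-2.949, 0.139, -0.001),
        "N3": (-2.342, 2.364, 0.001),
        "C4": (-1.265, 3.177, 0.000),
    },
    "C": {
        "C1'": (-2.477, 5.402, 0.000),
        "N1": (-1.285, 4.542, 0.000),
        "C2": (-1.472, 3.158, 0.000),
        "O2": (-2.628, 2.709, 0.001),
        "N3": (-0.391, 2.344, 0.000),
        "C4": (0.837, 2.868, 0.000),
        "N4": (1.875, 2.027, 0.001),
        "C5": (1.056, 4.275, 0.000),
        "C6": (-0.023, 5.068, 0.000),
    },
    "T": {
        "C1'": (-2.481, 5.354, 0.000),
        "N1": (-1.284, 4.500, 0.000),
        "C2": (-1.462, 3.135, 0.000),
        "O2": (-2.562, 2.608, 0.000),
        "N3": (-0.298, 2.407, 0.000),
        "C4": (0.994, 2.897, 0.000),
        "O4": (1.944, 2.119, 0.000),
        "C5": (1.106, 4.338, 0.000),
        "C7": (2.466, 4.961, 0.001),
        "C6": (-0.024, 5.057, 0.000),
    },
}

#: Ring heavy atoms used for the reference-frame fit.
RING_ATOMS: dict[str, tuple[str, ...]] = {
    "A": ("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"),
    "G": ("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"),
    "C": ("N1", "C2", "N3", "C4", "C5", "C6"),
    "T": ("N1", "C2", "N3", "C4", "C5", "C6"),
}

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

COMPLEMENT: dict[str, str] = {"A": "T", "T": "A", "G": "C", "C": "G"}

#: Canonical Watson-Crick heavy-atom hydrogen-bond pairs, keyed by the
#: purine of the pair; tuples are (purine atom, pyrimidine atom).
WC_HBOND_PAIRS: dict[str, tuple[tuple[str, str], ...]] = {
    "G": (("O6", "N4"), ("N1", "N3"), ("N2", "O2")),  # G.C: three bonds
    "A": (("N6", "O4"), ("N1", "N3")),  # A.T: two bonds
}

#: Backbone phosphorus position in the base-pair reference frame (Watson
#: strand), Angstrom.  A fibre-like caricature: fixed per level, chosen so
#: that a straight fibre at twist 36 deg / rise 3.38 A reproduces canonical
#: B-form groove dimensions (minor ~5.9 A, major ~11.5 A after the 5.8 A
#: backbone-radius correction).  The Crick-strand position follows by the
#: 180-degree flip about x: (x, -y, -z).
P_LOCAL_WATSON: tuple[float, float, float] = (-5.33, 7.62, 1.60)

#: Backbone radius correction subtracted from raw P-P distances, Angstrom.
GROOVE_P_RADIUS_CORRECTION: float = 5.8


def standard_base_atoms(base: str) -> dict[str, np.ndarray]:
    """Heavy-atom coordinates of an idealized base in its standard frame."""
    try:
        coords = STANDARD_BASE_COORDS[base.upper()]
    except KeyError:
        raise ValueError(f"unknown base type {base!r}; expected one of A,C,G,T") from None
    return {name: np.asarray(xyz, dtype=float) for name, xyz in coords.items()}
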