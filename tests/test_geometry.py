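"""Frames, helical parameters, bending, grooves and WC hydrogen bonds."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.spatial.transform import Rotation

from dnatwist.bases import P_LOCAL_WATSON, RING_ATOMS, standard_base_atoms
from dnatwist.geometry import (
    BaseFrame,
    IntraBpParams,
    StepParams,
    axis_bending,
    bp_frame_and_params,
    compose_bp,
    compose_step,
    end_to_end_twist,
    fit_base_frame,
    flip_crick,
    frames_from_params,
    groove_geometry,
    rotation_about_axis,
    step_params,
    wc_hbond_check,
)

from conftest import random_rotation


# --------------------------------------------------------------------------
# base-frame fitting
# --------------------------------------------------------------------------

@pytest.mark.parametrize("base", list("ACGT"))
def test_fit_base_frame_identity(base):
    frame = fit_base_frame(standard_base_atoms(base), base)
    assert np.allclose(frame.origin, 0.0, atol=1e-8)
    assert np.allclose(frame.axes, np.eye(3), atol=1e-8)


@pytest.mark.parametrize("base", list("ACGT"))
def test_fit_base_frame_equivariance(base, rng):
    R = random_rotation(rng)
    t = rng.normal(size=3) * 10
    atoms = {k: R @ v + t for k, v in standard_base_atoms(base).items()}
    frame = fit_base_frame(atoms, base)
    assert np.allclose(frame.origin, t, atol=1e-8)
    assert np.allclose(frame.axes, R, atol=1e-8)


def test_fit_base_frame_noise_matches_kabsch_oracle(rng):
    """With coordinate noise the fit must agree with an independent
    Kabsch superposition (scipy align_vectors) of the same atoms."""
    base = "G"
    R = random_rotation(rng)
    t = np.array([1.0, -2.0, 3.0])
    ring = RING_ATOMS[base]
    std = standard_base_atoms(base)
    atoms = {k: R @ v + t + rng.normal(0, 0.1, 3) for k, v in std.items()}
    frame = fit_base_frame(atoms, base)

    # oracle: scipy Rotation.align_vectors on centred ring coordinates
    P = np.array([std[a] for a in ring])
    Q = np.array([atoms[a] for a in ring])
    rot, _ = Rotation.align_vectors(Q - Q.mean(0), P - P.mean(0))
    R_oracle = rot.as_matrix()
    t_oracle = Q.mean(0) - R_oracle @ P.mean(0)
    assert np.allclose(frame.axes, R_oracle, atol=1e-6)
    assert np.allclose(frame.origin, t_oracle, atol=1e-6)
    # noise must not have thrown the frame far from the noise-free one
    assert np.abs(frame.axes - R).max() < 0.1
    assert np.abs(frame.origin - t).max() < 0.2


def test_fit_base_frame_missing_atom_is_named():
    atoms = standard_base_atoms("A")
    del atoms["N7"]
    with pytest.raises(ValueError, match="N7"):
        fit_base_frame(atoms, "A")


def test_fit_base_frame_unknown_base():
    with pytest.raises(ValueError, match="unknown base"):
        fit_base_frame(standard_base_atoms("A"), "X")


# --------------------------------------------------------------------------
# step parameters and their exact inverse
# --------------------------------------------------------------------------

def test_step_params_ideal_bdna():
    f0 = BaseFrame.identity()
    f1 = compose_step(f0, StepParams(0, 0, 3.38, 0, 0, 36.0))
    p = step_params(f0, f1)
    assert np.allclose(p.to_array(), [0, 0, 3.38, 0, 0, 36.0], atol=1e-8)


def test_step_params_identity():
    f = BaseFrame(np.array([1.0, 2, 3]), rotation_about_axis([1, 1, 0], 30))
    assert np.allclose(step_params(f, f).to_array(), 0.0, atol=1e-10)


@given(
    data=st.tuples(
        st.floats(-10, 10), st.floats(-10, 10), st.floats(-10, 10),
        st.floats(-59, 59), st.floats(-59, 59), st.floats(-59, 59),
    ),
    seed=st.integers(0, 2**31 - 1),
)
def test_step_roundtrip_property(data, seed):
    """compose_step is the exact inverse of step_params for any start frame
    and |angles| < 60 deg, |translations| < 10 A."""
    rng = np.random.default_rng(seed)
    frame = BaseFrame(rng.normal(size=3) * 5, random_rotation(rng))
    params = np.array(data)
    back = step_params(frame, compose_step(frame, params)).to_array()
    assert np.allclose(back, params, atol=1e-8)


def test_compose_step_zero_params_is_identity():
    f = BaseFrame(np.array([0.5, -1, 2.0]), rotation_about_axis([0, 1, 0], 17))
    g = compose_step(f, StepParams(0, 0, 0, 0, 0, 0))
    assert np.allclose(g.origin, f.origin)
    assert np.allclose(g.axes, f.axes)


def test_compose_thirteen_ideal_steps_total_twist():
    params = np.tile([0, 0, 3.4, 0, 0, 34.6], (13, 1))
    frames = frames_from_params(params)
    assert end_to_end_twist(frames) == pytest.approx(449.8, abs=1e-8)


# --------------------------------------------------------------------------
# intra-bp parameters
# --------------------------------------------------------------------------

def test_bp_coincident_frames_zero_params():
    f = BaseFrame(np.array([1.0, 0, 0]), rotation_about_axis([0, 0, 1], 25))
    mid, intra = bp_frame_and_params(f, f)
    assert np.allclose(intra.to_array(), 0.0, atol=1e-10)
    assert np.allclose(mid.axes, f.axes)


def test_pure_buckle_rotation():
    """A 10-degree relative rotation about the mid-frame x-axis is pure
    buckle."""
    mid = BaseFrame.identity()
    w, c = compose_bp(mid, IntraBpParams(0, 0, 0, 10.0, 0, 0))
    mid2, intra = bp_frame_and_params(w, c)
    assert intra.buckle == pytest.approx(10.0, abs=1e-8)
    assert np.allclose(
        [intra.shear, intra.stretch, intra.stagger, intra.propeller, intra.opening],
        0.0, atol=1e-8,
    )
    assert np.allclose(mid2.axes, mid.axes, atol=1e-10)


@given(
    vals=st.tuples(
        st.floats(-1, 1), st.floats(-1, 1), st.floats(-1, 1),
        st.floats(-25, 25), st.floats(-25, 25), st.floats(-25, 25),
    ),
    seed=st.integers(0, 2**31 - 1),
)
def test_intra_roundtrip_property(vals, seed):
    rng = np.random.default_rng(seed)
    mid = BaseFrame(rng.normal(size=3), random_rotation(rng))
    params = IntraBpParams(*vals)
    w, c = compose_bp(mid, params)
    mid2, back = bp_frame_and_params(w, c)
    assert np.allclose(back.to_array(), params.to_array(), atol=1e-8)
    assert np.allclose(mid2.origin, mid.origin, atol=1e-8)


def test_bp_frame_rejects_non_orthonormal():
    bad = BaseFrame(np.zeros(3), np.eye(3) + 0.05)
    with pytest.raises(ValueError, match="orthonormal"):
        bp_frame_and_params(bad, BaseFrame.identity())


# --------------------------------------------------------------------------
# end-to-end twist
# --------------------------------------------------------------------------

def test_end_to_end_twist_single_step_region():
    params = np.tile([0, 0, 3.38, 0, 0, 34.0], (5, 1))
    params[2, 5] = 40.0
    frames = frames_from_params(params)
    assert end_to_end_twist(frames, (3, 3)) == pytest.approx(40.0, abs=1e-8)


def test_end_to_end_twist_additive_over_subregions(rng):
    params = np.column_stack(
        [
            rng.normal(0, 0.4, 12), rng.normal(0, 0.4, 12), rng.normal(3.4, 0.3, 12),
            rng.normal(0, 3, 12), rng.normal(0, 4, 12), rng.normal(34, 3, 12),
        ]
    )
    frames = frames_from_params(params)
    total = end_to_end_twist(frames, (1, 12))
    split = end_to_end_twist(frames, (1, 5)) + end_to_end_twist(frames, (6, 12))
    assert total == pytest.approx(split, abs=1e-10)


def test_end_to_end_twist_empty_region_errors():
    frames = frames_from_params(np.tile([0, 0, 3.4, 0, 0, 34.0], (3, 1)))
    with pytest.raises(ValueError):
        end_to_end_twist(frames, (3, 2))
    with pytest.raises(ValueError):
        end_to_end_twist([frames[0]])


# --------------------------------------------------------------------------
# axis bending
# --------------------------------------------------------------------------

def test_axis_bending_straight_helix_is_zero():
    params = np.tile([0, 0, 3.38, 0, 0, 36.0], (10, 1))
    bend = axis_bending(frames_from_params(params))
    assert np.allclose(bend.angles, 0.0, atol=1e-8)


def test_axis_bending_single_roll_step():
    f0 = BaseFrame.identity()
    f1 = compose_step(f0, StepParams(0, 0, 3.38, 0, 5.0, 0))
    bend = axis_bending([f0, f1])
    assert bend.angles[0] == pytest.approx(5.0, abs=1e-6)


def test_axis_bending_matches_rotation_matrix_oracle(rng):
    """Random rolls/tilts: bend equals the angle computed by explicit
    rotation-matrix composition (scipy Rotation)."""
    params = np.column_stack(
        [
            np.zeros(8), np.zeros(8), np.full(8, 3.38),
            rng.normal(0, 4, 8), rng.normal(0, 6, 8), rng.normal(34, 4, 8),
        ]
    )
    frames = frames_from_params(params)
    bend = axis_bending(frames)
    for i in range(8):
        R_rel = Rotation.from_matrix(frames[i].axes.T @ frames[i + 1].axes)
        z2_in_1 = R_rel.as_matrix()[:, 2]
        oracle = np.degrees(np.arccos(np.clip(z2_in_1[2], -1, 1)))
        assert bend.angles[i] == pytest.approx(oracle, abs=1e-9)


def test_axis_bending_rigid_rotation_invariant(rng):
    params = np.column_stack(
        [
            np.zeros(6), np.zeros(6), np.full(6, 3.38),
            rng.normal(0, 3, 6), rng.normal(0, 5, 6), rng.normal(34, 3, 6),
        ]
    )
    frames = frames_from_params(params)
    R = random_rotation(rng)
    t = rng.normal(size=3) * 20
    moved = [BaseFrame(R @ f.origin + t, R @ f.axes) for f in frames]
    assert np.allclose(
        axis_bending(frames).angles, axis_bending(moved).angles, atol=1e-10
    )


# --------------------------------------------------------------------------
# groove geometry
# --------------------------------------------------------------------------

def _fibre(twist, n=20, rise=3.38):
    params = np.tile([0, 0, rise, 0, 0, twist], (n - 1, 1))
    frames = frames_from_params(params)
    p_local = np.asarray(P_LOCAL_WATSON)
    p_w = np.array([f.transform_points(p_local) for f in frames])
    p_c = np.array(
        [f.transform_points(p_local * np.array([1, -1, -1])) for f in frames]
    )
    return frames, p_w, p_c


def _brute_force_widths(p_w, p_c, frames, level, n_interp=400):
    """Independent oracle: dense sampling of every cross-strand backbone
    segment, classified minor/major by the bp-frame x-axis side."""
    origin, x_axis = frames[level].origin, frames[level].x
    best = {"minor": np.inf, "major": np.inf}
    for point, other in ((p_w[level], p_c), (p_c[level], p_w)):
        for a, b in zip(other[:-1], other[1:]):
            ts = np.linspace(0, 1, n_interp)
            pts = a[None] + ts[:, None] * (b - a)[None]
            d = np.linalg.norm(pts - point, axis=1)
            side = (0.5 * (pts + point) - origin) @ x_axis
            for key, mask in (("minor", side < 0), ("major", side >= 0)):
                if np.any(mask):
                    best[key] = min(best[key], float(d[mask].min()))
    return best["minor"] - 5.8, best["major"] - 5.8


def test_groove_widths_match_brute_force_scan():
    frames, p_w, p_c = _fibre(36.0)
    prof = groove_geometry(p_w, p_c, frames)
    for level in (8, 9, 10):
        minor, major = _brute_force_widths(p_w, p_c, frames, level)
        assert prof.minor_width[level] == pytest.approx(minor, abs=0.01)
        assert prof.major_width[level] == pytest.approx(major, abs=0.01)


def test_groove_widths_increase_with_radial_expansion():
    frames, p_w, p_c = _fibre(36.0)

    def expand(ps):
        out = ps.copy()
        radial = ps[:, :2]
        out[:, :2] = radial * (1 + 1.0 / np.linalg.norm(radial, axis=1))[:, None]
        return out

    base = groove_geometry(p_w, p_c, frames)
    wide = groove_geometry(expand(p_w), expand(p_c), frames)
    sel = base.defined & wide.defined
    assert np.all(wide.minor_width[sel] > base.minor_width[sel])
    assert np.all(wide.major_width[sel] > base.major_width[sel])


def test_undertwisting_widens_major_groove():
    relaxed = groove_geometry(*(_fibre(36.0)[1:]), _fibre(36.0)[0])
    under = groove_geometry(*(_fibre(31.0)[1:]), _fibre(31.0)[0])
    interior = slice(6, 14)
    assert np.all(
        under.major_width[interior] > relaxed.major_width[interior]
    )


def test_groove_missing_phosphates_flagged_not_fatal():
    frames, p_w, p_c = _fibre(36.0, n=12)
    p_w[4:8] = np.nan
    prof = groove_geometry(p_w, p_c, frames)
    assert prof.defined.dtype == bool
    assert np.isnan(prof.minor_width[0]) and not prof.defined[0]  # terminal level
    assert np.any(prof.defined)


# --------------------------------------------------------------------------
# Watson-Crick hydrogen bonds
# --------------------------------------------------------------------------

def _ideal_pair(base_w):
    from dnatwist.structure import build_atom_dicts

    atoms = build_atom_dicts(base_w, np.zeros((0, 6)))
    return atoms[0]


def test_wc_hbonds_ideal_gc_pair():
    aw, ac = _ideal_pair("G")
    max_d, melted, dists = wc_hbond_check(aw, ac, "GC")
    assert len(dists) == 3
    assert max_d < 4.0
    assert not melted


def test_wc_hbonds_opened_pair_is_melted():
    aw, ac = _ideal_pair("A")
    shifted = {k: v - np.array([0, 5.0, 0]) for k, v in ac.items()}  # pull apart
    _, melted, _ = wc_hbond_check(aw, shifted, "AT")
    assert melted


def test_wc_hbond_exact_threshold_counts_as_melted():
    # synthetic two-point geometry: purine/pyrimidine atoms exactly 4.0 A apart
    aw = {"O6": np.zeros(3), "N1": np.zeros(3), "N2": np.zeros(3)}
    ac = {"N4": np.array([4.0, 0, 0]), "N3": np.array([1.0, 0, 0]),
          "O2": np.array([2.0, 0, 0])}
    max_d, melted, _ = wc_hbond_check(aw, ac, "GC")
    assert max_d == pytest.approx(4.0)
    assert melted


def test_wc_hbond_unknown_pair_type():
    with pytest.raises(ValueError, match="unknown base pair"):
        wc_hbond_check({}, {}, "XZ")
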