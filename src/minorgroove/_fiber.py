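"""Idealized fiber-model duplex construction.

A duplex is generated by placing an idealized nucleotide (standard
reference-frame base + pseudorotation-parametrized deoxyribose + backbone from
ideal bond geometry) into every base-pair level of a uniform helix
(twist/rise), with the strand-2 partner obtained by the Watson-Crick dyad
(180 degree rotation about the pair x axis).

The per-form conformational constants in :data:`FORM_PARAMS` (glycosidic
torsion, backbone torsions, base-pair inclination and x-displacement, sugar
pucker) were fixed once by a least-squares calibration that closes the
O3'(i)-P(i+1) backbone linkage under the helical symmetry and reproduces the
canonical minor-groove width of each form (18.5 Å for ideal A-DNA, ~11.7 Å
direct P-P for B-DNA); they are packaged constants, not tunables.
"""

from __future__ import annotations

import numpy as np

from ._geometry import (
    dihedral,
    place_atom,
    rigid_transform,
    rotation_about_axis,
    rotation_between,
)
from ._tables import COMPLEMENT, GLYCOSIDIC_ATOMS, ONE_LETTER, STANDARD_BASE_COORDS

SUGAR_RING_ORDER = ("O4'", "C1'", "C2'", "C3'", "C4'")

# mean endocyclic bond length of deoxyribose, Å
_RING_BOND = 1.46

# ideal bond geometry for the exocyclic backbone, Å / degrees
_BOND_C3_O3 = 1.423
_BOND_C4_C5 = 1.510
_BOND_C5_O5 = 1.440
_BOND_O5_P = 1.593
_BOND_P_OP = 1.485
_ANGLE_O5_C5_C4 = 110.2
_ANGLE_P_O5_C5 = 120.9
_ANGLE_OP_P_O5 = 108.1


def build_sugar_ring(phase_construct: float, q: float, mirror: bool) -> dict[str, np.ndarray]:
    """Closed five-ring with out-of-plane displacements from a pucker phase.

    ``phase_construct`` is the construction phase of the z-displacement wave
    (degrees); it maps monotonically onto the pseudorotation phase and is
    calibrated per form.  ``q`` is the puckering amplitude in Å.
    """
    k = np.arange(5)
    z = q * np.sqrt(2.0 / 5.0) * np.cos(np.radians(phase_construct) + 4.0 * np.pi * k / 5.0)
    dz2 = np.mean(np.diff(np.concatenate([z, z[:1]])) ** 2)
    chord = np.sqrt(max(_RING_BOND**2 - dz2, 0.5))
    radius = chord / (2.0 * np.sin(np.pi / 5.0))
    theta = 2.0 * np.pi * k / 5.0
    y_sign = -1.0 if mirror else 1.0
    return {
        name: np.array([radius * np.cos(t), y_sign * radius * np.sin(t), zz])
        for name, t, zz in zip(SUGAR_RING_ORDER, theta, z)
    }


def _ring_substituent(center, nb1, nb2, bond: float, sign: float) -> np.ndarray:
    """Heavy substituent on a ring atom, tetrahedral to the two ring bonds."""
    u1 = (nb1 - center) / np.linalg.norm(nb1 - center)
    u2 = (nb2 - center) / np.linalg.norm(nb2 - center)
    bisector = -(u1 + u2)
    bisector /= np.linalg.norm(bisector)
    normal = np.cross(u1, u2)
    normal /= np.linalg.norm(normal)
    half = np.radians(54.75)
    d = bisector * np.cos(half) + sign * normal * np.sin(half)
    return center + bond * d / np.linalg.norm(d)


def build_nucleotide(base: str, params: dict) -> dict[str, np.ndarray]:
    """All heavy atoms of one nucleotide in the standard base-pair frame."""
    coords = {name: xyz.copy() for name, xyz in STANDARD_BASE_COORDS[base].items()}
    n_name, chi_ref = GLYCOSIDIC_ATOMS[base]
    c1_target = coords["C1'"]
    n_pos = coords[n_name]

    ring = build_sugar_ring(params["pucker_phase_construct"], params["pucker_q"], params["ring_mirror"])
    # glycosidic direction in ring-local coordinates
    n_dir_local = _ring_substituent(
        ring["C1'"], ring["O4'"], ring["C2'"], 1.0, params["sign_n"]
    ) - ring["C1'"]
    rot = rotation_between(n_dir_local, n_pos - c1_target)
    local = {name: rot @ (xyz - ring["C1'"]) + c1_target for name, xyz in ring.items()}

    # set the glycosidic torsion chi = O4'-C1'-N-(C4|C2)
    axis = n_pos - c1_target
    t0 = dihedral(local["O4'"], c1_target, n_pos, coords[chi_ref])
    for delta in (params["chi"] - t0, -(params["chi"] - t0)):
        rmat = rotation_about_axis(axis, delta)
        trial = {name: rmat @ (xyz - c1_target) + c1_target for name, xyz in local.items()}
        if abs(_ang_diff(dihedral(trial["O4'"], c1_target, n_pos, coords[chi_ref]), params["chi"])) < 1e-6:
            local = trial
            break
    else:  # pragma: no cover - defensive
        raise RuntimeError("could not set glycosidic torsion")
    coords.update({name: xyz for name, xyz in local.items() if name != "C1'"})

    coords["O3'"] = _ring_substituent(coords["C3'"], coords["C2'"], coords["C4'"], _BOND_C3_O3, params["sign_o3"])
    coords["C5'"] = _ring_substituent(coords["C4'"], coords["C3'"], coords["O4'"], _BOND_C4_C5, params["sign_c5"])
    coords["O5'"] = place_atom(coords["C3'"], coords["C4'"], coords["C5'"], _BOND_C5_O5, _ANGLE_O5_C5_C4, params["gamma"])
    coords["P"] = place_atom(coords["C4'"], coords["C5'"], coords["O5'"], _BOND_O5_P, _ANGLE_P_O5_C5, params["beta"])
    coords["OP1"] = place_atom(coords["C5'"], coords["O5'"], coords["P"], _BOND_P_OP, _ANGLE_OP_P_O5, params["alpha"] + 120.0)
    coords["OP2"] = place_atom(coords["C5'"], coords["O5'"], coords["P"], _BOND_P_OP, _ANGLE_OP_P_O5, params["alpha"] - 120.0)
    return coords


def _ang_diff(a: float, b: float) -> float:
    return (a - b + 180.0) % 360.0 - 180.0


_FLIP_X = np.diag([1.0, -1.0, -1.0])


def pair_level_transform(level: int, params: dict) -> tuple[np.ndarray, np.ndarray]:
    """Rotation/translation placing pair-local coordinates at a helix level."""
    # inclination tilts the pair long axis; rotating about the pair x axis
    # (the pseudo-dyad) keeps the two strands dyad-related
    incl = rotation_about_axis([1.0, 0.0, 0.0], params["incl"])
    helical = rotation_about_axis([0.0, 0.0, 1.0], level * params["twist"])
    rotation = helical @ incl
    translation = helical @ np.array([params["xdisp"], 0.0, 0.0]) + np.array(
        [0.0, 0.0, level * params["rise"]]
    )
    return rotation, translation


def build_fiber_coordinates(sequence: str, params: dict) -> tuple[list[dict], list[dict]]:
    """Atom dictionaries for both strands of a uniform duplex.

    Returns (strand1, strand2); each is a list indexed by base-pair level
    (strand 1 runs 5'->3' with increasing level, strand 2 antiparallel).
    """
    sequence = sequence.upper()
    if any(b not in "ACGT" for b in sequence):
        bad = sorted(set(sequence) - set("ACGT"))
        raise ValueError(f"invalid sequence characters: {bad}")
    unit_cache: dict[str, dict[str, np.ndarray]] = {}
    strand1: list[dict] = []
    strand2: list[dict] = []
    for level, letter in enumerate(sequence):
        base1 = "d" + letter
        base2 = "d" + COMPLEMENT[letter]
        for b in (base1, base2):
            if b not in unit_cache:
                unit_cache[b] = build_nucleotide(b, params)
        rot, trans = pair_level_transform(level, params)
        strand1.append({n: rot @ xyz + trans for n, xyz in unit_cache[base1].items()})
        strand2.append({n: rot @ (_FLIP_X @ xyz) + trans for n, xyz in unit_cache[base2].items()})
    return strand1, strand2


def sequence_of_strand2(sequence: str) -> str:
    """Strand-2 sequence in its own 5'->3' order."""
    return "".join(COMPLEMENT[b] for b in sequence.upper())[::-1]


def base_name(letter: str) -> str:
    return "d" + letter.upper()


def strand1_letter(name: str) -> str:
    return ONE_LETTER[name]


# ---------------------------------------------------------------------------
# frozen per-form conformational constants (see module docstring)
# ---------------------------------------------------------------------------

FORM_PARAMS: dict[str, dict] = {
    "A": {
        "twist": 32.7,
        "rise": 2.56,
        "xdisp": -3.2844415976651593,
        "incl": 27.57624390155997,
        "chi": -157.0,
        "gamma": 47.0,
        "beta": 172.91361957629988,
        "alpha": -70.0,
        "pucker_phase_construct": 107.99999908713689,  # C3'-endo (P = 18 deg)
        "pucker_q": 0.38,
        "ring_mirror": False,
        "sign_n": 1.0,
        "sign_o3": -1.0,
        "sign_c5": 1.0,
    },
    "B": {
        "twist": 36.0,
        "rise": 3.38,
        "xdisp": -0.04804078360954508,
        "incl": -1.901841932222642,
        "chi": -102.0,
        "gamma": 36.0,
        "beta": 102.03897480481011,
        "alpha": -47.0,
        "pucker_phase_construct": 251.9999959776309,  # C2'-endo (P = 162 deg)
        "pucker_q": 0.38,
        "ring_mirror": False,
        "sign_n": 1.0,
        "sign_o3": -1.0,
        "sign_c5": 1.0,
    },
}
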