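"""Backbone dihedrals, secondary-structure regions, protein-DNA interaction
modes (hydrogen bonds / van der Waals contacts) and Kabsch superposition.

Secondary structure is assigned from phi/psi regions (with a Cα-curvature
rule for turn/bend), not from hydrogen-bond energies; an importer for
externally produced DSSP output is provided for users who want the original
labels.  Hydrogen bonds use heavy-atom geometric criteria: donor-acceptor
distance ≤ 3.5 Å and antecedent-donor-acceptor angle ≥ 90°; van der Waals
contacts are non-hydrogen-bonded atom pairs within 4.0 Å.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from ._tables import (
    DNA_BASE_ACCEPTORS,
    DNA_BASE_DONORS,
    PROTEIN_BB_ACCEPTOR,
    PROTEIN_BB_DONOR,
    PROTEIN_SC_ACCEPTORS,
    PROTEIN_SC_DONORS,
    STANDARD_DNA,
    dna_target_class,
)
from ._geometry import bond_angle, dihedral
from .helix_model import Duplex
from .structure_io import ChainRecord, ResidueRecord

__all__ = [
    "HBOND_DISTANCE_MAX",
    "HBOND_ANGLE_MIN",
    "VDW_DISTANCE_MAX",
    "BackboneDihedrals",
    "HBond",
    "VdWContact",
    "SuperpositionResult",
    "compute_backbone_dihedrals",
    "assign_secondary_structure",
    "detect_hbonds",
    "classify_vdw_contacts",
    "kabsch_superpose",
    "representative_step",
    "import_dssp",
]

HBOND_DISTANCE_MAX = 3.5  # Å, donor-acceptor heavy atoms
HBOND_ANGLE_MIN = 90.0  # degrees, antecedent-donor-acceptor
VDW_DISTANCE_MAX = 4.0  # Å

SECONDARY_LABELS = (
    "α-helix", "3-10-helix", "β-strand", "polyproline-II",
    "turn", "bend", "others", "unassigned",
)

BEND_ANGLE = 70.0  # degrees of Cα virtual-bond curvature over 5 residues
TURN_ANGLE = 45.0

_BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})


@dataclass
class BackboneDihedrals:
    chain_id: str
    seq_id: str
    residue_type: str
    phi: Optional[float]
    psi: Optional[float]


@dataclass
class HBond:
    donor_residue: tuple[str, str]  # (chain, seq_id)
    donor_atom: str
    acceptor_residue: tuple[str, str]
    acceptor_atom: str
    distance: float
    angle: float
    protein_side: str  # side-chain | backbone
    dna_target: str  # base | deoxyribose | phosphate


@dataclass
class VdWContact:
    protein_residue: tuple[str, str]
    protein_atom: str
    dna_residue: tuple[str, str]
    dna_atom: str
    distance: float
    protein_side: str
    dna_target: str


@dataclass
class SuperpositionResult:
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float


# ---------------------------------------------------------------------------
# dihedrals and secondary structure
# ---------------------------------------------------------------------------


def compute_backbone_dihedrals(chain: ChainRecord) -> list[BackboneDihedrals]:
    """phi/psi for every residue of a protein chain (termini undefined)."""
    out: list[BackboneDihedrals] = []
    residues = chain.residues
    for i, res in enumerate(residues):
        phi = psi = None
        n, ca, c = res.coord("N"), res.coord("CA"), res.coord("C")
        if n is not None and ca is not None and c is not None:
            if i > 0:
                c_prev = residues[i - 1].coord("C")
                if c_prev is not None:
                    phi = dihedral(c_prev, n, ca, c)
            if i < len(residues) - 1:
                n_next = residues[i + 1].coord("N")
                if n_next is not None:
                    psi = dihedral(n, ca, c, n_next)
        out.append(BackboneDihedrals(chain.chain_id, res.seq_id, res.name, phi, psi))
    return out


def _region_label(phi: float, psi: float) -> Optional[str]:
    """phi/psi region membership; None when outside every named region.

    Polyproline-II overlaps the broad β region and takes precedence there
    (the two are distinguished by hydrogen bonding in energy-based
    assignments, which a dihedral-only classifier cannot see).
    """
    if -100 <= phi <= -30 and -80 <= psi <= -5:
        return "α-helix"
    if -90 <= phi <= -40 and -5 < psi <= 30:
        return "3-10-helix"
    if -90 <= phi <= -55 and 120 <= psi <= 180:
        return "polyproline-II"
    if -170 <= phi <= -70 and (90 <= psi <= 180 or -180 <= psi <= -170):
        return "β-strand"
    return None


def assign_secondary_structure(
    dihedrals: Sequence[BackboneDihedrals], chain: Optional[ChainRecord] = None
) -> dict[tuple[str, str], str]:
    """One label per residue from phi/psi regions plus Cα curvature.

    Returns a map (chain_id, seq_id) -> label.  Residues with undefined
    dihedrals are ``unassigned``; residues outside every named region are
    classified turn/bend when the Cα virtual-bond angle over the centered
    5-residue window exceeds :data:`TURN_ANGLE` / :data:`BEND_ANGLE`, and
    ``others`` otherwise.
    """
    curvature: dict[tuple[str, str], float] = {}
    if chain is not None:
        cas = [r.coord("CA") for r in chain.residues]
        for i, res in enumerate(chain.residues):
            if 2 <= i < len(cas) - 2 and all(
                c is not None for c in (cas[i - 2], cas[i], cas[i + 2])
            ):
                v1 = cas[i] - cas[i - 2]
                v2 = cas[i + 2] - cas[i]
                denom = np.linalg.norm(v1) * np.linalg.norm(v2)
                if denom > 1e-9:
                    cosang = float(np.dot(v1, v2) / denom)
                    curvature[(chain.chain_id, res.seq_id)] = float(
                        np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
                    )
    labels: dict[tuple[str, str], str] = {}
    for d in dihedrals:
        key = (d.chain_id, d.seq_id)
        if d.phi is None or d.psi is None:
            labels[key] = "unassigned"
            continue
        region = _region_label(d.phi, d.psi)
        if region is not None:
            labels[key] = region
            continue
        bend = curvature.get(key)
        if bend is not None and bend > BEND_ANGLE:
            labels[key] = "bend"
        elif bend is not None and bend > TURN_ANGLE:
            labels[key] = "turn"
        else:
            labels[key] = "others"
    return labels


# ---------------------------------------------------------------------------
# interaction modes
# ---------------------------------------------------------------------------


def _dna_residues(dna: Duplex | Iterable[ResidueRecord]) -> list[tuple[str, ResidueRecord]]:
    if isinstance(dna, Duplex):
        out = [(dna.strand1_chain, r) for r in dna.strand1_residues()]
        out += [(dna.strand2_chain, r) for r in dna.strand2_residues()]
        return out
    result = []
    for item in dna:
        if isinstance(item, tuple):
            result.append(item)
        else:
            result.append(("?", item))
    return result


def _protein_residues(protein) -> list[tuple[str, ResidueRecord]]:
    if isinstance(protein, ChainRecord):
        return [(protein.chain_id, r) for r in protein.residues if r.kind == "protein"]
    result = []
    for item in protein:
        if isinstance(item, ChainRecord):
            result.extend((item.chain_id, r) for r in item.residues if r.kind == "protein")
        elif isinstance(item, tuple):
            result.append(item)
        else:
            result.append(("?", item))
    return result


def _hbond_geometry(
    donor: np.ndarray, antecedent: Optional[np.ndarray], acceptor: np.ndarray
) -> Optional[tuple[float, float]]:
    dist = float(np.linalg.norm(donor - acceptor))
    if dist > HBOND_DISTANCE_MAX:
        return None
    if antecedent is None:
        return None
    angle = bond_angle(antecedent, donor, acceptor)
    if angle < HBOND_ANGLE_MIN:
        return None
    return dist, angle


def detect_hbonds(protein, dna: Duplex | Iterable[ResidueRecord]) -> list[HBond]:
    """Geometric hydrogen bonds between amino acid residues and DNA.

    Both directions are scanned (protein donor -> DNA acceptor and DNA donor
    -> protein acceptor).  Each bond is classified by protein side
    (backbone vs side chain) and DNA target (base / deoxyribose /
    phosphate).
    """
    bonds: list[HBond] = []
    prot = _protein_residues(protein)
    nucleotides = [(c, r) for c, r in _dna_residues(dna) if r.name in STANDARD_DNA]

    for pchain, pres in prot:
        donors: list[tuple[str, str]] = []
        if pres.atom(PROTEIN_BB_DONOR[0]) is not None:
            donors.append(PROTEIN_BB_DONOR)
        for d, ante in PROTEIN_SC_DONORS.get(pres.name, {}).items():
            donors.append((d, ante))
        acceptors = [PROTEIN_BB_ACCEPTOR] + list(PROTEIN_SC_ACCEPTORS.get(pres.name, ()))

        for nchain, nres in nucleotides:
            # protein donor -> DNA acceptor
            dna_acceptors = list(DNA_BASE_ACCEPTORS[nres.name]) + ["O4'", "OP1", "OP2", "O5'", "O3'"]
            for dname, aname in donors:
                dpos = pres.coord(dname)
                apos_ante = pres.coord(aname)
                if dpos is None:
                    continue
                for acc in dna_acceptors:
                    apos = nres.coord(acc)
                    if apos is None:
                        continue
                    geo = _hbond_geometry(dpos, apos_ante, apos)
                    if geo is None:
                        continue
                    bonds.append(
                        HBond(
                            donor_residue=(pchain, pres.seq_id),
                            donor_atom=dname,
                            acceptor_residue=(nchain, nres.seq_id),
                            acceptor_atom=acc,
                            distance=geo[0],
                            angle=geo[1],
                            protein_side="backbone" if dname in _BACKBONE_ATOMS else "side-chain",
                            dna_target=dna_target_class(acc),
                        )
                    )
            # DNA donor -> protein acceptor
            for dname, ante in DNA_BASE_DONORS[nres.name].items():
                dpos = nres.coord(dname)
                antepos = nres.coord(ante)
                if dpos is None:
                    continue
                for acc in acceptors:
                    apos = pres.coord(acc)
                    if apos is None:
                        continue
                    geo = _hbond_geometry(dpos, antepos, apos)
                    if geo is None:
                        continue
                    bonds.append(
                        HBond(
                            donor_residue=(nchain, nres.seq_id),
                            donor_atom=dname,
                            acceptor_residue=(pchain, pres.seq_id),
                            acceptor_atom=acc,
                            distance=geo[0],
                            angle=geo[1],
                            protein_side="backbone" if acc in _BACKBONE_ATOMS else "side-chain",
                            dna_target="base",
                        )
                    )
    return bonds


def classify_vdw_contacts(
    protein, dna: Duplex | Iterable[ResidueRecord], hbonds: Optional[list[HBond]] = None
) -> list[VdWContact]:
    """Heavy-atom pairs within 4.0 Å that are not hydrogen-bonded.

    ``hbonds`` defaults to running :func:`detect_hbonds` on the same input;
    the excluded pairs are the H-bonded donor/acceptor atom pairs.
    """
    if hbonds is None:
        hbonds = detect_hbonds(protein, dna)
    bonded: set[tuple] = set()
    for hb in hbonds:
        bonded.add((hb.donor_residue, hb.donor_atom, hb.acceptor_residue, hb.acceptor_atom))
        bonded.add((hb.acceptor_residue, hb.acceptor_atom, hb.donor_residue, hb.donor_atom))

    contacts: list[VdWContact] = []
    prot = _protein_residues(protein)
    nucleotides = [(c, r) for c, r in _dna_residues(dna) if r.name in STANDARD_DNA]
    for pchain, pres in prot:
        pkey = (pchain, pres.seq_id)
        for nchain, nres in nucleotides:
            nkey = (nchain, nres.seq_id)
            for patom in pres.atoms:
                for natom in nres.atoms:
                    d = float(np.linalg.norm(patom.coords - natom.coords))
                    if d > VDW_DISTANCE_MAX:
                        continue
                    if (pkey, patom.name, nkey, natom.name) in bonded:
                        continue
                    contacts.append(
                        VdWContact(
                            protein_residue=pkey,
                            protein_atom=patom.name,
                            dna_residue=nkey,
                            dna_atom=natom.name,
                            distance=d,
                            protein_side="backbone" if patom.name in _BACKBONE_ATOMS else "side-chain",
                            dna_target=dna_target_class(natom.name),
                        )
                    )
    return contacts


# ---------------------------------------------------------------------------
# Kabsch superposition
# ---------------------------------------------------------------------------


def kabsch_superpose(coords_a: np.ndarray, coords_b: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition of matched point sets.

    Returns the proper rotation R and translation t minimizing
    ||coords_a - (coords_b @ R.T + t)|| together with the residual RMSD.
    """
    a = np.asarray(coords_a, float)
    b = np.asarray(coords_b, float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("matched (n, 3) coordinate sets required")
    if a.shape[0] < 3:
        raise ValueError("at least 3 matched points required")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    # collinearity check via the second singular value of either set
    if np.linalg.svd(a0, compute_uv=False)[1] < 1e-8 or np.linalg.svd(b0, compute_uv=False)[1] < 1e-8:
        raise ValueError("degenerate (collinear) point set")
    h = b0.T @ a0
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = ca - rotation @ cb
    moved = b @ rotation.T + translation
    rmsd = float(np.sqrt(((a - moved) ** 2).sum() / a.shape[0]))
    return SuperpositionResult(rotation=rotation, translation=translation, rmsd=rmsd)


def _step_atom_coords(step, atom_names_per_residue: list[list[str]]) -> np.ndarray:
    coords = []
    residues = _step_residues(step)
    for res, names in zip(residues, atom_names_per_residue):
        for n in names:
            coords.append(res.coord(n))
    return np.array(coords, float)


def _step_residues(step) -> list[ResidueRecord]:
    duplex, k = step.duplex, step.index
    p0, p1 = duplex.pairs[k], duplex.pairs[k + 1]
    return [p0.res_i, p0.res_j, p1.res_i, p1.res_j]


def representative_step(steps: Sequence) -> int:
    """Index of the step minimizing the summed pairwise Kabsch RMSD.

    ``steps`` is a sequence of dinucleotide steps (or raw (n, 3) arrays).
    The atom correspondence across steps uses, per corresponding residue, the
    atoms present in all steps, in a fixed name order.  Ties break to the
    lowest index.
    """
    if len(steps) == 0:
        raise ValueError("no steps given")
    if len(steps) == 1:
        return 0

    if isinstance(steps[0], np.ndarray):
        coord_sets = [np.asarray(s, float) for s in steps]
    else:
        common: list[set[str]] = [set(), set(), set(), set()]
        for pos in range(4):
            names = None
            for step in steps:
                res = _step_residues(step)[pos]
                names = res.atom_names if names is None else names & res.atom_names
            common[pos] = names or set()
        ordered = [sorted(c) for c in common]
        coord_sets = [_step_atom_coords(step, ordered) for step in steps]

    n = len(coord_sets)
    total = np.zeros(n)
    for i in range(n):
        for j in range(i + 1, n):
            r = kabsch_superpose(coord_sets[i], coord_sets[j]).rmsd
            total[i] += r
            total[j] += r
    return int(np.argmin(total))


# ---------------------------------------------------------------------------
# DSSP-output importer (optional)
# ---------------------------------------------------------------------------

_DSSP_LETTER_MAP = {
    "H": "α-helix",
    "G": "3-10-helix",
    "E": "β-strand",
    "P": "polyproline-II",
    "T": "turn",
    "S": "bend",
    "B": "others",
    "I": "others",
    " ": "others",
    "": "others",
}


def import_dssp(path: str | Path) -> dict[tuple[str, str], str]:
    """Parse a classic columnar DSSP output file into per-residue labels."""
    labels: dict[tuple[str, str], str] = {}
    in_table = False
    for line in Path(path).read_text().splitlines():
        if line.lstrip().startswith("#  RESIDUE"):
            in_table = True
            continue
        if not in_table or len(line) < 17:
            continue
        resnum = line[5:11].strip()
        chain = line[11:12].strip()
        if not resnum:  # chain-break rows
            continue
        ss = line[16:17]
        labels[(chain, resnum)] = _DSSP_LETTER_MAP.get(ss, "others")
    return labels
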