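"""Double-helix geometry: base pairs, duplexes, groove widths, sugar puckers.

Minor groove width convention
-----------------------------
The width at a dinucleotide step is the minimum *direct* cross-strand P-P
distance among phosphates within ±3.5 base-pair levels of the step center,
restricted to phosphate pairs whose midpoint lies on the minor-groove side of
the step (closer to the step's minor-groove reference atoms than to its
major-groove ones).  No van der Waals correction is subtracted, so the value
is on the raw P-P scale on which the narrow (≤11 Å) / standard / wide (≥17 Å)
categories are defined; an ideal A-form fiber duplex measures 18.5 Å at its
central step, an ideal B-form duplex ~11.7 Å.

A width is defined only at steps with at least one flanking base pair on each
side; terminal steps (and every step of a ≤4-bp duplex) are undefined.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np

from ._tables import COMPLEMENT, ONE_LETTER, REFERENCE_ATOMS, STANDARD_DNA
from ._geometry import dihedral
from .structure_io import ChainRecord, ResidueRecord

logger = logging.getLogger(__name__)

__all__ = [
    "BasePair",
    "Duplex",
    "DinucleotideStep",
    "SugarPucker",
    "detect_base_pairs",
    "build_duplexes",
    "compute_minor_groove_width",
    "compute_sugar_pucker",
    "import_groove_widths",
    "write_groove_widths",
]

#: Watson-Crick geometric criteria (see package methods note)
WC_N_DISTANCE_MAX = 3.5  # purine N1 - pyrimidine N3, Å
WC_C1_DISTANCE_RANGE = (9.5, 11.5)  # C1'-C1', Å
MIN_DUPLEX_LENGTH = 3  # base pairs
GROOVE_WINDOW = 3.5  # levels around the step center searched for phosphates

_PURINES = {"dA", "dG"}


@dataclass
class BasePair:
    res_i: ResidueRecord
    res_j: ResidueRecord
    chain_i: str
    chain_j: str
    pair_class: str
    c1_distance: float
    n_distance: float

    @property
    def key_i(self) -> tuple[str, str]:
        return (self.chain_i, self.res_i.seq_id)

    @property
    def key_j(self) -> tuple[str, str]:
        return (self.chain_j, self.res_j.seq_id)


@dataclass
class Duplex:
    pairs: list[BasePair]
    strand1_chain: str
    strand2_chain: str

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def n_steps(self) -> int:
        return max(0, len(self.pairs) - 1)

    def strand1_residues(self) -> list[ResidueRecord]:
        return [p.res_i for p in self.pairs]

    def strand2_residues(self) -> list[ResidueRecord]:
        return [p.res_j for p in self.pairs]

    @property
    def sequence(self) -> str:
        """Strand-1 sequence, 5'->3', one letter per pair."""
        return "".join(ONE_LETTER[p.res_i.name] for p in self.pairs)

    def step_sequence(self, index: int) -> str:
        return self.sequence[index : index + 2]


@dataclass
class DinucleotideStep:
    duplex: Duplex
    index: int
    sequence: str
    minor_groove_width: Optional[float] = None
    pucker_labels: dict = field(default_factory=dict)


@dataclass
class SugarPucker:
    phase: float  # degrees in [0, 360)
    amplitude: float  # degrees, >= 0
    label: str  # C3'-endo | C2'-endo | other
    note: str = ""


# ---------------------------------------------------------------------------
# base-pair and duplex detection
# ---------------------------------------------------------------------------


def _wc_geometry(a: ResidueRecord, b: ResidueRecord) -> Optional[tuple[float, float]]:
    """(N-N distance, C1'-C1' distance) if a/b satisfy the WC criteria."""
    if COMPLEMENT.get(ONE_LETTER.get(a.name, "?")) != ONE_LETTER.get(b.name, "?"):
        return None
    purine, pyrimidine = (a, b) if a.name in _PURINES else (b, a)
    n1 = purine.coord("N1")
    n3 = pyrimidine.coord("N3")
    c1a = a.coord("C1'")
    c1b = b.coord("C1'")
    if n1 is None or n3 is None or c1a is None or c1b is None:
        return None
    n_dist = float(np.linalg.norm(n1 - n3))
    c1_dist = float(np.linalg.norm(c1a - c1b))
    if n_dist > WC_N_DISTANCE_MAX:
        return None
    lo, hi = WC_C1_DISTANCE_RANGE
    if not (lo <= c1_dist <= hi):
        return None
    return n_dist, c1_dist


def detect_base_pairs(dna_chains: Iterable[ChainRecord]) -> list[BasePair]:
    """Watson-Crick pairs between nucleotides of different chains.

    Candidates satisfying the geometric criteria are accepted greedily in
    order of increasing glycosidic-nitrogen distance, so every nucleotide
    participates in at most one pair.
    """
    chains = [c for c in dna_chains if c.kind in ("dna", "mixed")]
    candidates: list[tuple[float, float, int, str, ResidueRecord, str, ResidueRecord]] = []
    order = 0
    for ci in range(len(chains)):
        for cj in range(ci + 1, len(chains)):
            for ra in chains[ci].residues:
                if ra.name not in STANDARD_DNA:
                    continue
                for rb in chains[cj].residues:
                    if rb.name not in STANDARD_DNA:
                        continue
                    geo = _wc_geometry(ra, rb)
                    if geo is not None:
                        candidates.append(
                            (geo[0], geo[1], order, chains[ci].chain_id, ra, chains[cj].chain_id, rb)
                        )
                        order += 1
    candidates.sort(key=lambda c: (c[0], c[2]))
    used: set[int] = set()
    pairs: list[BasePair] = []
    for n_dist, c1_dist, _, chain_a, ra, chain_b, rb in candidates:
        if id(ra) in used or id(rb) in used:
            continue
        used.add(id(ra))
        used.add(id(rb))
        pairs.append(
            BasePair(
                res_i=ra, res_j=rb, chain_i=chain_a, chain_j=chain_b,
                pair_class="WC", c1_distance=c1_dist, n_distance=n_dist,
            )
        )
    return pairs


def build_duplexes(pairs: Iterable[BasePair], chains: Iterable[ChainRecord]) -> list[Duplex]:
    """Assemble maximal runs of sequence-adjacent antiparallel pairs.

    Adjacency requires consecutive residues (file order) on strand 1 together
    with consecutive residues in the opposite direction on strand 2.  Runs
    shorter than :data:`MIN_DUPLEX_LENGTH` are discarded.
    """
    chain_map = {c.chain_id: c for c in chains}
    position: dict[tuple[str, str], int] = {}
    for cid, chain in chain_map.items():
        for idx, res in enumerate(chain.residues):
            position[(cid, res.seq_id)] = idx

    by_chains: dict[tuple[str, str], list[BasePair]] = {}
    for p in pairs:
        # orient each pair consistently: lexicographically smaller chain is strand 1
        if (p.chain_j, p.chain_i) < (p.chain_i, p.chain_j):
            p = BasePair(p.res_j, p.res_i, p.chain_j, p.chain_i, p.pair_class, p.c1_distance, p.n_distance)
        by_chains.setdefault((p.chain_i, p.chain_j), []).append(p)

    duplexes: list[Duplex] = []
    for (c1, c2), group in sorted(by_chains.items()):
        group.sort(key=lambda p: position[p.key_i])
        run: list[BasePair] = []
        for p in group:
            if run:
                prev = run[-1]
                adj = (
                    position[p.key_i] == position[prev.key_i] + 1
                    and position[p.key_j] == position[prev.key_j] - 1
                )
                if not adj:
                    if len(run) >= MIN_DUPLEX_LENGTH:
                        duplexes.append(Duplex(run, c1, c2))
                    run = []
            run.append(p)
        if len(run) >= MIN_DUPLEX_LENGTH:
            duplexes.append(Duplex(run, c1, c2))
    return duplexes


# ---------------------------------------------------------------------------
# minor groove width
# ---------------------------------------------------------------------------


def _step_reference_coords(duplex: Duplex, step_index: int) -> tuple[list[np.ndarray], list[np.ndarray]]:
    minor, major = [], []
    for pair in (duplex.pairs[step_index], duplex.pairs[step_index + 1]):
        for res in (pair.res_i, pair.res_j):
            minor_name, major_name = REFERENCE_ATOMS[res.name]
            m = res.coord(minor_name)
            M = res.coord(major_name)
            if m is not None:
                minor.append(m)
            if M is not None:
                major.append(M)
    return minor, major


def compute_minor_groove_width(duplex: Duplex, step_index: int) -> Optional[float]:
    """Direct cross-strand P-P minor groove width at a step, or None.

    See the module docstring for the convention.  Missing phosphates within
    the search window are skipped; if no minor-groove-side phosphate pair
    remains, the width is undefined and the reason is logged.
    """
    n = len(duplex.pairs)
    k = step_index
    if k < 0 or k > n - 2:
        raise IndexError(f"step index {k} out of range for {n}-bp duplex")
    if k < 1 or k > n - 3:
        return None

    center = k + 0.5
    # phosphate of strand-1 residue i sits between levels i-1 and i;
    # strand 2 is antiparallel, so its phosphate at level j sits between j and j+1
    s1 = duplex.strand1_residues()
    s2 = duplex.strand2_residues()
    p1 = [
        (i, s1[i].coord("P"))
        for i in range(n)
        if abs((i - 0.5) - center) <= GROOVE_WINDOW and s1[i].coord("P") is not None
    ]
    p2 = [
        (j, s2[j].coord("P"))
        for j in range(n)
        if abs((j + 0.5) - center) <= GROOVE_WINDOW and s2[j].coord("P") is not None
    ]
    if not p1 or not p2:
        logger.info("step %d: no phosphates in the groove window", k)
        return None

    minor_refs, major_refs = _step_reference_coords(duplex, k)
    if not minor_refs or not major_refs:
        logger.info("step %d: missing reference atoms", k)
        return None

    best: Optional[float] = None
    for _, a in p1:
        for _, b in p2:
            mid = 0.5 * (a + b)
            d_minor = min(float(np.linalg.norm(mid - r)) for r in minor_refs)
            d_major = min(float(np.linalg.norm(mid - r)) for r in major_refs)
            if d_minor >= d_major:
                continue
            dist = float(np.linalg.norm(a - b))
            if best is None or dist < best:
                best = dist
    if best is None:
        logger.info("step %d: no minor-groove-side phosphate pair", k)
    return best


def enumerate_steps(duplex: Duplex, widths: Optional[dict[int, float]] = None) -> list[DinucleotideStep]:
    """All dinucleotide steps of a duplex with widths attached.

    ``widths`` may supply externally computed values (e.g. an imported 3DNA
    table); otherwise widths are computed with the packaged convention.
    """
    steps = []
    for k in range(duplex.n_steps):
        if widths is not None:
            w = widths.get(k)
        else:
            w = compute_minor_groove_width(duplex, k)
        steps.append(DinucleotideStep(duplex, k, duplex.step_sequence(k), w))
    return steps


# ---------------------------------------------------------------------------
# sugar pucker
# ---------------------------------------------------------------------------

_NU_ATOMS = (
    ("C4'", "O4'", "C1'", "C2'"),
    ("O4'", "C1'", "C2'", "C3'"),
    ("C1'", "C2'", "C3'", "C4'"),
    ("C2'", "C3'", "C4'", "O4'"),
    ("C3'", "C4'", "O4'", "C1'"),
)

PUCKER_BINS = {"C3'-endo": (0.0, 36.0), "C2'-endo": (144.0, 180.0)}
NEAR_PLANAR_AMPLITUDE = 5.0  # degrees


def compute_sugar_pucker(nucleotide: ResidueRecord) -> SugarPucker:
    """Pseudorotation phase/amplitude from the five endocyclic torsions.

    Uses the standard pseudorotation analysis of the furanose ring; phase bins
    [0°, 36°) -> C3'-endo and [144°, 180°) -> C2'-endo, everything else
    (including near-planar rings) -> other.
    """
    coords = {}
    for names in _NU_ATOMS:
        for name in names:
            if name not in coords:
                c = nucleotide.coord(name)
                if c is None:
                    raise ValueError(f"missing furanose ring atom {name} in {nucleotide.name} {nucleotide.seq_id}")
                coords[name] = c
    nu = [dihedral(*(coords[n] for n in names)) for names in _NU_ATOMS]
    numer = nu[4] + nu[1] - nu[3] - nu[0]
    denom = 2.0 * nu[2] * (math.sin(math.radians(36.0)) + math.sin(math.radians(72.0)))
    if abs(denom) < 1e-9:
        phase = 90.0 if numer >= 0 else 270.0
    else:
        phase = math.degrees(math.atan(numer / denom))
        if nu[2] < 0:
            phase += 180.0
    phase %= 360.0
    amplitude = nu[2] / math.cos(math.radians(phase)) if abs(math.cos(math.radians(phase))) > 1e-9 else abs(
        nu[4] + nu[1] - nu[3] - nu[0]
    ) / (2.0 * (math.sin(math.radians(36.0)) + math.sin(math.radians(72.0))))
    amplitude = abs(amplitude)

    note = ""
    if amplitude < NEAR_PLANAR_AMPLITUDE:
        label = "other"
        note = "near-planar"
    else:
        label = "other"
        for name, (lo, hi) in PUCKER_BINS.items():
            if lo <= phase < hi:
                label = name
                break
    return SugarPucker(phase=phase, amplitude=amplitude, label=label, note=note)


# ---------------------------------------------------------------------------
# groove-width table import/export (3DNA-style plain-text column layout)
# ---------------------------------------------------------------------------


def write_groove_widths(widths: dict[int, float], path: str | Path) -> None:
    """Write a step-index -> width table as TSV (undefined steps omitted)."""
    lines = ["step_index\tminor_groove_width_A"]
    for k in sorted(widths):
        if widths[k] is not None:
            lines.append(f"{k}\t{widths[k]:.4f}")
    Path(path).write_text("\n".join(lines) + "\n")


def import_groove_widths(
    path: str | Path, n_steps: Optional[int] = None
) -> tuple[dict[int, float], list[int]]:
    """Read a groove-width table; returns (mapping, unmatched step indices).

    Rows whose step index falls outside [0, n_steps-1] are reported as
    unmatched when ``n_steps`` is given.
    """
    mapping: dict[int, float] = {}
    unmatched: list[int] = []
    text = Path(path).read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.lower().startswith("step"):
            continue
        fields = line.split()
        try:
            k = int(fields[0])
            w = float(fields[1])
        except (IndexError, ValueError) as exc:
            raise ValueError(f"{path}: malformed groove-width row at line {lineno}: {line!r}") from exc
        if n_steps is not None and not (0 <= k < n_steps):
            unmatched.append(k)
            continue
        mapping[k] = w
    return mapping, unmatched
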