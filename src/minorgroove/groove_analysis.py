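"""Groove-width categories, interface segments, hexamer windows and
dinucleotide sequence preferences.

Width categories partition (0, inf): narrow (≤ 11.0 Å), standard
(11 < w < 17 Å) and wide (≥ 17 Å) on the direct P-P scale.  A protein-DNA
interface is a maximal run of contacted dinucleotide steps in which up to two
consecutive non-contacted steps are bridged; interfaces spanning at least six
nucleotides are scanned with a 6-nucleotide sliding window whose width is the
central step's and whose residue set is the union over its five internal
steps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import pandas as pd

from ._tables import COMPLEMENT
from .helix_model import Duplex, compute_minor_groove_width

logger = logging.getLogger(__name__)

__all__ = [
    "NARROW_MAX",
    "WIDE_MIN",
    "GAP_LIMIT",
    "InterfaceSegment",
    "HexamerWindow",
    "categorize_width",
    "build_interfaces",
    "sliding_hexamers",
    "gc_content",
    "width_by_gc",
    "sequence_preferences",
    "step_class",
]

NARROW_MAX = 11.0  # Å, inclusive
WIDE_MIN = 17.0  # Å, inclusive
GAP_LIMIT = 2  # bridged non-contacted steps
WINDOW_NUCLEOTIDES = 6


def categorize_width(
    width: float, narrow_max: float = NARROW_MAX, wide_min: float = WIDE_MIN
) -> str:
    """Map a defined minor groove width to narrow / standard / wide."""
    if width is None:
        raise ValueError("width is undefined")
    width = float(width)
    if not width > 0:
        raise ValueError(f"width must be positive, got {width}")
    if width <= narrow_max:
        return "narrow"
    if width >= wide_min:
        return "wide"
    return "standard"


@dataclass
class InterfaceSegment:
    duplex: Optional[Duplex]
    contacted_steps: list[int]
    start: int  # first contacted step
    end: int  # last contacted step (inclusive)

    @property
    def step_span(self) -> range:
        """All steps of the segment, bridged gaps included."""
        return range(self.start, self.end + 1)

    @property
    def n_nucleotides(self) -> int:
        return self.end - self.start + 2


@dataclass
class HexamerWindow:
    start: int  # strand-1 nucleotide index of the first of six nucleotides
    sequence: str
    width: float
    gc_content: float
    contacting_residues: frozenset = field(default_factory=frozenset)
    duplex: Optional[Duplex] = None

    @property
    def residue_types(self) -> frozenset:
        return frozenset(t for t, _ in self.contacting_residues)


def build_interfaces(
    contacted_steps: Iterable[int],
    duplex: Optional[Duplex] = None,
    gap_limit: int = GAP_LIMIT,
) -> list[InterfaceSegment]:
    """Maximal interface segments bridging gaps of at most ``gap_limit`` steps."""
    steps = sorted(set(contacted_steps))
    if not steps:
        return []
    segments: list[InterfaceSegment] = []
    run = [steps[0]]
    for s in steps[1:]:
        if s - run[-1] - 1 <= gap_limit:
            run.append(s)
        else:
            segments.append(InterfaceSegment(duplex, run, run[0], run[-1]))
            run = [s]
    segments.append(InterfaceSegment(duplex, run, run[0], run[-1]))
    return segments


def sliding_hexamers(
    segment: InterfaceSegment,
    duplex: Duplex,
    residues_by_step: Optional[Mapping[int, set]] = None,
    widths: Optional[Mapping[int, Optional[float]]] = None,
) -> list[HexamerWindow]:
    """Stride-1 six-nucleotide windows over an interface segment.

    A window starting at strand-1 nucleotide ``n0`` covers steps
    ``n0 .. n0+4``; its width is the central step's (``n0+2``) and it is
    skipped (with a log entry) when that width is undefined.  The window's
    residue set is the union of residues contacting any of its five steps.
    """
    residues_by_step = residues_by_step or {}
    sequence = duplex.sequence
    windows: list[HexamerWindow] = []
    first = segment.start
    last_start = segment.end + 1 - (WINDOW_NUCLEOTIDES - 1)
    for n0 in range(first, last_start + 1):
        if n0 < 0 or n0 + WINDOW_NUCLEOTIDES > len(sequence):
            continue
        central = n0 + 2
        if widths is not None:
            w = widths.get(central)
        else:
            w = compute_minor_groove_width(duplex, central)
        if w is None:
            logger.info("hexamer at %d skipped: undefined central-step width", n0)
            continue
        contacting: set = set()
        for s in range(n0, n0 + WINDOW_NUCLEOTIDES - 1):
            contacting |= set(residues_by_step.get(s, ()))
        seq = sequence[n0 : n0 + WINDOW_NUCLEOTIDES]
        windows.append(
            HexamerWindow(
                start=n0,
                sequence=seq,
                width=float(w),
                gc_content=sum(1 for b in seq if b in "GC") / WINDOW_NUCLEOTIDES,
                contacting_residues=frozenset(contacting),
                duplex=duplex,
            )
        )
    return windows


def gc_content(window: HexamerWindow) -> float:
    """Fraction of G/C base pairs among the hexamer's six pairs."""
    return sum(1 for b in window.sequence if b in "GC") / WINDOW_NUCLEOTIDES


def width_by_gc(
    windows: Iterable[HexamerWindow], per_amino_acid: bool = True
) -> dict:
    """Hexamer width distributions at each of the seven GC levels.

    Returns ``{"pooled": {k: [widths]}, "per_amino_acid": {aa: {k: [...]}}}``
    where ``k`` is the number of GC pairs (0..6).  A window contributes to an
    amino acid's table iff that amino acid type is among its contacting
    residues.
    """
    pooled: dict[int, list[float]] = {k: [] for k in range(7)}
    per_aa: dict[str, dict[int, list[float]]] = {}
    for w in windows:
        k = round(w.gc_content * WINDOW_NUCLEOTIDES)
        pooled[k].append(w.width)
        if per_amino_acid:
            for aa in sorted(w.residue_types):
                per_aa.setdefault(aa, {kk: [] for kk in range(7)})[k].append(w.width)
    out = {"pooled": pooled}
    if per_amino_acid:
        out["per_amino_acid"] = per_aa
    return out


# ---------------------------------------------------------------------------
# dinucleotide sequence preferences (complement-pooled)
# ---------------------------------------------------------------------------


def step_class(step_sequence: str) -> str:
    """Complement-pooled label for a strand-1 step sequence (e.g. 'ApA/TpT')."""
    s = step_sequence.upper()
    if len(s) != 2 or any(b not in "ACGT" for b in s):
        raise ValueError(f"not a dinucleotide step sequence: {step_sequence!r}")
    rc = COMPLEMENT[s[1]] + COMPLEMENT[s[0]]
    a, b = sorted([s, rc])
    if a == b:
        return f"{a[0]}p{a[1]}"
    return f"{a[0]}p{a[1]}/{b[0]}p{b[1]}"


STEP_CLASSES: tuple[str, ...] = tuple(
    sorted({step_class(x + y) for x in "ACGT" for y in "ACGT"})
)


def sequence_preferences(table) -> pd.DataFrame:
    """Per-amino-acid frequencies of contacted step classes.

    ``table`` is a dataset table (iterable of contact records with
    ``residue_type`` and ``step_sequence``).  Rows (amino acids) sum to 1;
    returns an empty frame for an empty table.
    """
    counts: dict[str, dict[str, int]] = {}
    for rec in table:
        if not rec.step_sequence:
            continue
        cls = step_class(rec.step_sequence)
        counts.setdefault(rec.residue_type, {c: 0 for c in STEP_CLASSES})[cls] += 1
    if not counts:
        return pd.DataFrame(columns=list(STEP_CLASSES))
    df = pd.DataFrame.from_dict(counts, orient="index").loc[
        sorted(counts), list(STEP_CLASSES)
    ]
    return df.div(df.sum(axis=1), axis=0)
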