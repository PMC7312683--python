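"""Minor-groove contact detection and dataset (DS1/DS2-style) assembly.

Each nucleobase carries one reference atom per groove, approximately central
in that groove: N3 (minor) and N6 (major) for adenine, N3/O6 for guanine,
O2/O4 for thymine, O2/N4 for cytosine.  An amino acid residue's distance to a
reference atom is the minimum Euclidean distance from any of its non-hydrogen
atoms.  A residue is minor-groove-contacting iff its globally nearest
reference atom (over all duplexes of the structure) is a minor-groove atom
and that distance is strictly below 6.0 Å.

Every contacting residue is then assigned a dinucleotide step: the nearest
contacted nucleotide together with whichever of its (up to two) same-strand
sequence neighbors has the closer minor-groove reference atom; exact ties go
to the 5' neighbor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np

from ._tables import AMINO_ACIDS, REFERENCE_ATOMS
from .groove_analysis import categorize_width
from .helix_model import Duplex
from .structure_io import ResidueRecord, StructureModel

logger = logging.getLogger(__name__)

__all__ = [
    "CONTACT_CUTOFF",
    "DEFAULT_EXCLUDED_FAMILIES",
    "ContactRecord",
    "DatasetTable",
    "reference_atoms",
    "find_groove_contacts",
    "assign_dinucleotide_step",
    "build_dataset",
    "ds_prune",
    "write_dataset_tsv",
    "read_dataset_tsv",
]

CONTACT_CUTOFF = 6.0  # Å, strict
DEFAULT_EXCLUDED_FAMILIES = frozenset({"PF00505", "PF00352"})

#: TSV column order for serialized dataset tables
_TSV_COLUMNS = (
    "structure_id", "chain", "residue_type", "residue_seq", "nucleotide",
    "step_index", "step_sequence", "groove", "distance_A", "width_A", "category",
)


def reference_atoms(base: str) -> tuple[str, str]:
    """(minor-groove atom, major-groove atom) for a standard base."""
    try:
        return REFERENCE_ATOMS[base]
    except KeyError:
        raise ValueError(f"no reference atoms for non-standard base {base!r}") from None


@dataclass
class ContactRecord:
    structure_id: str
    residue_chain: str
    residue_type: str
    residue_seq: str
    nucleotide_chain: str
    nucleotide_seq: str
    groove: str  # minor | major
    distance: float
    duplex: Optional[Duplex] = None
    step_index: Optional[int] = None
    step_sequence: str = ""
    minor_groove_width: Optional[float] = None
    width_category: str = ""

    @property
    def residue_key(self) -> tuple[str, str]:
        return (self.residue_chain, self.residue_seq)

    @property
    def residue_id(self) -> tuple[str, str, str]:
        return (self.structure_id, self.residue_chain, self.residue_seq)


@dataclass
class DatasetTable:
    records: list[ContactRecord] = field(default_factory=list)
    label: str = "custom"
    provenance: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def widths(self) -> np.ndarray:
        return np.array([r.minor_groove_width for r in self.records], dtype=float)


# ---------------------------------------------------------------------------
# contact detection
# ---------------------------------------------------------------------------


def _duplex_reference_atoms(duplexes: Iterable[Duplex]) -> list[tuple[Duplex, int, str, str, str, np.ndarray]]:
    """Flat list of (duplex, level, strand_chain, seq_id, groove, coords)."""
    out = []
    for duplex in duplexes:
        for level, pair in enumerate(duplex.pairs):
            for res, chain in ((pair.res_i, pair.chain_i), (pair.res_j, pair.chain_j)):
                minor_name, major_name = REFERENCE_ATOMS[res.name]
                for groove, name in (("minor", minor_name), ("major", major_name)):
                    c = res.coord(name)
                    if c is not None:
                        out.append((duplex, level, chain, res.seq_id, groove, c))
    return out


def find_groove_contacts(
    model: StructureModel, duplexes: list[Duplex], cutoff: float = CONTACT_CUTOFF
) -> list[ContactRecord]:
    """Minor-groove-contacting amino acid residues of a structure.

    Returns one record per retained residue, carrying the contacted duplex and
    nucleotide; records are ordered by (chain, residue file order).  The
    cutoff is strict (a residue at exactly ``cutoff`` is not a contact).
    """
    refs = _duplex_reference_atoms(duplexes)
    if not refs:
        return []
    ref_coords = np.array([r[5] for r in refs])
    records: list[ContactRecord] = []
    for chain in model.chains:
        if chain.kind not in ("protein", "mixed"):
            continue
        for res in chain.residues:
            if res.kind != "protein" or res.name not in AMINO_ACIDS:
                continue
            heavy = res.heavy_coords()
            if heavy.size == 0:
                continue
            # distance from each reference atom to the nearest residue heavy atom
            d = np.sqrt(
                ((ref_coords[:, None, :] - heavy[None, :, :]) ** 2).sum(axis=2)
            ).min(axis=1)
            best = int(np.argmin(d))
            duplex, level, nchain, nseq, groove, _ = refs[best]
            dist = float(d[best])
            if groove != "minor":
                continue
            if not dist < cutoff:
                continue
            records.append(
                ContactRecord(
                    structure_id=model.structure_id,
                    residue_chain=chain.chain_id,
                    residue_type=res.name,
                    residue_seq=res.seq_id,
                    nucleotide_chain=nchain,
                    nucleotide_seq=nseq,
                    groove="minor",
                    distance=dist,
                    duplex=duplex,
                    step_index=level,  # provisional; refined by assign_dinucleotide_step
                )
            )
    return records


def _residue_min_distance(res_heavy: np.ndarray, atom: Optional[np.ndarray]) -> float:
    if atom is None:
        return float("inf")
    return float(np.sqrt(((res_heavy - atom) ** 2).sum(axis=1)).min())


def assign_dinucleotide_step(contact: ContactRecord, duplex: Duplex, model: StructureModel) -> int:
    """Resolve the contact's dinucleotide step index within the duplex.

    The step spans the nearest contacted nucleotide and the same-strand
    sequence neighbor whose minor-groove reference atom is closer to the
    residue; at a duplex terminus the single existing neighbor is used, and an
    exact tie is broken toward the 5' neighbor.
    """
    res = model.residue(contact.residue_chain, contact.residue_seq)
    heavy = res.heavy_coords()

    strand1 = duplex.strand1_residues()
    strand2 = duplex.strand2_residues()
    on_strand1 = any(
        r.seq_id == contact.nucleotide_seq and c == contact.nucleotide_chain
        for r, c in ((x, duplex.strand1_chain) for x in strand1)
    )
    strand = strand1 if on_strand1 else strand2
    chain_id = duplex.strand1_chain if on_strand1 else duplex.strand2_chain
    if chain_id != contact.nucleotide_chain:
        raise ValueError("contact nucleotide does not belong to the duplex")
    level = next(
        i for i, r in enumerate(strand) if r.seq_id == contact.nucleotide_seq
    )

    def minor_dist(lvl: int) -> float:
        r = strand[lvl]
        minor_name, _ = REFERENCE_ATOMS[r.name]
        return _residue_min_distance(heavy, r.coord(minor_name))

    candidates = [lvl for lvl in (level - 1, level + 1) if 0 <= lvl < len(strand)]
    if not candidates:
        raise ValueError("duplex too short for step assignment")
    if len(candidates) == 1:
        neighbor = candidates[0]
    else:
        # note: on strand 1 the 5' neighbor is level-1, on strand 2 it is level+1
        five_prime = level - 1 if on_strand1 else level + 1
        d5 = minor_dist(five_prime)
        other = level + 1 if on_strand1 else level - 1
        d3 = minor_dist(other)
        neighbor = five_prime if d5 <= d3 else other
    step = min(level, neighbor)
    contact.step_index = step
    contact.step_sequence = duplex.step_sequence(step)
    return step


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------


def build_dataset(
    contacts: Iterable[ContactRecord],
    widths: Mapping[int, Optional[float]] | None = None,
    blacklist: Optional[set[tuple[str, str, str]]] = None,
    label: str = "DS1",
) -> DatasetTable:
    """Assemble a DS1-style table from step-assigned contacts.

    ``widths`` optionally overrides per-step widths (keyed by step index of
    the contact's duplex); by default each contact's width is computed from
    its duplex with the packaged convention.  Records with undefined width
    are dropped with a logged reason; ``blacklist`` entries —
    (structure_id, chain, seq_id) residue identities emulating manual
    curation — are removed.  One record per (residue, step) pair is kept.
    """
    from .helix_model import compute_minor_groove_width

    blacklist = blacklist or set()
    table = DatasetTable(label=label)
    seen: set[tuple] = set()
    n_blacklisted = n_undefined = 0
    for rec in contacts:
        if rec.residue_id in blacklist:
            n_blacklisted += 1
            logger.info("blacklisted residue %s", rec.residue_id)
            continue
        if rec.step_index is None or rec.duplex is None:
            logger.info("contact %s lacks a step assignment; dropped", rec.residue_id)
            n_undefined += 1
            continue
        if widths is not None:
            w = widths.get(rec.step_index)
        elif rec.minor_groove_width is not None:
            w = rec.minor_groove_width
        else:
            w = compute_minor_groove_width(rec.duplex, rec.step_index)
        if w is None:
            n_undefined += 1
            logger.info(
                "dropped %s: undefined width at step %d", rec.residue_id, rec.step_index
            )
            continue
        key = (rec.residue_id, id(rec.duplex), rec.step_index)
        if key in seen:
            continue
        seen.add(key)
        rec = replace(
            rec,
            minor_groove_width=float(w),
            width_category=categorize_width(float(w)),
        )
        table.records.append(rec)
    table.provenance.append(
        f"build_dataset: kept {len(table.records)}, "
        f"dropped {n_undefined} undefined-width, {n_blacklisted} blacklisted"
    )
    return table


def ds_prune(
    table: DatasetTable,
    family_annotations: Mapping[tuple[str, str, str], str],
    excluded_families: frozenset[str] = DEFAULT_EXCLUDED_FAMILIES,
    label: str = "DS2",
) -> DatasetTable:
    """DS2-style pruning: drop records whose residue maps to an excluded family.

    ``family_annotations`` maps (structure_id, chain, seq_id) to a family
    accession (e.g. Pfam); unannotated residues are retained.
    """
    kept = [
        r
        for r in table.records
        if family_annotations.get(r.residue_id) not in excluded_families
    ]
    out = DatasetTable(records=kept, label=label, provenance=list(table.provenance))
    out.provenance.append(
        f"ds_prune: excluded families {sorted(excluded_families)}; "
        f"removed {len(table.records) - len(kept)} records"
    )
    return out


def read_family_annotations(path: str | Path) -> dict[tuple[str, str, str], str]:
    """Read a TSV of structure_id, chain, residue_seq, family accession."""
    annotations: dict[tuple[str, str, str], str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#") or line.lower().startswith("structure_id"):
            continue
        fields = line.split("\t")
        if len(fields) != 4:
            raise ValueError(f"{path}: malformed annotation row at line {lineno}: {line!r}")
        annotations[(fields[0], fields[1], fields[2])] = fields[3]
    return annotations


# ---------------------------------------------------------------------------
# TSV serialization
# ---------------------------------------------------------------------------


def write_dataset_tsv(table: DatasetTable, path: str | Path) -> None:
    lines = ["\t".join(_TSV_COLUMNS)]
    for r in table.records:
        lines.append(
            "\t".join(
                (
                    r.structure_id,
                    r.residue_chain,
                    r.residue_type,
                    r.residue_seq,
                    f"{r.nucleotide_chain}:{r.nucleotide_seq}",
                    str(r.step_index if r.step_index is not None else ""),
                    r.step_sequence,
                    r.groove,
                    f"{r.distance:.4f}",
                    f"{r.minor_groove_width:.4f}" if r.minor_groove_width is not None else "",
                    r.width_category,
                )
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_dataset_tsv(path: str | Path, label: str = "custom") -> DatasetTable:
    text = Path(path).read_text().splitlines()
    if not text or text[0].split("\t") != list(_TSV_COLUMNS):
        raise ValueError(f"{path}: not a dataset table (unexpected header)")
    table = DatasetTable(label=label, provenance=[f"read from {path}"])
    for line in text[1:]:
        if not line.strip():
            continue
        f = line.split("\t")
        nchain, _, nseq = f[4].partition(":")
        table.records.append(
            ContactRecord(
                structure_id=f[0],
                residue_chain=f[1],
                residue_type=f[2],
                residue_seq=f[3],
                nucleotide_chain=nchain,
                nucleotide_seq=nseq,
                groove=f[7],
                distance=float(f[8]),
                step_index=int(f[5]) if f[5] else None,
                step_sequence=f[6],
                minor_groove_width=float(f[9]) if f[9] else None,
                width_category=f[10],
            )
        )
    return table
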