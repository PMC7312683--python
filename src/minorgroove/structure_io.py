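"""Structure parsing, chain classification, DNA validation and dataset filters.

The in-memory model is deliberately lightweight: a :class:`StructureModel` is a
list of chains, each an ordered list of residues with heavy-atom coordinates.
Hydrogens are dropped on parse (every distance criterion downstream is defined
over non-hydrogen atoms), alternate locations are collapsed to the
highest-occupancy conformer, and only the first MODEL of a multi-model file is
read.  Parsing of the PDB and mmCIF formats is delegated to gemmi.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np

from ._tables import (
    AMINO_ACIDS,
    ATOM_NAME_ALIASES,
    BARE_DNA_ALIASES,
    BASE_ATOMS,
    DNA_NAME_ALIASES,
    OPTIONAL_5PRIME_ATOMS,
    STANDARD_DNA,
    SUGAR_PHOSPHATE_ATOMS,
    element_of,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AtomRecord",
    "ResidueRecord",
    "ChainRecord",
    "StructureModel",
    "DatasetFilterCriteria",
    "ValidationReport",
    "StructureParseError",
    "parse_structure",
    "write_pdb",
    "classify_chains",
    "validate_dna_chain",
    "apply_dataset_filters",
]


class StructureParseError(ValueError):
    """Raised when a structure file cannot be interpreted."""


@dataclass
class AtomRecord:
    name: str
    element: str
    coords: np.ndarray
    is_hetatm: bool = False
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")
        if not self.element:
            raise ValueError(f"empty element for atom {self.name}")


@dataclass
class ResidueRecord:
    name: str
    seq_id: str
    atoms: list[AtomRecord] = field(default_factory=list)
    kind: str = "other"  # protein | dna | other

    def atom(self, name: str) -> Optional[AtomRecord]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coord(self, name: str) -> Optional[np.ndarray]:
        a = self.atom(name)
        return None if a is None else a.coords

    def heavy_coords(self) -> np.ndarray:
        """(n, 3) array of all (non-hydrogen) atom coordinates."""
        return np.array([a.coords for a in self.atoms], dtype=float).reshape(-1, 3)

    @property
    def atom_names(self) -> set[str]:
        return {a.name for a in self.atoms}


@dataclass
class ChainRecord:
    chain_id: str
    residues: list[ResidueRecord] = field(default_factory=list)
    kind: str = "other"  # protein | dna | mixed | other


@dataclass
class StructureModel:
    structure_id: str
    chains: list[ChainRecord] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [c.chain_id for c in self.chains]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate chain identifiers")

    def chain(self, chain_id: str) -> ChainRecord:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(chain_id)

    def residue(self, chain_id: str, seq_id: str) -> ResidueRecord:
        for r in self.chain(chain_id).residues:
            if r.seq_id == seq_id:
                return r
        raise KeyError((chain_id, seq_id))


@dataclass
class DatasetFilterCriteria:
    max_resolution: float = 3.5
    allowed_methods: frozenset[str] = frozenset({"X-RAY DIFFRACTION"})
    chain_allowlist: Optional[set[tuple[str, str]]] = None

    def __post_init__(self) -> None:
        if self.max_resolution <= 0:
            raise ValueError("max_resolution must be positive")
        self.allowed_methods = frozenset(m.upper() for m in self.allowed_methods)


@dataclass
class ValidationReport:
    chain_id: str
    passed: bool
    reasons: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# parsing / writing
# ---------------------------------------------------------------------------


def _seq_id(numbered) -> str:
    num = str(numbered.num) if numbered.num is not None else ""
    icode = numbered.icode.strip() if isinstance(numbered.icode, str) else ""
    return f"{num}{icode}"


def parse_structure(path: str | Path, format: str = "pdb") -> StructureModel:
    """Parse a PDB or mmCIF file into a :class:`StructureModel`.

    Only the first MODEL is read; hydrogens and waters' hydrogens are dropped;
    for alternate locations the highest-occupancy conformer is kept (ties go to
    the first conformer in file order).
    """
    import gemmi

    path = Path(path)
    if format not in ("pdb", "mmcif"):
        raise ValueError(f"unknown structure format label: {format!r}")
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        if format == "pdb":
            st = gemmi.read_pdb(str(path))
        else:
            doc = gemmi.cif.read(str(path))
            st = gemmi.make_structure_from_block(doc.sole_block())
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"{path}: {exc}") from exc
    if len(st) == 0 or sum(len(ch) for ch in st[0]) == 0:
        raise StructureParseError(f"{path}: no atoms found")

    st.setup_entities()
    model = st[0]
    chains: list[ChainRecord] = []
    for ch in model:
        residues: list[ResidueRecord] = []
        for res in ch:
            best: dict[str, AtomRecord] = {}
            order: list[str] = []
            for at in res:
                if at.element.is_hydrogen:
                    continue
                name = ATOM_NAME_ALIASES.get(at.name, at.name)
                rec = AtomRecord(
                    name=name,
                    element=at.element.name or element_of(name),
                    coords=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    is_hetatm=(res.het_flag == "H"),
                    occupancy=float(at.occ),
                    altloc=at.altloc or "",
                )
                if name not in best:
                    best[name] = rec
                    order.append(name)
                elif rec.occupancy > best[name].occupancy:
                    best[name] = rec
            if not best:
                continue
            residues.append(
                ResidueRecord(
                    name=res.name,
                    seq_id=_seq_id(res.seqid),
                    atoms=[best[n] for n in order],
                )
            )
        if residues:
            chains.append(ChainRecord(chain_id=ch.name, residues=residues))

    metadata: dict = {}
    method = dict(st.info).get("_exptl.method", "")
    if method:
        metadata["method"] = method
    if st.resolution and st.resolution > 0:
        metadata["resolution"] = float(st.resolution)
    return StructureModel(structure_id=st.name or path.stem, chains=chains, metadata=metadata)


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write the model as a minimal (but standard) PDB file."""
    lines: list[str] = []
    if model.metadata.get("method") or model.metadata.get("resolution"):
        method = model.metadata.get("method", "")
        lines.append(f"EXPDTA    {method}")
        if model.metadata.get("resolution") is not None:
            lines.append(
                "REMARK   2 RESOLUTION. "
                f"{float(model.metadata['resolution']):5.2f} ANGSTROMS."
            )
    serial = 1
    for chain in model.chains:
        for res in chain.residues:
            # split a trailing insertion code off the seq id
            sid = res.seq_id
            icode = " "
            if sid and sid[-1].isalpha():
                icode = sid[-1]
                sid = sid[:-1]
            resnum = int(sid) if sid else 0
            resname = res.name if len(res.name) <= 3 else res.name[:3]
            for atom in res.atoms:
                record = "HETATM" if atom.is_hetatm else "ATOM  "
                name = atom.name
                # PDB atom-name column convention
                pname = f" {name:<3s}" if len(name) < 4 and len(atom.element) == 1 else f"{name:<4s}"
                x, y, z = atom.coords
                lines.append(
                    f"{record}{serial:5d} {pname}{' '}{resname:>3s} "
                    f"{chain.chain_id[:1]}{resnum:4d}{icode}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
                    f"          {atom.element:>2s}"
                )
                serial += 1
        lines.append(f"TER   {serial:5d}")
        serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# classification / validation / filtering
# ---------------------------------------------------------------------------


def _normalize_residue(res: ResidueRecord) -> None:
    """Assign residue kind and canonical nucleotide names in place."""
    name = res.name.strip()
    if name in DNA_NAME_ALIASES:
        res.name = DNA_NAME_ALIASES[name]
        res.kind = "dna"
    elif name in BARE_DNA_ALIASES and res.atom("O2'") is None and res.atom("C1'") is not None:
        res.name = BARE_DNA_ALIASES[name]
        res.kind = "dna"
    elif name in AMINO_ACIDS:
        res.kind = "protein"
    else:
        res.kind = "other"


def classify_chains(model: StructureModel) -> StructureModel:
    """Annotate residue and chain kinds in place (idempotent); returns model."""
    for chain in model.chains:
        for res in chain.residues:
            _normalize_residue(res)
        has_protein = any(r.kind == "protein" for r in chain.residues)
        has_dna = any(r.kind == "dna" for r in chain.residues)
        if has_protein and has_dna:
            chain.kind = "mixed"
        elif has_protein:
            chain.kind = "protein"
        elif has_dna:
            chain.kind = "dna"
        else:
            chain.kind = "other"
    return model


def validate_dna_chain(chain: ChainRecord) -> ValidationReport:
    """Check a DNA chain for the dataset's admissibility rules.

    A chain passes when every residue is a standard deoxyribonucleotide
    (dA/dC/dG/dT), no nucleotide atom is HETATM-flagged, and the full heavy-atom
    inventory of every nucleotide is present (the 5'-terminal phosphate group
    is treated as optional, matching deposition practice).
    """
    reasons: list[str] = []
    for i, res in enumerate(chain.residues):
        if res.name not in STANDARD_DNA:
            reasons.append(f"non-standard residue {res.name} at {chain.chain_id}:{res.seq_id}")
            continue
        if any(a.is_hetatm for a in res.atoms):
            reasons.append(f"HETATM-flagged nucleotide at {chain.chain_id}:{res.seq_id}")
        expected = set(SUGAR_PHOSPHATE_ATOMS) | set(BASE_ATOMS[res.name])
        if i == 0:
            expected -= OPTIONAL_5PRIME_ATOMS
        missing = expected - res.atom_names
        for name in sorted(missing):
            reasons.append(
                f"missing heavy atom {name} in {res.name} at {chain.chain_id}:{res.seq_id}"
            )
    return ValidationReport(chain_id=chain.chain_id, passed=not reasons, reasons=reasons)


def apply_dataset_filters(
    models: Iterable[StructureModel],
    criteria: DatasetFilterCriteria,
) -> list[StructureModel]:
    """Apply experimental-method/resolution filters and the chain allow-list.

    Models failing the method or resolution criterion (or lacking resolution
    metadata) are dropped with a logged reason.  When an allow-list is given,
    protein chains not on it are removed from the retained models; DNA chains
    are always kept.  Input order is preserved.
    """
    kept: list[StructureModel] = []
    for model in models:
        method = str(model.metadata.get("method", "")).upper()
        if criteria.allowed_methods and method not in criteria.allowed_methods:
            logger.info("excluded %s: method %r not allowed", model.structure_id, method)
            continue
        resolution = model.metadata.get("resolution")
        if resolution is None:
            logger.info("excluded %s: missing resolution metadata", model.structure_id)
            continue
        if float(resolution) > criteria.max_resolution:
            logger.info(
                "excluded %s: resolution %.2f above %.2f",
                model.structure_id, float(resolution), criteria.max_resolution,
            )
            continue
        if criteria.chain_allowlist is not None:
            chains = []
            for ch in model.chains:
                if ch.kind == "protein" and (model.structure_id, ch.chain_id) not in criteria.chain_allowlist:
                    logger.info(
                        "dropped chain %s:%s: not on allow-list",
                        model.structure_id, ch.chain_id,
                    )
                    continue
                chains.append(ch)
            model = StructureModel(model.structure_id, chains, model.metadata)
        kept.append(model)
    return kept
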