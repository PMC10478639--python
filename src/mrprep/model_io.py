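"""Read and write predicted protein models and predicted-aligned-error matrices.

Predicted models from AlphaFold2, RoseTTAFold, ESMFold and kin arrive as PDB
or mmCIF files whose B-factor column carries a per-residue confidence value
(pLDDT on a 0-100 or 0-1 scale, or an estimated r.m.s.d. in Angstrom) rather
than a crystallographic displacement parameter.  This module loads such files
into a light in-memory representation (:class:`PredictedModel`) that preserves
residue identity, file order and the raw confidence column, writes models back
out, and parses the predicted-aligned-error (PAE) JSON files that accompany
AlphaFold-style predictions in their common dialects.

Parsing and serialisation of the structure formats themselves are delegated
to :mod:`gemmi`; this module only imposes the predicted-model conventions
(polymer atoms only, first NMR-style model only, one confidence value per
residue taken from the Calpha atom).
"""

from __future__ import annotations

import copy
import io
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Union

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "ResidueRecord",
    "PredictedModel",
    "PAEMatrix",
    "read_model",
    "write_model",
    "read_pae_json",
    "write_pae_json",
    "afdb_entry_urls",
]

AFDB_BASE_URL = "https://alphafold.ebi.ac.uk/files"

# Standard UniProt accession pattern (6- and 10-character forms).
_UNIPROT_RE = re.compile(
    r"^([OPQ][0-9][A-Z0-9]{3}[0-9]|[A-NR-Z][0-9]([A-Z][A-Z0-9]{2}[0-9]){1,2})$"
)

Source = Union[str, Path, io.IOBase]


@dataclass
class AtomRecord:
    """A single atom: name, element, coordinates and the B-column value.

    ``b_value`` holds whatever the source file stored in the B column --
    a raw confidence score before conversion, an isotropic B factor after.
    """

    name: str
    element: str
    x: float
    y: float
    z: float
    occupancy: float = 1.0
    b_value: float = 0.0

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass
class ResidueRecord:
    """One residue with its ordered atoms and the representative confidence.

    ``raw_confidence`` is the B-column value of the Calpha atom, falling back
    to the residue's first atom when no Calpha is present.  Predicted models
    write one confidence value per residue, so per-atom variation is ignored.
    """

    chain_id: str
    seq_id: int
    res_name: str
    atoms: list[AtomRecord]
    icode: str = ""

    @property
    def raw_confidence(self) -> float:
        return self.representative_atom().b_value

    def representative_atom(self) -> AtomRecord:
        for atom in self.atoms:
            if atom.name == "CA":
                return atom
        return self.atoms[0]

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_id, self.icode)


@dataclass
class PredictedModel:
    """An ordered, polymer-only view of a predicted structure.

    ``chains`` maps chain id to the ordered residue list; iteration order is
    file order.  ``source_tag`` is free-text provenance (producing program,
    conversion records appended by downstream steps).
    """

    chains: dict[str, list[ResidueRecord]] = field(default_factory=dict)
    source_tag: str = ""
    title: str | None = None

    def residues(self) -> Iterator[ResidueRecord]:
        for chain in self.chains.values():
            yield from chain

    @property
    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains.values())

    def raw_confidences(self) -> list[float]:
        return [r.raw_confidence for r in self.residues()]

    def representative_coordinates(self) -> np.ndarray:
        """(N, 3) array of Calpha (else first-atom) coordinates, file order."""
        return np.array([r.representative_atom().xyz for r in self.residues()])

    def has_calpha(self) -> list[bool]:
        return [any(a.name == "CA" for a in r.atoms) for r in self.residues()]

    def copy(self) -> "PredictedModel":
        return copy.deepcopy(self)

    def subset(self, indices: Iterable[int]) -> "PredictedModel":
        """New model containing the residues at the given file-order indices."""
        wanted = set(indices)
        out: dict[str, list[ResidueRecord]] = {}
        for i, res in enumerate(self.residues()):
            if i in wanted:
                out.setdefault(res.chain_id, []).append(copy.deepcopy(res))
        return PredictedModel(chains=out, source_tag=self.source_tag, title=self.title)

    def validate(self) -> None:
        seen: set[tuple[str, int, str]] = set()
        for chain_id, residues in self.chains.items():
            prev: tuple[int, str] | None = None
            for res in residues:
                if res.chain_id != chain_id:
                    raise ValueError(
                        f"residue {res.key} filed under chain {chain_id!r}"
                    )
                if not res.atoms:
                    raise ValueError(f"residue {res.key} has no atoms")
                if res.key in seen:
                    raise ValueError(f"duplicate residue identity {res.key}")
                seen.add(res.key)
                this = (res.seq_id, res.icode)
                if prev is not None and this <= prev:
                    raise ValueError(
                        f"residue order not increasing at {res.key} in chain {chain_id!r}"
                    )
                prev = this


@dataclass
class PAEMatrix:
    """L x L predicted-aligned-error matrix in Angstrom.

    Entry (i, j) is the expected positional error of residue i when the
    prediction is aligned on residue j; rows/columns index residues in model
    file order.  The matrix need not be symmetric.
    """

    values: np.ndarray
    max_pae: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError(f"inconsistent PAE: shape {self.values.shape} is not square")
        if np.any(self.values < 0):
            raise ValueError("invalid PAE value: negative entry")
        if self.max_pae is not None and np.any(self.values > self.max_pae + 1e-9):
            raise ValueError("invalid PAE value: entry exceeds max_pae")

    @property
    def size(self) -> int:
        return self.values.shape[0]

    def symmetrized(self) -> np.ndarray:
        return (self.values + self.values.T) / 2.0


# ---------------------------------------------------------------------------
# reading


def _read_text(source: Source) -> str:
    if isinstance(source, (str, Path)):
        return Path(source).read_text()
    data = source.read()
    if isinstance(data, bytes):
        return data.decode("utf-8", errors="replace")
    return data


def _detect_format(text: str) -> str:
    return "mmcif" if text.lstrip().startswith("data_") else "pdb"


def read_model(source: Source, format: str = "auto") -> PredictedModel:
    """Read a predicted model from a PDB or mmCIF file path or stream.

    Polymer atoms only: HETATM records and waters are dropped, as are altloc
    variants other than blank/'A'.  Only the first model of a multi-model
    file is read.  ``format='auto'`` decides by the leading bytes (``data_``
    means mmCIF).

    Raises
    ------
    ValueError
        "no atoms" for empty or polymer-free input, "malformed input" when
        the file cannot be parsed.
    """
    text = _read_text(source)
    if format == "auto":
        format = _detect_format(text)
    if format not in ("pdb", "mmcif"):
        raise ValueError(f"unknown format {format!r}")
    try:
        if format == "pdb":
            structure = gemmi.read_pdb_string(text)
        else:
            block = gemmi.cif.read_string(text).sole_block()
            structure = gemmi.make_structure_from_block(block)
    except Exception as exc:  # gemmi raises RuntimeError/ValueError with location info
        raise ValueError(f"malformed input: {exc}") from exc
    if len(structure) == 0:
        raise ValueError("no atoms: input contains no model")

    title = structure.name or None
    model = PredictedModel(source_tag=f"read:{format}", title=title)
    first = structure[0]
    for chain in first:
        residues: list[ResidueRecord] = []
        for res in chain:
            if res.het_flag == "H" or res.is_water():
                continue
            atoms: list[AtomRecord] = []
            for atom in res:
                if atom.altloc not in ("", "\x00", "A"):
                    continue
                atoms.append(
                    AtomRecord(
                        name=atom.name,
                        element=atom.element.name,
                        x=atom.pos.x,
                        y=atom.pos.y,
                        z=atom.pos.z,
                        occupancy=atom.occ,
                        b_value=atom.b_iso,
                    )
                )
            if not atoms:
                continue
            residues.append(
                ResidueRecord(
                    chain_id=chain.name,
                    seq_id=res.seqid.num,
                    icode=res.seqid.icode.strip(),
                    res_name=res.name,
                    atoms=atoms,
                )
            )
        if residues:
            model.chains[chain.name] = residues
    if model.n_residues == 0:
        raise ValueError("no atoms: input contains no polymer atoms")
    model.validate()
    return model


# ---------------------------------------------------------------------------
# writing

# PDB %8.3f coordinate field bounds
_PDB_COORD_MIN, _PDB_COORD_MAX = -999.999, 9999.999


def _to_gemmi(model: PredictedModel) -> gemmi.Structure:
    structure = gemmi.Structure()
    structure.name = model.title or ""
    gmodel = gemmi.Model("1")
    for chain_id, residues in model.chains.items():
        gchain = gemmi.Chain(chain_id)
        for res in residues:
            gres = gemmi.Residue()
            gres.name = res.res_name
            gres.seqid = gemmi.SeqId(res.seq_id, res.icode or " ")
            gres.het_flag = "A"
            for atom in res.atoms:
                gatom = gemmi.Atom()
                gatom.name = atom.name
                gatom.element = gemmi.Element(atom.element)
                gatom.pos = gemmi.Position(atom.x, atom.y, atom.z)
                gatom.occ = atom.occupancy
                gatom.b_iso = atom.b_value
                gres.add_atom(gatom)
            gchain.add_residue(gres)
        gmodel.add_chain(gchain)
    structure.add_model(gmodel)
    structure.setup_entities()
    return structure


def write_model(model: PredictedModel, format: str = "pdb") -> str:
    """Serialize a model to PDB (fixed columns, B as %6.2f) or mmCIF text."""
    if model.n_residues == 0:
        raise ValueError("no atoms: model is empty")
    if format not in ("pdb", "mmcif"):
        raise ValueError(f"unknown format {format!r}")
    if format == "pdb":
        for res in model.residues():
            for atom in res.atoms:
                for c in (atom.x, atom.y, atom.z):
                    if not (_PDB_COORD_MIN <= c <= _PDB_COORD_MAX):
                        raise ValueError(
                            "unrepresentable in PDB: coordinate "
                            f"{c:g} outside fixed-width columns (use mmCIF)"
                        )
    structure = _to_gemmi(model)
    if format == "pdb":
        return structure.make_pdb_string()
    return structure.make_mmcif_document().as_string()


# ---------------------------------------------------------------------------
# PAE JSON


def _unwrap(obj):
    # AFDB serves both bare objects and single-element list wrappers
    if isinstance(obj, list) and len(obj) == 1 and isinstance(obj[0], dict):
        return obj[0]
    return obj


def _dense_from_pairs(r1, r2, dist) -> np.ndarray:
    if not (len(r1) == len(r2) == len(dist)):
        raise ValueError("inconsistent PAE: pair list lengths differ")
    n_pairs = len(dist)
    size = int(round(np.sqrt(n_pairs)))
    if size * size != n_pairs:
        raise ValueError("inconsistent PAE: pair count is not a perfect square")
    values = np.full((size, size), np.nan)
    for i, j, d in zip(r1, r2, dist):
        i, j = int(i) - 1, int(j) - 1
        if not (0 <= i < size and 0 <= j < size):
            raise ValueError("inconsistent PAE: residue index out of range")
        values[i, j] = d
    if np.isnan(values).any():
        raise ValueError("inconsistent PAE: incomplete pair coverage")
    return values


def read_pae_json(source: Source) -> PAEMatrix:
    """Parse a PAE matrix from JSON in any of the common dialects.

    Supported dialects: flat pair lists keyed ``residue1``/``residue2``/
    ``distance`` (1-based indices, full L^2 coverage required); nested lists
    keyed ``predicted_aligned_error`` with optional
    ``max_predicted_aligned_error``; nested lists under a single ``pae`` key.
    """
    text = _read_text(source)
    try:
        obj = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed input: {exc}") from exc
    obj = _unwrap(obj)
    if not isinstance(obj, dict):
        raise ValueError("unknown PAE dialect: top-level JSON is not an object")

    if {"residue1", "residue2", "distance"} <= obj.keys():
        values = _dense_from_pairs(obj["residue1"], obj["residue2"], obj["distance"])
        max_pae = obj.get("max_predicted_aligned_error")
    elif "predicted_aligned_error" in obj:
        values = np.asarray(obj["predicted_aligned_error"], dtype=float)
        max_pae = obj.get("max_predicted_aligned_error")
    elif "pae" in obj:
        values = np.asarray(obj["pae"], dtype=float)
        max_pae = obj.get("max_pae")
    else:
        raise ValueError(f"unknown PAE dialect: keys {sorted(obj.keys())}")

    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError(f"inconsistent PAE: shape {values.shape} is not square")
    return PAEMatrix(values=values, max_pae=max_pae)


def write_pae_json(pae: PAEMatrix, dialect: str = "nested") -> str:
    """Serialize a PAE matrix into one of the supported JSON dialects.

    ``dialect``: "pairs" (flat residue1/residue2/distance lists), "nested"
    (predicted_aligned_error), or "pae" (single "pae" key).
    """
    values = pae.values
    n = pae.size
    max_pae = pae.max_pae if pae.max_pae is not None else float(values.max())
    if dialect == "pairs":
        r1, r2, dist = [], [], []
        for i in range(n):
            for j in range(n):
                r1.append(i + 1)
                r2.append(j + 1)
                dist.append(float(values[i, j]))
        obj = [{
            "residue1": r1,
            "residue2": r2,
            "distance": dist,
            "max_predicted_aligned_error": max_pae,
        }]
    elif dialect == "nested":
        obj = {
            "predicted_aligned_error": values.tolist(),
            "max_predicted_aligned_error": max_pae,
        }
    elif dialect == "pae":
        obj = {"pae": values.tolist()}
    else:
        raise ValueError(f"unknown PAE dialect {dialect!r}")
    return json.dumps(obj)


# ---------------------------------------------------------------------------
# AlphaFold database URL conventions


def afdb_entry_urls(uniprot_id: str, version: int = 4) -> dict[str, str]:
    """Deterministic AlphaFold-database download URLs for a UniProt accession.

    Follows the AFDB file-naming convention
    ``AF-<accession>-F1-model_v<version>.<ext>`` and the matching
    ``predicted_aligned_error`` JSON.  Purely string construction; no network
    access is performed.
    """
    if not _UNIPROT_RE.match(uniprot_id or ""):
        raise ValueError(f"invalid accession: {uniprot_id!r}")
    if version < 1:
        raise ValueError(f"invalid version {version}")
    stem = f"{AFDB_BASE_URL}/AF-{uniprot_id}-F1"
    return {
        "model_pdb": f"{stem}-model_v{version}.pdb",
        "model_cif": f"{stem}-model_v{version}.cif",
        "pae_json": f"{stem}-predicted_aligned_error_v{version}.json",
    }
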