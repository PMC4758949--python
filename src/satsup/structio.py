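"""Structure and table I/O.

Reads protein structures from PDB files into a lightweight residue-level
data model (heavy atoms only by default, one conformer per atom, author
numbering preserved) and writes them back out.  Also reads the tabular
inputs the pipeline consumes: per-mutant read counts across expression
levels, precomputed MS_seq tables, residue-pair lists, and melt curves.

Heteroatoms, waters and ligands are skipped on read: every downstream
distance is inter-residue.  Non-standard residues are kept but mapped to
the one-letter code ``'X'`` and excluded from centroid/contact operations
by the geometry layer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


class PdbParseError(ValueError):
    """Raised when a PDB file cannot be parsed."""


class EmptyStructureError(ValueError):
    """Raised when a structure contains no protein residues."""


class SchemaError(ValueError):
    """Raised when a tabular input is missing a required column."""


@dataclass
class Atom:
    """A heavy atom: name, element, coordinates in Angstrom."""

    name: str
    element: str
    coords: np.ndarray
    altloc: str = ""
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")
        if not self.element:
            self.element = _element_from_name(self.name)


@dataclass
class Residue:
    """One residue: chain id, author sequence number, one-letter code, atoms."""

    chain_id: str
    seq_num: int
    icode: str
    aa: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_num, self.icode)

    @property
    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.element not in ("H", "D")]

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coords_array(self) -> np.ndarray:
        return np.array([a.coords for a in self.heavy_atoms], dtype=float)


@dataclass
class StructureModel:
    """One pose of a structure: residues ordered by chain."""

    model_index: int
    residues: list[Residue] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [r.key for r in self.residues]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate (chain, seq_num, icode) in model")

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.residues:
            seen.setdefault(r.chain_id, None)
        return list(seen)

    def residue(self, chain_id: str, seq_num: int, icode: str = "") -> Residue | None:
        for r in self.residues:
            if r.key == (chain_id, seq_num, icode):
                return r
        return None

    def residues_at(self, seq_num: int, chains: list[str] | None = None) -> list[Residue]:
        """All residues with the given author number, across chains.

        The same position of a homo-oligomer occurs once per protomer;
        pairwise distances are minimised over these copies downstream.
        """
        out = [r for r in self.residues if r.seq_num == seq_num]
        if chains is not None:
            out = [r for r in out if r.chain_id in chains]
        return out

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)


@dataclass
class StructureEnsemble:
    """A (possibly multi-model) structure plus helix annotations."""

    id: str
    models: list[StructureModel]
    helices: list[tuple[str, int, int]] = field(default_factory=list)

    @property
    def first(self) -> StructureModel:
        return self.models[0]

    @property
    def n_models(self) -> int:
        return len(self.models)


def _element_from_name(name: str) -> str:
    stripped = name.strip()
    if not stripped:
        raise ValueError("cannot infer element from empty atom name")
    if stripped[0].isdigit():
        stripped = stripped.lstrip("0123456789")
    # two-letter elements in proteins are rare; single letter is the norm
    return stripped[0].upper()


def _resolve_altlocs(atoms: list[Atom]) -> list[Atom]:
    """Keep one conformer per atom name: highest occupancy, first on tie."""
    by_name: dict[str, Atom] = {}
    for a in atoms:
        prev = by_name.get(a.name)
        if prev is None or a.occupancy > prev.occupancy:
            by_name[a.name] = a
    return list(by_name.values())


def read_pdb(path: str | Path, hydrogen_policy: str = "drop") -> StructureEnsemble:
    """Read a PDB file into a :class:`StructureEnsemble`.

    All MODEL blocks are returned (a single implicit model if none).
    HELIX records populate ``helices``.  Alternate locations are resolved
    to the highest-occupancy conformer (first listed wins ties).
    Hydrogens are dropped unless ``hydrogen_policy="keep"``.  Waters,
    ligands and other heteroatoms are skipped.
    """
    path = Path(path)
    if hydrogen_policy not in ("drop", "keep"):
        raise ValueError(f"unknown hydrogen_policy {hydrogen_policy!r}")
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:  # gemmi names the bad line
        raise PdbParseError(f"{path}: {exc}") from exc
    st.setup_entities()

    helices: list[tuple[str, int, int]] = []
    for h in st.helices:
        helices.append(
            (h.start.chain_name, h.start.res_id.seqid.num, h.end.res_id.seqid.num)
        )

    models: list[StructureModel] = []
    for mi, gm in enumerate(st, start=1):
        residues: list[Residue] = []
        for chain in gm:
            for gres in chain:
                if gres.is_water():
                    continue
                resname = gres.name.upper()
                aa = THREE_TO_ONE.get(resname)
                if aa is None:
                    if gres.het_flag == "H":
                        continue  # ligand / modified hetero group
                    aa = "X"
                    logger.warning(
                        "non-standard residue %s %s%d mapped to 'X'",
                        resname, chain.name, gres.seqid.num,
                    )
                atoms = []
                for ga in gres:
                    if hydrogen_policy == "drop" and ga.element.name in ("H", "D"):
                        continue
                    atoms.append(
                        Atom(
                            name=ga.name,
                            element=ga.element.name or "",
                            coords=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                            altloc=ga.altloc if ga.altloc != "\x00" else "",
                            occupancy=ga.occ,
                        )
                    )
                atoms = _resolve_altlocs(atoms)
                if not atoms:
                    continue
                residues.append(
                    Residue(
                        chain_id=chain.name,
                        seq_num=gres.seqid.num,
                        icode=gres.seqid.icode.strip(),
                        aa=aa,
                        atoms=atoms,
                    )
                )
        if residues:
            models.append(StructureModel(model_index=mi, residues=residues))

    if not models:
        raise EmptyStructureError(f"{path}: no protein residues found")
    return StructureEnsemble(id=st.name or path.stem, models=models, helices=helices)


def write_pdb(ensemble: StructureEnsemble, path: str | Path) -> None:
    """Write an ensemble as PDB text.

    MODEL/ENDMDL records are emitted iff the ensemble holds more than one
    model; coordinates are written at 3 decimals.
    """
    if not ensemble.models:
        raise ValueError("cannot write an empty ensemble")
    lines: list[str] = []
    for chain_id, start, end in ensemble.helices:
        lines.append(
            f"HELIX    1   1 ALA {chain_id} {start:4d}  ALA {chain_id} {end:4d}  1"
            f"{'':30}{end - start + 1:6d}"
        )
    multi = len(ensemble.models) > 1
    for model in ensemble.models:
        if multi:
            lines.append(f"MODEL     {model.model_index:4d}")
        serial = 1
        prev_chain = None
        for res in ensemble_residues_in_order(model):
            if prev_chain is not None and res.chain_id != prev_chain:
                lines.append("TER")
            prev_chain = res.chain_id
            resname = ONE_TO_THREE.get(res.aa, "UNK")
            for atom in res.atoms:
                name = atom.name
                if len(name) < 4 and len(atom.element) == 1:
                    name = " " + name
                x, y, z = atom.coords
                lines.append(
                    f"ATOM  {serial:5d} {name:<4s} {resname:>3s} {res.chain_id:1s}"
                    f"{res.seq_num:4d}{res.icode or ' ':1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
                    f"          {atom.element:>2s}"
                )
                serial += 1
        lines.append("TER")
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def ensemble_residues_in_order(model: StructureModel) -> list[Residue]:
    return model.residues


_SCHEMAS = {
    "read_counts": {"position", "wt_aa", "mut_aa"},
    "ms_seq": {"position", "wt_aa", "mut_aa", "ms_seq"},
    "pairs": {"pos_x", "pos_y"},
    "melt": {"temperature_C", "signal"},
}


def read_table(path: str | Path, schema: str):
    """Read a TSV/CSV input file against a named schema.

    Schemas: ``read_counts`` (position, wt_aa, mut_aa, mid_<k>...),
    ``ms_seq`` (position, wt_aa, mut_aa, ms_seq), ``pairs``
    (pos_x, pos_y[, chain_x, chain_y]), ``melt`` (temperature_C, signal).
    Unknown columns are preserved as annotations on the returned object.
    Returns the matching domain container.
    """
    if schema not in _SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}")
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    missing = _SCHEMAS[schema] - set(df.columns)
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s) {sorted(missing)} for schema {schema!r}"
        )
    if df.empty:
        logger.warning("%s: empty data section", path)

    if schema == "read_counts":
        from satsup.mutsens import ReadCountTable

        mid_cols = [c for c in df.columns if c.startswith("mid_")]
        if len(mid_cols) < 2 and not df.empty:
            raise SchemaError(f"{path}: need >=2 mid_<k> columns, found {mid_cols}")
        return ReadCountTable.from_frame(df)
    if schema == "ms_seq":
        from satsup.mutsens import MutSensTable

        return MutSensTable.from_frame(df)
    if schema == "pairs":
        from satsup.discrimination import ContactPairSet

        pairs = [(int(r.pos_x), int(r.pos_y)) for r in df.itertuples()]
        return ContactPairSet(pairs=pairs, annotations=df)
    if schema == "melt":
        from satsup.meltfit import MeltCurve

        return MeltCurve(
            T=df["temperature_C"].to_numpy(float),
            y=df["signal"].to_numpy(float),
        )
    raise AssertionError("unreachable")
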