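"""Readers and writers for the formats the pipeline touches.

Structures come in as PDB pocket files (ATOM/HETATM records) or FASTA
sequences, ligands as SDF / MOL2 / SMILES, and affinity labels either as
whitespace-delimited index files (one complex per line, pKd/pKi in a fixed
column) or as delimited activity tables (one measurement per row).

Parsing of the standard formats is delegated to Biopython and RDKit; this
module only adapts their output into the small domain types the rest of the
package consumes.  Readers are deliberately permissive: malformed data lines
are skipped with a logged warning and a summary count rather than aborting a
whole dataset build.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.PDB import PDBParser
from rdkit import Chem

from .errors import EmptyStructureError, FormatError, SchemaError, StructureError

logger = logging.getLogger(__name__)

# One-letter codes of the 20 standard amino acids (for FASTA flagging).
STANDARD_AA1 = set("ACDEFGHIKLMNPQRSTVWY")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Residue:
    """One residue of a structure, identified by (chain, seq number, icode).

    ``atoms`` holds ``(element, x, y, z)`` tuples in Angstrom.  Alternate
    locations have already been collapsed to a single conformer.
    """

    chain_id: str
    res_seq: int
    insertion_code: str
    res_name: str
    atoms: tuple[tuple[str, float, float, float], ...]

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.res_seq, self.insertion_code)


@dataclass
class ResidueSet:
    """All residues of one structure or pocket, in file order."""

    residues: list[Residue]
    source_id: str = ""

    def __post_init__(self) -> None:
        keys = [r.key for r in self.residues]
        if len(keys) != len(set(keys)):
            raise ValueError(f"duplicate residue identity keys in {self.source_id!r}")

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self):
        return iter(self.residues)


@dataclass
class LigandStructure:
    """A small molecule with enough of a connection table for descriptors.

    ``mol`` may be an unsanitized RDKit molecule straight from the parser;
    sanitization is the standardization chain's job.  ``raw_text`` retains the
    original record so fallback conversion can start from the source bytes.
    """

    identifier: str
    mol: Chem.Mol | None
    source_format: str  # "SDF" | "MOL2" | "SMILES"
    raw_text: str = ""

    @property
    def num_heavy_atoms(self) -> int:
        return 0 if self.mol is None else self.mol.GetNumHeavyAtoms()


@dataclass(frozen=True)
class AffinityRecord:
    """One protein-ligand pair with its activity on the -log10(molar) scale."""

    complex_or_target_id: str
    ligand_id: str
    measure_type: str  # "Ki" | "Kd"
    neg_log_affinity: float
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.measure_type not in ("Ki", "Kd"):
            raise ValueError(f"measure_type must be Ki or Kd, got {self.measure_type!r}")


# ---------------------------------------------------------------------------
# PDB pockets
# ---------------------------------------------------------------------------

def read_pocket_pdb(path: str | Path) -> ResidueSet:
    """Read a pocket (or full protein) PDB file into a :class:`ResidueSet`.

    Both ATOM and HETATM records are kept — waters, ions and modified
    residues stay in the set under their ``res_name`` and are filtered out
    only at featurization.  Alternate locations are collapsed to one atom per
    position (the alphabetically first altLoc, i.e. the one listed first in
    essentially all deposited files).  Only the first NMR model is read.
    """
    path = Path(path)
    parser = PDBParser(QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            structure = parser.get_structure(path.stem, str(path))
    except OSError:
        raise
    except Exception as exc:  # Biopython raises assorted types on garbage
        if "empty" in str(exc).lower():
            raise EmptyStructureError(f"no parsable residues in {path}") from exc
        raise FormatError(f"cannot parse PDB file {path}: {exc}") from exc

    models = list(structure)
    if not models:
        raise EmptyStructureError(f"no parsable residues in {path}")

    residues: list[Residue] = []
    for chain in models[0]:
        for res in chain:
            hetflag, res_seq, icode = res.id
            atoms = []
            for atom in res:
                if atom.is_disordered():
                    atom = atom.disordered_get_list()[0]
                x, y, z = (float(v) for v in atom.coord)
                atoms.append((str(atom.element).strip() or atom.get_name()[0], x, y, z))
            if atoms:
                residues.append(
                    Residue(
                        chain_id=str(chain.id),
                        res_seq=int(res_seq),
                        insertion_code=icode.strip(),
                        res_name=res.get_resname().strip(),
                        atoms=tuple(atoms),
                    )
                )
    if not residues:
        raise EmptyStructureError(f"no parsable residues in {path}")
    return ResidueSet(residues=residues, source_id=path.stem)


def pocket_pdb_text(rs: ResidueSet) -> str:
    """Render a ResidueSet as minimal but valid ATOM records."""
    lines = []
    serial = 1
    for res in rs:
        for i, (element, x, y, z) in enumerate(res.atoms, start=1):
            name = f"{element}{i}"[:4]
            lines.append(
                f"ATOM  {serial:5d} {name:<4s}{res.res_name:>4s}"
                f"{res.chain_id[:1] or 'A':>2s}{res.res_seq:4d}{res.insertion_code[:1] or ' ':1s}"
                f"   {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {element:>2s}"
            )
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_pocket_pdb(rs: ResidueSet, path: str | Path) -> None:
    Path(path).write_text(pocket_pdb_text(rs))


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA records as ``(id, upper-cased sequence)`` in file order.

    Letters outside the 20 standard one-letter codes are preserved in the
    sequence but reported with a logged warning; composition counting
    excludes them later.
    """
    path = Path(path)
    text = path.read_text()
    if text.strip() and not text.lstrip().startswith(">"):
        raise FormatError(f"{path}: FASTA file must start with a '>' header line")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        odd = sorted({c for c in seq if c not in STANDARD_AA1})
        if odd:
            logger.warning(
                "%s: sequence %s contains %d non-standard letter(s): %s",
                path, rec.id, sum(seq.count(c) for c in odd), "".join(odd),
            )
        records.append((rec.id, seq))
    return records


def write_fasta(records: list[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n{seq}\n")


# ---------------------------------------------------------------------------
# index files
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IndexDialect:
    """Column layout of a whitespace-delimited affinity index file.

    The default matches the PDBbind v2016 layout: ``code resolution year
    -log(Kd/Ki) Kd/Ki-annotation ...`` with ``#`` comment lines.
    """

    code_col: int = 0
    value_col: int = 3
    measure_col: int | None = 4


def _measure_from_token(token: str | None) -> str:
    if token is None:
        return "Kd"
    t = token.strip()
    if t[:2].lower() == "ki":
        return "Ki"
    if t[:2].lower() == "kd":
        return "Kd"
    return "Kd"


def read_index(path: str | Path, dialect: IndexDialect = IndexDialect()) -> list[AffinityRecord]:
    """Read a PDBbind-style index file into affinity records.

    Lines starting with ``#`` are comments.  A line whose affinity field is
    not numeric (or that is too short) is skipped with a logged warning; a
    summary count of skipped lines is logged at the end.
    """
    path = Path(path)
    records: list[AffinityRecord] = []
    n_skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            try:
                code = fields[dialect.code_col]
                value = float(fields[dialect.value_col])
                token = (
                    fields[dialect.measure_col]
                    if dialect.measure_col is not None and dialect.measure_col < len(fields)
                    else None
                )
            except (IndexError, ValueError) as exc:
                logger.warning("%s line %d skipped: %s", path, lineno, exc)
                n_skipped += 1
                continue
            records.append(
                AffinityRecord(
                    complex_or_target_id=code,
                    ligand_id=code,
                    measure_type=_measure_from_token(token),
                    neg_log_affinity=value,
                    provenance=f"{path.name}:{lineno}",
                )
            )
    if n_skipped:
        logger.warning("%s: skipped %d malformed line(s)", path, n_skipped)
    return records


def write_index(records: list[AffinityRecord], path: str | Path) -> None:
    """Write records in the default index dialect (round-trips read_index)."""
    with open(path, "w") as fh:
        fh.write("# code  resolution  year  -logKd/Ki  Kd/Ki\n")
        for r in records:
            fh.write(
                f"{r.complex_or_target_id}  2.00  2020  {r.neg_log_affinity:.6f}"
                f"  {r.measure_type}=1nM\n"
            )


# ---------------------------------------------------------------------------
# ligand structures
# ---------------------------------------------------------------------------

_EXT_TO_FORMAT = {
    ".sdf": "SDF", ".mol": "SDF", ".mol2": "MOL2",
    ".smi": "SMILES", ".smiles": "SMILES",
}


def read_ligand(path: str | Path, format_hint: str | None = None) -> LigandStructure:
    """Read one ligand structure, deferring sanitization to standardization.

    The format is taken from ``format_hint`` (``"SDF"``, ``"MOL2"`` or
    ``"SMILES"``) or auto-detected from the file extension.  A structure whose
    connection table cannot be parsed at all raises :class:`StructureError`
    carrying the raw text, which the standardization chain can still feed to
    its conversion fallback.
    """
    path = Path(path)
    fmt = (format_hint or _EXT_TO_FORMAT.get(path.suffix.lower(), "")).upper()
    if fmt not in ("SDF", "MOL2", "SMILES"):
        raise FormatError(f"cannot determine ligand format for {path}")
    raw = path.read_text()
    return parse_ligand_text(raw, fmt, identifier=path.stem)


def parse_ligand_text(raw: str, fmt: str, identifier: str = "") -> LigandStructure:
    """Parse ligand text in the given format without sanitizing."""
    mol: Chem.Mol | None = None
    name = identifier
    if fmt == "SDF":
        block = raw.split("$$$$")[0]
        mol = Chem.MolFromMolBlock(block, sanitize=False, removeHs=False)
        if mol is not None and mol.HasProp("_Name") and mol.GetProp("_Name").strip():
            name = mol.GetProp("_Name").strip()
    elif fmt == "MOL2":
        mol = Chem.MolFromMol2Block(raw, sanitize=False, removeHs=False)
        if mol is not None and mol.HasProp("_Name") and mol.GetProp("_Name").strip():
            name = mol.GetProp("_Name").strip()
    elif fmt == "SMILES":
        line = next((ln for ln in raw.splitlines() if ln.strip()), "")
        parts = line.split()
        if parts:
            mol = Chem.MolFromSmiles(parts[0], sanitize=False)
            if len(parts) > 1:
                name = parts[1]
    else:
        raise FormatError(f"unsupported ligand format {fmt!r}")
    if mol is None or mol.GetNumHeavyAtoms() == 0:
        raise StructureError(
            f"unparsable {fmt} structure {identifier or '<text>'}", payload=raw
        )
    return LigandStructure(identifier=name or "ligand", mol=mol,
                           source_format=fmt, raw_text=raw)


# ---------------------------------------------------------------------------
# activity tables
# ---------------------------------------------------------------------------

ACTIVITY_COLUMNS = ("target_id", "ligand_id", "smiles", "measure_type", "value", "unit")


def read_activity_table(path: str | Path) -> pd.DataFrame:
    """Read a delimited activity table, preserving row order.

    Row order is load-bearing: keep-last deduplication retains the final
    record per protein-ligand pair in source order.  Extra columns are kept
    but ignored downstream; a missing required column raises SchemaError.
    """
    path = Path(path)
    sep = {".csv": ",", ".tsv": "\t"}.get(path.suffix.lower())
    if sep is None:
        df = pd.read_csv(path, sep=None, engine="python")
    else:
        df = pd.read_csv(path, sep=sep)
    missing = [c for c in ACTIVITY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    return df.reset_index(drop=True)


def write_activity_table(df: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in ACTIVITY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"activity table missing column(s): {', '.join(missing)}")
    df.to_csv(path, index=False)
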