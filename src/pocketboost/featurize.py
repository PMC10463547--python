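"""Feature computation: amino-acid composition and ligand descriptors.

The protein side of the model input is deliberately minimal: a 20-element
vector counting how often each standard amino acid occurs in the binding
pocket (or, for the sequence-homology probe, in the full chain).  Residue
order and geometry are discarded entirely.  The ligand side is a fixed,
ordered set of 18 scalar physicochemical/topological descriptors computed by
RDKit from the connection table.  Concatenation gives the 38-feature model
input.

The descriptor registry is configurable.  The shipped default of 18
descriptors is a standard physicochemical/topological panel chosen by this
package (molecular weight, cLogP, TPSA, H-bond donors/acceptors, rotatable
bonds, ring counts, heavy atoms, fraction sp3, formal charge, molar
refractivity and topological indices); it is a documented package default,
not a canonical list taken from elsewhere.
"""

from __future__ import annotations

import hashlib
import logging
import math
from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, GraphDescriptors, Lipinski, rdMolDescriptors

from .errors import FeatureError, SchemaError
from .io import LigandStructure, Residue, ResidueSet

logger = logging.getLogger(__name__)

# The 20 standard amino acids, alphabetical by three-letter code.  This fixed
# order defines the composition block of the feature schema.
STANDARD_AA3: tuple[str, ...] = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)
AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}
# One-letter codes in the same (three-letter alphabetical) order.
STANDARD_AA1_ORDERED: tuple[str, ...] = tuple(AA3_TO_1[a] for a in STANDARD_AA3)

COMPOSITION_NAMES: tuple[str, ...] = tuple(f"aa_{a}" for a in STANDARD_AA3)

DEFAULT_POCKET_CUTOFF = 10.0  # Angstrom; residues within this of the ligand


# ---------------------------------------------------------------------------
# descriptor registry
# ---------------------------------------------------------------------------

DESCRIPTOR_REGISTRY: dict[str, callable] = {
    "MolWt": Descriptors.MolWt,
    "MolLogP": Crippen.MolLogP,
    "MolMR": Crippen.MolMR,
    "TPSA": rdMolDescriptors.CalcTPSA,
    "NumHDonors": Lipinski.NumHDonors,
    "NumHAcceptors": Lipinski.NumHAcceptors,
    "NumRotatableBonds": Lipinski.NumRotatableBonds,
    "HeavyAtomCount": lambda m: m.GetNumHeavyAtoms(),
    "NumHeteroatoms": Lipinski.NumHeteroatoms,
    "RingCount": Lipinski.RingCount,
    "NumAromaticRings": Lipinski.NumAromaticRings,
    "NumSaturatedRings": Lipinski.NumSaturatedRings,
    "NumAliphaticRings": Lipinski.NumAliphaticRings,
    "FractionCSP3": Lipinski.FractionCSP3,
    "FormalCharge": Chem.GetFormalCharge,
    "BalabanJ": GraphDescriptors.BalabanJ,
    "BertzCT": GraphDescriptors.BertzCT,
    "Kappa2": rdMolDescriptors.CalcKappa2,
}

#: Default ordered 18-descriptor panel (registry insertion order).
DEFAULT_DESCRIPTOR_SET: tuple[str, ...] = tuple(DESCRIPTOR_REGISTRY)
assert len(DEFAULT_DESCRIPTOR_SET) == 18


# ---------------------------------------------------------------------------
# vector types
# ---------------------------------------------------------------------------

@dataclass
class CompositionVector:
    """Counts (or means) of the 20 standard amino acids, fixed order."""

    values: np.ndarray  # shape (20,)
    source_kind: str  # "pocket_file" | "computed_pocket" | "full_chain"
    n_excluded_nonstandard: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (20,):
            raise SchemaError(f"composition vector must have 20 entries, got {self.values.shape}")
        if (self.values < 0).any():
            raise SchemaError("composition counts must be non-negative")

    @property
    def names(self) -> tuple[str, ...]:
        return COMPOSITION_NAMES


@dataclass
class DescriptorVector:
    """Named ligand descriptor values, names and values aligned."""

    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.names = tuple(self.names)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != len(self.values):
            raise SchemaError("descriptor names and values misaligned")


@dataclass
class FeatureVector:
    """Composition block followed by descriptor block; 38 with defaults."""

    feature_names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.feature_names = tuple(self.feature_names)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.feature_names) != len(self.values):
            raise SchemaError("feature names and values misaligned")

    def __len__(self) -> int:
        return len(self.values)


def schema_hash(feature_names: Sequence[str]) -> str:
    """Stable hash of the feature ordering; guards against schema mixups."""
    return hashlib.sha256("\x1f".join(feature_names).encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

def aa_composition_from_residues(
    rs: ResidueSet | Sequence[Residue], source_kind: str = "pocket_file"
) -> CompositionVector:
    """Count standard residues; waters, ions, modified residues are excluded.

    The exclusions are tallied in ``n_excluded_nonstandard`` so that
    ``sum(values) + n_excluded == total residues scanned`` always holds.
    """
    counts = dict.fromkeys(STANDARD_AA3, 0)
    excluded = 0
    residues = rs.residues if isinstance(rs, ResidueSet) else list(rs)
    for res in residues:
        name = res.res_name.upper()
        if name in counts:
            counts[name] += 1
        else:
            excluded += 1
    if not residues:
        logger.warning("empty residue set: zero composition vector")
    return CompositionVector(
        values=np.array([counts[a] for a in STANDARD_AA3], dtype=float),
        source_kind=source_kind,
        n_excluded_nonstandard=excluded,
    )


def aa_composition_from_sequence(seq: str) -> CompositionVector:
    """Count standard one-letter codes over a full protein chain."""
    counts = dict.fromkeys(STANDARD_AA1_ORDERED, 0)
    excluded = 0
    for ch in seq.upper():
        if ch in counts:
            counts[ch] += 1
        else:
            excluded += 1
    if not seq:
        logger.warning("empty sequence: zero composition vector")
    return CompositionVector(
        values=np.array([counts[a] for a in STANDARD_AA1_ORDERED], dtype=float),
        source_kind="full_chain",
        n_excluded_nonstandard=excluded,
    )


def extract_pocket(
    protein: ResidueSet,
    ligand_atoms: Sequence[tuple[float, float, float]],
    cutoff: float = DEFAULT_POCKET_CUTOFF,
) -> ResidueSet:
    """Residues whose closest heavy atom is within ``cutoff`` A of the ligand.

    Distances use heavy atoms only (hydrogens are typically absent from
    deposited coordinates anyway); the cutoff is inclusive.
    """
    if not len(protein):
        raise ValueError("protein residue set is empty")
    lig = np.asarray(ligand_atoms, dtype=float)
    if lig.size == 0:
        raise ValueError("ligand coordinate list is empty")
    if lig.ndim != 2 or lig.shape[1] != 3:
        raise ValueError("ligand_atoms must be an (n, 3) coordinate list")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    kept = []
    for res in protein:
        coords = np.array(
            [(x, y, z) for el, x, y, z in res.atoms if el.upper() != "H"], dtype=float
        )
        if coords.size == 0:
            continue
        d2 = ((coords[:, None, :] - lig[None, :, :]) ** 2).sum(axis=2)
        if d2.min() <= cutoff * cutoff:
            kept.append(res)
    return ResidueSet(residues=kept, source_id=protein.source_id)


def mean_composition(vs: Sequence[CompositionVector]) -> CompositionVector:
    """Element-wise mean composition over several structures of one protein."""
    if not vs:
        raise ValueError("mean_composition needs at least one vector")
    kinds = {v.source_kind for v in vs}
    if len(kinds) > 1:
        raise ValueError(f"cannot average mixed source kinds: {sorted(kinds)}")
    stacked = np.stack([v.values for v in vs])
    return CompositionVector(
        values=stacked.mean(axis=0),
        source_kind=vs[0].source_kind,
        n_excluded_nonstandard=int(round(np.mean([v.n_excluded_nonstandard for v in vs]))),
    )


# ---------------------------------------------------------------------------
# ligand descriptors
# ---------------------------------------------------------------------------

def ligand_descriptors(
    mol: LigandStructure | Chem.Mol,
    descriptor_set: Sequence[str] = DEFAULT_DESCRIPTOR_SET,
) -> DescriptorVector:
    """Compute the named descriptors, in order, from a standardized molecule."""
    rdmol = mol.mol if isinstance(mol, LigandStructure) else mol
    if rdmol is None:
        raise FeatureError("ligand has no parsed molecule")
    values = []
    for name in descriptor_set:
        try:
            fn = DESCRIPTOR_REGISTRY[name]
        except KeyError:
            raise SchemaError(f"unknown descriptor {name!r}") from None
        try:
            v = float(fn(rdmol))
        except Exception as exc:
            raise FeatureError(f"descriptor {name} failed: {exc}") from exc
        if not math.isfinite(v):
            raise FeatureError(f"descriptor {name} returned a non-finite value")
        values.append(v)
    return DescriptorVector(names=tuple(descriptor_set), values=np.array(values))


def combine(comp: CompositionVector, desc: DescriptorVector) -> FeatureVector:
    """Concatenate composition block then descriptor block into model input."""
    names = comp.names + desc.names
    return FeatureVector(
        feature_names=names,
        values=np.concatenate([comp.values, desc.values]),
    )


def block_columns(feature_names: Sequence[str], block: str) -> np.ndarray:
    """Column indices for a feature block: protein_only, ligand_only, combined."""
    names = list(feature_names)
    is_protein = np.array([n.startswith("aa_") for n in names])
    if block == "protein_only":
        idx = np.flatnonzero(is_protein)
    elif block == "ligand_only":
        idx = np.flatnonzero(~is_protein)
    elif block == "combined":
        idx = np.arange(len(names))
    else:
        raise ValueError(f"unknown feature block {block!r}")
    if idx.size == 0:
        raise SchemaError(f"feature schema has no columns for block {block!r}")
    return idx
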