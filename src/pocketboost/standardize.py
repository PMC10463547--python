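"""Ligand standardization as an ordered fallback chain.

Most ligands pass the native RDKit sanitization directly.  Structures the
toolkit rejects (bad valences, odd aromatic perception) can be rescued in two
ways: a remote standardization web service (off by default — every default
code path is network-free), or conversion to SYBYL MOL2 via the Open Babel
command-line tool followed by a re-read, which lets Open Babel's more lenient
typing assign charges/bond orders that RDKit then accepts.

Stage ``i+1`` runs only when stage ``i`` failed; the outcome records exactly
which stage succeeded.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
import tempfile
import urllib.parse
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path

from rdkit import Chem

from .errors import StandardizationError
from .io import LigandStructure

logger = logging.getLogger(__name__)

STAGE_NATIVE = "native_sanitize"
STAGE_REMOTE = "remote_service"
STAGE_MOL2 = "mol2_conversion"

_FORMAT_TO_OBABEL = {"SDF": "sdf", "MOL2": "mol2", "SMILES": "smi"}


@dataclass
class StandardizationConfig:
    """Which stages run, and in what order.

    ``enable_remote`` is False by default: the remote service is a dataset
    construction convenience, not a predict-time dependency, and the test
    suite never requires network access.
    """

    stage_order: tuple[str, ...] = (STAGE_NATIVE, STAGE_REMOTE, STAGE_MOL2)
    enable_remote: bool = False
    remote_url: str = (
        "https://pubchem.ncbi.nlm.nih.gov/rest/pug/standardize/smiles/record/SDF"
    )
    enable_mol2_conversion: bool = True
    timeout_s: float = 30.0


@dataclass
class StandardizationOutcome:
    ligand: LigandStructure
    stage_used: str
    notes: str = ""


def _finish(mol: Chem.Mol, raw: LigandStructure, fmt: str) -> LigandStructure:
    """Canonicalize a sanitized mol into a fresh LigandStructure."""
    smiles = Chem.MolToSmiles(mol)
    canonical = Chem.MolFromSmiles(smiles)
    return LigandStructure(
        identifier=raw.identifier, mol=canonical, source_format=fmt,
        raw_text=raw.raw_text,
    )


def _stage_native(raw: LigandStructure, cfg: StandardizationConfig) -> LigandStructure:
    if raw.mol is None:
        raise ValueError("no parsed molecule to sanitize")
    mol = Chem.Mol(raw.mol)
    Chem.SanitizeMol(mol)  # raises on valence/kekulization problems
    return _finish(mol, raw, raw.source_format)


def _stage_remote(raw: LigandStructure, cfg: StandardizationConfig) -> LigandStructure:
    if not cfg.enable_remote:
        raise RuntimeError("remote standardization disabled by configuration")
    if raw.mol is None:
        raise ValueError("remote stage needs a parsed molecule to serialize")
    smiles = Chem.MolToSmiles(raw.mol, canonical=False)
    data = urllib.parse.urlencode({"smiles": smiles}).encode()
    req = urllib.request.Request(cfg.remote_url, data=data)
    with urllib.request.urlopen(req, timeout=cfg.timeout_s) as resp:
        sdf = resp.read().decode()
    mol = Chem.MolFromMolBlock(sdf.split("$$$$")[0])
    if mol is None:
        raise ValueError("remote service returned an unparsable record")
    return _finish(mol, raw, "SDF")


def _stage_mol2(raw: LigandStructure, cfg: StandardizationConfig) -> LigandStructure:
    if not cfg.enable_mol2_conversion:
        raise RuntimeError("mol2 conversion disabled by configuration")
    obabel = shutil.which("obabel")
    if obabel is None:
        raise RuntimeError("obabel executable not found on PATH")
    if not raw.raw_text:
        raise ValueError("no raw structure text to convert")
    in_fmt = _FORMAT_TO_OBABEL[raw.source_format]
    with tempfile.TemporaryDirectory() as tmp:
        src = Path(tmp) / f"ligand.{in_fmt}"
        dst = Path(tmp) / "ligand.mol2"
        src.write_text(raw.raw_text)
        proc = subprocess.run(
            [obabel, str(src), "-O", str(dst)],
            capture_output=True, text=True, timeout=cfg.timeout_s,
        )
        if proc.returncode != 0 or not dst.exists() or not dst.stat().st_size:
            raise ValueError(f"obabel conversion failed: {proc.stderr.strip()[:200]}")
        mol2_text = dst.read_text()
    mol = Chem.MolFromMol2Block(mol2_text)  # sanitizes; infers charges from SYBYL types
    if mol is None:
        raise ValueError("converted MOL2 block still rejected by sanitization")
    return _finish(mol, raw, "MOL2")


_STAGES = {STAGE_NATIVE: _stage_native, STAGE_REMOTE: _stage_remote, STAGE_MOL2: _stage_mol2}


def standardize_ligand(
    raw: LigandStructure, config: StandardizationConfig | None = None
) -> StandardizationOutcome:
    """Run the fallback chain and return the first stage that succeeds.

    Raises :class:`StandardizationError` with every stage's failure message
    when no enabled stage produces a sanitized molecule.  The standardized
    form (canonicalized via SMILES round-trip) is always the one used for
    descriptor calculation downstream.
    """
    cfg = config or StandardizationConfig()
    failures: dict[str, str] = {}
    for stage in cfg.stage_order:
        if stage not in _STAGES:
            raise ValueError(f"unknown standardization stage {stage!r}")
        try:
            ligand = _STAGES[stage](raw, cfg)
        except Exception as exc:  # each stage reports and hands over
            failures[stage] = str(exc)
            logger.debug("stage %s failed for %s: %s", stage, raw.identifier, exc)
            continue
        return StandardizationOutcome(
            ligand=ligand, stage_used=stage,
            notes="; ".join(f"{k} failed: {v}" for k, v in failures.items()),
        )
    raise StandardizationError(failures)


def standardize_batch(
    ligands: list[LigandStructure], config: StandardizationConfig | None = None
) -> tuple[list[StandardizationOutcome], list[tuple[str, str]]]:
    """Standardize many ligands; returns (outcomes, failures).

    ``failures`` is a list of ``(identifier, message)`` suitable for the
    per-dataset incompatibility report.
    """
    outcomes, failures = [], []
    for lig in ligands:
        try:
            outcomes.append(standardize_ligand(lig, config))
        except StandardizationError as exc:
            failures.append((lig.identifier, str(exc)))
    return outcomes, failures


def write_failure_report(failures: list[tuple[str, str]], path) -> None:
    """Emit the list of structures that no stage could standardize."""
    with open(path, "w") as fh:
        fh.write("# structures that failed every standardization stage\n")
        for ident, msg in failures:
            fh.write(f"{ident}\t{msg}\n")
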