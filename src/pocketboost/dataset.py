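"""Dataset assembly: CASF-style splits and curated activity-pair tables.

Two dataset archetypes are supported.  The benchmark-style build pairs each
complex in an index file with its pocket PDB and ligand file, featurizes both
sides, and labels rows train/test from a held-out core-id list.  The
activity-table build mirrors bioactivity database curation: keep only
Ki/Kd measurements, restrict to parseable small molecules under a molecular
weight ceiling, deduplicate repeated protein-ligand pairs keeping the last
record in source order, optionally drop promiscuous proteins whose ligand
count exceeds a threshold, and attach each protein's (possibly mean)
composition vector.

Every filter stage logs how many rows it removed, and the build log is
conserved: rows in + 0 = rows out + total drops.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors

from . import io as pio
from .errors import DataError, SchemaError, StandardizationError
from .featurize import (
    COMPOSITION_NAMES,
    DEFAULT_DESCRIPTOR_SET,
    CompositionVector,
    FeatureVector,
    aa_composition_from_residues,
    combine,
    ligand_descriptors,
    schema_hash,
)
from .standardize import StandardizationConfig, standardize_ligand

logger = logging.getLogger(__name__)

DEFAULT_MW_LIMIT = 700.0  # Da; ceiling for "small molecule" inclusion

_UNIT_TO_MOLAR = {
    "M": 1.0,
    "mM": 1e-3,
    "uM": 1e-6, "µM": 1e-6, "μM": 1e-6,
    "nM": 1e-9,
    "pM": 1e-12,
}


def neg_log_affinity(value: float, unit: str) -> float:
    """Convert an affinity measurement to -log10(molar), i.e. pKd/pKi."""
    try:
        factor = _UNIT_TO_MOLAR[unit.strip()]
    except (KeyError, AttributeError):
        raise ValueError(f"unknown concentration unit {unit!r}") from None
    if not (isinstance(value, (int, float)) and value > 0):
        raise ValueError(f"affinity value must be positive, got {value!r}")
    return -math.log10(value * factor)


@dataclass
class Dataset:
    """Model-ready rows: ids, one feature matrix, targets, optional splits."""

    ids: list[str]
    X: np.ndarray  # (n, d)
    y: np.ndarray  # (n,)
    feature_names: tuple[str, ...]
    split_labels: np.ndarray | None = None  # per-row label, e.g. train/test
    build_log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if len(self.ids) != len(set(self.ids)):
            raise SchemaError("dataset pair ids are not unique")
        if self.X.shape != (len(self.ids), len(self.feature_names)):
            raise SchemaError("feature matrix shape does not match ids/schema")
        if self.y.shape != (len(self.ids),):
            raise SchemaError("target vector length does not match ids")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def schema_hash(self) -> str:
        return schema_hash(self.feature_names)

    def subset(self, index: np.ndarray) -> "Dataset":
        index = np.asarray(index)
        return Dataset(
            ids=[self.ids[i] for i in index],
            X=self.X[index],
            y=self.y[index],
            feature_names=self.feature_names,
            split_labels=None if self.split_labels is None else self.split_labels[index],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=list(self.feature_names))
        df.insert(0, "pair_id", self.ids)
        df["target"] = self.y
        if self.split_labels is not None:
            df["split"] = self.split_labels
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, build_log: dict | None = None) -> "Dataset":
        feature_names = tuple(
            c for c in df.columns if c not in ("pair_id", "target", "split")
        )
        return cls(
            ids=list(df["pair_id"].astype(str)),
            X=df[list(feature_names)].to_numpy(dtype=float),
            y=df["target"].to_numpy(dtype=float),
            feature_names=feature_names,
            split_labels=df["split"].to_numpy() if "split" in df.columns else None,
            build_log=build_log or {},
        )

    @classmethod
    def from_rows(
        cls,
        rows: list[tuple[str, FeatureVector, float]],
        split_labels: list[str] | None = None,
        build_log: dict | None = None,
    ) -> "Dataset":
        if not rows:
            raise DataError("cannot build a dataset with zero rows")
        names = rows[0][1].feature_names
        for pid, fv, _ in rows:
            if fv.feature_names != names:
                raise SchemaError(f"row {pid} does not conform to the feature schema")
        return cls(
            ids=[r[0] for r in rows],
            X=np.stack([r[1].values for r in rows]),
            y=np.array([r[2] for r in rows], dtype=float),
            feature_names=names,
            split_labels=None if split_labels is None else np.asarray(split_labels),
            build_log=build_log or {},
        )


# ---------------------------------------------------------------------------
# CASF-style build
# ---------------------------------------------------------------------------

def build_casf_dataset(
    refined_index: str | Path,
    core_ids: list[str] | set[str],
    pocket_dir: str | Path,
    ligand_dir: str | Path,
    descriptor_set: tuple[str, ...] = DEFAULT_DESCRIPTOR_SET,
    standardize_config: StandardizationConfig | None = None,
) -> Dataset:
    """Featurize a refined-set index against pocket and ligand directories.

    Pocket files are expected as ``<id>_pocket.pdb`` (falling back to
    ``<id>.pdb``) and ligands as ``<id>.sdf`` / ``<id>.mol2`` / ``<id>.smi``.
    Rows whose ligand fails every standardization stage, or whose files are
    missing, are dropped and counted.  Split labels: ``test`` for ids in the
    core list, ``train`` for the remainder of the refined set.
    """
    pocket_dir, ligand_dir = Path(pocket_dir), Path(ligand_dir)
    core = set(core_ids)
    records = pio.read_index(refined_index)
    refined_ids = {r.complex_or_target_id for r in records}
    for cid in sorted(core - refined_ids):
        logger.warning("core id %s absent from refined index", cid)

    rows, labels = [], []
    log = {"n_input": len(records), "drop_missing_files": 0,
           "drop_standardization": 0, "drop_featurization": 0}
    for rec in records:
        cid = rec.complex_or_target_id
        pocket_path = pocket_dir / f"{cid}_pocket.pdb"
        if not pocket_path.exists():
            pocket_path = pocket_dir / f"{cid}.pdb"
        ligand_path = next(
            (ligand_dir / f"{cid}{ext}" for ext in (".sdf", ".mol2", ".smi")
             if (ligand_dir / f"{cid}{ext}").exists()),
            None,
        )
        if not pocket_path.exists() or ligand_path is None:
            log["drop_missing_files"] += 1
            logger.warning("missing structure files for %s", cid)
            continue
        try:
            ligand = pio.read_ligand(ligand_path)
            outcome = standardize_ligand(ligand, standardize_config)
        except (StandardizationError, Exception) as exc:
            if not isinstance(exc, (StandardizationError, pio.StructureError)):
                raise
            log["drop_standardization"] += 1
            logger.warning("ligand for %s failed standardization: %s", cid, exc)
            continue
        try:
            comp = aa_composition_from_residues(pio.read_pocket_pdb(pocket_path))
            desc = ligand_descriptors(outcome.ligand, descriptor_set)
        except Exception as exc:
            log["drop_featurization"] += 1
            logger.warning("featurization failed for %s: %s", cid, exc)
            continue
        rows.append((cid, combine(comp, desc), rec.neg_log_affinity))
        labels.append("test" if cid in core else "train")
    log["n_output"] = len(rows)
    return Dataset.from_rows(rows, split_labels=labels, build_log=log)


# ---------------------------------------------------------------------------
# activity-pair build
# ---------------------------------------------------------------------------

def apply_pair_filters(
    activities: pd.DataFrame,
    max_ligands_per_protein: int | None = None,
    mw_limit: float = DEFAULT_MW_LIMIT,
) -> tuple[pd.DataFrame, dict]:
    """Apply the curation filters in order, returning (table, drop log).

    Stages, in order: (1) keep Ki/Kd measurement types only; (2) keep rows
    whose structure parses and whose molecular weight is below ``mw_limit``;
    (3) keep-last deduplication per (target, ligand) pair in source order;
    (4) drop every protein whose surviving ligand count exceeds the
    threshold (the whole protein is removed, not subsampled).  The returned
    table gains a ``neg_log_affinity`` column and a ``mol_weight`` column.
    """
    df = activities.reset_index(drop=True).copy()
    log = {"n_input": len(df)}

    keep = df["measure_type"].astype(str).str.strip().isin(["Ki", "Kd"])
    log["drop_measure_type"] = int((~keep).sum())
    df = df[keep]

    def _mw(smiles: str) -> float:
        mol = Chem.MolFromSmiles(str(smiles))
        return float("nan") if mol is None else Descriptors.MolWt(mol)

    if "mol_weight" in df.columns:
        mw = df["mol_weight"].astype(float)
    else:
        mw = df["smiles"].map(_mw)
    ok = mw.notna() & (mw < mw_limit)
    log["drop_mw_or_unparsable"] = int((~ok).sum())
    df = df[ok].assign(mol_weight=mw[ok])

    before = len(df)
    df = df.drop_duplicates(subset=["target_id", "ligand_id"], keep="last")
    log["drop_duplicate_pairs"] = before - len(df)

    if max_ligands_per_protein is not None:
        counts = df.groupby("target_id")["ligand_id"].transform("size")
        keep = counts <= max_ligands_per_protein
        log["drop_protein_threshold"] = int((~keep).sum())
        df = df[keep]
    else:
        log["drop_protein_threshold"] = 0

    if "neg_log_affinity" in df.columns:
        pk = df["neg_log_affinity"].astype(float)
    elif df.empty:
        pk = pd.Series(dtype=float)
    else:
        pk = df.apply(lambda r: neg_log_affinity(float(r["value"]), str(r["unit"])), axis=1)
    df = df.assign(neg_log_affinity=pk)

    log["n_output"] = len(df)
    return df.reset_index(drop=True), log


def build_pair_dataset(
    activities: pd.DataFrame,
    target_compositions: dict[str, CompositionVector],
    max_ligands_per_protein: int | None = None,
    mw_limit: float = DEFAULT_MW_LIMIT,
    descriptor_set: tuple[str, ...] = DEFAULT_DESCRIPTOR_SET,
    standardize_config: StandardizationConfig | None = None,
) -> Dataset:
    """Curate an activity table and featurize the surviving pairs.

    ``target_compositions`` maps target id to its composition vector (a mean
    over structures when the protein appears more than once).  Rows whose
    target lacks a composition, or whose ligand defeats standardization, are
    dropped and logged.
    """
    df, log = apply_pair_filters(activities, max_ligands_per_protein, mw_limit)
    log["drop_missing_composition"] = 0
    log["drop_standardization"] = 0

    rows = []
    desc_cache: dict[str, object] = {}
    for _, row in df.iterrows():
        tid, lid = str(row["target_id"]), str(row["ligand_id"])
        comp = target_compositions.get(tid)
        if comp is None:
            log["drop_missing_composition"] += 1
            logger.warning("no composition for target %s; row dropped", tid)
            continue
        smiles = str(row["smiles"])
        if smiles not in desc_cache:
            try:
                lig = pio.parse_ligand_text(smiles, "SMILES", identifier=lid)
                outcome = standardize_ligand(lig, standardize_config)
                desc_cache[smiles] = ligand_descriptors(outcome.ligand, descriptor_set)
            except (StandardizationError, pio.StructureError) as exc:
                desc_cache[smiles] = None
                logger.warning("ligand %s failed standardization: %s", lid, exc)
        desc = desc_cache[smiles]
        if desc is None:
            log["drop_standardization"] += 1
            continue
        rows.append((f"{tid}:{lid}", combine(comp, desc), float(row["neg_log_affinity"])))
    log["n_output"] = len(rows)
    ds = Dataset.from_rows(rows, build_log=log)
    ds.build_log["n_proteins"] = len({pid.split(":", 1)[0] for pid in ds.ids})
    return ds
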