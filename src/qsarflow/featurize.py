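"""Molecular featurization: physicochemical descriptors and fingerprints.

Curated canonical SMILES are turned into a combined numeric feature
matrix.  Descriptors are RDKit's full standard physicochemical list;
fingerprints come in nine flavours (Morgan, feature-Morgan, atom pair,
topological torsion, RDKit path, Avalon, layered, MACCS keys, pattern).
Featurization is a pure function of (canonical structure, spec, toolkit
version): re-running yields an identical matrix.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import rdkit
from rdkit import Chem
from rdkit.Avalon import pyAvalonTools
from rdkit.Chem import Descriptors, MACCSkeys, rdFingerprintGenerator

from .errors import AlignmentError, ConfigurationError, EmptyDatasetError

logger = logging.getLogger(__name__)

FINGERPRINT_KINDS = (
    "morgan",
    "feat_morgan",
    "atom_pair",
    "torsion",
    "path",
    "avalon",
    "layered",
    "maccs",
    "pattern",
)

MACCS_NBITS = 167  # fixed key length; n_bits is ignored for maccs


@dataclass(frozen=True)
class FingerprintSpec:
    """Which fingerprint to compute and at what size.

    ``radius`` only applies to the Morgan variants; ``n_bits`` is ignored
    for MACCS keys (fixed 167-bit key set).
    """

    kind: str = "morgan"
    n_bits: int = 1024
    radius: int = 2

    def __post_init__(self) -> None:
        if self.kind not in FINGERPRINT_KINDS:
            raise ConfigurationError(
                f"unsupported fingerprint kind {self.kind!r}; choose from {FINGERPRINT_KINDS}"
            )
        if self.n_bits <= 0:
            raise ConfigurationError("n_bits must be positive")
        if self.radius < 0:
            raise ConfigurationError("radius must be non-negative")


@dataclass
class FeatureMatrix:
    """An n x p numeric feature table with per-column provenance tags.

    ``values`` is indexed by compound id; ``column_kind`` maps every column
    to ``"descriptor"`` or ``"fingerprint"``.
    """

    values: pd.DataFrame
    column_kind: pd.Series
    meta: dict = field(default_factory=dict)

    @property
    def row_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def column_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def subset_rows(self, ids) -> "FeatureMatrix":
        return FeatureMatrix(self.values.loc[list(ids)], self.column_kind, dict(self.meta))

    def subset_columns(self, names) -> "FeatureMatrix":
        names = list(names)
        missing = [c for c in names if c not in self.values.columns]
        if missing:
            raise AlignmentError(f"unknown feature columns: {missing[:5]}")
        return FeatureMatrix(self.values[names], self.column_kind[names], dict(self.meta))

    def to_csv(self, path) -> None:
        self.values.to_csv(path, index_label="compound_id")


def _mols(structures: list[str], ids: list[str] | None):
    if ids is None:
        ids = [f"row{i + 1}" for i in range(len(structures))]
    if len(ids) != len(structures):
        raise AlignmentError("ids and structures differ in length")
    out = []
    for cid, smi in zip(ids, structures):
        out.append((cid, Chem.MolFromSmiles(smi)))
    return out


def compute_descriptors(
    structures: list[str], ids: list[str] | None = None
) -> tuple[FeatureMatrix, list[tuple[str, str]]]:
    """Compute RDKit's standard physicochemical descriptor list.

    Returns the matrix plus ``(id, reason)`` rejections for structures that
    fail to parse or yield any non-finite descriptor value.
    """
    names = [name for name, _ in Descriptors._descList]
    rows, kept, rejections = [], [], []
    for cid, mol in _mols(structures, ids):
        if mol is None:
            rejections.append((cid, "invalid_structure"))
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            vals = Descriptors.CalcMolDescriptors(mol)
        vec = np.array([vals[n] for n in names], dtype=float)
        if not np.isfinite(vec).all():
            rejections.append((cid, "non_finite_descriptor"))
            continue
        rows.append(vec)
        kept.append(cid)
    if not rows:
        raise EmptyDatasetError("every structure was rejected during descriptor calculation")
    df = pd.DataFrame(np.vstack(rows), index=kept, columns=names)
    kind = pd.Series("descriptor", index=df.columns)
    meta = {"toolkit": f"rdkit-{rdkit.__version__}", "descriptor_set": "rdkit-standard"}
    if rejections:
        logger.info("descriptor stage rejected %d structures", len(rejections))
    return FeatureMatrix(df, kind, meta), rejections


def _fingerprint(mol, spec: FingerprintSpec) -> np.ndarray:
    if spec.kind in ("morgan", "feat_morgan"):
        inv = rdFingerprintGenerator.GetMorganFeatureAtomInvGen() if spec.kind == "feat_morgan" else None
        gen = rdFingerprintGenerator.GetMorganGenerator(
            radius=spec.radius, fpSize=spec.n_bits, atomInvariantsGenerator=inv
        )
        fp = gen.GetFingerprint(mol)
    elif spec.kind == "atom_pair":
        fp = rdFingerprintGenerator.GetAtomPairGenerator(fpSize=spec.n_bits).GetFingerprint(mol)
    elif spec.kind == "torsion":
        fp = rdFingerprintGenerator.GetTopologicalTorsionGenerator(fpSize=spec.n_bits).GetFingerprint(mol)
    elif spec.kind == "path":
        fp = rdFingerprintGenerator.GetRDKitFPGenerator(fpSize=spec.n_bits).GetFingerprint(mol)
    elif spec.kind == "avalon":
        fp = pyAvalonTools.GetAvalonFP(mol, nBits=spec.n_bits)
    elif spec.kind == "layered":
        fp = Chem.LayeredFingerprint(mol, fpSize=spec.n_bits)
    elif spec.kind == "maccs":
        fp = MACCSkeys.GenMACCSKeys(mol)
    elif spec.kind == "pattern":
        fp = Chem.PatternFingerprint(mol, fpSize=spec.n_bits)
    else:  # unreachable: FingerprintSpec validates kind
        raise ConfigurationError(f"unsupported fingerprint kind {spec.kind!r}")
    arr = np.zeros(fp.GetNumBits(), dtype=float)
    arr[list(fp.GetOnBits())] = 1.0
    return arr


def compute_fingerprints(
    structures: list[str], spec: FingerprintSpec, ids: list[str] | None = None
) -> tuple[FeatureMatrix, list[tuple[str, str]]]:
    """Compute one fingerprint block as an n x n_bits binary matrix."""
    if spec.kind == "maccs" and spec.n_bits != MACCS_NBITS:
        logger.warning("maccs keys have a fixed length of %d bits; n_bits=%d ignored",
                       MACCS_NBITS, spec.n_bits)
    rows, kept, rejections = [], [], []
    for cid, mol in _mols(structures, ids):
        if mol is None:
            rejections.append((cid, "invalid_structure"))
            continue
        rows.append(_fingerprint(mol, spec))
        kept.append(cid)
    if not rows:
        raise EmptyDatasetError("every structure was rejected during fingerprint calculation")
    width = rows[0].size
    df = pd.DataFrame(
        np.vstack(rows), index=kept, columns=[f"{spec.kind}_{i}" for i in range(width)]
    )
    kind = pd.Series("fingerprint", index=df.columns)
    meta = {"toolkit": f"rdkit-{rdkit.__version__}", "fingerprint_spec": vars(spec) | {}}
    return FeatureMatrix(df, kind, meta), rejections


def merge_feature_blocks(blocks: list[FeatureMatrix]) -> FeatureMatrix:
    """Column-concatenate feature blocks and drop constant columns.

    Constant (zero-variance) columns are removed here, before any scaling,
    because min-max scaling is undefined for max(x) == min(x); the removed
    names are recorded under ``meta["removed_constant_columns"]``.
    """
    if not blocks:
        raise ConfigurationError("no feature blocks to merge")
    first_ids = blocks[0].row_ids
    for b in blocks[1:]:
        if b.row_ids != first_ids:
            raise AlignmentError("feature blocks have mismatched row ids or row order")
    names = [c for b in blocks for c in b.column_names]
    if len(set(names)) != len(names):
        raise AlignmentError("feature blocks have overlapping column names")
    df = pd.concat([b.values for b in blocks], axis=1)
    kind = pd.concat([b.column_kind for b in blocks])
    constant = df.columns[(df.max(axis=0) == df.min(axis=0)).to_numpy()].tolist()
    if constant:
        logger.info("removing %d constant feature columns", len(constant))
        df = df.drop(columns=constant)
        kind = kind.drop(index=constant)
    meta = {}
    for b in blocks:
        meta.update(b.meta)
    meta["removed_constant_columns"] = constant
    if df.shape[1] == 0:
        raise EmptyDatasetError("all feature columns were constant")
    return FeatureMatrix(df, kind, meta)
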