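"""Pair featurization: fingerprints, descriptors, MoA vectors, mixture graphs.

Every pair featurization is invariant to argument order — mixtures are
unordered — either by construction (element-wise average/sum, label union)
or by canonical ordering (potency concatenation, graph block order).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import math

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Avalon import pyAvalonTools
from rdkit.Chem import Descriptors, rdFingerprintGenerator
from scipy.linalg import block_diag

from .core import Compound, CombinationKey, make_key

RDLogger.DisableLog("rdApp.*")


class UnparseableSmilesError(ValueError):
    """SMILES failed to parse; carries the offending compound id."""

    def __init__(self, compound_id: str, smiles: str):
        super().__init__(f"compound {compound_id!r}: unparseable SMILES {smiles!r}")
        self.compound_id = compound_id


class UnknownMoAError(KeyError):
    pass


@dataclass(frozen=True)
class FeatureVector:
    values: np.ndarray
    descriptor_name: str
    composition: str = "single"

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"{self.descriptor_name} vector contains non-finite entries")
        object.__setattr__(self, "values", vals)

    @property
    def length(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class MixtureGraph:
    """Two molecules as one graph: block-diagonal adjacency, stacked atom features."""

    adjacency: np.ndarray
    node_features: np.ndarray
    pair: CombinationKey


@lru_cache(maxsize=100_000)
def _mol(smiles: str):
    return Chem.MolFromSmiles(smiles)


def _require_mol(compound: Compound):
    mol = _mol(compound.smiles)
    if mol is None:
        raise UnparseableSmilesError(compound.id, compound.smiles)
    return mol


def _morgan(bits):
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=bits)

    def fn(mol):
        return np.asarray(gen.GetFingerprint(mol), dtype=float)

    return fn


def _avalon(bits):
    def fn(mol):
        return np.asarray(pyAvalonTools.GetAvalonFP(mol, nBits=bits), dtype=float)

    return fn


#: Names of the physicochemical descriptor battery, fixed for reproducibility.
PHYSCHEM_NAMES = tuple(name for name, _ in Descriptors.descList)


def _physchem(mol):
    vals = np.array([fn(mol) for _, fn in Descriptors.descList], dtype=float)
    vals[~np.isfinite(vals)] = 0.0
    return vals


_DESCRIPTORS = {
    "morgan-1024": _morgan(1024),
    "morgan-2048": _morgan(2048),
    "avalon-1024": _avalon(1024),
    "avalon-2048": _avalon(2048),
    "physchem": _physchem,
}

# Externally supplied descriptor tables (e.g. simplex-like families),
# keyed by compound id rather than computed from structure.
_TABLES: dict = {}


def register_descriptor(name: str, fn) -> None:
    """Register a structure-based descriptor family: ``fn(mol) -> 1-D array``."""
    _DESCRIPTORS[name] = fn


def register_descriptor_table(name: str, table: dict) -> None:
    """Register a precomputed descriptor family: compound id -> 1-D array."""
    _TABLES[name] = {k: np.asarray(v, dtype=float) for k, v in table.items()}


def available_descriptors() -> list:
    return sorted(set(_DESCRIPTORS) | set(_TABLES))


def compound_descriptor(compound: Compound, descriptor_name: str = "morgan-1024") -> FeatureVector:
    """Deterministic per-compound feature vector from the named family."""
    if descriptor_name in _TABLES:
        table = _TABLES[descriptor_name]
        if compound.id not in table:
            raise KeyError(f"compound {compound.id!r} missing from descriptor table {descriptor_name!r}")
        return FeatureVector(table[compound.id], descriptor_name)
    if descriptor_name not in _DESCRIPTORS:
        raise KeyError(f"unknown descriptor {descriptor_name!r}; available: {available_descriptors()}")
    mol = _require_mol(compound)
    return FeatureVector(_DESCRIPTORS[descriptor_name](mol), descriptor_name)


def compose_pair(fa: FeatureVector, fb: FeatureVector, mode: str = "average") -> FeatureVector:
    """Element-wise average or sum of two same-family vectors (order-invariant)."""
    if fa.descriptor_name != fb.descriptor_name:
        raise ValueError(f"descriptor mismatch: {fa.descriptor_name!r} vs {fb.descriptor_name!r}")
    if fa.length != fb.length:
        raise ValueError(f"length mismatch: {fa.length} vs {fb.length}")
    if mode == "average":
        values = (fa.values + fb.values) / 2.0
    elif mode == "sum":
        values = fa.values + fb.values
    else:
        raise ValueError(f"unknown composition mode {mode!r}")
    return FeatureVector(values, fa.descriptor_name, composition=mode)


def moa_pair_vector(a: Compound, b: Compound, vocabulary) -> FeatureVector:
    """Binary presence/absence vector over the MoA vocabulary for the pair.

    An element is 1 iff either compound carries that mechanism (set
    semantics: a shared label contributes a single 1).
    """
    index = {label: i for i, label in enumerate(vocabulary)}
    values = np.zeros(len(vocabulary))
    for label in a.moa_labels | b.moa_labels:
        if label not in index:
            raise UnknownMoAError(f"MoA label {label!r} not in vocabulary")
        values[index[label]] = 1.0
    return FeatureVector(values, "moa", composition="union")


def append_potency(f: FeatureVector, a: Compound, b: Compound) -> FeatureVector:
    """Concatenate the two log-IC50 values, ordered canonically by compound id."""
    for c in (a, b):
        if not math.isfinite(c.log_ic50):
            raise ValueError(f"compound {c.id!r} has no potency value")
    first, second = sorted((a, b), key=lambda c: c.id)
    values = np.concatenate([f.values, [first.log_ic50, second.log_ic50]])
    return FeatureVector(values, f.descriptor_name + "+potency", composition=f.composition)


# Atom feature columns: atomic number, degree, formal charge, aromatic flag,
# total attached hydrogens.
N_ATOM_FEATURES = 5


def _atom_features(mol) -> np.ndarray:
    rows = [
        [
            atom.GetAtomicNum(),
            atom.GetDegree(),
            atom.GetFormalCharge(),
            1.0 if atom.GetIsAromatic() else 0.0,
            atom.GetTotalNumHs(),
        ]
        for atom in mol.GetAtoms()
    ]
    return np.asarray(rows, dtype=float)


def mixture_graph(a: Compound, b: Compound) -> MixtureGraph:
    """Direct sum of the two molecular graphs (no inter-molecule edges).

    Blocks are ordered canonically by compound id so the result does not
    depend on argument order.
    """
    first, second = sorted((a, b), key=lambda c: c.id)
    mols = [_require_mol(first), _require_mol(second)]
    adjacency = block_diag(*[Chem.GetAdjacencyMatrix(m).astype(float) for m in mols])
    node_features = np.vstack([_atom_features(m) for m in mols])
    return MixtureGraph(adjacency=adjacency, node_features=node_features, pair=make_key(a.id, b.id))


def pair_feature_vector(
    a: Compound,
    b: Compound,
    descriptor_name: str = "morgan-1024",
    composition: str = "average",
    moa_vocabulary=None,
    include_potency: bool = False,
) -> np.ndarray:
    """Full pair feature vector: composed descriptor [+ MoA vector] [+ potencies]."""
    f = compose_pair(
        compound_descriptor(a, descriptor_name),
        compound_descriptor(b, descriptor_name),
        composition,
    )
    parts = [f.values]
    if moa_vocabulary is not None:
        parts.append(moa_pair_vector(a, b, moa_vocabulary).values)
    if include_potency:
        first, second = sorted((a, b), key=lambda c: c.id)
        parts.append(np.array([first.log_ic50, second.log_ic50]))
    return np.concatenate(parts)


def build_design_matrix(
    keys,
    compounds_by_id: dict,
    descriptor_name: str = "morgan-1024",
    composition: str = "average",
    moa_vocabulary=None,
    include_potency: bool = False,
) -> np.ndarray:
    """Stack pair feature vectors for a list of keys into a float32 matrix.

    Per-compound descriptors are computed once and reused across pairs.
    """
    ids = sorted({i for k in keys for i in (k.first, k.second)})
    desc = {i: compound_descriptor(compounds_by_id[i], descriptor_name).values for i in ids}
    moa_index = {label: j for j, label in enumerate(moa_vocabulary)} if moa_vocabulary is not None else None
    rows = []
    for k in keys:
        a, b = compounds_by_id[k.first], compounds_by_id[k.second]
        if composition == "average":
            vec = (desc[k.first] + desc[k.second]) / 2.0
        elif composition == "sum":
            vec = desc[k.first] + desc[k.second]
        else:
            raise ValueError(f"unknown composition mode {composition!r}")
        parts = [vec]
        if moa_index is not None:
            moa = np.zeros(len(moa_index))
            for label in a.moa_labels | b.moa_labels:
                if label not in moa_index:
                    raise UnknownMoAError(f"MoA label {label!r} not in vocabulary")
                moa[moa_index[label]] = 1.0
            parts.append(moa)
        if include_potency:
            parts.append(np.array([a.log_ic50, b.log_ic50]))
        rows.append(np.concatenate(parts))
    return np.asarray(rows, dtype=np.float32)
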