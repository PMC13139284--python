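"""Circular fingerprints, Tanimoto distances, and physicochemical
diagnostics.

Molecules are encoded as 1024-bit extended-connectivity (Morgan)
fingerprints of diameter 4 (radius 2), the representation used both for
modeling and for the Tanimoto-distance applicability domain.  LogP and
molecular weight back the split-diagnostic scatter plots.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors, rdFingerprintGenerator

RDLogger.DisableLog("rdApp.*")

DEFAULT_RADIUS = 2
DEFAULT_NBITS = 1024

_generators: dict[tuple[int, int], object] = {}


def _generator(radius: int, n_bits: int):
    key = (radius, n_bits)
    if key not in _generators:
        _generators[key] = rdFingerprintGenerator.GetMorganGenerator(
            radius=radius, fpSize=n_bits, includeChirality=False
        )
    return _generators[key]


def _mol(structure: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(structure)
    if mol is None:
        raise ValueError(f"unparseable structure: {structure!r}")
    return mol


@dataclasses.dataclass
class Fingerprint:
    bits: np.ndarray            # uint8 0/1 vector of fixed length
    on_bits: tuple[int, ...]    # sorted indices of set bits
    source_id: str | None = None

    def __len__(self) -> int:
        return len(self.bits)


def ecfp(
    structure: str,
    radius: int = DEFAULT_RADIUS,
    n_bits: int = DEFAULT_NBITS,
    source_id: str | None = None,
) -> Fingerprint:
    """Hashed circular fingerprint of the given radius (diameter = 2 x
    radius), invariant to the atom ordering of the input SMILES."""
    fp = _generator(radius, n_bits).GetFingerprint(_mol(structure))
    on = tuple(sorted(fp.GetOnBits()))
    bits = np.zeros(n_bits, dtype=np.uint8)
    bits[list(on)] = 1
    return Fingerprint(bits=bits, on_bits=on, source_id=source_id)


def fingerprint_matrix(
    structures, radius: int = DEFAULT_RADIUS, n_bits: int = DEFAULT_NBITS
) -> np.ndarray:
    """Stack fingerprints of many structures into an (n, n_bits) array."""
    X = np.zeros((len(structures), n_bits), dtype=np.uint8)
    for i, smi in enumerate(structures):
        X[i] = ecfp(smi, radius, n_bits).bits
    return X


def tanimoto(a: Fingerprint | np.ndarray, b: Fingerprint | np.ndarray) -> float:
    """Tanimoto similarity |a & b| / |a | b|; two all-zero vectors count
    as identical (similarity 1)."""
    va = a.bits if isinstance(a, Fingerprint) else np.asarray(a)
    vb = b.bits if isinstance(b, Fingerprint) else np.asarray(b)
    if va.shape != vb.shape:
        raise ValueError(f"fingerprint length mismatch: {va.shape} vs {vb.shape}")
    va = va.astype(bool)
    vb = vb.astype(bool)
    union = np.logical_or(va, vb).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(va, vb).sum() / union)


def tanimoto_distance_matrix(X: np.ndarray) -> np.ndarray:
    """Pairwise 1 - Tanimoto matrix for an (n, n_bits) 0/1 array."""
    X = np.asarray(X, dtype=np.float64)
    inter = X @ X.T
    pop = X.sum(axis=1)
    union = pop[:, None] + pop[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1e-300), 1.0)
    D = 1.0 - sim
    np.fill_diagonal(D, 0.0)
    return np.clip(D, 0.0, 1.0)


def distance_matrix(fps: list[Fingerprint]) -> np.ndarray:
    """DistanceMatrix over a list of Fingerprints (>= 2 required)."""
    if len(fps) < 2:
        raise ValueError("need at least 2 fingerprints")
    lengths = {len(fp) for fp in fps}
    if len(lengths) != 1:
        raise ValueError("fingerprints of mixed length")
    X = np.stack([fp.bits for fp in fps])
    return tanimoto_distance_matrix(X)


def descriptors(structure: str) -> tuple[float, float]:
    """(logP, molecular weight in g/mol) for split-diagnostic plots.

    LogP is the Crippen atom-contribution estimate; molecular weight is
    the average (isotope-abundance-weighted) formula mass.
    """
    mol = _mol(structure)
    return float(Crippen.MolLogP(mol)), float(Descriptors.MolWt(mol))
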