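"""Binary molecular fingerprints and Tanimoto similarity.

Three schemes are provided behind a common provider contract:

``MACCS``
    The 166 public MACCS structural keys via RDKit (declared length 167;
    RDKit leaves bit 0 unused and numbers the keys 1-166).
``ECFP4``
    Morgan circular fingerprint of radius 2 (diameter 4), hashed and folded
    to a configurable length (default 2048 bits).
``PUBCHEM``
    An 881-bit PubChem-style structural key set; see
    :mod:`cliffscape.pubchem_keys` for the exact, versioned definition.

Similarity between fingerprints of the same scheme is the Tanimoto
coefficient |A∩B| / |A∪B| over on-bits.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import MACCSkeys, rdFingerprintGenerator

from .io import ActivityTable, _standardize_smiles
from .pubchem_keys import N_BITS as PUBCHEM_N_BITS
from .pubchem_keys import pubchem_like_on_bits

logger = logging.getLogger(__name__)

SCHEMES = ("MACCS", "ECFP4", "PUBCHEM")
DEFAULT_ECFP4_LENGTH = 2048


@dataclass(frozen=True)
class BitFingerprint:
    """A binary fingerprint as a set of on-bits with a declared length."""

    on_bits: frozenset[int]
    length: int
    scheme: str

    def __post_init__(self) -> None:
        if self.on_bits and (min(self.on_bits) < 0 or max(self.on_bits) >= self.length):
            raise ValueError(
                f"on-bit out of range for {self.scheme} fingerprint of length {self.length}"
            )


def _maccs_bits(mol: Chem.Mol, length: int) -> BitFingerprint:
    bv = MACCSkeys.GenMACCSKeys(mol)
    return BitFingerprint(frozenset(bv.GetOnBits()), bv.GetNumBits(), "MACCS")


_morgan_generators: dict[int, object] = {}


def _ecfp4_bits(mol: Chem.Mol, length: int) -> BitFingerprint:
    gen = _morgan_generators.get(length)
    if gen is None:
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=length)
        _morgan_generators[length] = gen
    bv = gen.GetFingerprint(mol)
    return BitFingerprint(frozenset(bv.GetOnBits()), length, "ECFP4")


def _pubchem_bits(mol: Chem.Mol, length: int) -> BitFingerprint:
    return BitFingerprint(
        frozenset(pubchem_like_on_bits(mol)), PUBCHEM_N_BITS, "PUBCHEM"
    )


_PROVIDERS: dict[str, Callable[[Chem.Mol, int], BitFingerprint]] = {
    "MACCS": _maccs_bits,
    "ECFP4": _ecfp4_bits,
    "PUBCHEM": _pubchem_bits,
}


def compute_fingerprint(
    smiles_or_mol: str | Chem.Mol,
    scheme: str,
    ecfp_length: int = DEFAULT_ECFP4_LENGTH,
) -> BitFingerprint:
    """Compute a binary fingerprint for one molecule under the named scheme.

    Deterministic for a fixed RDKit version.  Accepts a SMILES string or a
    pre-parsed RDKit molecule.
    """
    if scheme not in _PROVIDERS:
        raise ValueError(f"unknown scheme {scheme!r}; supported: {list(_PROVIDERS)}")
    mol = (
        _standardize_smiles(smiles_or_mol)
        if isinstance(smiles_or_mol, str)
        else smiles_or_mol
    )
    return _PROVIDERS[scheme](mol, ecfp_length)


def tanimoto(a: BitFingerprint, b: BitFingerprint) -> float:
    """Tanimoto coefficient |A∩B| / |A∪B| between same-scheme fingerprints.

    Two empty fingerprints compare as 1.0 (they are indistinguishable under
    the scheme); this pathological case is logged.  An empty versus a
    non-empty fingerprint is 0.0.
    """
    if a.scheme != b.scheme:
        raise ValueError(f"scheme mismatch: {a.scheme} vs {b.scheme}")
    if not a.on_bits and not b.on_bits:
        logger.warning("Tanimoto of two empty %s fingerprints; returning 1.0", a.scheme)
        return 1.0
    inter = len(a.on_bits & b.on_bits)
    union = len(a.on_bits | b.on_bits)
    return inter / union


@dataclass
class SimilarityMatrix:
    """Symmetric matrix of pairwise Tanimoto coefficients for one scheme."""

    scheme: str
    values: np.ndarray
    ids: list[str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.ids):
            raise ValueError("similarity matrix must be square and match ids")
        if (v < 0).any() or (v > 1).any():
            raise ValueError("similarity values must lie in [0, 1]")
        if not np.allclose(v, v.T):
            raise ValueError("similarity matrix must be symmetric")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.ids)

    def pair(self, i: int, j: int) -> float:
        return float(self.values[i, j])

    def to_long_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "i": self.ids[i],
                "j": self.ids[j],
                "scheme": self.scheme,
                "similarity": float(self.values[i, j]),
            }
            for i, j in itertools.combinations(range(self.n), 2)
        ]
        return pd.DataFrame(rows)

    def write_csv(self, path: str | Path, long_format: bool = False) -> None:
        if long_format:
            self.to_long_dataframe().to_csv(path, index=False)
        else:
            pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(path)


def pairwise_similarity_matrix(
    table: ActivityTable,
    scheme: str,
    ecfp_length: int = DEFAULT_ECFP4_LENGTH,
) -> SimilarityMatrix:
    """Compute the n×n Tanimoto matrix for one fingerprint scheme.

    Each unordered pair is computed once; errors from fingerprint generation
    name the offending compound.
    """
    fps: list[BitFingerprint] = []
    for rec, mol in zip(table.compounds, table.mols):
        try:
            fps.append(compute_fingerprint(mol, scheme, ecfp_length))
        except Exception as exc:
            raise RuntimeError(
                f"fingerprint failed for compound {rec.compound_id}: {exc}"
            ) from exc
    n = len(fps)
    values = np.eye(n)
    for i, j in itertools.combinations(range(n), 2):
        values[i, j] = values[j, i] = tanimoto(fps[i], fps[j])
    return SimilarityMatrix(scheme=scheme, values=values, ids=table.ids)


def mean_pairwise_similarity(matrix: SimilarityMatrix) -> float:
    """Arithmetic mean of the n(n-1)/2 off-diagonal unordered entries.

    This is the data-driven similarity threshold used to split a SAS map
    into its high- and low-similarity halves.
    """
    n = matrix.n
    if n < 2:
        raise ValueError("mean pairwise similarity requires n >= 2")
    iu = np.triu_indices(n, k=1)
    return float(matrix.values[iu].mean())
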