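"""Pairwise structural similarity.

Hashed linear/branched path fingerprints (the open "Daylight-like" variant
provided by RDKit) and Tanimoto coefficients, batched into a validated
symmetric similarity matrix. A precomputed matrix from any other similarity
source can be supplied instead through :mod:`salicurves.io`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DegenerateInputError, ValidationError

logger = logging.getLogger(__name__)

_SYMMETRY_TOL = 1e-9


@dataclass(frozen=True)
class FingerprintParams:
    """Parameters of the hashed path fingerprint.

    n_bits : length of the bit vector (default 2048).
    max_path : maximum path length in bonds (default 7).
    min_path : minimum path length in bonds (default 1).

    Results are sensitive to these choices, so they are carried on every
    fingerprint and echoed into run manifests for provenance.
    """

    n_bits: int = 2048
    max_path: int = 7
    min_path: int = 1

    def __post_init__(self) -> None:
        if self.n_bits <= 0:
            raise ValidationError(f"n_bits must be positive, got {self.n_bits}")
        if not 1 <= self.min_path <= self.max_path:
            raise ValidationError(
                f"need 1 <= min_path <= max_path, got {self.min_path}..{self.max_path}"
            )


@dataclass(frozen=True)
class Fingerprint:
    """A fixed-length binary fingerprint stored as the set of on-bits."""

    bits: frozenset[int]
    params: FingerprintParams

    @property
    def n_bits(self) -> int:
        return self.params.n_bits

    def __len__(self) -> int:
        return len(self.bits)


@dataclass
class SimilarityMatrix:
    """Symmetric pairwise similarity, entries in [0, 1], unit diagonal."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValidationError(f"similarity matrix shape {v.shape} does not match {n} ids")
        if len(set(self.ids)) != n:
            raise ValidationError("duplicate ids in similarity matrix")
        if not np.all(np.isfinite(v)):
            raise ValidationError("similarity matrix contains non-finite entries")
        if np.any(v < -_SYMMETRY_TOL) or np.any(v > 1 + _SYMMETRY_TOL):
            bad = v[(v < -_SYMMETRY_TOL) | (v > 1 + _SYMMETRY_TOL)]
            raise ValidationError(f"similarity entries outside [0, 1]: e.g. {bad.flat[0]}")
        if np.max(np.abs(v - v.T)) > _SYMMETRY_TOL:
            raise ValidationError("similarity matrix is not symmetric within 1e-9")
        if np.max(np.abs(np.diag(v) - 1.0)) > _SYMMETRY_TOL:
            raise ValidationError("similarity matrix diagonal differs from 1 beyond 1e-9")
        v = np.clip((v + v.T) / 2.0, 0.0, 1.0)
        np.fill_diagonal(v, 1.0)
        self.values = v

    @property
    def n(self) -> int:
        return len(self.ids)

    def reindex(self, ids: Sequence[str]) -> "SimilarityMatrix":
        """Return the submatrix restricted to `ids`, in that order."""
        pos = {c: k for k, c in enumerate(self.ids)}
        missing = [c for c in ids if c not in pos]
        if missing:
            raise ValidationError(f"ids absent from similarity matrix: {missing[:5]}")
        idx = np.array([pos[c] for c in ids])
        return SimilarityMatrix(list(ids), self.values[np.ix_(idx, idx)])


def fingerprint(structure, params: FingerprintParams | None = None) -> Fingerprint:
    """Compute the hashed path fingerprint of one compound.

    `structure` may be a SMILES string or a CompoundRecord with a `smiles`
    attribute. The SMILES is canonicalized by the RDKit parser, so different
    valid writings of the same molecule give identical fingerprints.
    """
    from rdkit import Chem

    params = params or FingerprintParams()
    smiles = getattr(structure, "smiles", structure)
    if smiles is None or (isinstance(smiles, str) and not smiles.strip()):
        raise ValidationError(
            "compound has no structure; supply SMILES/SDF or use a precomputed "
            "similarity matrix instead of fingerprints"
        )
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValidationError(f"unparseable SMILES: {smiles!r}")
    bv = Chem.RDKFingerprint(
        mol, minPath=params.min_path, maxPath=params.max_path, fpSize=params.n_bits
    )
    return Fingerprint(frozenset(bv.GetOnBits()), params)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto coefficient |a∩b| / |a∪b|.

    Two empty fingerprints (molecules with no hashed features) are treated as
    identical, giving 1.0; such pairs are excluded from SALI landscapes anyway
    by the sim = 1 eligibility rule.
    """
    if a.params != b.params:
        raise ValidationError(
            f"fingerprint parameter mismatch: {a.params} vs {b.params}"
        )
    union = len(a.bits | b.bits)
    if union == 0:
        return 1.0
    return len(a.bits & b.bits) / union


def similarity_matrix(fps: Sequence[Fingerprint], ids: Sequence[str]) -> SimilarityMatrix:
    """All-pairs Tanimoto similarity for a list of fingerprints."""
    if len(fps) != len(ids):
        raise ValidationError(f"{len(fps)} fingerprints but {len(ids)} ids")
    if len(fps) < 2:
        raise DegenerateInputError("similarity matrix needs at least 2 compounds")
    n = len(fps)
    v = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            v[i, j] = v[j, i] = tanimoto(fps[i], fps[j])
    return SimilarityMatrix(list(ids), v)


def similarity_from_structures(
    records, params: FingerprintParams | None = None
) -> SimilarityMatrix:
    """Fingerprint every record and return the pairwise Tanimoto matrix."""
    params = params or FingerprintParams()
    fps = [fingerprint(r, params) for r in records]
    return similarity_matrix(fps, [r.id for r in records])
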