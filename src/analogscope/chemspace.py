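"""Chemical reference space: descriptor vectors, standardization,
distances and PCA projection.

The reference space is a low-dimensional vector space of
physicochemical descriptors relevant to lead optimization.  The default
seven dimensions are molecular weight, computed logP, H-bond donor and
acceptor counts, topological polar surface area, rotatable-bond count
and aromatic-ring count — a documented implementation choice, fully
configurable through the descriptor registry.  Distances are Euclidean
after per-dimension z-scoring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence, Union

import numpy as np
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors
from sklearn.decomposition import PCA

from .records import DEFAULT_DESCRIPTORS, CompoundRecord

DESCRIPTOR_REGISTRY: dict[str, Callable[[Chem.Mol], float]] = {
    "mw": Descriptors.MolWt,
    "logp": Crippen.MolLogP,
    "hbd": Lipinski.NumHDonors,
    "hba": Lipinski.NumHAcceptors,
    "tpsa": rdMolDescriptors.CalcTPSA,
    "rotatable_bonds": Lipinski.NumRotatableBonds,
    "aromatic_rings": rdMolDescriptors.CalcNumAromaticRings,
}


def register_descriptor(name: str, func: Callable[[Chem.Mol], float]) -> None:
    DESCRIPTOR_REGISTRY[name] = func


def compute_descriptors(
    record: Union[CompoundRecord, str, Chem.Mol],
    descriptor_set: Sequence[str] = DEFAULT_DESCRIPTORS,
) -> np.ndarray:
    """Descriptor vector for one molecule; canonicalization-invariant."""
    if isinstance(record, CompoundRecord):
        mol = record.mol
    elif isinstance(record, str):
        mol = Chem.MolFromSmiles(record)
    else:
        mol = record
    if mol is None:
        raise ValueError("unparseable molecule")
    values = []
    for name in descriptor_set:
        try:
            fn = DESCRIPTOR_REGISTRY[name]
        except KeyError:
            raise KeyError(f"unknown descriptor {name!r}") from None
        v = float(fn(mol))
        if not np.isfinite(v):
            raise ValueError(f"descriptor {name!r} not finite for molecule")
        values.append(v)
    return np.asarray(values, dtype=float)


def descriptor_matrix(
    records: Sequence[Union[CompoundRecord, str]],
    descriptor_set: Sequence[str] = DEFAULT_DESCRIPTORS,
) -> np.ndarray:
    return np.vstack([compute_descriptors(r, descriptor_set) for r in records])


@dataclass(frozen=True)
class StandardizedSpace:
    """Affine z-scoring transform fitted on a reference population."""

    center: np.ndarray
    scale: np.ndarray
    fitted_on: str = ""

    def transform(self, vectors: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(vectors) - self.center) / self.scale

    def inverse_transform(self, z: np.ndarray) -> np.ndarray:
        return np.atleast_2d(z) * self.scale + self.center


def fit_standardizer(vectors: np.ndarray, fitted_on: str = "") -> StandardizedSpace:
    """Fit per-dimension z-scoring (population sd).

    Constant dimensions get scale 1 with a warning: they carry no
    distance information, and a unit scale keeps the transform
    invertible without dividing by zero.
    """
    vectors = np.atleast_2d(np.asarray(vectors, dtype=float))
    if vectors.shape[0] < 2:
        raise ValueError("need at least two vectors to fit a standardizer")
    center = vectors.mean(axis=0)
    scale = vectors.std(axis=0)
    constant = scale == 0
    if constant.any():
        warnings.warn(
            f"constant descriptor dimension(s) {np.where(constant)[0].tolist()}; "
            "scale set to 1",
            stacklevel=2,
        )
        scale = np.where(constant, 1.0, scale)
    return StandardizedSpace(center=center, scale=scale, fitted_on=fitted_on)


def distance(
    a: np.ndarray, b: np.ndarray, space: StandardizedSpace
) -> float:
    """Euclidean distance between two descriptor vectors in z-scored units."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.shape != space.center.shape:
        raise TypeError("descriptor sets do not match")
    za = space.transform(a)[0]
    zb = space.transform(b)[0]
    return float(np.linalg.norm(za - zb))


def pairwise_distances(
    a: np.ndarray, b: np.ndarray, space: StandardizedSpace
) -> np.ndarray:
    """|a| x |b| standardized Euclidean distance matrix."""
    from scipy.spatial.distance import cdist

    return cdist(space.transform(a), space.transform(b))


def project_pca(
    vectors: np.ndarray, k: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """PCA projection to k components with explained-variance fractions.

    On rank-deficient input fewer components are returned with a
    warning.
    """
    vectors = np.atleast_2d(np.asarray(vectors, dtype=float))
    n, d = vectors.shape
    if k > d:
        raise ValueError(f"k={k} exceeds dimension {d}")
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} vectors for k={k}")
    rank = np.linalg.matrix_rank(vectors - vectors.mean(axis=0))
    k_eff = min(k, max(rank, 1))
    if k_eff < k:
        warnings.warn(
            f"input rank {rank} below requested {k} components; returning {k_eff}",
            stacklevel=2,
        )
    pca = PCA(n_components=k_eff, svd_solver="full")
    coords = pca.fit_transform(vectors)
    return coords, pca.explained_variance_ratio_
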