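"""Core record types shared across the package."""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Any, Mapping, Optional, Sequence

from rdkit import Chem

DEFAULT_DESCRIPTORS = (
    "mw",
    "logp",
    "hbd",
    "hba",
    "tpsa",
    "rotatable_bonds",
    "aromatic_rings",
)


class Origin(str, enum.Enum):
    """Provenance of a compound: measured analog or one of the design routes."""

    EA = "EA"
    DIVERSE_VA = "diverse_VA"
    CLOSE_IN_VA = "close_in_VA"
    FW_VA = "FW_VA"
    SAMPLED_VA = "sampled_VA"


def canonical_smiles(smiles: str) -> str:
    """Canonical SMILES, raising ``ValueError`` on unparseable input.

    Canonical SMILES is the identity key everywhere in this package:
    deduplication, population overlap and EA-exclusion all compare
    canonical strings.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


@dataclass(frozen=True)
class CompoundRecord:
    """A single compound: identifier, canonical SMILES, optional potency.

    Potency is a pIC50 (negative log10 of molar IC50, dimensionless).
    """

    identifier: str
    smiles: str
    potency: Optional[float] = None
    origin: Origin = Origin.EA
    metadata: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "smiles", canonical_smiles(self.smiles))
        if self.potency is not None:
            p = float(self.potency)
            if p != p or p in (float("inf"), float("-inf")):
                raise ValueError(
                    f"non-finite potency for {self.identifier!r}: {self.potency}"
                )
            object.__setattr__(self, "potency", p)

    @property
    def mol(self) -> Chem.Mol:
        return Chem.MolFromSmiles(self.smiles)


@dataclass
class RunConfig:
    """Configuration of a scoring run.

    radius is expressed in standardized-descriptor distance units
    (z-scored Euclidean space); sample_size and n_resamples mirror the
    resampling protocol (10 independent draws of 1000 virtual analogs
    by default).
    """

    radius: float = 1.0
    n_resamples: int = 10
    sample_size: int = 1000
    seed: int = 0
    descriptor_set: Sequence[str] = DEFAULT_DESCRIPTORS

    def __post_init__(self) -> None:
        if self.radius < 0:
            raise ValueError("radius must be nonnegative")
        if self.n_resamples < 1:
            raise ValueError("n_resamples must be positive")
        if self.sample_size < 1:
            raise ValueError("sample_size must be positive")

    def validate_for_scoring(self, n_eas: int) -> None:
        if self.sample_size < 2 * n_eas:
            warnings.warn(
                f"sample_size {self.sample_size} is below twice the number of "
                f"existing analogs ({n_eas}); scores may be unstable",
                stacklevel=2,
            )


def check_unique_identifiers(records: Sequence[CompoundRecord]) -> None:
    seen: set[str] = set()
    for rec in records:
        if rec.identifier in seen:
            raise ValueError(f"duplicate identifier: {rec.identifier!r}")
        seen.add(rec.identifier)
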