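"""Reading and writing compound sets and score reports.

Supported inputs: SMILES files (``SMILES<tab>id`` per line), CSV with
columns ``smiles``, ``id`` and optionally ``pIC50`` (extra columns are
preserved as opaque metadata), and SDF with the potency read from a
named property field.  Records failing to parse are reported, never
silently dropped.  Score reports round-trip through JSON.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
from rdkit import Chem

from .nbh import ScoreReport
from .records import CompoundRecord, Origin, check_unique_identifiers

logger = logging.getLogger(__name__)


class ParseReport(list):
    """Diagnostics for records that failed to parse: (row, reason)."""


def _record(
    smiles: str,
    identifier: str,
    potency,
    origin: Origin,
    metadata: Optional[dict] = None,
) -> CompoundRecord:
    pot = None
    if potency is not None and potency == potency and str(potency) != "":
        pot = float(potency)
    return CompoundRecord(
        identifier=str(identifier),
        smiles=smiles,
        potency=pot,
        origin=origin,
        metadata=metadata or {},
    )


def read_compounds(
    path: Union[str, Path],
    format: Optional[str] = None,
    potency_field: str = "pIC50",
    origin: Origin = Origin.EA,
) -> tuple[list[CompoundRecord], ParseReport]:
    """Read compounds from .smi, .csv or .sdf.

    Returns (records, parse diagnostics).  Raises on an unreadable
    file, zero valid molecules, or duplicate identifiers.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or path.suffix.lstrip(".").lower()
    failures = ParseReport()
    records: list[CompoundRecord] = []

    if fmt == "smi":
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            smiles = parts[0]
            ident = parts[1].strip() if len(parts) > 1 else f"mol{lineno}"
            try:
                records.append(_record(smiles, ident, None, origin))
            except ValueError as exc:
                failures.append((lineno, str(exc)))
    elif fmt == "csv":
        df = pd.read_csv(path)
        cols = {c.lower(): c for c in df.columns}
        if "smiles" not in cols:
            raise ValueError(f"{path}: CSV needs a 'smiles' column")
        id_col = cols.get("id")
        pot_col = cols.get(potency_field.lower())
        extra = [
            c
            for c in df.columns
            if c not in {cols["smiles"], id_col, pot_col}
        ]
        for i, row in df.iterrows():
            ident = row[id_col] if id_col else f"mol{i + 1}"
            pot = row[pot_col] if pot_col else None
            try:
                records.append(
                    _record(
                        row[cols["smiles"]],
                        ident,
                        pot,
                        origin,
                        metadata={c: row[c] for c in extra},
                    )
                )
            except ValueError as exc:
                failures.append((int(i) + 1, str(exc)))
    elif fmt == "sdf":
        supplier = Chem.SDMolSupplier(str(path))
        for i, mol in enumerate(supplier):
            if mol is None:
                failures.append((i + 1, "unparseable SDF record"))
                continue
            ident = (
                mol.GetProp("_Name")
                if mol.GetProp("_Name")
                else f"mol{i + 1}"
            )
            pot = (
                mol.GetProp(potency_field)
                if mol.HasProp(potency_field)
                else None
            )
            try:
                records.append(
                    _record(Chem.MolToSmiles(mol), ident, pot, origin)
                )
            except ValueError as exc:
                failures.append((i + 1, str(exc)))
    else:
        raise ValueError(f"unsupported format {fmt!r}")

    for row, reason in failures:
        logger.warning("%s record %s rejected: %s", path, row, reason)
    if not records:
        raise ValueError(f"{path}: no valid molecules")
    check_unique_identifiers(records)
    return records, failures


def write_compounds(
    records: Sequence[CompoundRecord], path: Union[str, Path]
) -> None:
    """Write records as CSV (smiles, id, pIC50, origin)."""
    df = pd.DataFrame(
        {
            "smiles": [r.smiles for r in records],
            "id": [r.identifier for r in records],
            "pIC50": [r.potency for r in records],
            "origin": [r.origin.value for r in records],
        }
    )
    df.to_csv(path, index=False)


def write_score_report(report: ScoreReport, path: Union[str, Path]) -> None:
    """Serialize a complete score report as JSON."""
    if report.n_resamples < 1 or report.sample_size < 1 or report.n_eas < 1:
        raise ValueError("incomplete score report")
    payload = dataclasses.asdict(report)
    payload["descriptor_set"] = list(report.descriptor_set)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_score_report(path: Union[str, Path]) -> ScoreReport:
    payload = json.loads(Path(path).read_text())
    payload["descriptor_set"] = tuple(payload["descriptor_set"])
    return ScoreReport(**payload)
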