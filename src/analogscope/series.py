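"""Analog series: cores with labeled substitution sites, R-group
decomposition, retrosynthetic fragmentation and substituent pools.

An analog series is a set of compounds sharing one core scaffold and
differing only in the substituents placed at the core's labeled
attachment points.  The core is written as SMILES with mapped dummy
atoms (``[*:1]``, ``[*:2]``, ...); a substituent is a fragment with a
single unmapped attachment dummy (``*C``, ``*OC`` ...) or the explicit
hydrogen placeholder :data:`H_SUB` for an unsubstituted site.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

from rdkit import Chem, RDLogger
from rdkit.Chem import rdRGroupDecomposition

from .records import CompoundRecord, canonical_smiles

logger = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.warning")

#: Explicit hydrogen placeholder for an unsubstituted site.
H_SUB = "[H]"

DEFAULT_MAX_SUBSTITUENT_ATOMS = 13


def heavy_atom_count(mol_or_smiles: Union[str, Chem.Mol]) -> int:
    mol = (
        Chem.MolFromSmiles(mol_or_smiles)
        if isinstance(mol_or_smiles, str)
        else mol_or_smiles
    )
    if mol is None:
        raise ValueError(f"unparseable SMILES: {mol_or_smiles!r}")
    return sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() > 1)


def normalize_substituent(smiles: str) -> str:
    """Canonicalize a single-attachment fragment; H placeholder passes through."""
    if smiles in (H_SUB, "H", "[H][*]", "[*][H]"):
        return H_SUB
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable substituent SMILES: {smiles!r}")
    dummies = [a for a in mol.GetAtoms() if a.GetAtomicNum() == 0]
    if len(dummies) != 1:
        raise ValueError(
            f"substituent must have exactly one attachment point: {smiles!r}"
        )
    dummies[0].SetAtomMapNum(0)
    dummies[0].SetIsotope(0)
    out = Chem.MolToSmiles(mol)
    if out in ("[H][*]", "[*][H]", "*[H]"):
        return H_SUB
    return out


@dataclass(frozen=True)
class FragmentationRule:
    """A cleavable-bond pattern: the bond between the first two matched atoms."""

    name: str
    smarts: str


#: Common retrosynthetic disconnections used to propose core scaffolds.
DEFAULT_RULES: tuple[FragmentationRule, ...] = (
    FragmentationRule("amide", "[$([CX3]=[OX1])]!@[NX3]"),
    FragmentationRule("ester", "[$([CX3]=[OX1])]!@[OX2]"),
    FragmentationRule("amine", "[NX3;!$([NX3][CX3]=[OX1,SX1,NX2])]!@[CX4]"),
    FragmentationRule("ether", "[OX2;!$([OX2][CX3]=[OX1])]!@[CX4]"),
    FragmentationRule("sulfonamide", "[$([SX4](=[OX1])=[OX1])]!@[NX3]"),
    FragmentationRule("aryl-alkyl", "[c]!@[CX4]"),
)


def load_rules(path: str) -> tuple[FragmentationRule, ...]:
    """Read a rule file: one ``name<tab>SMARTS`` per line, ``#`` comments."""
    rules = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, smarts = line.split(None, 1)
            if Chem.MolFromSmarts(smarts) is None:
                raise ValueError(f"invalid SMARTS in rule {name!r}: {smarts!r}")
            rules.append(FragmentationRule(name, smarts.strip()))
    return tuple(rules)


@dataclass(frozen=True)
class CoreScaffold:
    """A core with mapped attachment points ``[*:1]`` ... ``[*:n]``."""

    core_smiles: str
    n_sites: int
    site_labels: tuple[int, ...]

    @classmethod
    def from_smiles(cls, smiles: str) -> "CoreScaffold":
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ValueError(f"unparseable core SMILES: {smiles!r}")
        dummies = [a for a in mol.GetAtoms() if a.GetAtomicNum() == 0]
        if not dummies:
            raise ValueError("core has no attachment points")
        maps = [a.GetAtomMapNum() for a in dummies]
        if all(m == 0 for m in maps):
            for i, a in enumerate(dummies, start=1):
                a.SetAtomMapNum(i)
            maps = list(range(1, len(dummies) + 1))
        if len(set(maps)) != len(maps) or 0 in maps:
            raise ValueError(f"attachment points must carry distinct map numbers: {smiles!r}")
        for a in dummies:
            a.SetIsotope(0)
        labels = tuple(sorted(maps))
        return cls(Chem.MolToSmiles(mol), len(labels), labels)

    @property
    def mol(self) -> Chem.Mol:
        return Chem.MolFromSmiles(self.core_smiles)

    @property
    def canonical_key(self) -> str:
        """Identity of the core ignoring site numbering."""
        mol = self.mol
        for a in mol.GetAtoms():
            if a.GetAtomicNum() == 0:
                a.SetAtomMapNum(0)
        return Chem.MolToSmiles(mol)

    @property
    def heavy_atoms(self) -> int:
        return heavy_atom_count(self.mol)


def assemble(
    core: Union[str, CoreScaffold], substituents: Mapping[int, str]
) -> str:
    """Attach one substituent (or H) per site and return canonical SMILES.

    Raises ``ValueError`` when the combination is chemically invalid or a
    site is missing from ``substituents``.
    """
    core_smiles = core.core_smiles if isinstance(core, CoreScaffold) else core
    mol = Chem.MolFromSmiles(core_smiles)
    if mol is None:
        raise ValueError(f"unparseable core SMILES: {core_smiles!r}")
    sites = {
        a.GetAtomMapNum()
        for a in mol.GetAtoms()
        if a.GetAtomicNum() == 0 and a.GetAtomMapNum() > 0
    }
    missing = sites - set(substituents)
    if missing:
        raise ValueError(f"no substituent given for site(s) {sorted(missing)}")
    rw = Chem.RWMol(mol)
    frags = []
    for site in sorted(sites):
        sub = substituents[site]
        if sub == H_SUB:
            for a in rw.GetAtoms():
                if a.GetAtomicNum() == 0 and a.GetAtomMapNum() == site:
                    a.SetAtomicNum(1)
                    a.SetAtomMapNum(0)
                    a.SetIsotope(0)
        else:
            fmol = Chem.MolFromSmiles(sub)
            if fmol is None:
                raise ValueError(f"unparseable substituent SMILES: {sub!r}")
            fd = [a for a in fmol.GetAtoms() if a.GetAtomicNum() == 0]
            if len(fd) != 1:
                raise ValueError(
                    f"substituent must have exactly one attachment point: {sub!r}"
                )
            fd[0].SetAtomMapNum(site)
            fd[0].SetIsotope(0)
            frags.append(fmol)
    combined = rw.GetMol()
    for f in frags:
        combined = Chem.CombineMols(combined, f)
    try:
        zipped = Chem.molzip(combined)
        zipped = Chem.RemoveHs(zipped)
        Chem.SanitizeMol(zipped)
    except Exception as exc:  # rdkit raises several exception types here
        raise ValueError(f"invalid assembly for core {core_smiles!r}: {exc}") from exc
    return Chem.MolToSmiles(zipped)


def _matched_cut_bonds(
    mol: Chem.Mol, rules: Sequence[FragmentationRule]
) -> list[int]:
    bonds: set[int] = set()
    for rule in rules:
        patt = Chem.MolFromSmarts(rule.smarts)
        if patt is None:
            raise ValueError(f"invalid rule SMARTS: {rule.smarts!r}")
        for match in mol.GetSubstructMatches(patt):
            bond = mol.GetBondBetweenAtoms(match[0], match[1])
            if (
                bond is not None
                and not bond.IsInRing()
                and bond.GetBondType() == Chem.BondType.SINGLE
            ):
                bonds.add(bond.GetIdx())
    return sorted(bonds)


def _renumber_decomposition(
    core_mol: Chem.Mol, subs_by_label: Mapping[int, str]
) -> tuple[str, dict[int, str]]:
    """Relabel core sites 1..k by canonical atom rank; remap substituents."""
    plain = Chem.Mol(core_mol)
    label_at: dict[int, int] = {}
    for a in plain.GetAtoms():
        if a.GetAtomicNum() == 0:
            label_at[a.GetIdx()] = a.GetIsotope()
            a.SetIsotope(0)
            a.SetAtomMapNum(0)
    ranks = list(Chem.CanonicalRankAtoms(plain, breakTies=True))
    order = sorted(label_at, key=lambda idx: ranks[idx])
    new_subs: dict[int, str] = {}
    for site, idx in enumerate(order, start=1):
        plain.GetAtomWithIdx(idx).SetAtomMapNum(site)
        new_subs[site] = subs_by_label[label_at[idx]]
    return Chem.MolToSmiles(plain), new_subs


def fragment_compound(
    compound: Union[str, CompoundRecord, Chem.Mol],
    rules: Sequence[FragmentationRule] = DEFAULT_RULES,
    max_cuts: int = 4,
    max_substituent_atoms: int = DEFAULT_MAX_SUBSTITUENT_ATOMS,
) -> list[tuple[str, dict[int, str]]]:
    """Enumerate (core, substituents) decompositions along rule-matched bonds.

    Every returned pair reassembles to the input molecule.  When no
    rule-matching acyclic single bond exists, the trivial decomposition
    (whole molecule as core, no substituents) is returned.  Candidates
    are ordered by decreasing core size.
    """
    if isinstance(compound, CompoundRecord):
        mol = compound.mol
    elif isinstance(compound, str):
        mol = Chem.MolFromSmiles(compound)
    else:
        mol = compound
    if mol is None:
        raise ValueError("unparseable input molecule")

    cut_bonds = _matched_cut_bonds(mol, rules)
    if not cut_bonds:
        return [(Chem.MolToSmiles(mol), {})]
    # keep subset enumeration bounded on densely cleavable molecules
    while max_cuts > 1 and sum(
        1 for _ in itertools.islice(
            itertools.chain.from_iterable(
                itertools.combinations(cut_bonds, k)
                for k in range(1, max_cuts + 1)
            ),
            5001,
        )
    ) > 5000:
        max_cuts -= 1

    results: list[tuple[str, dict[int, str]]] = []
    seen: set[tuple[str, tuple[tuple[int, str], ...]]] = set()
    total_heavy = heavy_atom_count(mol)
    for k in range(1, max_cuts + 1):
        for subset in itertools.combinations(cut_bonds, k):
            frag = Chem.FragmentOnBonds(
                mol,
                list(subset),
                addDummies=True,
                dummyLabels=[(i + 1, i + 1) for i in range(k)],
            )
            try:
                pieces = Chem.GetMolFrags(frag, asMols=True, sanitizeFrags=True)
            except Exception:
                continue
            if len(pieces) != k + 1:
                continue
            n_dummies = [
                sum(1 for a in p.GetAtoms() if a.GetAtomicNum() == 0)
                for p in pieces
            ]
            core_candidates = (
                [i for i, n in enumerate(n_dummies) if n == k]
                if k > 1
                else [0, 1]
            )
            if k > 1 and (
                len(core_candidates) != 1
                or any(
                    n != 1
                    for i, n in enumerate(n_dummies)
                    if i != core_candidates[0]
                )
            ):
                continue
            for core_idx in core_candidates:
                # the core is the dominant part of the molecule
                if 2 * heavy_atom_count(pieces[core_idx]) < total_heavy:
                    continue
                subs_by_label: dict[int, str] = {}
                ok = True
                for i, piece in enumerate(pieces):
                    if i == core_idx:
                        continue
                    if n_dummies[i] != 1:
                        ok = False
                        break
                    if (
                        max_substituent_atoms is not None
                        and heavy_atom_count(piece) > max_substituent_atoms
                    ):
                        ok = False
                        break
                    dummy = next(
                        a for a in piece.GetAtoms() if a.GetAtomicNum() == 0
                    )
                    subs_by_label[dummy.GetIsotope()] = normalize_substituent(
                        Chem.MolToSmiles(piece)
                    )
                if not ok or len(subs_by_label) != k:
                    continue
                core_smiles, subs = _renumber_decomposition(
                    pieces[core_idx], subs_by_label
                )
                key = (
                    canonical_smiles_no_maps(core_smiles),
                    tuple(sorted(subs.items())),
                )
                if key in seen:
                    continue
                seen.add(key)
                results.append((core_smiles, subs))
    if not results:
        return [(Chem.MolToSmiles(mol), {})]
    results.sort(
        key=lambda cs: (-heavy_atom_count(Chem.MolFromSmiles(cs[0])), cs[0])
    )
    return results


def canonical_smiles_no_maps(smiles: str) -> str:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    for a in mol.GetAtoms():
        a.SetAtomMapNum(0)
    return Chem.MolToSmiles(mol)


@dataclass
class AnalogSeries:
    """A core scaffold plus its analogs with per-site substituent assignment."""

    core: CoreScaffold
    analogs: list[CompoundRecord]
    substituents: dict[str, tuple[str, ...]]
    target_name: str = ""

    def __post_init__(self) -> None:
        missing = [r.identifier for r in self.analogs if r.identifier not in self.substituents]
        if missing:
            raise ValueError(f"analogs without substituent assignment: {missing}")

    @property
    def n_sites(self) -> int:
        return self.core.n_sites

    @property
    def n_analogs(self) -> int:
        return len(self.analogs)

    @property
    def ea_smiles(self) -> set[str]:
        return {r.smiles for r in self.analogs}

    @property
    def potencies(self) -> dict[str, float]:
        return {
            r.identifier: r.potency
            for r in self.analogs
            if r.potency is not None
        }

    def unique_substituents(self, site: Optional[int] = None) -> set[str]:
        """Distinct non-H substituents, overall or for one site (1-based)."""
        out: set[str] = set()
        for subs in self.substituents.values():
            picks = subs if site is None else (subs[site - 1],)
            out.update(s for s in picks if s != H_SUB)
        return out

    def h_fraction(self, site: int) -> float:
        """Fraction of analogs carrying H at the given 1-based site."""
        vals = [subs[site - 1] for subs in self.substituents.values()]
        return sum(1 for s in vals if s == H_SUB) / len(vals)

    def heavy_atom_range(self) -> tuple[int, int]:
        counts = [heavy_atom_count(r.mol) for r in self.analogs]
        return min(counts), max(counts)

    def validate(self) -> None:
        """Check that every analog reassembles from core + substituents."""
        for rec in self.analogs:
            subs = {
                site: s
                for site, s in zip(self.core.site_labels, self.substituents[rec.identifier])
            }
            rebuilt = assemble(self.core, subs)
            if rebuilt != rec.smiles:
                raise ValueError(
                    f"analog {rec.identifier!r} does not reassemble: "
                    f"{rebuilt} != {rec.smiles}"
                )


def decompose_onto_core(
    core: CoreScaffold, records: Sequence[CompoundRecord]
) -> tuple[dict[str, tuple[str, ...]], list[str]]:
    """Per-site substituent assignment of compounds against one core.

    Uses R-group decomposition restricted to the labeled sites, so
    analogs carrying hydrogen at a site are matched (hydrogen is
    reported as :data:`H_SUB`).  Returns (assignments keyed by compound
    identifier, identifiers that do not match the core).
    """
    params = rdRGroupDecomposition.RGroupDecompositionParameters()
    params.onlyMatchAtRGroups = True
    params.removeHydrogensPostMatch = True
    mols = [r.mol for r in records]
    rows, unmatched_idx = rdRGroupDecomposition.RGroupDecompose(
        [core.mol], mols, asSmiles=True, options=params
    )
    unmatched = {records[i].identifier for i in unmatched_idx}
    matched_records = [r for i, r in enumerate(records) if i not in set(unmatched_idx)]
    assignments: dict[str, tuple[str, ...]] = {}
    for rec, row in zip(matched_records, rows):
        subs: list[str] = []
        ok = True
        for site in core.site_labels:
            raw = row.get(f"R{site}")
            if raw is None or raw.count("*") != 1:
                ok = False
                break
            try:
                subs.append(normalize_substituent(raw))
            except ValueError:
                ok = False
                break
        if not ok:
            unmatched.add(rec.identifier)
            continue
        assignments[rec.identifier] = tuple(subs)
    return assignments, sorted(unmatched)


def extract_series(
    compounds: Sequence[CompoundRecord],
    rules: Sequence[FragmentationRule] = DEFAULT_RULES,
    min_size: int = 3,
    max_cuts: int = 4,
) -> list[AnalogSeries]:
    """Group compounds into analog series by shared fragmentation cores.

    Candidate cores are proposed by retrosynthetic fragmentation of each
    compound; the core matching the most compounds wins, compounds are
    assigned to it (at most one series per compound), and the procedure
    repeats on the remainder.  Series smaller than ``min_size`` are
    discarded.  The result is independent of input order up to the
    documented tie-breaks (larger core, then lexicographic SMILES).
    """
    support: dict[str, set[str]] = {}
    rep_core: dict[str, str] = {}
    for rec in compounds:
        for core_smiles, subs in fragment_compound(
            rec, rules, max_cuts=max_cuts
        ):
            if not subs:
                continue  # trivial decomposition cannot found a series
            key = canonical_smiles_no_maps(core_smiles)
            support.setdefault(key, set()).add(rec.identifier)
            rep_core.setdefault(key, core_smiles)

    by_id = {r.identifier: r for r in compounds}
    unassigned = set(by_id)
    series_out: list[AnalogSeries] = []
    dead: set[str] = set()
    while True:
        best_key = None
        best_rank = None
        for key, members in support.items():
            if key in dead:
                continue
            n = len(members & unassigned)
            if n < min_size:
                continue
            core_mol = Chem.MolFromSmiles(key)
            rank = (-n, -heavy_atom_count(core_mol), key)
            if best_rank is None or rank < best_rank:
                best_rank = rank
                best_key = key
        if best_key is None:
            break
        core = CoreScaffold.from_smiles(rep_core[best_key])
        pool_records = [by_id[i] for i in sorted(unassigned)]
        assignments, _ = decompose_onto_core(core, pool_records)
        members = []
        subs_map = {}
        for rec in pool_records:
            if rec.identifier not in assignments:
                continue
            subs = dict(zip(core.site_labels, assignments[rec.identifier]))
            try:
                if assemble(core, subs) != rec.smiles:
                    continue
            except ValueError:
                continue
            members.append(rec)
            subs_map[rec.identifier] = assignments[rec.identifier]
        if len(members) < min_size:
            dead.add(best_key)
            continue
        series_out.append(
            AnalogSeries(core=core, analogs=members, substituents=subs_map)
        )
        unassigned -= {r.identifier for r in members}
    return series_out


@dataclass(frozen=True)
class SubstituentPool:
    """A deduplicated set of single-attachment fragments with a size cap."""

    fragments: tuple[str, ...]
    max_heavy_atoms: int
    provenance: str  # "series" | "external"

    def __len__(self) -> int:
        return len(self.fragments)

    def __iter__(self):
        return iter(self.fragments)


def build_pool(
    source: Union[AnalogSeries, Iterable[str]],
    max_heavy_atoms: int = DEFAULT_MAX_SUBSTITUENT_ATOMS,
) -> SubstituentPool:
    """Build a substituent pool from a series or an external fragment list."""
    if isinstance(source, AnalogSeries):
        raw = sorted(source.unique_substituents())
        provenance = "series"
    else:
        raw = list(source)
        provenance = "external"
    kept: list[str] = []
    seen: set[str] = set()
    for smi in raw:
        norm = normalize_substituent(smi)
        if norm == H_SUB:
            continue
        if heavy_atom_count(norm) > max_heavy_atoms:
            continue
        if norm in seen:
            continue
        seen.add(norm)
        kept.append(norm)
    if not kept:
        raise ValueError("substituent pool is empty after filtering")
    return SubstituentPool(tuple(sorted(kept)), max_heavy_atoms, provenance)
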