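"""Synthetic analog series, virtual-analog pools and SMILES corpora.

The generator emulates the data regime the diagnostics assume: a core
scaffold with 2-4 substitution sites, a per-site substituent alphabet,
and potencies that decompose into a base value, additive per-substituent
contributions, optional pairwise interaction (non-additivity) terms and
Gaussian measurement noise.  Molecules are real, valence-correct
structures assembled from a shipped core/fragment library, so
descriptor, fingerprint and SMILES code paths are exercised end to end.

All substituents attach through an sp3 carbon, so the default
aryl-alkyl retrosynthetic rule cleaves every substitution site and
series extraction can be validated against the generator's ground
truth.  All randomness flows from the single spec seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem, RDLogger

from .records import CompoundRecord, Origin

# trial strings are probed for validity on purpose; keep the log quiet
RDLogger.DisableLog("rdApp.error")
from .series import (
    H_SUB,
    AnalogSeries,
    CoreScaffold,
    SubstituentPool,
    assemble,
    build_pool,
)

#: Valence-correct cores with aromatic-carbon attachment points, by site count.
CORE_LIBRARY: dict[int, tuple[str, ...]] = {
    2: (
        "O=C(Nc1ccc([*:2])cc1)c1ccccc1[*:1]",
        "O=S(=O)(Nc1ccc([*:2])cc1)c1ccccc1[*:1]",
        "c1ccc(-c2ccc([*:2])cc2[*:1])cc1",
    ),
    3: (
        "O=C(Nc1ccc([*:2])cc1[*:3])c1ccccc1[*:1]",
        "O=C(Nc1ccc([*:3])cc1)c1ccc([*:1])cc1[*:2]",
    ),
    4: (
        "O=C(Nc1ccc([*:3])cc1[*:4])c1ccc([*:1])cc1[*:2]",
    ),
}

#: Substituent fragments, all sp3-carbon attached, <= 13 heavy atoms.
FRAGMENT_LIBRARY: tuple[str, ...] = (
    "*C",
    "*CC",
    "*CCC",
    "*C(C)C",
    "*CC(C)C",
    "*C(C)(C)C",
    "*CO",
    "*CCO",
    "*COC",
    "*CCOC",
    "*C(F)(F)F",
    "*CF",
    "*CCF",
    "*CN",
    "*CCN",
    "*CN(C)C",
    "*CC#N",
    "*CCl",
    "*Cc1ccccc1",
    "*CCc1ccccc1",
    "*C1CC1",
    "*C1CCC1",
    "*C1CCCC1",
    "*CSC",
    "*CC(N)=O",
    "*CC(=O)OC",
)


@dataclass
class SeriesGeneratorSpec:
    """Study conditions for one synthetic series.

    Per-substituent potency effects are drawn once from
    ``N(0, effect_sd)`` (hydrogen is the zero-effect reference);
    pairwise interaction terms from ``N(0, interaction_sd)``;
    per-compound noise from ``N(0, noise_sd)``.  Effects are in pIC50
    log units.
    """

    n_sites: int = 3
    substituents_per_site: int = 6
    n_eas: int = 30
    base_potency: float = 6.0
    effect_sd: float = 0.5
    interaction_sd: float = 0.0
    noise_sd: float = 0.0
    include_h: bool = True
    seed: int = 0
    core_smiles: Optional[str] = None

    def __post_init__(self) -> None:
        if self.n_sites not in CORE_LIBRARY and self.core_smiles is None:
            raise ValueError(
                f"no shipped core with {self.n_sites} sites; pass core_smiles"
            )
        for name in ("effect_sd", "interaction_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass
class GroundTruth:
    """The generator's potency decomposition, for oracle tests."""

    base_potency: float
    effects: dict[tuple[int, str], float]
    interactions: dict[tuple[int, str, int, str], float]
    noise: dict[str, float]
    alphabets: tuple[tuple[str, ...], ...]

    def clean_potency(self, subs: Sequence[str]) -> float:
        """Noise-free potency of a substituent combination."""
        p = self.base_potency
        for site, sub in enumerate(subs, start=1):
            p += self.effects.get((site, sub), 0.0)
        for (i, a), (j, b) in itertools.combinations(
            [(s + 1, sub) for s, sub in enumerate(subs)], 2
        ):
            p += self.interactions.get((i, a, j, b), 0.0)
        return p


@dataclass
class SyntheticSeries:
    series: AnalogSeries
    truth: GroundTruth
    spec: SeriesGeneratorSpec


def generate_series(spec: SeriesGeneratorSpec) -> SyntheticSeries:
    """Sample a synthetic analog series with a known potency decomposition.

    Deterministic given ``spec.seed``: the same spec yields the same
    molecules, potencies and ground truth.
    """
    ss = np.random.SeedSequence(spec.seed)
    rng_alpha, rng_combo, rng_effect, rng_noise = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    if spec.core_smiles is not None:
        core = CoreScaffold.from_smiles(spec.core_smiles)
    else:
        cores = CORE_LIBRARY[spec.n_sites]
        core = CoreScaffold.from_smiles(
            cores[rng_alpha.integers(len(cores))]
        )
    n_sites = core.n_sites

    alphabets = []
    for _ in range(n_sites):
        k = min(spec.substituents_per_site, len(FRAGMENT_LIBRARY))
        picks = list(
            rng_alpha.choice(len(FRAGMENT_LIBRARY), size=k, replace=False)
        )
        alpha = [FRAGMENT_LIBRARY[i] for i in picks]
        if spec.include_h:
            alpha.append(H_SUB)
        alphabets.append(tuple(alpha))
    alphabets = tuple(alphabets)

    space_size = int(np.prod([len(a) for a in alphabets]))
    if spec.n_eas > space_size:
        raise ValueError(
            f"n_eas={spec.n_eas} exceeds combinatorial space of {space_size}"
        )

    flat = rng_combo.choice(space_size, size=spec.n_eas, replace=False)
    combos = []
    for f in flat:
        idx = []
        rem = int(f)
        for alpha in reversed(alphabets):
            idx.append(rem % len(alpha))
            rem //= len(alpha)
        combos.append(tuple(alphabets[s][i] for s, i in enumerate(reversed(idx))))

    effects = {
        (site + 1, sub): (
            0.0 if sub == H_SUB else float(rng_effect.normal(0.0, spec.effect_sd))
        )
        for site, alpha in enumerate(alphabets)
        for sub in alpha
    }
    interactions: dict[tuple[int, str, int, str], float] = {}
    if spec.interaction_sd > 0:
        for i, j in itertools.combinations(range(1, n_sites + 1), 2):
            for a in alphabets[i - 1]:
                for b in alphabets[j - 1]:
                    interactions[(i, a, j, b)] = float(
                        rng_effect.normal(0.0, spec.interaction_sd)
                    )

    truth = GroundTruth(
        base_potency=spec.base_potency,
        effects=effects,
        interactions=interactions,
        noise={},
        alphabets=alphabets,
    )

    analogs: list[CompoundRecord] = []
    subs_map: dict[str, tuple[str, ...]] = {}
    seen: set[str] = set()
    for n, subs in enumerate(combos):
        smiles = assemble(core, dict(zip(core.site_labels, subs)))
        if smiles in seen:  # distinct combos give distinct molecules for
            continue  # the shipped asymmetric cores; guard anyway
        seen.add(smiles)
        noise = float(rng_noise.normal(0.0, spec.noise_sd)) if spec.noise_sd else 0.0
        ident = f"ea{n}"
        truth.noise[ident] = noise
        analogs.append(
            CompoundRecord(
                identifier=ident,
                smiles=smiles,
                potency=truth.clean_potency(subs) + noise,
                origin=Origin.EA,
            )
        )
        subs_map[ident] = subs
    series = AnalogSeries(core=core, analogs=analogs, substituents=subs_map)
    return SyntheticSeries(series=series, truth=truth, spec=spec)


def generate_va_pool(
    synth: SyntheticSeries | AnalogSeries,
    n: int,
    strategy: str = "recombination",
    seed: int = 0,
) -> list[CompoundRecord]:
    """Virtual-analog pools with known coverage geometry.

    Strategies: ``recombination`` draws close-in analogs from the
    series' own substituents (pool members populate EA-proximal space);
    ``copy`` duplicates EA structures (full coverage at any positive
    radius); ``remote`` decorates the core with long alkyl chains far
    outside the EA descriptor range (zero coverage at practical radii).
    """
    series = synth.series if isinstance(synth, SyntheticSeries) else synth
    if strategy == "recombination":
        from .design import EnumerationSpec, enumerate_vas

        spec = EnumerationSpec(
            series=series,
            pool=build_pool(series),
            n_target=n,
            seed=seed,
            origin=Origin.CLOSE_IN_VA,
            id_prefix="pool",
        )
        return enumerate_vas(spec)
    if strategy == "copy":
        return [
            CompoundRecord(
                identifier=f"copy{i}",
                smiles=r.smiles,
                origin=Origin.CLOSE_IN_VA,
            )
            for i, r in enumerate(series.analogs[:n])
        ]
    if strategy == "remote":
        chain = "*" + "C" * 14
        subs = {site: chain for site in series.core.site_labels}
        smiles = assemble(series.core, subs)
        out = []
        for i in range(n):
            # homologate one chain per index to make structures distinct
            subs_i = dict(subs)
            first = series.core.site_labels[0]
            subs_i[first] = "*" + "C" * (14 + i)
            out.append(
                CompoundRecord(
                    identifier=f"remote{i}",
                    smiles=assemble(series.core, subs_i),
                    origin=Origin.DIVERSE_VA,
                )
            )
        return out
    raise ValueError(f"unknown strategy {strategy!r}")


def external_fragment_pool(
    n: int = 40, seed: int = 0, max_heavy_atoms: int = 13
) -> SubstituentPool:
    """An external substituent pool for diverse enumeration.

    Combines shipped fragments with seeded chain/ring variations.
    """
    rng = np.random.default_rng(seed)
    frags = set(FRAGMENT_LIBRARY)
    attempts = 0
    while len(frags) < n and attempts < 50 * n:
        attempts += 1
        length = int(rng.integers(1, 7))
        body = "C" * length
        tail = ["", "O", "N", "F", "C#N", "OC"][int(rng.integers(6))]
        smi = "*" + body + tail
        if Chem.MolFromSmiles(smi) is not None:
            frags.add(smi)
    return build_pool(sorted(frags), max_heavy_atoms=max_heavy_atoms)


# building blocks for corpus molecules: simple drug-like pieces whose
# canonical SMILES jointly exercise the token set of the series cores
# (nested ring closures, carbonyls, sulfonyl, halogens, biaryl bonds)
_CORPUS_SCAFFOLDS = (
    "c1ccccc1",
    "c1ccncc1",
    "C1CCCCC1",
    "C1CCNCC1",
    "c1ccsc1",
    "c1ccc(-c2ccccc2)cc1",
    "c1ccc(-c2ccc(-c3ccccc3)cc2)cc1",
    "c1ccc2ccccc2c1",
    "C1CC1c1ccccc1",
    "c1ccc(C(N)=O)cc1",
)
_CORPUS_GROUPS = (
    "C",
    "CC",
    "O",
    "OC",
    "N",
    "F",
    "Cl",
    "Br",
    "C(C)C",
    "CO",
    "C#N",
    "C(N)=O",
    "C(=O)OC",
    "S(C)(=O)=O",
)


def generate_corpus(
    n: int, complexity: str = "simple", seed: int = 0, max_length: int = 120
) -> list[str]:
    """Unique, valid SMILES for generative pretraining.

    ``simple`` yields mostly chains and singly substituted rings;
    ``varied`` adds doubly substituted rings and longer branches.  All
    strings canonicalize and respect ``max_length``.
    """
    if n < 1:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    out: list[str] = []
    seen: set[str] = set()
    attempts = 0
    max_subs = 1 if complexity == "simple" else 2

    def random_chain(max_len: int = 8) -> str:
        length = int(rng.integers(1, max_len + 1))
        atoms = []
        prev_hetero = True  # no heteroatom first
        for _ in range(length):
            if not prev_hetero and rng.random() < 0.25:
                atoms.append("O" if rng.random() < 0.6 else "N")
                prev_hetero = True
            else:
                atoms.append("C")
                prev_hetero = False
            if atoms[-1] == "C" and rng.random() < 0.2:
                atoms[-1] = "C(C)"
        smi = "".join(atoms)
        if smi.endswith("C") and rng.random() < 0.35:
            tails = ("F", "Cl", "Br", "O", "N", "C#N", "C(N)=O", "S(C)(=O)=O")
            smi += tails[int(rng.integers(len(tails)))]
        return smi

    while len(out) < n and attempts < 200 * n:
        attempts += 1
        smi = random_chain()
        if rng.random() < 0.5:
            scaffold = _CORPUS_SCAFFOLDS[int(rng.integers(len(_CORPUS_SCAFFOLDS)))]
            if max_subs > 1 and rng.random() < 0.4:
                extra = _CORPUS_GROUPS[int(rng.integers(len(_CORPUS_GROUPS)))]
                scaffold = scaffold[:-2] + "(" + extra + ")" + scaffold[-2:]
            smi = smi + scaffold if smi.endswith(("C", ")")) else scaffold
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            continue
        can = Chem.MolToSmiles(mol)
        if can in seen or len(can) > max_length:
            continue
        seen.add(can)
        out.append(can)
    if len(out) < n:
        raise RuntimeError(f"could only generate {len(out)} of {n} corpus strings")
    return out
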