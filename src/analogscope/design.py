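"""Scaffold-based enumeration of diverse and close-in virtual analogs.

Both strategies decorate every substitution site of the series core
with either hydrogen (site-specific probability) or a substituent drawn
uniformly from a pool, and keep only unique products inside the
heavy-atom size range spanned by the existing analogs.  They differ
only in the pool: close-in analogs recombine substituents observed in
the series itself, diverse analogs draw from an external fragment pool.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .records import CompoundRecord, Origin
from .series import H_SUB, AnalogSeries, SubstituentPool, assemble, heavy_atom_count

logger = logging.getLogger(__name__)

#: rejection-sampling budget: draws allowed per requested virtual analog
MAX_DRAWS_PER_TARGET = 100


@dataclass
class EnumerationSpec:
    """Parameters of one enumeration run.

    ``h_probabilities`` defaults to the series statistic: the fraction
    of existing analogs carrying H at each site.  ``size_range``
    defaults to the min/max heavy-atom count over existing analogs.
    """

    series: AnalogSeries
    pool: SubstituentPool
    n_target: int
    seed: int
    size_range: Optional[tuple[int, int]] = None
    h_probabilities: Optional[Sequence[float]] = None
    origin: Origin = Origin.CLOSE_IN_VA
    id_prefix: str = "va"

    def __post_init__(self) -> None:
        if self.n_target < 1:
            raise ValueError("n_target must be positive")
        if len(self.pool) == 0:
            raise ValueError("substituent pool is empty")
        if self.size_range is None:
            self.size_range = self.series.heavy_atom_range()
        if self.h_probabilities is None:
            self.h_probabilities = tuple(
                self.series.h_fraction(site)
                for site in range(1, self.series.n_sites + 1)
            )
        self.h_probabilities = tuple(float(p) for p in self.h_probabilities)
        if len(self.h_probabilities) != self.series.n_sites:
            raise ValueError("one h_probability required per site")
        if any(not 0.0 <= p <= 1.0 for p in self.h_probabilities):
            raise ValueError("h_probabilities must lie in [0, 1]")


def enumerate_vas(spec: EnumerationSpec) -> list[CompoundRecord]:
    """Rejection-sample unique virtual analogs from the core + pool.

    Each draw independently sets every site to H (with its site
    probability) or to a uniform pool fragment; products outside the
    size range, duplicating an earlier product, or identical to an
    existing analog are rejected.  Deterministic given ``spec.seed``.
    Stops with a warning once the draw budget is exhausted.
    """
    rng = np.random.default_rng(spec.seed)
    series = spec.series
    core = series.core
    sites = core.site_labels
    fragments = list(spec.pool.fragments)
    lo, hi = spec.size_range
    ea_smiles = series.ea_smiles

    out: list[CompoundRecord] = []
    seen: set[str] = set()
    draws = 0
    budget = MAX_DRAWS_PER_TARGET * spec.n_target
    while len(out) < spec.n_target and draws < budget:
        draws += 1
        subs = {}
        for site, h_prob in zip(sites, spec.h_probabilities):
            if rng.random() < h_prob:
                subs[site] = H_SUB
            else:
                subs[site] = fragments[rng.integers(len(fragments))]
        try:
            smiles = assemble(core, subs)
        except ValueError:
            continue
        if smiles in seen or smiles in ea_smiles:
            continue
        if not lo <= heavy_atom_count(smiles) <= hi:
            continue
        seen.add(smiles)
        out.append(
            CompoundRecord(
                identifier=f"{spec.id_prefix}{len(out)}",
                smiles=smiles,
                origin=spec.origin,
                metadata={"substituents": tuple(subs[s] for s in sites)},
            )
        )
    if len(out) < spec.n_target:
        logger.warning(
            "enumeration shortfall: %d of %d unique virtual analogs after "
            "%d draws",
            len(out),
            spec.n_target,
            draws,
        )
    return out


def enumerate_close_in(
    series: AnalogSeries, n_target: int, seed: int, **kwargs
) -> list[CompoundRecord]:
    """Close-in enumeration: pool = substituents observed in the series."""
    from .series import build_pool

    pool = build_pool(series)
    spec = EnumerationSpec(
        series=series,
        pool=pool,
        n_target=n_target,
        seed=seed,
        origin=Origin.CLOSE_IN_VA,
        id_prefix="ci",
        **kwargs,
    )
    return enumerate_vas(spec)


def enumerate_diverse(
    series: AnalogSeries,
    pool: SubstituentPool,
    n_target: int,
    seed: int,
    **kwargs,
) -> list[CompoundRecord]:
    """Diverse enumeration: pool = external fragments not from the series."""
    spec = EnumerationSpec(
        series=series,
        pool=pool,
        n_target=n_target,
        seed=seed,
        origin=Origin.DIVERSE_VA,
        id_prefix="dv",
        **kwargs,
    )
    return enumerate_vas(spec)


def population_overlap(
    populations: dict[str, Sequence[CompoundRecord]],
) -> dict[tuple[str, str], int]:
    """Pairwise canonical-SMILES intersection counts between populations.

    The diagonal entry of a population against itself is its own number
    of unique compounds.
    """
    if len(populations) < 2:
        raise ValueError("need at least two populations")
    sets = {name: {r.smiles for r in recs} for name, recs in populations.items()}
    names = list(sets)
    out: dict[tuple[str, str], int] = {}
    for i, a in enumerate(names):
        for b in names[i:]:
            n = len(sets[a] & sets[b])
            out[(a, b)] = n
            out[(b, a)] = n
    return out
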