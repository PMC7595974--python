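"""Neighborhood-based diagnostic scores for analog series.

Each existing analog (EA) defines a chemical neighborhood (NBH): the
closed ball of a fixed radius around its descriptor vector in a
z-scored reference space.  A large population of virtual analogs (VAs)
is projected into the same space and the fraction and multiplicity of
VAs inside EA neighborhoods yield four diagnostics:

* coverage ``C``: fraction of VAs inside at least one NBH,
* density ``D``: ``1 - 1/d_mean`` where ``d_mean`` is the mean number
  of NBHs containing a covered VA (so ``D`` grows with NBH overlap),
* saturation ``S``: harmonic mean of C and D,
* progression ``P``: weighted mean pairwise potency range among the
  EAs whose NBHs jointly contain a VA — the SAR-discontinuity signal.

High S with low P marks a chemically saturated, SAR-flat (late-stage)
series; low S with high P marks an early series whose SAR still
responds strongly to small modifications.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .chemspace import (
    StandardizedSpace,
    descriptor_matrix,
    fit_standardizer,
    pairwise_distances,
)
from .records import CompoundRecord, RunConfig


@dataclass
class NeighborhoodAssignment:
    """Membership of VAs in EA neighborhoods at a fixed radius."""

    radius: float
    membership: dict[str, set[str]]  # EA id -> set of VA ids within radius
    va_count_total: int
    multiplicity: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.multiplicity:
            mult: dict[str, int] = {}
            for vas in self.membership.values():
                for v in vas:
                    mult[v] = mult.get(v, 0) + 1
            self.multiplicity = mult

    @property
    def covered_vas(self) -> set[str]:
        return {v for v, m in self.multiplicity.items() if m >= 1}


def assign_neighborhoods(
    eas: np.ndarray,
    vas: np.ndarray,
    radius: float,
    space: StandardizedSpace,
    ea_ids: Optional[Sequence[str]] = None,
    va_ids: Optional[Sequence[str]] = None,
) -> NeighborhoodAssignment:
    """Closed-ball NBH membership: VA v belongs to NBH(e) iff d(v, e) <= radius."""
    eas = np.atleast_2d(np.asarray(eas, dtype=float))
    vas = np.atleast_2d(np.asarray(vas, dtype=float))
    if eas.size == 0 or vas.size == 0:
        raise ValueError("EA and VA sets must be nonempty")
    if radius < 0:
        raise ValueError("radius must be nonnegative")
    ea_ids = list(ea_ids) if ea_ids is not None else [f"ea{i}" for i in range(len(eas))]
    va_ids = list(va_ids) if va_ids is not None else [f"va{i}" for i in range(len(vas))]
    dmat = pairwise_distances(eas, vas, space)
    inside = dmat <= radius
    membership = {
        ea_ids[i]: {va_ids[j] for j in np.nonzero(inside[i])[0]}
        for i in range(len(ea_ids))
    }
    return NeighborhoodAssignment(
        radius=float(radius), membership=membership, va_count_total=len(va_ids)
    )


def coverage_score(a: NeighborhoodAssignment) -> float:
    """Fraction of VAs falling into at least one EA neighborhood."""
    if a.va_count_total <= 0:
        raise ValueError("no VAs in assignment")
    return len(a.covered_vas) / a.va_count_total


def density_score(a: NeighborhoodAssignment) -> float:
    """1 - 1/d_mean with d_mean the mean NBH multiplicity of covered VAs.

    d_mean >= 1 by construction, so the score lies in [0, 1); with no
    covered VA there is no overlap information and the score is 0.
    """
    covered = a.covered_vas
    if not covered:
        return 0.0
    d_mean = sum(a.multiplicity[v] for v in covered) / len(covered)
    return 1.0 - 1.0 / d_mean


def saturation_score(c: float, d: float) -> float:
    """Harmonic mean of coverage and density; 0 when both vanish."""
    if c < 0 or d < 0:
        raise ValueError("scores must be nonnegative")
    if c + d == 0:
        return 0.0
    return 2.0 * c * d / (c + d)


def progression_score(
    a: NeighborhoodAssignment, potencies: Mapping[str, float]
) -> float:
    """Weighted mean pairwise potency range among EAs sharing covered VAs.

    For a VA contained in the NBHs of m >= 2 EAs, the mean absolute
    pairwise potency difference of those EAs is averaged with weight
    1/m; VAs with m == 1 carry no overlap information and weight 0.
    """
    ea_of_va: dict[str, list[str]] = {}
    for ea, vas in a.membership.items():
        for v in vas:
            ea_of_va.setdefault(v, []).append(ea)
    num = 0.0
    den = 0.0
    for v, eas in ea_of_va.items():
        m = len(eas)
        if m < 2:
            continue
        pots = []
        for e in eas:
            if e not in potencies:
                raise ValueError(f"missing potency for EA {e!r}")
            pots.append(potencies[e])
        pots = np.asarray(pots)
        diffs = np.abs(pots[:, None] - pots[None, :])
        delta_bar = diffs[np.triu_indices(m, k=1)].mean()
        w = 1.0 / m
        num += w * delta_bar
        den += w
    if den == 0.0:
        return 0.0
    return num / den


@dataclass
class ScoreReport:
    """C/D/S/P diagnostic scores with mean and sd over VA resamples."""

    c_mean: float
    c_sd: float
    d_mean: float
    d_sd: float
    s_mean: float
    s_sd: float
    p_mean: float
    p_sd: float
    n_resamples: int
    sample_size: int
    radius: float
    seed: int
    n_eas: int = 0
    va_pool_size: int = 0
    descriptor_set: tuple[str, ...] = ()
    standardized_on: str = "EAs + VA sample (per resample)"

    def as_dict(self) -> dict:
        return {
            "C": {"mean": self.c_mean, "sd": self.c_sd},
            "D": {"mean": self.d_mean, "sd": self.d_sd},
            "S": {"mean": self.s_mean, "sd": self.s_sd},
            "P": {"mean": self.p_mean, "sd": self.p_sd},
            "n_resamples": self.n_resamples,
            "sample_size": self.sample_size,
            "radius": self.radius,
            "seed": self.seed,
            "n_eas": self.n_eas,
            "va_pool_size": self.va_pool_size,
            "descriptor_set": list(self.descriptor_set),
            "standardized_on": self.standardized_on,
        }


def _sd(values: np.ndarray) -> float:
    # sample sd (ddof=1); a single resample has no spread estimate
    if len(values) < 2:
        return 0.0
    return float(np.std(values, ddof=1))


def score_assignment(
    a: NeighborhoodAssignment, potencies: Mapping[str, float]
) -> tuple[float, float, float, float]:
    c = coverage_score(a)
    d = density_score(a)
    s = saturation_score(c, d)
    p = progression_score(a, potencies)
    return c, d, s, p


def score_with_resampling(
    ea_records: Sequence[CompoundRecord],
    va_pool: Sequence[CompoundRecord],
    config: RunConfig,
) -> ScoreReport:
    """Compute C/D/S/P on repeated seeded VA subsamples.

    Per resample, ``sample_size`` VAs are drawn uniformly without
    replacement from the pool (VAs whose canonical SMILES equals an EA
    are removed first — a design route that reproduces training analogs
    would otherwise inflate coverage trivially), descriptors of EAs and
    the sample are z-scored together, and the four scores are computed
    at ``config.radius``.  Deterministic given ``config.seed``.
    """
    if not ea_records:
        raise ValueError("no EA records")
    ea_smiles = {r.smiles for r in ea_records}
    pool = [r for r in va_pool if r.smiles not in ea_smiles]
    if len(pool) < config.sample_size:
        raise ValueError(
            f"VA pool ({len(pool)} after EA removal) smaller than "
            f"sample_size {config.sample_size}"
        )
    config.validate_for_scoring(len(ea_records))
    ea_vectors = descriptor_matrix(ea_records, config.descriptor_set)
    pool_vectors = descriptor_matrix(pool, config.descriptor_set)
    potencies = {
        r.identifier: r.potency for r in ea_records if r.potency is not None
    }
    missing = [r.identifier for r in ea_records if r.potency is None]
    if missing:
        raise ValueError(f"EAs without potency: {missing}")
    ea_ids = [r.identifier for r in ea_records]

    rng = np.random.default_rng(config.seed)
    rows = []
    for _ in range(config.n_resamples):
        idx = rng.choice(len(pool), size=config.sample_size, replace=False)
        sample = pool_vectors[idx]
        space = fit_standardizer(
            np.vstack([ea_vectors, sample]), fitted_on="EAs+sample"
        )
        assignment = assign_neighborhoods(
            ea_vectors,
            sample,
            config.radius,
            space,
            ea_ids=ea_ids,
            va_ids=[pool[i].identifier for i in idx],
        )
        rows.append(score_assignment(assignment, potencies))
    arr = np.asarray(rows)
    return ScoreReport(
        c_mean=float(arr[:, 0].mean()),
        c_sd=_sd(arr[:, 0]),
        d_mean=float(arr[:, 1].mean()),
        d_sd=_sd(arr[:, 1]),
        s_mean=float(arr[:, 2].mean()),
        s_sd=_sd(arr[:, 2]),
        p_mean=float(arr[:, 3].mean()),
        p_sd=_sd(arr[:, 3]),
        n_resamples=config.n_resamples,
        sample_size=config.sample_size,
        radius=config.radius,
        seed=config.seed,
        n_eas=len(ea_records),
        va_pool_size=len(pool),
        descriptor_set=tuple(config.descriptor_set),
    )


def calibrate_radius(
    eas: np.ndarray,
    va_pool: np.ndarray,
    space: StandardizedSpace,
    target_quantile: float = 0.05,
) -> float:
    """NBH radius as a quantile of all EA-VA standardized distances.

    Monotone in the quantile; at q -> 1 every VA is covered.
    """
    if not 0.0 < target_quantile <= 1.0 or target_quantile != target_quantile:
        raise ValueError("target_quantile must be in (0, 1]")
    dmat = pairwise_distances(np.atleast_2d(eas), np.atleast_2d(va_pool), space)
    return float(np.quantile(dmat.ravel(), target_quantile))
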