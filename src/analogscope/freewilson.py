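"""Matched molecular pairs, Free-Wilson quartets and local additivity
predictions.

Within a series, a matched molecular pair (MMP) is two analogs
differing at exactly one substitution site.  A Free-Wilson (FW) quartet
is a reference analog plus two MMP partners differing from it at two
distinct sites, together with the fourth compound that combines both
exchanges.  Under substituent additivity the fourth compound's potency
is ``pot(x) + pot(y) - pot(ref)`` — a local mini-QSAR needing only
three measurements.  When the fourth compound is not among the existing
analogs it is a designed FW virtual analog; by construction FW virtual
analogs recombine only series-observed substituents and are therefore a
subset of the close-in enumerable space.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import networkx as nx
import numpy as np

from .records import CompoundRecord, Origin
from .series import AnalogSeries, assemble


@dataclass(frozen=True)
class MatchedMolecularPair:
    analog_a: str
    analog_b: str
    site: int
    substituent_a: str
    substituent_b: str


def compute_mmps(series: AnalogSeries) -> list[MatchedMolecularPair]:
    """All unordered analog pairs differing at exactly one site."""
    ids = sorted(series.substituents)
    mmps: list[MatchedMolecularPair] = []
    for i, a in enumerate(ids):
        subs_a = series.substituents[a]
        for b in ids[i + 1 :]:
            subs_b = series.substituents[b]
            diff = [
                k for k, (x, y) in enumerate(zip(subs_a, subs_b)) if x != y
            ]
            if len(diff) == 1:
                k = diff[0]
                mmps.append(
                    MatchedMolecularPair(
                        analog_a=a,
                        analog_b=b,
                        site=series.core.site_labels[k],
                        substituent_a=subs_a[k],
                        substituent_b=subs_b[k],
                    )
                )
    return mmps


def build_network(series: AnalogSeries) -> nx.Graph:
    """Undirected MMP network: nodes are analogs, edges carry the site."""
    g = nx.Graph()
    g.add_nodes_from(series.substituents)
    for mmp in compute_mmps(series):
        g.add_edge(mmp.analog_a, mmp.analog_b, site=mmp.site, mmp=mmp)
    return g


@dataclass(frozen=True)
class FWQuartet:
    """A double substituent-exchange cycle.

    ``ea_x`` differs from ``ea_ref`` at ``site_x`` only; ``ea_y`` at
    ``site_y`` only (distinct sites).  ``target_subs`` combines both
    exchanges; ``target_id`` is set when the target exists as an EA.
    """

    ea_ref: str
    ea_x: str
    ea_y: str
    site_x: int
    site_y: int
    target_subs: tuple[str, ...]
    target_smiles: str
    target_status: str  # "FW_EA" | "FW_VA"
    target_id: Optional[str] = None

    @property
    def members(self) -> tuple[str, ...]:
        ids = (self.ea_ref, self.ea_x, self.ea_y)
        return ids + ((self.target_id,) if self.target_id else ())


def find_quartets(
    series: AnalogSeries, network: Optional[nx.Graph] = None
) -> list[FWQuartet]:
    """Enumerate every FW quartet of the series exactly once.

    For each reference analog and unordered pair of distinct sites, each
    combination of an MMP partner at the first site with one at the
    second closes a quartet; site order is normalized (site_x < site_y)
    so no cycle is listed twice.
    """
    if network is None:
        network = build_network(series)
    site_index = {s: k for k, s in enumerate(series.core.site_labels)}
    subs_to_id = {subs: i for i, subs in series.substituents.items()}
    quartets: list[FWQuartet] = []
    seen: set[tuple] = set()
    for ref in sorted(network.nodes):
        partners_by_site: dict[int, list[str]] = {}
        for nbr in network.neighbors(ref):
            partners_by_site.setdefault(network.edges[ref, nbr]["site"], []).append(nbr)
        sites = sorted(partners_by_site)
        for i, sx in enumerate(sites):
            for sy in sites[i + 1 :]:
                for x in sorted(partners_by_site[sx]):
                    for y in sorted(partners_by_site[sy]):
                        subs = list(series.substituents[ref])
                        subs[site_index[sx]] = series.substituents[x][site_index[sx]]
                        subs[site_index[sy]] = series.substituents[y][site_index[sy]]
                        target_subs = tuple(subs)
                        key = (ref, x, y, sx, sy)
                        if key in seen:
                            continue
                        seen.add(key)
                        target_id = subs_to_id.get(target_subs)
                        smiles = assemble(
                            series.core,
                            dict(zip(series.core.site_labels, target_subs)),
                        )
                        quartets.append(
                            FWQuartet(
                                ea_ref=ref,
                                ea_x=x,
                                ea_y=y,
                                site_x=sx,
                                site_y=sy,
                                target_subs=target_subs,
                                target_smiles=smiles,
                                target_status="FW_EA" if target_id else "FW_VA",
                                target_id=target_id,
                            )
                        )
    return quartets


def generate_fw_vas(
    series: AnalogSeries, quartets: Optional[Sequence[FWQuartet]] = None
) -> list[CompoundRecord]:
    """Unique FW virtual analogs: quartet targets absent from the series."""
    if quartets is None:
        quartets = find_quartets(series)
    out: list[CompoundRecord] = []
    seen: set[str] = set()
    for q in quartets:
        if q.target_status != "FW_VA" or q.target_smiles in seen:
            continue
        seen.add(q.target_smiles)
        out.append(
            CompoundRecord(
                identifier=f"fw{len(out)}",
                smiles=q.target_smiles,
                origin=Origin.FW_VA,
                metadata={"substituents": q.target_subs},
            )
        )
    return out


def fw_predict(quartet: FWQuartet, potencies: Mapping[str, float]) -> float:
    """Additivity prediction: pot(x) + pot(y) - pot(ref)."""
    for ea in (quartet.ea_ref, quartet.ea_x, quartet.ea_y):
        if ea not in potencies:
            raise ValueError(f"missing potency for EA {ea!r}")
    return (
        potencies[quartet.ea_x]
        + potencies[quartet.ea_y]
        - potencies[quartet.ea_ref]
    )


def fw_predict_aggregate(
    target_smiles: str,
    quartets: Sequence[FWQuartet],
    potencies: Mapping[str, float],
) -> tuple[float, float, int]:
    """Mean, sample sd and count of predictions over supporting quartets."""
    support = [q for q in quartets if q.target_smiles == target_smiles]
    if not support:
        raise ValueError(f"no supporting quartet for {target_smiles!r}")
    preds = np.asarray([fw_predict(q, potencies) for q in support])
    sd = float(np.std(preds, ddof=1)) if len(preds) > 1 else 0.0
    return float(preds.mean()), sd, len(preds)


def predict_all_targets(
    series: AnalogSeries,
    quartets: Optional[Sequence[FWQuartet]] = None,
    status: Optional[str] = None,
) -> dict[str, tuple[float, float, int]]:
    """Aggregate predictions for every quartet target, keyed by SMILES.

    ``status`` restricts to "FW_VA" or "FW_EA" targets.
    """
    if quartets is None:
        quartets = find_quartets(series)
    potencies = series.potencies
    by_target: dict[str, list[FWQuartet]] = {}
    for q in quartets:
        if status is not None and q.target_status != status:
            continue
        by_target.setdefault(q.target_smiles, []).append(q)
    out = {}
    for smiles, qs in by_target.items():
        preds = np.asarray([fw_predict(q, potencies) for q in qs])
        sd = float(np.std(preds, ddof=1)) if len(preds) > 1 else 0.0
        out[smiles] = (float(preds.mean()), sd, len(qs))
    return out


def fw_ea_fraction(
    series: AnalogSeries, quartets: Optional[Sequence[FWQuartet]] = None
) -> tuple[int, float]:
    """Count and fraction of EAs appearing in at least one quartet (any role)."""
    if quartets is None:
        quartets = find_quartets(series)
    members: set[str] = set()
    for q in quartets:
        members.update(q.members)
    n = len(members)
    return n, n / series.n_analogs if series.n_analogs else 0.0


def fw_target_ea_count(
    series: AnalogSeries, quartets: Optional[Sequence[FWQuartet]] = None
) -> int:
    """EAs appearing as the predicted target of at least one quartet."""
    if quartets is None:
        quartets = find_quartets(series)
    return len({q.target_id for q in quartets if q.target_id is not None})
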