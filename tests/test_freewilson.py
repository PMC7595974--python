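"""MMPs, Free-Wilson quartets and local additivity predictions."""

import itertools

import numpy as np
import pytest

from analogscope.freewilson import (
    build_network,
    compute_mmps,
    find_quartets,
    fw_ea_fraction,
    fw_predict,
    fw_predict_aggregate,
    generate_fw_vas,
    predict_all_targets,
)
from analogscope.records import CompoundRecord
from analogscope.series import AnalogSeries, CoreScaffold, assemble, build_pool
from analogscope.synthetic import SeriesGeneratorSpec, generate_series


def _grid_series(pairs, potencies=None):
    """A 2-site series from explicit substituent pairs."""
    core = CoreScaffold.from_smiles("O=C(Nc1ccc([*:2])cc1)c1ccccc1[*:1]")
    recs, subs = [], {}
    for i, (a, b) in enumerate(pairs):
        ident = f"g{i}"
        pot = potencies[i] if potencies else 6.0
        recs.append(CompoundRecord(ident, assemble(core, {1: a, 2: b}), pot))
        subs[ident] = (a, b)
    return AnalogSeries(core=core, analogs=recs, substituents=subs)


class TestMMPs:
    def test_single_site_series_is_complete_graph(self):
        core = CoreScaffold.from_smiles("O=C(Nc1ccccc1)c1ccccc1[*:1]")
        subs = ["*C", "*CC", "*CCC", "*CO", "*C(C)C"]
        recs = [
            CompoundRecord(f"m{i}", assemble(core, {1: s}), 6.0)
            for i, s in enumerate(subs)
        ]
        series = AnalogSeries(
            core=core,
            analogs=recs,
            substituents={f"m{i}": (s,) for i, s in enumerate(subs)},
        )
        assert len(compute_mmps(series)) == 5 * 4 // 2

    def test_two_site_difference_is_not_an_mmp(self):
        series = _grid_series([("*C", "*C"), ("*CC", "*CC")])
        assert compute_mmps(series) == []

    def test_matches_bruteforce_pairwise_oracle(self):
        synth = generate_series(
            SeriesGeneratorSpec(n_sites=2, substituents_per_site=6, n_eas=20, seed=21)
        )
        series = synth.series
        got = {
            frozenset((m.analog_a, m.analog_b)) for m in compute_mmps(series)
        }
        expected = set()
        ids = list(series.substituents)
        for a, b in itertools.combinations(ids, 2):
            diff = sum(
                x != y
                for x, y in zip(series.substituents[a], series.substituents[b])
            )
            if diff == 1:
                expected.add(frozenset((a, b)))
        assert got == expected

    def test_network_has_no_self_loops(self, additive_series):
        g = build_network(additive_series.series)
        assert all(a != b for a, b in g.edges)


class TestQuartets:
    def test_full_two_by_two_grid_gives_four_existing_targets(self):
        series = _grid_series(
            [("*C", "*CO"), ("*CC", "*CO"), ("*C", "*CN"), ("*CC", "*CN")]
        )
        quartets = find_quartets(series)
        assert len(quartets) == 4
        assert all(q.target_status == "FW_EA" for q in quartets)
        assert {q.target_id for q in quartets} == {"g0", "g1", "g2", "g3"}

    def test_three_analogs_give_one_virtual_target(self):
        series = _grid_series([("*C", "*CO"), ("*CC", "*CO"), ("*C", "*CN")])
        quartets = find_quartets(series)
        assert len(quartets) == 1
        q = quartets[0]
        assert q.target_status == "FW_VA"
        assert q.target_subs == ("*CC", "*CN")
        assert len(generate_fw_vas(series, quartets)) == 1

    def test_single_site_series_has_no_quartets(self):
        core = CoreScaffold.from_smiles("O=C(Nc1ccccc1)c1ccccc1[*:1]")
        recs = [
            CompoundRecord(f"m{i}", assemble(core, {1: s}), 6.0)
            for i, s in enumerate(["*C", "*CC", "*CCC"])
        ]
        series = AnalogSeries(
            core=core,
            analogs=recs,
            substituents={f"m{i}": (s,) for i, s in enumerate(["*C", "*CC", "*CCC"])},
        )
        assert find_quartets(series) == []

    def test_enumeration_matches_bruteforce_triple_oracle(self):
        synth = generate_series(
            SeriesGeneratorSpec(n_sites=3, substituents_per_site=5, n_eas=30, seed=22)
        )
        series = synth.series
        quartets = find_quartets(series)
        got = {(q.ea_ref, frozenset((q.ea_x, q.ea_y))) for q in quartets}
        assert len(got) == len(quartets)  # each cycle enumerated once

        expected = set()
        ids = list(series.substituents)
        sites = series.core.site_labels
        for ref in ids:
            for x, y in itertools.permutations([i for i in ids if i != ref], 2):
                dx = [
                    s
                    for k, s in enumerate(sites)
                    if series.substituents[x][k] != series.substituents[ref][k]
                ]
                dy = [
                    s
                    for k, s in enumerate(sites)
                    if series.substituents[y][k] != series.substituents[ref][k]
                ]
                if len(dx) == 1 and len(dy) == 1 and dx[0] != dy[0]:
                    expected.add((ref, frozenset((x, y))))
        assert got == expected

    def test_fw_vas_are_subset_of_close_in_space(self, additive_series):
        series = additive_series.series
        pool = set(build_pool(series).fragments) | {"[H]"}
        for rec in generate_fw_vas(series):
            assert set(rec.metadata["substituents"]) <= pool

    def test_fully_enumerated_grid_yields_no_fw_vas(self):
        subs_a, subs_b = ["*C", "*CC"], ["*CO", "*CN"]
        series = _grid_series(list(itertools.product(subs_a, subs_b)))
        assert generate_fw_vas(series) == []


class TestPrediction:
    def test_additivity_identity(self):
        series = _grid_series(
            [("*C", "*CO"), ("*CC", "*CO"), ("*C", "*CN")],
            potencies=[5.0, 6.0, 5.5],
        )
        (q,) = find_quartets(series)
        assert fw_predict(q, series.potencies) == pytest.approx(6.5)

    def test_constant_potencies_predict_constant(self):
        series = _grid_series(
            [("*C", "*CO"), ("*CC", "*CO"), ("*C", "*CN")],
            potencies=[7.0, 7.0, 7.0],
        )
        (q,) = find_quartets(series)
        assert fw_predict(q, series.potencies) == pytest.approx(7.0)

    def test_missing_potency_raises(self):
        series = _grid_series([("*C", "*CO"), ("*CC", "*CO"), ("*C", "*CN")])
        (q,) = find_quartets(series)
        with pytest.raises(ValueError, match="missing potency"):
            fw_predict(q, {})

    def test_exact_on_additive_noiseless_series(self, additive_series):
        series = additive_series.series
        truth = additive_series.truth
        quartets = find_quartets(series)
        assert quartets
        pots = series.potencies
        for q in quartets:
            assert fw_predict(q, pots) == pytest.approx(
                truth.clean_potency(q.target_subs), abs=1e-9
            )

    def test_aggregate_sd_zero_under_additivity(self, additive_series):
        series = additive_series.series
        preds = predict_all_targets(series)
        assert preds
        for _, (mean, sd, n) in preds.items():
            assert sd == pytest.approx(0.0, abs=1e-9)
            assert n >= 1

    def test_aggregate_mean_and_sample_sd(self):
        series = _grid_series([("*C", "*CO"), ("*CC", "*CO"), ("*C", "*CN")])
        (q,) = find_quartets(series)
        import dataclasses

        q2 = dataclasses.replace(q, ea_ref="g0")
        mean, sd, n = fw_predict_aggregate(
            q.target_smiles, [q, q2], {"g0": 5.0, "g1": 6.0, "g2": 5.5}
        )
        assert n == 2
        assert mean == pytest.approx(6.5)
        assert sd == pytest.approx(0.0)

    def test_zero_supporting_quartets_raises(self):
        with pytest.raises(ValueError, match="no supporting quartet"):
            fw_predict_aggregate("CCO", [], {})

    def test_error_grows_with_interaction_magnitude(self):
        maes = []
        for interaction_sd in (0.0, 0.5, 2.0):
            errors = []
            for seed in range(5):
                synth = generate_series(
                    SeriesGeneratorSpec(
                        n_sites=2,
                        substituents_per_site=6,
                        n_eas=25,
                        interaction_sd=interaction_sd,
                        seed=300 + seed,
                    )
                )
                series = synth.series
                pots = series.potencies
                for q in find_quartets(series):
                    errors.append(
                        abs(
                            fw_predict(q, pots)
                            - synth.truth.clean_potency(q.target_subs)
                        )
                    )
            maes.append(np.mean(errors))
        assert maes[0] < maes[1] < maes[2]
        assert maes[0] == pytest.approx(0.0, abs=1e-9)


class TestFWEAFraction:
    def test_counts_any_role_membership(self):
        series = _grid_series([("*C", "*CO"), ("*CC", "*CO"), ("*C", "*CN")])
        n, frac = fw_ea_fraction(series)
        assert (n, frac) == (3, 1.0)

    def test_no_quartets_gives_zero(self):
        series = _grid_series([("*C", "*CO"), ("*CC", "*CN")])
        assert fw_ea_fraction(series) == (0, 0.0)
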