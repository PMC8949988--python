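"""Metabolite filtering, transition assembly, convolution handling and packaging."""

import math

import numpy as np
import pandas as pd
import pytest

from fiamrm import (
    BuilderConfig,
    CompoundRecord,
    PkaSet,
    TransitionCandidate,
    build_injection_sequence,
    build_method_set,
    dedup_enantiomers,
    detect_convolutions,
    filter_metabolites,
    fit_dp_model,
    package_methods,
    read_method_csv,
    select_transitions,
    write_method_csv,
)
from fiamrm.errors import InputError
from fiamrm.ionization import NEGATIVE, POSITIVE
from fiamrm.method_builder import (
    MrmMethodPackage,
    Selection,
    fill_missing_dp,
    method_table,
)

CFG = BuilderConfig()


def _rec(i, mw, pka=PkaSet(acidic=(3.0,)), **kw):
    defaults = dict(kegg_id=f"C{i:05d}", name=f"m{i}", mw=mw,
                    chembl_id=f"CH{i}" if pka else None, pka=pka,
                    formula=f"C{i}H{i}O", smiles=None, has_stereo=False)
    defaults.update(kw)
    return CompoundRecord(**defaults)


def _cand(kegg, mode, q1, q3, rank=1, intensity=None, dp=50.0):
    ce = 20.0 if mode == POSITIVE else -20.0
    return TransitionCandidate(kegg_id=kegg, mode=mode, q1=q1, q3=q3, ce=ce,
                               dp=dp, ep=10.0, cxp=4.0, dwell=50.0,
                               origin="predicted", intensity_rank=rank,
                               intensity=intensity)


class TestFilterMetabolites:
    def test_below_window_dropped(self):
        assert filter_metabolites([_rec(1, 18.0)], CFG) == []

    def test_amphoteric_mid_mass_kept(self):
        r = _rec(1, 180.16, PkaSet(acidic=(2.3,), basic=(9.7,)))
        assert filter_metabolites([r], CFG) == [r]

    def test_upper_boundary_strict(self):
        assert filter_metabolites([_rec(1, 1500.0)], CFG) == []
        assert filter_metabolites([_rec(1, 1499.9)], CFG) != []

    def test_unclassified_dropped(self):
        assert filter_metabolites([_rec(1, 200.0, pka=None)], CFG) == []


class TestDedupEnantiomers:
    def test_dl_pair_collapses_to_smallest_id(self):
        d = _rec(2, 89.09, smiles="N[C@@H](C)C(=O)O", formula="C3H7NO2",
                 has_stereo=True)
        l = _rec(1, 89.09, smiles="N[C@H](C)C(=O)O", formula="C3H7NO2",
                 has_stereo=True)
        out = dedup_enantiomers([d, l])
        assert [r.kegg_id for r in out] == ["C00001"]

    def test_structural_isomers_kept(self):
        a = _rec(1, 89.09, smiles="NCC(C)C(=O)O", formula="C3H7NO2")
        b = _rec(2, 89.09, smiles="CN(C)CC(=O)O", formula="C3H7NO2")
        assert len(dedup_enantiomers([a, b])) == 2

    def test_single_record_unchanged(self):
        r = _rec(1, 100.0)
        assert dedup_enantiomers([r]) == [r]


class TestAssembleCandidates:
    def test_origin_priority_and_predicted_fallback(self, organism_records,
                                                    transition_tables,
                                                    predicted_spectra):
        inhouse, lit = transition_tables
        cands, dropped = __import__("fiamrm").assemble_candidates(
            organism_records, inhouse, lit, predicted_spectra, CFG)
        inhouse_keys = set(zip(inhouse["kegg_id"], inhouse["mode"]))
        assert inhouse_keys & {(c.kegg_id, c.mode)
                               for cs in cands.values() for c in cs}
        for kegg, cs in cands.items():
            for c in cs:
                # per metabolite/mode, an in-house entry shadows prediction
                if (c.kegg_id, c.mode) in inhouse_keys:
                    assert c.origin == "inhouse"
                assert c.ep > 0 and c.cxp > 0 and c.dwell == CFG.dwell
                if c.origin == "predicted":
                    assert abs(c.ce) in (10.0, 20.0, 40.0)

    def test_defaults_applied_to_missing_potentials(self, organism_records,
                                                    transition_tables,
                                                    predicted_spectra):
        inhouse, lit = transition_tables  # literature rows have EP/CXP blank
        cands, _ = __import__("fiamrm").assemble_candidates(
            organism_records, inhouse, lit, predicted_spectra, CFG)
        lit_ids = set(lit["kegg_id"])
        seen = [c for cs in cands.values() for c in cs
                if c.origin == "literature" and c.kegg_id in lit_ids]
        assert seen
        assert all(c.ep == 10.0 and c.cxp == 4.0 for c in seen)


class TestDpModel:
    def test_two_point_interpolation(self):
        model = fit_dp_model([(100.0, 40.0, POSITIVE), (300.0, 80.0, POSITIVE)])
        assert model.predict(200.0, POSITIVE) == pytest.approx(60.0)

    def test_constant_dp(self):
        model = fit_dp_model([(100.0, 55.0, NEGATIVE), (300.0, 55.0, NEGATIVE)])
        assert model.predict(987.0, NEGATIVE) == pytest.approx(55.0)

    def test_seeded_points_match_normal_equations(self):
        rng = np.random.default_rng(5)
        mw = rng.uniform(50, 800, 15)
        dp = 0.15 * mw + 20 + rng.normal(0, 3, 15)
        model = fit_dp_model([(m, d, POSITIVE) for m, d in zip(mw, dp)])
        X = np.column_stack([mw, np.ones(15)])
        beta = np.linalg.solve(X.T @ X, X.T @ dp)
        s, i = model.coefs[POSITIVE]
        assert s == pytest.approx(beta[0], abs=1e-10)
        assert i == pytest.approx(beta[1], abs=1e-10)

    def test_single_mode_falls_back_to_pooled(self):
        model = fit_dp_model([(100.0, 40.0, POSITIVE), (300.0, 80.0, POSITIVE)])
        # negative mode has no points of its own
        assert model.predict(200.0, NEGATIVE) == pytest.approx(60.0)

    def test_too_few_points_is_error(self):
        with pytest.raises(InputError):
            fit_dp_model([(100.0, 40.0, POSITIVE)])

    def test_fill_missing_dp(self):
        model = fit_dp_model([(100.0, 40.0, POSITIVE), (300.0, 80.0, POSITIVE)])
        cands = {"C00001": [_cand("C00001", POSITIVE, 200.0, 90.0, dp=None)]}
        filled = fill_missing_dp(cands, model)
        assert filled["C00001"][0].dp == pytest.approx(60.0)


class TestDetectConvolutions:
    def test_same_mode_collision(self):
        cands = {"C00001": [_cand("C00001", NEGATIVE, 259.02, 97.0)],
                 "C00002": [_cand("C00002", NEGATIVE, 259.02, 97.0)]}
        groups = detect_convolutions(cands, 0.5)
        assert len(groups) == 1
        assert groups[0].member_ids == {"C00001", "C00002"}

    def test_cross_mode_is_not_a_convolution(self):
        cands = {"C00001": [_cand("C00001", NEGATIVE, 259.02, 97.0)],
                 "C00002": [_cand("C00002", POSITIVE, 259.02, 97.0)]}
        assert detect_convolutions(cands, 0.5) == []

    def test_outside_tolerance(self):
        cands = {"C00001": [_cand("C00001", NEGATIVE, 259.02, 97.0)],
                 "C00002": [_cand("C00002", NEGATIVE, 259.02, 97.51)]}
        assert detect_convolutions(cands, 0.5) == []

    def test_same_metabolite_never_groups_with_itself(self):
        cands = {"C00001": [_cand("C00001", NEGATIVE, 259.02, 97.0),
                            _cand("C00001", NEGATIVE, 259.02, 97.0, rank=2)]}
        assert detect_convolutions(cands, 0.5) == []


class TestSelectTransitions:
    def test_alternative_avoids_convolution(self):
        cands = {
            "C00001": [_cand("C00001", NEGATIVE, 259.0, 97.0, rank=1),
                       _cand("C00001", NEGATIVE, 259.0, 78.9, rank=2)],
            "C00002": [_cand("C00002", NEGATIVE, 259.0, 97.0, rank=1)],
        }
        groups = detect_convolutions(cands, 0.5)
        sel = select_transitions(cands, groups)
        assert sel["C00001"].candidate.q3 == 78.9
        assert not sel["C00001"].convolved

    def test_unavoidable_convolution_flagged(self):
        cands = {
            "C00001": [_cand("C00001", NEGATIVE, 259.0, 97.0, rank=1)],
            "C00002": [_cand("C00002", NEGATIVE, 259.0, 97.0, rank=1)],
        }
        sel = select_transitions(cands, detect_convolutions(cands, 0.5))
        assert sel["C00001"].convolved and sel["C00002"].convolved
        assert sel["C00001"].candidate.intensity_rank == 1

    def test_deferred_mode_prefers_convolution_free_polarity(self):
        cands = {
            "C00001": [_cand("C00001", POSITIVE, 261.0, 99.0, rank=1),
                       _cand("C00001", NEGATIVE, 259.0, 97.0, rank=1)],
            "C00002": [_cand("C00002", POSITIVE, 261.0, 99.0, rank=1)],
        }
        sel = select_transitions(cands, detect_convolutions(cands, 0.5))
        assert sel["C00001"].mode == NEGATIVE
        assert not sel["C00001"].convolved

    def test_exhaustive_oracle_small_instances(self):
        """On random ≤6-metabolite instances the selector returns a
        convolution-free transition whenever brute-force enumeration finds one."""
        rng = np.random.default_rng(11)
        q1_grid = [100.0, 100.2, 150.0, 150.3]
        q3_grid = [50.0, 50.3, 80.0]
        for _ in range(30):
            n_met = int(rng.integers(2, 7))
            cands = {}
            for i in range(n_met):
                kegg = f"C{i + 1:05d}"
                modes = [POSITIVE, NEGATIVE] if rng.random() < 0.4 else \
                    [rng.choice([POSITIVE, NEGATIVE])]
                cs = []
                for mode in modes:
                    for rank in range(1, int(rng.integers(1, 4)) + 1):
                        cs.append(_cand(kegg, mode,
                                        float(rng.choice(q1_grid)),
                                        float(rng.choice(q3_grid)),
                                        rank=rank, intensity=100.0 / rank))
                cands[kegg] = cs
            flat = [c for cs in cands.values() for c in cs]

            def brute_convolved(c):
                return any(o.kegg_id != c.kegg_id and o.mode == c.mode
                           and abs(o.q1 - c.q1) <= 0.5 and abs(o.q3 - c.q3) <= 0.5
                           for o in flat)

            sel = select_transitions(cands, detect_convolutions(cands, 0.5))
            for kegg, s in sel.items():
                free_exists = any(not brute_convolved(c) for c in cands[kegg])
                assert s.convolved == (not free_exists)
                assert brute_convolved(s.candidate) == s.convolved


def _selections(n, mode):
    out = {}
    for i in range(n):
        kegg = f"C{i + (0 if mode == POSITIVE else 50000):05d}"
        out[kegg] = Selection(kegg, _cand(kegg, mode, 100.0 + i, 60.0), False)
    return out


class TestPackageMethods:
    @pytest.mark.parametrize("n,mode,expected_sizes", [
        (96, POSITIVE, [32, 32, 32]),
        (156, NEGATIVE, [39, 39, 39, 39]),
        (41, POSITIVE, [21, 20]),
        (40, POSITIVE, [40]),
        (1, NEGATIVE, [1]),
    ])
    def test_balanced_distribution(self, n, mode, expected_sizes):
        pkgs = package_methods(_selections(n, mode), CFG)
        assert sorted((len(p) for p in pkgs), reverse=True) == expected_sizes
        assert all(p.mode == mode for p in pkgs)

    def test_conservation_and_balance_property(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            sels = {}
            for mode, n in ((POSITIVE, int(rng.integers(0, 130))),
                            (NEGATIVE, int(rng.integers(1, 130)))):
                sels.update({k: v for k, v in _selections(n, mode).items()})
            pkgs = package_methods(sels, CFG)
            # conservation: every metabolite in exactly one package
            ids = [t.kegg_id for p in pkgs for t in p.transitions]
            assert sorted(ids) == sorted(sels)
            for mode in (POSITIVE, NEGATIVE):
                sizes = [len(p) for p in pkgs if p.mode == mode]
                assert all(s <= CFG.max_per_package for s in sizes)
                if sizes:
                    assert max(sizes) - min(sizes) <= 1
                    n = sum(sizes)
                    assert len(sizes) == math.ceil(n / CFG.max_per_package)

    def test_packages_sorted_by_q1(self):
        pkgs = package_methods(_selections(90, POSITIVE), CFG)
        for p in pkgs:
            q1 = [t.q1 for t in p.transitions]
            assert q1 == sorted(q1)


class TestMethodTables:
    def test_table_columns_and_dwell(self):
        pkg = package_methods(_selections(2, POSITIVE), CFG)[0]
        df = method_table(pkg, {})
        assert list(df.columns) == ["Q1", "Q3", "Time(msec)", "ID", "DP", "EP",
                                    "CE", "CXP"]
        assert (df["Time(msec)"] == 50.0).all()
        assert len(df) == 2

    def test_csv_round_trip_reproduces_package(self, tmp_path):
        pkg = package_methods(_selections(3, NEGATIVE), CFG)[0]
        p = tmp_path / "method_negative_1.csv"
        write_method_csv(pkg, p, {})
        back = read_method_csv(p)
        assert back.mode == pkg.mode and back.index == pkg.index
        assert [(t.q1, t.q3, t.ce, t.dp) for t in back.transitions] == \
            [(t.q1, t.q3, t.ce, t.dp) for t in pkg.transitions]

    def test_csv_round_trip_byte_identical(self, tmp_path):
        pkg = package_methods(_selections(5, POSITIVE), CFG)[0]
        p1 = tmp_path / "method_positive_1.csv"
        p2 = tmp_path / "method_positive_1b.csv"
        write_method_csv(pkg, p1, {})
        write_method_csv(read_method_csv(p1, POSITIVE, 1), p2, {})
        assert p1.read_bytes() == p2.read_bytes()


class TestBuildMethodSet:
    def test_end_to_end(self, organism_records, transition_tables,
                        predicted_spectra, library_fixture):
        inhouse, lit = transition_tables
        ms = build_method_set(organism_records, inhouse, lit, predicted_spectra)
        assert len(ms.packages) >= 1
        # conservation through the whole build
        packaged = sorted(t.kegg_id for p in ms.packages for t in p.transitions)
        assert packaged == sorted(ms.selection["kegg_id"])
        # planted isobaric pairs show up as convolution groups
        for mode, pair in library_fixture.isobaric_pairs.items():
            assert any(set(pair) <= g.member_ids for g in ms.convolutions
                       if g.mode == mode)
        # every package stays single-polarity and within the size cap
        for p in ms.packages:
            assert len(p) <= BuilderConfig().max_per_package

    def test_analysis_time_is_package_count(self, organism_records,
                                            transition_tables, predicted_spectra):
        inhouse, lit = transition_tables
        ms = build_method_set(organism_records, inhouse, lit, predicted_spectra)
        assert ms.analysis_time_min == len(ms.packages)


class TestInjectionSequence:
    def _pkg(self, mode):
        return MrmMethodPackage(mode=mode, index=1,
                                transitions=(_cand("C00001", mode, 100.0, 60.0),))

    def test_qc_insertion_rule(self):
        seq = build_injection_sequence([f"s{i}" for i in range(12)], 1,
                                       [self._pkg(POSITIVE)], seed=1)
        one_plate = seq[seq["plate"] == 1]
        assert one_plate.iloc[0]["type"] == "blank"
        assert one_plate.iloc[1]["type"] == "qc"
        assert (one_plate["type"] == "qc").sum() == 3  # lead + after 6 + after 12
        # never more than 6 consecutive samples
        run = 0
        for t in one_plate["type"]:
            run = run + 1 if t == "sample" else 0
            assert run <= 6

    def test_same_seed_identical(self):
        pkgs = [self._pkg(POSITIVE), self._pkg(NEGATIVE)]
        a = build_injection_sequence(["a", "b", "c"], 2, pkgs, seed=42)
        b = build_injection_sequence(["a", "b", "c"], 2, pkgs, seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_zero_samples_degenerate(self):
        seq = build_injection_sequence([], 1, [self._pkg(POSITIVE)], seed=0)
        assert list(seq["type"]) == ["blank", "qc"]

    def test_one_plate_per_polarity(self):
        seq = build_injection_sequence(["a"], 1,
                                       [self._pkg(POSITIVE), self._pkg(NEGATIVE)],
                                       seed=0)
        assert set(seq["plate"]) == {1, 2}
        assert set(seq["polarity"]) == {POSITIVE, NEGATIVE}
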