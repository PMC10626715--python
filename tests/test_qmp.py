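"""OTU QC, rarefaction, copy-number correction and QMP construction."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from transitqmp.qmp import (
    CountTable,
    build_qmp,
    copy_number_correct,
    filter_otus,
    flag_low_depth_samples,
    rarefaction_curve,
    rarefy,
)


def _table(counts: dict, sample_types: dict | None = None) -> CountTable:
    df = pd.DataFrame(counts).T  # rows = OTUs
    meta = None
    if sample_types:
        meta = pd.DataFrame(
            {"sample_type": [sample_types.get(s, "experimental")
                             for s in df.columns]},
            index=df.columns,
        )
    return CountTable(df, sample_meta=meta if meta is not None else pd.DataFrame())


class TestFilterOtus:
    def test_low_prevalence_removed_despite_high_reads(self):
        # 100 samples; OTU present in 4 (< 5) with 300 reads total
        counts = {f"otu{i}": {f"s{j}": 1 for j in range(100)} for i in range(3)}
        counts["rare"] = {f"s{j}": 75 for j in range(4)}
        for c in counts.values():
            for j in range(100):
                c.setdefault(f"s{j}", 0)
        tbl = _table(counts)
        out = filter_otus(tbl)
        assert "rare" not in out.counts.index

    def test_singleton_removed(self):
        counts = {
            "single": {"s0": 1, "s1": 0, "s2": 0},
            "keep": {"s0": 5, "s1": 5, "s2": 5},
        }
        out = filter_otus(_table(counts))
        assert list(out.counts.index) == ["keep"]

    def test_total_read_rule(self):
        # 10 samples; OTU in 6 samples totalling 5 reads (5 <= 0.5*10)
        counts = {
            "low": {f"s{j}": (1 if j < 5 else 0) for j in range(10)},
            "keep": {f"s{j}": 3 for j in range(10)},
        }
        counts["low"]["s5"] = 0
        counts["low"]["s2"] = 1  # 6 samples, 6 reads -> survives total rule
        counts["low2"] = {f"s{j}": (1 if j < 5 else 0) for j in range(10)}
        out = filter_otus(_table(counts))
        assert "low2" not in out.counts.index  # 5 reads <= 5
        assert "keep" in out.counts.index

    def test_idempotent_and_never_removes_samples(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(
            rng.integers(0, 20, size=(30, 12)),
            index=[f"otu{i}" for i in range(30)],
            columns=[f"s{j}" for j in range(12)],
        )
        tbl = CountTable(counts)
        once = filter_otus(tbl)
        twice = filter_otus(once)
        pd.testing.assert_frame_equal(once.counts, twice.counts)
        assert list(once.counts.columns) == list(tbl.counts.columns)


class TestFlagLowDepth:
    def _tbl(self):
        counts = {
            "otu1": {"exp1": 60, "exp2": 500, "blank1": 400},
            "otu2": {"exp1": 23, "exp2": 400, "blank1": 348},
        }
        return _table(counts, {"blank1": "blank"})

    def test_sample_in_blank_range_removed(self):
        kept, removed = flag_low_depth_samples(self._tbl())
        assert removed == ["exp1"]  # 83 reads <= blank max 748
        assert "exp1" not in kept.counts.columns

    def test_boundary_sample_kept(self):
        tbl = self._tbl()
        tbl.counts.loc["otu1", "exp1"] = 61  # total 84 -> still below
        tbl.counts.loc["otu2", "exp1"] = 688  # total 749 > 748
        kept, removed = flag_low_depth_samples(tbl)
        assert removed == []

    def test_no_blanks_no_threshold_errors(self):
        tbl = _table({"otu1": {"s1": 100, "s2": 200}})
        with pytest.raises(ValueError, match="threshold"):
            flag_low_depth_samples(tbl)
        kept, removed = flag_low_depth_samples(tbl, blank_max_reads=50)
        assert removed == []


class TestRarefy:
    def test_full_depth_is_identity(self):
        tbl = _table({"a": {"s1": 5, "s2": 7}, "b": {"s1": 3, "s2": 1}})
        out = rarefy(tbl, depth=None, seed=0)
        assert out.sample_totals().eq(8).all()
        pd.testing.assert_series_equal(
            out.counts["s1"], tbl.counts["s1"], check_names=False
        )

    def test_hypergeometric_expectation(self):
        tbl = _table({"a": {"s": 12}, "b": {"s": 6}, "c": {"s": 2}})
        depth = 10
        draws = np.array([
            rarefy(tbl, depth=depth, seed=s).counts["s"].to_numpy()
            for s in range(1000)
        ])
        expect = depth * np.array([12, 6, 2]) / 20
        # hypergeometric variance with finite-population correction
        p = np.array([12, 6, 2]) / 20
        var = depth * p * (1 - p) * (20 - depth) / (20 - 1)
        se = np.sqrt(var / 1000)
        assert np.all(np.abs(draws.mean(axis=0) - expect) < 3 * se)

    def test_single_otu_sample(self):
        tbl = _table({"a": {"s": 50}})
        out = rarefy(tbl, depth=20, seed=1)
        assert out.counts.loc["a", "s"] == 20

    def test_depth_exceeding_total_names_sample(self):
        tbl = _table({"a": {"shallow": 5, "deep": 100}})
        with pytest.raises(ValueError, match="shallow"):
            rarefy(tbl, depth=50)


class TestRarefactionCurve:
    def test_endpoints(self):
        counts = np.array([5, 3, 2])
        assert rarefaction_curve(counts, [10])[0] == pytest.approx(3.0)
        assert rarefaction_curve(counts, [1])[0] == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration(self):
        counts = np.array([5, 3, 2])
        # enumerate all C(10,2) read pairs and count distinct OTUs observed
        reads = np.repeat([0, 1, 2], counts)
        richness = [len(set(pair)) for pair in itertools.combinations(reads, 2)]
        expected = np.mean(richness)
        assert rarefaction_curve(counts, [2])[0] == pytest.approx(expected)

    def test_depth_above_total_rejected(self):
        with pytest.raises(ValueError):
            rarefaction_curve(np.array([3, 2]), [6])


class TestCopyNumberCorrection:
    def test_equal_copies_reduce_to_read_proportions(self):
        counts = pd.DataFrame({"s": [30, 70]}, index=["a", "b"])
        cn = pd.Series([4, 4], index=["a", "b"])
        props = copy_number_correct(counts, cn)
        assert props["s"].tolist() == pytest.approx([0.3, 0.7])

    def test_worked_example(self):
        counts = pd.DataFrame({"s": [80, 20]}, index=["a", "b"])
        cn = pd.Series([4, 1], index=["a", "b"])
        props = copy_number_correct(counts, cn)
        assert props["s"].tolist() == pytest.approx([0.5, 0.5])

    def test_single_otu(self):
        counts = pd.DataFrame({"s": [42]}, index=["a"])
        props = copy_number_correct(counts, pd.Series([7], index=["a"]))
        assert props.loc["a", "s"] == 1.0

    def test_missing_copy_number_errors(self):
        counts = pd.DataFrame({"s": [10, 10]}, index=["a", "b"])
        with pytest.raises(ValueError, match="missing copy numbers"):
            copy_number_correct(counts, pd.Series([4], index=["a"]))


class TestBuildQmp:
    def test_single_otu(self):
        props = pd.DataFrame({"s": [1.0]}, index=["a"])
        qmp = build_qmp(props, pd.Series({"s": 1e9}))
        assert qmp.abundance.loc["a", "s"] == pytest.approx(1e9)

    def test_worked_example_and_round_trip(self):
        props = pd.DataFrame({"s": [0.25, 0.75]}, index=["a", "b"])
        qmp = build_qmp(props, pd.Series({"s": 4e8}))
        assert qmp.abundance["s"].tolist() == pytest.approx([1e8, 3e8])
        renorm = qmp.abundance["s"] / qmp.abundance["s"].sum()
        assert np.allclose(renorm, props["s"], atol=1e-12)

    def test_mismatched_samples_error(self):
        props = pd.DataFrame({"s1": [1.0]}, index=["a"])
        with pytest.raises(ValueError, match="differ"):
            build_qmp(props, pd.Series({"s2": 1e9}))


class TestEndToEndRecovery:
    def test_qmp_recovers_simulated_cell_concentrations(self):
        """Truth -> biased reads -> rarefy -> correct -> QMP, within the
        multinomial sampling bound at depth 10,000."""
        from transitqmp.reactor import ReactorConfig
        from transitqmp.simulate import default_panel, observe_reads, simulate_experiment

        panel = default_panel()
        with pytest.warns(UserWarning):  # sampled before stabilisation
            sim = simulate_experiment(
                ReactorConfig.for_arm("medium"), panel, n_days=3,
                sample_days=[3], seed=2,
            )
        truth = sim.samples.loc[(3, "proximal"), panel.ids].to_numpy(dtype=float)
        total = truth.sum()
        depth = 10000
        reads = observe_reads(truth, panel.copy_numbers, 2 * depth, seed=7)
        tbl = CountTable(pd.DataFrame({"s1": reads}, index=panel.ids))
        rare = rarefy(tbl, depth=depth, seed=3)
        props = copy_number_correct(
            rare.counts, pd.Series(panel.copy_numbers, index=panel.ids)
        )
        qmp = build_qmp(props, pd.Series({"s1": total}))
        est = qmp.abundance["s1"].to_numpy()
        rel = (est - truth) / truth
        rrmse = math.sqrt(np.mean(rel**2))
        p_read = truth * panel.copy_numbers
        p_read = p_read / p_read.sum()
        bound = math.sqrt(np.mean((1 - p_read) / (depth * p_read)))
        assert rrmse <= 3 * bound
        # column sums equal the cytometry total exactly
        assert qmp.column_totals()["s1"] == pytest.approx(total, rel=1e-12)
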