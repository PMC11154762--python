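import numpy as np
import pandas as pd
import pytest

from cytomr.exceptions import EmptySelectionError, InsufficientInstrumentsError
from cytomr.selection import (
    SelectionConfig,
    apply_selection_pipeline,
    clump,
    filter_confounders,
    filter_cross_exposure,
    filter_outcome_associated,
    select_instruments,
)
from cytomr.simulate import planted_violation_fixture
from cytomr.sumstats import ConfounderTable, LDTable

from conftest import make_dataset, make_instruments


class TestThresholdSelection:
    def test_strictly_below_threshold_kept(self):
        ds = make_dataset(pval=[1e-9, 2e-8, 1e-5])
        kept, entries = select_instruments(ds, 5e-8)
        assert kept.records["snp_id"].tolist() == ["rs1", "rs2"]

    def test_boundary_pval_removed(self):
        ds = make_dataset(pval=[5e-8, 1e-9, 1e-9])
        kept, _ = select_instruments(ds, 5e-8)
        assert "rs1" not in kept.snp_ids()

    def test_zero_survivors_signal(self):
        ds = make_dataset(pval=[0.5, 0.5, 0.5])
        with pytest.raises(EmptySelectionError):
            select_instruments(ds, 5e-8)


def _clump_oracle(records, ld, r2_threshold, window_kb):
    """Independent greedy-definition re-implementation on plain tuples."""
    rows = sorted(
        records.itertuples(index=False), key=lambda r: (r.pval, r.snp_id)
    )
    kept, excluded = [], set()
    for row in rows:
        if row.snp_id in excluded:
            continue
        kept.append(row.snp_id)
        for other in rows:
            if other.snp_id == row.snp_id or other.snp_id in excluded:
                continue
            if (
                other.chrom == row.chrom
                and abs(other.pos - row.pos) <= window_kb * 1000
                and ld.r2(row.snp_id, other.snp_id) >= r2_threshold
            ):
                excluded.add(other.snp_id)
    return kept


class TestClumping:
    def test_single_snp_kept(self):
        ds = make_dataset(snp_id=["rs1"], chrom=["1"], pos=[100])
        kept, _ = clump(ds, LDTable())
        assert kept.records["snp_id"].tolist() == ["rs1"]

    def test_weaker_snp_in_ld_removed(self):
        ds = make_dataset(
            snp_id=["rsA", "rsB"], chrom=["1", "1"], pos=[1_000_000, 1_050_000],
            pval=[1e-9, 1e-8],
        )
        ld = LDTable([("rsA", "rsB", 0.5)])
        kept, entries = clump(ds, ld)
        assert kept.records["snp_id"].tolist() == ["rsA"]
        removed = [e for e in entries if e.action == "removed"]
        assert removed[0].snp_id == "rsB" and "rsA" in removed[0].reason

    def test_low_ld_pair_both_kept(self):
        ds = make_dataset(
            snp_id=["rsA", "rsB"], chrom=["1", "1"], pos=[1_000_000, 1_050_000],
            pval=[1e-9, 1e-8],
        )
        kept, _ = clump(ds, LDTable([("rsA", "rsB", 0.005)]))
        assert set(kept.records["snp_id"]) == {"rsA", "rsB"}

    def test_outside_window_not_clumped(self):
        ds = make_dataset(
            snp_id=["rsA", "rsB"], chrom=["1", "1"],
            pos=[1_000_000, 1_000_000 + 10_001_000], pval=[1e-9, 1e-8],
        )
        kept, _ = clump(ds, LDTable([("rsA", "rsB", 0.9)]))
        assert set(kept.records["snp_id"]) == {"rsA", "rsB"}

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_independent_oracle_on_random_panels(self, seed):
        rng = np.random.default_rng(seed)
        j = 10
        ids = [f"rs{i}" for i in range(j)]
        ds = make_dataset(
            snp_id=ids,
            chrom=[str(rng.integers(1, 3)) for _ in range(j)],
            pos=[int(p) for p in rng.integers(1, 3e7, j)],
            pval=rng.uniform(1e-12, 1e-8, j).tolist(),
        )
        ld = LDTable()
        for a in range(j):
            for b in range(a + 1, j):
                if rng.random() < 0.4:
                    ld.add(ids[a], ids[b], float(rng.random()))
        kept, _ = clump(ds, ld)
        expected = _clump_oracle(ds.records, ld, 0.01, 10000)
        assert sorted(kept.records["snp_id"]) == sorted(expected)

    def test_missing_ld_pairs_counted(self):
        from cytomr.filterlog import FilterLog

        ds = make_dataset(
            snp_id=["rsA", "rsB"], chrom=["1", "1"], pos=[1_000_000, 1_050_000],
            pval=[1e-9, 1e-8],
        )
        log = FilterLog()
        clump(ds, LDTable(), log=log)
        assert log.missing_ld_pairs == 1


class TestCrossExposure:
    def test_shared_snp_removed_from_all(self):
        out, entries = filter_cross_exposure(
            {"IL16": {"rs1", "rs2"}, "CTACK": {"rs1", "rs3"}}
        )
        assert out == {"IL16": {"rs2"}, "CTACK": {"rs3"}}
        removed = [e.snp_id for e in entries if e.action == "removed"]
        assert removed.count("rs1") == 2

    def test_single_exposure_unchanged(self):
        out, _ = filter_cross_exposure({"IL16": {"rs1", "rs2"}})
        assert out == {"IL16": {"rs1", "rs2"}}


class TestConfounderFilter:
    def test_annotated_snp_removed_with_named_reason(self):
        ds = make_dataset()
        out, entries = filter_confounders(ds, ConfounderTable({"rs1": ["BMI"]}))
        assert sorted(out.records["snp_id"]) == ["rs2", "rs3"]
        removed = [e for e in entries if e.action == "removed"]
        assert removed[0].snp_id == "rs1" and "BMI" in removed[0].reason

    def test_empty_table_is_identity(self):
        ds = make_dataset()
        out, _ = filter_confounders(ds, ConfounderTable())
        assert out.records["snp_id"].tolist() == ds.records["snp_id"].tolist()


class TestOutcomeAssociationFilter:
    def test_strict_threshold(self):
        inst = make_instruments([0.2] * 3, 0.01, [0.02] * 3, 0.01,
                                pval_out=[1e-6, 0.3, 5e-5])
        out, entries = filter_outcome_associated(inst, 5e-5)
        # 1e-6 removed; 0.3 kept; exactly 5e-5 kept (strict <)
        assert out["snp_id"].tolist() == ["rs1", "rs2"]


class TestFullPipeline:
    def test_planted_fixture_one_removal_per_step(self):
        exposure, outcome, ld, conf, ctx, truth = planted_violation_fixture()
        inst, log = apply_selection_pipeline(
            exposure, outcome, ld, conf, ctx, SelectionConfig()
        )
        for step, sid in truth["removed_by_step"].items():
            assert log.removed(step) == [sid], f"step {step}"
        assert sorted(inst["snp_id"]) == truth["final"]

    def test_monotonic_and_complete_log(self):
        exposure, outcome, ld, conf, ctx, _ = planted_violation_fixture()
        _, log = apply_selection_pipeline(
            exposure, outcome, ld, conf, ctx, SelectionConfig()
        )
        df = log.to_frame()
        prev = None
        for step in sorted(df["step"].unique()):
            at_step = df[df["step"] == step]
            entering = set(at_step["snp_id"])
            # |kept| + |removed| equals that step's input size
            assert len(at_step) == len(entering)
            if prev is not None:
                assert entering <= prev, f"step {step} saw new SNPs"
            prev = set(at_step.loc[at_step["action"] == "kept", "snp_id"])
        # removed SNPs never reappear
        for step in sorted(df["step"].unique()):
            gone = set(log.removed(step))
            later = df[df["step"] > step]
            assert gone.isdisjoint(set(later["snp_id"]))

    def test_insufficient_survivors_signal(self):
        exposure = make_dataset(snp_id=["rs1", "rs2"], chrom=["1", "2"],
                                pos=[1, 2], pval=[1e-9, 1e-9],
                                beta=[0.2, 0.2])
        outcome = make_dataset(snp_id=["rs1", "rs2"], chrom=["1", "2"],
                               pos=[1, 2], pval=[0.5, 0.5])
        with pytest.raises(InsufficientInstrumentsError) as err:
            apply_selection_pipeline(
                exposure, outcome, cfg=SelectionConfig(min_instruments=3)
            )
        assert err.value.n_surviving == 2
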