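import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from panelscope.panel_model import PanelDefinition, TargetRegion, bin_panel
from panelscope import cnv_caller as cnv
from panelscope import synthetic_data as sim


def make_track(depths, pool, sample_id="s", sex="female", params=None):
    return cnv.normalize_fold_depth(cnv.BinDepths(sample_id, depths, sex), pool, params)


class TestNormalizeFoldDepth:
    def test_self_normalization(self, tiny_bins, flat_pool):
        track = make_track(np.full(len(tiny_bins), 500.0), flat_pool)
        assert np.allclose(track.fold, 1.0)
        assert np.allclose(track.z, 0.0)

    def test_half_depth_bins(self, tiny_bins, flat_pool):
        depths = np.full(len(tiny_bins), 500.0)
        depths[10:14] *= 0.5
        track = make_track(depths, flat_pool)
        # oracle: direct ratio arithmetic (median normalization unaffected by 4/100 bins)
        assert np.allclose(track.fold[10:14], 0.5)
        mask = np.ones(len(tiny_bins), bool)
        mask[10:14] = False
        assert np.allclose(track.fold[mask], 1.0)

    def test_library_size_invariance(self, tiny_bins, flat_pool):
        base = np.full(len(tiny_bins), 500.0)
        base[30:40] *= 0.5
        t1 = make_track(base, flat_pool)
        t2 = make_track(base * 7.3, flat_pool)
        assert np.allclose(t1.fold, t2.fold)
        assert np.allclose(t1.z, t2.z)

    def test_global_2x_no_cnv(self, tiny_bins, flat_pool):
        track = make_track(np.full(len(tiny_bins), 1000.0), flat_pool)
        assert np.allclose(track.fold, 1.0)

    def test_zero_median_sample_rejected(self, tiny_bins, flat_pool):
        with pytest.raises(cnv.CnvError, match="zero median"):
            make_track(np.zeros(len(tiny_bins)), flat_pool)

    def test_zero_pool_bin_flagged_uninformative(self, tiny_panel, tiny_bins):
        flat = np.full(len(tiny_bins), 500.0)
        dead = flat.copy()
        dead[5] = 0.0
        pool = cnv.ReferencePool(
            members=[cnv.BinDepths(f"r{i}", dead.copy(), "female") for i in range(3)],
            bins=tiny_bins,
        )
        track = make_track(flat, pool)
        assert not track.informative[5]
        assert np.isnan(track.fold[5])

    def test_misaligned_sample_rejected(self, flat_pool):
        with pytest.raises(cnv.CnvError):
            make_track(np.full(7, 100.0), flat_pool)

    def test_pool_needs_three_members(self, tiny_bins):
        flat = np.full(len(tiny_bins), 500.0)
        with pytest.raises(cnv.CnvError, match=">= 3"):
            cnv.ReferencePool(
                members=[cnv.BinDepths("a", flat), cnv.BinDepths("b", flat)], bins=tiny_bins
            )


class TestCallLossEvents:
    def test_null_profile_empty(self, tiny_panel, tiny_bins, flat_pool):
        track = make_track(np.full(len(tiny_bins), 500.0), flat_pool)
        assert cnv.call_loss_events(track, tiny_panel) == []

    def test_three_bin_drop_called_150bp(self, tiny_panel, tiny_bins, flat_pool):
        depths = np.full(len(tiny_bins), 500.0)
        depths[20:23] *= 0.5
        track = make_track(depths, flat_pool)
        events = cnv.call_loss_events(track, tiny_panel)
        assert len(events) == 1
        assert events[0].span_bp == 150
        assert events[0].n_bins == 3
        assert events[0].copy_number == 1

    def test_two_bin_drop_not_called(self, tiny_panel, tiny_bins, flat_pool):
        depths = np.full(len(tiny_bins), 500.0)
        depths[20:22] *= 0.5
        track = make_track(depths, flat_pool)
        # oracle: exhaustive run-length scan of the significance vector
        sig = (track.z < -3.0) & (track.fold < 0.75)
        longest = max(
            (len(run) for run in "".join("x" if s else "." for s in sig).split(".")), default=0
        )
        assert longest == 2
        assert cnv.call_loss_events(track, tiny_panel) == []

    def test_resolution_smallest_span_150(self, tiny_panel, tiny_bins, flat_pool):
        called = {}
        for width in (50, 100, 150, 200):
            depths = np.full(len(tiny_bins), 500.0)
            depths[20 : 20 + width // 50] *= 0.5
            track = make_track(depths, flat_pool)
            called[width] = bool(cnv.call_loss_events(track, tiny_panel))
        assert called == {50: False, 100: False, 150: True, 200: True}

    def test_runs_do_not_cross_chromosomes(self):
        panel = PanelDefinition(
            [TargetRegion("chr1", 0, 100, "A"), TargetRegion("chr2", 0, 100, "B")], bin_length=50
        )
        bins = bin_panel(panel)
        flat = np.full(4, 500.0)
        pool = cnv.ReferencePool(
            members=[cnv.BinDepths(f"r{i}", flat.copy()) for i in range(3)], bins=bins
        )
        depths = flat.copy() * np.array([1, 0.5, 0.5, 0.5])  # 1 bin chr1 + 2 bins chr2... no:
        depths = np.array([500.0, 250.0, 250.0, 250.0])  # last chr1 bin + both chr2 bins low
        track = make_track(depths, pool)
        # 3 significant bins, but split 1 + 2 across chromosomes -> no event
        assert cnv.call_loss_events(track, panel) == []

    def test_monotonicity_deepening_loss(self, tiny_panel, tiny_bins, flat_pool):
        base = np.full(len(tiny_bins), 500.0)
        base[40:46] *= 0.6
        e1 = cnv.call_loss_events(make_track(base, flat_pool), tiny_panel)
        deeper = np.full(len(tiny_bins), 500.0)
        deeper[40:46] *= 0.3
        e2 = cnv.call_loss_events(make_track(deeper, flat_pool), tiny_panel)
        assert len(e2) >= len(e1) == 1
        assert e2[0].span_bp >= e1[0].span_bp

    def test_invalid_params_rejected(self):
        with pytest.raises(cnv.CnvError):
            cnv.CnvParams(z_threshold=0)
        with pytest.raises(cnv.CnvError):
            cnv.CnvParams(min_consecutive_bins=-1)

    def test_gene_annotation(self, tiny_panel, tiny_bins, flat_pool):
        depths = np.full(len(tiny_bins), 500.0)
        depths[0:5] *= 0.5
        events = cnv.call_loss_events(make_track(depths, flat_pool), tiny_panel)
        assert events[0].genes == ["GENE"]
        assert events[0].labels == ["GENE:ex1"]


class TestEstimateCopyNumber:
    def test_exact_halving(self):
        mf, l2, est, n = cnv.estimate_copy_number([0.5, 0.5, 0.5], [50, 50, 50])
        assert (mf, l2, est, n) == (0.5, -1.0, 1.0, 1)

    def test_printed_log2_values(self):
        folds = [2**-1.06, 2**-1.12, 2**-1.04]
        mf, l2, est, n = cnv.estimate_copy_number(folds, [50, 50, 50])
        assert l2 == pytest.approx(-1.06)
        assert n == 1

    def test_identity(self):
        mf, l2, est, n = cnv.estimate_copy_number([1.0], [50])
        assert n == 2 and l2 == 0.0

    def test_zero_fold_sentinel(self):
        mf, l2, est, n = cnv.estimate_copy_number([0.0, 0.0, 0.0], [50, 50, 50])
        assert est == 0.0 and n == 0 and l2 == float("-inf")

    def test_ties_round_toward_lower_cn(self):
        # estimate exactly 1.5 -> copy number 1, not 2
        mf, l2, est, n = cnv.estimate_copy_number([0.75], [50])
        assert est == 1.5 and n == 1

    def test_male_x_ploidy_one(self, flat_pool):
        mf, l2, est, n = cnv.estimate_copy_number([0.4], [50], ploidy=1)
        assert est == pytest.approx(0.4) and n == 0

    def test_width_weighted_median(self):
        # wide bin dominates: values 0.5 (width 50) and 0.2 (width 3)
        assert cnv.weighted_median([0.2, 0.5], [3, 50]) == 0.5


class TestWeightedMedianProperty:
    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(0.0, 2.0), min_size=1, max_size=20))
    def test_equal_weights_matches_lower_median(self, values):
        got = cnv.weighted_median(values, [1.0] * len(values))
        srt = sorted(values)
        # lower median: element where cumulative weight first reaches half
        n = len(srt)
        want = srt[(n - 1) // 2] if n % 2 else srt[n // 2 - 1]
        assert got == want


class TestPipelineOnSimulatedData:
    def make_pool(self, panel, bins, seed=11, n=6, mean_depth=500.0):
        cfg = sim.SimulationConfig(seed=seed, mean_depth=mean_depth, pool_size=n)
        members = sim.simulate_reference_pool(cfg, panel)
        return cnv.ReferencePool(
            members=[
                cnv.BinDepths(sid, cnv.mean_bin_depths(df, bins), sex)
                for sid, sex, df in members
            ],
            bins=bins,
        )

    def test_table2_analog_cohort(self, bundled_panel, bundled_bins):
        pool = self.make_pool(bundled_panel, bundled_bins)
        deletions = sim.table2_analog_deletions(bundled_panel)
        detected = 0
        for i, d in enumerate(deletions):
            cfg = sim.SimulationConfig(seed=100 + i)
            df, _ = sim.simulate_depth_profile(cfg, bundled_panel, deletions=[d])
            sample = cnv.BinDepths(d.label, cnv.mean_bin_depths(df, bundled_bins), "female")
            events = cnv.call_loss_events(
                cnv.normalize_fold_depth(sample, pool), bundled_panel
            )
            hits = [e for e in events if d.gene in e.genes]
            if hits:
                detected += 1
                assert all(e.copy_number == 1 for e in hits)
                # recovered estimate near one copy (printed observed range 1.01-1.11)
                assert all(abs(e.copy_number_estimate - 1.0) <= 0.15 for e in hits)
        assert detected >= 4

    def test_homozygous_deletion(self, tiny_panel, tiny_bins, flat_pool):
        depths = np.full(len(tiny_bins), 500.0)
        depths[50:60] = 0.0
        events = cnv.call_loss_events(make_track(depths, flat_pool), tiny_panel)
        assert len(events) == 1
        assert events[0].copy_number == 0
        assert events[0].log2_ratio == float("-inf")

    def test_pool_member_zero_events(self, bundled_panel, bundled_bins):
        pool = self.make_pool(bundled_panel, bundled_bins)
        sample = cnv.BinDepths("member0", pool.members[0].depths.copy(), pool.members[0].sex)
        events = cnv.call_loss_events(
            cnv.normalize_fold_depth(sample, pool), bundled_panel
        )
        assert events == []

    def test_null_specificity_20_samples(self, bundled_panel, bundled_bins):
        """No false events and per-bin false-significance below nominal on
        20 seeded pool-like samples."""
        pool = self.make_pool(bundled_panel, bundled_bins)
        params = cnv.CnvParams()
        n_sig = n_bins = n_events = 0
        for s in range(20):
            cfg = sim.SimulationConfig(seed=5000 + s)
            df, _ = sim.simulate_depth_profile(cfg, bundled_panel)
            sample = cnv.BinDepths(f"null{s}", cnv.mean_bin_depths(df, bundled_bins), "female")
            track = cnv.normalize_fold_depth(sample, pool, params)
            sig = (
                track.informative
                & (np.nan_to_num(track.z, nan=np.inf) < -params.z_threshold)
                & (np.nan_to_num(track.fold, nan=np.inf) < params.fold_ceiling)
            )
            n_sig += int(sig.sum())
            n_bins += int(track.informative.sum())
            n_events += len(cnv.call_loss_events(track, bundled_panel, params))
        assert n_events == 0
        # conjunction of z- and fold-gates is rarer than the z tail alone
        assert n_sig / n_bins <= 0.0015 + 3 * math.sqrt(0.0015 / n_bins)

    def test_male_x_deletion(self, bundled_panel, bundled_bins):
        pool = self.make_pool(bundled_panel, bundled_bins)
        rpgr = bundled_panel.regions_for_gene("RPGR")
        ex1 = next(r for r in rpgr if r.label == "ex1")
        ex5 = next(r for r in rpgr if r.label == "ex5")
        deletion = sim.PlannedDeletion("chrX", ex1.start, ex5.end, "het", "RPGR")
        cfg = sim.SimulationConfig(seed=77, sex="male")
        df, _ = sim.simulate_depth_profile(cfg, bundled_panel, deletions=[deletion])
        sample = cnv.BinDepths("maleX", cnv.mean_bin_depths(df, bundled_bins), "male")
        events = cnv.call_loss_events(cnv.normalize_fold_depth(sample, pool), bundled_panel)
        hits = [e for e in events if "RPGR" in e.genes]
        assert hits
        # male X uses ploidy 1: half-depth fold gives estimate ~0.5 (ploidy 2
        # would put it near 1.0) and never a normal copy number
        for e in hits:
            assert e.copy_number_estimate == pytest.approx(0.5, abs=0.15)
            assert e.copy_number <= 1


class TestDepthIO:
    def test_tsv_round_trip(self, tiny_panel, tiny_bins, tmp_path):
        cfg = sim.SimulationConfig(seed=5, dispersion=0.0, mean_depth=100.0)
        df, _ = sim.simulate_depth_profile(cfg, tiny_panel)
        path = tmp_path / "s.depth.tsv"
        sim.write_depth_tsv(df, path)
        bd = cnv.bin_depths_from_tsv(path, tiny_panel, tiny_bins)
        assert np.allclose(bd.depths, 100.0)

    def test_missing_bases_count_zero(self, tiny_panel, tiny_bins, tmp_path):
        path = tmp_path / "s.depth.tsv"
        # only the first 25 bases of bin 0 covered at depth 100
        path.write_text("".join(f"chr1\t{p}\t100\n" for p in range(1, 26)))
        bd = cnv.bin_depths_from_tsv(path, tiny_panel, tiny_bins)
        assert bd.depths[0] == pytest.approx(50.0)
        assert np.all(bd.depths[1:] == 0)

    def test_pool_dir_with_manifest(self, tiny_panel, tiny_bins, tmp_path):
        cfg = sim.SimulationConfig(seed=9, pool_size=3, mean_depth=200.0)
        sim.simulate_reference_pool(cfg, tiny_panel, out_dir=tmp_path)
        pool = cnv.read_pool_dir(tmp_path, tiny_panel, tiny_bins)
        assert len(pool.members) == 3
        assert pool.members[0].sample_id == "ref00"

    def test_events_tsv_one_based(self, tiny_panel, tiny_bins, flat_pool, tmp_path):
        depths = np.full(len(tiny_bins), 500.0)
        depths[20:23] *= 0.5
        events = cnv.call_loss_events(make_track(depths, flat_pool), tiny_panel)
        out = tmp_path / "ev.tsv"
        cnv.events_to_tsv(events, out)
        import pandas as pd

        df = pd.read_csv(out, sep="\t")
        assert df.loc[0, "start"] == events[0].start + 1  # 1-based inclusive


def test_cnv_pipeline_audit_track(tiny_panel, tiny_bins, flat_pool):
    depths = np.full(len(tiny_bins), 500.0)
    depths[20:23] *= 0.5
    result = cnv.cnv_pipeline(cnv.BinDepths("s", depths, "female"), flat_pool, tiny_panel)
    assert len(result["events"]) == 1
    audit = result["audit_track"]
    assert len(audit["fold"]) == len(tiny_bins)
    assert audit["fold"][21] == pytest.approx(0.5)
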