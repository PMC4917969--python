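"""Focal amplification/deletion criteria against an independent rule checker."""

import numpy as np
import pandas as pd
import pytest

from plasmacnv.focal import (
    FocalCriteria,
    GeneAnnotation,
    call_focal_amplifications,
    call_focal_deletions,
    count_focal_per_sample,
    empty_track,
    flank_weighted_mean,
    interval_union_overlap,
    log2_to_copies,
)
from plasmacnv.segmentation import SegmentedProfile

from oracles import flank_mean_per_bp, focal_check_brute

KB = 1000


def _seg_profile(rows, sample="s"):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_bins", "bp", "mean_log2"])
    return SegmentedProfile(sample_id=sample, segments=df)


def _track(rows):
    if not rows:
        return empty_track()
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


class TestLog2ToCopies:
    @pytest.mark.parametrize(
        "log2,baseline,copies",
        [(0.58, 2, 3), (0.0, 2, 2), (1.0, 2, 4), (np.log2(13), 1, 13)],
    )
    def test_known_conversions(self, log2, baseline, copies):
        assert round(log2_to_copies(log2, baseline)) == copies

    def test_invalid_baseline(self):
        with pytest.raises(ValueError):
            log2_to_copies(0.5, 3)


class TestFlankWeightedMean:
    def test_zero_flanks(self):
        prof = _seg_profile(
            [
                ("chr1", 0, 30_000_000, 300, 30_000_000, 0.0),
                ("chr1", 30_000_000, 32_000_000, 20, 2_000_000, 1.0),
                ("chr1", 32_000_000, 60_000_000, 280, 28_000_000, 0.0),
            ]
        )
        assert flank_weighted_mean(prof, 1) == 0.0

    def test_symmetric_length_weighting(self):
        """10 Mb at 0.1 and 10 Mb at 0.3 on each side -> 0.2."""
        prof = _seg_profile(
            [
                ("chr1", 0, 10_000_000, 100, 10_000_000, 0.1),
                ("chr1", 10_000_000, 20_000_000, 100, 10_000_000, 0.3),
                ("chr1", 20_000_000, 22_000_000, 20, 2_000_000, 1.5),
                ("chr1", 22_000_000, 32_000_000, 100, 10_000_000, 0.3),
                ("chr1", 32_000_000, 42_000_000, 100, 10_000_000, 0.1),
            ]
        )
        assert flank_weighted_mean(prof, 2) == pytest.approx(0.2)

    def test_chromosome_start_uses_right_window_only(self):
        prof = _seg_profile(
            [
                ("chr1", 0, 2_000_000, 20, 2_000_000, 1.0),
                ("chr1", 2_000_000, 12_000_000, 100, 10_000_000, 0.4),
                ("chr1", 12_000_000, 50_000_000, 380, 38_000_000, 0.1),
            ]
        )
        got = flank_weighted_mean(prof, 0)
        brute = flank_mean_per_bp(prof.segments, 0)
        assert got == pytest.approx(brute, rel=1e-9)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_per_bp_oracle_on_random_profiles(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(3, 10)
        bounds = np.sort(rng.choice(np.arange(1, 80) * KB * 500, size=n - 1, replace=False))
        bounds = np.concatenate([[0], bounds, [40_000_000]])
        rows = [
            ("chr1", int(a), int(b), max(1, (b - a) // 50_000), int(b - a),
             float(rng.normal(0, 0.5)))
            for a, b in zip(bounds[:-1], bounds[1:])
        ]
        prof = _seg_profile(rows)
        target = int(rng.integers(0, n))
        got = flank_weighted_mean(prof, target)
        brute = flank_mean_per_bp(prof.segments, target)
        assert got == pytest.approx(brute, rel=1e-9, abs=1e-12)

    def test_missing_target_rejected(self):
        prof = _seg_profile([("chr1", 0, 1_000_000, 10, 1_000_000, 0.0)])
        with pytest.raises(KeyError):
            flank_weighted_mean(prof, 5)


class TestFocalExamples:
    def _genes(self):
        genes = _track(
            [
                ("chr1", 20_500_000, 20_600_000, "DRV1"),
                ("chr1", 21_000_000, 21_100_000, "GENE_A"),
                ("chr2", 10_200_000, 10_300_000, "DELG1"),
                ("chr2", 30_000_000, 30_100_000, "GENE_B"),
            ]
        )
        return GeneAnnotation(genes, drivers={"DRV1"}, deletion_genes={"DELG1"})

    def _amp_profile(self, mean=0.9, start=20_000_000, end=22_000_000):
        return _seg_profile(
            [
                ("chr1", 0, start, 200, start, 0.0),
                ("chr1", start, end, 20, end - start, mean),
                ("chr1", end, 60_000_000, 380, 60_000_000 - end, 0.0),
            ]
        )

    def test_driver_amplicon_called(self):
        events, rej = call_focal_amplifications(
            self._amp_profile(), self._genes(), empty_track(), empty_track()
        )
        assert len(events) == 1
        assert events["has_driver"].iloc[0]
        assert "DRV1" in events["genes"].iloc[0]
        assert len(rej) == 0

    def test_oversized_segment_rejected(self):
        prof = _seg_profile(
            [
                ("chr1", 0, 20_000_000, 200, 20_000_000, 0.0),
                ("chr1", 20_000_000, 45_000_000, 250, 25_000_000, 1.5),
                ("chr1", 45_000_000, 60_000_000, 150, 15_000_000, 0.0),
            ]
        )
        events, rej = call_focal_amplifications(
            prof, self._genes(), empty_track(), empty_track()
        )
        assert len(events) == 0
        assert rej["failed_rule"].tolist() == ["size"]

    def test_nondriver_amplicon_needs_058(self):
        prof = _seg_profile(
            [
                ("chr1", 0, 20_900_000, 200, 20_900_000, 0.0),
                ("chr1", 20_900_000, 21_500_000, 6, 600_000, 0.5),
                ("chr1", 21_500_000, 60_000_000, 380, 38_500_000, 0.0),
            ]
        )
        events, rej = call_focal_amplifications(
            prof, self._genes(), empty_track(), empty_track()
        )
        assert len(events) == 0
        assert rej["failed_rule"].tolist() == ["flank_delta"]

    def test_driver_gene_relaxes_flank_threshold(self):
        """A 0.5-amplitude amplicon fails as non-driver but passes with a driver."""
        prof = _seg_profile(
            [
                ("chr1", 0, 20_000_000, 200, 20_000_000, 0.0),
                ("chr1", 20_000_000, 22_000_000, 20, 2_000_000, 0.5),
                ("chr1", 22_000_000, 60_000_000, 380, 38_000_000, 0.0),
            ]
        )
        no_driver = GeneAnnotation(self._genes().genes, drivers=set())
        with_driver = self._genes()
        ev_no, _ = call_focal_amplifications(prof, no_driver, empty_track(), empty_track())
        ev_yes, _ = call_focal_amplifications(prof, with_driver, empty_track(), empty_track())
        assert len(ev_no) == 0 and len(ev_yes) == 1

    def test_segdup_covered_segment_rejected(self):
        segdup = _track([("chr1", 20_000_000, 21_300_000, "sd1")])  # 65% of 2 Mb
        events, rej = call_focal_amplifications(
            self._amp_profile(), self._genes(), segdup, empty_track()
        )
        assert len(events) == 0
        assert rej["failed_rule"].tolist() == ["segdup"]

    def test_germline_cnv_covered_segment_rejected(self):
        dgv = _track([("chr1", 20_000_000, 21_100_000, "dgv1")])  # 55% coverage
        events, rej = call_focal_amplifications(
            self._amp_profile(), self._genes(), empty_track(), dgv
        )
        assert len(events) == 0
        assert rej["failed_rule"].tolist() == ["germline_cnv"]

    def test_missing_tracks_rejected(self):
        with pytest.raises(ValueError):
            call_focal_amplifications(self._amp_profile(), self._genes(), None, None)

    def test_deletion_with_known_gene_called(self):
        prof = _seg_profile(
            [
                ("chr2", 0, 10_000_000, 100, 10_000_000, 0.0),
                ("chr2", 10_000_000, 11_000_000, 10, 1_000_000, -0.9),
                ("chr2", 11_000_000, 60_000_000, 490, 49_000_000, 0.0),
            ]
        )
        events, _ = call_focal_deletions(
            prof, self._genes(), empty_track(), empty_track()
        )
        assert len(events) == 1
        assert "DELG1" in events["genes"].iloc[0]

    def test_deletion_without_known_gene_rejected(self):
        prof = _seg_profile(
            [
                ("chr2", 0, 29_500_000, 295, 29_500_000, 0.0),
                ("chr2", 29_500_000, 30_500_000, 10, 1_000_000, -0.9),
                ("chr2", 30_500_000, 60_000_000, 295, 29_500_000, 0.0),
            ]
        )
        events, rej = call_focal_deletions(
            prof, self._genes(), empty_track(), empty_track()
        )
        assert len(events) == 0
        assert rej["failed_rule"].tolist() == ["no_deletion_gene"]

    def test_shallow_deletion_rejected_on_threshold(self):
        prof = _seg_profile(
            [
                ("chr2", 0, 10_000_000, 100, 10_000_000, 0.0),
                ("chr2", 10_000_000, 11_000_000, 10, 1_000_000, -0.15),
                ("chr2", 11_000_000, 60_000_000, 490, 49_000_000, 0.0),
            ]
        )
        events, rej = call_focal_deletions(
            prof, self._genes(), empty_track(), empty_track()
        )
        assert len(events) == 0
        assert len(rej) == 0  # below base threshold: not a traced candidate


def _random_configuration(rng):
    """A random segmented chromosome plus random annotation tracks.

    All coordinates land on a 1-kb lattice so the brute-force checker's
    block-based coverage count is exact.
    """
    chrom_len = 100_000_000
    n_seg = int(rng.integers(2, 9))
    cuts = np.sort(rng.choice(np.arange(1, chrom_len // KB), size=n_seg - 1, replace=False)) * KB
    bounds = np.concatenate([[0], cuts, [chrom_len]])
    rows = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        rows.append(
            ("chr1", int(a), int(b), max(1, (b - a) // 50_000), int(b - a),
             float(rng.choice([-1.2, -0.6, -0.3, 0.0, 0.25, 0.5, 0.7, 1.2])))
        )
    segments = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_bins", "bp", "mean_log2"]
    )

    def random_track(n_max, max_len_kb):
        n = int(rng.integers(0, n_max + 1))
        out = []
        for k in range(n):
            s = int(rng.integers(0, chrom_len // KB - max_len_kb)) * KB
            e = s + int(rng.integers(1, max_len_kb)) * KB
            out.append(("chr1", s, e, f"e{k}"))
        return _track(out)

    genes = random_track(12, 5000)
    genes["name"] = [f"G{k}" for k in range(len(genes))]
    drivers = set(rng.choice(genes["name"], size=len(genes) // 3, replace=False)) if len(genes) else set()
    del_genes = set(rng.choice(genes["name"], size=len(genes) // 3, replace=False)) if len(genes) else set()
    segdup = random_track(6, 30_000)
    germline = random_track(6, 30_000)
    return segments, genes, drivers, del_genes, segdup, germline


class TestOracleEquivalence:
    @pytest.mark.parametrize("batch", range(10))
    def test_caller_matches_brute_force_checker(self, batch):
        """Accept/reject decisions equal the independent rule-by-rule oracle
        over randomized segment/annotation configurations (100 per batch)."""
        rng = np.random.default_rng(1000 + batch)
        for _ in range(100):
            segments, genes, drivers, del_genes, segdup, germline = _random_configuration(rng)
            annotation = GeneAnnotation(
                genes if len(genes) else empty_track(),
                drivers=drivers,
                deletion_genes=del_genes,
            )
            prof = SegmentedProfile(sample_id="s", segments=segments)
            amps, _ = call_focal_amplifications(prof, annotation, segdup, germline)
            dels, _ = call_focal_deletions(prof, annotation, segdup, germline)
            called_amp = {(int(r["start"]), int(r["end"])) for _, r in amps.iterrows()}
            called_del = {(int(r["start"]), int(r["end"])) for _, r in dels.iterrows()}
            for i in range(len(segments)):
                key = (int(segments["start"].iloc[i]), int(segments["end"].iloc[i]))
                want_amp = focal_check_brute(
                    segments, i, genes, drivers, del_genes, segdup, germline,
                    "amplification",
                )
                want_del = focal_check_brute(
                    segments, i, genes, drivers, del_genes, segdup, germline,
                    "deletion",
                )
                assert (key in called_amp) == want_amp
                assert (key in called_del) == want_del


class TestAuditTrail:
    def test_every_rejected_candidate_has_one_rule(self):
        rng = np.random.default_rng(77)
        for _ in range(50):
            segments, genes, drivers, del_genes, segdup, germline = _random_configuration(rng)
            annotation = GeneAnnotation(
                genes if len(genes) else empty_track(),
                drivers=drivers,
                deletion_genes=del_genes,
            )
            prof = SegmentedProfile(sample_id="s", segments=segments)
            amps, rej = call_focal_amplifications(prof, annotation, segdup, germline)
            above = (segments["mean_log2"] > 0.2).sum()
            assert len(amps) + len(rej) == above
            if len(rej):
                assert rej["failed_rule"].notna().all()


class TestInternalExternalParity:
    def test_seg_roundtrip_produces_identical_calls(self, tmp_path, synthetic_genes):
        from plasmacnv.io import read_seg, write_seg

        prof = _seg_profile(
            [
                ("chr1", 0, 29_900_000, 299, 29_900_000, 0.0),
                ("chr1", 29_900_000, 32_000_000, 21, 2_100_000, 0.9),
                ("chr1", 32_000_000, 50_000_000, 180, 18_000_000, 0.0),
            ]
        )
        path = tmp_path / "x.seg"
        write_seg(prof, path)
        loaded = read_seg(path)[0]
        a, _ = call_focal_amplifications(prof, synthetic_genes, empty_track(), empty_track())
        b, _ = call_focal_amplifications(loaded, synthetic_genes, empty_track(), empty_track())
        pd.testing.assert_frame_equal(a, b)


class TestCountFocal:
    def _events(self, n, samples):
        rng = np.random.default_rng(0)
        return pd.DataFrame(
            {
                "sample": rng.choice(samples, size=n),
                "class": rng.choice(["amplification", "deletion"], size=n),
            }
        )

    def test_cohort_mean_594_over_95(self):
        events = self._events(594, [f"s{i}" for i in range(95)])
        out = count_focal_per_sample(events, n_samples=95)
        assert out["mean_per_unit"] == pytest.approx(6.25, abs=0.005)

    def test_one_per_patient_343_over_43(self):
        samples = [f"p{i}_s0" for i in range(43)]
        events = self._events(343, samples)
        pm = pd.DataFrame({"sample": samples, "patient": [s.split("_")[0] for s in samples]})
        out = count_focal_per_sample(events, one_per_patient=True, patient_map=pm)
        assert out["mean_per_unit"] == pytest.approx(7.98, abs=0.005)

    def test_no_events_mean_zero(self):
        events = pd.DataFrame(columns=["sample", "class"])
        out = count_focal_per_sample(events, n_samples=10)
        assert out["mean_per_unit"] == 0.0

    def test_missing_patient_mapping_rejected(self):
        events = pd.DataFrame({"sample": ["a"], "class": ["amplification"]})
        pm = pd.DataFrame({"sample": ["b"], "patient": ["p1"]})
        with pytest.raises(ValueError):
            count_focal_per_sample(events, one_per_patient=True, patient_map=pm)


class TestIntervalUnion:
    def test_overlapping_entries_counted_once(self):
        track = _track(
            [("chr1", 0, 600_000, "a"), ("chr1", 400_000, 1_000_000, "b")]
        )
        assert interval_union_overlap(track, "chr1", 0, 2_000_000) == 1_000_000

    def test_disjoint_entries_sum(self):
        track = _track([("chr1", 0, 100_000, "a"), ("chr1", 500_000, 700_000, "b")])
        assert interval_union_overlap(track, "chr1", 0, 1_000_000) == 300_000
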