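"""Per-transcript matryoshka scan, summary statistics, and report output."""

import numpy as np
import pytest

from anrfscan import (
    AnrfPlant,
    PlantSpec,
    ScanConfig,
    Transcript,
    realize_plant,
    scan_transcript,
    generate_transcriptome,
    summarize,
    summary_from_candidate_table,
    write_reports,
)


class _StubReport:
    """Minimal stand-in exposing what summarize() consumes."""

    def __init__(self, n_anrf):
        self.n_anrf = n_anrf


class TestScanTranscript:
    def test_reference_layout_end_to_end(self, kpilp_like, scan_config, model):
        t, e = kpilp_like
        report = scan_transcript(t, scan_config, model)
        assert (report.main_orf.start, report.main_orf.end) == (24, 629)
        assert report.main_orf.length_aa == 201
        assert [(u.start, u.end, u.length_aa) for u in report.uorfs] == [(1, 9, 2)]
        passing = [c for c in report.candidates if c.passes_abc]
        assert len(passing) == 1
        c = passing[0]
        assert (c.orf.start, c.orf.end, c.orf.length_aa) == (430, 591, 53)
        assert c.context.window == "AGAAAATGGGA" and c.context.favorable
        assert c.criterion_i and c.criterion_ii and c.criterion_iii
        assert c.pp_in_band
        assert report.matryoshka and report.signature_positive

    def test_unfavorable_context_gates_matryoshka(self, scan_config, model):
        rng = np.random.default_rng(21)
        spec = PlantSpec(anrf=AnrfPlant(context_class="unfavorable"))
        t, e = realize_plant("unfav", spec, rng, model)
        report = scan_transcript(t, scan_config, model)
        assert not e.expected_passes_abc
        assert report.matryoshka is False
        planted = [c for c in report.candidates if c.orf.start == e.anrf_start]
        assert planted and not planted[0].passes_abc

    def test_no_nested_sorf_means_no_candidates(self, scan_config, model):
        t = Transcript(id="bare", seq="CCTCC" + "ATG" + "GCTGCA" * 20 + "TAA" + "CCTCC")
        report = scan_transcript(t, scan_config, model)
        assert report.candidates == [] and report.matryoshka is False

    def test_muh_threshold_monotonic_in_criterion_iii(self, model):
        transcripts, _, _ = generate_transcriptome(15, seed=31, model=model)
        counts = []
        for thr in (0.2, 0.4, 0.6):
            cfg = ScanConfig(muH_threshold=thr)
            n = sum(
                c.criterion_iii
                for t in transcripts
                for c in scan_transcript(t, cfg, model).candidates
            )
            counts.append(n)
        assert counts[0] >= counts[1] >= counts[2]

    def test_pp_window_monotonic_in_criterion_ii(self, model):
        transcripts, _, _ = generate_transcriptome(15, seed=32, model=model)
        counts = []
        for window in (30, 60, 90):
            cfg = ScanConfig(pp_window=window)
            n = sum(
                c.criterion_ii
                for t in transcripts
                for c in scan_transcript(t, cfg, model).candidates
            )
            counts.append(n)
        assert counts[0] <= counts[1] <= counts[2]


class TestSummarize:
    def test_single_vs_double_anrf_percentages(self):
        reports = [_StubReport(1)] * 19 + [_StubReport(2)]
        s = summarize(reports)
        assert (s.pct_1, s.pct_2, s.pct_3plus) == (95.0, 5.0, 0.0)
        assert s.histogram == {1: 19, 2: 1}
        assert s.n_candidates == 21

    def test_empty_input(self):
        s = summarize([])
        assert (s.n_transcripts, s.n_candidates, s.histogram) == (0, 0, {})
        assert s.pct_1 is None

    def test_percentages_sum_to_100(self):
        rng = np.random.default_rng(14)
        for _ in range(25):
            reports = [_StubReport(int(k)) for k in rng.integers(0, 5, 30)]
            s = summarize(reports)
            if s.n_matryoshka:
                assert s.pct_1 + s.pct_2 + s.pct_3plus == pytest.approx(100.0, abs=0.1 + 1e-9)

    def test_histogram_counts_matryoshka_transcripts(self):
        reports = [_StubReport(0), _StubReport(1), _StubReport(3), _StubReport(4)]
        s = summarize(reports)
        assert sum(s.histogram.values()) == 3
        assert s.pct_3plus == pytest.approx(66.7)


class TestWriteReports:
    @pytest.fixture()
    def small_scan(self, model, scan_config):
        transcripts, _, _ = generate_transcriptome(4, seed=41, model=model)
        reports = [scan_transcript(t, scan_config, model) for t in transcripts]
        return reports, summarize(reports)

    def test_gff3_feature_bookkeeping(self, tmp_path, kpilp_like, scan_config, model):
        t, _ = kpilp_like
        report = scan_transcript(t, scan_config, model)
        paths = write_reports([report], summarize([report]), tmp_path / "out")
        lines = [
            l.split("\t") for l in paths["gff3"].read_text().splitlines()
            if not l.startswith("#")
        ]
        assert sum(1 for l in lines if l[2] == "main_ORF") == 1
        assert sum(1 for l in lines if l[2] == "uORF") == 1
        assert sum(1 for l in lines if l[2] == "ANRF") == len(report.candidates)

    def test_gff3_round_trips_coordinates(self, tmp_path, small_scan):
        reports, summary = small_scan
        paths = write_reports(reports, summary, tmp_path / "out")
        parsed = {}
        for line in paths["gff3"].read_text().splitlines():
            if line.startswith("#"):
                continue
            seqid, _, ftype, start, end, *_ = line.split("\t")
            parsed.setdefault((seqid, ftype), []).append((int(start), int(end)))
        for r in reports:
            assert (r.main_orf.start, r.main_orf.end) in parsed[(r.transcript_id, "main_ORF")]
            for c in r.candidates:
                assert (c.orf.start, c.orf.end) in parsed[(r.transcript_id, "ANRF")]

    def test_outputs_byte_identical_across_runs(self, tmp_path, model, scan_config):
        digests = []
        for run in ("x", "y"):
            transcripts, _, _ = generate_transcriptome(5, seed=42, model=model)
            reports = [scan_transcript(t, scan_config, model) for t in transcripts]
            paths = write_reports(reports, summarize(reports), tmp_path / run)
            digests.append(tuple(p.read_bytes() for p in paths.values()))
        assert digests[0] == digests[1]

    def test_stats_recomputed_from_candidate_table(self, tmp_path, small_scan):
        reports, summary = small_scan
        paths = write_reports(reports, summary, tmp_path / "out")
        recomputed = summary_from_candidate_table(paths["tsv"])
        assert recomputed.n_transcripts == summary.n_transcripts
        assert recomputed.n_candidates == summary.n_candidates
        assert recomputed.histogram == summary.histogram
        assert recomputed.pct_1 == summary.pct_1


def test_config_band_ordering_enforced():
    with pytest.raises(ValueError, match="sig_max_aa"):
        ScanConfig(sig_max_aa=120)


def test_config_yaml_round_trip(tmp_path):
    cfg = ScanConfig(pp_window=80, muH_threshold=0.35)
    path = tmp_path / "cfg.yaml"
    cfg.to_yaml(path)
    assert ScanConfig.from_yaml(path) == cfg
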