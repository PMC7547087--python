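"""Profile matrices, ordering propagation and per-state mean heatmaps."""

import numpy as np
import pytest

from ervdyn.coverage import CoverageTrack, log2_ratio_track, normalize_1x, pileup
from ervdyn.errors import ContractError, ParameterError
from ervdyn.genome import GenomeModel, GenomicInterval, IntervalSet, make_bins
from ervdyn.profiles import (
    build_matrix,
    element_average_coverage,
    state_mean_matrix,
    summarize_matrix,
    write_matrix_tsv,
)


def constant_track(genome, value=1.0):
    return CoverageTrack(
        genome, {c: np.full(l, float(value)) for c, l in genome.lengths.items()}
    )


@pytest.fixture
def big_genome():
    return GenomeModel({"chr1": 50_000, "chr2": 30_000})


class TestBuildMatrix:
    def test_constant_track_fills_matrix(self, big_genome):
        loci = IntervalSet([GenomicInterval("chr1", 20_000, 26_500)])
        for mode in ("reference-point", "scale-body"):
            m = build_matrix(constant_track(big_genome, 2.5), loci, mode)
            assert np.allclose(m.values[np.isfinite(m.values)], 2.5)
            assert np.isfinite(m.values).all()

    def test_reference_point_column_count(self, big_genome):
        loci = IntervalSet([GenomicInterval("chr1", 20_000, 21_000)])
        m = build_matrix(constant_track(big_genome), loci, "reference-point",
                         flank=2500, bin_width=50)
        assert m.n_cols == 100  # 2 * 2500 / 50

    def test_scale_body_column_count(self, big_genome):
        loci = IntervalSet([GenomicInterval("chr1", 20_000, 24_000)])
        m = build_matrix(constant_track(big_genome), loci, "scale-body",
                         flank=2500, body=6500, bin_width=50)
        assert m.n_cols == (2 * 2500 + 6500) // 50

    def test_step_track_orientation(self, big_genome):
        vals = {c: np.zeros(l) for c, l in big_genome.lengths.items()}
        vals["chr1"][25_000:] = 1.0  # step up exactly at the locus center
        track = CoverageTrack(big_genome, vals)
        loci = IntervalSet([GenomicInterval("chr1", 24_000, 26_000)])
        m = build_matrix(track, loci, "reference-point", flank=1000, bin_width=50)
        assert np.allclose(m.values[0, :20], 0.0)
        assert np.allclose(m.values[0, 20:], 1.0)

    def test_off_chromosome_positions_missing(self, big_genome):
        loci = IntervalSet([GenomicInterval("chr1", 0, 1000)])  # center 500 < flank
        m = build_matrix(constant_track(big_genome), loci, "reference-point",
                         flank=2500, bin_width=50)
        assert np.isnan(m.values[0, 0])
        assert np.isfinite(m.values[0, -1])

    def test_indivisible_parameters_rejected(self, big_genome):
        loci = IntervalSet([GenomicInterval("chr1", 0, 100)])
        with pytest.raises(ParameterError):
            build_matrix(constant_track(big_genome), loci, flank=2510, bin_width=50)

    def test_translation_equivariance(self, rng):
        genome = GenomeModel({"chr1": 20_000})
        vals = rng.random(20_000)
        shift = 1234
        shifted = np.roll(vals, shift)
        loci = IntervalSet([GenomicInterval("chr1", 8_000, 9_000)])
        loci_shifted = IntervalSet([GenomicInterval("chr1", 8_000 + shift, 9_000 + shift)])
        m1 = build_matrix(CoverageTrack(genome, {"chr1": vals}), loci,
                          flank=1000, bin_width=50)
        m2 = build_matrix(CoverageTrack(genome, {"chr1": shifted}), loci_shifted,
                          flank=1000, bin_width=50)
        assert np.allclose(m1.values, m2.values, equal_nan=True)


class TestSummarizeMatrix:
    def test_identical_rows_average(self, big_genome):
        loci = IntervalSet(
            [GenomicInterval("chr1", 10_000, 11_000), GenomicInterval("chr1", 30_000, 31_000)]
        )
        m = build_matrix(constant_track(big_genome, 4.0), loci, flank=500, bin_width=50)
        profile, _ = summarize_matrix(m)
        assert np.allclose(profile, m.values[0])

    def test_order_propagated_from_leftmost_panel(self, rng, big_genome):
        loci = IntervalSet(
            [GenomicInterval("chr1", s, s + 1000, f"L{i}") for i, s in
             enumerate(range(10_000, 40_000, 3000))]
        )
        track_a = CoverageTrack(big_genome, {c: rng.random(l) for c, l in big_genome.lengths.items()})
        track_b = CoverageTrack(big_genome, {c: rng.random(l) for c, l in big_genome.lengths.items()})
        ma = build_matrix(track_a, loci, flank=500, bin_width=50)
        mb = build_matrix(track_b, loci, flank=500, bin_width=50)
        _, order_b = summarize_matrix(mb, order_from=ma)
        row_means_a = np.nanmean(ma.values, axis=1)
        assert np.array_equal(order_b, np.argsort(-row_means_a, kind="stable"))

    def test_loci_mismatch_rejected(self, big_genome):
        l1 = IntervalSet([GenomicInterval("chr1", 10_000, 11_000)])
        l2 = IntervalSet([GenomicInterval("chr1", 12_000, 13_000)])
        m1 = build_matrix(constant_track(big_genome), l1, flank=500, bin_width=50)
        m2 = build_matrix(constant_track(big_genome), l2, flank=500, bin_width=50)
        with pytest.raises(ParameterError):
            summarize_matrix(m1, order_from=m2)

    def test_column_means_match_naive_loops(self, rng, big_genome):
        loci = IntervalSet(
            [GenomicInterval("chr1", s, s + 800) for s in range(5_000, 45_000, 4000)]
        )
        track = CoverageTrack(big_genome, {c: rng.random(l) for c, l in big_genome.lengths.items()})
        m = build_matrix(track, loci, flank=1000, bin_width=50)
        profile, _ = summarize_matrix(m)
        for j in range(m.n_cols):
            col = [v for v in m.values[:, j] if np.isfinite(v)]
            assert profile[j] == pytest.approx(np.mean(col))

    def test_partition_weighted_mean_identity(self, rng, big_genome):
        loci = IntervalSet(
            [GenomicInterval("chr1", s, s + 500) for s in range(5_000, 45_000, 2000)]
        )
        track = CoverageTrack(big_genome, {c: rng.random(l) for c, l in big_genome.lengths.items()})
        m = build_matrix(track, loci, flank=500, bin_width=50)
        k = 7
        a = IntervalSet(list(loci)[:k])
        b = IntervalSet(list(loci)[k:])
        pa, _ = summarize_matrix(build_matrix(track, a, flank=500, bin_width=50))
        pb, _ = summarize_matrix(build_matrix(track, b, flank=500, bin_width=50))
        pall, _ = summarize_matrix(m)
        combined = (len(a) * pa + len(b) * pb) / len(loci)
        assert np.allclose(pall, combined)


class TestElementAverageCoverage:
    def test_requires_normalized_track(self, big_genome):
        with pytest.raises(ContractError):
            element_average_coverage(
                constant_track(big_genome),
                IntervalSet([GenomicInterval("chr1", 10_000, 16_500)]),
            )

    def test_enrichment_plateau_and_flat_control(self, small_cfg, small_ann):
        from ervdyn.simulate import simulate_sample_fragments
        from ervdyn.genome import shuffle_matched

        elements = small_ann.truth.elements
        control = shuffle_matched(
            elements, small_ann.genome, seed=1,
            exclude=small_ann.truth.domains,
        )
        nf = 2500 // 50
        profs = {}
        for cond in ("WT", "KO"):
            frags = simulate_sample_fragments(small_cfg, small_ann, "ATAC",
                                              condition=cond, depth_x=30.0)
            track = normalize_1x(pileup(frags, small_ann.genome))
            profs[cond] = element_average_coverage(track, elements, control=control)
        # uniform wildtype background: shuffled control sits at FPGC ~ 1
        assert np.nanmean(profs["WT"]["control"][nf:-nf]) == pytest.approx(1.0, rel=0.1)
        # knockout: plateau over element bodies is threefold over the control
        # baseline (1x normalization deflates both by the same mass factor)
        body = profs["KO"]["elements"][nf:-nf]
        plateau = body[len(body) // 4: -len(body) // 4]
        baseline = np.nanmean(profs["KO"]["control"][nf:-nf])
        assert plateau.mean() / baseline == pytest.approx(3.0, rel=0.1)


class TestStateMeanMatrix:
    def test_track_against_itself_is_zero(self, big_genome, rng):
        chip = CoverageTrack(
            big_genome, {c: rng.random(l) + 0.5 for c, l in big_genome.lengths.items()}
        )
        ratio = log2_ratio_track(chip, chip)
        cats = {"stateA": IntervalSet([GenomicInterval("chr1", 0, 10_000)])}
        df = state_mean_matrix({"s1": ratio}, cats)
        assert df.loc["stateA", "s1"] == pytest.approx(0.0)

    def test_confined_enrichment_detected(self, big_genome):
        chip_vals = {c: np.ones(l) for c, l in big_genome.lengths.items()}
        chip_vals["chr1"][5_000:10_000] = 4.0
        chip = CoverageTrack(big_genome, chip_vals)
        ratio = log2_ratio_track(chip, constant_track(big_genome))
        cats = {
            "enriched": IntervalSet([GenomicInterval("chr1", 5_000, 10_000)]),
            "background": IntervalSet([GenomicInterval("chr1", 20_000, 30_000)]),
            "empty": IntervalSet([]),
        }
        df = state_mean_matrix({"s": ratio}, cats)
        assert df.loc["enriched", "s"] == pytest.approx(2.0)
        assert df.loc["background", "s"] == pytest.approx(0.0)
        assert np.isnan(df.loc["empty", "s"])

    def test_matches_nested_loop_oracle(self, rng, big_genome):
        tracks = {}
        for name in ("t1", "t2"):
            chip = CoverageTrack(
                big_genome, {c: rng.random(l) + 0.2 for c, l in big_genome.lengths.items()}
            )
            inp = CoverageTrack(
                big_genome, {c: rng.random(l) + 0.2 for c, l in big_genome.lengths.items()}
            )
            tracks[name] = log2_ratio_track(chip, inp)
        cats = {
            f"c{i}": IntervalSet(
                [GenomicInterval("chr2", s, s + 700) for s in range(i * 2000, 20_000, 5000)]
            )
            for i in range(3)
        }
        df = state_mean_matrix(tracks, cats)
        for cat, regions in cats.items():
            for name, track in tracks.items():
                means = [
                    np.nanmean(track.data[r.chrom][r.start:r.end]) for r in regions
                ]
                assert df.loc[cat, name] == pytest.approx(np.mean(means))


def test_matrix_tsv_roundtrip_header(tmp_path, big_genome):
    loci = IntervalSet([GenomicInterval("chr1", 10_000, 11_000, "L0")])
    m = build_matrix(constant_track(big_genome), loci, flank=500, bin_width=50)
    path = tmp_path / "matrix.tsv"
    write_matrix_tsv(m, str(path))
    lines = path.read_text().splitlines()
    import json

    header = json.loads(lines[0][1:])
    assert header["mode"] == "reference-point"
    assert len(lines) == 3  # header, column names, one locus row
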