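"""The generator plants what the analysis must recover."""

import numpy as np
import pytest
from scipy import stats

from chromspace import (
    EffectModel,
    SyntheticGenome,
    annotate_spacing,
    calibrate_spike,
    filter_outliers,
    fragment_pileup,
    make_expression,
    make_fragments,
    make_genome,
    make_promoter_table,
    make_torsion_track,
    moving_median_curve,
    orientation_fractions,
    region_sum,
    spike_scale_factor,
    upstream_sum,
)
from chromspace.synthetic import (
    read_expression_tsv,
    read_fragments_bed,
    write_expression_tsv,
    write_fragments_bed,
)


def adjacent_gaps(promoters):
    """(left_gap, right_gap) per promoter id from the sorted table."""
    out = {}
    by_chrom = {}
    for p in promoters:
        by_chrom.setdefault(p.chrom, []).append(p)
    for recs in by_chrom.values():
        recs = sorted(recs, key=lambda p: p.tss)
        for i, p in enumerate(recs):
            left = p.tss - recs[i - 1].tss if i > 0 else None
            right = recs[i + 1].tss - p.tss if i + 1 < len(recs) else None
            out[p.id] = (left, right)
    return out


class TestMakePromoterTable:
    def test_forced_two_promoter_divergent_pair(self):
        genome = make_genome(1, 10_000)
        proms = make_promoter_table(2, genome, spacing_law={"kind": "fixed", "value": 500},
                                    divergent_fraction=1.0, seed=7)
        assert len(proms) == 2
        a, b = proms
        assert b.tss - a.tss == 500
        assert (a.strand, b.strand) == ("-", "+")  # heads facing away
        ann = annotate_spacing(proms)
        assert all(x.orientation == "divergent" and x.distance == 500 for x in ann)

    def test_study_scale_table(self):
        genome = make_genome(4, 40_000_000)
        proms = make_promoter_table(16_972, genome, seed=0)
        assert len(proms) == 16_972
        assert len({p.id for p in proms}) == 16_972

    def test_sorted_by_chrom_then_coordinate(self):
        genome = make_genome(2, 5_000_000)
        proms = make_promoter_table(500, genome, seed=3)
        keys = [(p.chrom, p.tss) for p in proms]
        assert keys == sorted(keys, key=lambda t: (genome.chrom_names.index(t[0]), t[1]))

    def test_bimodal_spacing_law_realized(self):
        genome = make_genome(1, 50_000_000)
        law = {"kind": "mixture", "modes": [300, 10_000], "sd_frac": 0.05}
        proms = make_promoter_table(1_000, genome, spacing_law=law, seed=1)
        gaps = np.diff([p.tss for p in proms])
        near_short = np.abs(gaps - 300) < 150
        near_long = np.abs(gaps - 10_000) < 2_000
        assert near_short.mean() > 0.3 and near_long.mean() > 0.3
        assert (near_short | near_long).mean() > 0.95

    def test_requested_divergent_fraction_realized(self):
        genome = make_genome(2, 60_000_000)
        proms = make_promoter_table(10_000, genome, divergent_fraction=0.58, seed=3)
        ann = annotate_spacing(proms)
        frac = orientation_fractions(ann, [2_000])
        f, n = frac.loc[0, "fraction"], frac.loc[0, "n_total"]
        se = np.sqrt(0.58 * 0.42 / n)
        assert abs(f - 0.58) < 3 * se

    def test_genome_too_short_rejected(self):
        genome = make_genome(1, 1_000)
        with pytest.raises(ValueError, match="too short"):
            make_promoter_table(100, genome, spacing_law={"kind": "fixed", "value": 500},
                                seed=0)

    def test_reproducible(self):
        genome = make_genome(2, 5_000_000)
        a = make_promoter_table(300, genome, seed=42)
        b = make_promoter_table(300, genome, seed=42)
        assert a == b


class TestMakeFragments:
    def test_spike_count_conserved_verbatim(self):
        genome = make_genome(1, 2_000_000)
        proms = make_promoter_table(100, genome, seed=0)
        fs = make_fragments(proms, EffectModel(seed=0), 5_000, spike_count=5_000,
                            genome=genome)
        assert fs.spike_count == 5_000
        assert spike_scale_factor(fs.spike_count) == 2.0

    def test_null_boost_divergent_tandem_indistinguishable(self):
        genome = make_genome(2, 10_000_000)
        proms = make_promoter_table(500, genome, seed=1)
        eff = EffectModel(divergent_close_boost=1.0, seed=2)
        fs = make_fragments(proms, eff, 100_000, 10_000, genome)
        track = fragment_pileup(fs, genome)
        ann = {a.promoter_id: a for a in annotate_spacing(proms)}
        div = [region_sum(track, p) for p in proms if ann[p.id].orientation == "divergent"]
        tan = [region_sum(track, p) for p in proms if ann[p.id].orientation == "tandem"]
        _, p = stats.mannwhitneyu(div, tan, alternative="two-sided")
        assert p > 0.01

    @pytest.mark.parametrize("boost", [1.0, 2.0, 4.0])
    def test_planted_boost_recovered_within_3se(self, boost):
        # spacing law with well-separated modes so promoter windows never
        # bleed into a neighbor's window: close pairs at ~800 bp, the rest
        # at ~10 kb; "distant" promoters are isolated on both sides
        genome = make_genome(2, 60_000_000)
        law = {"kind": "mixture", "modes": [800, 10_000], "sd_frac": 0.03}
        proms = make_promoter_table(800, genome, spacing_law=law, seed=5)
        eff = EffectModel(divergent_close_boost=boost, distance_cutoff=1_000, seed=6)
        fs = make_fragments(proms, eff, 200_000, 10_000, genome, placement_sd=30.0)
        track = fragment_pileup(fs, genome)
        ann = {a.promoter_id: a for a in annotate_spacing(proms)}
        gaps = adjacent_gaps(proms)
        close_div = [region_sum(track, p) for p in proms
                     if ann[p.id].orientation == "divergent"
                     and ann[p.id].distance is not None and ann[p.id].distance < 1_000]
        isolated = [region_sum(track, p) for p in proms
                    if all(g is None or g >= 5_000 for g in gaps[p.id])]
        a, b = np.array(close_div), np.array(isolated)
        ratio = a.mean() / b.mean()
        se = ratio * np.sqrt(a.var(ddof=1) / (len(a) * a.mean() ** 2)
                             + b.var(ddof=1) / (len(b) * b.mean() ** 2))
        assert abs(ratio - boost) < 3 * se

    def test_empty_promoter_list_rejected(self):
        genome = make_genome(1, 1_000_000)
        with pytest.raises(ValueError, match="empty"):
            make_fragments([], EffectModel(), 100, 100, genome)

    def test_reproducible_and_roundtrips(self, tmp_path):
        genome = make_genome(1, 2_000_000)
        proms = make_promoter_table(50, genome, seed=0)
        a = make_fragments(proms, EffectModel(seed=9), 2_000, 1_000, genome)
        b = make_fragments(proms, EffectModel(seed=9), 2_000, 1_000, genome)
        assert a.intervals.equals(b.intervals)
        path = tmp_path / "frags.bed"
        write_fragments_bed(a, path)
        back = read_fragments_bed(path, spike_count=1_000)
        assert back.intervals[["chrom", "start", "end"]].astype(
            {"start": int, "end": int}).equals(a.intervals.reset_index(drop=True))


class TestMakeExpression:
    def test_group_medians_near_targets(self):
        genome = make_genome(2, 30_000_000)
        proms = make_promoter_table(4_000, genome, seed=2)
        expr = make_expression(proms, divergent_median=210.3, tandem_median=34.5,
                               dispersion=1.0, seed=3)
        ann = {a.promoter_id: a.orientation for a in annotate_spacing(proms)}
        div = [expr[p.id] for p in proms if ann[p.id] == "divergent"]
        tan = [expr[p.id] for p in proms if ann[p.id] == "tandem"]
        assert np.median(div) == pytest.approx(210.3, rel=0.10)
        assert np.median(tan) == pytest.approx(34.5, rel=0.10)

    def test_zero_dispersion_exact_medians(self):
        genome = make_genome(1, 5_000_000)
        proms = make_promoter_table(200, genome, seed=4)
        expr = make_expression(proms, 210.3, 34.5, dispersion=0.0, seed=0)
        assert set(expr.values()) <= {210.3, 34.5}

    def test_equal_medians_groups_exchangeable(self):
        genome = make_genome(1, 10_000_000)
        proms = make_promoter_table(1_000, genome, seed=5)
        expr = make_expression(proms, 50.0, 50.0, dispersion=0.8, seed=6)
        ann = {a.promoter_id: a.orientation for a in annotate_spacing(proms)}
        div = [expr[p.id] for p in proms if ann[p.id] == "divergent"]
        tan = [expr[p.id] for p in proms if ann[p.id] == "tandem"]
        _, p = stats.mannwhitneyu(div, tan, alternative="two-sided")
        assert p > 0.01

    def test_negative_median_rejected(self):
        genome = make_genome(1, 1_000_000)
        proms = make_promoter_table(10, genome, seed=0)
        with pytest.raises(ValueError):
            make_expression(proms, -1.0, 10.0)

    def test_expression_tsv_roundtrip(self, tmp_path):
        expr = {"a": 1.5, "b": 0.0, "c": 210.3}
        path = tmp_path / "e.tsv"
        write_expression_tsv(expr, path)
        assert read_expression_tsv(path) == expr


class TestMakeTorsionTrack:
    def setup_promoters(self, seed=0):
        genome = make_genome(1, 20_000_000)
        law = {"kind": "mixture", "modes": [500, 8_000], "sd_frac": 0.1}
        proms = make_promoter_table(1_500, genome, spacing_law=law, seed=seed)
        return genome, proms

    def test_null_enrichment_uncorrelated_with_distance(self):
        genome, proms = self.setup_promoters()
        track = make_torsion_track(proms, close_pair_enrichment=1.0, seed=1, genome=genome)
        sums = upstream_sum(track, proms)
        ann = {a.promoter_id: a for a in annotate_spacing(proms)}
        ids = [p.id for p in proms if ann[p.id].distance is not None]
        r, p = stats.spearmanr([ann[i].distance for i in ids], [sums[i] for i in ids])
        assert p > 0.01 or abs(r) < 0.05

    def test_planted_enrichment_gives_decreasing_curve(self):
        genome, proms = self.setup_promoters(seed=2)
        track = make_torsion_track(proms, close_pair_enrichment=4.0, seed=3, genome=genome,
                                   close_cutoff=1_000)
        sums = upstream_sum(track, proms)
        ann = {a.promoter_id: a for a in annotate_spacing(proms)}
        d = {i: ann[i].distance for i in sums if ann[i].distance is not None}
        curve = moving_median_curve({i: sums[i] for i in d}, d, statistic="mean")
        pts = curve.points
        far_level = pts[pts["median_distance"] > 2_000]["median_signal"].mean()
        close_level = pts[pts["median_distance"] < 800]["median_signal"].mean()
        assert close_level > 2.0 * far_level

    def test_injected_outlier_flagged_downstream(self):
        genome, proms = self.setup_promoters(seed=4)
        track = make_torsion_track(proms, close_pair_enrichment=1.0, seed=5, genome=genome)
        sums = upstream_sum(track, proms)
        arr = np.array(list(sums.values()))
        m, s = arr.mean(), arr.std(ddof=1)
        victim = list(sums)[0]
        sums[victim] = m + 64.7 * s  # plant a 64.7-SD outlier
        kept, report = filter_outliers(sums, threshold_sds=64, mean=m, sd=s)
        assert victim not in kept
        assert [k for k, _, _ in report.removed] == [victim]

    def test_reproducible(self):
        genome, proms = self.setup_promoters(seed=6)
        a = make_torsion_track(proms, 2.0, seed=7, genome=genome)
        b = make_torsion_track(proms, 2.0, seed=7, genome=genome)
        for c in genome.chrom_names:
            np.testing.assert_array_equal(a.values[c], b.values[c])
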