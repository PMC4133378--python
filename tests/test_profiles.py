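import numpy as np
import pytest

from epilandscape import profiles as prof
from epilandscape import windows as win
from epilandscape.genome_model import FeatureRecord, GenomicInterval


def make_te(chrom, start, end, te_id="te1"):
    return FeatureRecord(
        interval=GenomicInterval(chrom, start, end),
        kind="TE",
        feature_id=te_id,
        te_class="LTR",
        te_subfamily="RLG",
    )


def make_gene(chrom, start, end, strand, gene_id="g1", **kw):
    return FeatureRecord(
        interval=GenomicInterval(chrom, start, end, strand),
        kind="gene",
        feature_id=gene_id,
        **kw,
    )


def table_with_track(sizes, track="chip_count", fill=1.0):
    table = win.tile_genome(sizes)
    table.df[track] = fill
    return table


def contributing_bins(result, track="chip_count"):
    return set(result.df.loc[result.df[f"n_{track}"] > 0, "bin_index"])


class TestRelativeProfile:
    def test_midpoint_maps_to_scale_center(self):
        # window [1400,1500) midpoint 1450 == midpoint of element [950,1950)
        table = table_with_track({"chr1": 3000})
        te = make_te("chr1", 950, 1950)
        result = prof.relative_profile(table, [te], track_names=["chip_count"])
        row = result.df[result.df["bin_index"] == 31]
        # the window at the element center must land in bin 30 or 31
        center_bins = contributing_bins(result) & {30, 31}
        assert 31 in center_bins or 30 in center_bins
        assert row["segment"].iloc[0] == "internal"

    def test_upstream_950_lands_in_first_flank_bin(self):
        table = win.tile_genome({"chr1": 10_000})
        table.df["chip_count"] = 0.0
        table.df.loc[40, "chip_count"] = 99.0  # window [4000,4100), mid 4050
        te = make_te("chr1", 5000, 6000)
        result = prof.relative_profile(table, [te], track_names=["chip_count"])
        first_bin = result.df[result.df["bin_index"] == 1]
        assert first_bin["segment"].iloc[0] == "upstream"
        assert first_bin["mean_chip_count"].iloc[0] == pytest.approx(99.0)

    def test_flank_error(self, window_table):
        with pytest.raises(ValueError):
            prof.relative_profile(window_table, [make_te("chrA", 0, 100)], flank=0)

    def test_no_elements_error(self, window_table):
        with pytest.raises(ValueError):
            prof.relative_profile(window_table, [])

    def test_empty_result_warns(self):
        table = win.tile_genome({"chr1": 10_000})
        with pytest.warns(UserWarning, match="no window"):
            prof.relative_profile(
                table, [make_te("chrX", 0, 1000)], track_names=["chip_count"]
            )

    def test_bin_partition_invariant(self, window_table, manifest):
        result = prof.relative_profile(
            window_table, manifest.tes, track_names=["chip_count"]
        )
        # every retained window-element pair contributes to exactly one bin
        mids = window_table.midpoints()
        retained = 0
        for i in range(len(window_table)):
            chrom = window_table.df["chrom"].iloc[i]
            best = None
            for te in sorted(
                manifest.tes, key=lambda t: (t.interval.start, t.interval.end)
            ):
                if te.interval.chrom != chrom:
                    continue
                m = mids[i]
                if te.interval.start <= m < te.interval.end:
                    d = 0.0
                else:
                    d = min(abs(m - te.interval.start), abs(m - (te.interval.end - 1)))
                if best is None or d < best:
                    best = d
            if best is not None and best <= 1000:
                retained += 1
        assert result.df["n_chip_count"].sum() == retained

    def test_planted_internal_signal(self):
        # plant level 0.9 inside elements, 0.4 outside; 20 internal bins
        # must recover 0.9 exactly (no sampling noise on the track itself)
        sizes = {"chr1": 100_000}
        table = win.tile_genome(sizes)
        tes = [make_te("chr1", s, s + 4000, f"te{s}") for s in range(10_000, 90_000, 10_000)]
        level = np.full(len(table), 0.4)
        mids = table.midpoints()
        for te in tes:
            inside = (mids >= te.interval.start) & (mids < te.interval.end)
            level[inside] = 0.9
        table.df["mCG"] = level
        result = prof.relative_profile(table, tes, track_names=["mCG"])
        internal = result.df[result.df["segment"] == "internal"]
        assert np.allclose(internal["mean_mCG"], 0.9)
        flank = result.df[result.df["segment"] != "internal"]["mean_mCG"].dropna()
        assert (flank < 0.9).all()

    def test_flank_symmetry(self):
        # mirror-symmetric planted signal around elements -> symmetric bins
        sizes = {"chr1": 60_000}
        table = win.tile_genome(sizes)
        tes = [make_te("chr1", 20_000, 24_000), make_te("chr1", 40_000, 44_000, "te2")]
        mids = table.midpoints()
        signal = np.zeros(len(table))
        for te in tes:
            d = np.minimum(np.abs(mids - te.interval.start), np.abs(mids - te.interval.end + 1))
            outside = (mids < te.interval.start) | (mids >= te.interval.end)
            signal = np.where(outside & (d <= 1000), np.maximum(signal, 1000 - d), signal)
        table.df["chip_count"] = signal
        result = prof.relative_profile(table, tes, track_names=["chip_count"])
        up = result.df[result.df["segment"] == "upstream"]["mean_chip_count"].to_numpy()
        down = result.df[result.df["segment"] == "downstream"]["mean_chip_count"].to_numpy()
        np.testing.assert_allclose(up, down[::-1], atol=60)

    def test_scaling_invariant_to_length(self):
        # length-independent planted signal -> internal segment flat
        sizes = {"chr1": 200_000}
        table = win.tile_genome(sizes)
        rng = np.random.default_rng(0)
        tes, cursor = [], 5000
        for i, length in enumerate([1500, 3000, 6000, 12_000, 24_000]):
            tes.append(make_te("chr1", cursor, cursor + length, f"te{i}"))
            cursor += length + 4000
        mids = table.midpoints()
        level = np.full(len(table), 0.1)
        for te in tes:
            level[(mids >= te.interval.start) & (mids < te.interval.end)] = 0.8
        table.df["mCHG"] = level
        result = prof.relative_profile(table, tes, track_names=["mCHG"])
        internal = result.df[result.df["segment"] == "internal"]
        assert np.allclose(internal["mean_mCHG"], 0.8)


class TestAbsoluteProfile:
    def test_plus_strand_upstream_distance(self):
        table = win.tile_genome({"chr1": 20_000})
        table.df["chip_count"] = 0.0
        table.df.loc[90, "chip_count"] = 7.0  # window [9000,9100), mid 9050
        gene = make_gene("chr1", 10_000, 14_000, "+")
        p5, _ = prof.absolute_gene_profile(table, [gene], track_names=["chip_count"])
        # distance -950 -> bin floor((-950+2000)/50) = 21 -> bin_index 22
        row = p5.df[p5.df["bin_index"] == 22]
        assert row["mean_chip_count"].iloc[0] == pytest.approx(7.0)
        assert row["bin_center"].iloc[0] == pytest.approx(-925.0)

    def test_minus_strand_symmetry(self):
        # - strand gene: window right of the TSS is "upstream" after flip
        table = win.tile_genome({"chr1": 40_000})
        table.df["chip_count"] = 0.0
        table.df.loc[209, "chip_count"] = 7.0  # [20900,21000), mid 20950
        gene = make_gene("chr1", 15_000, 20_000, "-")  # TSS at 19,999
        p5, _ = prof.absolute_gene_profile(table, [gene], track_names=["chip_count"])
        hit = p5.df[p5.df["mean_chip_count"] == 7.0]
        assert len(hit) == 1
        assert hit["bin_center"].iloc[0] < 0  # upstream side after flip

    def test_gene_without_strand_errors(self, window_table):
        gene = make_gene("chrA", 1000, 3000, ".")
        with pytest.raises(ValueError, match="strand"):
            prof.absolute_gene_profile(window_table, [gene])

    def test_short_gene_capped(self):
        # 1.5 kb gene: no bins past +1.5 kb on the 5' plot
        table = table_with_track({"chr1": 20_000})
        gene = make_gene("chr1", 10_000, 11_500, "+")
        p5, _ = prof.absolute_gene_profile(table, [gene], track_names=["chip_count"])
        populated = p5.df[p5.df["n_chip_count"] > 0]
        assert populated["bin_center"].max() < 1500

    def test_planted_v_shape_recovered(self):
        # high-CHG flanks, zero at TSS: piecewise signal must be recovered
        table = win.tile_genome({"chr1": 200_000})
        genes = [
            make_gene("chr1", s, s + 6000, "+", f"g{s}") for s in range(20_000, 180_000, 20_000)
        ]
        mids = table.midpoints()
        level = np.full(len(table), 0.8)
        for g in genes:
            inside = (mids >= g.interval.start) & (mids < g.interval.end)
            level[inside] = 0.0
        table.df["mCHG"] = level
        p5, p3 = prof.absolute_gene_profile(table, genes, track_names=["mCHG"])
        upstream = p5.df[p5.df["bin_center"] < -200]["mean_mCHG"]
        body = p5.df[p5.df["bin_center"] > 200]["mean_mCHG"]
        assert upstream.mean() > 0.7
        assert body.mean() < 0.05

    def test_five_and_three_prime_agree_on_overlap(self):
        # genes >= 6 kb with uniform signal: genic bins agree between plots
        table = table_with_track({"chr1": 100_000}, fill=3.0)
        genes = [make_gene("chr1", 20_000, 27_000, "+", "a"),
                 make_gene("chr1", 50_000, 58_000, "-", "b")]
        p5, p3 = prof.absolute_gene_profile(table, genes, track_names=["chip_count"])
        g5 = p5.df[p5.df["bin_center"] > 0]["mean_chip_count"].dropna()
        g3 = p3.df[p3.df["bin_center"] < 0]["mean_chip_count"].dropna()
        assert np.allclose(g5, 3.0) and np.allclose(g3, 3.0)

    def test_bin_count(self, window_table, manifest):
        p5, p3 = prof.absolute_gene_profile(window_table, manifest.genes)
        assert p5.n_bins == 100 and p3.n_bins == 100


class TestMaskedProfile:
    def _setup(self):
        table = win.tile_genome({"chr1": 30_000})
        gene = make_gene("chr1", 10_000, 16_000, "+")
        te = make_te("chr1", 12_000, 14_000)
        mids = table.midpoints()
        level = np.full(len(table), 0.05)
        level[(mids >= 12_000) & (mids < 14_000)] = 0.9  # intronic TE
        table.df["mCHG"] = level
        return table, gene, te

    def test_mask_lowers_n_in_te_bins(self):
        table, gene, te = self._setup()
        unmasked, _ = prof.absolute_gene_profile(table, [gene], track_names=["mCHG"])
        masked, _ = prof.masked_profile(table, [gene], [te], track_names=["mCHG"])
        te_bins = (masked.df["bin_center"] >= 2000) & (masked.df["bin_center"] < 3000)
        assert masked.df.loc[te_bins, "n_mCHG"].sum() < unmasked.df.loc[te_bins, "n_mCHG"].sum()
        assert (masked.df["n_mCHG"] <= unmasked.df["n_mCHG"]).all()

    def test_masked_genic_mean_drops(self):
        table, gene, te = self._setup()
        unmasked, _ = prof.absolute_gene_profile(table, [gene], track_names=["mCHG"])
        masked, _ = prof.masked_profile(table, [gene], [te], track_names=["mCHG"])
        genic = unmasked.df["bin_center"] > 0
        assert np.nanmean(masked.df.loc[genic, "mean_mCHG"]) == pytest.approx(0.05, abs=0.01)
        assert np.nanmean(unmasked.df.loc[genic, "mean_mCHG"]) > np.nanmean(
            masked.df.loc[genic, "mean_mCHG"]
        )

    def test_no_mask_is_noop(self):
        table, gene, _ = self._setup()
        unmasked, _ = prof.absolute_gene_profile(table, [gene], track_names=["mCHG"])
        masked, _ = prof.masked_profile(table, [gene], [], track_names=["mCHG"])
        np.testing.assert_array_equal(
            masked.df["n_mCHG"].to_numpy(), unmasked.df["n_mCHG"].to_numpy()
        )


class TestGroupedProfiles:
    def test_two_groups(self):
        table = table_with_track({"chr1": 100_000})
        genes = [
            make_gene("chr1", 10_000 + i * 8000, 13_000 + i * 8000, "+",
                      f"g{i}", synteny="syntenic" if i % 2 else "inserted")
            for i in range(10)
        ]
        result = prof.grouped_profiles(table, genes, "synteny", track_names=["chip_count"])
        assert set(result) == {"syntenic", "inserted"}

    def test_single_label_equals_ungrouped(self, window_table, manifest):
        grouped = prof.grouped_profiles(
            window_table, manifest.genes, "gene_set", track_names=["mCG"]
        )
        assert set(grouped) == {"FGS"}
        p5, _ = prof.absolute_gene_profile(window_table, manifest.genes, track_names=["mCG"])
        np.testing.assert_allclose(
            grouped["FGS"][0].df["mean_mCG"], p5.df["mean_mCG"], equal_nan=True
        )

    def test_unknown_field_errors(self, window_table, manifest):
        with pytest.raises(ValueError, match="unknown"):
            prof.grouped_profiles(window_table, manifest.genes, "nonsense")

    def test_planted_group_ordering(self):
        table = win.tile_genome({"chr1": 200_000})
        genes = []
        mids = table.midpoints()
        level = np.full(len(table), 0.1)
        for i in range(10):
            s = 10_000 + i * 18_000
            label = "sg1" if i < 5 else "sg2"
            genes.append(make_gene("chr1", s, s + 5000, "+", f"g{i}", subgenome=label))
            inside = (mids >= s) & (mids < s + 5000)
            level[inside] = 0.8 if label == "sg1" else 0.3
        table.df["mCG"] = level
        grouped = prof.grouped_profiles(table, genes, "subgenome", track_names=["mCG"])
        body = lambda p: np.nanmean(p.df[p.df["bin_center"] > 0]["mean_mCG"])
        assert body(grouped["sg1"][0]) > body(grouped["sg2"][0])
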