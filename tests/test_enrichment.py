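"""Category enrichment ratios, hot-spot smoothing, Circos windows, bedgraph."""

import numpy as np
import pandas as pd
import pytest

from edmakit import enrichment as enr
from edmakit import export as exp


def make_dmrs_and_annotations(n_a, n_b, category_col="promoter"):
    """n_a hyper-in-A and n_b hyper-in-B DMRs, all carrying one category."""
    n = n_a + n_b
    dmrs = pd.DataFrame(
        {
            "mean_m": [2.0] * n_a + [-2.0] * n_b,
            "p": [0.01] * n,
            "direction": ["hyper_in_A"] * n_a + ["hyper_in_B"] * n_b,
        },
        index=[f"F{i:06d}" for i in range(n)],
    )
    ann = pd.DataFrame(
        {
            category_col: ["g1"] * n,
            "island_relation": ["open_sea"] * n,
            "repeat_classes": [""] * n,
        },
        index=dmrs.index,
    )
    return dmrs, ann


class TestEnrichmentTable:
    def test_power_of_two_ratio(self):
        dmrs, ann = make_dmrs_and_annotations(8, 2)
        out = enr.enrichment_table(dmrs, ann, pseudocount=0.0)
        row = out.set_index("category").loc["promoter"]
        assert row["hyper_in_A"] == 8 and row["hyper_in_B"] == 2
        assert row["log2_ratio"] == pytest.approx(2.0)

    def test_symmetry_zero(self):
        dmrs, ann = make_dmrs_and_annotations(5, 5)
        out = enr.enrichment_table(dmrs, ann)
        assert out.set_index("category").loc["promoter", "log2_ratio"] == 0

    def test_pseudocount_with_empty_cell(self):
        dmrs, ann = make_dmrs_and_annotations(8, 0)
        out = enr.enrichment_table(dmrs, ann, pseudocount=0.5)
        ratio = out.set_index("category").loc["promoter", "log2_ratio"]
        assert ratio == pytest.approx(np.log2(17.0))

    def test_antisymmetry_under_group_swap(self, rng):
        """Relabelling the groups negates every log2 ratio exactly."""
        n = 60
        dirs = rng.choice(["hyper_in_A", "hyper_in_B"], size=n)
        dmrs = pd.DataFrame(
            {"mean_m": np.where(dirs == "hyper_in_A", 2.0, -2.0),
             "p": 0.01, "direction": dirs},
            index=[f"F{i:06d}" for i in range(n)],
        )
        ann = pd.DataFrame(
            {
                "promoter": rng.choice(["g1", ""], size=n),
                "exon": rng.choice(["g2", ""], size=n),
                "island_relation": rng.choice(["island", "shore", "open_sea"], size=n),
                "repeat_classes": rng.choice(["LINE", "SINE", ""], size=n),
            },
            index=dmrs.index,
        )
        fwd = enr.enrichment_table(dmrs, ann).set_index("category")
        swapped = dmrs.copy()
        swapped["direction"] = np.where(
            dmrs["direction"] == "hyper_in_A", "hyper_in_B", "hyper_in_A"
        )
        rev = enr.enrichment_table(swapped, ann).set_index("category")
        assert np.allclose(fwd["log2_ratio"], -rev["log2_ratio"])
        assert (fwd["hyper_in_A"] == rev["hyper_in_B"]).all()

    def test_category_counts_conserved(self, rng):
        """Summed directional counts equal the number of (DMR, category)
        membership pairs."""
        dmrs, ann = make_dmrs_and_annotations(7, 3)
        ann["repeat_classes"] = "LINE,SINE"
        out = enr.enrichment_table(dmrs, ann)
        total = int((out["hyper_in_A"] + out["hyper_in_B"]).sum())
        memberships = sum(
            len(enr.annotation_categories(ann.loc[i])) for i in dmrs.index
        )
        assert total == memberships

    def test_unknown_category_rejected(self):
        dmrs, ann = make_dmrs_and_annotations(2, 2)
        with pytest.raises(enr.EnrichmentError):
            enr.enrichment_table(dmrs, ann, categories=["promotor"])  # typo

    def test_missing_annotation_rejected(self):
        dmrs, ann = make_dmrs_and_annotations(2, 2)
        with pytest.raises(enr.EnrichmentError):
            enr.enrichment_table(dmrs, ann.iloc[:2], pseudocount=0.5)


def brute_force_hotspots(positions, pvalues, half_width):
    out = np.empty(len(positions), dtype=float)
    for i, x in enumerate(positions):
        sel = np.abs(positions - x) <= half_width
        out[i] = pvalues[sel].mean()
    return out


class TestHotspots:
    def test_isolated_probe(self):
        track = enr.hotspots(np.array([10]), np.array([0.3]))
        assert track["smoothed_p"].iloc[0] == pytest.approx(0.3)

    def test_three_probe_mean(self):
        track = enr.hotspots(
            np.array([0, 50_000, 90_000]), np.array([0.1, 0.2, 0.3])
        )
        mid = track.set_index("position").loc[50_000, "smoothed_p"]
        assert mid == pytest.approx(0.2)

    def test_matches_quadratic_oracle(self, rng):
        """1,000 probes over two chromosomes: windowed means must equal a
        brute-force ±100 kb scan per chromosome."""
        chroms = rng.choice(["chr1", "chr2"], size=1_000)
        positions = rng.integers(0, 2_000_000, size=1_000)
        pvals = rng.uniform(size=1_000)
        track = enr.hotspots(positions, pvals, chroms)
        for chrom in ("chr1", "chr2"):
            sel = chroms == chrom
            order = np.argsort(positions[sel], kind="stable")
            expected = brute_force_hotspots(
                positions[sel][order], pvals[sel][order], 100_000
            )
            got = track.loc[track["chrom"] == chrom, "smoothed_p"].to_numpy()
            assert np.allclose(got, expected)

    def test_contraction(self, rng):
        positions = np.sort(rng.integers(0, 500_000, size=200))
        pvals = rng.uniform(size=200)
        track = enr.hotspots(positions, pvals)
        assert (track["smoothed_p"] >= pvals.min() - 1e-12).all()
        assert (track["smoothed_p"] <= pvals.max() + 1e-12).all()

    def test_zero_half_width_is_identity(self, rng):
        positions = np.arange(0, 1_000, 7)
        pvals = rng.uniform(size=positions.size)
        track = enr.hotspots(positions, pvals, window_half_width=0)
        assert np.allclose(track["smoothed_p"], pvals)

    def test_unsorted_input_sorted_output(self):
        track = enr.hotspots(np.array([90, 10, 50]), np.array([0.9, 0.1, 0.5]))
        assert list(track["position"]) == [10, 50, 90]


class TestCircosWindows:
    def _fits(self, positions, pvals, chrom="chr1", mean_m=None):
        return pd.DataFrame(
            {
                "chrom": chrom,
                "position": positions,
                "p": pvals,
                "mean_m": mean_m if mean_m is not None else np.zeros(len(positions)),
            }
        )

    def test_single_bin(self):
        fits = self._fits([100, 200, 300], [0.1, 0.2, 0.6])
        bins, _ = enr.circos_windows(fits, {"chr1": 1_000_000})
        assert len(bins) == 1
        assert bins["mean_p"].iloc[0] == pytest.approx(0.3)

    def test_boundary_position_goes_to_second_bin(self):
        fits = self._fits([5_000_000], [0.5])
        bins, _ = enr.circos_windows(fits, {"chr1": 10_000_000})
        assert bins.loc[0, "n_probes"] == 0
        assert bins.loc[1, "n_probes"] == 1

    def test_empty_bins_emitted_with_missing_marker(self):
        fits = self._fits([100], [0.5])
        bins, _ = enr.circos_windows(fits, {"chr1": 12_000_000})
        assert len(bins) == 3
        assert np.isnan(bins.loc[1, "mean_p"]) and np.isnan(bins.loc[2, "mean_p"])

    def test_against_binning_oracle(self, rng):
        positions = rng.integers(0, 30_000_000, size=500)
        pvals = rng.uniform(size=500)
        fits = self._fits(positions, pvals)
        bins, _ = enr.circos_windows(fits, {"chr1": 30_000_000})
        for k in range(6):
            sel = (positions >= k * 5_000_000) & (positions < (k + 1) * 5_000_000)
            expected = pvals[sel].mean() if sel.any() else np.nan
            got = bins.loc[k, "mean_p"]
            assert (np.isnan(got) and np.isnan(expected)) or got == pytest.approx(expected)

    def test_top_table_ranking_with_ties(self, rng):
        fits = self._fits(
            [0, 10, 20, 30],
            [0.01, 0.001, 0.001, 0.5],
            mean_m=[1.0, 0.5, 3.0, 2.0],
        )
        _, top = enr.circos_windows(fits, {"chr1": 1_000_000}, top_n=3)
        # ties on p broken by |mean_m| descending
        assert list(top["position"]) == [20, 10, 0]


class TestBedgraph:
    def test_format_line(self):
        track = pd.DataFrame(
            [{"chrom": "chr1", "start": 0, "end": 100, "value": 0.5}]
        )
        text = exp.export_bedgraph(track)
        lines = text.strip().splitlines()
        assert lines[0].startswith("track type=bedGraph")
        assert lines[1] == "chr1\t0\t100\t0.5"

    def test_empty_track_header_only(self):
        track = pd.DataFrame(columns=["chrom", "start", "end", "value"])
        text = exp.export_bedgraph(track)
        assert text.strip().splitlines() == ['track type=bedGraph name="edma_track"']

    def test_round_trip(self, rng, tmp_path):
        n = 50
        starts = np.sort(rng.choice(np.arange(0, 100_000, 10), size=n, replace=False))
        track = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": starts,
                "end": starts + 5,
                "value": rng.uniform(-3, 3, size=n),
            }
        )
        path = tmp_path / "t.bedgraph"
        exp.export_bedgraph(track, path)
        back = exp.parse_bedgraph(path)
        assert np.allclose(back["value"], track["value"], atol=1e-6)
        assert (back["start"].to_numpy() == track["start"].to_numpy()).all()

    def test_overlap_policy(self):
        track = pd.DataFrame(
            [
                {"chrom": "chr1", "start": 0, "end": 100, "value": 1.0},
                {"chrom": "chr1", "start": 50, "end": 150, "value": 2.0},
            ]
        )
        with pytest.raises(exp.ExportError):
            exp.export_bedgraph(track)
        merged = exp.export_bedgraph(track, overlap_policy="merge")
        assert "chr1\t100\t150\t2" in merged


def test_circos_exports(tmp_path):
    karyotype = exp.export_circos_karyotype({"chr1": 1_000, "chr2": 2_000})
    assert "chr - chr1 chr1 0 1000 grey" in karyotype
    track = pd.DataFrame(
        {"chrom": ["chr1", "chr1"], "start": [0, 500], "end": [500, 1000],
         "mean_p": [0.25, np.nan]}
    )
    text = exp.export_circos_data(track, value_column="mean_p")
    assert text.strip() == "chr1 0 500 0.25"  # NaN window skipped
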