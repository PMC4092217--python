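"""Annotation vectors: promoter windows, island relation/classes, repeats."""

import math

import numpy as np
import pandas as pd
import pytest

from edmakit import annotation as ann
from edmakit.restriction import RestrictionFragment


def make_islands(values, chrom="chr1", spacing=100_000, density=0.1):
    """Cohort of islands with the given lengths, CpG counts set so every
    island has identical density unless ``density`` is an iterable."""
    densities = (
        list(density) if np.iterable(density) else [density] * len(values)
    )
    islands = []
    for i, (length, d) in enumerate(zip(values, densities)):
        start = i * spacing
        isl = ann.CpGIslandRecord(chrom, start, start + int(length), name=f"i{i}")
        isl.cpg_count = int(round(d * length))
        islands.append(isl)
    return islands


class TestPromoterWindows:
    def test_plus_strand(self):
        g = ann.GeneModel("g", "chr1", "+", 100_000, 120_000, [(100_000, 120_000)])
        w = ann.promoter_windows(g)
        assert w["proximal_promoter"] == (99_000, 100_000)
        assert w["promoter"] == (95_000, 100_000)
        assert w["distal_promoter"] == (50_000, 100_000)

    def test_minus_strand_mirror(self):
        g = ann.GeneModel("g", "chr1", "-", 100, 500, [(100, 500)])
        w = ann.promoter_windows(g)
        assert w["proximal_promoter"] == (500, 1_500)

    def test_clipping_at_chromosome_start(self):
        g = ann.GeneModel("g", "chr1", "+", 300, 900, [(300, 900)])
        assert ann.promoter_windows(g)["proximal_promoter"] == (0, 300)

    def test_windows_nested(self):
        g = ann.GeneModel("g", "chr1", "+", 200_000, 210_000, [(200_000, 210_000)])
        w = ann.promoter_windows(g)
        (ps, pe), (ms, me), (ds, de) = (
            w["proximal_promoter"], w["promoter"], w["distal_promoter"]
        )
        assert ds <= ms <= ps and pe == me == de

    def test_invalid_strand(self):
        with pytest.raises(ann.AnnotationError):
            ann.GeneModel("g", "chr1", ".", 0, 10, [(0, 10)])


class TestIslandRelation:
    def setup_method(self):
        self.islands = [ann.CpGIslandRecord("chr1", 10_000, 11_000)]

    def test_overlap_by_one_nt(self):
        rel, d, _ = ann.island_relation(9_500, 10_001, self.islands)
        assert rel == "island" and d == 0

    def test_shore_inclusive_boundary(self):
        rel, d, _ = ann.island_relation(7_500, 8_000, self.islands)
        assert rel == "shore" and d == 2000

    def test_shelf(self):
        rel, d, _ = ann.island_relation(6_000, 7_000, self.islands)
        assert rel == "shelf" and d == 3000

    def test_open_sea_strict_boundary(self):
        rel, d, _ = ann.island_relation(1_000, 5_999, self.islands)
        assert rel == "open_sea" and d == 4001

    def test_no_islands(self):
        rel, d, nearest = ann.island_relation(0, 100, [])
        assert rel == "open_sea" and math.isinf(d) and nearest is None

    def test_order_invariance(self, rng):
        islands = make_islands([500, 800, 300, 1200], spacing=10_000)
        for _ in range(5):
            frag = sorted(rng.integers(0, 50_000, size=2))
            if frag[0] == frag[1]:
                continue
            base = ann.island_relation(frag[0], frag[1], islands)
            shuffled = list(islands)
            rng.shuffle(shuffled)
            assert ann.island_relation(frag[0], frag[1], shuffled)[:2] == base[:2]

    def test_tie_goes_to_longer_island(self):
        a = ann.CpGIslandRecord("chr1", 0, 500)
        b = ann.CpGIslandRecord("chr1", 1_600, 2_600)  # longer, same gap of 100
        rel, d, nearest = ann.island_relation(600, 1_500, [a, b])
        assert rel == "shore" and d == 100 and nearest is b


class TestClassifyIslands:
    def test_uniform_cohort_low_value_is_short(self):
        islands = make_islands(range(1, 101))
        ann.classify_islands(islands)
        # island of length 10 sits below the 20th percentile (20.8)
        assert islands[9].length_class == "short"
        assert islands[9].density_class == "intermediate"  # all equal densities

    def test_exact_percentile_is_intermediate(self):
        islands = make_islands([10, 20, 30, 40, 50, 60])
        # P20 of [10..60] with linear interpolation = 20 exactly
        assert float(np.percentile([10, 20, 30, 40, 50, 60], 20)) == 20.0
        ann.classify_islands(islands)
        assert islands[1].length_class == "intermediate"

    def test_identical_cohort_all_intermediate(self):
        islands = make_islands([400] * 10)
        ann.classify_islands(islands)
        assert {i.length_class for i in islands} == {"intermediate"}
        assert {i.density_class for i in islands} == {"intermediate"}

    def test_small_cohort_refused(self):
        with pytest.raises(ann.AnnotationError):
            ann.classify_islands(make_islands([100, 200, 300, 400]))

    def test_partition_proportions_on_large_cohort(self, rng):
        """Percentile classes split a continuous cohort ~20/60/20 (±5 %)."""
        lengths = rng.uniform(200, 3_000, size=1_000)
        densities = rng.uniform(0.02, 0.3, size=1_000)
        islands = make_islands(lengths, density=densities)
        ann.classify_islands(islands)
        for attr, low in (("length_class", "short"), ("density_class", "low")):
            counts = pd.Series([getattr(i, attr) for i in islands]).value_counts()
            n = len(islands)
            assert abs(counts[low] / n - 0.20) < 0.05
            assert abs(counts["intermediate"] / n - 0.60) < 0.05


def brute_force_annotation(frag, genes, islands, repeats):
    """Quadratic all-pairs oracle for one fragment's annotation."""

    def overlaps(s1, e1, s2, e2):
        return s1 < e2 and s2 < e1

    hits = {c: set() for c in ann.GENE_WINDOW_COLUMNS}
    for g in genes:
        if g.chrom != frag.chrom:
            continue
        for label, (ws, we) in ann.promoter_windows(g).items():
            if overlaps(frag.start, frag.end, ws, we):
                hits[label].add(g.gene_id)
        if any(overlaps(frag.start, frag.end, s, e) for s, e in g.exons):
            hits["exon"].add(g.gene_id)
        if any(overlaps(frag.start, frag.end, s, e) for s, e in g.introns):
            hits["intron"].add(g.gene_id)
    repeat_classes = {
        r.repeat_class
        for r in repeats.itertuples(index=False)
        if r.chrom == frag.chrom and overlaps(frag.start, frag.end, r.start, r.end)
    }
    same = [i for i in islands if i.chrom == frag.chrom]
    relation, _, _ = ann.island_relation(frag.start, frag.end, same)
    return hits, relation, repeat_classes


class TestAnnotate:
    def _fixture(self, rng, n_frags=50):
        genes = []
        for chrom in ("chr1", "chr2"):
            for k in range(6):
                s = int(rng.integers(0, 180_000))
                e = s + int(rng.integers(3_000, 20_000))
                n_ex = int(rng.integers(2, 5))
                cuts = np.sort(rng.choice(np.arange(s + 1, e), 2 * n_ex - 1, replace=False))
                bounds = np.concatenate([[s], cuts, [e]])
                exons = [(int(bounds[2 * i]), int(bounds[2 * i + 1])) for i in range(n_ex)]
                strand = "+" if rng.random() < 0.5 else "-"
                genes.append(ann.GeneModel(f"g_{chrom}_{k}", chrom, strand, s, e, exons))
        islands = []
        for chrom in ("chr1", "chr2"):
            pos = 0
            for k in range(8):
                pos += int(rng.integers(5_000, 30_000))
                isl = ann.CpGIslandRecord(chrom, pos, pos + int(rng.integers(300, 2_000)))
                isl.cpg_count = 50
                islands.append(isl)
        repeats = pd.DataFrame(
            [
                {
                    "chrom": str(rng.choice(["chr1", "chr2"])),
                    "start": (s := int(rng.integers(0, 200_000))),
                    "end": s + int(rng.integers(150, 1_500)),
                    "repeat_class": str(rng.choice(["LINE", "SINE", "LTR"])),
                }
                for _ in range(30)
            ]
        )
        frags = []
        for _ in range(n_frags):
            chrom = str(rng.choice(["chr1", "chr2"]))
            s = int(rng.integers(0, 200_000))
            frags.append(RestrictionFragment(chrom, s, s + int(rng.integers(50, 3_000))))
        return frags, genes, islands, repeats

    def test_exonic_fragment(self):
        g = ann.GeneModel("g1", "chr1", "+", 1_000, 9_000, [(1_000, 3_000), (6_000, 9_000)])
        frag = RestrictionFragment("chr1", 1_500, 1_700)
        table = ann.annotate([frag], [g], [], None)
        assert table.loc[0, "exon"] == "g1"
        assert table.loc[0, "intron"] == ""

    def test_exon_intron_boundary_sets_both(self):
        g = ann.GeneModel("g1", "chr1", "+", 1_000, 9_000, [(1_000, 3_000), (6_000, 9_000)])
        frag = RestrictionFragment("chr1", 2_900, 3_100)
        table = ann.annotate([frag], [g], [], None)
        assert table.loc[0, "exon"] == "g1"
        assert table.loc[0, "intron"] == "g1"

    def test_against_quadratic_oracle(self, rng):
        frags, genes, islands, repeats = self._fixture(rng)
        table = ann.annotate(frags, genes, islands, repeats)
        for i, frag in enumerate(frags):
            hits, relation, rep = brute_force_annotation(frag, genes, islands, repeats)
            row = table.iloc[i]
            for col in ann.GENE_WINDOW_COLUMNS:
                got = set(row[col].split(",")) - {""}
                assert got == hits[col], (i, col)
            assert row["island_relation"] == relation, i
            assert set(row["repeat_classes"].split(",")) - {""} == rep, i

    def test_stable_under_track_reordering(self, rng):
        frags, genes, islands, repeats = self._fixture(rng, n_frags=20)
        base = ann.annotate(frags, genes, islands, repeats)
        genes2 = list(genes)[::-1]
        islands2 = list(islands)[::-1]
        repeats2 = repeats.sample(frac=1.0, random_state=0).reset_index(drop=True)
        again = ann.annotate(frags, genes2, islands2, repeats2)
        pd.testing.assert_frame_equal(base, again)

    def test_chromosome_mismatch_raises(self):
        frag = RestrictionFragment("chr1", 0, 100)
        g = ann.GeneModel("g", "1", "+", 0, 1_000, [(0, 1_000)])  # bare naming
        with pytest.raises(ann.AnnotationError):
            ann.annotate([frag], [g], [], None)

    def test_island_classes_only_for_overlapping_fragments(self):
        islands = make_islands([500, 600, 700, 800, 900], spacing=10_000)
        ann.classify_islands(islands)
        on_island = RestrictionFragment("chr1", 10_050, 10_150)
        near_island = RestrictionFragment("chr1", 9_000, 9_500)
        table = ann.annotate([on_island, near_island], [], islands, None)
        assert table.loc[0, "island_relation"] == "island"
        assert table.loc[0, "island_length_class"] != ""
        assert table.loc[1, "island_relation"] == "shore"
        assert table.loc[1, "island_length_class"] == ""
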