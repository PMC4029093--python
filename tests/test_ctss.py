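"""CTSS construction, normalization and round-trip I/O."""

import numpy as np
import pandas as pd
import pytest

from cagepeaks import CTSSTable, count_ctss, merge_tables, read_ctss, tpm_normalize, write_ctss
from conftest import make_sam


class TestCountCtss:
    def test_empty_input_gives_empty_table(self, tmp_path):
        sam = make_sam(tmp_path / "empty.sam", [])
        table = count_ctss(str(sam))
        assert len(table) == 0
        assert table.library_size == 0

    def test_five_prime_ends_by_strand(self, tmp_path):
        # + read over [100,120) starts at 100; - read over [100,120) at 119
        sam = make_sam(
            tmp_path / "s.sam",
            [("f", 0, "chr1", 101, "20M"), ("r", 16, "chr1", 101, "20M")],
        )
        table = count_ctss(str(sam))
        recs = {(r.chrom, r.pos, r.strand): r.count for r in table.df.itertuples()}
        assert recs == {("chr1", 100, "+"): 1, ("chr1", 119, "-"): 1}

    def test_aggregation_at_shared_start(self, tmp_path):
        recs = [("a", 0, "chr1", 101, "20M")] * 3 + [("b", 0, "chr1", 102, "20M")]
        recs = [(f"r{i}", f, c, p, g) for i, (_, f, c, p, g) in enumerate(recs)]
        sam = make_sam(tmp_path / "s.sam", recs)
        table = count_ctss(str(sam))
        counts = dict(zip(table.df["pos"], table.df["count"]))
        assert counts == {100: 3, 101: 1}

    def test_unmapped_and_secondary_skipped(self, tmp_path):
        sam = make_sam(
            tmp_path / "s.sam",
            [
                ("ok", 0, "chr1", 101, "20M"),
                ("un", 4, "*", 0, "*"),
                ("sec", 256, "chr1", 201, "20M"),
                ("sup", 2048, "chr1", 301, "20M"),
            ],
        )
        table = count_ctss(str(sam))
        assert len(table) == 1 and table.library_size == 1

    def test_permutation_invariance_and_splitting(self, tmp_path, rng):
        recs = []
        for i in range(40):
            pos1 = int(rng.integers(1, 500))
            flag = 0 if rng.random() < 0.5 else 16
            recs.append((f"r{i}", flag, "chr1", pos1, "20M"))
        sam_a = make_sam(tmp_path / "a.sam", recs)
        perm = [recs[i] for i in rng.permutation(len(recs))]
        sam_b = make_sam(tmp_path / "b.sam", perm)
        assert count_ctss(str(sam_a)) == count_ctss(str(sam_b))
        # splitting the stream and summing tables equals counting the whole
        half = len(recs) // 2
        sam_1 = make_sam(tmp_path / "1.sam", recs[:half])
        sam_2 = make_sam(tmp_path / "2.sam", recs[half:])
        merged = merge_tables([count_ctss(str(sam_1)), count_ctss(str(sam_2))])
        assert merged == count_ctss(str(sam_a))


class TestTpmNormalize:
    def test_simple_counts(self, small_ctss):
        out = tpm_normalize(small_ctss)
        assert list(out.df["tpm"]) == [250000.0, 250000.0, 500000.0]
        # counts unchanged
        assert list(out.df["count"]) == [1, 1, 2]

    def test_whole_library_at_one_site(self):
        t = CTSSTable(pd.DataFrame(
            {"chrom": ["chr1"], "pos": [5], "strand": ["+"], "count": [7]}
        ))
        assert tpm_normalize(t).df["tpm"].iloc[0] == 1e6

    def test_tpm_sums_to_one_million(self, rng):
        df = pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": np.arange(200),
                "strand": "+",
                "count": rng.integers(1, 100, 200),
            }
        )
        out = tpm_normalize(CTSSTable(df))
        assert out.df["tpm"].sum() == pytest.approx(1e6, rel=1e-9)

    def test_empty_library_errors(self):
        empty = CTSSTable(pd.DataFrame(columns=["chrom", "pos", "strand", "count"]))
        with pytest.raises(ValueError, match="empty library"):
            tpm_normalize(empty)


class TestCtssIO:
    def test_round_trip_byte_identical(self, small_ctss, tmp_path):
        p1, p2 = tmp_path / "a.bed", tmp_path / "b.bed"
        write_ctss(small_ctss, p1)
        back = read_ctss(p1)
        assert back == small_ctss
        write_ctss(back, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_single_nucleotide_invariant(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t10\t12\tx\t3\t+\n")
        with pytest.raises(ValueError, match="single-nucleotide"):
            read_ctss(p)

    def test_non_integer_count(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t10\t11\tx\t3.5\t+\n")
        with pytest.raises(ValueError, match="non-integer count"):
            read_ctss(p)

    def test_unsorted_input_resorted(self, tmp_path):
        p = tmp_path / "u.bed"
        p.write_text(
            "chr1\t500\t501\tx\t2\t+\nchr1\t10\t11\ty\t1\t+\nchr1\t200\t201\tz\t4\t-\n"
        )
        t = read_ctss(p)
        assert list(t.df["pos"]) == [10, 500, 200]  # (chrom, strand, pos) order
        assert list(t.df["strand"]) == ["+", "+", "-"]
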