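import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lineagesv.io_formats import GenomicInterval
from lineagesv.svcore import (
    SVCallset,
    SVRecord,
    genotype_summary,
    match_callsets,
    reciprocal_overlap,
    subtelomeric_enrichment,
    sv_summary,
    window_density,
)


def _rec(start, end, svtype="DEL", chrom="chr1", id=None):
    return SVRecord(GenomicInterval(chrom, start, end), svtype, end - start,
                    id=id or f"{svtype}_{chrom}_{start}")


def test_svrecord_validation():
    with pytest.raises(ValueError):
        _rec(0, 40)                              # below 50 bp floor
    with pytest.raises(ValueError):
        SVRecord(GenomicInterval("c", 0, 100), "DEL", 90, id="x")
    ins = SVRecord.insertion("c", 10, "A" * 60, id="i")
    assert (ins.interval.start, ins.interval.end, ins.anchor_pos) == (10, 70, 10)


def test_reciprocal_overlap_identical_and_strict_edge():
    a = _rec(0, 500)
    assert reciprocal_overlap(a, _rec(0, 500))
    # 50% overlap fails the strict > rule
    assert not reciprocal_overlap(_rec(0, 1000), _rec(500, 1500))
    assert not reciprocal_overlap(a, _rec(0, 500, "INS"))
    assert reciprocal_overlap(a, _rec(0, 500, "INS"), type_aware=False)


def test_reciprocal_overlap_brute_force_oracle(rng):
    def brute(a, b, thr):
        if a.type != b.type or a.interval.chrom != b.interval.chrom:
            return False
        ov = len(set(range(a.interval.start, a.interval.end))
                 & set(range(b.interval.start, b.interval.end)))
        return ov > thr * a.length and ov > thr * b.length

    for _ in range(200):
        s1, s2 = rng.integers(0, 400, size=2)
        l1, l2 = rng.integers(50, 300, size=2)
        thr = float(rng.uniform(0.1, 0.9))
        a, b = _rec(int(s1), int(s1 + l1)), _rec(int(s2), int(s2 + l2))
        assert reciprocal_overlap(a, b, thr) == brute(a, b, thr)


@settings(derandomize=True, max_examples=100, deadline=None)
@given(st.integers(0, 500), st.integers(50, 300), st.integers(0, 500),
       st.integers(50, 300), st.floats(0.05, 0.95))
def test_reciprocal_overlap_symmetry_and_monotonicity(s1, l1, s2, l2, thr):
    a, b = _rec(s1, s1 + l1), _rec(s2, s2 + l2)
    assert reciprocal_overlap(a, b, thr) == reciprocal_overlap(b, a, thr)
    if reciprocal_overlap(a, b, thr):
        assert reciprocal_overlap(a, b, thr / 2)     # threshold-monotone


def test_match_callsets_identity_and_empty():
    query = SVCallset([_rec(i * 1000, i * 1000 + 100, id=f"q{i}") for i in range(20)])
    res = match_callsets(query, SVCallset([]))
    assert res.novelty_percent == 100 and res.pairs == []
    res = match_callsets(query, query)
    assert res.novelty_percent == 0 and len(res.pairs) == len(query)
    # matched pairs are one-to-one
    assert len({q for q, _ in res.pairs}) == len(res.pairs)
    assert len({r for _, r in res.pairs}) == len(res.pairs)


def test_match_callsets_published_novelty_ratio():
    """A query of 53,916 SVs with 1,997 matched reproduces the 96% novelty figure."""
    query = [_rec(i * 300, i * 300 + 100, id=f"q{i}") for i in range(53_916)]
    reference = [_rec(i * 300, i * 300 + 100, id=f"r{i}") for i in range(1_997)]
    res = match_callsets(SVCallset(query), SVCallset(reference))
    assert res.n_matched == 1_997
    assert res.novelty_percent == 96


def test_sv_summary_counts_and_medians(rng):
    records, lengths = [], []
    pos = 0
    for i in range(50):
        L = int(rng.integers(50, 500))
        lengths.append(L)
        records.append(_rec(pos, pos + L))
        pos += L + 10
    out = sv_summary(SVCallset(records), genome_size=1_000_000)
    assert out["total"] == 50
    assert out["counts"]["DEL"] == 50
    assert out["median_length"]["DEL"] == float(np.median(sorted(lengths)))
    assert out["median_length"]["INV"] is None
    empty = sv_summary(SVCallset([]), genome_size=100)
    assert empty["total"] == 0 and empty["median_length"]["DEL"] is None


def test_window_density_boundaries():
    chrom_lengths = {"chr1": 1_000_000}
    calls = SVCallset([_rec(499_999, 500_099, id="a"), _rec(500_000, 500_100, id="b")])
    df = window_density(calls, chrom_lengths, window=500_000)
    assert len(df) == 2
    assert df.loc[0, "total"] == 1 and df.loc[1, "total"] == 1  # half-open boundary


def test_window_density_histogram_oracle(rng):
    chrom_lengths = {"chr1": 730_000, "chr2": 510_000}
    records = []
    for i in range(300):
        chrom = "chr1" if rng.random() < 0.6 else "chr2"
        start = int(rng.integers(0, chrom_lengths[chrom] - 200))
        records.append(_rec(start, start + 100, chrom=chrom, id=f"s{i}"))
    window = 100_000
    df = window_density(SVCallset(records), chrom_lengths, window=window)
    for chrom, length in chrom_lengths.items():
        starts = [r.interval.start for r in records if r.interval.chrom == chrom]
        edges = np.arange(0, length + window, window)
        hist, _ = np.histogram(starts, bins=edges)
        got = df[df.chrom == chrom]["total"].to_numpy()
        assert np.array_equal(got, hist[: len(got)])


def test_subtelomeric_extreme_case():
    chrom_lengths = {"chr1": 30_000_000}
    records = [_rec(int(i * 40_000), int(i * 40_000) + 100, id=f"e{i}") for i in range(50)]
    res = subtelomeric_enrichment(SVCallset(records[:50]), chrom_lengths,
                                  margin=5_000_000, n_perm=200, seed=2)
    assert res.n_svs == 50
    # all SVs in the first 2 Mbp -> maximal fold, minimal p
    packed = [_rec(i * 200, i * 200 + 100, id=f"p{i}") for i in range(50)]
    res = subtelomeric_enrichment(SVCallset(packed), chrom_lengths,
                                  margin=5_000_000, n_perm=199, seed=2)
    assert res.n_subtelomeric == 50
    assert res.p_value == pytest.approx(1 / 200)


def test_subtelomeric_uniform_null_is_flat(rng):
    chrom_lengths = {"chr1": 40_000_000}
    records = [_rec(int(s), int(s) + 100, id=f"u{i}")
               for i, s in enumerate(rng.integers(0, 39_000_000, size=400))]
    res = subtelomeric_enrichment(SVCallset(records), chrom_lengths,
                                  margin=5_000_000, n_perm=500, seed=3)
    assert 0.7 < res.fold < 1.4
    assert res.p_value > 0.05


def test_subtelomeric_short_chromosome_flagged():
    chrom_lengths = {"tiny": 6_000_000}
    records = [_rec(1000, 1100, chrom="tiny")]
    res = subtelomeric_enrichment(SVCallset(records), chrom_lengths,
                                  margin=5_000_000, n_perm=10, seed=1)
    assert res.flagged_chroms == ["tiny"]


def _geno_df(rows):
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=[f"ind_{i}" for i in range(1, 6)])


def test_genotype_summary_published_percentages():
    """The printed 78.13/13.42/86.58/21.87 percentages follow from the counts."""
    n_inval, n_fixed, n_poly = 11_790, 5_654, 36_472
    rows = {}
    i = 0
    for _ in range(n_inval):
        rows[f"sv{i}"] = ["invalidated"] * 5; i += 1
    for _ in range(n_fixed):
        rows[f"sv{i}"] = ["1/1"] * 5; i += 1
    for _ in range(n_poly):
        rows[f"sv{i}"] = ["0/1", "0/0", "0/0", "0/0", "0/0"]; i += 1
    callset = SVCallset([_rec(j * 200, j * 200 + 100, id=f"sv{j}") for j in range(i)])
    out = genotype_summary(callset, _geno_df(rows))
    assert out.n_total == 53_916
    assert out.present_percent == 78.13
    assert out.invalidated_percent == 21.87
    assert out.fixed_percent == 13.42
    assert out.polymorphic_percent == 86.58


def test_genotype_summary_all_fixed_and_partition(rng):
    rows, records = {}, []
    for j in range(200):
        gt = rng.choice(["0/0", "0/1", "1/1", "invalidated"], size=5).tolist()
        rows[f"s{j}"] = gt
        records.append(_rec(j * 200, j * 200 + 100, id=f"s{j}"))
    out = genotype_summary(SVCallset(records), _geno_df(rows))
    assert out.n_invalidated + out.n_present + out.n_absent == out.n_total
    all11 = {f"s{j}": ["1/1"] * 5 for j in range(10)}
    out = genotype_summary(SVCallset(records[:10]), _geno_df(all11))
    assert out.fixed_percent == 100.0
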