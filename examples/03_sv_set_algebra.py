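"""Reciprocal-overlap set algebra, summaries and density statistics.

Matches a query callset against a reference set with the >50% reciprocal
rule, summarises type composition, and tests subtelomeric density
enrichment with a permutation null.
"""

import numpy as np

from lineagesv.io_formats import GenomicInterval
from lineagesv.svcore import (
    SVCallset, SVRecord, match_callsets, subtelomeric_enrichment, sv_summary,
    window_density,
)

rng = np.random.default_rng(8)
CHROM_LEN = 30_000_000


def rec(start, length, svtype="DEL", id=None):
    return SVRecord(GenomicInterval("chr1", start, start + length), svtype,
                    length, id=id or f"{svtype}_{start}")


# a callset enriched near the chromosome ends (subtelomeric clustering)
starts = np.concatenate([
    rng.integers(0, 5_000_000, size=300),
    rng.integers(CHROM_LEN - 5_000_000, CHROM_LEN - 1000, size=300),
    rng.integers(0, CHROM_LEN - 1000, size=900),
])
calls = SVCallset([rec(int(s), int(rng.integers(50, 800)), id=f"sv{i}")
                   for i, s in enumerate(starts)])

summary = sv_summary(calls, genome_size=CHROM_LEN)
print(f"{summary['total']} SVs, median DEL length "
      f"{summary['median_length']['DEL']:.0f} bp, affecting "
      f"{summary['genome_fraction_percent']}% of the genome")

# previously published set: a subset, jittered; novelty = unmatched fraction
published = SVCallset([
    SVRecord(GenomicInterval("chr1", r.interval.start + 10, r.interval.end + 10),
             r.type, r.length, id=f"pub{i}")
    for i, r in enumerate(calls[:300])
])
res = match_callsets(calls, published, threshold=0.5)
print(f"matched {res.n_matched}/{res.n_query}; novelty {res.novelty_percent}% "
      "(fraction of query SVs absent from the published set)")

density = window_density(calls, {"chr1": CHROM_LEN}, window=500_000)
print(f"window densities over {len(density)} windows of 500 kb, "
      f"max {density['total'].max()} SVs/window")

enr = subtelomeric_enrichment(calls, {"chr1": CHROM_LEN}, margin=5_000_000,
                              n_perm=1000, seed=9)
print(f"subtelomeric fold {enr.fold:.2f}, permutation p = {enr.p_value:.4g} "
      f"({enr.n_subtelomeric}/{enr.n_svs} SVs within 5 Mb of an end)")
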