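"""Close assembly gaps with flank anchoring and score assembly quality.

Derives an N-gapped "old reference" from a simulated genome, closes every
gap against the ungapped assembly, and verifies the filled sequences base
for base.  Also evaluates the QV formula on a genome-survey error rate.
"""

from lineagesv import simulate as sim
from lineagesv.asmqc import assembly_stats, close_gaps, compute_qv, find_gaps

ancestor = sim.generate_ancestral_genome(1, 800_000, repeat_fraction=0.4, seed=3)
genomes, _ = sim.evolve_genomes(ancestor, sim.default_branch_specs(0.0), seed=3)
assembly = genomes["macaque"]

gapped, gap_truth = sim.make_gapped_reference(assembly, n_gaps=10, seed=4)
print(f"planted {len(gap_truth)} gaps; find_gaps sees {len(find_gaps(gapped))}")

closures = close_gaps(gapped, assembly, flank=5000, min_aligned=2500)
removed = {(t.chrom, t.start, t.end): t.removed_sequence for t in gap_truth}
exact = sum(
    c.filled_sequence == removed[(c.gap.interval.chrom, c.gap.interval.start,
                                  c.gap.interval.end)]
    for c in closures if c.status == "closed")
print(f"closed {sum(c.status == 'closed' for c in closures)}/{len(closures)}, "
      f"{exact} fills string-equal to the removed truth")

stats = assembly_stats(gapped)
print(f"gapped reference: contig N50 {stats.contig_n50:,}, "
      f"scaffold N50 {stats.scaffold_n50:,}, "
      f"{stats.total_bases - stats.ungapped_bases:,} N bases")

# QV = -10*log10(P): at 1.11e-5 homozygous variants per base the score
# rounds to 50, i.e. about one consensus error per 100 kb
size = 2_950_026_318
qv = compute_qv(round(1.11e-5 * size), size)
print(f"QV for 1.11e-5 errors/base: {qv.qv:.2f} (rounds to {qv.qv_rounded})")
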