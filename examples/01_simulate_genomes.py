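"""Simulate a small catarrhine clade with known structural variants.

Builds a 2 Mb ancestral genome with diverged repeat copies, evolves the six
tip genomes of the fixed topology, and checks length conservation against
the planted truth table.
"""

from lineagesv import simulate as sim

ancestor = sim.generate_ancestral_genome(
    n_chrom=2, chrom_length=1_000_000, gc=0.41, repeat_fraction=0.5, seed=11)
specs = sim.default_branch_specs(subst_rate=0.002)
genomes, truth = sim.evolve_genomes(ancestor, specs, seed=11)

print(f"ancestor: {ancestor.total_bases:,} bp, "
      f"{len(ancestor.repeat_annotation)} repeat copies planted")
by_branch = {}
for t in truth:
    by_branch[t.branch] = by_branch.get(t.branch, 0) + 1
print("planted SVs per branch:", by_branch)
for tip in ("human", "macaque", "marmoset"):
    delta = genomes[tip].total_bases - ancestor.total_bases
    print(f"  {tip:9s} {genomes[tip].total_bases:,} bp ({delta:+d} vs ancestor)")
# Each tip's length offset equals the sum of signed SV lengths on its
# root-to-tip path; the truth table carries macaque-frame coordinates that
# downstream inference must recover.
dels = [t for t in truth if t.branch == "ape_ancestor" and t.type == "DEL"]
t = dels[0]
print(f"example truth: {t.id} {t.type} {t.length} bp on {t.branch}, "
      f"macaque frame {t.chrom}:{t.start}-{t.end}")
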