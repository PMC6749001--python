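import numpy as np
import pytest
from scipy import stats

from lineagesv import simulate as sim
from lineagesv.asmqc import find_gaps
from lineagesv.io_formats import species_groups


# ---------------------------------------------------------------------------
# ancestral genome
# ---------------------------------------------------------------------------

def test_ancestor_no_repeats_degenerate():
    g = sim.generate_ancestral_genome(1, 100_000, 0.41, 0.0, seed=1)
    assert list(g.chromosomes) == ["chr1"]
    assert len(g["chr1"]) == 100_000
    assert g.repeat_annotation == []


def test_ancestor_repeat_fraction_and_gc():
    g = sim.generate_ancestral_genome(2, 200_000, 0.41, 0.5, seed=7)
    covered = sum(e - s for _, s, e, _ in g.repeat_annotation)
    assert 0.45 <= covered / g.total_bases <= 0.55
    # GC of non-repeat bases close to the target
    occupied = {c: np.zeros(len(g[c]), dtype=bool) for c in g}
    for chrom, s, e, _cls in g.repeat_annotation:
        occupied[chrom][s:e] = True
    gc = at = 0
    for chrom in g:
        free = np.frombuffer(g[chrom].encode(), np.uint8)[~occupied[chrom]]
        gc += int(np.isin(free, [ord("G"), ord("C")]).sum())
        at += int(np.isin(free, [ord("A"), ord("T")]).sum())
    assert abs(gc / (gc + at) - 0.41) < 0.02


def test_ancestor_determinism_and_validation():
    a = sim.generate_ancestral_genome(1, 50_000, repeat_fraction=0.3, seed=3)
    b = sim.generate_ancestral_genome(1, 50_000, repeat_fraction=0.3, seed=3)
    assert a.chromosomes == b.chromosomes
    assert a.repeat_annotation == b.repeat_annotation
    with pytest.raises(ValueError):
        sim.generate_ancestral_genome(1, 50_000, repeat_fraction=0.96, seed=1)
    with pytest.raises(ValueError):
        sim.generate_ancestral_genome(1, 5000, seed=1)


# ---------------------------------------------------------------------------
# branch evolution
# ---------------------------------------------------------------------------

def _single_event_world(branch, svtype="DEL", L=500):
    anc = sim.generate_ancestral_genome(1, 60_000, repeat_fraction=0.0, seed=5)
    spec = sim.BranchSpec(branch, n_del=1 if svtype == "DEL" else 0,
                          n_ins=1 if svtype == "INS" else 0,
                          del_len=sim.LengthDist("uniform", low=L, high=L),
                          ins_len=sim.LengthDist("uniform", low=L, high=L))
    genomes, truth = sim.evolve_genomes(anc, [spec], seed=6)
    return anc, genomes, truth


def test_single_ape_ancestor_del_bookkeeping():
    anc, genomes, truth = _single_event_world("ape_ancestor", "DEL", 500)
    assert len(truth) == 1 and truth[0].type == "DEL"
    assert genomes["macaque"].chromosomes == anc.chromosomes
    assert genomes["marmoset"].chromosomes == anc.chromosomes
    for ape in sim.APE_TIPS:
        assert genomes[ape].total_bases == anc.total_bases - 500


def test_single_macaque_del_differs_from_all():
    anc, genomes, truth = _single_event_world("macaque", "DEL", 300)
    t = truth[0]
    assert genomes["macaque"].total_bases == anc.total_bases - 300
    for other in ("human", "marmoset"):
        assert genomes[other].chromosomes == anc.chromosomes
    # macaque-frame locus is the deletion point (sequence absent there)
    assert t.start == t.end


def test_default_spec_truth_counts():
    anc = sim.generate_ancestral_genome(2, 400_000, repeat_fraction=0.3, seed=11)
    genomes, truth = sim.evolve_genomes(anc, sim.default_branch_specs(0.0), seed=11)
    expected = 60 + 40 + 4 * 20
    assert len(truth) == expected
    by_branch = {b: sum(t.branch == b for t in truth) for b in sim.BRANCHES}
    assert by_branch["ape_ancestor"] == 60
    assert by_branch["macaque"] == 40
    assert all(by_branch[t] == 20 for t in sim.APE_TIPS)


def test_length_conservation_invariant(small_world):
    ancestor, genomes, truth = small_world
    path_of = {
        **{t: ("ape_ancestor", "great_ape_ancestor", t) for t in sim.APE_TIPS},
        "macaque": ("macaque",),
        "marmoset": ("marmoset",),
    }
    for tip, genome in genomes.items():
        delta = 0
        for t in truth:
            if t.branch in path_of[tip]:
                delta += {"DEL": -t.length, "INS": t.length,
                          "DUP": t.length, "INV": 0}[t.type]
        assert genome.total_bases == ancestor.total_bases + delta


def test_projection_soundness(small_world):
    _, genomes, truth = small_world
    mac = genomes["macaque"]
    for t in truth:
        if t.branch == "ape_ancestor" and t.type == "DEL":
            assert mac[t.chrom][t.start : t.end] == t.seq


def test_evolve_determinism(small_world):
    ancestor, genomes, _ = small_world
    specs = [
        sim.BranchSpec("ape_ancestor", n_del=8, n_ins=4),
        sim.BranchSpec("macaque", n_del=5, n_ins=3),
        sim.BranchSpec("marmoset"),
    ] + [sim.BranchSpec(t, n_del=3, n_ins=2) for t in sim.APE_TIPS]
    again, _ = sim.evolve_genomes(ancestor, specs, seed=102)
    assert all(again[t].chromosomes == genomes[t].chromosomes for t in genomes)


def test_evolve_rejects_duplicate_branch():
    anc = sim.generate_ancestral_genome(1, 50_000, seed=1)
    with pytest.raises(ValueError, match="duplicate"):
        sim.evolve_genomes(anc, [sim.BranchSpec("human"), sim.BranchSpec("human")], seed=1)


def test_branch_spec_validation():
    with pytest.raises(ValueError):
        sim.BranchSpec("no_such_branch")
    with pytest.raises(ValueError):
        sim.BranchSpec("human", n_del=-1)
    with pytest.raises(ValueError):
        sim.BranchSpec("human", subst_rate=0.2)


# ---------------------------------------------------------------------------
# gapped reference
# ---------------------------------------------------------------------------

def test_gapped_reference_zero_gaps(small_world):
    _, genomes, _ = small_world
    gapped, truth = sim.make_gapped_reference(genomes["macaque"], 0, seed=1)
    assert truth == []
    assert gapped.chromosomes == genomes["macaque"].chromosomes


def test_gapped_reference_round_trip(small_world):
    _, genomes, _ = small_world
    mac = genomes["macaque"]
    gapped, truth = sim.make_gapped_reference(mac, 10, seed=4)
    found = find_gaps(gapped)
    assert [(g.interval.chrom, g.interval.start, g.interval.end) for g in found] == \
        [(t.chrom, t.start, t.end) for t in truth]
    total_n = sum(gapped[c].count("N") for c in gapped)
    assert total_n == sum(t.end - t.start for t in truth)
    for t in truth:
        assert mac[t.chrom][t.start : t.end] == t.removed_sequence


# ---------------------------------------------------------------------------
# enhancer matrices
# ---------------------------------------------------------------------------

def test_enhancer_matrix_null_labels():
    matrix, labels = sim.simulate_enhancer_matrix(50, 0.0, 0.0, seed=2)
    assert set(labels) == {"null"}
    groups = species_groups(matrix.counts.columns)
    assert [len(groups[s]) for s in ("human", "chimp", "macaque")] == [3, 2, 3]


def test_enhancer_matrix_validation():
    with pytest.raises(ValueError, match="effect_log2fc"):
        sim.simulate_enhancer_matrix(100, 0.5, 0.0, effect_log2fc=0.0, seed=1)
    with pytest.raises(ValueError):
        sim.simulate_enhancer_matrix(100, 0.7, 0.7, seed=1)
    with pytest.raises(ValueError):
        sim.simulate_enhancer_matrix(100, 0.1, 0.1, samples=(1, 2, 3), seed=1)


def test_enhancer_matrix_planted_counts():
    _, labels = sim.simulate_enhancer_matrix(2000, 0.05, 0.05, (3, 2, 3), 2.0, 0.15, seed=3)
    assert (labels == "gain").sum() == 100
    assert (labels == "loss").sum() == 100


# ---------------------------------------------------------------------------
# genotype tables
# ---------------------------------------------------------------------------

def _toy_truth(n, in_repeat=False, svtype="DEL"):
    return [
        sim.TruthSV(id=f"t{i}", branch="ape_ancestor", type=svtype, chrom="chr1",
                    start=1000 * i, end=1000 * i + 100, length=100, in_repeat=in_repeat)
        for i in range(n)
    ]


def test_genotypes_all_fixed():
    df = sim.simulate_genotypes(_toy_truth(20), fixed_fraction=1.0, seed=1)
    assert (df.to_numpy() == "1/1").all()


def test_genotypes_repeat_insertions_invalidated():
    truth = _toy_truth(15, in_repeat=True, svtype="INS")
    df = sim.simulate_genotypes(truth, invalidation_rate_repeat_ins=1.0, seed=1)
    assert (df.to_numpy() == "invalidated").all()


def test_genotypes_fixed_fraction_binomial():
    truth = _toy_truth(1000)
    df = sim.simulate_genotypes(truth, fixed_fraction=0.13, seed=5,
                                invalidation_rate_repeat_ins=0.0)
    n_fixed = int((df.to_numpy() == "1/1").all(axis=1).sum())
    lo, hi = stats.binom.ppf([0.005, 0.995], 1000, 0.13)
    # the non-fixed arm can also draw all-hom genotypes at high AF, so the
    # planted-fixed count is a lower bound within the binomial band
    assert lo <= n_fixed
    assert n_fixed <= hi + 40
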