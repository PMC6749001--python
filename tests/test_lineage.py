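import numpy as np
import pytest

from lineagesv import simulate as sim
from lineagesv.io_formats import GenomeSequence
from lineagesv.lineage import (
    Anchors,
    HomologyMap,
    bidirectional_concordance,
    call_svs_between,
    chain_anchors,
    classify_great_ape,
    concordant_pairwise_calls,
    intersect_across_apes,
    kmer_index,
    outgroup_classify,
    overlay_human_coordinates,
    swap_frame,
    unique_anchors,
)
from lineagesv.svcore import SVCallset


def _random_genome(rng, n=10_000, name="g"):
    return GenomeSequence(name, {"chr1": "".join(rng.choice(list("ACGT"), size=n))})


def _revcomp(seq):
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


# ---------------------------------------------------------------------------
# anchors
# ---------------------------------------------------------------------------

def test_unique_anchors_tile_identical_genomes(rng):
    g = _random_genome(rng)
    anchors = unique_anchors(g, g, k=31)
    # nearly every position yields a unique shared 31-mer in random sequence
    n_kmers = 10_000 - 31 + 1
    assert len(anchors) > 0.99 * n_kmers
    assert bool(anchors.forward.all())
    # oracle: count of k-mers occurring exactly once, via a dict multiset
    seq = g["chr1"]
    counts = {}
    for i in range(n_kmers):
        km = seq[i : i + 31]
        canon = min(km, _revcomp(km))
        counts[canon] = counts.get(canon, 0) + 1
    assert len(anchors) == sum(1 for v in counts.values() if v == 1)


def test_unique_anchors_reverse_complement_orientation(rng):
    g = _random_genome(rng, 5000)
    rc = GenomeSequence("rc", {"chr1": _revcomp(g["chr1"])})
    anchors = unique_anchors(g, rc, k=31)
    assert len(anchors) > 4000
    assert not anchors.forward.any()


def test_unique_anchors_degenerate_and_validation(rng):
    a = GenomeSequence("a", {"c": "A" * 2000})
    assert len(unique_anchors(a, a, k=31)) == 0
    g = _random_genome(rng, 2000)
    with pytest.raises(ValueError):
        kmer_index(g, k=30)      # even
    with pytest.raises(ValueError):
        kmer_index(g, k=13)      # too small


# ---------------------------------------------------------------------------
# chaining
# ---------------------------------------------------------------------------

def _make_anchors(ref_pos, qry_pos, k=31):
    n = len(ref_pos)
    return Anchors(
        k=k,
        ref_chrom=np.zeros(n, dtype=np.int32),
        ref_pos=np.asarray(ref_pos, dtype=np.int64),
        qry_chrom=np.zeros(n, dtype=np.int32),
        qry_pos=np.asarray(qry_pos, dtype=np.int64),
        forward=np.ones(n, dtype=bool),
        ref_names=["chr1"],
        qry_names=["chr1"],
    )


def test_chain_colinear_anchors_single_chain():
    pos = np.arange(0, 5000, 40)
    chains = chain_anchors(_make_anchors(pos, pos + 7))
    assert len(chains) == 1
    assert len(chains[0]) == len(pos)
    assert chains[0].orientation == "+"


def test_chain_empty_input():
    assert chain_anchors(_make_anchors([], [])) == []


def test_chain_transposed_block_splits():
    # a transposed query block breaks colinearity: the LIS drops it and the
    # remaining chain splits at the breakpoint gap
    ref = np.arange(0, 4000, 40)
    qry = ref.copy()
    qry[30:60] = qry[30:60] - 2400          # transposed block
    chains = chain_anchors(_make_anchors(ref, qry), max_chain_gap=1000,
                           min_offset_run=1)
    assert len(chains) >= 2
    sizes = sorted(len(c) for c in chains)
    assert sum(sizes) <= len(ref)


def test_chain_lis_against_dp_oracle(rng):
    def dp_lis(values):
        best = [1] * len(values)
        for i in range(len(values)):
            for j in range(i):
                if values[j] < values[i]:
                    best[i] = max(best[i], best[j] + 1)
        return max(best) if values else 0

    for _ in range(200):
        n = int(rng.integers(2, 60))
        ref = np.sort(rng.choice(100_000, size=n, replace=False))
        qry = rng.choice(100_000, size=n, replace=False)
        chains = chain_anchors(_make_anchors(ref, qry),
                               max_chain_gap=10**9, min_offset_run=1)
        got = max((len(c) for c in chains), default=0)
        assert got == dp_lis(qry.tolist())


def test_chain_max_gap_splits():
    ref = np.array([0, 100, 200, 500_000, 500_100])
    chains = chain_anchors(_make_anchors(ref, ref), max_chain_gap=100_000,
                           min_offset_run=1)
    assert len(chains) == 2


# ---------------------------------------------------------------------------
# pairwise calling
# ---------------------------------------------------------------------------

def test_call_identity_is_empty(rng):
    g = _random_genome(rng, 20_000)
    assert len(call_svs_between(g, g)) == 0


def test_call_planted_deletion_exact(rng):
    ref = _random_genome(rng, 30_000, "ref")
    s, L = 12_000, 500
    query = GenomeSequence("q", {"chr1": ref["chr1"][:s] + ref["chr1"][s + L :]})
    calls = call_svs_between(ref, query)
    assert len(calls) == 1
    c = calls[0]
    assert c.type == "DEL" and c.length == L
    assert abs(c.interval.start - s) <= 31
    assert c.inserted_sequence == ref["chr1"][c.interval.start : c.interval.end]


def test_call_planted_insertion_sequence_recovered(rng):
    ref = _random_genome(rng, 30_000, "ref")
    p, L = 9_000, 300
    ins = "".join(rng.choice(list("ACGT"), size=L))
    query = GenomeSequence("q", {"chr1": ref["chr1"][:p] + ins + ref["chr1"][p:]})
    calls = call_svs_between(ref, query)
    assert len(calls) == 1
    c = calls[0]
    assert c.type == "INS" and c.length == L
    assert abs(c.interval.start - p) <= 31
    # allow breakpoint shift within junction micro-homology
    shift = c.interval.start - p
    expected = (ref["chr1"][p : p + shift] + ins + ref["chr1"][p:])[shift : shift + L] \
        if shift >= 0 else ins
    assert c.inserted_sequence == expected or c.inserted_sequence == ins


def test_swap_frame_round_trip(rng):
    ref = _random_genome(rng, 30_000, "ref")
    s, L = 15_000, 400
    query = GenomeSequence("q", {"chr1": ref["chr1"][:s] + ref["chr1"][s + L :]})
    fwd = call_svs_between(ref, query)
    rev = call_svs_between(query, ref)
    assert len(fwd) == len(rev) == 1
    assert rev[0].type == "INS"             # the deletion seen from the other side
    projected = swap_frame(rev)
    assert projected[0].type == "DEL"
    assert projected[0].interval.start == pytest.approx(fwd[0].interval.start, abs=31)
    assert projected[0].length == L


def test_bidirectional_concordance_filters_artifacts(rng):
    ref = _random_genome(rng, 40_000, "ref")
    s, L = 18_000, 400
    query = GenomeSequence("q", {"chr1": ref["chr1"][:s] + ref["chr1"][s + L :]})
    fwd = call_svs_between(ref, query)
    rev_proj = swap_frame(call_svs_between(query, ref))
    # inject a one-direction artifact into the forward set
    from lineagesv.svcore import SVRecord
    from lineagesv.io_formats import GenomicInterval
    artifact = SVRecord(GenomicInterval("chr1", 30_000, 30_200), "DEL", 200, id="art")
    fwd_plus = SVCallset(list(fwd) + [artifact], source=fwd.source)
    kept = bidirectional_concordance(fwd_plus, rev_proj)
    assert {r.id for r in kept} == {fwd[0].id}
    # monotone filter properties
    assert len(bidirectional_concordance(fwd, fwd)) == len(fwd)
    assert len(bidirectional_concordance(fwd, SVCallset([]))) == 0


# ---------------------------------------------------------------------------
# cross-ape intersection / overlay / outgroup classification
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def assv_world(small_world):
    _, genomes, truth = small_world
    mac = genomes["macaque"]
    per_ape = {
        ape: concordant_pairwise_calls(mac, genomes[ape], source=f"mac_{ape}")
        for ape in sim.APE_TIPS
    }
    calls = intersect_across_apes(per_ape)
    return genomes, truth, per_ape, calls


def _match(call, t):
    sv = call.sv
    return (sv.interval.chrom == t.chrom and sv.type == t.expected_call_type
            and abs(sv.length - t.length) <= max(0.1 * t.length, 10)
            and abs(sv.anchor_pos - t.start) <= 60)


def test_intersection_keeps_shared_drops_private(assv_world):
    genomes, truth, per_ape, calls = assv_world
    shared = [t for t in truth if t.branch in ("ape_ancestor", "macaque")]
    private = [t for t in truth if t.branch in sim.APE_TIPS]
    for t in shared:
        assert any(_match(c, t) for c in calls), t
    for t in private:
        assert not any(_match(c, t) for c in calls), t
    for c in calls:
        assert set(c.support) == {"human", "chimp", "gorilla", "orangutan"}


def test_intersection_order_independent(assv_world):
    genomes, truth, per_ape, calls = assv_world
    reordered = dict(reversed(list(per_ape.items())))
    again = intersect_across_apes(reordered)
    assert {c.sv.id for c in again} == {c.sv.id for c in calls}
    with pytest.raises(ValueError):
        intersect_across_apes({"human": per_ape["human"]})


def test_outgroup_classification_matches_branches(assv_world):
    genomes, truth, _, calls = assv_world
    hmap = HomologyMap(genomes["macaque"], genomes["marmoset"])
    for c in calls:
        outgroup_classify(c, homology=hmap)
    for t in truth:
        hits = [c for c in calls if _match(c, t)]
        if t.branch == "ape_ancestor":
            assert any(c.outgroup_class == "high_confident" for c in hits), t
        elif t.branch == "macaque":
            assert any(c.outgroup_class == "false" for c in hits), t


def test_outgroup_unlocatable_homology_is_uncertain(assv_world):
    genomes, truth, _, calls = assv_world
    # outgroup whose homologous locus is removed entirely
    target = next(c for c in calls if c.sv.type == "DEL")
    chrom = target.sv.interval.chrom
    s, e = target.sv.interval.start, target.sv.interval.end
    marm = genomes["marmoset"]
    chopped = GenomeSequence(
        "chopped", {chrom: marm[chrom][: s - 5000] + marm[chrom][e + 5000 :]})
    res = outgroup_classify(target, macaque=genomes["macaque"], outgroup=chopped)
    assert res.outgroup_class == "uncertain"


def test_great_ape_classification_requires_high_confident(assv_world):
    genomes, truth, _, calls = assv_world
    hmap = HomologyMap(genomes["macaque"], genomes["marmoset"])
    hc = None
    for c in calls:
        outgroup_classify(c, homology=hmap)
        if c.outgroup_class == "high_confident" and hc is None:
            hc = c
    # without a gibbon genome the call is uncertain by contract
    assert classify_great_ape(hc, gibbon=None) == "uncertain"
    low = next(c for c in calls if c.outgroup_class == "false")
    with pytest.raises(ValueError):
        classify_great_ape(low, gibbon=None)


def test_overlay_human_coordinates(assv_world):
    genomes, truth, per_ape, calls = assv_world
    grch38, _priv = sim.plant_svs(genomes["human"], n_del=2, n_ins=2, seed=77)
    vs_grch38 = call_svs_between(genomes["macaque"], grch38, source="mac_g38")
    annotated = overlay_human_coordinates(
        [c for c in calls], vs_grch38)
    shared = [c for c in annotated if not c.human_frame_missing]
    assert len(shared) == len(annotated)    # all candidates shared with 2nd human
    for c in shared:
        assert c.human_interval is not None
    # disjoint callsets annotate nothing
    nothing = overlay_human_coordinates(calls, SVCallset([]))
    assert all(c.human_frame_missing for c in nothing)
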