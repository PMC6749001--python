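import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lineagesv import simulate as sim
from lineagesv.io_formats import GenomicInterval
from lineagesv.lineage import LineageCall
from lineagesv.regulome import (
    annotate_near_genes,
    call_ades,
    intersect_assv_ade,
    layer_expression_test,
    two_sample_test,
)
from lineagesv.svcore import SVRecord


# ---------------------------------------------------------------------------
# two-sample test
# ---------------------------------------------------------------------------

def test_two_sample_identical_groups():
    p, d = two_sample_test([2.0, 2.0, 2.0], [2.0, 2.0])
    assert p == 1.0 and d == 0


def test_two_sample_textbook_pooled_t():
    x, y = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
    # closed form: pooled sd = 1, se = sqrt(2/3), t = -3/se, df = 4
    t_stat = (np.mean(x) - np.mean(y)) / np.sqrt(2 / 3)
    expected = 2 * stats.t.sf(abs(t_stat), df=4)
    p, d = two_sample_test(x, y)
    assert p == pytest.approx(expected, rel=1e-12)
    assert d == -1


def test_two_sample_symmetry_and_validation():
    x, y = [1.0, 2.0, 4.0], [3.0, 6.0, 7.0]
    p1, d1 = two_sample_test(x, y)
    p2, d2 = two_sample_test(y, x)
    assert p1 == p2 and d1 == -d2
    with pytest.raises(ValueError):
        two_sample_test([1.0], [2.0, 3.0])


# ---------------------------------------------------------------------------
# ADE calling
# ---------------------------------------------------------------------------

def test_ade_same_direction_rule():
    # macaque mean sits between human and chimp: opposite signs, never an ADE
    counts = pd.DataFrame({
        "human_1": [1000.0], "human_2": [1010.0], "human_3": [990.0],
        "chimp_1": [10.0], "chimp_2": [11.0],
        "macaque_1": [100.0], "macaque_2": [101.0], "macaque_3": [99.0],
    }, index=pd.Index(["e1"], name="enhancer"))
    from lineagesv.regulome import EnhancerMatrix
    m = EnhancerMatrix(counts=counts, intervals={}, region="PFC")
    rec = call_ades(m)[0]
    assert not rec.is_ade
    assert rec.p_mh < 0.05 and rec.p_mc < 0.05


def test_ade_planted_gain_detected_with_direction():
    matrix, labels = sim.simulate_enhancer_matrix(
        400, 0.1, 0.1, effect_log2fc=2.0, cv=0.10, seed=9)
    records = call_ades(matrix)
    planted = labels != "null"
    detected = np.array([r.is_ade for r in records])
    direction = np.array([r.direction for r in records], dtype=object)
    correct = detected & (direction == labels)
    assert correct[planted].mean() >= 0.9
    # fold change sign matches the planted direction for detected ADEs
    for r, lab in zip(records, labels):
        if r.is_ade and lab == "gain":
            assert r.log2fc > 0
        if r.is_ade and lab == "loss":
            assert r.log2fc < 0


def test_ade_power_monotone_in_effect():
    rates = []
    for fc in (0.5, 1.0, 2.0):
        matrix, labels = sim.simulate_enhancer_matrix(
            400, 0.25, 0.0, effect_log2fc=fc, cv=0.15, seed=12)
        records = call_ades(matrix)
        det = np.array([r.is_ade and r.direction == "gain" for r in records])
        rates.append(det[labels == "gain"].mean())
    assert rates[0] <= rates[1] + 0.05 and rates[1] <= rates[2] + 0.05
    assert rates[2] >= 0.9


# ---------------------------------------------------------------------------
# intersections and annotation
# ---------------------------------------------------------------------------

def _call(chrom, s, e, svtype="DEL", id="assv1", human=None):
    L = max(e - s, 50)
    if svtype == "INS":
        rec = SVRecord.insertion(chrom, s, "A" * L, id=id)
    else:
        rec = SVRecord(GenomicInterval(chrom, s, s + L), svtype, L, id=id)
    return LineageCall(sv=rec, human_interval=human)


def test_intersect_assv_ade_pairs_and_frame_check():
    from lineagesv.regulome import ADERecord
    ade = ADERecord("chr1:1000-2000", "PFC", 0.01, 0.01, 0.5, "gain", 1.5, True,
                    interval=GenomicInterval("chr1", 1000, 2000))
    inside = _call("chr1", 1200, 1300, human=("chr1", 1200, 1300))
    disjoint = _call("chr1", 9000, 9100, id="assv2", human=("chr1", 9000, 9100))
    out = intersect_assv_ade([inside, disjoint], [ade])
    assert len(out) == 1 and out.iloc[0]["assv_id"] == "assv1"
    with pytest.raises(ValueError, match="human-frame"):
        intersect_assv_ade([_call("chr1", 0, 100)], [ade])
    # a deletion that is a point in the human frame still intersects
    point = _call("chr1", 1500, 1600, id="assv3", human=("chr1", 1500, 1500))
    out = intersect_assv_ade([point], [ade])
    assert len(out) == 1


def test_intersect_assv_ade_brute_force_oracle(rng):
    from lineagesv.regulome import ADERecord
    ades = []
    for i in range(40):
        s = int(rng.integers(0, 50_000))
        ades.append(ADERecord(f"a{i}", "CB", 0.01, 0.01, 0.5, "gain", 1.0, True,
                              interval=GenomicInterval("chr1", s, s + 800)))
    calls = []
    for i in range(60):
        s = int(rng.integers(0, 50_000))
        calls.append(_call("chr1", s, s + 200, id=f"sv{i}", human=("chr1", s, s + 200)))
    out = intersect_assv_ade(calls, ades)
    brute = sum(
        1 for c in calls for a in ades
        if c.human_interval[1] < a.interval.end and a.interval.start < c.human_interval[2]
    )
    assert len(out) == brute


def test_annotate_near_genes_window_edges():
    genes = pd.DataFrame([
        {"gene_id": "G1", "chrom": "chr1", "start": 10_000, "end": 12_000},
    ])
    svs = {
        "near": ("chr1", 6_000, 6_100),       # 3.9-4 kb upstream -> assigned
        "far": ("chr1", 4_000, 4_100),        # 5.9 kb upstream -> intergenic
        "other": ("chr2", 10_500, 10_600),
    }
    out = annotate_near_genes(svs, genes, window=5000)
    assert out["near"] == ["G1"]
    assert out["far"] == []
    assert out["other"] == []


def test_annotate_near_genes_brute_force(rng):
    genes = pd.DataFrame([
        {"gene_id": f"G{i}", "chrom": "chr1",
         "start": int(s), "end": int(s) + 2000}
        for i, s in enumerate(rng.integers(0, 80_000, size=30))
    ])
    svs = {f"s{i}": ("chr1", int(s), int(s) + 150)
           for i, s in enumerate(rng.integers(0, 80_000, size=50))}
    out = annotate_near_genes(svs, genes, window=5000)
    for sid, (chrom, s, e) in svs.items():
        expected = sorted(
            row.gene_id for row in genes.itertuples()
            if s < row.end + 5000 and row.start - 5000 < e
        )
        assert out[sid] == expected


# ---------------------------------------------------------------------------
# layer expression
# ---------------------------------------------------------------------------

def test_layer_expression_identical_profiles():
    prof = np.linspace(1, 5, 17)
    p, d = layer_expression_test(prof, prof)
    assert p == 1.0 and d == 0


def test_layer_expression_shifted_profile(rng):
    base = np.linspace(1, 5, 17)
    shifted = base + 1.0 + rng.normal(0, 0.01, size=17)
    p, d = layer_expression_test(shifted, base)
    assert p < 0.05 and d == 1


def test_layer_expression_pairing_invariance(rng):
    a = rng.normal(5, 1, size=17)
    b = a + rng.normal(0.5, 0.3, size=17)
    p1, _ = layer_expression_test(a, b)
    perm = rng.permutation(17)
    p2, _ = layer_expression_test(a[perm], b[perm])
    assert p1 == pytest.approx(p2, rel=1e-9)
    with pytest.raises(ValueError):
        layer_expression_test(a, b[:16])
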