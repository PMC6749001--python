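"""Synthetic catarrhine genome simulator.

Generates the inputs the comparative analyses assume, with full ground
truth: an ancestral genome with planted, mutually diverged SINE/LINE-like
repeat copies; tip genomes for the fixed catarrhine topology
``(((((human, chimp), gorilla), orangutan)[, gibbon]), macaque), marmoset``
with structural variants and substitutions planted on labelled branches; an
N-gapped "old reference" derived from one genome; H3K27Ac count matrices
with planted ape-specific gains and losses; and SV genotype tables for a
small panel of individuals.

Branch lengths are irrelevant to the downstream inference (it uses
presence/absence patterns, not rates), so a branch is fully described by
its event counts, length distributions and substitution rate.  SV type
polarity is ape-centric: a DEL planted on ``ape_ancestor`` removes sequence
from every ape genome while macaque and marmoset retain it.

Truth coordinates are projected onto the macaque tip genome -- the
reference frame of the downstream analysis.  For events on the macaque
branch itself the locus in that frame is the event's own footprint (a
zero-width point for a macaque deletion, whose sequence is absent there).

Determinism: all routines take a seed and identical seeds give byte-
identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_formats import GenomeSequence, GenomicInterval
from .regulome import BRAIN_REGIONS, EnhancerMatrix

__all__ = [
    "BRANCHES",
    "APE_TIPS",
    "LengthDist",
    "BranchSpec",
    "TruthSV",
    "GapTruth",
    "default_branch_specs",
    "generate_ancestral_genome",
    "evolve_genomes",
    "plant_svs",
    "make_gapped_reference",
    "simulate_enhancer_matrix",
    "simulate_genotypes",
    "truth_to_dataframe",
]

BRANCHES = (
    "ape_ancestor", "great_ape_ancestor",
    "human", "chimp", "gorilla", "orangutan", "gibbon",
    "macaque", "marmoset",
)
APE_TIPS = ("human", "chimp", "gorilla", "orangutan")

_BASES = np.frombuffer(b"ACGTN", dtype=np.uint8)
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _decode(codes: np.ndarray) -> str:
    return bytes(_BASES[codes]).decode()


def _revcomp_codes(codes: np.ndarray) -> np.ndarray:
    out = codes[::-1].copy()
    acgt = out < 4
    out[acgt] = 3 - out[acgt]
    return out


def branch_tips(branch: str, include_gibbon: bool) -> tuple[str, ...]:
    """The tip genomes affected by an event on ``branch``."""
    apes = APE_TIPS + (("gibbon",) if include_gibbon else ())
    if branch == "ape_ancestor":
        return apes
    if branch == "great_ape_ancestor":
        return APE_TIPS
    if branch in BRANCHES:
        return (branch,)
    raise ValueError(f"unknown branch {branch!r}")


# ---------------------------------------------------------------------------
# specs and truth records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LengthDist:
    """A named SV length distribution with a hard floor at 50 bp.

    ``lognormal`` is parameterised by its median and log-scale sigma
    (defaults anchored on observed assembly-based SV catalogues: deletion
    median 319 bp, insertion median 231 bp, sigma 1.0); ``uniform`` by
    (low, high).
    """

    kind: str = "lognormal"
    median: float = 319.0
    sigma: float = 1.0
    low: int = 50
    high: int = 2000
    min_len: int = 50
    max_len: int = 20_000

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.kind == "lognormal":
            raw = rng.lognormal(mean=np.log(self.median), sigma=self.sigma, size=n)
        elif self.kind == "uniform":
            raw = rng.integers(self.low, self.high + 1, size=n).astype(float)
        else:
            raise ValueError(f"unknown length distribution {self.kind!r}")
        return np.clip(np.round(raw), self.min_len, self.max_len).astype(np.int64)


@dataclass(frozen=True)
class BranchSpec:
    """Event counts and rates for one branch of the fixed topology."""

    branch: str
    n_del: int = 0
    n_ins: int = 0
    n_dup: int = 0
    n_inv: int = 0
    del_len: LengthDist = field(default_factory=lambda: LengthDist(median=319.0))
    ins_len: LengthDist = field(default_factory=lambda: LengthDist(median=231.0))
    subst_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.branch not in BRANCHES:
            raise ValueError(f"unknown branch {self.branch!r}")
        if min(self.n_del, self.n_ins, self.n_dup, self.n_inv) < 0:
            raise ValueError("event counts must be >= 0")
        if not (0.0 <= self.subst_rate <= 0.05):
            raise ValueError("subst_rate must be in [0, 0.05]")


def default_branch_specs(subst_rate: float = 0.002,
                         include_gibbon: bool = False) -> list[BranchSpec]:
    """The default study conditions: 60 ape-ancestor events (~80% deletions,
    matching the observed ape-specific DEL:INS skew), 40 macaque-branch
    events and 20 per ape tip."""
    specs = [
        BranchSpec("ape_ancestor", n_del=45, n_ins=15, subst_rate=subst_rate),
        BranchSpec("great_ape_ancestor", subst_rate=subst_rate),
        BranchSpec("macaque", n_del=25, n_ins=15, subst_rate=subst_rate),
        BranchSpec("marmoset", subst_rate=subst_rate),
    ]
    for tip in APE_TIPS:
        specs.append(BranchSpec(tip, n_del=12, n_ins=8, subst_rate=subst_rate))
    if include_gibbon:
        specs.append(BranchSpec("gibbon", n_del=12, n_ins=8, subst_rate=subst_rate))
    return specs


@dataclass
class TruthSV:
    """A planted SV: the recovery target of the lineage inference.

    ``start``/``end`` are macaque-frame coordinates; they are zero-width
    where the affected sequence is absent from the macaque genome (ape-
    branch insertions, macaque-branch deletions).  ``seq`` is the variant
    sequence in the ancestral frame.
    """

    id: str
    branch: str
    type: str
    chrom: str
    start: int
    end: int
    length: int
    seq: str = ""
    in_repeat: bool = False

    @property
    def expected_call_type(self) -> str | None:
        """The type an ape-centric macaque-frame caller reports for this event.

        Macaque-branch events flip (a macaque insertion looks like an ape
        deletion); marmoset-branch events are invisible to macaque-ape
        comparisons.
        """
        if self.branch == "marmoset":
            return None
        if self.branch == "macaque":
            return {"DEL": "INS", "INS": "DEL"}.get(self.type)
        return self.type


@dataclass
class GapTruth:
    chrom: str
    start: int
    end: int
    removed_sequence: str

    def __post_init__(self) -> None:
        if len(self.removed_sequence) != self.end - self.start:
            raise ValueError("removed sequence length must equal gap length")


def truth_to_dataframe(truth: list[TruthSV]) -> pd.DataFrame:
    rows = [
        {
            "chrom": t.chrom, "start": t.start, "end": t.end, "id": t.id,
            "type": t.type, "branch": t.branch, "length": t.length,
            "in_repeat": t.in_repeat,
        }
        for t in truth
    ]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "id", "type",
                                       "branch", "length", "in_repeat"])


# ---------------------------------------------------------------------------
# ancestral genome
# ---------------------------------------------------------------------------

def _random_codes(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p).astype(np.uint8)


def _mutate_codes(rng: np.random.Generator, codes: np.ndarray, rate: float) -> np.ndarray:
    out = codes.copy()
    n_mut = rng.binomial(out.size, rate)
    if n_mut:
        pos = rng.choice(out.size, size=n_mut, replace=False)
        out[pos] = (out[pos] + rng.integers(1, 4, size=n_mut).astype(np.uint8)) % 4
    return out


def generate_ancestral_genome(n_chrom: int, chrom_length: int, gc: float = 0.41,
                              repeat_fraction: float = 0.0, seed: int = 0,
                              repeat_divergence: float = 0.05) -> GenomeSequence:
    """Random ancestral genome with planted, mutually diverged repeat copies.

    Copies of SINE-like (~300 bp) and LINE-like (1.5-6 kb) monomers are
    tiled at random non-overlapping positions until ``repeat_fraction`` of
    each chromosome is covered; each copy is independently mutated at
    ``repeat_divergence`` per base (and reverse-complemented half the time)
    so that copies stay k-mer distinguishable, as diverged repeat families
    in real genomes are.  The annotation records every planted copy.
    """
    if n_chrom < 1:
        raise ValueError("n_chrom must be >= 1")
    if chrom_length < 10_000:
        raise ValueError("chrom_length must be >= 10,000")
    if not (0 <= gc <= 1 and 0 <= repeat_fraction <= 1):
        raise ValueError("fractions must be in [0, 1]")
    if repeat_fraction > 0.95:
        raise ValueError("repeat_fraction > 0.95 cannot be tiled")
    rng = np.random.default_rng(seed)
    monomers = [
        ("SINE", _random_codes(rng, 300, gc)),
        ("SINE", _random_codes(rng, 300, gc)),
        ("SINE", _random_codes(rng, 300, gc)),
        ("LINE", _random_codes(rng, 1500, gc)),
        ("LINE", _random_codes(rng, 6000, gc)),
    ]
    monomer_weights = np.array([0.3, 0.3, 0.3, 0.07, 0.03])
    chroms: dict[str, str] = {}
    annotation: list[tuple] = []
    for ci in range(n_chrom):
        chrom = f"chr{ci + 1}"
        codes = _random_codes(rng, chrom_length, gc)
        target = int(repeat_fraction * chrom_length)
        occupied = np.zeros(chrom_length, dtype=bool)
        covered = 0
        attempts = 0
        max_attempts = 200 * max(1, target // 300)
        while covered < target and attempts < max_attempts:
            attempts += 1
            mi = int(rng.choice(len(monomers), p=monomer_weights))
            cls, mono = monomers[mi]
            L = mono.size
            if L > chrom_length:
                continue
            pos = int(rng.integers(0, chrom_length - L))
            if occupied[pos : pos + L].any():
                continue
            copy = _mutate_codes(rng, mono, repeat_divergence)
            if rng.random() < 0.5:
                copy = _revcomp_codes(copy)
            codes[pos : pos + L] = copy
            occupied[pos : pos + L] = True
            covered += L
            annotation.append((chrom, pos, pos + L, cls))
        if covered < target:
            raise ValueError(
                f"could not tile repeat_fraction={repeat_fraction} on {chrom} "
                f"({covered}/{target} bp placed)"
            )
        chroms[chrom] = _decode(codes)
    annotation.sort()
    return GenomeSequence("ancestor", chroms, repeat_annotation=annotation or None)


# ---------------------------------------------------------------------------
# branch evolution
# ---------------------------------------------------------------------------

@dataclass
class _Event:
    branch: str
    type: str
    chrom: str
    start: int          # ancestral coordinates
    end: int            # start for INS
    length: int
    seq_codes: np.ndarray


def _place_events(rng, spec: BranchSpec, ancestor: GenomeSequence,
                  occupied: dict[str, list[tuple[int, int]]],
                  min_spacing: int, edge_margin: int,
                  gc: float) -> list[_Event]:
    chrom_names = list(ancestor.chromosomes)
    lengths = np.array([len(ancestor[c]) for c in chrom_names], dtype=float)
    weights = lengths / lengths.sum()
    events: list[_Event] = []

    def try_place(svtype: str, L: int) -> _Event:
        for _ in range(2000):
            chrom = chrom_names[int(rng.choice(len(chrom_names), p=weights))]
            clen = len(ancestor[chrom])
            span = L if svtype != "INS" else 1
            lo, hi = edge_margin, clen - edge_margin - span
            if hi <= lo:
                continue
            start = int(rng.integers(lo, hi))
            end = start + (L if svtype != "INS" else 0)
            clash = False
            for os_, oe in occupied[chrom]:
                if start - min_spacing < oe and os_ < (end if end > start else start + 1) + min_spacing:
                    clash = True
                    break
            if clash:
                continue
            occupied[chrom].append((start, max(end, start + 1)))
            if svtype == "INS":
                seq = _random_codes(rng, L, gc)
            else:
                seq = _encode(ancestor[chrom][start:end])
            return _Event(spec.branch, svtype, chrom, start, end, L, seq)
        raise RuntimeError(
            f"SV placement exhausted on branch {spec.branch!r}; "
            "reduce event counts or spacing"
        )

    for svtype, n, dist in (("DEL", spec.n_del, spec.del_len),
                            ("INS", spec.n_ins, spec.ins_len),
                            ("DUP", spec.n_dup, spec.del_len),
                            ("INV", spec.n_inv, spec.del_len)):
        if n == 0:
            continue
        for L in dist.draw(rng, n):
            events.append(try_place(svtype, int(L)))
    return events


def evolve_genomes(ancestor: GenomeSequence, branch_specs: list[BranchSpec],
                   seed: int = 0, include_gibbon: bool | None = None,
                   min_spacing: int = 500, edge_margin: int = 2000,
                   gc: float = 0.41) -> tuple[dict[str, GenomeSequence], list[TruthSV]]:
    """Evolve tip genomes along the fixed catarrhine topology.

    Every tip genome is the ancestor transformed by the substitutions and
    SV events of all branches on its root-to-tip path.  Substitutions are
    drawn once per branch so that tips sharing a branch share its changes.
    Event placements are globally disjoint (with a ``min_spacing`` buffer),
    which keeps macaque-frame truth projection exact and guarantees that at
    most one event falls between any pair of alignment anchors.

    Returns the tip genomes and the truth table with macaque-frame
    coordinates.
    """
    spec_by_branch: dict[str, BranchSpec] = {}
    for spec in branch_specs:
        if spec.branch in spec_by_branch:
            raise ValueError(f"duplicate branch spec for {spec.branch!r}")
        spec_by_branch[spec.branch] = spec
    if include_gibbon is None:
        include_gibbon = "gibbon" in spec_by_branch
    active = [b for b in BRANCHES if include_gibbon or b != "gibbon"]
    for b in active:
        spec_by_branch.setdefault(b, BranchSpec(b))

    rng = np.random.default_rng(seed)
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in ancestor.chromosomes}
    events: list[_Event] = []
    for branch in active:
        events.extend(
            _place_events(rng, spec_by_branch[branch], ancestor, occupied,
                          min_spacing, edge_margin, gc)
        )

    # per-branch substitutions, shared across tips below that branch
    subst: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
    for branch in active:
        rate = spec_by_branch[branch].subst_rate
        per_chrom = {}
        for chrom, seq in ancestor.chromosomes.items():
            n = rng.binomial(len(seq), rate)
            if n:
                pos = np.sort(rng.choice(len(seq), size=n, replace=False))
                shift = rng.integers(1, 4, size=n).astype(np.uint8)
            else:
                pos = np.zeros(0, dtype=np.int64)
                shift = np.zeros(0, dtype=np.uint8)
            per_chrom[chrom] = (pos, shift)
        subst[branch] = per_chrom

    tips = APE_TIPS + (("gibbon",) if include_gibbon else ()) + ("macaque", "marmoset")
    path_of = {
        "human": ("ape_ancestor", "great_ape_ancestor", "human"),
        "chimp": ("ape_ancestor", "great_ape_ancestor", "chimp"),
        "gorilla": ("ape_ancestor", "great_ape_ancestor", "gorilla"),
        "orangutan": ("ape_ancestor", "great_ape_ancestor", "orangutan"),
        "gibbon": ("ape_ancestor", "gibbon"),
        "macaque": ("macaque",),
        "marmoset": ("marmoset",),
    }

    anc_codes = {c: _encode(s) for c, s in ancestor.chromosomes.items()}
    genomes: dict[str, GenomeSequence] = {}
    for tip in tips:
        path = path_of[tip]
        chroms: dict[str, str] = {}
        for chrom, base in anc_codes.items():
            codes = base.copy()
            for branch in path:
                pos, shift = subst[branch][chrom]
                if pos.size:
                    codes[pos] = (codes[pos] + shift) % 4
            tip_events = sorted(
                (ev for ev in events if ev.branch in path and ev.chrom == chrom),
                key=lambda ev: ev.start,
            )
            pieces = []
            cur = 0
            for ev in tip_events:
                pieces.append(codes[cur : ev.start])
                if ev.type == "DEL":
                    cur = ev.end
                elif ev.type == "INS":
                    pieces.append(ev.seq_codes)
                    cur = ev.start
                elif ev.type == "DUP":
                    pieces.append(codes[ev.start : ev.end])
                    pieces.append(codes[ev.start : ev.end])
                    cur = ev.end
                elif ev.type == "INV":
                    pieces.append(_revcomp_codes(codes[ev.start : ev.end]))
                    cur = ev.end
            pieces.append(codes[cur:])
            chroms[chrom] = _decode(np.concatenate(pieces))
        genomes[tip] = GenomeSequence(tip, chroms)

    # project truth onto the macaque frame
    mac_events = sorted(
        (ev for ev in events if ev.branch == "macaque"), key=lambda e: (e.chrom, e.start)
    )
    shifts: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in ancestor.chromosomes:
        starts, deltas = [0], [0]
        acc = 0
        for ev in (e for e in mac_events if e.chrom == chrom):
            if ev.type == "DEL":
                acc -= ev.length
                starts.append(ev.end)
            elif ev.type == "INS":
                acc += ev.length
                starts.append(ev.start + 1)
            elif ev.type == "DUP":
                acc += ev.length
                starts.append(ev.end)
            else:  # INV shifts nothing
                continue
            deltas.append(acc)
        shifts[chrom] = (np.array(starts), np.array(deltas))

    def project(chrom: str, x: int) -> int:
        starts, deltas = shifts[chrom]
        i = int(np.searchsorted(starts, x, side="right")) - 1
        return x + int(deltas[i])

    repeats: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e, _cls in ancestor.repeat_annotation:
        repeats.setdefault(chrom, []).append((s, e))

    def in_repeat(chrom: str, s: int, e: int) -> bool:
        span_end = e if e > s else s + 1
        return any(rs < span_end and s < re_ for rs, re_ in repeats.get(chrom, ()))

    truth: list[TruthSV] = []
    order = {b: i for i, b in enumerate(BRANCHES)}
    events.sort(key=lambda ev: (order[ev.branch], ev.chrom, ev.start))
    for i, ev in enumerate(events):
        if ev.branch == "macaque":
            if ev.type == "DEL":
                p = project(ev.chrom, ev.start)
                start, end = p, p
            elif ev.type == "INS":
                p = project(ev.chrom, ev.start)
                start, end = p, p + ev.length
            elif ev.type == "DUP":
                p = project(ev.chrom, ev.end)
                start, end = p, p + ev.length
            else:
                start = project(ev.chrom, ev.start)
                end = start + ev.length
        else:
            start = project(ev.chrom, ev.start)
            end = start + (ev.length if ev.type != "INS" else 0)
        truth.append(
            TruthSV(
                id=f"truth_{i:04d}",
                branch=ev.branch,
                type=ev.type,
                chrom=ev.chrom,
                start=start,
                end=end,
                length=ev.length,
                seq=_decode(ev.seq_codes),
                in_repeat=in_repeat(ev.chrom, ev.start, ev.end),
            )
        )
    return genomes, truth


def plant_svs(genome: GenomeSequence, n_del: int = 0, n_ins: int = 0,
              seed: int = 0, del_len: LengthDist | None = None,
              ins_len: LengthDist | None = None,
              min_spacing: int = 500, edge_margin: int = 2000,
              gc: float = 0.41) -> tuple[GenomeSequence, list[TruthSV]]:
    """Plant private SVs directly into one genome (e.g. to derive a second
    human assembly that differs from the first by private variants)."""
    spec = BranchSpec("human", n_del=n_del, n_ins=n_ins,
                      del_len=del_len or LengthDist(median=319.0),
                      ins_len=ins_len or LengthDist(median=231.0))
    rng = np.random.default_rng(seed)
    occupied = {c: [] for c in genome.chromosomes}
    events = _place_events(rng, spec, genome, occupied, min_spacing, edge_margin, gc)
    chroms: dict[str, str] = {}
    for chrom, seq in genome.chromosomes.items():
        codes = _encode(seq)
        pieces, cur = [], 0
        for ev in sorted((e for e in events if e.chrom == chrom), key=lambda e: e.start):
            pieces.append(codes[cur : ev.start])
            if ev.type == "DEL":
                cur = ev.end
            else:
                pieces.append(ev.seq_codes)
                cur = ev.start
        pieces.append(codes[cur:])
        chroms[chrom] = _decode(np.concatenate(pieces))
    truth = [
        TruthSV(id=f"private_{i:03d}", branch="human", type=ev.type, chrom=ev.chrom,
                start=ev.start, end=ev.end if ev.type != "INS" else ev.start,
                length=ev.length, seq=_decode(ev.seq_codes))
        for i, ev in enumerate(events)
    ]
    return GenomeSequence(genome.name + "_alt", chroms), truth


# ---------------------------------------------------------------------------
# gapped reference
# ---------------------------------------------------------------------------

def make_gapped_reference(genome: GenomeSequence, n_gaps: int,
                          gap_len_dist: LengthDist | None = None,
                          seed: int = 0, min_spacing: int = 6000
                          ) -> tuple[GenomeSequence, list[GapTruth]]:
    """Replace stretches of sequence with equal-length N runs.

    Gaps are placed at least ``min_spacing`` bp apart and from chromosome
    ends so that 5 kb flanks are available for closure.  The removed
    sequence is recorded as ground truth.
    """
    dist = gap_len_dist or LengthDist(kind="uniform", low=100, high=2000, min_len=2)
    rng = np.random.default_rng(seed)
    if n_gaps == 0:
        return GenomeSequence(genome.name + "_gapped", dict(genome.chromosomes),
                              repeat_annotation=genome.repeat_annotation or None), []
    chrom_names = list(genome.chromosomes)
    lens = np.array([len(genome[c]) for c in chrom_names], dtype=float)
    weights = lens / lens.sum()
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
    truth: list[GapTruth] = []
    for gi in range(n_gaps):
        L = max(2, int(dist.draw(rng, 1)[0]))
        for attempt in range(5000):
            chrom = chrom_names[int(rng.choice(len(chrom_names), p=weights))]
            clen = len(genome[chrom])
            lo, hi = min_spacing, clen - min_spacing - L
            if hi <= lo:
                continue
            start = int(rng.integers(lo, hi))
            end = start + L
            if any(start - min_spacing < oe and os_ < end + min_spacing
                   for os_, oe in placed[chrom]):
                continue
            placed[chrom].append((start, end))
            truth.append(GapTruth(chrom, start, end, genome[chrom][start:end]))
            break
        else:
            raise RuntimeError("cannot satisfy gap spacing; reduce n_gaps or gap length")
    chroms: dict[str, str] = {}
    for chrom, seq in genome.chromosomes.items():
        arr = bytearray(seq.encode())
        for s, e in placed[chrom]:
            arr[s:e] = b"N" * (e - s)
        chroms[chrom] = arr.decode()
    truth.sort(key=lambda t: (t.chrom, t.start))
    return GenomeSequence(genome.name + "_gapped", chroms), truth


# ---------------------------------------------------------------------------
# enhancer matrices
# ---------------------------------------------------------------------------

def simulate_enhancer_matrix(n_enhancers: int, frac_gain: float, frac_loss: float,
                             samples: tuple[int, int, int] = (3, 2, 3),
                             effect_log2fc: float = 2.0, cv: float = 0.15,
                             seed: int = 0, region: str = "PFC",
                             base_mean: float = 100.0,
                             chrom_lengths: dict[str, int] | None = None,
                             enhancer_len: int = 1000, spacing: int = 2000
                             ) -> tuple[EnhancerMatrix, np.ndarray]:
    """Simulate an H3K27Ac count matrix with planted ape gains and losses.

    Null enhancers draw all samples around a common per-enhancer log-normal
    mean; gain (loss) enhancers multiply (divide) the human and chimpanzee
    means by ``2**effect_log2fc``.  Per-sample multiplicative noise has
    coefficient of variation ``cv``.  Enhancer intervals are scattered over
    ``chrom_lengths`` when given, else tiled on a virtual chromosome.

    Returns the matrix plus the truth labels {gain, loss, null}.
    """
    n_h, n_c, n_m = samples
    if n_h < 2 or n_c < 2 or n_m < 2:
        raise ValueError("need >= 2 samples per species")
    if frac_gain + frac_loss > 1:
        raise ValueError("frac_gain + frac_loss must be <= 1")
    n_gain = int(round(frac_gain * n_enhancers))
    n_loss = int(round(frac_loss * n_enhancers))
    if (n_gain or n_loss) and effect_log2fc <= 0:
        raise ValueError("effect_log2fc must be positive when gains/losses are planted")
    rng = np.random.default_rng(seed)
    labels = np.array(["null"] * n_enhancers, dtype=object)
    idx = rng.permutation(n_enhancers)
    labels[idx[:n_gain]] = "gain"
    labels[idx[n_gain : n_gain + n_loss]] = "loss"

    base = rng.lognormal(mean=np.log(base_mean), sigma=0.5, size=n_enhancers)
    factor = np.ones(n_enhancers)
    factor[labels == "gain"] = 2.0 ** effect_log2fc
    factor[labels == "loss"] = 2.0 ** -effect_log2fc
    sigma = np.sqrt(np.log1p(cv * cv))

    def sample_block(mean: np.ndarray, n: int) -> np.ndarray:
        noise = rng.lognormal(mean=0.0, sigma=sigma, size=(n_enhancers, n))
        return mean[:, None] * noise

    data = np.hstack([
        sample_block(base * factor, n_h),
        sample_block(base * factor, n_c),
        sample_block(base, n_m),
    ])
    cols = ([f"human_{i+1}" for i in range(n_h)]
            + [f"chimp_{i+1}" for i in range(n_c)]
            + [f"macaque_{i+1}" for i in range(n_m)])

    intervals: dict[str, GenomicInterval] = {}
    ids = []
    if chrom_lengths:
        names = list(chrom_lengths)
        lens = np.array([chrom_lengths[c] for c in names], dtype=float)
        w = lens / lens.sum()
        for i in range(n_enhancers):
            chrom = names[int(rng.choice(len(names), p=w))]
            start = int(rng.integers(0, max(1, chrom_lengths[chrom] - enhancer_len)))
            iv = GenomicInterval(chrom, start, start + enhancer_len)
            eid = f"{chrom}:{iv.start}-{iv.end}"
            if eid in intervals:   # rare collision: nudge deterministically
                start += 1
                iv = GenomicInterval(chrom, start, start + enhancer_len)
                eid = f"{chrom}:{iv.start}-{iv.end}"
            intervals[eid] = iv
            ids.append(eid)
    else:
        for i in range(n_enhancers):
            start = i * (enhancer_len + spacing)
            iv = GenomicInterval("chrE", start, start + enhancer_len)
            eid = f"chrE:{iv.start}-{iv.end}"
            intervals[eid] = iv
            ids.append(eid)

    counts = pd.DataFrame(data, index=pd.Index(ids, name="enhancer"), columns=cols)
    return EnhancerMatrix(counts=counts, intervals=intervals, region=region), labels


# ---------------------------------------------------------------------------
# genotype tables
# ---------------------------------------------------------------------------

def simulate_genotypes(truth: list[TruthSV], n_individuals: int = 5,
                       fixed_fraction: float = 0.13,
                       invalidation_rate_repeat_ins: float = 0.5,
                       seed: int = 0) -> pd.DataFrame:
    """Simulate a present/fixed/polymorphic genotype table for an SV set.

    Fixed SVs are homozygous-alt in every individual; the rest segregate at
    an allele frequency ~ Uniform(0.1, 0.9) with Hardy-Weinberg genotypes.
    Insertions inside repeat annotation are marked invalidated (no usable
    genotype, as when short-read genotyping fails in repeats) with the given
    probability.
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    rng = np.random.default_rng(seed)
    cols = [f"ind_{i+1}" for i in range(n_individuals)]
    rows: dict[str, list[str]] = {}
    for t in truth:
        if t.type == "INS" and t.in_repeat and rng.random() < invalidation_rate_repeat_ins:
            rows[t.id] = ["invalidated"] * n_individuals
            continue
        if rng.random() < fixed_fraction:
            rows[t.id] = ["1/1"] * n_individuals
            continue
        af = rng.uniform(0.1, 0.9)
        alts = rng.binomial(2, af, size=n_individuals)
        rows[t.id] = [("0/0", "0/1", "1/1")[a] for a in alts]
    df = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    df.index.name = "sv_id"
    return df
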