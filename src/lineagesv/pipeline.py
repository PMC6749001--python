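"""End-to-end synthetic-to-report pipeline.

Runs: simulate genomes -> assembly QC (gap closure, contiguity) -> pairwise
SV calling with forward/reverse concordance -> cross-ape intersection ->
human-coordinate overlay -> outgroup classification -> truth evaluation ->
SV set summaries and genotype summaries -> differential-enhancer calling ->
trait-gene-set enrichment.  Every stochastic stage draws from a named
substream of the single top-level seed, so partial re-runs and full re-runs
are reproducible; the resolved configuration is embedded in the report.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import asmqc, enrich, lineage, regulome, simulate, svcore
from .io_formats import GenomeSequence, write_fasta

__all__ = ["PipelineConfig", "run_pipeline", "evaluate_assv_calls"]


@dataclass
class PipelineConfig:
    """Resolved parameters for one pipeline run.

    The defaults are the package's standard study conditions: a ~2 Mbp
    two-chromosome genome, 60 ape-ancestor + 40 macaque-branch + 20 per-ape-
    tip SV events, 0.002 substitutions per base per branch, and the
    enhancer-matrix design of three humans, two chimpanzees and three
    macaques.
    """

    seed: int = 0
    # ancestral genome
    n_chrom: int = 2
    chrom_length: int = 1_000_000
    gc: float = 0.41
    repeat_fraction: float = 0.5
    repeat_divergence: float = 0.05
    # branch events
    subst_rate: float = 0.002
    include_gibbon: bool = False
    event_scale: float = 1.0     # scales all branch event counts (tiny test runs)
    # alignment/calling
    k: int = 31
    min_len: int = 50
    max_chain_gap: int = 100_000
    threshold: float = 0.5
    # gap closure
    n_gaps: int = 12
    gap_len_low: int = 100
    gap_len_high: int = 2000
    flank: int = 5000
    min_aligned: int = 2500
    # outgroup classification
    outgroup_flank: int = 1000
    min_identity: float = 0.85
    span_tol: float = 0.1
    # second human assembly for the coordinate overlay
    n_private_human_svs: int = 5
    # SV set statistics
    window: int = 200_000
    subtelo_margin: int = 100_000
    n_perm: int = 500
    # genotypes
    n_individuals: int = 5
    fixed_fraction: float = 0.13
    invalidation_rate_repeat_ins: float = 0.5
    # enhancers
    n_enhancers: int = 2000
    frac_gain: float = 0.05
    frac_loss: float = 0.05
    enh_samples: tuple[int, int, int] = (3, 2, 3)
    effect_log2fc: float = 2.0
    cv: float = 0.15
    # enrichment
    n_trait_genes: int = 40
    gene_window: int = 5000
    n_iter: int = 2000
    # output
    outdir: str | None = None

    def __post_init__(self) -> None:
        if self.n_iter < 100:
            raise ValueError("n_iter must be >= 100")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "enh_samples" in data:
            data["enh_samples"] = tuple(data["enh_samples"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["enh_samples"] = list(d["enh_samples"])
        return d


def _stage_seeds(seed: int) -> dict[str, int]:
    names = ["ancestor", "evolve", "gaps", "private_human", "genotypes",
             "enhancers", "subtelo", "enrich", "trait_genes"]
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2**31)) for n, c in zip(names, children)}


def evaluate_assv_calls(calls: list[lineage.LineageCall],
                        truth: list[simulate.TruthSV],
                        tol: int = 50) -> dict:
    """Score the classified candidate set against the planted truth.

    An ape-ancestor truth is recovered when a call of the expected type lies
    within ``tol`` bp of its macaque-frame locus with a length within 10%,
    and that call is classified high_confident.  A macaque-branch truth
    "reaching the intersection stage" is one with any matching call; its
    correct classification is *false*.
    """
    def match(call: lineage.LineageCall, t: simulate.TruthSV) -> bool:
        sv = call.sv
        if sv.interval.chrom != t.chrom or sv.type != t.expected_call_type:
            return False
        if abs(sv.length - t.length) > max(0.1 * t.length, 10):
            return False
        anchor = t.start
        return abs(sv.anchor_pos - anchor) <= tol

    ape_truth = [t for t in truth if t.branch == "ape_ancestor"]
    mac_truth = [t for t in truth if t.branch == "macaque"]
    ape_recovered = 0
    for t in ape_truth:
        hits = [c for c in calls if match(c, t)]
        if any(c.outgroup_class == "high_confident" for c in hits):
            ape_recovered += 1
    mac_reaching = 0
    mac_false = 0
    for t in mac_truth:
        hits = [c for c in calls if match(c, t)]
        if hits:
            mac_reaching += 1
            if any(c.outgroup_class == "false" for c in hits):
                mac_false += 1
    n_hc = sum(c.outgroup_class == "high_confident" for c in calls)
    hc_matching_ape = sum(
        1 for c in calls
        if c.outgroup_class == "high_confident" and any(match(c, t) for t in ape_truth)
    )
    return {
        "n_ape_truth": len(ape_truth),
        "n_ape_recovered": ape_recovered,
        "sensitivity": ape_recovered / len(ape_truth) if ape_truth else float("nan"),
        "n_macaque_truth": len(mac_truth),
        "n_macaque_reaching_intersection": mac_reaching,
        "n_macaque_classified_false": mac_false,
        "macaque_false_rate": mac_false / mac_reaching if mac_reaching else float("nan"),
        "n_high_confident_calls": n_hc,
        "high_confident_precision": hc_matching_ape / n_hc if n_hc else float("nan"),
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline and return a JSON-serialisable report."""
    seeds = _stage_seeds(config.seed)
    report: dict = {"config": config.to_dict(), "stage_seeds": seeds}

    # --- simulate ---------------------------------------------------------
    ancestor = simulate.generate_ancestral_genome(
        config.n_chrom, config.chrom_length, gc=config.gc,
        repeat_fraction=config.repeat_fraction, seed=seeds["ancestor"],
        repeat_divergence=config.repeat_divergence,
    )
    specs = simulate.default_branch_specs(subst_rate=config.subst_rate,
                                          include_gibbon=config.include_gibbon)
    if config.event_scale != 1.0:
        specs = [
            dataclasses.replace(
                s,
                n_del=int(round(s.n_del * config.event_scale)),
                n_ins=int(round(s.n_ins * config.event_scale)),
            )
            for s in specs
        ]
    genomes, truth = simulate.evolve_genomes(ancestor, specs, seed=seeds["evolve"],
                                             include_gibbon=config.include_gibbon)
    report["simulation"] = {
        "ancestor_bases": ancestor.total_bases,
        "n_truth_svs": len(truth),
        "truth_by_branch": {
            b: sum(t.branch == b for t in truth)
            for b in simulate.BRANCHES if any(t.branch == b for t in truth)
        },
    }

    # --- assembly QC ------------------------------------------------------
    macaque = genomes["macaque"]
    gapped, gap_truth = simulate.make_gapped_reference(
        macaque, config.n_gaps,
        simulate.LengthDist(kind="uniform", low=config.gap_len_low,
                            high=config.gap_len_high, min_len=2),
        seed=seeds["gaps"],
    )
    closures = asmqc.close_gaps(gapped, macaque, flank=config.flank,
                                min_aligned=config.min_aligned, k=config.k)
    truth_by_locus = {(g.chrom, g.start, g.end): g.removed_sequence for g in gap_truth}
    n_closed = sum(c.status == "closed" for c in closures)
    exact = 0
    ident_num = ident_den = 0
    for c in closures:
        if c.status != "closed":
            continue
        key = (c.gap.interval.chrom, c.gap.interval.start, c.gap.interval.end)
        removed = truth_by_locus.get(key)
        if removed is None:
            continue
        if c.filled_sequence == removed:
            exact += 1
        n = min(len(c.filled_sequence), len(removed))
        if n:
            a = np.frombuffer(c.filled_sequence[:n].encode(), np.uint8)
            b = np.frombuffer(removed[:n].encode(), np.uint8)
            ident_num += int((a == b).sum())
            ident_den += max(len(c.filled_sequence), len(removed))
    stats = asmqc.assembly_stats(gapped)
    report["asmqc"] = {
        "n_gaps": len(gap_truth),
        "n_closed": n_closed,
        "closure_rate": n_closed / len(gap_truth) if gap_truth else float("nan"),
        "n_exact_fills": exact,
        "fill_identity": ident_num / ident_den if ident_den else float("nan"),
        "contig_n50": stats.contig_n50,
        "scaffold_n50": stats.scaffold_n50,
        "ungapped_bases": stats.ungapped_bases,
        "total_bases": stats.total_bases,
    }

    # --- pairwise calling and ASSV inference ------------------------------
    indexes = {name: lineage.kmer_index(g, config.k) for name, g in genomes.items()}
    per_ape: dict[str, svcore.SVCallset] = {}
    for ape in simulate.APE_TIPS:
        fwd = lineage.call_svs_between(indexes["macaque"], indexes[ape],
                                       macaque, genomes[ape], k=config.k,
                                       min_len=config.min_len,
                                       max_chain_gap=config.max_chain_gap,
                                       source=f"mac_{ape}")
        rev = lineage.call_svs_between(indexes[ape], indexes["macaque"],
                                       genomes[ape], macaque, k=config.k,
                                       min_len=config.min_len,
                                       max_chain_gap=config.max_chain_gap,
                                       source=f"{ape}_mac")
        per_ape[ape] = lineage.bidirectional_concordance(
            fwd, lineage.swap_frame(rev), threshold=config.threshold)
    calls = lineage.intersect_across_apes(per_ape, threshold=config.threshold,
                                          pivot="human")

    # second human assembly (GRCh38 stand-in) for the coordinate overlay
    grch38, _private = simulate.plant_svs(genomes["human"],
                                          n_del=config.n_private_human_svs,
                                          n_ins=config.n_private_human_svs,
                                          seed=seeds["private_human"])
    grch38_index = lineage.kmer_index(grch38, config.k)
    vs_grch38 = lineage.call_svs_between(indexes["macaque"], grch38_index,
                                         macaque, grch38, k=config.k,
                                         min_len=config.min_len,
                                         max_chain_gap=config.max_chain_gap,
                                         source="mac_grch38")
    calls = lineage.overlay_human_coordinates(calls, vs_grch38,
                                              threshold=config.threshold)

    marmoset_map = lineage.HomologyMap(macaque, genomes["marmoset"], k=config.k,
                                       max_chain_gap=config.max_chain_gap)
    for call in calls:
        lineage.outgroup_classify(call, homology=marmoset_map,
                                  flank=config.outgroup_flank,
                                  min_identity=config.min_identity,
                                  span_tol=config.span_tol)
    gibbon_map = None
    if config.include_gibbon:
        gibbon_map = lineage.HomologyMap(macaque, genomes["gibbon"], k=config.k,
                                         max_chain_gap=config.max_chain_gap)
    for call in calls:
        if call.outgroup_class == "high_confident":
            lineage.classify_great_ape(call, homology=gibbon_map,
                                       flank=config.outgroup_flank,
                                       min_identity=config.min_identity,
                                       span_tol=config.span_tol)
    by_class = {"high_confident": 0, "uncertain": 0, "false": 0}
    for c in calls:
        by_class[c.outgroup_class] += 1
    evaluation = evaluate_assv_calls(calls, truth, tol=config.k + 20)
    report["lineage"] = {
        "per_ape_concordant": {a: len(per_ape[a]) for a in per_ape},
        "n_candidates": len(calls),
        "by_outgroup_class": by_class,
        "n_human_frame_annotated": sum(not c.human_frame_missing for c in calls),
        "evaluation": evaluation,
    }
    assvs = [c for c in calls if c.outgroup_class == "high_confident"]

    # --- SV set statistics ------------------------------------------------
    union = per_ape["human"]
    summary = svcore.sv_summary(union, macaque.total_bases)
    subtelo = svcore.subtelomeric_enrichment(union, macaque.chrom_lengths,
                                             margin=config.subtelo_margin,
                                             n_perm=config.n_perm,
                                             seed=seeds["subtelo"])
    report["svcore"] = {
        "summary": summary,
        "subtelomeric": {
            "fold": subtelo.fold,
            "p_value": subtelo.p_value,
            "n_subtelomeric": subtelo.n_subtelomeric,
        },
    }

    # --- genotypes --------------------------------------------------------
    genotypes = simulate.simulate_genotypes(
        truth, n_individuals=config.n_individuals,
        fixed_fraction=config.fixed_fraction,
        invalidation_rate_repeat_ins=config.invalidation_rate_repeat_ins,
        seed=seeds["genotypes"],
    )
    truth_records = [
        svcore.SVRecord(
            interval=svcore.GenomicInterval(t.chrom, t.start, t.start + t.length),
            type=t.type, length=t.length, id=t.id, source="truth",
        )
        for t in truth
    ]
    geno = svcore.genotype_summary(svcore.SVCallset(truth_records, "truth"), genotypes)
    report["genotypes"] = {
        "present_percent": geno.present_percent,
        "invalidated_percent": geno.invalidated_percent,
        "fixed_percent": geno.fixed_percent,
        "polymorphic_percent": geno.polymorphic_percent,
    }

    # --- differential enhancers -------------------------------------------
    matrix, labels = simulate.simulate_enhancer_matrix(
        config.n_enhancers, config.frac_gain, config.frac_loss,
        samples=config.enh_samples, effect_log2fc=config.effect_log2fc,
        cv=config.cv, seed=seeds["enhancers"],
        chrom_lengths=grch38.chrom_lengths,
    )
    ades = regulome.call_ades(matrix)
    is_ade = np.array([a.is_ade for a in ades])
    directions = np.array([a.direction for a in ades], dtype=object)
    null_mask = labels == "null"
    planted_mask = ~null_mask
    correct = is_ade & planted_mask & (directions == labels)
    ade_records = [a for a in ades if a.is_ade]
    annotated_assvs = [c for c in assvs if c.human_interval is not None]
    pairs = (regulome.intersect_assv_ade(annotated_assvs, ade_records)
             if annotated_assvs else None)
    report["regulome"] = {
        "n_enhancers": int(len(labels)),
        "n_ades_called": int(is_ade.sum()),
        "null_call_rate": float(is_ade[null_mask].mean()) if null_mask.any() else float("nan"),
        "planted_detection_rate": float(correct[planted_mask].mean()) if planted_mask.any() else float("nan"),
        "n_assv_ade_pairs": int(len(pairs)) if pairs is not None else 0,
    }

    # --- enrichment -------------------------------------------------------
    universe = vs_grch38
    assv_call_ids = set()
    for call in assvs:
        partner = lineage._partner(call.sv, universe, config.threshold)
        if partner is not None:
            assv_call_ids.add(partner.id)
    enrichment = {}
    if len(assv_call_ids) >= 2:
        grng = np.random.default_rng(seeds["trait_genes"])
        names = list(grch38.chrom_lengths)
        lens = np.array([grch38.chrom_lengths[c] for c in names], dtype=float)
        w = lens / lens.sum()
        gene_len = 20_000

        def random_genes(n, prefix):
            rows = []
            for i in range(n):
                chrom = names[int(grng.choice(len(names), p=w))]
                start = int(grng.integers(0, grch38.chrom_lengths[chrom] - gene_len))
                rows.append({"gene_id": f"{prefix}{i}", "chrom": chrom,
                             "start": start, "end": start + gene_len})
            return rows

        import pandas as pd
        random_set = enrich.GeneSet("body_size", pd.DataFrame(random_genes(config.n_trait_genes, "rnd")))
        # planted set: genes centred on a sample of ASSV human-frame loci
        assv_loci = [universe.by_id()[i].mate for i in sorted(assv_call_ids)]
        picks = grng.choice(len(assv_loci), size=min(config.n_trait_genes // 2, len(assv_loci)),
                            replace=False)
        planted_rows = []
        for gi, pi in enumerate(sorted(picks.tolist())):
            chrom, s, _e = assv_loci[pi]
            start = max(0, s - gene_len // 2)
            planted_rows.append({"gene_id": f"pl{gi}", "chrom": chrom,
                                 "start": start, "end": start + gene_len})
        planted_rows.extend(random_genes(config.n_trait_genes - len(planted_rows), "plrnd"))
        planted_set = enrich.GeneSet("brain_size", pd.DataFrame(planted_rows))

        for label, gene_set in (("random", random_set), ("planted", planted_set)):
            res = enrich.permutation_enrichment(
                universe, sorted(assv_call_ids), gene_set,
                gene_window=config.gene_window, n_iter=config.n_iter,
                seed=seeds["enrich"], frame="mate",
            )
            fp, orr = enrich.fisher_enrichment(universe, sorted(assv_call_ids),
                                               gene_set, gene_window=config.gene_window,
                                               frame="mate")
            enrichment[label] = {
                "observed_genes": res.observed,
                "empirical_p": res.empirical_p,
                "fisher_p": fp,
                "odds_ratio": orr,
            }
    report["enrichment"] = enrichment

    if config.outdir:
        _write_bundle(report, config, genomes, truth, calls, Path(config.outdir))
    return report


def _write_bundle(report, config, genomes, truth, calls, outdir: Path):
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    simulate.truth_to_dataframe(truth).to_csv(outdir / "truth.tsv", sep="\t", index=False)
    rows = []
    for c in calls:
        h = c.human_interval
        rows.append({
            "chrom": c.sv.interval.chrom, "start": c.sv.interval.start,
            "end": c.sv.interval.end, "id": c.sv.id, "type": c.sv.type,
            "length": c.sv.length,
            "human_chrom": h[0] if h else "", "human_start": h[1] if h else "",
            "human_end": h[2] if h else "",
            "outgroup_class": c.outgroup_class or "",
            "great_ape_class": c.great_ape_class or "",
            "support": ";".join(f"{a}={i}" for a, i in sorted(c.support.items())),
        })
    import pandas as pd
    pd.DataFrame(rows).to_csv(outdir / "assv_calls.tsv", sep="\t", index=False)
    for name, g in genomes.items():
        write_fasta(g, outdir / f"{name}.fa")
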