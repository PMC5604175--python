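"""End-to-end analysis scenarios on synthetic crosses.

These drive the full tool chain against a seeded simulated population and
return both the pipeline outputs and the simulation truth, so callers
(tests, acceptance reporting, exploratory runs) can score recovery.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from . import qtlseq as qs
from . import simpop as sp
from . import wregion as wr


def qtlseq_end_to_end(seed: int = 7, reps: int = 2000, level: float = 0.95,
                      parent_depth: float = 40.0) -> dict:
    """QTL-seq sex-locus scan on a 253-progeny cross, bulks of 50 at 13x.

    The sex chromosome carries a 50-kb W insertion inside a wide
    low-recombination Z/W-divergent flank; a second chromosome provides
    the unlinked background. Parents are sequenced deeper than the bulks
    (heterozygous-site classification needs >= 16x in both).
    """
    cfg = sp.SimConfig(
        chrom_lengths=(3_000_000, 2_000_000),
        het_rate_p3=0.001, het_rate_p4=0.001, shared_snp_rate=0.0003,
        w_insert_len=50_000, w_locus=("chr01", 1_500_000),
        n_f1=253, bulk_size=50, depth=13.0, read_len=100,
        xover_rate=0.2, lability=(0.0, 0.0, 0.0), seed=seed,
        w_flank_bp=700_000, w_flank_het_rate=0.01)
    sim = sp.simulate_cross(cfg)
    rng = sim.rng
    female_bulk = sp.select_bulk(sim.f1, "female", cfg.bulk_size, rng)
    male_bulk = sp.select_bulk(sim.f1, "male", cfg.bulk_size, rng)

    pil_f = sp.sample_bulk_pileup(female_bulk, sim.truth, cfg, rng, sample="female")
    pil_m = sp.sample_bulk_pileup(male_bulk, sim.truth, cfg, rng, sample="male")
    deep = replace(cfg, depth=parent_depth)
    pil_p3 = sp.sample_bulk_pileup([sim.p3], sim.truth, deep, rng, sample="P3")
    pil_p4 = sp.sample_bulk_pileup([sim.p4], sim.truth, deep, rng, sample="P4")

    sub_ref, substitutions = qs.substitute_reference(sim.truth.reference, pil_p3)
    het_sites = qs.classify_het_sites(pil_p3, pil_p4)
    records = qs.bulk_snp_index(pil_f, pil_m, het_sites)
    lens = dict(zip(cfg.chrom_names, cfg.chrom_lengths))
    windows = qs.sliding_window(records, lens)
    depths = {min(r.depth_female, r.depth_male) for r in records}
    ci = qs.null_ci(depths, bulk_size=cfg.bulk_size, n_progeny=cfg.n_f1,
                    reps=reps, levels=(level,), seed=seed)
    qs.attach_window_ci(windows, records, ci)
    regions = qs.call_regions(windows, ci, level=level)

    return {"cfg": cfg, "sim": sim, "female_bulk": female_bulk,
            "male_bulk": male_bulk, "substitutions": substitutions,
            "het_sites": het_sites, "records": records, "windows": windows,
            "ci": ci, "regions": regions,
            "pileups": {"female": pil_f, "male": pil_m, "P3": pil_p3, "P4": pil_p4}}


def wregion_end_to_end(seed: int = 11, depth: float = 20.0,
                       genome_len: int = 300_000, insert_len: int = 50_000) -> dict:
    """W-insertion recovery from error-free bulk reads on parent assemblies.

    Background heterozygosity is zero so that the combined reference's
    duplicated common regions stay exact copies: under the tie-at-best
    uniqueness rule only insertion-overlapping reads map uniquely.
    """
    cfg = sp.SimConfig(
        chrom_lengths=(genome_len,), het_rate_p3=0.0, het_rate_p4=0.0,
        shared_snp_rate=0.0, w_insert_len=insert_len,
        w_locus=("chr01", genome_len // 2), n_f1=120, bulk_size=50,
        depth=depth, read_len=100, error_rate=0.0, xover_rate=0.5, seed=seed)
    sim = sp.simulate_cross(cfg)
    rng = sim.rng
    female_bulk = sp.select_bulk(sim.f1, "female", cfg.bulk_size, rng)
    male_bulk = sp.select_bulk(sim.f1, "male", cfg.bulk_size, rng)

    asm_f = {"P3ctg": sim.p3.haplotypes[1].realize(sim.truth.reference)["chr01"]}
    asm_m = {"P4ctg": sim.p4.haplotypes[0].realize(sim.truth.reference)["chr01"]}
    ref = wr.combine_references(asm_f, asm_m)

    def bulk_reads(bulk, prefix):
        seqs = {f"{ind.name}_h{h}": hap.realize(sim.truth.reference)["chr01"]
                for ind in bulk for h, hap in enumerate(ind.haplotypes)}
        return sp.sample_reads(seqs, cfg, rng, haploid_len=genome_len,
                               prefix=prefix)

    aln_f = wr.map_reads(bulk_reads(female_bulk, "f"), ref, max_mismatch=2)
    aln_m = wr.map_reads(bulk_reads(male_bulk, "m"), ref, max_mismatch=2)
    regions = wr.specific_regions(aln_f, aln_m, ref)
    selected = wr.select_specific_contigs(regions, min_fragment_bp=cfg.read_len)
    target = {"chr01W": asm_f["P3ctg"]}  # ZW reference-plant analog
    anchors = wr.anchor_contigs({c: ref.contigs[c] for c in selected}, target)
    call = wr.delineate_w_interval(anchors, regions, selected)

    w0 = cfg.w_locus[1]
    truth_interval = (w0, w0 + insert_len)  # P3ctg == chr01W coordinates
    return {"cfg": cfg, "sim": sim, "ref": ref, "alignments": (aln_f, aln_m),
            "regions": regions, "selected": selected, "anchors": anchors,
            "call": call, "truth_interval": truth_interval}


def simulate_marker_replicate(seed: int, n_f1: int = 150, n_per_chrom: int = 8,
                              chrom_len: int = 1_000_000, xover: float = 0.5,
                              repulsion_frac: float = 0.3):
    """Backcross-coded marker calls from simulated meioses on two chromosomes.

    Marker truth is the transmitted maternal haplotype at each position;
    a random subset is repulsion-coded (complemented). Returns (markers,
    truth chromosome per marker id).
    """
    from . import radmap as rm

    cfg = sp.SimConfig(chrom_lengths=(chrom_len, chrom_len), het_rate_p3=0.0,
                       het_rate_p4=0.0, shared_snp_rate=0.0, w_insert_len=0,
                       w_locus=("chr01", 1), n_f1=n_f1, bulk_size=1,
                       xover_rate=xover, seed=seed)
    rng = np.random.default_rng(seed)
    p1 = sp.ParentGenome("P1", (sp.Haplotype(), sp.Haplotype()), "ZW")
    p2 = sp.ParentGenome("P2", (sp.Haplotype(), sp.Haplotype()), "ZZ")
    f1 = sp.cross_f1(p1, p2, cfg, rng)
    markers, truth = [], {}
    for chrom in cfg.chrom_names:
        positions = np.linspace(chrom_len * 0.05, chrom_len * 0.95,
                                n_per_chrom).astype(int)
        jitter = rng.integers(-chrom_len // 50, chrom_len // 50, n_per_chrom)
        for p in np.sort(positions + jitter):
            calls = np.array([ind.gamete_source("maternal", chrom, int(p))
                              for ind in f1], dtype=np.int8)
            if rng.random() < repulsion_frac:
                calls = (1 - calls).astype(np.int8)
            mid = f"{chrom}:{int(p)}"
            markers.append(rm.RadMarker(mid, chrom, int(p), "P1", "SNP", calls))
            truth[mid] = chrom
    return markers, truth
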