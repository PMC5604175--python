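"""Genome-size estimators, assembly/annotation summaries, SSR scanning.

The k-mer estimator follows
    Rc = (Kc * Rl) / (Rl - k + 1)
    genome size = total read length / Rc
with Kc taken at the histogram mode above the first local minimum
(error-peak exclusion) when counted from reads, or supplied directly.
The flow-cytometry estimator scales a reference genome size by the ratio
of G1 fluorescence peak means, reported both unrounded and with the
one-decimal-ratio rounding convention.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simpop import revcomp
from .wregion import n_statistic


# ---------------------------------------------------------------------------
# k-mer genome size


@dataclass(frozen=True)
class KmerParams:
    k: int
    kc: float  # k-mer coverage
    rl: float  # mean read length (bp)
    total_len: float  # total read bases (bp)
    rc: float  # read coverage, derived
    size: float  # genome size (bp), derived


def kmer_params(k: int, kc: float, rl: float, total_len: float) -> KmerParams:
    """Direct-parameter entry: apply the two formulas verbatim."""
    if k >= rl:
        raise ValueError("k must be smaller than the read length")
    rc = (kc * rl) / (rl - k + 1)
    return KmerParams(k=k, kc=kc, rl=rl, total_len=total_len, rc=rc,
                      size=total_len / rc)


def kmer_histogram(reads, k: int) -> Counter:
    """Multiplicity histogram of canonical (strand-min) k-mers."""
    counts: Counter = Counter()
    for _, seq in reads:
        for i in range(len(seq) - k + 1):
            km = seq[i:i + k]
            counts[min(km, revcomp(km))] += 1
    hist: Counter = Counter()
    for mult in counts.values():
        hist[mult] += 1
    return hist


def kc_from_histogram(hist: Counter) -> float:
    """Histogram mode above the first local minimum (skip the error peak)."""
    if not hist:
        raise ValueError("empty histogram")
    xs = np.arange(1, max(hist) + 1)
    ys = np.array([hist.get(int(x), 0) for x in xs], dtype=float)
    first_min = 0
    for i in range(1, len(ys)):
        if ys[i] > ys[i - 1]:
            first_min = i
            break
    return float(xs[first_min + int(np.argmax(ys[first_min:]))])


def kmer_genome_size(reads, k: int) -> KmerParams:
    """Count canonical k-mers from reads and estimate the genome size."""
    lens = [len(s) for _, s in reads]
    if not lens:
        raise ValueError("no reads")
    rl = float(np.mean(lens))
    if k >= min(lens):
        raise ValueError("k must be smaller than the read length")
    kc = kc_from_histogram(kmer_histogram(reads, k))
    return kmer_params(k=k, kc=kc, rl=rl, total_len=float(sum(lens)))


# ---------------------------------------------------------------------------
# flow-cytometry genome size


@dataclass(frozen=True)
class FcmParams:
    peak_sample: float
    peak_ref: float
    ref_size: float  # bp (or any unit; outputs share it)


def fcm_genome_size(fcm: FcmParams) -> dict[str, float]:
    """Peak-mean ratio and genome size, unrounded and paper-rounded.

    ``ratio`` is reported to 3 decimals; ``size_rounded`` multiplies the
    reference size by the ratio rounded to one decimal, ``size`` by the
    full-precision ratio.
    """
    if fcm.peak_sample <= 0 or fcm.peak_ref <= 0:
        raise ValueError("fluorescence peaks must be positive")
    ratio = fcm.peak_sample / fcm.peak_ref
    return {
        "ratio": round(ratio, 3),
        "ratio_full": ratio,
        "size": fcm.ref_size * ratio,
        "size_rounded": fcm.ref_size * round(ratio, 1),
    }


def percent_excess(assembly_len: float, estimate: float) -> float:
    """Percent by which an assembly exceeds a genome-size estimate."""
    return 100.0 * (assembly_len - estimate) / estimate


# ---------------------------------------------------------------------------
# assembly statistics


@dataclass(frozen=True)
class AssemblyStats:
    n_scaffolds: int
    total_len: int
    largest: int
    n50: int
    n75: int
    gc_percent: float
    n_per_100kb: float


def assembly_stats(seqs: dict[str, str]) -> AssemblyStats:
    if not seqs:
        raise ValueError("empty assembly")
    lens = [len(s) for s in seqs.values()]
    total = sum(lens)
    gc = sum(s.count("G") + s.count("C") for s in seqs.values())
    acgt = sum(sum(s.count(b) for b in "ACGT") for s in seqs.values())
    ns = sum(s.count("N") for s in seqs.values())
    return AssemblyStats(
        n_scaffolds=len(lens), total_len=total, largest=max(lens),
        n50=n_statistic(lens, 0.5), n75=n_statistic(lens, 0.75),
        gc_percent=100.0 * gc / acgt if acgt else float("nan"),
        n_per_100kb=1e5 * ns / total)


# ---------------------------------------------------------------------------
# annotation statistics


def read_gff3(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["seqid", "source", "type", "start", "end",
                            "score", "strand", "phase", "attributes"])
    return df


def _attr(attributes: str, key: str) -> str | None:
    for field in attributes.split(";"):
        if field.startswith(key + "="):
            return field[len(key) + 1:]
    return None


def annotation_stats(gff: pd.DataFrame, seqs: dict[str, str] | None = None) -> dict:
    """Per-gene exon/intron summary from GFF3 gene models.

    Exons are grouped by their Parent transcript; introns are the gaps
    between consecutive exons of a transcript. Averages are per gene.
    """
    genes = gff[gff.type == "gene"]
    exons = gff[gff.type == "exon"].copy()
    n_genes = len(genes)
    if n_genes == 0:
        raise ValueError("no gene features")
    gene_spans = {_attr(r.attributes, "ID"): (r.seqid, r.start, r.end)
                  for r in genes.itertuples(index=False)}
    mrna_parent = {_attr(r.attributes, "ID"): _attr(r.attributes, "Parent")
                   for r in gff[gff.type == "mRNA"].itertuples(index=False)}
    exons["parent"] = [_attr(a, "Parent") for a in exons.attributes]
    exon_lens, intron_lens, exon_gc = [], [], [0, 0]
    n_exons = 0
    for parent, sub in exons.groupby("parent"):
        gene_id = mrna_parent.get(parent, parent)
        span = gene_spans.get(gene_id)
        sub = sub.sort_values("start")
        for r in sub.itertuples(index=False):
            if span is not None and (r.start < span[1] or r.end > span[2]):
                raise ValueError(f"exon outside gene span for {gene_id}")
            exon_lens.append(r.end - r.start + 1)
            n_exons += 1
            if seqs is not None and r.seqid in seqs:
                s = seqs[r.seqid][r.start - 1:r.end]
                exon_gc[0] += s.count("G") + s.count("C")
                exon_gc[1] += sum(s.count(b) for b in "ACGT")
        starts = sub.start.to_numpy()
        ends = sub.end.to_numpy()
        intron_lens.extend((starts[1:] - ends[:-1] - 1).tolist())
    n_introns = len(intron_lens)
    return {
        "n_genes": n_genes,
        "n_exons": n_exons,
        "n_introns": n_introns,
        "exons_per_gene": round(n_exons / n_genes, 2),
        "introns_per_gene": round(n_introns / n_genes, 2),
        "mean_exon_len": float(np.mean(exon_lens)) if exon_lens else float("nan"),
        "mean_intron_len": float(np.mean(intron_lens)) if intron_lens else float("nan"),
        "exon_gc_percent": (100.0 * exon_gc[0] / exon_gc[1]
                            if seqs is not None and exon_gc[1] else float("nan")),
    }


def per_gene_averages(n_exons: int, n_introns: int, n_genes: int) -> tuple[float, float]:
    """Table-style per-gene averages (2 decimals) from printed totals."""
    return round(n_exons / n_genes, 2), round(n_introns / n_genes, 2)


# ---------------------------------------------------------------------------
# SSR scanning


@dataclass(frozen=True)
class SsrRecord:
    seq_id: str
    start: int  # 0-based half-open
    end: int
    motif: str
    motif_len: int
    repeats: int


def _primitive(motif: str) -> bool:
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif == motif[:d] * (n // d):
            return False
    return True


def find_ssrs(seqs: dict[str, str], min_motif: int = 2, max_motif: int = 10,
              min_repeats: int = 10) -> list[SsrRecord]:
    """Maximal perfect tandem repeats of primitive motifs.

    Mononucleotide runs are excluded regardless of ``min_motif``; a run is
    reported once, under its primitive motif, spanning only whole copies.
    """
    if min_motif < 1 or max_motif < min_motif or min_repeats < 1:
        raise ValueError("parameters must be >= 1 and ordered")
    out: list[SsrRecord] = []
    for seq_id, seq in seqs.items():
        n = len(seq)
        claimed: list[tuple[int, int]] = []
        for m in range(max(min_motif, 2), max_motif + 1):
            i = 0
            while i + m <= n:
                j = i
                while j + m < n and seq[j + m] == seq[j] and seq[j] in "ACGT":
                    j += 1
                run_len = (j - i) + m  # bases where period-m repetition holds
                repeats = run_len // m
                if repeats >= min_repeats:
                    motif = seq[i:i + m]
                    if _primitive(motif) and all(c in "ACGT" for c in motif):
                        start, end = i, i + m * repeats
                        if not any(s <= start and end <= e for s, e in claimed):
                            out.append(SsrRecord(seq_id, start, end, motif, m, repeats))
                            claimed.append((start, end))
                    i = j + m
                else:
                    i += max(1, j - i + 1)
        out.sort(key=lambda r: (r.seq_id, r.start, r.motif_len))
    return out
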