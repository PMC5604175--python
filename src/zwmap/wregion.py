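"""Sex-specific region discovery on a combined dual-parent reference.

Bulk reads are placed with an exact-seed, bounded-Hamming mini-mapper
whose uniqueness flag (single best locus) is the analog of the MAPQ-60
rule; runs of bases covered by uniquely mapping self-bulk reads with
no other-bulk coverage become bulk-specific regions, which are then
size-filtered, anchored onto a target pseudo-chromosome by exact-match
chaining, and collapsed into a single W-linked interval.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from .simpop import revcomp


# ---------------------------------------------------------------------------
# combined reference


@dataclass
class CombinedRef:
    contigs: dict[str, str]
    source: dict[str, str]  # contig -> "female-asm" | "male-asm"


def combine_references(asm_female: dict[str, str], asm_male: dict[str, str]) -> CombinedRef:
    """Fuse two assemblies; colliding names are prefixed F|/M|."""
    if not asm_female or not asm_male:
        raise ValueError("empty assembly")
    contigs, source = {}, {}
    collisions = set(asm_female) & set(asm_male)
    for name, seq in asm_female.items():
        key = f"F|{name}" if name in collisions else name
        contigs[key], source[key] = seq, "female-asm"
    for name, seq in asm_male.items():
        key = f"M|{name}" if name in collisions else name
        contigs[key], source[key] = seq, "male-asm"
    return CombinedRef(contigs, source)


# ---------------------------------------------------------------------------
# mini-mapper


@dataclass(frozen=True)
class ReadAlignment:
    read_id: str
    contig: str
    pos: int
    strand: str
    n_best_loci: int
    unique: bool
    mismatches: int
    length: int


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


class MiniMapper:
    """Exact-seed + Hamming-extension read placement.

    Every reference position is indexed at ``seed_len``; a read is probed
    with floor(read_len / seed_len) disjoint seeds on both strands, so any
    locus with at most (n_seeds - 1) mismatches is guaranteed to be found
    (pigeonhole); with the default seed count >= max_mismatch + 1 the
    mapper is exact against a brute-force scan.
    """

    def __init__(self, ref: CombinedRef, seed_len: int = 20, max_mismatch: int = 3):
        self.ref = ref
        self.seed_len = seed_len
        self.max_mismatch = max_mismatch
        self.names = list(ref.contigs)
        self.arrs = {n: _encode(s) for n, s in ref.contigs.items()}
        self.index: dict[bytes, list[tuple[int, int]]] = defaultdict(list)
        for ci, name in enumerate(self.names):
            raw = ref.contigs[name].encode()
            for p in range(len(raw) - seed_len + 1):
                self.index[raw[p:p + seed_len]].append((ci, p))

    def map_read(self, read_id: str, seq: str) -> ReadAlignment | None:
        rl = len(seq)
        if rl < self.seed_len:
            raise ValueError("seed_len exceeds read length")
        n_seeds = rl // self.seed_len
        cands: set[tuple[int, int, str]] = set()
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            raw = s.encode()
            for k in range(n_seeds):
                off = k * self.seed_len
                for ci, p in self.index.get(raw[off:off + self.seed_len], ()):
                    start = p - off
                    if 0 <= start <= len(self.arrs[self.names[ci]]) - rl:
                        cands.add((ci, start, strand))
        if not cands:
            return None
        enc = {"+": _encode(seq), "-": _encode(revcomp(seq))}
        best: list[tuple[int, int, str]] = []
        best_mm = self.max_mismatch + 1
        for ci, start, strand in sorted(cands):
            arr = self.arrs[self.names[ci]]
            mm = int((arr[start:start + rl] != enc[strand]).sum())
            if mm < best_mm:
                best_mm, best = mm, [(ci, start, strand)]
            elif mm == best_mm:
                best.append((ci, start, strand))
        if best_mm > self.max_mismatch:
            return None
        ci, start, strand = min(best)
        return ReadAlignment(read_id, self.names[ci], start, strand,
                             len(best), len(best) == 1, best_mm, rl)


def map_reads(reads, ref: CombinedRef, seed_len: int = 20,
              max_mismatch: int = 3) -> list[ReadAlignment]:
    mapper = MiniMapper(ref, seed_len=seed_len, max_mismatch=max_mismatch)
    out = []
    for read_id, seq in reads:
        aln = mapper.map_read(read_id, seq)
        if aln is not None:
            out.append(aln)
    return out


def brute_force_map(read: str, ref: CombinedRef, max_mismatch: int):
    """All-positions Hamming scan oracle: (best loci list, mismatches)."""
    best_mm, best = max_mismatch + 1, []
    enc = {"+": _encode(read), "-": _encode(revcomp(read))}
    rl = len(read)
    for ci, name in enumerate(ref.contigs):
        arr = _encode(ref.contigs[name])
        if len(arr) < rl:
            continue
        win = np.lib.stride_tricks.sliding_window_view(arr, rl)
        for strand in ("+", "-"):
            mm = (win != enc[strand]).sum(axis=1)
            m = int(mm.min())
            if m < best_mm:
                best_mm = m
                best = [(ci, int(p), strand) for p in np.nonzero(mm == m)[0]]
            elif m == best_mm:
                best += [(ci, int(p), strand) for p in np.nonzero(mm == m)[0]]
    if best_mm > max_mismatch:
        return [], None
    return sorted(best), best_mm


# ---------------------------------------------------------------------------
# bulk-specific regions


@dataclass(frozen=True)
class SpecificRegion:
    contig: str
    start: int
    end: int
    bulk: str  # "female" | "male"
    mean_depth_self: float
    mean_depth_other: float
    frac_unique: float

    @property
    def length(self) -> int:
        return self.end - self.start


def _depth_tracks(alignments, contig_lens: dict[str, int]):
    uniq = {c: np.zeros(L + 1, dtype=np.int32) for c, L in contig_lens.items()}
    total = {c: np.zeros(L + 1, dtype=np.int32) for c, L in contig_lens.items()}
    for a in alignments:
        total[a.contig][a.pos] += 1
        total[a.contig][a.pos + a.length] -= 1
        if a.unique:
            uniq[a.contig][a.pos] += 1
            uniq[a.contig][a.pos + a.length] -= 1
    return ({c: np.cumsum(v[:-1]) for c, v in uniq.items()},
            {c: np.cumsum(v[:-1]) for c, v in total.items()})


def specific_regions(alignments_female, alignments_male, ref: CombinedRef,
                     min_frac_unique: float = 0.9,
                     max_other_depth: int = 0) -> list[SpecificRegion]:
    """Maximal per-base runs specific to one bulk.

    A base belongs to a female-specific run when female unique depth >= 1,
    male depth <= max_other_depth, and the fraction of overlapping female
    reads that map uniquely is >= min_frac_unique (and symmetrically for
    male-specific runs).
    """
    lens = {c: len(s) for c, s in ref.contigs.items()}
    f_uniq, f_tot = _depth_tracks(alignments_female, lens)
    m_uniq, m_tot = _depth_tracks(alignments_male, lens)
    out: list[SpecificRegion] = []
    for bulk, (s_uniq, s_tot, o_tot) in (("female", (f_uniq, f_tot, m_tot)),
                                         ("male", (m_uniq, m_tot, f_tot))):
        for contig, L in lens.items():
            su, st, ot = s_uniq[contig], s_tot[contig], o_tot[contig]
            with np.errstate(divide="ignore", invalid="ignore"):
                frac = np.where(st > 0, su / np.maximum(st, 1), 0.0)
            ok = (su >= 1) & (ot <= max_other_depth) & (frac >= min_frac_unique)
            for start, end in _runs(ok):
                out.append(SpecificRegion(
                    contig, start, end, bulk,
                    float(st[start:end].mean()), float(ot[start:end].mean()),
                    float(su[start:end].sum() / st[start:end].sum())))
    return out


def _runs(mask: np.ndarray):
    d = np.diff(np.concatenate(([0], mask.view(np.int8), [0])))
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0]
    return list(zip(starts.tolist(), ends.tolist()))


# ---------------------------------------------------------------------------
# size statistics and contig selection


def n_statistic(lengths, fraction: float) -> int:
    """Smallest length among the largest fragments reaching fraction x total."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    lens = sorted((int(x) for x in lengths), reverse=True)
    if not lens:
        raise ValueError("empty length list")
    target = fraction * sum(lens)
    acc = 0
    for L in lens:
        acc += L
        if acc >= target:
            return L
    return lens[-1]


def select_specific_contigs(regions: list[SpecificRegion],
                            min_fragment_bp: int | None = None,
                            bulk: str = "female") -> set[str]:
    """Contigs with at least one region strictly longer than the threshold.

    The default threshold is the N20 of the bulk's region lengths.
    """
    rs = [r for r in regions if r.bulk == bulk]
    if not rs:
        return set()
    if min_fragment_bp is None:
        min_fragment_bp = n_statistic([r.length for r in rs], 0.2)
    return {r.contig for r in rs if r.length > min_fragment_bp}


# ---------------------------------------------------------------------------
# exact-match anchoring


@dataclass
class AnchorHit:
    contig: str
    target: str
    t_start: int
    t_end: int
    strand: str
    matched_bp: int
    blocks: list[tuple[int, int, int]]  # (contig_pos, target_pos, length)

    def project(self, c_start: int, c_end: int) -> tuple[int, int] | None:
        """Map a contig interval to target coordinates via the chain."""
        lo = hi = None
        for cp, tp, ln in self.blocks:
            ov_lo, ov_hi = max(c_start, cp), min(c_end, cp + ln)
            if ov_lo >= ov_hi:
                continue
            if self.strand == "+":
                a, b = tp + (ov_lo - cp), tp + (ov_hi - cp)
            else:
                a, b = tp + (cp + ln - ov_hi), tp + (cp + ln - ov_lo)
            lo = a if lo is None else min(lo, a)
            hi = b if hi is None else max(hi, b)
        return None if lo is None else (lo, hi)


def anchor_contigs(contigs: dict[str, str], target: dict[str, str],
                   min_match_bp: int = 50, k: int = 32) -> dict[str, AnchorHit]:
    """Best collinear exact-match chain per contig against the target.

    k-mer seed matches are merged into maximal exact blocks per diagonal
    and chained in contig order; the chain with the largest matched length
    (>= min_match_bp) wins. Contigs without a chain are omitted.
    """
    index: dict[bytes, list[tuple[str, int]]] = defaultdict(list)
    for tname, tseq in target.items():
        raw = tseq.encode()
        for p in range(len(raw) - k + 1):
            index[raw[p:p + k]].append((tname, p))
    hits: dict[str, AnchorHit] = {}
    for cname, cseq in contigs.items():
        best: AnchorHit | None = None
        for strand in ("+", "-"):
            s = cseq if strand == "+" else revcomp(cseq)
            raw = s.encode()
            # diagonal -> list of contig positions (in strand orientation)
            diags: dict[tuple[str, int], list[tuple[int, int]]] = defaultdict(list)
            for cp in range(len(raw) - k + 1):
                for tname, tp in index.get(raw[cp:cp + k], ()):
                    diags[(tname, tp - cp)].append((cp, tp))
            blocks = []
            for (tname, _), pairs in diags.items():
                pairs.sort()
                run_start = prev = pairs[0]
                for cp, tp in pairs[1:]:
                    if cp == prev[0] + 1:
                        prev = (cp, tp)
                    else:
                        blocks.append((tname, run_start[0], run_start[1],
                                       prev[0] - run_start[0] + k))
                        run_start = prev = (cp, tp)
                blocks.append((tname, run_start[0], run_start[1],
                               prev[0] - run_start[0] + k))
            if not blocks:
                continue
            # chain per target sequence: greedy collinear selection
            by_target: dict[str, list] = defaultdict(list)
            for tname, cp, tp, ln in blocks:
                by_target[tname].append((cp, tp, ln))
            for tname, bl in by_target.items():
                bl.sort()
                chain: list[tuple[int, int, int]] = []
                last_c = last_t = -1
                for cp, tp, ln in bl:
                    if cp >= last_c and tp >= last_t:
                        chain.append((cp, tp, ln))
                        last_c, last_t = cp + ln, tp + ln
                matched = sum(ln for _, _, ln in chain)
                if matched < min_match_bp:
                    continue
                if strand == "-":
                    # express blocks in forward-contig coordinates
                    n = len(cseq)
                    chain = [(n - (cp + ln), tp, ln) for cp, tp, ln in chain]
                t0 = min(tp for _, tp, _ in chain)
                t1 = max(tp + ln for _, tp, ln in chain)
                hit = AnchorHit(cname, tname, t0, t1, strand, matched, sorted(chain))
                if best is None or hit.matched_bp > best.matched_bp:
                    best = hit
        if best is not None:
            hits[cname] = best
    return hits


# ---------------------------------------------------------------------------
# W-interval delineation


@dataclass
class WRegionCall:
    chrom: str | None
    start: int | None
    end: int | None
    supporting_contigs: list[str] = field(default_factory=list)
    supporting_regions: list[tuple[str, int, int]] = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return self.chrom is None


def delineate_w_interval(anchors: dict[str, AnchorHit],
                         regions: list[SpecificRegion],
                         contig_set: set[str] | None = None,
                         zz_alignments=None,
                         target_lengths: dict[str, int] | None = None) -> WRegionCall:
    """Minimal target interval covering all anchored female-specific regions.

    When a ZZ-selected bulk's alignments (against the target) are given,
    target bases covered by that bulk are removed before taking the span.
    """
    projected: list[tuple[str, int, int, str]] = []
    for r in regions:
        if r.bulk != "female":
            continue
        if contig_set is not None and r.contig not in contig_set:
            continue
        hit = anchors.get(r.contig)
        if hit is None:
            continue
        proj = hit.project(r.start, r.end)
        if proj is not None:
            projected.append((hit.target, proj[0], proj[1], r.contig))
    if not projected:
        return WRegionCall(None, None, None)
    # use the target chromosome supported by the most projected bases
    support = defaultdict(int)
    for t, a, b, _ in projected:
        support[t] += b - a
    chrom = max(support, key=support.get)
    projected = [p for p in projected if p[0] == chrom]
    lo = min(a for _, a, _, _ in projected)
    hi = max(b for _, _, b, _ in projected)
    if zz_alignments is not None:
        L = (target_lengths or {}).get(chrom, hi)
        cov = np.zeros(max(L, hi) + 1, dtype=np.int32)
        for a in zz_alignments:
            if a.contig == chrom:
                cov[a.pos] += 1
                cov[min(a.pos + a.length, len(cov) - 1)] -= 1
        cov = np.cumsum(cov)
        keep = np.zeros(len(cov), dtype=bool)
        for _, a, b, _ in projected:
            keep[a:b] = True
        keep &= cov[:len(keep)] == 0
        idx = np.nonzero(keep)[0]
        if len(idx) == 0:
            return WRegionCall(None, None, None)
        lo, hi = int(idx[0]), int(idx[-1]) + 1
    return WRegionCall(chrom, int(lo), int(hi),
                       supporting_contigs=sorted({c for _, _, _, c in projected}),
                       supporting_regions=[(t, a, b) for t, a, b, _ in projected])
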