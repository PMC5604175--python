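"""Pseudo-testcross RAD linkage mapping and scaffold anchoring.

Markers heterozygous in one parent and homozygous in the other are scored
as backcross-type calls (het/hom/missing) in the F1, filtered on exact
binomial segregation, thinned per interval, phased by iterative
repulsion-to-coupling conversion, grouped by single-linkage on (LOD, rf)
edges, ordered by greedy seriation, merged across the two parental maps,
and finally concatenated into N-gapped pseudo-molecules.

Genotype coding: 1 = het, 0 = hom, -1 = missing (int8 arrays).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .simpop import revcomp

HET, HOM, MISSING = 1, 0, -1


# ---------------------------------------------------------------------------
# domain types


@dataclass
class RadMarker:
    id: str
    scaffold: str
    pos: int
    parent: str  # "P1" | "P2"
    type: str  # "SNP" | "PA"
    calls: np.ndarray  # int8 per F1 individual
    phase: str = "unknown"  # coupling | repulsion | unknown
    depth: float = 0.0  # mean informative tag depth, used for thinning

    @property
    def n_informative(self) -> int:
        return int((self.calls != MISSING).sum())


@dataclass(frozen=True)
class TwoPointStat:
    marker_a: str
    marker_b: str
    n_informative: int
    n_recombinant: int
    rf: float
    lod: float


@dataclass
class LinkageGroup:
    id: str
    markers: list[RadMarker]
    cm: list[float]

    @property
    def scaffolds(self) -> list[str]:
        seen, out = set(), []
        for m in self.markers:
            if m.scaffold not in seen:
                seen.add(m.scaffold)
                out.append(m.scaffold)
        return out


@dataclass
class MergedChromosome:
    id: str
    pieces: list[tuple[str, str]]  # (scaffold id, orientation "+"|"-")


# ---------------------------------------------------------------------------
# tag placement


def align_tags(tags, scaffolds: dict[str, str], seed_len: int = 20,
               max_mismatch: int = 1) -> pd.DataFrame:
    """Place RAD tags; keep unique indel-free placements at multi-tag positions.

    Returns a table (tag_id, scaffold, pos, strand). Tags mapping to more
    than one best locus are discarded, as are positions supported by only
    a single tag.
    """
    from .wregion import CombinedRef, map_reads

    ref = CombinedRef(dict(scaffolds), {c: "female-asm" for c in scaffolds})
    alns = map_reads(tags, ref, seed_len=seed_len, max_mismatch=max_mismatch)
    rows = [(a.read_id, a.contig, a.pos, a.strand) for a in alns if a.unique]
    df = pd.DataFrame(rows, columns=["tag_id", "scaffold", "pos", "strand"])
    counts = df.groupby(["scaffold", "pos"])["tag_id"].transform("count")
    return df[counts > 1].reset_index(drop=True)


# ---------------------------------------------------------------------------
# marker selection


def segregation_filter(calls: np.ndarray, alpha: float = 0.05) -> bool:
    """Keep iff the het count sits in the exact central binomial interval.

    The interval is the central (1 - alpha) region of Binomial(n, 1/2)
    over the n informative individuals, inclusive at both ends.
    """
    from scipy.stats import binom

    informative = calls != MISSING
    n = int(informative.sum())
    if n == 0:
        raise ValueError("no informative individuals")
    k = int((calls[informative] == HET).sum())
    lo = int(binom.ppf(alpha / 2, n, 0.5))
    hi = n - lo
    return lo <= k <= hi


def _thin(markers: list[RadMarker], spacing_bp: int) -> list[RadMarker]:
    """At most one marker per spacing interval per scaffold.

    Preference: more informative F1 individuals, then higher tag depth.
    """
    kept: dict[tuple[str, int], RadMarker] = {}
    for m in markers:
        key = (m.scaffold, m.pos // spacing_bp)
        cur = kept.get(key)
        if cur is None or (m.n_informative, m.depth) > (cur.n_informative, cur.depth):
            kept[key] = m
    return sorted(kept.values(), key=lambda m: (m.scaffold, m.pos))


def _f1_snp_calls(site_key, informative_base: str, f1_pileups,
                  min_hom_depth: int = 3) -> tuple[np.ndarray, float]:
    calls = np.full(len(f1_pileups), MISSING, dtype=np.int8)
    depths = []
    for i, pv in enumerate(f1_pileups):
        row = pv.get(site_key)
        if row is None:
            continue
        inf_n = int(row[informative_base])
        total = int(row["A"] + row["C"] + row["G"] + row["T"])
        depths.append(total)
        if inf_n >= 1:
            calls[i] = HET
        elif total >= min_hom_depth:
            calls[i] = HOM
    return calls, (float(np.mean(depths)) if depths else 0.0)


def _pileup_lookup(df: pd.DataFrame) -> dict:
    return {(r.chrom, int(r.pos)): {"A": r.A, "C": r.C, "G": r.G, "T": r.T}
            for r in df.itertuples(index=False)}


def select_snp_markers(pileup_p1: pd.DataFrame, pileup_p2: pd.DataFrame,
                       f1_pileups: list[pd.DataFrame],
                       band: tuple[float, float] = (0.2, 0.8),
                       spacing_bp: int = 10_000, alpha: float = 0.05,
                       min_hom_depth: int = 3) -> list[RadMarker]:
    """SNP-type pseudo-testcross markers.

    Eligible sites have SNP-index in ``band`` (inclusive) in one parent and
    exactly 0 or 1 in the other; the informative allele is the one the
    heterozygous parent carries but the homozygous parent lacks. F1 calls:
    het iff the informative allele is observed; hom iff it is absent at
    depth >= min_hom_depth; else missing. Binomial segregation filtering
    and per-interval thinning follow.
    """
    from .qtlseq import snp_index

    lo, hi = band
    f1_tables = [_pileup_lookup(p) for p in f1_pileups]
    merged = pileup_p1.merge(pileup_p2, on=["chrom", "pos", "ref"], suffixes=("_1", "_2"))
    out: list[RadMarker] = []
    for row in merged.itertuples(index=False):
        r1 = pd.Series({"ref": row.ref, **{b: getattr(row, f"{b}_1") for b in "ACGT"}})
        r2 = pd.Series({"ref": row.ref, **{b: getattr(row, f"{b}_2") for b in "ACGT"}})
        for het_row, hom_row, parent in ((r1, r2, "P1"), (r2, r1, "P2")):
            i_het, d_het, alt = snp_index(het_row)
            if np.isnan(i_het) or not (lo <= i_het <= hi) or d_het == 0:
                continue
            i_hom, d_hom, _ = snp_index(hom_row, alt=alt)
            if np.isnan(i_hom) or i_hom not in (0.0, 1.0) or d_hom == 0:
                continue
            informative = alt if i_hom == 0.0 else row.ref
            calls, depth = _f1_snp_calls((row.chrom, int(row.pos)), informative,
                                         f1_tables, min_hom_depth)
            if (calls != MISSING).sum() == 0:
                continue
            if not segregation_filter(calls, alpha):
                continue
            out.append(RadMarker(
                id=f"{row.chrom}:{int(row.pos)}:{parent}", scaffold=row.chrom,
                pos=int(row.pos), parent=parent, type="SNP", calls=calls,
                depth=depth))
            break
    return _thin(out, spacing_bp)


def select_pa_markers(pa_sites: pd.DataFrame, f1_depths: np.ndarray,
                      min_het_depth: int = 3, min_informative: int = 120,
                      spacing_bp: int = 10_000, alpha: float = 0.05) -> list[RadMarker]:
    """Presence/absence-type markers from tag-depth patterns.

    ``pa_sites`` has columns (scaffold, pos, parent) for positions aligned
    by tags of exactly one parent and heterozygous in that parent;
    ``f1_depths`` is (n_sites x n_f1). F1 calls: depth >= min_het_depth is
    het, depth 0 is hom, 1..min_het_depth-1 is missing. Markers with fewer
    than ``min_informative`` scored individuals are excluded ("less than
    120"), then the binomial filter and thinning apply.
    """
    out: list[RadMarker] = []
    for i, row in enumerate(pa_sites.itertuples(index=False)):
        d = f1_depths[i]
        calls = np.full(len(d), MISSING, dtype=np.int8)
        calls[d >= min_het_depth] = HET
        calls[d == 0] = HOM
        if (calls != MISSING).sum() < min_informative:
            continue
        if not segregation_filter(calls, alpha):
            continue
        out.append(RadMarker(
            id=f"{row.scaffold}:{int(row.pos)}:{row.parent}:PA",
            scaffold=row.scaffold, pos=int(row.pos), parent=row.parent,
            type="PA", calls=calls, depth=float(d[d > 0].mean() if (d > 0).any() else 0)))
    return _thin(out, spacing_bp)


# ---------------------------------------------------------------------------
# two-point statistics


def _lod(n_par: int, n_rec: int) -> float:
    n = n_par + n_rec
    if n == 0:
        return 0.0
    rf = n_rec / n
    lod = 0.0
    if n_par:  # rf < 1 whenever n_par > 0
        lod += n_par * math.log10(2 * (1 - rf))
    if n_rec:  # rf > 0 whenever n_rec > 0
        lod += n_rec * math.log10(2 * rf)
    return lod


def two_point(m1: RadMarker, m2: RadMarker) -> TwoPointStat:
    """Backcross-model two-point stat: rf = recombinants / informative.

    Het-het and hom-hom pairs score parental; missing calls are excluded
    pairwise. LOD = n_par*log10(2(1-rf)) + n_rec*log10(2*rf) with the
    zero-count terms dropped, so rf = 0 gives n*log10(2) and rf = 1 the
    mirrored value under flipped coding.
    """
    inf = (m1.calls != MISSING) & (m2.calls != MISSING)
    n = int(inf.sum())
    if n == 0:
        raise ValueError("no shared informative individuals")
    n_rec = int((m1.calls[inf] != m2.calls[inf]).sum())
    rf = n_rec / n
    return TwoPointStat(m1.id, m2.id, n, n_rec, rf, _lod(n - n_rec, n_rec))


def pairwise_rf_lod(markers: list[RadMarker]):
    """Vectorised rf / LOD / shared-informative matrices over all pairs."""
    M = np.stack([m.calls for m in markers])
    A = (M == HET).astype(np.float64)
    B = (M == HOM).astype(np.float64)
    V = (M != MISSING).astype(np.float64)
    n_inf = V @ V.T
    n_rec = A @ B.T + B @ A.T
    with np.errstate(divide="ignore", invalid="ignore"):
        rf = np.where(n_inf > 0, n_rec / np.maximum(n_inf, 1), np.nan)
        n_par = n_inf - n_rec
        lod = np.zeros_like(rf)
        lod += np.where(n_par > 0, n_par * np.log10(np.maximum(2 * (1 - rf), 1e-300)), 0.0)
        lod += np.where(n_rec > 0, n_rec * np.log10(np.maximum(2 * rf, 1e-300)), 0.0)
    return rf, lod, n_inf


# ---------------------------------------------------------------------------
# scaffold splitting


@dataclass
class ScaffoldPiece:
    scaffold: str
    piece_id: str
    start: int
    end: int
    markers: list[RadMarker]  # positions shifted to piece coordinates


def split_scaffolds(markers: list[RadMarker], scaffold_lengths: dict[str, int],
                    rf_threshold: float = 0.25,
                    mode: str = "adjacent") -> list[ScaffoldPiece]:
    """Cut scaffolds between marker pairs whose rf exceeds the threshold.

    ``mode="adjacent"``: scan consecutive markers in coordinate order; a
    cut at the integer midpoint of the first offending pair restarts the
    scan after the cut. ``mode="anchor"``: rf is measured against the
    first marker of the current piece instead.
    """
    by_scaffold: dict[str, list[RadMarker]] = {}
    for m in markers:
        by_scaffold.setdefault(m.scaffold, []).append(m)
    pieces: list[ScaffoldPiece] = []
    for scaffold, ms in by_scaffold.items():
        ms.sort(key=lambda m: m.pos)
        L = scaffold_lengths[scaffold]
        cuts: list[int] = []
        anchor = 0
        i = 0
        while i + 1 < len(ms):
            ref_i = anchor if mode == "anchor" else i
            stat = two_point(ms[ref_i], ms[i + 1])
            if stat.rf > rf_threshold:
                cuts.append((ms[i].pos + ms[i + 1].pos) // 2)
                anchor = i + 1
            i += 1
        bounds = [0] + cuts + [L]
        for pi, (a, b) in enumerate(zip(bounds[:-1], bounds[1:])):
            sub = [replace(m, pos=m.pos - a) for m in ms if a <= m.pos < b]
            pieces.append(ScaffoldPiece(scaffold, f"{scaffold}.{pi}", a, b, sub))
    return pieces


def flanking_markers(piece: ScaffoldPiece) -> list[RadMarker]:
    """The two outermost markers of a piece (fewer if it has < 3)."""
    ms = sorted(piece.markers, key=lambda m: m.pos)
    return ms if len(ms) <= 2 else [ms[0], ms[-1]]


# ---------------------------------------------------------------------------
# repulsion conversion


def _complement(calls: np.ndarray) -> np.ndarray:
    out = calls.copy()
    mask = out != MISSING
    out[mask] = 1 - out[mask]
    return out


def convert_repulsion(markers: list[RadMarker],
                      lod_schedule: tuple[float, ...] = (10, 5, 3)) -> list[RadMarker]:
    """Iteratively complement repulsion-phase markers to coupling.

    At each LOD threshold in the schedule, the largest coupling-connected
    component (edges: rf < 0.5, LOD >= threshold) anchors the phase; any
    marker with rf > 0.5 and flipped-coding LOD >= threshold against an
    anchor marker is complemented. Repeats until stable, then moves to the
    next (lower) threshold. Returns new marker objects.
    """
    ms = [replace(m, calls=m.calls.copy()) for m in markers]
    if len(ms) < 2:
        return ms
    for threshold in lod_schedule:
        while True:
            rf, lod, _ = pairwise_rf_lod(ms)
            n = len(ms)
            # coupling graph components, largest first, each anchors its phase
            parent = list(range(n))

            def find(x):
                while parent[x] != x:
                    parent[x] = parent[parent[x]]
                    x = parent[x]
                return x

            for i in range(n):
                for j in range(i + 1, n):
                    if rf[i, j] < 0.5 and lod[i, j] >= threshold:
                        parent[find(i)] = find(j)
            comps: dict[int, list[int]] = {}
            for i in range(n):
                comps.setdefault(find(i), []).append(i)
            flipped_lod = _flipped_lod(rf, lod, ms)
            to_flip = set()
            for anchor in sorted(comps.values(), key=len, reverse=True):
                aset = set(anchor)
                for i in range(n):
                    if i in aset or i in to_flip:
                        continue
                    for j in anchor:
                        if j in to_flip:
                            continue
                        if rf[i, j] > 0.5 and flipped_lod[i, j] >= threshold:
                            to_flip.add(i)
                            break
            if not to_flip:
                break
            for i in to_flip:
                ms[i] = replace(ms[i], calls=_complement(ms[i].calls),
                                phase="repulsion")
    for i, m in enumerate(ms):
        if m.phase == "unknown":
            ms[i] = replace(m, phase="coupling")
    return ms


def _flipped_lod(rf: np.ndarray, lod: np.ndarray, ms) -> np.ndarray:
    """LOD of each pair after complementing one member (rf -> 1 - rf)."""
    _, _, n_inf = pairwise_rf_lod(ms)
    n_rec_f = (1 - rf) * n_inf  # flipped recombinant count
    n_par_f = n_inf - n_rec_f
    rff = np.where(n_inf > 0, n_rec_f / np.maximum(n_inf, 1), np.nan)
    out = np.zeros_like(rf)
    out += np.where(n_par_f > 0, n_par_f * np.log10(np.maximum(2 * (1 - rff), 1e-300)), 0.0)
    out += np.where(n_rec_f > 0, n_rec_f * np.log10(np.maximum(2 * rff, 1e-300)), 0.0)
    return out


# ---------------------------------------------------------------------------
# grouping, ordering, map distance


def haldane_cm(rf: float) -> float:
    rf = min(rf, 0.4999999)
    return -50.0 * math.log(1 - 2 * rf)


def kosambi_cm(rf: float) -> float:
    rf = min(rf, 0.4999999)
    return 25.0 * math.log((1 + 2 * rf) / (1 - 2 * rf))


def build_groups_and_order(markers: list[RadMarker], lod_min: float = 3.0,
                           rf_max: float = 0.25, min_size: int = 3,
                           map_fn: str = "haldane") -> list[LinkageGroup]:
    """Single-linkage grouping then greedy seriation within groups.

    Edges join markers with LOD > lod_min and rf < rf_max; groups smaller
    than ``min_size`` are discarded. Within a group, chains are merged
    end-to-end by smallest endpoint rf; cM positions accumulate through
    the chosen map function.
    """
    fn = haldane_cm if map_fn == "haldane" else kosambi_cm
    n = len(markers)
    if n == 0:
        return []
    rf, lod, _ = pairwise_rf_lod(markers)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if lod[i, j] > lod_min and rf[i, j] < rf_max:
                parent[find(i)] = find(j)
    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)
    groups = []
    for gi, members in enumerate(sorted(comps.values(), key=len, reverse=True)):
        if len(members) < min_size:
            continue
        order = _greedy_order(members, rf)
        cm = [0.0]
        for a, b in zip(order[:-1], order[1:]):
            cm.append(cm[-1] + fn(rf[a, b]))
        groups.append(LinkageGroup(
            id=f"LG{gi + 1}",
            markers=[markers[i] for i in order], cm=cm))
    return groups


def _greedy_order(members: list[int], rf: np.ndarray) -> list[int]:
    """Merge chains at their closest endpoints until one path remains."""
    paths = [[m] for m in members]
    while len(paths) > 1:
        best = None
        for i in range(len(paths)):
            for j in range(i + 1, len(paths)):
                for ei in (0, -1):
                    for ej in (0, -1):
                        d = rf[paths[i][ei], paths[j][ej]]
                        if best is None or d < best[0]:
                            best = (d, i, j, ei, ej)
        _, i, j, ei, ej = best
        a = paths[i] if ei == -1 else paths[i][::-1]
        b = paths[j] if ej == 0 else paths[j][::-1]
        merged = a + b
        paths = [p for k, p in enumerate(paths) if k not in (i, j)] + [merged]
    return paths[0]


# ---------------------------------------------------------------------------
# map merging and pseudo-molecules


def merge_maps(map_p1: list[LinkageGroup], map_p2: list[LinkageGroup]) -> list[MergedChromosome]:
    """Pair LGs by shared scaffold count and interleave scaffold orders.

    Greedy pairing by descending shared count; ties prefer the
    lower-numbered P2 LG. The P1 scaffold order is the backbone; P2-only
    scaffolds are inserted after their nearest preceding shared scaffold
    in the P2 order. Unpaired LGs pass through. Chromosome ids follow the
    P1 numbering.
    """
    shared = {}
    for i, g1 in enumerate(map_p1):
        for j, g2 in enumerate(map_p2):
            shared[(i, j)] = len(set(g1.scaffolds) & set(g2.scaffolds))
    pairs = sorted(shared.items(), key=lambda kv: (-kv[1], kv[0][0], kv[0][1]))
    used1, used2, match = set(), set(), {}
    for (i, j), count in pairs:
        if count == 0 or i in used1 or j in used2:
            continue
        match[i] = j
        used1.add(i)
        used2.add(j)
    out: list[MergedChromosome] = []
    for i, g1 in enumerate(map_p1):
        order = list(g1.scaffolds)
        if i in match:
            g2 = map_p2[match[i]]
            shared_set = set(order) & set(g2.scaffolds)
            prev_shared = None
            for s in g2.scaffolds:
                if s in shared_set:
                    prev_shared = s
                elif s not in order:
                    if prev_shared is None:
                        order.insert(0, s)
                    else:
                        order.insert(order.index(prev_shared) + 1, s)
        orient = {s: o for s, o in _orientations(g1).items()}
        if i in match:
            for s, o in _orientations(map_p2[match[i]]).items():
                orient.setdefault(s, o)
        out.append(MergedChromosome(
            id=f"chr{i + 1:02d}", pieces=[(s, orient.get(s, "+")) for s in order]))
    for j, g2 in enumerate(map_p2):
        if j not in used2:
            out.append(MergedChromosome(
                id=f"chrP2_{j + 1:02d}",
                pieces=[(s, o) for s, o in _orientations(g2).items()]))
    return out


def _orientations(group: LinkageGroup) -> dict[str, str]:
    """Scaffold orientation from the bp-vs-cM trend of its markers."""
    by_scaffold: dict[str, list[tuple[int, float]]] = {}
    for m, c in zip(group.markers, group.cm):
        by_scaffold.setdefault(m.scaffold, []).append((m.pos, c))
    out = {}
    for s, pts in by_scaffold.items():
        if len(pts) < 2:
            out[s] = "+"
        else:
            pos, cm = zip(*pts)
            slope = np.polyfit(pos, cm, 1)[0] if len(set(pos)) > 1 else 0.0
            out[s] = "-" if slope < 0 else "+"
    return out


def build_pseudomolecules(merged: list[MergedChromosome],
                          scaffold_seqs: dict[str, str],
                          gap_n: int = 1000):
    """Concatenate oriented scaffold pieces with N-gaps; emit an AGP table.

    Returns (sequences, placement DataFrame). Placement coordinates are
    1-based inclusive, AGP style.
    """
    seqs: dict[str, str] = {}
    rows = []
    for chrom in merged:
        parts: list[str] = []
        cursor = 0
        part_no = 0
        for k, (scaffold, orient) in enumerate(chrom.pieces):
            if scaffold not in scaffold_seqs:
                raise KeyError(f"missing sequence for scaffold {scaffold}")
            if k > 0 and gap_n > 0:
                part_no += 1
                rows.append((chrom.id, cursor + 1, cursor + gap_n, part_no,
                             "N", "gap", 1, gap_n, "+"))
                parts.append("N" * gap_n)
                cursor += gap_n
            s = scaffold_seqs[scaffold]
            if orient == "-":
                s = revcomp(s)
            part_no += 1
            rows.append((chrom.id, cursor + 1, cursor + len(s), part_no,
                         "W", scaffold, 1, len(s), orient))
            parts.append(s)
            cursor += len(s)
        seqs[chrom.id] = "".join(parts)
    agp = pd.DataFrame(rows, columns=["object", "object_beg", "object_end",
                                      "part_number", "component_type",
                                      "component_id", "component_beg",
                                      "component_end", "orientation"])
    return seqs, agp
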