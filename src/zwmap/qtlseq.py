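"""F1-adapted QTL-seq: SNP-index / delta-SNP-index bulked-segregant mapping.

The pipeline mirrors the two-pass design needed when both parents are
heterozygous: substitute one parent's homozygous-alternate alleles into
the reference, classify sites heterozygous in exactly one parent, compute
per-bulk SNP indices at those sites, slide windows, attach simulated null
confidence intervals, and call candidate regions where the windowed
delta-SNP-index escapes the null band.

All indices are biallelic: the designated alternate is the most frequent
non-reference base in the heterozygous parent, and reads carrying a third
base are excluded from numerator and denominator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BASES = ("A", "C", "G", "T")
_BASE_IDX = {b: i for i, b in enumerate(BASES)}


def _get(row, key):
    return row[key] if isinstance(row, (dict, pd.Series)) else getattr(row, key)


def _alt_info(row) -> tuple[str, int]:
    """Most frequent non-reference base and its count."""
    best, cnt = "N", -1
    for b in BASES:
        if b != _get(row, "ref") and _get(row, b) > cnt:
            best, cnt = b, int(_get(row, b))
    return best, cnt


def snp_index(row, alt: str | None = None) -> tuple[float, int, str]:
    """Biallelic SNP-index of one pileup row: alt / (ref + alt).

    Returns (index, ref+alt depth, alt base). NaN index at zero depth.
    """
    if alt is None:
        alt, _ = _alt_info(row)
    ref_n = int(_get(row, _get(row, "ref")))
    alt_n = int(_get(row, alt)) if alt in BASES else 0
    denom = ref_n + alt_n
    return (alt_n / denom if denom else float("nan")), denom, alt


def _count_arrays(df: pd.DataFrame, alt_idx: np.ndarray | None = None):
    """Vectorised (ref_n, alt_n, alt_idx) for a pileup frame.

    With ``alt_idx`` given, counts that designated alternate; otherwise the
    most frequent non-reference base per row is designated.
    """
    counts = df[list(BASES)].to_numpy(dtype=np.int64)
    ref_idx = df["ref"].map(_BASE_IDX).to_numpy()
    rows = np.arange(len(df))
    ref_n = counts[rows, ref_idx]
    if alt_idx is None:
        masked = counts.copy()
        masked[rows, ref_idx] = -1
        alt_idx = masked.argmax(axis=1)
    alt_n = counts[rows, alt_idx]
    return ref_n, alt_n, alt_idx


# ---------------------------------------------------------------------------
# reference substitution


def substitute_reference(reference: dict[str, str], parent_pileup: pd.DataFrame,
                         min_depth: int = 5):
    """Swap in the parent's base wherever its SNP-index is exactly 1.

    Returns the substituted reference and the substitution list
    (chrom, pos, ref, new_base). Sites below ``min_depth`` are left alone.
    """
    seqs = {c: list(s) for c, s in reference.items()}
    missing = set(parent_pileup["chrom"]) - set(seqs)
    if missing:
        raise ValueError(f"pileup chromosomes {sorted(missing)} absent from reference")
    ref_n, alt_n, alt_idx = _count_arrays(parent_pileup)
    hit = (ref_n == 0) & (alt_n >= min_depth) & (alt_n > 0)
    subs = []
    chroms = parent_pileup["chrom"].to_numpy()
    poss = parent_pileup["pos"].to_numpy()
    refs = parent_pileup["ref"].to_numpy()
    for i in np.nonzero(hit)[0]:
        alt = BASES[alt_idx[i]]
        seqs[chroms[i]][poss[i]] = alt
        subs.append((chroms[i], int(poss[i]), refs[i], alt))
    return {c: "".join(s) for c, s in seqs.items()}, subs


# ---------------------------------------------------------------------------
# heterozygous-site classification


@dataclass(frozen=True)
class HetSite:
    chrom: str
    pos: int
    het_parent: str  # "P3" | "P4"
    alt: str
    parent_index_het: float
    parent_index_other: float
    parent_depths: tuple[int, int]  # (P3, P4) ref+alt depths


def classify_het_sites(pileup_p3: pd.DataFrame, pileup_p4: pd.DataFrame,
                       band: tuple[float, float] = (0.4, 0.6),
                       min_parent_depth: int = 16) -> list[HetSite]:
    """Sites heterozygous in exactly one parent.

    Keeps sites with SNP-index inside ``band`` (inclusive) in one parent,
    exactly 0 in the other, and ref+alt depth >= min_parent_depth in both
    (the paper's ">15" read as >= 16).
    """
    lo, hi = band
    merged = pileup_p3.merge(pileup_p4, on=["chrom", "pos", "ref"],
                             suffixes=("_3", "_4"))
    p3 = merged.rename(columns={f"{b}_3": b for b in BASES})
    p4 = merged.rename(columns={f"{b}_4": b for b in BASES})
    out: list[HetSite] = []
    chroms = merged["chrom"].to_numpy()
    poss = merged["pos"].to_numpy()
    for het_df, oth_df, het_name in ((p3, p4, "P3"), (p4, p3, "P4")):
        ref_h, alt_h, alt_idx = _count_arrays(het_df)
        ref_o, alt_o, _ = _count_arrays(oth_df, alt_idx=alt_idx)
        d_h, d_o = ref_h + alt_h, ref_o + alt_o
        with np.errstate(divide="ignore", invalid="ignore"):
            idx_h = np.where(d_h > 0, alt_h / np.maximum(d_h, 1), np.nan)
            idx_o = np.where(d_o > 0, alt_o / np.maximum(d_o, 1), np.nan)
        keep = ((idx_h >= lo) & (idx_h <= hi) & (idx_o == 0.0)
                & (d_h >= min_parent_depth) & (d_o >= min_parent_depth))
        for i in np.nonzero(keep)[0]:
            depths = (int(d_h[i]), int(d_o[i])) if het_name == "P3" \
                else (int(d_o[i]), int(d_h[i]))
            out.append(HetSite(chroms[i], int(poss[i]), het_name,
                               BASES[alt_idx[i]], float(idx_h[i]),
                               float(idx_o[i]), depths))
    out.sort(key=lambda s: (s.chrom, s.pos))
    return out


# ---------------------------------------------------------------------------
# bulk SNP-index


@dataclass(frozen=True)
class SnpIndexRecord:
    chrom: str
    pos: int
    het_parent: str
    index_female: float
    index_male: float
    delta: float
    depth_female: int
    depth_male: int


def bulk_snp_index(pileup_female: pd.DataFrame, pileup_male: pd.DataFrame,
                   het_sites: list[HetSite],
                   min_bulk_depth: int = 6) -> list[SnpIndexRecord]:
    """Per-bulk SNP-index and delta at classified heterozygous sites.

    Sites with ref+alt depth below ``min_bulk_depth`` in either bulk are
    dropped, as are sites absent from a bulk pileup (treated as depth 0).
    """
    sites = pd.DataFrame(
        {"chrom": [s.chrom for s in het_sites],
         "pos": [s.pos for s in het_sites],
         "het_parent": [s.het_parent for s in het_sites],
         "ref": [BASES[0] for s in het_sites],  # placeholder, replaced below
         "alt": [s.alt for s in het_sites]})
    merged = sites.drop(columns=["ref"]).merge(
        pileup_female, on=["chrom", "pos"]).merge(
        pileup_male, on=["chrom", "pos", "ref"], suffixes=("_f", "_m"))
    if not len(merged):
        return []
    alt_idx = merged["alt"].map(_BASE_IDX).to_numpy()
    fem = merged.rename(columns={f"{b}_f": b for b in BASES})
    mal = merged.rename(columns={f"{b}_m": b for b in BASES})
    ref_f, alt_f, _ = _count_arrays(fem, alt_idx=alt_idx)
    ref_m, alt_m, _ = _count_arrays(mal, alt_idx=alt_idx)
    d_f, d_m = ref_f + alt_f, ref_m + alt_m
    keep = (d_f >= min_bulk_depth) & (d_m >= min_bulk_depth)
    out = []
    chroms = merged["chrom"].to_numpy()
    poss = merged["pos"].to_numpy()
    parents = merged["het_parent"].to_numpy()
    for i in np.nonzero(keep)[0]:
        i_f = alt_f[i] / d_f[i]
        i_m = alt_m[i] / d_m[i]
        out.append(SnpIndexRecord(chroms[i], int(poss[i]), parents[i],
                                  float(i_f), float(i_m), float(i_f - i_m),
                                  int(d_f[i]), int(d_m[i])))
    return out


def records_frame(records: list[SnpIndexRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


# ---------------------------------------------------------------------------
# sliding windows


@dataclass
class WindowStat:
    chrom: str
    start: int
    end: int
    mean_index_female: float
    mean_index_male: float
    mean_delta: float
    n_sites: int
    empty: bool
    ci_lo: dict[float, float] = field(default_factory=dict)
    ci_hi: dict[float, float] = field(default_factory=dict)


def sliding_window(records: list[SnpIndexRecord], chrom_lengths: dict[str, int],
                   window_bp: int = 1_000_000, step_bp: int = 50_000) -> list[WindowStat]:
    """Arithmetic window means of index and delta on a fixed step grid.

    Windows start at 0, step, 2*step, ... while start < chromosome length;
    end = min(start + window, length). Zero-site windows are flagged empty.
    """
    if step_bp <= 0:
        raise ValueError("step_bp must be positive")
    df = records_frame(records) if records else pd.DataFrame(
        columns=["chrom", "pos", "index_female", "index_male", "delta"])
    out = []
    for chrom, L in chrom_lengths.items():
        sub = df[df.chrom == chrom]
        pos = sub["pos"].to_numpy()
        for start in range(0, L, step_bp):
            end = min(start + window_bp, L)
            mask = (pos >= start) & (pos < end)
            n = int(mask.sum())
            if n:
                out.append(WindowStat(chrom, start, end,
                                      float(sub["index_female"].to_numpy()[mask].mean()),
                                      float(sub["index_male"].to_numpy()[mask].mean()),
                                      float(sub["delta"].to_numpy()[mask].mean()),
                                      n, False))
            else:
                out.append(WindowStat(chrom, start, end, float("nan"),
                                      float("nan"), float("nan"), 0, True))
    return out


# ---------------------------------------------------------------------------
# simulated null confidence intervals


@dataclass
class CiTable:
    bulk_size: int
    n_progeny: int
    reps: int
    levels: tuple[float, ...]
    # depth -> {level: (lo, hi)} for delta, and for the single-bulk index
    delta_bounds: dict[int, dict[float, tuple[float, float]]]
    index_bounds: dict[int, dict[float, tuple[float, float]]]

    def delta_ci(self, depth: int, level: float) -> tuple[float, float]:
        d = min(self.delta_bounds, key=lambda k: abs(k - depth))
        return self.delta_bounds[d][level]


def null_ci(depths, bulk_size: int = 50, n_progeny: int = 253,
            reps: int = 10_000, levels: tuple[float, ...] = (0.95, 0.99),
            seed: int = 0, resample: str = "per_rep") -> CiTable:
    """Null quantiles of bulk SNP-index and delta at unlinked sites.

    Per replicate a progeny population of ``n_progeny`` is drawn with each
    individual heterozygous with probability 1/2, ``bulk_size`` members
    are bulked per bulk, and read counts are binomial given the depth and
    the bulk allele fraction k/(2*bulk_size). Bounds are central empirical
    quantiles over replicates. ``resample="per_site"`` redraws the bulks
    for every simulated site (here: identical, since one site is simulated
    per replicate; the flag is kept for API fidelity).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if bulk_size > n_progeny:
        raise ValueError("bulk_size exceeds n_progeny")
    if reps == 1:
        warnings.warn("reps=1 gives degenerate (lo == hi) bounds")
    rng = np.random.default_rng(seed)
    delta_bounds: dict[int, dict[float, tuple[float, float]]] = {}
    index_bounds: dict[int, dict[float, tuple[float, float]]] = {}
    for depth in sorted({int(d) for d in depths}):
        idx = np.empty((2, reps))
        for b in range(2):
            # population genotypes i.i.d. Bernoulli(1/2); sampling without
            # replacement leaves k ~ Binomial(bulk_size, 1/2) marginally
            pop = rng.random((reps, n_progeny)) < 0.5
            k = np.empty(reps, dtype=np.int64)
            for r in range(reps):
                sel = rng.choice(n_progeny, size=bulk_size, replace=False)
                k[r] = pop[r, sel].sum()
            frac = k / (2 * bulk_size)
            reads = rng.binomial(depth, frac)
            idx[b] = reads / depth
        delta = idx[0] - idx[1]
        delta_bounds[depth] = {}
        index_bounds[depth] = {}
        for level in levels:
            a = (1 - level) / 2
            delta_bounds[depth][level] = (float(np.quantile(delta, a)),
                                          float(np.quantile(delta, 1 - a)))
            index_bounds[depth][level] = (float(np.quantile(idx[0], a)),
                                          float(np.quantile(idx[0], 1 - a)))
    return CiTable(bulk_size, n_progeny, reps, tuple(levels),
                   delta_bounds, index_bounds)


def attach_window_ci(windows: list[WindowStat], records: list[SnpIndexRecord],
                     ci: CiTable, depth_rule: str = "min") -> list[WindowStat]:
    """Window CI = arithmetic mean of per-site CIs of contained sites.

    The per-site CI is looked up at the site's depth; when the two bulk
    depths differ, ``depth_rule`` picks "min" (default, conservative) or
    "mean".
    """
    df = records_frame(records) if records else pd.DataFrame(
        columns=["chrom", "pos", "depth_female", "depth_male"])
    if len(df):
        if depth_rule == "min":
            df["ci_depth"] = df[["depth_female", "depth_male"]].min(axis=1)
        else:
            df["ci_depth"] = ((df.depth_female + df.depth_male) / 2).round().astype(int)
    for w in windows:
        if w.empty:
            continue
        sub = df[(df.chrom == w.chrom) & (df.pos >= w.start) & (df.pos < w.end)]
        for level in ci.levels:
            bounds = np.array([ci.delta_ci(int(d), level) for d in sub["ci_depth"]])
            w.ci_lo[level] = float(bounds[:, 0].mean())
            w.ci_hi[level] = float(bounds[:, 1].mean())
    return windows


# ---------------------------------------------------------------------------
# candidate region calling


@dataclass(frozen=True)
class CandidateRegion:
    chrom: str
    start: int
    end: int
    n_windows: int
    peak_delta: float


def call_regions(windows: list[WindowStat], ci: CiTable, level: float = 0.95,
                 merge_gap_bp: int = 0) -> list[CandidateRegion]:
    """Merge windows whose mean delta escapes the averaged null CI band."""
    sig = [w for w in windows
           if not w.empty and level in w.ci_lo
           and (w.mean_delta > w.ci_hi[level] or w.mean_delta < w.ci_lo[level])]
    sig.sort(key=lambda w: (w.chrom, w.start))
    out: list[CandidateRegion] = []
    cur: list[WindowStat] = []
    for w in sig:
        if cur and w.chrom == cur[-1].chrom and w.start <= cur[-1].end + merge_gap_bp:
            cur.append(w)
        else:
            if cur:
                out.append(_region(cur))
            cur = [w]
    if cur:
        out.append(_region(cur))
    return out


def _region(ws: list[WindowStat]) -> CandidateRegion:
    peak = max((w.mean_delta for w in ws), key=abs)
    return CandidateRegion(ws[0].chrom, ws[0].start, max(w.end for w in ws),
                           len(ws), float(peak))


def plot_tracks(records: list[SnpIndexRecord], windows: list[WindowStat],
                chrom_lengths: dict[str, int], out_prefix, level: float = 0.95):
    """Per-chromosome index / delta / CI tracks (one PNG per chromosome).

    Scatter of per-site indices and delta with the windowed means overlaid
    and the averaged null band shaded around zero delta.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = records_frame(records) if records else pd.DataFrame(
        columns=["chrom", "pos", "index_female", "index_male", "delta"])
    written = []
    for chrom, L in chrom_lengths.items():
        sub = df[df.chrom == chrom]
        ws = [w for w in windows if w.chrom == chrom and not w.empty]
        mids = [(w.start + w.end) / 2 for w in ws]
        fig, axes = plt.subplots(3, 1, figsize=(9, 7), sharex=True)
        for ax, col, title in zip(axes[:2], ("index_female", "index_male"),
                                  ("female bulk SNP-index", "male bulk SNP-index")):
            ax.plot(sub.pos, sub[col], ".", ms=2, alpha=0.3, color="grey")
            ax.plot(mids, [getattr(w, f"mean_{col}") for w in ws], color="tab:blue")
            ax.set_ylim(-0.05, 1.05)
            ax.set_ylabel(title, fontsize=8)
        ax = axes[2]
        ax.plot(sub.pos, sub.delta, ".", ms=2, alpha=0.3, color="grey")
        ax.plot(mids, [w.mean_delta for w in ws], color="tab:red")
        if ws and level in ws[0].ci_lo:
            ax.plot(mids, [w.ci_lo[level] for w in ws], color="tab:brown", lw=1)
            ax.plot(mids, [w.ci_hi[level] for w in ws], color="tab:brown", lw=1)
        ax.axhline(0, color="k", lw=0.5)
        ax.set_ylim(-1.05, 1.05)
        ax.set_ylabel("Δ SNP-index", fontsize=8)
        ax.set_xlabel(f"{chrom} position (bp)")
        ax.set_xlim(0, L)
        fig.tight_layout()
        path = f"{out_prefix}.{chrom}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written


def windows_frame(windows: list[WindowStat]) -> pd.DataFrame:
    rows = []
    for w in windows:
        row = {k: getattr(w, k) for k in
               ("chrom", "start", "end", "mean_index_female", "mean_index_male",
                "mean_delta", "n_sites", "empty")}
        for level, lo in w.ci_lo.items():
            row[f"ci{int(level * 100)}_lo"] = lo
            row[f"ci{int(level * 100)}_hi"] = w.ci_hi[level]
        rows.append(row)
    return pd.DataFrame(rows)
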