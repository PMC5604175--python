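"""Synthetic dioecious cross simulator.

Generates two highly heterozygous parents (a ZW female carrying a
female-specific W insertion and a ZZ male), an F1 population with labile
ZW sex expression, phenotype-selected bulks, per-site pileup tables,
shotgun reads and RAD tags — together with a truth table that records
every simulated variant and the exact W-insertion interval, so downstream
callers can be scored against known ground truth.

Coordinates are 0-based half-open throughout. Haplotypes are stored
sparsely as substitutions against a shared reference backbone plus an
optional inserted segment; sequence realisation is explicit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(BASES)}
_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# configuration and domain types


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the simulated cross.

    ``lability`` is (eps, mu, nu): the probabilities that a ZW individual
    expresses male / monoecious / non-flowering phenotype instead of
    female. ZZ individuals are deterministically male.
    """

    chrom_lengths: tuple[int, ...] = (1_000_000,)
    het_rate_p3: float = 0.002
    het_rate_p4: float = 0.002
    shared_snp_rate: float = 0.0005
    w_insert_len: int = 20_000
    w_locus: tuple[str, int] = ("chr01", 500_000)
    n_f1: int = 253
    bulk_size: int = 50
    depth: float = 13.0
    read_len: int = 100
    error_rate: float = 0.0
    xover_rate: float = 1.0
    lability: tuple[float, float, float] = (0.0, 0.0, 0.0)
    seed: int = 0
    # Z/W divergence flanking the insertion (see w-linked flag in TruthTable)
    w_flank_bp: int = 0
    w_flank_het_rate: float = 0.0

    def __post_init__(self):
        for name in ("het_rate_p3", "het_rate_p4", "shared_snp_rate", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        eps, mu, nu = self.lability
        if min(eps, mu, nu) < 0 or eps + mu + nu > 1.0:
            raise ValueError("lability probabilities must be >= 0 and sum to <= 1")
        if self.bulk_size > self.n_f1:
            raise ValueError("bulk_size exceeds n_f1")
        if any(L <= 0 for L in self.chrom_lengths):
            raise ValueError("zero-length chromosome")
        chrom, pos = self.w_locus
        if chrom not in self.chrom_names:
            raise ValueError(f"w_locus chromosome {chrom!r} not among chromosomes")
        if not 0 <= pos <= self.chrom_lengths[self.chrom_names.index(chrom)]:
            raise ValueError("w_locus outside its chromosome")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1:02d}" for i in range(len(self.chrom_lengths))]

    def chrom_len(self, chrom: str) -> int:
        return self.chrom_lengths[self.chrom_names.index(chrom)]


@dataclass
class Haplotype:
    """Sparse haplotype: substitutions vs the reference + optional insert."""

    variants: dict[str, dict[int, str]] = field(default_factory=dict)
    insert: tuple[str, int, str] | None = None  # (chrom, ref_pos, sequence)

    def base_at(self, chrom: str, pos: int, ref_base: str) -> str:
        return self.variants.get(chrom, {}).get(pos, ref_base)

    def realize(self, reference: Mapping[str, str]) -> dict[str, str]:
        out = {}
        for chrom, ref in reference.items():
            seq = list(ref)
            for pos, base in self.variants.get(chrom, {}).items():
                seq[pos] = base
            if self.insert is not None and self.insert[0] == chrom:
                _, at, ins = self.insert
                seq[at:at] = list(ins)
            out[chrom] = "".join(seq)
        return out


@dataclass
class ParentGenome:
    name: str
    haplotypes: tuple[Haplotype, Haplotype]
    sex_genotype: str  # "ZZ" | "ZW"
    w_segment: tuple[str, int, int] | None = None  # W-haplotype coordinates

    def __post_init__(self):
        carriers = sum(h.insert is not None for h in self.haplotypes)
        if self.sex_genotype == "ZW" and self.w_segment is not None and carriers != 1:
            raise ValueError("ZW parent must carry the W segment on exactly one haplotype")
        if self.sex_genotype == "ZZ" and carriers:
            raise ValueError("ZZ parent cannot carry a W segment")


@dataclass
class F1Individual:
    name: str
    haplotypes: tuple[Haplotype, Haplotype]  # (maternal, paternal)
    sex_genotype: str  # "ZZ" | "ZW"
    phenotype: str  # male | female | monoecious | nonflowering
    # per-parent gamete mosaics: chrom -> (start_hap, breakpoints); the
    # transmitted haplotype at position p is start_hap XOR (#breakpoints <= p) % 2
    gametes: dict[str, dict[str, tuple[int, tuple[int, ...]]]] = field(default_factory=dict)

    def gamete_source(self, parent: str, chrom: str, pos: int) -> int:
        start, breaks = self.gametes[parent][chrom]
        return (start + int(np.searchsorted(np.asarray(breaks), pos, side="right"))) % 2


@dataclass
class TruthTable:
    """Ground truth for one simulated cross.

    ``variants`` columns: chrom, pos (0-based, reference coords), ref, alt,
    category (p3het | p4het | shared), w_linked (bool). ``w_interval`` is
    the inserted segment in W-haplotype coordinates. ``reference`` is the
    shared backbone the parents were derived from (the analog of the
    assembled reference genome).
    """

    variants: pd.DataFrame
    w_interval: tuple[str, int, int] | None
    reference: dict[str, str]

    def sites(self, category: str | None = None, w_linked: bool | None = None) -> pd.DataFrame:
        df = self.variants
        if category is not None:
            df = df[df.category == category]
        if w_linked is not None:
            df = df[df.w_linked == w_linked]
        return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# parent simulation


_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq(L: int, rng: np.random.Generator) -> str:
    return _BASE_BYTES[rng.integers(0, 4, size=L)].tobytes().decode()


def _random_reference(cfg: SimConfig, rng: np.random.Generator) -> dict[str, str]:
    return {name: _random_seq(L, rng)
            for name, L in zip(cfg.chrom_names, cfg.chrom_lengths)}


def _other_base(ref_base: str, rng: np.random.Generator) -> str:
    choices = [b for b in BASES if b != ref_base]
    return choices[rng.integers(0, 3)]


def simulate_parents(cfg: SimConfig, rng: np.random.Generator | None = None):
    """Build the ZW female (P3 analog), ZZ male (P4 analog) and truth table.

    Per-bp independent draws assign each position at most one variant
    category (p3het / p4het / shared); within the configured flank of the
    W locus additional female-heterozygous sites are placed with their
    alternate allele on the W haplotype and flagged ``w_linked``. The
    female parent carries a random insert of ``w_insert_len`` bases at
    ``w_locus`` on haplotype 1 (the W haplotype).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    reference = _random_reference(cfg, rng)

    p3_haps = (Haplotype(), Haplotype())
    p4_haps = (Haplotype(), Haplotype())
    for h in (*p3_haps, *p4_haps):
        h.variants = {c: {} for c in cfg.chrom_names}

    rows: list[tuple] = []
    w_chrom, w_pos = cfg.w_locus
    r3, r4, rs = cfg.het_rate_p3, cfg.het_rate_p4, cfg.shared_snp_rate
    for chrom, L in zip(cfg.chrom_names, cfg.chrom_lengths):
        u = rng.random(L)
        cat = np.full(L, -1, dtype=np.int8)
        cat[u < r3] = 0
        cat[(u >= r3) & (u < r3 + r4)] = 1
        cat[(u >= r3 + r4) & (u < r3 + r4 + rs)] = 2
        if chrom == w_chrom and cfg.w_flank_bp > 0 and cfg.w_flank_het_rate > 0:
            lo = max(0, w_pos - cfg.w_flank_bp)
            hi = min(L, w_pos + cfg.w_flank_bp)
            flank = rng.random(hi - lo) < cfg.w_flank_het_rate
            idx = np.nonzero(flank)[0] + lo
            cat[idx[cat[idx] == -1]] = 3
        for pos in np.nonzero(cat >= 0)[0]:
            pos = int(pos)
            ref_base = reference[chrom][pos]
            alt = _other_base(ref_base, rng)
            c = cat[pos]
            if c == 0:  # het in P3, hom-ref in P4
                p3_haps[rng.integers(0, 2)].variants[chrom][pos] = alt
                rows.append((chrom, pos, ref_base, alt, "p3het", False))
            elif c == 1:  # het in P4, hom-ref in P3
                p4_haps[rng.integers(0, 2)].variants[chrom][pos] = alt
                rows.append((chrom, pos, ref_base, alt, "p4het", False))
            elif c == 2:  # shared: both parents homozygous for the alternate
                for h in (*p3_haps, *p4_haps):
                    h.variants[chrom][pos] = alt
                rows.append((chrom, pos, ref_base, alt, "shared", False))
            else:  # W-linked divergence: alt rides the W haplotype of P3
                p3_haps[1].variants[chrom][pos] = alt
                rows.append((chrom, pos, ref_base, alt, "p3het", True))

    w_interval = None
    w_segment = None
    if cfg.w_insert_len > 0:
        ins = _random_seq(cfg.w_insert_len, rng)
        p3_haps[1].insert = (w_chrom, w_pos, ins)
        w_interval = (w_chrom, w_pos, w_pos + cfg.w_insert_len)
        w_segment = w_interval

    variants = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "category", "w_linked"])
    truth = TruthTable(variants=variants, w_interval=w_interval, reference=reference)
    p3 = ParentGenome("P3", p3_haps, "ZW", w_segment=w_segment)
    p4 = ParentGenome("P4", p4_haps, "ZZ")
    return p3, p4, truth


# ---------------------------------------------------------------------------
# meiosis and the F1 population


def _variant_arrays(parent: ParentGenome, chrom_names):
    """Per-haplotype sorted (positions, bases) arrays, cached on the parent."""
    cache = getattr(parent, "_varr", None)
    if cache is not None:
        return cache
    cache = []
    for hap in parent.haplotypes:
        per_chrom = {}
        for chrom in chrom_names:
            items = sorted(hap.variants.get(chrom, {}).items())
            pos = np.fromiter((p for p, _ in items), dtype=np.int64, count=len(items))
            bases = np.array([b for _, b in items], dtype="U1")
            per_chrom[chrom] = (pos, bases)
        cache.append(per_chrom)
    parent._varr = cache  # type: ignore[attr-defined]
    return cache


def _gamete(parent: ParentGenome, cfg: SimConfig, rng: np.random.Generator):
    """One meiotic product: a mosaic haplotype plus its breakpoint record."""
    hap = Haplotype(variants={})
    mosaic: dict[str, tuple[int, tuple[int, ...]]] = {}
    varr = _variant_arrays(parent, cfg.chrom_names)
    for chrom, L in zip(cfg.chrom_names, cfg.chrom_lengths):
        n_xo = rng.poisson(cfg.xover_rate)
        breaks = tuple(sorted(int(b) for b in rng.integers(1, L, size=n_xo))) if n_xo else ()
        start = int(rng.integers(0, 2))
        mosaic[chrom] = (start, breaks)
        barr = np.asarray(breaks, dtype=np.int64)
        merged: dict[int, str] = {}
        for src in (0, 1):
            pos, bases = varr[src][chrom]
            if len(pos):
                seg = (start + np.searchsorted(barr, pos, side="right")) % 2
                sel = seg == src
                merged.update(zip(pos[sel].tolist(), bases[sel].tolist()))
        hap.variants[chrom] = merged
        for src in (0, 1):
            cand = parent.haplotypes[src].insert
            if cand is not None and cand[0] == chrom:
                seg = (start + int(np.searchsorted(barr, cand[1], side="right"))) % 2
                if seg == src:
                    hap.insert = cand
    return hap, mosaic


def cross_f1(p3: ParentGenome, p4: ParentGenome, cfg: SimConfig,
             rng: np.random.Generator | None = None) -> list[F1Individual]:
    """Cross a ZW parent with a ZZ parent: n_f1 progeny with labile sex.

    Meiosis draws Poisson(xover_rate) crossovers per chromosome at uniform
    positions without interference. The transmitted maternal haplotype at
    the W locus decides ZW vs ZZ; phenotype follows the lability model
    (ZZ deterministically male).
    """
    if {p3.sex_genotype, p4.sex_genotype} != {"ZW", "ZZ"}:
        raise ValueError("cross requires one ZW and one ZZ parent")
    mother, father = (p3, p4) if p3.sex_genotype == "ZW" else (p4, p3)
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    eps, mu, nu = cfg.lability
    w_chrom, w_pos = cfg.w_locus
    out = []
    for i in range(cfg.n_f1):
        mat, mat_mosaic = _gamete(mother, cfg, rng)
        pat, pat_mosaic = _gamete(father, cfg, rng)
        start, breaks = mat_mosaic[w_chrom]
        src = (start + int(np.searchsorted(np.asarray(breaks), w_pos, side="right"))) % 2
        sex = "ZW" if src == 1 else "ZZ"  # maternal haplotype 1 is W
        if sex == "ZZ":
            phenotype = "male"
        else:
            u = rng.random()
            if u < eps:
                phenotype = "male"
            elif u < eps + mu:
                phenotype = "monoecious"
            elif u < eps + mu + nu:
                phenotype = "nonflowering"
            else:
                phenotype = "female"
        out.append(F1Individual(
            name=f"F1_{i:04d}", haplotypes=(mat, pat), sex_genotype=sex,
            phenotype=phenotype,
            gametes={"maternal": mat_mosaic, "paternal": pat_mosaic}))
    return out


def select_bulk(f1: Sequence[F1Individual], phenotype: str, size: int,
                rng: np.random.Generator) -> list[F1Individual]:
    pool = [ind for ind in f1 if ind.phenotype == phenotype]
    if len(pool) < size:
        raise ValueError(f"only {len(pool)} {phenotype} individuals for a bulk of {size}")
    idx = rng.choice(len(pool), size=size, replace=False)
    return [pool[int(i)] for i in idx]


# ---------------------------------------------------------------------------
# pileup and read sampling


def sample_bulk_pileup(bulk: Sequence[F1Individual | ParentGenome],
                       truth: TruthTable, cfg: SimConfig,
                       rng: np.random.Generator,
                       sites: pd.DataFrame | None = None,
                       sample: str = "bulk") -> pd.DataFrame:
    """Per-site allele counts a read aligner would yield at variant sites.

    At each site, depth ~ Poisson(cfg.depth); every read is drawn from a
    uniformly random member's uniformly random haplotype and its base is
    flipped to a uniformly random other base with probability error_rate.
    """
    if not bulk:
        raise ValueError("empty bulk")
    if sites is None:
        sites = truth.variants
    sites = sites.reset_index(drop=True)
    n_site = len(sites)
    haps = [h for member in bulk for h in member.haplotypes]
    n_hap = len(haps)

    # allele matrix: site x haplotype base index
    allele = np.empty((n_site, n_hap), dtype=np.int8)
    chroms = sites["chrom"].to_numpy()
    poss = sites["pos"].to_numpy()
    refs = sites["ref"].to_numpy()
    for j, hap in enumerate(haps):
        col = np.fromiter((_BASE_IDX[r] for r in refs), dtype=np.int8, count=n_site)
        for i in range(n_site):
            v = hap.variants.get(chroms[i])
            if v:
                b = v.get(int(poss[i]))
                if b is not None:
                    col[i] = _BASE_IDX[b]
        allele[:, j] = col

    depths = rng.poisson(cfg.depth, size=n_site)
    total = int(depths.sum())
    site_idx = np.repeat(np.arange(n_site), depths)
    hap_idx = rng.integers(0, n_hap, size=total)
    bases = allele[site_idx, hap_idx]
    if cfg.error_rate > 0 and total:
        err = rng.random(total) < cfg.error_rate
        shift = rng.integers(1, 4, size=int(err.sum()))
        bases[err] = (bases[err] + shift) % 4

    counts = np.zeros((n_site, 4), dtype=np.int64)
    np.add.at(counts, (site_idx, bases), 1)
    df = pd.DataFrame({
        "chrom": chroms, "pos": poss, "ref": refs,
        "A": counts[:, 0], "C": counts[:, 1], "G": counts[:, 2], "T": counts[:, 3],
        "depth": depths, "sample": sample,
    })
    return df


def sample_reads(seqs: Mapping[str, str], cfg: SimConfig, rng: np.random.Generator,
                 haploid_len: int | None = None, prefix: str = "r") -> list[tuple[str, str]]:
    """Uniform fixed-length shotgun reads from a set of sequences.

    The emitted read count is Poisson with mean depth x L / read_len where
    L is ``haploid_len`` if given (so that pooled multi-haplotype sources
    can be sequenced to a per-locus total depth) else the summed source
    length. Reads come off either strand with probability 1/2.
    """
    names = list(seqs)
    lens = np.array([len(seqs[n]) for n in names])
    if (lens < cfg.read_len).any():
        raise ValueError("read_len exceeds a source sequence length")
    L = haploid_len if haploid_len is not None else int(lens.sum())
    n_reads = int(rng.poisson(cfg.depth * L / cfg.read_len))
    src = rng.choice(len(names), size=n_reads, p=lens / lens.sum())
    out = []
    for i in range(n_reads):
        s = seqs[names[int(src[i])]]
        pos = int(rng.integers(0, len(s) - cfg.read_len + 1))
        read = s[pos:pos + cfg.read_len]
        if rng.random() < 0.5:
            read = revcomp(read)
        if cfg.error_rate > 0:
            arr = np.frombuffer(read.encode(), dtype=np.uint8).copy()
            err = np.nonzero(rng.random(cfg.read_len) < cfg.error_rate)[0]
            for j in err:
                arr[j] = ord(_other_base(chr(arr[j]), rng))
            read = arr.tobytes().decode()
        out.append((f"{prefix}{i:07d}", read))
    return out


# ---------------------------------------------------------------------------
# RAD-tag digestion


@dataclass(frozen=True)
class RadTag:
    chrom: str
    start: int  # 0-based, on the forward strand of the source
    end: int
    strand: str  # "+"|"-": orientation of the tag read
    seq: str


def digest_radtags(seqs: Mapping[str, str], site1: str = "TTAATTAA",
                   site2: str = "CATG", tag_len: int = 100) -> list[RadTag]:
    """Tags from double digestion: one per strand-oriented site1 occurrence.

    A forward tag runs from the 3' edge of a site1 occurrence to the far
    edge of the nearest downstream site2 occurrence, truncated to
    ``tag_len``; a reverse tag runs the same way on the opposite strand.
    Occurrences without a downstream site2 yield no tag (the protocol's
    second cut is required).
    """
    if not site1 or not site2:
        raise ValueError("site strings must be non-empty")
    tags: list[RadTag] = []
    site1_rc, site2_rc = revcomp(site1), revcomp(site2)
    for chrom, seq in seqs.items():
        s2_f = _find_all(seq, site2)
        s2_r = _find_all(seq, site2_rc)
        for p in _find_all(seq, site1):
            junction = p + len(site1)
            nxt = _first_at_or_after(s2_f, junction)
            if nxt is not None:
                end = min(nxt + len(site2), junction + tag_len)
                if end > junction:
                    tags.append(RadTag(chrom, junction, end, "+", seq[junction:end]))
        for p in _find_all(seq, site1_rc):
            junction = p  # 3' edge on the minus strand
            prev = _last_start_before(s2_r, len(site2), junction)
            if prev is not None:
                start = max(prev, junction - tag_len)
                if junction > start:
                    tags.append(RadTag(chrom, start, junction, "-",
                                       revcomp(seq[start:junction])))
    return tags


def _find_all(seq: str, motif: str) -> list[int]:
    out, i = [], seq.find(motif)
    while i != -1:
        out.append(i)
        i = seq.find(motif, i + 1)
    return out


def _first_at_or_after(positions: list[int], x: int) -> int | None:
    i = int(np.searchsorted(np.asarray(positions), x, side="left")) if positions else 0
    return positions[i] if i < len(positions) else None


def _last_start_before(positions: list[int], motif_len: int, x: int) -> int | None:
    starts = [p for p in positions if p + motif_len <= x]
    return starts[-1] if starts else None


# ---------------------------------------------------------------------------
# convenience: whole-cross container used by the CLI and acceptance runs


@dataclass
class CrossSim:
    cfg: SimConfig
    p3: ParentGenome
    p4: ParentGenome
    truth: TruthTable
    f1: list[F1Individual]
    rng: np.random.Generator


def simulate_cross(cfg: SimConfig) -> CrossSim:
    rng = np.random.default_rng(cfg.seed)
    p3, p4, truth = simulate_parents(cfg, rng)
    f1 = cross_f1(p3, p4, cfg, rng)
    return CrossSim(cfg=cfg, p3=p3, p4=p4, truth=truth, f1=f1, rng=rng)
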