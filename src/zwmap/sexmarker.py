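"""In silico PCR / CAPS genotyping of sex-linked markers and association stats.

Primer matching is exact (presence/absence assays on near-identical
templates); restriction digestion is modelled by site occurrence plus a
cut offset; genotype-to-sex inference follows the dominant ZW model in
which the W-linked amplicon marks ZW and its absence (with an amplifying
control) marks ZZ. The Fisher test uses the two-sided probability-mass
criterion computed in exact integer arithmetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .simpop import revcomp

ENZYMES = {
    "EcoRI": ("GAATTC", 1),  # G^AATTC
    "PacI": ("TTAATTAA", 5),
    "NlaIII": ("CATG", 4),
}


@dataclass(frozen=True)
class PrimerPair:
    name: str
    forward: str
    reverse: str
    max_product: int = 5000

    def __post_init__(self):
        for p in (self.forward, self.reverse):
            if not p or any(c not in "ACGT" for c in p):
                raise ValueError("primers must be non-empty and ACGT only")


@dataclass(frozen=True)
class Amplicon:
    template: str
    start: int  # 0-based half-open, includes both primer sites
    end: int
    seq: str

    @property
    def length(self) -> int:
        return self.end - self.start


def _find_all(seq: str, motif: str) -> list[int]:
    out, i = [], seq.find(motif)
    while i != -1:
        out.append(i)
        i = seq.find(motif, i + 1)
    return out


def insilico_pcr(template: str, primers: PrimerPair,
                 template_name: str = "template") -> list[Amplicon]:
    """All products from exact forward/reverse primer site pairs in range."""
    if any(c not in "ACGTN" for c in template):
        raise ValueError("template must be ACGTN")
    rev_site = revcomp(primers.reverse)
    out = []
    for f in _find_all(template, primers.forward):
        for r in _find_all(template, rev_site):
            end = r + len(rev_site)
            if end - f <= 0 or end - f > primers.max_product:
                continue
            if r < f + len(primers.forward) - len(rev_site):
                continue
            out.append(Amplicon(template_name, f, end, template[f:end]))
    return sorted(out, key=lambda a: (a.start, a.end))


# ---------------------------------------------------------------------------
# CAPS genotyping


@dataclass
class CapsResult:
    genotype: str  # "A/A" | "A/B" | "B/B" | "no-amp"
    amplicon_lengths: list[list[int]] = field(default_factory=list)
    fragment_lengths: list[list[int]] = field(default_factory=list)


def digest_fragments(seq: str, enzyme_site: str, cut_offset: int) -> list[int]:
    """Fragment lengths from cutting at every site occurrence."""
    cuts = sorted(p + cut_offset for p in _find_all(seq, enzyme_site))
    bounds = [0] + [c for c in cuts if 0 < c < len(seq)] + [len(seq)]
    return [b - a for a, b in zip(bounds[:-1], bounds[1:])]


def caps_genotype(amplicons_per_haplotype: list[list[Amplicon]],
                  enzyme_site: str = "GAATTC", cut_offset: int = 1) -> CapsResult:
    """Genotype a diploid template from per-haplotype digestion patterns.

    A/A: no amplified haplotype cut; B/B: all cut; A/B: mixed. Haplotypes
    without an amplicon are invisible (dominant assay): if neither
    haplotype amplifies the call is no-amp; if one does, the call reflects
    the visible band pattern alone.
    """
    amp_lens, frag_lens, cut_flags = [], [], []
    for amps in amplicons_per_haplotype:
        amp_lens.append([a.length for a in amps])
        frags = []
        for a in amps:
            frags.extend(digest_fragments(a.seq, enzyme_site, cut_offset))
        frag_lens.append(frags)
        if amps:
            cut_flags.append(any(enzyme_site in a.seq for a in amps))
    if not cut_flags:
        return CapsResult("no-amp", amp_lens, frag_lens)
    if all(cut_flags):
        geno = "B/B"
    elif not any(cut_flags):
        geno = "A/A"
    else:
        geno = "A/B"
    return CapsResult(geno, amp_lens, frag_lens)


def dominant_genotype(marker_amplified: bool, control_amplified: bool) -> str:
    """W-linked presence/absence call: ZW | ZZ | failed."""
    if not control_amplified:
        return "failed"
    return "ZW" if marker_amplified else "ZZ"


# ---------------------------------------------------------------------------
# Fisher's exact test (two-sided, probability-mass criterion)


@dataclass(frozen=True)
class Table2x2:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")


def fisher_exact(t: Table2x2) -> float:
    """Two-sided p: sum of hypergeometric probabilities <= that of ``t``.

    Computed in exact integer arithmetic (sums of binomial-coefficient
    products over a common denominator), falling back to log-space
    summation above n = 2000.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if n == 0:
        return 1.0
    k_lo, k_hi = max(0, c1 - r2), min(r1, c1)
    if n <= 2000:
        weights = {k: math.comb(r1, k) * math.comb(r2, c1 - k)
                   for k in range(k_lo, k_hi + 1)}
        total = sum(weights.values())
        obs = weights[a]
        tail = sum(w for w in weights.values() if w <= obs)
        return tail / total
    # log-space path for very large tables
    logs = {k: (math.lgamma(r1 + 1) - math.lgamma(k + 1) - math.lgamma(r1 - k + 1)
                + math.lgamma(r2 + 1) - math.lgamma(c1 - k + 1)
                - math.lgamma(r2 - c1 + k + 1))
            for k in range(k_lo, k_hi + 1)}
    mx = max(logs.values())
    total = sum(math.exp(v - mx) for v in logs.values())
    obs = logs[a]
    tail = sum(math.exp(v - mx) for v in logs.values() if v <= obs + 1e-12)
    return tail / total


# ---------------------------------------------------------------------------
# concordance reporting


def concordance_report(genotype_calls: dict[str, str],
                       phenotypes: pd.DataFrame) -> dict:
    """Cross genotype calls against multi-season sex phenotypes.

    ``phenotypes`` columns: id, season, sex. Produces per-season and
    consistency-collapsed 2x2 tables (ZW-call vs non-male phenotype),
    concordance fractions and Fisher p-values; individuals with
    inconsistent sex across seasons are tabulated separately, ids without
    phenotype records are listed as unphenotyped.
    """
    if not genotype_calls:
        raise ValueError("empty genotype calls")
    pheno_ids = set(phenotypes["id"])
    unphenotyped = sorted(set(genotype_calls) - pheno_ids)
    report: dict = {"unphenotyped": unphenotyped, "per_season": {}, "tables": {}}

    def table_for(records: pd.DataFrame) -> tuple[Table2x2, float, float]:
        a = b = c = d = 0  # rows: call ZW / ZZ; cols: phenotype non-male / male
        for r in records.itertuples(index=False):
            call = genotype_calls.get(r.id)
            if call not in ("ZW", "ZZ"):
                continue
            male = r.sex == "male"
            if call == "ZW":
                b, a = (b + 1, a) if male else (b, a + 1)
            else:
                d, c = (d + 1, c) if male else (d, c + 1)
        t = Table2x2(a, b, c, d)
        total = a + b + c + d
        conc = (a + d) / total if total else float("nan")
        p = fisher_exact(t) if total else float("nan")
        return t, conc, p

    for season, sub in phenotypes.groupby("season"):
        t, conc, p = table_for(sub)
        report["per_season"][str(season)] = {
            "table": [[t.a, t.b], [t.c, t.d]], "concordance": conc, "fisher_p": p}

    by_id = phenotypes.groupby("id")["sex"].agg(lambda s: sorted(set(s)))
    consistent = by_id[by_id.map(len) == 1].map(lambda s: s[0])
    inconsistent = sorted(by_id[by_id.map(len) > 1].index)
    cons_df = pd.DataFrame({"id": consistent.index, "season": "all",
                            "sex": consistent.values})
    t, conc, p = table_for(cons_df)
    report["tables"]["consistent"] = {
        "table": [[t.a, t.b], [t.c, t.d]], "concordance": conc, "fisher_p": p}
    report["inconsistent_ids"] = inconsistent
    report["inconsistent_calls"] = {
        i: genotype_calls.get(i) for i in inconsistent if i in genotype_calls}
    return report
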