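"""Genome-wide integration-site preference analysis.

Insertion coordinates (the first base of the TA target dinucleotide) are classified
into gene-related categories, profiled along gene bodies and around TSSs, normalized
by expression group, and compared with computationally generated random loci for
fold enrichment with Fisher's exact test.  The local sequence context around each TA
is stacked into a target-site matrix to recover the palindromic integration consensus.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .discovery import revcomp

log = logging.getLogger(__name__)

FEATURE_CATEGORIES = ["promoter", "exon", "intron", "genic_unresolved",
                      "downstream", "intergenic"]

_IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("GC"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CGT"): "B", frozenset("AGT"): "D", frozenset("ACT"): "H",
    frozenset("ACG"): "V", frozenset("ACGT"): "N",
}


@dataclass(frozen=True)
class InsertionSite:
    chrom: str
    position: int               # 0-based first base of the TA dinucleotide
    strand: str | None = None
    sample_label: str = "sites"

    def __post_init__(self):
        if self.position < 0:
            raise ValueError("position must be >= 0")


@dataclass
class GeneModel:
    chrom: str
    start: int
    end: int
    strand: str
    name: str
    exons: list[tuple[int, int]] | None = None
    expression: float | None = None

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"gene {self.name}: start >= end")
        if self.exons:
            for s, e in self.exons:
                if not (self.start <= s < e <= self.end):
                    raise ValueError(f"gene {self.name}: exon outside gene body")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start


@dataclass(frozen=True)
class StateSegment:
    chrom: str
    start: int
    end: int
    state: str


@dataclass
class FeatureAnnotation:
    site: InsertionSite
    category: str
    gene_name: str | None


@dataclass
class EnrichmentResult:
    label: str
    obs_count: int
    obs_total: int
    bg_count: int
    bg_total: int
    fold: float | None          # None when the state is absent from the background
    p_value: float
    stars: str


@dataclass
class TargetSiteMatrix:
    halfwidth: int
    counts: np.ndarray          # shape (2*halfwidth + 2, 4), A C G T
    consensus: str
    palindrome_score: float
    n_sites: int
    n_partial: int


# ---------------------------------------------------------------------------
# Fisher's exact test and star rating
# ---------------------------------------------------------------------------

_EXACT_FISHER_LIMIT = 500


def fisher_exact(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p: sum of hypergeometric point probabilities no larger
    than the observed table's.  Small tables use exact rational arithmetic; large
    tables fall back to scipy's implementation of the same definition."""
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("counts must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n = a + b + c + d
    if n == 0 or a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        return 1.0
    if n > _EXACT_FISHER_LIMIT:
        return float(stats.fisher_exact([[a, b], [c, d]])[1])
    # all point probabilities share the denominator C(n, col1), so the "pmf <=
    # observed pmf" comparison is exact on integer numerators
    row1, col1 = a + b, a + c
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    nums = [math.comb(row1, k) * math.comb(n - row1, col1 - k)
            for k in range(lo, hi + 1)]
    num_obs = nums[a - lo]
    total = sum(x for x in nums if x <= num_obs)
    return float(min(Fraction(1), Fraction(total, math.comb(n, col1))))


def stars(p: float) -> str:
    """Significance symbols: **** p<=1e-4; *** (1e-4,1e-3]; ** (1e-3,1e-2];
    * (1e-2,0.05]; ns otherwise."""
    if p <= 1e-4:
        return "****"
    if p <= 1e-3:
        return "***"
    if p <= 1e-2:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


# ---------------------------------------------------------------------------
# random background loci
# ---------------------------------------------------------------------------

def ta_positions(genome: Mapping[str, str]) -> dict[str, np.ndarray]:
    """0-based start positions of every TA dinucleotide, per contig."""
    out = {}
    for chrom, seq in genome.items():
        arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
        hits = np.nonzero((arr[:-1] == ord("T")) & (arr[1:] == ord("A")))[0]
        out[chrom] = hits
    return out


def generate_random_loci(chrom_sizes: Mapping[str, int], n: int = 100_000,
                         seed: int | None = None, mode: str = "uniform",
                         genome: Mapping[str, str] | None = None,
                         label: str = "random") -> list[InsertionSite]:
    """Computationally generated random loci: uniform over the genome, or restricted
    to TA dinucleotide starts (ta_matched) as a TA-conditioned null."""
    if n <= 0:
        raise ValueError("n must be > 0")
    rng = np.random.default_rng(seed)
    if mode == "uniform":
        chroms = sorted(chrom_sizes)
        sizes = np.array([max(0, chrom_sizes[c] - 1) for c in chroms], dtype=float)
        if sizes.sum() <= 0:
            raise ValueError("total genome length must be > 0")
        picks = rng.choice(len(chroms), size=n, p=sizes / sizes.sum())
        sites = []
        for ci in picks:
            pos = int(rng.integers(0, int(sizes[ci])))
            sites.append(InsertionSite(chroms[ci], pos, None, label))
        return sites
    if mode == "ta_matched":
        if genome is None:
            raise ValueError("ta_matched mode requires the genome sequence")
        tas = ta_positions(genome)
        chroms = sorted(tas)
        counts = np.array([len(tas[c]) for c in chroms], dtype=float)
        if counts.sum() == 0:
            raise ValueError("genome contains no TA dinucleotide")
        picks = rng.choice(len(chroms), size=n, p=counts / counts.sum())
        sites = []
        for ci in picks:
            pos = int(tas[chroms[ci]][rng.integers(0, len(tas[chroms[ci]]))])
            sites.append(InsertionSite(chroms[ci], pos, None, label))
        return sites
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# feature assignment
# ---------------------------------------------------------------------------

def _gene_windows(gene: GeneModel, promoter_bp: int, downstream_bp: int):
    if gene.strand == "+":
        prom = (gene.start - promoter_bp, gene.start)
        down = (gene.end, gene.end + downstream_bp)
    else:
        prom = (gene.end, gene.end + promoter_bp)
        down = (gene.start - downstream_bp, gene.start)
    return prom, down


def assign_feature(site: InsertionSite, genes: Sequence[GeneModel],
                   promoter_bp: int = 1000,
                   downstream_bp: int = 1000) -> FeatureAnnotation:
    """Single-label category with precedence promoter > exon > intron >
    genic_unresolved > downstream > intergenic; ties within a category resolve to the
    gene with the nearest TSS."""
    pos = site.position
    best_rank = len(FEATURE_CATEGORIES) - 1
    best: tuple[int, int, str] | None = None  # (rank, |d_tss|, gene name)
    for g in genes:
        if g.chrom != site.chrom:
            continue
        prom, down = _gene_windows(g, promoter_bp, downstream_bp)
        cat = None
        if prom[0] <= pos < prom[1]:
            cat = "promoter"
        elif g.start <= pos < g.end:
            if g.exons is None:
                cat = "genic_unresolved"
            elif any(s <= pos < e for s, e in g.exons):
                cat = "exon"
            else:
                cat = "intron"
        elif down[0] <= pos < down[1]:
            cat = "downstream"
        if cat is None:
            continue
        key = (FEATURE_CATEGORIES.index(cat), abs(pos - g.tss), g.name)
        if best is None or key < best:
            best = key
    if best is None:
        return FeatureAnnotation(site, "intergenic", None)
    return FeatureAnnotation(site, FEATURE_CATEGORIES[best[0]], best[2])


def feature_distribution(sites_by_sample: Mapping[str, Sequence[InsertionSite]],
                         genes: Sequence[GeneModel],
                         background_label: str = "random",
                         promoter_bp: int = 1000,
                         downstream_bp: int = 1000) -> pd.DataFrame:
    """Per-sample category fractions plus Fisher tests against the background sample.

    Returns tidy rows (sample, category, count, fraction, fold, p_value, stars); the
    background sample gets fold 1 and p 1 against itself by construction.
    """
    if background_label not in sites_by_sample:
        raise ValueError(f"background sample {background_label!r} missing")
    counts: dict[str, dict[str, int]] = {}
    totals: dict[str, int] = {}
    for label, sites in sites_by_sample.items():
        if len(sites) == 0:
            raise ValueError(f"sample {label!r} is empty")
        c = dict.fromkeys(FEATURE_CATEGORIES, 0)
        for s in sites:
            ann = assign_feature(s, genes, promoter_bp, downstream_bp)
            c[ann.category] += 1
        counts[label] = c
        totals[label] = len(sites)
    bg, bg_total = counts[background_label], totals[background_label]
    rows = []
    for label in sites_by_sample:
        for cat in FEATURE_CATEGORIES:
            k, n = counts[label][cat], totals[label]
            bk, bn = bg[cat], bg_total
            fold = (k / n) / (bk / bn) if bk > 0 else None
            p = fisher_exact(k, n - k, bk, bn - bk)
            rows.append({"sample": label, "category": cat, "count": k,
                         "fraction": k / n, "fold": fold, "p_value": p,
                         "stars": stars(p)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# positional profiles
# ---------------------------------------------------------------------------

def gene_body_decile(sites: Sequence[InsertionSite],
                     genes: Sequence[GeneModel]) -> tuple[np.ndarray, int]:
    """Histogram of fractional positions along gene bodies in 10 equal segments.

    The fractional position runs in transcript orientation; the last nucleotide of a
    gene maps to the tenth segment.  Returns (fractions over 10 bins, n_skipped)
    where skipped sites fell in no gene body.
    """
    counts = np.zeros(10, dtype=np.int64)
    skipped = 0
    for s in sites:
        hit = None
        for g in genes:
            if g.chrom == s.chrom and g.start <= s.position < g.end:
                hit = g
                break
        if hit is None:
            skipped += 1
            continue
        L = hit.end - hit.start
        d = (s.position - hit.start) if hit.strand == "+" else (hit.end - 1 - s.position)
        counts[min(int(10 * d / L), 9)] += 1
    total = counts.sum()
    frac = counts / total if total else counts.astype(float)
    return frac, skipped


def tss_profile(sites: Sequence[InsertionSite], genes: Sequence[GeneModel],
                halfwidth: int = 3000, bin_bp: int = 100
                ) -> tuple[np.ndarray, np.ndarray]:
    """Signed strand-aware distances to the nearest TSS, binned over +/- halfwidth.

    Returns (bin_left_edges, counts); sites with no TSS within range are excluded.
    """
    if halfwidth <= 0:
        raise ValueError("halfwidth must be > 0")
    tss_by_chrom: dict[str, list[tuple[int, str]]] = {}
    for g in genes:
        tss_by_chrom.setdefault(g.chrom, []).append((g.tss, g.strand))
    offsets = []
    for s in sites:
        best = None
        for tss, strand in tss_by_chrom.get(s.chrom, []):
            off = s.position - tss if strand == "+" else tss - s.position
            if abs(off) <= halfwidth and (best is None or abs(off) < abs(best)):
                best = off
        if best is not None:
            offsets.append(best)
    edges = np.arange(-halfwidth, halfwidth + bin_bp, bin_bp)
    counts, _ = np.histogram(offsets, bins=edges)
    return edges[:-1], counts


def expression_binned_frequency(sites: Sequence[InsertionSite],
                                genes: Sequence[GeneModel],
                                n_groups: int = 8) -> pd.DataFrame:
    """Insertion frequency in equal-count gene groups of increasing expression.

    Genes are ranked by expression (stable order on ties) and split into n_groups
    octile-style groups; the reported frequency is intragenic insertions per Mb of
    summed gene length in the group, which also normalizes per gene because the
    groups hold equal gene counts.
    """
    expressed = [g for g in genes if g.expression is not None]
    if len(expressed) < n_groups:
        raise ValueError(f"need expression for >= {n_groups} genes")
    if all(g.expression == 0 for g in expressed):
        log.warning("all expression values are zero; reporting a single group")
        n_groups = 1
    order = sorted(range(len(expressed)), key=lambda i: (expressed[i].expression, i))
    groups = np.array_split(order, n_groups)
    gene_group = {expressed[i].name: gi for gi, idx in enumerate(groups) for i in idx}
    hit_counts = np.zeros(n_groups, dtype=np.int64)
    for s in sites:
        for g in expressed:
            if g.chrom == s.chrom and g.start <= s.position < g.end:
                hit_counts[gene_group[g.name]] += 1
                break
    rows = []
    for gi, idx in enumerate(groups):
        glen = sum(expressed[i].end - expressed[i].start for i in idx)
        rows.append({
            "group": gi,
            "n_genes": len(idx),
            "mean_expression": float(np.mean([expressed[i].expression for i in idx])),
            "gene_length_mb": glen / 1e6,
            "insertions": int(hit_counts[gi]),
            "insertions_per_mb": hit_counts[gi] / (glen / 1e6) if glen else float("nan"),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# chromatin-state enrichment
# ---------------------------------------------------------------------------

def _assign_states(sites: Sequence[InsertionSite],
                   segs_by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[str]]]
                   ) -> list[str | None]:
    out = []
    for s in sites:
        entry = segs_by_chrom.get(s.chrom)
        if entry is None:
            out.append(None)
            continue
        starts, ends, states = entry
        i = int(np.searchsorted(starts, s.position, side="right")) - 1
        if i >= 0 and s.position < ends[i]:
            out.append(states[i])
        else:
            out.append(None)
    return out


def chromatin_state_enrichment(sites: Sequence[InsertionSite],
                               state_segments: Sequence[StateSegment],
                               random_sites: Sequence[InsertionSite]
                               ) -> list[EnrichmentResult]:
    """Per-state fold enrichment of observed sites over random loci with Fisher p.

    Overlapping segments with conflicting state labels are an error; states present in
    the observed sample but absent from the background are reported with fold None
    rather than a fabricated value.
    """
    segs_by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[str]]] = {}
    for chrom in {seg.chrom for seg in state_segments}:
        segs = sorted((s for s in state_segments if s.chrom == chrom),
                      key=lambda s: s.start)
        offenders = [
            f"{a.chrom}:{a.start}-{a.end}({a.state})/{b.start}-{b.end}({b.state})"
            for a, b in zip(segs, segs[1:])
            if b.start < a.end and a.state != b.state]
        if offenders:
            raise ValueError("conflicting overlapping segments: " + ", ".join(offenders))
        segs_by_chrom[chrom] = (np.array([s.start for s in segs]),
                                np.array([s.end for s in segs]),
                                [s.state for s in segs])
    all_states = sorted({s.state for s in state_segments})
    obs_states = _assign_states(sites, segs_by_chrom)
    bg_states = _assign_states(random_sites, segs_by_chrom)
    obs_total = sum(st is not None for st in obs_states)
    bg_total = sum(st is not None for st in bg_states)
    results = []
    for state in all_states:
        k = sum(st == state for st in obs_states)
        bk = sum(st == state for st in bg_states)
        fold = ((k / obs_total) / (bk / bg_total)
                if bk > 0 and obs_total and bg_total else None)
        p = fisher_exact(k, obs_total - k, bk, bg_total - bk)
        results.append(EnrichmentResult(label=state, obs_count=k, obs_total=obs_total,
                                        bg_count=bk, bg_total=bg_total, fold=fold,
                                        p_value=p, stars=stars(p)))
    return results


# ---------------------------------------------------------------------------
# target-site sequence context
# ---------------------------------------------------------------------------

def target_site_matrix(sites: Sequence[InsertionSite], genome: Mapping[str, str],
                       halfwidth: int = 10,
                       require_ta: bool = True) -> TargetSiteMatrix:
    """Stack the sequence windows around each TA into per-position base counts.

    Windows cover halfwidth bp either side of the 2-bp TA and are oriented by site
    strand when present.  Non-TA-anchored sites are logged and (by default) excluded;
    windows truncated at contig edges contribute to the positions they cover.
    The consensus is the per-position majority base (IUPAC code on ties) and the
    palindrome score is the reverse-complement self-agreement of the central 8-mer.
    """
    W = 2 * halfwidth + 2
    counts = np.zeros((W, 4), dtype=np.int64)
    used = partial = 0
    for s in sites:
        contig = genome.get(s.chrom)
        if contig is None:
            continue
        if contig[s.position:s.position + 2].upper() != "TA":
            log.debug("site %s:%d is not TA-anchored", s.chrom, s.position)
            if require_ta:
                continue
        lo, hi = s.position - halfwidth, s.position + 2 + halfwidth
        window = contig[max(0, lo):hi].upper()
        pad_left = max(0, -lo)
        if pad_left or len(window) + pad_left < W:
            partial += 1
        if s.strand == "-":
            window = revcomp(window)
            pad_left = W - pad_left - len(window)
        for i, base in enumerate(window):
            j = "ACGT".find(base)
            if j >= 0:
                counts[pad_left + i, j] += 1
        used += 1
    consensus = []
    for row in counts:
        if row.sum() == 0:
            consensus.append("N")
            continue
        winners = frozenset("ACGT"[i] for i in np.nonzero(row == row.max())[0])
        consensus.append(_IUPAC[winners])
    cons = "".join(consensus)
    central = cons[halfwidth - 3:halfwidth + 5]
    return TargetSiteMatrix(halfwidth=halfwidth, counts=counts, consensus=cons,
                            palindrome_score=palindrome_score(central),
                            n_sites=used, n_partial=partial)


def palindrome_score(s: str) -> float:
    """Fraction of positions equal to the reverse complement's matching position."""
    if not s:
        return 0.0
    rc = revcomp(s)
    return sum(a == b for a, b in zip(s, rc)) / len(s)
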