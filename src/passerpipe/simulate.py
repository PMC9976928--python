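"""Ground-truthed synthetic inputs for every pipeline stage.

The generator builds genomes with planted transposon families of controlled age and
intactness, and insertion-site sets with controlled feature/TSS/expression/motif
biases.  Truth tables record every planted coordinate and generative parameter so
recovery can be scored exactly.  Defaults mirror the structure of the most active
natural Passer element (stickleback): 28-bp perfect TIRs, a TA target-site
duplication, and a 425-aa transposase carrying two DBD motifs and a DD35D triad, in
an element of roughly 2.4 kb; burst ages are expressed directly as Kimura-2-parameter
targets so truth lives on the same scale as the measured landscapes.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .annotation import MotifProfile
from .discovery import HomologyHit, revcomp
from .insertions import GeneModel, InsertionSite, StateSegment, ta_positions

log = logging.getLogger(__name__)

# Toy DBD motif consensi for the synthetic transposase (test stand-ins, not natural
# Brk/HTH sequences).
BRK_CONSENSUS = "WRKPFCEQLG"
HTH_CONSENSUS = "LIGHRAEYNQWD"


def toy_profiles() -> list[MotifProfile]:
    """Weight matrices matching the planted synthetic DBD motifs."""
    return [MotifProfile.from_consensus("Brk", BRK_CONSENSUS),
            MotifProfile.from_consensus("HTH", HTH_CONSENSUS)]


_CODONS = {
    "A": ["GCT", "GCC", "GCA", "GCG"], "C": ["TGT", "TGC"],
    "D": ["GAT", "GAC"], "E": ["GAA", "GAG"], "F": ["TTT", "TTC"],
    "G": ["GGT", "GGC", "GGA", "GGG"], "H": ["CAT", "CAC"],
    "I": ["ATT", "ATC", "ATA"], "K": ["AAA", "AAG"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"],
    "M": ["ATG"], "N": ["AAT", "AAC"],
    "P": ["CCT", "CCC", "CCA", "CCG"], "Q": ["CAA", "CAG"],
    "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "T": ["ACT", "ACC", "ACA", "ACG"], "V": ["GTT", "GTC", "GTA", "GTG"],
    "W": ["TGG"], "Y": ["TAT", "TAC"],
}
_AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class AncestralElement:
    sequence: str
    tir_len: int
    tsd: str
    orf_start: int              # nt offset of ATG within the element
    orf_end: int                # half-open, includes stop codon
    protein: str
    triad_positions: tuple[int, int, int]
    motif_positions: dict[str, int]

    @property
    def length_aa(self) -> int:
        return (self.orf_end - self.orf_start) // 3 - 1


@dataclass
class SiteBiasModel:
    """Generative biases for synthetic insertion sites over TA positions.

    genic_fold is the target observed enrichment fold of genic insertions over a
    TA-matched random background (the sampling weight ratio is derived from it);
    tss_weight/tss_sigma add a Gaussian bump around TSSs; expression_exponent couples
    the per-gene rate to the gene's expression rank; motif_weights multiplies by a
    per-8-mer-context weight.
    """
    genic_fold: float = 1.0
    tss_sigma: float | None = None
    tss_weight: float = 0.0
    expression_exponent: float = 0.0
    motif_weights: Mapping[str, float] | None = None
    n_sites: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.genic_fold < 0 or self.tss_weight < 0:
            raise ValueError("folds and weights must be >= 0")


# ---------------------------------------------------------------------------
# background genome, genes, chromatin states
# ---------------------------------------------------------------------------

def random_genome(seed: int, lengths: Mapping[str, int] | int = 500_000,
                  gc: float = 0.41) -> dict[str, str]:
    """i.i.d. background genome at the given GC content (vertebrate-like default)."""
    if isinstance(lengths, int):
        lengths = {"chr1": lengths}
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return {c: "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])
            for c, n in lengths.items()}


def make_genes(chrom_sizes: Mapping[str, int], n_genes: int, seed: int,
               length_range: tuple[int, int] = (3000, 9000),
               n_exons_range: tuple[int, int] = (2, 5),
               margin: int = 1500,
               expression_sigma: float = 1.5) -> list[GeneModel]:
    """Non-overlapping gene models with exons and lognormal expression values."""
    rng = np.random.default_rng(seed)
    genes: list[GeneModel] = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_sizes}
    chroms = sorted(chrom_sizes)
    attempts = 0
    while len(genes) < n_genes and attempts < 50 * n_genes:
        attempts += 1
        chrom = chroms[rng.integers(len(chroms))]
        L = int(rng.integers(length_range[0], length_range[1] + 1))
        if chrom_sizes[chrom] < L + 2 * margin:
            continue
        s = int(rng.integers(margin, chrom_sizes[chrom] - L - margin))
        e = s + L
        if any(s - margin < oe and os_ < e + margin for os_, oe in occupied[chrom]):
            continue
        occupied[chrom].append((s, e))
        n_ex = int(rng.integers(n_exons_range[0], n_exons_range[1] + 1))
        cuts = np.sort(rng.choice(np.arange(1, 2 * n_ex - 1), size=2 * n_ex - 2,
                                  replace=False)) if n_ex > 1 else np.array([])
        bounds = np.concatenate([[0], (cuts / (2 * n_ex - 1) * L).astype(int), [L]])
        exons = [(s + int(bounds[2 * i]), s + int(bounds[2 * i + 1]))
                 for i in range(n_ex)]
        exons = [(a, b) for a, b in exons if b > a]
        strand = "+" if rng.random() < 0.5 else "-"
        expr = float(rng.lognormal(mean=1.0, sigma=expression_sigma))
        genes.append(GeneModel(chrom=chrom, start=s, end=e, strand=strand,
                               name=f"gene{len(genes):04d}", exons=exons,
                               expression=expr))
    if len(genes) < n_genes:
        log.warning("placed only %d of %d requested genes", len(genes), n_genes)
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes


def make_chromatin_states(chrom_sizes: Mapping[str, int], n_states: int = 5,
                          mean_segment: int = 2000,
                          seed: int = 0) -> list[StateSegment]:
    """Toy chromatin-state segmentation: geometric segment lengths tiling each contig."""
    rng = np.random.default_rng(seed)
    labels = [f"E{i + 1}" for i in range(n_states)]
    segs = []
    for chrom in sorted(chrom_sizes):
        pos = 0
        while pos < chrom_sizes[chrom]:
            L = int(rng.geometric(1.0 / mean_segment))
            end = min(pos + max(L, 200), chrom_sizes[chrom])
            segs.append(StateSegment(chrom, pos, end, labels[rng.integers(n_states)]))
            pos = end
    return segs


# ---------------------------------------------------------------------------
# ancestral element
# ---------------------------------------------------------------------------

def make_ancestral_element(seed: int, tir_len: int = 28, orf_aa: int = 425,
                           spacer23: int = 35,
                           element_len: int = 2388) -> AncestralElement:
    """Construct an ancestor that passes every detector by construction.

    The element is TIR + 5' UTR + ORF + 3' UTR + reverse-complement TIR; the protein
    starts with M, carries the two toy DBD motifs, and a DDxD triad with the requested
    spacer.  An in-frame stop just before the ATG keeps the ORF call at exactly
    orf_aa residues.
    """
    if orf_aa < 301:
        raise ValueError("orf_aa must be >= 301 to satisfy the intact-transposase rule")
    cds_len = 3 * (orf_aa + 1)
    overhead = 2 * tir_len + cds_len + 6   # TIRs + CDS + upstream in-frame stop
    if element_len < overhead + 40:
        raise ValueError("element_len too small for the requested ORF and TIRs")
    if not 1600 <= element_len <= 4000:
        raise ValueError("element_len outside the 1.6-4.0 kb family range")
    rng = np.random.default_rng(seed)

    protein = list("".join(rng.choice(list(_AA20), size=orf_aa)))
    protein[0] = "M"
    motif_positions = {}
    for name, consensus, pos in (("Brk", BRK_CONSENSUS, 20),
                                 ("HTH", HTH_CONSENSUS, 60)):
        protein[pos:pos + len(consensus)] = list(consensus)
        motif_positions[name] = pos
    d1, d2 = 150, 260
    d3 = d2 + spacer23 + 1
    if d3 >= orf_aa:
        raise ValueError("protein too short for the requested triad spacing")
    for p in (d1, d2, d3):
        protein[p] = "D"
    protein = "".join(protein)

    cds = "".join(_CODONS[aa][rng.integers(len(_CODONS[aa]))] for aa in protein) + "TAA"
    tir = "".join(rng.choice(list("ACGT"), size=tir_len))
    utr_total = element_len - 2 * tir_len - len(cds)
    utr5_len = utr_total // 2
    utr5 = "".join(rng.choice(list("ACGT"), size=utr5_len - 3)) + "TAA"
    utr3 = "".join(rng.choice(list("ACGT"), size=utr_total - utr5_len))
    # pin the bases just inside the TIRs to a non-complementary pair so the
    # inverted repeat is exactly tir_len long, not extended by a chance match
    utr5 = "A" + utr5[1:]
    utr3 = utr3[:-1] + "A"
    seq = tir + utr5 + cds + utr3 + revcomp(tir)
    orf_start = tir_len + utr5_len
    return AncestralElement(sequence=seq, tir_len=tir_len, tsd="TA",
                            orf_start=orf_start, orf_end=orf_start + len(cds),
                            protein=protein, triad_positions=(d1, d2, d3),
                            motif_positions=motif_positions)


# ---------------------------------------------------------------------------
# K-targeted mutagenesis
# ---------------------------------------------------------------------------

def solve_pq(k_target: float, ts_tv_ratio: float = 2.0,
             tol: float = 1e-9) -> tuple[float, float]:
    """Solve K(P, Q) = k_target with P/Q = ts_tv_ratio (1-D root find)."""
    import math
    if k_target < 0 or k_target > 0.3:
        raise ValueError("K target must lie in [0, 0.3]")
    if ts_tv_ratio <= 0:
        raise ValueError("ts_tv_ratio must be > 0")
    if k_target == 0:
        return 0.0, 0.0
    R = ts_tv_ratio

    def kval(q):
        p = R * q
        return -0.5 * math.log(1 - 2 * p - q) - 0.25 * math.log(1 - 2 * q)

    q_hi = 1.0 / (2 * R + 1) * (1 - 1e-12)
    q = brentq(lambda x: kval(x) - k_target, 0.0, q_hi, xtol=1e-15, rtol=1e-15)
    if abs(kval(q) - k_target) > tol:
        raise ValueError(f"K target {k_target} unattainable at ratio {ts_tv_ratio}")
    return R * q, q


_TS_PARTNER = np.array([2, 3, 0, 1])     # A<->G, C<->T on ACGT=0123


def mutate_to_k(seq: str, k_target: float, ts_tv_ratio: float = 2.0,
                seed: int | None = None) -> str:
    """Apply per-site substitutions at the (P, Q) solving K = k_target.

    Each site independently mutates to its transition partner with probability P or
    to one of its two transversion partners (equiprobable) with total probability Q,
    so the expected measured K2P distance to the input equals the target.
    """
    P, Q = solve_pq(k_target, ts_tv_ratio)
    if P + Q == 0:
        return seq
    rng = np.random.default_rng(seed)
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8).copy()
    idx = np.full(len(arr), -1, dtype=np.int64)
    for i, b in enumerate(b"ACGT"):
        idx[arr == b] = i
    r = rng.random(len(arr))
    coin = rng.random(len(arr)) < 0.5
    valid = idx >= 0
    ts_mask = valid & (r < P)
    tv_mask = valid & (r >= P) & (r < P + Q)
    new = idx.copy()
    new[ts_mask] = _TS_PARTNER[idx[ts_mask]]
    tv = np.where(coin, idx ^ 1, idx ^ 3)
    new[tv_mask] = tv[tv_mask]
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    out = arr.copy()
    out[valid] = lut[new[valid]]
    return out.tobytes().decode()


# ---------------------------------------------------------------------------
# family planting
# ---------------------------------------------------------------------------

def _break_copy(seq: str, ancestor: AncestralElement, mode: str,
                rng: np.random.Generator) -> tuple[str, str]:
    if mode == "truncate":
        frac = 0.2 + 0.3 * rng.random()     # delete >= 20% from one end
        cut = int(len(seq) * frac)
        if rng.random() < 0.5:
            return seq[cut:], f"5'-truncated {cut} bp"
        return seq[:-cut], f"3'-truncated {cut} bp"
    # break the ORF with a planted in-frame stop near codon 200
    stop_nt = ancestor.orf_start + 3 * 200
    return seq[:stop_nt] + "TAA" + seq[stop_nt + 3:], "ORF stop at codon 200"


def plant_family(genome: Mapping[str, str], ancestor: AncestralElement,
                 bursts: Sequence[tuple[float, int, float]], seed: int,
                 min_spacing: int = 3000,
                 edge_margin: int = 2500,
                 ts_tv_ratio: float = 2.0) -> tuple[dict[str, str], pd.DataFrame]:
    """Insert mutated copies of the ancestor at TA sites, creating the TA duplication.

    bursts is a list of (K_target, n_copies, intact_fraction); non-intact copies are
    either end-truncated (>=20%) or ORF-broken.  Returns the modified genome and a
    truth table with one row per planted copy (final coordinates, burst id, K target,
    intactness, truncation description).
    """
    rng = np.random.default_rng(seed)
    n_total = sum(n for _, n, _ in bursts)
    tas = ta_positions(genome)
    # choose well-separated TA sites away from contig edges
    chosen: list[tuple[str, int]] = []
    for chrom in sorted(tas):
        arr = tas[chrom]
        ok = (arr > edge_margin) & (arr < len(genome[chrom]) - edge_margin)
        # plant only at TA sites isolated from other TA dinucleotides: a second TA
        # within a few bp of the duplicated one makes the boundary parse genuinely
        # ambiguous (the element could equally be read a few bp wider), so such
        # contexts carry no exact ground truth
        iso = 12
        if len(arr) > 1:
            gap_prev = np.diff(arr, prepend=arr[0] - iso)
            gap_next = np.diff(arr, append=arr[-1] + iso)
            ok &= (gap_prev >= iso) & (gap_next >= iso)
        chosen.extend((chrom, int(p)) for p in arr[ok])
    rng.shuffle(chosen)
    picked: dict[str, list[int]] = {}
    for chrom, p in chosen:
        ps = picked.setdefault(chrom, [])
        if all(abs(p - q) >= min_spacing for q in ps):
            ps.append(p)
        if sum(len(v) for v in picked.values()) == n_total:
            break
    if sum(len(v) for v in picked.values()) < n_total:
        raise ValueError("insufficient well-separated TA sites; use a larger genome")

    assignments = []
    for burst_id, (k_target, n_copies, intact_fraction) in enumerate(bursts):
        n_intact = int(round(intact_fraction * n_copies))
        for i in range(n_copies):
            assignments.append((burst_id, k_target, i < n_intact))
    rng.shuffle(assignments)

    new_genome = dict(genome)
    rows = []
    copy_no = 0
    flat = [(chrom, p) for chrom in sorted(picked) for p in picked[chrom]]
    per_chrom: dict[str, list[tuple[int, str, dict]]] = {}
    for (chrom, p), (burst_id, k_target, intact) in zip(flat, assignments):
        sub_seed = int(rng.integers(2**31 - 1))
        seq = mutate_to_k(ancestor.sequence, k_target, ts_tv_ratio, seed=sub_seed)
        truncation = "none"
        if not intact:
            mode = "truncate" if rng.random() < 0.5 else "orf_break"
            seq, truncation = _break_copy(seq, ancestor, mode, rng)
        meta = {"copy_id": f"copy{copy_no:04d}", "burst_id": burst_id,
                "K_target": k_target, "intact": intact, "truncation": truncation}
        per_chrom.setdefault(chrom, []).append((p, seq, meta))
        copy_no += 1
    for chrom, inserts in per_chrom.items():
        inserts.sort(key=lambda t: t[0])
        g = genome[chrom]
        pieces = []
        prev = 0
        shift = 0
        for p, seq, meta in inserts:
            pieces.append(g[prev:p + 2])
            start = p + 2 + shift
            pieces.append(seq + "TA")
            rows.append({**meta, "chrom": chrom, "true_start": start,
                         "true_end": start + len(seq)})
            shift += len(seq) + 2
            prev = p + 2
        pieces.append(g[prev:])
        new_genome[chrom] = "".join(pieces)
    truth = pd.DataFrame(rows).sort_values(["chrom", "true_start"]).reset_index(drop=True)
    return new_genome, truth


def hits_from_truth(truth: pd.DataFrame, seed: int, jitter: int = 7,
                    query_id: str = "transposase") -> list[HomologyHit]:
    """Synthetic homology hits standing in for the external TblastN search: one hit
    per planted copy with boundaries jittered by up to `jitter` bp either way."""
    rng = np.random.default_rng(seed)
    hits = []
    for row in truth.itertuples(index=False):
        ds = int(rng.integers(-jitter, jitter + 1))
        de = int(rng.integers(-jitter, jitter + 1))
        s = max(0, row.true_start + ds)
        e = row.true_end + de
        hits.append(HomologyHit(query_id=query_id, chrom=row.chrom, start=s, end=e,
                                strand="+", percent_identity=95.0, evalue=1e-180,
                                aligned_length=e - s))
    return hits


# ---------------------------------------------------------------------------
# biased insertion sites
# ---------------------------------------------------------------------------

def simulate_sites(genome: Mapping[str, str], genes: Sequence[GeneModel],
                   bias: SiteBiasModel,
                   label: str = "PS") -> tuple[list[InsertionSite], pd.DataFrame]:
    """Weighted sampling of TA positions under the bias model (with replacement).

    The genic weight ratio is derived from the target fold g and the genic TA
    fraction f as r = g(1-f)/(1-gf), so a TA-matched background comparison recovers
    g in expectation.  Returns the sites and a truth table of the sampled positions
    with their generative weights.
    """
    tas = ta_positions(genome)
    chroms = sorted(c for c in tas if len(tas[c]))
    if not chroms:
        raise ValueError("genome contains no TA positions")
    chrom_idx = np.concatenate([np.full(len(tas[c]), i) for i, c in enumerate(chroms)])
    pos = np.concatenate([tas[c] for c in chroms])
    w = np.ones(len(pos), dtype=float)

    in_gene = np.zeros(len(pos), dtype=bool)
    for g in genes:
        if g.chrom not in chroms:
            continue
        ci = chroms.index(g.chrom)
        in_gene |= (chrom_idx == ci) & (pos >= g.start) & (pos < g.end)
    f = in_gene.mean()
    if bias.genic_fold != 1.0:
        if bias.genic_fold * f >= 1.0:
            raise ValueError(
                f"target genic fold {bias.genic_fold} infeasible at genic TA "
                f"fraction {f:.3f}")
        r = bias.genic_fold * (1 - f) / (1 - bias.genic_fold * f)
        w[in_gene] *= r

    if bias.tss_sigma and bias.tss_weight > 0:
        for i, c in enumerate(chroms):
            tss = np.sort([g.tss for g in genes if g.chrom == c])
            if len(tss) == 0:
                continue
            mask = chrom_idx == i
            p = pos[mask]
            j = np.clip(np.searchsorted(tss, p), 0, len(tss) - 1)
            jm = np.clip(j - 1, 0, len(tss) - 1)
            d = np.minimum(np.abs(p - tss[j]), np.abs(p - tss[jm]))
            w[mask] *= 1 + bias.tss_weight * np.exp(-d**2 / (2 * bias.tss_sigma**2))

    if bias.expression_exponent != 0.0:
        expressed = [g for g in genes if g.expression is not None]
        order = sorted(range(len(expressed)),
                       key=lambda i: (expressed[i].expression, i))
        rank_frac = {expressed[i].name: (r + 1) / len(expressed)
                     for r, i in enumerate(order)}
        for g in expressed:
            if g.chrom not in chroms:
                continue
            ci = chroms.index(g.chrom)
            mask = (chrom_idx == ci) & (pos >= g.start) & (pos < g.end)
            w[mask] *= rank_frac[g.name] ** bias.expression_exponent

    if bias.motif_weights:
        for i in range(len(pos)):
            c = chroms[chrom_idx[i]]
            ctx = genome[c][pos[i] - 3:pos[i] + 5]
            if len(ctx) == 8:
                w[i] *= bias.motif_weights.get(ctx, 1.0)

    if w.sum() <= 0:
        raise ValueError("all sampling weights are zero")
    p_norm = w / w.sum()
    rng = np.random.default_rng(bias.seed)
    picks = rng.choice(len(pos), size=bias.n_sites, replace=True, p=p_norm)
    sites = [InsertionSite(chroms[chrom_idx[i]], int(pos[i]), "+", label)
             for i in picks]
    truth = pd.DataFrame({
        "chrom": [chroms[chrom_idx[i]] for i in picks],
        "position": pos[picks],
        "in_gene": in_gene[picks],
        "weight": w[picks],
    })
    truth.attrs["genic_ta_fraction"] = float(f)
    return sites, truth
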