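"""Candidate-locus discovery and element boundary calling.

Homology hits (e.g. TblastN of a transposase against a genome, run externally) are
merged into candidate loci, extracted with flanking sequence, and refined into precise
element boundaries by jointly detecting the terminal inverted repeats (TIRs) and the
target-site duplication (TSD).  Passer-family elements carry short (<30 bp) TIRs and a
TA TSD, so boundary scoring rewards an anchored inverted repeat plus a TA duplication
immediately outside it.

Coordinates are 0-based half-open throughout; minus-strand loci are normalized to
transposase-sense orientation on extraction so all downstream steps see one strand.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement; non-ACGT characters map to N-like behaviour via identity."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HomologyHit:
    """One HSP of the external homology search, in internal coordinates."""
    query_id: str
    chrom: str
    start: int              # 0-based
    end: int                # half-open
    strand: str             # '+' or '-'
    percent_identity: float
    evalue: float
    aligned_length: int

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError(f"percent_identity out of [0,100]: {self.percent_identity}")


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"empty interval {self.chrom}:{self.start}-{self.end}")


@dataclass
class CandidateLocus:
    """A merged-hit interval with flanking sequence, in element-sense orientation."""
    chrom: str
    core_start: int         # plus-strand genome coordinates of the merged hit interval
    core_end: int
    strand: str
    left_flank: str         # oriented: 5' of the element sense
    right_flank: str
    core_seq: str

    @property
    def region(self) -> str:
        return self.left_flank + self.core_seq + self.right_flank


@dataclass(frozen=True)
class TIRPair:
    left_seq: str           # 5' TIR as it appears at the element start
    right_seq: str          # 3' TIR as it appears at the element end
    length: int
    mismatches: int
    left_offset: int        # bp from the element 5' terminus to the TIR start
    right_offset: int       # bp from the element 3' terminus to the TIR end

    @property
    def score(self) -> int:
        """Matched positions minus 2x mismatches."""
        return self.length - 3 * self.mismatches


@dataclass(frozen=True)
class TSDCall:
    sequence: str
    length: int
    is_ta: bool


@dataclass
class TransposonCopy:
    locus: CandidateLocus
    element_start: int      # plus-strand genome coordinates of the refined element
    element_end: int
    tir: TIRPair | None
    tsd: TSDCall | None
    element_seq: str        # element-sense sequence
    boundary_score: float
    copy_id: str = ""


# ---------------------------------------------------------------------------
# hit merging and flank extraction
# ---------------------------------------------------------------------------

def merge_hits(hits: Sequence[HomologyHit], max_gap: int = 200,
               min_identity: float = 0.0,
               max_evalue: float = 1e-100) -> list[GenomicInterval]:
    """Merge same-chromosome, same-strand hits whose gaps are <= max_gap.

    Hits failing the identity or e-value filter are dropped first; malformed hits
    (start >= end) are rejected per record with a logged reason, never aborting.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    kept: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for h in hits:
        if h.start >= h.end:
            log.warning("rejecting hit %s:%d-%d (start >= end)", h.chrom, h.start, h.end)
            continue
        if h.percent_identity < min_identity:
            continue
        if h.evalue > max_evalue:
            continue
        kept.setdefault((h.chrom, h.strand), []).append((h.start, h.end))
    out: list[GenomicInterval] = []
    for (chrom, strand), ivs in sorted(kept.items()):
        ivs.sort()
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s - cur_e <= max_gap:
                cur_e = max(cur_e, e)
            else:
                out.append(GenomicInterval(chrom, cur_s, cur_e, strand))
                cur_s, cur_e = s, e
        out.append(GenomicInterval(chrom, cur_s, cur_e, strand))
    return out


def extract_flanks(interval: GenomicInterval, genome: Mapping[str, str],
                   flank_size: int = 2000) -> CandidateLocus:
    """Extract the core and up to flank_size bp on each side, truncated at contig ends.

    Minus-strand loci are reverse-complemented into transposase-sense orientation and
    their flanks swapped, so the returned locus always reads 5'->3' along the element.
    """
    if flank_size <= 0:
        raise ValueError("flank_size must be > 0")
    if interval.chrom not in genome:
        raise KeyError(f"contig {interval.chrom!r} not present in genome")
    contig = genome[interval.chrom]
    s, e = interval.start, interval.end
    left = contig[max(0, s - flank_size):s]
    core = contig[s:e]
    right = contig[e:e + flank_size]
    if interval.strand == "-":
        left, core, right = revcomp(right), revcomp(core), revcomp(left)
    return CandidateLocus(chrom=interval.chrom, core_start=s, core_end=e,
                          strand=interval.strand, left_flank=left.upper(),
                          right_flank=right.upper(), core_seq=core.upper())


# ---------------------------------------------------------------------------
# TIR / TSD detection
# ---------------------------------------------------------------------------

def _encode(seq: str, invalid_code: int) -> np.ndarray:
    """Byte-encode a sequence; non-ACGT positions get a side-specific code so that
    ambiguity characters always count as mismatches (even N vs N)."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    valid = np.isin(arr, np.frombuffer(b"ACGT", dtype=np.uint8))
    arr[~valid] = invalid_code
    return arr


def _best_ir(left: np.ndarray, right_rc: np.ndarray, min_len: int, max_len: int,
             max_mismatch_frac: float, max_terminal_offset: int):
    """Best substitution-only inverted repeat between the two encoded terminal windows.

    Returns (score, length, mismatches, left_offset, right_offset) or None.  Ties
    prefer higher score, then longer repeat, then fewer mismatches, then smaller
    terminal offsets.
    """
    best = None
    best_key = None
    for a in range(max_terminal_offset + 1):
        x = left[a:a + max_len]
        if len(x) < min_len:
            break
        for b in range(max_terminal_offset + 1):
            y = right_rc[b:b + max_len]
            cap = min(len(x), len(y))
            if cap < min_len:
                continue
            neq = (x[:cap] != y[:cap]).astype(np.int64)
            mism = np.cumsum(neq)
            lengths = np.arange(1, cap + 1)
            ok = (lengths >= min_len) & (mism <= max_mismatch_frac * lengths)
            if not ok.any():
                continue
            scores = lengths - 3 * mism
            scores_ok = np.where(ok, scores, np.iinfo(np.int64).min)
            i = int(np.argmax(scores_ok))
            # among equal scores prefer the longest qualifying length
            top = scores_ok[i]
            cand_idx = np.nonzero(scores_ok == top)[0]
            i = int(cand_idx[-1])
            L, m = int(lengths[i]), int(mism[i])
            key = (int(top), L, -m, -(a + b), -a, -b)
            if best_key is None or key > best_key:
                best_key = key
                best = (int(top), L, m, a, b)
    return best


def detect_tir(element_seq: str, min_len: int = 10, max_len: int = 40,
               terminal_window: int = 60, max_mismatch_frac: float = 0.2,
               max_terminal_offset: int = 5) -> TIRPair | None:
    """Find the highest-scoring inverted repeat anchored near both element termini.

    The score is matched positions minus twice the mismatches (= length - 3*mism);
    gaps are not modelled because Passer TIRs are short (<30 bp).
    """
    n = len(element_seq)
    if n < 2 * terminal_window:
        raise ValueError("element too short")
    seq = element_seq.upper()
    left = _encode(seq[:terminal_window], invalid_code=1)
    right_rc = _encode(revcomp(seq[-terminal_window:]), invalid_code=2)
    hit = _best_ir(left, right_rc, min_len, max_len, max_mismatch_frac,
                   max_terminal_offset)
    if hit is None:
        return None
    _, L, m, a, b = hit
    return TIRPair(left_seq=seq[a:a + L],
                   right_seq=seq[n - b - L:n - b],
                   length=L, mismatches=m, left_offset=a, right_offset=b)


def detect_tsd(left_flank: str, right_flank: str, k_min: int = 2,
               k_max: int = 10) -> TSDCall | None:
    """Longest exact duplication between the left-flank suffix and right-flank prefix.

    Words containing ambiguity characters never match.  Returns None (logged) for
    empty flanks or when no k in [k_min, k_max] matches.
    """
    if not left_flank or not right_flank:
        log.debug("empty flank: no TSD search possible")
        return None
    lf, rf = left_flank.upper(), right_flank.upper()
    hi = min(k_max, len(lf), len(rf))
    for k in range(hi, k_min - 1, -1):
        word = lf[-k:]
        if word == rf[:k] and all(c in "ACGT" for c in word):
            return TSDCall(sequence=word, length=k, is_ta=(word == "TA"))
    return None


# ---------------------------------------------------------------------------
# boundary calling
# ---------------------------------------------------------------------------

def call_boundaries(locus: CandidateLocus, boundary_slop: int = 30,
                    tir_params: dict | None = None,
                    tsd_params: dict | None = None,
                    ta_bonus: float = 10.0) -> TransposonCopy:
    """Refine element boundaries within +/- boundary_slop of the homology core.

    Every candidate (start, end) pair is scored as
    ``tir_score + ta_bonus*(TA TSD present) + tsd_length`` and the maximizer wins;
    homology cores start inside the coding sequence, so the slop must exceed the TIR
    length for the true termini to be reachable.  If no inverted repeat is found
    anywhere, the copy keeps the core boundaries with tir=None and score 0.
    """
    if boundary_slop < 0:
        raise ValueError("boundary_slop must be >= 0")
    tp = dict(min_len=10, max_len=40, terminal_window=60,
              max_mismatch_frac=0.2, max_terminal_offset=5)
    if tir_params:
        tp.update(tir_params)
    sp = dict(k_min=2, k_max=10)
    if tsd_params:
        sp.update(tsd_params)

    region = locus.region.upper()
    n = len(region)
    cs = len(locus.left_flank)
    ce = cs + len(locus.core_seq)
    min_elem = 2 * tp["terminal_window"]

    s_lo, s_hi = max(0, cs - boundary_slop), min(cs + boundary_slop, n - min_elem)
    e_lo, e_hi = max(s_lo + min_elem, ce - boundary_slop), min(n, ce + boundary_slop)
    starts = np.arange(s_lo, s_hi + 1)
    ends = np.arange(e_lo, e_hi + 1)
    max_off = tp["max_terminal_offset"]
    max_len = tp["max_len"]

    fwd = _encode(region, invalid_code=1)
    rc = _encode(revcomp(region), invalid_code=2)

    # Best anchored-IR score for every (left TIR start u, right TIR end v).
    u_vals = np.arange(s_lo, s_hi + max_off + 1)
    v_vals = np.arange(e_lo - max_off, e_hi + 1)
    NEG = np.iinfo(np.int64).min
    M = np.full((len(u_vals), len(v_vals)), NEG, dtype=np.int64)
    lengths = np.arange(1, max_len + 1)
    for ui, u in enumerate(u_vals):
        x = fwd[u:u + max_len]
        for vi, v in enumerate(v_vals):
            if v - u < min_elem:
                continue
            y = rc[n - v:n - v + max_len]
            cap = min(len(x), len(y), (v - u) // 2)
            if cap < tp["min_len"]:
                continue
            mism = np.cumsum((x[:cap] != y[:cap]).astype(np.int64))
            ls = lengths[:cap]
            ok = (ls >= tp["min_len"]) & (mism <= tp["max_mismatch_frac"] * ls)
            if ok.any():
                M[ui, vi] = int(np.max(np.where(ok, ls - 3 * mism, NEG)))

    # TIR score per boundary pair = max over terminal offsets (a, b) <= max_off,
    # charging 2 per offset bp: a TIR flush with the termini marks a real boundary,
    # and with a smaller charge the self-reverse-complementary TA TSD extends the IR
    # and lets slightly shifted boundaries tie with or outscore the true ones.
    OFFSET_CHARGE = 2
    nS, nE = len(starts), len(ends)
    tir_score = np.full((nS, nE), NEG, dtype=np.int64)
    for a in range(max_off + 1):
        for b in range(max_off + 1):
            # starts[i]+a -> u index i+a ; ends[j]-b -> v index j + (max_off - b)
            sub = M[a:a + nS, max_off - b:max_off - b + nE]
            shifted = np.where(sub > NEG, sub - OFFSET_CHARGE * (a + b), NEG)
            np.maximum(tir_score, shifted, out=tir_score)

    # TSD length / TA flag per boundary pair.
    tsd_len = np.zeros((nS, nE), dtype=np.int64)
    tsd_ta = np.zeros((nS, nE), dtype=bool)
    for i, s in enumerate(starts):
        lf = region[:s]
        for j, e in enumerate(ends):
            call = detect_tsd(lf, region[e:], **sp)
            if call is not None:
                tsd_len[i, j] = call.length
                tsd_ta[i, j] = call.is_ta

    found = tir_score > NEG
    if not found.any():
        tsd = detect_tsd(locus.left_flank, locus.right_flank, **sp)
        return _make_copy(locus, cs, ce, None, tsd, region[cs:ce], 0.0)

    total = np.where(found, tir_score + ta_bonus * tsd_ta + tsd_len, -np.inf)
    # Selection.  The family targets TA, so whenever some candidate pair shows a TA
    # TSD the choice is restricted to those (TSD-class prior).  Within the class the
    # maximum wins, except that among candidates scoring within `outer_margin` of it
    # the outermost (longest) element is preferred: a transposon's own TIR can
    # contain short internal repeats (a TA at offset j mirrors into an exact
    # internal TSD+TIR decoy at (s+j, e-j)), and such decoys of a real element
    # always lie inside it, never outside.
    outer_margin = 3.0
    if tsd_ta.any() and total[tsd_ta].max() > -np.inf:
        class_total = np.where(tsd_ta, total, -np.inf)
        best_val = class_total.max()
        elig = np.argwhere(class_total >= best_val - outer_margin)
        cand_list = sorted(
            (-(int(ends[j]) - int(starts[i])), -class_total[i, j],
             abs(int(starts[i]) - cs) + abs(int(ends[j]) - ce),
             int(starts[i]), int(ends[j]))
            for i, j in elig)
        _, neg_score, _, s_best, e_best = cand_list[0]
        score = -neg_score
    else:
        best_val = total.max()
        cand = np.argwhere(total == best_val)
        # deterministic tie-break: closest to the core, then smallest (start, end)
        cand_list = sorted(
            (abs(int(starts[i]) - cs) + abs(int(ends[j]) - ce),
             int(starts[i]), int(ends[j]))
            for i, j in cand)
        _, s_best, e_best = cand_list[0]
        score = float(best_val)
    elem = region[s_best:e_best]
    tir = detect_tir(elem, **tp)
    tsd = detect_tsd(region[:s_best], region[e_best:], **sp)
    return _make_copy(locus, s_best, e_best, tir, tsd, elem, float(score))


def _make_copy(locus: CandidateLocus, s_region: int, e_region: int,
               tir: TIRPair | None, tsd: TSDCall | None,
               elem: str, score: float) -> TransposonCopy:
    """Convert oriented region offsets back to plus-strand genome coordinates."""
    cs = len(locus.left_flank)
    ce = cs + len(locus.core_seq)
    dl, dr = s_region - cs, e_region - ce
    if locus.strand == "+":
        gs, ge = locus.core_start + dl, locus.core_end + dr
    else:
        gs, ge = locus.core_start - dr, locus.core_end - dl
    return TransposonCopy(locus=locus, element_start=gs, element_end=ge,
                          tir=tir, tsd=tsd, element_seq=elem, boundary_score=score)


def discover(genome: Mapping[str, str], hits: Sequence[HomologyHit],
             flank_size: int = 2000, max_gap: int = 200,
             min_identity: float = 0.0, max_evalue: float = 1e-100,
             boundary_slop: int = 30, **boundary_kwargs) -> list[TransposonCopy]:
    """Full discovery stage: merge hits, extract flanks, call boundaries."""
    intervals = merge_hits(hits, max_gap=max_gap, min_identity=min_identity,
                           max_evalue=max_evalue)
    copies = []
    for k, iv in enumerate(intervals):
        locus = extract_flanks(iv, genome, flank_size=flank_size)
        copy = call_boundaries(locus, boundary_slop=boundary_slop, **boundary_kwargs)
        copy.copy_id = f"{iv.chrom}:{iv.start}-{iv.end}({iv.strand})"
        copies.append(copy)
    return copies
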