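"""Family consensus building, identity statistics and Kimura-2-parameter landscapes.

Each copy is aligned to the family consensus (or to a representative element when the
family has five or fewer intact copies) and its divergence is summarised by the Kimura
two-parameter distance

    K = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

with P and Q the transition and transversion proportions over comparable columns
(pairwise deletion of gaps and ambiguity characters).  Binning the aligned bp of each
copy by K% produces the divergence landscape whose multimodality reveals repeated
invasion bursts; copies below a configurable K threshold (default 2%) are flagged as
young insertions.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from Bio import Align

from .discovery import revcomp

log = logging.getLogger(__name__)

MAX_ALIGN_LEN = 20_000

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


@dataclass(frozen=True)
class PairwiseAlignment:
    seq_a_aligned: str
    seq_b_aligned: str
    score: float

    def __post_init__(self):
        if len(self.seq_a_aligned) != len(self.seq_b_aligned):
            raise ValueError("aligned sequences differ in length")


@dataclass
class ConsensusElement:
    sequence: str
    column_support: np.ndarray | None   # shape (L, 5): A C G T gap counts
    n_copies_used: int
    mode: str                           # 'consensus' | 'representative'


@dataclass
class DivergenceRecord:
    copy_id: str
    P: float
    Q: float
    K: float                            # nan when saturated
    valid_columns: int
    aligned_bp: int
    saturated: bool


@dataclass
class DivergenceLandscape:
    family_id: str
    bin_width: float                    # percent
    bins: dict[float, int]              # bin lower edge (%) -> coverage bp

    def to_rows(self) -> list[tuple[float, int]]:
        return sorted(self.bins.items())


@dataclass(frozen=True)
class IdentityReport:
    transposase_identity: float
    tir_identity_5p: float
    tir_identity_3p: float
    intraelement_tir_identity: float


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

def _aligner(match: float, mismatch: float, gap: float) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = match
    a.mismatch_score = mismatch
    a.open_gap_score = gap
    a.extend_gap_score = gap
    return a


def align_global(a: str, b: str, match: float = 1.0, mismatch: float = -1.0,
                 gap: float = -2.0) -> PairwiseAlignment:
    """Optimal global alignment under a linear gap penalty (first optimal traceback)."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if max(len(a), len(b)) > MAX_ALIGN_LEN:
        raise ValueError(
            f"sequence exceeds {MAX_ALIGN_LEN} bp; align in windows instead")
    aln = _aligner(match, mismatch, gap).align(a.upper(), b.upper())[0]
    return PairwiseAlignment(seq_a_aligned=aln[0], seq_b_aligned=aln[1],
                             score=float(aln.score))


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def build_consensus(copies: Sequence[str], reference: str | None = None,
                    min_for_consensus: int = 5,
                    ids: Sequence[str] | None = None) -> ConsensusElement:
    """Majority-rule consensus from a center-star alignment of copies to a reference.

    With more than `min_for_consensus` copies a true consensus is built: every copy is
    aligned to the reference, per-reference-column base counts are accumulated, columns
    where gaps hold the majority are dropped, and ties between bases resolve in fixed
    A<C<G<T order (logged).  With five or fewer copies the family is represented by the
    reference itself (callers pass the intact copy with complete TIRs), matching the
    representative-sequence rule used for sparse families.
    """
    if not copies:
        raise ValueError("no copies supplied")
    ref = reference if reference is not None else copies[0]
    if len(copies) <= min_for_consensus:
        return ConsensusElement(sequence=ref.upper(), column_support=None,
                                n_copies_used=len(copies), mode="representative")
    L = len(ref)
    counts = np.zeros((L, 5), dtype=np.int64)  # A C G T gap
    for copy in copies:
        aln = align_global(ref, copy)
        ri = 0
        for ca, cb in zip(aln.seq_a_aligned, aln.seq_b_aligned):
            if ca == "-":
                continue  # insertion in the copy relative to the reference
            if cb == "-":
                counts[ri, 4] += 1
            else:
                j = _BASE_INDEX.get(cb)
                if j is not None:  # ambiguity characters carry no vote
                    counts[ri, j] += 1
            ri += 1
    out = []
    kept = []
    n = len(copies)
    for ri in range(L):
        base_counts = counts[ri, :4]
        if counts[ri, 4] > n / 2:
            continue  # gap-majority column dropped
        top = base_counts.max()
        if top == 0:
            continue
        winners = np.nonzero(base_counts == top)[0]
        if len(winners) > 1:
            log.debug("consensus tie at column %d between %s; A<C<G<T order used",
                      ri, [("ACGT")[w] for w in winners])
        out.append("ACGT"[winners[0]])
        kept.append(ri)
    return ConsensusElement(sequence="".join(out), column_support=counts[kept],
                            n_copies_used=n, mode="consensus")


def pairwise_identity(seqs: Sequence[str]) -> float:
    """Mean percent identity over all unordered pairs (gap columns excluded)."""
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    vals = []
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            aln = align_global(seqs[i], seqs[j])
            cols = matches = 0
            for ca, cb in zip(aln.seq_a_aligned, aln.seq_b_aligned):
                if ca == "-" or cb == "-":
                    continue
                cols += 1
                matches += ca == cb
            vals.append(100.0 * matches / cols if cols else 0.0)
    return float(np.mean(vals))


def identity_report(transposases: Sequence[str], tirs_5p: Sequence[str],
                    tirs_3p: Sequence[str]) -> IdentityReport:
    """Family identity summary: transposase identity over all intact proteins, TIR
    identity within each end, and mean intra-element 5' vs reverse-complemented 3'
    TIR identity."""
    if len(tirs_5p) != len(tirs_3p):
        raise ValueError("5' and 3' TIR lists must pair up per element")
    intra = float(np.mean([
        pairwise_identity([t5, revcomp(t3)]) for t5, t3 in zip(tirs_5p, tirs_3p)
    ]))
    return IdentityReport(
        transposase_identity=pairwise_identity(transposases),
        tir_identity_5p=pairwise_identity(tirs_5p),
        tir_identity_3p=pairwise_identity(tirs_3p),
        intraelement_tir_identity=intra,
    )


# ---------------------------------------------------------------------------
# Kimura two-parameter divergence
# ---------------------------------------------------------------------------

def k2p(alignment: PairwiseAlignment, copy_id: str = "") -> DivergenceRecord:
    """Kimura-2-parameter record for an aligned pair.

    Comparable columns require both bases in {A,C,G,T}; gaps and ambiguity codes are
    excluded from the P/Q denominators (pairwise deletion).  When either log argument
    is <= 0 the distance is saturated: K is NaN and the record is excluded from
    landscapes.
    """
    valid = ts = tv = aligned = 0
    for ca, cb in zip(alignment.seq_a_aligned.upper(), alignment.seq_b_aligned.upper()):
        if ca != "-" and cb != "-":
            aligned += 1
        if ca in "ACGT" and cb in "ACGT":
            valid += 1
            if ca != cb:
                if (ca, cb) in _TRANSITIONS:
                    ts += 1
                else:
                    tv += 1
    if valid == 0:
        raise ValueError("no comparable sites")
    P, Q = ts / valid, tv / valid
    arg1, arg2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    saturated = arg1 <= 0.0 or arg2 <= 0.0
    K = float("nan") if saturated else -0.5 * math.log(arg1) - 0.25 * math.log(arg2)
    return DivergenceRecord(copy_id=copy_id, P=P, Q=Q, K=K, valid_columns=valid,
                            aligned_bp=aligned, saturated=saturated)


def copy_alignment_stats(copy_seq: str, consensus_seq: str) -> tuple[float, float]:
    """(coverage, identity) of a copy against the family consensus: coverage is
    aligned bp over the consensus length, identity is computed on aligned columns.
    Both are 0..1 fractions, the inputs to the copy-counting thresholds."""
    aln = align_global(consensus_seq, copy_seq)
    cols = matches = 0
    for ca, cb in zip(aln.seq_a_aligned, aln.seq_b_aligned):
        if ca == "-" or cb == "-":
            continue
        cols += 1
        matches += ca == cb
    coverage = cols / len(consensus_seq)
    identity = matches / cols if cols else 0.0
    return coverage, identity


def family_divergence(copies: Mapping[str, str],
                      consensus: ConsensusElement) -> list[DivergenceRecord]:
    """Per-copy divergence, measured copy-vs-consensus."""
    return [k2p(align_global(consensus.sequence, seq), copy_id=cid)
            for cid, seq in copies.items()]


def landscape(records: Sequence[DivergenceRecord], bin_width: float = 1.0,
              family_id: str = "") -> DivergenceLandscape:
    """Bin each non-saturated copy's aligned bp at its K% (coverage-conserving)."""
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    bins: dict[float, int] = {}
    for r in records:
        if r.saturated:
            continue
        b = math.floor(100.0 * r.K / bin_width) * bin_width
        bins[b] = bins.get(b, 0) + r.aligned_bp
    return DivergenceLandscape(family_id=family_id, bin_width=bin_width, bins=bins)


def landscape_modes(ls: DivergenceLandscape, top: int = 2) -> list[float]:
    """Bin centers of the `top` local coverage maxima, sorted by K."""
    rows = ls.to_rows()
    if not rows:
        return []
    edges = [b for b, _ in rows]
    cov = {b: c for b, c in rows}
    peaks = []
    for b in edges:
        left = cov.get(b - ls.bin_width, 0)
        right = cov.get(b + ls.bin_width, 0)
        if cov[b] >= left and cov[b] >= right:
            peaks.append((cov[b], b))
    peaks.sort(reverse=True)
    centers = sorted(b + ls.bin_width / 2 for _, b in peaks[:top])
    return centers


def flag_young(records: Sequence[DivergenceRecord], threshold: float = 0.02,
               min_young_copies: int = 5,
               min_young_frac: float = 0.10) -> tuple[list[bool], bool]:
    """Per-copy young flags (strict K < threshold) and the family-level
    recently-active call (enough young copies in count or fraction)."""
    flags = [(not r.saturated) and r.K < threshold for r in records]
    n_young = sum(flags)
    active = bool(records) and (n_young >= min_young_copies
                                or n_young / len(records) >= min_young_frac)
    return flags, active


def plot_landscape(landscapes: Sequence[DivergenceLandscape], path: str,
                   max_k: float = 40.0) -> None:
    """Stacked coverage-vs-K% bar chart, one panel per family."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(len(landscapes), 1, squeeze=False,
                             figsize=(8, 2.2 * len(landscapes)))
    for ax, ls in zip(axes.ravel(), landscapes):
        rows = [(b, c) for b, c in ls.to_rows() if b <= max_k]
        if rows:
            xs, ys = zip(*rows)
            ax.bar(xs, ys, width=ls.bin_width, align="edge")
        ax.set_ylabel("coverage (bp)")
        ax.set_title(ls.family_id or "family")
    axes.ravel()[-1].set_xlabel("Kimura divergence (%)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
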