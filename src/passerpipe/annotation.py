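"""Classification of called copies: transposase ORF, catalytic triad, DBD motifs.

An intact Passer copy carries both TIRs and a TSD, plus an ORF encoding a >=300-aa
transposase whose protein contains two DNA-binding-domain motifs (Brk- and HTH-like)
and the DD35D catalytic triad: three aspartates with exactly 35 residues between the
second and the third.  Domain detection uses position-weight-matrix scanning against
user-supplied profiles; family copy numbers are counted against a consensus at the
>40% coverage / >80% identity thresholds.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Seq import Seq

from .discovery import TransposonCopy

log = logging.getLogger(__name__)

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}
_STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class TransposaseORF:
    nt_start: int           # within the element, 0-based
    nt_end: int             # half-open, includes the stop codon
    protein_seq: str
    length_aa: int


@dataclass(frozen=True)
class CatalyticTriad:
    pos_d1: int
    pos_d2: int
    pos_d3: int

    @property
    def spacer23(self) -> int:
        return self.pos_d3 - self.pos_d2 - 1


@dataclass
class MotifProfile:
    """Per-position amino-acid weight matrix with a hit threshold."""
    name: str
    matrix: np.ndarray      # shape (width, 20), columns ordered by AA_ALPHABET
    threshold: float

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @classmethod
    def from_consensus(cls, name: str, consensus: str, match: float = 2.0,
                       other: float = 0.0, threshold_frac: float = 0.8) -> "MotifProfile":
        mat = np.full((len(consensus), 20), other, dtype=float)
        for i, aa in enumerate(consensus):
            mat[i, _AA_INDEX[aa]] = match
        return cls(name=name, matrix=mat, threshold=threshold_frac * match * len(consensus))


@dataclass(frozen=True)
class MotifScan:
    name: str
    score: float
    position: int           # leftmost argmax window start; -1 when not scannable
    hit: bool


@dataclass
class CopyClassification:
    copy_id: str
    category: str           # intact | coding_only | fragment
    reasons: list[str]


# ---------------------------------------------------------------------------
# ORF and domain detection
# ---------------------------------------------------------------------------

def find_longest_orf(element_seq: str, min_aa: int = 300) -> TransposaseORF | None:
    """Longest ATG-to-stop ORF over the three forward frames (sense orientation).

    length_aa excludes the stop codon; returns None when no ORF reaches min_aa.
    """
    seq = element_seq.upper()
    best: tuple[int, int, int] | None = None  # (-aa, start, end) minimized
    for frame in range(3):
        start = None
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i:i + 3]
            if codon in _STOPS:
                if start is not None:
                    aa = (i + 3 - start) // 3 - 1
                    if aa >= min_aa and (best is None or (-aa, start) < best[:2]):
                        best = (-aa, start, i + 3)
                    start = None
            elif codon == "ATG" and start is None:
                start = i
    if best is None:
        return None
    _, s, e = best
    protein = str(Seq(seq[s:e - 3]).translate())
    return TransposaseORF(nt_start=s, nt_end=e, protein_seq=protein,
                          length_aa=(e - s) // 3 - 1)


def find_triad(protein_seq: str, spacer23: int = 35,
               d1_d2_range: tuple[int, int] = (50, 250),
               allow_e_third: bool = False) -> CatalyticTriad | None:
    """First DD(spacer23)D triad: D at i, D at j with j-i in d1_d2_range, and a third
    D (optionally E) exactly spacer23 residues after the second.

    Returns the triad with the smallest i, then smallest j; None when absent.
    """
    if not protein_seq:
        raise ValueError("empty protein")
    p = protein_seq.upper()
    third = "DE" if allow_e_third else "D"
    ds = [i for i, c in enumerate(p) if c == "D"]
    lo, hi = d1_d2_range
    for i in ds:
        for j in ds:
            if j <= i or not lo <= j - i <= hi:
                continue
            k = j + spacer23 + 1
            if k < len(p) and p[k] in third:
                return CatalyticTriad(pos_d1=i, pos_d2=j, pos_d3=k)
    return None


def scan_motif(protein_seq: str, profile: MotifProfile) -> MotifScan:
    """Slide the weight matrix along the protein; hit iff the max score reaches the
    profile threshold.  Leftmost maximal window wins; unknown residues score 0."""
    p = protein_seq.upper()
    w = profile.width
    if len(p) < w:
        log.warning("protein (%d aa) shorter than profile %s (%d); no hit",
                    len(p), profile.name, w)
        return MotifScan(profile.name, float("-inf"), -1, False)
    idx = np.array([_AA_INDEX.get(c, -1) for c in p])
    n_win = len(p) - w + 1
    scores = np.zeros(n_win)
    for offset in range(w):
        col = idx[offset:offset + n_win]
        valid = col >= 0
        scores[valid] += profile.matrix[offset, col[valid]]
    pos = int(np.argmax(scores))
    best = float(scores[pos])
    return MotifScan(profile.name, best, pos, best >= profile.threshold)


# ---------------------------------------------------------------------------
# classification and copy counting
# ---------------------------------------------------------------------------

def classify_copy(copy: TransposonCopy, orf: TransposaseORF | None,
                  triad: CatalyticTriad | None,
                  motif_results: Sequence[MotifScan]) -> CopyClassification:
    """Apply the intactness rule: TIRs + TSD + qualifying ORF + both DBD motifs +
    catalytic triad.  A copy whose protein rules all pass but whose termini are
    incomplete is coding_only; anything else is a fragment."""
    reasons: list[str] = []
    tir_ok = copy.tir is not None
    tsd_ok = copy.tsd is not None
    orf_ok = orf is not None
    triad_ok = triad is not None
    motifs_ok = bool(motif_results) and all(m.hit for m in motif_results)
    reasons.append("TIR pair detected" if tir_ok else "TIR pair not detected")
    reasons.append("TSD detected" if tsd_ok else "TSD not detected")
    reasons.append(f"ORF {orf.length_aa} aa" if orf_ok else "no qualifying ORF")
    reasons.append("DD35D triad found" if triad_ok else "catalytic triad missing")
    for m in motif_results:
        reasons.append(f"motif {m.name} {'hit' if m.hit else 'miss'} (score {m.score:g})")
    coding = orf_ok and triad_ok and motifs_ok
    if coding and tir_ok and tsd_ok:
        category = "intact"
    elif coding:
        category = "coding_only"
    else:
        category = "fragment"
    return CopyClassification(copy_id=copy.copy_id, category=category, reasons=reasons)


def annotate_copy(copy: TransposonCopy, profiles: Sequence[MotifProfile],
                  min_aa: int = 300, spacer23: int = 35,
                  d1_d2_range: tuple[int, int] = (50, 250)) -> CopyClassification:
    """Convenience wrapper running ORF, triad and motif rules then classifying."""
    orf = find_longest_orf(copy.element_seq, min_aa=min_aa)
    triad = None
    scans: list[MotifScan] = []
    if orf is not None:
        triad = find_triad(orf.protein_seq, spacer23=spacer23, d1_d2_range=d1_d2_range)
        scans = [scan_motif(orf.protein_seq, pr) for pr in profiles]
    else:
        scans = [MotifScan(pr.name, float("-inf"), -1, False) for pr in profiles]
    return classify_copy(copy, orf, triad, scans)


def count_copies(copy_stats: Iterable[tuple[float, float]],
                 min_coverage: float = 0.40,
                 min_identity: float = 0.80) -> int:
    """Count copies strictly exceeding both the coverage and identity thresholds.

    copy_stats yields (coverage, identity) per copy, where coverage is aligned bp over
    the consensus length and identity is computed on aligned columns (both 0..1).
    """
    return sum(1 for cov, ident in copy_stats
               if cov > min_coverage and ident > min_identity)


# ---------------------------------------------------------------------------
# profile TSV round-trip
# ---------------------------------------------------------------------------

def write_profile_tsv(profile: MotifProfile, path: str | Path) -> None:
    """Profile format: '#name<TAB>threshold' header, then one row per position with
    20 tab-separated weights ordered by ACDEFGHIKLMNPQRSTVWY."""
    with open(path, "w") as fh:
        fh.write(f"#{profile.name}\t{profile.threshold!r}\n")
        fh.write("\t".join(AA_ALPHABET) + "\n")
        for row in profile.matrix:
            fh.write("\t".join(repr(float(x)) for x in row) + "\n")


def read_profile_tsv(path: str | Path) -> MotifProfile:
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith("#"):
            raise ValueError("profile TSV must start with '#name<TAB>threshold'")
        name, threshold = header[1:].split("\t")
        fh.readline()  # alphabet line
        rows = [[float(x) for x in line.split("\t")] for line in fh if line.strip()]
    return MotifProfile(name=name, matrix=np.array(rows), threshold=float(threshold))
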