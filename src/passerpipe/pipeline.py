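"""End-to-end orchestration: simulate -> discover -> annotate -> dynamics -> insertions.

Every stage reads and writes plain-text interchange files (FASTA/BED/TSV) so runs are
diffable and any stage can be re-run from prior outputs.  All thresholds live in
RunConfig with the family's published defaults; the config (and the seed) is
serialized into every output directory, and identical config + seed reproduces
byte-identical outputs.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import annotation, dynamics, insertions, io, simulate
from .discovery import discover as _discover
from .discovery import revcomp

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    seed: int = 7
    # discovery
    flank_size: int = 2000
    max_evalue: float = 1e-100
    merge_gap: int = 200
    min_hit_identity: float = 0.0
    boundary_slop: int = 30
    # annotation
    min_aa: int = 300
    spacer23: int = 35
    min_coverage: float = 0.40
    min_identity: float = 0.80
    # dynamics
    bin_width: float = 1.0
    young_threshold: float = 0.02
    # insertions
    promoter_bp: int = 1000
    downstream_bp: int = 1000
    tss_halfwidth: int = 3000
    tss_bin: int = 100
    n_groups: int = 8
    n_random: int = 100_000
    random_mode: str = "uniform"
    target_halfwidth: int = 10
    # synthetic inputs (run-all on a generated fixture)
    synthetic: dict[str, Any] = field(default_factory=dict)

    def validate(self) -> None:
        checks = [
            ("flank_size", self.flank_size > 0),
            ("max_evalue", self.max_evalue >= 0),
            ("merge_gap", self.merge_gap >= 0),
            ("boundary_slop", self.boundary_slop >= 0),
            ("min_aa", self.min_aa > 0),
            ("spacer23", self.spacer23 >= 0),
            ("min_coverage", 0.0 <= self.min_coverage <= 1.0),
            ("min_identity", 0.0 <= self.min_identity <= 1.0),
            ("bin_width", self.bin_width > 0),
            ("young_threshold", 0.0 < self.young_threshold < 1.0),
            ("tss_halfwidth", self.tss_halfwidth > 0),
            ("n_groups", self.n_groups >= 1),
            ("n_random", self.n_random > 0),
            ("random_mode", self.random_mode in ("uniform", "ta_matched")),
        ]
        bad = [name for name, ok in checks if not ok]
        if bad:
            raise ValueError(f"invalid config field(s): {', '.join(bad)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config field(s): {', '.join(sorted(unknown))}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


@dataclass
class RunReport:
    stages: dict[str, dict[str, int]] = field(default_factory=dict)

    def record(self, stage: str, **counts: int) -> None:
        self.stages[stage] = dict(counts)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"stages": self.stages}, fh, indent=2, sort_keys=True)
            fh.write("\n")


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

_SYNTH_DEFAULTS = dict(
    genome_length=400_000, gc=0.41, n_chroms=2,
    bursts=[[0.01, 12, 1.0]],
    n_genes=40, n_sites=1000, n_states=5,
    site_genic_fold=2.0,
)


def stage_simulate(cfg: RunConfig, outdir: Path) -> None:
    """Generate the full synthetic fixture: genome with a planted family, homology
    hits, gene models, chromatin states and biased insertion sites."""
    p = {**_SYNTH_DEFAULTS, **cfg.synthetic}
    outdir.mkdir(parents=True, exist_ok=True)
    per = p["genome_length"] // p["n_chroms"]
    lengths = {f"chr{i + 1}": per for i in range(p["n_chroms"])}
    genome = simulate.random_genome(cfg.seed, lengths, gc=p["gc"])
    ancestor = simulate.make_ancestral_element(cfg.seed + 1)
    bursts = [tuple(b) for b in p["bursts"]]
    genome, truth = simulate.plant_family(genome, ancestor, bursts, seed=cfg.seed + 2)
    hits = simulate.hits_from_truth(truth, seed=cfg.seed + 3)
    sizes = {c: len(s) for c, s in genome.items()}
    genes = simulate.make_genes(sizes, p["n_genes"], seed=cfg.seed + 4)
    states = simulate.make_chromatin_states(sizes, n_states=p["n_states"],
                                            seed=cfg.seed + 5)
    bias = simulate.SiteBiasModel(genic_fold=p["site_genic_fold"],
                                  n_sites=p["n_sites"], seed=cfg.seed + 6)
    sites, site_truth = simulate.simulate_sites(genome, genes, bias, label="PS")

    io.write_fasta(genome, outdir / "genome.fa")
    io.write_fasta({"ancestor": ancestor.sequence}, outdir / "ancestor.fa")
    truth.to_csv(outdir / "truth_copies.tsv", sep="\t", index=False)
    io.write_blast_tab(hits, outdir / "hits.tsv")
    io.write_genes_tsv(genes, outdir / "genes.tsv")
    io.write_states_bed(states, outdir / "states.bed")
    io.write_sites_bed(sites, outdir / "sites.bed")
    site_truth.to_csv(outdir / "truth_sites.tsv", sep="\t", index=False)


def stage_discover(cfg: RunConfig, genome_path: Path, hits_path: Path,
                   outdir: Path) -> tuple[int, int]:
    outdir.mkdir(parents=True, exist_ok=True)
    genome = io.read_fasta(genome_path)
    hits = io.read_blast_tab(hits_path)
    copies = _discover(genome, hits, flank_size=cfg.flank_size,
                       max_gap=cfg.merge_gap, min_identity=cfg.min_hit_identity,
                       max_evalue=cfg.max_evalue, boundary_slop=cfg.boundary_slop)
    rows = []
    seqs = {}
    for i, c in enumerate(copies):
        cid = f"copy{i:04d}"
        c.copy_id = cid
        rows.append({
            "chrom": c.locus.chrom, "start": c.element_start, "end": c.element_end,
            "name": cid, "score": c.boundary_score, "strand": c.locus.strand,
            "tir_len": c.tir.length if c.tir else 0,
            "tir_mismatches": c.tir.mismatches if c.tir else 0,
            "tsd_seq": c.tsd.sequence if c.tsd else "",
        })
        seqs[cid] = c.element_seq
    pd.DataFrame(rows).to_csv(outdir / "copies.bed", sep="\t", index=False,
                              header=False)
    io.write_fasta(seqs, outdir / "elements.fa")
    return len(hits), len(copies)


def stage_annotate(cfg: RunConfig, elements_path: Path, outdir: Path,
                   copies_bed: Path) -> pd.DataFrame:
    """Classify each called copy and emit the per-copy table + family summary."""
    outdir.mkdir(parents=True, exist_ok=True)
    elements = io.read_fasta(elements_path)
    bed = pd.read_csv(copies_bed, sep="\t", header=None,
                      names=["chrom", "start", "end", "name", "score", "strand",
                             "tir_len", "tir_mismatches", "tsd_seq"],
                      dtype={"tsd_seq": str}, keep_default_na=False)
    profiles = simulate.toy_profiles()
    rows = []
    for rec in bed.itertuples(index=False):
        seq = elements[rec.name]
        orf = annotation.find_longest_orf(seq, min_aa=cfg.min_aa)
        triad = (annotation.find_triad(orf.protein_seq, spacer23=cfg.spacer23)
                 if orf else None)
        scans = ([annotation.scan_motif(orf.protein_seq, pr) for pr in profiles]
                 if orf else [])
        tir_ok = rec.tir_len > 0
        tsd_ok = bool(rec.tsd_seq)
        coding = orf is not None and triad is not None and bool(scans) \
            and all(m.hit for m in scans)
        if coding and tir_ok and tsd_ok:
            cat = "intact"
        elif coding:
            cat = "coding_only"
        else:
            cat = "fragment"
        rows.append({
            "copy_id": rec.name, "category": cat,
            "orf_aa": orf.length_aa if orf else 0,
            "triad": "/".join(map(str, (triad.pos_d1, triad.pos_d2, triad.pos_d3)))
                     if triad else "",
            "motif_scores": ";".join(f"{m.name}={m.score:g}" for m in scans),
        })
    df = pd.DataFrame(rows)
    df.to_csv(outdir / "classification.tsv", sep="\t", index=False)
    return df


def stage_dynamics(cfg: RunConfig, elements_path: Path,
                   classification: pd.DataFrame, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    elements = io.read_fasta(elements_path)
    intact_ids = list(classification.loc[classification.category == "intact",
                                         "copy_id"])
    if not intact_ids:
        log.warning("no intact copies; skipping dynamics stage")
        (outdir / "divergence.tsv").write_text(
            "copy_id\tP\tQ\tK\tvalid_columns\taligned_bp\tsaturated\tyoung\n")
        return
    intact = {cid: elements[cid] for cid in intact_ids}
    consensus = dynamics.build_consensus([intact[c] for c in intact_ids],
                                         reference=intact[intact_ids[0]])
    io.write_fasta({"consensus": consensus.sequence}, outdir / "consensus.fa")
    records = dynamics.family_divergence(
        {cid: seq for cid, seq in elements.items()}, consensus)
    young, active = dynamics.flag_young(records, threshold=cfg.young_threshold)
    rows = [{
        "copy_id": r.copy_id, "P": round(r.P, 6), "Q": round(r.Q, 6),
        "K": "" if r.saturated else round(r.K, 6),
        "valid_columns": r.valid_columns, "aligned_bp": r.aligned_bp,
        "saturated": r.saturated, "young": y,
    } for r, y in zip(records, young)]
    pd.DataFrame(rows).to_csv(outdir / "divergence.tsv", sep="\t", index=False)
    ls = dynamics.landscape(records, bin_width=cfg.bin_width, family_id="family")
    pd.DataFrame(ls.to_rows(), columns=["bin_low_pct", "coverage_bp"]).to_csv(
        outdir / "landscape.tsv", sep="\t", index=False)
    stats = [dynamics.copy_alignment_stats(seq, consensus.sequence)
             for seq in elements.values()]
    total = annotation.count_copies(stats, min_coverage=cfg.min_coverage,
                                    min_identity=cfg.min_identity)
    summary = pd.DataFrame([{
        "total_copies": total,
        "intact_copies": len(intact_ids),
        "consensus_length": len(consensus.sequence),
        "consensus_mode": consensus.mode,
        "recently_active": active,
        "n_young": sum(young),
    }])
    summary.to_csv(outdir / "family_summary.tsv", sep="\t", index=False)


def stage_insertions(cfg: RunConfig, genome_path: Path, sites_path: Path,
                     genes_path: Path, states_path: Path, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    genome = io.read_fasta(genome_path)
    sites = io.read_sites_bed(sites_path)
    genes = io.read_genes_tsv(genes_path)
    states = io.read_states_bed(states_path)
    sizes = {c: len(s) for c, s in genome.items()}
    randoms = insertions.generate_random_loci(
        sizes, n=cfg.n_random, seed=cfg.seed, mode=cfg.random_mode, genome=genome)
    by_sample: dict[str, list] = {"random": randoms}
    for s in sites:
        by_sample.setdefault(s.sample_label, []).append(s)

    fd = insertions.feature_distribution(by_sample, genes,
                                         promoter_bp=cfg.promoter_bp,
                                         downstream_bp=cfg.downstream_bp)
    fd.to_csv(outdir / "feature_distribution.tsv", sep="\t", index=False)

    frac, skipped = insertions.gene_body_decile(sites, genes)
    pd.DataFrame({"decile": range(10), "fraction": frac}).to_csv(
        outdir / "gene_body_deciles.tsv", sep="\t", index=False)

    edges, counts = insertions.tss_profile(sites, genes,
                                           halfwidth=cfg.tss_halfwidth,
                                           bin_bp=cfg.tss_bin)
    pd.DataFrame({"offset_bp": edges, "count": counts}).to_csv(
        outdir / "tss_profile.tsv", sep="\t", index=False)

    expr = insertions.expression_binned_frequency(sites, genes,
                                                  n_groups=cfg.n_groups)
    expr.to_csv(outdir / "expression_groups.tsv", sep="\t", index=False)

    enr = insertions.chromatin_state_enrichment(sites, states, randoms)
    pd.DataFrame([{
        "state": e.label, "obs_count": e.obs_count, "bg_count": e.bg_count,
        "fold": "" if e.fold is None else round(e.fold, 4),
        "p_value": e.p_value, "stars": e.stars,
    } for e in enr]).to_csv(outdir / "chromatin_enrichment.tsv", sep="\t",
                            index=False)

    tsm = insertions.target_site_matrix(sites, genome,
                                        halfwidth=cfg.target_halfwidth)
    mat = pd.DataFrame(tsm.counts, columns=list("ACGT"))
    mat.insert(0, "offset", range(-cfg.target_halfwidth,
                                  cfg.target_halfwidth + 2))
    mat.to_csv(outdir / "target_site_matrix.tsv", sep="\t", index=False)
    with open(outdir / "target_site_consensus.tsv", "w") as fh:
        fh.write("consensus\tpalindrome_score\tn_sites\n")
        fh.write(f"{tsm.consensus}\t{tsm.palindrome_score}\t{tsm.n_sites}\n")


def run_pipeline(cfg: RunConfig, outdir: str | Path) -> RunReport:
    """Run every stage on the synthetic fixture described by cfg.synthetic."""
    cfg.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport()

    sim = out / "simulate"
    stage_simulate(cfg, sim)
    truth = pd.read_csv(sim / "truth_copies.tsv", sep="\t")
    report.record("simulate", planted_copies=len(truth))

    disc = out / "discover"
    n_hits, n_copies = stage_discover(cfg, sim / "genome.fa", sim / "hits.tsv", disc)
    report.record("discover", hits_in=n_hits, copies_out=n_copies,
                  dropped=n_hits - n_copies)

    ann = out / "annotate"
    classification = stage_annotate(cfg, disc / "elements.fa", ann,
                                    disc / "copies.bed")
    report.record("annotate", copies_in=n_copies,
                  intact=int((classification.category == "intact").sum()),
                  coding_only=int((classification.category == "coding_only").sum()),
                  fragment=int((classification.category == "fragment").sum()))

    dyn = out / "dynamics"
    stage_dynamics(cfg, disc / "elements.fa", classification, dyn)
    report.record("dynamics", copies_in=n_copies)

    ins = out / "insertions"
    stage_insertions(cfg, sim / "genome.fa", sim / "sites.bed",
                     sim / "genes.tsv", sim / "states.bed", ins)
    n_sites = len(io.read_sites_bed(sim / "sites.bed"))
    report.record("insertions", sites_in=n_sites, random_loci=cfg.n_random)

    cfg.to_yaml(out / "config.yaml")
    report.to_json(out / "run_report.json")
    return report
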