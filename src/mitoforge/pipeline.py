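"""End-to-end pipeline driver: simulate -> assemble -> numt -> capture ->
diversity -> parsimony, with a manifest of every artifact written.

Every stage draws its randomness from seeds derived deterministically from
the global seed, so re-running a configuration reproduces identical files
(checksums are recorded in the manifest).
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as mio
from .assemble import AssemblyConfig, assemble_mitogenome
from .capture import call_consensus, design_baits, place_reads
from .diversity import (AlignmentMatrix, block_density, identity_matrix,
                        nucleotide_diversity, pairwise_differences)
from .numt import NumtConfig, calibrate_identity_threshold, filter_and_dedupe, \
    local_search, summarize_numts
from .parsimony import Tree, homoplasy_indices
from .seqs import CircularSequence
from .synth import (MitogenomeSpec, ReadProfile, generate_mitogenome,
                    mutate_substitutions, plant_numts, default_primer_tiling,
                    simulate_pcr_evidence, simulate_reads)

log = logging.getLogger("mitoforge")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "mitoforge_out"
    stages: tuple[str, ...] = ("simulate", "assemble", "numt", "capture",
                               "diversity", "parsimony")
    genome: MitogenomeSpec = field(default_factory=MitogenomeSpec)
    coverage: float = 100.0
    n_long: int = 3
    long_error: float = 0.10
    background_length: int = 200_000
    n_numts: int = 8
    numt_length_range: tuple[int, int] | None = None   # default (54, 5499) clamped
    n_individuals: int = 6
    individual_divergence: float = 0.002
    capture_coverage: float = 40.0
    assembly: AssemblyConfig = field(default_factory=AssemblyConfig)
    numt_config: NumtConfig = field(default_factory=NumtConfig)


def _sha(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _derive_seed(seed: int, salt: str) -> int:
    h = hashlib.sha256(f"{seed}:{salt}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def _cr_block_span(features) -> tuple[int, int]:
    crs = [f for f in features if f.name in ("CR1", "CR2")]
    start = min(f.start for f in crs)
    end = max(f.end for f in crs)
    margin = 300
    return max(0, start - margin), end + margin


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the requested stages in dependency order; returns (and writes)
    a manifest mapping artifact names to paths and checksums."""
    cfg = config
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    state: dict = {}

    stage_order = ["simulate", "assemble", "numt", "capture", "diversity",
                   "parsimony"]
    todo = [s for s in stage_order if s in cfg.stages]
    for stage in todo:
        log.info("running stage %s (seed %d)", stage, cfg.seed)
        try:
            _STAGES[stage](cfg, out, state, artifacts)
        except Exception as exc:     # noqa: BLE001 - re-raised typed
            raise PipelineError(stage, exc) from exc

    manifest = {
        "seed": cfg.seed,
        "outdir": str(out),
        "stages": todo,
        "artifacts": {name: {"path": str(p), "sha256": _sha(p)}
                      for name, p in sorted(artifacts.items())},
    }
    mio.write_json(out / "manifest.json", manifest)
    return manifest


def _stage_simulate(cfg, out, state, artifacts) -> None:
    spec = dataclasses.replace(cfg.genome, rng_seed=_derive_seed(cfg.seed, "genome"))
    genome, features = generate_mitogenome(spec)
    state["genome"] = genome
    state["features"] = features
    mio.write_fasta(out / "mitogenome.fasta", genome)
    mio.write_feature_table(out / "features.tsv", features)
    artifacts["mitogenome"] = out / "mitogenome.fasta"
    artifacts["features"] = out / "features.tsv"

    length_range = cfg.numt_length_range or (54, min(5499, genome.length))
    background = plant_numts(cfg.background_length, genome, cfg.n_numts,
                             length_range=length_range,
                             seed=_derive_seed(cfg.seed, "numts"))
    state["background"] = background
    mio.write_fasta(out / "nuclear_background.fasta",
                    [("nuclear_background", background.seq)])
    mio.write_numt_truth(out / "numt_truth.tsv", background)
    artifacts["nuclear_background"] = out / "nuclear_background.fasta"
    artifacts["numt_truth"] = out / "numt_truth.tsv"

    profile = ReadProfile(coverage=cfg.coverage, n_long=cfg.n_long,
                          long_error=cfg.long_error,
                          long_span=_cr_block_span(features))
    reads = simulate_reads(genome, profile, seed=_derive_seed(cfg.seed, "reads"))
    state["reads"] = reads
    artifacts.update({k: Path(v) for k, v in
                      mio.write_read_set(reads, out / "reads").items()})

    pairs = default_primer_tiling(genome)
    evidence = simulate_pcr_evidence(genome, pairs,
                                     insert_model=(profile.insert_mean,
                                                   profile.insert_sd),
                                     long_reads=reads.long_reads)
    state["evidence"] = evidence
    mio.write_amplicon_table(out / "amplicons.tsv", evidence)
    artifacts["amplicons"] = out / "amplicons.tsv"


def _stage_assemble(cfg, out, state, artifacts) -> None:
    acfg = dataclasses.replace(
        cfg.assembly,
        mito_cov_estimate=cfg.assembly.mito_cov_estimate or cfg.coverage,
        autosomal_cov_estimate=cfg.assembly.autosomal_cov_estimate or 1.0)
    report = assemble_mitogenome(state["reads"], state["genome"],
                                 state["features"], state["evidence"], acfg)
    state["assembly_report"] = report
    mio.write_fasta(out / "assembly.fasta", report.assembled)
    mio.write_json(out / "assembly_report.json", report)
    mio.write_bed_track(out / "forks.bed", "fork events",
                        [(report.assembled.id, f.position, f.position + 1,
                          "resolved" if not f.ambiguous else "ambiguous")
                         for f in report.forks])
    artifacts["assembly"] = out / "assembly.fasta"
    artifacts["assembly_report"] = out / "assembly_report.json"
    artifacts["forks"] = out / "forks.bed"


def _stage_numt(cfg, out, state, artifacts) -> None:
    genome = state["genome"]
    hits = local_search(genome, [("nuclear_background", state["background"].seq)],
                        cfg.numt_config)
    # calibrate on a small synthetic congener panel around the genome
    rng = np.random.default_rng(_derive_seed(cfg.seed, "panel"))
    panel = [("self", genome.seq)]
    for i, div in enumerate((0.03, 0.08)):
        panel.append((f"congener{i}",
                      mutate_substitutions(genome.seq,
                                           round(div * genome.length), rng)))
    threshold = calibrate_identity_threshold(panel)
    cfg.numt_config.identity_threshold = threshold
    kept = filter_and_dedupe(hits, threshold)
    report = summarize_numts(kept, len(state["background"].seq), cfg.numt_config)
    state["numt_hits"] = kept
    state["numt_report"] = report
    mio.write_numt_hits(out / "numt_hits.tsv", kept)
    mio.write_json(out / "numt_report.json", report)
    artifacts["numt_hits"] = out / "numt_hits.tsv"
    artifacts["numt_report"] = out / "numt_report.json"


def _stage_capture(cfg, out, state, artifacts) -> None:
    genome = state["genome"]
    baits = design_baits(genome)
    mio.write_fasta(out / "baits.fasta",
                    [(f"bait{idx:05d}", seq) for idx, (s, seq) in enumerate(baits.baits)])
    mio.write_bed_track(out / "baits.bed", "baits",
                        [(genome.id, s, s + baits.bait_length, f"bait{idx:05d}")
                         for idx, (s, _) in enumerate(baits.baits)])
    artifacts["baits"] = out / "baits.fasta"
    artifacts["baits_bed"] = out / "baits.bed"

    rng = np.random.default_rng(_derive_seed(cfg.seed, "individuals"))
    consensi = []
    for i in range(cfg.n_individuals):
        n_mut = round(cfg.individual_divergence * genome.length) if i else 0
        indiv = CircularSequence(
            f"indiv{i:02d}", mutate_substitutions(genome.seq, n_mut, rng))
        reads = simulate_reads(indiv,
                               ReadProfile(coverage=cfg.capture_coverage),
                               seed=_derive_seed(cfg.seed, f"cap{i}"))
        placements = place_reads(reads, genome)
        cons = call_consensus(placements, genome, individual_id=indiv.id)
        consensi.append(cons)
    state["consensi"] = consensi
    mio.write_fasta(out / "consensus.fasta",
                    [(c.individual_id, c.seq) for c in consensi])
    mio.write_depth_track(out / "depth_indiv00.tsv", genome.id,
                          consensi[0].depth)
    artifacts["consensus"] = out / "consensus.fasta"
    artifacts["depth_indiv00"] = out / "depth_indiv00.tsv"


def _stage_diversity(cfg, out, state, artifacts) -> None:
    consensi = state["consensi"]
    aln = AlignmentMatrix.from_sequences(
        [(c.individual_id, c.seq) for c in consensi])
    state["alignment"] = aln
    ref, other = aln.taxa[0], aln.taxa[-1]
    diffs = pairwise_differences(aln, ref, other)
    track = block_density(diffs, aln.length)
    pi = nucleotide_diversity(aln)
    ident = identity_matrix(aln)
    state["pi"] = pi
    mio.write_difference_csv(out / "differences.csv", diffs)
    mio.write_density_track(out / "density.bed", ref, track)
    with open(out / "identity_matrix.csv", "w") as fh:
        fh.write("," + ",".join(aln.taxa) + "\n")
        for t, row in zip(aln.taxa, ident):
            fh.write(t + "," + ",".join(f"{v:.4f}" for v in row) + "\n")
    mio.write_json(out / "diversity.json",
                   {"pi": pi, "n_taxa": len(aln.taxa),
                    "n_differences": diffs and len(diffs.positions)})
    for name in ("differences.csv", "density.bed", "identity_matrix.csv",
                 "diversity.json"):
        artifacts[name.split(".")[0]] = out / name


def _stage_parsimony(cfg, out, state, artifacts) -> None:
    aln = state["alignment"]
    taxa = aln.taxa
    newick = _caterpillar(taxa)
    (out / "topology.nwk").write_text(newick + "\n")
    tree = Tree.from_newick(newick)
    stats_all = homoplasy_indices(tree, aln, sites="all")
    stats_inf = homoplasy_indices(tree, aln, sites="informative")
    mio.write_json(out / "parsimony.json",
                   {"all_sites": stats_all, "informative_sites": stats_inf})
    artifacts["topology"] = out / "topology.nwk"
    artifacts["parsimony"] = out / "parsimony.json"


def _caterpillar(taxa: list[str]) -> str:
    inner = f"({taxa[0]},{taxa[1]})"
    for t in taxa[2:]:
        inner = f"({inner},{t})"
    return inner + ";"


_STAGES = {
    "simulate": _stage_simulate,
    "assemble": _stage_assemble,
    "numt": _stage_numt,
    "capture": _stage_capture,
    "diversity": _stage_diversity,
    "parsimony": _stage_parsimony,
}
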