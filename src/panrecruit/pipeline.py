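"""End-to-end orchestration: simulate -> qc -> pangenome -> recruit -> lca
-> diversity, as one reproducible, seeded run with a machine-readable
manifest.

A run simulates one community (taxonomy, reference genes, a second
"database" strain per species for pan-genome construction, an environmental
strain that the reads are drawn from, and a host genome) and any number of
samples — independent abundance draws over the same species set, mirroring
a trap-versus-surroundings comparison.  Each stage writes its outputs under
the run directory and records a parameter hash plus output checksums in
``run_manifest.json``; identical config + seed reproduce identical bytes.

One global seed fans out to per-stage streams through fixed offsets, so a
stage can be rerun in isolation and still match a full run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import __version__
from .errors import PipelineError
from .pangenome import ClusterParams, GeneSequence, build_pangenomes
from .qc import QcParams, host_subtract, merge_pairs, quality_filter
from .recruit import (
    profile,
    recruit_reads,
    recruitment_plot_points,
    write_hits_tsv,
    write_summary_tsv,
)
from .simulate import (
    SimulationConfig,
    mutate_strain,
    simulate_host_genome,
    simulate_reads,
    simulate_reference_genes,
    simulate_taxonomy,
    species_ids,
    write_reference_fasta,
)
from .stats import alpha_diversity, complete_linkage, differential_abundance
from .taxonomy import assign_read, rank_profile, write_assignments, write_profile

logger = logging.getLogger("panrecruit")

STAGES = ("simulate", "qc", "pangenome", "recruit", "lca", "diversity")
# fixed per-stage seed offsets (global seed fans out through these)
_STAGE_SEED = {name: 10 * (i + 1) for i, name in enumerate(STAGES)}


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimBlock(_Block):
    n_species: int = Field(5, ge=1)
    genes_per_species: int = Field(20, ge=1)
    gene_length_range: tuple[int, int] = (400, 900)
    strain_divergence: float = Field(0.08, ge=0.0, le=0.15)
    db_strain_divergence: float = Field(0.05, ge=0.0, le=0.15)
    abundance_lognormal_mu: float = 0.0
    abundance_lognormal_sigma: float = Field(1.5, gt=0.0)
    n_read_pairs: int = Field(4000, ge=1)
    read_length: int = Field(250, ge=30)
    fragment_length_mean: int = Field(350, ge=30)
    fragment_length_sd: float = Field(40.0, ge=0.0)
    error_rate: float = Field(0.0005, ge=0.0, le=0.05)
    host_fraction: float = Field(0.1, ge=0.0, le=1.0)
    host_genome_length: int = Field(50_000, ge=1000)
    n_samples: int = Field(2, ge=1)
    genera: Optional[int] = None


class QcBlock(_Block):
    q_threshold: int = Field(30, ge=0, le=60)
    min_pass_fraction: float = Field(0.98, gt=0.0, le=1.0)
    min_overlap: int = Field(10, ge=1)
    max_overlap_mismatch_rate: float = Field(0.25, ge=0.0, le=1.0)
    host_min_identity: float = Field(0.9, gt=0.0, le=1.0)
    host_min_read_fraction: float = Field(0.8, gt=0.0, le=1.0)


class ClusterBlock(_Block):
    identity_threshold: float = Field(0.90, ge=0.5, le=1.0)
    word_size: int = Field(8, ge=4)


class RecruitBlock(_Block):
    min_identity: float = Field(0.7, gt=0.0, le=1.0)
    min_read_fraction: float = Field(0.8, gt=0.0, le=1.0)
    seed_length: int = Field(15, ge=8)


class LcaBlock(_Block):
    top_percent: float = Field(0.10, gt=0.0, le=1.0)
    min_score: float = 50.0


class StatsBlock(_Block):
    n_perm: int = Field(999, ge=99)
    rank: str = "family"
    n_pseudo_replicates: int = Field(4, ge=2)

    @field_validator("rank")
    @classmethod
    def _rank_valid(cls, v: str) -> str:
        from .taxonomy import RANKS

        if v not in RANKS:
            raise ValueError(f"unknown rank {v!r}")
        return v


class RunConfig(_Block):
    """Validated pipeline configuration; unknown keys are rejected."""

    seed: int = 0
    simulate: SimBlock = Field(default_factory=SimBlock)
    qc: QcBlock = Field(default_factory=QcBlock)
    pangenome: ClusterBlock = Field(default_factory=ClusterBlock)
    recruit: RecruitBlock = Field(default_factory=RecruitBlock)
    lca: LcaBlock = Field(default_factory=LcaBlock)
    stats: StatsBlock = Field(default_factory=StatsBlock)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)


def _params_hash(block: BaseModel) -> str:
    payload = json.dumps(block.model_dump(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _file_hashes(paths: list[Path], root: Path) -> dict[str, str]:
    return {
        str(p.relative_to(root)): hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(paths)
    }


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute all stages in order and return (and write) the run manifest.

    A stage failure halts the run: partial outputs are retained, the
    manifest records the failing stage with a FAILED status, and a
    PipelineError naming the stage is raised.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "stages": [],
    }
    state: dict = {}
    stage_fns = {
        "simulate": _stage_simulate,
        "qc": _stage_qc,
        "pangenome": _stage_pangenome,
        "recruit": _stage_recruit,
        "lca": _stage_lca,
        "diversity": _stage_diversity,
    }
    blocks = {
        "simulate": config.simulate,
        "qc": config.qc,
        "pangenome": config.pangenome,
        "recruit": config.recruit,
        "lca": config.lca,
        "diversity": config.stats,
    }
    try:
        for name in STAGES:
            logger.info("stage %s: start", name)
            try:
                outputs = stage_fns[name](config, state, out)
            except Exception as exc:
                manifest["stages"].append(
                    {
                        "name": name,
                        "status": "FAILED",
                        "params_hash": _params_hash(blocks[name]),
                        "error": str(exc),
                    }
                )
                (out / "FAILED").write_text(f"stage {name}: {exc}\n")
                _write_manifest(manifest, out)
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            manifest["stages"].append(
                {
                    "name": name,
                    "status": "PASS",
                    "params_hash": _params_hash(blocks[name]),
                    "outputs": _file_hashes(outputs, out),
                }
            )
            logger.info("stage %s: done (%d outputs)", name, len(outputs))
        _write_manifest(manifest, out)
        return manifest
    finally:
        logger.removeHandler(handler)
        handler.close()


def _write_manifest(manifest: dict, out: Path) -> None:
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# stages


def _sim_config(config: RunConfig) -> SimulationConfig:
    s = config.simulate
    return SimulationConfig(
        n_species=s.n_species,
        genes_per_species=s.genes_per_species,
        gene_length_range=s.gene_length_range,
        strain_divergence=s.strain_divergence,
        abundance_lognormal_mu=s.abundance_lognormal_mu,
        abundance_lognormal_sigma=s.abundance_lognormal_sigma,
        n_read_pairs=s.n_read_pairs,
        read_length=s.read_length,
        fragment_length_mean=s.fragment_length_mean,
        fragment_length_sd=s.fragment_length_sd,
        error_rate=s.error_rate,
        host_fraction=s.host_fraction,
        host_genome_length=s.host_genome_length,
        seed=config.seed + _STAGE_SEED["simulate"],
    )


def _sample_names(n: int) -> list[str]:
    return [f"sample_{i}" for i in range(n)]


def _stage_simulate(config: RunConfig, state: dict, out: Path) -> list[Path]:
    s = config.simulate
    sim = _sim_config(config)
    genera = s.genera or max(1, s.n_species // 3)
    taxonomy = simulate_taxonomy(s.n_species, genera, seed=sim.seed)
    refs = simulate_reference_genes(sim)
    db_strains = {
        sp: mutate_strain(refs[sp], s.db_strain_divergence, seed=[sim.seed, 20, i])
        for i, sp in enumerate(species_ids(s.n_species))
    }
    env_strains = {
        sp: mutate_strain(refs[sp], sim.divergences[i], seed=[sim.seed, 21, i])
        for i, sp in enumerate(species_ids(s.n_species))
    }
    host = simulate_host_genome(s.host_genome_length, seed=[sim.seed, 2])

    outputs: list[Path] = []
    taxonomy.to_tsv(out / "taxonomy.tsv")
    outputs.append(out / "taxonomy.tsv")
    write_reference_fasta(refs, out / "refs")
    outputs += sorted((out / "refs").glob("*.fasta"))

    samples = {}
    for i, name in enumerate(_sample_names(s.n_samples)):
        reads, truth = simulate_reads(sim, env_strains, host, sample_key=i)
        r1 = out / f"reads_{name}_R1.fastq"
        r2 = out / f"reads_{name}_R2.fastq"
        reads.write(r1, r2)
        truth_path = out / f"truth_{name}.tsv"
        truth.to_tsv(truth_path)
        outputs += [r1, r2, truth_path]
        samples[name] = (reads, truth)

    state.update(
        taxonomy=taxonomy, refs=refs, db_strains=db_strains,
        env_strains=env_strains, host=host, samples=samples, sim=sim,
    )
    return outputs


def _stage_qc(config: RunConfig, state: dict, out: Path) -> list[Path]:
    q = config.qc
    params = QcParams(
        q_threshold=q.q_threshold,
        min_pass_fraction=q.min_pass_fraction,
        min_overlap=q.min_overlap,
        max_overlap_mismatch_rate=q.max_overlap_mismatch_rate,
    )
    outputs: list[Path] = []
    qc_reads = {}
    report_rows = []
    for name, (reads, _) in state["samples"].items():
        merged, n_failed = merge_pairs(
            reads.r1, reads.r2, reads.quality, reads.ids, params
        )
        passed = [r for r in merged if quality_filter(r, params)]
        kept, removed = host_subtract(
            passed,
            [("host", state["host"])],
            min_identity=q.host_min_identity,
            min_read_fraction=q.host_min_read_fraction,
            seed_length=config.recruit.seed_length,
        )
        qc_reads[name] = kept
        report_rows.append(
            (name, len(reads), n_failed, len(passed), removed["host"], len(kept))
        )
        from .io import write_fastq

        path = out / f"qc_{name}.fastq"
        write_fastq(kept, path)
        outputs.append(path)
    report = pd.DataFrame(
        report_rows,
        columns=["sample", "pairs", "merge_failed", "qc_passed", "host_removed", "kept"],
    )
    report.to_csv(out / "qc_report.tsv", sep="\t", index=False)
    outputs.append(out / "qc_report.tsv")
    state["qc_reads"] = qc_reads
    return outputs


def _stage_pangenome(config: RunConfig, state: dict, out: Path) -> list[Path]:
    params = ClusterParams(
        identity_threshold=config.pangenome.identity_threshold,
        word_size=config.pangenome.word_size,
    )
    genes: list[GeneSequence] = []
    for sp in sorted(state["refs"]):
        for gid, seq in sorted(state["refs"][sp].items()):
            genes.append(GeneSequence(gid, sp, "ref", seq))
        for gid, seq in sorted(state["db_strains"][sp].items()):
            genes.append(GeneSequence(f"{gid}_b1", sp, "db1", seq))
    pangenomes = build_pangenomes(genes, params)
    outputs: list[Path] = []
    pg_dir = out / "pangenomes"
    pg_dir.mkdir(exist_ok=True)
    for sp, pg in sorted(pangenomes.items()):
        pg.write_fasta(pg_dir / f"{sp}.pangenome.fasta")
        pg.write_clusters_tsv(pg_dir / f"{sp}.clusters.tsv")
        outputs += [pg_dir / f"{sp}.pangenome.fasta", pg_dir / f"{sp}.clusters.tsv"]
    state["pangenomes"] = pangenomes
    return outputs


def _stage_recruit(config: RunConfig, state: dict, out: Path) -> list[Path]:
    r = config.recruit
    pangenomes = [state["pangenomes"][sp] for sp in sorted(state["pangenomes"])]
    outputs: list[Path] = []
    recruited = {}
    for name, reads in state["qc_reads"].items():
        grouped = recruit_reads(
            ((rd.id, rd.sequence) for rd in reads),
            pangenomes,
            min_identity=r.min_identity,
            min_read_fraction=r.min_read_fraction,
            seed_length=r.seed_length,
        )
        recruited[name] = grouped
        profiles = [profile(grouped[pg.species_id], pg) for pg in pangenomes]
        write_summary_tsv(profiles, out / f"recruitment_summary_{name}.tsv")
        outputs.append(out / f"recruitment_summary_{name}.tsv")
        all_hits = [h for pg in pangenomes for h in grouped[pg.species_id]]
        write_hits_tsv(all_hits, out / f"hits_{name}.tsv")
        outputs.append(out / f"hits_{name}.tsv")
        points = pd.concat(
            [
                recruitment_plot_points(grouped[pg.species_id], pg).assign(
                    species_id=pg.species_id
                )
                for pg in pangenomes
            ],
            ignore_index=True,
        )
        points.to_csv(out / f"plot_points_{name}.tsv", sep="\t", index=False)
        outputs.append(out / f"plot_points_{name}.tsv")
        with open(out / f"consensus_{name}.fasta", "w") as fh:
            for pg, prof in zip(pangenomes, profiles):
                fh.write(f">{pg.species_id}_consensus\n{prof.consensus}\n")
        outputs.append(out / f"consensus_{name}.fasta")
    state["recruited"] = recruited
    return outputs


def _stage_lca(config: RunConfig, state: dict, out: Path) -> list[Path]:
    tree = state["taxonomy"].pad_ranks()
    outputs: list[Path] = []
    profiles = {}
    assignments_by_sample = {}
    for name, grouped in state["recruited"].items():
        by_read: dict[str, list[tuple[str, float]]] = {}
        for sp, hits in grouped.items():
            for h in hits:
                by_read.setdefault(h.read_id, []).append((sp, h.score))
        assignments = []
        for read_id in sorted(by_read):
            a = assign_read(
                by_read[read_id],
                tree,
                top_percent=config.lca.top_percent,
                min_score=config.lca.min_score,
                read_id=read_id,
            )
            if a is not None:
                assignments.append(a)
        assignments_by_sample[name] = assignments
        write_assignments(assignments, out / f"assignments_{name}.tsv")
        outputs.append(out / f"assignments_{name}.tsv")
        prof = rank_profile(assignments, tree, config.stats.rank)
        write_profile(prof, out / f"profile_{config.stats.rank}_{name}.tsv")
        outputs.append(out / f"profile_{config.stats.rank}_{name}.tsv")
        profiles[name] = rank_profile(assignments, tree, "species")
    state["species_profiles"] = profiles
    state["taxonomy_padded"] = tree
    return outputs


def _stage_diversity(config: RunConfig, state: dict, out: Path) -> list[Path]:
    profiles = state["species_profiles"]
    table = pd.DataFrame(profiles).fillna(0).astype(int)
    table = table.loc[sorted(table.index), sorted(table.columns)]
    table.index.name = "species"
    outputs: list[Path] = []
    table.to_csv(out / "species_counts.tsv", sep="\t")
    outputs.append(out / "species_counts.tsv")

    rows = []
    for name in table.columns:
        rep = alpha_diversity(table[name])
        rows.append(
            (name, rep.s_obs, round(rep.chao1, 6), round(rep.shannon, 6),
             round(rep.simpson_lambda, 6), round(rep.gini_simpson, 6))
        )
    pd.DataFrame(
        rows,
        columns=["sample", "s_obs", "chao1", "shannon", "simpson_lambda", "gini_simpson"],
    ).to_csv(out / "diversity.tsv", sep="\t", index=False)
    outputs.append(out / "diversity.tsv")

    if table.shape[1] >= 2:
        newick = complete_linkage(table)
        (out / "dendrogram.nwk").write_text(newick + "\n")
        outputs.append(out / "dendrogram.nwk")
        names = sorted(table.columns)
        half = max(1, len(names) // 2)
        res = differential_abundance(
            table,
            names[:half],
            names[half:],
            n_perm=config.stats.n_perm,
            seed=config.seed + _STAGE_SEED["diversity"],
            n_pseudo=config.stats.n_pseudo_replicates,
        )
        res.round(6).to_csv(out / "diffabund.tsv", sep="\t")
        outputs.append(out / "diffabund.tsv")
    return outputs
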