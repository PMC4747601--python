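"""Synthetic community generator with known ground truth.

Emulates the statistical structure the downstream analysis assumes: a
multi-species community with log-normal abundances (a few dominant taxa, a
long tail), per-species environmental strains diverged from their reference
genes by point substitutions, substitution-dominated sequencing error with a
constant Phred quality, and a configurable fraction of host-derived read
pairs.  Everything is deterministic per seed, down to byte-identical FASTQ
output.

The generator is the package's stand-in for the field data the analysis was
designed around (2x250 bp paired-end shotgun sequencing of a host-associated
community): it is first-class, tested code, and every simulated read carries
a ground-truth origin used to score host subtraction, recruitment and
taxonomic assignment.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .sequtils import decode, random_dna
from .taxonomy import TaxonNode, TaxonomyTree

#: Gene lengths must comfortably exceed the clustering word size downstream.
_MIN_GENE_LENGTH = 24

HOST_LABEL = "host"


def species_ids(n_species: int) -> list[str]:
    return [f"s{i:03d}" for i in range(n_species)]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic community.

    ``strain_divergence`` is the per-site substitution probability separating
    the sequenced environmental strain of each species from its reference
    genes; a scalar applies to all species, a sequence gives one value per
    species.  ``error_rate`` is the per-base sequencing substitution
    probability; qualities are constant at Q = round(-10 log10 error_rate),
    capped to [2, 40].
    """

    n_species: int = 10
    genes_per_species: int = 30
    gene_length_range: tuple[int, int] = (400, 1200)
    strain_divergence: float | Sequence[float] = 0.08
    abundance_lognormal_mu: float = 0.0
    abundance_lognormal_sigma: float = 1.5
    n_read_pairs: int = 100_000
    read_length: int = 250
    fragment_length_mean: int = 350
    fragment_length_sd: float = 40.0
    error_rate: float = 0.0005
    host_fraction: float = 0.1
    host_genome_length: int = 200_000
    indel_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.gene_length_range
        if self.n_species < 1:
            raise ConfigError("n_species must be >= 1")
        if self.genes_per_species < 0:
            raise ConfigError("genes_per_species must be >= 0")
        if lo > hi or lo < _MIN_GENE_LENGTH:
            raise ConfigError(
                f"gene_length_range must be ordered with min >= {_MIN_GENE_LENGTH}"
            )
        for d in self.divergences:
            if not 0.0 <= d <= 0.15:
                raise ConfigError("strain_divergence must be in [0, 0.15] per species")
        if self.abundance_lognormal_sigma <= 0:
            raise ConfigError("abundance_lognormal_sigma must be > 0")
        if not 0.0 <= self.error_rate <= 0.05:
            raise ConfigError("error_rate must be in [0, 0.05]")
        if not 0.0 <= self.host_fraction <= 1.0:
            raise ConfigError("host_fraction must be in [0, 1]")
        if not 0.0 <= self.indel_rate <= 0.05:
            raise ConfigError("indel_rate must be in [0, 0.05]")
        if self.read_length > self.fragment_length_mean:
            raise ConfigError("read_length must be <= fragment_length_mean")
        if self.read_length < 1 or self.n_read_pairs < 0:
            raise ConfigError("read_length must be >= 1 and n_read_pairs >= 0")

    @property
    def divergences(self) -> tuple[float, ...]:
        d = self.strain_divergence
        if isinstance(d, (int, float)):
            return (float(d),) * self.n_species
        if len(d) != self.n_species:
            raise ConfigError("strain_divergence sequence must have one value per species")
        return tuple(float(x) for x in d)

    @property
    def quality(self) -> int:
        if self.error_rate <= 0:
            return 40
        return int(min(40, max(2, round(-10.0 * np.log10(self.error_rate)))))


@dataclass
class GroundTruth:
    """Per-read origin labels plus the community's true parameters."""

    origins: dict[str, str]                 # read id -> species_id or "host"
    abundances: dict[str, float]            # species_id -> true proportion
    divergences: dict[str, float]           # species_id -> strain divergence

    def __post_init__(self) -> None:
        total = sum(self.abundances.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"true abundances sum to {total}, expected 1")

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            sorted(self.origins.items()), columns=["read_id", "origin"]
        )
        df.to_csv(path, sep="\t", index=False)


@dataclass
class PairedReads:
    """A batch of equal-length read pairs as code matrices plus a constant Q."""

    ids: list[str]
    r1: np.ndarray  # (n, read_length) uint8 codes
    r2: np.ndarray
    quality: int

    def __len__(self) -> int:
        return len(self.ids)

    def write(self, r1_path: str | Path, r2_path: str | Path) -> None:
        _write_fastq_matrix(self.ids, self.r1, self.quality, r1_path, mate=1)
        _write_fastq_matrix(self.ids, self.r2, self.quality, r2_path, mate=2)


def _write_fastq_matrix(
    ids: list[str], seqs: np.ndarray, quality: int, path: str | Path, mate: int
) -> None:
    qline = chr(quality + 33) * seqs.shape[1] if len(ids) else ""
    chunks = []
    for i, rid in enumerate(ids):
        chunks.append(f"@{rid}/{mate}\n{decode(seqs[i])}\n+\n{qline}\n")
    Path(path).write_text("".join(chunks))


# ---------------------------------------------------------------------------
# taxonomy


def simulate_taxonomy(n_species: int, genera: int, seed: int) -> TaxonomyTree:
    """Random rooted taxonomy over the ladder root>domain>phylum>family>genus>species.

    Each species leaf has exactly one parent genus; every genus hosts at
    least one species.  Genera are grouped pairwise into families and
    families pairwise into phyla under a single domain.
    """
    if not 1 <= genera <= n_species:
        raise ConfigError("need 1 <= genera <= n_species")
    rng = np.random.default_rng(seed)
    sp = species_ids(n_species)
    genus_of = np.empty(n_species, dtype=int)
    genus_of[:genera] = np.arange(genera)
    if n_species > genera:
        genus_of[genera:] = rng.integers(0, genera, size=n_species - genera)
    n_fam = max(1, (genera + 1) // 2)
    fam_of = np.empty(genera, dtype=int)
    fam_of[:n_fam] = np.arange(n_fam)
    if genera > n_fam:
        fam_of[n_fam:] = rng.integers(0, n_fam, size=genera - n_fam)
    n_phy = max(1, (n_fam + 1) // 2)
    phy_of = np.empty(n_fam, dtype=int)
    phy_of[:n_phy] = np.arange(n_phy)
    if n_fam > n_phy:
        phy_of[n_phy:] = rng.integers(0, n_phy, size=n_fam - n_phy)

    nodes = [TaxonNode("root", "root", "root", "root"),
             TaxonNode("d000", "root", "domain", "Bacteria")]
    nodes += [TaxonNode(f"p{i:03d}", "d000", "phylum", f"Phylum_{i}") for i in range(n_phy)]
    nodes += [
        TaxonNode(f"f{i:03d}", f"p{phy_of[i]:03d}", "family", f"Family_{i}")
        for i in range(n_fam)
    ]
    nodes += [
        TaxonNode(f"g{i:03d}", f"f{fam_of[i]:03d}", "genus", f"Genus_{i}")
        for i in range(genera)
    ]
    nodes += [
        TaxonNode(sp[i], f"g{genus_of[i]:03d}", "species", f"Species_{i}")
        for i in range(n_species)
    ]
    return TaxonomyTree(nodes)


# ---------------------------------------------------------------------------
# reference genes, strains, host


def simulate_reference_genes(config: SimulationConfig) -> dict[str, dict[str, str]]:
    """Per-species reference gene sets: i.i.d. uniform bases, lengths uniform
    in ``gene_length_range``, deterministic per seed."""
    rng = np.random.default_rng([config.seed, 1])
    lo, hi = config.gene_length_range
    out: dict[str, dict[str, str]] = {}
    for sp in species_ids(config.n_species):
        genes: dict[str, str] = {}
        for j in range(config.genes_per_species):
            length = int(rng.integers(lo, hi + 1))
            genes[f"{sp}_g{j:03d}"] = random_dna(length, rng)
        out[sp] = genes
    return out


def mutate_strain(
    genes: dict[str, str],
    divergence: float,
    seed: int | Sequence[int],
    indel_rate: float = 0.0,
) -> dict[str, str]:
    """Derive a strain by substituting each site independently with
    probability ``divergence`` (always to a different base).

    An optional ``indel_rate`` adds single-base insertions/deletions (half
    each) so gap-aware alignment can be exercised; at the default 0 the gene
    lengths are preserved exactly.
    """
    if not 0.0 <= divergence <= 0.15:
        raise ConfigError("divergence must be in [0, 0.15]")
    if not 0.0 <= indel_rate <= 0.05:
        raise ConfigError("indel_rate must be in [0, 0.05]")
    from .sequtils import encode

    rng = np.random.default_rng(seed)
    out: dict[str, str] = {}
    for gene_id, seq in genes.items():
        codes = encode(seq).copy()
        mask = rng.random(codes.size) < divergence
        shift = rng.integers(1, 4, size=codes.size, dtype=np.uint8)
        codes[mask] = (codes[mask] + shift[mask]) % 4
        if indel_rate > 0:
            r = rng.random(codes.size)
            keep = r >= indel_rate / 2.0          # delete site when below
            ins_mask = (r >= indel_rate / 2.0) & (r < indel_rate)
            pieces = []
            ins_bases = rng.integers(0, 4, size=int(ins_mask.sum()), dtype=np.uint8)
            k = 0
            for i in range(codes.size):
                if keep[i]:
                    pieces.append(codes[i])
                if ins_mask[i]:
                    pieces.append(ins_bases[k])
                    k += 1
            codes = np.array(pieces, dtype=np.uint8)
        out[gene_id] = decode(codes)
    return out


def simulate_host_genome(length: int, seed: int | Sequence[int]) -> str:
    """One long random sequence standing in for the host + eukaryote panel."""
    if length < 1:
        raise ConfigError("host genome length must be >= 1")
    return random_dna(length, np.random.default_rng(seed))


# ---------------------------------------------------------------------------
# reads


def simulate_reads(
    config: SimulationConfig,
    strains: dict[str, dict[str, str]],
    host: str,
    sample_key: int = 0,
) -> tuple[PairedReads, GroundTruth]:
    """Draw paired-end reads from the community and the host genome.

    Abundances are drawn log-normal and normalized; each pair picks the host
    with probability ``host_fraction`` and otherwise a species by abundance,
    then a uniformly random gene of that species' strain.  Fragment lengths
    are normal (clipped below at the read length); both mates lie inside the
    fragment with the reverse mate reverse-complemented.  When a fragment is
    longer than the chosen source sequence the source is resampled, erroring
    after 100 failed rounds.  ``sample_key`` separates the random streams of
    independent samples drawn from the same configuration.
    """
    from .sequtils import encode, revcomp_codes

    rng = np.random.default_rng([config.seed, 3, sample_key])
    n = config.n_read_pairs
    sp = species_ids(config.n_species)
    if set(strains) != set(sp):
        raise ConfigError("strains must cover exactly the configured species")

    raw = rng.lognormal(config.abundance_lognormal_mu, config.abundance_lognormal_sigma, config.n_species)
    abund = raw / raw.sum()

    is_host = rng.random(n) < config.host_fraction
    sp_idx = rng.choice(config.n_species, size=n, p=abund)

    # concatenated source pool: all strain genes then the host genome
    seq_codes: list[np.ndarray] = []
    gene_offsets: dict[str, np.ndarray] = {}
    gene_lengths: dict[str, np.ndarray] = {}
    offset = 0
    for s in sp:
        offs, lens = [], []
        for gid in sorted(strains[s]):
            codes = encode(strains[s][gid])
            seq_codes.append(codes)
            offs.append(offset)
            lens.append(codes.size)
            offset += codes.size
        gene_offsets[s] = np.array(offs, dtype=np.int64)
        gene_lengths[s] = np.array(lens, dtype=np.int64)
    host_codes = encode(host)
    host_offset = offset
    seq_codes.append(host_codes)
    big = np.concatenate(seq_codes) if seq_codes else host_codes

    frag = np.rint(rng.normal(config.fragment_length_mean, config.fragment_length_sd, n)).astype(np.int64)
    frag = np.maximum(frag, config.read_length)

    src_offset = np.empty(n, dtype=np.int64)
    src_length = np.empty(n, dtype=np.int64)
    src_offset[is_host] = host_offset
    src_length[is_host] = len(host)
    micro = ~is_host
    micro_idx = np.flatnonzero(micro)
    if micro_idx.size:
        for s_i, s in enumerate(sp):
            rows = micro_idx[sp_idx[micro_idx] == s_i]
            if rows.size == 0:
                continue
            if gene_lengths[s].size == 0:
                raise ConfigError(f"species {s} has no genes to sample fragments from")
            g = rng.integers(0, gene_lengths[s].size, size=rows.size)
            src_offset[rows] = gene_offsets[s][g]
            src_length[rows] = gene_lengths[s][g]
            bad = rows[frag[rows] > src_length[rows]]
            attempts = 0
            while bad.size:
                attempts += 1
                if attempts > 100:
                    raise ConfigError(
                        "fragment longer than source sequence after 100 resampling rounds"
                    )
                g = rng.integers(0, gene_lengths[s].size, size=bad.size)
                src_offset[bad] = gene_offsets[s][g]
                src_length[bad] = gene_lengths[s][g]
                bad = bad[frag[bad] > src_length[bad]]
    if np.any(frag[is_host] > len(host)):
        raise ConfigError("fragment longer than the host genome")

    start = src_offset + np.floor(rng.random(n) * (src_length - frag + 1)).astype(np.int64)
    cols = np.arange(config.read_length)
    r1 = big[start[:, None] + cols] if n else np.empty((0, config.read_length), np.uint8)
    end = start + frag
    r2f = big[(end - config.read_length)[:, None] + cols] if n else r1
    r2 = np.ascontiguousarray((3 - r2f)[:, ::-1])  # reverse complement

    if config.error_rate > 0 and n:
        for mat in (r1, r2):
            mask = rng.random(mat.shape) < config.error_rate
            shift = rng.integers(1, 4, size=mat.shape, dtype=np.uint8)
            mat[mask] = (mat[mask] + shift[mask]) % 4

    ids = [f"read{i:07d}" for i in range(n)]
    origin = np.where(is_host, HOST_LABEL, np.array(sp, dtype=object)[sp_idx])
    truth = GroundTruth(
        origins=dict(zip(ids, origin.tolist())),
        abundances=dict(zip(sp, abund.tolist())),
        divergences=dict(zip(sp, config.divergences)),
    )
    return PairedReads(ids, r1, r2, config.quality), truth


def write_reference_fasta(genes: dict[str, dict[str, str]], out_dir: str | Path) -> None:
    """Write one ``refs/<species>.fasta`` per species."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for sp, gset in genes.items():
        with open(out / f"{sp}.fasta", "w") as fh:
            for gid in sorted(gset):
                fh.write(f">{gid}\n{gset[gid]}\n")
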