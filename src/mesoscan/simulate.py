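"""Chromosomal-evolution simulator with ground-truth synteny classes.

Two genomes are derived from a common synthetic ancestor — an ordered
gene map per chromosome — by applying gene loss, intra-chromosomal
inversions and inter-chromosomal translocations at controlled rates.
Comparing the derived genomes yields a :class:`~mesoscan.io.MatchSet`
with one match per surviving orthologous gene (emulating the
gene-granular matches a translated-DNA comparison produces), together
with a :class:`TruthLog` whose replay reproduces each derived genome
exactly.  Named scenarios fix all rates so that ``(name, seed)``
identifies a complete experiment:

* ``colinear`` — no rearrangements, mild gene loss: macrosynteny.
* ``inversion_only`` — heavy inversions, no translocations: gene
  content is conserved per chromosome while order and orientation are
  randomized, the defining property of mesosynteny.
* ``translocation_rich`` — heavy translocations spread each
  chromosome's content over many partners: degraded or no synteny.
* ``unrelated`` — matches placed uniformly at random with no ancestral
  structure: no synteny.
* ``degraded_meso`` — inversions plus moderate translocations on a
  genome rich in lineage-specific chromosomes: degraded mesosynteny.

Scenario genomes include a few *private* (lineage-specific)
chromosomes that share no genes between the lineages, emulating the
conditionally dispensable chromosomes of real fungal genomes.  Besides
realism this heterogeneity is what gives the binomial conservation
test its contrast: when every chromosome is conserved to the same
degree, a pair's observed conservation level equals the genome-wide
background exactly and no pair can test as significant.

Inversion and translocation breakpoints fall in intergenic space only,
so genes are never truncated and the ground truth stays gene-granular.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .io import ANTIPARALLEL, PARALLEL, GenomeIndex, Match, MatchSet


@dataclass(frozen=True)
class Gene:
    """One gene of the synthetic gene map."""

    gid: str
    length: int
    strand: int  # +1 or -1

    def flipped(self) -> "Gene":
        return Gene(self.gid, self.length, -self.strand)


@dataclass
class Genome:
    """An ordered gene map: chromosome name -> ordered genes."""

    label: str
    chromosomes: dict[str, list[Gene]]

    def gene_chromosome(self) -> dict[str, str]:
        """Map every gene id to the chromosome currently carrying it."""
        return {g.gid: c for c, genes in self.chromosomes.items() for g in genes}

    def copy(self, label: str | None = None) -> "Genome":
        return Genome(
            label if label is not None else self.label,
            {c: list(genes) for c, genes in self.chromosomes.items()},
        )


@dataclass(frozen=True)
class SimConfig:
    """Rates and sizes of one simulated evolution experiment.

    Defaults give eight chromosomes of ~750 kb (300 genes of 1500 bp
    separated by 1-kb spacers), all passing the 500-kb length filter,
    and no evolution at all; scenarios override the rates.
    """

    seed: int | None = None
    n_chromosomes: int = 8
    genes_per_chromosome: int = 300
    gene_len: int = 1_500
    intergenic_len: int = 1_000
    n_inversions: int = 0  # per chromosome, per lineage
    n_translocations: int = 0  # per genome (lineage)
    gene_loss_frac: float = 0.0  # per gene, per lineage
    pct_similarity: float = 85.0
    chromosome_len_jitter: float = 0.0  # fraction applied to gene counts
    gene_len_jitter: float = 0.0  # fraction applied to gene lengths
    n_private_chromosomes: int = 0  # lineage-specific, no cross matches
    n_background_matches: int = 0  # random matches (unrelated scenario)

    def __post_init__(self) -> None:
        for name in ("n_chromosomes", "genes_per_chromosome", "gene_len", "intergenic_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("gene_loss_frac", "chromosome_len_jitter", "gene_len_jitter"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_private_chromosomes > self.n_chromosomes:
            raise ValueError("n_private_chromosomes exceeds n_chromosomes")


Operation = dict  # {"kind": ..., parameters} — JSON-serializable


@dataclass
class TruthLog:
    """Record of the operations applied to one lineage (or a pair).

    ``replay`` of a lineage log on the ancestor reproduces the derived
    genome exactly.  Pair-level logs (from :func:`genome_pair` or
    :func:`scenario`) carry one sub-log per lineage.
    """

    intended_class: str | None = None
    operations: tuple[Operation, ...] = ()
    lineage_logs: dict[str, "TruthLog"] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "intended_class": self.intended_class,
            "operations": [dict(op) for op in self.operations],
            "lineage_logs": {k: v.to_dict() for k, v in self.lineage_logs.items()},
        }


# ---------------------------------------------------------------------------
# ancestor and evolution


def make_ancestor(config: SimConfig, rng: np.random.Generator | None = None) -> Genome:
    """Build the ancestral gene map, deterministic under the seed.

    Genes are non-overlapping, strand-labelled and separated by
    intergenic spacers; with zero jitter every chromosome has the same
    gene count and every gene the configured length.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    chromosomes: dict[str, list[Gene]] = {}
    total = 0
    for ci in range(1, config.n_chromosomes + 1):
        n_genes = config.genes_per_chromosome
        if config.chromosome_len_jitter:
            factor = 1.0 + rng.uniform(-config.chromosome_len_jitter, config.chromosome_len_jitter)
            n_genes = max(1, round(n_genes * factor))
        genes = []
        for gi in range(1, n_genes + 1):
            length = config.gene_len
            if config.gene_len_jitter:
                factor = 1.0 + rng.uniform(-config.gene_len_jitter, config.gene_len_jitter)
                length = max(1, round(length * factor))
            strand = 1 if rng.random() < 0.5 else -1
            genes.append(Gene(f"c{ci:02d}g{gi:04d}", length, strand))
        chromosomes[f"chr{ci}"] = genes
        total += n_genes
    if total == 0:
        raise ValueError("configuration yields zero genes")
    return Genome("ancestor", chromosomes)


def _apply_operation(genome: Genome, op: Operation) -> None:
    kind = op["kind"]
    if kind == "diverge":
        suffix = op["suffix"]
        for chrom in op["chromosomes"]:
            genome.chromosomes[chrom] = [
                Gene(f"{g.gid}|{suffix}", g.length, g.strand)
                for g in genome.chromosomes[chrom]
            ]
    elif kind == "loss":
        lost = set(op["genes"])
        for chrom, genes in genome.chromosomes.items():
            genome.chromosomes[chrom] = [g for g in genes if g.gid not in lost]
    elif kind == "inversion":
        genes = genome.chromosomes[op["chromosome"]]
        i, j = op["start"], op["end"]
        genes[i : j + 1] = [g.flipped() for g in reversed(genes[i : j + 1])]
    elif kind == "translocation":
        src = genome.chromosomes[op["source"]]
        i, size = op["start"], op["size"]
        segment = src[i : i + size]
        del src[i : i + size]
        genome.chromosomes[op["target"]][op["position"] : op["position"]] = segment
    else:
        raise ValueError(f"unknown operation kind {kind!r}")


def evolve(
    ancestor: Genome,
    config: SimConfig,
    rng: np.random.Generator,
    lineage: str = "derived",
) -> tuple[Genome, TruthLog]:
    """Derive one lineage from the ancestor under the configured rates.

    Operations are applied in order: divergence of private
    chromosomes, gene loss, inversions (per chromosome), then
    translocations.  All random choices are recorded in the returned
    :class:`TruthLog`, whose :func:`replay` reproduces the result.
    """
    genome = ancestor.copy(label=lineage)
    ops: list[Operation] = []

    if config.n_private_chromosomes:
        private = list(genome.chromosomes)[-config.n_private_chromosomes :]
        op = {"kind": "diverge", "chromosomes": private, "suffix": lineage}
        _apply_operation(genome, op)
        ops.append(op)

    if config.gene_loss_frac > 0:
        lost = [
            g.gid
            for genes in genome.chromosomes.values()
            for g in genes
            if rng.random() < config.gene_loss_frac
        ]
        op = {"kind": "loss", "genes": lost}
        _apply_operation(genome, op)
        ops.append(op)

    for chrom in genome.chromosomes:
        n = len(genome.chromosomes[chrom])
        if n < 1:
            continue
        for _ in range(config.n_inversions):
            i = int(rng.integers(0, n))
            j = int(rng.integers(0, n))
            if i > j:
                i, j = j, i
            op = {"kind": "inversion", "chromosome": chrom, "start": i, "end": j}
            _apply_operation(genome, op)
            ops.append(op)

    chrom_names = list(genome.chromosomes)
    for _ in range(config.n_translocations):
        candidates = [c for c in chrom_names if len(genome.chromosomes[c]) >= 2]
        if len(candidates) < 1 or len(chrom_names) < 2:
            break
        src = candidates[int(rng.integers(0, len(candidates)))]
        n_src = len(genome.chromosomes[src])
        size = int(rng.integers(1, max(1, n_src // 10) + 1))
        start = int(rng.integers(0, n_src - size + 1))
        targets = [c for c in chrom_names if c != src]
        tgt = targets[int(rng.integers(0, len(targets)))]
        pos = int(rng.integers(0, len(genome.chromosomes[tgt]) + 1))
        op = {
            "kind": "translocation",
            "source": src,
            "start": start,
            "size": size,
            "target": tgt,
            "position": pos,
        }
        _apply_operation(genome, op)
        ops.append(op)

    return genome, TruthLog(operations=tuple(ops))


def replay(ancestor: Genome, log: TruthLog, label: str = "replayed") -> Genome:
    """Re-apply a recorded lineage log to the ancestor."""
    genome = ancestor.copy(label=label)
    for op in log.operations:
        _apply_operation(genome, op)
    return genome


# ---------------------------------------------------------------------------
# projection to match coordinates


def layout(
    genome: Genome, intergenic_len: int
) -> tuple[GenomeIndex, dict[str, tuple[str, int, int]]]:
    """Assign 1-based coordinates to every gene.

    Genes are laid head to tail separated by ``intergenic_len`` bp;
    the chromosome length is the end of its last gene.  Returns the
    genome's :class:`GenomeIndex` and a map ``gid -> (chromosome,
    start, end)``.
    """
    sequences: list[tuple[str, int]] = []
    coords: dict[str, tuple[str, int, int]] = {}
    for chrom, genes in genome.chromosomes.items():
        pos = 1
        end = 0
        for g in genes:
            end = pos + g.length - 1
            coords[g.gid] = (chrom, pos, end)
            pos = end + intergenic_len + 1
        sequences.append((chrom, end if end else intergenic_len))
    return GenomeIndex(genome.label, tuple(sequences)), coords


def project_matches(
    genome_a: Genome, genome_b: Genome, config: SimConfig
) -> MatchSet:
    """Emulate a whole-genome comparison of two derived genomes.

    Every gene surviving in both genomes produces one match spanning
    its coordinates in each; orientation is anti-parallel when the two
    copies sit on opposite strands.  Lost and lineage-private genes
    produce no matches.
    """
    index_a, coords_a = layout(genome_a, config.intergenic_len)
    index_b, coords_b = layout(genome_b, config.intergenic_len)
    strand_b = {g.gid: g.strand for genes in genome_b.chromosomes.values() for g in genes}
    matches: list[Match] = []
    for genes in genome_a.chromosomes.values():
        for g in genes:
            if g.gid not in coords_b:
                continue
            chrom_a, sa, ea = coords_a[g.gid]
            chrom_b, sb, eb = coords_b[g.gid]
            orientation = PARALLEL if g.strand == strand_b[g.gid] else ANTIPARALLEL
            matches.append(
                Match(
                    ref_id=chrom_a,
                    qry_id=chrom_b,
                    ref_start=sa,
                    ref_end=ea,
                    qry_start=sb,
                    qry_end=eb,
                    pct_similarity=config.pct_similarity,
                    orientation=orientation,
                )
            )
    return MatchSet(index_a, index_b, tuple(matches))


def self_comparison(genome: GenomeIndex) -> MatchSet:
    """The match set of a genome aligned against itself.

    One full-length, parallel, 100%-similar match per sequence — what a
    whole-genome aligner reports for the trivial self-diagonal.
    """
    matches = tuple(
        Match(s, s, 1, length, 1, length, 100.0, PARALLEL)
        for s, length in genome.sequences
    )
    return MatchSet(genome, genome, matches)


def random_matchset(
    config: SimConfig, rng: np.random.Generator, n_matches: int | None = None
) -> MatchSet:
    """Matches placed uniformly at random between two unrelated genomes.

    Match positions are drawn length-proportionally across sequences
    and uniformly within them, with gene-sized spans, random
    orientation and mediocre similarity: the background a comparison of
    two unrelated genomes produces.
    """
    n_matches = config.n_background_matches if n_matches is None else n_matches
    ancestor_a = make_ancestor(config, rng)
    ancestor_b = make_ancestor(config, rng)
    index_a, _ = layout(ancestor_a.copy(label="A"), config.intergenic_len)
    index_b, _ = layout(ancestor_b.copy(label="B"), config.intergenic_len)

    def draw(index: GenomeIndex) -> tuple[str, int, int]:
        lengths = np.array([l for _, l in index.sequences], dtype=float)
        i = int(rng.choice(len(lengths), p=lengths / lengths.sum()))
        seq_id, seq_len = index.sequences[i]
        span = min(config.gene_len, seq_len)
        start = int(rng.integers(1, seq_len - span + 2))
        return seq_id, start, start + span - 1

    matches = []
    for _ in range(n_matches):
        ref_id, rs, re_ = draw(index_a)
        qry_id, qs, qe = draw(index_b)
        orientation = PARALLEL if rng.random() < 0.5 else ANTIPARALLEL
        pct = float(rng.uniform(50.0, 70.0))
        matches.append(Match(ref_id, qry_id, rs, re_, qs, qe, pct, orientation))
    return MatchSet(index_a, index_b, tuple(matches))


def genome_pair(
    config: SimConfig, seed: int | None = None
) -> tuple[MatchSet, TruthLog]:
    """Simulate one genome pair under ``config`` and compare them."""
    rng = np.random.default_rng(seed if seed is not None else config.seed)
    ancestor = make_ancestor(config, rng)
    derived_a, log_a = evolve(ancestor, config, rng, "A")
    derived_b, log_b = evolve(ancestor, config, rng, "B")
    matchset = project_matches(derived_a, derived_b, config)
    return matchset, TruthLog(lineage_logs={"A": log_a, "B": log_b})


# ---------------------------------------------------------------------------
# scenarios

_BASE = dict(
    n_chromosomes=8,
    n_private_chromosomes=2,
    genes_per_chromosome=300,
    gene_len=1_500,
    intergenic_len=1_000,
    gene_loss_frac=0.05,
)

SCENARIO_CONFIGS: Mapping[str, SimConfig] = {
    "colinear": SimConfig(pct_similarity=88.0, **_BASE),
    "inversion_only": SimConfig(n_inversions=900, pct_similarity=82.0, **_BASE),
    "translocation_rich": SimConfig(n_translocations=60, pct_similarity=75.0, **_BASE),
    "unrelated": SimConfig(
        n_chromosomes=8,
        genes_per_chromosome=300,
        gene_len=1_500,
        intergenic_len=1_000,
        n_background_matches=600,
        pct_similarity=60.0,
    ),
    "degraded_meso": SimConfig(
        n_chromosomes=12,
        n_private_chromosomes=8,
        genes_per_chromosome=300,
        gene_len=1_500,
        intergenic_len=500,
        n_inversions=900,
        n_translocations=60,
        gene_loss_frac=0.05,
        pct_similarity=70.0,
    ),
}

_SCENARIO_CLASS = {
    "colinear": "macrosynteny",
    "inversion_only": "mesosynteny",
    "translocation_rich": "degraded",
    "unrelated": "none",
    "degraded_meso": "degraded",
}


def scenario(name: str, seed: int) -> tuple[MatchSet, TruthLog]:
    """Run a canned evolutionary regime; ``(name, seed)`` fixes everything.

    Raises
    ------
    ValueError
        For an unknown scenario name.
    """
    if name not in SCENARIO_CONFIGS:
        raise ValueError(
            f"unknown scenario {name!r}; choose from {sorted(SCENARIO_CONFIGS)}"
        )
    config = SCENARIO_CONFIGS[name]
    if name == "unrelated":
        rng = np.random.default_rng(seed)
        matchset = random_matchset(config, rng)
        truth = TruthLog(intended_class="none")
    else:
        matchset, truth = genome_pair(config, seed)
        truth.intended_class = _SCENARIO_CLASS[name]
    return matchset, truth


# ---------------------------------------------------------------------------
# optional FASTA emission (integration with external aligners)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = {65: "T", 67: "G", 71: "C", 84: "A"}


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[ord(c)] for c in reversed(seq))


def write_fasta(
    genome: Genome,
    config: SimConfig,
    path,
    *,
    gene_sequences: dict[str, str] | None = None,
    seed: int = 0,
) -> dict[str, str]:
    """Emit a synthetic FASTA for a (derived) gene map.

    Shared ancestral gene sequences (generated here on first use, or
    passed in so both lineages place identical orthologs) are laid out
    at the gene coordinates, reverse-complemented on the minus strand,
    with random intergenic filler.  Intended for integration tests that
    shell out to an external aligner; the library itself never reads
    these files back.
    """
    rng = np.random.default_rng(seed)
    if gene_sequences is None:
        gene_sequences = {}
    with open(path, "w") as fh:
        for chrom, genes in genome.chromosomes.items():
            parts: list[str] = []
            for i, g in enumerate(genes):
                if i:
                    parts.append(_random_seq(rng, config.intergenic_len))
                base_gid = g.gid.split("|")[0]
                if base_gid not in gene_sequences:
                    gene_sequences[base_gid] = _random_seq(rng, g.length)
                seq = gene_sequences[base_gid][: g.length].ljust(g.length, "A")
                parts.append(seq if g.strand > 0 else _revcomp(seq))
            fh.write(f">{chrom}\n")
            seq = "".join(parts) or _random_seq(rng, config.intergenic_len)
            for j in range(0, len(seq), 80):
                fh.write(seq[j : j + 80] + "\n")
    return gene_sequences
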