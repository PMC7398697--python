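"""Synthetic TIER-seq datasets: toy genome, planted cleavage sites, counts.

The generator emulates the twelve-library design of a transient-RNase E
inactivation experiment: wild-type (WT) and temperature-sensitive (TS)
strains, each grown at the permissive (30 degC) and non-permissive (44 degC)
temperature, in biological triplicate.  Cleavage sites carrying the RNase E
consensus (RN^WUU, written RNWTT on the DNA coding strand) are planted in
transcribed features; their 5'-end signal is strong wherever the nuclease
is active and depleted by a configurable factor only in the TS strain at
44 degC — the signature the caller looks for.

Counts follow a negative-binomial background with per-gene expression
levels and per-library size factors, so the normalisation, dispersion and
testing machinery downstream is exercised under realistic overdispersion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
import numpy as np

from .coverage_io import (
    AnnotationSet,
    Feature,
    FivePrimeCoverage,
    Genome,
    SampleDesign,
    revcomp,
    write_annotation,
    write_count_table,
    write_design,
    write_genome,
)
from .errors import InputError, SizingError

SITE_CLASSES = ("CDS", "5UTR", "3UTR", "sRNA")

_CLASS_TO_FTYPE = {
    "CDS": "CDS",
    "5UTR": "five_prime_UTR",
    "3UTR": "three_prime_UTR",
    "sRNA": "sRNA",
}

_STOPS = ("TAA", "TAG", "TGA")


@dataclass
class SimConfig:
    """Parameters of a synthetic TIER-seq scenario.

    Defaults describe the standard desk-scale scenario: two 200-kb
    chromosomes, 150 genes, 120 planted sites with 8-fold depletion in the
    TS strain at 44 degC, NB dispersion 0.1 and a background of 2 expected
    5'-end reads per transcribed nucleotide.
    """

    n_chromosomes: int = 2
    chrom_length: int = 200_000
    n_genes: int = 150
    utr5_len: int = 60
    utr3_len: int = 150
    cds_len_range: tuple[int, int] = (300, 900)
    srna_fraction: float = 0.3
    srna_len: int = 80
    n_planted_sites: int = 120
    class_weights: dict[str, float] = field(
        default_factory=lambda: {"CDS": 0.7, "5UTR": 0.1, "3UTR": 0.1, "sRNA": 0.1}
    )
    depletion_factor: float = 8.0
    site_strength: float = 50.0
    background_rate: float = 2.0
    nb_dispersion: float = 0.1
    leak_fraction: float = 0.02
    library_size_factors: tuple[float, ...] | None = None
    n_replicates: int = 3
    expression_range: tuple[float, float] = (0.2, 5.0)
    edge_margin: int = 10
    min_gene_gap: int = 100
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_chromosomes, self.chrom_length, self.n_genes) <= 0:
            raise InputError("counts must be positive")
        if self.n_planted_sites < 0:
            raise InputError("n_planted_sites must be >= 0")
        if self.depletion_factor < 1:
            raise InputError("depletion_factor must be >= 1")
        if self.nb_dispersion < 0:
            raise InputError("nb_dispersion must be >= 0")
        if self.site_strength <= 0 or self.background_rate <= 0:
            raise InputError("rates must be positive")
        if not (0 <= self.srna_fraction <= 1):
            raise InputError("srna_fraction must be in [0, 1]")
        if self.srna_len + self.edge_margin > self.utr3_len:
            raise InputError("sRNA does not fit inside the 3'UTR")
        if self.library_size_factors is not None:
            if any(f <= 0 for f in self.library_size_factors):
                raise InputError("library size factors must be positive")
        weights = self.class_weights
        if abs(sum(weights.values()) - 1.0) > 1e-9:
            raise InputError("class weights must sum to 1")
        if set(weights) - set(SITE_CLASSES):
            raise InputError(f"class weights restricted to {SITE_CLASSES}")
        max_gene = self.utr5_len + self.cds_len_range[1] + self.utr3_len
        per_chrom = self.n_genes // self.n_chromosomes + 1
        if per_chrom * (max_gene + self.min_gene_gap) > self.chrom_length:
            raise SizingError(
                f"{self.n_genes} genes of up to {max_gene} nt do not fit into "
                f"{self.n_chromosomes} x {self.chrom_length} nt"
            )


@dataclass(frozen=True)
class PlantedSite:
    """Ground truth for one planted cleavage site.

    ``pos`` is the first nucleotide of the downstream cleavage fragment
    (the detected 5' end) in 0-based genomic coordinates; the 5-nt motif
    occupies genomic positions [pos-2, pos+2].
    """

    chrom: str
    pos: int
    strand: str
    class_label: str
    gene_id: str
    depletion_factor: float


@dataclass
class SimulationTruth:
    """Everything the generator planted, for recovery scoring."""

    genome: Genome
    annotation: AnnotationSet
    design: list[SampleDesign]
    planted_sites: list[PlantedSite]

    def site_keys(self) -> set[tuple[str, int, str]]:
        return {(s.chrom, s.pos, s.strand) for s in self.planted_sites}


def make_design(n_replicates: int = 3) -> list[SampleDesign]:
    """Sample sheet: WT/TS x 30/44 degC x replicates, in fixed order."""
    design = []
    for strain in ("WT", "TS"):
        for temp in (30, 44):
            for rep in range(1, n_replicates + 1):
                design.append(
                    SampleDesign(
                        sample_id=f"{strain}_{temp}_r{rep}",
                        strain=strain,
                        temperature=temp,
                        replicate=rep,
                    )
                )
    return design


def _rng(config: SimConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, *key])


def generate_genome(config: SimConfig) -> tuple[Genome, AnnotationSet]:
    """Random genome with non-overlapping gene models.

    Each gene carries a 5'UTR, a CDS (ATG ... stop, length a multiple of 3)
    and a 3'UTR; a ``srna_fraction`` of genes additionally carries an
    annotated sRNA occupying the 3'-terminal part of the 3'UTR, emulating
    3'UTR-derived sRNAs.  Deterministic given ``config.seed``.
    """
    config.validate()
    rng = _rng(config, 0)
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    sequences = [
        bytearray(rng.choice(alphabet, size=config.chrom_length).tobytes())
        for _ in range(config.n_chromosomes)
    ]
    chrom_ids = [f"chr{i + 1}" for i in range(config.n_chromosomes)]

    counts = [config.n_genes // config.n_chromosomes] * config.n_chromosomes
    for i in range(config.n_genes % config.n_chromosomes):
        counts[i] += 1

    features: list[Feature] = []
    gene_no = 0
    for ci, n_here in enumerate(counts):
        chrom = chrom_ids[ci]
        seq = sequences[ci]
        cursor = config.min_gene_gap
        for _ in range(n_here):
            gene_no += 1
            gid = f"gene{gene_no:04d}"
            cds_len = 3 * int(
                rng.integers(config.cds_len_range[0] // 3, config.cds_len_range[1] // 3 + 1)
            )
            gene_len = config.utr5_len + cds_len + config.utr3_len
            gap = int(rng.integers(0, config.min_gene_gap + 1))
            start = cursor + gap
            end = start + gene_len
            if end > config.chrom_length - config.min_gene_gap:
                raise SizingError(
                    f"gene layout overflows {chrom} at gene {gid}"
                )
            cursor = end + config.min_gene_gap
            strand = "+" if rng.random() < 0.5 else "-"

            if strand == "+":
                utr5 = (start, start + config.utr5_len)
                cds = (utr5[1], utr5[1] + cds_len)
                utr3 = (cds[1], end)
                seq[cds[0] : cds[0] + 3] = b"ATG"
                stop = _STOPS[int(rng.integers(3))].encode()
                seq[cds[1] - 3 : cds[1]] = stop
            else:
                utr3 = (start, start + config.utr3_len)
                cds = (utr3[1], utr3[1] + cds_len)
                utr5 = (cds[1], end)
                seq[cds[1] - 3 : cds[1]] = revcomp("ATG").encode()
                stop = _STOPS[int(rng.integers(3))]
                seq[cds[0] : cds[0] + 3] = revcomp(stop).encode()

            features.append(Feature(chrom, start, end, strand, "gene", gid))
            features.append(
                Feature(chrom, utr5[0], utr5[1], strand, "five_prime_UTR", f"{gid}.5UTR", gid)
            )
            features.append(Feature(chrom, cds[0], cds[1], strand, "CDS", f"{gid}.CDS", gid))
            features.append(
                Feature(chrom, utr3[0], utr3[1], strand, "three_prime_UTR", f"{gid}.3UTR", gid)
            )
            if rng.random() < config.srna_fraction:
                # sRNA occupies the 3'-terminal srna_len nt of the 3'UTR
                if strand == "+":
                    s_start, s_end = utr3[1] - config.srna_len, utr3[1]
                else:
                    s_start, s_end = utr3[0], utr3[0] + config.srna_len
                features.append(
                    Feature(chrom, s_start, s_end, strand, "sRNA", f"sRNA_{gid}", gid)
                )

    genome = Genome([(cid, bytes(seq).decode()) for cid, seq in zip(chrom_ids, sequences)])
    return genome, AnnotationSet(features, genome=genome)


def _sample_motif(rng: np.random.Generator) -> str:
    """One DNA realisation of the RNWTT consensus."""
    r = "AG"[int(rng.integers(2))]
    n = "ACGT"[int(rng.integers(4))]
    w = "AT"[int(rng.integers(2))]
    return r + n + w + "TT"


def plant_cleavage_sites(
    genome: Genome, annotation: AnnotationSet, config: SimConfig
) -> SimulationTruth:
    """Write RNWTT motifs into transcribed features and record the truth.

    The recorded position is the first nucleotide of the downstream
    fragment; for a site at position p the motif is written over genomic
    [p-2, p+2] in transcript orientation (reverse-complemented on the -
    strand).  Sites in the sRNA class are planted exactly at the sRNA's
    annotated 5' end, emulating RNase E-dependent sRNA maturation.
    Collisions are re-drawn; exhaustion raises :class:`SizingError`.
    """
    config.validate()
    rng = _rng(config, 1)
    seqs = {cid: bytearray(genome.sequence(cid).encode()) for cid in genome.chrom_ids}
    by_class = {
        label: annotation.of_type(ftype) for label, ftype in _CLASS_TO_FTYPE.items()
    }
    labels = [c for c in SITE_CLASSES if config.class_weights.get(c, 0) > 0]
    for label in labels:
        if not by_class[label]:
            raise SizingError(f"no features available for site class {label}")
    probs = np.array([config.class_weights[c] for c in labels])
    probs = probs / probs.sum()

    margin = config.edge_margin
    used: set[tuple[str, int, str]] = set()
    occupied: dict[str, set[int]] = {cid: set() for cid in genome.chrom_ids}
    planted: list[PlantedSite] = []
    max_tries = 200 * max(config.n_planted_sites, 1)
    tries = 0
    while len(planted) < config.n_planted_sites:
        tries += 1
        if tries > max_tries:
            raise SizingError(
                f"could not place {config.n_planted_sites} sites after {tries} draws"
            )
        label = labels[int(rng.choice(len(labels), p=probs))]
        feats = by_class[label]
        feat = feats[int(rng.integers(len(feats)))]
        if label == "sRNA":
            pos = feat.five_prime_pos()
        else:
            if len(feat) <= 2 * margin:
                continue
            offset = int(rng.integers(margin, len(feat) - margin))
            pos = feat.start + offset if feat.strand == "+" else feat.end - 1 - offset
        if label != "sRNA" and any(
            f.ftype == "sRNA"
            for f in annotation.overlapping(feat.chrom, pos, pos + 1, feat.strand)
        ):
            continue  # nested sRNA wins classification; keep labels faithful
        key = (feat.chrom, pos, feat.strand)
        window = range(pos - 2, pos + 3)
        if key in used or any(p in occupied[feat.chrom] for p in window):
            continue
        if window[0] < 0 or window[-1] >= genome.length(feat.chrom):
            continue
        motif = _sample_motif(rng)
        written = motif if feat.strand == "+" else revcomp(motif)
        seqs[feat.chrom][pos - 2 : pos + 3] = written.encode()
        used.add(key)
        occupied[feat.chrom].update(window)
        planted.append(
            PlantedSite(
                chrom=feat.chrom,
                pos=pos,
                strand=feat.strand,
                class_label=label,
                gene_id=feat.parent_gene_id or feat.feature_id,
                depletion_factor=config.depletion_factor,
            )
        )

    mutated = Genome([(cid, bytes(seqs[cid]).decode()) for cid in genome.chrom_ids])
    annotation = AnnotationSet(annotation.features, genome=mutated)
    return SimulationTruth(
        genome=mutated,
        annotation=annotation,
        design=make_design(config.n_replicates),
        planted_sites=planted,
    )


def _expression_levels(annotation: AnnotationSet, config: SimConfig) -> dict[str, float]:
    """Per-gene expression multipliers, log-uniform over expression_range."""
    rng = _rng(config, 2)
    lo, hi = config.expression_range
    genes = sorted(f.feature_id for f in annotation.of_type("gene"))
    levels = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(genes)))
    return dict(zip(genes, levels))


def _base_mean_arrays(
    truth: SimulationTruth, config: SimConfig, expr: dict[str, float]
) -> dict[tuple[str, str], np.ndarray]:
    """Condition-independent NB mean per (chrom, strand) position."""
    genome = truth.genome
    leak = config.background_rate * config.leak_fraction
    base = {
        (cid, s): np.full(genome.length(cid), leak, dtype=np.float64)
        for cid in genome.chrom_ids
        for s in ("+", "-")
    }
    for f in truth.annotation.of_type("gene"):
        base[(f.chrom, f.strand)][f.start : f.end] = (
            config.background_rate * expr[f.feature_id]
        )
    return base


def simulate_counts(
    truth: SimulationTruth, config: SimConfig
) -> dict[str, FivePrimeCoverage]:
    """Draw NB 5'-end counts for every library in the design.

    Background mean at a transcribed position is background_rate x
    expression level x library size factor; planted sites are boosted by
    ``site_strength`` wherever RNase E is active and by
    ``site_strength / depletion_factor`` in TS libraries at 44 degC.
    Dispersion 0 degenerates to Poisson.  One RNG stream per sample keyed
    by (seed, sample index), so adding a library never perturbs the others.
    """
    config.validate()
    design = truth.design
    if config.library_size_factors is not None:
        if len(config.library_size_factors) != len(design):
            raise InputError(
                f"need {len(design)} library size factors, got "
                f"{len(config.library_size_factors)}"
            )
        lib_factors = list(config.library_size_factors)
    else:
        lib_rng = _rng(config, 4)
        lib_factors = list(
            np.exp(lib_rng.uniform(np.log(0.5), np.log(2.0), size=len(design)))
        )

    expr = _expression_levels(truth.annotation, config)
    base = _base_mean_arrays(truth, config, expr)

    out: dict[str, FivePrimeCoverage] = {}
    for si, sample in enumerate(design):
        rng = _rng(config, 3, si)
        inactive = sample.strain == "TS" and sample.temperature == 44
        arrays: dict[tuple[str, str], np.ndarray] = {}
        mu_by_key = {k: v * lib_factors[si] for k, v in base.items()}
        for site in truth.planted_sites:
            factor = config.site_strength
            if inactive:
                factor /= site.depletion_factor
            mu_by_key[(site.chrom, site.strand)][site.pos] *= factor
        for key, mu in mu_by_key.items():
            if config.nb_dispersion > 0:
                shape = 1.0 / config.nb_dispersion
                lam = rng.gamma(shape, mu * config.nb_dispersion)
                arrays[key] = rng.poisson(lam).astype(np.int64)
            else:
                arrays[key] = rng.poisson(mu).astype(np.int64)
        cov = FivePrimeCoverage(sample_id=sample.sample_id, arrays=arrays)
        cov.n_counted = cov.total()
        out[sample.sample_id] = cov
    return out


@dataclass
class SimulatedDataset:
    """A complete in-memory synthetic TIER-seq dataset."""

    config: SimConfig
    truth: SimulationTruth
    coverages: dict[str, FivePrimeCoverage]


def simulate(config: SimConfig | None = None, **overrides) -> SimulatedDataset:
    """Generate genome, annotation, planted sites and counts in one call."""
    config = replace(config, **overrides) if config else SimConfig(**overrides)
    genome, annotation = generate_genome(config)
    truth = plant_cleavage_sites(genome, annotation, config)
    coverages = simulate_counts(truth, config)
    return SimulatedDataset(config=config, truth=truth, coverages=coverages)


def write_truth_bed(truth: SimulationTruth, path: str | Path) -> None:
    """Planted sites as BED6 (name = class:gene)."""
    with open(path, "w") as fh:
        for s in sorted(truth.planted_sites, key=lambda x: (x.chrom, x.pos, x.strand)):
            fh.write(
                f"{s.chrom}\t{s.pos}\t{s.pos + 1}\t{s.class_label}:{s.gene_id}\t0\t{s.strand}\n"
            )


def write_dataset(dataset: SimulatedDataset, outdir: str | Path) -> None:
    """Write FASTA, GFF3, design sheet, truth BED and per-sample count TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_genome(dataset.truth.genome, outdir / "genome.fa")
    write_annotation(dataset.truth.annotation, outdir / "annotation.gff3")
    write_design(dataset.truth.design, outdir / "design.tsv")
    write_truth_bed(dataset.truth, outdir / "truth.bed")
    counts_dir = outdir / "counts"
    counts_dir.mkdir(exist_ok=True)
    for sample_id, cov in dataset.coverages.items():
        write_count_table(cov, counts_dir / f"{sample_id}.tsv")
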