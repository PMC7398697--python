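"""Genomic classification of cleavage sites and positional statistics.

Covers the descriptive layer of the analysis: assigning each called site
to a transcript class (CDS, 5'UTR, 3'UTR, sRNA, antisense, intergenic),
per-gene site counts and densities, metagene profiles anchored at start
and stop codons, and matching of cleavage sites to annotated sRNA 5' ends
(the signature of RNase E-dependent sRNA maturation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coverage_io import AnnotationSet, Feature
from .errors import InputError

SITE_CLASS_ORDER = ("CDS", "5UTR", "asRNA", "3UTR", "IGR", "sRNA")

# same-strand precedence: nested sRNAs beat their host 3'UTR, UTRs beat CDS
_PRECEDENCE = ("sRNA", "five_prime_UTR", "three_prime_UTR", "CDS")
_FTYPE_TO_CLASS = {
    "sRNA": "sRNA",
    "five_prime_UTR": "5UTR",
    "three_prime_UTR": "3UTR",
    "CDS": "CDS",
}


def classify_site(
    chrom: str, pos: int, strand: str, annotation: AnnotationSet
) -> tuple[str, str | None]:
    """Class label (and gene id) for a single site.

    Same-strand overlap wins with precedence sRNA > 5'UTR > 3'UTR > CDS;
    a site overlapping only opposite-strand annotation is antisense
    (asRNA); a site overlapping nothing is intergenic (IGR).
    """
    same = [
        f
        for f in annotation.overlapping(chrom, pos, pos + 1, strand)
        if f.ftype in _FTYPE_TO_CLASS
    ]
    if same:
        for ftype in _PRECEDENCE:
            hits = [f for f in same if f.ftype == ftype]
            if hits:
                win = hits[0]
                gid = win.parent_gene_id or win.feature_id
                return _FTYPE_TO_CLASS[ftype], gid
    other = "-" if strand == "+" else "+"
    opposite = [
        f
        for f in annotation.overlapping(chrom, pos, pos + 1, other)
        if f.ftype in _FTYPE_TO_CLASS
    ]
    if opposite:
        win = opposite[0]
        return "asRNA", win.parent_gene_id or win.feature_id
    return "IGR", None


def classify_sites(sites: pd.DataFrame, annotation: AnnotationSet) -> pd.DataFrame:
    """Add class_label and gene_id columns to a site table.

    ``sites`` is indexed by (chrom, pos0, strand) as produced by the
    caller; the returned copy carries one label per site (classification
    is total).
    """
    labels: list[str] = []
    genes: list[str | None] = []
    for chrom, pos, strand in sites.index:
        label, gid = classify_site(chrom, int(pos), strand, annotation)
        labels.append(label)
        genes.append(gid)
    out = sites.copy()
    out["class_label"] = labels
    out["gene_id"] = genes
    return out


@dataclass
class ClassDistribution:
    """Counts and fractions of sites per transcript class."""

    counts: pd.Series
    fractions: pd.Series

    @property
    def n_sites(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"count": self.counts, "fraction": self.fractions})


def class_distribution(classified: pd.DataFrame) -> ClassDistribution:
    """Tally site classes; requires a classified, non-empty site table."""
    if len(classified) == 0:
        raise InputError("no sites to tally")
    if "class_label" not in classified.columns:
        raise InputError("sites are not classified; run classify_sites first")
    counts = (
        classified["class_label"]
        .value_counts()
        .reindex(SITE_CLASS_ORDER, fill_value=0)
        .astype(int)
    )
    counts.index.name = "class"
    return ClassDistribution(counts=counts, fractions=counts / counts.sum())


# ---------------------------------------------------------------------------
# Per-gene statistics
# ---------------------------------------------------------------------------


def _gene_extents(annotation: AnnotationSet, extent: str) -> list[Feature]:
    """One extent feature per gene: full transcript span or CDS only."""
    if extent == "full":
        return annotation.of_type("gene")
    if extent == "cds":
        return annotation.of_type("CDS")
    raise InputError(f"extent must be 'full' or 'cds', got {extent!r}")


@dataclass
class GeneSiteStats:
    """Per-gene site counts and densities (sites per kb)."""

    per_gene: pd.DataFrame  # gene_id, length_nt, n_sites, sites_per_kb
    median_sites_per_kb: float
    mean_sites_per_kb: float


def gene_site_stats(
    sites: pd.DataFrame, annotation: AnnotationSet, extent: str = "full"
) -> GeneSiteStats:
    """Site count and density per gene.

    The gene extent defaults to the full annotated transcript span
    (5'UTR + CDS + 3'UTR); only same-strand sites inside the extent are
    counted.  Density is count / (length in kb); the summary median and
    mean are taken across all genes with a nonzero extent.
    """
    feats = _gene_extents(annotation, extent)
    pos_by_key: dict[tuple[str, str], np.ndarray] = {}
    for (chrom, strand), group in _sites_by_chrom_strand(sites).items():
        pos_by_key[(chrom, strand)] = group
    rows = []
    for f in sorted(feats, key=lambda x: x.feature_id):
        gid = f.parent_gene_id or f.feature_id
        length = len(f)
        if length == 0:
            continue
        positions = pos_by_key.get((f.chrom, f.strand))
        if positions is None:
            n = 0
        else:
            n = int(
                np.searchsorted(positions, f.end) - np.searchsorted(positions, f.start)
            )
        rows.append((gid, length, n, n / (length / 1000.0)))
    per_gene = pd.DataFrame(
        rows, columns=["gene_id", "length_nt", "n_sites", "sites_per_kb"]
    ).set_index("gene_id")
    if len(per_gene):
        med = float(per_gene["sites_per_kb"].median())
        mean = float(per_gene["sites_per_kb"].mean())
    else:
        med = mean = 0.0
    return GeneSiteStats(per_gene=per_gene, median_sites_per_kb=med, mean_sites_per_kb=mean)


def _sites_by_chrom_strand(sites: pd.DataFrame) -> dict[tuple[str, str], np.ndarray]:
    out: dict[tuple[str, str], np.ndarray] = {}
    if len(sites) == 0:
        return out
    idx = sites.index.to_frame(index=False)
    for (chrom, strand), grp in idx.groupby(["chrom", "strand"], sort=True):
        out[(chrom, strand)] = np.sort(grp["pos0"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# Metagene profiles
# ---------------------------------------------------------------------------


@dataclass
class MetageneProfile:
    """Site density as a function of distance from a codon anchor.

    Offsets are in transcript orientation (negative = upstream of the
    anchor, anchor = 0); density at offset o is the number of sites at o
    summed over genes, divided by the number of genes whose annotated
    transcript extent covers o.
    """

    anchor: str
    offsets: np.ndarray
    density: np.ndarray
    n_sites: np.ndarray
    n_genes: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "offset": self.offsets,
                "density": self.density,
                "n_sites": self.n_sites,
                "n_genes": self.n_genes,
            }
        )


def _anchor_position(cds: Feature, anchor: str) -> int:
    """Genomic position of offset 0: first base of the start codon, or the
    last base of the stop codon."""
    if anchor == "start_codon":
        return cds.start if cds.strand == "+" else cds.end - 1
    if anchor == "stop_codon":
        return cds.end - 1 if cds.strand == "+" else cds.start
    raise InputError(f"anchor must be start_codon or stop_codon, got {anchor!r}")


def metagene_profile(
    sites: pd.DataFrame,
    annotation: AnnotationSet,
    anchor: str = "start_codon",
    window: int = 100,
) -> MetageneProfile:
    """Aggregate site density around start or stop codons.

    For each gene the anchor is taken from its CDS; sites within +/-window
    of the anchor (transcript orientation) are histogrammed, and each
    offset is normalised by the number of genes whose transcript extent
    (gene feature span) covers that offset.
    """
    offsets = np.arange(-window, window + 1)
    site_counts = np.zeros(offsets.size, dtype=np.int64)
    gene_cov = np.zeros(offsets.size, dtype=np.int64)
    pos_by_key = _sites_by_chrom_strand(sites)
    gene_span = {
        (g.parent_gene_id or g.feature_id): g for g in annotation.of_type("gene")
    }
    for cds in annotation.of_type("CDS"):
        gid = cds.parent_gene_id or cds.feature_id
        a = _anchor_position(cds, anchor)
        span = gene_span.get(gid, cds)
        # transcript offsets covered by the gene extent, clipped to window
        if cds.strand == "+":
            lo, hi = span.start - a, span.end - 1 - a
        else:
            lo, hi = a - (span.end - 1), a - span.start
        lo, hi = max(lo, -window), min(hi, window)
        if lo <= hi:
            gene_cov[lo + window : hi + window + 1] += 1
        positions = pos_by_key.get((cds.chrom, cds.strand))
        if positions is None:
            continue
        g_lo, g_hi = a - window, a + window
        sel = positions[(positions >= g_lo) & (positions <= g_hi)]
        for p in sel:
            off = p - a if cds.strand == "+" else a - p
            site_counts[off + window] += 1
    with np.errstate(divide="ignore", invalid="ignore"):
        density = np.where(gene_cov > 0, site_counts / np.maximum(gene_cov, 1), 0.0)
    return MetageneProfile(
        anchor=anchor,
        offsets=offsets,
        density=density,
        n_sites=site_counts,
        n_genes=gene_cov,
    )


# ---------------------------------------------------------------------------
# sRNA 5'-end matching
# ---------------------------------------------------------------------------


def match_srna_5p(
    sites: pd.DataFrame, annotation: AnnotationSet, window: int = 3
) -> pd.DataFrame:
    """Match cleavage sites to annotated sRNA 5' ends.

    An sRNA is matched when a same-strand site falls on one of the first
    ``window`` nucleotides of the sRNA (default: the first three bases, in
    transcript orientation) — evidence that the sRNA's mature 5' end is
    generated by RNase E.  Returns one row per matched sRNA with the
    matching site position closest to the 5' end.
    """
    keys = set(sites.index)
    rows = []
    for srna in sorted(annotation.of_type("sRNA"), key=lambda f: f.feature_id):
        p0 = srna.five_prime_pos()
        step = 1 if srna.strand == "+" else -1
        for k in range(window):
            pos = p0 + step * k
            if (srna.chrom, pos, srna.strand) in keys:
                rows.append(
                    (srna.feature_id, srna.chrom, pos, srna.strand, k, srna.parent_gene_id)
                )
                break
    return pd.DataFrame(
        rows,
        columns=["srna_id", "chrom", "site_pos0", "strand", "offset_from_5p", "host_gene_id"],
    )
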