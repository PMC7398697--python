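"""Cleavage consensus motif and sequence/structure context profiles.

The motif model is a 5-column position frequency matrix over the window
spanning two nucleotides upstream and three downstream of the scissile
bond (the site coordinate is the first downstream base, i.e. the detected
5' end).  Per-column information content uses the standard logo formula
R(l) = log2(4) - (H(l) + e_n) with the small-sample correction
e_n = (s - 1) / (2 n ln 2) for alphabet size s = 4; twice e_n is the
total height of the logo error bar.

Sequence context is summarised as an AU-content profile, and structural
context as a folding-energy profile from a Nussinov-style base-pair
energy dynamic programme (GC -3, AU -2, GU -1, hairpin loops >= 3 nt).
The energy is a structure *score* in arbitrary units, not kcal/mol: the
supported readout is the profile shape (less pairing potential around
cleavage sites), and ``mfe_profile`` accepts any callable with the same
signature for users who want a thermodynamic folder.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .coverage_io import Genome
from .errors import InputError

ALPHABET = "ACGT"
_A2I = {c: i for i, c in enumerate(ALPHABET)}

IUPAC_CODES = {
    frozenset("A"): "A",
    frozenset("C"): "C",
    frozenset("G"): "G",
    frozenset("T"): "T",
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("GC"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
    frozenset("CGT"): "B",
    frozenset("AGT"): "D",
    frozenset("ACT"): "H",
    frozenset("ACG"): "V",
    frozenset("ACGT"): "N",
}


# ---------------------------------------------------------------------------
# Site windows and the motif model
# ---------------------------------------------------------------------------


def extract_site_windows(
    sites: pd.DataFrame,
    genome: Genome,
    upstream: int = 2,
    downstream: int = 3,
) -> list[str]:
    """Transcript-orientation sequence windows around each site.

    For a site at position p the window covers genomic
    [p - upstream, p + downstream), reverse-complemented on the - strand so
    the cut always falls between window positions ``upstream`` and
    ``upstream + 1``.  Sites too close to a chromosome end are skipped with
    a warning.
    """
    windows: list[str] = []
    skipped = 0
    for chrom, pos, strand in sites.index:
        start, end = int(pos) - upstream, int(pos) + downstream
        if start < 0 or end > genome.length(chrom):
            skipped += 1
            continue
        windows.append(genome.fetch(chrom, start, end, strand))
    if skipped:
        warnings.warn(
            f"skipped {skipped} site(s) within {upstream} nt of a chromosome end",
            stacklevel=2,
        )
    return windows


@dataclass
class MotifModel:
    """Position frequency matrix over A/C/G/T with logo statistics."""

    counts: np.ndarray  # shape (4, L)
    n: int  # windows per column

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def frequencies(self) -> np.ndarray:
        return self.counts / max(self.n, 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts.T, columns=list(ALPHABET), index=pd.RangeIndex(self.length, name="column")
        )


def position_frequency_matrix(windows: Sequence[str]) -> MotifModel:
    """Tally windows into a PFM; windows containing non-ACGT are skipped."""
    clean = [w.upper() for w in windows if set(w.upper()) <= set(ALPHABET)]
    if not clean:
        raise InputError("no usable windows (empty input or all contain N)")
    length = len(clean[0])
    if any(len(w) != length for w in clean):
        raise InputError("windows have unequal lengths")
    counts = np.zeros((4, length), dtype=np.int64)
    for w in clean:
        for j, c in enumerate(w):
            counts[_A2I[c], j] += 1
    return MotifModel(counts=counts, n=len(clean))


def information_content(model: MotifModel) -> tuple[np.ndarray, float]:
    """Per-column information content R(l) in bits, and e_n.

    R(l) = max(0, 2 - (H(l) + e_n)) with H the Shannon entropy of observed
    column frequencies and e_n = 3 / (2 n ln 2) the small-sample
    correction; the logo error bar totals 2 e_n.
    """
    if model.n < 1:
        raise InputError("motif model is empty")
    freqs = model.frequencies
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(freqs > 0, freqs * np.log2(np.where(freqs > 0, freqs, 1.0)), 0.0)
    entropy = -terms.sum(axis=0)
    e_n = 3.0 / (2.0 * model.n * np.log(2.0))
    r = np.maximum(0.0, 2.0 - (entropy + e_n))
    return r, e_n


def consensus_call(model: MotifModel, iupac_cutoff: float = 0.9) -> str:
    """IUPAC consensus: per column, the smallest high-frequency letter set.

    Letters are added in descending frequency (ties alphabetical) until
    their cumulative frequency reaches ``iupac_cutoff``; the set maps to
    its IUPAC degenerate code (all four letters -> N).
    """
    freqs = model.frequencies
    out = []
    for j in range(model.length):
        col = freqs[:, j]
        order = sorted(range(4), key=lambda i: (-col[i], ALPHABET[i]))
        chosen: list[str] = []
        cum = 0.0
        for i in order:
            chosen.append(ALPHABET[i])
            cum += col[i]
            if cum >= iupac_cutoff:
                break
        out.append(IUPAC_CODES[frozenset(chosen)])
    return "".join(out)


def format_rna_consensus(consensus: str, cut_after: int = 2) -> str:
    """RNA-style display with the scissile bond marked, e.g. 'RN^WUU'."""
    rna = consensus.replace("T", "U")
    return rna[:cut_after] + "↓" + rna[cut_after:]


# ---------------------------------------------------------------------------
# AU-content context
# ---------------------------------------------------------------------------


@dataclass
class ContextProfile:
    """Mean (and SD) of a sequence metric at offsets around sites."""

    metric: str
    offsets: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n_sites: int
    window: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"offset": self.offsets, "mean": self.mean, "sd": self.sd}
        )


def _site_context(
    sites: pd.DataFrame, genome: Genome, left: int, right: int
) -> list[str]:
    """Transcript-orientation context strings covering offsets [left, right)."""
    out = []
    for chrom, pos, strand in sites.index:
        p = int(pos)
        if strand == "+":
            start, end = p + left, p + right
        else:
            start, end = p - right + 1, p - left + 1
        if start < 0 or end > genome.length(chrom):
            continue
        out.append(genome.fetch(chrom, start, end, strand))
    return out


def au_content_profile(
    sites: pd.DataFrame, genome: Genome, flank: int = 50, window: int = 10
) -> ContextProfile:
    """A/U fraction of a sliding window at each offset around the sites.

    At offset o the window covers transcript positions [o, o + window)
    relative to the site; values are averaged over sites (sites whose full
    context leaves the chromosome are dropped).
    """
    contexts = _site_context(sites, genome, -flank, flank + window)
    if not contexts:
        raise InputError("no sites with full context windows")
    arr = np.array([[c in "AT" for c in ctx] for ctx in contexts], dtype=np.float64)
    offsets = np.arange(-flank, flank + 1)
    means = np.empty(offsets.size)
    sds = np.empty(offsets.size)
    for i, o in enumerate(offsets):
        frac = arr[:, i : i + window].mean(axis=1)
        means[i] = frac.mean()
        sds[i] = frac.std(ddof=0)
    return ContextProfile(
        metric="AU_fraction",
        offsets=offsets,
        mean=means,
        sd=sds,
        n_sites=len(contexts),
        window=window,
    )


# ---------------------------------------------------------------------------
# Folding-energy proxy
# ---------------------------------------------------------------------------

PAIR_ENERGY = {
    ("G", "C"): -3.0,
    ("C", "G"): -3.0,
    ("A", "T"): -2.0,
    ("T", "A"): -2.0,
    ("G", "T"): -1.0,
    ("T", "G"): -1.0,
}

MIN_HAIRPIN_LOOP = 3


def fold_energy(sequence: str) -> float:
    """Minimum pairing energy over nested secondary structures.

    Nussinov-style interval dynamic programme: structures are sets of
    non-crossing base pairs with hairpin loops of at least 3 unpaired
    nucleotides; pair energies are GC/CG -3, AU/UA -2, GU/UG -1 (RNA input
    is accepted, U is treated as T).  Returns 0 for unpairable sequences.
    """
    s = sequence.upper().replace("U", "T")
    if not s:
        raise InputError("empty sequence")
    if set(s) - set(ALPHABET):
        raise InputError(f"illegal characters in sequence: {set(s) - set(ALPHABET)}")
    n = len(s)
    if n < MIN_HAIRPIN_LOOP + 2:
        return 0.0
    e = np.zeros((n, n), dtype=np.float64)
    for span in range(MIN_HAIRPIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = min(e[i + 1, j], e[i, j - 1])
            pe = PAIR_ENERGY.get((s[i], s[j]))
            if pe is not None:
                best = min(best, e[i + 1, j - 1] + pe)
            for k in range(i + 1, j):
                v = e[i, k] + e[k + 1, j]
                if v < best:
                    best = v
            e[i, j] = best
    return float(e[0, n - 1])


def mfe_profile(
    sites: pd.DataFrame,
    genome: Genome,
    flank: int = 50,
    window: int = 40,
    step: int = 5,
    energy_fn: Callable[[str], float] = fold_energy,
    max_sites: int | None = None,
) -> ContextProfile:
    """Mean folding energy of sliding windows at offsets around sites.

    ``energy_fn`` defaults to the in-package pair-energy DP and can be
    swapped for an external thermodynamic folder.  ``max_sites`` caps the
    number of sites scored (first rows of the table) to bound runtime.
    """
    use = sites if max_sites is None else sites.iloc[:max_sites]
    contexts = _site_context(use, genome, -flank, flank + window)
    if not contexts:
        raise InputError("no sites with full context windows")
    offsets = np.arange(-flank, flank + 1, step)
    means = np.empty(offsets.size)
    sds = np.empty(offsets.size)
    for i, o in enumerate(offsets):
        j = o + flank
        vals = np.array([energy_fn(ctx[j : j + window]) for ctx in contexts])
        means[i] = vals.mean()
        sds[i] = vals.std(ddof=0)
    return ContextProfile(
        metric="fold_energy",
        offsets=offsets,
        mean=means,
        sd=sds,
        n_sites=len(contexts),
        window=window,
    )


# ---------------------------------------------------------------------------
# Output helpers
# ---------------------------------------------------------------------------


def write_motif_json(
    model: MotifModel, path: str | Path, iupac_cutoff: float = 0.9
) -> dict:
    """Write counts, frequencies, IC, e_n and consensus as JSON; return it."""
    r, e_n = information_content(model)
    consensus = consensus_call(model, iupac_cutoff=iupac_cutoff)
    payload = {
        "alphabet": ALPHABET,
        "n": model.n,
        "counts": model.counts.tolist(),
        "frequencies": model.frequencies.tolist(),
        "information_content_bits": [round(x, 6) for x in r.tolist()],
        "small_sample_correction_bits": round(e_n, 6),
        "error_bar_total_height_bits": round(2 * e_n, 6),
        "consensus_dna": consensus,
        "consensus_rna_display": format_rna_consensus(consensus),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return payload


def write_logo_table(model: MotifModel, path: str | Path) -> None:
    """Logo-ready TSV: per column, letter frequencies and scaled heights."""
    r, e_n = information_content(model)
    freqs = model.frequencies
    with open(path, "w") as fh:
        fh.write("column\tbase\tfrequency\theight_bits\tic_bits\te_n_bits\n")
        for j in range(model.length):
            for i, base in enumerate(ALPHABET):
                fh.write(
                    f"{j}\t{base}\t{freqs[i, j]:.6f}\t{freqs[i, j] * r[j]:.6f}"
                    f"\t{r[j]:.6f}\t{e_n:.6f}\n"
                )
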