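import numpy as np
import pandas as pd
import pytest

import tiercall as tc


def sites_df(keys):
    """Build a bare site table indexed by (chrom, pos0, strand)."""
    idx = pd.MultiIndex.from_tuples(keys, names=["chrom", "pos0", "strand"])
    return pd.DataFrame(index=idx)


@pytest.fixture(scope="session")
def default_scenario():
    """Full default synthetic scenario run once: 2 x 200 kb, 150 genes,
    120 planted sites, 8x depletion, NB dispersion 0.1, triplicates."""
    ds = tc.simulate(seed=1)
    matrix = tc.build_count_matrix(ds.coverages, ds.truth.design)
    results, sf = tc.run_differential(matrix, ds.truth.design)
    sites = tc.call_cleavage_sites(results)
    return {
        "dataset": ds,
        "matrix": matrix,
        "results": results,
        "size_factors": sf,
        "sites": sites,
    }


@pytest.fixture(scope="session")
def null_scenario():
    """Same scenario with zero planted sites (null calibration)."""
    ds = tc.simulate(seed=2, n_planted_sites=0)
    matrix = tc.build_count_matrix(ds.coverages, ds.truth.design)
    results, _ = tc.run_differential(matrix, ds.truth.design)
    sites = tc.call_cleavage_sites(results)
    return {"dataset": ds, "results": results, "sites": sites}


@pytest.fixture(scope="session")
def toy_locus():
    """Hand-built genome + annotation for classification tests.

    chr1 (+): gene1 spans [100, 400): 5'UTR [100,150), CDS [150,350),
    3'UTR [350,400) with a nested sRNA [360,400).
    chr1 (-): gene2 spans [600, 800): 3'UTR [600,700), CDS [700,760),
    5'UTR [760,800).
    """
    rng = np.random.default_rng(42)
    seq = "".join(rng.choice(list("ACGT"), size=1000))
    genome = tc.Genome([("chr1", seq)])
    F = tc.Feature
    feats = [
        F("chr1", 100, 400, "+", "gene", "gene1"),
        F("chr1", 100, 150, "+", "five_prime_UTR", "gene1.5UTR", "gene1"),
        F("chr1", 150, 350, "+", "CDS", "gene1.CDS", "gene1"),
        F("chr1", 350, 400, "+", "three_prime_UTR", "gene1.3UTR", "gene1"),
        F("chr1", 360, 400, "+", "sRNA", "sRNA_gene1", "gene1"),
        F("chr1", 600, 800, "-", "gene", "gene2"),
        F("chr1", 600, 700, "-", "three_prime_UTR", "gene2.3UTR", "gene2"),
        F("chr1", 700, 760, "-", "CDS", "gene2.CDS", "gene2"),
        F("chr1", 760, 800, "-", "five_prime_UTR", "gene2.5UTR", "gene2"),
    ]
    return genome, tc.AnnotationSet(feats, genome=genome)
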