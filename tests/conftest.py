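"""Shared fixtures: one default simulation reused across test modules."""

import numpy as np
import pytest
from hypothesis import settings

from erv_activity import synthetic

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_config():
    return synthetic.SyntheticConfig(seed=11)


@pytest.fixture(scope="session")
def sim(default_config):
    """One full simulation at study-condition defaults."""
    return synthetic.simulate(default_config)


@pytest.fixture(scope="session")
def sim_dir(default_config, tmp_path_factory):
    """The same simulation written to disk (GTF, .out, FASTA, TSVs)."""
    d = tmp_path_factory.mktemp("simdata")
    synthetic.simulate_to_dir(default_config, d)
    return d


def brute_force_context(sim_result):
    """Per-base context oracle: coverage depth and exon membership arrays.

    Independent of the interval-sweep implementation: every chromosome
    position is counted directly.
    """
    cfg = sim_result.config
    L = cfg.chrom_length
    chroms = {}
    for g in sim_result.annotation.genes:
        gene = g.to_gene()
        depth, exon = chroms.setdefault(
            gene.chrom, (np.zeros(L, dtype=np.int16), np.zeros(L, dtype=bool))
        )
        depth[gene.start : gene.end] += 1
        for s, e in gene.exons:
            exon[s:e] = True

    def classify(locus):
        if locus.chrom not in chroms:
            return "intergenic"
        depth, exon = chroms[locus.chrom]
        d = depth[locus.start : locus.end]
        n0 = int((d == 0).sum())
        n1 = int((d == 1).sum())
        n2 = int((d >= 2).sum())
        best = max(n2, n1, n0)
        if n2 == best:
            return "overlapped"
        if n1 == best:
            genic = d >= 1
            ex = exon[locus.start : locus.end] & genic
            n_ex = int(ex.sum())
            if n_ex == int(genic.sum()):
                return "exon"
            if n_ex == 0:
                return "intron"
            return "others"
        return "intergenic"

    return classify
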