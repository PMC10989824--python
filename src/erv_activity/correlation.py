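"""Context-stratified co-expression of active ERV loci with host genes.

Each point is one (locus, host gene) pair; x and y are replicate-mean
log2(TPM + 1) within one tissue.  Pairs are restricted to loci active in
that tissue with a defined host gene, stratified into the three genic
context categories (exon, intron, overlapped).  Intergenic loci have no
assignable target gene and are excluded; intragenic loci spanning an exon
boundary ("others") fit none of the three categories and are excluded too.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

CATEGORIES = ("exon", "intron", "overlapped")


@dataclass(frozen=True)
class CorrelationResult:
    category: str
    tissue: str
    n_pairs: int
    r: float | None
    p_value: float | None
    slope: float | None
    intercept: float | None
    reason: str | None = None  # set when r is undefined


def pair_loci_genes(assignments: dict, activity_table, tissue: str) -> list[tuple[str, str, str]]:
    """(locus, host gene, category) pairs for loci active in ``tissue``.

    One pair per locus, using the majority-overlap host gene.
    """
    active = set(activity_table.active_in(tissue))
    pairs = []
    for lid, asn in assignments.items():
        if lid not in active:
            continue
        category = asn.context_label
        if category not in CATEGORIES:
            continue
        host = asn.host_gene
        if host is None:
            continue
        pairs.append((lid, host, category))
    return sorted(pairs)


def correlate(
    erv_tpm: pd.DataFrame,
    gene_tpm: pd.DataFrame,
    pairs: list[tuple[str, str, str]],
    tissue_samples: list[str],
    tissue: str,
) -> list[CorrelationResult]:
    """Pearson correlation per context category within one tissue.

    x = replicate-mean log2(gene TPM + 1), y = same for the locus.
    Categories with < 3 pairs, or zero variance in x or y, report an
    undefined r with the reason.
    """
    results = []
    for category in CATEGORIES:
        sub = [(l, g) for l, g, c in pairs if c == category]
        if len(sub) < 3:
            results.append(
                CorrelationResult(category, tissue, len(sub), None, None, None, None,
                                  reason="fewer than 3 pairs"))
            continue
        loci = [l for l, _ in sub]
        genes = [g for _, g in sub]
        y = np.log2(erv_tpm.loc[loci, tissue_samples].to_numpy(dtype=float) + 1).mean(axis=1)
        x = np.log2(gene_tpm.loc[genes, tissue_samples].to_numpy(dtype=float) + 1).mean(axis=1)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            results.append(
                CorrelationResult(category, tissue, len(sub), None, None, None, None,
                                  reason="zero variance"))
            continue
        lr = stats.linregress(x, y)
        results.append(
            CorrelationResult(
                category, tissue, len(sub),
                float(lr.rvalue), float(lr.pvalue),
                float(lr.slope), float(lr.intercept),
            )
        )
    return results


def correlation_table(results: list[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "category": r.category,
                "tissue": r.tissue,
                "n_pairs": r.n_pairs,
                "R": r.r,
                "p": r.p_value,
                "slope": r.slope,
                "intercept": r.intercept,
                "note": r.reason or "",
            }
            for r in results
        ]
    )
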