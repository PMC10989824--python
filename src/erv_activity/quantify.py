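"""Read counting (union mode), TPM conversion and a PCA report.

Counting reimplements htseq-count union-mode semantics on one feature set
at a time: a read (or fragment, for pairs) contributes to a feature only
when its aligned blocks overlap exactly one feature; overlaps with two or
more features are discarded as ambiguous, no overlap is ``no_feature``.
Genes and ERV loci are counted in separate passes, so TPM denominators are
computed within each feature set.

TPM_i = 1e6 * (c_i / l_i) / sum_j (c_j / l_j), per sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Features x samples matrix of counts or TPM with sample metadata."""

    values: pd.DataFrame
    lengths: pd.Series
    sample_sheet: pd.DataFrame  # index: sample id; columns: tissue, replicate
    kind: str  # "counts" | "tpm"

    def __post_init__(self) -> None:
        if self.kind not in ("counts", "tpm"):
            raise ValueError(f"bad matrix kind {self.kind!r}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        missing = set(self.values.index) - set(self.lengths.index)
        if missing:
            raise ValueError(f"features missing lengths: {sorted(missing)[:3]}...")

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def tissues(self) -> list[str]:
        return sorted(self.sample_sheet["tissue"].unique())

    def samples_of(self, tissue: str) -> list[str]:
        sel = self.sample_sheet.index[self.sample_sheet["tissue"] == tissue]
        return [s for s in self.values.columns if s in set(sel)]

    def write(self, prefix: str | Path) -> None:
        prefix = str(prefix)
        self.values.to_csv(f"{prefix}.{self.kind}.tsv", sep="\t", index_label="feature")
        self.lengths.rename("length").to_csv(
            f"{prefix}.lengths.tsv", sep="\t", index_label="feature"
        )
        self.sample_sheet.to_csv(f"{prefix}.samples.tsv", sep="\t", index_label="sample")

    @classmethod
    def read(cls, prefix: str | Path, kind: str = "counts") -> "ExpressionMatrix":
        prefix = str(prefix)
        values = pd.read_csv(f"{prefix}.{kind}.tsv", sep="\t", index_col="feature")
        lengths = pd.read_csv(f"{prefix}.lengths.tsv", sep="\t", index_col="feature")[
            "length"
        ]
        sheet = pd.read_csv(f"{prefix}.samples.tsv", sep="\t", index_col="sample")
        return cls(values=values, lengths=lengths, sample_sheet=sheet, kind=kind)


def _feature_trees(features) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for f in features:
        trees.setdefault(f.chrom, IntervalTree()).addi(f.start, f.end, f.locus_id)
    return trees


def count_reads(
    sam_path: str | Path,
    features,
    sample_id: str = "sample",
    stranded: bool = False,
) -> tuple[pd.Series, dict[str, int]]:
    """Union-mode read counting of one SAM file against one feature set.

    Parameters
    ----------
    sam_path
        SAM file with a header.  Paired reads are counted once as a
        fragment, using the union of both mates' aligned blocks.
    features
        Objects with ``locus_id``, ``chrom``, ``start``, ``end`` (and
        ``strand`` when ``stranded``).
    stranded
        Require read strand to match the feature strand.

    Returns
    -------
    (counts, counters)
        Per-feature counts (index = feature ids, in input order) and the
        bookkeeping counters ``assigned``, ``ambiguous``, ``no_feature``,
        ``skipped``; these sum to the number of fragments processed.
    """
    trees = _feature_trees(features)
    strands = {f.locus_id: f.strand for f in features} if stranded else {}
    counts: dict[str, int] = {f.locus_id: 0 for f in features}
    counters = {"assigned": 0, "ambiguous": 0, "no_feature": 0, "skipped": 0}
    pending: dict[str, list] = {}

    def resolve(blocks: list[tuple[str, int, int, bool]]) -> None:
        hits: set[str] = set()
        known_chrom = False
        for chrom, bstart, bend, is_reverse in blocks:
            tree = trees.get(chrom)
            if tree is None:
                continue
            known_chrom = True
            for iv in tree.overlap(bstart, bend):
                if stranded:
                    want = "-" if is_reverse else "+"
                    if strands[iv.data] != want:
                        continue
                hits.add(iv.data)
        if not blocks:
            counters["skipped"] += 1
        elif len(hits) == 1:
            counts[hits.pop()] += 1
            counters["assigned"] += 1
        elif len(hits) == 0:
            if not known_chrom:
                logger.debug("fragment on unknown chromosome counted as no_feature")
            counters["no_feature"] += 1
        else:
            counters["ambiguous"] += 1

    with pysam.AlignmentFile(str(sam_path), "r") as sam:
        if sam.header.nreferences == 0:
            raise ValueError(f"{sam_path}: SAM has no @SQ header records")
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                counters["skipped"] += 1
                continue
            blocks = [
                (rec.reference_name, s, e, rec.is_reverse) for s, e in rec.get_blocks()
            ]
            if rec.is_paired:
                if rec.query_name in pending:
                    resolve(pending.pop(rec.query_name) + blocks)
                else:
                    pending[rec.query_name] = blocks
            else:
                resolve(blocks)
    for blocks in pending.values():  # mates whose partner never appeared
        resolve(blocks)
    series = pd.Series(counts, name=sample_id)
    return series, counters


def count_matrix(
    sam_paths: dict[str, str | Path],
    features,
    sample_sheet: pd.DataFrame,
    stranded: bool = False,
) -> ExpressionMatrix:
    """Count several SAM files (sample id -> path) into one matrix."""
    cols = {}
    for sample, path in sam_paths.items():
        counts, counters = count_reads(path, features, sample, stranded=stranded)
        logger.info("counted %s: %s", sample, counters)
        cols[sample] = counts
    values = pd.DataFrame(cols)
    lengths = pd.Series({f.locus_id: f.end - f.start for f in features})
    return ExpressionMatrix(values, lengths, sample_sheet, "counts")


def compute_tpm(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Convert a counts matrix to TPM (per-sample sums equal 1e6).

    An all-zero sample stays all-zero (no division by zero) and is logged.
    """
    if matrix.kind != "counts":
        raise ValueError("compute_tpm expects a counts matrix")
    lengths = matrix.lengths.reindex(matrix.values.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()][0]
        raise ValueError(f"feature {missing} has no length")
    if (lengths <= 0).any():
        bad = lengths.index[lengths <= 0][0]
        raise ValueError(f"feature {bad} has non-positive length")
    rate = matrix.values.div(lengths, axis=0)
    denom = rate.sum(axis=0)
    zero = denom == 0
    if zero.any():
        logger.warning("all-zero samples in TPM conversion: %s", list(denom.index[zero]))
        denom = denom.replace(0, np.nan)
    tpm = (rate / denom * 1e6).fillna(0.0)
    return ExpressionMatrix(tpm, matrix.lengths, matrix.sample_sheet, "tpm")


def pca_report(
    matrix: ExpressionMatrix, n_components: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples on log2(TPM + 1), centered but not scaled.

    Sign convention: for each component the largest-magnitude feature
    loading is made positive, so coordinates are deterministic.  A zero-
    variance dataset reports all variance fractions as 0.

    Returns a (samples x [PC1..PCk, tissue]) frame and the variance
    fractions of the retained components.
    """
    X = np.log2(matrix.values.to_numpy(dtype=float).T + 1.0)
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 samples")
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(n_components, len(S))
    for comp in range(k):
        j = int(np.argmax(np.abs(Vt[comp])))
        if Vt[comp, j] < 0:
            Vt[comp] *= -1
            U[:, comp] *= -1
    coords = U[:, :k] * S[:k]
    total = float((S**2).sum())
    varfrac = (S[:k] ** 2 / total) if total > 0 else np.zeros(k)
    df = pd.DataFrame(
        coords, index=matrix.values.columns, columns=[f"PC{i+1}" for i in range(k)]
    )
    df["tissue"] = matrix.sample_sheet.reindex(df.index)["tissue"]
    return df, varfrac
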