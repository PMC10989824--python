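"""Gene model construction and two-level genomic-context classification.

The gene model is built from a GTF: per gene, the *refined exon set* is the
union of exons over all annotated transcripts (sorted and merged) and the
introns are the complement of that union within the gene span (min exon
start to max exon end).  Each chromosome is then partitioned by gene-span
coverage depth into intergenic (0 genes), intragenic (exactly 1) and
overlapped (>=2) regions.

An ERV locus is classified at two levels:

* level 1 -- the partition category holding the majority of its bases
  (ties broken overlapped > intragenic > intergenic);
* level 2 (intragenic loci only) -- ``exon`` if the genic part of the locus
  lies entirely within the refined exon union, ``intron`` if it avoids the
  exon union entirely, and ``others`` when it crosses an exon boundary.

Strand is ignored throughout; all coordinates are 0-based half-open.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

LEVEL1 = ("intergenic", "intragenic", "overlapped")
LEVEL2 = ("intron", "exon", "others")


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Sort-and-merge half-open intervals into a disjoint sorted list."""
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _overlap_bp(intervals: Sequence[tuple[int, int]], start: int, end: int) -> int:
    """Total overlap of [start, end) with a sorted disjoint interval list."""
    total = 0
    starts = [s for s, _ in intervals]
    i = max(0, bisect_right(starts, start) - 1)
    for s, e in intervals[i:]:
        if s >= end:
            break
        total += max(0, min(e, end) - max(s, start))
    return total


@dataclass(frozen=True)
class Gene:
    gene_id: str
    chrom: str
    strand: str
    start: int  # min exon start over all transcripts
    end: int  # max exon end
    exons: tuple[tuple[int, int], ...]  # refined (merged) exon union

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        out = []
        for (s1, e1), (s2, _) in zip(self.exons, self.exons[1:]):
            if e1 < s2:
                out.append((e1, s2))
        return tuple(out)


@dataclass(frozen=True)
class ContextAssignment:
    """Two-level context of one locus.

    ``level2`` is present iff ``level1 == "intragenic"``; ``host_genes``
    (gene id, overlap bp) is sorted by descending overlap then gene id and
    is empty iff the locus is intergenic.
    """

    locus_id: str
    level1: str
    level2: str | None
    host_genes: tuple[tuple[str, int], ...]

    @property
    def context_label(self) -> str:
        """Flat five-way label used by summaries and the simulator."""
        if self.level1 == "intragenic":
            return self.level2  # type: ignore[return-value]
        return self.level1

    @property
    def host_gene(self) -> str | None:
        """The single (majority-overlap) host gene, or None if intergenic."""
        return self.host_genes[0][0] if self.host_genes else None


def assign_host_gene(assignment: ContextAssignment) -> str | None:
    """First host gene by descending overlap (ties by gene id); None if intergenic."""
    return assignment.host_gene


@dataclass
class GeneModel:
    genes: dict[str, Gene]
    chrom_lengths: dict[str, int] | None = None
    _span_trees: dict[str, IntervalTree] = field(default_factory=dict, repr=False)
    _segments: dict[str, list[tuple[int, int, int]]] = field(
        default_factory=dict, repr=False
    )
    _exon_union: dict[str, list[tuple[int, int]]] = field(
        default_factory=dict, repr=False
    )

    def __post_init__(self) -> None:
        by_chrom: dict[str, list[Gene]] = {}
        for g in self.genes.values():
            by_chrom.setdefault(g.chrom, []).append(g)
        for chrom, genes in by_chrom.items():
            tree = IntervalTree()
            exons: list[tuple[int, int]] = []
            for g in genes:
                tree.addi(g.start, g.end, g.gene_id)
                exons.extend(g.exons)
            self._span_trees[chrom] = tree
            self._exon_union[chrom] = merge_intervals(exons)
            self._segments[chrom] = self._sweep(genes)

    @staticmethod
    def _sweep(genes: list[Gene]) -> list[tuple[int, int, int]]:
        """Coverage-depth segments (start, end, depth>=1) from gene spans."""
        events: dict[int, int] = {}
        for g in genes:
            events[g.start] = events.get(g.start, 0) + 1
            events[g.end] = events.get(g.end, 0) - 1
        segments = []
        depth = 0
        prev = None
        for pos in sorted(events):
            if prev is not None and depth > 0 and pos > prev:
                segments.append((prev, pos, depth))
            depth += events[pos]
            prev = pos
        return segments

    def chromosomes(self) -> list[str]:
        return sorted(self._span_trees)

    def coverage_bp(self, chrom: str, start: int, end: int) -> tuple[int, int, int]:
        """(intergenic, intragenic, overlapped) bp of [start, end) on chrom."""
        single = multi = 0
        for s, e, depth in self._segments.get(chrom, []):
            if s >= end:
                break
            ov = max(0, min(e, end) - max(s, start))
            if ov == 0:
                continue
            if depth == 1:
                single += ov
            else:
                multi += ov
        return (end - start) - single - multi, single, multi

    def exon_bp(self, chrom: str, start: int, end: int) -> int:
        """Overlap of [start, end) with the chromosome-wide refined exon union."""
        return _overlap_bp(self._exon_union.get(chrom, []), start, end)

    def genes_overlapping(self, chrom: str, start: int, end: int) -> list[tuple[str, int]]:
        """(gene_id, overlap bp) sorted by descending overlap then gene id."""
        tree = self._span_trees.get(chrom)
        if tree is None:
            return []
        hits = []
        for iv in tree.overlap(start, end):
            ov = min(iv.end, end) - max(iv.begin, start)
            hits.append((iv.data, ov))
        return sorted(hits, key=lambda t: (-t[1], t[0]))

    def partition(self, chrom: str, length: int) -> list[tuple[int, int, str]]:
        """Tile [0, length) with labelled (start, end, level1) segments."""
        out: list[tuple[int, int, str]] = []
        pos = 0
        for s, e, depth in self._segments.get(chrom, []):
            s, e = max(0, s), min(e, length)
            if s >= e:
                continue
            if pos < s:
                out.append((pos, s, "intergenic"))
            out.append((s, e, "intragenic" if depth == 1 else "overlapped"))
            pos = e
        if pos < length:
            out.append((pos, length, "intergenic"))
        return out


def _validate_gtf_exons(path: str | Path) -> bool:
    """Check exon records carry gene_id/transcript_id; return True if any features."""
    has_features = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}: line {lineno}: not a 9-column GTF record")
            has_features = True
            if fields[2] != "exon":
                continue
            if "gene_id" not in fields[8]:
                raise ValueError(f"{path}: line {lineno}: exon record lacks gene_id")
            if "transcript_id" not in fields[8]:
                raise ValueError(
                    f"{path}: line {lineno}: exon record lacks transcript_id"
                )
    return has_features


def build_gene_model(
    gtf_path: str | Path, chrom_lengths: dict[str, int] | None = None
) -> GeneModel:
    """Build a :class:`GeneModel` from a GTF file.

    Gene spans are derived from exon records (min exon start to max exon
    end over all transcripts); a GTF with zero features yields a model in
    which everything is intergenic.
    """
    if not _validate_gtf_exons(gtf_path):
        return GeneModel(genes={}, chrom_lengths=chrom_lengths)
    db = gffutils.create_db(
        str(gtf_path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exons_by_gene: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str]] = {}
    for f in db.features_of_type("exon"):
        gid = f.attributes["gene_id"][0]
        exons_by_gene.setdefault(gid, []).append((f.start - 1, f.end))
        meta[gid] = (f.seqid, f.strand if f.strand in "+-" else "+")
    genes = {}
    for gid, exons in exons_by_gene.items():
        merged = merge_intervals(exons)
        chrom, strand = meta[gid]
        genes[gid] = Gene(
            gene_id=gid,
            chrom=chrom,
            strand=strand,
            start=merged[0][0],
            end=merged[-1][1],
            exons=tuple(merged),
        )
    return GeneModel(genes=genes, chrom_lengths=chrom_lengths)


def build_gene_model_from_genes(
    genes: Iterable[Gene], chrom_lengths: dict[str, int] | None = None
) -> GeneModel:
    """Build a model directly from in-memory :class:`Gene` records."""
    return GeneModel(genes={g.gene_id: g for g in genes}, chrom_lengths=chrom_lengths)


def classify_locus(locus, model: GeneModel) -> ContextAssignment:
    """Classify one ERV locus into the two-level context scheme.

    ``locus`` needs ``locus_id``, ``chrom``, ``start`` and ``end``
    attributes.  Loci on chromosomes absent from the model are intergenic
    by convention (logged).
    """
    if locus.chrom not in model._span_trees:
        logger.debug("locus %s: chromosome %s not in gene model", locus.locus_id, locus.chrom)
        return ContextAssignment(locus.locus_id, "intergenic", None, ())
    inter, single, multi = model.coverage_bp(locus.chrom, locus.start, locus.end)
    best = max(multi, single, inter)
    if multi == best:
        level1 = "overlapped"
    elif single == best:
        level1 = "intragenic"
    else:
        level1 = "intergenic"
    host = tuple(model.genes_overlapping(locus.chrom, locus.start, locus.end))
    if level1 == "intergenic":
        return ContextAssignment(locus.locus_id, "intergenic", None, host)
    if level1 == "overlapped":
        return ContextAssignment(locus.locus_id, "overlapped", None, host)
    genic = single + multi
    exon_in_genic = model.exon_bp(locus.chrom, locus.start, locus.end)
    if exon_in_genic == genic:
        level2 = "exon"
    elif exon_in_genic == 0:
        level2 = "intron"
    else:
        level2 = "others"
    return ContextAssignment(locus.locus_id, "intragenic", level2, host)


def classify_catalog(catalog, model: GeneModel) -> dict[str, ContextAssignment]:
    """Classify every locus; returns mapping locus_id -> assignment."""
    return {loc.locus_id: classify_locus(loc, model) for loc in catalog}


def write_assignments(assignments: dict[str, ContextAssignment], path: str | Path) -> None:
    """Write assignments as TSV (locus_id, level1, level2, host_gene, overlap_bp)."""
    with open(path, "w") as fh:
        fh.write("locus_id\tlevel1\tlevel2\thost_gene\toverlap_bp\n")
        for lid in sorted(assignments):
            a = assignments[lid]
            hg = a.host_gene or "."
            ov = a.host_genes[0][1] if a.host_genes else 0
            fh.write(f"{lid}\t{a.level1}\t{a.level2 or '.'}\t{hg}\t{ov}\n")


def read_assignments(path: str | Path) -> dict[str, ContextAssignment]:
    """Read a TSV written by :func:`write_assignments`.

    Only the majority host gene survives a round-trip; that is the only
    one downstream consumers (correlation pairing) use.
    """
    out = {}
    with open(path) as fh:
        header = fh.readline()
        assert header.startswith("locus_id")
        for line in fh:
            lid, l1, l2, hg, ov = line.rstrip("\n").split("\t")
            host = () if hg == "." else ((hg, int(ov)),)
            out[lid] = ContextAssignment(lid, l1, None if l2 == "." else l2, host)
    return out
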