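"""ERV locus catalog: RepeatMasker ``.out`` parsing, class assignment, summaries.

RepeatMasker reports one row per repeat match in a whitespace-aligned table
with three header lines and 1-based inclusive query coordinates; the strand
column uses ``C`` for the complement strand.  Rows whose class/family field
is an LTR-type repeat become :class:`ErvLocus` records (internally 0-based
half-open); everything else (SINE/LINE/DNA/Simple_repeat/...) is skipped
and counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

logger = logging.getLogger(__name__)

#: The four ERV classes summarised in catalog tables, in display order.
ERV_CLASSES = ("ERV1", "ERVK", "ERVL", "ERVL-MaLR")

#: Context columns of the per-chromosome summary table.
SUMMARY_CONTEXTS = ("Intron", "Exon", "Others", "Intergenic", "Overlapped region")


@dataclass(frozen=True)
class ErvLocus:
    """One ERV repeat interval.

    Coordinates are 0-based half-open; ``length == end - start``.
    """

    locus_id: str
    chrom: str
    start: int
    end: int
    strand: str
    family: str
    erv_class: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"locus {self.locus_id}: start must be < end ({self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"locus {self.locus_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


class RepeatMaskerParseError(ValueError):
    """A malformed row in a RepeatMasker ``.out`` file."""


def assign_erv_class(family_or_class: str) -> str:
    """Map a RepeatMasker class/family string to an ERV class.

    Longest-token precedence: ``ERVL-MaLR`` must win before ``ERVL``;
    any other LTR-type string falls into ``other-LTR``.  Total function.
    """
    if not family_or_class:
        raise ValueError("empty class/family string")
    s = family_or_class
    if "ERVL-MaLR" in s:
        return "ERVL-MaLR"
    if "ERVL" in s:
        return "ERVL"
    if "ERVK" in s:
        return "ERVK"
    if "ERV1" in s:
        return "ERV1"
    return "other-LTR"


def _is_ltr_row(class_family: str) -> bool:
    return class_family.split("/")[0].rstrip("?") == "LTR"


def parse_repeatmasker(path: str | Path, stats: dict | None = None) -> list[ErvLocus]:
    """Parse a RepeatMasker ``.out`` file into an ERV locus catalog.

    Parameters
    ----------
    path
        RepeatMasker ``.out`` file (3 header lines, whitespace-aligned
        columns, 1-based inclusive query coordinates, strand ``+``/``C``).
    stats
        Optional dict; on return holds ``parsed`` (loci emitted) and
        ``skipped`` (non-LTR rows).

    Returns
    -------
    list of ErvLocus
        One locus per LTR-type row, ids ``erv_NNNNNN`` in row order,
        coordinates converted to 0-based half-open, ``C`` mapped to ``-``.
        An empty file after headers yields an empty catalog.
    """
    loci: list[ErvLocus] = []
    skipped = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = line.split()
            # The two header lines start with column titles, not scores.
            if fields[0] in ("SW", "score"):
                continue
            if len(fields) < 14:
                raise RepeatMaskerParseError(
                    f"{path}: line {lineno}: expected >=14 whitespace-separated "
                    f"fields, got {len(fields)}"
                )
            try:
                chrom = fields[4]
                begin = int(fields[5])
                end = int(fields[6])
                strand = fields[8]
                family = fields[9]
                class_family = fields[10]
            except ValueError as exc:
                raise RepeatMaskerParseError(
                    f"{path}: line {lineno}: malformed row: {exc}"
                ) from exc
            if strand not in ("+", "C"):
                raise RepeatMaskerParseError(
                    f"{path}: line {lineno}: bad strand field {strand!r}"
                )
            if not _is_ltr_row(class_family):
                skipped += 1
                continue
            loci.append(
                ErvLocus(
                    locus_id=f"erv_{len(loci):06d}",
                    chrom=chrom,
                    start=begin - 1,
                    end=end,
                    strand="+" if strand == "+" else "-",
                    family=family,
                    erv_class=assign_erv_class(class_family),
                )
            )
    if skipped:
        logger.info("parse_repeatmasker: skipped %d non-LTR rows", skipped)
    if stats is not None:
        stats["parsed"] = len(loci)
        stats["skipped"] = skipped
    return loci


def write_bed(catalog: Iterable[ErvLocus], path: str | Path) -> None:
    """Write the catalog as BED6 plus class and family columns."""
    with open(path, "w") as fh:
        for loc in catalog:
            fh.write(
                f"{loc.chrom}\t{loc.start}\t{loc.end}\t{loc.locus_id}\t0\t"
                f"{loc.strand}\t{loc.erv_class}\t{loc.family}\n"
            )


def read_bed(path: str | Path) -> list[ErvLocus]:
    """Read a catalog written by :func:`write_bed`."""
    loci = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, end, name, _score, strand, cls, family = line.rstrip(
                "\n"
            ).split("\t")
            loci.append(
                ErvLocus(
                    locus_id=name,
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    strand=strand,
                    family=family,
                    erv_class=cls,
                )
            )
    return loci


def summarize_catalog(
    catalog: list[ErvLocus],
    context_assignments: dict,
    include_other_ltr: bool = False,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-chromosome x class x context count table plus class bp fractions.

    Parameters
    ----------
    catalog
        ERV loci.
    context_assignments
        Mapping locus_id -> :class:`~erv_activity.context.ContextAssignment`.
    include_other_ltr
        Whether loci of class ``other-LTR`` enter the table; excluded by
        default so the table mirrors the four-class layout.

    Returns
    -------
    (table, bp_fractions)
        ``table`` has one row per chromosome and a (class, context)
        MultiIndex on columns; its grand total equals the number of
        summarised loci.  ``bp_fractions`` gives each class's fraction of
        total ERV bp (over the same loci).
    """
    classes = list(ERV_CLASSES) + (["other-LTR"] if include_other_ltr else [])
    rows: dict[str, dict[tuple[str, str], int]] = {}
    bp: dict[str, int] = {c: 0 for c in classes}
    n_summarised = 0
    for loc in catalog:
        if loc.locus_id not in context_assignments:
            raise KeyError(f"locus {loc.locus_id} has no context assignment")
        if loc.erv_class not in classes:
            continue
        asn = context_assignments[loc.locus_id]
        ctx = {
            "intergenic": "Intergenic",
            "overlapped": "Overlapped region",
            "intron": "Intron",
            "exon": "Exon",
            "others": "Others",
        }[asn.context_label]
        cell = rows.setdefault(loc.chrom, {})
        cell[(loc.erv_class, ctx)] = cell.get((loc.erv_class, ctx), 0) + 1
        bp[loc.erv_class] += loc.length
        n_summarised += 1
    columns = pd.MultiIndex.from_product(
        [classes, SUMMARY_CONTEXTS], names=["class", "context"]
    )
    table = pd.DataFrame(0, index=sorted(rows), columns=columns, dtype=int)
    for chrom, cells in rows.items():
        for key, n in cells.items():
            table.loc[chrom, key] = n
    table.index.name = "chrom"
    assert int(table.to_numpy().sum()) == n_summarised
    total_bp = sum(bp.values())
    fractions = pd.Series(
        {c: (bp[c] / total_bp if total_bp else 0.0) for c in classes}, name="bp_fraction"
    )
    return table, fractions
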