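"""Synthetic inputs with planted ground truth for every pipeline stage.

The generator emulates the study design the pipeline targets: a
multi-chromosome genome with a GTF gene annotation (including overlapping
gene pairs and multi-transcript genes, so exon-union refinement is
exercised), a RepeatMasker-format ERV catalog spanning all context
categories and the four ERV classes, negative-binomial multi-tissue count
matrices with planted active/inactive, tissue-specific and gene-coupled
loci, and locus nucleotide sequences carrying mutated env ORFs of known
retroviral genus.

Counts, not reads, are the primary simulated unit (the downstream claims
live at count level); a small SAM emitter with uniform read placement
exists solely to exercise the counting path.

All outputs are pure functions of (config, seed): the same configuration
produces byte-identical files.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from .catalog import ErvLocus
from .context import Gene, GeneModel, build_gene_model_from_genes, merge_intervals

logger = logging.getLogger(__name__)

CONTEXTS = ("intergenic", "intron", "exon", "others", "overlapped")
CLASSES = ("ERV1", "ERVK", "ERVL", "ERVL-MaLR")
GENERA = (
    "Gammaretrovirus",
    "Alpharetrovirus",
    "Betaretrovirus",
    "Epsilonretrovirus",
    "Lentivirus",
    "Deltaretrovirus",
    "Spumaretrovirus",
)
TISSUE_NAMES = ("lung", "trachea", "amygdala")

# Log2-scale parameters of the expression model (documented in the methods
# note; the analytic correlation helper below depends on them).
GENE_LOG2_MEAN = 5.0
GENE_LOG2_SD = 2.0
GENE_TISSUE_SD = 0.25
ERV_LOG2_BASE = 3.0
ERV_LOG2_SD = 1.0

_FAMILIES = {
    "ERV1": ("MER4-int", "HERVE-int", "LTR10A"),
    "ERVK": ("ERVK9-int", "MER11A", "LTR5"),
    "ERVL": ("ERVL-int", "MLT2A1", "LTR16A"),
    "ERVL-MaLR": ("MLT1A", "MSTA", "THE1B"),
}
_CLASS_STRINGS = {
    "ERV1": "LTR/ERV1",
    "ERVK": "LTR/ERVK",
    "ERVL": "LTR/ERVL",
    "ERVL-MaLR": "LTR/ERVL-MaLR",
}
_DECOYS = (("AluY", "SINE/Alu"), ("L1MA4", "LINE/L1"), ("(TA)n", "Simple_repeat"))

AA20 = "ACDEFGHIKLMNPQRSTVWY"
_AA_TO_CODONS: dict[str, list[str]] = {}
for codon, aa in standard_dna_table.forward_table.items():
    _AA_TO_CODONS.setdefault(aa, []).append(codon)
for aa in _AA_TO_CODONS:
    _AA_TO_CODONS[aa].sort()


class PackingError(ValueError):
    """Genes cannot fit on the configured chromosomes."""


class ContextInfeasibleError(ValueError):
    """A requested ERV context cannot be planted in the annotation."""


@dataclass
class SyntheticConfig:
    """All knobs of the generator; defaults are the study conditions.

    Defaults mirror the target study design: three tissues x three
    replicates, 44% of loci active, 38.1% of active loci tissue-specific,
    a class mix of 46.8 / 29.9 / 15.1 / 8.2% (ERVL-MaLR / ERVL / ERV1 /
    ERVK) and a context mix dominated by intergenic (71.4%) and intronic
    loci.
    """

    n_chromosomes: int = 2
    chrom_length: int = 1_000_000
    n_genes: int = 200
    frac_overlapping_gene_pairs: float = 0.05
    n_erv_loci: int = 2000
    class_mix: dict = field(
        default_factory=lambda: {
            "ERVL-MaLR": 0.468,
            "ERVL": 0.299,
            "ERV1": 0.151,
            "ERVK": 0.082,
        }
    )
    context_mix: dict = field(
        default_factory=lambda: {
            "intergenic": 0.714,
            "intron": 0.270,
            "exon": 0.006,
            "others": 0.006,
            "overlapped": 0.004,
        }
    )
    n_tissues: int = 3
    n_replicates: int = 3
    frac_active: float = 0.44
    frac_tissue_specific: float = 0.381
    frac_shared_pair: float = 0.15
    frac_core_upregulated: float = 0.15
    planted_log2fc: float = 2.0
    nb_dispersion: float = 0.1
    coupling_by_context: dict = field(
        default_factory=lambda: {
            "exon": 0.3,
            "intron": 0.6,
            "others": 0.3,
            "overlapped": 0.9,
            "intergenic": 0.0,
        }
    )
    library_size: int = 1_000_000
    n_env_loci: int = 24
    env_mutation_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_chromosomes", "chrom_length", "n_tissues", "n_replicates",
                     "library_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("n_genes", "n_erv_loci", "n_env_loci"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("frac_overlapping_gene_pairs", "frac_active",
                     "frac_tissue_specific", "frac_shared_pair",
                     "frac_core_upregulated", "env_mutation_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        for mix, keys in ((self.class_mix, CLASSES), (self.context_mix, CONTEXTS)):
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError(f"mix fractions must sum to 1: {mix}")
            unknown = set(mix) - set(keys)
            if unknown:
                raise ValueError(f"unknown mix keys: {unknown}")
            if any(v < 0 for v in mix.values()):
                raise ValueError("mix fractions must be non-negative")
        for ctx, c in self.coupling_by_context.items():
            if not 0.0 <= c <= 1.0:
                raise ValueError(f"coupling for {ctx} outside [0, 1]")

    @property
    def tissues(self) -> tuple[str, ...]:
        names = list(TISSUE_NAMES[: self.n_tissues])
        names += [f"tissue{i+1}" for i in range(len(names), self.n_tissues)]
        return tuple(names)

    @property
    def samples(self) -> list[tuple[str, str, int]]:
        """(sample id, tissue, replicate) triples."""
        return [
            (f"{t}_r{r+1}", t, r + 1)
            for t in self.tissues
            for r in range(self.n_replicates)
        ]


@dataclass
class GroundTruth:
    """Planted truth for every emitted locus."""

    tissues: tuple[str, ...] = ()
    context: dict = field(default_factory=dict)  # locus -> context label
    host_gene: dict = field(default_factory=dict)  # locus -> gene id or None
    activity: dict = field(default_factory=dict)  # locus -> sorted tuple of tissues
    planted_lfc: dict = field(default_factory=dict)  # locus -> (tissue, log2fc)
    env: dict = field(default_factory=dict)  # locus -> {genus, query_id, ...}

    def validate(self, catalog: list[ErvLocus]) -> None:
        ids = [loc.locus_id for loc in catalog]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate locus ids in catalog")
        if set(self.context) != set(ids):
            raise ValueError("truth context labels do not cover the catalog exactly")
        active = {lid for lid, ts in self.activity.items() if ts}
        specific = {lid for lid, ts in self.activity.items() if len(ts) == 1}
        if not specific <= active:
            raise ValueError("tissue-specific loci must be a subset of active loci")

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "tissues": list(self.tissues),
                    "context": self.context,
                    "host_gene": self.host_gene,
                    "activity": {k: list(v) for k, v in self.activity.items()},
                    "planted_lfc": {k: list(v) for k, v in self.planted_lfc.items()},
                    "env": self.env,
                },
                fh,
                indent=1,
                sort_keys=True,
            )
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            tissues=tuple(d["tissues"]),
            context=d["context"],
            host_gene=d["host_gene"],
            activity={k: tuple(v) for k, v in d["activity"].items()},
            planted_lfc={k: (v[0], float(v[1])) for k, v in d["planted_lfc"].items()},
            env=d["env"],
        )


def _allocate(n: int, fractions: dict) -> dict:
    """Largest-remainder allocation of n items over fractional shares."""
    quotas = {k: n * f for k, f in fractions.items()}
    base = {k: int(math.floor(q)) for k, q in quotas.items()}
    left = n - sum(base.values())
    order = sorted(quotas, key=lambda k: (-(quotas[k] - base[k]), k))
    for k in order[:left]:
        base[k] += 1
    return base


def _rng(config: SyntheticConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stage])


# ---------------------------------------------------------------------------
# Annotation


@dataclass
class SynGene:
    gene_id: str
    chrom: str
    strand: str
    offset: int  # genomic start of the first exon
    transcripts: dict  # transcript id -> list of (start, end), genomic

    @property
    def exon_union(self) -> list[tuple[int, int]]:
        return merge_intervals(
            [iv for exons in self.transcripts.values() for iv in exons]
        )

    def to_gene(self) -> Gene:
        union = self.exon_union
        return Gene(
            gene_id=self.gene_id,
            chrom=self.chrom,
            strand=self.strand,
            start=union[0][0],
            end=union[-1][1],
            exons=tuple(union),
        )


@dataclass
class Annotation:
    genes: list
    chrom_lengths: dict

    @property
    def model(self) -> GeneModel:
        return build_gene_model_from_genes(
            [g.to_gene() for g in self.genes], self.chrom_lengths
        )

    def to_gtf(self, path: str | Path) -> None:
        lines = ["#!genome-build synthetic", "#!genome-version 1"]
        for g in sorted(self.genes, key=lambda g: (g.chrom, g.offset, g.gene_id)):
            union = g.exon_union
            span = (union[0][0] + 1, union[-1][1])
            attrs = f'gene_id "{g.gene_id}";'
            lines.append(
                f"{g.chrom}\tsynthetic\tgene\t{span[0]}\t{span[1]}\t.\t{g.strand}\t.\t{attrs}"
            )
            for tid in sorted(g.transcripts):
                exons = g.transcripts[tid]
                tattrs = f'gene_id "{g.gene_id}"; transcript_id "{tid}";'
                lines.append(
                    f"{g.chrom}\tsynthetic\ttranscript\t{exons[0][0] + 1}\t"
                    f"{exons[-1][1]}\t.\t{g.strand}\t.\t{tattrs}"
                )
                for s, e in exons:
                    lines.append(
                        f"{g.chrom}\tsynthetic\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{tattrs}"
                    )
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")


def _gene_structure(rng: np.random.Generator) -> list[tuple[int, int]]:
    """Relative exon intervals of one gene (intron lengths >= 1500)."""
    n_exons = int(rng.integers(2, 4))
    exon_lens = rng.integers(400, 801, size=n_exons)
    intron_lens = rng.integers(1500, 3501, size=n_exons - 1)
    exons = []
    pos = 0
    for i in range(n_exons):
        exons.append((pos, pos + int(exon_lens[i])))
        pos += int(exon_lens[i])
        if i < n_exons - 1:
            pos += int(intron_lens[i])
    return exons


def _make_transcripts(
    gene_id: str, exons_rel: list[tuple[int, int]], offset: int, rng: np.random.Generator
) -> dict:
    """One full transcript plus (usually) a variant exercising exon-union merge."""
    genomic = [(offset + s, offset + e) for s, e in exons_rel]
    transcripts = {f"{gene_id}.t1": genomic}
    if rng.random() < 0.6:
        if len(genomic) >= 3 and rng.random() < 0.5:
            skip = int(rng.integers(1, len(genomic) - 1))
            variant = [iv for i, iv in enumerate(genomic) if i != skip]
        else:
            # extend the first exon into the intron: the union differs from t1
            ext = int(rng.integers(100, 301))
            s0, e0 = genomic[0]
            limit = genomic[1][0] - 100 if len(genomic) > 1 else e0 + ext
            variant = [(s0, min(e0 + ext, limit))] + genomic[1:]
        transcripts[f"{gene_id}.t2"] = variant
    return transcripts


def generate_annotation(config: SyntheticConfig) -> Annotation:
    """Generate the toy gene annotation.

    Overlapping gene pairs: floor(n_genes * frac_overlapping_gene_pairs / 2)
    pairs share a span overlap of 500-1200 bp.  Raises
    :class:`PackingError` when genes cannot fit in the chromosomes.
    """
    rng = _rng(config, 1)
    chroms = [f"chr{i+1}" for i in range(config.n_chromosomes)]
    chrom_lengths = {c: config.chrom_length for c in chroms}
    if config.n_genes == 0:
        return Annotation(genes=[], chrom_lengths=chrom_lengths)

    n_pairs = int(config.n_genes * config.frac_overlapping_gene_pairs / 2)
    # Units: overlapping pairs first, then singletons.
    units: list[list[list[tuple[int, int]]]] = []
    for _ in range(n_pairs):
        units.append([_gene_structure(rng), _gene_structure(rng)])
    for _ in range(config.n_genes - 2 * n_pairs):
        units.append([_gene_structure(rng)])

    per_chrom: dict[str, list] = {c: [] for c in chroms}
    for i, unit in enumerate(units):
        per_chrom[chroms[i % len(chroms)]].append(unit)

    genes: list[SynGene] = []
    gene_idx = 0
    min_gap = 1000
    for chrom in chroms:
        chrom_units = per_chrom[chrom]
        if not chrom_units:
            continue
        spans = []
        overlaps = []
        for unit in chrom_units:
            if len(unit) == 2:
                la = unit[0][-1][1]
                lb = unit[1][-1][1]
                ov = int(rng.integers(500, min(1201, min(la, lb))))
                spans.append(la + lb - ov)
                overlaps.append(ov)
            else:
                spans.append(unit[0][-1][1])
                overlaps.append(0)
        needed = sum(spans) + (len(chrom_units) + 1) * min_gap
        if needed > config.chrom_length:
            raise PackingError(
                f"{chrom}: {len(chrom_units)} gene units need {needed} bp "
                f"but chrom_length is {config.chrom_length}"
            )
        slack = config.chrom_length - needed
        extras = rng.multinomial(slack, [1.0 / (len(chrom_units) + 1)] * (len(chrom_units) + 1))
        pos = min_gap + int(extras[0])
        for ui, unit in enumerate(chrom_units):
            offset = pos
            for gi, exons_rel in enumerate(unit):
                if gi == 1:
                    offset = pos + unit[0][-1][1] - overlaps[ui]
                gid = f"g{gene_idx:04d}"
                gene_idx += 1
                strand = "+" if rng.random() < 0.5 else "-"
                transcripts = _make_transcripts(gid, exons_rel, offset, rng)
                genes.append(SynGene(gid, chrom, strand, offset, transcripts))
            pos += spans[ui] + min_gap + int(extras[ui + 1])
    return Annotation(genes=genes, chrom_lengths=chrom_lengths)


# ---------------------------------------------------------------------------
# ERV catalog


def _context_regions(model: GeneModel, chrom_lengths: dict) -> dict:
    """Candidate placement regions per context.

    intergenic/overlapped: depth-0 / depth->=2 partition segments;
    intron/exon: depth-1 segments intersected with the exon-union
    complement / the exon union; others: exon boundaries inside depth-1
    segments (stored as (chrom, boundary, lo, hi) windows).
    """
    regions: dict = {c: [] for c in CONTEXTS}
    for chrom, length in sorted(chrom_lengths.items()):
        exon_union = model._exon_union.get(chrom, [])
        for s, e, label in model.partition(chrom, length):
            if label == "intergenic":
                if e - s >= 120:
                    regions["intergenic"].append((chrom, s + 1, e - 1))
            elif label == "overlapped":
                if e - s >= 120:
                    regions["overlapped"].append((chrom, s + 1, e - 1))
            else:  # depth-1: split by the exon union
                pieces = [(s, e)]
                exonic = []
                for xs, xe in exon_union:
                    if xe <= s or xs >= e:
                        continue
                    exonic.append((max(xs, s), min(xe, e)))
                for xs, xe in exonic:
                    if xe - xs >= 120:
                        regions["exon"].append((chrom, xs + 1, xe - 1))
                intronic = []
                pos = s
                for xs, xe in exonic:
                    if pos < xs:
                        intronic.append((pos, xs))
                    pos = xe
                if pos < e:
                    intronic.append((pos, e))
                for is_, ie in intronic:
                    if ie - is_ >= 120:
                        regions["intron"].append((chrom, is_ + 1, ie - 1))
                # exon/intron boundaries strictly inside the segment
                for xs, xe in exonic:
                    for b in (xs, xe):
                        lo = max(s + 1, b - 400)
                        hi = min(e - 1, b + 400)
                        if b - lo >= 60 and hi - b >= 60:
                            regions["others"].append((chrom, b, lo, hi))
    return regions


def generate_erv_catalog(
    config: SyntheticConfig, annotation: Annotation
) -> tuple[list[ErvLocus], GroundTruth]:
    """Plant n_erv_loci ERV intervals with known context labels.

    Contexts are planted against the gene model derived from the emitted
    annotation, so re-deriving them downstream recovers the planted labels
    exactly.  Raises :class:`ContextInfeasibleError` when a requested
    context has no candidate region (e.g. ``overlapped`` without
    overlapping genes).
    """
    rng = _rng(config, 2)
    model = annotation.model
    truth = GroundTruth(tissues=config.tissues)
    counts = _allocate(config.n_erv_loci, config.context_mix)
    regions = _context_regions(model, annotation.chrom_lengths)
    for ctx, n in counts.items():
        if n > 0 and not regions[ctx]:
            raise ContextInfeasibleError(
                f"context {ctx!r}: requested {n} loci but the annotation offers "
                "no suitable region"
            )
    class_counts = _allocate(config.n_erv_loci, config.class_mix)
    class_pool = [c for c, n in sorted(class_counts.items()) for _ in range(n)]
    rng.shuffle(class_pool)

    placements = []  # (chrom, start, end, context)
    for ctx in CONTEXTS:
        for _ in range(counts[ctx]):
            if ctx == "others":
                chrom, b, lo, hi = regions[ctx][int(rng.integers(len(regions[ctx])))]
                left = int(rng.integers(50, min(400, b - lo) + 1))
                right = int(rng.integers(50, min(400, hi - b) + 1))
                start, end = b - left, b + right
            else:
                chrom, rs, re_ = regions[ctx][int(rng.integers(len(regions[ctx])))]
                max_len = min(1500, re_ - rs)
                length = int(rng.integers(100, max_len + 1)) if max_len > 100 else max_len
                start = int(rng.integers(rs, re_ - length + 1))
                end = start + length
            placements.append((chrom, start, end, ctx))

    placements.sort(key=lambda p: (p[0], p[1], p[2]))
    catalog = []
    for i, (chrom, start, end, ctx) in enumerate(placements):
        cls = class_pool[i]
        fam_options = _FAMILIES[cls]
        family = fam_options[int(rng.integers(len(fam_options)))]
        lid = f"erv_{i:06d}"
        catalog.append(
            ErvLocus(
                locus_id=lid,
                chrom=chrom,
                start=start,
                end=end,
                strand="+" if rng.random() < 0.5 else "-",
                family=family,
                erv_class=cls,
            )
        )
        truth.context[lid] = ctx
        if ctx == "intergenic":
            truth.host_gene[lid] = None
        else:
            hosts = model.genes_overlapping(chrom, start, end)
            truth.host_gene[lid] = hosts[0][0] if hosts else None
    return catalog, truth


def write_repeatmasker(
    catalog: list[ErvLocus],
    path: str | Path,
    chrom_lengths: dict,
    config: SyntheticConfig | None = None,
    n_decoys: int | None = None,
) -> None:
    """Emit a RepeatMasker ``.out`` file (3 header lines, 15 columns).

    A sprinkling of non-LTR decoy rows (SINE/LINE/Simple_repeat) is
    interleaved so parsers must skip them; decoys never collide with the
    planted locus ids because ids are assigned per LTR row.
    """
    seed = config.seed if config is not None else 0
    rng = np.random.default_rng([seed, 3])
    if n_decoys is None:
        n_decoys = len(catalog) // 50
    rows = []
    for loc in catalog:
        rows.append(
            (
                loc.chrom,
                loc.start + 1,
                loc.end,
                "+" if loc.strand == "+" else "C",
                loc.family,
                _CLASS_STRINGS[loc.erv_class],
            )
        )
    chroms = sorted(chrom_lengths)
    for _ in range(n_decoys):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(1, chrom_lengths[chrom] - 400))
        length = int(rng.integers(80, 400))
        fam, cls = _DECOYS[int(rng.integers(len(_DECOYS)))]
        rows.append((chrom, start, start + length, "+", fam, cls))
    rows.sort(key=lambda r: (r[0], r[1], r[2]))
    header = (
        "   SW   perc perc perc  query      position in query           matching"
        "       repeat              position in repeat\n"
        "score   div. del. ins.  sequence   begin  end          (left)  repeat"
        "         class/family        begin  end    (left)   ID\n"
        "\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for i, (chrom, begin, end, strand, fam, cls) in enumerate(rows, start=1):
            score = int(rng.integers(200, 5000))
            div = rng.uniform(1.0, 30.0)
            dele = rng.uniform(0.0, 8.0)
            ins = rng.uniform(0.0, 8.0)
            left = chrom_lengths[chrom] - end
            rlen = end - begin + 1
            fh.write(
                f"{score:>5} {div:5.1f} {dele:4.1f} {ins:4.1f}  {chrom:<9} "
                f"{begin:>7} {end:>7} ({left}) {strand} {fam:<14} {cls:<18} "
                f"{1:>5} {rlen:>6} (0) {i:>6}\n"
            )


# ---------------------------------------------------------------------------
# Counts


def simulate_counts(
    config: SyntheticConfig,
    truth: GroundTruth,
    annotation: Annotation,
    catalog: list[ErvLocus],
):
    """NB-distributed count matrices for genes and ERV loci.

    Extends ``truth`` in place with per-locus activity sets and planted
    fold changes.  Per-sample totals are scaled to library_size with a
    0.95-1.05 depth jitter; inactive loci have expected count exactly 0;
    a locus with host gene g and context c has
    log2 mu = coupling[c] * log2 mu_g + an independent N(3, 1) term.

    Returns (gene matrix, erv matrix) as
    :class:`~erv_activity.quantify.ExpressionMatrix` counts.
    """
    import pandas as pd

    from .quantify import ExpressionMatrix

    rng = _rng(config, 4)
    tissues = config.tissues
    genes = [g.to_gene() for g in annotation.genes]
    gene_ids = [g.gene_id for g in genes]
    n_genes, n_loci = len(genes), len(catalog)

    gene_base = rng.normal(GENE_LOG2_MEAN, GENE_LOG2_SD, size=n_genes)
    gene_tissue = rng.normal(0.0, GENE_TISSUE_SD, size=(n_genes, len(tissues)))
    gene_log2 = gene_base[:, None] + gene_tissue  # genes x tissues

    # --- plant activity sets ------------------------------------------------
    locus_ids = [loc.locus_id for loc in catalog]
    n_active = int(round(config.frac_active * n_loci))
    order = rng.permutation(n_loci)
    active_idx = order[:n_active]
    n_ts = int(round(config.frac_tissue_specific * n_active))
    n_shared = int(round(config.frac_shared_pair * n_active)) if len(tissues) > 2 else 0
    ts_idx = active_idx[:n_ts]
    shared_idx = active_idx[n_ts : n_ts + n_shared]
    core_idx = active_idx[n_ts + n_shared :]
    for lid in locus_ids:
        truth.activity[lid] = ()
    for j, i in enumerate(ts_idx):
        truth.activity[locus_ids[i]] = (tissues[j % len(tissues)],)
    pair_choices = [
        (a, b) for ai, a in enumerate(tissues) for b in tissues[ai + 1 :]
    ]
    for j, i in enumerate(shared_idx):
        truth.activity[locus_ids[i]] = tuple(sorted(pair_choices[j % len(pair_choices)]))
    for i in core_idx:
        truth.activity[locus_ids[i]] = tuple(sorted(tissues))
    n_up = int(round(config.frac_core_upregulated * len(core_idx)))
    for j, i in enumerate(core_idx[:n_up]):
        truth.planted_lfc[locus_ids[i]] = (
            tissues[j % len(tissues)],
            config.planted_log2fc,
        )

    # --- locus expected counts ---------------------------------------------
    gene_pos = {gid: k for k, gid in enumerate(gene_ids)}
    indep = rng.normal(ERV_LOG2_BASE, ERV_LOG2_SD, size=n_loci)
    erv_log2 = np.zeros((n_loci, len(tissues)))
    for i, loc in enumerate(catalog):
        ctx = truth.context[loc.locus_id]
        coupling = config.coupling_by_context.get(ctx, 0.0)
        host = truth.host_gene.get(loc.locus_id)
        if host is not None and coupling > 0:
            erv_log2[i] = coupling * gene_log2[gene_pos[host]] + indep[i]
        else:
            erv_log2[i] = indep[i]
    erv_mu = np.exp2(erv_log2)
    for i, lid in enumerate(locus_ids):
        active_in = set(truth.activity[lid])
        for ti, t in enumerate(tissues):
            if t not in active_in:
                erv_mu[i, ti] = 0.0
        if lid in truth.planted_lfc:
            t, lfc = truth.planted_lfc[lid]
            erv_mu[i, tissues.index(t)] *= 2.0**lfc
    gene_mu = np.exp2(gene_log2)

    # --- sampling, normalised to library size -------------------------------
    samples = config.samples
    sample_ids = [s for s, _, _ in samples]
    gene_counts = np.zeros((n_genes, len(samples)), dtype=int)
    erv_counts = np.zeros((n_loci, len(samples)), dtype=int)
    for sj, (_, tissue, _) in enumerate(samples):
        ti = tissues.index(tissue)
        mu = np.concatenate([gene_mu[:, ti], erv_mu[:, ti]])
        total = mu.sum()
        depth = rng.uniform(0.95, 1.05)
        scale = (config.library_size * depth / total) if total > 0 else 0.0
        mu = mu * scale
        draws = np.zeros_like(mu)
        pos = mu > 0
        if config.nb_dispersion > 0:
            r = 1.0 / config.nb_dispersion
            p = r / (r + mu[pos])
            draws[pos] = rng.negative_binomial(r, p)
        else:
            draws[pos] = rng.poisson(mu[pos])
        gene_counts[:, sj] = draws[:n_genes]
        erv_counts[:, sj] = draws[n_genes:]

    sheet = pd.DataFrame(
        {"tissue": [t for _, t, _ in samples], "replicate": [r for _, _, r in samples]},
        index=pd.Index(sample_ids, name="sample"),
    )
    gene_lengths = pd.Series(
        {g.gene_id: sum(e - s for s, e in g.exons) for g in genes}, name="length"
    )
    erv_lengths = pd.Series({loc.locus_id: loc.length for loc in catalog}, name="length")
    gene_em = ExpressionMatrix(
        pd.DataFrame(gene_counts, index=gene_ids, columns=sample_ids),
        gene_lengths,
        sheet,
        "counts",
    )
    erv_em = ExpressionMatrix(
        pd.DataFrame(erv_counts, index=locus_ids, columns=sample_ids),
        erv_lengths,
        sheet,
        "counts",
    )
    return gene_em, erv_em


def analytic_population_r(
    config: SyntheticConfig,
    context: str,
    gene_log2len_var: float = 0.0,
    locus_log2len_var: float = 0.0,
) -> float:
    """Population Pearson R implied by the coupling model.

    On log2(TPM) scale, x = log2 mu_g - log2 len_g + const and
    y = c * log2 mu_g + indep - log2 len_l + const, hence

        R = c * V / sqrt((V + Vgl) * (c^2 V + sigma_e^2 + Vll))

    with V the across-gene variance of log2 mu_g (gene spread plus tissue
    effect), sigma_e the independent ERV term's sd and Vgl/Vll the log2
    length variances supplied from the realised design.  NB measurement
    noise is ignored (negligible at the default means and replicate
    counts).
    """
    c = config.coupling_by_context.get(context, 0.0)
    v = GENE_LOG2_SD**2 + GENE_TISSUE_SD**2
    num = c * v
    den = math.sqrt((v + gene_log2len_var) * (c**2 * v + ERV_LOG2_SD**2 + locus_log2len_var))
    return num / den if den > 0 else 0.0


# ---------------------------------------------------------------------------
# env sequences


def _reverse_translate(pep: str, rng: np.random.Generator) -> str:
    return "".join(
        _AA_TO_CODONS[aa][int(rng.integers(len(_AA_TO_CODONS[aa])))] for aa in pep
    )


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    bases = "ACGT"
    chars = list(seq)
    hits = np.nonzero(rng.random(len(chars)) < rate)[0]
    for i in hits:
        alternatives = bases.replace(chars[i], "")
        chars[i] = alternatives[int(rng.integers(3))]
    return "".join(chars)


def _random_nt(n: int, rng: np.random.Generator) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def generate_env_panel(config: SyntheticConfig) -> list:
    """Synthetic env query panel: one representative protein per genus.

    Stand-in for a curated panel of representative retroviral env
    proteins; sequences are random over the 20-aa alphabet with an SU
    span at aa 60-240.
    """
    from .env_screen import EnvQuery

    rng = _rng(config, 5)
    queries = []
    for gi, genus in enumerate(GENERA):
        seq = "".join(AA20[i] for i in rng.integers(0, 20, size=300))
        queries.append(EnvQuery(f"env_q{gi+1}_{genus}", genus, seq, (60, 240)))
    return queries


def generate_env_sequences(
    config: SyntheticConfig,
    truth: GroundTruth,
    catalog: list[ErvLocus],
    queries: list | None = None,
) -> tuple[dict, list]:
    """Locus nucleotide sequences, a subset carrying planted env ORFs.

    Returns (sequences, queries): sequences maps locus_id -> nucleotide
    string; the env-carrying subset (recorded in ``truth.env``) embeds a
    reverse-translated window of a known query, mutated at
    env_mutation_rate, at a random frame and strand.
    """
    if config.env_mutation_rate > 0.35:
        logger.warning(
            "env_mutation_rate %.2f may push identity below alignment "
            "thresholds; loci emitted anyway",
            config.env_mutation_rate,
        )
    rng = _rng(config, 6)
    if queries is None:
        queries = generate_env_panel(config)
    eligible = [loc for loc in catalog if loc.length >= 450]
    n_env = min(config.n_env_loci, len(eligible))
    chosen_idx = rng.choice(len(eligible), size=n_env, replace=False) if n_env else []
    chosen = {eligible[int(i)].locus_id for i in chosen_idx}
    sequences = {}
    for loc in catalog:
        seq = _random_nt(loc.length, rng)
        if loc.locus_id in chosen:
            q = queries[int(rng.integers(len(queries)))]
            max_aa = (loc.length - 3) // 3
            orf_aa = int(min(len(q.sequence), max_aa))
            w = int(rng.integers(0, len(q.sequence) - orf_aa + 1))
            pep = q.sequence[w : w + orf_aa]
            orf_nt = _mutate(
                _reverse_translate(pep, rng), config.env_mutation_rate, rng
            )
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                orf_nt = str(Seq(orf_nt).reverse_complement())
            offset = int(rng.integers(0, loc.length - len(orf_nt) + 1))
            seq = seq[:offset] + orf_nt + seq[offset + len(orf_nt) :]
            su = q.su_span
            su_overlap = max(0, min(w + orf_aa, su[1]) - max(w, su[0])) if su else None
            truth.env[loc.locus_id] = {
                "genus": q.genus,
                "query_id": q.query_id,
                "query_span": [w, w + orf_aa],
                "strand": strand,
                "offset": offset,
                "su_overlap": su_overlap,
            }
        sequences[loc.locus_id] = seq
    return sequences, queries


def write_fasta(sequences: dict, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_env_panel(queries: list, path: str | Path) -> None:
    with open(path, "w") as fh:
        for q in queries:
            tag = f" genus={q.genus}"
            if q.su_span:
                tag += f" su_span={q.su_span[0]}-{q.su_span[1]}"
            fh.write(f">{q.query_id}{tag}\n")
            for i in range(0, len(q.sequence), 60):
                fh.write(q.sequence[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# SAM emitter (tests the counting path only)


def sam_from_counts(
    counts,
    features,
    chrom_lengths: dict,
    seed: int = 0,
    read_len: int = 100,
) -> str:
    """SAM text with `counts[f]` single-end reads placed uniformly in each feature.

    Reads lie entirely within their source feature (the read length is
    clamped to the feature length), so with disjoint features union-mode
    counting recovers the counts exactly.
    """
    rng = np.random.default_rng([seed, 7])
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for chrom in sorted(chrom_lengths):
        lines.append(f"@SQ\tSN:{chrom}\tLN:{chrom_lengths[chrom]}")
    for f in features:
        n = int(counts[f.locus_id])
        flen = f.end - f.start
        rl = min(read_len, flen)
        for i in range(n):
            pos = f.start + int(rng.integers(0, flen - rl + 1))
            lines.append(
                f"{f.locus_id}.r{i}\t0\t{f.chrom}\t{pos + 1}\t60\t{rl}M\t*\t0\t0\t"
                f"{'A' * rl}\t{'I' * rl}"
            )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# One-call orchestration


@dataclass
class SimulationResult:
    config: SyntheticConfig
    annotation: Annotation
    catalog: list
    truth: GroundTruth
    gene_counts: object
    erv_counts: object
    sequences: dict
    queries: list


def simulate(config: SyntheticConfig) -> SimulationResult:
    """Run every generator stage in order; returns all in-memory objects."""
    annotation = generate_annotation(config)
    catalog, truth = generate_erv_catalog(config, annotation)
    gene_em, erv_em = simulate_counts(config, truth, annotation, catalog)
    sequences, queries = generate_env_sequences(config, truth, catalog)
    truth.validate(catalog)
    return SimulationResult(
        config, annotation, catalog, truth, gene_em, erv_em, sequences, queries
    )


def simulate_to_dir(config: SyntheticConfig, outdir: str | Path) -> SimulationResult:
    """Run the generator and write every pipeline input to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result = simulate(config)
    result.annotation.to_gtf(outdir / "annotation.gtf")
    write_repeatmasker(
        result.catalog, outdir / "repeats.out", result.annotation.chrom_lengths, config
    )
    result.gene_counts.write(outdir / "genes")
    result.erv_counts.write(outdir / "ervs")
    write_fasta(result.sequences, outdir / "loci.fasta")
    write_env_panel(result.queries, outdir / "env_panel.fasta")
    result.truth.to_json(outdir / "truth.json")
    with open(outdir / "config.json", "w") as fh:
        json.dump(asdict(config), fh, indent=1, sort_keys=True)
        fh.write("\n")
    return result
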