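"""End-to-end orchestration: catalog -> context -> quantify -> activity ->
differential expression -> correlation -> env screen, with a machine-readable
run report and checksum-based stage caching."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import activity as activity_mod
from . import catalog as catalog_mod
from . import context as context_mod
from . import correlation as correlation_mod
from . import diffexpr
from . import env_screen
from . import quantify
from . import __version__

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and parameters of one pipeline run.

    Input paths point at a RepeatMasker ``.out``, a GTF, count-matrix
    prefixes (as written by :class:`~erv_activity.quantify.ExpressionMatrix`),
    a locus FASTA and an env query panel; ``outdir`` receives all stage
    outputs plus ``report.json``.
    """

    rm_out: str
    gtf: str
    gene_counts_prefix: str
    erv_counts_prefix: str
    loci_fasta: str
    env_panel: str
    outdir: str
    min_count: int = 1
    min_replicates: int = 1
    fdr: float = 0.05
    min_fold: float = 2.0
    env_min_score: float = env_screen.DEFAULT_MIN_SCORE
    env_min_aln_len: int = env_screen.DEFAULT_MIN_ALN_LEN
    locus_set: str = "core"  # "core" | "all" for tissue-specificity calls
    overlapped_definition: str = "multi_gene"
    seed: int = 0

    def validate(self) -> None:
        for name in ("rm_out", "gtf", "loci_fasta", "env_panel"):
            if not Path(getattr(self, name)).exists():
                raise FileNotFoundError(f"{name}: {getattr(self, name)} does not exist")
        for prefix in (self.gene_counts_prefix, self.erv_counts_prefix):
            if not Path(f"{prefix}.counts.tsv").exists():
                raise FileNotFoundError(f"count matrix {prefix}.counts.tsv missing")
        if self.locus_set not in ("core", "all"):
            raise ValueError("locus_set must be 'core' or 'all'")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunReport:
    version: str = __version__
    config: dict = field(default_factory=dict)
    stages: dict = field(default_factory=dict)  # name -> {inputs, outputs, counts}

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


class _Runner:
    def __init__(self, config: RunConfig, resume: bool) -> None:
        self.config = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.report = RunReport(config=asdict(config))
        self.previous: dict = {}
        report_path = self.outdir / "report.json"
        if resume and report_path.exists():
            with open(report_path) as fh:
                self.previous = json.load(fh).get("stages", {})

    def cached(self, name: str, inputs: list[str], outputs: list[str]) -> bool:
        prev = self.previous.get(name)
        if not prev:
            return False
        if any(not Path(o).exists() for o in outputs):
            return False
        current = {str(p): _sha256(p) for p in inputs}
        if prev.get("inputs") != current:
            logger.info("stage %s: stale cache (input checksum mismatch), recomputing", name)
            return False
        return True

    def record(self, name: str, inputs: list[str], outputs: list[str], counts: dict) -> None:
        self.report.stages[name] = {
            "inputs": {str(p): _sha256(p) for p in inputs},
            "outputs": {str(p): _sha256(p) for p in outputs},
            "counts": counts,
        }


def run_pipeline(config: RunConfig, resume: bool = True) -> RunReport:
    """Run all stages in dependency order; any stage failure aborts with its name.

    With ``resume=True`` a stage whose outputs exist and whose input
    checksums match the previous report is skipped (counts are carried
    over); a checksum mismatch triggers recomputation.
    """
    config.validate()
    runner = _Runner(config, resume)
    out = runner.outdir

    def stage(name, inputs, outputs, fn):
        inputs = [str(i) for i in inputs]
        outputs = [str(o) for o in outputs]
        if runner.cached(name, inputs, outputs):
            logger.info("stage %s: cached, skipping", name)
            runner.report.stages[name] = runner.previous[name]
            return None
        try:
            counts = fn()
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        runner.record(name, inputs, outputs, counts)
        return counts

    # --- catalog ------------------------------------------------------------
    catalog_bed = out / "catalog.bed"

    def do_catalog():
        stats: dict = {}
        loci = catalog_mod.parse_repeatmasker(config.rm_out, stats)
        catalog_mod.write_bed(loci, catalog_bed)
        return {"loci": len(loci), "skipped_rows": stats["skipped"]}

    stage("catalog", [config.rm_out], [catalog_bed], do_catalog)
    catalog = catalog_mod.read_bed(catalog_bed)

    # --- context ------------------------------------------------------------
    context_tsv = out / "context.tsv"

    def do_context():
        model = context_mod.build_gene_model(config.gtf)
        assignments = context_mod.classify_catalog(catalog, model)
        context_mod.write_assignments(assignments, context_tsv)
        by_label: dict = {}
        for a in assignments.values():
            by_label[a.context_label] = by_label.get(a.context_label, 0) + 1
        assert sum(by_label.values()) == len(catalog)
        return {"assigned": len(assignments), "by_context": by_label}

    stage("context", [config.rm_out, config.gtf, catalog_bed], [context_tsv], do_context)
    assignments = context_mod.read_assignments(context_tsv)

    # --- quantify (TPM + PCA) ----------------------------------------------
    gene_counts = quantify.ExpressionMatrix.read(config.gene_counts_prefix)
    erv_counts = quantify.ExpressionMatrix.read(config.erv_counts_prefix)
    gene_tpm = quantify.compute_tpm(gene_counts)
    erv_tpm = quantify.compute_tpm(erv_counts)
    pca_tsv = out / "pca.tsv"

    def do_quantify():
        gene_tpm.values.to_csv(out / "genes.tpm.tsv", sep="\t", index_label="feature")
        erv_tpm.values.to_csv(out / "ervs.tpm.tsv", sep="\t", index_label="feature")
        coords, varfrac = quantify.pca_report(erv_tpm)
        coords.to_csv(pca_tsv, sep="\t", index_label="sample")
        return {
            "samples": len(gene_tpm.samples),
            "pc_variance_fractions": [round(float(v), 4) for v in varfrac],
        }

    quant_inputs = [
        f"{config.gene_counts_prefix}.counts.tsv",
        f"{config.erv_counts_prefix}.counts.tsv",
    ]
    stage("quantify", quant_inputs, [out / "genes.tpm.tsv", out / "ervs.tpm.tsv", pca_tsv], do_quantify)

    # --- activity -----------------------------------------------------------
    activity_tsv = out / "activity.tsv"
    venn_json = out / "venn.json"
    table = activity_mod.call_active(
        erv_counts.values, erv_counts.sample_sheet, config.min_count, config.min_replicates
    )

    def do_activity():
        venn = activity_mod.venn_summary(table)
        table.write(activity_tsv)
        activity_mod.write_venn(venn, venn_json)
        assert len(table.labels) == len(catalog)
        return {
            "active_union": venn["union"],
            "core": venn["core"],
            "per_tissue": venn["per_tissue"],
            "exclusive": venn["exclusive"],
        }

    stage("activity", quant_inputs[1:], [activity_tsv, venn_json], do_activity)

    # --- differential expression -------------------------------------------
    tissues = sorted(erv_counts.sample_sheet["tissue"].unique())
    if config.locus_set == "core":
        de_ids = table.labels.index[table.labels == "core"]
    else:
        de_ids = table.labels.index[table.labels != "inactive"]
    ts_tsv = out / "ts_labels.tsv"
    de_outputs = [out / f"de_{a}_vs_{b}.tsv" for a in tissues for b in tissues if a < b]

    def do_de():
        sub = erv_counts.values.loc[de_ids]
        if len(de_ids) == 0 or len(tissues) < 2:
            pd.Series(dtype=object).to_csv(ts_tsv, sep="\t", header=["label"])
            return {"tested": 0}
        results = diffexpr.run_pairwise(
            sub, erv_counts.sample_sheet, tissues, fdr=config.fdr, min_fold=config.min_fold
        )
        for (a, b), df in results.items():
            df.to_csv(out / f"de_{a}_vs_{b}.tsv", sep="\t", index_label="locus_id")
        labels = diffexpr.call_tissue_specific_up(results, tissues)
        labels.rename("label").to_csv(ts_tsv, sep="\t", index_label="locus_id")
        up_counts = {
            t: int((labels == f"up-in:{t}").sum()) for t in tissues
        }
        return {
            "tested": len(de_ids),
            "upregulated_per_tissue": up_counts,
            "up_in_two": int((labels == "up-in-two").sum()),
        }

    stage("diffexpr", quant_inputs[1:] + [activity_tsv], de_outputs + [ts_tsv], do_de)

    # --- correlation --------------------------------------------------------
    corr_tsv = out / "correlation.tsv"

    def do_correlate():
        frames = []
        for t in tissues:
            pairs = correlation_mod.pair_loci_genes(assignments, table, t)
            res = correlation_mod.correlate(
                erv_tpm.values, gene_tpm.values, pairs, erv_tpm.samples_of(t), t
            )
            frames.append(correlation_mod.correlation_table(res))
        df = pd.concat(frames, ignore_index=True)
        df.to_csv(corr_tsv, sep="\t", index=False)
        return {"rows": len(df)}

    stage("correlate", quant_inputs + [context_tsv, activity_tsv], [corr_tsv], do_correlate)

    # --- env screen ---------------------------------------------------------
    env_tsv = out / "env_hits.tsv"
    env_json = out / "env_summary.json"

    def do_env():
        sequences = env_screen.read_fasta(config.loci_fasta)
        queries = env_screen.read_env_panel(config.env_panel)
        found = env_screen.screen_catalog(
            sequences, queries, config.env_min_score, config.env_min_aln_len
        )
        rows = []
        for lid, (genus, hit) in sorted(found.items()):
            rows.append(
                {
                    "locus_id": lid,
                    "query_id": hit.query_id,
                    "genus": genus,
                    "score": hit.score,
                    "aln_len": hit.aln_len,
                    "identity": round(hit.identity, 4),
                    "frame": hit.frame,
                    "strand": hit.strand,
                    "su_coverage": hit.su_coverage,
                    "su_flag": hit.su_flag,
                }
            )
        pd.DataFrame(
            rows,
            columns=[
                "locus_id", "query_id", "genus", "score", "aln_len",
                "identity", "frame", "strand", "su_coverage", "su_flag",
            ],
        ).to_csv(env_tsv, sep="\t", index=False)
        ts_labels = None
        env_ids = [lid for lid in found if lid in erv_counts.values.index]
        if len(env_ids) >= 1 and len(tissues) >= 2:
            try:
                env_results = diffexpr.run_pairwise(
                    erv_counts.values.loc[env_ids],
                    erv_counts.sample_sheet,
                    tissues,
                    fdr=config.fdr,
                    min_fold=config.min_fold,
                )
                ts_labels = diffexpr.call_tissue_specific_up(env_results, tissues)
            except ValueError:
                ts_labels = None
        summary = env_screen.env_expression_summary(
            {lid: found[lid] for lid in env_ids}, erv_counts.values, table, ts_labels
        )
        with open(env_json, "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return {"env_loci": len(found), "active_env": summary["n_active"]}

    stage(
        "env",
        [config.loci_fasta, config.env_panel, activity_tsv],
        [env_tsv, env_json],
        do_env,
    )

    runner.report.write(out / "report.json")
    return runner.report
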