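"""End-to-end orchestration: counts -> RPKM -> combi -> score -> filter.

The pipeline consumes either precomputed per-sample count tables or SAM/BAM
pairs (genome pass + junction pass) per condition, and writes every
intermediate table plus a run manifest (package version, configuration
echo, input checksums, effective thresholds) so a run is reproducible and
auditable. Given fixed inputs the pipeline is deterministic.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .annotation import _file_sha256, assign_window_lengths, parse_gtf
from .core import (
    ArhParams,
    WeibullBackground,
    attach_pvalues,
    exon_results_to_frame,
    fit_weibull_background,
    results_to_frame,
    score_genes,
)
from .counting import (
    count_exon_reads,
    count_junction_reads,
    merge_counts,
    read_count_table,
    write_count_table,
)
from .postprocess import FilterConfig, select_candidates
from .quantify import combi_counts, gene_rpkm, rpkm

__all__ = ["PipelineError", "RunConfig", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Everything one two-condition run needs.

    Exactly one input mode per condition: a count TSV (``case_counts``/
    ``control_counts``) or a genome-pass + junction-pass alignment pair.
    """

    annotation: str
    out_dir: str
    case_counts: str | None = None
    control_counts: str | None = None
    case_genome_alignments: str | None = None
    case_junction_alignments: str | None = None
    control_genome_alignments: str | None = None
    control_junction_alignments: str | None = None
    background: str | None = None  # pre-fitted background file
    arh: ArhParams = field(default_factory=ArhParams)
    filters: FilterConfig = field(default_factory=FilterConfig)
    aligner: str = "synthetic"
    read_length: int = 75
    multimap_policy: str = "count_all"
    min_background_scores: int = 100
    seed: int = 0

    def input_paths(self) -> dict[str, str]:
        fields = (
            "annotation",
            "case_counts",
            "control_counts",
            "case_genome_alignments",
            "case_junction_alignments",
            "control_genome_alignments",
            "control_junction_alignments",
            "background",
        )
        return {f: getattr(self, f) for f in fields if getattr(self, f) is not None}

    def validate(self) -> None:
        for name, path in self.input_paths().items():
            if not Path(path).exists():
                raise PipelineError(f"config: input {name} does not exist: {path}")
        for cond in ("case", "control"):
            has_counts = getattr(self, f"{cond}_counts") is not None
            has_bams = getattr(self, f"{cond}_genome_alignments") is not None
            if has_counts == has_bams:
                raise PipelineError(
                    f"config: condition {cond!r} needs exactly one of a count "
                    "table or a genome+junction alignment pair"
                )
            if has_bams and getattr(self, f"{cond}_junction_alignments") is None:
                raise PipelineError(
                    f"config: condition {cond!r}: junction alignments missing"
                )


def _stage(name: str):
    class _ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            return False

    return _ctx()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow; returns paths and key in-memory results."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    with _stage("annotation"):
        index = parse_gtf(config.annotation)
        assign_window_lengths(index, config.read_length, config.aligner)

    counts = {}
    with _stage("counting"):
        for cond in ("case", "control"):
            table = getattr(config, f"{cond}_counts")
            if table is not None:
                counts[cond] = read_count_table(table, sample_id=cond)
            else:
                exon_fc = count_exon_reads(
                    getattr(config, f"{cond}_genome_alignments"),
                    index,
                    multimap_policy=config.multimap_policy,
                    sample_id=cond,
                )
                junc_fc = count_junction_reads(
                    getattr(config, f"{cond}_junction_alignments"),
                    index,
                    sample_id=cond,
                )
                counts[cond] = merge_counts(exon_fc, junc_fc, sample_id=cond)
                write_count_table(counts[cond], out / f"counts_{cond}.tsv")

    with _stage("quantification"):
        expr = {c: rpkm(fc) for c, fc in counts.items()}
        combi = {c: combi_counts(expr[c], index) for c in expr}
        gexpr = {c: gene_rpkm(counts[c], index) for c in counts}

    with _stage("scoring"):
        results = score_genes(combi["case"], combi["control"], config.arh)
        scores = np.array(
            [r.arh for r in results if r.status == "ok" and np.isfinite(r.arh)]
        )
        if config.background is not None:
            background = WeibullBackground.from_file(config.background)
        else:
            background = fit_weibull_background(
                scores, min_scores=config.min_background_scores
            )
        attach_pvalues(results, background)
        gene_df = results_to_frame(results)
        exon_df = exon_results_to_frame(results, combi["case"], combi["control"])

    with _stage("filtering"):
        exon_counts = {c: counts[c].by_type("exon") for c in counts}
        exon_expr = {c: expr[c].by_type("exon") for c in counts}
        candidates = select_candidates(
            gene_results=gene_df[gene_df["status"] == "ok"],
            exon_results=exon_df[
                exon_df["gene_id"].isin(gene_df.loc[gene_df.status == "ok", "gene_id"])
            ],
            counts_case=exon_counts["case"],
            counts_control=exon_counts["control"],
            expr_case=exon_expr["case"],
            expr_control=exon_expr["control"],
            gene_expr_case=gexpr["case"],
            gene_expr_control=gexpr["control"],
            library_case=counts["case"].total,
            library_control=counts["control"].total,
            config=config.filters,
        )

    with _stage("output"):
        paths = {
            "genes": out / "genes.tsv",
            "exons": out / "exons.tsv",
            "candidates": out / "candidates.tsv",
            "background": out / "background.txt",
            "manifest": out / "manifest.json",
        }
        gene_df.to_csv(paths["genes"], sep="\t", index=False, float_format="%.10g")
        exon_df.to_csv(paths["exons"], sep="\t", index=False, float_format="%.10g")
        candidates.to_csv(
            paths["candidates"], sep="\t", index=False, float_format="%.10g"
        )
        background.to_file(paths["background"])
        manifest = {
            "arhseq_version": __version__,
            "config": {
                k: (dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v)
                for k, v in dataclasses.asdict(config).items()
            },
            "inputs_sha256": {
                name: _file_sha256(path)
                for name, path in config.input_paths().items()
            },
            "effective_thresholds": {
                "min_rpkm": config.filters.min_rpkm,
                "max_pvalue": config.filters.max_pvalue,
                "min_reads": config.filters.min_reads,
                "count_test_alpha": config.filters.count_test_alpha,
                "deviation_threshold": candidates.attrs.get("deviation_threshold"),
                "alpha_pseudocount": config.arh.alpha,
            },
            "background": {
                "scale": background.scale,
                "shape": background.shape,
                "n_fit": background.n_fit,
                "source": config.background or "fitted_from_run",
            },
            "n_genes_scored": int((gene_df["status"] == "ok").sum()),
            "n_candidates": int(len(candidates)),
        }
        with open(paths["manifest"], "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")

    return {
        "paths": {k: str(v) for k, v in paths.items()},
        "gene_results": gene_df,
        "exon_results": exon_df,
        "candidates": candidates,
        "background": background,
        "manifest": manifest,
    }
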