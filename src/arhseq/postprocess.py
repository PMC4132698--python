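"""Candidate selection filters applied after scoring.

Selection proceeds in two stages. Gene stage: the gene must be expressed
(RPKM >= 0.75 in at least one condition) and carry a splicing P-value
below 0.2. Exon stage, within passing genes: the exon must be expressed in
at least one condition, covered by at least 10 raw reads in at least one
condition, show a significant read-count difference under a Poisson-based
conditional test, and its absolute splicing deviation must exceed a
quantile threshold of the pooled |deviation| distribution (95% by default;
recomputed from the run at hand, with an option to force a fixed value).

All thresholds are inclusive/exclusive exactly as stated: RPKM >= 0.75
keeps the boundary, P < 0.2 and |s| > threshold drop theirs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "FilterError",
    "FilterConfig",
    "expression_filter",
    "coverage_filter",
    "poisson_count_test",
    "deviation_quantile_threshold",
    "select_candidates",
    "PASS_EXPRESSED",
    "PASS_COVERED",
    "PASS_COUNT_TEST",
    "PASS_DEVIATION",
    "PASS_ALL",
]


class FilterError(ValueError):
    """Invalid filter configuration or inconsistent inputs."""


@dataclass
class FilterConfig:
    """Thresholds of the candidate-selection stage."""

    min_rpkm: float = 0.75
    max_pvalue: float = 0.2
    min_reads: int = 10
    deviation_quantile: float = 0.95
    count_test_alpha: float = 0.01
    fixed_deviation_threshold: float | None = None  # e.g. 2.03 to pin the gate

    def __post_init__(self) -> None:
        if min(self.min_rpkm, self.max_pvalue, self.min_reads, self.count_test_alpha) <= 0:
            raise FilterError("all thresholds must be positive")
        if not 0 < self.deviation_quantile < 1:
            raise FilterError("deviation_quantile must lie in (0, 1)")


def expression_filter(case, control, min_rpkm: float = 0.75):
    """Keep a feature iff its RPKM reaches min_rpkm in at least one condition."""
    case = np.asarray(case, dtype=float)
    control = np.asarray(control, dtype=float)
    keep = np.maximum(case, control) >= min_rpkm
    return bool(keep) if keep.ndim == 0 else keep


def coverage_filter(count_case, count_control, min_reads: int = 10):
    """Keep an exon iff it has min_reads raw reads in at least one condition."""
    case = np.asarray(count_case)
    control = np.asarray(count_control)
    keep = np.maximum(case, control) >= min_reads
    return bool(keep) if keep.ndim == 0 else keep


def poisson_count_test(
    k_case: int,
    k_control: int,
    n_case: int,
    n_control: int,
    alternative: str = "doubled",
) -> float:
    """Two-sample Poisson rate test, conditional binomial form.

    Given K = k_case + k_control total reads, under the null of equal rates
    k_case ~ Binomial(K, n_case / (n_case + n_control)). Two-sided P by
    doubling the smaller tail (capped at 1); ``alternative="minlike"``
    sums all outcomes no more likely than the observed one instead.
    """
    if min(k_case, k_control) < 0:
        raise FilterError("counts must be non-negative")
    if min(n_case, n_control) <= 0:
        raise FilterError("library sizes must be positive")
    total = k_case + k_control
    if total == 0:
        return 1.0
    p0 = n_case / (n_case + n_control)
    if alternative == "doubled":
        lower = sps.binom.cdf(k_case, total, p0)
        upper = sps.binom.sf(k_case - 1, total, p0)
        return float(min(1.0, 2.0 * min(lower, upper)))
    if alternative == "minlike":
        return float(sps.binomtest(k_case, total, p0).pvalue)
    raise FilterError(f"unknown alternative {alternative!r}")


def deviation_quantile_threshold(abs_deviations, q: float = 0.95) -> float:
    """Empirical quantile (linear interpolation) of pooled |deviations|."""
    x = np.asarray(abs_deviations, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 20:
        raise FilterError(
            f"need >= 20 deviation values for a stable quantile, got {x.size}"
        )
    if not 0 < q < 1:
        raise FilterError("quantile must lie in (0, 1)")
    return float(np.quantile(x, q))


PASS_EXPRESSED = 1
PASS_COVERED = 2
PASS_COUNT_TEST = 4
PASS_DEVIATION = 8
PASS_ALL = PASS_EXPRESSED | PASS_COVERED | PASS_COUNT_TEST | PASS_DEVIATION


def select_candidates(
    gene_results: pd.DataFrame,
    exon_results: pd.DataFrame,
    counts_case: dict[str, int],
    counts_control: dict[str, int],
    expr_case: dict[str, float],
    expr_control: dict[str, float],
    gene_expr_case: dict[str, float],
    gene_expr_control: dict[str, float],
    library_case: int,
    library_control: int,
    config: FilterConfig | None = None,
) -> pd.DataFrame:
    """Compose all filters into the final candidate exon table.

    ``gene_results`` / ``exon_results`` are the frames produced by the
    scoring step; counts are raw exon read counts and ``expr_*`` exon RPKM
    values per condition. Output is sorted by gene P-value then descending
    |deviation|; only exons passing every filter are returned, with a
    ``passed_filters`` bitmask column (all bits set).
    """
    config = config or FilterConfig()
    required = {"gene_id", "pvalue"}
    if not required <= set(gene_results.columns):
        raise FilterError(f"gene results need columns {sorted(required)}")
    required = {"exon_id", "gene_id", "deviation"}
    if not required <= set(exon_results.columns):
        raise FilterError(f"exon results need columns {sorted(required)}")
    unknown_genes = set(exon_results["gene_id"]) - set(gene_results["gene_id"])
    if unknown_genes:
        raise FilterError(
            f"exon results reference unknown genes: {sorted(unknown_genes)[:5]}"
        )

    if config.fixed_deviation_threshold is not None:
        dev_threshold = config.fixed_deviation_threshold
    else:
        dev_threshold = deviation_quantile_threshold(
            exon_results["deviation"].abs(), config.deviation_quantile
        )

    gene_pass = {}
    for row in gene_results.itertuples(index=False):
        expressed = expression_filter(
            gene_expr_case.get(row.gene_id, 0.0),
            gene_expr_control.get(row.gene_id, 0.0),
            config.min_rpkm,
        )
        gene_pass[row.gene_id] = (
            np.isfinite(row.pvalue) and row.pvalue < config.max_pvalue and expressed
        )

    pvalues = dict(zip(gene_results["gene_id"], gene_results["pvalue"]))
    rows = []
    exon_sorted = exon_results.sort_values("exon_id", kind="mergesort")
    for row in exon_sorted.itertuples(index=False):
        if not gene_pass.get(row.gene_id, False):
            continue
        eid = row.exon_id
        kc = int(counts_case.get(eid, 0))
        kk = int(counts_control.get(eid, 0))
        rc = float(expr_case.get(eid, 0.0))
        rk = float(expr_control.get(eid, 0.0))
        mask = 0
        if expression_filter(rc, rk, config.min_rpkm):
            mask |= PASS_EXPRESSED
        if coverage_filter(kc, kk, config.min_reads):
            mask |= PASS_COVERED
        count_p = poisson_count_test(kc, kk, library_case, library_control)
        if count_p < config.count_test_alpha:
            mask |= PASS_COUNT_TEST
        if abs(row.deviation) > dev_threshold:
            mask |= PASS_DEVIATION
        if mask == PASS_ALL:
            rows.append(
                {
                    "gene_id": row.gene_id,
                    "pvalue": pvalues[row.gene_id],
                    "exon_id": eid,
                    "deviation": row.deviation,
                    "count_case": kc,
                    "count_control": kk,
                    "count_test_p": count_p,
                    "rpkm_case": rc,
                    "rpkm_control": rk,
                    "passed_filters": mask,
                }
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "pvalue",
            "exon_id",
            "deviation",
            "count_case",
            "count_control",
            "count_test_p",
            "rpkm_case",
            "rpkm_control",
            "passed_filters",
        ],
    )
    if len(out):
        out["abs_dev"] = out["deviation"].abs()
        out = (
            out.sort_values(
                ["pvalue", "abs_dev", "exon_id"],
                ascending=[True, False, True],
                kind="mergesort",
            )
            .drop(columns="abs_dev")
            .reset_index(drop=True)
        )
    out.attrs["deviation_threshold"] = dev_threshold
    return out
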