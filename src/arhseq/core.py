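"""Entropy-based differential-splicing score and its Weibull null model.

For one gene with exon combi-count vectors ``c^case`` and ``c^control``
(n >= 2 exons) the score is built in four steps:

1. Per-exon log fold change with pseudocount alpha:
   ``logFC_i = log2((c_i^case + alpha) / (c_i^control + alpha))``.
2. Splicing deviation: ``s_i = logFC_i - b`` with baseline ``b`` the median
   exon logFC (robust to the spliced exon itself). Uniform expression fold
   changes cancel here, which makes the score independent of differential
   gene expression.
3. Probability transform: ``p_i = 2^|s_i| / sum_j 2^|s_j|``. Deviations
   concentrated on few exons give a peaked distribution; no deviation gives
   the uniform distribution.
4. Score: ``ARH = (1 - H/log2 n) * (1 - 2^(-max_i |s_i|))`` where
   ``H = -sum p_i log2 p_i`` is the Shannon entropy in bits. The first
   factor is the normalized entropy deficit relative to uniform (this is
   the exon-number normalization); the second damps genes whose deviations
   are uniformly small. ARH lies in [0, 1) and is 0 exactly when all
   |s_i| are equal.

Scores pooled over many case-control comparisons follow a Weibull null
closely; its maximum-likelihood fit converts scores to upper-tail P-values
``p = exp(-(score/lambda)^k)``. These P-values are conservative when the
background was fitted on strongly-splicing comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .quantify import CombiTable

__all__ = [
    "ScoringError",
    "DegenerateFitError",
    "ArhParams",
    "DeviationVector",
    "GeneSpliceResult",
    "WeibullBackground",
    "splicing_deviation",
    "deviation_probabilities",
    "entropy",
    "arh_score",
    "score_gene",
    "score_genes",
    "results_to_frame",
    "exon_results_to_frame",
    "fit_weibull_background",
    "arh_pvalue",
    "attach_pvalues",
]

LOG_BASE = 2  # fixed; deviations, entropy and quantile gates are in bits


class ScoringError(ValueError):
    """Invalid input to the splicing score."""


class DegenerateFitError(ScoringError):
    """Background fit attempted on degenerate (e.g. constant) scores."""


@dataclass
class ArhParams:
    """Tunable scoring parameters.

    alpha: pseudocount in RPKM units added to both conditions before the
        log ratio; keeps zero counts finite while staying below the 0.75
        expression-call threshold so expressed signal dominates. alpha = 0
        is permitted for strictly positive combi vectors (it makes the
        score exactly invariant under uniform expression fold changes) but
        produces infinities on zeros.
    baseline: "median_logfc" (default, robust) or "gene_sum"
        (log2 ratio of summed combi-counts).
    """

    alpha: float = 0.5
    baseline: str = "median_logfc"

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ScoringError(f"pseudocount alpha must be >= 0, got {self.alpha}")
        if self.baseline not in ("median_logfc", "gene_sum"):
            raise ScoringError(f"unknown baseline {self.baseline!r}")


@dataclass
class DeviationVector:
    """Per-exon splicing deviations of one gene (log2 scale)."""

    gene_id: str
    exon_ids: list[str]
    logfc: np.ndarray
    baseline: float
    deviations: np.ndarray  # s_i = logfc_i - baseline

    @property
    def n(self) -> int:
        return len(self.exon_ids)

    @property
    def max_abs_deviation(self) -> float:
        return float(np.max(np.abs(self.deviations)))


@dataclass
class GeneSpliceResult:
    """Gene-level score with its per-exon decomposition."""

    gene_id: str
    n: int
    exon_ids: list[str]
    deviations: np.ndarray
    probabilities: np.ndarray
    entropy: float
    arh: float
    max_abs_deviation: float
    status: str = "ok"  # "ok" | "not_scored"
    pvalue: float | None = None


def splicing_deviation(
    case: np.ndarray | list[float],
    control: np.ndarray | list[float],
    params: ArhParams | None = None,
    gene_id: str = "",
    exon_ids: list[str] | None = None,
) -> DeviationVector:
    """Per-exon log2 fold changes re-centred on the gene baseline."""
    params = params or ArhParams()
    case = np.asarray(case, dtype=float)
    control = np.asarray(control, dtype=float)
    if case.shape != control.shape:
        raise ScoringError(
            f"gene {gene_id or '?'}: case/control cover different exon sets"
        )
    n = case.size
    if n < 2:
        raise ScoringError(
            f"gene {gene_id or '?'}: need >=2 exons, got {n} "
            "(single-exon genes are excluded upstream)"
        )
    if np.any(case < 0) or np.any(control < 0):
        raise ScoringError(f"gene {gene_id or '?'}: negative combi-counts")
    a = params.alpha
    logfc = np.log2(case + a) - np.log2(control + a)
    if params.baseline == "median_logfc":
        b = float(np.median(logfc))
    else:
        b = math.log2(case.sum() + a) - math.log2(control.sum() + a)
    return DeviationVector(
        gene_id=gene_id,
        exon_ids=exon_ids or [str(i) for i in range(n)],
        logfc=logfc,
        baseline=b,
        deviations=logfc - b,
    )


def deviation_probabilities(dev: DeviationVector) -> np.ndarray:
    """p_i proportional to 2^|s_i|; uniform when all deviations vanish."""
    w = np.exp2(np.abs(dev.deviations))
    return w / w.sum()


def entropy(p: np.ndarray | list[float]) -> float:
    """Shannon entropy in bits; validates that p sums to 1."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ScoringError("probabilities must be non-negative")
    if abs(p.sum() - 1.0) > 1e-6:
        raise ScoringError(f"probabilities sum to {p.sum():.8f}, not 1")
    return float(sps.entropy(p, base=2))


def arh_score(dev: DeviationVector) -> float:
    """Entropy deficit of the deviation distribution, damped by max |s|."""
    p = deviation_probabilities(dev)
    h = entropy(p)
    n = dev.n
    return (1.0 - h / math.log2(n)) * (1.0 - 2.0 ** (-dev.max_abs_deviation))


def score_gene(
    case: np.ndarray,
    control: np.ndarray,
    params: ArhParams | None = None,
    gene_id: str = "",
    exon_ids: list[str] | None = None,
) -> GeneSpliceResult:
    dev = splicing_deviation(case, control, params, gene_id, exon_ids)
    p = deviation_probabilities(dev)
    h = entropy(p)
    return GeneSpliceResult(
        gene_id=gene_id,
        n=dev.n,
        exon_ids=dev.exon_ids,
        deviations=dev.deviations,
        probabilities=p,
        entropy=h,
        arh=(1.0 - h / math.log2(dev.n)) * (1.0 - 2.0 ** (-dev.max_abs_deviation)),
        max_abs_deviation=dev.max_abs_deviation,
    )


def score_genes(
    case: CombiTable,
    control: CombiTable,
    params: ArhParams | None = None,
) -> list[GeneSpliceResult]:
    """Score every shared scoring gene; deterministic (sorted) gene order.

    Genes whose combi-counts are zero everywhere in both conditions carry no
    information and are emitted with status "not_scored" (score NaN) so they
    can be excluded from ranking and background fitting.
    """
    if set(case.genes) != set(control.genes):
        raise ScoringError(
            "case and control tables cover different gene sets "
            f"(e.g. {sorted(set(case.genes) ^ set(control.genes))[:3]})"
        )
    params = params or ArhParams()
    out: list[GeneSpliceResult] = []
    for gene_id in sorted(case.genes):
        exon_ids = case.genes[gene_id]
        if exon_ids != control.genes[gene_id]:
            raise ScoringError(f"gene {gene_id}: exon sets differ between tables")
        cv = case.gene_vector(gene_id)
        kv = control.gene_vector(gene_id)
        if cv.size < 2:
            continue
        if not (np.any(cv > 0) or np.any(kv > 0)):
            out.append(
                GeneSpliceResult(
                    gene_id=gene_id,
                    n=cv.size,
                    exon_ids=exon_ids,
                    deviations=np.zeros(cv.size),
                    probabilities=np.full(cv.size, 1.0 / cv.size),
                    entropy=math.log2(cv.size),
                    arh=float("nan"),
                    max_abs_deviation=0.0,
                    status="not_scored",
                )
            )
            continue
        out.append(score_gene(cv, kv, params, gene_id, exon_ids))
    return out


def results_to_frame(results: list[GeneSpliceResult], bh_column: bool = True) -> pd.DataFrame:
    """Gene-level results table; optionally adds a Benjamini-Hochberg column."""
    df = pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in results],
            "n_exons": [r.n for r in results],
            "arh": [r.arh for r in results],
            "pvalue": [r.pvalue if r.pvalue is not None else float("nan") for r in results],
            "max_abs_deviation": [r.max_abs_deviation for r in results],
            "status": [r.status for r in results],
        }
    )
    if bh_column:
        ok = df["pvalue"].notna().to_numpy()
        padj = np.full(len(df), np.nan)
        if ok.sum() > 0:
            padj[ok] = multipletests(df.loc[ok, "pvalue"], method="fdr_bh")[1]
        df["pvalue_bh"] = padj
    return df


def exon_results_to_frame(
    results: list[GeneSpliceResult],
    case: CombiTable | None = None,
    control: CombiTable | None = None,
) -> pd.DataFrame:
    """Per-exon deviations and probabilities (one row per exon of each gene)."""
    rows = []
    for r in results:
        for eid, s, p in zip(r.exon_ids, r.deviations, r.probabilities):
            rows.append(
                {
                    "exon_id": eid,
                    "gene_id": r.gene_id,
                    "deviation": float(s),
                    "probability": float(p),
                    "combi_case": case.values.get(eid, float("nan")) if case else float("nan"),
                    "combi_control": control.values.get(eid, float("nan")) if control else float("nan"),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class WeibullBackground:
    """Null distribution of scores: Weibull(scale, shape) with x > 0."""

    scale: float
    shape: float
    se_scale: float
    se_shape: float
    n_fit: int
    n_dropped_zero: int = 0

    def __post_init__(self) -> None:
        if self.scale <= 0 or self.shape <= 0:
            raise ScoringError("Weibull scale and shape must be positive")

    def survival(self, score: float | np.ndarray) -> float | np.ndarray:
        """Upper-tail probability P(S >= score); equals 1 at score 0."""
        x = np.asarray(score, dtype=float)
        if np.any(x < 0):
            raise ScoringError("scores must be non-negative")
        out = np.exp(-((x / self.scale) ** self.shape))
        return float(out) if out.ndim == 0 else out

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for key in ("scale", "shape", "se_scale", "se_shape", "n_fit", "n_dropped_zero"):
                fh.write(f"{key}\t{getattr(self, key)}\n")

    @classmethod
    def from_file(cls, path) -> "WeibullBackground":
        kv: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                if line.strip():
                    key, value = line.rstrip("\n").split("\t")
                    kv[key] = value
        return cls(
            scale=float(kv["scale"]),
            shape=float(kv["shape"]),
            se_scale=float(kv["se_scale"]),
            se_shape=float(kv["se_shape"]),
            n_fit=int(kv["n_fit"]),
            n_dropped_zero=int(kv.get("n_dropped_zero", 0)),
        )


def _weibull_observed_information(x: np.ndarray, lam: float, k: float) -> np.ndarray:
    """Observed information matrix of (scale, shape) at the MLE."""
    n = x.size
    z = (x / lam) ** k
    u = np.log(x / lam)
    d2_kk = -n / k**2 - float(np.sum(z * u**2))
    d2_ll = n * k / lam**2 - k * (k + 1) / lam**2 * float(np.sum(z))
    d2_kl = -n / lam + k / lam * float(np.sum(z * u)) + float(np.sum(z)) / lam
    hess = np.array([[d2_ll, d2_kl], [d2_kl, d2_kk]])
    return -hess


def fit_weibull_background(
    scores: np.ndarray | list[float], min_scores: int = 100
) -> WeibullBackground:
    """Maximum-likelihood Weibull fit to a pool of positive scores.

    Zero and non-finite scores are dropped (Weibull support is x > 0) and
    their count reported. The shape parameter solves the profile-likelihood
    equation by bracketed root finding; the scale then has a closed form.
    Standard errors come from the inverse observed information.
    """
    x = np.asarray(scores, dtype=float)
    n_zero = int(np.sum(x == 0))
    x = x[np.isfinite(x) & (x > 0)]
    if x.size < min_scores:
        raise ScoringError(
            f"only {x.size} usable scores (need >= {min_scores}); "
            "pool scores from more case-control comparisons"
        )
    lx = np.log(x)
    if np.allclose(x, x[0]):
        raise DegenerateFitError("all scores identical; background fit is degenerate")

    mean_lx = lx.mean()

    def profile(k: float) -> float:
        xk = np.exp(k * lx)  # x**k, stable for the bracketed k range
        return float((xk * lx).sum() / xk.sum() - 1.0 / k - mean_lx)

    lo, hi = 1e-3, 1.0
    while profile(hi) < 0 and hi < 1e3:
        hi *= 2.0
    k_hat = float(optimize.brentq(profile, lo, hi, xtol=1e-12, rtol=1e-12))
    lam_hat = float(np.exp(np.log(np.mean(np.exp(k_hat * lx))) / k_hat))

    info = _weibull_observed_information(x, lam_hat, k_hat)
    cov = np.linalg.inv(info)
    se_scale, se_shape = np.sqrt(np.diag(cov))
    return WeibullBackground(
        scale=lam_hat,
        shape=k_hat,
        se_scale=float(se_scale),
        se_shape=float(se_shape),
        n_fit=int(x.size),
        n_dropped_zero=n_zero,
    )


def arh_pvalue(score: float, background: WeibullBackground) -> float:
    """Upper-tail Weibull P-value of one score (1 at score 0)."""
    return float(background.survival(score))


def attach_pvalues(
    results: list[GeneSpliceResult], background: WeibullBackground
) -> list[GeneSpliceResult]:
    """Set ``pvalue`` on every scored result in place; returns the list."""
    for r in results:
        if r.status == "ok" and np.isfinite(r.arh):
            r.pvalue = arh_pvalue(r.arh, background)
    return results
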