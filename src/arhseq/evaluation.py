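"""Benchmarking of splicing predictions against curated true-positive events.

Predictions are sorted by decreasing splicing indication and the positions
of known true-positive events are located in the ranked list; the ROC and
its AUC (tie-aware, i.e. the normalized Mann-Whitney U statistic) quantify
performance. Everything scored but not in the true-positive set counts as
negative — there is no curated true-negative list, so specificity estimates
are conservative whenever real but un-annotated splicing events rank high.

Multiple pairwise comparisons can be pooled into one joint ranking (each
item tagged by its comparison); per-comparison AUCs and their mean are
reported alongside the pooled AUC since either aggregate may be wanted.

A minimal Splicing Index baseline (exon fold change corrected by gene fold
change) is included as an in-package comparator; scores of external methods
are ingested from TSV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn import metrics as skm

__all__ = [
    "EvaluationError",
    "TruePositiveSet",
    "LabeledRanking",
    "load_true_positives",
    "rank_and_label",
    "roc_auc",
    "precision_recall",
    "pool_comparisons",
    "top_k_overlap",
    "splicing_index_baseline",
    "plot_roc",
]


class EvaluationError(ValueError):
    """Invalid evaluation input."""


@dataclass
class TruePositiveSet:
    """Curated differential-splicing events between two conditions."""

    events: list[tuple[str, str | None, str, str]]  # gene, exon?, cond_a, cond_b
    level: str  # "gene" | "exon"

    def __post_init__(self) -> None:
        if self.level not in ("gene", "exon"):
            raise EvaluationError(f"unknown level {self.level!r}")
        self.events = sorted(set(self.events), key=lambda e: tuple(str(x) for x in e))

    @property
    def ids(self) -> set[str]:
        """Identifiers at the set's level (gene ids or exon ids)."""
        if self.level == "gene":
            return {g for g, *_ in self.events}
        return {e for _, e, *_ in self.events if e is not None}

    def __len__(self) -> int:
        return len(self.events)


@dataclass
class LabeledRanking:
    """Items sorted by decreasing score with true-positive labels."""

    ids: list[str]
    scores: np.ndarray
    labels: np.ndarray  # bool, True = known positive
    tag: str = ""
    unmatched: list[str] = field(default_factory=list)

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())

    @property
    def n_negative(self) -> int:
        return int(len(self.labels) - self.labels.sum())


def load_true_positives(
    path: str | Path,
    level: str = "gene",
    condition_pair: tuple[str, str] | None = None,
    expression: Mapping[str, tuple[float, float]] | None = None,
    min_rpkm: float = 0.75,
) -> TruePositiveSet:
    """Read a true-positive event TSV (gene_id, exon_id, condition_a/b).

    For pairwise evaluation, events attributed to other condition pairs are
    excluded (pair order is ignored). When per-id expression values for the
    two conditions are supplied, events whose feature is expressed in
    neither condition are dropped.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_id", "exon_id", "condition_a", "condition_b"}
    missing = required - set(df.columns)
    if missing:
        raise EvaluationError(f"{path}: missing columns {sorted(missing)}")
    events: list[tuple[str, str | None, str, str]] = []
    for row in df.itertuples(index=False):
        exon = row.exon_id if isinstance(row.exon_id, str) and row.exon_id else None
        if level == "exon" and exon is None:
            continue
        if condition_pair is not None:
            if {row.condition_a, row.condition_b} != set(condition_pair):
                continue
        if expression is not None:
            key = row.gene_id if level == "gene" else exon
            a, b = expression.get(key, (0.0, 0.0))
            if max(a, b) < min_rpkm:
                continue
        events.append((row.gene_id, exon, row.condition_a, row.condition_b))
    return TruePositiveSet(events=events, level=level)


def rank_and_label(
    scores: Mapping[str, float],
    true_positives: TruePositiveSet | set[str],
    tag: str = "",
) -> LabeledRanking:
    """Sort by decreasing score (stable on id for ties) and attach labels."""
    tp_ids = (
        true_positives.ids
        if isinstance(true_positives, TruePositiveSet)
        else set(true_positives)
    )
    for i, v in scores.items():
        if not math.isfinite(v):
            raise EvaluationError(f"non-finite score for {i!r}")
    order = sorted(scores, key=lambda i: (-scores[i], i))
    return LabeledRanking(
        ids=order,
        scores=np.array([scores[i] for i in order], dtype=float),
        labels=np.array([i in tp_ids for i in order], dtype=bool),
        tag=tag,
        unmatched=sorted(tp_ids - set(scores)),
    )


def _check_two_classes(r: LabeledRanking) -> None:
    if r.n_positive == 0 or r.n_negative == 0:
        raise EvaluationError(
            f"ranking {r.tag or '?'} needs at least one positive and one "
            f"negative (got {r.n_positive} / {r.n_negative})"
        )


def roc_auc(r: LabeledRanking) -> tuple[pd.DataFrame, float]:
    """ROC step curve (FPR, TPR) and tie-aware AUC."""
    _check_two_classes(r)
    fpr, tpr, _ = skm.roc_curve(r.labels, r.scores)
    auc = float(skm.roc_auc_score(r.labels, r.scores))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr}), auc


def precision_recall(r: LabeledRanking) -> pd.DataFrame:
    """Precision-recall curve over the same ranking."""
    _check_two_classes(r)
    precision, recall, _ = skm.precision_recall_curve(r.labels, r.scores)
    return pd.DataFrame({"recall": recall[::-1], "precision": precision[::-1]})


def pool_comparisons(
    rankings: Sequence[LabeledRanking],
) -> tuple[LabeledRanking, pd.DataFrame]:
    """Concatenate comparisons into one joint ranking.

    Items are tagged by their comparison so identical ids from different
    comparisons stay distinct. Returns the pooled ranking plus a summary
    frame of per-comparison AUCs with their mean and the pooled AUC.
    """
    if not rankings:
        raise EvaluationError("no rankings to pool")
    scores: dict[str, float] = {}
    tp: set[str] = set()
    per = []
    for idx, r in enumerate(rankings):
        tag = r.tag or f"comparison{idx}"
        for i, s, lab in zip(r.ids, r.scores, r.labels):
            key = f"{tag}:{i}"
            scores[key] = float(s)
            if lab:
                tp.add(key)
        _, auc = roc_auc(r)
        per.append({"comparison": tag, "auc": auc})
    pooled = rank_and_label(scores, tp, tag="pooled")
    _, pooled_auc = roc_auc(pooled)
    summary = pd.DataFrame(per)
    summary.attrs["mean_auc"] = float(summary["auc"].mean())
    summary.attrs["pooled_auc"] = pooled_auc
    return pooled, summary


def top_k_overlap(
    rankings: Mapping[str, Sequence[str] | LabeledRanking], k: int = 250
) -> pd.DataFrame:
    """Pairwise |top-k intersection| matrix across methods."""
    if len(rankings) < 2:
        raise EvaluationError("need rankings from at least two methods")
    tops = {}
    for method, r in rankings.items():
        ids = r.ids if isinstance(r, LabeledRanking) else list(r)
        tops[method] = set(ids[:k])
    methods = list(tops)
    mat = pd.DataFrame(index=methods, columns=methods, dtype=int)
    for a in methods:
        for b in methods:
            mat.loc[a, b] = len(tops[a] & tops[b])
    return mat


def splicing_index_baseline(
    exon_case: Mapping[str, float],
    exon_control: Mapping[str, float],
    gene_case: Mapping[str, float],
    gene_control: Mapping[str, float],
    gene_of: Mapping[str, str],
    alpha: float = 0.5,
) -> pd.DataFrame:
    """Splicing Index comparator: gene-corrected exon log fold change.

    SI_i = log2(((e_i^case+a)/(g^case+a)) / ((e_i^control+a)/(g^control+a)));
    the splicing indication used for ranking is |SI_i|.
    """
    if alpha < 0:
        raise EvaluationError("pseudocount must be >= 0")
    rows = []
    for eid, gid in gene_of.items():
        if eid not in exon_case or eid not in exon_control:
            raise EvaluationError(f"exon {eid} missing from expression input")
        num = (exon_case[eid] + alpha) / (gene_case[gid] + alpha)
        den = (exon_control[eid] + alpha) / (gene_control[gid] + alpha)
        if den == 0 or num == 0:
            raise EvaluationError(
                f"exon {eid}: zero expression with zero pseudocount"
            )
        si = math.log2(num / den)
        rows.append({"exon_id": eid, "gene_id": gid, "si": si, "score": abs(si)})
    return pd.DataFrame(rows)


def plot_roc(curves: Mapping[str, pd.DataFrame], path: str | Path) -> None:
    """Write a ROC plot (one line per labeled curve) to PNG/SVG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for label, curve in curves.items():
        ax.plot(curve["fpr"], curve["tpr"], label=label)
    ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(str(path))
    plt.close(fig)
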