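"""Cohort-level statistics for the TD-score.

Classification of BRCA1-type homologous-recombination deficiency from the
per-sample TD-score (positive call at score >= threshold, BRCA1 labels as
positives, BRCA2 and HRP pooled as negatives), ROC/AUC via the Mann-Whitney
identity, group comparisons, and per-gene recurrence testing with Fisher's
exact test and Hochberg step-up adjustment.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .td_detect import SampleTDProfile

POSITIVE_CLASS = "BRCA1"
NEGATIVE_CLASSES = ("BRCA2", "HRP")
COHORT_COLUMNS = ["sample_id", "td_score", "class_label", "er_status"]


def make_cohort_table(rows: Iterable[Mapping]) -> pd.DataFrame:
    """Normalize rows into the cohort table (sample_id, td_score, class_label, er_status)."""
    df = pd.DataFrame(rows)
    if "er_status" not in df.columns:
        df["er_status"] = "NA"
    df = df[COHORT_COLUMNS].copy()
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in cohort table")
    if (df["td_score"] < 0).any():
        raise ValueError("td_score must be non-negative")
    return df


def load_cohort_table(summaries: str | Path | Sequence[str | Path], labels: str | Path) -> pd.DataFrame:
    """Join one or more ``sample_summary.tsv`` files with a labels TSV."""
    if isinstance(summaries, (str, Path)):
        summaries = [summaries]
    scores = pd.concat([pd.read_csv(p, sep="\t") for p in summaries], ignore_index=True)
    lab = pd.read_csv(labels, sep="\t")
    if "er_status" not in lab.columns:
        lab["er_status"] = "NA"
    merged = scores.merge(lab[["sample_id", "class_label", "er_status"]], on="sample_id", how="left")
    merged["class_label"] = merged["class_label"].fillna("NA")
    merged["er_status"] = merged["er_status"].fillna("NA")
    return make_cohort_table(merged.to_dict("records"))


def _labeled(cohort: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Positive (BRCA1) and negative (BRCA2 + HRP) score vectors; NA excluded."""
    pos = cohort.loc[cohort["class_label"] == POSITIVE_CLASS, "td_score"].to_numpy()
    neg = cohort.loc[cohort["class_label"].isin(NEGATIVE_CLASSES), "td_score"].to_numpy()
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("need at least one positive and one negative labeled sample")
    return pos, neg


@dataclasses.dataclass(frozen=True)
class ClassifierResult:
    threshold: int
    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)


def classify(cohort: pd.DataFrame, threshold: int) -> ClassifierResult:
    """Call BRCA1-type at td_score >= threshold; report the confusion counts."""
    pos, neg = _labeled(cohort)
    tp = int((pos >= threshold).sum())
    fp = int((neg >= threshold).sum())
    return ClassifierResult(threshold=threshold, tp=tp, fn=len(pos) - tp, tn=len(neg) - fp, fp=fp)


@dataclasses.dataclass(frozen=True)
class RocResult:
    points: tuple[tuple[int, float, float], ...]  # (threshold, tpr, fpr)
    auc: float
    auc_ci: tuple[float, float] | None = None


def roc_auc(cohort: pd.DataFrame, n_boot: int = 0, seed: int | None = None) -> RocResult:
    """ROC over all integer thresholds and AUC via the Mann-Whitney identity.

    AUC = U / (n1*n2) with tied pairs contributing 1/2 — identical to the
    probability that a random positive outscores a random negative. An
    optional stratified bootstrap (resampling positives and negatives
    separately) gives a percentile 95% CI.
    """
    pos, neg = _labeled(cohort)
    thresholds = range(0, int(max(pos.max(), neg.max())) + 2)
    points = tuple(
        (t, float((pos >= t).mean()), float((neg >= t).mean())) for t in thresholds
    )
    auc = _auc_mwu(pos, neg)
    ci = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        boots = np.array(
            [
                _auc_mwu(rng.choice(pos, len(pos)), rng.choice(neg, len(neg)))
                for _ in range(n_boot)
            ]
        )
        ci = (float(np.quantile(boots, 0.025)), float(np.quantile(boots, 0.975)))
    return RocResult(points=points, auc=auc, auc_ci=ci)


def _auc_mwu(pos: np.ndarray, neg: np.ndarray) -> float:
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2
    return float(u / (len(pos) * len(neg)))


def mann_whitney(scores_a: Sequence[float], scores_b: Sequence[float]) -> float:
    """Two-sided Mann-Whitney U p-value.

    Exact enumeration when n1*n2 <= 400 and no ties; otherwise the normal
    approximation with tie and continuity corrections. Degenerate input where
    every observation is identical carries no evidence and returns 1.0.
    """
    a, b = np.asarray(scores_a, float), np.asarray(scores_b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(a) * len(b) <= 400 and not has_ties) else "asymptotic"
    return float(
        stats.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True).pvalue
    )


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Standard definition: the sum of hypergeometric point probabilities of all
    tables with the observed margins no more likely than the observed table.
    A table with any zero margin is uninformative and returns 1.0.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        return 1.0
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def hochberg_adjust(pvals: Sequence[float]) -> list[float]:
    """Hochberg step-up adjusted p-values, in the input order.

    With p(1) <= ... <= p(m) ascending, adjusted(i) = min over j >= i of
    (m - j + 1) * p(j), capped at 1.
    """
    pvals = list(pvals)
    if not pvals:
        return []
    if any(p < 0 or p > 1 for p in pvals):
        raise ValueError("p-values must lie in [0, 1]")
    return [float(q) for q in multipletests(pvals, method="simes-hochberg")[1]]


def bh_adjust(pvals: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg adjusted p-values (alternative to Hochberg)."""
    if not list(pvals):
        return []
    return [float(q) for q in multipletests(list(pvals), method="fdr_bh")[1]]


@dataclasses.dataclass(frozen=True)
class RecurrenceRow:
    gene_id: str
    gene_name: str
    n_group1_with_td: int
    n_group2_with_td: int
    n1: int
    n2: int
    p_nominal: float
    p_adjusted: float


def recurrence_from_counts(
    counts: Mapping[str, tuple[int, int]],
    n1: int,
    n2: int,
    adjust: str = "hochberg",
    gene_names: Mapping[str, str] | None = None,
) -> list[RecurrenceRow]:
    """Fisher + multiplicity adjustment from per-gene affected-sample counts.

    ``counts`` maps gene id to (samples with a TD in group 1, in group 2);
    group sizes are n1 and n2. All supplied genes are tested; the adjustment
    spans exactly this gene set.
    """
    genes = list(counts)
    ps = [
        fisher_exact_two_sided(a, n1 - a, b, n2 - b) for a, b in (counts[g] for g in genes)
    ]
    adj = hochberg_adjust(ps) if adjust == "hochberg" else bh_adjust(ps)
    names = gene_names or {}
    rows = [
        RecurrenceRow(
            gene_id=g,
            gene_name=names.get(g, g),
            n_group1_with_td=counts[g][0],
            n_group2_with_td=counts[g][1],
            n1=n1,
            n2=n2,
            p_nominal=p,
            p_adjusted=q,
        )
        for g, p, q in zip(genes, ps, adj)
    ]
    rows.sort(key=lambda r: (r.p_adjusted, r.p_nominal, r.gene_id))
    return rows


def recurrence_table(
    profiles: Sequence[SampleTDProfile],
    cohort: pd.DataFrame,
    adjust: str = "hochberg",
    min_samples: int = 2,
) -> list[RecurrenceRow]:
    """Per-gene recurrence testing of TD-affected samples, BRCA1 vs the rest.

    A gene is recurrent when at least ``min_samples`` distinct samples carry a
    TD in it (counted over all profiled samples); each sample contributes at
    most once per gene no matter how many of its regions hit the gene. For
    every recurrent gene the BRCA1-type count is compared against the pooled
    BRCA2-type + HRP count with Fisher's exact test, adjusted across the
    recurrent genes.
    """
    labels = dict(zip(cohort["sample_id"], cohort["class_label"]))
    gene_samples: dict[str, set[str]] = {}
    gene_names: dict[str, str] = {}
    for profile in profiles:
        for call in profile.calls:
            for gid in call.gene_ids:
                gene_samples.setdefault(gid, set()).add(profile.sample_id)
                gene_names.setdefault(gid, gid)
    n1 = int((cohort["class_label"] == POSITIVE_CLASS).sum())
    n2 = int(cohort["class_label"].isin(NEGATIVE_CLASSES).sum())
    counts = {}
    for gid, samples in gene_samples.items():
        if len(samples) < min_samples:
            continue
        a = sum(1 for s in samples if labels.get(s) == POSITIVE_CLASS)
        b = sum(1 for s in samples if labels.get(s) in NEGATIVE_CLASSES)
        counts[gid] = (a, b)
    return recurrence_from_counts(counts, n1, n2, adjust=adjust, gene_names=gene_names)


def recurrence_rows_to_frame(rows: Sequence[RecurrenceRow], adjust: str = "hochberg") -> pd.DataFrame:
    adj_col = "p_adjusted_hochberg" if adjust == "hochberg" else "p_adjusted_bh"
    return pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "gene_name": r.gene_name,
                "n_group1_with_td": r.n_group1_with_td,
                "n_group2_with_td": r.n_group2_with_td,
                "n1": r.n1,
                "n2": r.n2,
                "p_nominal": r.p_nominal,
                adj_col: r.p_adjusted,
            }
            for r in rows
        ]
    )
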