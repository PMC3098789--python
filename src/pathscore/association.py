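"""Statistical association between pathway scores and sample features.

Four procedures rank pathways by association with:

* a binary class label — two-sample Wilcoxon rank-sum test per pathway
  (exact for small tie-free samples, tie-corrected normal approximation
  otherwise);
* a continuous variable — Pearson correlation with a Student-t p-value
  (t = r sqrt(n-2) / sqrt(1-r^2), n-2 df);
* survival — samples split into two groups by the exact one-dimensional
  2-means partition of the scores, Kaplan-Meier curves per group, and a
  logrank test of curve equality;
* gene-level alterations — per-sample hypergeometric upper-tail probability
  that the pathway's genes are altered more often than chance given the
  sample's overall alteration load, combined across samples by Fisher's
  omnibus statistic X = -2 sum ln p, referred to chi-square with 2S df.

P-values are adjusted per run (Bonferroni by default, Benjamini-Hochberg
optional) across every pathway x metric hypothesis tested, and results are
returned sorted by raw p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _lifelines_logrank
from scipy import stats

from .metrics import PathwayScoreMatrix
from .pathway_model import PathwayNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "ClinicalTable",
    "AssociationResult",
    "binary_classification",
    "linear_correlation",
    "kmeans_split",
    "kaplan_meier",
    "logrank_test",
    "survival_association",
    "gene_hits",
    "adjust_pvalues",
    "run_analysis",
    "read_clinical",
]

TestKind = Literal["class", "correlation", "survival", "genehits"]


@dataclass
class ClinicalTable:
    """Sample-level covariates for one of the four association tests."""

    kind: TestKind
    sample_ids: list[str]
    labels: list[str] | None = None            # binary class
    values: np.ndarray | None = None           # continuous variable
    times: np.ndarray | None = None            # survival
    events: np.ndarray | None = None
    alterations: pd.DataFrame | None = None    # genes x samples, 0/1

    def __post_init__(self) -> None:
        if self.kind == "survival":
            self.times = np.asarray(self.times, dtype=float)
            self.events = np.asarray(self.events, dtype=int)
            if np.any(self.times < 0):
                raise ValueError("survival times must be nonnegative")
            if not set(np.unique(self.events)) <= {0, 1}:
                raise ValueError("event indicators must be 0 or 1")
        elif self.kind == "correlation":
            self.values = np.asarray(self.values, dtype=float)
        elif self.kind == "genehits":
            if self.alterations is None:
                raise ValueError("genehits table needs an alteration matrix")
            uniq = set(np.unique(self.alterations.to_numpy()))
            if not uniq <= {0, 1}:
                raise ValueError("alteration matrix must be logical (0/1)")


@dataclass
class AssociationResult:
    pathway_id: str
    metric: str
    statistic: float
    p_raw: float
    p_adjusted: float = np.nan
    extras: dict = field(default_factory=dict)


def binary_classification(
    scores: Sequence[float], labels: Sequence[str], pathway_id: str = "", metric: str = ""
) -> AssociationResult:
    """Wilcoxon rank-sum test of pathway scores between two sample classes.

    Exact p by enumeration when min(n1, n2) <= 10 with no ties, otherwise a
    tie-corrected normal approximation.  Constant scores give p = 1.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = sorted(set(labels.tolist()))
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    a = scores[labels == classes[0]]
    b = scores[labels == classes[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each class needs at least two samples")
    if np.ptp(scores) == 0:
        return AssociationResult(
            pathway_id, metric, np.nan, 1.0,
            extras={"n1": len(a), "n2": len(b), "constant": True},
        )
    has_ties = len(np.unique(scores)) < len(scores)
    method = "exact" if (min(len(a), len(b)) <= 10 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    direction = float(np.sign(np.median(a) - np.median(b)))
    return AssociationResult(
        pathway_id, metric, float(res.statistic), float(res.pvalue),
        extras={
            "n1": len(a), "n2": len(b), "classes": classes,
            "direction": direction, "method": method,
        },
    )


def linear_correlation(
    scores: Sequence[float], variable: Sequence[float],
    pathway_id: str = "", metric: str = "",
) -> AssociationResult:
    """Pearson correlation with two-sided Student-t p-value (n-2 df)."""
    x = np.asarray(scores, dtype=float)
    y = np.asarray(variable, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need at least 3 paired values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return AssociationResult(
            pathway_id, metric, np.nan, 1.0, extras={"n": len(x), "constant": True}
        )
    rho, p = stats.pearsonr(x, y)
    if abs(rho) >= 1.0 - 1e-12:
        p = 0.0
    return AssociationResult(
        pathway_id, metric, float(rho), float(p), extras={"n": len(x)}
    )


def kmeans_split(
    scores: Sequence[float], min_group_size: int = 5
) -> tuple[np.ndarray, np.ndarray]:
    """Optimal 1-D two-group partition minimising within-group sum of squares.

    In one dimension the 2-means optimum is a contiguous split of the sorted
    values, so all n-1 split points are scanned exactly (no iterative
    clustering).  Ties break toward the smaller low-score group.  Returns
    boolean masks (low_group, high_group) aligned with the input order.
    """
    x = np.asarray(scores, dtype=float)
    n = len(x)
    if n < 2 * min_group_size:
        raise ValueError(
            f"need at least {2 * min_group_size} samples for groups of {min_group_size}"
        )
    if np.ptp(x) == 0:
        raise ValueError("constant scores cannot be split")
    order = np.argsort(x, kind="stable")
    xs = x[order]
    csum = np.cumsum(xs)
    csq = np.cumsum(xs**2)
    best_i, best_ss = None, np.inf
    for i in range(min_group_size, n - min_group_size + 1):
        ss_lo = csq[i - 1] - csum[i - 1] ** 2 / i
        ss_hi = (csq[-1] - csq[i - 1]) - (csum[-1] - csum[i - 1]) ** 2 / (n - i)
        ss = ss_lo + ss_hi
        # strict improvement beyond rounding noise keeps the smaller low group on ties
        if best_i is None or ss < best_ss - 1e-12 * (1 + abs(best_ss)):
            best_ss, best_i = ss, i
    low = np.zeros(n, dtype=bool)
    low[order[:best_i]] = True
    return low, ~low


def kaplan_meier(
    times: Sequence[float], events: Sequence[int]
) -> tuple[np.ndarray, np.ndarray]:
    """Product-limit survival estimate; returns (event_times, S(t)).

    Right-censored observations leave the risk set without contributing an
    event.  S is reported at each distinct event time.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) == 0:
        raise ValueError("empty survival input")
    kmf = KaplanMeierFitter().fit(times, events)
    sf = kmf.survival_function_.iloc[:, 0]
    event_times = np.unique(times[events == 1])
    return event_times, sf.loc[event_times].to_numpy()


def logrank_test(
    group1: tuple[Sequence[float], Sequence[int]],
    group2: tuple[Sequence[float], Sequence[int]],
) -> tuple[float, float]:
    """Standard logrank chi-square (1 df) comparing two survival samples."""
    t1, e1 = (np.asarray(v) for v in group1)
    t2, e2 = (np.asarray(v) for v in group2)
    if len(t1) == 0 or len(t2) == 0:
        raise ValueError("both groups must be nonempty")
    if e1.sum() + e2.sum() == 0:
        return 0.0, 1.0
    res = _lifelines_logrank(t1, t2, event_observed_A=e1, event_observed_B=e2)
    return float(res.test_statistic), float(res.p_value)


def survival_association(
    scores: Sequence[float],
    times: Sequence[float],
    events: Sequence[int],
    min_group_size: int = 5,
    pathway_id: str = "",
    metric: str = "",
) -> AssociationResult:
    """Split samples by score (exact 2-means), then logrank on the two groups."""
    scores = np.asarray(scores, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    low, high = kmeans_split(scores, min_group_size=min_group_size)
    chi2, p = logrank_test((times[low], events[low]), (times[high], events[high]))
    return AssociationResult(
        pathway_id, metric, chi2, p,
        extras={"n_low": int(low.sum()), "n_high": int(high.sum())},
    )


def gene_hits(
    alterations: pd.DataFrame, net: PathwayNetwork, pathway_id: str | None = None
) -> AssociationResult:
    """Hypergeometric enrichment of alterations in the pathway's gene set.

    For each sample s with at least one altered gene, p_s = P(X >= k_s) with
    X ~ Hypergeom(N, K, n_s): N assayed genes, K of them in the pathway, n_s
    altered in s, k_s of those in the pathway.  Samples with no alterations
    are excluded.  Omnibus X = -2 sum ln p_s ~ chi-square(2S) under the null.
    """
    pid = pathway_id or net.pathway_id
    universe = [str(g) for g in alterations.index]
    n_universe = len(universe)
    pathway_genes = net.gene_set() & set(universe)
    if not pathway_genes:
        return AssociationResult(
            pid, "genehits", np.nan, 1.0, extras={"testable": False}
        )
    mat = alterations.to_numpy(dtype=int)
    in_pathway = np.array([g in pathway_genes for g in universe])
    n_altered = mat.sum(axis=0)
    k_hits = mat[in_pathway].sum(axis=0)
    p_per_sample = []
    for n_s, k_s in zip(n_altered, k_hits):
        if n_s == 0:
            continue
        p_s = float(
            stats.hypergeom.sf(k_s - 1, n_universe, len(pathway_genes), int(n_s))
        )
        p_per_sample.append(min(max(p_s, 1e-300), 1.0))
    if not p_per_sample:
        return AssociationResult(
            pid, "genehits", 0.0, 1.0, extras={"testable": False, "n_samples": 0}
        )
    x = -2.0 * float(np.sum(np.log(p_per_sample)))
    p = float(stats.chi2.sf(x, 2 * len(p_per_sample)))
    return AssociationResult(
        pid, "genehits", x, p,
        extras={
            "testable": True,
            "n_samples": len(p_per_sample),
            "n_pathway_genes": len(pathway_genes),
        },
    )


def adjust_pvalues(p_raw: Sequence[float], method: str = "bonferroni") -> np.ndarray:
    """Bonferroni (min(1, m*p)) or Benjamini-Hochberg, order preserved."""
    p = np.asarray(p_raw, dtype=float)
    m = len(p)
    if m == 0:
        return p.copy()
    if method == "bonferroni":
        return np.minimum(1.0, m * p)
    if method == "bh":
        order = np.argsort(p, kind="stable")
        ranked = p[order] * m / np.arange(1, m + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty(m)
        out[order] = np.minimum(1.0, ranked)
        return out
    raise ValueError(f"unknown adjustment method {method!r}")


def run_analysis(
    scores: PathwayScoreMatrix,
    clinical: ClinicalTable,
    test: TestKind,
    metrics: Sequence[str] = ("activity", "consistency"),
    nets: Sequence[PathwayNetwork] | None = None,
    min_group_size: int = 5,
    adjust: str = "bonferroni",
    restrict_class: str | None = None,
) -> pd.DataFrame:
    """Apply one association test to every pathway x metric pair and rank.

    Adjusted p-values are computed across the whole family of hypotheses in
    the run; the returned table is sorted ascending by raw p-value.
    ``restrict_class`` limits the analysed samples to those with the given
    label (only meaningful when the clinical table carries labels).
    """
    if test not in ("class", "correlation", "survival", "genehits"):
        raise ValueError(f"unknown test kind {test!r}")
    samples = [s for s in scores.sample_ids if s in set(clinical.sample_ids)]
    if restrict_class is not None:
        if clinical.labels is None:
            raise ValueError("class restriction requires labels")
        keep = {
            s for s, lab in zip(clinical.sample_ids, clinical.labels)
            if lab == restrict_class
        }
        samples = [s for s in samples if s in keep]
    if not samples:
        raise ValueError("no samples shared between scores and clinical table")
    logger.info(
        "%s test on %d/%d samples shared with the clinical table",
        test, len(samples), len(scores.sample_ids),
    )
    pos = {s: i for i, s in enumerate(clinical.sample_ids)}
    idx = [pos[s] for s in samples]

    results: list[AssociationResult] = []
    if test == "genehits":
        if nets is None:
            raise ValueError("genehits requires the pathway networks")
        alt = clinical.alterations[samples]
        for net in nets:
            if net.pathway_id not in scores.pathway_ids:
                continue
            res = gene_hits(alt, net)
            if res.extras.get("testable", True):
                results.append(res)
            else:
                logger.warning("pathway %s not testable for gene hits", net.pathway_id)
    else:
        for metric in metrics:
            frame = getattr(scores, metric)[samples]
            for pid, row in frame.iterrows():
                vals = row.to_numpy(dtype=float)
                if np.any(np.isnan(vals)):
                    logger.warning("pathway %s %s: missing scores, skipped", pid, metric)
                    continue
                try:
                    if test == "class":
                        labels = [clinical.labels[i] for i in idx]
                        res = binary_classification(vals, labels, pid, metric)
                    elif test == "correlation":
                        res = linear_correlation(
                            vals, clinical.values[idx], pid, metric
                        )
                    else:
                        res = survival_association(
                            vals, clinical.times[idx], clinical.events[idx],
                            min_group_size=min_group_size,
                            pathway_id=pid, metric=metric,
                        )
                except ValueError as exc:
                    logger.warning("pathway %s %s skipped: %s", pid, metric, exc)
                    continue
                results.append(res)

    if not results:
        raise ValueError("no testable pathway/metric combinations")
    adj = adjust_pvalues([r.p_raw for r in results], method=adjust)
    for r, pa in zip(results, adj):
        r.p_adjusted = float(pa)
    table = pd.DataFrame(
        {
            "pathway_id": [r.pathway_id for r in results],
            "metric": [r.metric for r in results],
            "statistic": [r.statistic for r in results],
            "p_raw": [r.p_raw for r in results],
            "p_adjusted": [r.p_adjusted for r in results],
            "extras": [r.extras for r in results],
        }
    )
    return table.sort_values("p_raw", kind="stable").reset_index(drop=True)


def read_clinical(path, kind: TestKind) -> ClinicalTable:
    """Read a clinical table in the tab-delimited exchange formats.

    ``class``/``correlation``: two columns (sample_id, value); ``survival``:
    three columns (sample_id, time, event); ``genehits``: a logical matrix
    with gene rows and a sample-id header.
    """
    from pathlib import Path as _Path

    path = _Path(path)
    if kind == "genehits":
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        df.index = df.index.map(str)
        df.columns = df.columns.map(str)
        return ClinicalTable(
            kind="genehits", sample_ids=list(df.columns), alterations=df
        )
    rows = []
    with path.open(encoding="utf-8") as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            rows.append(line.split("\t"))
    if rows and kind != "class":
        try:
            float(rows[0][1])
        except ValueError:
            rows = rows[1:]  # header
    elif rows and rows[0][0].lower() in ("sample", "sample_id"):
        rows = rows[1:]
    if not rows:
        raise ValueError(f"{path}: no clinical rows")
    samples = [r[0] for r in rows]
    if kind == "class":
        return ClinicalTable(kind="class", sample_ids=samples, labels=[r[1] for r in rows])
    if kind == "correlation":
        return ClinicalTable(
            kind="correlation", sample_ids=samples,
            values=np.array([float(r[1]) for r in rows]),
        )
    if kind == "survival":
        return ClinicalTable(
            kind="survival", sample_ids=samples,
            times=np.array([float(r[1]) for r in rows]),
            events=np.array([int(r[2]) for r in rows]),
        )
    raise ValueError(f"unknown test kind {kind!r}")
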