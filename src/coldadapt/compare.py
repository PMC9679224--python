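"""Cross-species statistics: per-pathway ANOVA with Tukey post-hoc tests,
pairwise-significance heatmaps, species clustering, difference-vs-difference
regressions against growth parameters, and gene-redundancy profiling.

No multiple-testing correction is applied across pathways: the heatmaps
count raw Tukey p < alpha outcomes, so the significance level is an
explicit knob rather than an adjusted quantity.  Tukey tests use the
studentized-range distribution with the Tukey-Kramer unequal-n adjustment
(protein counts per pathway differ across species).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

logger = logging.getLogger(__name__)

GROWTH_PARAMS = ("OTG", "Gr")


@dataclass(frozen=True)
class TukeyOutcome:
    """One pairwise Tukey comparison within a (pathway, metric) cell."""

    pathway: str
    metric: str
    entity_a: str
    entity_b: str
    p_value: float


@dataclass
class PairwiseSignificanceMatrix:
    """Counts of (pathway x metric) cells significant between entity pairs."""

    entities: list[str]
    counts: np.ndarray
    alpha: float

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        n = len(self.entities)
        if self.counts.shape != (n, n):
            raise ValueError("counts shape does not match entities")
        if not np.array_equal(self.counts, self.counts.T):
            raise ValueError("counts must be symmetric")
        if np.any(np.diag(self.counts)):
            raise ValueError("diagonal must be zero")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.entities, columns=self.entities)


@dataclass(frozen=True)
class DeltaRegressionResult:
    """OLS of pairwise metric differences on pairwise growth differences."""

    pathway: str
    flex_metric: str
    growth_param: str
    n_pairs: int
    slope: float
    intercept: float
    r2: float
    direction: str
    two_point: bool


def anova_tukey(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> tuple[float, dict[tuple[str, str], float]]:
    """One-way fixed-effects ANOVA plus all-pairs Tukey HSD p-values.

    Groups with fewer than 2 observations are excluded with a warning;
    with fewer than 2 usable groups, or zero pooled variance, the test is
    skipped and recorded untested as ``(nan, {})``.
    """
    usable: dict[str, np.ndarray] = {}
    for name, values in groups.items():
        arr = np.asarray(values, dtype=float)
        if arr.size < 2:
            logger.warning("group %r has <2 observations; excluded", name)
            continue
        usable[name] = arr
    if len(usable) < 2:
        logger.warning("fewer than 2 usable groups; test skipped")
        return float("nan"), {}
    arrays = list(usable.values())
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0 or all(np.ptp(a) == 0 for a in arrays):
        logger.warning("zero within-group variance; test skipped")
        return float("nan"), {}
    anova_p = float(stats.f_oneway(*arrays).pvalue)
    tukey = stats.tukey_hsd(*arrays)
    names = list(usable)
    pair_p: dict[tuple[str, str], float] = {}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            pair_p[(names[i], names[j])] = float(tukey.pvalue[i, j])
    return anova_p, pair_p


def compare_flexibility(
    long_table: pd.DataFrame,
    alpha: float = 0.05,
    entity_of: Mapping[str, str] | None = None,
) -> list[TukeyOutcome]:
    """Run ANOVA + Tukey per (pathway, metric) cell of a long-format table.

    ``long_table`` needs columns species, pathway, metric, value (as
    produced by :func:`coldadapt.flexibility.aggregate_by_pathway`).
    ``entity_of`` optionally maps species onto grouping entities (e.g. OTG
    or Gr classes); by default each species is its own entity.  Only cells
    whose omnibus ANOVA could be run yield Tukey outcomes.
    """
    df = long_table.copy()
    if entity_of is not None:
        df["entity"] = df["species"].map(entity_of)
        df = df.dropna(subset=["entity"])
    else:
        df["entity"] = df["species"]
    outcomes: list[TukeyOutcome] = []
    for (pathway, metric), cell in df.groupby(["pathway", "metric"], sort=True):
        groups = {
            str(entity): grp["value"].to_numpy()
            for entity, grp in cell.groupby("entity", sort=True)
        }
        anova_p, pair_p = anova_tukey(groups, alpha=alpha)
        if np.isnan(anova_p):
            continue
        for (a, b), p in pair_p.items():
            outcomes.append(
                TukeyOutcome(
                    pathway=str(pathway), metric=str(metric),
                    entity_a=a, entity_b=b, p_value=p,
                )
            )
    return outcomes


def significance_heatmap(
    outcomes: Iterable[TukeyOutcome],
    entities: Sequence[str],
    alpha: float = 0.05,
) -> dict[str, PairwiseSignificanceMatrix]:
    """Per-metric and combined matrices of significant-cell counts.

    Each significant (pathway x metric x pair) outcome increments one
    symmetric cell; the ``combined`` matrix sums over metrics.
    """
    entities = list(entities)
    index = {e: i for i, e in enumerate(entities)}
    per_metric: dict[str, np.ndarray] = {}
    combined = np.zeros((len(entities), len(entities)), dtype=int)
    for oc in outcomes:
        if oc.p_value >= alpha:
            continue
        if oc.entity_a not in index or oc.entity_b not in index:
            continue
        i, j = index[oc.entity_a], index[oc.entity_b]
        mat = per_metric.setdefault(
            oc.metric, np.zeros((len(entities), len(entities)), dtype=int)
        )
        mat[i, j] += 1
        mat[j, i] += 1
        combined[i, j] += 1
        combined[j, i] += 1
    result = {
        metric: PairwiseSignificanceMatrix(entities, mat, alpha)
        for metric, mat in sorted(per_metric.items())
    }
    result["combined"] = PairwiseSignificanceMatrix(entities, combined, alpha)
    return result


def cluster_entities(matrix: PairwiseSignificanceMatrix):
    """Average-linkage (UPGMA-style) dendrogram over the count-matrix rows.

    Entities are clustered by Euclidean distance between their rows of
    significant-difference counts; deterministic for a given matrix.
    Returns a dendropy tree.
    """
    import dendropy

    n = len(matrix.entities)
    if n < 3:
        logger.warning("fewer than 3 entities; trivial tree returned")
        newick = "(" + ",".join(matrix.entities) + ");"
        return dendropy.Tree.get(data=newick, schema="newick")
    linkage = hierarchy.linkage(
        matrix.counts.astype(float), method="average", metric="euclidean"
    )
    root, _ = hierarchy.to_tree(linkage, rd=True)

    # ultrametric rendering: edge length = half the merge-height difference
    def render(node, parent_dist: float) -> str:
        length = max(parent_dist - node.dist, 0.0) / 2.0
        if node.is_leaf():
            return f"{matrix.entities[node.id]}:{length:.6g}"
        left = render(node.get_left(), node.dist)
        right = render(node.get_right(), node.dist)
        return f"({left},{right}):{length:.6g}"

    return dendropy.Tree.get(data=render(root, root.dist) + ";", schema="newick")


def delta_regression(
    group_means: pd.DataFrame,
    growth: Mapping[str, Mapping[str, float]],
    significant: Iterable[tuple[str, str, tuple[str, str]]],
) -> list[DeltaRegressionResult]:
    """Regress pairwise metric differences on pairwise growth differences.

    ``group_means`` needs columns entity, pathway, metric, mean;
    ``growth`` maps entity to ``{"OTG": ..., "Gr": ...}``; ``significant``
    lists the (pathway, metric, (entity_a, entity_b)) cells whose pairs
    enter the regression.  Each (pathway, metric, growth parameter) with at
    least 2 pairs yields an OLS fit with intercept; 2-point fits are
    flagged (their r2 is identically 1).
    """
    pairs_by_cell: dict[tuple[str, str], list[tuple[str, str]]] = {}
    for pathway, metric, pair in significant:
        pairs_by_cell.setdefault((pathway, metric), []).append(tuple(pair))
    means = {
        (row.entity, row.pathway, row.metric): float(row.mean)
        for row in group_means.itertuples(index=False)
    }
    results: list[DeltaRegressionResult] = []
    for (pathway, metric), pairs in sorted(pairs_by_cell.items()):
        pairs = sorted(set(pairs))
        if len(pairs) < 2:
            logger.warning(
                "cell (%s, %s) has <2 significant pairs; skipped", pathway, metric
            )
            continue
        for param in GROWTH_PARAMS:
            x, y = [], []
            for a, b in pairs:
                key_a, key_b = (a, pathway, metric), (b, pathway, metric)
                if key_a not in means or key_b not in means:
                    continue
                x.append(growth[a][param] - growth[b][param])
                y.append(means[key_a] - means[key_b])
            if len(x) < 2 or np.ptp(x) == 0:
                continue
            res = stats.linregress(x, y)
            two_point = len(x) == 2
            r2 = 1.0 if two_point else float(res.rvalue**2)
            results.append(
                DeltaRegressionResult(
                    pathway=pathway,
                    flex_metric=metric,
                    growth_param=param,
                    n_pairs=len(x),
                    slope=float(res.slope),
                    intercept=float(res.intercept),
                    r2=r2,
                    direction="positive" if res.slope >= 0 else "negative",
                    two_point=two_point,
                )
            )
    return results


def redundancy_table(
    cds_by_species: Mapping[str, Sequence],
    top_n: int = 20,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Counts of CDSs sharing an annotation label, per species.

    Rows are ranked by total count across species (ties alphabetically)
    and truncated to ``top_n``; unannotated CDSs are excluded and their
    number returned per species.
    """
    species = sorted(cds_by_species)
    counts: dict[str, dict[str, int]] = {}
    unannotated: dict[str, int] = {}
    for sp in species:
        unannotated[sp] = 0
        for cds in cds_by_species[sp]:
            if not cds.annotation_label:
                unannotated[sp] += 1
                continue
            counts.setdefault(cds.annotation_label, {}).setdefault(sp, 0)
            counts[cds.annotation_label][sp] += 1
    rows = []
    for label in counts:
        row = {"annotation_label": label}
        row.update({sp: counts[label].get(sp, 0) for sp in species})
        row["total"] = sum(counts[label].get(sp, 0) for sp in species)
        rows.append(row)
    df = pd.DataFrame(rows, columns=["annotation_label", *species, "total"])
    if not df.empty:
        df = df.sort_values(
            ["total", "annotation_label"], ascending=[False, True]
        ).head(top_n).reset_index(drop=True)
    return df, unannotated


def redundancy_ratio(cds_records: Sequence) -> float:
    """Annotated CDS count over the number of distinct annotation labels."""
    labels = [c.annotation_label for c in cds_records if c.annotation_label]
    if not labels:
        return float("nan")
    return len(labels) / len(set(labels))
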