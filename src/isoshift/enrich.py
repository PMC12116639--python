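"""Enrichment statistics: Fisher odds-ratio target overrepresentation,
Kolmogorov-Smirnov fold-change distance, gene-set overrepresentation, and
the direction-consistency rule.

The Fisher analysis asks whether an isomiR's targets are overrepresented
among genes regulated in the direction opposite to the isomiR (repression
logic: an upregulated isomiR should push its targets down).  The 2x2 table
is (td, tn, nd, nn) = targets/non-targets among regulated/non-regulated
genes, the odds ratio is (td/tn)/(nd/nn), and the p-value is the one-sided
hypergeometric tail.  "Non-regulated" excludes *all* differentially
expressed genes, both directions.

The KS analysis compares the log2 fold-change distributions of seed-bearing
target genes vs the remaining universe; the distance D is the maximum
absolute ECDF difference.  A direction flag (sign of the median target
shift relative to non-targets) feeds the consistency rule: a candidate
isomiR is kept only when its own fold change is opposite in sign to its
targets' shift.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .de import bh_fdr

__all__ = [
    "ContingencyCounts",
    "OrResult",
    "KsResult",
    "fisher_or",
    "fisher_or_table",
    "ks_distance",
    "ks_seed_enrichment",
    "ks_table",
    "direction_consistent",
    "geneset_enrichment",
    "read_gmt",
]


@dataclass(frozen=True)
class ContingencyCounts:
    """2x2 target-by-regulation table.

    td / tn: targets among regulated and non-regulated genes;
    nd / nn: non-targets among the same classes.
    """

    td: int
    tn: int
    nd: int
    nn: int

    @property
    def total(self) -> int:
        return self.td + self.tn + self.nd + self.nn

    def odds_ratio(self) -> float:
        """(td/tn)/(nd/nn); +inf when a zero denominator meets td > 0."""
        if self.tn == 0 or self.nd == 0:
            return math.inf if self.td > 0 else math.nan
        if self.nn == 0:
            return 0.0 if self.td == 0 else math.inf
        return (self.td / self.tn) / (self.nd / self.nn)


@dataclass
class OrResult:
    isomir: str
    counts: ContingencyCounts
    odds_ratio: float
    pvalue: float
    qvalue: float = math.nan


@dataclass
class KsResult:
    isomir: str
    distance: float
    pvalue: float
    n_targets: int
    n_nontargets: int
    direction: int  # sign of (median target lfc - median non-target lfc)
    qvalue: float = math.nan


def _hypergeom_p_greater(c: ContingencyCounts) -> float:
    """One-sided (overrepresentation) Fisher p: upper hypergeometric tail."""
    n_targets = c.td + c.tn
    n_regulated = c.td + c.nd
    return float(stats.hypergeom.sf(c.td - 1, c.total, n_targets, n_regulated))


def fisher_or(
    target_set: set[str],
    regulated_genes: set[str],
    universe: set[str],
    exclude: set[str] | None = None,
    isomir: str = "",
    alternative: str = "greater",
) -> OrResult:
    """Target overrepresentation among regulated genes.

    ``regulated_genes`` is the opposite-direction DE set for the isomiR
    under test; ``exclude`` holds the remaining DE genes (same direction),
    which are removed from the non-regulated class so that "non-regulated"
    means not differentially expressed at all.
    """
    if not universe:
        raise ValueError("empty universe")
    regulated = regulated_genes & universe
    excluded = (exclude or set()) - regulated
    nonregulated = universe - regulated - excluded
    targets = target_set & universe
    td = len(targets & regulated)
    tn = len(targets & nonregulated)
    nd = len(regulated - targets)
    nn = len(nonregulated - targets)
    c = ContingencyCounts(td, tn, nd, nn)
    if alternative == "greater":
        p = _hypergeom_p_greater(c)
    else:
        _, p = stats.fisher_exact([[td, tn], [nd, nn]], alternative=alternative)
    return OrResult(isomir=isomir, counts=c, odds_ratio=c.odds_ratio(), pvalue=float(p))


def fisher_or_table(results: list[OrResult]) -> pd.DataFrame:
    """BH-adjust a family of odds-ratio tests and tabulate them."""
    if results:
        qs = bh_fdr([r.pvalue for r in results])
        for r, q in zip(results, qs):
            r.qvalue = float(q)
    return pd.DataFrame(
        [
            {
                "isomir": r.isomir,
                "td": r.counts.td,
                "tn": r.counts.tn,
                "nd": r.counts.nd,
                "nn": r.counts.nn,
                "odds_ratio": r.odds_ratio,
                "pvalue": r.pvalue,
                "FDR": r.qvalue,
            }
            for r in results
        ]
    )


def ks_distance(a, b) -> float:
    """Two-sample KS statistic: sup over pooled points of |ECDF_a - ECDF_b|."""
    a = np.sort(np.asarray(a, dtype=float))
    b = np.sort(np.asarray(b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, pooled, side="right") / a.size
    cdf_b = np.searchsorted(b, pooled, side="right") / b.size
    return float(np.max(np.abs(cdf_a - cdf_b)))


def ks_seed_enrichment(
    log2fc_by_gene: pd.Series, seed_target_genes: set[str], isomir: str = ""
) -> KsResult:
    """KS comparison of target vs non-target fold-change distributions.

    The p-value is the asymptotic two-sided Kolmogorov distribution of
    sqrt(nm/(n+m)) * D, appropriate for gene-scale universes.
    """
    lfc = log2fc_by_gene.dropna()
    if not np.isfinite(lfc.to_numpy()).all():
        raise ValueError("non-finite log2 fold changes")
    is_target = lfc.index.isin(seed_target_genes)
    t = lfc.to_numpy()[is_target]
    nt = lfc.to_numpy()[~is_target]
    if t.size == 0 or nt.size == 0:
        raise ValueError("target and non-target partitions must both be non-empty")
    d = ks_distance(t, nt)
    en = math.sqrt(t.size * nt.size / (t.size + nt.size))
    p = float(np.clip(special.kolmogorov(en * d), 0.0, 1.0))
    direction = int(np.sign(np.median(t) - np.median(nt)))
    return KsResult(
        isomir=isomir,
        distance=d,
        pvalue=p,
        n_targets=int(t.size),
        n_nontargets=int(nt.size),
        direction=direction,
    )


def ks_table(results: list[KsResult], isomir_lfc: dict[str, float] | None = None) -> pd.DataFrame:
    """BH-adjust a family of KS tests; annotate direction consistency."""
    if results:
        qs = bh_fdr([r.pvalue for r in results])
        for r, q in zip(results, qs):
            r.qvalue = float(q)
    rows = []
    for r in results:
        row = {
            "isomir": r.isomir,
            "distance": r.distance,
            "pvalue": r.pvalue,
            "FDR": r.qvalue,
            "direction": r.direction,
        }
        if isomir_lfc is not None and r.isomir in isomir_lfc:
            row["consistent"] = direction_consistent(isomir_lfc[r.isomir], r)
        rows.append(row)
    return pd.DataFrame(rows)


def direction_consistent(isomir_log2fc: float, ks_result: KsResult) -> bool:
    """Repression logic: the isomiR's change must oppose its targets' shift.

    True iff sign(isomiR log2FC) == -sign(target direction flag).  A zero
    median difference is inconsistent by convention.
    """
    if ks_result.direction == 0 or isomir_log2fc == 0:
        return False
    return np.sign(isomir_log2fc) == -ks_result.direction


def geneset_enrichment(
    down_targets: set[str], geneset_collection: dict[str, list[str]], universe: set[str]
) -> pd.DataFrame:
    """Per-gene-set one-sided Fisher overrepresentation of a gene collection.

    Sets are intersected with the universe first; BH across sets; rows with
    q < 0.05 are flagged enriched.
    """
    if not geneset_collection:
        raise ValueError("empty gene-set collection")
    hits = down_targets & universe
    results = []
    for name, members in geneset_collection.items():
        mset = set(members) & universe
        r = fisher_or(hits, mset, universe, isomir=name)
        results.append(r)
    tab = fisher_or_table(results).rename(columns={"isomir": "gene_set"})
    tab["enriched"] = tab["FDR"] < 0.05
    return tab.sort_values(["pvalue", "gene_set"]).reset_index(drop=True)


def read_gmt(path) -> dict[str, list[str]]:
    """Parse a GMT file: tab-separated set name, description, members."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3 and parts[0]:
                sets[parts[0]] = [g for g in parts[2:] if g]
    return sets
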