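"""Transcription-factor triangulation.

Candidate regulators of the observed expression changes are found by
intersecting three independent lines of evidence:

1. TFs whose gene regulon (TF->gene edge table) is overrepresented in the
   top up/down-regulated genes (hypergeometric, with a minimum hit count);
2. TFs whose own gene is differentially expressed;
3. TFs with recorded TF->miRNA-gene edges to the differentially expressed
   miRNAs (a mature isomiR label is mapped to its miRNA gene(s) first —
   5'-isoforms share their canonical miRNA's gene).

The result is a TF x miRNA-gene boolean matrix sorted by coverage, the
number of candidate miRNA genes each TF regulates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .de import FilterThresholds
from .reference import parse_isomir_label

__all__ = [
    "candidate_tfs",
    "filter_de_tfs",
    "map_matures_to_genes",
    "mirna_regulator_matrix",
    "TriangulationResult",
]


def candidate_tfs(
    tf_gene_edges: pd.DataFrame,
    top_up_genes: list[str],
    top_down_genes: list[str],
    universe: set[str],
    min_regulon_hits: int = 3,
) -> pd.DataFrame:
    """TFs whose regulon is overrepresented in the top regulated genes.

    The up and down lists are pooled; a TF qualifies with at least
    ``min_regulon_hits`` regulon genes inside the pooled list and is ranked
    by the hypergeometric overrepresentation p-value against the universe.
    Returns a DataFrame (tf, regulon_size, hits, pvalue) sorted by p.
    """
    if tf_gene_edges.empty:
        raise ValueError("empty TF->gene edge table")
    edges = tf_gene_edges.drop_duplicates(subset=["tf", "gene"])
    top = (set(top_up_genes) | set(top_down_genes)) & universe
    n_universe, n_top = len(universe), len(top)
    rows = []
    for tf, sub in edges.groupby("tf"):
        regulon = set(sub["gene"]) & universe
        hits = len(regulon & top)
        if hits < min_regulon_hits:
            continue
        p = float(stats.hypergeom.sf(hits - 1, n_universe, len(regulon), n_top))
        rows.append({"tf": tf, "regulon_size": len(regulon), "hits": hits, "pvalue": p})
    return (
        pd.DataFrame(rows, columns=["tf", "regulon_size", "hits", "pvalue"])
        .sort_values(["pvalue", "tf"])
        .reset_index(drop=True)
    )


def filter_de_tfs(
    candidates: pd.DataFrame | list[str],
    de_records: pd.DataFrame,
    thresholds: FilterThresholds | None = None,
) -> list[str]:
    """Keep candidate TFs whose own gene is differentially expressed.

    Applies the gene DE rule: BH q below ``de_fdr`` and fold change above
    ``min_fold``.  TFs absent from the expression table are dropped with a
    warning.
    """
    thresholds = thresholds or FilterThresholds()
    names = list(candidates["tf"]) if isinstance(candidates, pd.DataFrame) else list(candidates)
    kept = []
    for tf in names:
        if tf not in de_records.index:
            warnings.warn(f"TF {tf} absent from the expression table; dropped")
            continue
        rec = de_records.loc[tf]
        if rec["qvalue"] < thresholds.de_fdr and abs(rec["log2FC"]) > np.log2(thresholds.min_fold):
            kept.append(tf)
    return kept


def map_matures_to_genes(
    isomir_labels: list[str], mature2gene: pd.DataFrame
) -> tuple[dict[str, list[str]], list[str]]:
    """Map isomiR labels to miRNA gene ids via their canonical mature name.

    A mature may map to several miRNA genes (paralogous loci); 5'-isoforms
    inherit their canonical mature's genes.  Returns (label -> gene ids,
    unmapped labels).
    """
    lut = mature2gene.groupby("mature")["mirna_gene"].agg(list).to_dict()
    mapped: dict[str, list[str]] = {}
    unmapped: list[str] = []
    for label in isomir_labels:
        name = parse_isomir_label(label).name
        genes = lut.get(name)
        if genes:
            mapped[label] = sorted(set(genes))
        else:
            unmapped.append(label)
    return mapped, unmapped


@dataclass
class TriangulationResult:
    """TF x miRNA-gene boolean matrix, sorted by per-TF coverage."""

    matrix: pd.DataFrame            # index TF, columns miRNA gene ids, bool
    coverage: pd.Series             # per-TF count of regulated candidate miRNA genes
    unmapped_isomirs: list[str] = field(default_factory=list)


def mirna_regulator_matrix(
    de_tfs: list[str],
    tf_mirna_edges: pd.DataFrame,
    candidate_mirna_genes: list[str],
    unmapped_isomirs: list[str] | None = None,
) -> TriangulationResult:
    """Intersect DE TFs with the TF->miRNA edge table.

    Cell (TF, miRNA gene) is true iff an edge exists; TFs regulating none of
    the candidate miRNA genes are dropped; rows are sorted by coverage
    descending (ties by TF name).
    """
    genes = sorted(set(candidate_mirna_genes))
    edges = tf_mirna_edges.drop_duplicates(subset=["tf", "mirna_gene"])
    edges = edges[edges["tf"].isin(de_tfs) & edges["mirna_gene"].isin(genes)]
    matrix = pd.DataFrame(False, index=sorted(de_tfs), columns=genes, dtype=bool)
    for _, row in edges.iterrows():
        matrix.loc[row["tf"], row["mirna_gene"]] = True
    coverage = matrix.sum(axis=1)
    keep = coverage[coverage > 0]
    order = keep.sort_index().sort_values(ascending=False, kind="stable").index
    matrix = matrix.loc[order]
    return TriangulationResult(
        matrix=matrix,
        coverage=matrix.sum(axis=1),
        unmapped_isomirs=list(unmapped_isomirs or []),
    )
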