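"""End-to-end orchestration: quant -> normalize -> DE -> select -> targets ->
enrichment -> TF triangulation, driven by one YAML-serializable config.

Every stage is a pure function of its inputs, so a rerun with the same
config and inputs is byte-identical.  Stage outputs are written as TSV/JSON
under ``outdir``; the expensive quantification stage can be reused from a
previous run with ``reuse_quant``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .de import (
    FilterThresholds,
    bh_fdr,
    de_feature_sets,
    nb_wald_de,
    select_abundant,
    select_top_expressed,
    size_factors,
    to_fpkm,
    to_rpm,
)
from .enrich import (
    direction_consistent,
    fisher_or,
    fisher_or_table,
    geneset_enrichment,
    ks_seed_enrichment,
    ks_table,
    read_gmt,
)
from .quant import build_lookup, quantify, read_fastq_seqs, trim_reads
from .reference import MirnaReference, parse_isomir_label
from .simulate import ADAPTER
from .targets import build_target_sets, isoform_sequences_from_reference
from .tf import candidate_tfs, filter_de_tfs, map_matures_to_genes, mirna_regulator_matrix

__all__ = ["RunConfig", "RunReport", "run_pipeline"]

_PATH_FIELDS = (
    "reads_dir",
    "hairpin_fasta",
    "mature_tsv",
    "gene_counts",
    "gene_lengths",
    "groups",
    "utr_fasta",
    "validated_tsv",
    "predicted_tsv",
    "gmt",
    "tf_gene_tsv",
    "tf_mirna_tsv",
    "mature2gene_tsv",
)


@dataclass
class RunConfig:
    """Paths to every input plus the thresholds and configurable flags."""

    reads_dir: str
    hairpin_fasta: str
    mature_tsv: str
    gene_counts: str
    gene_lengths: str
    groups: str
    utr_fasta: str
    validated_tsv: str
    predicted_tsv: str
    gmt: str
    tf_gene_tsv: str
    tf_mirna_tsv: str
    mature2gene_tsv: str
    outdir: str = "results"
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    adapter: str = ADAPTER
    min_overlap: int = 3
    window5: int = 3
    window3: int = 5
    seed_kind: str = "6mer"
    with_a1: bool = False
    fisher_alternative: str = "greater"
    min_regulon_hits: int = 3
    reference_group: str | None = None
    reuse_quant: bool = False
    rng_seed: int = 0

    def validate(self) -> None:
        missing = [f for f in _PATH_FIELDS if not Path(getattr(self, f)).exists()]
        if missing:
            raise FileNotFoundError(
                "missing inputs: "
                + ", ".join(f"{f}={getattr(self, f)}" for f in missing)
            )
        self.thresholds.validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        thr = raw.pop("thresholds", None)
        cfg = cls(**raw)
        if thr:
            cfg.thresholds = FilterThresholds(**thr)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


@dataclass
class RunReport:
    """Per-stage record counts plus a config echo; consistency-checked."""

    counts: dict
    version: str
    config: dict

    def check(self) -> None:
        c = self.counts
        assert c["isomirs_de"] <= c["isomirs_abundant"] <= c["isomirs_quantified"]
        assert c["isomirs_final"] <= c["isomirs_de"]
        assert c["tfs_final"] <= c["tfs_de"] <= c["tfs_candidate"]
        assert c["genes_universe"] <= c["genes_total"]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"counts": self.counts, "version": self.version, "config": self.config},
                       indent=1, default=str)
        )


def _load_groups(path: str) -> pd.Series:
    tab = pd.read_csv(path, sep="\t", index_col=0)
    return tab.iloc[:, 0]


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full analysis; writes stage outputs under ``config.outdir``."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    thr = config.thresholds
    groups = _load_groups(config.groups)
    reference = MirnaReference.read(config.hairpin_fasta, config.mature_tsv)

    # ---- stage 1: quantify isomiRs ---------------------------------------
    counts_path = outdir / "isomir_counts.tsv"
    if config.reuse_quant and counts_path.exists():
        iso_counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    else:
        fastqs = sorted(Path(config.reads_dir).glob("*.fastq"))
        if not fastqs:
            raise FileNotFoundError(f"no FASTQ files in {config.reads_dir}")
        index = build_lookup(reference, config.window5, config.window3)
        trimmed = {}
        for fq in fastqs:
            seqs, _ = trim_reads(read_fastq_seqs(fq), config.adapter, config.min_overlap)
            trimmed[fq.stem] = seqs
        quant = quantify(trimmed, index)
        iso_counts = quant.counts
        iso_counts.rename_axis("isomir").to_csv(counts_path, sep="\t")
        quant.detailed.to_csv(outdir / "isomir_counts_detailed.tsv", sep="\t", index=False)
        quant.unmapped.rename("unmapped").rename_axis("sample").to_csv(
            outdir / "unmapped.tsv", sep="\t"
        )
    iso_counts = iso_counts.reindex(columns=groups.index)

    # ---- stage 2: isomiR normalization, DE, abundance selection ----------
    iso_rpm = to_rpm(iso_counts)
    iso_de = nb_wald_de(iso_counts, groups, reference_group=config.reference_group)
    abundant = select_abundant(iso_rpm, thr)
    iso_sets = de_feature_sets(
        iso_de.loc[abundant], thr, apply_fold=thr.fold_applies_to_isomirs
    )
    de_isomirs = iso_sets["all"]
    iso_de.rename_axis("isomir").to_csv(outdir / "isomir_de.tsv", sep="\t")

    # ---- stage 3: gene normalization, DE, universe selection -------------
    gene_counts = pd.read_csv(config.gene_counts, sep="\t", index_col=0)
    gene_counts = gene_counts.reindex(columns=groups.index)
    gene_lengths = pd.read_csv(config.gene_lengths, sep="\t", index_col=0).iloc[:, 0]
    gene_sf = size_factors(gene_counts)
    fpkm = to_fpkm(gene_counts / gene_sf, gene_lengths)
    universe = set(
        select_top_expressed(fpkm, min(thr.top_genes, gene_counts.shape[0]))
    )
    gene_de = nb_wald_de(
        gene_counts, groups, sf=gene_sf, reference_group=config.reference_group
    )
    gene_de.rename_axis("gene").to_csv(outdir / "gene_de.tsv", sep="\t")
    gde = gene_de.loc[sorted(universe)]
    gene_sets_dir = de_feature_sets(gde, thr, apply_fold=True)
    up_genes, down_genes = set(gene_sets_dir["up"]), set(gene_sets_dir["down"])

    # ---- stage 4: target sets --------------------------------------------
    validated = pd.read_csv(config.validated_tsv, sep="\t")
    predicted = pd.read_csv(config.predicted_tsv, sep="\t")
    utrs = _read_fasta_dict(config.utr_fasta)
    iso_seqs = isoform_sequences_from_reference(reference, de_isomirs)
    target_sets = build_target_sets(
        validated, predicted, utrs, iso_seqs, universe,
        seed_kind=config.seed_kind, with_a1=config.with_a1,
    )
    pd.DataFrame(
        [
            {"isomir": ts.isomir, "gene": g, "provenance": ts.provenance}
            for ts in target_sets.values()
            for g in sorted(ts.genes)
        ]
    ).to_csv(outdir / "target_sets.tsv", sep="\t", index=False)

    # ---- stage 5: enrichment ---------------------------------------------
    iso_lfc = {label: float(iso_de.loc[label, "log2FC"]) for label in de_isomirs}
    lfc_by_gene = gde["log2FC"]
    or_results, ks_results = [], []
    for label in de_isomirs:
        ts = target_sets[label]
        opposite = down_genes if iso_lfc[label] > 0 else up_genes
        same = up_genes if iso_lfc[label] > 0 else down_genes
        if ts.provenance == "validated" and ts.genes:
            or_results.append(
                fisher_or(set(ts.genes), opposite, universe, exclude=same,
                          isomir=label, alternative=config.fisher_alternative)
            )
        if ts.genes and len(ts.genes) < len(universe):
            ks_results.append(
                ks_seed_enrichment(lfc_by_gene, set(ts.genes), isomir=label)
            )
    or_tab = fisher_or_table(or_results)
    ks_tab = ks_table(ks_results, isomir_lfc=iso_lfc)
    or_tab.to_csv(outdir / "fisher_or.tsv", sep="\t", index=False)
    ks_tab.to_csv(outdir / "ks_enrichment.tsv", sep="\t", index=False)
    if len(ks_tab):
        final = ks_tab[(ks_tab["FDR"] < thr.de_fdr) & ks_tab["consistent"]]
        final_isomirs = sorted(final["isomir"])
    else:
        final_isomirs = []

    down_targets = set().union(
        *[set(target_sets[l].genes) for l in de_isomirs if iso_lfc[l] > 0], set()
    ) & down_genes
    gmt = read_gmt(config.gmt)
    gs_tab = geneset_enrichment(down_targets, gmt, universe)
    gs_tab.to_csv(outdir / "geneset_enrichment.tsv", sep="\t", index=False)

    # ---- stage 6: TF triangulation ---------------------------------------
    ranked = gde["log2FC"].sort_index().sort_values(kind="stable")
    top_n = min(thr.top_regulated, len(ranked))
    top_down = list(ranked.index[:top_n])
    top_up = list(ranked.index[::-1][:top_n])
    tf_gene = pd.read_csv(config.tf_gene_tsv, sep="\t")
    tf_mirna = pd.read_csv(config.tf_mirna_tsv, sep="\t")
    mature2gene = pd.read_csv(config.mature2gene_tsv, sep="\t")
    cands = candidate_tfs(tf_gene, top_up, top_down, universe, config.min_regulon_hits)
    de_tfs = filter_de_tfs(cands, gene_de, thr)
    mirna_labels = final_isomirs if final_isomirs else de_isomirs
    mapped, unmapped_labels = map_matures_to_genes(mirna_labels, mature2gene)
    candidate_mirna_genes = sorted({g for gs in mapped.values() for g in gs})
    tri = mirna_regulator_matrix(de_tfs, tf_mirna, candidate_mirna_genes, unmapped_labels)
    cands.to_csv(outdir / "tf_candidates.tsv", sep="\t", index=False)
    tri.matrix.astype(int).rename_axis("tf").to_csv(outdir / "tf_mirna_matrix.tsv", sep="\t")

    # ---- report -----------------------------------------------------------
    report = RunReport(
        counts={
            "samples": int(len(groups)),
            "isomirs_quantified": int(iso_counts.shape[0]),
            "isomirs_abundant": int(len(abundant)),
            "isomirs_de": int(len(de_isomirs)),
            "isomirs_de_up": int(len(iso_sets["up"])),
            "isomirs_de_down": int(len(iso_sets["down"])),
            "isomirs_final": int(len(final_isomirs)),
            "genes_total": int(gene_counts.shape[0]),
            "genes_universe": int(len(universe)),
            "genes_de_up": int(len(up_genes)),
            "genes_de_down": int(len(down_genes)),
            "targets_per_isomir": {l: int(len(target_sets[l].genes)) for l in de_isomirs},
            "fisher_enriched": int((or_tab["FDR"] < thr.de_fdr).sum()) if len(or_tab) else 0,
            "ks_enriched": int((ks_tab["FDR"] < thr.de_fdr).sum()) if len(ks_tab) else 0,
            "genesets_enriched": int(gs_tab["enriched"].sum()),
            "tfs_candidate": int(len(cands)),
            "tfs_de": int(len(de_tfs)),
            "tfs_final": int(tri.matrix.shape[0]),
            "unmapped_isomir_labels": list(unmapped_labels),
            "final_isomirs": final_isomirs,
        },
        version=__version__,
        config=asdict(config),
    )
    report.check()
    report.to_json(outdir / "report.json")
    return report


def _read_fasta_dict(path: str) -> dict[str, str]:
    from Bio import SeqIO

    return {
        rec.id: str(rec.seq).upper().replace("U", "T")
        for rec in SeqIO.parse(str(path), "fasta")
    }
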