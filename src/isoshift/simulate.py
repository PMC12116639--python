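"""Synthetic two-group small-RNA / mRNA study generator with planted truth.

Emulates the statistical structure of a knockdown-vs-control xenograft design:
two groups of 7 and 8 samples, negative-binomial counts, a minority of
isomiRs and genes carrying planted effects of at least two-fold, seed-match
sites planted in the 3'UTRs of target genes, and regulator edge tables
consistent with the planted transcription factors.  Every downstream claim of
the pipeline (quantification, differential expression, target recovery,
enrichment, TF triangulation) can therefore be checked against machine-
readable truth.

Outputs are plain text: FASTQ (Phred+33, constant quality), FASTA, TSV with
header rows, GMT and JSON.  All sequences are emitted in the DNA alphabet;
converting to U-alphabet for display is the pipeline's job.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .reference import IsomirId, Mature, MirnaReference

__all__ = [
    "SimulationConfig",
    "Truth",
    "SyntheticBundle",
    "AmbiguousReferenceError",
    "make_reference",
    "simulate_smallrna_reads",
    "simulate_gene_counts",
    "make_utrs_and_tables",
    "generate",
    "nb_draws",
]

ADAPTER = "AGATCGGAAGAGCACACGTCT"  # 3' sequencing adapter appended to every read
READ_LENGTH = 50
_BASES = np.array(list("ACGT"))

# shifts assigned to successive isoforms of one miRNA: canonical first,
# then the 5'-shift variants observed to matter in practice
_SHIFT_ORDER = (0, 1, -1, 2, -2)


class AmbiguousReferenceError(RuntimeError):
    """Raised when distinct mature 16-mer prefixes cannot be sampled."""


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study.

    Defaults describe the emulated design: 7 control vs 8 knockdown samples,
    NB dispersion 0.1 (typical bulk RNA-seq), planted effects of at least
    one log2 unit (the two-fold differential-expression threshold), and 20%
    decoy rows in every relational table.
    """

    n_mirnas: int = 30
    n_isoforms_per_mirna: int = 3
    n_genes: int = 2000
    n_samples_per_group: tuple[int, int] = (7, 8)
    depth_smallrna: int = 20_000
    nb_dispersion: float = 0.1
    planted_isomir_effects: dict[str, float] | None = None
    planted_gene_effects: dict[str, float] | None = None
    n_active_isomirs: int = 4
    target_fraction: float = 0.03
    background_de_fraction: float = 0.05
    decoy_rate: float = 0.2
    n_planted_tfs: int = 2
    n_decoy_tfs: int = 4
    n_gene_sets: int = 8
    tf_regulon_size: int = 20
    mature_len: tuple[int, int] = (20, 24)
    utr_len: tuple[int, int] = (200, 400)
    gene_log_mean: float = np.log(300.0)
    gene_log_sigma: float = 1.0
    rng_seed: int = 0

    group_names: tuple[str, str] = ("shLuc", "shCD44")

    def validate(self) -> None:
        if min(self.n_mirnas, self.n_isoforms_per_mirna, self.n_genes) < 1:
            raise ValueError("counts must be >= 1")
        if min(self.n_samples_per_group) < 1 or self.depth_smallrna < 1:
            raise ValueError("sample counts and depth must be >= 1")
        if self.nb_dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if not (0.0 <= self.target_fraction <= 1.0 and 0.0 <= self.decoy_rate <= 1.0):
            raise ValueError("fractions must lie in [0, 1]")
        for name, effects in (
            ("planted_isomir_effects", self.planted_isomir_effects),
            ("planted_gene_effects", self.planted_gene_effects),
        ):
            if effects:
                bad = {k: v for k, v in effects.items() if v != 0 and abs(v) < 1.0}
                if bad:
                    raise ValueError(
                        f"{name}: planted |log2 effects| must be 0 or >= 1, got {bad}"
                    )

    @property
    def samples(self) -> list[str]:
        g1, g2 = self.group_names
        n1, n2 = self.n_samples_per_group
        return [f"{g1}_{i+1}" for i in range(n1)] + [f"{g2}_{i+1}" for i in range(n2)]

    @property
    def groups(self) -> pd.Series:
        g1, g2 = self.group_names
        n1, n2 = self.n_samples_per_group
        return pd.Series([g1] * n1 + [g2] * n2, index=self.samples, name="group")


@dataclass
class Truth:
    """Machine-readable planted truth emitted beside the synthetic data."""

    true_isomir_fc: dict[str, float]
    true_gene_fc: dict[str, float]
    true_targets: dict[str, list[str]]
    true_tf_regulators: dict[str, dict[str, list[str]]]
    baseline_proportions: dict[str, float]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "Truth":
        return cls(**json.loads(Path(path).read_text()))


def _rng(config: SimulationConfig, stage: int, rng_seed: int | None = None) -> np.random.Generator:
    seed = config.rng_seed if rng_seed is None else rng_seed
    return np.random.default_rng(np.random.SeedSequence([int(seed), stage]))


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


# --------------------------------------------------------------------------
# reference
# --------------------------------------------------------------------------

def make_reference(config: SimulationConfig, rng_seed: int | None = None) -> MirnaReference:
    """Generate a miRBase-like reference of hairpins with embedded matures.

    Mature sequences are 20-24 nt with pairwise-distinct 16-nt prefixes so
    that exact-lookup quantification is unambiguous; each hairpin carries
    8 nt of flank on both sides of the mature, leaving room for the +/-
    shift windows.  Raises :class:`AmbiguousReferenceError` if prefix
    uniqueness cannot be achieved within bounded retries.
    """
    config.validate()
    rng = _rng(config, stage=1, rng_seed=rng_seed)
    lo, hi = config.mature_len
    flank = 8
    hairpins: dict[str, str] = {}
    matures: list[Mature] = []
    prefixes: set[str] = set()
    for i in range(config.n_mirnas):
        name = f"syn-mir-{i+1:03d}-5p"
        hp_name = f"syn-mir-{i+1:03d}"
        for attempt in range(100):
            mlen = int(rng.integers(lo, hi + 1))
            mature = _random_seq(rng, mlen)
            if mature[:16] not in prefixes:
                break
        else:
            raise AmbiguousReferenceError(
                f"could not sample a unique 16-mer prefix for {name}"
            )
        prefixes.add(mature[:16])
        hairpin = _random_seq(rng, flank) + mature + _random_seq(rng, flank)
        hairpins[hp_name] = hairpin
        matures.append(Mature(name, hp_name, flank, flank + mlen))
    ref = MirnaReference(hairpins=hairpins, matures=matures)
    ref.validate()
    return ref


def reference_isoforms(reference: MirnaReference, config: SimulationConfig) -> list[IsomirId]:
    """The isoforms the generator expresses: canonical plus 5'-shift variants."""
    shifts = _SHIFT_ORDER[: config.n_isoforms_per_mirna]
    return [IsomirId(m.name, s) for m in reference.matures for s in shifts]


def mirna_gene_id(hairpin_name: str) -> str:
    """Map a hairpin name to its miRNA gene id (``syn-mir-001`` -> ``SYNMIR001``)."""
    return hairpin_name.replace("syn-mir-", "SYNMIR").replace("-", "")


def _plant_isomir_effects(
    isoforms: list[IsomirId], config: SimulationConfig, rng: np.random.Generator
) -> dict[str, float]:
    if config.planted_isomir_effects is not None:
        return dict(config.planted_isomir_effects)
    n = min(config.n_active_isomirs, len(isoforms))
    # spread active isoforms over distinct miRNAs, alternating canonical/+1
    by_mirna: dict[str, list[IsomirId]] = {}
    for iso in isoforms:
        by_mirna.setdefault(iso.name, []).append(iso)
    mirna_names = sorted(by_mirna)
    chosen_mirnas = list(rng.choice(mirna_names, size=n, replace=False))
    effects: dict[str, float] = {}
    for k, mname in enumerate(chosen_mirnas):
        isos = by_mirna[mname]
        iso = isos[k % len(isos)]
        magnitude = float(rng.uniform(1.2, 2.0))
        sign = 1.0 if k % 2 == 0 else -1.0
        effects[iso.label] = sign * magnitude
    return effects


def _baseline_proportions(
    isoforms: list[IsomirId],
    effects: dict[str, float],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.Series:
    """Log-normal miRNA abundances, canonical-dominated isoform split.

    Active isomiRs are boosted into the abundant tier so that planted
    effects survive the mean-RPM and cumulative-share selection filters.
    """
    weights = {}
    mirna_w = {
        m: float(w)
        for m, w in zip(
            sorted({iso.name for iso in isoforms}),
            rng.lognormal(mean=0.0, sigma=1.5, size=len({iso.name for iso in isoforms})),
        )
    }
    active_mirnas = {IsomirId(*_split(label)).name for label in effects}
    hi = np.quantile(list(mirna_w.values()), 0.8)
    for m in active_mirnas:
        mirna_w[m] = max(mirna_w[m], hi) * 10.0
    iso_split = {0: 0.62, 1: 0.22, -1: 0.10, 2: 0.04, -2: 0.02}
    for iso in isoforms:
        weights[iso.label] = mirna_w[iso.name] * iso_split[iso.shift5]
    s = pd.Series(weights, dtype=float)
    return s / s.sum()


def _split(label: str) -> tuple[str, int]:
    name, _, shift = label.rpartition("|")
    return name, int(shift)


# --------------------------------------------------------------------------
# small-RNA reads
# --------------------------------------------------------------------------

@dataclass
class ReadSimulation:
    """Per-sample FASTQ records plus the realized per-isoform read tallies."""

    reads: dict[str, list[tuple[str, str]]]  # sample -> [(read_id, sequence)]
    tallies: pd.DataFrame                    # isoform label x sample, ints
    proportions: pd.DataFrame                # expected proportions per sample

    def write_fastq(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for sample, recs in self.reads.items():
            p = outdir / f"{sample}.fastq"
            with open(p, "w") as fh:
                for rid, seq in recs:
                    fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
            paths[sample] = p
        return paths


def make_read(isoform_seq: str, rng: np.random.Generator) -> str:
    """One sequencer read: isoform, then the 3' adapter, padded/truncated to 50 nt."""
    raw = isoform_seq + ADAPTER
    if len(raw) >= READ_LENGTH:
        return raw[:READ_LENGTH]
    return raw + _random_seq(rng, READ_LENGTH - len(raw))


def simulate_smallrna_reads(
    reference: MirnaReference,
    config: SimulationConfig,
    effects: dict[str, float] | None = None,
    baseline: pd.Series | None = None,
    rng_seed: int | None = None,
) -> ReadSimulation:
    """Multinomial small-RNA reads at the configured depth per sample.

    Group-2 isoform abundances are the baseline scaled by ``2**log2fc`` for
    planted isomiRs, renormalized.  Every read is its isoform sequence plus
    the adapter, padded to the read length; the realized multinomial tallies
    are returned so quantification can be checked exactly.
    """
    rng = _rng(config, stage=2, rng_seed=rng_seed)
    isoforms = reference_isoforms(reference, config)
    if effects is None:
        effects = _plant_isomir_effects(isoforms, config, _rng(config, stage=10, rng_seed=rng_seed))
    iso_by_label = {iso.label: iso for iso in isoforms}
    missing = [label for label in effects if label not in iso_by_label]
    if missing:
        raise ValueError(
            f"planted isomiRs not generatable from the reference: {missing}"
        )
    if baseline is None:
        baseline = _baseline_proportions(isoforms, effects, config, _rng(config, stage=11, rng_seed=rng_seed))
    seqs = {iso.label: reference.isoform_seq(iso) for iso in isoforms}

    g1, g2 = config.group_names
    prop2 = baseline.copy()
    for label, fc in effects.items():
        prop2[label] *= 2.0 ** fc
    prop2 /= prop2.sum()
    props = {g1: baseline / baseline.sum(), g2: prop2}

    labels = list(baseline.index)
    reads: dict[str, list[tuple[str, str]]] = {}
    tallies = pd.DataFrame(0, index=labels, columns=config.samples, dtype=int)
    prop_table = pd.DataFrame(index=labels, columns=config.samples, dtype=float)
    for sample, group in config.groups.items():
        p = props[group].reindex(labels).to_numpy()
        counts = rng.multinomial(config.depth_smallrna, p)
        tallies[sample] = counts
        prop_table[sample] = p
        recs = []
        i = 0
        for label, c in zip(labels, counts):
            for _ in range(int(c)):
                recs.append((f"{sample}:{i}", make_read(seqs[label], rng)))
                i += 1
        reads[sample] = recs
    return ReadSimulation(reads=reads, tallies=tallies, proportions=prop_table)


# --------------------------------------------------------------------------
# gene counts
# --------------------------------------------------------------------------

def nb_draws(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float, size=None
) -> np.ndarray:
    """NB draws parameterized by mean and dispersion (Var = mu + a*mu^2).

    A dispersion below 1e-12 falls back to the Poisson limit.
    """
    mean = np.asarray(mean, dtype=float)
    if np.any(mean <= 0):
        raise ValueError("NB means must be positive")
    if dispersion < 1e-12:
        return rng.poisson(mean, size=size)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


def simulate_gene_counts(
    config: SimulationConfig,
    gene_effects: dict[str, float] | None = None,
    gene_names: list[str] | None = None,
    rng_seed: int | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Genes x samples NB count matrix plus gene (transcript) lengths.

    Baseline means are log-normal; group-2 means are scaled by ``2**log2fc``
    for planted genes.  Lengths are uniform in [500, 5000] nt.
    """
    rng = _rng(config, stage=3, rng_seed=rng_seed)
    if gene_names is None:
        gene_names = [f"GENE{i+1:05d}" for i in range(config.n_genes)]
    if gene_effects is None:
        gene_effects = config.planted_gene_effects or {}
    mu0 = rng.lognormal(config.gene_log_mean, config.gene_log_sigma, size=len(gene_names))
    mu0 = np.maximum(mu0, 1.0)
    fc = np.array([gene_effects.get(g, 0.0) for g in gene_names])
    g1, g2 = config.group_names
    counts = pd.DataFrame(index=gene_names, columns=config.samples, dtype=int)
    for sample, group in config.groups.items():
        mu = mu0 * (2.0 ** fc) if group == g2 else mu0
        counts[sample] = nb_draws(rng, mu, config.nb_dispersion)
    lengths = pd.Series(
        rng.integers(500, 5001, size=len(gene_names)), index=gene_names, name="length"
    )
    return counts, lengths


# --------------------------------------------------------------------------
# UTRs and relation tables
# --------------------------------------------------------------------------

def _revcomp_dna(seq: str) -> str:
    return str(Seq(seq.replace("U", "T")).reverse_complement())


def _seed6(isoform_seq: str) -> str:
    return isoform_seq[1:7]  # positions 2-7 of the isoform, 1-based


@dataclass
class TableBundle:
    utrs: dict[str, str]
    validated: pd.DataFrame    # columns mirna, gene
    predicted: pd.DataFrame    # columns isomir, gene
    genesets: dict[str, list[str]]
    tf_gene: pd.DataFrame      # columns tf, gene, mode
    tf_mirna: pd.DataFrame     # columns tf, mirna_gene
    mature2gene: pd.DataFrame  # columns mature, mirna_gene, host_gene_note


def make_utrs_and_tables(
    reference: MirnaReference,
    config: SimulationConfig,
    effects: dict[str, float],
    targets: dict[str, list[str]],
    gene_names: list[str],
    gene_effects: dict[str, float],
    tf_truth: dict[str, dict[str, list[str]]],
    decoy_tf_plan: dict[str, dict] | None = None,
    rng_seed: int | None = None,
) -> TableBundle:
    """3'UTR FASTA plus all relational tables, consistent with the truth.

    Every planted target's UTR carries at least one exact seed site (the DNA
    reverse complement of the targeting isomiR's 6-mer seed); UTRs of
    non-target genes are rejection-sampled to contain no site of any active
    isomiR.  Tables hold exactly the planted relations plus Bernoulli decoy
    rows at ``config.decoy_rate``.
    """
    rng = _rng(config, stage=4, rng_seed=rng_seed)
    lo, hi = config.utr_len
    if hi < 20:
        raise ValueError("UTRs too short to host a seed site")

    active_sites = {
        label: _revcomp_dna(_seed6(reference.isoform_seq(IsomirId(*_split(label)))))
        for label in effects
    }
    site_list = list(active_sites.values())
    gene_to_iso = {g: label for label, genes in targets.items() for g in genes}

    utrs: dict[str, str] = {}
    for gene in gene_names:
        for _ in range(200):
            utr = _random_seq(rng, int(rng.integers(lo, hi + 1)))
            if gene in gene_to_iso:
                site = active_sites[gene_to_iso[gene]]
                pos = int(rng.integers(0, len(utr) - len(site) + 1))
                utr = utr[:pos] + site + utr[pos + len(site):]
                others = [s for lbl, s in active_sites.items() if lbl != gene_to_iso[gene]]
                if not any(s in utr for s in others):
                    break
            elif not any(s in utr for s in site_list):
                break
        else:
            raise RuntimeError(f"could not sample a site-consistent UTR for {gene}")
        utrs[gene] = utr

    # -- target tables ------------------------------------------------------
    inactive_matures = sorted(
        {m.name for m in reference.matures}
        - {_split(label)[0] for label in effects}
    )
    validated_rows, predicted_rows = [], []
    non_target_genes = [g for g in gene_names if g not in gene_to_iso]
    for label, genes in sorted(targets.items()):
        name, shift = _split(label)
        rows = validated_rows if shift == 0 else predicted_rows
        key = name if shift == 0 else label
        for g in genes:
            rows.append((key, g))
        n_decoy = int(rng.binomial(len(genes), config.decoy_rate))
        for g in rng.choice(non_target_genes, size=n_decoy, replace=False):
            rows.append((key, g))
    # background rows for inactive miRNAs, so the tables are not trivially sparse
    for name in inactive_matures:
        for g in rng.choice(gene_names, size=5, replace=False):
            validated_rows.append((name, g))
            predicted_rows.append((f"{name}|+1", g))
    validated = pd.DataFrame(sorted(set(validated_rows)), columns=["mirna", "gene"])
    predicted = pd.DataFrame(sorted(set(predicted_rows)), columns=["isomir", "gene"])

    # -- gene sets ----------------------------------------------------------
    genesets: dict[str, list[str]] = {}
    down_targets = sorted(
        g for g, iso in gene_to_iso.items() if gene_effects.get(g, 0.0) < 0
    )
    if down_targets:
        genesets["HALLMARK_PLANTED_REPRESSION"] = down_targets
    for i in range(config.n_gene_sets):
        size = int(rng.integers(20, 41))
        genesets[f"HALLMARK_SYN_{i+1:02d}"] = sorted(
            rng.choice(gene_names, size=size, replace=False)
        )

    # -- TF tables ----------------------------------------------------------
    tf_gene_rows, tf_mirna_rows = [], []
    for tf, d in sorted(tf_truth.items()):
        for g in d["genes"]:
            tf_gene_rows.append((tf, g, "Regulation"))
        for mg in d["mirna_genes"]:
            tf_mirna_rows.append((tf, mg))
    if decoy_tf_plan:
        for tf, d in sorted(decoy_tf_plan.items()):
            for g in d.get("genes", []):
                tf_gene_rows.append((tf, g, "Regulation"))
            for mg in d.get("mirna_genes", []):
                tf_mirna_rows.append((tf, mg))
    tf_gene = pd.DataFrame(sorted(set(tf_gene_rows)), columns=["tf", "gene", "mode"])
    tf_mirna = pd.DataFrame(sorted(set(tf_mirna_rows)), columns=["tf", "mirna_gene"])

    mature2gene = pd.DataFrame(
        [
            (m.name, mirna_gene_id(m.hairpin), "")
            for m in reference.matures
        ],
        columns=["mature", "mirna_gene", "host_gene_note"],
    )
    return TableBundle(
        utrs=utrs,
        validated=validated,
        predicted=predicted,
        genesets=genesets,
        tf_gene=tf_gene,
        tf_mirna=tf_mirna,
        mature2gene=mature2gene,
    )


# --------------------------------------------------------------------------
# full bundle
# --------------------------------------------------------------------------

@dataclass
class SyntheticBundle:
    config: SimulationConfig
    reference: MirnaReference
    truth: Truth
    read_sim: ReadSimulation
    gene_counts: pd.DataFrame
    gene_lengths: pd.Series
    tables: TableBundle
    tf_gene_names: list[str] = field(default_factory=list)

    @property
    def groups(self) -> pd.Series:
        return self.config.groups

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write every pipeline input to ``outdir``; returns a path manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        fastq_dir = outdir / "reads"
        self.read_sim.write_fastq(fastq_dir)
        paths["reads_dir"] = fastq_dir
        self.reference.write(outdir / "hairpins.fasta", outdir / "matures.tsv")
        paths["hairpin_fasta"] = outdir / "hairpins.fasta"
        paths["mature_tsv"] = outdir / "matures.tsv"
        self.gene_counts.rename_axis("gene").to_csv(outdir / "gene_counts.tsv", sep="\t")
        self.gene_lengths.rename_axis("gene").to_csv(outdir / "gene_lengths.tsv", sep="\t")
        self.groups.rename_axis("sample").to_csv(outdir / "groups.tsv", sep="\t")
        with open(outdir / "utrs.fasta", "w") as fh:
            for gene, seq in sorted(self.tables.utrs.items()):
                fh.write(f">{gene}\n{seq}\n")
        self.tables.validated.to_csv(outdir / "validated_targets.tsv", sep="\t", index=False)
        self.tables.predicted.to_csv(outdir / "predicted_targets.tsv", sep="\t", index=False)
        with open(outdir / "genesets.gmt", "w") as fh:
            for name, members in self.tables.genesets.items():
                fh.write("\t".join([name, "synthetic"] + list(members)) + "\n")
        self.tables.tf_gene.to_csv(outdir / "tf_gene.tsv", sep="\t", index=False)
        self.tables.tf_mirna.to_csv(outdir / "tf_mirna.tsv", sep="\t", index=False)
        self.tables.mature2gene.to_csv(outdir / "mature2gene.tsv", sep="\t", index=False)
        self.truth.to_json(outdir / "truth.json")
        self.read_sim.tallies.rename_axis("isomir").to_csv(outdir / "true_tallies.tsv", sep="\t")
        for key, fname in [
            ("gene_counts", "gene_counts.tsv"), ("gene_lengths", "gene_lengths.tsv"),
            ("groups", "groups.tsv"), ("utr_fasta", "utrs.fasta"),
            ("validated_tsv", "validated_targets.tsv"), ("predicted_tsv", "predicted_targets.tsv"),
            ("gmt", "genesets.gmt"), ("tf_gene_tsv", "tf_gene.tsv"),
            ("tf_mirna_tsv", "tf_mirna.tsv"), ("mature2gene_tsv", "mature2gene.tsv"),
            ("truth_json", "truth.json"),
        ]:
            paths[key] = outdir / fname
        return paths


def generate(config: SimulationConfig | None = None, rng_seed: int | None = None) -> SyntheticBundle:
    """Generate the complete synthetic study.

    Planted structure: ``n_active_isomirs`` isomiRs get log2 effects
    alternating in sign; each active isomiR gets a disjoint block of
    ``target_fraction * n_genes`` target genes whose planted fold change is
    opposite in sign to the isomiR's (repression logic); a further
    ``background_de_fraction`` of genes are differentially expressed without
    being targets.  Planted TFs regulate blocks of strongly-changed genes,
    are differentially expressed themselves, and carry edges to the active
    miRNA genes; decoy TFs break exactly one of those three requirements.
    """
    config = config or SimulationConfig()
    config.validate()
    seed = config.rng_seed if rng_seed is None else rng_seed

    reference = make_reference(config, rng_seed=seed)
    isoforms = reference_isoforms(reference, config)
    effects = _plant_isomir_effects(isoforms, config, _rng(config, 10, seed))
    baseline = _baseline_proportions(isoforms, effects, config, _rng(config, 11, seed))
    read_sim = simulate_smallrna_reads(reference, config, effects, baseline, rng_seed=seed)

    rng = _rng(config, stage=5, rng_seed=seed)
    gene_names = [f"GENE{i+1:05d}" for i in range(config.n_genes)]
    n_tfs = config.n_planted_tfs + config.n_decoy_tfs
    tf_names = [f"TF{i+1:02d}" for i in range(n_tfs)]
    all_genes = gene_names + tf_names

    # targets: disjoint blocks of ordinary genes per active isomiR
    n_targets_each = max(1, int(round(config.target_fraction * config.n_genes)))
    shuffled = list(rng.permutation(gene_names))
    targets: dict[str, list[str]] = {}
    gene_effects: dict[str, float] = dict(config.planted_gene_effects or {})
    cursor = 0
    for label in sorted(effects):
        block = sorted(shuffled[cursor : cursor + n_targets_each])
        cursor += n_targets_each
        targets[label] = block
        sign = -1.0 if effects[label] > 0 else 1.0
        for g in block:
            gene_effects.setdefault(g, sign * float(rng.uniform(1.0, 2.0)))
    # background DE genes (non-targets)
    n_bg = int(round(config.background_de_fraction * config.n_genes))
    bg = shuffled[cursor : cursor + n_bg]
    for k, g in enumerate(bg):
        gene_effects.setdefault(g, (1.0 if k % 2 == 0 else -1.0) * float(rng.uniform(1.0, 2.5)))

    # TF truth: planted TFs regulate strongly-changed genes, are DE, and
    # carry miRNA edges; each decoy class breaks one funnel stage
    de_pool = sorted(gene_effects, key=lambda g: -abs(gene_effects[g]))
    active_mirna_genes = sorted(
        {mirna_gene_id(reference.mature(_split(label)[0]).hairpin) for label in effects}
    )
    tf_truth: dict[str, dict[str, list[str]]] = {}
    decoy_plan: dict[str, dict] = {}
    regulon_size = min(config.tf_regulon_size, max(1, len(de_pool) // 2))
    for i, tf in enumerate(tf_names):
        pool = de_pool[: max(200, 3 * regulon_size)]
        regulon = sorted(rng.choice(pool, size=regulon_size, replace=False))
        if i < config.n_planted_tfs:
            gene_effects[tf] = float(rng.choice([-1.0, 1.0])) * float(rng.uniform(1.5, 2.5))
            tf_truth[tf] = {"genes": regulon, "mirna_genes": active_mirna_genes}
        else:
            kind = i % 3
            if kind == 0:   # enriched regulon, but the TF itself is not DE
                decoy_plan[tf] = {"genes": regulon, "mirna_genes": active_mirna_genes}
            elif kind == 1: # DE, enriched regulon, but no miRNA edge
                gene_effects[tf] = float(rng.uniform(1.5, 2.5))
                decoy_plan[tf] = {"genes": regulon, "mirna_genes": []}
            else:           # random regulon: never enriched in the top lists
                decoy_plan[tf] = {
                    "genes": sorted(rng.choice(gene_names, size=regulon_size,
                                               replace=False)),
                    "mirna_genes": active_mirna_genes,
                }

    counts, lengths = simulate_gene_counts(
        config, gene_effects=gene_effects, gene_names=all_genes, rng_seed=seed
    )
    tables = make_utrs_and_tables(
        reference, config, effects, targets, all_genes, gene_effects,
        tf_truth, decoy_plan, rng_seed=seed,
    )
    truth = Truth(
        true_isomir_fc=dict(sorted(effects.items())),
        true_gene_fc=dict(sorted(gene_effects.items())),
        true_targets={k: list(v) for k, v in sorted(targets.items())},
        true_tf_regulators=tf_truth,
        baseline_proportions=baseline.to_dict(),
    )
    return SyntheticBundle(
        config=config,
        reference=reference,
        truth=truth,
        read_sim=read_sim,
        gene_counts=counts,
        gene_lengths=lengths,
        tables=tables,
        tf_gene_names=tf_names,
    )
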