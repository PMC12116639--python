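"""Seed derivation for 5'-shifted isoforms, 3'UTR site scanning and target-set
assembly.

The seed of a miRNA is nucleotides 2-7 (6mer) or 2-8 (7mer-m8) counted from
the 5' end.  Crucially these positions are taken on the *isoform* sequence:
a +1 5'-shift drops the first nucleotide, so the shifted isoform's 6mer seed
equals positions 3-8 of the canonical mature, and its target repertoire
changes accordingly.  A seed site on an mRNA 3'UTR is the DNA reverse
complement of the seed on the sense strand (7mer-A1: the 6mer site followed
by an A).

Target sets combine two provenances: validated interactions (database rows,
used as-is for canonical isoforms) and predicted interactions for shifted
isoforms, which are additionally required to carry at least one seed site in
the gene's 3'UTR — the seed-presence filter that removes spurious predicted
rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio.Seq import Seq

from .reference import IsomirId, MirnaReference

__all__ = [
    "isoform_sequence",
    "seed_of",
    "site_patterns",
    "scan_utr",
    "TargetSet",
    "build_target_sets",
]

_SEED_KINDS = {"6mer": (1, 7), "7mer-m8": (1, 8)}


def isoform_sequence(
    mature_seq: str,
    shift5: int,
    hairpin_seq: str | None = None,
    mature_start: int | None = None,
) -> str:
    """Apply a 5' shift to a mature sequence.

    ``shift5 = +k`` drops the k leading nucleotides; ``shift5 = -k``
    prepends the k hairpin nucleotides upstream of the mature start, which
    requires hairpin context.
    """
    if shift5 == 0:
        return mature_seq
    if shift5 > 0:
        if shift5 >= len(mature_seq):
            raise ValueError("shift removes the entire mature sequence")
        return mature_seq[shift5:]
    if hairpin_seq is None or mature_start is None:
        raise ValueError("5' extension requires hairpin context")
    k = -shift5
    if mature_start - k < 0:
        raise ValueError("5' extension runs past the hairpin start")
    return hairpin_seq[mature_start - k : mature_start] + mature_seq


def seed_of(isoform_seq: str, kind: str = "6mer") -> str:
    """Seed of an isoform: positions 2-7 (6mer) or 2-8 (7mer-m8), 1-based.

    Returned in the RNA alphabet regardless of the input alphabet.
    """
    try:
        start, end = _SEED_KINDS[kind]
    except KeyError:
        raise ValueError(f"unknown seed kind {kind!r}") from None
    if len(isoform_seq) < 8:
        raise ValueError("isoform too short to have a seed")
    return isoform_seq[start:end].upper().replace("T", "U")


def site_patterns(seed: str, with_a1: bool = False) -> list[str]:
    """UTR sense-strand site strings for a seed: its DNA reverse complement.

    With ``with_a1`` a 7mer-A1 variant (6mer site followed by A) is added.
    """
    seed = seed.upper()
    if any(ch not in "ACGU" for ch in seed.replace("T", "U")):
        raise ValueError(f"non-ACGU symbol in seed {seed!r}")
    site = str(Seq(seed.replace("U", "T")).reverse_complement())
    patterns = [site]
    if with_a1:
        patterns.append(site + "A")
    return patterns


def scan_utr(utr_seq: str, site_strings: list[str]) -> int:
    """Total count of (overlapping) site occurrences in a sense-strand UTR."""
    utr = utr_seq.upper().replace("U", "T")
    total = 0
    for site in site_strings:
        pos = utr.find(site)
        while pos != -1:
            total += 1
            pos = utr.find(site, pos + 1)
    return total


@dataclass
class TargetSet:
    """Genes assigned to one isomiR, with provenance."""

    isomir: str
    genes: frozenset[str]
    provenance: str  # "validated" | "predicted+seed"


def _column(table: pd.DataFrame, candidates: tuple[str, ...]) -> str:
    for c in candidates:
        if c in table.columns:
            return c
    raise KeyError(f"none of {candidates} found in columns {list(table.columns)}")


def build_target_sets(
    validated_table: pd.DataFrame,
    predicted_table: pd.DataFrame,
    utrs: dict[str, str],
    isomirs: dict[str, str],
    universe: set[str],
    reference: MirnaReference | None = None,
    seed_kind: str = "6mer",
    with_a1: bool = False,
) -> dict[str, TargetSet]:
    """Assemble the per-isomiR target set within a gene universe.

    ``isomirs`` maps isomiR labels to their isoform sequences.  Canonical
    isoforms (``|0``) take validated rows (keyed by mature name) intersected
    with the universe — validated interactions are not seed-filtered.
    Shifted isoforms take predicted rows (keyed by full label) intersected
    with the universe *and* with genes whose UTR carries >= 1 site for the
    re-derived shifted seed.  IsomiRs without table entries get empty sets.
    """
    vcol_m = _column(validated_table, ("mirna", "mirna_label", "mature"))
    vcol_g = _column(validated_table, ("gene", "gene_id"))
    pcol_m = _column(predicted_table, ("isomir", "mirna_label", "mirna"))
    pcol_g = _column(predicted_table, ("gene", "gene_id"))
    validated = validated_table.groupby(vcol_m)[vcol_g].agg(set).to_dict()
    predicted = predicted_table.groupby(pcol_m)[pcol_g].agg(set).to_dict()

    out: dict[str, TargetSet] = {}
    for label, iso_seq in isomirs.items():
        iso = _parse(label)
        if iso.canonical:
            genes = validated.get(iso.name, set()) & universe
            out[label] = TargetSet(label, frozenset(genes), "validated")
        else:
            candidates = predicted.get(label, set()) & universe
            sites = site_patterns(seed_of(iso_seq, seed_kind), with_a1=with_a1)
            genes = {
                g for g in candidates if g in utrs and scan_utr(utrs[g], sites) >= 1
            }
            out[label] = TargetSet(label, frozenset(genes), "predicted+seed")
    return out


def _parse(label: str) -> IsomirId:
    name, _, shift = label.rpartition("|")
    return IsomirId(name, int(shift)) if name else IsomirId(label, 0)


def isoform_sequences_from_reference(
    reference: MirnaReference, labels: list[str]
) -> dict[str, str]:
    """Isoform sequences (DNA alphabet) for a list of isomiR labels."""
    out = {}
    for label in labels:
        iso = _parse(label)
        m = reference.mature(iso.name)
        out[label] = isoform_sequence(
            reference.mature_seq(iso.name),
            iso.shift5,
            hairpin_seq=reference.hairpins[m.hairpin],
            mature_start=m.start,
        )
    return out
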