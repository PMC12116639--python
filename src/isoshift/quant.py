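"""Adapter trimming and exact-lookup isomiR quantification.

Small-RNA reads are trimmed of their 3' adapter, then matched exactly
against a lookup table of every hairpin substring reachable by moving the
canonical mature 5' end by up to ``window5`` nt and the 3' end by up to
``window3`` nt.  Counts are keyed by the ``name|<signed 5' shift>`` label
convention: the number after the ``|`` is the shift of the 5' end in the
5'->3' direction, so ``mir-X|+1`` is shortened by one nt at the 5' end and
``mir-X|0`` is the canonical isoform.  3'-shift variants are collapsed into
those labels; the detailed (shift5, shift3) resolution is kept in an
auxiliary table.

Matching is exact: no mismatches and no non-templated additions.  A trimmed
read matching k distinct reference loci contributes weight 1/k to each, so
mapped weight plus unmapped reads always equals the total read count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .reference import IsomirId, MirnaReference
from .simulate import ADAPTER

__all__ = [
    "trim_adapter",
    "TrimStats",
    "trim_reads",
    "build_lookup",
    "LookupIndex",
    "quantify",
    "QuantResult",
    "read_fastq_seqs",
]

MIN_TRIMMED_LENGTH = 16


def trim_adapter(read_seq: str, adapter_seq: str = ADAPTER, min_overlap: int = 3) -> str | None:
    """Remove the 3' adapter from one read.

    Returns the prefix of the read before the leftmost adapter evidence:
    either a full occurrence of the adapter, or a prefix of the adapter of
    length >= ``min_overlap`` anchored at the read's end.  Reads with no
    adapter evidence are returned whole; trimmed sequences shorter than
    16 nt are rejected (``None``).
    """
    if not read_seq:
        raise ValueError("empty read")
    if not adapter_seq:
        raise ValueError("empty adapter")
    if min_overlap < 3:
        raise ValueError("min_overlap must be >= 3")
    n, alen = len(read_seq), len(adapter_seq)
    cut = n
    for i in range(n):
        tail = read_seq[i:]
        if len(tail) >= alen:
            if tail.startswith(adapter_seq):
                cut = i
                break
        elif len(tail) >= min_overlap and adapter_seq.startswith(tail):
            cut = i
            break
    trimmed = read_seq[:cut]
    if cut < n and len(trimmed) < MIN_TRIMMED_LENGTH:
        return None
    if cut == n and len(trimmed) < MIN_TRIMMED_LENGTH:
        return None
    return trimmed


@dataclass
class TrimStats:
    total: int = 0
    kept: int = 0
    too_short: int = 0


def trim_reads(
    seqs: list[str], adapter_seq: str = ADAPTER, min_overlap: int = 3
) -> tuple[list[str], TrimStats]:
    """Trim a batch of reads; U is normalized to T before matching."""
    stats = TrimStats()
    out: list[str] = []
    for s in seqs:
        stats.total += 1
        t = trim_adapter(s.upper().replace("U", "T"), adapter_seq, min_overlap)
        if t is None:
            stats.too_short += 1
        else:
            stats.kept += 1
            out.append(t)
    return out, stats


@dataclass
class LookupIndex:
    """Exact sequence -> isomiR identity map over all shift-window substrings."""

    table: dict[str, tuple[IsomirId, ...]]
    window5: int
    window3: int
    clipped: list[str] = field(default_factory=list)  # isoform labels whose window left the hairpin

    def lookup(self, seq: str) -> tuple[IsomirId, ...]:
        return self.table.get(seq, ())


def build_lookup(reference: MirnaReference, window5: int = 3, window3: int = 5) -> LookupIndex:
    """Index every hairpin substring reachable within the shift windows.

    A substring arising from several matures (or several loci) maps to all
    of its IsomirIds.  Windows that would leave the hairpin are silently
    clipped and recorded in ``clipped``.
    """
    if window5 < 0 or window3 < 0:
        raise ValueError("windows must be >= 0")
    table: dict[str, list[IsomirId]] = {}
    clipped: list[str] = []
    for m in reference.matures:
        hp = reference.hairpins[m.hairpin]
        for s5 in range(-window5, window5 + 1):
            for s3 in range(-window3, window3 + 1):
                start, end = m.start + s5, m.end + s3
                iso = IsomirId(m.name, s5, s3)
                if start < 0 or end > len(hp) or end - start < MIN_TRIMMED_LENGTH:
                    clipped.append(f"{iso.label};{s3:+d}")
                    continue
                table.setdefault(hp[start:end], []).append(iso)
    return LookupIndex(
        table={k: tuple(sorted(v)) for k, v in table.items()},
        window5=window5,
        window3=window3,
        clipped=clipped,
    )


@dataclass
class QuantResult:
    """IsomiR count matrix plus the detailed shift3-resolved table."""

    counts: pd.DataFrame        # label (name|shift5) x sample, fractional weights
    detailed: pd.DataFrame      # columns: mature, shift5, shift3, sample, weight, sequence
    unmapped: pd.Series         # per-sample unmapped read counts
    total_reads: pd.Series      # per-sample trimmed read counts

    def conservation_ok(self, atol: float = 1e-9) -> bool:
        return bool(
            ((self.counts.sum(axis=0) + self.unmapped - self.total_reads).abs() < atol).all()
        )


def quantify(trimmed_by_sample: dict[str, list[str]], index: LookupIndex) -> QuantResult:
    """Count isomiRs per sample by exact lookup.

    Each read's unit weight is split 1/k over its k matching loci; counts
    are aggregated into ``name|shift5`` rows (3'-shift variants collapsed),
    with the full resolution kept in ``detailed``.  Unmapped reads are
    tallied, never dropped silently, so column sums conserve read counts.
    """
    rows: dict[str, dict[str, float]] = {}
    detail: dict[tuple[str, int, int, str], tuple[float, str]] = {}
    unmapped: dict[str, int] = {}
    totals: dict[str, int] = {}
    for sample, seqs in trimmed_by_sample.items():
        unmapped[sample] = 0
        totals[sample] = len(seqs)
        for seq in seqs:
            hits = index.lookup(seq)
            if not hits:
                unmapped[sample] += 1
                continue
            w = 1.0 / len(hits)
            for iso in hits:
                rows.setdefault(iso.label, {})[sample] = (
                    rows.setdefault(iso.label, {}).get(sample, 0.0) + w
                )
                key = (iso.name, iso.shift5, iso.shift3, sample)
                prev = detail.get(key, (0.0, seq))[0]
                detail[key] = (prev + w, seq)
    samples = list(trimmed_by_sample)
    counts = (
        pd.DataFrame(rows).T.reindex(columns=samples).fillna(0.0).sort_index()
        if rows
        else pd.DataFrame(columns=samples, dtype=float)
    )
    detailed = pd.DataFrame(
        [
            {
                "mature": name,
                "shift5": s5,
                "shift3": s3,
                "sample": sample,
                "weight": w,
                "sequence": seq.replace("T", "U"),
            }
            for (name, s5, s3, sample), (w, seq) in sorted(detail.items())
        ]
    )
    return QuantResult(
        counts=counts,
        detailed=detailed,
        unmapped=pd.Series(unmapped).reindex(samples).fillna(0).astype(int),
        total_reads=pd.Series(totals).reindex(samples).astype(int),
    )


def read_fastq_seqs(path: str | Path) -> list[str]:
    """Sequences of a (plain-text) FASTQ file, in file order."""
    return [str(rec.seq) for rec in SeqIO.parse(str(path), "fastq")]
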