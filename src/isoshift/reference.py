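"""miRNA reference model: hairpin precursors and mature sequences with coordinates.

A reference is a set of hairpin (precursor) sequences plus, for each mature
miRNA, the half-open interval ``[start, end)`` on its hairpin where the
canonical mature sequence sits.  5'-shifted isoforms are substrings of the
hairpin obtained by moving those interval ends, so the hairpin context is what
makes negative (5'-extended) shifts well defined.

Sequences are stored in the DNA alphabet (ACGT); conversion to the RNA
alphabet for display is the caller's concern.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = ["Mature", "MirnaReference", "IsomirId", "parse_isomir_label"]


@dataclass(frozen=True)
class Mature:
    """Canonical mature miRNA: name plus location on its hairpin."""

    name: str
    hairpin: str
    start: int
    end: int  # half-open


@dataclass(frozen=True, order=True)
class IsomirId:
    """A mature miRNA name with signed 5' and 3' end shifts.

    ``shift5 = +k`` means the 5' end moved k nt in the 5'->3' direction
    (isoform shortened at the 5' end); negative means 5'-extended.
    ``shift3 = +k`` means extended at the 3' end.  The canonical isoform is
    ``shift5 == shift3 == 0``.  Row labels collapse shift3 and render as
    ``name|+1`` / ``name|0`` / ``name|-1``.
    """

    name: str
    shift5: int
    shift3: int = 0

    @property
    def label(self) -> str:
        return f"{self.name}|{self.shift5:+d}" if self.shift5 else f"{self.name}|0"

    @property
    def canonical(self) -> bool:
        return self.shift5 == 0


def parse_isomir_label(label: str) -> IsomirId:
    """Parse ``name|+1`` style labels; a bare mature name means canonical."""
    if "|" not in label:
        return IsomirId(label, 0)
    name, _, shift = label.rpartition("|")
    return IsomirId(name, int(shift))


@dataclass
class MirnaReference:
    """Hairpin sequences plus mature coordinates.

    Invariant: ``hairpins[m.hairpin][m.start:m.end]`` is the mature sequence
    of every ``m`` in ``matures``; checked by :meth:`validate`.
    """

    hairpins: dict[str, str]
    matures: list[Mature] = field(default_factory=list)

    def validate(self) -> None:
        names = [m.name for m in self.matures]
        if len(set(names)) != len(names):
            raise ValueError("mature names are not unique")
        for m in self.matures:
            hp = self.hairpins.get(m.hairpin)
            if hp is None:
                raise ValueError(f"mature {m.name} refers to unknown hairpin {m.hairpin}")
            if not (0 <= m.start < m.end <= len(hp)):
                raise ValueError(f"mature {m.name} coordinates outside hairpin")

    def mature_seq(self, name: str) -> str:
        m = self.mature(name)
        return self.hairpins[m.hairpin][m.start : m.end]

    def mature(self, name: str) -> Mature:
        for m in self.matures:
            if m.name == name:
                return m
        raise KeyError(name)

    def isoform_seq(self, iso: IsomirId) -> str:
        """Hairpin substring for an isoform; raises if the shift window
        leaves the hairpin."""
        m = self.mature(iso.name)
        hp = self.hairpins[m.hairpin]
        start = m.start + iso.shift5
        end = m.end + iso.shift3
        if not (0 <= start < end <= len(hp)):
            raise ValueError(f"isoform {iso.label} window outside hairpin {m.hairpin}")
        return hp[start:end]

    # ------------------------------------------------------------------ I/O
    def write(self, hairpin_fasta: str | Path, mature_tsv: str | Path) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in sorted(self.hairpins.items())
        ]
        SeqIO.write(records, str(hairpin_fasta), "fasta")
        rows = [
            {"mature": m.name, "hairpin": m.hairpin, "start": m.start, "end": m.end}
            for m in self.matures
        ]
        pd.DataFrame(rows).to_csv(mature_tsv, sep="\t", index=False)

    @classmethod
    def read(cls, hairpin_fasta: str | Path, mature_tsv: str | Path) -> "MirnaReference":
        hairpins = {
            rec.id: str(rec.seq).upper().replace("U", "T")
            for rec in SeqIO.parse(str(hairpin_fasta), "fasta")
        }
        tab = pd.read_csv(mature_tsv, sep="\t")
        matures = [
            Mature(r["mature"], r["hairpin"], int(r["start"]), int(r["end"]))
            for _, r in tab.iterrows()
        ]
        ref = cls(hairpins=hairpins, matures=matures)
        ref.validate()
        return ref
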