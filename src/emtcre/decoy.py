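"""Dumbbell decoy oligodeoxynucleotide (ODN) design and verification.

A dumbbell decoy is a pair of partially complementary oligos carrying two
copies of a cis-regulatory element (CRE); after annealing, hairpin arms at
both ends are ligated into a closed, nuclease-resistant structure that
titrates the transcription factors recognizing the element.  Construction
is purely sequence-level here:

    odn1 = core x n_repeats + arm1
    odn2 = revcomp(core x n_repeats) + arm2

so the repeat regions of the two strands are reverse complements by
construction and form the double-stranded CRE-bearing stem.

Verification utilities recover the repeat unit of an oligo
(:func:`detect_tandem_repeat`, 5'-anchored maximal unit) and report the
longest reverse-complementary block between a pair
(:func:`verify_duplex`).  Five published decoy pairs (Evi-1, FTS-1, SRY,
GC-Box and a scrambled control) ship as a reference fixture; two of them
carry spaced rather than exact-tandem repeats, for which duplex
verification plus substring search of the declared core is the appropriate
check.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from emtcre.errors import DataError
from emtcre.promoters import revcomp

__all__ = [
    "DumbbellDecoy",
    "DuplexReport",
    "build_decoy",
    "detect_tandem_repeat",
    "verify_duplex",
    "load_printed_decoys",
    "DEFAULT_ARM1",
    "DEFAULT_ARM2",
]

# hairpin-loop ligation arms shared by the published decoy pairs
DEFAULT_ARM1 = "cttggtttttccaag"
DEFAULT_ARM2 = "ccgtctttttgacgg"


def _check_dna(seq: str, what: str, allow_empty: bool = False) -> str:
    seq = seq.strip().lower()
    if not seq and not allow_empty:
        raise DataError(f"{what} must be nonempty DNA")
    if set(seq) - set("acgt"):
        raise DataError(f"{what} contains non-ACGT characters: {seq!r}")
    return seq


@dataclass
class DumbbellDecoy:
    """A designed decoy pair; sequences stored lowercase 5'->3'."""

    name: str
    core: str
    n_repeats: int
    arm1: str
    arm2: str
    odn1: str
    odn2: str

    @property
    def repeat_region(self) -> str:
        return self.core * self.n_repeats

    def to_fasta_records(self) -> list[tuple[str, str]]:
        return [(f"{self.name}_ODN1", self.odn1),
                (f"{self.name}_ODN2", self.odn2)]


def build_decoy(core: str, arm1: str = DEFAULT_ARM1, arm2: str = DEFAULT_ARM2,
                n_repeats: int = 2, name: str = "decoy") -> DumbbellDecoy:
    """Construct a tandem-repeat dumbbell decoy pair from a CRE core."""
    core = _check_dna(core, "core")
    arm1 = _check_dna(arm1, "arm1", allow_empty=True)
    arm2 = _check_dna(arm2, "arm2", allow_empty=True)
    if n_repeats < 1:
        raise DataError("n_repeats must be >= 1")
    repeat = core * n_repeats
    return DumbbellDecoy(
        name=name, core=core, n_repeats=n_repeats, arm1=arm1, arm2=arm2,
        odn1=repeat + arm1, odn2=revcomp(repeat).lower() + arm2)


def detect_tandem_repeat(seq: str) -> tuple[str, int, int]:
    """Maximal 5'-anchored tandem repeat of a sequence.

    Returns ``(unit, count, start)`` where ``unit`` is the longest prefix
    whose exact tandem repetition anchored at the 5' end occurs at least
    twice (ties between unit lengths resolve to the longest unit; start is
    always 0 by the anchoring).  If no unit repeats, ``(seq, 1, 0)``.
    """
    seq = _check_dna(seq, "sequence")
    n = len(seq)
    for u in range(n // 2, 0, -1):
        unit = seq[:u]
        count = 1
        while seq[count * u:(count + 1) * u] == unit:
            count += 1
        if count >= 2:
            return unit, count, 0
    return seq, 1, 0


@dataclass
class DuplexReport:
    """Longest reverse-complementary block between two oligos."""

    block: str
    length: int
    start1: int  # 0-based start of the block in odn1
    start2: int  # 0-based start of the complementary block in odn2
    min_block: int

    @property
    def passed(self) -> bool:
        return self.length >= self.min_block


def verify_duplex(odn1: str, odn2: str, min_block: int = 15) -> DuplexReport:
    """Longest block of odn1 whose reverse complement occurs in odn2.

    Classic longest-common-substring dynamic programming between ``odn1``
    and ``revcomp(odn2)``; coordinates are reported on both input oligos.
    """
    s1 = _check_dna(odn1, "odn1")
    s2rc = revcomp(_check_dna(odn2, "odn2")).lower()
    n, m = len(s1), len(s2rc)
    best_len, best_i, best_j = 0, 0, 0
    prev = [0] * (m + 1)
    for i in range(1, n + 1):
        cur = [0] * (m + 1)
        ci = s1[i - 1]
        for j in range(1, m + 1):
            if ci == s2rc[j - 1]:
                cur[j] = prev[j - 1] + 1
                if cur[j] > best_len:
                    best_len, best_i, best_j = cur[j], i, j
        prev = cur
    block = s1[best_i - best_len:best_i]
    # position of the complementary block on odn2 itself
    start2 = m - best_j if best_len else 0
    return DuplexReport(block=block, length=best_len,
                        start1=best_i - best_len, start2=start2,
                        min_block=min_block)


def load_printed_decoys(path: str | Path | None = None) -> pd.DataFrame:
    """The five published decoy pairs (name, declared core, odn1, odn2)."""
    if path is None:
        from emtcre.data import PRINTED_DECOYS as path
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("core", "odn1", "odn2"):
        df[col] = df[col].str.lower()
    return df


def write_decoys_fasta(decoys: list[DumbbellDecoy], path: str | Path) -> None:
    with open(path, "w") as fh:
        for d in decoys:
            for name, seq in d.to_fasta_records():
                fh.write(f">{name}\n{seq}\n")
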