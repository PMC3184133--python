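"""Strand-aware TSS-anchored promoter windows.

The promoter of a gene is the window from 1500 bp upstream to 500 bp
downstream of its annotated transcription start site (positions −1500 to
+499 in transcription orientation, 2000 bp total, half-open on the
downstream side).  For minus-strand genes the mirrored window is taken on
the reference and reverse-complemented, so that in-window position 0 is
always −1500 and the base at in-window offset ``up`` is the TSS base.
Windows overhanging a contig end are truncated (never padded) and flagged.

Coordinates are 0-based half-open internally; BED input is used as is and
GFF3 (1-based inclusive) is converted on read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from emtcre.errors import ConfigurationError, DataError, ParseError

__all__ = [
    "PromoterRecord",
    "PromoterSet",
    "extract_promoters",
    "read_tss_annotation",
    "revcomp",
]

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class PromoterRecord:
    """One promoter window in transcription orientation."""

    gene_id: str
    sequence: str
    strand: str = "+"
    contig: str | None = None
    tss: int | None = None  # 0-based genomic coordinate of the TSS base
    #: index of the TSS base inside ``sequence`` (``up`` when unclipped)
    tss_index: int = 1500
    clipped: bool = False
    group: str | None = None

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        if set(self.sequence) - set("ACGTN"):
            raise DataError(
                f"{self.gene_id}: promoter sequence contains characters "
                "outside A/C/G/T/N")

    def __len__(self) -> int:
        return len(self.sequence)


class PromoterSet:
    """Ordered collection of promoter records with FASTA round-trip."""

    def __init__(self, records: list[PromoterRecord]):
        self.records = list(records)
        seen: set[str] = set()
        for r in self.records:
            if r.gene_id in seen:
                raise DataError(f"duplicate promoter record for {r.gene_id}")
            seen.add(r.gene_id)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, gene_id: str) -> PromoterRecord:
        for r in self.records:
            if r.gene_id == gene_id:
                return r
        raise KeyError(gene_id)

    @property
    def gene_ids(self) -> list[str]:
        return [r.gene_id for r in self.records]

    def subset(self, gene_ids) -> "PromoterSet":
        wanted = set(gene_ids)
        return PromoterSet([r for r in self.records if r.gene_id in wanted])

    # -- serialization -----------------------------------------------------

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for r in self.records:
                group = r.group or "."
                fh.write(f">{r.gene_id}|{group}|{r.strand}\n")
                for i in range(0, len(r.sequence), 70):
                    fh.write(r.sequence[i:i + 70] + "\n")

    @classmethod
    def from_fasta(cls, path: str | Path, tss_index: int = 1500
                   ) -> "PromoterSet":
        from Bio import SeqIO

        records = []
        for rec in SeqIO.parse(str(path), "fasta"):
            fields = rec.id.split("|")
            gene = fields[0]
            group = fields[1] if len(fields) > 1 and fields[1] != "." else None
            strand = fields[2] if len(fields) > 2 else "+"
            records.append(PromoterRecord(
                gene_id=gene, sequence=str(rec.seq), strand=strand,
                group=group, tss_index=min(tss_index, len(rec.seq) - 1)))
        return cls(records)

    def manifest(self) -> pd.DataFrame:
        rows = [{
            "gene_id": r.gene_id, "contig": r.contig, "strand": r.strand,
            "tss": r.tss, "length": len(r), "tss_index": r.tss_index,
            "clipped": r.clipped, "group": r.group,
        } for r in self.records]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# annotation parsing


def _gff_attr(attrs: str, keys=("gene_id", "ID", "Name")) -> str | None:
    for part in attrs.strip().strip(";").split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" in part:
            k, v = part.split("=", 1)
        elif " " in part:
            k, v = part.split(None, 1)
        else:
            continue
        if k.strip() in keys:
            return v.strip().strip('"')
    return None


def read_tss_annotation(path: str | Path) -> pd.DataFrame:
    """Read TSS annotations from BED6 or GFF3.

    Returns a frame with columns gene_id / contig / tss / strand where
    ``tss`` is the 0-based coordinate of the TSS base.  For BED, single-base
    intervals denote the TSS itself; longer intervals are taken as the gene
    span (TSS = start on '+', end−1 on '−').  For GFF3 the feature span is
    used the same way after 1-based → 0-based conversion.
    """
    path = Path(path)
    is_gff = path.suffix.lower() in {".gff", ".gff3", ".gtf"}
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if is_gff:
                if len(f) < 9:
                    raise ParseError("GFF3 line has fewer than 9 fields", ln)
                contig, start, end, strand = f[0], int(f[3]) - 1, int(f[4]), f[6]
                gene = _gff_attr(f[8]) or f"feature_{ln}"
            else:
                if len(f) < 6:
                    raise ParseError("BED line has fewer than 6 fields", ln)
                contig, start, end = f[0], int(f[1]), int(f[2])
                gene, strand = f[3], f[5]
            if strand not in "+-":
                raise ParseError(f"invalid strand {strand!r}", ln)
            if end - start == 1:
                tss = start
            else:
                tss = start if strand == "+" else end - 1
            rows.append({"gene_id": gene, "contig": contig,
                         "tss": tss, "strand": strand})
    return pd.DataFrame(rows, columns=["gene_id", "contig", "tss", "strand"])


# ---------------------------------------------------------------------------
# extraction


def _contig_sequence(genome, contig: str) -> str:
    seq = genome[contig]
    return str(seq[:]) if not isinstance(seq, str) else seq


def extract_promoters(genome, annotations, up: int = 1500, down: int = 500,
                      groups: dict[str, str] | None = None) -> PromoterSet:
    """Extract TSS-anchored promoter windows from a genome.

    Parameters
    ----------
    genome:
        Path to a FASTA file, or any mapping of contig name to sequence
        (a :class:`pyfaidx.Fasta` works).
    annotations:
        Path to a BED6/GFF3 file, or a DataFrame with columns
        gene_id / contig / tss / strand (``tss`` 0-based).
    up, down:
        Window extent in bases upstream/downstream of the TSS; the window is
        half-open, ``[−up, +down)`` in transcription orientation.
    groups:
        Optional gene_id -> group label map recorded on the records.
    """
    if up + down <= 0:
        raise ConfigurationError("promoter window has zero length")
    if isinstance(genome, (str, Path)):
        import pyfaidx

        genome = pyfaidx.Fasta(str(genome), as_raw=True)
    if isinstance(annotations, (str, Path)):
        annotations = read_tss_annotation(annotations)

    records: list[PromoterRecord] = []
    seen: set[str] = set()
    for row in annotations.itertuples():
        if row.gene_id in seen:
            warnings.warn(f"duplicate TSS for {row.gene_id}; first one wins")
            continue
        seen.add(row.gene_id)
        try:
            contig_seq = _contig_sequence(genome, row.contig)
        except KeyError:
            raise DataError(f"contig {row.contig!r} not found in genome") from None
        n = len(contig_seq)
        t = int(row.tss)
        if row.strand == "+":
            start, end = t - up, t + down
        else:
            start, end = t - down + 1, t + up + 1
        cstart, cend = max(0, start), min(n, end)
        if cend <= cstart:
            raise DataError(
                f"{row.gene_id}: promoter window [{start}, {end}) lies "
                f"entirely outside contig {row.contig} (length {n})")
        seq = contig_seq[cstart:cend].upper()
        clipped = (cstart != start) or (cend != end)
        if row.strand == "+":
            tss_index = t - cstart
        else:
            seq = revcomp(seq)
            tss_index = cend - 1 - t
        records.append(PromoterRecord(
            gene_id=row.gene_id, sequence=seq, strand=row.strand,
            contig=row.contig, tss=t, tss_index=tss_index, clipped=clipped,
            group=(groups or {}).get(row.gene_id)))
    return PromoterSet(records)
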