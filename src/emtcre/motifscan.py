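"""Position-weight-matrix library parsing and promoter scanning.

A PWM is stored as a 4xL count matrix (A, C, G, T rows).  Scoring is
log2-odds of the pseudocounted position probabilities against a background
(uniform by default), and a window is a hit when its score reaches a
configurable fraction of the matrix's maximum achievable score (0.85 by
default).  Both strands are scanned; windows containing N score -inf.
Overlapping hits are all reported — the counting unit downstream is
occurrences, and promoters carrying several copies of the same element
("clusters") are meaningful.

Libraries are read either from TRANSFAC-style flat files (ID / P0 blocks,
parsed with Biopython) or from a simple text dialect: a ``>NAME`` line
followed by one whitespace-separated A C G T count row per position, blocks
separated by blank lines.  A directory mixes both freely.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from emtcre.errors import ConfigurationError, ParseError
from emtcre.promoters import PromoterRecord, PromoterSet

__all__ = [
    "PWM",
    "MotifLibrary",
    "MotifHit",
    "parse_matrix_library",
    "write_matrix_library",
    "scan_promoter",
    "scan_group",
]

_ALPHABET = "ACGT"
_IDX = {b: i for i, b in enumerate(_ALPHABET)}

DEFAULT_THRESHOLD_FRACTION = 0.85
DEFAULT_PSEUDOCOUNT = 0.25


@dataclass
class PWM:
    """Named position count matrix with log-odds scoring."""

    name: str
    counts: np.ndarray  # shape (4, L), rows A C G T
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25))
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise ConfigurationError(
                f"PWM {self.name}: counts must be 4 x L")
        if (self.counts < 0).any() or (self.counts.sum(axis=0) == 0).any():
            raise ConfigurationError(
                f"PWM {self.name}: column counts must be >= 0 and not "
                "all zero")
        if not np.isclose(self.background.sum(), 1.0):
            raise ConfigurationError(
                f"PWM {self.name}: background must sum to 1")
        if not 0 < self.threshold_fraction <= 1:
            raise ConfigurationError(
                f"PWM {self.name}: threshold_fraction must be in (0, 1]")

    def __len__(self) -> int:
        return self.counts.shape[1]

    @property
    def probabilities(self) -> np.ndarray:
        c = self.counts + self.pseudocount
        return c / c.sum(axis=0, keepdims=True)

    @property
    def log_odds(self) -> np.ndarray:
        """log2( p / background ), shape (4, L)."""
        return np.log2(self.probabilities / self.background[:, None])

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())

    @property
    def min_score(self) -> float:
        return float(self.log_odds.min(axis=0).sum())

    @property
    def consensus(self) -> str:
        return "".join(_ALPHABET[i] for i in self.counts.argmax(axis=0))

    def reverse_complement(self) -> "PWM":
        return PWM(name=self.name, counts=self.counts[::-1, ::-1].copy(),
                   pseudocount=self.pseudocount,
                   background=self.background[::-1].copy(),
                   threshold_fraction=self.threshold_fraction)

    def score(self, window: str) -> float:
        """Log-odds score of one L-length window (N scores -inf)."""
        if len(window) != len(self):
            raise ConfigurationError("window length != motif length")
        lo = self.log_odds
        total = 0.0
        for j, b in enumerate(window.upper()):
            if b not in _IDX:
                return float("-inf")
            total += lo[_IDX[b], j]
        return total


class MotifLibrary:
    """Ordered name -> PWM mapping."""

    def __init__(self, pwms: list[PWM]):
        self._pwms: dict[str, PWM] = {}
        for p in pwms:
            if p.name in self._pwms:
                raise ConfigurationError(f"duplicate motif name {p.name!r}")
            self._pwms[p.name] = p

    def __getitem__(self, name: str) -> PWM:
        return self._pwms[name]

    def __contains__(self, name: str) -> bool:
        return name in self._pwms

    def __iter__(self):
        return iter(self._pwms.values())

    def __len__(self) -> int:
        return len(self._pwms)

    @property
    def names(self) -> list[str]:
        return list(self._pwms)


# ---------------------------------------------------------------------------
# parsing


def _parse_simple(text: str, origin: str) -> list[PWM]:
    pwms: list[PWM] = []
    name = None
    rows: list[list[float]] = []

    def flush(line_no):
        nonlocal name, rows
        if name is not None:
            if not rows:
                raise ParseError(f"motif {name!r} has no count rows", line_no)
            pwms.append(PWM(name=name, counts=np.array(rows).T))
        name, rows = None, []

    for ln, line in enumerate(text.splitlines(), 1):
        s = line.strip()
        if not s or s.startswith("#"):
            continue
        if s.startswith(">"):
            flush(ln)
            name = s[1:].strip()
            continue
        if name is None:
            raise ParseError(f"count row before any >NAME header in {origin}",
                             ln)
        fields = s.split()
        if len(fields) != 4:
            raise ParseError(
                f"expected 4 count fields (A C G T), got {len(fields)}", ln)
        try:
            rows.append([float(f) for f in fields])
        except ValueError:
            raise ParseError(f"non-numeric count in {origin}", ln) from None
    flush(None)
    return pwms


def _parse_transfac(path: Path) -> list[PWM]:
    from Bio import motifs as bio_motifs

    with open(path) as fh:
        try:
            records = bio_motifs.parse(fh, "TRANSFAC")
        except Exception as exc:  # surface Biopython's message with context
            raise ParseError(f"cannot parse TRANSFAC file {path}: {exc}") from exc
    pwms = []
    for m in records:
        name = m.get("ID") or m.get("AC") or m.name
        counts = np.array([list(m.counts[b]) for b in _ALPHABET], dtype=float)
        pwms.append(PWM(name=str(name), counts=counts))
    return pwms


def _looks_like_transfac(text: str) -> bool:
    for line in text.splitlines():
        s = line.strip()
        if not s:
            continue
        if s.startswith(">"):
            return False
        if s.split()[0] in {"VV", "ID", "AC", "P0", "PO", "XX"}:
            return True
    return False


def parse_matrix_library(path: str | Path) -> MotifLibrary:
    """Load PWMs from a file or a directory of files (dialects may mix)."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"matrix library {path} does not exist")
    files = sorted(p for p in path.iterdir() if p.is_file()) \
        if path.is_dir() else [path]
    pwms: list[PWM] = []
    for f in files:
        text = f.read_text()
        if _looks_like_transfac(text):
            pwms.extend(_parse_transfac(f))
        else:
            pwms.extend(_parse_simple(text, str(f)))
    return MotifLibrary(pwms)


def default_library() -> MotifLibrary:
    """The bundled convenience matrices (SRY, FTS-1, Evi-1, GC-Box, Elk-1,
    CREB) — synthetic fixtures, not database reproductions."""
    from emtcre.data import MATRIX_DIR

    return parse_matrix_library(MATRIX_DIR)


def write_matrix_library(lib: MotifLibrary, path: str | Path) -> None:
    """Write a library in the simple text dialect (lossless round-trip)."""
    with open(path, "w") as fh:
        for pwm in lib:
            fh.write(f">{pwm.name}\n")
            for col in pwm.counts.T:
                fh.write("\t".join(f"{v:g}" for v in col) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# scanning


@dataclass(frozen=True)
class MotifHit:
    gene_id: str
    element: str
    offset: int  # window start relative to the TSS (TSS = 0)
    strand: str
    score: float


def _encode(seq: str) -> np.ndarray:
    idx = np.full(len(seq), -1, dtype=np.int64)
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    for b, i in _IDX.items():
        idx[arr == ord(b)] = i
    return idx


def _window_scores(idx: np.ndarray, log_odds: np.ndarray) -> np.ndarray:
    """Score every window start; windows containing N get -inf."""
    L = log_odds.shape[1]
    n = idx.size - L + 1
    if n <= 0:
        return np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(idx, L)
    valid = (windows >= 0).all(axis=1)
    safe = np.where(windows >= 0, windows, 0)
    scores = log_odds.T[np.arange(L), safe].sum(axis=1)
    return np.where(valid, scores, -np.inf)


def scan_promoter(promoter: PromoterRecord | str, pwm: PWM,
                  threshold_fraction: float | None = None) -> list[MotifHit]:
    """All positions where the PWM scores above threshold, both strands.

    The hit threshold is ``threshold_fraction x max achievable score``.
    Offsets are the window start relative to the TSS when a
    :class:`PromoterRecord` is given (its ``tss_index``), or 0-based window
    coordinates for a bare sequence.  Hits are sorted by offset, plus strand
    first on ties.
    """
    if isinstance(promoter, PromoterRecord):
        seq, gene, anchor = promoter.sequence, promoter.gene_id, promoter.tss_index
    else:
        seq, gene, anchor = str(promoter), "", 0
    if len(seq) < len(pwm):
        raise ConfigurationError(
            f"promoter ({len(seq)} bp) shorter than motif {pwm.name} "
            f"({len(pwm)} bp)")
    frac = pwm.threshold_fraction if threshold_fraction is None \
        else threshold_fraction
    if not 0 < frac <= 1:
        raise ConfigurationError("threshold_fraction must be in (0, 1]")
    threshold = frac * pwm.max_score

    idx = _encode(seq)
    hits: list[MotifHit] = []
    for strand, lo in (("+", pwm.log_odds),
                       ("-", pwm.reverse_complement().log_odds)):
        scores = _window_scores(idx, lo)
        for i in np.nonzero(scores >= threshold)[0]:
            hits.append(MotifHit(gene_id=gene, element=pwm.name,
                                 offset=int(i) - anchor, strand=strand,
                                 score=float(scores[i])))
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def scan_group(promoters: PromoterSet, library: MotifLibrary,
               threshold_fraction: float | None = None) -> pd.DataFrame:
    """Scan every promoter against every library motif.

    Returns the hit table (gene_id, element, offset, strand, score) with
    per-gene per-element counts and a cluster flag (>= 2 occurrences of the
    same element in one promoter) obtainable via :func:`hit_counts`.
    """
    if len(promoters) == 0:
        raise ConfigurationError("empty promoter set")
    rows = []
    for rec in promoters:
        for pwm in library:
            if len(rec) < len(pwm):
                warnings.warn(f"{rec.gene_id}: shorter than motif {pwm.name}; "
                              "skipped")
                continue
            for h in scan_promoter(rec, pwm, threshold_fraction):
                rows.append((h.gene_id, h.element, h.offset, h.strand, h.score))
    return pd.DataFrame(rows, columns=["gene_id", "element", "offset",
                                       "strand", "score"])


def hit_counts(hits: pd.DataFrame) -> pd.DataFrame:
    """Per (gene, element) occurrence counts with a cluster flag."""
    if hits.empty:
        return pd.DataFrame(columns=["gene_id", "element", "count", "cluster"])
    counts = (hits.groupby(["gene_id", "element"]).size()
              .rename("count").reset_index())
    counts["cluster"] = counts["count"] >= 2
    return counts
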