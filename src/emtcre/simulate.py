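"""Synthetic inputs with planted ground truth.

Two generators cover everything the downstream stages consume:

``simulate_probe_matrix``
    Multi-probe-per-transcript intensity data in the style of Affymetrix
    expression arrays: an additive Gaussian optical background plus an
    exponentially distributed hybridization signal (the classic
    normal+exponential convolution), per-gene stage-specific planted fold
    changes, multiplicative log-normal measurement noise, and a monotone
    per-array distortion of the intensity scale that pairwise normalization
    must remove.

``simulate_promoters``
    Promoter windows with motif instances planted at controlled per-group
    mean occurrences (Poisson counts, so per-gene multiplicity — "clusters" —
    arises naturally), uniform placement without overlap, random site strand,
    and i.i.d. background sequence of chosen GC content.  ``embed_in_genome``
    turns a set of simulated promoters into a toy genome FASTA plus TSS
    annotations so that strand-aware promoter extraction can be exercised on
    it and must return the original windows exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from emtcre.errors import ConfigurationError
from emtcre.probe_matrix import ProbeMatrix
from emtcre.promoters import PromoterRecord, PromoterSet, revcomp

__all__ = [
    "SimConfig",
    "PromoterSimConfig",
    "GroundTruth",
    "simulate_probe_matrix",
    "simulate_promoters",
    "embed_in_genome",
    "write_tss_bed",
]


# ---------------------------------------------------------------------------
# configuration


@dataclass
class SimConfig:
    """Conditions for the probe-level intensity simulation.

    Defaults emulate a small oligonucleotide-array time course: 3 biological
    replicates per time point, 11 probes per transcript, scanner-scale
    intensities (background ~100 units, mean specific signal ~3000 units).
    """

    n_genes: int = 200
    probes_per_gene: int = 11
    timepoints: tuple[str, ...] = ("T0", "T6", "T18", "T96")
    n_replicates: int = 3
    frac_up: float = 0.05
    frac_down: float = 0.05
    planted_log2fc: float = 1.5
    #: probability that a gene differentially expressed at one stage stays
    #: differentially expressed (same direction) at the next stage
    persistence: float = 0.6
    background_mean: float = 100.0
    background_sd: float = 15.0
    signal_scale: float = 3000.0
    #: SD of multiplicative measurement noise on the log2 signal
    noise_sd: float = 0.2
    #: per-array monotone distortion strength; arrays draw an exponent
    #: uniformly between 1 and this value (1.0 = no distortion)
    distortion_exponent: float = 1.2
    seed: int = 0

    def validate(self) -> None:
        if not (0 <= self.frac_up <= 1 and 0 <= self.frac_down <= 1):
            raise ConfigurationError("frac_up/frac_down must lie in [0, 1]")
        if self.frac_up + self.frac_down > 1:
            raise ConfigurationError("frac_up + frac_down must be <= 1")
        if self.probes_per_gene < 2:
            raise ConfigurationError("probes_per_gene must be >= 2")
        if min(self.background_mean, self.signal_scale) <= 0:
            raise ConfigurationError("intensity scales must be positive")
        if self.background_sd < 0 or self.noise_sd < 0:
            raise ConfigurationError("noise SDs must be nonnegative")
        if self.distortion_exponent <= 0:
            raise ConfigurationError("distortion_exponent must be positive")
        if len(self.timepoints) < 2:
            raise ConfigurationError("need a baseline plus >=1 stage")
        if not (0 <= self.persistence <= 1):
            raise ConfigurationError("persistence must lie in [0, 1]")


@dataclass
class PromoterSimConfig:
    """Conditions for one promoter group (e.g. genes up-regulated at T6)."""

    n_genes: int = 50
    promoter_length: int = 2000
    #: index of the TSS base inside the window (window = 1500 bp upstream +
    #: 500 bp downstream by default)
    tss_offset: int = 1500
    #: element name -> expected planted occurrences per promoter (Poisson
    #: mean; values > 1 plant multi-occurrence clusters)
    planted_freq: dict[str, float] = field(default_factory=dict)
    gc_content: float = 0.45
    group: str = "up"
    seed: int = 0

    def validate(self) -> None:
        if self.promoter_length <= 0:
            raise ConfigurationError("promoter_length must be positive")
        if not 0 <= self.tss_offset < self.promoter_length:
            raise ConfigurationError("tss_offset outside the promoter window")
        if not 0 < self.gc_content < 1:
            raise ConfigurationError("gc_content must lie in (0, 1)")
        if any(v < 0 for v in self.planted_freq.values()):
            raise ConfigurationError("planted_freq values must be >= 0")


@dataclass
class GroundTruth:
    """Planted truth emitted alongside the synthetic files."""

    #: (gene, stage) -> "up" | "down"; absent pairs are null
    de_labels: dict[tuple[str, str], str] = field(default_factory=dict)
    #: (gene, element) -> list of (window offset, strand) of planted sites
    planted_sites: dict[tuple[str, str], list[tuple[int, str]]] = field(
        default_factory=dict
    )

    def label(self, gene: str, stage: str) -> str:
        return self.de_labels.get((gene, stage), "null")

    def genes_with_label(self, stage: str, label: str) -> list[str]:
        return sorted(g for (g, s), v in self.de_labels.items()
                      if s == stage and v == label)

    def merge(self, other: "GroundTruth") -> "GroundTruth":
        out = GroundTruth(dict(self.de_labels),
                          {k: list(v) for k, v in self.planted_sites.items()})
        out.de_labels.update(other.de_labels)
        for k, v in other.planted_sites.items():
            out.planted_sites.setdefault(k, []).extend(v)
        return out

    # -- serialization -----------------------------------------------------

    def de_table(self) -> pd.DataFrame:
        rows = [{"gene_id": g, "stage": s, "label": v}
                for (g, s), v in sorted(self.de_labels.items())]
        return pd.DataFrame(rows, columns=["gene_id", "stage", "label"])

    def sites_table(self) -> pd.DataFrame:
        rows = [{"gene_id": g, "element": e, "offset": o, "strand": st}
                for (g, e), sites in sorted(self.planted_sites.items())
                for o, st in sites]
        return pd.DataFrame(rows,
                            columns=["gene_id", "element", "offset", "strand"])

    def write(self, de_path: str | Path | None = None,
              sites_path: str | Path | None = None) -> None:
        if de_path is not None:
            self.de_table().to_csv(de_path, sep="\t", index=False)
        if sites_path is not None:
            self.sites_table().to_csv(sites_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# intensity simulation


def _distort(intensity: np.ndarray, gamma: float) -> np.ndarray:
    """Monotone per-array distortion: power law on the rescaled log scale."""
    if gamma == 1.0:
        return intensity
    x = np.log(intensity)
    lo, hi = x.min(), x.max()
    if hi == lo:
        return intensity
    u = (x - lo) / (hi - lo)
    return np.exp(lo + (hi - lo) * u ** gamma)


def _plant_de_labels(cfg: SimConfig, genes: list[str],
                     rng: np.random.Generator) -> dict[tuple[str, str], str]:
    """Stage-wise up/down labels with Markov persistence between stages.

    Each stage carries exactly round(frac * n_genes) genes per direction:
    survivors from the previous stage (kept with probability ``persistence``)
    topped up with fresh draws from the currently-null pool.
    """
    n_up = round(cfg.frac_up * cfg.n_genes)
    n_down = round(cfg.frac_down * cfg.n_genes)
    labels: dict[tuple[str, str], str] = {}
    prev: dict[str, list[str]] = {"up": [], "down": []}
    for stage in cfg.timepoints[1:]:
        chosen: dict[str, list[str]] = {}
        taken: set[str] = set()
        for direction, n_target in (("up", n_up), ("down", n_down)):
            keep = [g for g in prev[direction]
                    if rng.random() < cfg.persistence][:n_target]
            taken |= set(keep)
            pool = [g for g in genes if g not in taken
                    and g not in prev["up"] and g not in prev["down"]]
            need = n_target - len(keep)
            fresh = list(rng.choice(pool, size=need, replace=False)) if need else []
            taken |= set(fresh)
            chosen[direction] = keep + fresh
        for direction in ("up", "down"):
            for g in chosen[direction]:
                labels[(g, stage)] = direction
        prev = chosen
    return labels


def simulate_probe_matrix(cfg: SimConfig) -> tuple[ProbeMatrix, GroundTruth]:
    """Simulate a probe-level time-course experiment with planted truth.

    The intensity model per measurement is::

        I = distort( background + affinity * 2**(delta + eps) )

    with ``background ~ N(background_mean, background_sd)``, a probe-specific
    ``affinity ~ Exponential(signal_scale)`` shared across arrays,
    ``delta`` the planted log2 fold change of the gene at the array's stage,
    ``eps ~ N(0, noise_sd)`` fresh per measurement, and ``distort`` a
    per-array monotone power-law warp of the log-intensity scale (the
    baseline array is never distorted).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    width = max(4, len(str(cfg.n_genes)))
    genes = [f"g{i + 1:0{width}d}" for i in range(cfg.n_genes)]
    probe_ids = [f"{g}_p{j + 1:02d}" for g in genes
                 for j in range(cfg.probes_per_gene)]
    gene_of = pd.Series(np.repeat(genes, cfg.probes_per_gene),
                        index=pd.Index(probe_ids, name="probe_id"),
                        name="gene_id")

    labels = _plant_de_labels(cfg, genes, rng)
    truth = GroundTruth(de_labels=labels)

    n_probes = len(probe_ids)
    affinity = rng.exponential(cfg.signal_scale, size=n_probes)

    glo, ghi = sorted((1.0, cfg.distortion_exponent))
    columns: dict[str, np.ndarray] = {}
    sign = {"up": 1.0, "down": -1.0}
    for ti, tp in enumerate(cfg.timepoints):
        delta_gene = np.array([
            sign.get(labels.get((g, tp), ""), 0.0) * cfg.planted_log2fc
            for g in genes
        ])
        delta = np.repeat(delta_gene, cfg.probes_per_gene)
        for r in range(cfg.n_replicates):
            bg = rng.normal(cfg.background_mean, cfg.background_sd, n_probes)
            eps = rng.normal(0.0, cfg.noise_sd, n_probes)
            intensity = bg + affinity * 2.0 ** (delta + eps)
            intensity = np.maximum(intensity, 1e-6)
            baseline = ti == 0 and r == 0
            gamma = 1.0 if baseline else rng.uniform(glo, ghi)
            columns[f"{tp}_r{r + 1}"] = _distort(intensity, gamma)

    intensities = pd.DataFrame(columns, index=gene_of.index)
    pm = ProbeMatrix(intensities, gene_of,
                     extra_header={"seed": cfg.seed,
                                   "planted_log2fc": cfg.planted_log2fc})
    return pm, truth


# ---------------------------------------------------------------------------
# promoter simulation

_BASES = np.array(list("ACGT"))


def _random_sequence(n: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=n, p=p)]


def simulate_promoters(cfg: PromoterSimConfig, library
                       ) -> tuple[PromoterSet, GroundTruth]:
    """Simulate one promoter group with planted motif consensus instances.

    ``library`` is a :class:`~emtcre.motifscan.MotifLibrary` (anything
    mapping element name -> object with a ``consensus`` string works); every
    key of ``cfg.planted_freq`` must resolve in it.  Per gene the number of
    planted copies of each element is Poisson(``planted_freq``); sites are
    placed uniformly without overlap, on a random strand (minus-strand sites
    are inserted as the reverse complement of the consensus).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    consensus: dict[str, str] = {}
    for name in cfg.planted_freq:
        try:
            motif = library[name]
        except KeyError:
            raise ConfigurationError(f"motif {name!r} not in library") from None
        seq = motif.consensus if hasattr(motif, "consensus") else str(motif)
        if len(seq) >= cfg.promoter_length:
            raise ConfigurationError(
                f"motif {name!r} ({len(seq)} bp) does not fit in a "
                f"{cfg.promoter_length} bp promoter")
        consensus[name] = str(seq).upper()

    width = max(4, len(str(cfg.n_genes)))
    records: list[PromoterRecord] = []
    truth = GroundTruth()
    for i in range(cfg.n_genes):
        gene = f"{cfg.group}_{i + 1:0{width}d}"
        seq = _random_sequence(cfg.promoter_length, cfg.gc_content, rng)
        occupied: list[tuple[int, int]] = []
        for name in sorted(consensus):
            unit = consensus[name]
            n_sites = rng.poisson(cfg.planted_freq[name])
            for _ in range(n_sites):
                placed = False
                for _attempt in range(200):
                    off = int(rng.integers(0, cfg.promoter_length - len(unit) + 1))
                    if any(off < e and off + len(unit) > s for s, e in occupied):
                        continue
                    strand = "+" if rng.random() < 0.5 else "-"
                    insert = unit if strand == "+" else revcomp(unit)
                    seq[off:off + len(unit)] = list(insert)
                    occupied.append((off, off + len(unit)))
                    truth.planted_sites.setdefault((gene, name), []).append(
                        (off, strand))
                    placed = True
                    break
                if not placed:  # promoter saturated; drop the site
                    pass
        gene_strand = "+" if rng.random() < 0.5 else "-"
        records.append(PromoterRecord(
            gene_id=gene, sequence="".join(seq), strand=gene_strand,
            tss_index=cfg.tss_offset, group=cfg.group))
    return PromoterSet(records), truth


def embed_in_genome(promoter_set: PromoterSet, spacer: int = 200,
                    contig: str = "chrS", gc_content: float = 0.45,
                    seed: int = 0) -> tuple[dict[str, str], pd.DataFrame]:
    """Embed promoter windows into a synthetic contig with TSS annotations.

    Records with ``strand == '-'`` are placed as the reverse complement of
    their window, so extracting the annotated window from the returned genome
    (1500 up / 500 down around each TSS by default) reproduces every promoter
    sequence exactly.

    Returns ``(genome, tss_table)`` where genome maps contig name to sequence
    and the table has columns gene_id / contig / tss / strand.
    """
    rng = np.random.default_rng(seed)
    parts: list[str] = []
    rows = []
    cursor = 0
    for rec in promoter_set:
        gap = "".join(_random_sequence(spacer, gc_content, rng))
        parts.append(gap)
        cursor += spacer
        window = rec.sequence
        L = len(window)
        if rec.strand == "+":
            parts.append(window)
            tss = cursor + rec.tss_index
        else:
            parts.append(revcomp(window))
            tss = cursor + L - 1 - rec.tss_index
        rows.append({"gene_id": rec.gene_id, "contig": contig,
                     "tss": tss, "strand": rec.strand})
        cursor += L
    parts.append("".join(_random_sequence(spacer, gc_content, rng)))
    genome = {contig: "".join(parts)}
    return genome, pd.DataFrame(rows, columns=["gene_id", "contig", "tss", "strand"])


def write_tss_bed(tss_table: pd.DataFrame, path: str | Path) -> None:
    """Write TSS annotations as 6-column BED (single-base intervals)."""
    with open(path, "w") as fh:
        for row in tss_table.itertuples():
            fh.write(f"{row.contig}\t{row.tss}\t{row.tss + 1}\t"
                     f"{row.gene_id}\t0\t{row.strand}\n")


def config_to_dict(cfg) -> dict:
    """Flat dict view of a simulation config (for manifests/headers)."""
    return dataclasses.asdict(cfg)
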