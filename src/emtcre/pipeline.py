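"""End-to-end orchestration: simulate → normalize → DE → sets → promoters →
scan → profile → decoys, with a provenance manifest.

Every stage writes plain-text artifacts (TSV / FASTA / BED / Newick / JSON)
into the run directory; tabular outputs carry the configuration hash in a
``#`` header line, and the manifest records the hash, seeds, package
version, per-stage log and SHA-256 checksums of every artifact.  Nothing in
the outputs depends on wall clock, so a rerun with the same configuration
is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from emtcre.errors import ConfigurationError, DataError
from emtcre.simulate import (GroundTruth, PromoterSimConfig, SimConfig,
                             embed_in_genome, simulate_probe_matrix,
                             simulate_promoters, write_tss_bed)
from emtcre.normalization import normalize_experiment
from emtcre.diffexpr import (Contrast, hier_cluster, rank_de, select_genes,
                             shared_with_endpoint, stage_profiles,
                             up_down_ratio, venn_partition, write_de_table)
from emtcre.promoters import PromoterSet, extract_promoters
from emtcre.motifscan import default_library, parse_matrix_library, scan_group
from emtcre.cre_profile import (frequency_timecourse, tabulate_frequencies,
                                top_k_elements)
from emtcre.decoy import build_decoy, verify_duplex, write_decoys_fasta

__all__ = ["PipelineConfig", "run_pipeline"]

DEFAULT_DECOY_CORES = {
    "SRY": "acttttgtttttt",
    "FTS-1": "tgattgatcct",
    "Evi-1": "gacaagataa",
    "GC-Box": "ccccgcccc",
    "Elk-1": "ccggaagt",
    "CREB": "tgacgtca",
}


@dataclass
class PipelineConfig:
    """Structured configuration of a full synthetic-data run."""

    seed: int = 1
    baseline: str = "T0"
    emt_stages: tuple[str, ...] = ("T6", "T18", "T96")
    endpoint: str | None = "NIH3T3"
    sim: dict = field(default_factory=dict)
    # thresholds
    fc_cutoff: float = 1.75
    alpha: float = 0.01
    threshold_fraction: float = 0.85
    top_k: int = 6
    up: int = 1500
    down: int = 500
    n_perm: int = 600
    # promoter simulation: truth group -> element -> mean planted occurrences
    gc_content: float = 0.45
    group_freqs: dict = field(default_factory=dict)
    matrix_library: str | None = None  # path; bundled fixtures when None
    decoy_top_n: int = 4
    decoy_cores: dict = field(default_factory=lambda: dict(DEFAULT_DECOY_CORES))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigurationError(f"config file {path} does not exist")
        raw = yaml.safe_load(path.read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        cfg = cls()
        stages = raw.pop("stages", {})
        cfg.baseline = stages.get("baseline", cfg.baseline)
        cfg.emt_stages = tuple(stages.get("emt", cfg.emt_stages))
        cfg.endpoint = stages.get("endpoint", cfg.endpoint)
        thresholds = raw.pop("thresholds", {})
        for k in ("fc_cutoff", "alpha", "threshold_fraction", "top_k",
                  "up", "down"):
            if k in thresholds:
                setattr(cfg, k, thresholds[k])
        promoters = raw.pop("promoters", {})
        cfg.gc_content = promoters.get("gc_content", cfg.gc_content)
        # a bare `null:` YAML key parses to None; normalize it
        cfg.group_freqs = {("null" if k is None else k): v
                           for k, v in promoters.get("group_freqs", {}).items()}
        decoys = raw.pop("decoys", {})
        cfg.decoy_top_n = decoys.get("top_n", cfg.decoy_top_n)
        cfg.decoy_cores.update(decoys.get("cores", {}))
        for k in ("seed", "sim", "n_perm", "matrix_library"):
            if k in raw:
                setattr(cfg, k, raw.pop(k))
        if raw:
            raise ConfigurationError(f"unknown config keys: {sorted(raw)}")
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.fc_cutoff < 1:
            raise ConfigurationError("fc_cutoff must be >= 1")
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must be in (0, 1)")
        if not 0 < self.threshold_fraction <= 1:
            raise ConfigurationError("threshold_fraction must be in (0, 1]")
        if self.top_k < 1 or self.decoy_top_n < 1:
            raise ConfigurationError("top_k / decoy top_n must be >= 1")
        if self.up < 0 or self.down < 0 or self.up + self.down <= 0:
            raise ConfigurationError("invalid promoter window")

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "stages": {"baseline": self.baseline,
                       "emt": list(self.emt_stages),
                       "endpoint": self.endpoint},
            "sim": dict(self.sim),
            "thresholds": {"fc_cutoff": self.fc_cutoff, "alpha": self.alpha,
                           "threshold_fraction": self.threshold_fraction,
                           "top_k": self.top_k, "up": self.up,
                           "down": self.down},
            "n_perm": self.n_perm,
            "promoters": {"gc_content": self.gc_content,
                          "group_freqs": self.group_freqs},
            "matrix_library": self.matrix_library,
            "decoys": {"top_n": self.decoy_top_n,
                       "cores": dict(self.decoy_cores)},
        }

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def sim_config(self) -> SimConfig:
        timepoints = [self.baseline, *self.emt_stages]
        if self.endpoint:
            timepoints.append(self.endpoint)
        kwargs = dict(self.sim)
        kwargs.setdefault("seed", self.seed)
        kwargs["timepoints"] = tuple(timepoints)
        return SimConfig(**kwargs)


def _write_tsv(df: pd.DataFrame, path: Path, config_hash: str,
               index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, sep="\t", index=index, float_format="%.6g",
                  lineterminator="\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _planting_group(gene: str, truth: GroundTruth, stages) -> str:
    """Earliest-up wins; any down → 'down'; otherwise 'null'."""
    for s in stages:
        if truth.label(gene, s) == "up":
            return f"{s}_up"
    for s in stages:
        if truth.label(gene, s) == "down":
            return "down"
    return "null"


def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> Path:
    """Execute every stage on synthetic data; returns the run directory."""
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    h = cfg.config_hash
    log: list[str] = []

    def stage(name):
        log.append(name)

    try:
        # -- simulate expression --------------------------------------------
        stage("simulate")
        pm, truth = simulate_probe_matrix(cfg.sim_config())
        pm.to_tsv(outdir / "probe_matrix.tsv", {"config_hash": h})
        truth.write(outdir / "truth_de.tsv", None)

        # -- normalize -------------------------------------------------------
        stage("normalize")
        nm = normalize_experiment(pm)
        nm.to_tsv(outdir / "normalized.tsv", {"config_hash": h})

        # -- differential expression ----------------------------------------
        stage("de")
        base_arrays = tuple(nm.arrays_for(cfg.baseline))
        contrast_stages = list(cfg.emt_stages) + \
            ([cfg.endpoint] if cfg.endpoint else [])
        tables: dict[str, pd.DataFrame] = {}
        for s in contrast_stages:
            c = Contrast(name=f"{s}_vs_{cfg.baseline}",
                         treatment=tuple(nm.arrays_for(s)),
                         control=base_arrays)
            t = rank_de(nm, c, n_perm=cfg.n_perm, seed=cfg.seed,
                        fc_cutoff=cfg.fc_cutoff, alpha=cfg.alpha)
            tables[s] = t
            write_de_table(t, outdir / f"de_{s}.tsv")

        # -- stage-wise set logic -------------------------------------------
        stage("sets")
        emt_tables = {s: tables[s] for s in cfg.emt_stages}
        _write_tsv(up_down_ratio(emt_tables), outdir / "updown_ratio.tsv", h)
        if len(cfg.emt_stages) == 3:
            for direction in ("up", "down"):
                sets = {s: select_genes(tables[s], direction)
                        for s in cfg.emt_stages}
                vp = venn_partition(sets, direction=direction)
                _write_tsv(vp.to_table(), outdir / f"venn_{direction}.tsv", h)
        if cfg.endpoint:
            rows = []
            endpoint_table = tables[cfg.endpoint]
            for s in cfg.emt_stages:
                ov = shared_with_endpoint(tables[s], endpoint_table)
                rows.append({"stage": s, "n_shared": len(ov.shared),
                             "frac_of_stage": ov.frac_of_stage,
                             "frac_of_endpoint": ov.frac_of_endpoint})
            _write_tsv(pd.DataFrame(rows), outdir / "endpoint_overlap.tsv", h)
        de_any = sorted(set().union(
            *(select_genes(tables[s], "any") for s in contrast_stages)))
        if len(de_any) >= 2:
            prof = stage_profiles(nm, de_any, stages=contrast_stages)
            clust = hier_cluster(prof)
            (outdir / "cluster.newick").write_text(clust.newick + "\n")
            _write_tsv(pd.DataFrame({"gene_id": clust.ordered_genes}),
                       outdir / "cluster_order.tsv", h)

        # -- promoter simulation & genome embedding -------------------------
        stage("promoters")
        library = parse_matrix_library(cfg.matrix_library) \
            if cfg.matrix_library else default_library()
        gene_groups: dict[str, list[str]] = {}
        for g in sorted(set(pm.gene_ids)):
            gene_groups.setdefault(
                _planting_group(g, truth, cfg.emt_stages), []).append(g)
        records = []
        site_truth = GroundTruth()
        for gi, (grp, genes) in enumerate(sorted(gene_groups.items())):
            freqs = cfg.group_freqs.get(grp, cfg.group_freqs.get("null", {}))
            pcfg = PromoterSimConfig(
                n_genes=len(genes), tss_offset=cfg.up,
                promoter_length=cfg.up + cfg.down,
                planted_freq=dict(freqs), gc_content=cfg.gc_content,
                group=grp, seed=cfg.seed + 101 + gi)
            ps, ptruth = simulate_promoters(pcfg, library)
            renames = dict(zip(ps.gene_ids, genes))
            for rec in ps:
                rec.gene_id = renames[rec.gene_id]
                records.append(rec)
            for (g, e), sites in ptruth.planted_sites.items():
                site_truth.planted_sites[(renames[g], e)] = sites
        records.sort(key=lambda r: r.gene_id)
        sim_promoters = PromoterSet(records)
        site_truth.write(None, outdir / "truth_sites.tsv")
        genome, tss = embed_in_genome(sim_promoters, seed=cfg.seed + 977,
                                      gc_content=cfg.gc_content)
        with open(outdir / "genome.fa", "w") as fh:
            for contig, seq in genome.items():
                fh.write(f">{contig}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i:i + 70] + "\n")
        write_tss_bed(tss, outdir / "tss.bed")

        groups_of = {r.gene_id: r.group for r in sim_promoters}
        promoters = extract_promoters(genome, tss, up=cfg.up, down=cfg.down,
                                      groups=groups_of)
        promoters.to_fasta(outdir / "promoters.fa")
        _write_tsv(promoters.manifest(), outdir / "promoter_manifest.tsv", h)

        # -- scanning & CRE frequency profiling -----------------------------
        stage("scan")
        hits = scan_group(promoters, library,
                          threshold_fraction=cfg.threshold_fraction)
        _write_tsv(hits, outdir / "hits.tsv", h)

        stage("profile")
        elements = library.names
        profile_rows = []
        for s in cfg.emt_stages:
            for direction in ("up", "down"):
                genes = select_genes(tables[s], direction)
                if not genes:
                    log.append(f"profile:{s}:{direction}:empty")
                    continue
                profile_rows.append(tabulate_frequencies(
                    hits, genes, stage=s, group=direction, elements=elements))
        if not profile_rows:
            raise DataError("no differentially expressed gene groups to "
                            "profile")
        profile = pd.concat(profile_rows, ignore_index=True)
        _write_tsv(profile, outdir / "cre_profile.tsv", h)

        up_profile = profile[profile["group"] == "up"]
        stages_up = list(dict.fromkeys(up_profile["stage"]))
        if len(stages_up) >= 2:
            tc = frequency_timecourse(up_profile, stage_order=stages_up)
            _write_tsv(tc, outdir / "cre_timecourse_up.tsv", h)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tops = top_k_elements(profile, k=cfg.top_k)
        _write_tsv(pd.DataFrame(
            [{"stage": s, "group": g, "top_elements": ",".join(v)}
             for (s, g), v in sorted(tops.items())]),
            outdir / "top_elements.tsv", h)

        # -- decoy design ----------------------------------------------------
        stage("decoy")
        pooled = (up_profile.groupby("element")["freq_percent"].mean()
                  .sort_values(ascending=False))
        chosen = [e for e in pooled.index if e in cfg.decoy_cores]
        chosen = chosen[:cfg.decoy_top_n]
        decoys = [build_decoy(cfg.decoy_cores[e], name=e) for e in chosen]
        write_decoys_fasta(decoys, outdir / "decoys.fa")
        rows = []
        for d in decoys:
            rep = verify_duplex(d.odn1, d.odn2)
            rows.append({"name": d.name, "core": d.core,
                         "odn1": d.odn1, "odn2": d.odn2,
                         "duplex_block": rep.length, "passed": rep.passed})
        _write_tsv(pd.DataFrame(rows), outdir / "decoy_verification.tsv", h)
    except (ConfigurationError, DataError) as exc:
        failed = log[-1] if log else "start"
        raise type(exc)(f"[stage {failed}] {exc}") from exc

    # -- manifest ------------------------------------------------------------
    stage("manifest")
    artifacts = sorted(p.name for p in outdir.iterdir()
                       if p.is_file() and p.name != "manifest.json")
    import emtcre

    manifest = {
        "config": cfg.to_dict(),
        "config_hash": h,
        "version": emtcre.__version__,
        "stages": log,
        "checksums": {name: _sha256(outdir / name) for name in artifacts},
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return outdir
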