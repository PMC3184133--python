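"""Simulate the probe-level EMT time course with planted ground truth.

Writes the probe intensity matrix and the planted differential-expression
labels into the run directory and reports what was planted.
"""

from emtcre.simulate import simulate_probe_matrix

from _common import parse_args


def main() -> None:
    cfg, run = parse_args(__doc__)
    pm, truth = simulate_probe_matrix(cfg.sim_config())
    pm.to_tsv(run / "probe_matrix.tsv", {"config_hash": cfg.config_hash})
    truth.write(run / "truth_de.tsv", None)

    sim = cfg.sim_config()
    print(f"simulated {sim.n_genes} genes x {sim.probes_per_gene} probes, "
          f"{len(pm.arrays)} arrays ({', '.join(sim.timepoints)})")
    for stage in sim.timepoints[1:]:
        n_up = len(truth.genes_with_label(stage, "up"))
        n_down = len(truth.genes_with_label(stage, "down"))
        print(f"  {stage}: planted {n_up} up / {n_down} down")
    print(f"wrote {run / 'probe_matrix.tsv'} and truth_de.tsv")


if __name__ == "__main__":
    main()
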