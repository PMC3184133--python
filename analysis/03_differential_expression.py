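"""Call differentially expressed genes per stage and analyse set structure.

Rank-based testing per contrast (each stage versus baseline, plus the
fibroblast endpoint), Venn partition of the three EMT stages, up/down
balance, overlap of each stage with the endpoint contrast, and hierarchical
clustering of the changed genes.
"""

import warnings

import pandas as pd

from emtcre.diffexpr import (Contrast, hier_cluster, rank_de, select_genes,
                             shared_with_endpoint, stage_profiles,
                             up_down_ratio, venn_partition, write_de_table)
from emtcre.normalization import NormalizedMatrix

from _common import parse_args


def main() -> None:
    cfg, run = parse_args(__doc__)
    nm = NormalizedMatrix.from_tsv(run / "normalized.tsv")

    stages = list(cfg.emt_stages) + ([cfg.endpoint] if cfg.endpoint else [])
    tables = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for s in stages:
            c = Contrast(f"{s}_vs_{cfg.baseline}",
                         tuple(nm.arrays_for(s)),
                         tuple(nm.arrays_for(cfg.baseline)))
            tables[s] = rank_de(nm, c, n_perm=cfg.n_perm, seed=cfg.seed,
                                fc_cutoff=cfg.fc_cutoff, alpha=cfg.alpha)
            write_de_table(tables[s], run / f"de_{s}.tsv")

    ratio = up_down_ratio({s: tables[s] for s in cfg.emt_stages})
    ratio.to_csv(run / "updown_ratio.tsv", sep="\t", index=False)
    print("percent up-regulated among selected genes:")
    for row in ratio.itertuples():
        print(f"  {row.stage:<8} {row.n_up:4d} up / {row.n_down:4d} down "
              f"-> {row.percent_up:.1f}%")

    if len(cfg.emt_stages) == 3:
        for direction in ("up", "down"):
            sets = {s: select_genes(tables[s], direction)
                    for s in cfg.emt_stages}
            vp = venn_partition(sets, direction=direction)
            vp.to_table().to_csv(run / f"venn_{direction}.tsv", sep="\t",
                                 index=False)
            triple = vp.region(*cfg.emt_stages)
            print(f"{direction}: {len(triple)} genes shared by all three "
                  "stages")

    if cfg.endpoint:
        rows = []
        for s in cfg.emt_stages:
            ov = shared_with_endpoint(tables[s], tables[cfg.endpoint])
            rows.append({"stage": s, "n_shared": len(ov.shared),
                         "frac_of_stage": ov.frac_of_stage,
                         "frac_of_endpoint": ov.frac_of_endpoint})
            print(f"{s} vs {cfg.endpoint}: {len(ov.shared)} shared "
                  f"({100 * ov.frac_of_stage:.0f}% of stage, "
                  f"{100 * ov.frac_of_endpoint:.0f}% of endpoint)")
        pd.DataFrame(rows).to_csv(run / "endpoint_overlap.tsv", sep="\t",
                                  index=False)

    de_any = sorted(set().union(*(select_genes(tables[s], "any")
                                  for s in stages)))
    if len(de_any) >= 2:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            prof = stage_profiles(nm, de_any, stages=stages)
            clust = hier_cluster(prof)
        (run / "cluster.newick").write_text(clust.newick + "\n")
        print(f"clustered {len(de_any)} changed genes "
              f"-> {run / 'cluster.newick'}")


if __name__ == "__main__":
    main()
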