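"""Chart the CRE frequency statistic per stage and rank the elements.

For each stage's up- and down-regulated gene groups the percentile of
frequency (100 x occurrences / genes) is tabulated per element, the top-6
elements are listed, and the time course (with last-minus-first trends) is
written for the up-regulated groups.
"""

import warnings

import pandas as pd

from emtcre.cre_profile import (frequency_timecourse, tabulate_frequencies,
                                top_k_elements)
from emtcre.diffexpr import select_genes
from emtcre.motifscan import default_library, parse_matrix_library

from _common import parse_args


def main() -> None:
    cfg, run = parse_args(__doc__)
    hits = pd.read_csv(run / "hits.tsv", sep="\t")
    library = parse_matrix_library(cfg.matrix_library) \
        if cfg.matrix_library else default_library()

    rows = []
    for s in cfg.emt_stages:
        table = pd.read_csv(run / f"de_{s}.tsv", sep="\t", comment="#",
                            index_col="gene_id")
        for direction in ("up", "down"):
            genes = select_genes(table, direction)
            if genes:
                rows.append(tabulate_frequencies(
                    hits, genes, stage=s, group=direction,
                    elements=library.names))
    profile = pd.concat(rows, ignore_index=True)
    profile.to_csv(run / "cre_profile.tsv", sep="\t", index=False)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tops = top_k_elements(profile, k=cfg.top_k)
    print(f"top {cfg.top_k} elements per stage/group:")
    for (s, g), elements in sorted(tops.items()):
        print(f"  {s:<5} {g:<5} {', '.join(elements)}")

    up = profile[profile["group"] == "up"]
    stages_present = [s for s in cfg.emt_stages
                      if s in set(up["stage"])]
    if len(stages_present) >= 2:
        tc = frequency_timecourse(up, stage_order=stages_present)
        tc.to_csv(run / "cre_timecourse_up.tsv", sep="\t", index=False)
        trends = tc.drop_duplicates("element").set_index("element")["trend"]
        print("frequency trend (last - first stage, up-regulated genes):")
        for e, t in trends.sort_values().items():
            print(f"  {e:<8} {t:+.1f}%")


if __name__ == "__main__":
    main()
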