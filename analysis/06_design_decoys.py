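"""Design dumbbell decoy pairs against the most frequent up-regulated CREs.

Takes the four elements with the highest mean frequency across stages in
the up-regulated groups, builds tandem-repeat dumbbell decoys from their
core sequences, and verifies duplex structure; also re-verifies the five
published decoy pairs.
"""

import pandas as pd

from emtcre.decoy import (build_decoy, detect_tandem_repeat,
                          load_printed_decoys, verify_duplex,
                          write_decoys_fasta)

from _common import parse_args


def main() -> None:
    cfg, run = parse_args(__doc__)
    profile = pd.read_csv(run / "cre_profile.tsv", sep="\t")
    up = profile[profile["group"] == "up"]
    pooled = (up.groupby("element")["freq_percent"].mean()
              .sort_values(ascending=False))
    chosen = [e for e in pooled.index if e in cfg.decoy_cores]
    chosen = chosen[:cfg.decoy_top_n]

    print(f"designing decoys for the {cfg.decoy_top_n} most frequent "
          f"up-regulated elements: {', '.join(chosen)}")
    decoys, rows = [], []
    for e in chosen:
        d = build_decoy(cfg.decoy_cores[e], name=e)
        rep = verify_duplex(d.odn1, d.odn2)
        decoys.append(d)
        rows.append({"name": e, "core": d.core, "odn1": d.odn1,
                     "odn2": d.odn2, "duplex_block": rep.length,
                     "passed": rep.passed})
        print(f"  {e:<8} core {d.core:<14} duplex block {rep.length} bp "
              f"({'ok' if rep.passed else 'FAIL'})")
    write_decoys_fasta(decoys, run / "decoys.fa")
    pd.DataFrame(rows).to_csv(run / "decoy_verification.tsv", sep="\t",
                              index=False)

    printed = load_printed_decoys()
    print("published decoy pairs:")
    for row in printed.itertuples():
        rep = verify_duplex(row.odn1, row.odn2, min_block=15)
        unit, count, _ = detect_tandem_repeat(row.odn1)
        print(f"  {row.name:<11} duplex {rep.length:2d} bp "
              f"{'ok' if rep.passed else 'FAIL'}; 5' tandem unit "
              f"{unit[:14]!r} x{count}")


if __name__ == "__main__":
    main()
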