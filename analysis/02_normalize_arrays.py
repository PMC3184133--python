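"""Background-correct every array and align it to the baseline array.

Reports the fitted background parameters per array and writes the
normalized log2 matrix.
"""

import warnings

from emtcre.normalization import normalize_experiment
from emtcre.probe_matrix import ProbeMatrix

from _common import parse_args


def main() -> None:
    cfg, run = parse_args(__doc__)
    pm = ProbeMatrix.from_tsv(run / "probe_matrix.tsv")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        nm = normalize_experiment(pm)
    nm.to_tsv(run / "normalized.tsv", {"config_hash": cfg.config_hash})

    print(f"baseline array: {nm.baseline}")
    print("array          bg mean   bg sd   signal mean")
    for arr, (mu, sigma, alpha) in nm.background_fits.items():
        print(f"  {arr:<12} {mu:8.1f} {sigma:7.1f} {alpha:12.1f}")
    print(f"wrote {run / 'normalized.tsv'}")


if __name__ == "__main__":
    main()
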