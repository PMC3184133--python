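"""Probe-level intensity container and its TSV serialization.

The layout mirrors multi-probe oligonucleotide arrays (several probes
interrogate each transcript): rows are probes grouped by gene, columns are
arrays labelled ``<condition>_r<replicate>`` (e.g. ``T6_r2``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from emtcre.errors import DataError

__all__ = ["ProbeMatrix", "array_condition"]


def array_condition(label: str) -> str:
    """Condition part of an array label (``T6_r2`` -> ``T6``)."""
    if "_r" in label:
        return label.rsplit("_r", 1)[0]
    return label


@dataclass
class ProbeMatrix:
    """Probe-level intensities with a probe-to-gene map.

    Parameters
    ----------
    intensities:
        DataFrame indexed by probe id, one column per array, nonnegative
        fluorescence units.
    gene_ids:
        Series mapping probe id to gene id (same index as ``intensities``).
    """

    intensities: pd.DataFrame
    gene_ids: pd.Series
    extra_header: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.intensities.index.equals(self.gene_ids.index):
            raise DataError("probe index of intensities and gene_ids differ")
        if (self.intensities.to_numpy() < 0).any():
            raise DataError("negative intensities are not allowed")

    @property
    def arrays(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def conditions(self) -> dict[str, str]:
        """Map array label -> condition label."""
        return {a: array_condition(a) for a in self.arrays}

    def arrays_for(self, condition: str) -> list[str]:
        return [a for a in self.arrays if array_condition(a) == condition]

    @property
    def n_probes(self) -> int:
        return len(self.intensities)

    def probes_of(self, gene: str) -> pd.Index:
        return self.gene_ids.index[self.gene_ids == gene]

    # -- serialization -----------------------------------------------------

    def to_tsv(self, path: str | Path, header_lines: dict | None = None) -> None:
        path = Path(path)
        df = self.intensities.copy()
        df.insert(0, "gene_id", self.gene_ids)
        with open(path, "w") as fh:
            for k, v in {**self.extra_header, **(header_lines or {})}.items():
                fh.write(f"# {k}={v}\n")
            df.to_csv(fh, sep="\t", index_label="probe_id",
                      float_format="%.6f", lineterminator="\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ProbeMatrix":
        path = Path(path)
        header: dict = {}
        with open(path) as fh:
            while True:
                pos = fh.tell()
                line = fh.readline()
                if not line.startswith("#"):
                    fh.seek(pos)
                    break
                body = line[1:].strip()
                if "=" in body:
                    k, v = body.split("=", 1)
                    header[k.strip()] = v.strip()
            df = pd.read_csv(fh, sep="\t", index_col="probe_id")
        gene_ids = df.pop("gene_id")
        return cls(df.astype(float), gene_ids, extra_header=header)
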