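"""Readers and writers for the pipeline's plain-text formats.

All tabular outputs carry a provenance header of ``#``-prefixed comment
lines (tool version, seed, stage); readers skip comment lines.  Formats:

* ``probes.seg.tsv`` — patient_id, chrom, pos, state ({loss,neutral,gain})
* ``genes.bed`` / ``gaps.bed`` — 4-column BED (0-based half-open)
* ``chrom.sizes`` — chromosome name and length
* ``clinical.csv`` — covariates, follow-up time (years), event flag
* ``gene_calls.tsv`` — patients x genes matrix with values {-1, 0, 1}
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calls import CODE_STATES, STATE_CODES


def provenance_header(stage: str, seed: int | None = None, **extra) -> str:
    fields = {"tool": f"ddrcna v{__version__}", "stage": stage}
    if seed is not None:
        fields["seed"] = seed
    fields.update(extra)
    return "".join(f"# {k}={v}\n" for k, v in fields.items())


def file_checksum(path) -> str:
    return hashlib.md5(Path(path).read_bytes()).hexdigest()


def write_table(df: pd.DataFrame, path, stage: str, seed: int | None = None,
                sep: str = "\t", index: bool = False, **extra) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(provenance_header(stage, seed, **extra))
        df.to_csv(fh, sep=sep, index=index)


def read_table(path, sep: str = "\t", **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, comment="#", **kwargs)


def write_probes(probes: pd.DataFrame, path, seed: int | None = None) -> None:
    out = probes.copy()
    if pd.api.types.is_integer_dtype(out["state"]):
        out["state"] = out["state"].map(CODE_STATES)
    write_table(out, path, stage="simulate", seed=seed)


def read_probes(path) -> pd.DataFrame:
    df = read_table(path)
    df["state"] = df["state"].map(STATE_CODES).astype(np.int8)
    df["chrom"] = df["chrom"].astype("category")
    return df


def read_bed(path, names=("chrom", "start", "end", "name")) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", header=None, names=list(names))


def read_chrom_sizes(path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["chrom", "size"])
    return dict(zip(df["chrom"], df["size"]))


def write_clinical(clinical: pd.DataFrame, path, seed: int | None = None) -> None:
    write_table(clinical, path, stage="simulate", seed=seed, sep=",")


def read_clinical(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    df["event"] = df["event"].astype(bool)
    return df


def write_matrix(matrix: pd.DataFrame, path, seed: int | None = None,
                 stage: str = "call") -> None:
    write_table(matrix.rename_axis("patient_id"), path, stage=stage,
                seed=seed, index=True)


def read_matrix(path) -> pd.DataFrame:
    df = read_table(path).set_index("patient_id")
    return df.astype(np.int8)
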