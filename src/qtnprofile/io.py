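"""Plain-text readers/writers for the pipeline's file formats.

Formats (all delimited text, ids 1-based, 0 = unknown parent, SNP indices
0-based, positions in cM at the file boundary):

* pedigree CSV — ``id,sire,dam,sex,generation`` (sex coded M/F);
* SNP map TSV — ``snp_index,chrom,pos_cm``;
* genotype matrix TSV — one row per genotyped individual, ``id`` then one
  0/1/2 column per SNP;
* phenotype CSV — ``id,phenotype,tbv`` (tbv kept for validation only);
* square matrices as TSV with an id header row/column (debug aid).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "write_pedigree", "read_pedigree",
    "write_map", "read_map",
    "write_genotypes", "read_genotypes",
    "write_phenotypes", "read_phenotypes",
    "write_matrix", "read_matrix",
]

_SEX_CODE = np.array(["M", "F"])


def write_pedigree(ped: pd.DataFrame, path) -> None:
    out = ped.copy()
    out["sex"] = _SEX_CODE[out["sex"].to_numpy()]
    out.to_csv(path, index=False)


def read_pedigree(path) -> pd.DataFrame:
    ped = pd.read_csv(path)
    ped["sex"] = (ped["sex"].to_numpy() == "F").astype(np.int8)
    return ped


def write_map(map_table: pd.DataFrame, path) -> None:
    map_table.to_csv(path, sep="\t", index=False)


def read_map(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_genotypes(genotypes: np.ndarray, ids: np.ndarray, path) -> None:
    with open(path, "w") as fh:
        for i, row in zip(ids, genotypes):
            fh.write(str(int(i)) + "\t" + "\t".join(map(str, row.tolist())) + "\n")


def read_genotypes(path) -> tuple[np.ndarray, np.ndarray]:
    """Returns ``(genotypes, ids)``."""
    raw = np.loadtxt(path, dtype=np.int64, ndmin=2)
    return raw[:, 1:].astype(np.int8), raw[:, 0]


def write_phenotypes(phen: pd.DataFrame, path) -> None:
    phen.to_csv(path, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_matrix(mat: np.ndarray, ids: np.ndarray, path) -> None:
    df = pd.DataFrame(mat, index=ids, columns=ids)
    df.to_csv(path, sep="\t", index_label="id")


def read_matrix(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col="id")
    return df.to_numpy(), df.index.to_numpy()


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
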