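"""Bundled data resources: Grantham distances, divergence region presets,
grouping dictionaries and the KIR-ligand interaction table.

Everything here is an editable plain-text fixture under ``hlakit/data/``;
users can point the corresponding loaders at their own files to customize
groupings or regions.
"""

from __future__ import annotations

import math
from functools import lru_cache
from importlib import resources as _importlib_resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .nomenclature import Dictionary, read_dictionary

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWVY"

# Grantham's amino-acid properties: composition (c), polarity (p),
# volume (v).  Distance d(i,j) = rho * sqrt(alpha*(ci-cj)^2 +
# beta*(pi-pj)^2 + gamma*(vi-vj)^2) with alpha=1.833, beta=0.1018,
# gamma=0.000399 and rho=50.723 scaling the mean distance to 100.
GRANTHAM_PROPERTIES: dict[str, tuple[float, float, float]] = {
    "S": (1.42, 9.2, 32.0),
    "R": (0.65, 10.5, 124.0),
    "L": (0.0, 4.9, 111.0),
    "P": (0.39, 8.0, 32.5),
    "T": (0.71, 8.6, 61.0),
    "A": (0.0, 8.1, 31.0),
    "V": (0.0, 5.9, 84.0),
    "G": (0.74, 9.0, 3.0),
    "I": (0.0, 5.2, 111.0),
    "F": (0.0, 5.2, 132.0),
    "Y": (0.20, 6.2, 136.0),
    "C": (2.75, 5.5, 55.0),
    "H": (0.58, 10.4, 96.0),
    "Q": (0.89, 10.5, 85.0),
    "N": (1.33, 11.6, 56.0),
    "K": (0.33, 11.3, 119.0),
    "D": (1.38, 13.0, 54.0),
    "E": (0.92, 12.3, 83.0),
    "M": (0.0, 5.7, 105.0),
    "W": (0.13, 5.4, 170.0),
}

_ALPHA, _BETA, _GAMMA, _RHO = 1.833, 0.1018, 0.000399, 50.723


def grantham_from_formula() -> pd.DataFrame:
    """Recompute the 20x20 Grantham distance matrix from the c/p/v formula.

    Values are rounded to integers as conventionally published; a handful of
    cells differ by 1 from the original printed table because the scale
    constant itself was rounded.
    """
    aas = sorted(GRANTHAM_PROPERTIES)
    mat = pd.DataFrame(0.0, index=aas, columns=aas)
    for i in aas:
        ci, pi, vi = GRANTHAM_PROPERTIES[i]
        for j in aas:
            cj, pj, vj = GRANTHAM_PROPERTIES[j]
            d = _RHO * math.sqrt(
                _ALPHA * (ci - cj) ** 2
                + _BETA * (pi - pj) ** 2
                + _GAMMA * (vi - vj) ** 2
            )
            mat.loc[i, j] = round(d)
    return mat


def _data_path(name: str) -> Path:
    return Path(str(_importlib_resources.files("hlakit").joinpath("data", name)))


class GranthamMatrix:
    """Symmetric 20x20 physicochemical distance matrix with zero diagonal."""

    def __init__(self, frame: pd.DataFrame):
        if not np.allclose(frame.values, frame.values.T):
            raise ValueError("Grantham matrix must be symmetric")
        if not np.allclose(np.diag(frame.values), 0.0):
            raise ValueError("Grantham matrix must have zero diagonal")
        off = frame.values[~np.eye(len(frame), dtype=bool)]
        if not (off > 0).all():
            raise ValueError("off-diagonal Grantham distances must be > 0")
        self.frame = frame

    def distance(self, a: str, b: str) -> float:
        return float(self.frame.loc[a, b])


@lru_cache(maxsize=1)
def load_grantham_matrix(path: str | Path | None = None) -> GranthamMatrix:
    p = Path(path) if path is not None else _data_path("grantham.tsv")
    frame = pd.read_csv(p, sep="\t", index_col=0)
    frame.columns = [str(c) for c in frame.columns]
    return GranthamMatrix(frame.astype(float))


@lru_cache(maxsize=8)
def load_region(name: str, path: str | Path | None = None) -> list[int]:
    """Class-I divergence region presets: ``ARD``, ``B_pocket``, ``F_pocket``.

    Position lists live in ``data/divergence_regions.yaml`` (1-based mature
    protein numbering) and can be overridden with a user file.
    """
    p = Path(path) if path is not None else _data_path("divergence_regions.yaml")
    with open(p) as fh:
        regions = yaml.safe_load(fh)
    if name not in regions:
        raise KeyError(
            f"unknown region {name!r}; available: {sorted(regions)}"
        )
    spec = regions[name]
    if isinstance(spec, dict):  # {start: .., end: ..} ranges
        return list(range(int(spec["start"]), int(spec["end"]) + 1))
    return [int(x) for x in spec]


def load_supertypes() -> Dictionary:
    """Class-I supertype groupings (2-field resolution, editable TSV)."""
    return read_dictionary(_data_path("supertypes.tsv"))


def load_g_groups() -> Dictionary:
    """Example G-group dictionary (3-field resolution, editable TSV)."""
    return read_dictionary(_data_path("g_groups.tsv"))


def load_nk_ligands() -> Dictionary:
    """Bw4/Bw6 and C1/C2 NK-cell ligand epitope groupings."""
    return read_dictionary(_data_path("nk_ligands.tsv"))


def load_interactions(path: str | Path | None = None) -> pd.DataFrame:
    """Validated KIR receptor / HLA ligand-group interaction table.

    Columns: ``interaction``, ``kir_gene``, ``ligand_variable``.
    """
    p = Path(path) if path is not None else _data_path("kir_interactions.tsv")
    return pd.read_csv(p, sep="\t", comment="#")
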