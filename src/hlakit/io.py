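"""Table readers/writers and run configuration.

All inputs are delimited text (comma or tab, sniffed from the header line):
HLA calls with an ``ID`` column and ``<GENE>_1``/``<GENE>_2`` allele
columns, KIR gene-content tables, phenotype tables, and grouping
dictionaries.  Result tables are written as TSV with a stable column order
and fixed decimal formatting (scientific notation below 1e-4) so golden-
file comparisons are stable across runs.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .nomenclature import HlaCalls

logger = logging.getLogger("hlakit")


class FormatError(ValueError):
    """Raised for malformed input tables."""


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_table(path: str | Path, index_col: str = "ID") -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"input file does not exist: {path}")
    sep = _sniff_sep(path)
    frame = pd.read_csv(path, sep=sep, dtype=str)
    if index_col not in frame.columns:
        raise FormatError(f"{path}: required column {index_col!r} missing")
    if frame[index_col].duplicated().any():
        dups = frame.loc[frame[index_col].duplicated(), index_col].tolist()
        raise FormatError(f"{path}: duplicate IDs {dups}")
    return frame.set_index(index_col)


def read_hla_table(path: str | Path) -> HlaCalls:
    """Read an HLA genotype table into :class:`HlaCalls`.

    Columns are paired by their ``_1``/``_2`` suffix; an unpaired gene
    column is a format error naming the column.  Blank and ``NA`` cells
    become missing; every other cell must parse as an allele.
    """
    frame = read_table(path)
    frame = frame.replace({"": np.nan, "NA": np.nan})
    try:
        return HlaCalls(frame)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_hla_table(calls: HlaCalls, path: str | Path) -> None:
    out = calls.frame.copy()
    out.index.name = "ID"
    out.to_csv(path, sep="\t", na_rep="")


def read_kir_table(path: str | Path) -> pd.DataFrame:
    """Raw KIR gene-content table (coercion happens in kir_presence)."""
    return read_table(path)


def read_pheno_table(path: str | Path) -> pd.DataFrame:
    frame = read_table(path)
    # numeric phenotype/covariate columns come back as strings; coerce
    for col in frame.columns:
        converted = pd.to_numeric(frame[col], errors="coerce")
        if converted.notna().sum() >= frame[col].notna().sum():
            frame[col] = converted
    return frame


def format_results(table: pd.DataFrame) -> pd.DataFrame:
    """Fixed decimal formatting for stable result files."""
    out = table.copy()
    for col in out.columns:
        if not pd.api.types.is_float_dtype(out[col]):
            continue
        def fmt(x: float) -> str:
            if pd.isna(x):
                return "NA"
            if x != 0 and abs(x) < 1e-4:
                return f"{x:.6e}"
            return f"{x:.6f}"
        out[col] = out[col].map(fmt)
    return out


def write_results(table: pd.DataFrame, path: str | Path) -> None:
    format_results(table).to_csv(path, sep="\t", index=False, na_rep="NA")


@dataclasses.dataclass
class RunConfig:
    """Flat key-value run configuration (YAML file and/or CLI flags)."""

    hla: str | None = None
    kir: str | None = None
    pheno: str | None = None
    dictionary: str | None = None
    alignment: str | None = None
    reference_frequencies: str | None = None
    experiments: tuple[str, ...] = ("hla_alleles",)
    family: str = "logistic"
    formula: str = "outcome ~ term"
    time: str | None = None
    event: str | None = None
    inheritance: str = "additive"
    correction: str = "BH"
    lower_frequency: float = 0.0
    upper_frequency: float = 1.0
    hwe_mode: str = "report"
    hwe_alpha: float = 0.05
    conditional_threshold: float = 0.05
    max_rounds: int = 10
    n_fields: int = 2
    output_dir: str = "."
    seed: int = 0
    n_individuals: int = 1000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise FormatError(f"{path}: unknown config keys {sorted(unknown)}")
        if "experiments" in raw and isinstance(raw["experiments"], list):
            raw["experiments"] = tuple(raw["experiments"])
        return cls(**raw)

    def merged(self, **overrides) -> "RunConfig":
        data = dataclasses.asdict(self)
        for k, v in overrides.items():
            if v is not None:
                data[k] = v
        if isinstance(data.get("experiments"), list):
            data["experiments"] = tuple(data["experiments"])
        return RunConfig(**data)

    def log_header(self) -> str:
        lines = ["# run configuration"]
        for f in dataclasses.fields(self):
            lines.append(f"# {f.name}={getattr(self, f.name)}")
        return "\n".join(lines)
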