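"""HLA allele nomenclature: parsing, validation, resolution reduction and
dictionary-based grouping.

HLA alleles are named ``GENE*F1:F2:F3:F4`` with one to four numeric fields of
two or more digits and an optional trailing expression suffix (N = null,
L = low, S = secreted, C = cytoplasm, A = aberrant, Q = questionable).  The
first two fields define the mature protein; fields three and four add
synonymous and non-coding variation.  Grouping dictionaries (supertypes,
G groups, NK-cell ligand epitopes, user tables) map alleles, stated at a
declared field resolution, onto named groups.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger("hlakit")

EXPRESSION_SUFFIXES = "NLSCAQ"

_ALLELE_RE = re.compile(
    r"^(?P<gene>[A-Za-z][A-Za-z0-9]*)\*"
    r"(?P<fields>\d+(?::\d+){0,3})"
    r"(?P<suffix>[A-Za-z]?)$"
)


class HlaParseError(ValueError):
    """Raised when an allele string violates the nomenclature grammar."""


class ResolutionError(ValueError):
    """Raised when an allele lacks the fields required for a reduction."""


class DictionaryError(ValueError):
    """Raised when a grouping dictionary violates its invariants on load."""


@dataclass(frozen=True)
class HlaAllele:
    """A structured HLA allele name.

    Attributes
    ----------
    gene : str
        Locus symbol, e.g. ``A`` or ``DQB1``.
    fields : tuple of str
        One to four numeric field strings, each at least two digits.
    suffix : str
        Optional expression suffix character, or ``""``.
    """

    gene: str
    fields: tuple[str, ...]
    suffix: str = ""

    def __post_init__(self) -> None:
        if not self.gene:
            raise HlaParseError("allele gene symbol is empty")
        if not 1 <= len(self.fields) <= 4:
            raise HlaParseError(
                f"allele must have 1-4 fields, got {len(self.fields)}"
            )
        for f in self.fields:
            if not 2 <= len(f) <= 3 or not f.isdigit():
                raise HlaParseError(
                    f"allele field {f!r} must be a string of 2-3 digits"
                )
        if self.suffix and self.suffix not in EXPRESSION_SUFFIXES:
            raise HlaParseError(
                f"unknown expression suffix {self.suffix!r} "
                f"(expected one of {EXPRESSION_SUFFIXES})"
            )

    @property
    def resolution(self) -> int:
        """Number of fields present (1-4)."""
        return len(self.fields)

    @property
    def is_null(self) -> bool:
        """True for N-suffixed (not expressed) alleles."""
        return self.suffix == "N"

    def render(self) -> str:
        return f"{self.gene}*{':'.join(self.fields)}{self.suffix}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


def parse_allele(text: str) -> HlaAllele:
    """Parse an allele string into an :class:`HlaAllele`.

    Round-trips: ``parse_allele(s).render() == s`` for every well-formed
    string.  Malformed input raises :class:`HlaParseError` naming the
    offending token.
    """
    if not text:
        raise HlaParseError("empty allele string")
    m = _ALLELE_RE.match(text)
    if m is None:
        if "*" not in text:
            raise HlaParseError(f"{text!r}: missing '*' separator")
        raise HlaParseError(f"{text!r}: not a valid allele string")
    fields = tuple(m.group("fields").split(":"))
    if len(fields) > 4:
        raise HlaParseError(f"{text!r}: more than 4 fields")
    for f in fields:
        if not 2 <= len(f) <= 3:
            raise HlaParseError(
                f"{text!r}: field {f!r} is not 2-3 digits (legacy "
                "separator-less names are not valid)"
            )
    suffix = m.group("suffix")
    if suffix and suffix not in EXPRESSION_SUFFIXES:
        raise HlaParseError(f"{text!r}: unknown suffix {suffix!r}")
    return HlaAllele(gene=m.group("gene"), fields=fields, suffix=suffix)


def reduce_resolution(allele: HlaAllele, n_fields: int) -> HlaAllele:
    """Truncate an allele to its first ``n_fields`` fields.

    The expression suffix is dropped on actual truncation (a suffix refers to
    the full-resolution sequence); reducing to the allele's own resolution is
    the identity.  Reducing *beyond* the available resolution raises
    :class:`ResolutionError` — the name is never padded.
    """
    if not 1 <= n_fields <= 4:
        raise ValueError(f"n_fields must be 1..4, got {n_fields}")
    if n_fields > len(allele.fields):
        raise ResolutionError(
            f"{allele.render()}: cannot reduce to {n_fields} fields, "
            f"only {len(allele.fields)} available"
        )
    if n_fields == len(allele.fields):
        return allele
    return replace(allele, fields=allele.fields[:n_fields], suffix="")


# ---------------------------------------------------------------------------
# Diploid calls container
# ---------------------------------------------------------------------------

class HlaCalls:
    """Per-individual diploid HLA genotypes across genes.

    Wraps a frame indexed by individual ID with two string columns per gene
    (``<GENE>_1`` / ``<GENE>_2``); missing calls are ``None``/``NaN``.  Every
    non-missing cell is validated to parse and to match its column's gene.
    """

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        if frame.index.has_duplicates:
            dups = frame.index[frame.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate individual IDs: {dups}")
        genes: list[str] = []
        for col in frame.columns:
            if col.endswith("_1"):
                gene = col[:-2]
                if f"{gene}_2" not in frame.columns:
                    raise ValueError(f"column {col} has no matching {gene}_2")
                genes.append(gene)
            elif col.endswith("_2"):
                if f"{col[:-2]}_1" not in frame.columns:
                    raise ValueError(f"column {col} has no matching {col[:-2]}_1")
            else:
                raise ValueError(
                    f"column {col!r} is not of the form <GENE>_1/<GENE>_2"
                )
        for gene in genes:
            for slot in (1, 2):
                for ind, val in frame[f"{gene}_{slot}"].items():
                    if val is None or (isinstance(val, float) and pd.isna(val)):
                        continue
                    try:
                        a = parse_allele(str(val))
                    except HlaParseError:
                        continue  # tolerated here; validate_calls reports it
                    if a.gene != gene:
                        raise ValueError(
                            f"individual {ind}: allele {val} in column "
                            f"{gene}_{slot} does not belong to gene {gene}"
                        )
        self._frame = frame
        self._genes = genes

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    @property
    def individuals(self) -> pd.Index:
        return self._frame.index

    @property
    def genes(self) -> list[str]:
        return list(self._genes)

    def __len__(self) -> int:
        return len(self._frame)

    def pair(self, individual, gene: str) -> tuple[str | None, str | None]:
        """The two allele strings (or None) for one individual and gene."""
        row = self._frame.loc[individual]
        out = []
        for slot in (1, 2):
            v = row[f"{gene}_{slot}"]
            out.append(None if pd.isna(v) else str(v))
        return tuple(out)  # type: ignore[return-value]

    def alleles(self, gene: str | None = None) -> set[str]:
        """Distinct non-missing allele strings, optionally for one gene."""
        genes = [gene] if gene is not None else self._genes
        out: set[str] = set()
        for g in genes:
            for slot in (1, 2):
                out.update(self._frame[f"{g}_{slot}"].dropna().astype(str))
        return out


def validate_calls(
    calls: HlaCalls, known: Iterable[str] | None = None
) -> pd.DataFrame:
    """Advisory validation of every genotype cell.

    Returns a report frame with one row per failing cell (columns
    ``individual``, ``column``, ``value``, ``message``); an empty frame means
    every cell passed.  With ``known`` supplied, alleles absent from the
    known-name set are flagged in addition to grammar failures.  The calls
    object is never modified — partial datasets remain usable.
    """
    known_set = set(known) if known is not None else None
    rows = []
    for col in calls.frame.columns:
        for ind, val in calls.frame[col].items():
            if pd.isna(val):
                continue
            text = str(val)
            try:
                parse_allele(text)
            except HlaParseError as exc:
                rows.append((ind, col, text, f"malformed: {exc}"))
                continue
            if known_set is not None and text not in known_set:
                rows.append((ind, col, text, "unknown allele"))
    return pd.DataFrame(
        rows, columns=["individual", "column", "value", "message"]
    )


# ---------------------------------------------------------------------------
# Grouping dictionaries
# ---------------------------------------------------------------------------

@dataclass
class Dictionary:
    """Allele-grouping table declared at a fixed field resolution.

    ``entries`` maps group label -> set of allele names stated at
    ``resolution`` fields; an allele may belong to at most one group.
    ``values`` optionally carries a numeric score per allele (quantitative
    custom dictionaries).
    """

    name: str
    resolution: int
    entries: dict[str, frozenset[str]]
    values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._allele_to_group: dict[str, str] = {}
        for group, alleles in self.entries.items():
            if not group:
                raise DictionaryError(f"dictionary {self.name}: empty group label")
            for a in alleles:
                parse_allele(a)
                if a in self._allele_to_group:
                    raise DictionaryError(
                        f"dictionary {self.name}: allele {a} appears under "
                        f"both {self._allele_to_group[a]!r} and {group!r}"
                    )
                self._allele_to_group[a] = group

    @property
    def groups(self) -> list[str]:
        return list(self.entries)

    def genes(self) -> set[str]:
        """Locus symbols covered by the dictionary."""
        return {parse_allele(a).gene for a in self._allele_to_group}

    def group_genes(self, group: str) -> set[str]:
        return {parse_allele(a).gene for a in self.entries[group]}

    def lookup(self, name: str) -> str | None:
        return self._allele_to_group.get(name)


def map_to_group(allele: HlaAllele, dictionary: Dictionary) -> str | None:
    """Map an allele to its dictionary group, or None when unmapped.

    The query is reduced to the dictionary's declared resolution before
    lookup; an allele of insufficient resolution maps to nothing.
    """
    if allele.resolution < dictionary.resolution:
        return None
    reduced = reduce_resolution(allele, dictionary.resolution)
    return dictionary.lookup(reduced.render())


def read_dictionary(path: str | Path) -> Dictionary:
    """Load a grouping dictionary from its TSV format.

    ``#``-prefixed header lines carry ``name=`` and ``resolution=``; body
    lines are ``group<TAB>allele`` with an optional numeric third column for
    quantitative dictionaries.
    """
    path = Path(path)
    name = path.stem
    resolution = 2
    entries: dict[str, set[str]] = {}
    values: dict[str, float] = {}
    has_values = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("name="):
                    name = body[len("name="):].strip()
                elif body.startswith("resolution="):
                    resolution = int(body[len("resolution="):].strip())
                continue
            parts = line.split("\t")
            if len(parts) not in (2, 3):
                raise DictionaryError(
                    f"{path}:{lineno}: expected 2 or 3 tab-separated columns"
                )
            group, allele = parts[0], parts[1]
            entries.setdefault(group, set()).add(allele)
            if len(parts) == 3:
                has_values = True
                try:
                    values[allele] = float(parts[2])
                except ValueError as exc:
                    raise DictionaryError(
                        f"{path}:{lineno}: non-numeric value {parts[2]!r}"
                    ) from exc
    if has_values and len(values) < sum(len(v) for v in entries.values()):
        raise DictionaryError(f"{path}: value column present but incomplete")
    return Dictionary(
        name=name,
        resolution=resolution,
        entries={g: frozenset(v) for g, v in entries.items()},
        values=values,
    )


def write_dictionary(dictionary: Dictionary, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# name={dictionary.name}\n")
        fh.write(f"# resolution={dictionary.resolution}\n")
        for group in dictionary.entries:
            for allele in sorted(dictionary.entries[group]):
                if dictionary.values:
                    fh.write(f"{group}\t{allele}\t{dictionary.values[allele]}\n")
                else:
                    fh.write(f"{group}\t{allele}\n")
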