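"""Protein-alignment tables and residue queries.

Per-gene protein alignments give, for every allele row and every labelled
position (1-based mature-protein numbering; negative labels are leader
peptide), a residue code.  The normalized text layout mirrors the IMGT
convention: the first data row is the reference sequence written explicitly;
subsequent rows use ``-`` for identity-with-reference, ``*`` for unknown and
``.`` for indel.  These tables are the substrate for amino-acid variable
expansion, NK-epitope refinement at position 80, and Grantham divergence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .nomenclature import HlaAllele, parse_allele, reduce_resolution

logger = logging.getLogger("hlakit")

UNKNOWN = "*"
INDEL = "."
IDENTITY = "-"


class AlignmentError(ValueError):
    """Raised for malformed alignment files."""


class UnmappedAlleleError(KeyError):
    """Raised when no alignment row shares the query's 2-field prefix."""


@dataclass
class AlignmentTable:
    """Explicit residue matrix for one gene.

    ``residues`` is indexed by allele name with one column per position
    label; every cell is an explicit amino-acid letter, ``*`` (unknown) or
    ``.`` (indel) — identity codes are resolved at parse time.  The first
    row is the reference and contains no unknown/indel codes.
    """

    gene: str
    positions: list[int]
    residues: pd.DataFrame  # alleles x positions

    def __post_init__(self) -> None:
        self._rows = [parse_allele(a) for a in self.residues.index]

    @property
    def reference_allele(self) -> str:
        return str(self.residues.index[0])

    @property
    def alleles(self) -> list[str]:
        return list(self.residues.index)

    # -- allele -> row resolution ------------------------------------------

    def match_row(self, allele: HlaAllele | str) -> str:
        """Resolve an allele to an alignment row by longest-prefix match.

        The query is reduced to 2-field; candidate rows must share that
        prefix.  Among candidates the row sharing the longest field prefix
        with the *full* query wins; ties break by file order.  No candidate
        raises :class:`UnmappedAlleleError`.
        """
        if isinstance(allele, str):
            allele = parse_allele(allele)
        if allele.gene != self.gene:
            raise UnmappedAlleleError(
                f"allele {allele.render()} is not from gene {self.gene}"
            )
        need = min(2, allele.resolution)
        prefix = allele.fields[:need]
        best: str | None = None
        best_len = -1
        for name, row in zip(self.residues.index, self._rows):
            if row.fields[: len(prefix)] != prefix:
                continue
            shared = 0
            for a, b in zip(allele.fields, row.fields):
                if a != b:
                    break
                shared += 1
            if shared > best_len:
                best, best_len = str(name), shared
        if best is None:
            raise UnmappedAlleleError(
                f"no alignment row for {allele.render()} "
                f"(2-field prefix {allele.gene}*{':'.join(prefix)})"
            )
        return best


def parse_alignment(text: str) -> AlignmentTable:
    """Parse the normalized alignment layout into an explicit residue table.

    Header lines: ``# gene=<symbol>`` and ``# positions=<comma-separated
    integer labels>``.  Data lines: ``allele<TAB>sequence``.  The reference
    (first) row must be fully explicit; later rows may use ``-``/``*``/``.``
    codes, which are resolved here so every stored cell is explicit.
    """
    gene: str | None = None
    positions: list[int] | None = None
    rows: list[tuple[str, str]] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if body.startswith("gene="):
                gene = body[len("gene="):].strip()
            elif body.startswith("positions="):
                positions = [
                    int(tok) for tok in body[len("positions="):].split(",")
                ]
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise AlignmentError(f"line {lineno}: expected allele<TAB>sequence")
        rows.append((parts[0], parts[1]))
    if gene is None or positions is None:
        raise AlignmentError("missing '# gene=' or '# positions=' header")
    if not rows:
        raise AlignmentError("alignment has no reference row")
    seen: set[str] = set()
    for name, _ in rows:
        if name in seen:
            raise AlignmentError(f"duplicate allele row {name!r}")
        seen.add(name)
    width = len(positions)
    ref_name, ref_seq = rows[0]
    if len(ref_seq) != width:
        raise AlignmentError(
            f"reference row has {len(ref_seq)} residues, expected {width}"
        )
    if any(c in (UNKNOWN, INDEL, IDENTITY) for c in ref_seq):
        raise AlignmentError("reference row must be fully explicit")
    data: dict[str, list[str]] = {ref_name: list(ref_seq)}
    for name, seq in rows[1:]:
        if len(seq) != width:
            raise AlignmentError(
                f"row {name} has {len(seq)} residues, expected {width} (ragged)"
            )
        data[name] = [
            ref_seq[i] if c == IDENTITY else c for i, c in enumerate(seq)
        ]
    frame = pd.DataFrame.from_dict(data, orient="index", columns=positions)
    parsed_gene = parse_allele(ref_name).gene
    if parsed_gene != gene:
        raise AlignmentError(
            f"reference allele {ref_name} does not belong to gene {gene}"
        )
    return AlignmentTable(gene=gene, positions=list(positions), residues=frame)


def render_alignment(table: AlignmentTable) -> str:
    """Serialize back to the normalized layout (identity codes restored)."""
    lines = [
        f"# gene={table.gene}",
        f"# positions={','.join(str(p) for p in table.positions)}",
    ]
    ref = table.residues.iloc[0]
    lines.append(f"{table.reference_allele}\t{''.join(ref)}")
    for name in table.residues.index[1:]:
        row = table.residues.loc[name]
        coded = "".join(
            IDENTITY if r == ref.iloc[i] else r for i, r in enumerate(row)
        )
        lines.append(f"{name}\t{coded}")
    return "\n".join(lines) + "\n"


def read_alignment(path: str | Path) -> AlignmentTable:
    return parse_alignment(Path(path).read_text())


def residues_at(
    table: AlignmentTable,
    allele: HlaAllele | str,
    positions: Sequence[int],
) -> list[str]:
    """Residue codes for one allele at the requested position labels.

    The allele is resolved to a row via :meth:`AlignmentTable.match_row`;
    unknown residues come back as ``*`` and propagate as missing values
    downstream rather than raising.
    """
    row_name = table.match_row(allele)
    row = table.residues.loc[row_name]
    out = []
    for pos in positions:
        if pos not in table.residues.columns:
            raise KeyError(f"position {pos} not in {table.gene} alignment")
        out.append(str(row[pos]))
    return out


def variable_positions(
    table: AlignmentTable, alleles: Iterable[HlaAllele | str]
) -> list[int]:
    """Positions with >=2 distinct non-unknown residues among ``alleles``.

    The allele set is typically restricted to those observed in a dataset so
    the amino-acid expansion only creates variables that can vary.  Unknown
    codes carry no variation; indels count as a residue state.
    """
    rows: list[str] = []
    seen: set[str] = set()
    for a in alleles:
        name = table.match_row(a)
        if name not in seen:
            seen.add(name)
            rows.append(name)
    if not rows:
        return []
    sub = table.residues.loc[rows]
    out = []
    for pos in table.positions:
        vals = {v for v in sub[pos] if v != UNKNOWN}
        if len(vals) >= 2:
            out.append(pos)
    return sorted(out)
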