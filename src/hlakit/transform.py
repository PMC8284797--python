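"""Transformation of HLA/KIR genotype data into association-ready variables.

Each transform produces an :class:`Experiment` — an individuals-by-variables
value matrix (diploid copy counts 0/1/2, binary indicators, or continuous
scores) with per-variable metadata: the grouping label used by omnibus
tests, the inheritance models that make sense for the variable's coding,
and its population frequency.  A :class:`Dataset` collects experiments next
to the phenotype table under a global variable-name uniqueness contract, so
any variable can be substituted into a model formula unambiguously.

Missing-call policy: if either allele slot of a gene is missing for an
individual, every variable derived from that gene is missing for that
individual.  This keeps the diploid conservation invariant exact — on
complete calls, allele-count and residue-count variables sum to 2 per
individual per gene/group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .alignment import INDEL, UNKNOWN, AlignmentTable, UnmappedAlleleError, residues_at, variable_positions
from .nomenclature import (
    Dictionary,
    HlaCalls,
    ResolutionError,
    map_to_group,
    parse_allele,
    reduce_resolution,
)
from .resources import GranthamMatrix, load_region

logger = logging.getLogger("hlakit")

#: inheritance models applicable per variable kind
MODELS_COUNT = ("additive", "dominant", "recessive", "overdominant")
MODELS_BINARY = ("additive", "dominant")
MODELS_CONTINUOUS = ("additive",)

CLASS_I_GENES = ("A", "B", "C")


class AssemblyError(ValueError):
    """Raised when experiments cannot be combined into a Dataset."""


@dataclass
class Experiment:
    """A named variables-by-individuals value matrix with variable metadata.

    ``values``: frame indexed by individual, one column per variable.
    ``var_meta``: frame indexed by variable with columns ``kind`` (count /
    binary / continuous), ``group`` (omnibus grouping label or None),
    ``models`` (comma-joined applicable inheritance models), ``freq``
    (allele frequency for counts, carrier frequency for binaries, NaN for
    continuous).  ``attrs`` carries transform-specific context (e.g. the
    alignment behind an amino-acid experiment).
    """

    name: str
    values: pd.DataFrame
    var_meta: pd.DataFrame
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()]
            raise AssemblyError(
                f"experiment {self.name}: duplicate variable names {list(dups)}"
            )
        if list(self.var_meta.index) != list(self.values.columns):
            self.var_meta = self.var_meta.reindex(self.values.columns)
        counts = self.values.loc[
            :, self.var_meta["kind"].isin(["count", "binary"])
        ].to_numpy(dtype=float)
        finite = counts[np.isfinite(counts)]
        if finite.size and not ((finite >= 0) & (finite <= 2)).all():
            raise ValueError(
                f"experiment {self.name}: copy-number values outside [0, 2]"
            )

    @property
    def variables(self) -> list[str]:
        return list(self.values.columns)

    def applicable_models(self, variable: str) -> tuple[str, ...]:
        return tuple(self.var_meta.loc[variable, "models"].split(","))


@dataclass
class Dataset:
    """Named experiments plus the phenotype table, sharing one individual
    index; variable names are unique across the whole collection."""

    experiments: dict[str, Experiment]
    pheno: pd.DataFrame

    def variable(self, name: str) -> tuple[Experiment, pd.Series]:
        for exp in self.experiments.values():
            if name in exp.values.columns:
                return exp, exp.values[name]
        raise KeyError(f"variable {name!r} not in any experiment")

    @property
    def individuals(self) -> pd.Index:
        return self.pheno.index


def _make_meta(
    variables: Sequence[str],
    kind: str,
    models: tuple[str, ...],
    freqs: Mapping[str, float] | None = None,
    groups: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    meta = pd.DataFrame(index=pd.Index(variables, name="variable"))
    meta["kind"] = kind
    meta["group"] = (
        [groups.get(v) for v in variables] if groups else None
    )
    meta["models"] = ",".join(models)
    meta["freq"] = (
        [freqs.get(v, np.nan) for v in variables] if freqs is not None else np.nan
    )
    return meta


def _count_frequencies(values: pd.DataFrame) -> dict[str, float]:
    """Allele frequency per copy-count variable: copies / (2 * non-missing n)."""
    out = {}
    for col in values.columns:
        v = values[col].dropna()
        out[col] = float(v.sum() / (2 * len(v))) if len(v) else np.nan
    return out


def _carrier_frequencies(values: pd.DataFrame) -> dict[str, float]:
    out = {}
    for col in values.columns:
        v = values[col].dropna()
        out[col] = float((v > 0).mean()) if len(v) else np.nan
    return out


def _gene_pairs(
    calls: HlaCalls, gene: str
) -> pd.DataFrame:
    """Two string columns (a1, a2) for one gene, NaN-preserving."""
    return pd.DataFrame(
        {
            "a1": calls.frame[f"{gene}_1"],
            "a2": calls.frame[f"{gene}_2"],
        }
    )


# ---------------------------------------------------------------------------
# HLA allele and group counts
# ---------------------------------------------------------------------------

def hla_allele_counts(
    calls: HlaCalls, n_fields: int = 2, drop_null: bool = False
) -> Experiment:
    """Diploid copy counts per distinct allele at ``n_fields`` resolution.

    Alleles that cannot be reduced to ``n_fields`` become missing (logged);
    a missing slot makes the whole gene missing for that individual.  With
    ``drop_null`` set, N-suffixed (not expressed) alleles are treated as
    missing as well.
    """
    per_gene: list[pd.DataFrame] = []
    n_unreducible = 0
    for gene in calls.genes:
        pairs = _gene_pairs(calls, gene)
        # reduce each distinct allele string once, then map
        cache: dict[str, object] = {}

        def _reduce(x):
            nonlocal n_unreducible
            if x not in cache:
                a = parse_allele(x)
                if drop_null and a.is_null:
                    cache[x] = np.nan
                else:
                    try:
                        cache[x] = reduce_resolution(a, n_fields).render()
                    except ResolutionError:
                        n_unreducible += 1
                        cache[x] = np.nan
            return cache[x]

        reduced = pairs.copy()
        for col in ("a1", "a2"):
            reduced[col] = pairs[col].map(
                lambda x: np.nan if pd.isna(x) else _reduce(str(x))
            )
        complete = reduced.dropna()
        variables = sorted(set(complete["a1"]) | set(complete["a2"]))
        var_idx = {v: i for i, v in enumerate(variables)}
        arr = np.full((len(calls.individuals), len(variables)), np.nan)
        row_pos = pd.Series(
            np.arange(len(calls.individuals)), index=calls.individuals
        )
        rows = row_pos.loc[complete.index].to_numpy()
        arr[rows, :] = 0.0
        for col in ("a1", "a2"):
            cols = complete[col].map(var_idx).to_numpy(dtype=int)
            np.add.at(arr, (rows, cols), 1.0)
        per_gene.append(
            pd.DataFrame(arr, index=calls.individuals, columns=variables)
        )
    if n_unreducible:
        logger.warning(
            "hla_allele_counts: %d calls below %d-field resolution set missing",
            n_unreducible, n_fields,
        )
    values = pd.concat(per_gene, axis=1) if per_gene else pd.DataFrame(
        index=calls.individuals
    )
    meta = _make_meta(
        values.columns, "count", MODELS_COUNT, _count_frequencies(values)
    )
    return Experiment("hla_alleles", values, meta, attrs={"n_fields": n_fields})


def hla_group_counts(
    calls: HlaCalls, dictionary: Dictionary, name: str | None = None
) -> Experiment:
    """Copy counts per dictionary group (supertypes, G groups, custom).

    Alleles mapping to no group contribute to no variable; the number of
    unmapped alleles is logged.  Genes not covered by the dictionary do not
    force missingness; a missing call at a covered gene blanks the groups
    that draw on that gene.
    """
    covered = {g: dictionary.group_genes(g) for g in dictionary.groups}
    variables = dictionary.groups
    mat = pd.DataFrame(
        0.0, index=calls.individuals, columns=variables, dtype=float
    )
    n_unmapped = 0
    gene_missing = {
        gene: calls.frame[[f"{gene}_1", f"{gene}_2"]].isna().any(axis=1)
        for gene in calls.genes
    }
    for gene in calls.genes:
        if gene not in dictionary.genes():
            continue
        pairs = _gene_pairs(calls, gene)
        for col in ("a1", "a2"):
            for ind, x in pairs[col].dropna().items():
                group = map_to_group(parse_allele(str(x)), dictionary)
                if group is None:
                    n_unmapped += 1
                else:
                    mat.loc[ind, group] += 1
    for group, genes in covered.items():
        miss = pd.Series(False, index=calls.individuals)
        for gene in genes:
            if gene in gene_missing:
                miss |= gene_missing[gene]
        mat.loc[miss, group] = np.nan
    # groups spanning several genes (e.g. Bw4 on HLA-A and -B) can tally
    # above the diploid bound; copy dose saturates at 2
    over = (mat > 2).sum().sum()
    if over:
        logger.info(
            "hla_group_counts(%s): %d values clipped to the diploid bound",
            dictionary.name, int(over),
        )
        mat = mat.clip(upper=2)
    if n_unmapped:
        logger.info(
            "hla_group_counts(%s): %d alleles unmapped", dictionary.name, n_unmapped
        )
    meta = _make_meta(
        variables, "count", MODELS_COUNT, _count_frequencies(mat)
    )
    return Experiment(name or f"hla_{dictionary.name}", mat, meta,
                      attrs={"dictionary": dictionary.name})


# ---------------------------------------------------------------------------
# Amino-acid expansion
# ---------------------------------------------------------------------------

def aa_counts(
    calls: HlaCalls,
    tables: Mapping[str, AlignmentTable] | AlignmentTable,
    drop_null: bool = False,
) -> Experiment:
    """Residue copy counts at every variable amino-acid position.

    One variable per (gene, position, residue) named ``<GENE>_<pos>_<res>``
    with omnibus group ``<GENE>_<pos>``; positions are restricted to those
    actually variable among the dataset's alleles.  Unknown residues and
    unmappable alleles make the individual missing for the affected
    variables (logged), never an error.
    """
    if isinstance(tables, AlignmentTable):
        tables = {tables.gene: tables}
    blocks: list[pd.DataFrame] = []
    groups: dict[str, str] = {}
    n_unmapped = 0
    observed_alleles: dict[str, set[str]] = {}
    allele_freqs: dict[str, dict[str, float]] = {}
    for gene in calls.genes:
        if gene not in tables:
            continue
        table = tables[gene]
        alleles = calls.alleles(gene)
        if drop_null:
            alleles = {a for a in alleles if not parse_allele(a).is_null}
        mappable = set()
        for a in alleles:
            try:
                table.match_row(a)
                mappable.add(a)
            except UnmappedAlleleError:
                n_unmapped += 1
        observed_alleles[gene] = mappable
        stacked = pd.concat(
            [calls.frame[f"{gene}_1"], calls.frame[f"{gene}_2"]]
        ).dropna().astype(str)
        allele_freqs[gene] = (
            (stacked.value_counts() / len(stacked)).to_dict() if len(stacked) else {}
        )
        if not mappable:
            continue
        positions = variable_positions(table, mappable)
        if not positions:
            continue
        residue_of = {
            a: dict(zip(positions, residues_at(table, a, positions)))
            for a in mappable
        }
        variables: list[str] = []
        for pos in positions:
            residues = sorted(
                {residue_of[a][pos] for a in mappable} - {UNKNOWN}
            )
            for res in residues:
                var = f"{gene}_{pos}_{res}"
                variables.append(var)
                groups[var] = f"{gene}_{pos}"
        mat = pd.DataFrame(
            np.nan, index=calls.individuals, columns=variables, dtype=float
        )
        pairs = _gene_pairs(calls, gene)
        for ind, row in pairs.iterrows():
            a1, a2 = row["a1"], row["a2"]
            if pd.isna(a1) or pd.isna(a2):
                continue
            a1, a2 = str(a1), str(a2)
            if drop_null and (
                parse_allele(a1).is_null or parse_allele(a2).is_null
            ):
                continue
            if a1 not in residue_of or a2 not in residue_of:
                continue
            for pos in positions:
                r1, r2 = residue_of[a1][pos], residue_of[a2][pos]
                if r1 == UNKNOWN or r2 == UNKNOWN:
                    continue  # missing at this position only
                # zero-fill the whole position group, then add the two copies
                for var in [v for v in variables if groups[v] == f"{gene}_{pos}"]:
                    mat.loc[ind, var] = 0.0
                mat.loc[ind, f"{gene}_{pos}_{r1}"] += 1
                mat.loc[ind, f"{gene}_{pos}_{r2}"] += 1
        blocks.append(mat)
    if n_unmapped:
        logger.warning("aa_counts: %d alleles had no alignment row", n_unmapped)
    values = pd.concat(blocks, axis=1) if blocks else pd.DataFrame(
        index=calls.individuals
    )
    meta = _make_meta(
        values.columns, "count", MODELS_COUNT,
        _count_frequencies(values), groups,
    )
    return Experiment(
        "hla_aa", values, meta,
        attrs={
            "tables": dict(tables),
            "observed_alleles": observed_alleles,
            "allele_frequencies": allele_freqs,
        },
    )


# ---------------------------------------------------------------------------
# Intra-individual diversity
# ---------------------------------------------------------------------------

def heterozygosity(calls: HlaCalls, n_fields: int = 2) -> Experiment:
    """Binary heterozygosity indicator per gene at a given resolution.

    1 iff the two reduced alleles differ; missing if either call is missing
    or cannot be reduced.
    """
    cols = {}
    for gene in calls.genes:
        pairs = _gene_pairs(calls, gene)
        vals = []
        for _, row in pairs.iterrows():
            a1, a2 = row["a1"], row["a2"]
            if pd.isna(a1) or pd.isna(a2):
                vals.append(np.nan)
                continue
            try:
                r1 = reduce_resolution(parse_allele(str(a1)), n_fields).render()
                r2 = reduce_resolution(parse_allele(str(a2)), n_fields).render()
            except ResolutionError:
                vals.append(np.nan)
                continue
            vals.append(float(r1 != r2))
        cols[f"{gene}_het"] = vals
    values = pd.DataFrame(cols, index=calls.individuals)
    meta = _make_meta(
        values.columns, "binary", MODELS_BINARY, _carrier_frequencies(values)
    )
    return Experiment("hla_het", values, meta, attrs={"n_fields": n_fields})


def grantham_divergence(
    calls: HlaCalls,
    tables: Mapping[str, AlignmentTable] | AlignmentTable,
    matrix: GranthamMatrix,
    region: str | Sequence[int] = "ARD",
    genes: Sequence[str] = CLASS_I_GENES,
) -> Experiment:
    """Evolutionary divergence of each class I allele pair.

    For each gene the value is the mean Grantham distance d(residue1,
    residue2) over the region's positions; positions where either residue
    is unknown or an indel are excluded from both numerator and denominator.
    Homozygotes score 0.  ``region`` is a preset name (``ARD``,
    ``B_pocket``, ``F_pocket``) or an explicit position list.
    """
    if isinstance(tables, AlignmentTable):
        tables = {tables.gene: tables}
    positions_wanted = (
        load_region(region) if isinstance(region, str) else [int(p) for p in region]
    )
    cols = {}
    n_empty = 0
    for gene in calls.genes:
        if gene not in genes or gene not in tables:
            continue
        table = tables[gene]
        region_pos = [p for p in positions_wanted if p in table.residues.columns]
        pairs = _gene_pairs(calls, gene)
        cache: dict[str, dict[int, str]] = {}

        def res_map(allele: str) -> dict[int, str] | None:
            if allele not in cache:
                try:
                    cache[allele] = dict(
                        zip(region_pos, residues_at(table, allele, region_pos))
                    )
                except UnmappedAlleleError:
                    cache[allele] = None  # type: ignore[assignment]
            return cache[allele]

        vals = []
        for _, row in pairs.iterrows():
            a1, a2 = row["a1"], row["a2"]
            if pd.isna(a1) or pd.isna(a2):
                vals.append(np.nan)
                continue
            m1, m2 = res_map(str(a1)), res_map(str(a2))
            if m1 is None or m2 is None:
                vals.append(np.nan)
                continue
            dists = [
                matrix.distance(m1[p], m2[p])
                for p in region_pos
                if m1[p] not in (UNKNOWN, INDEL) and m2[p] not in (UNKNOWN, INDEL)
            ]
            if not dists:
                n_empty += 1
                vals.append(np.nan)
                continue
            vals.append(float(np.mean(dists)))
        cols[f"{gene}_divergence"] = vals
    if n_empty:
        logger.warning(
            "grantham_divergence: %d individuals had no usable positions", n_empty
        )
    values = pd.DataFrame(cols, index=calls.individuals)
    meta = _make_meta(values.columns, "continuous", MODELS_CONTINUOUS)
    return Experiment("hla_divergence", values, meta,
                      attrs={"region": region})


# ---------------------------------------------------------------------------
# NK-cell ligand groups, KIR presence, interactions
# ---------------------------------------------------------------------------

def nk_ligands(
    calls: HlaCalls,
    dictionary: Dictionary,
    tables: Mapping[str, AlignmentTable] | AlignmentTable | None = None,
    refine_bw4_80: bool = False,
) -> Experiment:
    """Bw4/Bw6/C1/C2 epitope copy counts via the ligand matching table.

    With ``refine_bw4_80`` the Bw4 count is split by the residue at mature
    position 80 (Thr -> ``Bw4_80T``, Ile -> ``Bw4_80I``), the dimorphism
    that modulates KIR3DL1 binding; this is the only alignment-derived step
    and requires the relevant gene alignments.
    """
    base = hla_group_counts(calls, dictionary, name="hla_NK_ligands")
    if not refine_bw4_80:
        return base
    if tables is None:
        raise ValueError("refine_bw4_80 requires protein alignments")
    if isinstance(tables, AlignmentTable):
        tables = {tables.gene: tables}
    values = base.values.copy()
    for var in ("Bw4_80T", "Bw4_80I"):
        values[var] = 0.0
    bw4_genes = dictionary.group_genes("Bw4") if "Bw4" in dictionary.entries else set()
    n_unresolved = 0
    for gene in calls.genes:
        if gene not in bw4_genes:
            continue
        pairs = _gene_pairs(calls, gene)
        for col in ("a1", "a2"):
            for ind, x in pairs[col].dropna().items():
                allele = parse_allele(str(x))
                if map_to_group(allele, dictionary) != "Bw4":
                    continue
                table = tables.get(gene)
                res = None
                if table is not None and 80 in table.residues.columns:
                    try:
                        res = residues_at(table, allele, [80])[0]
                    except UnmappedAlleleError:
                        res = None
                if res == "T":
                    values.loc[ind, "Bw4_80T"] += 1
                elif res == "I":
                    values.loc[ind, "Bw4_80I"] += 1
                else:
                    n_unresolved += 1
    if n_unresolved:
        logger.warning(
            "nk_ligands: %d Bw4 alleles had no position-80 residue", n_unresolved
        )
    # Bw4 missingness propagates to its refined splits
    values.loc[base.values["Bw4"].isna(), ["Bw4_80T", "Bw4_80I"]] = np.nan
    values[["Bw4_80T", "Bw4_80I"]] = values[["Bw4_80T", "Bw4_80I"]].clip(upper=2)
    values = values.drop(columns=["Bw4"])
    meta = _make_meta(
        values.columns, "count", MODELS_COUNT, _count_frequencies(values)
    )
    return Experiment("hla_NK_ligands", values, meta,
                      attrs={"dictionary": dictionary.name, "refined": True})


def kir_presence(raw: pd.DataFrame) -> Experiment:
    """Binary presence variables from a KIR gene-content table.

    Accepts ``1``/``Y`` for presence and ``0``/``N`` for absence,
    case-insensitively; any other code becomes missing with a warning.  A
    column with no coercible value at all is a format error.
    """
    mapping = {"1": 1.0, "Y": 1.0, "0": 0.0, "N": 0.0}
    values = pd.DataFrame(index=raw.index)
    for col in raw.columns:
        coerced = []
        bad = 0
        for v in raw[col]:
            if pd.isna(v):
                coerced.append(np.nan)
                continue
            key = str(v).strip().upper()
            if key.endswith(".0"):  # numeric round-trip artifacts
                key = key[:-2]
            if key in mapping:
                coerced.append(mapping[key])
            else:
                bad += 1
                coerced.append(np.nan)
        s = pd.Series(coerced, index=raw.index, dtype=float)
        if s.notna().sum() == 0 and len(s) > 0:
            raise ValueError(
                f"KIR column {col!r}: no value coercible to presence/absence"
            )
        if bad:
            logger.warning(
                "kir_presence: column %s had %d unrecognised codes set missing",
                col, bad,
            )
        values[col] = s
    meta = _make_meta(
        values.columns, "binary", MODELS_BINARY, _carrier_frequencies(values)
    )
    return Experiment("kir_genes", values, meta)


def hla_kir_interactions(
    ligands: Experiment,
    kir: Experiment,
    interactions: pd.DataFrame,
) -> Experiment:
    """Binary receptor-ligand interaction variables.

    One variable per interaction row: 1 iff the KIR gene is present AND the
    ligand-group copy count is at least 1; missing if either side is
    missing.  Rows naming absent KIR columns or ligand variables raise a
    configuration error listing every miss.
    """
    individuals = ligands.values.index.intersection(kir.values.index)
    missing_refs = []
    for _, row in interactions.iterrows():
        if row["kir_gene"] not in kir.values.columns:
            missing_refs.append(f"KIR gene {row['kir_gene']!r}")
        if row["ligand_variable"] not in ligands.values.columns:
            missing_refs.append(f"ligand variable {row['ligand_variable']!r}")
    if missing_refs:
        raise ValueError(
            "interaction table references missing data: " + ", ".join(missing_refs)
        )
    values = pd.DataFrame(index=individuals)
    for _, row in interactions.iterrows():
        lig = ligands.values.loc[individuals, row["ligand_variable"]]
        rec = kir.values.loc[individuals, row["kir_gene"]]
        out = ((lig >= 1) & (rec > 0)).astype(float)
        out[lig.isna() | rec.isna()] = np.nan
        values[row["interaction"]] = out
    meta = _make_meta(
        values.columns, "binary", MODELS_BINARY, _carrier_frequencies(values)
    )
    return Experiment("hla_kir_interactions", values, meta)


# ---------------------------------------------------------------------------
# Custom dictionaries and dataset assembly
# ---------------------------------------------------------------------------

def custom_transform(
    calls: HlaCalls, dictionary: Dictionary, mode: str = "count"
) -> Experiment:
    """User-dictionary transform: ``count``, ``binary`` or ``quantitative``.

    Count mode reproduces :func:`hla_group_counts`; binary collapses to
    carrier status; quantitative sums the dictionary's numeric per-allele
    values over both chromosomes (variables keyed by group label; unmapped
    alleles contribute 0).
    """
    if mode not in ("count", "binary", "quantitative"):
        raise ValueError(f"unknown custom mode {mode!r}")
    if mode == "quantitative" and not dictionary.values:
        raise ValueError(
            f"dictionary {dictionary.name} has no value column for "
            "quantitative mode"
        )
    base = hla_group_counts(calls, dictionary, name=f"hla_{dictionary.name}")
    if mode == "count":
        return base
    if mode == "binary":
        values = (base.values >= 1).astype(float)
        values[base.values.isna()] = np.nan
        meta = _make_meta(
            values.columns, "binary", MODELS_BINARY, _carrier_frequencies(values)
        )
        return Experiment(base.name, values, meta, attrs=base.attrs)
    # quantitative: per-group score summed over both alleles
    covered = {g: dictionary.group_genes(g) for g in dictionary.groups}
    values = pd.DataFrame(
        0.0, index=calls.individuals, columns=dictionary.groups, dtype=float
    )
    for gene in calls.genes:
        if gene not in dictionary.genes():
            continue
        pairs = _gene_pairs(calls, gene)
        for col in ("a1", "a2"):
            for ind, x in pairs[col].dropna().items():
                allele = parse_allele(str(x))
                group = map_to_group(allele, dictionary)
                if group is None:
                    continue
                key = reduce_resolution(allele, dictionary.resolution).render()
                values.loc[ind, group] += dictionary.values[key]
    gene_missing = {
        gene: calls.frame[[f"{gene}_1", f"{gene}_2"]].isna().any(axis=1)
        for gene in calls.genes
    }
    for group, genes in covered.items():
        miss = pd.Series(False, index=calls.individuals)
        for gene in genes:
            if gene in gene_missing:
                miss |= gene_missing[gene]
        values.loc[miss, group] = np.nan
    meta = _make_meta(values.columns, "continuous", MODELS_CONTINUOUS)
    return Experiment(f"hla_{dictionary.name}", values, meta,
                      attrs={"dictionary": dictionary.name, "mode": mode})


def assemble_dataset(
    experiments: Iterable[Experiment], pheno: pd.DataFrame
) -> Dataset:
    """Combine experiments and phenotypes into a :class:`Dataset`.

    Individuals are inner-joined across all experiments and the phenotype
    table (dropped IDs logged); a variable name appearing in two experiments
    or clashing with a phenotype column is an assembly error.
    """
    experiments = list(experiments)
    seen: dict[str, str] = {}
    for exp in experiments:
        for var in exp.values.columns:
            if var in seen:
                raise AssemblyError(
                    f"variable {var!r} appears in both {seen[var]!r} "
                    f"and {exp.name!r}"
                )
            if var in pheno.columns:
                raise AssemblyError(
                    f"variable {var!r} clashes with a phenotype column"
                )
            seen[var] = exp.name
    shared = pheno.index
    for exp in experiments:
        shared = shared.intersection(exp.values.index)
    dropped = len(pheno.index) - len(shared)
    if dropped:
        logger.info("assemble_dataset: %d individuals dropped by inner join", dropped)
    out = {
        exp.name: Experiment(
            exp.name, exp.values.loc[shared], exp.var_meta, exp.attrs
        )
        for exp in experiments
    }
    return Dataset(experiments=out, pheno=pheno.loc[shared])
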