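"""Seeded synthetic-data generators: genotypes, alignments, dictionaries
and phenotypes.

Every generator is a pure function of its :class:`SimConfig` (seed
included): the same configuration reproduces byte-identical output.
Genotypes are drawn as two independent alleles per gene from a per-gene
frequency table, i.e. exact Hardy-Weinberg proportions by construction
(an inbreeding-style ``hwe_f`` knob injects excess homozygosity for power
testing); LD-proxy alleles are produced by per-haplotype copy-with-fresh-
redraw, giving a haplotype correlation exactly equal to the copy
probability.  Phenotypes follow a generalized linear construction: a
linear predictor over planted effect variables feeds a logistic link
(binary), Gaussian noise (continuous), or an exponential proportional-
hazards draw with uniform censoring (survival).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .nomenclature import HlaCalls
from .transform import Dataset

DEFAULT_HLA_FREQS: dict[str, dict[str, float]] = {
    "A": {
        "A*01:01": 0.18, "A*02:01": 0.28, "A*03:01": 0.14,
        "A*11:01": 0.06, "A*24:02": 0.10, "A*26:01": 0.04,
        "A*32:01": 0.04, "A*68:01": 0.04, "A*23:01": 0.04, "A*31:01": 0.08,
    },
    "B": {
        "B*07:02": 0.14, "B*08:01": 0.12, "B*15:01": 0.07,
        "B*18:01": 0.05, "B*27:05": 0.04, "B*35:01": 0.07,
        "B*40:01": 0.06, "B*44:02": 0.09, "B*51:01": 0.06,
        "B*57:01": 0.04, "B*58:01": 0.03, "B*44:03": 0.05,
        "B*14:02": 0.04, "B*38:01": 0.04, "B*55:01": 0.04, "B*13:02": 0.06,
    },
    "C": {
        "C*01:02": 0.05, "C*02:02": 0.05, "C*03:03": 0.06, "C*03:04": 0.08,
        "C*04:01": 0.13, "C*05:01": 0.08, "C*06:02": 0.09, "C*07:01": 0.15,
        "C*07:02": 0.14, "C*08:02": 0.05, "C*12:03": 0.06, "C*15:02": 0.03,
        "C*16:01": 0.03,
    },
}

DEFAULT_KIR_FREQS: dict[str, float] = {
    "KIR3DL1": 0.94, "KIR3DS1": 0.38, "KIR2DL1": 0.97, "KIR2DL2": 0.55,
    "KIR2DL3": 0.89, "KIR2DS1": 0.37, "KIR2DS2": 0.55,
}


@dataclass
class SimConfig:
    """Simulation conditions (deterministic given ``seed``).

    ``ld_proxies`` entries are ``(source_gene, source_allele, proxy_gene,
    proxy_allele, r)``: the proxy gene's haplotypes copy the source-allele
    indicator with probability ``r`` (else a fresh draw), so the
    per-haplotype indicator correlation equals ``r``.  ``effects`` maps
    variable names (in the generated variable space) to effect sizes on the
    linear predictor scale.
    """

    n_individuals: int = 1000
    seed: int = 0
    hla_freqs: dict[str, dict[str, float]] = dataclass_field(
        default_factory=lambda: {g: dict(v) for g, v in DEFAULT_HLA_FREQS.items()}
    )
    kir_freqs: dict[str, float] = dataclass_field(
        default_factory=lambda: dict(DEFAULT_KIR_FREQS)
    )
    ld_proxies: list[tuple[str, str, str, str, float]] = dataclass_field(
        default_factory=list
    )
    effects: dict[str, float] = dataclass_field(default_factory=dict)
    outcome_family: str = "binary"
    intercept: float = 0.0
    noise_sd: float = 1.0
    baseline_hazard: float = 0.1
    censor_max: float = 20.0
    hwe_f: float = 0.0  # excess-homozygosity (inbreeding-style) parameter

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for gene, freqs in self.hla_freqs.items():
            total = sum(freqs.values())
            if not freqs or abs(total - 1.0) > 1e-6:
                raise ValueError(
                    f"gene {gene}: allele frequencies sum to {total}, not 1"
                )
        if self.outcome_family not in ("binary", "continuous", "survival"):
            raise ValueError(f"unknown outcome family {self.outcome_family!r}")


def _stream_rng(seed: int, salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, salt]))


def gen_hla_calls(cfg: SimConfig) -> HlaCalls:
    """Draw diploid HLA calls per gene under exact HWE (or ``hwe_f``)."""
    rng = _stream_rng(cfg.seed, 1)
    n = cfg.n_individuals
    ids = [f"IND{i:05d}" for i in range(n)]
    data: dict[str, list[str]] = {}
    haplotypes: dict[str, np.ndarray] = {}
    for gene in sorted(cfg.hla_freqs):
        freqs = cfg.hla_freqs[gene]
        alleles = sorted(freqs)
        p = np.array([freqs[a] for a in alleles])
        p = p / p.sum()
        a1 = rng.choice(len(alleles), size=n, p=p)
        a2 = rng.choice(len(alleles), size=n, p=p)
        if cfg.hwe_f > 0:
            force = rng.random(n) < cfg.hwe_f
            a2 = np.where(force, a1, a2)
        haplotypes[gene] = np.stack([a1, a2])
        data[f"{gene}_1"] = [alleles[i] for i in a1]
        data[f"{gene}_2"] = [alleles[i] for i in a2]
    for src_gene, src_allele, proxy_gene, proxy_allele, r in cfg.ld_proxies:
        if not 0 <= r <= 1:
            raise ValueError(f"LD proxy correlation {r} outside [0, 1]")
        src_alleles = sorted(cfg.hla_freqs[src_gene])
        src_idx = src_alleles.index(src_allele)
        p_src = cfg.hla_freqs[src_gene][src_allele]
        other = f"{proxy_gene}*99:99"
        cols: dict[int, list[str]] = {0: [], 1: []}
        for hap in (0, 1):
            src_ind = haplotypes[src_gene][hap] == src_idx
            copy = rng.random(cfg.n_individuals) < r
            fresh = rng.random(cfg.n_individuals) < p_src
            ind = np.where(copy, src_ind, fresh)
            cols[hap] = [proxy_allele if x else other for x in ind]
        data[f"{proxy_gene}_1"] = cols[0]
        data[f"{proxy_gene}_2"] = cols[1]
    frame = pd.DataFrame(data, index=pd.Index(ids, name="ID"))
    return HlaCalls(frame)


def gen_kir_calls(cfg: SimConfig) -> pd.DataFrame:
    """Independent presence draws per KIR gene, emitted as ``Y``/``N``."""
    rng = _stream_rng(cfg.seed, 2)
    n = cfg.n_individuals
    ids = [f"IND{i:05d}" for i in range(n)]
    data = {}
    for gene in sorted(cfg.kir_freqs):
        present = rng.random(n) < cfg.kir_freqs[gene]
        data[gene] = np.where(present, "Y", "N")
    return pd.DataFrame(data, index=pd.Index(ids, name="ID"))


def gen_phenotype(ds: Dataset, cfg: SimConfig) -> pd.DataFrame:
    """Simulate outcome columns over a dataset's planted-effect variables.

    The linear predictor is ``intercept + sum(effect * variable)`` using the
    variables' stored (additive) values.  Returns a frame indexed like the
    dataset: ``outcome`` for binary/continuous families, ``time`` +
    ``event`` for survival.
    """
    rng = _stream_rng(cfg.seed, 3)
    lp = pd.Series(cfg.intercept, index=ds.individuals, dtype=float)
    for var, beta in sorted(cfg.effects.items()):
        _, series = ds.variable(var)
        lp = lp + beta * series.reindex(ds.individuals).fillna(0.0)
    n = len(lp)
    if cfg.outcome_family == "binary":
        prob = 1.0 / (1.0 + np.exp(-lp.to_numpy()))
        y = (rng.random(n) < prob).astype(float)
        return pd.DataFrame({"outcome": y}, index=ds.individuals)
    if cfg.outcome_family == "continuous":
        y = lp.to_numpy() + rng.normal(0.0, cfg.noise_sd, size=n)
        return pd.DataFrame({"outcome": y}, index=ds.individuals)
    hazard = cfg.baseline_hazard * np.exp(lp.to_numpy())
    t_event = rng.exponential(1.0 / hazard)
    t_censor = rng.uniform(0, cfg.censor_max, size=n)
    time = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(float)
    return pd.DataFrame({"time": time, "event": event}, index=ds.individuals)


def gen_alignment_fixture(
    gene: str,
    n_alleles: int,
    variable_position_spec: Mapping[int, Sequence[str]],
    seed: int,
    n_positions: int | None = None,
    unknown_rate: float = 0.0,
    indel_rate: float = 0.0,
) -> str:
    """Generate a normalized alignment file for ``n_alleles`` 2-field alleles.

    ``variable_position_spec`` maps position labels to the residue sets that
    must each appear among the allele rows (e.g. ``{9: "FYL"}``); other
    positions are constant apart from optional unknown/indel codes injected
    at the given per-cell rates (never in the reference row).  The output
    round-trips through the alignment parser.
    """
    rng = _stream_rng(seed, 4)
    aas = "ARNDCQEGHILKMFPSTWVY"
    positions = sorted(variable_position_spec)
    if n_positions is None:
        n_positions = max(positions, default=0) + 3
    all_positions = sorted(set(range(1, n_positions + 1)) | set(positions))
    allele_names = [f"{gene}*{i + 1:02d}:01" for i in range(n_alleles)]
    ref_seq = {}
    for pos in all_positions:
        if pos in variable_position_spec:
            ref_seq[pos] = variable_position_spec[pos][0]
        else:
            ref_seq[pos] = aas[rng.integers(len(aas))]
    lines = [
        f"# gene={gene}",
        f"# positions={','.join(str(p) for p in all_positions)}",
        f"{allele_names[0]}\t{''.join(ref_seq[p] for p in all_positions)}",
    ]
    for i, name in enumerate(allele_names[1:], start=1):
        row = []
        for pos in all_positions:
            if pos in variable_position_spec:
                residues = list(variable_position_spec[pos])
                res = residues[i % len(residues)]
            else:
                res = ref_seq[pos]
                u = rng.random()
                if u < unknown_rate:
                    res = "*"
                elif u < unknown_rate + indel_rate:
                    res = "."
            row.append("-" if res == ref_seq[pos] else res)
        lines.append(f"{name}\t{''.join(row)}")
    return "\n".join(lines) + "\n"
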