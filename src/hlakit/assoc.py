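"""Statistical association engine.

The engine substitutes each genetic variable, in turn, for the literal
placeholder token ``term`` in a user-written model formula (e.g.
``diagnosis ~ term + sex`` or ``diagnosis ~ term + sex + term:sex``), fits
the requested family (linear, logistic, Cox proportional hazards) and
collects the term's estimate, standard error, confidence interval and
p-value into a tidy result table with multiple-testing correction.

Additional modes: Hardy-Weinberg testing (chi-square, optional
Levene-Haldane exact enumeration), frequency filtering, genetic inheritance
encodings, omnibus likelihood-ratio tests over grouped variables (e.g. all
residues at one amino-acid position), stepwise forward conditional search,
and residue-to-allele mapping for fine-mapping follow-up.

Model fitting is delegated to statsmodels (OLS / Logit) and lifelines
(CoxPHFitter, Efron tie handling); internally the substituted variable is
renamed to a reserved token so arbitrary variable names like ``A*02:01``
never meet the formula parser.
"""

from __future__ import annotations

import logging
import math
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import patsy
from scipy import stats

import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

from lifelines import CoxPHFitter

from .alignment import UNKNOWN
from .nomenclature import parse_allele
from .transform import Dataset, Experiment, _carrier_frequencies, _count_frequencies, _make_meta

logger = logging.getLogger("hlakit")

PLACEHOLDER = "term"
_TERM_RE = re.compile(r"\bterm\b")

#: reserved internal column names; guaranteed not to collide with user data
_TERM_COL = "term__x"
_COND_COL = "cond__{i}"

INHERITANCE_MODELS = ("additive", "dominant", "recessive", "overdominant")

RESULT_COLUMNS = [
    "variable", "model", "estimate", "se", "ci_lo", "ci_hi",
    "p", "p_adj", "freq", "count", "group", "round",
]


class EmptyResultError(ValueError):
    """Raised when no variable survives filtering for an association scan."""


class ApplicabilityError(ValueError):
    """Raised when an inheritance model does not fit a variable's coding."""


@dataclass
class ModelSpec:
    """Model family plus a formula template containing the ``term`` token.

    For ``family="cox"`` the template is the right-hand side only (e.g.
    ``term + age``) and ``time`` / ``event`` name the phenotype columns of
    the survival outcome.
    """

    family: str  # linear | logistic | cox
    formula_template: str
    time: str | None = None
    event: str | None = None
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if self.family not in ("linear", "logistic", "cox"):
            raise ValueError(f"unknown family {self.family!r}")
        if not _TERM_RE.search(self.formula_template):
            raise ValueError(
                f"formula template must contain the placeholder "
                f"{PLACEHOLDER!r}: {self.formula_template!r}"
            )
        if self.family == "cox" and (self.time is None or self.event is None):
            raise ValueError("cox family requires time and event column names")

    def substitute(self, replacement: str) -> str:
        return _TERM_RE.sub(replacement, self.formula_template)

    def null_formula(self) -> str:
        """Template with every term-containing element removed (for LRTs)."""
        if "~" in self.formula_template:
            lhs, rhs = self.formula_template.split("~", 1)
            lhs = lhs.strip() + " ~ "
        else:
            lhs, rhs = "", self.formula_template
        kept = [
            tok.strip() for tok in rhs.split("+")
            if tok.strip() and not _TERM_RE.search(tok)
        ]
        return lhs + (" + ".join(kept) if kept else "1")

    def covariates(self) -> list[str]:
        """Covariate tokens of the template (term-containing tokens excluded)."""
        rhs = self.formula_template.split("~", 1)[-1]
        return [
            tok.strip() for tok in rhs.split("+")
            if tok.strip() and tok.strip() != "1" and not _TERM_RE.search(tok)
        ]


@dataclass
class AssociationResult:
    """Tidy per-variable association table plus scan metadata."""

    table: pd.DataFrame
    family: str
    correction: str
    selected: list[str] = field(default_factory=list)

    def top(self, n: int = 10) -> pd.DataFrame:
        return self.table.head(n)


# ---------------------------------------------------------------------------
# Multiple-testing correction
# ---------------------------------------------------------------------------

_METHOD_MAP = {
    "bonferroni": "bonferroni",
    "holm": "holm",
    "BH": "fdr_bh",
    "fdr_bh": "fdr_bh",
    "BY": "fdr_by",
    "fdr_by": "fdr_by",
}


def adjust_pvalues(p: Sequence[float], method: str = "BH") -> np.ndarray:
    """Multiple-testing correction (bonferroni, holm, BH, BY, none).

    NaN entries are preserved and excluded from the family size m.
    """
    arr = np.asarray(p, dtype=float)
    if method == "none":
        return arr.copy()
    if method not in _METHOD_MAP:
        raise ValueError(
            f"unknown correction method {method!r}; "
            f"choose from {sorted(_METHOD_MAP) + ['none']}"
        )
    out = np.full(arr.shape, np.nan)
    mask = ~np.isnan(arr)
    if mask.any():
        out[mask] = multipletests(arr[mask], method=_METHOD_MAP[method])[1]
    return out


# ---------------------------------------------------------------------------
# Hardy-Weinberg testing
# ---------------------------------------------------------------------------

def _hwe_chisq(n0: int, n1: int, n2: int) -> tuple[float, float]:
    n = n0 + n1 + n2
    p = (2 * n2 + n1) / (2 * n)
    q = 1 - p
    exp = np.array([n * q * q, 2 * n * p * q, n * p * p])
    obs = np.array([n0, n1, n2], dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = (obs - exp) ** 2 / exp
    stat = float(np.nansum(terms[exp > 0]))
    return stat, float(stats.chi2.sf(stat, df=1))


def _hwe_exact(n0: int, n1: int, n2: int) -> float:
    """Levene-Haldane exact test: enumerate heterozygote counts conditional
    on the rare-allele count and sum the probabilities of configurations no
    more likely than the observed one."""
    n = n0 + n1 + n2
    n_rare = min(2 * n2 + n1, 2 * n0 + n1)
    het_parity = n_rare % 2
    hets = range(het_parity, n_rare + 1, 2)

    def log_prob(nh: int) -> float:
        nr_hom = (n_rare - nh) // 2
        nc_hom = n - nh - nr_hom
        return (
            nh * math.log(2)
            + math.lgamma(n + 1)
            - math.lgamma(nh + 1)
            - math.lgamma(nr_hom + 1)
            - math.lgamma(nc_hom + 1)
            + math.lgamma(n_rare + 1)
            + math.lgamma(2 * n - n_rare + 1)
            - math.lgamma(2 * n + 1)
        )

    logs = {nh: log_prob(nh) for nh in hets}
    mx = max(logs.values())
    probs = {nh: math.exp(v - mx) for nh, v in logs.items()}
    total = sum(probs.values())
    obs = probs[n1]
    return min(1.0, sum(v for v in probs.values() if v <= obs * (1 + 1e-12)) / total)


def hwe_test(
    experiment: Experiment,
    mode: str = "report",
    alpha: float = 0.05,
    test: str = "chisq",
) -> pd.DataFrame | tuple[pd.DataFrame, Experiment]:
    """Hardy-Weinberg deviation test per copy-count variable.

    Each variable's 0/1/2 copies define allele-vs-rest genotype counts
    (n0, n1, n2); the default test is the 1-df chi-square of observed vs
    expected proportions under the estimated allele frequency, ``test=
    "exact"`` switches to the Levene-Haldane enumeration.  Variables with
    fewer than 2 observed genotype classes are skipped and flagged.  In
    ``filter`` mode the experiment is additionally returned with variables
    at p < alpha removed.
    """
    if mode not in ("report", "filter"):
        raise ValueError(f"unknown HWE mode {mode!r}")
    if test not in ("chisq", "exact"):
        raise ValueError(f"unknown HWE test {test!r}")
    count_vars = [
        v for v in experiment.variables
        if experiment.var_meta.loc[v, "kind"] == "count"
    ]
    rows = []
    for var in count_vars:
        v = experiment.values[var].dropna()
        n0 = int((v == 0).sum())
        n1 = int((v == 1).sum())
        n2 = int((v == 2).sum())
        observed_classes = sum(1 for c in (n0, n1, n2) if c > 0)
        if observed_classes < 2:
            rows.append((var, n0, n1, n2, np.nan, np.nan, "skipped: <2 genotype classes"))
            continue
        if test == "chisq":
            stat, p = _hwe_chisq(n0, n1, n2)
        else:
            stat, p = np.nan, _hwe_exact(n0, n1, n2)
        rows.append((var, n0, n1, n2, stat, p, ""))
    report = pd.DataFrame(
        rows, columns=["variable", "n0", "n1", "n2", "statistic", "p", "flag"]
    )
    if mode == "report":
        return report
    drop = set(report.loc[report["p"] < alpha, "variable"])
    kept = [v for v in experiment.variables if v not in drop]
    logger.info("hwe_test: filtered %d/%d variables at alpha=%g",
                len(drop), len(count_vars), alpha)
    filtered = Experiment(
        experiment.name,
        experiment.values[kept],
        experiment.var_meta.loc[kept],
        experiment.attrs,
    )
    return report, filtered


# ---------------------------------------------------------------------------
# Inheritance encodings and frequency filtering
# ---------------------------------------------------------------------------

def encode_inheritance(
    counts: pd.Series,
    model: str,
    applicable: Iterable[str] | None = None,
) -> pd.Series:
    """Genetic inheritance encoding of a 0/1/2 copy-count vector.

    additive = copies; dominant = any copy; recessive = both copies;
    overdominant = exactly one copy.  Missing propagates.  When the
    variable's applicable-model list is supplied, an unlisted model raises
    :class:`ApplicabilityError`.
    """
    if model not in INHERITANCE_MODELS:
        raise ValueError(f"unknown inheritance model {model!r}")
    if applicable is not None and model not in tuple(applicable):
        raise ApplicabilityError(
            f"model {model!r} not applicable (allowed: {tuple(applicable)})"
        )
    if model == "additive":
        return counts.astype(float)
    if model == "dominant":
        out = (counts >= 1).astype(float)
    elif model == "recessive":
        out = (counts == 2).astype(float)
    else:  # overdominant
        out = (counts == 1).astype(float)
    out[counts.isna()] = np.nan
    return out


def variable_frequency(
    experiment: Experiment, variable: str, carrier: bool = False
) -> tuple[float, int]:
    """(frequency, carrier count) for one variable.

    Copy-count variables report allele frequency (copies / 2n) by default or
    carrier frequency on request; binary variables always report carrier
    frequency; continuous variables report NaN.
    """
    kind = experiment.var_meta.loc[variable, "kind"]
    v = experiment.values[variable].dropna()
    if kind == "continuous" or not len(v):
        return np.nan, int((v > 0).sum()) if len(v) else 0
    n_carriers = int((v > 0).sum())
    if kind == "binary" or carrier:
        return float((v > 0).mean()), n_carriers
    return float(v.sum() / (2 * len(v))), n_carriers


def frequency_filter(
    experiment: Experiment,
    lower: float = 0.0,
    upper: float = 1.0,
    carrier: bool = False,
) -> Experiment:
    """Drop variables outside the [lower, upper] frequency window.

    Binary variables are filtered on carrier frequency, copy-count variables
    on allele frequency (carrier frequency with ``carrier=True``);
    continuous variables are exempt.
    """
    if not 0 <= lower <= upper <= 1:
        raise ValueError(f"invalid frequency window [{lower}, {upper}]")
    keep = []
    for var in experiment.variables:
        kind = experiment.var_meta.loc[var, "kind"]
        if kind == "continuous":
            keep.append(var)
            continue
        f, _ = variable_frequency(experiment, var, carrier=carrier)
        if not np.isnan(f) and lower <= f <= upper:
            keep.append(var)
    return Experiment(
        experiment.name,
        experiment.values[keep],
        experiment.var_meta.loc[keep],
        experiment.attrs,
    )


# ---------------------------------------------------------------------------
# Single-variable fits
# ---------------------------------------------------------------------------

def _referenced_columns(frame: pd.DataFrame, formula: str, spec: ModelSpec) -> list[str]:
    """Frame columns mentioned by name anywhere in the formula (plus the
    survival outcome columns for Cox)."""
    cols = [
        c for c in frame.columns
        if re.search(rf"\b{re.escape(str(c))}\b", formula)
    ]
    if spec.family == "cox":
        for c in (spec.time, spec.event):
            if c not in cols:
                cols.append(c)
    return cols


def _fit_single(
    spec: ModelSpec, frame: pd.DataFrame, formula: str, coef: str
) -> dict | None:
    """Fit one substituted model and extract the coefficient named ``coef``.

    Returns None on convergence failure / perfect separation so the caller
    can emit a flagged missing-stat row instead of aborting the scan.
    """
    alpha = 1 - spec.ci_level
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if spec.family == "linear":
                fit = smf.ols(formula, data=frame, missing="drop").fit()
            elif spec.family == "logistic":
                fit = smf.logit(formula, data=frame, missing="drop").fit(
                    disp=False, maxiter=200
                )
                if not fit.mle_retvals.get("converged", True):
                    return None
            else:
                cph = CoxPHFitter()
                use = frame[_referenced_columns(frame, formula, spec)].dropna()
                cph.fit(
                    use, duration_col=spec.time, event_col=spec.event,
                    formula=formula,
                )
                s = cph.summary.loc[coef]
                z = stats.norm.ppf(1 - alpha / 2)
                return {
                    "estimate": float(s["coef"]),
                    "se": float(s["se(coef)"]),
                    "ci_lo": float(s["coef"] - z * s["se(coef)"]),
                    "ci_hi": float(s["coef"] + z * s["se(coef)"]),
                    "p": float(s["p"]),
                    "llf": float(cph.log_likelihood_),
                    "nobs": int(len(use)),
                }
        if coef not in fit.params.index:
            return None
        est = float(fit.params[coef])
        se = float(fit.bse[coef])
        if not np.isfinite(est) or not np.isfinite(se) or se > 1e6:
            return None
        ci = fit.conf_int(alpha=alpha).loc[coef]
        return {
            "estimate": est,
            "se": se,
            "ci_lo": float(ci[0]),
            "ci_hi": float(ci[1]),
            "p": float(fit.pvalues[coef]),
            "llf": float(fit.llf),
            "nobs": int(fit.nobs),
        }
    except Exception as exc:
        logger.debug("fit failed: %s", exc)
        return None


def _working_frame(
    ds: Dataset, spec: ModelSpec, conditional_on: Sequence[str] = ()
) -> tuple[pd.DataFrame, str]:
    """Phenotype frame plus safe-named conditioning columns; returns the
    frame and the formula suffix conditioning on prior selections."""
    frame = ds.pheno.copy()
    suffix = ""
    for i, var in enumerate(conditional_on):
        _, series = ds.variable(var)
        col = _COND_COL.format(i=i)
        frame[col] = series.reindex(frame.index).astype(float)
        suffix += f" + {col}"
    return frame, suffix


def run_association(
    ds: Dataset,
    spec: ModelSpec,
    experiment: str,
    inheritance: str = "additive",
    correction: str = "BH",
    lower_frequency: float = 0.0,
    upper_frequency: float = 1.0,
    carrier_frequency: bool = False,
    conditional_on: Sequence[str] = (),
    exclude: Iterable[str] = (),
) -> AssociationResult:
    """Iterative placeholder-substitution association scan.

    Every variable of ``experiment`` that survives the frequency window is
    substituted for the ``term`` token, the model is fitted, and the term's
    estimate / SE / CI / p are collected; p-values are corrected across the
    scan with ``correction`` and rows sorted by corrected then nominal p.
    Variables whose coding does not support ``inheritance`` are skipped
    (logged); non-converging fits yield flagged missing-stat rows.
    """
    if experiment not in ds.experiments:
        raise KeyError(f"experiment {experiment!r} not in dataset")
    exp = ds.experiments[experiment]
    before = len(exp.variables)
    exp = frequency_filter(
        exp, lower_frequency, upper_frequency, carrier=carrier_frequency
    )
    exclude_set = set(exclude) | set(conditional_on)
    variables = [v for v in exp.variables if v not in exclude_set]
    skipped = [
        v for v in variables if inheritance not in exp.applicable_models(v)
    ]
    if skipped:
        logger.info(
            "run_association: %d variables skipped (model %s not applicable)",
            len(skipped), inheritance,
        )
    variables = [v for v in variables if v not in set(skipped)]
    if not variables:
        raise EmptyResultError(
            f"no variables to test in {experiment!r}: {before} before "
            f"filters, 0 after (window [{lower_frequency}, {upper_frequency}], "
            f"inheritance {inheritance!r})"
        )
    frame, cond_suffix = _working_frame(ds, spec, conditional_on)
    formula = spec.substitute(_TERM_COL) + cond_suffix
    rows = []
    for var in variables:
        series = exp.values[var]
        encoded = (
            encode_inheritance(series, inheritance)
            if exp.var_meta.loc[var, "kind"] in ("count", "binary")
            else series.astype(float)
        )
        frame[_TERM_COL] = encoded.reindex(frame.index)
        res = _fit_single(spec, frame, formula, _TERM_COL)
        freq, count = variable_frequency(exp, var, carrier=carrier_frequency)
        base = {
            "variable": var,
            "model": inheritance,
            "freq": freq,
            "count": count,
            "group": exp.var_meta.loc[var, "group"],
            "round": np.nan,
        }
        if res is None:
            rows.append({**base, "estimate": np.nan, "se": np.nan,
                         "ci_lo": np.nan, "ci_hi": np.nan, "p": np.nan})
        else:
            rows.append({**base, **{k: res[k] for k in
                                    ("estimate", "se", "ci_lo", "ci_hi", "p")}})
    table = pd.DataFrame(rows)
    table["p_adj"] = adjust_pvalues(table["p"].to_numpy(), correction)
    table = table[RESULT_COLUMNS].sort_values(
        ["p_adj", "p", "variable"], kind="mergesort", na_position="last"
    ).reset_index(drop=True)
    return AssociationResult(table=table, family=spec.family, correction=correction)


# ---------------------------------------------------------------------------
# Omnibus likelihood-ratio tests
# ---------------------------------------------------------------------------

def _design_rank(frame: pd.DataFrame, formula: str) -> int:
    rhs = formula.split("~", 1)[-1] if "~" in formula else formula
    mat = patsy.dmatrix(rhs or "1", frame, return_type="dataframe")
    return int(np.linalg.matrix_rank(mat.to_numpy()))


def _loglik(spec: ModelSpec, frame: pd.DataFrame, formula: str) -> tuple[float, int]:
    """(log-likelihood, design rank) of one fitted model."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if spec.family == "linear":
            fit = smf.ols(formula, data=frame, missing="drop").fit()
            return float(fit.llf), _design_rank(frame, formula)
        if spec.family == "logistic":
            y, X = patsy.dmatrices(formula, frame, return_type="dataframe")
            rank = int(np.linalg.matrix_rank(X.to_numpy()))
            fit = sm.Logit(y, X).fit(disp=False, maxiter=200)
            return float(fit.llf), rank
        cph = CoxPHFitter()
        rhs = formula.split("~", 1)[-1].strip() if "~" in formula else formula
        cph.fit(frame, duration_col=spec.time, event_col=spec.event,
                formula=rhs if rhs else "1")
        return float(cph.log_likelihood_), _design_rank(frame, rhs or "1")


def _drop_aliased(values: pd.DataFrame, base: np.ndarray) -> list[str]:
    """Greedily keep columns that increase the rank of [base | kept]."""
    kept: list[str] = []
    current = base
    rank = np.linalg.matrix_rank(current) if current.size else 0
    for col in values.columns:
        cand = np.column_stack([current, values[col].to_numpy()])
        r = np.linalg.matrix_rank(cand)
        if r > rank:
            kept.append(col)
            current, rank = cand, r
    return kept


def omnibus(
    ds: Dataset,
    spec: ModelSpec,
    experiment: str,
    correction: str = "BH",
    conditional_on: Sequence[str] = (),
) -> pd.DataFrame:
    """Per-group likelihood-ratio (omnibus) tests.

    For each omnibus group (e.g. all residues at one amino-acid position)
    the full model adds every group variable except a reference level (the
    most frequent, for stable conditioning; aliased columns dropped) to the
    covariate-only null model; the statistic is 2*(ll_full - ll_null) with
    degrees of freedom equal to the design-rank difference.  Groups reduced
    to a single non-reference level degenerate to a 1-df test and are
    flagged.
    """
    if experiment not in ds.experiments:
        raise KeyError(f"experiment {experiment!r} not in dataset")
    exp = ds.experiments[experiment]
    groups = exp.var_meta["group"].dropna()
    if groups.empty:
        raise ValueError(
            f"experiment {experiment!r} carries no omnibus group metadata"
        )
    base_frame, cond_suffix = _working_frame(ds, spec, conditional_on)
    null_formula = spec.null_formula() + cond_suffix
    rows = []
    for group in sorted(groups.unique()):
        members = list(groups.index[groups == group])
        freqs = exp.var_meta.loc[members, "freq"]
        reference = freqs.idxmax()
        others = [v for v in members if v != reference]
        flag = ""
        frame = base_frame.copy()
        safe = {}
        for i, var in enumerate(others):
            col = f"g__{i}"
            frame[col] = exp.values[var].reindex(frame.index).astype(float)
            safe[col] = var
        # listwise-complete rows over the columns the models actually use
        needed = _referenced_columns(frame, null_formula, spec) + list(safe)
        use = frame[needed].dropna()
        if not len(use):
            rows.append((group, len(members), 0, np.nan, np.nan, "no complete rows"))
            continue
        # drop aliased columns against the null design
        null_rhs = null_formula.split("~", 1)[-1] if "~" in null_formula else null_formula
        base_mat = patsy.dmatrix(null_rhs or "1", use, return_type="dataframe").to_numpy()
        kept = _drop_aliased(use[list(safe)], base_mat)
        if len(kept) < len(safe):
            flag = "aliased columns dropped"
        if len(kept) == 1:
            flag = (flag + "; " if flag else "") + "single non-reference level"
        if not kept:
            rows.append((group, len(members), 0, 0.0, 1.0,
                         (flag + "; " if flag else "") + "no informative levels"))
            continue
        full_formula = spec.substitute("(" + " + ".join(kept) + ")") + cond_suffix
        try:
            ll_full, rank_full = _loglik(spec, use, full_formula)
            ll_null, rank_null = _loglik(spec, use, null_formula)
        except Exception as exc:
            logger.warning("omnibus: group %s fit failed: %s", group, exc)
            rows.append((group, len(members), len(kept), np.nan, np.nan, "fit failed"))
            continue
        df = max(rank_full - rank_null, 0)
        stat = max(2 * (ll_full - ll_null), 0.0)
        p = float(stats.chi2.sf(stat, df)) if df > 0 else 1.0
        rows.append((group, len(members), df, stat, p, flag))
    table = pd.DataFrame(
        rows, columns=["group", "n_variables", "df", "statistic", "p", "flag"]
    )
    table["p_adj"] = adjust_pvalues(table["p"].to_numpy(), correction)
    return table.sort_values(
        ["p_adj", "p", "group"], kind="mergesort", na_position="last"
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Stepwise conditional search
# ---------------------------------------------------------------------------

def conditional_search(
    ds: Dataset,
    spec: ModelSpec,
    experiment: str,
    threshold: float = 0.05,
    correction: str = "bonferroni",
    max_rounds: int = 10,
    inheritance: str = "additive",
    collinearity_r: float = 0.999,
    **scan_kwargs,
) -> AssociationResult:
    """Stepwise forward selection of independent association signals.

    Round r re-runs the association scan conditioning on all previously
    selected variables (round 1 is exactly the unconditional scan), then
    selects the variable with the smallest corrected p-value if it passes
    ``threshold`` (ties by variable name).  A candidate nearly collinear
    (|r| > ``collinearity_r``) with a prior selection is skipped with a
    warning and the next-best considered.  The returned table stacks every
    round (column ``round``), and ``selected`` records the chosen sequence.
    """
    if not 0 <= threshold < 1:
        raise ValueError(f"threshold must be in [0, 1), got {threshold}")
    selected: list[str] = []
    tables = []
    for rnd in range(1, max_rounds + 1):
        try:
            res = run_association(
                ds, spec, experiment,
                inheritance=inheritance, correction=correction,
                conditional_on=selected, **scan_kwargs,
            )
        except EmptyResultError:
            break
        tab = res.table.copy()
        tab["round"] = rnd
        tables.append(tab)
        candidates = tab.dropna(subset=["p_adj"])
        candidates = candidates[candidates["p_adj"] < threshold]
        pick = None
        for _, row in candidates.sort_values(
            ["p_adj", "p", "variable"], kind="mergesort"
        ).iterrows():
            var = row["variable"]
            if selected:
                _, series = ds.variable(var)
                collinear = False
                for prev in selected:
                    _, pser = ds.variable(prev)
                    pair = pd.concat([series, pser], axis=1).dropna()
                    if len(pair) < 3:
                        continue
                    r = pair.corr().iloc[0, 1]
                    if np.isnan(r) or abs(r) > collinearity_r:
                        collinear = True
                        break
                if collinear:
                    logger.warning(
                        "conditional_search: %s collinear with a prior "
                        "selection, skipped", var,
                    )
                    continue
            pick = var
            break
        if pick is None:
            break
        selected.append(pick)
    table = (
        pd.concat(tables, ignore_index=True)
        if tables else pd.DataFrame(columns=RESULT_COLUMNS)
    )
    return AssociationResult(
        table=table, family=spec.family, correction=correction,
        selected=selected,
    )


# ---------------------------------------------------------------------------
# Residue-to-allele mapping and frequency comparison
# ---------------------------------------------------------------------------

def alleles_for_aa(ds: Dataset, gene: str, position: int) -> pd.DataFrame:
    """Partition a gene's observed alleles by residue at one position.

    Supports fine-mapping follow-up: after an omnibus scan flags a position,
    this maps each residue back to the set of observed alleles that carry
    it (with allele frequencies).  Alleles with an unknown residue are
    listed under the ``*`` bucket.
    """
    aa_exp = None
    for exp in ds.experiments.values():
        if "tables" in exp.attrs and "observed_alleles" in exp.attrs:
            aa_exp = exp
            break
    if aa_exp is None:
        raise KeyError("dataset holds no amino-acid experiment")
    group = f"{gene}_{position}"
    if not (aa_exp.var_meta["group"] == group).any():
        raise KeyError(
            f"position {position} is not variable for gene {gene} in this dataset"
        )
    table = aa_exp.attrs["tables"][gene]
    alleles = sorted(aa_exp.attrs["observed_alleles"][gene])
    from .alignment import residues_at as _residues_at

    rows = []
    for allele in alleles:
        res = _residues_at(table, allele, [position])[0]
        rows.append({"residue": res, "allele": allele})
    out = pd.DataFrame(rows)
    freqs = aa_exp.attrs.get("allele_frequencies", {}).get(gene, {})
    out["frequency"] = [freqs.get(a, np.nan) for a in out["allele"]]
    return out.sort_values(["residue", "allele"]).reset_index(drop=True)


def compare_frequencies(
    experiment: Experiment,
    reference: pd.DataFrame,
    carrier: bool = False,
) -> pd.DataFrame:
    """Compare dataset variable frequencies with a local reference table.

    ``reference`` has a ``variable`` column plus one frequency column per
    population.  Output: per variable the dataset frequency, each reference
    frequency, the difference (dataset - reference), and a flag for
    variables absent from the reference.
    """
    if "variable" not in reference.columns:
        raise ValueError("reference table requires a 'variable' column")
    pops = [c for c in reference.columns if c != "variable"]
    rows = []
    ref_idx = reference.set_index("variable")
    for var in experiment.variables:
        f, _ = variable_frequency(experiment, var, carrier=carrier)
        row = {"variable": var, "dataset_freq": f}
        if var in ref_idx.index:
            row["flag"] = ""
            for pop in pops:
                rf = float(ref_idx.loc[var, pop])
                row[f"{pop}_freq"] = rf
                row[f"{pop}_diff"] = f - rf
        else:
            row["flag"] = "not in reference"
            for pop in pops:
                row[f"{pop}_freq"] = np.nan
                row[f"{pop}_diff"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
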