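"""Statistical engine versus independently scripted refits."""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats
from scipy.special import comb

import hlakit as hk
from hlakit.assoc import ApplicabilityError, EmptyResultError, _hwe_chisq, _hwe_exact
from hlakit.transform import MODELS_BINARY, MODELS_COUNT, _make_meta


def count_experiment(columns: dict[str, np.ndarray], name="geno") -> hk.Experiment:
    values = pd.DataFrame(
        {k: v.astype(float) for k, v in columns.items()},
        index=pd.Index([f"I{i}" for i in range(len(next(iter(columns.values()))))],
                       name="ID"),
    )
    freqs = {k: np.nansum(v) / (2 * np.sum(~np.isnan(v)))
             for k, v in columns.items()}
    meta = _make_meta(list(values.columns), "count", MODELS_COUNT, freqs)
    return hk.Experiment(name, values, meta)


def genotype_vector(n0: int, n1: int, n2: int) -> np.ndarray:
    return np.array([0] * n0 + [1] * n1 + [2] * n2, dtype=float)


# ---------------------------------------------------------------------------
# Hardy-Weinberg testing
# ---------------------------------------------------------------------------

def test_hwe_chisq_perfect_proportions():
    exp = count_experiment({"v": genotype_vector(25, 50, 25)})
    report = hk.hwe_test(exp)
    assert report.loc[0, "statistic"] == pytest.approx(0.0)
    assert report.loc[0, "p"] == pytest.approx(1.0)


def test_hwe_chisq_total_heterozygote_deficit():
    # n0=50, n1=0, n2=50: chi-square = n = 100 in closed form
    stat, p = _hwe_chisq(50, 0, 50)
    assert stat == pytest.approx(100.0)
    assert p < 1e-20
    exp = count_experiment({"v": genotype_vector(50, 0, 50)})
    report = hk.hwe_test(exp)
    assert report.loc[0, "statistic"] == pytest.approx(100.0)


def hwe_exact_enumeration(n0: int, n1: int, n2: int) -> float:
    """Independent Levene-Haldane oracle via exact binomial coefficients:
    P(nAB | n, nA) = C(n, nAB) C(n - nAB, (nA - nAB)/2) 2^nAB / C(2n, nA)
    summed over configurations no more probable than the observed."""
    n = n0 + n1 + n2
    na = min(2 * n2 + n1, 2 * n0 + n1)
    def prob(nab):
        if (na - nab) % 2:
            return 0.0
        naa = (na - nab) // 2
        nbb = n - nab - naa
        if naa < 0 or nbb < 0:
            return 0.0
        num = comb(n, nab, exact=True) * comb(n - nab, naa, exact=True) * 2 ** nab
        den = comb(2 * n, na, exact=True)
        return num / den
    p_obs = prob(n1)
    return min(1.0, sum(
        prob(nab) for nab in range(na + 1)
        if prob(nab) <= p_obs * (1 + 1e-12)
    ))


@pytest.mark.parametrize(
    "n0, n1, n2",
    [(21, 3, 1), (10, 25, 15), (40, 8, 2), (5, 20, 25), (13, 14, 3)],
)
def test_hwe_exact_matches_enumeration(n0, n1, n2):
    assert _hwe_exact(n0, n1, n2) == pytest.approx(
        hwe_exact_enumeration(n0, n1, n2), rel=1e-10
    )


def test_hwe_monomorphic_skipped_and_filter_mode():
    exp = count_experiment({
        "mono": genotype_vector(50, 0, 0),
        "bad": genotype_vector(40, 0, 10),
        "ok": genotype_vector(13, 24, 13),
    })
    report, filtered = hk.hwe_test(exp, mode="filter", alpha=0.05)
    flags = dict(zip(report["variable"], report["flag"]))
    assert "skipped" in flags["mono"]
    assert set(filtered.variables) == {"mono", "ok"}


# ---------------------------------------------------------------------------
# inheritance encodings, filtering, correction
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "count, expected",
    [
        (2, {"dominant": 1, "recessive": 1, "additive": 2, "overdominant": 0}),
        (1, {"dominant": 1, "recessive": 0, "additive": 1, "overdominant": 1}),
        (0, {"dominant": 0, "recessive": 0, "additive": 0, "overdominant": 0}),
    ],
)
def test_encode_inheritance_table(count, expected):
    s = pd.Series([float(count)])
    for model, val in expected.items():
        assert hk.encode_inheritance(s, model).iloc[0] == val


def test_encode_inheritance_applicability():
    s = pd.Series([0.0, 1.0])
    with pytest.raises(ApplicabilityError):
        hk.encode_inheritance(s, "recessive", applicable=MODELS_BINARY)


def test_frequency_filter_examples():
    rng = np.random.default_rng(0)
    exp = count_experiment({
        "rare": genotype_vector(99, 2, 0),     # allele freq ~0.0099
        "common": genotype_vector(50, 40, 11),
    })
    kept = hk.frequency_filter(exp, lower=0.02)
    assert kept.variables == ["common"]
    identity = hk.frequency_filter(exp, 0.0, 1.0)
    assert identity.variables == exp.variables


def test_frequency_filter_monotone_and_brute_force():
    rng = np.random.default_rng(42)
    cols = {f"v{i}": rng.integers(0, 3, 80).astype(float) for i in range(12)}
    exp = count_experiment(cols)
    windows = [(0.3, 0.7), (0.2, 0.8), (0.1, 0.9), (0.0, 1.0)]
    prev: set[str] = set()
    for lo, hi in windows:
        kept = set(hk.frequency_filter(exp, lo, hi).variables)
        brute = {
            k for k, v in cols.items()
            if lo <= np.sum(v) / (2 * len(v)) <= hi
        }
        assert kept == brute
        assert prev <= kept  # widening never removes a survivor
        prev = kept


def test_adjust_pvalues():
    assert hk.adjust_pvalues([0.01] * 10, "bonferroni")[0] == pytest.approx(0.1)
    p = np.array([0.2, 0.01, np.nan, 0.04])
    assert np.allclose(hk.adjust_pvalues(p, "none"), p, equal_nan=True)
    with pytest.raises(ValueError):
        hk.adjust_pvalues([0.5], "magic")


def test_bh_matches_step_up_formula():
    rng = np.random.default_rng(1)
    for _ in range(5):
        p = rng.random(17)
        got = hk.adjust_pvalues(p, "BH")
        # independent step-up: sort ascending, p*(m/rank), cummin from right
        m = len(p)
        order = np.argsort(p)
        scaled = p[order] * m / np.arange(1, m + 1)
        adj = np.minimum.accumulate(scaled[::-1])[::-1].clip(max=1)
        expected = np.empty(m)
        expected[order] = adj
        assert np.allclose(got, expected)


# ---------------------------------------------------------------------------
# association scans vs independent refits
# ---------------------------------------------------------------------------

def _simulated_dataset(seed=5, n=150, family="logistic"):
    rng = np.random.default_rng(seed)
    cols = {f"g{i}": rng.binomial(2, 0.3, n).astype(float) for i in range(6)}
    exp = count_experiment(cols)
    sex = rng.integers(0, 2, n).astype(float)
    lp = 0.8 * cols["g0"] - 0.3 + 0.4 * sex
    if family == "logistic":
        outcome = (rng.random(n) < 1 / (1 + np.exp(-lp))).astype(float)
        pheno = pd.DataFrame({"outcome": outcome, "sex": sex}, index=exp.values.index)
    elif family == "linear":
        pheno = pd.DataFrame(
            {"outcome": lp + rng.normal(0, 1, n), "sex": sex},
            index=exp.values.index,
        )
    else:
        t_event = rng.exponential(1 / (0.1 * np.exp(lp)))
        t_cens = rng.uniform(0, 25, n)
        pheno = pd.DataFrame(
            {"time": np.minimum(t_event, t_cens),
             "event": (t_event <= t_cens).astype(float), "sex": sex},
            index=exp.values.index,
        )
    return hk.assemble_dataset([exp], pheno)


@pytest.mark.parametrize("family", ["linear", "logistic"])
def test_run_association_matches_raw_refit(family):
    ds = _simulated_dataset(family=family)
    spec = hk.ModelSpec(family=family, formula_template="outcome ~ term + sex")
    res = hk.run_association(ds, spec, "geno", correction="BH")
    for _, row in res.table.iterrows():
        g = ds.experiments["geno"].values[row["variable"]].to_numpy()
        X = sm.add_constant(np.column_stack([g, ds.pheno["sex"].to_numpy()]))
        y = ds.pheno["outcome"].to_numpy()
        if family == "linear":
            fit = sm.OLS(y, X).fit()
        else:
            fit = sm.Logit(y, X).fit(disp=False)
        assert row["estimate"] == pytest.approx(fit.params[1], rel=1e-6)
        assert row["se"] == pytest.approx(fit.bse[1], rel=1e-6)
        assert row["p"] == pytest.approx(fit.pvalues[1], rel=1e-6, abs=1e-12)


def test_run_association_cox_matches_phreg():
    ds = _simulated_dataset(family="cox", seed=8)
    spec = hk.ModelSpec(
        family="cox", formula_template="term + sex", time="time", event="event"
    )
    res = hk.run_association(ds, spec, "geno", correction="BH")
    for _, row in res.table.iterrows():
        g = ds.experiments["geno"].values[row["variable"]].to_numpy()
        X = np.column_stack([g, ds.pheno["sex"].to_numpy()])
        # independent route: statsmodels PHReg with Efron ties
        fit = sm.PHReg(
            ds.pheno["time"].to_numpy(), X,
            status=ds.pheno["event"].to_numpy(), ties="efron",
        ).fit()
        assert row["estimate"] == pytest.approx(fit.params[0], rel=1e-4)
        assert row["se"] == pytest.approx(fit.bse[0], rel=1e-4)


def test_run_association_interaction_template():
    ds = _simulated_dataset()
    spec = hk.ModelSpec(
        family="logistic",
        formula_template="outcome ~ term + sex + term:sex",
    )
    res = hk.run_association(ds, spec, "geno")
    # main-effect coefficient is reported, not the interaction row
    g = ds.experiments["geno"].values["g0"].to_numpy()
    sex = ds.pheno["sex"].to_numpy()
    X = sm.add_constant(np.column_stack([g, sex, g * sex]))
    fit = sm.Logit(ds.pheno["outcome"].to_numpy(), X).fit(disp=False)
    row = res.table.set_index("variable").loc["g0"]
    assert row["estimate"] == pytest.approx(fit.params[1], rel=1e-6)


def test_run_association_empty_after_filter():
    ds = _simulated_dataset()
    spec = hk.ModelSpec(family="logistic", formula_template="outcome ~ term")
    with pytest.raises(EmptyResultError):
        hk.run_association(ds, spec, "geno", lower_frequency=0.999)


def test_association_invariant_to_individual_and_slot_order(tiny_calls, grantham):
    rng = np.random.default_rng(3)
    cfg = hk.SimConfig(n_individuals=120, seed=31, effects={"A*02:01": 0.6})
    calls = hk.gen_hla_calls(cfg)
    exp = hk.hla_allele_counts(calls, 2)
    ds0 = hk.assemble_dataset([exp], pd.DataFrame(index=calls.individuals))
    pheno = hk.gen_phenotype(ds0, cfg)
    spec = hk.ModelSpec(family="logistic", formula_template="outcome ~ term")

    def scan(frame):
        c = hk.HlaCalls(frame)
        e = hk.hla_allele_counts(c, 2)
        d = hk.assemble_dataset([e], pheno.loc[frame.index])
        return hk.run_association(d, spec, "hla_alleles", lower_frequency=0.05)

    base = scan(calls.frame)
    perm = scan(calls.frame.sample(frac=1, random_state=1))
    swapped_frame = calls.frame.copy()
    for gene in calls.genes:
        swapped_frame[[f"{gene}_1", f"{gene}_2"]] = (
            calls.frame[[f"{gene}_2", f"{gene}_1"]].to_numpy()
        )
    swap = scan(swapped_frame)
    for other in (perm, swap):
        a = base.table.set_index("variable").sort_index()
        b = other.table.set_index("variable").sort_index()
        assert np.allclose(a["estimate"], b["estimate"], rtol=1e-8)
        assert np.allclose(a["p"], b["p"], rtol=1e-8)


# ---------------------------------------------------------------------------
# omnibus LRT vs nested refits
# ---------------------------------------------------------------------------

def _aa_dataset(seed=17, n=180):
    al = hk.parse_alignment(hk.gen_alignment_fixture(
        "DQB1", 6, {9: "FYL", 57: "AD"}, seed=3
    ))
    freqs = {f"DQB1*{i+1:02d}:01": f
             for i, f in enumerate([0.3, 0.2, 0.15, 0.15, 0.1, 0.1])}
    cfg = hk.SimConfig(
        n_individuals=n, seed=seed, hla_freqs={"DQB1": freqs},
        effects={"DQB1_9_F": 0.9},
    )
    calls = hk.gen_hla_calls(cfg)
    aa = hk.aa_counts(calls, al)
    ds0 = hk.assemble_dataset([aa], pd.DataFrame(index=calls.individuals))
    pheno = hk.gen_phenotype(ds0, cfg)
    rng = np.random.default_rng(seed + 1)
    pheno["sex"] = rng.integers(0, 2, len(pheno)).astype(float)
    return hk.assemble_dataset([aa], pheno)


def test_omnibus_matches_nested_refit():
    ds = _aa_dataset()
    spec = hk.ModelSpec(family="logistic", formula_template="outcome ~ term + sex")
    table = hk.omnibus(ds, spec, "hla_aa").set_index("group")
    aa = ds.experiments["hla_aa"]
    for group in table.index:
        members = list(aa.var_meta.index[aa.var_meta["group"] == group])
        freqs = aa.var_meta.loc[members, "freq"]
        others = [v for v in members if v != freqs.idxmax()]
        sub = pd.concat(
            [ds.pheno[["outcome", "sex"]], aa.values[others]], axis=1
        ).dropna()
        y = sub["outcome"].to_numpy()
        X_null = sm.add_constant(sub[["sex"]].to_numpy())
        X_full = sm.add_constant(
            np.column_stack([sub[["sex"]].to_numpy(), sub[others].to_numpy()])
        )
        ll_full = sm.Logit(y, X_full).fit(disp=False).llf
        ll_null = sm.Logit(y, X_null).fit(disp=False).llf
        stat = 2 * (ll_full - ll_null)
        assert table.loc[group, "statistic"] == pytest.approx(stat, abs=1e-6)
        df = np.linalg.matrix_rank(X_full) - np.linalg.matrix_rank(X_null)
        assert table.loc[group, "df"] == df
        assert table.loc[group, "p"] == pytest.approx(
            stats.chi2.sf(stat, df), rel=1e-6
        )


def test_omnibus_constant_group_gives_p_one():
    n = 40
    values = pd.DataFrame(
        {
            "G_1_A": np.ones(n), "G_1_B": np.zeros(n),
        },
        index=pd.Index([f"I{i}" for i in range(n)], name="ID"),
    )
    meta = _make_meta(
        list(values.columns), "count", MODELS_COUNT,
        {"G_1_A": 0.5, "G_1_B": 0.0},
        {"G_1_A": "G_1", "G_1_B": "G_1"},
    )
    exp = hk.Experiment("aa", values, meta)
    rng = np.random.default_rng(0)
    pheno = pd.DataFrame(
        {"outcome": rng.integers(0, 2, n).astype(float)}, index=values.index
    )
    ds = hk.assemble_dataset([exp], pheno)
    spec = hk.ModelSpec(family="logistic", formula_template="outcome ~ term")
    table = hk.omnibus(ds, spec, "aa")
    assert table.loc[0, "statistic"] == pytest.approx(0.0)
    assert table.loc[0, "p"] == pytest.approx(1.0)


def test_omnibus_three_residue_group_df_two():
    ds = _aa_dataset()
    spec = hk.ModelSpec(family="logistic", formula_template="outcome ~ term")
    table = hk.omnibus(ds, spec, "hla_aa").set_index("group")
    assert table.loc["DQB1_9", "df"] == 2


# ---------------------------------------------------------------------------
# conditional search
# ---------------------------------------------------------------------------

def test_conditional_round_one_equals_unconditional():
    ds = _simulated_dataset(seed=9)
    spec = hk.ModelSpec(family="logistic", formula_template="outcome ~ term")
    flat = hk.run_association(ds, spec, "geno", correction="bonferroni")
    cond = hk.conditional_search(
        ds, spec, "geno", threshold=0.05, correction="bonferroni"
    )
    r1 = cond.table[cond.table["round"] == 1].drop(columns="round")
    flat_t = flat.table.drop(columns="round")
    pd.testing.assert_frame_equal(
        r1.reset_index(drop=True), flat_t.reset_index(drop=True)
    )


def test_conditional_threshold_zero_selects_nothing():
    ds = _simulated_dataset(seed=9)
    spec = hk.ModelSpec(family="logistic", formula_template="outcome ~ term")
    res = hk.conditional_search(ds, spec, "geno", threshold=0.0)
    assert res.selected == []


# ---------------------------------------------------------------------------
# residue-to-allele mapping and frequency comparison
# ---------------------------------------------------------------------------

def test_alleles_for_aa_partition():
    ds = _aa_dataset()
    buckets = hk.alleles_for_aa(ds, "DQB1", 9)
    assert set(buckets["residue"]) == {"F", "Y", "L"}
    # partition: disjoint buckets covering every observed allele
    assert buckets["allele"].is_unique
    observed = ds.experiments["hla_aa"].attrs["observed_alleles"]["DQB1"]
    assert set(buckets["allele"]) == observed
    with pytest.raises(KeyError):
        hk.alleles_for_aa(ds, "DQB1", 8)   # not a variable position


def test_alleles_for_aa_single_allele():
    al = hk.parse_alignment(hk.gen_alignment_fixture("A", 3, {5: "KR"}, seed=2))
    frame = pd.DataFrame(
        {"A_1": ["A*01:01", "A*02:01"], "A_2": ["A*02:01", "A*02:01"]},
        index=pd.Index(["S0", "S1"], name="ID"),
    )
    aa = hk.aa_counts(hk.HlaCalls(frame), al)
    pheno = pd.DataFrame({"outcome": [0.0, 1.0]}, index=frame.index)
    ds = hk.assemble_dataset([aa], pheno)
    buckets = hk.alleles_for_aa(ds, "A", 5)
    grouped = buckets.groupby("residue")["allele"].apply(set)
    assert all(len(v) >= 1 for v in grouped.values)


def test_compare_frequencies():
    exp = count_experiment({
        "A*02:01": genotype_vector(80, 20, 0),   # freq 0.10
        "A*03:01": genotype_vector(90, 10, 0),
    })
    ref = pd.DataFrame({"variable": ["A*02:01"], "EUR": [0.08]})
    table = hk.compare_frequencies(exp, ref).set_index("variable")
    assert table.loc["A*02:01", "EUR_diff"] == pytest.approx(0.02)
    assert table.loc["A*03:01", "flag"] == "not in reference"
    # dataset frequencies equal the brute-force tally
    assert table.loc["A*02:01", "dataset_freq"] == pytest.approx(0.10)
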