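import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from editkit import (
    CountTable,
    differential_table,
    fold_change,
    high_expression_subset,
    poisson_diff_pvalue,
    reversal_filter,
    simulate_count_tables,
    tmm_normalize,
)
from editkit.expression import ExpressionRecord


# --- fold-change -----------------------------------------------------------

@pytest.mark.parametrize(
    "a,b,expected",
    [
        (5296, 14463, -1.4492),   # published normalized counts, down-regulated
        (0, 18813, -14.1995),     # zero count guarded by the +1 pseudocount
        (14093, 0, 13.7828),
    ],
)
def test_fold_change_reproduces_published_values(a, b, expected):
    assert round(fold_change(a, b), 4) == expected


def test_fold_change_zero_for_equal_counts():
    for x in (0, 1, 5, 1e6):
        assert fold_change(x, x) == 0.0


@given(
    a=st.floats(min_value=0, max_value=1e7, allow_nan=False),
    b=st.floats(min_value=0, max_value=1e7, allow_nan=False),
)
def test_fold_change_antisymmetric(a, b):
    assert fold_change(a, b) == pytest.approx(-fold_change(b, a), abs=1e-12)


def test_negative_counts_rejected():
    with pytest.raises(ValueError):
        fold_change(-1, 5)


# --- TMM -------------------------------------------------------------------

def _table(arrays, names=("A", "B")):
    df = pd.DataFrame(
        {n: a for n, a in zip(names, arrays)},
        index=[f"m{i}" for i in range(len(arrays[0]))],
    )
    return CountTable(df=df)


def test_identical_samples_have_unit_factors(rng):
    counts = rng.poisson(200, size=300)
    t = _table([counts, counts])
    res = tmm_normalize(t)
    assert res.factors["A"] == pytest.approx(1.0, abs=1e-9)
    assert res.factors["B"] == pytest.approx(1.0, abs=1e-9)


def test_pure_library_depth_difference_recovered(rng):
    """Sample B is the same composition at 3x depth; the effective library
    ratio (total x factor) must recover 3 within 1% and normalized counts
    must agree."""
    mu = rng.lognormal(5, 1.5, size=500)
    a = rng.poisson(mu)
    b = rng.poisson(3 * mu)
    res = tmm_normalize(_table([a, b]))
    eff = (b.sum() * res.factors["B"]) / (a.sum() * res.factors["A"])
    assert eff == pytest.approx(3.0, rel=0.01)
    norm = res.table.df
    big = mu > 200
    rel = (norm["B"][big] + 1) / (norm["A"][big] + 1)
    assert np.median(rel) == pytest.approx(1.0, rel=0.02)


def test_trimming_makes_effective_ratio_robust_to_asymmetric_de(rng):
    """5% of genes 4-fold up in B only: the trimmed estimator keeps the
    effective library ratio for the unchanged majority within 2%."""
    mu = rng.lognormal(5, 1.5, size=600)
    a = rng.poisson(mu)
    mu_b = mu.copy()
    mu_b[:30] *= 4.0

    def eff(bb):
        res = tmm_normalize(_table([a, bb]))
        return (bb.sum() * res.factors["B"]) / (a.sum() * res.factors["A"])

    ratio = eff(rng.poisson(mu_b)) / eff(rng.poisson(mu))
    assert ratio == pytest.approx(1.0, rel=0.02)


def test_normalization_is_idempotent(rng):
    mu = rng.lognormal(5, 1.5, size=400)
    t = _table([rng.poisson(mu), rng.poisson(2.5 * mu)])
    res = tmm_normalize(t)
    res2 = tmm_normalize(res.table)
    for s in ("A", "B"):
        assert res2.factors[s] == pytest.approx(1.0, abs=1e-2)


def test_all_zero_sample_rejected():
    with pytest.raises(ValueError, match="all-zero"):
        tmm_normalize(_table([np.array([1, 2, 3]), np.zeros(3, dtype=int)]))


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
def test_tmm_factors_cross_checked_against_edger(tmp_path, rng):
    """Independent oracle: edgeR's TMM on the same table."""
    mu = rng.lognormal(5, 1.5, size=400)
    a, b, c = rng.poisson(mu), rng.poisson(2 * mu), rng.poisson(0.7 * mu)
    t = _table([a, b, c], names=("A", "B", "C"))
    csv = tmp_path / "counts.csv"
    t.df.to_csv(csv)
    script = tmp_path / "tmm.R"
    script.write_text(textwrap.dedent("""
        suppressMessages(library(edgeR))
        x <- read.csv(commandArgs(TRUE)[1], row.names = 1)
        f <- calcNormFactors(as.matrix(x), method = "TMM")
        cat(f, sep = "\\n")
    """))
    out = subprocess.run(
        ["Rscript", str(script), str(csv)], capture_output=True, text=True, check=True
    )
    expected = [float(v) for v in out.stdout.split()]
    res = tmm_normalize(t)
    got = [res.factors[s] for s in ("A", "B", "C")]
    assert got == pytest.approx(expected, rel=0.05)


# --- exact Poisson difference test ----------------------------------------

def test_equal_counts_equal_libraries_give_p_one():
    assert poisson_diff_pvalue(57, 57, 1e6, 1e6) == 1.0


def test_double_zero_is_p_one_by_convention():
    assert poisson_diff_pvalue(0, 0, 1e6, 1e6) == 1.0


from oracles import poisson_twosided as _oracle_p  # noqa: E402


def test_poisson_test_matches_brute_force_oracle(rng):
    for _ in range(200):
        n = int(rng.integers(1, 5001))
        a = int(rng.binomial(n, rng.uniform(0.05, 0.95)))
        b = n - a
        lib_a = float(rng.uniform(1e5, 1e7))
        lib_b = float(rng.uniform(1e5, 1e7))
        got = poisson_diff_pvalue(a, b, lib_a, lib_b)
        want = _oracle_p(a, b, lib_a, lib_b)
        assert got == pytest.approx(want, rel=1e-9, abs=1e-300)


def test_example_case_against_oracle():
    assert poisson_diff_pvalue(100, 200, 1e6, 1e6) == pytest.approx(
        _oracle_p(100, 200, 1e6, 1e6), rel=1e-9
    )


def test_invariant_under_sample_swap(rng):
    for _ in range(20):
        a, b = int(rng.integers(0, 500)), int(rng.integers(0, 500))
        la, lb = float(rng.uniform(1e5, 1e6)), float(rng.uniform(1e5, 1e6))
        assert poisson_diff_pvalue(a, b, la, lb) == pytest.approx(
            poisson_diff_pvalue(b, a, lb, la), rel=1e-12
        )


# --- differential table and filters ---------------------------------------

def test_published_direction_counts_in_highly_expressed_set(cfg):
    from editkit import load_table2

    df = load_table2()
    signs = np.sign([fold_change(a, b) for a, b in zip(df["adar2"], df["adar2_ea"])])
    assert (signs < 0).sum() == 13
    assert (signs > 0).sum() == 3


def test_empty_table_gives_empty_records(cfg):
    t = CountTable(df=pd.DataFrame({"A": [], "B": []}))
    assert differential_table(t, "A", "B", cfg) == []


def test_unknown_sample_rejected(cfg):
    t = _table([np.array([1]), np.array([2])])
    with pytest.raises(KeyError):
        differential_table(t, "A", "Z", cfg)


def test_null_tables_give_no_significant_calls(cfg):
    n_runs_with_fp = 0
    for seed in range(20):
        table, _ = simulate_count_tables(
            1000, {"A": 1e6, "B": 1e6}, frac_changed=0.0, rng_seed=seed
        )
        records = differential_table(table, "A", "B", cfg)
        if any(r.significant for r in records):
            n_runs_with_fp += 1
    assert n_runs_with_fp <= 1  # >= 95% of runs clean


def test_planted_two_fold_changes_recovered(cfg):
    recalls = []
    fp_runs = 0
    for seed in range(10):
        # every miRNA at mean count 1000; a 10% subset truly 2-fold changed
        table, truth = simulate_count_tables(
            500, {"A": 5e5, "B": 5e5}, frac_changed=0.1, log2_effect=1.0,
            sigma=0.0, rng_seed=100 + seed,
        )
        norm = tmm_normalize(table)
        records = differential_table(norm.table, "A", "B", cfg)
        called = {r.mirna for r in records if r.significant}
        changed = set(truth.index[truth["changed"]])
        recalls.append(len(called & changed) / len(changed))
        if called - changed:
            fp_runs += 1
    assert np.mean(recalls) >= 0.9
    assert fp_runs <= 1


def _rec(mirna, a, b, significant=True, sum_ok=True, effect_ok=True):
    return ExpressionRecord(
        mirna=mirna, count_a=a, count_b=b, log2_ratio=fold_change(a, b),
        p_value=0.001, p_adjusted=0.001 if significant else 0.9,
        significant=significant, passes_sum_filter=sum_ok,
        passes_effect_filter=effect_ok,
    )


def test_high_expression_boundary_inclusive(cfg):
    records = [_rec("keep", 5000, 5000), _rec("drop", 5000, 4999)]
    kept = high_expression_subset(records, cfg)
    assert [r.mirna for r in kept] == ["keep"]


def test_reversal_requires_strict_sign_opposition():
    c1 = [_rec("m1", 100, 300), _rec("m2", 100, 300), _rec("m3", 100, 300)]
    for r in c1:
        assert r.log2_ratio < 0
    c2 = [_rec("m1", 140, 100), _rec("m2", 90, 100), _rec("m3", 100, 100)]
    assert reversal_filter(c1, c2) == ["m1"]


def test_unselected_records_never_reverse():
    c1 = [_rec("m1", 100, 300, significant=False)]
    c2 = [_rec("m1", 300, 100)]
    assert reversal_filter(c1, c2) == []
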