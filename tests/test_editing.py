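import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from editkit import (
    MiRNAReference,
    PositionTally,
    amplicon_editing,
    binomial_site_pvalue,
    call_sample,
    call_sites,
    compare_conditions,
    context_profile,
)
from editkit.editing import STATUS_ND, STATUS_SIGNIFICANT


def _tally_for(ref, rows):
    """rows: {pos0: {'A': n, 'G': n, ...}}"""
    t = PositionTally.empty(ref)
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    for pos, counts in rows.items():
        for base, n in counts.items():
            t.counts[pos, idx[base]] = n
    return t


REF = MiRNAReference(id="m1", sequence="TTACGGTACCGTTAGCATCGGA")
A_POS = 2  # 0-based position of an A outside the seed's first base


# --- binomial p-value ------------------------------------------------------

def test_zero_alternates_gives_p_one():
    assert binomial_site_pvalue(0, 1000, 0.001) == 1.0
    assert binomial_site_pvalue(0, 0, 0.001) == 1.0


def test_upper_tail_matches_exact_rational_summation():
    # frozen from an exact Fraction-arithmetic oracle:
    # P(X >= 5), X ~ Binomial(1000, 0.001) = 3.63687802952179e-3
    p = binomial_site_pvalue(5, 1000, 0.001)
    assert p == pytest.approx(3.63687802952179e-3, rel=1e-12)


def test_saturated_site_is_tiny_but_positive():
    p = binomial_site_pvalue(50, 50, 0.001)
    assert 0.0 < p <= 1e-100  # bounded by 0.001**50 = 1e-150


def test_agrees_with_direct_pmf_summation_oracle(rng):
    """Direct log-gamma/recurrence tail summation oracle, n <= 1e4."""
    from oracles import binom_upper_tail

    for _ in range(50):
        n = int(rng.integers(1, 10001))
        k = int(rng.integers(1, min(n, 30) + 1))
        rate = float(rng.choice([0.0005, 0.001, 0.01]))
        got = binomial_site_pvalue(k, n, rate)
        assert got == pytest.approx(binom_upper_tail(k, n, rate), rel=1e-9, abs=1e-300)


@given(
    n=st.integers(min_value=1, max_value=2000),
    k=st.integers(min_value=0, max_value=2000),
)
def test_pvalue_monotone_in_alternate_count(n, k):
    k = min(k, n)
    if k < n:
        assert binomial_site_pvalue(k + 1, n, 0.001) <= binomial_site_pvalue(k, n, 0.001)


def test_pvalue_monotone_in_error_rate():
    p1 = binomial_site_pvalue(5, 1000, 0.001)
    p2 = binomial_site_pvalue(5, 1000, 0.002)
    assert p2 >= p1


def test_invalid_error_rate_rejected():
    with pytest.raises(ValueError):
        binomial_site_pvalue(1, 10, 0.0)


# --- site calling ----------------------------------------------------------

def test_low_coverage_site_is_nd(cfg):
    t = _tally_for(REF, {A_POS: {"G": 9}})
    calls = call_sites(t, REF, cfg)
    (c,) = calls
    assert c.coverage == 9
    assert c.status == STATUS_ND


def test_coverage_ten_is_determined(cfg):
    t = _tally_for(REF, {A_POS: {"G": 10}})
    (c,) = call_sites(t, REF, cfg)
    assert c.status != STATUS_ND


def test_editing_level_uses_ref_plus_alt_denominator(cfg):
    t = _tally_for(REF, {A_POS: {"A": 30, "G": 70, "C": 10}})
    calls = call_sites(t, REF, cfg)
    g = next(c for c in calls if c.alt_base == "G")
    assert g.editing_level == pytest.approx(100.0 * 70 / (30 + 70))
    assert g.coverage == 110
    assert g.is_AtoG


def test_seed_annotation_uses_configured_span(cfg):
    t = _tally_for(REF, {A_POS: {"A": 50, "G": 50}})
    (g,) = [c for c in call_sites(t, REF, cfg) if c.alt_base == "G"]
    # position 3 (1-based) lies inside the default 2-8 seed
    assert g.position == A_POS + 1 == 3
    assert g.in_seed


def test_null_tallies_produce_no_significant_calls(cfg, rng):
    """Type-I check at small scale: error-only mismatches, Bonferroni."""
    refs = [
        MiRNAReference(id=f"n{i}", sequence="".join(rng.choice(list("ACGT"), size=22)))
        for i in range(20)
    ]
    n_sig = 0
    for run in range(10):
        tallies = {}
        for ref in refs:
            t = PositionTally.empty(ref)
            idx = {"A": 0, "C": 1, "G": 2, "T": 3}
            for pos in range(22):
                errors = rng.binomial(1000, 0.001)
                t.counts[pos, idx[ref.sequence[pos]]] = 1000 - errors
                for _ in range(errors):
                    alts = [b for b in "ACGT" if b != ref.sequence[pos]]
                    t.counts[pos, idx[alts[rng.integers(3)]]] += 1
            tallies[ref.id] = t
        calls = call_sample(tallies, refs, cfg)
        n_sig += sum(c.status == STATUS_SIGNIFICANT for c in calls)
    assert n_sig == 0


# --- cross-sample comparison ----------------------------------------------

def test_identical_samples_give_identical_columns(cfg):
    t = _tally_for(REF, {A_POS: {"A": 40, "G": 60}})
    calls = call_sites(t, REF, cfg)
    table = compare_conditions({"s1": calls, "s2": calls}, cfg)
    assert (table["s1_level"] == table["s2_level"]).all()
    assert (table["s1_status"] == table["s2_status"]).all()


def test_site_absent_in_one_sample_reports_nd(cfg):
    t = _tally_for(REF, {A_POS: {"A": 40, "G": 60}})
    calls = call_sites(t, REF, cfg)
    table = compare_conditions({"a": calls, "b": []}, cfg)
    import pandas as pd

    row = table.iloc[0]
    assert row["a_level"] == pytest.approx(60.0)
    assert pd.isna(row["b_level"])
    assert row["b_status"] == STATUS_ND


def test_sites_planted_only_in_active_sample_are_enzyme_specific(cfg):
    active_t = _tally_for(REF, {A_POS: {"A": 400, "G": 600}})
    control_t = _tally_for(REF, {A_POS: {"A": 999, "G": 1}})
    active_calls = call_sites(active_t, REF, cfg)
    control_calls = call_sites(control_t, REF, cfg)
    table = compare_conditions(
        {"adar2": active_calls, "ea": control_calls}, cfg, active="adar2", control="ea"
    )
    assert table["enzyme_specific"].sum() == 1
    flagged = table[table["enzyme_specific"]].iloc[0]
    assert flagged["position"] == A_POS + 1


# --- sequence context ------------------------------------------------------

def test_single_site_upstream_context(cfg):
    # REF has T at position 1 (0-based), A at position 2
    t = _tally_for(REF, {A_POS: {"A": 10, "G": 90}})
    calls = [c for c in call_sites(t, REF, cfg) if c.is_AtoG]
    prof = context_profile(calls, [REF])
    assert prof.upstream["T"] == 1.0
    assert prof.downstream[REF.sequence[A_POS + 1]] == 1.0


def test_empty_call_list_rejected(cfg):
    with pytest.raises(ValueError):
        context_profile([], [REF])


def test_random_sites_give_near_uniform_profile(cfg, rng):
    refs, calls = [], []
    for i in range(400):
        seq = "".join(rng.choice(list("ACGT"), size=22))
        pos = int(rng.integers(1, 21))
        seq = seq[:pos] + "A" + seq[pos + 1:]
        ref = MiRNAReference(id=f"c{i}", sequence=seq)
        t = _tally_for(ref, {pos: {"A": 50, "G": 50}})
        calls.extend(c for c in call_sites(t, ref, cfg) if c.is_AtoG)
        refs.append(ref)
    prof = context_profile(calls, refs)
    for base in "ACGT":
        assert prof.upstream[base] == pytest.approx(0.25, abs=0.08)
        assert prof.downstream[base] == pytest.approx(0.25, abs=0.08)


# --- amplicon mode ---------------------------------------------------------

PRE = MiRNAReference(
    id="pre-mir-x",
    sequence="TTGACCTAGCATCGGAACCGTAGCATTGGACCTTAGCAACGT",
    kind="precursor",
)


def test_planted_amplicon_level_recovered(cfg, rng):
    pos = PRE.sequence.index("A")
    n = 5000
    g = rng.binomial(n, 0.2)
    t = _tally_for(PRE, {pos: {"A": n - g, "G": g}})
    calls = amplicon_editing(t, PRE, cfg, anchor=1)
    (c,) = calls
    sd = 100 * math.sqrt(0.2 * 0.8 / n)
    assert c.editing_level == pytest.approx(20.0, abs=2 * sd)


def test_anchor_relative_labels(cfg):
    pos = PRE.sequence.index("A", 10)  # 0-based
    t = _tally_for(PRE, {pos: {"A": 50, "G": 50}})
    anchor = pos + 1  # site at the anchor base
    (c,) = amplicon_editing(t, PRE, cfg, anchor=anchor)
    assert c.label == "+1"
    (c2,) = amplicon_editing(t, PRE, cfg, anchor=anchor + 1)
    assert c2.label == "-1"


def test_no_a_to_g_mismatches_gives_empty_list(cfg):
    pos = PRE.sequence.index("C")
    t = _tally_for(PRE, {pos: {"C": 90, "T": 10}})
    assert amplicon_editing(t, PRE, cfg, anchor=1) == []


def test_anchor_outside_reference_rejected(cfg):
    t = PositionTally.empty(PRE)
    with pytest.raises(ValueError):
        amplicon_editing(t, PRE, cfg, anchor=len(PRE) + 1)
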