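"""Signed clinical associations and biomarker classification."""

import math

import numpy as np
import pandas as pd
import pytest

from mirscreen.cohort import (
    ENDPOINT_M,
    ENDPOINT_P,
    ENDPOINT_SURVIVAL,
    ENDPOINT_T,
    AssociationRecord,
    CohortDataset,
    PrognosticScreen,
    classify_biomarker,
    filter_mirnas,
    metastasis_association,
    stage_association,
    survival_association,
    volcano_and_venn,
)
from mirscreen.simulate import SimulationSpec, make_cohort


def _record(endpoint, sign, p=0.01, mirna="m"):
    applicable = sign is not None
    return AssociationRecord(
        mirna, endpoint, 0.5 if sign == "+" else -0.5, sign or "0",
        p if sign != "0" else 0.5, 100, applicable=applicable,
    )


def _records(survival, t, p_stage, m):
    return {
        ENDPOINT_SURVIVAL: _record(ENDPOINT_SURVIVAL, survival),
        ENDPOINT_T: _record(ENDPOINT_T, t),
        ENDPOINT_P: _record(ENDPOINT_P, p_stage),
        ENDPOINT_M: _record(ENDPOINT_M, m),
    }


# ----------------------------------------------------------- filtering
def test_prevalence_filter():
    expr = pd.DataFrame(
        {f"s{i}": [1.0, 1.0 if i < 10 else 0.0, 1.0] for i in range(350)},
        index=["common", "rare", "everywhere"],
    )
    kept = filter_mirnas(expr, min_expressed_samples=300)
    assert set(kept.index) == {"common", "everywhere"}
    assert set(filter_mirnas(expr, 0).index) == set(expr.index)


# ----------------------------------------------------------- survival
def test_identical_curves_null():
    n = 40
    expr = pd.Series(np.r_[np.zeros(n // 2), np.ones(n // 2)])
    times = pd.Series(np.tile([100.0, 200, 300, 400], n // 4))
    events = pd.Series(np.ones(n, dtype=int))
    rec = survival_association("m", expr, times, events)
    assert rec.p == pytest.approx(1.0)
    assert rec.sign == "0"


def test_survival_direction_and_sign():
    rng = np.random.default_rng(0)
    n = 200
    expr = pd.Series(rng.normal(size=n))
    high = expr > expr.median()
    times = pd.Series(np.where(high, rng.exponential(1000, n), rng.exponential(200, n)))
    events = pd.Series(np.ones(n, dtype=int))
    rec = survival_association("m", expr, times, events)
    assert rec.sign == "+" and rec.p < 0.05 and rec.effect > 0


def test_all_censored_not_applicable():
    expr = pd.Series([1.0, 2, 3, 4, 5, 6])
    times = pd.Series([10.0] * 6)
    events = pd.Series([0] * 6)
    rec = survival_association("m", expr, times, events)
    assert not rec.applicable and rec.sign == "0"


def test_survival_power_on_planted_hazard():
    """Planted 2-fold hazard for low expressors is detected >= 80% at n=300."""
    rng = np.random.default_rng(42)
    hits = 0
    n_rep = 200
    for _ in range(n_rep):
        n = 300
        expr = pd.Series(rng.normal(size=n))
        low = expr <= expr.median()
        lam = np.where(low, 2.0 / 1000, 1.0 / 1000)
        t = rng.exponential(1 / lam)
        c = rng.exponential(2000, n)
        rec = survival_association(
            "m", expr, pd.Series(np.minimum(t, c)), pd.Series((t <= c).astype(int))
        )
        hits += rec.sign == "+" and rec.p < 0.05
    assert hits / n_rep >= 0.80


# ----------------------------------------------------------- stages
def test_stage_monotone_and_null():
    stage = pd.Series(np.repeat([1, 2, 3, 4], 10).astype(float))
    expr = stage + 10.0  # perfectly concordant with stage (shared tie structure)
    rec = stage_association("m", expr, stage, ENDPOINT_T)
    assert rec.effect == pytest.approx(1.0) and rec.sign == "+"
    const = pd.Series(np.full(40, 2.0))
    assert not stage_association("m", expr, const, ENDPOINT_T).applicable


def test_stage_type1_error_calibration():
    """Independent stage: false-positive rate within alpha + 2*SE over replicates."""
    rng = np.random.default_rng(9)
    n_rep, n, alpha = 200, 300, 0.05
    false_pos = 0
    for _ in range(n_rep):
        expr = pd.Series(rng.normal(size=n))
        stage = pd.Series(rng.integers(1, 5, size=n).astype(float))
        rec = stage_association("m", expr, stage, ENDPOINT_T)
        false_pos += rec.sign != "0"
    bound = alpha + 2 * math.sqrt(alpha * (1 - alpha) / n_rep)
    assert false_pos / n_rep <= bound


# ----------------------------------------------------------- metastasis
def test_mannwhitney_exact_small_groups():
    """Complete separation of 10 vs 10: p = 2 / C(20, 10) exactly."""
    expr = pd.Series(np.r_[np.arange(10, dtype=float), np.arange(100, 110, dtype=float)])
    m = pd.Series(np.r_[np.zeros(10), np.ones(10)])
    rec = metastasis_association("m", expr, m)
    assert rec.p == pytest.approx(2 / math.comb(20, 10), rel=1e-12)
    assert rec.sign == "+" and rec.effect == pytest.approx(1.0)


def test_mannwhitney_identical_and_empty_group():
    expr = pd.Series(np.r_[np.arange(10, dtype=float), np.arange(10, dtype=float) + 0.5])
    m = pd.Series(np.r_[np.zeros(10), np.ones(10)])
    rec = metastasis_association("m", expr, m)
    assert rec.sign == "0"
    rec2 = metastasis_association("m", expr, pd.Series(np.zeros(20)))
    assert not rec2.applicable


# ----------------------------------------------------------- sign antisymmetry
def test_negating_expression_flips_signs_preserves_p():
    rng = np.random.default_rng(17)
    n = 150
    expr = pd.Series(rng.normal(size=n))
    times = pd.Series(rng.exponential(500 * np.exp(0.7 * expr.to_numpy())))
    events = pd.Series(rng.random(n) < 0.8).astype(int)
    stage = pd.Series(np.clip(np.round(2.5 + 0.5 * expr + rng.normal(0, 1, n)), 1, 4))
    m = pd.Series((rng.random(n) < 1 / (1 + np.exp(-expr))).astype(float))
    for fn, args in [
        (survival_association, (times, events)),
        (stage_association, (stage,)),
        (metastasis_association, (m,)),
    ]:
        rec = fn("m", expr, *args)
        neg = fn("m", -expr, *args)
        assert neg.p == pytest.approx(rec.p, rel=1e-9)
        flip = {"+": "-", "-": "+", "0": "0"}
        assert neg.sign == flip[rec.sign]


# ----------------------------------------------------------- classification
def test_table1_row_patterns():
    """The two worked sign patterns classify as suppressor and oncogenic."""
    supp = classify_biomarker(_records("+", "-", "-", "-"))
    assert supp.klass == "suppressor" and supp.promising
    onco = classify_biomarker(_records("-", "+", "+", "+"))
    assert onco.klass == "oncogenic" and onco.promising


def test_all_null_and_single_endpoint():
    assert classify_biomarker(_records("0", "0", "0", "0")).klass == "none"
    single = classify_biomarker(_records("+", "0", "0", "0"))
    assert single.klass == "none" and not single.conflict


def test_conflicting_signs_flagged():
    # survival '-' (oncogenic orientation) with stage '-' (suppressor)
    call = classify_biomarker(_records("-", "-", "0", "0"))
    assert call.klass == "none" and call.conflict and not call.promising


def test_two_endpoints_without_m_not_promising():
    call = classify_biomarker(_records("+", "-", "-", "0"))
    assert call.klass == "suppressor" and not call.promising


def test_missing_endpoint_rejected():
    with pytest.raises(ValueError):
        classify_biomarker({ENDPOINT_SURVIVAL: _record(ENDPOINT_SURVIVAL, "+")})


# ----------------------------------------------------------- venn / volcano
def test_venn_membership_and_volcano_tables():
    records = {
        "supp_all": _records("+", "-", "-", "-"),
        "onco_all": _records("-", "+", "+", "+"),
        "surv_only": _records("+", "0", "0", "0"),
        "silent": _records("0", "0", "0", "0"),
    }
    volcano, venn = volcano_and_venn(records)
    assert set(volcano) == {ENDPOINT_SURVIVAL, ENDPOINT_T, ENDPOINT_P, ENDPOINT_M}
    assert len(volcano[ENDPOINT_SURVIVAL]) == 4
    assert venn["suppressor"]["111"] == 1
    assert venn["suppressor"]["100"] == 1
    assert venn["oncogenic"]["111"] == 1
    assert sum(venn["oncogenic"].values()) == 1
    with pytest.raises(ValueError):
        volcano_and_venn({})


def test_no_significant_mirnas_empty_venn():
    _, venn = volcano_and_venn({"a": _records("0", "0", "0", "0")})
    assert all(v == 0 for counts in venn.values() for v in counts.values())


# ----------------------------------------------------------- end to end
def test_screen_recovers_planted_classes_and_handles_missing():
    spec = SimulationSpec(seed=123, n_patients=300, clinical_missing_rate=0.1)
    expr, clinical, truth = make_cohort(spec)
    res = PrognosticScreen(
        CohortDataset(expr, clinical), min_expressed_samples=150
    ).fit()
    calls = res.calls_table.set_index("mirna_id")
    for _, row in truth.iterrows():
        if row["class"] != "none" and row["mirna_id"] in calls.index:
            assert calls.loc[row["mirna_id"], "class"] == row["class"]
    # rare miRNAs are filtered out before testing
    assert not any(m.startswith("miR-sim-rare") for m in calls.index)
    # missing clinical fields reduce n_used but nothing crashes
    assoc = res.associations
    n_surv = assoc.loc[assoc["endpoint"] == ENDPOINT_SURVIVAL, "n_used"].max()
    n_t = assoc.loc[assoc["endpoint"] == ENDPOINT_T, "n_used"].max()
    assert n_t < n_surv <= 300
    assert "Prognostic miRNA screen" in res.summary()


def test_dataset_validation():
    expr = pd.DataFrame({"s1": [1.0]}, index=["m1"])
    clin = pd.DataFrame(
        {"os_days": [-5.0], "os_event": [1], "t_stage": [1.0],
         "p_stage": [1.0], "m_stage": [0.0]},
        index=pd.Index(["s1"], name="sample_id"),
    )
    with pytest.raises(ValueError):
        CohortDataset(expr, clin)
    clin2 = clin.copy()
    clin2.index = pd.Index(["other"], name="sample_id")
    with pytest.raises(ValueError):
        CohortDataset(expr, clin2)
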