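"""Caller confidence filters: printed thresholds, boundaries, monotonicity."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cnvcurate import caller_filters as cf
from cnvcurate.intervals import CnvCall, CnvRecordSet, CnvType, GenomicInterval
from cnvcurate.oracles import oracle_gatk4_threshold


def make_call(caller="cnvpytor", cnv_type=CnvType.DEL, quality=None,
              genotype=None, genotype_filter=None, filters=("PASS",),
              **metrics):
    return CnvCall(interval=GenomicInterval("1", 1000, 6000), type=cnv_type,
                   caller=caller, quality=quality, genotype=genotype,
                   genotype_filter=genotype_filter,
                   filter_status=frozenset(filters), metrics=dict(metrics))


@pytest.mark.parametrize("metrics,kept,reason", [
    ({"pytorP1": 0.01, "Q0": 0.2, "pytorRD": 0.4}, True, None),
    ({"pytorP1": 0.06, "Q0": 0.2, "pytorRD": 0.4}, False, "pytorP1"),
    ({"pytorP1": 0.01, "Q0": 0.2, "pytorRD": 1.0}, False, "pytorRD"),
    ({"pytorP1": 0.01, "Q0": 0.95, "pytorRD": 0.4}, False, "Q0"),
    # boundaries: strict inequalities exactly as printed
    ({"pytorP1": 0.05, "Q0": 0.9, "pytorRD": 0.75}, True, None),
    ({"pytorP1": 0.05, "Q0": 0.9, "pytorRD": 1.25}, True, None),
])
def test_cnvpytor_rule(metrics, kept, reason):
    outcome = cf.filter_cnvpytor(make_call(**metrics))
    assert outcome.kept is kept
    if reason:
        assert reason in outcome.reasons


def test_cnvpytor_conjunctive_mode_requires_all_conditions():
    call = make_call(pytorP1=0.06, Q0=0.2, pytorRD=0.4)
    assert cf.filter_cnvpytor(call, conjunctive=True).kept
    call = make_call(pytorP1=0.06, Q0=0.95, pytorRD=1.0)
    assert not cf.filter_cnvpytor(call, conjunctive=True).kept


@pytest.mark.parametrize("w,ks,kept", [
    (0.04, 0.04, True), (0.06, 0.01, False), (0.05, 0.05, True),
    (0.01, 0.06, False),
])
def test_controlfreec_rule(w, ks, kept):
    assert cf.filter_controlfreec(make_call("controlfreec", W=w, KS=ks)).kept is kept


@pytest.mark.parametrize("filters,ft,gt,kept", [
    (("PASS",), "PASS", "0/1", True),
    (("LowQual",), "PASS", "0/1", False),
    (("PASS",), "PASS", "0/0", False),
    (("PASS",), "LowGQ", "0/1", False),
    (("PASS",), None, "0/1", True),   # missing FT treated as passing
    ((), "PASS", None, True),          # missing GT treated as non-0/0
])
def test_delly_manta_pass_gt_rule(filters, ft, gt, kept):
    call = make_call("delly", filters=filters, genotype_filter=ft, genotype=gt)
    assert cf.filter_pass_gt(call).kept is kept


@pytest.mark.parametrize("quality,kept", [(119, False), (120, True),
                                          (500, True), (0, False)])
def test_lumpy_rule(quality, kept):
    assert cf.filter_lumpy(make_call("lumpy", quality=quality)).kept is kept


@pytest.mark.parametrize("cnv_type,metrics,kept", [
    (CnvType.DEL, {"max_CW": 0.3, "TF": 3}, True),
    (CnvType.DEL, {"max_CW": 0.3, "TF": 2}, False),
    (CnvType.DUP, {"max_CW": 0.3, "U": 1}, False),
    (CnvType.DUP, {"max_CW": 0.3, "U": 2}, True),
    (CnvType.DEL, {"max_CW": 0.19, "TF": 10}, False),
    (CnvType.DEL, {"max_CW": 0.2, "TF": 10}, True),
])
def test_wham_rule(cnv_type, metrics, kept):
    assert cf.filter_wham(make_call("wham", cnv_type, **metrics)).kept is kept


@pytest.mark.parametrize("filters,kept", [
    (("PASS",), True), (("NO_ASSEMBLY",), False),
    (("NO_ASSEMBLY", "PASS"), False),
])
def test_gridss_rule(filters, kept):
    assert cf.filter_gridss(make_call("gridss", filters=filters)).kept is kept


@pytest.mark.parametrize("cnv_type,bf,ratio,kept", [
    (CnvType.DEL, 20, 0.5, True),
    (CnvType.DEL, 20, 0.9, False),
    (CnvType.DUP, 14, 1.5, False),
    (CnvType.DUP, 15, 1.1, True),
    (CnvType.DUP, 15, 1.09, False),
    (CnvType.DEL, 15, 0.8, True),
])
def test_exomedepth_rule(cnv_type, bf, ratio, kept):
    call = make_call("exomedepth", cnv_type, BF=bf, reads_ratio=ratio)
    assert cf.filter_exomedepth(call).kept is kept


@pytest.mark.parametrize("cnv_type,cn,nt,qs,kept", [
    (CnvType.DEL, 0, 70, 699, False),   # T = min(1000, max(400, 700)) = 700
    (CnvType.DEL, 0, 70, 700, True),
    (CnvType.DEL, 1, 5, 100, True),     # T = min(1000, max(100, 50)) = 100
    (CnvType.DEL, 1, 5, 99, False),
    (CnvType.DUP, 3, 200, 399, False),  # T = min(400, max(50, 800)) = 400
    (CnvType.DUP, 3, 200, 400, True),
])
def test_gatk4_rule(cnv_type, cn, nt, qs, kept):
    call = make_call("gatk4", cnv_type, QS=qs, CN=cn, nt=nt)
    assert cf.filter_gatk4(call).kept is kept


def test_gatk4_del_other_cn_not_applicable():
    call = make_call("gatk4", CnvType.DEL, QS=1, CN=2, nt=100)
    assert cf.filter_gatk4(call).kept


def test_gatk4_threshold_formula_matches_direct_evaluation():
    """Thresholds equal min/max formula for nt in 1..200, both CN states."""
    for nt in range(1, 201):
        for cn in (0, 1):
            assert cf.gatk4_qs_threshold(CnvType.DEL, cn, nt) == \
                oracle_gatk4_threshold("DEL", cn, nt)
        assert cf.gatk4_qs_threshold(CnvType.DUP, -1, nt) == \
            oracle_gatk4_threshold("DUP", -1, nt)


def test_gatk4_threshold_bounds():
    for nt in range(1, 500):
        assert 400 <= cf.gatk4_qs_threshold(CnvType.DEL, 0, nt) <= 1000
        assert 100 <= cf.gatk4_qs_threshold(CnvType.DEL, 1, nt) <= 1000
        assert 50 <= cf.gatk4_qs_threshold(CnvType.DUP, -1, nt) <= 400


def test_apply_caller_filters_lumpy_counts():
    calls = [make_call("lumpy", quality=q) for q in (100, 130, 119)]
    record_set = CnvRecordSet(sample="s", caller="lumpy", calls=calls)
    survivors, report = cf.apply_caller_filters(record_set)
    assert len(survivors) == 1
    assert report.removed_by_reason == {"quality": 2}


def test_pass_through_caller_keeps_everything():
    calls = [make_call("cn.mops") for _ in range(4)]
    record_set = CnvRecordSet(sample="s", caller="cn.mops", calls=calls)
    survivors, report = cf.apply_caller_filters(record_set)
    assert len(survivors) == 4


def test_unknown_caller_raises_with_registry():
    with pytest.raises(KeyError, match="lumpy"):
        cf.evaluate_call(make_call("mysterycaller"))


def test_missing_metric_policies():
    call = make_call("cnvpytor")  # no metrics at all
    assert cf.filter_cnvpytor(call, policy="lenient").kept
    with pytest.raises(cf.MissingMetricError):
        cf.filter_cnvpytor(call, policy="strict")


def test_filter_fidelity_against_oracle_table(caller_fixture, tmp_path):
    """Module kept/removed equals the generator's oracle table exactly."""
    from cnvcurate import io_vcf_bed
    from cnvcurate.profiles import CallerProfile
    paths, expected = caller_fixture
    by_key = {(r["caller"], r["chrom"], r["start"], r["end"]): r
              for r in expected}
    checked = 0
    for caller, path in paths.items():
        records = io_vcf_bed.read_vcf(path, CallerProfile.default(caller))
        assert len(records) == sum(1 for r in expected if r["caller"] == caller)
        for call in records:
            exp = by_key[(caller, call.interval.chrom, call.interval.start,
                          call.interval.end)]
            outcome = cf.evaluate_call(call)
            assert outcome.kept == exp["kept"], exp
            assert sorted(outcome.reasons) == sorted(exp["reasons"]), exp
            checked += 1
    assert checked == len(expected)


@settings(max_examples=100, derandomize=True)
@given(q1=st.floats(0, 2000), q2=st.floats(0, 2000))
def test_lumpy_monotone_in_quality(q1, q2):
    """Raising QUAL never flips kept to removed."""
    lo, hi = sorted((q1, q2))
    if cf.filter_lumpy(make_call("lumpy", quality=lo)).kept:
        assert cf.filter_lumpy(make_call("lumpy", quality=hi)).kept


@settings(max_examples=100, derandomize=True)
@given(bf1=st.floats(0, 100), bf2=st.floats(0, 100),
       ratio=st.floats(0, 2))
def test_exomedepth_monotone_in_bf(bf1, bf2, ratio):
    lo, hi = sorted((bf1, bf2))
    low_call = make_call("exomedepth", BF=lo, reads_ratio=ratio)
    high_call = make_call("exomedepth", BF=hi, reads_ratio=ratio)
    if cf.filter_exomedepth(low_call).kept:
        assert cf.filter_exomedepth(high_call).kept


@settings(max_examples=100, derandomize=True)
@given(qs1=st.floats(0, 2000), qs2=st.floats(0, 2000),
       cn=st.sampled_from((0, 1)), nt=st.integers(1, 300))
def test_gatk4_monotone_in_qs(qs1, qs2, cn, nt):
    lo, hi = sorted((qs1, qs2))
    low_call = make_call("gatk4", CnvType.DEL, QS=lo, CN=cn, nt=nt)
    high_call = make_call("gatk4", CnvType.DEL, QS=hi, CN=cn, nt=nt)
    if cf.filter_gatk4(low_call).kept:
        assert cf.filter_gatk4(high_call).kept


def test_filters_are_pure():
    call = make_call(pytorP1=0.06, Q0=0.2, pytorRD=0.4)
    first = cf.filter_cnvpytor(call)
    second = cf.filter_cnvpytor(call)
    assert first.kept == second.kept and first.reasons == second.reasons
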