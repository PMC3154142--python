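import numpy as np
import pandas as pd
import pytest

from imprintscan import (
    DMLCall,
    aggregate_dml_to_dmrs,
    annotate_cnv_overlap,
    apply_consistency_filter,
    assign_parental_origin,
    call_candidate_dml,
    consistency_filter,
)
from imprintscan.errors import ConfigError, UndefinedValueError, ValidationError
from imprintscan.sam import SamResult
from imprintscan.screen import REASON_CHM, REASON_NORMAL


def make_sam_result(q_by_probe):
    probes = pd.Index(list(q_by_probe))
    q = pd.Series(q_by_probe, name="q_value")
    zeros = pd.Series(0.0, index=probes)
    return SamResult(
        d=zeros, s=zeros, s0=0.0, pi0=1.0, delta_table=pd.DataFrame(),
        q=q, called=[p for p, v in q_by_probe.items() if v <= 0.001],
        statistic="two_class", n_permutations_used=0, exhaustive=False,
    )


def profiles_frame(rows):
    return pd.DataFrame.from_dict(
        rows, orient="index",
        columns=["diandric", "digynic", "normal_placenta", "chm"],
    )


@pytest.mark.parametrize(
    "dia,dig,expected",
    [(0.60, 0.30, "paternal"), (0.20, 0.55, "maternal")],
)
def test_parental_origin_designation(dia, dig, expected):
    assert assign_parental_origin(dia, dig) == expected


def test_parental_origin_tie_undefined():
    with pytest.raises(UndefinedValueError):
        assign_parental_origin(0.40, 0.40)


def test_candidate_thresholds_fdr_and_magnitude():
    sam = make_sam_result({"keep": 0.0005, "small": 0.0005, "weak_q": 0.05})
    profiles = profiles_frame(
        {
            "keep": [0.60, 0.40, 0.50, 0.58],   # q ok, |delta|=0.20 > 0.15
            "small": [0.50, 0.36, 0.43, 0.48],  # q ok, |delta|=0.14 -> excluded
            "weak_q": [0.70, 0.40, 0.55, 0.68], # delta ok, q=0.05 -> excluded
        }
    )
    calls = call_candidate_dml(sam, profiles, 0.001, 0.15)
    assert [c.probe_id for c in calls] == ["keep"]
    assert calls[0].origin == "paternal"
    assert calls[0].delta_beta == pytest.approx(0.20)


def test_candidate_threshold_is_strict():
    sam = make_sam_result({"edge": 0.0005})
    # delta is exactly the threshold (dyadic values, no rounding): excluded
    profiles = profiles_frame({"edge": [0.625, 0.50, 0.55, 0.60]})
    assert call_candidate_dml(sam, profiles, 0.001, 0.125) == []


def test_bad_thresholds_rejected():
    sam = make_sam_result({"p": 0.5})
    profiles = profiles_frame({"p": [0.6, 0.4, 0.5, 0.6]})
    with pytest.raises(ConfigError):
        call_candidate_dml(sam, profiles, 1.5, 0.15)


def _call(probe, dia, dig, normal, chm):
    return DMLCall(
        probe_id=probe,
        origin=assign_parental_origin(dia, dig),
        mean_diandric=dia, mean_digynic=dig, mean_normal=normal, mean_chm=chm,
        delta_beta=dia - dig, q_value=0.0005,
    )


@pytest.mark.parametrize(
    "dia,dig,normal,chm,consistent,reason",
    [
        (0.60, 0.30, 0.45, 0.70, True, ""),
        (0.60, 0.30, 0.70, 0.62, False, REASON_NORMAL),
        (0.60, 0.30, 0.45, 0.28, False, REASON_CHM),
        # boundary: normal exactly at a triploid mean is "between" (closed interval)
        (0.60, 0.30, 0.30, 0.55, True, ""),
        (0.60, 0.30, 0.60, 0.55, True, ""),
        # boundary: CHM exactly equidistant is eliminated (strict "closer to")
        (0.75, 0.25, 0.50, 0.50, False, REASON_CHM),
        # maternal-origin case: digynic higher, CHM low and diandric-like
        (0.20, 0.55, 0.40, 0.22, True, ""),
    ],
)
def test_consistency_filter_clauses(dia, dig, normal, chm, consistent, reason):
    out = consistency_filter(_call("cg1", dia, dig, normal, chm))
    assert out.consistent is consistent
    assert out.elimination_reason == reason


def test_consistency_filter_requires_reference_means():
    call = _call("cg1", 0.6, 0.3, np.nan, 0.7)
    with pytest.raises(ValidationError):
        consistency_filter(call)


def test_screen_composition_order_irrelevant():
    """Filtering by (FDR and delta) then consistency equals the reverse order."""
    sam = make_sam_result({"a": 0.0005, "b": 0.0005, "c": 0.05})
    profiles = profiles_frame(
        {"a": [0.60, 0.30, 0.45, 0.70], "b": [0.60, 0.30, 0.70, 0.62],
         "c": [0.70, 0.30, 0.50, 0.65]}
    )
    candidates = call_candidate_dml(sam, profiles, 0.001, 0.15)
    retained, eliminated = apply_consistency_filter(candidates)
    # reverse: consistency on everything first, thresholds second
    all_calls = [
        _call(p, *profiles.loc[p]) for p in profiles.index
    ]
    cons_first = [c for c in (consistency_filter(c) for c in all_calls) if c.consistent]
    rethresholded = [
        c for c in cons_first
        if sam.q[c.probe_id] <= 0.001 and abs(c.delta_beta) > 0.15
    ]
    assert {c.probe_id for c in retained} == {c.probe_id for c in rethresholded} == {"a"}
    assert {c.probe_id for c in eliminated} == {"b"}


# ---------------------------------------------------------------- aggregation
def annotation_for(probes_genes):
    rows = []
    for i, (probe, gene) in enumerate(probes_genes):
        rows.append({"probe_id": probe, "gene_symbol": gene,
                     "chromosome": "7", "position": 1000 + 100 * i})
    return pd.DataFrame(rows).set_index("probe_id")


def test_aggregation_groups_by_gene_and_origin():
    calls = [_call(f"cg{i}", 0.2, 0.55, 0.4, 0.22) for i in range(3)]
    ann = annotation_for([(f"cg{i}", "MEST") for i in range(3)])
    dmrs = aggregate_dml_to_dmrs(calls, ann)
    assert len(dmrs) == 1
    assert dmrs[0].probe_ids == ["cg0", "cg1", "cg2"]
    assert (dmrs[0].start, dmrs[0].end) == (1000, 1200)


def test_dual_origin_gene_yields_two_dmrs_one_gene():
    calls = [_call("cgM", 0.2, 0.55, 0.4, 0.22), _call("cgP", 0.6, 0.3, 0.45, 0.58)]
    ann = annotation_for([("cgM", "GNAS"), ("cgP", "GNAS")])
    dmrs = aggregate_dml_to_dmrs(calls, ann)
    assert len(dmrs) == 2
    assert {d.origin for d in dmrs} == {"maternal", "paternal"}
    assert {d.gene_symbol for d in dmrs} == {"GNAS"}


def test_unannotated_probe_becomes_singleton_dmr():
    calls = [_call("cgX", 0.6, 0.3, 0.45, 0.58)]
    ann = annotation_for([("cgX", "")])
    dmrs = aggregate_dml_to_dmrs(calls, ann)
    assert dmrs[0].dmr_id == "cgX|paternal"  # keyed by probe id
    assert dmrs[0].probe_ids == ["cgX"]
    assert (dmrs[0].start, dmrs[0].end) == (1000, 1000)


def test_full_accounting_identity_108_63_62():
    """122 candidates - 14 eliminated = 108 final over 62 genes -> 63 DMRs."""
    calls, probes_genes = [], []
    # 61 single-origin genes x ~ sharing 106 probes; 1 dual-origin gene with 2
    n_consistent = 0
    gene_idx = 0
    while n_consistent < 106:
        gene = f"G{gene_idx:03d}"
        for _ in range(2 if n_consistent < 90 else 1):
            if n_consistent >= 106:
                break
            probe = f"cg{len(probes_genes):04d}"
            calls.append(_call(probe, 0.6, 0.3, 0.45, 0.58))
            probes_genes.append((probe, gene))
            n_consistent += 1
        gene_idx += 1
    # the dual-origin gene: one paternal + one maternal probe
    for origin_args in [(0.6, 0.3, 0.45, 0.58), (0.2, 0.55, 0.4, 0.22)]:
        probe = f"cg{len(probes_genes):04d}"
        calls.append(_call(probe, *origin_args))
        probes_genes.append((probe, "GDUAL"))
    # 14 candidates that violate a consistency clause
    for i in range(14):
        probe = f"bad{i:02d}"
        calls.append(_call(probe, 0.6, 0.3, 0.70, 0.62))
        probes_genes.append((probe, f"B{i:02d}"))
    assert len(calls) == 122
    retained, eliminated = apply_consistency_filter(calls)
    assert len(eliminated) == 14
    assert len(retained) == 122 - 14 == 108
    ann = annotation_for(probes_genes)
    dmrs = aggregate_dml_to_dmrs(retained, ann)
    genes = {d.gene_symbol for d in dmrs}
    assert len(genes) == 62
    assert len(dmrs) == 63  # one gene contributes both origins


# ---------------------------------------------------------------- CNV overlap
def test_cnv_overlap_boundary_convention():
    calls = [_call("cgA", 0.6, 0.3, 0.45, 0.58), _call("cgB", 0.6, 0.3, 0.45, 0.58)]
    ann = pd.DataFrame(
        [
            {"probe_id": "cgA", "gene_symbol": "GA", "chromosome": "1", "position": 1000},
            {"probe_id": "cgB", "gene_symbol": "GB", "chromosome": "1", "position": 1001},
        ]
    ).set_index("probe_id")
    out = annotate_cnv_overlap(calls, [("1", 999, 1000)], ann)
    flags = {c.probe_id: c.cnv_overlap for c in out}
    assert flags == {"cgA": True, "cgB": False}


def test_cnv_empty_interval_set_all_false():
    calls = [_call("cgA", 0.6, 0.3, 0.45, 0.58)]
    ann = annotation_for([("cgA", "GA")])
    out = annotate_cnv_overlap(calls, [], ann)
    assert out[0].cnv_overlap is False


def test_cnv_malformed_interval_rejected():
    calls = [_call("cgA", 0.6, 0.3, 0.45, 0.58)]
    ann = annotation_for([("cgA", "GA")])
    with pytest.raises(ValidationError):
        annotate_cnv_overlap(calls, [("1", 1000, 1000)], ann)


def test_origin_always_matches_delta_sign():
    rng = np.random.default_rng(21)
    sam_q, rows = {}, {}
    for i in range(40):
        dia, dig = rng.uniform(0, 1, 2)
        if abs(dia - dig) < 1e-6:
            continue
        sam_q[f"cg{i}"] = 0.0005
        rows[f"cg{i}"] = [dia, dig, (dia + dig) / 2, dia]
    calls = call_candidate_dml(make_sam_result(sam_q), profiles_frame(rows), 0.001, 0.15)
    for c in calls:
        assert (c.origin == "paternal") == (c.delta_beta > 0)
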