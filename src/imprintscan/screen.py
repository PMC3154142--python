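"""The candidate-DML screen: thresholding, parental-origin designation,
reference-group consistency filtering, DMR aggregation and CNV annotation.

Logic of the screen: at a genuinely imprinted CpG the diandric group
(1 maternal + 2 paternal genomes) and the digynic group (2 + 1) differ in
mean methylation by up to 1/3; candidates are probes passing both the
permutation-FDR cut and a |delta beta| magnitude cut.  A candidate whose
methylation is higher in diandries is methylated on the paternal allele
("paternal DML"), higher in digynies means maternal.  Two reference groups
then police secondary effects: chromosomally normal placentas (1 + 1) must
sit between the two triploid means, and androgenetic CHMs (0 + 2) must sit
closer to the diandric mean.  Surviving probes aggregate into regions per
(gene, origin) - so a gene carrying both a maternal and a paternal region
contributes two DMRs.
"""

from __future__ import annotations

import pandas as pd
from intervaltree import IntervalTree

from .errors import ConfigError, UndefinedValueError, ValidationError
from .io import DMLCall, DMR
from .sam import SamResult

REASON_NORMAL = "normal_not_intermediate"
REASON_CHM = "chm_not_diandric_like"


def assign_parental_origin(mean_diandric: float, mean_digynic: float) -> str:
    """Paternal if methylation is higher in diandries, maternal if higher in
    digynies; an exact tie is undefined (cannot occur past the magnitude cut)."""
    if mean_diandric > mean_digynic:
        return "paternal"
    if mean_digynic > mean_diandric:
        return "maternal"
    raise UndefinedValueError("origin undefined: group means are exactly equal")


def call_candidate_dml(
    sam: SamResult,
    profiles: pd.DataFrame,
    fdr_threshold: float = 0.001,
    delta_threshold: float = 0.15,
) -> list[DMLCall]:
    """Candidate DML: q <= fdr_threshold AND |delta beta| > delta_threshold.

    ``profiles`` is a probes x groups mean-beta frame containing at least the
    ``diandric`` and ``digynic`` columns; ``normal_placenta`` and ``chm``
    means are carried along (NaN when absent) for the consistency filter.
    """
    if not (0 < fdr_threshold < 1 and 0 < delta_threshold < 1):
        raise ConfigError("thresholds must lie in (0, 1)")
    for col in ("diandric", "digynic"):
        if col not in profiles.columns:
            raise ValidationError(f"profiles lack required group column {col!r}")
    calls = []
    for probe in sam.q.index:
        q = float(sam.q[probe])
        if q > fdr_threshold or probe not in profiles.index:
            continue
        mean_a = float(profiles.at[probe, "diandric"])
        mean_g = float(profiles.at[probe, "digynic"])
        delta = mean_a - mean_g
        if abs(delta) <= delta_threshold:
            continue
        calls.append(
            DMLCall(
                probe_id=probe,
                origin=assign_parental_origin(mean_a, mean_g),
                mean_diandric=mean_a,
                mean_digynic=mean_g,
                mean_normal=float(profiles.at[probe, "normal_placenta"])
                if "normal_placenta" in profiles.columns
                else float("nan"),
                mean_chm=float(profiles.at[probe, "chm"])
                if "chm" in profiles.columns
                else float("nan"),
                delta_beta=delta,
                q_value=q,
            )
        )
    return calls


def consistency_filter(call: DMLCall) -> DMLCall:
    """Flag a candidate as consistent with the imprinting dosage model.

    Consistent iff (a) the normal-placenta mean lies within the closed
    interval spanned by the two triploid means, and (b) the CHM mean is
    strictly closer to the diandric than to the digynic mean.  Ties on (b)
    eliminate the probe (conservative).  The failing clause is recorded in
    ``elimination_reason``.
    """
    if pd.isna(call.mean_normal) or pd.isna(call.mean_chm):
        raise ValidationError(
            f"probe {call.probe_id}: normal/CHM reference means required"
        )
    lo = min(call.mean_diandric, call.mean_digynic)
    hi = max(call.mean_diandric, call.mean_digynic)
    if not (lo <= call.mean_normal <= hi):
        consistent, reason = False, REASON_NORMAL
    elif not (
        abs(call.mean_chm - call.mean_diandric) < abs(call.mean_chm - call.mean_digynic)
    ):
        consistent, reason = False, REASON_CHM
    else:
        consistent, reason = True, ""
    return DMLCall(
        probe_id=call.probe_id,
        origin=call.origin,
        mean_diandric=call.mean_diandric,
        mean_digynic=call.mean_digynic,
        mean_normal=call.mean_normal,
        mean_chm=call.mean_chm,
        delta_beta=call.delta_beta,
        q_value=call.q_value,
        consistent=consistent,
        elimination_reason=reason,
        cnv_overlap=call.cnv_overlap,
    )


def apply_consistency_filter(
    calls: list[DMLCall],
) -> tuple[list[DMLCall], list[DMLCall]]:
    """Split candidates into (retained, eliminated) by the consistency rule."""
    flagged = [consistency_filter(c) for c in calls]
    return [c for c in flagged if c.consistent], [c for c in flagged if not c.consistent]


def aggregate_dml_to_dmrs(calls: list[DMLCall], ann: pd.DataFrame) -> list[DMR]:
    """Group consistent calls by (gene_symbol, origin) into DMRs.

    A gene with both maternal and paternal calls yields two DMRs; probes
    without a gene symbol become singleton DMRs keyed by probe id.  The DMR
    span is the min..max 1-based position of member probes (1 bp for a
    single array probe).
    """
    groups: dict[tuple[str, str], list[DMLCall]] = {}
    for call in calls:
        if call.probe_id not in ann.index:
            raise ValidationError(f"probe {call.probe_id} missing from annotation")
        gene = str(ann.at[call.probe_id, "gene_symbol"] or "")
        key = (gene if gene else call.probe_id, call.origin)
        groups.setdefault(key, []).append(call)
    dmrs = []
    for (gene, origin), members in sorted(groups.items()):
        probe_ids = sorted(m.probe_id for m in members)
        chroms = {str(ann.at[p, "chromosome"]) for p in probe_ids}
        if len(chroms) > 1:
            raise ValidationError(
                f"gene {gene!r} spans multiple chromosomes: {sorted(chroms)}"
            )
        positions = [int(ann.at[p, "position"]) for p in probe_ids]
        dmrs.append(
            DMR(
                dmr_id=f"{gene}|{origin}",
                gene_symbol=gene,
                origin=origin,
                probe_ids=probe_ids,
                chromosome=chroms.pop(),
                start=min(positions),
                end=max(positions),
                mean_abs_delta=float(
                    sum(abs(m.delta_beta) for m in members) / len(members)
                ),
            )
        )
    return dmrs


def annotate_cnv_overlap(
    calls: list[DMLCall],
    intervals: list[tuple[str, int, int]],
    ann: pd.DataFrame,
) -> list[DMLCall]:
    """Set ``cnv_overlap`` per call from user-supplied 0-based half-open
    intervals (e.g. a known-CNV BED track).  Annotation only; not a filter."""
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end in intervals:
        if start >= end:
            raise ValidationError(f"malformed interval {chrom}:[{start}, {end})")
        trees.setdefault(str(chrom).removeprefix("chr"), IntervalTree()).addi(start, end)
    out = []
    for call in calls:
        chrom = str(ann.at[call.probe_id, "chromosome"])
        pos0 = int(ann.at[call.probe_id, "position"]) - 1  # 1-based point -> 0-based
        hit = bool(trees.get(chrom, IntervalTree()).overlaps_point(pos0))
        out.append(
            DMLCall(
                **{
                    **call.__dict__,
                    "cnv_overlap": hit,
                }
            )
        )
    return out
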