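"""Tissue- and gestational-age-specificity of identified DMRs.

Imprinted regions are classified on three axes: differential methylation
across somatic tissues and placenta (multiclass permutation screen),
placenta-specific methylation (group-mean margin rule) and change across
gestational age (midgestation vs term placenta, two-class screen).  Regions
touched by neither tissue nor gestation effects are "stable" - the behaviour
expected of germline (primary) imprints.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import pandas as pd

from .errors import ValidationError
from .io import BetaMatrix, DMR
from .sam import SamConfig, sam_multiclass, sam_two_class

#: the five-tissue panel used for the multiclass comparison; the placenta
#: representative is the midgestation set.
TISSUE_PANEL = ("brain", "kidney", "muscle", "placenta_mid", "maternal_blood")
PLACENTA_TISSUE = "placenta_mid"


@dataclass
class DmrClassification:
    dmr_id: str
    tissue_differential: bool | None
    placenta_specific: bool | None
    gestation_change: bool | None
    stable: bool | None
    known_imprinted: bool


def tissue_differential_probes(
    bm: BetaMatrix, sheet: pd.DataFrame, cfg: SamConfig | None = None
) -> set[str]:
    """Probes differentially methylated across the five-tissue panel
    (multiclass permutation screen at cfg.fdr_target)."""
    present = set(sheet.loc[[s for s in bm.samples if s in sheet.index], "group"])
    missing = [t for t in TISSUE_PANEL if t not in present]
    if missing:
        raise ValidationError(f"tissue panel groups missing from data: {missing}")
    res = sam_multiclass(bm, sheet, list(TISSUE_PANEL), cfg)
    return set(res.called)


def is_placenta_specific(tissue_means: dict[str, float], margin: float = 0.15) -> bool:
    """True iff the placenta mean exceeds the *maximum* non-placental tissue
    mean by more than ``margin`` (default 0.15, i.e. >15 percentage points)."""
    others = [v for k, v in tissue_means.items() if k != PLACENTA_TISSUE]
    if PLACENTA_TISSUE not in tissue_means or not others:
        raise ValidationError("need a placenta mean and at least one other tissue")
    return tissue_means[PLACENTA_TISSUE] - max(others) > margin


def placenta_specific_probes(
    bm: BetaMatrix, sheet: pd.DataFrame, margin: float = 0.15
) -> set[str]:
    """Probes passing the placenta-margin rule on raw tissue group means."""
    from .profiles import group_mean_frame

    panel = sheet[sheet["group"].isin(TISSUE_PANEL)]
    sub = bm.select_samples([s for s in bm.samples if s in panel.index])
    means = group_mean_frame(sub, panel)
    flags = set()
    for probe in sub.probes:
        if is_placenta_specific(means.loc[probe].to_dict(), margin):
            flags.add(probe)
    return flags


def gestation_change_probes(
    bm: BetaMatrix, sheet: pd.DataFrame, cfg: SamConfig | None = None
) -> set[str]:
    """Probes whose placental methylation changes between midgestation and
    term (two-class permutation screen at cfg.fdr_target)."""
    res = sam_two_class(bm, sheet, "placenta_mid", "placenta_term", cfg)
    return set(res.called)


def classify_dmrs(
    dmrs: list[DMR],
    tissue_probes: set[str],
    placenta_probes: set[str],
    gestation_probes: set[str],
    known_imprinted_genes: set[str] | None = None,
    probes_in_matrix: set[str] | None = None,
) -> list[DmrClassification]:
    """Roll probe-level calls up to DMR flags (any member probe triggers the
    flag) and derive stability.

    stable = (not tissue_differential) and (not gestation_change);
    placenta_specific implies tissue_differential.  A DMR with no member
    probe present in the analysed matrix is classified unknown (all-None
    flags) with a warning.
    """
    known = known_imprinted_genes or set()
    out = []
    for dmr in dmrs:
        members = dmr.probe_ids
        if probes_in_matrix is not None:
            members = [p for p in members if p in probes_in_matrix]
        if not members:
            warnings.warn(f"DMR {dmr.dmr_id} has no probes in the matrix; unknown")
            out.append(
                DmrClassification(
                    dmr.dmr_id, None, None, None, None, dmr.gene_symbol in known
                )
            )
            continue
        tissue = any(p in tissue_probes for p in members)
        placenta = any(p in placenta_probes for p in members)
        gestation = any(p in gestation_probes for p in members)
        # a placenta-margin hit is itself a tissue difference
        tissue = tissue or placenta
        out.append(
            DmrClassification(
                dmr_id=dmr.dmr_id,
                tissue_differential=tissue,
                placenta_specific=placenta,
                gestation_change=gestation,
                stable=(not tissue) and (not gestation),
                known_imprinted=dmr.gene_symbol in known,
            )
        )
    return out


def classification_table(classifications: list[DmrClassification]) -> pd.DataFrame:
    """TSV-ready table: one row per DMR with Y/N flags."""
    rows = []
    for c in classifications:
        def yn(v):
            return "?" if v is None else ("Y" if v else "N")

        rows.append(
            {
                "dmr_id": c.dmr_id,
                "tissue_specific": yn(c.tissue_differential),
                "placenta_specific": yn(c.placenta_specific),
                "change_in_gestation": yn(c.gestation_change),
                "stable": yn(c.stable),
                "known_imprinted": "Y" if c.known_imprinted else "N",
            }
        )
    return pd.DataFrame(rows)
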