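"""Beta computation from two-channel intensities and probe-level quality filtering.

The array reports, per CpG, a fluorescence intensity for the methylated
allele (M) and one for the unmethylated allele (U); the methylation fraction
is beta = M / (M + U + offset).  Probes whose detection p-value exceeds the
threshold in *any* sample are dropped from the whole study.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, UndefinedValueError, ValidationError
from .io import BetaMatrix


@dataclass(frozen=True)
class IntensityPair:
    """Background-corrected fluorescence signals for one probe in one sample."""

    methylated_signal: float
    unmethylated_signal: float

    def __post_init__(self):
        if self.methylated_signal < 0 or self.unmethylated_signal < 0:
            raise ValidationError("intensities must be non-negative")


def beta_from_intensities(pair: IntensityPair, offset: float = 0.0) -> float:
    """Methylation fraction M / (M + U + offset), in [0, 1].

    ``offset`` defaults to 0 (the plain signal ratio); platform software
    conventionally adds a small constant (e.g. 100) to stabilise low-signal
    probes, available here as a knob.
    """
    if offset < 0:
        raise ConfigError("offset must be non-negative")
    denom = pair.methylated_signal + pair.unmethylated_signal + offset
    if denom == 0:
        raise UndefinedValueError(
            "beta undefined: both signals zero with zero offset (map to missing)"
        )
    return pair.methylated_signal / denom


def filter_by_detection(
    bm: BetaMatrix, alpha: float = 0.05, allow_missing: bool = False
) -> tuple[BetaMatrix, list[str]]:
    """Retain probes whose detection p-value is <= alpha in every sample.

    Returns the filtered matrix plus the list of removed probe ids.  With no
    detection p-values present the call is an error unless ``allow_missing``
    is set, in which case the matrix passes through unchanged.  Idempotent.
    """
    if not 0 < alpha <= 1:
        raise ConfigError("alpha must lie in (0, 1]")
    if bm.detection_p is None:
        if allow_missing:
            return bm, []
        raise ConfigError(
            "detection p-values absent; pass allow_missing=True to skip the filter"
        )
    dp = bm.detection_p.to_numpy()
    # a probe fails if any sample's detection p exceeds alpha (NaN counts as failed)
    fails = np.any(~(dp <= alpha), axis=1)
    removed = bm.probes[fails].tolist()
    kept = bm.probes[~fails]
    return bm.select_probes(kept), removed
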