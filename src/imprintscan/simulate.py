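"""Synthetic beta-value matrices with the allele-dosage structure the screen
assumes, plus ground-truth labels for recovery and calibration tests.

The generator's dosage model: a sample group contributes ``n_mat`` maternal
and ``n_pat`` paternal haploid genomes (diandric triploid 1+2, digynic 2+1,
biparental tissues 1+1, androgenetic moles 0+2).  At a maternally methylated
imprinted locus with allele levels m1 (methylated) and m0 (unmethylated),
the expected methylation fraction is the genome-dosage average

    beta = (n_mat * m1 + n_pat * m0) / (n_mat + n_pat)

attenuated toward the midpoint (m1 + m0) / 2 by the imprint ``fidelity``
(the fraction of cells actually carrying the imprint; a mixture of cell
types or incomplete CpG methylation lowers it).  With m1 = 1, m0 = 0 and
full fidelity this yields the classic values: 1/3 in diandries vs 2/3 in
digynies (a 33.3% difference), 1/2 in biparental tissue, 0 in moles at a
maternal locus.  Paternally methylated loci mirror the roles of m1 and m0.

Noise is logit-normal: beta values are perturbed on the logit scale and
mapped back, respecting the [0, 1] bounds and the variance shrinkage near
them that real arrays show.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError
from .io import BetaMatrix, CHROMOSOMES

#: (maternal, paternal) haploid genome counts per study group
GROUP_DOSAGE = {
    "diandric": (1, 2),
    "digynic": (2, 1),
    "normal_placenta": (1, 1),
    "chm": (0, 2),
    "maternal_blood": (1, 1),
    "brain": (1, 1),
    "kidney": (1, 1),
    "muscle": (1, 1),
    "placenta_mid": (1, 1),
    "placenta_term": (1, 1),
}

#: groups that are placental tissue (tissue-specific probes run high here)
PLACENTAL_GROUPS = (
    "diandric",
    "digynic",
    "normal_placenta",
    "chm",
    "placenta_mid",
    "placenta_term",
)

#: the study's sample plan
DEFAULT_SAMPLES = {
    "diandric": 10,
    "digynic": 10,
    "normal_placenta": 10,
    "chm": 6,
    "maternal_blood": 10,
    "brain": 8,
    "kidney": 12,
    "muscle": 11,
    "placenta_mid": 10,
    "placenta_term": 10,
}

_EPS = 1e-3  # clip bound before the logit transform


@dataclass(frozen=True)
class BackgroundMix:
    """Two-component logit-normal mixture for background (non-imprinted)
    promoter methylation; promoters are bimodal: mostly unmethylated CpG
    islands plus a methylated minority."""

    low: float = 0.10
    high: float = 0.85
    weight_low: float = 0.6
    spread: float = 0.6  # logit-scale sd of each component


@dataclass
class SimConfig:
    """Generator settings; defaults encode the study design."""

    n_background: int = 5000
    n_maternal_dmr: int = 50
    n_paternal_dmr: int = 50
    n_tissue_specific: int = 30
    n_gestation_drift: int = 20
    n_divergent_background: int = 0  # blood-vs-placenta background offsets
    samples_per_group: dict = field(default_factory=lambda: dict(DEFAULT_SAMPLES))
    m_methylated: float = 1.0
    m_unmethylated: float = 0.0
    fidelity: float = 1.0
    noise_sd: float = 0.05
    background_mix: BackgroundMix = field(default_factory=BackgroundMix)
    tissue_beta_placenta: float = 0.6
    tissue_beta_other: float = 0.3
    gestation_beta_mid: float = 0.3
    gestation_beta_term: float = 0.6
    probes_per_gene: int = 2
    n_detection_fail: int = 0
    seed: int = 0

    def __post_init__(self):
        counts = (
            self.n_background,
            self.n_maternal_dmr,
            self.n_paternal_dmr,
            self.n_tissue_specific,
            self.n_gestation_drift,
            self.n_divergent_background,
        )
        if any(c < 0 for c in counts):
            raise ConfigError("probe counts must be >= 0")
        for name in ("m_methylated", "m_unmethylated", "fidelity"):
            if not 0 <= getattr(self, name) <= 1:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        for g in self.samples_per_group:
            if g not in GROUP_DOSAGE:
                raise ConfigError(f"group {g!r} has no dosage definition")


@dataclass
class SimTruth:
    """Ground truth: per-probe class label and expected beta per group."""

    labels: pd.Series  # probe -> class
    expected: pd.DataFrame  # probes x groups
    origin: pd.Series  # probe -> maternal/paternal/"" for non-imprinted

    def probes_of(self, label: str) -> list[str]:
        return self.labels.index[self.labels == label].tolist()


def expected_beta(
    origin: str,
    n_maternal_genomes: int,
    n_paternal_genomes: int,
    m1: float = 1.0,
    m0: float = 0.0,
    fidelity: float = 1.0,
) -> float:
    """Expected methylation fraction at an imprinted locus under the
    haploid-genome-dosage model (see module docstring)."""
    total = n_maternal_genomes + n_paternal_genomes
    if total < 1:
        raise ConfigError("at least one haploid genome required")
    if origin == "maternal":
        dosage = (n_maternal_genomes * m1 + n_paternal_genomes * m0) / total
    elif origin == "paternal":
        dosage = (n_maternal_genomes * m0 + n_paternal_genomes * m1) / total
    else:
        raise ConfigError(f"origin must be maternal/paternal, got {origin!r}")
    midpoint = (m1 + m0) / 2
    return fidelity * dosage + (1 - fidelity) * midpoint


def _logit(p):
    return np.log(p / (1 - p))


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


def _draw_background(rng, n, mix: BackgroundMix):
    comp = rng.random(n) < mix.weight_low
    centre = np.where(comp, mix.low, mix.high)
    vals = _logistic(_logit(centre) + rng.normal(0, mix.spread, n))
    return np.clip(vals, _EPS, 1 - _EPS)


def simulate_dataset(cfg: SimConfig | None = None):
    """Generate (BetaMatrix, sample sheet, annotation, SimTruth).

    Reproducible per ``cfg.seed``.  With ``noise_sd == 0`` and full fidelity
    every cell equals its group's expected value exactly.
    """
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    groups = [g for g, n in cfg.samples_per_group.items() if n > 0]

    # --- probe classes, ids, annotation -------------------------------------
    classes = (
        ["maternal_dmr"] * cfg.n_maternal_dmr
        + ["paternal_dmr"] * cfg.n_paternal_dmr
        + ["tissue_specific"] * cfg.n_tissue_specific
        + ["gestation_drift"] * cfg.n_gestation_drift
        + ["divergent_background"] * cfg.n_divergent_background
        + ["background"] * cfg.n_background
    )
    n_probes = len(classes)
    if n_probes == 0:
        raise ConfigError("no probes requested")
    probe_ids = [f"cg{i:08d}" for i in range(n_probes)]

    gene_prefix = {
        "maternal_dmr": "MATG",
        "paternal_dmr": "PATG",
        "tissue_specific": "TISG",
        "gestation_drift": "GESG",
        "divergent_background": "DBGG",
        "background": "BKGG",
    }
    genes, counters, within = [], {}, {}
    for cls in classes:
        per_gene = cfg.probes_per_gene if cls.endswith("_dmr") else 1
        idx = counters.get(cls, 0)
        genes.append(f"{gene_prefix[cls]}{idx // per_gene:05d}")
        counters[cls] = idx + 1
    # one chromosome per gene; member probes sit 100 bp apart within the gene
    gene_order: dict[str, int] = {}
    for g in genes:
        gene_order.setdefault(g, len(gene_order))
    member_idx: dict[str, int] = {}
    chroms, positions = [], []
    for g in genes:
        k = member_idx.get(g, 0)
        member_idx[g] = k + 1
        chroms.append(CHROMOSOMES[gene_order[g] % 22])
        positions.append(1 + 10_000 * (gene_order[g] // 22) + 100 * k)
    ann = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "gene_symbol": genes,
            "chromosome": chroms,
            "position": positions,
        }
    ).set_index("probe_id")

    # --- expected beta per probe x group ------------------------------------
    expected = pd.DataFrame(index=pd.Index(probe_ids, name="probe_id"), columns=groups, dtype=float)
    origin = pd.Series("", index=expected.index, name="origin")
    bg_vals = _draw_background(rng, n_probes, cfg.background_mix)
    somatic_vals = _draw_background(rng, n_probes, cfg.background_mix)
    for i, (probe, cls) in enumerate(zip(probe_ids, classes)):
        for g in groups:
            n_mat, n_pat = GROUP_DOSAGE[g]
            if cls in ("maternal_dmr", "paternal_dmr"):
                o = "maternal" if cls == "maternal_dmr" else "paternal"
                val = expected_beta(
                    o, n_mat, n_pat, cfg.m_methylated, cfg.m_unmethylated, cfg.fidelity
                )
                origin.iloc[i] = o
            elif cls == "tissue_specific":
                val = (
                    cfg.tissue_beta_placenta
                    if g in PLACENTAL_GROUPS
                    else cfg.tissue_beta_other
                )
            elif cls == "gestation_drift":
                val = (
                    cfg.gestation_beta_term
                    if g == "placenta_term"
                    else cfg.gestation_beta_mid
                )
            elif cls == "divergent_background":
                val = bg_vals[i] if g in PLACENTAL_GROUPS else somatic_vals[i]
            else:
                val = bg_vals[i]
            expected.at[probe, g] = val

    # --- samples, noise ------------------------------------------------------
    prefix = {
        "diandric": "dia",
        "digynic": "dig",
        "normal_placenta": "pln",
        "chm": "chm",
        "maternal_blood": "mwb",
        "brain": "brn",
        "kidney": "kid",
        "muscle": "mus",
        "placenta_mid": "plm",
        "placenta_term": "plt",
    }
    sample_ids, sample_groups, gest_age = [], [], []
    for g in groups:
        for j in range(cfg.samples_per_group[g]):
            sample_ids.append(f"{prefix[g]}{j + 1:02d}")
            sample_groups.append(g)
            gest_age.append(
                {"placenta_mid": 20.0, "placenta_term": 40.0}.get(g, np.nan)
            )
    sheet = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "group": sample_groups,
            "sex": "unknown",
            "gestational_age": gest_age,
        }
    ).set_index("sample_id")

    E = np.column_stack([expected[g].to_numpy() for g in sample_groups])
    if cfg.noise_sd == 0:
        beta = E.copy()
    else:
        mu = _logit(np.clip(E, _EPS, 1 - _EPS))
        beta = _logistic(mu + rng.normal(0, cfg.noise_sd, E.shape))
        beta = np.clip(beta, _EPS, 1 - _EPS)
    beta_df = pd.DataFrame(beta, index=expected.index, columns=sample_ids)

    detection = pd.DataFrame(
        rng.uniform(0.0, 0.04, beta.shape), index=expected.index, columns=sample_ids
    )
    if cfg.n_detection_fail > 0:
        fail_probes = rng.choice(n_probes, size=min(cfg.n_detection_fail, n_probes), replace=False)
        for p in fail_probes:
            detection.iat[int(p), int(rng.integers(len(sample_ids)))] = 0.06

    truth = SimTruth(
        labels=pd.Series(classes, index=expected.index, name="class"),
        expected=expected,
        origin=origin,
    )
    return BetaMatrix(beta_df, detection), sheet, ann, truth


def simulate_null_dataset(cfg: SimConfig | None = None):
    """Same tuple with zero imprinted/structured probes (pure background)."""
    cfg = cfg or SimConfig()
    null_cfg = replace(
        cfg,
        n_maternal_dmr=0,
        n_paternal_dmr=0,
        n_tissue_specific=0,
        n_gestation_drift=0,
        n_divergent_background=0,
    )
    return simulate_dataset(null_cfg)
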