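"""Synthetic transcriptome, count, allele, and plate generators.

The generators plant known context effects so every pipeline stage can be
tested for parameter recovery without external data.  Defaults encode the
qualitative biology the analyses are about: UGA > UAG > UAA stop-codon
permissiveness, nt+4 C > U > A/G, readthrough increasing with 3'-UTR
length, and a sparse P-site codon effect.  The latent model is

    log2 RE = intercept + b_stop + b_nt4 + b_len * log10(utr3_len)
              + b_psite + Normal(0, sigma)

with stop-codon usage anchored at 49/27/24% (UGA/UAG/UAA) and nt+4
favouring A and G over C with U depleted.  With the default b_len = 0.8
per log10 nt and log-normal 3'-UTR lengths (ln-sigma 1.0), the latent
length-RE correlation is ~0.30 (variance arithmetic in the methods note).

Counts are gamma-Poisson (negative binomial) around region-length- and
expression-scaled means; plates are log-normal multiplicative noise
around planted readthrough percentages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import MrnaRecord, find_extension_region
from .dualluc import LucExperiment
from .genetics import SENSE_CODONS
from .ptc import PtcAllele

_BASES = np.frombuffer(b"ACGU", dtype=np.uint8)


@dataclass
class SimConfig:
    """Study conditions for the synthetic transcriptome."""

    n_transcripts: int = 3000
    stop_freqs: dict = field(
        default_factory=lambda: {"UGA": 0.49, "UAG": 0.27, "UAA": 0.24})
    nt4_freqs: dict = field(
        default_factory=lambda: {"A": 0.32, "C": 0.24, "G": 0.32, "U": 0.12})
    utr5_range: tuple = (50, 300)          # nt, uniform
    cds_codons_range: tuple = (40, 400)    # sense codons incl. start, uniform
    utr3_ln_mean: float = math.log(300.0)  # ln nt
    utr3_ln_sigma: float = 1.0
    utr3_min: int = 36
    intercept: float = -6.0                # log2 RE ~ 1.6% basal readthrough
    beta_stop: dict = field(
        default_factory=lambda: {"UGA": 0.6, "UAG": 0.0, "UAA": -0.4})
    beta_nt4: dict = field(
        default_factory=lambda: {"C": 0.3, "U": 0.1, "A": -0.2, "G": -0.2})
    beta_len: float = 0.8                  # per log10 nt of 3'-UTR
    beta_psite: dict = field(
        default_factory=lambda: {"UGG": 0.3, "AAG": -0.2})
    sigma: float = 1.0                     # residual SD of log2 RE
    coverage: float = 0.5                  # mean CDS reads per nt
    expr_ln_sigma: float = 0.7             # per-transcript expression spread
    dispersion: float = 10.0               # negative-binomial size parameter
    seed: int = 0

    def __post_init__(self):
        for name in ("stop_freqs", "nt4_freqs"):
            total = sum(getattr(self, name).values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1, got {total}")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")


def strong_signal_config(**overrides) -> SimConfig:
    """High signal-to-noise conditions for model-comparison analyses.

    Doubled context effects and halved residual noise, so differences
    between feature-schema variants are resolvable at desk scale.
    """
    cfg = SimConfig(
        beta_stop={"UGA": 1.2, "UAG": 0.0, "UAA": -0.8},
        beta_nt4={"C": 0.6, "U": 0.2, "A": -0.4, "G": -0.4},
        beta_psite={"UGG": 0.6, "AAG": -0.4},
        sigma=0.5,
    )
    for key, value in overrides.items():
        setattr(cfg, key, value)
    return cfg


def _random_bases(rng: np.random.Generator, n: int) -> str:
    if n <= 0:
        return ""
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode()


def _random_sense_codons(rng: np.random.Generator, n: int) -> str:
    idx = rng.integers(0, len(SENSE_CODONS), size=n)
    return "".join(SENSE_CODONS[i] for i in idx)


def simulate_catalog(config: SimConfig) -> tuple[list[MrnaRecord], pd.DataFrame]:
    """Draw a transcript catalog with planted latent log2 RE per record.

    Returns (records, truth) where truth has columns transcript_id,
    true_log2_re, stop_codon, nt4, psite_codon, utr3_len.
    """
    rng = np.random.default_rng(config.seed)
    stops = list(config.stop_freqs)
    stop_p = [config.stop_freqs[s] for s in stops]
    nt4s = list(config.nt4_freqs)
    nt4_p = [config.nt4_freqs[b] for b in nt4s]

    records, rows = [], []
    for i in range(config.n_transcripts):
        utr5_len = int(rng.integers(*config.utr5_range))
        n_codons = int(rng.integers(*config.cds_codons_range))
        utr3_len = max(config.utr3_min,
                       int(round(rng.lognormal(config.utr3_ln_mean,
                                               config.utr3_ln_sigma))))
        stop = stops[rng.choice(len(stops), p=stop_p)]
        nt4 = nt4s[rng.choice(len(nt4s), p=nt4_p)]

        cds = "AUG" + _random_sense_codons(rng, n_codons - 1)
        psite = cds[-3:]
        sequence = (
            _random_bases(rng, utr5_len) + cds + stop + nt4
            + _random_bases(rng, utr3_len - 4)
        )
        record = MrnaRecord(f"TX{i:05d}", sequence, utr5_len, 3 * n_codons, utr3_len)
        true_re = (
            config.intercept
            + config.beta_stop.get(stop, 0.0)
            + config.beta_nt4.get(nt4, 0.0)
            + config.beta_len * math.log10(utr3_len)
            + config.beta_psite.get(psite, 0.0)
            + (rng.normal(0.0, config.sigma) if config.sigma > 0 else 0.0)
        )
        records.append(record)
        rows.append({
            "transcript_id": record.transcript_id,
            "true_log2_re": true_re,
            "stop_codon": stop,
            "nt4": nt4,
            "psite_codon": psite,
            "utr3_len": utr3_len,
        })
    return records, pd.DataFrame(rows)


def _negbin(rng: np.random.Generator, mean: np.ndarray, size_param: float) -> np.ndarray:
    """Gamma-Poisson negative binomial; infinite size gives the Poisson limit."""
    mean = np.clip(mean, 0.0, None)
    if np.isinf(size_param):
        return rng.poisson(mean)
    lam = np.where(mean > 0, rng.gamma(size_param, 1.0, size=len(mean)) * mean / size_param, 0.0)
    return rng.poisson(lam)


def simulate_counts(
    records: list[MrnaRecord], true_log2_re: np.ndarray, config: SimConfig
) -> pd.DataFrame:
    """Region read counts consistent with the planted log2 RE values.

    CDS counts are negative binomial around coverage x expression x
    length; extension-region counts scale the per-nt CDS rate by
    2^(true log2 RE).  One library size (the grand total) is shared.
    """
    rng = np.random.default_rng([config.seed, 1])
    n = len(records)
    ext = [find_extension_region(r) for r in records]
    cds_len = np.array([r.cds_len for r in records], dtype=float)
    ext_len = np.array([e.length for e in ext], dtype=float)
    expr = rng.lognormal(0.0, config.expr_ln_sigma, size=n)
    rate = config.coverage * expr  # reads per nt of CDS
    cds_mean = rate * cds_len
    ext_mean = rate * np.power(2.0, np.asarray(true_log2_re, dtype=float)) * ext_len
    cds_count = _negbin(rng, cds_mean, config.dispersion)
    ext_count = _negbin(rng, ext_mean, config.dispersion)
    library = int(cds_count.sum() + ext_count.sum())
    return pd.DataFrame({
        "transcript_id": [r.transcript_id for r in records],
        "cds_count": cds_count.astype(int),
        "ext_count": ext_count.astype(int),
        "cds_len": cds_len.astype(int),
        "ext_len": ext_len.astype(int),
        "library_size": max(library, 1),
    })


def simulate_alleles(
    n_alleles: int,
    seed: int = 0,
    gene_codons: int = 120,
    utr3_native_range: tuple = (100, 2000),
) -> list[PtcAllele]:
    """Random nonsense alleles over random stop-less gene bodies."""
    rng = np.random.default_rng(seed)
    alleles = []
    stops = ("UGA", "UAG", "UAA")
    for i in range(n_alleles):
        body = "AUG" + _random_sense_codons(rng, gene_codons - 2) + "UAA"
        k = int(rng.integers(10, gene_codons - 10))
        utr3_len = int(rng.integers(*utr3_native_range))
        alleles.append(PtcAllele(
            name=f"PTC{i:03d}",
            gene_cds=body,
            utr3_native=_random_bases(rng, utr3_len),
            ptc_codon_index=k,
            ptc_stop=stops[int(rng.integers(0, 3))],
        ))
    return alleles


def simulate_reporter_spec(
    seed: int = 0,
    upstream_codons: int = 310,
    downstream_codons: int = 550,
    utr3_tail_len: int = 150,
) -> "ReporterSpec":
    """A synthetic dual-luciferase backbone (stand-in for the real construct;
    random stop-less upstream gene, start-less downstream gene, vector tail)."""
    from .ptc import ReporterSpec

    rng = np.random.default_rng(seed)
    upstream = "AUG" + _random_sense_codons(rng, upstream_codons - 1)
    downstream = _random_sense_codons(rng, downstream_codons - 1) + "UAA"
    return ReporterSpec(
        upstream_gene=upstream,
        downstream_gene=downstream,
        utr3_tail=_random_bases(rng, utr3_tail_len),
    )


def simulate_dualluc(
    truth: dict,
    noise_ln_sigma: float = 0.1,
    n_experiments: int = 6,
    n_wells: int = 4,
    outlier_rate: float = 0.0,
    outlier_factor: float = 5.0,
    seed: int = 0,
) -> tuple[list[LucExperiment], list[dict]]:
    """Replicate luciferase plates around planted readthrough percentages.

    ``truth`` maps allele -> {"untreated": percent, "G418": percent}.
    Renilla signals are log-normal around a plate constant; firefly is
    Renilla x truth/100 under multiplicative log-normal noise.  Planted
    outlier wells (firefly multiplied by ``outlier_factor``) occur at
    ``outlier_rate`` and are reported alongside.
    """
    rng = np.random.default_rng(seed)
    experiments, planted = [], []
    for allele in sorted(truth):
        for e in range(n_experiments):
            for condition, level in sorted(truth[allele].items()):
                if level <= 0:
                    raise ValueError(f"{allele}/{condition}: truth must be positive")
                wells = []
                for w in range(n_wells):
                    renilla = rng.lognormal(math.log(1e6), 0.2)
                    noise = rng.lognormal(0.0, noise_ln_sigma) if noise_ln_sigma > 0 else 1.0
                    firefly = renilla * level / 100.0 * noise
                    if outlier_rate > 0 and rng.random() < outlier_rate:
                        firefly *= outlier_factor
                        planted.append({"allele": allele, "experiment": f"E{e}",
                                        "condition": condition, "well": w})
                    wells.append((firefly, renilla))
                experiments.append(
                    LucExperiment(allele, f"E{e}", condition, wells))
    return experiments, planted
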