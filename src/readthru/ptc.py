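"""Premature-termination-codon (PTC) readthrough prediction.

A nonsense allele is specified in transcript space: the gene's coding
sequence, the codon index replaced by a stop, and the stop identity.
Two sequence contexts can be built for prediction:

* **native** — the PTC embedded in the gene's own mRNA: the CDS is
  truncated at the PTC and everything downstream (the former CDS
  remainder plus the native 3'-UTR) becomes the new 3'-UTR, with the
  extension region re-anchored at the PTC.
* **reporter** — the PTC plus three flanking codons on each side inserted
  between a stop-less upstream luciferase gene and a start-less
  downstream luciferase gene, exactly as a dual-luciferase construct
  carries it; features outside the insert come from the reporter
  backbone and are constant across alleles.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .catalog import MrnaRecord
from .features import extract_feature_table
from .forest import TrainedModel, predict_readthrough
from .genetics import STOP_CODONS, normalize_rna
from .stats import correlate


@dataclass(frozen=True)
class PtcAllele:
    """A nonsense allele in transcript coordinates.

    ``gene_cds`` is the full coding sequence including the native stop
    codon; ``ptc_codon_index`` is the 1-based codon replaced by
    ``ptc_stop``.
    """

    name: str
    gene_cds: str
    utr3_native: str
    ptc_codon_index: int
    ptc_stop: str
    utr5_native: str = ""

    def __post_init__(self):
        object.__setattr__(self, "gene_cds", normalize_rna(self.gene_cds))
        object.__setattr__(self, "utr3_native", normalize_rna(self.utr3_native))
        object.__setattr__(self, "utr5_native", normalize_rna(self.utr5_native))
        if len(self.gene_cds) % 3 != 0:
            raise ValueError(f"{self.name}: CDS length not a multiple of 3")
        n_codons = len(self.gene_cds) // 3
        if not 1 <= self.ptc_codon_index < n_codons:
            raise ValueError(
                f"{self.name}: PTC codon index {self.ptc_codon_index} outside "
                f"[1, {n_codons - 1}]"
            )
        if self.ptc_stop not in STOP_CODONS:
            raise ValueError(f"{self.name}: {self.ptc_stop!r} is not a stop codon")


@dataclass(frozen=True)
class ReporterSpec:
    """Dual-luciferase construct layout around the PTC insert."""

    upstream_gene: str    # stop-less Renilla CDS (starts with its AUG)
    downstream_gene: str  # start-less firefly CDS (ends with its stop)
    utr3_tail: str        # vector sequence from the firefly stop to poly(A)
    flank_codons: int = 3
    utr5: str = ""

    def __post_init__(self):
        for f in ("upstream_gene", "downstream_gene", "utr3_tail", "utr5"):
            object.__setattr__(self, f, normalize_rna(getattr(self, f)))
        if len(self.upstream_gene) % 3 != 0:
            raise ValueError("upstream gene length not a multiple of 3")
        if self.flank_codons < 0:
            raise ValueError("flank_codons must be >= 0")
        for i in range(0, len(self.upstream_gene), 3):
            if self.upstream_gene[i:i + 3] in STOP_CODONS:
                raise ValueError("upstream gene contains an in-frame stop codon")

    @property
    def utr3_reporter_len(self) -> int:
        """nt from the PTC to the poly(A) signal, constant across alleles."""
        return 3 + 3 * self.flank_codons + len(self.downstream_gene) + len(self.utr3_tail)


def build_native_record(allele: PtcAllele) -> MrnaRecord:
    """The allele's native mRNA with the PTC as its stop codon."""
    k = allele.ptc_codon_index
    if k == 1:
        raise ValueError(f"{allele.name}: PTC at codon 1 leaves no P-site codon")
    upstream = allele.gene_cds[:3 * (k - 1)]
    downstream = allele.gene_cds[3 * k:]
    sequence = allele.utr5_native + upstream + allele.ptc_stop + downstream + allele.utr3_native
    return MrnaRecord(
        transcript_id=allele.name,
        sequence=sequence,
        utr5_len=len(allele.utr5_native),
        cds_len=3 * (k - 1),
        utr3_len=3 + len(downstream) + len(allele.utr3_native),
    )


def build_reporter_record(allele: PtcAllele, spec: ReporterSpec) -> MrnaRecord:
    """The allele's PTC in the dual-luciferase construct."""
    k = allele.ptc_codon_index
    fc = spec.flank_codons
    n_codons = len(allele.gene_cds) // 3
    if k - 1 < fc or n_codons - k < fc:
        raise ValueError(
            f"{allele.name}: flank of {fc} codons extends past the gene ends"
        )
    up_flank = allele.gene_cds[3 * (k - 1 - fc):3 * (k - 1)]
    down_flank = allele.gene_cds[3 * k:3 * (k + fc)]
    cds = spec.upstream_gene + up_flank
    sequence = (spec.utr5 + cds + allele.ptc_stop + down_flank
                + spec.downstream_gene + spec.utr3_tail)
    return MrnaRecord(
        transcript_id=allele.name,
        sequence=sequence,
        utr5_len=len(spec.utr5),
        cds_len=len(cds),
        utr3_len=spec.utr3_reporter_len,
    )


def predict_alleles(
    model: TrainedModel,
    alleles: list[PtcAllele],
    scheme: str,
    spec: ReporterSpec | None = None,
    nc_seed: int = 0,
) -> pd.DataFrame:
    """Predict readthrough for each allele under one context scheme.

    Returns a table ``name, scheme, predicted_log2_re`` plus the feature
    columns used, for audit.  Negative-control features (which carry no
    signal in a trained model but are part of the schema) are attached
    from ``nc_seed``.
    """
    if scheme == "native":
        records = [build_native_record(a) for a in alleles]
    elif scheme == "reporter":
        if spec is None:
            raise ValueError("reporter scheme needs a ReporterSpec")
        records = [build_reporter_record(a, spec) for a in alleles]
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    table, excluded = extract_feature_table(records, model.schema)
    if excluded:
        raise ValueError(f"alleles with N in feature windows: {excluded}")
    from .features import attach_negative_controls

    table = attach_negative_controls(table, seed=nc_seed)
    preds = predict_readthrough(model, table)
    out = table.copy()
    out.insert(0, "name", table["transcript_id"])
    out.insert(1, "scheme", scheme)
    out.insert(2, "predicted_log2_re", preds)
    return out.drop(columns=["transcript_id"])


def compare_prediction_schemes(
    pred_a, pred_b, leave_out: int = 0
) -> tuple[float, float, pd.DataFrame]:
    """Spearman agreement between two paired prediction (or measurement) sets.

    With ``leave_out=k > 0``, also reports the k points whose joint removal
    most increases rho (brute force over all k-subsets) — the outlier
    sensitivity used to flag discordant alleles.
    """
    a = np.asarray(pred_a, dtype=float)
    b = np.asarray(pred_b, dtype=float)
    if len(a) != len(b):
        raise ValueError("length mismatch")
    rho, p, n = correlate(a, b)
    outliers = pd.DataFrame(columns=["removed", "rho_without"])
    if leave_out > 0 and n - leave_out >= 4:
        best_rho, best_set = -np.inf, None
        for combo in itertools.combinations(range(n), leave_out):
            mask = np.ones(n, dtype=bool)
            mask[list(combo)] = False
            r, _, _ = correlate(a[mask], b[mask])
            if r > best_rho:
                best_rho, best_set = r, combo
        outliers = pd.DataFrame(
            {"removed": list(best_set), "rho_without": best_rho}
        )
    return rho, p, outliers
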