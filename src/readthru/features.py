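"""Stop-codon context feature engineering.

Each transcript's extended stop-codon context is encoded into a fixed,
named feature vector used by the random-forest models:

* **context** (21) — the stop codon itself, the nine nucleotides upstream
  of it (nt -1..-9), the nine nucleotides after it (nt +4..+12, where the
  stop codon bases are numbered +1..+3), and the P-site codon and its
  amino acid.  These are the features a minimal reporter construct carries.
* **tunnel** (10) — aggregate physicochemical properties of the last 30
  encoded residues, i.e. the nascent-peptide stretch occupying the
  ribosome's exit tunnel at termination.
* **other** (44) — nucleotides nt -10..-30 and nt +13..+30, the three
  region lengths, and the E-site codon/amino acid.
* **negative_control** (2) — a random integer 1..100 and a random letter
  from {A,C,G,U} assigned per transcript, setting the importance baseline
  for an uninformative feature.

21 + 10 + 44 = 75 biological features; the two negative controls sit
outside that count.  Positions that run off the annotated regions are set
to the explicit missing level ``"NA_short"`` rather than dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import MrnaRecord
from .genetics import (
    ALL_CODONS,
    AMINO_ACIDS,
    AROMATIC_AA,
    CODON_TABLE,
    KYTE_DOOLITTLE,
    NEGATIVE_AA,
    NUCLEOTIDES,
    POLAR_AA,
    POSITIVE_AA,
    SMALL_AA,
    STOP_CODONS,
    charge_class,
    translate,
)

NA_LEVEL = "NA_short"

TUNNEL_WINDOW = 30  # residues

UPSTREAM_CONTEXT = 9    # nt -1..-9
UPSTREAM_TOTAL = 30     # nt -1..-30
DOWNSTREAM_CONTEXT = 12  # nt +4..+12 (stop bases are +1..+3)
DOWNSTREAM_TOTAL = 30    # nt +4..+30

TUNNEL_FEATURES = (
    "tunnel_frac_positive",
    "tunnel_frac_negative",
    "tunnel_net_charge",
    "tunnel_mean_hydropathy",
    "tunnel_frac_aromatic",
    "tunnel_frac_proline",
    "tunnel_frac_glycine",
    "tunnel_frac_polar",
    "tunnel_frac_small",
    "tunnel_cterm_charge",
)

VARIANT_NAMES = ("reduced", "mock1", "mock2", "mock3", "assay")


@dataclass(frozen=True)
class FeatureSchema:
    """A named, ordered feature composition with per-feature group tags."""

    name: str
    feature_names: tuple[str, ...]
    groups: dict[str, str] = field(hash=False)

    def __post_init__(self):
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("duplicate feature names")
        if set(self.groups) != set(self.feature_names):
            raise ValueError("groups must tag exactly the schema's features")

    def count(self, group: str) -> int:
        return sum(1 for g in self.groups.values() if g == group)

    @property
    def biological_features(self) -> tuple[str, ...]:
        return tuple(
            f for f in self.feature_names if self.groups[f] != "negative_control"
        )

    def subset(self, name: str, keep: set[str]) -> "FeatureSchema":
        names = tuple(f for f in self.feature_names if f in keep)
        return FeatureSchema(name, names, {f: self.groups[f] for f in names})


@dataclass
class FeatureVector:
    transcript_id: str
    values: dict[str, object]
    valid: bool = True
    invalid_reason: str | None = None


def default_schema() -> FeatureSchema:
    """The "full" schema (version full-v1): 75 features + 2 negative controls."""
    names: list[str] = []
    groups: dict[str, str] = {}

    def add(name: str, group: str) -> None:
        names.append(name)
        groups[name] = group

    add("stop_codon", "context")
    for k in range(1, UPSTREAM_CONTEXT + 1):
        add(f"nt_m{k}", "context")
    for m in range(4, DOWNSTREAM_CONTEXT + 1):
        add(f"nt_p{m}", "context")
    add("psite_codon", "context")
    add("psite_aa", "context")
    for f in TUNNEL_FEATURES:
        add(f, "tunnel")
    for k in range(UPSTREAM_CONTEXT + 1, UPSTREAM_TOTAL + 1):
        add(f"nt_m{k}", "other")
    for m in range(DOWNSTREAM_CONTEXT + 1, DOWNSTREAM_TOTAL + 1):
        add(f"nt_p{m}", "other")
    add("utr5_len", "other")
    add("cds_len", "other")
    add("utr3_len", "other")
    add("esite_codon", "other")
    add("esite_aa", "other")
    add("nc_number", "negative_control")
    add("nc_letter", "negative_control")
    return FeatureSchema("full", tuple(names), groups)


def feature_kind(name: str) -> str:
    """Value domain of a feature: one of nucleotide, stop, codon, aa,
    charge, letter, numeric."""
    if name.startswith("nt_"):
        return "nucleotide"
    if name == "stop_codon":
        return "stop"
    if name in ("psite_codon", "esite_codon"):
        return "codon"
    if name in ("psite_aa", "esite_aa"):
        return "aa"
    if name == "tunnel_cterm_charge":
        return "charge"
    if name == "nc_letter":
        return "letter"
    return "numeric"


#: Fixed, alphabetically ordered level registries per categorical kind;
#: the trailing NA level doubles as the bucket for unseen levels.
LEVEL_REGISTRY: dict[str, tuple[str, ...]] = {
    "nucleotide": NUCLEOTIDES + (NA_LEVEL,),
    "stop": STOP_CODONS,
    "codon": ALL_CODONS + (NA_LEVEL,),
    "aa": AMINO_ACIDS + (NA_LEVEL,),
    "charge": ("negative", "neutral", "positive"),
    "letter": NUCLEOTIDES,
}


def extract_features(record: MrnaRecord, schema: FeatureSchema) -> FeatureVector:
    """Pure read-off of schema features from one valid record.

    Out-of-range positions become ``NA_LEVEL``; an ``N`` inside any
    requested window invalidates the vector (``valid=False``).  Negative
    control slots are left unset; see :func:`attach_negative_controls`.
    """
    seq = record.sequence
    stop0 = record.stop_offset
    values: dict[str, object] = {}
    saw_n = False

    def nt_at(offset: int, lower_bound: int) -> str:
        nonlocal saw_n
        if offset < lower_bound or offset >= len(seq):
            return NA_LEVEL
        base = seq[offset]
        if base == "N":
            saw_n = True
        return base

    def codon_at(offset: int) -> str:
        nonlocal saw_n
        if offset < record.utr5_len:
            return NA_LEVEL
        codon = seq[offset:offset + 3]
        if "N" in codon:
            saw_n = True
        return codon

    for name in schema.feature_names:
        group = schema.groups[name]
        if group == "negative_control":
            continue
        if name == "stop_codon":
            values[name] = record.stop_codon
        elif name.startswith("nt_m"):
            k = int(name[4:])
            # upstream positions are CDS positions; running past the start
            # codon yields the explicit missing level
            values[name] = nt_at(stop0 - k, record.utr5_len)
        elif name.startswith("nt_p"):
            m = int(name[4:])
            values[name] = nt_at(stop0 + m - 1, 0)
        elif name == "psite_codon":
            values[name] = codon_at(stop0 - 3)
        elif name == "esite_codon":
            values[name] = codon_at(stop0 - 6) if record.cds_len >= 6 else NA_LEVEL
        elif name == "psite_aa":
            codon = codon_at(stop0 - 3)
            values[name] = CODON_TABLE.get(codon, NA_LEVEL)
        elif name == "esite_aa":
            codon = codon_at(stop0 - 6) if record.cds_len >= 6 else NA_LEVEL
            values[name] = CODON_TABLE.get(codon, NA_LEVEL)
        elif name.startswith("tunnel_"):
            pass  # computed in one pass below
        elif name == "utr5_len":
            values[name] = record.utr5_len
        elif name == "cds_len":
            values[name] = record.cds_len
        elif name == "utr3_len":
            values[name] = record.utr3_len
        else:
            raise KeyError(f"unknown feature {name!r}")

    tunnel_requested = [f for f in schema.feature_names if f.startswith("tunnel_")]
    if tunnel_requested:
        n_res = min(TUNNEL_WINDOW, record.cds_len // 3)
        tail = seq[stop0 - 3 * n_res:stop0]
        if "N" in tail:
            saw_n = True
            for f in tunnel_requested:
                values[f] = np.nan
        else:
            aa = translate(tail)
            n = len(aa)
            pos = sum(a in POSITIVE_AA for a in aa)
            neg = sum(a in NEGATIVE_AA for a in aa)
            computed = {
                "tunnel_frac_positive": pos / n,
                "tunnel_frac_negative": neg / n,
                "tunnel_net_charge": pos - neg,
                "tunnel_mean_hydropathy": sum(KYTE_DOOLITTLE[a] for a in aa) / n,
                "tunnel_frac_aromatic": sum(a in AROMATIC_AA for a in aa) / n,
                "tunnel_frac_proline": aa.count("P") / n,
                "tunnel_frac_glycine": aa.count("G") / n,
                "tunnel_frac_polar": sum(a in POLAR_AA for a in aa) / n,
                "tunnel_frac_small": sum(a in SMALL_AA for a in aa) / n,
                "tunnel_cterm_charge": charge_class(aa[-1]),
            }
            for f in tunnel_requested:
                values[f] = computed[f]

    if saw_n:
        return FeatureVector(record.transcript_id, values, valid=False,
                             invalid_reason="N in a requested window")
    return FeatureVector(record.transcript_id, values)


def extract_feature_table(
    records: list[MrnaRecord], schema: FeatureSchema
) -> tuple[pd.DataFrame, list[str]]:
    """Feature matrix for many records; invalid records (N in a window)
    are excluded and returned by id."""
    rows, excluded = [], []
    for record in records:
        vec = extract_features(record, schema)
        if vec.valid:
            rows.append({"transcript_id": vec.transcript_id, **vec.values})
        else:
            excluded.append(vec.transcript_id)
    columns = ["transcript_id"] + [
        f for f in schema.feature_names
        if schema.groups[f] != "negative_control"
    ]
    df = pd.DataFrame(rows, columns=columns)
    return df, excluded


def attach_negative_controls(table: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Add nc_number ~ U{1..100} and nc_letter ~ U{A,C,G,U} per transcript.

    The assignment is keyed on (seed, transcript_id), so it is reproducible,
    independent of all biological features, and invariant to row order.
    """
    from zlib import crc32

    out = table.copy()
    numbers, letters = [], []
    for tid in out["transcript_id"].astype(str):
        rng = np.random.default_rng([seed, crc32(tid.encode())])
        numbers.append(int(rng.integers(1, 101)))
        letters.append(NUCLEOTIDES[int(rng.integers(0, 4))])
    out["nc_number"] = numbers
    out["nc_letter"] = letters
    return out


def derive_variant_schema(
    variant: str,
    importance: pd.DataFrame | None = None,
    seed: int = 0,
    base: FeatureSchema | None = None,
) -> FeatureSchema:
    """Model-comparison schemas.

    * ``reduced`` — the assay's context features plus every non-tunnel
      feature that clears the importance baseline (without an importance
      table: context + 3'-UTR length).
    * ``assay`` — reduced minus 3'-UTR length and every other
      non-context feature (i.e. exactly the 21 context features a
      reporter construct carries).
    * ``mock1..3`` — seeded random draws of low-importance features,
      matched in size to reduced.  Requires an importance table.

    Thresholds: the scaled permutation importance is a t-like statistic,
    so the two negative-control scores alone are a noisy cutoff.  A
    feature counts as *important* when its score exceeds both the larger
    negative-control score and 2 (nominally significant); it is eligible
    for a mock when its score is at most max(larger NC score, 0) — a
    non-positive permutation importance is uninformative by definition
    even when both controls happen to land below zero.
    """
    if variant not in VARIANT_NAMES:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANT_NAMES}")
    base = base or default_schema()
    context = {f for f in base.feature_names if base.groups[f] == "context"}

    if importance is not None:
        imp = importance.set_index("feature")["importance"]
        nc_scores = [imp[f] for f in ("nc_number", "nc_letter") if f in imp.index]
        if not nc_scores:
            raise ValueError("importance table lacks negative-control rows")
        baseline = max(nc_scores)
        important = {
            f for f in base.biological_features
            if f in imp.index and imp[f] > max(baseline, 2.0)
        }
    else:
        if variant.startswith("mock"):
            raise ValueError("mock variants require an importance table")
        baseline = None
        important = {"utr3_len"}

    reduced = {
        f for f in (context | important)
        if base.groups[f] not in ("tunnel", "negative_control")
    }

    if variant == "reduced":
        keep = reduced
    elif variant == "assay":
        keep = reduced & context
    else:
        low = [
            f for f in base.biological_features
            if f in imp.index and imp[f] <= max(baseline, 0.0)
        ]
        if len(low) < len(reduced):
            raise ValueError(
                f"only {len(low)} low-importance features available, "
                f"need {len(reduced)} for {variant}"
            )
        k = int(variant[4:])
        rng = np.random.default_rng([seed, k])
        keep = set(rng.choice(sorted(low), size=len(reduced), replace=False))

    keep |= {"nc_number", "nc_letter"}
    return base.subset(variant, keep)


def encode_feature_matrix(
    table: pd.DataFrame, schema: FeatureSchema
) -> tuple[np.ndarray, list[str]]:
    """Encode the feature table into a float matrix for tree models.

    Categorical features become integer codes via the fixed alphabetical
    level registries (trees see them as integer-coded categories; the
    level order is frozen for reproducibility).  Unseen levels map to the
    NA bucket.  Returns (matrix, warnings).
    """
    warnings: list[str] = []
    cols = []
    for name in schema.feature_names:
        kind = feature_kind(name)
        col = table[name]
        if kind == "numeric":
            cols.append(pd.to_numeric(col).to_numpy(dtype=np.float64))
            continue
        levels = LEVEL_REGISTRY[kind]
        lookup = {lev: i for i, lev in enumerate(levels)}
        na_code = lookup.get(NA_LEVEL, len(levels) - 1)
        codes = np.empty(len(col), dtype=np.float64)
        unseen = set()
        for i, v in enumerate(col):
            code = lookup.get(v)
            if code is None:
                unseen.add(v)
                code = na_code
            codes[i] = code
        if unseen:
            warnings.append(
                f"{name}: unseen levels {sorted(map(str, unseen))} mapped to NA bucket"
            )
        cols.append(codes)
    return np.column_stack(cols), warnings
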