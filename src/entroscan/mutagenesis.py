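"""Mutagenesis feature evaluation.

Structural mutants (designed to disrupt one of a riboswitch's two
functional conformations) are expected to show a *drop* in folding-space
diversity relative to wild type; non-structural mutants are not.  The
protocol scores each feature by the per-mutant percentage change Δ%,
predicts "structural" when Δ falls strictly below a per-record threshold
(0 by default; a small negative allowance when the mutant's length
differs from wild type, since entropy scales roughly linearly with
length), and summarizes with sensitivity, specificity, and MCC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .classify import mcc as _mcc

STRUCTURAL = "structural"
NON_STRUCTURAL = "non-structural"


@dataclass
class MutantRecord:
    """One mutant's Δ% values against its wild type."""

    wild_type_id: str
    mutant_id: str
    feature_deltas: Mapping[str, float]
    disrupts_one_structure: bool
    threshold: float = 0.0

    def __post_init__(self):
        if self.threshold > 0:
            raise ValueError("decision threshold must be <= 0")
        for k, v in self.feature_deltas.items():
            if not math.isfinite(v):
                raise ValueError(f"non-finite delta for feature {k}")


def delta_percent(wild_value: float, mutant_value: float) -> float:
    """Percentage change 100·(mutant − wild)/|wild|.

    The absolute-value denominator keeps the sign convention "negative Δ
    means a decrease" even for negative wild-type values (possible for
    Sil); wild type of exactly 0 is an error.
    """
    if wild_value == 0:
        raise ValueError("wild-type value is zero; delta percent undefined")
    return 100.0 * (mutant_value - wild_value) / abs(wild_value)


def classify_mutant(delta: float, threshold: float = 0.0) -> str:
    """Predict 'structural' iff Δ is strictly below the threshold.

    Zero or positive Δ (relative to the threshold) predicts a
    non-structural mutant.
    """
    return STRUCTURAL if delta < threshold else NON_STRUCTURAL


def evaluate_feature(
    records: Sequence[MutantRecord], feature: str
) -> tuple[float, float, float]:
    """(sensitivity %, specificity %, MCC) of one feature over the records.

    Sensitivity: share of structural mutants predicted structural.
    Specificity: share of non-structural mutants predicted non-structural.
    """
    tp = fp = tn = fn = 0
    for rec in records:
        if feature not in rec.feature_deltas:
            raise KeyError(f"record {rec.mutant_id}: no delta for feature {feature!r}")
        predicted = classify_mutant(rec.feature_deltas[feature], rec.threshold)
        if rec.disrupts_one_structure:
            if predicted == STRUCTURAL:
                tp += 1
            else:
                fn += 1
        else:
            if predicted == NON_STRUCTURAL:
                tn += 1
            else:
                fp += 1
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("need at least one record of each label")
    sensitivity = 100.0 * tp / (tp + fn)
    specificity = 100.0 * tn / (tn + fp)
    return sensitivity, specificity, float(_mcc(tp, fp, tn, fn))


def evaluate_all(
    records: Sequence[MutantRecord], features: Sequence[str]
) -> pd.DataFrame:
    rows = []
    for f in features:
        sens, spec, m = evaluate_feature(records, f)
        rows.append({"feature": f, "sensitivity_pct": sens, "specificity_pct": spec, "mcc": m})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# TSV I/O

_META_COLUMNS = {"wild_type_id", "mutant_id", "disrupts_one_structure", "threshold"}


def read_mutant_table(path: str | Path) -> list[MutantRecord]:
    """Read a mutant table: one row per mutant, one ``d<FEATURE>`` column per
    feature Δ%, a yes/no disruption label, and a per-record threshold."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = _META_COLUMNS - set(df.columns)
    if missing:
        raise ValueError(f"mutant table missing columns: {sorted(missing)}")
    feature_cols = [c for c in df.columns if c.startswith("d") and c not in _META_COLUMNS]
    records = []
    for _, row in df.iterrows():
        records.append(
            MutantRecord(
                wild_type_id=str(row["wild_type_id"]),
                mutant_id=str(row["mutant_id"]),
                feature_deltas={c[1:]: float(row[c]) for c in feature_cols},
                disrupts_one_structure=str(row["disrupts_one_structure"]).strip().lower()
                in ("yes", "true", "1"),
                threshold=float(row["threshold"]),
            )
        )
    return records


def write_mutant_table(records: Sequence[MutantRecord], path: str | Path) -> None:
    features = list(records[0].feature_deltas)
    rows = []
    for r in records:
        row = {
            "wild_type_id": r.wild_type_id,
            "mutant_id": r.mutant_id,
            "disrupts_one_structure": "yes" if r.disrupts_one_structure else "no",
            "threshold": r.threshold,
        }
        row.update({f"d{f}": r.feature_deltas[f] for f in features})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def bundled_mutant_records() -> list[MutantRecord]:
    """The curated mutant Δ% table shipped with the package.

    18 published mutants of six riboswitches (TPP, FMN, SAM-I, two
    magnesium riboswitches, and the ROSE-P2 thermosensor) with their
    reported percentage changes in RND, BJK, BJKbp, and Sil.  The ROSE-P2
    deletion mutant is one nucleotide shorter than wild type and carries
    the −0.74 length-adjusted threshold.
    """
    return read_mutant_table(Path(__file__).parent / "data" / "mutant_deltas.tsv")
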