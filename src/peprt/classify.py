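"""Four-group confidence classification of MS/MS peptide identifications.

A peptide-spectrum match carries two largely independent lines of evidence:
the Sequest cross-correlation score (Xcorr, spectral evidence) and the
difference between its experimental and QSRR-predicted retention times
(chromatographic evidence).  Crossing a charge-dependent Xcorr acceptance
rule (the Washburn criteria: Xcorr > 1.9 for 1+, > 2.2 for 2+, >= 3.75 for
3+, with deltaCn > 0.08 when available) with a |delta tR| < 5 min rule
partitions the matches into four groups:

===============================  ===========  ==============
group                            Xcorr rule   |delta tR| rule
===============================  ===========  ==============
CORRECT                          pass         pass
INCORRECT                        fail         fail
POTENTIAL_FALSE_POSITIVE         pass         fail
POTENTIAL_FALSE_NEGATIVE         fail         pass
===============================  ===========  ==============

Records in the two mixed groups deserve re-examination: a confident
spectrum eluting far from its predicted time may be a spurious match, and
a weak spectrum eluting exactly where predicted may be a genuine peptide
lost to the score threshold.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import pandas as pd

from .descriptors import DescriptorPair
from .model import Prediction
from .peptides import Peptide

__all__ = [
    "ConfidenceGroup",
    "ClassificationThresholds",
    "IdentificationRecord",
    "xcorr_pass",
    "classify_record",
    "classify_table",
    "strain_report",
]

GROUP_COLUMN = "group"


class ConfidenceGroup(str, enum.Enum):
    CORRECT = "CORRECT"
    INCORRECT = "INCORRECT"
    POTENTIAL_FALSE_POSITIVE = "POTENTIAL_FALSE_POSITIVE"
    POTENTIAL_FALSE_NEGATIVE = "POTENTIAL_FALSE_NEGATIVE"

    def __str__(self) -> str:  # serialize as the bare name
        return self.value


@dataclass(frozen=True)
class ClassificationThresholds:
    """Score and retention-time acceptance thresholds.

    Xcorr boundaries are strict (>) for charges 1 and 2 and inclusive (>=)
    for charge 3; deltaCn is strict (>); the retention rule accepts
    |delta tR| strictly below ``delta_tr_max``.
    """

    xcorr_min_by_charge: dict[int, float] = field(
        default_factory=lambda: {1: 1.9, 2: 2.2, 3: 3.75}
    )
    delta_cn_min: float = 0.08
    delta_tr_max: float = 5.0  # min

    def __post_init__(self) -> None:
        if set(self.xcorr_min_by_charge) != {1, 2, 3}:
            raise ValueError("thresholds required for charges 1, 2 and 3")
        if any(v <= 0 for v in self.xcorr_min_by_charge.values()):
            raise ValueError("Xcorr thresholds must be positive")
        if self.delta_cn_min <= 0 or self.delta_tr_max <= 0:
            raise ValueError("thresholds must be positive")


@dataclass(frozen=True)
class IdentificationRecord:
    """One peptide-spectrum match with its scores and retention evidence."""

    protein_label: str
    peptide: Peptide
    mz: float
    charge: int
    xcorr: float
    missed_cleavages: int
    descriptors: DescriptorPair
    t_r_exp: float
    prediction: Prediction
    delta_cn: float | None = None

    def __post_init__(self) -> None:
        if self.xcorr < 0:
            raise ValueError("Xcorr must be non-negative")


def xcorr_pass(
    charge: int,
    xcorr: float,
    delta_cn: float | None = None,
    th: ClassificationThresholds | None = None,
) -> bool:
    """Charge-dependent Xcorr (and optional deltaCn) acceptance."""
    th = th or ClassificationThresholds()
    if charge not in th.xcorr_min_by_charge:
        raise ValueError(
            f"no Xcorr threshold for charge {charge}; supported charges: "
            f"{sorted(th.xcorr_min_by_charge)}"
        )
    limit = th.xcorr_min_by_charge[charge]
    # inclusive boundary only for the triply-charged threshold
    score_ok = xcorr >= limit if charge == 3 else xcorr > limit
    cn_ok = delta_cn is None or delta_cn > th.delta_cn_min
    return score_ok and cn_ok


def classify_record(
    r: IdentificationRecord, th: ClassificationThresholds | None = None
) -> ConfidenceGroup:
    """Assign one record to its confidence group (see module docstring)."""
    th = th or ClassificationThresholds()
    if r.prediction.abs_delta_t_r is None or not math.isfinite(
        r.prediction.abs_delta_t_r
    ):
        raise ValueError(f"record {r.peptide}: missing delta tR")
    score_ok = xcorr_pass(r.charge, r.xcorr, r.delta_cn, th)
    rt_ok = r.prediction.abs_delta_t_r < th.delta_tr_max
    if score_ok:
        return (
            ConfidenceGroup.CORRECT
            if rt_ok
            else ConfidenceGroup.POTENTIAL_FALSE_POSITIVE
        )
    return (
        ConfidenceGroup.POTENTIAL_FALSE_NEGATIVE
        if rt_ok
        else ConfidenceGroup.INCORRECT
    )


def classify_table(
    table: pd.DataFrame, th: ClassificationThresholds | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify every row of a peptide table.

    ``table`` needs columns ``charge``, ``xcorr``, ``t_r_exp`` and
    ``t_r_pred`` (``delta_cn`` is honoured when present).  Returns the
    table with ``group`` and ``abs_delta_t_r`` columns appended (input row
    order preserved) and a per-group summary frame with count, min and max
    |delta tR|; groups absent from the data get count 0.
    """
    th = th or ClassificationThresholds()
    out = table.copy()
    groups: list[str] = []
    abs_dtr: list[float] = []
    for idx, row in out.iterrows():
        try:
            signed = float(row["t_r_exp"]) - float(row["t_r_pred"])
            mag = abs(signed)
            cn = row.get("delta_cn")
            cn = None if cn is None or pd.isna(cn) else float(cn)
            ok = xcorr_pass(int(row["charge"]), float(row["xcorr"]), cn, th)
        except (ValueError, KeyError) as exc:
            raise ValueError(f"row {idx}: {exc}") from exc
        if ok:
            g = (
                ConfidenceGroup.CORRECT
                if mag < th.delta_tr_max
                else ConfidenceGroup.POTENTIAL_FALSE_POSITIVE
            )
        else:
            g = (
                ConfidenceGroup.POTENTIAL_FALSE_NEGATIVE
                if mag < th.delta_tr_max
                else ConfidenceGroup.INCORRECT
            )
        groups.append(g.value)
        abs_dtr.append(mag)
    out[GROUP_COLUMN] = groups
    out["abs_delta_t_r"] = abs_dtr
    summaries = []
    for g in ConfidenceGroup:
        sub = out[out[GROUP_COLUMN] == g.value]
        summaries.append(
            {
                "group": g.value,
                "count": len(sub),
                "min_abs_delta_t_r": sub["abs_delta_t_r"].min() if len(sub) else None,
                "max_abs_delta_t_r": sub["abs_delta_t_r"].max() if len(sub) else None,
            }
        )
    return out, pd.DataFrame(summaries)


def strain_report(classified_by_sample: dict[str, pd.DataFrame]) -> str:
    """Comparative per-sample report of group membership and counts.

    ``classified_by_sample`` maps a sample label (e.g. a strain name) to a
    table already carrying the ``group`` column.  The report lists, per
    sample and group, the member peptides with their protein labels and
    |delta tR|; it states counts only and draws no biological inference.
    """
    if not classified_by_sample:
        raise ValueError("at least one sample required")
    lines: list[str] = []
    for sample, table in classified_by_sample.items():
        lines.append(f"=== Sample: {sample} ({len(table)} identifications) ===")
        for g in ConfidenceGroup:
            sub = table[table[GROUP_COLUMN] == g.value]
            lines.append(f"[{g.value}] n={len(sub)}")
            for _, row in sub.iterrows():
                dtr = abs(float(row["t_r_exp"]) - float(row["t_r_pred"]))
                lines.append(
                    f"  {row['protein_label']}\t{row['peptide_sequence']}\t"
                    f"charge {int(row['charge'])}\tXcorr {float(row['xcorr']):.2f}\t"
                    f"|dtR| {dtr:.2f}"
                )
        lines.append("")
    return "\n".join(lines)
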