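"""Reading, writing and bundled examples of the canonical peptide table.

A peptide table is a pandas DataFrame, one row per peptide-spectrum match,
with a fixed, case-sensitive column vocabulary::

    protein_label, peptide_sequence, mz, charge, xcorr, missed_cleavages,
    clogp, log_sum_k1, t_r_exp, t_r_pred, delta_t_r, group

Optional columns may be absent depending on the processing stage (a raw
table has no descriptors; only a classified table has ``group``).  Units:
minutes for all retention columns, thomson for ``mz``.  Unknown extra
columns are preserved verbatim.

Three datasets are bundled:

* ``calibration_model_proteins`` — 50 tryptic peptides of eight standard
  proteins (BSA, HSA, ovalbumin, beta-lactoglobulin, beta-casein,
  myoglobin, IGFBP-1, ribonuclease B) with descriptors and experimental
  gradient retention times; the QSRR calibration set.
* ``sasp_dprpe`` — 26 SASP (small acid-soluble spore protein)
  identifications from *Bacillus subtilis* ΔprpE spores.
* ``sasp_168`` — 8 SASP identifications from the standard 168 strain.

The SASP tables carry a ``printed_group`` column recording the confidence
block each row was originally listed under.  All values are transcribed
verbatim from the source tables, including their internal inconsistencies;
``load_anomalies`` returns the sidecar documenting those, and nothing in
the package silently corrects them.
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "COLUMNS",
    "MANDATORY_COLUMNS",
    "read_table",
    "write_table",
    "load_fixture",
    "load_anomalies",
    "calibration_model",
    "FIXTURES",
]

logger = logging.getLogger(__name__)

#: Canonical column order.
COLUMNS = (
    "protein_label",
    "peptide_sequence",
    "mz",
    "charge",
    "xcorr",
    "missed_cleavages",
    "clogp",
    "log_sum_k1",
    "t_r_exp",
    "t_r_pred",
    "delta_t_r",
    "group",
)

#: Columns every peptide table must carry.
MANDATORY_COLUMNS = ("protein_label", "peptide_sequence")

_INT_COLUMNS = {"charge", "missed_cleavages"}
# decimals written per column
_PRECISION = {
    "mz": 4,
    "xcorr": 2,
    "clogp": 4,
    "log_sum_k1": 4,
    "t_r_exp": 2,
    "t_r_pred": 2,
    "delta_t_r": 2,
    "abs_delta_t_r": 2,
}

FIXTURES = ("calibration_model_proteins", "sasp_dprpe", "sasp_168")

_DIALECTS = {"csv": ",", "tsv": "\t"}


def _sep(dialect: str) -> str:
    try:
        return _DIALECTS[dialect]
    except KeyError:
        raise ValueError(f"unknown dialect {dialect!r}; use 'csv' or 'tsv'") from None


def stage_of(table: pd.DataFrame) -> str:
    """Processing stage implied by the columns present."""
    cols = set(table.columns)
    if "group" in cols:
        return "classified"
    if "t_r_pred" in cols:
        return "predicted"
    if "log_sum_k1" in cols:
        return "descriptors"
    return "raw"


def read_table(path: str | Path, dialect: str = "csv") -> pd.DataFrame:
    """Read a peptide table; numbers use the period decimal separator.

    Raises on a missing mandatory column and on unparseable numeric cells
    (with row/column context); extra columns are kept verbatim.
    """
    df = pd.read_csv(path, sep=_sep(dialect), dtype=str, keep_default_na=False)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {missing}")
    for col in df.columns:
        if col in _INT_COLUMNS or col in _PRECISION:
            parsed = []
            for i, cell in enumerate(df[col]):
                cell = cell.strip()
                try:
                    if cell == "":
                        parsed.append(None)
                    elif col in _INT_COLUMNS:
                        parsed.append(int(cell))
                    else:
                        parsed.append(float(cell))
                except ValueError:
                    raise ValueError(
                        f"{path}: unparseable value {cell!r} "
                        f"(row {i + 2}, column {col!r})"
                    ) from None
            df[col] = pd.array(
                parsed, dtype="Int64" if col in _INT_COLUMNS else "Float64"
            )
    logger.info("read %d record(s) from %s (stage: %s)", len(df), path, stage_of(df))
    return df


def write_table(table: pd.DataFrame, path: str | Path, dialect: str = "csv") -> None:
    """Write a peptide table at the canonical per-column precision.

    Retention columns are written with 2 decimals, descriptors and m/z
    with 4; a written table round-trips through :func:`read_table` to the
    written precision.
    """
    out = table.copy()
    ordered = [c for c in COLUMNS if c in out.columns] + [
        c for c in out.columns if c not in COLUMNS
    ]
    out = out[ordered]
    for col, nd in _PRECISION.items():
        if col in out.columns:
            out[col] = out[col].map(
                lambda v: "" if pd.isna(v) else f"{float(v):.{nd}f}"
            )
    out.to_csv(path, sep=_sep(dialect), index=False)
    logger.info("wrote %d record(s) to %s", len(table), path)


def fixture_path(name: str) -> Path:
    if name not in FIXTURES:
        raise ValueError(f"unknown fixture {name!r}; available: {FIXTURES}")
    with resources.as_file(resources.files("peprt.data") / f"{name}.csv") as p:
        return p


def load_fixture(name: str) -> pd.DataFrame:
    """Load one of the bundled datasets (see module docstring for names)."""
    return read_table(fixture_path(name))


def load_anomalies() -> pd.DataFrame:
    """The sidecar annotation of known inconsistencies in the bundled data."""
    with resources.as_file(resources.files("peprt.data") / "anomalies.csv") as p:
        return pd.read_csv(p)


def calibration_model():
    """The canonical QSRR model: an OLS refit on the bundled calibration set.

    Returns ``(QsrrModel, FitStatistics)`` fitted on the 50 calibration
    peptides using their printed descriptors and experimental retention
    times.  This refit — not :data:`peprt.model.REFERENCE_MODEL` — is what
    reproduces the reported calibration statistics.
    """
    from .descriptors import DescriptorPair
    from .model import fit_mlr

    cal = load_fixture("calibration_model_proteins")
    rows = [
        (DescriptorPair(float(r.log_sum_k1), float(r.clogp)), float(r.t_r_exp))
        for r in cal.itertuples()
    ]
    return fit_mlr(rows)
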