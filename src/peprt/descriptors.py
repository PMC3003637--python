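"""QSRR structural descriptors for gradient RP-LC peptide retention.

Two descriptors drive the retention model:

* ``log Sum(k+1)_AA`` — the base-10 logarithm of the sum, over a peptide's
  residues, of (retention factor + 1).  Retention factors ``k`` are
  dimensionless measures of how strongly a free amino acid is retained on a
  C18 column; only the seven hydrophobic residues I, L, M, F, W, Y, V carry
  non-zero values, every other residue is ascribed k = 0, and the "+1" keeps
  the logarithm finite for peptides made only of weakly retained residues.
* ``clogP`` — the calculated octanol/water partition coefficient of the
  whole peptide.  It is always a supplied input column, never computed here.

The per-residue ``k`` values are not tabulated in the bundled calibration
data, but they are exactly recoverable from the printed descriptor column:
``10**log_sum - length`` is a linear function of the residue counts, so a
non-negative least-squares solve over the retained residues reconstructs
them (:func:`solve_retention_factors`).  The shipped default table is that
reconstruction and is user-overridable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import nnls

from .peptides import AMINO_ACIDS, Peptide

__all__ = [
    "RETAINED_RESIDUES",
    "RetentionFactorTable",
    "DescriptorPair",
    "SolveResult",
    "sum_k_plus_1",
    "log_sum_descriptor",
    "solve_retention_factors",
    "attach_clogp",
]

logger = logging.getLogger(__name__)

#: The seven most-retained residues carrying non-zero retention factors.
RETAINED_RESIDUES = ("I", "L", "M", "F", "W", "Y", "V")


@dataclass(frozen=True)
class RetentionFactorTable:
    """Per-residue retention factors; k = 0 outside the retained set."""

    k: dict[str, float]

    def __post_init__(self) -> None:
        table = {a: 0.0 for a in AMINO_ACIDS}
        for res, val in self.k.items():
            if res not in AMINO_ACIDS:
                raise ValueError(f"unknown residue {res!r} in retention table")
            if val < 0:
                raise ValueError(f"retention factor for {res} is negative")
            table[res] = float(val)
        object.__setattr__(self, "k", table)

    @property
    def retained_set(self) -> frozenset[str]:
        return frozenset(a for a, v in self.k.items() if v > 0)

    @classmethod
    def from_file(cls, path: str | Path) -> "RetentionFactorTable":
        """Read a two-column (residue, k) delimited text file."""
        k: dict[str, float] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            res, val = line.replace(",", "\t").split()
            k[res.upper()] = float(val)
        return cls(k=k)

    def to_file(self, path: str | Path) -> None:
        lines = ["# residue\tk"]
        for res in sorted(self.k):
            if self.k[res] > 0:
                lines.append(f"{res}\t{self.k[res]:.6f}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def default(cls) -> "RetentionFactorTable":
        """The shipped table, reconstructed from the bundled calibration data.

        These values are a least-squares reconstruction from printed
        descriptors (see :func:`solve_retention_factors`), not an
        independently measured set; override with :meth:`from_file` to use
        your own retention data.
        """
        with resources.as_file(
            resources.files("peprt.data") / "retention_factors.tsv"
        ) as path:
            return cls.from_file(path)


@dataclass(frozen=True)
class DescriptorPair:
    """The two QSRR descriptors of one peptide."""

    log_sum_k1: float
    clogp: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.log_sum_k1) and math.isfinite(self.clogp)):
            raise ValueError("descriptors must be finite")


def sum_k_plus_1(p: Peptide, kt: RetentionFactorTable | None = None) -> float:
    """Sum over residues of (k + 1); equals length + total retained k."""
    kt = kt or RetentionFactorTable.default()
    return sum(kt.k[a] + 1.0 for a in p)


def log_sum_descriptor(p: Peptide, kt: RetentionFactorTable | None = None) -> float:
    """log10 of :func:`sum_k_plus_1`; >= log10(length), so always finite."""
    return math.log10(sum_k_plus_1(p, kt))


@dataclass(frozen=True)
class SolveResult:
    """Outcome of a retention-factor reconstruction."""

    table: RetentionFactorTable
    residuals: tuple[float, ...]  # reconstructed - printed, per input row
    excluded: tuple[int, ...]  # indices of rows dropped as outliers


def solve_retention_factors(
    rows: Sequence[tuple[Peptide, float]],
    retained: Sequence[str] = RETAINED_RESIDUES,
    outlier_tol: float | None = None,
) -> SolveResult:
    """Recover retention factors from (peptide, printed log_sum_k1) rows.

    Solves ``min ||counts @ k - (10**printed - length)||`` with k >= 0 over
    the retained residues.  If ``outlier_tol`` is given, rows whose
    reconstructed descriptor differs from the printed one by more than the
    tolerance are iteratively excluded from the solve (and reported in the
    result); residuals are still returned for every input row.
    """
    if len(rows) < len(retained):
        raise ValueError(
            f"need at least {len(retained)} rows to identify "
            f"{len(retained)} retention factors, got {len(rows)}"
        )
    counts = np.array(
        [[p.sequence.count(a) for a in retained] for p, _ in rows], dtype=float
    )
    lengths = np.array([p.length for p, _ in rows], dtype=float)
    printed = np.array([v for _, v in rows], dtype=float)
    rank = np.linalg.matrix_rank(counts)
    if rank < len(retained):
        zero = [a for j, a in enumerate(retained) if not counts[:, j].any()]
        raise ValueError(
            "retention-factor design matrix is rank deficient"
            + (f"; residues never observed: {zero}" if zero else "")
        )
    target = 10.0**printed - lengths

    keep = np.ones(len(rows), dtype=bool)
    while True:
        k, _ = nnls(counts[keep], target[keep])
        recon = np.log10(lengths + counts @ k)
        resid = recon - printed
        if outlier_tol is None:
            break
        keep_new = np.abs(resid) <= outlier_tol
        if keep_new.sum() < len(retained) or (keep_new == keep).all():
            break
        keep = keep_new
    excluded = tuple(int(i) for i in np.flatnonzero(~keep))
    for i in excluded:
        logger.warning(
            "retention-factor solve excluded row %d (%s, printed %.4f, "
            "reconstructed %.4f)",
            i,
            rows[i][0],
            printed[i],
            recon[i],
        )
    table = RetentionFactorTable(k=dict(zip(retained, map(float, k))))
    return SolveResult(
        table=table, residuals=tuple(map(float, resid)), excluded=excluded
    )


def attach_clogp(records, clogp_column) -> tuple[list, list[int]]:
    """Pair computed log-sum descriptors with supplied clogP values.

    ``records`` is a sequence of (peptide, log_sum_k1); ``clogp_column``
    supplies one clogP per record (None/NaN marks a missing value).  Returns
    completed :class:`DescriptorPair` objects (None where clogP is missing)
    plus the indices of flagged records, which callers must exclude from
    modelling.  clogP is stored verbatim — it is an externally calculated
    input, never computed here.
    """
    records = list(records)
    clogp_column = list(clogp_column)
    if len(records) != len(clogp_column):
        raise ValueError("one clogP value required per record")
    out: list[DescriptorPair | None] = []
    flagged: list[int] = []
    for i, ((_, log_sum), clogp) in enumerate(zip(records, clogp_column)):
        if clogp is None or (isinstance(clogp, float) and math.isnan(clogp)):
            flagged.append(i)
            out.append(None)
        else:
            out.append(DescriptorPair(log_sum_k1=log_sum, clogp=float(clogp)))
    if flagged:
        logger.warning(
            "%d record(s) missing clogP excluded from modelling: rows %s",
            len(flagged),
            flagged,
        )
    return out, flagged
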