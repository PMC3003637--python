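"""Synthetic peptide tables with known ground truth.

The generator emulates the structure of a shotgun LC-MS/MS identification
table: random tryptic-like peptides, descriptors computed from a known
retention-factor table, experimental retention times equal to a known QSRR
model's prediction plus Gaussian noise, and Xcorr scores drawn from
separate distributions for genuinely present ("true") and spurious
("false") matches.  Because every quantity is generated from a known
model, the tables support parameter-recovery tests: refitting must
recover the generating coefficients, and the retention-factor solver must
recover the generating k table.

Defaults mirror the bundled calibration conditions: 50 peptides and a
residual scale of 1.45 min around a model fitted to that calibration set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .descriptors import RETAINED_RESIDUES, RetentionFactorTable, log_sum_descriptor
from .model import QsrrModel
from .peptides import AMINO_ACIDS, Peptide, count_missed_cleavages, mz

__all__ = ["SyntheticConfig", "generate_synthetic"]

_NON_RETAINED = sorted(AMINO_ACIDS - set(RETAINED_RESIDUES))


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the synthetic table generator; the seed fixes everything."""

    n_peptides: int = 50
    length_range: tuple[int, int] = (5, 30)
    retained_frequency: float = 0.35  # ~hydrophobic residue share in proteomes
    k_table: RetentionFactorTable | None = None  # None -> shipped defaults
    model: QsrrModel | None = None  # None -> refit of bundled calibration
    sigma: float = 1.45  # residual SD of t_r_exp around the model, min
    true_fraction: float = 1.0  # fraction of genuinely present matches
    xcorr_true: tuple[float, float] = (3.5, 0.8)  # normal mean/SD, clipped >= 0
    xcorr_false: tuple[float, float] = (1.0, 0.4)
    clogp_loc: float = -4.0
    clogp_scale: float = 2.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not 0 <= self.true_fraction <= 1:
            raise ValueError("true_fraction must be in [0, 1]")
        if not 0 <= self.retained_frequency <= 1:
            raise ValueError("retained_frequency must be in [0, 1]")


def _random_peptide(rng: np.random.Generator, cfg: SyntheticConfig) -> Peptide:
    length = int(rng.integers(cfg.length_range[0], cfg.length_range[1] + 1))
    retained = rng.random(length) < cfg.retained_frequency
    chars = [
        (
            RETAINED_RESIDUES[rng.integers(len(RETAINED_RESIDUES))]
            if r
            else _NON_RETAINED[rng.integers(len(_NON_RETAINED))]
        )
        for r in retained
    ]
    return Peptide("".join(chars))


def generate_synthetic(cfg: SyntheticConfig) -> tuple[pd.DataFrame, dict]:
    """Generate a peptide table plus its ground truth.

    Returns ``(table, truth)`` where ``table`` carries the canonical raw +
    descriptor + retention columns and ``truth`` holds the generating
    ``k_table``, ``model``, per-row ``is_true`` labels and the noiseless
    retention times.  Identical configs (same seed) give identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    k_table = cfg.k_table or RetentionFactorTable.default()
    model = cfg.model
    if model is None:
        from .tables import calibration_model

        model, _ = calibration_model()

    peptides = [_random_peptide(rng, cfg) for _ in range(cfg.n_peptides)]
    charges = rng.choice([1, 2, 3], size=cfg.n_peptides, p=[0.2, 0.6, 0.2])
    log_sum = np.array([log_sum_descriptor(p, k_table) for p in peptides])
    clogp = rng.normal(cfg.clogp_loc, cfg.clogp_scale, cfg.n_peptides)
    t_true = model.k1 + model.k2 * log_sum + model.k3 * clogp
    is_true = rng.random(cfg.n_peptides) < cfg.true_fraction
    noise = rng.normal(0.0, cfg.sigma, cfg.n_peptides) if cfg.sigma else 0.0
    # genuine matches elute near prediction; spurious ones anywhere in the run
    t_exp = np.where(is_true, t_true + noise, rng.uniform(0.0, 90.0, cfg.n_peptides))
    xcorr = np.where(
        is_true,
        rng.normal(*cfg.xcorr_true, cfg.n_peptides),
        rng.normal(*cfg.xcorr_false, cfg.n_peptides),
    ).clip(min=0.0)

    table = pd.DataFrame(
        {
            "protein_label": [
                f"synthetic_{'true' if t else 'false'}" for t in is_true
            ],
            "peptide_sequence": [p.sequence for p in peptides],
            "mz": [mz(p, int(z)) for p, z in zip(peptides, charges)],
            "charge": charges.astype(int),
            "xcorr": xcorr,
            "missed_cleavages": [count_missed_cleavages(p) for p in peptides],
            "clogp": clogp,
            "log_sum_k1": log_sum,
            "t_r_exp": t_exp,
        }
    )
    truth = {
        "k_table": k_table,
        "model": model,
        "is_true": is_true,
        "t_r_noiseless": t_true,
        "t_r_exp_exact": t_exp,
        "log_sum_exact": log_sum,
        "clogp_exact": clogp,
    }
    return table, truth
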