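"""qPCR copy-number formulas, estimated absolute abundance, and alpha diversity.

Total microbial loads are quantified by qPCR against a plasmid standard.  The
standard's copy number per ng of DNA is ``(N_L * A * 1e-9) / (660 * n)`` with
Avogadro's number ``N_L``, molecular weight ``A`` (g/mol) and amplicon length
``n`` (bp; 660 g/mol per bp of double-stranded DNA).  Per-sample total copies
per mL of rumen fluid are ``(M_Q * C * V_D) / (S * V)`` from the quantified
mean copy number ``M_Q``, DNA concentration ``C`` (ng/ul), eluted DNA volume
``V_D`` (ul), DNA input ``S`` (ng) and fluid volume ``V`` (mL).  Estimated
absolute abundance (EAA) of a taxon is its relative abundance times the
sample's total copies, so EAA row sums conserve the totals.

Shannon diversity uses log base 2 by default (configurable); Chao1 uses the
classic estimator S_obs + F1^2/(2*F2), switching to the bias-corrected form
S_obs + F1*(F1-1)/(2*(F2+1)) when no doubletons are observed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, UndefinedStatisticError

__all__ = [
    "AVOGADRO",
    "QpcrStandard",
    "QpcrSampleRecord",
    "standard_copy_number",
    "copies_per_ml",
    "estimated_absolute_abundance",
    "eaa_table",
    "shannon",
    "chao1",
    "subsample_counts",
]

AVOGADRO = 6.02e23  # molecules per mol


@dataclass(frozen=True)
class QpcrStandard:
    """Plasmid standard: molecular weight (g/mol) and amplicon length (bp)."""

    molecular_weight: float
    amplicon_length: float
    avogadro: float = AVOGADRO

    def __post_init__(self):
        if min(self.molecular_weight, self.amplicon_length, self.avogadro) <= 0:
            raise InvalidParameterError("qPCR standard parameters must be positive")


@dataclass(frozen=True)
class QpcrSampleRecord:
    """One sample's qPCR bookkeeping (units in the field names)."""

    mean_copies: float  # M_Q, quantified mean copy number
    dna_conc_ng_ul: float  # C
    eluted_volume_ul: float  # V_D
    dna_input_ng: float  # S
    fluid_volume_ml: float  # V

    def __post_init__(self):
        vals = (
            self.mean_copies,
            self.dna_conc_ng_ul,
            self.eluted_volume_ul,
            self.dna_input_ng,
            self.fluid_volume_ml,
        )
        if min(vals) <= 0:
            raise InvalidParameterError("qPCR sample record entries must be positive")


def standard_copy_number(std: QpcrStandard) -> float:
    """Copies per ng of standard DNA: (N_L * A * 1e-9) / (660 * n)."""
    return std.avogadro * std.molecular_weight * 1e-9 / (660.0 * std.amplicon_length)


def copies_per_ml(rec: QpcrSampleRecord) -> float:
    """Total marker-gene copies per mL rumen fluid: (M_Q * C * V_D) / (S * V)."""
    return (
        rec.mean_copies
        * rec.dna_conc_ng_ul
        * rec.eluted_volume_ul
        / (rec.dna_input_ng * rec.fluid_volume_ml)
    )


def estimated_absolute_abundance(rel_abundance: float, total_copies: float) -> float:
    """EAA of one taxon: relative abundance (fraction) times total copies/mL."""
    rel = np.asarray(rel_abundance, dtype=float)
    if np.any(rel < 0) or np.any(rel > 1):
        raise InvalidParameterError("relative abundance must lie in [0, 1]")
    return rel * total_copies


def eaa_table(fractions: pd.DataFrame, total_copies: pd.Series) -> pd.DataFrame:
    """Table-wide EAA: each sample row scaled by its total copies per mL.

    Row sums of the result equal the per-sample totals (conservation).
    """
    missing = fractions.index.difference(total_copies.index)
    if len(missing):
        raise InvalidParameterError(f"missing total copies for samples: {list(missing)[:5]}")
    vals = fractions.to_numpy(dtype=float)
    if np.any(vals < 0) or np.any(vals > 1 + 1e-9):
        raise InvalidParameterError("relative abundances must lie in [0, 1]")
    totals = total_copies.loc[fractions.index].to_numpy(dtype=float)
    return pd.DataFrame(
        vals * totals[:, None], index=fractions.index, columns=fractions.columns
    )


def shannon(x, base: float = 2.0) -> float:
    """Shannon diversity H = -sum p_i log_base p_i of counts or fractions."""
    p = np.asarray(x, dtype=float).ravel()
    if np.any(p < 0):
        raise InvalidParameterError("abundances must be nonnegative")
    total = p.sum()
    if total <= 0:
        raise UndefinedStatisticError("diversity undefined for an all-zero vector")
    p = p[p > 0] / total
    return float(-(p * (np.log(p) / np.log(base))).sum())


def chao1(counts) -> float:
    """Chao1 richness from integer counts.

    Classic form S_obs + F1^2/(2*F2); when F2 = 0 the bias-corrected form
    S_obs + F1*(F1-1)/(2*(F2+1)) is used.  Delegates to scikit-bio.
    """
    c = np.asarray(counts)
    if np.any(c < 0):
        raise InvalidParameterError("counts must be nonnegative")
    if not np.all(np.equal(np.mod(c, 1), 0)):
        raise InvalidParameterError("Chao1 requires integer counts")
    c = c.astype(int)
    if c.sum() == 0:
        raise UndefinedStatisticError("richness undefined for an all-zero vector")
    from skbio.diversity.alpha import chao1 as _skbio_chao1

    f2 = int(np.sum(c == 2))
    return float(_skbio_chao1(c, bias_corrected=(f2 == 0)))


def subsample_counts(counts, depth: int, rng: np.random.Generator) -> np.ndarray:
    """Rarefy a count vector to ``depth`` reads without replacement.

    Provided for parity with rarefied-depth diversity workflows; diversity
    functions themselves operate on whatever counts they are given.
    """
    c = np.asarray(counts, dtype=int)
    total = int(c.sum())
    if depth > total:
        raise InvalidParameterError(f"depth {depth} exceeds total count {total}")
    expanded = np.repeat(np.arange(c.size), c)
    picked = rng.choice(expanded, size=depth, replace=False)
    return np.bincount(picked, minlength=c.size)
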