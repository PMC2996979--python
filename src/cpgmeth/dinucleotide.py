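"""Per-sequence dinucleotide observed/expected ratios.

The central statistic is the CpG observed/expected ratio

    CpGo/e = n_CpG / (n_C × n_G) × l² / (l − 1)

where *l* is the number of unambiguous nucleotides in the sequence.
Because methylated cytosines deaminate to thymine over evolutionary
time, persistently methylated sequence is depleted of CpG: a low CpGo/e
predicts hyper-methylation, a value near 1 predicts hypo-methylation.
GpCo/e (no depletion mechanism; composition control, expected ≈ 1) and
TpGo/e (the decay product; anticorrelated with CpGo/e) are computed by
the same formula with the corresponding counts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .seq_io import UNAMBIGUOUS, SequenceRecord

logger = logging.getLogger(__name__)


class InsufficientDataError(ValueError):
    """Too few usable observations for the requested statistic."""


@dataclass(frozen=True)
class DinucleotideProfile:
    """Base/dinucleotide counts and o/e ratios for one sequence.

    ``l`` counts only unambiguous A/C/G/T bases; dinucleotide windows
    containing an ambiguous base contribute to no count. Ratios are
    ``None`` (never zero) when their denominator vanishes or ``l < 2``.
    """

    sequence_id: str
    l: int
    n_C: int
    n_G: int
    n_T: int
    n_CpG: int
    n_GpC: int
    n_TpG: int
    cpg_oe: float | None
    gpc_oe: float | None
    tpg_oe: float | None


def _oe_ratio(n_xy: int, n_x: int, n_y: int, l: int) -> float | None:
    if l < 2 or n_x == 0 or n_y == 0:
        return None
    return n_xy / (n_x * n_y) * l * l / (l - 1)


def profile_sequence(record: SequenceRecord) -> DinucleotideProfile:
    """Count bases and overlapping dinucleotides, then form o/e ratios.

    Scanning is left to right over adjacent positions; a window with an
    ambiguous base (N or any non-ACGT IUPAC code) is skipped, and
    ambiguous bases are excluded from ``l`` and the base counts.
    Degenerate inputs yield undefined ratios, never exceptions.
    """
    seq = record.sequence
    n_c = n_g = n_t = l = 0
    n_cpg = n_gpc = n_tpg = 0
    prev = ""
    for base in seq:
        if base in UNAMBIGUOUS:
            l += 1
            if base == "C":
                n_c += 1
            elif base == "G":
                n_g += 1
            elif base == "T":
                n_t += 1
            if prev:
                pair = prev + base
                if pair == "CG":
                    n_cpg += 1
                elif pair == "GC":
                    n_gpc += 1
                elif pair == "TG":
                    n_tpg += 1
            prev = base
        else:
            prev = ""  # window spanning an ambiguous base counts nothing
    return DinucleotideProfile(
        sequence_id=record.id,
        l=l, n_C=n_c, n_G=n_g, n_T=n_t,
        n_CpG=n_cpg, n_GpC=n_gpc, n_TpG=n_tpg,
        cpg_oe=_oe_ratio(n_cpg, n_c, n_g, l),
        gpc_oe=_oe_ratio(n_gpc, n_g, n_c, l),
        tpg_oe=_oe_ratio(n_tpg, n_t, n_g, l),
    )


def profile_collection(records: Sequence[SequenceRecord]) -> list[DinucleotideProfile]:
    """Profile every record, preserving order, and log the defined/undefined
    CpGo/e split."""
    if not records:
        raise InsufficientDataError("no records to profile")
    profiles = [profile_sequence(r) for r in records]
    n_def = sum(p.cpg_oe is not None for p in profiles)
    logger.info("profiled %d sequences: %d defined CpGo/e, %d undefined",
                len(profiles), n_def, len(profiles) - n_def)
    return profiles


def profiles_to_frame(profiles: Iterable[DinucleotideProfile]) -> pd.DataFrame:
    """Tabulate profiles (column order matches the TSV output contract)."""
    return pd.DataFrame(
        [
            {
                "sequence_id": p.sequence_id, "l": p.l,
                "n_C": p.n_C, "n_G": p.n_G, "n_T": p.n_T,
                "n_CpG": p.n_CpG, "n_GpC": p.n_GpC, "n_TpG": p.n_TpG,
                "cpg_oe": p.cpg_oe, "gpc_oe": p.gpc_oe, "tpg_oe": p.tpg_oe,
            }
            for p in profiles
        ]
    )


def defined_cpg_oe(profiles: Iterable[DinucleotideProfile]) -> np.ndarray:
    """CpGo/e values of profiles where the ratio is defined."""
    return np.array([p.cpg_oe for p in profiles if p.cpg_oe is not None])


def tpg_correlation(profiles: Sequence[DinucleotideProfile]) -> tuple[float, float, int]:
    """Pearson correlation between CpGo/e and TpGo/e across sequences.

    CpG→TpG deamination predicts a negative correlation. Returns
    ``(r, two-sided p, n_pairs)`` over sequences where both ratios are
    defined.

    Raises
    ------
    InsufficientDataError
        Fewer than 3 usable pairs, or no variation in either variable.
    """
    pairs = [(p.cpg_oe, p.tpg_oe) for p in profiles
             if p.cpg_oe is not None and p.tpg_oe is not None]
    if len(pairs) < 3:
        raise InsufficientDataError(
            f"need >= 3 sequences with defined CpGo/e and TpGo/e, got {len(pairs)}"
        )
    x, y = map(np.asarray, zip(*pairs))
    if math.isclose(float(np.var(x)), 0.0) or math.isclose(float(np.var(y)), 0.0):
        raise InsufficientDataError("no variation in CpGo/e or TpGo/e")
    res = stats.pearsonr(x, y)
    logger.info("CpGo/e vs TpGo/e: r=%.4f p=%.3g over %d pairs",
                res.statistic, res.pvalue, len(pairs))
    return float(res.statistic), float(res.pvalue), len(pairs)
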