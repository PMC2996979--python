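"""Bisulfite conversion simulation and per-CpG methylation calling.

Sodium bisulfite deaminates unmethylated cytosine to uracil (read as T
after PCR) while 5-methylcytosine resists. Comparing cloned converted
reads to the untreated reference therefore identifies methylated
cytosines: a reference CpG read as C is methylated, read as T is
unmethylated. Cytosines outside CpG context are essentially never
methylated in animals, so the fraction of non-CpG cytosines read as T
(the conversion rate) is a quality control expected near 100%.

Only the converted sense (top) strand is modelled; clones are aligned
to the reference with a deterministic global aligner (match +1,
mismatch −1, gap −2) before calling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio import Align

from .msp import MethylationStateMap

logger = logging.getLogger(__name__)

_CALL_METH = "methylated"
_CALL_UNMETH = "unmethylated"
_CALL_AMBIG = "ambiguous"


class AlignmentFailureError(ValueError):
    """Clone does not align to the reference (identity below the floor)."""


@dataclass(frozen=True)
class BisulfiteClone:
    """One sequenced clone of a bisulfite-PCR product (sense strand)."""

    clone_id: str
    sequence: str
    source_reference_id: str = ""

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if set(seq) - set("ACGT"):
            raise ValueError(f"clone {self.clone_id}: non-ACGT characters")
        object.__setattr__(self, "sequence", seq)


@dataclass
class CloneCalls:
    """Per-clone calling result against one reference."""

    clone_id: str
    cpg_calls: dict[int, str]      # reference CpG position -> call
    n_converted: int               # non-CpG Cs read as T
    n_failed: int                  # non-CpG Cs still read as C
    identity: float

    @property
    def conversion_rate(self) -> float | None:
        total = self.n_converted + self.n_failed
        return self.n_converted / total if total else None


@dataclass
class MethylationCallSet:
    """Aggregated per-site calls across clones for one reference.

    ``fractions`` maps each reference CpG position to
    methylated / (methylated + unmethylated); ambiguous calls are
    excluded from the denominator. ``conversion_rate`` pools non-CpG
    cytosine conversions across all clones.
    """

    reference_id: str
    cpg_positions: list[int]
    calls: dict[tuple[int, str], str]  # (cpg_position, clone_id) -> call
    clone_ids: list[int] | list[str] = field(default_factory=list)
    fractions: dict[int, float | None] = field(default_factory=dict)
    conversion_rate: float | None = None

    def lollipop_report(self) -> str:
        """Plain-text lollipop plot: one row per CpG site, one column per
        clone; ● methylated, ○ unmethylated, ? ambiguous."""
        marker = {_CALL_METH: "●", _CALL_UNMETH: "○",
                  _CALL_AMBIG: "?"}
        width = max((len(str(c)) for c in self.clone_ids), default=5)
        head = "site".ljust(8) + " ".join(str(c).rjust(width)
                                          for c in self.clone_ids) + "  fraction"
        lines = [head]
        for pos in self.cpg_positions:
            row = str(pos).ljust(8)
            row += " ".join(
                marker[self.calls[(pos, c)]].rjust(width) for c in self.clone_ids
            )
            frac = self.fractions.get(pos)
            row += "  " + ("NA" if frac is None else f"{frac:.2f}")
            lines.append(row)
        return "\n".join(lines)


def cpg_positions(reference: str) -> list[int]:
    """0-based positions of the C of every CG dinucleotide."""
    ref = reference.upper()
    return [i for i in range(len(ref) - 1) if ref[i:i + 2] == "CG"]


def convert_in_silico(reference: str, state_map: MethylationStateMap,
                      failure_rate: float = 0.0, seed: int = 0) -> str:
    """Apply bisulfite chemistry to a reference under a methylation map.

    Methylated Cs stay C; each unmethylated C independently converts to
    T with probability ``1 − failure_rate`` (remaining C on conversion
    failure). Other bases and sequence length are unchanged.
    """
    if not 0.0 <= failure_rate <= 1.0:
        raise ValueError("failure_rate must be in [0, 1]")
    ref = reference.upper()
    state_map.validate_against(ref, require_cpg=False)
    rng = np.random.default_rng(seed)
    out = list(ref)
    for i, base in enumerate(out):
        if base != "C" or i in state_map.methylated_positions:
            continue
        if rng.random() < 1.0 - failure_rate:
            out[i] = "T"
    return "".join(out)


def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = 1
    al.mismatch_score = -1
    al.open_gap_score = -2
    al.extend_gap_score = -2
    return al


def call_clone(reference: str, clone: BisulfiteClone,
               min_identity: float = 0.6) -> CloneCalls:
    """Call methylation at every reference cytosine from one clone.

    The clone is globally aligned to the reference; for each reference C
    aligned without a gap: in CpG context clone C → methylated, clone
    T → unmethylated; in non-CpG context clone T → converted, clone C →
    conversion failure; anything else (or a gap) is ambiguous.
    """
    ref = reference.upper()
    aln = _aligner().align(ref, clone.sequence)[0]
    ref_aln, clone_aln = str(aln[0]), str(aln[1])
    matches = sum(a == b for a, b in zip(ref_aln, clone_aln) if a != "-" and b != "-")
    identity = matches / len(ref_aln)
    if identity < min_identity:
        raise AlignmentFailureError(
            f"clone {clone.clone_id}: alignment identity {identity:.2f} below "
            f"{min_identity:.2f}; clone likely from a different locus"
        )

    cpg = set(cpg_positions(ref))
    aligned_base: dict[int, str] = {}
    ref_pos = 0
    for a, b in zip(ref_aln, clone_aln):
        if a != "-":
            aligned_base[ref_pos] = b  # '-' when clone has a gap here
            ref_pos += 1

    calls: dict[int, str] = {}
    n_conv = n_fail = 0
    for i, base in enumerate(ref):
        if base != "C":
            continue
        b = aligned_base.get(i, "-")
        if i in cpg:
            if b == "C":
                calls[i] = _CALL_METH
            elif b == "T":
                calls[i] = _CALL_UNMETH
            else:
                calls[i] = _CALL_AMBIG
        else:
            if b == "T":
                n_conv += 1
            elif b == "C":
                n_fail += 1
            # gaps/other bases are ambiguous: counted in neither tally
    return CloneCalls(clone_id=clone.clone_id, cpg_calls=calls,
                      n_converted=n_conv, n_failed=n_fail, identity=identity)


def summarize_calls(reference: str, clones: list[BisulfiteClone],
                    reference_id: str = "reference",
                    min_identity: float = 0.6) -> MethylationCallSet:
    """Aggregate clone calls into per-site fractions and a pooled
    conversion rate.

    Clones failing alignment are dropped with a warning; at least one
    clone must pass.
    """
    sites = cpg_positions(reference)
    per_clone: list[CloneCalls] = []
    for clone in clones:
        try:
            per_clone.append(call_clone(reference, clone, min_identity))
        except AlignmentFailureError as exc:
            logger.warning("%s", exc)
    if not per_clone:
        raise AlignmentFailureError("no clone passed alignment to the reference")

    calls = {
        (pos, cc.clone_id): cc.cpg_calls.get(pos, _CALL_AMBIG)
        for cc in per_clone for pos in sites
    }
    fractions: dict[int, float | None] = {}
    for pos in sites:
        n_m = sum(calls[(pos, cc.clone_id)] == _CALL_METH for cc in per_clone)
        n_u = sum(calls[(pos, cc.clone_id)] == _CALL_UNMETH for cc in per_clone)
        fractions[pos] = n_m / (n_m + n_u) if (n_m + n_u) else None
    total_conv = sum(cc.n_converted for cc in per_clone)
    total_fail = sum(cc.n_failed for cc in per_clone)
    conv_rate = (total_conv / (total_conv + total_fail)
                 if (total_conv + total_fail) else None)
    return MethylationCallSet(
        reference_id=reference_id, cpg_positions=sites, calls=calls,
        clone_ids=[cc.clone_id for cc in per_clone], fractions=fractions,
        conversion_rate=conv_rate,
    )
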