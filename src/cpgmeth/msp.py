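"""Methylation-sensitive PCR (MSP) simulation and interpretation.

HpaII and MspI are isoschizomers recognising CCGG. MspI cuts
regardless of CpG methylation; HpaII is blocked when the internal CpG
(the second C of CCGG) is methylated. Digesting genomic DNA with each
enzyme and then amplifying across the sites therefore reads out
methylation: a template cut inside the amplicon yields no product.

Pattern logic over (undigested, HpaII, MspI) presence calls:

=========  =========  ========  =============================================
undigested HpaII      MspI      call
=========  =========  ========  =============================================
+          +          −         methylated (all assayed sites)
+          −          −         unmethylated (at least one site unmethylated)
−          ·          ·         inconclusive (positive control failed)
+          +          +         inconclusive (no effective site / digestion
                                failure)
+          −          +         inconsistent (violates enzyme logic)
=========  =========  ========  =============================================

Coordinates are 0-based half-open throughout; CCGG is its own reverse
complement, so single-strand search loses nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum


class Enzyme(str, Enum):
    HPAII = "HpaII"
    MSPI = "MspI"


class MspCall(str, Enum):
    METHYLATED = "methylated"
    UNMETHYLATED = "unmethylated"
    INCONCLUSIVE = "inconclusive"
    INCONSISTENT = "inconsistent"


@dataclass
class MethylationStateMap:
    """Methylated cytosine positions (0-based, given strand) for one sequence."""

    sequence_id: str
    methylated_positions: set[int] = field(default_factory=set)

    def validate_against(self, sequence: str, require_cpg: bool = True) -> None:
        seq = sequence.upper()
        for pos in self.methylated_positions:
            if not (0 <= pos < len(seq)) or seq[pos] != "C":
                raise ValueError(
                    f"{self.sequence_id}: position {pos} is not a C"
                )
            if require_cpg and not (pos + 1 < len(seq) and seq[pos + 1] == "G"):
                raise ValueError(
                    f"{self.sequence_id}: position {pos} is not in CpG context"
                )


@dataclass(frozen=True)
class MspResult:
    """Presence/absence pattern and derived call for one gene/amplicon."""

    gene_id: str
    undigested_present: bool
    hpaii_present: bool
    mspi_present: bool
    n_sites: int
    call: MspCall


def find_ccgg_sites(sequence: str,
                    region: tuple[int, int] | None = None) -> list[int]:
    """All (possibly overlapping) CCGG start positions, ascending.

    ``region`` restricts the search to a half-open interval; a site must
    lie fully inside it.
    """
    seq = sequence.upper()
    start, end = (0, len(seq)) if region is None else region
    if not (0 <= start <= end <= len(seq)):
        raise ValueError(f"region {region} outside sequence of length {len(seq)}")
    sites = []
    i = seq.find("CCGG", start)
    while i != -1 and i + 4 <= end:
        sites.append(i)
        i = seq.find("CCGG", i + 1)
    return sites


def simulate_digest(sequence: str, state_map: MethylationStateMap,
                    enzyme: Enzyme | str,
                    amplicon: tuple[int, int] | None = None) -> bool:
    """Predict whether PCR across ``amplicon`` succeeds after digestion.

    A CCGG site cuts under MspI always; under HpaII only when the
    internal CpG (position site+1) is unmethylated. Amplification is
    predicted iff no site inside the amplicon is cut.
    """
    enzyme = Enzyme(enzyme)
    sites = find_ccgg_sites(sequence, amplicon)
    for s in sites:
        if enzyme is Enzyme.MSPI:
            return False  # cuts every site
        if (s + 1) not in state_map.methylated_positions:
            return False  # HpaII cuts unmethylated internal CpG
    return True


def interpret_pattern(undigested: bool, hpaii: bool, mspi: bool,
                      n_sites: int) -> MspCall:
    """Convert a presence/absence triple into a methylation call."""
    if not undigested or n_sites == 0:
        return MspCall.INCONCLUSIVE
    if hpaii and not mspi:
        return MspCall.METHYLATED
    if not hpaii and not mspi:
        return MspCall.UNMETHYLATED
    if hpaii and mspi:
        return MspCall.INCONCLUSIVE
    return MspCall.INCONSISTENT  # (+, −, +): MspI product without HpaII's


def run_assay(gene_id: str, sequence: str, state_map: MethylationStateMap,
              amplicon: tuple[int, int] | None = None) -> MspResult:
    """Full in-silico MSP for one gene: digest under both enzymes and call."""
    state_map.validate_against(sequence, require_cpg=False)
    n_sites = len(find_ccgg_sites(sequence, amplicon))
    undigested = True  # no enzyme, template intact
    hpaii = simulate_digest(sequence, state_map, Enzyme.HPAII, amplicon)
    mspi = simulate_digest(sequence, state_map, Enzyme.MSPI, amplicon)
    return MspResult(
        gene_id=gene_id, undigested_present=undigested, hpaii_present=hpaii,
        mspi_present=mspi, n_sites=n_sites,
        call=interpret_pattern(undigested, hpaii, mspi, n_sites),
    )
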