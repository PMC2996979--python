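"""Synthetic sequence populations with known methylation ground truth.

The generator realises the mechanism that makes CpGo/e informative:
methylated CpG dinucleotides deaminate to TpG over evolutionary time,
so a class of sequences with decay probability *d* loses a fraction *d*
of its CpGs to TpG. Sequences are built as iid bases at a configured
GC content, then every CpG is independently replaced by TpG with the
sequence's decay probability, drawn per sequence from its class's
normal (clamped to [0, 0.98]).

Because a conversion also removes one C from the o/e denominator, the
expected ratio under decay *d* is not simply 1 − d:

    E[CpGo/e] ≈ (1 − d) · l / (l − (l − 1)·p_G·d)

with p_G = gc_content / 2 (≈ (1 − d)/(1 − p_G·d) for long sequences);
:func:`expected_cpg_oe` is the analytic oracle and
:func:`decay_for_target_mean` inverts it. The same accounting makes the
GpCo/e control stay at 1: GpC occurrences destroyed by conversion are
exactly compensated by the lost Cs. Default class geometry targets the
fitted transcriptome components (CpGo/e means 0.40 and 0.70).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bisulfite import BisulfiteClone, convert_in_silico
from .msp import MethylationStateMap
from .seq_io import AnnotationTable, SequenceRecord


class ConfigValidationError(ValueError):
    """Invalid synthetic configuration; message lists offending fields."""


@dataclass(frozen=True)
class MixtureClass:
    """One methylation class: mixing weight and CpG decay distribution."""

    weight: float
    decay_mean: float
    decay_sd: float


@dataclass(frozen=True)
class GoCategory:
    """One synthetic GO-Slim category drawing members from one class."""

    slim_term: str
    class_index: int
    n_members: int


@dataclass
class SyntheticConfig:
    """Full parameterisation of the generators (seeded).

    Defaults emulate the study population: 12,210 annotated EST contigs
    whose CpGo/e distribution mixes a hyper-methylated class (target
    mean 0.40) and a hypo-methylated class (target mean 0.70) with
    weights 0.45/0.55.
    """

    seed: int = 0
    n_sequences: int = 12210
    length_range: tuple[int, int] = (300, 900)
    gc_content: float = 0.5
    mixture: list[MixtureClass] = field(default_factory=lambda: [
        MixtureClass(0.45, decay_for_target_mean(0.40, 0.5), 0.10),
        MixtureClass(0.55, decay_for_target_mean(0.70, 0.5), 0.18),
    ])
    go_categories: list[GoCategory] = field(default_factory=list)
    bisulfite_n_clones: int = 4
    bisulfite_methylation_probs: tuple[float, ...] = (0.25, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    bisulfite_failure_rate: float = 0.0

    def validate(self) -> None:
        problems = []
        if self.n_sequences < 1:
            problems.append("n_sequences must be >= 1")
        if not (1 <= self.length_range[0] <= self.length_range[1]):
            problems.append("length_range must satisfy 1 <= min <= max")
        if not 0.0 < self.gc_content < 1.0:
            problems.append("gc_content must be in (0, 1)")
        if not self.mixture:
            problems.append("mixture must have >= 1 class")
        else:
            if abs(sum(c.weight for c in self.mixture) - 1.0) > 1e-9:
                problems.append("mixture weights must sum to 1")
            if any(c.decay_sd < 0 for c in self.mixture):
                problems.append("decay_sd must be >= 0")
        for cat in self.go_categories:
            if cat.n_members < 1:
                problems.append(f"go category {cat.slim_term!r}: n_members >= 1")
            if not 0 <= cat.class_index < len(self.mixture):
                problems.append(f"go category {cat.slim_term!r}: bad class_index")
        if self.bisulfite_n_clones < 1:
            problems.append("bisulfite_n_clones must be >= 1")
        if any(not 0.0 <= p <= 1.0 for p in self.bisulfite_methylation_probs):
            problems.append("bisulfite methylation probs must be in [0, 1]")
        if not 0.0 <= self.bisulfite_failure_rate <= 1.0:
            problems.append("bisulfite_failure_rate must be in [0, 1]")
        if problems:
            raise ConfigValidationError("; ".join(problems))


def sample_mixture_values(n: int, weights, means, sds,
                          seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Draw n values from a normal mixture; returns (values, labels).

    This samples the CpGo/e *values* directly (no sequences), e.g. for
    mixture-fit calibration at the fitted transcriptome geometry
    0.45·N(0.40, 0.12²) + 0.55·N(0.70, 0.21²).
    """
    weights = np.asarray(weights, dtype=float)
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ConfigValidationError("mixture weights must sum to 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    labels = rng.choice(weights.size, size=n, p=weights)
    values = rng.normal(means[labels], sds[labels])
    return values, labels


def expected_cpg_oe(decay: float, gc_content: float = 0.5,
                    length: int = 600) -> float:
    """Analytic expected CpGo/e of an iid sequence after CpG→TpG decay."""
    p_g = gc_content / 2.0
    l = length
    return (1.0 - decay) * l / (l - (l - 1) * p_g * decay)


def decay_for_target_mean(target: float, gc_content: float = 0.5) -> float:
    """Decay probability whose long-sequence expected CpGo/e equals ``target``."""
    p_g = gc_content / 2.0
    if not 0.0 < target <= 1.0:
        raise ValueError("target mean must be in (0, 1]")
    return (1.0 - target) / (1.0 - target * p_g)


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    return rng.choice(np.array(list("ACGT")), size=n, p=p)


def _apply_decay(bases: np.ndarray, d: float, rng: np.random.Generator) -> str:
    """Replace each CpG with TpG independently with probability d.

    CG occurrences cannot overlap and a C→T change never creates a new
    CG, so one vectorised pass is exact.
    """
    seq = bases.copy()
    cg = np.nonzero((seq[:-1] == "C") & (seq[1:] == "G"))[0]
    hit = cg[rng.random(cg.size) < d]
    seq[hit] = "T"
    return "".join(seq)


def generate_population(config: SyntheticConfig
                        ) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Generate the sequence population and its ground-truth table.

    Returns ``(records, truth)`` where ``truth`` has one row per
    sequence with its class index and realised decay probability.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    weights = np.array([c.weight for c in config.mixture])
    lo, hi = config.length_range
    records: list[SequenceRecord] = []
    rows = []
    for i in range(config.n_sequences):
        cls = int(rng.choice(len(weights), p=weights))
        c = config.mixture[cls]
        d = float(np.clip(rng.normal(c.decay_mean, c.decay_sd), 0.0, 0.98))
        length = int(rng.integers(lo, hi + 1))
        bases = _random_bases(rng, length, config.gc_content)
        seq = _apply_decay(bases, d, rng)
        sid = f"synth{i:06d}"
        records.append(SequenceRecord(sid, seq, description=f"class={cls}"))
        rows.append({"sequence_id": sid, "class_index": cls, "decay": d,
                     "length": length})
    truth = pd.DataFrame(rows)
    return records, truth


def generate_annotations(truth: pd.DataFrame,
                         config: SyntheticConfig) -> AnnotationTable:
    """Assign synthetic GO ids so each configured GO-Slim category draws
    ``n_members`` sequences (without replacement) from its methylation
    class. Membership may overlap across categories, never within one.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    rows = []
    slim_map: dict[str, str] = {}
    for idx, cat in enumerate(config.go_categories):
        members = truth.loc[truth["class_index"] == cat.class_index,
                            "sequence_id"].to_numpy()
        if cat.n_members > members.size:
            raise ConfigValidationError(
                f"category {cat.slim_term!r}: n_members={cat.n_members} exceeds "
                f"class size {members.size}"
            )
        go_id = f"GO:{8000000 + idx:07d}"
        slim_map[go_id] = cat.slim_term
        chosen = rng.choice(members, size=cat.n_members, replace=False)
        rows.extend({"sequence_id": s, "go_id": go_id} for s in chosen)
    df = pd.DataFrame(rows, columns=["sequence_id", "go_id"])
    return AnnotationTable(rows=df, slim_map=slim_map)


def generate_bisulfite_set(
    reference_length: int = 180,
    methylation_probs: tuple[float, ...] = (0.25, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0),
    n_clones: int = 4,
    failure_rate: float = 0.0,
    seed: int = 0,
    gc_content: float = 0.5,
) -> tuple[str, list[MethylationStateMap], list[BisulfiteClone]]:
    """Generate a reference amplicon and bisulfite clones with known truth.

    The reference carries exactly ``len(methylation_probs)`` CpG sites
    (evenly spaced); each clone draws an independent methylation state
    per site from its probability, then is converted in silico.
    Returns ``(reference, per-clone state maps, clones)``.
    """
    n_sites = len(methylation_probs)
    if n_sites < 2:
        raise ConfigValidationError("need >= 2 CpG sites in the reference")
    if reference_length < 4 * n_sites:
        raise ConfigValidationError("reference_length too short for the sites")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    # background free of CpG, then plant CGs at evenly spaced positions
    bases = _random_bases(rng, reference_length, gc_content)
    for i in range(len(bases) - 1):
        if bases[i] == "C" and bases[i + 1] == "G":
            bases[i] = "T"
    spacing = reference_length // (n_sites + 1)
    site_positions = [spacing * (j + 1) for j in range(n_sites)]
    for pos in site_positions:
        bases[pos], bases[pos + 1] = "C", "G"
        if pos >= 1 and bases[pos - 1] == "C":
            bases[pos - 1] = "A"  # avoid creating an extra CpG upstream
    reference = "".join(bases)

    state_maps: list[MethylationStateMap] = []
    clones: list[BisulfiteClone] = []
    for c in range(n_clones):
        methylated = {
            pos for pos, p in zip(site_positions, methylation_probs)
            if rng.random() < p
        }
        sm = MethylationStateMap(sequence_id=f"clone{c + 1}",
                                 methylated_positions=methylated)
        converted = convert_in_silico(reference, sm, failure_rate,
                                      seed=int(rng.integers(2**31)))
        state_maps.append(sm)
        clones.append(BisulfiteClone(clone_id=f"clone{c + 1}",
                                     sequence=converted,
                                     source_reference_id="synthetic_amplicon"))
    return reference, state_maps, clones
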