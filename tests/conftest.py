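import numpy as np
import pytest
from hypothesis import settings

from cpgmeth.dinucleotide import DinucleotideProfile

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260923)


def make_profile(seq_id: str, cpg_oe: float | None,
                 tpg_oe: float | None = None) -> DinucleotideProfile:
    """Minimal profile carrying only the ratios (for fit/ANOVA tests)."""
    return DinucleotideProfile(
        sequence_id=seq_id, l=100, n_C=25, n_G=25, n_T=25,
        n_CpG=6, n_GpC=6, n_TpG=6,
        cpg_oe=cpg_oe, gpc_oe=1.0, tpg_oe=tpg_oe,
    )


@pytest.fixture
def toy_fasta(tmp_path):
    def _write(content: str, name: str = "toy.fasta"):
        p = tmp_path / name
        p.write_text(content)
        return p
    return _write
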