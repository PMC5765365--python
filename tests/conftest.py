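import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20171120)


@pytest.fixture
def random_codon_alignment(rng):
    """Factory for random gap-free codon alignment pairs (possibly multi-hit
    codons), guaranteed stop-free."""
    from foamrates.simulate import SENSE_CODONS

    def make(n_codons: int, p_mut: float = 0.15):
        from foamrates.molevol import CODON_AA, STOP_CODONS

        c1 = list(rng.choice(SENSE_CODONS, size=n_codons))
        c2 = []
        for cod in c1:
            new = cod
            for pos in range(3):
                if rng.random() < p_mut:
                    cand = new[:pos] + "ACGT"[rng.integers(4)] + new[pos + 1 :]
                    if cand not in STOP_CODONS:
                        new = cand
            c2.append(new)
        return "".join(c1), "".join(c2)

    return make
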