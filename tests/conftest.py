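import numpy as np
import pandas as pd
import pytest

from sortscreen import (
    GuideLibrary,
    GuideRecord,
    NON_TARGETING,
    ScreenSimConfig,
    simulate_sort_screen,
)


@pytest.fixture(scope="session")
def null_screen():
    """A default-condition null screen (all delta = 0), shared read-only."""
    cfg = ScreenSimConfig(seed=1)
    cm, samples, truth = simulate_sort_screen(cfg)
    return cfg, cm, samples, truth


@pytest.fixture(scope="session")
def signal_screen():
    """20/200 genes perturbed at |delta| = 1.5 (10 up, 10 down), 500x depth."""
    effects = {f"GENE{i:03d}": 1.5 for i in range(1, 11)}
    effects.update({f"GENE{i:03d}": -1.5 for i in range(11, 21)})
    cfg = ScreenSimConfig(depth=500.0, effects=effects, seed=42)
    cm, samples, truth = simulate_sort_screen(cfg)
    return cfg, cm, samples, truth


@pytest.fixture
def tiny_library():
    """Three targeting guides over two genes plus two NT controls."""
    mk = lambda i, s, g: GuideRecord(
        guide_id=f"g{i}", spacer=s, pam="AAGAGT", target_gene=g,
        chrom="chr1", start=10 * i, end=10 * i + 21, strand="+",
    )
    records = [
        mk(1, "ACGTACGTACGTACGTACGTA", "GENEA"),
        mk(2, "TTGCATTGCATTGCATTGCAT", "GENEA"),
        mk(3, "GGCCAAGGCCAAGGCCAAGGC", "GENEB"),
        GuideRecord(guide_id="nt1", spacer="A" * 21, target_gene=NON_TARGETING),
        GuideRecord(guide_id="nt2", spacer="C" * 21, target_gene=NON_TARGETING),
    ]
    return GuideLibrary(records, pam_pattern="NNGRRT", spacer_length=21)


def random_dna(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))
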