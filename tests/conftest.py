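import numpy as np
import pytest

from somnoscore.io_formats import ARTIFACT, NREM, REM, WAKE, Hypnogram

STAGE_CODES = {"W": WAKE, "N": NREM, "R": REM, "A": ARTIFACT}


def hyp(codes: str, epoch_length: float = 10.0, start_zt: float = 0.0) -> Hypnogram:
    """Compact hypnogram literal, e.g. hyp('NNWWN')."""
    return Hypnogram(
        np.array([STAGE_CODES[c] for c in codes]),
        epoch_length=epoch_length,
        start_zt=start_zt,
    )


def random_labels(rng: np.random.Generator, n: int, p_art: float = 0.05) -> np.ndarray:
    """Random label sequences biased toward realistic stage frequencies."""
    return rng.choice(
        [WAKE, NREM, REM, ARTIFACT],
        size=n,
        p=[0.35, 0.45, 0.15, p_art] if p_art else [0.4, 0.45, 0.15, 0.0],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)
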