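import numpy as np
import pytest

from tatamark import ModelConfig


@pytest.fixture(scope="session")
def default_config() -> ModelConfig:
    return ModelConfig.default()


@pytest.fixture(scope="session")
def toy_config() -> ModelConfig:
    """4-bp window, ATAT consensus, unit calibrations (a=0, b=1).

    PWM rows are A, C, G, T; each column scores 1 for its consensus base
    and 0 otherwise.  The slide table scores only TA (2) and AT (1) steps,
    the bend table TA (4) and AT (2), so every raw term is hand-computable.
    """
    pwm = np.zeros((4, 4))
    for j, base_row in enumerate([0, 3, 0, 3]):  # A T A T
        pwm[base_row, j] = 1.0
    slide = {a + b: 0.0 for a in "ACGT" for b in "ACGT"}
    bend = dict(slide)
    slide.update(TA=2.0, AT=1.0)
    bend.update(TA=4.0, AT=2.0)
    unit = {"stop": (0.0, 1.0), "slide": (0.0, 1.0), "bend": (0.0, 1.0)}
    return ModelConfig(pwm=pwm, slide_property=slide, bend_property=bend,
                       calibration=unit)


def random_sequence(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))
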