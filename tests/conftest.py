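import io

import numpy as np
import pytest

from motifspacing.motifs import PWM, parse_jaspar
from motifspacing.pipeline import DEMO_JASPAR


JASPAR_SINGLE = """\
>M1
A [ 10  0  3 ]
C [  0 10  3 ]
G [  0  0  3 ]
T [  0  0  1 ]
"""


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def demo_pwms():
    """The two synthetic demonstration motifs (ETS-like, bZIP-like)."""
    return parse_jaspar(DEMO_JASPAR)


@pytest.fixture
def simple_pwm():
    return parse_jaspar(JASPAR_SINGLE, pseudocount=1.0)[0]


@pytest.fixture
def random_pwm():
    """An informative random 8-mer motif; fixed seed so thresholds are stable."""
    r = np.random.default_rng(42)
    probs = r.dirichlet([0.5] * 4, size=8)
    return PWM(name="RND", probs=probs)
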