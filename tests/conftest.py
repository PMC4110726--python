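import os
import sys

import pytest

sys.path.insert(0, os.path.dirname(__file__))

from helpers import random_kmer_points  # noqa: E402


@pytest.fixture(scope="session")
def small_points():
    return random_kmer_points(300, 8, seed=1234)
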