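"""Small shared test utilities."""

import numpy as np


def maxwellian(n, T):
    """Maxwellian energy distribution with density n and temperature T."""
    c = n * 2.0 / np.sqrt(np.pi) * T**-1.5
    return lambda e: c * np.sqrt(np.maximum(e, 0.0)) * np.exp(-e / T)
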