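import numpy as np
import pytest

from hearkit.gammatone import build_filterbank


@pytest.fixture(scope="session")
def toy_bank():
    """Small dictionary for oracle-checked matching-pursuit tests."""
    return build_filterbank(M=4, fmin=100, fmax=1500, sample_rate=4000)


@pytest.fixture(scope="session")
def default_bank():
    """The default 64-filter dictionary at 16 kHz."""
    return build_filterbank(M=64, sample_rate=16_000)


def brute_force_mp(x, bank, K):
    """Exhaustive matching pursuit: every filter x every offset, direct inner
    products.  Independent of the FFT implementation under test.

    Candidate atoms truncated by the signal end are renormalised to unit
    norm, matching the documented dictionary convention.
    """
    n = len(x)
    r = np.asarray(x, dtype=float).copy()
    irs = [f.impulse_response for f in bank.filters]
    selections = []
    for _ in range(K):
        best = (-1, -1, 0.0, -1.0)
        for m, ir in enumerate(irs):
            for t in range(n):
                L = min(len(ir), n - t)
                seg = ir[:L]
                nrm = np.linalg.norm(seg)
                if nrm <= 1e-12:
                    continue
                v = float(r[t : t + L] @ (seg / nrm))
                if abs(v) > best[3]:
                    best = (m, t, v, abs(v))
        m, t, v, _ = best
        L = min(len(irs[m]), n - t)
        g = irs[m][:L] / np.linalg.norm(irs[m][:L])
        r[t : t + L] -= v * g
        selections.append((m, t, v))
    return selections, r
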