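import numpy as np
import pytest

from ctcsim.chemistry import BindingSystem
from ctcsim.signalling import RateConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def system():
    return BindingSystem(ka=1e10)


@pytest.fixture
def analog_system():
    return BindingSystem(ka=1e10, ka_analog=1e7)


@pytest.fixture
def rates():
    return RateConfig()


def bisect_pair_oracle(total_a: float, total_i: float, ka: float,
                       iters: int = 200) -> float:
    """Independent bisection oracle for the binary complex concentration:
    root of ka*(Ta - C)*(Ti - C) - C on [0, min(Ta, Ti)]."""
    if ka == 0 or total_a == 0 or total_i == 0:
        return 0.0
    lo, hi = 0.0, min(total_a, total_i)

    def residual(c: float) -> float:
        return ka * (total_a - c) * (total_i - c) - c

    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if residual(mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def grid_oracle_analog(total_a, total_i, total_d, ka, kd,
                       rounds: int = 12, n: int = 41):
    """Independent 2-D grid-search oracle for the shared-species system:
    minimizes the two normalized mass-action residuals over
    (complex_ai, complex_di) with iterative refinement."""
    best = (float("inf"), 0.0, 0.0)
    lo1, hi1 = 0.0, min(total_a, total_i)
    lo2, hi2 = 0.0, min(total_d, total_i)
    for _ in range(rounds):
        step1 = (hi1 - lo1) / (n - 1) if hi1 > lo1 else 0.0
        step2 = (hi2 - lo2) / (n - 1) if hi2 > lo2 else 0.0
        for i in range(n):
            for j in range(n):
                c1 = lo1 + i * step1
                c2 = lo2 + j * step2
                if c1 + c2 > total_i:
                    continue
                fa, fi, fd = total_a - c1, total_i - c1 - c2, total_d - c2
                r1 = (ka * fa * fi - c1) / (ka * total_a * total_i + 1e-300)
                r2 = ((kd * fd * fi - c2) / (kd * total_d * total_i + 1e-300)
                      if kd > 0 else c2)
                score = r1 * r1 + r2 * r2
                if score < best[0]:
                    best = (score, c1, c2)
        _, c1, c2 = best
        w1, w2 = (hi1 - lo1) / 4, (hi2 - lo2) / 4
        lo1, hi1 = max(0.0, c1 - w1), min(min(total_a, total_i), c1 + w1)
        lo2, hi2 = max(0.0, c2 - w2), min(min(total_d, total_i), c2 + w2)
    return best[1], best[2]
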