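"""Shared fixtures and independent oracles used across the suite."""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from regnet.motifs import Pwm


def exact_hypergeom_sf(k: int, N: int, n1: int, n2: int) -> Fraction:
    """Brute-force exact upper tail P(X >= k) by term enumeration."""
    lo = max(0, n1 + n2 - N)
    hi = min(n1, n2)
    total = Fraction(0)
    denom = comb(N, n2)
    for i in range(max(k, lo), hi + 1):
        total += Fraction(comb(n1, i) * comb(N - n1, n2 - i), denom)
    return total


def exact_binom_sf(k: int, n: int, p: Fraction) -> Fraction:
    """Brute-force exact binomial upper tail with rational arithmetic."""
    total = Fraction(0)
    for i in range(max(k, 0), n + 1):
        total += comb(n, i) * p**i * (1 - p) ** (n - i)
    return total


@pytest.fixture
def pwm_acgt() -> Pwm:
    """Deterministic 4-mer PWM with consensus ACGT (0.97 consensus mass)."""
    return Pwm.from_consensus("M_ACGT", "ACGT", p_consensus=1.0, score_threshold=6.0)


@pytest.fixture
def small_library() -> list[Pwm]:
    return [
        Pwm.from_consensus("M1", "ACGTACGT", p_consensus=0.99),
        Pwm.from_consensus("M2", "TTGACCAA", p_consensus=0.99),
        Pwm.from_consensus("M3", "GGGCATTA", p_consensus=0.99),
    ]


def random_de_table(rng: np.random.Generator, n: int) -> pd.DataFrame:
    lfc = rng.normal(0, 1, n)
    p = rng.uniform(0, 1, n)
    return pd.DataFrame(
        {"log2fc": lfc, "pvalue": p, "padj": np.minimum(p * 2, 1.0)},
        index=pd.Index([f"g{i:05d}" for i in range(n)], name="gene"),
    )
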