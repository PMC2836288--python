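"""Shared fixture builders for the test suite.

Fingerprints are built programmatically; sizes are chosen with spacing
larger than the matching tolerance so that band identity is unambiguous
unless a test deliberately constructs near-ties.
"""

from __future__ import annotations

from typing import Optional, Sequence

import pytest

from hicfmap.assembly import sulston_log10
from hicfmap.fingerprints import Band, Fingerprint


def make_fp(
    clone_id: str,
    sizes: Sequence[float],
    library: str = "L",
    channel: Optional[str] = "BamHI",
    plate: Optional[str] = None,
) -> Fingerprint:
    return Fingerprint(
        clone_id,
        library,
        tuple(Band(size=float(s), channel=channel) for s in sizes),
        plate=plate,
    )


def grid(start: float, n: int, step: float = 3.0) -> list[float]:
    """n sizes spaced by ``step`` (> 2 x tolerance by default: no chaining)."""
    return [start + step * i for i in range(n)]


def m_for_score_between(
    n1: int, n2: int, log10_hi: float, log10_lo: float, tolerance: float = 0.5, gel_range: float = 900.0
) -> int:
    """Smallest matched-band count whose Sulston score falls inside
    (10**log10_hi excluded, 10**log10_lo included] — i.e. passes the ``lo``
    cutoff but not the ``hi`` one.  Used to tune staged-join fixtures."""
    for m in range(1, min(n1, n2) + 1):
        s = sulston_log10(n1, n2, m, tolerance, gel_range)
        if s <= log10_lo:
            if s > log10_hi:
                return m
            raise AssertionError(
                f"no m with score in (1e{log10_hi:g}, 1e{log10_lo:g}] for n1={n1}, n2={n2}"
            )
    raise AssertionError(f"no m passes 1e{log10_lo:g} for n1={n1}, n2={n2}")


@pytest.fixture
def tolerance() -> float:
    return 0.5
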