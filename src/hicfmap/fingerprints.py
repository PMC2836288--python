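"""Core record types for SNaPshot HICF fingerprints.

A fingerprint is the edited set of dye-channel-tagged restriction-fragment
sizes observed for one BAC clone.  Four of the five digestion enzymes
(BamHI, EcoRI, XbaI, XhoI) leave fluorescently labeled ends, so every band
carries a dye channel named after the enzyme that created its labeled end;
the fifth enzyme (HaeIII) cuts bluntly and is unlabeled.  Band sizes are
fractional base pairs because capillary electrophoresis sizes fragments to
sub-bp resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

#: Dye channels, named after the labeled enzymes, in canonical order.
LABELED_ENZYMES: tuple[str, ...] = ("BamHI", "EcoRI", "XbaI", "XhoI")

CHANNEL_INDEX: dict[Optional[str], int] = {name: i for i, name in enumerate(LABELED_ENZYMES)}
#: Single-channel data (e.g. plain .sizes files) carries no channel label.
CHANNEL_INDEX[None] = 0

#: Offset separating channels in the packed band encoding.  Must exceed the
#: largest representable band size plus any matching tolerance so that bands
#: from different channels can never match.
CHANNEL_STRIDE = 2000.0


def channel_rank(channel: Optional[str]) -> int:
    try:
        return CHANNEL_INDEX[channel]
    except KeyError:
        raise ValueError(
            f"unknown channel {channel!r}; expected one of {LABELED_ENZYMES} or None"
        ) from None


@dataclass(frozen=True)
class Band:
    """One sized restriction fragment.

    ``size`` is the observed (noisy) size in bp; ``true_size`` optionally
    retains the pre-noise integer fragment length for diagnostics.
    ``channel`` is the labeled enzyme that created the band, or None for
    single-channel data.
    """

    size: float
    channel: Optional[str] = None
    true_size: Optional[float] = None

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise ValueError(f"band size must be positive, got {self.size}")
        channel_rank(self.channel)  # validates


@dataclass
class Fingerprint:
    """Edited band set of one BAC clone.

    Bands are kept sorted by (channel, size).  ``plate`` is optional
    microtiter-plate metadata used by cross-contamination screening.
    """

    clone_id: str
    library_name: str
    bands: tuple[Band, ...]
    plate: Optional[str] = None
    _packed: Optional[np.ndarray] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.bands = tuple(
            sorted(self.bands, key=lambda b: (channel_rank(b.channel), b.size))
        )
        self._packed = None

    @property
    def n_bands(self) -> int:
        return len(self.bands)

    def packed(self) -> np.ndarray:
        """Bands encoded as one sorted float array, channels kept apart.

        Encoding: ``channel_rank * CHANNEL_STRIDE + size``.  Because the
        stride exceeds any band size plus tolerance, a single two-pointer
        sweep over two packed arrays performs per-channel band matching.
        """
        if self._packed is None:
            arr = np.array(
                [channel_rank(b.channel) * CHANNEL_STRIDE + b.size for b in self.bands],
                dtype=np.float64,
            )
            arr.sort()
            self._packed = arr
        return self._packed

    def sizes_in_channel(self, channel: Optional[str]) -> np.ndarray:
        return np.array([b.size for b in self.bands if b.channel == channel])

    def with_bands(self, bands: Iterable[Band]) -> "Fingerprint":
        return Fingerprint(self.clone_id, self.library_name, tuple(bands), self.plate)


def sort_fingerprints(fps: Sequence[Fingerprint]) -> list[Fingerprint]:
    """Canonical processing order: lexicographic by clone id."""
    return sorted(fps, key=lambda f: f.clone_id)
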