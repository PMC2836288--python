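"""Fingerprint editing: vector-band removal, size-window collection,
unsuitable-clone filtering, cross-contamination screening and control-clone
checks.

Mirrors the editing a GenoProfiler-style workflow applies before contig
assembly: known vector/artifact bands are struck from every fingerprint,
only fragments inside the collected size window (100-1000 bp) are kept,
clones with implausibly few or many bands are dropped, and near-identical
fingerprints within a microtiter plate — the signature of well-to-well
cross-contamination — are eliminated.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from sklearn.base import BaseEstimator, TransformerMixin

from .assembly import AssemblyParams, PairScores, build_contigs, match_bands, score_all_pairs
from .fingerprints import Band, Fingerprint, sort_fingerprints


@dataclass
class EditParams:
    """Editing thresholds.

    ``min_bands``/``max_bands`` bound the plausible band count of a suitable
    clone ("unsuitable length" filtering); both bounds are inclusive.
    ``cross_contam_similarity`` is the fraction of the smaller clone's bands
    that must match (within ``match_tolerance``, per channel) for a same-plate
    pair to be flagged as cross-contaminated.
    """

    size_min: float = 100.0
    size_max: float = 1000.0
    vector_band_sizes: Tuple[Tuple[Optional[str], float], ...] = ()
    vector_tolerance: float = 0.5
    min_bands: int = 25
    max_bands: int = 250
    cross_contam_similarity: float = 0.95
    match_tolerance: float = 0.5
    keep_one_of_pair: bool = False
    screen_cross_contamination: bool = True

    def validate(self) -> None:
        if not self.size_min < self.size_max:
            raise ValueError("size_min must be < size_max")
        if not 0 < self.cross_contam_similarity <= 1:
            raise ValueError("cross_contam_similarity must be in (0, 1]")
        if self.min_bands < 0 or self.max_bands < self.min_bands:
            raise ValueError("band-count bounds must satisfy 0 <= min <= max")


@dataclass
class EditReport:
    """Counts reconcile exactly: input = unsuitable + cross-contaminated + retained."""

    n_input: int
    n_removed_unsuitable: int
    n_removed_cross_contaminated: int
    n_retained: int
    removal_reasons: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = (
            self.n_removed_unsuitable
            + self.n_removed_cross_contaminated
            + self.n_retained
        )
        if total != self.n_input:
            raise ValueError(
                f"edit report does not reconcile: {self.n_input} != {total}"
            )


def remove_vector_bands(fp: Fingerprint, params: EditParams) -> Fingerprint:
    """Strike any band within ``vector_tolerance`` of a listed vector band in
    the same channel.  An empty vector list leaves the fingerprint unchanged."""
    if not params.vector_band_sizes:
        return fp
    kept = []
    for band in fp.bands:
        hit = any(
            band.channel == ch and abs(band.size - size) <= params.vector_tolerance
            for ch, size in params.vector_band_sizes
        )
        if not hit:
            kept.append(band)
    return fp.with_bands(kept)


def apply_size_window(fp: Fingerprint, params: EditParams) -> Fingerprint:
    """Keep only bands inside the collected size window (inclusive bounds)."""
    return fp.with_bands(
        b for b in fp.bands if params.size_min <= b.size <= params.size_max
    )


def filter_unsuitable(
    fps: Sequence[Fingerprint], params: EditParams
) -> Tuple[List[Fingerprint], EditReport]:
    """Drop clones whose band count falls outside [min_bands, max_bands]."""
    retained: List[Fingerprint] = []
    reasons: Dict[str, str] = {}
    for fp in sort_fingerprints(fps):
        if fp.n_bands < params.min_bands:
            reasons[fp.clone_id] = "too_few_bands"
        elif fp.n_bands > params.max_bands:
            reasons[fp.clone_id] = "too_many_bands"
        else:
            retained.append(fp)
    report = EditReport(
        n_input=len(fps),
        n_removed_unsuitable=len(reasons),
        n_removed_cross_contaminated=0,
        n_retained=len(retained),
        removal_reasons=reasons,
    )
    return retained, report


def band_sharing_fraction(f1: Fingerprint, f2: Fingerprint, tolerance: float) -> float:
    """Matched bands as a fraction of the smaller clone's band count — the
    same band-matching routine the assembler uses (single source of truth)."""
    n_lo = min(f1.n_bands, f2.n_bands)
    if n_lo == 0:
        return 0.0
    return match_bands(f1, f2, tolerance) / n_lo


def detect_cross_contamination(
    fps: Sequence[Fingerprint],
    params: EditParams,
    plates: Optional[Mapping[str, str]] = None,
) -> Tuple[List[Fingerprint], List[Tuple[str, str]]]:
    """Flag near-identical same-plate fingerprint pairs and remove them.

    Plate assignment comes from ``plates`` (clone id -> plate) or the
    fingerprints' own ``plate`` attribute; if neither is available the whole
    input is treated as one plate, with a warning.  Both members of a flagged
    pair are removed unless ``keep_one_of_pair`` is set (then the
    lexicographically smaller clone id survives).
    """
    fps = sort_fingerprints(fps)
    plate_of: Dict[str, Optional[str]] = {}
    for fp in fps:
        plate_of[fp.clone_id] = (
            plates.get(fp.clone_id) if plates is not None else fp.plate
        )
    if all(p is None for p in plate_of.values()) and len(fps) > 1:
        warnings.warn(
            "no plate metadata available; treating all fingerprints as one plate",
            stacklevel=2,
        )
    groups: Dict[Optional[str], List[Fingerprint]] = {}
    for fp in fps:
        groups.setdefault(plate_of[fp.clone_id], []).append(fp)

    flagged_pairs: List[Tuple[str, str]] = []
    flagged: set = set()
    for plate in sorted(groups, key=lambda p: (p is not None, p)):
        group = groups[plate]
        for i, f1 in enumerate(group):
            for f2 in group[i + 1 :]:
                sim = band_sharing_fraction(f1, f2, params.match_tolerance)
                if sim >= params.cross_contam_similarity:
                    flagged_pairs.append((f1.clone_id, f2.clone_id))
                    flagged.add(f2.clone_id)
                    if not params.keep_one_of_pair:
                        flagged.add(f1.clone_id)
    retained = [fp for fp in fps if fp.clone_id not in flagged]
    return retained, flagged_pairs


def edit_fingerprints(
    fps: Sequence[Fingerprint],
    params: Optional[EditParams] = None,
    plates: Optional[Mapping[str, str]] = None,
) -> Tuple[List[Fingerprint], EditReport]:
    """Full edit pass: vector bands, size window, unsuitable clones,
    cross-contamination.  Idempotent and independent of input order."""
    params = params or EditParams()
    params.validate()
    cleaned = [
        apply_size_window(remove_vector_bands(fp, params), params)
        for fp in sort_fingerprints(fps)
    ]
    suitable, report = filter_unsuitable(cleaned, params)
    if params.screen_cross_contamination:
        retained, flagged_pairs = detect_cross_contamination(suitable, params, plates)
    else:
        retained = suitable
    reasons = dict(report.removal_reasons)
    removed_cc = {f.clone_id for f in suitable} - {f.clone_id for f in retained}
    for cid in sorted(removed_cc):
        reasons[cid] = "cross_contaminated"
    final_report = EditReport(
        n_input=len(fps),
        n_removed_unsuitable=report.n_removed_unsuitable,
        n_removed_cross_contaminated=len(removed_cc),
        n_retained=len(retained),
        removal_reasons=reasons,
    )
    return retained, final_report


class FingerprintEditor(BaseEstimator, TransformerMixin):
    """Fingerprint editing with a scikit-learn transformer surface.

    ``transform`` runs the full edit pass and records the resulting
    :class:`EditReport` in ``report_``.  Parameters mirror
    :class:`EditParams`.
    """

    def __init__(
        self,
        size_min: float = 100.0,
        size_max: float = 1000.0,
        vector_band_sizes: Tuple[Tuple[Optional[str], float], ...] = (),
        vector_tolerance: float = 0.5,
        min_bands: int = 25,
        max_bands: int = 250,
        cross_contam_similarity: float = 0.95,
        match_tolerance: float = 0.5,
        keep_one_of_pair: bool = False,
        screen_cross_contamination: bool = True,
    ):
        self.size_min = size_min
        self.size_max = size_max
        self.vector_band_sizes = vector_band_sizes
        self.vector_tolerance = vector_tolerance
        self.min_bands = min_bands
        self.max_bands = max_bands
        self.cross_contam_similarity = cross_contam_similarity
        self.match_tolerance = match_tolerance
        self.keep_one_of_pair = keep_one_of_pair
        self.screen_cross_contamination = screen_cross_contamination

    def _params(self) -> EditParams:
        return EditParams(**self.get_params())

    def fit(self, X: Sequence[Fingerprint], y=None) -> "FingerprintEditor":
        self._params().validate()
        return self

    def transform(
        self, X: Sequence[Fingerprint], plates: Optional[Mapping[str, str]] = None
    ) -> List[Fingerprint]:
        retained, report = edit_fingerprints(X, self._params(), plates)
        self.report_ = report
        return retained


@dataclass
class ControlCloneReport:
    """Assembly outcome of replicate fingerprints of a single control clone.

    If fingerprinting conditions drifted between libraries, replicates of the
    same control clone would split into separate contigs; a single dominant
    contig indicates uniform conditions.
    """

    n_fingerprints: int
    n_contigs: int
    largest_contig_size: int
    n_singletons: int

    @property
    def percent_in_largest(self) -> float:
        if self.n_fingerprints == 0:
            return 0.0
        return round(100.0 * self.largest_contig_size / self.n_fingerprints, 2)


def control_clone_check(
    control_fps: Sequence[Fingerprint],
    params: Optional[AssemblyParams] = None,
    scores: Optional[PairScores] = None,
) -> ControlCloneReport:
    """Assemble control-clone replicates at the initial Sulston cutoff and
    report how many land in the largest contig."""
    if len(control_fps) < 2:
        raise ValueError("need at least 2 control fingerprints")
    params = params or AssemblyParams()
    if scores is None:
        scores = score_all_pairs(control_fps, params)
    result = build_contigs(scores, params.initial_cutoff, params)
    sizes = sorted((len(c.members) for c in result.contigs.values()), reverse=True)
    return ControlCloneReport(
        n_fingerprints=len(control_fps),
        n_contigs=result.n_contigs,
        largest_contig_size=sizes[0] if sizes else 0,
        n_singletons=result.n_singletons,
    )
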