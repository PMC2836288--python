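"""Sulston-score overlap detection and FPC-style contig assembly cascade.

The probability that two clones share at least ``m`` band sizes by chance is
scored with the classical Sulston coincidence probability: with band counts
``nL <= nH``, matching tolerance ``t`` and effective gel range ``G``, a band
of the smaller fingerprint has a chance partner with probability
``x = 1 - (1 - 2 t / G) ** nH`` and the score is the binomial tail
``sum_{j=m}^{nL} C(nL, j) x^j (1 - x)^(nL - j)``, evaluated in log space.
Lower scores mean stronger overlap evidence.

Assembly follows the cascade used for wheat chromosome-arm HICF maps:
single-linkage clustering at a stringent initial cutoff, deQing of contigs
whose Q-clone (consensus-conflicting) fraction exceeds a bound, staged
singleton-to-contig joining, end-merging of remaining singletons, and staged
contig-to-contig end merging down to a permissive cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.special import gammaln
from sklearn.base import BaseEstimator

from .fingerprints import Fingerprint, sort_fingerprints

_LOG10 = math.log(10.0)
#: Probabilities are compared in log10 space with this absolute slack to
#: avoid floating-point threshold flapping at the cascade cutoffs.
LOG10_EPS = 1e-9


@dataclass
class AssemblyParams:
    """Tolerance, chance-match model and the full cutoff cascade.

    ``gel_range`` is the effective per-channel sizing range G entering the
    chance-match probability; with the 100-1000 bp collection window it
    defaults to 900 bp.  Cutoff lists are ordered from stringent to
    permissive (strictly increasing probabilities).
    """

    tolerance: float = 0.5
    gel_range: float = 900.0
    initial_cutoff: float = 1e-50
    deq_max_q_fraction: float = 0.15
    deq_stringency_step: float = 10.0
    singleton_join_cutoffs: Tuple[float, ...] = (1e-30, 1e-22)
    singleton_end_merge_cutoff: float = 1e-15
    contig_merge_cutoffs: Tuple[float, ...] = (1e-30, 1e-20, 1e-15, 1e-12)
    contig_merge_min_overlap_clones: int = 1
    end_depth: int = 2
    q_conflict_fraction: float = 0.5

    def validate(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        if self.gel_range <= self.tolerance:
            raise ValueError("gel_range must exceed tolerance")
        for name in ("singleton_join_cutoffs", "contig_merge_cutoffs"):
            cuts = getattr(self, name)
            if any(b <= a for a, b in zip(cuts, cuts[1:])):
                raise ValueError(f"{name} must be strictly increasing: {cuts}")
        for name in (
            "initial_cutoff",
            "singleton_end_merge_cutoff",
            "deq_max_q_fraction",
        ):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.deq_stringency_step <= 1:
            raise ValueError("deq_stringency_step must be > 1")
        if self.end_depth < 1 or self.contig_merge_min_overlap_clones < 1:
            raise ValueError("end_depth and contig_merge_min_overlap_clones must be >= 1")

    @property
    def loosest_cutoff(self) -> float:
        return max(
            self.initial_cutoff,
            *self.singleton_join_cutoffs,
            self.singleton_end_merge_cutoff,
            *self.contig_merge_cutoffs,
        )


# ---------------------------------------------------------------------------
# band matching and the Sulston score
# ---------------------------------------------------------------------------


def _match_packed(a: Sequence[float], b: Sequence[float], tolerance: float) -> int:
    """Greedy two-pointer matching of two sorted band lists.

    Each band is used at most once; advancing the pointer of the smaller
    unmatched size first makes the pairing nearest-candidate-first with ties
    broken toward the smaller size.  For threshold matching of sorted points
    on a line this greedy is a maximum matching.
    """
    i = j = m = 0
    na, nb = len(a), len(b)
    while i < na and j < nb:
        d = a[i] - b[j]
        if d > tolerance:
            j += 1
        elif d < -tolerance:
            i += 1
        else:
            m += 1
            i += 1
            j += 1
    return m


def match_bands(f1: Fingerprint, f2: Fingerprint, tolerance: float = 0.5) -> int:
    """Number of bands shared within ``tolerance``, matched per channel."""
    return _match_packed(f1.packed().tolist(), f2.packed().tolist(), tolerance)


def chance_match_probability(n_high: int, tolerance: float, gel_range: float) -> float:
    """Probability x that one band has a chance partner among n_high bands."""
    return -math.expm1(n_high * math.log1p(-2.0 * tolerance / gel_range))


from functools import lru_cache


@lru_cache(maxsize=1 << 20)
def _sulston_log10_cached(n_lo: int, n_hi: int, m: int, tolerance: float, gel_range: float) -> float:
    x = chance_match_probability(n_hi, tolerance, gel_range)
    if x >= 1.0:
        return 0.0
    j = np.arange(m, n_lo + 1, dtype=np.float64)
    log_pmf = (
        gammaln(n_lo + 1.0)
        - gammaln(j + 1.0)
        - gammaln(n_lo - j + 1.0)
        + j * math.log(x)
        + (n_lo - j) * math.log1p(-x)
    )
    peak = float(log_pmf.max())
    return (peak + math.log(float(np.exp(log_pmf - peak).sum()))) / _LOG10


def sulston_log10(
    n1: int, n2: int, m: int, tolerance: float = 0.5, gel_range: float = 900.0
) -> float:
    """log10 of the Sulston coincidence score (stable in deep tails)."""
    n_lo, n_hi = (n1, n2) if n1 <= n2 else (n2, n1)
    if not 0 <= m <= n_lo:
        raise ValueError(f"matched count m={m} outside [0, min(n1, n2)={n_lo}]")
    if m == 0:
        return 0.0
    return _sulston_log10_cached(n_lo, n_hi, m, tolerance, gel_range)


def sulston_score(
    n1: int, n2: int, m: int, tolerance: float = 0.5, gel_range: float = 900.0
) -> float:
    """The Sulston score as a probability in (0, 1].

    May underflow to 0.0 for extremely deep tails; use :func:`sulston_log10`
    when comparing against cutoffs.
    """
    return 10.0 ** sulston_log10(n1, n2, m, tolerance, gel_range)


# ---------------------------------------------------------------------------
# all-pairs scoring with a conservative coarse-bin prescreen
# ---------------------------------------------------------------------------


@dataclass
class PairScores:
    """Sparse map of clone-pair log10 Sulston scores below the loosest cutoff."""

    log10_scores: Dict[Tuple[str, str], float]
    neighbors: Dict[str, Dict[str, float]]
    clone_ids: Tuple[str, ...]

    def get_log10(self, a: str, b: str) -> Optional[float]:
        key = (a, b) if a < b else (b, a)
        return self.log10_scores.get(key)

    def __len__(self) -> int:
        return len(self.log10_scores)


def _min_matches_required(
    n_lo: int, n_hi: int, log10_cutoff: float, tolerance: float, gel_range: float
) -> int:
    """Smallest m whose score passes the cutoff; n_lo + 1 if impossible."""
    for m in range(1, n_lo + 1):
        if sulston_log10(n_lo, n_hi, m, tolerance, gel_range) <= log10_cutoff + LOG10_EPS:
            return m
    return n_lo + 1


def _candidate_pairs(
    packed: List[np.ndarray], tolerance: float, min_rough: int
) -> Iterable[Tuple[int, int]]:
    """Index pairs whose coarse co-binned band count reaches ``min_rough``.

    Bands are hashed into bins of width ``tolerance``; any two bands within
    tolerance land in the same or adjacent bins, so the co-bin count (with
    one side dilated by +-1 bin) upper-bounds the true matched-band count and
    the prescreen can never drop a pair that could pass the loosest cutoff.
    """
    n = len(packed)
    col_of: Dict[int, int] = {}
    rows_m, cols_m = [], []
    rows_d, cols_d = [], []
    for i, arr in enumerate(packed):
        bins = np.floor(arr / tolerance).astype(np.int64)
        for b in bins.tolist():
            col = col_of.setdefault(b, len(col_of))
            rows_m.append(i)
            cols_m.append(col)
        for b in bins.tolist():
            for bb in (b - 1, b, b + 1):
                col = col_of.setdefault(bb, len(col_of))
                rows_d.append(i)
                cols_d.append(col)
    ncols = len(col_of)
    M = csr_matrix(
        (np.ones(len(rows_m)), (rows_m, cols_m)), shape=(n, ncols), dtype=np.int32
    )
    D = csr_matrix(
        (np.ones(len(rows_d)), (rows_d, cols_d)), shape=(n, ncols), dtype=np.int32
    )
    rough = (M @ D.T).tocoo()
    keep = (rough.data >= min_rough) & (rough.row < rough.col)
    pairs = sorted(zip(rough.row[keep].tolist(), rough.col[keep].tolist()))
    return pairs


def score_all_pairs(
    fps: Sequence[Fingerprint], params: AssemblyParams
) -> PairScores:
    """Score all unordered fingerprint pairs, keeping those at or below the
    loosest cascade cutoff.  Deterministic: input is processed in clone-id
    order and pair keys are sorted."""
    params.validate()
    fps = sort_fingerprints(fps)
    ids = tuple(f.clone_id for f in fps)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate clone ids in fingerprint set")
    packed = [f.packed() for f in fps]
    counts = [len(p) for p in packed]
    log10_loosest = math.log10(params.loosest_cutoff)

    n = len(fps)
    scores: Dict[Tuple[str, str], float] = {}
    neighbors: Dict[str, Dict[str, float]] = {cid: {} for cid in ids}
    if n < 2:
        return PairScores(scores, neighbors, ids)

    nonzero = [c for c in counts if c > 0]
    if not nonzero:
        return PairScores(scores, neighbors, ids)
    n_min = min(nonzero)
    min_rough = _min_matches_required(
        n_min, n_min, log10_loosest, params.tolerance, params.gel_range
    )

    if n <= 64:
        pairs: Iterable[Tuple[int, int]] = (
            (i, j) for i in range(n) for j in range(i + 1, n)
        )
    else:
        pairs = _candidate_pairs(packed, params.tolerance, min_rough)

    lists = [p.tolist() for p in packed]
    for i, j in pairs:
        if counts[i] == 0 or counts[j] == 0:
            continue
        m = _match_packed(lists[i], lists[j], params.tolerance)
        if m == 0:
            continue
        s = sulston_log10(counts[i], counts[j], m, params.tolerance, params.gel_range)
        if s <= log10_loosest + LOG10_EPS:
            a, b = ids[i], ids[j]
            scores[(a, b)] = s
            neighbors[a][b] = s
            neighbors[b][a] = s
    return PairScores(scores, neighbors, ids)


# ---------------------------------------------------------------------------
# contigs and the assembly result
# ---------------------------------------------------------------------------


@dataclass
class Contig:
    contig_id: str
    members: Tuple[str, ...]
    built_at_cutoff: float
    q_flags: Optional[Dict[str, bool]] = None
    linear_order: Optional[Tuple[str, ...]] = None
    consensus_bands: Optional[np.ndarray] = None  # packed encoding

    @property
    def q_fraction(self) -> float:
        if not self.q_flags:
            return 0.0
        return sum(self.q_flags.values()) / len(self.members)


def _contig_id(members: Iterable[str]) -> str:
    return "ctg_" + min(members)


@dataclass
class AssemblyResult:
    contigs: Dict[str, Contig]
    singletons: List[str]
    params: AssemblyParams
    stage_log: List[str] = field(default_factory=list)
    stage_joined: Dict[str, str] = field(default_factory=dict)
    clone_ids: Tuple[str, ...] = ()

    def membership(self) -> Dict[str, Optional[str]]:
        out: Dict[str, Optional[str]] = {c: None for c in self.singletons}
        for cid, contig in self.contigs.items():
            for m in contig.members:
                out[m] = cid
        return out

    @property
    def n_contigs(self) -> int:
        return len(self.contigs)

    @property
    def n_singletons(self) -> int:
        return len(self.singletons)

    def check_partition(self) -> None:
        """Contig members and singletons must partition the input clone set."""
        seen: List[str] = list(self.singletons)
        for contig in self.contigs.values():
            seen.extend(contig.members)
        if len(seen) != len(set(seen)):
            raise AssertionError("clone assigned to more than one contig/singleton slot")
        if set(seen) != set(self.clone_ids):
            raise AssertionError("contig members + singletons != input clones")


def _components(
    members: Sequence[str], scores: PairScores, log10_cutoff: float
) -> List[List[str]]:
    """Connected components of the score graph restricted to ``members``."""
    parent = {m: m for m in members}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    member_set = set(members)
    for a in sorted(members):
        for b, s in sorted(scores.neighbors.get(a, {}).items()):
            if b in member_set and a < b and s <= log10_cutoff + LOG10_EPS:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)
    comps: Dict[str, List[str]] = {}
    for m in members:
        comps.setdefault(find(m), []).append(m)
    return [sorted(c) for c in sorted(comps.values(), key=min)]


def build_contigs(
    scores: PairScores,
    cutoff: float,
    params: Optional[AssemblyParams] = None,
    clone_ids: Optional[Sequence[str]] = None,
) -> AssemblyResult:
    """Single-linkage clustering: contigs are connected components of the
    graph whose edges are pair scores at or below ``cutoff``."""
    params = params or AssemblyParams()
    ids = tuple(sorted(clone_ids if clone_ids is not None else scores.clone_ids))
    log10_cutoff = math.log10(cutoff)
    contigs: Dict[str, Contig] = {}
    singletons: List[str] = []
    result = AssemblyResult({}, [], params, clone_ids=ids)
    for comp in _components(ids, scores, log10_cutoff):
        if len(comp) == 1:
            singletons.append(comp[0])
        else:
            cid = _contig_id(comp)
            contigs[cid] = Contig(cid, tuple(comp), built_at_cutoff=cutoff)
            for m in comp:
                result.stage_joined[m] = f"initial@{cutoff:g}"
    result.contigs = contigs
    result.singletons = sorted(singletons)
    result.stage_log.append(
        f"build_contigs cutoff={cutoff:g}: {len(contigs)} contigs, "
        f"{len(singletons)} singletons"
    )
    return result


# ---------------------------------------------------------------------------
# Q clones and deQing
# ---------------------------------------------------------------------------


def flag_q_clones(
    contig: Contig,
    fingerprints: Mapping[str, Fingerprint],
    params: AssemblyParams,
) -> Dict[str, bool]:
    """Flag members conflicting with the contig's consensus band set.

    The consensus is the union of band clusters (merged within tolerance,
    per channel) supported by at least two distinct members.  A member is Q
    when more than ``q_conflict_fraction`` of its bands lack consensus
    support.  Contigs of fewer than three members carry no Q flags
    (insufficient evidence); their consensus is still computed.
    """
    tol = params.tolerance
    values: List[float] = []
    owners: List[int] = []
    members = contig.members
    for idx, m in enumerate(members):
        arr = fingerprints[m].packed()
        values.extend(arr.tolist())
        owners.extend([idx] * len(arr))
    order = np.argsort(np.asarray(values), kind="stable")
    sv = np.asarray(values)[order]
    so = np.asarray(owners)[order]

    consensus: List[float] = []
    start = 0
    for end in range(1, len(sv) + 1):
        if end == len(sv) or sv[end] - sv[start] > tol + LOG10_EPS:
            if len(set(so[start:end].tolist())) >= 2:
                consensus.append(float(sv[start:end].mean()))
            start = end
    cons = np.asarray(consensus)
    contig.consensus_bands = cons

    flags: Dict[str, bool] = {}
    if len(members) < 3:
        contig.q_flags = {}
        return {}
    for m in members:
        arr = fingerprints[m].packed()
        if len(arr) == 0:
            flags[m] = False
            continue
        if len(cons) == 0:
            unsupported = len(arr)
        else:
            pos = np.searchsorted(cons, arr)
            left = np.abs(arr - cons[np.clip(pos - 1, 0, len(cons) - 1)])
            right = np.abs(arr - cons[np.clip(pos, 0, len(cons) - 1)])
            unsupported = int((np.minimum(left, right) > tol + LOG10_EPS).sum())
        flags[m] = unsupported / len(arr) > params.q_conflict_fraction
    contig.q_flags = flags
    return flags


_MAX_DEQ_ROUNDS = 200


def deq(
    result: AssemblyResult,
    fingerprints: Mapping[str, Fingerprint],
    scores: PairScores,
    params: Optional[AssemblyParams] = None,
) -> AssemblyResult:
    """Dissolve and re-cluster contigs until none exceeds the Q-clone bound.

    Every offending contig is re-clustered at a cutoff ``deq_stringency_step``
    times more stringent than the one it was built at; rounds repeat,
    tightening each time, until all contigs satisfy the bound or dissolve to
    singletons.  Terminates because each tightening strictly reduces the edge
    set available to the offender's members.
    """
    params = params or result.params
    for _ in range(_MAX_DEQ_ROUNDS):
        offenders = []
        for cid in sorted(result.contigs):
            contig = result.contigs[cid]
            if contig.q_flags is None:
                flag_q_clones(contig, fingerprints, params)
            if len(contig.members) >= 3 and contig.q_fraction > params.deq_max_q_fraction:
                offenders.append(cid)
        if not offenders:
            break
        for cid in offenders:
            contig = result.contigs.pop(cid)
            new_cutoff = contig.built_at_cutoff / params.deq_stringency_step
            comps = _components(contig.members, scores, math.log10(new_cutoff))
            n_new = 0
            for comp in comps:
                if len(comp) == 1:
                    result.singletons.append(comp[0])
                    result.stage_joined.pop(comp[0], None)
                else:
                    ncid = _contig_id(comp)
                    result.contigs[ncid] = Contig(
                        ncid, tuple(comp), built_at_cutoff=new_cutoff
                    )
                    for m in comp:
                        result.stage_joined[m] = f"deq@{new_cutoff:g}"
                    n_new += 1
            result.stage_log.append(
                f"deq: dissolved {cid} (Q fraction {contig.q_fraction:.2f}) "
                f"-> {n_new} contigs at {new_cutoff:g}"
            )
        result.singletons = sorted(result.singletons)
    else:
        raise RuntimeError("deQing failed to converge")
    return result


# ---------------------------------------------------------------------------
# singleton joining, ordering, end merging, contig merging
# ---------------------------------------------------------------------------


def _best_contig_for(
    clone: str,
    scores: PairScores,
    member_of: Mapping[str, Optional[str]],
    allowed: Optional[Mapping[str, set]] = None,
) -> Optional[Tuple[float, str]]:
    """Best (log10 score, contig id) reachable from ``clone``; ties go to the
    lexicographically smallest contig id.  ``allowed`` optionally restricts
    the reachable members per contig (used for end merging)."""
    best: Optional[Tuple[float, str]] = None
    for nbr, s in sorted(scores.neighbors.get(clone, {}).items()):
        cid = member_of.get(nbr)
        if cid is None:
            continue
        if allowed is not None and nbr not in allowed.get(cid, ()):
            continue
        if best is None or s < best[0] - LOG10_EPS or (
            abs(s - best[0]) <= LOG10_EPS and cid < best[1]
        ):
            best = (s, cid)
    return best


def join_singletons(
    result: AssemblyResult,
    scores: PairScores,
    params: Optional[AssemblyParams] = None,
) -> AssemblyResult:
    """Staged singleton-to-contig joining at the configured cutoffs."""
    params = params or result.params
    for stage_idx, cutoff in enumerate(params.singleton_join_cutoffs, start=1):
        log10_cutoff = math.log10(cutoff)
        member_of = result.membership()
        joined = []
        for s in sorted(result.singletons):
            best = _best_contig_for(s, scores, member_of)
            if best is not None and best[0] <= log10_cutoff + LOG10_EPS:
                cid = best[1]
                contig = result.contigs.pop(cid)
                new_members = tuple(sorted(contig.members + (s,)))
                ncid = _contig_id(new_members)
                result.contigs[ncid] = replace(
                    contig,
                    contig_id=ncid,
                    members=new_members,
                    q_flags=None,
                    linear_order=None,
                    consensus_bands=None,
                )
                member_of = {
                    **member_of,
                    s: ncid,
                    **{m: ncid for m in new_members},
                }
                result.stage_joined[s] = f"singleton_join@{cutoff:g}"
                joined.append(s)
        result.singletons = sorted(set(result.singletons) - set(joined))
        result.stage_log.append(
            f"join_singletons stage {stage_idx} cutoff={cutoff:g}: joined {len(joined)}"
        )
    return result


def order_contig(contig: Contig, scores: PairScores) -> Tuple[str, ...]:
    """Seriation of contig members along the diameter path of the
    maximum-significance spanning tree (edge weight = -log10 score); members
    off the path are inserted next to their best-scoring ordered neighbor.
    Deterministic under ties (lexicographic)."""
    members = sorted(contig.members)
    if len(members) <= 2:
        contig.linear_order = tuple(members)
        return contig.linear_order

    G = nx.Graph()
    G.add_nodes_from(members)
    member_set = set(members)
    for a in members:
        for b, s in sorted(scores.neighbors.get(a, {}).items()):
            if b in member_set and a < b:
                G.add_edge(a, b, weight=-s)

    order: List[str] = []
    for comp_nodes in sorted(nx.connected_components(G), key=min):
        sub = G.subgraph(comp_nodes)
        if sub.number_of_nodes() == 1:
            order.extend(comp_nodes)
            continue
        tree = nx.maximum_spanning_tree(sub, weight="weight")

        def farthest(src: str) -> str:
            dist = nx.single_source_dijkstra_path_length(
                tree, src, weight=lambda u, v, d: d["weight"]
            )
            dmax = max(dist.values())
            return min(n for n, d in dist.items() if d == dmax)

        u = farthest(min(comp_nodes))
        v = farthest(u)
        path = nx.shortest_path(tree, u, v)
        if path[0] > path[-1]:
            path = path[::-1]
        placed = list(path)
        placed_set = set(placed)
        remaining = sorted(set(comp_nodes) - placed_set)
        nbr_sorted = {
            m: sorted(scores.neighbors.get(m, {}).items(), key=lambda kv: (kv[1], kv[0]))
            for m in remaining
        }
        while remaining:
            best = None  # (score, off-path member, anchor)
            for m in remaining:
                for anchor, s in nbr_sorted[m]:
                    if anchor in placed_set:
                        cand = (s, m, anchor)
                        if best is None or cand < best:
                            best = cand
                        break  # neighbors pre-sorted: first placed one is best
            if best is None:  # no edge into the ordered part; append sorted
                placed.extend(remaining)
                break
            _, m, anchor = best
            placed.insert(placed.index(anchor) + 1, m)
            placed_set.add(m)
            remaining.remove(m)
        order.extend(placed)
    contig.linear_order = tuple(order)
    return contig.linear_order


def _end_members(contig: Contig, scores: PairScores, params: AssemblyParams) -> set:
    if contig.linear_order is None or len(contig.linear_order) != len(contig.members):
        order_contig(contig, scores)
    d = params.end_depth
    lo = contig.linear_order
    return set(lo[:d]) | set(lo[-d:])


def end_merge_singletons(
    result: AssemblyResult,
    scores: PairScores,
    params: Optional[AssemblyParams] = None,
) -> AssemblyResult:
    """Join remaining singletons that overlap a contig end.

    A singleton joins only when its best passing score is against a member
    within ``end_depth`` of either end of a contig's linear order."""
    params = params or result.params
    cutoff = params.singleton_end_merge_cutoff
    log10_cutoff = math.log10(cutoff)
    member_of = result.membership()
    ends = {cid: _end_members(c, scores, params) for cid, c in result.contigs.items()}
    joined = []
    for s in sorted(result.singletons):
        best = _best_contig_for(s, scores, member_of, allowed=ends)
        if best is not None and best[0] <= log10_cutoff + LOG10_EPS:
            cid = best[1]
            contig = result.contigs.pop(cid)
            ends.pop(cid)
            new_members = tuple(sorted(contig.members + (s,)))
            ncid = _contig_id(new_members)
            new_contig = replace(
                contig,
                contig_id=ncid,
                members=new_members,
                q_flags=None,
                linear_order=None,
                consensus_bands=None,
            )
            result.contigs[ncid] = new_contig
            ends[ncid] = _end_members(new_contig, scores, params)
            member_of = {**member_of, s: ncid, **{m: ncid for m in new_members}}
            result.stage_joined[s] = f"end_merge@{cutoff:g}"
            joined.append(s)
    result.singletons = sorted(set(result.singletons) - set(joined))
    result.stage_log.append(
        f"end_merge_singletons cutoff={cutoff:g}: joined {len(joined)}"
    )
    return result


def merge_contigs(
    result: AssemblyResult,
    scores: PairScores,
    params: Optional[AssemblyParams] = None,
) -> AssemblyResult:
    """Staged end-to-end contig merging, iterated to a fixed point per cutoff.

    Two contigs merge when at least ``contig_merge_min_overlap_clones``
    end-clone pairs (one member within ``end_depth`` of an end of each) score
    at or below the stage cutoff."""
    params = params or result.params
    for cutoff in params.contig_merge_cutoffs:
        log10_cutoff = math.log10(cutoff)
        merged = True
        while merged:
            merged = False
            ends = {
                cid: _end_members(c, scores, params)
                for cid, c in sorted(result.contigs.items())
            }
            ids = sorted(result.contigs)
            for i, ca in enumerate(ids):
                for cb in ids[i + 1 :]:
                    n_links = 0
                    for a in sorted(ends[ca]):
                        for b in sorted(ends[cb]):
                            s = scores.get_log10(a, b)
                            if s is not None and s <= log10_cutoff + LOG10_EPS:
                                n_links += 1
                    if n_links >= params.contig_merge_min_overlap_clones:
                        A = result.contigs.pop(ca)
                        B = result.contigs.pop(cb)
                        members = tuple(sorted(A.members + B.members))
                        ncid = _contig_id(members)
                        nc = Contig(
                            ncid,
                            members,
                            built_at_cutoff=max(A.built_at_cutoff, B.built_at_cutoff),
                        )
                        order_contig(nc, scores)
                        result.contigs[ncid] = nc
                        result.stage_log.append(
                            f"merge_contigs cutoff={cutoff:g}: {ca} + {cb} -> {ncid}"
                        )
                        merged = True
                        break
                if merged:
                    break
    return result


# ---------------------------------------------------------------------------
# the full cascade
# ---------------------------------------------------------------------------


def assemble_pipeline(
    fps: Sequence[Fingerprint],
    params: Optional[AssemblyParams] = None,
    scores: Optional[PairScores] = None,
) -> AssemblyResult:
    """Run the full cascade: initial clustering, deQing, singleton joining,
    singleton end-merging and contig merging.  The result satisfies the
    partition invariant (checked)."""
    params = params or AssemblyParams()
    params.validate()
    fps = sort_fingerprints(fps)
    fp_by_id = {f.clone_id: f for f in fps}
    if len(fp_by_id) != len(fps):
        raise ValueError("duplicate clone ids")
    if scores is None:
        scores = score_all_pairs(fps, params)
    result = build_contigs(scores, params.initial_cutoff, params)
    result.check_partition()
    result = deq(result, fp_by_id, scores, params)
    result.check_partition()
    result = join_singletons(result, scores, params)
    result.check_partition()
    result = end_merge_singletons(result, scores, params)
    result.check_partition()
    result = merge_contigs(result, scores, params)
    result.check_partition()
    for cid in sorted(result.contigs):
        contig = result.contigs[cid]
        if contig.linear_order is None or len(contig.linear_order) != len(contig.members):
            order_contig(contig, scores)
        flag_q_clones(contig, fp_by_id, params)
    result.stage_log.append(
        f"final: {result.n_contigs} contigs, {result.n_singletons} singletons"
    )
    return result


class SulstonAssembler(BaseEstimator):
    """Sulston-score contig assembler with a scikit-learn clusterer surface.

    ``fit`` takes a sequence of :class:`Fingerprint` objects and exposes the
    assembly as ``labels_`` (contig index per input fingerprint, -1 for
    singletons), ``contigs_``, ``singletons_`` and the full ``result_``.

    Parameters mirror :class:`AssemblyParams`.
    """

    def __init__(
        self,
        tolerance: float = 0.5,
        gel_range: float = 900.0,
        initial_cutoff: float = 1e-50,
        deq_max_q_fraction: float = 0.15,
        deq_stringency_step: float = 10.0,
        singleton_join_cutoffs: Tuple[float, ...] = (1e-30, 1e-22),
        singleton_end_merge_cutoff: float = 1e-15,
        contig_merge_cutoffs: Tuple[float, ...] = (1e-30, 1e-20, 1e-15, 1e-12),
        contig_merge_min_overlap_clones: int = 1,
        end_depth: int = 2,
        q_conflict_fraction: float = 0.5,
    ):
        self.tolerance = tolerance
        self.gel_range = gel_range
        self.initial_cutoff = initial_cutoff
        self.deq_max_q_fraction = deq_max_q_fraction
        self.deq_stringency_step = deq_stringency_step
        self.singleton_join_cutoffs = singleton_join_cutoffs
        self.singleton_end_merge_cutoff = singleton_end_merge_cutoff
        self.contig_merge_cutoffs = contig_merge_cutoffs
        self.contig_merge_min_overlap_clones = contig_merge_min_overlap_clones
        self.end_depth = end_depth
        self.q_conflict_fraction = q_conflict_fraction

    def _params(self) -> AssemblyParams:
        return AssemblyParams(**self.get_params())

    def fit(self, X: Sequence[Fingerprint], y=None) -> "SulstonAssembler":
        params = self._params()
        self.result_ = assemble_pipeline(list(X), params)
        membership = self.result_.membership()
        contig_ids = sorted(self.result_.contigs)
        index_of = {cid: i for i, cid in enumerate(contig_ids)}
        self.labels_ = np.array(
            [
                index_of[membership[f.clone_id]]
                if membership[f.clone_id] is not None
                else -1
                for f in X
            ],
            dtype=int,
        )
        self.contigs_ = self.result_.contigs
        self.singletons_ = self.result_.singletons
        self.n_contigs_ = self.result_.n_contigs
        return self

    def fit_predict(self, X: Sequence[Fingerprint], y=None) -> np.ndarray:
        return self.fit(X, y).labels_
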