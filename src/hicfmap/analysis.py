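"""Merged-library feasibility analysis.

Quantifies how faithfully contig assembly keeps clones from homoeologous
chromosome arms apart: single-arm libraries are merged in silico, assembled,
every contig is classified by its prevalent source library, and the clones
from other libraries inside it are counted as misincorporated.  Because
flow-sorted libraries carry ~10% of clones from other chromosome arms, a
baseline misincorporation of contamination_rate x n_homoeologous_arms /
total_arms is expected even for a perfectly separating assembler.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .assembly import AssemblyParams, AssemblyResult, assemble_pipeline
from .editing import EditParams, edit_fingerprints
from .fingerprints import Fingerprint
from .simulate import (
    DEFAULT_NOISE_SD,
    LibraryParams,
    SimParams,
    arms_by_id,
    diverge_homoeologs,
    fingerprint_library,
    generate_arm,
    sample_library,
)


@dataclass
class LibrarySummary:
    library_name: str
    n_clones_after_editing: int
    n_contigs: int
    n_singletons: int

    def __post_init__(self) -> None:
        for f in (self.n_clones_after_editing, self.n_contigs, self.n_singletons):
            if f < 0:
                raise ValueError("counts must be >= 0")


def library_summary(name: str, n_clones: int, result: AssemblyResult) -> LibrarySummary:
    return LibrarySummary(name, n_clones, result.n_contigs, result.n_singletons)


def summarize_assemblies(
    summaries: Sequence[LibrarySummary],
    merged: Optional[LibrarySummary] = None,
) -> pd.DataFrame:
    """Per-library clone/contig/singleton counts plus a totals row (column
    sums of the per-library rows); an optional merged-library row follows."""
    rows = [
        {
            "library": s.library_name,
            "n_clones_after_editing": s.n_clones_after_editing,
            "n_contigs": s.n_contigs,
            "n_singletons": s.n_singletons,
        }
        for s in summaries
    ]
    df = pd.DataFrame(
        rows, columns=["library", "n_clones_after_editing", "n_contigs", "n_singletons"]
    )
    total = {
        "library": "Total",
        "n_clones_after_editing": int(df["n_clones_after_editing"].sum()) if len(df) else 0,
        "n_contigs": int(df["n_contigs"].sum()) if len(df) else 0,
        "n_singletons": int(df["n_singletons"].sum()) if len(df) else 0,
    }
    df = pd.concat([df, pd.DataFrame([total])], ignore_index=True)
    if merged is not None:
        df = pd.concat(
            [
                df,
                pd.DataFrame(
                    [
                        {
                            "library": merged.library_name,
                            "n_clones_after_editing": merged.n_clones_after_editing,
                            "n_contigs": merged.n_contigs,
                            "n_singletons": merged.n_singletons,
                        }
                    ]
                ),
            ],
            ignore_index=True,
        )
    return df


def merge_libraries(
    libraries: Mapping[str, Sequence[Fingerprint]],
) -> Tuple[List[Fingerprint], Dict[str, int]]:
    """Union of per-library fingerprints, each retaining its library name.

    Clone ids must be unique across the merged set (they are expected to be
    prefixed with their library name).  Returns the merged collection and
    the per-library sizes recorded for later adjustment.
    """
    merged: List[Fingerprint] = []
    sizes: Dict[str, int] = {}
    seen: set = set()
    for name in sorted(libraries):
        fps = libraries[name]
        sizes[name] = len(fps)
        for fp in fps:
            if fp.clone_id in seen:
                raise ValueError(f"duplicate clone id after merging: {fp.clone_id}")
            seen.add(fp.clone_id)
            merged.append(fp)
    return merged, sizes


@dataclass
class ContigClassification:
    contig_id: str
    counts: Dict[str, int]
    prevalent_library: str  # library name or "ambiguous"
    min_clones_threshold: int

    @property
    def n_clones(self) -> int:
        return sum(self.counts.values())


def classify_contigs(
    result: AssemblyResult,
    library_of: Mapping[str, str],
    min_clones: int = 4,
) -> Tuple[List[ContigClassification], int]:
    """Classify each contig of >= min_clones members by prevalent library.

    The prevalent library must hold a strict majority of the maximum count;
    exact ties are classified "ambiguous" and excluded from the tables but
    counted.  Returns (classifications, n_ambiguous).
    """
    classifications: List[ContigClassification] = []
    n_ambiguous = 0
    for cid in sorted(result.contigs):
        contig = result.contigs[cid]
        if len(contig.members) < min_clones:
            continue
        counts: Dict[str, int] = {}
        for m in contig.members:
            lib = library_of[m]
            counts[lib] = counts.get(lib, 0) + 1
        top = max(counts.values())
        leaders = sorted(lib for lib, c in counts.items() if c == top)
        if len(leaders) > 1:
            n_ambiguous += 1
            prevalent = "ambiguous"
        else:
            prevalent = leaders[0]
            classifications.append(
                ContigClassification(cid, counts, prevalent, min_clones)
            )
    return classifications, n_ambiguous


@dataclass
class MisincorporationTable:
    """Per-prevalent-library clone-source counts and percentages.

    ``raw`` percentages divide each source-library count by the row total;
    ``adjusted`` first rescales each count by (prevalent library size /
    source library size) to compensate for unequal library sizes, then
    row-percentages (``adjustment_method`` records this).  The
    misincorporated percentage is the complement of the prevalent one.
    """

    counts: pd.DataFrame  # prevalent library x source library, raw counts
    raw_percent: pd.DataFrame
    adjusted_percent: Optional[pd.DataFrame]
    misincorporated_percent: pd.Series  # raw scale
    adjusted_misincorporated_percent: Optional[pd.Series]
    adjustment_method: Optional[str]

    def validate(self) -> None:
        for _, row in self.raw_percent.iterrows():
            if abs(row.sum() - 100.0) > 0.02:
                raise AssertionError("raw row percentages do not sum to 100")


def misincorporation_table(
    classifications: Sequence[ContigClassification],
    library_sizes: Optional[Mapping[str, int]] = None,
    adjust: bool = False,
) -> MisincorporationTable:
    """Aggregate contig classifications into the misincorporation table."""
    if not classifications:
        raise ValueError("no classified contigs")
    libraries = sorted(
        {c.prevalent_library for c in classifications}
        | {lib for c in classifications for lib in c.counts}
    )
    counts = pd.DataFrame(0, index=libraries, columns=libraries, dtype=int)
    for c in classifications:
        for lib, k in c.counts.items():
            counts.loc[c.prevalent_library, lib] += k
    counts = counts.loc[counts.sum(axis=1) > 0]

    raw = counts.div(counts.sum(axis=1), axis=0) * 100.0
    raw = raw.round(2)
    mis = (100.0 - pd.Series(np.diag(raw.loc[:, raw.index]), index=raw.index)).round(2)

    adjusted = adj_mis = method = None
    if adjust:
        if library_sizes is None:
            raise ValueError("library_sizes required for adjusted percentages")
        for lib in counts.columns:
            if library_sizes.get(lib, 0) <= 0:
                raise ValueError(f"library size for {lib!r} must be positive")
        scaled = counts.astype(float).copy()
        for prev in scaled.index:
            for src in scaled.columns:
                scaled.loc[prev, src] *= library_sizes[prev] / library_sizes[src]
        adjusted = (scaled.div(scaled.sum(axis=1), axis=0) * 100.0).round(2)
        adj_mis = (
            100.0 - pd.Series(np.diag(adjusted.loc[:, adjusted.index]), index=adjusted.index)
        ).round(2)
        method = "count * prevalent_library_size / source_library_size, then row-percentaged"

    table = MisincorporationTable(counts, raw, adjusted, mis, adj_mis, method)
    table.validate()
    return table


@dataclass
class ExpectedContamination:
    contamination_rate: float  # percent
    total_arms: int
    n_homoeologous_arms: int

    @property
    def expected_percent(self) -> float:
        return expected_contamination(
            self.contamination_rate, self.total_arms, self.n_homoeologous_arms
        )


def expected_contamination(rate: float, total_arms: int, n_homoeo: int) -> float:
    """Expected percentage of homoeologous-arm clones in a flow-sorted
    library: contamination rate x homoeologous arms / total arms (percent,
    2 decimals)."""
    if total_arms <= 0:
        raise ValueError("total_arms must be > 0")
    return round(rate * n_homoeo / total_arms, 2)


def singleton_crosscheck(
    misincorporated: Sequence[Tuple[str, str, str]],
    individual_results: Mapping[str, AssemblyResult],
) -> pd.DataFrame:
    """Fraction of misincorporated clones that were singletons in their own
    or the prevalent library's individual assembly.

    ``misincorporated`` rows are (clone_id, source_library, prevalent_library).
    Contaminating clones from other chromosomes are expected to overlap
    nothing in their own library and thus to have been singletons there.
    """
    rows: Dict[str, Dict[str, int]] = {}
    for clone_id, source_lib, prevalent_lib in misincorporated:
        rec = rows.setdefault(
            prevalent_lib, {"n": 0, "singleton": 0, "not_assessable": 0}
        )
        rec["n"] += 1
        assessable = False
        is_singleton = False
        for lib in (source_lib, prevalent_lib):
            res = individual_results.get(lib)
            if res is None:
                continue
            membership = res.membership()
            if clone_id in membership:
                assessable = True
                if membership[clone_id] is None:
                    is_singleton = True
        if not assessable:
            rec["not_assessable"] += 1
        elif is_singleton:
            rec["singleton"] += 1
    out = []
    for lib in sorted(rows):
        rec = rows[lib]
        assessable = rec["n"] - rec["not_assessable"]
        out.append(
            {
                "prevalent_library": lib,
                "n_misincorporated": rec["n"],
                "n_singleton_in_individual": rec["singleton"],
                "n_not_assessable": rec["not_assessable"],
                "fraction_singleton": (
                    rec["singleton"] / assessable if assessable else float("nan")
                ),
            }
        )
    return pd.DataFrame(
        out,
        columns=[
            "prevalent_library",
            "n_misincorporated",
            "n_singleton_in_individual",
            "n_not_assessable",
            "fraction_singleton",
        ],
    )


def _observed_vs_designed(
    counts: pd.DataFrame,
    library_sizes: Mapping[str, int],
    rate_of: Mapping[str, float],
    n_nontarget_arms: int,
) -> pd.DataFrame:
    """Per-row misincorporation with a 95% binomial CI against the designed
    homoeolog-contamination fraction of the sampling scheme."""
    rows = []
    for prev in counts.index:
        row = counts.loc[prev]
        n_total = int(row.sum())
        k_mis = int(n_total - row.get(prev, 0))
        expected_count = sum(
            library_sizes.get(lib, 0) * rate_of.get(lib, 0.0) / n_nontarget_arms
            for lib in library_sizes
            if lib != prev
        )
        designed = expected_count / n_total if n_total else 0.0
        ci = binomtest(k_mis, max(n_total, 1)).proportion_ci(confidence_level=0.95)
        rows.append(
            {
                "prevalent_library": prev,
                "n_contig_clones": n_total,
                "n_misincorporated": k_mis,
                "observed_percent": round(100.0 * k_mis / n_total, 2) if n_total else 0.0,
                "designed_percent": round(100.0 * designed, 2),
                "ci_low_percent": round(100.0 * ci.low, 2),
                "ci_high_percent": round(100.0 * ci.high, 2),
                "designed_within_ci": bool(ci.low <= designed <= ci.high),
            }
        )
    return pd.DataFrame(rows)


def pool_observed_vs_expected(reports: Sequence["FeasibilityReport"]) -> pd.DataFrame:
    """Pool misincorporation counts of replicate experiments (one per seed)
    and recompute the per-row binomial CI against the pooled designed
    fraction."""
    if not reports:
        raise ValueError("no reports to pool")
    pooled_counts: Optional[pd.DataFrame] = None
    sizes: Dict[str, int] = {}
    rate_of: Dict[str, float] = {}
    n_nontarget = None
    for rep in reports:
        c = rep.misincorporation_raw.counts
        pooled_counts = c if pooled_counts is None else pooled_counts.add(c, fill_value=0)
        for lp in rep.config.libraries:
            rate_of[lp.library_name] = lp.contamination_rate
        for name, fps_n in (
            rep.library_summaries.set_index("library")["n_clones_after_editing"]
            .drop(["Total", "Merged library"], errors="ignore")
            .items()
        ):
            sizes[name] = sizes.get(name, 0) + int(fps_n)
        n_nontarget = rep.config.sim.n_homoeologs - 1 + rep.config.sim.n_decoy_arms
    pooled_counts = pooled_counts.fillna(0).astype(int)
    return _observed_vs_designed(pooled_counts, sizes, rate_of, max(n_nontarget, 1))


# ---------------------------------------------------------------------------
# the full simulated feasibility experiment
# ---------------------------------------------------------------------------


@dataclass
class ExperimentConfig:
    """Study conditions of the simulated feasibility experiment.

    Defaults follow the wheat chromosome-3 setting: three homoeologous arms
    with fully turned-over intergenic space and 3% gene divergence, three
    single-arm libraries with ~10-11.4% flow-sorting contamination and
    insert sizes of 80/103/110 kb, in a 40-arm karyotype context.
    """

    sim: SimParams = field(default_factory=SimParams)
    libraries: Tuple[LibraryParams, ...] = ()
    edit: EditParams = field(default_factory=EditParams)
    assembly: AssemblyParams = field(default_factory=AssemblyParams)
    noise_sd: float = DEFAULT_NOISE_SD
    min_clones_table: int = 4
    seed: int = 0

    @classmethod
    def default(cls, seed: int = 0, **sim_overrides) -> "ExperimentConfig":
        sim = SimParams(seed=seed, **sim_overrides)
        libraries = (
            LibraryParams("3AS", "ancestor_A", 600, 80_000.0, 10_000.0, 0.110, seed),
            LibraryParams("3B", "ancestor_B", 400, 103_000.0, 12_000.0, 0.114, seed),
            LibraryParams("3DS", "ancestor_D", 500, 110_000.0, 13_000.0, 0.100, seed),
        )
        # The simulator does not model well-to-well DNA carry-over, and at
        # scaled-down arm length the cross-contamination screen's nested-clone
        # false-positive rate would dominate, so the screen is off here.
        edit = EditParams(screen_cross_contamination=False)
        return cls(sim=sim, libraries=libraries, edit=edit, seed=seed)


@dataclass
class FeasibilityReport:
    config: ExperimentConfig
    library_summaries: pd.DataFrame
    merged_result: AssemblyResult
    individual_results: Dict[str, AssemblyResult]
    misincorporation_raw: MisincorporationTable
    misincorporation_adjusted: MisincorporationTable
    n_ambiguous_contigs: int
    expected_contamination: pd.DataFrame
    observed_vs_expected: pd.DataFrame
    singleton_crosscheck: pd.DataFrame
    library_of: Dict[str, str]
    true_contaminant: Dict[str, bool]
    merged_fingerprints: List[Fingerprint] = field(default_factory=list)


def _derived_seeds(seed: int, n: int) -> List[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def run_feasibility_experiment(config: Optional[ExperimentConfig] = None) -> FeasibilityReport:
    """Simulate, fingerprint, edit, assemble (individually and merged) and
    tabulate misincorporation with its expected baseline."""
    config = config or ExperimentConfig.default()
    sim = config.sim
    sim.validate()
    if not config.libraries:
        raise ValueError("experiment needs at least one library")

    n_lib = len(config.libraries)
    seeds = _derived_seeds(config.seed, 3 + sim.n_decoy_arms + 2 * n_lib)
    arm_seed, div_seed, _ = seeds[0], seeds[1], seeds[2]
    decoy_seeds = seeds[3 : 3 + sim.n_decoy_arms]
    lib_seeds = seeds[3 + sim.n_decoy_arms : 3 + sim.n_decoy_arms + n_lib]
    fp_seeds = seeds[3 + sim.n_decoy_arms + n_lib :]

    ancestor = generate_arm(sim, genome_label="anc", rng_seed=arm_seed, arm_id="ancestor")
    homoeologs = diverge_homoeologs(ancestor, sim, rng_seed=div_seed)
    # decoy arms model unrelated chromosomes in the karyotype: random
    # sequence of the same length (their gene content is irrelevant here)
    decoy_sim = SimParams(
        arm_length=sim.arm_length, gene_density=0.0, n_homoeologs=sim.n_homoeologs
    )
    decoys = [
        generate_arm(decoy_sim, genome_label="X", rng_seed=s, arm_id=f"decoy_{i:02d}")
        for i, s in enumerate(decoy_seeds)
    ]
    all_arms = arms_by_id(list(homoeologs) + decoys)

    edited: Dict[str, List[Fingerprint]] = {}
    true_contaminant: Dict[str, bool] = {}
    for lp, lseed, fseed in zip(config.libraries, lib_seeds, fp_seeds):
        lp = LibraryParams(
            lp.library_name,
            lp.target_arm,
            lp.n_clones,
            lp.insert_mean,
            lp.insert_sd,
            lp.contamination_rate,
            seed=lseed,
        )
        clones = sample_library(homoeologs, decoys, lp)
        for c in clones:
            true_contaminant[c.clone_id] = c.is_contaminant
        fps = fingerprint_library(clones, all_arms, noise_sd=config.noise_sd, seed=fseed)
        kept, _ = edit_fingerprints(fps, config.edit)
        edited[lp.library_name] = kept

    individual_results = {
        name: assemble_pipeline(fps, config.assembly) for name, fps in sorted(edited.items())
    }
    merged_fps, library_sizes = merge_libraries(edited)
    merged_result = assemble_pipeline(merged_fps, config.assembly)

    summaries = [
        library_summary(name, len(edited[name]), individual_results[name])
        for name in sorted(edited)
    ]
    merged_summary = LibrarySummary(
        "Merged library",
        len(merged_fps),
        merged_result.n_contigs,
        merged_result.n_singletons,
    )
    summary_df = summarize_assemblies(summaries, merged_summary)

    library_of = {fp.clone_id: fp.library_name for fp in merged_fps}
    classifications, n_ambiguous = classify_contigs(
        merged_result, library_of, min_clones=config.min_clones_table
    )
    mis_raw = misincorporation_table(classifications, library_sizes, adjust=False)
    mis_adj = misincorporation_table(classifications, library_sizes, adjust=True)

    # expected baseline (karyotype arithmetic) and the sampling design
    n_homoeo_other = sim.n_homoeologs - 1
    exp_rows = []
    for lp in config.libraries:
        exp_rows.append(
            {
                "library": lp.library_name,
                "contamination_rate_pct": 100.0 * lp.contamination_rate,
                "total_arms": sim.total_arms_in_genome,
                "n_homoeologous_arms": n_homoeo_other,
                "expected_percent": expected_contamination(
                    100.0 * lp.contamination_rate,
                    sim.total_arms_in_genome,
                    n_homoeo_other,
                ),
            }
        )
    expected_df = pd.DataFrame(exp_rows)

    # observed vs designed: binomial CI on the misincorporated count per row.
    # The expected number of foreign clones in row R's contigs is the number
    # of clones in the *other* libraries whose true source is R's target arm:
    # each contaminant picks R's arm with probability 1/n_nontarget_arms.
    n_nontarget = n_homoeo_other + sim.n_decoy_arms
    rate_of = {lp.library_name: lp.contamination_rate for lp in config.libraries}
    ove_df = _observed_vs_designed(
        mis_raw.counts, library_sizes, rate_of, max(n_nontarget, 1)
    )

    # singleton cross-check over the misincorporated clones
    mis_clones = []
    for c in classifications:
        if c.prevalent_library == "ambiguous":
            continue
        contig = merged_result.contigs[c.contig_id]
        for m in contig.members:
            if library_of[m] != c.prevalent_library:
                mis_clones.append((m, library_of[m], c.prevalent_library))
    crosscheck = singleton_crosscheck(mis_clones, individual_results)

    return FeasibilityReport(
        config=config,
        library_summaries=summary_df,
        merged_result=merged_result,
        individual_results=individual_results,
        misincorporation_raw=mis_raw,
        misincorporation_adjusted=mis_adj,
        n_ambiguous_contigs=n_ambiguous,
        expected_contamination=expected_df,
        observed_vs_expected=ove_df,
        singleton_crosscheck=crosscheck,
        library_of=library_of,
        true_contaminant=true_contaminant,
        merged_fingerprints=merged_fps,
    )
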