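"""Synthetic allopolyploid chromosome arms, BAC libraries and HICF fingerprints.

The generator emulates the situation in which restriction-fingerprint contig
assembly of an allopolyploid is feasible at all: homoeologous chromosome arms
whose (sparse) genes are weakly diverged point-wise, while the transposon-rich
intergenic space has been wholesale replaced between genomes.  Libraries are
built from flow-sorted single arms and therefore carry a known percentage of
contaminating clones from other, non-homoeologous chromosome arms.

Fingerprinting follows the five-enzyme SNaPshot HICF protocol: simultaneous
digestion with BamHI, EcoRI, XbaI, XhoI (labeled) and HaeIII (blunt,
unlabeled), with every labeled fragment end contributing one band in the
corresponding dye channel, plus sub-bp Gaussian sizing noise.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.stats import truncnorm

from .fingerprints import Band, Fingerprint, LABELED_ENZYMES

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class Enzyme:
    name: str
    site: str
    cut_offset: int  # cut after this many bases of the site
    labeled: bool


#: The five SNaPshot HICF enzymes with their published cut positions.
#: BamHI G^GATCC, EcoRI G^AATTC, XbaI T^CTAGA, XhoI C^TCGAG, HaeIII GG^CC.
ENZYMES: tuple[Enzyme, ...] = (
    Enzyme("BamHI", "GGATCC", 1, True),
    Enzyme("EcoRI", "GAATTC", 1, True),
    Enzyme("XbaI", "TCTAGA", 1, True),
    Enzyme("XhoI", "CTCGAG", 1, True),
    Enzyme("HaeIII", "GGCC", 2, False),
)


@dataclass
class SimParams:
    """Genome-simulation parameters.

    arm_length            length of each homoeologous arm, bp
    gene_density          genes per Mbp
    gene_length_mean      mean gene length, bp
    n_homoeologs          number of homoeologous arms sharing the gene set
    gene_divergence       substitutions/site between any two homoeologs' genes
    intergenic_turnover   probability an intergenic block is replaced by fresh
                          sequence in each homoeolog (1.0 = full turnover)
    n_decoy_arms          unrelated arms serving as contamination source
    total_arms_in_genome  karyotype context used for expected-contamination
                          arithmetic (e.g. 40 arms in hexaploid wheat with a
                          telosome, 41 with the extra telosome)
    """

    arm_length: int = 2_000_000
    gene_density: float = 10.0
    gene_length_mean: float = 3_000.0
    n_homoeologs: int = 3
    gene_divergence: float = 0.03
    intergenic_turnover: float = 1.0
    n_decoy_arms: int = 37
    total_arms_in_genome: int = 40
    seed: int = 0

    def validate(self) -> None:
        if self.arm_length <= 0:
            raise ValueError("arm_length must be > 0")
        if self.gene_length_mean <= 0:
            raise ValueError("gene_length_mean must be > 0")
        if self.gene_density < 0:
            raise ValueError("gene_density must be >= 0")
        if not 0.0 <= self.gene_divergence <= 0.25:
            raise ValueError("gene_divergence must be in [0, 0.25]")
        if not 0.0 <= self.intergenic_turnover <= 1.0:
            raise ValueError("intergenic_turnover must be in [0, 1]")
        if self.n_homoeologs < 1:
            raise ValueError("n_homoeologs must be >= 1")
        if self.n_decoy_arms < 0 or self.total_arms_in_genome < 1:
            raise ValueError("arm counts must be positive")


@dataclass
class ChromosomeArm:
    """One simulated chromosome arm: sequence plus annotated gene intervals."""

    arm_id: str
    genome_label: str
    sequence: str
    gene_intervals: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        L = len(self.sequence)
        prev_end = 0
        for start, end in self.gene_intervals:
            if not (0 <= start < end <= L):
                raise ValueError(f"gene interval ({start}, {end}) outside arm of length {L}")
            if start < prev_end:
                raise ValueError("gene intervals overlap")
            prev_end = end

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class LibraryParams:
    library_name: str
    target_arm: str
    n_clones: int = 500
    insert_mean: float = 100_000.0
    insert_sd: float = 12_000.0
    contamination_rate: float = 0.10
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.contamination_rate < 1.0:
            raise ValueError("contamination_rate must be in [0, 1)")
        if self.insert_mean <= 0:
            raise ValueError("insert_mean must be > 0")
        if self.n_clones < 0:
            raise ValueError("n_clones must be >= 0")


@dataclass(frozen=True)
class BACClone:
    clone_id: str
    library_name: str
    true_source_arm: str
    start: int
    insert_length: int
    is_contaminant: bool


@dataclass(frozen=True)
class Fragment:
    """Maximal uncut interval of a digested sequence.

    ``left_enzyme``/``right_enzyme`` name the enzyme whose cut created each
    end; None marks a clone terminus (unlabeled).
    """

    start: int
    end: int
    left_enzyme: Optional[str]
    right_enzyme: Optional[str]

    @property
    def length(self) -> int:
        return self.end - self.start


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    codes = rng.integers(0, 4, size=length, dtype=np.uint8)
    return _BASES[codes].tobytes().decode("ascii")


def _genome_labels(n: int) -> list[str]:
    # wheat convention for three genomes; plain letters otherwise
    if n <= 3:
        return ["A", "B", "D"][:n]
    return list(string.ascii_uppercase[:n])


def generate_arm(
    params: SimParams,
    genome_label: str = "A",
    rng_seed: Optional[int] = None,
    arm_id: Optional[str] = None,
) -> ChromosomeArm:
    """Generate one arm: uniform random sequence with non-overlapping genes.

    Gene count is gene_density x arm_length (in Mbp); gene lengths are drawn
    from a gamma distribution (shape 4) around gene_length_mean and placed
    uniformly without overlap by distributing the leftover intergenic space.
    """
    params.validate()
    rng = np.random.default_rng(params.seed if rng_seed is None else rng_seed)
    L = params.arm_length
    n_genes = int(round(params.gene_density * L / 1e6))
    sequence = _random_sequence(rng, L)

    intervals: list[tuple[int, int]] = []
    if n_genes > 0:
        shape = 4.0
        lengths = np.maximum(
            rng.gamma(shape, params.gene_length_mean / shape, size=n_genes), 200.0
        ).astype(np.int64)
        free = L - int(lengths.sum())
        if free < n_genes:  # need at least ~1 bp of intergenic spacing
            raise ValueError(
                f"gene density too high: {n_genes} genes totalling {int(lengths.sum())} bp "
                f"cannot be placed without overlap on a {L} bp arm"
            )
        # stick-breaking: split the free space into n_genes+1 gaps
        cuts = np.sort(rng.integers(0, free + 1, size=n_genes))
        gaps = np.diff(np.concatenate(([0], cuts)))
        pos = 0
        for gap, glen in zip(gaps, lengths):
            pos += int(gap)
            intervals.append((pos, pos + int(glen)))
            pos += int(glen)
    return ChromosomeArm(
        arm_id=arm_id or f"arm_{genome_label}",
        genome_label=genome_label,
        sequence=sequence,
        gene_intervals=tuple(intervals),
    )


def _mutate(seq_codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Point-substitute each position with probability ``rate`` (to a different base)."""
    if rate <= 0:
        return seq_codes
    out = seq_codes.copy()
    hits = np.nonzero(rng.random(out.size) < rate)[0]
    if hits.size:
        # add 1..3 mod 4: always a different base
        out[hits] = (out[hits] + rng.integers(1, 4, size=hits.size, dtype=np.uint8)) % 4
    return out


_CODE_OF = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE_OF[_b] = _i


def _to_codes(sequence: str) -> np.ndarray:
    codes = _CODE_OF[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    if (codes == 255).any():
        raise ValueError("sequence contains characters outside {A,C,G,T}")
    return codes


def _to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def diverge_homoeologs(
    ancestor: ChromosomeArm,
    params: SimParams,
    rng_seed: Optional[int] = None,
) -> list[ChromosomeArm]:
    """Derive n_homoeologs arms from a common ancestor.

    Genes keep their ancestral coordinates and are point-mutated in each
    homoeolog at half the pairwise gene_divergence (so any two homoeologs
    differ at ~gene_divergence substitutions/site).  Each intergenic block is
    independently replaced by fresh random sequence of the same length with
    probability intergenic_turnover, modelling the wholesale turnover of
    transposon space; otherwise it is inherited unchanged.
    """
    params.validate()
    if params.n_homoeologs < 2:
        raise ValueError("n_homoeologs must be >= 2 to diverge homoeologs")
    rng = np.random.default_rng(params.seed + 1 if rng_seed is None else rng_seed)
    codes = _to_codes(ancestor.sequence)
    L = len(codes)
    # intergenic blocks: complement of the gene intervals
    blocks: list[tuple[int, int]] = []
    pos = 0
    for start, end in ancestor.gene_intervals:
        if start > pos:
            blocks.append((pos, start))
        pos = end
    if pos < L:
        blocks.append((pos, L))

    per_homoeolog_rate = params.gene_divergence / 2.0
    arms = []
    for label in _genome_labels(params.n_homoeologs):
        out = codes.copy()
        for start, end in ancestor.gene_intervals:
            out[start:end] = _mutate(codes[start:end], per_homoeolog_rate, rng)
        for start, end in blocks:
            if rng.random() < params.intergenic_turnover:
                out[start:end] = rng.integers(0, 4, size=end - start, dtype=np.uint8)
        arms.append(
            ChromosomeArm(
                arm_id=f"{ancestor.arm_id}_{label}",
                genome_label=label,
                sequence=_to_str(out),
                gene_intervals=ancestor.gene_intervals,
            )
        )
    return arms


def sample_library(
    arms: Sequence[ChromosomeArm],
    decoy_arms: Sequence[ChromosomeArm],
    lp: LibraryParams,
) -> list[BACClone]:
    """Draw a BAC library from a flow-sorted target arm with contamination.

    Each clone is a contaminant with probability ``contamination_rate``; its
    source is then uniform over all non-target arms (homoeologous and decoy
    alike), emulating flow-sorting impurity in which every other chromosome
    arm is an equally likely contaminant.  Insert lengths follow a normal
    distribution truncated at [0.2, 3] x insert_mean; starts are uniform.
    """
    lp.validate()
    targets = [a for a in arms if a.arm_id == lp.target_arm]
    if not targets:
        raise ValueError(f"target arm {lp.target_arm!r} not found")
    target = targets[0]
    others = [a for a in arms if a.arm_id != lp.target_arm] + list(decoy_arms)
    if lp.contamination_rate > 0 and not others:
        raise ValueError("contamination_rate > 0 requires a non-empty decoy/homoeolog pool")

    rng = np.random.default_rng(lp.seed)
    lo, hi = 0.2 * lp.insert_mean, 3.0 * lp.insert_mean
    a = (lo - lp.insert_mean) / lp.insert_sd
    b = (hi - lp.insert_mean) / lp.insert_sd
    lengths = truncnorm.rvs(
        a, b, loc=lp.insert_mean, scale=lp.insert_sd, size=lp.n_clones, random_state=rng
    ).astype(np.int64)
    contaminant = rng.random(lp.n_clones) < lp.contamination_rate
    source_idx = rng.integers(0, max(len(others), 1), size=lp.n_clones)
    starts_u = rng.random(lp.n_clones)

    clones = []
    for i in range(lp.n_clones):
        src = others[int(source_idx[i])] if contaminant[i] else target
        ins = int(lengths[i])
        if ins > len(src):
            raise ValueError(
                f"insert of {ins} bp exceeds arm {src.arm_id} ({len(src)} bp)"
            )
        start = int(starts_u[i] * (len(src) - ins + 1))
        clones.append(
            BACClone(
                clone_id=f"{lp.library_name}_{i:05d}",
                library_name=lp.library_name,
                true_source_arm=src.arm_id,
                start=start,
                insert_length=ins,
                is_contaminant=bool(contaminant[i]),
            )
        )
    return clones


def digest(sequence: str) -> list[Fragment]:
    """Cut a sequence with all five HICF enzymes simultaneously.

    Returns the maximal uncut fragments with each end annotated by the
    enzyme that created it (None = terminal end).  Overlapping site
    occurrences are all honoured; in the (rare) event that two enzymes cut
    at the same phosphodiester position the enzyme earlier in ENZYMES wins.
    """
    if not sequence:
        return []
    cuts: dict[int, str] = {}
    for enz in ENZYMES:
        pos = sequence.find(enz.site)
        while pos != -1:
            cut = pos + enz.cut_offset
            if 0 < cut < len(sequence) and cut not in cuts:
                cuts[cut] = enz.name
            pos = sequence.find(enz.site, pos + 1)
    boundaries = sorted(cuts)
    frags = []
    prev, prev_enz = 0, None
    for cut in boundaries:
        frags.append(Fragment(prev, cut, prev_enz, cuts[cut]))
        prev, prev_enz = cut, cuts[cut]
    frags.append(Fragment(prev, len(sequence), prev_enz, None))
    return frags


_LABELED = {e.name for e in ENZYMES if e.labeled}

#: Default capillary sizing noise (bp, 1 sd) and its truncation bound.
DEFAULT_NOISE_SD = 0.08
NOISE_CLIP = 0.4


def fingerprint_clone(
    clone: BACClone,
    arms: Mapping[str, ChromosomeArm],
    noise_sd: float = DEFAULT_NOISE_SD,
    rng: Optional[np.random.Generator] = None,
    rng_seed: Optional[int] = None,
    double_label_mode: str = "both",
    plate: Optional[str] = None,
) -> Fingerprint:
    """Digest a clone insert and emit one band per labeled fragment end.

    A fragment whose two ends were both created by labeled enzymes yields two
    bands of the same size, one in each end's dye channel (SNaPshot labels
    each cut end independently); set ``double_label_mode="first"`` to emit a
    single band in the first channel instead.  Observed sizes are the true
    fragment length plus Gaussian noise (sd ``noise_sd``, truncated at
    +-0.4 bp).  Out-of-window bands are retained here; editing removes them.
    """
    if double_label_mode not in ("both", "first"):
        raise ValueError("double_label_mode must be 'both' or 'first'")
    arm = arms[clone.true_source_arm]
    if not (0 <= clone.start and clone.start + clone.insert_length <= len(arm)):
        raise ValueError(f"clone {clone.clone_id} interval outside arm {arm.arm_id}")
    if rng is None:
        rng = np.random.default_rng(rng_seed)
    insert = arm.sequence[clone.start : clone.start + clone.insert_length]
    emit: list[tuple[int, str]] = []
    for frag in digest(insert):
        channels = [e for e in (frag.left_enzyme, frag.right_enzyme) if e in _LABELED]
        if double_label_mode == "first" and len(channels) == 2:
            channels = channels[:1]
        emit.extend((frag.length, ch) for ch in channels)
    if noise_sd > 0 and emit:
        noise = np.clip(rng.normal(0.0, noise_sd, size=len(emit)), -NOISE_CLIP, NOISE_CLIP)
    else:
        noise = np.zeros(len(emit))
    bands = [
        Band(size=length + eps, channel=ch, true_size=float(length))
        for (length, ch), eps in zip(emit, noise.tolist())
        if length + eps > 0
    ]
    return Fingerprint(clone.clone_id, clone.library_name, tuple(bands), plate=plate)


def fingerprint_library(
    clones: Sequence[BACClone],
    arms: Mapping[str, ChromosomeArm],
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
    double_label_mode: str = "both",
    plate_size: int = 96,
) -> list[Fingerprint]:
    """Fingerprint every clone with an independent, reproducible noise stream.

    Clones are assigned to microtiter plates of ``plate_size`` wells in
    order, providing the plate metadata cross-contamination screening needs.
    """
    seeds = np.random.SeedSequence(seed).spawn(len(clones))
    return [
        fingerprint_clone(
            clone,
            arms,
            noise_sd=noise_sd,
            rng=np.random.default_rng(s),
            double_label_mode=double_label_mode,
            plate=f"{clone.library_name}_p{i // plate_size:03d}",
        )
        for i, (clone, s) in enumerate(zip(clones, seeds))
    ]


def coverage(n_clones: int, avg_insert: float, chrom_size: float) -> float:
    """Fold chromosome coverage of a library, rounded to one decimal."""
    if chrom_size <= 0:
        raise ValueError("chrom_size must be > 0")
    return round(n_clones * avg_insert / chrom_size, 1)


def arms_by_id(arms: Iterable[ChromosomeArm]) -> dict[str, ChromosomeArm]:
    return {a.arm_id: a for a in arms}
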