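"""File formats: FPC-style .sizes band files, TSV tables, FASTA/BED output,
configuration and run manifests.

The ``channel_offset`` .sizes dialect packs dye channel and 0.1 bp size
resolution into the single integer per band that FPC-style band files carry:
``value = channel_rank * channel_offset_step + round(size * size_scale)``.
The ``plain`` dialect is the classic single-channel file of integer sizes.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .assembly import AssemblyParams, AssemblyResult, Contig
from .editing import EditParams, EditReport
from .fingerprints import Band, Fingerprint, LABELED_ENZYMES, channel_rank
from .simulate import BACClone, ChromosomeArm, LibraryParams, SimParams


@dataclass(frozen=True)
class SizesDialect:
    encoding: str = "channel_offset"  # "plain" or "channel_offset"
    channel_offset_step: int = 20000
    size_scale: int = 10  # 10 = 0.1 bp resolution

    def __post_init__(self) -> None:
        if self.encoding not in ("plain", "channel_offset"):
            raise ValueError(f"unknown .sizes encoding {self.encoding!r}")
        if self.channel_offset_step <= self.size_scale * 1000:
            raise ValueError("channel_offset_step must exceed size_scale * 1000")


PLAIN = SizesDialect(encoding="plain")
CHANNEL_OFFSET = SizesDialect(encoding="channel_offset")


def _detect_dialect(values: Sequence[int], dialect: Optional[SizesDialect]) -> SizesDialect:
    if dialect is not None:
        return dialect
    step = CHANNEL_OFFSET.channel_offset_step
    return CHANNEL_OFFSET if values and max(values) >= step else PLAIN


def read_sizes(
    path: Union[str, Path],
    dialect: Optional[SizesDialect] = None,
    library_name: Optional[str] = None,
) -> List[Fingerprint]:
    """Parse a .sizes band file: repeated records of a ``clone_name n_bands``
    header line followed by ``n_bands`` integer lines.  With no explicit
    dialect the encoding is auto-detected from the maximum band value."""
    path = Path(path)
    library = library_name if library_name is not None else path.stem
    records: List[Tuple[str, List[int]]] = []
    with open(path) as fh:
        lines = [ln.strip() for ln in fh]
    i = 0
    lineno = 0
    n_lines = len(lines)
    while i < n_lines:
        lineno = i + 1
        if not lines[i]:
            i += 1
            continue
        parts = lines[i].split()
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 'clone_name n_bands' header")
        name, n_str = parts
        try:
            n_bands = int(n_str)
        except ValueError:
            raise ValueError(f"{path}:{lineno}: non-numeric band count for {name!r}") from None
        vals: List[int] = []
        i += 1
        while len(vals) < n_bands and i < n_lines:
            if lines[i]:
                try:
                    vals.append(int(lines[i]))
                except ValueError:
                    raise ValueError(
                        f"{path}:{i + 1}: non-numeric band value for clone {name!r}"
                    ) from None
            i += 1
        if len(vals) != n_bands:
            raise ValueError(
                f"{path}:{lineno}: clone {name!r} declares {n_bands} bands, found {len(vals)}"
            )
        records.append((name, vals))

    all_values = [v for _, vals in records for v in vals]
    dia = _detect_dialect(all_values, dialect)
    fps = []
    for name, vals in records:
        bands = []
        for v in vals:
            if dia.encoding == "channel_offset":
                ch_idx, raw = divmod(v, dia.channel_offset_step)
                if ch_idx >= len(LABELED_ENZYMES):
                    raise ValueError(f"{path}: channel index {ch_idx} out of range in {name!r}")
                bands.append(Band(size=raw / dia.size_scale, channel=LABELED_ENZYMES[ch_idx]))
            else:
                bands.append(Band(size=float(v), channel=None))
        fps.append(Fingerprint(name, library, tuple(bands)))
    return fps


def write_sizes(
    fps: Sequence[Fingerprint],
    path: Union[str, Path],
    dialect: SizesDialect = CHANNEL_OFFSET,
) -> None:
    """Write fingerprints as a .sizes file; round-trips with read_sizes.

    Plain encoding is single-channel and refuses channel-labeled data
    (the write would be lossy)."""
    path = Path(path)
    lines: List[str] = []
    for fp in sorted(fps, key=lambda f: f.clone_id):
        values = []
        for band in fp.bands:
            if dialect.encoding == "plain":
                if band.channel is not None:
                    raise ValueError(
                        f"plain .sizes cannot represent channel-labeled band of {fp.clone_id!r}"
                    )
                values.append(int(round(band.size)))
            else:
                scaled = int(round(band.size * dialect.size_scale))
                if scaled >= dialect.channel_offset_step:
                    raise ValueError(
                        f"band size {band.size} of {fp.clone_id!r} overflows the "
                        f"channel_offset dialect (max {dialect.channel_offset_step / dialect.size_scale})"
                    )
                values.append(channel_rank(band.channel) * dialect.channel_offset_step + scaled)
        lines.append(f"{fp.clone_id} {len(values)}")
        lines.extend(str(v) for v in sorted(values))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

FINGERPRINT_COLUMNS = ["clone_id", "library", "channel", "size_bp"]
MEMBERSHIP_COLUMNS = ["clone_id", "library", "contig_id", "q_flag", "stage"]


def fingerprints_to_frame(fps: Sequence[Fingerprint]) -> pd.DataFrame:
    rows = [
        {
            "clone_id": fp.clone_id,
            "library": fp.library_name,
            "channel": b.channel if b.channel is not None else "",
            "size_bp": round(b.size, 4),
        }
        for fp in sorted(fps, key=lambda f: f.clone_id)
        for b in fp.bands
    ]
    return pd.DataFrame(rows, columns=FINGERPRINT_COLUMNS)


def write_fingerprints_tsv(fps: Sequence[Fingerprint], path: Union[str, Path]) -> None:
    fingerprints_to_frame(fps).to_csv(path, sep="\t", index=False)


def read_fingerprints_tsv(path: Union[str, Path]) -> List[Fingerprint]:
    df = pd.read_csv(path, sep="\t", dtype={"clone_id": str, "library": str})
    missing = [c for c in FINGERPRINT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing fingerprint TSV column(s): {missing}")
    if len(df) and not pd.api.types.is_numeric_dtype(df["size_bp"]):
        raise ValueError(f"{path}: size_bp column must be numeric")
    fps = []
    for (clone_id, library), group in df.groupby(["clone_id", "library"], sort=True):
        bands = tuple(
            Band(
                size=float(r.size_bp),
                channel=None if pd.isna(r.channel) or r.channel == "" else str(r.channel),
            )
            for r in group.itertuples()
        )
        fps.append(Fingerprint(str(clone_id), str(library), bands))
    return fps


def membership_to_frame(result: AssemblyResult, library_of: Mapping[str, str]) -> pd.DataFrame:
    rows = []
    membership = result.membership()
    for clone_id in sorted(membership):
        cid = membership[clone_id]
        q = False
        stage = result.stage_joined.get(clone_id, "")
        if cid is not None:
            q = bool(result.contigs[cid].q_flags.get(clone_id, False)) if result.contigs[cid].q_flags else False
        rows.append(
            {
                "clone_id": clone_id,
                "library": library_of.get(clone_id, ""),
                "contig_id": cid if cid is not None else "singleton",
                "q_flag": int(q),
                "stage": stage if cid is not None else "",
            }
        )
    return pd.DataFrame(rows, columns=MEMBERSHIP_COLUMNS)


def write_membership_tsv(
    result: AssemblyResult, library_of: Mapping[str, str], path: Union[str, Path]
) -> None:
    membership_to_frame(result, library_of).to_csv(path, sep="\t", index=False)


def read_membership_tsv(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"clone_id": str, "library": str, "contig_id": str})
    missing = [c for c in MEMBERSHIP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing membership TSV column(s): {missing}")
    return df


def membership_frame_to_result(df: pd.DataFrame) -> AssemblyResult:
    """Reconstruct a membership-only AssemblyResult from a membership table
    (contig members and singletons; no scores, orders or consensus)."""
    contigs: Dict[str, Contig] = {}
    singletons: List[str] = []
    params = AssemblyParams()
    for cid, group in df.groupby("contig_id", sort=True):
        clones = sorted(group["clone_id"].astype(str))
        if cid == "singleton":
            singletons.extend(clones)
        else:
            contigs[str(cid)] = Contig(str(cid), tuple(clones), params.initial_cutoff)
    return AssemblyResult(
        contigs,
        sorted(singletons),
        params,
        clone_ids=tuple(sorted(df["clone_id"].astype(str))),
    )


def write_edit_report_tsv(report: EditReport, path: Union[str, Path]) -> None:
    rows = [
        {"clone_id": cid, "removal_reason": reason}
        for cid, reason in sorted(report.removal_reasons.items())
    ]
    pd.DataFrame(rows, columns=["clone_id", "removal_reason"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# FASTA / BED
# ---------------------------------------------------------------------------


def write_arms_fasta(arms: Sequence[ChromosomeArm], path: Union[str, Path]) -> None:
    records = [
        SeqRecord(Seq(a.sequence), id=a.arm_id, description=f"genome={a.genome_label}")
        for a in arms
    ]
    SeqIO.write(records, str(path), "fasta")


def read_arms_fasta(path: Union[str, Path]) -> List[ChromosomeArm]:
    arms = []
    for rec in SeqIO.parse(str(path), "fasta"):
        label = "?"
        for token in rec.description.split():
            if token.startswith("genome="):
                label = token.split("=", 1)[1]
        arms.append(ChromosomeArm(rec.id, label, str(rec.seq).upper()))
    return arms


def write_clones_bed(clones: Sequence[BACClone], path: Union[str, Path]) -> None:
    """Clone placements as BED6 (0-based half-open); the score column carries
    the is_contaminant flag (0/1)."""
    lines = [
        "\t".join(
            [
                c.true_source_arm,
                str(c.start),
                str(c.start + c.insert_length),
                c.clone_id,
                str(int(c.is_contaminant)),
                "+",
            ]
        )
        for c in sorted(clones, key=lambda c: c.clone_id)
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_clones_bed(path: Union[str, Path], library_of=None) -> List[BACClone]:
    clones = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 6:
            raise ValueError(f"{path}:{lineno}: expected 6 BED columns")
        arm, start, end, name, score, _strand = parts[:6]
        library = library_of(name) if library_of else name.rsplit("_", 1)[0]
        clones.append(
            BACClone(
                clone_id=name,
                library_name=library,
                true_source_arm=arm,
                start=int(start),
                insert_length=int(end) - int(start),
                is_contaminant=bool(int(score)),
            )
        )
    return clones


# ---------------------------------------------------------------------------
# configuration and run manifest
# ---------------------------------------------------------------------------


def load_config(path: Union[str, Path]) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def config_to_experiment(cfg: dict, seed: Optional[int] = None):
    """Build an ExperimentConfig from a flat-keyed config mapping."""
    from .analysis import ExperimentConfig  # local import to avoid a cycle

    sim = SimParams(**cfg.get("sim", {}))
    libraries = tuple(LibraryParams(**lib) for lib in cfg.get("libraries", []))
    edit = EditParams(**{
        k: (tuple(tuple(x) for x in v) if k == "vector_band_sizes" else v)
        for k, v in cfg.get("edit", {}).items()
    })
    asm_cfg = {
        k: (tuple(v) if isinstance(v, list) else v)
        for k, v in cfg.get("assembly", {}).items()
    }
    assembly = AssemblyParams(**asm_cfg)
    exp = cfg.get("experiment", {})
    config = ExperimentConfig(
        sim=sim,
        libraries=libraries,
        edit=edit,
        assembly=assembly,
        noise_sd=exp.get("noise_sd", 0.08),
        min_clones_table=exp.get("min_clones_table", 4),
        seed=exp.get("seed", 0),
    )
    if seed is not None:
        config.seed = seed
        config.sim.seed = seed
    if not config.libraries:
        raise ValueError("config defines no libraries")
    return config


def file_digest(path: Union[str, Path]) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Snapshot sufficient to re-run a pipeline invocation bit-identically:
    the full configuration, the seed, and digests of inputs and outputs."""

    command: str
    seed: Optional[int]
    config: dict
    inputs: Dict[str, str] = field(default_factory=dict)
    outputs: Dict[str, str] = field(default_factory=dict)
    timings_s: Dict[str, float] = field(default_factory=dict)

    def write(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def params_to_dict(obj) -> dict:
    d = asdict(obj)
    return {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}
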