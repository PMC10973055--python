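"""Read, validate and align frame-wise phase and instrument annotation files.

Two on-disk dialects are supported:

* phase files: TSV with columns ``Frame`` (integer, 0-based, one row per
  frame at ``phase_fps``) and ``Phase`` (text); the header row is optional
  and sniffed from the first line.
* instrument files: TSV with a mandatory header, first column ``Frame``,
  then one 0/1 column per instrument.  Columns are matched to the config
  vocabulary by name, so file column order is free.  Rows are sampled at
  ``instrument_fps``; the frame column may count in source-video units
  (0, 25, 50, ... at stride 25) or in sample units (0, 1, 2, ...).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from splitaudit.config import DatasetConfig, SplitAssignment, Surgery

logger = logging.getLogger(__name__)

__all__ = [
    "read_phase_file",
    "read_instrument_file",
    "downsample_phases",
    "exclude_idle",
    "load_dataset",
    "discover_annotation_paths",
    "LoadResult",
    "AnnotationError",
]

PHASE_SUFFIX = "-phase.txt"
INSTRUMENT_SUFFIX = "-tool.txt"


class AnnotationError(ValueError):
    """Malformed or vocabulary-inconsistent annotation file."""


def _read_tsv_rows(path: Path) -> list[list[str]]:
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        return [row for row in reader if row and any(cell.strip() for cell in row)]


def read_phase_file(path: str | Path, config: DatasetConfig) -> list[str]:
    """Parse a phase TSV into a per-frame label list keyed by 0-based index.

    The header row is optional; it is detected by a non-integer first cell.
    Frame indices must be 0-based, contiguous and strictly increasing.
    """
    path = Path(path)
    rows = _read_tsv_rows(path)
    if not rows:
        raise AnnotationError(f"{path}: empty phase file")
    # Header sniff: a first cell that does not parse as an integer is a header.
    try:
        int(rows[0][0])
    except ValueError:
        rows = rows[1:]
    if not rows:
        raise AnnotationError(f"{path}: phase file has a header but no data rows")

    vocab = set(config.phases)
    labels: list[str] = []
    prev = -1
    for lineno, row in enumerate(rows):
        if len(row) < 2:
            raise AnnotationError(f"{path}: row {lineno} has fewer than 2 columns")
        try:
            idx = int(row[0])
        except ValueError as exc:
            raise AnnotationError(f"{path}: non-integer frame index {row[0]!r}") from exc
        if idx <= prev:
            raise AnnotationError(
                f"{path}: frame index {idx} not strictly increasing (after {prev})"
            )
        if idx != prev + 1:
            raise AnnotationError(
                f"{path}: frame index {idx} leaves a gap after {prev}"
            )
        prev = idx
        label = row[1].strip()
        if label not in vocab:
            raise AnnotationError(
                f"{path}: unknown phase label {label!r} "
                f"(vocabulary: {sorted(vocab)})"
            )
        labels.append(label)
    return labels


def read_instrument_file(
    path: str | Path, config: DatasetConfig
) -> tuple[list[int], list[tuple[int, ...]]]:
    """Parse an instrument TSV into (frame indices, 0/1 vectors).

    Returns vectors in *config* instrument order regardless of file column
    order; the mapping is by column name.
    """
    path = Path(path)
    rows = _read_tsv_rows(path)
    if not rows:
        raise AnnotationError(f"{path}: empty instrument file")
    header = [c.strip() for c in rows[0]]
    file_instruments = header[1:]
    if set(file_instruments) != set(config.instruments):
        missing = set(config.instruments) - set(file_instruments)
        extra = set(file_instruments) - set(config.instruments)
        raise AnnotationError(
            f"{path}: instrument header mismatch "
            f"(missing {sorted(missing)}, unexpected {sorted(extra)})"
        )
    # column position of each config instrument in the file
    col_of = [file_instruments.index(name) + 1 for name in config.instruments]

    indices: list[int] = []
    vectors: list[tuple[int, ...]] = []
    prev = -1
    for row in rows[1:]:
        if len(row) != len(header):
            raise AnnotationError(f"{path}: ragged row {row!r}")
        idx = int(row[0])
        if idx <= prev:
            raise AnnotationError(
                f"{path}: frame index {idx} not strictly increasing (after {prev})"
            )
        prev = idx
        vec = []
        for col in col_of:
            cell = row[col].strip()
            if cell not in ("0", "1"):
                raise AnnotationError(
                    f"{path}: cell {cell!r} at frame {idx} outside {{0,1}}"
                )
            vec.append(int(cell))
        indices.append(idx)
        vectors.append(tuple(vec))
    if not indices:
        raise AnnotationError(f"{path}: instrument file has no data rows")
    return indices, vectors


def downsample_phases(
    labels: Sequence[str], phase_fps: int, instrument_fps: int
) -> list[str]:
    """Keep every stride-th label so phases align with instrument samples.

    The stride is ``phase_fps / instrument_fps`` and must be integral; the
    kept frames are 0, s, 2s, ..., so the output has ceil(n / s) entries.
    """
    if instrument_fps < 1 or phase_fps < instrument_fps:
        raise ValueError("need phase_fps >= instrument_fps >= 1")
    if phase_fps % instrument_fps != 0:
        raise ValueError(
            f"phase_fps ({phase_fps}) not divisible by instrument_fps ({instrument_fps})"
        )
    stride = phase_fps // instrument_fps
    return list(labels[::stride])


def exclude_idle(surgery: Surgery, idle_label: str) -> Surgery:
    """Drop all frames labelled with the idle phase.

    Remaining frames keep their original source indices.  Runs of one phase
    that were separated only by idle frames become adjacent, so later
    run-length encoding merges them and no self-transition can appear.
    """
    if surgery.phases is None or idle_label not in surgery.phases:
        return surgery
    keep = [i for i, p in enumerate(surgery.phases) if p != idle_label]
    if not keep:
        raise AnnotationError(
            f"surgery {surgery.surgery_id!r}: all frames are idle ({idle_label!r})"
        )
    return Surgery(
        surgery_id=surgery.surgery_id,
        frame_indices=tuple(surgery.frame_indices[i] for i in keep),
        phases=tuple(surgery.phases[i] for i in keep),
        instruments=(
            tuple(surgery.instruments[i] for i in keep)
            if surgery.instruments is not None
            else None
        ),
    )


@dataclass
class LoadResult:
    """Surgeries plus a coverage report of what each one shipped."""

    surgeries: list[Surgery]
    split: SplitAssignment
    phase_only: list[str] = field(default_factory=list)
    instrument_only: list[str] = field(default_factory=list)
    truncated: dict[str, int] = field(default_factory=dict)  # id -> dropped frames


def _normalize_instrument_indices(
    indices: list[int], stride: int, path: Path
) -> list[int]:
    """Map instrument-file frame indices to sample positions 0, 1, 2, ...

    Accepts source-unit indices (multiples of the stride) and sample-unit
    indices (consecutive from 0).
    """
    if stride > 1 and all(i % stride == 0 for i in indices):
        return [i // stride for i in indices]
    if indices == list(range(len(indices))):
        return indices
    if stride == 1 and indices == list(range(indices[0], indices[0] + len(indices))):
        return [i - indices[0] for i in indices]
    raise AnnotationError(
        f"{path}: instrument frame indices neither multiples of stride {stride} "
        "nor consecutive sample positions"
    )


def load_surgery(
    surgery_id: str,
    config: DatasetConfig,
    phase_path: str | Path | None = None,
    instrument_path: str | Path | None = None,
) -> tuple[Surgery, int]:
    """Load and align one surgery; returns (surgery, dropped_frame_count)."""
    if phase_path is None and instrument_path is None:
        raise AnnotationError(f"surgery {surgery_id!r}: no annotation file")
    stride = config.stride

    phases: list[str] | None = None
    if phase_path is not None:
        raw = read_phase_file(phase_path, config)
        phases = downsample_phases(raw, config.phase_fps, config.instrument_fps)

    vectors: list[tuple[int, ...]] | None = None
    positions: list[int] | None = None
    if instrument_path is not None:
        idx, vectors = read_instrument_file(instrument_path, config)
        positions = _normalize_instrument_indices(idx, stride, Path(instrument_path))

    dropped = 0
    if phases is not None and vectors is not None:
        n = min(len(phases), len(vectors))
        dropped = max(len(phases), len(vectors)) - n
        if dropped:
            logger.warning(
                "surgery %s: phase stream (%d) and instrument stream (%d) "
                "disagree in length; truncating to %d frames (%d dropped)",
                surgery_id, len(phases), len(vectors), n, dropped,
            )
        phases = phases[:n]
        vectors = vectors[:n]
        frame_indices = tuple(i * stride for i in range(n))
    elif phases is not None:
        frame_indices = tuple(i * stride for i in range(len(phases)))
    else:
        assert positions is not None and vectors is not None
        frame_indices = tuple(p * stride for p in positions)

    surgery = Surgery(
        surgery_id=surgery_id,
        frame_indices=frame_indices,
        phases=tuple(phases) if phases is not None else None,
        instruments=tuple(vectors) if vectors is not None else None,
    )
    if config.idle_phase_label is not None:
        surgery = exclude_idle(surgery, config.idle_phase_label)
    return surgery, dropped


def load_dataset(
    config: DatasetConfig,
    paths: Mapping[str, Mapping[str, str | Path | None]],
) -> LoadResult:
    """Load every surgery named by the config split.

    ``paths`` maps surgery id to ``{"phase": ..., "instruments": ...}``;
    either entry may be missing or None.  A surgery in the split with no
    file at all is an error; duplicates in ``paths`` cannot occur by
    construction of the mapping.
    """
    if config.split is None:
        raise ValueError("config has no split assignment")
    result = LoadResult(surgeries=[], split=config.split)
    for sid in config.split.surgery_ids:
        entry = paths.get(sid, {})
        phase_path = entry.get("phase")
        instrument_path = entry.get("instruments")
        if phase_path is None and instrument_path is None:
            raise AnnotationError(
                f"split references surgery {sid!r} but no annotation file was found"
            )
        surgery, dropped = load_surgery(sid, config, phase_path, instrument_path)
        if dropped:
            result.truncated[sid] = dropped
        if surgery.has_phases and not surgery.has_instruments:
            result.phase_only.append(sid)
        elif surgery.has_instruments and not surgery.has_phases:
            result.instrument_only.append(sid)
        result.surgeries.append(surgery)
    return result


def discover_annotation_paths(
    directory: str | Path,
    surgery_ids: Sequence[str],
    phase_suffix: str = PHASE_SUFFIX,
    instrument_suffix: str = INSTRUMENT_SUFFIX,
) -> dict[str, dict[str, Path | None]]:
    """Locate ``<id><suffix>`` annotation files for each surgery id."""
    directory = Path(directory)
    out: dict[str, dict[str, Path | None]] = {}
    for sid in surgery_ids:
        phase = directory / f"{sid}{phase_suffix}"
        tool = directory / f"{sid}{instrument_suffix}"
        out[sid] = {
            "phase": phase if phase.exists() else None,
            "instruments": tool if tool.exists() else None,
        }
    return out
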