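"""Synthetic surgical-workflow annotation generator.

Emulates the statistical structure of real workflow datasets: an ordered
phase grammar with optional/skipped/repeated phases, phase-correlated
instrument usage, and heavy duration imbalance.  Generation is fully
deterministic for a fixed seed, and the generator reports the exact
ground-truth inventory of attributes it produced per set, so audits can be
verified closed-loop.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

from splitaudit.config import (
    END,
    START,
    DatasetConfig,
    SetLabel,
    SplitAssignment,
    Surgery,
    sorted_surgeries,
)
from splitaudit.io_annotations import INSTRUMENT_SUFFIX, PHASE_SUFFIX
from splitaudit.split_audit import AttributeKey, AttributeKind
from splitaudit.workflow_stats import make_transition

__all__ = [
    "Quirk",
    "Plant",
    "GeneratorSpec",
    "SyntheticDataset",
    "dense_spec",
    "generate_dataset",
    "plant_unrepresented",
    "write_fixture",
]


class DegenerateSpecError(ValueError):
    """The phase chain failed to reach END within the length cutoff."""


@dataclass(frozen=True)
class Quirk:
    """A workflow deviation applied to a deterministic fraction of surgeries.

    Kinds: ``skip_first`` starts the surgery directly in ``phase_index``;
    ``end_in`` appends a final run of ``phase_index`` (a late return to an
    earlier phase).  Quirks attach to the lexicographically first
    floor(fraction * N) surgery ids so tests can name the affected surgeries.
    """

    kind: str
    phase_index: int
    fraction: float

    def __post_init__(self) -> None:
        if self.kind not in ("skip_first", "end_in"):
            raise ValueError(f"unknown quirk kind {self.kind!r}")
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("quirk fraction must be in [0, 1]")


@dataclass(frozen=True)
class Plant:
    """A deliberately unrepresented attribute.

    ``kind`` is TRANSITION (payload: (source_idx, target_idx) phase indices)
    or COMBINATION (payload: instrument indices).  The attribute is injected
    into surgeries outside ``victim_set`` and suppressed everywhere else, so
    a correct audit must flag exactly it for exactly that set.
    """

    kind: AttributeKind
    payload: tuple[int, ...]
    victim_set: SetLabel


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the synthetic workflow generator.

    The default phase process is a linear forward chain visiting every phase
    once (END after the last); a custom row-stochastic ``transition`` matrix
    of shape P x (P+1) (last column = END) may be supplied instead.  Run
    lengths are geometric with per-phase means.  Instrument vectors are drawn
    per frame either from per-phase Bernoulli probabilities or from a shared
    pool of exact visible-sets with probabilities.
    """

    n_phases: int
    n_instruments: int
    n_surgeries: int
    seed: int = 0
    transition: tuple[tuple[float, ...], ...] | None = None
    initial_dist: tuple[float, ...] | None = None
    mean_run_length: tuple[float, ...] | None = None
    instrument_mode: str = "bernoulli"
    instrument_probs: tuple[tuple[float, ...], ...] | None = None  # P x I
    combo_pool: tuple[tuple[tuple[int, ...], float], ...] | None = None
    persistence: float = 0.0
    quirks: tuple[Quirk, ...] = ()
    planted: Plant | None = None
    split_counts: tuple[int, int, int] | None = None
    max_length: int = 5000

    def __post_init__(self) -> None:
        if self.n_phases < 2 or self.n_instruments < 1 or self.n_surgeries < 2:
            raise ValueError("need >= 2 phases, >= 1 instrument, >= 2 surgeries")
        if self.instrument_mode not in ("bernoulli", "pool"):
            raise ValueError(f"unknown instrument_mode {self.instrument_mode!r}")
        if self.transition is not None:
            if len(self.transition) != self.n_phases:
                raise ValueError("transition matrix must have one row per phase")
            for row in self.transition:
                if len(row) != self.n_phases + 1:
                    raise ValueError("transition rows need P + 1 columns (last = END)")
                if any(p < 0 for p in row) or abs(sum(row) - 1.0) > 1e-9:
                    raise ValueError("transition rows must be stochastic")
        if self.mean_run_length is not None and any(
            m < 1 for m in self.mean_run_length
        ):
            raise ValueError("mean run lengths must be >= 1")
        if self.instrument_mode == "pool":
            if not self.combo_pool:
                raise ValueError("pool mode requires combo_pool")
            total = sum(p for _, p in self.combo_pool)
            if abs(total - 1.0) > 1e-9:
                raise ValueError("combo_pool probabilities must sum to 1")
        if not 0.0 <= self.persistence <= 1.0:
            raise ValueError("persistence must be in [0, 1]")

    # -- derived defaults ----------------------------------------------------

    def effective_mean_runs(self) -> tuple[float, ...]:
        if self.mean_run_length is not None:
            return self.mean_run_length
        return tuple(10.0 for _ in range(self.n_phases))

    def effective_transition(self) -> tuple[tuple[float, ...], ...]:
        if self.transition is not None:
            return self.transition
        # linear chain: phase p -> p+1, last phase -> END
        rows = []
        for p in range(self.n_phases):
            row = [0.0] * (self.n_phases + 1)
            row[p + 1] = 1.0  # index n_phases == END
            rows.append(tuple(row))
        return tuple(rows)

    @property
    def is_linear_chain(self) -> bool:
        return self.transition is None

    def effective_initial(self) -> tuple[float, ...]:
        if self.initial_dist is not None:
            return self.initial_dist
        return (1.0,) + (0.0,) * (self.n_phases - 1)

    def effective_split_counts(self) -> tuple[int, int, int]:
        if self.split_counts is not None:
            n_train, n_val, n_test = self.split_counts
            if n_train + n_val + n_test != self.n_surgeries:
                raise ValueError("split_counts must sum to n_surgeries")
            return self.split_counts
        n = self.n_surgeries
        n_test = max(1, round(0.3 * n))
        n_val = round(0.2 * n)
        n_train = n - n_val - n_test
        if n_train < 1:
            n_train, n_val = 1, n - 1 - n_test
        return (n_train, n_val, n_test)


def dense_spec(
    n_phases: int = 5,
    n_instruments: int = 5,
    n_surgeries: int = 12,
    seed: int = 0,
    mean_run_length: float = 15.0,
) -> GeneratorSpec:
    """A dense pool-mode spec whose attributes appear in every set w.h.p.

    Every surgery walks the full linear phase chain and instrument sets are
    drawn from a small shared pool, so an audit of the untouched spec yields
    no unrepresented attributes; ideal substrate for planting.
    """
    if n_instruments < 3:
        raise ValueError("dense_spec needs >= 3 instruments")
    singles = tuple(((i,), 0.5 / n_instruments) for i in range(n_instruments))
    pool = (
        ((), 0.15),
        *singles,
        ((0, 1), 0.13),
        ((1, 2), 0.12),
        ((0, 1, 2), 0.10),
    )
    return GeneratorSpec(
        n_phases=n_phases,
        n_instruments=n_instruments,
        n_surgeries=n_surgeries,
        seed=seed,
        instrument_mode="pool",
        combo_pool=pool,
        mean_run_length=tuple(mean_run_length for _ in range(n_phases)),
    )


@dataclass
class SyntheticDataset:
    """Generated surgeries, their config/split, and the true attribute sets."""

    surgeries: list[Surgery]
    config: DatasetConfig
    inventory: dict[SetLabel, set[AttributeKey]] = field(default_factory=dict)

    @property
    def split(self) -> SplitAssignment:
        assert self.config.split is not None
        return self.config.split


def _surgery_ids(n: int) -> list[str]:
    return [f"s{i:03d}" for i in range(1, n + 1)]


def _geometric(rng: random.Random, mean: float) -> int:
    """Geometric run length with the given mean, support {1, 2, ...}."""
    if mean <= 1.0:
        return 1
    p = 1.0 / mean
    u = rng.random()
    return 1 + int(math.log(1.0 - u) / math.log(1.0 - p))


def _weighted_choice(rng: random.Random, weights: Sequence[float]) -> int:
    u = rng.random()
    acc = 0.0
    for i, w in enumerate(weights):
        acc += w
        if u < acc:
            return i
    return len(weights) - 1


def _build_runs(
    spec: GeneratorSpec, rng: random.Random, skip_first_to: int | None
) -> list[tuple[int, int]]:
    """Phase run list [(phase_index, length), ...] of one surgery."""
    matrix = spec.effective_transition()
    means = spec.effective_mean_runs()
    end = spec.n_phases
    if skip_first_to is not None:
        phase = skip_first_to
    else:
        phase = _weighted_choice(rng, spec.effective_initial())
    runs: list[tuple[int, int]] = []
    total = 0
    while True:
        length = _geometric(rng, means[phase])
        runs.append((phase, length))
        total += length
        if total > spec.max_length:
            raise DegenerateSpecError(
                f"surgery exceeded max_length={spec.max_length} without reaching END"
            )
        nxt = _weighted_choice(rng, matrix[phase])
        if nxt == end:
            return runs
        phase = nxt


def _apply_end_in(
    runs: list[tuple[int, int]], phase_index: int, rng: random.Random, mean: float
) -> list[tuple[int, int]]:
    if runs[-1][0] == phase_index:
        return runs
    return runs + [(phase_index, _geometric(rng, mean))]


def _inject_transition(
    runs: list[tuple[int, int]],
    source: int,
    target: int,
    rng: random.Random,
    means: Sequence[float],
) -> list[tuple[int, int]]:
    """Make the planted transition source->target occur exactly once.

    Backward (target < source): after the first run of ``source`` insert a
    replay of phases target..source, so the only novel boundary is
    source->target.  Forward skip (target > source + 1): delete the runs of
    the intermediate phases, creating source->target directly.
    """
    phases = [p for p, _ in runs]
    if source not in phases:
        raise ValueError(f"cannot inject: phase {source} absent from surgery")
    i = phases.index(source)
    if target < source:
        replay = [
            (p, _geometric(rng, means[p])) for p in range(target, source + 1)
        ]
        return runs[: i + 1] + replay + runs[i + 1 :]
    if target > source + 1:
        out = [
            (p, ln) for (p, ln) in runs if not (source < p < target)
        ]
        return out
    raise ValueError("planted transition must be backward or skip >= 2 ahead")


def _draw_vectors(
    spec: GeneratorSpec,
    runs: Sequence[tuple[int, int]],
    rng: random.Random,
) -> list[tuple[int, ...]]:
    pool = spec.combo_pool
    if spec.instrument_mode == "pool" and spec.planted is not None and (
        spec.planted.kind is AttributeKind.COMBINATION
    ):
        # suppress the planted combination from the natural pool
        assert pool is not None
        planted = tuple(sorted(spec.planted.payload))
        kept = [(c, p) for c, p in pool if tuple(sorted(c)) != planted]
        total = sum(p for _, p in kept)
        pool = tuple((c, p / total) for c, p in kept)

    vectors: list[tuple[int, ...]] = []
    prev: tuple[int, ...] | None = None
    for phase, length in runs:
        for _ in range(length):
            if prev is not None and spec.persistence > 0 and rng.random() < spec.persistence:
                vectors.append(prev)
                continue
            if spec.instrument_mode == "pool":
                assert pool is not None
                idx = _weighted_choice(rng, [p for _, p in pool])
                visible = set(pool[idx][0])
            else:
                probs = (
                    spec.instrument_probs[phase]
                    if spec.instrument_probs is not None
                    else tuple(0.3 for _ in range(spec.n_instruments))
                )
                visible = {i for i in range(spec.n_instruments) if rng.random() < probs[i]}
            if (
                spec.planted is not None
                and spec.planted.kind is AttributeKind.COMBINATION
                and visible == set(spec.planted.payload)
            ):
                visible.discard(min(visible))  # suppress accidental exact match
            vec = tuple(1 if i in visible else 0 for i in range(spec.n_instruments))
            vectors.append(vec)
            prev = vec
    return vectors


def generate_dataset(spec: GeneratorSpec) -> SyntheticDataset:
    """Generate surgeries, config and the ground-truth attribute inventory.

    Deterministic for a fixed spec (including its seed): the same spec always
    yields bit-identical datasets.
    """
    ids = _surgery_ids(spec.n_surgeries)
    n_train, n_val, n_test = spec.effective_split_counts()
    split = SplitAssignment.from_lists(
        train=ids[:n_train],
        val=ids[n_train : n_train + n_val],
        test=ids[n_train + n_val :],
    )
    phases = tuple(f"Phase{p + 1:02d}" for p in range(spec.n_phases))
    instruments = tuple(f"Tool{i + 1:02d}" for i in range(spec.n_instruments))
    config = DatasetConfig(
        name=f"synthetic-{spec.seed}",
        phases=phases,
        instruments=instruments,
        phase_fps=1,
        instrument_fps=1,
        split=split,
    )

    # deterministic quirk assignment: lexicographically first floor(f*N) ids
    quirk_of: dict[str, list[Quirk]] = {sid: [] for sid in ids}
    for quirk in spec.quirks:
        n_affected = int(quirk.fraction * spec.n_surgeries)
        for sid in ids[:n_affected]:
            quirk_of[sid].append(quirk)

    # planting: inject into the first surgery of each non-victim set
    inject_into: set[str] = set()
    if spec.planted is not None:
        if spec.planted.kind is AttributeKind.TRANSITION and not spec.is_linear_chain:
            raise ValueError(
                "transition planting requires the default linear phase chain"
            )
        for label in split.nonempty_sets():
            if label is not spec.planted.victim_set:
                members = split.members(label)
                if spec.planted.kind is AttributeKind.TRANSITION and len(members) < 2:
                    raise ValueError(
                        f"set {label.value!r} needs >= 2 surgeries for transition planting"
                    )
                inject_into.add(members[0])

    means = spec.effective_mean_runs()
    surgeries: list[Surgery] = []
    inventory: dict[SetLabel, set[AttributeKey]] = {label: set() for label in SetLabel}

    for sid in ids:
        rng = random.Random(f"{spec.seed}:{sid}")
        skip_to: int | None = None
        for q in quirk_of[sid]:
            if q.kind == "skip_first":
                skip_to = q.phase_index
        runs = _build_runs(spec, rng, skip_to)
        for q in quirk_of[sid]:
            if q.kind == "end_in":
                runs = _apply_end_in(runs, q.phase_index, rng, means[q.phase_index])
        if (
            spec.planted is not None
            and spec.planted.kind is AttributeKind.TRANSITION
            and sid in inject_into
        ):
            src, tgt = spec.planted.payload
            runs = _inject_transition(runs, src, tgt, rng, means)

        vectors = _draw_vectors(spec, runs, rng)
        if (
            spec.planted is not None
            and spec.planted.kind is AttributeKind.COMBINATION
            and sid in inject_into
        ):
            planted_vec = tuple(
                1 if i in spec.planted.payload else 0
                for i in range(spec.n_instruments)
            )
            mid = len(vectors) // 2
            for j in range(mid, min(mid + 3, len(vectors))):
                vectors[j] = planted_vec

        labels = []
        for p, length in runs:
            labels.extend([phases[p]] * length)
        surgery = Surgery(
            surgery_id=sid,
            frame_indices=tuple(range(len(labels))),
            phases=tuple(labels),
            instruments=tuple(vectors),
        )
        surgeries.append(surgery)

        # ground-truth inventory from the generator's own run/vector records
        set_label = split.set_of(sid)
        inv = inventory[set_label]
        run_phases = [phases[p] for p, _ in runs]
        for ph in set(run_phases):
            inv.add(AttributeKey(AttributeKind.PHASE, ph))
        inv.add(
            AttributeKey(
                AttributeKind.TRANSITION, make_transition(START, run_phases[0], config)
            )
        )
        for a, b in zip(run_phases, run_phases[1:]):
            inv.add(
                AttributeKey(AttributeKind.TRANSITION, make_transition(a, b, config))
            )
        inv.add(
            AttributeKey(
                AttributeKind.TRANSITION, make_transition(run_phases[-1], END, config)
            )
        )
        for vec in vectors:
            visible = tuple(i for i, bit in enumerate(vec) if bit)
            for i in visible:
                inv.add(AttributeKey(AttributeKind.INSTRUMENT, instruments[i]))
            if len(visible) >= 2:
                inv.add(
                    AttributeKey(
                        AttributeKind.COMBINATION,
                        tuple(instruments[i] for i in visible),
                    )
                )

    return SyntheticDataset(surgeries=surgeries, config=config, inventory=inventory)


def plant_unrepresented(
    spec: GeneratorSpec,
    kind: AttributeKind | str,
    payload: Sequence[int],
    victim_set: SetLabel | str,
) -> GeneratorSpec:
    """Return a spec whose datasets miss exactly one attribute in one set.

    ``payload`` holds phase indices (source, target) for TRANSITION plants
    and instrument indices for COMBINATION plants.  The attribute occurs only
    outside ``victim_set``, so a correct audit flags it for exactly that set.
    """
    kind = AttributeKind(kind)
    victim = SetLabel(victim_set) if not isinstance(victim_set, SetLabel) else victim_set
    payload_t = tuple(int(x) for x in payload)
    if kind is AttributeKind.TRANSITION:
        if len(payload_t) != 2:
            raise ValueError("transition plant needs (source, target) phase indices")
        src, tgt = payload_t
        if not (0 <= src < spec.n_phases and 0 <= tgt < spec.n_phases):
            raise ValueError("plant phase index out of range")
        if tgt == src or tgt == src + 1:
            raise ValueError(
                "planted transition must not occur naturally (backward or skip >= 2)"
            )
    elif kind is AttributeKind.COMBINATION:
        if len(payload_t) < 2:
            raise ValueError("combination plant needs >= 2 instrument indices")
        if any(not 0 <= i < spec.n_instruments for i in payload_t):
            raise ValueError("plant instrument index out of range")
        payload_t = tuple(sorted(payload_t))
    else:
        raise ValueError(f"cannot plant attributes of kind {kind.value!r}")
    return replace(spec, planted=Plant(kind=kind, payload=payload_t, victim_set=victim))


def write_fixture(
    surgeries: Sequence[Surgery],
    config: DatasetConfig,
    directory: str | Path,
    stride: int | None = None,
) -> DatasetConfig:
    """Write annotations + config to disk in the phase/tool TSV dialect.

    Phase files are written at ``phase_fps`` (each common-rate label repeated
    ``stride`` times), instrument files at ``instrument_fps`` with source-unit
    frame indices — so reading the files back through the annotation loaders
    reproduces the input surgeries exactly.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stride = config.stride if stride is None else stride
    out_config = DatasetConfig(
        name=config.name,
        phases=config.phases,
        instruments=config.instruments,
        phase_fps=config.instrument_fps * stride,
        instrument_fps=config.instrument_fps,
        idle_phase_label=config.idle_phase_label,
        split=config.split,
    )
    for s in sorted_surgeries(list(surgeries)):
        expected = tuple(j * config.stride for j in range(s.duration))
        if s.frame_indices != expected:
            raise ValueError(
                f"surgery {s.surgery_id!r}: fixture writer needs contiguous "
                f"common-rate frames"
            )
        if s.phases is not None:
            lines = ["Frame\tPhase"]
            frame = 0
            for label in s.phases:
                for _ in range(stride):
                    lines.append(f"{frame}\t{label}")
                    frame += 1
            (directory / f"{s.surgery_id}{PHASE_SUFFIX}").write_text(
                "\n".join(lines) + "\n"
            )
        if s.instruments is not None:
            header = "Frame\t" + "\t".join(config.instruments)
            lines = [header]
            for j, vec in enumerate(s.instruments):
                lines.append(f"{j * stride}\t" + "\t".join(str(b) for b in vec))
            (directory / f"{s.surgery_id}{INSTRUMENT_SUFFIX}").write_text(
                "\n".join(lines) + "\n"
            )
    out_config.to_file(directory / "config.yaml")
    return out_config
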