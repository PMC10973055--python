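"""Independent brute-force recount used as the oracle in equivalence tests.

Deliberately avoids every aggregation helper of the package: plain frame
loops and dict arithmetic only, so it cannot share a bug with the code it
checks.
"""

from collections import defaultdict

from splitaudit.config import END, START


def naive_recount(surgeries, split, config):
    """Frame-by-frame tally of every audited quantity."""
    res = {
        "phase_frames": defaultdict(int),       # (phase, set) -> frames
        "phase_surgeries": defaultdict(int),    # phase -> #surgeries containing it
        "transitions": defaultdict(int),        # (src, tgt, set) -> occurrences
        "instr_frames": defaultdict(int),       # (instrument, set) -> frames
        "idle": defaultdict(int),               # set -> frames
        "singletons": defaultdict(int),         # (instr_index, set) -> frames
        "combos": defaultdict(int),             # (sorted idx tuple, set) -> frames
        "phase_instr": defaultdict(int),        # (phase, instrument, set) -> frames
        "annotated": defaultdict(int),          # set -> instrument-annotated frames
        "durations": {},                        # surgery_id -> frames
    }
    for s in surgeries:
        lbl = split.set_of(s.surgery_id)
        res["durations"][s.surgery_id] = len(s.frame_indices)
        if s.phases is not None:
            prev = None
            seen = set()
            for p in s.phases:
                res["phase_frames"][(p, lbl)] += 1
                seen.add(p)
                if prev is not None and p != prev:
                    res["transitions"][(prev, p, lbl)] += 1
                prev = p
            res["transitions"][(START, s.phases[0], lbl)] += 1
            res["transitions"][(s.phases[-1], END, lbl)] += 1
            for p in seen:
                res["phase_surgeries"][p] += 1
        if s.instruments is not None:
            for vec in s.instruments:
                res["annotated"][lbl] += 1
                visible = tuple(i for i, b in enumerate(vec) if b)
                for i in visible:
                    res["instr_frames"][(config.instruments[i], lbl)] += 1
                if len(visible) == 0:
                    res["idle"][lbl] += 1
                elif len(visible) == 1:
                    res["singletons"][(visible[0], lbl)] += 1
                else:
                    res["combos"][(visible, lbl)] += 1
        if s.phases is not None and s.instruments is not None:
            for p, vec in zip(s.phases, s.instruments):
                for i, b in enumerate(vec):
                    if b:
                        res["phase_instr"][(p, config.instruments[i], lbl)] += 1
    return res


def naive_direction(source, target, config):
    """Transition direction from conceptual order, computed independently."""
    if source == START or target == END:
        return "boundary"
    if list(config.phases).index(target) > list(config.phases).index(source):
        return "forward"
    return "backward"
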