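"""Trial scheduling for the three-phase object-location memory paradigm.

The paradigm has three phases. During *encoding*, participants learn
object-location associations (four screen positions: top, bottom, left,
right), each object shown twice. During the *working-memory* (WM) phase a
retro-cue task is run on a subset of the encoded objects: two intact objects
are shown (one on the horizontal axis, one on the vertical axis), a cue
indicates which axis will be tested (selective cue) or is uninformative
(neutral cue, Experiment 2 only), and a central probe requires a match /
no-match decision. During *retrieval*, every encoded object's location is
reported twice.

Conditions describe what happened to an object in the WM phase:

=====  =========================================================
PT     prioritization + testing (cued, hence tested, in WM)
NPT    non-prioritization + testing (neutral cue; Experiment 2)
NP     non-prioritization (shown in WM but never cued)
ABS    absent from the WM task (long-term-memory-only control)
=====  =========================================================

Experiment 1 splits objects equally into {PT, NP, ABS}; Experiment 2 into
{PT, NPT, NP, ABS}. Every WM-eligible object appears exactly four times in
the WM phase, always at its encoding location.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LOCATIONS = ("top", "bottom", "left", "right")
HORIZONTAL = frozenset({"left", "right"})
VERTICAL = frozenset({"top", "bottom"})

CONDITIONS_EXP1 = ("PT", "NP", "ABS")
CONDITIONS_EXP2 = ("PT", "NPT", "NP", "ABS")

#: token used in the probe_object column for probes drawn from the unseen pool
NEW_TOKEN = "new"


class ConfigurationError(ValueError):
    """Raised when requested design parameters are internally inconsistent."""


class SchedulingError(RuntimeError):
    """Raised when a trial schedule cannot satisfy the pairing constraints."""


@dataclass(frozen=True)
class ObjectSpec:
    """One stimulus object with its fixed location and WM condition."""

    object_id: int
    location: str
    condition: str
    experiment: int

    def __post_init__(self) -> None:
        if self.location not in LOCATIONS:
            raise ConfigurationError(f"unknown location {self.location!r}")
        conditions = CONDITIONS_EXP1 if self.experiment == 1 else CONDITIONS_EXP2
        if self.condition not in conditions:
            raise ConfigurationError(
                f"condition {self.condition!r} invalid for experiment {self.experiment}"
            )

    @property
    def axis(self) -> str:
        return "horizontal" if self.location in HORIZONTAL else "vertical"


@dataclass(frozen=True)
class WMTrial:
    """One working-memory trial: two displayed objects, a cue, and a probe."""

    index: int
    object_on_horizontal_axis: int
    object_on_vertical_axis: int
    cue_type: str  # selective | neutral
    cued_axis: str  # horizontal | vertical | none
    probe_object: int | str  # object_id or NEW_TOKEN-prefixed id
    probe_kind: str  # match | noncued | new | displayed | absent
    correct_response: str  # yes | no


@dataclass
class PhaseSchedule:
    """Ordered trial list for one phase.

    ``trials`` holds plain object ids for encoding/retrieval and
    :class:`WMTrial` instances for the WM phase.
    """

    phase: str
    trials: list = field(default_factory=list)

    @property
    def n_trials(self) -> int:
        return len(self.trials)


def _balanced_locations(n: int, cond_index: int, rng: np.random.Generator) -> list[str]:
    """Locations for ``n`` same-condition objects, as near-equal as possible.

    The ``n % 4`` leftover locations are taken from a rotation starting at
    ``cond_index`` so that leftovers of different conditions land on
    different locations; this keeps overall location counts exact and makes
    the horizontal/vertical appearance counts of the PT and NP conditions
    complementary (required for axis pairing in the WM phase).
    """
    base, extra = divmod(n, 4)
    locs = [loc for loc in LOCATIONS for _ in range(base)]
    locs += [LOCATIONS[(cond_index + j) % 4] for j in range(extra)]
    return [str(locs[i]) for i in rng.permutation(len(locs))]


def assign_conditions(n_objects: int, experiment: int, seed: int) -> list[ObjectSpec]:
    """Randomly split ``n_objects`` into the experiment's WM conditions.

    Condition counts are exact (a third per condition in Experiment 1, a
    quarter in Experiment 2) and locations are balanced: each location is
    used exactly ``n_objects / 4`` times overall and within each condition
    the per-location counts differ by at most one.
    """
    if experiment not in (1, 2):
        raise ConfigurationError(f"experiment must be 1 or 2, got {experiment}")
    conditions = CONDITIONS_EXP1 if experiment == 1 else CONDITIONS_EXP2
    k = len(conditions)
    if n_objects == 0:
        return []
    if n_objects % k:
        raise ConfigurationError(
            f"n_objects={n_objects} not divisible by {k} (experiment {experiment} conditions)"
        )
    if n_objects % 4:
        raise ConfigurationError(
            f"n_objects={n_objects} not divisible by 4 (location balance)"
        )
    rng = np.random.default_rng(seed)
    per = n_objects // k
    order = rng.permutation(n_objects)
    objects: list[ObjectSpec] = [None] * n_objects  # type: ignore[list-item]
    pos = 0
    for ci, cond in enumerate(conditions):
        ids = order[pos : pos + per]
        pos += per
        locs = _balanced_locations(per, ci, rng)
        for oid, loc in zip(ids, locs):
            objects[int(oid)] = ObjectSpec(int(oid), loc, cond, experiment)
    return objects


def _double_pass_order(n: int, rng: np.random.Generator) -> np.ndarray:
    """Two concatenated independent permutations of ``range(n)``."""
    return np.concatenate([rng.permutation(n), rng.permutation(n)])


def build_encoding_schedule(objects: list[ObjectSpec], seed: int) -> PhaseSchedule:
    """Encoding order: every object once, then every object once more."""
    if not objects:
        raise ConfigurationError("empty object list")
    rng = np.random.default_rng(seed)
    order = _double_pass_order(len(objects), rng)
    ids = [objects[i].object_id for i in order]
    return PhaseSchedule(phase="encoding", trials=ids)


def build_retrieval_schedule(objects: list[ObjectSpec], seed: int) -> PhaseSchedule:
    """Retrieval order: each object's location reported twice."""
    if not objects:
        raise ConfigurationError("empty object list")
    rng = np.random.default_rng(seed)
    order = _double_pass_order(len(objects), rng)
    ids = [objects[i].object_id for i in order]
    return PhaseSchedule(phase="retrieval", trials=ids)


def _appearances(objs: list[ObjectSpec], rng: np.random.Generator) -> list[ObjectSpec]:
    """Each object four times, shuffled."""
    apps = [o for o in objs for _ in range(4)]
    return [apps[i] for i in rng.permutation(len(apps))]


def _probe_template(counts: dict[str, int], rng: np.random.Generator) -> list[str]:
    tmpl = [k for k, c in counts.items() for _ in range(c)]
    return [tmpl[i] for i in rng.permutation(len(tmpl))]


def build_wm_schedule(objects: list[ObjectSpec], experiment: int, seed: int) -> PhaseSchedule:
    """Working-memory trial schedule with exact probe-kind proportions.

    Selective trials pair one PT object with one NP object, one per axis;
    probes are the cued object (match, 50% of selective trials), the
    non-cued object (25%) or a never-encoded new object (25%). Experiment-2
    neutral trials pair two NPT objects at different positions; the probe is
    one of the displayed objects (50%) or a new object (50%). All counts are
    assigned by shuffled exact-count templates, never sampled, so the
    printed proportions hold exactly and "no" responses are exactly half of
    each cue type's trials.
    """
    if experiment not in (1, 2):
        raise ConfigurationError(f"experiment must be 1 or 2, got {experiment}")
    rng = np.random.default_rng(seed)
    pt = [o for o in objects if o.condition == "PT"]
    np_ = [o for o in objects if o.condition == "NP"]
    npt = [o for o in objects if o.condition == "NPT"]
    if not pt or not np_:
        raise SchedulingError("need PT and NP objects to build selective WM trials")

    # --- selective trials: PT on one axis, NP on the other ------------------
    pt_h = _appearances([o for o in pt if o.axis == "horizontal"], rng)
    pt_v = _appearances([o for o in pt if o.axis == "vertical"], rng)
    np_h = _appearances([o for o in np_ if o.axis == "horizontal"], rng)
    np_v = _appearances([o for o in np_ if o.axis == "vertical"], rng)
    if len(pt_h) != len(np_v) or len(pt_v) != len(np_h):
        raise SchedulingError(
            "PT/NP horizontal-vertical appearance counts not complementary; "
            "cannot pair one object per axis"
        )
    pairs = [(a, b) for a, b in zip(pt_h, np_v)] + [(a, b) for a, b in zip(pt_v, np_h)]
    n_sel = len(pairs)
    if n_sel % 4:
        raise SchedulingError(
            f"{n_sel} selective trials not divisible by 4; exact 50/25/25 "
            "probe proportions unattainable"
        )
    kinds = _probe_template(
        {"match": n_sel // 2, "noncued": n_sel // 4, "new": n_sel // 4}, rng
    )
    pairs = [pairs[i] for i in rng.permutation(n_sel)]

    next_new = max(o.object_id for o in objects) + 1  # reserved unseen pool
    trials: list[WMTrial] = []
    for (pt_obj, np_obj), kind in zip(pairs, kinds):
        h, v = (pt_obj, np_obj) if pt_obj.axis == "horizontal" else (np_obj, pt_obj)
        if kind == "match":
            probe, resp = pt_obj.object_id, "yes"
        elif kind == "noncued":
            probe, resp = np_obj.object_id, "no"
        else:
            probe, resp = next_new, "no"
            next_new += 1
        trials.append(
            WMTrial(
                index=-1,
                object_on_horizontal_axis=h.object_id,
                object_on_vertical_axis=v.object_id,
                cue_type="selective",
                cued_axis=pt_obj.axis,
                probe_object=probe,
                probe_kind=kind,
                correct_response=resp,
            )
        )

    # --- neutral trials (Experiment 2): two NPT objects ---------------------
    if experiment == 2:
        if not npt:
            raise SchedulingError("experiment 2 requires NPT objects")
        apps = _appearances(npt, rng)
        if len(apps) % 2:
            raise SchedulingError("odd number of NPT appearances")
        neutral_pairs = _pair_distinct_positions(apps, rng)
        n_neu = len(neutral_pairs)
        if n_neu % 2:
            raise SchedulingError("neutral trial count must be even for 50/50 probes")
        kinds = _probe_template({"displayed": n_neu // 2, "absent": n_neu // 2}, rng)
        for (a, b), kind in zip(neutral_pairs, kinds):
            # exactly one of the two displayed objects can sit on each axis
            # only when axes differ; otherwise record by position order
            h, v = _axis_slots(a, b)
            if kind == "displayed":
                probe = (a if rng.random() < 0.5 else b).object_id
                resp = "yes"
            else:
                probe, resp = next_new, "no"
                next_new += 1
            trials.append(
                WMTrial(
                    index=-1,
                    object_on_horizontal_axis=h.object_id,
                    object_on_vertical_axis=v.object_id,
                    cue_type="neutral",
                    cued_axis="none",
                    probe_object=probe,
                    probe_kind=kind,
                    correct_response=resp,
                )
            )

    trials = [trials[i] for i in rng.permutation(len(trials))]
    trials = [
        WMTrial(index=i, **{k: v for k, v in t.__dict__.items() if k != "index"})
        for i, t in enumerate(trials)
    ]
    return PhaseSchedule(phase="wm", trials=trials)


def _axis_slots(a: ObjectSpec, b: ObjectSpec) -> tuple[ObjectSpec, ObjectSpec]:
    """Assign two objects to the (horizontal, vertical) display slots."""
    if a.axis == "horizontal" and b.axis == "vertical":
        return a, b
    if b.axis == "horizontal" and a.axis == "vertical":
        return b, a
    # same-axis pair (possible for neutral trials): keep stable order
    return a, b


def _pair_distinct_positions(
    apps: list[ObjectSpec], rng: np.random.Generator, max_tries: int = 200
) -> list[tuple[ObjectSpec, ObjectSpec]]:
    """Pair appearances so the two objects of a trial occupy different positions.

    Randomized greedy with restart; each appearance is used exactly once.
    """
    for _ in range(max_tries):
        pool = [apps[i] for i in rng.permutation(len(apps))]
        pairs: list[tuple[ObjectSpec, ObjectSpec]] = []
        ok = True
        while pool:
            a = pool.pop()
            j = next(
                (
                    idx
                    for idx in range(len(pool) - 1, -1, -1)
                    if pool[idx].location != a.location
                    and pool[idx].object_id != a.object_id
                ),
                None,
            )
            if j is None:
                ok = False
                break
            pairs.append((a, pool.pop(j)))
        if ok:
            return pairs
    raise SchedulingError("could not pair appearances at distinct positions")


def count_probe_instances(wm_schedule: PhaseSchedule) -> dict[int, int]:
    """How often each displayed (old) object served as the central probe.

    New-object probes are not counted. For objects shown in the WM phase the
    count lies in 0..4 (each object appears in four trials and can be probed
    at most once per trial).
    """
    counts: dict[int, int] = {}
    for t in wm_schedule.trials:
        for oid in (t.object_on_horizontal_axis, t.object_on_vertical_axis):
            counts.setdefault(oid, 0)
        if t.probe_kind in ("match", "noncued", "displayed"):
            counts[t.probe_object] = counts.get(t.probe_object, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# TSV serialization
# ---------------------------------------------------------------------------

_TSV_COLUMNS = [
    "phase",
    "trial_index",
    "object_id",
    "object_on_horizontal_axis",
    "object_on_vertical_axis",
    "cue_type",
    "cued_axis",
    "probe_object",
    "probe_kind",
    "correct_response",
]


def schedule_to_frame(schedule: PhaseSchedule) -> pd.DataFrame:
    rows = []
    if schedule.phase == "wm":
        for t in schedule.trials:
            rows.append(
                {
                    "phase": "wm",
                    "trial_index": t.index,
                    "object_id": "",
                    "object_on_horizontal_axis": t.object_on_horizontal_axis,
                    "object_on_vertical_axis": t.object_on_vertical_axis,
                    "cue_type": t.cue_type,
                    "cued_axis": t.cued_axis,
                    "probe_object": t.probe_object,
                    "probe_kind": t.probe_kind,
                    "correct_response": t.correct_response,
                }
            )
    else:
        for i, oid in enumerate(schedule.trials):
            rows.append(
                {
                    "phase": schedule.phase,
                    "trial_index": i,
                    "object_id": oid,
                    "object_on_horizontal_axis": "",
                    "object_on_vertical_axis": "",
                    "cue_type": "",
                    "cued_axis": "",
                    "probe_object": "",
                    "probe_kind": "",
                    "correct_response": "",
                }
            )
    return pd.DataFrame(rows, columns=_TSV_COLUMNS)


def schedule_to_tsv(schedule: PhaseSchedule, path=None) -> str:
    """Serialize a schedule to TSV; returns the text (also written to path)."""
    text = schedule_to_frame(schedule).to_csv(sep="\t", index=False)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def schedule_from_tsv(source) -> PhaseSchedule:
    """Inverse of :func:`schedule_to_tsv` (lossless round trip)."""
    if isinstance(source, str) and "\t" in source:
        df = pd.read_csv(io.StringIO(source), sep="\t", keep_default_na=False)
    else:
        df = pd.read_csv(source, sep="\t", keep_default_na=False)
    phase = str(df["phase"].iloc[0])
    if phase == "wm":
        trials = [
            WMTrial(
                index=int(r.trial_index),
                object_on_horizontal_axis=int(r.object_on_horizontal_axis),
                object_on_vertical_axis=int(r.object_on_vertical_axis),
                cue_type=str(r.cue_type),
                cued_axis=str(r.cued_axis),
                probe_object=int(r.probe_object),
                probe_kind=str(r.probe_kind),
                correct_response=str(r.correct_response),
            )
            for r in df.itertuples()
        ]
        return PhaseSchedule(phase="wm", trials=trials)
    return PhaseSchedule(phase=phase, trials=[int(x) for x in df["object_id"]])
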