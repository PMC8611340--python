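"""Per-participant trial schedules for the goal-relevance affect paradigm.

Each participant sees five blocks of 76 images with a momentary-affect
rating (valence and arousal sliders) after every fourth image, i.e. 19
ratings per block.  Four blocks carry the attention task: every image is
cued task-relevant or task-irrelevant, and 160 of the 304 task images carry
a target shape (circle or rectangle).  The remaining block is a passive
control block (no cues, no targets) placed either first or last.

Randomization respects the balance constraints of the original design:

* relevant/irrelevant counts are equal overall (152 each), per task block
  (38 each) and within each of the four temporal positions between two
  consecutive ratings (38 each);
* pleasant/unpleasant image counts are equal per block (38 each), per
  temporal position within the task portion, per relevance level and per
  target condition;
* no image repeats within a block (images may repeat across blocks, at most
  twice per participant).

Balance is achieved constructively for the marginal constraints and by
bounded rejection sampling for the relevance-by-valence joint count;
:func:`audit_schedule` re-checks every invariant by independent counting.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["ScheduleError", "build_schedule", "audit_schedule"]

TRIALS_PER_BLOCK = 76
WINDOW = 4  # images between consecutive affect ratings
WINDOWS_PER_BLOCK = TRIALS_PER_BLOCK // WINDOW  # 19
N_TASK_BLOCKS = 4
N_BLOCKS = N_TASK_BLOCKS + 1
TASK_TRIALS = N_TASK_BLOCKS * TRIALS_PER_BLOCK  # 304
N_TARGET_TRIALS = 160  # 52.6% of task images
MAX_ATTEMPTS = 1000

# The three complementary families of 2-subsets of the four window positions.
_PAIR_FAMILIES = (((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2)))


class ScheduleError(RuntimeError):
    """Raised when schedule constraints cannot be satisfied or fail audit."""


def _balanced_window_pairs(n_windows: int, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Pick one 2-subset of positions {0..3} per window so that each position
    is chosen in exactly half the windows (n_windows must be even)."""
    assert n_windows % 2 == 0
    half = n_windows // 2
    counts = rng.multinomial(half, [1 / 3] * 3)
    pairs: list[tuple[int, int]] = []
    for cnt, (p, q) in zip(counts, _PAIR_FAMILIES):
        pairs.extend([p] * cnt + [q] * cnt)
    order = rng.permutation(len(pairs))
    return [pairs[i] for i in order]


def _random_window_pairs(n_windows: int, rng: np.random.Generator) -> list[tuple[int, int]]:
    all_pairs = [p for fam in _PAIR_FAMILIES for p in fam]
    return [all_pairs[i] for i in rng.integers(0, 6, size=n_windows)]


def _pairs_to_flags(pairs: list[tuple[int, int]]) -> np.ndarray:
    """Expand window pairs into a flat boolean per-trial vector."""
    flags = np.zeros(len(pairs) * WINDOW, dtype=bool)
    for w, (i, j) in enumerate(pairs):
        flags[w * WINDOW + i] = True
        flags[w * WINDOW + j] = True
    return flags


def _assign_stimuli(
    ids: np.ndarray, n_blocks: int, per_block: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Distribute stimulus ids over blocks: each id used at most twice, never
    twice in the same block.  Greedy, most-remaining-uses first."""
    if len(ids) < per_block:
        raise ScheduleError(
            f"catalog category too small: {len(ids)} stimuli for {per_block} slots"
        )
    if 2 * len(ids) < n_blocks * per_block:
        raise ScheduleError("catalog too small even with two presentations per image")
    remaining = dict.fromkeys(ids.tolist(), 2)
    out = []
    for _ in range(n_blocks):
        noise = rng.random(len(ids))
        order = sorted(range(len(ids)), key=lambda k: (-remaining[ids[k]], noise[k]))
        chosen = [ids[k] for k in order if remaining[ids[k]] > 0][:per_block]
        if len(chosen) < per_block:
            raise ScheduleError("ran out of stimulus presentations")
        for sid in chosen:
            remaining[sid] -= 1
        out.append(np.array(chosen)[rng.permutation(per_block)])
    return out


def _participant_schedule(
    pid: str,
    catalog: pd.DataFrame,
    control_first: bool,
    rng: np.random.Generator,
) -> pd.DataFrame:
    n_task_windows = N_TASK_BLOCKS * WINDOWS_PER_BLOCK  # 76

    # Relevance: balanced across task windows -> equal per position and per block.
    rel_pairs = _balanced_window_pairs(n_task_windows, rng)
    rel_flags = _pairs_to_flags(rel_pairs)

    # Valence over the task portion: balanced the same way, then rejected until
    # the relevance-by-valence joint is exactly balanced (76 relevant-pleasant).
    for _ in range(MAX_ATTEMPTS):
        val_pairs = _balanced_window_pairs(n_task_windows, rng)
        val_flags = _pairs_to_flags(val_pairs)  # True = pleasant
        if int(np.sum(rel_flags & val_flags)) == TASK_TRIALS // 4:
            break
    else:
        raise ScheduleError("could not balance valence within relevance levels")
    control_val_flags = _pairs_to_flags(_random_window_pairs(WINDOWS_PER_BLOCK, rng))

    # Targets: within each valence category of the task portion, 40 circles,
    # 40 rectangles, 72 no-target, randomly placed.
    n_cat = TASK_TRIALS // 2
    n_shape = N_TARGET_TRIALS // 4
    target_by_cat = {}
    for cat in (True, False):
        labels = np.array(
            ["circle"] * n_shape + ["rectangle"] * n_shape + ["none"] * (n_cat - 2 * n_shape)
        )
        target_by_cat[cat] = labels[rng.permutation(n_cat)]

    # Stimuli: 38 of each category per block, no within-block repeats.
    per_block = TRIALS_PER_BLOCK // 2
    ids_p = catalog.loc[catalog["category"] == "pleasant", "stimulus_id"].to_numpy()
    ids_u = catalog.loc[catalog["category"] == "unpleasant", "stimulus_id"].to_numpy()
    stim_p = _assign_stimuli(ids_p, N_BLOCKS, per_block, rng)
    stim_u = _assign_stimuli(ids_u, N_BLOCKS, per_block, rng)

    control_block = 1 if control_first else N_BLOCKS
    rows = []
    task_cursor = 0  # index into the flat task-portion vectors
    cat_cursor = {True: 0, False: 0}
    for block in range(1, N_BLOCKS + 1):
        is_control = block == control_block
        stim_iter_p = iter(stim_p[block - 1])
        stim_iter_u = iter(stim_u[block - 1])
        for trial in range(1, TRIALS_PER_BLOCK + 1):
            if is_control:
                pleasant = bool(control_val_flags[trial - 1])
                relevance = "not_applicable"
                target = "none"
            else:
                pleasant = bool(val_flags[task_cursor])
                relevance = "relevant" if rel_flags[task_cursor] else "irrelevant"
                target = target_by_cat[pleasant][cat_cursor[pleasant]]
                cat_cursor[pleasant] += 1
                task_cursor += 1
            sid = next(stim_iter_p) if pleasant else next(stim_iter_u)
            rows.append(
                (
                    pid,
                    block,
                    "control" if is_control else "task",
                    trial,
                    sid,
                    "pleasant" if pleasant else "unpleasant",
                    relevance,
                    target,
                    trial % WINDOW == 0,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id",
            "block_index",
            "block_type",
            "trial_index",
            "stimulus_id",
            "category",
            "relevance",
            "target",
            "is_rating_trial",
        ],
    )


def build_schedule(
    n_participants: int,
    catalog: pd.DataFrame,
    control_position: str = "alternating",
    seed: int = 0,
) -> pd.DataFrame:
    """Build seeded per-participant trial schedules.

    Parameters
    ----------
    n_participants
        Number of independent participant schedules to generate.
    catalog
        Stimulus catalog (see :mod:`affectdyn.catalog`); needs at least 38
        stimuli per category.
    control_position
        'first', 'last', or 'alternating' (control block balanced across
        participants, matching the counterbalanced design).
    seed
        Seeds one :class:`numpy.random.SeedSequence`; per-participant streams
        are spawned from it, so schedules are reproducible bit-for-bit.
    """
    if control_position not in ("first", "last", "alternating"):
        raise ValueError("control_position must be 'first', 'last' or 'alternating'")
    children = np.random.SeedSequence(seed).spawn(n_participants)
    frames = []
    for i, child in enumerate(children):
        if control_position == "alternating":
            control_first = i % 2 == 0
        else:
            control_first = control_position == "first"
        frames.append(
            _participant_schedule(
                f"p{i:03d}", catalog, control_first, np.random.default_rng(child)
            )
        )
    schedule = pd.concat(frames, ignore_index=True)
    audit_schedule(schedule)
    return schedule


def audit_schedule(schedule: pd.DataFrame) -> None:
    """Independent counting audit of every schedule invariant.

    Recounts (rather than trusts) the construction: block sizes, rating
    cadence, target tally, relevance and valence balance at each margin, and
    within-block stimulus uniqueness.  Raises :class:`ScheduleError` on any
    violation.
    """

    def _fail(pid: str, msg: str) -> None:
        raise ScheduleError(f"participant {pid}: {msg}")

    for pid, df in schedule.groupby("participant_id", sort=False):
        if len(df) != N_BLOCKS * TRIALS_PER_BLOCK:
            _fail(pid, f"expected {N_BLOCKS * TRIALS_PER_BLOCK} trials, got {len(df)}")
        blocks = df.groupby("block_index")
        if any(len(b) != TRIALS_PER_BLOCK for _, b in blocks):
            _fail(pid, "block size != 76")
        n_control_blocks = df.loc[df["block_type"] == "control", "block_index"].nunique()
        if n_control_blocks != 1:
            _fail(pid, f"{n_control_blocks} control blocks")

        rating = df["is_rating_trial"].to_numpy()
        expected = (df["trial_index"].to_numpy() % WINDOW) == 0
        if not np.array_equal(rating, expected):
            _fail(pid, "rating trials are not every fourth trial")

        control = df[df["block_type"] == "control"]
        if not (control["relevance"] == "not_applicable").all():
            _fail(pid, "control trials carry relevance cues")
        if not (control["target"] == "none").all():
            _fail(pid, "control trials carry targets")

        task = df[df["block_type"] == "task"]
        if len(task) != TASK_TRIALS:
            _fail(pid, f"task portion has {len(task)} trials")
        if int((task["target"] != "none").sum()) != N_TARGET_TRIALS:
            _fail(pid, "task target count != 160")

        rel = task["relevance"] == "relevant"
        if int(rel.sum()) != TASK_TRIALS // 2:
            _fail(pid, "relevant/irrelevant counts unequal overall")
        position = (task["trial_index"] - 1) % WINDOW
        for pos in range(WINDOW):
            if int(rel[position == pos].sum()) != TASK_TRIALS // (2 * WINDOW):
                _fail(pid, f"relevance unbalanced at temporal position {pos + 1}")
        for b, bdf in task.groupby("block_index"):
            if int((bdf["relevance"] == "relevant").sum()) != TRIALS_PER_BLOCK // 2:
                _fail(pid, f"relevance unbalanced in block {b}")

        pleasant = df["category"] == "pleasant"
        for b, bdf in df.groupby("block_index"):
            if int((bdf["category"] == "pleasant").sum()) != TRIALS_PER_BLOCK // 2:
                _fail(pid, f"valence unbalanced in block {b}")
        task_pleasant = task["category"] == "pleasant"
        for pos in range(WINDOW):
            if int(task_pleasant[position == pos].sum()) != TASK_TRIALS // (2 * WINDOW):
                _fail(pid, f"valence unbalanced at temporal position {pos + 1}")
        for lvl in ("relevant", "irrelevant"):
            sub = task[task["relevance"] == lvl]
            if int((sub["category"] == "pleasant").sum()) != len(sub) // 2:
                _fail(pid, f"valence unbalanced within {lvl} trials")
        for tgt, sub in task.groupby("target"):
            if int((sub["category"] == "pleasant").sum()) * 2 != len(sub):
                _fail(pid, f"valence unbalanced within target condition {tgt!r}")

        for b, bdf in df.groupby("block_index"):
            if bdf["stimulus_id"].duplicated().any():
                _fail(pid, f"stimulus repeated within block {b}")
        if (df["stimulus_id"].value_counts() > 2).any():
            _fail(pid, "stimulus shown more than twice")
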