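"""Stimulus-sequence generation for the load x tone block design.

Four block types cross visual load (low, high) with the tone stream
(oddball, equiprobable control).  Each block has 360 trials of 500 ms; a
cross and a tone are presented simultaneously for 100 ms at trial onset.

Oddball stream: 550-Hz standards with 12.5% 500-Hz deviants, at least
three standards between consecutive deviants, preceded by seven warm-up
standards.  Control stream: eight tones (500..974 Hz) each at 12.5%,
arranged in sets of 8 where every set is a permutation of the eight
frequencies and the same tone never repeats across a set boundary;
preceded by the seven non-500-Hz tones in random order as warm-up.

Visual stream: crosses in 5 colors x 2 orientations.  Exactly 72 targets
and 288 non-targets; the run of non-targets preceding each target has
length 2..6; each target combination and each non-target combination
appears equally often.  Target positions are statistically and -- after
session composition -- exactly independent of tone identity: 20% of
500-Hz trials and 20% of the remaining trials carry a target.

Deviant/target placements are sampled *uniformly* over all sequences
satisfying the constraints (not greedily), via stars-and-bars for the
min-gap constraint and a dynamic-programming composition table for the
bounded-gap constraint.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Iterator, Literal, Sequence

import numpy as np
import pandas as pd

ODDBALL_FREQUENCIES = (500.0, 550.0)
CONTROL_FREQUENCIES = (500.0, 550.0, 605.0, 666.0, 732.0, 805.0, 886.0, 974.0)
DEVIANT_HZ = 500.0
STANDARD_HZ = 550.0

COLORS = ("red", "blue", "green", "yellow", "violet")
ORIENTATIONS = ("upright", "inverted")

Load = Literal["low", "high"]
ToneCondition = Literal["oddball", "control"]


class DesignError(ValueError):
    """Raised for infeasible or inconsistent block configurations."""


@dataclass(frozen=True)
class ToneEvent:
    index: int
    frequency: float
    role: str  # standard | deviant | critical | control | warmup


@dataclass(frozen=True)
class VisualEvent:
    index: int
    color: str
    orientation: str
    is_target: bool
    role: str  # main | warmup


@dataclass(frozen=True)
class BlockDesign:
    load: Load = "low"
    tone_condition: ToneCondition = "oddball"
    n_trials: int = 360
    trial_period_ms: float = 500.0
    stim_duration_ms: float = 100.0
    warmup_count: int = 7
    deviant_rate: float = 0.125
    target_rate: float = 0.20
    gap_min: int = 2  # non-targets between visual targets
    gap_max: int = 6
    min_standards_between_deviants: int = 3

    def __post_init__(self) -> None:
        n_dev = self.n_trials * self.deviant_rate
        n_tgt = self.n_trials * self.target_rate
        if abs(n_dev - round(n_dev)) > 1e-9 or abs(n_tgt - round(n_tgt)) > 1e-9:
            raise DesignError(
                f"n_trials*rate must be integral; got {n_dev} deviants, {n_tgt} targets"
            )

    @property
    def n_deviants(self) -> int:
        return round(self.n_trials * self.deviant_rate)

    @property
    def n_targets(self) -> int:
        return round(self.n_trials * self.target_rate)


def target_rule(load: Load, color: str, orientation: str) -> bool:
    """Target definition: identical stimuli in both loads, only the rule changes.

    Low load: any red cross.  High load: upright yellow or inverted green.
    """
    if load == "low":
        return color == "red"
    return (color == "yellow" and orientation == "upright") or (
        color == "green" and orientation == "inverted"
    )


def _combinations(load: Load) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """(target combos, non-target combos) under the given load rule."""
    targets, nontargets = [], []
    for c in COLORS:
        for o in ORIENTATIONS:
            (targets if target_rule(load, c, o) else nontargets).append((c, o))
    return targets, nontargets


@dataclass
class ToneSequence:
    design: BlockDesign
    frequencies: np.ndarray  # Hz, warm-up trials first
    roles: np.ndarray  # str array, "warmup" for warm-up trials
    is_warmup: np.ndarray  # bool

    @property
    def events(self) -> list[ToneEvent]:
        return [
            ToneEvent(i, float(f), str(r))
            for i, (f, r) in enumerate(zip(self.frequencies, self.roles))
        ]

    @property
    def onset_ms(self) -> np.ndarray:
        return np.arange(len(self.frequencies)) * self.design.trial_period_ms

    def __len__(self) -> int:
        return len(self.frequencies)


@dataclass
class VisualSequence:
    design: BlockDesign
    colors: np.ndarray
    orientations: np.ndarray
    is_target: np.ndarray  # bool
    is_warmup: np.ndarray  # bool

    @property
    def events(self) -> list[VisualEvent]:
        return [
            VisualEvent(i, str(c), str(o), bool(t), "warmup" if w else "main")
            for i, (c, o, t, w) in enumerate(
                zip(self.colors, self.orientations, self.is_target, self.is_warmup)
            )
        ]

    def __len__(self) -> int:
        return len(self.colors)


# ---------------------------------------------------------------------------
# uniform constrained placement


def _deviant_positions(n_trials: int, n_dev: int, min_gap: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform sample of deviant positions with >= min_gap standards between.

    Gap decomposition: g0 >= 0 standards, then for each subsequent deviant
    a gap >= min_gap, trailing gap >= 0.  Subtracting the minima leaves a
    uniform weak composition, sampled exactly by stars and bars.
    """
    n_std = n_trials - n_dev
    slack = n_std - min_gap * (n_dev - 1)
    if n_dev < 0 or (n_dev > 0 and slack < 0):
        raise DesignError(
            f"infeasible: {n_dev} deviants with min gap {min_gap} in {n_trials} trials"
        )
    if n_dev == 0:
        return np.empty(0, dtype=int)
    # weak composition of `slack` into n_dev+1 parts, uniform via stars & bars
    bars = np.sort(rng.choice(slack + n_dev, size=n_dev, replace=False))
    parts = np.diff(np.concatenate(([-1], bars, [slack + n_dev]))) - 1
    gaps = parts[:-1].copy()
    gaps[1:] += min_gap
    return np.cumsum(gaps + 1) - 1  # position of each deviant


@lru_cache(maxsize=None)
def _gap_count(total: int, k: int, lo: int, hi: int) -> int:
    """Number of compositions of `total` into k parts each in [lo, hi]."""
    if k == 0:
        return 1 if total == 0 else 0
    if total < k * lo or total > k * hi:
        return 0
    return sum(_gap_count(total - p, k - 1, lo, hi) for p in range(lo, hi + 1))


def _gap_composition(total: int, k: int, lo: int, hi: int, rng: np.random.Generator) -> list[int]:
    """Uniform composition of `total` into k parts in [lo, hi] via DP counts."""
    if _gap_count(total, k, lo, hi) == 0:
        raise DesignError(
            f"infeasible: {k} gaps in [{lo},{hi}] cannot sum to {total}"
        )
    out = []
    rem, parts_left = total, k
    for _ in range(k):
        weights = [_gap_count(rem - p, parts_left - 1, lo, hi) for p in range(lo, hi + 1)]
        tot = sum(weights)
        u = rng.random() * tot
        acc = 0.0
        for p, w in zip(range(lo, hi + 1), weights):
            acc += w
            if u < acc:
                out.append(p)
                rem -= p
                parts_left -= 1
                break
    return out


# ---------------------------------------------------------------------------
# block generators


def generate_oddball_block(design: BlockDesign, seed: int | np.random.Generator) -> ToneSequence:
    """Oddball tone stream: uniform min-gap deviant placement, 7 warm-up standards."""
    if design.tone_condition != "oddball":
        raise DesignError("design.tone_condition must be 'oddball'")
    rng = np.random.default_rng(seed)
    n, n_dev = design.n_trials, design.n_deviants
    pos = _deviant_positions(n, n_dev, design.min_standards_between_deviants, rng)
    freqs = np.full(n, STANDARD_HZ)
    roles = np.full(n, "standard", dtype=object)
    freqs[pos] = DEVIANT_HZ
    roles[pos] = "deviant"
    w = design.warmup_count
    freqs = np.concatenate([np.full(w, STANDARD_HZ), freqs])
    roles = np.concatenate([np.full(w, "warmup", dtype=object), roles])
    warm = np.zeros(n + w, dtype=bool)
    warm[:w] = True
    return ToneSequence(design, freqs, roles, warm)


def generate_control_block(
    design: BlockDesign,
    seed: int | np.random.Generator,
    frequencies: Sequence[float] = CONTROL_FREQUENCIES,
) -> ToneSequence:
    """Equiprobable control stream: sets of 8, no repeat across set boundaries.

    A set violating the boundary constraint is re-drawn whole, which keeps
    each set uniform over the permutations admissible after its predecessor.
    """
    frequencies = tuple(frequencies)
    if len(frequencies) < 2:
        raise DesignError("need at least 2 control frequencies")
    if design.n_trials % len(frequencies):
        raise DesignError(
            f"n_trials={design.n_trials} not divisible by {len(frequencies)} frequencies"
        )
    rng = np.random.default_rng(seed)
    k = len(frequencies)
    n_sets = design.n_trials // k
    freq_arr = np.asarray(frequencies)
    sets: list[np.ndarray] = []
    last = None
    for _ in range(n_sets):
        while True:
            perm = freq_arr[rng.permutation(k)]
            if last is None or perm[0] != last:
                break
        sets.append(perm)
        last = perm[-1]
    freqs = np.concatenate(sets)
    roles = np.where(freqs == DEVIANT_HZ, "critical", "control").astype(object)
    # warm-up: the seven non-critical tones, randomized
    warm_freqs = np.array([f for f in frequencies if f != DEVIANT_HZ])
    warm_freqs = warm_freqs[rng.permutation(len(warm_freqs))][: design.warmup_count]
    freqs = np.concatenate([warm_freqs, freqs])
    roles = np.concatenate([np.full(len(warm_freqs), "warmup", dtype=object), roles])
    warm = np.zeros(len(freqs), dtype=bool)
    warm[: len(warm_freqs)] = True
    return ToneSequence(design, freqs, roles, warm)


def generate_visual_block(design: BlockDesign, seed: int | np.random.Generator) -> VisualSequence:
    """Visual cross stream with gap-constrained targets and balanced combinations.

    The 72 pre-target runs of non-targets (each 2..6 long, summing to 288)
    are drawn uniformly over all valid compositions; the block ends on a
    target.  Combination labels are balanced exactly and shuffled within
    the target and non-target position sets.
    """
    rng = np.random.default_rng(seed)
    n_tgt = design.n_targets
    n_non = design.n_trials - n_tgt
    if n_tgt * design.gap_min > n_non or n_tgt * design.gap_max < n_non:
        raise DesignError(
            f"infeasible: {n_tgt} gaps in [{design.gap_min},{design.gap_max}] "
            f"cannot sum to {n_non}"
        )
    gaps = _gap_composition(n_non, n_tgt, design.gap_min, design.gap_max, rng)
    is_target = np.zeros(design.n_trials, dtype=bool)
    pos = -1
    for g in gaps:
        pos += g + 1
        is_target[pos] = True

    tgt_combos, non_combos = _combinations(design.load)
    if n_tgt % len(tgt_combos) or n_non % len(non_combos):
        raise DesignError("combination counts do not divide target/non-target counts")
    tgt_labels = np.array(tgt_combos * (n_tgt // len(tgt_combos)), dtype=object)
    non_labels = np.array(non_combos * (n_non // len(non_combos)), dtype=object)
    rng.shuffle(tgt_labels)
    rng.shuffle(non_labels)

    colors = np.empty(design.n_trials, dtype=object)
    orients = np.empty(design.n_trials, dtype=object)
    colors[is_target] = [c for c, _ in tgt_labels]
    orients[is_target] = [o for _, o in tgt_labels]
    colors[~is_target] = [c for c, _ in non_labels]
    orients[~is_target] = [o for _, o in non_labels]

    w = design.warmup_count
    warm_idx = rng.integers(0, len(non_combos), size=w)
    warm_colors = np.array([non_combos[i][0] for i in warm_idx], dtype=object)
    warm_orients = np.array([non_combos[i][1] for i in warm_idx], dtype=object)
    colors = np.concatenate([warm_colors, colors])
    orients = np.concatenate([warm_orients, orients])
    is_target = np.concatenate([np.zeros(w, dtype=bool), is_target])
    warm = np.zeros(design.n_trials + w, dtype=bool)
    warm[:w] = True
    return VisualSequence(design, colors, orients, is_target, warm)


def tone_target_counts(tones: ToneSequence, visual: VisualSequence) -> tuple[int, int]:
    """(# targets on 500-Hz trials, # targets on other trials), non-warm-up."""
    m = ~tones.is_warmup
    crit = tones.frequencies[m] == DEVIANT_HZ
    tgt = visual.is_target[~visual.is_warmup]
    return int(np.sum(tgt & crit)), int(np.sum(tgt & ~crit))


def pair_visual_with_tones(
    design: BlockDesign,
    tones: ToneSequence,
    seed: int | np.random.Generator,
    max_draws: int = 10_000,
) -> VisualSequence:
    """Draw visual blocks until target rate is exactly 20% per tone class.

    Rejection keeps the gap composition uniform *conditional* on exact
    tone-target independence (targets on exactly 20% of 500-Hz trials and
    20% of the remaining trials), the property the design guarantees.
    """
    rng = np.random.default_rng(seed)
    m = ~tones.is_warmup
    n_crit = int(np.sum(tones.frequencies[m] == DEVIANT_HZ))
    want_crit = round(n_crit * design.target_rate)
    want_other = design.n_targets - want_crit
    if abs(n_crit * design.target_rate - want_crit) > 1e-9:
        raise DesignError("target rate not integral on the 500-Hz trial class")
    for _ in range(max_draws):
        vis = generate_visual_block(design, rng)
        if tone_target_counts(tones, vis) == (want_crit, want_other):
            return vis
    raise DesignError("could not align visual targets with tone classes")


CONDITIONS: tuple[tuple[Load, ToneCondition], ...] = (
    ("low", "oddball"),
    ("low", "control"),
    ("high", "oddball"),
    ("high", "control"),
)


def compose_session(
    seed: int | np.random.Generator,
    base_design: BlockDesign | None = None,
) -> list[tuple[BlockDesign, ToneSequence, VisualSequence]]:
    """Eight blocks: the four load x tone conditions, twice, each half a
    random permutation of the four conditions.  Visual targets are exactly
    independent of tone class in every block."""
    rng = np.random.default_rng(seed)
    base = base_design or BlockDesign()
    order = [CONDITIONS[i] for i in rng.permutation(4)] + [
        CONDITIONS[i] for i in rng.permutation(4)
    ]
    session = []
    for load, tone_cond in order:
        design = replace(base, load=load, tone_condition=tone_cond)
        if tone_cond == "oddball":
            tones = generate_oddball_block(design, rng)
        else:
            tones = generate_control_block(design, rng)
        visual = pair_visual_with_tones(design, tones, rng)
        session.append((design, tones, visual))
    return session


# ---------------------------------------------------------------------------
# validation


@dataclass
class Violation:
    constraint: str
    indices: tuple[int, ...] = ()
    detail: str = ""


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def add(self, constraint: str, indices: Sequence[int] = (), detail: str = "") -> None:
        self.violations.append(Violation(constraint, tuple(int(i) for i in indices), detail))

    def __iter__(self) -> Iterator[Violation]:
        return iter(self.violations)


def _validate_tones(seq: ToneSequence, report: ValidationReport) -> None:
    d = seq.design
    m = ~seq.is_warmup
    freqs = seq.frequencies[m]
    roles = seq.roles[m]
    if d.tone_condition == "oddball":
        allowed = set(ODDBALL_FREQUENCIES)
        if not set(np.unique(freqs)) <= allowed:
            report.add("oddball_frequencies", detail=f"frequencies outside {allowed}")
        dev_idx = np.flatnonzero(roles == "deviant")
        if not np.all(freqs[dev_idx] == DEVIANT_HZ):
            report.add("deviant_frequency", dev_idx[freqs[dev_idx] != DEVIANT_HZ])
        if len(dev_idx) != d.n_deviants:
            report.add("deviant_count", detail=f"{len(dev_idx)} != {d.n_deviants}")
        gaps = np.diff(dev_idx) - 1
        bad = np.flatnonzero(gaps < d.min_standards_between_deviants)
        if bad.size:
            report.add("deviant_min_gap", dev_idx[bad + 1],
                       detail=f"gaps {gaps[bad].tolist()} < {d.min_standards_between_deviants}")
        warm_f = seq.frequencies[seq.is_warmup]
        if not np.all(warm_f == STANDARD_HZ):
            report.add("warmup_standards", np.flatnonzero(seq.is_warmup))
    else:
        k = len(CONTROL_FREQUENCIES)
        if len(freqs) % k:
            report.add("control_set_size", detail=f"{len(freqs)} trials not multiple of {k}")
        else:
            sets = freqs.reshape(-1, k)
            for i, s in enumerate(sets):
                if len(set(s.tolist())) != k:
                    report.add("control_set_permutation", (i * k,),
                               detail=f"set {i} is not a permutation")
            rep = np.flatnonzero(freqs[1:] == freqs[:-1]) + 1
            if rep.size:
                report.add("control_adjacent_repeat", rep)
        crit = np.flatnonzero(roles == "critical")
        if not np.all(freqs[crit] == DEVIANT_HZ):
            report.add("critical_frequency", crit)


def _validate_visual(seq: VisualSequence, report: ValidationReport) -> None:
    d = seq.design
    m = ~seq.is_warmup
    tgt = seq.is_target[m]
    if int(tgt.sum()) != d.n_targets:
        report.add("target_count", detail=f"{int(tgt.sum())} != {d.n_targets}")
    if int((~tgt).sum()) != d.n_trials - d.n_targets:
        report.add("nontarget_count")
    pos = np.flatnonzero(tgt)
    if pos.size:
        runs = np.diff(np.concatenate(([-1], pos))) - 1
        bad = np.flatnonzero((runs < d.gap_min) | (runs > d.gap_max))
        if bad.size:
            report.add("target_gap_range", pos[bad],
                       detail=f"runs {runs[bad].tolist()} outside [{d.gap_min},{d.gap_max}]")
    # rule consistency and combination balance
    tgt_combos, non_combos = _combinations(d.load)
    colors = seq.colors[m]
    orients = seq.orientations[m]
    rule = np.array([target_rule(d.load, c, o) for c, o in zip(colors, orients)])
    mism = np.flatnonzero(rule != tgt)
    if mism.size:
        report.add("target_rule", mism)
    for combos, mask, name in ((tgt_combos, tgt, "target"), (non_combos, ~tgt, "nontarget")):
        want = int(mask.sum()) // len(combos)
        for c, o in combos:
            got = int(np.sum((colors == c) & (orients == o) & mask))
            if got != want:
                report.add(f"{name}_combination_balance", detail=f"{c}/{o}: {got} != {want}")
    if np.any(seq.is_target[seq.is_warmup]):
        report.add("warmup_target", np.flatnonzero(seq.is_target & seq.is_warmup))


def validate_block(seq: ToneSequence | VisualSequence) -> ValidationReport:
    """Report every violated sequence invariant; never raises on bad content."""
    report = ValidationReport()
    if isinstance(seq, ToneSequence):
        _validate_tones(seq, report)
    else:
        _validate_visual(seq, report)
    return report


# ---------------------------------------------------------------------------
# serialization


def sequences_to_frame(tones: ToneSequence, visual: VisualSequence) -> pd.DataFrame:
    """Tidy event table: one row per (trial, stream)."""
    rows = []
    period = tones.design.trial_period_ms
    for i, (f, r, w) in enumerate(zip(tones.frequencies, tones.roles, tones.is_warmup)):
        rows.append((i, i * period, "tone", f"{f:g}", str(r), False, bool(w)))
    for i, (c, o, t, w) in enumerate(
        zip(visual.colors, visual.orientations, visual.is_target, visual.is_warmup)
    ):
        rows.append((i, i * period, "visual", f"{c}_{o}",
                     "warmup" if w else "main", bool(t), bool(w)))
    return pd.DataFrame(
        rows, columns=["index", "onset_ms", "stream", "value", "role", "is_target", "is_warmup"]
    )


def write_sequences_tsv(path, tones: ToneSequence, visual: VisualSequence) -> None:
    sequences_to_frame(tones, visual).to_csv(path, sep="\t", index=False)


def read_sequences_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
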