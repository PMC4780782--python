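"""Deterministic, seeded constructors of the experimental designs.

Four designs are covered:

* phoneme identification along a six-step VOT continuum (10 repetitions per
  level by default, 60 trials),
* AX (same-different) discrimination over all identical pairs and both orders
  of every adjacent one-step pair (5 repetitions each, 80 trials),
* global and partial letter report with 10 consonants under tight balance
  constraints (letter counts, per-position counts, cue coverage, no repeated
  letter within a string, no forbidden bigram),
* single-letter identification at five presentation durations.

Every builder is a pure function of its parameters and a seed: the multiset
of conditions is fixed by the design, only the presentation order is a seeded
permutation.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

DEFAULT_VOT_LEVELS = (-75, -45, -15, 15, 45, 75)

#: the 10 consonants of the letter-report tasks
DEFAULT_ALPHABET = ("B", "P", "T", "F", "L", "M", "D", "S", "R", "H")

#: digraphs / frequent French bigrams excluded from adjacent positions,
#: plus their reverses
DEFAULT_FORBIDDEN_BIGRAMS = frozenset(
    {"PH", "HP", "TH", "HT", "TR", "RT", "PL", "LP", "BR", "RB"}
)

SINGLE_LETTER_DURATIONS_MS = (33, 50, 67, 84, 101)


@dataclass(frozen=True)
class VotContinuum:
    """An ordered VOT grid in milliseconds (default -75 .. +75 in 30 ms steps)."""

    levels_ms: tuple[int, ...] = DEFAULT_VOT_LEVELS

    def __post_init__(self) -> None:
        lv = tuple(self.levels_ms)
        if len(lv) < 2 or len(lv) % 2 != 0:
            raise ValueError("continuum must have an even number (>=2) of levels")
        if any(b <= a for a, b in zip(lv, lv[1:])):
            raise ValueError("VOT levels must be strictly increasing")
        object.__setattr__(self, "levels_ms", lv)

    def adjacent_pairs(self) -> list[tuple[int, int]]:
        """Both orders of every one-step pair on the grid."""
        out = []
        for a, b in zip(self.levels_ms, self.levels_ms[1:]):
            out.append((a, b))
            out.append((b, a))
        return out

    def pair_centers(self) -> tuple[float, ...]:
        return tuple((a + b) / 2 for a, b in zip(self.levels_ms, self.levels_ms[1:]))


@dataclass(frozen=True)
class IdentificationDesign:
    trials: tuple[int, ...]
    repetitions_per_level: int
    continuum: VotContinuum = field(default_factory=VotContinuum)


@dataclass(frozen=True)
class DiscriminationDesign:
    trials: tuple[tuple[int, int], ...]
    repetitions_per_pair: int
    continuum: VotContinuum = field(default_factory=VotContinuum)


@dataclass(frozen=True)
class LetterReportDesign:
    strings: tuple[str, ...]
    alphabet: tuple[str, ...]
    mode: str  # "global" or "partial"
    cue_positions: tuple[int, ...] | None = None  # partial report only, 0-based


@dataclass(frozen=True)
class SingleLetterDesign:
    trials: tuple[tuple[str, int], ...]  # (letter, duration_ms)
    durations_ms: tuple[int, ...] = SINGLE_LETTER_DURATIONS_MS


def _permute(items: list, seed: int) -> list:
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(items))
    return [items[i] for i in order]


def build_identification_design(
    continuum: VotContinuum | None = None, reps: int = 10, seed: int = 0
) -> IdentificationDesign:
    """Balanced identification block: each continuum level `reps` times, seeded order."""
    continuum = continuum or VotContinuum()
    if reps < 1:
        raise ValueError("reps must be >= 1")
    trials = [v for v in continuum.levels_ms for _ in range(reps)]
    return IdentificationDesign(
        trials=tuple(_permute(trials, seed)),
        repetitions_per_level=reps,
        continuum=continuum,
    )


def build_discrimination_design(
    continuum: VotContinuum | None = None, reps: int = 5, seed: int = 0
) -> DiscriminationDesign:
    """AX block: every identical pair plus both orders of each adjacent pair.

    With the default continuum and ``reps=5`` this is the 80-pair block:
    6 identical pairs and 10 ordered one-step pairs, five trials each.
    """
    continuum = continuum or VotContinuum()
    if reps < 1:
        raise ValueError("reps must be >= 1")
    pairs = [(v, v) for v in continuum.levels_ms] + continuum.adjacent_pairs()
    trials = [p for p in pairs for _ in range(reps)]
    return DiscriminationDesign(
        trials=tuple(_permute(trials, seed)),
        repetitions_per_pair=reps,
        continuum=continuum,
    )


def _report_quotas(mode: str, n_letters: int) -> tuple[int, int]:
    """(n_strings, per-position count of each letter) for a report mode."""
    if mode == "global":
        return 20, 2
    if mode == "partial":
        return 50, 5
    raise ValueError(f"unknown report mode: {mode!r}")


def check_letter_report(design: LetterReportDesign) -> None:
    """Independent post-hoc verification of every letter-report invariant.

    Counts are recomputed from the emitted strings, not taken from the
    construction. Raises ``ValueError`` on the first violated constraint.
    """
    n_strings, per_pos = _report_quotas(design.mode, len(design.alphabet))
    length = 5
    total_per_letter = per_pos * length
    if len(design.strings) != n_strings:
        raise ValueError(f"expected {n_strings} strings, got {len(design.strings)}")
    letter_counts: Counter = Counter()
    pos_counts: Counter = Counter()
    for s in design.strings:
        if len(s) != length:
            raise ValueError(f"string {s!r} is not length {length}")
        if len(set(s)) != length:
            raise ValueError(f"string {s!r} repeats a letter")
        for pos, ch in enumerate(s):
            if ch not in design.alphabet:
                raise ValueError(f"letter {ch!r} outside the alphabet")
            letter_counts[ch] += 1
            pos_counts[(ch, pos)] += 1
    for ch in design.alphabet:
        if letter_counts[ch] != total_per_letter:
            raise ValueError(
                f"letter {ch} occurs {letter_counts[ch]} times, expected {total_per_letter}"
            )
        for pos in range(length):
            if pos_counts[(ch, pos)] != per_pos:
                raise ValueError(
                    f"letter {ch} at position {pos}: {pos_counts[(ch, pos)]}"
                    f" occurrences, expected {per_pos}"
                )
    if design.mode == "partial":
        if design.cue_positions is None or len(design.cue_positions) != n_strings:
            raise ValueError("partial report needs one cue per string")
        cued = Counter(
            (s[c], c) for s, c in zip(design.strings, design.cue_positions)
        )
        for ch in design.alphabet:
            for pos in range(length):
                if cued[(ch, pos)] != 1:
                    raise ValueError(
                        f"(letter, position) ({ch}, {pos}) cued {cued[(ch, pos)]}"
                        " times, expected exactly once"
                    )


def _forbidden(a: str, b: str, forbidden_bigrams: frozenset[str]) -> bool:
    return (a + b) in forbidden_bigrams


def _row_cost(row: list[str], forbidden_bigrams: frozenset[str]) -> int:
    dup = len(row) - len(set(row))
    bigr = sum(1 for a, b in zip(row, row[1:]) if _forbidden(a, b, forbidden_bigrams))
    return dup + bigr


def _row_ok(row: list[str], forbidden_bigrams: frozenset[str]) -> bool:
    return _row_cost(row, forbidden_bigrams) == 0


def _repair_grid(
    grid: list[list[str]],
    forbidden_bigrams: frozenset[str],
    rng: np.random.Generator,
    locked: set[tuple[int, int]] | None = None,
) -> bool:
    """Cost-decreasing constraint repair by within-column swaps.

    Swapping two cells of the same column preserves every column balance
    count, so only the row constraints (letter uniqueness, forbidden
    bigrams) change. A swap is kept when it strictly lowers the combined
    violation count of the two touched rows. ``locked`` cells (cued targets
    in partial report) are never moved. Returns True when every row is valid.
    """
    locked = locked or set()
    n_rows, n_cols = len(grid), len(grid[0])
    for _ in range(200):  # repair passes
        bad = [r for r in range(n_rows) if not _row_ok(grid[r], forbidden_bigrams)]
        if not bad:
            return True
        progress = False
        for r in bad:
            cost_r = _row_cost(grid[r], forbidden_bigrams)
            if cost_r == 0:
                continue
            for c in rng.permutation(n_cols):
                if (r, c) in locked:
                    continue
                done = False
                for r2 in rng.permutation(n_rows):
                    if r2 == r or (int(r2), int(c)) in locked:
                        continue
                    before = cost_r + _row_cost(grid[r2], forbidden_bigrams)
                    grid[r][c], grid[r2][c] = grid[r2][c], grid[r][c]
                    after = _row_cost(grid[r], forbidden_bigrams) + _row_cost(
                        grid[r2], forbidden_bigrams
                    )
                    if after < before:
                        progress = True
                        done = True
                        break
                    grid[r][c], grid[r2][c] = grid[r2][c], grid[r][c]
                if done:
                    break
        if not progress:
            return False
    return all(_row_ok(row, forbidden_bigrams) for row in grid)


def build_letter_report_design(
    mode: str,
    alphabet: tuple[str, ...] = DEFAULT_ALPHABET,
    forbidden_bigrams: frozenset[str] = DEFAULT_FORBIDDEN_BIGRAMS,
    seed: int = 0,
    max_attempts: int = 200,
) -> LetterReportDesign:
    """Generate a balanced letter-report stimulus set by randomized repair.

    Global report: 20 five-letter strings, each letter 10 times, exactly twice
    per position. Partial report: 50 strings, each letter 25 times, 5 per
    position, and each (letter, position) combination cued exactly once.

    Construction: each column is dealt a balanced multiset of letters (for
    partial report, the cue assignment pins one cell per (letter, position));
    rows violating the no-repeat / forbidden-bigram constraints are then
    repaired by within-column swaps, restarting up to ``max_attempts`` times.

    Raises ``RuntimeError`` if no valid set is found within ``max_attempts``
    (an over-restrictive bigram list).
    """
    alphabet = tuple(alphabet)
    if len(set(alphabet)) != len(alphabet) or len(alphabet) != 10:
        raise ValueError("alphabet must contain 10 distinct letters")
    if max_attempts < 1:
        raise ValueError("max_attempts must be >= 1")
    forbidden_bigrams = frozenset(forbidden_bigrams)
    n_strings, per_pos = _report_quotas(mode, len(alphabet))
    length = 5
    rng = np.random.default_rng(seed)

    for _ in range(max_attempts):
        cue_positions: list[int] | None = None
        locked: set[tuple[int, int]] = set()
        grid = [["" for _ in range(length)] for _ in range(n_strings)]
        if mode == "partial":
            # one trial per (letter, position) cue; seeded assignment to rows
            combos = list(itertools.product(alphabet, range(length)))
            combos = [combos[i] for i in rng.permutation(len(combos))]
            cue_positions = [pos for _, pos in combos]
            for r, (letter, pos) in enumerate(combos):
                grid[r][pos] = letter
                locked.add((r, pos))
        # deal the remaining balanced column pools
        for c in range(length):
            pool: list[str] = []
            pinned = Counter(grid[r][c] for r in range(n_strings) if grid[r][c])
            for ch in alphabet:
                pool.extend([ch] * (per_pos - pinned[ch]))
            pool = [pool[i] for i in rng.permutation(len(pool))]
            it = iter(pool)
            for r in range(n_strings):
                if not grid[r][c]:
                    grid[r][c] = next(it)
        if _repair_grid(grid, forbidden_bigrams, rng, locked):
            design = LetterReportDesign(
                strings=tuple("".join(row) for row in grid),
                alphabet=alphabet,
                mode=mode,
                cue_positions=tuple(cue_positions) if cue_positions else None,
            )
            check_letter_report(design)
            return design
    raise RuntimeError(
        f"could not satisfy letter-report constraints in {max_attempts} attempts;"
        " the forbidden-bigram list may be over-restrictive"
    )


def build_single_letter_design(
    alphabet: tuple[str, ...] = DEFAULT_ALPHABET,
    durations_ms: tuple[int, ...] = SINGLE_LETTER_DURATIONS_MS,
    seed: int = 0,
) -> SingleLetterDesign:
    """Single-letter control: each letter once at each duration (50 trials)."""
    trials = [(ch, d) for ch in alphabet for d in durations_ms]
    return SingleLetterDesign(
        trials=tuple(_permute(trials, seed)), durations_ms=tuple(durations_ms)
    )
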