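"""Variable-site extraction and simple indel coding.

A variable alignment column holds >= 2 distinct states across sequences.
Maximal runs of adjacent gap-bearing columns that share one presence/absence
pattern are grouped into single indel events (simple indel coding), so a
4 bp insertion counts as one character, not four.  One-base indels sitting
next to a homopolymer run (classically a poly-T stretch, a slippage
hotspot) can be flagged and excluded from haplotype definition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from collections import Counter
from pathlib import Path
from typing import Iterable, Sequence

from .io_align import Alignment

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class VariantColumn:
    position: int                       # 1-based alignment column
    kind: str                           # "substitution" | "gap_member"
    consensus_state: str
    observed_states: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.observed_states) < 2:
            raise ValueError(f"column {self.position}: fewer than two states")
        gap = "-" in self.observed_states
        if gap != (self.kind == "gap_member"):
            raise ValueError(f"column {self.position}: kind/gap mismatch")


@dataclass(frozen=True)
class IndelEvent:
    start: int                          # 1-based inclusive
    end: int
    homopolymer_attached: bool = False
    homopolymer_base: str | None = None

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("event end before start")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def columns(self) -> range:
        return range(self.start, self.end + 1)

    @property
    def label(self) -> str:
        return str(self.start) if self.length == 1 else f"{self.start}-{self.end}"


@dataclass(frozen=True)
class MatrixColumn:
    """One retained character of a condensed matrix."""

    label: str                          # "357" or "569-574"
    kind: str                           # "substitution" | "indel_event"
    consensus_state: str
    event: IndelEvent | None = None


@dataclass
class CondensedMatrix:
    """Sequences reduced to their states at retained variable characters."""

    columns: list[MatrixColumn]
    rows: dict[str, tuple[str, ...]]    # sequence id -> state vector
    excluded_columns: frozenset[int]    # alignment columns dropped from typing
    species: dict[str, str] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.columns)
        for seq_id, states in self.rows.items():
            if len(states) != n:
                raise ValueError(f"row {seq_id!r} has {len(states)} states, want {n}")

    @property
    def consensus(self) -> tuple[str, ...]:
        return tuple(c.consensus_state for c in self.columns)

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            if self.excluded_columns:
                excl = ",".join(str(c) for c in sorted(self.excluded_columns))
                fh.write(f"# excluded_columns\t{excl}\n")
            fh.write("id\t" + "\t".join(c.label for c in self.columns) + "\n")
            fh.write("consensus\t" + "\t".join(self.consensus) + "\n")
            for seq_id, states in self.rows.items():
                fh.write(seq_id + "\t" + "\t".join(states) + "\n")
        return path


def extract_variable_columns(aln: Alignment) -> list[VariantColumn]:
    """All columns with >= 2 distinct states.

    The consensus is the majority state; ties break to the state of the
    first sequence (and are logged).  Columns containing a gap in any
    sequence are marked ``gap_member``.
    """
    out = []
    for pos in range(1, aln.length + 1):
        states = aln.column(pos)
        distinct = set(states)
        if len(distinct) < 2:
            continue
        counts = Counter(states)
        top = counts.most_common()
        best, best_n = top[0]
        tied = [s for s, n in top if n == best_n]
        if len(tied) > 1:
            best = states[0]
            logger.info(
                "column %d: consensus tie among %s, using first-sequence state %s",
                pos, sorted(tied), best,
            )
        kind = "gap_member" if "-" in distinct else "substitution"
        out.append(
            VariantColumn(
                position=pos,
                kind=kind,
                consensus_state=best,
                observed_states=frozenset(distinct),
            )
        )
    return out


def _gap_pattern(aln: Alignment, pos: int) -> frozenset[str]:
    return frozenset(s.id for s in aln if s.residues[pos - 1] == "-")


def group_indel_events(aln: Alignment, cols: Sequence[VariantColumn]) -> list[IndelEvent]:
    """Group adjacent gap columns with identical gap patterns into events.

    Each maximal run of adjacent ``gap_member`` columns in which exactly the
    same sequences are gapped forms one event; a change in the pattern splits
    the run.
    """
    gap_positions = sorted(c.position for c in cols if c.kind == "gap_member")
    events: list[IndelEvent] = []
    run_start: int | None = None
    prev_pos: int | None = None
    prev_pat: frozenset[str] | None = None
    for pos in gap_positions:
        pat = _gap_pattern(aln, pos)
        if run_start is not None and pos == prev_pos + 1 and pat == prev_pat:
            prev_pos = pos
            continue
        if run_start is not None:
            events.append(IndelEvent(start=run_start, end=prev_pos))
        run_start, prev_pos, prev_pat = pos, pos, pat
    if run_start is not None:
        events.append(IndelEvent(start=run_start, end=prev_pos))
    return events


def _event_residues(aln: Alignment, event: IndelEvent) -> tuple[list[str], list[str]]:
    """Per-carrier residue strings over the event columns, and carrier ids."""
    carriers, residues = [], []
    for s in aln:
        chunk = s.residues[event.start - 1 : event.end]
        if "-" not in chunk:
            carriers.append(s.id)
            residues.append(chunk)
    return residues, carriers


def _flank_run(seq: str, start0: int, end0: int, base: str) -> int:
    """Longest run of `base` in the ungapped context adjacent to [start0, end0]."""
    left = 0
    i = start0 - 1
    while i >= 0:
        ch = seq[i]
        if ch == "-":
            i -= 1
            continue
        if ch != base:
            break
        left += 1
        i -= 1
    right = 0
    i = end0 + 1
    while i < len(seq):
        ch = seq[i]
        if ch == "-":
            i += 1
            continue
        if ch != base:
            break
        right += 1
        i += 1
    # the indel sits inside (or at the edge of) one homopolymer run, so the
    # two flanks belong to the same stretch and count together
    return left + right


def flag_homopolymer_indels(
    aln: Alignment,
    events: Iterable[IndelEvent],
    base: str = "T",
    min_run: int = 4,
) -> list[IndelEvent]:
    """Flag events whose residues are all `base` next to a >= min_run homopolymer.

    The inserted/deleted residues must consist solely of `base`, and the
    adjacent ungapped context (taken from the first sequence carrying the
    residues, deterministically) must contain a run of at least `min_run`
    copies of `base` on one side.
    """
    if min_run < 2:
        raise ValueError(f"min_run must be >= 2, got {min_run}")
    out = []
    for ev in events:
        residues, carriers = _event_residues(aln, ev)
        flagged = False
        if residues and all(set(r) == {base} for r in residues):
            carrier = aln.get(carriers[0])
            run = _flank_run(carrier.residues, ev.start - 1, ev.end - 1, base)
            flagged = run >= min_run
        out.append(replace(ev, homopolymer_attached=flagged,
                           homopolymer_base=base if flagged else None))
    return out


def condense(
    aln: Alignment,
    cols: Sequence[VariantColumn],
    events: Sequence[IndelEvent],
    exclude_homopolymer: bool = True,
) -> CondensedMatrix:
    """Collapse each indel event to one character and build per-sequence rows.

    Substitution columns are kept as-is; each indel event becomes one
    presence/absence character whose present state is the carried residue
    string (e.g. ``CGTCCT``) and whose absent state is ``-``.  Events flagged
    homopolymer-attached are excluded when `exclude_homopolymer` is set; their
    member columns are recorded in ``excluded_columns``.
    """
    event_cols = {pos for ev in events for pos in ev.columns}
    matrix_cols: list[tuple[int, MatrixColumn]] = []
    for c in cols:
        if c.kind == "substitution" and c.position not in event_cols:
            matrix_cols.append(
                (c.position,
                 MatrixColumn(label=str(c.position), kind="substitution",
                              consensus_state=c.consensus_state))
            )
    excluded: set[int] = set()
    for ev in events:
        if exclude_homopolymer and ev.homopolymer_attached:
            excluded.update(ev.columns)
            logger.info("excluding homopolymer-attached indel event %s", ev.label)
            continue
        # present state: majority carried residue string; absent state: "-"
        residues, _ = _event_residues(aln, ev)
        n_total = len(aln.sequences)
        n_present = len(residues)
        present_state = Counter(residues).most_common(1)[0][0] if residues else "-"
        consensus = present_state if n_present * 2 > n_total else "-"
        matrix_cols.append(
            (ev.start,
             MatrixColumn(label=ev.label, kind="indel_event",
                          consensus_state=consensus, event=ev))
        )
    matrix_cols.sort(key=lambda t: t[0])
    columns = [mc for _, mc in matrix_cols]

    rows: dict[str, tuple[str, ...]] = {}
    for s in aln:
        states = []
        for mc in columns:
            if mc.kind == "substitution":
                states.append(s.residues[int(mc.label) - 1])
            else:
                ev = mc.event
                chunk = s.residues[ev.start - 1 : ev.end]
                states.append("-" if "-" in chunk else chunk)
        rows[s.id] = tuple(states)
    return CondensedMatrix(
        columns=columns,
        rows=rows,
        excluded_columns=frozenset(excluded),
        species={s.id: s.species for s in aln},
        provenance={s.id: s.provenance for s in aln},
    )


def condense_alignment(
    aln: Alignment,
    exclude_homopolymer: bool = True,
    homopolymer_base: str = "T",
    homopolymer_min_run: int = 4,
) -> CondensedMatrix:
    """Convenience: extract columns, group + flag events, condense."""
    cols = extract_variable_columns(aln)
    events = group_indel_events(aln, cols)
    events = flag_homopolymer_indels(aln, events, base=homopolymer_base,
                                     min_run=homopolymer_min_run)
    return condense(aln, cols, events, exclude_homopolymer=exclude_homopolymer)
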