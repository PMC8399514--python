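"""Haplotype (chlorotype/ribotype) definition, assignment and classification.

A haplotype is one distinct state vector over the retained characters of a
condensed matrix.  Frequent types that are not structurally reducible to
another frequent type are designated *main* types; the remainder are
classified as local variants of one main (main + extra non-consensus
states), intermediates between two mains (ambiguity codes or mixed states
at the columns that distinguish the two), or unique.

IUPAC ambiguity characters are literal states here: an ``R`` is a state of
its own, not "A or G" — a single additive polymorphic site defines a typed
variant rather than triggering phasing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .variants import CondensedMatrix, MatrixColumn

logger = logging.getLogger(__name__)

AMBIGUITY_SETS = {
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}


def state_set(state: str) -> frozenset[str]:
    """Base set covered by a single-column state (literal for plain bases)."""
    if state in AMBIGUITY_SETS:
        return AMBIGUITY_SETS[state]
    return frozenset({state})


@dataclass(frozen=True)
class Role:
    kind: str                               # main | variant | intermediate | unique
    mains: tuple[str, ...] = ()

    def __str__(self) -> str:
        if self.kind == "variant":
            return f"variant_of({self.mains[0]})"
        if self.kind == "intermediate":
            return f"intermediate({self.mains[0]},{self.mains[1]})"
        return self.kind


MAIN = Role("main")
UNIQUE = Role("unique")


def variant_of(main: str) -> Role:
    return Role("variant", (main,))


def intermediate(m1: str, m2: str) -> Role:
    return Role("intermediate", (m1, m2))


@dataclass
class HaploType:
    name: str
    states: tuple[str, ...]
    counts: dict[str, int] = field(default_factory=dict)  # species -> n
    role: Role | None = None

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class TypeCatalog:
    marker: str
    columns: list[MatrixColumn]
    types: dict[str, HaploType]                 # name -> type, insertion-ordered
    assignment: dict[str, str]                  # sequence id -> type name

    def __post_init__(self) -> None:
        vectors = [t.states for t in self.types.values()]
        if len(set(vectors)) != len(vectors):
            raise ValueError("distinct types must have distinct state vectors")

    @property
    def consensus(self) -> tuple[str, ...]:
        return tuple(c.consensus_state for c in self.columns)

    @property
    def mains(self) -> list[HaploType]:
        return [t for t in self.types.values() if t.role == MAIN]

    def by_vector(self) -> dict[tuple[str, ...], str]:
        return {t.states: name for name, t in self.types.items()}

    def group_of(self, name: str) -> str:
        """Main type a name belongs to: itself if main, its main if a variant,
        else its own name."""
        t = self.types[name]
        if t.role is not None and t.role.kind == "variant":
            return t.role.mains[0]
        return name

    def to_tsv(self, path: str | Path) -> Path:
        """Export in the condensed-table layout: rows = types, '.' = consensus."""
        path = Path(path)
        cons = self.consensus
        with open(path, "w") as fh:
            fh.write("type\trole\tn\t" + "\t".join(c.label for c in self.columns) + "\n")
            fh.write("consensus\t\t\t" + "\t".join(cons) + "\n")
            for name, t in self.types.items():
                cells = [s if s != cons[i] else "." for i, s in enumerate(t.states)]
                role = str(t.role) if t.role is not None else ""
                fh.write(f"{name}\t{role}\t{t.total}\t" + "\t".join(cells) + "\n")
        return path


def _alpha_name(i: int) -> str:
    """A, B, ..., Z, AA, AB, ... deterministic naming by rank."""
    name = ""
    i += 1
    while i > 0:
        i, rem = divmod(i - 1, 26)
        name = chr(ord("A") + rem) + name
    return name


def define_types(
    m: CondensedMatrix,
    marker: str = "other",
    naming: str | Mapping[tuple[str, ...], str] = "alpha",
) -> TypeCatalog:
    """One type per distinct state vector, with per-species counts.

    ``naming="alpha"`` names types A, B, C, ... by descending total count,
    ties broken by first occurrence in the matrix.  A mapping from state
    vector to name may be given instead (e.g. to reproduce published type
    labels).
    """
    if not m.rows:
        raise ValueError("empty condensed matrix")
    order: list[tuple[str, ...]] = []
    members: dict[tuple[str, ...], list[str]] = {}
    for seq_id, states in m.rows.items():
        if states not in members:
            members[states] = []
            order.append(states)
        members[states].append(seq_id)
    ranked = sorted(order, key=lambda v: (-len(members[v]), order.index(v)))
    types: dict[str, HaploType] = {}
    assignment: dict[str, str] = {}
    for rank, vec in enumerate(ranked):
        if isinstance(naming, str):
            name = _alpha_name(rank)
        else:
            name = naming[vec]
        counts: dict[str, int] = {}
        for seq_id in members[vec]:
            sp = m.species.get(seq_id, "unknown")
            counts[sp] = counts.get(sp, 0) + 1
            assignment[seq_id] = name
        types[name] = HaploType(name=name, states=vec, counts=counts)
    return TypeCatalog(marker=marker, columns=list(m.columns), types=types,
                       assignment=assignment)


@dataclass(frozen=True)
class NovelAssignment:
    nearest: str
    differing_columns: tuple[str, ...]


def assign_sequence(
    states: Sequence[str], cat: TypeCatalog
) -> str | NovelAssignment:
    """Exact-state match to a catalog type, else 'novel' with the nearest type."""
    states = tuple(states)
    if len(states) != len(cat.columns):
        raise ValueError(
            f"state vector length {len(states)} != catalog columns {len(cat.columns)}"
        )
    lookup = cat.by_vector()
    if states in lookup:
        return lookup[states]
    best_name, best_cols = None, None
    for name, t in cat.types.items():
        diff = tuple(
            cat.columns[i].label for i, (a, b) in enumerate(zip(states, t.states))
            if a != b
        )
        if best_cols is None or len(diff) < len(best_cols):
            best_name, best_cols = name, diff
    return NovelAssignment(nearest=best_name, differing_columns=best_cols)


def _is_superset_of(
    t: tuple[str, ...], m: tuple[str, ...], consensus: tuple[str, ...]
) -> bool:
    """t equals m plus extra non-consensus states (m consensus wherever they differ)."""
    diff = [i for i, (a, b) in enumerate(zip(t, m)) if a != b]
    if not diff:
        return False
    return all(m[i] == consensus[i] and t[i] != consensus[i] for i in diff)


def designate_mains(cat: TypeCatalog, min_main_count: int = 10) -> TypeCatalog:
    """Designate main types and classify the rest.

    A type is main iff its total count reaches `min_main_count` and it is not
    expressible as an already-designated main plus extra non-consensus states.
    Candidates are examined in descending count order (ties by catalog order),
    so a large type is never demoted by a smaller one.  Non-mains get their
    role from :func:`classify_variant`.
    """
    cons = cat.consensus
    ordered = sorted(cat.types.values(), key=lambda t: -t.total)
    mains: list[HaploType] = []
    for t in ordered:
        if t.total >= min_main_count and not any(
            _is_superset_of(t.states, m.states, cons) for m in mains
        ):
            mains.append(t)
    new_types: dict[str, HaploType] = {}
    main_names = {m.name for m in mains}
    for name, t in cat.types.items():
        if name in main_names:
            new_types[name] = replace(t, role=MAIN)
        else:
            role = classify_variant(t, mains, cons)
            new_types[name] = replace(t, role=role)
    return TypeCatalog(marker=cat.marker, columns=cat.columns, types=new_types,
                       assignment=dict(cat.assignment))


def classify_variant(
    t: HaploType, mains: Sequence[HaploType], consensus: Sequence[str]
) -> Role:
    """Role of a non-main type relative to the designated mains.

    * ``variant_of(M)``: t = M plus extra non-consensus states, preferring a
      main for which all other mains are consensus at the extra columns.
    * ``intermediate(M1, M2)``: at every column distinguishing M1 from M2,
      t carries an ambiguity code covering both states or one of the two
      states, genuinely mixing the two mains (not collapsing onto either).
    * ``unique`` otherwise.
    """
    cons = tuple(consensus)
    mains = sorted(mains, key=lambda m: -m.total)
    if any(t.states == m.states for m in mains):
        raise ValueError(f"type {t.name} equals a main type")

    def variant_pass(strict: bool) -> Role | None:
        # strict: the extra columns must be consensus in all *other* mains too,
        # so a type straddling two mains falls through to the intermediate rule
        for m in mains:
            if not _is_superset_of(t.states, m.states, cons):
                continue
            diff = [i for i, (a, b) in enumerate(zip(t.states, m.states)) if a != b]
            others_ok = all(
                o.states[i] == cons[i] for o in mains if o is not m for i in diff
            )
            if others_ok or not strict:
                return variant_of(m.name)
        return None

    role = variant_pass(strict=True)
    if role is not None:
        return role

    def hamming(v: tuple[str, ...], w: tuple[str, ...]) -> int:
        return sum(a != b for a, b in zip(v, w))

    dist = {m.name: hamming(t.states, m.states) for m in mains}
    # candidate pairs in order of how closely t sits between the two mains;
    # within a pair the nearer (then larger) main is named first
    pairs = []
    for i1, m1 in enumerate(mains):
        for m2 in mains[i1 + 1:]:
            first, second = m1, m2
            if (dist[m2.name], -m2.total) < (dist[m1.name], -m1.total):
                first, second = m2, m1
            pairs.append((dist[m1.name] + dist[m2.name], dist[first.name],
                          -first.total, first, second))
    pairs.sort(key=lambda p: p[:3])
    for _, _, _, m1, m2 in pairs:
        d12 = [i for i, (a, b) in enumerate(zip(m1.states, m2.states)) if a != b]
        if not d12:
            continue
        ok = True
        like_m1 = like_m2 = ambig = 0
        for i in d12:
            s = t.states[i]
            both = state_set(m1.states[i]) | state_set(m2.states[i])
            if s in AMBIGUITY_SETS and both <= state_set(s):
                ambig += 1
            elif s == m1.states[i]:
                like_m1 += 1
            elif s == m2.states[i]:
                like_m2 += 1
            else:
                ok = False
                break
        restriction_m1 = all(t.states[i] == m1.states[i] for i in d12)
        restriction_m2 = all(t.states[i] == m2.states[i] for i in d12)
        # must genuinely involve both mains at their distinguishing columns,
        # not collapse onto either one
        if (ok and not restriction_m1 and not restriction_m2
                and (ambig > 0 or (like_m1 > 0 and like_m2 > 0))):
            return intermediate(m1.name, m2.name)
    role = variant_pass(strict=False)
    if role is not None:
        return role
    return UNIQUE


def tabulate_counts(cat: TypeCatalog) -> pd.DataFrame:
    """Per-type, per-species counts with role and per-role totals appended."""
    species = sorted({sp for t in cat.types.values() for sp in t.counts})
    rows = []
    for name, t in cat.types.items():
        row = {"type": name, "role": str(t.role) if t.role else "",
               "total": t.total}
        for sp in species:
            row[sp] = t.counts.get(sp, 0)
        rows.append(row)
    df = pd.DataFrame(rows)
    if not df.empty:
        role_class = df["role"].str.replace(r"\(.*\)", "", regex=True)
        totals = df.groupby(role_class)["total"].sum()
        for cls, n in totals.items():
            logger.info("role class %s: %d sequences", cls or "unclassified", n)
        df.attrs["role_totals"] = totals.to_dict()
    return df


def assign_clade(
    chlorotype: str,
    ribotypes: Iterable[str],
    chloro_cat: TypeCatalog,
    ribo_cat: TypeCatalog,
    em_chlorotype: str = "A",
    em_ribotype: str = "A",
) -> str:
    """EM/WM lineage call from one individual's chloro- and ribotypes.

    EM: chlorotype in the A group (A or a variant of A) and every ribotype in
    the ribotype-A group.  WM: chlorotype outside the A group.  Admixed:
    A-group chlorotype together with at least one non-A-group ribotype (the
    pattern of the contact-zone populations).  Undetermined otherwise.
    """
    ribotypes = list(ribotypes)
    if chlorotype not in chloro_cat.types:
        raise KeyError(f"unknown chlorotype {chlorotype!r}")
    for r in ribotypes:
        if r not in ribo_cat.types:
            raise KeyError(f"unknown ribotype {r!r}")
    chloro_em = chloro_cat.group_of(chlorotype) == em_chlorotype
    if not chloro_em:
        return "WM"
    if not ribotypes:
        return "undetermined"
    ribo_em = [ribo_cat.group_of(r) == em_ribotype for r in ribotypes]
    if all(ribo_em):
        return "EM"
    return "admixed"
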