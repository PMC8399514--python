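"""Deconvolution of superimposed intragenomic ITS paralogs from direct reads.

A direct Sanger read over an individual carrying two divergent ITS copies
shows the position-wise superposition of both templates: isolated additive
polymorphic sites (IUPAC ambiguity codes) where the copies differ by a SNP,
and a sustained run of ambiguities after the point where a length difference
(here a 6 bp insertion) throws the two templates out of register.

Given a clear reference sequence from a geographically neighbouring
homozygous individual, the second copy is recovered by base subtraction: at
every ambiguous position the member of the ambiguity set not explained by
the reference is kept.  Past the divergence breakpoint the reference
register is re-checked over candidate offsets so an unrelated reference is
rejected rather than silently mis-subtracted.

All positions in this module are 1-based *read* (degapped) coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .catalog import AMBIGUITY_SETS, state_set

logger = logging.getLogger(__name__)

_UNION_CODE = {frozenset(s): a for a, s in AMBIGUITY_SETS.items()}
for _b in "ACGT":
    _UNION_CODE[frozenset(_b)] = _b


def iupac_union(a: str, b: str) -> str:
    """IUPAC code covering the union of two base/ambiguity codes."""
    return _UNION_CODE[state_set(a) | state_set(b)]


class PhasingError(RuntimeError):
    pass


class UnresolvableTailError(PhasingError):
    """No reference offset reached the support threshold past the breakpoint."""

    def __init__(self, msg: str, partial: "PhasingResult"):
        super().__init__(msg)
        self.partial = partial


@dataclass(frozen=True)
class MixedTrace:
    read: str
    source_id: str = "trace"
    mixing: str = "balanced"            # balanced | skewed

    def __post_init__(self) -> None:
        if self.mixing not in ("balanced", "skewed"):
            raise ValueError(f"unknown mixing {self.mixing!r}")
        bad = set(self.read) - set(AMBIGUITY_SETS) - set("ACGT")
        if bad:
            raise ValueError(f"non-IUPAC characters in read: {sorted(bad)}")

    @property
    def ambiguous_positions(self) -> tuple[int, ...]:
        return tuple(i + 1 for i, ch in enumerate(self.read)
                     if ch in AMBIGUITY_SETS)


@dataclass(frozen=True)
class HetCall:
    is_heterozygous: bool
    additive_sites: tuple[int, ...]
    breakpoint: int | None = None       # 1-based read position

    def __post_init__(self) -> None:
        if self.breakpoint is not None and not self.is_heterozygous:
            raise ValueError("breakpoint without heterozygosity")


@dataclass(frozen=True)
class PhasingResult:
    ribotype_1: str                     # the reference used
    ribotype_2: str | None              # recovered copy over the resolvable window
    resolved_through: int               # last resolved read position
    mode: str                           # both_recovered | dominant_only
    reference_offset: int = 0

    def __post_init__(self) -> None:
        if self.mode == "dominant_only" and self.ribotype_2 is not None:
            raise ValueError("dominant_only result cannot carry a second copy")


@dataclass(frozen=True)
class SuperpositionModel:
    """Parameters of the two-paralog superposition."""

    indel_motif: str = "CGTCCT"
    snp_count_min: int = 1
    snp_count_max: int = 5
    minor_detection_rate: float = 0.1   # chance a minor-copy base surfaces (skewed)
    max_offset: int = 10
    support_threshold: float = 0.9

    def __post_init__(self) -> None:
        if not self.indel_motif:
            raise ValueError("indel motif must be non-empty")
        if not 0 <= self.snp_count_min <= self.snp_count_max:
            raise ValueError("invalid SNP count range")
        if not 0.0 <= self.minor_detection_rate <= 1.0:
            raise ValueError("minor detection rate outside [0, 1]")


DEFAULT_MODEL = SuperpositionModel()


def superimpose(
    t1: str, t2: str, mixing: str = "balanced", seed: int | None = None,
    model: SuperpositionModel = DEFAULT_MODEL, source_id: str = "trace",
) -> MixedTrace:
    """Forward model of a direct read over two co-amplified templates.

    Balanced mixing writes the IUPAC union of the two template bases at each
    read position; skewed mixing writes the dominant (first) template's base,
    with the minor base surfacing only at positions sampled at the minor
    detection rate.  The read ends where the shorter template ends.
    """
    for t in (t1, t2):
        if "-" in t:
            raise ValueError("superimpose takes ungapped template sequences")
    n = min(len(t1), len(t2))
    if mixing == "balanced":
        read = "".join(iupac_union(t1[k], t2[k]) for k in range(n))
    elif mixing == "skewed":
        rng = np.random.default_rng(seed)
        surfaced = rng.random(n) < model.minor_detection_rate
        read = "".join(
            iupac_union(t1[k], t2[k]) if surfaced[k] and t1[k] != t2[k] else t1[k]
            for k in range(n)
        )
    else:
        raise ValueError(f"unknown mixing {mixing!r}")
    return MixedTrace(read=read, source_id=source_id, mixing=mixing)


def detect_heterozygote(
    trace: MixedTrace, window: int = 20, min_run: int = 4
) -> HetCall:
    """Call a read heterozygous from its additive sites and ambiguity tail.

    Heterozygous iff the read carries at least one ambiguity *and* some
    window of `window` positions contains >= `min_run` ambiguities (the
    out-of-register tail).  The breakpoint is the first position of the
    first such window.  A read with only isolated additive sites is not
    called heterozygous — such sites define typed variants instead.
    """
    if window < min_run:
        raise ValueError(f"window {window} smaller than min_run {min_run}")
    sites = trace.ambiguous_positions
    breakpoint_: int | None = None
    if len(sites) >= min_run:
        arr = np.array(sites)
        for i in range(len(arr) - min_run + 1):
            if arr[i + min_run - 1] - arr[i] < window:
                breakpoint_ = int(arr[i])
                break
    is_het = bool(sites) and breakpoint_ is not None
    if sites and not is_het:
        logger.info("%s: %d isolated additive site(s), not phased",
                    trace.source_id, len(sites))
    return HetCall(is_heterozygous=is_het, additive_sites=sites,
                   breakpoint=breakpoint_ if is_het else None)


def _subtract_base(code: str, ref_base: str) -> str:
    s = state_set(code)
    if len(s) == 1:
        return code
    if ref_base in s:
        rest = s - {ref_base}
        return next(iter(rest)) if len(rest) == 1 else _UNION_CODE[frozenset(rest)]
    # reference does not explain this position; keep the full ambiguity
    return code


def _offset_support(read: str, ref: str, start0: int, offset: int) -> float:
    n = ok = 0
    for k in range(start0, len(read)):
        r = k + offset
        if not 0 <= r < len(ref):
            continue
        n += 1
        if ref[r] in state_set(read[k]):
            ok += 1
    return ok / n if n else 0.0


def subtract_reference(
    trace: MixedTrace,
    reference: str,
    model: SuperpositionModel = DEFAULT_MODEL,
    het: HetCall | None = None,
) -> PhasingResult:
    """Recover the second template of a mixed read against a clear reference.

    Before the breakpoint each ambiguity is resolved to its member not
    matching the reference.  From the breakpoint on, the reference register
    is re-scored over offsets 0, ±1..±`model.max_offset`; the best-supported
    offset (ties to the smallest shift) must explain at least
    `model.support_threshold` of the remaining positions, otherwise an
    :class:`UnresolvableTailError` carrying the truncated result is raised.

    For a balanced noise-free trace built by :func:`superimpose`, subtraction
    with either true template as reference returns the other template exactly
    over the resolvable window.
    """
    if len(reference) < len(trace.read):
        raise ValueError("reference must be at least as long as the trace")
    if trace.mixing == "skewed":
        # only the predominant copy is extracted: at the few surfaced minor
        # sites the member not explained by the reference is taken as dominant
        dominant = "".join(
            c if c not in AMBIGUITY_SETS else _subtract_base(c, reference[k])
            for k, c in enumerate(trace.read)
        )
        return PhasingResult(ribotype_1=dominant, ribotype_2=None,
                             resolved_through=len(trace.read),
                             mode="dominant_only")
    if het is None:
        het = detect_heterozygote(trace)
    read = trace.read
    bp0 = (het.breakpoint - 1) if het.breakpoint is not None else len(read)
    out = [_subtract_base(read[k], reference[k]) for k in range(bp0)]
    offset = 0
    if bp0 < len(read):
        candidates = [0]
        for o in range(1, model.max_offset + 1):
            candidates.extend((o, -o))
        scored = [(o, _offset_support(read, reference, bp0, o)) for o in candidates]
        offset, support = max(scored, key=lambda t: t[1])
        # stable preference for the smallest shift on exact ties
        for o, s in scored:
            if s == support:
                offset = o
                break
        if support < model.support_threshold:
            partial = PhasingResult(ribotype_1=reference, ribotype_2="".join(out),
                                    resolved_through=bp0, mode="both_recovered")
            raise UnresolvableTailError(
                f"{trace.source_id}: best offset {offset} explains only "
                f"{support:.2f} of the tail", partial)
        for k in range(bp0, len(read)):
            r = k + offset
            ref_base = reference[r] if 0 <= r < len(reference) else ""
            out.append(_subtract_base(read[k], ref_base))
    return PhasingResult(ribotype_1=reference, ribotype_2="".join(out),
                         resolved_through=len(read), mode="both_recovered",
                         reference_offset=offset)


def phase_individual(
    trace: MixedTrace,
    candidate_refs: Iterable[tuple[str, str, float]],
    model: SuperpositionModel = DEFAULT_MODEL,
) -> tuple[str, PhasingResult]:
    """Phase against the nearest consistent reference.

    `candidate_refs` yields ``(ref_id, sequence, geographic_distance)``.
    Candidates are tried in ascending distance (ties by id; the choice is
    logged); the first whose subtraction re-superimposes to reproduce the
    read exactly is accepted.  Returns ``(ref_id, result)``.
    """
    candidates = sorted(candidate_refs, key=lambda c: (c[2], c[0]))
    if not candidates:
        raise PhasingError("no candidate references supplied")
    if len(candidates) > 1 and candidates[0][2] == candidates[1][2]:
        logger.info("%s: tied reference distances, trying %s first by id order",
                    trace.source_id, candidates[0][0])
    errors = []
    for ref_id, ref_seq, _dist in candidates:
        if len(ref_seq) < len(trace.read):
            errors.append(f"{ref_id}: shorter than read")
            continue
        try:
            result = subtract_reference(trace, ref_seq, model=model)
        except UnresolvableTailError as exc:
            errors.append(f"{ref_id}: {exc}")
            continue
        if result.mode == "dominant_only":
            return ref_id, result
        check = superimpose(ref_seq[: len(result.ribotype_2)], result.ribotype_2)
        if check.read == trace.read:
            return ref_id, result
        errors.append(f"{ref_id}: inconsistent re-superposition")
    raise PhasingError(
        f"{trace.source_id}: all candidate references inconsistent: {errors}"
    )


def realign_recovered(recovered: str, aligned_template: str) -> str:
    """Re-insert gaps into a recovered read-coordinate sequence.

    `aligned_template` is an alignment row whose degapped sequence matches the
    recovered copy position-for-position (e.g. the alignment row of the same
    ribotype); the recovered sequence is emitted in alignment coordinates so
    it can be typed and labelled ``extracted_from_heterozygote``.
    """
    degapped_len = len(aligned_template.replace("-", ""))
    if len(recovered) != degapped_len:
        raise ValueError(
            f"recovered length {len(recovered)} != template degapped length "
            f"{degapped_len}"
        )
    out, k = [], 0
    for ch in aligned_template:
        if ch == "-":
            out.append("-")
        else:
            out.append(recovered[k])
            k += 1
    return "".join(out)
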