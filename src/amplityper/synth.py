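"""Synthetic data: reconstructed variable-site tables and simulated datasets.

Two kinds of data are produced:

* Reconstructions of the published variable-site tables for the three
  markers (trnL-trnF and rpl32-trnL chloroplast intergenic spacers, nuclear
  ITS), expanded into full-length gapped alignments with one sequence per
  sampled individual.  Only the tabulated variable columns are meaningful;
  the invariant background is filled from a fixed-seed stream so the
  alignments are byte-stable, and the poly-T context around the 1 bp
  chloroplast indels is embedded explicitly so the homopolymer rule fires.
  The population assignments and coordinates attached to these alignments
  are synthetic stand-ins (the study's sampling localities are not part of
  the tables).

* Seeded simulated datasets with the same statistical structure: a
  ubiquitous ribotype co-occurring regionally with divergent paralogous
  ribotypes (1-5 SNPs plus a 6 bp CGTCCT insertion in the last third of the
  sequence), region-specific chlorotypes, populations of two individuals,
  and a configurable fraction of heterozygous individuals whose direct
  traces superimpose two ribotypes of different length.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

from .io_align import AlignedSequence, Alignment, PopulationRecord
from .phasing import MixedTrace, superimpose
from .variants import CondensedMatrix, condense_alignment

# --------------------------------------------------------------------------
# transcribed variable-site tables
#
# positions are 1-based alignment columns; an (start, end) tuple is a
# multi-column insertion scored as one event; row tokens: "." = consensus,
# "+" = insertion present, "-" = gap/absent, else the literal state.
# --------------------------------------------------------------------------

TRNL_TRNF_TABLE = {
    "marker": "trnL-trnF",
    "length": 427,
    "positions": [48, 50, 86, 91, 160, 166, 261, 262, 293, 294, 295, 296,
                  357, 359, 366],
    "consensus": "C T T G T C - - - - - - T C T".split(),
    "rows": [
        ("A", {"cre": 55, "alb": 30, "can": 1}, False,
         ". G . T G . . . . . . . G . ."),
        ("B", {"cre": 1}, False,
         ". G G T G . . . . . . . G . ."),
        ("C", {"cre": 6, "can": 1}, False,
         "T . . . . . T . . . . . . . ."),
        ("D", {"cre": 48}, False,
         "T . . . . . T T C T T T . T -"),
        ("E", {"cre": 16}, False,
         "T . . . . T T . C T T T . T -"),
    ],
    # poly-T stretch context for the 1 bp indels at 261/262 and neutral
    # flanks for the 4 bp indel and the single-column gap at 366
    "forced_background": {254: "G", 255: "T", 256: "T", 257: "T", 258: "T",
                          259: "T", 260: "T", 292: "A", 297: "G",
                          365: "A", 367: "C"},
}

RPL32_TRNL_TABLE = {
    "marker": "rpl32-trnL",
    "length": 899,
    "positions": [194, 315, 411, 435, 739],
    "consensus": "G C G A G".split(),
    "rows": [
        ("A", {"cre": 51, "alb": 26, "can": 1}, False, ". . . . ."),
        ("B", {"cre": 3}, False, ". A . . ."),
        ("C", {"cre": 1}, False, ". . . . T"),
        ("D", {"cre": 59, "can": 1}, False, "T . T G ."),
    ],
    "forced_background": {},
}

ITS_INSERTION_MOTIF = "CGTCCT"

ITS_TABLE = {
    "marker": "ITS",
    "length": 699,
    "positions": [17, 66, 100, 111, 150, 151, 152, 153, 188, 229, 241, 386,
                  442, 453, 454, 455, 475, 526, (569, 574), 591, 598, 606,
                  632, 640, 647, 651],
    "consensus": "C G C C G T C G G C C C G C T G A C + G A G C C C C".split(),
    "rows": [
        ("A",   {"cre": 48, "alb": 3}, False,
         ". . . . . . . . . . . . . . . . . . - . . . T . . ."),
        ("A1",  {"cre": 2}, False,
         ". . . . . . . . . . . . . . . . . . - A . . T . . ."),
        ("A2",  {"cre": 1}, False,
         ". S . . . . . . . . . . . . . . . . - . . . T . . ."),
        ("A3",  {"cre": 1}, True,
         ". . . T . . . . . . . T . . . . . . - . . . T . . ."),
        ("A4",  {"cre": 1}, True,
         ". . . . T . . . . . . . . . . . . . - . . . T . . ."),
        ("A5",  {"cre": 1}, False,
         ". . . . . . . . . . . . R . . . . . - . . . T . . ."),
        ("A6",  {"cre": 1}, True,
         ". . . . . . . . . . . . . . . . R . - . . . T . . ."),
        ("A7",  {"cre": 1}, True,
         ". . . . . . . . . . . . . . . . . Y - . . . T . . ."),
        ("A8",  {"cre": 1}, True,
         ". . . . . . . . . . . . . . . . . . - . . . T . . G"),
        ("A9",  {"cre": 1}, True,
         ". . . . . . . . . . . . . . . . . . - . . . T . G G"),
        ("B",   {"alb": 13}, False,
         ". . . . . . . . . . . . . . . . . . + . . . . . . ."),
        ("B1",  {"alb": 2}, False,
         ". . . . . Y . . . . . . . . . . . . + . . . . . . ."),
        ("B2",  {"alb": 7}, False,
         ". . . . . C . . . . . . . . . . . . + . . . . . . ."),
        ("C",   {"cre": 18}, False,
         ". . . . . . . T . . . . . . C A . . + . . . . . . ."),
        ("C1",  {"cre": 1}, False,
         "S . . . . . . T . . . . . . C A . . + . . . . . . ."),
        ("C2",  {"cre": 1}, False,
         "S . . . . . . T . . M . . . C A . . + . . . . . . ."),
        ("C3",  {"cre": 1}, False,
         ". . . . . . . T . Y . . . . C A . . + . . . . . . ."),
        ("C4",  {"cre": 1}, False,
         ". . . . . . . T A . . . . . C A . . + . . . . . . ."),
        ("C5",  {"cre": 1}, False,
         ". . . . . . . T . . . . . T C A . . + . . . . . . ."),
        ("C7",  {"cre": 1}, True,
         ". . . . . . . T . . . . . . . A . . + . . . . . . ."),
        ("C8",  {"cre": 1}, False,
         ". . . . . . S T . . . . . . C A . . + . . . . . . ."),
        ("C10", {"cre": 1}, False,
         ". . Y . . . . K . . . . . . Y A . . + . R . Y . . ."),
        ("D",   {"cre": 27}, False,
         ". . . . . . . . . . . . . . . . G . + . . . . . . ."),
        ("D1",  {"cre": 1}, False,
         ". . . . . . . . . . . . . . . . G T + . . . . . . ."),
        ("D2",  {"cre": 1}, False,
         ". . . . . . . . . . . . . . . . G Y + . . . . . . ."),
        ("D3",  {"cre": 1}, True,
         ". . . . . . . . . . . . . . . . R . + . R . Y . . ."),
        ("E",   {"cre": 1}, True,
         ". . . . . . . . . . . . . . . . . . + . . . . A . ."),
        ("E1",  {"cre": 1}, True,
         ". . . . T . . . . . . . . . . . . . + . . T . A . ."),
        ("F",   {"cre": 2}, True,
         ". . T T . . . . . . . . . . . R . . + . G A T . . ."),
    ],
    "forced_background": {},
}

TABLES = {
    "trnL-trnF": TRNL_TRNF_TABLE,
    "rpl32-trnL": RPL32_TRNL_TABLE,
    "ITS": ITS_TABLE,
}

_BACKGROUND_SEED = 20210806  # fixed: fixture alignments are byte-stable


def _column_span(pos) -> tuple[int, int]:
    return (pos, pos) if isinstance(pos, int) else pos


def _expand_state(token: str, consensus: str, span: tuple[int, int]) -> str:
    """Alignment-space characters for one table cell."""
    width = span[1] - span[0] + 1
    state = consensus if token == "." else token
    if state == "+":
        assert width == len(ITS_INSERTION_MOTIF)
        return ITS_INSERTION_MOTIF
    if state == "-":
        return "-" * width
    assert width == 1
    return state


def table_consensus_sequence(table: dict, rng: np.random.Generator) -> list[str]:
    """Full-length consensus background with variable columns filled in."""
    length = table["length"]
    seq = list(rng.choice(list("ACGT"), size=length))
    for pos, base in table["forced_background"].items():
        seq[pos - 1] = base
    for pos, cons in zip(table["positions"], table["consensus"]):
        span = _column_span(pos)
        chars = _expand_state(".", cons, span)
        seq[span[0] - 1 : span[1]] = list(chars)
    return seq


@dataclass
class MarkerFixture:
    marker: str
    alignment: Alignment
    table: dict
    naming: dict[tuple[str, ...], str] = field(default_factory=dict)

    def condensed(self, exclude_homopolymer: bool = True) -> CondensedMatrix:
        """Condensed matrix with the *printed* consensus row.

        The tables state their consensus explicitly, and it is not always
        the majority state of the tabulated sequences (the most common type
        dominates several columns); the printed consensus is authoritative
        for main/variant structure, so it replaces the recomputed majority.
        """
        matrix = condense_alignment(self.alignment,
                                    exclude_homopolymer=exclude_homopolymer)
        printed: dict[str, str] = {}
        for pos, cons in zip(self.table["positions"], self.table["consensus"]):
            span = _column_span(pos)
            label = (str(span[0]) if span[0] == span[1]
                     else f"{span[0]}-{span[1]}")
            printed[label] = _expand_state(".", cons, span)
        columns = [replace(c, consensus_state=printed[c.label])
                   if c.label in printed else c
                   for c in matrix.columns]
        matrix.columns = columns
        return matrix


def _synthetic_coordinates(rng: np.random.Generator) -> tuple[float, float]:
    # Mediterranean-basin plausible stand-in coordinates (synthetic)
    return (float(np.round(rng.uniform(31.0, 45.0), 3)),
            float(np.round(rng.uniform(-9.0, 35.0), 3)))


def expand_table(table: dict) -> MarkerFixture:
    """Expand one transcribed table into a full-length gapped alignment.

    Each tabulated type contributes one sequence per counted individual;
    sequence ids encode the printed type name (``cre-D3-01``), individuals
    are paired into synthetic populations of two, and rows marked as coming
    solely from heterozygous plants carry the corresponding provenance flag.
    """
    rng = np.random.default_rng([_BACKGROUND_SEED, table["length"]])
    consensus = table_consensus_sequence(table, rng)
    sequences: list[AlignedSequence] = []
    naming: dict[tuple[str, ...], str] = {}
    for name, counts, het_only, tokens in table["rows"]:
        cells = tokens.split()
        seq = list(consensus)
        for pos, cons, token in zip(table["positions"], table["consensus"], cells):
            span = _column_span(pos)
            seq[span[0] - 1 : span[1]] = list(_expand_state(token, cons, span))
        residues = "".join(seq)
        for sp in sorted(counts):
            for i in range(counts[sp]):
                sequences.append(AlignedSequence(
                    id=f"{sp}-{name}-{i + 1:02d}",
                    residues=residues,
                    species=sp,
                    population=f"{sp}-{name}-p{i // 2 + 1:02d}",
                    provenance=("extracted_from_heterozygote" if het_only
                                else "direct"),
                ))
    aln = Alignment(sequences=sequences, marker=table["marker"])
    fixture = MarkerFixture(marker=table["marker"], alignment=aln, table=table)
    matrix = fixture.condensed(exclude_homopolymer=True)
    for seq_id, states in matrix.rows.items():
        naming.setdefault(states, seq_id.split("-")[1])
    fixture.naming = naming
    return fixture


def paper_fixtures() -> dict[str, MarkerFixture]:
    """Reconstructed table fixtures for all three markers."""
    return {marker: expand_table(table) for marker, table in TABLES.items()}


def fixture_populations(fixtures: Iterable[MarkerFixture],
                        seed: int = _BACKGROUND_SEED) -> list[PopulationRecord]:
    """Synthetic population records covering every fixture population id."""
    rng = np.random.default_rng(seed)
    records: dict[str, PopulationRecord] = {}
    for fx in fixtures:
        for s in fx.alignment:
            if s.population in records:
                continue
            lat, lon = _synthetic_coordinates(rng)
            records[s.population] = PopulationRecord(
                population=s.population, country="synthetic",
                latitude=lat, longitude=lon, species=s.species,
            )
    return list(records.values())


# --------------------------------------------------------------------------
# simulated datasets
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationSpec:
    """Study-structure parameters for the simulated datasets.

    Defaults mirror the study conditions: marker alignment lengths
    427/899/699, a 6 bp CGTCCT insertion in the last third of the ITS
    separating the ubiquitous ribotype from the regional paralogs, 1-5 SNPs
    between paralog pairs, two individuals per population and an
    intraindividual-polymorphism fraction of 0.27 within the regions where
    paralogs co-occur.
    """

    trnl_length: int = 427
    rpl32_length: int = 899
    its_length: int = 699               # aligned length; base copy is 6 shorter
    indel_motif: str = ITS_INSERTION_MOTIF
    insertion_column: int = 569         # 1-based aligned start of the motif
    snp_count_min: int = 1
    snp_count_max: int = 5
    n_regional_types: int = 3
    variants_per_main: int = 1
    populations_per_region: int = 4
    individuals_per_population: int = 2
    het_fraction: float = 0.27
    skewed_fraction: float = 0.0
    indel_probability: float = 0.5      # for free trace pairs only
    seed: int = 2021

    def __post_init__(self) -> None:
        for frac in (self.het_fraction, self.skewed_fraction,
                     self.indel_probability):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.its_length < 3 * len(self.indel_motif):
            raise ValueError("ITS length must be at least 3x the motif length")
        if not 0 <= self.snp_count_min <= self.snp_count_max:
            raise ValueError("invalid SNP count range")
        base_len = self.its_length - len(self.indel_motif)
        if not base_len * 2 // 3 <= self.insertion_column <= base_len:
            raise ValueError("insertion column must fall in the last third")


@dataclass
class SyntheticDataset:
    spec: SimulationSpec
    populations: list[PopulationRecord]
    individuals: pd.DataFrame
    trnl_alignment: Alignment
    rpl32_alignment: Alignment
    its_reads: dict[str, MixedTrace]
    its_true_alignment: Alignment       # one row per carried ribotype copy
    ribotype_sequences: dict[str, str]  # aligned, length its_length
    trnl_types: dict[str, str]
    rpl32_types: dict[str, str]


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def _mutate(seq: str, positions: Iterable[int], rng: np.random.Generator) -> str:
    s = list(seq)
    for p in positions:
        s[p] = rng.choice([b for b in "ACGT" if b != s[p]])
    return "".join(s)


def _aligned_its(ungapped: str, spec: SimulationSpec, has_insertion: bool) -> str:
    """Pad a base-copy sequence with gap columns at the insertion site."""
    col = spec.insertion_column - 1
    if has_insertion:
        return ungapped
    return ungapped[:col] + "-" * len(spec.indel_motif) + ungapped[col:]


def generate_dataset(spec: SimulationSpec = SimulationSpec()) -> SyntheticDataset:
    """Simulate a regionally structured dataset with known truth.

    Region 0 carries only the ubiquitous ribotype (the genetically
    homogeneous lineage); each further region is seeded with one regional
    ribotype co-occurring with the ubiquitous one, plus a region-specific
    chlorotype for both chloroplast markers.  A fraction of the regional
    individuals is heterozygous and contributes a superimposed direct trace.
    """
    rng = np.random.default_rng(spec.seed)
    motif_len = len(spec.indel_motif)
    base_len = spec.its_length - motif_len
    n_regions = spec.n_regional_types + 1

    ribo_a = _random_seq(rng, base_len)
    col = spec.insertion_column - 1
    # distinct SNP positions across regional ribotypes keep all types distinct
    pool = list(rng.permutation(col - 1))
    ribotypes_ungapped: dict[str, str] = {"A": ribo_a}
    has_insertion: dict[str, bool] = {"A": False}
    regional_names = []
    for r in range(spec.n_regional_types):
        k = int(rng.integers(spec.snp_count_min, spec.snp_count_max + 1)) or 1
        positions, pool = pool[:k], pool[k:]
        if len(positions) < k:
            raise ValueError("sequence too short for the requested types")
        name = f"R{r + 1}"
        mutated = _mutate(ribo_a, positions, rng)
        ribotypes_ungapped[name] = (mutated[:col] + spec.indel_motif
                                    + mutated[col:])
        has_insertion[name] = True
        regional_names.append(name)
        for v in range(spec.variants_per_main):
            vpos, pool = pool[:1], pool[1:]
            vname = f"{name}.{v + 1}"
            vseq = _mutate(ribotypes_ungapped[name],
                           [vpos[0] + (motif_len if vpos[0] >= col else 0)], rng)
            ribotypes_ungapped[vname] = vseq
            has_insertion[vname] = True

    ribotype_sequences = {
        name: _aligned_its(seq, spec, has_insertion[name])
        for name, seq in ribotypes_ungapped.items()
    }

    def chloro_catalog(length: int) -> dict[str, str]:
        base = _random_seq(rng, length)
        cat = {"A": base}
        cpool = list(rng.permutation(length))
        for r in range(spec.n_regional_types):
            m = int(rng.integers(1, 4))
            positions, cpool[:] = cpool[:m], cpool[m:]
            cat[f"R{r + 1}"] = _mutate(base, positions, rng)
        return cat

    trnl_types = chloro_catalog(spec.trnl_length)
    rpl32_types = chloro_catalog(spec.rpl32_length)

    region_centres = [(38.0 + 1.5 * r, -4.0 + 10.0 * r) for r in range(n_regions)]
    populations: list[PopulationRecord] = []
    rows = []
    trnl_seqs, rpl32_seqs, its_true = [], [], []
    its_reads: dict[str, MixedTrace] = {}
    serial = 0
    variant_used = {name: 0 for name in regional_names}
    for r in range(n_regions):
        region_ribo = None if r == 0 else regional_names[r - 1]
        chloro = "A" if r == 0 else f"R{r}"
        lat0, lon0 = region_centres[r]
        for p in range(spec.populations_per_region):
            pop = f"reg{r}-pop{p + 1:02d}"
            populations.append(PopulationRecord(
                population=pop, country=f"region{r}",
                latitude=float(np.round(lat0 + rng.uniform(-1.0, 1.0), 3)),
                longitude=float(np.round(lon0 + rng.uniform(-1.0, 1.0), 3)),
                species="cre",
            ))
            for _ in range(spec.individuals_per_population):
                serial += 1
                ind = f"ind{serial:03d}"
                het = bool(region_ribo and rng.random() < spec.het_fraction)
                if het:
                    ribos = ("A", region_ribo)
                    mixing = ("skewed" if rng.random() < spec.skewed_fraction
                              else "balanced")
                    t1 = ribotypes_ungapped["A"]
                    t2 = ribotypes_ungapped[region_ribo]
                    trace = superimpose(t1, t2, mixing=mixing,
                                        seed=int(rng.integers(2**31)),
                                        source_id=ind)
                else:
                    mixing = "none"
                    if region_ribo is None:
                        choice = "A"
                    else:
                        choice = region_ribo if rng.random() < 0.5 else "A"
                        if (spec.variants_per_main
                                and choice == region_ribo
                                and variant_used[region_ribo] < spec.variants_per_main):
                            variant_used[region_ribo] += 1
                            choice = f"{region_ribo}.{variant_used[region_ribo]}"
                    ribos = (choice,)
                    trace = MixedTrace(read=ribotypes_ungapped[choice],
                                       source_id=ind, mixing="balanced")
                its_reads[ind] = trace
                for copy in ribos:
                    its_true.append(AlignedSequence(
                        id=f"{ind}-{copy}",
                        residues=ribotype_sequences[copy],
                        species="cre", population=pop,
                        provenance=("extracted_from_heterozygote" if het
                                    else "direct"),
                    ))
                trnl_seqs.append(AlignedSequence(
                    id=ind, residues=trnl_types[chloro], species="cre",
                    population=pop))
                rpl32_seqs.append(AlignedSequence(
                    id=ind, residues=rpl32_types[chloro], species="cre",
                    population=pop))
                rows.append({"id": ind, "population": pop, "region": r,
                             "species": "cre", "chlorotype": chloro,
                             "ribotypes": ribos, "heterozygous": het,
                             "mixing": mixing})

    return SyntheticDataset(
        spec=spec,
        populations=populations,
        individuals=pd.DataFrame(rows),
        trnl_alignment=Alignment(trnl_seqs, marker="trnL-trnF"),
        rpl32_alignment=Alignment(rpl32_seqs, marker="rpl32-trnL"),
        its_reads=its_reads,
        its_true_alignment=Alignment(its_true, marker="ITS"),
        ribotype_sequences=ribotype_sequences,
        trnl_types=trnl_types,
        rpl32_types=rpl32_types,
    )


def generate_trace_pair(
    spec: SimulationSpec, seed: int,
    force_snps: int | None = None, force_indel: bool | None = None,
    mixing: str = "balanced",
) -> tuple[str, str, MixedTrace, dict]:
    """One seeded paralog pair and its superimposed trace, with truth.

    The second copy differs from the first by k SNPs (k uniform on the SNP
    range unless forced) and, with the spec's indel probability (unless
    forced), by the motif insertion at a uniform position in the last third.
    """
    rng = np.random.default_rng(seed)
    base_len = spec.its_length - len(spec.indel_motif)
    r1 = _random_seq(rng, base_len)
    k = (force_snps if force_snps is not None
         else int(rng.integers(spec.snp_count_min, spec.snp_count_max + 1)))
    snp_positions = sorted(rng.choice(base_len * 2 // 3, size=k, replace=False)
                           ) if k else []
    r2 = _mutate(r1, snp_positions, rng)
    with_indel = (force_indel if force_indel is not None
                  else bool(rng.random() < spec.indel_probability))
    insertion_point = None
    if with_indel:
        insertion_point = int(rng.integers(base_len * 2 // 3, base_len))
        r2 = r2[:insertion_point] + spec.indel_motif + r2[insertion_point:]
    trace = superimpose(r1, r2, mixing=mixing, seed=seed)
    truth = {"snps": [p + 1 for p in snp_positions],
             "insertion_point": None if insertion_point is None
             else insertion_point + 1,
             "mixing": mixing}
    return r1, r2, trace, truth
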