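"""Per-population haplotype composition, lineage summaries, KML export and
the end-to-end pipeline driver.

The composition tables answer "which types, in which populations, how
often"; the lineage (EM/WM) call combines an individual's chlorotype with
its ribotype(s).  Maps are exported as OGC KML 2.2 with one placemark per
population, the icon colour keyed to the dominant type and the icon shape
to the species (squares for C. albidus-style samples, circles otherwise).
"""

from __future__ import annotations

import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from . import network as net_mod
from . import phasing as phase_mod
from . import variants as var_mod
from .catalog import TypeCatalog, assign_clade, define_types, designate_mains
from .io_align import (Alignment, PopulationRecord, read_aligned_fasta,
                       read_population_table, read_sequences)

logger = logging.getLogger(__name__)

KML_NS = "http://www.opengis.net/kml/2.2"


@dataclass(frozen=True)
class IndividualTyping:
    """One individual's marker types, as fed into the geographic summary."""

    id: str
    population: str
    species: str = "unknown"
    chlorotype: str | None = None
    ribotypes: tuple[str, ...] = ()


@dataclass
class PopulationComposition:
    population: str
    record: PopulationRecord | None
    species: str
    type_counts: dict[str, dict[str, int]]      # marker -> type -> individuals
    clade_calls: dict[str, str]                 # individual -> EM/WM/admixed/...
    missing: dict[str, int] = field(default_factory=dict)  # marker -> n missing

    @property
    def dominant_type(self) -> dict[str, str]:
        out = {}
        for marker, counts in self.type_counts.items():
            if counts:
                out[marker] = max(sorted(counts), key=lambda t: counts[t])
        return out


def _clade_for(ind: IndividualTyping, chloro_cat: TypeCatalog | None,
               ribo_cat: TypeCatalog | None) -> str:
    has_chloro = ind.chlorotype is not None and chloro_cat is not None
    has_ribo = bool(ind.ribotypes) and ribo_cat is not None
    if not has_chloro and not has_ribo:
        return "undetermined"
    if has_chloro and has_ribo:
        return assign_clade(ind.chlorotype, ind.ribotypes, chloro_cat, ribo_cat)
    if has_chloro:
        return "EM" if chloro_cat.group_of(ind.chlorotype) == "A" else "WM"
    groups = {ribo_cat.group_of(r) for r in ind.ribotypes}
    return "EM" if groups == {"A"} else "WM"


def compose_population_table(
    individuals: Sequence[IndividualTyping],
    pops: Sequence[PopulationRecord],
    chloro_cat: TypeCatalog | None = None,
    ribo_cat: TypeCatalog | None = None,
) -> tuple[list[PopulationComposition], list[IndividualTyping]]:
    """Per-population type counts and per-individual lineage calls.

    Individuals whose population has no metadata record are returned in the
    orphans list (never silently dropped).  An individual missing one marker
    is counted under that marker's missing-data tally; the lineage call is
    made from the marker present and only degrades to ``undetermined`` when
    both markers are absent.
    """
    by_pop: dict[str, PopulationRecord] = {p.population: p for p in pops}
    orphans = [ind for ind in individuals if ind.population not in by_pop]
    if orphans:
        logger.warning("%d individual(s) with unknown population: %s",
                       len(orphans), [o.id for o in orphans])
    comps: dict[str, PopulationComposition] = {}
    for rec in pops:
        comps[rec.population] = PopulationComposition(
            population=rec.population, record=rec, species=rec.species,
            type_counts={"chloroplast": {}, "ITS": {}}, clade_calls={},
            missing={"chloroplast": 0, "ITS": 0},
        )
    for ind in individuals:
        if ind.population not in comps:
            continue
        comp = comps[ind.population]
        if ind.chlorotype is not None:
            counts = comp.type_counts["chloroplast"]
            counts[ind.chlorotype] = counts.get(ind.chlorotype, 0) + 1
        else:
            comp.missing["chloroplast"] += 1
        if ind.ribotypes:
            counts = comp.type_counts["ITS"]
            for r in ind.ribotypes:
                counts[r] = counts.get(r, 0) + 1
        else:
            comp.missing["ITS"] += 1
        comp.clade_calls[ind.id] = _clade_for(ind, chloro_cat, ribo_cat)
    return list(comps.values()), orphans


def composition_frame(comps: Iterable[PopulationComposition]) -> pd.DataFrame:
    """Long-format table: one row per population x marker x type."""
    rows = []
    for comp in comps:
        for marker, counts in sorted(comp.type_counts.items()):
            for type_name in sorted(counts):
                rows.append({
                    "population": comp.population, "marker": marker,
                    "type": type_name, "count": counts[type_name],
                    "missing": comp.missing.get(marker, 0),
                })
            if not counts:
                rows.append({"population": comp.population, "marker": marker,
                             "type": "", "count": 0,
                             "missing": comp.missing.get(marker, 0)})
    return pd.DataFrame(rows)


_KML_COLORS = ["ff0000ff", "ffff0000", "ff00ff00", "ff00ffff", "ffff00ff",
               "ffffff00", "ff000000", "ff888888", "ff0088ff", "ff8800ff"]
_SQUARE = "http://maps.google.com/mapfiles/kml/shapes/placemark_square.png"
_CIRCLE = "http://maps.google.com/mapfiles/kml/shapes/placemark_circle.png"


def export_kml(
    comps: Sequence[PopulationComposition],
    path: str | Path,
    marker: str = "chloroplast",
    square_species: str = "alb",
) -> Path:
    """One placemark per population; colour = dominant type, shape = species."""
    path = Path(path)
    ET.register_namespace("", KML_NS)
    kml = ET.Element(f"{{{KML_NS}}}kml")
    doc = ET.SubElement(kml, f"{{{KML_NS}}}Document")
    type_names = sorted({comp.dominant_type.get(marker)
                         for comp in comps if comp.dominant_type.get(marker)})
    for i, type_name in enumerate(type_names):
        for shape, href in (("square", _SQUARE), ("circle", _CIRCLE)):
            style = ET.SubElement(doc, f"{{{KML_NS}}}Style",
                                  id=f"type-{type_name}-{shape}")
            icon_style = ET.SubElement(style, f"{{{KML_NS}}}IconStyle")
            color = ET.SubElement(icon_style, f"{{{KML_NS}}}color")
            color.text = _KML_COLORS[i % len(_KML_COLORS)]
            icon = ET.SubElement(icon_style, f"{{{KML_NS}}}Icon")
            ET.SubElement(icon, f"{{{KML_NS}}}href").text = href
    for comp in comps:
        if comp.record is None:
            logger.warning("population %s: no coordinates, placemark skipped",
                           comp.population)
            continue
        dom = comp.dominant_type.get(marker)
        if dom is None:
            continue
        pm = ET.SubElement(doc, f"{{{KML_NS}}}Placemark")
        ET.SubElement(pm, f"{{{KML_NS}}}name").text = comp.population
        shape = "square" if comp.species == square_species else "circle"
        ET.SubElement(pm, f"{{{KML_NS}}}styleUrl").text = f"#type-{dom}-{shape}"
        desc = ", ".join(f"{t}:{n}" for t, n
                         in sorted(comp.type_counts[marker].items()))
        ET.SubElement(pm, f"{{{KML_NS}}}description").text = desc
        point = ET.SubElement(pm, f"{{{KML_NS}}}Point")
        coords = ET.SubElement(point, f"{{{KML_NS}}}coordinates")
        coords.text = f"{comp.record.longitude},{comp.record.latitude},0"
    tree = ET.ElementTree(kml)
    ET.indent(tree)
    tree.write(path, xml_declaration=True, encoding="unicode")
    return path


# --------------------------------------------------------------------------
# pipeline driver
# --------------------------------------------------------------------------

class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


DEFAULT_PARAMS = {
    "min_main_count": 10,
    "exclude_homopolymer": True,
    "homopolymer_base": "T",
    "homopolymer_min_run": 4,
    "phasing_window": 20,
    "phasing_min_run": 4,
    "msn_metric": "events_total",
    "its_copy_delimiter": None,
}


def _load_config(config: Mapping | str | Path) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    cfg = dict(config)
    cfg["params"] = {**DEFAULT_PARAMS, **cfg.get("params", {})}
    return cfg


def run_pipeline(config: Mapping | str | Path) -> dict:
    """Run variant extraction, typing, phasing, networks and geographic
    summaries from a single YAML-style configuration.

    Config keys: ``markers`` (marker name -> aligned FASTA path),
    ``its_reads`` (optional ungapped FASTA of direct reads), ``metadata``
    (population CSV path), ``outdir``, ``params`` (threshold overrides),
    ``seed``.  Outputs are deterministic given config + seed; every excluded
    column, tie-break and reference choice is logged.  A stage failure
    raises :class:`PipelineStageError`; outputs of earlier stages remain.
    """
    cfg = _load_config(config)
    params = cfg["params"]
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {"catalogs": {}, "params": params}

    stage = "io"
    try:
        alignments: dict[str, Alignment] = {}
        for marker, path in cfg.get("markers", {}).items():
            alignments[marker] = read_aligned_fasta(path, marker=marker)
        pops = (read_population_table(cfg["metadata"])
                if cfg.get("metadata") else [])
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc

    stage = "typing"
    try:
        for marker, aln in alignments.items():
            matrix = var_mod.condense_alignment(
                aln,
                exclude_homopolymer=params["exclude_homopolymer"],
                homopolymer_base=params["homopolymer_base"],
                homopolymer_min_run=params["homopolymer_min_run"],
            )
            cat = define_types(matrix, marker=marker)
            cat = designate_mains(cat, min_main_count=params["min_main_count"])
            results["catalogs"][marker] = cat
            safe = marker.replace("/", "_")
            matrix.to_tsv(outdir / f"condensed_{safe}.tsv")
            cat.to_tsv(outdir / f"catalog_{safe}.tsv")
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc

    stage = "phasing"
    phasing_report = []
    try:
        if cfg.get("its_reads"):
            reads = read_sequences(cfg["its_reads"])
            coords = {p.population: (p.latitude, p.longitude) for p in pops}
            traces, clean = [], []
            for s in reads:
                trace = phase_mod.MixedTrace(read=s.degapped(), source_id=s.id,
                                             mixing="balanced")
                het = phase_mod.detect_heterozygote(
                    trace, window=params["phasing_window"],
                    min_run=params["phasing_min_run"])
                if het.is_heterozygous:
                    traces.append((s, trace, het))
                else:
                    clean.append(s)
            phased_seqs = []
            for s, trace, het in traces:
                lat0, lon0 = coords.get(s.population, (0.0, 0.0))
                candidates = []
                for ref in clean:
                    lat, lon = coords.get(ref.population, (0.0, 0.0))
                    dist = ((lat - lat0) ** 2 + (lon - lon0) ** 2) ** 0.5
                    candidates.append((ref.id, ref.degapped(), dist))
                try:
                    ref_id, result = phase_mod.phase_individual(trace, candidates)
                    phased_seqs.append(AlignedSequenceLike(
                        s.id, result.ribotype_2, s.species, s.population))
                    phasing_report.append({
                        "id": s.id, "heterozygous": True,
                        "breakpoint": het.breakpoint, "mode": result.mode,
                        "reference": ref_id})
                except phase_mod.PhasingError as exc:
                    phasing_report.append({
                        "id": s.id, "heterozygous": True,
                        "breakpoint": het.breakpoint, "mode": "failed",
                        "reference": ""})
                    logger.warning("%s", exc)
            for s in clean:
                phasing_report.append({"id": s.id, "heterozygous": False,
                                       "breakpoint": None, "mode": "clean",
                                       "reference": ""})
            report = pd.DataFrame(phasing_report).sort_values("id")
            report.to_csv(outdir / "phasing_report.tsv", sep="\t", index=False)
            with open(outdir / "phased_reads.fasta", "w") as fh:
                for p in phased_seqs:
                    fh.write(f">{p.id}|{p.species}|{p.population}|"
                             f"extracted_from_heterozygote\n{p.residues}\n")
            results["phasing_report"] = report
        elif "ITS" not in alignments:
            logger.info("no ITS input: phasing skipped")
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc

    stage = "network"
    try:
        for marker, cat in results["catalogs"].items():
            if len(cat.types) < 2:
                continue
            d = net_mod.pairwise_matrix(cat, metric=params["msn_metric"])
            sizes = {name: t.total for name, t in cat.types.items()}
            species = {name: t.counts for name, t in cat.types.items()}
            net = net_mod.build_msn(d, sizes=sizes, species=species)
            safe = marker.replace("/", "_")
            d.to_tsv(outdir / f"distances_{safe}.tsv")
            net_mod.export_network(net, outdir / f"network_{safe}.graphml",
                                   format="graphml")
            net_mod.export_network(net, outdir / f"network_{safe}.dot",
                                   format="dot")
            results.setdefault("networks", {})[marker] = net
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc

    stage = "geo"
    try:
        if pops:
            chloro_marker = next(
                (m for m in ("trnL-trnF", "rpl32-trnL") if m in alignments), None)
            chloro_cat = results["catalogs"].get(chloro_marker)
            ribo_cat = results["catalogs"].get("ITS")
            delim = params["its_copy_delimiter"]
            individuals: dict[str, dict] = {}
            if chloro_cat is not None:
                for s in alignments[chloro_marker]:
                    individuals.setdefault(s.id, {
                        "population": s.population, "species": s.species,
                        "ribotypes": []})
                    individuals[s.id]["chlorotype"] = chloro_cat.assignment[s.id]
            if ribo_cat is not None:
                for s in alignments["ITS"]:
                    ind_id = s.id.split(delim)[0] if delim else s.id
                    entry = individuals.setdefault(ind_id, {
                        "population": s.population, "species": s.species,
                        "ribotypes": []})
                    entry["ribotypes"].append(ribo_cat.assignment[s.id])
            typed = [IndividualTyping(
                id=k, population=v["population"], species=v["species"],
                chlorotype=v.get("chlorotype"),
                ribotypes=tuple(v["ribotypes"]))
                for k, v in sorted(individuals.items())]
            comps, orphans = compose_population_table(
                typed, pops, chloro_cat=chloro_cat, ribo_cat=ribo_cat)
            composition_frame(comps).to_csv(
                outdir / "composition.tsv", sep="\t", index=False)
            clades = pd.DataFrame(
                [{"individual": i, "population": c.population, "clade": cl}
                 for c in comps for i, cl in sorted(c.clade_calls.items())])
            clades.to_csv(outdir / "clades.csv", index=False)
            if orphans:
                pd.DataFrame([{"id": o.id, "population": o.population}
                              for o in orphans]).to_csv(
                    outdir / "orphans.tsv", sep="\t", index=False)
            export_kml(comps, outdir / "map.kml")
            results["compositions"] = comps
            results["orphans"] = orphans
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc

    stage = "log"
    try:
        log = {"params": {k: v for k, v in params.items()},
               "seed": cfg.get("seed"),
               "markers": sorted(alignments),
               "n_sequences": {m: len(a) for m, a in alignments.items()},
               "n_types": {m: len(c.types)
                           for m, c in results["catalogs"].items()}}
        with open(outdir / "run_log.yaml", "w") as fh:
            yaml.safe_dump(log, fh, sort_keys=True)
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc
    return results


@dataclass
class AlignedSequenceLike:
    id: str
    residues: str
    species: str
    population: str
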