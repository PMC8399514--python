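"""Population composition tables, KML export and the pipeline driver."""

import xml.etree.ElementTree as ET

import pytest

from amplityper.georeport import (IndividualTyping, PipelineStageError,
                                  compose_population_table, composition_frame,
                                  export_kml, run_pipeline)
from amplityper.io_align import PopulationRecord, write_aligned_fasta, \
    write_population_table
from amplityper.synth import fixture_populations

NS = {"k": "http://www.opengis.net/kml/2.2"}


def two_pop_setup(trnl_catalog, its_catalog):
    pops = [PopulationRecord("P1", "Spain", 38.9, -1.8, "cre"),
            PopulationRecord("P2", "France", 43.5, 5.0, "alb")]
    inds = [
        IndividualTyping("i1", "P1", "cre", chlorotype="D", ribotypes=("A", "D")),
        IndividualTyping("i2", "P1", "cre", chlorotype="D", ribotypes=("D",)),
        IndividualTyping("i3", "P2", "alb", chlorotype="A", ribotypes=("B",)),
        IndividualTyping("i4", "P2", "alb", chlorotype="A", ribotypes=()),
    ]
    comps, orphans = compose_population_table(inds, pops,
                                              chloro_cat=trnl_catalog,
                                              ribo_cat=its_catalog)
    return pops, inds, comps, orphans


class TestComposePopulationTable:
    def test_known_truth_composition_recovered(self, trnl_catalog, its_catalog):
        _, _, comps, orphans = two_pop_setup(trnl_catalog, its_catalog)
        assert not orphans
        by_pop = {c.population: c for c in comps}
        assert by_pop["P1"].type_counts["chloroplast"] == {"D": 2}
        assert by_pop["P1"].type_counts["ITS"] == {"A": 1, "D": 2}
        assert by_pop["P1"].clade_calls == {"i1": "WM", "i2": "WM"}

    def test_missing_marker_does_not_downgrade_clade(self, trnl_catalog,
                                                     its_catalog):
        _, _, comps, _ = two_pop_setup(trnl_catalog, its_catalog)
        p2 = {c.population: c for c in comps}["P2"]
        assert p2.missing["ITS"] == 1
        # i4 has only its chlorotype: still called from the marker present
        assert p2.clade_calls["i4"] == "EM"

    def test_counts_conserve_individuals(self, trnl_catalog, its_catalog):
        _, inds, comps, _ = two_pop_setup(trnl_catalog, its_catalog)
        total = sum(sum(c.type_counts["chloroplast"].values()) for c in comps)
        missing = sum(c.missing["chloroplast"] for c in comps)
        assert total + missing == len(inds)

    def test_unknown_population_listed_as_orphan(self, trnl_catalog,
                                                 its_catalog):
        inds = [IndividualTyping("ghost", "NOPE", "cre", chlorotype="A")]
        comps, orphans = compose_population_table(
            inds, [PopulationRecord("P1", "x", 0.0, 0.0, "cre")],
            chloro_cat=trnl_catalog, ribo_cat=its_catalog)
        assert [o.id for o in orphans] == ["ghost"]

    def test_empty_population_list_yields_empty_table(self):
        comps, orphans = compose_population_table([], [])
        assert comps == [] and orphans == []
        assert composition_frame(comps).empty


class TestExportKml:
    def test_single_population_single_placemark(self, trnl_catalog,
                                                its_catalog, tmp_path):
        _, _, comps, _ = two_pop_setup(trnl_catalog, its_catalog)
        path = export_kml(comps[:1], tmp_path / "m.kml")
        tree = ET.parse(path)
        assert len(tree.findall(".//k:Placemark", NS)) == 1

    def test_albidus_population_gets_square_style(self, trnl_catalog,
                                                  its_catalog, tmp_path):
        _, _, comps, _ = two_pop_setup(trnl_catalog, its_catalog)
        path = export_kml(comps, tmp_path / "m.kml")
        tree = ET.parse(path)
        styles = {pm.findtext("k:name", namespaces=NS):
                  pm.findtext("k:styleUrl", namespaces=NS)
                  for pm in tree.findall(".//k:Placemark", NS)}
        assert styles["P2"].endswith("-square")
        assert styles["P1"].endswith("-circle")

    def test_round_trip_recovers_coordinates(self, trnl_catalog, its_catalog,
                                             tmp_path):
        pops, _, comps, _ = two_pop_setup(trnl_catalog, its_catalog)
        path = export_kml(comps, tmp_path / "m.kml")
        tree = ET.parse(path)
        coords = {pm.findtext("k:name", namespaces=NS):
                  pm.findtext(".//k:coordinates", namespaces=NS)
                  for pm in tree.findall(".//k:Placemark", NS)}
        lon, lat, _ = map(float, coords["P1"].split(","))
        assert (lat, lon) == (38.9, -1.8)


@pytest.fixture(scope="module")
def fixture_files(tmp_path_factory, fixtures):
    out = tmp_path_factory.mktemp("fixture_files")
    paths = {}
    for marker, fx in fixtures.items():
        p = out / (marker.replace("/", "_") + ".fasta")
        write_aligned_fasta(fx.alignment, p)
        paths[marker] = str(p)
    pops = fixture_populations(fixtures.values())
    meta = out / "pops.csv"
    write_population_table(pops, meta)
    return paths, str(meta)


class TestRunPipeline:
    def test_full_run_reproduces_type_inventories(self, fixture_files,
                                                  tmp_path):
        paths, meta = fixture_files
        res = run_pipeline({"markers": paths, "metadata": meta,
                            "outdir": str(tmp_path / "run"), "seed": 1})
        sizes = {m: len(c.types) for m, c in res["catalogs"].items()}
        assert sizes == {"trnL-trnF": 5, "rpl32-trnL": 4, "ITS": 29}
        assert (tmp_path / "run" / "map.kml").exists()

    def test_runs_are_byte_identical(self, fixture_files, tmp_path):
        paths, meta = fixture_files
        for d in ("a", "b"):
            run_pipeline({"markers": paths, "metadata": meta,
                          "outdir": str(tmp_path / d), "seed": 1})
        for p in (tmp_path / "a").iterdir():
            if p.suffix in (".tsv", ".csv", ".yaml"):
                assert p.read_bytes() == (tmp_path / "b" / p.name).read_bytes()

    def test_missing_its_runs_chloroplast_only(self, fixture_files, tmp_path):
        paths, meta = fixture_files
        chloro = {m: p for m, p in paths.items() if m != "ITS"}
        res = run_pipeline({"markers": chloro, "metadata": meta,
                            "outdir": str(tmp_path / "run"), "seed": 1})
        assert set(res["catalogs"]) == {"trnL-trnF", "rpl32-trnL"}
        assert "phasing_report" not in res

    def test_phasing_stage_recovers_heterozygous_reads(self, dataset,
                                                       tmp_path):
        from amplityper.io_align import write_population_table

        pop_of = dict(zip(dataset.individuals["id"],
                          dataset.individuals["population"]))
        reads = tmp_path / "reads.fasta"
        with open(reads, "w") as fh:
            for ind, tr in dataset.its_reads.items():
                fh.write(f">{ind}|cre|{pop_of[ind]}|direct\n{tr.read}\n")
        meta = tmp_path / "pops.csv"
        write_population_table(dataset.populations, meta)
        res = run_pipeline({"markers": {}, "its_reads": str(reads),
                            "metadata": str(meta),
                            "outdir": str(tmp_path / "run")})
        rep = res["phasing_report"]
        n_het_true = int(dataset.individuals["heterozygous"].sum())
        assert (rep["mode"] == "both_recovered").sum() == n_het_true
        assert (rep["mode"] == "clean").sum() == len(rep) - n_het_true
        phased = (tmp_path / "run" / "phased_reads.fasta").read_text()
        assert phased.count(">") == n_het_true
        assert "extracted_from_heterozygote" in phased

    def test_bad_path_raises_stage_named_error(self, tmp_path):
        with pytest.raises(PipelineStageError) as exc:
            run_pipeline({"markers": {"ITS": str(tmp_path / "missing.fasta")},
                          "outdir": str(tmp_path / "run")})
        assert exc.value.stage == "io"
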