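"""Aggregation tests: every operation against an independent brute-force
recount over the same fixture index."""

import random
from collections import Counter

import numpy as np
import pandas as pd
import pytest

from mdmine import fixtures
from mdmine.gmx_formats import MdpSummary, parse_mdp, summarize_mdp
from mdmine.harvester import DatasetRecord, FileRecord, HarvestIndex
from mdmine.inference import default_config
from mdmine.report import (crosstab_thermo_baro, ecdf, engine_distribution,
                           export_tsv, files_per_year, production_time_split,
                           round_half_away, search, tabulate_by_repository,
                           temperature_histogram, trajectory_share,
                           unknown_extension_top)


def _small_index():
    """Hand-built index: 2 repositories, 3 datasets, loose + in-zip files."""
    datasets = [
        DatasetRecord("repoA", "d1", "Gromacs molecular dynamics run",
                      "Martini bilayer", "2016-04-01"),
        DatasetRecord("repoA", "d2", "spreadsheets", "numbers", "2016-09-09"),
        DatasetRecord("repoB", "d3", "md simulation trajectory archive",
                      "solvated protein", "2020-01-15"),
    ]
    files = [
        FileRecord("repoA", "d1", "run.mdp", size_bytes=100),
        FileRecord("repoA", "d1", "traj.xtc", size_bytes=10 ** 9),
        FileRecord("repoA", "d2", "books.csv", size_bytes=50),
        FileRecord("repoA", "d2", "bundle.zip", size_bytes=200),
        FileRecord("repoA", "d2", "in/notes.txt", from_zip=True,
                   zip_parent="bundle.zip"),
        FileRecord("repoA", "d2", "in/conf.gro", from_zip=True,
                   zip_parent="bundle.zip"),
        FileRecord("repoB", "d3", "topol.top", size_bytes=70),
        FileRecord("repoB", "d3", "README", size_bytes=5),
        FileRecord("repoB", "d3", "traj.trr", size_bytes=2 * 10 ** 9),
    ]
    return HarvestIndex(datasets=datasets, files=files)


class TestTabulate:
    def test_against_brute_force(self):
        index = _small_index()
        rows = {r.repository: r for r in tabulate_by_repository(index)}
        assert rows["repoA"].dataset_count == 2
        assert rows["repoA"].loose_file_count == 4
        assert rows["repoA"].zip_file_count == 1
        assert rows["repoA"].in_zip_file_count == 2
        assert rows["repoA"].total_file_count == 6
        assert rows["repoA"].total_size_gb == pytest.approx(
            (100 + 10 ** 9 + 50 + 200) / 1e9)
        assert rows["repoA"].first_date == "2016-04-01"
        total = rows["total"]
        assert total.dataset_count == 3
        assert total.total_file_count == 9
        assert total.loose_file_count + 0 == 7
        assert total.total_file_count == total.loose_file_count + total.in_zip_file_count

    def test_single_gigabyte_unit(self):
        index = HarvestIndex(
            datasets=[DatasetRecord("r", "d", "t", "", "2020-01-01")],
            files=[FileRecord("r", "d", "big.xtc", size_bytes=10 ** 9)])
        rows = tabulate_by_repository(index)
        assert rows[0].total_size_gb == pytest.approx(1.0)

    def test_empty_index(self):
        rows = tabulate_by_repository(HarvestIndex())
        assert len(rows) == 1
        assert rows[0].repository == "total"
        assert rows[0].total_file_count == 0

    def test_totals_equal_column_sums_on_random_profile(self):
        profile = (
            fixtures.RepoProfile("r1", 7, "2015-01-01", "2020-12-31",
                                 n_loose_files=40, n_zip_files=3,
                                 n_in_zip_files=25, total_size_bytes=123456789),
            fixtures.RepoProfile("r2", 2, "2018-06-01", "2019-06-01",
                                 n_loose_files=11, n_zip_files=1,
                                 n_in_zip_files=5, total_size_bytes=987654),
        )
        index, truth = fixtures.make_index(profile, seed=3)
        rows = {r.repository: r for r in tabulate_by_repository(index)}
        for name, t in truth.items():
            r = rows[name]
            assert r.dataset_count == t["dataset_count"]
            assert r.loose_file_count == t["loose_file_count"]
            assert r.zip_file_count == t["zip_file_count"]
            assert r.in_zip_file_count == t["in_zip_file_count"]
            assert r.total_file_count == t["total_file_count"]
            assert r.total_size_gb == pytest.approx(t["total_size_bytes"] / 1e9)
        total = rows["total"]
        assert total.total_file_count == sum(
            t["total_file_count"] for t in truth.values())


class TestFilesPerYear:
    def test_counts_by_dataset_year(self):
        index = _small_index()
        per_year = files_per_year(index, by_repository=False)
        # d1 and d2 deposited 2016 (2 + 4 files incl. in-zip), d3 in 2020
        assert per_year.loc[2016] == 6
        assert per_year.loc[2020] == 3

    def test_zip_members_count_like_loose_files(self):
        index = _small_index()
        by_repo = files_per_year(index)
        brute = Counter()
        dates = {(d.repository, d.dataset_id): int(d.created_date[:4])
                 for d in index.datasets}
        for f in index.files:
            brute[(dates[(f.repository, f.dataset_id)], f.repository)] += 1
        assert dict(by_repo.items()) == dict(brute)

    def test_empty(self):
        assert files_per_year(HarvestIndex()).empty


class TestEngineDistribution:
    def test_counts_sum_to_total(self):
        index = _small_index()
        counts = engine_distribution(index)
        assert sum(counts.values()) == len(index.files)
        # d2 has no MD keyword: its files cannot claim ambiguous extensions,
        # but d3 does, so .top counts as gromacs
        assert counts["gromacs"] == 5  # mdp, xtc, gro(in zip), top, trr
        assert counts["unknown"] == 4

    def test_simple_mix(self):
        datasets = [DatasetRecord("r", "d", "plain title", "", "2020-01-01")]
        files = [FileRecord("r", "d", f"t{i}.xtc") for i in range(10)]
        files += [FileRecord("r", "d", f"n{i}.txt") for i in range(5)]
        counts = engine_distribution(HarvestIndex(datasets=datasets, files=files))
        assert counts == {"gromacs": 10, "unknown": 5}

    def test_empty(self):
        assert engine_distribution(HarvestIndex()) == {}


class TestUnknownExtensionTop:
    def _index(self, spec):
        datasets = [DatasetRecord("r", "d", "no keywords", "", "2020-01-01")]
        files = []
        for ext, n in spec.items():
            for i in range(n):
                name = f"f{len(files)}" if ext == "none" else f"f{len(files)}.{ext}"
                files.append(FileRecord("r", "d", name))
        return HarvestIndex(datasets=datasets, files=files)

    def test_lexicographic_tie_break(self):
        top = unknown_extension_top(self._index({"txt": 5, "dat": 5, "png": 1}), 2)
        assert top == [("dat", 5), ("txt", 5)]

    def test_n_larger_than_distinct(self):
        top = unknown_extension_top(self._index({"txt": 2, "none": 1}), 10)
        assert top == [("txt", 2), ("none", 1)]

    def test_md_files_excluded(self):
        top = unknown_extension_top(self._index({"xtc": 9, "txt": 1}), 5)
        assert top == [("txt", 1)]

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            unknown_extension_top(HarvestIndex(), 0)


class TestEcdf:
    def test_known_values(self):
        e = ecdf([1, 2, 2, 4])
        assert list(e.values) == [1, 2, 4]
        assert list(e.fractions) == pytest.approx([0.25, 0.75, 1.0])

    def test_single_value(self):
        e = ecdf([7.0])
        assert e(7.0) == 1.0
        assert e(6.9) == 0.0

    def test_against_brute_force(self):
        rng = random.Random(11)
        for _ in range(100):
            values = [rng.randrange(0, 20) for _ in range(rng.randrange(1, 40))]
            e = ecdf(values)
            for x in range(-1, 21):
                brute = sum(v <= x for v in values) / len(values)
                assert e(x) == pytest.approx(brute)

    def test_conserves_mass(self):
        e = ecdf([3, 1, 4, 1, 5])
        assert e.fractions[-1] == pytest.approx(1.0)
        assert np.all(np.diff(e.fractions) >= 0)


def _mdp_summary(thermostat="undefined", barostat="undefined", **kwargs):
    s = MdpSummary(**kwargs)
    s.thermostat = thermostat
    s.barostat = barostat
    return s


class TestCrossTab:
    def test_cells_and_no_coupling_group(self):
        summaries = ([_mdp_summary("v-rescale", "parrinello-rahman")] * 3
                     + [_mdp_summary()])
        ct = crosstab_thermo_baro(summaries)
        assert ct.cell("v-rescale", "parrinello-rahman") == 3
        assert ct.no_coupling_count == 1
        assert ct.grand_total == 4

    def test_permutation_invariance(self):
        a = [_mdp_summary("v-rescale", "no"), _mdp_summary("berendsen", "berendsen")]
        fwd = crosstab_thermo_baro(a)
        rev = crosstab_thermo_baro(list(reversed(a)))
        assert np.array_equal(fwd.counts, rev.counts)

    def test_grand_total_property(self):
        rng = random.Random(5)
        thermos = ["v-rescale", "berendsen", "nose-hoover", "undefined"]
        baros = ["parrinello-rahman", "c-rescale", "no", "undefined"]
        summaries = [_mdp_summary(rng.choice(thermos), rng.choice(baros))
                     for _ in range(137)]
        assert crosstab_thermo_baro(summaries).grand_total == 137


class TestTrajectoryShare:
    def test_corpus_counts_give_34_percent(self):
        profile = (fixtures.RepoProfile(
            "zenodo", 50, "2014-01-01", "2023-03-01",
            n_loose_files=sum(fixtures.GROMACS_FILE_CENSUS.values()),
            loose_extensions=fixtures.GROMACS_FILE_CENSUS),)
        index, _ = fixtures.make_index(profile, seed=0)
        share = trajectory_share(index)
        assert share.trajectory_count == 28559 + 1406
        assert share.gromacs_count == 87204
        assert share.percent == 34

    def test_no_gromacs_files_is_an_error(self):
        index = HarvestIndex(
            datasets=[DatasetRecord("r", "d", "x", "", "2020-01-01")],
            files=[FileRecord("r", "d", "a.txt")])
        with pytest.raises(ZeroDivisionError):
            trajectory_share(index)

    def test_all_trajectories(self):
        index = HarvestIndex(
            datasets=[DatasetRecord("r", "d", "x", "", "2020-01-01")],
            files=[FileRecord("r", "d", f"t{i}.xtc") for i in range(4)])
        assert trajectory_share(index).percent == 100

    def test_rounding_half_away_from_zero(self):
        assert round_half_away(33.5) == 34
        assert round_half_away(34.49) == 34
        assert round_half_away(-0.5) == -1


class TestTemperatureHistogram:
    def test_binning_rule(self):
        summaries = [_mdp_summary(ref_t_K=t) for t in (298.0, 298.9, 310.0)]
        hist = temperature_histogram(summaries, bin_width_K=2.0)
        assert hist == {298.0: 2, 310.0: 1}

    def test_absent_temperatures_excluded_and_counts_conserved(self):
        summaries = [_mdp_summary(ref_t_K=t) for t in (100.0, 305.5, 305.9)]
        summaries.append(_mdp_summary(ref_t_K=None))
        hist = temperature_histogram(summaries)
        assert sum(hist.values()) == 3

    def test_invalid_width(self):
        with pytest.raises(ValueError):
            temperature_histogram([], bin_width_K=0)


class TestProductionTimeSplit:
    def _production(self, dt, nsteps):
        return summarize_mdp(parse_mdp(
            f"integrator = md\ndt = {dt}\nnsteps = {nsteps}\ntcoupl = v-rescale\n"))

    def test_bands_and_resolution(self):
        summaries = (
            [self._production(0.02, 100_000_000)] * 2   # CG, 2000 ns
            + [self._production(0.002, 5_000_000)] * 3  # AA, 10 ns
            + [self._production(0.002, 100_000_000)] * 1  # AA, 200 ns
            + [summarize_mdp(parse_mdp("integrator = steep\n"))]  # excluded
        )
        table = production_time_split(summaries)
        assert table.loc["coarse-grain", ">1 us"] == 2
        assert table.loc["all-atom", "<=50 ns"] == 3
        assert table.loc["all-atom", "50 ns - 1 us"] == 1
        assert table.values.sum() == 6

    def test_boundary_50ns_in_lower_band(self):
        s = self._production(0.002, 25_000_000)  # exactly 50 ns
        table = production_time_split([s])
        assert table.loc["all-atom", "<=50 ns"] == 1


class TestSearch:
    def test_no_predicates_is_identity(self):
        index = _small_index()
        hits = search(index)
        assert len(hits) == len(index.files)

    def test_text_query_substring(self):
        index = _small_index()
        hits = search(index, text_query="martini")
        assert set(hits["dataset_id"]) == {"d1"}

    def test_anti_monotonicity(self):
        index = _small_index()
        broad = search(index, text_query="md")
        narrow = search(index, text_query="md", extension="xtc")
        assert len(narrow) <= len(broad)

    def test_filters_match_brute_force(self):
        index = _small_index()
        hits = search(index, repository="repoA", extension="gro")
        brute = [f for f in index.files
                 if f.repository == "repoA" and f.extension == "gro"]
        assert len(hits) == len(brute)
        assert list(hits["file_name"]) == sorted(f.file_name for f in brute)

    def test_engine_filter(self):
        index = _small_index()
        hits = search(index, engine="gromacs")
        assert set(hits["extension"]) == {"mdp", "xtc", "gro", "top", "trr"}

    def test_numeric_range_needs_summary_table(self):
        index = _small_index()
        with pytest.raises(ValueError):
            search(index, n_particles_range=(100, None))

    def test_particle_range_filter(self):
        index = _small_index()
        gro = pd.DataFrame([
            {"repository": "repoA", "dataset_id": "d2",
             "file_name": "in/conf.gro", "n_particles": 2_000_000},
        ])
        hits = search(index, extension="gro",
                      n_particles_range=(10 ** 6, None), gro_summaries=gro)
        assert list(hits["file_name"]) == ["in/conf.gro"]
        none = search(index, extension="gro",
                      n_particles_range=(None, 10 ** 5), gro_summaries=gro)
        assert none.empty


class TestExportTsv:
    def test_round_trip(self, tmp_path):
        table = pd.DataFrame({"a": [1, 2], "b": ["x", "y"], "c": [0.5, 1.5]})
        path = export_tsv(table, tmp_path / "t.tsv")
        back = pd.read_csv(path, sep="\t")
        pd.testing.assert_frame_equal(back, table)

    def test_empty_table_header_only(self, tmp_path):
        path = export_tsv(pd.DataFrame(columns=["x", "y"]), tmp_path / "e.tsv")
        assert path.read_text(encoding="utf-8") == "x\ty\n"

    def test_embedded_tabs_and_newlines_sanitized(self, tmp_path):
        table = pd.DataFrame({"desc": ["has\ttab", "has\nnewline"]})
        path = export_tsv(table, tmp_path / "s.tsv")
        lines = path.read_text(encoding="utf-8").splitlines()
        assert lines == ["desc", "has tab", "has newline"]
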