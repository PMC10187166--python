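import json

import pytest

from mdmine import fixtures

WATER_GRO = (
    "single TIP3P water\n"
    "    3\n"
    "    1SOL     OW    1   1.000   1.000   1.000\n"
    "    1SOL    HW1    2   1.100   1.000   1.000\n"
    "    1SOL    HW2    3   1.000   1.100   1.000\n"
    "   2.00000   2.00000   2.00000\n"
)


def mock_repo_spec(name="zenodo-like", dialect="zenodo", **overrides):
    """A small mock repository: 3 datasets, one MD-related with a zip."""
    spec = {
        "name": name,
        "dialect": dialect,
        "datasets": [
            {
                "id": "ds-md",
                "title": "Gromacs molecular dynamics of a POPC bilayer",
                "description": "Martini coarse-grain simulations.",
                "created_date": "2021-06-01",
                "files": [
                    {"name": "run.mdp", "size": 1024},
                    {"name": "notes.txt", "size": 64},
                ],
                "zips": [
                    {"name": "traj.zip", "size": 4096, "entries": [
                        {"path": "a/md.xtc", "size": 100},
                        {"path": "a/conf.gro", "size": 50},
                        {"path": "a/fig.png", "size": 1},
                        {"path": "b/table.dat", "size": 2},
                    ]},
                ],
            },
            {
                "id": "ds-photos",
                "title": "Holiday photographs",
                "description": "Nothing molecular here.",
                "created_date": "2020-05-05",
                "files": [{"name": "img1.png", "size": 3}],
                "zips": [],
            },
            {
                "id": "ds-unrelated",
                "title": "Spreadsheet archive",
                "description": "Accounting tables.",
                "created_date": "2019-03-03",
                "files": [{"name": "books.xlsx", "size": 7}],
                "zips": [],
            },
        ],
    }
    spec.update(overrides)
    return spec


@pytest.fixture
def mock_adapter():
    return fixtures.make_mock_repository(mock_repo_spec())


@pytest.fixture
def mock_repo_json(tmp_path):
    path = tmp_path / "repo.json"
    path.write_text(json.dumps(mock_repo_spec()), encoding="utf-8")
    return path
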