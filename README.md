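# mdmine

Molecular-dynamics (MD) simulation files are scattered across generalist
data repositories — Zenodo, Figshare, the Open Science Framework — where
they are technically public but effectively dark: not indexed as MD data,
not searchable by system or simulation parameters, and often buried inside
zip archives. `mdmine` is a toolkit for shedding light on that data. It

* **harvests** repositories with an *Explore-and-Expand* strategy:
  *Explore* finds datasets through MD-specific file extensions (``.xtc``,
  ``.gro``, ``.mdp``, ``.prmtop``, ``.psf``, ...), optionally combined
  with MD keywords for ambiguous extensions; *Expand* then indexes every
  file of each hit dataset, including zip-archive members recovered from
  the repository's content preview; a final cleaning pass drops datasets
  that turn out to contain no trusted MD file type;
* **parses** Gromacs files natively — fixed-column ``.gro`` coordinates,
  ``key = value`` ``.mdp`` run parameters, ``.xtc`` XDR binary
  trajectories (header-only frame counting, no coordinate decoding) and
  ``.log`` run logs;
* **infers** metadata by auditable rules: engine assignment by extension,
  molecular composition from a curated residue-name lexicon (protein /
  lipid / nucleic / glucid / water-ions), system classification by solute
  content, all-atom vs coarse-grain from the integration time step
  (dt ≥ 10 fs ⇒ coarse-grain), production-run detection (``md``/``sd``
  integrator and planned time > 1 ns), and thermostat/barostat
  normalisation onto the Gromacs vocabularies;
* **profiles** the corpus: per-repository totals, files per deposition
  year, engine distributions, planned simulation time `t = dt × nsteps`,
  thermostat × barostat cross-tabulations, temperature histograms,
  cumulative distributions of system sizes and frame counts — plus a
  keyword/filter search exported as TSV.

Repositories sit behind a three-method adapter contract, so the whole
pipeline runs identically against live REST APIs and against in-memory
mock repositories, and every input format has a deterministic synthetic
generator (`mdmine.fixtures`) that returns the artefact together with the
ground truth its parser must reproduce.

## Worked example

```python
from mdmine import fixtures, report
from mdmine.harvester import default_queries, run_harvest
from mdmine.gmx_formats import parse_mdp, summarize_mdp
from mdmine.inference import infer_resolution, infer_run_type

# harvest a mock repository holding one MD dataset with a zip archive
adapter = fixtures.make_mock_repository({
    "name": "zenodo-like", "dialect": "zenodo", "datasets": [
        {"id": "d1", "title": "Gromacs molecular dynamics of a POPC bilayer",
         "description": "Martini simulations", "created_date": "2021-06-01",
         "files": [{"name": "run.mdp", "size": 1024}],
         "zips": [{"name": "traj.zip", "size": 4096, "entries": [
             {"path": "a/md.xtc", "size": 100},
             {"path": "a/conf.gro", "size": 50}]}]}]})
index = run_harvest([adapter], default_queries())
print(len(index.datasets), len(index.files))
# 1 4            <- the dataset, its mdp, the zip, and 2 zip members

row = report.tabulate_by_repository(index)[-1]
print(row.loose_file_count, row.in_zip_file_count, row.total_file_count)
# 2 2 4

# profile a run-parameter file
s = summarize_mdp(parse_mdp("integrator = md\ndt = 0.02\nnsteps = 100000000\n"
                            "tcoupl = v-rescale\npcoupl = parrinello-rahman\n"))
print(s.sim_time_ns, s.thermostat, s.barostat)
# 2000.0 v-rescale parrinello-rahman
print(infer_resolution(s.dt_ps), infer_run_type(s))
# coarse-grain production  <- 20 fs time step: a Martini-style setup,
#                             2 µs of planned dynamics
```

A command-line interface wraps the same library calls:

```bash
mdmine harvest --config run.yaml            # Explore-and-Expand -> Parquet/TSV index
mdmine parse   --files-root data/ --out parsed/
mdmine report  --index out/ --report repository-summary --out table.tsv
mdmine search  --index out/ --query martini --filter extension=xtc --out hits.tsv
```

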