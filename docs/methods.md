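# Methods

## The harvesting model

Free-text search over generalist repositories yields many false positives
for MD data, because dataset titles and descriptions are uncurated
free text. `mdmine` therefore inverts the search: MD engines emit files
with characteristic extensions, and those extensions drive discovery.

The pipeline has three phases.

1. **Explore.** For each (extension, optional keyword) query, ask the
   repository which datasets contain a matching file. Extensions differ
   in their level of trust: `.xtc` or `.prmtop` are essentially unique to
   their engines and query alone; ambiguous extensions (`.top`, `.dcd`,
   `.inp`, `.crd`, `.ndx`, `.mae`) are only trusted when the dataset
   metadata also contains an MD keyword ("molecular dynamics",
   "gromacs", "martini", ...). The default query list is generated from
   the engine rule table: one keyword-free query per unique extension,
   one query per (ambiguous extension × keyword) pair.
2. **Expand.** A deposition is assumed coherent: once any MD file is
   found, *every* file of the dataset is indexed regardless of type. Zip
   archives are expanded through the repository's HTML content preview;
   the Zenodo-style preview is capped at 1,000 entries (the listing is
   flagged truncated), the OSF-style repository offers none (the archive
   stays indexed as a single opaque file).
3. **Clean.** Expanding through zip previews can drag in datasets whose
   only "MD-looking" member was a false positive (a `.log` in a zip of
   photographs). A dataset is kept only if at least one of its files —
   loose or in-zip — carries a trusted MD extension; otherwise the
   dataset and all its files are dropped. The step is idempotent.

Repositories sit behind a three-method adapter contract (`search`,
`fetch_dataset`, `fetch_zip_listing`), so the engine is tested entirely
against deterministic in-memory mocks; a thin live Zenodo adapter
(stdlib HTTP, retry with exponential backoff) is provided outside the
test-critical path. Only the latest version of a deposition is indexed,
and files inside zips are never downloaded during harvest.

## Format parsing

* **`.gro`** is parsed by fixed columns: residue number (1–5), residue
  name (6–10), atom name (11–15), atom number (16–20), three 8-wide
  position fields in nm, and three more 8-wide velocity fields when the
  line is long enough to hold them. Residue/atom numbers wrap above
  99,999 in large systems; they are stored verbatim and never used for
  counting — the particle count is the declared count line, validated
  against the number of atom lines. The box line must hold 3 or 9
  floats.
* **`.mdp`** parsing strips `;` comments, splits each line on the first
  `=`, normalises keys (lowercase, `-` → `_`, the Gromacs preprocessor
  convention) and resolves duplicates last-wins. Lines without `=` are
  warnings, never fatal. The profiling summary reads `dt` (default
  0.001 ps when absent, the Gromacs runtime default), `nsteps` (default
  0), and the first `ref_t` group (a warning is emitted when groups
  differ); the planned simulation time is `dt × nsteps`. Unreadable
  numeric tokens mark the field absent with a warning rather than
  failing the file.
* **`.xtc`** is scanned header-only. Each frame starts with a
  big-endian XDR header (magic 1995, atom count, step, time), a 9-float
  box, and a coordinate block: systems of ≤ 9 atoms store plain floats;
  larger systems store a compressed block whose own header (atom count,
  precision, integer bounds, small-index, byte count) gives the number
  of bytes to skip, padded to a multiple of 4. Frame counting therefore
  never decompresses coordinates. A trailing partial frame sets a
  `truncated` flag; a wrong magic on the first frame or an atom-count
  change mid-stream is an error.
* **`.log`** is scanned for the `GROMACS version:` line (or the
  `:-) GROMACS … (-:` banner) and the line following `Command line:`.

All text parsers accept LF and CRLF and fall back from UTF-8 to latin-1.

## Inference rules and their parameters

| rule | default | rationale |
| --- | --- | --- |
| coarse-grain cutoff | dt ≥ 0.01 ps (10 fs), inclusive | steps this large are only stable for coarse-grain force fields (Martini uses 20–30 fs); 10 fs itself classifies as coarse-grain |
| production filter | integrator ∈ {md, sd} and time > 1 ns | excludes minimisation and most equilibration; the production condition takes precedence over the no-coupling rule |
| non-production | minimiser integrator, or neither thermostat nor barostat | setups without any bath coupling are not used to generate production data |
| thermostat vocabulary | no, berendsen, nose-hoover, andersen, andersen-massive, v-rescale | the closed Gromacs option set; anything else is "unrecognized", absent is "undefined" |
| barostat vocabulary | no, berendsen, c-rescale, parrinello-rahman, mttk | same treatment |
| GB | 10⁹ bytes (decimal) | repository-style size reporting |
| time bands | ≤ 50 ns, 50 ns–1 µs, > 1 µs (left band closed) | band edges exactly 50 and 1000 ns |
| rounding | half away from zero | percentages printed as integers |

System classification labels a structure by the sorted set of non-solvent
categories present (protein, lipid, nucleic, glucid); water/ions and
unrecognised residues are excluded from membership, giving 15 combination
labels plus "water/ions only" and "other". The residue lexicon ships as
an editable YAML file (`mdmine/data/default_config.yaml`) covering the
standard amino acids with protonation variants, common Gromacs / CHARMM /
Martini lipid names, DNA/RNA residues, common sugars, and water/ion names
(including Martini `W`/`WF`). Lexicon membership is necessarily
incomplete — force fields invent residue names freely — and single-letter
collisions are resolved by fiat (e.g. `CA` is treated as a calcium ion).
Users with differently named systems should load their own configuration.

## The synthetic-data generators

Every pipeline input has a generator returning the artefact plus the
ground truth its consumer must reproduce, making generator/parser pairs
self-checking:

* `make_gro` builds systems from per-category molecule counts with fixed
  templates (water 3 atoms, protein residue 8, lipid 50, nucleic 20,
  glucid 12, plus a template hook); coordinates are uniform in the box.
* `make_mdp` renders the same logical entries in four dialects (spaced,
  compact, mixed-case, commented) to exercise parser normalisation.
* `make_xtc` emits structurally valid XDR frames; compressed payloads
  are arbitrary bytes of the correct padded length. Small-system
  (≤ 9 atoms) fixtures are fully valid and are cross-checked against
  MDAnalysis's complete decoder; conversely the header-only scanner is
  checked on trajectories written by MDAnalysis.
* `make_mock_repository` builds an adapter from a JSON-friendly spec,
  rendering zip previews as dialect HTML so the harvest path exercises
  real markup parsing.
* `make_index` generates a harvest index hitting exact per-repository
  marginals (dataset, loose/zip/in-zip file counts, byte totals split
  exactly, date ranges interpolated), used as the oracle for every
  aggregation.

What the generators deliberately do **not** emulate: physically
meaningful coordinates or trajectories, force-field-consistent
topologies, real repository markup drift, or the long-tailed messiness
of real metadata. Passing tests therefore demonstrate the correctness of
parsing, rule application and aggregation — not the recall of the
harvest strategy on live repositories, which depends on repository
search behaviour outside this package's control.

All generators are pure functions of their arguments including the seed
(`random.Random`, no global state); the same spec is byte-identical
across runs.

## Problem sizes and numerical choices

The acceptance script rebuilds the reference corpus index
(245,756 file records across three repositories) and the Gromacs census
index (87,204 records) in memory — a few seconds each — and uses 100
seeds per format for the adjunction sweep. Integer columns are summed
exactly; byte totals are summed as integers and converted to GB once.
The planned-time invariant `sim_time_ns = dt × nsteps / 1000` is exact
in floating point for the representable inputs used. Ties in the
extension ranking break lexicographically so reports are deterministic;
search output is ordered by (repository, dataset id, file name).

## Known limitations

* Engine assignment is by extension only; the contents of non-Gromacs
  files are never inspected, and NAMD and CHARMM cannot be
  distinguished (their extensions overlap).
* `.tpr`, `.trr` payloads and topology semantics are not parsed; those
  files are counted and sized only.
* The temperature comes from `ref_t` alone (first coupling group).
* The planned simulation time is the configured product, not evidence
  the run reached its end.
* Zip previews capped at 1,000 entries under-count large archives; the
  truncation flag records this but nothing can recover the unseen tail.
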