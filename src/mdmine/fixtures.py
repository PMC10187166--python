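"""Deterministic synthetic-data generators for every pipeline input.

Each generator returns both the artefact (text, bytes, adapter or index)
and the ground truth a parser or aggregation must reproduce, making the
generator/parser pair a self-checking adjunction.  All generators are
pure functions of their arguments — the seed included — with no global
random state.

Coordinates, sizes and member names are pseudo-random but physically
meaningless: parsers never look past format validity, and trajectories
carry correctly sized but arbitrary compressed payloads.
"""

from __future__ import annotations

import datetime as _dt
import json
import random
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

from .gmx_formats import XTC_MAGIC, XtcSummary
from .harvester import (ZIP_PREVIEW_CAPS, DatasetRecord, FileRecord,
                        HarvestIndex, ZipListing, extension_of,
                        parse_zip_preview)
from .inference import CATEGORIES, GroSummary, classify_system

__all__ = [
    "ResidueTemplate",
    "DEFAULT_TEMPLATES",
    "make_gro",
    "make_mdp",
    "make_xtc",
    "MockRepositoryAdapter",
    "make_mock_repository",
    "RepoProfile",
    "make_index",
    "REFERENCE_CORPUS_PROFILE",
    "GROMACS_FILE_CENSUS",
]


# ---------------------------------------------------------------------------
# .gro generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ResidueTemplate:
    """One molecule template: residue names to cycle through and the atom
    names of a single molecule."""

    residue_names: tuple[str, ...]
    atom_names: tuple[str, ...]

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)


DEFAULT_TEMPLATES: dict[str, ResidueTemplate] = {
    "water_ions": ResidueTemplate(("SOL",), ("OW", "HW1", "HW2")),
    "protein": ResidueTemplate(
        ("ALA", "GLY", "LEU", "VAL", "LYS", "ASP", "PHE", "SER"),
        ("N", "CA", "C", "O", "CB", "CG", "CD", "CE")),
    "lipid": ResidueTemplate(
        ("POPC", "DPPC", "DOPC", "POPE"),
        tuple(f"C{i}" for i in range(1, 51))),
    "nucleic": ResidueTemplate(
        ("DA", "DC", "DG", "DT"),
        tuple(f"N{i}" for i in range(1, 21))),
    "glucid": ResidueTemplate(
        ("GLC", "NAG", "MAN", "GAL"),
        tuple(f"S{i}" for i in range(1, 13))),
    # deliberately outside every lexicon category
    "other": ResidueTemplate(("UNK",), ("X1", "X2", "X3", "X4", "X5")),
}

_CATEGORY_ORDER = ("protein", "lipid", "nucleic", "glucid", "water_ions", "other")


def make_gro(composition: Mapping[str, int],
             seed: int = 0,
             box_nm: Sequence[float] = (10.0, 10.0, 10.0),
             with_velocities: bool = False,
             title: str = "synthetic system",
             templates: Optional[Mapping[str, ResidueTemplate]] = None,
             ) -> tuple[str, GroSummary]:
    """Emit a format-valid .gro file plus its ground-truth composition.

    ``composition`` maps category names to *molecule* counts; each
    category's template fixes the atoms per molecule (water 3, protein
    residue 8, lipid 50, nucleic 20, glucid 12, "other" 5).  Custom
    templates may be supplied per category.  Residue and atom numbers
    wrap above 99,999 as in real large systems.
    """
    tpl = dict(DEFAULT_TEMPLATES)
    if templates:
        tpl.update(templates)
    unknown = set(composition) - set(tpl)
    if unknown:
        raise ValueError(f"no template for categories {sorted(unknown)}")
    rng = random.Random(seed)

    lines: list[str] = []
    counts: dict[str, int] = {c: 0 for c in CATEGORIES}
    counts["other"] = 0
    residue_number = 0
    atom_number = 0
    for category in _CATEGORY_ORDER:
        n_molecules = int(composition.get(category, 0))
        if n_molecules < 0:
            raise ValueError(f"negative molecule count for {category!r}")
        template = tpl[category]
        for i in range(n_molecules):
            residue_number += 1
            resname = template.residue_names[i % len(template.residue_names)]
            for atom_name in template.atom_names:
                atom_number += 1
                x = rng.uniform(0.0, box_nm[0])
                y = rng.uniform(0.0, box_nm[1])
                z = rng.uniform(0.0, box_nm[2])
                line = (f"{(residue_number - 1) % 99999 + 1:5d}{resname:<5s}"
                        f"{atom_name:>5s}{(atom_number - 1) % 99999 + 1:5d}"
                        f"{x:8.3f}{y:8.3f}{z:8.3f}")
                if with_velocities:
                    line += "".join(f"{rng.uniform(-1, 1):8.4f}" for _ in range(3))
                lines.append(line)
            counts[category] += template.n_atoms

    total = atom_number
    box_line = "".join(f"{v:10.5f}" for v in box_nm)
    text = "\n".join([title, f"{total:5d}", *lines, box_line]) + "\n"
    truth = GroSummary(
        n_particles=total,
        category_counts=counts,
        system_class=classify_system(counts),
        has_velocities=with_velocities and total > 0,
    )
    return text, truth


# ---------------------------------------------------------------------------
# .mdp generation
# ---------------------------------------------------------------------------

_MDP_STYLES = ("spaced", "compact", "mixed-case", "commented")


def make_mdp(entries: Mapping[str, str], style: str = "spaced",
             seed: int = 0) -> str:
    """Render logical .mdp entries in one of several dialects.

    All styles parse back to the same normalised entries: ``spaced`` pads
    around ``=``; ``compact`` strips whitespace; ``mixed-case`` re-cases
    keys and swaps ``_`` for ``-``; ``commented`` interleaves ``;``
    comments and trailing remarks.
    """
    if style not in _MDP_STYLES:
        raise ValueError(f"style must be one of {_MDP_STYLES}")
    rng = random.Random(seed)
    lines: list[str] = []
    if style == "commented":
        lines.append("; synthetic run parameters")
    for key, value in entries.items():
        if style == "compact":
            lines.append(f"{key}={value}")
        elif style == "mixed-case":
            shown = key.replace("_", "-")
            shown = "".join(c.upper() if rng.random() < 0.5 else c for c in shown)
            lines.append(f"{shown} = {value}")
        elif style == "commented":
            lines.append(f"{key:<24s} = {value} ; set by generator")
            if rng.random() < 0.3:
                lines.append("")
        else:
            lines.append(f"{key:<24s} = {value}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# .xtc generation
# ---------------------------------------------------------------------------

def make_xtc(n_atoms: int, n_frames: int, seed: int = 0,
             truncate_last: bool = False,
             dt_per_frame_ps: float = 10.0) -> tuple[bytes, XtcSummary]:
    """Emit structurally valid XTC bytes plus the ground-truth scan result.

    Frames carry correct big-endian XDR headers (magic 1995, atom count,
    step, time) and correctly *sized* coordinate blocks; compressed
    payloads are arbitrary bytes, since a header-only scan never decodes
    them.  ``truncate_last`` drops a suffix of the final frame, which a
    scanner must report as one fewer complete frame plus a truncation
    flag.
    """
    if n_atoms < 1:
        raise ValueError("n_atoms must be >= 1")
    if n_frames < 0:
        raise ValueError("n_frames must be >= 0")
    if truncate_last and n_frames < 1:
        raise ValueError("cannot truncate an empty trajectory")
    rng = random.Random(seed)
    chunks: list[bytes] = []
    frame_sizes: list[int] = []
    for frame in range(n_frames):
        parts = [struct.pack(">iii", XTC_MAGIC, n_atoms, frame * 100),
                 struct.pack(">f", frame * dt_per_frame_ps)]
        box = [0.0] * 9
        box[0] = box[4] = box[8] = 5.0
        parts.append(struct.pack(">9f", *box))
        parts.append(struct.pack(">i", n_atoms))
        if n_atoms <= 9:
            coords = [rng.uniform(0.0, 5.0) for _ in range(3 * n_atoms)]
            parts.append(struct.pack(f">{3 * n_atoms}f", *coords))
        else:
            parts.append(struct.pack(">f", 1000.0))           # precision
            parts.append(struct.pack(">3i", 0, 0, 0))          # min ints
            parts.append(struct.pack(">3i", 5000, 5000, 5000))  # max ints
            parts.append(struct.pack(">i", 14))                # small-index
            nbytes = rng.randrange(8, 3 * n_atoms + 8)
            parts.append(struct.pack(">i", nbytes))
            padded = (nbytes + 3) & ~3
            parts.append(rng.randbytes(padded))
        frame_bytes = b"".join(parts)
        chunks.append(frame_bytes)
        frame_sizes.append(len(frame_bytes))

    complete = n_frames
    truncated = False
    if truncate_last:
        keep = frame_sizes[-1] // 2 or 1
        chunks[-1] = chunks[-1][:keep]
        complete = n_frames - 1
        truncated = True

    data = b"".join(chunks)
    truth = XtcSummary(
        n_atoms=n_atoms if n_frames else 0,
        n_frames=complete,
        first_time_ps=0.0 if complete else None,
        last_time_ps=(complete - 1) * dt_per_frame_ps if complete else None,
        truncated=truncated,
    )
    return data, truth


# ---------------------------------------------------------------------------
# mock repository adapters
# ---------------------------------------------------------------------------

class MockRepositoryAdapter:
    """An in-memory repository honouring the adapter contract.

    Backed entirely by a JSON-friendly spec::

        {"name": "zenodo-like", "dialect": "zenodo", "preview_cap": 1000,
         "search_includes_zip_entries": false,
         "datasets": [
            {"id": "...", "title": "...", "description": "...",
             "created_date": "2021-05-02", "doi": null, "license": null,
             "files": [{"name": "run.mdp", "size": 1234}, ...],
             "zips": [{"name": "bundle.zip", "size": 99,
                       "entries": [{"path": "a/x.gro", "size": 10}, ...]},
                      ...]}]}

    ``dialect`` selects the zip-preview markup emitted (``zenodo`` or
    ``figshare``); ``null`` means the repository offers no preview and
    ``fetch_zip_listing`` reports unsupported.  The preview is rendered
    as HTML and run through :func:`mdmine.harvester.parse_zip_preview`,
    so the harvest path exercises real markup parsing.
    """

    def __init__(self, spec: Mapping):
        self.spec = spec
        self.name = spec.get("name", "mock")
        self.dialect = spec.get("dialect")
        if self.dialect is not None and self.dialect not in ZIP_PREVIEW_CAPS:
            raise ValueError(f"unknown dialect {self.dialect!r}")
        cap = spec.get("preview_cap")
        if cap is None and self.dialect is not None:
            cap = ZIP_PREVIEW_CAPS[self.dialect]
        self.preview_cap: Optional[int] = cap
        self.search_includes_zip_entries = bool(
            spec.get("search_includes_zip_entries", False))
        self._datasets = {str(d["id"]): d for d in spec.get("datasets", [])}

    # -- contract ----------------------------------------------------------

    def search(self, query) -> list[str]:
        ext = query.file_type.lower().lstrip(".")
        hits: list[str] = []
        for ds_id in sorted(self._datasets):
            d = self._datasets[ds_id]
            if query.keyword is not None:
                blob = (d.get("title", "") + " " + d.get("description", "")).lower()
                if query.keyword.lower() not in blob:
                    continue
            names = [f["name"] for f in d.get("files", [])]
            names += [z["name"] for z in d.get("zips", [])]
            if self.search_includes_zip_entries:
                for z in d.get("zips", []):
                    names += [e["path"] for e in z.get("entries", [])]
            if any(extension_of(n) == ext for n in names):
                hits.append(ds_id)
        return hits

    def fetch_dataset(self, dataset_id: str):
        if dataset_id not in self._datasets:
            from .harvester import DatasetNotFoundError
            raise DatasetNotFoundError(dataset_id)
        d = self._datasets[dataset_id]
        record = DatasetRecord(
            repository=self.name,
            dataset_id=dataset_id,
            title=d.get("title", ""),
            description=d.get("description", ""),
            created_date=d.get("created_date", ""),
            doi=d.get("doi"),
            license=d.get("license"),
        )
        files = [
            FileRecord(repository=self.name, dataset_id=dataset_id,
                       file_name=f["name"], size_bytes=f.get("size"))
            for f in d.get("files", [])
        ]
        files += [
            FileRecord(repository=self.name, dataset_id=dataset_id,
                       file_name=z["name"], size_bytes=z.get("size"))
            for z in d.get("zips", [])
        ]
        return record, files

    def fetch_zip_listing(self, file: FileRecord) -> ZipListing:
        d = self._datasets.get(file.dataset_id)
        if d is None:
            from .harvester import DatasetNotFoundError
            raise DatasetNotFoundError(file.dataset_id)
        zips = {z["name"]: z for z in d.get("zips", [])}
        if file.file_name not in zips:
            raise KeyError(f"{file.file_name} is not a zip of {file.dataset_id}")
        if self.dialect is None:
            return ZipListing(supported=False)
        entries = zips[file.file_name].get("entries", [])
        shown = entries if self.preview_cap is None else entries[: self.preview_cap]
        markup = self._render_preview(shown)
        listing = parse_zip_preview(markup, self.dialect)
        if self.preview_cap is not None:
            listing.truncated = len(listing.entries) == self.preview_cap
        return listing

    # -- markup rendering --------------------------------------------------

    def _render_preview(self, entries) -> str:
        if self.dialect == "zenodo":
            items = "\n".join(
                f'  <li><a href="#">{e["path"]}</a>'
                + (f'<span class="size">{e["size"]}</span>' if e.get("size") is not None else "")
                + "</li>"
                for e in entries)
            return f'<html><body><ul class="zip-files">\n{items}\n</ul></body></html>'
        rows = "\n".join(
            f'  <tr><td>{e["path"]}</td><td>'
            + (str(e["size"]) if e.get("size") is not None else "")
            + "</td></tr>"
            for e in entries)
        return f"<html><body><table>\n{rows}\n</table></body></html>"


def make_mock_repository(spec: Union[Mapping, str, Path]) -> MockRepositoryAdapter:
    """Build a mock adapter from a spec mapping or a JSON spec file."""
    if isinstance(spec, (str, Path)):
        spec = json.loads(Path(spec).read_text(encoding="utf-8"))
    return MockRepositoryAdapter(spec)


# ---------------------------------------------------------------------------
# synthetic harvest indices with exact marginals
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RepoProfile:
    """Exact per-repository marginals a synthetic index must hit.

    ``n_loose_files`` counts files directly in datasets and includes the
    ``n_zip_files`` archives; ``total_size_bytes`` is spread exactly over
    the loose files.  ``loose_extensions`` pins part of the extension
    histogram; the remainder cycles through a mixed non-MD pool.
    """

    name: str
    n_datasets: int
    first_date: str
    last_date: str
    n_loose_files: int
    n_zip_files: int = 0
    n_in_zip_files: int = 0
    total_size_bytes: int = 0
    loose_extensions: Optional[Mapping[str, int]] = None


# Corpus statistics of MD-related depositions indexed across Zenodo,
# Figshare and OSF as of March 2023 (sizes in decimal GB ~ 12851 / 736 /
# 495); OSF offers no zip preview, hence zero archive members there.
REFERENCE_CORPUS_PROFILE: tuple[RepoProfile, ...] = (
    RepoProfile("figshare", 913, "2012-08-20", "2023-03-03",
                n_loose_files=3336, n_zip_files=590, n_in_zip_files=74720,
                total_size_bytes=736 * 10 ** 9),
    RepoProfile("osf", 55, "2017-05-24", "2023-02-05",
                n_loose_files=6146, n_zip_files=14, n_in_zip_files=0,
                total_size_bytes=495 * 10 ** 9),
    RepoProfile("zenodo", 1011, "2014-11-19", "2023-03-05",
                n_loose_files=20250, n_zip_files=1780, n_in_zip_files=141304,
                total_size_bytes=12851 * 10 ** 9),
)

# Per-extension census of the Gromacs files in the same corpus; the tail
# of less common types is folded into .edr so the total matches the
# 87,204 Gromacs-assigned files.
GROMACS_FILE_CENSUS: dict[str, int] = {
    "xtc": 28559,
    "trr": 1406,
    "mdp": 10055,
    "gro": 9718,
    "itp": 13058,
    "top": 7009,
    "tpr": 4987,
    "edr": 12412,
}

_FILLER_EXTENSIONS = ("pdb", "txt", "dat", "png", "xvg", "csv", "none", "out")


def _interpolate_dates(first: str, last: str, n: int) -> list[str]:
    d0 = _dt.date.fromisoformat(first)
    d1 = _dt.date.fromisoformat(last)
    if n == 1:
        return [first]
    span = (d1 - d0).days
    return [(d0 + _dt.timedelta(days=round(span * i / (n - 1)))).isoformat()
            for i in range(n)]


def make_index(profile: Sequence[RepoProfile], seed: int = 0,
               ) -> tuple[HarvestIndex, dict[str, dict[str, int]]]:
    """Generate a harvest index hitting the profile's marginals exactly.

    Returns the index and a per-repository ground-truth dict (dataset,
    loose, zip, in-zip and total file counts, byte total, date range) for
    aggregation-oracle tests.  Deterministic for a fixed seed.
    """
    rng = random.Random(seed)
    datasets: list[DatasetRecord] = []
    files: list[FileRecord] = []
    truth: dict[str, dict] = {}

    for repo in profile:
        if repo.n_zip_files > repo.n_loose_files:
            raise ValueError("zip files are loose files; count exceeds total")
        if repo.n_in_zip_files and not repo.n_zip_files:
            raise ValueError("in-zip files need at least one zip")
        if repo.n_datasets <= 0 and (repo.n_loose_files or repo.n_in_zip_files):
            raise ValueError("files need at least one dataset")

        dates = _interpolate_dates(repo.first_date, repo.last_date,
                                   max(repo.n_datasets, 1))
        ds_ids = [f"{repo.name}-{i:06d}" for i in range(repo.n_datasets)]
        for ds_id, date in zip(ds_ids, dates):
            datasets.append(DatasetRecord(
                repository=repo.name,
                dataset_id=ds_id,
                title=f"Molecular dynamics simulation deposition {ds_id}",
                description="Synthetic deposition generated for corpus "
                            "profiling; includes Gromacs input and output files.",
                created_date=date,
                doi=f"10.5072/{ds_id}",
                license="CC-BY-4.0",
            ))

        # extension list for non-zip loose files
        n_plain = repo.n_loose_files - repo.n_zip_files
        ext_list: list[str] = []
        if repo.loose_extensions:
            for ext, count in sorted(repo.loose_extensions.items()):
                ext_list.extend([ext] * count)
        if len(ext_list) > n_plain:
            raise ValueError("loose_extensions exceed the plain loose file count")
        for i in range(n_plain - len(ext_list)):
            ext_list.append(_FILLER_EXTENSIONS[i % len(_FILLER_EXTENSIONS)])

        # exact byte split over loose files
        sizes: list[int] = []
        if repo.n_loose_files:
            base, rem = divmod(repo.total_size_bytes, repo.n_loose_files)
            sizes = [base + (1 if i < rem else 0)
                     for i in range(repo.n_loose_files)]
        elif repo.total_size_bytes:
            raise ValueError("bytes without loose files")

        size_iter = iter(sizes)
        for i, ext in enumerate(ext_list):
            ds_id = ds_ids[i % len(ds_ids)]
            name = (f"file_{i:06d}" if ext == "none" else f"file_{i:06d}.{ext}")
            files.append(FileRecord(
                repository=repo.name, dataset_id=ds_id, file_name=name,
                size_bytes=next(size_iter)))
        zip_names: list[tuple[str, str]] = []
        for j in range(repo.n_zip_files):
            ds_id = ds_ids[j % len(ds_ids)]
            name = f"bundle_{j:05d}.zip"
            files.append(FileRecord(
                repository=repo.name, dataset_id=ds_id, file_name=name,
                size_bytes=next(size_iter)))
            zip_names.append((ds_id, name))
        for k in range(repo.n_in_zip_files):
            ds_id, parent = zip_names[k % len(zip_names)]
            ext = _FILLER_EXTENSIONS[rng.randrange(len(_FILLER_EXTENSIONS))]
            member = (f"{parent[:-4]}/member_{k:06d}"
                      if ext == "none" else f"{parent[:-4]}/member_{k:06d}.{ext}")
            files.append(FileRecord(
                repository=repo.name, dataset_id=ds_id, file_name=member,
                from_zip=True, zip_parent=parent))

        truth[repo.name] = {
            "dataset_count": repo.n_datasets,
            "loose_file_count": repo.n_loose_files,
            "zip_file_count": repo.n_zip_files,
            "in_zip_file_count": repo.n_in_zip_files,
            "total_file_count": repo.n_loose_files + repo.n_in_zip_files,
            "total_size_bytes": repo.total_size_bytes,
            "first_date": repo.first_date if repo.n_datasets else None,
            "last_date": repo.last_date if repo.n_datasets else None,
        }

    index = HarvestIndex(datasets=datasets, files=files,
                         manifest={"generator": "make_index", "seed": seed})
    return index, truth
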