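"""The Explore-and-Expand harvesting engine.

Generalist data repositories (Zenodo, Figshare, OSF, ...) hold MD files
that free-text search finds poorly.  The Explore-and-Expand strategy goes
the other way around:

Explore
    Query each repository for datasets holding MD-specific file types,
    optionally combined with an MD keyword for ambiguous extensions.
Expand
    For every hit dataset, index *all* of its files regardless of type —
    a researcher's deposition is assumed coherent — including the members
    of zip archives, recovered from the repository's HTML content preview.
Clean
    Drop datasets that, once fully listed, contain no file with a trusted
    MD extension; this removes false positives picked up through zip
    archives.

Repositories are represented by adapters implementing a three-method
contract (:class:`RepositoryAdapter`), so the engine runs identically
against live APIs and recorded/mock fixtures.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
import time
import urllib.parse
import urllib.request
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Protocol, Sequence, Union, runtime_checkable

import pandas as pd
from lxml import html as lxml_html

logger = logging.getLogger("mdmine.harvester")

__all__ = [
    "QuerySpec",
    "DatasetRecord",
    "FileRecord",
    "ZipListing",
    "RepositoryAdapter",
    "HarvestIndex",
    "extension_of",
    "explore",
    "expand",
    "clean_datasets",
    "run_harvest",
    "parse_zip_preview",
    "default_queries",
    "ZenodoAdapter",
]

# Entry caps of the repositories' zip content previews; None = no cap.
ZIP_PREVIEW_CAPS = {"zenodo": 1000, "figshare": None}

ARCHIVE_EXTENSIONS = frozenset({"zip", "tar", "gz", "bz2", "xz", "7z", "rar"})


def extension_of(file_name: str) -> str:
    """Lowercase extension after the final dot; dotless names give ``"none"``."""
    name = file_name.rsplit("/", 1)[-1]
    if "." not in name.lstrip("."):
        return "none"
    return name.rsplit(".", 1)[-1].lower() or "none"


@dataclass(frozen=True)
class QuerySpec:
    """One Explore query: a file type, optionally tied to a keyword."""

    file_type: str
    keyword: Optional[str] = None
    repository: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.file_type:
            raise ValueError("QuerySpec.file_type must be non-empty")


@dataclass(frozen=True)
class DatasetRecord:
    """One deposition: identity plus the free-text metadata searched."""

    repository: str
    dataset_id: str
    title: str = ""
    description: str = ""
    created_date: str = ""          # ISO date
    doi: Optional[str] = None
    license: Optional[str] = None


@dataclass(frozen=True)
class FileRecord:
    """One indexed file, loose or inside a zip archive."""

    repository: str
    dataset_id: str
    file_name: str
    extension: str = ""
    size_bytes: Optional[int] = None
    download_url: Optional[str] = None
    from_zip: bool = False
    zip_parent: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.extension:
            object.__setattr__(self, "extension", extension_of(self.file_name))
        if self.from_zip != (self.zip_parent is not None):
            raise ValueError("from_zip must match the presence of zip_parent")

    @property
    def is_archive(self) -> bool:
        return self.extension in ARCHIVE_EXTENSIONS


@dataclass
class ZipListing:
    """Content preview of a zip archive.

    ``truncated`` is set when the repository capped the preview;
    ``supported`` is False when the repository offers no preview at all
    (the archive is then indexed as a single opaque file).
    """

    entries: list[tuple[str, Optional[int]]] = field(default_factory=list)
    truncated: bool = False
    supported: bool = True


@runtime_checkable
class RepositoryAdapter(Protocol):
    """Behaviour contract every repository backend implements."""

    name: str

    def search(self, query: QuerySpec) -> list[str]:
        """Dataset ids matching one Explore query (deterministic order)."""
        ...

    def fetch_dataset(self, dataset_id: str) -> tuple[DatasetRecord, list[FileRecord]]:
        """Metadata and loose file listing of one dataset."""
        ...

    def fetch_zip_listing(self, file: FileRecord) -> ZipListing:
        """Content preview of a zip file (``supported=False`` when absent)."""
        ...


class DatasetNotFoundError(KeyError):
    pass


class HarvestError(RuntimeError):
    """Adapter transport failure, with the failing query attached."""

    def __init__(self, message: str, query: Optional[QuerySpec] = None):
        super().__init__(message)
        self.query = query


# ---------------------------------------------------------------------------
# the index container
# ---------------------------------------------------------------------------

@dataclass
class HarvestIndex:
    """Datasets plus files plus the run manifest; persists as Parquet/TSV."""

    datasets: list[DatasetRecord] = field(default_factory=list)
    files: list[FileRecord] = field(default_factory=list)
    manifest: dict = field(default_factory=dict)

    def dataset_frame(self) -> pd.DataFrame:
        cols = ["repository", "dataset_id", "title", "description",
                "created_date", "doi", "license"]
        if not self.datasets:
            return pd.DataFrame(columns=cols)
        df = pd.DataFrame([vars(d) for d in self.datasets])
        return df[cols]

    def file_frame(self) -> pd.DataFrame:
        cols = ["repository", "dataset_id", "file_name", "extension",
                "size_bytes", "download_url", "from_zip", "zip_parent"]
        if not self.files:
            return pd.DataFrame(columns=cols)
        records = [
            {c: getattr(f, c) for c in cols}
            for f in self.files
        ]
        return pd.DataFrame(records)[cols]

    def save(self, directory: Union[str, Path], tsv: bool = True) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.dataset_frame().to_parquet(directory / "datasets.parquet", index=False)
        self.file_frame().to_parquet(directory / "files.parquet", index=False)
        if tsv:
            from .report import export_tsv
            export_tsv(self.dataset_frame(), directory / "datasets.tsv")
            export_tsv(self.file_frame(), directory / "files.tsv")
        (directory / "manifest.json").write_text(
            json.dumps(self.manifest, indent=2, sort_keys=True, default=str),
            encoding="utf-8",
        )

    @classmethod
    def load(cls, directory: Union[str, Path]) -> "HarvestIndex":
        directory = Path(directory)
        ddf = pd.read_parquet(directory / "datasets.parquet")
        fdf = pd.read_parquet(directory / "files.parquet")
        manifest_path = directory / "manifest.json"
        manifest = (json.loads(manifest_path.read_text(encoding="utf-8"))
                    if manifest_path.exists() else {})
        datasets = [
            DatasetRecord(**{k: (None if pd.isna(v) else v) for k, v in row.items()})
            for row in ddf.to_dict("records")
        ]
        files = []
        for row in fdf.to_dict("records"):
            clean = {k: (None if pd.isna(v) else v) for k, v in row.items()}
            if clean.get("size_bytes") is not None:
                clean["size_bytes"] = int(clean["size_bytes"])
            clean["from_zip"] = bool(clean.get("from_zip"))
            files.append(FileRecord(**clean))
        return cls(datasets=datasets, files=files, manifest=manifest)


# ---------------------------------------------------------------------------
# Explore / Expand / Clean
# ---------------------------------------------------------------------------

def explore(adapter: RepositoryAdapter, queries: Sequence[QuerySpec]) -> set[str]:
    """Run the Explore phase: the deduplicated union of per-query hits.

    Transport errors are re-raised as :class:`HarvestError` with the
    failing query attached; hits gathered before the failure are carried
    on the exception (``partial`` attribute).
    """
    if not queries:
        raise ValueError("explore() needs at least one query")
    hits: set[str] = set()
    for query in queries:
        if query.repository is not None and query.repository != adapter.name:
            continue
        try:
            hits.update(adapter.search(query))
        except Exception as exc:  # noqa: BLE001 — adapter faults become HarvestError
            err = HarvestError(f"search failed on {adapter.name}: {exc}", query=query)
            err.partial = hits  # type: ignore[attr-defined]
            raise err from exc
    return hits


def expand(adapter: RepositoryAdapter,
           dataset_id: str) -> tuple[DatasetRecord, list[FileRecord]]:
    """Run the Expand phase on one dataset: index every file it holds.

    Zip archives are expanded through the repository's content preview;
    when the preview is unsupported or fails, the archive stays indexed as
    a single file and a warning is logged.
    """
    try:
        dataset, loose = adapter.fetch_dataset(dataset_id)
    except DatasetNotFoundError:
        raise
    except KeyError as exc:
        raise DatasetNotFoundError(str(exc)) from exc
    records: list[FileRecord] = list(loose)
    for f in loose:
        if f.extension != "zip":
            continue
        try:
            listing = adapter.fetch_zip_listing(f)
        except Exception as exc:  # noqa: BLE001
            logger.warning("zip listing failed for %s/%s/%s: %s",
                           f.repository, f.dataset_id, f.file_name, exc)
            continue
        if not listing.supported:
            logger.warning("no zip preview on %s; %s indexed as a single file",
                           adapter.name, f.file_name)
            continue
        for path, size in listing.entries:
            records.append(FileRecord(
                repository=f.repository,
                dataset_id=f.dataset_id,
                file_name=path,
                size_bytes=size,
                from_zip=True,
                zip_parent=f.file_name,
            ))
    return dataset, records


def clean_datasets(index: HarvestIndex,
                   trusted_types: Iterable[str]) -> tuple[HarvestIndex, int]:
    """Drop datasets with no file (loose or in-zip) of a trusted MD type.

    Returns the filtered index and the number of datasets removed.  The
    operation is idempotent.
    """
    trusted = {t.lower().lstrip(".") for t in trusted_types}
    keep: set[tuple[str, str]] = set()
    for f in index.files:
        if f.extension in trusted:
            keep.add((f.repository, f.dataset_id))
    kept_datasets = [d for d in index.datasets if (d.repository, d.dataset_id) in keep]
    kept_keys = {(d.repository, d.dataset_id) for d in kept_datasets}
    kept_files = [f for f in index.files if (f.repository, f.dataset_id) in kept_keys]
    removed = len(index.datasets) - len(kept_datasets)
    manifest = dict(index.manifest)
    manifest["datasets_removed_by_cleaning"] = manifest.get(
        "datasets_removed_by_cleaning", 0) + removed
    return HarvestIndex(datasets=kept_datasets, files=kept_files,
                        manifest=manifest), removed


def run_harvest(adapters: Sequence[RepositoryAdapter],
                queries: Sequence[QuerySpec],
                trusted_types: Optional[Iterable[str]] = None) -> HarvestIndex:
    """The full Explore -> Expand -> Clean pipeline over several adapters.

    Per-adapter failures are isolated: the run continues with the
    remaining adapters and the manifest records the failures.  Output
    ordering is deterministic for fixed backing stores (datasets sorted
    by repository then id).
    """
    if not adapters:
        raise ValueError("run_harvest() needs at least one adapter")
    if trusted_types is None:
        from .inference import default_config
        trusted_types = default_config().trusted_extensions

    index = HarvestIndex()
    manifest: dict = {
        "queries": [vars(q) for q in queries],
        "started_utc": _dt.datetime.now(_dt.timezone.utc).isoformat(),
        "repositories": {},
        "failures": [],
        "dataset_provenance": {},
    }
    for adapter in adapters:
        try:
            hits = explore(adapter, queries)
        except HarvestError as exc:
            logger.error("adapter %s failed during explore: %s", adapter.name, exc)
            manifest["failures"].append(
                {"repository": adapter.name, "phase": "explore", "error": str(exc),
                 "query": vars(exc.query) if exc.query else None})
            hits = getattr(exc, "partial", set())
        n_files = 0
        for dataset_id in sorted(hits):
            try:
                dataset, files = expand(adapter, dataset_id)
            except DatasetNotFoundError:
                logger.warning("dataset %s vanished between explore and expand; skipped",
                               dataset_id)
                manifest["failures"].append(
                    {"repository": adapter.name, "phase": "expand",
                     "dataset_id": dataset_id, "error": "not found"})
                continue
            index.datasets.append(dataset)
            index.files.extend(files)
            n_files += len(files)
            manifest["dataset_provenance"][f"{adapter.name}/{dataset_id}"] = "explore"
        manifest["repositories"][adapter.name] = {
            "datasets": len(hits), "files": n_files}
    index.datasets.sort(key=lambda d: (d.repository, d.dataset_id))
    index.files.sort(key=lambda f: (f.repository, f.dataset_id, f.from_zip,
                                    f.zip_parent or "", f.file_name))
    index.manifest = manifest
    cleaned, removed = clean_datasets(index, trusted_types)
    cleaned.manifest["finished_utc"] = _dt.datetime.now(_dt.timezone.utc).isoformat()
    for repo, stats in cleaned.manifest["repositories"].items():
        kept = sum(1 for d in cleaned.datasets if d.repository == repo)
        stats["datasets_kept"] = kept
    return cleaned


def default_queries(repository: Optional[str] = None) -> list[QuerySpec]:
    """The default Explore query list derived from the engine rule table.

    Unique extensions query alone; ambiguous extensions are combined with
    each MD keyword.
    """
    from .inference import default_config

    cfg = default_config()
    queries: list[QuerySpec] = []
    for ext in sorted(cfg.engine_rules):
        rule = cfg.engine_rules[ext]
        if rule.requires_keyword:
            for kw in cfg.keywords:
                queries.append(QuerySpec(ext, kw, repository))
        else:
            queries.append(QuerySpec(ext, None, repository))
    return queries


# ---------------------------------------------------------------------------
# zip content preview parsing
# ---------------------------------------------------------------------------

def _parse_size(token: Optional[str]) -> Optional[int]:
    if token is None:
        return None
    token = token.strip().replace(",", "")
    if not token:
        return None
    try:
        return int(token)
    except ValueError:
        return None


def parse_zip_preview(markup: Union[str, bytes], dialect: str) -> ZipListing:
    """Parse a repository's HTML zip-content preview into a listing.

    Two dialects are understood (they are the structures the mock
    repositories emit; live-site markup drifts and real adapters may
    override this):

    ``zenodo``
        ``<ul class="zip-files">`` with one ``<li>`` per member: an
        ``<a>`` holding the path and an optional ``<span class="size">``.
        The preview is capped at 1,000 entries; a listing of exactly the
        cap is flagged truncated.
    ``figshare``
        A ``<table>`` with one row per member: first cell path, second
        cell size.  No cap.

    Unparseable markup yields an empty listing with a warning logged.
    """
    if dialect not in ZIP_PREVIEW_CAPS:
        raise ValueError(f"unknown zip preview dialect {dialect!r}")
    if isinstance(markup, bytes):
        markup = markup.decode("utf-8", errors="replace")
    if not markup.strip():
        raise ValueError("empty markup")
    entries: list[tuple[str, Optional[int]]] = []
    try:
        doc = lxml_html.fromstring(markup)
        if dialect == "zenodo":
            for li in doc.xpath("//ul[@class='zip-files']//li") or doc.findall(".//li"):
                link = li.find(".//a")
                if link is None or not (link.text or "").strip():
                    continue
                size_el = li.find(".//span[@class='size']")
                entries.append(((link.text or "").strip(),
                                _parse_size(size_el.text if size_el is not None else None)))
        else:  # figshare
            for tr in doc.findall(".//tr"):
                cells = tr.findall(".//td")
                if not cells:
                    continue
                path = (cells[0].text_content() or "").strip()
                if not path:
                    continue
                size = _parse_size(cells[1].text_content() if len(cells) > 1 else None)
                entries.append((path, size))
    except Exception as exc:  # noqa: BLE001 — malformed previews are non-fatal
        logger.warning("unparseable %s zip preview: %s", dialect, exc)
        return ZipListing(entries=[], truncated=False)
    cap = ZIP_PREVIEW_CAPS[dialect]
    truncated = cap is not None and len(entries) == cap
    return ZipListing(entries=entries, truncated=truncated)


# ---------------------------------------------------------------------------
# a thin live adapter (not used by the test suite)
# ---------------------------------------------------------------------------

class ZenodoAdapter:
    """Minimal live Zenodo backend over its public REST API.

    Network access, retry-with-backoff and rate limiting live here, kept
    out of the test-critical path; the engine itself is exercised against
    mock adapters.
    """

    name = "zenodo"
    base_url = "https://zenodo.org/api"

    def __init__(self, sleep_s: float = 1.0, max_retries: int = 3,
                 page_size: int = 100):
        self.sleep_s = sleep_s
        self.max_retries = max_retries
        self.page_size = page_size

    def _get(self, url: str) -> dict:
        last: Optional[Exception] = None
        for attempt in range(self.max_retries):
            try:
                with urllib.request.urlopen(url, timeout=30) as resp:
                    return json.loads(resp.read().decode("utf-8"))
            except Exception as exc:  # noqa: BLE001
                last = exc
                time.sleep(self.sleep_s * (2 ** attempt))
        raise HarvestError(f"GET {url} failed after {self.max_retries} tries: {last}")

    def search(self, query: QuerySpec) -> list[str]:
        terms = [f'filetype:"{query.file_type}"']
        if query.keyword:
            terms.append(f'"{query.keyword}"')
        q = urllib.parse.quote(" AND ".join(terms))
        ids: list[str] = []
        page = 1
        while True:
            payload = self._get(
                f"{self.base_url}/records?q={q}&size={self.page_size}&page={page}")
            hits = payload.get("hits", {}).get("hits", [])
            ids.extend(str(h["id"]) for h in hits)
            if len(hits) < self.page_size:
                break
            page += 1
            time.sleep(self.sleep_s)
        return ids

    def fetch_dataset(self, dataset_id: str) -> tuple[DatasetRecord, list[FileRecord]]:
        payload = self._get(f"{self.base_url}/records/{dataset_id}")
        meta = payload.get("metadata", {})
        dataset = DatasetRecord(
            repository=self.name,
            dataset_id=str(dataset_id),
            title=meta.get("title", ""),
            description=meta.get("description", ""),
            created_date=str(payload.get("created", ""))[:10],
            doi=payload.get("doi"),
            license=(meta.get("license") or {}).get("id")
            if isinstance(meta.get("license"), dict) else meta.get("license"),
        )
        files = [
            FileRecord(
                repository=self.name,
                dataset_id=str(dataset_id),
                file_name=f.get("key", ""),
                size_bytes=f.get("size"),
                download_url=(f.get("links") or {}).get("self"),
            )
            for f in payload.get("files", [])
        ]
        return dataset, files

    def fetch_zip_listing(self, file: FileRecord) -> ZipListing:
        if not file.download_url:
            return ZipListing(supported=False)
        # The preview is HTML served next to the file; fetch and parse it.
        url = file.download_url.rstrip("/") + "/preview"
        try:
            with urllib.request.urlopen(url, timeout=30) as resp:
                markup = resp.read().decode("utf-8", errors="replace")
        except Exception:  # noqa: BLE001
            return ZipListing(supported=False)
        return parse_zip_preview(markup, "zenodo")
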