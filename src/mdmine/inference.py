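"""Rule-based metadata inference.

Every label this module produces is derived from simple, auditable rules:

* files are assigned to an MD engine purely by their extension, with
  ambiguous extensions (.top, .dcd, ...) trusted only when the dataset
  metadata carries an MD keyword;
* particles are categorised (protein / lipid / nucleic / glucid /
  water_ions) by looking their residue name up in a curated lexicon, and
  a system is classified by the set of non-solvent categories it contains;
* model resolution is inferred from the integration time step — steps of
  10 fs and above are only stable for coarse-grain models such as Martini;
* a run counts as production when it integrates dynamics (``md``/``sd``)
  for more than 1 ns, and as non-production when it is a minimiser or
  couples to neither a temperature nor a pressure bath;
* thermostat and barostat tokens are normalised onto the closed Gromacs
  vocabularies.

The lexicon, engine rule table and keyword list ship as an editable YAML
file (see :func:`load_config`).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import yaml

from .gmx_formats import GroStructure, MdpSummary

__all__ = [
    "EngineRule",
    "ResidueLexicon",
    "GroSummary",
    "RunLabel",
    "InferenceConfig",
    "load_config",
    "default_config",
    "assign_engine",
    "categorize_residue",
    "summarize_composition",
    "classify_system",
    "infer_resolution",
    "infer_run_type",
    "normalize_thermostat",
    "normalize_barostat",
]

CATEGORIES = ("protein", "lipid", "nucleic", "glucid", "water_ions")
SOLUTE_CATEGORIES = ("protein", "lipid", "nucleic", "glucid")

ENGINES = ("gromacs", "amber", "namd-charmm", "desmond")

# Closed vocabularies from the Gromacs documentation.
THERMOSTATS = ("no", "berendsen", "nose-hoover", "andersen", "andersen-massive",
               "v-rescale")
BAROSTATS = ("no", "berendsen", "c-rescale", "parrinello-rahman", "mttk")

# Coarse-grain models (Martini and kin) integrate with steps of 10 fs and up.
CG_DT_CUTOFF_PS = 0.01

PRODUCTION_INTEGRATORS = frozenset({"md", "sd"})
MINIMIZER_INTEGRATORS = frozenset({"steep", "cg", "l-bfgs", "l_bfgs"})


@dataclass(frozen=True)
class EngineRule:
    """One extension -> engine assignment rule."""

    extension: str
    engine: str
    requires_keyword: bool = False


@dataclass
class ResidueLexicon:
    """Case-insensitive residue-name -> category lookup."""

    category_of: dict[str, str]

    def __post_init__(self) -> None:
        self.category_of = {k.upper(): v for k, v in self.category_of.items()}

    def lookup(self, name: str) -> str:
        return self.category_of.get(name.strip().upper(), "other")


@dataclass
class InferenceConfig:
    """Curated configuration: lexicon, engine rules and keyword list."""

    lexicon: ResidueLexicon
    engine_rules: dict[str, EngineRule]
    keywords: tuple[str, ...]
    trusted_extensions: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.trusted_extensions:
            self.trusted_extensions = tuple(sorted(self.engine_rules))

    def has_md_keyword(self, *texts: Optional[str]) -> bool:
        blob = " ".join(t for t in texts if t).lower()
        return any(kw in blob for kw in self.keywords)


def _build_config(raw: Mapping) -> InferenceConfig:
    lex: dict[str, str] = {}
    for category, tokens in raw["residue_categories"].items():
        if category not in CATEGORIES:
            raise ValueError(f"unknown residue category {category!r}")
        for token in tokens:
            token = str(token).upper()
            if lex.get(token, category) != category:
                raise ValueError(f"residue {token!r} mapped to two categories")
            lex[token] = category
    rules: dict[str, EngineRule] = {}
    for engine, spec in raw["engines"].items():
        if engine not in ENGINES:
            raise ValueError(f"unknown engine {engine!r}")
        for ext in spec.get("unique", []):
            rules[str(ext).lower()] = EngineRule(str(ext).lower(), engine, False)
        for ext in spec.get("ambiguous", []):
            rules[str(ext).lower()] = EngineRule(str(ext).lower(), engine, True)
    keywords = tuple(str(k).lower() for k in raw.get("keywords", []))
    return InferenceConfig(lexicon=ResidueLexicon(lex), engine_rules=rules,
                           keywords=keywords)


def load_config(path: Union[str, Path]) -> InferenceConfig:
    """Load a lexicon / rule-table / keyword configuration from YAML."""
    with open(path, "r", encoding="utf-8") as fh:
        return _build_config(yaml.safe_load(fh))


_DEFAULT: Optional[InferenceConfig] = None


def default_config() -> InferenceConfig:
    """The packaged curated configuration (cached)."""
    global _DEFAULT
    if _DEFAULT is None:
        ref = importlib.resources.files("mdmine.data") / "default_config.yaml"
        _DEFAULT = _build_config(yaml.safe_load(ref.read_text(encoding="utf-8")))
    return _DEFAULT


# ---------------------------------------------------------------------------
# engine assignment
# ---------------------------------------------------------------------------

def assign_engine(extension: str, dataset_has_md_keyword: bool = False,
                  rules: Optional[Mapping[str, EngineRule]] = None) -> str:
    """Assign a file extension to an MD engine, or ``"unknown"``.

    Ambiguous extensions (``requires_keyword``) are assigned only when the
    owning dataset's metadata contains an MD keyword.
    """
    if rules is None:
        rules = default_config().engine_rules
    rule = rules.get(extension.lower().lstrip("."))
    if rule is None:
        return "unknown"
    if rule.requires_keyword and not dataset_has_md_keyword:
        return "unknown"
    return rule.engine


# ---------------------------------------------------------------------------
# composition and system class
# ---------------------------------------------------------------------------

def categorize_residue(name: str, lexicon: Optional[ResidueLexicon] = None) -> str:
    """Look a residue name up in the lexicon; unmapped names are ``"other"``."""
    if lexicon is None:
        lexicon = default_config().lexicon
    return lexicon.lookup(name)


def classify_system(category_counts: Mapping[str, int]) -> str:
    """Label a system by its set of non-solvent molecular categories.

    The label is the sorted ``+``-joined set of categories with nonzero
    particle counts, excluding water/ions and ``other``.  Systems with no
    such category are ``"water/ions only"`` when they contain water/ions
    and nothing unrecognised, else ``"other"``.
    """
    members = sorted(c for c in SOLUTE_CATEGORIES if category_counts.get(c, 0) > 0)
    if members:
        return "+".join(members)
    if category_counts.get("water_ions", 0) > 0 and category_counts.get("other", 0) == 0:
        return "water/ions only"
    return "other"


@dataclass
class GroSummary:
    """Particle count, per-category composition and system class."""

    n_particles: int
    category_counts: dict[str, int]
    system_class: str
    has_velocities: bool = False


def summarize_composition(structure: GroStructure,
                          lexicon: Optional[ResidueLexicon] = None) -> GroSummary:
    """Tally particles per category and classify the system."""
    if lexicon is None:
        lexicon = default_config().lexicon
    counts: dict[str, int] = {c: 0 for c in CATEGORIES}
    counts["other"] = 0
    for atom in structure.atoms:
        counts[lexicon.lookup(atom.residue_name)] += 1
    return GroSummary(
        n_particles=structure.declared_atom_count,
        category_counts=counts,
        system_class=classify_system(counts),
        has_velocities=structure.has_velocities,
    )


# ---------------------------------------------------------------------------
# resolution and run type
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RunLabel:
    resolution: str   # all-atom | coarse-grain | unknown
    run_type: str     # production | non-production | unknown


def infer_resolution(dt_ps: Optional[float]) -> str:
    """Classify model resolution from the integration time step.

    Steps of 10 fs (dt = 0.01 ps) and above are only numerically stable
    for coarse-grain force fields, so the cutoff is inclusive.
    """
    if dt_ps is None:
        return "unknown"
    return "coarse-grain" if dt_ps >= CG_DT_CUTOFF_PS else "all-atom"


def infer_run_type(summary: MdpSummary, min_time_ns: float = 1.0) -> str:
    """Label a parameter file as production, non-production or unknown.

    Production: dynamics integrator (``md``/``sd``) with a planned
    simulation time above ``min_time_ns`` — the filter that excludes most
    minimisation and equilibration setups.  Non-production: an energy
    minimiser, or coupling to neither a thermostat nor a barostat.
    """
    integrator = (summary.integrator or "").lower()
    if (integrator in PRODUCTION_INTEGRATORS
            and summary.sim_time_ns is not None
            and summary.sim_time_ns > min_time_ns):
        return "production"
    if integrator in MINIMIZER_INTEGRATORS:
        return "non-production"
    if summary.thermostat in ("undefined", "no") and summary.barostat in ("undefined", "no"):
        return "non-production"
    return "unknown"


def label_run(summary: MdpSummary, min_time_ns: float = 1.0) -> RunLabel:
    return RunLabel(resolution=infer_resolution(summary.dt_ps),
                    run_type=infer_run_type(summary, min_time_ns))


# ---------------------------------------------------------------------------
# thermostat / barostat vocabulary normalisation
# ---------------------------------------------------------------------------

def _normalize_vocab(raw: Optional[str], vocabulary: tuple[str, ...]) -> str:
    if raw is None or not str(raw).strip():
        return "undefined"
    token = str(raw).strip().lower()
    if token == "undefined":  # keeps normalisation idempotent
        return "undefined"
    # Gromacs spells these with '-'; accept '_' and spaces as separators.
    canonical = token.replace("_", "-").replace(" ", "-")
    return canonical if canonical in vocabulary else "unrecognized"


def normalize_thermostat(raw: Optional[str]) -> str:
    """Map a tcoupl token onto the Gromacs thermostat vocabulary."""
    return _normalize_vocab(raw, THERMOSTATS)


def normalize_barostat(raw: Optional[str]) -> str:
    """Map a pcoupl token onto the Gromacs barostat vocabulary."""
    return _normalize_vocab(raw, BAROSTATS)
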