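"""Native parsers for the Gromacs file formats mined by the pipeline.

Four formats are handled, each with a summary object tailored to corpus
profiling rather than to simulation replay:

``.gro``
    Fixed-column coordinate text: a title line, a particle count, one line
    per particle (residue number/name, atom name/number, position in nm,
    optional velocity in nm/ps) and a box line of 3 or 9 floats.
``.mdp``
    ``key = value`` run-parameter text.  Keys are normalised (lowercased,
    ``-`` mapped to ``_``) the same way the Gromacs preprocessor treats
    them, so ``Tcoupl``, ``tcoupl`` and ``tCoupl`` collapse to one key.
``.xtc``
    XDR-encoded compressed binary trajectory.  Only frame headers are
    decoded — coordinates are skipped by length — which is all that is
    needed to count frames and particles.
``.log``
    Free-text run log, scanned for the Gromacs version banner and the
    echoed command line.

All text parsers accept LF and CRLF line endings, and byte inputs are
decoded as UTF-8 with a latin-1 fallback.
"""

from __future__ import annotations

import io
import math
import re
import struct
from dataclasses import dataclass, field
from typing import BinaryIO, Iterable, Mapping, Optional, TextIO, Union

__all__ = [
    "GroAtomLine",
    "GroStructure",
    "MdpParameters",
    "MdpSummary",
    "XtcSummary",
    "LogSummary",
    "GroParseError",
    "XtcFormatError",
    "parse_gro",
    "parse_mdp",
    "summarize_mdp",
    "scan_xtc",
    "parse_log",
]

# Gromacs runtime defaults applied when a .mdp omits the key entirely.
DEFAULT_DT_PS = 0.001
DEFAULT_NSTEPS = 0

XTC_MAGIC = 1995
# Coordinate blocks for systems this small are stored as plain floats.
XTC_UNCOMPRESSED_MAX_ATOMS = 9


class GroParseError(ValueError):
    """A .gro file violates the fixed-column layout or its own count line."""

    def __init__(self, message: str, line_number: Optional[int] = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class XtcFormatError(ValueError):
    """A byte stream is not a structurally valid XTC trajectory."""


def _as_text(source: Union[str, bytes, TextIO]) -> str:
    if isinstance(source, str):
        return source
    if isinstance(source, bytes):
        try:
            return source.decode("utf-8")
        except UnicodeDecodeError:
            return source.decode("latin-1")
    return source.read()


def _as_bytes(source: Union[bytes, bytearray, BinaryIO]) -> bytes:
    if isinstance(source, (bytes, bytearray)):
        return bytes(source)
    return source.read()


# ---------------------------------------------------------------------------
# .gro — fixed-column coordinates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroAtomLine:
    """One particle record of a .gro file.

    Residue and atom numbers wrap above 99,999 in large systems; they are
    kept verbatim and never used for counting.
    """

    residue_number: int
    residue_name: str
    atom_name: str
    atom_number: int
    x: float
    y: float
    z: float
    vx: Optional[float] = None
    vy: Optional[float] = None
    vz: Optional[float] = None

    @property
    def has_velocity(self) -> bool:
        return self.vx is not None


@dataclass
class GroStructure:
    """A parsed .gro file: title, particles and box vectors (nm)."""

    title: str
    declared_atom_count: int
    atoms: list[GroAtomLine]
    box: tuple[float, ...]

    @property
    def has_velocities(self) -> bool:
        return bool(self.atoms) and all(a.has_velocity for a in self.atoms)


def _float_field(line: str, start: int, end: int, line_number: int, what: str) -> float:
    token = line[start:end].strip()
    try:
        value = float(token)
    except ValueError:
        raise GroParseError(f"cannot read {what} from columns {start + 1}-{end}: {token!r}",
                            line_number) from None
    if not math.isfinite(value):
        raise GroParseError(f"non-finite {what}: {token!r}", line_number)
    return value


def _int_field(line: str, start: int, end: int, line_number: int, what: str) -> int:
    token = line[start:end].strip()
    try:
        return int(token)
    except ValueError:
        raise GroParseError(f"cannot read {what} from columns {start + 1}-{end}: {token!r}",
                            line_number) from None


def parse_gro(source: Union[str, bytes, TextIO]) -> GroStructure:
    """Parse a .gro coordinate file.

    Columns follow the canonical layout: residue number (1-5), residue
    name (6-10), atom name (11-15), atom number (16-20), then three 8-wide
    position fields; three further 8-wide fields, when present, hold
    velocities.

    Raises
    ------
    GroParseError
        If the file has fewer than 3 lines, the declared particle count
        disagrees with the number of atom lines, a fixed-column field is
        not numeric, or the box line has neither 3 nor 9 floats.
    """
    text = _as_text(source)
    lines = text.replace("\r\n", "\n").split("\n")
    # trailing newline produces one empty trailing element
    while lines and lines[-1] == "":
        lines.pop()
    if len(lines) < 3:
        raise GroParseError("a .gro file needs at least a title, a count and a box line")

    title = lines[0]
    try:
        declared = int(lines[1].strip())
    except ValueError:
        raise GroParseError(f"cannot read particle count: {lines[1]!r}", 2) from None
    if declared < 0:
        raise GroParseError(f"negative particle count: {declared}", 2)

    atom_lines = lines[2:-1]
    if len(atom_lines) != declared:
        raise GroParseError(
            f"declared particle count {declared} but found {len(atom_lines)} atom lines"
        )

    atoms: list[GroAtomLine] = []
    for i, line in enumerate(atom_lines):
        n = i + 3  # 1-based file line number
        residue_number = _int_field(line, 0, 5, n, "residue number")
        residue_name = line[5:10].strip()
        atom_name = line[10:15].strip()
        if not residue_name:
            raise GroParseError("empty residue name", n)
        if not atom_name:
            raise GroParseError("empty atom name", n)
        atom_number = _int_field(line, 15, 20, n, "atom number")
        x = _float_field(line, 20, 28, n, "x position")
        y = _float_field(line, 28, 36, n, "y position")
        z = _float_field(line, 36, 44, n, "z position")
        vx = vy = vz = None
        if len(line.rstrip()) > 44 + 23:  # room for three more 8-wide fields
            vx = _float_field(line, 44, 52, n, "x velocity")
            vy = _float_field(line, 52, 60, n, "y velocity")
            vz = _float_field(line, 60, 68, n, "z velocity")
        atoms.append(GroAtomLine(residue_number, residue_name, atom_name,
                                 atom_number, x, y, z, vx, vy, vz))

    box_tokens = lines[-1].split()
    try:
        box = tuple(float(t) for t in box_tokens)
    except ValueError:
        raise GroParseError(f"cannot read box line: {lines[-1]!r}", len(lines)) from None
    if len(box) not in (3, 9):
        raise GroParseError(
            f"box line must have 3 or 9 floats, found {len(box)}", len(lines)
        )
    return GroStructure(title=title, declared_atom_count=declared, atoms=atoms, box=box)


# ---------------------------------------------------------------------------
# .mdp — run parameters
# ---------------------------------------------------------------------------

def normalize_mdp_key(key: str) -> str:
    """Lowercase and map ``-`` to ``_``, the Gromacs preprocessor convention."""
    return key.strip().lower().replace("-", "_")


@dataclass
class MdpParameters:
    """Raw key/value entries of a .mdp file, keys normalised, last wins."""

    entries: dict[str, str] = field(default_factory=dict)
    source_line_count: int = 0
    warnings: list[str] = field(default_factory=list)

    def serialize(self) -> str:
        """Render back to ``key = value`` lines (re-parsing is the identity)."""
        return "\n".join(f"{k} = {v}" for k, v in self.entries.items()) + "\n"


def parse_mdp(source: Union[str, bytes, TextIO]) -> MdpParameters:
    """Parse a .mdp parameter file.

    ``;`` comments run to end of line, blank lines are skipped, each
    remaining line splits on the first ``=``.  Duplicate keys resolve
    last-wins.  A non-blank line without ``=`` is recorded as a warning,
    never fatal.
    """
    text = _as_text(source)
    params = MdpParameters()
    for i, raw in enumerate(text.replace("\r\n", "\n").split("\n"), start=1):
        params.source_line_count = i
        line = raw.split(";", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            params.warnings.append(f"line {i}: no '=' separator: {raw.strip()!r}")
            continue
        key, value = line.split("=", 1)
        key = normalize_mdp_key(key)
        if not key:
            params.warnings.append(f"line {i}: empty key: {raw.strip()!r}")
            continue
        params.entries[key] = value.strip()
        # dict preserves first-insertion order; re-setting keeps position but
        # the value is the last occurrence, matching the preprocessor.
    return params


@dataclass
class MdpSummary:
    """Profiling summary of one .mdp file.

    ``sim_time_ns`` is the planned simulation length, the product of the
    time step and the number of steps; it is absent when either token was
    present but unreadable.
    """

    integrator: Optional[str] = None
    dt_ps: Optional[float] = DEFAULT_DT_PS
    nsteps: Optional[int] = DEFAULT_NSTEPS
    ref_t_K: Optional[float] = None
    tcoupl_raw: Optional[str] = None
    pcoupl_raw: Optional[str] = None
    thermostat: str = "undefined"
    barostat: str = "undefined"
    sim_time_ns: Optional[float] = 0.0
    warnings: list[str] = field(default_factory=list)


def summarize_mdp(params: MdpParameters) -> MdpSummary:
    """Distil an :class:`MdpParameters` into the profiled quantities.

    Missing ``dt`` defaults to 0.001 ps and missing ``nsteps`` to 0 (the
    Gromacs runtime defaults); unreadable numeric tokens mark the field
    absent with a warning instead of failing.  The reference temperature is
    the first group of ``ref_t``; differing groups emit a warning.
    """
    from .inference import normalize_barostat, normalize_thermostat

    s = MdpSummary()
    e = params.entries

    s.integrator = e.get("integrator") or None

    if "dt" in e:
        try:
            s.dt_ps = float(e["dt"])
        except ValueError:
            s.dt_ps = None
            s.warnings.append(f"unreadable dt: {e['dt']!r}")
    if s.dt_ps is not None and s.dt_ps <= 0:
        s.warnings.append(f"non-positive dt: {s.dt_ps}")
        s.dt_ps = None

    if "nsteps" in e:
        try:
            s.nsteps = int(float(e["nsteps"]))
        except ValueError:
            s.nsteps = None
            s.warnings.append(f"unreadable nsteps: {e['nsteps']!r}")

    if "ref_t" in e:
        groups = e["ref_t"].split()
        if groups:
            try:
                values = [float(g) for g in groups]
                s.ref_t_K = values[0]
                if len(set(values)) > 1:
                    s.warnings.append(f"differing ref_t groups: {e['ref_t']!r}")
            except ValueError:
                s.warnings.append(f"unreadable ref_t: {e['ref_t']!r}")

    s.tcoupl_raw = e.get("tcoupl")
    s.pcoupl_raw = e.get("pcoupl")
    s.thermostat = normalize_thermostat(s.tcoupl_raw)
    s.barostat = normalize_barostat(s.pcoupl_raw)

    if s.dt_ps is not None and s.nsteps is not None:
        s.sim_time_ns = s.dt_ps * s.nsteps / 1000.0
    else:
        s.sim_time_ns = None
    return s


# ---------------------------------------------------------------------------
# .xtc — XDR binary trajectory, header-only scan
# ---------------------------------------------------------------------------

@dataclass
class XtcSummary:
    """Frame and particle counts from a header-only trajectory scan."""

    n_atoms: int
    n_frames: int
    first_time_ps: Optional[float] = None
    last_time_ps: Optional[float] = None
    truncated: bool = False


def scan_xtc(source: Union[bytes, bytearray, BinaryIO]) -> XtcSummary:
    """Count frames and particles of an XTC byte stream without decoding
    coordinates.

    Each frame starts with a big-endian XDR header — magic 1995, atom
    count, step, time — followed by a 9-float box and the coordinate
    block.  Systems of at most 9 atoms store plain floats; larger systems
    store a compressed block whose layout (atom count, precision, integer
    bounds, small-index, byte count) gives the number of bytes to skip,
    rounded up to a multiple of 4.

    A trailing partial frame sets ``truncated`` instead of failing.

    Raises
    ------
    XtcFormatError
        If the first frame's magic is not 1995 (the stream is not XTC) or
        a later frame reports a different atom count than the first.
    """
    data = _as_bytes(source)
    view = memoryview(data)
    pos = 0
    size = len(data)

    n_atoms = 0
    n_frames = 0
    first_time: Optional[float] = None
    last_time: Optional[float] = None

    def read_ints(offset: int, count: int) -> tuple[int, ...]:
        return struct.unpack_from(f">{count}i", view, offset)

    while pos < size:
        try:
            if pos + 16 > size:
                raise EOFError
            magic, atoms, _step = read_ints(pos, 3)
            (time_ps,) = struct.unpack_from(">f", view, pos + 12)
            pos += 16
            if magic != XTC_MAGIC:
                if n_frames == 0:
                    raise XtcFormatError(
                        f"bad magic number {magic} (expected {XTC_MAGIC}); not an XTC stream"
                    )
                raise XtcFormatError(f"bad magic number {magic} in frame {n_frames}")
            if n_frames == 0:
                n_atoms = atoms
            elif atoms != n_atoms:
                raise XtcFormatError(
                    f"inconsistent atom count: frame {n_frames} has {atoms}, "
                    f"first frame had {n_atoms}"
                )
            # 9-float box
            if pos + 36 > size:
                raise EOFError
            pos += 36
            # coordinate block: leading (repeated) atom count
            if pos + 4 > size:
                raise EOFError
            (block_atoms,) = read_ints(pos, 1)
            pos += 4
            if block_atoms != atoms:
                raise XtcFormatError(
                    f"coordinate block atom count {block_atoms} differs from header {atoms}"
                )
            if atoms <= XTC_UNCOMPRESSED_MAX_ATOMS:
                need = 12 * atoms
                if pos + need > size:
                    raise EOFError
                pos += need
            else:
                # precision, 3 min ints, 3 max ints, small-index, byte count
                if pos + 36 > size:
                    raise EOFError
                (nbytes,) = read_ints(pos + 32, 1)
                pos += 36
                if nbytes < 0:
                    raise XtcFormatError(f"negative compressed block size {nbytes}")
                padded = (nbytes + 3) & ~3
                if pos + padded > size:
                    raise EOFError
                pos += padded
        except EOFError:
            # partial trailing frame: count what completed, flag truncation
            return XtcSummary(
                n_atoms=n_atoms,
                n_frames=n_frames,
                first_time_ps=first_time,
                last_time_ps=last_time,
                truncated=True,
            )
        n_frames += 1
        if first_time is None:
            first_time = time_ps
        last_time = time_ps

    return XtcSummary(
        n_atoms=n_atoms,
        n_frames=n_frames,
        first_time_ps=first_time,
        last_time_ps=last_time,
        truncated=False,
    )


# ---------------------------------------------------------------------------
# .log — run log scan
# ---------------------------------------------------------------------------

@dataclass
class LogSummary:
    gromacs_version: Optional[str] = None
    command_line: Optional[str] = None


_VERSION_RE = re.compile(r"GROMACS\s+version:\s*(\S+)", re.IGNORECASE)
_BANNER_RE = re.compile(r":-\)\s*GROMACS\s*-\s*[^,]+,\s*(?:VERSION\s+)?(\S+?)\s*(?:\(-:)?\s*$",
                        re.IGNORECASE)


def parse_log(source: Union[str, bytes, TextIO]) -> LogSummary:
    """Extract the Gromacs version and command line from a run log.

    The version comes from the first ``GROMACS version:`` line or, failing
    that, from the ``:-) GROMACS - gmx mdrun, VERSION (-:`` banner.  The
    command line is the first non-blank line following ``Command line:``.
    Fields are absent when no pattern matches.
    """
    text = _as_text(source)
    summary = LogSummary()
    lines = text.replace("\r\n", "\n").split("\n")
    for i, line in enumerate(lines):
        if summary.gromacs_version is None:
            m = _VERSION_RE.search(line)
            if m:
                summary.gromacs_version = m.group(1)
            else:
                m = _BANNER_RE.search(line)
                if m:
                    summary.gromacs_version = m.group(1)
        if summary.command_line is None and line.strip().lower() == "command line:":
            for follow in lines[i + 1:]:
                if follow.strip():
                    summary.command_line = follow.strip()
                    break
        if summary.gromacs_version is not None and summary.command_line is not None:
            break
    return summary
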