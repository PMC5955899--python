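"""Reading, writing and validating raw keystroke session logs.

A typing session is one short transcription on a touchscreen keyboard. The
capture layer records, for every key tap, the press and release timestamps in
milliseconds and the OS-reported normalised pressure in [0, 1]. The canonical
on-disk format is one event per line::

    press_ms<TAB>release_ms<TAB>pressure

Comment/header lines start with ``#``. Comma-delimited files are tolerated. An
optional fourth column flags artefact events (e.g. long presses on keyboards
that support them); flagged events are dropped on read.

Cohorts are described by a tab-separated manifest with one row per subject
(subject id, group label, semicolon-joined session file paths, optional UPDRS
Part III item scores).
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable

from .errors import EmptySessionError, MalformedLogError

__all__ = [
    "KeystrokeEvent",
    "TypingSession",
    "SubjectRecord",
    "ValidationReport",
    "read_session_log",
    "write_session_log",
    "validate_session",
    "write_cohort",
    "read_cohort",
    "MIN_TYPING_RATE_CPM",
]

#: Sessions typed slower than this (characters per minute) are excluded.
MIN_TYPING_RATE_CPM = 20.0

_SPLIT = re.compile(r"[,\t ]+")
_FLAG_TOKENS = {"1", "l", "long", "x", "true"}


@dataclass(frozen=True)
class KeystrokeEvent:
    """One key tap: press/release timestamps (ms) and normalised pressure."""

    t_press: int
    t_release: int
    pressure: float

    def __post_init__(self) -> None:
        if self.t_press < 0:
            raise MalformedLogError(f"negative press timestamp {self.t_press}")
        if self.t_release <= self.t_press:
            raise MalformedLogError(
                f"release ({self.t_release}) must follow press ({self.t_press})"
            )
        if not 0.0 <= self.pressure <= 1.0:
            raise MalformedLogError(f"pressure {self.pressure} outside [0, 1]")


@dataclass
class TypingSession:
    """Ordered keystroke events of one transcription excerpt."""

    subject_id: str
    session_index: int
    events: list[KeystrokeEvent]

    def __post_init__(self) -> None:
        presses = [e.t_press for e in self.events]
        if any(b <= a for a, b in zip(presses, presses[1:])):
            raise MalformedLogError("press timestamps must be strictly increasing")

    @property
    def n_chars(self) -> int:
        """Number of keys pressed (N)."""
        return len(self.events)

    @property
    def duration_s(self) -> float:
        """Last release minus first press, in seconds."""
        if not self.events:
            return 0.0
        return (self.events[-1].t_release - self.events[0].t_press) / 1000.0


@dataclass
class SubjectRecord:
    """A subject's group label, sessions and optional clinical scores."""

    subject_id: str
    label: str  # "PD" or "control"
    sessions: list[TypingSession] = field(default_factory=list)
    updrs_items: dict[str, int] | None = None
    updrs_total: int | None = None

    def __post_init__(self) -> None:
        if self.label not in ("PD", "control"):
            raise ValueError(f"label must be 'PD' or 'control', got {self.label!r}")
        if self.updrs_items is not None and any(v < 0 for v in self.updrs_items.values()):
            raise ValueError("UPDRS item scores must be non-negative")


@dataclass(frozen=True)
class ValidationReport:
    subject_id: str
    session_index: int
    typing_rate: float | None  # chars per minute; None when undefined
    passed: bool
    reasons: tuple[str, ...]


def _coerce_stream(source: str | Path | IO[str]) -> IO[str]:
    if isinstance(source, Path):
        return source.open()
    if isinstance(source, str):
        if "\n" in source or "\t" in source or "," in source:
            return io.StringIO(source)
        return open(source)
    return source


def read_session_log(
    source: str | Path | IO[str], subject_id: str, session_index: int
) -> TypingSession:
    """Parse a raw session log into a :class:`TypingSession`.

    Events are sorted by press timestamp; flagged (artefact) events are
    dropped. Raises :class:`EmptySessionError` for event-free files and
    :class:`MalformedLogError` for invariant violations (bad fields, pressure
    outside [0, 1], release before press, duplicate press timestamps).
    """
    stream = _coerce_stream(source)
    events: list[KeystrokeEvent] = []
    for lineno, line in enumerate(stream, start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        tokens = [t for t in _SPLIT.split(line) if t]
        if len(tokens) not in (3, 4):
            raise MalformedLogError(f"line {lineno}: expected 3 or 4 fields, got {len(tokens)}")
        if len(tokens) == 4 and tokens[3].lower() in _FLAG_TOKENS:
            continue  # flagged artefact event (e.g. long press)
        try:
            t_press, t_release = int(tokens[0]), int(tokens[1])
            pressure = float(tokens[2])
        except ValueError as exc:
            raise MalformedLogError(f"line {lineno}: {exc}") from exc
        events.append(KeystrokeEvent(t_press, t_release, pressure))
    if not events:
        raise EmptySessionError(f"{subject_id} session {session_index}: no events")
    events.sort(key=lambda e: e.t_press)
    presses = [e.t_press for e in events]
    if any(b <= a for a, b in zip(presses, presses[1:])):
        raise MalformedLogError("duplicate press timestamps")
    return TypingSession(subject_id, session_index, events)


def write_session_log(session: TypingSession, target: str | Path | IO[str] | None = None) -> str:
    """Serialise a session to the canonical tab-delimited text format.

    Returns the serialised text; also writes it to ``target`` when given.
    ``read_session_log(write_session_log(s))`` reproduces ``s`` exactly.
    """
    lines = ["# press_ms\trelease_ms\tpressure"]
    for e in session.events:
        lines.append(f"{e.t_press}\t{e.t_release}\t{e.pressure:.3f}")
    text = "\n".join(lines) + "\n"
    if isinstance(target, (str, Path)):
        Path(target).write_text(text)
    elif target is not None:
        target.write(text)
    return text


def validate_session(
    session: TypingSession, min_rate_cpm: float = MIN_TYPING_RATE_CPM
) -> ValidationReport:
    """Check the typing-rate lower bound (inclusive: rate >= bound passes).

    The rate is N keys over the total session duration (last release minus
    first press). Single-event sessions have an undefined rate and fail.
    Failing sessions are meant to be omitted from downstream analysis.
    """
    reasons: list[str] = []
    if session.n_chars < 2:
        return ValidationReport(
            session.subject_id,
            session.session_index,
            None,
            False,
            ("typing rate undefined for a session with fewer than two events",),
        )
    rate = session.n_chars / (session.duration_s / 60.0)
    if rate < min_rate_cpm:
        reasons.append(
            f"typing rate {rate:.1f} cpm below the {min_rate_cpm:g} cpm lower bound"
        )
    return ValidationReport(
        session.subject_id, session.session_index, rate, not reasons, tuple(reasons)
    )


# ---------------------------------------------------------------------------
# Cohort manifests


def _session_filename(subject_id: str, session_index: int) -> str:
    return f"{subject_id}_s{session_index:02d}.txt"


def write_cohort(subjects: Iterable[SubjectRecord], out_dir: str | Path) -> Path:
    """Write session logs and a per-subject manifest under ``out_dir``.

    Returns the manifest path. UPDRS item columns are prefixed ``updrs_``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    subjects = list(subjects)
    item_names = sorted({k for s in subjects if s.updrs_items for k in s.updrs_items})
    header = ["subject_id", "label", "sessions", "updrs_total"] + [
        f"updrs_{k}" for k in item_names
    ]
    rows = ["\t".join(header)]
    for subj in subjects:
        paths = []
        for sess in subj.sessions:
            name = _session_filename(subj.subject_id, sess.session_index)
            write_session_log(sess, out / name)
            paths.append(name)
        items = subj.updrs_items or {}
        row = [
            subj.subject_id,
            subj.label,
            ";".join(paths),
            "" if subj.updrs_total is None else str(subj.updrs_total),
        ] + [str(items.get(k, "")) for k in item_names]
        rows.append("\t".join(row))
    manifest = out / "manifest.tsv"
    manifest.write_text("\n".join(rows) + "\n")
    return manifest


def read_cohort(manifest: str | Path) -> list[SubjectRecord]:
    """Load a cohort written by :func:`write_cohort`."""
    manifest = Path(manifest)
    base = manifest.parent
    lines = manifest.read_text().strip().splitlines()
    header = lines[0].split("\t")
    idx = {name: i for i, name in enumerate(header)}
    item_cols = [h for h in header if h.startswith("updrs_") and h != "updrs_total"]
    subjects: list[SubjectRecord] = []
    for line in lines[1:]:
        cells = line.split("\t")
        sid, label = cells[idx["subject_id"]], cells[idx["label"]]
        sessions = []
        for k, rel in enumerate(filter(None, cells[idx["sessions"]].split(";")), start=1):
            m = re.search(r"_s(\d+)\.txt$", rel)
            session_index = int(m.group(1)) if m else k
            sessions.append(read_session_log(base / rel, sid, session_index))
        def cell(col: str) -> str:
            i = idx.get(col)
            return cells[i] if i is not None and i < len(cells) else ""

        total_cell = cell("updrs_total")
        items = {
            c.removeprefix("updrs_"): int(cell(c)) for c in item_cols if cell(c) != ""
        }
        subjects.append(
            SubjectRecord(
                sid,
                label,
                sessions,
                updrs_items=items or None,
                updrs_total=int(total_cell) if total_cell else None,
            )
        )
    return subjects
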