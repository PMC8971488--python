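"""Reactivity-profile containers and database I/O.

A reactivity profile carries, for one transcript, the per-nucleotide signal
produced by chemical probing (e.g. SHAPE): high values mark flexible,
typically unpaired positions, low values mark constrained, typically paired
positions.  Positions without usable signal are MISSING and represented as
``numpy.nan``.  Databases of profiles can alternatively carry per-base
pairing probabilities, in which case every defined value lies in [0, 1].

On-disk formats
---------------
* RNA Framework-style reactivity XML (input): ``<transcript id=...>`` records
  with ``<sequence>`` and ``<reactivity>`` children, the latter a
  comma-separated list with ``NaN`` for missing values.
* A plain TSV fallback (input): ``id<TAB>sequence<TAB>r1,r2,...``.
* A versioned plain-text database format (input/output), documented in
  :func:`write_db`.

Coordinates are 0-based half-open everywhere in the API; user-facing reports
convert to 1-based inclusive.
"""

from __future__ import annotations

import io
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "MISSING",
    "ReactivityProfile",
    "ProfileDatabase",
    "read_rnaframework_xml",
    "read_tsv",
    "cap_reactivity",
    "write_db",
    "load_db",
]

#: Sentinel for positions without usable probing signal.
MISSING = float("nan")

_VALID_BASES = frozenset("ACGUN")

SHAPE_KIND = "shape-reactivity"
BPP_KIND = "base-pairing-probability"

_DB_MAGIC = "#shapesearch-db"
_DB_VERSION = "1"


def _normalize_sequence(seq: str, record: str) -> str:
    s = "".join(seq.split()).upper().replace("T", "U")
    bad = set(s) - _VALID_BASES
    if bad:
        raise ValueError(
            f"record {record!r}: invalid bases {sorted(bad)} "
            "(alphabet is A/C/G/U/N; T is normalized to U)"
        )
    return s


@dataclass(frozen=True)
class ReactivityProfile:
    """One transcript: identifier, sequence and per-base reactivities.

    Parameters
    ----------
    id : str
        Non-empty transcript identifier, unique within a database.
    sequence : str
        RNA sequence over A/C/G/U/N.  ``T`` is accepted and normalized to
        ``U``; other ambiguity codes are rejected.
    reactivity : numpy.ndarray
        Float vector, same length as ``sequence``; ``nan`` marks MISSING and
        every defined value must be >= 0.
    """

    id: str
    sequence: str
    reactivity: np.ndarray

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("profile id must be non-empty")
        object.__setattr__(
            self, "sequence", _normalize_sequence(self.sequence, self.id)
        )
        arr = np.asarray(self.reactivity, dtype=float)
        arr = np.array(arr, copy=True)
        arr.setflags(write=False)
        object.__setattr__(self, "reactivity", arr)
        if arr.ndim != 1 or len(self.sequence) != arr.size:
            raise ValueError(
                f"record {self.id!r}: sequence length {len(self.sequence)} != "
                f"reactivity length {arr.size}"
            )
        defined = arr[~np.isnan(arr)]
        if defined.size and defined.min() < 0:
            raise ValueError(
                f"record {self.id!r}: negative reactivity values are not allowed"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def slice(self, start: int, end: int, new_id: str | None = None) -> "ReactivityProfile":
        """Sub-profile over the 0-based half-open interval [start, end)."""
        if not (0 <= start <= end <= len(self)):
            raise ValueError(f"invalid interval [{start}, {end}) for length {len(self)}")
        return ReactivityProfile(
            id=new_id or self.id,
            sequence=self.sequence[start:end],
            reactivity=self.reactivity[start:end],
        )


def cap_reactivity(profile: ReactivityProfile, max_reactivity: float) -> np.ndarray:
    """Return the profile's values with every defined entry capped.

    Each non-missing value ``v`` is replaced by ``min(v, max_reactivity)``;
    missing values are preserved and the input profile is unmodified.
    """
    if not max_reactivity > 0:
        raise ValueError("max_reactivity must be positive")
    return np.minimum(profile.reactivity, max_reactivity)


@dataclass
class ProfileDatabase:
    """Ordered collection of reactivity profiles of one signal kind.

    ``kind`` is either ``"shape-reactivity"`` or
    ``"base-pairing-probability"``; pairing-probability databases must have
    every defined value <= 1.  ``metadata`` carries free-form provenance
    (e.g. shuffling seed) persisted in the file header.
    """

    entries: list[ReactivityProfile]
    kind: str = SHAPE_KIND
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in (SHAPE_KIND, BPP_KIND):
            raise ValueError(f"unknown database kind {self.kind!r}")
        ids = [e.id for e in self.entries]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate entry ids: {dup}")
        if self.kind == BPP_KIND:
            for e in self.entries:
                defined = e.reactivity[~np.isnan(e.reactivity)]
                if defined.size and defined.max() > 1:
                    raise ValueError(
                        f"record {e.id!r}: pairing probabilities must be <= 1"
                    )

    @property
    def total_length(self) -> int:
        return sum(len(e) for e in self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __getitem__(self, entry_id: str) -> ReactivityProfile:
        for e in self.entries:
            if e.id == entry_id:
                return e
        raise KeyError(entry_id)


# ---------------------------------------------------------------------------
# parsing helpers


def _parse_reactivity_string(text: str, record: str) -> np.ndarray:
    tokens = [t for t in re.split(r"[,\s]+", text.strip()) if t]
    values = np.empty(len(tokens), dtype=float)
    for i, tok in enumerate(tokens):
        if tok.lower() == "nan":
            values[i] = np.nan
            continue
        try:
            values[i] = float(tok)
        except ValueError:
            raise ValueError(
                f"record {record!r}: unparseable reactivity token {tok!r} "
                f"at position {i}"
            ) from None
    return values


def read_rnaframework_xml(path: str | Path) -> list[ReactivityProfile]:
    """Parse an RNA Framework-style normalized reactivity XML file.

    Every ``<transcript>`` element (any nesting) must carry an ``id``
    attribute and ``<sequence>``/``<reactivity>`` children of equal length;
    ``NaN`` tokens denote missing values, whitespace and newlines inside the
    blocks are ignored, and ``T`` is normalized to ``U``.
    """
    path = Path(path)
    tree = ET.parse(path)
    profiles: list[ReactivityProfile] = []
    records = tree.getroot().iter("transcript")
    for rec in records:
        rec_id = rec.get("id", "")
        if not rec_id:
            raise ValueError(f"{path}: <transcript> without an id attribute")
        seq_el = rec.find("sequence")
        rea_el = rec.find("reactivity")
        if seq_el is None or rea_el is None or not (seq_el.text and rea_el.text):
            raise ValueError(
                f"record {rec_id!r}: missing <sequence> or <reactivity> block"
            )
        values = _parse_reactivity_string(rea_el.text, rec_id)
        profiles.append(
            ReactivityProfile(id=rec_id, sequence=seq_el.text, reactivity=values)
        )
    if not profiles:
        raise ValueError(f"{path}: no <transcript> records found")
    return profiles


def read_tsv(path: str | Path) -> list[ReactivityProfile]:
    """Parse the plain TSV fallback: ``id<TAB>sequence<TAB>r1,r2,...``."""
    profiles = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{ln}: expected 3 tab-separated fields")
            rec_id, seq, rea = parts
            profiles.append(
                ReactivityProfile(
                    id=rec_id,
                    sequence=seq,
                    reactivity=_parse_reactivity_string(rea, rec_id),
                )
            )
    if not profiles:
        raise ValueError(f"{path}: no records found")
    return profiles


# ---------------------------------------------------------------------------
# versioned database text format


def _format_value(v: float) -> str:
    if np.isnan(v):
        return "NaN"
    # shortest representation that round-trips the float64 bit pattern
    return repr(float(v))


def write_db(db: ProfileDatabase, path: str | Path) -> None:
    """Persist a database in the versioned plain-text format.

    Layout::

        #shapesearch-db<TAB>v1<TAB>kind=<kind>[<TAB>key=value ...]
        >entry_id
        SEQUENCE
        r1,r2,NaN,...

    Values are written with the shortest decimal representation that
    round-trips the exact float64 value; NaN marks missing positions.  The
    header is self-describing so that corrupt or foreign files fail loudly
    on load.
    """
    path = Path(path)
    buf = io.StringIO()
    header = [_DB_MAGIC, f"v{_DB_VERSION}", f"kind={db.kind}"]
    for k in sorted(db.metadata):
        header.append(f"{k}={db.metadata[k]}")
    buf.write("\t".join(header) + "\n")
    for e in db.entries:
        buf.write(f">{e.id}\n{e.sequence}\n")
        buf.write(",".join(_format_value(v) for v in e.reactivity) + "\n")
    path.write_text(buf.getvalue())


def load_db(path: str | Path) -> ProfileDatabase:
    """Load a database written by :func:`write_db` (round-trip identity)."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or not lines[0].startswith(_DB_MAGIC):
        raise ValueError(
            f"{path}: not a shapesearch database (missing {_DB_MAGIC!r} header)"
        )
    fields = lines[0].split("\t")
    if len(fields) < 3 or fields[1] != f"v{_DB_VERSION}":
        raise ValueError(
            f"{path}: unsupported database format version {fields[1:2]!r}; "
            f"this build reads v{_DB_VERSION}"
        )
    meta: dict[str, str] = {}
    kind = None
    for f in fields[2:]:
        if "=" not in f:
            raise ValueError(f"{path}: malformed header field {f!r}")
        k, v = f.split("=", 1)
        if k == "kind":
            kind = v
        else:
            meta[k] = v
    if kind is None:
        raise ValueError(f"{path}: header lacks the kind= field")

    entries: list[ReactivityProfile] = []
    i = 1
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        if not lines[i].startswith(">"):
            raise ValueError(f"{path}:{i + 1}: expected '>' entry header")
        if i + 2 >= len(lines):
            raise ValueError(f"{path}: truncated entry at line {i + 1}")
        rec_id = lines[i][1:].strip()
        seq = lines[i + 1].strip()
        values = _parse_reactivity_string(lines[i + 2], rec_id)
        entries.append(ReactivityProfile(id=rec_id, sequence=seq, reactivity=values))
        i += 3
    return ProfileDatabase(entries=entries, kind=kind, metadata=meta)
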