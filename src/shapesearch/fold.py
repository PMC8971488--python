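"""Consensus-structure significance testing of matched alignments.

A significant reactivity-profile match can be tested for a conserved
secondary structure: the aligned sequences (with their reactivity tracks as
pseudo-energy restraints) are folded into a consensus structure by an
RNAalifold-compatible engine, the alignment columns are block-shuffled to
build a null distribution of consensus free energies, and the true energy
is converted into a normal Z-score whose lower-tail probability is the
structure p-value (more negative energy than the shuffles = significant).
Structures with p < 0.05 whose base pairs are supported as canonical
(AU/GC/GU) by at least 75% per sequence are retained.

The folding engine is an injected dependency: the production adapter shells
out to the RNAalifold executable; tests use a deterministic mock.
"""

from __future__ import annotations

import re
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import norm

from .align import AlignmentResult
from .profiles import ReactivityProfile

__all__ = [
    "ProfileAlignment",
    "FoldEvaluation",
    "MockFoldEngine",
    "RNAalifoldEngine",
    "PROBE_PRESETS",
    "shuffle_alignment",
    "evaluate_fold",
    "bp_support",
    "retain",
    "parse_dotbracket",
    "write_stockholm",
]

#: Deigan slope/intercept presets (kcal/mol) per probing reagent.
PROBE_PRESETS = {"2A3": (1.0, -0.4), "NAI": (1.1, 0.0), "NAI-N3": (2.4, -0.6)}

GAP = "-"

_CANONICAL = frozenset({"AU", "UA", "GC", "CG", "GU", "UG"})


@dataclass
class ProfileAlignment:
    """Two or more aligned rows of gapped sequence plus reactivity track.

    ``gapped_reactivities`` holds nan at gap columns (and at genuinely
    missing positions); the gap structure is defined by the sequence rows.
    Degapping any row reproduces the original subsequence and its
    reactivity run exactly.
    """

    names: list[str]
    gapped_sequences: list[str]
    gapped_reactivities: list[np.ndarray]

    def __post_init__(self) -> None:
        if len(self.names) < 2:
            raise ValueError("an alignment needs at least two rows")
        ncol = {len(s) for s in self.gapped_sequences}
        ncol |= {len(r) for r in self.gapped_reactivities}
        if len(ncol) != 1:
            raise ValueError("rows must have equal column counts")
        self.gapped_reactivities = [
            np.asarray(r, dtype=float) for r in self.gapped_reactivities
        ]

    @property
    def n_columns(self) -> int:
        return len(self.gapped_sequences[0])

    def degapped_row(self, i: int) -> tuple[str, np.ndarray]:
        seq = self.gapped_sequences[i]
        keep = [c for c, b in enumerate(seq) if b != GAP]
        return (
            "".join(seq[c] for c in keep),
            self.gapped_reactivities[i][keep],
        )

    @classmethod
    def from_alignment_result(
        cls,
        result: AlignmentResult,
        query: ReactivityProfile,
        entry: ReactivityProfile,
    ) -> "ProfileAlignment":
        """Render a pairwise alignment result into gapped rows."""
        qs, ds = [], []
        qr, dr = [], []
        for c in result.aligned_columns:
            if c[0] == "pair":
                _, qi, di = c
                qs.append(query.sequence[qi])
                ds.append(entry.sequence[di])
                qr.append(query.reactivity[qi])
                dr.append(entry.reactivity[di])
            elif c[0] == "gapq":
                qs.append(GAP)
                ds.append(entry.sequence[c[1]])
                qr.append(np.nan)
                dr.append(entry.reactivity[c[1]])
            else:
                qs.append(query.sequence[c[1]])
                ds.append(GAP)
                qr.append(query.reactivity[c[1]])
                dr.append(np.nan)
        return cls(
            names=[result.query_id, result.db_entry_id],
            gapped_sequences=["".join(qs), "".join(ds)],
            gapped_reactivities=[np.array(qr), np.array(dr)],
        )


@dataclass
class FoldEvaluation:
    """Consensus structure with its energy Z-score significance."""

    structure: str
    energy: float
    null_energies: np.ndarray
    z: float
    p_value: float
    bp_support_per_row: list[float] = field(default_factory=list)


class MockFoldEngine:
    """Deterministic stand-in engine for tests and dry runs.

    ``energy_fn(alignment) -> float`` lets tests control the null energy
    distribution; the fixed ``structure`` is returned for every call.
    """

    def __init__(self, structure: str, energy: float = -10.0, energy_fn=None):
        self.structure = structure
        self.energy = energy
        self.energy_fn = energy_fn

    def consensus_fold(self, alignment: ProfileAlignment, slope=1.0, intercept=0.0):
        _check_not_degenerate(alignment)
        e = self.energy_fn(alignment) if self.energy_fn is not None else self.energy
        return self.structure, float(e)


class RNAalifoldEngine:
    """Adapter shelling out to an RNAalifold-compatible executable.

    The alignment is written in Clustal format; per-row reactivity tracks
    become SHAPE restraint files applied with the Deigan conversion
    (``--shapeMethod=Dm<slope>b<intercept>``).  Requires the executable on
    PATH (ViennaRNA's RNAalifold); :meth:`available` reports presence.
    """

    def __init__(self, executable: str = "RNAalifold", use_reactivity: bool = True):
        self.executable = executable
        self.use_reactivity = use_reactivity

    def available(self) -> bool:
        return shutil.which(self.executable) is not None

    def consensus_fold(self, alignment: ProfileAlignment, slope=1.0, intercept=0.0):
        _check_not_degenerate(alignment)
        if not self.available():
            raise RuntimeError(f"{self.executable} not found on PATH")
        with tempfile.TemporaryDirectory() as td:
            tdir = Path(td)
            aln_path = tdir / "aln.aln"
            names = [f"seq{i}" for i in range(len(alignment.names))]
            lines = ["CLUSTAL W\n\n"]
            for n, s in zip(names, alignment.gapped_sequences):
                lines.append(f"{n:<10} {s}\n")
            aln_path.write_text("".join(lines))
            cmd = [self.executable, "--noPS", "-r"]
            if self.use_reactivity:
                shape_files = []
                for i, n in enumerate(names):
                    seq, rea = alignment.degapped_row(i)
                    sf = tdir / f"{n}.shape"
                    rows = [
                        f"{p + 1} {v:.4f}\n"
                        for p, v in enumerate(rea)
                        if not np.isnan(v)
                    ]
                    sf.write_text("".join(rows))
                    shape_files.append(str(sf))
                cmd.append("--shape=" + ",".join(shape_files))
                cmd.append(f"--shapeMethod=Dm{slope}b{intercept}")
            cmd.append(str(aln_path))
            proc = subprocess.run(
                cmd, capture_output=True, text=True, cwd=td, check=True
            )
            return _parse_alifold_output(proc.stdout)


def _parse_alifold_output(stdout: str) -> tuple[str, float]:
    for line in stdout.splitlines():
        m = re.match(r"^([.()]+)\s+\(\s*(-?\d+\.?\d*)", line.strip())
        if m:
            return m.group(1), float(m.group(2))
    raise ValueError("could not parse consensus structure from engine output")


def _check_not_degenerate(alignment: ProfileAlignment) -> None:
    for i in range(len(alignment.names)):
        seq, _ = alignment.degapped_row(i)
        if not seq:
            raise ValueError("degenerate alignment: a row contains only gaps")


def shuffle_alignment(
    alignment: ProfileAlignment, block: int = 3, rng: np.random.Generator | None = None
) -> ProfileAlignment:
    """Block-shuffle alignment columns, keeping rows synchronized.

    Columns are partitioned into consecutive blocks of ``block`` (last
    possibly shorter); block order is permuted, then columns within each
    block are permuted.  A column moves as a unit across all rows and both
    tracks, so the column multiset is preserved exactly.
    """
    if alignment.n_columns < 2:
        raise ValueError("need at least two columns to shuffle")
    rng = np.random.default_rng() if rng is None else rng
    ncol = alignment.n_columns
    blocks = [list(range(s, min(s + block, ncol))) for s in range(0, ncol, block)]
    order: list[int] = []
    for b in rng.permutation(len(blocks)):
        cols = blocks[b]
        order.extend(cols[i] for i in rng.permutation(len(cols)))
    return ProfileAlignment(
        names=list(alignment.names),
        gapped_sequences=[
            "".join(s[c] for c in order) for s in alignment.gapped_sequences
        ],
        gapped_reactivities=[r[order] for r in alignment.gapped_reactivities],
    )


def evaluate_fold(
    alignment: ProfileAlignment,
    engine,
    n_shuffles: int = 100,
    rng: np.random.Generator | None = None,
    slope: float = 1.0,
    intercept: float = 0.0,
    shuffle_block: int = 3,
) -> FoldEvaluation:
    """Fold the alignment and score its energy against shuffled nulls.

    z = (E_true - mean(E_null)) / sd(E_null); p is the lower-tail normal
    probability (a consensus more stable than shuffled alignments is
    significant).  A zero-variance null is degenerate and reported p = 1.
    """
    rng = np.random.default_rng() if rng is None else rng
    structure, energy = engine.consensus_fold(alignment, slope, intercept)
    null = np.empty(n_shuffles)
    for i in range(n_shuffles):
        shuf = shuffle_alignment(alignment, block=shuffle_block, rng=rng)
        _, null[i] = engine.consensus_fold(shuf, slope, intercept)
    sd = float(np.std(null, ddof=1))
    if sd == 0:
        z, p = 0.0, 1.0
    else:
        z = (energy - float(np.mean(null))) / sd
        p = float(norm.cdf(z))
    ev = FoldEvaluation(
        structure=structure, energy=energy, null_energies=null, z=float(z), p_value=p
    )
    ev.bp_support_per_row = bp_support(structure, alignment)
    return ev


def parse_dotbracket(structure: str) -> list[tuple[int, int]]:
    """Base pairs (0-based column indices) of a balanced dot-bracket string."""
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at column {i}")
            pairs.append((stack.pop(), i))
        elif c != ".":
            raise ValueError(f"unsupported structure character {c!r}")
    if stack:
        raise ValueError("unbalanced '(' in structure")
    return sorted(pairs)


def bp_support(structure: str, alignment: ProfileAlignment) -> list[float]:
    """Per-row fraction of consensus pairs that are canonical in that row.

    A pair is supported by a row when its two bases form AU, GC or GU
    (either orientation); pairs touching a gap or N are unsupported.
    Returns one fraction per row; with zero pairs the list is empty.
    """
    pairs = parse_dotbracket(structure)
    if len(structure) != alignment.n_columns:
        raise ValueError("structure length does not match alignment columns")
    if not pairs:
        return []
    fractions = []
    for seq in alignment.gapped_sequences:
        ok = sum(1 for i, j in pairs if seq[i] + seq[j] in _CANONICAL)
        fractions.append(ok / len(pairs))
    return fractions


def retain(
    evaluation: FoldEvaluation,
    p_cut: float = 0.05,
    support_cut: float = 0.75,
    support_mode: str = "min",
) -> bool:
    """Retention gate for covariation follow-up.

    True iff p < ``p_cut`` and the per-row base-pair support reaches
    ``support_cut`` — for every row (``support_mode="min"``, the strict
    default) or on average (``"mean"``).  A structure with no pairs has
    undefined support and is never retained.
    """
    if not evaluation.bp_support_per_row:
        return False
    if support_mode == "min":
        s = min(evaluation.bp_support_per_row)
    elif support_mode == "mean":
        s = float(np.mean(evaluation.bp_support_per_row))
    else:
        raise ValueError(f"unknown support_mode {support_mode!r}")
    return evaluation.p_value < p_cut and s >= support_cut


def write_stockholm(
    alignment: ProfileAlignment, structure: str | None, path
) -> None:
    """Write a Stockholm file with an SS_cons line for a retained structure."""
    path = Path(path)
    width = max(len(n) for n in alignment.names) + 2
    lines = ["# STOCKHOLM 1.0\n"]
    for n, s in zip(alignment.names, alignment.gapped_sequences):
        lines.append(f"{n:<{width}}{s}\n")
    if structure is not None:
        lines.append(f"{'#=GC SS_cons':<{width}}{structure}\n")
    lines.append("//\n")
    path.write_text("".join(lines))
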