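"""Stimulation grid and travelling-wave stimulus sequences.

The vibrotactile rig is a 4 x 4 grid of piezoelectric stimulators covering
digits D2-D5 at four proximal-distal (PD) sites along each digit, PD1 (tip)
to PD4 (base).  Grid coordinates are expressed in "grid units": the digit
coordinate ``d`` runs 1..4 with 1 = D2 and 4 = D5 (little finger); the
proximal-distal coordinate ``pd`` runs 1..4 with 1 = tip.

Site linear index convention (fixed throughout the package)::

    site = (d - 1) * n_pd + (pd - 1)

i.e. C-order flattening of a (digit, pd) array.

A travelling-wave (TW) sequence activates "lines" of the grid in succession:

* ``between``  - the four digit columns (all PD sites of one digit at once),
* ``within``   - the four PD rows (one PD site on every digit at once),
* ``diagonal`` - the seven anti-diagonals of the grid, ordered from the
  (D2, PD1) corner; lines contain 1-4 sites.

Each line stays on for ``s_on`` seconds, so one cycle lasts
``n_lines * s_on`` seconds (16 s for between/within, 28 s for diagonal at
the study's 4 s ON duration), and the sequence repeats for ``n_cycles``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "GridSpec",
    "StimulusSequence",
    "build_tw_sequence",
    "time_reverse",
    "concatenate_sequences",
    "write_sequence_tsv",
    "read_sequence_tsv",
]

PARADIGMS = ("between", "within", "diagonal")
DIRECTIONS = ("forward", "reverse")


@dataclass(frozen=True)
class GridSpec:
    """The 4 x 4 digit x proximal-distal stimulation grid."""

    n_digits: int = 4
    n_pd: int = 4

    @property
    def n_sites(self) -> int:
        return self.n_digits * self.n_pd

    @property
    def digit_coords(self) -> np.ndarray:
        """Digit coordinate (grid units, 1 = D2) of every site, site order."""
        return np.repeat(np.arange(1, self.n_digits + 1), self.n_pd).astype(float)

    @property
    def pd_coords(self) -> np.ndarray:
        """PD coordinate (grid units, 1 = tip) of every site, site order."""
        return np.tile(np.arange(1, self.n_pd + 1), self.n_digits).astype(float)

    @property
    def digit_labels(self) -> list[str]:
        return [f"D{i + 2}" for i in range(self.n_digits)]

    @property
    def pd_labels(self) -> list[str]:
        return [f"PD{i + 1}" for i in range(self.n_pd)]

    def site_index(self, d: int, pd: int) -> int:
        """Linear site index of grid cell (d, pd), both 1-based grid units."""
        if not (1 <= d <= self.n_digits and 1 <= pd <= self.n_pd):
            raise ValueError(f"grid cell ({d}, {pd}) outside {self.n_digits}x{self.n_pd} grid")
        return (d - 1) * self.n_pd + (pd - 1)

    def site_coords(self, site: int) -> tuple[int, int]:
        """Inverse of :meth:`site_index`."""
        if not 0 <= site < self.n_sites:
            raise ValueError(f"site index {site} out of range")
        return site // self.n_pd + 1, site % self.n_pd + 1


@dataclass
class StimulusSequence:
    """A binary time x site stimulus description with cycle metadata.

    ``matrix`` has one row per fMRI volume (TR) and one column per grid
    site.  ``run_boundaries`` lists half-open (start, stop) row ranges of
    the runs the sequence is composed of; HRF convolution and detrending
    must never cross these boundaries.
    """

    matrix: np.ndarray
    tr: float
    cycle_len: float
    n_cycles: int
    paradigm: str
    direction: str
    grid: GridSpec = field(default_factory=GridSpec)
    run_boundaries: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != self.grid.n_sites:
            raise ValueError(
                f"stimulus matrix must be (time, {self.grid.n_sites}), got {self.matrix.shape}"
            )
        if not np.isin(self.matrix, (0, 1)).all():
            raise ValueError("stimulus matrix entries must be binary")
        if not self.run_boundaries:
            self.run_boundaries = [(0, self.matrix.shape[0])]

    @property
    def n_timepoints(self) -> int:
        return self.matrix.shape[0]

    @property
    def cycle_len_tp(self) -> int:
        return int(round(self.cycle_len / self.tr))


def _paradigm_lines(paradigm: str, grid: GridSpec) -> list[list[int]]:
    """Site-index membership of each stimulation line, forward order."""
    if paradigm == "between":
        return [
            [grid.site_index(d, pd) for pd in range(1, grid.n_pd + 1)]
            for d in range(1, grid.n_digits + 1)
        ]
    if paradigm == "within":
        return [
            [grid.site_index(d, pd) for d in range(1, grid.n_digits + 1)]
            for pd in range(1, grid.n_pd + 1)
        ]
    if paradigm == "diagonal":
        # anti-diagonals d + pd = const, ordered from the (D2, PD1) corner
        n_lines = grid.n_digits + grid.n_pd - 1
        lines = []
        for k in range(n_lines):
            line = [
                grid.site_index(d, pd)
                for d in range(1, grid.n_digits + 1)
                for pd in range(1, grid.n_pd + 1)
                if (d - 1) + (pd - 1) == k
            ]
            lines.append(line)
        return lines
    raise ValueError(f"unknown paradigm {paradigm!r}; expected one of {PARADIGMS}")


def build_tw_sequence(
    paradigm: str,
    direction: str = "forward",
    n_cycles: int = 12,
    s_on: float = 4.0,
    tr: float = 2.0,
    grid: GridSpec | None = None,
) -> StimulusSequence:
    """Construct a travelling-wave stimulus sequence.

    Parameters
    ----------
    paradigm : {"between", "within", "diagonal"}
    direction : {"forward", "reverse"}
        The reverse sequence is the time-reversed forward sequence.
    n_cycles : int
        Number of stimulation cycles (study protocol: 12).
    s_on : float
        Seconds each line stays on (study protocol: 4 s).
    tr : float
        Volume repetition time in seconds (study protocol: 2 s).  ``s_on``
        must be an integer multiple of ``tr``.
    """
    grid = grid or GridSpec()
    if direction not in DIRECTIONS:
        raise ValueError(f"unknown direction {direction!r}")
    rows_per_line = s_on / tr
    if abs(rows_per_line - round(rows_per_line)) > 1e-9:
        raise ValueError(
            f"s_on ({s_on} s) must be an integer multiple of tr ({tr} s): "
            "stimulus timing cannot be represented on the volume grid"
        )
    rows_per_line = int(round(rows_per_line))
    lines = _paradigm_lines(paradigm, grid)
    cycle = np.zeros((len(lines) * rows_per_line, grid.n_sites), dtype=np.uint8)
    for i, line in enumerate(lines):
        cycle[i * rows_per_line : (i + 1) * rows_per_line, line] = 1
    if direction == "reverse":
        cycle = cycle[::-1]
    matrix = np.tile(cycle, (n_cycles, 1))
    return StimulusSequence(
        matrix=matrix,
        tr=tr,
        cycle_len=len(lines) * s_on,
        n_cycles=n_cycles,
        paradigm=paradigm,
        direction=direction,
        grid=grid,
    )


def time_reverse(seq: StimulusSequence) -> StimulusSequence:
    """Reverse a sequence in time (an involution).

    Run boundaries are reversed along with the rows so that run membership
    is preserved.
    """
    n = seq.n_timepoints
    boundaries = [(n - stop, n - start) for start, stop in reversed(seq.run_boundaries)]
    direction = {"forward": "reverse", "reverse": "forward"}.get(seq.direction, seq.direction)
    return replace(
        seq,
        matrix=seq.matrix[::-1].copy(),
        direction=direction,
        run_boundaries=boundaries,
    )


def concatenate_sequences(seqs: list[StimulusSequence]) -> StimulusSequence:
    """Concatenate runs into one session-level sequence.

    Run boundaries are recorded so that downstream convolution and
    detrending treat each run independently and never introduce spurious
    correlations across the discontinuity between scans.
    """
    if not seqs:
        raise ValueError("need at least one sequence")
    tr = seqs[0].tr
    grid = seqs[0].grid
    for s in seqs:
        if abs(s.tr - tr) > 1e-12:
            raise ValueError("cannot concatenate sequences with different TR")
        if s.grid.n_sites != grid.n_sites:
            raise ValueError("cannot concatenate sequences on different grids")
    boundaries: list[tuple[int, int]] = []
    offset = 0
    for s in seqs:
        boundaries.extend((offset + a, offset + b) for a, b in s.run_boundaries)
        offset += s.n_timepoints
    paradigm = seqs[0].paradigm if len({s.paradigm for s in seqs}) == 1 else "concat"
    return StimulusSequence(
        matrix=np.concatenate([s.matrix for s in seqs], axis=0),
        tr=tr,
        cycle_len=seqs[0].cycle_len,
        n_cycles=sum(s.n_cycles for s in seqs),
        paradigm=paradigm,
        direction="mixed" if len({s.direction for s in seqs}) > 1 else seqs[0].direction,
        grid=grid,
        run_boundaries=boundaries,
    )


def write_sequence_tsv(seq: StimulusSequence, path) -> None:
    """Write a stimulus sequence as TSV with a commented metadata header."""
    header = (
        f"# tr={seq.tr}\n"
        f"# cycle_len={seq.cycle_len}\n"
        f"# n_cycles={seq.n_cycles}\n"
        f"# paradigm={seq.paradigm}\n"
        f"# direction={seq.direction}\n"
        f"# run_boundaries={';'.join(f'{a}:{b}' for a, b in seq.run_boundaries)}\n"
        "# site index = (digit-1)*4 + (pd-1); digit 1 = D2, pd 1 = tip\n"
    )
    buf = io.StringIO()
    np.savetxt(buf, seq.matrix, fmt="%d", delimiter="\t")
    with open(path, "w") as fh:
        fh.write(header)
        fh.write(buf.getvalue())


def read_sequence_tsv(path) -> StimulusSequence:
    meta: dict[str, str] = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                if "=" in line:
                    key, _, val = line[1:].partition("=")
                    meta[key.strip()] = val.strip()
            elif line.strip():
                rows.append([int(v) for v in line.split()])
    boundaries = [
        tuple(int(x) for x in part.split(":"))
        for part in meta.get("run_boundaries", "").split(";")
        if part
    ]
    return StimulusSequence(
        matrix=np.array(rows, dtype=np.uint8),
        tr=float(meta["tr"]),
        cycle_len=float(meta["cycle_len"]),
        n_cycles=int(meta["n_cycles"]),
        paradigm=meta["paradigm"],
        direction=meta["direction"],
        run_boundaries=[(a, b) for a, b in boundaries],
    )
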