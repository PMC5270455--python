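"""Target inhibition maps: data model, Gray-code grid I/O, binarization.

A target inhibition map (TIM) records, for every subset of a panel of n
inhibitable targets, whether jointly inhibiting that subset blocks tumor
proliferation at steady state.  Its probabilistic extension (PTIM) stores a
normalized sensitivity in [0, 1] per subset, interpreted as the steady-state
probability of the non-tumorous phenotype under sustained inhibition.

Subsets are indexed by an n-bit integer with the first panel target as the
most significant bit; published maps lay the 2^n entries out as a grid whose
row and column labels follow a reflected-binary Gray sequence so that
adjacent cells differ by a single inhibition.
"""

from __future__ import annotations

import csv
import io
import json
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "TargetPanel",
    "PTIM",
    "TIM",
    "GridLayout",
    "gray_order",
    "read_ptim",
    "read_ptim_text",
    "write_ptim",
    "ptim_entry",
    "binarize",
    "minimal_blocking_sets",
    "feasible_mutation_patterns",
    "MonotonicityError",
]


class MonotonicityError(ValueError):
    """Raised when an operation requiring a monotone TIM receives one that
    is not: ``subset``/``superset`` name a violating pair."""

    def __init__(self, subset: frozenset, superset: frozenset):
        self.subset = subset
        self.superset = superset
        super().__init__(
            f"TIM is not monotone: {sorted(subset)} blocks but its superset "
            f"{sorted(superset)} does not"
        )


@dataclass(frozen=True)
class TargetPanel:
    """Ordered panel of distinct inhibitable targets.

    The first-listed target occupies the most significant of the n target
    bits; the tumor-status bit is the least significant bit of the full
    (n+1)-bit dynamic state.  Panels are capped at 16 targets so the
    2^(n+1)-state space stays explicitly enumerable.
    """

    names: tuple[str, ...]

    def __post_init__(self):
        names = tuple(self.names)
        object.__setattr__(self, "names", names)
        if not names:
            raise ValueError("panel must contain at least one target")
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate target names in panel: {names}")
        if any(not n for n in names):
            raise ValueError("target names must be nonempty")
        if len(names) > 16:
            raise ValueError("panels above 16 targets are not supported")

    @property
    def n(self) -> int:
        return len(self.names)

    @property
    def n_subsets(self) -> int:
        return 1 << self.n

    @property
    def n_states(self) -> int:
        """Size of the dynamic state space: n target bits plus tumor bit."""
        return 1 << (self.n + 1)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown target {name!r}; panel is {self.names}") from None

    def encode(self, subset: Iterable[str]) -> int:
        """Subset -> n-bit index (first panel target = MSB)."""
        idx = 0
        for name in subset:
            idx |= 1 << (self.n - 1 - self.index(name))
        return idx

    def decode(self, index: int) -> frozenset:
        if not 0 <= index < self.n_subsets:
            raise ValueError(f"subset index {index} out of range for n={self.n}")
        return frozenset(
            name for j, name in enumerate(self.names) if index >> (self.n - 1 - j) & 1
        )

    def subsets(self) -> Iterable[frozenset]:
        for i in range(self.n_subsets):
            yield self.decode(i)

    def label(self, subset: Iterable[str]) -> str:
        """Human-readable label: names joined by '+', empty string for none."""
        members = set(subset)
        return "+".join(n for n in self.names if n in members)


@dataclass(frozen=True)
class PTIM:
    """Probabilistic target inhibition map: sensitivity per inhibition subset."""

    panel: TargetPanel
    values: np.ndarray

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.shape != (self.panel.n_subsets,):
            raise ValueError(
                f"expected {self.panel.n_subsets} sensitivities, got shape {vals.shape}"
            )
        if np.any(vals < 0) or np.any(vals > 1):
            bad = int(np.argmax((vals < 0) | (vals > 1)))
            raise ValueError(
                f"sensitivity out of [0, 1] for subset "
                f"{sorted(self.panel.decode(bad))}: {vals[bad]}"
            )

    def entry(self, subset: Iterable[str]) -> float:
        return float(self.values[self.panel.encode(subset)])

    def binarize(self, alpha: float) -> "TIM":
        return binarize(self, alpha)


@dataclass(frozen=True)
class TIM:
    """Binary target inhibition map.

    Monotonicity (supersets of a blocking set also block) holds for TIMs
    produced from pathways but is deliberately not enforced on construction:
    experimentally derived maps may violate it.
    """

    panel: TargetPanel
    bits: np.ndarray

    def __post_init__(self):
        bits = np.asarray(self.bits, dtype=np.int8)
        object.__setattr__(self, "bits", bits)
        if bits.shape != (self.panel.n_subsets,):
            raise ValueError(
                f"expected {self.panel.n_subsets} bits, got shape {bits.shape}"
            )
        if not np.all((bits == 0) | (bits == 1)):
            raise ValueError("TIM entries must be 0 or 1")

    def entry(self, subset: Iterable[str]) -> int:
        return int(self.bits[self.panel.encode(subset)])

    def check_monotone(self) -> None:
        """Raise :class:`MonotonicityError` naming a violating pair, if any.

        It suffices to compare each blocking subset with its immediate
        (one-target-larger) supersets.
        """
        n = self.panel.n
        for i in range(self.panel.n_subsets):
            if not self.bits[i]:
                continue
            for b in range(n):
                j = i | (1 << b)
                if j != i and not self.bits[j]:
                    raise MonotonicityError(self.panel.decode(i), self.panel.decode(j))

    def blocking_sets(self) -> list[frozenset]:
        return [self.panel.decode(i) for i in range(self.panel.n_subsets) if self.bits[i]]


def gray_order(k: int) -> list[tuple[int, ...]]:
    """Reflected-binary Gray sequence over k bits, starting at all-zeros.

    Adjacent entries differ in exactly one bit; entry i is ``i ^ (i >> 1)``
    written MSB-first.
    """
    if k < 0:
        raise ValueError(f"bit count must be nonnegative, got {k}")
    out = []
    for i in range(1 << k):
        g = i ^ (i >> 1)
        out.append(tuple((g >> (k - 1 - j)) & 1 for j in range(k)))
    return out


@dataclass(frozen=True)
class GridLayout:
    """Gray-coded grid layout for a panel.

    Columns carry the first ceil(n/2) panel targets, rows the remainder;
    within each group the first-listed target is the MSB and labels follow
    the reflected Gray sequence, matching the published table layout.
    """

    column_targets: tuple[str, ...]
    row_targets: tuple[str, ...]

    @classmethod
    def from_panel(cls, panel: TargetPanel) -> "GridLayout":
        k = math.ceil(panel.n / 2)
        return cls(tuple(panel.names[:k]), tuple(panel.names[k:]))

    def __post_init__(self):
        object.__setattr__(self, "column_targets", tuple(self.column_targets))
        object.__setattr__(self, "row_targets", tuple(self.row_targets))

    @property
    def panel(self) -> TargetPanel:
        return TargetPanel(self.column_targets + self.row_targets)

    def column_subsets(self) -> list[frozenset]:
        names = self.column_targets
        return [
            frozenset(n for n, b in zip(names, bits) if b)
            for bits in gray_order(len(names))
        ]

    def row_subsets(self) -> list[frozenset]:
        names = self.row_targets
        return [
            frozenset(n for n, b in zip(names, bits) if b)
            for bits in gray_order(len(names))
        ]


def _grid_to_values(panel: TargetPanel, layout: GridLayout, grid: np.ndarray) -> np.ndarray:
    rows = layout.row_subsets()
    cols = layout.column_subsets()
    if grid.shape != (len(rows), len(cols)):
        raise ValueError(
            f"grid shape {grid.shape} does not match layout "
            f"({len(rows)} rows x {len(cols)} columns)"
        )
    values = np.empty(panel.n_subsets)
    for r, rsub in enumerate(rows):
        for c, csub in enumerate(cols):
            values[panel.encode(rsub | csub)] = grid[r, c]
    return values


def ptim_from_grid(
    grid: Sequence[Sequence[float]],
    panel: TargetPanel | Sequence[str],
    layout: GridLayout | None = None,
) -> PTIM:
    """Build a PTIM from a Gray-coded grid of sensitivities."""
    if not isinstance(panel, TargetPanel):
        panel = TargetPanel(tuple(panel))
    layout = layout or GridLayout.from_panel(panel)
    arr = np.asarray(grid, dtype=float)
    return PTIM(panel, _grid_to_values(panel, layout, arr))


def tim_from_grid(
    grid: Sequence[Sequence[int]],
    panel: TargetPanel | Sequence[str],
    layout: GridLayout | None = None,
) -> TIM:
    """Build a binary TIM from a Gray-coded grid of 0/1 entries."""
    if not isinstance(panel, TargetPanel):
        panel = TargetPanel(tuple(panel))
    layout = layout or GridLayout.from_panel(panel)
    arr = np.asarray(grid, dtype=float)
    return TIM(panel, _grid_to_values(panel, layout, arr).astype(np.int8))


def _parse_label(label: str) -> frozenset:
    label = label.strip()
    return frozenset(p for p in label.split("+") if p) if label else frozenset()


def read_ptim_text(text: str, fmt: str = "auto") -> PTIM:
    """Parse a PTIM from grid CSV or flat JSON text.

    Grid CSV: header row and first column carry Gray-coded inhibition labels
    (target names joined by '+', empty = no inhibition); cells are decimals.
    Flat JSON: ``{"targets": [...], "values": {"K1+K3": 0.7, "": 0.0, ...}}``
    and is layout-free.
    """
    if fmt == "auto":
        fmt = "json" if text.lstrip().startswith("{") else "grid"
    if fmt == "json":
        doc = json.loads(text)
        panel = TargetPanel(tuple(doc["targets"]))
        values = np.zeros(panel.n_subsets)
        seen = np.zeros(panel.n_subsets, dtype=bool)
        for label, val in doc["values"].items():
            idx = panel.encode(_parse_label(label))
            values[idx] = float(val)
            seen[idx] = True
        if not seen.all():
            missing = panel.decode(int(np.argmin(seen)))
            raise ValueError(f"flat PTIM is missing subset {sorted(missing)}")
        return PTIM(panel, values)
    if fmt != "grid":
        raise ValueError(f"unknown PTIM format {fmt!r}")

    reader = list(csv.reader(io.StringIO(text)))
    reader = [row for row in reader if any(cell.strip() for cell in row)]
    if len(reader) < 2:
        raise ValueError("grid CSV must have a header row and at least one data row")
    col_labels = [_parse_label(c) for c in reader[0][1:]]
    row_labels = [_parse_label(row[0]) for row in reader[1:]]
    nrows, ncols = len(row_labels), len(col_labels)
    if nrows & (nrows - 1) or ncols & (ncols - 1):
        raise ValueError(
            f"grid must be a power-of-two shape, got {nrows} rows x {ncols} columns"
        )
    col_targets: list[str] = []
    for lab in col_labels:
        for t in lab:
            if t not in col_targets:
                col_targets.append(t)
    row_targets: list[str] = []
    for lab in row_labels:
        for t in lab:
            if t not in row_targets:
                row_targets.append(t)
    panel = TargetPanel(tuple(col_targets) + tuple(row_targets))
    values = np.full(panel.n_subsets, np.nan)
    for r, row in enumerate(reader[1:]):
        cells = row[1:]
        if len(cells) != ncols:
            raise ValueError(f"row {r} has {len(cells)} cells, expected {ncols}")
        for c, cell in enumerate(cells):
            try:
                val = float(cell)
            except ValueError:
                raise ValueError(
                    f"non-numeric cell at row {r}, column {c}: {cell!r}"
                ) from None
            values[panel.encode(row_labels[r] | col_labels[c])] = val
    if np.isnan(values).any():
        missing = panel.decode(int(np.argmax(np.isnan(values))))
        raise ValueError(f"grid does not cover subset {sorted(missing)}")
    return PTIM(panel, values)


def read_ptim(path, fmt: str = "auto") -> PTIM:
    """Read a PTIM from a grid CSV or flat JSON file."""
    with open(path) as fh:
        text = fh.read()
    if fmt == "auto" and str(path).endswith(".json"):
        fmt = "json"
    return read_ptim_text(text, fmt)


def write_ptim(
    ptim: PTIM, path=None, layout: GridLayout | None = None, fmt: str = "grid"
) -> str:
    """Serialize a PTIM to grid CSV (Gray layout) or flat JSON.

    Returns the text; also writes it to ``path`` when given.
    """
    panel = ptim.panel
    if fmt == "json":
        text = json.dumps(
            {
                "targets": list(panel.names),
                "values": {
                    panel.label(panel.decode(i)): float(ptim.values[i])
                    for i in range(panel.n_subsets)
                },
            },
            indent=1,
        )
    elif fmt == "grid":
        layout = layout or GridLayout.from_panel(panel)
        buf = io.StringIO()
        writer = csv.writer(buf, lineterminator="\n")
        cols = layout.column_subsets()
        writer.writerow([""] + [panel.label(c) for c in cols])
        for rsub in layout.row_subsets():
            writer.writerow(
                [panel.label(rsub)]
                + [repr(float(ptim.values[panel.encode(rsub | c)])) for c in cols]
            )
        text = buf.getvalue()
    else:
        raise ValueError(f"unknown PTIM format {fmt!r}")
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def ptim_entry(ptim: PTIM | TIM, subset: Iterable[str]) -> float:
    """Sensitivity (or bit) for one inhibition subset."""
    return ptim.entry(subset)


def binarize(ptim: PTIM, alpha: float) -> TIM:
    """Threshold a PTIM: bit = 1 iff sensitivity >= alpha.

    The closed lower boundary matters for published maps whose cells sit
    exactly on a threshold (a 0.55 entry thresholded at 0.55 counts as
    blocking).
    """
    if not 0 < alpha <= 1:
        raise ValueError(f"threshold must lie in (0, 1], got {alpha}")
    return TIM(ptim.panel, (ptim.values >= alpha).astype(np.int8))


def minimal_blocking_sets(tim: TIM) -> list[frozenset]:
    """Inclusion-minimal blocking subsets of a monotone TIM.

    Every blocking set contains one of them and the returned family is an
    antichain; the result is ordered by size then lexicographically.
    """
    tim.check_monotone()
    n = tim.panel.n
    out = []
    for i in range(tim.panel.n_subsets):
        if not tim.bits[i]:
            continue
        if all(not tim.bits[i & ~(1 << b)] for b in range(n) if i >> b & 1):
            out.append(tim.panel.decode(i))
    return sorted(out, key=lambda s: (len(s), sorted(s)))


def feasible_mutation_patterns(tim: TIM) -> list[frozenset]:
    """Mutation / latent-activation patterns compatible with a monotone TIM.

    A pattern M is feasible only if inhibiting all of M blocks the tumor;
    otherwise the mutated targets could not be driving proliferation.
    Returns the nonempty blocking subsets in size-then-lexicographic order.
    """
    tim.check_monotone()
    pats = [
        tim.panel.decode(i)
        for i in range(1, tim.panel.n_subsets)
        if tim.bits[i]
    ]
    return sorted(pats, key=lambda s: (len(s), sorted(s)))
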