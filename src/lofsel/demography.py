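"""Piecewise-constant demographic histories.

A demographic history is a sequence of epochs, each with a constant diploid
effective population size, indexed in generations before present (generation 0
is the present).  Histories are preceded by a long burn-in at a constant size
so that the population starts each simulation at mutation-selection-drift
equilibrium.

The packaged default approximates the Schiffels-Durbin history of European
effective population size: a burn-in at N=14,448 for 10N generations followed
by N_e = 613,285 over the most recent 124 generations.  The ``modified``
variant additionally sets N_e = 5,000,000 over the last 50 generations, which
better matches the singleton-heavy site frequency spectrum of large exome
samples.  The intermediate (pre-124-generation) epochs of the full published
trajectory are not reproduced here; the packaged table deliberately contains
only these documented sizes (the ancestral size is held until the onset of
recent growth), and any analysis accepts a user-supplied epoch table instead.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, replace
from pathlib import Path
import numpy as np
import pandas as pd

__all__ = [
    "Epoch",
    "EpochSchedule",
    "build_default_schedule",
    "constant_schedule",
    "read_schedule_tsv",
    "write_schedule_tsv",
]

#: diploid size of the default burn-in population (oldest Schiffels-Durbin size)
DEFAULT_BURNIN_SIZE = 14_448
#: burn-in length: 10N generations of the burn-in size
DEFAULT_BURNIN_GENERATIONS = 10 * DEFAULT_BURNIN_SIZE

_RECENT_SIZE = 613_285
_RECENT_SPAN = 124
_GROWTH_SIZE = 5_000_000
_GROWTH_SPAN = 50


@dataclass(frozen=True)
class Epoch:
    """A constant-size interval ``[start_gen, end_gen)`` in generations before present.

    ``start_gen`` is the older (inclusive) bound, ``end_gen`` the younger
    (exclusive) bound; ``end_gen == 0`` means the epoch reaches the present.
    ``size`` is the diploid effective population size.
    """

    start_gen: int
    end_gen: int
    size: int

    def __post_init__(self) -> None:
        if self.size < 2:
            raise ValueError(f"epoch size must be >= 2, got {self.size}")
        if not self.start_gen > self.end_gen >= 0:
            raise ValueError(
                f"need start_gen > end_gen >= 0, got [{self.start_gen}, {self.end_gen})"
            )

    @property
    def length(self) -> int:
        return self.start_gen - self.end_gen


@dataclass(frozen=True)
class EpochSchedule:
    """A contiguous stack of epochs plus a constant-size burn-in behind them."""

    epochs: tuple[Epoch, ...]
    burnin_generations: int
    burnin_size: int

    def __post_init__(self) -> None:
        if not self.epochs:
            raise ValueError("schedule needs at least one epoch")
        eps = tuple(sorted(self.epochs, key=lambda e: -e.start_gen))
        object.__setattr__(self, "epochs", eps)
        if eps[-1].end_gen != 0:
            raise ValueError("youngest epoch must end at the present (end_gen=0)")
        for older, younger in zip(eps, eps[1:]):
            if older.end_gen != younger.start_gen:
                raise ValueError(
                    f"epochs must tile with no gaps/overlaps: "
                    f"[{older.start_gen},{older.end_gen}) then "
                    f"[{younger.start_gen},{younger.end_gen})"
                )
        if self.burnin_generations < 1:
            raise ValueError("burn-in must last at least one generation")
        if self.burnin_size < 2:
            raise ValueError("burn-in size must be >= 2")

    @property
    def model_start(self) -> int:
        """Oldest epoch boundary (generations before present), excluding burn-in."""
        return self.epochs[0].start_gen

    @property
    def total_span(self) -> int:
        return self.burnin_generations + self.model_start

    def size_at(self, g: int) -> int:
        """Diploid size of the epoch containing generation ``g`` before present.

        Generations older than ``model_start`` (including anything beyond the
        nominal burn-in span) return the burn-in size.
        """
        if g < 0:
            raise ValueError(f"generation before present must be >= 0, got {g}")
        if g >= self.model_start:
            return self.burnin_size
        for e in self.epochs:
            if e.start_gen > g >= e.end_gen:
                return e.size
        raise AssertionError("unreachable: epochs tile [0, model_start)")

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(lengths, sizes) oldest-first, with the burn-in as the first entry.

        This is the flat representation consumed by the simulation kernels.
        """
        lengths = [self.burnin_generations] + [e.length for e in self.epochs]
        sizes = [self.burnin_size] + [e.size for e in self.epochs]
        return np.asarray(lengths, dtype=np.int64), np.asarray(sizes, dtype=np.int64)

    def with_burnin(self, generations: int) -> "EpochSchedule":
        """Same history with a rescaled burn-in length (desk-scale runs)."""
        return replace(self, burnin_generations=int(generations))


def constant_schedule(size: int, span: int = 1, burnin_generations: int | None = None) -> EpochSchedule:
    """A constant-size history: one epoch of ``span`` generations plus burn-in.

    With the default burn-in of ``10 * size`` generations the population is at
    equilibrium when the epoch era starts.
    """
    if burnin_generations is None:
        burnin_generations = 10 * int(size)
    return EpochSchedule(
        epochs=(Epoch(start_gen=span, end_gen=0, size=int(size)),),
        burnin_generations=int(burnin_generations),
        burnin_size=int(size),
    )


def _default_epoch_table() -> pd.DataFrame:
    ref = importlib.resources.files("lofsel").joinpath("data/schiffels_durbin_eur_approx.tsv")
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def build_default_schedule(variant: str = "modified") -> EpochSchedule:
    """The packaged European demographic model.

    Parameters
    ----------
    variant
        ``"standard"``: the history ends with N_e = 613,285 over the most
        recent 124 generations.  ``"modified"``: identical except the most
        recent 50 generations have N_e = 5,000,000 (generations 50-124 before
        present remain at 613,285).
    """
    if variant not in ("standard", "modified"):
        raise ValueError(f"unknown demographic variant {variant!r}; use 'standard' or 'modified'")
    table = _default_epoch_table()
    epochs: list[Epoch] = [
        Epoch(int(r.start_gen), int(r.end_gen), int(r.size)) for r in table.itertuples()
    ]
    if variant == "modified":
        # split the terminal 613,285 epoch and graft on the recent growth spurt
        last = epochs.pop()
        assert last.size == _RECENT_SIZE and last.end_gen == 0
        epochs.append(Epoch(last.start_gen, _GROWTH_SPAN, last.size))
        epochs.append(Epoch(_GROWTH_SPAN, 0, _GROWTH_SIZE))
    return EpochSchedule(
        epochs=tuple(epochs),
        burnin_generations=DEFAULT_BURNIN_GENERATIONS,
        burnin_size=DEFAULT_BURNIN_SIZE,
    )


def read_schedule_tsv(
    path: str | Path,
    burnin_generations: int,
    burnin_size: int,
) -> EpochSchedule:
    """Read an epoch table (columns: start_gen, end_gen, size) from TSV."""
    table = pd.read_csv(path, sep="\t")
    missing = {"start_gen", "end_gen", "size"} - set(table.columns)
    if missing:
        raise ValueError(f"epoch table {path} missing columns: {sorted(missing)}")
    epochs = tuple(Epoch(int(r.start_gen), int(r.end_gen), int(r.size)) for r in table.itertuples())
    return EpochSchedule(epochs=epochs, burnin_generations=burnin_generations, burnin_size=burnin_size)


def write_schedule_tsv(schedule: EpochSchedule, path: str | Path) -> None:
    pd.DataFrame(
        {
            "start_gen": [e.start_gen for e in schedule.epochs],
            "end_gen": [e.end_gen for e in schedule.epochs],
            "size": [e.size for e in schedule.epochs],
        }
    ).to_csv(path, sep="\t", index=False)
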