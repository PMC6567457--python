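"""Per-location behavioral labels and run-length segments.

Every segmentation method in this package emits a :class:`StateSequence`:
one label per GPS location, drawn from {foraging, commuting, omitted}.
"Omitted" marks locations a method cannot classify (e.g. trip ends that
lack a turn angle, or path ends where first-passage time is undefined);
downstream evaluation excludes them from both error-rate denominators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

COMMUTING: int = 0
FORAGING: int = 1
OMITTED: int = -1

LABEL_NAMES = {COMMUTING: "commuting", FORAGING: "foraging", OMITTED: "omitted"}
NAME_LABELS = {v: k for k, v in LABEL_NAMES.items()}


@dataclass
class Segment:
    """Maximal run of identical non-omitted labels."""

    start: int          # index of first location in the run
    stop: int           # exclusive
    label: int
    n_locations: int

    def duration(self, dt: float) -> float:
        return self.n_locations * dt


@dataclass
class StateSequence:
    """Per-location behavioral labels for one trip.

    Parameters
    ----------
    labels
        Integer array, one entry per GPS location: ``FORAGING`` (1),
        ``COMMUTING`` (0) or ``OMITTED`` (-1).
    dt
        Nominal fix interval in seconds, used to convert run lengths to
        durations.
    trip_id, method
        Bookkeeping tags carried through to evaluation tables.
    """

    labels: np.ndarray
    dt: float = 15.0
    trip_id: str = ""
    method: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        bad = ~np.isin(self.labels, (COMMUTING, FORAGING, OMITTED))
        if bad.any():
            raise ValueError(f"unknown state codes: {np.unique(self.labels[bad])}")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_omitted(self) -> int:
        return int(np.sum(self.labels == OMITTED))

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label

    def segments(self) -> list[Segment]:
        """Maximal runs of identical non-omitted labels.

        Omitted locations are transparent: they neither form segments nor
        break a run whose flanking labels agree, so leading/trailing
        unclassifiable points never split a bout in two.
        """
        keep = self.labels != OMITTED
        idx = np.nonzero(keep)[0]
        if idx.size == 0:
            return []
        lab = self.labels[idx]
        # boundaries where the label changes within the kept subsequence
        change = np.nonzero(np.diff(lab))[0]
        starts = np.concatenate(([0], change + 1))
        stops = np.concatenate((change + 1, [lab.size]))
        return [
            Segment(
                start=int(idx[a]),
                stop=int(idx[b - 1]) + 1,
                label=int(lab[a]),
                n_locations=int(b - a),
            )
            for a, b in zip(starts, stops)
        ]

    def iter_names(self) -> Iterator[str]:
        for v in self.labels:
            yield LABEL_NAMES[int(v)]


def from_names(names, dt: float = 15.0, trip_id: str = "", method: str = "") -> StateSequence:
    """Build a StateSequence from string labels ('foraging' / 'commuting' / 'omitted')."""
    try:
        codes = np.array([NAME_LABELS[str(s)] for s in names], dtype=np.int8)
    except KeyError as e:  # pragma: no cover - message only
        raise ValueError(f"unknown state name: {e}") from None
    return StateSequence(codes, dt=dt, trip_id=trip_id, method=method)
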