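"""Labeled OS/CS dwell durations with censoring flags.

The first and last dwell of every trace are right/left-censored by the
recording window and are excluded from likelihood fits; dwells shorter than
the applied minimum-dwell cutoff ``t_min`` are discarded during extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["DwellSet"]

_LABELS = ("CS", "OS")


@dataclass
class DwellSet:
    """Alternating labeled dwell durations (s) from one or more traces."""

    labels: np.ndarray          # array of "OS"/"CS"
    durations: np.ndarray       # seconds, > 0
    censored: np.ndarray        # bool, True for window-truncated dwells
    t_min: float = 0.0          # applied minimum-dwell cutoff (s)
    starts: np.ndarray | None = None  # optional dwell start times (s)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        self.durations = np.asarray(self.durations, dtype=float)
        self.censored = np.asarray(self.censored, dtype=bool)
        if not (len(self.labels) == len(self.durations) == len(self.censored)):
            raise ValueError("labels, durations and censored must have equal length")
        if np.any(self.durations <= 0):
            raise ValueError("durations must be > 0")
        bad = set(self.labels) - set(_LABELS)
        if bad:
            raise ValueError(f"unknown dwell labels: {bad}")

    def __len__(self) -> int:
        return len(self.durations)

    def select(self, label: str, censored: bool | None = False) -> np.ndarray:
        """Durations with the given label; by default uncensored only."""
        m = self.labels == label
        if censored is not None:
            m &= self.censored == censored
        return self.durations[m]

    def uncensored(self, label: str) -> np.ndarray:
        """Uncensored retained durations (>= t_min) for fitting."""
        d = self.select(label, censored=False)
        return d[d >= self.t_min]

    @staticmethod
    def concatenate(sets: list["DwellSet"]) -> "DwellSet":
        if not sets:
            raise ValueError("nothing to concatenate")
        t_min = sets[0].t_min
        return DwellSet(
            labels=np.concatenate([s.labels for s in sets]),
            durations=np.concatenate([s.durations for s in sets]),
            censored=np.concatenate([s.censored for s in sets]),
            t_min=t_min,
        )
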