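"""Stimulation-event records: one subject, one world coordinate, binary outcome flags."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError


@dataclass(frozen=True)
class StimulationRecord:
    """A single stimulation event.

    Parameters
    ----------
    subject_id
        Opaque subject identifier; repeated stimulations share it.
    world_mm
        World (MNI) coordinate of the stimulated locus, millimetres.
    behaviours
        Mapping from behaviour name to a binary outcome flag. A locus may
        carry several positive flags at once: the behavioural classification
        is not mutually exclusive.
    """

    subject_id: str
    world_mm: tuple[float, float, float]
    behaviours: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if len(self.world_mm) != 3:
            raise InvalidArgumentError("world_mm must have three components")
        for name, flag in self.behaviours.items():
            if flag not in (0, 1):
                raise InvalidArgumentError(
                    f"behaviour {name!r} flag must be 0 or 1, got {flag!r}"
                )

    def flag(self, behaviour: str) -> int:
        return int(self.behaviours[behaviour])


def behaviour_vector(records: list[StimulationRecord], behaviour: str) -> np.ndarray:
    """Binary outcome vector for one behaviour, aligned with ``records``."""
    return np.array([r.flag(behaviour) for r in records], dtype=float)


def subject_ids(records: list[StimulationRecord]) -> list[str]:
    """Unique subject identifiers in sorted order."""
    return sorted({r.subject_id for r in records})


def subject_blocks(records: list[StimulationRecord]) -> dict[str, np.ndarray]:
    """Row-index arrays grouped per subject (sorted subject order)."""
    out: dict[str, list[int]] = {}
    for i, r in enumerate(records):
        out.setdefault(r.subject_id, []).append(i)
    return {s: np.asarray(out[s], dtype=int) for s in sorted(out)}


def coords_array(records: list[StimulationRecord]) -> np.ndarray:
    """(n, 3) array of world coordinates."""
    return np.array([r.world_mm for r in records], dtype=float)
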