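"""The cyclic breath-hold paradigm and its timing arithmetic.

One cycle is natural breathing, then visually paced breathing, then an
end-expiration breath-hold; the cycle repeats a fixed number of times while
BOLD volumes are acquired every TR seconds.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Paradigm:
    """Timing of the breath-hold task.

    Defaults are the standard protocol: 14 s natural breathing, 16 s paced
    breathing, a 15 s end-expiration hold, six cycles, TR = 2 s.
    """

    natural_s: float = 14.0
    paced_s: float = 16.0
    hold_s: float = 15.0
    n_cycles: int = 6
    tr: float = 2.0

    def __post_init__(self) -> None:
        for name in ("natural_s", "paced_s", "hold_s", "tr"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")

    @property
    def cycle_s(self) -> float:
        """Duration of one natural + paced + hold cycle in seconds."""
        return self.natural_s + self.paced_s + self.hold_s

    @property
    def total_s(self) -> float:
        """Total task duration in seconds."""
        return self.cycle_s * self.n_cycles

    def hold_windows(self) -> list[tuple[float, float]]:
        """(start, end) of every breath-hold period, in seconds from task onset."""
        off = self.natural_s + self.paced_s
        return [
            (k * self.cycle_s + off, (k + 1) * self.cycle_s)
            for k in range(self.n_cycles)
        ]

    def n_frames(self, tr: float | None = None, drop_first: int = 0) -> int:
        """Number of BOLD frames covering the task, minus ``drop_first`` dummies."""
        tr = self.tr if tr is None else tr
        n = int(self.total_s / tr) - drop_first
        if n <= 0:
            raise ValueError("paradigm shorter than the frames requested")
        return n


def make_paradigm(**overrides: float) -> Paradigm:
    """Build a :class:`Paradigm`, overriding any timing field by keyword."""
    return Paradigm(**overrides)
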