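"""Pacing protocols: fixed-rate trains, variable-rate (restitution) ramps,
and spontaneous (unpaced) recordings."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PacingProtocol"]


@dataclass
class PacingProtocol:
    """Stimulus schedule for a recording.

    ``fixed`` and ``ramp`` protocols carry explicit stimulus times (ms);
    ``ramp`` additionally records which rate step each stimulus belongs to,
    so restitution analysis can discard non-steady-state beats per step.
    ``spontaneous`` has no stimuli; beats are found from the signal itself.
    """

    mode: str  # "fixed" | "ramp" | "spontaneous"
    stimulus_times: np.ndarray | None = None
    step_of_stimulus: np.ndarray | None = None  # ramp only: rate-step index
    step_bpm: np.ndarray | None = None  # ramp only: bpm per step
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("fixed", "ramp", "spontaneous"):
            raise ValueError(f"unknown pacing mode {self.mode!r}")
        if self.mode == "spontaneous":
            return
        if self.stimulus_times is None:
            raise ValueError(f"{self.mode} protocol requires stimulus times")
        self.stimulus_times = np.asarray(self.stimulus_times, dtype=float)
        if np.any(np.diff(self.stimulus_times) <= 0):
            raise ValueError("stimulus times must be strictly increasing")
        if self.mode == "ramp":
            if self.step_of_stimulus is None:
                raise ValueError("ramp protocol requires step_of_stimulus")
            self.step_of_stimulus = np.asarray(self.step_of_stimulus, dtype=int)
            if self.step_of_stimulus.size != self.stimulus_times.size:
                raise ValueError("step_of_stimulus must align with stimulus_times")

    @property
    def n_stimuli(self) -> int:
        return 0 if self.stimulus_times is None else int(self.stimulus_times.size)

    @classmethod
    def fixed(
        cls, rate_hz: float = 1.0, n_beats: int = 10, start_ms: float = 50.0
    ) -> "PacingProtocol":
        """Fixed-rate train: ``n_beats`` stimuli at ``rate_hz`` starting at ``start_ms``."""
        if rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        cl = 1000.0 / rate_hz
        times = start_ms + cl * np.arange(n_beats)
        return cls("fixed", stimulus_times=times, meta={"rate_hz": rate_hz})

    @classmethod
    def ramp(
        cls,
        bpm_start: float = 60.0,
        bpm_end: float = 200.0,
        bpm_step: float = 10.0,
        beats_per_step: int = 8,
        start_ms: float = 50.0,
    ) -> "PacingProtocol":
        """Variable-rate ramp covering ``bpm_start``–``bpm_end``.

        Default mirrors a dynamic-restitution protocol: 60→200 bpm in 10 bpm
        increments, 8 paced beats per step.
        """
        if not (bpm_start > 0 and bpm_end > bpm_start and bpm_step > 0):
            raise ValueError("ramp requires 0 < bpm_start < bpm_end and bpm_step > 0")
        bpms = np.arange(bpm_start, bpm_end + 1e-9, bpm_step)
        times: list[float] = []
        steps: list[int] = []
        t = start_ms
        for i_step, bpm in enumerate(bpms):
            cl = 60000.0 / bpm
            for _ in range(beats_per_step):
                times.append(t)
                steps.append(i_step)
                t += cl
        return cls(
            "ramp",
            stimulus_times=np.asarray(times),
            step_of_stimulus=np.asarray(steps),
            step_bpm=bpms,
            meta={
                "bpm_start": bpm_start,
                "bpm_end": bpm_end,
                "bpm_step": bpm_step,
                "beats_per_step": beats_per_step,
            },
        )

    @classmethod
    def spontaneous(cls) -> "PacingProtocol":
        return cls("spontaneous")

    def end_time(self, duration_pad_ms: float = 0.0) -> float:
        """Time of last stimulus plus an optional pad (ms)."""
        if self.stimulus_times is None:
            return duration_pad_ms
        return float(self.stimulus_times[-1]) + duration_pad_ms
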