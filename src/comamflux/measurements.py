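"""Measurement containers for parallel labeling experiments."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .emu import EmuNode, TracerSpec


@dataclass
class MidMeasurement:
    """One measured mass-isotopomer distribution (full molecule or fragment)."""

    metabolite: str
    fractions: np.ndarray
    sd: np.ndarray
    positions: tuple[int, ...] | None = None  # None = full molecule

    def __post_init__(self):
        self.fractions = np.asarray(self.fractions, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if self.fractions.shape != self.sd.shape:
            raise ValueError("fractions and sd must have matching shapes")
        if np.any(self.sd <= 0):
            raise ValueError("measurement sds must be positive")

    def target(self, model) -> "str | EmuNode":
        if self.positions is None:
            return self.metabolite
        return EmuNode(self.metabolite, tuple(self.positions))


@dataclass
class LabelingExperiment:
    """MIDs measured under one tracer condition (one replicate)."""

    id: str
    tracers: dict[str, TracerSpec]
    mids: list[MidMeasurement] = field(default_factory=list)

    @property
    def n_independent(self) -> int:
        # closure removes one degree of freedom per MID vector
        return sum(len(m.fractions) - 1 for m in self.mids)


@dataclass
class MeasurementSet:
    """Parallel labeling datasets plus the measured efflux rates.

    ``effluxes`` maps reaction ids to ``(value, sd)``; they are imposed as
    hard constraints on the flux basis (equivalently: pinned parameters), so
    they contribute to neither the residual nor the net degrees of freedom.
    """

    experiments: list[LabelingExperiment]
    effluxes: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def n_independent(self) -> int:
        return sum(e.n_independent for e in self.experiments)
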