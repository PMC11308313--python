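"""Simulation grid: time step, duration and transport slice volume."""

from __future__ import annotations

from dataclasses import dataclass

#: smallest admissible transport slice, mL
SLICE_VOLUME_FLOOR_ML = 1e-5


@dataclass(frozen=True)
class SimulationGrid:
    """Discretization of a simulation run.

    ``dt_h`` is the integrator/transport time step and ``duration_h``
    the simulated span.  ``slice_volume_ml`` controls the resolution of
    the shared-volume slice chain; when ``None`` it defaults to 1/200 of
    the shared volume (with a 1e-5 mL floor), which resolves a push-out
    front to half a percent of the dead volume.
    """

    dt_h: float
    duration_h: float
    slice_volume_ml: float | None = None

    def __post_init__(self) -> None:
        if self.dt_h <= 0:
            raise ValueError(f"dt_h must be > 0, got {self.dt_h}")
        if self.duration_h < self.dt_h:
            raise ValueError("duration_h must be >= dt_h")
        if self.slice_volume_ml is not None and self.slice_volume_ml <= 0:
            raise ValueError("slice_volume_ml must be > 0")

    def resolve_slice_volume(self, shared_volume_ml: float) -> float:
        if self.slice_volume_ml is not None:
            return self.slice_volume_ml
        return max(shared_volume_ml / 200.0, SLICE_VOLUME_FLOOR_ML)

    @property
    def n_steps(self) -> int:
        return int(round(self.duration_h / self.dt_h))
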