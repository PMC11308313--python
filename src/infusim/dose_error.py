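"""Dosing-error curves, integrated errors and mechanism decomposition.

The dosing error of a drug is the difference between its delivered
stock-solution flow at the vascular access point and the rate implied
by the pump settings.  Three mechanisms produce transient errors after
a set-flow change:

* **push-out** — the dead volume still holds the old mixing ratio but
  is expelled at the new total flow;
* **Poiseuille smearing** — laminar washout spreads the composition
  front (first fluid arrives at half the mean transit time, the tail
  lingers);
* **mechanical compliance** — compressible syringe plungers store and
  release volume as branch pressures re-equilibrate, which can even
  drive mixed fluid backwards up the other pumps' lines.

The decomposition runs three nested simulations — (a) rigid syringes
with plug transport, (b) rigid syringes with the laminar kernel,
(c) the full model — and attributes dev(a) to push-out,
dev(b) - dev(a) to the Poiseuille profile and dev(c) - dev(b) to
compliance.  The three components sum to the full-model deviation at
every grid point by construction; the ordering (transport first,
compliance last) is a documented convention, as any ablation ordering
defines a slightly different split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import SimulationGrid
from .hydraulics import InfusionNetwork
from .transport import DoseTimeSeries, simulate_doses

__all__ = [
    "ErrorDecomposition",
    "deviation",
    "integrate_error",
    "decompose",
]


class AlignmentError(ValueError):
    """Time grids of compared series do not match."""


class InvalidWindowError(ValueError):
    """Requested integration window is empty or outside the series."""


@dataclass
class ErrorDecomposition:
    """Per-drug deviation split into mechanism components.

    All component arrays are (n_drugs, n_times) in mL/h;
    ``push_out + poiseuille + compliance == total`` at every point.
    ``integrated`` maps drug -> signed error in mL over the full run,
    with separate overdose/underdose magnitudes.
    """

    times: np.ndarray
    drugs: tuple[str, ...]
    push_out: np.ndarray
    poiseuille: np.ndarray
    compliance: np.ndarray
    total: np.ndarray
    integrated: dict[str, dict[str, float]]

    def to_frame(self):
        import pandas as pd

        frames = []
        for d, drug in enumerate(self.drugs):
            frames.append(
                pd.DataFrame(
                    {
                        "time_h": self.times,
                        "drug": drug,
                        "push_out_ml_h": self.push_out[d],
                        "poiseuille_ml_h": self.poiseuille[d],
                        "compliance_ml_h": self.compliance[d],
                        "total_deviation_ml_h": self.total[d],
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


def deviation(series: DoseTimeSeries) -> np.ndarray:
    """Delivered minus set dose rate, per drug per time point (mL/h)."""
    return series.delivered - series.set_rates


def _check_aligned(a: DoseTimeSeries, b: DoseTimeSeries) -> None:
    if a.drugs != b.drugs or a.times.shape != b.times.shape or not np.allclose(
        a.times, b.times
    ):
        raise AlignmentError("dose series are on different grids")


def integrate_error(
    times: np.ndarray,
    deviation_ml_h: np.ndarray,
    window: tuple[float, float] | None = None,
) -> dict[str, float]:
    """Integrate one drug's deviation curve over a time window.

    Returns the signed error plus the separate overdose (positive part)
    and underdose (negative part) magnitudes, all in mL, by trapezoidal
    quadrature.
    """
    times = np.asarray(times, dtype=float)
    dev = np.asarray(deviation_ml_h, dtype=float)
    if window is None:
        mask = np.ones(times.size, dtype=bool)
    else:
        t0, t1 = window
        if t1 <= t0 or t0 > times[-1] or t1 < times[0]:
            raise InvalidWindowError(f"window {window} outside simulated span")
        mask = (times >= t0) & (times <= t1)
        if mask.sum() < 2:
            raise InvalidWindowError(f"window {window} contains fewer than 2 samples")
    t = times[mask]
    d = dev[mask]
    signed = float(np.trapezoid(d, t))
    overdose = float(np.trapezoid(np.clip(d, 0.0, None), t))
    underdose = float(np.trapezoid(np.clip(-d, 0.0, None), t))
    return {"signed_ml": signed, "overdose_ml": overdose, "underdose_ml": underdose}


def decompose(
    network: InfusionNetwork,
    grid: SimulationGrid,
    initial_mixture: dict[str, float] | None = None,
) -> ErrorDecomposition:
    """Three-way mechanism decomposition by nested ablation.

    Simulates (a) rigid + plug, (b) rigid + laminar kernel, (c) the
    full model on the same grid and differences the deviation curves.
    If the network is configured rigid (all compliances zero) the
    compliance component is identically zero; with the plug kernel
    forced, the Poiseuille component would be too.
    """
    rigid = network.with_compliance_scale(0.0)
    kw = dict(grid=grid, initial_mixture=initial_mixture)
    s_a = simulate_doses(rigid, kernel="plug", **kw)
    s_b = simulate_doses(rigid, kernel="poiseuille", **kw)
    s_c = simulate_doses(network, kernel="poiseuille", **kw)
    _check_aligned(s_a, s_b)
    _check_aligned(s_b, s_c)

    dev_a = deviation(s_a)
    dev_b = deviation(s_b)
    dev_c = deviation(s_c)

    integrated = {}
    for d, drug in enumerate(s_c.drugs):
        entry = integrate_error(s_c.times, dev_c[d])
        for name, component in (
            ("push_out", dev_a[d]),
            ("poiseuille", dev_b[d] - dev_a[d]),
            ("compliance", dev_c[d] - dev_b[d]),
        ):
            comp = integrate_error(s_c.times, component)
            entry[f"{name}_signed_ml"] = comp["signed_ml"]
            entry[f"{name}_abs_ml"] = comp["overdose_ml"] + comp["underdose_ml"]
        integrated[drug] = entry

    return ErrorDecomposition(
        times=s_c.times.copy(),
        drugs=s_c.drugs,
        push_out=dev_a,
        poiseuille=dev_b - dev_a,
        compliance=dev_c - dev_b,
        total=dev_c,
        integrated=integrated,
    )
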