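"""Single-cycle kinetics: 1:1 Langmuir simulation and least-squares fitting.

The binding model is dR/dt = kon*C*(Rmax - R) - koff*R.  Within a phase of
constant analyte concentration C this has the closed form

    association:  R(t) = Req + (R0 - Req) * exp(-(kon*C + koff) * (t - t0)),
                  Req  = kon*C*Rmax / (kon*C + koff)
    dissociation: R(t) = R0 * exp(-koff * (t - t0))

with the response level carried across phase boundaries (no regeneration —
the defining feature of the single-cycle protocol).  Fitting is nonlinear
least squares over (kon, koff, Rmax) in log space, since the rates span
orders of magnitude; KD is reported as koff/kon.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares


class FitError(RuntimeError):
    """The optimizer failed to converge; no best-so-far result is returned."""


def dilution_series(top: float, steps: int, factor: float = 2.0) -> list[float]:
    """Ascending serial-dilution concentrations ending at ``top``.

    ``series[i] = top / factor**(steps - 1 - i)``.
    """
    if top <= 0:
        raise ValueError("top concentration must be positive")
    if steps < 1:
        raise ValueError("steps must be >= 1")
    if factor <= 1:
        raise ValueError("dilution factor must be > 1")
    return [top / factor ** (steps - 1 - i) for i in range(steps)]


@dataclass(frozen=True)
class SckProtocol:
    """Sequential ascending injections without regeneration."""

    concentrations: tuple[float, ...]        # molar, strictly ascending
    association_s: float = 120.0             # per injection
    dissociation_s: float = 10.0             # between injections
    final_dissociation_s: float = 600.0      # after the last injection

    def __post_init__(self) -> None:
        if not self.concentrations:
            raise ValueError("protocol needs at least one injection")
        if any(c <= 0 for c in self.concentrations):
            raise ValueError("concentrations must be strictly positive")
        if any(b <= a for a, b in zip(self.concentrations,
                                      self.concentrations[1:])):
            raise ValueError("concentrations must be strictly ascending")
        for duration in (self.association_s, self.dissociation_s,
                         self.final_dissociation_s):
            if duration <= 0:
                raise ValueError("durations must be positive")

    @classmethod
    def default(cls) -> "SckProtocol":
        """Five 120 s injections (3.125..50 nM, twofold), 10 s gaps, 600 s
        final dissociation."""
        return cls(tuple(dilution_series(50e-9, 5, 2.0)))

    def phases(self) -> list[tuple[str, float, float, float]]:
        """(label, concentration, t_start, t_end) for every phase."""
        out = []
        t = 0.0
        n = len(self.concentrations)
        for i, conc in enumerate(self.concentrations, start=1):
            out.append((f"assoc_{i}", conc, t, t + self.association_s))
            t += self.association_s
            if i < n:
                out.append((f"dissoc_{i}", 0.0, t, t + self.dissociation_s))
                t += self.dissociation_s
            else:
                out.append(("dissoc_final", 0.0, t, t + self.final_dissociation_s))
                t += self.final_dissociation_s
        return out

    @property
    def duration(self) -> float:
        return self.phases()[-1][3]


@dataclass(frozen=True)
class Sensorgram:
    """Time-resolved response with per-point phase labels."""

    time: np.ndarray      # seconds, strictly increasing
    response: np.ndarray  # resonance units
    phase: np.ndarray     # phase label per point

    def __post_init__(self) -> None:
        if not (len(self.time) == len(self.response) == len(self.phase)):
            raise ValueError("time/response/phase must have equal length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_s": self.time, "response_RU": self.response, "phase": self.phase}
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Sensorgram":
        return cls(
            time=frame["time_s"].to_numpy(dtype=float),
            response=frame["response_RU"].to_numpy(dtype=float),
            phase=frame["phase"].to_numpy(dtype=object),
        )


@dataclass(frozen=True)
class KineticFit:
    """Fitted 1:1 Langmuir parameters; ``kd`` is always ``koff/kon``."""

    kon: float           # 1/(M*s)
    koff: float          # 1/s
    rmax: float          # RU
    kd: float            # M
    residual_norm: float
    initial_guess: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if min(self.kon, self.koff, self.rmax) <= 0:
            raise ValueError("kon, koff and Rmax must be positive")
        if abs(self.kon * self.kd - self.koff) > 1e-12 * self.koff:
            raise ValueError("KD inconsistent with koff/kon")


def kd_from_rates(kon: float, koff: float) -> float:
    """Equilibrium dissociation constant KD = koff / kon (molar)."""
    if kon <= 0:
        raise ValueError("kon must be positive")
    if koff < 0:
        raise ValueError("koff must be non-negative")
    return koff / kon


def _model_response(
    times: np.ndarray,
    protocol: SckProtocol,
    kon: float,
    koff: float,
    rmax: float,
    bulk_shift: float | np.ndarray = 0.0,
) -> np.ndarray:
    """Piecewise closed-form response at arbitrary times within the protocol."""
    phases = protocol.phases()
    bulk = np.broadcast_to(
        np.asarray(bulk_shift, dtype=float), (len(protocol.concentrations),)
    )
    response = np.empty_like(times, dtype=float)
    level = 0.0
    injection = -1
    for label, conc, t0, t1 in phases:
        last = label == "dissoc_final"
        mask = (times >= t0) & ((times <= t1) if last else (times < t1))
        dt = times[mask] - t0
        if conc > 0.0:
            injection += 1
            rate = kon * conc + koff
            req = kon * conc * rmax / rate
            values = req + (level - req) * np.exp(-rate * dt)
            response[mask] = values + bulk[injection]
            level = req + (level - req) * math.exp(-rate * (t1 - t0))
        else:
            values = level * np.exp(-koff * dt)
            response[mask] = values
            level = level * math.exp(-koff * (t1 - t0))
    return response


def simulate_sck(
    protocol: SckProtocol,
    kon: float,
    koff: float,
    rmax: float,
    sampling_rate_hz: float = 1.0,
    noise_sd: float = 0.0,
    bulk_shift: float | list[float] = 0.0,
    seed=0,
) -> Sensorgram:
    """Simulate a single-cycle sensorgram from the closed-form model.

    ``bulk_shift`` (scalar or per-injection) is an additive refractive-index
    step applied during association phases only; ``noise_sd`` adds white
    Gaussian noise.
    """
    if min(kon, koff, rmax) < 0 or kon == 0 or rmax == 0:
        raise ValueError("kon and Rmax must be positive; koff non-negative")
    if sampling_rate_hz <= 0:
        raise ValueError("sampling rate must be positive")
    total = protocol.duration
    times = np.arange(0.0, total + 0.5 / sampling_rate_hz, 1.0 / sampling_rate_hz)
    times = times[times <= total]
    response = _model_response(times, protocol, kon, koff, rmax,
                               np.asarray(bulk_shift, dtype=float))
    if noise_sd > 0:
        response = response + np.random.default_rng(seed).normal(
            0.0, noise_sd, size=times.shape
        )
    labels = np.empty(times.shape, dtype=object)
    for label, _, t0, t1 in protocol.phases():
        last = label == "dissoc_final"
        mask = (times >= t0) & ((times <= t1) if last else (times < t1))
        labels[mask] = label
    return Sensorgram(times, response, labels)


def subtract_reference(
    sample: Sensorgram, reference: Sensorgram, interpolate: bool = False
) -> Sensorgram:
    """Differential response: sample minus reference channel.

    Time grids must match exactly unless ``interpolate`` is set, in which
    case the reference is linearly resampled onto the sample grid.
    """
    if sample.time.shape == reference.time.shape and np.allclose(
        sample.time, reference.time
    ):
        ref = reference.response
    elif interpolate:
        ref = np.interp(sample.time, reference.time, reference.response)
    else:
        raise ValueError("time grids differ; pass interpolate=True to resample")
    return Sensorgram(sample.time, sample.response - ref, sample.phase)


def _guess_koff(sensorgram: Sensorgram) -> float:
    """Log-linear slope of the terminal dissociation phase."""
    mask = sensorgram.phase == "dissoc_final"
    t = sensorgram.time[mask]
    r = sensorgram.response[mask]
    keep = r > 0
    if keep.sum() >= 3:
        slope = np.polyfit(t[keep], np.log(r[keep]), 1)[0]
        if slope < 0:
            return float(min(max(-slope, 1e-7), 1.0))
    return 1e-3


def fit_1to1(
    sensorgram: Sensorgram,
    protocol: SckProtocol,
    initial_guess: dict[str, float] | None = None,
    max_iterations: int = 200,
    tolerance: float = 1e-12,
) -> KineticFit:
    """Fit (kon, koff, Rmax) to a sensorgram by nonlinear least squares.

    Optimization runs in log-parameter space.  Without an explicit
    ``initial_guess`` the start point uses the terminal-dissociation slope
    for koff, the peak response for Rmax, and a small multi-start sweep over
    kon decades; the best-converged fit is returned.  Non-convergence raises
    :class:`FitError` with diagnostics.
    """
    times = sensorgram.time
    data = sensorgram.response

    def residuals(log_params: np.ndarray) -> np.ndarray:
        # clip to keep exp() finite when the optimizer probes extreme steps
        kon, koff, rmax = np.exp(np.clip(log_params, -60.0, 60.0))
        return _model_response(times, protocol, kon, koff, rmax) - data

    if initial_guess is not None:
        starts = [(initial_guess["kon"], initial_guess["koff"],
                   initial_guess["rmax"])]
    else:
        koff0 = _guess_koff(sensorgram)
        peak = float(np.max(np.abs(data)))
        rmax0 = max(2.0 * peak, 1e-3)
        starts = [(kon0, koff0, rmax0) for kon0 in (1e3, 1e4, 1e5, 1e6)]

    best = None
    diagnostics = []
    for start in starts:
        result = least_squares(
            residuals,
            np.log(np.asarray(start, dtype=float)),
            method="lm" if len(times) >= 3 else "trf",
            xtol=tolerance, ftol=tolerance, gtol=tolerance,
            max_nfev=max_iterations * 10,
        )
        diagnostics.append((start, result.status, float(result.cost)))
        if result.status > 0 and (best is None or result.cost < best.cost):
            best = result
    if best is None:
        raise FitError(f"1:1 fit did not converge; attempts: {diagnostics}")

    kon, koff, rmax = (float(v) for v in np.exp(best.x))
    return KineticFit(
        kon=kon, koff=koff, rmax=rmax, kd=kd_from_rates(kon, koff),
        residual_norm=float(np.linalg.norm(best.fun)),
        initial_guess={"kon": starts[0][0], "koff": starts[0][1],
                       "rmax": starts[0][2]},
    )
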